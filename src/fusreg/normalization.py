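"""Median-of-ratios normalization and pre-model diagnostics.

Size factors follow the median-of-ratios recipe: per gene, counts are divided
by that gene's geometric mean across samples; a sample's factor is the median
of those ratios over genes expressed in every sample. A shifted-log transform
plus PCA gives a quick look at the main drivers of transcriptome-wide
variability, and an OLS fit of MBA on CE quantifies how collinear the two
dose metrics are (VIF = 1 / (1 - R^2)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def drop_allzero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero counts in every sample (logged)."""
    keep = counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d all-zero genes of %d", n_dropped, len(counts))
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame, method: str = "ratio") -> pd.Series:
    """Per-sample median-of-ratios size factors (not rescaled afterwards).

    ``method="ratio"`` uses only genes with nonzero counts in all samples (the
    classic estimator) and errors if none exist; ``method="poscounts"`` falls
    back to geometric means over positive counts only, usable for sparse data.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    if method == "ratio":
        log_geomean = logc.mean(axis=1)
        usable = np.isfinite(log_geomean)
        if not usable.any():
            raise ValueError(
                "no gene has nonzero counts in all samples; retry with "
                "method='poscounts' (pseudo-reference over positive counts)"
            )
        ratios = logc[usable] - log_geomean[usable, None]
        log_sf = np.median(ratios, axis=0)
    elif method == "poscounts":
        pos = mat > 0
        if not pos.any(axis=1).all():
            raise ValueError("poscounts requires every gene to be expressed somewhere")
        log_geomean = np.where(pos, logc, 0.0).sum(axis=1) / pos.sum(axis=1)
        ratios = np.where(pos, logc - log_geomean[:, None], np.nan)
        log_sf = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    sf = np.exp(log_sf)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def vst_pca(
    counts: pd.DataFrame,
    sf: pd.Series,
    n_top_genes: int = 500,
    n_components: int = 2,
):
    """Shifted-log transform + PCA on the most variable genes.

    transform = log2(count / size_factor + 1); genes are ranked by variance of
    the transformed values, the top ``n_top_genes`` centered and decomposed by
    SVD. Component signs are fixed so the largest-magnitude loading is
    positive, making the output deterministic.

    Returns
    -------
    coords : DataFrame (samples x components, columns PC1..)
    explained_variance_ratio : ndarray
    """
    n_genes, n_samples = counts.shape
    if n_components > n_samples:
        raise ValueError(f"cannot extract {n_components} components from {n_samples} samples")
    if n_top_genes > n_genes:
        raise ValueError(f"n_top_genes = {n_top_genes} exceeds the {n_genes} genes present")
    x = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    order = np.argsort(x.var(axis=1))[::-1][:n_top_genes]
    top = x[order]
    centered = (top - top.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(min(n_components, s.size)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(coords, index=counts.columns, columns=cols), evr


@dataclass
class CollinearityReport:
    """OLS of MBA on CE and the implied variance inflation factor."""

    r_squared: float
    vif: float
    slope: float
    intercept: float
    n_samples_used: int


def variance_inflation_factor(r_squared: float) -> float:
    """VIF = 1 / (1 - R^2); infinite (with warning) at R^2 = 1."""
    if not (0 <= r_squared <= 1):
        raise ValueError("R^2 must lie in [0, 1]")
    if r_squared >= 1.0 - 1e-12:
        warnings.warn("R^2 = 1: predictors perfectly collinear, VIF infinite")
        return float("inf")
    return 1.0 / (1.0 - r_squared)


def collinearity(samples: pd.DataFrame, fus_only: bool = True) -> CollinearityReport:
    """Regress MBA on CE over samples with both metrics measured.

    ``fus_only`` restricts to FUS-treated samples (paired dose measurements);
    untreated baselines carry assigned values and would distort the fit.
    """
    sel = samples["ce"].notna() & samples["mba"].notna()
    if fus_only and "fus" in samples:
        sel &= samples["fus"].astype(int) == 1
    sub = samples.loc[sel]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 samples with paired CE and MBA, found {len(sub)}")
    ce = sub["ce"].to_numpy(dtype=float)
    mba = sub["mba"].to_numpy(dtype=float)
    if np.var(ce) == 0:
        raise ValueError("CE has zero variance among selected samples")
    fit = stats.linregress(ce, mba)
    r2 = float(fit.rvalue**2)
    return CollinearityReport(
        r_squared=r2,
        vif=variance_inflation_factor(r2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_samples_used=int(len(sub)),
    )
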