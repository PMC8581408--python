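"""Per-gene negative-binomial GLMs with continuous dose covariates.

The engine fits, for every gene, a log-link NB regression of counts on one
continuous blood-brain-barrier-disruption metric (contrast enhancement CE or
microbubble activation MBA) plus dummy-coded confounders (sex, anesthesia,
sequencing batch), with median-of-ratios size factors entering as an offset:

    K_ij ~ NB(mu_ij, alpha_i),   ln mu_ij = ln s_j + x_j' beta_i,
    Var(K_ij) = mu_ij + alpha_i mu_ij^2.

Two encodings of the dose-response form share the log link: the
"exponential" form uses the raw metric as covariate (expression proportional
to e^{beta1 * metric}) and the "linear" form uses ln(metric) (expression
proportional to metric^{beta1}, which contains straight proportionality at
beta1 = 1). Untreated samples carry metric = 1, so the linear-form covariate
is exactly 0 at baseline. Crossing form x metric x timepoint gives the 8
model permutations.

Dispersion is estimated gene-wise by maximum adjusted (Cox-Reid) likelihood,
regularized toward a mean-dispersion trend alpha(mu) = a1/mu + a0 via a
log-normal prior, with far outliers kept unshrunken. The metric coefficient
is tested by a Wald z-test and corrected per model with Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, t as t_dist

from .normalization import drop_allzero_genes, size_factors

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-8
ALPHA_MAX = 100.0
DISPERSION_PRIOR_SD = 0.5  # sd of the log-normal shrinkage prior on ln(alpha)
OUTLIER_RATIO = 10.0  # raw dispersion > 10x trend: left unshrunken


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One of the 8 regression permutations (metric x form x timepoint)."""

    metric: str  # "ce" | "mba"
    form: str  # "linear" | "exponential"
    timepoint: str  # "6h" | "24h"
    covariates: Tuple[str, ...] = ("sex", "anesthesia", "batch")
    alpha_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.metric not in ("ce", "mba"):
            raise ValueError(f"metric must be 'ce' or 'mba', got {self.metric!r}")
        if self.form not in ("linear", "exponential"):
            raise ValueError(f"form must be 'linear' or 'exponential', got {self.form!r}")

    @property
    def label(self) -> str:
        return f"{self.metric}_{self.form}_{self.timepoint}"


def enumerate_model_specs(
    covariates: Sequence[str] = ("sex", "anesthesia", "batch"),
    alpha_threshold: float = 0.05,
) -> List[ModelSpec]:
    """All 8 permutations: {CE, MBA} x {linear, exponential} x {6h, 24h}."""
    return [
        ModelSpec(metric=m, form=f, timepoint=t, covariates=tuple(covariates), alpha_threshold=alpha_threshold)
        for m, f, t in itertools.product(("ce", "mba"), ("linear", "exponential"), ("6h", "24h"))
    ]


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient after dropping unestimable columns."""


@dataclass
class DesignMatrix:
    """Realized design for one model: matrix, column labels, bookkeeping."""

    matrix: np.ndarray  # n_samples x p
    columns: List[str]
    sample_ids: List[str]
    metric_col: int
    dropped: List[str] = field(default_factory=list)
    reference_levels: Dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def build_design(samples: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble intercept + metric + dummy-coded confounders for one model.

    Samples are filtered to ``spec.timepoint``; for MBA models, samples without
    a recorded MBA are excluded (untreated samples carry the assigned value 1,
    not a missing value). Covariates with a single level among the selected
    samples are dropped with a warning; the reference level of each retained
    covariate is the lexicographically first.
    """
    sub = samples.loc[samples["timepoint"].astype(str) == spec.timepoint].copy()
    metric_raw = pd.to_numeric(sub[spec.metric], errors="coerce")
    usable = metric_raw.notna()
    if (~usable).any():
        logger.info(
            "model %s: excluding %d samples without measured %s",
            spec.label, int((~usable).sum()), spec.metric,
        )
    sub = sub.loc[usable]
    if len(sub) < 3:
        raise ValueError(f"model {spec.label}: only {len(sub)} usable samples (< 3)")
    metric_vals = metric_raw.loc[usable].to_numpy(dtype=float)
    if (metric_vals <= 0).any():
        raise ValueError(f"{spec.metric} values must be positive (untreated samples are assigned 1)")

    x = metric_vals if spec.form == "exponential" else np.log(metric_vals)

    cols: List[np.ndarray] = [np.ones(len(sub)), x]
    names: List[str] = ["intercept", f"x_{spec.metric}"]
    dropped: List[str] = []
    refs: Dict[str, str] = {}
    for cov in spec.covariates:
        levels = sorted(sub[cov].astype(str).unique())
        if len(levels) < 2:
            dropped.append(cov)
            logger.warning("model %s: covariate %r has a single level, dropped", spec.label, cov)
            continue
        refs[cov] = levels[0]
        for level in levels[1:]:
            cols.append((sub[cov].astype(str) == level).to_numpy(dtype=float))
            names.append(f"{cov}[{level}]")
    mat = np.column_stack(cols)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        aliased = [names[j] for j in range(mat.shape[1]) if abs(r[j, j]) < 1e-10]
        # all-baseline input (every metric value 1, linear form): the metric
        # column is identically 0 and the model degenerates to covariates-only
        # rather than failing
        if aliased == [names[1]] and np.all(mat[:, 1] == 0.0):
            logger.warning(
                "model %s: metric column identically 0 (all samples at baseline); "
                "model reduces to covariates-only", spec.label,
            )
        else:
            raise RankDeficiencyError(
                f"design for model {spec.label} is rank deficient; aliased columns: {aliased}"
            )
    return DesignMatrix(
        matrix=mat, columns=names, sample_ids=list(sub["sample_id"].astype(str)),
        metric_col=1, dropped=dropped, reference_levels=refs,
    )


# ---------------------------------------------------------------------------
# negative-binomial likelihood machinery (vectorized over genes)
# ---------------------------------------------------------------------------

def _nb_loglik(counts: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; ``alpha`` is per gene (G,), arrays (G, n)."""
    a = alpha[:, None]
    inv = 1.0 / a
    ll = (
        gammaln(counts + inv)
        - gammaln(inv)
        - gammaln(counts + 1.0)
        + counts * np.log(a * mu / (1.0 + a * mu))
        - inv * np.log1p(a * mu)
    )
    return ll.sum(axis=1)


def _cox_reid(mu: np.ndarray, alpha: np.ndarray, design: np.ndarray) -> np.ndarray:
    """-0.5 log det (X' W X) with W the NB working weights, per gene."""
    w = mu / (1.0 + alpha[:, None] * mu)  # G x n
    xtwx = np.einsum("np,gn,nq->gpq", design, w, design)
    sign, logdet = np.linalg.slogdet(xtwx)
    logdet = np.where(sign > 0, logdet, np.inf)
    return -0.5 * logdet


def nb_adjusted_loglik(
    counts: np.ndarray, mu: np.ndarray, alpha: np.ndarray, design: Optional[np.ndarray]
) -> np.ndarray:
    """Cox-Reid adjusted profile likelihood in alpha (design=None: unadjusted)."""
    ll = _nb_loglik(counts, mu, alpha)
    if design is not None:
        ll = ll + _cox_reid(mu, alpha, design)
    return ll


def _maximize_log_alpha(
    objective, lo: float = np.log(ALPHA_MIN), hi: float = np.log(ALPHA_MAX),
    n_genes: int = 1, tol: float = 1e-4, max_iter: int = 60,
) -> np.ndarray:
    """Vectorized golden-section maximization of a per-gene objective over ln(alpha).

    ``objective(log_alpha_vector) -> per-gene values``; every gene keeps its
    own bracket, all brackets shrinking simultaneously. Relies on the NB
    profile likelihood being unimodal in ln(alpha) on this bracket.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_genes, lo)
    b = np.full(n_genes, hi)
    for _ in range(max_iter):
        if np.all(b - a < tol):
            break
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = objective(c)
        fd = objective(d)
        take_left = fc > fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
    return (a + b) / 2.0


# ---------------------------------------------------------------------------
# GLM fitting (batched IRLS)
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Batched fit results: coefficients, covariances, fitted means, flags."""

    beta: np.ndarray  # G x p
    cov: np.ndarray  # G x p x p (observed information inverse)
    mu: np.ndarray  # G x n fitted means
    converged: np.ndarray  # G bool
    n_iter: int


def fit_glm(
    counts: np.ndarray,
    sf: np.ndarray,
    design: np.ndarray,
    alpha: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    ridge: float = 1e-8,
) -> GLMFit:
    """IRLS for log-link NB GLMs, all genes at once, offset ln(size factor).

    Fisher-scoring weights mu/(1 + alpha mu) drive the iterations; the reported
    covariance is the inverse observed information evaluated at the optimum.
    Genes whose update exceeds ``max_iter`` iterations without the max absolute
    coefficient change dropping below ``tol`` are flagged unconverged.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    g, n = counts.shape
    p = design.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (g,)).copy()
    log_sf = np.log(sf)[None, :]

    beta = np.zeros((g, p))
    beta[:, 0] = np.log(np.mean(counts / sf[None, :], axis=1) + 1e-6)
    active = np.ones(g, dtype=bool)
    converged = np.zeros(g, dtype=bool)
    eye = ridge * np.eye(p)[None, :, :]

    it = 0
    for it in range(1, max_iter + 1):
        if not active.any():
            break
        b = beta[active]
        y = counts[active]
        al = alpha[active][:, None]
        eta = np.clip(b @ design.T + log_sf, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + al * mu)
        z = (eta - log_sf) + (y - mu) / mu
        xtwx = np.einsum("np,gn,nq->gpq", design, w, design) + eye
        xtwz = np.einsum("np,gn,gn->gp", design, w, z)
        b_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(b_new - b), axis=1)
        beta[active] = b_new
        done = delta < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False

    eta = np.clip(beta @ design.T + log_sf, -30.0, 30.0)
    mu = np.exp(eta)
    # observed information: w_obs = mu (1 + alpha y) / (1 + alpha mu)^2
    al = alpha[:, None]
    w_obs = mu * (1.0 + al * counts) / (1.0 + al * mu) ** 2
    info = np.einsum("np,gn,nq->gpq", design, w_obs, design) + eye
    cov = np.linalg.inv(info)
    return GLMFit(beta=beta, cov=cov, mu=mu, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    """Gene-wise raw, trend-fitted, and final (MAP-shrunken) dispersions."""

    raw: np.ndarray
    trend: np.ndarray
    final: np.ndarray
    base_mean: np.ndarray
    trend_coefs: Tuple[float, float]  # (a0, a1) in alpha(mu) = a1/mu + a0
    outlier: np.ndarray


def _moments_dispersion(norm_counts: np.ndarray) -> np.ndarray:
    m = norm_counts.mean(axis=1)
    v = norm_counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (v - m) / m**2
    return np.clip(np.nan_to_num(a, nan=ALPHA_MIN), ALPHA_MIN, ALPHA_MAX)


def _fit_trend(alpha_hat: np.ndarray, base_mean: np.ndarray) -> Tuple[float, float]:
    """Iteratively reweighted fit of alpha = a1/mu + a0 across genes.

    Gamma-style IRLS (weights 1/fitted^2) with outlier trimming: genes whose
    ratio to the fitted trend leaves [1e-4, 15] are excluded and the fit
    repeated. Raises if too few usable genes remain.
    """
    use = (alpha_hat > ALPHA_MIN * 1.01) & (base_mean > 0)
    if use.sum() < 10:
        raise RuntimeError("too few genes with informative dispersions for a trend fit")
    y = alpha_hat[use]
    z = np.column_stack([np.ones(use.sum()), 1.0 / base_mean[use]])
    keep = np.ones(y.size, dtype=bool)
    coef = np.array([np.median(y), 0.0])
    for _ in range(20):
        zz, yy = z[keep], y[keep]
        fitted = np.maximum(zz @ coef, 1e-10)
        w = 1.0 / fitted**2
        lhs = (zz * w[:, None]).T @ zz
        rhs = (zz * w[:, None]).T @ yy
        new = np.linalg.solve(lhs, rhs)
        new = np.maximum(new, 0.0)
        if np.allclose(new, coef, rtol=1e-4, atol=1e-12):
            coef = new
            break
        coef = new
        ratio = y / np.maximum(z @ coef, 1e-10)
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.sum() < 10:
            raise RuntimeError("trend fit trimmed away nearly all genes")
    if not np.isfinite(coef).all() or coef.sum() <= 0:
        raise RuntimeError("trend fit did not converge to positive coefficients")
    # sanity check against an ill-conditioned design (e.g. no spread in mu):
    # the trend at the central mean must be commensurate with typical alpha
    med_pred = coef[0] + coef[1] / np.median(base_mean[use])
    med_alpha = np.median(y)
    if not (med_alpha / 10 <= med_pred <= med_alpha * 10):
        raise RuntimeError("trend prediction far from the central dispersion (ill-conditioned fit)")
    return float(coef[0]), float(coef[1])


def estimate_dispersions(
    counts: np.ndarray,
    sf: np.ndarray,
    design: np.ndarray,
    prior_sd: float = DISPERSION_PRIOR_SD,
) -> DispersionEstimates:
    """Raw MLE -> mean trend -> log-normal-prior MAP, per gene.

    Raw estimates start from method-of-moments on normalized counts, are used
    to fit the GLM means, then refined by maximizing the Cox-Reid adjusted NB
    likelihood in ln(alpha) at those fixed means. The trend alpha(mu) =
    a1/mu + a0 is fitted across genes by iteratively reweighted regression
    (global mean fallback on failure). Final dispersions maximize adjusted
    likelihood plus a N(ln trend, prior_sd^2) prior on ln(alpha); raw values
    more than 10x the trend are treated as outliers and kept unshrunken.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    g, n = counts.shape
    if n - design.shape[1] < 2:
        raise ValueError("need >= 2 residual degrees of freedom to estimate dispersion")
    norm_counts = counts / sf[None, :]
    base_mean = norm_counts.mean(axis=1)

    alpha_mom = _moments_dispersion(norm_counts)
    fit0 = fit_glm(counts, sf, design, alpha_mom)
    mu = fit0.mu

    def raw_objective(log_a: np.ndarray) -> np.ndarray:
        return nb_adjusted_loglik(counts, mu, np.exp(log_a), design)

    log_raw = _maximize_log_alpha(raw_objective, n_genes=g)
    raw = np.exp(log_raw)

    try:
        a0, a1 = _fit_trend(raw, base_mean)
        trend = np.clip(a1 / np.maximum(base_mean, 1e-12) + a0, ALPHA_MIN, ALPHA_MAX)
    except RuntimeError as err:
        logger.warning("dispersion trend fit failed (%s); using global mean dispersion", err)
        mean_disp = float(np.clip(raw.mean(), ALPHA_MIN, ALPHA_MAX))
        a0, a1 = mean_disp, 0.0
        trend = np.full(g, mean_disp)

    log_trend = np.log(trend)

    def map_objective(log_a: np.ndarray) -> np.ndarray:
        prior = -((log_a - log_trend) ** 2) / (2.0 * prior_sd**2)
        return nb_adjusted_loglik(counts, mu, np.exp(log_a), design) + prior

    log_map = _maximize_log_alpha(map_objective, n_genes=g)
    final = np.exp(log_map)
    outlier = raw > OUTLIER_RATIO * trend
    final = np.where(outlier, raw, final)
    final = np.clip(final, ALPHA_MIN, ALPHA_MAX)
    return DispersionEstimates(
        raw=raw, trend=trend, final=final, base_mean=base_mean,
        trend_coefs=(a0, a1), outlier=outlier,
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def wald_test(
    coef: np.ndarray, se: np.ndarray, df: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-sided Wald test of coef = 0; NaN propagates (unconverged fits).

    With ``df=None`` the reference is the standard normal. The model driver
    passes ``df = n - p`` (residual degrees of freedom) instead: the
    finite-sample distribution of coef/SE has slightly heavier tails than
    normal because SE is estimated, and the Student-t reference restores
    false-discovery calibration at moderate sample sizes.
    """
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se
    z = np.where(se > 0, z, np.nan)
    if df is None:
        p = 2.0 * norm.sf(np.abs(z))
    else:
        if df < 1:
            raise ValueError("df must be >= 1")
        p = 2.0 * t_dist.sf(np.abs(z), df)
    return z, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN entries preserved."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# the 8-model driver
# ---------------------------------------------------------------------------

def fit_model(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    spec: ModelSpec,
    sf: Optional[pd.Series] = None,
    min_mean: float = 0.0,
) -> pd.DataFrame:
    """Fit one model permutation; returns the per-gene FitTable.

    Columns: gene, baseMean, coef, se, stat, pvalue, padj, converged,
    significant. ``coef`` is the metric coefficient on the natural-log scale.
    """
    design = build_design(samples, spec)
    if design.n < 3:
        raise ValueError(f"model {spec.label}: only {design.n} usable samples (< 3)")
    sub = counts[design.sample_ids]
    sub = drop_allzero_genes(sub)
    if sf is None:
        sf_vec = size_factors(sub).to_numpy()
    else:
        sf_vec = sf.loc[design.sample_ids].to_numpy(dtype=float)
    mat = sub.to_numpy(dtype=float)
    base_mean = (mat / sf_vec[None, :]).mean(axis=1)
    keep = base_mean >= min_mean
    sub, mat, base_mean = sub.loc[keep], mat[keep], base_mean[keep]

    disp = estimate_dispersions(mat, sf_vec, design.matrix)
    fit = fit_glm(mat, sf_vec, design.matrix, disp.final)
    j = design.metric_col
    coef = fit.beta[:, j]
    se = np.sqrt(np.maximum(fit.cov[:, j, j], 0.0))
    stat, pval = wald_test(coef, se, df=design.n - design.p)
    stat = np.where(fit.converged, stat, np.nan)
    pval = np.where(fit.converged, pval, np.nan)
    padj = bh_adjust(pval)
    table = pd.DataFrame(
        {
            "gene": sub.index,
            "baseMean": base_mean,
            "coef": coef,
            "se": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "converged": fit.converged,
        }
    ).set_index("gene", drop=False)
    table["significant"] = table["padj"] < spec.alpha_threshold
    table.attrs["spec"] = spec
    table.attrs["design_columns"] = design.columns
    table.attrs["dropped_covariates"] = design.dropped
    table.attrs["n_samples"] = design.n
    return table


def run_models(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    specs: Optional[Sequence[ModelSpec]] = None,
    min_mean: float = 0.0,
    alpha: float = 0.05,
) -> Dict[str, pd.DataFrame]:
    """Fit all (default 8) model permutations; failing specs are skipped.

    Size factors are computed once on the full count matrix and reused for
    every model subset, mirroring a single normalization of the pooled data.
    """
    if specs is None:
        specs = enumerate_model_specs(alpha_threshold=alpha)
    counts = drop_allzero_genes(counts)
    sf = size_factors(counts)
    tables: Dict[str, pd.DataFrame] = {}
    for spec in specs:
        try:
            tables[spec.label] = fit_model(counts, samples, spec, sf=sf, min_mean=min_mean)
        except (ValueError, RankDeficiencyError) as err:
            logger.error("model %s skipped: %s", spec.label, err)
    return tables
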