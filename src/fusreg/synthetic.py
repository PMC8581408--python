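"""Synthetic study generator: metrics, covariates, NB counts, waveforms, gene sets.

Emulates a pooled murine focused-ultrasound (FUS) blood-brain-barrier-disruption
transcriptomic study: ``n_samples`` brains (default 75), of which
``n_fus_positive`` were FUS-treated with a paired contrast-enhancement (CE)
measurement and ``n_mba_measured`` of those also carry a microbubble-activation
(MBA) measurement from passive cavitation detection. Untreated samples are
assigned CE = MBA = 1 (the no-disruption baseline, so ln(metric) = 0).

For treated samples (ln-shifted) CE and MBA are drawn from a correlated
log-normal pair calibrated so the ordinary-least-squares R-squared of MBA on CE
hits a target (default 0.59). Counts are negative-binomial with a log-linear
mean in the metric (raw metric for the "exponential" dose form, ln(metric) for
the "linear" form), per-gene sex/anesthesia/batch offsets, and a dispersion
trend alpha = a1/mu + a0 with log-normal jitter. Ground truth (which genes are
non-null, their coefficients and dispersions) is retained for parameter-recovery
benchmarking.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .gmt import GeneSetCollection, write_gmt  # noqa: F401  (re-exported writer)
from .pcd import WaveformRecord, ResolutionError

LOG_MU_MAX = np.log(1e8)  # clamp for exp() overflow in the count mean


@dataclass
class SimConfig:
    """Study-design and effect-size knobs for the generator.

    Defaults mirror the emulated study design at desk scale: 75 samples with
    27 FUS+ (18 of which have MBA measured) and 2,000 genes.
    """

    n_samples: int = 75
    n_genes: int = 2000
    frac_nonnull: float = 0.1
    effect_size_log: float = 1.0
    ce_mba_r2: float = 0.59
    n_fus_positive: int = 27
    n_mba_measured: int = 18
    dispersion_trend: Tuple[float, float] = (0.05, 3.0)  # (a0, a1)
    dispersion_jitter_sd: float = 0.3
    covariate_effects: Dict[str, float] = field(
        default_factory=lambda: {"sex": 0.2, "anesthesia": 0.4, "batch": 0.1}
    )
    # marginal of ln(metric - 1) for treated samples; a modelling choice, not
    # a literature value (the study never reports CE/MBA marginals)
    ln_metric_mean: float = 0.5
    ln_metric_sd: float = 0.5
    base_log_mean: float = float(np.log(50.0))
    base_log_sd: float = 1.0
    size_factor_sd: float = 0.2
    # restrict ground-truth effects to one metric/form (None = mixed)
    metric: Optional[str] = None  # "ce" | "mba"
    form: Optional[str] = None  # "linear" | "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_nonnull <= 1):
            raise ValueError("frac_nonnull must lie in [0, 1]")
        if not (0 <= self.ce_mba_r2 < 1):
            raise ValueError("ce_mba_r2 must lie in [0, 1)")
        if self.n_fus_positive > self.n_samples:
            raise ValueError("n_fus_positive cannot exceed n_samples")
        if self.n_mba_measured > self.n_fus_positive:
            raise ValueError("n_mba_measured cannot exceed n_fus_positive")
        a0, a1 = self.dispersion_trend
        if a0 < 0 or a1 < 0 or self.dispersion_jitter_sd < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.metric not in (None, "ce", "mba"):
            raise ValueError("metric must be None, 'ce' or 'mba'")
        if self.form not in (None, "linear", "exponential"):
            raise ValueError("form must be None, 'linear' or 'exponential'")


@dataclass
class GroundTruth:
    """Exact generating parameters, kept for recovery benchmarks.

    ``genes`` columns: gene_id, is_nonnull, metric, form, beta0, beta1,
    dispersion. ``samples`` holds the realized covariates and true CE/MBA;
    ``size_factors`` the per-sample scale used when drawing counts.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    size_factors: Optional[pd.Series] = None
    covariate_coefs: Optional[Dict[str, np.ndarray]] = None


@functools.lru_cache(maxsize=32)
def _calibrate_rho(target_r2: float, mean: float, sd: float) -> float:
    """Gaussian-copula correlation giving the target OLS R^2 on raw metrics.

    The metrics are shifted log-normals (1 + exp(mean + sd*Z)), so the raw-scale
    squared Pearson correlation (= OLS R^2) is a monotone but nonlinear function
    of the latent normal correlation rho; we invert it by Monte Carlo with a
    fixed internal stream plus root bracketing.
    """
    if target_r2 == 0.0:
        return 0.0
    rng = np.random.default_rng(20210)
    z1, z2 = rng.standard_normal((2, 200_000))
    ce = 1.0 + np.exp(mean + sd * z1)

    def realized_r2(rho: float) -> float:
        w = rho * z1 + np.sqrt(1.0 - rho**2) * z2
        mba = 1.0 + np.exp(mean + sd * w)
        return float(np.corrcoef(ce, mba)[0, 1] ** 2)

    return float(brentq(lambda r: realized_r2(r) - target_r2, 0.0, 0.999999, xtol=1e-6))


def simulate_metrics(cfg: SimConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Draw the sample table: covariates plus correlated CE/MBA values.

    FUS-negative samples receive CE = MBA = 1 exactly. FUS-positive samples
    draw correlated shifted log-normal metrics; only the first
    ``n_mba_measured`` treated samples have MBA recorded (others get NaN,
    mimicking sessions without usable cavitation data).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_id = [f"S{i + 1:03d}" for i in range(n)]
    fus = np.zeros(n, dtype=int)
    fus[: cfg.n_fus_positive] = 1
    # covariates are spread over both treatment arms and timepoints
    # deterministically (period-4 sex vs period-2 timepoint avoids aliasing)
    idx = np.arange(n)
    sex = np.where((idx // 2) % 2 == 0, "F", "M")
    anesthesia = np.where(rng.random(n) < 0.5, "Iso", "KA")
    batch = np.array([f"b{(i % 3) + 1}" for i in range(n)])
    timepoint = np.where(idx % 2 == 0, "6h", "24h")

    ce = np.ones(n)
    mba = np.ones(n)
    if cfg.n_fus_positive > 0:
        rho = _calibrate_rho(cfg.ce_mba_r2, cfg.ln_metric_mean, cfg.ln_metric_sd)
        z1 = rng.standard_normal(cfg.n_fus_positive)
        z2 = rng.standard_normal(cfg.n_fus_positive)
        w = rho * z1 + np.sqrt(1.0 - rho**2) * z2
        ce[: cfg.n_fus_positive] = 1.0 + np.exp(cfg.ln_metric_mean + cfg.ln_metric_sd * z1)
        mba[: cfg.n_fus_positive] = 1.0 + np.exp(cfg.ln_metric_mean + cfg.ln_metric_sd * w)

    mba_recorded = mba.astype(float).copy()
    # treated sessions beyond n_mba_measured lack cavitation recordings
    mba_recorded[cfg.n_mba_measured : cfg.n_fus_positive] = np.nan

    samples = pd.DataFrame(
        {
            "sample_id": sample_id,
            "sex": sex,
            "anesthesia": anesthesia,
            "batch": batch,
            "timepoint": timepoint,
            "fus": fus,
            "ce": ce,
            "mba": mba_recorded,
        }
    ).set_index("sample_id", drop=False)
    truth_samples = samples.copy()
    truth_samples["mba_true"] = mba
    truth = GroundTruth(genes=pd.DataFrame(), samples=truth_samples)
    return samples, truth


def _draw_gene_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    g = cfg.n_genes
    n_nonnull = int(round(cfg.frac_nonnull * g))
    is_nonnull = np.zeros(g, dtype=bool)
    is_nonnull[:n_nonnull] = True
    metric = np.array(
        [cfg.metric or ("ce" if rng.random() < 0.5 else "mba") for _ in range(g)]
    )
    form = np.array(
        [cfg.form or ("linear" if rng.random() < 0.5 else "exponential") for _ in range(g)]
    )
    beta1 = np.where(is_nonnull, cfg.effect_size_log * rng.choice([-1.0, 1.0], size=g), 0.0)
    beta0 = cfg.base_log_mean + cfg.base_log_sd * rng.standard_normal(g)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:05d}" for i in range(g)],
            "is_nonnull": is_nonnull,
            "metric": metric,
            "form": form,
            "beta0": beta0,
            "beta1": beta1,
        }
    ).set_index("gene_id", drop=False)


def simulate_counts(truth: GroundTruth, cfg: SimConfig) -> pd.DataFrame:
    """Draw the gene x sample NB count matrix implied by the ground truth.

    The log mean of gene i in sample j is
    ``beta0_i + beta1_i * x_ij + sum_c gamma_ic * d_jc + ln(sf_j)`` where
    ``x`` is the metric (exponential form) or its natural log (linear form)
    and ``d`` are dummy-coded covariates with per-gene coefficients. Counts are
    gamma-Poisson draws with dispersion ``alpha_i = a1/mu_i + a0`` times
    log-normal jitter. Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    samples = truth.samples
    if truth.genes.empty:
        truth.genes = _draw_gene_truth(cfg, rng)
    genes = truth.genes
    g, n = len(genes), len(samples)

    mba = samples["mba_true"].to_numpy() if "mba_true" in samples else samples["mba"].to_numpy()
    mba = np.where(np.isnan(mba), 1.0, mba)
    metric_vals = {"ce": samples["ce"].to_numpy(), "mba": mba}

    x = np.empty((g, n))
    for form, transform in (("exponential", lambda v: v), ("linear", np.log)):
        mask = genes["form"].to_numpy() == form
        for met in ("ce", "mba"):
            rows = mask & (genes["metric"].to_numpy() == met)
            x[rows] = transform(metric_vals[met])[None, :]

    log_q = genes["beta0"].to_numpy()[:, None] + genes["beta1"].to_numpy()[:, None] * x

    cov_coefs: Dict[str, np.ndarray] = {}
    for cov, scale in cfg.covariate_effects.items():
        levels = np.sort(samples[cov].unique())
        coefs = scale * rng.standard_normal((g, len(levels) - 1))
        cov_coefs[cov] = coefs
        for k, level in enumerate(levels[1:]):
            log_q += coefs[:, k : k + 1] * (samples[cov].to_numpy() == level)[None, :]

    sf = np.exp(cfg.size_factor_sd * rng.standard_normal(n))
    if np.any(log_q > LOG_MU_MAX):
        warnings.warn("some simulated log-means exceeded the overflow clamp; clipping")
        log_q = np.minimum(log_q, LOG_MU_MAX)
    mu = sf[None, :] * np.exp(log_q)

    q_bar = np.exp(log_q).mean(axis=1)
    a0, a1 = cfg.dispersion_trend
    alpha = a1 / q_bar + a0
    if cfg.dispersion_jitter_sd > 0:
        alpha = alpha * np.exp(cfg.dispersion_jitter_sd * rng.standard_normal(g))
    alpha = np.maximum(alpha, 0.0)

    # gamma-Poisson mixture == NB(mean mu, variance mu + alpha mu^2)
    alpha_eff = np.maximum(alpha, 1e-10)[:, None]
    lam = rng.gamma(shape=1.0 / alpha_eff, scale=alpha_eff * mu)
    counts = rng.poisson(lam)

    genes = genes.assign(dispersion=alpha)
    truth.genes = genes
    truth.size_factors = pd.Series(sf, index=samples.index, name="size_factor")
    truth.covariate_coefs = cov_coefs
    return pd.DataFrame(counts, index=genes.index, columns=samples.index)


def simulate_dataset(cfg: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: metrics then counts. Returns (counts, samples, truth)."""
    samples, truth = simulate_metrics(cfg)
    counts = simulate_counts(truth, cfg)
    return counts, samples, truth


SYNTHETIC_REFERENCE_CENTER = 3.5e6  # documented choice of "insensitive" band


def simulate_waveforms(
    harmonic_amp: float,
    noise_sd: float,
    fs: float,
    n_pulses: int,
    pulse_len: int,
    seed: int,
    harmonic_freq: float = 2.22e6,
    max_band_bin_width: float = 40.0,
) -> WaveformRecord:
    """Per-pulse hydrophone traces: a second-harmonic tone over white noise.

    The tone has continuous phase across the appended pulse train so its
    energy concentrates in one spectral bin. Raises if ``fs`` violates Nyquist
    for the tone, or if the appended record is too short for the band-peak
    statistic (bin width > ``max_band_bin_width``).
    """
    if fs <= 2 * harmonic_freq:
        raise ValueError(
            f"fs = {fs:g} Hz violates Nyquist for a {harmonic_freq:g} Hz tone (need fs > {2 * harmonic_freq:g})"
        )
    total = n_pulses * pulse_len
    bin_width = fs / total
    if bin_width > max_band_bin_width:
        needed = int(np.ceil(fs / max_band_bin_width))
        raise ResolutionError(
            f"appended record of {total} samples gives {bin_width:g} Hz bins; "
            f"need >= {needed} total samples for <= {max_band_bin_width:g} Hz bins"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(total) / fs
    signal = harmonic_amp * np.sin(2 * np.pi * harmonic_freq * t)
    signal = signal + noise_sd * rng.standard_normal(total)
    pulses = [signal[i * pulse_len : (i + 1) * pulse_len] for i in range(n_pulses)]
    return WaveformRecord(pulses=pulses, fs=fs)


def make_toy_gmt(
    n_sets: int,
    sizes: Tuple[int, int],
    seed: int,
    universe: Optional[list] = None,
    n_universe: int = 2000,
) -> GeneSetCollection:
    """Random gene-set collection over a gene universe, for pipeline tests."""
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = [f"G{i + 1:05d}" for i in range(n_universe)]
    universe = list(universe)
    lo, hi = sizes
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("set size bounds must satisfy 1 <= lo <= hi <= |universe|")
    out = GeneSetCollection()
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        out.add(f"SET_{s + 1:04d}", [universe[i] for i in members], "synthetic")
    return out


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def write_metadata_tsv(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("sample_id", drop=False)
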