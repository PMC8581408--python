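"""The NB regression engine: designs, dispersions, IRLS fits, Wald/BH inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusreg import (
    ModelSpec,
    SimConfig,
    bh_adjust,
    build_design,
    enumerate_model_specs,
    estimate_dispersions,
    fit_glm,
    fit_model,
    run_models,
    simulate_dataset,
    wald_test,
)
from fusreg.nb_glm import _maximize_log_alpha, nb_adjusted_loglik
from fusreg.normalization import size_factors


def make_samples(n, timepoint="6h", fus=None, ce=None, mba=None, sex=None, anesthesia=None, batch=None):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "timepoint": timepoint,
            "fus": fus if fus is not None else [1] * n,
            "ce": ce if ce is not None else np.linspace(1.0, 4.0, n),
            "mba": mba if mba is not None else np.linspace(1.0, 5.0, n),
            "sex": sex if sex is not None else [["F", "M"][i % 2] for i in range(n)],
            "anesthesia": anesthesia if anesthesia is not None else [["KA", "Iso"][(i // 2) % 2] for i in range(n)],
            "batch": batch if batch is not None else ["b1"] * n,
        }
    ).set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# model enumeration and design matrices
# ---------------------------------------------------------------------------

def test_exactly_eight_model_permutations():
    specs = enumerate_model_specs()
    assert len(specs) == 8
    assert len({s.label for s in specs}) == 8
    assert {s.metric for s in specs} == {"ce", "mba"}
    assert {s.form for s in specs} == {"linear", "exponential"}
    assert {s.timepoint for s in specs} == {"6h", "24h"}


def test_untreated_linear_covariate_is_exactly_zero():
    samples = make_samples(8, fus=[0] * 8, ce=[1.0] * 8, mba=[1.0] * 8)
    design = build_design(samples, ModelSpec("ce", "linear", "6h"))
    assert np.all(design.matrix[:, design.metric_col] == 0.0)


def test_untreated_exponential_covariate_is_exactly_one():
    samples = make_samples(6, fus=[1, 1, 0, 0, 0, 0], ce=[2.5, 3.0, 1.0, 1.0, 1.0, 1.0])
    design = build_design(samples, ModelSpec("ce", "exponential", "6h"))
    assert np.all(design.matrix[2:, design.metric_col] == 1.0)
    np.testing.assert_allclose(design.matrix[:2, design.metric_col], [2.5, 3.0])


def test_balanced_two_by_two_design_enumeration():
    samples = make_samples(
        8, sex=["F", "F", "M", "M"] * 2, anesthesia=["KA", "Iso"] * 4, batch=["b1"] * 8
    )
    spec = ModelSpec("ce", "linear", "6h", covariates=("sex", "anesthesia"))
    design = build_design(samples, spec)
    assert design.columns == ["intercept", "x_ce", "sex[M]", "anesthesia[KA]"]
    assert np.linalg.matrix_rank(design.matrix) == 4
    assert design.reference_levels == {"sex": "F", "anesthesia": "Iso"}


def test_single_level_covariate_dropped_with_warning(caplog):
    samples = make_samples(6, sex=["F"] * 6)
    with caplog.at_level("WARNING"):
        design = build_design(samples, ModelSpec("ce", "linear", "6h", covariates=("sex",)))
    assert "sex" in design.dropped
    assert design.columns == ["intercept", "x_ce"]


def test_mba_model_excludes_unmeasured_samples():
    mba = [2.0, 3.0, np.nan, np.nan, 1.0, 1.0]
    samples = make_samples(6, fus=[1, 1, 1, 1, 0, 0], mba=mba)
    design = build_design(samples, ModelSpec("mba", "exponential", "6h"))
    assert design.n == 4
    assert design.sample_ids == ["S0", "S1", "S4", "S5"]


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

def test_intercept_only_equal_counts_closed_form():
    counts = np.full((1, 12), 7.0)
    design = np.ones((12, 1))
    fit = fit_glm(counts, np.ones(12), design, alpha=np.array([1e-10]))
    assert fit.beta[0, 0] == pytest.approx(np.log(7.0), abs=1e-8)
    assert fit.converged[0]


def test_poisson_limit_matches_statsmodels_glm(rng):
    """alpha -> 0: coefficients and SEs agree with a Poisson GLM oracle."""
    import statsmodels.api as sm

    n, n_genes = 40, 50
    x = np.column_stack([np.ones(n), rng.uniform(0, 2, n), rng.integers(0, 2, n)])
    sf = np.exp(rng.normal(0, 0.2, n))
    beta_true = rng.normal(0, 0.4, (n_genes, 3))
    beta_true[:, 0] += 3.0
    mu = sf[None, :] * np.exp(beta_true @ x.T)
    counts = rng.poisson(mu).astype(float)
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    fit = fit_glm(counts, sf, x, alpha=np.full(keep.sum(), 1e-8))
    for i in range(counts.shape[0]):
        oracle = sm.GLM(
            counts[i], x, family=sm.families.Poisson(), offset=np.log(sf)
        ).fit()
        np.testing.assert_allclose(fit.beta[i], oracle.params, atol=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov[i])), oracle.bse, atol=1e-4, rtol=1e-3
        )


def test_offset_correctness_under_global_size_factor_scaling():
    """Scaling every size factor by c shifts only the intercept, by -ln c.

    This is the exact invariance the ln(sf) offset must satisfy (for any
    dispersion): the fitted means, hence all non-intercept coefficients, are
    unchanged when the normalization is rescaled.
    """
    cfg = SimConfig(n_genes=40, n_samples=20, n_fus_positive=8, n_mba_measured=8, seed=21)
    counts, samples, _ = simulate_dataset(cfg)
    counts = counts[counts.sum(axis=1) > 0]
    design = build_design(samples.assign(timepoint="6h"), ModelSpec("ce", "linear", "6h"))
    mat = counts[design.sample_ids].to_numpy(float)
    sf = size_factors(counts[design.sample_ids]).to_numpy()
    alpha = np.full(len(mat), 0.1)
    c = 2.7
    base = fit_glm(mat, sf, design.matrix, alpha)
    scaled = fit_glm(mat, c * sf, design.matrix, alpha)
    np.testing.assert_allclose(scaled.beta[:, 0], base.beta[:, 0] - np.log(c), atol=1e-6)
    np.testing.assert_allclose(scaled.beta[:, 1:], base.beta[:, 1:], atol=1e-6)


def test_single_gene_beta_recovery(rng):
    """Known beta1 = 1.0 at n = 75: mean estimate over replicates within 0.1."""
    n = 75
    x = np.column_stack([np.ones(n), np.concatenate([np.zeros(50), rng.uniform(0.7, 1.8, 25)])])
    mu = 50 * np.exp(1.0 * x[:, 1])
    alpha_true = 0.08
    estimates = []
    for _ in range(200):
        lam = rng.gamma(1 / alpha_true, alpha_true * mu)
        y = rng.poisson(lam)[None, :].astype(float)
        fit = fit_glm(y, np.ones(n), x, np.array([alpha_true]))
        estimates.append(fit.beta[0, 1])
    assert np.mean(estimates) == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def test_dispersion_mle_matches_grid_oracle(rng):
    """Vectorized golden-section agrees with a dense grid search per gene."""
    n = 30
    design = np.column_stack([np.ones(n), rng.uniform(0, 2, n)])
    mu = np.exp(3.0 + 0.5 * design[:, 1])[None, :] * np.ones((5, 1))
    counts = rng.poisson(rng.gamma(1 / 0.2, 0.2 * mu)).astype(float)

    def objective(log_a):
        return nb_adjusted_loglik(counts, mu, np.exp(log_a), design)

    log_hat = _maximize_log_alpha(objective, n_genes=5)
    grid = np.linspace(np.log(1e-8), np.log(100), 20001)
    for i in range(5):
        vals = [
            nb_adjusted_loglik(counts[i : i + 1], mu[i : i + 1], np.array([np.exp(g)]), design)[0]
            for g in grid
        ]
        assert log_hat[i] == pytest.approx(grid[int(np.argmax(vals))], abs=1e-3)


def test_poisson_counts_yield_tiny_dispersion(rng):
    n, g = 100, 300
    design = np.column_stack([np.ones(n), rng.uniform(0, 2, n)])
    mu = np.exp(rng.uniform(2, 5, g))[:, None] * np.exp(0.3 * design[:, 1])[None, :]
    counts = rng.poisson(mu).astype(float)
    disp = estimate_dispersions(counts, np.ones(n), design)
    assert np.median(disp.final) <= 0.01


def test_dispersion_trend_parameter_recovery():
    """True trend a1 = 3, a0 = 0.05 recovered within 30% at 2,000 genes."""
    cfg = SimConfig(
        n_genes=2000, n_samples=75, frac_nonnull=0.0,
        dispersion_trend=(0.05, 3.0), dispersion_jitter_sd=0.3,
        metric="ce", form="linear", seed=31,
    )
    counts, samples, _ = simulate_dataset(cfg)
    samples = samples.assign(timepoint="6h")
    design = build_design(samples, ModelSpec("ce", "linear", "6h"))
    sub = counts[design.sample_ids]
    sub = sub[sub.sum(axis=1) > 0]
    disp = estimate_dispersions(
        sub.to_numpy(float), size_factors(sub).to_numpy(), design.matrix
    )
    a0_hat, a1_hat = disp.trend_coefs
    assert a0_hat == pytest.approx(0.05, rel=0.3)
    assert a1_hat == pytest.approx(3.0, rel=0.3)
    assert np.all(disp.final >= 1e-8)


def test_dispersion_outliers_left_unshrunken(rng):
    n, g = 60, 200
    design = np.ones((n, 1))
    mu = np.full((g, n), 100.0)
    alpha = np.full(g, 0.05)
    alpha[0] = 3.0  # one wildly overdispersed gene
    counts = rng.poisson(rng.gamma(1 / alpha[:, None], alpha[:, None] * mu)).astype(float)
    disp = estimate_dispersions(counts, np.ones(n), design)
    assert disp.outlier[0]
    assert disp.final[0] == pytest.approx(disp.raw[0])
    assert disp.final[0] > 1.0


# ---------------------------------------------------------------------------
# Wald test and BH correction
# ---------------------------------------------------------------------------

def test_wald_trivial_values():
    z, p = wald_test(np.array([0.0]), np.array([1.0]))
    assert p[0] == pytest.approx(1.0)
    z, p = wald_test(np.array([1.96]), np.array([1.0]))
    assert p[0] == pytest.approx(0.05, abs=0.001)
    z, p = wald_test(np.array([1.0]), np.array([0.0]))
    assert np.isnan(p[0])


def test_null_pvalues_approximately_uniform():
    """All-null simulation: raw p-values pass a KS test at the 1% level."""
    from scipy import stats

    cfg = SimConfig(n_genes=2000, frac_nonnull=0.0, metric="ce", form="linear", seed=41)
    counts, samples, _ = simulate_dataset(cfg)
    samples = samples.assign(timepoint="6h")
    table = fit_model(counts, samples, ModelSpec("ce", "linear", "6h"))
    pvals = table["pvalue"].dropna().to_numpy()
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_bh_hand_computed_step_up():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_edge_cases():
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    np.testing.assert_allclose(bh_adjust([0.03]), [0.03])
    out = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(out[1]) and not np.isnan(out[0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.uniform(0, 1, 200)
    ours = bh_adjust(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs, rtol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_order_equivariant_and_monotone(pvals):
    p = np.array(pvals)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
    # monotone within the table: larger p never gets a smaller adjusted p
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)
    perm = np.argsort(p, kind="mergesort")[::-1]
    np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], rtol=1e-12)


# ---------------------------------------------------------------------------
# the 8-model driver
# ---------------------------------------------------------------------------

def test_run_models_fits_all_eight(small_dataset):
    counts, samples, _ = small_dataset
    tables = run_models(counts, samples)
    assert len(tables) == 8
    for label, table in tables.items():
        assert {"baseMean", "coef", "se", "stat", "pvalue", "padj", "significant"} <= set(table.columns)
        ok = table.dropna(subset=["padj"])
        assert np.all(ok["padj"] >= ok["pvalue"] - 1e-12)
        assert np.all((ok["padj"] >= 0) & (ok["padj"] <= 1))


def test_sparse_spec_skipped_others_proceed(small_dataset, caplog):
    counts, samples, _ = small_dataset
    crippled = samples.copy()
    # leave fewer than 3 measured MBA values at 6h
    at_6h = crippled.index[(crippled["timepoint"] == "6h")]
    crippled.loc[at_6h[2:], "mba"] = np.nan
    crippled.loc[crippled["timepoint"] == "24h", "mba"] = np.nan
    with caplog.at_level("ERROR"):
        tables = run_models(counts, crippled)
    assert "mba_linear_6h" not in tables and "mba_linear_24h" not in tables
    assert "ce_linear_6h" in tables and len(tables) == 4


def test_matched_model_finds_most_true_positives():
    """Counts generated under exponential/CE: the matched permutation recovers
    at least as many true positives on average as any other permutation."""
    totals = {}
    n_seeds = 6
    for i in range(n_seeds):
        # moderate effect + wide metric spread: power sits in the sensitive
        # regime where the dose-form encoding actually matters
        cfg = SimConfig(
            n_genes=300, metric="ce", form="exponential",
            effect_size_log=0.08, ln_metric_sd=1.0, seed=100 + i,
        )
        counts, samples, truth = simulate_dataset(cfg)
        samples = samples.assign(timepoint="6h")
        tables = run_models(counts, samples, specs=[
            s for s in enumerate_model_specs() if s.timepoint == "6h"
        ])
        for label, table in tables.items():
            nonnull = truth.genes.loc[table.index, "is_nonnull"].to_numpy()
            totals[label] = totals.get(label, 0) + int(
                (table["significant"].to_numpy() & nonnull).sum()
            )
    assert max(totals, key=totals.get) == "ce_exponential_6h"
    # the mismatched metric finds clearly fewer
    assert totals["ce_exponential_6h"] > totals["mba_exponential_6h"]
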