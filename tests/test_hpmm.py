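import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from aseqtl.hpmm import (
    fit_betabin,
    fit_hpmm,
    fit_interaction,
    fit_null,
    pairs_from_observations,
)
from aseqtl.hpmm import test_beta as beta_test  # alias: not a pytest test
from conftest import make_balanced_pairs


# ---------------------------------------------------------------------------
# exact symmetry oracles
# ---------------------------------------------------------------------------


def test_balanced_pairs_give_zero_beta():
    obs = make_balanced_pairs(n_pairs=25, count=40)
    fit = fit_hpmm(obs)
    assert fit.converged
    assert abs(fit.beta) < 1e-6


def test_allele_relabel_antisymmetry(small_dataset):
    fit1 = fit_hpmm(small_dataset)
    flipped = small_dataset.copy()
    flipped["X"] = 1.0 - flipped["X"]
    fit2 = fit_hpmm(flipped)
    assert abs(fit1.beta + fit2.beta) < 1e-6
    # SEs come from a finite-difference Hessian: agreement is step-limited
    assert fit1.se_beta == pytest.approx(fit2.se_beta, abs=1e-4)


def test_offset_scaling_invariance(small_dataset):
    fit1 = fit_hpmm(small_dataset)
    scaled = small_dataset.copy()
    scaled["K"] = scaled["K"] * 10.0
    fit2 = fit_hpmm(scaled)
    assert abs(fit1.beta - fit2.beta) < 1e-6
    assert abs((fit1.mu - np.log(10.0)) - fit2.mu) < 1e-6
    assert fit1.var_b == pytest.approx(fit2.var_b, abs=1e-6)


# ---------------------------------------------------------------------------
# degenerate variance components vs a plain Poisson GLM (statsmodels oracle)
# ---------------------------------------------------------------------------


def test_zero_variance_matches_poisson_glm(small_dataset):
    obs = small_dataset
    fit = fit_hpmm(obs, fix_var_b=0.0, fix_var_eps=0.0)

    Z = sm.add_constant(obs["X"].to_numpy())
    glm = sm.GLM(
        obs["y"].to_numpy(),
        Z,
        family=sm.families.Poisson(),
        offset=np.log(obs["K"].to_numpy()),
    ).fit()
    assert fit.mu == pytest.approx(glm.params[0], abs=1e-5)
    assert fit.beta == pytest.approx(glm.params[1], abs=1e-5)
    assert fit.se_beta == pytest.approx(glm.bse[1], rel=1e-3)
    # and the log-likelihoods agree (no latent effects left)
    assert fit.loglik == pytest.approx(glm.llf, abs=1e-4)


# ---------------------------------------------------------------------------
# tests of beta
# ---------------------------------------------------------------------------


def test_wald_p_value_formula(small_dataset):
    fit = fit_hpmm(small_dataset)
    expected = 2.0 * stats.norm.sf(abs(fit.beta) / fit.se_beta)
    assert beta_test(fit, method="wald") == pytest.approx(expected, rel=1e-12)
    assert fit.p_value == pytest.approx(expected, rel=1e-12)


def test_lrt_matches_chi2_formula(small_dataset):
    fit = fit_hpmm(small_dataset)
    null = fit_null(small_dataset)
    assert null.beta is None and null.p_value is None
    assert null.loglik <= fit.loglik + 1e-6
    stat = max(2.0 * (fit.loglik - null.loglik), 0.0)
    expected = stats.chi2.sf(stat, df=1)
    assert beta_test(fit, method="lrt", null_fit=null) == pytest.approx(expected)


def test_lrt_requires_null_fit(small_dataset):
    fit = fit_hpmm(small_dataset)
    with pytest.raises(ValueError):
        beta_test(fit, method="lrt")
    with pytest.raises(ValueError):
        beta_test(fit, method="nope")


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------


def test_auto_drop_eps_on_non_overdispersed_data():
    # balanced deterministic counts carry no observation-level noise at all
    obs = make_balanced_pairs(n_pairs=30, count=40)
    fit = fit_hpmm(obs)
    assert fit.model == "hpmm_no_eps"
    assert fit.var_eps == 0.0


def test_include_eps_false_sets_label(small_dataset):
    fit = fit_hpmm(small_dataset, include_eps=False)
    assert fit.model == "hpmm_no_eps" and fit.var_eps == 0.0


def test_covariate_enters_fit(small_dataset):
    obs = small_dataset.copy()
    rng = np.random.default_rng(0)
    subjects = obs["subject_id"].unique()
    age = dict(zip(subjects, rng.normal(size=len(subjects))))
    obs["age"] = obs["subject_id"].map(age)
    fit = fit_hpmm(obs, covariates=("age",))
    assert "age" in fit.gamma and np.isfinite(fit.gamma["age"])


def test_counts_and_metadata(small_dataset):
    fit = fit_hpmm(small_dataset)
    n_pairs = (small_dataset.groupby("subject_id").size() == 2).sum()
    assert fit.n_obs == len(small_dataset)
    assert fit.n_subjects == small_dataset["subject_id"].nunique()
    assert fit.n_double_het == n_pairs
    assert fit.var_b > 0


def test_validation_errors():
    obs = make_balanced_pairs(n_pairs=3)
    with pytest.raises(ValueError, match="missing required column"):
        fit_hpmm(obs.drop(columns=["K"]))
    bad = obs.copy()
    bad.loc[0, "y"] = -1.0
    with pytest.raises(ValueError, match="non-negative"):
        fit_hpmm(bad)
    const = obs.copy()
    const["X"] = 1.0
    with pytest.raises(ValueError, match="untestable"):
        fit_hpmm(const)
    triple = pd.concat([obs, obs.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="observations"):
        fit_hpmm(triple)


# ---------------------------------------------------------------------------
# interaction model
# ---------------------------------------------------------------------------


def test_interaction_requires_group_column(small_dataset):
    with pytest.raises(ValueError, match="'D'"):
        fit_interaction(small_dataset)


def test_interaction_fit_fields(small_dataset):
    obs = small_dataset.copy()
    subjects = sorted(obs["subject_id"].unique())
    labels = {s: float(i % 2) for i, s in enumerate(subjects)}
    obs["D"] = obs["subject_id"].map(labels)
    fit = fit_interaction(obs)
    assert fit.converged
    for val in (fit.alpha, fit.delta, fit.se_delta):
        assert np.isfinite(val)
    assert 0.0 < fit.p_delta <= 1.0
    assert set(fit.coef) >= {"(Intercept)", "X", "D", "X:D"}


def test_interaction_constant_group_rejected(small_dataset):
    obs = small_dataset.copy()
    obs["D"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        fit_interaction(obs)


# ---------------------------------------------------------------------------
# beta-binomial comparator
# ---------------------------------------------------------------------------


def test_pairs_from_observations():
    obs = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b", "hom"],
            "y": [30.0, 10.0, 5.0, 15.0, 99.0],
            "X": [1.0, 0.0, 0.0, 1.0, 1.0],
            "K": [50.0] * 5,
        }
    )
    y_eff, n_tot = pairs_from_observations(obs)
    assert list(y_eff) == [30.0, 15.0]
    assert list(n_tot) == [40.0, 20.0]


def test_betabin_balanced_is_centred():
    y = np.full(40, 25.0)
    n = np.full(40, 50.0)
    fit = fit_betabin(y, n)
    assert fit.converged
    # rho sits on its lower bound for equal counts, which limits how
    # sharply L-BFGS-B resolves the (flat) beta direction
    assert abs(fit.beta) < 1e-3
    assert fit.p_value > 0.9


def test_betabin_matches_binomial_glm_without_overdispersion():
    # y ~ Binomial(n, p) exactly proportioned: rho -> 0 and beta -> logit(p)
    rng = np.random.default_rng(3)
    n = np.full(200, 60.0)
    y = rng.binomial(60, 0.62, size=200).astype(float)
    fit = fit_betabin(y, n)
    glm = sm.GLM(
        np.column_stack([y, n - y]), np.ones((len(y), 1)),
        family=sm.families.Binomial(),
    ).fit()
    assert fit.rho < 0.01
    assert fit.beta == pytest.approx(glm.params[0], abs=5e-3)


def test_betabin_drops_zero_totals():
    y = np.array([5.0, 0.0, 8.0])
    n = np.array([10.0, 0.0, 16.0])
    with pytest.warns(UserWarning, match="zero total"):
        fit = fit_betabin(y, n)
    assert fit.n_pairs == 2
    with pytest.raises(ValueError):
        fit_betabin(np.array([0.0]), np.array([0.0]))
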