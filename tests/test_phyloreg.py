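"""Phylogenetic regression machinery: closed forms, reductions, calibration."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sopt
from scipy import special

from thermsds import (
    LambdaCorrelation,
    OUCorrelation,
    Phylogeny,
    ancova_interaction,
    area_weights,
    lambda_correlation_matrix,
    lr_anova,
    ou_correlation_matrix,
    pgls_fit,
    phylo_logistic_fit,
    phylosig_lambda,
    simulate_binary_mk,
    simulate_ou_trait,
    variance_heterogeneity_test,
)
from thermsds.phyloreg import CollinearityError


def ols_oracle(y, X):
    return np.linalg.lstsq(X, y, rcond=None)[0]


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------
def test_ou_two_tips_closed_form():
    t = Phylogeny.from_newick("(A:0.4,B:0.4);")
    m = ou_correlation_matrix(t, 2.0)
    assert m[0, 1] == pytest.approx(np.exp(-2.0 * 0.8))
    assert m[0, 0] == m[1, 1] == 1.0


def test_ou_large_alpha_is_identity(tree5):
    # smallest patristic distance on tree5 is 0.6, so exp(-1e3*0.6) ~ 0
    m = ou_correlation_matrix(tree5, 1e3)
    assert np.allclose(m, np.eye(tree5.n_tips), atol=1e-12)


def test_ou_matrix_matches_brute_force_distances(tree5):
    m = ou_correlation_matrix(tree5, 1.0)
    assert np.allclose(m, np.exp(-tree5.distances))


def test_ou_nonpositive_alpha_rejected(tree5):
    with pytest.raises(ValueError):
        ou_correlation_matrix(tree5, 0.0)


def test_lambda_matrix_limits(tree5):
    assert np.allclose(lambda_correlation_matrix(tree5, 0.0), np.eye(5))
    bm = lambda_correlation_matrix(tree5, 1.0)
    t = np.sqrt(np.diag(tree5.cov))
    assert np.allclose(bm, tree5.cov / np.outer(t, t))
    half = lambda_correlation_matrix(tree5, 0.5)
    off = ~np.eye(5, dtype=bool)
    assert np.allclose(half[off], 0.5 * bm[off])


# ---------------------------------------------------------------------------
# area weights
# ---------------------------------------------------------------------------
def test_area_weights_printed_formula_cases():
    assert np.allclose(area_weights([50.0, 50.0, 50.0]), 1.0)
    assert np.allclose(area_weights([1e2, 1e4]), [1.0, 2.0])
    rng = np.random.default_rng(0)
    areas = rng.uniform(10, 1e6, 20)
    la = np.log10(areas)
    assert np.allclose(area_weights(areas), la / la.min())
    with pytest.raises(ValueError):
        area_weights([0.5, 100.0])
    with pytest.raises(ValueError):
        area_weights([-3.0, 100.0])


# ---------------------------------------------------------------------------
# PGLS core
# ---------------------------------------------------------------------------
def test_star_tree_pgls_equals_ols(star50):
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    y = 1 + 2 * x + rng.normal(size=50)
    X = pd.DataFrame({"const": np.ones(50), "x": x})
    fit = pgls_fit(y, X, star50, LambdaCorrelation(0.0))
    assert np.allclose(fit.params.values, ols_oracle(y, X.values), atol=1e-8)


def test_exact_linear_response_interpolated(tree40):
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = 3.0 - 1.5 * x
    X = pd.DataFrame({"const": np.ones(40), "x": x})
    for corr in (OUCorrelation(2.0), LambdaCorrelation(1.0), OUCorrelation()):
        fit = pgls_fit(y, X, tree40, corr)
        assert fit.params["const"] == pytest.approx(3.0, abs=1e-7)
        assert fit.params["x"] == pytest.approx(-1.5, abs=1e-7)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)


def test_three_way_no_phylogeny_consistency(tree40):
    """OU with huge alpha, lambda 0 and plain OLS agree on one dataset."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = 0.5 + x + rng.normal(size=40)
    X = pd.DataFrame({"const": np.ones(40), "x": x})
    f_ou = pgls_fit(y, X, tree40, OUCorrelation(5e3))
    f_l0 = pgls_fit(y, X, tree40, LambdaCorrelation(0.0))
    ols = ols_oracle(y, X.values)
    assert np.allclose(f_ou.params.values, ols, atol=1e-4)
    assert np.allclose(f_l0.params.values, ols, atol=1e-10)


def test_tip_reordering_invariance(tree40):
    rng = np.random.default_rng(4)
    labels = tree40.tip_labels
    x = pd.Series(rng.normal(size=40), index=labels)
    y = pd.Series(2 * x.values + rng.normal(size=40), index=labels)
    X = pd.DataFrame({"const": np.ones(40), "x": x}, index=labels)
    fit1 = pgls_fit(y, X, tree40, OUCorrelation(1.0))
    perm = rng.permutation(labels)
    fit2 = pgls_fit(y.loc[perm], X.loc[perm], tree40, OUCorrelation(1.0))
    assert np.allclose(fit1.params.values, fit2.params.values, atol=1e-10)
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)


def test_equal_weights_match_unweighted(tree40):
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    X = pd.DataFrame({"const": np.ones(40), "x": x})
    f1 = pgls_fit(y, X, tree40, OUCorrelation(2.0))
    f2 = pgls_fit(y, X, tree40, OUCorrelation(2.0), weights=np.full(40, 1.0))
    assert np.allclose(f1.params.values, f2.params.values, atol=1e-12)


def test_collinear_design_names_columns(tree40):
    x = np.ones(40)
    X = pd.DataFrame({"const": np.ones(40), "dup": x})
    with pytest.raises(CollinearityError, match="dup|const"):
        pgls_fit(np.arange(40.0), X, tree40)


def test_slope_recovery_under_ou_noise(tree40):
    """beta estimates are unbiased under the generating OU model."""
    states = simulate_binary_mk(tree40, rates=(2.0, 2.0), seed=7).tip_states
    X = pd.DataFrame({"const": np.ones(40),
                      "sds": states.values.astype(float)})
    est = []
    for s in range(60):
        noise = simulate_ou_trait(tree40, alpha=3.0, sigma=1.0, seed=s).values
        y = 20.0 - 3.0 * X["sds"].values + noise
        est.append(pgls_fit(y, X, tree40).params["sds"])
    assert np.mean(est) == pytest.approx(-3.0, abs=3 * np.std(est) / np.sqrt(60))


# ---------------------------------------------------------------------------
# LR tests and variance heterogeneity
# ---------------------------------------------------------------------------
def test_lr_identical_models_give_zero(tree40):
    rng = np.random.default_rng(8)
    y = rng.normal(size=40)
    X = pd.DataFrame({"const": np.ones(40)})
    f = pgls_fit(y, X, tree40, OUCorrelation(1.0))
    with pytest.raises(ValueError):  # same parameter count is not nested
        lr_anova(f, f)
    g = pgls_fit(y, X.assign(x=rng.normal(size=40)), tree40, OUCorrelation(1.0))
    res = lr_anova(f, g)
    assert res.df == 1
    assert res.statistic >= 0
    assert 0 <= res.pvalue <= 1


def test_variance_multiplier_df_bookkeeping(tree40):
    rng = np.random.default_rng(9)
    y = rng.normal(size=40)
    group = np.array([0] * 20 + [1] * 20)
    res = variance_heterogeneity_test(y, group, tree40)
    assert res.df == 1  # one extra variance multiplier
    assert res.statistic >= 0 and np.isfinite(res.statistic)
    assert res.variance_multipliers[0] == 1.0


def test_variance_heterogeneity_detects_inflated_group():
    from thermsds import simulate_tree

    tree = simulate_tree(100, seed=31)
    hits = 0
    for s in range(12):
        rng = np.random.default_rng(100 + s)
        base = simulate_ou_trait(tree, alpha=3.0, sigma=1.0, seed=s).values
        group = (np.arange(100) >= 50).astype(int)
        y = base.copy()
        y[group == 1] += rng.normal(0, 2.0, 50)  # variance x ~5 in group B
        hits += variance_heterogeneity_test(y, group, tree).pvalue < 0.05
    assert hits >= 8


def test_variance_heterogeneity_rejects_degenerate_group(tree40):
    y = np.random.default_rng(0).normal(size=40)
    group = np.array([0] * 39 + [1])
    with pytest.raises(ValueError):
        variance_heterogeneity_test(y, group, tree40)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------
def test_ancova_collinear_covariate_rejected(tree40):
    f = np.array([0.0, 1.0] * 20)
    with pytest.raises(CollinearityError):
        ancova_interaction(np.arange(40.0), f, f, tree40)


def test_ancova_detects_differing_slopes(tree40):
    rng = np.random.default_rng(10)
    f = (rng.random(40) < 0.5).astype(float)
    c = rng.normal(size=40)
    hits = 0
    for s in range(15):
        noise = simulate_ou_trait(tree40, alpha=3.0, sigma=0.5, seed=s).values
        y = 1.0 + 0.5 * f + c + 1.5 * f * c + noise
        fit = ancova_interaction(y, f, c, tree40)
        hits += fit.pvalues["sds:duration"] < 0.05
    assert hits >= 12


def test_ancova_interaction_calibrated_under_null(tree40):
    rng = np.random.default_rng(11)
    f = (rng.random(40) < 0.5).astype(float)
    c = rng.normal(size=40)
    hits = 0
    for s in range(40):
        noise = simulate_ou_trait(tree40, alpha=3.0, sigma=0.5, seed=s).values
        y = 1.0 + 0.5 * f + c + noise  # no interaction
        fit = ancova_interaction(y, f, c, tree40)
        hits += fit.pvalues["sds:duration"] < 0.05
    assert hits <= 6  # ~5% nominal


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------
def test_lambda_recovery_for_brownian_trait():
    from thermsds import simulate_tree

    tree = simulate_tree(150, seed=21)
    lams = [phylosig_lambda(
        simulate_ou_trait(tree, alpha=0.0, sigma=1.0, seed=s).values, tree
    ).lambda_hat for s in range(15)]
    assert 0.9 <= np.median(lams) <= 1.05


def test_lambda_destroyed_by_shuffling():
    from thermsds import simulate_tree

    tree = simulate_tree(150, seed=22)
    rng = np.random.default_rng(0)
    lams = []
    for s in range(10):
        y = simulate_ou_trait(tree, alpha=0.0, sigma=1.0, seed=s).values
        lams.append(phylosig_lambda(rng.permutation(y), tree).lambda_hat)
    assert np.median(lams) <= 0.1


def test_lambda_loglik_optimality(tree40):
    y = simulate_ou_trait(tree40, alpha=1.0, sigma=1.0, seed=3).values
    fit = phylosig_lambda(y, tree40)
    assert fit.loglik_hat >= fit.loglik0 - 1e-9
    assert fit.lr_statistic >= 0


def test_lambda_constant_trait_rejected(tree40):
    with pytest.raises(ValueError):
        phylosig_lambda(np.ones(40), tree40)


# ---------------------------------------------------------------------------
# phylogenetic logistic regression
# ---------------------------------------------------------------------------
def firth_oracle(y, X):
    """Independent Firth fit: directly maximize the penalized likelihood."""

    def negpen(beta):
        eta = X @ beta
        mu = special.expit(eta)
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        W = mu * (1 - mu)
        info = X.T @ (X * W[:, None])
        return -(ll + 0.5 * np.linalg.slogdet(info)[1])

    res = sopt.minimize(negpen, np.zeros(X.shape[1]), method="BFGS",
                        options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def test_star_tree_logistic_matches_firth_oracle(star50):
    rng = np.random.default_rng(12)
    x = rng.normal(size=50)
    y = (rng.random(50) < special.expit(0.5 + 1.2 * x)).astype(float)
    X = pd.DataFrame({"const": np.ones(50), "x": x})
    fit = phylo_logistic_fit(y, X, star50, alpha=1e6)
    oracle = firth_oracle(y, X.values)
    assert np.allclose(fit.params.values, oracle, atol=1e-4)


def test_complete_separation_stays_finite(star50):
    x = np.linspace(-2, 2, 50)
    y = (x > 0).astype(float)
    X = pd.DataFrame({"const": np.ones(50), "x": x})
    fit = phylo_logistic_fit(y, X, star50, alpha=1e6)
    assert np.all(np.isfinite(fit.params.values))
    assert fit.separation_flag


def test_single_class_response_rejected(star50):
    X = pd.DataFrame({"const": np.ones(50)})
    with pytest.raises(ValueError):
        phylo_logistic_fit(np.zeros(50), X, star50)


def test_threshold_model_sign_recovery():
    """Latent OU + logistic link: the coefficient sign is recovered."""
    from thermsds import simulate_tree

    tree = simulate_tree(120, seed=23)
    correct = 0
    n_reps = 25
    for s in range(n_reps):
        rng = np.random.default_rng(1000 + s)
        x = simulate_ou_trait(tree, alpha=2.0, sigma=1.0, seed=s).values
        y = (rng.random(120) < special.expit(1.5 * x)).astype(float)
        X = pd.DataFrame({"const": np.ones(120), "x": x})
        fit = phylo_logistic_fit(y, X, tree)
        correct += fit.params["x"] > 0
    assert correct >= int(0.9 * n_reps)
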