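import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from copath.association import (
    CONTRASTS,
    Contrast,
    ContrastInfeasibleError,
    allelic_odds_ratio,
    compute_pcs,
    fit_logistic,
    run_site_gwas,
)
from copath.schemes import classify_frame
from copath.simulate import SimulationConfig, generate_cohort


def newton_oracle(y, x):
    """Independent logistic ML via scipy BFGS on the exact likelihood."""

    def negll(beta):
        eta = x @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = optimize.minimize(negll, np.zeros(x.shape[1]), method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    beta = res.x
    mu = 1 / (1 + np.exp(-(x @ beta)))
    info = (x.T * (mu * (1 - mu))) @ x
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


# --- contrasts --------------------------------------------------------------


def test_contrast_catalog():
    assert CONTRASTS["LB_vs_ctrl"].case_category == "AD-LB+"
    assert CONTRASTS["ADLB_vs_AD"].control_category == "AD+LB-"


def test_contrast_validation():
    with pytest.raises(ValueError):
        Contrast("bad", "AD+LB+", "AD+LB+")
    with pytest.raises(ValueError):
        Contrast("bad", "AD+LB+", "unclassified")


# --- PCA --------------------------------------------------------------------


def test_pcs_rank_one_recovers_generator():
    rng = np.random.default_rng(0)
    v = rng.normal(size=80)
    dosages = np.clip(np.outer(np.full(5, 0.35), v) + 1.0, 0, 2)
    pcs = compute_pcs(dosages, k=1)
    r = np.corrcoef(pcs[:, 0], v)[0, 1]
    assert abs(r) > 0.9999


def test_pcs_permutation_equivariance():
    rng = np.random.default_rng(1)
    dosages = rng.binomial(2, 0.3, size=(40, 60)).astype(float)
    pcs = compute_pcs(dosages, k=3)
    perm = rng.permutation(60)
    pcs_perm = compute_pcs(dosages[:, perm], k=3)
    assert np.allclose(pcs_perm, pcs[perm], atol=1e-8)


def test_pcs_separate_planted_subpopulations():
    config = SimulationConfig(
        n_per_site=(250, 250), n_variants=200, pop_divergence_fst=0.1, seed=7,
        genotype_missing_rate=0.0, duplicate_rate=0.0, first_degree_rate=0.0,
    )
    _, gm, _, truth = generate_cohort(config)
    pcs = compute_pcs(gm.dosages, k=2)
    r = np.corrcoef(pcs[:, 0], truth.subpopulation)[0, 1]
    assert abs(r) > 0.9


def test_pcs_constant_matrix_errors():
    with pytest.raises(ValueError):
        compute_pcs(np.ones((5, 30)), k=2)


def test_pcs_deterministic_sign():
    rng = np.random.default_rng(2)
    dosages = rng.binomial(2, 0.4, size=(30, 50)).astype(float)
    assert np.array_equal(compute_pcs(dosages, k=4), compute_pcs(dosages, k=4))


# --- logistic fitter --------------------------------------------------------


def test_fit_matches_newton_oracle_with_covariates():
    rng = np.random.default_rng(3)
    n = 200
    dose = rng.binomial(2, 0.3, n).astype(float)
    cov = rng.normal(size=(n, 2))
    eta = -0.5 + 0.8 * dose + 0.3 * cov[:, 0] - 0.2 * cov[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    res = fit_logistic(y, dose, cov)
    x = np.column_stack([np.ones(n), dose, cov])
    beta_o, se_o = newton_oracle(y, x)
    assert res.beta == pytest.approx(beta_o[1], abs=1e-6)
    assert res.se == pytest.approx(se_o[1], abs=1e-6)
    assert res.converged and not res.firth_used


def test_fit_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    n = 150
    dose = rng.binomial(2, 0.25, n).astype(float)
    y = (rng.random(n) < 0.3 + 0.1 * dose).astype(float)
    res = fit_logistic(y, dose)
    x = np.column_stack([np.ones(n), dose])
    sm_fit = statsmodels.Logit(y, x).fit(disp=0, tol=1e-12)
    assert res.beta == pytest.approx(sm_fit.params[1], abs=1e-6)
    assert res.se == pytest.approx(sm_fit.bse[1], abs=1e-6)


def test_fit_genotype_table_closed_form():
    """A 2x3 genotype table fit equals the cell-likelihood optimum."""
    counts = {(0, 0): 120, (0, 1): 60, (0, 2): 12, (1, 0): 40, (1, 1): 55, (1, 2): 25}
    y = np.concatenate([np.full(c, s, dtype=float) for (s, _), c in counts.items()])
    d = np.concatenate([np.full(c, g, dtype=float) for (_, g), c in counts.items()])
    res = fit_logistic(y, d)

    def negll(beta):  # six-cell likelihood
        ll = 0.0
        for (s, g), c in counts.items():
            eta = beta[0] + beta[1] * g
            ll += c * (s * eta - np.logaddexp(0.0, eta))
        return -ll

    opt = optimize.minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    assert res.beta == pytest.approx(opt.x[1], abs=1e-6)


def test_wald_p_uniform_under_null():
    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(500):
        n = 2000
        dose = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.4).astype(float)
        pvals.append(fit_logistic(y, dose).p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_allele_flip_equivariance():
    rng = np.random.default_rng(6)
    n = 300
    dose = rng.binomial(2, 0.3, n).astype(float)
    cov = rng.normal(size=(n, 1))
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * dose - 0.2)))).astype(float)
    a = fit_logistic(y, dose, cov)
    b = fit_logistic(y, 2.0 - dose, cov)
    assert a.beta == pytest.approx(-b.beta, abs=1e-8)
    assert a.p == pytest.approx(b.p, rel=1e-8)


def test_covariate_location_invariance():
    rng = np.random.default_rng(7)
    n = 400
    dose = rng.binomial(2, 0.3, n).astype(float)
    age = rng.normal(85, 8, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.7 * dose - 1 + 0.02 * (age - 85))))
         ).astype(float)
    a = fit_logistic(y, dose, age)
    b = fit_logistic(y, dose, age + 40.0)
    assert a.beta == pytest.approx(b.beta, abs=1e-7)


def test_fit_errors():
    y = np.array([0.0, 1.0, 0.0, 1.0])
    with pytest.raises(ValueError, match="monomorphic"):
        fit_logistic(y, np.ones(4))
    with pytest.raises(ValueError, match="design"):
        fit_logistic(np.ones(4), np.array([0.0, 1, 2, 1]))
    with pytest.raises(ValueError, match="missing"):
        fit_logistic(y, np.array([0.0, np.nan, 1, 2]))


def test_firth_engages_on_separation():
    # perfectly separated data: ML diverges, Firth gives a finite estimate
    dose = np.array([0.0] * 20 + [2.0] * 20)
    y = np.array([0.0] * 20 + [1.0] * 20)
    res = fit_logistic(y, dose)
    assert res.firth_used
    assert np.isfinite(res.beta) and np.isfinite(res.se)
    assert res.beta > 0


def test_firth_not_triggered_on_balanced_data():
    rng = np.random.default_rng(8)
    for seed in range(5):
        n = 500
        dose = rng.binomial(2, 0.4, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * dose - 0.2)))).astype(float)
        res = fit_logistic(y, dose)
        assert not res.firth_used and res.converged


def test_firth_matches_ml_closely_when_well_conditioned():
    rng = np.random.default_rng(9)
    n = 4000
    dose = rng.binomial(2, 0.4, n).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.4 * dose - 0.3)))).astype(float)
    ml = fit_logistic(y, dose, firth_fallback=False)
    firth = fit_logistic(y, dose + 0.0, firth_fallback=True)
    # force firth by calling the internal path
    from copath.association import _firth

    x = np.column_stack([np.ones(n), dose])
    beta_f, cov_f, conv = _firth(y, x)
    assert conv
    assert beta_f[1] == pytest.approx(ml.beta, abs=5e-3)


# --- allele-count helper ----------------------------------------------------


def test_allelic_or_known_counts():
    # 744/2144 case alleles vs 249/2526 control alleles
    oracle = (744 * (2526 - 249)) / ((2144 - 744) * 249)
    assert allelic_odds_ratio(744, 2144, 249, 2526) == pytest.approx(oracle)
    assert round(allelic_odds_ratio(744, 2144, 249, 2526), 2) == 4.86


def test_allelic_or_validation():
    with pytest.raises(ValueError):
        allelic_odds_ratio(-1, 10, 2, 10)
    with pytest.raises(ValueError):
        allelic_odds_ratio(11, 10, 2, 10)


# --- site GWAS --------------------------------------------------------------


@pytest.fixture(scope="module")
def classified_cohort():
    config = SimulationConfig(n_per_site=(700, 350), n_variants=25, seed=21)
    pheno, gm, kinship, truth = generate_cohort(config)
    pheno = pheno.dropna(subset=["sex", "age_at_death"])
    pheno = pheno[pheno["lewy_dist"] != "olfactory_or_unspecified"].copy()
    pheno["category"] = classify_frame(pheno, "current")
    return pheno, gm, truth


def test_run_site_gwas_schema(classified_cohort):
    pheno, gm, truth = classified_cohort
    res = run_site_gwas(pheno, gm, "AD_vs_ctrl", site="nacc", n_pcs=4)
    assert len(res) > 0
    for col in ("variant", "beta", "se", "p", "n_cases", "n_controls",
                "eaf", "firth_used"):
        assert col in res.columns
    assert (res["p"] > 0).all() and (res["p"] <= 1).all()
    # per-variant missing dosages shrink counts slightly, never grow them
    n_cases_total = (pheno["site"].eq("nacc") & pheno["category"].eq("AD+LB-")).sum()
    assert (res["n_cases"] <= n_cases_total).all()
    assert (res["n_cases"] >= 0.9 * n_cases_total).all()


def test_run_site_gwas_infeasible_contrast(classified_cohort):
    pheno, gm, _ = classified_cohort
    empty_site = pheno[pheno["category"] != "AD-LB+"]
    with pytest.raises(ContrastInfeasibleError, match="LB_vs_ctrl"):
        run_site_gwas(empty_site, gm, "LB_vs_ctrl", site="nacc", n_pcs=4)


def test_run_site_gwas_fit_subset(classified_cohort):
    pheno, gm, truth = classified_cohort
    res = run_site_gwas(pheno, gm, "AD_vs_ctrl", site="nacc", n_pcs=4,
                        fit_variant_ids=[truth.causal_variant_id])
    assert list(res["variant"]) == [truth.causal_variant_id]
    assert res["beta"].iloc[0] > 0  # planted risk effect


def test_run_site_gwas_needs_category_or_scheme(classified_cohort):
    pheno, gm, _ = classified_cohort
    with pytest.raises(ValueError, match="scheme"):
        run_site_gwas(pheno.drop(columns="category"), gm, "AD_vs_ctrl",
                      site="nacc")
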