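"""Per-site case-control association: maximum-likelihood logistic regression
of case status on per-allele dosage with sex, age-at-death and principal
component covariates.

The fitter is written from first principles (iteratively reweighted least
squares, Wald standard errors from the observed information) with a Firth
bias-reduced fallback for separation, because the single-variant logistic
model *is* the statistic reported downstream — no external GWAS tool is
called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .schemes import ClassificationScheme, classify_frame, resolve_scheme
from .variant_qc import alt_allele_frequency, apply_variant_filters

__all__ = [
    "Contrast",
    "CONTRASTS",
    "AssociationResult",
    "ContrastInfeasibleError",
    "allelic_odds_ratio",
    "compute_pcs",
    "fit_logistic",
    "run_site_gwas",
]


def allelic_odds_ratio(
    case_alt: int, case_total: int, control_alt: int, control_total: int
) -> float:
    """Crude (unadjusted) allelic odds ratio from allele counts.

    ``*_total`` are total allele counts (2 x individuals); the OR is
    (case_alt / case_ref) / (control_alt / control_ref).  This is the
    count-table arithmetic used for frequency tables, not the covariate-
    adjusted estimate the regression produces.
    """
    for name, v in [("case_alt", case_alt), ("case_total", case_total),
                    ("control_alt", control_alt), ("control_total", control_total)]:
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer")
    case_ref = case_total - case_alt
    control_ref = control_total - control_alt
    if min(case_ref, control_ref) < 0:
        raise ValueError("alt count exceeds total allele count")
    if case_ref == 0 or control_alt == 0:
        return float("inf")
    return (case_alt * control_ref) / (case_ref * control_alt)

MAX_IRLS_ITER = 25
IRLS_TOL = 1e-10
MAX_FIRTH_ITER = 200


@dataclass(frozen=True)
class Contrast:
    """A case category versus a control category."""

    name: str
    case_category: str
    control_category: str

    def __post_init__(self):
        bad = {"unclassified", "excluded"}
        if self.case_category == self.control_category:
            raise ValueError("case and control categories must differ")
        if self.case_category in bad or self.control_category in bad:
            raise ValueError("contrast categories must be real pathology categories")


#: The four contrasts analyzed throughout: each pathology category against
#: double-negative controls, plus co-pathology against sole-AD.
CONTRASTS = {
    "ADLB_vs_ctrl": Contrast("ADLB_vs_ctrl", "AD+LB+", "AD-LB-"),
    "AD_vs_ctrl": Contrast("AD_vs_ctrl", "AD+LB-", "AD-LB-"),
    "LB_vs_ctrl": Contrast("LB_vs_ctrl", "AD-LB+", "AD-LB-"),
    "ADLB_vs_AD": Contrast("ADLB_vs_AD", "AD+LB+", "AD+LB-"),
}


class ContrastInfeasibleError(RuntimeError):
    """Raised when a site has no cases or no controls for a contrast."""


@dataclass
class AssociationResult:
    variant_id: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    eaf: float
    converged: bool
    firth_used: bool
    or_: float = field(init=False)
    ci95: tuple = field(init=False)

    def __post_init__(self):
        self.or_ = float(np.exp(self.beta))
        self.ci95 = (
            float(np.exp(self.beta - 1.959963984540054 * self.se)),
            float(np.exp(self.beta + 1.959963984540054 * self.se)),
        )


def compute_pcs(
    dosages: np.ndarray, k: int = 10, min_variance: float = 1e-12
) -> np.ndarray:
    """Top-k principal components of a variants x samples dosage matrix.

    Missing dosages are mean-imputed per variant; variants are mean-centered
    and unit-variance standardized; constant variants are ignored.  Signs
    are fixed by making each component's largest-magnitude variant loading
    positive, so results are deterministic.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2:
        raise ValueError("dosages must be a 2-D variants x samples array")
    n_variants, n_samples = d.shape
    if n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    mean = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), mean, d)
    std = d.std(axis=1)
    informative = std > np.sqrt(min_variance)
    if informative.sum() < k:
        raise ValueError(
            f"only {int(informative.sum())} non-constant variants; "
            f"cannot compute {k} components"
        )
    x = (d[informative] - mean[informative]) / std[informative, None]
    # samples x variants
    u, s, vt = np.linalg.svd(x.T / np.sqrt(x.shape[0]), full_matrices=False)
    pcs = u[:, :k] * s[:k]
    loadings = vt[:k]
    for j in range(k):
        lead = np.argmax(np.abs(loadings[j]))
        if loadings[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def _loglik(y, x, beta):
    eta = x @ beta
    # numerically safe log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(y: np.ndarray, x: np.ndarray):
    """Plain ML logistic via IRLS. Returns (beta, cov, converged)."""
    n, p = x.shape
    beta = np.zeros(p)
    ybar = y.mean()
    beta[0] = np.log(ybar / (1 - ybar))  # intercept warm start
    ll_old = _loglik(y, x, beta)
    converged = False
    cov = np.full((p, p), np.nan)
    for _ in range(MAX_IRLS_ITER):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.max(w) < 1e-12:
            break
        xtw = x.T * w
        info = xtw @ x
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        beta_new = beta + step
        ll_new = _loglik(y, x, beta_new)
        # step-halving if the likelihood worsens or overflows
        halves = 0
        while not (np.isfinite(ll_new) and ll_new >= ll_old) and halves < 10:
            step /= 2.0
            beta_new = beta + step
            ll_new = _loglik(y, x, beta_new)
            halves += 1
        beta = beta_new
        if abs(ll_new - ll_old) <= IRLS_TOL * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    if converged:
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = (x.T * w) @ x
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            converged = False
    return beta, cov, converged


def _firth(y: np.ndarray, x: np.ndarray):
    """Firth bias-reduced logistic fit. Returns (beta, cov, converged)."""
    n, p = x.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(MAX_FIRTH_ITER):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        sqw = np.sqrt(w)
        xw = x * sqw[:, None]
        info = xw.T @ xw
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", xw, info_inv, xw)  # hat diagonal
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # damping for stability far from the optimum
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (x.T * w) @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return beta, cov, converged


def fit_logistic(
    case_status: np.ndarray,
    dosage: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "",
    firth_fallback: bool = True,
) -> AssociationResult:
    """Fit case status ~ dosage + covariates; report the dosage coefficient.

    Falls back to Firth bias-reduced likelihood when plain ML fails to
    converge or shows signs of (quasi-)separation (diverging estimate or
    standard error on the dosage term).
    """
    y = np.asarray(case_status, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if y.shape != d.shape or y.ndim != 1:
        raise ValueError("case_status and dosage must be 1-D and aligned")
    if np.isnan(d).any():
        raise ValueError("dosage contains missing values; drop them before fitting")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("case_status must be binary 0/1")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("design error: need at least one case and one control")
    if np.nanstd(d) == 0:
        raise ValueError(f"monomorphic variant {variant_id!r}: constant dosage")

    cols = [np.ones_like(y), d]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if np.isnan(cov).any():
            raise ValueError("covariates contain missing values")
        cols.append(cov)
    x = np.column_stack(cols)

    beta, covm, converged = _irls(y, x)
    se = float(np.sqrt(covm[1, 1])) if np.isfinite(covm[1, 1]) else np.inf
    suspicious = (
        not converged
        or not np.isfinite(se)
        or se > 50.0
        or abs(beta[1]) > 15.0
    )
    firth_used = False
    if suspicious and firth_fallback:
        beta, covm, converged = _firth(y, x)
        se = float(np.sqrt(covm[1, 1])) if np.isfinite(covm[1, 1]) else np.inf
        firth_used = True

    b = float(beta[1])
    z = b / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return AssociationResult(
        variant_id=variant_id,
        beta=b,
        se=se,
        p=p,
        n_cases=n_cases,
        n_controls=n_controls,
        eaf=alt_allele_frequency(d),
        converged=bool(converged),
        firth_used=firth_used,
    )


def run_site_gwas(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    contrast: Union[str, Contrast],
    scheme: Union[str, ClassificationScheme, None] = None,
    site: Optional[str] = None,
    n_pcs: int = 10,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
    miss_max: float = 0.20,
    r2_min: float = 0.8,
    hwe_controls_only: bool = True,
    firth_fallback: bool = True,
    fit_variant_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Classify, select the contrast's case/control subset, QC variants on
    that subset, compute PCs, and fit every surviving variant.

    ``phenotypes`` must carry id/sex/age_at_death and either a ``category``
    column or the staging columns needed by ``scheme``.  Returns one row per
    analyzed variant with the summary-statistics schema used downstream.
    ``fit_variant_ids`` restricts which variants are *fitted* (PCs and QC
    still use the full post-QC panel), useful for targeted lookups.
    """
    if isinstance(contrast, str):
        contrast = CONTRASTS[contrast]
    pheno = phenotypes
    if site is not None:
        pheno = pheno[pheno["site"] == site]
    if "category" in pheno.columns:
        category = pheno["category"]
    else:
        if scheme is None:
            raise ValueError("need either a category column or a scheme")
        category = classify_frame(pheno, resolve_scheme(scheme))

    is_case = category == contrast.case_category
    is_control = category == contrast.control_category
    selected = pheno[is_case | is_control]
    n_cases = int(is_case.sum())
    n_controls = int(is_control.sum())
    if n_cases == 0 or n_controls == 0:
        raise ContrastInfeasibleError(
            f"contrast {contrast.name} infeasible"
            + (f" at site {site!r}" if site else "")
            + f": {n_cases} cases, {n_controls} controls"
        )

    ids = list(selected["id"])
    control_ids = list(pheno.loc[is_control, "id"])
    kept, _report = apply_variant_filters(
        genotypes,
        sample_ids=ids,
        hwe_sample_ids=control_ids if hwe_controls_only else None,
        maf_min=maf_min,
        hwe_p_min=hwe_p_min,
        miss_max=miss_max,
        r2_min=r2_min,
    )
    if kept.n_variants == 0:
        raise ContrastInfeasibleError(
            f"contrast {contrast.name}: no variants survive QC"
        )

    pcs = compute_pcs(kept.dosages, k=min(n_pcs, kept.n_variants, len(ids) - 1))
    y_full = (category.loc[selected.index] == contrast.case_category).to_numpy(float)
    sex = selected["sex"].to_numpy(float)
    aad = selected["age_at_death"].to_numpy(float)
    base_cov = np.column_stack([sex, aad, pcs])

    fit_set = None if fit_variant_ids is None else set(fit_variant_ids)
    rows = []
    for i in range(kept.n_variants):
        if fit_set is not None and kept.variants["id"].iloc[i] not in fit_set:
            continue
        dose = kept.dosages[i]
        ok = ~np.isnan(dose)
        meta = kept.variants.iloc[i]
        try:
            res = fit_logistic(
                y_full[ok],
                dose[ok],
                base_cov[ok],
                variant_id=str(meta["id"]),
                firth_fallback=firth_fallback,
            )
        except ValueError:
            continue  # e.g. monomorphic within non-missing subset
        rows.append(
            {
                "variant": res.variant_id,
                "chrom": meta["chrom"],
                "pos": meta["pos"],
                "effect_allele": meta["alt"],
                "other_allele": meta["ref"],
                "eaf": res.eaf,
                "beta": res.beta,
                "se": res.se,
                "or": res.or_,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "p": res.p,
                "n_cases": res.n_cases,
                "n_controls": res.n_controls,
                "converged": res.converged,
                "firth_used": res.firth_used,
            }
        )
    return pd.DataFrame(rows)
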