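"""Per-variant quality control: allele frequency, exact Hardy-Weinberg test,
missingness and imputation-quality filters.

Boundary semantics are strict: variants are dropped for MAF *below* the
minimum, missingness *above* the maximum, HWE p *below* the threshold, and
imputed variants are kept only with R-squared strictly above the cutoff.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "minor_allele_frequency",
    "alt_allele_frequency",
    "hwe_exact_test",
    "genotype_counts",
    "apply_variant_filters",
]


def alt_allele_frequency(dosages: np.ndarray) -> float:
    """Alt-allele frequency p = sum(dose) / (2 * n non-missing)."""
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all dosages missing; allele frequency undefined")
    return float(d[ok].sum() / (2.0 * n))


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF = min(p, 1-p); invariant to swapping ref/alt (d -> 2-d)."""
    p = alt_allele_frequency(dosages)
    return min(p, 1.0 - p)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one (the mid-free two-sided exact test used by standard QC
    tools).  Returns a p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be nonnegative integers: {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele count
    if rare == 0:
        return 1.0

    # Conditional distribution over heterozygote counts h (same parity as
    # rare), built by the standard two-way recurrence from the mode.
    h_values = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
    probs = {h: 0.0 for h in h_values}
    mode = rare * (2 * n - rare) // (2 * n)
    if mode % 2 != rare % 2:
        mode += 1
    probs[mode] = 1.0
    # going down: P(h-2) = P(h) * h*(h-1) / ((rare-h+2)*(2n-rare-h+2))
    h = mode
    while h - 2 >= h_values[0]:
        probs[h - 2] = probs[h] * (h * (h - 1.0)) / (
            (rare - h + 2.0) * (2 * n - rare - h + 2.0)
        )
        h -= 2
    # going up: P(h+2) = P(h) * 4*nra*nca / ((h+2)*(h+1)) with
    # nra = (rare-h)/2, nca = (2n-rare-h)/2 homozygote counts at h.
    h = mode
    while h + 2 <= h_values[-1]:
        nra = (rare - h) / 2.0
        nca = (2 * n - rare - h) / 2.0
        probs[h + 2] = probs[h] * (4.0 * nra * nca) / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def genotype_counts(
    gm: GenotypeMatrix, variant_index: int, sample_idx: Optional[np.ndarray] = None
) -> tuple:
    """(n_hom_ref, n_het, n_hom_alt) from hard calls, else rounded dosages."""
    source = gm.hard_genotypes if gm.hard_genotypes is not None else gm.dosages
    g = source[variant_index]
    if sample_idx is not None:
        g = g[sample_idx]
    g = g[~np.isnan(g)]
    g = np.clip(np.rint(g), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def apply_variant_filters(
    gm: GenotypeMatrix,
    sample_ids: Optional[Sequence] = None,
    hwe_sample_ids: Optional[Sequence] = None,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
    miss_max: float = 0.20,
    r2_min: float = 0.8,
) -> tuple:
    """Evaluate all per-variant filters on a sample subset.

    Parameters
    ----------
    sample_ids
        Individuals on which MAF/missingness are evaluated (default: all).
    hwe_sample_ids
        Individuals on which the HWE test is evaluated; defaults to
        ``sample_ids`` (pass the control subset to test in controls only).

    Returns
    -------
    (kept, report)
        ``kept`` is the filtered :class:`GenotypeMatrix` restricted to
        ``sample_ids``; ``report`` is a tidy frame with one row per
        (variant, failed filter) — empty if nothing was dropped.  All
        filters are evaluated for every variant, so the dropped set does not
        depend on evaluation order.
    """
    for name, value, lo, hi in [
        ("maf_min", maf_min, 0.0, 0.5),
        ("hwe_p_min", hwe_p_min, 0.0, 1.0),
        ("miss_max", miss_max, 0.0, 1.0),
        ("r2_min", r2_min, 0.0, 1.0),
    ]:
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside [{lo}, {hi}]")

    sub = gm if sample_ids is None else gm.subset_samples(sample_ids)
    if hwe_sample_ids is None:
        hwe_idx = None
        hwe_gm = sub
    else:
        hwe_gm = gm
        hwe_idx = gm.sample_indices(hwe_sample_ids)

    rows = []
    keep = np.ones(sub.n_variants, dtype=bool)
    for i in range(sub.n_variants):
        vid = sub.variants["id"].iloc[i]
        d = sub.dosages[i]
        n_missing = int(np.isnan(d).sum())
        miss_frac = n_missing / len(d) if len(d) else 1.0
        if miss_frac > miss_max:
            rows.append((vid, "missingness", miss_frac))
            keep[i] = False
        if miss_frac < 1.0:
            maf = minor_allele_frequency(d)
            if maf < maf_min:
                rows.append((vid, "low_maf", maf))
                keep[i] = False
        r2 = sub.variants["imputation_r2"].iloc[i]
        if not pd.isna(r2) and not r2 > r2_min:
            rows.append((vid, "low_r2", float(r2)))
            keep[i] = False
        n_rr, n_ra, n_aa = genotype_counts(hwe_gm, i, hwe_idx)
        if n_rr + n_ra + n_aa > 0:
            hwe_p = hwe_exact_test(n_rr, n_ra, n_aa)
            if hwe_p < hwe_p_min:
                rows.append((vid, "hwe", hwe_p))
                keep[i] = False
    report = pd.DataFrame(rows, columns=["variant", "reason", "value"])
    return sub.subset_variants(keep), report
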