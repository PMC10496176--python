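"""Fixed-effect inverse-variance-weighted meta-analysis of per-site summary
statistics, significance flagging, and Manhattan-plot data preparation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "AlleleMismatchError",
    "ivw_meta",
    "meta_analyze",
    "flag_significance",
    "manhattan_data",
    "GENOME_WIDE_THRESHOLD",
]

GENOME_WIDE_THRESHOLD = 5e-8
_P_FLOOR = 1e-320

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlleleMismatchError(ValueError):
    """Raised when study alleles cannot be reconciled for one variant."""


@dataclass
class MetaResult:
    variant_id: str
    beta_meta: float
    se_meta: float
    p_meta: float
    n_studies: int
    betas: tuple
    ses: tuple
    direction: str


def ivw_meta(
    betas: Sequence[float], ses: Sequence[float], variant_id: str = ""
) -> MetaResult:
    """Combine per-study (beta, se) by inverse-variance weighting.

    w_i = 1/se_i^2; beta = sum(w b)/sum(w); se = sum(w)^-1/2; two-sided
    normal p.  Study order is irrelevant.
    """
    betas = tuple(float(b) for b in betas)
    ses = tuple(float(s) for s in ses)
    if len(betas) != len(ses) or not betas:
        raise ValueError("need equal, nonzero numbers of betas and ses")
    if any(not np.isfinite(s) or s <= 0 for s in ses):
        raise ValueError("standard errors must be finite and positive")
    w = np.array([1.0 / s**2 for s in ses])
    beta = float(np.dot(w, betas) / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(min(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)), 1.0))
    direction = "".join("+" if b > 0 else "-" if b < 0 else "0" for b in betas)
    return MetaResult(
        variant_id=variant_id,
        beta_meta=beta,
        se_meta=se,
        p_meta=p,
        n_studies=len(betas),
        betas=betas,
        ses=ses,
        direction=direction,
    )


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_alleles(
    ref_ea: str, ref_oa: str, ea: str, oa: str, beta: float, eaf: float
) -> tuple:
    """Align one study's effect to a reference effect/other allele pair.

    Returns (beta, eaf) on the reference orientation.  A swapped pair flips
    the sign; strand flips are rejected for A/T and C/G ambiguous variants.
    """
    ref_ea, ref_oa, ea, oa = (a.upper() for a in (ref_ea, ref_oa, ea, oa))
    if (ea, oa) == (ref_ea, ref_oa):
        return beta, eaf
    if (ea, oa) == (ref_oa, ref_ea):
        return -beta, 1.0 - eaf
    comp = {a: _COMPLEMENT.get(a, a) for a in (ea, oa)}
    if _is_ambiguous(ref_ea, ref_oa) or _is_ambiguous(ea, oa):
        raise AlleleMismatchError(
            f"ambiguous strand for alleles {ea}/{oa} vs {ref_ea}/{ref_oa}"
        )
    if (comp[ea], comp[oa]) == (ref_ea, ref_oa):
        return beta, eaf
    if (comp[ea], comp[oa]) == (ref_oa, ref_ea):
        return -beta, 1.0 - eaf
    raise AlleleMismatchError(
        f"irreconcilable alleles {ea}/{oa} vs {ref_ea}/{ref_oa}"
    )


def meta_analyze(site_results: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """IVW-combine per-site association tables matched on chrom:pos.

    Variants present in a single site are reported with n_studies = 1 and
    flagged.  The first site carrying a variant defines the effect-allele
    orientation; other sites are harmonized onto it (sign flip for swapped
    alleles; ambiguous strand mismatches raise).
    """
    if not site_results:
        raise ValueError("no site results supplied")
    merged: dict = {}
    order: list = []
    for study_idx, df in enumerate(site_results):
        for row in df.itertuples():
            key = (row.chrom, row.pos)
            if key not in merged:
                merged[key] = {
                    "variant": row.variant,
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "effect_allele": row.effect_allele,
                    "other_allele": row.other_allele,
                    "betas": [],
                    "ses": [],
                    "eafs": [],
                    "ns": [],
                }
                order.append(key)
            rec = merged[key]
            beta, eaf = harmonize_alleles(
                rec["effect_allele"],
                rec["other_allele"],
                row.effect_allele,
                row.other_allele,
                row.beta,
                row.eaf,
            )
            rec["betas"].append(beta)
            rec["ses"].append(row.se)
            rec["eafs"].append(eaf)
            rec["ns"].append(row.n_cases + row.n_controls)

    rows = []
    for key in order:
        rec = merged[key]
        m = ivw_meta(rec["betas"], rec["ses"], variant_id=rec["variant"])
        n_total = int(sum(rec["ns"]))
        eaf = float(np.average(rec["eafs"], weights=rec["ns"]))
        rows.append(
            {
                "variant": rec["variant"],
                "chrom": rec["chrom"],
                "pos": rec["pos"],
                "effect_allele": rec["effect_allele"],
                "other_allele": rec["other_allele"],
                "eaf": eaf,
                "beta": m.beta_meta,
                "se": m.se_meta,
                "p": m.p_meta,
                "n": n_total,
                "n_studies": m.n_studies,
                "direction": m.direction,
                "single_study": m.n_studies == 1,
            }
        )
    return pd.DataFrame(rows)


def flag_significance(
    results: pd.DataFrame,
    gw_threshold: float = GENOME_WIDE_THRESHOLD,
    nominal: float = 0.05,
) -> pd.DataFrame:
    """Annotate genome-wide (p < gw) and nominal (p < 0.05) flags; strict."""
    out = results.copy()
    out["genome_wide"] = out["p"] < gw_threshold
    out["nominal"] = out["p"] < nominal
    return out


def manhattan_data(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: cumulative genome coordinate, -log10 p, chrom parity.

    Chromosomes are ordered numerically 1..22 (non-numeric labels follow,
    lexicographically); p-values are floored at 1e-320 so -log10 is finite.
    """

    def chrom_key(c):
        s = str(c).removeprefix("chr")
        return (0, int(s)) if s.isdigit() else (1, s)

    out = results.copy()
    out["_ck"] = out["chrom"].map(chrom_key)
    out = out.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck")
    offset = 0
    coords = np.empty(len(out), dtype=float)
    parity = np.empty(len(out), dtype=int)
    chrom_index = 0
    for _, group_idx in out.groupby("chrom", sort=False).indices.items():
        pos = out["pos"].to_numpy()[group_idx]
        coords[group_idx] = pos + offset
        parity[group_idx] = chrom_index % 2
        offset += pos.max()
        chrom_index += 1
    out["cum_pos"] = coords
    out["neg_log10_p"] = -np.log10(np.maximum(out["p"].to_numpy(float), _P_FLOOR))
    out["chrom_parity"] = parity
    return out.reset_index(drop=True)
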