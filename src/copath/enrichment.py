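"""Survey of literature risk loci in this pipeline's results.

For each known locus from a clinical case-control GWAS the survey records
whether the matched variant is nominally significant *and* agrees with the
literature effect direction after allele harmonization.  Under the null an
independent variant passes both by chance with probability alpha/2 (two-sided
significance times a coin-flip on direction), so alpha = 0.05 gives the 2.5%
chance level the enrichment fraction is compared against with an exact
binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .meta import AlleleMismatchError, harmonize_alleles

__all__ = [
    "EnrichmentSummary",
    "harmonize_and_match",
    "concordant_hit",
    "enrichment_summary",
    "summarize_counts",
]

LOCUS_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "direction",
    "source",
    "label",
]


@dataclass
class EnrichmentSummary:
    contrast: Optional[str]
    n_tested: int
    n_hits: int
    fraction: float
    chance_level: float
    binomial_p: float

    @property
    def fraction_pct(self) -> float:
        """Fraction as a percentage rounded to one decimal place."""
        return round(100.0 * self.fraction, 1)

    @property
    def chance_level_pct(self) -> float:
        return round(100.0 * self.chance_level, 1)


def harmonize_and_match(loci: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Match literature loci to meta results by chrom:pos.

    Adds ``match_status`` (matched / unmatched / allele_mismatch), the
    pipeline's harmonized beta (sign-flipped when the locus lists the
    opposite effect allele) and p-value.  Unmatched and mismatched loci are
    kept in the output so the denominator bookkeeping stays explicit; only
    ``matched`` rows count toward n_tested.
    """
    missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"locus table missing columns: {missing}")
    index = {}
    for row in results.itertuples():
        index[(str(row.chrom), int(row.pos))] = row

    rows = []
    for locus in loci.itertuples():
        out = {c: getattr(locus, c) for c in LOCUS_COLUMNS}
        hit = index.get((str(locus.chrom), int(locus.pos)))
        if hit is None:
            out.update(match_status="unmatched", beta=np.nan, p=np.nan)
        else:
            try:
                # express the pipeline effect on the locus's effect allele
                beta, _ = harmonize_alleles(
                    str(locus.effect_allele),
                    str(locus.other_allele),
                    str(hit.effect_allele),
                    str(hit.other_allele),
                    float(hit.beta),
                    float(hit.eaf),
                )
            except AlleleMismatchError:
                out.update(match_status="allele_mismatch", beta=np.nan, p=np.nan)
            else:
                out.update(match_status="matched", beta=beta, p=float(hit.p))
        rows.append(out)
    return pd.DataFrame(rows)


def concordant_hit(row, alpha: float = 0.05) -> bool:
    """True iff p < alpha and the harmonized effect agrees in direction."""
    if isinstance(row, dict):
        row = pd.Series(row)
    if getattr(row, "match_status", "matched") != "matched":
        raise ValueError("concordant_hit requires a matched row")
    lit_sign = 1.0 if str(row.direction).strip() in ("+", "+1", "1") else -1.0
    return bool(row.p < alpha) and bool(np.sign(row.beta) == lit_sign)


def summarize_counts(
    n_hits: int,
    n_tested: int,
    alpha: float = 0.05,
    contrast: Optional[str] = None,
) -> EnrichmentSummary:
    """Enrichment summary from hit/denominator counts.

    chance_level = alpha * 1/2; binomial_p is the exact upper-tail
    probability of observing at least n_hits successes in n_tested trials at
    the chance level.
    """
    if n_tested < 1:
        raise ValueError("n_tested must be at least 1")
    if not 0 <= n_hits <= n_tested:
        raise ValueError("n_hits must lie in [0, n_tested]")
    chance = alpha * 0.5
    binom_p = float(stats.binom.sf(n_hits - 1, n_tested, chance))
    return EnrichmentSummary(
        contrast=contrast,
        n_tested=int(n_tested),
        n_hits=int(n_hits),
        fraction=n_hits / n_tested,
        chance_level=chance,
        binomial_p=binom_p,
    )


def enrichment_summary(
    matched: pd.DataFrame,
    alpha: float = 0.05,
    contrast: Optional[str] = None,
) -> EnrichmentSummary:
    """Summarize a matched locus table (output of harmonize_and_match)."""
    tested = matched[matched["match_status"] == "matched"]
    if len(tested) == 0:
        raise ValueError("no matched loci to test")
    n_hits = int(sum(concordant_hit(row, alpha) for row in tested.itertuples()))
    return summarize_counts(n_hits, len(tested), alpha=alpha, contrast=contrast)
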