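"""Cohort-level exclusions and kinship-based relative pruning.

Exclusion removes individuals whose Lewy-body distribution is
olfactory-bulb/unspecified and individuals missing sex or age-at-death.
Pruning builds connected components over pairs at or above the first-degree
kinship threshold and keeps exactly one member per component: the
youngest-at-death pathology case if the component contains any case,
otherwise the oldest control, otherwise the oldest member.  Ties break
lexicographically by id, so the result is independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .schemes import CASE_CATEGORIES

__all__ = [
    "KinshipPair",
    "DUPLICATE_KINSHIP_THRESHOLD",
    "FIRST_DEGREE_KINSHIP_THRESHOLD",
    "exclude_ineligible",
    "prune_relatives",
]

# KING convention cutoffs (the estimator itself is out of scope; kinship
# coefficients arrive precomputed).
DUPLICATE_KINSHIP_THRESHOLD = 0.354
FIRST_DEGREE_KINSHIP_THRESHOLD = 0.177


@dataclass(frozen=True)
class KinshipPair:
    id1: str
    id2: str
    kinship: float

    def __post_init__(self):
        if self.id1 == self.id2:
            raise ValueError(f"self-pair in kinship table: {self.id1!r}")
        if not 0.0 <= self.kinship <= 0.5:
            raise ValueError(
                f"kinship {self.kinship} for ({self.id1}, {self.id2}) "
                "outside [0, 0.5]"
            )


def exclude_ineligible(records: pd.DataFrame) -> tuple:
    """Apply cohort-level exclusions; returns (kept, exclusions).

    ``exclusions`` has columns (id, reason) with machine-readable reason
    codes: NACCLEWY4 (olfactory/unspecified Lewy bodies), missing_sex,
    missing_aad.  A record can match several reasons; the first in that
    order is reported.
    """
    reasons = []
    for row in records.itertuples():
        if getattr(row, "lewy_dist", None) == "olfactory_or_unspecified":
            reasons.append((row.id, "NACCLEWY4"))
        elif pd.isna(getattr(row, "sex", None)):
            reasons.append((row.id, "missing_sex"))
        elif pd.isna(getattr(row, "age_at_death", None)):
            reasons.append((row.id, "missing_aad"))
    exclusions = pd.DataFrame(reasons, columns=["id", "reason"])
    kept = records[~records["id"].isin(exclusions["id"])].reset_index(drop=True)
    return kept, exclusions


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def prune_relatives(
    records: pd.DataFrame,
    kinship: Iterable[KinshipPair],
    category: Mapping[str, str],
    dup_threshold: float = DUPLICATE_KINSHIP_THRESHOLD,
    first_degree_threshold: float = FIRST_DEGREE_KINSHIP_THRESHOLD,
) -> list:
    """Return the ids retained after duplicate/first-degree pruning.

    ``records`` needs columns id and age_at_death; ``category`` maps each id
    to its pathology category (cases are AD+LB+, AD+LB-, AD-LB+; controls
    are AD-LB-).  ``dup_threshold`` is accepted for interface completeness:
    duplicates necessarily exceed the first-degree threshold, so one
    component pass handles both.
    """
    ids = list(records["id"])
    id_set = set(ids)
    age = dict(zip(records["id"], records["age_at_death"]))

    uf = _UnionFind()
    linked = set()
    for pair in kinship:
        if isinstance(pair, (tuple, list)):
            pair = KinshipPair(*pair)
        for i in (pair.id1, pair.id2):
            if i not in id_set:
                raise KeyError(f"kinship id {i!r} not present in records")
        if pair.kinship >= min(first_degree_threshold, dup_threshold):
            uf.union(pair.id1, pair.id2)
            linked.update((pair.id1, pair.id2))

    components: dict = {}
    for i in sorted(linked):
        components.setdefault(uf.find(i), []).append(i)

    removed = set()
    for members in components.values():
        cases = [i for i in members if category.get(i) in CASE_CATEGORIES]
        controls = [i for i in members if category.get(i) == "AD-LB-"]
        if cases:
            # youngest age-at-death among cases; ties -> lexicographic id
            keep = min(cases, key=lambda i: (age[i], i))
        elif controls:
            keep = min(controls, key=lambda i: (-age[i], i))
        else:
            keep = min(members, key=lambda i: (-age[i], i))
        removed.update(set(members) - {keep})

    return [i for i in ids if i not in removed]
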