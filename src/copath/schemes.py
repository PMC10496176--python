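"""Decision-table classification of autopsy staging into pathology categories.

Individuals are staged on three axes — neurofibrillary-tangle spread (Braak
stage 0–VI), neuritic-plaque density (CERAD: absent/sparse/moderate/frequent)
and anatomical Lewy-body distribution — and assigned to one of four
case-control categories (AD+LB+, AD+LB-, AD-LB+, AD-LB-), or left
unclassified (gray zones) or excluded.  A :class:`ClassificationScheme` is a
fully-enumerated, serializable decision table: 5 Lewy-distribution cells and
56 (Braak x CERAD x LB-status) cells.  Three built-in schemes are shipped as
YAML data files and validated for totality at load time.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml

__all__ = [
    "BRAAK_STAGES",
    "CERAD_SCORES",
    "LEWY_DISTRIBUTIONS",
    "CATEGORIES",
    "CASE_CATEGORIES",
    "PathologyRecord",
    "ClassificationScheme",
    "SchemeError",
    "parse_braak",
    "parse_cerad",
    "parse_lewy",
    "builtin_scheme",
    "classify",
    "classify_frame",
    "tabulate",
    "scheme_concordance",
]

# Ordinal codings.  Braak 0..6 (integer or Roman numerals I-VI); CERAD 0..3
# (NACC-style codes or words); Lewy distribution uses NACC NACCLEWY codes
# 0..4 where 4 is olfactory-bulb/unspecified.
BRAAK_STAGES = tuple(range(7))
CERAD_SCORES = tuple(range(4))
CERAD_WORDS = ("absent", "sparse", "moderate", "frequent")
LEWY_DISTRIBUTIONS = (
    "none",
    "brainstem",
    "limbic",
    "neocortical",
    "olfactory_or_unspecified",
)
LB_STATUSES = ("LB+", "LB-")

AD_LABELS = ("AD+", "AD-", "unclassified")
LB_LABELS = ("LB+", "LB-", "excluded")

CATEGORIES = ("AD+LB+", "AD+LB-", "AD-LB+", "AD-LB-", "unclassified", "excluded")
#: Categories counted as cases in at least one contrast (everything but controls).
CASE_CATEGORIES = frozenset({"AD+LB+", "AD+LB-", "AD-LB+"})

_ROMAN = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}
_LEWY_CODES = {
    "0": "none",
    "1": "brainstem",
    "2": "limbic",
    "3": "neocortical",
    "4": "olfactory_or_unspecified",
}
_LEWY_ALIASES = {
    "none": "none",
    "no": "none",
    "absent": "none",
    "brainstem": "brainstem",
    "brainstem-predominant": "brainstem",
    "limbic": "limbic",
    "transitional": "limbic",
    "neocortical": "neocortical",
    "diffuse": "neocortical",
    "cortical": "neocortical",
    "olfactory": "olfactory_or_unspecified",
    "olfactory_or_unspecified": "olfactory_or_unspecified",
    "unspecified": "olfactory_or_unspecified",
}


class SchemeError(ValueError):
    """Raised for unknown schemes, non-total tables, or bad cell labels."""


def parse_braak(value: Union[int, str]) -> int:
    """Parse a Braak stage from an integer 0-6 or Roman numeral 0/I-VI."""
    if isinstance(value, bool):
        raise ValueError(f"invalid Braak stage: {value!r}")
    if isinstance(value, (int, float)) and not isinstance(value, str):
        iv = int(value)
        if iv != value or iv not in BRAAK_STAGES:
            raise ValueError(f"invalid Braak stage: {value!r}")
        return iv
    s = str(value).strip().upper()
    if s in _ROMAN:
        return _ROMAN[s]
    if s.isdigit() and int(s) in BRAAK_STAGES:
        return int(s)
    raise ValueError(f"invalid Braak stage: {value!r}")


def parse_cerad(value: Union[int, str]) -> int:
    """Parse a CERAD score from a 0-3 code or a word (absent..frequent)."""
    if isinstance(value, bool):
        raise ValueError(f"invalid CERAD score: {value!r}")
    if isinstance(value, (int, float)) and not isinstance(value, str):
        iv = int(value)
        if iv != value or iv not in CERAD_SCORES:
            raise ValueError(f"invalid CERAD score: {value!r}")
        return iv
    s = str(value).strip().lower()
    if s in CERAD_WORDS:
        return CERAD_WORDS.index(s)
    if s.isdigit() and int(s) in CERAD_SCORES:
        return int(s)
    raise ValueError(f"invalid CERAD score: {value!r}")


def parse_lewy(value: Union[int, str]) -> str:
    """Parse a Lewy-body distribution from a NACC-style code 0-4 or a word."""
    if isinstance(value, bool):
        raise ValueError(f"invalid Lewy distribution: {value!r}")
    if isinstance(value, (int, float)) and not isinstance(value, str):
        iv = int(value)
        if iv != value or str(iv) not in _LEWY_CODES:
            raise ValueError(f"invalid Lewy distribution: {value!r}")
        return _LEWY_CODES[str(iv)]
    s = str(value).strip().lower()
    if s in _LEWY_CODES:
        return _LEWY_CODES[s]
    if s in _LEWY_ALIASES:
        return _LEWY_ALIASES[s]
    raise ValueError(f"invalid Lewy distribution: {value!r}")


@dataclass
class PathologyRecord:
    """One autopsied individual's staging plus demographics."""

    id: str
    braak: Optional[int] = None
    cerad: Optional[int] = None
    lewy_dist: Optional[str] = None
    site: Optional[str] = None
    sex: Optional[int] = None  # 1 = female, 0 = male
    age_at_death: Optional[float] = None


@dataclass
class ClassificationScheme:
    """A named, total decision table over staging triples.

    ``lb_rule`` maps each of the 5 Lewy distributions to LB+/LB-/excluded;
    ``ad_rule`` maps every (braak, cerad, lb_status) triple — 7 x 4 x 2 = 56
    cells — to AD+/AD-/unclassified.  Totality is enforced at construction.
    """

    name: str
    lb_rule: Mapping[str, str] = field(repr=False)
    ad_rule: Mapping[tuple, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for dist in LEWY_DISTRIBUTIONS:
            label = self.lb_rule.get(dist)
            if label not in LB_LABELS:
                raise SchemeError(
                    f"scheme {self.name!r}: lb_rule cell {dist!r} missing or "
                    f"invalid ({label!r})"
                )
        extra = set(self.lb_rule) - set(LEWY_DISTRIBUTIONS)
        if extra:
            raise SchemeError(f"scheme {self.name!r}: unknown lb_rule cells {extra}")
        for b in BRAAK_STAGES:
            for c in CERAD_SCORES:
                for lb in LB_STATUSES:
                    label = self.ad_rule.get((b, c, lb))
                    if label not in AD_LABELS:
                        raise SchemeError(
                            f"scheme {self.name!r}: ad_rule cell "
                            f"(braak={b}, cerad={c}, {lb}) missing or invalid "
                            f"({label!r})"
                        )
        if len(self.ad_rule) != 56:
            raise SchemeError(
                f"scheme {self.name!r}: ad_rule has {len(self.ad_rule)} cells, "
                "expected 56"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        ad = {
            lb: {str(b): [self.ad_rule[(b, c, lb)] for c in CERAD_SCORES]
                 for b in BRAAK_STAGES}
            for lb in LB_STATUSES
        }
        return {"name": self.name, "lb_rule": dict(self.lb_rule), "ad_rule": ad}

    @classmethod
    def from_dict(cls, data: Mapping) -> "ClassificationScheme":
        try:
            name = data["name"]
            lb_rule = dict(data["lb_rule"])
            ad_nested = data["ad_rule"]
        except KeyError as exc:  # pragma: no cover - defensive
            raise SchemeError(f"scheme file missing key: {exc}") from exc
        ad_rule = {}
        for lb, rows in ad_nested.items():
            for b, labels in rows.items():
                for c, label in enumerate(labels):
                    ad_rule[(int(b), c, lb)] = label
        return cls(name=name, lb_rule=lb_rule, ad_rule=ad_rule)

    @classmethod
    def from_yaml(cls, path) -> "ClassificationScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_BUILTIN_NAMES = ("current", "tsuang", "kaivola")
_builtin_cache: dict = {}


def builtin_scheme(name: str) -> ClassificationScheme:
    """Load one of the shipped schemes: ``current``, ``tsuang``, ``kaivola``."""
    if name not in _BUILTIN_NAMES:
        raise SchemeError(
            f"unknown scheme {name!r}; built-ins are {', '.join(_BUILTIN_NAMES)}"
        )
    if name not in _builtin_cache:
        ref = importlib.resources.files("copath.data").joinpath(f"scheme_{name}.yaml")
        with ref.open() as fh:
            _builtin_cache[name] = ClassificationScheme.from_dict(yaml.safe_load(fh))
    return _builtin_cache[name]


def resolve_scheme(scheme: Union[str, ClassificationScheme]) -> ClassificationScheme:
    """Accept a scheme object, a built-in name, or a YAML file path."""
    if isinstance(scheme, ClassificationScheme):
        return scheme
    if scheme in _BUILTIN_NAMES:
        return builtin_scheme(scheme)
    return ClassificationScheme.from_yaml(scheme)


def classify(record: PathologyRecord, scheme: ClassificationScheme) -> str:
    """Assign one pathology category to a fully-staged record.

    Olfactory-bulb/unspecified Lewy-body distribution forces exclusion under
    every scheme (a cohort-level rule), before the scheme's own tables apply.
    """
    for fieldname in ("braak", "cerad", "lewy_dist"):
        if getattr(record, fieldname) is None:
            raise ValueError(
                f"record {record.id!r}: missing staging field {fieldname!r}"
            )
    if record.lewy_dist == "olfactory_or_unspecified":
        return "excluded"
    lb_status = scheme.lb_rule[record.lewy_dist]
    if lb_status == "excluded":
        return "excluded"
    ad_status = scheme.ad_rule[(record.braak, record.cerad, lb_status)]
    if ad_status == "unclassified":
        return "unclassified"
    return ad_status + lb_status


def classify_frame(
    frame: pd.DataFrame, scheme: Union[str, ClassificationScheme]
) -> pd.Series:
    """Vectorized :func:`classify` over a phenotype table.

    Expects integer ``braak``/``cerad`` and canonical ``lewy_dist`` columns
    (as produced by :func:`copath.io.read_phenotypes`).
    """
    scheme = resolve_scheme(scheme)
    out = []
    for row in frame.itertuples():
        rec = PathologyRecord(
            id=str(row.id),
            braak=None if pd.isna(row.braak) else int(row.braak),
            cerad=None if pd.isna(row.cerad) else int(row.cerad),
            lewy_dist=None if pd.isna(row.lewy_dist) else row.lewy_dist,
        )
        out.append(classify(rec, scheme))
    return pd.Series(out, index=frame.index, name="category")


def tabulate(
    records: Iterable[PathologyRecord], scheme: Union[str, ClassificationScheme]
) -> pd.Series:
    """Category counts for a set of records; counts sum to len(records)."""
    scheme = resolve_scheme(scheme)
    counts = Counter(classify(r, scheme) for r in records)
    return pd.Series(
        [counts.get(cat, 0) for cat in CATEGORIES], index=CATEGORIES, name="n"
    )


def scheme_concordance(
    records: Iterable[PathologyRecord],
    scheme_a: Union[str, ClassificationScheme],
    scheme_b: Union[str, ClassificationScheme],
) -> pd.DataFrame:
    """Cross-tabulation of category assignments under two schemes."""
    scheme_a = resolve_scheme(scheme_a)
    scheme_b = resolve_scheme(scheme_b)
    table = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for rec in records:
        table.loc[classify(rec, scheme_a), classify(rec, scheme_b)] += 1
    return table
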