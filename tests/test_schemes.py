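import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from copath.schemes import (
    BRAAK_STAGES,
    CATEGORIES,
    CERAD_SCORES,
    LEWY_DISTRIBUTIONS,
    ClassificationScheme,
    PathologyRecord,
    SchemeError,
    builtin_scheme,
    classify,
    parse_braak,
    parse_cerad,
    parse_lewy,
    scheme_concordance,
    tabulate,
)

ALL_TRIPLES = list(
    itertools.product(BRAAK_STAGES, CERAD_SCORES, LEWY_DISTRIBUTIONS)
)


def rec(braak, cerad, lewy, rid="x"):
    return PathologyRecord(id=rid, braak=braak, cerad=cerad, lewy_dist=lewy)


# --- parsing ----------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [(0, 0), ("0", 0), ("III", 3), ("vi", 6), ("IV", 4), (6, 6), ("2", 2)],
)
def test_parse_braak(raw, expected):
    assert parse_braak(raw) == expected


@pytest.mark.parametrize("raw", ["VII", -1, 7, "x", 3.5])
def test_parse_braak_rejects(raw):
    with pytest.raises(ValueError):
        parse_braak(raw)


@pytest.mark.parametrize(
    "raw,expected",
    [("absent", 0), ("sparse", 1), ("Moderate", 2), ("frequent", 3),
     (0, 0), ("3", 3)],
)
def test_parse_cerad(raw, expected):
    assert parse_cerad(raw) == expected


@pytest.mark.parametrize(
    "raw,expected",
    [(0, "none"), ("4", "olfactory_or_unspecified"), ("brainstem", "brainstem"),
     ("transitional", "limbic"), ("diffuse", "neocortical")],
)
def test_parse_lewy(raw, expected):
    assert parse_lewy(raw) == expected


def test_parse_lewy_rejects():
    with pytest.raises(ValueError):
        parse_lewy("cerebellum")


# --- built-in schemes -------------------------------------------------------


def test_unknown_scheme_lists_builtins():
    with pytest.raises(SchemeError, match="current"):
        builtin_scheme("nonexistent")


@pytest.mark.parametrize("name", ["current", "tsuang", "kaivola"])
def test_totality(name):
    """Every staging triple maps to exactly one category."""
    scheme = builtin_scheme(name)
    for b, c, l in ALL_TRIPLES:
        category = classify(rec(b, c, l), scheme)
        assert category in CATEGORIES


@pytest.mark.parametrize(
    "braak,cerad,lewy,expected",
    [
        # quoted cell assignments for the study's own criteria
        (5, 3, "neocortical", "AD+LB+"),
        (3, 1, "limbic", "AD+LB+"),
        (5, 0, "none", "unclassified"),
        (3, 3, "brainstem", "unclassified"),
        (4, 1, "none", "AD-LB-"),
        (0, 0, "none", "AD-LB-"),
        (3, 2, "none", "AD-LB-"),
        (4, 2, "limbic", "AD+LB+"),
        (6, 1, "brainstem", "unclassified"),
        (6, 1, "limbic", "AD+LB+"),
    ],
)
def test_current_scheme_worked_examples(braak, cerad, lewy, expected):
    assert classify(rec(braak, cerad, lewy), builtin_scheme("current")) == expected


def test_olfactory_always_excluded():
    for name in ("current", "tsuang", "kaivola"):
        scheme = builtin_scheme(name)
        for b in BRAAK_STAGES:
            for c in CERAD_SCORES:
                assert classify(rec(b, c, "olfactory_or_unspecified"), scheme) == (
                    "excluded"
                )


def test_tsuang_excludes_brainstem():
    scheme = builtin_scheme("tsuang")
    assert classify(rec(2, 0, "brainstem"), scheme) == "excluded"
    assert classify(rec(2, 0, "none"), scheme) == "AD-LB-"


def test_kaivola_lower_threshold():
    scheme = builtin_scheme("kaivola")
    assert classify(rec(3, 1, "none"), scheme) == "AD+LB-"
    assert classify(rec(3, 0, "none"), scheme) == "AD-LB-"
    assert classify(rec(2, 3, "limbic"), scheme) == "AD-LB+"


def test_current_gray_zones_exact():
    """The unclassified cells are exactly the three quoted rules."""
    scheme = builtin_scheme("current")
    expected = set()
    for lb in ("LB+", "LB-"):
        for c in CERAD_SCORES:
            for b in (5, 6):
                if c == 0:
                    expected.add((b, c, lb))
    for b in (5, 6):
        expected.add((b, 1, "LB-"))
    expected.add((3, 3, "LB-"))
    actual = {cell for cell, v in scheme.ad_rule.items() if v == "unclassified"}
    assert actual == expected


def test_nesting_current_superset_of_tsuang():
    """For LB+ individuals the current AD+ region strictly contains tsuang's."""
    current = builtin_scheme("current")
    tsuang = builtin_scheme("tsuang")
    cur = {(b, c) for b in BRAAK_STAGES for c in CERAD_SCORES
           if current.ad_rule[(b, c, "LB+")] == "AD+"}
    tsu = {(b, c) for b in BRAAK_STAGES for c in CERAD_SCORES
           if tsuang.ad_rule[(b, c, "LB+")] == "AD+"}
    assert tsu < cur


def test_monotone_in_stratum():
    """Under `current`, cells above an AD+ cell are AD+ (gray zones have
    CERAD below every AD+ cell, so they never interleave)."""
    scheme = builtin_scheme("current")
    for lb in ("LB+", "LB-"):
        for b, c in itertools.product(BRAAK_STAGES, CERAD_SCORES):
            if scheme.ad_rule[(b, c, lb)] != "AD+":
                continue
            for b2 in range(b, 7):
                for c2 in range(c, 4):
                    assert scheme.ad_rule[(b2, c2, lb)] == "AD+"


def test_lbplus_no_adminus_above_relaxed_threshold():
    scheme = builtin_scheme("current")
    for b in range(3, 7):
        for c in range(1, 4):
            assert scheme.ad_rule[(b, c, "LB+")] != "AD-"


# --- classify / tabulate ----------------------------------------------------


def test_classify_missing_field_names_field_and_id():
    with pytest.raises(ValueError, match="cerad"):
        classify(PathologyRecord(id="r7", braak=3, lewy_dist="none"),
                 builtin_scheme("current"))


def test_tabulate_quadrant_exemplars():
    records = [
        rec(5, 3, "neocortical", "a"),
        rec(5, 3, "none", "b"),
        rec(0, 0, "limbic", "c"),
        rec(0, 0, "none", "d"),
    ]
    counts = tabulate(records, "current")
    for cat in ("AD+LB+", "AD+LB-", "AD-LB+", "AD-LB-"):
        assert counts[cat] == 1
    assert counts.sum() == 4


def test_tabulate_empty():
    counts = tabulate([], "current")
    assert counts.sum() == 0


def test_tabulate_56_cell_enumeration():
    """Enumerate every (braak, cerad, LB-status) cell once; the unclassified
    count must equal a direct scan of the decision table (7 cells: the three
    gray-zone rules)."""
    scheme = builtin_scheme("current")
    records = []
    for i, (b, c, lb) in enumerate(
        itertools.product(BRAAK_STAGES, CERAD_SCORES, ("limbic", "none"))
    ):
        records.append(rec(b, c, lb, rid=f"r{i}"))
    counts = tabulate(records, scheme)
    oracle = sum(1 for v in scheme.ad_rule.values() if v == "unclassified")
    assert counts["unclassified"] == oracle == 7
    assert counts.sum() == 56


def test_concordance_identity_diagonal():
    records = [rec(b, c, l, rid=f"{b}{c}{l}") for b, c, l in ALL_TRIPLES]
    table = scheme_concordance(records, "current", "current")
    off_diag = table.to_numpy().sum() - sum(
        table.loc[cat, cat] for cat in CATEGORIES
    )
    assert off_diag == 0
    assert table.to_numpy().sum() == len(records)


def test_concordance_quoted_disagreements():
    cur, tsu = builtin_scheme("current"), builtin_scheme("tsuang")
    r = rec(3, 1, "limbic")
    assert classify(r, cur) == "AD+LB+"
    assert classify(r, tsu) == "AD-LB+"
    r = rec(2, 0, "brainstem")
    assert classify(r, cur) == "AD-LB-"
    assert classify(r, tsu) == "excluded"


def test_concordance_margins_match_tabulations():
    records = [rec(b, c, l, rid=f"{b}{c}{l}") for b, c, l in ALL_TRIPLES]
    table = scheme_concordance(records, "current", "kaivola")
    assert (table.sum(axis=1) == tabulate(records, "current")).all()
    assert (table.sum(axis=0) == tabulate(records, "kaivola")).all()


# --- serialization ----------------------------------------------------------


def test_scheme_yaml_roundtrip(tmp_path):
    scheme = builtin_scheme("current")
    path = tmp_path / "scheme.yaml"
    scheme.to_yaml(path)
    loaded = ClassificationScheme.from_yaml(path)
    assert loaded.name == scheme.name
    assert loaded.lb_rule == dict(scheme.lb_rule)
    assert loaded.ad_rule == dict(scheme.ad_rule)


def test_nontotal_scheme_rejected():
    scheme = builtin_scheme("current")
    data = scheme.to_dict()
    data["ad_rule"]["LB+"]["3"] = data["ad_rule"]["LB+"]["3"][:3]  # drop a cell
    with pytest.raises(SchemeError):
        ClassificationScheme.from_dict(data)


def test_bad_lb_label_rejected():
    data = builtin_scheme("current").to_dict()
    data["lb_rule"]["none"] = "LB?"
    with pytest.raises(SchemeError, match="none"):
        ClassificationScheme.from_dict(data)


# --- properties -------------------------------------------------------------


@given(
    braak=st.sampled_from(BRAAK_STAGES),
    cerad=st.sampled_from(CERAD_SCORES),
    lewy=st.sampled_from(LEWY_DISTRIBUTIONS),
    name=st.sampled_from(["current", "tsuang", "kaivola"]),
)
def test_classification_total_and_pure(braak, cerad, lewy, name):
    scheme = builtin_scheme(name)
    first = classify(rec(braak, cerad, lewy), scheme)
    assert first in CATEGORIES
    assert classify(rec(braak, cerad, lewy), scheme) == first
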