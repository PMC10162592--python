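"""The core statistic: ratios, peer distributions, z-scores, ranking.

Includes a brute-force oracle — naive Python loops over a dict of counts
— against which the vectorised engine is checked on small matrices.
"""

import statistics
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rxoutliers import engine, ingest

# ---------------------------------------------------------------------------
# brute-force oracle (independent of the pandas implementation)
# ---------------------------------------------------------------------------


def brute_force_zscores(counts: dict[tuple[str, str], int]) -> dict:
    """Naive recomputation of every z-score from a (org, chemical) -> items
    dict: derive denominators, ratios, per-chemical mean and sample SD,
    then standardise.  Chemicals with no items anywhere carry no rows."""
    all_orgs = sorted({o for o, _ in counts})
    chems = sorted(
        {c for (_, c) in counts if sum(v for (o2, c2), v in counts.items() if c2 == c) > 0}
    )
    denom: dict[tuple[str, str], int] = {}
    for o in all_orgs:
        for c in chems:
            key = (o, c[:7])
            denom[key] = denom.get(key, 0) + counts.get((o, c), 0)
    ratios = {
        (o, c): counts.get((o, c), 0) / denom[(o, c[:7])]
        for o in all_orgs
        for c in chems
        if denom[(o, c[:7])] > 0
    }
    z = {}
    for c in chems:
        vals = [ratios[(o, c)] for o in all_orgs if (o, c) in ratios]
        if not vals:
            continue
        mu = statistics.fmean(vals)
        sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
        for o in all_orgs:
            if (o, c) in ratios:
                z[(o, c)] = (ratios[(o, c)] - mu) / sd if sd > 0 else 0.0
    return z


def matrix_from_counts(counts: dict[tuple[str, str], int]) -> ingest.CountMatrix:
    rows = [
        (org, chem, items, date(2021, 6, 1))
        for (org, chem), items in sorted(counts.items())
    ]
    recs = pd.DataFrame(
        rows, columns=["practice_code", "bnf_code", "items", "month"]
    )
    return ingest.build_count_matrix(recs, "practice")


def engine_zscores(matrix: ingest.CountMatrix, ddof=1) -> dict:
    ratios = engine.compute_ratios(matrix)
    scores = engine.compute_zscores(ratios, engine.fit_distribution(ratios, ddof=ddof))
    return {
        (r.org_code, r.chemical_code): r.z for r in scores.itertuples()
    }


_ORGS = ["P1", "P2", "P3", "P4", "P5"]
_CHEMS = ["0501120A0", "0501120B0", "0212000A0", "0212000B0", "0212000C0"]

_counts_st = st.dictionaries(
    st.tuples(st.sampled_from(_ORGS), st.sampled_from(_CHEMS)),
    st.integers(min_value=0, max_value=100),
    min_size=1,
    max_size=20,
).filter(lambda d: any(v > 0 for v in d.values()))


@given(_counts_st)
def test_zscores_match_brute_force_oracle(counts):
    expected = brute_force_zscores(counts)
    got = engine_zscores(matrix_from_counts(counts))
    assert set(got) == set(expected)
    for key, z in expected.items():
        assert got[key] == pytest.approx(z, abs=1e-12)


# ---------------------------------------------------------------------------
# unit behaviour of each operation
# ---------------------------------------------------------------------------


class TestComputeRatios:
    def test_worked_example_values(self, devon_matrix):
        r = engine.compute_ratios(devon_matrix).set_index("chemical_code")
        assert r.loc["0501120L0", "ratio"] == pytest.approx(1372 / 4754)
        assert round(r.loc["0501120L0", "ratio"], 2) == 0.29
        assert round(r.loc["0105000S0", "ratio"], 2) == 0.98

    def test_zero_numerator_contributes_ratio_zero(self):
        m = matrix_from_counts({("P1", "0501120A0"): 10, ("P2", "0501120A0"): 5,
                                ("P2", "0501120B0"): 5})
        r = engine.compute_ratios(m)
        p1b = r.loc[(r.org_code == "P1") & (r.chemical_code == "0501120B0")]
        assert len(p1b) == 1 and p1b["ratio"].iloc[0] == 0.0

    def test_zero_denominator_org_gets_no_row(self):
        m = matrix_from_counts({("P1", "0501120A0"): 10, ("P2", "0212000A0"): 5,
                                ("P2", "0212000B0"): 1})
        r = engine.compute_ratios(m)
        assert r.loc[(r.org_code == "P1") & (r.subparagraph_code == "0212000")].empty


class TestFitDistribution:
    def test_arithmetic_progression(self):
        ratios = pd.DataFrame(
            {"chemical_code": ["C"] * 3, "org_code": list("abc"),
             "ratio": [0.1, 0.2, 0.3]}
        )
        d = engine.fit_distribution(ratios).iloc[0]
        assert d["mean"] == pytest.approx(0.2)
        assert d["sd"] == pytest.approx(0.1)
        assert d["n_orgs"] == 3

    def test_single_org_and_constant_ratios_have_sd_zero(self):
        one = pd.DataFrame({"chemical_code": ["C"], "org_code": ["a"], "ratio": [0.5]})
        assert engine.fit_distribution(one)["sd"].iloc[0] == 0.0
        const = pd.DataFrame(
            {"chemical_code": ["C"] * 10, "org_code": list("abcdefghij"),
             "ratio": [0.4] * 10}
        )
        d = engine.fit_distribution(const).iloc[0]
        assert d["mean"] == pytest.approx(0.4) and d["sd"] == 0.0

    def test_population_sd_option(self):
        ratios = pd.DataFrame(
            {"chemical_code": ["C"] * 2, "org_code": list("ab"), "ratio": [0.0, 1.0]}
        )
        assert engine.fit_distribution(ratios, ddof=0)["sd"].iloc[0] == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            engine.fit_distribution(pd.DataFrame(columns=["chemical_code", "ratio"]))


def test_zscore_substitution_and_degenerate_sd():
    ratios = pd.DataFrame(
        {"org_code": list("abc"), "chemical_code": ["C"] * 3,
         "ratio": [0.3, 0.2, 0.2]}
    )
    dists = pd.DataFrame(
        {"chemical_code": ["C"], "n_orgs": [3], "mean": [0.2], "sd": [0.1]}
    )
    z = engine.compute_zscores(ratios, dists)["z"].tolist()
    assert z == pytest.approx([1.0, 0.0, 0.0])
    degen = dists.assign(sd=[0.0])
    z0 = engine.compute_zscores(ratios, degen)["z"]
    assert (z0 == 0).all() and np.isfinite(z0).all()


def _scores(zs: dict[str, float], org="P1") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "org_code": [org] * len(zs),
            "chemical_code": list(zs),
            "ratio": [0.5 + z / 10 for z in zs.values()],
            "mean": [0.5] * len(zs),
            "z": list(zs.values()),
            "chemical_items": [10] * len(zs),
        }
    )


class TestRankingAndSelection:
    def test_rank_descending_by_z(self):
        ranked = engine.rank_within_org(
            _scores({"A": 2.0, "B": -1.0, "C": 0.5}), "P1"
        )
        assert ranked["chemical_code"].tolist() == ["A", "C", "B"]

    def test_tie_broken_by_code_when_deviation_equal(self):
        df = _scores({"02AAAAAA0": 1.0, "01AAAAAA0": 1.0})
        ranked = engine.rank_within_org(df, "P1")
        assert ranked["chemical_code"].tolist() == ["01AAAAAA0", "02AAAAAA0"]

    def test_unknown_org_is_error(self):
        with pytest.raises(KeyError):
            engine.rank_within_org(_scores({"A": 1.0}), "NOPE")

    def test_select_extremes_respects_zero_boundary(self):
        zs = {f"C{i:02d}": z for i, z in enumerate([3.0, 2.0, 1.0, 0.5, -0.2, -2.5])}
        ranked = engine.rank_within_org(_scores(zs), "P1")
        higher, lower = engine.select_extremes(ranked, k=10)
        assert len(higher) == 4 and len(lower) == 2  # never padded across zero
        assert lower["z"].iloc[0] == -2.5  # most negative first

    def test_ranking_antisymmetry(self):
        rng = np.random.default_rng(0)
        zs = {f"C{i:02d}": float(z) for i, z in enumerate(rng.normal(size=15))}
        df = _scores(zs)
        fwd = engine.rank_within_org(df, "P1")["chemical_code"].tolist()
        neg = df.assign(z=-df["z"], ratio=0.5 - (df["ratio"] - 0.5))
        rev = engine.rank_within_org(neg, "P1")["chemical_code"].tolist()
        assert rev == fwd[::-1]


class TestSuppression:
    def test_modes(self):
        rows = _scores({"A": 2.0, "B": 1.0})
        rows.loc[rows.chemical_code == "A", "chemical_items"] = 1
        shown = engine.suppress_low_counts(rows, 5, "show")
        assert shown["suppressed"].tolist() == [True, False]
        dropped = engine.suppress_low_counts(rows, 5, "drop")
        assert dropped["chemical_code"].tolist() == ["B"]

    def test_threshold_is_inclusive_and_zero_disables(self):
        rows = _scores({"A": 1.0})
        rows["chemical_items"] = 6
        assert not engine.suppress_low_counts(rows, 5, "show")["suppressed"].any()
        rows["chemical_items"] = 5
        assert engine.suppress_low_counts(rows, 5, "show")["suppressed"].all()
        assert not engine.suppress_low_counts(rows, 0, "show")["suppressed"].any()

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            engine.suppress_low_counts(_scores({"A": 1.0}), 5, "hide")


class TestSummarizeLevel:
    def _extremes(self, higher, lower):
        rows = [("O1", f"H{i}", z, "higher") for i, z in enumerate(higher)]
        rows += [("O1", f"L{i}", z, "lower") for i, z in enumerate(lower)]
        return pd.DataFrame(rows, columns=["org_code", "chemical_code", "z", "side"])

    def test_single_value_side(self):
        s = engine.summarize_level(self._extremes([5.0], []), "stp")
        assert s.higher == {"max": 5.0, "median": 5.0, "q1": 5.0, "q3": 5.0, "iqr": 0.0}
        assert s.lower is None

    def test_linear_interpolation_quantiles(self):
        # frozen from numpy's linear rule on {4,5,6,7}: q1=4.75, q3=6.25
        s = engine.summarize_level(self._extremes([4, 5, 6, 7], [-1.0, -2.0]), "ccg")
        assert s.higher["median"] == pytest.approx(5.5)
        assert s.higher["q1"] == pytest.approx(4.75)
        assert s.higher["q3"] == pytest.approx(6.25)
        assert s.higher["iqr"] == pytest.approx(1.5)
        assert s.lower["min"] == -2.0
        assert s.n_unique_outlier_chemicals == 6


# ---------------------------------------------------------------------------
# statistical invariants
# ---------------------------------------------------------------------------


@given(_counts_st)
def test_compositional_closure(counts):
    """Within each organisation and subparagraph, the rates sum to 1."""
    r = engine.compute_ratios(matrix_from_counts(counts))
    sums = r.groupby(["org_code", "subparagraph_code"])["ratio"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


@given(_counts_st)
def test_zscore_standardization(counts):
    """Per chemical with sd > 0, z-scores have mean 0 and sample SD 1."""
    m = matrix_from_counts(counts)
    ratios = engine.compute_ratios(m)
    dists = engine.fit_distribution(ratios)
    scores = engine.compute_zscores(ratios, dists)
    for chem, grp in scores.groupby("chemical_code"):
        if grp["sd"].iloc[0] > 0:
            assert abs(grp["z"].mean()) < 1e-9
            assert abs(grp["z"].std(ddof=1) - 1) < 1e-9


@given(_counts_st, st.integers(min_value=2, max_value=9))
def test_scale_invariance(counts, factor):
    """Multiplying every organisation's counts in a subparagraph by a
    common positive integer leaves ratios, hence z-scores, unchanged."""
    base = engine_zscores(matrix_from_counts(counts))
    scaled_counts = {k: v * factor for k, v in counts.items()}
    scaled = engine_zscores(matrix_from_counts(scaled_counts))
    assert set(base) == set(scaled)
    for key in base:
        assert scaled[key] == pytest.approx(base[key], abs=1e-9)


def test_analyze_end_to_end_report_columns(devon_matrix):
    from rxoutliers import simulate

    res = engine.analyze(
        devon_matrix, k=10, names=simulate.devon_name_lookup()
    )
    assert list(res.extremes.columns) == engine.REPORT_COLUMNS
    # a single organisation is its own peer group: all z = 0, no extremes
    assert res.extremes.empty
    assert (res.scores["z"] == 0).all()
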