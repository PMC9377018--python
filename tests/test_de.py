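"""Donor-aware DE test: statistic, exact permutation null, gene selection.

The permutation machinery is checked against an independent brute-force
oracle that re-derives the Wilcoxon scores from the raw per-cell values for
every group assignment (no reuse of the package's score table).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pwsc.core import log_cpm_normalize
from pwsc.de import (DETestResult, PairwiseScoreTable, _score_matrix_from_cells,
                     median_cross_statistic, pairwise_scores, permutation_pvalue,
                     rank_biserial_score, select_de_genes)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracle: recompute everything from raw cells per assignment


def brute_force_pvalue(cells_by_donor: dict[str, np.ndarray],
                       grouping: dict[str, str]) -> tuple[float, float]:
    """Exhaustive two-sided permutation p-value from first principles."""

    def score(x, y):
        u = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        return 2.0 * u / (len(x) * len(y)) - 1.0

    def statistic(patients, controls):
        vals = sorted(score(cells_by_donor[p], cells_by_donor[c])
                      for p in patients for c in controls)
        n = len(vals)
        mid = n // 2
        return vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0

    donors = sorted(cells_by_donor)
    n_pat = sum(grouping[d] == "patient" for d in donors)
    t_obs = statistic([d for d in donors if grouping[d] == "patient"],
                      [d for d in donors if grouping[d] == "control"])
    hits = total = 0
    for pat in itertools.combinations(donors, n_pat):
        ctl = [d for d in donors if d not in pat]
        total += 1
        if abs(statistic(list(pat), ctl)) >= abs(t_obs) - 1e-12:
            hits += 1
    return t_obs, hits / total


def table_from_raw(cells_by_donor: dict[str, np.ndarray]) -> PairwiseScoreTable:
    donors = sorted(cells_by_donor)
    expr = np.concatenate([cells_by_donor[d] for d in donors])[None, :]
    codes = np.concatenate([[i] * len(cells_by_donor[d])
                            for i, d in enumerate(donors)])
    scores = _score_matrix_from_cells(expr.astype(float), codes, len(donors))
    return PairwiseScoreTable(scores=scores, genes=["g"], donors=donors,
                              cells_per_donor={d: len(v) for d, v in
                                               cells_by_donor.items()})


# ---------------------------------------------------------------------------


class TestRankBiserial:
    @pytest.mark.parametrize("x,y,expected", [
        ([5, 6, 7], [1, 2, 3], 1.0),       # complete separation
        ([1, 2, 3], [1, 2, 3], 0.0),       # identical, ties at 1/2
        ([1, 4], [2, 3], 0.0),             # U = 2 of 4 pairs
        ([1, 2, 3], [5, 6, 7], -1.0),
    ])
    def test_known_values(self, x, y, expected):
        assert rank_biserial_score(x, y) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial_score([], [1.0])

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=8),
           st.lists(st.integers(0, 30), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_matches_pair_enumeration_and_antisymmetry(self, x, y):
        u = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        expected = 2 * u / (len(x) * len(y)) - 1
        s = rank_biserial_score(x, y)
        assert s == pytest.approx(expected)
        assert rank_biserial_score(y, x) == pytest.approx(-s)
        assert -1.0 <= s <= 1.0


class TestPairwiseScores:
    def test_expression_filter_and_pair_count(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, size=(100, 3)) + 1
        counts[:, 2] = 0
        counts[:8, 2] = 5            # expressed in 8% of cells -> dropped
        donors = np.repeat(["P1", "P2", "C1", "C2"], 25)
        m = make_matrix(counts, donors,
                        np.where(np.char.startswith(donors.astype(str), "P"),
                                 "patient", "control"),
                        ["balf"] * 100, clusters=["k"] * 100)
        t = pairwise_scores(log_cpm_normalize(m), "k")
        assert "G2" not in t.genes
        assert t.scores.shape == (2, 4, 4)   # C(4,2)=6 pairs stored antisymmetrically
        np.testing.assert_allclose(t.scores, -t.scores.transpose(0, 2, 1))

    def test_constant_expression_scores_zero(self):
        counts = np.full((20, 2), 3)
        donors = np.repeat(["P1", "C1"], 10)
        m = make_matrix(counts, donors, ["patient"] * 10 + ["control"] * 10,
                        ["balf"] * 20, clusters=["k"] * 20)
        t = pairwise_scores(log_cpm_normalize(m), "k")
        np.testing.assert_array_equal(t.scores, 0.0)


class TestMedianStatistic:
    def test_two_vs_two_median_zero(self):
        # pair scores (+1, +1, -1, -1) across the four cross pairs
        cells = {"P1": np.array([10, 11]), "P2": np.array([0, 1]),
                 "C1": np.array([5, 6]), "C2": np.array([5, 6])}
        t = table_from_raw(cells)
        grouping = {"P1": "patient", "P2": "patient",
                    "C1": "control", "C2": "control"}
        assert median_cross_statistic(t, grouping)["g"] == pytest.approx(0.0)

    def test_complete_separation_is_one(self):
        cells = {"P1": np.array([9, 10]), "P2": np.array([7, 8]),
                 "C1": np.array([0, 1]), "C2": np.array([2, 3])}
        t = table_from_raw(cells)
        grouping = dict.fromkeys(["P1", "P2"], "patient") | \
            dict.fromkeys(["C1", "C2"], "control")
        assert median_cross_statistic(t, grouping)["g"] == 1.0

    def test_single_pair_identity(self):
        cells = {"P1": np.array([3, 9]), "C1": np.array([4, 5])}
        t = table_from_raw(cells)
        grouping = {"P1": "patient", "C1": "control"}
        expected = rank_biserial_score(cells["P1"], cells["C1"])
        assert median_cross_statistic(t, grouping)["g"] == pytest.approx(expected)

    def test_one_sided_grouping_rejected(self):
        cells = {"P1": np.array([1.0]), "P2": np.array([2.0])}
        t = table_from_raw(cells)
        with pytest.raises(ValueError):
            median_cross_statistic(t, {"P1": "patient", "P2": "patient"})


class TestPermutation:
    def test_spec_worked_example(self):
        cells = {"P1": np.array([10, 11]), "P2": np.array([8, 9]),
                 "C1": np.array([0, 1]), "C2": np.array([2, 3])}
        grouping = {"P1": "patient", "P2": "patient",
                    "C1": "control", "C2": "control"}
        res = permutation_pvalue(table_from_raw(cells), grouping)
        assert res.table.loc["g", "statistic"] == 1.0
        assert res.table.loc["g", "p_value"] == pytest.approx(4 / 6)
        assert res.n_permutations == 6

    def test_degenerate_identical_cells_p_one(self):
        cells = {d: np.full(5, 2.0) for d in ["P1", "P2", "C1", "C2"]}
        grouping = {"P1": "patient", "P2": "patient",
                    "C1": "control", "C2": "control"}
        res = permutation_pvalue(table_from_raw(cells), grouping)
        assert res.table.loc["g", "p_value"] == 1.0

    def test_permutation_count_is_binomial_coefficient(self):
        rng = np.random.default_rng(0)
        cells = {f"P{i}": rng.poisson(3, 4).astype(float) for i in range(9)}
        cells |= {f"C{i}": rng.poisson(3, 4).astype(float) for i in range(6)}
        grouping = {d: ("patient" if d.startswith("P") else "control")
                    for d in cells}
        res = permutation_pvalue(table_from_raw(cells), grouping)
        assert res.n_permutations == math.comb(15, 6) == 5005
        assert res.exact

    def test_matches_brute_force_oracle(self):
        """Exact equality with from-scratch enumeration on random fixtures."""
        rng = np.random.default_rng(123)
        for _ in range(30):
            n_pat = rng.integers(1, 4)
            n_ctl = rng.integers(1, 4)
            if n_pat + n_ctl < 3:
                continue
            cells = {f"P{i}": rng.poisson(3, rng.integers(2, 10)).astype(float)
                     for i in range(n_pat)}
            cells |= {f"C{i}": rng.poisson(3, rng.integers(2, 10)).astype(float)
                      for i in range(n_ctl)}
            grouping = {d: ("patient" if d.startswith("P") else "control")
                        for d in cells}
            t_oracle, p_oracle = brute_force_pvalue(cells, grouping)
            res = permutation_pvalue(table_from_raw(cells), grouping)
            assert res.table.loc["g", "statistic"] == pytest.approx(t_oracle)
            assert res.table.loc["g", "p_value"] == pytest.approx(p_oracle)

    def test_label_swap_negates_statistic_keeps_p(self):
        rng = np.random.default_rng(5)
        cells = {f"P{i}": rng.normal(1, 1, 6) for i in range(3)}
        cells |= {f"C{i}": rng.normal(0, 1, 6) for i in range(3)}
        g1 = {d: ("patient" if d.startswith("P") else "control") for d in cells}
        g2 = {d: ("control" if v == "patient" else "patient") for d, v in g1.items()}
        t = table_from_raw(cells)
        r1 = permutation_pvalue(t, g1)
        r2 = permutation_pvalue(t, g2)
        assert r1.table.loc["g", "statistic"] == pytest.approx(
            -r2.table.loc["g", "statistic"])
        assert r1.table.loc["g", "p_value"] == pytest.approx(
            r2.table.loc["g", "p_value"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        cells = {f"P{i}": rng.gamma(2, 1, 8) for i in range(3)}
        cells |= {f"C{i}": rng.gamma(3, 1, 8) for i in range(2)}
        grouping = {d: ("patient" if d.startswith("P") else "control")
                    for d in cells}
        r1 = permutation_pvalue(table_from_raw(cells), grouping)
        warped = {d: np.log1p(v) ** 3 for d, v in cells.items()}
        r2 = permutation_pvalue(table_from_raw(warped), grouping)
        assert r1.table.loc["g", "p_value"] == r2.table.loc["g", "p_value"]
        assert r1.table.loc["g", "statistic"] == pytest.approx(
            r2.table.loc["g", "statistic"])

    def test_monte_carlo_fallback_reported(self):
        rng = np.random.default_rng(2)
        cells = {f"P{i}": rng.poisson(3, 3).astype(float) for i in range(5)}
        cells |= {f"C{i}": rng.poisson(3, 3).astype(float) for i in range(5)}
        grouping = {d: ("patient" if d.startswith("P") else "control")
                    for d in cells}
        res = permutation_pvalue(table_from_raw(cells), grouping,
                                 max_exact=100, seed=0)
        assert not res.exact
        assert res.n_permutations == 100
        assert res.table.loc["g", "p_value"] >= 1 / 100


class TestSelectDeGenes:
    def _result(self, stats, pvals, genes=None):
        genes = genes or [f"g{i}" for i in range(len(stats))]
        tab = pd.DataFrame({"statistic": stats, "p_value": pvals,
                            "direction": ["up"] * len(stats)},
                           index=pd.Index(genes, name="gene"))
        return DETestResult(table=tab, n_permutations=100, n_patients=2,
                            n_controls=2, exact=True)

    def test_cutoff_boundary(self):
        r = self._result([0.74, 0.76, -0.8, 0.75], [0.01] * 4)
        out = select_de_genes(r)
        assert set(out.index) == {"g1", "g2", "g3"}

    def test_truncation_and_order(self):
        n = 400
        rng = np.random.default_rng(0)
        pv = rng.uniform(0.001, 0.05, n)
        r = self._result([0.9] * n, pv)
        out = select_de_genes(r)
        assert len(out) == 300
        assert (np.diff(out["p_value"].to_numpy()) >= 0).all()

    def test_tie_break_by_abs_stat_then_name(self):
        r = self._result([0.8, -0.9, 0.9], [0.01, 0.01, 0.01],
                         genes=["b", "c", "a"])
        out = select_de_genes(r)
        assert list(out.index) == ["a", "c", "b"]
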