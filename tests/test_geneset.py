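"""Gene-set group-separation ratio: worked example, null calibration,
invariances, ranking and word frequencies."""

import numpy as np
import pandas as pd
import pytest

from pwsc.core import GeneSetCollection, PseudobulkProfile, log_cpm_normalize
from pwsc.geneset import (GeneSetDistanceResult, gene_set_distance,
                          prepare_profiles, rank_gene_sets,
                          term_word_frequencies)
from conftest import make_matrix


def profile(values: np.ndarray, groups: list[str], genes=None) -> PseudobulkProfile:
    genes = genes or [f"G{i}" for i in range(values.shape[1])]
    donors = [f"d{i}" for i in range(values.shape[0])]
    return PseudobulkProfile(
        values=pd.DataFrame(values, index=donors, columns=genes),
        donor_groups=dict(zip(donors, groups)),
        cluster_label="k")


TOY_GROUPS = ["patient", "patient", "control", "control"]


def toy_profile():
    """3 genes, two constant; patients at 0/1 and controls at 10/11 on the
    varying gene -> hand-enumerated ratio 7/(1+1) = 3.5."""
    vals = np.array([[5.0, 2.0, 0.0],
                     [5.0, 2.0, 1.0],
                     [5.0, 2.0, 10.0],
                     [5.0, 2.0, 11.0]])
    return profile(vals, TOY_GROUPS)


class TestDistanceRatio:
    def test_worked_example_euclidean(self):
        d = gene_set_distance(toy_profile(), ["G0", "G1", "G2"])
        assert d.value == pytest.approx(3.5)
        assert d.n_genes_used == 3

    def test_manhattan_same_on_single_varying_gene(self):
        d = gene_set_distance(toy_profile(), ["G0", "G1", "G2"],
                              metric="manhattan")
        assert d.value == pytest.approx(3.5)

    def test_too_few_genes_skipped_with_reason(self):
        d = gene_set_distance(toy_profile(), ["G0", "G1"])
        assert d.value is None and d.reason == "too_few_genes"

    def test_degenerate_identical_donors(self):
        vals = np.ones((4, 3))
        d = gene_set_distance(profile(vals, TOY_GROUPS), ["G0", "G1", "G2"])
        assert d.value is None and d.reason == "degenerate"

    def test_perfect_separation_flagged(self):
        vals = np.array([[0.0, 0, 0], [0, 0, 0], [5, 5, 5], [5, 5, 5]])
        d = gene_set_distance(profile(vals, TOY_GROUPS), ["G0", "G1", "G2"])
        assert d.value is None and d.reason == "perfect_separation"

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 5))
        groups = ["patient"] * 3 + ["control"] * 3
        genes = [f"G{i}" for i in range(5)]
        a = gene_set_distance(profile(vals, groups), genes).value
        b = gene_set_distance(profile(vals + 7.3, groups), genes).value
        assert a == pytest.approx(b)

    def test_rotation_invariance_euclidean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        groups = ["patient"] * 3 + ["control"] * 3
        genes = [f"G{i}" for i in range(4)]
        a = gene_set_distance(profile(vals, groups), genes).value
        b = gene_set_distance(profile(vals @ q, groups), genes).value
        assert a == pytest.approx(b)

    def test_monotone_in_group_shift(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 4))
        groups = ["patient"] * 4 + ["control"] * 4
        genes = [f"G{i}" for i in range(4)]
        ratios = []
        for shift in (0.0, 1.0, 3.0, 8.0):
            vals = base.copy()
            vals[:4] += shift
            ratios.append(gene_set_distance(profile(vals, groups), genes).value)
        assert all(np.diff(ratios) > 0)

    def test_null_median_near_half(self):
        """Exchangeable donors: over many random sets the median ratio is
        ~0.5 (overall mean distance ~ each within-group mean distance)."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 300))
        groups = ["patient"] * 5 + ["control"] * 5
        p = profile(vals, groups)
        ratios = []
        for _ in range(250):
            genes = [f"G{i}" for i in rng.choice(300, size=10, replace=False)]
            ratios.append(gene_set_distance(p, genes).value)
        assert np.median(ratios) == pytest.approx(0.5, abs=0.05)


class TestPrepareProfiles:
    def _matrix(self, k1_cells_for_c2=12):
        rows, donors, clusters = [], [], []
        rng = np.random.default_rng(0)
        for donor in ["P1", "P2", "C1", "C2"]:
            for cluster, n in (("k0", 12),
                               ("k1", k1_cells_for_c2 if donor == "C2" else 12)):
                for _ in range(n):
                    rows.append(rng.poisson(5, 20) + 1)
                    donors.append(donor)
                    clusters.append(cluster)
        groups = ["patient" if d.startswith("P") else "control" for d in donors]
        m = make_matrix(np.array(rows), donors, groups, ["balf"] * len(rows),
                        clusters)
        return log_cpm_normalize(m)

    def test_cluster_dropped_when_any_donor_below_min(self):
        profs = prepare_profiles(self._matrix(k1_cells_for_c2=9))
        assert set(profs) == {"k0"}

    def test_all_retained_with_enough_cells(self):
        profs = prepare_profiles(self._matrix())
        assert set(profs) == {"k0", "k1"}
        assert sorted(profs["k0"].donors) == ["C1", "C2", "P1", "P2"]

    def test_low_expression_genes_excluded(self):
        m = self._matrix()
        dense = m.counts_dense()
        dense[:, 0] = 0
        dense[:2, 0] = 3  # ~2% of cells
        m2 = log_cpm_normalize(make_matrix(dense, m.cell_meta["donor_id"],
                                           m.cell_meta["group"],
                                           m.cell_meta["tissue"],
                                           m.cell_meta["cluster_label"]))
        profs = prepare_profiles(m2)
        assert "G0" not in profs["k0"].values.columns

    def test_no_cluster_survives_is_error(self):
        with pytest.raises(ValueError):
            prepare_profiles(self._matrix(), min_cells_per_donor=1000)


class TestRanking:
    def test_planted_set_ranks_first(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(8, 100))
        vals[:4, :5] += 6.0   # patients shifted on the planted genes
        groups = ["patient"] * 4 + ["control"] * 4
        p = profile(vals, groups)
        sets = {"PLANTED": ("", [f"G{i}" for i in range(5)])}
        for i in range(50):
            draw = rng.choice(np.arange(5, 100), size=5, replace=False)
            sets[f"NULL_{i:02d}"] = ("", [f"G{j}" for j in draw])
        res = rank_gene_sets(GeneSetCollection(sets=sets), p)
        assert res.ranked.index[0] == "PLANTED"
        assert res.ranked.loc["PLANTED", "rank"] == 1

    def test_identical_sets_tie_break_by_name(self):
        p = toy_profile()
        c = GeneSetCollection(sets={"B_SET": ("", ["G0", "G1", "G2"]),
                                    "A_SET": ("", ["G0", "G1", "G2"])})
        res = rank_gene_sets(c, p)
        assert list(res.ranked.index) == ["A_SET", "B_SET"]

    def test_metrics_agree_in_rank(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(8, 60))
        vals[:4, :10] += rng.uniform(0.5, 3.0, size=10)
        groups = ["patient"] * 4 + ["control"] * 4
        p = profile(vals, groups)
        sets = {}
        for i in range(40):
            draw = rng.choice(60, size=6, replace=False)
            sets[f"S{i:02d}"] = ("", [f"G{j}" for j in draw])
        c = GeneSetCollection(sets=sets)
        r_e = rank_gene_sets(c, p, metric="euclidean").ranked["rank"]
        r_m = rank_gene_sets(c, p, metric="manhattan").ranked["rank"]
        joined = pd.concat([r_e, r_m], axis=1, keys=["e", "m"])
        rho = joined.corr(method="spearman").loc["e", "m"]
        assert rho > 0.8


class TestWordFrequencies:
    def _result(self, names):
        ranked = pd.DataFrame({"ratio": np.linspace(2, 1, len(names)),
                               "n_genes_used": 5,
                               "rank": np.arange(1, len(names) + 1)},
                              index=pd.Index(names, name="set"))
        return GeneSetDistanceResult(ranked=ranked, skipped=pd.DataFrame(),
                                     metric="euclidean")

    def test_tokenization_and_prefix_strip(self):
        r = self._result(["GO_LIPID_STORAGE", "KEGG_LIPID_METABOLISM"])
        freq = term_word_frequencies(r, top_frac=1.0)
        assert freq["lipid"] == 2
        assert freq["storage"] == 1 and freq["metabolism"] == 1
        assert "go" not in freq.index and "kegg" not in freq.index

    def test_stopwords_removed(self):
        r = self._result(["GO_RESPONSE_OF_CELL_TO_LIPID"])
        freq = term_word_frequencies(r, top_frac=1.0)
        assert "of" not in freq.index and "to" not in freq.index

    def test_top_fraction_restricts(self):
        names = [f"GO_TERM{i}_ALPHA" if i == 0 else f"GO_TERM{i}_BETA"
                 for i in range(100)]
        freq = term_word_frequencies(self._result(names), top_frac=0.01)
        assert "alpha" in freq.index and "beta" not in freq.index
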