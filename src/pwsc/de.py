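"""Distribution-free, donor-aware differential expression testing.

The test avoids pseudoreplication (treating cells as independent samples)
without pooling cells into mini-bulk or assuming a count distribution:

1. For every gene and every pair of donors, the two donors' per-cell
   expression values are compared with the Wilcoxon rank-sum test,
   summarized as the rank-biserial correlation ``2U/(n1·n2) − 1`` ∈ [−1, 1]
   (0 = stochastic equality, +1 = complete separation).
2. The test statistic ``T`` for a gene is the median rank-biserial score
   over all (patient, control) donor pairs.
3. Significance comes from the exact permutation null: every reassignment
   of donors to groups (preserving group sizes) yields a permuted ``T``
   from the *precomputed* pair scores; the two-sided p-value is the
   fraction of assignments (the observed one included) with
   ``|T_perm| ≥ |T_obs|``.

Because the pair scores are computed once, the permutation null costs a
median over a score lookup per assignment — no re-ranking.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import CountMatrix

__all__ = [
    "rank_biserial_score",
    "PairwiseScoreTable",
    "pairwise_scores",
    "median_cross_statistic",
    "permutation_pvalue",
    "select_de_genes",
    "DETestResult",
]

_EPS = 1e-12  # guards float comparisons of exactly representable scores


def rank_biserial_score(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank-biserial correlation between two samples.

    Returns ``2·U/(n_x·n_y) − 1`` where ``U`` counts pairs with
    ``x_i > y_j`` plus half the ties; positive means ``x`` is
    stochastically larger.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_biserial_score requires non-empty samples")
    ranks = rankdata(np.concatenate([x, y]))  # midranks = ½-tie convention
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2
    return 2.0 * u / (x.size * y.size) - 1.0


@dataclasses.dataclass
class PairwiseScoreTable:
    """All donor-pair rank-biserial scores for one cluster.

    ``scores[g, i, j]`` is the score of donor ``i`` versus donor ``j`` on
    gene ``g`` (antisymmetric: ``scores[g, j, i] = −scores[g, i, j]``).
    Only genes passing the expression-fraction filter are present.
    """

    scores: np.ndarray  # (n_genes, n_donors, n_donors)
    genes: list[str]
    donors: list[str]
    cells_per_donor: dict[str, int]
    cluster_label: str | None = None

    def donor_index(self, grouping: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray]:
        """Split donor positions into (patients, controls) per ``grouping``."""
        missing = [d for d in self.donors if d not in grouping]
        if missing:
            raise ValueError(f"grouping does not cover donors: {missing}")
        pat = np.array([i for i, d in enumerate(self.donors)
                        if grouping[d] == "patient"], dtype=int)
        ctl = np.array([i for i, d in enumerate(self.donors)
                        if grouping[d] == "control"], dtype=int)
        if pat.size == 0 or ctl.size == 0:
            raise ValueError("both groups must be non-empty")
        return pat, ctl


@dataclasses.dataclass
class DETestResult:
    """Per-gene statistic and permutation p-value for one cluster."""

    table: pd.DataFrame  # index gene; columns statistic, p_value, direction
    n_permutations: int
    n_patients: int
    n_controls: int
    exact: bool
    cluster_label: str | None = None


def _score_matrix_from_cells(expr: np.ndarray, donor_codes: np.ndarray,
                             n_donors: int) -> np.ndarray:
    """Rank-biserial score for every donor pair, vectorized across genes.

    ``expr`` is (n_genes, n_cells); ``donor_codes`` maps each cell to a
    donor index.  For each unordered donor pair the joint midranks across
    both donors' cells are computed once for all genes.
    """
    n_genes = expr.shape[0]
    scores = np.zeros((n_genes, n_donors, n_donors))
    cells_of = [np.flatnonzero(donor_codes == d) for d in range(n_donors)]
    for i, j in itertools.combinations(range(n_donors), 2):
        ci, cj = cells_of[i], cells_of[j]
        ni, nj = ci.size, cj.size
        joint = np.concatenate([expr[:, ci], expr[:, cj]], axis=1)
        ranks = rankdata(joint, axis=1)
        u = ranks[:, :ni].sum(axis=1) - ni * (ni + 1) / 2
        s = 2.0 * u / (ni * nj) - 1.0
        scores[:, i, j] = s
        scores[:, j, i] = -s
    return scores


def pairwise_scores(m: CountMatrix, cluster: str,
                    min_expr_frac: float = 0.10) -> PairwiseScoreTable:
    """Pair scores for one cluster on the normalized layer.

    Donors without cells in the cluster are excluded first; genes expressed
    (normalized value > 0) in less than ``min_expr_frac`` of the cluster's
    cells are disregarded.
    """
    mask = (m.cell_meta["cluster_label"] == cluster).to_numpy()
    if not mask.any():
        raise ValueError(f"unknown or empty cluster {cluster!r}")
    norm = m.normalized_dense()[mask]
    meta = m.cell_meta.loc[mask]
    donors = sorted(meta["donor_id"].unique())
    if len(donors) < 2:
        raise ValueError("need at least two donors with cells in the cluster")
    groups = meta.groupby("donor_id")["group"].first()
    if len(set(groups)) < 2:
        raise ValueError("need at least one donor per group in the cluster")
    expressed_frac = (norm > 0).mean(axis=0)
    gene_keep = expressed_frac >= min_expr_frac
    genes = [g for g, k in zip(m.gene_ids, gene_keep) if k]
    codes = meta["donor_id"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    scores = _score_matrix_from_cells(norm[:, gene_keep].T, codes, len(donors))
    cells_per_donor = meta["donor_id"].value_counts().to_dict()
    return PairwiseScoreTable(scores=scores, genes=genes, donors=donors,
                              cells_per_donor=cells_per_donor,
                              cluster_label=str(cluster))


def _cross_median(scores: np.ndarray, pat: np.ndarray, ctl: np.ndarray) -> np.ndarray:
    """Median over (patient, control) pair scores, per gene."""
    cross = scores[:, pat[:, None], ctl[None, :]]
    return np.median(cross.reshape(scores.shape[0], -1), axis=1)


def median_cross_statistic(t: PairwiseScoreTable,
                           grouping: Mapping[str, str]) -> pd.Series:
    """The test statistic: per gene, the median score over all ordered
    (patient, control) donor pairs.  Even pair counts use the mean of the
    middle two."""
    pat, ctl = t.donor_index(grouping)
    return pd.Series(_cross_median(t.scores, pat, ctl), index=t.genes,
                     name="statistic")


def _assignments(n_donors: int, n_patients: int, max_exact: int,
                 identity: tuple[int, ...], seed: int | None) -> tuple[np.ndarray, bool]:
    """All (or a seeded subsample of) patient-index subsets, identity included."""
    total = math.comb(n_donors, n_patients)
    if total <= max_exact:
        subsets = np.array(list(itertools.combinations(range(n_donors), n_patients)),
                           dtype=int)
        return subsets, True
    rng = np.random.default_rng(seed)
    chosen = {identity}
    while len(chosen) < max_exact:
        draw = tuple(sorted(rng.choice(n_donors, size=n_patients, replace=False)))
        chosen.add(draw)
    return np.array(sorted(chosen), dtype=int), False


def permutation_pvalue(t: PairwiseScoreTable, grouping: Mapping[str, str],
                       max_exact: int = 200000,
                       seed: int | None = None) -> DETestResult:
    """Exact (or seeded Monte-Carlo) permutation p-values for every gene.

    Enumerates all ``C(n_P + n_C, n_P)`` reassignments of donors to groups
    preserving group sizes; each permuted statistic reuses the precomputed
    pair scores.  Two-sided: ``p = #{|T_perm| ≥ |T_obs|} / #assignments``,
    the identity assignment always counted, so ``p ≥ 1/n_permutations``.
    """
    pat, ctl = t.donor_index(grouping)
    n_donors = len(t.donors)
    if n_donors < 3:
        raise ValueError("permutation test needs at least 3 donors")
    identity = tuple(sorted(pat.tolist()))
    subsets, exact = _assignments(n_donors, pat.size, max_exact, identity, seed)
    n_assign = subsets.shape[0]

    t_obs = _cross_median(t.scores, pat, ctl)
    all_idx = np.arange(n_donors)
    n_genes = t.scores.shape[0]
    exceed = np.zeros(n_genes, dtype=np.int64)
    # chunk over assignments to bound the (genes × assignments × pairs) block
    n_pairs = pat.size * ctl.size
    chunk = max(1, int(10_000_000 // max(1, n_genes * n_pairs)))
    flat = t.scores.reshape(n_genes, -1)
    for start in range(0, n_assign, chunk):
        block = subsets[start:start + chunk]
        ctl_block = np.array([np.setdiff1d(all_idx, row, assume_unique=True)
                              for row in block])
        # flat index of (p, c) pairs for each assignment in the block
        pairs = (block[:, :, None] * n_donors + ctl_block[:, None, :]).reshape(
            block.shape[0], -1)
        perm_t = np.median(flat[:, pairs], axis=2)
        exceed += (np.abs(perm_t) >= np.abs(t_obs)[:, None] - _EPS).sum(axis=1)
    pvals = exceed / n_assign

    direction = np.where(t_obs > 0, "up", np.where(t_obs < 0, "down", "none"))
    table = pd.DataFrame({"statistic": t_obs, "p_value": pvals,
                          "direction": direction}, index=pd.Index(t.genes, name="gene"))
    return DETestResult(table=table, n_permutations=n_assign,
                        n_patients=pat.size, n_controls=ctl.size, exact=exact,
                        cluster_label=t.cluster_label)


def select_de_genes(r: DETestResult, stat_cutoff: float = 0.75,
                    top_n: int = 300) -> pd.DataFrame:
    """Rank and truncate the DE result.

    Keeps genes with ``|T| ≥ stat_cutoff`` (inclusive), sorts ascending by
    p-value with ties broken by ``|T|`` descending then gene symbol, and
    returns at most ``top_n`` rows.
    """
    tab = r.table.copy()
    tab = tab[np.abs(tab["statistic"]) >= stat_cutoff - _EPS]
    tab = tab.rename_axis("gene").reset_index()
    tab["_abs"] = -np.abs(tab["statistic"])
    tab = (tab.sort_values(["p_value", "_abs", "gene"], kind="mergesort")
           .drop(columns="_abs").set_index("gene"))
    return tab.head(top_n)
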