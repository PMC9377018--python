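"""Gene-set group-separation analysis on donor pseudobulk profiles.

For each annotated cell state, donors are represented by their mean
normalized expression restricted to a gene set; the "gene set distance" of
the set is

    ratio = mean(all pairwise donor distances)
            / (mean(within-patient distances) + mean(within-control distances))

Under exchangeable donors every mean distance is about equal, so the ratio
sits near 0.5; when the groups separate, between-group pairs inflate the
numerator and the ratio approaches or exceeds 1.  Gene sets are ranked per
cell state by this ratio; the word frequencies of the top-ranked set names
summarize which functions drive the separation.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import CountMatrix, GeneSetCollection, PseudobulkProfile, pseudobulk_mean

__all__ = [
    "prepare_profiles",
    "gene_set_distance",
    "GeneSetDistance",
    "rank_gene_sets",
    "GeneSetDistanceResult",
    "term_word_frequencies",
    "DEFAULT_STOPWORDS",
    "COLLECTION_PREFIXES",
]

#: Filler and connective words removed from set-name tokenization.
DEFAULT_STOPWORDS = frozenset("""
a an and are as at by for from in into of on or the to via with within
regulation process positive negative pathway activity response signaling
""".split())

#: Gene-set collection prefixes stripped before counting words.
COLLECTION_PREFIXES = ("GO", "GOBP", "GOCC", "GOMF", "KEGG", "REACTOME",
                       "HALLMARK", "WP", "PID", "BIOCARTA")

MIN_GENES_PER_SET = 3


def prepare_profiles(m: CountMatrix, min_cells_per_donor: int = 10,
                     min_expr_frac: float = 0.05) -> dict[str, PseudobulkProfile]:
    """Donor × gene pseudobulk profiles per cluster, with the entry filters.

    A cluster is retained only if *every* donor has at least
    ``min_cells_per_donor`` cells in it; within a retained cluster, genes
    expressed in less than ``min_expr_frac`` of the cluster's cells are
    excluded before averaging.
    """
    if "cluster_label" not in m.cell_meta.columns:
        raise ValueError("cell_meta has no cluster_label column")
    donors = m.cell_meta["donor_id"].unique()
    norm = m.normalized_dense()
    profiles: dict[str, PseudobulkProfile] = {}
    for cluster in sorted(m.cell_meta["cluster_label"].dropna().unique()):
        sub = m.cell_meta[m.cell_meta["cluster_label"] == cluster]
        counts = sub["donor_id"].value_counts()
        if len(counts) < len(donors) or (counts < min_cells_per_donor).any():
            continue
        mask = (m.cell_meta["cluster_label"] == cluster).to_numpy()
        frac = (norm[mask] > 0).mean(axis=0)
        gene_keep = frac >= min_expr_frac
        prof = pseudobulk_mean(m.subset(genes=gene_keep), cluster)
        profiles[str(cluster)] = prof
    if not profiles:
        raise ValueError("no cluster satisfies the per-donor cell-count rule")
    return profiles


@dataclasses.dataclass
class GeneSetDistance:
    """Distance ratio of one gene set on one profile.

    ``value`` is None when the ratio is undefined; ``reason`` then says why
    (``too_few_genes``, ``degenerate`` for 0/0, ``perfect_separation`` for
    a positive numerator over a zero denominator).
    """

    value: float | None
    n_genes_used: int
    reason: str | None = None


def gene_set_distance(p: PseudobulkProfile, genes: Sequence[str],
                      metric: Literal["euclidean", "manhattan"] = "euclidean",
                      ) -> GeneSetDistance:
    """The group-separation ratio of one gene set on one pseudobulk profile."""
    present = [g for g in dict.fromkeys(genes) if g in p.values.columns]
    if len(present) < MIN_GENES_PER_SET:
        return GeneSetDistance(value=None, n_genes_used=len(present),
                               reason="too_few_genes")
    groups = np.array([p.donor_groups[d] for d in p.donors])
    if (groups == "patient").sum() < 2 or (groups == "control").sum() < 2:
        return GeneSetDistance(value=None, n_genes_used=len(present),
                               reason="too_few_donors_per_group")
    x = p.values[present].to_numpy()
    dmat = squareform(pdist(x, metric="cityblock" if metric == "manhattan"
                            else "euclidean"))
    iu = np.triu_indices(len(groups), k=1)
    overall = dmat[iu].mean()
    within = {}
    for grp in ("patient", "control"):
        idx = np.flatnonzero(groups == grp)
        ii, jj = np.triu_indices(len(idx), k=1)
        within[grp] = dmat[idx[ii], idx[jj]].mean()
    denom = within["patient"] + within["control"]
    if denom == 0:
        reason = "degenerate" if overall == 0 else "perfect_separation"
        return GeneSetDistance(value=None, n_genes_used=len(present),
                               reason=reason)
    return GeneSetDistance(value=overall / denom, n_genes_used=len(present))


@dataclasses.dataclass
class GeneSetDistanceResult:
    """Ranked gene sets for one cluster."""

    ranked: pd.DataFrame     # index set name; ratio, n_genes_used, rank
    skipped: pd.DataFrame    # index set name; n_genes_used, reason
    metric: str
    cluster_label: str | None = None


def rank_gene_sets(c: GeneSetCollection, p: PseudobulkProfile,
                   metric: Literal["euclidean", "manhattan"] = "euclidean",
                   ) -> GeneSetDistanceResult:
    """Rank every gene set of a collection by descending distance ratio.

    Undefined sets (too few genes, degenerate distances) are excluded from
    the ranking and reported separately.  Ties break by ``n_genes_used``
    descending, then set name.
    """
    rows, skipped = [], []
    for name in c.names():
        d = gene_set_distance(p, c.genes(name), metric=metric)
        if d.value is None:
            skipped.append((name, d.n_genes_used, d.reason))
        else:
            rows.append((name, d.value, d.n_genes_used))
    ranked = pd.DataFrame(rows, columns=["set", "ratio", "n_genes_used"])
    ranked = ranked.sort_values(["ratio", "n_genes_used", "set"],
                                ascending=[False, False, True],
                                kind="mergesort").set_index("set")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    skipped_df = pd.DataFrame(skipped, columns=["set", "n_genes_used", "reason"]
                              ).set_index("set")
    return GeneSetDistanceResult(ranked=ranked, skipped=skipped_df,
                                 metric=metric,
                                 cluster_label=p.cluster_label)


def term_word_frequencies(r: GeneSetDistanceResult, top_frac: float = 0.01,
                          stopwords: Sequence[str] | frozenset = DEFAULT_STOPWORDS,
                          ) -> pd.Series:
    """Word counts over the names of the top-ranked fraction of gene sets.

    Set names are split on underscores/whitespace, lowercased, and
    collection prefixes and stopwords are dropped.
    """
    n_top = max(1, int(np.ceil(top_frac * len(r.ranked))))
    stop = {w.lower() for w in stopwords}
    prefixes = {p.lower() for p in COLLECTION_PREFIXES}
    counts: Counter[str] = Counter()
    for name in r.ranked.index[:n_top]:
        words = [w.lower() for w in re.split(r"[_\s]+", str(name)) if w]
        for w in words:
            if w in prefixes or w in stop:
                continue
            counts[w] += 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)
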