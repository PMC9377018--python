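"""Machine-learning consolidation of multiple cell-type annotations and the
four-step cluster annotation.

Three independent per-cell annotations (e.g. two correlation-based
references plus a signature-regression method) are harmonized to a common
label standard and *triplicated*: every cell contributes three training
rows with identical features and one of its three labels.  A
gradient-boosted tree classifier is trained under grouped 3-fold
cross-validation — all three rows of a cell stay on the same side of every
split — and each cell receives the class-probability argmax from the model
that never saw it.

The cluster-level four-step annotation then takes the per-cell consolidated
labels: (1) per-cell classifier labels, (2) externally supplied cluster
labels, (3) majority label and purity per cluster, (4) marker-gene
confirmation of the majority label and flagging of low-purity clusters as
"mixed cells".
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import GroupKFold

from .core import CountMatrix

__all__ = [
    "TrainingTable",
    "build_training_table",
    "grouped_cv_predict",
    "ConsolidatedAnnotation",
    "marker_genes",
    "four_step_annotate",
    "ClusterAnnotation",
]


@dataclasses.dataclass
class TrainingTable:
    """Triplicated training rows: 3 per cell, identical features, one label
    per annotation source."""

    features: pd.DataFrame   # one row per (cell, source)
    target: pd.Series        # harmonized label per row
    cell_ids: pd.Series      # group key per row
    feature_genes: list[str]

    def __post_init__(self) -> None:
        per_cell = self.cell_ids.value_counts()
        if (per_cell != 3).any():
            bad = per_cell[per_cell != 3].index.tolist()[:5]
            raise ValueError(f"cells without exactly 3 rows: {bad}")


def build_training_table(m: CountMatrix, labels: Sequence[Sequence[str]],
                         label_map: Mapping[str, str],
                         top_k_genes: int | None = 2000) -> TrainingTable:
    """Assemble the triplicated table from three per-cell annotations.

    Features per cell: raw counts (optionally restricted to the
    ``top_k_genes`` most variable genes), a tissue indicator, and the
    per-cell QC metrics (n_genes, total_counts, pct_mito).  Labels are
    harmonized through ``label_map``; any observed label missing from the
    map is an error naming it.
    """
    if len(labels) != 3:
        raise ValueError(f"expected 3 annotation sources, got {len(labels)}")
    labels = [np.asarray(lab) for lab in labels]
    for lab in labels:
        if lab.size != m.n_cells:
            raise ValueError("each annotation must cover all cells")
    observed = set().union(*[set(lab) for lab in labels])
    unmapped = sorted(observed - set(label_map))
    if unmapped:
        raise ValueError(f"labels missing from label_map: {unmapped}")

    counts = m.counts_dense().astype(float)
    gene_ids = np.asarray(m.gene_ids)
    if top_k_genes is not None and top_k_genes < counts.shape[1]:
        var = counts.var(axis=0)
        keep = np.sort(np.argsort(var)[::-1][:top_k_genes])
        counts = counts[:, keep]
        gene_ids = gene_ids[keep]
    feats = pd.DataFrame(counts, columns=gene_ids)
    feats["tissue_is_balf"] = (m.cell_meta["tissue"] == "balf").astype(float).to_numpy()
    for col in ("n_genes", "total_counts", "pct_mito"):
        feats[col] = m.cell_meta[col].to_numpy(dtype=float)

    cell_ids = (m.cell_meta["cell_id"].astype(str)
                if "cell_id" in m.cell_meta.columns
                else pd.Series([f"cell{i}" for i in range(m.n_cells)]))
    rows = pd.concat([feats] * 3, ignore_index=True)
    target = pd.Series(np.concatenate([[label_map[l] for l in lab] for lab in labels]),
                       name="label")
    groups = pd.Series(np.tile(cell_ids.to_numpy(), 3), name="cell_id")
    return TrainingTable(features=rows, target=target, cell_ids=groups,
                         feature_genes=list(gene_ids))


@dataclasses.dataclass
class ConsolidatedAnnotation:
    """Per-cell consolidated labels and class probabilities."""

    labels: pd.Series              # index cell_id
    probabilities: pd.DataFrame    # cell_id × class, rows sum to 1


def grouped_cv_predict(t: TrainingTable, n_folds: int = 3,
                       seed: int | None = 0,
                       classifier_params: Mapping | None = None,
                       ) -> ConsolidatedAnnotation:
    """Out-of-fold consolidated prediction for every cell.

    Folds partition *cells*, never rows: a cell's three labeled rows land
    entirely in training or entirely in test.  The classifier is a
    gradient-boosted decision-tree ensemble (100 trees, depth 3, learning
    rate 0.1 unless overridden).  A fold whose training data misses a
    class triggers a warning; predictions are still produced.
    """
    unique_cells = t.cell_ids.unique()
    if len(unique_cells) < n_folds:
        raise ValueError("need at least n_folds distinct cells")
    params = dict(n_estimators=100, max_depth=3, learning_rate=0.1,
                  random_state=seed)
    params.update(classifier_params or {})
    X = t.features.to_numpy()
    y = t.target.to_numpy()
    all_classes = np.unique(y)
    cv = GroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    labels = pd.Series(index=pd.Index(unique_cells, name="cell_id"), dtype=object)
    proba = pd.DataFrame(0.0, index=labels.index, columns=all_classes)
    groups = t.cell_ids.to_numpy()
    for train_idx, test_idx in cv.split(X, y, groups=groups):
        missing = set(all_classes) - set(y[train_idx])
        if missing:
            warnings.warn(f"fold training data misses classes {sorted(missing)}")
        clf = GradientBoostingClassifier(**params)
        clf.fit(X[train_idx], y[train_idx])
        # each cell appears as 3 identical feature rows; predict one per cell
        test_cells = pd.Series(groups[test_idx])
        first_row = test_cells.drop_duplicates().index.to_numpy()
        cells = test_cells.iloc[first_row].to_numpy()
        p = clf.predict_proba(X[test_idx][first_row])
        for cls_idx, cls in enumerate(clf.classes_):
            proba.loc[cells, cls] = p[:, cls_idx]
    labels[:] = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
    return ConsolidatedAnnotation(labels=labels, probabilities=proba)


def marker_genes(m: CountMatrix, cluster: str, adj_p_max: float = 0.001,
                 min_logfc: float = 0.4, min_frac: float = 0.5) -> pd.DataFrame:
    """Cluster-versus-rest marker genes on the normalized layer.

    Per gene: Wilcoxon rank-sum p-value (Bonferroni-adjusted over all
    genes), natural-log fold change of the expm1-space means (pseudocount
    1), and the expressed fraction within the cluster.  Retained markers
    satisfy adj_p < ``adj_p_max``, logFC ≥ ``min_logfc`` (inclusive) and
    in-cluster expressed fraction ≥ ``min_frac``.
    """
    if "cluster_label" not in m.cell_meta.columns:
        raise ValueError("cell_meta has no cluster_label column")
    if m.cell_meta["cluster_label"].nunique() < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    mask = (m.cell_meta["cluster_label"] == cluster).to_numpy()
    if mask.sum() < 3:
        raise ValueError(f"cluster {cluster!r} has fewer than 3 cells")
    norm = m.normalized_dense()
    inside, outside = norm[mask], norm[~mask]
    with np.errstate(all="ignore"):
        _, pvals = mannwhitneyu(inside, outside, alternative="two-sided", axis=0)
    # constant genes yield nan p-values; they carry no evidence
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    adj = np.minimum(pvals * m.n_genes, 1.0)  # Bonferroni
    lfc = (np.log(np.expm1(inside).mean(axis=0) + 1.0)
           - np.log(np.expm1(outside).mean(axis=0) + 1.0))
    frac = (inside > 0).mean(axis=0)
    tab = pd.DataFrame({"adj_p_value": adj, "log_fc": lfc, "frac_expressed": frac},
                       index=pd.Index(m.gene_ids, name="gene"))
    eps = 1e-12
    keep = ((tab["adj_p_value"] < adj_p_max)
            & (tab["log_fc"] >= min_logfc - eps)
            & (tab["frac_expressed"] >= min_frac))
    return tab[keep].sort_values("adj_p_value", kind="mergesort")


@dataclasses.dataclass
class ClusterAnnotation:
    """Cluster-level outcome of the four-step annotation."""

    table: pd.DataFrame  # index cluster; majority_label, purity, confirmed, mixed


def four_step_annotate(cells: ConsolidatedAnnotation, m: CountMatrix,
                       marker_dict: Mapping[str, Sequence[str]],
                       purity_min: float = 0.5) -> ClusterAnnotation:
    """Steps 3-4 of the annotation strategy on consolidated per-cell labels.

    Per cluster: the majority consolidated label and its purity (fraction
    of cells carrying it); the cluster is *confirmed* when at least one
    canonical marker of the majority label (from ``marker_dict``) passes
    :func:`marker_genes` for that cluster, and flagged *mixed* when purity
    falls below ``purity_min``.  A label absent from ``marker_dict``
    leaves the cluster unconfirmed (not an error).
    """
    cell_ids = (m.cell_meta["cell_id"].astype(str)
                if "cell_id" in m.cell_meta.columns
                else pd.Series([f"cell{i}" for i in range(m.n_cells)]))
    labels = cells.labels.loc[cell_ids].to_numpy()
    clusters = m.cell_meta["cluster_label"]
    rows = []
    for c in sorted(clusters.dropna().unique()):
        in_c = labels[(clusters == c).to_numpy()]
        counts = pd.Series(in_c).value_counts()
        majority = counts.index[0]
        purity = counts.iloc[0] / counts.sum()
        confirmed = False
        canonical = marker_dict.get(majority)
        if canonical:
            found = marker_genes(m, c)
            confirmed = bool(set(canonical) & set(found.index))
        rows.append((c, majority, float(purity), confirmed, purity < purity_min))
    table = pd.DataFrame(rows, columns=["cluster", "majority_label", "purity",
                                        "confirmed", "mixed"]).set_index("cluster")
    return ClusterAnnotation(table=table)
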