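"""Core containers, I/O, quality control and normalization.

The central container is :class:`CountMatrix`: a cell × gene integer count
matrix with per-cell metadata (donor, clinical group, tissue, optional
cluster label) and an optional log-CPM normalized layer.  Everything
downstream — the donor-aware DE test, the gene-set distance analysis and
the annotators — consumes this container or the per-donor pseudobulk
profiles derived from it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "PseudobulkProfile",
    "read_count_matrix",
    "write_count_matrix",
    "qc_filter",
    "log_cpm_normalize",
    "pseudobulk_mean",
    "read_gmt",
    "write_gmt",
]

VALID_GROUPS = ("patient", "control")
VALID_TISSUES = ("balf", "blood")

#: Gene symbols matching any of these prefixes are treated as mitochondrial.
MITO_PREFIXES = ("MT-",)

#: Highly abundant mitochondrial rRNAs that are typically removed before QC.
DEFAULT_GENE_BLACKLIST = ("MT-RNR1", "MT-RNR2")


class FormatError(ValueError):
    """A file did not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """Container contents violate an invariant."""


@dataclasses.dataclass
class CountMatrix:
    """Cell × gene counts with per-cell metadata and an optional normalized layer.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows (dense or CSR sparse).
    cell_meta
        One row per cell.  Required columns: ``donor_id``, ``group``
        (``patient``/``control``), ``tissue`` (``balf``/``blood``).
        Optional: ``cluster_label``.  The derived columns ``n_genes``,
        ``total_counts`` and ``pct_mito`` are computed on construction if
        absent.
    gene_ids
        Unique gene symbols, one per column.
    normalized
        Optional real matrix of the same shape (see
        :func:`log_cpm_normalize`).
    """

    counts: sp.csr_matrix | np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: list[str]
    normalized: sp.csr_matrix | np.ndarray | None = None

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
        else:
            self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValidationError(
                f"cell_meta has {len(self.cell_meta)} rows but counts has "
                f"{self.counts.shape[0]} cells"
            )
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[1]} columns"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        dupes = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
        if len(dupes):
            raise ValidationError(f"duplicate gene symbols: {sorted(set(dupes))}")
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if np.any(data < 0) or not np.allclose(data, np.round(data)):
            raise ValidationError("counts must be non-negative integers")
        for col in ("donor_id", "group", "tissue"):
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta is missing column {col!r}")
        bad = set(self.cell_meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        bad = set(self.cell_meta["tissue"]) - set(VALID_TISSUES)
        if bad:
            raise ValidationError(f"unknown tissue labels: {sorted(bad)}")
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        self._ensure_qc_columns()
        if "pct_mito" in self.cell_meta:
            pm = self.cell_meta["pct_mito"].to_numpy()
            if np.any((pm < 0) | (pm > 100)):
                raise ValidationError("pct_mito outside [0, 100]")

    # -- derived per-cell metrics ------------------------------------------

    def _ensure_qc_columns(self) -> None:
        missing = [c for c in ("n_genes", "total_counts", "pct_mito")
                   if c not in self.cell_meta.columns]
        if not missing:
            return
        dense = self.counts.toarray() if sp.issparse(self.counts) else self.counts
        total = dense.sum(axis=1)
        n_genes = (dense > 0).sum(axis=1)
        mito = np.array([is_mito(g) for g in self.gene_ids])
        mito_counts = dense[:, mito].sum(axis=1) if mito.any() else np.zeros(len(total))
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * mito_counts / np.maximum(total, 1), 0.0)
        if "n_genes" in missing:
            self.cell_meta["n_genes"] = n_genes.astype(int)
        if "total_counts" in missing:
            self.cell_meta["total_counts"] = total.astype(int)
        if "pct_mito" in missing:
            self.cell_meta["pct_mito"] = pct

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) else np.asarray(self.counts)

    def normalized_dense(self) -> np.ndarray:
        if self.normalized is None:
            raise ValidationError("no normalized layer; run log_cpm_normalize first")
        return (self.normalized.toarray() if sp.issparse(self.normalized)
                else np.asarray(self.normalized))

    def subset(self, cells: np.ndarray | None = None,
               genes: np.ndarray | None = None) -> "CountMatrix":
        """Return a new CountMatrix restricted to boolean/integer selections."""
        counts = self.counts
        normalized = self.normalized
        meta = self.cell_meta
        gene_ids = np.asarray(self.gene_ids)
        if cells is not None:
            counts = counts[cells]
            meta = meta.iloc[np.flatnonzero(cells) if np.asarray(cells).dtype == bool
                             else cells]
            if normalized is not None:
                normalized = normalized[cells]
        if genes is not None:
            counts = counts[:, genes]
            gene_ids = gene_ids[genes]
            if normalized is not None:
                normalized = normalized[:, genes]
        return CountMatrix(counts=counts, cell_meta=meta.reset_index(drop=True),
                           gene_ids=list(gene_ids), normalized=normalized)

    def drop_genes(self, blacklist: Sequence[str]) -> "CountMatrix":
        """Remove blacklisted genes (e.g. MT-RNR1/MT-RNR2) before QC."""
        keep = ~np.isin(np.asarray(self.gene_ids), list(blacklist))
        out = self.subset(genes=keep)
        # per-cell metrics must be recomputed without the removed genes
        out.cell_meta = out.cell_meta.drop(columns=["n_genes", "total_counts", "pct_mito"])
        out._ensure_qc_columns()
        return out

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (counts in ``X``,
        normalized layer under ``layers['lognorm']``)."""
        import anndata

        ad = anndata.AnnData(
            X=sp.csr_matrix(self.counts),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        if self.normalized is not None:
            ad.layers["lognorm"] = sp.csr_matrix(self.normalized)
        return ad


def is_mito(gene: str, prefixes: Sequence[str] = MITO_PREFIXES) -> bool:
    return any(gene.upper().startswith(p) for p in prefixes)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed): name → (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclasses.dataclass
class PseudobulkProfile:
    """Per-donor mean normalized expression within one cluster.

    ``values`` is a donor × gene DataFrame; donors with no cells in the
    cluster are absent (never zero-filled).
    """

    values: pd.DataFrame
    donor_groups: dict[str, str]
    cluster_label: str

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate donors in pseudobulk profile")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite pseudobulk values")

    @property
    def donors(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_matrix(path: str | Path, format: str = "mtx_dir") -> CountMatrix:
    """Read a CountMatrix from disk.

    ``mtx_dir``: a directory with ``matrix.mtx`` (triplet COO, cells ×
    genes), ``genes.tsv`` (one symbol per line) and ``cells.tsv``
    (tab-separated metadata with header, one row per cell).

    ``csv``: a dense table, cells in rows, first columns = metadata
    (``donor_id``, ``group``, ``tissue``, optionally ``cluster_label``),
    remaining columns = gene symbols.
    """
    path = Path(path)
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FormatError(f"missing {mtx}")
        try:
            counts = scipy.io.mmread(mtx)
        except Exception as exc:  # pragma: no cover - scipy message varies
            raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
        genes = (path / "genes.tsv").read_text().split()
        cells = pd.read_csv(path / "cells.tsv", sep="\t")
        return CountMatrix(counts=sp.csr_matrix(counts), cell_meta=cells,
                           gene_ids=genes)
    if format == "csv":
        df = pd.read_csv(path)
        meta_cols = [c for c in ("cell_id", "donor_id", "group", "tissue",
                                 "cluster_label") if c in df.columns]
        gene_cols = [c for c in df.columns if c not in meta_cols]
        counts = df[gene_cols].to_numpy()
        return CountMatrix(counts=sp.csr_matrix(counts),
                           cell_meta=df[meta_cols].copy(), gene_ids=gene_cols)
    raise FormatError(f"unknown format {format!r}")


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write in the ``mtx_dir`` dialect understood by :func:`read_count_matrix`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
    (path / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
    cols = [c for c in ("cell_id", "donor_id", "group", "tissue", "cluster_label")
            if c in m.cell_meta.columns]
    m.cell_meta[cols].to_csv(path / "cells.tsv", sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, genes...).

    Duplicate genes within a set are stored once (first occurrence kept).
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                              "expected at least 3 (name, description, genes)")
        name, desc, *genes = fields
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = (desc, list(dict.fromkeys(g for g in genes if g)))
    return GeneSetCollection(sets=sets)


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in c.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# quality control and normalization


def qc_filter(
    m: CountMatrix,
    tissue_mito_max: Mapping[str, float] | None = None,
    min_genes_per_cell: int = 100,
    min_cells_per_gene: int = 3,
) -> CountMatrix:
    """Standard QC: drop rare genes, low-complexity cells and high-mito cells.

    Genes present in fewer than ``min_cells_per_gene`` cells are removed
    first; then cells expressing fewer than ``min_genes_per_cell`` genes
    (counted on the retained genes) and cells whose mitochondrial fraction
    strictly exceeds their tissue's threshold (percent; default blood 5,
    balf 10) are removed.  Both count thresholds are inclusive ("at
    least"), the mito thresholds strict ("greater than").  pct_mito is
    evaluated on the matrix as loaded (before the gene filter), matching
    per-cell QC on the full transcriptome.
    """
    if tissue_mito_max is None:
        tissue_mito_max = {"blood": 5.0, "balf": 10.0}
    dense = m.counts_dense()
    expressed = dense > 0
    gene_keep = np.ones(m.n_genes, dtype=bool)
    pct_mito = m.cell_meta["pct_mito"].to_numpy()
    limits = m.cell_meta["tissue"].map(tissue_mito_max).to_numpy(dtype=float)
    cell_keep = ~(pct_mito > limits)
    # gene→cell passes are repeated until stable: removing cells can push a
    # gene below the cell-count threshold, and idempotence is part of the
    # filter's contract.
    while True:
        new_gene = gene_keep & (expressed[cell_keep].sum(axis=0) >= min_cells_per_gene)
        new_cell = cell_keep & (expressed[:, new_gene].sum(axis=1) >= min_genes_per_cell)
        if new_gene.sum() == gene_keep.sum() and new_cell.sum() == cell_keep.sum():
            gene_keep, cell_keep = new_gene, new_cell
            break
        gene_keep, cell_keep = new_gene, new_cell
        if not cell_keep.any():
            raise ValidationError("QC removed every cell")
    if not cell_keep.any():
        raise ValidationError("QC removed every cell")
    return m.subset(cells=cell_keep, genes=gene_keep)


def log_cpm_normalize(m: CountMatrix, scale: float = 10000.0) -> CountMatrix:
    """Attach the log-CPM layer: ln(1 + count / cell_total × scale).

    Cell totals are taken over the current gene selection; a zero-total
    cell makes the quotient undefined and raises an error naming the cell.
    """
    dense = m.counts_dense().astype(float)
    totals = dense.sum(axis=1)
    if np.any(totals == 0):
        bad = np.flatnonzero(totals == 0)
        ids = (m.cell_meta["cell_id"].iloc[bad].tolist()
               if "cell_id" in m.cell_meta.columns else bad.tolist())
        raise ValidationError(f"cells with zero total counts: {ids}")
    normalized = np.log1p(dense / totals[:, None] * scale)
    return CountMatrix(counts=m.counts, cell_meta=m.cell_meta.copy(),
                       gene_ids=list(m.gene_ids), normalized=normalized)


def pseudobulk_mean(m: CountMatrix, cluster: str) -> PseudobulkProfile:
    """Per-donor mean of normalized expression over the donor's cells in
    ``cluster``.  Donors without cells in the cluster are absent from the
    result."""
    if "cluster_label" not in m.cell_meta.columns:
        raise ValidationError("cell_meta has no cluster_label column")
    mask = (m.cell_meta["cluster_label"] == cluster).to_numpy()
    if not mask.any():
        raise ValidationError(f"unknown or empty cluster {cluster!r}")
    norm = m.normalized_dense()[mask]
    meta = m.cell_meta.loc[mask]
    values = (pd.DataFrame(norm, columns=m.gene_ids, index=meta.index)
              .groupby(meta["donor_id"].to_numpy()).mean())
    values.index.name = "donor_id"
    donor_groups = (meta.groupby("donor_id")["group"].first()).to_dict()
    return PseudobulkProfile(values=values, donor_groups=donor_groups,
                             cluster_label=str(cluster))
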