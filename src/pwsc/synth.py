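"""Seeded synthetic fixtures with the statistical structure the methods assume.

Three generators cover every input the library needs, so the whole test
suite and all examples run without any download:

* :func:`synth_grouped_counts` — donor-structured counts from the
  negative-binomial / log-normal-donor-mean model: planted DE genes differ
  between patient and control groups *only in dispersion* (equal means),
  all other genes are exchangeable between groups.
* :func:`synth_reference_and_clusters` — a reference signature matrix plus
  clustered cells generated from the reference profiles (with NB noise and
  optional mixed clusters), with a truth table for recovery tests.
* :func:`synth_gene_sets` — a GMT-able collection where one planted set
  holds exactly the planted DE genes and the rest are size-matched random
  draws.

A single global seed fans out deterministically to per-component child
seeds through :class:`numpy.random.SeedSequence` (children in the fixed
order counts → reference → gene sets), so each sub-fixture is individually
reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import ReferenceSignature
from .core import CountMatrix, GeneSetCollection
from .simulation import sample_donor_means

__all__ = ["FixtureSpec", "synth_grouped_counts",
           "synth_reference_and_clusters", "synth_gene_sets"]


@dataclasses.dataclass
class FixtureSpec:
    """Parameterization of the synthetic study.

    ``planted_de_genes`` maps gene index → (σ_patient, σ_control); all
    remaining genes use ``sigma_null`` in both groups.  ``n_clusters``
    cells are split evenly across clusters; ``mixed_clusters`` maps a
    cluster index to mixing weights over reference cell types.
    """

    n_patients: int = 4
    n_controls: int = 4
    cells_per_donor: tuple[int, int] = (30, 60)
    n_genes: int = 60
    n_clusters: int = 3
    planted_de_genes: dict[int, tuple[float, float]] = dataclasses.field(
        default_factory=dict)
    planted_shift_genes: dict[int, float] = dataclasses.field(
        default_factory=dict)
    sigma_null: float = 0.5
    n_cell_types: int = 3
    markers_per_type: int = 8
    planted_gene_sets: int = 20
    genes_per_set: int = 8
    mixed_clusters: dict[int, Sequence[float]] = dataclasses.field(
        default_factory=dict)
    tissue: str = "balf"
    seed: int = 0

    def __post_init__(self) -> None:
        for idx in (*self.planted_de_genes, *self.planted_shift_genes):
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"planted gene index {idx} out of range")
        if min(self.n_patients, self.n_controls, self.n_genes,
               self.n_clusters) < 1:
            raise ValueError("all counts must be positive")

    def child_rngs(self) -> tuple[np.random.Generator, ...]:
        return tuple(np.random.default_rng(c)
                     for c in np.random.SeedSequence(self.seed).spawn(3))


def _donor_frame(spec: FixtureSpec, rng: np.random.Generator
                 ) -> tuple[list[str], dict[str, str], np.ndarray]:
    donors = [f"P{i+1}" for i in range(spec.n_patients)] + \
             [f"C{i+1}" for i in range(spec.n_controls)]
    groups = {d: ("patient" if d.startswith("P") else "control") for d in donors}
    lo, hi = spec.cells_per_donor
    n_cells = rng.integers(lo, hi + 1, size=len(donors))
    return donors, groups, n_cells


def synth_grouped_counts(spec: FixtureSpec) -> CountMatrix:
    """Donor-structured counts with dispersion-only planted DE genes.

    Every gene's per-donor mean comes from the shared LogNormal(1, 0.15);
    planted dispersion genes use σ_patient / σ_control per group, all
    others the common ``sigma_null`` — so group *means* agree everywhere
    and only planted genes differ in distribution shape.  Genes in
    ``planted_shift_genes`` instead multiply the patient donors' means by
    the given factor (a conventional location effect).  Cells are assigned
    round-robin to ``n_clusters`` clusters independently of donor.
    """
    rng = spec.child_rngs()[0]
    donors, groups, n_cells = _donor_frame(spec, rng)
    blocks, meta_rows = [], []
    for d_idx, donor in enumerate(donors):
        n = int(n_cells[d_idx])
        mu = sample_donor_means(spec.n_genes, 1, seed=rng)[:, 0]
        block = np.empty((n, spec.n_genes), dtype=np.int64)
        for g in range(spec.n_genes):
            if g in spec.planted_de_genes:
                sig_p, sig_c = spec.planted_de_genes[g]
                sigma = sig_p if groups[donor] == "patient" else sig_c
            else:
                sigma = spec.sigma_null
            mean = mu[g]
            if g in spec.planted_shift_genes and groups[donor] == "patient":
                mean = mu[g] * spec.planted_shift_genes[g]
            r = mean * sigma / (1.0 - sigma)
            block[:, g] = rng.negative_binomial(r, sigma, size=n)
        blocks.append(block)
        for i in range(n):
            meta_rows.append((f"{donor}_c{i}", donor, groups[donor],
                              spec.tissue, f"cluster{i % spec.n_clusters}"))
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "donor_id", "group",
                                            "tissue", "cluster_label"])
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    return CountMatrix(counts=sp.csr_matrix(np.concatenate(blocks, axis=0)),
                       cell_meta=meta, gene_ids=genes)


def synth_reference_and_clusters(spec: FixtureSpec
                                 ) -> tuple[ReferenceSignature, CountMatrix,
                                            pd.DataFrame]:
    """Reference signatures plus clustered cells drawn from them.

    Each cell type gets a base log-normal expression profile with
    ``markers_per_type`` strongly up-regulated marker genes.  Each cluster
    is generated from one cell type (NB noise around the type profile), or
    from a weighted mixture for clusters listed in ``mixed_clusters``.
    Returns (reference, counts-with-cluster-labels, truth table); the
    truth table covers every cluster with its dominant type and mixing
    weights, and each cell's actual generating type is recorded in the
    ``true_type`` metadata column.
    """
    rng = spec.child_rngs()[1]
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    types = [f"type{i+1}" for i in range(spec.n_cell_types)]
    base = rng.lognormal(mean=1.0, sigma=0.3,
                         size=(spec.n_cell_types, spec.n_genes))
    marker_pool = rng.permutation(spec.n_genes)
    for t in range(spec.n_cell_types):
        markers = marker_pool[t * spec.markers_per_type:
                              (t + 1) * spec.markers_per_type]
        base[t, markers] *= 8.0  # planted signatures
    profiles = pd.DataFrame(base, index=types, columns=genes)

    donors, groups, n_cells = _donor_frame(spec, rng)
    blocks, meta_rows, truth_rows = [], [], []
    sigma = spec.sigma_null
    for k in range(spec.n_clusters):
        weights = np.zeros(spec.n_cell_types)
        if k in spec.mixed_clusters:
            weights[:] = np.asarray(spec.mixed_clusters[k], dtype=float)
            weights /= weights.sum()
        else:
            weights[k % spec.n_cell_types] = 1.0
        truth_rows.append((f"cluster{k}", types[int(np.argmax(weights))],
                           weights.tolist()))
        for d_idx, donor in enumerate(donors):
            n = max(1, int(n_cells[d_idx]) // spec.n_clusters)
            cell_types = rng.choice(spec.n_cell_types, size=n, p=weights)
            mu = base[cell_types]  # (n, n_genes)
            r = mu * sigma / (1.0 - sigma)
            block = rng.negative_binomial(r, sigma)
            blocks.append(block)
            for i in range(n):
                meta_rows.append((f"{donor}_k{k}_c{i}", donor, groups[donor],
                                  spec.tissue, f"cluster{k}",
                                  types[int(cell_types[i])]))
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "donor_id", "group",
                                            "tissue", "cluster_label",
                                            "true_type"])
    counts = CountMatrix(counts=sp.csr_matrix(np.concatenate(blocks, axis=0)),
                         cell_meta=meta, gene_ids=genes)
    truth = pd.DataFrame(truth_rows, columns=["cluster", "true_type", "weights"]
                         ).set_index("cluster")
    ref = ReferenceSignature(profiles=profiles)
    return ref, counts, truth


def synth_gene_sets(spec: FixtureSpec) -> GeneSetCollection:
    """Planted separating set (exactly the planted DE genes) plus
    size-matched random null sets."""
    if not spec.planted_de_genes:
        raise ValueError("spec has no planted DE genes")
    rng = spec.child_rngs()[2]
    genes = np.array([f"G{i:04d}" for i in range(spec.n_genes)])
    planted = sorted(spec.planted_de_genes)
    sets: dict[str, tuple[str, list[str]]] = {
        "PLANTED_SEPARATING_SET": ("planted dispersion-shift genes",
                                   list(genes[planted])),
    }
    size = max(len(planted), spec.genes_per_set)
    for i in range(spec.planted_gene_sets):
        draw = rng.choice(spec.n_genes, size=min(size, spec.n_genes),
                          replace=False)
        sets[f"NULL_SET_{i:03d}"] = ("random null set", list(genes[np.sort(draw)]))
    return GeneSetCollection(sets=sets)
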