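import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pwsc.core import CountMatrix, log_cpm_normalize


def make_matrix(counts, donors, groups, tissues, clusters=None, genes=None):
    counts = np.asarray(counts)
    meta = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(counts.shape[0])],
        "donor_id": donors,
        "group": groups,
        "tissue": tissues,
    })
    if clusters is not None:
        meta["cluster_label"] = clusters
    genes = genes or [f"G{i}" for i in range(counts.shape[1])]
    return CountMatrix(counts=sp.csr_matrix(counts), cell_meta=meta,
                       gene_ids=genes)


@pytest.fixture
def tiny_matrix():
    """3 cells x 4 genes, two donors, one mito gene."""
    counts = [[10, 90, 0, 0],
              [0, 50, 50, 0],
              [1, 1, 1, 1]]
    return make_matrix(counts,
                       donors=["d1", "d1", "d2"],
                       groups=["patient", "patient", "control"],
                       tissues=["balf", "balf", "blood"],
                       genes=["MT-CO1", "ACTB", "CD68", "LYZ"])


@pytest.fixture
def clustered_matrix():
    """Two clusters, four donors (2 patients / 2 controls), normalized."""
    rng = np.random.default_rng(42)
    donors = np.repeat(["P1", "P2", "C1", "C2"], 30)
    groups = np.where(np.char.startswith(donors.astype(str), "P"),
                      "patient", "control")
    clusters = np.tile(["k0", "k1"], 60)
    counts = rng.poisson(5, size=(120, 10)) + 1
    # plant a separating gene in cluster k0: patients higher on G0
    in_k0 = clusters == "k0"
    is_pat = groups == "patient"
    counts[in_k0 & is_pat, 0] += 40
    m = make_matrix(counts, donors, groups, ["balf"] * 120, clusters)
    return log_cpm_normalize(m)
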