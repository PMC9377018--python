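"""Simulation benchmark for the donor-aware DE test.

The generative model: per gene and donor, a mean is drawn from a shared
log-normal, ``μ ~ LogNormal(m=1, s=0.15)``, giving between-individual
variability with an identical law in both groups.  Per-cell counts are
negative binomial with ``h(μ,σ) = μ·σ/(1−σ)`` successes and success
probability ``σ`` (counting failures), so ``E[count] = μ`` for every σ and
``Var[count] = μ/σ``.  Two regimes:

* case I  — σ1 ≠ σ2: the groups share mean structure but differ in
  distribution shape; a mean-based test sees nothing, a distribution test
  should (false-negative-rate benchmark).
* case II — σ1 = σ2: the groups are exchangeable; any rejection is a false
  positive (type-I-error benchmark).

Each (σ1, σ2) combination simulates 3 independent "sets" of 50 genes; the
false negative rate is the percentage of genes with p > 0.05 (case I) and
the false positive rate the percentage with p < 0.05 (case II).  An edgeR
comparison arm (TMM + exactTest via Rscript) runs on identical counts.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import subprocess
import tempfile
import warnings
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .de import PairwiseScoreTable, _score_matrix_from_cells, permutation_pvalue

__all__ = [
    "SimulationScenario",
    "SimulatedSet",
    "sample_donor_means",
    "simulate_counts",
    "simulate_set",
    "run_scenario",
    "error_rates",
    "run_benchmark",
    "edger_available",
    "edger_pvalues",
    "DEFAULT_EQUAL_SIGMA_GRID",
    "DEFAULT_UNEQUAL_SIGMA_GRID",
    "CELLS_PER_DONOR_PRESETS",
]

#: Equal-dispersion (case II) grid: nine σ values spanning [0.1, 0.9].
DEFAULT_EQUAL_SIGMA_GRID: list[tuple[float, float]] = [
    (round(s, 2), round(s, 2)) for s in np.linspace(0.1, 0.9, 9)
]

#: Unequal-dispersion (case I) grid: combinations 1-5 have wide σ gaps
#: (clear distribution differences), 6-8 narrow gaps, and combination 9
#: uses the very small σ1 = 0.086 whose zero inflation again makes the
#: distributions clearly distinct.
DEFAULT_UNEQUAL_SIGMA_GRID: list[tuple[float, float]] = [
    (0.1, 0.9), (0.1, 0.7), (0.2, 0.9), (0.2, 0.6), (0.3, 0.8),
    (0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.086, 0.25),
]

#: Donor cells-per-donor ranges, largest to smallest cohort depth.
CELLS_PER_DONOR_PRESETS: dict[str, tuple[int, int]] = {
    "combination1": (100, 500),
    "combination2": (50, 250),
    "combination3": (20, 100),
}


@dataclasses.dataclass
class SimulationScenario:
    """Full parameterization of one benchmark cell."""

    sigma1: float
    sigma2: float
    m: float = 1.0
    s: float = 0.15
    n_patients: int = 9
    n_controls: int = 6
    cells_per_donor: tuple[int, int] | Sequence[int] = (100, 500)
    genes_per_set: int = 50
    n_sets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for sig in (self.sigma1, self.sigma2):
            if not 0 < sig < 1:
                raise ValueError(f"sigma must be in (0, 1), got {sig}")
        if self.genes_per_set < 1:
            raise ValueError("genes_per_set must be >= 1")

    @property
    def case(self) -> str:
        return "II" if self.sigma1 == self.sigma2 else "I"

    @property
    def n_donors(self) -> int:
        return self.n_patients + self.n_controls


@dataclasses.dataclass
class SimulatedSet:
    """One simulated set: counts plus the donor layout that generated it."""

    counts: np.ndarray          # (n_genes, n_cells) integer
    donor_codes: np.ndarray     # cell -> donor position
    donors: list[str]
    grouping: dict[str, str]


def sample_donor_means(n_genes: int, n_donors: int, m: float = 1.0,
                       s: float = 0.15,
                       seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw the (gene × donor) log-normal mean matrix, one shared law for
    all donors regardless of group."""
    if s <= 0:
        raise ValueError("s must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.lognormal(mean=m, sigma=s, size=(n_genes, n_donors))


def simulate_counts(mu: float, sigma: float, n_cells: int,
                    seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Negative-binomial counts with ``h(μ,σ) = μσ/(1−σ)`` successes and
    success probability σ (counting failures): ``E = μ``, ``Var = μ/σ``."""
    if not 0 < sigma < 1:
        raise ValueError(f"sigma must be in (0, 1), got {sigma}")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r = mu * sigma / (1.0 - sigma)
    return rng.negative_binomial(r, sigma, size=n_cells)


def _donor_cell_counts(sc: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    cpd = sc.cells_per_donor
    if isinstance(cpd, tuple) and len(cpd) == 2 and all(isinstance(v, int) for v in cpd):
        return rng.integers(cpd[0], cpd[1] + 1, size=sc.n_donors)
    cpd = np.asarray(cpd, dtype=int)
    if cpd.size != sc.n_donors:
        raise ValueError("cells_per_donor list must have one entry per donor")
    return cpd


def simulate_set(sc: SimulationScenario, set_index: int = 0) -> SimulatedSet:
    """Simulate one set of ``genes_per_set`` independent genes.

    Deterministic in ``(sc, set_index)``: the scenario seed is fanned out
    to per-set child seeds via :class:`numpy.random.SeedSequence`.
    """
    child = np.random.SeedSequence(sc.seed).spawn(sc.n_sets)[set_index]
    rng = np.random.default_rng(child)
    donors = [f"P{i+1}" for i in range(sc.n_patients)] + \
             [f"C{i+1}" for i in range(sc.n_controls)]
    grouping = {d: ("patient" if d.startswith("P") else "control") for d in donors}
    n_cells_per_donor = _donor_cell_counts(sc, rng)
    mu = sample_donor_means(sc.genes_per_set, sc.n_donors, sc.m, sc.s, rng)
    blocks, codes = [], []
    for d in range(sc.n_donors):
        sigma = sc.sigma1 if grouping[donors[d]] == "patient" else sc.sigma2
        n = int(n_cells_per_donor[d])
        block = np.empty((sc.genes_per_set, n), dtype=np.int64)
        for g in range(sc.genes_per_set):
            block[g] = simulate_counts(mu[g, d], sigma, n, rng)
        blocks.append(block)
        codes.append(np.full(n, d))
    return SimulatedSet(counts=np.concatenate(blocks, axis=1),
                        donor_codes=np.concatenate(codes),
                        donors=donors, grouping=grouping)


def score_table_for_set(s: SimulatedSet) -> PairwiseScoreTable:
    """Pairwise rank-biserial scores on raw simulated counts (rank-based,
    so normalization is immaterial for equal-depth simulated genes)."""
    scores = _score_matrix_from_cells(s.counts.astype(float), s.donor_codes,
                                      len(s.donors))
    cells = {d: int((s.donor_codes == i).sum()) for i, d in enumerate(s.donors)}
    genes = [f"g{i}" for i in range(s.counts.shape[0])]
    return PairwiseScoreTable(scores=scores, genes=genes, donors=s.donors,
                              cells_per_donor=cells)


def run_scenario(sc: SimulationScenario,
                 max_exact: int = 200000) -> list[pd.DataFrame]:
    """Run the donor-aware DE test on every set of a scenario.

    Returns one DataFrame per set with per-gene ``statistic`` and
    ``p_value`` (no expression filter: every simulated gene is tested).
    """
    out = []
    for set_index in range(sc.n_sets):
        sim = simulate_set(sc, set_index)
        table = score_table_for_set(sim)
        res = permutation_pvalue(table, sim.grouping, max_exact=max_exact,
                                 seed=sc.seed + set_index)
        out.append(res.table)
    return out


def error_rates(pvals: Sequence[float], case: Literal["I", "II"],
                alpha: float = 0.05) -> float:
    """FNR (case I, % of p > α) or FPR (case II, % of p < α), in percent.

    A p-value exactly equal to α counts toward neither rate (strict
    inequalities on both sides).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if case == "I":
        return 100.0 * float((p > alpha).mean())
    if case == "II":
        return 100.0 * float((p < alpha).mean())
    raise ValueError(f"case must be 'I' or 'II', got {case!r}")


# ---------------------------------------------------------------------------
# edgeR comparison arm


def _harness_script() -> Path:
    return Path(importlib.resources.files("pwsc") / "edger_harness.R")


def edger_available() -> bool:
    """True if Rscript and the edgeR package can be invoked."""
    try:
        proc = subprocess.run(
            ["Rscript", "-e", "suppressMessages(library(edgeR)); cat('ok')"],
            capture_output=True, text=True, timeout=120)
    except (OSError, subprocess.TimeoutExpired):
        return False
    return proc.returncode == 0 and "ok" in proc.stdout


def edger_pvalues(sets: Iterable[SimulatedSet],
                  unit: Literal["donor", "cell"] = "donor") -> list[np.ndarray]:
    """exactTest p-values for each simulated set, via one Rscript call.

    ``unit="donor"`` (default) sums counts per donor so edgeR's samples are
    statistically independent units; ``unit="cell"`` passes each cell as a
    library (treats cells as replicates, ignoring donor structure).
    """
    sets = list(sets)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        for i, s in enumerate(sets):
            if unit == "donor":
                mat = np.stack([s.counts[:, s.donor_codes == d].sum(axis=1)
                                for d in range(len(s.donors))], axis=1)
                samples = s.donors
            else:
                mat = s.counts
                samples = [f"cell{j}" for j in range(s.counts.shape[1])]
            df = pd.DataFrame(mat, columns=samples,
                              index=[f"g{g}" for g in range(mat.shape[0])])
            df.to_csv(tmp / f"counts_{i}.tsv", sep="\t")
            if unit == "donor":
                groups = [s.grouping[d] for d in s.donors]
            else:
                groups = [s.grouping[s.donors[c]] for c in s.donor_codes]
            (tmp / f"groups_{i}.txt").write_text("\n".join(groups) + "\n")
        proc = subprocess.run(
            ["Rscript", str(_harness_script()), str(tmp), str(len(sets))],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"edgeR harness failed:\n{proc.stderr}")
        return [pd.read_csv(tmp / f"pvalues_{i}.tsv", sep="\t")["p_value"].to_numpy()
                for i in range(len(sets))]


def run_benchmark(grid: Iterable[SimulationScenario],
                  methods: Sequence[str] = ("median_wilcoxon_perm", "edger"),
                  alpha: float = 0.05,
                  max_exact: int = 200000,
                  edger_unit: Literal["donor", "cell"] = "donor") -> pd.DataFrame:
    """Run the full benchmark: one row per (scenario, set, method).

    Columns: scenario id, σ1, σ2, case, set index, method, rate type
    (``fnr``/``fpr``) and the rate in percent.  If the R harness is
    unavailable the edgeR arm is skipped with a warning and the
    proposed-method rows are still produced.
    """
    grid = list(grid)
    want_edger = "edger" in methods
    if want_edger and not edger_available():
        warnings.warn("edgeR harness unavailable; skipping the edger arm")
        want_edger = False
    rows = []
    edger_jobs: list[tuple[int, int, SimulatedSet]] = []
    for si, sc in enumerate(grid):
        for set_index in range(sc.n_sets):
            sim = simulate_set(sc, set_index)
            if "median_wilcoxon_perm" in methods:
                table = score_table_for_set(sim)
                res = permutation_pvalue(table, sim.grouping,
                                         max_exact=max_exact,
                                         seed=sc.seed + set_index)
                rate = error_rates(res.table["p_value"], sc.case, alpha)
                rows.append((si, sc.sigma1, sc.sigma2, sc.case, set_index,
                             "median_wilcoxon_perm",
                             "fnr" if sc.case == "I" else "fpr", rate))
            if want_edger:
                edger_jobs.append((si, set_index, sim))
    if edger_jobs:
        pvals = edger_pvalues([s for _, _, s in edger_jobs], unit=edger_unit)
        for (si, set_index, _), p in zip(edger_jobs, pvals):
            sc = grid[si]
            rate = error_rates(p, sc.case, alpha)
            rows.append((si, sc.sigma1, sc.sigma2, sc.case, set_index, "edger",
                         "fnr" if sc.case == "I" else "fpr", rate))
    return pd.DataFrame(rows, columns=["scenario", "sigma1", "sigma2", "case",
                                       "set", "method", "rate_type", "rate"])
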