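"""Coalescent SNP simulation for the fur-seal demographic scenarios.

Two scenario families are provided. The *two-decline* scenario models, in
backward time, two descendant demes (NZ-North and NZ-South) that merge at
the post-sealing recolonization time into a small refugium, which then grows
back (backward: is resized) to the historical size at the European-sealing
time and to the pre-human size at the Polynesian-hunting time. The *null*
scenario keeps a single constant ancestral size behind the same divergence.
A finite-island model supplies the neutral null for the FST-outlier scan.

All loci are unlinked; each carries exactly one mutation placed uniformly on
the genealogy's total branch length, and loci are redrawn until the pooled
minor-allele frequency clears the ascertainment threshold (Hudson-style SNP
sampling). Times are generations throughout; the generation-time entry is
used only when annotating reports in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .genotypes import GenotypeMatrix, LocusInfo, PopulationMap


class ScenarioError(ValueError):
    """Invalid demographic scenario or parameter set."""


class SimulationError(RuntimeError):
    """Simulation failed (e.g. ascertainment redraw cap exceeded)."""


@dataclass
class ScenarioParams:
    """Parameters of the two-decline recolonization history.

    Sizes are diploid effective sizes; times are generations before present.
    """

    Ne_NZ_S: float
    Ne_NZ_N: float
    Ne_refugium: float
    Ne_historical_NZ: float
    Ne_pre_historical: float
    t_Polynesian: float
    t_Europeans: float
    t_post_seal: float

    def validate(self) -> None:
        for name in ("Ne_NZ_S", "Ne_NZ_N", "Ne_refugium", "Ne_historical_NZ", "Ne_pre_historical"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be > 0")
        for name in ("t_Polynesian", "t_Europeans", "t_post_seal"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be > 0")
        if not self.t_Europeans > self.t_post_seal:
            raise ScenarioError("condition violated: t_Europeans > t_post_seal")
        if not self.t_Polynesian > self.t_Europeans:
            raise ScenarioError("condition violated: t_Polynesian > t_Europeans")
        if not self.Ne_pre_historical > self.Ne_NZ_N:
            raise ScenarioError("condition violated: Ne_pre_historical > Ne_NZ_N")
        if not self.Ne_pre_historical > self.Ne_NZ_S:
            raise ScenarioError("condition violated: Ne_pre_historical > Ne_NZ_S")


@dataclass(frozen=True)
class Event:
    """Backward-time demographic event.

    ``merge`` moves every lineage of ``deme`` into deme 0 (optionally
    resizing deme 0); ``resize`` sets the size of ``deme``.
    """

    time: float
    action: str  # "merge" | "resize"
    deme: int
    size: float | None = None


@dataclass
class DemographicScenario:
    """Piecewise-constant multi-deme demography with diploid sample sizes."""

    deme_labels: list
    sample_sizes: list  # diploid individuals per deme
    initial_sizes: list  # diploid Ne per deme at time 0
    events: list = field(default_factory=list)
    migration_rate: float = 0.0  # per-lineage, to a uniformly chosen other deme
    generation_time_years: float = 7.0

    def validate(self) -> None:
        if len(self.deme_labels) != len(self.sample_sizes) or len(self.deme_labels) != len(self.initial_sizes):
            raise ScenarioError("deme label / sample size / initial size lengths differ")
        if any(s <= 0 for s in self.initial_sizes):
            raise ScenarioError("all deme sizes must be > 0")
        if any(n < 1 for n in self.sample_sizes):
            raise ScenarioError("all sample sizes must be >= 1")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScenarioError("event times must be strictly increasing backward")
        if any(t <= 0 for t in times):
            raise ScenarioError("event times must be > 0")
        merged = {e.deme for e in self.events if e.action == "merge"}
        if len(self.deme_labels) > 1 and self.migration_rate <= 0:
            needed = set(range(1, len(self.deme_labels)))
            if not needed <= merged:
                raise ScenarioError("scenario never reaches a single ancestral deme")

    # -- kernel encoding -------------------------------------------------
    def _arrays(self):
        samples = np.asarray([2 * int(n) for n in self.sample_sizes], dtype=np.int64)
        sizes0 = np.asarray(self.initial_sizes, dtype=float)
        ev_time = np.asarray([e.time for e in self.events], dtype=float)
        ev_kind = np.asarray(
            [_kernels.EV_MERGE if e.action == "merge" else _kernels.EV_RESIZE for e in self.events],
            dtype=np.int64,
        )
        ev_deme = np.asarray([e.deme for e in self.events], dtype=np.int64)
        ev_size = np.asarray([-1.0 if e.size is None else float(e.size) for e in self.events], dtype=float)
        return samples, sizes0, float(self.migration_rate), ev_time, ev_kind, ev_deme, ev_size


@dataclass
class SimConfig:
    """Locus count, SNP ascertainment threshold and seed for one dataset."""

    n_loci: int = 1000
    min_maf_pooled: float = 0.05
    max_redraws_per_locus: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ScenarioError("n_loci must be >= 1")
        if not 0.0 <= self.min_maf_pooled < 0.5:
            raise ScenarioError("min_maf_pooled must be in [0, 0.5)")


def build_two_decline_scenario(p: ScenarioParams, n_N: int, n_S: int) -> DemographicScenario:
    """Two isolated demes merging into a refugium that was larger in the past.

    Backward in time: [0, t_post_seal) two demes sized Ne_NZ_N / Ne_NZ_S;
    at t_post_seal a single deme of size Ne_refugium; at t_Europeans resized
    to Ne_historical_NZ; at t_Polynesian resized to Ne_pre_historical.
    """
    p.validate()
    sc = DemographicScenario(
        deme_labels=["NZ-N", "NZ-S"],
        sample_sizes=[n_N, n_S],
        initial_sizes=[p.Ne_NZ_N, p.Ne_NZ_S],
        events=[
            Event(p.t_post_seal, "merge", 1, p.Ne_refugium),
            Event(p.t_Europeans, "resize", 0, p.Ne_historical_NZ),
            Event(p.t_Polynesian, "resize", 0, p.Ne_pre_historical),
        ],
    )
    sc.validate()
    return sc


def build_null_scenario(Ne_constant: float, Ne_NZ_N: float, Ne_NZ_S: float,
                        t_post_seal: float, n_N: int, n_S: int) -> DemographicScenario:
    """Same divergence, but a single constant-size ancestral deme."""
    if min(Ne_constant, Ne_NZ_N, Ne_NZ_S) <= 0:
        raise ScenarioError("all sizes must be > 0")
    if t_post_seal <= 0:
        raise ScenarioError("t_post_seal must be > 0")
    sc = DemographicScenario(
        deme_labels=["NZ-N", "NZ-S"],
        sample_sizes=[n_N, n_S],
        initial_sizes=[Ne_NZ_N, Ne_NZ_S],
        events=[Event(t_post_seal, "merge", 1, Ne_constant)],
    )
    sc.validate()
    return sc


# ---------------------------------------------------------------------------
# simulation entry points
# ---------------------------------------------------------------------------

def simulate_derived(scenario: DemographicScenario, cfg: SimConfig):
    """Fast path: (genes x loci) derived-allele indicator matrix.

    Genes are ordered deme by deme (2 * sample_sizes[d] copies each).
    """
    scenario.validate()
    cfg.validate()
    samples, sizes0, mig, ev_t, ev_k, ev_d, ev_s = scenario._arrays()
    derived, flag = _kernels.simulate_batch(
        cfg.n_loci, samples, sizes0, mig, ev_t, ev_k, ev_d, ev_s,
        cfg.min_maf_pooled, cfg.max_redraws_per_locus, _as_kernel_seed(cfg.seed),
    )
    if flag < 0:
        raise SimulationError(
            f"locus {-1 - flag}: exceeded {cfg.max_redraws_per_locus} ascertainment "
            f"redraws (scenario={scenario.deme_labels}, min_maf={cfg.min_maf_pooled})"
        )
    return derived


def _as_kernel_seed(seed: int) -> int:
    return int(np.uint32(seed))


def derived_to_genotypes(derived: np.ndarray, scenario: DemographicScenario,
                         chrom: str = "sim") -> tuple:
    """Pair gene copies into diploids within demes -> (GenotypeMatrix, PopulationMap).

    Gene copies within a deme are exchangeable, so consecutive pairing is a
    random pairing in distribution.
    """
    n_loci = derived.shape[1]
    dosage_blocks, individuals, colony_of = [], [], {}
    g0 = 0
    for label, n_dip in zip(scenario.deme_labels, scenario.sample_sizes):
        genes = derived[g0:g0 + 2 * n_dip].astype(np.int8)
        dosage_blocks.append(genes[0::2] + genes[1::2])
        for i in range(n_dip):
            ind = f"{label}_{i + 1:03d}"
            individuals.append(ind)
            colony_of[ind] = label
        g0 += 2 * n_dip
    calls = np.vstack(dosage_blocks)
    loci = [LocusInfo(f"L{j + 1:06d}", chrom, j + 1, ("A", "G")) for j in range(n_loci)]
    pops = PopulationMap(colony_of, {l: l for l in scenario.deme_labels})
    return GenotypeMatrix(individuals, loci, calls), pops


def simulate_dataset(scenario: DemographicScenario, cfg: SimConfig):
    """Simulate a diploid SNP dataset; returns (GenotypeMatrix, PopulationMap)."""
    return derived_to_genotypes(simulate_derived(scenario, cfg), scenario)


def simulate_locus(scenario: DemographicScenario, seed: int) -> np.ndarray:
    """One ascertainment-free SNP: per-gene derived-allele indicators."""
    scenario.validate()
    samples, sizes0, mig, ev_t, ev_k, ev_d, ev_s = scenario._arrays()
    derived, flag = _kernels.simulate_batch(
        1, samples, sizes0, mig, ev_t, ev_k, ev_d, ev_s, 0.0, 1, _as_kernel_seed(seed)
    )
    return derived[:, 0]


def simulate_tree(scenario: DemographicScenario, seed: int):
    """One genealogy as (parent, node_time); leaves first, root parent = -1."""
    scenario.validate()
    samples, sizes0, mig, ev_t, ev_k, ev_d, ev_s = scenario._arrays()
    return _kernels.simulate_tree(samples, sizes0, mig, ev_t, ev_k, ev_d, ev_s,
                                  _as_kernel_seed(seed))


def total_branch_length(parent: np.ndarray, time: np.ndarray) -> float:
    root = int(np.flatnonzero(parent < 0)[0])
    v = np.arange(len(parent)) != root
    return float((time[parent[v]] - time[v]).sum())


# ---------------------------------------------------------------------------
# finite-island model
# ---------------------------------------------------------------------------

def island_scenario(n_demes: int, deme_size: float, migration_rate: float,
                    sample_sizes) -> DemographicScenario:
    """Symmetric finite-island model (no demographic events)."""
    if migration_rate <= 0:
        raise ScenarioError("island model needs migration_rate > 0")
    sizes = [float(deme_size)] * n_demes
    labels = [f"D{i + 1}" for i in range(n_demes)]
    sample_sizes = list(sample_sizes)
    if len(sample_sizes) != n_demes:
        raise ScenarioError("sample_sizes length must equal n_demes")
    return DemographicScenario(labels, sample_sizes, sizes, events=[],
                               migration_rate=float(migration_rate))


def island_model_dataset(n_demes: int, deme_size: float, migration_rate: float,
                         sample_sizes, cfg: SimConfig):
    """Simulate an island-model SNP dataset; returns (GenotypeMatrix, PopulationMap)."""
    sc = island_scenario(n_demes, deme_size, migration_rate, sample_sizes)
    return derived_to_genotypes(simulate_derived(sc, cfg), sc)


def expected_island_fst(deme_size: float, migration_rate: float, n_demes: int) -> float:
    """Closed-form finite-island FST, 1 / (1 + 4Nm (d/(d-1))^2)."""
    c = n_demes / (n_demes - 1.0)
    return 1.0 / (1.0 + 4.0 * deme_size * migration_rate * c * c)
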