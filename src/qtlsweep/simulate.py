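"""Synthetic-data generators for every pipeline input.

Four generators cover the pipeline's data needs so all stages are testable
without external downloads:

* neutral coalescent haplotypes with recombination under piecewise-constant
  demography (msprime ancestry + infinite-sites binary mutations);
* site samples drawn from a sweep-distorted frequency spectrum (the forward
  sampler matching the CLR model, used for power checks);
* per-fly chill-coma recovery phenotypes with line, background and
  interaction effects on the log scale;
* qPCR Cq tables with per-gene amplification efficiencies, stable reference
  genes, pool-level loading offsets and technical-replicate noise.

All generators are pure functions of (config, seed).

Scaling conventions: population sizes are haploid counts, epoch times are in
generations.  ``theta`` and ``rho`` are per-site scaled rates referred to the
most recent epoch size N0 (mutation rate μ = θ / (2 N0), so a constant-size
model has E[π] = θ per site).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .sfs import SFSpectrum, SweepTransform


@dataclass
class DemographyModel:
    """Piecewise-constant size history, most recent epoch first.

    ``epochs`` is a list of (start_time, haploid_size); the first start time
    must be 0 and times must strictly increase going into the past.
    """

    epochs: list[tuple[float, float]]
    label: str = "custom"

    def __post_init__(self) -> None:
        times = [t for t, _ in self.epochs]
        if not self.epochs or times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(later <= earlier for earlier, later in zip(times, times[1:])):
            raise ValueError("epoch start times must strictly increase")
        if any(size <= 0 for _, size in self.epochs):
            raise ValueError("population sizes must be positive")

    @property
    def current_size(self) -> float:
        return self.epochs[0][1]

    def to_msprime(self) -> msprime.Demography:
        demo = msprime.Demography()
        demo.add_population(name="pop0", initial_size=self.current_size)
        for start, size in self.epochs[1:]:
            demo.add_population_parameters_change(time=start, initial_size=size, population="pop0")
        return demo

    @classmethod
    def constant(cls, size: float = 1e6) -> "DemographyModel":
        return cls([(0.0, size)], label="constant")


#: Toy stand-in for an out-of-Africa founding bottleneck: a severe size
#: reduction 20-60 k generations ago with recovery to the ancestral size,
#: which depresses diversity relative to a constant-size population of the
#: ancestral size at the same mutation rate.  Parameter values are
#: illustrative only — inference-derived demographies should be supplied by
#: the user.
TOY_EUROPEAN_BOTTLENECK = DemographyModel(
    epochs=[(0.0, 1e6), (20_000.0, 4e4), (60_000.0, 1e6)],
    label="toy-european-bottleneck",
)


@dataclass
class SimulationConfig:
    n: int = 20
    length: int = 50_000
    theta: float = 0.01
    rho: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.theta < 0 or self.rho < 0:
            raise ValueError("theta and rho must be non-negative")


@dataclass
class HaplotypeData:
    """0/1 haplotype matrix (rows = samples) with continuous positions."""

    positions: np.ndarray
    matrix: np.ndarray
    length: int
    n: int

    @property
    def segsites(self) -> int:
        return self.matrix.shape[1]

    def integer_positions(self) -> np.ndarray:
        """Snap continuous positions to unique 1-based integer coordinates.

        Collisions are resolved by shifting a colliding site to the next
        free coordinate, so no mutation is lost (dropping sites would bias
        diversity estimators downward by ~θ·S/L).
        """
        # site positions are ascending, so a single bump pass suffices
        ints = np.floor(self.positions).astype(np.int64) + 1
        for k in range(1, ints.size):
            if ints[k] <= ints[k - 1]:
                ints[k] = ints[k - 1] + 1
        return ints

    def to_ms_text(self) -> str:
        lines = ["//", f"segsites: {self.segsites}"]
        rel = self.positions / self.length
        lines.append("positions: " + " ".join(f"{p:.6f}" for p in rel))
        for row in self.matrix:
            lines.append("".join(str(int(x)) for x in row))
        return "\n".join(lines) + "\n"


def _derive_seeds(seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(k, dtype=np.uint64)
    return [int(s % (2**31 - 2)) + 1 for s in state]


def simulate_neutral_haplotypes(
    cfg: SimulationConfig, demography: DemographyModel | None = None
) -> HaplotypeData:
    """Neutral coalescent haplotypes with recombination.

    Infinite-sites 0/1 mutations (ancestral state 0) on continuous positions
    in [0, length); per-site rates are rescaled by the most recent epoch size
    so that a constant-size model satisfies E[π] = θ and E[S] = θ·L·a(n).
    """
    demography = demography or DemographyModel.constant()
    n0 = demography.current_size
    mu = cfg.theta / (2.0 * n0)
    r = cfg.rho / (2.0 * n0)
    seed_anc, seed_mut = _derive_seeds(cfg.seed, 2)
    ts = msprime.sim_ancestry(
        samples=cfg.n,
        ploidy=1,
        sequence_length=cfg.length,
        recombination_rate=r,
        demography=demography.to_msprime(),
        random_seed=seed_anc,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed_mut,
    )
    positions = np.array([s.position for s in mts.sites()])
    matrix = mts.genotype_matrix().T.astype(np.int8)  # rows = samples
    return HaplotypeData(positions=positions, matrix=matrix, length=cfg.length, n=cfg.n)


def simulate_sweep_sfs_sites(
    bg: SFSpectrum,
    center: float,
    alpha: float,
    n_sites: int,
    length: float,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sites whose classes follow the sweep-transformed spectrum.

    Positions are uniform on [0, length]; each site's derived-allele class is
    drawn from the post-sweep spectrum at its own escape probability
    p_e = 1 − exp(−α·|pos − center|).  Returns (positions, classes).
    """
    if not bg.extended:
        raise ValueError("sweep site sampling requires an extended background spectrum")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.uniform(0.0, length, size=n_sites))
    pe = 1.0 - np.exp(-alpha * np.abs(positions - center))
    probs = SweepTransform(bg).matrix(pe)  # (n_sites, n+1)
    u = rng.uniform(size=n_sites)
    cum = np.cumsum(probs, axis=1)
    classes = (u[:, None] > cum).sum(axis=1)
    return positions, classes.astype(int)


def sites_from_haplotypes(hap: HaplotypeData, population: str = "sim") -> list:
    """Segregating sites of a 0/1 haplotype matrix as classified site records.

    The ancestral state (0) maps to base A with outgroup A, derived (1) to G,
    so downstream polarization recovers the simulated derived counts.
    Positions are reported on a 1-based integer grid (collisions shifted to
    the next free coordinate); monomorphic positions are implicit — pass
    ``length − segsites`` as the invariant-site count to window statistics.
    """
    from .alignment import SiteRecord

    ints = hap.integer_positions()
    records = []
    n = hap.n
    for k, pos in enumerate(ints):
        j = int(hap.matrix[:, k].sum())
        status = "biallelic" if 0 < j < n else "monomorphic"
        counts = {}
        if n - j > 0:
            counts["A"] = n - j
        if j > 0:
            counts["G"] = j
        records.append(
            SiteRecord(
                coord=int(pos),
                allele_counts={population: counts},
                n_valid={population: n},
                outgroup_base="A",
                status=status,
            )
        )
    return records


def empirical_sfs(hap: HaplotypeData) -> SFSpectrum:
    """Polymorphic-class spectrum of one simulated replicate."""
    counts = np.bincount(hap.matrix.sum(axis=0), minlength=hap.n + 1).astype(float)
    counts[0] = counts[hap.n] = 0.0
    return SFSpectrum(hap.n, counts / counts.sum(), extended=False, source="simulated",
                      n_sites=int(counts.sum()))


@dataclass
class PhenotypeSimConfig:
    """Two-by-two chill-coma phenotype design on the log-minutes scale.

    ``effect_L`` is added for the E line, ``effect_G`` for the deletion
    background, ``effect_LxG`` for the E/deletion cell; recovery times are
    rounded up to whole minutes (scoring resolution is one minute).
    """

    mu: float = math.log(32.0)
    effect_L: float = 0.0
    effect_G: float = 0.0
    effect_LxG: float = 0.0
    sigma: float = 0.25
    n_per_cell: int = 35
    deletion_id: str = "Df(sim)"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")


def simulate_ccrt_dataset(cfg: PhenotypeSimConfig) -> pd.DataFrame:
    """Per-fly chill-coma recovery times for the four genotype classes."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    fly = 0
    for line in ("E", "A"):
        for background in ("def", "bal"):
            loc = cfg.mu
            if line == "E":
                loc += cfg.effect_L
            if background == "def":
                loc += cfg.effect_G
            if line == "E" and background == "def":
                loc += cfg.effect_LxG
            log_ccrt = rng.normal(loc, cfg.sigma, size=cfg.n_per_cell)
            minutes = np.maximum(np.ceil(np.exp(log_ccrt)).astype(int), 1)
            for m in minutes:
                rows.append(
                    {
                        "fly_id": f"fly{fly}",
                        "line": line,
                        "background": background,
                        "deletion_id": cfg.deletion_id,
                        "ccrt_minutes": int(m),
                    }
                )
                fly += 1
    return pd.DataFrame(rows)


@dataclass
class QpcrSimConfig:
    """qPCR design: genes × (population, treatment) groups × pools × triplicates.

    ``true_log2_fold`` maps gene -> {(population, treatment): log2 fold
    relative to the calibrator group}; reference genes must be flat (fold 0).
    ``efficiencies`` are per-gene amplification efficiencies in (1, 2].
    """

    efficiencies: dict[str, float] = field(
        default_factory=lambda: {"target": 2.0, "RpS20": 2.0, "RpL32": 2.0}
    )
    reference_genes: tuple[str, ...] = ("RpS20", "RpL32")
    true_log2_fold: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    populations: tuple[str, ...] = ("NL", "ZK")
    treatments: tuple[str, ...] = ("control", "t10", "t15")
    base_cq: float = 22.0
    pool_sd: float = 0.3
    tech_sd: float = 0.15
    n_pools: int = 3
    n_tech: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        for gene, eff in self.efficiencies.items():
            if not 1.0 < eff <= 2.0:
                raise ValueError(f"efficiency for {gene} must lie in (1, 2]")
        for ref in self.reference_genes:
            if ref not in self.efficiencies:
                raise ValueError(f"reference gene {ref} lacks an efficiency")
            folds = self.true_log2_fold.get(ref, {})
            if any(abs(v) > 1e-12 for v in folds.values()):
                raise ValueError("reference genes must have true_log2_fold = 0")
        if self.tech_sd <= 0 or self.n_pools < 1 or self.n_tech < 1:
            raise ValueError("invalid replication settings")


def simulate_qpcr_cq(cfg: QpcrSimConfig) -> pd.DataFrame:
    """Long-format Cq table.

    Cq = base − log_E(quantity) + pool offset + technical noise, where the
    pool offset models RNA loading differences shared by all genes of a pool
    (it cancels under reference-gene normalization) and quantity = 2^fold.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    pool_offsets = {}
    for pop in cfg.populations:
        for treatment in cfg.treatments:
            for p in range(cfg.n_pools):
                pool_offsets[(pop, treatment, p)] = rng.normal(0.0, cfg.pool_sd)
    for gene, eff in cfg.efficiencies.items():
        folds = cfg.true_log2_fold.get(gene, {})
        for pop in cfg.populations:
            for treatment in cfg.treatments:
                l2f = folds.get((pop, treatment), 0.0)
                for p in range(cfg.n_pools):
                    pool_id = f"{pop}-{treatment}-p{p}"
                    mean_cq = (
                        cfg.base_cq
                        - l2f * math.log(2.0) / math.log(eff)
                        + pool_offsets[(pop, treatment, p)]
                    )
                    for t in range(cfg.n_tech):
                        rows.append(
                            {
                                "gene": gene,
                                "pool_id": pool_id,
                                "population": pop,
                                "treatment": treatment,
                                "tech_replicate": t,
                                "cq": mean_cq + rng.normal(0.0, cfg.tech_sd),
                            }
                        )
    return pd.DataFrame(rows)
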