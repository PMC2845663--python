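"""Forward-in-time simulator of predominantly selfing annual-plant
metapopulations with full pedigree truth.

The model: discrete non-overlapping generations; each stand holds a fixed
number of plants (its carrying capacity).  Every offspring picks a random
ovule parent from the stand; with probability ``t`` (the outcrossing rate
per ovule) a pollen parent is drawn from the other plants of the stand —
uniformly when the pollen kernel is infinite (random partner), otherwise
weighted by a Gaussian kernel of scale ``mating_kernel_sigma`` on planar
distance (nearest-neighbor mating).  Otherwise the ovule self-fertilizes.
Meiosis applies a Poisson number of crossovers per chromosome at uniform bp
positions.  Offspring are placed near their mother (Gaussian seed
dispersal) and rare whole-seed migration moves a selfed seed between
stands.  Mutation is disabled: at a few tens of generations the single-base
mutation rate is negligible next to even a very low outcrossing rate.

Every birth is logged (mother, father, selfed flag, crossovers), so every
sampled genotype is derivable from the founders via the event log, and
outcrossing / migration footprints in the output have known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypeTable, Marker, MarkerMap, StandInfo

__all__ = [
    "ARABIDOPSIS_CHROM_LENGTHS",
    "SimConfig",
    "PedigreeTruth",
    "SimulatedDataset",
    "generate_founders",
    "simulate",
    "sample_survey",
    "make_ril_stand",
]

# The five A. thaliana chromosome lengths (bp), for realistic marker spacing.
ARABIDOPSIS_CHROM_LENGTHS = (30_400_000, 19_700_000, 23_500_000, 18_600_000, 27_000_000)


@dataclass
class SimConfig:
    """Parameters of the selfing-metapopulation simulator.

    ``t`` may be a scalar (global outcrossing probability per ovule), a
    sequence of per-stand values, or — via ``t_schedule`` — a per-generation
    sequence, which makes it possible to let lineages fix by selfing and
    then inject a known pulse of outcrossing.
    ``mating_kernel_sigma = inf`` means random-partner outcrossing.
    """

    n_stands: int = 10
    capacity: int | Sequence[int] = 20
    n_markers: int = 100
    maf_range: tuple[float, float] = (0.2, 0.5)
    founders_per_stand: int = 5
    t: float | Sequence[float] = 0.02
    t_schedule: Sequence[float] | None = None  # overrides t per generation
    mating_kernel_sigma: float = math.inf  # meters
    seed_dispersal_sigma: float = 0.3  # meters
    stand_extent: float = 5.0  # meters; founders scattered over this scale
    migration_rate: float = 0.0  # per stand per generation
    generations: int = 20
    recomb_rate: float = 1.0  # expected crossovers per chromosome per meiosis
    chrom_lengths: Sequence[int] = ARABIDOPSIS_CHROM_LENGTHS
    region_extent: float = 20_000.0  # meters; stands scattered over this scale
    site_types: Sequence[str] | None = None  # per stand; default all "rural"
    seed: int = 0

    def __post_init__(self):
        if self.n_markers < 1 or self.generations < 1 or self.n_stands < 1:
            raise ValueError("n_markers, generations and n_stands must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for p in np.atleast_1d(np.asarray(self.t, dtype=float)):
            if not 0.0 <= p <= 1.0:
                raise ValueError("outcrossing probability must be in [0, 1]")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")

    def capacities(self) -> np.ndarray:
        cap = np.broadcast_to(np.asarray(self.capacity, dtype=int), (self.n_stands,))
        if (cap < 1).any():
            raise ValueError("capacities must be >= 1")
        return cap.copy()

    def t_per_stand(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.t, dtype=float), (self.n_stands,)).copy()


@dataclass
class IndividualRecord:
    individual_id: str
    stand_id: str
    generation: int
    mother_id: str
    father_id: str
    selfed: bool
    # crossover bp positions per gamete: two tuples of (chrom, pos) lists
    crossovers: tuple[tuple[tuple[int, float], ...], tuple[tuple[int, float], ...]]


@dataclass
class PedigreeTruth:
    """Complete event log of a simulation run."""

    individuals: dict[str, IndividualRecord] = field(default_factory=dict)
    outcross_events: list[dict] = field(default_factory=list)
    migration_events: list[dict] = field(default_factory=list)
    founder_ids: list[str] = field(default_factory=list)

    def is_pure_selfed(self, individual_id: str) -> bool:
        """True when the whole ancestry back to a founder is selfing."""
        cur = individual_id
        while cur in self.individuals:
            rec = self.individuals[cur]
            if not rec.selfed:
                return False
            cur = rec.mother_id
        return True

    def outcrossed_in_generation(self, generation: int) -> list[IndividualRecord]:
        return [
            r
            for r in self.individuals.values()
            if r.generation == generation and not r.selfed
        ]


@dataclass
class SimulatedDataset:
    table: GenotypeTable
    marker_map: MarkerMap
    stands: list[StandInfo]
    truth: PedigreeTruth
    haplotypes: dict[str, np.ndarray]  # every pedigree individual -> (2, L)
    positions: dict[str, tuple[float, float]]  # final generation only
    config: SimConfig

    def genotype_of(self, individual_id: str) -> np.ndarray:
        return self.haplotypes[individual_id].sum(axis=0).astype(np.int8)


# ---------------------------------------------------------------------------
# founders and meiosis
# ---------------------------------------------------------------------------


def generate_founders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, MarkerMap]:
    """Draw the founder haplotype pool and a random marker map.

    Markers are placed uniformly at random along the configured chromosome
    lengths; the per-marker allele-b frequency among founder haplotypes is
    drawn uniformly from ``maf_range``.  Founders are fully inbred: each
    founder is one haplotype, used doubled.  Returns an array of shape
    (n_stands * founders_per_stand, L) and the map.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.n_markers
    lens = np.asarray(config.chrom_lengths, dtype=np.int64)
    chroms = rng.integers(0, len(lens), size=L)
    pos = np.array([rng.integers(1, lens[c] + 1) for c in chroms], dtype=np.int64)
    order = np.lexsort((pos, chroms))
    chroms, pos = chroms[order], pos[order]
    # de-duplicate coincident positions deterministically
    for i in range(1, L):
        if chroms[i] == chroms[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    markers = [
        Marker(f"m{c + 1}_{i + 1:04d}", int(c + 1), int(p), "A", "C")
        for i, (c, p) in enumerate(zip(chroms, pos))
    ]
    marker_map = MarkerMap(markers)
    n_haps = config.n_stands * config.founders_per_stand
    freqs = rng.uniform(*config.maf_range, size=L)
    pool = (rng.random((n_haps, L)) < freqs[None, :]).astype(np.int8)
    return pool, marker_map


def _meiosis(
    haps: np.ndarray,
    marker_map: MarkerMap,
    chrom_lengths: Sequence[int],
    recomb_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[tuple[int, float], ...], np.ndarray]:
    """One gamete from a diploid: Poisson crossovers per chromosome.

    Returns the gamete, the crossover (chrom, bp) positions, and the phase
    vector saying which parental haplotype each marker was copied from.
    """
    L = haps.shape[1]
    gamete = np.empty(L, dtype=np.int8)
    phase_out = np.empty(L, dtype=np.int8)
    xovers: list[tuple[int, float]] = []
    for chrom, sl in marker_map.chromosome_slices().items():
        length = chrom_lengths[chrom - 1]
        k = rng.poisson(recomb_rate)
        start = int(rng.integers(0, 2))
        if k == 0:
            gamete[sl] = haps[start, sl]
            phase_out[sl] = start
            continue
        cuts = np.sort(rng.uniform(0, length, size=k))
        phase = (start + np.searchsorted(cuts, marker_map.positions[sl])) % 2
        idx = np.arange(sl.start, sl.stop)
        gamete[sl] = haps[phase, idx]
        phase_out[sl] = phase
        xovers.extend((chrom, float(c)) for c in cuts)
    return gamete, tuple(xovers), phase_out


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


def simulate(config: SimConfig) -> SimulatedDataset:
    """Run the forward simulation and return the final generation with truth."""
    rng = np.random.default_rng(config.seed)
    pool, marker_map = generate_founders(config, rng)
    L = config.n_markers
    caps = config.capacities()
    t_stand = config.t_per_stand()
    lens = list(config.chrom_lengths)

    site_types = list(config.site_types or ["rural"] * config.n_stands)
    stand_xy = rng.uniform(0, config.region_extent, size=(config.n_stands, 2))
    stands = [
        StandInfo(f"S{s + 1:03d}", site_types[s], float(stand_xy[s, 0]), float(stand_xy[s, 1]))
        for s in range(config.n_stands)
    ]

    truth = PedigreeTruth()
    haplotypes: dict[str, np.ndarray] = {}  # every individual, all generations
    # state per stand: list of (id, haps (2,L), (x, y) local coords)
    state: list[list[tuple[str, np.ndarray, tuple[float, float]]]] = []
    for s in range(config.n_stands):
        plants = []
        for f in range(caps[s]):
            hap = pool[s * config.founders_per_stand + f % config.founders_per_stand]
            pid = f"F_s{s}_{f}"
            xy = tuple(rng.uniform(0, config.stand_extent, size=2))
            plants.append((pid, np.stack([hap, hap]), xy))
            haplotypes[pid] = plants[-1][1]
            if f < config.founders_per_stand:
                truth.founder_ids.append(pid)
        state.append(plants)

    for gen in range(1, config.generations + 1):
        new_state: list[list[tuple[str, np.ndarray, tuple[float, float]]]] = []
        for s in range(config.n_stands):
            plants = state[s]
            n = len(plants)
            t = t_stand[s] if config.t_schedule is None else config.t_schedule[gen - 1]
            coords = np.array([p[2] for p in plants])
            offspring = []
            mothers = rng.integers(0, n, size=caps[s])
            for k in range(caps[s]):
                mi = int(mothers[k])
                outcross = n > 1 and rng.random() < t
                if outcross:
                    if math.isinf(config.mating_kernel_sigma):
                        fi = int(rng.integers(0, n - 1))
                        fi = fi if fi < mi else fi + 1
                    else:
                        d2 = ((coords - coords[mi]) ** 2).sum(axis=1)
                        w = np.exp(-d2 / (2 * config.mating_kernel_sigma**2))
                        w[mi] = 0.0
                        if w.sum() <= 0:
                            w[:] = 1.0
                            w[mi] = 0.0
                        fi = int(rng.choice(n, p=w / w.sum()))
                else:
                    fi = mi
                gam_m, xo_m, _ = _meiosis(plants[mi][1], marker_map, lens, config.recomb_rate, rng)
                gam_f, xo_f, _ = _meiosis(plants[fi][1], marker_map, lens, config.recomb_rate, rng)
                cid = f"g{gen}_s{s}_{k}"
                xy = (
                    plants[mi][2][0] + rng.normal(0, config.seed_dispersal_sigma),
                    plants[mi][2][1] + rng.normal(0, config.seed_dispersal_sigma),
                )
                rec = IndividualRecord(
                    cid, stands[s].stand_id, gen, plants[mi][0], plants[fi][0],
                    fi == mi, (xo_m, xo_f),
                )
                truth.individuals[cid] = rec
                if fi != mi:
                    truth.outcross_events.append(
                        {"child": cid, "mother": plants[mi][0], "father": plants[fi][0],
                         "generation": gen, "stand_id": stands[s].stand_id}
                    )
                offspring.append((cid, np.stack([gam_m, gam_f]), xy))
                haplotypes[cid] = offspring[-1][1]
            new_state.append(offspring)
        # whole-seed migration: a selfed seed of a random plant moves stands
        if config.migration_rate > 0 and config.n_stands > 1:
            for s in range(config.n_stands):
                if rng.random() < config.migration_rate:
                    src = int(rng.integers(0, config.n_stands - 1))
                    src = src if src < s else src + 1
                    donor = new_state[src][int(rng.integers(0, len(new_state[src])))]
                    slot = int(rng.integers(0, len(new_state[s])))
                    mid = f"g{gen}_s{s}_mig{slot}"
                    xy = tuple(rng.uniform(0, config.stand_extent, size=2))
                    displaced = new_state[s][slot]
                    truth.individuals.pop(displaced[0], None)
                    haplotypes.pop(displaced[0], None)
                    rec = truth.individuals[donor[0]]
                    truth.individuals[mid] = IndividualRecord(
                        mid, stands[s].stand_id, gen, rec.mother_id, rec.father_id,
                        rec.selfed, rec.crossovers,
                    )
                    truth.migration_events.append(
                        {"individual": mid, "source_stand": stands[src].stand_id,
                         "dest_stand": stands[s].stand_id, "generation": gen}
                    )
                    new_state[s][slot] = (mid, donor[1].copy(), xy)
                    haplotypes[mid] = new_state[s][slot][1]
        state = new_state

    # assemble final-generation genotype table
    meta_rows = []
    calls = []
    positions: dict[str, tuple[float, float]] = {}
    for s in range(config.n_stands):
        for pid, haps, xy in state[s]:
            meta_rows.append((pid, stands[s].stand_id, 0, pd.NA))
            calls.append(haps.sum(axis=0))
            positions[pid] = xy
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "stand_id", "year", "transect_index"])
    meta["transect_index"] = meta["transect_index"].astype("Int64")
    table = GenotypeTable(meta, np.array(calls, dtype=np.int8), marker_map)
    return SimulatedDataset(table, marker_map, stands, truth, haplotypes, positions, config)


def sample_survey(
    dataset: SimulatedDataset,
    per_stand_cap: int = 30,
    full_census_below: int = 20,
    seed: int | None = None,
) -> GenotypeTable:
    """Survey sampling: everything in small stands, 20-30 plants in large ones.

    Stands of at most ``full_census_below`` plants are sampled completely;
    larger stands contribute a uniform-random 20 to ``per_stand_cap``
    plants.  Transect order within a stand is the rank of the plant's local
    x coordinate, mimicking sampling along a line.
    """
    rng = np.random.default_rng(seed)
    table = dataset.table
    keep_rows: list[int] = []
    transect: dict[int, int] = {}
    for sid, rows in table.stand_groups().items():
        if rows.size > full_census_below:
            k = int(rng.integers(full_census_below, min(per_stand_cap, rows.size) + 1))
            rows = rng.choice(rows, size=k, replace=False)
        xs = np.array([dataset.positions[table.sample_ids[i]][0] for i in rows])
        for rank, i in enumerate(rows[np.argsort(xs, kind="stable")]):
            transect[int(i)] = rank
        keep_rows.extend(int(i) for i in rows)
    keep_rows.sort()
    sub = table.subset(keep_rows)
    sub.meta["transect_index"] = pd.array(
        [transect[i] for i in keep_rows], dtype="Int64"
    )
    return sub


# ---------------------------------------------------------------------------
# natural recombinant-inbred stands
# ---------------------------------------------------------------------------


def make_ril_stand(
    n_lines: int = 6,
    n_markers: int = 60,
    n_differentiating: int | None = None,
    n_meioses: int = 3,
    recomb_rate: float = 1.0,
    seed: int = 0,
) -> tuple[GenotypeTable, dict]:
    """Simulate a stand of natural recombinant inbred lines with known truth.

    Two fully homozygous founders cross once; each line descends from the F1
    by ``n_meioses`` rounds of gamete formation under selfing, and is fixed
    as a doubled haploid of the final gamete — a fully homozygous mosaic of
    the two founder genomes.  Returns the stand genotype table (founders
    included as the first two samples) and a truth dict with the founder
    genotypes, each line's founder-origin painting, and true crossover
    positions.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_stands=1, n_markers=n_markers, founders_per_stand=2, seed=seed)
    pool, marker_map = generate_founders(cfg, rng)
    hapA, hapB = pool[0].copy(), pool[1].copy()
    if n_differentiating is not None:
        # force an exact number of differentiating markers
        hapB = hapA.copy()
        flip = rng.choice(n_markers, size=n_differentiating, replace=False)
        hapB[flip] = 1 - hapB[flip]
    lens = list(cfg.chrom_lengths)

    lines = []
    truth_paint = []
    truth_xo = []
    for _ in range(n_lines):
        # track founder origin alongside alleles through the meioses
        haps = np.stack([hapA, hapB])
        origin = np.stack([np.zeros(n_markers, np.int8), np.ones(n_markers, np.int8)])
        xo_all: list[tuple[int, float]] = []
        idx = np.arange(n_markers)
        for g in range(n_meioses):
            gam1, xo1, ph1 = _meiosis(haps, marker_map, lens, recomb_rate, rng)
            og1 = origin[ph1, idx]
            xo_all.extend(xo1)
            if g < n_meioses - 1:
                # selfing: a full diploid offspring keeps residual heterozygosity
                gam2, xo2, ph2 = _meiosis(haps, marker_map, lens, recomb_rate, rng)
                haps = np.stack([gam1, gam2])
                origin = np.stack([og1, origin[ph2, idx]])
                xo_all.extend(xo2)
            else:
                # fix the line as a doubled haploid of the final gamete
                haps = np.stack([gam1, gam1])
                origin = np.stack([og1, og1])
        lines.append(haps[0] * 2)
        truth_paint.append(origin[0].copy())
        truth_xo.append(xo_all)

    calls = [hapA * 2, hapB * 2] + lines
    ids = ["founderA", "founderB"] + [f"ril{i + 1}" for i in range(n_lines)]
    meta = pd.DataFrame(
        {"sample_id": ids, "stand_id": "RIL", "year": 0,
         "transect_index": pd.array([pd.NA] * len(ids), dtype="Int64")}
    )
    table = GenotypeTable(meta, np.array(calls, dtype=np.int8), marker_map)
    truth = {
        "founders": {"founderA": hapA * 2, "founderB": hapB * 2},
        "paintings": {f"ril{i + 1}": truth_paint[i] for i in range(n_lines)},
        "crossovers": {f"ril{i + 1}": truth_xo[i] for i in range(n_lines)},
        "marker_map": marker_map,
    }
    return table, truth
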