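"""Forward-time individual-based simulator of an expanding city-block grid.

The generator emulates the demographic history the analyses assume for an
urban insect invasion: a rectangular grid of city blocks separated by
streets, colonized as a west-to-east wave (new columns of blocks activate
at a fixed cadence, each seeded by a handful of founders from the nearest
occupied column), with persistent but rare street-crossing dispersal,
occasional long-distance jumps (flight or human-mediated transport), and
stepwise microsatellite mutation.

Each generation runs, in order: migration, Wright-Fisher reproduction
within blocks, stepwise mutation of transmitted alleles, and colonization
of any newly activating column.  Sampling at the two configured
generations draws individuals (optionally stratified by transect thirds)
into a :class:`~urbanbarrier.genotype_io.MicrosatDataset` with true block
labels, positions uniform within the block footprint, and the sampling
generation recorded as the collection year.

All randomness flows from the single ``seed`` in the config; identical
configs produce byte-identical datasets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .genotype_io import Genotype, LocusDef, MicrosatDataset, SampleRecord

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "simulate",
    "default_study_config",
]


class SimulationError(Exception):
    """Impossible simulation state (extinction, oversampling, bad config)."""


@dataclass
class SimulationConfig:
    """All knobs of the block-grid simulator.

    Dispersal is per individual per generation: with probability
    ``p_street`` the individual crosses a street to an orthogonally
    adjacent block (picking one of the four directions uniformly; it stays
    put if that direction leaves the grid or hits a not-yet-built block),
    with probability ``p_jump`` it relocates to a uniformly chosen active
    block anywhere, otherwise it stays.  Columns of blocks activate
    west to east every ``founding_interval`` generations, each new block
    seeded by ``n_founders`` propagules copied from the nearest occupied
    column; ``founding_interval = 0`` builds the whole grid at once.

    ``init_mode`` controls the westernmost (or, when the whole grid starts
    active, every) starting block: ``"pool"`` fills it to carrying
    capacity with genotypes drawn from a diverse source pool of
    ``n_source_alleles`` equifrequent alleles per locus (an established
    city core); ``"distinct_blocks"`` fixes every starting block for its
    own private homozygous genotype (useful for isolation scenarios).

    The transect is an open system at its western edge: each generation,
    every individual in the westernmost column is replaced with
    probability ``source_rate`` by an immigrant drawn from the source
    pool, so the old city core sustains diversity while the eastward wave
    of serial founder events erodes it.  Set ``source_rate = 0`` for a
    fully closed grid.
    """

    n_cols: int = 12
    n_rows: int = 3
    block_side: float = 80.0
    street_width: float = 10.0
    n_per_block: int = 40
    n_loci: int = 13
    mutation_rate: float = 1e-3
    p_street: float = 0.002
    p_jump: float = 0.0005
    founding_interval: int = 8
    n_founders: int = 5
    n_generations: int = 104
    sample_years: tuple[int, int] = (98, 104)
    samples_per_year: int = 90
    thirds_sampling: bool = True
    seed: int = 0
    n_source_alleles: int = 6
    init_mode: str = "pool"
    source_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise SimulationError("grid must have at least 1 column and 1 row")
        if self.n_per_block < 1:
            raise SimulationError("n_per_block must be >= 1")
        if self.n_loci < 1:
            raise SimulationError("n_loci must be >= 1")
        if not (0.0 <= self.p_street + self.p_jump <= 1.0):
            raise SimulationError("p_street + p_jump must lie in [0, 1]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise SimulationError("mutation_rate must lie in [0, 1]")
        if self.n_founders < 1 or self.n_founders > self.n_per_block:
            raise SimulationError("need 1 <= n_founders <= n_per_block")
        if self.founding_interval < 0:
            raise SimulationError("founding_interval must be >= 0")
        self.sample_years = tuple(int(y) for y in self.sample_years)
        for y in self.sample_years:
            if not (0 <= y <= self.n_generations):
                raise SimulationError(
                    f"sample year {y} outside 0..{self.n_generations}"
                )
        if self.init_mode not in {"pool", "distinct_blocks"}:
            raise SimulationError(f"unknown init_mode {self.init_mode!r}")
        if not (0.0 <= self.source_rate <= 1.0):
            raise SimulationError("source_rate must lie in [0, 1]")

    def digest(self) -> str:
        """Stable hash of the config, recorded as dataset provenance."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: 13 loci, two collection years of 90
    samples each along a ~1 km west-to-east transect of 36 blocks."""
    return SimulationConfig(seed=seed)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

# microsatellite panel template: repeat units cycle over di-/tri-/tetra-
# nucleotide loci; offsets stagger fragment-size ranges below the GenePop
# 999 bp encoding limit.
_REPEAT_CYCLE = (2, 3, 4)
_BASE_UNIT = 10  # initial alleles sit 10..10+n_source_alleles-1 repeat units up


def _make_loci(n_loci: int) -> tuple[LocusDef, ...]:
    loci = []
    for l in range(n_loci):
        repeat = _REPEAT_CYCLE[l % len(_REPEAT_CYCLE)]
        loci.append(
            LocusDef(name=f"ms{l + 1:02d}", repeat_size=repeat, reference_offset=90 + 7 * l)
        )
    return tuple(loci)


class _State:
    """Mutable population state: genotype units, block assignment."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.geno = np.empty((0, cfg.n_loci, 2), dtype=np.int64)  # repeat units
        self.block = np.empty(0, dtype=np.int64)  # flat block index r*n_cols+c
        self.active_col = np.zeros(cfg.n_cols, dtype=bool)
        # flat-index neighbor table, -1 where off-grid
        nb = np.full((cfg.n_rows * cfg.n_cols, 4), -1, dtype=np.int64)
        for r in range(cfg.n_rows):
            for c in range(cfg.n_cols):
                b = r * cfg.n_cols + c
                if c > 0:
                    nb[b, 0] = b - 1
                if c < cfg.n_cols - 1:
                    nb[b, 1] = b + 1
                if r > 0:
                    nb[b, 2] = b - cfg.n_cols
                if r < cfg.n_rows - 1:
                    nb[b, 3] = b + cfg.n_cols
        self.neighbors = nb

    # -- helpers --------------------------------------------------------

    def block_col(self, b: np.ndarray) -> np.ndarray:
        return b % self.cfg.n_cols

    def active_blocks(self) -> np.ndarray:
        cols = np.arange(self.cfg.n_cols)[self.active_col]
        return np.concatenate(
            [r * self.cfg.n_cols + cols for r in range(self.cfg.n_rows)]
        )

    def source_pool_genotypes(self, n: int) -> np.ndarray:
        units = self.rng.integers(
            _BASE_UNIT,
            _BASE_UNIT + self.cfg.n_source_alleles,
            size=(n, self.cfg.n_loci, 2),
        )
        return units.astype(np.int64)

    def add(self, geno: np.ndarray, block: np.ndarray) -> None:
        self.geno = np.concatenate([self.geno, geno])
        self.block = np.concatenate([self.block, block])

    # -- per-generation steps -------------------------------------------

    def migrate(self) -> None:
        cfg, rng = self.cfg, self.rng
        n = len(self.block)
        if n == 0 or cfg.p_street + cfg.p_jump == 0:
            return
        u = rng.random(n)
        jump = u < cfg.p_jump
        street = (~jump) & (u < cfg.p_jump + cfg.p_street)
        if jump.any():
            targets = self.active_blocks()
            self.block[jump] = rng.choice(targets, size=int(jump.sum()))
        if street.any():
            movers = np.flatnonzero(street)
            dirs = rng.integers(0, 4, size=len(movers))
            dest = self.neighbors[self.block[movers], dirs]
            ok = dest >= 0
            ok[ok] &= self.active_col[self.block_col(dest[ok])]
            self.block[movers[ok]] = dest[ok]

    def reproduce(self) -> None:
        cfg, rng = self.cfg, self.rng
        if len(self.block) == 0:
            raise SimulationError("population extinct: no individuals in any block")
        new_geno, new_block = [], []
        order = np.argsort(self.block, kind="stable")
        sorted_blocks = self.block[order]
        bounds = np.searchsorted(sorted_blocks, np.arange(cfg.n_rows * cfg.n_cols + 1))
        for b in np.unique(sorted_blocks):
            idx = order[bounds[b] : bounds[b + 1]]
            m = len(idx)
            k = cfg.n_per_block
            mothers = idx[rng.integers(0, m, size=k)]
            fathers = idx[rng.integers(0, m, size=k)]
            pick_m = rng.integers(0, 2, size=(k, cfg.n_loci))
            pick_f = rng.integers(0, 2, size=(k, cfg.n_loci))
            child = np.empty((k, cfg.n_loci, 2), dtype=np.int64)
            cols = np.arange(cfg.n_loci)
            child[:, :, 0] = self.geno[mothers[:, None], cols[None, :], pick_m]
            child[:, :, 1] = self.geno[fathers[:, None], cols[None, :], pick_f]
            new_geno.append(child)
            new_block.append(np.full(k, b, dtype=np.int64))
        self.geno = np.concatenate(new_geno)
        self.block = np.concatenate(new_block)

    def mutate(self) -> None:
        cfg, rng = self.cfg, self.rng
        if cfg.mutation_rate == 0 or len(self.block) == 0:
            return
        hits = rng.random(self.geno.shape) < cfg.mutation_rate
        if hits.any():
            step = rng.integers(0, 2, size=self.geno.shape) * 2 - 1
            self.geno[hits] += step[hits]
            np.maximum(self.geno, 1, out=self.geno)  # floor at one repeat

    def core_immigration(self) -> None:
        """Replace a ``source_rate`` fraction of the westernmost column's
        residents with immigrants from the city-core source pool."""
        cfg, rng = self.cfg, self.rng
        if cfg.source_rate == 0 or len(self.block) == 0:
            return
        west = np.flatnonzero(self.block_col(self.block) == 0)
        if len(west) == 0:
            return
        repl = west[rng.random(len(west)) < cfg.source_rate]
        if len(repl):
            self.geno[repl] = self.source_pool_genotypes(len(repl))

    def activate_column(self, c: int, from_source: bool = False) -> None:
        """Build column ``c``.  Starting columns (``from_source``) fill to
        carrying capacity from the external source pool (or with private
        block genotypes under ``init_mode="distinct_blocks"``); later
        columns are seeded block by block with a founder propagule copied
        from one randomly chosen block of the nearest occupied column
        (sampling with replacement; the source is untouched) — the serial
        bottleneck of an expansion wave."""
        cfg, rng = self.cfg, self.rng
        self.active_col[c] = True
        if from_source:
            for r in range(cfg.n_rows):
                b = r * cfg.n_cols + c
                if cfg.init_mode == "distinct_blocks":
                    units = np.full(
                        (cfg.n_per_block, cfg.n_loci, 2), _BASE_UNIT + b, dtype=np.int64
                    )
                else:
                    units = self.source_pool_genotypes(cfg.n_per_block)
                self.add(units, np.full(cfg.n_per_block, b, dtype=np.int64))
            return
        occupied_cols = np.unique(self.block_col(self.block))
        if len(occupied_cols) == 0:
            raise SimulationError(f"column {c} activates but no source column is occupied")
        src_col = occupied_cols[np.argmin(np.abs(occupied_cols - c))]
        col_idx = np.flatnonzero(self.block_col(self.block) == src_col)
        for r in range(cfg.n_rows):
            b = r * cfg.n_cols + c
            # propagule from the spatially nearest source: the same-row block
            # of the source column, falling back to the whole column if that
            # block happens to be empty
            src_idx = col_idx[self.block[col_idx] == r * cfg.n_cols + src_col]
            if len(src_idx) == 0:
                src_idx = col_idx
            founders = rng.choice(src_idx, size=cfg.n_founders, replace=True)
            self.add(self.geno[founders].copy(), np.full(cfg.n_founders, b, dtype=np.int64))


def _activation_generation(cfg: SimulationConfig, c: int) -> int:
    return 0 if cfg.founding_interval == 0 else c * cfg.founding_interval


def _sample_population(
    state: _State, gen: int, cfg: SimulationConfig, rng: np.random.Generator,
    loci: tuple[LocusDef, ...],
) -> list[SampleRecord]:
    n_alive = len(state.block)
    if n_alive < cfg.samples_per_year:
        raise SimulationError(
            f"generation {gen}: cannot sample {cfg.samples_per_year} from "
            f"{n_alive} living individuals"
        )
    cols = state.block_col(state.block)
    if cfg.thirds_sampling:
        thirds = (3 * cols) // cfg.n_cols
        base, rem = divmod(cfg.samples_per_year, 3)
        quotas = [base + (1 if t < rem else 0) for t in range(3)]
        chosen: list[np.ndarray] = []
        for t, q in enumerate(quotas):
            pool = np.flatnonzero(thirds == t)
            if len(pool) < q:
                raise SimulationError(
                    f"generation {gen}: transect third {t} holds {len(pool)} "
                    f"individuals, cannot sample {q}"
                )
            chosen.append(rng.choice(pool, size=q, replace=False))
        idx = np.concatenate(chosen)
    else:
        idx = rng.choice(n_alive, size=cfg.samples_per_year, replace=False)
    pitch = cfg.block_side + cfg.street_width
    records = []
    for i, ind in enumerate(idx):
        b = int(state.block[ind])
        r, c = divmod(b, cfg.n_cols)
        x = c * pitch + rng.uniform(0, cfg.block_side)
        y = r * pitch + rng.uniform(0, cfg.block_side)
        geno: list[Genotype] = []
        for l, locus in enumerate(loci):
            a = locus.reference_offset + int(state.geno[ind, l, 0]) * locus.repeat_size
            bb = locus.reference_offset + int(state.geno[ind, l, 1]) * locus.repeat_size
            geno.append((min(a, bb), max(a, bb)))
        records.append(
            SampleRecord(
                sample_id=f"y{gen}s{i:03d}",
                x=float(x),
                y=float(y),
                block_id=f"c{c:02d}r{r}",
                year=gen,
                genotype=tuple(geno),
            )
        )
    return records


def simulate(cfg: SimulationConfig) -> MicrosatDataset:
    """Run the forward simulation and return the sampled dataset.

    Raises :class:`SimulationError` on total extinction or when a sampling
    event asks for more individuals than are alive.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = _make_loci(cfg.n_loci)
    state = _State(cfg, rng)
    samples: list[SampleRecord] = []

    # generation 0: build every column whose activation time is 0
    for c in range(cfg.n_cols):
        if _activation_generation(cfg, c) == 0:
            state.activate_column(c, from_source=True)
    if 0 in cfg.sample_years:
        samples.extend(_sample_population(state, 0, cfg, rng, loci))

    for gen in range(1, cfg.n_generations + 1):
        state.migrate()
        state.reproduce()
        state.mutate()
        state.core_immigration()
        for c in range(cfg.n_cols):
            if not state.active_col[c] and _activation_generation(cfg, c) == gen:
                state.activate_column(c)
        if len(state.block) == 0:
            raise SimulationError(f"generation {gen}: population extinct")
        for y in cfg.sample_years:
            if y == gen:
                samples.extend(_sample_population(state, gen, cfg, rng, loci))

    if not samples:
        raise SimulationError("no sampling generation was reached")
    return MicrosatDataset(
        loci=loci,
        samples=tuple(samples),
        provenance=f"synthetic_city:{cfg.digest()}",
    )
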