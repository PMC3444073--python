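"""Genetic-algorithm band selection.

A chromosome is a fixed-size set of distinct valid band indices (kept
sorted); its fitness is the overall validation accuracy of the
spectral-angle-mapper classifier restricted to those bands. Evolution uses
fitness-proportional (roulette-wheel) parent selection, single-point
crossover on the sorted representation with duplicate repair,
per-chromosome single-gene mutation, and elitism, so the best fitness per
generation is non-decreasing. Also provides the chromosome-size sweep, the
repeated-run consistency protocol with per-run data reshuffling, and
gap-based grouping of pooled winner genes into waveband regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .sam import BatchSAM, evaluate
from .spectra import SpectralGrid, SpectralLibrary, SplitLibrary, split_per_species

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chromosome:
    """A candidate solution: k distinct valid band indices, sorted ascending."""

    genes: tuple[int, ...]

    def __post_init__(self) -> None:
        genes = tuple(int(g) for g in self.genes)
        if len(genes) == 0:
            raise ValueError("chromosome must hold at least one gene")
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes: {genes}")
        if any(b > a for a, b in zip(genes[1:], genes)):
            genes = tuple(sorted(genes))
        object.__setattr__(self, "genes", genes)

    @property
    def k(self) -> int:
        return len(self.genes)

    def wavelengths(self, grid: SpectralGrid) -> np.ndarray:
        return grid.wavelengths_um[list(self.genes)]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of one evolution run.

    Defaults follow the full-scale protocol (population 1,000, up to 500
    generations, crossover probability 1, per-chromosome mutation
    probability 0.01, elite count 2, 85% fitness threshold); scaled runs
    override ``population_size`` and ``max_generations``. The run stops at
    ``max_generations`` or once the best fitness has failed to improve by
    more than ``plateau_epsilon`` for ``plateau_generations`` consecutive
    generations.
    """

    k: int
    population_size: int = 1000
    max_generations: int = 500
    crossover_probability: float = 1.0
    mutation_probability: float = 0.01
    elite_count: int = 2
    fitness_threshold: float = 85.0
    plateau_generations: int = 50
    plateau_epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("chromosome size k must be >= 1")
        for name in ("crossover_probability", "mutation_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must satisfy 0 <= elite < population_size")


@dataclass(frozen=True)
class GARunResult:
    """Outcome of one evolution run."""

    winner: Chromosome
    winner_fitness: float
    best_fitness_by_generation: np.ndarray
    generations_run: int
    gene_frequency_by_generation: np.ndarray  # (generations, n_bands) counts
    seed: int


@dataclass(frozen=True)
class BandGroup:
    """Cluster of pooled winner genes in wavelength."""

    n_genes: int
    wl_min_um: float
    wl_max_um: float
    mean_um: float
    sd_um: float
    region: str


@dataclass(frozen=True)
class SweepResult:
    """Winner fitness per chromosome size and the minimal size meeting the
    fitness threshold (``None`` if none did)."""

    k_values: tuple[int, ...]
    winner_fitness_by_k: tuple[float, ...]
    minimal_k: int | None
    runs: tuple[GARunResult, ...]


@dataclass(frozen=True)
class RepeatResult:
    """Outcome of the repeated-run consistency protocol."""

    runs: tuple[GARunResult, ...]
    split_seeds: tuple[int, ...]
    pooled_gene_counts: np.ndarray  # per-band winner-gene counts
    pooled_wavelengths: np.ndarray  # one entry per pooled winner gene

    @property
    def winner_fitnesses(self) -> np.ndarray:
        return np.array([r.winner_fitness for r in self.runs])


def init_population(
    cfg: GAConfig, grid: SpectralGrid, rng: np.random.Generator | None = None
) -> list[Chromosome]:
    """Seeded random initial population: k distinct valid bands each."""
    valid = grid.valid_indices
    if cfg.k > valid.size:
        raise ValueError(f"k={cfg.k} exceeds the {valid.size} valid bands")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return [
        Chromosome(tuple(rng.choice(valid, size=cfg.k, replace=False)))
        for _ in range(cfg.population_size)
    ]


def fitness(ch: Chromosome, split: SplitLibrary) -> float:
    """Overall SAM validation accuracy (%) of the chromosome's bands."""
    _, acc = evaluate(split, ch.genes)
    return acc


def roulette_select(
    population: Sequence[Chromosome],
    fitnesses: Sequence[float],
    n_parents: int,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Fitness-proportional sampling with replacement.

    If every fitness is zero the selection falls back to uniform (logged):
    a fitness-proportional wheel is undefined at total weight zero.
    """
    fits = np.asarray(fitnesses, dtype=float)
    if np.any(fits < 0):
        raise ValueError("fitness values must be non-negative")
    total = fits.sum()
    if total == 0.0:
        logger.warning("all-zero fitness: roulette falls back to uniform selection")
        idx = rng.integers(0, len(population), size=n_parents)
    else:
        idx = rng.choice(len(population), size=n_parents, p=fits / total)
    return [population[int(i)] for i in idx]


def _repair_duplicates(
    genes: list[int], valid: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Replace duplicated bands with fresh uniformly drawn valid bands."""
    unique = list(dict.fromkeys(genes))
    if len(unique) < k:
        pool = np.setdiff1d(valid, np.asarray(unique, dtype=int), assume_unique=False)
        extra = rng.choice(pool, size=k - len(unique), replace=False)
        logger.debug("crossover repair drew %d replacement bands", k - len(unique))
        unique.extend(int(e) for e in extra)
    return tuple(sorted(unique))


def single_point_crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    valid_indices: np.ndarray,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover on the sorted representation.

    A cut position c is drawn uniformly from {1, ..., k-1}; each parent
    splits into two segments and the tail segments are exchanged, producing
    two offspring. Any band duplicated by the splice is repaired by a fresh
    uniformly drawn valid band not already in the child. With k = 1
    crossover degenerates to a copy.
    """
    if parent_a.k != parent_b.k:
        raise ValueError("parents must have equal chromosome size")
    k = parent_a.k
    if k == 1:
        return parent_a, parent_b
    c = int(rng.integers(1, k))
    a, b = parent_a.genes, parent_b.genes
    child_a = _repair_duplicates(list(a[:c] + b[c:]), valid_indices, k, rng)
    child_b = _repair_duplicates(list(b[:c] + a[c:]), valid_indices, k, rng)
    return Chromosome(child_a), Chromosome(child_b)


def mutate(
    ch: Chromosome, pm: float, grid: SpectralGrid, rng: np.random.Generator
) -> Chromosome:
    """With probability pm, replace one uniformly chosen gene by a
    uniformly chosen valid band not already in the chromosome."""
    if rng.random() >= pm:
        return ch
    valid = grid.valid_indices
    pool = np.setdiff1d(valid, np.asarray(ch.genes, dtype=int))
    if pool.size == 0:
        return ch
    pos = int(rng.integers(0, ch.k))
    genes = list(ch.genes)
    genes[pos] = int(rng.choice(pool))
    return Chromosome(tuple(sorted(genes)))


def evolve(
    split: SplitLibrary,
    cfg: GAConfig,
    evaluator: BatchSAM | None = None,
) -> GARunResult:
    """Run one evolution and return the winner with its trajectory.

    Per generation: score every chromosome, log the best, copy the
    ``elite_count`` fittest unchanged into the next generation, fill the
    rest with offspring of roulette-selected parents (crossover with
    probability pc, then mutation). Offspring are generated in pairs; an
    odd remainder drops one child. Elitism makes the best-fitness series
    non-decreasing. Fully reproducible from ``cfg.seed``.
    """
    grid = split.train.grid
    if evaluator is None:
        evaluator = BatchSAM(split)
    rng = np.random.default_rng(cfg.seed)
    valid = grid.valid_indices
    pop = init_population(cfg, grid, rng)

    best_series: list[float] = []
    gene_freq: list[np.ndarray] = []
    best_ch: Chromosome | None = None
    best_fit = -np.inf
    stall = 0

    for gen in range(cfg.max_generations):
        fits = np.array([evaluator.accuracy(ch.genes) for ch in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit + cfg.plateau_epsilon:
            best_fit = float(fits[gen_best])
            best_ch = pop[gen_best]
            stall = 0
        else:
            stall += 1
            if fits[gen_best] > best_fit:  # epsilon-small improvement
                best_fit = float(fits[gen_best])
                best_ch = pop[gen_best]
        best_series.append(best_fit)
        freq = np.zeros(grid.n_bands, dtype=int)
        for ch in pop:
            freq[list(ch.genes)] += 1
        gene_freq.append(freq)
        logger.debug("generation %d: best fitness %.2f%%", gen, best_fit)
        if stall >= cfg.plateau_generations:
            break
        if gen == cfg.max_generations - 1:
            break

        order = np.argsort(-fits, kind="stable")
        elites = [pop[int(i)] for i in order[: cfg.elite_count]]
        n_offspring = cfg.population_size - cfg.elite_count
        n_parents = n_offspring + (n_offspring % 2)
        parents = roulette_select(pop, fits, n_parents, rng)
        offspring: list[Chromosome] = []
        for i in range(0, n_parents, 2):
            pa, pb = parents[i], parents[i + 1]
            if rng.random() < cfg.crossover_probability:
                ca, cb = single_point_crossover(pa, pb, valid, rng)
            else:
                ca, cb = pa, pb
            offspring.append(mutate(ca, cfg.mutation_probability, grid, rng))
            offspring.append(mutate(cb, cfg.mutation_probability, grid, rng))
        pop = elites + offspring[:n_offspring]

    assert best_ch is not None
    return GARunResult(
        winner=best_ch,
        winner_fitness=best_fit,
        best_fitness_by_generation=np.asarray(best_series),
        generations_run=len(best_series),
        gene_frequency_by_generation=np.vstack(gene_freq),
        seed=cfg.seed,
    )


def sweep_chromosome_size(
    split: SplitLibrary, cfg: GAConfig, k_values: Sequence[int]
) -> SweepResult:
    """Winner fitness as a function of chromosome size.

    Runs one evolution per k and reports the smallest k whose winner
    fitness reaches ``cfg.fitness_threshold`` (or ``None``).
    """
    k_values = tuple(int(k) for k in k_values)
    if not k_values:
        raise ValueError("k_values must be non-empty")
    if list(k_values) != sorted(k_values):
        raise ValueError("k_values must be ascending")
    evaluator = BatchSAM(split)
    runs = []
    for k in k_values:
        runs.append(evolve(split, replace(cfg, k=k), evaluator=evaluator))
    fitnesses = tuple(r.winner_fitness for r in runs)
    minimal_k = next(
        (k for k, f in zip(k_values, fitnesses) if f >= cfg.fitness_threshold), None
    )
    return SweepResult(
        k_values=k_values,
        winner_fitness_by_k=fitnesses,
        minimal_k=minimal_k,
        runs=tuple(runs),
    )


def repeat_runs(
    lib: SpectralLibrary,
    cfg: GAConfig,
    n_runs: int,
    n_train: int,
) -> RepeatResult:
    """Repeated-run consistency protocol.

    Each run reshuffles the per-species train/validation split with a
    fresh seed and evolves from a fresh GA seed; winner genes are pooled
    into a per-band histogram (and as raw wavelengths) for region grouping.
    Both seeds derive deterministically from ``cfg.seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    states = np.random.SeedSequence(cfg.seed).generate_state(2 * n_runs)
    derived = (states % np.uint32(2**31)).astype(np.int64)
    runs = []
    split_seeds = []
    grid = lib.grid
    pooled = np.zeros(grid.n_bands, dtype=int)
    wavelengths: list[float] = []
    for r in range(n_runs):
        split_seed = int(derived[2 * r])
        ga_seed = int(derived[2 * r + 1])
        split = split_per_species(lib, n_train, split_seed)
        result = evolve(split, replace(cfg, seed=ga_seed))
        runs.append(result)
        split_seeds.append(split_seed)
        pooled[list(result.winner.genes)] += 1
        wavelengths.extend(float(w) for w in result.winner.wavelengths(grid))
        logger.info(
            "run %d/%d: winner fitness %.2f%% after %d generations",
            r + 1, n_runs, result.winner_fitness, result.generations_run,
        )
    return RepeatResult(
        runs=tuple(runs),
        split_seeds=tuple(split_seeds),
        pooled_gene_counts=pooled,
        pooled_wavelengths=np.sort(np.asarray(wavelengths)),
    )


def band_region(mean_um: float) -> str:
    """Spectral-region label: mid infrared below 6 um, thermal infrared
    from 8 um; the masked 6-8 um window maps to 'excluded'."""
    if mean_um < 6.0:
        return "mid infrared"
    if mean_um >= 8.0:
        return "thermal infrared"
    return "excluded"


def group_bands(
    pooled_wavelengths_um: Sequence[float], gap_um: float = 0.15
) -> list[BandGroup]:
    """Single-linkage 1-D clustering of pooled winner-gene wavelengths.

    Genes are sorted and a new group starts whenever the gap to the
    previous gene exceeds ``gap_um``; each group reports count, wavelength
    range, mean and standard deviation (population sd, so a singleton has
    sd 0). Groups are ordered by wavelength.
    """
    wl = np.sort(np.asarray(pooled_wavelengths_um, dtype=float))
    if wl.size == 0:
        raise ValueError("no pooled genes to group")
    breaks = np.flatnonzero(np.diff(wl) > gap_um) + 1
    groups = []
    for chunk in np.split(wl, breaks):
        mean = float(chunk.mean())
        groups.append(
            BandGroup(
                n_genes=int(chunk.size),
                wl_min_um=float(chunk.min()),
                wl_max_um=float(chunk.max()),
                mean_um=mean,
                sd_um=float(chunk.std(ddof=0)),
                region=band_region(mean),
            )
        )
    return groups
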