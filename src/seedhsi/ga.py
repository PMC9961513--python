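"""Genetic-algorithm effective-waveband selection with PLS RMSECV fitness.

Individuals are binary masks over band windows.  Fitness is the root mean
squared cross-validation error of a PLS regression of the class-indicator
matrix restricted to the active bands, minimised over the LV count.  Default
parameters: population 64, 100 generations, double (two-point) crossover,
per-gene mutation rate 0.005, termination when 50% of the population share an
identical gene vector, one replicate run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .models import CVPlan, _PLSCore, class_indicators

__all__ = [
    "GAConfig",
    "GAResult",
    "fitness_rmsecv",
    "two_point_crossover",
    "ga_run",
]

WORST_FITNESS = 1e30


@dataclass(frozen=True)
class GAConfig:
    population: int = 64
    max_generations: int = 100
    mutation_rate: float = 0.005
    convergence_percent: float = 50.0
    n_iterations: int = 1
    window_width: int = 1
    init_density: float = 0.3
    max_lv: int = 10
    elitism: bool = True
    rng_seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.mutation_rate < 1.0:
            raise InputError("mutation_rate must be in (0, 1)")
        if self.population < 2 or self.population % 2:
            raise InputError("population must be an even integer >= 2")
        if self.window_width < 1:
            raise InputError("window_width must be >= 1")
        if not 0.0 < self.convergence_percent <= 100.0:
            raise InputError("convergence_percent must be in (0, 100]")


@dataclass
class GAResult:
    best_mask: np.ndarray  # selected band indices
    n_selected: int
    best_fitness: float
    fitness_trace: list[dict]  # per generation: best / mean RMSECV
    selection_frequency: np.ndarray  # per-band inclusion rate, final population
    n_generations: int
    converged: bool
    config: GAConfig = field(repr=False, default=None)


def fitness_rmsecv(mask, X_cal, y_cal, cv: CVPlan, max_lv: int = 10) -> float:
    """RMSECV of the indicator-matrix PLS restricted to the masked bands.

    For every fold the model is refit on the training part at up to ``max_lv``
    components; RMSECV is evaluated at each LV count and the minimum is the
    fitness (lower is better).  A mask whose matrix supports no PLS component
    scores ``WORST_FITNESS`` instead of raising.
    """
    mask = np.asarray(mask)
    cols = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask, int).ravel()
    if cols.size == 0:
        raise InputError("mask selects no bands")
    X = np.asarray(X_cal, float)[:, cols]
    Y, _ = class_indicators(y_cal)
    n, q = Y.shape
    max_lv = int(min(max_lv, cols.size, n - n // cv.n_splits - 1))
    if max_lv < 1:
        return WORST_FITNESS
    press = None
    counted = 0
    for train, val in cv.folds():
        try:
            core = _PLSCore(X[train], Y[train], max_lv)
        except InputError:
            return WORST_FITNESS
        a_max = core.n_components
        if press is None:
            press = np.zeros(a_max)
        elif a_max < press.size:
            press = press[:a_max]
        Xv_c = X[val] - core.x_mean
        scores = Xv_c @ core.W @ np.linalg.inv(core.P.T @ core.W)
        resid = Y[val] - core.y_mean
        for a in range(press.size):
            resid = resid - np.outer(scores[:, a], core.Q[:, a])
            press[a] += float(np.sum(resid**2))
        counted += val.size
    if press is None or counted == 0:
        return WORST_FITNESS
    rmsecv = np.sqrt(press / (counted * q))
    return float(rmsecv.min())


def _repair(child: np.ndarray, parent_union: np.ndarray, rng: np.random.Generator):
    if not child.any():
        candidates = np.flatnonzero(parent_union)
        if candidates.size == 0:
            candidates = np.arange(child.size)
        child[rng.choice(candidates)] = True
    return child


def two_point_crossover(
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    cuts: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Double crossover: swap the segment between two uniform cut points.

    ``cuts`` may pin the cut points (useful for exhaustive testing); children
    with no active gene are repaired by switching on one locus active in
    either parent.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise InputError("parents must share gene length")
    L = a.size
    if cuts is None:
        i, j = sorted(int(c) for c in rng.integers(0, L + 1, size=2))
    else:
        i, j = sorted(int(c) for c in cuts)
    c1, c2 = a.copy(), b.copy()
    c1[i:j], c2[i:j] = b[i:j].copy(), a[i:j].copy()
    union = a | b
    return _repair(c1, union, rng), _repair(c2, union, rng)


def _genes_to_band_mask(genes: np.ndarray, n_bands: int, window_width: int) -> np.ndarray:
    if window_width == 1:
        return genes[:n_bands]
    mask = np.repeat(genes, window_width)[:n_bands]
    return mask


def _modal_share(population: list[np.ndarray]) -> float:
    counts: dict[bytes, int] = {}
    for genes in population:
        key = genes.tobytes()
        counts[key] = counts.get(key, 0) + 1
    return max(counts.values()) / len(population)


def _ga_single_run(X, y, config: GAConfig, cv: CVPlan, rng: np.random.Generator):
    n_bands = X.shape[1]
    n_genes = -(-n_bands // config.window_width)
    cache: dict[bytes, float] = {}

    def evaluate(genes: np.ndarray) -> float:
        key = genes.tobytes()
        if key not in cache:
            mask = _genes_to_band_mask(genes, n_bands, config.window_width)
            if not mask.any():
                cache[key] = WORST_FITNESS
            else:
                cache[key] = fitness_rmsecv(mask, X, y, cv, config.max_lv)
        return cache[key]

    population = []
    for _ in range(config.population):
        genes = rng.random(n_genes) < config.init_density
        if not genes.any():
            genes[rng.integers(n_genes)] = True
        population.append(genes)

    trace: list[dict] = []
    converged = False
    generation = 0
    fitness = np.array([evaluate(g) for g in population])
    for generation in range(1, config.max_generations + 1):
        order = np.argsort(fitness, kind="stable")
        population = [population[i] for i in order]
        fitness = fitness[order]
        trace.append(
            {
                "generation": generation,
                "best": float(fitness[0]),
                "mean": float(np.mean(fitness)),
            }
        )
        if _modal_share(population) * 100.0 >= config.convergence_percent:
            converged = True
            break
        if generation == config.max_generations:
            break
        # rank selection: top half breeds
        half = config.population // 2
        parents = population[:half]
        pairing = rng.permutation(half)
        children: list[np.ndarray] = []
        for k in range(0, half - 1, 2):
            c1, c2 = two_point_crossover(
                parents[pairing[k]], parents[pairing[k + 1]], rng
            )
            children.extend([c1, c2])
        while len(children) < config.population - half:
            children.append(parents[int(rng.integers(half))].copy())
        next_pop = [g.copy() for g in parents] + children[: config.population - half]
        start = 1 if config.elitism else 0  # elite individual mutates never
        for idx in range(start, len(next_pop)):
            flips = rng.random(n_genes) < config.mutation_rate
            if flips.any():
                genes = next_pop[idx].copy()
                genes[flips] = ~genes[flips]
                next_pop[idx] = _repair(genes, genes | True, rng)
        population = next_pop
        fitness = np.array([evaluate(g) for g in population])

    order = np.argsort(fitness, kind="stable")
    population = [population[i] for i in order]
    fitness = fitness[order]
    best_genes = population[0]
    band_mask = _genes_to_band_mask(best_genes, n_bands, config.window_width)
    freq = np.mean(
        [_genes_to_band_mask(g, n_bands, config.window_width) for g in population],
        axis=0,
    )
    return GAResult(
        best_mask=np.flatnonzero(band_mask),
        n_selected=int(band_mask.sum()),
        best_fitness=float(fitness[0]),
        fitness_trace=trace,
        selection_frequency=freq,
        n_generations=generation,
        converged=converged,
        config=config,
    )


def ga_run(X_cal, y_cal, config: GAConfig, cv: CVPlan | None = None) -> GAResult:
    """Run the GA (``config.n_iterations`` replicates; best result returned)."""
    if config.rng_seed is None:
        raise InputError("GAConfig.rng_seed must be set for a reproducible run")
    X = np.asarray(X_cal, float)
    y = np.asarray(y_cal)
    if cv is None:
        from .models import venetian_blinds

        cv = venetian_blinds(X.shape[0])
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_iterations)
    best: GAResult | None = None
    for ss in seeds:
        result = _ga_single_run(X, y, config, cv, np.random.default_rng(ss))
        if best is None or result.best_fitness < best.best_fitness:
            best = result
    return best
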