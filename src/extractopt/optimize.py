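"""Genetic-algorithm search for extraction conditions maximizing the responses.

The optimizer works on the coded factor box [-1, 1]^k with a real-coded GA:
tournament selection, blend (BLX-alpha) crossover, Gaussian mutation and
elitism.  Candidate settings are decoded to actual units for every surrogate
evaluation, so under ordinal coding a frequency candidate snaps to the
nearest physically available level.  Multiple responses are combined into a
single fitness by a weighted min-max-normalized sum, each response rescaled
by its observed range so that no assay dominates through its units.

A brute-force lattice search over the same box serves as an independent
verification oracle for the GA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignTable, FactorSpec, decode_value

__all__ = [
    "GaConfig",
    "OptimizationResult",
    "scalarize",
    "make_scalar_objective",
    "ga_optimize",
    "grid_search_oracle",
]


@dataclass(frozen=True)
class GaConfig:
    """Settings of the real-coded genetic algorithm."""

    factors: tuple[FactorSpec, ...]
    weights: tuple[float, ...]
    norm_min: tuple[float, ...]  # observed response minima (normalization)
    norm_max: tuple[float, ...]
    scheme: str = "affine"
    population: int = 50
    generations: int = 100
    crossover_fraction: float = 0.8
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.2  # in coded units
    elitism: int = 2
    tournament_k: int = 3
    blend_alpha: float = 0.5
    seed: int = 0
    seed_points: tuple[tuple[float, ...], ...] = ()  # coded candidates to inject

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
        if any(hi <= lo for lo, hi in zip(self.norm_min, self.norm_max)):
            raise ValueError("degenerate normalization range")


@dataclass
class OptimizationResult:
    """Best settings found, their predicted responses and the GA trace."""

    best_actual: dict[str, float]
    best_coded: np.ndarray
    predicted: dict[str, float]
    fitness: float
    trace: pd.DataFrame  # best-ever fitness per generation
    config: GaConfig = field(repr=False)


def scalarize(
    predicted: np.ndarray,
    weights,
    norm_min,
    norm_max,
) -> np.ndarray:
    """Weighted mean of min-max-normalized responses.

    ``predicted`` is (n_points, n_responses); the result lies in [0, 1]
    whenever every prediction stays inside its observed range.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")
    lo = np.asarray(norm_min, dtype=float)
    hi = np.asarray(norm_max, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("degenerate normalization range")
    P = np.atleast_2d(np.asarray(predicted, dtype=float))
    normed = (P - lo) / (hi - lo)
    return (normed @ w) / w.sum()


def make_scalar_objective(predict_fn, config: GaConfig):
    """Wrap a (points -> responses) surrogate into a coded-space fitness.

    ``predict_fn`` takes a DataFrame of actual-unit factor settings and
    returns an (n, n_responses) array/frame.  The returned callable maps an
    (n, k) array of coded candidates to an (n,) fitness vector.
    """
    names = [f.name for f in config.factors]

    def fitness(coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(coded)
        actual = pd.DataFrame(
            {
                f.name: decode_value(f, coded[:, i], config.scheme)
                for i, f in enumerate(config.factors)
            }
        )[names]
        pred = np.asarray(predict_fn(actual), dtype=float)
        return scalarize(pred, config.weights, config.norm_min, config.norm_max)

    return fitness


def ga_optimize(predict_fn, config: GaConfig) -> OptimizationResult:
    """Maximize the scalarized surrogate prediction over the factor box.

    Deterministic for a fixed config (including its seed).  Individuals whose
    fitness evaluates non-finite are discarded with a warning (replaced by
    the worst finite fitness so selection never favors them).
    """
    k = len(config.factors)
    rng = np.random.default_rng(config.seed)
    fitness_fn = make_scalar_objective(predict_fn, config)

    pop = rng.uniform(-1.0, 1.0, size=(config.population, k))
    for i, pt in enumerate(config.seed_points[: config.population]):
        pop[i] = np.clip(np.asarray(pt, dtype=float), -1.0, 1.0)

    def evaluate(P: np.ndarray) -> np.ndarray:
        fit = fitness_fn(P)
        bad = ~np.isfinite(fit)
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} individual(s) produced non-finite fitness; discarded",
                stacklevel=2,
            )
            floor = fit[~bad].min() if np.any(~bad) else 0.0
            fit = np.where(bad, floor - 1.0, fit)
        return fit

    fit = evaluate(pop)
    best_i = int(np.argmax(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    trace = [best_f]

    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: config.elitism]].copy()

        # tournament selection of parents
        n_off = config.population - config.elitism
        idx = rng.integers(0, config.population, size=(n_off, config.tournament_k))
        winners = idx[np.arange(n_off), np.argmax(fit[idx], axis=1)]
        parents = pop[winners]

        # blend crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, n_off - 1, 2):
            if rng.random() < config.crossover_fraction:
                a, b = parents[i], parents[i + 1]
                lo = np.minimum(a, b) - config.blend_alpha * np.abs(a - b)
                hi = np.maximum(a, b) + config.blend_alpha * np.abs(a - b)
                children[i] = rng.uniform(lo, hi)
                children[i + 1] = rng.uniform(lo, hi)

        # Gaussian mutation
        mask = rng.random(children.shape) < config.mutation_rate
        children = children + mask * rng.normal(0.0, config.mutation_sigma, children.shape)
        children = np.clip(children, -1.0, 1.0)

        pop = np.vstack([elite, children])
        fit = evaluate(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_f = float(fit[gen_best])
            best_x = pop[gen_best].copy()
        trace.append(best_f)

    best_actual = {
        f.name: float(decode_value(f, best_x[i], config.scheme))
        for i, f in enumerate(config.factors)
    }
    pred = np.asarray(
        predict_fn(pd.DataFrame({k_: [v] for k_, v in best_actual.items()})),
        dtype=float,
    ).ravel()
    # report the fitness of the decoded (physically realizable) settings
    best_f = float(scalarize(pred, config.weights, config.norm_min, config.norm_max)[0])
    return OptimizationResult(
        best_actual=best_actual,
        best_coded=best_x,
        predicted={f"Y{i+1}": float(v) for i, v in enumerate(pred)},
        fitness=best_f,
        trace=pd.DataFrame(
            {"generation": np.arange(len(trace)), "best_fitness": trace}
        ).set_index("generation"),
        config=config,
    )


def grid_search_oracle(
    predict_fn,
    config: GaConfig,
    resolution: int = 21,
    max_points: int = 2_000_000,
) -> tuple[dict[str, float], float]:
    """Exhaustive lattice search over the coded box; exact lattice arg-max."""
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    k = len(config.factors)
    if resolution**k > max_points:
        raise ValueError(
            f"lattice of {resolution}^{k} points exceeds the cap of {max_points}"
        )
    axes = [np.linspace(-1.0, 1.0, resolution)] * k
    mesh = np.meshgrid(*axes, indexing="ij")
    coded = np.column_stack([m.ravel() for m in mesh])
    fitness_fn = make_scalar_objective(predict_fn, config)
    fit = fitness_fn(coded)
    best = int(np.nanargmax(fit))
    best_actual = {
        f.name: float(decode_value(f, coded[best, i], config.scheme))
        for i, f in enumerate(config.factors)
    }
    return best_actual, float(fit[best])
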