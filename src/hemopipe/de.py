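"""Greedy differential evolution for the enhancement parameters.

The four decision variables (alpha, beta, gamma, delta) are tuned per
image by a best/2 differential evolution: mutants are built around the
current population best, crossed binomially with their targets, clamped
to the box constraints, and kept only if they do not decrease the
objective (ties go to the trial).  Greedy one-to-one survivor selection
makes the best objective monotone over iterations.

All randomness flows from a single :class:`numpy.random.Generator` seeded
once.  Draw order: population init row-major; then per iteration, per
individual: mutation indices, the scaling factor A, four crossover
uniforms, one forced dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import hsi_to_rgb, rgb_to_hsi
from .enhancement import (
    EnhancementConfig,
    EnhancementParams,
    LocalStats,
    ObjectiveBreakdown,
    apply_enhancement,
    enhancement_objective,
    local_window_stats,
)

__all__ = [
    "DEState",
    "de_init_population",
    "de_mutate",
    "de_crossover",
    "de_select",
    "optimize_enhancement",
    "enhance_rgb",
]

_NDIM = 4  # (alpha, beta, gamma, delta)


@dataclass
class DEState:
    """Population, fitnesses and the incumbent best of a DE run."""

    population: np.ndarray  # (N_p, 4)
    fitnesses: np.ndarray  # (N_p,)
    best: EnhancementParams
    best_fitness: float
    iteration: int = 0
    history: list[float] = field(default_factory=list)

    @property
    def pop_size(self) -> int:
        return self.population.shape[0]


def de_init_population(
    n_pop: int,
    lb: np.ndarray,
    ub: np.ndarray,
    objective,
    rng: np.random.Generator,
) -> DEState:
    """Draw N_p uniform vectors in the box and evaluate them.

    ``objective`` maps a length-4 vector to a scalar to maximize.  The
    best-of-population becomes the incumbent.  N_p >= 5 because mutation
    needs four donor indices distinct from the target.
    """
    if n_pop < 5:
        raise ValueError("population size must be at least 5 (mutation needs 5 distinct indices)")
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    pop = lb + rng.random((n_pop, _NDIM)) * (ub - lb)
    fit = np.array([objective(row) for row in pop])
    b = int(np.argmax(fit))
    state = DEState(
        population=pop,
        fitnesses=fit,
        best=EnhancementParams.from_vector(pop[b]),
        best_fitness=float(fit[b]),
    )
    state.history.append(state.best_fitness)
    return state


def de_mutate(state: DEState, i: int, rng: np.random.Generator) -> np.ndarray:
    """Best/2 mutant: P_b + A*(P_r1 - P_r2) + A*(P_r3 - P_r4).

    The four donor indices are distinct from each other and from ``i``;
    the scaling factor A is a fresh uniform draw in [0, 1] per call.
    """
    n = state.pop_size
    if n < 5:
        raise ValueError("mutation needs a population of at least 5")
    candidates = np.delete(np.arange(n), i)
    r1, r2, r3, r4 = rng.choice(candidates, size=4, replace=False)
    a = rng.random()
    p = state.population
    return (
        state.best.to_vector()
        + a * (p[r1] - p[r2])
        + a * (p[r3] - p[r4])
    )


def de_crossover(
    target: np.ndarray,
    mutant: np.ndarray,
    cr: float,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial crossover with one forced dimension, clamped to the box."""
    draws = rng.random(_NDIM)
    forced = rng.integers(_NDIM)
    take_mutant = draws <= cr
    take_mutant[forced] = True
    trial = np.where(take_mutant, mutant, target)
    return np.clip(trial, lb, ub)


def de_select(target_fit: float, trial_fit: float) -> bool:
    """Greedy survivor rule: keep the target only if the trial is strictly worse.

    Returns True when the trial replaces the target (ties included).
    """
    return not (trial_fit < target_fit)


def optimize_enhancement(
    img: np.ndarray,
    cfg: EnhancementConfig | None = None,
    seed: int | np.random.Generator = 0,
    on_iteration=None,
) -> tuple[EnhancementParams, np.ndarray, list[float]]:
    """Tune (alpha, beta, gamma, delta) for one intensity image.

    Runs init -> (mutate, crossover, greedy select) x T, maximizing the
    edge/entropy objective of the enhanced image.  Window statistics are
    computed once from the input image and reused for every candidate.
    ``on_iteration``, if given, is called with the :class:`DEState` after
    initialization and after every iteration (e.g. to audit bound closure).

    Returns the best parameters, the enhanced image under them, and the
    per-iteration best-objective history (length T + 1, non-decreasing).
    """
    cfg = cfg or EnhancementConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats = local_window_stats(img, cfg.window)
    lb, ub = cfg.bounds_arrays()

    def objective(vec: np.ndarray) -> float:
        enhanced = apply_enhancement(img, stats, EnhancementParams.from_vector(vec))
        return enhancement_objective(enhanced, cfg).objective

    state = de_init_population(cfg.pop_size, lb, ub, objective, rng)
    if on_iteration is not None:
        on_iteration(state)
    for t in range(cfg.iterations):
        for i in range(state.pop_size):
            mutant = de_mutate(state, i, rng)
            trial = de_crossover(state.population[i], mutant, cfg.crossover_rate, lb, ub, rng)
            trial_fit = objective(trial)
            if de_select(state.fitnesses[i], trial_fit):
                state.population[i] = trial
                state.fitnesses[i] = trial_fit
                if trial_fit >= state.best_fitness:
                    state.best = EnhancementParams.from_vector(trial)
                    state.best_fitness = float(trial_fit)
        state.iteration = t + 1
        state.history.append(state.best_fitness)
        if on_iteration is not None:
            on_iteration(state)

    enhanced = apply_enhancement(img, stats, state.best)
    return state.best, enhanced, state.history


def enhance_rgb(
    rgb: np.ndarray,
    cfg: EnhancementConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, EnhancementParams, list[float]]:
    """Enhance an RGB image through the HSI intensity channel.

    Converts to HSI, stretches the I channel with DE-tuned parameters,
    and converts back; hue and saturation pass through untouched.
    """
    h, s, inten = rgb_to_hsi(rgb)
    params, enhanced_i, history = optimize_enhancement(inten, cfg, seed)
    return hsi_to_rgb(h, s, enhanced_i), params, history
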