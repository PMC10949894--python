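"""Binary Grey Wolf wrapper feature selection, with a GA baseline.

A wolf is a binary mask over the fused feature columns.  The pack ranks
its three best masks as alpha, beta and delta leaders; every wolf then
updates each bit by (i) measuring a coefficient-scaled distance to each
leader bit, (ii) squashing the scaled distance through a steep sigmoid
into a step probability, (iii) thresholding the step against a uniform
draw, (iv) OR-ing the step with the leader bit, and (v) picking one of
the three resulting candidate bits uniformly.  The encircling coefficient
``a`` decays linearly from 2 to 0 over the run, shifting the update from
exploration toward copying the leaders.

Masks are scored by the wrapper fitness (minimized)

    Gamma = alpha1 * e + alpha2 * (q_s / q_t)

where ``e`` is the holdout error of a k-NN classifier trained on the
selected columns, ``q_s`` the number of selected columns and ``q_t`` the
total.  alpha1 = 0.99, alpha2 = 0.01 makes accuracy dominant and the
parsimony term a tie-breaker; the empty mask scores Gamma = 1.

:func:`ga_select` runs a standard generational genetic algorithm on the
same fitness, as the convergence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureMatrix

__all__ = [
    "FitnessConfig",
    "GWOConfig",
    "GAConfig",
    "HoldoutSplit",
    "encircling_coefficient",
    "leader_distance",
    "step_size",
    "binarize_step",
    "combine_leader",
    "stochastic_crossover",
    "selection_fitness",
    "update_leaders",
    "gwo_select",
    "ga_select",
    "save_mask",
    "load_mask",
    "save_history",
]


# ---------------------------------------------------------------------------
# fitness


@dataclass(frozen=True)
class FitnessConfig:
    """Wrapper-fitness settings.

    k: neighbour count of the inner k-NN.
    holdout: fraction h_o of rows held out for the error estimate.
    alpha1 / alpha2: weights of error and parsimony; must sum to 1.
    metric: k-NN distance metric ('euclidean' or 'cosine').
    resample_per_call: draw a fresh holdout for every evaluation instead
        of one fixed stratified split per optimizer run.
    """

    k: int = 5
    holdout: float = 0.2
    alpha1: float = 0.99
    alpha2: float = 0.01
    metric: str = "euclidean"
    resample_per_call: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.holdout < 1:
            raise ValueError("holdout fraction must be in (0, 1)")
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-12:
            raise ValueError("alpha1 + alpha2 must equal 1")


@dataclass(frozen=True)
class HoldoutSplit:
    """A fixed stratified train/holdout row partition."""

    train_idx: np.ndarray
    test_idx: np.ndarray

    @classmethod
    def draw(cls, labels: np.ndarray, holdout: float, rng: np.random.Generator) -> "HoldoutSplit":
        idx = np.arange(len(labels))
        tr, te = train_test_split(
            idx,
            test_size=holdout,
            stratify=labels,
            random_state=int(rng.integers(2**31 - 1)),
        )
        return cls(train_idx=np.sort(tr), test_idx=np.sort(te))


def selection_fitness(
    mask: np.ndarray,
    features: FeatureMatrix,
    cfg: FitnessConfig | None = None,
    split: HoldoutSplit | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Gamma = alpha1 * holdout-kNN-error + alpha2 * (q_s / q_t) for one mask.

    The empty mask is scored 1 (the worst possible value) without training
    anything.  ``split`` fixes the holdout partition; when absent one is
    drawn from ``rng`` (stratified).
    """
    cfg = cfg or FitnessConfig()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (features.n_features,):
        raise ValueError(
            f"mask length {mask.shape} does not match {features.n_features} features"
        )
    q_s = int(mask.sum())
    if q_s == 0:
        return 1.0
    if split is None:
        rng = rng or np.random.default_rng()
        split = HoldoutSplit.draw(features.labels, cfg.holdout, rng)
    x = features.values[:, mask]
    y = features.labels
    if len(split.train_idx) < cfg.k:
        raise ValueError(
            f"k={cfg.k} neighbours need at least k training rows, got {len(split.train_idx)}"
        )
    knn = KNeighborsClassifier(n_neighbors=cfg.k, metric=cfg.metric, algorithm="brute")
    knn.fit(x[split.train_idx], y[split.train_idx])
    acc = float(np.mean(knn.predict(x[split.test_idx]) == y[split.test_idx]))
    err = 1.0 - acc
    return cfg.alpha1 * err + cfg.alpha2 * (q_s / features.n_features)


# ---------------------------------------------------------------------------
# binary GWO primitives


def encircling_coefficient(t: int, t_max: int) -> float:
    """a(t) = 2 - 2 t / t_max, decreasing linearly from 2 to 0."""
    if t_max < 1:
        raise ValueError("t_max must be at least 1")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration {t} outside [0, {t_max}]")
    return 2.0 - 2.0 * t / t_max


def leader_distance(c: float, leader_bit: int, wolf_bit: int) -> float:
    """Per-dimension distance to a leader: |c * leader_bit - wolf_bit|."""
    return abs(c * leader_bit - wolf_bit)


def step_size(a_coef: float, d: float) -> float:
    """Sigmoid step probability S = 1 / (1 + exp(-10 (a_coef * d - 0.5)))."""
    return float(1.0 / (1.0 + np.exp(-10.0 * (a_coef * d - 0.5))))


def binarize_step(s: float, r: float) -> int:
    """Threshold the step probability against a uniform draw (1 iff S >= r)."""
    return 1 if s >= r else 0


def combine_leader(leader_bit: int, delta_bit: int) -> int:
    """Candidate bit: 1 iff leader bit + step bit >= 1 (logical OR)."""
    return 1 if (leader_bit + delta_bit) >= 1 else 0


def stochastic_crossover(z1: int, z2: int, z3: int, r: float) -> int:
    """Pick among the three leader-derived candidate bits by thirds of r."""
    if r < 1.0 / 3.0:
        return z1
    if r < 2.0 / 3.0:
        return z2
    return z3


# ---------------------------------------------------------------------------
# leader bookkeeping


@dataclass(frozen=True)
class Leaders:
    """Alpha/beta/delta masks and fitnesses (f_alpha <= f_beta <= f_delta)."""

    v_alpha: np.ndarray
    v_beta: np.ndarray
    v_delta: np.ndarray
    f_alpha: float = np.inf
    f_beta: float = np.inf
    f_delta: float = np.inf

    @classmethod
    def initial(cls, d_max: int) -> "Leaders":
        z = np.zeros(d_max, dtype=np.int8)
        return cls(z, z.copy(), z.copy())


def update_leaders(leaders: Leaders, candidate: np.ndarray, f: float) -> Leaders:
    """Rank a freshly evaluated wolf into the alpha/beta/delta hierarchy.

    Strict-inequality cascade: a candidate beating alpha demotes the old
    alpha to beta; one beating only beta demotes the old beta to delta;
    anything else becomes the new delta.  Equal fitness never displaces a
    leader of the same rank.
    """
    candidate = np.asarray(candidate, dtype=np.int8).copy()
    if f < leaders.f_alpha:
        return replace(
            leaders,
            v_beta=leaders.v_alpha, f_beta=leaders.f_alpha,
            v_alpha=candidate, f_alpha=f,
        )
    if f < leaders.f_beta:
        return replace(
            leaders,
            v_delta=leaders.v_beta, f_delta=leaders.f_beta,
            v_beta=candidate, f_beta=f,
        )
    return replace(leaders, v_delta=candidate, f_delta=f)


# ---------------------------------------------------------------------------
# optimizers


@dataclass(frozen=True)
class GWOConfig:
    """Budget of a binary GWO run: pack size n_p and iteration count t_max."""

    n_pop: int = 20
    t_max: int = 50
    fitness: FitnessConfig = field(default_factory=FitnessConfig)

    def __post_init__(self) -> None:
        if self.n_pop < 3:
            raise ValueError("pack needs at least 3 wolves (alpha, beta, delta)")
        if self.t_max < 1:
            raise ValueError("t_max must be at least 1")


@dataclass
class SelectionHistory:
    """Per-iteration trace of the incumbent best mask."""

    f_alpha: list[float] = field(default_factory=list)
    q_s: list[int] = field(default_factory=list)


def _validate_features(features: FeatureMatrix) -> None:
    if len(np.unique(features.labels)) < 2:
        raise ValueError("feature selection needs at least two label classes")


def _make_fitness(features, cfg: FitnessConfig, rng: np.random.Generator):
    """Bind the fitness to one holdout split drawn from the run RNG."""
    if cfg.resample_per_call:
        return lambda mask: selection_fitness(mask, features, cfg, split=None, rng=rng)
    split = HoldoutSplit.draw(features.labels, cfg.holdout, rng)
    return lambda mask: selection_fitness(mask, features, cfg, split=split)


def gwo_select(
    features: FeatureMatrix,
    cfg: GWOConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, SelectionHistory]:
    """Run the binary Grey Wolf optimizer and return the alpha mask.

    Per iteration every wolf is evaluated and ranked into the leader
    hierarchy, then every bit of every wolf is rewritten through the
    sigmoid / threshold / OR / crossover chain driven by the decaying
    encircling coefficient.  RNG draw order per wolf-dimension: a1, a2,
    a3, c1, c2, c3, three binarization draws, one crossover draw.

    Returns the final alpha mask (int8 0/1 vector) and the per-iteration
    history of f_alpha (non-increasing) and its selected count.
    """
    cfg = cfg or GWOConfig()
    _validate_features(features)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fitness = _make_fitness(features, cfg.fitness, rng)

    d_max = features.n_features
    pop = rng.integers(0, 2, size=(cfg.n_pop, d_max), dtype=np.int8)
    leaders = Leaders.initial(d_max)
    history = SelectionHistory()

    for t in range(1, cfg.t_max + 1):
        for j in range(cfg.n_pop):
            leaders = update_leaders(leaders, pop[j], fitness(pop[j]))
        history.f_alpha.append(leaders.f_alpha)
        history.q_s.append(int(leaders.v_alpha.sum()))

        a = encircling_coefficient(t, cfg.t_max)
        leader_stack = np.stack(
            [leaders.v_alpha, leaders.v_beta, leaders.v_delta], axis=1
        ).astype(float)  # (d_max, 3)
        for j in range(cfg.n_pop):
            # One (d_max, 10) block consumes the identical uniform stream as
            # per-dimension draws of (a1,a2,a3, c1,c2,c3, r4 x3, r6).
            draws = rng.random((d_max, 10))
            a_coefs = 2.0 * a * draws[:, 0:3] - a
            c_coefs = 2.0 * draws[:, 3:6]
            r4 = draws[:, 6:9]
            r6 = draws[:, 9]
            dist = np.abs(c_coefs * leader_stack - pop[j][:, None])
            s = 1.0 / (1.0 + np.exp(-10.0 * (a_coefs * dist - 0.5)))
            step = (s >= r4).astype(np.int8)
            z = ((leader_stack + step) >= 1).astype(np.int8)  # OR with leader bit
            pick = np.where(r6 < 1.0 / 3.0, 0, np.where(r6 < 2.0 / 3.0, 1, 2))
            pop[j] = z[np.arange(d_max), pick]

    return leaders.v_alpha.copy(), history


@dataclass(frozen=True)
class GAConfig:
    """Generational GA baseline: tournament selection, uniform crossover,
    bit-flip mutation, one elite."""

    n_pop: int = 20
    t_max: int = 50
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/d_max
    fitness: FitnessConfig = field(default_factory=FitnessConfig)


def ga_select(
    features: FeatureMatrix,
    cfg: GAConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, SelectionHistory]:
    """Genetic-algorithm baseline minimizing the same wrapper fitness.

    Same history contract as :func:`gwo_select`: the best-so-far fitness
    trace is non-increasing (the elite survives every generation).
    """
    cfg = cfg or GAConfig()
    _validate_features(features)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fitness = _make_fitness(features, cfg.fitness, rng)

    d_max = features.n_features
    p_mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / d_max
    pop = rng.integers(0, 2, size=(cfg.n_pop, d_max), dtype=np.int8)
    fits = np.array([fitness(m) for m in pop])
    best_i = int(np.argmin(fits))
    best, best_f = pop[best_i].copy(), float(fits[best_i])
    history = SelectionHistory()
    history.f_alpha.append(best_f)
    history.q_s.append(int(best.sum()))

    def tournament() -> np.ndarray:
        idx = rng.integers(0, cfg.n_pop, size=cfg.tournament)
        return pop[idx[np.argmin(fits[idx])]]

    for _ in range(1, cfg.t_max):
        children = [best.copy()]  # elitism
        while len(children) < cfg.n_pop:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                take = rng.random(d_max) < 0.5
                c1 = np.where(take, p1, p2).astype(np.int8)
                c2 = np.where(take, p2, p1).astype(np.int8)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for c in (c1, c2):
                flip = rng.random(d_max) < p_mut
                c[flip] ^= 1
                children.append(c)
        pop = np.array(children[: cfg.n_pop])
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_f:
            best, best_f = pop[gen_best].copy(), float(fits[gen_best])
        history.f_alpha.append(best_f)
        history.q_s.append(int(best.sum()))

    return best, history


# ---------------------------------------------------------------------------
# mask / history files


def save_mask(mask: np.ndarray, path, gamma: float | None = None) -> None:
    """Write selected indices, one 0-based index per line, with a header
    comment recording d_max and the achieved fitness."""
    mask = np.asarray(mask).astype(bool)
    with open(path, "w") as fh:
        gtxt = f"{gamma:.6f}" if gamma is not None else "nan"
        fh.write(f"# d_max={mask.size} gamma={gtxt}\n")
        for i in np.flatnonzero(mask):
            fh.write(f"{i}\n")


def load_mask(path) -> np.ndarray:
    """Read a mask file back into a 0/1 vector of length d_max."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#") or "d_max=" not in header:
            raise ValueError(f"{path}: missing mask header")
        d_max = int(header.split("d_max=")[1].split()[0])
        mask = np.zeros(d_max, dtype=np.int8)
        for line in fh:
            line = line.strip()
            if line:
                mask[int(line)] = 1
    return mask


def save_history(history: SelectionHistory, path) -> None:
    """Write the convergence trace as a delimited table."""
    with open(path, "w") as fh:
        fh.write("iteration\tf_alpha\tq_s\n")
        for t, (f, q) in enumerate(zip(history.f_alpha, history.q_s), start=1):
            fh.write(f"{t}\t{f:.10g}\t{q}\n")
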