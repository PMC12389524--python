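"""Particle swarm optimizers and the cross-validation fitness adapter.

Two velocity updates are provided, both minimizing a black-box fitness over a
box-bounded search space:

* plain PSO:  ``V <- w V + c1 r1 (pbest - X) + c2 r2 (gbest - X)``
* CLPSO:      ``V <- w V + c r (pbest_exemplar - X)`` where each *dimension*
  of each particle follows the personal best of a possibly different particle
  (its exemplar).  Exemplars are drawn dimension-wise with a per-particle
  learning probability Pc and refreshed only after a particle has failed to
  improve for ``refreshing_gap`` consecutive steps.  Because a particle can
  learn different dimensions from different swarm members, diversity is
  preserved and premature convergence to local optima is suppressed.

Constants follow the canonical CLPSO literature: Pc_i ramps from 0.05 to 0.5
across the swarm via an exponential schedule, refreshing gap 7, acceleration
c = 1.49445, and inertia decaying linearly from 0.9 to 0.4 over the
evaluation budget.  Integer dimensions keep a continuous position and are
rounded only when the fitness is evaluated, so swarm dynamics are unchanged.

``cv_fitness`` turns a model family plus a descriptor table into a fitness
function mapping a hyperparameter position to seeded k-fold cross-validation
loss, which is what the QSAR pipelines optimize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from mixqsar.datasets import DescriptorTable
from mixqsar.ensembles import TreeConfig, fit_gbdt, fit_rf
from mixqsar.errors import ConfigurationError, ConvergenceError
from mixqsar.kernels import KernelSpec
from mixqsar.svr import KernelSVR

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("svr_poly", "svr_mixed", "rf", "gbdt")


@dataclass
class SearchSpace:
    """Box bounds with per-dimension kind (real or integer) and names.

    Dimensions whose ``scale`` is ``"log"`` are searched in log10 space: the
    swarm sees uniform coordinates between log10(lower) and log10(upper) and
    positions are exponentiated back when a fitness is evaluated or a best
    position reported.  This is the usual parametrization for SVR cost and
    kernel-width hyperparameters, whose plausible values span decades.
    """

    lower: np.ndarray
    upper: np.ndarray
    kinds: tuple[str, ...]
    names: tuple[str, ...]
    scales: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.scales is None:
            self.scales = tuple("linear" for _ in self.names)
        if not (
            len(self.lower) == len(self.upper) == len(self.kinds)
            == len(self.names) == len(self.scales)
        ):
            raise ConfigurationError("search-space fields must have equal lengths")
        if not (self.lower < self.upper).all():
            raise ConfigurationError("every lower bound must be < its upper bound")
        bad = set(self.kinds) - {"real", "integer"}
        if bad:
            raise ConfigurationError(f"unknown dimension kinds: {sorted(bad)}")
        bad = set(self.scales) - {"linear", "log"}
        if bad:
            raise ConfigurationError(f"unknown dimension scales: {sorted(bad)}")
        for kind, scale in zip(self.kinds, self.scales):
            if kind == "integer" and scale == "log":
                raise ConfigurationError("integer dimensions must use linear scale")
        if any(s == "log" for s in self.scales) and not (
            self.lower[[s == "log" for s in self.scales]] > 0
        ).all():
            raise ConfigurationError("log-scale dimensions need positive bounds")
        self._log = np.array([s == "log" for s in self.scales])
        # internal (swarm) coordinates: log10 for log dims, identity otherwise
        self._ilower = self.lower.copy()
        self._iupper = self.upper.copy()
        self._ilower[self._log] = np.log10(self.lower[self._log])
        self._iupper[self._log] = np.log10(self.upper[self._log])

    @property
    def n_dims(self) -> int:
        return len(self.lower)

    @property
    def internal_lower(self) -> np.ndarray:
        return self._ilower

    @property
    def internal_upper(self) -> np.ndarray:
        return self._iupper

    @property
    def span(self) -> np.ndarray:
        return self._iupper - self._ilower

    def round_position(self, position: np.ndarray) -> np.ndarray:
        """Map an internal swarm coordinate to raw parameter values:
        exponentiate log dimensions, round integer dimensions."""
        out = np.array(position, dtype=float)
        out[self._log] = 10.0 ** out[self._log]
        for d, kind in enumerate(self.kinds):
            if kind == "integer":
                out[d] = np.round(out[d])
        return out

    def to_dict(self) -> dict:
        return {
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "kinds": list(self.kinds),
            "names": list(self.names),
            "scales": list(self.scales),
        }

    @classmethod
    def from_dict(cls, mapping: dict) -> "SearchSpace":
        return cls(
            np.asarray(mapping["lower"], dtype=float),
            np.asarray(mapping["upper"], dtype=float),
            tuple(mapping["kinds"]),
            tuple(mapping["names"]),
            tuple(mapping["scales"]) if "scales" in mapping else None,
        )


def learning_probabilities(n_particles: int) -> np.ndarray:
    """Canonical CLPSO schedule: Pc_i from 0.05 up to 0.5 across the swarm."""
    if n_particles == 1:
        return np.array([0.05])
    i = np.arange(n_particles)
    return 0.05 + 0.45 * (np.exp(10 * i / (n_particles - 1)) - 1) / (np.exp(10) - 1)


@dataclass
class SwarmState:
    """Full optimizer state; every operation mutates and returns it."""

    space: SearchSpace
    positions: np.ndarray
    velocities: np.ndarray
    pbest: np.ndarray
    pbest_fitness: np.ndarray
    gbest: np.ndarray
    gbest_fitness: float
    exemplars: np.ndarray  # (particles, dims) indices into the swarm
    stagnation: np.ndarray
    rng: np.random.Generator
    inertia: float = 0.9
    c: float = 1.49445
    c1: float = 1.49445
    c2: float = 1.49445
    vmax: np.ndarray = None  # type: ignore[assignment]
    refreshing_gap: int = 7
    pc: np.ndarray = None  # type: ignore[assignment]
    eval_count: int = 0
    trace: list = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.positions)


def _evaluate(state: SwarmState, fitness_fn, position: np.ndarray) -> float:
    value = fitness_fn(state.space.round_position(position))
    value = float(value)
    if not np.isfinite(value):
        logger.warning("non-finite fitness at %s; penalizing with +inf", position)
        value = np.inf
    state.eval_count += 1
    state.trace.append(value)
    return value


def init_swarm(
    fitness_fn,
    space: SearchSpace,
    n_particles: int,
    seed: int,
    vmax_fraction: float = 0.2,
    refreshing_gap: int = 7,
    c: float = 1.49445,
    c1: float = 1.49445,
    c2: float = 1.49445,
    inertia: float = 0.9,
) -> SwarmState:
    """Uniform random initialization; evaluates every particle once."""
    if n_particles < 1:
        raise ConfigurationError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    d = space.n_dims
    positions = space.internal_lower + rng.uniform(size=(n_particles, d)) * space.span
    vmax = vmax_fraction * space.span
    velocities = rng.uniform(-1.0, 1.0, size=(n_particles, d)) * vmax
    state = SwarmState(
        space=space,
        positions=positions,
        velocities=velocities,
        pbest=positions.copy(),
        pbest_fitness=np.full(n_particles, np.inf),
        gbest=positions[0].copy(),
        gbest_fitness=np.inf,
        exemplars=np.tile(np.arange(n_particles)[:, None], (1, d)),
        stagnation=np.zeros(n_particles, dtype=int),
        rng=rng,
        inertia=inertia,
        c=c,
        c1=c1,
        c2=c2,
        vmax=vmax,
        refreshing_gap=refreshing_gap,
        pc=learning_probabilities(n_particles),
    )
    for i in range(n_particles):
        state.pbest_fitness[i] = _evaluate(state, fitness_fn, positions[i])
    best = int(np.argmin(state.pbest_fitness))
    state.gbest = state.pbest[best].copy()
    state.gbest_fitness = float(state.pbest_fitness[best])
    assign_exemplars(state, particles=np.arange(n_particles))
    return state


def _clamp(state: SwarmState) -> None:
    """Clamp positions to bounds, zeroing velocity in clamped dimensions."""
    low, high = state.space.internal_lower, state.space.internal_upper
    below = state.positions < low
    above = state.positions > high
    state.positions = np.clip(state.positions, low, high)
    state.velocities[below | above] = 0.0


def _update_bests(state: SwarmState, fitness: np.ndarray) -> None:
    improved = fitness < state.pbest_fitness
    state.pbest[improved] = state.positions[improved]
    state.pbest_fitness[improved] = fitness[improved]
    state.stagnation[improved] = 0
    state.stagnation[~improved] += 1
    best = int(np.argmin(state.pbest_fitness))
    if state.pbest_fitness[best] < state.gbest_fitness:
        state.gbest = state.pbest[best].copy()
        state.gbest_fitness = float(state.pbest_fitness[best])


def pso_step(state: SwarmState, fitness_fn, rand1=None, rand2=None) -> SwarmState:
    """One plain-PSO velocity/position update over the whole swarm.

    ``rand1``/``rand2`` override the per-particle-per-dimension uniforms
    (test hook); by default they are drawn fresh from the state's generator.
    """
    shape = state.positions.shape
    r1 = state.rng.uniform(size=shape) if rand1 is None else np.broadcast_to(rand1, shape)
    r2 = state.rng.uniform(size=shape) if rand2 is None else np.broadcast_to(rand2, shape)
    state.velocities = (
        state.inertia * state.velocities
        + state.c1 * r1 * (state.pbest - state.positions)
        + state.c2 * r2 * (state.gbest - state.positions)
    )
    state.velocities = np.clip(state.velocities, -state.vmax, state.vmax)
    state.positions = state.positions + state.velocities
    _clamp(state)
    fitness = np.array([_evaluate(state, fitness_fn, p) for p in state.positions])
    _update_bests(state, fitness)
    return state


def assign_exemplars(
    state: SwarmState,
    learning_probs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    particles: np.ndarray | None = None,
) -> SwarmState:
    """Refresh comprehensive-learning exemplar assignments.

    For every dimension of each refreshed particle: with probability Pc_i the
    exemplar is the better (by pbest fitness) of two other particles drawn at
    random; otherwise the particle follows its own pbest.  If every dimension
    ends up self-assigned, one random dimension is forced to a random other
    particle.  By default only particles whose stagnation counter exceeded
    the refreshing gap are touched.
    """
    rng = rng or state.rng
    pc = state.pc if learning_probs is None else np.asarray(learning_probs, dtype=float)
    ps, d = state.exemplars.shape
    if particles is None:
        particles = np.flatnonzero(state.stagnation > state.refreshing_gap)
    for i in np.atleast_1d(particles):
        i = int(i)
        if ps == 1:
            state.exemplars[i] = i  # degenerate swarm: only self to learn from
            logger.debug("swarm of size 1: exemplar is self")
            state.stagnation[i] = 0
            continue
        others = np.delete(np.arange(ps), i)
        row = np.full(d, i)
        for dim in range(d):
            if rng.uniform() < pc[i]:
                pick = rng.choice(others, size=min(2, len(others)), replace=False)
                row[dim] = pick[np.argmin(state.pbest_fitness[pick])]
        if (row == i).all():
            dim = int(rng.integers(d))
            row[dim] = int(rng.choice(others))
        state.exemplars[i] = row
        state.stagnation[i] = 0
    return state


def clpso_step(state: SwarmState, fitness_fn, rand=None) -> SwarmState:
    """One CLPSO update: each dimension follows its exemplar's pbest."""
    shape = state.positions.shape
    r = state.rng.uniform(size=shape) if rand is None else np.broadcast_to(rand, shape)
    exemplar_pbest = state.pbest[state.exemplars, np.arange(shape[1])[None, :]]
    state.velocities = state.inertia * state.velocities + state.c * r * (
        exemplar_pbest - state.positions
    )
    state.velocities = np.clip(state.velocities, -state.vmax, state.vmax)
    state.positions = state.positions + state.velocities
    _clamp(state)
    fitness = np.array([_evaluate(state, fitness_fn, p) for p in state.positions])
    _update_bests(state, fitness)
    assign_exemplars(state)
    return state


def optimize(
    fitness_fn,
    space: SearchSpace,
    n_particles: int = 20,
    max_evaluations: int = 500,
    seed: int = 0,
    algorithm: str = "clpso",
    inertia_start: float = 0.9,
    inertia_end: float = 0.4,
    **swarm_kwargs,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run a full swarm optimization and return (best position, fitness, trace).

    The trace is the fitness of every evaluation in order.  Integer
    dimensions of the returned position are rounded.  Deterministic for a
    fixed seed and deterministic fitness.
    """
    if algorithm not in ("clpso", "pso"):
        raise ConfigurationError("algorithm must be 'clpso' or 'pso'")
    if max_evaluations < n_particles:
        raise ConfigurationError("max_evaluations must cover at least the initial swarm")
    state = init_swarm(fitness_fn, space, n_particles, seed, inertia=inertia_start, **swarm_kwargs)
    step = clpso_step if algorithm == "clpso" else pso_step
    while state.eval_count + n_particles <= max_evaluations:
        frac = state.eval_count / max_evaluations
        state.inertia = inertia_start + (inertia_end - inertia_start) * frac
        step(state, fitness_fn)
    best = state.space.round_position(state.gbest)
    return best, state.gbest_fitness, np.asarray(state.trace)


# ---------------------------------------------------------------------------
# cross-validation fitness adapter


def default_search_space(family: str) -> SearchSpace:
    """Reasonable box bounds for each model family (descriptors z-scored)."""
    if family == "svr_poly":
        return SearchSpace(
            [0.01, 0.001, 0.01, 0.0, 1.0],
            [5000.0, 0.5, 10.0, 5.0, 4.0],
            ("real", "real", "real", "real", "integer"),
            ("cost", "epsilon", "gamma", "offset", "degree"),
            ("log", "log", "log", "linear", "linear"),
        )
    if family == "svr_mixed":
        return SearchSpace(
            [0.01, 0.001, 0.01, 0.01, 0.0, 1.0, 0.0, 0.0],
            [1000.0, 0.5, 5.0, 10.0, 5.0, 4.0, 1.0, 1.0],
            ("real", "real", "real", "real", "real", "integer", "real", "real"),
            ("cost", "epsilon", "sigma", "gamma", "offset", "degree", "weight_trig", "weight_poly"),
            ("log", "log", "log", "log", "linear", "linear", "linear", "linear"),
        )
    if family == "rf":
        return SearchSpace(
            [10.0, 2.0, 2.0, 1.0],
            [600.0, 10.0, 10.0, 10.0],
            ("integer", "integer", "integer", "integer"),
            ("n_trees", "max_depth", "min_samples_split", "min_samples_leaf"),
        )
    if family == "gbdt":
        return SearchSpace(
            [5.0, 0.01, 1.0],
            [200.0, 0.5, 8.0],
            ("integer", "real", "integer"),
            ("n_stages", "learning_rate", "max_depth"),
        )
    raise ConfigurationError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


class _TreeEstimator:
    """fit/predict adapter over the ensemble fitting functions."""

    def __init__(self, builder):
        self._builder = builder

    def fit(self, X, y):
        self._model = self._builder(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


def build_estimator(family: str, params: dict, **svr_kwargs):
    """Instantiate an unfitted estimator from named hyperparameters.

    Mixed-kernel weight pairs with alpha + beta > 1 are repaired by scaling
    both onto the simplex face; the repair is logged.  ``svr_kwargs`` are
    forwarded to :class:`KernelSVR` (e.g. a larger iteration budget for a
    final refit).
    """
    if family == "svr_poly":
        spec = KernelSpec(
            family="poly",
            gamma=params["gamma"],
            offset=params["offset"],
            degree=int(round(params.get("degree", 3))),
        )
        return KernelSVR(spec, cost=params["cost"], epsilon=params["epsilon"], **svr_kwargs)
    if family == "svr_mixed":
        a, b = params["weight_trig"], params["weight_poly"]
        if a + b > 1.0:
            logger.info("repairing infeasible weights alpha=%.4f beta=%.4f", a, b)
            a, b = a / (a + b), b / (a + b)
        spec = KernelSpec(
            family="mixed",
            gamma=params["gamma"],
            offset=params["offset"],
            degree=int(round(params.get("degree", 3))),
            sigma=params["sigma"],
            weight_trig=a,
            weight_poly=b,
        )
        return KernelSVR(spec, cost=params["cost"], epsilon=params["epsilon"], **svr_kwargs)
    if family == "rf":
        cfg = TreeConfig(
            max_depth=int(round(params["max_depth"])),
            min_samples_split=int(round(params["min_samples_split"])),
            min_samples_leaf=int(round(params["min_samples_leaf"])),
        )
        return _TreeEstimator(
            lambda X, y: fit_rf(
                X, y, n_trees=int(round(params["n_trees"])), tree_config=cfg,
                seed=int(params.get("seed", 0)),
            )
        )
    if family == "gbdt":
        cfg = TreeConfig(max_depth=int(round(params["max_depth"])))
        return _TreeEstimator(
            lambda X, y: fit_gbdt(
                X, y, n_stages=int(round(params["n_stages"])),
                learning_rate=params["learning_rate"], tree_config=cfg,
            )
        )
    raise ConfigurationError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, contiguous near-equal blocks."""
    if not 2 <= k <= n:
        raise ConfigurationError(f"folds must lie in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, k)]


def cv_fitness(
    model_family: str,
    table: DescriptorTable,
    space: SearchSpace,
    metric: str = "rmse",
    folds: int = 5,
    seed: int = 0,
):
    """Fitness function: hyperparameter position -> mean k-fold CV loss.

    Folds are fixed once per adapter (seeded shuffle, contiguous blocks), so
    the fitness is deterministic in the position.  Results are cached keyed
    by the rounded position to avoid redundant refits during swarm search.
    """
    if model_family not in MODEL_FAMILIES:
        raise ConfigurationError(
            f"unknown model family {model_family!r}; expected one of {MODEL_FAMILIES}"
        )
    if metric not in ("rmse", "one_minus_q2"):
        raise ConfigurationError("metric must be 'rmse' or 'one_minus_q2'")
    X, y = table.X, table.response
    fold_idx = kfold_indices(len(y), folds, seed)
    sst = float(np.sum((y - y.mean()) ** 2))
    cache: dict[tuple, float] = {}

    def fitness(position: np.ndarray) -> float:
        position = np.asarray(position, dtype=float)
        if len(position) != len(space.names):
            raise ConfigurationError(
                f"position has {len(position)} dims, space has {len(space.names)}"
            )
        key = tuple(np.round(position, 8))
        if key in cache:
            return cache[key]
        params = dict(zip(space.names, position))
        pooled = np.empty_like(y)
        try:
            for test in fold_idx:
                train = np.setdiff1d(np.arange(len(y)), test)
                est = build_estimator(model_family, params)
                est.fit(X[train], y[train])
                pooled[test] = est.predict(X[test])
            sse = float(np.sum((y - pooled) ** 2))
            value = np.sqrt(sse / len(y)) if metric == "rmse" else sse / sst
        except (
            ValueError,
            FloatingPointError,
            np.linalg.LinAlgError,
            ConvergenceError,
        ) as exc:
            logger.warning("fitness evaluation failed at %s: %s", params, exc)
            value = np.inf
        cache[key] = value
        return value

    return fitness
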