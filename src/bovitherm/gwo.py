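"""Grey wolf optimizer over mixed continuous/categorical search spaces.

Positions live on the unit hypercube (one coordinate per dimension) and are
decoded to typed hyperparameter values.  The canonical update maintains the
three best wolves (alpha, beta, delta); every other wolf moves to the mean
of three leader-guided positions with the exploration coefficient ``a``
decaying linearly from 2 to 0.

A pluggable ``minimize(objective, space, config)`` convention keeps the
door open for alternative optimizers (e.g. a library-backed Bayesian
optimizer) behind the same interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Dim",
    "SearchSpace",
    "Candidate",
    "GwoConfig",
    "TuneResult",
    "gwo_minimize",
    "tune",
]

KINDS = ("continuous", "log-continuous", "integer", "categorical")


@dataclass(frozen=True)
class Dim:
    """One search dimension: a bounded interval or a list of options."""

    name: str
    kind: str
    bounds: tuple | None = None      # (low, high) for non-categorical kinds
    options: tuple | None = None     # for categorical kind

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown dim kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.options:
                raise ValueError(f"dim {self.name!r}: categorical options must be non-empty")
        else:
            if self.bounds is None or len(self.bounds) != 2:
                raise ValueError(f"dim {self.name!r}: bounds required")
            low, high = self.bounds
            if not low < high:
                raise ValueError(f"dim {self.name!r}: bounds must satisfy low < high")
            if self.kind == "log-continuous" and low <= 0:
                raise ValueError(f"dim {self.name!r}: log-continuous bounds must be > 0")

    def decode(self, p: float):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"dim {self.name!r}: coordinate {p} outside [0, 1]")
        if self.kind == "continuous":
            low, high = self.bounds
            return min(max(low + p * (high - low), low), high)
        if self.kind == "log-continuous":
            low, high = self.bounds
            value = math.exp(math.log(low) + p * (math.log(high) - math.log(low)))
            return min(max(value, low), high)  # guard float round-off at p=1
        if self.kind == "integer":
            low, high = self.bounds
            return int(min(max(math.floor(low + p * (high - low)), low), high))
        k = len(self.options)
        return self.options[min(math.floor(p * k), k - 1)]

    def encode(self, value) -> float:
        """Inverse of decode (up to rounding); used for warm starts."""
        if self.kind == "categorical":
            try:
                idx = self.options.index(value)
            except ValueError:
                raise ValueError(f"dim {self.name!r}: {value!r} not among options")
            return (idx + 0.5) / len(self.options)
        low, high = self.bounds
        if self.kind == "log-continuous":
            p = (math.log(value) - math.log(low)) / (math.log(high) - math.log(low))
        else:
            p = (value - low) / (high - low)
        return float(min(max(p, 0.0), 1.0))

    def validate(self, value) -> None:
        if self.kind == "categorical":
            if value not in self.options:
                raise ValueError(
                    f"hyperparameter {self.name!r}={value!r} not among options {self.options}"
                )
            return
        low, high = self.bounds
        if not low <= value <= high:
            raise ValueError(
                f"hyperparameter {self.name!r}={value!r} outside range [{low}, {high}]"
            )
        if self.kind == "integer" and int(value) != value:
            raise ValueError(f"hyperparameter {self.name!r}={value!r} must be an integer")


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of dims defining one hyperparameter domain."""

    dims: tuple[Dim, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("dim names must be unique")

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def decode(self, position: np.ndarray) -> dict:
        position = np.asarray(position, dtype=float)
        if position.shape != (self.n_dims,):
            raise ValueError(f"position must have shape ({self.n_dims},)")
        return {d.name: d.decode(float(p)) for d, p in zip(self.dims, position)}

    def encode(self, params: dict) -> np.ndarray:
        return np.array([d.encode(params[d.name]) for d in self.dims], dtype=float)

    def validate(self, params: dict) -> None:
        for d in self.dims:
            if d.name not in params:
                raise ValueError(f"missing hyperparameter {d.name!r}")
            d.validate(params[d.name])


@dataclass
class Candidate:
    """A point in the search space with its decoded values and fitness."""

    position: np.ndarray
    decoded: dict
    fitness: float


@dataclass
class GwoConfig:
    population: int = 30
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4 (three leaders plus followers)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _evaluate(objective, space: SearchSpace, positions: np.ndarray) -> list[Candidate]:
    out = []
    for pos in positions:
        decoded = space.decode(pos)
        try:
            fit = float(objective(decoded))
        except FloatingPointError:
            fit = float("inf")
        if not np.isfinite(fit):
            logger.warning("objective returned non-finite fitness for %s", decoded)
            fit = float("inf")
        out.append(Candidate(pos.copy(), decoded, fit))
    return out


def gwo_minimize(
    objective,
    space: SearchSpace,
    config: GwoConfig,
    initial_positions: np.ndarray | None = None,
) -> tuple[Candidate, list[float]]:
    """Minimize ``objective`` (decoded-candidate -> fitness, lower better).

    Returns the best-ever candidate and the per-epoch best-fitness curve
    (element 0 is the best of the initial population; the curve is
    monotonically non-increasing by best-ever tracking).
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.population, space.n_dims
    positions = rng.random((n, d))
    if initial_positions is not None:
        initial_positions = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        m = min(len(initial_positions), n)
        positions[:m] = np.clip(initial_positions[:m], 0.0, 1.0)

    wolves = _evaluate(objective, space, positions)
    order = np.argsort([w.fitness for w in wolves], kind="stable")
    best = wolves[order[0]]
    curve = [best.fitness]

    for epoch in range(config.epochs):
        a = 2.0 - epoch * (2.0 / config.epochs)  # linear 2 -> 0
        leaders = [wolves[order[0]].position, wolves[order[1]].position, wolves[order[2]].position]
        new_positions = np.empty_like(positions)
        for i in range(n):
            x = positions[i]
            guided = np.empty((3, d))
            for j, leader in enumerate(leaders):
                r1 = rng.random(d)
                r2 = rng.random(d)
                A = 2.0 * a * r1 - a
                C = 2.0 * r2
                guided[j] = leader - A * np.abs(C * leader - x)
            new_positions[i] = guided.mean(axis=0)
        positions = np.clip(new_positions, 0.0, 1.0)
        wolves = _evaluate(objective, space, positions)
        order = np.argsort([w.fitness for w in wolves], kind="stable")
        if wolves[order[0]].fitness < best.fitness:
            best = wolves[order[0]]
        curve.append(best.fitness)

    return best, curve


@dataclass
class TuneResult:
    family: str
    feature_set: str
    best_params: dict
    cv_rmse: float
    default_cv_rmse: float
    curve: list[float] = field(default_factory=list)
    seed: int = 0


def tune(
    family: str,
    spec,
    table,
    gwo_config: GwoConfig,
    split_config=None,
    space: SearchSpace | None = None,
    warm_start_default: bool = True,
) -> TuneResult:
    """GWO hyperparameter search for one model family on one feature set.

    Fitness is the mean 5-fold CV RMSE on the training partition; the test
    partition is never touched.  With ``warm_start_default`` the
    default (midpoint) candidate joins the initial population, so the tuned
    fitness can never exceed the default's.
    """
    from . import bench, featuresets  # local import: bench depends on this module

    if split_config is None:
        split_config = bench.SplitConfig(seed=gwo_config.seed)
    if space is None:
        space = bench.family_space(family)
    X, y = featuresets.materialize(table, spec)
    X_tr, _, y_tr, _ = bench.split_train_test(X, y, split_config)

    def objective(params: dict) -> float:
        return bench.cv_rmse(family, params, X_tr, y_tr, split_config)

    default = bench.default_params(family)
    default_fitness = objective(default)
    init = space.encode(default)[None, :] if warm_start_default else None
    best, curve = gwo_minimize(objective, space, gwo_config, initial_positions=init)
    return TuneResult(
        family=family,
        feature_set=spec.name,
        best_params=best.decoded,
        cv_rmse=best.fitness,
        default_cv_rmse=default_fitness,
        curve=curve,
        seed=gwo_config.seed,
    )
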