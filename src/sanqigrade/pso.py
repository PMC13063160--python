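"""Particle-swarm optimization of classifier hyperparameters.

Canonical global-best PSO: each particle's velocity gets an inertia term plus
cognitive (personal-best) and social (global-best) pulls with per-dimension
U(0,1) weights; positions are clamped to the search box with the velocity
zeroed on any clamped dimension.  Integer dimensions are rounded only when a
position is handed to the objective, so the swarm itself moves continuously.

The default search box follows the grading study: learning_rate [0.001, 0.1],
tree depth [4, 12], boosting iterations [500, 2000], L2 leaf regularization
[1, 10].  Fitness is validation accuracy of the refit classifier.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import LabeledDataset, smote_balance, stratified_split
from .modeling import ModelSpec, train_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamBounds:
    """Per-dimension (name, lower, upper, kind) search box."""

    dims: tuple[tuple[str, float, float, str], ...]

    def __post_init__(self) -> None:
        for name, lo, hi, kind in self.dims:
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound must be <= upper bound")
            if kind not in ("real", "integer"):
                raise ValueError(f"{name}: kind must be 'real' or 'integer'")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d[0] for d in self.dims)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d[1] for d in self.dims], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([d[2] for d in self.dims], dtype=float)

    def to_params(self, position: np.ndarray) -> dict:
        """Round integer dims; return a name → value map for the objective."""
        out = {}
        for (name, lo, hi, kind), v in zip(self.dims, position):
            v = float(np.clip(v, lo, hi))
            out[name] = int(round(v)) if kind == "integer" else v
        return out


DEFAULT_BOUNDS = ParamBounds((
    ("learning_rate", 0.001, 0.1, "real"),
    ("depth", 4, 12, "integer"),
    ("iterations", 500, 2000, "integer"),
    ("l2_leaf_reg", 1.0, 10.0, "real"),
))


@dataclass
class SwarmState:
    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_values: np.ndarray
    gbest_position: np.ndarray
    gbest_value: float


def pso_optimize(
    objective,
    bounds: ParamBounds,
    swarm_size: int = 20,
    iterations: int = 30,
    w: float = 0.72,
    c1: float = 1.49,
    c2: float = 1.49,
    seed: int = 0,
    init_positions: np.ndarray | None = None,
) -> tuple[dict, float, list[dict]]:
    """Maximize ``objective(params)`` over the box; returns (params, fitness, trace).

    ``init_positions`` lets callers pin particles (e.g. the default
    hyperparameters) into the initial swarm.  Non-finite fitness values are
    treated as −∞ with a warning.  The per-iteration trace records the global
    best so far; it is non-decreasing by construction.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lower, bounds.upper
    ndim = len(lo)
    pos = rng.uniform(lo, hi, size=(swarm_size, ndim))
    if init_positions is not None:
        init_positions = np.atleast_2d(np.asarray(init_positions, float))
        pos[: len(init_positions)] = np.clip(init_positions, lo, hi)
    span = hi - lo
    vel = rng.uniform(-span, span, size=(swarm_size, ndim)) * 0.1

    def evaluate(p: np.ndarray) -> float:
        val = objective(bounds.to_params(p))
        if not np.isfinite(val):
            warnings.warn("non-finite fitness; treating as -inf")
            return -np.inf
        return float(val)

    pbest_val = np.array([evaluate(p) for p in pos])
    pbest_pos = pos.copy()
    g = int(np.argmax(pbest_val))
    state = SwarmState(pos, vel, pbest_pos, pbest_val,
                       pbest_pos[g].copy(), float(pbest_val[g]))
    trace = [{"iteration": 0, "gbest_fitness": state.gbest_value,
              "gbest_params": bounds.to_params(state.gbest_position)}]

    for it in range(1, iterations + 1):
        r1 = rng.random((swarm_size, ndim))
        r2 = rng.random((swarm_size, ndim))
        state.velocities = (w * state.velocities
                            + c1 * r1 * (state.pbest_positions - state.positions)
                            + c2 * r2 * (state.gbest_position - state.positions))
        state.positions = state.positions + state.velocities
        below = state.positions < lo
        above = state.positions > hi
        state.positions = np.clip(state.positions, lo, hi)
        state.velocities[below | above] = 0.0
        for i in range(swarm_size):
            val = evaluate(state.positions[i])
            if val > state.pbest_values[i]:
                state.pbest_values[i] = val
                state.pbest_positions[i] = state.positions[i].copy()
                if val > state.gbest_value:
                    state.gbest_value = val
                    state.gbest_position = state.positions[i].copy()
        trace.append({"iteration": it, "gbest_fitness": state.gbest_value,
                      "gbest_params": bounds.to_params(state.gbest_position)})

    return bounds.to_params(state.gbest_position), state.gbest_value, trace


def tune_model(
    spec: ModelSpec,
    ds: LabeledDataset,
    bounds: ParamBounds = DEFAULT_BOUNDS,
    validation_fraction: float = 0.25,
    swarm_size: int = 20,
    iterations: int = 30,
    seed: int = 0,
    smote_target="majority",
) -> tuple[ModelSpec, float, list[dict]]:
    """PSO-tune a classifier's hyperparameters on an inner validation split.

    The training partition is split (1 − validation_fraction) / validation,
    the inner training part is SMOTE-balanced, and validation accuracy is the
    fitness.  One particle starts at the spec's current hyperparameters, so
    the tuned model can never score below the default configuration.
    """
    inner_train, inner_val = stratified_split(ds, 1.0 - validation_fraction,
                                              seed=seed)
    balanced = smote_balance(inner_train, target_count=smote_target, seed=seed)

    def objective(params: dict) -> float:
        try:
            candidate = replace(spec, hyperparameters={**spec.hyperparameters,
                                                       **params})
            model = train_model(candidate, balanced)
            return float(np.mean(model.predict(inner_val.X) == inner_val.y))
        except Exception as exc:
            logger.warning("tuning candidate failed: %s", exc)
            return -np.inf

    default_pos = np.array([
        np.clip(float(spec.hyperparameters.get(
            name, REGISTRY_DEFAULT_POSITION.get(name, (lo + hi) / 2.0))), lo, hi)
        for name, lo, hi, _ in bounds.dims
    ])
    best_params, best_fitness, trace = pso_optimize(
        objective, bounds, swarm_size=swarm_size, iterations=iterations,
        seed=seed, init_positions=default_pos[None, :])
    tuned = replace(spec, hyperparameters={**spec.hyperparameters, **best_params})
    return tuned, best_fitness, trace


# canonical fallback starting values used when the spec leaves a dim unset
REGISTRY_DEFAULT_POSITION = {
    "learning_rate": 0.1, "depth": 6, "iterations": 500, "l2_leaf_reg": 3.0,
}


def tuning_report_json(bounds: ParamBounds, trace: list[dict],
                       final_params: dict) -> str:
    return json.dumps({
        "bounds": [{"name": n, "lower": lo, "upper": hi, "kind": k}
                   for n, lo, hi, k in bounds.dims],
        "trace": trace,
        "final_params": final_params,
    }, indent=2)
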