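"""Synthetic trial datasets for testing the analysis pipeline end to end.

Three generator families: ``bernoulli`` draws responses from a known
psychometric curve (closed-form recovery oracle); ``linear-mle`` is an
idealised weighted-average integrator with known single-cue standard
deviations (makes the implied-uncertainty algebra exactly invertible);
``full-model`` runs the actual model observers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cue_integration import NoiseModel
from .image_statistics import DistributionSet
from .observers import (
    EXP1_SPEED_LEVELS,
    EXP2_LEVELS,
    ConflictModelParams,
    ExperimentConfig,
    simulate_experiment,
)

__all__ = [
    "SyntheticObserverSpec",
    "generate_exp1_dataset",
    "generate_exp2_dataset",
    "validate_trials",
]

_GENERATORS = ("full-model", "linear-mle", "bernoulli")

EXP1_COLUMNS = {
    "experiment",
    "surface_size",
    "level",
    "norm_level",
    "conflict_direction",
    "interval_order",
    "chosen_interval",
    "chose_consistent",
    "norm_response",
}
EXP2_COLUMNS = {
    "experiment",
    "conflict_type",
    "level",
    "magnitude",
    "interval_order",
    "chosen_interval",
    "correct",
}


@dataclass(frozen=True)
class SyntheticObserverSpec:
    """One synthetic observer: a generator family plus its parameters."""

    generator: str
    parameters: Mapping = field(default_factory=dict)
    trials_per_level: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.generator not in _GENERATORS:
            raise ValueError(f"generator must be one of {_GENERATORS}")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")


def _per_condition(value, key):
    if isinstance(value, Mapping):
        return float(value[key])
    return float(value)


def _exp1_row(size, level, direction, order, chose_consistent):
    consistent_interval = 1 if order == 0 else 2
    return dict(
        experiment="exp1",
        surface_size=size,
        level=level,
        norm_level=round(direction * level, 10) + 0.0,
        conflict_direction=direction,
        interval_order=order,
        chosen_interval=consistent_interval if chose_consistent else 3 - consistent_interval,
        chose_consistent=bool(chose_consistent),
        norm_response=bool(chose_consistent) if direction == 1 else not chose_consistent,
    )


def generate_exp1_dataset(
    spec: SyntheticObserverSpec,
    dists: DistributionSet | None = None,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Trial table for the speed-discrimination design.

    ``bernoulli`` parameters: ``mu``, ``sigma`` (scalars or per-size
    mappings) of the normalised psychometric curve.  ``linear-mle``
    parameters: ``sigma_cd``, ``sigma_cs`` in level (log2-ratio) units,
    scalars or per-size mappings.  ``full-model`` parameters:
    ``n_disparity``, ``n_size`` (requires ``dists``).
    """
    config = config or ExperimentConfig()
    if spec.generator == "full-model":
        if dists is None:
            raise ValueError("full-model generator requires a DistributionSet")
        noise = NoiseModel(
            spec.parameters["n_disparity"], spec.parameters["n_size"]
        )
        return simulate_experiment(
            "exp1", dists, noise,
            trials_per_level=spec.trials_per_level, seed=spec.seed, config=config,
        )
    rng = np.random.default_rng(spec.seed)
    rows = []
    for size in config.surface_sizes:
        if spec.generator == "bernoulli":
            mu = _per_condition(spec.parameters["mu"], size)
            sigma = _per_condition(spec.parameters["sigma"], size)
        else:
            s_cd = _per_condition(spec.parameters["sigma_cd"], size)
            s_cs = _per_condition(spec.parameters["sigma_cs"], size)
            w_cd = s_cs**2 / (s_cd**2 + s_cs**2)
            w_cs = 1.0 - w_cd
            sigma_comb = np.sqrt(s_cd**2 * s_cs**2 / (s_cd**2 + s_cs**2))
        for level in EXP1_SPEED_LEVELS:
            for _ in range(spec.trials_per_level):
                direction = 1 if rng.random() < 0.5 else -1
                order = int(rng.integers(2))
                if spec.generator == "bernoulli":
                    # curve defined on the direction-normalised axis
                    p = norm.cdf((direction * level - mu) / sigma)
                    norm_resp = rng.random() < p
                    chose_consistent = norm_resp if direction == 1 else not norm_resp
                else:
                    c = config.exp1_conflict
                    percept_conflict = (
                        w_cs * (direction * c)
                        + w_cd * (-direction * c)
                        + rng.normal(0.0, sigma_comb)
                    )
                    percept_consistent = level + rng.normal(0.0, sigma_comb)
                    chose_consistent = percept_consistent > percept_conflict
                rows.append(_exp1_row(size, level, direction, order, chose_consistent))
    return pd.DataFrame(rows)


def generate_exp2_dataset(
    spec: SyntheticObserverSpec,
    dists: DistributionSet | None = None,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Trial table for the conflict-discrimination design.

    ``bernoulli`` parameters: ``mu``, ``sigma`` per conflict type (scalars
    or mappings keyed by conflict type) of the scaled (0.5-floor) curve on
    conflict magnitude.  ``full-model`` runs the co-occurrence observer and
    accepts ``n_disparity``, ``n_size``, ``t_inhibitory``, ``t_conflict``.
    """
    config = config or ExperimentConfig()
    if spec.generator == "linear-mle":
        raise ValueError("linear-mle generator is defined for exp1 only")
    if spec.generator == "full-model":
        if dists is None:
            raise ValueError("full-model generator requires a DistributionSet")
        noise = NoiseModel(spec.parameters["n_disparity"], spec.parameters["n_size"])
        params = ConflictModelParams(
            noise=noise,
            t_inhibitory=spec.parameters.get("t_inhibitory", 1.5e-5),
            t_conflict=spec.parameters.get("t_conflict", 0.15),
        )
        return simulate_experiment(
            "exp2", dists, noise,
            trials_per_level=spec.trials_per_level, seed=spec.seed, config=config,
            observer="cooccurrence", conflict_params=params,
        )
    rng = np.random.default_rng(spec.seed)
    rows = []
    for ctype, levels in EXP2_LEVELS.items():
        mu = _per_condition(spec.parameters["mu"], ctype)
        sigma = _per_condition(spec.parameters["sigma"], ctype)
        for level in levels:
            magnitude = abs(level)
            p = 0.5 + 0.5 * norm.cdf((magnitude - mu) / sigma)
            for _ in range(spec.trials_per_level):
                correct = rng.random() < p
                order = int(rng.integers(2))
                conflict_interval = 2 if order == 0 else 1
                rows.append(
                    dict(
                        experiment="exp2",
                        conflict_type=ctype,
                        level=level,
                        magnitude=magnitude,
                        interval_order=order,
                        chosen_interval=(
                            conflict_interval if correct else 3 - conflict_interval
                        ),
                        correct=bool(correct),
                    )
                )
    return pd.DataFrame(rows)


def validate_trials(trials: pd.DataFrame, design: str) -> None:
    """Raise if a trial table does not satisfy the common schema."""
    required = EXP1_COLUMNS if design == "exp1" else EXP2_COLUMNS
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if not trials["chosen_interval"].isin([1, 2]).all():
        raise ValueError("chosen_interval must be 1 or 2")
    if design == "exp1":
        if not trials["conflict_direction"].isin([-1, 1]).all():
            raise ValueError("conflict_direction must be +-1")
    else:
        if not trials["magnitude"].ge(0).all():
            raise ValueError("conflict magnitude must be >= 0")
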