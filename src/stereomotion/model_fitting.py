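"""Observer-model parameter fitting by mean-squared-error minimisation.

The objective simulates the full experiment at candidate parameters with
common random numbers (the same per-trial seed sequence for every
evaluation), so the MSE between model and observed proportions is a
deterministic function of the parameters; it is minimised by a multi-start
Nelder-Mead simplex over log-transformed noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cue_integration import NoiseModel
from .image_statistics import DistributionSet
from .observers import ConflictModelParams, ExperimentConfig, simulate_experiment

__all__ = ["FitSpec", "FitResult", "fit_observer", "parameter_recovery", "mse_objective"]


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``design`` selects the experiment; exp1 fits (n_disparity, n_size), exp2
    additionally fits (t_inhibitory, t_conflict) of the co-occurrence
    detector.  ``trials_per_level`` is the model trial count per objective
    evaluation.
    """

    design: str = "exp1"
    initial: dict[str, float] = field(
        default_factory=lambda: {"n_disparity": 0.5, "n_size": 2.0}
    )
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "n_disparity": (0.01, 5.0),
            "n_size": (0.05, 10.0),
            "t_inhibitory": (1e-8, 1e-2),
            "t_conflict": (0.01, 0.9),
        }
    )
    trials_per_level: int = 100
    n_starts: int = 3
    max_evaluations: int = 60
    observer: str = "cooccurrence"

    @property
    def parameter_names(self) -> tuple[str, ...]:
        if self.design == "exp1":
            return ("n_disparity", "n_size")
        return ("n_disparity", "n_size", "t_inhibitory", "t_conflict")


@dataclass
class FitResult:
    parameters: dict[str, float]
    objective: float
    n_evaluations: int
    converged: bool
    model_proportions: pd.DataFrame
    starts: list[dict] = field(default_factory=list)


def _observed_table(trials: pd.DataFrame, design: str) -> pd.DataFrame:
    if design == "exp1":
        keys, resp = ["surface_size", "norm_level"], "norm_response"
    else:
        keys, resp = ["conflict_type", "level"], "correct"
    g = trials.groupby(keys)[resp].agg(["mean", "count"]).reset_index()
    return g.rename(columns={"mean": "proportion", "count": "n"})


def _model_proportions(
    design: str,
    params: dict[str, float],
    dists: DistributionSet,
    spec: FitSpec,
    crn_seed: int,
    config: ExperimentConfig | None,
) -> pd.DataFrame:
    noise = NoiseModel(params["n_disparity"], params["n_size"])
    conflict_params = None
    if design == "exp2" and spec.observer == "cooccurrence":
        conflict_params = ConflictModelParams(
            noise=noise,
            t_inhibitory=params.get("t_inhibitory", 1.5e-5),
            t_conflict=params.get("t_conflict", 0.15),
        )
    trials = simulate_experiment(
        design,
        dists,
        noise,
        trials_per_level=spec.trials_per_level,
        seed=crn_seed,
        config=config,
        observer=spec.observer,
        conflict_params=conflict_params,
    )
    return _observed_table(trials, design)


def mse_objective(
    observed: pd.DataFrame,
    model: pd.DataFrame,
    design: str,
) -> float:
    """Mean squared error between observed and model proportions across conditions."""
    keys = (
        ["surface_size", "norm_level"] if design == "exp1" else ["conflict_type", "level"]
    )
    merged = observed.merge(model, on=keys, suffixes=("_obs", "_model"))
    if len(merged) == 0:
        raise ValueError("observed and model tables share no conditions")
    return float(np.mean((merged["proportion_obs"] - merged["proportion_model"]) ** 2))


def _to_vector(params: dict[str, float], names) -> np.ndarray:
    # log transform keeps positivity and makes simplex steps scale-free
    return np.array([np.log(params[n]) for n in names])


def _from_vector(x: np.ndarray, names, bounds) -> dict[str, float]:
    out = {}
    for val, name in zip(np.exp(x), names):
        lo, hi = bounds[name]
        out[name] = float(np.clip(val, lo, hi))
    return out


def fit_observer(
    trials: pd.DataFrame,
    spec: FitSpec,
    dists: DistributionSet,
    seed: int | None = 0,
    config: ExperimentConfig | None = None,
) -> FitResult:
    """Minimise the model-vs-data MSE over the FitSpec's free parameters."""
    observed = _observed_table(trials, spec.design)
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2**31))
    names = spec.parameter_names
    evaluations = 0

    def objective(x):
        nonlocal evaluations
        evaluations += 1
        params = _from_vector(x, names, spec.bounds)
        model = _model_proportions(spec.design, params, dists, spec, crn_seed, config)
        return mse_objective(observed, model, spec.design)

    starts = []
    best = None
    for start in range(spec.n_starts):
        x0 = _to_vector(spec.initial, names)
        if start > 0:
            x0 = x0 + rng.normal(0.0, 0.5, size=len(x0))
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={
                "maxfev": spec.max_evaluations,
                "xatol": 0.02,
                "fatol": 1e-5,
            },
        )
        starts.append({"x0": list(x0), "objective": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    params = _from_vector(best.x, names, spec.bounds)
    model = _model_proportions(spec.design, params, dists, spec, crn_seed, config)
    return FitResult(
        parameters=params,
        objective=float(best.fun),
        n_evaluations=evaluations,
        converged=bool(best.success),
        model_proportions=model,
        starts=starts,
    )


def parameter_recovery(
    design: str,
    true_params: dict[str, float],
    dists: DistributionSet,
    n_repeats: int = 3,
    trials_per_level: int = 200,
    seed: int | None = 0,
    spec: FitSpec | None = None,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Generate data at known parameters and re-fit; one row per repeat/parameter."""
    spec = spec or FitSpec(design=design)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        noise = NoiseModel(true_params["n_disparity"], true_params["n_size"])
        conflict_params = None
        if design == "exp2" and spec.observer == "cooccurrence":
            conflict_params = ConflictModelParams(
                noise=noise,
                t_inhibitory=true_params.get("t_inhibitory", 1.5e-5),
                t_conflict=true_params.get("t_conflict", 0.15),
            )
        data = simulate_experiment(
            design, dists, noise,
            trials_per_level=trials_per_level,
            seed=int(rng.integers(2**31)),
            config=config,
            observer=spec.observer,
            conflict_params=conflict_params,
        )
        fit = fit_observer(data, spec, dists, seed=int(rng.integers(2**31)), config=config)
        for name in spec.parameter_names:
            rows.append(
                dict(
                    repeat=rep,
                    parameter=name,
                    true=true_params[name],
                    recovered=fit.parameters[name],
                    error=fit.parameters[name] - true_params[name],
                    objective=fit.objective,
                )
            )
    return pd.DataFrame(rows)
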