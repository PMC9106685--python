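"""Psychometric fitting and derived analyses.

Cumulative-Gaussian fits (binomial maximum likelihood) give the PSE and JND
for the speed task and 75%-correct thresholds for the conflict task; the
implied-uncertainty algebra converts PSEs and combined-cue JNDs into
single-cue variances under standard linear integration, and threshold-level
conflicts are re-expressed as equivalent physical size ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from . import geometry
from .geometry import ConflictSpec
from .observers import ExperimentConfig, make_stimulus

__all__ = [
    "PsychometricDataset",
    "PsychometricFit",
    "ImpliedUncertainty",
    "EquivalentSizeResult",
    "fit_cumulative_gaussian",
    "fit_scaled_cumulative_gaussian",
    "implied_uncertainties",
    "predict_combined",
    "constant_cd_prediction",
    "equivalent_size_ratios",
    "dataset_from_trials",
]


@dataclass(frozen=True)
class PsychometricDataset:
    """Success counts per stimulus level for one condition."""

    levels: np.ndarray
    n_trials: np.ndarray
    n_success: np.ndarray

    def __post_init__(self) -> None:
        L, n, k = map(np.asarray, (self.levels, self.n_trials, self.n_success))
        if not (len(L) == len(n) == len(k)):
            raise ValueError("levels, n_trials and n_success must align")
        if len(np.unique(L)) < 2:
            raise ValueError("need at least 2 distinct levels")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("0 <= n_success <= n_trials violated")

    @property
    def proportions(self) -> np.ndarray:
        return self.n_success / self.n_trials


@dataclass(frozen=True)
class PsychometricFit:
    mu: float
    sigma: float
    log_likelihood: float
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def pse(self) -> float:
        return self.mu

    @property
    def jnd(self) -> float:
        """JND = sigma, the 84% point relative to the PSE."""
        return self.sigma


def _binomial_nll(levels, n, k, mu, sigma, floor):
    p = floor + (1.0 - floor) * norm.cdf((levels - mu) / sigma)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))


def _fit(data: PsychometricDataset, floor: float) -> PsychometricFit:
    levels = np.asarray(data.levels, dtype=float)
    n = np.asarray(data.n_trials, dtype=float)
    k = np.asarray(data.n_success, dtype=float)
    span = levels.max() - levels.min()
    # probit-regression initialisation on the proportions
    p0 = np.clip((k + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)
    z = norm.ppf(np.clip((p0 - floor) / (1.0 - floor), 1e-4, 1 - 1e-4))
    slope = np.polyfit(levels, z, 1)
    sigma0 = 1.0 / abs(slope[0]) if slope[0] != 0 else span
    mu0 = -slope[1] * sigma0 * np.sign(slope[0]) if slope[0] != 0 else levels.mean()
    sigma0 = float(np.clip(sigma0, span / 100.0, span * 10.0))

    def objective(theta):
        return _binomial_nll(levels, n, k, theta[0], np.exp(theta[1]), floor)

    best = None
    for mu_init in (mu0, levels.mean()):
        res = minimize(
            objective, x0=[mu_init, np.log(sigma0)], method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], float(np.exp(best.x[1]))
    flags = []
    props = data.proportions
    if floor == 0.0 and (np.all(props >= 0.5) or np.all(props <= 0.5)):
        flags.append("no-transition")
    if not best.success:
        flags.append("non-convergence")
    if not levels.min() <= mu <= levels.max():
        flags.append("pse-outside-range")
    return PsychometricFit(
        mu=float(mu),
        sigma=sigma,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        flags=tuple(flags),
    )


def fit_cumulative_gaussian(data: PsychometricDataset) -> PsychometricFit:
    """Binomial ML fit of ``Phi((x - mu) / sigma)``; mu is the PSE, sigma the JND."""
    return _fit(data, floor=0.0)


def fit_scaled_cumulative_gaussian(data: PsychometricDataset) -> PsychometricFit:
    """Fit ``0.5 + 0.5 * Phi((x - mu) / sigma)`` to proportion-correct data.

    The returned ``mu`` is where the curve crosses 75% correct — the
    threshold.  If performance never rises credibly above chance the fit is
    flagged ``unmeasurable``.
    """
    fit = _fit(data, floor=0.5)
    flags = list(fit.flags)
    props = data.proportions
    n = np.asarray(data.n_trials)
    # binomial check that at least one level clears chance
    se = np.sqrt(0.25 / n)
    if not np.any(props > 0.5 + 2 * se):
        flags.append("unmeasurable")
    if np.all(props >= 0.75):
        flags.append("threshold-below-range")
    return PsychometricFit(
        mu=fit.mu,
        sigma=fit.sigma,
        log_likelihood=fit.log_likelihood,
        converged=fit.converged,
        flags=tuple(dict.fromkeys(flags)),
    )


@dataclass(frozen=True)
class ImpliedUncertainty:
    """Single-cue variances implied by a combined-cue PSE and JND."""

    w_cd: float
    w_cs: float
    sigma2_cd: float
    sigma2_cs: float
    sigma2_combined: float
    flags: tuple[str, ...] = ()


def implied_uncertainties(
    pse: float, s: float, d: float, sigma2_combined: float
) -> ImpliedUncertainty:
    """Invert the standard linear-integration relations.

    ``w_cd = (pse - s) / (d - s)`` with ``s``/``d`` the CS/CD speeds in the
    conflict stimulus; the implied variances follow from
    ``sigma2_cd = (w_cs / w_cd + 1) * sigma2_combined`` and
    ``sigma2_cs = sigma2_cd * w_cd / w_cs``.  Recombining the outputs
    through the reliability-sum rule returns ``sigma2_combined`` exactly.
    """
    if s == d:
        raise ValueError("cue speeds s and d must differ")
    if sigma2_combined <= 0:
        raise ValueError("sigma2_combined must be positive")
    w_cd = (pse - s) / (d - s)
    w_cs = 1.0 - w_cd
    flags = []
    if not (0.0 < w_cd < 1.0):
        # implied linear-integration model violated; values returned for inspection
        flags.append("weights-outside-unit-interval")
    with np.errstate(divide="ignore"):
        # (w_cs/w_cd) * s2 + s2 == s2 / w_cd since the weights sum to one
        sigma2_cd = (w_cs / w_cd) * sigma2_combined + sigma2_combined
        sigma2_cs = sigma2_cd * (w_cd / w_cs)
    return ImpliedUncertainty(
        w_cd, w_cs, float(sigma2_cd), float(sigma2_cs), sigma2_combined, tuple(flags)
    )


def predict_combined(sigma2_cd: float, sigma2_cs: float) -> tuple[float, float]:
    """Forward linear-integration model: (w_cd, combined variance).

    The weight on CD is the CS-to-CD variance ratio normalised
    (``w_cd / w_cs = sigma2_cs / sigma2_cd``) and the combined variance is
    the product-over-sum of the single-cue variances.
    """
    w_cd = sigma2_cs / (sigma2_cd + sigma2_cs)
    sigma2_comb = sigma2_cd * sigma2_cs / (sigma2_cd + sigma2_cs)
    return float(w_cd), float(sigma2_comb)


def constant_cd_prediction(
    pses: np.ndarray, s: float, d: float, sigma2_cd_reference: float
) -> np.ndarray:
    """Implied CS variance per condition if CD uncertainty were constant.

    Uses each condition's PSE-derived weight ratio with a fixed reference CD
    variance (the smallest-surface value): ``sigma2_cs = sigma2_cd_ref * w_cd / w_cs``.
    """
    pses = np.asarray(pses, dtype=float)
    w_cd = (pses - s) / (d - s)
    w_cs = 1.0 - w_cd
    with np.errstate(divide="ignore", invalid="ignore"):
        return sigma2_cd_reference * w_cd / w_cs


@dataclass(frozen=True)
class EquivalentSizeResult:
    """Mean (over simulations) of the per-motion max |log2 size ratio|."""

    conflict_type: str
    threshold: float
    mean_max_log2_ratio: float
    per_simulation: np.ndarray = field(repr=False)


def equivalent_size_ratios(
    threshold: float,
    conflict_type: str,
    n_sims: int = 1000,
    config: ExperimentConfig | None = None,
    seed: int | None = None,
) -> EquivalentSizeResult:
    """Equivalent physical size change for threshold-level conflicts.

    Per simulated motion (with the experiment's amplitude, size and duration
    jitters), the conflicting surface size ``s_cd`` is computed per display
    frame from the CD-defined position and the CS-defined image size; the
    motion is summarised by ``max |log2(s_cd / s_cs)|`` across frames and
    the result is the mean over simulations.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(seed)
    v = config.geometry.viewing_distance
    # thresholds are conflict magnitudes; frequency conflicts slow the CS
    # waveform, so their signed level is the negated magnitude
    level = -threshold if conflict_type == "frequency" else threshold
    values = np.empty(n_sims)
    for i in range(n_sims):
        amp = config.amplitude + rng.uniform(-config.amplitude_jitter, config.amplitude_jitter)
        size = config.exp2_surface_size + rng.uniform(-config.size_jitter, config.size_jitter)
        dur = config.duration + rng.uniform(-config.duration_jitter, config.duration_jitter)
        stim = make_stimulus(
            config, size, amp, dur,
            conflict=ConflictSpec(conflict_type, level), target_cue="cs",
        )
        m_cd = stim.cd_trajectory.distance_moved
        m_cs = stim.cs_trajectory.distance_moved
        s_cd = geometry.equivalent_surface_size(v, m_cd, m_cs, size)
        values[i] = np.max(np.abs(np.log2(s_cd / size)))
    return EquivalentSizeResult(
        conflict_type=conflict_type,
        threshold=threshold,
        mean_max_log2_ratio=float(values.mean()),
        per_simulation=values,
    )


def dataset_from_trials(
    trials: pd.DataFrame,
    level_column: str,
    response_column: str,
) -> PsychometricDataset:
    """Aggregate a trial table into per-level success counts."""
    g = trials.groupby(level_column)[response_column].agg(["count", "sum"])
    return PsychometricDataset(
        levels=g.index.to_numpy(dtype=float),
        n_trials=g["count"].to_numpy(),
        n_success=g["sum"].to_numpy(dtype=float),
    )
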