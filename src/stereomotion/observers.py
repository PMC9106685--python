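"""Model observers for the two 2IFC tasks.

Experiment 1: a speed-in-depth discrimination observer that compares
stochastic perceived-speed draws between a consistent-cue interval and an
amplitude-conflict interval.

Experiment 2: four conflict detectors — per-segment inter-cue differences in
estimated distance moved (max or sd), two surface-size-estimate variants,
and the cue co-occurrence detector with its inhibitory-flag thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels, geometry
from .cue_integration import (
    NoiseModel,
    SegmentSamples,
    estimate_segments,
    estimate_speed,
    sample_segments,
)
from .geometry import ConflictSpec, CueStimulus, Trajectory, ViewingGeometry
from .image_statistics import (
    CooccurrenceTable,
    DistributionSet,
    SceneGrid,
    SignalGrid,
    SimulationRanges,
    build_distributions,
    simulate_motions,
)

__all__ = [
    "ConflictModelParams",
    "ExperimentConfig",
    "EXP1_SPEED_LEVELS",
    "EXP2_LEVELS",
    "build_observer_distributions",
    "make_stimulus",
    "exp1_stimulus_pair",
    "exp2_stimulus_pair",
    "speed_2ifc_choice",
    "conflict_variant_m_difference",
    "conflict_variant_size_estimates",
    "cooccurrence_probability",
    "cooccurrence_probabilities",
    "cooccurrence_conflict_decision",
    "simulate_experiment",
]


@dataclass(frozen=True)
class ConflictModelParams:
    """Free parameters of the cue co-occurrence conflict detector."""

    noise: NoiseModel
    t_inhibitory: float = 1.5e-5
    t_conflict: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.t_inhibitory < 1.0:
            raise ValueError("t_inhibitory must lie in (0, 1)")
        if not 0.0 < self.t_conflict < 1.0:
            raise ValueError("t_conflict must lie in (0, 1)")


#: 7 equally spaced consistent-interval speed ratios, log2 units.
EXP1_SPEED_LEVELS = tuple(round(x, 10) for x in np.linspace(-1.2, 1.2, 7))

#: 7 equally spaced conflict levels per type (log2 units; log2 units; radians).
EXP2_LEVELS = {
    "amplitude": tuple(round(x, 10) for x in np.linspace(-1.0, 1.0, 7)),
    "frequency": tuple(round(x, 10) for x in np.linspace(-2.0, 0.0, 7)),
    "phase": tuple(float(x) for x in np.linspace(0.0, np.pi, 7)),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Stimulus and randomisation parameters shared by both experiment designs."""

    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)
    amplitude: float = 80.0
    duration: float = 1.5
    frame_rate: float = 60.0
    surface_sizes: tuple[float, ...] = (10.0, 40.0, 60.0)
    exp2_surface_size: float = 40.0
    exp1_conflict: float = 0.32
    amplitude_jitter: float = 20.0
    size_jitter: float = 10.0
    duration_jitter: float = 0.067
    stride_frames: int = 5
    #: Exp. 2 only: the consistent interval reuses the conflict interval's
    #: jittered base parameters, isolating the manipulated conflict.
    shared_interval_base: bool = True


def build_observer_distributions(
    n: int = 1_000_000,
    seed: int | None = 0,
    cd_width: float = 0.2,
    cs_width: float = 0.004,
    n_v: int = 38,
    n_m: int = 50,
    ranges: SimulationRanges | None = None,
) -> DistributionSet:
    """Distribution set at a resolution sized for the trial-level observers.

    The observer models evaluate thousands of weighted posteriors per
    psychometric function, so they run on a coarser (configurable) grid than
    the scene-recovery analyses.
    """
    ranges = ranges or SimulationRanges()
    samples = simulate_motions(n, ranges, seed)
    signal_grid = SignalGrid.from_samples(samples, cd_width=cd_width, cs_width=cs_width)
    scene_grid = SceneGrid.regular(ranges, n_v=n_v, n_m=n_m)
    return build_distributions(
        n=n, seed=seed, ranges=ranges, signal_grid=signal_grid, scene_grid=scene_grid
    )


def make_stimulus(
    config: ExperimentConfig,
    surface_size: float,
    amplitude: float,
    duration: float,
    conflict: ConflictSpec | None = None,
    target_cue: str = "cs",
) -> CueStimulus:
    """Build a (possibly conflicting) triangular-wave stimulus."""
    base = geometry.triangular_trajectory(amplitude, duration, config.frame_rate)
    if conflict is None:
        cd_traj, cs_traj = base, base
    else:
        cd_traj, cs_traj = geometry.apply_conflict(base, conflict, target_cue, amplitude)
    return CueStimulus(cd_traj, cs_traj, surface_size, config.geometry)


def _jitter(rng: np.random.Generator, base: float, half_range: float) -> float:
    return base + rng.uniform(-half_range, half_range)


def exp1_stimulus_pair(
    config: ExperimentConfig,
    surface_size: float,
    speed_level: float,
    conflict_direction: int,
    rng: np.random.Generator,
) -> tuple[CueStimulus, CueStimulus]:
    """(consistent, conflict) stimuli for one Experiment 1 trial.

    The conflict interval carries the counterbalanced amplitude conflict
    (CS scaled by ``2**(direction * level)``, CD by the inverse); the
    consistent interval's amplitude is scaled by ``2**speed_level``.  Each
    interval draws its own amplitude and duration jitter.
    """
    if conflict_direction not in (-1, 1):
        raise ValueError("conflict_direction must be +1 or -1")
    amp_con = _jitter(rng, config.amplitude, config.amplitude_jitter)
    dur_con = _jitter(rng, config.duration, config.duration_jitter)
    consistent = make_stimulus(
        config, surface_size, amp_con * 2.0**speed_level, dur_con
    )
    amp_cfl = _jitter(rng, config.amplitude, config.amplitude_jitter)
    dur_cfl = _jitter(rng, config.duration, config.duration_jitter)
    spec = ConflictSpec("amplitude", conflict_direction * config.exp1_conflict)
    conflict = make_stimulus(
        config, surface_size, amp_cfl, dur_cfl, conflict=spec, target_cue="both"
    )
    return consistent, conflict


def exp2_stimulus_pair(
    config: ExperimentConfig,
    conflict_type: str,
    level: float,
    rng: np.random.Generator,
) -> tuple[CueStimulus, CueStimulus]:
    """(consistent, conflict) stimuli for one Experiment 2 trial.

    The conflict manipulation is applied to the CS cue only.  Amplitude,
    surface size and duration are jittered; with ``shared_interval_base``
    the consistent interval reuses the conflict interval's jittered values.
    """
    def draw():
        return (
            _jitter(rng, config.amplitude, config.amplitude_jitter),
            _jitter(rng, config.exp2_surface_size, config.size_jitter),
            _jitter(rng, config.duration, config.duration_jitter),
        )

    amp, size, dur = draw()
    conflict = make_stimulus(
        config, size, amp, dur, conflict=ConflictSpec(conflict_type, level), target_cue="cs"
    )
    if not config.shared_interval_base:
        amp, size, dur = draw()
    consistent = make_stimulus(config, size, amp, dur)
    return consistent, conflict


def _choose_larger(a: float, b: float, rng: np.random.Generator) -> int:
    """Index (0/1) of the larger value; exact ties broken by fair coin."""
    if np.isnan(a) and np.isnan(b):
        return int(rng.integers(2))
    if np.isnan(a):
        return 1
    if np.isnan(b):
        return 0
    if a == b:
        return int(rng.integers(2))
    return 0 if a > b else 1


def speed_2ifc_choice(
    stimulus_a: CueStimulus,
    stimulus_b: CueStimulus,
    noise: NoiseModel,
    dists: DistributionSet,
    rng: np.random.Generator,
    stride_frames: int = 5,
) -> int:
    """Interval (0/1) judged to contain the faster motion-in-depth."""
    sa = estimate_speed(stimulus_a, noise, dists, rng, stride_frames)
    sb = estimate_speed(stimulus_b, noise, dists, rng, stride_frames)
    return _choose_larger(sa, sb, rng)


def _interval_m_difference(
    stimulus: CueStimulus,
    noise: NoiseModel,
    dists: DistributionSet,
    statistic: str,
    rng: np.random.Generator,
    stride_frames: int,
) -> float:
    est = estimate_segments(sample_segments(stimulus, stride_frames), noise, dists, rng)
    diff = np.abs(est.m_cs - est.m_cd)
    diff = diff[np.isfinite(diff)]
    if len(diff) == 0:
        return np.nan
    return float(np.max(diff)) if statistic == "max" else float(np.std(diff))


def conflict_variant_m_difference(
    stimulus_a: CueStimulus,
    stimulus_b: CueStimulus,
    noise: NoiseModel,
    dists: DistributionSet,
    rng: np.random.Generator,
    statistic: str = "max",
    stride_frames: int = 5,
) -> int:
    """Interval with the larger per-segment |m_cs - m_cd| statistic."""
    if statistic not in ("max", "sd"):
        raise ValueError("statistic must be 'max' or 'sd'")
    da = _interval_m_difference(stimulus_a, noise, dists, statistic, rng, stride_frames)
    db = _interval_m_difference(stimulus_b, noise, dists, statistic, rng, stride_frames)
    return _choose_larger(da, db, rng)


def _interval_size_statistic(
    stimulus: CueStimulus,
    noise: NoiseModel,
    dists: DistributionSet,
    mode: str,
    rng: np.random.Generator,
    stride_frames: int,
) -> float:
    samples = sample_segments(stimulus, stride_frames)
    est = estimate_segments(samples, noise, dists, rng)
    # measured image size at the segment end, with its own measurement noise
    alpha = samples.size_end + rng.normal(0.0, noise.n_size, samples.n_segments)
    if mode == "per_cue_difference":
        s_cd = geometry.size_from_angle(alpha, np.maximum(est.v_cd - est.m_cd, 1.0))
        s_cs = geometry.size_from_angle(alpha, np.maximum(est.v_cs - est.m_cs, 1.0))
        diff = np.abs(s_cd - s_cs)
        diff = diff[np.isfinite(diff)]
        return float(np.mean(diff)) if len(diff) else np.nan
    sizes = geometry.size_from_angle(
        alpha, np.maximum(est.v_combined - est.m_combined, 1.0)
    )
    sizes = sizes[np.isfinite(sizes)]
    return float(np.std(sizes)) if len(sizes) else np.nan


def conflict_variant_size_estimates(
    stimulus_a: CueStimulus,
    stimulus_b: CueStimulus,
    noise: NoiseModel,
    dists: DistributionSet,
    rng: np.random.Generator,
    mode: str = "per_cue_difference",
    stride_frames: int = 5,
) -> int:
    """Interval with the larger surface-size-estimate conflict statistic.

    ``per_cue_difference`` recovers a size per cue from that cue's (v, m)
    estimate and the measured image size; ``combined_sd`` takes the standard
    deviation of sizes recovered from the combined-cue estimates.
    """
    if mode not in ("per_cue_difference", "combined_sd"):
        raise ValueError("mode must be 'per_cue_difference' or 'combined_sd'")
    da = _interval_size_statistic(stimulus_a, noise, dists, mode, rng, stride_frames)
    db = _interval_size_statistic(stimulus_b, noise, dists, mode, rng, stride_frames)
    return _choose_larger(da, db, rng)


def cooccurrence_probability(
    disp_start: float,
    disp_end: float,
    size_start: float,
    size_end: float,
    noise: NoiseModel,
    co_table: CooccurrenceTable,
) -> float:
    """Expected co-occurrence mass for one segment's measurements.

    ``sum_ij L_cs(i) L_cd(j) p(CS ∩ CD)[i, j]``, where the L terms are the
    measurement distributions over signal bins.  Mass falling outside the
    simulated signal range contributes zero (no renormalisation): such
    signal values never co-occur in rigid-motion scenes.
    """
    out = np.empty(1)
    _kernels._cooccurrence_probabilities(
        np.array([float(disp_start)]),
        np.array([float(disp_end)]),
        np.array([float(size_start)]),
        np.array([float(size_end)]),
        np.sqrt(2.0) * noise.n_disparity,
        noise.n_size,
        co_table.signal_grid.cd_edges,
        co_table.signal_grid.cs_edges,
        co_table.table,
        out,
    )
    return float(out[0])


def cooccurrence_probabilities(
    samples: SegmentSamples,
    noise: NoiseModel,
    co_table: CooccurrenceTable,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-segment co-occurrence probabilities with fresh measurement noise."""
    n = samples.n_segments
    d0 = samples.disp_start + rng.normal(0.0, noise.n_disparity, n)
    d1 = samples.disp_end + rng.normal(0.0, noise.n_disparity, n)
    s0 = samples.size_start + rng.normal(0.0, noise.n_size, n)
    s1 = samples.size_end + rng.normal(0.0, noise.n_size, n)
    out = np.empty(n)
    _kernels._cooccurrence_probabilities(
        d0, d1, s0, s1,
        np.sqrt(2.0) * noise.n_disparity, noise.n_size,
        co_table.signal_grid.cd_edges, co_table.signal_grid.cs_edges,
        co_table.table, out,
    )
    return out


def _interval_in_conflict(
    stimulus: CueStimulus,
    params: ConflictModelParams,
    co_table: CooccurrenceTable,
    rng: np.random.Generator,
    stride_frames: int,
) -> bool:
    samples = sample_segments(stimulus, stride_frames)
    p = cooccurrence_probabilities(samples, params.noise, co_table, rng)
    inhibitory = p < params.t_inhibitory
    return float(np.mean(inhibitory)) > params.t_conflict


def cooccurrence_conflict_decision(
    stimulus_a: CueStimulus,
    stimulus_b: CueStimulus,
    params: ConflictModelParams,
    co_table: CooccurrenceTable,
    rng: np.random.Generator,
    stride_frames: int = 5,
) -> int:
    """Interval (0/1) judged to contain the cue conflict.

    Each interval receives a discrete conflict/no-conflict judgement (the
    proportion of sub-threshold co-occurrence segments compared against
    ``t_conflict``); if both or neither is flagged the choice is an unbiased
    guess.
    """
    fa = _interval_in_conflict(stimulus_a, params, co_table, rng, stride_frames)
    fb = _interval_in_conflict(stimulus_b, params, co_table, rng, stride_frames)
    if fa == fb:
        return int(rng.integers(2))
    return 0 if fa else 1


_EXP2_OBSERVERS = {
    "cooccurrence",
    "m_difference_max",
    "m_difference_sd",
    "size_per_cue",
    "size_combined_sd",
}


def simulate_experiment(
    design: str,
    dists: DistributionSet,
    noise: NoiseModel,
    trials_per_level: int = 30,
    seed: int | None = None,
    config: ExperimentConfig | None = None,
    observer: str = "cooccurrence",
    conflict_params: ConflictModelParams | None = None,
    conflict_types: tuple[str, ...] = ("amplitude", "frequency", "phase"),
) -> pd.DataFrame:
    """Full factorial model-observer trial table for one experiment.

    ``design='exp1'`` crosses surface sizes with the 7 speed-ratio levels and
    records whether the consistent interval was judged faster; ``'exp2'``
    crosses conflict types with their 7 levels and records whether the
    conflict interval was chosen.  Interval order is randomised per trial.
    """
    config = config or ExperimentConfig()
    # One spawned seed per trial: a trial's randomness is independent of how
    # much randomness other trials consumed, so re-simulations at different
    # observer parameters share their random numbers trial-for-trial.
    seq = np.random.SeedSequence(seed)

    def trial_rng():
        return np.random.default_rng(seq.spawn(1)[0])

    rows = []
    if design == "exp1":
        for size in config.surface_sizes:
            for level in EXP1_SPEED_LEVELS:
                for t in range(trials_per_level):
                    rng = trial_rng()
                    direction = 1 if rng.random() < 0.5 else -1
                    consistent, conflict = exp1_stimulus_pair(
                        config, size, level, direction, rng
                    )
                    order = int(rng.integers(2))  # 0: consistent first
                    pair = (consistent, conflict) if order == 0 else (conflict, consistent)
                    choice = speed_2ifc_choice(
                        pair[0], pair[1], noise, dists, rng, config.stride_frames
                    )
                    chose_consistent = (choice == 0) == (order == 0)
                    # Normalisation for conflict direction: mirror both the
                    # level axis and the response for direction -1 trials, so
                    # the pooled function rises toward the CS cue's side.
                    rows.append(
                        dict(
                            experiment="exp1",
                            surface_size=size,
                            level=level,
                            norm_level=round(direction * level, 10) + 0.0,
                            conflict_direction=direction,
                            interval_order=order,
                            chosen_interval=choice + 1,
                            chose_consistent=chose_consistent,
                            norm_response=(
                                chose_consistent if direction == 1 else not chose_consistent
                            ),
                        )
                    )
    elif design == "exp2":
        if observer not in _EXP2_OBSERVERS:
            raise ValueError(f"unknown exp2 observer {observer!r}")
        if observer == "cooccurrence" and conflict_params is None:
            conflict_params = ConflictModelParams(noise=noise)
        for ctype in conflict_types:
            for level in EXP2_LEVELS[ctype]:
                for t in range(trials_per_level):
                    rng = trial_rng()
                    consistent, conflict = exp2_stimulus_pair(config, ctype, level, rng)
                    order = int(rng.integers(2))  # 0: consistent first
                    pair = (consistent, conflict) if order == 0 else (conflict, consistent)
                    if observer == "cooccurrence":
                        choice = cooccurrence_conflict_decision(
                            pair[0], pair[1], conflict_params, dists.cooccurrence,
                            rng, config.stride_frames,
                        )
                    elif observer.startswith("m_difference"):
                        choice = conflict_variant_m_difference(
                            pair[0], pair[1], noise, dists, rng,
                            statistic=observer.rsplit("_", 1)[1],
                            stride_frames=config.stride_frames,
                        )
                    else:
                        mode = (
                            "per_cue_difference"
                            if observer == "size_per_cue"
                            else "combined_sd"
                        )
                        choice = conflict_variant_size_estimates(
                            pair[0], pair[1], noise, dists, rng,
                            mode=mode, stride_frames=config.stride_frames,
                        )
                    chose_conflict = (choice == 1) == (order == 0)
                    rows.append(
                        dict(
                            experiment="exp2",
                            conflict_type=ctype,
                            level=level,
                            magnitude=abs(level),
                            interval_order=order,
                            chosen_interval=choice + 1,
                            correct=chose_conflict,
                        )
                    )
    else:
        raise ValueError("design must be 'exp1' or 'exp2'")
    return pd.DataFrame(rows)
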