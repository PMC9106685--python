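"""Closed-form imaging geometry for motion along the line of sight.

All distances are in millimetres, all angles in arcminutes externally
(radians internally).  The sign convention throughout: the distance moved
``m`` is positive toward the observer, so an approach produces a negative
(crossed) change in disparity and an image-size ratio greater than one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ARCMIN_PER_RAD",
    "DEFAULT_INTEROCULAR_MM",
    "ViewingGeometry",
    "Trajectory",
    "CueStimulus",
    "ConflictSpec",
    "binocular_disparity",
    "cd_signal",
    "angular_size",
    "pixel_angular_size",
    "size_from_angle",
    "cs_signal",
    "triangular_wave",
    "triangular_trajectory",
    "apply_conflict",
    "equivalent_surface_size",
]

ARCMIN_PER_RAD = 60.0 * 180.0 / np.pi

#: Interocular separation default, mm (standard adult mean; configurable).
DEFAULT_INTEROCULAR_MM = 65.0


@dataclass(frozen=True)
class ViewingGeometry:
    """Interocular separation and viewing distance defining the imaging equations."""

    interocular_separation: float = DEFAULT_INTEROCULAR_MM
    viewing_distance: float = 764.0

    def __post_init__(self) -> None:
        if self.interocular_separation <= 0:
            raise ValueError("interocular_separation must be positive")
        if self.viewing_distance <= 0:
            raise ValueError("viewing_distance must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Sampled depth trajectory.

    ``distance_moved`` holds positions relative to the fixation plane
    (positive toward the observer) sampled at ``frame_times``; both endpoints
    of each displayed frame interval are included, so the arrays have
    ``n_frames + 1`` entries and span ``[0, duration]`` inclusive.
    """

    frame_times: np.ndarray
    distance_moved: np.ndarray
    frame_rate: float
    duration: float
    #: generating waveform amplitude, if known (sampled maxima undershoot it
    #: when a peak falls between frames)
    amplitude: float | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frame_times) - 1

    def __post_init__(self) -> None:
        if len(self.frame_times) != len(self.distance_moved):
            raise ValueError("frame_times and distance_moved must align")
        if self.n_frames != round(self.duration * self.frame_rate):
            raise ValueError("frame count must equal round(duration * frame_rate)")


@dataclass(frozen=True)
class CueStimulus:
    """A stimulus carrying (possibly conflicting) depth waveforms per cue."""

    cd_trajectory: Trajectory
    cs_trajectory: Trajectory
    surface_size: float
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)

    def __post_init__(self) -> None:
        a, b = self.cd_trajectory, self.cs_trajectory
        if a.frame_rate != b.frame_rate or a.duration != b.duration:
            raise ValueError("cue trajectories must share frame_rate and duration")
        if self.surface_size <= 0:
            raise ValueError("surface_size must be positive")
        v = self.geometry.viewing_distance
        if np.any(v - a.distance_moved <= 0) or np.any(v - b.distance_moved <= 0):
            raise ValueError("trajectory passes behind the observer (v - m <= 0)")


ConflictType = Literal["amplitude", "frequency", "phase"]


@dataclass(frozen=True)
class ConflictSpec:
    """One cue-conflict manipulation.

    ``level`` is in log2 units for amplitude and frequency conflicts and in
    radians for phase conflicts.
    """

    conflict_type: ConflictType
    level: float

    def __post_init__(self) -> None:
        if self.conflict_type not in ("amplitude", "frequency", "phase"):
            raise ValueError(f"unknown conflict_type {self.conflict_type!r}")
        if self.conflict_type == "phase" and not 0.0 <= self.level <= np.pi:
            raise ValueError("phase level must lie in [0, pi]")


def _as_positive(name: str, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return x


def binocular_disparity(v, i: float = DEFAULT_INTEROCULAR_MM):
    """Vergence-defined disparity angle ``2*atan((i/2)/v)`` in arcmin.

    Strictly decreasing in viewing distance ``v`` (mm).
    """
    v = _as_positive("viewing distance v", v)
    i = _as_positive("interocular separation i", i)
    return 2.0 * np.arctan((i / 2.0) / v) * ARCMIN_PER_RAD


def cd_signal(v, m, i: float = DEFAULT_INTEROCULAR_MM):
    """Changing-disparity signal in arcmin.

    ``CD = 2*atan((i/2)/v) - 2*atan((i/2)/(v-m))``; negative values indicate
    a crossed (approaching) change.  Requires ``v - m > 0``.
    """
    v = _as_positive("viewing distance v", v)
    m = np.asarray(m, dtype=float)
    _as_positive("distance v - m", v - m)
    return binocular_disparity(v, i) - binocular_disparity(v - m, i)


def angular_size(s, v):
    """Full angular subtense ``2*atan((s/2)/v)`` in arcmin of extent ``s`` at distance ``v``."""
    s = _as_positive("surface size s", s)
    v = _as_positive("viewing distance v", v)
    return 2.0 * np.arctan((s / 2.0) / v) * ARCMIN_PER_RAD


def pixel_angular_size(display_width: float, n_pixels: int, v: float) -> float:
    """Angular subtense in arcmin of one pixel of a display at distance ``v`` (mm)."""
    pitch = _as_positive("display width", display_width) / n_pixels
    return float(np.arctan(pitch / _as_positive("viewing distance v", v)) * ARCMIN_PER_RAD)


def size_from_angle(angle_arcmin, v):
    """Physical extent subtending ``angle_arcmin`` at distance ``v`` (inverse of angular_size)."""
    v = _as_positive("viewing distance v", v)
    angle = np.asarray(angle_arcmin, dtype=float) / ARCMIN_PER_RAD
    return 2.0 * v * np.tan(angle / 2.0)


def cs_signal(v, m, s):
    """Changing-size signal: ratio of angular sizes after/before the motion.

    ``CS = 2*atan((s/2)/(v-m)) / 2*atan((s/2)/v)``; ratios above one indicate
    an increase in image size (approach).  Requires ``v - m > 0``.
    """
    v = _as_positive("viewing distance v", v)
    m = np.asarray(m, dtype=float)
    _as_positive("distance v - m", v - m)
    return angular_size(s, v - m) / angular_size(s, v)


def triangular_wave(phase):
    """Unit triangular waveform on cycle phase: 0 -> +1 -> -1 -> 0.

    ``phase`` is in cycles; the waveform has period 1, peaks +1 at 0.25 and
    -1 at 0.75, and zero mean.
    """
    p = np.mod(np.asarray(phase, dtype=float), 1.0)
    return np.where(p <= 0.25, 4.0 * p, np.where(p <= 0.75, 2.0 - 4.0 * p, 4.0 * p - 4.0))


def sample_waveform(
    amplitude: float,
    duration: float,
    frame_rate: float,
    freq_cycles: float = 1.0,
    phase: float = 0.0,
) -> Trajectory:
    """Sample ``amplitude * tri(freq * t/duration + phase/2pi)`` at the frame rate."""
    if amplitude < 0 or duration <= 0 or frame_rate <= 0:
        raise ValueError("amplitude must be >= 0; duration and frame_rate positive")
    n = round(duration * frame_rate)
    t = np.arange(n + 1) / frame_rate
    m = amplitude * triangular_wave(freq_cycles * t / duration + phase / (2.0 * np.pi))
    return Trajectory(
        frame_times=t,
        distance_moved=m,
        frame_rate=frame_rate,
        duration=duration,
        amplitude=amplitude,
    )


def triangular_trajectory(amplitude: float, duration: float, frame_rate: float) -> Trajectory:
    """One full triangular cycle in depth: 0 -> +A -> -A -> 0.

    Total path length is ``4 * amplitude`` and the speed-in-depth is constant
    at ``4 * amplitude / duration`` (80 mm over 1.5 s gives the 213 mm/s
    baseline).
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    return sample_waveform(amplitude, duration, frame_rate)


def apply_conflict(
    base: Trajectory,
    spec: ConflictSpec,
    target_cue: str = "cs",
    amplitude: float | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Build (cd_trajectory, cs_trajectory) with the given conflict applied.

    ``target_cue`` is ``"cs"`` (perturb CS only, CD keeps the base waveform),
    ``"cd"`` or ``"both"`` (counterbalanced: the perturbation is applied with
    opposite signs to CS and CD about the base, so the CS/CD ratio is twice
    the level while their geometric mean stays at the base).  Only amplitude
    conflicts support the counterbalanced split.
    """
    if target_cue not in ("cs", "cd", "both"):
        raise ValueError(f"unknown target_cue {target_cue!r}")
    if amplitude is None:
        amplitude = (
            base.amplitude
            if base.amplitude is not None
            else float(np.max(np.abs(base.distance_moved)))
        )
    dur, fr = base.duration, base.frame_rate

    def build(amp_scale=1.0, freq=1.0, ph=0.0):
        return sample_waveform(amplitude * amp_scale, dur, fr, freq_cycles=freq, phase=ph)

    kind, level = spec.conflict_type, spec.level
    if kind == "amplitude":
        if target_cue == "both":
            return build(2.0 ** -level), build(2.0 ** level)
        scaled = build(2.0 ** level)
        return (scaled, build()) if target_cue == "cd" else (build(), scaled)
    if target_cue == "both":
        raise ValueError("counterbalanced conflicts are defined for amplitude only")
    if kind == "frequency":
        perturbed = build(freq=2.0 ** level)
    else:  # phase
        perturbed = build(ph=level)
    return (perturbed, build()) if target_cue == "cd" else (build(), perturbed)


def equivalent_surface_size(v, m_cd, m_cs, s_cs):
    """Physical size at the CD-defined position matching the CS-defined image.

    ``s_cd = 2 * (v - m_cd) * tan(theta)`` with
    ``theta = atan((s_cs/2) / (v - m_cs))``.  When the two cues agree
    (``m_cd == m_cs``) this returns ``s_cs`` exactly.
    """
    v = _as_positive("viewing distance v", v)
    m_cd = np.asarray(m_cd, dtype=float)
    m_cs = np.asarray(m_cs, dtype=float)
    _as_positive("distance v - m_cd", v - m_cd)
    _as_positive("distance v - m_cs", v - m_cs)
    s_cs = _as_positive("surface size s_cs", s_cs)
    theta = np.arctan((s_cs / 2.0) / (v - m_cs))
    return 2.0 * (v - m_cd) * np.tan(theta)
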