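"""Monte Carlo image statistics for motion-in-depth.

Simulates linear motions of fronto-parallel surfaces over uniform ranges of
viewing distance, surface size and distance moved, and tabulates

* the binned joint posteriors ``p(v, m | CD)`` and ``p(v, m | CS)`` — one
  row-normalised (v, m) histogram per signal bin, and
* the co-occurrence distribution ``p(CS ∩ CD)`` over signal pairs,

then uses the tables to recover scene parameters for held-out motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import geometry
from .geometry import DEFAULT_INTEROCULAR_MM

__all__ = [
    "SimulationRanges",
    "SceneSampleSet",
    "SignalGrid",
    "SceneGrid",
    "PosteriorTable",
    "CooccurrenceTable",
    "DistributionSet",
    "simulate_motions",
    "build_posterior_tables",
    "build_cooccurrence",
    "build_distributions",
    "estimate_scene_noiseless",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SimulationRanges:
    """Uniform sampling ranges for the simulated linear motions (mm)."""

    v: tuple[float, float] = (500.0, 10000.0)
    s: tuple[float, float] = (2.0, 1000.0)
    m: tuple[float, float] = (-100.0, 100.0)
    interocular: float = DEFAULT_INTEROCULAR_MM

    def __post_init__(self) -> None:
        for name in ("v", "s", "m"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range {name} must be increasing")
        if self.v[0] - max(self.m[1], 0.0) <= 0:
            raise ValueError("motions may pass behind the observer")


@dataclass(frozen=True)
class SceneSampleSet:
    """Simulated motions with their noiseless CD and CS signals."""

    v: np.ndarray
    s: np.ndarray
    m: np.ndarray
    cd: np.ndarray
    cs: np.ndarray
    seed: int | None
    ranges: SimulationRanges = field(default_factory=SimulationRanges)

    @property
    def n(self) -> int:
        return len(self.v)


def simulate_motions(
    n: int, ranges: SimulationRanges | None = None, seed: int | None = None
) -> SceneSampleSet:
    """Draw ``n`` linear motions with independent uniform (v, s, m).

    Each motion is defined by its start (the fixation plane, at viewing
    distance ``v``) and end position only; CD and CS are the noiseless
    signals of that displacement.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or SimulationRanges()
    rng = np.random.default_rng(seed)
    v = rng.uniform(*ranges.v, size=n)
    s = rng.uniform(*ranges.s, size=n)
    m = rng.uniform(*ranges.m, size=n)
    cd = geometry.cd_signal(v, m, ranges.interocular)
    cs = geometry.cs_signal(v, m, s)
    return SceneSampleSet(v=v, s=s, m=m, cd=cd, cs=cs, seed=seed, ranges=ranges)


def _check_edges(name: str, edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError(f"{name} must be strictly increasing 1-D edges")
    return edges


@dataclass(frozen=True)
class SignalGrid:
    """Bin edges for the CD (arcmin) and CS (ratio) signal axes."""

    cd_edges: np.ndarray
    cs_edges: np.ndarray

    def __post_init__(self) -> None:
        _check_edges("cd_edges", self.cd_edges)
        _check_edges("cs_edges", self.cs_edges)

    @classmethod
    def from_samples(
        cls, samples: SceneSampleSet, cd_width: float = 0.1, cs_width: float = 0.002
    ) -> "SignalGrid":
        """Regular grid covering the empirical signal range of ``samples``."""

        def cover(x, w):
            lo = np.floor(x.min() / w) * w
            hi = np.ceil(x.max() / w) * w
            return np.arange(lo, hi + w / 2, w)

        return cls(cd_edges=cover(samples.cd, cd_width), cs_edges=cover(samples.cs, cs_width))

    def edges(self, cue: str) -> np.ndarray:
        return self.cd_edges if cue == "cd" else self.cs_edges


@dataclass(frozen=True)
class SceneGrid:
    """Bin edges for the (v, m) scene axes."""

    v_edges: np.ndarray
    m_edges: np.ndarray

    def __post_init__(self) -> None:
        _check_edges("v_edges", self.v_edges)
        _check_edges("m_edges", self.m_edges)

    @classmethod
    def regular(
        cls,
        ranges: SimulationRanges | None = None,
        n_v: int = 95,
        n_m: int = 100,
    ) -> "SceneGrid":
        ranges = ranges or SimulationRanges()
        return cls(
            v_edges=np.linspace(*ranges.v, n_v + 1),
            m_edges=np.linspace(*ranges.m, n_m + 1),
        )

    @property
    def v_centers(self) -> np.ndarray:
        return 0.5 * (self.v_edges[:-1] + self.v_edges[1:])

    @property
    def m_centers(self) -> np.ndarray:
        return 0.5 * (self.m_edges[:-1] + self.m_edges[1:])

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.v_edges) - 1, len(self.m_edges) - 1


def _bin_index(x: np.ndarray, edges: np.ndarray, what: str) -> np.ndarray:
    idx = np.searchsorted(edges, x, side="right") - 1
    # points exactly on the top edge belong to the last bin
    idx = np.where(x == edges[-1], len(edges) - 2, idx)
    if np.any(idx < 0) or np.any(idx > len(edges) - 2):
        raise ValueError(f"{what} values fall outside the grid")
    return idx


class PosteriorTable:
    """Binned joint posterior ``p(v, m | signal)`` for one cue.

    Stores raw histogram counts indexed ``(signal_bin, v_bin, m_bin)``; the
    conditional for a signal bin is its counts slice normalised to sum to
    one.  Signal bins with zero counts are unsupported.
    """

    def __init__(
        self,
        cue: Literal["cd", "cs"],
        signal_grid: SignalGrid,
        scene_grid: SceneGrid,
        counts: np.ndarray,
    ) -> None:
        if cue not in ("cd", "cs"):
            raise ValueError("cue must be 'cd' or 'cs'")
        n_sig = len(signal_grid.edges(cue)) - 1
        if counts.shape != (n_sig,) + scene_grid.shape:
            raise ValueError("counts shape does not match grids")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.cue = cue
        self.signal_grid = signal_grid
        self.scene_grid = scene_grid
        self.counts = counts
        self.row_totals = counts.reshape(n_sig, -1).sum(axis=1)
        self.supported = self.row_totals > 0
        self._cond_flat: np.ndarray | None = None
        # per-signal-bin marginal means (nan where unsupported)
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = self.row_totals.astype(float)
            self.mean_v = counts.sum(axis=2) @ scene_grid.v_centers / tot
            self.mean_m = counts.sum(axis=1) @ scene_grid.m_centers / tot

    @property
    def signal_edges(self) -> np.ndarray:
        return self.signal_grid.edges(self.cue)

    @property
    def n_signal_bins(self) -> int:
        return len(self.signal_edges) - 1

    def signal_bin(self, value) -> np.ndarray:
        return _bin_index(np.asarray(value, dtype=float), self.signal_edges, f"{self.cue} signal")

    def conditional(self, signal_bin: int) -> np.ndarray:
        """Normalised (v, m) distribution for one signal bin."""
        total = self.row_totals[signal_bin]
        if total == 0:
            raise ValueError(f"signal bin {signal_bin} is unsupported (no samples)")
        return self.counts[signal_bin].astype(float) / total

    def conditional_matrix(self, dtype=np.float32) -> np.ndarray:
        """All conditionals, flattened to ``(n_signal_bins, n_v * n_m)``.

        Unsupported rows are all-zero.  Cached; used by the fast observer
        kernels.
        """
        if self._cond_flat is None or self._cond_flat.dtype != dtype:
            flat = self.counts.reshape(self.n_signal_bins, -1).astype(dtype)
            tot = self.row_totals.astype(dtype)
            np.divide(flat, tot[:, None], out=flat, where=tot[:, None] > 0)
            self._cond_flat = flat
        return self._cond_flat


class CooccurrenceTable:
    """Normalised 2-D histogram ``p(CS ∩ CD)`` indexed ``(cs_bin, cd_bin)``."""

    def __init__(self, signal_grid: SignalGrid, counts: np.ndarray) -> None:
        n_cs = len(signal_grid.cs_edges) - 1
        n_cd = len(signal_grid.cd_edges) - 1
        if counts.shape != (n_cs, n_cd):
            raise ValueError("counts shape does not match signal grid")
        if np.any(counts < 0) or counts.sum() == 0:
            raise ValueError("counts must be non-negative with positive total")
        self.signal_grid = signal_grid
        self.counts = counts
        self.table = counts.astype(float) / counts.sum()


def build_posterior_tables(
    samples: SceneSampleSet,
    signal_grid: SignalGrid | None = None,
    scene_grid: SceneGrid | None = None,
) -> dict[str, PosteriorTable]:
    """Histogram ``(v, m)`` conditioned on each cue's signal bin."""
    signal_grid = signal_grid or SignalGrid.from_samples(samples)
    scene_grid = scene_grid or SceneGrid.regular(samples.ranges)
    iv = _bin_index(samples.v, scene_grid.v_edges, "v")
    im = _bin_index(samples.m, scene_grid.m_edges, "m")
    n_v, n_m = scene_grid.shape
    tables: dict[str, PosteriorTable] = {}
    for cue in ("cd", "cs"):
        edges = signal_grid.edges(cue)
        isig = _bin_index(getattr(samples, cue), edges, f"{cue} signal")
        n_sig = len(edges) - 1
        flat = np.ravel_multi_index((isig, iv, im), (n_sig, n_v, n_m))
        counts = np.bincount(flat, minlength=n_sig * n_v * n_m).reshape(n_sig, n_v, n_m)
        tables[cue] = PosteriorTable(cue, signal_grid, scene_grid, counts.astype(np.int64))
    return tables


def build_cooccurrence(
    samples: SceneSampleSet, signal_grid: SignalGrid | None = None
) -> CooccurrenceTable:
    """2-D normalised histogram of the (cs, cd) signal pairs."""
    signal_grid = signal_grid or SignalGrid.from_samples(samples)
    ics = _bin_index(samples.cs, signal_grid.cs_edges, "cs signal")
    icd = _bin_index(samples.cd, signal_grid.cd_edges, "cd signal")
    n_cs = len(signal_grid.cs_edges) - 1
    n_cd = len(signal_grid.cd_edges) - 1
    flat = np.ravel_multi_index((ics, icd), (n_cs, n_cd))
    counts = np.bincount(flat, minlength=n_cs * n_cd).reshape(n_cs, n_cd)
    return CooccurrenceTable(signal_grid, counts.astype(np.int64))


@dataclass
class DistributionSet:
    """The full set of simulation-derived distributions plus build metadata."""

    posterior_cd: PosteriorTable
    posterior_cs: PosteriorTable
    cooccurrence: CooccurrenceTable
    n: int
    seed: int | None
    ranges: SimulationRanges

    @property
    def signal_grid(self) -> SignalGrid:
        return self.posterior_cd.signal_grid

    @property
    def scene_grid(self) -> SceneGrid:
        return self.posterior_cd.scene_grid

    def posterior(self, cue: str) -> PosteriorTable:
        return self.posterior_cd if cue == "cd" else self.posterior_cs


def build_distributions(
    n: int = 1_000_000,
    seed: int | None = None,
    ranges: SimulationRanges | None = None,
    signal_grid: SignalGrid | None = None,
    scene_grid: SceneGrid | None = None,
) -> DistributionSet:
    """Simulate motions and build all tables in one pass."""
    samples = simulate_motions(n, ranges, seed)
    signal_grid = signal_grid or SignalGrid.from_samples(samples)
    scene_grid = scene_grid or SceneGrid.regular(samples.ranges)
    tables = build_posterior_tables(samples, signal_grid, scene_grid)
    co = build_cooccurrence(samples, signal_grid)
    return DistributionSet(
        posterior_cd=tables["cd"],
        posterior_cs=tables["cs"],
        cooccurrence=co,
        n=n,
        seed=seed,
        ranges=samples.ranges,
    )


def estimate_scene_noiseless(cd, cs, dists: DistributionSet):
    """Marginal-mean scene estimates from noiseless signals.

    Per-cue estimates are the marginal means of that cue's conditional;
    the combined estimate is the marginal mean of the renormalised
    elementwise product of the two conditionals.  Signals in unsupported
    bins yield NaN estimates (flagged, not clamped).

    Returns a dict with keys ``('cd'|'cs'|'combined', 'v'|'m')`` mapping to
    arrays aligned with the inputs.
    """
    cd = np.atleast_1d(np.asarray(cd, dtype=float))
    cs = np.atleast_1d(np.asarray(cs, dtype=float))
    if cd.shape != cs.shape:
        raise ValueError("cd and cs must align")
    tab_cd, tab_cs = dists.posterior_cd, dists.posterior_cs
    icd = tab_cd.signal_bin(cd)
    ics = tab_cs.signal_bin(cs)
    out = {
        ("cd", "v"): tab_cd.mean_v[icd],
        ("cd", "m"): tab_cd.mean_m[icd],
        ("cs", "v"): tab_cs.mean_v[ics],
        ("cs", "m"): tab_cs.mean_m[ics],
    }
    grid = dists.scene_grid
    vc, mc = grid.v_centers, grid.m_centers
    comb_v = np.full(cd.shape, np.nan)
    comb_m = np.full(cd.shape, np.nan)
    ok = tab_cd.supported[icd] & tab_cs.supported[ics]
    for k in np.flatnonzero(ok):
        prod = tab_cd.counts[icd[k]].astype(float) * tab_cs.counts[ics[k]]
        total = prod.sum()
        if total == 0:
            continue  # irreconcilable at this resolution -> stays NaN
        prod /= total
        comb_v[k] = prod.sum(axis=1) @ vc
        comb_m[k] = prod.sum(axis=0) @ mc
    out[("combined", "v")] = comb_v
    out[("combined", "m")] = comb_m
    return out


def _r_squared(truth: np.ndarray, est: np.ndarray) -> float:
    ok = np.isfinite(est)
    if ok.sum() < 3:
        return float("nan")
    c = np.corrcoef(truth[ok], est[ok])[0, 1]
    return float(c * c)


def evaluate_recovery(
    dists: DistributionSet, n_test: int = 10_000, seed: int | None = None
) -> dict:
    """Scene-parameter recovery on a fresh set of simulated motions.

    Returns squared Pearson correlations between true and estimated values
    for each cue and parameter, the number of excluded (out-of-support)
    motions, and the viewing distance beyond which the combined-cue v
    estimate saturates.
    """
    test = simulate_motions(n_test, dists.ranges, seed)
    est = estimate_scene_noiseless(test.cd, test.cs, dists)
    r2 = {
        (cue, par): _r_squared(getattr(test, par), est[(cue, par)])
        for cue in ("cd", "cs", "combined")
        for par in ("v", "m")
    }
    n_excluded = int(np.sum(~np.isfinite(est[("combined", "m")])))
    return {
        "r2": r2,
        "n_test": n_test,
        "n_excluded": n_excluded,
        "v_saturation": _v_saturation(test.v, est[("combined", "v")]),
    }


def _v_saturation(v_true: np.ndarray, v_est: np.ndarray, bin_mm: float = 500.0) -> float:
    """Distance beyond which the binned slope of v_est vs v_true drops below 0.5."""
    ok = np.isfinite(v_est)
    v_true, v_est = v_true[ok], v_est[ok]
    edges = np.arange(v_true.min(), v_true.max() + bin_mm, bin_mm)
    idx = np.clip(np.searchsorted(edges, v_true, side="right") - 1, 0, len(edges) - 2)
    means = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() >= 10:
            means[b] = v_est[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    slope = np.gradient(means, centers)
    below = np.flatnonzero(slope < 0.5)
    return float(centers[below[0]]) if len(below) else float(centers[-1])
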