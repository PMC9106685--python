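"""Inner-loop numerics for the model observers.

The per-segment computation — Gaussian / ratio-of-Gaussians measurement
weights, weighted-posterior mixtures, cue combination and marginal means —
is written as plain loops so numba can compile it; if numba is unavailable
the same functions run as (slow) pure Python.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True)
def _ratio_cdf(z: float, mu_num: float, mu_den: float, sigma: float) -> float:
    # P(X/Y <= z) for independent X~N(mu_num, s^2), Y~N(mu_den, s^2), in the
    # working regime where Y is almost surely positive:
    # X/Y <= z  <=>  X - z Y <= 0, and X - z Y ~ N(mu_num - z mu_den, s^2 (1+z^2)).
    return _norm_cdf((z * mu_den - mu_num) / (sigma * math.sqrt(1.0 + z * z)))


@njit(cache=True)
def _ratio_pdf(z: float, mu_num: float, mu_den: float, sigma: float) -> float:
    # Hinkley density of N(mu_num, sigma^2) / N(mu_den, sigma^2), independent.
    a = math.sqrt(z * z + 1.0) / sigma
    b = (mu_num * z + mu_den) / (sigma * sigma)
    c = (mu_num * mu_num + mu_den * mu_den) / (sigma * sigma)
    d = math.exp((b * b - c * a * a) / (2.0 * a * a))
    s2 = sigma * sigma
    term1 = b * d / (a * a * a) * _INV_SQRT_2PI / s2 * (2.0 * _norm_cdf(b / a) - 1.0)
    term2 = math.exp(-0.5 * c) / (a * a * math.pi * s2)
    return term1 + term2


@njit(cache=True)
def _estimate_segments(
    d_start,
    d_end,
    s_start,
    s_end,
    sd_cd,
    n_size,
    cd_edges,
    cs_edges,
    P_cd,
    P_cs,
    v_flat,
    m_flat,
    out,
):
    """Per-segment scene estimates from noisy measurements.

    ``out`` has shape (n_segments, 6) and receives
    (m_cd, v_cd, m_cs, v_cs, m_comb, v_comb); NaN where a posterior has no
    support.  ``P_cd`` / ``P_cs`` are row-normalised conditionals flattened
    over the (v, m) scene grid.
    """
    n_seg = d_start.shape[0]
    n_scene = P_cd.shape[1]
    n_cd = cd_edges.shape[0] - 1
    n_cs = cs_edges.shape[0] - 1
    b_cd = np.zeros(n_scene, dtype=np.float64)
    b_cs = np.zeros(n_scene, dtype=np.float64)
    for k in range(n_seg):
        # --- CD weights: Gaussian CDF differences in a +-8 sigma window ---
        mu = d_start[k] - d_end[k]
        lo = np.searchsorted(cd_edges, mu - 8.0 * sd_cd) - 1
        hi = np.searchsorted(cd_edges, mu + 8.0 * sd_cd)
        if lo < 0:
            lo = 0
        if hi > n_cd:
            hi = n_cd
        b_cd[:] = 0.0
        w_tot = 0.0
        for i in range(lo, hi):
            w = _norm_cdf((cd_edges[i + 1] - mu) / sd_cd) - _norm_cdf((cd_edges[i] - mu) / sd_cd)
            if w <= 0.0:
                continue
            w_tot += w
            for s in range(n_scene):
                b_cd[s] += w * P_cd[i, s]
        # --- CS weights: ratio-of-Gaussians density integrated per bin ---
        ratio_sd = n_size * _SQRT2 * abs(s_end[k] / s_start[k]) / abs(s_start[k])
        r_mu = s_end[k] / s_start[k]
        lo2 = np.searchsorted(cs_edges, r_mu - 10.0 * ratio_sd) - 1
        hi2 = np.searchsorted(cs_edges, r_mu + 10.0 * ratio_sd)
        if lo2 < 0:
            lo2 = 0
        if hi2 > n_cs:
            hi2 = n_cs
        b_cs[:] = 0.0
        for i in range(lo2, hi2):
            w = _ratio_cdf(cs_edges[i + 1], s_end[k], s_start[k], n_size) - _ratio_cdf(
                cs_edges[i], s_end[k], s_start[k], n_size
            )
            if w <= 0.0:
                continue
            for s in range(n_scene):
                b_cs[s] += w * P_cs[i, s]
        # --- marginal means per cue and combined ---
        t_cd = 0.0
        t_cs = 0.0
        for s in range(n_scene):
            t_cd += b_cd[s]
            t_cs += b_cs[s]
        if t_cd > 0.0:
            sm = 0.0
            sv = 0.0
            for s in range(n_scene):
                sm += b_cd[s] * m_flat[s]
                sv += b_cd[s] * v_flat[s]
            out[k, 0] = sm / t_cd
            out[k, 1] = sv / t_cd
        else:
            out[k, 0] = np.nan
            out[k, 1] = np.nan
        if t_cs > 0.0:
            sm = 0.0
            sv = 0.0
            for s in range(n_scene):
                sm += b_cs[s] * m_flat[s]
                sv += b_cs[s] * v_flat[s]
            out[k, 2] = sm / t_cs
            out[k, 3] = sv / t_cs
        else:
            out[k, 2] = np.nan
            out[k, 3] = np.nan
        t = 0.0
        sm = 0.0
        sv = 0.0
        for s in range(n_scene):
            p = b_cd[s] * b_cs[s]
            t += p
            sm += p * m_flat[s]
            sv += p * v_flat[s]
        if t > 0.0:
            out[k, 4] = sm / t
            out[k, 5] = sv / t
        else:
            out[k, 4] = np.nan
            out[k, 5] = np.nan


@njit(cache=True)
def _cooccurrence_probabilities(
    d_start,
    d_end,
    s_start,
    s_end,
    sd_cd,
    n_size,
    cd_edges,
    cs_edges,
    co_table,
    out,
):
    """Expected co-occurrence mass per segment under the measurement weights.

    ``co_table`` is the normalised p(CS ∩ CD) indexed (cs_bin, cd_bin);
    ``out`` (n_segments,) receives sum_ij L_cs(i) L_cd(j) co_table[i, j].
    """
    n_seg = d_start.shape[0]
    n_cd = cd_edges.shape[0] - 1
    n_cs = cs_edges.shape[0] - 1
    for k in range(n_seg):
        mu = d_start[k] - d_end[k]
        lo = max(np.searchsorted(cd_edges, mu - 8.0 * sd_cd) - 1, 0)
        hi = min(np.searchsorted(cd_edges, mu + 8.0 * sd_cd), n_cd)
        r_mu = s_end[k] / s_start[k]
        ratio_sd = n_size * _SQRT2 * abs(r_mu) / abs(s_start[k])
        lo2 = max(np.searchsorted(cs_edges, r_mu - 10.0 * ratio_sd) - 1, 0)
        hi2 = min(np.searchsorted(cs_edges, r_mu + 10.0 * ratio_sd), n_cs)
        # Truncated mass is deliberately NOT renormalised: measurement mass
        # falling outside the simulated signal range never co-occurs, which
        # is itself evidence of conflict.
        total = 0.0
        for i in range(lo2, hi2):
            wcs = _ratio_cdf(cs_edges[i + 1], s_end[k], s_start[k], n_size) - _ratio_cdf(
                cs_edges[i], s_end[k], s_start[k], n_size
            )
            if wcs <= 0.0:
                continue
            for j in range(lo, hi):
                wcd = _norm_cdf((cd_edges[j + 1] - mu) / sd_cd) - _norm_cdf(
                    (cd_edges[j] - mu) / sd_cd
                )
                if wcd > 0.0:
                    total += wcs * wcd * co_table[i, j]
        out[k] = total
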