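"""Sinogram-domain simulation of blank, transmission and emission data.

Instead of photon tracking, expected counts are computed per sinogram
bin from the geometric sensitivity, attenuation factors and energy
models, and Poisson samples are drawn from the expectations.  Event
mechanisms that act on single coincidences (Compton scattering with
Klein-Nishina kinematics, energy-window selection with a Gaussian
resolution model, TOF discrimination of emission-origin events) are
applied to sampled per-event attributes and accumulated into separate
scatter/contamination categories, so no-scatter datasets are exact
subsets of the full ones.

Rate model.  The Lu-176 beta decay in one crystal coincident with its
307 keV prompt gamma detected in an opposing crystal drives the blank
rate; the per-cc singles rate in the default energy window is the
calibration anchor, with the beta-window detection probability folded
into a single constant.  An ``exposure_scale`` factor scales all
expectations to desk-level counts; it multiplies blank and object
scans alike, so count-statistics comparisons remain internally
consistent.  Randoms are never generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .constants import (C_MM_PER_PS, ETA_307, F18_HALF_LIFE_MIN,
                        FWHM_TO_SIGMA, LU176_GAMMA_LINES, MU_LYSO_511)
from .geometry import (EnergyWindow, GAMMA_WINDOW_250, BETA_WINDOW_250,
                       LORTable, bin_crystal_pairs, lor_row_lookup)
from .phantom import Phantom
from .projector import (attenuation_factors, forward_project,
                        tof_forward_project)

__all__ = [
    "LuSourceModel", "SinogramSet", "NormalizationFactors",
    "decay_factor", "energy_sigma", "energy_window_survival",
    "apply_energy_window", "blank_expectation", "simulate_blank",
    "simulate_transmission", "simulate_emission", "reject_by_tof",
    "normalization_factors", "exposure_scale_for_target",
    "emission_sensitivity_for_target",
    "save_sinogram_set", "load_sinogram_set",
]


@dataclass(frozen=True)
class LuSourceModel:
    """Lu-176 background source model.

    ``rate_per_cc`` is the measured singles rate per cc of LYSO in the
    scanner's default (430-645 keV) window, used as the decay-rate
    anchor.  ``beta_detection_prob`` is the probability that the beta
    deposit falls inside the chosen beta window, kept as a single
    calibration constant (the beta spectrum itself is not modelled).
    Only the 307 keV line produces transmission coincidences in the
    windows used here; the other line probabilities are retained for
    rate bookkeeping.
    """

    rate_per_cc: float = 92.2
    gamma_lines: dict = field(default_factory=lambda: dict(LU176_GAMMA_LINES))
    beta_detection_prob: float = 1.0

    def __post_init__(self):
        if self.rate_per_cc < 0:
            raise ValueError("rate must be >= 0")
        if not 0.0 <= self.beta_detection_prob <= 1.0:
            raise ValueError("beta_detection_prob must be a probability")


@dataclass
class SinogramSet:
    """Blank / transmission / TOF-emission count arrays over an LOR table.

    Count arrays are flat over the table rows (emission carries a
    trailing TOF axis).  Scatter and contamination categories are kept
    separate; the ``transmission`` and ``emission`` properties return
    the requested combination.
    """

    table: LORTable
    duration_s: float = 0.0
    blank: Optional[np.ndarray] = None
    blank_duration_s: float = 0.0
    blank_expect: Optional[np.ndarray] = None
    tran_true: Optional[np.ndarray] = None
    tran_scat307: Optional[np.ndarray] = None
    tran_contam511: Optional[np.ndarray] = None
    tran_additive: Optional[np.ndarray] = None  # r_i expectation
    emis_true: Optional[np.ndarray] = None
    emis_scat: Optional[np.ndarray] = None
    emis_additive: Optional[np.ndarray] = None  # s_it expectation
    emission_scale: float = 1.0  # counts per (kBq/ml * mm) incl. duration & decay
    exposure_scale: float = 1.0
    seed: Optional[int] = None
    windows: dict = field(default_factory=dict)

    def transmission(self, include_scatter: bool = False,
                     include_contamination: bool = False) -> np.ndarray:
        y = self.tran_true.copy()
        if include_scatter and self.tran_scat307 is not None:
            y = y + self.tran_scat307
        if include_contamination and self.tran_contam511 is not None:
            y = y + self.tran_contam511
        return y

    def emission(self, include_scatter: bool = False) -> np.ndarray:
        y = self.emis_true.copy()
        if include_scatter and self.emis_scat is not None:
            y = y + self.emis_scat
        return y

    def blank_for_transmission(self) -> np.ndarray:
        """Blank expectation referred to the transmission duration."""
        if self.blank_expect is not None:
            return self.blank_expect * (self.duration_s / self.blank_duration_s)
        return self.blank * (self.duration_s / self.blank_duration_s)


@dataclass
class NormalizationFactors:
    """Per-LOR relative detection efficiencies, mean 1."""

    n_i: np.ndarray

    def __post_init__(self):
        if np.any(~np.isfinite(self.n_i)) or np.any(self.n_i <= 0):
            raise ValueError("normalization factors must be finite and positive")


# ---------------------------------------------------------------------------
# Energy and decay models
# ---------------------------------------------------------------------------

def decay_factor(duration_s: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Time-integrated decay factor over a scan starting at the
    activity reference time: (1 - 2^(-T/T12)) * T12 / (T ln 2)."""
    t = duration_s / 60.0
    if t == 0:
        return 1.0
    return (1.0 - 2.0 ** (-t / half_life_min)) * half_life_min / (t * math.log(2.0))


def energy_sigma(energy_kev, resolution_511: float = 0.117) -> np.ndarray:
    """Gaussian sigma of the measured energy: fractional FWHM scales
    as 1/sqrt(E), anchored at 511 keV."""
    e = np.asarray(energy_kev, dtype=float)
    fwhm = resolution_511 * np.sqrt(511.0 * e)
    return fwhm * FWHM_TO_SIGMA


def energy_window_survival(energy_kev, window: EnergyWindow,
                           resolution_511: float = 0.117) -> np.ndarray:
    """Closed-form probability that a deposit of the given true energy
    is measured inside the window."""
    s = energy_sigma(energy_kev, resolution_511)
    e = np.asarray(energy_kev, dtype=float)
    return ndtr((window.high - e) / s) - ndtr((window.low - e) / s)


def apply_energy_window(energies, window: EnergyWindow, seed=None,
                        resolution_511: float = 0.117,
                        rng: Optional[np.random.Generator] = None):
    """Smear event energies with the resolution model and test the
    window.  Returns the boolean pass mask."""
    rng = rng or np.random.default_rng(seed)
    e = np.asarray(energies, dtype=float)
    meas = e + rng.standard_normal(e.shape) * energy_sigma(e, resolution_511)
    return (meas >= window.low) & (meas <= window.high)


# ---------------------------------------------------------------------------
# Blank and transmission
# ---------------------------------------------------------------------------

def blank_expectation(table: LORTable, lu_model: LuSourceModel, duration_s: float,
                      gamma_window: EnergyWindow = GAMMA_WINDOW_250,
                      exposure_scale: float = 1.0) -> np.ndarray:
    """Expected blank counts per LOR.

    Rate per ordered crystal pair = crystal decay rate x beta-window
    probability x solid-angle fraction of the opposing crystal x
    photoabsorption probability in it x energy-window survival of the
    307 keV line; both orderings contribute.
    """
    geom = table.geometry
    rate_crystal = lu_model.rate_per_cc * geom.crystal_volume_cc
    p_gamma = lu_model.gamma_lines.get(307.0, 1.0)
    p_stop = 1.0 - math.exp(-ETA_307 * MU_LYSO_511 * geom.crystal_length)
    surv = float(energy_window_survival(307.0, gamma_window,
                                        geom.energy_resolution_511))
    omega = table.geom_weight / (4.0 * math.pi)
    rate = (2.0 * rate_crystal * lu_model.beta_detection_prob * p_gamma
            * omega * p_stop * surv)
    return exposure_scale * duration_s * rate


def simulate_blank(table: LORTable, lu_model: LuSourceModel, duration_s: float,
                   seed: int = 0, gamma_window: EnergyWindow = GAMMA_WINDOW_250,
                   exposure_scale: float = 1.0) -> SinogramSet:
    """Poisson blank scan (no object in the FOV)."""
    rng = np.random.default_rng(seed)
    expect = blank_expectation(table, lu_model, duration_s, gamma_window,
                               exposure_scale)
    return SinogramSet(table=table, blank=rng.poisson(expect).astype(np.int64),
                       blank_duration_s=duration_s, blank_expect=expect,
                       exposure_scale=exposure_scale, seed=seed,
                       windows={"gamma": [gamma_window.low, gamma_window.high]})


def exposure_scale_for_target(table: LORTable, phantom: Phantom,
                              lu_model: LuSourceModel, duration_s: float,
                              target_true_counts: float,
                              gamma_window: EnergyWindow = GAMMA_WINDOW_250) -> float:
    """Exposure factor making the expected unscattered transmission
    count of a scan equal the desk-scale target."""
    b = blank_expectation(table, lu_model, duration_s, gamma_window)
    a = attenuation_factors(phantom.mu511, table.end307_a, table.end307_b,
                            phantom.grid, energy_mode=307)
    return float(target_true_counts / np.sum(b * a))


def simulate_transmission(table: LORTable, phantom: Phantom,
                          lu_model: LuSourceModel, duration_s: float,
                          seed: int = 0, scatter_mode: str = "none",
                          gamma_window: EnergyWindow = GAMMA_WINDOW_250,
                          beta_window: EnergyWindow = BETA_WINDOW_250,
                          exposure_scale: float = 1.0,
                          blank_duration_s: Optional[float] = None,
                          blank_seed_offset: int = 7919,
                          emission: Optional[SinogramSet] = None) -> SinogramSet:
    """Transmission scan through the phantom, with category bookkeeping.

    ``scatter_mode='single_scatter'`` adds Klein-Nishina single-scatter
    events of the 307 keV photons; if an emission dataset is supplied,
    contamination of the transmission window by Compton-scattered
    511 keV photons is sampled as well and filtered by the per-LOR TOF
    threshold rule.
    """
    if scatter_mode not in ("none", "single_scatter"):
        raise ValueError(f"unknown scatter_mode {scatter_mode!r}")
    rng = np.random.default_rng(seed)
    geom = table.geometry
    b_exp = blank_expectation(table, lu_model, duration_s, gamma_window,
                              exposure_scale)
    a307 = attenuation_factors(phantom.mu511, table.end307_a, table.end307_b,
                               phantom.grid, energy_mode=307)
    true = rng.poisson(b_exp * a307).astype(np.int64)

    scat = np.zeros(len(table), dtype=np.int64)
    contam = np.zeros(len(table), dtype=np.int64)
    if scatter_mode == "single_scatter":
        scat = _sample_scatter_307(table, phantom, b_exp, a307, gamma_window, rng)
        if emission is not None:
            contam = _sample_contamination_511(table, phantom, emission,
                                               gamma_window, beta_window, rng)

    bl_dur = blank_duration_s if blank_duration_s is not None else 10.0 * duration_s
    bl = simulate_blank(table, lu_model, bl_dur, seed + blank_seed_offset,
                        gamma_window, exposure_scale)
    return SinogramSet(
        table=table, duration_s=duration_s,
        blank=bl.blank, blank_duration_s=bl_dur, blank_expect=bl.blank_expect,
        tran_true=true, tran_scat307=scat, tran_contam511=contam,
        tran_additive=np.zeros(len(table)),
        exposure_scale=exposure_scale, seed=seed,
        windows={"gamma": [gamma_window.low, gamma_window.high],
                 "beta": [beta_window.low, beta_window.high]})


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def emission_sensitivity_for_target(table: LORTable, phantom: Phantom,
                                    duration_s: float,
                                    target_counts: float) -> float:
    """Sensitivity constant (counts per kBq/ml/mm of attenuated line
    integral per second) that makes the expected true-count total of a
    scan equal the desk-scale target."""
    proj = forward_project(phantom.activity, table.end511_a, table.end511_b,
                           phantom.grid)
    a511 = attenuation_factors(phantom.mu511, table.end511_a, table.end511_b,
                               phantom.grid, energy_mode=511)
    tot = float(np.sum(proj * a511)) * duration_s * decay_factor(duration_s)
    return target_counts / tot if tot > 0 else 0.0


def simulate_emission(table: LORTable, phantom: Phantom, duration_s: float,
                      seed: int = 0, target_counts: Optional[float] = None,
                      sensitivity: Optional[float] = None,
                      scatter_mode: str = "none",
                      start_time_s: float = 0.0,
                      emission_window: Optional[EnergyWindow] = None) -> SinogramSet:
    """TOF emission scan of the phantom activity.

    Expectation per LOR/TOF bin = sensitivity x duration x
    time-integrated F-18 decay factor x TOF forward projection of the
    activity x 511 keV attenuation factor (uniform ideal efficiency,
    n_i-free).  Either ``sensitivity`` (counts per kBq/ml/mm of line
    integral per second) or a ``target_counts`` total must be given.
    ``start_time_s`` shifts the scan start from the activity reference
    time (sequential bed positions decay accordingly).
    """
    spec = table.spec
    if spec.tof_bins < 1:
        raise ValueError("emission requires a TOF sinogram spec")
    rng = np.random.default_rng(seed)
    dec = decay_factor(duration_s)
    dec *= 2.0 ** (-(start_time_s / 60.0) / F18_HALF_LIFE_MIN)
    proj = tof_forward_project(phantom.activity, table.end511_a, table.end511_b,
                               phantom.grid, table.geometry, spec.tof_bins)
    a511 = attenuation_factors(phantom.mu511, table.end511_a, table.end511_b,
                               phantom.grid, energy_mode=511)
    base = proj * a511[:, None]
    if sensitivity is None:
        if target_counts is None:
            raise ValueError("give either sensitivity or target_counts")
        tot = float(base.sum()) * duration_s * dec
        sensitivity = target_counts / tot if tot > 0 else 0.0
    scale = sensitivity * duration_s * dec
    expect = scale * base
    true = rng.poisson(expect).astype(np.int64)
    scat = None
    if scatter_mode == "single_scatter":
        win = emission_window or EnergyWindow(430.0, 645.0, "emission_511")
        scat = _sample_scatter_emission(table, phantom, expect, win, rng)
    return SinogramSet(table=table, duration_s=duration_s,
                       emis_true=true, emis_scat=scat,
                       emis_additive=np.zeros_like(expect),
                       emission_scale=scale, seed=seed)


def reject_by_tof(tof_ps, thresholds_ps) -> np.ndarray:
    """Accept mask of the transmission TOF rule: an event is accepted
    iff |TOF| exceeds the per-LOR threshold (crystal-origin events sit
    at the LOR flight time, body-origin events below it)."""
    return np.abs(np.asarray(tof_ps, float)) > np.asarray(thresholds_ps, float)


# ---------------------------------------------------------------------------
# Klein-Nishina single-scatter samplers
# ---------------------------------------------------------------------------

def _kn_sample_cos(rng, e_kev: float, n: int) -> np.ndarray:
    """Rejection-sample scattering angle cosines from the
    Klein-Nishina differential cross-section at the given energy."""
    k = e_kev / 511.0
    out = np.empty(n)
    have = 0
    # envelope: uniform in cos with the maximum of the KN kernel
    cgrid = np.linspace(-1.0, 1.0, 201)
    fmax = _kn_kernel(k, cgrid).max() * 1.05
    while have < n:
        m = max(2 * (n - have), 128)
        c = rng.uniform(-1.0, 1.0, m)
        u = rng.uniform(0.0, fmax, m)
        acc = c[u <= _kn_kernel(k, c)]
        take = min(len(acc), n - have)
        out[have:have + take] = acc[:take]
        have += take
    return out


def _kn_kernel(k: float, cos_t) -> np.ndarray:
    r = 1.0 / (1.0 + k * (1.0 - np.asarray(cos_t, float)))  # E'/E
    return r * r * (r + 1.0 / r - (1.0 - np.asarray(cos_t, float) ** 2))


def _scatter_frame(d, cos_t, phi):
    """Rotate unit vectors d by polar angle acos(cos_t), azimuth phi."""
    d = np.asarray(d, float)
    # orthonormal basis (e1, e2) perpendicular to d
    helper = np.where(np.abs(d[:, 2:3]) < 0.9,
                      np.tile([0.0, 0.0, 1.0], (len(d), 1)),
                      np.tile([1.0, 0.0, 0.0], (len(d), 1)))
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    return (d * cos_t[:, None]
            + e1 * (sin_t * np.cos(phi))[:, None]
            + e2 * (sin_t * np.sin(phi))[:, None])


def _sample_vertex_on_chord(table, rows, phantom, rng, start=None):
    """Sample a scatter vertex on each row's chord, with probability
    proportional to the local attenuation coefficient (rejection
    against the phantom's maximum mu).  ``start`` optionally replaces
    endpoint A by an interior emission point.  Returns (vertex,
    mask_found)."""
    grid = phantom.grid
    mu = phantom.mu511
    mu_max = float(mu.max())
    p1 = table.end307_a[rows] if start is None else start
    p2 = table.end307_b[rows]
    n = len(rows)
    v = np.zeros((n, 3))
    found = np.zeros(n, dtype=bool)
    pending = np.arange(n)
    for _ in range(30):
        if len(pending) == 0:
            break
        a = rng.random(len(pending))
        pt = p1[pending] + a[:, None] * (p2[pending] - p1[pending])
        ijk = np.floor((pt - grid.origin) / grid.voxel_size).astype(np.int64)
        inside = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
        muv = np.zeros(len(pending))
        ii = ijk[inside]
        muv[inside] = mu[ii[:, 0], ii[:, 1], ii[:, 2]]
        acc = rng.random(len(pending)) * mu_max < muv
        sel = pending[acc]
        v[sel] = pt[acc]
        found[sel] = True
        pending = pending[~acc]
    return v, found


def _propagate_to_ring(geometry, origin, direction):
    """Intersect rays with the detector cylinder; return (ring, trans,
    hit_mask) of the struck crystal."""
    R = geometry.ring_radius
    ox, oy = origin[:, 0], origin[:, 1]
    dx, dy = direction[:, 0], direction[:, 1]
    a = dx * dx + dy * dy
    b = 2.0 * (ox * dx + oy * dy)
    c = ox * ox + oy * oy - R * R
    disc = b * b - 4.0 * a * c
    hit = (a > 1e-12) & (disc > 0.0)
    t = np.zeros(len(origin))
    t[hit] = (-b[hit] + np.sqrt(disc[hit])) / (2.0 * a[hit])
    hit &= t > 1e-6
    p = origin + t[:, None] * direction
    pitch = geometry.unit_length / geometry.rings_per_unit
    zidx = np.round(p[:, 2] / pitch + (geometry.n_rings - 1) / 2.0).astype(np.int64)
    hit &= (zidx >= 0) & (zidx < geometry.n_rings)
    ang = np.arctan2(p[:, 1], p[:, 0]) % (2.0 * math.pi)
    tidx = np.floor(ang / (2.0 * math.pi / geometry.crystals_per_ring)).astype(np.int64)
    tidx = np.clip(tidx, 0, geometry.crystals_per_ring - 1)
    return zidx, tidx, hit


def _sample_rows(rng, weights, n):
    csum = np.cumsum(weights)
    if csum[-1] <= 0:
        return np.empty(0, dtype=np.int64)
    return np.searchsorted(csum, rng.random(n) * csum[-1])


def _sample_scatter_307(table, phantom, b_exp, a307, gamma_window, rng):
    """Single-scatter of the 307 keV photon along its primary chord."""
    geom, spec = table.geometry, table.spec
    interact = b_exp * (1.0 - a307)
    total = float(interact.sum())
    out = np.zeros(len(table), dtype=np.int64)
    n_ev = rng.poisson(total)
    if n_ev == 0:
        return out
    lut = lor_row_lookup(table)
    batch = 200_000
    done = 0
    while done < n_ev:
        m = min(batch, n_ev - done)
        done += m
        rows = _sample_rows(rng, interact, m)
        # emitting side chosen at random (both orderings are in b_exp)
        swap = rng.random(m) < 0.5
        pa = np.where(swap[:, None], table.end307_b[rows], table.end307_a[rows])
        pb = np.where(swap[:, None], table.end307_a[rows], table.end307_b[rows])
        ring_a = np.where(swap, table.ring_b[rows], table.ring_a[rows])
        trans_a = np.where(swap, table.trans_b[rows], table.trans_a[rows])

        v, okv = _sample_vertex_on_chord(_Rows(pa, pb), np.arange(m), phantom, rng)
        d = pb - pa
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        cos_t = _kn_sample_cos(rng, 307.0, m)
        e_out = 307.0 / (1.0 + (307.0 / 511.0) * (1.0 - cos_t))
        newd = _scatter_frame(d, cos_t, rng.uniform(0, 2 * math.pi, m))
        ring_b, trans_b, hit = _propagate_to_ring(geom, v, newd)
        ok = okv & hit
        ok &= apply_energy_window(e_out, gamma_window, rng=rng,
                                  resolution_511=geom.energy_resolution_511)
        radial, angle, plA, plB, valid = bin_crystal_pairs(
            geom, spec, ring_a, trans_a, ring_b, trans_b)
        ok &= valid
        rws = lut[angle[ok], radial[ok], plA[ok], plB[ok]]
        rws = rws[rws >= 0]
        np.add.at(out, rws, 1)
    return out


class _Rows:
    """Adapter exposing endpoint arrays as an LORTable-like object for
    the vertex sampler."""

    def __init__(self, a, b):
        self.end307_a = a
        self.end307_b = b


def _sample_contamination_511(table, phantom, emission, gamma_window,
                              beta_window, rng):
    """Compton-scattered 511 keV emission pairs leaking into the
    transmission windows, filtered by the TOF threshold rule."""
    geom, spec = table.geometry, table.spec
    y = emission.emis_true.astype(float)
    lor_tot = y.sum(axis=1)
    scatter_prob = 1.0 - attenuation_factors(
        phantom.mu511, table.end511_a, table.end511_b, phantom.grid, 511)
    weights = lor_tot * scatter_prob
    n_ev = rng.poisson(float(weights.sum()))
    out = np.zeros(len(table), dtype=np.int64)
    if n_ev == 0:
        return out
    lut = lor_row_lookup(table)
    sigma_t = geom.ctr_ps * FWHM_TO_SIGMA
    n_tof = spec.tof_bins
    bw = geom.tof_bin_width_ps
    batch = 200_000
    done = 0
    while done < n_ev:
        m = min(batch, n_ev - done)
        done += m
        rows = _sample_rows(rng, weights, m)
        # emission point from the TOF profile of the LOR
        prob = y[rows] + 1e-12
        cdf = np.cumsum(prob, axis=1)
        u = rng.random(m) * cdf[:, -1]
        kbin = (u[:, None] > cdf).sum(axis=1)
        t_emit = (kbin - n_tof // 2 + rng.random(m) - 0.5) * bw
        pa = table.end511_a[rows]
        pb = table.end511_b[rows]
        dvec = pb - pa
        L = np.linalg.norm(dvec, axis=1)
        dunit = dvec / L[:, None]
        u_mm = 0.5 * C_MM_PER_PS * t_emit  # signed, toward B
        p0 = pa + (0.5 * L + u_mm)[:, None] * dunit
        # photon toward B scatters at a vertex on p0 -> B
        v, okv = _sample_vertex_on_chord(_Rows(p0, pb), np.arange(m), phantom, rng)
        cos_t = _kn_sample_cos(rng, 511.0, m)
        e_out = 511.0 / (1.0 + (511.0 / 511.0) * (1.0 - cos_t))
        newd = _scatter_frame(dunit, cos_t, rng.uniform(0, 2 * math.pi, m))
        ring_b, trans_b, hit = _propagate_to_ring(geom, v, newd)
        ok = okv & hit
        ok &= apply_energy_window(e_out, gamma_window, rng=rng,
                                  resolution_511=geom.energy_resolution_511)
        ok &= apply_energy_window(np.full(m, 511.0), beta_window, rng=rng,
                                  resolution_511=geom.energy_resolution_511)
        ring_a = table.ring_a[rows]
        trans_a = table.trans_a[rows]
        # TOF of the new pair (A, B')
        xb, yb = geom.crystal_xy(trans_b)
        zb = geom.ring_z(ring_b)
        pbp = np.stack([xb, yb, zb], axis=1)
        t_a = np.linalg.norm(p0 - pa, axis=1) / C_MM_PER_PS
        t_b = (np.linalg.norm(v - p0, axis=1)
               + np.linalg.norm(pbp - v, axis=1)) / C_MM_PER_PS
        tof = (t_a - t_b) + rng.standard_normal(m) * sigma_t
        thr = np.linalg.norm(pbp - pa, axis=1) / C_MM_PER_PS - 500.0
        ok &= reject_by_tof(tof, thr)
        radial, angle, plA, plB, valid = bin_crystal_pairs(
            geom, spec, ring_a, trans_a, ring_b, trans_b)
        ok &= valid
        rws = lut[angle[ok], radial[ok], plA[ok], plB[ok]]
        rws = rws[rws >= 0]
        np.add.at(out, rws, 1)
    return out


def _sample_scatter_emission(table, phantom, expect, window, rng):
    """Small-angle Compton-scattered 511 keV pairs remaining inside
    the emission energy window, on their displaced LORs."""
    geom, spec = table.geometry, table.spec
    lor_tot = expect.sum(axis=1)
    scatter_prob = 1.0 - attenuation_factors(
        phantom.mu511, table.end511_a, table.end511_b, phantom.grid, 511)
    weights = lor_tot * scatter_prob
    n_ev = rng.poisson(float(weights.sum()))
    out = np.zeros_like(expect, dtype=np.int64)
    if n_ev == 0:
        return out
    lut = lor_row_lookup(table)
    n_tof = spec.tof_bins
    bw = geom.tof_bin_width_ps
    sigma_t = geom.ctr_ps * FWHM_TO_SIGMA
    batch = 200_000
    done = 0
    while done < n_ev:
        m = min(batch, n_ev - done)
        done += m
        rows = _sample_rows(rng, weights, m)
        prob = expect[rows] + 1e-12
        cdf = np.cumsum(prob, axis=1)
        u = rng.random(m) * cdf[:, -1]
        kbin = (u[:, None] > cdf).sum(axis=1)
        t_emit = (kbin - n_tof // 2 + rng.random(m) - 0.5) * bw
        pa = table.end511_a[rows]
        pb = table.end511_b[rows]
        dvec = pb - pa
        L = np.linalg.norm(dvec, axis=1)
        dunit = dvec / L[:, None]
        p0 = pa + (0.5 * L + 0.5 * C_MM_PER_PS * t_emit)[:, None] * dunit
        v, okv = _sample_vertex_on_chord(_Rows(p0, pb), np.arange(m), phantom, rng)
        cos_t = _kn_sample_cos(rng, 511.0, m)
        e_out = 511.0 / (2.0 - cos_t)
        newd = _scatter_frame(dunit, cos_t, rng.uniform(0, 2 * math.pi, m))
        ring_b, trans_b, hit = _propagate_to_ring(geom, v, newd)
        ok = okv & hit
        ok &= apply_energy_window(e_out, window, rng=rng,
                                  resolution_511=geom.energy_resolution_511)
        ring_a = table.ring_a[rows]
        trans_a = table.trans_a[rows]
        xb, yb = geom.crystal_xy(trans_b)
        zb = geom.ring_z(ring_b)
        pbp = np.stack([xb, yb, zb], axis=1)
        t_a = np.linalg.norm(p0 - pa, axis=1) / C_MM_PER_PS
        t_b = (np.linalg.norm(v - p0, axis=1)
               + np.linalg.norm(pbp - v, axis=1)) / C_MM_PER_PS
        tof = (t_a - t_b) + rng.standard_normal(m) * sigma_t
        kt = np.clip(np.round(tof / bw).astype(np.int64) + n_tof // 2, 0, n_tof - 1)
        radial, angle, plA, plB, valid = bin_crystal_pairs(
            geom, spec, ring_a, trans_a, ring_b, trans_b)
        ok &= valid
        rws = lut[angle[ok], radial[ok], plA[ok], plB[ok]]
        keep = rws >= 0
        np.add.at(out, (rws[keep], kt[ok][keep]), 1)
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalization_factors(table: LORTable, mode: str = "ideal", seed: int = 0,
                          crystal_efficiency: Optional[dict] = None,
                          counts_per_lor: float = 200.0,
                          n_outer: int = 20) -> NormalizationFactors:
    """Per-LOR normalization factors.

    ``ideal`` returns all ones.  ``annulus`` simulates a scan of a
    thin activity annulus just inside the FOV and estimates crystal
    efficiencies and a radial geometric profile by alternating
    component-based updates; with uniform simulated efficiencies the
    factors converge to one.  ``crystal_efficiency`` maps
    ``(ring, trans)`` to an injected relative efficiency for
    validation studies.
    """
    n = len(table)
    if mode == "ideal":
        return NormalizationFactors(n_i=np.ones(n))
    if mode != "annulus":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    geom = table.geometry
    # analytic chord of the annulus (mid-radius ring, small thickness)
    r_ann = geom.transaxial_fov / 2.0 - 10.0
    thick = 6.0
    spec = table.spec
    width = geom.transaxial_fov / spec.n_radial
    s = (table.radial - spec.n_radial // 2) * width
    inside = np.abs(s) < r_ann
    chord = np.zeros(n)
    o = np.sqrt(np.clip(r_ann**2 - s[inside]**2, 0.0, None))
    chord[inside] = 2.0 * thick * r_ann / np.maximum(o, thick / 2.0)
    eff = np.ones(n)
    if crystal_efficiency:
        for (ring, trans), e in crystal_efficiency.items():
            eff[(table.ring_a == ring) & (table.trans_a == trans)] *= e
            eff[(table.ring_b == ring) & (table.trans_b == trans)] *= e
    expect = chord * eff
    tot = expect.sum()
    if tot <= 0:
        raise ValueError("annulus scan produced no counts")
    expect *= counts_per_lor * np.count_nonzero(chord) / tot
    y = rng.poisson(expect).astype(float)

    # component-based alternating estimation
    cid_a = table.ring_a.astype(np.int64) * geom.crystals_per_ring + table.trans_a
    cid_b = table.ring_b.astype(np.int64) * geom.crystals_per_ring + table.trans_b
    ncr = geom.n_rings * geom.crystals_per_ring
    eps = np.ones(ncr)
    g = np.ones(spec.n_radial)
    act = chord > 0
    for _ in range(n_outer):
        model_wo_eps = chord * g[table.radial]
        denom_a = np.bincount(cid_a[act], weights=(model_wo_eps * eps[cid_b])[act],
                              minlength=ncr)
        denom_b = np.bincount(cid_b[act], weights=(model_wo_eps * eps[cid_a])[act],
                              minlength=ncr)
        num = (np.bincount(cid_a[act], weights=y[act], minlength=ncr)
               + np.bincount(cid_b[act], weights=y[act], minlength=ncr))
        den = denom_a + denom_b
        good = den > 0
        eps = np.where(good, np.divide(num, den, out=np.ones(ncr),
                                       where=good), eps)
        # fix the multiplicative gauge: efficiencies average to one,
        # the geometric profile absorbs the global scale
        seen = np.zeros(ncr, dtype=bool)
        seen[cid_a[act]] = True
        seen[cid_b[act]] = True
        eps[seen] /= eps[seen].mean()
        eps = np.clip(eps, 1e-3, 1e3)
        model_wo_g = chord * eps[cid_a] * eps[cid_b]
        num_g = np.bincount(table.radial[act], weights=y[act],
                            minlength=spec.n_radial)
        den_g = np.bincount(table.radial[act], weights=model_wo_g[act],
                            minlength=spec.n_radial)
        goodg = den_g > 0
        g[goodg] = num_g[goodg] / den_g[goodg]
    n_i = eps[cid_a] * eps[cid_b]
    n_i /= n_i[act].mean()
    n_i = np.clip(n_i, 1e-6, None)
    return NormalizationFactors(n_i=n_i)


# ---------------------------------------------------------------------------
# Serialization (HDF5 container)
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = ("blank", "blank_expect", "tran_true", "tran_scat307",
                 "tran_contam511", "tran_additive", "emis_true", "emis_scat",
                 "emis_additive")


def save_sinogram_set(sino: SinogramSet, path) -> None:
    """Write the count arrays plus a JSON-style header (geometry hash,
    spec, duration, seed, windows) to a chunked HDF5 container."""
    import h5py
    import json
    from dataclasses import asdict

    with h5py.File(path, "w") as fh:
        for name in _ARRAY_FIELDS:
            arr = getattr(sino, name)
            if arr is not None:
                fh.create_dataset(name, data=arr, chunks=True, compression="gzip")
        hdr = {
            "duration_s": sino.duration_s,
            "blank_duration_s": sino.blank_duration_s,
            "emission_scale": sino.emission_scale,
            "exposure_scale": sino.exposure_scale,
            "seed": sino.seed,
            "windows": sino.windows,
            "geometry": asdict(sino.table.geometry),
            "spec": asdict(sino.table.spec),
            "geometry_hash": hash(sino.table.geometry) % (2**31),
        }
        fh.attrs["header"] = json.dumps(hdr)


def load_sinogram_set(path, table: LORTable) -> SinogramSet:
    import h5py
    import json

    with h5py.File(path, "r") as fh:
        hdr = json.loads(fh.attrs["header"])
        kw = {}
        for name in _ARRAY_FIELDS:
            if name in fh:
                kw[name] = fh[name][...]
        return SinogramSet(table=table, duration_s=hdr["duration_s"],
                           blank_duration_s=hdr["blank_duration_s"],
                           emission_scale=hdr["emission_scale"],
                           exposure_scale=hdr["exposure_scale"],
                           seed=hdr["seed"], windows=hdr["windows"], **kw)
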