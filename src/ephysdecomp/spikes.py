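"""Spike detection, per-AP features, per-sweep features, passive properties.

Feature definitions (all on current-clamp voltage traces):

* **onset** — first sample where the smoothed dV/dt exceeds 10 mV/ms and the
  ensuing excursion reaches the validation level (default -20 mV).
* **threshold** — voltage at which dV/dt reaches 20 mV/ms.
* **amplitude** — peak voltage minus the pre-step membrane potential
  (mean over the 50 ms preceding step onset).
* **FWHM** — duration at half of (peak - onset voltage), measured from the
  onset-referenced half level, with sub-sample interpolation.
* **rise time** — between the 20% and 80% amplitude points of the rising
  phase (onset-to-peak referenced).
* **decay time** — time from the peak until the voltage has completed 63%
  of the drop from peak toward the post-spike minimum (the e-fold, "37%
  remaining" convention).
* **post-spike voltage** — minimum voltage after the peak minus the
  threshold voltage (negative = undershoot below threshold).
* **latency** — step onset to first AP onset.
* **adaptation index** — mean of (ISI[i+1]-ISI[i])/(ISI[i+1]+ISI[i]) after
  discarding the first two ISIs; undefined (NaN) with fewer than 4 ISIs.
* **rheobase** — smallest step current with at least one AP.
* **R_in / tau_m** — from a -50 pA, 10 ms hyperpolarizing pulse: single
  exponential fit of the charging transient; R_in uses the fitted asymptote
  (the pulse is shorter than tau, so the last sample would be biased).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .protocol import CURRENT_CLAMP, Protocol, Trace
from .signal_utils import smoothed_derivative

__all__ = [
    "SpikeFeatureSet",
    "SweepFeatures",
    "PassiveProps",
    "FICurve",
    "detect_spikes",
    "ap_features",
    "sweep_features",
    "rheobase",
    "passive_props",
    "fi_curve",
    "adaptation_index",
    "ONSET_SLOPE_MV_PER_MS",
    "THRESHOLD_SLOPE_MV_PER_MS",
    "VALIDATION_MV",
]

ONSET_SLOPE_MV_PER_MS = 10.0
THRESHOLD_SLOPE_MV_PER_MS = 20.0
#: an excursion must exceed this voltage to count as an AP
VALIDATION_MV = -20.0
#: minimum separation between detected onsets (ms)
REFRACTORY_MS = 2.0
#: baseline window before step onset used for the AP amplitude reference (ms)
BASELINE_WINDOW_MS = 50.0


@dataclass(frozen=True)
class SpikeFeatureSet:
    onset_time_ms: float
    onset_v: float
    threshold_v: float
    peak_time_ms: float
    peak_v: float
    amplitude: float
    fwhm_ms: float
    rise_time_20_80_ms: float
    decay_time_37_ms: float
    post_spike_voltage: float


@dataclass
class SweepFeatures:
    spike_count: int
    latency_ms: float  # NaN if no spikes
    isis_ms: list[float]
    adaptation_index: float  # NaN if undefined
    firing_rate_hz: float
    step_current: float


@dataclass(frozen=True)
class PassiveProps:
    r_in_mohm: float
    tau_m_ms: float
    rmp_mv: float


@dataclass
class FICurve:
    currents_pa: np.ndarray
    rates_hz: np.ndarray
    rheobase_pa: float  # NaN if no sweep fired

    def __post_init__(self) -> None:
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        self.rates_hz = np.asarray(self.rates_hz, dtype=float)


def _require_cc(trace: Trace) -> None:
    if trace.mode != CURRENT_CLAMP:
        raise ValueError(
            f"expected a current-clamp voltage trace, got mode {trace.mode!r}"
        )


def detect_spikes(
    trace: Trace,
    onset_slope: float = ONSET_SLOPE_MV_PER_MS,
    validation_mv: float = VALIDATION_MV,
    refractory_ms: float = REFRACTORY_MS,
) -> list[int]:
    """Indices of AP onsets: first sample of each run where the smoothed
    dV/dt exceeds ``onset_slope`` and the following excursion reaches
    ``validation_mv``.  Strictly increasing; onsets closer than
    ``refractory_ms`` to the previous accepted onset are rejected."""
    _require_cc(trace)
    v = trace.signal
    dt = trace.dt_ms
    dvdt = smoothed_derivative(v, dt)
    fast = dvdt > onset_slope
    # run starts: first index of each contiguous fast run
    starts = np.flatnonzero(fast & ~np.roll(fast, 1))
    if fast.size and fast[0]:
        starts = np.concatenate(([0], starts[starts != 0]))

    onsets: list[int] = []
    refr = int(round(refractory_ms / dt))
    for i0 in starts:
        if onsets and i0 - onsets[-1] < refr:
            continue
        # the excursion to validate is the contiguous fast-rising run plus a
        # short margin (the AP peak sits just after dV/dt returns below the
        # onset slope), capped at 5 ms
        i_run = i0
        cap = min(v.size, i0 + int(round(5.0 / dt)))
        while i_run < cap and fast[i_run]:
            i_run += 1
        i1 = min(v.size, i_run + int(round(1.0 / dt)) + 1)
        if np.max(v[i0:i1]) >= validation_mv:
            onsets.append(int(i0))
    return onsets


def _interp_crossing_time(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return t1
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def _crossing_before(v, times, i_ref, level, direction):
    """Sub-sample time where v crosses ``level`` scanning backward from i_ref."""
    for i in range(i_ref, 0, -1):
        y0, y1 = v[i - 1], v[i]
        if direction == "up" and y0 < level <= y1:
            return _interp_crossing_time(times[i - 1], times[i], y0, y1, level)
    return times[0]


def _crossing_after(v, times, i_ref, level, direction, i_max=None):
    i_max = v.size if i_max is None else i_max
    for i in range(i_ref + 1, i_max):
        y0, y1 = v[i - 1], v[i]
        if direction == "down" and y0 >= level > y1:
            return _interp_crossing_time(times[i - 1], times[i], y0, y1, level)
    return times[i_max - 1]


def ap_features(
    trace: Trace,
    onset_index: int,
    baseline_v: float,
    next_onset_index: int | None = None,
    threshold_slope: float = THRESHOLD_SLOPE_MV_PER_MS,
) -> SpikeFeatureSet:
    """Per-AP scalar features for the AP starting at ``onset_index``.

    ``baseline_v`` is the pre-step membrane potential (used as the amplitude
    reference); ``next_onset_index`` bounds the search for the peak and the
    post-spike minimum (defaults to 20 ms past the onset or the next AP).
    """
    _require_cc(trace)
    v = trace.signal
    dt = trace.dt_ms
    t = trace.time_ms
    i_on = int(onset_index)
    i_end = v.size if next_onset_index is None else int(next_onset_index)
    i_end = min(i_end, i_on + int(round(20.0 / dt)))
    if i_end <= i_on + 2:
        raise ValueError("malformed AP: window after onset too short")

    seg = v[i_on:i_end]
    i_pk = i_on + int(np.argmax(seg))
    if i_pk == i_on or i_pk >= i_end - 1:
        raise ValueError("malformed AP: no interior peak found before next spike")
    peak_v = float(v[i_pk])
    onset_v = float(v[i_on])

    # threshold: voltage at which smoothed dV/dt reaches the threshold slope
    dvdt = smoothed_derivative(v, dt)
    thr_v = onset_v
    for i in range(i_on, i_pk + 1):
        if dvdt[i] >= threshold_slope:
            if i > i_on and dvdt[i - 1] < threshold_slope:
                t_frac = (threshold_slope - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
                thr_v = float(v[i - 1] + t_frac * (v[i] - v[i - 1]))
            else:
                thr_v = float(v[i])
            break

    # post-spike minimum between peak and the end of the window
    i_min = i_pk + int(np.argmin(v[i_pk:i_end]))
    post_min_v = float(v[i_min])

    amplitude = peak_v - baseline_v

    # FWHM at half of (peak - onset voltage), measured from onset
    half_level = onset_v + 0.5 * (peak_v - onset_v)
    t_up = _crossing_before(v, t, i_pk, half_level, "up")
    t_down = _crossing_after(v, t, i_pk, half_level, "down", i_max=i_end)
    fwhm = t_down - t_up

    # rise time between the 20% and 80% levels of the onset-to-peak rise
    lvl20 = onset_v + 0.2 * (peak_v - onset_v)
    lvl80 = onset_v + 0.8 * (peak_v - onset_v)
    t20 = _crossing_before(v, t, i_pk, lvl20, "up")
    t80 = _crossing_before(v, t, i_pk, lvl80, "up")
    rise = t80 - t20

    # decay time: peak -> 37% remaining of the peak-to-post-minimum drop
    lvl37 = post_min_v + 0.37 * (peak_v - post_min_v)
    t37 = _crossing_after(v, t, i_pk, lvl37, "down", i_max=i_min + 1)
    decay = t37 - t[i_pk]

    return SpikeFeatureSet(
        onset_time_ms=float(t[i_on]),
        onset_v=onset_v,
        threshold_v=thr_v,
        peak_time_ms=float(t[i_pk]),
        peak_v=peak_v,
        amplitude=amplitude,
        fwhm_ms=float(fwhm),
        rise_time_20_80_ms=float(rise),
        decay_time_37_ms=float(decay),
        post_spike_voltage=post_min_v - thr_v,
    )


def adaptation_index(isis_ms, skip: int = 2) -> float:
    """Pairwise-normalized mean ISI change after discarding the first
    ``skip`` ISIs: mean of (ISI[i+1]-ISI[i])/(ISI[i+1]+ISI[i]).

    NaN when fewer than two ISIs remain after the skip.
    """
    isis = np.asarray(list(isis_ms), dtype=float)[skip:]
    if isis.size < 2:
        return math.nan
    pairs = (isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])
    return float(np.mean(pairs))


def sweep_features(
    trace: Trace,
    protocol: Protocol,
    skip_isis: int = 2,
    **detect_kwargs,
) -> SweepFeatures:
    """Spike count, latency, ISIs, adaptation index and firing rate of one
    step sweep.  Only spikes inside the step epoch are counted."""
    _require_cc(trace)
    ep = protocol.step_epoch()
    dt = trace.dt_ms
    onsets = np.asarray(detect_spikes(trace, **detect_kwargs), dtype=int)
    t_on = onsets * dt
    inside = (t_on >= ep.start_ms) & (t_on < ep.end_ms)
    t_on = t_on[inside]

    n = int(t_on.size)
    isis = list(np.diff(t_on)) if n >= 2 else []
    step_dur_ms = ep.end_ms - ep.start_ms
    level = trace.meta.get("level")
    if level is None:
        # read the step amplitude off the command waveform
        sl = trace.slice_ms(ep.start_ms, ep.end_ms)
        level = float(np.median(trace.command[sl]))
    return SweepFeatures(
        spike_count=n,
        latency_ms=float(t_on[0] - ep.start_ms) if n else math.nan,
        isis_ms=[float(x) for x in isis],
        adaptation_index=adaptation_index(isis, skip=skip_isis),
        firing_rate_hz=n / (step_dur_ms / 1000.0),
        step_current=float(level),
    )


def rheobase(sweeps) -> float:
    """Smallest step current with at least one AP.

    ``sweeps``: iterable of (step_current, SweepFeatures) or of
    SweepFeatures.  Returns NaN if no sweep fired.  Order-independent;
    duplicate currents are an input error.
    """
    pairs = []
    for item in sweeps:
        if isinstance(item, SweepFeatures):
            pairs.append((item.step_current, item))
        else:
            cur, feat = item
            pairs.append((float(cur), feat))
    if not pairs:
        raise ValueError("rheobase needs at least one sweep")
    currents = [c for c, _ in pairs]
    if len(set(currents)) != len(currents):
        raise ValueError("duplicate step currents in sweep set")
    firing = [c for c, f in pairs if f.spike_count >= 1]
    return min(firing) if firing else math.nan


def passive_props(
    trace: Trace,
    pulse_start_ms: float,
    pulse_dur_ms: float = 10.0,
    pulse_pa: float = -50.0,
    rmp_window_ms: float = 50.0,
) -> PassiveProps:
    """Input resistance, membrane time constant, and resting potential from
    a small hyperpolarizing pulse.

    The charging transient is fit with V(t) = V0 + dV*(1-exp(-t/tau)); R_in
    uses the fitted steady-state asymptote dV (the pulse is typically
    shorter than tau).  The pulse must be spike-free.
    """
    _require_cc(trace)
    dt = trace.dt_ms
    sl = trace.slice_ms(pulse_start_ms, pulse_start_ms + pulse_dur_ms)
    seg = trace.signal[sl]
    if seg.size < 8:
        raise ValueError("pulse window too short for a fit")
    onset_times = np.asarray(detect_spikes(trace), dtype=float) * dt
    if np.any(
        (onset_times >= pulse_start_ms - 2.0)
        & (onset_times < pulse_start_ms + pulse_dur_ms)
    ):
        raise ValueError("spikes detected inside the passive pulse window")

    t_rel = np.arange(seg.size) * dt
    v0 = float(seg[0])

    def charging(t, dv, tau):
        return v0 + dv * (1.0 - np.exp(-t / tau))

    dv0 = float(seg[-1] - seg[0]) or -1.0
    popt, _ = curve_fit(
        charging, t_rel, seg, p0=(dv0, pulse_dur_ms / 2.0),
        bounds=([-np.inf, 1e-3], [np.inf, 1e4]), maxfev=10000,
    )
    dv_ss, tau = float(popt[0]), float(popt[1])
    r_in = abs(dv_ss) / abs(pulse_pa) * 1000.0  # mV/pA -> GOhm -> MOhm

    i0 = trace.slice_ms(0.0, rmp_window_ms)
    rmp = float(np.mean(trace.signal[i0]))
    return PassiveProps(r_in_mohm=r_in, tau_m_ms=tau, rmp_mv=rmp)


def fi_curve(sweeps) -> FICurve:
    """Firing rate versus step current, with the rheobase attached.

    ``sweeps``: iterable of SweepFeatures (or (current, SweepFeatures)).
    """
    pairs = []
    for item in sweeps:
        if isinstance(item, SweepFeatures):
            pairs.append((item.step_current, item))
        else:
            cur, feat = item
            pairs.append((float(cur), feat))
    if not pairs:
        raise ValueError("fi_curve needs at least one sweep")
    currents = [c for c, _ in pairs]
    if len(set(currents)) != len(currents):
        raise ValueError("duplicate step currents in sweep set")
    pairs.sort(key=lambda p: p[0])
    rates = [f.firing_rate_hz for _, f in pairs]
    return FICurve(
        currents_pa=np.array([c for c, _ in pairs]),
        rates_hz=np.array(rates),
        rheobase_pa=rheobase(pairs),
    )
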