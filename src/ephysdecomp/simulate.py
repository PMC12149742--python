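"""Synthetic patch-clamp data with ground truth.

Simulates the single-compartment model of :mod:`ephysdecomp.model` under
current- or voltage-clamp protocols, generates Poisson trains of synaptic
events, and synthesizes 1-D axon-initial-segment intensity profiles.  Every
generator takes an explicit seed and returns the underlying ground truth
(per-channel currents, true rheobase, event times, analytic edge positions)
so downstream analyses can be tested against an oracle.

Integration uses exponential Euler on both the gating variables and the
membrane potential at a fine internal step (0.005 ms by default), with
outputs decimated to the protocol's acquisition grid (50 kHz by default).
Recording noise is additive Gaussian on the recorded signal only; the
dynamics themselves are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._compat import njit
from .kinetics import (
    a_inf, b_inf, m_inf, h_inf, n_inf,
    tau_a, tau_b, tau_m, tau_h, tau_n,
)
from .model import NeuronModel
from .protocol import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    Protocol,
    Trace,
)

__all__ = [
    "SweepGroundTruth",
    "SimGroundTruth",
    "simulate_neuron",
    "simulate_event_trace",
    "synth_ais_profile",
    "resting_potential",
    "DEFAULT_NOISE_SD_MV",
    "DEFAULT_NOISE_SD_PA",
]

#: default recording-noise standard deviations
DEFAULT_NOISE_SD_MV = 0.2
DEFAULT_NOISE_SD_PA = 5.0

_DT_INTERNAL_MS = 0.005
_SETTLE_MS = 300.0  # un-recorded settling at holding before each sweep


@dataclass
class SweepGroundTruth:
    """Noise-free state and per-channel currents of one simulated sweep,
    sampled on the recorded grid (all currents in pA, v in mV)."""

    v: np.ndarray
    i_na: np.ndarray
    i_dr: np.ndarray
    i_a: np.ndarray
    i_l: np.ndarray
    i_inj: np.ndarray

    @property
    def i_total(self) -> np.ndarray:
        """Summed ionic current (pA)."""
        return self.i_na + self.i_dr + self.i_a + self.i_l


@dataclass
class SimGroundTruth:
    """Ground truth attached to a simulation.

    For neuron simulations ``sweeps`` holds per-sweep channel currents and
    ``true_rheobase_pa`` the smallest step level that fired (None if no sweep
    fired or the protocol is not a current-step family).  For synaptic-event
    simulations ``event_times_s``/``event_amplitudes`` hold the generated
    events.
    """

    sweeps: list[SweepGroundTruth] = field(default_factory=list)
    true_rheobase_pa: float | None = None
    spiking_levels: list[float] = field(default_factory=list)
    event_times_s: np.ndarray | None = None
    event_amplitudes: np.ndarray | None = None


@njit(inline='always')
def _state_deriv(v, m, h, n, a, b, i_cmd, C, gNa, gDR, gA, gL, ENa, EK, EL):
    i_ion = (
        gNa * m * m * m * h * (v - ENa)
        + (gDR * n * n * n * n + gA * a * a * a * b) * (v - EK)
        + gL * (v - EL)
    )
    dv = (i_cmd - i_ion) / C
    dm = (m_inf(v) - m) / tau_m(v)
    dh = (h_inf(v) - h) / tau_h(v)
    dn = (n_inf(v) - n) / tau_n(v)
    da = (a_inf(v) - a) / tau_a(v)
    db = (b_inf(v) - b) / tau_b(v)
    return dv, dm, dh, dn, da, db


@njit
def _run_current_clamp(C, gNa, gDR, gA, gL, ENa, EK, EL,
                       cmd_fine, dt, decim, n_settle, v0):
    # classic RK4 on the full state: the recorded trajectory then satisfies
    # C dV/dt = I_inj - sum(I_ion) to fourth order, which the charge-balance
    # oracle of the AP-current reconstruction relies on
    n_fine = cmd_fine.size
    n_out = n_fine // decim
    v_out = np.empty(n_out)
    ina_out = np.empty(n_out)
    idr_out = np.empty(n_out)
    ia_out = np.empty(n_out)
    il_out = np.empty(n_out)

    v = v0
    m = m_inf(v); h = h_inf(v); n = n_inf(v)
    a = a_inf(v); b = b_inf(v)

    for k in range(-n_settle, n_fine):
        if k >= 0:
            i_cmd = cmd_fine[k]
            if k % decim == 0:
                j = k // decim
                v_out[j] = v
                ina_out[j] = gNa * m * m * m * h * (v - ENa)
                idr_out[j] = gDR * n * n * n * n * (v - EK)
                ia_out[j] = gA * a * a * a * b * (v - EK)
                il_out[j] = gL * (v - EL)
        else:
            i_cmd = cmd_fine[0]  # settle at holding, not recorded
        k1 = _state_deriv(v, m, h, n, a, b, i_cmd, C, gNa, gDR, gA, gL, ENa, EK, EL)
        k2 = _state_deriv(v + 0.5 * dt * k1[0], m + 0.5 * dt * k1[1],
                          h + 0.5 * dt * k1[2], n + 0.5 * dt * k1[3],
                          a + 0.5 * dt * k1[4], b + 0.5 * dt * k1[5],
                          i_cmd, C, gNa, gDR, gA, gL, ENa, EK, EL)
        k3 = _state_deriv(v + 0.5 * dt * k2[0], m + 0.5 * dt * k2[1],
                          h + 0.5 * dt * k2[2], n + 0.5 * dt * k2[3],
                          a + 0.5 * dt * k2[4], b + 0.5 * dt * k2[5],
                          i_cmd, C, gNa, gDR, gA, gL, ENa, EK, EL)
        k4 = _state_deriv(v + dt * k3[0], m + dt * k3[1], h + dt * k3[2],
                          n + dt * k3[3], a + dt * k3[4], b + dt * k3[5],
                          i_cmd, C, gNa, gDR, gA, gL, ENa, EK, EL)
        v = v + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m = m + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        h = h + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        n = n + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        a = a + dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        b = b + dt / 6.0 * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
        if not np.isfinite(v):
            return False, v_out, ina_out, idr_out, ia_out, il_out
    return True, v_out, ina_out, idr_out, ia_out, il_out


@njit
def _run_voltage_clamp(gNa, gDR, gA, gL, ENa, EK, EL,
                       cmd_fine, dt, decim, n_settle):
    n_fine = cmd_fine.size
    n_out = n_fine // decim
    ina_out = np.empty(n_out)
    idr_out = np.empty(n_out)
    ia_out = np.empty(n_out)
    il_out = np.empty(n_out)
    v_out = np.empty(n_out)

    v = cmd_fine[0]
    m = m_inf(v); h = h_inf(v); n = n_inf(v)
    a = a_inf(v); b = b_inf(v)
    for _ in range(n_settle):
        m = m_inf(v) + (m - m_inf(v)) * np.exp(-dt / tau_m(v))
        h = h_inf(v) + (h - h_inf(v)) * np.exp(-dt / tau_h(v))
        n = n_inf(v) + (n - n_inf(v)) * np.exp(-dt / tau_n(v))
        a = a_inf(v) + (a - a_inf(v)) * np.exp(-dt / tau_a(v))
        b = b_inf(v) + (b - b_inf(v)) * np.exp(-dt / tau_b(v))

    for k in range(n_fine):
        v = cmd_fine[k]
        if k % decim == 0:
            j = k // decim
            v_out[j] = v
            ina_out[j] = gNa * m * m * m * h * (v - ENa)
            idr_out[j] = gDR * n * n * n * n * (v - EK)
            ia_out[j] = gA * a * a * a * b * (v - EK)
            il_out[j] = gL * (v - EL)
        m = m_inf(v) + (m - m_inf(v)) * np.exp(-dt / tau_m(v))
        h = h_inf(v) + (h - h_inf(v)) * np.exp(-dt / tau_h(v))
        n = n_inf(v) + (n - n_inf(v)) * np.exp(-dt / tau_n(v))
        a = a_inf(v) + (a - a_inf(v)) * np.exp(-dt / tau_a(v))
        b = b_inf(v) + (b - b_inf(v)) * np.exp(-dt / tau_b(v))
    return True, v_out, ina_out, idr_out, ia_out, il_out


def _fine_grid(protocol: Protocol) -> tuple[float, int]:
    """Internal step and decimation factor for a protocol's sampling."""
    dt_out = protocol.dt_ms
    decim = max(1, int(np.ceil(dt_out / _DT_INTERNAL_MS - 1e-9)))
    return dt_out / decim, decim


def simulate_neuron(
    model: NeuronModel,
    protocol: Protocol,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[list[Trace], SimGroundTruth]:
    """Simulate the model under a protocol; one Trace per sweep level.

    ``noise_sd`` is the SD of additive Gaussian recording noise on the
    recorded signal (mV in current clamp, pA in voltage clamp); ``None``
    selects the mode's default.  Ground-truth channel currents are returned
    noise-free.  Deterministic for a fixed seed.
    """
    protocol.validate()
    if noise_sd is None:
        noise_sd = (
            DEFAULT_NOISE_SD_MV if protocol.mode == CURRENT_CLAMP else DEFAULT_NOISE_SD_PA
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    dt_fine, decim = _fine_grid(protocol)
    n_settle = int(round(_SETTLE_MS / dt_fine))
    rng = np.random.default_rng(seed)

    traces: list[Trace] = []
    gt = SimGroundTruth()
    for s in range(protocol.n_sweeps):
        cmd_fine = protocol.command(s, dt_fine)
        cmd_out = cmd_fine[::decim].copy()
        if protocol.mode == CURRENT_CLAMP:
            ok, v, ina, idr, ia, il = _run_current_clamp(
                model.C, model.g_Na, model.g_DR, model.g_A, model.g_L,
                model.E_Na, model.E_K, model.E_L,
                cmd_fine, dt_fine, decim, n_settle, model.E_L,
            )
            signal = v
        else:
            ok, v, ina, idr, ia, il = _run_voltage_clamp(
                model.g_Na, model.g_DR, model.g_A, model.g_L,
                model.E_Na, model.E_K, model.E_L,
                cmd_fine, dt_fine, decim, n_settle,
            )
            signal = ina + idr + ia + il
        if not ok or not np.all(np.isfinite(signal)):
            raise RuntimeError(
                f"integrator failure (non-finite state) on sweep {s} "
                f"(level {protocol.sweep_levels[s]})"
            )
        noisy = signal + rng.normal(0.0, noise_sd, signal.size) if noise_sd > 0 else signal.copy()
        traces.append(
            Trace(
                dt_ms=protocol.dt_ms,
                signal=noisy,
                command=cmd_out,
                mode=protocol.mode,
                meta={
                    "sweep": s,
                    "level": float(protocol.sweep_levels[s]),
                    "protocol": protocol,
                    "seed": seed,
                    "noise_sd": noise_sd,
                },
            )
        )
        gt.sweeps.append(
            SweepGroundTruth(v=v, i_na=ina, i_dr=idr, i_a=ia, i_l=il, i_inj=cmd_out)
        )

    if protocol.mode == CURRENT_CLAMP and protocol.epochs:
        _attach_true_rheobase(protocol, gt)
    return traces, gt


def _attach_true_rheobase(protocol: Protocol, gt: SimGroundTruth) -> None:
    """Mark spiking sweeps (upward 0 mV crossing of the noise-free voltage
    inside the step epoch) and record the smallest spiking level."""
    try:
        ep = protocol.step_epoch()
    except ValueError:
        return
    dt = protocol.dt_ms
    i0, i1 = int(ep.start_ms / dt), int(ep.end_ms / dt)
    for level, sweep in zip(protocol.sweep_levels, gt.sweeps):
        v = sweep.v[i0:i1]
        crossed = np.any((v[:-1] < 0.0) & (v[1:] >= 0.0))
        if crossed:
            gt.spiking_levels.append(float(level))
    gt.true_rheobase_pa = min(gt.spiking_levels) if gt.spiking_levels else None


def resting_potential(model: NeuronModel, settle_ms: float = 1000.0) -> float:
    """Zero-current resting potential (mV), from a long settling run."""
    proto = Protocol(
        mode=CURRENT_CLAMP,
        holding=0.0,
        duration_ms=settle_ms,
        epochs=[],
        sweep_levels=[0.0],
    )
    traces, _ = simulate_neuron(model, proto, noise_sd=0.0, seed=0)
    return float(traces[0].signal[-1])


# --------------------------------------------------------------------------
# Synaptic events
# --------------------------------------------------------------------------

def biexp_kernel(rise_tau_ms: float, decay_tau_ms: float, dt_ms: float,
                 length_ms: float | None = None) -> np.ndarray:
    """Bi-exponential synaptic kernel, normalized to unit peak."""
    if not decay_tau_ms > rise_tau_ms > 0:
        raise ValueError("need decay_tau > rise_tau > 0")
    if length_ms is None:
        length_ms = rise_tau_ms + 6.0 * decay_tau_ms
    t = np.arange(0.0, length_ms, dt_ms)
    k = np.exp(-t / decay_tau_ms) - np.exp(-t / rise_tau_ms)
    return k / k.max()


def simulate_event_trace(
    rate_hz: float,
    amp_mean: float,
    amp_cv: float,
    rise_tau_ms: float,
    decay_tau_ms: float,
    duration_s: float,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    seed: int = 0,
    sample_rate_hz: float = 50_000.0,
    baseline: float = 0.0,
    mode: str = VOLTAGE_CLAMP,
) -> tuple[Trace, SimGroundTruth]:
    """Poisson train of bi-exponential synaptic events plus recording noise.

    Event amplitudes are log-normal with the stated mean magnitude and
    coefficient of variation; the sign of ``amp_mean`` sets the polarity
    (negative for inward currents).  Ground-truth onset times and signed
    amplitudes are returned sorted by time.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz < 0 or amp_cv < 0 or noise_sd < 0:
        raise ValueError("rate, amp_cv and noise_sd must be non-negative")

    dt_ms = 1000.0 / sample_rate_hz
    n = int(round(duration_s * 1000.0 / dt_ms))
    rng = np.random.default_rng(seed)

    n_events = rng.poisson(rate_hz * duration_s)
    times_s = np.sort(rng.uniform(0.0, duration_s, n_events))
    mag = abs(amp_mean)
    if n_events and mag > 0 and amp_cv > 0:
        sigma2 = np.log1p(amp_cv ** 2)
        mu = np.log(mag) - sigma2 / 2.0
        mags = rng.lognormal(mu, np.sqrt(sigma2), n_events)
    else:
        mags = np.full(n_events, mag)
    amps = np.sign(amp_mean) * mags if amp_mean != 0 else mags

    signal = np.full(n, float(baseline))
    kernel = biexp_kernel(rise_tau_ms, decay_tau_ms, dt_ms)
    for t_s, a in zip(times_s, amps):
        i0 = int(round(t_s * 1000.0 / dt_ms))
        i1 = min(i0 + kernel.size, n)
        if i0 < n:
            signal[i0:i1] += a * kernel[: i1 - i0]
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, n)

    trace = Trace(
        dt_ms=dt_ms,
        signal=signal,
        command=np.zeros(n),
        mode=mode,
        meta={"seed": seed, "rate_hz": rate_hz, "rise_tau_ms": rise_tau_ms,
              "decay_tau_ms": decay_tau_ms, "noise_sd": noise_sd},
    )
    gt = SimGroundTruth(event_times_s=times_s, event_amplitudes=amps)
    return trace, gt


# --------------------------------------------------------------------------
# AIS intensity profiles
# --------------------------------------------------------------------------

def synth_ais_profile(
    start_um: float,
    end_um: float,
    plateau: float = 1000.0,
    edge_sd_um: float = 1.0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    step_um: float = 0.1,
    seed: int = 0,
    margin_um: float | None = None,
):
    """Synthetic Ankyrin-G-like intensity profile along an axon.

    A plateau between ``start_um`` and ``end_um`` with Gaussian-smoothed
    edges of scale ``edge_sd_um`` (a boxcar as ``edge_sd_um`` -> 0), riding
    on ``baseline``, plus optional Gaussian noise.  The analytic
    threshold-crossing positions for any threshold fraction f are

        start + edge_sd * Phi^-1(f)   and   end - edge_sd * Phi^-1(f)

    (Phi the standard normal CDF); the generator records the edge parameters
    in the profile metadata so tests can evaluate them.
    """
    from scipy.stats import norm

    from .ais import AISProfile

    if not 0 <= start_um < end_um:
        raise ValueError("need 0 <= start_um < end_um")
    if not plateau > baseline >= 0:
        raise ValueError("need plateau > baseline >= 0")
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    if margin_um is None:
        margin_um = max(5.0, 5.0 * edge_sd_um)

    x = np.arange(0.0, end_um + margin_um + step_um / 2, step_um)
    if edge_sd_um > 0:
        shape = norm.cdf((x - start_um) / edge_sd_um) - norm.cdf((x - end_um) / edge_sd_um)
    else:
        shape = ((x >= start_um) & (x <= end_um)).astype(float)
    intensity = baseline + (plateau - baseline) * shape
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, x.size)

    return AISProfile(
        distance_um=x,
        intensity=intensity,
        meta={
            "true_start_um": start_um,
            "true_end_um": end_um,
            "edge_sd_um": edge_sd_um,
            "plateau": plateau,
            "baseline": baseline,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def analytic_edge_crossings(
    start_um: float, end_um: float, edge_sd_um: float, threshold_frac: float
) -> tuple[float, float]:
    """Closed-form threshold crossings of the Gaussian-edged profile
    (normalized to its plateau)."""
    from scipy.stats import norm

    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    off = edge_sd_um * norm.ppf(threshold_frac)
    return start_um + off, end_um - off
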