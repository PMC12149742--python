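"""Voltage-clamp step analysis: I/V, pharmacological subtraction, G/V,
Boltzmann activation fits.

The workflow mirrors standard K+-current isolation: record a voltage-step
family in TTx (total K+ current), repeat after adding 4-AP (delayed
rectifier only), subtract the two sweep families samplewise to isolate the
4-AP-sensitive (A-type) component, then measure a per-step statistic
(``peak`` for the inactivating A-current, ``steady`` for the sustained DR),
convert to conductance with g = I/(V - E_rev), normalize to G/Gmax and fit

    G/Gmax = 1 / (1 + exp((V1/2 - V) / k))

The equivalent gating charge z is derived from the slope as z = RT/(F*k),
with RT/F = 25.7 mV at room temperature (25 C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

from .protocol import VOLTAGE_CLAMP, Protocol, Trace

__all__ = [
    "IVCurve",
    "GVCurve",
    "BoltzmannFit",
    "measure_iv",
    "subtract_currents",
    "gv_from_iv",
    "fit_boltzmann",
    "nernst_potential",
    "RT_OVER_F_MV",
    "default_k_reversal",
]

#: RT/F at 25 C (mV)
RT_OVER_F_MV = 25.7

#: default measurement window (ms): steady = last 50 ms of the step,
#: peak = first 50 ms of the step
DEFAULT_WINDOW_MS = 50.0

#: driving-force guard: conductance is only computed for V > E_rev + this (mV)
DRIVING_FORCE_GUARD_MV = 10.0


@dataclass
class IVCurve:
    voltages_mv: np.ndarray
    currents_pa: np.ndarray
    statistic: str  # "steady" | "peak"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        if self.voltages_mv.shape != self.currents_pa.shape:
            raise ValueError("voltages and currents must align")
        if np.any(np.diff(self.voltages_mv) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.statistic not in ("steady", "peak"):
            raise ValueError("statistic must be 'steady' or 'peak'")


@dataclass
class GVCurve:
    voltages_mv: np.ndarray
    g_ns: np.ndarray
    g_norm: np.ndarray
    e_rev_mv: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.g_ns = np.asarray(self.g_ns, dtype=float)
        self.g_norm = np.asarray(self.g_norm, dtype=float)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann activation curve.

    ``v_half`` (mV), ``k_slope`` (mV, > 0), equivalent gating charge
    ``z = RT/(F*k_slope)``, amplitude ``gmax`` (units of the fitted data),
    sum-of-squares ``residual``, and the standard error / 95% CI of v_half.
    """

    v_half_mv: float
    k_slope_mv: float
    z: float
    gmax: float
    residual: float
    v_half_stderr: float | None
    v_half_ci95: tuple[float, float] | None
    k_at_bound: bool = False


def nernst_potential(c_out_mm: float, c_in_mm: float, z: int = 1,
                     rt_over_f_mv: float = RT_OVER_F_MV) -> float:
    """Nernst equilibrium potential (mV) for an ion at the given inner and
    outer concentrations."""
    if c_out_mm <= 0 or c_in_mm <= 0:
        raise ValueError("concentrations must be positive")
    return rt_over_f_mv / z * float(np.log(c_out_mm / c_in_mm))


def default_k_reversal() -> float:
    """K+ Nernst potential for the standard bath (5 mM K+) and pipette
    (120 K-gluconate + 10 KCl = 130 mM K+) solutions at 25 C: about -84 mV.
    Used as the default E_rev for K+-current conductance conversion."""
    return nernst_potential(5.0, 130.0)


def _step_window(sweeps: list[Trace], protocol: Protocol | None):
    if protocol is None:
        protocol = sweeps[0].meta.get("protocol")
    if protocol is None:
        raise ValueError("pass protocol= or provide traces with protocol metadata")
    ep = protocol.step_epoch()
    return protocol, ep


def _check_grid(levels: np.ndarray) -> None:
    if levels.size >= 3:
        diffs = np.diff(levels)
        step = np.min(diffs)
        bad = ~np.isclose(diffs, step, rtol=1e-6, atol=1e-9)
        if np.any(bad):
            missing = []
            for i in np.flatnonzero(bad):
                missing.extend(
                    np.arange(levels[i] + step, levels[i + 1] - step / 2, step).tolist()
                )
            raise ValueError(f"missing step levels: {missing}")


def measure_iv(
    sweeps: list[Trace],
    statistic: str = "steady",
    window_ms: float = DEFAULT_WINDOW_MS,
    protocol: Protocol | None = None,
) -> IVCurve:
    """Per-step current statistic versus command voltage.

    ``steady``: mean current over the last ``window_ms`` of the step.
    ``peak``: the extremum (largest deviation from baseline) within the
    first ``window_ms`` of the step, signed.
    The baseline holding current (mean over the 20 ms before step onset)
    is subtracted in both cases.
    """
    if not sweeps:
        raise ValueError("empty sweep set")
    if statistic not in ("steady", "peak"):
        raise ValueError("statistic must be 'steady' or 'peak'")
    for tr in sweeps:
        if tr.mode != VOLTAGE_CLAMP:
            raise ValueError("measure_iv needs voltage-clamp traces")
    protocol, ep = _step_window(sweeps, protocol)
    if window_ms <= 0 or window_ms > ep.end_ms - ep.start_ms:
        raise ValueError("window must lie inside the step")

    volts, curr = [], []
    for tr in sweeps:
        sl_base = tr.slice_ms(max(0.0, ep.start_ms - 20.0), ep.start_ms)
        base = float(np.mean(tr.signal[sl_base]))
        sl_step = tr.slice_ms(ep.start_ms, ep.end_ms)
        v_cmd = float(np.median(tr.command[sl_step]))
        if statistic == "steady":
            sl = tr.slice_ms(ep.end_ms - window_ms, ep.end_ms)
            val = float(np.mean(tr.signal[sl])) - base
        else:
            sl = tr.slice_ms(ep.start_ms, ep.start_ms + window_ms)
            seg = tr.signal[sl] - base
            val = float(seg[np.argmax(np.abs(seg))])
        volts.append(v_cmd)
        curr.append(val)

    order = np.argsort(volts)
    volts = np.asarray(volts)[order]
    curr = np.asarray(curr)[order]
    _check_grid(volts)
    return IVCurve(volts, curr, statistic, meta={"window_ms": window_ms})


def subtract_currents(total, dr):
    """total - dr, samplewise on sweep families or pointwise on IVCurves.

    Sweep families must share sweep count, sampling and command waveforms;
    IVCurves must share voltage grids and statistic.  Metadata records the
    operand provenance.
    """
    if isinstance(total, IVCurve) and isinstance(dr, IVCurve):
        if total.statistic != dr.statistic:
            raise ValueError("IVCurve statistics differ")
        if total.voltages_mv.shape != dr.voltages_mv.shape or not np.allclose(
            total.voltages_mv, dr.voltages_mv
        ):
            raise ValueError("voltage grids differ")
        return IVCurve(
            total.voltages_mv.copy(),
            total.currents_pa - dr.currents_pa,
            total.statistic,
            meta={"operation": "subtract", "total": total.meta, "dr": dr.meta},
        )
    total_l, dr_l = list(total), list(dr)
    if len(total_l) != len(dr_l):
        raise ValueError("sweep counts differ")
    out = []
    for a, b in zip(total_l, dr_l):
        if a.dt_ms != b.dt_ms or a.signal.size != b.signal.size:
            raise ValueError("sweep grids differ")
        if not np.allclose(a.command, b.command):
            raise ValueError("command waveforms differ between operands")
        out.append(
            Trace(
                dt_ms=a.dt_ms,
                signal=a.signal - b.signal,
                command=a.command.copy(),
                mode=a.mode,
                units=a.units,
                meta={**a.meta, "operation": "subtract"},
            )
        )
    return out


def gv_from_iv(iv: IVCurve, e_rev_mv: float | None = None) -> GVCurve:
    """Convert an I/V curve to conductance, g = I/(V - E_rev), restricted to
    V > E_rev + 10 mV (driving-force guard), normalized to its maximum.

    ``e_rev_mv`` defaults to the K+ Nernst potential of the standard
    solutions (about -84 mV).
    """
    if e_rev_mv is None:
        e_rev_mv = default_k_reversal()
    keep = iv.voltages_mv > e_rev_mv + DRIVING_FORCE_GUARD_MV
    if not np.any(keep):
        raise ValueError(
            f"all voltages within {DRIVING_FORCE_GUARD_MV} mV of E_rev="
            f"{e_rev_mv:.1f} mV; no conductance can be computed"
        )
    v = iv.voltages_mv[keep]
    g = iv.currents_pa[keep] / (v - e_rev_mv)  # pA/mV = nS
    gmax = np.max(g)
    if gmax <= 0:
        raise ValueError("non-positive maximal conductance")
    return GVCurve(v, g, g / gmax, float(e_rev_mv), meta={"statistic": iv.statistic})


def fit_boltzmann(gv, voltages_mv=None) -> BoltzmannFit:
    """Least-squares Boltzmann fit of normalized conductance.

    ``gv`` may be a GVCurve or an array of normalized conductances (then
    pass ``voltages_mv``).  The fit is multi-start from a fixed grid of
    (v_half, k) initializations and is deterministic given the data.
    """
    if isinstance(gv, GVCurve):
        v = gv.voltages_mv
        y = gv.g_norm
    else:
        y = np.asarray(gv, dtype=float)
        v = np.asarray(voltages_mv, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 points spanning the activation rise")

    model = lmfit.Model(
        lambda x, gmax, v_half, k: gmax / (1.0 + np.exp((v_half - x) / k))
    )
    k_min, k_max = 0.5, 60.0
    best = None
    for v0 in np.linspace(v.min(), v.max(), 5):
        for k0 in (5.0, 10.0, 25.0):
            params = model.make_params(gmax=max(y.max(), 1e-6), v_half=v0, k=k0)
            params["k"].set(min=k_min, max=k_max)
            params["gmax"].set(min=1e-9)
            try:
                res = model.fit(y, params, x=v)
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
    if best is None or not best.success:
        raise RuntimeError("Boltzmann fit failed to converge from all starts")

    v_half = float(best.params["v_half"].value)
    k = float(best.params["k"].value)
    gmax = float(best.params["gmax"].value)
    stderr = best.params["v_half"].stderr
    ci = None
    if stderr is not None and np.isfinite(stderr):
        ci = (v_half - 1.96 * stderr, v_half + 1.96 * stderr)
    k_at_bound = bool(np.isclose(k, k_min) or np.isclose(k, k_max))
    return BoltzmannFit(
        v_half_mv=v_half,
        k_slope_mv=k,
        z=RT_OVER_F_MV / k,
        gmax=gmax,
        residual=float(best.chisqr),
        v_half_stderr=None if stderr is None else float(stderr),
        v_half_ci95=ci,
        k_at_bound=k_at_bound,
    )
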