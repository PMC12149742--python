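"""Net ionic current underlying the action potential, from the AP waveform.

The net membrane current is reconstructed from the voltage trajectory as
``i_net = -C * dV/dt`` (pF * mV/ms = pA).  During a current step this equals
the summed ionic current *minus* the injected current; with
``correct_injection=True`` the injected command is added back so the result
is the pure ionic sum.  The current over the AP window is partitioned into
an inward (Na+) lobe between onset and shortly after the peak and an
outward (K+) lobe between the peak and the post-spike minimum, and both
peak amplitudes and transferred charges are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import CURRENT_CLAMP, Trace
from .signal_utils import smoothed_derivative
from .spikes import detect_spikes

__all__ = ["NetCurrent", "net_ion_current"]

#: derivative settings for waveform reconstruction: a short, high-order
#: Savitzky-Golay stencil is near-interpolating, so -C dV/dt tracks the
#: summed channel currents to a fraction of a percent; the wider smoothing
#: used for slope-threshold spike detection would bias the upstroke
RECON_DERIV_WINDOW = 7
RECON_DERIV_POLYORDER = 5

#: window extends this far before the AP onset (ms)
PRE_ONSET_MS = 1.0
#: inward lobe ends this long after the AP peak (ms)
NA_POST_PEAK_MS = 0.5


@dataclass
class NetCurrent:
    """Reconstructed current over one AP window (times in ms, currents pA,
    charges pC).  ``na_peak`` is the magnitude of the inward peak."""

    time_ms: np.ndarray
    i_net: np.ndarray
    i_inj: np.ndarray
    i_corrected: np.ndarray
    corrected_injection: bool
    na_peak_pa: float
    k_peak_pa: float
    na_charge_pc: float
    k_charge_pc: float


def net_ion_current(
    trace: Trace,
    C_pf: float,
    window_ms: tuple[float, float] | None = None,
    correct_injection: bool = False,
    onset_index: int | None = None,
) -> NetCurrent:
    """Reconstruct -C*dV/dt around a single AP and quantify its lobes.

    Parameters
    ----------
    trace : current-clamp voltage trace
    C_pf : membrane capacitance (pF); must be supplied, not estimated
    window_ms : explicit (start, end) analysis window; default is
        onset - 1 ms to the post-spike minimum of the AP at ``onset_index``
    correct_injection : if True, analyze i_net + i_inj (the pure ionic sum);
        if False (default) analyze the raw -C*dV/dt, which still contains
        the injected step
    onset_index : AP onset sample (from detect_spikes); default: the only
        AP in the trace (error if there is not exactly one).
    """
    if trace.mode != CURRENT_CLAMP:
        raise ValueError("net_ion_current needs a current-clamp trace")
    if C_pf <= 0:
        raise ValueError("capacitance must be positive")

    dt = trace.dt_ms
    v = trace.signal
    onsets = detect_spikes(trace)

    if window_ms is None:
        if onset_index is None:
            if len(onsets) != 1:
                raise ValueError(
                    f"trace contains {len(onsets)} APs; pass onset_index or "
                    "window_ms to select exactly one"
                )
            onset_index = onsets[0]
        i_on = int(onset_index)
        nxt = [o for o in onsets if o > i_on]
        i_stop = nxt[0] if nxt else min(v.size, i_on + int(round(20.0 / dt)))
        i_pk = i_on + int(np.argmax(v[i_on:i_stop]))
        i_min = i_pk + int(np.argmin(v[i_pk:i_stop]))
        i0 = max(0, i_on - int(round(PRE_ONSET_MS / dt)))
        i1 = i_min + 1
    else:
        sl = trace.slice_ms(*window_ms)
        i0, i1 = sl.start, sl.stop
        inside = [o for o in onsets if i0 <= o < i1]
        if len(inside) > 1:
            raise ValueError(f"window contains {len(inside)} APs; need at most one")
        i_on = inside[0] if inside else i0
        seg = v[i0:i1]
        i_pk = i0 + int(np.argmax(seg))
        i_min = i_pk + int(np.argmin(v[i_pk:i1])) if i_pk < i1 - 1 else i1 - 1

    t = trace.time_ms[i0:i1]
    dvdt = smoothed_derivative(v, dt, window=RECON_DERIV_WINDOW,
                               polyorder=RECON_DERIV_POLYORDER)[i0:i1]
    i_net = -C_pf * dvdt
    i_inj = trace.command[i0:i1]
    i_corr = i_net + i_inj if correct_injection else i_net

    # inward (Na+) lobe: onset .. peak + 0.5 ms
    na_lo = max(i_on - i0, 0)
    na_hi = min(i_pk - i0 + int(round(NA_POST_PEAK_MS / dt)) + 1, i_corr.size)
    na_seg = i_corr[na_lo:na_hi]
    # outward (K+) lobe: peak .. post-spike minimum
    k_lo = max(i_pk - i0, 0)
    k_seg = i_corr[k_lo:]

    na_peak = float(max(0.0, -np.min(na_seg))) if na_seg.size else 0.0
    k_peak = float(max(0.0, np.max(k_seg))) if k_seg.size else 0.0
    # pA * ms = fC; /1000 -> pC
    na_charge = float(-np.sum(np.minimum(na_seg, 0.0)) * dt / 1000.0) if na_seg.size else 0.0
    k_charge = float(np.sum(np.maximum(k_seg, 0.0)) * dt / 1000.0) if k_seg.size else 0.0

    return NetCurrent(
        time_ms=t,
        i_net=i_net,
        i_inj=i_inj,
        i_corrected=i_corr,
        corrected_injection=correct_injection,
        na_peak_pa=na_peak,
        k_peak_pa=k_peak,
        na_charge_pc=na_charge,
        k_charge_pc=k_charge,
    )
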