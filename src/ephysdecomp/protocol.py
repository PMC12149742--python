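"""Stimulus protocols and recorded traces.

A :class:`Protocol` is a family of sweeps sharing a common epoch layout; a
step family varies one epoch's command level across ``sweep_levels``.  A
:class:`Trace` is one uniformly sampled sweep: the recorded signal (mV in
current clamp, pA in voltage clamp) together with the command waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Epoch",
    "Protocol",
    "Trace",
    "current_step_protocol",
    "current_ramp_protocol",
    "voltage_step_protocol",
    "CURRENT_CLAMP",
    "VOLTAGE_CLAMP",
]

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


@dataclass(frozen=True)
class Epoch:
    """One command epoch.

    ``level`` is the command during the epoch; ``None`` means "use the
    sweep's entry from ``sweep_levels``".  For ramps the command runs
    linearly from ``level`` (or the sweep level) to ``ramp_to`` over the
    epoch.
    """

    start_ms: float
    end_ms: float
    level: float | None = None
    ramp_to: float | None = None


@dataclass
class Protocol:
    """A sweep family: mode, holding command, epochs, and sweep levels."""

    mode: str
    holding: float
    duration_ms: float
    epochs: list[Epoch]
    sweep_levels: list[float] = field(default_factory=lambda: [0.0])
    sample_rate_hz: float = 50_000.0
    inter_sweep_interval_s: float = 5.0  # 0.2 Hz delivery; metadata only

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration_ms <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be positive")
        prev_end = 0.0
        for ep in sorted(self.epochs, key=lambda e: e.start_ms):
            if ep.start_ms < 0 or ep.end_ms > self.duration_ms:
                raise ValueError(
                    f"epoch [{ep.start_ms}, {ep.end_ms}] ms outside protocol "
                    f"duration {self.duration_ms} ms"
                )
            if ep.start_ms >= ep.end_ms:
                raise ValueError("epoch must have start < end")
            if ep.start_ms < prev_end:
                raise ValueError("epochs overlap")
            prev_end = ep.end_ms
        if len(self.sweep_levels) > 1:
            diffs = np.diff(self.sweep_levels)
            if not np.all(diffs > 0):
                raise ValueError("sweep_levels must be strictly increasing")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_levels)

    def n_samples(self, dt_ms: float | None = None) -> int:
        dt = self.dt_ms if dt_ms is None else dt_ms
        return int(round(self.duration_ms / dt))

    def command(self, sweep: int, dt_ms: float | None = None) -> np.ndarray:
        """Command waveform of one sweep, sampled at ``dt_ms`` (default:
        the protocol's own sampling interval)."""
        dt = self.dt_ms if dt_ms is None else dt_ms
        n = self.n_samples(dt)
        t = np.arange(n) * dt
        cmd = np.full(n, float(self.holding))
        level_of_sweep = float(self.sweep_levels[sweep])
        for ep in self.epochs:
            sel = (t >= ep.start_ms) & (t < ep.end_ms)
            lvl = level_of_sweep if ep.level is None else float(ep.level)
            if ep.ramp_to is None:
                cmd[sel] = lvl
            else:
                frac = (t[sel] - ep.start_ms) / (ep.end_ms - ep.start_ms)
                cmd[sel] = lvl + frac * (float(ep.ramp_to) - lvl)
        return cmd

    def step_epoch(self) -> Epoch:
        """The sweep-level-dependent epoch (the main step)."""
        for ep in self.epochs:
            if ep.level is None:
                return ep
        raise ValueError("protocol has no sweep-level-dependent epoch")


@dataclass
class Trace:
    """One uniformly sampled sweep."""

    dt_ms: float
    signal: np.ndarray
    command: np.ndarray
    mode: str
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.signal.shape != self.command.shape:
            raise ValueError("signal and command must have equal length")
        if not self.units:
            self.units = "mV" if self.mode == CURRENT_CLAMP else "pA"

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.signal.size) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.signal.size * self.dt_ms

    def slice_ms(self, start_ms: float, end_ms: float) -> slice:
        """Index slice covering [start_ms, end_ms)."""
        i0 = max(int(np.ceil(start_ms / self.dt_ms - 1e-9)), 0)
        i1 = min(int(np.ceil(end_ms / self.dt_ms - 1e-9)), self.signal.size)
        return slice(i0, i1)


def current_step_protocol(
    start_pa: float = -200.0,
    stop_pa: float = 400.0,
    step_pa: float = 50.0,
    step_onset_ms: float = 100.0,
    step_dur_ms: float = 1000.0,
    holding_pa: float = 0.0,
    passive_pulse: bool = True,
    passive_pulse_pa: float = -50.0,
    passive_pulse_ms: float = 10.0,
    tail_ms: float = 200.0,
    sample_rate_hz: float = 50_000.0,
) -> Protocol:
    """Family of 1-s somatic current steps (default -200..400 pA in 50 pA
    increments) with an optional -50 pA / 10 ms pulse after the step for
    monitoring input resistance and membrane time constant."""
    levels = list(np.arange(start_pa, stop_pa + 0.5 * step_pa, step_pa))
    epochs = [Epoch(step_onset_ms, step_onset_ms + step_dur_ms)]
    t = step_onset_ms + step_dur_ms
    if passive_pulse:
        pulse_start = t + 150.0  # let the membrane settle after the step
        epochs.append(
            Epoch(pulse_start, pulse_start + passive_pulse_ms, level=passive_pulse_pa)
        )
        t = pulse_start + passive_pulse_ms
    return Protocol(
        mode=CURRENT_CLAMP,
        holding=holding_pa,
        duration_ms=t + tail_ms,
        epochs=epochs,
        sweep_levels=levels,
        sample_rate_hz=sample_rate_hz,
    )


def current_ramp_protocol(
    rate_pa_per_ms: float = 4.0,
    start_pa: float = -200.0,
    stop_pa: float = 600.0,
    onset_ms: float = 100.0,
    holding_pa: float = 0.0,
    tail_ms: float = 100.0,
    sample_rate_hz: float = 50_000.0,
) -> Protocol:
    """Continuous current ramp (default 4 pA/ms from -200 to 600 pA)."""
    if rate_pa_per_ms <= 0:
        raise ValueError("ramp rate must be positive")
    ramp_ms = (stop_pa - start_pa) / rate_pa_per_ms
    epochs = [Epoch(onset_ms, onset_ms + ramp_ms, level=start_pa, ramp_to=stop_pa)]
    return Protocol(
        mode=CURRENT_CLAMP,
        holding=holding_pa,
        duration_ms=onset_ms + ramp_ms + tail_ms,
        epochs=epochs,
        sweep_levels=[start_pa],
        sample_rate_hz=sample_rate_hz,
    )


def voltage_step_protocol(
    start_mv: float = -100.0,
    stop_mv: float = 50.0,
    step_mv: float = 10.0,
    holding_mv: float = -80.0,
    step_onset_ms: float = 100.0,
    step_dur_ms: float = 500.0,
    tail_ms: float = 100.0,
    sample_rate_hz: float = 50_000.0,
) -> Protocol:
    """0.5-s voltage steps (default -100..50 mV in 10 mV increments) from a
    -80 mV holding potential."""
    levels = list(np.arange(start_mv, stop_mv + 0.5 * step_mv, step_mv))
    epochs = [Epoch(step_onset_ms, step_onset_ms + step_dur_ms)]
    return Protocol(
        mode=VOLTAGE_CLAMP,
        holding=holding_mv,
        duration_ms=step_onset_ms + step_dur_ms + tail_ms,
        epochs=epochs,
        sweep_levels=levels,
        sample_rate_hz=sample_rate_hz,
    )
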