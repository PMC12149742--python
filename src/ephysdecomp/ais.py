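"""Axon-initial-segment quantification from 1-D intensity profiles.

Consumes Ankyrin-G (or similar AIS marker) fluorescence intensity sampled
along a traced axon as distance/intensity pairs, and calls the AIS start,
middle, end and length by thresholding the smoothed, baseline-subtracted,
peak-normalized profile.  Image processing and neurite tracing are upstream
of this module: it reads two-column tables, not images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AISProfile",
    "AISMeasure",
    "measure_ais",
    "load_profile_csv",
    "aggregate_by_culture",
    "DEFAULT_THRESHOLD_FRAC",
    "DEFAULT_SMOOTH_UM",
]

#: fraction of the normalized peak used to call start/end positions
DEFAULT_THRESHOLD_FRAC = 0.33
#: moving-average smoothing window (µm)
DEFAULT_SMOOTH_UM = 1.0


@dataclass
class AISProfile:
    """Intensity versus distance from the soma edge, on a uniform grid."""

    distance_um: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance_um.ndim != 1 or self.distance_um.shape != self.intensity.shape:
            raise ValueError("distance and intensity must be equal-length 1-D arrays")
        if self.distance_um.size < 4:
            raise ValueError("profile too short")
        steps = np.diff(self.distance_um)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("distance must be a uniformly increasing grid")
        if self.distance_um[0] < -1e-9:
            raise ValueError("distances must start at >= 0")

    @property
    def step_um(self) -> float:
        return float(self.distance_um[1] - self.distance_um[0])


@dataclass(frozen=True)
class AISMeasure:
    """Called AIS positions (µm from the soma edge)."""

    start_um: float
    middle_um: float
    end_um: float
    length_um: float
    threshold_frac: float

    def __post_init__(self) -> None:
        if not self.start_um < self.middle_um < self.end_um:
            raise ValueError("expected start < middle < end")


def measure_ais(
    profile: AISProfile,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    smooth_window_um: float = DEFAULT_SMOOTH_UM,
) -> AISMeasure:
    """Call AIS start/middle/end/length from an intensity profile.

    The profile is smoothed with a moving average of width
    ``smooth_window_um``, baseline-subtracted (baseline = mean of the first
    and last 10% of samples, robust to soma bleed-through) and normalized to
    its maximum.  The start is the first crossing above ``threshold_frac``,
    the end the last, both refined by sub-grid linear interpolation.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    x = profile.distance_um
    y = profile.intensity.copy()
    step = profile.step_um

    win = max(1, int(round(smooth_window_um / step)))
    if win > 1:
        kernel = np.ones(win) / win
        # reflect-pad so edges are not biased toward zero
        pad = win // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="same")[pad:pad + x.size]

    n_tail = max(1, x.size // 10)
    baseline = 0.5 * (y[:n_tail].mean() + y[-n_tail:].mean())
    peak = y.max()
    if peak <= baseline:
        raise ValueError("profile has no intensity above baseline")
    norm = (y - baseline) / (peak - baseline)

    above = norm >= threshold_frac
    if not above.any():
        raise ValueError("no samples above threshold")
    first = int(np.argmax(above))
    last = int(x.size - 1 - np.argmax(above[::-1]))
    if first == 0 or last == x.size - 1:
        raise ValueError(
            "profile is clipped: intensity does not fall below threshold at "
            "both ends; extend the traced profile"
        )

    def interp_cross(i_lo: int, i_hi: int) -> float:
        # linear interpolation of the threshold crossing between two samples
        y0, y1 = norm[i_lo], norm[i_hi]
        if y1 == y0:
            return float(x[i_hi])
        frac = (threshold_frac - y0) / (y1 - y0)
        return float(x[i_lo] + frac * (x[i_hi] - x[i_lo]))

    start = interp_cross(first - 1, first)
    end = interp_cross(last + 1, last)
    return AISMeasure(
        start_um=start,
        middle_um=0.5 * (start + end),
        end_um=end,
        length_um=end - start,
        threshold_frac=threshold_frac,
    )


def load_profile_csv(path) -> AISProfile:
    """Read a two-column (distance_um, intensity) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected a two-column CSV (distance_um, intensity)")
    return AISProfile(
        distance_um=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        meta={"source": str(path)},
    )


def aggregate_by_culture(measures: pd.DataFrame) -> pd.DataFrame:
    """Average per-cell AIS measures within each culture.

    ``measures`` must have columns ``culture_id`` plus numeric measure
    columns (e.g. start_um/middle_um/end_um/length_um); returns one row per
    culture with the cell means.
    """
    if "culture_id" not in measures.columns:
        raise ValueError("measures table needs a culture_id column")
    return measures.groupby("culture_id").mean(numeric_only=True).reset_index()
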