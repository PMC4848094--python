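"""Polysome A254 sucrose-gradient trace quantification.

The quantification follows a minima-as-boundaries scheme: after optional
moving-average smoothing, local minima of the absorbance curve (plus both
endpoints) delimit the peaks; the baseline is the chord connecting the
lowest minimum in the first half of the trace with the lowest minimum in
the second half; each peak's value is the trapezoidal integral of the
curve above that baseline. Peaks are then labeled positionally — 40S, 60S,
80S, then polysome_2, polysome_3, ... — giving the free-subunit 60S/40S
ratio and the polysome/monosome (P/M) ratio, i.e. summed polysome area
over the 80S monosome area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "PolysomeTrace",
    "Peak",
    "PeakSet",
    "RatioResult",
    "find_minima",
    "build_baseline",
    "integrate_peaks",
    "label_and_ratios",
    "quantify_trace",
]


@dataclass(frozen=True)
class PolysomeTrace:
    """Sampled A254 curve: strictly increasing positions, >= 16 samples."""

    positions: np.ndarray
    a254: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.a254, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "a254", val)
        if pos.shape != val.shape or pos.ndim != 1:
            raise DataError("trace: positions and a254 must be equal-length vectors")
        if len(pos) < 16:
            raise DataError("trace: need >= 16 samples")
        if not np.all(np.diff(pos) > 0):
            raise DataError("trace: positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"position": self.positions, "a254": self.a254}).to_csv(
            path, index=False, float_format="%.8g"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PolysomeTrace":
        df = pd.read_csv(path)
        cols = [c.lower() for c in df.columns]
        if "position" in cols and "a254" in cols:
            df.columns = cols
            return cls(df["position"].to_numpy(), df["a254"].to_numpy())
        # headerless two-column fallback
        df = pd.read_csv(path, header=None)
        if df.shape[1] != 2:
            raise DataError(f"{path}: expected columns position,a254")
        return cls(df[0].to_numpy(float), df[1].to_numpy(float))


@dataclass(frozen=True)
class Peak:
    left: int  # boundary indices into the trace
    right: int
    apex_position: float
    area: float
    label: str = ""


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]
    baseline: tuple[float, float]  # (slope, intercept) in position units

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.label for p in self.peaks],
                "left": [p.left for p in self.peaks],
                "right": [p.right for p in self.peaks],
                "apex_position": [p.apex_position for p in self.peaks],
                "area": [p.area for p in self.peaks],
            }
        )


@dataclass(frozen=True)
class RatioResult:
    """60S/40S and polysome/monosome ratios with the areas behind them."""

    ratio_60_40: Optional[float]
    ratio_p_m: Optional[float]
    components: dict[str, float]


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    if window >= len(values):
        raise DataError("smooth_window must be smaller than the trace length")
    # truncated-window mean: near the edges, average only the samples that
    # exist, so endpoint values are not overweighted
    kernel = np.ones(window)
    sums = np.convolve(values.astype(float), kernel, mode="same")
    norms = np.convolve(np.ones(len(values)), kernel, mode="same")
    return sums / norms


def find_minima(
    trace: PolysomeTrace,
    smooth_window: Optional[int] = None,
    min_separation: Optional[int] = None,
    min_prominence: Optional[float] = None,
) -> np.ndarray:
    """Peak-boundary indices: both endpoints plus filtered interior minima.

    On the (optionally smoothed) curve, peaks with topographic prominence
    of at least ``min_prominence`` (default 5% of the dynamic range) are
    located and the lowest sample between each consecutive pair becomes a
    boundary minimum — so minima separating only sub-prominence bumps are
    dropped, merging their segments. Boundary minima closer than
    ``min_separation`` samples (default 2% of the trace length) are merged
    keeping the lower. Interior boundaries are, by construction, strictly
    lower than their neighbors on the smoothed curve.
    """
    from scipy.signal import find_peaks

    if smooth_window is None:
        smooth_window = max(5, len(trace) // 50)
    y = _smooth(trace.a254, smooth_window)
    n = len(y)
    if min_separation is None:
        min_separation = max(1, int(round(0.02 * n)))
    if min_prominence is None:
        min_prominence = 0.05 * float(np.ptp(y))

    apexes, _ = find_peaks(y, prominence=min_prominence)
    apexes = list(apexes)
    # an endpoint acts as an apex when the curve falls away from it and it
    # rises sufficiently above the global minimum (e.g. a V-shaped trace)
    if y[0] > y[1] and y[0] - y.min() >= min_prominence:
        apexes.insert(0, 0)
    if y[-1] > y[-2] and y[-1] - y.min() >= min_prominence:
        apexes.append(n - 1)
    interior = [
        int(left + np.argmin(y[left : right + 1]))
        for left, right in zip(apexes[:-1], apexes[1:])
    ]

    # merge close minima, keeping the lower
    merged: list[int] = []
    for i in interior:
        if merged and i - merged[-1] < min_separation:
            if y[i] < y[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return np.array([0] + [i for i in merged if 0 < i < n - 1] + [n - 1], dtype=int)


def build_baseline(
    trace: PolysomeTrace, minima: np.ndarray, smooth_window: int = 1
) -> tuple[float, float]:
    """Baseline chord: lowest minimum in each half of the trace, connected.

    Halves are split at the midpoint position. If a half contains no
    boundary minimum the half's endpoint is used instead, with a warning.
    Anchor *values* are read from a more heavily smoothed curve (5x the
    detection window) so that picking the lowest of several noisy minima
    does not drag the baseline down. Returns (slope, intercept) over
    position.
    """
    anchor_window = 1 if smooth_window <= 1 else min(5 * smooth_window, len(trace) // 4)
    pos, val = trace.positions, _smooth(trace.a254, anchor_window)
    mid = 0.5 * (pos[0] + pos[-1])
    halves = []
    for predicate, fallback in (
        (lambda p: p <= mid, 0),
        (lambda p: p > mid, len(pos) - 1),
    ):
        candidates = [i for i in minima if predicate(pos[i])]
        if not candidates:
            warnings.warn("build_baseline: no minimum in one half; using its endpoint")
            candidates = [fallback]
        halves.append(min(candidates, key=lambda i: (val[i], i)))
    i1, i2 = halves
    if pos[i2] == pos[i1]:
        return 0.0, float(val[i1])
    slope = (val[i2] - val[i1]) / (pos[i2] - pos[i1])
    return float(slope), float(val[i1] - slope * pos[i1])


def integrate_peaks(
    trace: PolysomeTrace,
    minima: np.ndarray,
    baseline: tuple[float, float],
    noise_floor_frac: float = 0.01,
    smooth_window: int = 1,
) -> PeakSet:
    """Trapezoidal integral above baseline per inter-minima segment.

    The integrand is the (optionally smoothed) curve minus the baseline,
    clipped to zero — integrating the smoothed curve keeps rectified noise
    in near-baseline stretches from counting as peak area; boxcar
    smoothing conserves the integral of real peaks.
    Segments with area below ``noise_floor_frac`` of the largest segment's
    area are discarded as noise.
    """
    if minima[0] != 0 or minima[-1] != len(trace) - 1:
        raise DataError("integrate_peaks: minima must include both trace endpoints")
    slope, intercept = baseline
    y = _smooth(trace.a254, smooth_window)
    above = np.clip(y - (slope * trace.positions + intercept), 0.0, None)
    peaks = []
    for left, right in zip(minima[:-1], minima[1:]):
        seg = slice(left, right + 1)
        area = float(np.trapezoid(above[seg], trace.positions[seg]))
        apex = left + int(np.argmax(above[seg]))
        peaks.append(Peak(int(left), int(right), float(trace.positions[apex]), area))
    max_area = max((p.area for p in peaks), default=0.0)
    kept = tuple(p for p in peaks if p.area > noise_floor_frac * max_area and p.area > 0)
    return PeakSet(kept, baseline)


def label_and_ratios(peaks: PeakSet) -> tuple[PeakSet, RatioResult]:
    """Label peaks positionally and compute the 60S/40S and P/M ratios.

    The first three retained peaks in gradient order are 40S, 60S and 80S;
    later peaks are polysome_2, polysome_3, ... With fewer than three peaks
    only the computable ratios are emitted and the rest are None.
    """
    labels = ["40S", "60S", "80S"] + [
        f"polysome_{k}" for k in range(2, 2 + max(0, len(peaks.peaks) - 3))
    ]
    labeled = tuple(
        Peak(p.left, p.right, p.apex_position, p.area, labels[i])
        for i, p in enumerate(peaks.peaks)
    )
    areas = {p.label: p.area for p in labeled}
    ratio_60_40 = (
        areas["60S"] / areas["40S"]
        if "60S" in areas and areas.get("40S", 0) > 0
        else None
    )
    poly_total = sum(a for lbl, a in areas.items() if lbl.startswith("polysome"))
    ratio_p_m = poly_total / areas["80S"] if areas.get("80S", 0) > 0 else None
    components = dict(areas)
    components["polysome_total"] = poly_total
    return PeakSet(labeled, peaks.baseline), RatioResult(ratio_60_40, ratio_p_m, components)


def quantify_trace(
    trace: PolysomeTrace,
    smooth_window: Optional[int] = None,
    min_separation: Optional[int] = None,
    min_prominence: Optional[float] = None,
    noise_floor_frac: float = 0.01,
) -> tuple[PeakSet, RatioResult]:
    """Full trace quantification: minima, baseline, integration, labeling."""
    if smooth_window is None:
        smooth_window = max(5, len(trace) // 50)
    minima = find_minima(trace, smooth_window, min_separation, min_prominence)
    baseline = build_baseline(trace, minima, smooth_window)
    peaks = integrate_peaks(trace, minima, baseline, noise_floor_frac, smooth_window)
    return label_and_ratios(peaks)
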