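"""Chromatogram integration and dequenching-rate analytics.

Size-exclusion chromatography (SEC) traces are smoothed with a
Savitzky-Golay filter (default window 1000 points, polynomial order 2 —
appropriate for finely sampled traces of ~0.002 mL/point), peaks are
detected with amplitude/distance/prominence thresholds, and integrated areas
under the curve (IAUC) are computed over explicit elution-volume windows by
the trapezoidal rule with linear interpolation at the window edges.

Fluorescence-dequenching disassembly traces are summarized by the ordinary
least-squares slope over a stated linear fit window (default 95-350 s);
relative activity of two enzyme forms is the ratio of slopes with
first-order error propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import linregress

__all__ = [
    "Chromatogram",
    "PeakSet",
    "KineticTrace",
    "read_chromatogram",
    "read_trace",
    "smooth_chromatogram",
    "subtract_linear_baseline",
    "find_chromatogram_peaks",
    "integrate_window",
    "disassembly_rate",
    "rate_ratio",
]


@dataclass
class Chromatogram:
    """An elution trace: volume (mL, strictly increasing) vs absorbance (mAU)."""

    volume: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.volume.ndim != 1 or self.volume.shape != self.absorbance.shape:
            raise ValueError("volume and absorbance must be equal-length 1-D arrays")
        if self.volume.size < 2:
            raise ValueError("a chromatogram needs at least 2 points")
        if not np.all(np.diff(self.volume) > 0):
            raise ValueError("volume must be strictly increasing")


@dataclass
class PeakSet:
    """Detected peaks: (apex_volume mL, apex_absorbance mAU, prominence mAU)."""

    peaks: list[tuple[float, float, float]]
    integration_windows: list[tuple[float, float, float]] = field(default_factory=list)
    # each window is (lo mL, hi mL, area mAU*mL)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.peaks, columns=["apex_volume_mL", "apex_absorbance_mAU", "prominence_mAU"]
        )


@dataclass
class KineticTrace:
    """Time course of a fluorescence signal with a linear fit window (s)."""

    time: np.ndarray
    signal: np.ndarray
    fit_window: tuple[float, float] = (95.0, 350.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be equal-length 1-D arrays")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


def _read_two_columns(path, names: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    a = cols.get(names[0].lower(), df.columns[0])
    b = cols.get(names[1].lower(), df.columns[1])
    return df[a].to_numpy(float), df[b].to_numpy(float)


def read_chromatogram(path, label: str | None = None) -> Chromatogram:
    """Read a 2-column CSV/TSV trace (volume_mL, absorbance_mAU)."""
    v, a = _read_two_columns(path, ("volume_mL", "absorbance_mAU"))
    return Chromatogram(v, a, label=label or Path(path).stem)


def read_trace(path, fit_window=(95.0, 350.0), label: str | None = None) -> KineticTrace:
    """Read a 2-column CSV/TSV time course (time_s, signal)."""
    t, s = _read_two_columns(path, ("time_s", "signal"))
    return KineticTrace(t, s, fit_window=tuple(fit_window), label=label or Path(path).stem)


def smooth_chromatogram(
    chrom: Chromatogram, window: int = 1000, polyorder: int = 2
) -> Chromatogram:
    """Savitzky-Golay smoothing; the window is clamped to the largest odd
    value not exceeding the series length."""
    n = chrom.volume.size
    if n < polyorder + 2:
        raise ValueError(f"series of {n} points is too short for polyorder {polyorder}")
    w = min(int(window), n)
    if w % 2 == 0:
        w -= 1
    w = max(w, polyorder + 1 + (polyorder % 2))  # smallest valid odd window
    smoothed = savgol_filter(chrom.absorbance, window_length=w, polyorder=polyorder)
    return Chromatogram(chrom.volume.copy(), smoothed, label=chrom.label + "_filtered")


def subtract_linear_baseline(
    chrom: Chromatogram, region: tuple[float, float]
) -> Chromatogram:
    """Optional baseline correction: subtract the least-squares line fitted
    over a stated flat region (mL)."""
    lo, hi = region
    mask = (chrom.volume >= lo) & (chrom.volume <= hi)
    if mask.sum() < 2:
        raise ValueError(f"baseline region {region} contains fewer than 2 points")
    fit = linregress(chrom.volume[mask], chrom.absorbance[mask])
    corrected = chrom.absorbance - (fit.intercept + fit.slope * chrom.volume)
    return Chromatogram(chrom.volume.copy(), corrected, label=chrom.label + "_baselined")


def find_chromatogram_peaks(
    chrom: Chromatogram,
    min_height: float = 10.0,
    min_distance_ml: float = 1.0,
    min_prominence: float = 0.5,
) -> PeakSet:
    """Local maxima above ``min_height`` mAU, separated by at least
    ``min_distance_ml`` mL, with prominence above ``min_prominence`` mAU.

    The distance threshold is converted to samples using the median volume
    step; non-uniform sampling (>5% step spread) triggers a warning because
    that conversion is then only approximate.
    """
    steps = np.diff(chrom.volume)
    step = float(np.median(steps))
    if steps.size and (steps.max() - steps.min()) > 0.05 * step:
        warnings.warn(
            "non-uniform volume sampling (>5% step variation); the distance "
            "threshold conversion to samples is approximate",
            stacklevel=2,
        )
    distance = max(1, int(round(min_distance_ml / step)))
    idx, props = find_peaks(
        chrom.absorbance,
        height=min_height,
        distance=distance,
        prominence=min_prominence,
    )
    peaks = [
        (float(chrom.volume[i]), float(chrom.absorbance[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    return PeakSet(peaks=peaks)


def integrate_window(chrom: Chromatogram, lo: float, hi: float) -> float:
    """Trapezoidal integral of absorbance over [lo, hi] mL (units mAU*mL),
    with linear interpolation at the window edges."""
    if not (lo < hi):
        raise ValueError(f"empty integration window [{lo}, {hi}]")
    v, a = chrom.volume, chrom.absorbance
    if lo < v[0] or hi > v[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] outside the recorded volume range [{v[0]}, {v[-1]}]"
        )
    inner = (v > lo) & (v < hi)
    grid = np.concatenate(([lo], v[inner], [hi]))
    vals = np.concatenate(([np.interp(lo, v, a)], a[inner], [np.interp(hi, v, a)]))
    return float(np.trapezoid(vals, grid))


def disassembly_rate(trace: KineticTrace) -> tuple[float, float]:
    """OLS slope (signal/s) and its standard error over the fit window."""
    lo, hi = trace.fit_window
    mask = (trace.time >= lo) & (trace.time <= hi)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} points in fit window [{lo}, {hi}]; need >= 3")
    fit = linregress(trace.time[mask], trace.signal[mask])
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return float(fit.slope), stderr


def rate_ratio(
    a: tuple[float, float], b: tuple[float, float]
) -> tuple[float, float]:
    """Ratio of two slopes with first-order error propagation.

    ``a`` and ``b`` are (slope, stderr) pairs; returns (ratio, stderr).
    """
    sa, ea = a
    sb, eb = b
    if abs(sb) <= 1e-300 or abs(sb) <= 1e-12 * abs(sa):
        raise ValueError("denominator slope is (near) zero; ratio undefined")
    ratio = sa / sb
    err = abs(ratio) * np.sqrt((ea / sa) ** 2 + (eb / sb) ** 2) if sa != 0 else abs(ea / sb)
    return float(ratio), float(err)
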