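"""Label-removal calibration: dilution standard curves and membrane line profiles.

A serial dilution of labelled lysate into unlabelled lysate gives a
standard curve (signal vs dilution fraction, log-log linear for geometric
dilutions in the linear range); the residual signal after a removal
treatment (e.g. MESNa reduction of a disulfide-linked label) is read off
the inverted curve. When the treated signal falls below the lowest
standard, the estimate is reported as a bound ("more than X% removed").

Line profiles drawn across the plasma membrane, peak-aligned and averaged,
quantify removal per channel directly on images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .scenes import DilutionSeries

__all__ = [
    "RemovalEstimate",
    "StandardCurve",
    "ProfileSet",
    "fit_standard_curve",
    "estimate_removal",
    "extract_and_average_profiles",
    "profile_removal_ratio",
]


@dataclass(frozen=True)
class StandardCurve:
    """Log-log linear calibration: log(signal) = slope·log(fraction) + intercept."""

    slope: float
    intercept: float
    fraction_range: tuple[float, float]
    signal_range: tuple[float, float]

    def signal_to_fraction(self, signal: float) -> float:
        if signal <= 0:
            raise ValueError("signal must be positive to invert the log-log curve")
        return float(np.exp((np.log(signal) - self.intercept) / self.slope))


@dataclass(frozen=True)
class RemovalEstimate:
    """Residual label fraction after treatment; bound_flag marks estimates
    below the lowest standard, where residual_fraction is an upper bound."""

    residual_fraction: float
    bound_flag: bool = False

    @property
    def removal_percent(self) -> float:
        return 100.0 * (1.0 - self.residual_fraction)

    def describe(self) -> str:
        if self.bound_flag:
            return f"more than {self.removal_percent:.4g}% removed"
        return f"{self.removal_percent:.4g}% removed"


@dataclass(frozen=True)
class ProfileSet:
    """Peak-aligned line profiles and their average trace, per channel."""

    profiles: Mapping[str, np.ndarray]  # channel -> (n_lines, n_points)
    average: Mapping[str, np.ndarray]  # channel -> (n_points,)

    def peak(self, channel: str) -> float:
        return float(np.max(self.average[channel]))


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """Least-squares linear fit of log(signal) vs log(fraction).

    Requires at least three standards spanning at least two decades of
    dilution, with signal monotonically increasing in fraction.
    """
    fr, sig = series.fractions, series.signals
    if fr.size < 3:
        raise ValueError("need at least 3 standards")
    if fr.max() / fr.min() < 100:
        raise ValueError("standards must span at least two decades of dilution")
    if np.any(sig <= 0):
        raise ValueError("standard signals must be positive")
    order = np.argsort(fr)
    if np.any(np.diff(sig[order]) <= 0):
        raise ValueError("standard signals must increase monotonically with fraction")
    slope, intercept = np.polyfit(np.log(fr), np.log(sig), 1)
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        fraction_range=(float(fr.min()), float(fr.max())),
        signal_range=(float(sig.min()), float(sig.max())),
    )


def estimate_removal(
    series: DilutionSeries, curve: StandardCurve | None = None
) -> RemovalEstimate:
    """Removal efficiency of the treatment from the dilution series.

    The treated signal is mapped through the inverted standard curve. If it
    falls below the lowest standard's signal, the lowest standard fraction
    is reported as an upper bound on the residual (bound_flag set), i.e.
    "more than 100·(1−f_min)% removed". A treated signal above the
    undiluted standard would imply negative removal and is an error.
    """
    if curve is None:
        curve = fit_standard_curve(series)
    treated = series.treated_signal
    sig_min, sig_max = curve.signal_range
    if treated > sig_max:
        raise ValueError("treated signal exceeds the undiluted standard: removal negative")
    if treated <= sig_min:
        return RemovalEstimate(residual_fraction=curve.fraction_range[0], bound_flag=True)
    return RemovalEstimate(residual_fraction=curve.signal_to_fraction(treated))


def _sample_line(
    img: np.ndarray, start: Sequence[float], end: Sequence[float], n_points: int
) -> np.ndarray:
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0.0, 1.0, n_points)
    coords = start[:, None] * (1 - t) + end[:, None] * t
    return ndimage.map_coordinates(
        np.asarray(img, dtype=float), coords, order=1, mode="nearest"
    )


def extract_and_average_profiles(
    channels: Mapping[str, np.ndarray],
    lines: Sequence[tuple[Sequence[float], Sequence[float]]],
    n_points: int = 101,
    cell_mask: np.ndarray | None = None,
) -> ProfileSet:
    """Sample intensity profiles along lines crossing the membrane and
    average them after aligning each profile on its intensity peak.

    Lines are ((y0, x0), (y1, x1)) endpoint pairs in pixel coordinates,
    sampled bilinearly at ``n_points`` evenly spaced positions. If a
    ``cell_mask`` is given, lines that do not cross the mask boundary
    exactly once are skipped with a warning. Alignment shifts each profile
    so its maximum sits at the trace center (edge values padded).
    """
    if len(lines) < 1:
        raise ValueError("need at least one line")
    keep = []
    for i, (p0, p1) in enumerate(lines):
        if cell_mask is not None:
            inside = _sample_line(cell_mask.astype(float), p0, p1, n_points) > 0.5
            n_cross = int(np.abs(np.diff(inside.astype(int))).sum())
            if n_cross != 1:
                warnings.warn(f"line {i} crosses the cell boundary {n_cross} times; skipped")
                continue
        keep.append((p0, p1))
    if not keep:
        raise ValueError("no usable lines (none crosses the membrane exactly once)")

    center = n_points // 2
    profiles, average = {}, {}
    for name, img in channels.items():
        rows = []
        for p0, p1 in keep:
            prof = _sample_line(img, p0, p1, n_points)
            shift = center - int(np.argmax(prof))
            rows.append(np.roll(prof, shift))
        arr = np.vstack(rows)
        profiles[name] = arr
        average[name] = arr.mean(axis=0)
    return ProfileSet(profiles=profiles, average=average)


def profile_removal_ratio(
    control: ProfileSet, treated: ProfileSet
) -> dict[str, float]:
    """Per-channel removal percent from average-trace peak heights.

    removal% = 100 × (1 − treated peak / control peak); supports the
    two-channel differential readout (reducible vs non-reducible label on
    the same structure). A zero control peak makes the channel undefined
    (NaN, with a warning).
    """
    out = {}
    for name in control.average:
        if name not in treated.average:
            raise ValueError(f"channel {name!r} missing from treated profiles")
        cp, tp = control.peak(name), treated.peak(name)
        if cp == 0:
            warnings.warn(f"channel {name!r}: control peak is zero; removal undefined")
            out[name] = float("nan")
        else:
            out[name] = 100.0 * (1.0 - tp / cp)
    return out
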