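"""Pixel-mask co-localisation and per-cell uptake quantification.

One channel of a two-colour image (the mask channel, e.g. transferrin) is
blurred, thresholded at the base of its intensity histogram and dilated into
a binary mask; the co-localised fraction is then the share of the (black-
level-zeroed) signal channel's intensity that falls on mask-positive pixels
inside a region of interest. A chance-overlap control repeats the
measurement with the mask channel translated ~500 nm out of register.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskSpec",
    "ColocResult",
    "CellUptake",
    "blur_channel",
    "estimate_black_level",
    "build_mask",
    "masked_fraction",
    "offset_overlap_control",
    "cell_mean_uptake",
]


@dataclass(frozen=True)
class MaskSpec:
    """Parameters of the binary-mask construction.

    ``blur_sigma`` is the Gaussian pre-blur in pixels (0.7 matches routine
    confocal noise reduction); the black level is the intensity at which the
    histogram falls to ``black_level_fraction`` of its modal (background)
    bin count; ``dilation_radius`` grows mask-positive pixels with a square
    structuring element of side ``2r+1``.
    """

    blur_sigma: float = 0.7
    black_level_fraction: float = 1e-3
    black_level_bins: int = 1024
    dilation_radius: int = 1

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")
        if self.dilation_radius < 0 or int(self.dilation_radius) != self.dilation_radius:
            raise ValueError("dilation_radius must be a non-negative integer")
        if not (0 < self.black_level_fraction < 1):
            raise ValueError("black_level_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ColocResult:
    """Share of signal intensity on mask-positive pixels within an ROI."""

    total_intensity: float
    masked_intensity: float
    n_rois: int = 1

    @property
    def percent_coloc(self) -> float:
        if self.total_intensity == 0:
            return float("nan")
        return 100.0 * self.masked_intensity / self.total_intensity

    @property
    def defined(self) -> bool:
        return self.total_intensity != 0


@dataclass(frozen=True)
class CellUptake:
    """Background-subtracted, control-normalised mean intensity of one cell.

    Negative values are retained: cell-to-cell variability can put a cell
    below the empirically determined background.
    """

    cell_id: int
    mean_intensity: float
    normalised_value: float


def blur_channel(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur; ``sigma=0`` returns the input unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    channel = np.asarray(channel, dtype=float)
    if sigma == 0:
        return channel.copy()
    return ndimage.gaussian_filter(channel, sigma=sigma, mode="nearest")


def estimate_black_level(
    channel: np.ndarray,
    fraction: float = 1e-3,
    n_bins: int = 1024,
) -> float:
    """Intensity at the base of the background peak of the histogram.

    Formalises the manual "set the black level at the base of the
    histogram" step: find the modal (background) bin, then scan upward and
    return the left edge of the first bin whose count falls below
    ``fraction`` of the modal count. Monotone in ``fraction``.
    """
    values = np.asarray(channel, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty channel")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        warnings.warn("flat histogram: all pixels equal; black level is that value")
        return lo
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    mode = int(np.argmax(counts))
    floor = fraction * counts[mode]
    for i in range(mode + 1, n_bins):
        if counts[i] < floor:
            return float(edges[i])
    return hi


def build_mask(channel: np.ndarray, spec: MaskSpec = MaskSpec()) -> np.ndarray:
    """Blur, threshold at the black level, and dilate into a binary mask."""
    blurred = blur_channel(channel, spec.blur_sigma)
    if np.all(blurred == blurred.flat[0]) and blurred.flat[0] == 0:
        return np.zeros_like(blurred, dtype=bool)
    level = estimate_black_level(
        blurred, fraction=spec.black_level_fraction, n_bins=spec.black_level_bins
    )
    mask = blurred > level
    r = int(spec.dilation_radius)
    if r > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=np.ones((2 * r + 1,) * mask.ndim, bool))
    return mask


def _zeroed(signal: np.ndarray, black_level: float | None) -> np.ndarray:
    signal = np.asarray(signal, dtype=float)
    if black_level is None:
        black_level = estimate_black_level(signal)
    return np.clip(signal - black_level, 0.0, None)


def masked_fraction(
    signal: np.ndarray,
    mask: np.ndarray,
    roi: np.ndarray | None = None,
    black_level: float | None = None,
) -> ColocResult:
    """Percent of ROI signal intensity lying on mask-positive pixels.

    The signal channel is black-level-zeroed (level estimated from its
    histogram unless given) before summation, mirroring how the background
    of the measured channel is zeroed before the logical AND.
    """
    signal = np.asarray(signal)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != signal.shape:
        raise ValueError("signal and mask shapes differ")
    if roi is None:
        roi = np.ones_like(mask)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != signal.shape:
        raise ValueError("roi shape differs from signal")
    if not roi.any():
        raise ValueError("empty ROI")
    z = _zeroed(signal, black_level)
    total = float(z[roi].sum())
    masked = float(z[mask & roi].sum())
    return ColocResult(total_intensity=total, masked_intensity=masked)


def offset_overlap_control(
    signal: np.ndarray,
    mask_channel: np.ndarray,
    spec: MaskSpec = MaskSpec(),
    roi: np.ndarray | None = None,
    offset_nm: float = 500.0,
    pixel_size_nm: float = 25.0,
    black_level: float | None = None,
) -> ColocResult:
    """Chance-overlap control: mask channel shifted ~500 nm along x.

    The binary mask is built from the mask channel and then translated by
    ``round(offset_nm / pixel_size_nm)`` pixels in +x (the black level is
    estimated on the unshifted channel, so the zero-filled edge cannot
    distort the histogram); columns with no shifted data are dropped from
    the ROI rather than wrapped or zero-filled.
    """
    signal = np.asarray(signal, dtype=float)
    mask_channel = np.asarray(mask_channel, dtype=float)
    offset_px = int(round(offset_nm / pixel_size_nm))
    nx = signal.shape[-1]
    if abs(offset_px) >= nx:
        raise ValueError(f"offset of {offset_px} px exceeds image x extent {nx}")
    if roi is None:
        roi = np.ones(signal.shape, dtype=bool)
    roi = roi.copy()
    mask = build_mask(mask_channel, spec)
    shifted = np.zeros_like(mask)
    if offset_px > 0:
        shifted[..., offset_px:] = mask[..., :-offset_px]
        roi[..., :offset_px] = False
    elif offset_px < 0:
        shifted[..., :offset_px] = mask[..., -offset_px:]
        roi[..., offset_px:] = False
    else:
        shifted = mask
    return masked_fraction(signal, shifted, roi=roi, black_level=black_level)


def cell_mean_uptake(
    signal: np.ndarray,
    cell_rois: Sequence[np.ndarray] | np.ndarray,
    control_cells_signal: Sequence[np.ndarray] | None = None,
    control_cell_ids: Sequence[int] | None = None,
    background: float | None = None,
) -> list[CellUptake]:
    """Per-cell mean uptake, background-subtracted and control-normalised.

    ``cell_rois`` is either a label image or a list of boolean masks.
    Background is the scalar mean over the 4 °C-labelled control cells
    (``control_cells_signal``, list of per-cell pixel arrays) unless given
    directly. After subtraction, values are scaled so the mean over the
    normalisation group (``control_cell_ids``, default all cells) is 1;
    cells dimmer than background keep their negative values.
    """
    signal = np.asarray(signal, dtype=float)
    if isinstance(cell_rois, np.ndarray) and cell_rois.dtype != object and cell_rois.ndim == signal.ndim and cell_rois.dtype != bool:
        labels = np.asarray(cell_rois)
        ids = [int(v) for v in np.unique(labels) if v != 0]
        masks = [(labels == v) for v in ids]
    else:
        masks = [np.asarray(m, dtype=bool) for m in cell_rois]
        ids = list(range(1, len(masks) + 1))

    if background is None:
        if not control_cells_signal:
            raise ValueError("need control cells (or an explicit background level)")
        background = float(np.mean([np.mean(c) for c in control_cells_signal]))

    means, kept_ids = [], []
    for cid, m in zip(ids, masks):
        if not m.any():
            warnings.warn(f"cell {cid}: empty ROI, skipped")
            continue
        means.append(float(signal[m].mean()) - background)
        kept_ids.append(cid)
    if not means:
        return []

    if control_cell_ids is None:
        ref = means
    else:
        ref = [v for cid, v in zip(kept_ids, means) if cid in set(control_cell_ids)]
        if not ref:
            raise ValueError("no normalisation-group cell has a non-empty ROI")
    scale = float(np.mean(ref))
    if scale == 0:
        warnings.warn("normalisation group mean is 0; values left unscaled")
        scale = 1.0
    return [
        CellUptake(cell_id=cid, mean_intensity=v, normalised_value=v / scale)
        for cid, v in zip(kept_ids, means)
    ]
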