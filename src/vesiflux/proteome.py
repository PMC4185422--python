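"""Surface-proteome statistics: plasma-membrane abundance and SILAC bands.

PMA(x) = copy number of protein x / Σ copy numbers of all plasma-membrane
proteins × 100, giving each protein's share of the plasma-membrane
proteome; a rank-coverage curve shows how deeply a detection experiment
samples that proteome. SILAC heavy/light ratios of biotinylated (surface)
proteins are classified as accumulated/depleted/unchanged against a band
of ±2 SD around the mean of the non-biotinylated (intracellular control)
ratio distribution, by default on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ControlBand",
    "compute_pma",
    "coverage_by_rank",
    "fit_control_band",
    "classify_silac",
]


@dataclass(frozen=True)
class ControlBand:
    """±2 SD band around the control-distribution mean, on a stated scale."""

    center: float
    half_width: float
    scale: str = "log2"  # "log2" | "linear"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("degenerate band: half_width must be positive")
        if self.scale not in ("log2", "linear"):
            raise ValueError("scale must be 'log2' or 'linear'")

    @property
    def low(self) -> float:
        return self.center - self.half_width

    @property
    def high(self) -> float:
        return self.center + self.half_width


def compute_pma(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``pma`` column: percent share of plasma-membrane copies.

    Expects columns ``accession``, ``copy_number`` and boolean
    ``is_plasma_membrane``. Non-plasma-membrane rows get NaN. The PMA of
    plasma-membrane rows sums to 100 exactly.
    """
    out = table.copy()
    pm = out["is_plasma_membrane"].astype(bool)
    if not pm.any():
        raise ValueError("no plasma-membrane protein in the table")
    copies = out.loc[pm, "copy_number"].astype(float)
    if (copies < 0).any():
        raise ValueError("copy numbers must be non-negative")
    total = copies.sum()
    if total == 0:
        raise ValueError("all plasma-membrane copy numbers are zero")
    out["pma"] = np.nan
    out.loc[pm, "pma"] = 100.0 * copies / total
    return out


def coverage_by_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Detection coverage of the plasma-membrane proteome by abundance rank.

    Plasma-membrane proteins are sorted by PMA descending; the result has
    one row per rank with the protein's pma, its ``detected`` flag, the
    cumulative detected count and the cumulative detection fraction.
    """
    if "pma" not in table.columns:
        raise ValueError("run compute_pma first")
    pm = table[table["is_plasma_membrane"].astype(bool)].copy()
    pm = pm.sort_values("pma", ascending=False, kind="mergesort").reset_index(drop=True)
    pm["rank"] = np.arange(1, len(pm) + 1)
    det = pm["detected"].astype(bool).to_numpy()
    pm["cumulative_detected"] = np.cumsum(det)
    pm["cumulative_fraction"] = pm["cumulative_detected"] / pm["rank"]
    return pm[["rank", "accession", "pma", "detected",
               "cumulative_detected", "cumulative_fraction"]]


def _on_scale(ratios: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log2":
        if np.any(ratios <= 0):
            raise ValueError("ratios must be positive on the log2 scale")
        return np.log2(ratios)
    return ratios


def fit_control_band(
    table: pd.DataFrame, scale: str = "log2", n_sd: float = 2.0
) -> ControlBand:
    """Mean ± 2 SD band of the non-biotinylated (control) ratio distribution.

    Computed on the chosen scale from rows with ``is_biotinylated == False``;
    needs at least 20 control rows for a stable band.
    """
    ctrl = table.loc[~table["is_biotinylated"].astype(bool), "ratio"].to_numpy(float)
    if ctrl.size < 20:
        raise ValueError(f"only {ctrl.size} control rows; need >= 20")
    vals = _on_scale(ctrl, scale)
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate band: control ratios have zero spread")
    return ControlBand(center=float(vals.mean()), half_width=n_sd * sd, scale=scale)


def classify_silac(table: pd.DataFrame, band: ControlBand) -> pd.DataFrame:
    """Classify biotinylated rows against the control band.

    Above the band → ``accumulated`` (enriched at the surface when uptake
    is blocked), below → ``depleted``, inside (inclusive) → ``unchanged``.
    Control rows are never classified (empty class).
    """
    out = table.copy()
    vals = _on_scale(out["ratio"].to_numpy(float), band.scale)
    cls = np.where(vals > band.high, "accumulated",
                   np.where(vals < band.low, "depleted", "unchanged"))
    biotin = out["is_biotinylated"].astype(bool).to_numpy()
    out["class"] = np.where(biotin, cls, "")
    return out
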