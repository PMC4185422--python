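"""Reading and writing scenes, ROIs and tables (OME-TIFF, CSV, YAML)."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .scenes import GroundTruth, ImageStack, SceneSpec

__all__ = [
    "write_scene",
    "read_stack",
    "read_rois",
    "spec_to_yaml",
    "spec_from_yaml",
    "read_dilution_table",
    "read_lines_csv",
]


def write_scene(
    out_dir: str | Path,
    stack: ImageStack,
    truth: GroundTruth | None = None,
    spec: SceneSpec | None = None,
    name: str = "scene",
) -> Path:
    """Write a scene as OME-TIFF (+ ground-truth CSV and spec YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(stack.channels)
    data = np.stack([np.asarray(stack.channels[n], dtype=np.float32) for n in names])
    if data.ndim == 3:  # (C, Y, X) -> add a singleton Z
        data = data[:, None]
    vz, vy, vx = stack.voxel_size
    tif_path = out / f"{name}.ome.tif"
    tifffile.imwrite(
        tif_path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeZ": vz / 1000.0,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": vy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": vx / 1000.0,
            "PhysicalSizeXUnit": "µm",
        },
    )
    if truth is not None:
        truth.records.to_csv(out / f"{name}_truth.csv", index=False)
        tifffile.imwrite(out / f"{name}_cellmask.tif",
                         truth.cell_mask.astype(np.uint8))
    if spec is not None:
        (out / f"{name}_spec.yaml").write_text(spec_to_yaml(spec))
    return tif_path


def _channel_names_from_ome(tif: tifffile.TiffFile, n_channels: int) -> list[str]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        names = [
            ch.get("Name") or f"ch{i}"
            for i, ch in enumerate(root.iter(f"{{{ns['ome']}}}Channel"))
        ]
        if len(names) == n_channels:
            return names
    except Exception:
        pass
    return [f"ch{i}" for i in range(n_channels)]


def read_stack(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a multi-channel (OME-)TIFF into an :class:`ImageStack`.

    Channel names come from the OME metadata unless overridden; voxel size
    (nm) from the OME physical pixel sizes, else the caller, else the
    package default of (150, 25, 25) nm with a best-effort assumption.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        axes = tif.series[0].axes if tif.series else ""
        vs = voxel_size
        if vs is None and tif.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tif.ome_metadata)
                pix = next(p for p in root.iter() if p.tag.endswith("Pixels"))
                vs = (
                    float(pix.get("PhysicalSizeZ", 0.15)) * 1000.0,
                    float(pix.get("PhysicalSizeY", 0.025)) * 1000.0,
                    float(pix.get("PhysicalSizeX", 0.025)) * 1000.0,
                )
            except Exception:
                vs = None
        if data.ndim == 2:
            data = data[None, None]
        elif data.ndim == 3:
            # ambiguous: (C, Y, X) vs (Z, Y, X); trust the axes string
            data = data[:, None] if axes.startswith("C") else data[None]
        elif data.ndim == 4 and axes.startswith("Z"):
            data = np.moveaxis(data, 1, 0)  # ZCYX -> CZYX
        names = list(channel_names) if channel_names else _channel_names_from_ome(
            tif, data.shape[0]
        )
    channels = {n: data[i].astype(float) for i, n in enumerate(names)}
    return ImageStack(channels=channels, voxel_size=vs or (150.0, 25.0, 25.0))


def read_rois(path: str | Path, shape: tuple[int, int] | None = None) -> list[np.ndarray]:
    """Read cell ROIs from a label TIFF or a polygon CSV.

    A label image yields one boolean mask per non-zero label. A CSV needs
    columns ``cell_id, y, x`` (one row per polygon vertex) and the target
    image ``shape``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(str(path))
        return [labels == v for v in np.unique(labels) if v != 0]
    from skimage.draw import polygon2mask

    if shape is None:
        raise ValueError("polygon ROIs need the target image shape")
    df = pd.read_csv(path)
    masks = []
    for _, grp in df.groupby("cell_id", sort=True):
        masks.append(polygon2mask(shape, grp[["y", "x"]].to_numpy(float)))
    return masks


def spec_to_yaml(spec: SceneSpec) -> str:
    d = dataclasses.asdict(spec)
    d["membrane_background"] = dict(d["membrane_background"])
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return yaml.safe_dump(d, sort_keys=True)


def spec_from_yaml(text: str) -> SceneSpec:
    d = yaml.safe_load(text) or {}
    fields = {f.name for f in dataclasses.fields(SceneSpec)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown scene parameters: {sorted(unknown)}")
    for k in ("image_shape", "voxel_size", "psf_sigma_nm", "cell_axes_fraction",
              "channel_names"):
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return SceneSpec(**d)


def read_dilution_table(path: str | Path):
    """Read a dilution-series CSV: columns ``fraction, signal`` plus one row
    with fraction = 'treated' (or NaN) holding the treated signal."""
    from .scenes import DilutionSeries

    df = pd.read_csv(path)
    is_treated = df["fraction"].astype(str).str.lower().eq("treated") | df[
        "fraction"
    ].isna()
    treated = df.loc[is_treated, "signal"]
    if len(treated) != 1:
        raise ValueError("dilution table needs exactly one treated row")
    std = df.loc[~is_treated].astype({"fraction": float, "signal": float})
    std = std.sort_values("fraction", ascending=False)
    return DilutionSeries(
        standards=tuple(zip(std["fraction"], std["signal"])),
        treated_signal=float(treated.iloc[0]),
    )


def read_lines_csv(path: str | Path) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Read line endpoints from CSV columns ``y0, x0, y1, x1``."""
    df = pd.read_csv(path)
    return [
        ((float(r.y0), float(r.x0)), (float(r.y1), float(r.x1)))
        for r in df.itertuples()
    ]
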