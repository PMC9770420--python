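"""Readers and writers: OME-TIFF stacks, CSV tables, YAML/JSON configs.

Two-channel fields are stored as OME-TIFF with axes CZYX, channel names
"nuclei" and "vwf", and the physical calibration (pixel size, z-step) in
the OME metadata so that a written field round-trips losslessly.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .quantification import SlideResult
from .segmentation import FieldCounts, FieldImage
from .synthetic import GroundTruth

__all__ = [
    "write_field_ome_tiff",
    "read_field_tiff",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "counts_to_frame",
    "write_counts_csv",
    "read_counts_csv",
    "slides_to_frame",
    "write_manifest",
    "read_manifest",
    "load_yaml",
]


def write_field_ome_tiff(image: FieldImage, path) -> Path:
    """Write one field as an OME-TIFF (CZYX) with physical calibration."""
    path = Path(path)
    data = np.stack([image.nuclei_channel, image.vwf_channel])  # (C, Z, Y, X)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": image.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": ["nuclei", "vwf"]},
        },
    )
    return path


def _ome_physical_sizes(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    if not tif.ome_metadata:
        return None, None
    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, None
    px = pixels.get("PhysicalSizeX")
    pz = pixels.get("PhysicalSizeZ")
    return (float(px) if px else None, float(pz) if pz else None)


def read_field_tiff(
    path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    axes: str = "CZYX",
    field_id: str | None = None,
    slide_id: str = "slide0",
    condition_id: str = "",
) -> FieldImage:
    """Read a two-channel z-stack TIFF into a :class:`FieldImage`.

    Physical calibration is taken from the OME metadata when present;
    explicit ``pixel_size_um`` / ``z_step_um`` arguments override it and
    are required for plain TIFFs without calibration.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = series.axes if len(series.axes) == data.ndim else axes
        meta_px, meta_pz = _ome_physical_sizes(tif)
    order = [file_axes.index(ax) for ax in "CZYX" if ax in file_axes]
    if data.ndim == 3:  # single z-plane stacks stored as CYX
        data = data[:, None, :, :] if file_axes.startswith("C") else data[None]
    elif data.ndim == 4:
        data = np.transpose(data, order)
    else:
        raise ValueError(f"{path}: expected a 3-D or 4-D stack, got {data.shape}")
    if data.shape[0] != 2:
        raise ValueError(f"{path}: expected 2 channels, got {data.shape[0]}")
    px = pixel_size_um if pixel_size_um is not None else meta_px
    pz = z_step_um if z_step_um is not None else meta_pz
    if px is None or pz is None:
        raise ValueError(
            f"{path}: no pixel size / z-step in metadata; pass pixel_size_um "
            "and z_step_um explicitly"
        )
    return FieldImage(
        nuclei_channel=data[0],
        vwf_channel=data[1],
        pixel_size_um=float(px),
        z_step_um=float(pz),
        field_id=field_id or path.stem.replace(".ome", ""),
        slide_id=slide_id,
        condition_id=condition_id,
    )


# ---------------------------------------------------------------------------
# Ground truth


def ground_truth_to_frame(truth: GroundTruth, field_id: str = "") -> pd.DataFrame:
    rows = []
    for n in truth.nuclei:
        rows.append(
            dict(
                field_id=field_id,
                type="nucleus",
                y_px=n.centroid_px[0],
                x_px=n.centroid_px[1],
                z_slice=np.nan,
                size1_px=n.radii_px[0],
                size2_px=n.radii_px[1],
                orientation_rad=n.orientation_rad,
            )
        )
    for w in truth.wpbs:
        rows.append(
            dict(
                field_id=field_id,
                type="wpb",
                y_px=w.centroid_px[0],
                x_px=w.centroid_px[1],
                z_slice=w.z_center,
                size1_px=w.length_px,
                size2_px=w.width_px,
                orientation_rad=w.orientation_rad,
            )
        )
    for im in truth.immature:
        rows.append(
            dict(
                field_id=field_id,
                type="immature",
                y_px=im.centroid_px[0],
                x_px=im.centroid_px[1],
                z_slice=im.z_center,
                size1_px=im.radius_px,
                size2_px=np.nan,
                orientation_rad=np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "field_id",
            "type",
            "y_px",
            "x_px",
            "z_slice",
            "size1_px",
            "size2_px",
            "orientation_rad",
        ],
    )


def write_ground_truth_csv(truth: GroundTruth, path, field_id: str = "") -> Path:
    path = Path(path)
    ground_truth_to_frame(truth, field_id).to_csv(path, index=False)
    return path


def read_ground_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Counts and slide summaries


def counts_to_frame(counts: list[FieldCounts], conditions: list[dict] | None = None) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(counts):
        row = dict(
            field_id=c.field_id,
            slide_id=c.slide_id,
            condition_id=c.condition_id,
            nuclei_count=c.nuclei_count,
            wpb_count=c.wpb_count,
        )
        if conditions:
            row.update(conditions[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_counts_csv(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_counts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def slides_to_frame(slides: list[SlideResult]) -> pd.DataFrame:
    rows = []
    for s in slides:
        row = dict(
            slide_id=s.slide_id,
            total_nuclei=s.total_nuclei,
            total_wpb=s.total_wpb,
            wpb_per_nuclei=s.wpb_per_nuclei,
            mean_cells_per_field=s.mean_cells_per_field,
            confluency=s.confluency,
            valid=s.valid,
        )
        row.update({k: v for k, v in s.condition.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manifests and configs


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return data
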