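"""Reading and writing spectral stacks and ROI sets.

Stacks travel as multi-page TIFF (one page per emission window, 16-bit
unsigned containers holding 12-bit values) accompanied by a JSON sidecar
``<stem>.json`` carrying the acquisition metadata that TIFF itself does not
standardise::

    {"centers_nm": [...], "bandwidth_nm": 15.0, "step_nm": 5.21,
     "excitation_nm": 470.0, "pixel_size_um": 0.361, "bit_depth": 12,
     "channel_label": "NCL-Dys1"}

ROI sets travel as CSV with columns
``center_row, center_col, semi_major, semi_minor, theta`` (theta in radians)
plus an optional leading ``field_id`` column for multi-field archives.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .model import EllipticalROI, SpectralStack, WavelengthAxis

__all__ = [
    "StackFormatError",
    "StackMetadataError",
    "read_stack",
    "write_stack",
    "read_roi_set",
    "write_roi_set",
]

ROI_COLUMNS = ["center_row", "center_col", "semi_major", "semi_minor", "theta"]


class StackFormatError(ValueError):
    """The TIFF payload is malformed (missing or ragged pages)."""


class StackMetadataError(ValueError):
    """Metadata is absent or inconsistent with the pixel data."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: SpectralStack, path: str | Path) -> Path:
    """Write `stack` as multi-page TIFF plus JSON metadata sidecar.

    Returns the TIFF path; the sidecar is written next to it.
    """
    path = Path(path)
    stack.validate()
    pages = np.moveaxis(stack.cube, 2, 0).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "centers_nm": list(stack.axis.centers),
        "bandwidth_nm": stack.axis.bandwidth,
        "step_nm": stack.axis.step,
        "excitation_nm": stack.excitation,
        "pixel_size_um": stack.pixel_size,
        "bit_depth": stack.bit_depth,
        "channel_label": stack.channel_label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path, channel_label: str | None = None) -> SpectralStack:
    """Read a multi-page TIFF lambda stack with its JSON sidecar.

    Parameters
    ----------
    path
        TIFF file; the sidecar ``<path>.json`` must exist.
    channel_label
        Overrides the sidecar's ``channel_label`` when given.

    Raises
    ------
    StackFormatError
        Missing or ragged pages.
    StackMetadataError
        Missing sidecar / wavelength axis, or pixel values exceeding the
        declared bit-depth ceiling.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise StackMetadataError(f"no wavelength-axis sidecar found at {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "centers_nm" not in meta:
        raise StackMetadataError(f"sidecar {sidecar} lacks 'centers_nm'")

    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(tif.pages) == 0:
            raise StackFormatError(f"{path} contains no pages")
        if len(shapes) != 1:
            raise StackFormatError(f"{path} has ragged page shapes {sorted(shapes)}")
        pages = tif.asarray()
    if pages.ndim == 2:  # single-window stack
        pages = pages[None, :, :]
    cube = np.moveaxis(pages, 0, 2)

    axis = WavelengthAxis(meta["centers_nm"], meta["bandwidth_nm"], meta["step_nm"])
    if len(axis) != cube.shape[2]:
        raise StackMetadataError(
            f"{path}: {cube.shape[2]} pages but {len(axis)} wavelength centers"
        )
    bit_depth = int(meta.get("bit_depth", 12))
    ceiling = (1 << bit_depth) - 1
    if cube.max(initial=0) > ceiling:
        raise StackMetadataError(
            f"{path}: intensity {cube.max()} exceeds the {bit_depth}-bit ceiling {ceiling}"
        )
    return SpectralStack(
        cube=cube,
        axis=axis,
        excitation=float(meta.get("excitation_nm", float("nan"))),
        pixel_size=float(meta.get("pixel_size_um", 0.361)),
        bit_depth=bit_depth,
        channel_label=channel_label if channel_label is not None else meta.get("channel_label", ""),
    )


def write_roi_set(
    rois: Sequence[EllipticalROI],
    path: str | Path,
    field_ids: Sequence[str] | None = None,
) -> Path:
    """Write ROIs as CSV (theta in radians, >= 6 decimals preserved)."""
    path = Path(path)
    records = {}
    if field_ids is not None:
        if len(field_ids) != len(rois):
            raise ValueError("field_ids must align with rois")
        records["field_id"] = list(field_ids)
    for col in ROI_COLUMNS:
        records[col] = [getattr(r, col) for r in rois]
    pd.DataFrame(records, columns=(["field_id"] if field_ids is not None else []) + ROI_COLUMNS).to_csv(
        path, index=False, float_format="%.9g"
    )
    return path


def read_roi_set(path: str | Path) -> list[EllipticalROI]:
    """Read an ROI CSV back into validated ellipses, in file order.

    Raises
    ------
    ValueError
        Missing columns or an ROI violating its invariants
        (e.g. ``semi_minor = 0``).
    """
    df = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ROI file lacks columns {missing}")
    rois = []
    for i, row in df.iterrows():
        try:
            rois.append(
                EllipticalROI(
                    center_row=float(row["center_row"]),
                    center_col=float(row["center_col"]),
                    semi_major=float(row["semi_major"]),
                    semi_minor=float(row["semi_minor"]),
                    theta=float(row["theta"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: invalid ROI on data row {i}: {exc}") from exc
    return rois


def read_roi_fields(path: str | Path) -> dict[str, list[EllipticalROI]]:
    """Read a multi-field ROI CSV, grouped by its ``field_id`` column."""
    df = pd.read_csv(path)
    if "field_id" not in df.columns:
        return {"": read_roi_set(path)}
    out: dict[str, list[EllipticalROI]] = {}
    for fid, sub in df.groupby("field_id", sort=False):
        out[str(fid)] = [
            EllipticalROI(
                float(r["center_row"]),
                float(r["center_col"]),
                float(r["semi_major"]),
                float(r["semi_minor"]),
                float(r["theta"]),
            )
            for _, r in sub.iterrows()
        ]
    return out
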