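"""Per-ROI spectral signatures and peak-intensity quantification.

Each ROI yields its spectral signature: the mean intensity of its rasterized
pixels in every emission window.  The emission peak is chosen once on the
average signature (per field, or per biopsy when fields are pooled — the
default), and every ROI's single reported value is its signature read at
that common peak window.  Biopsy-level results are the mean and standard
error of the pooled per-ROI peak intensities (78 at the default 3 fields x
26 ROIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EllipticalROI, SpectralStack, Spectrum, WavelengthAxis
from .roi_detection import ROISet

__all__ = [
    "FieldQuantification",
    "BiopsyResult",
    "roi_mean_spectrum",
    "peak_wavelength",
    "quantify_field",
    "aggregate_biopsy",
    "detection_percentage",
]


@dataclass
class FieldQuantification:
    """Spectral signatures and peak intensities of one field's ROIs."""

    field_id: str
    spectra: list[Spectrum]
    rois: list[EllipticalROI]
    peak_index: int
    peak_center_nm: float
    peak_intensities: np.ndarray  # per ROI, a.u.


@dataclass
class BiopsyResult:
    """Pooled peak-intensity summary of one biopsy for one antibody."""

    biopsy_id: str
    group_label: str
    antibody_label: str
    n_rois: int
    mean_intensity: float
    se_intensity: float
    peak_center_nm: float
    peak_policy: str
    roi_values: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def roi_mean_spectrum(stack: SpectralStack, roi: EllipticalROI) -> Spectrum:
    """Mean intensity of the ROI's pixels in every wavelength window.

    A pixel belongs to the ROI iff its centre satisfies the ellipse
    inequality; the ROI must rasterize to at least one in-bounds pixel.
    """
    rr, cc = roi.pixel_coords()
    rows, cols, _ = stack.shape
    if rr.size == 0:
        raise ValueError(f"ROI {roi} rasterizes to zero pixels")
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= rows or cc.max() >= cols:
        raise ValueError(f"ROI {roi} extends outside the {rows}x{cols} frame")
    values = stack.cube[rr, cc, :].mean(axis=0, dtype=float)
    return Spectrum(axis=stack.axis, values=values)


def peak_wavelength(spectra: list[Spectrum]) -> tuple[float, int]:
    """Centre and index of the maximum of the element-wise mean spectrum.

    Ties resolve to the lowest wavelength.  All spectra must share one axis.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis != axis:
            raise ValueError("spectra have mismatched wavelength axes")
    mean = np.mean([s.values for s in spectra], axis=0)
    k = int(np.argmax(mean))
    return float(axis.centers[k]), k


def quantify_field(stack: SpectralStack, rois: ROISet | list[EllipticalROI],
                   field_id: str | None = None) -> FieldQuantification:
    """Signatures for every ROI plus per-ROI intensities at the field peak."""
    if isinstance(rois, ROISet):
        roi_list = rois.rois
        fid = field_id if field_id is not None else rois.field_id
    else:
        roi_list = list(rois)
        fid = field_id or ""
    if not roi_list:
        raise ValueError("empty ROI set")
    spectra = [roi_mean_spectrum(stack, r) for r in roi_list]
    center, k = peak_wavelength(spectra)
    return FieldQuantification(
        field_id=fid,
        spectra=spectra,
        rois=roi_list,
        peak_index=k,
        peak_center_nm=center,
        peak_intensities=np.array([s.values[k] for s in spectra]),
    )


def aggregate_biopsy(
    fields: list[FieldQuantification],
    biopsy_id: str,
    group_label: str,
    antibody_label: str,
    peak_policy: str = "per_biopsy",
) -> BiopsyResult:
    """Pool a biopsy's fields into its single-value intensity summary.

    With ``peak_policy='per_biopsy'`` (default) the emission peak is
    re-selected on the mean signature pooled over all ROIs of all fields and
    every ROI is re-read at that window; ``'per_field'`` keeps each field's
    own peak.  SE is computed over the pooled ROIs, not over field means.
    """
    if not fields:
        raise ValueError("need at least one quantified field")
    if peak_policy == "per_biopsy":
        all_spectra = [s for f in fields for s in f.spectra]
        center, k = peak_wavelength(all_spectra)
        values = np.array([s.values[k] for s in all_spectra])
    elif peak_policy == "per_field":
        center = float(np.mean([f.peak_center_nm for f in fields]))
        values = np.concatenate([f.peak_intensities for f in fields])
    else:
        raise ValueError(f"unknown peak_policy {peak_policy!r}")
    n = values.size
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return BiopsyResult(
        biopsy_id=biopsy_id,
        group_label=group_label,
        antibody_label=antibody_label,
        n_rois=int(n),
        mean_intensity=mean,
        se_intensity=se,
        peak_center_nm=center,
        peak_policy=peak_policy,
        roi_values=values,
    )


def detection_percentage(signal_au: float, reference_mean_au: float) -> float:
    """Signal as a percentage of a reference mean, to one decimal.

    >>> detection_percentage(15, 2982.9)
    0.5
    """
    if reference_mean_au <= 0:
        raise ValueError("reference mean must be positive")
    return round(100.0 * signal_au / reference_mean_au, 1)
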