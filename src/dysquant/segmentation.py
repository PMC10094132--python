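"""Muscle-fibre detection in the membrane-guide channel.

First stage of automatic ROI placement: pick the brightest emission window
as the working image, median-denoise it, binarize (Otsu by default), and
extract the fibre interiors as the cleaned connected components of the
*complement* of the bright mask — in the guide channel the sarcolemma is the
bright class and fibre interiors are the darker regions it encloses.
Regions are filtered by area and circularity (muscle fibres are polygonal,
so the circularity floor is deliberately permissive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening
from skimage.segmentation import clear_border

from .model import SpectralStack

__all__ = [
    "FibreRegion",
    "select_reference_slice",
    "denoise_median",
    "binarize",
    "extract_fibre_regions",
]


@dataclass
class FibreRegion:
    """One detected fibre interior on the reference slice."""

    label: int
    pixel_mask: np.ndarray  # boolean, full image frame
    area_px: int
    centroid: tuple[float, float]
    circularity: float
    mean_intensity: float


def select_reference_slice(stack: SpectralStack) -> tuple[int, np.ndarray]:
    """Index and image of the brightest wavelength window.

    Brightness is the mean intensity over the whole slice; ties go to the
    lowest index.
    """
    means = stack.cube.reshape(-1, stack.n_lambda).mean(axis=0)
    k = int(np.argmax(means))  # argmax returns the first (lowest) maximiser
    return k, stack.cube[:, :, k]


def denoise_median(image: np.ndarray, radius_px: int = 1) -> np.ndarray:
    """Median filter over a (2r+1) x (2r+1) square window, reflected edges."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    size = 2 * radius_px + 1
    return ndimage.median_filter(image, size=size, mode="reflect")


def binarize(
    image: np.ndarray, method: str = "otsu", threshold: float | None = None
) -> np.ndarray:
    """Boolean mask ``image > threshold``.

    With ``method='otsu'`` the threshold maximises Otsu's between-class
    variance; a constant image makes that criterion degenerate and raises.
    """
    image = np.asarray(image)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        if image.min() == image.max():
            raise ValueError("Otsu threshold undefined for a constant image")
        t = float(threshold_otsu(image))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return image > t


def extract_fibre_regions(
    mask: np.ndarray,
    min_area_px: int = 300,
    min_circularity: float = 0.3,
    morphology_radius_px: int = 2,
    clear_border_components: bool = False,
    reference_image: np.ndarray | None = None,
) -> list[FibreRegion]:
    """Fibre interiors from a fibre-bright binary mask.

    `mask` must already be fibre-interior-bright (i.e. the complement of the
    wall mask when the wall is the bright class).  Cleaning sequence: binary
    opening (disc of `morphology_radius_px`), hole filling, optional removal
    of frame-touching components, then area and circularity
    (4*pi*area/perimeter**2) filters.  Surviving regions are labelled 1..K
    in decreasing area order.
    """
    cleaned = opening(mask, disk(morphology_radius_px))
    cleaned = ndimage.binary_fill_holes(cleaned)
    if clear_border_components:
        cleaned = clear_border(cleaned)
    lab = sk_label(cleaned, connectivity=1)
    regions = []
    for rp in regionprops(lab):
        if rp.area < min_area_px:
            continue
        perim = rp.perimeter
        circ = 4.0 * np.pi * rp.area / (perim * perim) if perim > 0 else 0.0
        if circ < min_circularity:
            continue
        pix = lab == rp.label
        mean_int = float(reference_image[pix].mean()) if reference_image is not None else float("nan")
        regions.append(
            FibreRegion(
                label=0,  # assigned after sorting
                pixel_mask=pix,
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                circularity=float(circ),
                mean_intensity=mean_int,
            )
        )
    regions.sort(key=lambda r: -r.area_px)
    for i, r in enumerate(regions, start=1):
        r.label = i
    return regions
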