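"""Automatic placement of elliptical sarcolemma ROIs.

Second and third stages of the automatic pipeline: the detected fibre
interiors are dilated and subtracted to expose the inter-fibre band where
the sarcolemma lies; small ellipses are proposed along that band's skeleton,
oriented by the local wall tangent; each candidate is scored by brightness,
tangent alignment and wall overlap; and the best-ranked non-overlapping 26
are selected.  The whole chain runs on the membrane-guide channel only, so
ROI placement is blind to the dystrophin signal being quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor
from skimage.morphology import dilation, disk, skeletonize

from .model import EllipticalROI, SpectralStack
from .segmentation import (
    FibreRegion,
    binarize,
    denoise_median,
    extract_fibre_regions,
    select_reference_slice,
)

__all__ = [
    "SarcolemmaMask",
    "ROIScore",
    "ROISet",
    "DetectionConfig",
    "tangent_field",
    "locate_sarcolemma",
    "propose_ellipses",
    "score_rois",
    "select_top",
    "detect_rois",
]


@dataclass
class SarcolemmaMask:
    """Estimated sarcolemma band with per-pixel tangent orientation."""

    mask: np.ndarray
    thickness_px: float
    tangent_field: np.ndarray  # radians in [0, pi), defined everywhere


@dataclass(frozen=True)
class ROIScore:
    """Ranking components, each in [0, 1].

    brightness: mean guide intensity in the ROI over the field maximum;
    orientation: |cos(theta - local wall tangent)|;
    wall_overlap: (fraction of ROI pixels on the wall) minus (fraction off),
    clipped to [0, 1]; total: convex combination with the given weights.
    """

    brightness: float
    orientation: float
    wall_overlap: float
    total: float


@dataclass
class ROISet:
    """Selected ROIs of one field, sorted by non-increasing score."""

    field_id: str
    rois: list[EllipticalROI]
    scores: list[ROIScore]
    n_requested: int
    shortfall: bool = False


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of the automatic ROI pipeline (all stages)."""

    median_radius_px: int = 1
    binarize_method: str = "otsu"
    fixed_threshold: float | None = None
    morphology_radius_px: int = 2
    min_area_px: int = 300
    min_circularity: float = 0.3
    clear_border_components: bool = False
    dilation_radius_px: int = 4
    semi_major_px: float | None = None  # None -> tied to measured wall thickness
    semi_minor_px: float | None = None
    spacing_px: float | None = None
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_rois: int = 26


def tangent_field(mask: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Local wall orientation (radians in [0, pi)) from the structure tensor.

    The tangent is the direction of least intensity variation: the
    eigenvector of the smaller eigenvalue of the smoothed structure tensor.
    Angles are measured from the +col axis toward the +row axis.
    """
    a, b, c = structure_tensor(mask.astype(float), sigma=sigma, order="rc")
    # largest eigenvalue of [[a, b], [b, c]]
    half = 0.5 * (a + c)
    root = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
    l1 = half + root
    # normal (dominant) eigenvector, two algebraic forms; pick the better
    n1 = np.stack([b, l1 - a])  # (dr, dc)
    n2 = np.stack([l1 - c, b])
    use2 = (n2**2).sum(axis=0) > (n1**2).sum(axis=0)
    nr = np.where(use2, n2[0], n1[0])
    nc = np.where(use2, n2[1], n1[1])
    # tangent perpendicular to the normal
    tr, tc = -nc, nr
    theta = np.arctan2(tr, tc) % np.pi
    # isotropic pixels (no structure): define horizontal
    theta[np.hypot(tr, tc) < 1e-12] = 0.0
    return theta


def locate_sarcolemma(
    regions: list[FibreRegion],
    image_shape: tuple[int, int],
    dilation_radius_px: int = 4,
) -> SarcolemmaMask:
    """The inter-fibre band: union of dilated fibres minus the fibres.

    Median thickness is estimated from the distance transform sampled on the
    band's skeleton (2 x the median skeleton-to-edge distance).
    """
    if not regions:
        raise ValueError("locate_sarcolemma needs at least one fibre region")
    interiors = np.zeros(image_shape, dtype=bool)
    for r in regions:
        interiors |= r.pixel_mask
    dilated = dilation(interiors, disk(dilation_radius_px))
    mask = dilated & ~interiors
    if mask.any():
        dist = ndimage.distance_transform_edt(mask)
        skel = skeletonize(mask)
        samples = dist[skel] if skel.any() else dist[mask]
        thickness = float(2.0 * np.median(samples))
    else:
        thickness = 0.0
    return SarcolemmaMask(mask=mask, thickness_px=thickness, tangent_field=tangent_field(mask))


def propose_ellipses(
    sarc: SarcolemmaMask,
    semi_major_px: float,
    semi_minor_px: float,
    spacing_px: float,
) -> list[EllipticalROI]:
    """Candidate ellipses along the sarcolemma skeleton.

    Skeleton pixels are visited in deterministic (row, col) order and kept
    as centres whenever they lie at least `spacing_px` from every centre
    already kept (greedy spacing-constrained sampling).  Each candidate's
    major axis follows the local wall tangent; candidates whose raster would
    leave the frame are dropped.
    """
    if not sarc.mask.any():
        return []
    shape = sarc.mask.shape
    skel = skeletonize(sarc.mask)
    pts = np.argwhere(skel)  # argwhere is already (row, col) sorted
    kept: list[tuple[int, int]] = []
    kept_arr = np.empty((0, 2))
    out: list[EllipticalROI] = []
    sp2 = spacing_px**2
    for r, c in pts:
        if kept_arr.size:
            d2 = ((kept_arr - (r, c)) ** 2).sum(axis=1)
            if (d2 < sp2).any():
                continue
        roi = EllipticalROI(float(r), float(c), semi_major_px, semi_minor_px,
                            float(sarc.tangent_field[r, c]))
        rr, cc = roi.pixel_coords()
        if rr.size == 0 or rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
            continue
        kept.append((r, c))
        kept_arr = np.asarray(kept, dtype=float)
        out.append(roi)
    return out


def score_rois(
    cands: list[EllipticalROI],
    ref_image: np.ndarray,
    sarc: SarcolemmaMask,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> list[ROIScore]:
    """Score each candidate by brightness, orientation and wall overlap."""
    w_b, w_o, w_w = weights
    if min(weights) < 0:
        raise ValueError("weights must be non-negative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    shape = ref_image.shape
    field_max = float(ref_image.max()) if ref_image.size else 0.0
    scores = []
    for roi in cands:
        rr, cc = roi.pixel_coords()
        if rr.size == 0 or rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
            raise ValueError(f"candidate {roi} lies outside the image")
        brightness = float(ref_image[rr, cc].mean()) / field_max if field_max > 0 else 0.0
        r0 = int(round(roi.center_row))
        c0 = int(round(roi.center_col))
        orientation = abs(np.cos(roi.theta - sarc.tangent_field[r0, c0]))
        frac_in = float(sarc.mask[rr, cc].mean())
        wall_overlap = float(np.clip(frac_in - (1.0 - frac_in), 0.0, 1.0))
        total = w_b * brightness + w_o * orientation + w_w * wall_overlap
        scores.append(ROIScore(brightness, float(orientation), wall_overlap, float(total)))
    return scores


def select_top(
    cands: list[EllipticalROI],
    scores: list[ROIScore],
    n: int = 26,
    field_id: str = "",
    image_shape: tuple[int, int] | None = None,
) -> ROISet:
    """Greedy best-first selection of up to `n` non-overlapping ROIs.

    Candidates are visited in descending total score, ties broken by
    (row, col) of the centre; a candidate is skipped if its rasterized
    pixels intersect any already selected ROI.  Selecting fewer than `n`
    sets the shortfall flag.
    """
    if len(cands) != len(scores):
        raise ValueError("candidates and scores must align")
    order = sorted(
        range(len(cands)),
        key=lambda i: (-scores[i].total, cands[i].center_row, cands[i].center_col),
    )
    if image_shape is None and cands:
        # occupancy grid sized to cover all candidates
        max_r = int(max(c.center_row + c.semi_major for c in cands)) + 2
        max_c = int(max(c.center_col + c.semi_major for c in cands)) + 2
        image_shape = (max_r, max_c)
    occupied = np.zeros(image_shape or (1, 1), dtype=bool)
    sel_rois: list[EllipticalROI] = []
    sel_scores: list[ROIScore] = []
    for i in order:
        rr, cc = cands[i].pixel_coords()
        if occupied[rr, cc].any():
            continue
        occupied[rr, cc] = True
        sel_rois.append(cands[i])
        sel_scores.append(scores[i])
        if len(sel_rois) == n:
            break
    return ROISet(
        field_id=field_id,
        rois=sel_rois,
        scores=sel_scores,
        n_requested=n,
        shortfall=len(sel_rois) < n,
    )


def detect_rois(
    beta_stack: SpectralStack,
    config: DetectionConfig | None = None,
    field_id: str = "",
) -> ROISet:
    """Full automatic ROI pipeline on the membrane-guide channel.

    Composition: reference-slice selection -> median denoise -> binarize ->
    fibre extraction -> sarcolemma localisation -> ellipse proposal ->
    scoring -> top-n selection.  Deterministic for a fixed configuration;
    errors from a stage are re-raised tagged with the stage name.
    """
    cfg = config or DetectionConfig()

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"ROI detection failed at stage '{name}': {exc}") from exc

    _, ref = _stage("select_reference_slice", select_reference_slice, beta_stack)
    den = _stage("denoise_median", denoise_median, ref, cfg.median_radius_px)
    bright = _stage("binarize", binarize, den, cfg.binarize_method, cfg.fixed_threshold)
    # wall is the bright class; fibres are components of the complement
    regions = _stage(
        "extract_fibre_regions",
        extract_fibre_regions,
        ~bright,
        cfg.min_area_px,
        cfg.min_circularity,
        cfg.morphology_radius_px,
        cfg.clear_border_components,
        den,
    )
    sarc = _stage("locate_sarcolemma", locate_sarcolemma, regions, ref.shape, cfg.dilation_radius_px)
    semi_minor = cfg.semi_minor_px if cfg.semi_minor_px is not None else max(1.0, sarc.thickness_px / 2.0)
    semi_major = cfg.semi_major_px if cfg.semi_major_px is not None else 2.0 * semi_minor
    spacing = cfg.spacing_px if cfg.spacing_px is not None else 2.0 * semi_major
    cands = _stage("propose_ellipses", propose_ellipses, sarc, semi_major, semi_minor, spacing)
    scores = _stage("score_rois", score_rois, cands, den, sarc, cfg.weights)
    return _stage("select_top", select_top, cands, scores, cfg.n_rois, field_id, ref.shape)
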