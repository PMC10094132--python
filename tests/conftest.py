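"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dysquant.model import EllipticalROI
from dysquant.simulate import (
    NoiseModel,
    dystrophin_channel,
    generate_geometry,
    group_intensity_params,
    reference_spectrin_params,
    render_field,
    spectrin_channel,
)
from dysquant.workflow import PipelineConfig, quantify_cohort, simulate_cohort

CONTROL_DYS = (2982.9, 29.3)  # reference control level, NCL-Dys1 (mean, SE/78 ROIs)
CONTROL_BETA = (1832.17, 132.30)

NOISELESS = NoiseModel(read_sd=0.0, shot_scale=0.0)


def control_channels(noise: NoiseModel | None = None, wall_sd: float | None = None):
    """Channel specs for a control-level field, optionally noiseless."""
    from dataclasses import replace

    kw = {} if noise is None else {"noise": noise}
    dys_p = group_intensity_params("CONTROL", *CONTROL_DYS, **kw)
    beta_p = reference_spectrin_params("CONTROL")
    if noise is not None:
        beta_p = replace(beta_p, noise=noise)
    if wall_sd is not None:
        dys_p = replace(dys_p, wall_sd=wall_sd)
        beta_p = replace(beta_p, wall_sd=wall_sd)
    return spectrin_channel(beta_p), dystrophin_channel("NCL-Dys1", dys_p)


@pytest.fixture(scope="session")
def default_geometry():
    """Default 512x512 field geometry: 30 fibres, 4 px wall, no confounders."""
    return generate_geometry(512, 512, 30, 4.0, None, seed=11)


@pytest.fixture(scope="session")
def control_field(default_geometry):
    """Default control-level field with realistic noise."""
    beta, dys = control_channels()
    return render_field(default_geometry, beta, dys, seed=12)


@pytest.fixture(scope="session")
def noiseless_field(default_geometry):
    """Noise-free control field (zero read and shot noise, zero wall SD)."""
    beta, dys = control_channels(noise=NOISELESS, wall_sd=0.0)
    return render_field(default_geometry, beta, dys, seed=13)


@pytest.fixture(scope="session")
def cohort_bundle():
    """Reference-shaped cohort (10 DMD / 3 BMD / 6 control x 3 fields) at the
    published levels for all three antibodies, quantified in auto and oracle
    modes.  Frames are 320x320 (~14 fibres) to keep the suite fast; the
    cohort shape, ROI counts and intensity levels are the stated ones."""
    cfg = PipelineConfig(
        rows=320, cols=320, n_fibres=14, seed=20230328 % 99991,
        antibodies=("NCL-Dys1", "NCL-Dys2", "NCL-Dys3"),
    )
    cohort = simulate_cohort(cfg)
    auto_summary, auto_roi = quantify_cohort(cohort, cfg, "auto")
    oracle_summary, oracle_roi = quantify_cohort(cohort, cfg, "oracle")
    return dict(
        config=cfg,
        cohort=cohort,
        auto_summary=auto_summary,
        auto_roi=auto_roi,
        oracle_summary=oracle_summary,
        oracle_roi=oracle_roi,
    )


# ---------------------------------------------------------------------------
# independent oracles


def median_filter_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force per-pixel neighbourhood median with reflected edges."""
    pad = np.pad(image, radius, mode="symmetric")
    out = np.empty_like(image)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = np.median(pad[r : r + 2 * radius + 1, c : c + 2 * radius + 1])
    return out


def otsu_mask_oracle(image: np.ndarray) -> np.ndarray:
    """Exhaustive-threshold-sweep Otsu: mask maximising between-class variance."""
    flat = image.ravel().astype(float)
    best_t, best_var = None, -1.0
    for t in np.unique(flat)[:-1]:
        lo = flat[flat <= t]
        hi = flat[flat > t]
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return image > best_t


def roi_mean_oracle(cube: np.ndarray, roi: EllipticalROI) -> np.ndarray:
    """Per-pixel summation oracle for the ROI mean spectrum."""
    rows, cols, nl = cube.shape
    total = np.zeros(nl)
    count = 0
    ct, st = np.cos(roi.theta), np.sin(roi.theta)
    for r in range(rows):
        for c in range(cols):
            dr, dc = r - roi.center_row, c - roi.center_col
            u = dc * ct + dr * st
            v = -dc * st + dr * ct
            if (u / roi.semi_major) ** 2 + (v / roi.semi_minor) ** 2 <= 1.0:
                total += cube[r, c, :]
                count += 1
    return total / count


def select_top_oracle(cands, scores, n):
    """Sort-all-then-greedily-filter-overlaps reference for selection."""
    order = sorted(
        range(len(cands)),
        key=lambda i: (-scores[i].total, cands[i].center_row, cands[i].center_col),
    )
    chosen = []
    pixels: set[tuple[int, int]] = set()
    for i in order:
        rr, cc = cands[i].pixel_coords()
        pset = set(zip(rr.tolist(), cc.tolist()))
        if pixels & pset:
            continue
        pixels |= pset
        chosen.append(i)
        if len(chosen) == n:
            break
    return chosen


def match_fibres(regions, geometry, max_centroid_dist=5.0, min_iou=0.5):
    """Match detected fibre regions to ground-truth interiors.

    Returns (recall, precision, mean centroid error of matches)."""
    truth = []
    for lab in geometry.fibre_labels():
        mask = geometry.label_image == lab
        rr, cc = np.nonzero(mask)
        truth.append((mask, (rr.mean(), cc.mean())))
    used = set()
    matches = 0
    errs = []
    for reg in regions:
        best, best_d = None, np.inf
        for j, (tmask, tc) in enumerate(truth):
            if j in used:
                continue
            d = np.hypot(reg.centroid[0] - tc[0], reg.centroid[1] - tc[1])
            if d < best_d:
                best, best_d = j, d
        if best is None or best_d > max_centroid_dist:
            continue
        tmask = truth[best][0]
        inter = np.logical_and(reg.pixel_mask, tmask).sum()
        union = np.logical_or(reg.pixel_mask, tmask).sum()
        if inter / union >= min_iou:
            used.add(best)
            matches += 1
            errs.append(best_d)
    recall = matches / len(truth)
    precision = matches / len(regions) if regions else 0.0
    return recall, precision, (float(np.mean(errs)) if errs else np.nan)


def roi_wall_fraction(roi: EllipticalROI, wall_mask: np.ndarray) -> float:
    rr, cc = roi.pixel_coords()
    return float(wall_mask[rr, cc].mean())
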