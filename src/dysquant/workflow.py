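"""End-to-end orchestration: configuration, cohort simulation, quantification.

This module strings the pieces together the way a study would run them:
simulate (or load) a cohort of two-channel lambda stacks, place ROIs
automatically / from ground-truth oracles / from user-supplied CSVs,
quantify peak intensities, and emit tidy per-ROI and per-biopsy tables.
Everything is driven by a single `PipelineConfig` and is deterministic for a
fixed (config, seed) pair; disk layouts carry a provenance block (config
hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .model import EllipticalROI, SpectralStack
from .quantify import BiopsyResult, aggregate_biopsy, quantify_field
from .roi_detection import DetectionConfig, ROISet, detect_rois
from .simulate import (
    GroupSpec,
    PlacementError,
    SyntheticBiopsy,
    generate_cohort,
    oracle_rois,
    reference_cohort_groups,
)

__all__ = [
    "PipelineConfig",
    "simulate_cohort",
    "load_cohort",
    "quantify_biopsy",
    "quantify_cohort",
    "write_cohort",
]

ROIMode = Literal["auto", "oracle", "manual"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the simulation + detection + quantification pipeline."""

    # detection
    median_radius_px: int = 1
    binarize_method: str = "otsu"
    fixed_threshold: float | None = None
    morphology_radius_px: int = 2
    min_area_px: int = 300
    min_circularity: float = 0.3
    clear_border_components: bool = False
    dilation_radius_px: int = 4
    semi_major_px: float | None = None
    semi_minor_px: float | None = None
    spacing_px: float | None = None
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_rois: int = 26
    # simulation
    rows: int = 512
    cols: int = 512
    n_fibres: int = 30
    wall_thickness_px: float = 4.0
    fields_per_biopsy: int = 3
    confounder_fracs: Mapping[str, float] = field(
        default_factory=lambda: {"vessel": 0.02, "adipose": 0.03, "connective": 0.03}
    )
    antibodies: tuple[str, ...] = ("NCL-Dys1",)
    # quantification
    peak_policy: str = "per_biopsy"
    seed: int = 0

    def detection(self) -> DetectionConfig:
        return DetectionConfig(
            median_radius_px=self.median_radius_px,
            binarize_method=self.binarize_method,
            fixed_threshold=self.fixed_threshold,
            morphology_radius_px=self.morphology_radius_px,
            min_area_px=self.min_area_px,
            min_circularity=self.min_circularity,
            clear_border_components=self.clear_border_components,
            dilation_radius_px=self.dilation_radius_px,
            semi_major_px=self.semi_major_px,
            semi_minor_px=self.semi_minor_px,
            spacing_px=self.spacing_px,
            weights=tuple(self.weights),
            n_rois=self.n_rois,
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "weights" in data:
            data["weights"] = tuple(data["weights"])
        if "antibodies" in data:
            data["antibodies"] = tuple(data["antibodies"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["weights"] = list(d["weights"])
        d["antibodies"] = list(d["antibodies"])
        d["confounder_fracs"] = dict(d["confounder_fracs"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["confounder_fracs"] = dict(d["confounder_fracs"])
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def simulate_cohort(
    config: PipelineConfig,
    groups: Sequence[GroupSpec] | None = None,
    seed: int | None = None,
) -> list[SyntheticBiopsy]:
    """Generate the configured synthetic cohort in memory.

    Defaults to the reference cohort shape (10 DMD / 3 BMD / 6 control) at
    the published intensity levels for `config.antibodies`.
    """
    groups = list(groups) if groups is not None else reference_cohort_groups(config.antibodies)
    return generate_cohort(
        groups,
        fields_per_biopsy=config.fields_per_biopsy,
        rows=config.rows,
        cols=config.cols,
        n_fibres=config.n_fibres,
        wall_thickness_px=config.wall_thickness_px,
        confounder_fracs=config.confounder_fracs,
        seed=config.seed if seed is None else seed,
    )


def _field_rois(
    field_obj,
    config: PipelineConfig,
    roi_mode: ROIMode,
    field_id: str,
    manual: Mapping[str, list[EllipticalROI]] | None = None,
) -> ROISet:
    if roi_mode == "auto":
        return detect_rois(field_obj.beta_stack, config.detection(), field_id=field_id)
    if roi_mode == "oracle":
        geo = field_obj.geometry
        b = max(1.0, config.wall_thickness_px / 2.0)
        try:
            rois = oracle_rois(geo, n=config.n_rois, ellipse_params=(2.0 * b, b),
                               seed=field_obj.seed)
        except PlacementError as exc:
            return ROISet(field_id, exc.rois, [], config.n_rois, shortfall=True)
        return ROISet(field_id, rois, [], config.n_rois)
    if roi_mode == "manual":
        if manual is None or field_id not in manual:
            raise ValueError(f"no manual ROIs supplied for field {field_id!r}")
        return ROISet(field_id, list(manual[field_id]), [], len(manual[field_id]))
    raise ValueError(f"unknown roi_mode {roi_mode!r}")


def quantify_biopsy(
    biopsy: SyntheticBiopsy,
    config: PipelineConfig,
    roi_mode: ROIMode = "auto",
    manual: Mapping[str, list[EllipticalROI]] | None = None,
) -> tuple[dict[str, BiopsyResult], list[ROISet]]:
    """Place ROIs on each field's guide channel and quantify every antibody.

    ROIs are placed once per field (guide channel only) and reused across
    dystrophin channels.  Returns per-antibody biopsy results plus the ROI
    sets actually used.
    """
    roisets = []
    per_antibody_fields: dict[str, list] = {ab: [] for ab in biopsy.fields[0].dys_stacks}
    beta_fields = []
    for i, fld in enumerate(biopsy.fields):
        fid = f"{biopsy.biopsy_id}/f{i}"
        rs = _field_rois(fld, config, roi_mode, fid, manual)
        roisets.append(rs)
        for ab, stack in fld.dys_stacks.items():
            per_antibody_fields[ab].append(quantify_field(stack, rs))
        beta_fields.append(quantify_field(fld.beta_stack, rs))
    results = {
        ab: aggregate_biopsy(fq, biopsy.biopsy_id, biopsy.group_label, ab, config.peak_policy)
        for ab, fq in per_antibody_fields.items()
    }
    results["beta-spectrin"] = aggregate_biopsy(
        beta_fields, biopsy.biopsy_id, biopsy.group_label, "beta-spectrin", config.peak_policy
    )
    return results, roisets


def quantify_cohort(
    biopsies: Sequence[SyntheticBiopsy],
    config: PipelineConfig,
    roi_mode: ROIMode = "auto",
    manual: Mapping[str, list[EllipticalROI]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a cohort; returns (biopsy summary, long per-ROI table).

    Summary columns: biopsy_id, group, antibody, n_rois, mean_intensity,
    se_intensity, peak_center_nm, roi_mode.  The long table has one row per
    (biopsy, antibody, ROI) with its peak-window value.
    """
    summary_rows = []
    roi_rows = []
    for biopsy in biopsies:
        results, roisets = quantify_biopsy(biopsy, config, roi_mode, manual)
        for ab, res in results.items():
            summary_rows.append(
                dict(
                    biopsy_id=res.biopsy_id,
                    group=res.group_label,
                    antibody=ab,
                    n_rois=res.n_rois,
                    mean_intensity=res.mean_intensity,
                    se_intensity=res.se_intensity,
                    peak_center_nm=res.peak_center_nm,
                    roi_mode=roi_mode,
                )
            )
            for j, v in enumerate(res.roi_values):
                roi_rows.append(
                    dict(
                        biopsy_id=res.biopsy_id,
                        group=res.group_label,
                        antibody=ab,
                        roi_id=j,
                        value=float(v),
                        roi_mode=roi_mode,
                    )
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(roi_rows)


# ---------------------------------------------------------------------------
# disk layout


def write_cohort(
    biopsies: Sequence[SyntheticBiopsy], config: PipelineConfig, out_dir: str | Path
) -> Path:
    """Write a simulated cohort to disk (TIFF stacks + sidecars + truth).

    Layout: ``<out>/<biopsy_id>/f<k>/<channel>.tif[.json]`` plus
    ``truth.json`` and ``oracle_rois.csv`` per field, and a top-level
    ``manifest.json`` with the provenance block.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "provenance": _provenance(config),
        "biopsies": [],
    }
    for biopsy in biopsies:
        brec = {
            "biopsy_id": biopsy.biopsy_id,
            "group": biopsy.group_label,
            "true_means": biopsy.true_means,
            "fields": [],
        }
        for i, fld in enumerate(biopsy.fields):
            fdir = out / biopsy.biopsy_id / f"f{i}"
            fdir.mkdir(parents=True, exist_ok=True)
            dio.write_stack(fld.beta_stack, fdir / "beta-spectrin.tif")
            for ab, stack in fld.dys_stacks.items():
                dio.write_stack(stack, fdir / f"{ab}.tif")
            truth = {
                ch: dataclasses.asdict(tr) for ch, tr in fld.truth.items()
            }
            for tr in truth.values():
                tr["per_fibre_wall"] = {str(k): v for k, v in tr["per_fibre_wall"].items()}
            (fdir / "truth.json").write_text(json.dumps(truth, indent=1))
            try:
                b = max(1.0, config.wall_thickness_px / 2.0)
                orois = oracle_rois(fld.geometry, config.n_rois, (2.0 * b, b), seed=fld.seed)
                dio.write_roi_set(orois, fdir / "oracle_rois.csv")
            except PlacementError:
                pass
            brec["fields"].append(f"{biopsy.biopsy_id}/f{i}")
        manifest["biopsies"].append(brec)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_cohort(in_dir: str | Path) -> list[dict]:
    """Load a written cohort back as light records (stacks read lazily).

    Each record: ``{"biopsy_id", "group", "fields": [dict of channel ->
    SpectralStack, plus 'oracle_rois' when present]}``.
    """
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    cohort = []
    for brec in manifest["biopsies"]:
        fields = []
        for fid in brec["fields"]:
            fdir = in_dir / fid
            channels: dict[str, object] = {}
            for tif in sorted(fdir.glob("*.tif")):
                channels[tif.stem] = dio.read_stack(tif)
            entry = {"field_id": fid, "channels": channels}
            oc = fdir / "oracle_rois.csv"
            if oc.exists():
                entry["oracle_rois"] = dio.read_roi_set(oc)
            fields.append(entry)
        cohort.append(
            {"biopsy_id": brec["biopsy_id"], "group": brec["group"],
             "true_means": brec.get("true_means", {}), "fields": fields}
        )
    return cohort


def _provenance(config: PipelineConfig) -> dict:
    from . import __version__

    return {"config_digest": config.digest(), "seed": config.seed, "version": __version__}
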