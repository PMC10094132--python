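"""Synthetic two-channel spectral muscle fields with known ground truth.

The generator emulates a transversely cut muscle section imaged as two
co-registered lambda stacks:

* a membrane-guide channel (anti-beta-spectrin, Cy5-like emission collected
  590-780 nm) in which the sarcolemma is the bright structure used to place
  ROIs, and
* a dystrophin channel (AF488-like emission collected 485-625 nm) whose
  sarcolemmal intensity is the quantity under study and varies by diagnosis
  (near-absent in DMD, reduced in BMD, full in controls).

Geometry is a perturbed Voronoi tessellation of Poisson-disc seed points:
packed convex-ish polygonal fibre interiors separated by a sarcolemma wall
of roughly constant thickness, optionally interrupted by confounder regions
(vessels, adipose, connective tissue) that a correct ROI-placement pipeline
must avoid.  Emission spectra are Gaussians integrated over the overlapping
detection windows; intensities are quantized to 12 bits after adding
signal-dependent shot noise and constant readout noise.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erf
from skimage.morphology import skeletonize

from .model import MAX_12BIT, EllipticalROI, SpectralStack, WavelengthAxis

__all__ = [
    "BACKGROUND",
    "WALL",
    "VESSEL",
    "ADIPOSE",
    "CONNECTIVE",
    "FluorophoreModel",
    "NoiseModel",
    "GroupIntensityParams",
    "ChannelSpec",
    "FieldGeometry",
    "ChannelTruth",
    "SyntheticField",
    "SyntheticBiopsy",
    "GroupSpec",
    "build_wavelength_axis",
    "generate_geometry",
    "render_field",
    "generate_cohort",
    "oracle_rois",
    "PlacementError",
    "dystrophin_axis",
    "spectrin_axis",
    "dystrophin_channel",
    "spectrin_channel",
    "REFERENCE_DYSTROPHIN_LEVELS",
    "REFERENCE_SPECTRIN_LEVELS",
    "group_intensity_params",
    "reference_spectrin_params",
    "reference_cohort_groups",
]

# label_image class codes (fibre interiors are labelled 1..K)
BACKGROUND = 0
WALL = -1
VESSEL = -2
ADIPOSE = -3
CONNECTIVE = -4

_CONFOUNDER_CODES = {"vessel": VESSEL, "adipose": ADIPOSE, "connective": CONNECTIVE}

#: Reference group mean peak intensities (a.u.) and their standard errors
#: over 78 ROIs, per dystrophin antibody; used as simulator defaults.
REFERENCE_DYSTROPHIN_LEVELS: dict[str, dict[str, tuple[float, float]]] = {
    "NCL-Dys1": {"DMD": (500.8, 17.6), "BMD": (1190.8, 42.1), "CONTROL": (2982.9, 29.3)},
    "NCL-Dys2": {"DMD": (590.7, 25.3), "BMD": (1219.7, 44.56), "CONTROL": (2732.214, 28.4)},
    "NCL-Dys3": {"DMD": (296.8, 7.35), "BMD": (526.02, 17.13), "CONTROL": (2920.4, 30.91)},
}

#: Reference beta-spectrin group means (a.u.) with standard errors; the
#: membrane guide is brighter in dystrophic muscle than in controls.
REFERENCE_SPECTRIN_LEVELS: dict[str, tuple[float, float]] = {
    "DMD": (2346.13, 65.88),
    "BMD": (2379.38, 62.43),
    "CONTROL": (1832.17, 132.30),
}

#: ROI count behind the published standard errors (3 fields x 26 ROIs).
ROIS_PER_BIOPSY = 78


def build_wavelength_axis(
    start_nm: float, stop_nm: float, step_nm: float, bandwidth_nm: float
) -> WavelengthAxis:
    """Detection axis with centers ``start, start+step, ...`` up to `stop_nm`.

    >>> len(build_wavelength_axis(485, 625, 5.21, 15))
    27
    """
    if step_nm <= 0:
        raise ValueError("step must be positive")
    if not start_nm < stop_nm:
        raise ValueError("need start_nm < stop_nm")
    n = int(math.floor((stop_nm - start_nm) / step_nm + 1e-9)) + 1
    centers = start_nm + step_nm * np.arange(n)
    return WavelengthAxis(centers, bandwidth_nm, step_nm)


def dystrophin_axis() -> WavelengthAxis:
    """Default dystrophin-channel detection axis (485-625 nm, 15/5.21 nm)."""
    return build_wavelength_axis(485.0, 625.0, 5.21, 15.0)


def spectrin_axis() -> WavelengthAxis:
    """Default beta-spectrin-channel detection axis (590-780 nm, 15/5.21 nm)."""
    return build_wavelength_axis(590.0, 780.0, 5.21, 15.0)


@dataclass(frozen=True)
class FluorophoreModel:
    """Gaussian emission line: peak wavelength, spectral width, amplitude."""

    peak_nm: float
    sigma_nm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError("sigma_nm must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    def window_weights(self, axis: WavelengthAxis, normalize: bool = True) -> np.ndarray:
        """Gaussian emission integrated over each detection window.

        With ``normalize=True`` the weights are scaled so the brightest
        window equals `amplitude`; a structure rendered at base intensity I
        then shows I x amplitude in its peak window.
        """
        lo, hi = axis.window_edges()
        s = self.sigma_nm * math.sqrt(2.0)
        w = 0.5 * (erf((hi - self.peak_nm) / s) - erf((lo - self.peak_nm) / s))
        if normalize:
            w = w / w.max()
        return self.amplitude * w


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: constant readout SD plus Gaussian-approximated shot noise.

    Per-pixel variance = ``read_sd**2 + shot_scale * signal``.
    """

    read_sd: float = 8.0
    shot_scale: float = 1.0

    def sd(self, signal: np.ndarray) -> np.ndarray:
        return np.sqrt(self.read_sd**2 + self.shot_scale * np.maximum(signal, 0.0))


@dataclass(frozen=True)
class GroupIntensityParams:
    """Per-channel intensity regime of one diagnostic group.

    `wall_mean` is the mean noiseless sarcolemma intensity in the peak
    emission window (a.u.); `wall_sd` the between-fibre (hence between-ROI)
    SD of that intensity.  Interior and background levels are fractions of
    `wall_mean`; confounder classes likewise (vessels stay membrane-bright
    in the guide channel but not in the dystrophin channel).
    """

    group_label: str
    wall_mean: float
    wall_sd: float = 0.0
    cytoplasm_frac: float = 0.08
    background_frac: float = 0.02
    confounder_fracs: Mapping[str, float] = field(
        default_factory=lambda: {"vessel": 0.6, "adipose": 0.1, "connective": 0.15}
    )
    autofluorescence: float = 5.0
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.wall_mean < 0 or self.wall_sd < 0:
            raise ValueError("wall_mean and wall_sd must be non-negative")
        for name, frac in (("cytoplasm_frac", self.cytoplasm_frac),
                           ("background_frac", self.background_frac)):
            if not 0 <= frac < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class ChannelSpec:
    """Bundle of everything needed to render one channel."""

    label: str
    params: GroupIntensityParams
    fluorophore: FluorophoreModel
    axis: WavelengthAxis
    excitation: float


def dystrophin_channel(label: str, params: GroupIntensityParams) -> ChannelSpec:
    """AF488-like dystrophin channel (peak 519 nm, excited at 470 nm)."""
    return ChannelSpec(label, params, FluorophoreModel(519.0, 25.0), dystrophin_axis(), 470.0)


def spectrin_channel(params: GroupIntensityParams) -> ChannelSpec:
    """Cy5-like beta-spectrin guide channel (peak 670 nm, excited at 570 nm)."""
    return ChannelSpec("beta-spectrin", params, FluorophoreModel(670.0, 30.0), spectrin_axis(), 570.0)


@dataclass
class FieldGeometry:
    """Ground-truth geometry of one synthetic field.

    `label_image` holds fibre labels (>= 1) on fibre interiors and the class
    codes WALL/VESSEL/ADIPOSE/CONNECTIVE/BACKGROUND elsewhere.  `wall_owner`
    gives, for every pixel, the label of the nearest fibre seed (used to
    assign per-fibre wall intensities).
    """

    label_image: np.ndarray
    wall_mask: np.ndarray
    fibre_count: int
    wall_thickness_px: float
    wall_owner: np.ndarray
    seed_points: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape  # type: ignore[return-value]

    @property
    def fibre_interior_mask(self) -> np.ndarray:
        return self.label_image >= 1

    def class_mask(self, code: int) -> np.ndarray:
        return self.label_image == code

    def fibre_labels(self) -> np.ndarray:
        labs = np.unique(self.label_image)
        return labs[labs >= 1]


def _poisson_disc(rng: np.random.Generator, rows: int, cols: int, n: int) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling of n points (row, col)."""
    min_dist = 0.55 * math.sqrt(rows * cols / n)
    pts: list[tuple[float, float]] = []
    max_tries = 400 * n
    for _ in range(max_tries):
        p = (rng.uniform(0, rows), rng.uniform(0, cols))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_dist**2 for q in pts):
            pts.append(p)
            if len(pts) == n:
                break
    if len(pts) < n:
        raise ValueError(
            f"could not place {n} fibre seeds in a {rows}x{cols} frame "
            f"(min spacing {min_dist:.1f} px); fewer fibres or a larger frame needed"
        )
    return np.asarray(pts)


def generate_geometry(
    rows: int,
    cols: int,
    n_fibres: int,
    wall_thickness_px: float = 4.0,
    confounder_fracs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> FieldGeometry:
    """Packed polygonal fibres separated by a sarcolemma wall.

    Fibres are the cells of a Voronoi tessellation of Poisson-disc seed
    points, evaluated on smoothly warped coordinates so edges are gently
    curved rather than ruler-straight.  The wall is the band where the
    distance to the two nearest seeds differs by less than
    `wall_thickness_px` (width ~ the requested thickness).

    `confounder_fracs` maps class names (``vessel``, ``adipose``,
    ``connective``) to target area fractions; whole cells are converted,
    never more than 20% of the fibres in total.
    """
    if n_fibres < 1:
        raise ValueError("n_fibres must be >= 1")
    if wall_thickness_px < 1:
        raise ValueError("wall_thickness_px must be >= 1")
    if rows * cols / n_fibres < 64:
        raise ValueError(
            f"too many fibres for the frame: {n_fibres} fibres leave "
            f"{rows * cols / n_fibres:.0f} px each (need >= 64)"
        )
    rng = np.random.default_rng(seed)
    pts = _poisson_disc(rng, rows, cols, n_fibres)

    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    # smooth sinusoidal warp so Voronoi edges are not perfectly straight
    warp_r = np.zeros_like(rr)
    warp_c = np.zeros_like(cc)
    for _ in range(3):
        k1, k2 = rng.integers(1, 4, size=2)
        amp = rng.uniform(2.0, 5.0)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        warp_r += amp * np.sin(2 * np.pi * (k1 * rr / rows + k2 * cc / cols) + ph1)
        warp_c += amp * np.sin(2 * np.pi * (k2 * rr / rows + k1 * cc / cols) + ph2)

    coords = np.column_stack(((rr + warp_r).ravel(), (cc + warp_c).ravel()))
    if n_fibres >= 2:
        dist, idx = cKDTree(pts).query(coords, k=2)
        d1 = dist[:, 0].reshape(rows, cols)
        d2 = dist[:, 1].reshape(rows, cols)
        owner = (idx[:, 0] + 1).reshape(rows, cols).astype(np.int32)  # labels 1..n
        wall = (d2 - d1) <= wall_thickness_px
    else:
        # single fibre: a ring at a fixed radius from the seed stands in for
        # the cell boundary
        d1 = np.hypot(rr + warp_r - pts[0, 0], cc + warp_c - pts[0, 1])
        owner = np.ones((rows, cols), dtype=np.int32)
        radius = 0.3 * min(rows, cols)
        wall = np.abs(d1 - radius) <= wall_thickness_px / 2.0

    label_image = owner.copy()
    label_image[wall] = WALL

    confounder_fracs = dict(confounder_fracs or {})
    if confounder_fracs:
        max_convert = max(0, int(0.2 * n_fibres))
        order = rng.permutation(n_fibres) + 1
        area = rows * cols
        converted = 0
        cursor = 0
        for cls, frac in confounder_fracs.items():
            if cls not in _CONFOUNDER_CODES:
                raise ValueError(f"unknown confounder class {cls!r}")
            code = _CONFOUNDER_CODES[cls]
            placed = 0
            target = frac * area
            while placed < target and converted < max_convert and cursor < n_fibres:
                lab = order[cursor]
                cursor += 1
                cell = owner == lab  # interior plus this cell's share of wall
                label_image[cell] = code
                placed += int(cell.sum())
                converted += 1

    wall_mask = label_image == WALL
    fibre_labels = np.unique(label_image[label_image >= 1])
    return FieldGeometry(
        label_image=label_image,
        wall_mask=wall_mask,
        fibre_count=int(fibre_labels.size),
        wall_thickness_px=float(wall_thickness_px),
        wall_owner=owner,
        seed_points=pts,
    )


@dataclass
class ChannelTruth:
    """Noiseless ground truth of one rendered channel at its peak window."""

    wall_mean: float
    realized_wall_mean: float
    cytoplasm: float
    background: float
    autofluorescence: float
    peak_index: int
    peak_center_nm: float
    clipping_warning: bool
    per_fibre_wall: dict[int, float]


@dataclass
class SyntheticField:
    """Two co-registered rendered channels plus their generating truth.

    `dys_stacks` maps antibody label to its rendered dystrophin channel;
    `dys_stack` is the first (for the common single-antibody case).
    """

    beta_stack: SpectralStack
    dys_stacks: dict[str, SpectralStack]
    geometry: FieldGeometry
    truth: dict[str, ChannelTruth]
    seed: int

    @property
    def dys_stack(self) -> SpectralStack:
        return next(iter(self.dys_stacks.values()))


def _base_intensity_image(
    geometry: FieldGeometry,
    params: GroupIntensityParams,
    per_fibre_wall: dict[int, float],
) -> np.ndarray:
    """Noiseless per-pixel intensity at the peak window (before spectrum)."""
    li = geometry.label_image
    base = np.full(geometry.shape, params.background_frac * params.wall_mean)
    base[li >= 1] = params.cytoplasm_frac * params.wall_mean
    for cls, code in _CONFOUNDER_CODES.items():
        frac = params.confounder_fracs.get(cls, 0.0)
        base[li == code] = frac * params.wall_mean
    wall_vals = np.zeros(max(per_fibre_wall, default=0) + 1)
    for lab, v in per_fibre_wall.items():
        wall_vals[lab] = v
    wm = geometry.wall_mask
    base[wm] = wall_vals[geometry.wall_owner[wm]]
    return base


def _render_channel(
    geometry: FieldGeometry,
    spec: ChannelSpec,
    rng: np.random.Generator,
    pixel_size: float,
    bleed: tuple[np.ndarray, FluorophoreModel, float] | None = None,
) -> tuple[SpectralStack, ChannelTruth, np.ndarray]:
    params = spec.params
    labels = geometry.fibre_labels()
    draws = params.wall_mean + params.wall_sd * rng.standard_normal(labels.size)
    per_fibre = {int(l): float(max(v, 0.0)) for l, v in zip(labels, draws)}
    base = _base_intensity_image(geometry, params, per_fibre)

    w = spec.fluorophore.window_weights(spec.axis)
    noiseless = base[:, :, None] * w[None, None, :] + params.autofluorescence
    if bleed is not None:
        other_base, other_fluor, coeff = bleed
        if coeff > 0:
            leak_w = other_fluor.window_weights(spec.axis, normalize=False)
            own_peak = other_fluor.window_weights(other_fluor_axis(spec, other_fluor), normalize=False).max()
            noiseless = noiseless + coeff * other_base[:, :, None] * (leak_w / own_peak)[None, None, :]

    noisy = noiseless + params.noise.sd(noiseless) * rng.standard_normal(noiseless.shape)
    cube = np.clip(np.rint(noisy), 0, MAX_12BIT).astype(np.uint16)

    peak_idx = int(np.argmax(w))
    wall_noiseless_peak = noiseless[:, :, peak_idx][geometry.wall_mask]
    clipping = bool(np.mean(wall_noiseless_peak > MAX_12BIT) > 0.01) if wall_noiseless_peak.size else False
    realized = float(np.mean([per_fibre[l] for l in per_fibre])) if per_fibre else 0.0
    truth = ChannelTruth(
        wall_mean=params.wall_mean,
        realized_wall_mean=realized,
        cytoplasm=params.cytoplasm_frac * params.wall_mean,
        background=params.background_frac * params.wall_mean,
        autofluorescence=params.autofluorescence,
        peak_index=peak_idx,
        peak_center_nm=float(spec.axis.centers[peak_idx]),
        clipping_warning=clipping,
        per_fibre_wall=per_fibre,
    )
    stack = SpectralStack(
        cube=cube,
        axis=spec.axis,
        excitation=spec.excitation,
        pixel_size=pixel_size,
        bit_depth=12,
        channel_label=spec.label,
    )
    return stack, truth, base


def other_fluor_axis(spec: ChannelSpec, other: FluorophoreModel) -> WavelengthAxis:
    """Native axis of a leaking fluorophore (dystrophin- vs spectrin-range)."""
    return dystrophin_axis() if other.peak_nm < 600 else spectrin_axis()


def render_field(
    geometry: FieldGeometry,
    beta: ChannelSpec,
    dys: ChannelSpec | Sequence[ChannelSpec],
    seed: int = 0,
    pixel_size: float = 0.361,
    bleed_dys_into_beta: float = 0.0,
    bleed_beta_into_dys: float = 0.0,
) -> SyntheticField:
    """Render the guide channel and one or more dystrophin channels.

    Slice k of a channel is ``quantize(base * window_weight_k +
    autofluorescence + bleed + noise)`` clipped to the 12-bit ceiling;
    ``truth`` records per channel the noiseless peak-window intensities and
    a clipping warning when more than 1% of wall pixels would saturate.
    """
    dys_list = [dys] if isinstance(dys, ChannelSpec) else list(dys)
    rng = np.random.default_rng(seed)
    # dystrophin channels first: their base images feed optional bleed into beta
    dys_stacks: dict[str, SpectralStack] = {}
    truth: dict[str, ChannelTruth] = {}
    first_dys_base = None
    for ch in dys_list:
        stack, tr, base = _render_channel(geometry, ch, rng, pixel_size)
        dys_stacks[ch.label] = stack
        truth[ch.label] = tr
        if first_dys_base is None:
            first_dys_base = base

    beta_bleed = None
    if bleed_dys_into_beta > 0 and first_dys_base is not None:
        beta_bleed = (first_dys_base, dys_list[0].fluorophore, bleed_dys_into_beta)
    beta_stack, beta_truth, beta_base = _render_channel(
        geometry, beta, rng, pixel_size, bleed=beta_bleed
    )
    truth[beta.label] = beta_truth

    if bleed_beta_into_dys > 0:
        # re-render dystrophin channels with the beta leak folded in
        rng = np.random.default_rng(seed)
        for ch in dys_list:
            stack, tr, _ = _render_channel(
                geometry, ch, rng, pixel_size,
                bleed=(beta_base, beta.fluorophore, bleed_beta_into_dys),
            )
            dys_stacks[ch.label] = stack
            truth[ch.label] = tr

    return SyntheticField(
        beta_stack=beta_stack,
        dys_stacks=dys_stacks,
        geometry=geometry,
        truth=truth,
        seed=seed,
    )


class PlacementError(RuntimeError):
    """Raised when fewer oracle ROIs fit than requested."""

    def __init__(self, message: str, achieved: int, rois: list[EllipticalROI]):
        super().__init__(message)
        self.achieved = achieved
        self.rois = rois


def oracle_rois(
    geometry: FieldGeometry,
    n: int = 26,
    ellipse_params: tuple[float, float] = (4.0, 2.0),
    seed: int = 0,
    min_wall_frac: float = 0.9,
) -> list[EllipticalROI]:
    """Membrane-only elliptical ROIs standing in for a human operator.

    Candidates are skeleton pixels of the ground-truth wall, visited in a
    seeded random order; an ellipse (major axis along the local wall
    tangent) is accepted iff it lies in bounds, >= `min_wall_frac` of its
    pixels fall on the wall, and it does not touch an already accepted ROI.
    """
    from .roi_detection import tangent_field  # local import: avoids cycle

    if not geometry.wall_mask.any():
        raise ValueError("geometry has an empty wall mask")
    a, b = ellipse_params
    rng = np.random.default_rng(seed)
    skel = skeletonize(geometry.wall_mask)
    tangents = tangent_field(geometry.wall_mask)
    cand = np.argwhere(skel)
    rng.shuffle(cand)

    shape = geometry.shape
    occupied = np.zeros(shape, dtype=bool)
    out: list[EllipticalROI] = []
    for r, c in cand:
        roi = EllipticalROI(float(r), float(c), a, b, float(tangents[r, c]))
        rr, cc = roi.pixel_coords()
        if rr.size == 0:
            continue
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
            continue
        if np.mean(geometry.wall_mask[rr, cc]) < min_wall_frac:
            continue
        if occupied[rr, cc].any():
            continue
        occupied[rr, cc] = True
        out.append(roi)
        if len(out) == n:
            return out
    raise PlacementError(
        f"only {len(out)} of {n} non-overlapping membrane ROIs fit", len(out), out
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group of a synthetic cohort.

    `channel_params` maps channel labels to intensity regimes and must
    contain the key ``"beta-spectrin"``; every other key is rendered as a
    dystrophin-channel antibody.  Per-biopsy wall means are drawn around the
    group mean with SD ``between_biopsy_frac * wall_mean``.
    """

    group_label: str
    n_biopsies: int
    channel_params: Mapping[str, GroupIntensityParams]
    between_biopsy_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.n_biopsies < 1:
            raise ValueError("n_biopsies must be >= 1")
        if "beta-spectrin" not in self.channel_params:
            raise ValueError("channel_params must include 'beta-spectrin'")


@dataclass
class SyntheticBiopsy:
    biopsy_id: str
    group_label: str
    fields: list[SyntheticField]
    true_means: dict[str, float]  # channel label -> biopsy-level wall mean


def group_intensity_params(
    group_label: str, mean: float, se: float, n_rois: int = ROIS_PER_BIOPSY, **kwargs
) -> GroupIntensityParams:
    """Intensity regime from a published (mean, SE-over-n-ROIs) pair.

    The between-ROI SD is recovered as ``se * sqrt(n_rois)``.
    """
    return GroupIntensityParams(
        group_label=group_label, wall_mean=mean, wall_sd=se * math.sqrt(n_rois), **kwargs
    )


def reference_spectrin_params(group_label: str) -> GroupIntensityParams:
    """Guide-channel regime at the published group mean.

    The membrane-integrity control varies modestly between fibres (10% CV);
    its published errors are not tied to a 78-ROI convention, so the
    dystrophin table's sd = se * sqrt(78) reconstruction does not apply.
    """
    mean, _ = REFERENCE_SPECTRIN_LEVELS[group_label]
    return GroupIntensityParams(
        group_label=group_label, wall_mean=mean, wall_sd=0.10 * mean
    )


def reference_cohort_groups(
    antibodies: Sequence[str] = ("NCL-Dys1",),
    n_biopsies: Mapping[str, int] | None = None,
) -> list[GroupSpec]:
    """The reference cohort: 10 DMD, 3 BMD, 6 control biopsies at the
    published group intensity levels for the requested antibodies."""
    n_biopsies = dict(n_biopsies or {"DMD": 10, "BMD": 3, "CONTROL": 6})
    groups = []
    for g, nb in n_biopsies.items():
        ch: dict[str, GroupIntensityParams] = {"beta-spectrin": reference_spectrin_params(g)}
        for ab in antibodies:
            m, se = REFERENCE_DYSTROPHIN_LEVELS[ab][g]
            ch[ab] = group_intensity_params(g, m, se)
        groups.append(GroupSpec(group_label=g, n_biopsies=nb, channel_params=ch))
    return groups


def generate_cohort(
    groups: Sequence[GroupSpec],
    fields_per_biopsy: int = 3,
    rows: int = 512,
    cols: int = 512,
    n_fibres: int = 30,
    wall_thickness_px: float = 4.0,
    confounder_fracs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[SyntheticBiopsy]:
    """Render a whole synthetic cohort, deterministic per seed.

    Each biopsy gets its own wall means (group mean perturbed by the
    between-biopsy SD) and `fields_per_biopsy` independent fields.
    """
    if not groups:
        raise ValueError("empty cohort spec")
    biopsies: list[SyntheticBiopsy] = []
    for gi, gspec in enumerate(groups):
        for bi in range(gspec.n_biopsies):
            bss = np.random.SeedSequence(seed, spawn_key=(gi, bi))
            brng = np.random.default_rng(bss)
            true_means: dict[str, float] = {}
            biopsy_params: dict[str, GroupIntensityParams] = {}
            for label, p in gspec.channel_params.items():
                shift = gspec.between_biopsy_frac * p.wall_mean * brng.standard_normal()
                mean_b = max(p.wall_mean + shift, 0.0)
                true_means[label] = mean_b
                biopsy_params[label] = replace(p, wall_mean=mean_b)
            fields = []
            for fi in range(fields_per_biopsy):
                fss = np.random.SeedSequence(seed, spawn_key=(gi, bi, fi))
                geo_seed, render_seed = (int(s) % (2**31) for s in fss.generate_state(2))
                geometry = generate_geometry(
                    rows, cols, n_fibres, wall_thickness_px, confounder_fracs, seed=geo_seed
                )
                beta = spectrin_channel(biopsy_params["beta-spectrin"])
                dys = [
                    dystrophin_channel(lbl, prm)
                    for lbl, prm in biopsy_params.items()
                    if lbl != "beta-spectrin"
                ]
                fields.append(render_field(geometry, beta, dys, seed=render_seed))
            biopsies.append(
                SyntheticBiopsy(
                    biopsy_id=f"{gspec.group_label}-{bi + 1:02d}",
                    group_label=gspec.group_label,
                    fields=fields,
                    true_means=true_means,
                )
            )
    return biopsies
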