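"""Core data model for spectral (x-y-lambda) confocal quantification.

A spectral confocal acquisition produces, per channel, a cube of
``rows x cols x n_lambda`` intensities: one 2-D slice per emission-detection
window.  Windows are characterised by their centre wavelengths (strictly
ascending, evenly stepped) and a common bandwidth; windows may overlap
(bandwidth larger than the step is the normal acquisition regime here:
15 nm windows stepped by 5.21 nm).

Quantification happens inside small elliptical regions of interest (ROIs)
placed on the sarcolemma, so the model also defines the ellipse geometry and
its exact rasterization (a pixel belongs to the ellipse iff its centre
satisfies the ellipse inequality).

Coordinate convention: 0-based ``(row, col)``, origin at the top-left, row
increasing downward.  Ellipse orientation ``theta`` is measured from the
+col axis toward the +row axis, in ``[0, pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WavelengthAxis",
    "SpectralStack",
    "EllipticalROI",
    "Spectrum",
    "MAX_12BIT",
]

#: Ceiling of a 12-bit encoded intensity.
MAX_12BIT = 4095


@dataclass(frozen=True)
class WavelengthAxis:
    """Emission-detection wavelength axis of a lambda stack.

    Parameters
    ----------
    centers
        Window centre wavelengths in nm, strictly increasing and evenly
        spaced by `step`.
    bandwidth
        Width of each detection window in nm (> 0).  May exceed `step`,
        in which case adjacent windows overlap.
    step
        Centre-to-centre spacing in nm (> 0).
    """

    centers: tuple[float, ...]
    bandwidth: float
    step: float

    def __init__(self, centers: Sequence[float], bandwidth: float, step: float):
        object.__setattr__(self, "centers", tuple(float(c) for c in centers))
        object.__setattr__(self, "bandwidth", float(bandwidth))
        object.__setattr__(self, "step", float(step))
        self._validate()

    def _validate(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.size < 1:
            raise ValueError("wavelength axis needs at least one center")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if c.size > 1:
            d = np.diff(c)
            if np.any(d <= 0):
                raise ValueError("centers must be strictly increasing")
            if np.any(np.abs(d - self.step) > 1e-6):
                raise ValueError(
                    "center spacing must equal step within 1e-6 nm; "
                    f"got spacings {d} for step {self.step}"
                )

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def centers_nm(self) -> np.ndarray:
        return np.asarray(self.centers, dtype=float)

    def nearest_index(self, wavelength_nm: float) -> int:
        """Index of the window centre closest to `wavelength_nm` (ties -> lower)."""
        return int(np.argmin(np.abs(self.centers_nm - wavelength_nm)))

    def window_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) edges of every detection window, in nm."""
        c = self.centers_nm
        half = self.bandwidth / 2.0
        return c - half, c + half


@dataclass
class SpectralStack:
    """One channel's x-y-lambda intensity cube plus acquisition metadata.

    Intensities are arbitrary units bounded by the encoding bit depth
    (12 bits -> [0, 4095] by default).
    """

    cube: np.ndarray
    axis: WavelengthAxis
    excitation: float
    pixel_size: float = 0.361  # um per pixel (linear pitch)
    bit_depth: int = 12
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        self.validate()

    @property
    def intensity_ceiling(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape  # type: ignore[return-value]

    @property
    def n_lambda(self) -> int:
        return self.cube.shape[2]

    def validate(self) -> None:
        if self.cube.ndim != 3:
            raise ValueError(f"cube must be rows x cols x n_lambda, got ndim={self.cube.ndim}")
        rows, cols, nl = self.cube.shape
        if rows < 1 or cols < 1:
            raise ValueError("cube must have at least one row and one column")
        if nl != len(self.axis):
            raise ValueError(
                f"cube has {nl} wavelength slices but axis has {len(self.axis)} centers"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        lo = self.cube.min(initial=0)
        hi = self.cube.max(initial=0)
        if lo < 0 or hi > self.intensity_ceiling:
            raise ValueError(
                f"intensities [{lo}, {hi}] exceed the {self.bit_depth}-bit range "
                f"[0, {self.intensity_ceiling}]"
            )

    def slice_image(self, k: int) -> np.ndarray:
        """The 2-D image of wavelength window `k`."""
        return self.cube[:, :, k]


@dataclass(frozen=True)
class EllipticalROI:
    """A small ellipse placed on the sarcolemma; the unit of quantification.

    ``theta`` is the orientation of the major axis, measured from the +col
    axis toward the +row axis; it is normalised into ``[0, pi)``.
    """

    center_row: float
    center_col: float
    semi_major: float
    semi_minor: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"need semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        object.__setattr__(self, "theta", float(self.theta) % np.pi)

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the rasterized ellipse on an image of `shape`.

        Raises
        ------
        ValueError
            If any rasterized pixel falls outside the image bounds, or the
            raster is empty.
        """
        rr, cc = self.pixel_coords()
        if rr.size == 0:
            raise ValueError(f"ROI {self} rasterizes to zero pixels")
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
            raise ValueError(f"ROI {self} extends outside image bounds {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of pixels whose centres satisfy the ellipse inequality."""
        a, b = self.semi_major, self.semi_minor
        # bounding box of the rotated ellipse
        ct, st = np.cos(self.theta), np.sin(self.theta)
        half_c = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
        half_r = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
        r0 = int(np.floor(self.center_row - half_r))
        r1 = int(np.ceil(self.center_row + half_r))
        c0 = int(np.floor(self.center_col - half_c))
        c1 = int(np.ceil(self.center_col + half_c))
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
        dr = rr - self.center_row
        dc = cc - self.center_col
        u = dc * ct + dr * st  # along major axis
        v = -dc * st + dr * ct  # along minor axis
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return rr[inside].ravel(), cc[inside].ravel()

    def overlaps(self, other: "EllipticalROI") -> bool:
        """Exact rasterized pixel-set intersection test."""
        d2 = (self.center_row - other.center_row) ** 2 + (
            self.center_col - other.center_col
        ) ** 2
        reach = self.semi_major + other.semi_major + 2.0
        if d2 > reach * reach:  # cheap reject
            return False
        a = set(zip(*(x.tolist() for x in self.pixel_coords())))
        b = set(zip(*(x.tolist() for x in other.pixel_coords())))
        return not a.isdisjoint(b)


@dataclass
class Spectrum:
    """Mean intensity inside one ROI as a function of emission wavelength."""

    axis: WavelengthAxis
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.axis):
            raise ValueError(
                f"spectrum has {self.values.size} values for {len(self.axis)} windows"
            )
        if np.any(self.values < 0):
            raise ValueError("spectral values must be non-negative")

    def peak_index(self) -> int:
        return int(np.argmax(self.values))

    def value_at(self, index: int) -> float:
        return float(self.values[index])
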