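"""Morphological quantification of fluorescence micrographs.

Reimplements the particle-analysis workflow used to score amyloid burden
and cerebral amyloid angiopathy (CAA): maximum z-projection, rolling-ball
background subtraction, median filtering, fixed-value thresholding, binary
erosion/dilation, connected-component particle analysis, area fractions,
the plaque-on-vessel CAA% measure, and particle-count densities.

Intensity planes are float arrays in (y, x); stacks are (channel, z, y, x).
Areas are reported in both pixels and um^2 via the stack's pixel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import median as _sk_median
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.restoration import rolling_ball

__all__ = [
    "ImageStack",
    "RegionMask",
    "ParticleSet",
    "AreaFractionResult",
    "max_project",
    "subtract_background",
    "median_filter",
    "make_mask",
    "morph",
    "analyze_particles",
    "area_fraction",
    "caa_fraction",
    "count_cells",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)  # structuring element for erode/dilate
_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity for particle labeling


@dataclass
class ImageStack:
    """channel x z x y x x intensity lattice with physical pixel size."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be (channel, z, y, x)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one name per channel required")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if (self.data < 0).any():
            raise ValueError("intensities must be non-negative")

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        if not 0 <= channel < self.data.shape[0]:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)


@dataclass
class RegionMask:
    """Binary plane plus a record of how it was produced."""

    mask: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class ParticleSet:
    """Labeled 8-connected components with per-particle geometry."""

    labels: np.ndarray
    table: pd.DataFrame  # per particle: label, area_px, area_um2, centroid y/x
    pixel_size_um: float = 1.0

    @property
    def count(self) -> int:
        return len(self.table)

    @property
    def total_area_px(self) -> int:
        return int(self.table["area_px"].sum())


@dataclass
class AreaFractionResult:
    object_area_px: float
    roi_area_px: float
    percent: float
    pixel_size_um: float = 1.0

    @property
    def object_area_um2(self) -> float:
        return self.object_area_px * self.pixel_size_um**2


def max_project(stack: ImageStack, channel: int | str) -> np.ndarray:
    """Maximum-intensity projection of one channel over z."""
    c = stack.channel_index(channel)
    return stack.data[c].max(axis=0)


def subtract_background(plane: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction, clipped at zero.

    The background is the classical ball-opening estimate (a ball of the
    given radius rolled under the intensity surface). A radius at or above
    the smallest image dimension degenerates to global-minimum subtraction.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    plane = np.asarray(plane, dtype=float)
    if radius >= min(plane.shape):
        warnings.warn(
            "rolling-ball radius >= image size; subtracting global minimum",
            stacklevel=2,
        )
        return plane - plane.min()
    bg = rolling_ball(plane, radius=radius)
    return np.clip(plane - bg, 0.0, None)


def median_filter(plane: np.ndarray, radius: int = 2) -> np.ndarray:
    """Median over a disk of the given pixel radius; reflected edges."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return _sk_median(
        np.asarray(plane, dtype=float), footprint=disk(radius), mode="reflect"
    )


def make_mask(plane: np.ndarray, threshold: float | str) -> RegionMask:
    """Threshold a plane into a binary mask (pixel >= threshold is true).

    ``threshold`` is an absolute intensity by default — matching the
    practice of thresholding compared sections identically — or the string
    ``"otsu"`` for automatic bimodal thresholding.
    """
    plane = np.asarray(plane, dtype=float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown auto threshold method {threshold!r}")
        value = float(threshold_otsu(plane))
        tag = f"otsu={value:.4g}"
    else:
        value = float(threshold)
        if not np.isfinite(value):
            raise ValueError("threshold must be finite")
        tag = f"threshold={value:.6g}"
    mask = plane >= value
    if mask.all() or not mask.any():
        warnings.warn(
            f"mask is all-{'foreground' if mask.all() else 'background'}",
            stacklevel=2,
        )
    return RegionMask(mask=mask, provenance=(tag,))


def morph(mask: RegionMask, op: str, iterations: int) -> RegionMask:
    """Binary erosion or dilation with a 3x3 square, one pass per iteration."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return RegionMask(mask.mask.copy(), mask.provenance + (f"{op} x0",))
    if op == "erode":
        out = ndimage.binary_erosion(mask.mask, structure=_SQUARE3,
                                     iterations=iterations)
    elif op == "dilate":
        out = ndimage.binary_dilation(mask.mask, structure=_SQUARE3,
                                      iterations=iterations)
    else:
        raise ValueError("op must be 'erode' or 'dilate'")
    return RegionMask(out, mask.provenance + (f"{op} x{iterations}",))


def analyze_particles(
    mask: RegionMask | np.ndarray,
    min_area: float = 0.0,
    pixel_size_um: float = 1.0,
    connectivity: int = 8,
) -> ParticleSet:
    """Label connected components and tabulate per-particle area/centroid.

    Components are 8-connected by default (diagonally touching pixels
    merge); those below ``min_area`` (px^2) are discarded.
    """
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    structure = _EIGHT if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(m, structure=structure)
    rows = []
    if n:
        areas = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        centroids = ndimage.center_of_mass(m, labels, index=np.arange(1, n + 1))
        for lab, area, (cy, cx) in zip(range(1, n + 1), areas, centroids):
            if area < min_area:
                labels[labels == lab] = 0
                continue
            rows.append(
                {
                    "label": lab,
                    "area_px": int(area),
                    "area_um2": float(area) * pixel_size_um**2,
                    "centroid_y": float(cy),
                    "centroid_x": float(cx),
                }
            )
    table = pd.DataFrame(
        rows, columns=["label", "area_px", "area_um2", "centroid_y", "centroid_x"]
    )
    return ParticleSet(labels=labels, table=table, pixel_size_um=pixel_size_um)


def area_fraction(
    particles: ParticleSet, roi: RegionMask | np.ndarray
) -> AreaFractionResult:
    """Percent of ROI area occupied by particles: 100 * object / ROI."""
    roi_m = roi.mask if isinstance(roi, RegionMask) else np.asarray(roi, bool)
    roi_area = int(roi_m.sum())
    if roi_area == 0:
        raise ValueError("ROI is empty")
    object_area = int(((particles.labels > 0) & roi_m).sum())
    return AreaFractionResult(
        object_area_px=object_area,
        roi_area_px=roi_area,
        percent=100.0 * object_area / roi_area,
        pixel_size_um=particles.pixel_size_um,
    )


def caa_fraction(
    stack: ImageStack,
    vessel_channel: int | str,
    plaque_channel: int | str,
    vessel_threshold: float | str,
    plaque_threshold: float | str,
    bg_radius: int = 50,
    median_radius: int = 3,
    erode_iter: int = 2,
    dilate_iter: int = 2,
) -> AreaFractionResult:
    """CAA%: percent of vessel-mask area covered by plaque signal.

    The vessel channel is max-projected, background-subtracted (rolling
    ball), median-filtered, thresholded, eroded then dilated; the resulting
    mask area is the total vessel area. The plaque channel is max-projected,
    restricted to the vessel mask, thresholded, and the plaque-on-vessel
    area divided by the vessel area (x100) is returned.
    """
    vplane = max_project(stack, vessel_channel)
    vplane = subtract_background(vplane, radius=bg_radius)
    vplane = median_filter(vplane, radius=median_radius)
    vmask = make_mask(vplane, vessel_threshold)
    vmask = morph(vmask, "erode", erode_iter)
    vmask = morph(vmask, "dilate", dilate_iter)
    if vmask.area_px == 0:
        raise ValueError("no vessels detected (empty vessel mask)")
    pplane = max_project(stack, plaque_channel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-background plaque is a valid 0% case
        pmask = make_mask(pplane, plaque_threshold)
    caa_area = int((pmask.mask & vmask.mask).sum())
    return AreaFractionResult(
        object_area_px=caa_area,
        roi_area_px=vmask.area_px,
        percent=100.0 * caa_area / vmask.area_px,
        pixel_size_um=stack.pixel_size_um,
    )


def count_cells(
    plane: np.ndarray,
    threshold: float | str,
    bg_radius: int = 50,
    median_radius: int = 2,
    min_area: float = 0.0,
    pixel_size_um: float = 1.0,
    roi: RegionMask | np.ndarray | None = None,
) -> tuple[int, float]:
    """Automated particle counting; returns (count, density per um^2).

    Pipeline: background subtraction -> median filter -> threshold ->
    particle analysis; the count is normalised to the analysed area (the
    ROI if given, else the full frame).
    """
    plane = subtract_background(np.asarray(plane, float), radius=bg_radius)
    plane = median_filter(plane, radius=median_radius)
    mask = make_mask(plane, threshold)
    if roi is not None:
        roi_m = roi.mask if isinstance(roi, RegionMask) else np.asarray(roi, bool)
        mask = RegionMask(mask.mask & roi_m, mask.provenance + ("roi",))
        area_px = int(roi_m.sum())
    else:
        area_px = plane.size
    particles = analyze_particles(mask, min_area=min_area,
                                  pixel_size_um=pixel_size_um)
    area_um2 = area_px * pixel_size_um**2
    return particles.count, particles.count / area_um2
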