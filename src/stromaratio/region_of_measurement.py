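"""Regions in which the tumor-stroma ratio is measured.

Two regions are supported:

* **MI (most invasive)** — the single circular field of view of 1.6 mm
  radius (a 10x objective field) with the highest tumor fraction, where
  tumor fraction is tumor/(tumor+stroma), i.e. background is excluded from
  the denominator.  Candidate disks are only valid when more than 2/3 of
  their in-bounds non-NODATA area is tumor-or-stroma tissue, which excludes
  fields hanging off the tissue border.

* **WT (whole tumor bed)** — all pixels whose local tumor density (fraction
  of tumor within a disk neighborhood) exceeds a threshold.  The threshold
  rises for small tumors, shrinking the stroma margin painted around small
  lesions; small disconnected components are discarded.

Disk counts are computed by FFT convolution of 0/1 indicator rasters with a
rasterized disk kernel and rounded back to exact integers, so the optimized
search is bit-equivalent to brute-force per-center counting.  Disks clipped
by the image border are normalized by their in-bounds area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import (
    EmptyMapError,
    EmptyRomError,
    NoTumorError,
    NoValidFovError,
    ParameterError,
)
from .tissue_model import NODATA, STROMA, TUMOR, ClassMap

DEFAULT_MI_RADIUS_UM = 1600.0
DEFAULT_MIN_TISSUE_FRACTION = 2.0 / 3.0

DEFAULT_WT_KERNEL_RADIUS_UM = 500.0
DEFAULT_TAU_BASE = 0.15
DEFAULT_TAU_MAX = 0.50
DEFAULT_AREA_REF_MM2 = 50.0
DEFAULT_MIN_COMPONENT_MM2 = 0.1


@dataclass(frozen=True)
class FovCandidate:
    """One candidate circular field of view."""

    center: tuple[int, int]
    radius_um: float
    tumor_fraction: float
    tissue_fraction: float

    def is_valid(self, min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION) -> bool:
        return self.tissue_fraction > min_tissue_fraction


@dataclass
class RegionOfMeasurement:
    """Boolean mask plus the parameters that fully determine it."""

    mask: np.ndarray
    kind: Literal["MI", "WT"]
    params: dict

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class DensityField:
    """Local tumor density in [0, 1]; NaN where the map is NODATA."""

    values: np.ndarray
    kernel_radius_um: float


def disk_kernel(radius_px: float) -> np.ndarray:
    """Rasterized disk: pixel centers within ``radius_px`` of the center."""
    r = int(np.floor(radius_px))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= radius_px * radius_px


def _disk_counts(indicator: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Exact integer counts of ``indicator`` within the disk at every pixel."""
    out = fftconvolve(indicator.astype(np.float64), kernel.astype(np.float64), mode="same")
    return np.maximum(np.rint(out), 0).astype(np.int64)


def find_most_invasive_fov(
    cm: ClassMap,
    radius_um: float = DEFAULT_MI_RADIUS_UM,
    stride_px: int | None = None,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
) -> tuple[FovCandidate, RegionOfMeasurement]:
    """Find the valid circular field of view maximizing tumor fraction.

    Candidate centers lie on a regular grid with spacing ``stride_px``
    (default: disk radius / 16).  For each center, the disk (clipped at the
    borders) is scored by tumor fraction tumor/(tumor+stroma); candidates
    whose tissue fraction (tumor+stroma over all in-bounds non-NODATA
    pixels) is not strictly above ``min_tissue_fraction`` are invalid.
    Ties break toward higher tissue fraction, then row-major center order.

    Raises
    ------
    EmptyMapError
        If the map has no non-NODATA pixels.
    NoValidFovError
        If no candidate passes the tissue-fraction rule.
    """
    valid = cm.valid_mask()
    if not valid.any():
        raise EmptyMapError("class map contains only NODATA")
    radius_px = radius_um / cm.meta.mpp
    if stride_px is None:
        stride_px = max(1, int(round(radius_px / 16)))
    if stride_px < 1:
        raise ParameterError(f"stride_px must be >= 1, got {stride_px}")

    kernel = disk_kernel(radius_px)
    tumor_cnt = _disk_counts(cm.labels == TUMOR, kernel)
    stroma_cnt = _disk_counts(cm.labels == STROMA, kernel)
    valid_cnt = _disk_counts(valid, kernel)

    h, w = cm.shape
    best: tuple[float, float, tuple[int, int]] | None = None
    for r in range(0, h, stride_px):
        for c in range(0, w, stride_px):
            n_valid = valid_cnt[r, c]
            if n_valid == 0:
                continue
            n_tissue = tumor_cnt[r, c] + stroma_cnt[r, c]
            tissue_fraction = n_tissue / n_valid
            if not tissue_fraction > min_tissue_fraction:
                continue
            tumor_fraction = tumor_cnt[r, c] / n_tissue if n_tissue > 0 else 0.0
            if (
                best is None
                or tumor_fraction > best[0]
                or (tumor_fraction == best[0] and tissue_fraction > best[1])
            ):
                best = (tumor_fraction, tissue_fraction, (r, c))
    if best is None:
        raise NoValidFovError(
            f"no field of view with tissue fraction > {min_tissue_fraction:.3f}"
        )
    tumor_fraction, tissue_fraction, center = best
    cand = FovCandidate(
        center=center,
        radius_um=radius_um,
        tumor_fraction=tumor_fraction,
        tissue_fraction=tissue_fraction,
    )
    rr, cc = np.mgrid[0:h, 0:w]
    disk = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius_px * radius_px
    rom = RegionOfMeasurement(
        mask=disk & valid,
        kind="MI",
        params={
            "radius_um": radius_um,
            "stride_px": stride_px,
            "min_tissue_fraction": min_tissue_fraction,
            "center": list(center),
            "mpp": cm.meta.mpp,
        },
    )
    return cand, rom


def brute_force_most_invasive(
    cm: ClassMap,
    radius_um: float = DEFAULT_MI_RADIUS_UM,
    stride_px: int = 1,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
) -> FovCandidate:
    """Reference search: per-center pixel counting without convolutions.

    Exists as an independent cross-check of :func:`find_most_invasive_fov`;
    identical scoring and tie rules, quadratic cost.
    """
    valid = cm.valid_mask()
    if not valid.any():
        raise EmptyMapError("class map contains only NODATA")
    radius_px = radius_um / cm.meta.mpp
    kernel = disk_kernel(radius_px)
    kr = kernel.shape[0] // 2
    h, w = cm.shape
    labels = cm.labels
    best: tuple[float, float, tuple[int, int]] | None = None
    for r in range(0, h, stride_px):
        for c in range(0, w, stride_px):
            r0, r1 = max(0, r - kr), min(h, r + kr + 1)
            c0, c1 = max(0, c - kr), min(w, c + kr + 1)
            ksub = kernel[r0 - r + kr : r1 - r + kr, c0 - c + kr : c1 - c + kr]
            win = labels[r0:r1, c0:c1]
            n_tumor = int(np.count_nonzero(ksub & (win == TUMOR)))
            n_stroma = int(np.count_nonzero(ksub & (win == STROMA)))
            n_valid = int(np.count_nonzero(ksub & (win != NODATA)))
            if n_valid == 0:
                continue
            n_tissue = n_tumor + n_stroma
            tissue_fraction = n_tissue / n_valid
            if not tissue_fraction > min_tissue_fraction:
                continue
            tumor_fraction = n_tumor / n_tissue if n_tissue > 0 else 0.0
            if (
                best is None
                or tumor_fraction > best[0]
                or (tumor_fraction == best[0] and tissue_fraction > best[1])
            ):
                best = (tumor_fraction, tissue_fraction, (r, c))
    if best is None:
        raise NoValidFovError("no valid field of view")
    tf, sf, center = best
    return FovCandidate(center=center, radius_um=radius_um, tumor_fraction=tf, tissue_fraction=sf)


def local_tumor_density(
    cm: ClassMap,
    kernel_radius_um: float = DEFAULT_WT_KERNEL_RADIUS_UM,
    tissue_only: bool = False,
) -> DensityField:
    """Fraction of tumor pixels within a disk neighborhood of every pixel.

    The denominator counts all in-bounds non-NODATA pixels in the disk
    (background included), so necrotic cores inside a tumor lower the
    density smoothly; set ``tissue_only=True`` to count only tumor+stroma.
    Disks clipped at the border are normalized by their in-bounds area.
    NODATA pixels carry NaN.
    """
    if kernel_radius_um < cm.meta.mpp:
        raise ParameterError(
            f"kernel radius {kernel_radius_um} um is smaller than one pixel "
            f"({cm.meta.mpp} um)"
        )
    radius_px = kernel_radius_um / cm.meta.mpp
    kernel = disk_kernel(radius_px)
    tumor_cnt = _disk_counts(cm.labels == TUMOR, kernel)
    if tissue_only:
        denom = tumor_cnt + _disk_counts(cm.labels == STROMA, kernel)
    else:
        denom = _disk_counts(cm.valid_mask(), kernel)
    values = np.full(cm.shape, np.nan, dtype=np.float64)
    ok = denom > 0
    values[ok] = tumor_cnt[ok] / denom[ok]
    values[~cm.valid_mask()] = np.nan
    return DensityField(values=values, kernel_radius_um=kernel_radius_um)


def dynamic_threshold(
    tumor_area_mm2: float,
    tau_base: float = DEFAULT_TAU_BASE,
    tau_max: float = DEFAULT_TAU_MAX,
    area_ref_mm2: float = DEFAULT_AREA_REF_MM2,
) -> float:
    """Size-dependent density threshold for the tumor bed.

    Piecewise linear: tau_base for tumors at least as large as the
    reference area, rising linearly to tau_max as the tumor area shrinks to
    zero.  A higher threshold for small tumors leaves a smaller stroma
    margin around the tumor tissue.
    """
    if tumor_area_mm2 < 0:
        raise ParameterError(f"tumor area must be >= 0, got {tumor_area_mm2}")
    if not (0 < tau_base <= tau_max < 1):
        raise ParameterError(
            f"need 0 < tau_base <= tau_max < 1, got {tau_base}, {tau_max}"
        )
    if area_ref_mm2 <= 0:
        raise ParameterError(f"area_ref_mm2 must be > 0, got {area_ref_mm2}")
    if tumor_area_mm2 >= area_ref_mm2:
        return tau_base
    return tau_base + (tau_max - tau_base) * (1.0 - tumor_area_mm2 / area_ref_mm2)


def estimate_tumor_bed(
    cm: ClassMap,
    kernel_radius_um: float = DEFAULT_WT_KERNEL_RADIUS_UM,
    tau_base: float = DEFAULT_TAU_BASE,
    tau_max: float = DEFAULT_TAU_MAX,
    area_ref_mm2: float = DEFAULT_AREA_REF_MM2,
    min_component_mm2: float = DEFAULT_MIN_COMPONENT_MM2,
    tissue_only: bool = False,
) -> RegionOfMeasurement:
    """Threshold the local tumor density into the whole-tumor bed mask.

    The tumor area (mm^2) sets the threshold via :func:`dynamic_threshold`;
    pixels with density strictly above it enter the mask, and 8-connected
    components smaller than ``min_component_mm2`` are removed.

    Raises
    ------
    NoTumorError
        If the map contains no tumor pixels.
    EmptyRomError
        If thresholding (plus small-component removal) leaves no pixels.
    """
    n_tumor = cm.count(TUMOR)
    if n_tumor == 0:
        raise NoTumorError("class map contains no tumor pixels")
    px_area_mm2 = (cm.meta.mpp / 1000.0) ** 2
    tumor_area_mm2 = n_tumor * px_area_mm2
    tau = dynamic_threshold(tumor_area_mm2, tau_base, tau_max, area_ref_mm2)
    density = local_tumor_density(cm, kernel_radius_um, tissue_only=tissue_only)
    with np.errstate(invalid="ignore"):
        mask = density.values > tau
    mask &= cm.valid_mask()
    if min_component_mm2 > 0 and mask.any():
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * px_area_mm2 >= min_component_mm2) + 1
        mask = np.isin(lab, keep)
    if not mask.any():
        raise EmptyRomError(
            f"tumor-bed threshold tau={tau:.3f} left an empty region "
            f"(tumor area {tumor_area_mm2:.2f} mm^2)"
        )
    return RegionOfMeasurement(
        mask=mask,
        kind="WT",
        params={
            "kernel_radius_um": kernel_radius_um,
            "tau_base": tau_base,
            "tau_max": tau_max,
            "area_ref_mm2": area_ref_mm2,
            "min_component_mm2": min_component_mm2,
            "tissue_only": tissue_only,
            "tau": tau,
            "tumor_area_mm2": tumor_area_mm2,
            "mpp": cm.meta.mpp,
        },
    )
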