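"""Synthetic tissue masks and patient cohorts with known ground truth.

Every pipeline stage can be exercised without patient data:

* :func:`generate_mask` paints a label raster with organic tumor/stroma
  interdigitation (thresholded smoothed-noise fields seeded with a chosen
  number of tumor nests), background blobs standing in for necrosis and
  adipose tissue, and a designated circular field in which the realized
  stroma fraction is planted exactly by quantile-thresholding the noise
  field — the ground-truth record carries exact pixel tallies.

* :func:`generate_cohort` simulates a two-arm cohort with exponential
  baseline survival calibrated to a chosen median, multiplicative hazards
  for the stroma-rich and TIL-low strata, uniform-fraction right censoring
  hitting an exact censoring fraction, and progression-free survival drawn
  as a Beta fraction of overall survival.

Both generators are pure functions of their specification (including the
seed): the same spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .tissue_model import BACKGROUND, NODATA, STROMA, TUMOR, ClassMap, SlideMeta

DEFAULT_MI_RADIUS_UM = 1600.0


@dataclass(frozen=True)
class MaskSpec:
    """Specification of one synthetic label raster.

    Defaults describe a 6.4 x 6.4 mm tile at a 25 um/px working resolution
    with a planted 1.6 mm most-invasive disk, moderate background blobs and
    a handful of tumor nests — roughly the texture scale of an ovarian
    tumor section at low magnification.
    """

    width_px: int = 256
    height_px: int = 256
    mpp: float = 25.0
    target_stroma_fraction_mi: float = 0.4
    target_stroma_fraction_wt: float = 0.5
    background_blob_fraction: float = 0.15
    n_tumor_nests: int = 4
    mi_radius_um: float = DEFAULT_MI_RADIUS_UM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "target_stroma_fraction_mi",
            "target_stroma_fraction_wt",
            "background_blob_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"{name} must be in [0, 1], got {v}")
        if self.width_px < 1 or self.height_px < 1 or self.mpp <= 0:
            raise SpecError("invalid raster geometry")


@dataclass
class GroundTruth:
    """Exact pixel tallies of a generated mask."""

    mi_center: tuple[int, int]
    mi_radius_px: float
    mi_n_tumor: int
    mi_n_stroma: int
    mi_n_background: int
    n_tumor: int
    n_stroma: int
    n_background: int

    @property
    def mi_stroma_fraction(self) -> float:
        return self.mi_n_stroma / (self.mi_n_stroma + self.mi_n_tumor)

    @property
    def mi_stroma_percent(self) -> float:
        # same expression shape as the TSR tally, for bit-equal comparison
        return 100.0 * self.mi_n_stroma / (self.mi_n_stroma + self.mi_n_tumor)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=sigma)


def _threshold_exact_count(field_vals: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting exactly the k largest entries of ``field_vals``.

    Ties in the continuous noise field are measure-zero but broken
    deterministically by flat index via argsort.
    """
    flat = field_vals.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(field_vals.shape)


def _stratified_stroma_split(
    region: np.ndarray,
    fraction: float,
    field_vals: np.ndarray,
    tile: int,
) -> np.ndarray:
    """Select stroma pixels within ``region`` tile-by-tile.

    The global stroma count equals ``round(fraction * n_region)`` exactly
    (largest-remainder allocation across tiles), while per-tile counts stay
    within one pixel of the tile quota — so the local stroma fraction is
    homogeneous at scales above the tile size and no sub-region is
    substantially more tumor-dense than the whole.
    """
    h, w = region.shape
    n_region = int(region.sum())
    k_total = int(round(fraction * n_region))
    blocks = []
    for r0 in range(0, h, tile):
        for c0 in range(0, w, tile):
            block = np.zeros((h, w), dtype=bool)
            block[r0 : r0 + tile, c0 : c0 + tile] = True
            block &= region
            nb = int(block.sum())
            if nb:
                blocks.append((block, nb))
    quotas = np.array([fraction * nb for _, nb in blocks])
    ks = np.floor(quotas).astype(int)
    short = k_total - ks.sum()
    if short > 0:
        order = np.argsort(quotas - ks)[::-1]
        for i in order[:short]:
            if ks[i] < blocks[i][1]:
                ks[i] += 1
    elif short < 0:
        order = np.argsort(quotas - ks)
        for i in order[:-short]:
            if ks[i] > 0:
                ks[i] -= 1
    out = np.zeros((h, w), dtype=bool)
    for (block, _), k in zip(blocks, ks):
        if k:
            vals = np.where(block, field_vals, -np.inf)
            out |= _threshold_exact_count(vals, int(k))
    return out


def generate_mask(spec: MaskSpec) -> tuple[ClassMap, GroundTruth]:
    """Generate a label raster with an exactly planted MI stroma fraction.

    The designated most-invasive disk sits at the raster center, contains
    only tumor and stroma, and its stroma pixel count equals
    ``round(target_stroma_fraction_mi * n_disk_px)`` exactly.  Outside the
    disk, background blobs cover ``background_blob_fraction`` of the area
    and the remaining tissue is split toward ``target_stroma_fraction_wt``
    with an exact stroma count per coarse tile (total off by at most one
    pixel per tile from the target fraction).
    """
    h, w = spec.height_px, spec.width_px
    radius_px = spec.mi_radius_um / spec.mpp
    cr, cc = h // 2, w // 2
    if cr - radius_px < 0 or cc - radius_px < 0 or cr + radius_px >= h or cc + radius_px >= w:
        raise SpecError(
            f"planted disk of radius {radius_px:.1f} px does not fit in "
            f"{h}x{w}"
        )
    rng = np.random.default_rng(spec.seed)
    rr, ccx = np.mgrid[0:h, 0:w]
    disk = ((rr - cr) ** 2 + (ccx - cc) ** 2) <= radius_px * radius_px

    # Spatially-correlated fields; nest bumps bias where tumor concentrates.
    sigma = max(2.0, min(h, w) / 24)
    tumor_field = _smooth_noise(rng, (h, w), sigma)
    for _ in range(spec.n_tumor_nests):
        nr, nc = rng.integers(0, h), rng.integers(0, w)
        bump = np.exp(-(((rr - nr) ** 2 + (ccx - nc) ** 2) / (2 * (sigma * 3) ** 2)))
        tumor_field += 1.5 * bump
    bg_field = _smooth_noise(rng, (h, w), sigma)

    labels = np.empty((h, w), dtype=np.uint8)

    # Outside the disk: background blobs, then tumor/stroma split.  The
    # split is stratified over coarse tiles with an exact stroma count per
    # tile, so the local tumor density stays near 1 - target everywhere and
    # no off-disk region can out-compete the planted field of view (as long
    # as the planted tumor fraction exceeds the whole-tumor one).
    outside = ~disk
    n_out = int(outside.sum())
    n_bg = int(round(spec.background_blob_fraction * n_out))
    bg_vals = np.where(outside, bg_field, -np.inf)
    bg_mask = _threshold_exact_count(bg_vals, n_bg)
    tissue_out = outside & ~bg_mask
    labels[outside] = BACKGROUND
    labels[tissue_out] = TUMOR
    tile = max(8, int(round(min(h, w) / 16)))
    stroma_out = _stratified_stroma_split(
        tissue_out, spec.target_stroma_fraction_wt, -tumor_field, tile
    )
    labels[stroma_out] = STROMA

    # Inside the disk: pure tissue with the exact planted stroma count,
    # stratified so the planted disk itself is the most tumor-dense field
    # whenever its tumor fraction exceeds the whole-tumor one.
    labels[disk] = TUMOR
    stroma_mi = _stratified_stroma_split(
        disk, spec.target_stroma_fraction_mi, -tumor_field, tile
    )
    labels[stroma_mi] = STROMA

    meta = SlideMeta(
        slide_id=f"synthetic-{spec.seed}",
        mpp=spec.mpp,
        width_px=w,
        height_px=h,
    )
    cm = ClassMap(labels=labels, meta=meta)
    gt = GroundTruth(
        mi_center=(cr, cc),
        mi_radius_px=radius_px,
        mi_n_tumor=int(np.count_nonzero(labels[disk] == TUMOR)),
        mi_n_stroma=int(np.count_nonzero(labels[disk] == STROMA)),
        mi_n_background=int(np.count_nonzero(labels[disk] == BACKGROUND)),
        n_tumor=cm.count(TUMOR),
        n_stroma=cm.count(STROMA),
        n_background=cm.count(BACKGROUND),
    )
    return cm, gt


def planted_disk_rom(cm: ClassMap, gt: GroundTruth):
    """Region of measurement over the generator's planted MI disk."""
    from .region_of_measurement import RegionOfMeasurement

    h, w = cm.shape
    rr, cc = np.mgrid[0:h, 0:w]
    disk = ((rr - gt.mi_center[0]) ** 2 + (cc - gt.mi_center[1]) ** 2) <= gt.mi_radius_px**2
    return RegionOfMeasurement(
        mask=disk & cm.valid_mask(),
        kind="MI",
        params={"planted": True, "center": list(gt.mi_center), "radius_px": gt.mi_radius_px},
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one simulated patient cohort.

    Defaults emulate an advanced-stage ovarian-cancer cohort: median OS
    around 38 months, moderate censoring, one third stroma-rich, hazard
    ratios of 1.6 for stroma-rich and 1.5 for TIL-low on the scale typical
    of crude TSR effects, and TIL ordinal bins skewed toward low counts.
    """

    n_patients: int = 340
    hr_stroma_rich: float = 1.6
    hr_til_low: float = 1.5
    baseline_median_os_months: float = 38.0
    censoring_fraction: float = 0.15
    prevalence_stroma_rich: float = 0.33
    til_bin_distribution: tuple[float, ...] = (0.10, 0.20, 0.25, 0.20, 0.15, 0.10)
    prop_pds: float = 0.42
    tsr_cutoff_percent: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecError("n_patients must be >= 1")
        if self.hr_stroma_rich <= 0 or self.hr_til_low <= 0:
            raise SpecError("hazard ratios must be > 0")
        if not (0.0 <= self.censoring_fraction < 1.0):
            raise SpecError("censoring_fraction must be in [0, 1)")
        if not (0.0 <= self.prevalence_stroma_rich <= 1.0):
            raise SpecError("prevalence must be in [0, 1]")
        if abs(sum(self.til_bin_distribution) - 1.0) > 1e-9:
            raise SpecError("til_bin_distribution must sum to 1")


@dataclass
class TrueParams:
    """Every generative constant of a simulated cohort."""

    baseline_rate: float
    hr_stroma_rich: float
    hr_til_low: float
    til_high_threshold: int
    censoring_fraction: float
    pfs_beta: tuple[float, float]
    tsr_cutoff_percent: float
    seed: int


def _til_high_threshold(dist: Sequence[float]) -> int:
    """Bin code at/above which the top quartile of the distribution sits.

    Same ceil-quantile tie rule as the analysis-side categorization, but
    computed from the theoretical distribution: the smallest code whose
    upper-tail mass is <= 25% once the code below is included.
    """
    cdf = np.cumsum(dist)
    for code in range(len(dist)):
        if cdf[code] >= 0.75:
            # mass strictly below `code` plus ties at `code` straddle 75%
            return code if cdf[code] > 0.75 or code == len(dist) - 1 else code + 1
    return len(dist) - 1


def generate_cohort(spec: CohortSpec) -> tuple[list, TrueParams]:
    """Simulate patient records with known proportional-hazards structure.

    Overall survival is exponential with rate ln(2)/median scaled by
    ``hr_stroma_rich`` for stroma-rich patients and ``hr_til_low`` for
    TIL-low patients (CD8 bin below the distribution's top quartile).  A
    randomly chosen ``round(censoring_fraction * n)`` patients are right
    censored at a uniform fraction of their event time, so the realized
    censoring fraction is exact.  PFS is a Beta(2, 2)-distributed fraction
    of OS with its own event indicator.  Continuous TSR scores are drawn
    uniformly on the rich/poor side of ``tsr_cutoff_percent``.
    """
    from .cohort_stats import PatientRecord

    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    rich = rng.random(n) < spec.prevalence_stroma_rich
    dist = np.asarray(spec.til_bin_distribution)
    til_bins = {
        m: rng.choice(len(dist), size=n, p=dist)
        for m in ("cd8", "cd20", "cd68", "cd103")
    }
    thr = _til_high_threshold(spec.til_bin_distribution)
    til_low = til_bins["cd8"] < thr

    lam0 = np.log(2.0) / spec.baseline_median_os_months
    lam = lam0 * np.where(rich, spec.hr_stroma_rich, 1.0) * np.where(til_low, spec.hr_til_low, 1.0)
    os_t = rng.exponential(1.0 / lam)

    os_event = np.ones(n, dtype=np.int64)
    n_cens = int(round(spec.censoring_fraction * n))
    cens_idx = rng.choice(n, size=n_cens, replace=False)
    os_event[cens_idx] = 0
    os_obs = os_t.copy()
    os_obs[cens_idx] = os_t[cens_idx] * rng.random(n_cens)

    pfs_frac = rng.beta(2.0, 2.0, size=n)
    pfs_obs = os_obs * pfs_frac
    pfs_event = np.where(rng.random(n) < 0.85, 1, 0)
    pfs_event[os_event == 0] = np.where(rng.random((os_event == 0).sum()) < 0.5, 1, 0)

    cut = spec.tsr_cutoff_percent
    tsr = np.where(
        rich,
        cut + rng.random(n) * (95.0 - cut),
        5.0 + rng.random(n) * max(cut - 5.0, 1e-9),
    )
    noise = rng.normal(0.0, 7.0, size=n)
    tsr_manual = np.clip(np.round((tsr + noise) / 10.0) * 10.0, 0.0, 100.0)

    treat = np.where(rng.random(n) < spec.prop_pds, "PDS", "NACT")
    age_group = rng.choice(["<65", "65-75", ">75"], size=n, p=[0.45, 0.38, 0.17])
    figo = rng.choice(["II", "III", "IV"], size=n, p=[0.06, 0.64, 0.30])
    residual = rng.choice(["complete", "optimal", "suboptimal"], size=n, p=[0.57, 0.34, 0.09])

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                treatment=str(treat[i]),
                os_months=float(os_obs[i]),
                os_event=int(os_event[i]),
                pfs_months=float(pfs_obs[i]),
                pfs_event=int(pfs_event[i]),
                covariates={
                    "age_group": str(age_group[i]),
                    "figo_stage": str(figo[i]),
                    "residual_status": str(residual[i]),
                    "stroma_rich": int(rich[i]),
                    "til_low": int(til_low[i]),
                },
                til_scores={m: int(b[i]) for m, b in til_bins.items()},
                tsr_manual_mi=float(tsr_manual[i]),
                tsr_auto_mi=float(tsr[i]),
                tsr_auto_wt=float(np.clip(tsr[i] + rng.normal(0, 3.0), 0, 100)),
            )
        )
    true = TrueParams(
        baseline_rate=lam0,
        hr_stroma_rich=spec.hr_stroma_rich,
        hr_til_low=spec.hr_til_low,
        til_high_threshold=thr,
        censoring_fraction=n_cens / n,
        pfs_beta=(2.0, 2.0),
        tsr_cutoff_percent=cut,
        seed=spec.seed,
    )
    return records, true


def generate_changepoint_cohort(
    n: int = 300,
    true_cutoff: float = 30.0,
    hazard_ratio: float = 2.0,
    baseline_median_os_months: float = 38.0,
    censoring_fraction: float = 0.15,
    seed: int = 0,
):
    """Cohort whose hazard doubles above a known TSR change point.

    TSR is uniform on [5, 95]; patients with TSR >= ``true_cutoff`` carry
    ``hazard_ratio`` times the baseline hazard.  Used to verify that the
    survival-driven cutoff search recovers a known change point.
    Returns (tsr, os_months, os_event) arrays.
    """
    rng = np.random.default_rng(seed)
    tsr = 5.0 + 90.0 * rng.random(n)
    lam0 = np.log(2.0) / baseline_median_os_months
    lam = lam0 * np.where(tsr >= true_cutoff, hazard_ratio, 1.0)
    t = rng.exponential(1.0 / lam)
    event = np.ones(n, dtype=np.int64)
    n_cens = int(round(censoring_fraction * n))
    idx = rng.choice(n, size=n_cens, replace=False)
    event[idx] = 0
    t[idx] = t[idx] * rng.random(n_cens)
    return tsr, t, event
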