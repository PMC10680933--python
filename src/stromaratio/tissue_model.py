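"""Slide metadata, tissue class maps, and patch-based classification.

A whole-slide image is represented here only after tissue typing: a
:class:`ClassMap` is a 2-D label raster over {background, tumor, stroma}
plus a NODATA code, carrying physical resolution (micrometers per pixel) so
that downstream geometry (field-of-view radii, tumor-bed areas) can be
expressed in micrometers and millimeters.

The patch machinery extracts overlapping RGB tiles, pushes them through a
pluggable classifier producing per-class probabilities, and stitches the
per-patch probabilities back into a per-pixel probability map whose argmax
yields the class map.  The classifier slot accepts any callable mapping an
RGB tile to a 3-vector of probabilities; the package ships a deterministic
palette-based classifier for synthetic fixtures and a small trainable
color/texture baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from .errors import ContractError, DataError, ParameterError, SizeError

# Label codes.  BACKGROUND covers necrosis, adipose tissue, psammoma bodies,
# vessels and glass; NODATA marks unscanned/excluded area and is ignored by
# every tally.
BACKGROUND = 0
TUMOR = 1
STROMA = 2
NODATA = 255

VALID_CODES = frozenset({BACKGROUND, TUMOR, STROMA, NODATA})

#: Default fixture palette used by the reference classifier and the
#: synthetic RGB renderer: nominal colors for tumor (red), stroma (green),
#: background (blue); NODATA renders white.
FIXTURE_PALETTE: dict[int, tuple[int, int, int]] = {
    TUMOR: (200, 30, 30),
    STROMA: (30, 160, 60),
    BACKGROUND: (70, 70, 220),
}

# Order in which class probabilities are stacked everywhere in the package.
CLASS_ORDER = (BACKGROUND, TUMOR, STROMA)


@dataclass(frozen=True)
class SlideMeta:
    """Physical metadata of one slide raster.

    Parameters
    ----------
    slide_id : str
        Opaque identifier.
    mpp : float
        Micrometers per pixel, isotropic.  H&E slides scanned at 40x are
        typically 0.25 um/px; analysis often runs at a coarser working
        resolution.
    width_px, height_px : int
        Raster dimensions in pixels.
    magnification_label : str, optional
        Free-text magnification tag such as ``"20x"``.
    """

    slide_id: str
    mpp: float
    width_px: int
    height_px: int
    magnification_label: str | None = None

    def __post_init__(self) -> None:
        if not self.mpp > 0:
            raise ParameterError(f"mpp must be > 0, got {self.mpp}")
        if self.width_px < 1 or self.height_px < 1:
            raise ParameterError(
                f"raster dimensions must be >= 1, got {self.width_px}x{self.height_px}"
            )

    @property
    def width_um(self) -> float:
        return self.width_px * self.mpp

    @property
    def height_um(self) -> float:
        return self.height_px * self.mpp


@dataclass
class ClassMap:
    """A 2-D tissue label raster with physical metadata.

    ``labels`` holds the codes {0=BACKGROUND, 1=TUMOR, 2=STROMA, 255=NODATA}
    in a ``(height_px, width_px)`` uint8 array, row-major, 0-based.
    """

    labels: np.ndarray
    meta: SlideMeta

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise DataError("labels must be a 2-D raster")
        if self.labels.shape != (self.meta.height_px, self.meta.width_px):
            raise DataError(
                f"labels shape {self.labels.shape} does not match metadata "
                f"({self.meta.height_px}, {self.meta.width_px})"
            )
        bad = set(np.unique(self.labels)) - VALID_CODES
        if bad:
            raise DataError(f"labels contain invalid codes {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def count(self, code: int) -> int:
        return int(np.count_nonzero(self.labels == code))

    def valid_mask(self) -> np.ndarray:
        """Boolean raster of non-NODATA pixels."""
        return self.labels != NODATA


@dataclass
class PatchGrid:
    """Overlapping RGB tiles on a regular, border-clamped grid."""

    patch_size_px: int
    stride_px: int
    origins: list[tuple[int, int]]
    patches: list[np.ndarray] = field(repr=False)


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities stitched from overlapping patches.

    ``probs`` has shape ``(3, H, W)`` ordered (background, tumor, stroma);
    ``counts`` is the number of patches covering each pixel.  Probabilities
    are defined (and sum to 1) only where ``counts >= 1``.
    """

    probs: np.ndarray
    counts: np.ndarray


PatchClassifier = Callable[[np.ndarray], np.ndarray]


def _axis_origins(length: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, length - patch + 1, stride))
    last = length - patch
    if origins[-1] != last:
        origins.append(last)  # clamp so the final patch abuts the border
    return origins


def extract_patches(
    image: np.ndarray,
    meta: SlideMeta,
    patch_size_px: int = 256,
    stride_px: int = 128,
) -> PatchGrid:
    """Extract overlapping tiles on a regular grid clamped to the border.

    Origins form a stride-spaced grid; the last row/column is clamped so the
    final patches abut the image border without out-of-bounds reads, and
    every pixel is covered by at least one patch.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if (h, w) != (meta.height_px, meta.width_px):
        raise DataError(f"image shape {(h, w)} disagrees with metadata")
    if stride_px < 1:
        raise ParameterError(f"stride_px must be >= 1, got {stride_px}")
    if patch_size_px > min(h, w):
        raise SizeError(
            f"patch of {patch_size_px} px does not fit inside a {h}x{w} image"
        )
    if stride_px > patch_size_px:
        raise ParameterError("stride_px must not exceed patch_size_px")

    rows = _axis_origins(h, patch_size_px, stride_px)
    cols = _axis_origins(w, patch_size_px, stride_px)
    origins = [(r, c) for r in rows for c in cols]
    patches = [image[r : r + patch_size_px, c : c + patch_size_px] for r, c in origins]
    return PatchGrid(patch_size_px, stride_px, origins, patches)


def palette_classifier(
    palette: dict[int, tuple[int, int, int]] | None = None,
) -> PatchClassifier:
    """Deterministic reference classifier for synthetic fixtures.

    Each pixel of a tile is assigned to the nearest palette color; the
    returned probability vector is the fraction of tile pixels per class in
    the order (background, tumor, stroma).  A tile painted entirely in the
    tumor color therefore maps to (0, 1, 0)-style hard probabilities.
    """
    pal = FIXTURE_PALETTE if palette is None else palette
    codes = np.array(CLASS_ORDER)
    colors = np.array([pal[c] for c in CLASS_ORDER], dtype=np.float64)  # (3, 3)

    def classify(tile: np.ndarray) -> np.ndarray:
        rgb = np.asarray(tile, dtype=np.float64).reshape(-1, 3)
        d2 = ((rgb[:, None, :] - colors[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        frac = np.bincount(nearest, minlength=len(codes)).astype(np.float64)
        return frac / frac.sum()

    return classify


def classify_patches(grid: PatchGrid, classifier: PatchClassifier) -> ProbabilityMap:
    """Classify every patch and accumulate probabilities over footprints.

    Overlapping contributions are averaged per pixel: the stitched
    probability at a pixel is the mean of the probability vectors of all
    patches covering it.
    """
    max_r = max(r for r, _ in grid.origins) + grid.patch_size_px
    max_c = max(c for _, c in grid.origins) + grid.patch_size_px
    sums = np.zeros((3, max_r, max_c), dtype=np.float64)
    counts = np.zeros((max_r, max_c), dtype=np.int64)
    p = grid.patch_size_px
    for (r, c), tile in zip(grid.origins, grid.patches):
        vec = np.asarray(classifier(tile), dtype=np.float64)
        if vec.shape != (3,) or np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-6:
            raise ContractError(
                f"classifier returned {vec!r}; expected a 3-vector of "
                "probabilities summing to 1"
            )
        sums[:, r : r + p, c : c + p] += vec[:, None, None]
        counts[r : r + p, c : c + p] += 1
    covered = counts > 0
    probs = np.zeros_like(sums)
    probs[:, covered] = sums[:, covered] / counts[covered]
    return ProbabilityMap(probs=probs, counts=counts)


def stitch_to_classmap(probs: ProbabilityMap, meta: SlideMeta) -> ClassMap:
    """Argmax the stitched probabilities into a label raster.

    Ties resolve to the lowest class code (BACKGROUND before TUMOR before
    STROMA), which deterministically excludes ambiguous tissue from the
    tumor/stroma tallies.  Pixels covered by no patch become NODATA.
    """
    h, w = meta.height_px, meta.width_px
    labels = np.full((h, w), NODATA, dtype=np.uint8)
    ph, pw = probs.counts.shape
    hh, ww = min(h, ph), min(w, pw)
    sub = probs.probs[:, :hh, :ww]
    covered = probs.counts[:hh, :ww] > 0
    # CLASS_ORDER is sorted by code, so np.argmax's first-max rule is the
    # lowest-code tie rule.
    arg = np.argmax(sub, axis=0)
    codes = np.array(CLASS_ORDER, dtype=np.uint8)[arg]
    labels[:hh, :ww][covered] = codes[covered]
    return ClassMap(labels=labels, meta=meta)


def segment_image(
    image: np.ndarray,
    meta: SlideMeta,
    classifier: PatchClassifier | None = None,
    patch_size_px: int = 256,
    stride_px: int = 128,
) -> ClassMap:
    """Convenience pipeline: extract -> classify -> stitch."""
    if classifier is None:
        classifier = palette_classifier()
    grid = extract_patches(image, meta, patch_size_px, stride_px)
    probs = classify_patches(grid, classifier)
    return stitch_to_classmap(probs, meta)


def downsample_majority(cm: ClassMap, factor: int) -> ClassMap:
    """Downsample a class map by an integer factor with per-block majority vote.

    Blocks straddling the right/bottom border are padded with NODATA; ties
    within a block resolve to the lowest code present.  The resulting map
    has ``mpp`` scaled by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return ClassMap(labels=cm.labels.copy(), meta=cm.meta)
    h, w = cm.shape
    nh, nw = -(-h // factor), -(-w // factor)
    padded = np.full((nh * factor, nw * factor), NODATA, dtype=np.uint8)
    padded[:h, :w] = cm.labels
    blocks = padded.reshape(nh, factor, nw, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nh, nw, factor * factor)
    out = np.empty((nh, nw), dtype=np.uint8)
    # bincount per block; NODATA (255) mapped to bin 3 for compact counting
    remap = np.where(blocks == NODATA, 3, blocks)
    counts = np.stack(
        [(remap == k).sum(axis=2) for k in range(4)], axis=0
    )  # (4, nh, nw)
    # lowest code wins ties among {0,1,2}; NODATA only if it is the strict
    # majority contender (argmax order puts it last)
    arg = np.argmax(counts, axis=0)
    out = np.where(arg == 3, NODATA, arg).astype(np.uint8)
    meta = SlideMeta(
        slide_id=cm.meta.slide_id,
        mpp=cm.meta.mpp * factor,
        width_px=nw,
        height_px=nh,
        magnification_label=cm.meta.magnification_label,
    )
    return ClassMap(labels=out, meta=meta)


# ---------------------------------------------------------------------------
# Disk I/O: single-channel 8-bit PNG/TIFF + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_classmap(cm: ClassMap, path: str | Path) -> Path:
    """Write labels as an 8-bit single-channel PNG/TIFF with a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, cm.labels)
    else:
        Image.fromarray(cm.labels, mode="L").save(path)
    sidecar = {
        "slide_id": cm.meta.slide_id,
        "mpp": cm.meta.mpp,
        "width_px": cm.meta.width_px,
        "height_px": cm.meta.height_px,
    }
    if cm.meta.magnification_label is not None:
        sidecar["magnification_label"] = cm.meta.magnification_label
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_classmap(path: str | Path) -> ClassMap:
    """Read a label raster and its JSON sidecar back into a ClassMap."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        labels = np.asarray(tifffile.imread(path))
    else:
        labels = np.asarray(Image.open(path))
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise DataError(f"missing JSON sidecar for {path}")
    sc = json.loads(sidecar_file.read_text())
    meta = SlideMeta(
        slide_id=sc["slide_id"],
        mpp=float(sc["mpp"]),
        width_px=int(sc["width_px"]),
        height_px=int(sc["height_px"]),
        magnification_label=sc.get("magnification_label"),
    )
    return ClassMap(labels=labels, meta=meta)


def render_rgb(
    cm: ClassMap, palette: dict[int, tuple[int, int, int]] | None = None
) -> np.ndarray:
    """Render a class map as an RGB fixture image using the nominal palette.

    NODATA renders white; intended for round-tripping through the patch
    classifier in tests and demos.
    """
    pal = FIXTURE_PALETTE if palette is None else palette
    h, w = cm.shape
    rgb = np.full((h, w, 3), 255, dtype=np.uint8)
    for code, color in pal.items():
        rgb[cm.labels == code] = color
    return rgb
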