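"""Tumor-stroma ratio measurement, stratification, and scoring protocol.

TSR is the percentage of stroma among tumor+stroma pixels inside a region
of measurement; background and NODATA never enter the tallies.  Patients
are stratified stroma-rich (TSR >= 50%) versus stroma-poor (< 50%) by
default, mirroring manual pathology practice, and a survival-driven grid
search can locate the cutoff with the highest log-rank discrimination.

The module also reproduces the manual scoring protocol: tenfold percentage
scores from two raters, a third-rater consensus rule for discordant pairs,
and manual-versus-automated concordance as Pearson r plus ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConsensusRequiredError,
    DataError,
    DegenerateInputError,
    EmptyTissueError,
    NoAdmissibleCutoffError,
    ParameterError,
)
from .region_of_measurement import RegionOfMeasurement
from .tissue_model import BACKGROUND, STROMA, TUMOR, ClassMap

STROMA_RICH = "STROMA_RICH"
STROMA_POOR = "STROMA_POOR"

DEFAULT_CUTOFF_PERCENT = 50.0


@dataclass(frozen=True)
class TSRResult:
    stroma_percent: float
    n_tumor_px: int
    n_stroma_px: int
    n_background_px_excluded: int
    rom_kind: Literal["MI", "WT"]
    category: str


@dataclass(frozen=True)
class ManualScore:
    """One pathologist's tenfold-percentage stroma score."""

    rater_id: str
    stroma_percent_tenfold: int
    region: Literal["MI", "WT"]

    def __post_init__(self) -> None:
        v = self.stroma_percent_tenfold
        if v not in range(0, 101, 10):
            raise ParameterError(
                f"manual score must be a multiple of 10 in [0, 100], got {v}"
            )


@dataclass
class CutoffSearchResult:
    grid: list[tuple[float, float, float]]  # (cutoff, logrank chi2, p)
    optimal_cutoff_percent: float
    subgroup_label: str
    skipped_cutoffs: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ConcordanceResult:
    pearson_r: float
    icc: float
    n_pairs: int
    icc_model: str = "ICC(2,1) two-way random, absolute agreement, single rater"


def stratify(stroma_percent: float, cutoff_percent: float = DEFAULT_CUTOFF_PERCENT) -> str:
    """Stroma-rich iff stroma percentage >= cutoff (default 50%)."""
    if not (0.0 <= stroma_percent <= 100.0):
        raise ParameterError(f"stroma_percent must be in [0, 100], got {stroma_percent}")
    return STROMA_RICH if stroma_percent >= cutoff_percent else STROMA_POOR


def measure_tsr(
    cm: ClassMap,
    rom: RegionOfMeasurement,
    cutoff_percent: float = DEFAULT_CUTOFF_PERCENT,
) -> TSRResult:
    """Measure stromal percentage inside a region of measurement.

    Only tumor and stroma pixels enter the ratio; background pixels inside
    the region are counted but excluded, NODATA is ignored entirely.
    """
    if rom.mask.shape != cm.shape:
        raise DataError("region mask is not aligned to the class map")
    labels = cm.labels[rom.mask]
    n_tumor = int(np.count_nonzero(labels == TUMOR))
    n_stroma = int(np.count_nonzero(labels == STROMA))
    n_background = int(np.count_nonzero(labels == BACKGROUND))
    if n_tumor + n_stroma == 0:
        raise EmptyTissueError("region contains no tumor or stroma pixels")
    stroma_percent = 100.0 * n_stroma / (n_stroma + n_tumor)
    return TSRResult(
        stroma_percent=stroma_percent,
        n_tumor_px=n_tumor,
        n_stroma_px=n_stroma,
        n_background_px_excluded=n_background,
        rom_kind=rom.kind,
        category=stratify(stroma_percent, cutoff_percent),
    )


def consensus_manual(
    score_a: ManualScore,
    score_b: ManualScore,
    score_c: ManualScore | None = None,
) -> float:
    """Consensus of two raters, resolved by a third on discordance.

    Agreement returns the shared value; a discordant pair requires a third
    score and returns the median of the three (a deterministic stand-in for
    a consensus discussion, recorded as such in provenance).
    """
    if score_a.region != score_b.region:
        raise DataError("scores refer to different regions")
    if score_a.stroma_percent_tenfold == score_b.stroma_percent_tenfold:
        return float(score_a.stroma_percent_tenfold)
    if score_c is None:
        raise ConsensusRequiredError(
            f"raters disagree ({score_a.stroma_percent_tenfold} vs "
            f"{score_b.stroma_percent_tenfold}) and no third score was given"
        )
    values = [
        score_a.stroma_percent_tenfold,
        score_b.stroma_percent_tenfold,
        score_c.stroma_percent_tenfold,
    ]
    return float(np.median(values))


def concordance(scores_x: Sequence[float], scores_y: Sequence[float]) -> ConcordanceResult:
    """Pearson r and single-rater absolute-agreement ICC between two raters.

    The ICC flavor is fixed to ICC(2,1) — two-way random effects, absolute
    agreement, single rater — so a constant shift between raters lowers the
    ICC while leaving Pearson r at 1.
    """
    x = np.asarray(scores_x, dtype=np.float64)
    y = np.asarray(scores_y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("score series must be 1-D and of equal length")
    if len(x) < 3:
        raise DataError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("a score series is constant")
    r = float(stats.pearsonr(x, y).statistic)

    import warnings

    import pingouin as pg

    n = len(x)
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["x", "y"], n),
            "score": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        # perfect agreement gives a zero error mean square; the ICC point
        # estimate is still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        icc_table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        )
    # McGraw-Wong label ICC(A,1) == Shrout-Fleiss ICC(2,1):
    # two-way random effects, absolute agreement, single rater.
    icc2 = float(icc_table.set_index("Type").loc["ICC(A,1)", "ICC"])
    return ConcordanceResult(pearson_r=r, icc=icc2, n_pairs=n)


def optimal_cutoff_search(
    tsr_percent: Sequence[float],
    os_time: Sequence[float],
    os_event: Sequence[int],
    grid_step: float = 1.0,
    grid_range: tuple[float, float] = (5.0, 95.0),
    min_group_size: int = 5,
    subgroup_label: str = "",
) -> CutoffSearchResult:
    """Grid-search the TSR cutoff with the highest log-rank discrimination.

    Each grid cutoff dichotomizes the cohort at TSR >= cutoff and is scored
    by the two-group log-rank chi-square on overall survival; cutoffs
    leaving fewer than ``min_group_size`` patients on either side are
    skipped (and recorded).  No multiple-testing correction is applied —
    the full grid is returned so callers can apply one.
    """
    tsr = np.asarray(tsr_percent, dtype=np.float64)
    time = np.asarray(os_time, dtype=np.float64)
    event = np.asarray(os_event, dtype=np.int64)
    if not (len(tsr) == len(time) == len(event)):
        raise DataError("input series have unequal lengths")
    if event.sum() < 1:
        raise DataError("need at least one event")

    from .cohort_stats import logrank_test

    lo, hi = grid_range
    cutoffs = np.arange(lo, hi + grid_step / 2, grid_step)
    grid: list[tuple[float, float, float]] = []
    skipped: list[float] = []
    best: tuple[float, float] | None = None  # (chi2, cutoff)
    for c in cutoffs:
        rich = tsr >= c
        n_rich, n_poor = int(rich.sum()), int((~rich).sum())
        if min(n_rich, n_poor) < min_group_size:
            skipped.append(float(c))
            continue
        chi2, _, p = logrank_test(
            [(time[rich], event[rich]), (time[~rich], event[~rich])]
        )
        grid.append((float(c), chi2, p))
        if best is None or chi2 > best[0]:
            best = (chi2, float(c))
    if best is None:
        raise NoAdmissibleCutoffError(
            f"no cutoff in [{lo}, {hi}] leaves >= {min_group_size} patients per side"
        )
    return CutoffSearchResult(
        grid=grid,
        optimal_cutoff_percent=best[1],
        subgroup_label=subgroup_label,
        skipped_cutoffs=skipped,
    )


def tsr_csv_row(slide_id: str, result: TSRResult, params_hash: str) -> dict:
    """Flatten one TSR measurement into the per-slide CSV schema."""
    return {
        "slide_id": slide_id,
        "rom_kind": result.rom_kind,
        "stroma_percent": result.stroma_percent,
        "n_tumor_px": result.n_tumor_px,
        "n_stroma_px": result.n_stroma_px,
        "category": result.category,
        "params_hash": params_hash,
    }
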