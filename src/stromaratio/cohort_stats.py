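"""Cohort-level statistics: survival, association tests, risk grouping.

Survival machinery follows standard oncology-cohort practice: Kaplan-Meier
product-limit curves with the log-rank test, Cox proportional-hazards
models with Efron tie handling, a univariable screen at p < 0.10 feeding
backward selection at p_stay = 0.05 with the exposure of interest forced
into the model, and right censoring throughout.  Times are months.

Categorical associations dispatch between the Pearson chi-square test
(without continuity correction) and Fisher's exact test when more than 20%
of expected cell counts fall below 5.

Tumor-infiltrating-lymphocyte (TIL) counts arrive as ordinal bins 0..5 for
counts {0, 1-5, 6-19, 20-49, 50-100, >100}; quartile-based categorization
marks the top quartile as TIL-high, and the joint TSR x TIL classifier maps
(stroma category, TIL level) onto three prognostic risk groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FitError, ParameterError

TIL_BIN_LABELS = ("0", "1-5", "6-19", "20-49", "50-100", ">100")
TIL_MARKERS = ("cd8", "cd20", "cd68", "cd103")

RISK_LOW = "LOW"
RISK_MEDIUM = "MEDIUM"
RISK_HIGH = "HIGH"

TEN_YEAR_MONTHS = 120.0


@dataclass
class PatientRecord:
    """One patient's survival endpoints, covariates and scores."""

    patient_id: str
    treatment: Literal["PDS", "NACT"]
    os_months: float
    os_event: int
    pfs_months: float | None = None
    pfs_event: int | None = None
    covariates: dict = field(default_factory=dict)
    til_scores: dict = field(default_factory=dict)  # marker -> bin 0..5
    tsr_manual_mi: float | None = None
    tsr_manual_wt: float | None = None
    tsr_auto_mi: float | None = None
    tsr_auto_wt: float | None = None

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise DataError(f"{self.patient_id}: negative OS time")
        if self.os_event not in (0, 1):
            raise DataError(f"{self.patient_id}: os_event must be 0/1")
        if self.pfs_months is not None:
            if self.pfs_months < 0:
                raise DataError(f"{self.patient_id}: negative PFS time")
            if self.pfs_months > self.os_months + 1e-9:
                raise DataError(f"{self.patient_id}: PFS exceeds OS")
            if self.pfs_event not in (0, 1):
                raise DataError(f"{self.patient_id}: pfs_event must be 0/1")


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the distinct event times; ``survival`` the estimate just
    after each, starting from S(0) = 1; ``at_risk`` the risk-set size at
    each event time.  At tied times, events precede censorings.
    """

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def survival_at(self, horizon: float) -> float:
        """Step-function value S(horizon); 1.0 before the first event."""
        idx = np.searchsorted(self.times, horizon, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs from a proportional-hazards fit."""

    table: pd.DataFrame  # index: covariate; columns: hr, ci_lower, ci_upper, p
    covariates: list[str]
    ties: str = "efron"
    selection_trace: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate of the survival function."""
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=np.int64)
    if len(t) < 1:
        raise DataError("need at least one observation")
    if np.any(t < 0):
        raise DataError("negative survival time")
    if not set(np.unique(e)) <= {0, 1}:
        raise DataError("events must be 0/1")

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    return KMCurve(
        times=ev.index.to_numpy(dtype=np.float64),
        at_risk=ev["at_risk"].to_numpy(dtype=np.int64),
        survival=kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(),
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]],
) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi2, df, p)."""
    if len(groups) < 2:
        raise ParameterError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=np.float64)
        e = np.asarray(e, dtype=np.int64)
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), i))
    all_t = np.concatenate(times)
    all_e = np.concatenate(events)
    all_g = np.concatenate(labels)
    if all_e.sum() < 1:
        raise ParameterError("log-rank test needs at least one event")

    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(all_t, all_g, all_e)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def _records_frame(
    records: Sequence[PatientRecord],
    endpoint: Literal["OS", "PFS"],
    covariates: Sequence[str],
) -> pd.DataFrame:
    rows = []
    for r in records:
        if endpoint == "OS":
            time, event = r.os_months, r.os_event
        else:
            if r.pfs_months is None:
                continue
            time, event = r.pfs_months, r.pfs_event
        row = {"time": time, "event": event}
        source = {
            **r.covariates,
            "tsr_manual_mi": r.tsr_manual_mi,
            "tsr_manual_wt": r.tsr_manual_wt,
            "tsr_auto_mi": r.tsr_auto_mi,
            "tsr_auto_wt": r.tsr_auto_wt,
            **{f"{m}_bin": b for m, b in r.til_scores.items()},
        }
        for c in covariates:
            if c not in source:
                raise DataError(f"covariate {c!r} missing for {r.patient_id}")
            row[c] = source[c]
        rows.append(row)
    df = pd.DataFrame(rows).dropna()
    if df.empty:
        raise DataError("no complete records for the requested covariates")
    return df


def cox_fit(
    records: Sequence[PatientRecord] | pd.DataFrame,
    endpoint: Literal["OS", "PFS"] = "OS",
    covariates: Sequence[str] = (),
) -> CoxResult:
    """Cox proportional-hazards fit with Efron tie handling.

    Accepts either patient records or a prepared frame with ``time`` and
    ``event`` columns.  Hazard ratios are exp(coef) with Wald 95% CIs.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["time", "event", *covariates]].dropna().copy()
    else:
        df = _records_frame(records, endpoint, covariates)
    if df["event"].sum() < 1:
        raise FitError("no events in the data")
    for c in covariates:
        if df[c].nunique() < 2:
            raise FitError(f"covariate {c!r} is constant")

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    fit_warnings: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
        fit_warnings = [str(w.message) for w in caught if "convergence" in str(w.message).lower() or "separation" in str(w.message).lower()]
    except ConvergenceError as exc:
        raise FitError(f"Cox fit failed to converge: {exc}") from exc

    s = cph.summary
    table = pd.DataFrame(
        {
            "hr": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxResult(table=table, covariates=list(covariates), warnings=fit_warnings)


def screen_and_select(
    records: Sequence[PatientRecord] | pd.DataFrame,
    endpoint: Literal["OS", "PFS"],
    candidate_covariates: Sequence[str],
    exposure: str,
    p_enter: float = 0.10,
    p_stay: float = 0.05,
) -> CoxResult:
    """Univariable screen then backward selection, with the exposure forced.

    Each candidate is screened with a univariable Cox fit; those with
    p < ``p_enter`` join the multivariable model.  Backward elimination then
    repeatedly drops the largest-p candidate while its p >= ``p_stay``.
    The exposure always stays in the model regardless of its p-value.
    """
    if not candidate_covariates:
        raise ParameterError("candidate covariate list is empty")
    trace: list[str] = []
    entered: list[str] = []
    for c in candidate_covariates:
        if c == exposure:
            continue
        uni = cox_fit(records, endpoint, [c])
        p = uni.p(c)
        if p < p_enter:
            entered.append(c)
            trace.append(f"enter {c} (univariable p={p:.4f})")
        else:
            trace.append(f"screen out {c} (univariable p={p:.4f})")

    current = list(entered)
    while True:
        model = cox_fit(records, endpoint, [exposure, *current])
        if not current:
            break
        pvals = {c: model.p(c) for c in current}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] >= p_stay:
            current.remove(worst)
            trace.append(f"drop {worst} (p={pvals[worst]:.4f})")
        else:
            break
    model.selection_trace = trace
    return model


def association_test(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[str, float | None, float]:
    """Chi-square / Fisher dispatch on a contingency table.

    Pearson chi-square without continuity correction unless more than 20%
    of expected cell counts are below 5, in which case Fisher's exact test
    is used (2x2 only; larger sparse tables are refused with a message).
    Returns (test_name, statistic_or_None, p).
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2:
        raise DataError("contingency table must be 2-D")
    if np.any(tab < 0):
        raise DataError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise DataError("contingency table has a zero margin")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if np.mean(expected < 5) > 0.20:
        if tab.shape != (2, 2):
            raise ParameterError(
                "more than 20% of expected counts are below 5 but the table "
                f"is {tab.shape}; Fisher's exact test is only available for "
                "2x2 tables — collapse categories first"
            )
        _, p = stats.fisher_exact(tab)
        return ("fisher", None, float(p))
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return ("chi-square", float(chi2), float(p))


@dataclass
class TilCategories:
    """Result of TIL categorization over a cohort."""

    labels: np.ndarray  # per-patient "LOW"/"MEDIUM"/"HIGH"
    thresholds: tuple[int, ...]
    scheme: str
    degenerate: bool = False


def _ceil_quantile(bins: np.ndarray, q: float) -> int:
    """Smallest integer >= the linear-interpolation quantile of the codes.

    With ordinal codes, a quantile boundary falling inside a tied value
    sends the whole tied mass to the upper side.
    """
    return int(np.ceil(np.quantile(bins, q)))


def categorize_til(
    bins: Sequence[int],
    scheme: Literal["quartile_binary", "tertile_3way"] = "quartile_binary",
) -> TilCategories:
    """Categorize ordinal TIL bins by empirical quartiles.

    ``quartile_binary`` marks the top quartile of the bin distribution as
    HIGH (everything else LOW); ``tertile_3way`` splits at the 25th and
    75th percentiles into LOW / MEDIUM / HIGH.  All-equal input degenerates
    to all-LOW with a flag.
    """
    arr = np.asarray(bins, dtype=np.int64)
    if arr.size == 0:
        raise DataError("empty TIL input")
    if arr.size < 4:
        raise DataError("need at least 4 patients for quartile thresholds")
    if np.any((arr < 0) | (arr > 5)):
        raise DataError("TIL bins must lie in 0..5")
    if np.ptp(arr) == 0:
        return TilCategories(
            labels=np.full(arr.shape, "LOW"),
            thresholds=(),
            scheme=scheme,
            degenerate=True,
        )
    if scheme == "quartile_binary":
        thr = _ceil_quantile(arr, 0.75)
        labels = np.where(arr >= thr, "HIGH", "LOW")
        return TilCategories(labels=labels, thresholds=(thr,), scheme=scheme)
    if scheme == "tertile_3way":
        t_lo = _ceil_quantile(arr, 0.25)
        t_hi = _ceil_quantile(arr, 0.75)
        labels = np.where(arr >= t_hi, "HIGH", np.where(arr >= t_lo, "MEDIUM", "LOW"))
        return TilCategories(labels=labels, thresholds=(t_lo, t_hi), scheme=scheme)
    raise ParameterError(f"unknown scheme {scheme!r}")


def joint_risk_group(stroma_category: str, til_binary: str) -> str:
    """Three-tier joint TSR x TIL prognostic class.

    LOW risk = stroma-poor with high TILs; HIGH risk = stroma-rich with low
    TILs; the two mixed combinations are MEDIUM.
    """
    from .tsr import STROMA_POOR, STROMA_RICH

    if stroma_category not in (STROMA_RICH, STROMA_POOR):
        raise DataError(f"unknown stroma category {stroma_category!r}")
    if til_binary not in ("HIGH", "LOW"):
        raise DataError(f"unknown TIL level {til_binary!r}")
    rich = stroma_category == STROMA_RICH
    high = til_binary == "HIGH"
    if not rich and high:
        return RISK_LOW
    if rich and not high:
        return RISK_HIGH
    return RISK_MEDIUM


# ---------------------------------------------------------------------------
# Cohort CSV schema

COHORT_COLUMNS = [
    "patient_id",
    "treatment",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "age_group",
    "figo_stage",
    "residual_status",
    "cd8_bin",
    "cd20_bin",
    "cd68_bin",
    "cd103_bin",
    "tsr_manual_mi",
    "tsr_manual_wt",
    "tsr_auto_mi",
    "tsr_auto_wt",
]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "treatment": r.treatment,
                "os_months": r.os_months,
                "os_event": r.os_event,
                "pfs_months": r.pfs_months,
                "pfs_event": r.pfs_event,
                "age_group": r.covariates.get("age_group"),
                "figo_stage": r.covariates.get("figo_stage"),
                "residual_status": r.covariates.get("residual_status"),
                **{f"{m}_bin": r.til_scores.get(m) for m in TIL_MARKERS},
                "tsr_manual_mi": r.tsr_manual_mi,
                "tsr_manual_wt": r.tsr_manual_wt,
                "tsr_auto_mi": r.tsr_auto_mi,
                "tsr_auto_wt": r.tsr_auto_wt,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in ("patient_id", "treatment", "os_months", "os_event") if c not in df.columns]
    if missing:
        raise DataError(f"cohort table is missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            til = {
                m: int(row[f"{m}_bin"])
                for m in TIL_MARKERS
                if f"{m}_bin" in df.columns and pd.notna(row.get(f"{m}_bin"))
            }
            covs = {
                k: row[k]
                for k in ("age_group", "figo_stage", "residual_status")
                if k in df.columns and pd.notna(row[k])
            }

            def _opt(col: str) -> float | None:
                return float(row[col]) if col in df.columns and pd.notna(row.get(col)) else None

            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    treatment=str(row["treatment"]),
                    os_months=float(row["os_months"]),
                    os_event=int(row["os_event"]),
                    pfs_months=_opt("pfs_months"),
                    pfs_event=int(row["pfs_event"]) if pd.notna(row.get("pfs_event")) else None,
                    covariates=covs,
                    til_scores=til,
                    tsr_manual_mi=_opt("tsr_manual_mi"),
                    tsr_manual_wt=_opt("tsr_manual_wt"),
                    tsr_auto_mi=_opt("tsr_auto_mi"),
                    tsr_auto_wt=_opt("tsr_auto_wt"),
                )
            )
        except (DataError, ValueError) as exc:
            raise DataError(f"row {i}: {exc}") from exc
    return records


def read_cohort_csv(path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path))
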