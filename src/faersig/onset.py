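"""Time-to-onset of adverse events: days from first target-drug therapy start
to the event date, with the study's data-quality exclusions.

A report contributes one onset value (case-level by default): the calendar
difference between its event date and the *earliest day-precision* therapy
start among the rows linked to the target drug.  Reports are excluded, with
a coded reason, when either date is missing, not known to the day, or when
the event precedes the start (a data-entry error in spontaneous reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .case_selection import TargetDrugSpec, target_drug_rows
from .dates import DateParseError, PartialDate, Precision, parse_partial_date
from .descriptives import proportion

DAYS_PER_YEAR = 365.25

# year bins of the onset histogram, half-open [lower, upper)
BIN_EDGES_YEARS = (0.0, 1.0, 3.0, 5.0, 7.0, 9.0, 11.0, math.inf)
BIN_LABELS = ("<1 y", "1-3 y", "3-5 y", "5-7 y", "7-9 y", "9-11 y", ">=11 y")


class ExclusionReason(str, Enum):
    EVENT_BEFORE_START = "event-before-start"
    IMPRECISE_DATE = "imprecise-date"
    MISSING_DATE = "missing-date"


def onset_days(
    event: PartialDate | None, start: PartialDate | None
) -> int | ExclusionReason:
    """Calendar-day difference, or the exclusion reason.

    Exclusions are data, not errors: a missing date, a date not known to
    the day, or an event before the therapy start each return the matching
    reason code.
    """
    if event is None or start is None:
        return ExclusionReason.MISSING_DATE
    if event.precision is not Precision.DAY or start.precision is not Precision.DAY:
        return ExclusionReason.IMPRECISE_DATE
    delta = (event.to_date() - start.to_date()).days
    if delta < 0:
        return ExclusionReason.EVENT_BEFORE_START
    return delta


def first_start(ther: pd.DataFrame, target_seqs: set[str]) -> PartialDate | None:
    """Earliest day-precision therapy start among the target drug's rows.

    Rows with blank, imprecise or malformed start dates are skipped; when
    no day-precision start exists the anchor is missing.
    """
    best: PartialDate | None = None
    for _, row in ther.iterrows():
        if str(row["drug_seq"]) not in target_seqs:
            continue
        try:
            d = parse_partial_date(row.get("start_dt", ""))
        except DateParseError:
            continue
        if d is None or d.precision is not Precision.DAY:
            continue
        if best is None or d.to_date() < best.to_date():
            best = d
    return best


def compute_onsets(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    ther: pd.DataFrame,
    case_ids: set[str],
    spec: TargetDrugSpec,
    reac: pd.DataFrame | None = None,
    per_event: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Onset per target case, plus the excluded cases with reasons.

    Returns ``(onsets, exclusions)``: onsets has columns (primaryid,
    onset_days); exclusions has (primaryid, reason).  With ``per_event``
    each distinct PT of a case contributes one record (sharing the case's
    onset), matching event-level counting; default is one record per case.
    """
    links = target_drug_rows(drug, spec)
    seqs_by_case: dict[str, set[str]] = {}
    for pid, seq in zip(links["primaryid"], links["drug_seq"]):
        seqs_by_case.setdefault(pid, set()).add(str(seq))
    ther_by_case = dict(tuple(ther.groupby("primaryid"))) if len(ther) else {}

    demo_sel = demo[demo["primaryid"].isin(case_ids)]
    included: list[tuple[str, int]] = []
    excluded: list[tuple[str, str]] = []
    for _, row in demo_sel.iterrows():
        pid = row["primaryid"]
        try:
            event = parse_partial_date(row.get("event_dt", ""))
        except DateParseError:
            # a malformed digit string is an incorrect date, not day-precision
            excluded.append((pid, ExclusionReason.IMPRECISE_DATE.value))
            continue
        start = first_start(
            ther_by_case.get(pid, ther.iloc[0:0]), seqs_by_case.get(pid, set())
        )
        if event is not None and start is None:
            excluded.append((pid, ExclusionReason.MISSING_DATE.value))
            continue
        result = onset_days(event, start)
        if isinstance(result, ExclusionReason):
            excluded.append((pid, result.value))
        else:
            included.append((pid, result))

    onsets = pd.DataFrame(included, columns=["primaryid", "onset_days"])
    exclusions = pd.DataFrame(excluded, columns=["primaryid", "reason"])
    if per_event and reac is not None and len(onsets):
        events = reac[reac["primaryid"].isin(set(onsets["primaryid"]))]
        pairs = events.loc[:, ["primaryid", "pt"]].drop_duplicates()
        onsets = pairs.merge(onsets, on="primaryid", how="left").loc[
            :, ["primaryid", "pt", "onset_days"]
        ]
    return onsets.reset_index(drop=True), exclusions.reset_index(drop=True)


@dataclass(frozen=True)
class OnsetSummary:
    """Median/IQR (linear-interpolation quartiles) and year-bin histogram."""

    n: int
    median_days: float
    iqr_lo: float
    iqr_hi: float
    bin_counts: dict[str, int]
    bin_percent: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": list(self.bin_counts),
                "count": list(self.bin_counts.values()),
                "percent": [self.bin_percent[k] for k in self.bin_counts],
            }
        )


def summarize_onset(onset_days_values, decimals: int = 2) -> OnsetSummary:
    """Summary of onset times in days.

    Quartiles use linear interpolation between order statistics, so the
    IQR endpoints of an integer sample can be fractional (e.g. ``.25``).
    Year bins are half-open [lower, upper) with a 365.25-day year.
    """
    values = np.asarray(list(onset_days_values), dtype=float)
    if values.size == 0:
        return OnsetSummary(
            0, math.nan, math.nan, math.nan,
            {lbl: 0 for lbl in BIN_LABELS}, {lbl: math.nan for lbl in BIN_LABELS},
        )
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    years = values / DAYS_PER_YEAR
    edges = np.asarray(BIN_EDGES_YEARS)
    idx = np.searchsorted(edges, years, side="right") - 1
    counts = {lbl: int((idx == i).sum()) for i, lbl in enumerate(BIN_LABELS)}
    percent = {
        lbl: proportion(c, int(values.size), decimals) for lbl, c in counts.items()
    }
    return OnsetSummary(
        n=int(values.size),
        median_days=float(med),
        iqr_lo=float(q1),
        iqr_hi=float(q3),
        bin_counts=counts,
        bin_percent=percent,
    )
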