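"""Descriptive summaries of target-drug reports: demographics, outcomes, yearly counts.

Mirrors the clinical-characteristics table of a pharmacovigilance study:
sex, age group (years), weight group (kg), reporter occupation, top
reporting countries, serious-outcome distribution, top indications — each
as count and percentage of the block's denominator — plus yearly report
counts and subgroup partitions for stratified signal analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

# FAERS age-unit codes -> factor converting the value to years
AGE_UNIT_TO_YEARS: Mapping[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

LBS_TO_KG = 0.45359237

OCCUPATION_LABELS: Mapping[str, str] = {
    "CN": "Consumer",
    "MD": "Physician",
    "HP": "Health professional",
    "OT": "Other health-professional",
    "PH": "Pharmacist",
    "RN": "Registered nurse",
}

OUTCOME_CODES = ("HO", "OT", "DE", "LT", "DS", "CA", "RI")

UNKNOWN = "Unknown"


def proportion(count: int, denominator: int, decimals: int = 1) -> float:
    """Percentage ``100*count/denominator`` rounded half-up to ``decimals``.

    Computed in exact decimal arithmetic so that half-way cases round up
    (the convention used in the published tables), independent of binary
    float representation.  A zero denominator yields NaN.
    """
    if denominator == 0:
        return math.nan
    if not 0 <= count <= denominator:
        raise ValueError(f"count {count} outside [0, {denominator}]")
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(count) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return float(pct)


def normalize_age(value: float | str | None, unit: str | None) -> float | None:
    """Age in years from a FAERS (value, unit-code) pair; None when unknowable."""
    v = _to_number(value)
    if v is None:
        return None
    if v < 0:
        log.warning("negative age %r treated as unknown", value)
        return None
    factor = AGE_UNIT_TO_YEARS.get((unit or "").strip().upper())
    if factor is None:
        return None
    return v * factor


def normalize_weight(value: float | str | None, unit: str | None) -> float | None:
    """Weight in kg; LBS converted at 0.45359237 kg/lb; nonpositive -> unknown."""
    v = _to_number(value)
    if v is None:
        return None
    if v <= 0:
        log.warning("nonpositive weight %r treated as unknown", value)
        return None
    u = (unit or "").strip().upper()
    if u == "KG":
        return v
    if u == "LBS":
        return v * LBS_TO_KG
    return None


def _to_number(value: float | str | None) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        try:
            return float(value)
        except ValueError:
            return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def age_group(years: float | None) -> str:
    """Bands as printed: <18 is [0,18), 18~65 is [18,65], >65 is (65, inf)."""
    if years is None:
        return UNKNOWN
    if years < 18:
        return "<18"
    if years <= 65:
        return "18~65"
    return ">65"


def weight_group(kg: float | None) -> str:
    """Bands as printed: <50 kg is [0,50), 50~100 kg is [50,100], >100 kg beyond."""
    if kg is None:
        return UNKNOWN
    if kg < 50:
        return "<50 kg"
    if kg <= 100:
        return "50~100 kg"
    return ">100 kg"


@dataclass(frozen=True)
class CategoryCount:
    label: str
    count: int
    percent: float


@dataclass(frozen=True)
class DemographicSummary:
    """Count/percentage blocks over the target-drug cases.

    ``n_cases`` is the denominator of the sex/age/weight/occupation/country
    blocks.  The outcome block's denominator counts outcome *rows* plus one
    Unknown per case with no outcome row; the indication block counts
    distinct (case, indication) pairs linked to the target drug.
    """

    n_cases: int
    sex: list[CategoryCount] = field(default_factory=list)
    age: list[CategoryCount] = field(default_factory=list)
    weight: list[CategoryCount] = field(default_factory=list)
    occupation: list[CategoryCount] = field(default_factory=list)
    country: list[CategoryCount] = field(default_factory=list)
    outcome: list[CategoryCount] = field(default_factory=list)
    indication: list[CategoryCount] = field(default_factory=list)
    n_outcomes: int = 0
    n_indications: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block in (
            "sex",
            "age",
            "weight",
            "occupation",
            "country",
            "outcome",
            "indication",
        ):
            for cc in getattr(self, block):
                rows.append((block, cc.label, cc.count, cc.percent))
        return pd.DataFrame(rows, columns=["block", "category", "count", "percent"])


def _block(counts: Mapping[str, int], denominator: int, decimals: int = 1) -> list[CategoryCount]:
    return [
        CategoryCount(label, int(c), proportion(int(c), denominator, decimals))
        for label, c in counts.items()
    ]


def summarize_demographics(
    demos: pd.DataFrame,
    outcomes: pd.DataFrame,
    indications: pd.DataFrame,
    target_links: pd.DataFrame,
    case_ids: set[str] | None = None,
    top_k: int = 5,
    decimals: int = 1,
) -> DemographicSummary:
    """Build every block of the clinical-characteristics table.

    ``target_links`` is the (primaryid, drug_seq) frame of rows that matched
    the target drug (see :func:`faersig.case_selection.target_drug_rows`);
    indications are counted only when linked to one of those drug sequences.
    """
    demo = demos if case_ids is None else demos[demos["primaryid"].isin(case_ids)]
    ids = set(demo["primaryid"])
    n = len(demo)

    sex_raw = demo["sex"].str.strip().str.upper() if n else pd.Series(dtype=str)
    sex_counts = {
        "Female": int((sex_raw == "F").sum()),
        "Male": int((sex_raw == "M").sum()),
        UNKNOWN: int((~sex_raw.isin(["F", "M"])).sum()),
    }

    ages = [
        normalize_age(v, u) for v, u in zip(demo.get("age", []), demo.get("age_cod", []))
    ]
    age_counts: dict[str, int] = {g: 0 for g in ("<18", "18~65", ">65", UNKNOWN)}
    for a in ages:
        age_counts[age_group(a)] += 1

    weights = [
        normalize_weight(v, u) for v, u in zip(demo.get("wt", []), demo.get("wt_cod", []))
    ]
    weight_counts: dict[str, int] = {
        g: 0 for g in ("<50 kg", "50~100 kg", ">100 kg", UNKNOWN)
    }
    for w in weights:
        weight_counts[weight_group(w)] += 1

    occ_raw = demo["occp_cod"].str.strip().str.upper() if n else pd.Series(dtype=str)
    occ_counts = {label: 0 for label in OCCUPATION_LABELS.values()}
    occ_counts[UNKNOWN] = 0
    for code in occ_raw:
        occ_counts[OCCUPATION_LABELS.get(code, UNKNOWN)] += 1

    country_raw = demo["reporter_country"].str.strip() if n else pd.Series(dtype=str)
    country_named = country_raw[country_raw != ""]
    top_countries = country_named.value_counts().head(top_k)
    country_counts = {str(k): int(v) for k, v in top_countries.items()}

    outc = outcomes[outcomes["primaryid"].isin(ids)] if len(outcomes) else outcomes
    outc_codes = outc["outc_cod"].str.strip().str.upper() if len(outc) else pd.Series(dtype=str)
    cases_with_outcome = set(outc["primaryid"]) if len(outc) else set()
    n_unknown_outcome = len(ids - cases_with_outcome)
    outcome_denominator = len(outc) + n_unknown_outcome
    outcome_counts = {code: int((outc_codes == code).sum()) for code in OUTCOME_CODES}
    outcome_counts[UNKNOWN] = n_unknown_outcome

    if len(indications) and len(target_links):
        linked = indications.merge(
            target_links, on=["primaryid", "drug_seq"], how="inner"
        )
        linked = linked[linked["primaryid"].isin(ids)]
        pairs = linked.loc[:, ["primaryid", "indi_pt"]].drop_duplicates()
        pairs = pairs[pairs["indi_pt"].str.strip() != ""]
    else:
        pairs = pd.DataFrame({"primaryid": [], "indi_pt": []})
    n_ind = len(pairs)
    top_ind = pairs["indi_pt"].value_counts().head(top_k) if n_ind else pd.Series(dtype=int)
    ind_counts = {str(k): int(v) for k, v in top_ind.items()}

    return DemographicSummary(
        n_cases=n,
        sex=_block(sex_counts, n, decimals),
        age=_block(age_counts, n, decimals),
        weight=_block(weight_counts, n, decimals),
        occupation=_block(occ_counts, n, decimals),
        country=_block(country_counts, n, decimals),
        outcome=_block(outcome_counts, outcome_denominator, decimals),
        indication=_block(ind_counts, n_ind, decimals),
        n_outcomes=outcome_denominator,
        n_indications=n_ind,
    )


def count_by_year(demos: pd.DataFrame) -> dict[int, int]:
    """Reports per FDA-receipt year, zero-filled over the observed range."""
    if demos.empty:
        return {}
    years = demos["fda_dt"].str.strip().str[:4].astype(int)
    counts = years.value_counts().to_dict()
    lo, hi = min(counts), max(counts)
    return {y: int(counts.get(y, 0)) for y in range(lo, hi + 1)}


def subgroup_split(
    pairs: pd.DataFrame, demos: pd.DataFrame, by: str
) -> dict[str, pd.DataFrame]:
    """Partition case–event pairs by a case-level stratum (sex or occupation).

    Unknown values form their own stratum; the returned frames are disjoint
    and their union is the input, so downstream signal statistics can run
    per stratum unchanged.
    """
    if by == "sex":
        raw = demos["sex"].str.strip().str.upper()
        stratum = raw.where(raw.isin(["F", "M"]), UNKNOWN)
    elif by == "occupation":
        raw = demos["occp_cod"].str.strip().str.upper()
        stratum = raw.map(OCCUPATION_LABELS).fillna(UNKNOWN)
    else:
        raise ValueError(f"unknown subgroup key: {by!r} (expected 'sex' or 'occupation')")
    lookup = dict(zip(demos["primaryid"], stratum))
    labels = pairs["primaryid"].map(lambda p: lookup.get(p, UNKNOWN))
    out: dict[str, pd.DataFrame] = {}
    for label in sorted(set(labels)):
        out[label] = pairs[labels == label].reset_index(drop=True)
    return out


def iter_blocks(summary: DemographicSummary) -> Iterable[tuple[str, list[CategoryCount], int]]:
    """(block name, categories, denominator) triples — convenient for checks."""
    yield "sex", summary.sex, summary.n_cases
    yield "age", summary.age, summary.n_cases
    yield "weight", summary.weight, summary.n_cases
    yield "occupation", summary.occupation, summary.n_cases
    yield "outcome", summary.outcome, summary.n_outcomes
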