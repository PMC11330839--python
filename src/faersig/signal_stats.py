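"""Disproportionality statistics on 2x2 contingency tables of spontaneous reports.

For each adverse-event term (MedDRA PT or SOC) the database splits into

    a = reports with the target drug and the term
    b = reports with the target drug, other terms
    c = reports with other drugs and the term
    d = reports with other drugs and other terms

and four frequentist/Bayesian measures of disproportionate reporting are
computed:

* ROR  = ad/bc with a log-normal 95% CI; signal when the lower bound
  exceeds 1 and a >= 3.
* PRR  = [a(c+d)]/[c(a+b)] with the Pearson chi-square (no continuity
  correction); signal when PRR >= 2, chi2 >= 4 and a >= 3.
* BCPNN information component IC = log2(a*N/((a+c)(a+b))), with the lower
  interval bound IC025 from the closed-form moment approximation of the
  Bayesian confidence propagation neural network (uniform Beta margins);
  signal when IC025 > 0.
* EBGM = a*N/((a+c)(a+b)) — the observed/expected ratio reported as a
  plug-in geometric mean with a log-normal lower bound EBGM05 (not the
  full gamma-Poisson shrinkage fit); signal when EBGM05 > 2.

Undefined quantities (zero cells) are NaN; a NaN never raises a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as _stats

ALGORITHMS = ("ror", "prr", "bcpnn", "mgps")

_LN2 = math.log(2.0)


class ConsistencyError(ValueError):
    """Counts that contradict the case totals they were built from."""


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts underlying every statistic (floats allowed so a
    0.5 continuity shift stays representable)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"negative cell {name}={v}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def shifted(self, delta: float = 0.5) -> "ContingencyTable":
        """Haldane–Anscombe style shift of every cell (opt-in only)."""
        return ContingencyTable(self.a + delta, self.b + delta, self.c + delta, self.d + delta)


def build_contingency(
    term: str,
    target_pairs: pd.DataFrame,
    all_pairs: pd.DataFrame,
    target_case_count: int,
    total_case_count: int,
    term_column: str = "pt",
) -> ContingencyTable:
    """2x2 table for one term from unique case–term pairs.

    ``target_pairs``/``all_pairs`` hold unique (primaryid, term) rows for
    the target-drug cases and for every deduplicated case respectively.
    """
    a = int((target_pairs[term_column] == term).sum())
    total_with = int((all_pairs[term_column] == term).sum())
    c = total_with - a
    b = target_case_count - a
    d = (total_case_count - target_case_count) - c
    if b < 0 or c < 0 or d < 0:
        raise ConsistencyError(
            f"term {term!r}: counts a={a}, with={total_with} inconsistent with "
            f"targets={target_case_count}, total={total_case_count}"
        )
    return ContingencyTable(a, b, c, d)


def build_all_tables(
    target_pairs: pd.DataFrame,
    all_pairs: pd.DataFrame,
    target_case_count: int,
    total_case_count: int,
    term_column: str = "pt",
) -> dict[str, ContingencyTable]:
    """Tables for every term reported at least once with the target drug."""
    a_counts = target_pairs[term_column].value_counts()
    tot_counts = all_pairs[term_column].value_counts()
    out: dict[str, ContingencyTable] = {}
    for term, a in a_counts.items():
        a = int(a)
        c = int(tot_counts.get(term, 0)) - a
        b = target_case_count - a
        d = (total_case_count - target_case_count) - c
        if b < 0 or c < 0 or d < 0:
            raise ConsistencyError(f"inconsistent counts for term {term!r}")
        out[str(term)] = ContingencyTable(a, b, c, d)
    return out


# ---------------------------------------------------------------------------
# The four statistics


def compute_ror(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio ad/bc with log-normal 95% CI.

    Any zero cell leaves all three values NaN — no continuity correction is
    applied by default (apply :meth:`ContingencyTable.shifted` explicitly
    for a Haldane correction).
    """
    if min(t.a, t.b, t.c, t.d) <= 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo = math.exp(math.log(ror) - 1.96 * se)
    hi = math.exp(math.log(ror) + 1.96 * se)
    return (ror, lo, hi)


def compute_prr_chi2(t: ContingencyTable) -> tuple[float, float, float]:
    """PRR and the (uncorrected) Pearson chi-square with its 1-df upper-tail p."""
    if t.c <= 0 or (t.a + t.b) <= 0:
        return (math.nan, math.nan, math.nan)
    prr = (t.a * (t.c + t.d)) / (t.c * (t.a + t.b))
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if denom <= 0:
        return (prr, math.nan, math.nan)
    chi2 = ((t.a * t.d - t.b * t.c) ** 2) * t.n / denom
    p = float(_stats.chi2.sf(chi2, df=1))
    return (prr, chi2, p)


def bcpnn_moments(t: ContingencyTable) -> tuple[float, float]:
    """Posterior mean and variance of the information component.

    Closed-form moment approximation of the original BCPNN with uniform
    Beta(1,1) priors on both margins and the standard adjustment of the
    joint-cell prior so that E(IC) is near 0 under independence.  Isolated
    here so an alternative (e.g. Monte-Carlo posterior) can be swapped in.
    """
    a, n = t.a, t.n
    n1 = t.a + t.b  # target-drug margin
    n2 = t.a + t.c  # event margin
    alpha1 = beta1 = 1.0
    alpha = beta = 2.0
    gamma11 = 1.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((n1 + alpha1) * (n2 + beta1))
    e_ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta) / ((n + gamma) * (n1 + alpha1) * (n2 + beta1))
    )
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - n1 + alpha - alpha1) / ((n1 + alpha1) * (1 + n + alpha))
        + (n - n2 + beta - beta1) / ((n2 + beta1) * (1 + n + beta))
    ) / (_LN2**2)
    return (e_ic, v_ic)


def compute_ic(t: ContingencyTable) -> tuple[float, float]:
    """Plug-in IC point value and the Bayesian lower bound IC025 = E(IC) - 2*sqrt(V(IC))."""
    if t.a <= 0:
        return (math.nan, math.nan)
    ic = math.log2(t.a * t.n / ((t.a + t.c) * (t.a + t.b)))
    e_ic, v_ic = bcpnn_moments(t)
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return (ic, ic025)


def compute_ebgm(t: ContingencyTable) -> tuple[float, float]:
    """Plug-in EBGM (observed/expected) with log-normal lower bound EBGM05.

    The point value needs only a > 0; the bound additionally needs all
    cells positive (else NaN while the point value is still returned).
    """
    if t.a <= 0:
        return (math.nan, math.nan)
    ebgm = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    if min(t.b, t.c, t.d) <= 0:
        return (ebgm, math.nan)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    ebgm05 = math.exp(math.log(ebgm) - 1.96 * se)
    return (ebgm, ebgm05)


# ---------------------------------------------------------------------------
# Estimates, screening criteria, multiplicity


@dataclass
class SignalEstimates:
    """All four statistics, interval bounds and criteria flags for one term."""

    term: str
    level: str  # "PT" or "SOC"
    n: int  # = a, the report count for the term with the target drug
    table: ContingencyTable
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    chi2_p: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    soc: str = ""
    flags: dict[str, bool] = field(default_factory=dict)
    flagged_by_all: bool = False
    bonferroni_significant: bool = False


def evaluate_criteria(e: SignalEstimates) -> dict[str, bool]:
    """Screening gates of the four algorithms (NaN comparisons are false).

    ROR: lower 95% bound > 1 and n >= 3.  PRR: PRR >= 2, chi2 >= 4, n >= 3.
    BCPNN: IC025 > 0.  MGPS: EBGM05 > 2.
    """
    return {
        "ror": bool(e.ror_lo > 1.0 and e.n >= 3),
        "prr": bool(e.prr >= 2.0 and e.chi2 >= 4.0 and e.n >= 3),
        "bcpnn": bool(e.ic025 > 0.0),
        "mgps": bool(e.ebgm05 > 2.0),
    }


def compute_signal_estimates(
    term: str,
    level: str,
    table: ContingencyTable,
    soc: str = "",
    continuity_correction: bool = False,
) -> SignalEstimates:
    """Evaluate all four statistics and their flags on one table."""
    t = table.shifted(0.5) if continuity_correction else table
    e = SignalEstimates(term=term, level=level, n=int(table.a), table=table, soc=soc or term)
    e.ror, e.ror_lo, e.ror_hi = compute_ror(t)
    e.prr, e.chi2, e.chi2_p = compute_prr_chi2(t)
    e.ic, e.ic025 = compute_ic(t)
    e.ebgm, e.ebgm05 = compute_ebgm(t)
    e.flags = evaluate_criteria(e)
    e.flagged_by_all = all(e.flags.values())
    return e


@dataclass(frozen=True)
class ScreenResult:
    """Intersection screening of the four algorithms."""

    intersection: list[SignalEstimates]  # flagged by all four
    reported: list[SignalEstimates]  # intersection further filtered to n >= min_n
    venn: dict[tuple[str, ...], int]  # exact flag subset -> term count (>=1 flag only)
    min_n: int


def screen_terms(estimates: Sequence[SignalEstimates], min_n: int = 11) -> ScreenResult:
    """Apply the four-algorithm intersection and the reporting cut n >= min_n.

    The reported list is sorted by SOC name, then descending n, then term —
    a deterministic order matching the published table layout.  The Venn
    counts key each exact subset of flagging algorithms among terms flagged
    by at least one.
    """
    intersection = [e for e in estimates if e.flagged_by_all]
    reported = sorted(
        (e for e in intersection if e.n >= min_n),
        key=lambda e: (e.soc, -e.n, e.term),
    )
    venn: dict[tuple[str, ...], int] = {}
    for e in estimates:
        subset = tuple(alg for alg in ALGORITHMS if e.flags.get(alg))
        if subset:
            venn[subset] = venn.get(subset, 0) + 1
    return ScreenResult(
        intersection=sorted(intersection, key=lambda e: (e.soc, -e.n, e.term)),
        reported=reported,
        venn=venn,
        min_n=min_n,
    )


def bonferroni(
    estimates: Iterable[SignalEstimates], alpha: float = 0.05, min_a: int = 3
) -> list[SignalEstimates]:
    """Bonferroni-adjust the chi-square p-values across the tested family.

    The family is every term with n >= ``min_a`` at the analyzed level (the
    same gate the screening criteria use); a term is significant when its
    p-value is at most alpha/m.  Returns the same estimates, updated.
    """
    estimates = list(estimates)
    family = [e for e in estimates if e.n >= min_a]
    m = len(family)
    if m == 0:
        warnings.warn("Bonferroni: no terms with n >= %d; nothing adjusted" % min_a)
        return estimates
    cutoff = alpha / m
    for e in estimates:
        e.bonferroni_significant = bool(
            e.n >= min_a and not math.isnan(e.chi2_p) and e.chi2_p <= cutoff
        )
    return estimates


# ---------------------------------------------------------------------------
# Pipeline orchestration


def analyze_terms(
    target_pairs: pd.DataFrame,
    all_pairs: pd.DataFrame,
    target_case_count: int,
    total_case_count: int,
    level: str = "PT",
    term_column: str = "pt",
    soc_of: Mapping[str, str] | None = None,
    continuity_correction: bool = False,
    alpha: float = 0.05,
) -> list[SignalEstimates]:
    """Tables + all four statistics + Bonferroni for every observed term."""
    tables = build_all_tables(
        target_pairs, all_pairs, target_case_count, total_case_count, term_column
    )
    estimates = [
        compute_signal_estimates(
            term,
            level,
            tab,
            soc=(soc_of or {}).get(term, term if level == "SOC" else ""),
            continuity_correction=continuity_correction,
        )
        for term, tab in sorted(tables.items())
    ]
    return bonferroni(estimates, alpha=alpha)


def estimates_frame(estimates: Sequence[SignalEstimates]) -> pd.DataFrame:
    """Flat table mirroring the published signal tables (one row per term)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "soc": e.soc,
                "term": e.term,
                "level": e.level,
                "n": e.n,
                "a": e.table.a,
                "b": e.table.b,
                "c": e.table.c,
                "d": e.table.d,
                "ror": e.ror,
                "ror_lo": e.ror_lo,
                "ror_hi": e.ror_hi,
                "prr": e.prr,
                "chi2": e.chi2,
                "chi2_p": e.chi2_p,
                "ic": e.ic,
                "ic025": e.ic025,
                "ebgm": e.ebgm,
                "ebgm05": e.ebgm05,
                "flag_ror": e.flags.get("ror", False),
                "flag_prr": e.flags.get("prr", False),
                "flag_bcpnn": e.flags.get("bcpnn", False),
                "flag_mgps": e.flags.get("mgps", False),
                "flagged_by_all": e.flagged_by_all,
                "bonferroni_significant": e.bonferroni_significant,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["soc", "n", "term"], ascending=[True, False, True]).reset_index(
            drop=True
        )
    return df


def venn_frame(result: ScreenResult) -> pd.DataFrame:
    rows = [
        {"algorithms": "+".join(subset), "terms": count}
        for subset, count in sorted(result.venn.items())
    ]
    return pd.DataFrame(rows, columns=["algorithms", "terms"])
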