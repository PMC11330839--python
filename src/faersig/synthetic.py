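"""Synthetic FAERS-style data with known ground truth.

Generates quarterly table sets (DEMO/DRUG/REAC/OUTC/INDI/THER) from an
explicit generative model: each case is a target-drug case with probability
``target_drug_fraction``; its adverse-event preferred terms are independent
Bernoulli draws over a vocabulary, with the *odds* of injected terms
multiplied by a configurable true odds ratio among target-drug cases (odds
parameterization so the true reporting odds ratio is exact, not
approximate).  Every case reports at least one term — empty draws are
resampled, which is exactly conditioning on a non-empty term set, and the
closed-form expectations in :func:`true_contingency` account for it.

The generator also injects the messiness the pipeline must survive:
duplicate report versions sharing a CASEID (with the intended survivor
recorded), partial dates, events dated before therapy start, and missing
event dates — each labelled in the ground truth so deduplication and onset
exclusions can be checked exactly.

The vocabulary is synthetic (MedDRA is licensed and cannot ship with test
data) apart from a handful of real example terms used in the documentation;
a PT->SOC map is emitted alongside the tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ingest import TABLE_KINDS, WRITE_ALIASES, DELIMITER, SCHEMAS
from .onset import ExclusionReason


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class VocabularyTerm:
    pt: str
    soc: str
    background_probability: float


@dataclass(frozen=True)
class InjectedSignal:
    """A drug–event association of known strength.

    ``true_odds_ratio`` multiplies the odds of the term among target-drug
    cases relative to the background odds.
    """

    pt: str
    true_odds_ratio: float


def default_vocabulary() -> list[VocabularyTerm]:
    """~50 synthetic PTs over 8 synthetic SOCs plus a few real example terms.

    Background probabilities sum to ~2.4 events per case so that almost
    every case reports at least one term and the non-empty conditioning in
    the generative model stays mild.
    """
    terms: list[VocabularyTerm] = [
        VocabularyTerm("Pyrexia", "General disorders and administration site conditions", 0.12),
        VocabularyTerm("Cough", "Respiratory, thoracic and mediastinal disorders", 0.08),
        VocabularyTerm("Rhinorrhoea", "Respiratory, thoracic and mediastinal disorders", 0.05),
        VocabularyTerm("Pneumonia", "Infections and infestations", 0.06),
    ]
    probs = (0.10, 0.06, 0.04, 0.03, 0.02, 0.012)
    for letter in "ABCDEFGH":
        soc = f"Synthetic SOC {letter} disorders"
        for i, p in enumerate(probs, start=1):
            terms.append(VocabularyTerm(f"Synthetic PT {letter}{i}", soc, p))
    return terms


DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    # loosely echoes a pediatric-skewed, consumer-heavy reporting population
    "sex": {"F": 0.45, "M": 0.375, "": 0.175},
    "occupation": {"CN": 0.74, "MD": 0.126, "HP": 0.052, "OT": 0.046,
                   "PH": 0.003, "RN": 0.001, "": 0.032},
    "country": {"US": 0.40, "BR": 0.255, "CO": 0.071, "GB": 0.042,
                "DE": 0.028, "FR": 0.05, "JP": 0.05, "": 0.104},
}


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults emulate the study conditions."""

    seed: int = 0
    n_cases: int = 5000
    target_drug_fraction: float = 0.05
    pt_vocabulary: list[VocabularyTerm] = field(default_factory=default_vocabulary)
    injected_signals: list[InjectedSignal] = field(default_factory=list)
    duplicate_version_probability: float = 0.20
    partial_date_probability: float = 0.10
    event_before_start_probability: float = 0.02
    missing_event_date_probability: float = 0.05
    demographics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    # log-normal onset-time parameters on the day scale: median exp(mu) ~ 1466 d
    onset_log_mean: float = 7.29
    onset_log_sd: float = 1.2
    date_range: tuple[int, int] = (2005, 2023)
    target_drug_names: tuple[str, ...] = ("GALSULFASE", "NAGLAZYME")

    def validate(self) -> None:
        for name in (
            "target_drug_fraction",
            "duplicate_version_probability",
            "partial_date_probability",
            "event_before_start_probability",
            "missing_event_date_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_cases <= 0:
            raise SimulationConfigError(f"n_cases must be positive, got {self.n_cases}")
        pts = [t.pt for t in self.pt_vocabulary]
        if len(pts) != len(set(pts)):
            raise SimulationConfigError("pt_vocabulary has duplicate PTs")
        for t in self.pt_vocabulary:
            if not 0.0 < t.background_probability < 1.0:
                raise SimulationConfigError(
                    f"background probability of {t.pt!r} must be in (0,1)"
                )
        vocab = set(pts)
        for s in self.injected_signals:
            if s.pt not in vocab:
                raise SimulationConfigError(f"injected signal PT {s.pt!r} not in vocabulary")
            if s.true_odds_ratio <= 0:
                raise SimulationConfigError(
                    f"true_odds_ratio of {s.pt!r} must be positive"
                )
        y0, y1 = self.date_range
        if y0 > y1:
            raise SimulationConfigError(f"date_range start {y0} after end {y1}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "pt_vocabulary" in raw:
            raw["pt_vocabulary"] = [VocabularyTerm(**t) for t in raw["pt_vocabulary"]]
        if "injected_signals" in raw:
            raw["injected_signals"] = [InjectedSignal(**s) for s in raw["injected_signals"]]
        if "date_range" in raw:
            raw["date_range"] = tuple(raw["date_range"])
        if "target_drug_names" in raw:
            raw["target_drug_names"] = tuple(raw["target_drug_names"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    injected_odds_ratios: dict[str, float]
    dedup_survivors: dict[str, str]  # caseid -> primaryid that must survive dedup
    target_primaryids: list[str]  # surviving primaryids of target-drug cases
    onset_days: dict[str, int]  # surviving target primaryid -> true onset (included)
    onset_exclusions: dict[str, str]  # surviving target primaryid -> reason code

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class SimulatedData:
    tables: dict[str, pd.DataFrame]
    meddra_map: dict[str, str]
    ground_truth: GroundTruth
    config: SimulationConfig


def _background_and_target_probs(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    p = np.array([t.background_probability for t in config.pt_vocabulary])
    p_target = p.copy()
    index = {t.pt: i for i, t in enumerate(config.pt_vocabulary)}
    for sig in config.injected_signals:
        j = index[sig.pt]
        odds = p[j] / (1.0 - p[j]) * sig.true_odds_ratio
        p_target[j] = odds / (1.0 + odds)
    return p, p_target


def _dates_to_compact(dates: np.ndarray) -> np.ndarray:
    if dates.size == 0:
        return np.empty(0, dtype="U8")
    return np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")


def _choice(rng: np.random.Generator, dist: Mapping[str, float], size: int) -> np.ndarray:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(keys, dtype=object), size=size, p=probs).astype(str)


def simulate(config: SimulationConfig, seed: int | None = None) -> SimulatedData:
    """Draw a full table set from the generative model; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cases
    vocab = config.pt_vocabulary
    pt_names = np.array([t.pt for t in vocab], dtype=object)

    caseids = np.char.add("", (np.arange(n) + 10_000_000).astype(str))
    pid1 = np.char.add(caseids, "1")
    pid2 = np.char.add(caseids, "2")

    is_target = rng.random(n) < config.target_drug_fraction

    # --- adverse-event terms: independent Bernoulli, >=1 enforced by resampling
    p_bg, p_tg = _background_and_target_probs(config)
    probs = np.where(is_target[:, None], p_tg[None, :], p_bg[None, :])
    events = rng.random((n, len(vocab))) < probs
    while True:
        empty = ~events.any(axis=1)
        if not empty.any():
            break
        k = int(empty.sum())
        events[empty] = rng.random((k, len(vocab))) < probs[empty]

    # --- therapy start, event date, FDA receipt date
    y0, y1 = config.date_range
    base = np.datetime64(f"{y0:04d}-01-01")
    span = (np.datetime64(f"{y1:04d}-12-31") - base).astype(int)
    start_dates = base + rng.integers(0, span + 1, n).astype("timedelta64[D]")
    true_onset = np.rint(
        rng.lognormal(config.onset_log_mean, config.onset_log_sd, n)
    ).astype(int)
    event_dates = start_dates + true_onset.astype("timedelta64[D]")
    fda_dates = event_dates + rng.integers(3, 120, n).astype("timedelta64[D]")

    start_str = _dates_to_compact(start_dates)
    event_str = _dates_to_compact(event_dates)
    fda_str = _dates_to_compact(fda_dates)

    # --- injected data-quality problems (mutually exclusive per case)
    u = rng.random(n)
    p_ebs = config.event_before_start_probability
    p_imp = config.partial_date_probability
    p_mis = config.missing_event_date_probability
    ebs_mask = u < p_ebs
    imp_mask = (u >= p_ebs) & (u < p_ebs + p_imp)
    mis_mask = (u >= p_ebs + p_imp) & (u < p_ebs + p_imp + p_mis)

    if ebs_mask.any():
        back = rng.integers(1, 101, int(ebs_mask.sum())).astype("timedelta64[D]")
        event_str[ebs_mask] = _dates_to_compact(start_dates[ebs_mask] - back)
    if imp_mask.any():
        # truncate the event date to month or year precision
        to_month = rng.random(int(imp_mask.sum())) < 0.5
        idx = np.flatnonzero(imp_mask)
        trunc = np.array([s[:6] if m else s[:4] for s, m in zip(event_str[idx], to_month)],
                         dtype=event_str.dtype)
        event_str[idx] = trunc
    mis_blank_event = np.zeros(n, dtype=bool)
    mis_degrade_start = np.zeros(n, dtype=bool)
    if mis_mask.any():
        # half lose the event date, half lose day precision of the start
        which = rng.random(int(mis_mask.sum())) < 0.5
        idx = np.flatnonzero(mis_mask)
        mis_blank_event[idx[which]] = True
        mis_degrade_start[idx[~which]] = True
        event_str[mis_blank_event] = ""
        start_idx = np.flatnonzero(mis_degrade_start)
        start_str[start_idx] = np.array(
            [s[:6] for s in start_str[start_idx]], dtype=start_str.dtype
        )

    # --- duplicate report versions sharing the CASEID
    dup_mask = rng.random(n) < config.duplicate_version_probability
    n_dup = int(dup_mask.sum())
    # later / equal / earlier FDA date for the higher-numbered version
    dup_kind = rng.choice(np.array(["later", "equal", "earlier"], dtype=object),
                          size=n_dup, p=[0.60, 0.25, 0.15])
    fda2 = fda_dates[dup_mask].copy()
    fda2[dup_kind == "later"] += rng.integers(
        1, 180, int((dup_kind == "later").sum())
    ).astype("timedelta64[D]")
    fda2[dup_kind == "earlier"] -= rng.integers(
        1, 90, int((dup_kind == "earlier").sum())
    ).astype("timedelta64[D]")
    fda2_str = _dates_to_compact(fda2)
    # survivor by the dedup rule itself stated independently: latest FDA date,
    # ties to the higher primaryid (version 2 has the higher id)
    survivor = dict(zip(caseids, pid1))
    for cid, p2, kind in zip(caseids[dup_mask], pid2[dup_mask], dup_kind):
        if kind in ("later", "equal"):
            survivor[str(cid)] = str(p2)

    # --- demographics
    demo_dist = config.demographics
    sex = _choice(rng, demo_dist["sex"], n)
    occp = _choice(rng, demo_dist["occupation"], n)
    country = _choice(rng, demo_dist["country"], n)

    age_known = rng.random(n) < 0.55
    age_grp = rng.choice(np.array(["child", "adult", "senior"], dtype=object),
                         size=n, p=[0.68, 0.30, 0.02])
    age_years = np.where(
        age_grp == "child", rng.uniform(0.2, 18, n),
        np.where(age_grp == "adult", rng.uniform(18, 66, n), rng.uniform(66, 85, n)),
    )
    age_in_months = age_known & (age_years < 2.0)
    age_val = np.where(age_in_months, np.rint(age_years * 12), np.floor(age_years))
    age = np.where(age_known, age_val.astype(int).astype(str), "")
    age_cod = np.where(age_known, np.where(age_in_months, "MON", "YR"), "")

    wt_known = rng.random(n) < 0.54
    wt_grp = rng.choice(np.array(["light", "mid", "heavy"], dtype=object),
                        size=n, p=[0.88, 0.115, 0.005])
    wt_kg = np.where(
        wt_grp == "light", rng.uniform(8, 50, n),
        np.where(wt_grp == "mid", rng.uniform(50, 100, n), rng.uniform(101, 140, n)),
    )
    in_lbs = rng.random(n) < 0.10
    wt_val = np.where(in_lbs, wt_kg / 0.45359237, wt_kg)
    wt = np.where(wt_known, np.char.mod("%.1f", wt_val), "")
    wt_cod = np.where(wt_known, np.where(in_lbs, "LBS", "KG"), "")

    # --- assemble DEMO (version 1 for everyone, version 2 for duplicates)
    def demo_frame(pids: np.ndarray, idx: np.ndarray, fda: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "primaryid": pids,
                "caseid": caseids[idx],
                "fda_dt": fda,
                "event_dt": event_str[idx],
                "sex": sex[idx],
                "age": age[idx],
                "age_cod": age_cod[idx],
                "wt": wt[idx],
                "wt_cod": wt_cod[idx],
                "occp_cod": occp[idx],
                "reporter_country": country[idx],
            },
            dtype=str,
        )

    all_idx = np.arange(n)
    demo = pd.concat(
        [
            demo_frame(pid1, all_idx, fda_str),
            demo_frame(pid2[dup_mask], all_idx[dup_mask], fda2_str),
        ],
        ignore_index=True,
    )

    # --- DRUG / THER / INDI (content keyed by case, emitted per version)
    filler_names = np.array([f"SYNTH DRUG {k:02d}" for k in range(1, 11)], dtype=object)
    primary_name = np.where(
        is_target,
        rng.choice(np.array(config.target_drug_names, dtype=object), size=n),
        rng.choice(filler_names, size=n),
    ).astype(str)
    primary_ai = np.where(is_target, config.target_drug_names[0], primary_name)
    has_concomitant = rng.random(n) < 0.35
    conc_name = rng.choice(filler_names, size=n).astype(str)

    target_indi = _choice(
        rng,
        {"Mucopolysaccharidosis VI": 0.78, "Product used for unknown indication": 0.17,
         "Mucopolysaccharidosis": 0.04, "Lipidosis": 0.01},
        n,
    )
    other_indi = _choice(
        rng,
        {"Product used for unknown indication": 0.80, "Hypertension": 0.12, "Pain": 0.08},
        n,
    )
    indi_pt = np.where(is_target, target_indi, other_indi)

    # --- OUTC
    n_outc = rng.choice(np.array([0, 1, 2]), size=n, p=[0.30, 0.55, 0.15])
    outc_dist = {"HO": 0.42, "OT": 0.34, "DE": 0.10, "LT": 0.03,
                 "DS": 0.02, "CA": 0.005, "RI": 0.005}

    ev_case, ev_term = np.nonzero(events)

    def content_tables(pids_for_case: np.ndarray, idx: np.ndarray) -> dict[str, pd.DataFrame]:
        """DRUG/REAC/OUTC/INDI/THER rows for the given cases under the given ids."""
        pid_of = dict(zip(all_idx[idx], pids_for_case))
        sel = np.isin(ev_case, idx)
        reac = pd.DataFrame(
            {
                "primaryid": [pid_of[i] for i in ev_case[sel]],
                "pt": pt_names[ev_term[sel]].astype(str),
            },
            dtype=str,
        )
        drug_rows = {
            "primaryid": list(pids_for_case) + list(pids_for_case[has_concomitant[idx]]),
            "drug_seq": ["1"] * len(idx) + ["2"] * int(has_concomitant[idx].sum()),
            "role_cod": ["PS"] * len(idx) + ["C"] * int(has_concomitant[idx].sum()),
            "drugname": list(primary_name[idx]) + list(conc_name[idx][has_concomitant[idx]]),
            "prod_ai": list(primary_ai[idx]) + list(conc_name[idx][has_concomitant[idx]]),
        }
        drug = pd.DataFrame(drug_rows, dtype=str)
        ther = pd.DataFrame(
            {
                "primaryid": pids_for_case,
                "drug_seq": "1",
                "start_dt": start_str[idx],
                "end_dt": "",
            },
            dtype=str,
        )
        indi = pd.DataFrame(
            {"primaryid": pids_for_case, "drug_seq": "1", "indi_pt": indi_pt[idx]},
            dtype=str,
        )
        outc_pids: list[str] = []
        for i, pid in zip(idx, pids_for_case):
            outc_pids.extend([pid] * int(n_outc[i]))
        outc = pd.DataFrame(
            {
                "primaryid": outc_pids,
                "outc_cod": _choice(rng, outc_dist, len(outc_pids)),
            },
            dtype=str,
        )
        return {"DRUG": drug, "REAC": reac, "OUTC": outc, "INDI": indi, "THER": ther}

    v1 = content_tables(pid1, all_idx)
    v2 = content_tables(pid2[dup_mask], all_idx[dup_mask])
    tables: dict[str, pd.DataFrame] = {"DEMO": demo.reset_index(drop=True)}
    for kind in ("DRUG", "REAC", "OUTC", "INDI", "THER"):
        tables[kind] = pd.concat([v1[kind], v2[kind]], ignore_index=True)

    # --- ground truth
    onset_days: dict[str, int] = {}
    onset_excl: dict[str, str] = {}
    target_pids: list[str] = []
    for i in np.flatnonzero(is_target):
        pid = survivor[str(caseids[i])]
        target_pids.append(pid)
        if ebs_mask[i]:
            onset_excl[pid] = ExclusionReason.EVENT_BEFORE_START.value
        elif imp_mask[i]:
            onset_excl[pid] = ExclusionReason.IMPRECISE_DATE.value
        elif mis_mask[i]:
            onset_excl[pid] = ExclusionReason.MISSING_DATE.value
        else:
            onset_days[pid] = int(true_onset[i])

    truth = GroundTruth(
        injected_odds_ratios={s.pt: s.true_odds_ratio for s in config.injected_signals},
        dedup_survivors={str(k): str(v) for k, v in survivor.items()},
        target_primaryids=sorted(target_pids),
        onset_days=onset_days,
        onset_exclusions=onset_excl,
    )
    meddra = {t.pt: t.soc for t in vocab}
    return SimulatedData(tables=tables, meddra_map=meddra, ground_truth=truth, config=config)


def true_contingency(config: SimulationConfig, pt: str) -> dict[str, float]:
    """Expected 2x2 cell *fractions* for a term, in closed form.

    Resampling empty cases is conditioning on >=1 term, so the conditional
    per-term probability is p_t / P(any term); the four cell fractions are
    products of that with the target-drug Bernoulli.  Exact for the
    generative model, hence usable as an analytic oracle.
    """
    pts = [t.pt for t in config.pt_vocabulary]
    if pt not in pts:
        raise KeyError(f"unknown PT: {pt!r}")
    j = pts.index(pt)
    p_bg, p_tg = _background_and_target_probs(config)
    z_bg = 1.0 - float(np.prod(1.0 - p_bg))
    z_tg = 1.0 - float(np.prod(1.0 - p_tg))
    p_other = p_bg[j] / z_bg
    p_target = p_tg[j] / z_tg
    f = config.target_drug_fraction
    return {
        "a": f * p_target,
        "b": f * (1.0 - p_target),
        "c": (1.0 - f) * p_other,
        "d": (1.0 - f) * (1.0 - p_other),
    }


def expected_ror(config: SimulationConfig, pt: str) -> float:
    cells = true_contingency(config, pt)
    return (cells["a"] * cells["d"]) / (cells["b"] * cells["c"])


# ---------------------------------------------------------------------------
# Writing FAERS-dialect files


def write_quarter(
    tables: Mapping[str, pd.DataFrame], directory: str | Path, label: str = "23Q4"
) -> list[Path]:
    """Write a table set as ``$``-delimited quarter files (DEMO23Q4.txt ...).

    Uses the on-disk FAERS header names; round-trips exactly through
    :func:`faersig.ingest.read_table`.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for kind in TABLE_KINDS:
        if kind not in tables:
            continue
        df = tables[kind]
        aliases = WRITE_ALIASES.get(kind, {})
        cols = list(df.columns)
        header = [aliases.get(c, c) for c in cols]
        path = d / f"{kind}{label}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(DELIMITER.join(header) + "\n")
            for row in df.itertuples(index=False):
                cells = ["" if v is None else str(v) for v in row]
                for v in cells:
                    if DELIMITER in v:
                        raise ValueError(f"cell value contains the delimiter: {v!r}")
                fh.write(DELIMITER.join(cells) + "\n")
        written.append(path)
    return written


def _quarter_label(fda_dt: str) -> str:
    y = int(fda_dt[:4])
    m = int(fda_dt[4:6]) if len(fda_dt) >= 6 else 1
    return f"{y % 100:02d}Q{(m - 1) // 3 + 1}"


def write_dataset(
    sim: SimulatedData, directory: str | Path, split_quarters: bool = True
) -> list[Path]:
    """Emit quarter directories plus meddra_map.tsv and ground_truth.json.

    With ``split_quarters`` the reports are partitioned by FDA-receipt
    quarter (as real FAERS extracts are); otherwise a single quarter
    directory holds everything.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    demo = sim.tables["DEMO"]
    if split_quarters and len(demo):
        labels = demo["fda_dt"].map(_quarter_label)
    else:
        labels = pd.Series(["23Q4"] * len(demo), index=demo.index)
    dirs: list[Path] = []
    for label in sorted(labels.unique()):
        mask = labels == label
        pids = set(demo.loc[mask, "primaryid"])
        subset = {"DEMO": demo[mask]}
        for kind in ("DRUG", "REAC", "OUTC", "INDI", "THER"):
            df = sim.tables[kind]
            subset[kind] = df[df["primaryid"].isin(pids)]
        qdir = root / label.lower()
        write_quarter(subset, qdir, label)
        dirs.append(qdir)
    pd.DataFrame(
        {"pt": list(sim.meddra_map), "soc": list(sim.meddra_map.values())}
    ).to_csv(root / "meddra_map.tsv", sep="\t", index=False)
    sim.ground_truth.to_json(root / "ground_truth.json")
    return dirs
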