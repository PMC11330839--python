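"""Target-drug case selection and the unique case–event pairs all counting rests on.

A report belongs to the target drug when at least one of its DRUG rows names
the drug — by generic or brand name, matched exactly after uppercasing and
trimming — with an accepted role code (primary suspect by default).  Every
disproportionality count downstream is over unique (case, term) pairs: a
case contributes a preferred term at most once, and at System Organ Class
level a case contributes a SOC at most once regardless of how many of its
PTs map into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class ConfigurationError(ValueError):
    pass


class UnmappedTermError(KeyError):
    """PT(s) observed in the data but absent from the PT->SOC map."""

    def __init__(self, terms: list[str]):
        self.terms = terms
        super().__init__(
            "preferred terms missing from the PT->SOC map: " + ", ".join(terms)
        )


VALID_ROLES = frozenset({"PS", "SS", "C", "I"})


@dataclass(frozen=True)
class TargetDrugSpec:
    """Name synonyms and role codes identifying the drug of interest."""

    synonyms: frozenset[str]
    roles: frozenset[str] = frozenset({"PS"})

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ConfigurationError("target drug needs at least one name synonym")
        if not self.roles:
            raise ConfigurationError("target drug needs at least one role code")
        bad = self.roles - VALID_ROLES
        if bad:
            raise ConfigurationError(f"unknown role codes: {sorted(bad)}")

    @classmethod
    def from_names(
        cls, names: Iterable[str], roles: Iterable[str] = ("PS",)
    ) -> "TargetDrugSpec":
        return cls(
            synonyms=frozenset(n.strip().upper() for n in names if n.strip()),
            roles=frozenset(r.strip().upper() for r in roles),
        )


GALSULFASE = TargetDrugSpec.from_names(["GALSULFASE", "NAGLAZYME"])


def select_target_cases(drugs: pd.DataFrame, spec: TargetDrugSpec) -> set[str]:
    """Primaryids with >=1 drug row matching a synonym with an accepted role.

    Matching is exact (not substring) on the uppercased, trimmed drug name
    or active ingredient; the synonym list is user-extensible configuration.
    """
    if drugs.empty:
        return set()
    name = drugs["drugname"].str.strip().str.upper()
    match = name.isin(spec.synonyms)
    if "prod_ai" in drugs.columns:
        ai = drugs["prod_ai"].str.strip().str.upper()
        match |= ai.isin(spec.synonyms)
    match &= drugs["role_cod"].str.strip().str.upper().isin(spec.roles)
    return set(drugs.loc[match, "primaryid"])


def target_drug_rows(drugs: pd.DataFrame, spec: TargetDrugSpec) -> pd.DataFrame:
    """The (primaryid, drug_seq) rows that matched the target drug.

    These links anchor indication counting and therapy start dates to the
    target drug rather than co-reported medication.
    """
    if drugs.empty:
        return drugs.loc[:, ["primaryid", "drug_seq"]].copy()
    name = drugs["drugname"].str.strip().str.upper()
    match = name.isin(spec.synonyms)
    if "prod_ai" in drugs.columns:
        match |= drugs["prod_ai"].str.strip().str.upper().isin(spec.synonyms)
    match &= drugs["role_cod"].str.strip().str.upper().isin(spec.roles)
    return (
        drugs.loc[match, ["primaryid", "drug_seq"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )


def collect_case_events(case_ids: set[str], reacs: pd.DataFrame) -> pd.DataFrame:
    """Unique (primaryid, pt) pairs for the given cases, deterministically ordered."""
    if reacs.empty or not case_ids:
        return pd.DataFrame({"primaryid": pd.Series(dtype=str), "pt": pd.Series(dtype=str)})
    sel = reacs[reacs["primaryid"].isin(case_ids)].copy()
    sel["pt"] = sel["pt"].str.strip()
    sel = sel[sel["pt"] != ""]
    return (
        sel.loc[:, ["primaryid", "pt"]]
        .drop_duplicates()
        .sort_values(["primaryid", "pt"], kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class MeddraMap:
    """A total PT -> SOC mapping (MedDRA is licensed, so it is user-supplied)."""

    entries: Mapping[str, str] = field(default_factory=dict)

    def soc_of(self, pt: str) -> str:
        try:
            return self.entries[pt]
        except KeyError:
            raise UnmappedTermError([pt]) from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeddraMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if "pt" not in cols or "soc" not in cols:
            raise ConfigurationError(
                f"{path}: PT->SOC map needs columns 'pt' and 'soc' (got {cols})"
            )
        return cls(entries=dict(zip(df["pt"].str.strip(), df["soc"].str.strip())))


def map_to_soc(
    pairs: pd.DataFrame, meddra: MeddraMap, unique: bool = True
) -> pd.DataFrame:
    """Map case–PT pairs to case–SOC pairs.

    With ``unique=True`` (default) a case counts once per SOC however many
    of its PTs fall in it; ``unique=False`` keeps one row per PT-in-SOC for
    pair-level counting.  Raises :class:`UnmappedTermError` listing every
    PT missing from the map.
    """
    if pairs.empty:
        return pd.DataFrame({"primaryid": pd.Series(dtype=str), "soc": pd.Series(dtype=str)})
    missing = sorted(set(pairs["pt"]) - set(meddra.entries))
    if missing:
        raise UnmappedTermError(missing)
    out = pd.DataFrame(
        {"primaryid": pairs["primaryid"], "soc": pairs["pt"].map(meddra.entries)}
    )
    if unique:
        out = out.drop_duplicates()
    return out.sort_values(["primaryid", "soc"], kind="mergesort").reset_index(drop=True)
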