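"""Reading FAERS-style quarterly ASCII extracts and removing duplicate report versions.

FAERS quarters ship as ``$``-delimited text tables (DEMO, DRUG, REAC, OUTC,
INDI, THER) with a header line and no quoting.  This module parses them into
pandas DataFrames with canonical lower-case column names, concatenates
quarters, and collapses multiple versions of the same case: when several
report versions share a CASEID the most recent FDA receipt date wins, and on
a tie the higher PRIMARYID wins.

All values are kept as stripped strings; typed interpretation (dates, ages,
weights) happens in the analysis modules so that dirty fields never abort
ingestion.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .dates import pad_compact

DELIMITER = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER")


class FormatError(ValueError):
    """A table file that does not conform to the expected FAERS dialect."""


@dataclass(frozen=True)
class TableSchema:
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    # on-disk header name -> canonical name (drug_seq columns differ per table)
    aliases: Mapping[str, str] = field(default_factory=dict)

    @property
    def columns(self) -> tuple[str, ...]:
        return self.required + self.optional


SCHEMAS: dict[str, TableSchema] = {
    "DEMO": TableSchema(
        required=("primaryid", "caseid", "fda_dt"),
        optional=(
            "event_dt",
            "sex",
            "age",
            "age_cod",
            "wt",
            "wt_cod",
            "occp_cod",
            "reporter_country",
        ),
        # older quarters code sex as GNDR_COD
        aliases={"gndr_cod": "sex"},
    ),
    "DRUG": TableSchema(
        required=("primaryid", "drug_seq", "role_cod", "drugname"),
        optional=("prod_ai",),
    ),
    "REAC": TableSchema(required=("primaryid", "pt")),
    "OUTC": TableSchema(required=("primaryid", "outc_cod")),
    "INDI": TableSchema(
        required=("primaryid", "drug_seq", "indi_pt"),
        aliases={"indi_drug_seq": "drug_seq"},
    ),
    "THER": TableSchema(
        required=("primaryid", "drug_seq"),
        optional=("start_dt", "end_dt"),
        aliases={"dsg_drug_seq": "drug_seq"},
    ),
}

# canonical -> on-disk header used when writing FAERS-dialect files
WRITE_ALIASES: dict[str, dict[str, str]] = {
    "DEMO": {},
    "DRUG": {},
    "REAC": {},
    "OUTC": {},
    "INDI": {"drug_seq": "indi_drug_seq"},
    "THER": {"drug_seq": "dsg_drug_seq"},
}


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Parse one ``$``-delimited FAERS table into a canonical DataFrame.

    Header matching is case-insensitive; unknown extra columns are dropped,
    missing optional columns are added as empty strings, and every cell is
    stripped of surrounding whitespace.  A missing required column raises
    :class:`FormatError` naming the column.
    """
    kind = table_kind.upper()
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    schema = SCHEMAS[kind]
    path = Path(path)
    text = _read_text(path)
    lines = text.splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (no header)")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    header = [schema.aliases.get(h, h) for h in header]
    for col in schema.required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows = [line.split(DELIMITER) for line in lines[1:] if line.strip() != ""]
    df = pd.DataFrame(rows, columns=None, dtype=str)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=str) for c in schema.columns})
        return df
    # ragged lines: pad/trim to header width
    ncol = len(header)
    if df.shape[1] < ncol:
        for i in range(df.shape[1], ncol):
            df[i] = ""
    df = df.iloc[:, :ncol]
    df.columns = header
    df = df.loc[:, ~df.columns.duplicated()]
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        if col in df.columns:
            out[col] = df[col].fillna("").astype(str).str.strip()
        else:
            out[col] = ""
    return out.reset_index(drop=True)


def _quarter_files(directory: Path, kind: str) -> list[Path]:
    pat = re.compile(rf"^{kind}.*\.txt$", re.IGNORECASE)
    return sorted(p for p in directory.iterdir() if p.is_file() and pat.match(p.name))


def load_quarters(directories: Iterable[str | Path]) -> dict[str, pd.DataFrame]:
    """Read every table of every quarter directory and concatenate per kind.

    Files are located by prefix (``DEMO*.txt`` etc., case-insensitive).
    Concatenation happens before deduplication, so the same case appearing
    in several quarters is resolved by :func:`deduplicate`.
    """
    frames: dict[str, list[pd.DataFrame]] = {k: [] for k in TABLE_KINDS}
    for d in directories:
        d = Path(d)
        if not d.is_dir():
            raise FileNotFoundError(f"not a directory: {d}")
        for kind in TABLE_KINDS:
            for f in _quarter_files(d, kind):
                frames[kind].append(read_table(f, kind))
    out: dict[str, pd.DataFrame] = {}
    for kind in TABLE_KINDS:
        if frames[kind]:
            out[kind] = pd.concat(frames[kind], ignore_index=True)
        else:
            out[kind] = pd.DataFrame(
                {c: pd.Series(dtype=str) for c in SCHEMAS[kind].columns}
            )
    return out


def _primaryid_order_key(s: pd.Series) -> pd.Series:
    """Numeric ordering for digit identifiers, lexicographic fallback."""
    num = pd.to_numeric(s, errors="coerce")
    if num.notna().all():
        return num
    width = int(s.str.len().max() or 0)
    return s.str.rjust(width, "0")


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one report version per CASEID.

    Within a caseid the kept record has the latest FDA_DT (partial dates
    padded with 01 for ordering only); ties are broken by the higher
    PRIMARYID.  Output is sorted by caseid, one row per caseid.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_fda_key"] = work["fda_dt"].map(pad_compact)
    work["_pid_key"] = _primaryid_order_key(work["primaryid"])
    work = work.sort_values(
        ["caseid", "_fda_key", "_pid_key"], kind="mergesort"
    ).drop_duplicates(subset="caseid", keep="last")
    work = work.sort_values("caseid", kind="mergesort")
    return work.drop(columns=["_fda_key", "_pid_key"]).reset_index(drop=True)


def restrict_to_cases(
    tables: Mapping[str, pd.DataFrame], primaryids: Iterable[str]
) -> dict[str, pd.DataFrame]:
    """Drop rows of every non-DEMO table whose report version was deduplicated away."""
    keep = set(primaryids)
    out: dict[str, pd.DataFrame] = {}
    for kind, df in tables.items():
        if kind == "DEMO" or df.empty:
            out[kind] = df.copy()
        else:
            out[kind] = df[df["primaryid"].isin(keep)].reset_index(drop=True)
    return out


def ingest_quarters(directories: Iterable[str | Path]) -> tuple[dict[str, pd.DataFrame], dict]:
    """Full ingest: concatenate quarters, deduplicate, discard orphan rows.

    Returns the deduplicated table set and an ingest log with report counts
    before and after duplicate removal.
    """
    tables = load_quarters(directories)
    n_before = len(tables["DEMO"])
    demo = deduplicate(tables["DEMO"])
    tables = restrict_to_cases(tables, demo["primaryid"])
    tables["DEMO"] = demo
    log = {
        "reports_before_dedup": n_before,
        "reports_after_dedup": len(demo),
        "distinct_caseids": int(demo["caseid"].nunique()),
    }
    return tables, log


# ---------------------------------------------------------------------------
# Normalized on-disk store (TSV per table) produced by `faersig ingest`

STORE_FILES = {kind: f"{kind.lower()}.tsv" for kind in TABLE_KINDS}


def write_store(
    tables: Mapping[str, pd.DataFrame], directory: str | Path, log: dict | None = None
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for kind, fname in STORE_FILES.items():
        tables[kind].to_csv(d / fname, sep="\t", index=False)
    if log is not None:
        (d / "ingest_log.json").write_text(json.dumps(log, indent=2) + "\n")


def read_store(directory: str | Path) -> dict[str, pd.DataFrame]:
    d = Path(directory)
    out: dict[str, pd.DataFrame] = {}
    for kind, fname in STORE_FILES.items():
        f = d / fname
        if f.exists():
            out[kind] = pd.read_csv(f, sep="\t", dtype=str, keep_default_na=False)
        else:
            out[kind] = pd.DataFrame(
                {c: pd.Series(dtype=str) for c in SCHEMAS[kind].columns}
            )
    return out
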