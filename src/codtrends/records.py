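"""Reading, validation, filtering and maturity coding of survey records.

Three delimited-text inputs (comma default, tab accepted), each with a
one-line header and optional leading ``#`` metadata lines:

``individuals.csv``  date,sd,gear,length_cm,weight_g,sex,maturity
``catches.csv``      haul,date,sd,length_class,count          (long form)
``series.csv``       year,catch,ssb,tsb_gt35,f46,m46,recruits,cbh_ssb,spr_ssb,fa

Dates are ISO-8601; two-digit archival years are rejected rather than
guessed.  Malformed rows are never silently dropped: they are collected
into a rejects list with line numbers and reasons, and every filter is a
pure, order-preserving, idempotent operation so that at each stage
``records in == records kept + records removed``.

Maturity coding follows the eight-degree Maier gonad scale: stages 1-2 are
immature, 3-7 mature or maturing in the current year; a range such as
"2-3" collapses to its lowest endpoint before coding.  Stage 8 (spent) is
excluded by default (conservative; configurable).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("codtrends")

__all__ = [
    "RecordSet",
    "SeriesTable",
    "code_maturity",
    "code_maturity_column",
    "filter_spawning_window",
    "filter_subdivisions",
    "read_individual_records",
    "read_catch_records",
    "read_series_table",
    "write_table",
    "write_annual_series",
    "write_trend_report",
    "write_correlation_report",
    "write_series_table",
    "IMMATURE_STAGES",
    "MATURE_STAGES",
]

IMMATURE_STAGES = frozenset({1, 2})
MATURE_STAGES = frozenset({3, 4, 5, 6, 7})
CORE_SUBDIVISIONS = frozenset({25, 26, 27, 28, 29})
SPAWNING_MONTHS = tuple(range(4, 9))  # April-August inclusive

INDIVIDUAL_COLUMNS = ["date", "sd", "gear", "length_cm", "weight_g", "sex", "maturity"]
CATCH_COLUMNS = ["haul", "date", "sd", "length_class", "count"]

# en/em dashes and minus normalised to ASCII hyphen before parsing ranges
_DASHES = re.compile(r"[‐-―−]")
_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass
class RecordSet:
    """Parsed records plus the rows that failed validation."""

    records: pd.DataFrame
    rejects: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SeriesTable:
    """Year-indexed assessment/forage table with declared units."""

    table: pd.DataFrame  # index: year
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# maturity coding
# ---------------------------------------------------------------------------

def _parse_stage(raw) -> int | None:
    """Lowest Maier stage encoded by ``raw``; None when missing/unparseable.

    A range like "2-3" (any dash flavour) collapses to its lowest endpoint.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if isinstance(raw, (int, np.integer)):
        return int(raw)
    if isinstance(raw, float):
        return int(raw) if raw.is_integer() else None
    s = _DASHES.sub("-", str(raw).strip())
    if s == "" or s.lower() in {"na", "nan"}:
        return None
    m = re.fullmatch(r"(\d+)(?:\s*-\s*(\d+))?", s)
    if m is None:
        return None
    lo = int(m.group(1))
    if m.group(2) is not None and int(m.group(2)) < lo:
        return None  # unordered range
    return lo


def code_maturity(maturity_raw, exclude_stages=frozenset({8})) -> str:
    """Binary maturity status from a raw Maier stage or range.

    Returns ``"immature"`` (stages 1-2), ``"mature"`` (3-7) or
    ``"excluded"`` (stage 8/spent by default, missing, or unparseable —
    logged, never silently dropped).
    """
    stage = _parse_stage(maturity_raw)
    if stage is None:
        if maturity_raw is not None and not (
            isinstance(maturity_raw, float) and np.isnan(maturity_raw)
        ):
            logger.warning("unparseable maturity token %r -> excluded", maturity_raw)
        return "excluded"
    if stage in exclude_stages or not 1 <= stage <= 8:
        return "excluded"
    if stage in IMMATURE_STAGES:
        return "immature"
    if stage in MATURE_STAGES:
        return "mature"
    # stage 8 (spent) not excluded by configuration: the fish has spawned
    return "mature" if stage == 8 else "excluded"


def code_maturity_column(records: pd.DataFrame, exclude_stages=frozenset({8})) -> pd.DataFrame:
    """Copy of ``records`` with a ``maturity_status`` column added.

    Conservation: immature + mature + excluded == len(records).
    """
    out = records.copy()
    out["maturity_status"] = [
        code_maturity(v, exclude_stages) for v in out["maturity"]
    ]
    return out


# ---------------------------------------------------------------------------
# filters (order-preserving, idempotent)
# ---------------------------------------------------------------------------

def filter_spawning_window(records: pd.DataFrame, months=SPAWNING_MONTHS) -> pd.DataFrame:
    """Keep records sampled during the spawning window (April-August).

    Records with missing dates are removed (and countable by the caller via
    the length difference)."""
    keep = records["month"].isin(months) & records["month"].notna()
    return records.loc[keep]


def filter_subdivisions(records: pd.DataFrame, sds=CORE_SUBDIVISIONS) -> pd.DataFrame:
    """Keep records from the given ICES subdivisions (default core 25-29)."""
    return records.loc[records["sd"].isin(set(int(s) for s in sds))]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def _read_raw(path) -> tuple[pd.DataFrame, int]:
    """Raw string-typed table plus the number of leading metadata lines."""
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_meta += 1
            else:
                break
    df = pd.read_csv(
        path, sep=_sniff_sep(path), comment="#", dtype=str,
        skip_blank_lines=False, keep_default_na=False,
    )
    return df, n_meta


def _parse_date(token: str):
    """(date string, year, month) or None when not a valid ISO-8601 date."""
    token = token.strip()
    if not _ISO_DATE.match(token):
        return None
    try:
        ts = pd.Timestamp(token)
    except ValueError:
        return None
    return token, ts.year, ts.month


def read_individual_records(path) -> RecordSet:
    """Read individual-fish records, validating each row.

    Valid rows need an ISO date (4-digit year), an integer subdivision and a
    positive length; weight, sex and maturity are optional.  Invalid rows go
    to ``rejects`` as (line_number, reason, raw_row) tuples.  Unknown
    columns produce a warning and are carried through untouched.
    """
    raw, n_meta = _read_raw(path)
    unknown = [c for c in raw.columns if c not in INDIVIDUAL_COLUMNS]
    if unknown:
        logger.warning("%s: unknown columns %s carried through", path, unknown)
    missing = [c for c in ("date", "sd", "length_cm") if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: required columns missing: {missing}")

    rows, rejects = [], []
    first_data_line = n_meta + 2  # 1-based; header occupies one line
    for i, row in enumerate(raw.itertuples(index=False)):
        line_no = first_data_line + i
        r = dict(zip(raw.columns, row))
        parsed = _parse_date(r["date"])
        if parsed is None:
            rejects.append((line_no, f"invalid ISO date {r['date']!r}", r))
            continue
        date, year, month = parsed
        try:
            sd = int(r["sd"])
        except ValueError:
            rejects.append((line_no, f"invalid subdivision {r['sd']!r}", r))
            continue
        try:
            length = float(r["length_cm"])
        except ValueError:
            rejects.append((line_no, f"invalid length {r['length_cm']!r}", r))
            continue
        if not length > 0:
            rejects.append((line_no, f"non-positive length {length}", r))
            continue
        weight = np.nan
        w_raw = r.get("weight_g", "")
        if w_raw not in ("", "NA"):
            try:
                weight = float(w_raw)
            except ValueError:
                rejects.append((line_no, f"invalid weight {w_raw!r}", r))
                continue
        rows.append(
            {
                "date": date,
                "year": year,
                "month": month,
                "sd": sd,
                "gear": r.get("gear", "") or None,
                "length_cm": length,
                "weight_g": weight,
                "sex": r.get("sex", "") or "unknown",
                "maturity": r.get("maturity", "") or None,
            }
        )
    for line_no, reason, _ in rejects:
        logger.warning("%s line %d rejected: %s", path, line_no, reason)
    records = pd.DataFrame(
        rows,
        columns=["date", "year", "month", "sd", "gear", "length_cm", "weight_g", "sex", "maturity"],
    )
    return RecordSet(records, rejects)


def read_catch_records(path) -> RecordSet:
    """Read long-form haul length-frequency records (1-cm classes).

    Length classes are integer lower bounds of half-open [LC, LC+1) cm bins;
    counts must be non-negative integers."""
    raw, n_meta = _read_raw(path)
    missing = [c for c in CATCH_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: required columns missing: {missing}")
    rows, rejects = [], []
    first_data_line = n_meta + 2
    for i, row in enumerate(raw.itertuples(index=False)):
        line_no = first_data_line + i
        r = dict(zip(raw.columns, row))
        parsed = _parse_date(r["date"])
        if parsed is None:
            rejects.append((line_no, f"invalid ISO date {r['date']!r}", r))
            continue
        date, year, month = parsed
        try:
            sd = int(r["sd"])
            lc = int(r["length_class"])
            count = int(r["count"])
        except ValueError:
            rejects.append((line_no, "non-integer sd/length_class/count", r))
            continue
        if count < 0:
            rejects.append((line_no, f"negative count {count}", r))
            continue
        rows.append(
            {"haul": r["haul"], "date": date, "year": year, "month": month,
             "sd": sd, "length_class": lc, "count": count}
        )
    for line_no, reason, _ in rejects:
        logger.warning("%s line %d rejected: %s", path, line_no, reason)
    records = pd.DataFrame(
        rows, columns=["haul", "date", "year", "month", "sd", "length_class", "count"]
    )
    return RecordSet(records, rejects)


def read_series_table(path) -> SeriesTable:
    """Read the year-indexed assessment/forage table.

    Leading ``# key: value`` lines become metadata (units etc.); empty cells
    are explicit missing values."""
    metadata = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    if "year" not in df.columns:
        raise ValueError(f"{path}: required column 'year' missing")
    if df["year"].duplicated().any():
        dup = df.loc[df["year"].duplicated(), "year"].tolist()
        raise ValueError(f"{path}: duplicate years {dup}")
    df = df.set_index(df["year"].astype(int)).drop(columns="year").sort_index()
    df.index.name = "year"
    return SeriesTable(df, metadata)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(path, df: pd.DataFrame, metadata: dict | None = None, index: bool = False) -> None:
    """CSV writer used by all report outputs.

    Numeric text uses Python repr so a write -> read round trip reproduces
    every float exactly.  Optional metadata is emitted as ``# key: value``
    header lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index)


def write_annual_series(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write long-form annual indicators (year, indicator, value, n, flag)."""
    write_table(path, df, metadata)


def write_trend_report(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    write_table(path, df, metadata)


def write_correlation_report(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    write_table(path, df, metadata)


def write_series_table(path, series: SeriesTable) -> None:
    write_table(path, series.table.reset_index(), series.metadata)
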