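"""Reading prescribing extracts and aggregating them to count matrices.

The monthly prescribing files contain one row per (practice, presentation,
month) with an item count — the number of prescriptions dispensed.  This
module parses that long format, applies the study-window and chapter-scope
filters, collapses presentations to chemicals, and aggregates everything
to a per-level :class:`CountMatrix`: chemical numerators together with
subparagraph denominators for each organisation over the window.

Denominators are always *derived* by summing the in-scope chemical counts,
never read from input, so out-of-scope chapters cannot leak into them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import pandas as pd

from . import bnf
from .orgs import LEVELS, OrgHierarchy

log = logging.getLogger(__name__)

#: default column names of the NHSBSA English Prescribing Dataset dialect
DEFAULT_COLUMNS = {
    "practice_code": "PRACTICE_CODE",
    "bnf_code": "BNF_CODE",
    "items": "ITEMS",
    "month": "YEAR_MONTH",
}

RECORD_COLUMNS = ["practice_code", "bnf_code", "items", "month"]


class IngestError(ValueError):
    pass


def _first_of_month(d: date) -> date:
    return date(d.year, d.month, 1)


@dataclass(frozen=True)
class StudyWindow:
    """Half-open month window ``[start_month, end_month)``.

    Both bounds are first-of-month dates; a window "June 1 to December 1"
    therefore covers exactly the six months June-November.
    """

    start_month: date
    end_month: date

    def __post_init__(self) -> None:
        for d in (self.start_month, self.end_month):
            if d.day != 1:
                raise ValueError(f"window bound {d} is not a first-of-month date")
        if not self.start_month < self.end_month:
            raise ValueError(
                f"window start {self.start_month} must precede end {self.end_month}"
            )

    @classmethod
    def from_strings(cls, start: str, end: str) -> "StudyWindow":
        """Parse bounds given as ``YYYY-MM`` (or anything pandas parses)."""
        return cls(
            pd.Period(start, freq="M").start_time.date(),
            pd.Period(end, freq="M").start_time.date(),
        )

    @property
    def n_months(self) -> int:
        return (
            (self.end_month.year - self.start_month.year) * 12
            + self.end_month.month
            - self.start_month.month
        )


@dataclass
class ParseReport:
    """Bookkeeping from a CSV parse: totals and malformed-row counts."""

    n_rows: int = 0
    n_malformed: int = 0
    examples: list[str] | None = None


def _parse_month(values: pd.Series) -> pd.Series:
    """Parse YEAR_MONTH-style values (``202106``, ``2021-06``, dates)."""
    s = values.astype(str).str.strip()
    compact = s.str.fullmatch(r"\d{6}")
    out = pd.Series(pd.NaT, index=s.index, dtype="datetime64[ns]")
    if compact.any():
        out.loc[compact] = pd.to_datetime(
            s[compact], format="%Y%m", errors="coerce"
        )
    rest = ~compact
    if rest.any():
        parsed = pd.to_datetime(s[rest], errors="coerce", format="mixed")
        out.loc[rest] = parsed
    # months must be first-of-month dates
    out.loc[out.dt.day != 1] = pd.NaT
    return out


def _coerce_chunk(
    chunk: pd.DataFrame, cols: dict[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Coerce one raw chunk to record columns; return (frame, bad mask)."""
    missing = [c for c in cols.values() if c not in chunk.columns]
    if missing:
        raise IngestError(f"prescribing file is missing column(s): {missing}")
    df = pd.DataFrame(
        {
            "practice_code": chunk[cols["practice_code"]].astype(str).str.strip(),
            "bnf_code": chunk[cols["bnf_code"]].astype(str).str.strip(),
            "items": pd.to_numeric(
                chunk[cols["items"]].astype(str).str.replace(",", "", regex=False),
                errors="coerce",
            ),
            "month": _parse_month(chunk[cols["month"]]),
        }
    )
    bad = (
        df["items"].isna()
        | (df["items"] < 0)
        | (df["items"] % 1 != 0)
        | df["month"].isna()
        | (df["practice_code"] == "")
    )
    return df, bad


def normalize_records(
    raw: pd.DataFrame, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Coerce an in-memory raw extract (NHSBSA-style headers) to the tidy
    record layout; malformed rows are dropped with a warning."""
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})
    df, bad = _coerce_chunk(raw, cols)
    if bad.any():
        log.warning("%d malformed row(s) dropped during normalisation",
                    int(bad.sum()))
    df = df.loc[~bad]
    df["items"] = df["items"].astype(int)
    df["month"] = df["month"].dt.date
    return df.reset_index(drop=True)


def read_prescribing_csv(
    path,
    column_map: dict[str, str] | None = None,
    *,
    malformed_tolerance: float = 0.01,
    chunksize: int = 200_000,
) -> tuple[pd.DataFrame, ParseReport]:
    """Parse a prescribing CSV into a tidy record frame.

    Parameters
    ----------
    path
        CSV file (gzip accepted, inferred from the extension).
    column_map
        Overrides for :data:`DEFAULT_COLUMNS`, keyed by logical name
        (``practice_code``, ``bnf_code``, ``items``, ``month``).
    malformed_tolerance
        Maximum tolerated fraction of malformed rows (unparseable item
        counts or months, empty practice codes).  Malformed rows are
        counted and reported, and exceeding the tolerance is an error.

    Returns ``(records, report)`` where ``records`` has columns
    ``practice_code, bnf_code, items, month`` with ``items`` integer and
    ``month`` a first-of-month date.  Item counts with thousands
    separators ("10,437") are accepted.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})

    chunks: list[pd.DataFrame] = []
    report = ParseReport(examples=[])
    try:
        reader = pd.read_csv(
            path, dtype=str, chunksize=chunksize, compression="infer"
        )
    except pd.errors.EmptyDataError:
        log.warning("prescribing file %s is empty", path)
        return (
            pd.DataFrame(columns=RECORD_COLUMNS),
            report,
        )

    for chunk in reader:
        df, bad = _coerce_chunk(chunk, cols)
        report.n_rows += len(df)
        n_bad = int(bad.sum())
        if n_bad:
            report.n_malformed += n_bad
            for idx in df.index[bad][: max(0, 5 - len(report.examples))]:
                report.examples.append(str(chunk.loc[idx].to_dict()))
        df = df.loc[~bad]
        df["items"] = df["items"].astype(int)
        df["month"] = df["month"].dt.date
        chunks.append(df)

    if report.n_rows == 0:
        log.warning("prescribing file %s contains no data rows", path)
        return pd.DataFrame(columns=RECORD_COLUMNS), report
    if report.n_malformed > malformed_tolerance * report.n_rows:
        raise IngestError(
            f"{report.n_malformed}/{report.n_rows} malformed rows exceeds "
            f"tolerance {malformed_tolerance:.2%}; first examples: "
            f"{report.examples}"
        )
    if report.n_malformed:
        log.warning(
            "%d of %d rows malformed and skipped", report.n_malformed, report.n_rows
        )
    records = pd.concat(chunks, ignore_index=True)
    log.info("parsed %d prescribing records", len(records))
    return records, report


def filter_window(records: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Keep records with ``start_month <= month < end_month``."""
    keep = (records["month"] >= window.start_month) & (
        records["month"] < window.end_month
    )
    log.info(
        "window %s..%s kept %d of %d records",
        window.start_month, window.end_month, int(keep.sum()), len(records),
    )
    return records.loc[keep].reset_index(drop=True)


def filter_scope(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records whose BNF code is valid, >= 9 characters and in
    chapters 1-15; malformed and out-of-scope codes are counted and logged.
    """
    codes = records["bnf_code"].astype(str)
    wellformed = codes.str.fullmatch(r"\d{2}[0-9A-Z]{7,13}")
    chapter = pd.to_numeric(codes.str[:2], errors="coerce")
    keep = wellformed & chapter.between(1, 23) & chapter.isin(list(bnf.SCOPE_CHAPTERS))
    n_malformed = int((~wellformed).sum())
    if n_malformed:
        log.warning(
            "dropped %d record(s) with malformed/short BNF codes (e.g. %s)",
            n_malformed, codes[~wellformed].iloc[0],
        )
    n_out = int((wellformed & ~keep).sum())
    if n_out:
        log.info("dropped %d record(s) outside chapters 1-15", n_out)
    return records.loc[keep].reset_index(drop=True)


MATRIX_COLUMNS = [
    "org_code",
    "chemical_code",
    "chemical_items",
    "n_products",
    "subparagraph_code",
    "subparagraph_items",
]


@dataclass
class CountMatrix:
    """Chemical numerators + subparagraph denominators at one level.

    ``frame`` is tidy, one row per (organisation, chemical) with a
    positive observation, columns :data:`MATRIX_COLUMNS`.  Denominators
    repeat across the rows of a subparagraph.  Zero-count cells are
    absent, not stored as 0.  ``n_products`` counts the distinct
    presentation-level codes observed for the chemical in that
    organisation over the window.
    """

    level: str
    frame: pd.DataFrame
    window: StudyWindow | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        missing = [c for c in MATRIX_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"count matrix frame missing columns: {missing}")
        if (self.frame["chemical_items"] < 0).any():
            raise ValueError("negative chemical_items")

    def validate_derived(self) -> None:
        """Assert denominators equal the sum of member chemical counts.

        Holds by construction for matrices built by
        :func:`build_count_matrix`; matrices with externally supplied
        denominators (e.g. transcribed report tables listing only some
        chemicals) need not satisfy it.
        """
        sums = self.frame.groupby(["org_code", "subparagraph_code"])[
            "chemical_items"
        ].transform("sum")
        if not (sums == self.frame["subparagraph_items"]).all():
            raise AssertionError("subparagraph denominators are not the member sums")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, level: str, window: StudyWindow | None = None) -> "CountMatrix":
        frame = pd.read_csv(
            path,
            dtype={
                "org_code": str,
                "chemical_code": str,
                "subparagraph_code": str,
            },
        )
        return cls(level=level, frame=frame, window=window)


def build_count_matrix(
    records: pd.DataFrame,
    level: str,
    hierarchy: OrgHierarchy | None = None,
    window: StudyWindow | None = None,
) -> CountMatrix:
    """Aggregate scope-filtered records to a :class:`CountMatrix`.

    ``records`` must already be filtered (typical practices, chapters
    1-15, study window).  Presentation codes collapse to their chemical,
    months are summed, and counts are summed to ``level`` through the
    hierarchy; practices unmapped at that level are excluded and logged.
    Subparagraph denominators are recomputed from the chemical counts.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    df = records.copy()
    short = df["bnf_code"].str.len() < bnf.CHEMICAL_LEN
    if short.any():
        log.warning(
            "dropping %d record(s) with codes shorter than a chemical",
            int(short.sum()),
        )
        df = df.loc[~short]
    df["chemical_code"] = df["bnf_code"].str[: bnf.CHEMICAL_LEN]

    if level == "practice":
        df["org_code"] = df["practice_code"]
    else:
        if hierarchy is None:
            raise ValueError(f"level {level!r} requires an OrgHierarchy")
        parent_map = hierarchy.parents[level]
        df["org_code"] = df["practice_code"].map(parent_map)
        unmapped = df["org_code"].isna()
        if unmapped.any():
            log.warning(
                "excluding %d record(s) from practices with no %s parent",
                int(unmapped.sum()), level.upper(),
            )
            df = df.loc[~unmapped]

    grouped = (
        df.groupby(["org_code", "chemical_code"])
        .agg(chemical_items=("items", "sum"), n_products=("bnf_code", "nunique"))
        .reset_index()
    )
    grouped = grouped.loc[grouped["chemical_items"] > 0]
    grouped["subparagraph_code"] = grouped["chemical_code"].str[: bnf.SUBPARAGRAPH_LEN]
    denom = grouped.groupby(["org_code", "subparagraph_code"])[
        "chemical_items"
    ].transform("sum")
    grouped["subparagraph_items"] = denom
    grouped = (
        grouped.loc[:, MATRIX_COLUMNS]
        .sort_values(["org_code", "chemical_code"], kind="mergesort")
        .reset_index(drop=True)
    )
    log.info(
        "count matrix at %s level: %d organisations, %d chemicals, %d cells",
        level,
        grouped["org_code"].nunique(),
        grouped["chemical_code"].nunique(),
        len(grouped),
    )
    return CountMatrix(level=level, frame=grouped, window=window)
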