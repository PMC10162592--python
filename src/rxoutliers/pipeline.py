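"""End-to-end glue: records -> filters -> count matrices -> analysis.

One function, :func:`run_levels`, covers the whole path the CLI (and the
tests) use: apply the typicality, chapter-scope and window filters to a
record stream, roll counts up to each requested administrative level, and
run the outlier statistic at each.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import engine, ingest, orgs

log = logging.getLogger(__name__)


def prepare_records(
    records: pd.DataFrame,
    hierarchy: orgs.OrgHierarchy,
    window: ingest.StudyWindow | None = None,
) -> pd.DataFrame:
    """Apply the study filters: typical practices, chapters 1-15, window.

    ``records`` may be tidy (``practice_code/bnf_code/items/month``) or a
    raw extract with NHSBSA-style headers, which is normalised first.
    """
    if not set(ingest.RECORD_COLUMNS).issubset(records.columns):
        records = ingest.normalize_records(records)
    out = orgs.filter_typical(records, hierarchy)
    out = ingest.filter_scope(out)
    if window is not None:
        out = ingest.filter_window(out, window)
    return out


def run_levels(
    records: pd.DataFrame,
    hierarchy: orgs.OrgHierarchy,
    *,
    levels: tuple[str, ...] = orgs.LEVELS,
    window: ingest.StudyWindow | None = None,
    k: int = 10,
    suppress_threshold: int = 0,
    suppress_mode: str = "show",
    names: pd.DataFrame | None = None,
    ddof: int = 1,
) -> dict[str, engine.AnalysisResult]:
    """Filter once, then build and analyse a count matrix per level."""
    for level in levels:
        if level not in orgs.LEVELS:
            raise ValueError(f"unknown level {level!r}")
    filtered = prepare_records(records, hierarchy, window)
    results: dict[str, engine.AnalysisResult] = {}
    for level in levels:
        matrix = ingest.build_count_matrix(filtered, level, hierarchy, window)
        results[level] = engine.analyze(
            matrix,
            k=k,
            suppress_threshold=suppress_threshold,
            suppress_mode=suppress_mode,
            names=names,
            ddof=ddof,
        )
    return results
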