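"""The outlier statistic: ratios, peer mean/SD, z-scores, ranking.

For each organisation and chemical, the prescribing rate is the number of
items containing the chemical divided by the number of items containing
any chemical of the same BNF subparagraph (its drug class) — all statin
items as a proportion of all lipid-regulating-drug items, say.  The rate
is computed for every peer organisation at the same administrative level,
its cross-organisation mean and SD are taken, and each organisation's
rate is re-expressed as a z-score.  Ranking the z-scores within an
organisation surfaces its most unusual chemicals: the top of the list is
prescribed *more* than peers, the bottom *less*.

Degenerate-case policy (the statistic must stay finite):

* an organisation with a zero subparagraph denominator has no defined
  rate for that subparagraph's chemicals and is excluded from their peer
  distributions (0/0);
* an organisation with a positive denominator but no items of the
  chemical contributes rate 0;
* a chemical whose peer SD is 0 (every organisation identical) gives
  z = 0 everywhere — identical-to-peers is by definition not an outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import CountMatrix

log = logging.getLogger(__name__)

SUPPRESS_MODES = ("show", "redact", "drop")

#: columns of one report row, mirroring the dashboard tables
REPORT_COLUMNS = [
    "org_code",
    "side",
    "rank",
    "chemical_code",
    "chemical_name",
    "n_products",
    "chemical_items",
    "subparagraph_code",
    "subparagraph_name",
    "subparagraph_items",
    "ratio",
    "mean",
    "sd",
    "z",
    "suppressed",
]


def compute_ratios(matrix: CountMatrix) -> pd.DataFrame:
    """One row per (organisation, chemical) with a defined rate.

    The catalogue of chemicals is the union observed across organisations;
    every organisation whose subparagraph denominator is positive gets a
    row for each catalogue chemical of that subparagraph, with
    ``chemical_items`` (and hence ``ratio``) zero where it prescribed
    none.  Organisations with a zero denominator get no row.
    """
    frame = matrix.frame
    catalogue = frame[["chemical_code", "subparagraph_code"]].drop_duplicates()
    denoms = frame[["org_code", "subparagraph_code", "subparagraph_items"]].drop_duplicates()
    dupes = denoms.duplicated(subset=["org_code", "subparagraph_code"])
    if dupes.any():
        raise ValueError(
            "inconsistent subparagraph denominators within an organisation"
        )
    denoms = denoms.loc[denoms["subparagraph_items"] > 0]
    dense = denoms.merge(catalogue, on="subparagraph_code", how="inner")
    dense = dense.merge(
        frame[["org_code", "chemical_code", "chemical_items", "n_products"]],
        on=["org_code", "chemical_code"],
        how="left",
    )
    dense["chemical_items"] = dense["chemical_items"].fillna(0).astype(int)
    dense["n_products"] = dense["n_products"].fillna(0).astype(int)
    dense["ratio"] = dense["chemical_items"] / dense["subparagraph_items"]
    return (
        dense.loc[
            :,
            [
                "org_code",
                "chemical_code",
                "subparagraph_code",
                "chemical_items",
                "subparagraph_items",
                "n_products",
                "ratio",
            ],
        ]
        .sort_values(["org_code", "chemical_code"], kind="mergesort")
        .reset_index(drop=True)
    )


def fit_distribution(ratios: pd.DataFrame, *, ddof: int = 1) -> pd.DataFrame:
    """Per-chemical peer distribution: ``n_orgs``, ``mean``, ``sd``.

    ``sd`` is the sample SD (divisor n-1) by default; pass ``ddof=0`` for
    the population SD.  A chemical observed in a single organisation gets
    ``sd = 0``.
    """
    if ratios.empty:
        raise ValueError("cannot fit distributions to an empty ratio set")
    g = ratios.groupby("chemical_code")["ratio"]
    dist = pd.DataFrame(
        {
            "n_orgs": g.size(),
            "mean": g.mean(),
            "sd": g.std(ddof=ddof).fillna(0.0),
        }
    ).reset_index()
    return dist


def compute_zscores(ratios: pd.DataFrame, dists: pd.DataFrame) -> pd.DataFrame:
    """Join peer distributions onto the ratio rows and add ``z``.

    ``z = (ratio - mean) / sd`` where ``sd > 0``; otherwise 0.  Every
    ratio's chemical must have a distribution.
    """
    scores = ratios.merge(dists, on="chemical_code", how="left", validate="m:1")
    if scores["mean"].isna().any():
        missing = scores.loc[scores["mean"].isna(), "chemical_code"].unique()
        raise ValueError(f"no distribution for chemical(s): {missing[:5].tolist()}")
    sd = scores["sd"].to_numpy()
    dev = (scores["ratio"] - scores["mean"]).to_numpy()
    scores["z"] = np.where(sd > 0, dev / np.where(sd > 0, sd, 1.0), 0.0)
    return scores


def rank_within_org(scores: pd.DataFrame, org_code: str) -> pd.DataFrame:
    """An organisation's chemicals ordered from most-above to most-below
    peers: z descending, ties broken by |ratio - mean| descending then
    chemical code ascending, so the order is reproducible run-to-run.
    """
    if org_code not in set(scores["org_code"]):
        raise KeyError(f"no scores for organisation {org_code!r}")
    sub = scores.loc[scores["org_code"] == org_code].copy()
    sub["_dev"] = (sub["ratio"] - sub["mean"]).abs()
    sub = sub.sort_values(
        ["z", "_dev", "chemical_code"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_dev")
    return sub.reset_index(drop=True)


def select_extremes(ranked: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k strictly positive and bottom-k strictly negative z rows.

    ``higher`` keeps ranking order (largest z first); ``lower`` is ordered
    most-negative first.  Shorter lists are returned when fewer chemicals
    qualify; the zero boundary is never crossed to pad a list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    higher = ranked.loc[ranked["z"] > 0].head(k).reset_index(drop=True)
    lower = ranked.loc[ranked["z"] < 0].iloc[::-1].head(k).reset_index(drop=True)
    return higher, lower


def suppress_low_counts(
    rows: pd.DataFrame, threshold: int = 5, mode: str = "show"
) -> pd.DataFrame:
    """Flag (and per ``mode`` remove) rows with small item counts.

    Rows with ``chemical_items <= threshold`` are flagged ``suppressed``.
    ``mode='show'`` keeps them visible, ``'redact'`` keeps them but marks
    them for display-time masking, ``'drop'`` removes them entirely (so a
    subsequent extreme-selection re-ranks without them).  Small counts can
    be rogue one-off prescriptions or genuinely important rare signals;
    the choice is the user's.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in SUPPRESS_MODES:
        raise ValueError(f"mode must be one of {SUPPRESS_MODES}")
    out = rows.copy()
    out["suppressed"] = out["chemical_items"] <= threshold if threshold else False
    if mode == "drop":
        out = out.loc[~out["suppressed"]].reset_index(drop=True)
    return out


@dataclass
class LevelSummary:
    """Distribution of extreme z-scores across one administrative level.

    Pools every organisation's selected "higher than most" (positive z)
    and "lower than most" (negative z) chemicals; ``higher``/``lower``
    hold max-or-min, median, Q1, Q3 and IQR = Q3 - Q1 of the pooled
    z-scores, or ``None`` when a side is empty.  Quantiles use linear
    interpolation between order statistics (recorded in
    ``quantile_rule``).
    """

    level: str
    n_orgs: int
    n_unique_outlier_chemicals: int
    higher: dict[str, float] | None
    lower: dict[str, float] | None
    quantile_rule: str = "linear"

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n_orgs": self.n_orgs,
            "n_unique_outlier_chemicals": self.n_unique_outlier_chemicals,
            "higher": self.higher,
            "lower": self.lower,
            "quantile_rule": self.quantile_rule,
        }


def _side_stats(z: np.ndarray, extreme: str) -> dict[str, float]:
    q1, med, q3 = np.quantile(z, [0.25, 0.5, 0.75], method="linear")
    stats = {
        extreme: float(z.max() if extreme == "max" else z.min()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }
    return stats


def summarize_level(extremes: pd.DataFrame, level: str) -> LevelSummary:
    """Summarise all organisations' extreme rows at one level.

    ``extremes`` must carry ``org_code``, ``chemical_code``, ``z`` and a
    ``side`` column in {"higher", "lower"} — i.e. the concatenation of
    every organisation's top-k and bottom-k rows.
    """
    if extremes.empty:
        return LevelSummary(level, 0, 0, None, None)
    hi = extremes.loc[extremes["side"] == "higher", "z"].to_numpy(float)
    lo = extremes.loc[extremes["side"] == "lower", "z"].to_numpy(float)
    return LevelSummary(
        level=level,
        n_orgs=int(extremes["org_code"].nunique()),
        n_unique_outlier_chemicals=int(extremes["chemical_code"].nunique()),
        higher=_side_stats(hi, "max") if hi.size else None,
        lower=_side_stats(lo, "min") if lo.size else None,
    )


@dataclass
class AnalysisResult:
    """Everything the reporting layer needs for one level."""

    level: str
    scores: pd.DataFrame  # dense (org, chemical) rows with ratio/mean/sd/z
    extremes: pd.DataFrame  # REPORT_COLUMNS rows for every organisation
    summary: LevelSummary
    k: int = 10
    suppress_threshold: int = 0
    suppress_mode: str = "show"


def _attach_names(df: pd.DataFrame, names: pd.DataFrame | None) -> pd.DataFrame:
    out = df.copy()
    if names is None:
        out["chemical_name"] = out["chemical_code"]
        out["subparagraph_name"] = out["subparagraph_code"]
        return out
    out = out.merge(
        names[["chemical_code", "chemical_name"]], on="chemical_code", how="left"
    )
    sub_names = names[["subparagraph_code", "subparagraph_name"]].drop_duplicates(
        "subparagraph_code"
    )
    out = out.merge(sub_names, on="subparagraph_code", how="left")
    out["chemical_name"] = out["chemical_name"].fillna(out["chemical_code"])
    out["subparagraph_name"] = out["subparagraph_name"].fillna(
        out["subparagraph_code"]
    )
    return out


def analyze(
    matrix: CountMatrix,
    *,
    k: int = 10,
    suppress_threshold: int = 0,
    suppress_mode: str = "show",
    names: pd.DataFrame | None = None,
    ddof: int = 1,
) -> AnalysisResult:
    """Run the full statistic on one count matrix.

    Computes rates, peer distributions and z-scores; applies low-count
    suppression; ranks within each organisation and selects the top-k
    "higher than most" and bottom-k "lower than most" chemicals; and
    summarises the level.  ``names`` is an optional chemical/subparagraph
    name lookup (codes are used where names are missing).
    """
    ratios = compute_ratios(matrix)
    dists = fit_distribution(ratios, ddof=ddof)
    scores = compute_zscores(ratios, dists)
    scored = suppress_low_counts(scores, suppress_threshold, suppress_mode)

    pieces: list[pd.DataFrame] = []
    for org in sorted(scored["org_code"].unique()):
        ranked = rank_within_org(scored, org)
        higher, lower = select_extremes(ranked, k)
        for side, side_rows in (("higher", higher), ("lower", lower)):
            if side_rows.empty:
                continue
            rows = side_rows.copy()
            rows["side"] = side
            rows["rank"] = np.arange(1, len(rows) + 1)
            pieces.append(rows)

    if pieces:
        extremes = pd.concat(pieces, ignore_index=True)
        extremes = _attach_names(extremes, names)
        extremes = extremes.loc[:, REPORT_COLUMNS]
    else:
        extremes = pd.DataFrame(columns=REPORT_COLUMNS)

    summary = summarize_level(extremes, matrix.level)
    log.info(
        "level %s: %d organisations, %d unique outlier chemicals",
        matrix.level, summary.n_orgs, summary.n_unique_outlier_chemicals,
    )
    return AnalysisResult(
        level=matrix.level,
        scores=scores,
        extremes=extremes,
        summary=summary,
        k=k,
        suppress_threshold=suppress_threshold,
        suppress_mode=suppress_mode,
    )
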