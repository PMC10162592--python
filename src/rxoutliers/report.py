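"""Per-organisation dashboards: report tables and density sparklines.

Each organisation's dashboard shows its top-k "higher than most" and
bottom-k "lower than most" chemicals in the published column order
(chemical + product count, chemical items, subparagraph, subparagraph
items, ratio, mean, SD, z score), plus, per chemical, a small density
plot of the rate across all peer organisations (blue curve) with the
organisation's own rate marked by a vertical red line.

Densities are Gaussian kernel estimates with Scott's rule bandwidth
``h = sigma_hat * n**(-1/5)`` (sigma_hat = sample SD).  Dashboards are
self-contained static HTML with inline SVG — identical inputs always
produce byte-identical output.
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .engine import SUPPRESS_MODES, AnalysisResult

log = logging.getLogger(__name__)

GRID_POINTS = 200
GRID_PAD_BANDWIDTHS = 3.0


class DegenerateDistributionError(ValueError):
    """All peer rates identical: no density curve can be drawn."""


@dataclass
class DensityCurve:
    """A kernel density estimate of one chemical's rate across peers."""

    grid: np.ndarray
    density: np.ndarray
    org_ratio: float
    bandwidth: float
    degenerate: bool = False

    def integral(self) -> float:
        if self.degenerate:
            return float("nan")
        return float(np.trapezoid(self.density, self.grid))


def compute_density(ratios, org_ratio: float) -> DensityCurve:
    """Gaussian KDE of peer rates with Scott's-rule bandwidth.

    ``ratios`` are the rates of all organisations for one chemical (at
    least 2 values).  When every value is identical the distribution is
    degenerate — there is nothing to smooth — and a marker curve is
    returned instead (``degenerate=True``, empty grid).

    The grid has 200 evenly spaced points spanning
    ``[min - 3h, max + 3h]`` so the curve visibly decays to ~0.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 peer rates for a density")
    if np.ptp(x) == 0:
        return DensityCurve(
            grid=np.array([]),
            density=np.array([]),
            org_ratio=float(org_ratio),
            bandwidth=0.0,
            degenerate=True,
        )
    kde = gaussian_kde(x, bw_method="scott")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(
        x.min() - GRID_PAD_BANDWIDTHS * h,
        x.max() + GRID_PAD_BANDWIDTHS * h,
        GRID_POINTS,
    )
    return DensityCurve(
        grid=grid,
        density=kde(grid),
        org_ratio=float(org_ratio),
        bandwidth=h,
    )


@dataclass
class ReportConfig:
    """Rendering options for dashboards."""

    k: int = 10
    suppress_threshold: int = 5
    suppress_mode: str = "show"
    level: str = "practice"
    decimals: int = 2  # ratio/mean/SD/z rounding in tables

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.suppress_mode not in SUPPRESS_MODES:
            raise ValueError(f"suppress_mode must be one of {SUPPRESS_MODES}")


# ---------------------------------------------------------------------------
# HTML rendering (plain string templating; no external template engine)
# ---------------------------------------------------------------------------

_TABLE_HEADERS = [
    "BNF chemical (number of products)",
    "Chemical items, n",
    "BNF subparagraph",
    "Subparagraph items, n",
    "Ratio",
    "Mean",
    "SD",
    "z score",
    "Distribution",
]

_CSS = """
body { font-family: sans-serif; margin: 2em; color: #222; }
h1 { font-size: 1.4em; } h2 { font-size: 1.1em; margin-top: 2em; }
table { border-collapse: collapse; width: 100%; }
th, td { border: 1px solid #ccc; padding: 4px 8px; text-align: left; font-size: 0.9em; }
th { background: #f0f0f0; }
td.num { text-align: right; }
tr.suppressed td { color: #999; font-style: italic; }
.empty { color: #777; font-style: italic; }
.degenerate { color: #777; font-size: 0.8em; }
"""

_TOGGLE_JS = """
function toggleSuppressed(box) {
  document.querySelectorAll('tr.suppressed').forEach(function (tr) {
    tr.style.display = box.checked ? 'none' : '';
  });
}
"""


def _svg_sparkline(curve: DensityCurve, width: int = 220, height: int = 48) -> str:
    """Inline SVG: blue density curve, red vertical line at the
    organisation's own rate."""
    if curve.degenerate:
        return (
            '<span class="degenerate">all organisations identical '
            f"(rate {curve.org_ratio:.4g})</span>"
        )
    gx, gy = curve.grid, curve.density
    x0, x1 = float(gx[0]), float(gx[-1])
    ymax = float(gy.max()) or 1.0
    xs = (gx - x0) / (x1 - x0) * (width - 2) + 1
    ys = height - 2 - gy / ymax * (height - 4)
    pts = " ".join(f"{x:.2f},{y:.2f}" for x, y in zip(xs, ys))
    rx = (min(max(curve.org_ratio, x0), x1) - x0) / (x1 - x0) * (width - 2) + 1
    return (
        f'<svg width="{width}" height="{height}" role="img">'
        f'<polyline points="{pts}" fill="none" stroke="#1f77b4" stroke-width="1"/>'
        f'<line x1="{rx:.2f}" y1="2" x2="{rx:.2f}" y2="{height - 2}" '
        'stroke="#d62728" stroke-width="1.5"/></svg>'
    )


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def _render_row(row: pd.Series, curve: DensityCurve | None, config: ReportConfig) -> str:
    suppressed = bool(row.get("suppressed", False))
    redact = suppressed and config.suppress_mode == "redact"
    chem_items = (
        f"&le;{config.suppress_threshold}" if redact else f"{int(row['chemical_items'])}"
    )
    cells = [
        f"{html.escape(str(row['chemical_name']))} ({int(row['n_products'])})",
        chem_items,
        html.escape(str(row["subparagraph_name"])),
        f"{int(row['subparagraph_items'])}",
        _fmt(row["ratio"], config.decimals),
        _fmt(row["mean"], config.decimals),
        _fmt(row["sd"], config.decimals),
        _fmt(row["z"], config.decimals),
        _svg_sparkline(curve) if curve is not None else "",
    ]
    cls = ' class="suppressed"' if suppressed else ""
    tds = "".join(
        f'<td class="num">{c}</td>' if i in (1, 3, 4, 5, 6, 7) else f"<td>{c}</td>"
        for i, c in enumerate(cells)
    )
    return f"<tr{cls}>{tds}</tr>"


def _render_table(
    rows: pd.DataFrame,
    curves: dict[str, DensityCurve],
    config: ReportConfig,
    empty_text: str,
) -> str:
    head = "".join(f"<th>{h}</th>" for h in _TABLE_HEADERS)
    if rows.empty:
        body = (
            f'<tr><td class="empty" colspan="{len(_TABLE_HEADERS)}">'
            f"{empty_text}</td></tr>"
        )
    else:
        body = "".join(
            _render_row(row, curves.get(row["chemical_code"]), config)
            for _, row in rows.iterrows()
        )
    return f"<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>"


def render_dashboard(
    org_code: str,
    org_name: str,
    higher: pd.DataFrame,
    lower: pd.DataFrame,
    curves: dict[str, DensityCurve],
    config: ReportConfig,
) -> str:
    """Render one organisation's dashboard as self-contained HTML.

    ``higher``/``lower`` are report-row frames (see
    :data:`rxoutliers.engine.REPORT_COLUMNS`); ``curves`` maps chemical
    codes to peer-distribution curves.  Output is deterministic: no
    timestamps, no random identifiers.
    """
    toggle = ""
    if config.suppress_threshold > 0 and config.suppress_mode != "drop":
        toggle = (
            '<label><input type="checkbox" onchange="toggleSuppressed(this)"> '
            f"Hide counts of {config.suppress_threshold} or less</label>"
        )
    title = html.escape(f"{org_name} ({org_code}) — prescribing outliers")
    parts = [
        "<!DOCTYPE html>",
        '<html lang="en"><head><meta charset="utf-8">',
        f"<title>{title}</title>",
        f"<style>{_CSS}</style>",
        f"<script>{_TOGGLE_JS}</script>",
        "</head><body>",
        f"<h1>{title}</h1>",
        "<p>Each chemical's prescribing rate (items as a proportion of its "
        "BNF subparagraph's items) is compared across all peer "
        f"organisations at {html.escape(config.level)} level and expressed "
        "as a z score; the blue curve shows the peer distribution, the red "
        "line this organisation.</p>",
        toggle,
        f"<h2>Prescribing higher than most (top {config.k})</h2>",
        _render_table(higher, curves, config, "no chemicals above the peer mean"),
        f"<h2>Prescribing lower than most (bottom {config.k})</h2>",
        _render_table(lower, curves, config, "no chemicals below the peer mean"),
        "</body></html>",
    ]
    return "\n".join(parts)


def dashboard_for_org(
    result: AnalysisResult,
    org_code: str,
    config: ReportConfig,
    org_name: str | None = None,
) -> str:
    """Build the dashboard for one organisation from an analysis result,
    computing a peer density curve for each of its extreme chemicals."""
    rows = result.extremes.loc[result.extremes["org_code"] == org_code]
    higher = rows.loc[rows["side"] == "higher"]
    lower = rows.loc[rows["side"] == "lower"]
    curves: dict[str, DensityCurve] = {}
    for _, row in rows.iterrows():
        chem = row["chemical_code"]
        peers = result.scores.loc[
            result.scores["chemical_code"] == chem, "ratio"
        ].to_numpy()
        if peers.size >= 2:
            curves[chem] = compute_density(peers, row["ratio"])
    return render_dashboard(
        org_code, org_name or org_code, higher, lower, curves, config
    )
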