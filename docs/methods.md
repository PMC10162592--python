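# Methods

## The statistic and its assumptions

For each organisation `i` and chemical `c`, the prescribing rate is the
chemical's item count divided by the item count of its BNF subparagraph
(drug class) in the same organisation over the study window:
`r_ic = items_ic / items_is(c)`. The rates for one chemical across all
peer organisations at the same administrative level are summarised by
their mean and standard deviation and each organisation's rate is
re-expressed as a z-score; ranking z within an organisation orders its
chemicals from most-unusually-high to most-unusually-low. The top-k and
bottom-k (default 10) per organisation are reported.

Interpreting z-scores as "number of SDs from the mean" implicitly leans
on approximate normality of the cross-organisation rate distribution.
That is plausible when item counts are large (CCG/STP aggregation) and
fails gracefully when they are not: with rare chemicals or tiny
denominators the SD can be near zero and z-scores become huge. Those
extreme values are not errors — they flag genuinely rare prescribing —
but they motivate the low-count suppression option below. The method is
a *ranking*, not a hypothesis test; no multiple-testing correction is
applied, and output should be read as a candidate list for expert
review, since legitimate reasons for outlying prescribing (local
formularies, shared-care arrangements, stable elderly patients) are
common.

## Degenerate inputs and numerical choices

* **Zero denominator** (organisation has no items in a class): the rate
  0/0 is undefined, so the organisation is excluded from that chemical's
  peer distribution and ranking.
* **Zero numerator with positive denominator** contributes rate 0 — the
  organisation demonstrably chooses other drugs in the class.
* **SD = 0** (every peer identical): z = 0 for all. An organisation
  identical to its peers is by definition not an outlier, and this
  avoids infinities.
* **SD divisor**: sample SD (n−1) by default, switchable to population
  SD (`ddof=0`). The standardisation invariant tested (z mean 0, sample
  SD 1 per chemical) is stated for the default.
* **Tie-breaks in ranking**: descending z, then descending
  |rate − mean|, then ascending chemical code — so reports are
  byte-reproducible run to run.
* **Quantiles** in level summaries use linear interpolation between
  order statistics (numpy's default), recorded as `quantile_rule` in the
  summary output.
* **Rounding**: dashboards show ratio/mean/SD/z to 2 decimals; the
  machine-readable CSV/JSON keeps full precision. Rounded values can
  therefore not be used to recompute each other (a z of 10.2 can coexist
  with a printed mean and SD of 0).

## Scope and filters

Analysis is restricted to BNF chapters 1–15 (inclusive), the chapters
with a genuine chemical/subparagraph structure; later chapters
(dressings, appliances) are excluded before denominators are formed, and
denominators are always recomputed from in-scope chemical counts so
out-of-scope items can never leak in. The study window is half-open
(`[start, end)` on first-of-month dates), so "June to December"
covers exactly six months, June–November; items are summed over the
window months. Only practices flagged "typical" in the organisation
register are analysed (prisons and specialist clinics distort peer
comparison); the flag is taken as input, not derived. Codes shorter
than 9 characters carry no chemical identity and are rejected rather
than padded — the extract's occasional 8-character grouping codes are
logged and dropped.

Counts roll up a snapshot-static four-level hierarchy (practice → PCN →
CCG → STP). Practices missing a parent at some level stay in lower-level
analyses and are excluded, with a warning, from that level's roll-up;
records from practices absent from the register are dropped with a
warning rather than failing the run.

## Suppression of small counts

Rows with `chemical_items ≤ threshold` (default 5) can be shown,
redacted (count masked as "≤5" in dashboards) or dropped before
extreme-selection. Small counts cut both ways: they may be rogue
single prescriptions or important rare signals (the worked-example CCG's
gluten-free items were exactly such a find), so the mode is a user
choice, not a fixed policy.

## Density plots

Each reported chemical gets a Gaussian kernel density estimate of the
peer rates, computed by `scipy.stats.gaussian_kde` with Scott's rule
(`h = σ̂ · n^(−1/5)`, σ̂ the sample SD), evaluated on 200 evenly spaced
points spanning the data range padded by 3 bandwidths so the curve
visibly decays. The trapezoidal integral of each non-degenerate curve is
within 2% of 1 (property-tested). When all peer rates are identical the
distribution is a point mass and a textual marker is rendered instead of
a curve. Dashboards are static self-contained HTML with hand-built
inline SVG and no timestamps, making byte-determinism testable; the
small-count toggle is client-side JavaScript.

## Synthetic data generator

The generator emulates the *shape* of the public prescribing extract,
not its pharmacology. Per practice, subparagraph and month it draws a
proportion vector from `Dirichlet(concentration × baseline)`, applies
any planted multiplicative odds shifts (renormalising the rest of the
vector), draws a total volume from a rounded log-normal, and allocates
items multinomially among the class's chemicals, splitting each
chemical's items across two presentation-level codes. This
Dirichlet-multinomial structure is the minimal model producing
compositional counts with tunable between-organisation dispersion — the
structure the z-score statistic assumes — and is deliberately not
claimed to be the data-generating process of real prescribing.

Defaults, chosen once as the package's study conditions:

| parameter | default | why |
|---|---|---|
| tree shape | 2 STP × 2 CCG × 3 PCN × 5 practices (60) | smallest tree exercising all four levels with meaningful peer groups |
| catalogue | 10 subparagraphs × 4 chemicals | enough chemicals for a full top/bottom-10 per practice |
| baseline proportions | geometric (0.53, 0.27, 0.13, 0.07) | dominant first-line drug plus alternatives, as in real classes |
| concentration | 50 | between-practice rate SD of a few percentage points, a realistic spread |
| volume log-mean/SD | 5.0 / 0.5 | median ≈ 150 items/practice/class/month with a heavy right tail, mimicking skewed practice sizes |
| months | 6 from 2021-06 | the standard half-year analysis window |
| planted magnitude | 3.0 (odds) | shifts the default chemical's true rate ≈ 0.27 → 0.52, roughly 8–9 cross-practice SDs of the aggregated rate — comfortably above the ≥ 5 SD regime where recovery should be near-certain |
| atypical practices | 2 | exercises the typicality filter |

What passing tests on synthetic data do **not** show: robustness to the
real extract's non-Dirichlet dispersion (formulary-driven bimodality,
spatial correlation between neighbouring practices), seasonality,
mid-window organisational changes, or name/code quirks of the live BNF
tables beyond those modelled. The published-dashboard fixture mitigates
the last point for the ratio arithmetic: the 20 printed
chemical/subparagraph count pairs of a real CCG's report are carried as
a fixture (with synthetic stand-in codes, since the published table
prints names only) and the pipeline must reproduce every printed ratio.

All randomness flows from a single integer seed through numpy's PCG64
generator, so outputs are byte-identical across runs and platforms.

## Problem sizes

Tests and the acceptance script run the default 60-practice
configuration (about 29,000 extract rows per replicate; 20 replicates
for the recovery rate) and 5×5 matrices for oracle equivalence — sizes
chosen so the full statistical behaviour is exercised while the whole
suite stays fast on a single CPU. National scale (≈ 6,500 practices,
2,369 chemicals) changes only runtime, not code paths: the engine is
vectorised pandas/numpy throughout and the ingest layer parses in
chunks.

## Known limitations

* Normality, as discussed above; no robust (median/MAD) variant is
  provided.
* The level summary pools each organisation's selected extremes, so its
  quartiles depend on k.
* The hierarchy is static; analyses spanning an NHS reorganisation need
  two runs with two registers.
* Cost, quantity and dose-level fields of the extract are out of scope;
  the statistic is item-count-based only.
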