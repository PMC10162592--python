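# rxoutliers

Hypothesis-free detection of unusual prescribing behaviour in English
primary-care dispensing data.

NHS medicines-optimisation teams traditionally monitor prescribing
against prospectively chosen indicators. `rxoutliers` takes the opposite,
hypothesis-free route: it scans *every* drug chemical and asks, for each
organisation, "is this organisation's use of this chemical unusual
relative to its peers?" — then ranks the answers so the most unusual
chemicals surface first. It is aimed at pharmacists, commissioners and
analysts working with the openly published practice-level prescribing
extracts, as a way to generate candidate lists for local review rather
than definitive judgements.

## The statistic

Prescribing items are classified by a pseudo-BNF (British National
Formulary) hierarchy: the first 9 characters of a code identify the
*chemical* (active ingredient), the first 7 its *subparagraph* (drug
class, e.g. quinolones). For organisation *i* and chemical *c* with
class *s(c)*, the prescribing rate over the study window is the
compositional ratio

```
r_ic = items_ic / items_is(c)          (chemical items / subparagraph items)
```

i.e. the chemical's share of its own drug class in that organisation.
Across all peer organisations at one administrative level the mean μ_c
and standard deviation σ_c of r_·c are taken, and each organisation's
rate is standardised:

```
z_ic = (r_ic − μ_c) / σ_c
```

Ranking z_i· within an organisation puts the chemicals it prescribes
most unusually *often* at the top ("higher than most") and most
unusually *rarely* at the bottom ("lower than most"). The analysis is
repeated at four NHS administrative levels — practice, primary care
network (PCN), clinical commissioning group (CCG) and sustainability and
transformation partnership (STP) — since each retains prescribing
decision-making power. Degenerate cases are kept finite: a zero class
denominator contributes no rate, a zero numerator contributes rate 0,
and σ_c = 0 gives z = 0.

The package also ships:

* an ingest layer for the NHSBSA extract dialect (scope filter to BNF
  chapters 1–15, "typical practice" filter, half-open month window,
  roll-up through the organisation hierarchy);
* optional suppression of small counts (≤ 5 items by default — show,
  redact or drop);
* per-organisation static HTML dashboards with the two ranked tables and
  a Gaussian kernel density of each chemical's peer rates (Scott's-rule
  bandwidth `h = σ̂ · n^(−1/5)`), the organisation's own rate marked in
  red;
* a seeded Dirichlet-multinomial synthetic-data generator with planted
  anomalous prescribers, so the whole pipeline is testable end-to-end
  without any download.

## Worked example

Simulate a small national-style extract (60 typical practices in
2 STPs × 2 CCGs × 3 PCNs; 10 drug classes × 4 chemicals; June–November
2021) in which practice `P00001`'s odds of prescribing chemical
`0100010B0` are tripled, then run the practice-level analysis:

```python
from rxoutliers import simulate, orgs, pipeline

cfg = simulate.default_config(seed=42, planted=(simulate.example_planted(),))
ds = simulate.generate(cfg)
hierarchy = orgs.load_hierarchy(ds.register, ds.mapping)
res = pipeline.run_levels(
    ds.records, hierarchy, levels=("practice",), window=cfg.window,
    k=10, names=simulate.name_lookup(cfg),
)["practice"]

extremes = res.extremes
print(extremes[(extremes.org_code == "P00001") & (extremes.side == "higher")]
      .head(3)[["rank", "chemical_name", "chemical_items",
                "subparagraph_items", "ratio", "mean", "sd", "z"]]
      .round(3).to_string(index=False))
```

```
 rank     chemical_name  chemical_items  subparagraph_items  ratio  mean    sd     z
    1 Chemical 0100010B             489                 934  0.524 0.269 0.045 5.711
    2 Chemical 0302010B             261                 792  0.330 0.269 0.031 1.926
    3 Chemical 0908010C             263                1435  0.183 0.135 0.027 1.803
```

The planted chemical ranks first: `P00001` devoted 52.4% of its class-
`0100010` items to it, while the average peer practice devoted 26.9%
(SD 4.5 percentage points) — 5.7 standard deviations above the mean.
The next rows are ordinary sampling noise (z ≈ 1.9). `res.summary`
summarises the whole level (60 practices, 40 distinct outlier chemicals,
pooled higher-side median z ≈ 1.12, maximum 5.71).

The same pipeline is exposed as a CLI:

```bash
rxoutliers simulate --seed 42 --out-dir simulated/
rxoutliers run    --prescribing simulated/prescribing.csv \
                  --register simulated/register.csv --mapping simulated/mapping.csv \
                  --names simulated/names.csv --level all \
                  --start-month 2021-06 --end-month 2021-12 --out-dir results/
rxoutliers report --prescribing simulated/prescribing.csv \
                  --register simulated/register.csv --mapping simulated/mapping.csv \
                  --level ccg --top-k 10 --out-dir results/
```

`run` writes `outliers_<level>.csv` / `.json` (full precision) and
`summary_<level>.json`; `report` additionally writes one
`dashboards/<org_code>.html` per organisation, with ratio/mean/SD/z
rounded to 2 decimals as in the tables above.

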