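# btrefuge

Population-genetic modelling and monitoring analysis of **dominant Bt
resistance under refuge management**, built around the cotton bollworm
(*Helicoverpa armigera*) and Cry1Ac cotton in northern China.

Refuges of non-Bt host plants are the backbone of resistance management for
Bt crops, but classical theory supports them mainly for *rare, recessive*
resistance.  The T92C substitution in *HaTSPAN1* is neither: it confers
dominant resistance (h = 0.79) and reached frequency 0.10 by 2016.  This
package provides the quantitative machinery to study whether — and when —
large refuges can halt such an allele:

* `btrefuge.popgen` — deterministic one-locus, two-allele selection
  recursion with habitat-weighted fitness, three generations per year:
  `p' = p(p·w_rr + q·w_rs) / (p²w_rr + 2pq·w_rs + q²w_ss)` with
  `w_g = R·w_g_refuge + (1−R)·w_g_Bt`, plus the balanced-polymorphism
  equilibrium `p* = (w_rs−w_ss)/(2w_rs−w_ss−w_rr)` for overdominant
  marginal fitness.
* `btrefuge.refuge` — the *effective refuge percentage*: non-Bt host-plant
  hectares weighted by moth production relative to non-Bt cotton, as a
  share of total selection habitat; plus the fitted northern-China yearly
  trend (2.85 %/year).
* `btrefuge.amplicon` — allele-frequency estimation from pooled,
  dual-tagged amplicon sequencing: pair merging, exact-tag demultiplexing,
  the `1/(2n)` rare-sequence error filter, per-site frequencies, and
  bootstrap annual means.
* `btrefuge.stats` — monitoring statistics: continuity-corrected Wilson
  intervals, genotype-tally allele frequencies, diagnostic-dose bioassay
  summaries, log-scale trend/correlation tests, pooled-variance t-tests.
* `btrefuge.synth` — synthetic moth pools, reads, bioassays, and crop
  tables with known ground truth, so every stage is testable end to end.
* `btrefuge.cli` / `btrefuge.pipeline` — a `btrefuge` command with
  subcommands `simulate`, `refuge`, `freq`, `stats`, `synth`, `all`.

It is aimed at resistance-management modellers and molecular monitoring
groups who want a small, fully tested reference implementation rather than
a spreadsheet.

## Worked example

Simulate the three refuge hypotheses — no refuge, a 10% non-Bt-cotton-only
refuge, and the full effective-refuge series — from the observed 2006
starting frequency of 0.001:

```python
from btrefuge import ScenarioConfig, RefugeSeries, run_scenarios
from btrefuge.refuge import refuge_series_from_regression

years = range(2006, 2021)
scenarios = {
    "no_refuge": ScenarioConfig(2006, 2020, RefugeSeries.constant(0.0, years)),
    "cotton_only": ScenarioConfig(2006, 2020, RefugeSeries.constant(0.10, years)),
    "effective_refuge": ScenarioConfig(
        2006, 2020, refuge_series_from_regression(years=years)
    ),
}
table = run_scenarios(scenarios)
print(table.pivot(index="year", columns="scenario", values="p").round(4)
      .loc[[2006, 2007, 2009, 2012, 2016, 2020]])
```

```
scenario  cotton_only  effective_refuge  no_refuge
year
2006           0.0010            0.0010     0.0010
2007           0.0768            0.0024     0.7947
2009           0.8129            0.0109     0.9651
2012           0.9595            0.0538     0.9961
2016           0.9916            0.1379     0.9998
2020           0.9980            0.1447     1.0000
```

Reading the table: with no refuge the dominant allele sweeps past 0.75
within a single season (0.79 entering 2007); a cotton-only refuge of 10%
delays the sweep by only two years (past 0.75 in 2009); the observed
effective refuge — rising from ~53% to 90% of selection habitat — holds the
allele near 0.14 through 2020, close to the balanced-polymorphism
equilibrium (~0.11 at 90% refuge) where selection for resistance on Bt
cotton is offset by the recessive fitness cost in refuges.

The same analysis, plus a synthetic monitoring dataset (pooled amplicon
reads, bioassays, crop tables) and its full re-analysis, runs from the
shell:

```bash
btrefuge all --out results/demo --seed 1
```

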