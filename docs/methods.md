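# Methods

## The biological problem

Transgenic cotton expressing the Bt toxin Cry1Ac selects strongly for
resistance in the cotton bollworm *Helicoverpa armigera*.  In northern China
a single substitution (T92C) in the tetraspanin gene *HaTSPAN1* confers
*dominant* resistance, which standard refuge theory — built for rare,
recessive resistance — is not expected to contain.  The package asks, and
lets a user re-ask quantitatively: can a large enough refuge of non-Bt host
plants halt a dominant resistance allele that is already common?  It couples
a deterministic population-genetic simulator to (i) an accounting of the
"effective refuge" provided by non-Bt cotton and other host crops, and
(ii) a pooled-amplicon monitoring pipeline that estimates the allele's
frequency from field samples, so predicted and observed trajectories can be
compared on the same axis.

## Selection model

One locus, two alleles (`r` resistant, `s` susceptible), a single panmictic
population, discrete generations, no mutation, migration or drift.  Each
generation: Hardy-Weinberg genotype formation, viability selection, random
mating of survivors.  With genotype fitness `w = (w_ss, w_rs, w_rr)` and
allele frequency `p` (`q = 1 - p`):

```
p' = p (p w_rr + q w_rs) / (p² w_rr + 2pq w_rs + q² w_ss)
```

Habitat structure enters only through the marginal fitness.  Larvae develop
on Bt cotton with probability `1 - R` and on refuge plants with probability
`R` (the effective refuge fraction for that year), and adults mate at random
across habitats, so

```
w_g = R · w_g_refuge + (1 - R) · w_g_Bt        for g in {ss, rs, rr}.
```

Three generations per year are simulated (the bollworm completes three
generations on cotton in northern China); the same yearly `R` applies to all
three.

### Fitness parameterisation

All fitness is relative to susceptible homozygotes on non-Bt hosts
(`w_ss_refuge = 1`).  Defaults are the empirical values for the T92C /
Cry1Ac system:

| parameter | default | meaning |
|---|---|---|
| `h` | 0.79 | dominance of resistance on Bt cotton (0 recessive, 1 dominant) |
| `cost` | 0.36 | recessive fitness cost: `w_rr_refuge = 1 - cost`, `w_rs_refuge = 1` |
| `incomplete_resistance` | 0.49 | fitness of `rr` on Bt cotton |
| `w_ss_bt` | 0 | susceptibles on Bt cotton (diagnostic-dose mortality is 100%) |
| `p0` | 0.001 | observed 2006 allele frequency, the anchor for all scenarios |

Heterozygote fitness on Bt cotton interpolates with the dominance
parameter: `w_rs_bt = w_ss_bt + h (w_rr_bt - w_ss_bt)`.

Two readings of "incomplete resistance" are implemented, selected by
`incomplete_resistance_mode`:

* **absolute** (default): `w_rr_bt = 0.49` is the measured fitness of
  resistant homozygotes on Bt cotton itself.  This is the reading the
  empirical numbers support directly — resistant insects score 0.49 on Bt
  cotton versus 0.64 (`1 - cost`) on non-Bt hosts — and it is internally
  consistent with the halt of the sweep near frequency 0.10–0.15 at high
  refuge: with `R = 0.9` the marginal fitnesses are overdominant
  (`w = (0.900, 0.939, 0.625)`) with balanced-polymorphism equilibrium
  `p* ≈ 0.110`.
* **ratio**: `w_rr_bt = 0.49 · (1 - cost) = 0.3136`, incomplete resistance
  read as a Bt/non-Bt fitness ratio.  Under this reading the same
  equilibrium sits at `p* ≈ 0.072`, too low to be compatible with a
  projected 2020 frequency of 0.13; it is retained for sensitivity
  analyses.

### Reporting convention

Field samples are collected during the growing season, so the frequency
reported for calendar year `y` is the frequency **after** year `y`'s three
generations of selection under that year's refuge fraction `R(y)`; the
series is anchored at the observed starting value in the first year
(`p(2006) = 0.001`, no selection applied to the anchor year).  The
alternative convention (report entering the year, select with the departure
year's refuge) shifts the trajectory by one year's selection; the
convention used here is the one under which the effective-refuge scenario
reproduces the reference projection for 2020 (see below).  A
`RefugeSeries` must therefore cover `start_year + 1 .. end_year`.

### Overdominance check

`overdominance_equilibrium(w)` returns the classical balanced-polymorphism
frequency `p* = (w_rs - w_ss) / (2 w_rs - w_ss - w_rr)` whenever
`w_rs > max(w_ss, w_rr)`, and `None` otherwise.  It is verification
plumbing: property tests iterate the recursion 20 000 generations and
require convergence to `p*` within 1e-6.

## Effective refuge percentage

For one year's crop records (area, Bt share, and moth production per
hectare relative to non-Bt cotton):

```
ERP = 100 · Σ_i a_i (1 - b_i) w_i / [ Σ_i a_i (1 - b_i) w_i + Σ_i a_i b_i ]
```

Bt hectares enter the denominator hectare-for-hectare — they are selection
habitat, not moth production — and insecticide sprays are deliberately not
used to adjust the refuge (a conservative choice: sprays are heavier on
cotton than on refuge crops).  The packaged yearly series for the
"non-Bt cotton plus other host plants" scenario evaluates the fitted
northern-China trend `ERP(year) = 2.85·year - 5667` (percent), clamped to
[0, 100] because 2006 and 2020 extrapolate beyond the fitted 2007–2019
range.  The trend reproduces the reported period means (66% for 2007–2015,
85% for 2016–2019) to well under 1 percentage point.

## Pooled-amplicon frequency estimation

Each site's sample is a pool of one hind leg per moth (`n` legs).  Site
identity is encoded by a 6-bp tag on each primer, so the amplicon is
216 bp: forward tag + 204-bp genomic fragment + reverse complement of the
reverse tag, sequenced as 150-bp paired ends (84-bp overlap).

1. **Merge** — R1 and the reverse complement of R2 must agree on the whole
   overlap; any disagreement rejects the pair.  Full overlap-alignment
   merging is out of scope; the known amplicon length fixes the overlap.
2. **Demultiplex** — exact match of both tags (no mismatch tolerance);
   unmatched pairs are rejected.  Assigned + rejected = input, always.
3. **Filter** — identical 204-bp sequences are collapsed; a distinct
   sequence is removed when its frequency among the site's reads is
   strictly below `1/(2n)`, the smallest allele frequency a pool of `n`
   diploid individuals can contain.  The filter is idempotent.
4. **Classify** — surviving reads are scored by the base at the variant
   offset: resistant, susceptible, or other.  Reads with a non-canonical
   base stay in the denominator (they survived filtering); the site
   frequency is `r / (r + s + other)`.

The variant offset is a required input; synthetic references place it at
position 101 (0-based, mid-fragment) and record it in the FASTA header.

Annual means are unweighted across sites, with a percentile bootstrap CI
(default 1000 replicates) resampling sites with replacement;
square-root-of-legs weighting is available and agrees closely.  For four or
fewer sites, tests compare the bootstrap bounds to the exhaustively
enumerated resampling distribution.

## Monitoring statistics

* **Wilson interval with continuity correction** (Newcombe's closed form)
  for proportions from individual genotyping; lower bound 0 at 0 successes,
  upper bound 1 at `n` successes.  Verified against numerical inversion of
  the continuity-corrected score test.
* **Genotype tally frequency** `(2·rr + rs) / 2N` for individually
  genotyped resistant moths.
* **Bioassay resistance percentage**: unweighted across-site mean of
  percent survival at the diagnostic dose, site-level bootstrap CI (the CI
  method for bioassay means is a package choice, consistent with the
  pooled-frequency procedure).
* **Trend and association tests**: OLS of log10(response) on year, and
  Pearson correlation of log10 pairs, with two-sided p from the
  t-distribution on `n - 2` df.  Base 10 is used for all log transforms.
* **Two-sample t-test**: pooled variance, `df = n_a + n_b - 2`, two-sided
  (Welch is deliberately not used; pooled df matches the reference
  analyses, e.g. df = 11 for groups of 9 and 4 years).

## Synthetic data generator

The generator emulates the monitoring study's inputs with known ground
truth: Hardy-Weinberg moth pools (multinomial), pooled amplicon libraries
(reads drawn from the pool's allele copies, binomially by default or by
deterministic proportional allocation so error-free recovery is exact when
the depth divides evenly), per-base substitution errors, diagnostic-dose
bioassays (genotype-specific survival, susceptibles dying with certainty by
default), and crop tables, including one constructed to reproduce a target
refuge series exactly.

Deliberate simplifications: substitution errors are applied at the template
(amplicon) level so both reads of a pair see them consistently — they model
PCR/template errors, while read-discordant sequencing errors would simply
be rejected at the merge step; no indels, chimeras, quality-score
structure, or coverage bias.  Passing recovery tests therefore demonstrates
correctness of the estimation logic under idealised error structure, not
robustness to every artefact of real libraries.  Default study conditions
for recovery tests: pools of 100 legs, read depth 10 000, per-base error
rate 0.001, true frequencies spanning 0.01–0.5.

## Numerical choices and degenerate inputs

* The recursion clips `p'` into [0, 1] only to absorb last-bit rounding;
  zero mean fitness raises an explicit extinction error rather than NaN.
* Equal fitness leaves `p` unchanged to machine precision (the recursion
  cancels algebraically).
* Bootstrap quantiles use linear interpolation (`numpy.quantile` default);
  a single site collapses the interval to the point estimate.
* Constant response in the log-linear regression returns slope 0 and
  R² = 0 (no explained variance) instead of NaN.
* All generators accept integer seeds (or a `numpy` Generator); the
  pipeline derives child seeds from one master `SeedSequence`, so full runs
  are byte-identical under a fixed seed and config.

## Problem sizes

The packaged default analysis simulates 2006–2020 (42 generations per
scenario), surveys 4 sites in each of 4 years at depth 1500, and uses 1000
bootstrap replicates; recovery tests use single pools at depth 10 000.
These sizes give sub-minute full runs while keeping Monte-Carlo error well
inside the tested tolerances.

## Known limitations

* Single locus: other resistance alleles are ignored, which can overstate
  the focal allele's selective advantage.
* One refuge fraction per year; within-year crop phenology and
  habitat-specific population regulation (soft selection) are not modelled.
* The hypothesis that only non-Bt cotton acts as refuge ships without an
  authoritative yearly series (the underlying areas are not in the main
  text); it is exercised with configurable constant fractions in
  (0, 0.15].
* The exact per-read inclusion rules of the original NGS toolchain
  (quality trimming, mapping) are replaced by the simplified merge /
  exact-tag / identity-collapse pipeline described above.
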