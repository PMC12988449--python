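# Methods

## The measurement problem

A burden-of-disease release is a snapshot of a model: each release
re-estimates attributable deaths and DALYs for the whole historical period,
so successive releases publish competing values for the same
(risk factor, metric, calendar year) cell. Differences between a cell's
original estimate and its later revisions cannot reflect changes in
population health — the year is fixed — so revision spread isolates the
effect of methodology and input-data changes. `revstab` treats the published
numbers as the data and quantifies that spread; it does not attempt to
re-run or approximate the underlying estimation machinery.

Two panel constructions separate the questions being asked:

* **Index-year series** (one per risk × metric): each release's estimate for
  its own final estimation year. Spread here mixes genuine temporal change
  with revision effects; it answers "how much did the headline number move
  from release to release".
* **Matched-year panels** (one per risk × metric × calendar year, requiring
  at least two releases): all values published for that same year. The only
  varying factor is the release, so spread here is pure revision
  instability.

All panel statistics are complete-case: a release that did not publish a
cell is simply absent, the panel's `n` is recorded, and panels with fewer
than two values are skipped with a ledger entry rather than contributing
zeros. No interpolation or imputation happens anywhere in the pipeline.

## Instability statistics

For a panel of values $v_1,\dots,v_n$ ($n \ge 2$, all $\ge 0$):

* **Range-to-mean** $\mathrm{R{:}M} = (\max v - \min v)/\bar v$. The
  denominator is the arithmetic mean by default; a median denominator is
  selectable (`rm_denominator="median"`) but gives materially different
  values and is not the convention the flag cutoffs were designed for. An
  all-zero panel returns 0 (zero range).
* **Coefficient of variation** $\mathrm{CV} = s/\bar v$ with the sample
  standard deviation ($n-1$ denominator) by default. With the tiny panels
  involved ($n \le 8$) the $n$ vs $n-1$ choice is material, so it is an
  explicit `cv_ddof` parameter; $n-1$ is the conventional sample default.
* **Flags**: R:M > 1 "concern", > 1.5 "extreme"; CV > 0.2 "high", > 0.5
  "very high". All comparisons are strict — a panel at exactly the cutoff is
  not flagged. The cutoffs are configuration values, not constants.

Both statistics are scale invariant (property-tested), so risks whose
burdens differ by orders of magnitude are comparable; values are stored in
raw persons / person-years and any scaling to thousands or millions happens
only in report rendering. Neither statistic uses the published uncertainty
intervals — they deliberately measure point-estimate movement only.

Numerical choices: an exactly constant panel returns CV = 0 by
short-circuit, because the two-pass standard deviation otherwise leaks
rounding error of order $10^{-16}\bar v$ into what should be a flagless
zero. Group-level proportions reported as text use round-half-up integer
percents (so 17 of 34 renders as 50%, 145 of 675 as 21%).

## Interval consistency

For each ordered pair of releases (reference, comparison), every cell at the
finest available stratification (sex × location × cause group × year) where
the reference published a 95% uncertainty interval and the comparison
published a point estimate is classified below / within / above the
reference interval. Containment is closed — a point exactly on a bound
counts as within — because "outside" is read strictly and ties have measure
zero in real data. Cells missing either side are ledgered, never counted, so
per-risk denominators are data-driven. Coverage summaries report per-risk
and aggregate counts ordered by the proportion outside.

## Ranking churn

Within each release, a user-chosen comparable risk set is ranked by
attributable burden (rank 1 = largest; ties broken lexicographically by
canonical name for determinism). Releases in which any member of the set
lacks a value are dropped from the ranking and ledgered, rather than ranked
on a shrunken set — rank numbers must mean the same thing in every column.
Per-risk trajectories report the rank path, its range, and the longest run
of consecutive releases with unchanged rank (computed by run-length
encoding, oracle-tested). The rank set is an explicit parameter because
league tables are only meaningful within a comparable stratum (e.g. ranking
dietary risks against each other, not level-2 aggregates against level-3
components).

## The synthetic revision process

The generator exists to make the pipeline testable end-to-end with known
truth; it emulates the *structure* of a release history, not the magnitudes
of any real risk. On the log scale:

$$\log V_{riy} = \log A_r + g_r (y - y_0) + \delta_{ri} + \varepsilon_{riy}$$

* $A_r$: baseline burden at the first estimation year, drawn log-uniformly
  over $[10^4, 10^7]$ deaths — a few orders of magnitude, like a real risk
  portfolio. DALYs are a fixed ×25 of the deaths scale so both metrics share
  a risk's revision history.
* $g_r$: true per-year log trend, uniform on ±3%/yr — modest genuine change
  over a 13-year window.
* $\delta_{ri} \sim N(0, \tau^2)$: the per-release systematic shift standing
  in for methodology and data changes; **independent** per release by
  default, or a **random walk** (cumulative increments) to emulate drifting
  methodology. Shared between deaths and DALYs of a risk.
* $\varepsilon_{riy} \sim N(0, \sigma^2)$: iid per-record noise.
* Published intervals are multiplicative:
  $[V e^{-z s_{ui}}, V e^{+z s_{ui}}]$ with $z = 1.96$.

Defaults mirror the study conditions the pipeline targets: 66 risks, eight
releases (2010, 2013, 2015, 2016, 2017, 2019, 2021, 2023), each release
estimating every index year up to its own — so matched-year panels have
$n = 2\ldots8$ exactly as the real release grid produces. $\tau = 0.3$,
$\sigma = 0.1$ (revision shifts dominating record noise, consistent with the
fold-change-sized revisions that motivate the analysis) and $s_{ui} = 0.2$
(intervals of roughly ±30%, a plausible published width) are the stated
calibration conditions; all are constructor arguments. A single seeded
generator draws in a documented order (baselines, growth rates, shift
matrix, record noise over the sorted record grid), so one seed yields a
bit-identical table.

Because everything is lognormal, two calibration targets are exact:

* matched-year values in independent mode are iid lognormal with log-SD
  $\sqrt{\tau^2+\sigma^2}$, so their population CV is
  $\sqrt{e^{\tau^2+\sigma^2} - 1}$ (0.3243 at the defaults);
* the log-difference of two releases' values for one cell has SD
  $\sqrt{2(\tau^2+\sigma^2)}$, so the probability a later point falls inside
  an earlier interval is $2\Phi\!\big(z s_{ui}/\sqrt{2(\tau^2+\sigma^2)}\big) - 1$;
  setting $s_{ui} = \sqrt{2(\tau^2+\sigma^2)}$ makes the interval exactly
  nominal (95%).

The empirical median matched-year CV sits a few hundredths *below* the
population value (≈0.28 vs 0.324 at the defaults) because the sample SD is
downward-biased at $n \le 8$ and the CV sampling distribution is
right-skewed; the calibration test's ±0.05 band accommodates exactly this
known bias, and the monotonicity of median CV in $\tau$ is tested
separately. Interval-coverage calibration is checked to within 2 percentage
points over ≥ 5000 comparisons.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: correlated revisions across risks (real
methodology changes move whole risk families together), name/definition
changes across releases (the synthetic map is the identity), sex/region
stratification of the interval analysis (the generator emits the global
stratum; the comparison machinery itself is stratification-agnostic and
tested on hand-built stratified fixtures), non-lognormal heavy-tailed
revisions, and any resemblance to actual per-risk magnitudes.

## Design choices where the design was open

* **Fail-fast ingest**: rows failing validation abort the read with
  row-numbered diagnostics rather than being dropped with a warning — a
  single validated entry point beats silently shrinking data. Records whose
  interval fails to bracket the point are the one exception: they are kept
  and flagged (`ui_violation`), since the published numbers are the data.
* **Harmonization resolution order**: an (raw name, release) entry beats an
  (raw name, any) entry, so a name that changed meaning between releases can
  be split. Unmapped names go to a report and are excluded, not fatal —
  mirroring the practice of dropping non-comparable risks. The shipped
  exclusion list (child-abuse/bullying items, the combined alcohol-and-drug
  aggregate) is an approximation and fully configurable.
* **Model/Results shape**: the orchestration layer follows the
  statsmodels pattern (model object from data + configuration, `fit()`
  returning a results object with `summary()` and exporters) because the
  pipeline is "configure, run once, inspect many tables"; the per-stage
  functions remain importable for piecemeal use.
* **Percent formatting** is round-half-up (not banker's rounding) to match
  the reporting convention the flag tables use.
* **Manifest determinism**: the run manifest records config echo, input and
  output SHA-256 checksums and library versions, and deliberately excludes
  timestamps so byte-identical reruns are verifiable.

## Problem sizes

The test and calibration runs use 120–500 synthetic risks over the full
eight-release grid (36 year-cells per risk and metric, i.e. up to 36 000
records per run) — large enough that median-CV and coverage estimates are
stable to well inside their tolerance bands, as chosen sizes for routine
re-runs of the suite.

## Known limitations

* R:M and CV are undefined for $n < 2$ and noisy at $n = 2\!-\!3$; early
  releases contribute few overlapping years, so their matched-year panels
  are short and complete-case `n` must be read alongside every statistic.
* The interval-consistency analysis takes published intervals at face value;
  it cannot distinguish intervals that were too narrow from revisions that
  were unusually large.
* Rank trajectories require the full risk set in every ranked release;
  sparse early releases can leave few rankable columns.
* The pipeline measures instability; it attributes nothing. Separating
  genuine epidemiological change from methodological artefact requires
  information outside the published numbers.
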