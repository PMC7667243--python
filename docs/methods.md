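# Methods

This note documents the generative model behind the synthetic samples, the
mathematics of the two gating routes, the comparison statistics, the
numerical conventions, and the limits of what the package's passing tests
can and cannot show about real cytometry data.

## The scientific setting

A PID-screening tube measures three scatter parameters and eleven surface
markers per cell.  Two analysis routes produce, for every sample, absolute
counts (cells/µL) for ~20 lymphocyte populations: expert manual gating (a
fixed Boolean hierarchy over marker thresholds) and automated gating &
identification (cluster all events, classify clusters against a
healthy-donor database, alarm anything unusual).  The quantities that matter
downstream are *paired*: per population, the percent difference between the
two routes, whether it exceeds the 20 % equivalence limit used in accredited
laboratories, and whether the two counts would be *interpreted* differently
against age-matched p5–p95 reference intervals.  Real patient files are not
distributable, so the package evaluates both routes on synthetic samples
whose per-event ground truth is known exactly.

## Generative model

**Bands.** Marker expression within a population is modelled as one of four
bands on the asinh-transformed scale (`asinh(raw / cofactor)`, cofactor
150): neg, lo, pos, hi with means 0 / 1.5 / 3.0 / 4.5 and a common SD of
0.25 (all configurable via `BandModel`).  Raw intensities are
`sinh(t)·cofactor` clipped to the instrument range [0, 262144].  The default
SD puts the midpoint gating cuts exactly 3 σ from the adjacent band means,
so per-marker band leakage is ~0.135 % per side.  This choice is deliberate:
a terminal population's gate path stacks ~8–10 strict band predicates, and
the stacked leakage must stay well below the 5 % recovery tolerance the test
suite demands of both routes.  (At SD 0.35 the stacked leakage alone is
~10–13 %, which no threshold placement can repair; weak-separation regimes
are therefore studied by *raising* `BandModel.sd`, never by new code paths.)

**Populations.** The registry (`data/populations.yaml`) defines 17 terminal
lymphoid populations (4 B-cell, 12 T-cell, NK) under the
lymphocytes → B/T/NK → CD4/CD8 → maturation-subset hierarchy, each with a
band level per marker and a `fraction_range` — the interval from which a
sample's true fraction of WBC is drawn uniformly.  The shipped fractions are
order-of-magnitude-plausible healthy-adult values (e.g. CD4⁺ naive 6–10 % of
WBC, terminal-effector subsets well below 1 %); they are simulator inputs,
not claims about any cohort.  Markers are generated independently per
channel; the real tube multiplexes some markers per detector, but the gating
logic operates at marker level, so the simulator does too, and CD16&CD56 is
the single combined channel it is on the physical tube.

**Nuisance events.** Debris sits at low scatter; a single `other_leukocyte`
class (CD45⁺ but not CD45^hi, high scatter) stands in for all non-lymphoid
leukocytes; doublets are two random lymphoid singlets with summed areas and
a pulse height at the singlet level, so their FSC-H/FSC-A ratio is ≈ 0.5.
Default rates: 2 % doublets, 3 % debris.

**Aberrations.** An `AberrationSpec` adds a shift (transformed units) to one
population × marker mean.  Three presets emulate reported patient patterns:
`dim_cd4` (−3.0 on CD4 of every CD4⁺ subset — a staining failure that makes
CD4⁺ cells look CD4⁻CD8⁻TCRγδ⁻), `igd_dim` (+1.5 on IgD of switched memory
B cells/plasma cells), `dim_tcrgd` (−3.0 on TCRγδ of the γδ compartment).
An optional `cd27_smear` widens the CD27 band of the two memory-B
populations that are discriminated by CD27 alone — the hardest
manual/automated disagreement mode.

**Seeding.** All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); cohorts derive per-sample seeds from a master
seed; there is no global RNG state anywhere.

## Manual gating

Pre-gating removes doublets (keep events whose FSC-H/FSC-A ratio lies within
25 % of the sample's median ratio), debris (below the FSC-A floor of the
lymphocyte rectangle) and non-lymphoid events (outside the FSC-A/SSC-A
rectangle or not CD45^hi).  The gate tree (`data/gate_tree.yaml`) then
assigns every lymphocyte-gated event top-down by band predicates.  The
printed superscript notation maps to bands as: `-` = neg, `lo` = lo,
`+` = pos∨hi, `hi` = hi, `- to lo` = neg∨lo, `lo to +` = lo∨pos∨hi,
`- to +` = neg∨lo∨pos.  Sibling predicates are proved mutually exclusive by
brute-force enumeration over all band assignments at tree-load time; events
matching no sibling stay in that parent's explicit `unclassified` remainder
rather than being forced into the nearest gate — in practice that call is
made by a human, which this engine refuses to simulate silently.  The WBC
denominator for relative counts is every non-doublet, non-debris event, and
absolute counts use the dual-platform formula `%WBC × WBC/µL / 100`.

The observer model jitters every marker cut point by an independent
N(0, jitter_sd²) draw (default 0.1 transformed units ≈ 40 % of a band SD).
Jitter 0 reproduces the canonical threshold set bit-exactly.  Observer
variability is modelled *only* as threshold jitter: the mechanism behind
real analyst disagreement is unobservable, so the model reproduces its
outcome (a nonzero manual CV) with the simplest auditable cause.

## Automated gating

The commercial tools this route emulates do not publish their internals, so
the module fixes a transparent surrogate and claims nothing about agreement
with any proprietary implementation:

1. **Feature space** — the 11 transformed markers plus FSC-A and SSC-A
   divided by 10⁴ (which puts a typical lymphocyte scatter SD on the scale
   of a fluorescence band SD), 13 dimensions.
2. **Over-clustering** — seeded k-means with `k = max(50, ⌈√N⌉)`;
   full-batch while `N·k ≤ 5·10⁶`, mini-batch (batch 4096) above, both
   deterministic for a fixed seed.
3. **Classification** — per-population mean and covariance pooled from ≥10
   labelled healthy samples, covariance shrunk as
   `(1−λ)S + λ·diag(S)` with λ = 0.1 (small populations are otherwise
   ill-conditioned).  A cluster centroid joins its nearest population by
   squared Mahalanobis distance iff that distance is below the
   χ²(df = 13) quantile at 0.999; near-exact ties (≤ 10⁻¹²) break toward
   the larger training count, then lexicographically.
4. **Checks** — unassigned clusters carry their three nearest candidates and
   are excluded from counts until an expert resolves them
   (`resolve_checks`); auto-assigned clusters are immutable unless an
   explicit override flag is set.
5. **Report** — counts, range status against the age-matched p5–p95
   interval, and a remark for every out-of-range population.  The CD4⁺CD8⁺
   double-positive subset is not in the database by default (mirroring
   observed automated behaviour); its events therefore surface as checks,
   which dominates the ~0.5 % checks fraction on healthy samples.  The
   checks fraction is reported against both denominators (lymphoid events
   and all events) since either convention is defensible.

**Why over-clustering matters.** With k forced down to the number of true
populations, k-means can prefer merging two 6 σ-separated minor subsets
(the CD8 terminal-effector pair, ~550 events) over leaving a 40× larger
population unsplit — cluster-level classification then misassigns the merged
cluster.  At the default `k ≈ √N` the clusters are effectively pure and
cluster-level labels agree with per-event nearest-Mahalanobis classification
for ≥ 99 % of events (the residual disagreement is almost entirely the
double-positive subset, by design).

## Comparison statistics

`pct_diff = (MG − AG&I)/MG × 100`, signed and manual-referenced; both
counts 0 gives 0, MG = 0 with AG&I > 0 is undefined and treated as
non-equivalent.  Equivalence is the strict `|pct_diff| < 20`.  Clinical
relevance is evaluated only for observations failing the 20 % criterion and
means the two counts fall in different categories of the inclusive
[p5, p95] interval (any mismatch counts, including below-vs-above).
Reference ranges are empirical 5th/95th percentiles (linear interpolation)
of ground-truth absolute counts from a simulated healthy cohort — real
published reference values are proprietary to their cohort, so ranges are
always derived, never shipped as constants.  Age bins default to
0–2 / 2–5 / 5–10 / 10–18 / 18–65 / 65+ years (a package convention; the
shipped simulated cohorts are adults, so the harness derives a single
18–65 bin).

CVs use the sample SD (n−1) over 5 replicates, with CV undefined (and
excluded from medians) when the replicate mean is 0; identical replicates
short-circuit to exactly 0 to avoid floating-point mean round-off.  The
intra-observer automated replicates rerun a fully deterministic pipeline, so
their CV is exactly 0; inter-observer automated replicates vary only the
clustering seed.  Spearman uses average ranks on ties and is undefined for a
constant vector; the variance-ratio F test is two-sided with
(n−1, n−1)-style degrees of freedom and p = 1 flagged when both variances
vanish; the Yates χ² is `Σ(|O−E|−0.5)²/E` on 2×2 tables; Bonferroni rejects
at the strict `p < α/m` and reports `min(1, m·p)`.

## Problem sizes

The suite and acceptance script run at desk scale, chosen so every check
finishes on one CPU while keeping the Monte-Carlo error far below the
tolerances being asserted: database training 10 × 30 000 events, reference
ranges 250 × 15 000, healthy evaluation 26 × 100 000, reproducibility
12 samples × 5 replicates at 100 000 events, aberration replicates at
25 000–30 000 events, and one 10⁶-event sample for the recovery check
(ground-truth recovery within 5 % for every population ≥ 0.5 % of WBC, both
routes; measured ≈ 1 %).

## Numerical conventions and edge cases

- Scatter channels are never transformed; the QC windows (median FSC-A in
  (50 000, 60 000), median SSC-A in (11 000, 13 000) over lymphocyte-gated
  events) are strict at both ends, matching their printed `>`/`<` form.
- Raw intensities clip to [0, 262144]; the neg band (mean 0) therefore has
  half its mass exactly at 0 raw — medians and band classification are
  unaffected, and tests that reason about clipped means use the closed-form
  truncated-normal expectation.
- Events with zero FSC-A are excluded by the singlet gate and tallied.
- `derive_reference_ranges` refuses empty or < 20-sample age bins and
  degenerate (p5 = p95) intervals.
- The leakage guard in `run_study` rejects any evaluation sample whose id
  appears in the database's training cohort.

## What passing tests do and do not show

The simulator draws each marker independently within a population from a
single Gaussian band, with no spillover/compensation artefacts, no
acquisition drift, no maturation continua (CD27 heterogeneity is only
approximated by the optional smear), and doublets formed from exactly two
cells.  Under these conditions both routes recover ground truth to ~1 % and
disagree on essentially nothing — which is the point: the harness verifies
the *machinery* (partitions exact, formulas correct, alarms fire where they
must, automated reproducibility strictly better than jittered manual
gating), not the field performance of either route.  Real samples with
continuous maturation, correlated markers and instrument drift will produce
larger manual/automated differences than any number reported here; the
package's claims are about the implemented algorithms on the stated
generative model.  The automated route is a surrogate whose agreement with
any commercial implementation is unknown and not claimed.
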