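# pidotkit

Manual versus automated gating of PIDOT-like flow cytometry data, on
synthetic samples with known ground truth.

Clinical immunophenotyping laboratories screening for primary
immunodeficiencies (PID) enumerate ~20 blood lymphocyte populations from a
single 14-parameter tube (FSC-A, FSC-H, SSC-A plus CD45, CD3, CD19,
CD16&CD56, CD4, CD8, TCRγδ, CD27, CD45RA, IgM, IgD).  Two analysis routes
exist: expert **manual gating** (MG), a hierarchical Boolean strategy over
2-D dot plots, and **automated gating & identification** (AG&I), which
clusters all events and classifies the clusters against a database built
from healthy donors.  This package implements both routes transparently and
the statistics used to compare them — so that the comparison itself
(equivalence rates, clinical-relevance rates, observer reproducibility,
alarm behaviour under staining aberrations) can be studied end to end on
simulated data where the true answer is known.

## What is inside

- **`panel_io`** — panel definition, the `EventMatrix` container, FCS
  3.0/3.1 reading and FCS 3.1 writing, a CSV dialect, `asinh(x/cofactor)`
  fluorescence transform, and lymphocyte scatter QC (median FSC-A in
  (50 000, 60 000) and median SSC-A in (11 000, 13 000)).
- **`synthetic_cohort`** — generative templates for 22 populations plus
  debris/doublet/non-lymphoid nuisance events; marker expression as
  neg/lo/pos/hi bands on the asinh scale; patient-like aberrations (dim CD4,
  dim IgD on switched memory B cells, dim TCRγδ); age-stratified empirical
  p5–p95 reference ranges from simulated healthy cohorts; an observer model
  (seeded jitter on gating thresholds).
- **`manual_gating`** — deterministic gate tree implementing the standard
  hierarchy: singlet gate (FSC-H/FSC-A), debris/lymphocyte gate
  (scatter + CD45^hi), then B/T/NK lineages and maturation subsets by band
  predicates; absolute counts via the dual-platform formula
  `count/µL = %WBC × WBC/µL / 100`.
- **`autogate`** — AG&I surrogate: seeded k-means over-clustering
  (`k = max(50, ⌈√N⌉)`), cluster-centroid classification against a
  per-population mean/covariance database by squared Mahalanobis distance
  with a χ²(df = 13) cutoff, unassignable clusters surfaced as *checks* with
  candidate populations, and a report flagging every count outside the
  age-matched p5–p95 range (*remarks*).
- **`comparison_stats`** — the paired comparison.  For each population,
  `pct_diff = (MG − AG&I)/MG × 100`; the routes are *equivalent* when
  `|pct_diff| < 20 %`, and a non-equivalent observation is *clinically
  relevant* when the two counts fall in different reference-interval
  categories.  Reproducibility (CV% over 5 replicates), Spearman rank
  correlation, variance-ratio F test, Yates-corrected χ², Bonferroni.

## Worked example

```python
import pidotkit as pk

registry = pk.load_registry()
band = pk.BandModel()

# one synthetic healthy sample with ground-truth labels
meta = pk.SampleMeta("HD1", age_years=35.0, wbc_per_ul=6000.0)
events, labels = pk.simulate_sample(registry, band, meta, 100_000, seed=1)
tev = pk.transform_fluorescence(events)

# manual gating
counts = pk.population_counts(pk.manual_gate(tev))
print(counts.loc["b_cells"])

# automated gating against a database built from 10 training samples
ages, wbcs = pk.hd_cohort_metadata(10, seed=7)
train = pk.simulate_cohort(registry, band, 10, ages, wbcs, seed=42,
                           n_events=30_000, sample_prefix="TRAIN")
db = pk.build_database([(pk.transform_fluorescence(e), l) for e, l in train],
                       seed=42, registry=registry)
report, assignments, ag_labels = pk.autogate_sample(tev, db, meta, seed=3)
print(f"checks: {100 * report.checks_fraction:.2f}% of lymphoid events")
print(pk.percent_difference(counts.loc['b_cells', 'abs_per_ul'],
                            report.table.loc['b_cells', 'abs_per_ul']))
```

prints (values from this exact seed):

```
events        3497.000000
pct_wbc          3.681053
abs_per_ul     220.863158
Name: b_cells, dtype: float64
checks: 0.51% of lymphoid events
-0.34315127251927596
```

The last line is the signed percent difference — here −0.34 %, far inside
the 20 % equivalence limit.  The `events` row is the number of gated B cells, `pct_wbc` their
share of all white cells, and `abs_per_ul` the dual-platform absolute count;
`checks` is the fraction of lymphoid events the automated route refused to
assign and handed to the expert.

Command-line wrappers mirror the pipeline stages: `pidot-io inspect|qc`,
`pidot-sim sample|ranges`, `pidot-gate manual|auto|build-db`, and
`pidot-study run`.

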