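"""Method-comparison layer: manual vs automated counts, reproducibility, tests.

For every (sample, population) pair the two gating routes yield absolute
counts (cells/uL).  The comparison statistic is the signed, manual-referenced
percent difference

    pct_diff = (count_MG - count_AGI) / count_MG * 100

and the two routes are *equivalent* on that observation when
``|pct_diff| < 20`` (the EN ISO 15189-style criterion).  Observations failing
the 20% criterion are additionally checked for *clinical relevance*: the two
counts are compared against the age-matched p5-p95 reference interval, and a
difference is clinically relevant iff the two routes land in different
interval categories (below / in range / above).

The reproducibility harness replays the analysis five times per condition
(intra-observer: one analyst; inter-observer: five analysts) and summarises
per-population coefficients of variation, CV% = SD/mean * 100 with the
sample SD (n-1).  Classic tests used when summarising a study: Spearman rank
correlation, variance-ratio F test, Yates-corrected chi-square, Bonferroni
correction.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import DomainError, InputError, LeakageError, ParameterError
from .autogate import AutoGateReport, ReferenceDatabase, autogate_sample
from .manual_gating import (
    GateTree,
    ThresholdSet,
    load_gate_tree,
    load_thresholds,
    manual_gate,
    population_counts,
)
from .panel_io import EventMatrix, transform_fluorescence
from .synthetic_cohort import (
    ObserverModel,
    ReferenceRanges,
    TemplateRegistry,
    load_registry,
    perturb_thresholds,
)

EQUIVALENCE_LIMIT_PCT = 20.0

#: The 20 reported populations entering the manual/automated comparison by
#: default; the CD4+CD8+ double-positive and IgD+IgM- post-GC subsets are
#: excluded because the automated route does not model them separately.
DEFAULT_COMPARISON_POPULATIONS = (
    "lymphocytes", "b_cells", "pre_gc_b", "unswitched_mbc_pc",
    "switched_mbc_pc", "t_cells", "cd4_t", "cd4_naive", "cd4_cm", "cd4_em",
    "cd4_td", "cd8_t", "cd8_naive", "cd8_cm", "cd8_em", "cd8_td27pos",
    "cd8_td27neg", "tcrgd_neg_dn_t", "tcrgd_pos_t", "nk_cells",
)


# ---------------------------------------------------------------------------
# Elementary comparison operations
# ---------------------------------------------------------------------------

def percent_difference(count_mg: float, count_ag: float) -> float:
    """Signed manual-referenced percent difference.

    ``(MG - AGI) / MG * 100``; both zero -> 0; MG zero with AGI positive is
    undefined (NaN, treated downstream as non-equivalent).
    """
    if count_mg < 0 or count_ag < 0:
        raise DomainError("counts must be non-negative")
    if count_mg == 0:
        return 0.0 if count_ag == 0 else math.nan
    return (count_mg - count_ag) / count_mg * 100.0


def is_equivalent(pct_diff: float) -> bool:
    """EN ISO 15189-style equivalence: defined and |pct_diff| < 20."""
    return not math.isnan(pct_diff) and abs(pct_diff) < EQUIVALENCE_LIMIT_PCT


def clinical_relevance(
    count_mg: float, count_ag: float, reference: tuple[float, float]
) -> tuple[str, str, bool]:
    """Interval category of each count and whether they disagree.

    The in-range category is the inclusive interval [p5, p95]; any category
    mismatch (including below vs above) is a different clinical
    interpretation, hence relevant.
    """
    p5, p95 = reference
    if not p5 < p95:
        raise ParameterError("reference interval requires p5 < p95")

    def status(x: float) -> str:
        if x < p5:
            return "below_p5"
        if x > p95:
            return "above_p95"
        return "in_range"

    s_mg, s_ag = status(count_mg), status(count_ag)
    return s_mg, s_ag, s_mg != s_ag


@dataclass(frozen=True)
class ComparisonRecord:
    """Paired manual/automated counts for one population in one sample."""

    sample_id: str
    group: str
    population: str
    count_mg: float
    count_ag: float
    pct_diff: float  # NaN when undefined
    equivalent: bool
    mg_status: str
    ag_status: str
    clinically_relevant: bool


def compare_counts(
    sample_id: str,
    group: str,
    population: str,
    count_mg: float,
    count_ag: float,
    reference: tuple[float, float] | None,
) -> ComparisonRecord:
    """One paired observation.  Clinical relevance is evaluated only for
    observations that already fail the 20% criterion (as in the study
    design); equivalent observations are never clinically relevant."""
    pd_ = percent_difference(count_mg, count_ag)
    eq = is_equivalent(pd_)
    mg_status = ag_status = "unknown"
    relevant = False
    if reference is not None:
        mg_status, ag_status, mismatch = clinical_relevance(
            count_mg, count_ag, reference
        )
        relevant = (not eq) and mismatch
    return ComparisonRecord(
        sample_id, group, population, count_mg, count_ag, pd_, eq,
        mg_status, ag_status, relevant,
    )


# ---------------------------------------------------------------------------
# Reproducibility
# ---------------------------------------------------------------------------

def cv_percent(replicates: Sequence[float], ddof: int = 1) -> tuple[float, float, float]:
    """(mean, SD, CV%) of replicate counts; CV is NaN for zero mean.

    SD is the sample SD (``ddof=1``) by default; set ``ddof=0`` for the
    population convention.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise InputError("CV needs at least two replicates")
    if np.all(x == x[0]):
        # exact: identical replicates have zero spread (no mean round-off)
        mean = float(x[0])
        return mean, 0.0, math.nan if mean == 0 else 0.0
    mean = float(x.mean())
    sd = float(x.std(ddof=ddof))
    cv = math.nan if mean == 0 else 100.0 * sd / mean
    return mean, sd, cv


@dataclass
class ReproducibilityResult:
    """Long-format CV table plus per-(method, mode) median CV%.

    Medians are taken over defined CVs only (zero-mean replicate sets are
    excluded).
    """

    cv_table: pd.DataFrame  # sample_id, population, method, mode, mean, sd, cv_pct

    def median_cv(self, method: str, mode: str) -> float:
        t = self.cv_table
        sel = t[(t["method"] == method) & (t["mode"] == mode)]["cv_pct"].dropna()
        return float(sel.median()) if len(sel) else math.nan


def reproducibility(
    replicate_tables: Sequence[pd.DataFrame],
    mode: str,
    method: str,
    sample_id: str,
    n_expected: int = 5,
    ddof: int = 1,
) -> pd.DataFrame:
    """CV rows from replicate count tables (same populations in each).

    ``replicate_tables`` are count tables indexed by population with an
    ``abs_per_ul`` column, one per replicate analysis.
    """
    if len(replicate_tables) != n_expected:
        raise InputError(
            f"expected {n_expected} replicates, got {len(replicate_tables)}"
        )
    pops = list(replicate_tables[0].index)
    for t in replicate_tables[1:]:
        if list(t.index) != pops:
            raise InputError("replicate tables disagree on population sets")
    rows = []
    for pop in pops:
        values = [float(t.loc[pop, "abs_per_ul"]) for t in replicate_tables]
        mean, sd, cv = cv_percent(values, ddof=ddof)
        rows.append(
            {
                "sample_id": sample_id,
                "population": pop,
                "method": method,
                "mode": mode,
                "mean": mean,
                "sd": sd,
                "cv_pct": cv,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classic tests
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties); NaN if a vector is
    constant (undefined, reported as such)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(sps.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class FTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def variance_ratio_f_test(
    cv_set_a: Sequence[float], cv_set_b: Sequence[float]
) -> FTestResult:
    """Two-sided variance-ratio F test between two sets of values.

    F is the larger sample variance over the smaller, with (n-1, n-1) style
    degrees of freedom following the ordering; both-variances-zero is
    degenerate with p = 1 by convention (flagged).
    """
    a = np.asarray(cv_set_a, dtype=float)
    b = np.asarray(cv_set_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each set needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return FTestResult(1.0, 1.0, degenerate=True)
    if va >= vb:
        num_df, den_df, v_num, v_den = a.size - 1, b.size - 1, va, vb
    else:
        num_df, den_df, v_num, v_den = b.size - 1, a.size - 1, vb, va
    if v_den == 0:
        return FTestResult(math.inf, 0.0, degenerate=True)
    f = v_num / v_den
    p = min(1.0, 2.0 * float(sps.f.sf(f, num_df, den_df)))
    return FTestResult(float(f), p)


def chi_square_yates(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square on a 2x2 table.

    Statistic is sum((|O - E| - 0.5)^2 / E), p from chi-square with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("chi_square_yates expects a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise InputError("table entries must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InputError("all table margins must be positive")
    stat, p, _, _ = sps.chi2_contingency(t, correction=True)
    return float(stat), float(p)


def bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """(reject, adjusted p) under the Bonferroni correction.

    Rejection uses the strict inequality p < alpha/m; adjusted p is
    min(1, m * p).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise InputError("p values must lie in [0, 1]")
    m = p.size
    return p < alpha / m, np.minimum(1.0, m * p)


def delta_mfi(
    events: EventMatrix,
    labels: np.ndarray,
    population_a: str,
    population_b: str,
    marker: str,
    min_events: int = 10,
) -> float:
    """Difference of per-population median raw intensities of one marker.

    Reported in raw channel units (the scale diagnostic MFIs are quoted on);
    transformed matrices are inverted first.
    """
    raw = events.raw()
    labels = np.asarray(labels, dtype=object)
    x = raw.channel(marker)
    meds = []
    for pop in (population_a, population_b):
        sel = labels == pop
        if sel.sum() < min_events:
            raise InputError(
                f"population {pop!r} has {int(sel.sum())} events, "
                f"needs >= {min_events}"
            )
        meds.append(float(np.median(x[sel])))
    return meds[0] - meds[1]


# ---------------------------------------------------------------------------
# Study harness
# ---------------------------------------------------------------------------

@dataclass
class StudySummary:
    """Per population x group discrepancy table plus rank correlations."""

    table: pd.DataFrame  # population, group, n, n_gt20, pct_gt20,
    #                      n_clin_rel, pct_clin_rel, spearman_rho

    def overall_gt20_pct(self, group: str = "total") -> float:
        t = self.table[self.table["group"] == group]
        return 100.0 * t["n_gt20"].sum() / t["n"].sum()

    def overall_clin_rel_pct(self, group: str = "total") -> float:
        t = self.table[self.table["group"] == group]
        return 100.0 * t["n_clin_rel"].sum() / t["n"].sum()


@dataclass
class StudyResult:
    records: list[ComparisonRecord]
    summary: StudySummary
    reproducibility: ReproducibilityResult | None
    mg_counts: dict[str, pd.DataFrame]
    ag_reports: dict[str, AutoGateReport]


def _records_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize_records(records: Sequence[ComparisonRecord]) -> StudySummary:
    """Tabulate >20%-difference and clinical-relevance rates per population
    per group (plus a 'total' margin), with explicit denominators."""
    frame = _records_frame(records)
    rows = []
    groups = sorted(frame["group"].unique()) + ["total"]
    for pop, sub in frame.groupby("population", sort=False):
        for g in groups:
            s = sub if g == "total" else sub[sub["group"] == g]
            if not len(s):
                continue
            n = len(s)
            n_gt20 = int((~s["equivalent"]).sum())
            n_rel = int(s["clinically_relevant"].sum())
            rho = (
                spearman_rho(s["count_mg"], s["count_ag"])
                if n >= 3
                else math.nan
            )
            rows.append(
                {
                    "population": pop,
                    "group": g,
                    "n": n,
                    "n_gt20": n_gt20,
                    "pct_gt20": 100.0 * n_gt20 / n,
                    "n_clin_rel": n_rel,
                    "pct_clin_rel": 100.0 * n_rel / n,
                    "spearman_rho": rho,
                }
            )
    return StudySummary(pd.DataFrame(rows))


def run_study(
    cohort: Sequence[tuple[EventMatrix, np.ndarray]],
    db: ReferenceDatabase,
    ranges: ReferenceRanges,
    observers: Sequence[ObserverModel] | None = None,
    seed: int = 0,
    registry: TemplateRegistry | None = None,
    tree: GateTree | None = None,
    thresholds: ThresholdSet | None = None,
    comparison_populations: Sequence[str] = DEFAULT_COMPARISON_POPULATIONS,
    n_repro_samples: int = 12,
    n_replicates: int = 5,
    cutoff_quantile: float = 0.999,
    run_reproducibility: bool = True,
) -> StudyResult:
    """Analyze a labelled cohort in parallel by both gating routes.

    For every sample: manual gating with the canonical thresholds and the
    automated pipeline (per-sample clustering seed derived from ``seed``),
    a :class:`ComparisonRecord` per comparison population, and — on a
    randomly chosen subset of ``n_repro_samples`` samples — the
    intra/inter-observer reproducibility replicates: manual replicates
    re-gate with observer-jittered thresholds (intra: one analyst, five
    jitter draws; inter: five analysts); automated intra-replicates rerun
    the identical deterministic pipeline (CV exactly 0) and automated
    inter-replicates vary only the clustering seed.

    The database must be built on a disjoint training cohort; overlapping
    sample ids raise :class:`LeakageError`.
    """
    registry = registry or load_registry()
    tree = tree or load_gate_tree()
    thresholds = thresholds or load_thresholds()

    ids = [ev.sample_meta.sample_id for ev, _ in cohort]
    overlap = set(ids) & set(db.train_sample_ids)
    if overlap:
        raise LeakageError(f"evaluation samples in training cohort: {sorted(overlap)}")

    def sample_seed(sample_id: str, salt: int = 0) -> int:
        # stable per-sample seed: invariant under cohort permutation
        return (seed * 1_000_003 + zlib.crc32(sample_id.encode()) + salt) % 2**31

    records: list[ComparisonRecord] = []
    mg_counts: dict[str, pd.DataFrame] = {}
    ag_reports: dict[str, AutoGateReport] = {}
    transformed: dict[str, EventMatrix] = {}
    for events, _labels in cohort:
        meta = events.sample_meta
        tev = (
            events
            if events.scale == "transformed"
            else transform_fluorescence(events, thresholds.cofactor)
        )
        transformed[meta.sample_id] = tev
        mg = manual_gate(tev, tree, thresholds, meta)
        counts = population_counts(mg, meta)
        ag_seed = sample_seed(meta.sample_id)
        report, _, _ = autogate_sample(
            tev, db, meta, ranges, seed=ag_seed,
            cutoff_quantile=cutoff_quantile, thresholds=thresholds,
            registry=registry,
        )
        mg_counts[meta.sample_id] = counts
        ag_reports[meta.sample_id] = report
        for pop in comparison_populations:
            c_mg = float(counts.loc[pop, "abs_per_ul"])
            c_ag = (
                float(report.table.loc[pop, "abs_per_ul"])
                if pop in report.table.index
                else 0.0
            )
            records.append(
                compare_counts(
                    meta.sample_id, meta.group, pop, c_mg, c_ag,
                    ranges.lookup(pop, meta.age_years),
                )
            )

    summary = summarize_records(records)

    repro = None
    if run_reproducibility:
        if observers is None:
            observers = [
                ObserverModel(0.1, sample_seed(f"observer-{j}")) for j in range(5)
            ]
        pick_rng = np.random.default_rng(seed)
        sorted_ids = sorted(ids)
        pick = pick_rng.choice(
            len(sorted_ids), size=min(n_repro_samples, len(sorted_ids)),
            replace=False,
        )
        cv_frames = []
        for i in sorted(pick):
            sid = sorted_ids[i]
            tev = transformed[sid]
            meta = tev.sample_meta

            def mg_table(obs: ObserverModel) -> pd.DataFrame:
                th = perturb_thresholds(thresholds, obs)
                res = manual_gate(tev, tree, th, meta)
                return population_counts(res, meta).loc[
                    list(comparison_populations)
                ]

            intra_obs = observers[0]
            mg_intra = [
                mg_table(
                    ObserverModel(
                        intra_obs.jitter_sd,
                        sample_seed(f"intra-{sid}", salt=r + 1),
                    )
                )
                for r in range(n_replicates)
            ]
            mg_inter = [mg_table(obs) for obs in observers[:n_replicates]]

            def ag_table(ag_seed: int) -> pd.DataFrame:
                rep, _, _ = autogate_sample(
                    tev, db, meta, ranges, seed=ag_seed,
                    cutoff_quantile=cutoff_quantile, thresholds=thresholds,
                    registry=registry,
                )
                t = rep.table.reindex(list(comparison_populations))
                return t.assign(abs_per_ul=t["abs_per_ul"].fillna(0.0))

            fixed_seed = sample_seed(f"ag-intra-{sid}")
            ag_intra_tbl = ag_table(fixed_seed)
            ag_intra = [ag_intra_tbl] * n_replicates  # deterministic rerun
            ag_inter = [
                ag_table(sample_seed(f"ag-inter-{sid}", salt=r + 1))
                for r in range(n_replicates)
            ]
            for tables, mode, method in (
                (mg_intra, "intra", "MG"),
                (mg_inter, "inter", "MG"),
                (ag_intra, "intra", "AGI"),
                (ag_inter, "inter", "AGI"),
            ):
                cv_frames.append(
                    reproducibility(
                        tables, mode, method, sid,
                        n_expected=n_replicates,
                    )
                )
        repro = ReproducibilityResult(pd.concat(cv_frames, ignore_index=True))

    return StudyResult(
        records=records,
        summary=summary,
        reproducibility=repro,
        mg_counts=mg_counts,
        ag_reports=ag_reports,
    )
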