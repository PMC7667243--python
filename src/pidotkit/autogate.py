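"""Automated gating & identification: cluster, classify against a database.

The commercial tools this emulates do not publish their internals, so this
module fixes a transparent surrogate with auditable math that reproduces the
described behaviours: (1) seeded k-means over-clustering of all lymphoid
events of a sample, (2) classification of each cluster centroid against a
reference database of per-population multivariate summaries built from
labelled healthy samples, by squared Mahalanobis distance with a chi-square
cutoff, (3) unassignable clusters surfaced as "checks" carrying up to three
candidate populations for expert resolution, and (4) an automated report
with a numerical "remark" for every population whose absolute count falls
outside the age-matched p5-p95 reference interval.

Feature space: the 11 asinh-transformed markers plus FSC-A and SSC-A scaled
by a fixed constant so scatter and fluorescence live on comparable scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cluster import KMeans, MiniBatchKMeans

from ._errors import (
    BuildError,
    InputError,
    NumericError,
    ParameterError,
    RangeCoverageError,
)
from .manual_gating import (
    ThresholdSet,
    debris_mask,
    exclude_doublets,
    gate_lymphocytes,
    load_thresholds,
)
from .panel_io import EventMatrix, SampleMeta
from .synthetic_cohort import ReferenceRanges, TemplateRegistry, load_registry

#: Raw scatter units divided by this before entering the feature space, so a
#: typical lymphocyte scatter SD (~2500) lands near the fluorescence band SD.
SCATTER_SCALE = 10_000.0

#: Populations excluded from the default database build; the CD4+CD8+
#: double-positive subset is not a separate automated population by default
#: (a flag adds it back).
DEFAULT_DB_EXCLUDE = ("cd4_cd8_dp_t",)


def feature_matrix(events: EventMatrix) -> tuple[np.ndarray, list[str]]:
    """Events -> (N x 13) feature matrix and feature names."""
    if events.scale != "transformed":
        raise ParameterError("autogate operates on transformed events")
    panel = events.panel
    names = panel.fluorescence_names + ["FSC-A", "SSC-A"]
    cols = [events.channel(m) for m in panel.fluorescence_names]
    cols.append(events.channel("FSC-A") / SCATTER_SCALE)
    cols.append(events.channel("SSC-A") / SCATTER_SCALE)
    return np.column_stack(cols), names


@dataclass
class ReferenceDatabase:
    """Per-population location/scatter summaries from labelled HD samples.

    Covariances are shrunk toward their diagonal,
    ``(1 - shrinkage) * S + shrinkage * diag(S)``, which keeps small
    populations well conditioned.  Versioned and immutable once built.
    """

    feature_names: list[str]
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    train_counts: dict[str, int]
    panel_version: str
    build_seed: int
    shrinkage: float
    train_sample_ids: tuple[str, ...] = ()
    _inv: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def populations(self) -> list[str]:
        return list(self.means)

    def inverse_covariance(self, population: str) -> np.ndarray:
        if population not in self._inv:
            cov = self.covariances[population]
            try:
                self._inv[population] = np.linalg.inv(cov)
            except np.linalg.LinAlgError as exc:
                raise NumericError(
                    f"covariance of {population!r} is singular despite "
                    f"shrinkage {self.shrinkage}"
                ) from exc
        return self._inv[population]

    def mahalanobis_sq(self, points: np.ndarray, population: str) -> np.ndarray:
        """Squared Mahalanobis distance of each row to one population."""
        d = points - self.means[population]
        return np.einsum("ij,jk,ik->i", d, self.inverse_covariance(population), d)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "format": "pidotkit-refdb-1",
            "feature_names": self.feature_names,
            "panel_version": self.panel_version,
            "build_seed": self.build_seed,
            "shrinkage": self.shrinkage,
            "train_sample_ids": list(self.train_sample_ids),
            "populations": {
                p: {
                    "mean": self.means[p].tolist(),
                    "covariance": self.covariances[p].tolist(),
                    "n_train": self.train_counts[p],
                }
                for p in self.means
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDatabase":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        if raw.get("format") != "pidotkit-refdb-1":
            raise InputError(f"{path}: not a pidotkit reference database")
        pops = raw["populations"]
        return cls(
            feature_names=list(raw["feature_names"]),
            means={p: np.asarray(s["mean"]) for p, s in pops.items()},
            covariances={p: np.asarray(s["covariance"]) for p, s in pops.items()},
            train_counts={p: int(s["n_train"]) for p, s in pops.items()},
            panel_version=raw["panel_version"],
            build_seed=int(raw["build_seed"]),
            shrinkage=float(raw["shrinkage"]),
            train_sample_ids=tuple(raw.get("train_sample_ids", ())),
        )


def build_database(
    labeled_cohort: Sequence[tuple[EventMatrix, np.ndarray]],
    seed: int = 0,
    shrinkage: float = 0.1,
    registry: TemplateRegistry | None = None,
    include_populations: Sequence[str] | None = None,
    min_events: int = 50,
    min_samples: int = 10,
) -> ReferenceDatabase:
    """Pooled per-population mean/covariance from labelled (transformed)
    healthy samples.

    Every included population must contribute at least ``min_events`` pooled
    training events; deficient populations are listed in the raised
    :class:`BuildError`.  Deterministic given its inputs.
    """
    if len(labeled_cohort) < min_samples:
        raise BuildError(
            f"database build needs >= {min_samples} samples, got {len(labeled_cohort)}"
        )
    if not (0.0 <= shrinkage <= 1.0):
        raise ParameterError("shrinkage must lie in [0, 1]")
    registry = registry or load_registry()
    if include_populations is None:
        include_populations = [
            t for t in registry.terminals if t not in DEFAULT_DB_EXCLUDE
        ]
    pooled: dict[str, list[np.ndarray]] = {p: [] for p in include_populations}
    sample_ids = []
    feature_names: list[str] = []
    for events, labels in labeled_cohort:
        feats, feature_names = feature_matrix(events)
        labels = np.asarray(labels, dtype=object)
        for p in include_populations:
            sel = labels == p
            if sel.any():
                pooled[p].append(feats[sel])
        if events.sample_meta is not None:
            sample_ids.append(events.sample_meta.sample_id)
    deficient = {
        p: sum(map(len, blocks))
        for p, blocks in pooled.items()
        if sum(map(len, blocks)) < min_events
    }
    if deficient:
        raise BuildError(
            f"populations with < {min_events} pooled training events: {deficient}"
        )
    means, covs, counts = {}, {}, {}
    for p, blocks in pooled.items():
        x = np.concatenate(blocks, axis=0)
        means[p] = x.mean(axis=0)
        s = np.cov(x, rowvar=False, ddof=1)
        covs[p] = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
        counts[p] = x.shape[0]
    return ReferenceDatabase(
        feature_names=feature_names,
        means=means,
        covariances=covs,
        train_counts=counts,
        panel_version=registry.version,
        build_seed=int(seed),
        shrinkage=shrinkage,
        train_sample_ids=tuple(sample_ids),
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def default_k(n_events: int) -> int:
    """Over-clustering default: max(50, ceil(sqrt(N)))."""
    return max(50, int(np.ceil(np.sqrt(n_events))))


def cluster_events(
    events: EventMatrix, k: int | None = None, seed: int = 0
) -> np.ndarray:
    """Seeded k-means over-clustering in the full feature space.

    Full-batch k-means is used while N*k is small; larger problems switch to
    the mini-batch variant (still deterministic for a fixed seed).
    """
    feats, _ = feature_matrix(events)
    n = feats.shape[0]
    if k is None:
        k = default_k(n)
    if k < 1 or k > n:
        raise ParameterError(f"k={k} outside [1, N={n}]")
    if n * k <= 5_000_000:
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    else:
        km = MiniBatchKMeans(
            n_clusters=k,
            n_init=3,
            batch_size=4096,
            max_iter=200,
            random_state=int(seed),
        )
    return km.fit_predict(feats)


# ---------------------------------------------------------------------------
# Cluster classification
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    cluster_id: int
    event_indices: np.ndarray
    population: str | None
    distance: float
    candidates: list[tuple[str, float]]
    expert_resolved: bool = False
    discarded: bool = False

    @property
    def assigned(self) -> bool:
        return self.population is not None and not self.discarded


def classify_clusters(
    events: EventMatrix,
    cluster_labels: np.ndarray,
    db: ReferenceDatabase,
    cutoff_quantile: float = 0.999,
) -> list[ClusterAssignment]:
    """Assign each cluster to its nearest database population, or flag it.

    A cluster centroid is assigned to the minimum-Mahalanobis population iff
    the squared distance is below the chi-square quantile at
    ``cutoff_quantile`` (df = number of features); otherwise the cluster is a
    "check" carrying the three nearest candidates sorted by distance.
    Near-exact ties (within 1e-12) break toward the larger training count,
    then lexicographic name.
    """
    if not (0.0 < cutoff_quantile < 1.0):
        raise ParameterError("cutoff_quantile must lie in (0, 1)")
    feats, names = feature_matrix(events)
    if names != db.feature_names:
        raise InputError("event feature space does not match the database panel")
    cluster_labels = np.asarray(cluster_labels)
    ids = np.unique(cluster_labels)
    centroids = np.stack([feats[cluster_labels == c].mean(axis=0) for c in ids])
    pops = db.populations
    dists = np.column_stack([db.mahalanobis_sq(centroids, p) for p in pops])
    cutoff = chi2.ppf(cutoff_quantile, df=len(db.feature_names))
    out = []
    for row, cid in enumerate(ids):
        d = dists[row]
        order = np.argsort(d, kind="stable")
        best = order[0]
        # documented tie rule: larger training count, then lexicographic name
        ties = [j for j in order if d[j] - d[best] <= 1e-12]
        if len(ties) > 1:
            best = min(ties, key=lambda j: (-db.train_counts[pops[j]], pops[j]))
        idx = np.flatnonzero(cluster_labels == cid)
        if d[best] <= cutoff:
            out.append(
                ClusterAssignment(int(cid), idx, pops[best], float(d[best]),
                                  candidates=[])
            )
        else:
            cands = [(pops[j], float(d[j])) for j in order[:3]]
            out.append(
                ClusterAssignment(int(cid), idx, None, float(d[best]), cands)
            )
    return out


def resolve_checks(
    assignments: Sequence[ClusterAssignment],
    resolution: Mapping[int, str],
    db: ReferenceDatabase | None = None,
    allow_override: bool = False,
) -> list[ClusterAssignment]:
    """Apply an expert's resolution map to unassigned clusters.

    ``resolution`` maps cluster id -> population name or ``"discard"``.
    Touching an automatically assigned cluster is an error unless
    ``allow_override`` is set (the extended-revision mode); unresolved checks
    stay unassigned and are excluded from counts.
    """
    by_id = {a.cluster_id: a for a in assignments}
    unknown = set(resolution) - set(by_id)
    if unknown:
        raise InputError(f"resolution map names unknown clusters {sorted(unknown)}")
    out = []
    for a in assignments:
        if a.cluster_id not in resolution:
            out.append(a)
            continue
        if a.assigned and not allow_override:
            raise InputError(
                f"cluster {a.cluster_id} is auto-assigned; expert resolution "
                "requires allow_override"
            )
        target = resolution[a.cluster_id]
        if target == "discard":
            out.append(
                ClusterAssignment(a.cluster_id, a.event_indices, None, a.distance,
                                  a.candidates, expert_resolved=True, discarded=True)
            )
        else:
            if db is not None and target not in db.populations:
                raise InputError(f"unknown resolution population {target!r}")
            out.append(
                ClusterAssignment(a.cluster_id, a.event_indices, target, a.distance,
                                  a.candidates, expert_resolved=True)
            )
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

#: Aggregate populations reported on top of the database terminals.
AGGREGATES = ("lymphocytes", "b_cells", "t_cells", "cd4_t", "cd8_t")


@dataclass
class AutoGateReport:
    """Automated report for one sample: counts, range status, checks."""

    table: pd.DataFrame
    checks: list[ClusterAssignment]
    checks_fraction: float  # checks / lymphoid-gated events
    checks_fraction_total: float  # checks / all events (second convention)
    meta: SampleMeta

    @property
    def remarks(self) -> list[str]:
        return list(self.table.index[self.table["remark"]])


def autogate_report(
    assignments: Sequence[ClusterAssignment],
    meta: SampleMeta,
    ranges: ReferenceRanges | None,
    registry: TemplateRegistry,
    wbc_events: int,
    lymphoid_events: int,
    total_events: int,
    populations: Sequence[str] | None = None,
) -> AutoGateReport:
    """Tabulate per-population counts, flag out-of-range values as remarks.

    ``populations`` restricts the report to the populations the database can
    actually assign (plus the aggregates); populations the automated route
    does not model are not reported rather than being reported as zero.
    """
    if meta is None:
        raise ParameterError("autogate report requires sample metadata")
    assigned_counts: dict[str, int] = {}
    check_events = 0
    checks = []
    for a in assignments:
        if a.assigned:
            assigned_counts[a.population] = (
                assigned_counts.get(a.population, 0) + a.event_indices.size
            )
        elif a.discarded:
            continue
        else:
            check_events += a.event_indices.size
            checks.append(a)
    rows = []
    if populations is None:
        reportable = set(assigned_counts)
    else:
        reportable = set(populations)
    report_pops = [p for p in registry.populations
                   if p in AGGREGATES or p in reportable]
    for pop in report_pops:
        if pop in AGGREGATES:
            members = registry.terminal_descendants(pop)
            n = sum(assigned_counts.get(t, 0) for t in members)
        else:
            n = assigned_counts.get(pop, 0)
        pct = 100.0 * n / wbc_events if wbc_events else 0.0
        abs_count = pct * meta.wbc_per_ul / 100.0
        status, remark, p5, p95 = "unknown", False, np.nan, np.nan
        if ranges is not None:
            try:
                p5, p95 = ranges.lookup(pop, meta.age_years)
            except RangeCoverageError:
                if pop in ("lymphocytes",) or registry.populations[pop].terminal:
                    raise
            else:
                status = ranges.status(abs_count, pop, meta.age_years)
                remark = status != "in_range"
        rows.append(
            {
                "population": pop,
                "events": n,
                "pct_wbc": pct,
                "abs_per_ul": abs_count,
                "p5": p5,
                "p95": p95,
                "status": status,
                "remark": remark,
            }
        )
    table = pd.DataFrame(rows).set_index("population")
    return AutoGateReport(
        table=table,
        checks=checks,
        checks_fraction=check_events / lymphoid_events if lymphoid_events else 0.0,
        checks_fraction_total=check_events / total_events if total_events else 0.0,
        meta=meta,
    )


def autogate_sample(
    events: EventMatrix,
    db: ReferenceDatabase,
    meta: SampleMeta | None = None,
    ranges: ReferenceRanges | None = None,
    seed: int = 0,
    k: int | None = None,
    cutoff_quantile: float = 0.999,
    thresholds: ThresholdSet | None = None,
    registry: TemplateRegistry | None = None,
    resolution: Mapping[int, str] | None = None,
) -> tuple[AutoGateReport, list[ClusterAssignment], np.ndarray]:
    """Full automated pipeline on one transformed sample.

    Pre-gating (doublets, debris, lymphocyte scatter gate) always uses the
    canonical threshold set — the automated route has no observer-dependent
    inputs, which is exactly the reproducibility claim under test.  Returns
    the report, the cluster assignments and per-event labels (population,
    'check', 'excluded', or a pre-gating label).
    """
    thresholds = thresholds or load_thresholds()
    registry = registry or load_registry()
    meta = meta or events.sample_meta
    n = events.n_events

    singlet = exclude_doublets(events, thresholds.doublet_tolerance)
    debris = debris_mask(events, thresholds) & singlet
    lymph = gate_lymphocytes(events, thresholds) & singlet & ~debris
    lymph_idx = np.flatnonzero(lymph)
    wbc_events = int(np.sum(singlet & ~debris))

    sub = EventMatrix(
        events.values[lymph_idx],
        panel=events.panel,
        sample_meta=meta,
        scale=events.scale,
        cofactor=events.cofactor,
    )
    cluster_labels = cluster_events(sub, k=k, seed=seed)
    assignments = classify_clusters(sub, cluster_labels, db, cutoff_quantile)
    if resolution:
        assignments = resolve_checks(assignments, resolution, db)

    labels = np.full(n, "non_lymphoid", dtype=object)
    labels[~singlet] = "doublet"
    labels[debris] = "debris"
    for a in assignments:
        if a.assigned:
            labels[lymph_idx[a.event_indices]] = a.population
        elif a.discarded:
            labels[lymph_idx[a.event_indices]] = "excluded"
        else:
            labels[lymph_idx[a.event_indices]] = "check"

    report = autogate_report(
        assignments, meta, ranges, registry,
        wbc_events=wbc_events,
        lymphoid_events=len(lymph_idx),
        total_events=n,
        populations=db.populations,
    )
    return report, assignments, labels
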