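"""Synthetic PIDOT-like samples with ground truth, reference ranges, observers.

The generator emulates a lysed-blood sample stained with the 11-marker PID
screening tube: ~20 labelled lymphocyte populations at age-plausible
frequencies, a background of non-lymphoid leukocytes, plus debris and
cell-doublet nuisance events.  Marker expression is modelled per population
as one of four bands (neg / lo / pos / hi) on the asinh-transformed scale;
band levels per population come from a YAML registry shipped with the
package.  All randomness flows from explicit integer seeds.

Also here: empirical age-stratified p5-p95 reference ranges derived from
simulated healthy cohorts, and the threshold-jitter observer model used to
emulate analyst-to-analyst manual-gating variability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import (
    InsufficientDataError,
    ParameterError,
    RangeCoverageError,
    RegistryError,
)
from .panel_io import RAW_MAX, EventMatrix, PanelDefinition, SampleMeta, pidot_panel

BANDS = ("neg", "lo", "pos", "hi")
NUISANCE_LABELS = ("debris", "doublet", "other_leukocyte")

#: Age-bin convention for reference-range stratification (years).  The edges
#: are a configurable package convention, not a claim about any guideline.
DEFAULT_AGE_BINS = (0.0, 2.0, 5.0, 10.0, 18.0, 65.0, 120.0)


@dataclass(frozen=True)
class BandModel:
    """Generative stand-in for the neg / lo / + / hi marker-band notation.

    ``means`` are the band centres on the asinh scale; ``sd`` is the common
    within-band standard deviation.  Defaults keep adjacent bands at least
    3 sd apart so that ground truth is recoverable by midpoint thresholds;
    weak-separation regimes are produced by raising ``sd``, never by new
    code paths.
    """

    means: tuple[float, float, float, float] = (0.0, 1.5, 3.0, 4.5)
    sd: float = 0.25
    fsc_sd: float = 2500.0
    ssc_sd: float = 1200.0
    fsc_h_ratio_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ParameterError("band sd must be positive")
        gaps = np.diff(self.means)
        if not (gaps > 0).all():
            raise ParameterError("band means must be strictly increasing")
        if (gaps < 3 * self.sd).any():
            raise ParameterError("adjacent band means must be >= 3 sd apart")

    def mean_of(self, band: str) -> float:
        return self.means[BANDS.index(band)]


@dataclass(frozen=True)
class AberrationSpec:
    """A patient-like staining/expression aberration.

    Adds ``shift`` (transformed units) to the band mean of ``marker`` for all
    events of ``population``.  Examples emulating reported patient patterns
    are available from :func:`aberration_presets`.
    """

    population: str
    marker: str
    shift: float
    label: str = ""


@dataclass(frozen=True)
class PopulationTemplate:
    name: str
    parent: str | None
    terminal: bool
    bands: Mapping[str, str] | None = None
    scatter_mean: tuple[float, float] | None = None
    scatter_sd: tuple[float, float] | None = None
    fraction_range: tuple[float, float] | None = None


#: Populations a pidot-v1 registry must provide (the 20 reported populations
#: plus the IgD+IgM- post-germinal-center and CD4+CD8+ double-positive
#: subsets).
REQUIRED_POPULATIONS = (
    "lymphocytes", "b_cells", "pre_gc_b", "unswitched_mbc_pc",
    "switched_mbc_pc", "igd_pos_igm_neg_post_gc", "t_cells", "tcrgd_pos_t",
    "tcrgd_neg_dn_t", "cd4_t", "cd4_naive", "cd4_cm", "cd4_em", "cd4_td",
    "cd8_t", "cd8_naive", "cd8_cm", "cd8_em", "cd8_td27pos", "cd8_td27neg",
    "cd4_cd8_dp_t", "nk_cells",
)


class TemplateRegistry:
    """Population hierarchy + per-population generative templates."""

    def __init__(
        self,
        populations: Mapping[str, PopulationTemplate],
        nuisance: Mapping[str, PopulationTemplate],
        panel: PanelDefinition | None = None,
        version: str = "custom",
    ) -> None:
        self.populations = dict(populations)
        self.nuisance = dict(nuisance)
        self.panel = panel or pidot_panel()
        self.version = version
        self._validate()

    def _validate(self) -> None:
        markers = set(self.panel.fluorescence_names)
        for name, tpl in self.populations.items():
            if tpl.parent is not None and tpl.parent not in self.populations:
                raise RegistryError(f"{name}: unknown parent {tpl.parent!r}")
            if tpl.terminal:
                if tpl.bands is None or set(tpl.bands) != markers:
                    raise RegistryError(f"{name}: bands must cover all markers")
                if tpl.fraction_range is None or not (
                    0 < tpl.fraction_range[0] <= tpl.fraction_range[1] < 1
                ):
                    raise RegistryError(f"{name}: bad fraction_range")
                bad = [b for b in tpl.bands.values() if b not in BANDS]
                if bad:
                    raise RegistryError(f"{name}: unknown band levels {bad}")
        roots = [n for n, t in self.populations.items() if t.parent is None]
        if roots != ["lymphocytes"]:
            raise RegistryError(f"expected single root 'lymphocytes', got {roots}")
        if self.version == "pidot-v1":
            missing = [p for p in REQUIRED_POPULATIONS if p not in self.populations]
            if missing:
                raise RegistryError(f"pidot-v1 registry missing {missing}")

    @property
    def terminals(self) -> list[str]:
        return [n for n, t in self.populations.items() if t.terminal]

    def children(self, name: str) -> list[str]:
        return [n for n, t in self.populations.items() if t.parent == name]

    def terminal_descendants(self, name: str) -> list[str]:
        tpl = self.populations[name]
        if tpl.terminal:
            return [name]
        out: list[str] = []
        for c in self.children(name):
            out.extend(self.terminal_descendants(c))
        return out

    def ancestry(self, name: str) -> list[str]:
        """Path from root to ``name`` inclusive."""
        path = [name]
        while (p := self.populations[path[-1]].parent) is not None:
            path.append(p)
        return path[::-1]


def load_registry(path: str | Path | None = None) -> TemplateRegistry:
    """Load the template registry (default: the shipped pidot-v1 YAML)."""
    if path is None:
        path = Path(__file__).parent / "data" / "populations.yaml"
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)

    def mk(name: str, spec: Mapping, parent_key: bool = True) -> PopulationTemplate:
        return PopulationTemplate(
            name=name,
            parent=spec.get("parent") if parent_key else None,
            terminal=bool(spec.get("terminal", True)),
            bands=spec.get("bands"),
            scatter_mean=tuple(spec["scatter_mean"]) if "scatter_mean" in spec else None,
            scatter_sd=tuple(spec["scatter_sd"]) if "scatter_sd" in spec else None,
            fraction_range=tuple(spec["fraction_range"])
            if "fraction_range" in spec
            else None,
        )

    pops = {n: mk(n, s) for n, s in raw["populations"].items()}
    nuis = {n: mk(n, s, parent_key=False) for n, s in raw["nuisance"].items()}
    return TemplateRegistry(pops, nuis, version=raw.get("version", "custom"))


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------

def _draw_fractions(
    registry: TemplateRegistry,
    rng: np.random.Generator,
    overrides: Mapping[str, float] | None,
) -> dict[str, float]:
    fractions: dict[str, float] = {}
    for name in registry.terminals:
        lo, hi = registry.populations[name].fraction_range
        fractions[name] = rng.uniform(lo, hi)
    if overrides:
        unknown = set(overrides) - set(fractions)
        if unknown:
            raise RegistryError(f"fraction overrides for unknown terminals {unknown}")
        fractions.update(overrides)
    total = sum(fractions.values())
    if total >= 0.9:
        raise RegistryError(
            f"lymphoid fractions sum to {total:.3f}; no room for other leukocytes"
        )
    return fractions


def _block(
    tpl: PopulationTemplate,
    n: int,
    band_model: BandModel,
    panel: PanelDefinition,
    rng: np.random.Generator,
    cofactor: float,
    shifts: Mapping[str, float],
    sd_scale: Mapping[str, float],
) -> np.ndarray:
    """Raw-scale event block for one template."""
    out = np.empty((n, panel.n_channels))
    fsc = rng.normal(tpl.scatter_mean[0], (tpl.scatter_sd or
                                           (band_model.fsc_sd, band_model.ssc_sd))[0], n)
    ssc = rng.normal(tpl.scatter_mean[1], (tpl.scatter_sd or
                                           (band_model.fsc_sd, band_model.ssc_sd))[1], n)
    fsc = np.clip(fsc, 0.0, RAW_MAX)
    ssc = np.clip(ssc, 0.0, RAW_MAX)
    fsc_h = np.clip(fsc * rng.normal(1.0, band_model.fsc_h_ratio_sd, n), 0.0, RAW_MAX)
    out[:, panel.index("FSC-A")] = fsc
    out[:, panel.index("FSC-H")] = fsc_h
    out[:, panel.index("SSC-A")] = ssc
    for marker in panel.fluorescence_names:
        mu = band_model.mean_of(tpl.bands[marker]) + shifts.get(marker, 0.0)
        sd = band_model.sd * sd_scale.get(marker, 1.0)
        t = rng.normal(mu, sd, n)
        out[:, panel.index(marker)] = np.clip(np.sinh(t) * cofactor, 0.0, RAW_MAX)
    return out


def simulate_sample(
    registry: TemplateRegistry,
    band_model: BandModel,
    meta: SampleMeta,
    n_events: int,
    seed: int,
    aberrations: Sequence[AberrationSpec] = (),
    doublet_rate: float = 0.02,
    debris_rate: float = 0.03,
    fraction_overrides: Mapping[str, float] | None = None,
    cofactor: float = 150.0,
    cd27_smear: float = 0.0,
) -> tuple[EventMatrix, np.ndarray]:
    """Simulate one raw-scale sample and its per-event ground-truth labels.

    Population event counts are a multinomial draw from per-sample fractions
    drawn uniformly inside each template's ``fraction_range`` (overridable to
    emulate expansions).  Doublets sum the raw intensities of two random
    lymphoid singlets with FSC-H staying at the singlet level; debris sits at
    low scatter.  ``cd27_smear`` widens the CD27 band of the memory B-cell
    populations to emulate that marker's heterogeneous expression, the
    hardest manual/automated disagreement mode.  Deterministic given
    ``seed`` and inputs.
    """
    if n_events < 1:
        raise ParameterError("n_events must be positive")
    for rate, name in ((doublet_rate, "doublet_rate"), (debris_rate, "debris_rate")):
        if not (0.0 <= rate <= 0.2):
            raise ParameterError(f"{name} must lie in [0, 0.2]")
    for ab in aberrations:
        if ab.population not in registry.populations and ab.population not in registry.nuisance:
            raise RegistryError(f"aberration targets unknown population {ab.population!r}")
    rng = np.random.default_rng(seed)
    panel = registry.panel
    fractions = _draw_fractions(registry, rng, fraction_overrides)

    terminals = registry.terminals
    wbc_scale = 1.0 - doublet_rate - debris_rate
    lymph_total = sum(fractions.values())
    class_names = ["debris", "doublet"] + terminals + ["other_leukocyte"]
    probs = np.array(
        [debris_rate, doublet_rate]
        + [fractions[t] * wbc_scale for t in terminals]
        + [(1.0 - lymph_total) * wbc_scale]
    )
    counts = rng.multinomial(n_events, probs / probs.sum())

    shift_map = {
        name: {ab.marker: ab.shift for ab in aberrations if ab.population == name}
        for name in set(ab.population for ab in aberrations)
    }
    smear_targets = {"unswitched_mbc_pc", "pre_gc_b"}

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    n_doublets = counts[class_names.index("doublet")]
    for name, n in zip(class_names, counts):
        if n == 0 or name == "doublet":
            continue
        tpl = (
            registry.populations.get(name)
            or registry.nuisance[name]
        )
        sd_scale = (
            {"CD27": 1.0 + cd27_smear}
            if cd27_smear > 0 and name in smear_targets
            else {}
        )
        blocks.append(
            _block(tpl, n, band_model, panel, rng, cofactor,
                   shift_map.get(name, {}), sd_scale)
        )
        labels.append(np.full(n, name, dtype=object))

    if n_doublets > 0:
        # Each doublet is two lymphoid singlets coincident in the laser spot:
        # areas add, pulse height stays near the singlet level.
        lymph_probs = np.array([fractions[t] for t in terminals])
        lymph_probs = lymph_probs / lymph_probs.sum()
        halves = []
        for _ in range(2):
            picks = rng.choice(len(terminals), size=n_doublets, p=lymph_probs)
            half = np.empty((n_doublets, panel.n_channels))
            for j in np.unique(picks):
                tpl = registry.populations[terminals[j]]
                m = int((picks == j).sum())
                half[picks == j] = _block(
                    tpl, m, band_model, panel, rng, cofactor,
                    shift_map.get(terminals[j], {}), {},
                )
            halves.append(half)
        doublet = halves[0] + halves[1]
        ih = panel.index("FSC-H")
        doublet[:, ih] = np.maximum(halves[0][:, ih], halves[1][:, ih])
        np.clip(doublet, 0.0, RAW_MAX, out=doublet)
        blocks.append(doublet)
        labels.append(np.full(n_doublets, "doublet", dtype=object))

    values = np.concatenate(blocks, axis=0)
    label_arr = np.concatenate(labels)
    order = rng.permutation(values.shape[0])
    events = EventMatrix(values[order], panel=panel, sample_meta=meta, scale="raw")
    return events, label_arr[order]


def simulate_cohort(
    registry: TemplateRegistry,
    band_model: BandModel,
    n_samples: int,
    ages: Sequence[float],
    wbc: Sequence[float],
    seed: int,
    n_events: int = 20_000,
    group: str = "HD",
    sample_prefix: str = "S",
    **sample_kwargs,
) -> list[tuple[EventMatrix, np.ndarray]]:
    """Simulate ``n_samples`` independent samples with per-sample seeds
    derived deterministically from the master seed."""
    if len(ages) != n_samples or len(wbc) != n_samples:
        raise ParameterError("ages and wbc lists must have length n_samples")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_samples)
    out = []
    for i in range(n_samples):
        meta = SampleMeta(
            sample_id=f"{sample_prefix}{i:03d}",
            age_years=float(ages[i]),
            wbc_per_ul=float(wbc[i]),
            group=group,
        )
        out.append(
            simulate_sample(
                registry, band_model, meta, n_events, int(child_seeds[i]),
                **sample_kwargs,
            )
        )
    return out


def hd_cohort_metadata(
    n_samples: int, seed: int, age_range: tuple[float, float] = (20.0, 60.0),
    wbc_range: tuple[float, float] = (4000.0, 10000.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Healthy-adult ages (years) and WBC counts (/uL), uniform draws."""
    rng = np.random.default_rng(seed)
    return (
        rng.uniform(*age_range, n_samples),
        rng.uniform(*wbc_range, n_samples),
    )


# ---------------------------------------------------------------------------
# Ground-truth counting
# ---------------------------------------------------------------------------

def truth_counts(
    labels: np.ndarray, meta: SampleMeta, registry: TemplateRegistry
) -> pd.DataFrame:
    """Ground-truth count table (events, %WBC, absolute /uL) per population.

    The WBC denominator is every non-doublet, non-debris event; parent
    populations are sums of their terminal descendants; absolute counts use
    the dual-platform formula %WBC x WBC/uL / 100.
    """
    labels = np.asarray(labels, dtype=object)
    wbc_events = int(np.sum((labels != "doublet") & (labels != "debris")))
    term_counts = pd.Series(labels).value_counts().to_dict()
    rows = []
    for name in registry.populations:
        n = sum(term_counts.get(t, 0) for t in registry.terminal_descendants(name))
        pct = 100.0 * n / wbc_events
        rows.append(
            {
                "population": name,
                "events": n,
                "pct_wbc": pct,
                "abs_per_ul": pct * meta.wbc_per_ul / 100.0,
            }
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Reference ranges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRanges:
    """Age-stratified empirical p5-p95 absolute-count reference intervals."""

    age_edges: tuple[float, ...]
    table: Mapping[tuple[str, int], tuple[float, float]]

    def bin_of(self, age_years: float) -> int:
        edges = self.age_edges
        for i in range(len(edges) - 1):
            if edges[i] <= age_years < edges[i + 1]:
                return i
        raise RangeCoverageError(f"age {age_years} outside bins {edges}")

    def lookup(self, population: str, age_years: float) -> tuple[float, float]:
        b = self.bin_of(age_years)
        try:
            return self.table[(population, b)]
        except KeyError:
            raise RangeCoverageError(
                f"no reference range for {population!r} in age bin {b} "
                f"[{self.age_edges[b]}, {self.age_edges[b + 1]})"
            ) from None

    def status(self, count: float, population: str, age_years: float) -> str:
        """'below_p5' | 'in_range' | 'above_p95' (in-range is inclusive)."""
        p5, p95 = self.lookup(population, age_years)
        if count < p5:
            return "below_p5"
        if count > p95:
            return "above_p95"
        return "in_range"

    def to_yaml(self, path: str | Path) -> Path:
        payload = {
            "age_edges": list(self.age_edges),
            "ranges": [
                {"population": p, "bin": b, "p5": float(lo), "p95": float(hi)}
                for (p, b), (lo, hi) in sorted(self.table.items())
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh)
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceRanges":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            age_edges=tuple(raw["age_edges"]),
            table={
                (r["population"], int(r["bin"])): (float(r["p5"]), float(r["p95"]))
                for r in raw["ranges"]
            },
        )


def derive_reference_ranges(
    cohort_truths: Iterable[tuple[np.ndarray, SampleMeta]],
    registry: TemplateRegistry,
    age_bins: Sequence[float] = (18.0, 65.0),
    min_per_bin: int = 20,
) -> ReferenceRanges:
    """Empirical 5th/95th percentiles of ground-truth absolute counts per
    population per age bin (linear interpolation between order statistics).

    Every bin must hold at least ``min_per_bin`` samples; an empty or
    deficient bin raises :class:`InsufficientDataError` naming the bin, and
    degenerate p5 == p95 intervals are rejected.
    """
    edges = tuple(float(e) for e in age_bins)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ParameterError("age_bins must be strictly increasing edges")
    per_bin: dict[int, list[pd.DataFrame]] = {i: [] for i in range(len(edges) - 1)}
    for labels, meta in cohort_truths:
        idx = None
        for i in range(len(edges) - 1):
            if edges[i] <= meta.age_years < edges[i + 1]:
                idx = i
                break
        if idx is None:
            raise RangeCoverageError(
                f"sample {meta.sample_id} age {meta.age_years} outside bins {edges}"
            )
        per_bin[idx].append(truth_counts(labels, meta, registry))
    table: dict[tuple[str, int], tuple[float, float]] = {}
    for i, frames in per_bin.items():
        if len(frames) < min_per_bin:
            raise InsufficientDataError(
                f"age bin [{edges[i]}, {edges[i + 1]}) has {len(frames)} samples, "
                f"needs >= {min_per_bin}"
            )
        counts = pd.concat([f["abs_per_ul"] for f in frames], axis=1)
        for pop, row in counts.iterrows():
            p5, p95 = np.percentile(row.to_numpy(), [5.0, 95.0], method="linear")
            if not p5 < p95:
                raise InsufficientDataError(
                    f"degenerate reference interval (p5 == p95) for {pop!r} "
                    f"in age bin {i}"
                )
            table[(pop, i)] = (float(p5), float(p95))
    return ReferenceRanges(age_edges=edges, table=table)


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverModel:
    """An analyst modelled as seeded jitter on the manual-gating cut points.

    ``jitter_sd`` (transformed units) is the SD of the independent normal
    shift applied to every marker cut point; 0 reproduces the canonical
    threshold set exactly.
    """

    jitter_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")


def perturb_thresholds(thresholds, observer: ObserverModel):
    """Observer-specific threshold set: every marker cut point shifted by an
    independent N(0, jitter_sd^2) draw.  jitter_sd = 0 is the identity."""
    if observer.jitter_sd == 0:
        return thresholds
    rng = np.random.default_rng(observer.seed)
    new_cuts = {}
    for marker, cuts in thresholds.cuts.items():
        shifted = tuple(c + rng.normal(0.0, observer.jitter_sd) for c in cuts)
        new_cuts[marker] = shifted
    return dataclasses.replace(thresholds, cuts=new_cuts)


# ---------------------------------------------------------------------------
# Aberration presets (patient-like patterns)
# ---------------------------------------------------------------------------

def aberration_presets() -> dict[str, list[AberrationSpec]]:
    """Named aberration scenarios emulating reported patient patterns.

    ``dim_cd4``      technical staining issue pulling CD4 to the negative
                     band on every CD4+ T-cell subset, so those events look
                     like CD4-CD8- TCRgd- T cells.
    ``igd_dim``      switched memory B cells with residual dim IgD, blurring
                     the switched vs IgD+IgM- post-GC distinction.
    ``dim_tcrgd``    TCRgd staining failure on an (often expanded) TCRgd+
                     compartment, pushing it into the CD4-CD8- TCRgd- gate.
    """
    return {
        "dim_cd4": [
            AberrationSpec(p, "CD4", -3.0, "dim CD4 staining")
            for p in ("cd4_naive", "cd4_cm", "cd4_em", "cd4_td")
        ],
        "igd_dim": [
            AberrationSpec("switched_mbc_pc", "IgD", +1.5, "IgD-dim IgM- B cells")
        ],
        "dim_tcrgd": [
            AberrationSpec("tcrgd_pos_t", "TCRgd", -3.0, "dim TCRgd staining")
        ],
    }
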