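"""Deterministic hierarchical Boolean gating of the 11-marker screening tube.

Implements the expert manual-gating strategy as a fixed gate tree over marker
*bands*: each fluorescence intensity (asinh scale) is discretized into
neg / lo / pos / hi by three per-marker cut points, and every node of the
tree is a conjunction of band requirements.  Pre-gating removes doublets
(FSC-H/FSC-A ratio), debris and non-lymphoid events (scatter rectangle +
CD45 hi) before the lineage and maturation subsets are assigned.

Events matching no sibling at a level are kept in that parent's explicit
``unclassified`` remainder instead of being forced into the nearest gate:
in real practice that call is made by a human, which this engine refuses to
simulate silently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, MetadataError, ParameterError
from .panel_io import EventMatrix, SampleMeta

#: Band tokens of the printed superscript notation -> admissible band codes
#: (0=neg, 1=lo, 2=pos, 3=hi).  "+" means positive-or-high; "hi" is strict.
BAND_TOKENS: dict[str, frozenset[int]] = {
    "-": frozenset({0}),
    "lo": frozenset({1}),
    "+": frozenset({2, 3}),
    "hi": frozenset({3}),
    "-..lo": frozenset({0, 1}),
    "lo..+": frozenset({1, 2, 3}),
    "-..+": frozenset({0, 1, 2}),
}

NON_LYMPHOID_LABELS = ("doublet", "debris", "non_lymphoid")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-marker band cut points plus the scatter pre-gates."""

    cuts: Mapping[str, tuple[float, float, float]]
    fsc_gate: tuple[float, float]
    ssc_gate: tuple[float, float]
    doublet_tolerance: float = 0.25
    cofactor: float = 150.0
    version: str = "custom"

    def __post_init__(self) -> None:
        for marker, c in self.cuts.items():
            if len(c) != 3 or not (c[0] < c[1] < c[2]):
                raise ConfigurationError(
                    f"cut points for {marker!r} must be strictly increasing"
                )
        if not (0.0 <= self.doublet_tolerance < 1.0):
            raise ConfigurationError("doublet tolerance must lie in [0, 1)")

    def band_codes(self, events: EventMatrix) -> dict[str, np.ndarray]:
        """Band code (0..3) per event for every marker with cuts."""
        if events.scale != "transformed":
            raise ParameterError("band classification requires transformed events")
        return {
            m: np.searchsorted(np.asarray(c), events.channel(m), side="left")
            for m, c in self.cuts.items()
        }


def load_thresholds(path: str | Path | None = None) -> ThresholdSet:
    """Load a threshold set (default: the shipped pidot-v1 YAML)."""
    if path is None:
        path = Path(__file__).parent / "data" / "thresholds.yaml"
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return ThresholdSet(
        cuts={m: tuple(c) for m, c in raw["cuts"].items()},
        fsc_gate=tuple(raw["lymphocyte_gate"]["fsc_a"]),
        ssc_gate=tuple(raw["lymphocyte_gate"]["ssc_a"]),
        doublet_tolerance=float(raw.get("doublet_ratio_tolerance", 0.25)),
        cofactor=float(raw.get("cofactor", 150.0)),
        version=raw.get("version", "custom"),
    )


@dataclass(frozen=True)
class GateNode:
    name: str
    parent: str | None
    terminal: bool
    requires: Mapping[str, frozenset[int]]


class GateTree:
    """Single-rooted gate hierarchy with mutually exclusive siblings.

    ``validate`` proves sibling exclusivity by brute-force enumeration of all
    band assignments over the markers the siblings constrain; events matching
    no sibling fall into the parent's explicit unclassified remainder, which
    makes siblings jointly exhaustive by construction.
    """

    def __init__(self, nodes: Mapping[str, GateNode]) -> None:
        self.nodes = dict(nodes)
        self.validate()

    @property
    def root(self) -> str:
        roots = [n for n, node in self.nodes.items() if node.parent is None]
        if len(roots) != 1:
            raise ConfigurationError(f"gate tree must have one root, got {roots}")
        return roots[0]

    def children(self, name: str) -> list[str]:
        return [n for n, node in self.nodes.items() if node.parent == name]

    def validate(self) -> None:
        root = self.root  # raises if not single-rooted
        # acyclicity / reachability
        seen = set()
        stack = [root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ConfigurationError(f"cycle at node {n!r}")
            seen.add(n)
            stack.extend(self.children(n))
        if seen != set(self.nodes):
            raise ConfigurationError(
                f"unreachable nodes: {sorted(set(self.nodes) - seen)}"
            )
        # sibling mutual exclusivity by enumeration over the involved markers
        for parent in self.nodes:
            sibs = self.children(parent)
            if len(sibs) < 2:
                continue
            markers = sorted({m for s in sibs for m in self.nodes[s].requires})
            for combo in itertools.product(range(4), repeat=len(markers)):
                assignment = dict(zip(markers, combo))
                matches = [
                    s
                    for s in sibs
                    if all(
                        assignment[m] in allowed
                        for m, allowed in self.nodes[s].requires.items()
                    )
                ]
                if len(matches) > 1:
                    raise ConfigurationError(
                        f"siblings {matches} of {parent!r} overlap on bands "
                        f"{assignment}"
                    )

    def table_order(self) -> list[str]:
        """Populations in report order: depth-first in declaration order."""
        order: list[str] = []

        def walk(name: str) -> None:
            order.append(name)
            for c in self.children(name):
                walk(c)

        walk(self.root)
        return order


def load_gate_tree(path: str | Path | None = None) -> GateTree:
    """Load a gate tree (default: the shipped pidot-v1 YAML)."""
    if path is None:
        path = Path(__file__).parent / "data" / "gate_tree.yaml"
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    nodes = {}
    for name, spec in raw["nodes"].items():
        requires = {}
        for marker, token in (spec.get("requires") or {}).items():
            if token not in BAND_TOKENS:
                raise ConfigurationError(
                    f"{name}: unknown band token {token!r} for {marker!r}"
                )
            requires[marker] = BAND_TOKENS[token]
        nodes[name] = GateNode(
            name=name,
            parent=spec.get("parent"),
            terminal=bool(spec.get("terminal", False)),
            requires=requires,
        )
    return GateTree(nodes)


# ---------------------------------------------------------------------------
# Pre-gating
# ---------------------------------------------------------------------------

def exclude_doublets(events: EventMatrix, tolerance: float = 0.25) -> np.ndarray:
    """Singlet mask from the FSC-H/FSC-A pulse-shape ratio.

    An event is kept iff its ratio lies within ``tolerance`` (relative) of
    the sample's robust singlet ratio, the median ratio.  Events with zero
    FSC-A are excluded.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    fsc_a = events.channel("FSC-A")
    fsc_h = events.channel("FSC-H")
    valid = fsc_a > 0
    ratio = np.full(events.n_events, np.nan)
    ratio[valid] = fsc_h[valid] / fsc_a[valid]
    med = np.nanmedian(ratio)
    keep = valid & (np.abs(ratio - med) <= tolerance * med)
    return keep


def gate_lymphocytes(events: EventMatrix, thresholds: ThresholdSet) -> np.ndarray:
    """Lymphocyte mask: scatter rectangle plus CD45 in the high band."""
    fsc = events.channel("FSC-A")
    ssc = events.channel("SSC-A")
    in_rect = (
        (fsc >= thresholds.fsc_gate[0])
        & (fsc <= thresholds.fsc_gate[1])
        & (ssc >= thresholds.ssc_gate[0])
        & (ssc <= thresholds.ssc_gate[1])
    )
    cd45_hi = events.channel("CD45") >= thresholds.cuts["CD45"][2]
    return in_rect & cd45_hi


def debris_mask(events: EventMatrix, thresholds: ThresholdSet) -> np.ndarray:
    """Debris: events below the FSC-A floor of the lymphocyte rectangle."""
    return events.channel("FSC-A") < thresholds.fsc_gate[0]


# ---------------------------------------------------------------------------
# Hierarchical classification
# ---------------------------------------------------------------------------

@dataclass
class GatingResult:
    """Per-event labels plus per-population counts for one gated sample.

    ``labels`` holds, for every event of the input matrix, either a terminal
    population, 'unclassified', or one of 'doublet' / 'debris' /
    'non_lymphoid'.  ``node_events`` counts events reaching each tree node
    (parents include their unclassified remainder, so child counts plus the
    remainder sum exactly to the parent).
    """

    labels: np.ndarray
    node_events: dict[str, int]
    unclassified_events: dict[str, int]
    meta: SampleMeta | None
    n_events: int
    wbc_events: int
    zero_fsc_events: int = 0
    tree: GateTree | None = field(default=None, repr=False)


def classify_events(
    events: EventMatrix, tree: GateTree, thresholds: ThresholdSet
) -> np.ndarray:
    """Assign every event (assumed pre-gated to the tree root) a terminal
    label via top-down band predicates; non-matching events get
    'unclassified'."""
    tree.validate()
    codes = thresholds.band_codes(events)
    labels = np.full(events.n_events, "unclassified", dtype=object)

    def descend(node: str, idx: np.ndarray) -> None:
        children = tree.children(node)
        if not children:
            labels[idx] = node
            return
        remaining = idx
        for child in children:
            req = tree.nodes[child].requires
            if remaining.size == 0:
                break
            match = np.ones(remaining.size, dtype=bool)
            for marker, allowed in req.items():
                match &= np.isin(codes[marker][remaining], list(allowed))
            descend(child, remaining[match])
            remaining = remaining[~match]
        # leftover events stay 'unclassified' under this parent

    descend(tree.root, np.arange(events.n_events))
    return labels


def manual_gate(
    events: EventMatrix,
    tree: GateTree | None = None,
    thresholds: ThresholdSet | None = None,
    meta: SampleMeta | None = None,
) -> GatingResult:
    """Full manual-gating pipeline on a transformed sample.

    Order: doublet exclusion -> debris / lymphocyte scatter+CD45 gate ->
    hierarchical band classification.  The WBC denominator for relative
    counts is every non-doublet, non-debris event.
    """
    tree = tree or load_gate_tree()
    thresholds = thresholds or load_thresholds()
    meta = meta or events.sample_meta
    n = events.n_events

    singlet = exclude_doublets(events, thresholds.doublet_tolerance)
    debris = debris_mask(events, thresholds) & singlet
    lymph = gate_lymphocytes(events, thresholds) & singlet & ~debris

    labels = np.full(n, "non_lymphoid", dtype=object)
    labels[~singlet] = "doublet"
    labels[debris] = "debris"
    lymph_idx = np.flatnonzero(lymph)

    sub = EventMatrix(
        events.values[lymph_idx],
        panel=events.panel,
        sample_meta=meta,
        scale=events.scale,
        cofactor=events.cofactor,
    )
    sub_labels = classify_events(sub, tree, thresholds)
    labels[lymph_idx] = sub_labels

    # per-node counts: events whose deepest assignment lies in the subtree
    node_events: dict[str, int] = {}
    uncls: dict[str, int] = {}
    codes = thresholds.band_codes(sub)

    def count(node: str, idx: np.ndarray) -> int:
        children = tree.children(node)
        total = idx.size
        node_events[node] = total
        remaining = idx
        child_sum = 0
        for child in children:
            match = np.ones(remaining.size, dtype=bool)
            for marker, allowed in tree.nodes[child].requires.items():
                match &= np.isin(codes[marker][remaining], list(allowed))
            child_sum += count(child, remaining[match])
            remaining = remaining[~match]
        if children:
            uncls[node] = total - child_sum
        return total

    count(tree.root, np.arange(len(lymph_idx)))

    return GatingResult(
        labels=labels,
        node_events=node_events,
        unclassified_events=uncls,
        meta=meta,
        n_events=n,
        wbc_events=int(np.sum(singlet & ~debris)),
        zero_fsc_events=int(np.sum(events.channel("FSC-A") <= 0)),
        tree=tree,
    )


def population_counts(result: GatingResult, meta: SampleMeta | None = None) -> pd.DataFrame:
    """Count table (events, %WBC, absolute /uL) in gating-hierarchy order.

    Absolute counts follow the dual-platform formula:
    %WBC x WBC/uL / 100, with the WBC count taken from the sample metadata.
    """
    meta = meta or result.meta
    if meta is None or meta.wbc_per_ul is None:
        raise MetadataError("population_counts requires sample metadata with WBC")
    rows = []
    order = result.tree.table_order() if result.tree is not None else sorted(
        result.node_events
    )
    for name in order:
        n = result.node_events.get(name, 0)
        pct = 100.0 * n / result.wbc_events if result.wbc_events else 0.0
        rows.append(
            {
                "population": name,
                "events": n,
                "pct_wbc": pct,
                "abs_per_ul": pct * meta.wbc_per_ul / 100.0,
            }
        )
    return pd.DataFrame(rows).set_index("population")
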