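"""Shared fixtures: registry, band model, a healthy sample, database, ranges.

Heavy artifacts are session-scoped so the whole suite simulates each of them
once.  Every fixture is seeded; nothing here touches the filesystem except
through tmp_path in individual tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import pidotkit as pk


@pytest.fixture(scope="session")
def registry():
    return pk.load_registry()


@pytest.fixture(scope="session")
def band_model():
    return pk.BandModel()


@pytest.fixture(scope="session")
def thresholds():
    return pk.load_thresholds()


@pytest.fixture(scope="session")
def gate_tree():
    return pk.load_gate_tree()


@pytest.fixture(scope="session")
def hd_meta():
    return pk.SampleMeta("HD000", age_years=35.0, wbc_per_ul=6000.0, group="HD")


@pytest.fixture(scope="session")
def hd_sample(registry, band_model, hd_meta):
    """One 60k-event healthy sample: (raw EventMatrix, truth labels)."""
    return pk.simulate_sample(registry, band_model, hd_meta, 60_000, seed=101)


@pytest.fixture(scope="session")
def hd_transformed(hd_sample):
    events, labels = hd_sample
    return pk.transform_fluorescence(events), labels


@pytest.fixture(scope="session")
def reference_db(registry, band_model):
    """Database from 10 labelled training samples (30k events each)."""
    ages, wbcs = pk.hd_cohort_metadata(10, seed=7)
    cohort = pk.simulate_cohort(
        registry, band_model, 10, ages, wbcs, seed=42, n_events=30_000,
        sample_prefix="TRAIN",
    )
    labeled = [(pk.transform_fluorescence(ev), lab) for ev, lab in cohort]
    return pk.build_database(labeled, seed=42, registry=registry)


@pytest.fixture(scope="session")
def reference_ranges(registry, band_model):
    """p5-p95 ranges from 40 simulated healthy adults (truth labels only)."""
    ages, wbcs = pk.hd_cohort_metadata(40, seed=8)
    cohort = pk.simulate_cohort(
        registry, band_model, 40, ages, wbcs, seed=43, n_events=15_000,
        sample_prefix="REF",
    )
    return pk.derive_reference_ranges(
        [(lab, ev.sample_meta) for ev, lab in cohort], registry
    )


def make_band_events(band_rows, panel=None, cofactor=150.0, meta=None):
    """Transformed EventMatrix from a list of marker->band-mean dicts.

    Each row becomes one event sitting exactly at its band means (default
    band model), with lymphocyte-typical scatter.  Used to exercise gate
    predicates without sampling noise.
    """
    panel = panel or pk.pidot_panel()
    means = {"neg": 0.0, "lo": 1.5, "pos": 3.0, "hi": 4.5}
    values = np.zeros((len(band_rows), panel.n_channels))
    for i, row in enumerate(band_rows):
        values[i, panel.index("FSC-A")] = 55_000.0
        values[i, panel.index("FSC-H")] = 55_000.0
        values[i, panel.index("SSC-A")] = 12_000.0
        for marker in panel.fluorescence_names:
            values[i, panel.index(marker)] = means[row.get(marker, "neg")]
    return pk.EventMatrix(
        values, panel=panel, sample_meta=meta, scale="transformed",
        cofactor=cofactor,
    )
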