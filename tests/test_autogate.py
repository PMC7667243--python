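"""Reference database, clustering, cluster classification, checks, reports."""

import numpy as np
import pytest
from scipy.stats import chi2

import pidotkit as pk
from pidotkit._errors import BuildError, InputError, ParameterError
from pidotkit.autogate import default_k, feature_matrix



class TestBuildDatabase:
    def test_all_default_populations_present(self, reference_db, registry):
        expected = {t for t in registry.terminals if t != "cd4_cd8_dp_t"}
        assert set(reference_db.populations) == expected
        assert all(n >= 50 for n in reference_db.train_counts.values())

    def test_mean_matches_direct_averaging(self, registry, band_model, hd_meta):
        cohort = []
        for s in range(10):
            ev, lab = pk.simulate_sample(
                registry, band_model, hd_meta, 10_000, seed=100 + s
            )
            cohort.append((pk.transform_fluorescence(ev), lab))
        db = pk.build_database(cohort, seed=0, registry=registry)
        pooled = []
        for tev, lab in cohort:
            feats, _ = feature_matrix(tev)
            pooled.append(feats[np.asarray(lab) == "cd4_naive"])
        direct = np.concatenate(pooled).mean(axis=0)
        np.testing.assert_allclose(db.means["cd4_naive"], direct, atol=1e-9)

    def test_full_shrinkage_gives_diagonal_covariance(
        self, registry, band_model, hd_meta
    ):
        cohort = []
        for s in range(10):
            ev, lab = pk.simulate_sample(
                registry, band_model, hd_meta, 20_000, seed=200 + s
            )
            cohort.append((pk.transform_fluorescence(ev), lab))
        db = pk.build_database(cohort, seed=0, shrinkage=1.0, registry=registry)
        cov = db.covariances["t_cells" if "t_cells" in db.covariances else "nk_cells"]
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() == 0.0

    def test_deficient_population_listed(self, registry, band_model, hd_meta):
        cohort = []
        for s in range(10):
            ev, lab = pk.simulate_sample(
                registry, band_model, hd_meta, 300, seed=300 + s
            )
            cohort.append((pk.transform_fluorescence(ev), lab))
        with pytest.raises(BuildError, match="igd_pos_igm_neg_post_gc"):
            pk.build_database(cohort, seed=0, registry=registry)

    def test_too_few_samples(self, registry, hd_transformed):
        events, labels = hd_transformed
        with pytest.raises(BuildError):
            pk.build_database([(events, labels)], registry=registry)

    def test_json_round_trip(self, reference_db, tmp_path):
        path = reference_db.to_json(tmp_path / "db.json")
        back = pk.ReferenceDatabase.from_json(path)
        assert back.populations == reference_db.populations
        np.testing.assert_allclose(
            back.means["nk_cells"], reference_db.means["nk_cells"]
        )
        np.testing.assert_allclose(
            back.covariances["nk_cells"], reference_db.covariances["nk_cells"]
        )
        assert back.train_sample_ids == reference_db.train_sample_ids


class TestClusterEvents:
    def _two_blobs(self, n=2000, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        panel = pk.pidot_panel()
        values = np.zeros((n, 14))
        values[:, panel.index("FSC-A")] = 55_000
        values[:, panel.index("FSC-H")] = 55_000
        values[:, panel.index("SSC-A")] = 12_000
        half = n // 2
        values[:half, panel.index("CD4")] = rng.normal(0.0, 0.25, half)
        values[half:, panel.index("CD4")] = rng.normal(sep * 0.25, 0.25, n - half)
        truth = np.array([0] * half + [1] * (n - half))
        events = pk.EventMatrix(values, panel=panel, scale="transformed",
                                cofactor=150.0)
        return events, truth

    def test_default_k_rule(self):
        assert default_k(100) == 50
        assert default_k(1_000_000) == 1000

    def test_separated_blobs_stay_pure(self):
        events, truth = self._two_blobs()
        labels = pk.cluster_events(events, k=10, seed=1)
        for c in np.unique(labels):
            members = truth[labels == c]
            contamination = min(members.mean(), 1 - members.mean())
            assert contamination <= 0.05

    def test_seeded_determinism(self):
        events, _ = self._two_blobs()
        a = pk.cluster_events(events, k=8, seed=3)
        b = pk.cluster_events(events, k=8, seed=3)
        assert (a == b).all()

    def test_k_one_single_cluster(self):
        events, _ = self._two_blobs(n=100)
        labels = pk.cluster_events(events, k=1, seed=0)
        assert set(labels) == {0}

    def test_k_larger_than_n_rejected(self):
        events, _ = self._two_blobs(n=50)
        with pytest.raises(ParameterError):
            pk.cluster_events(events, k=51, seed=0)


class TestClassifyClusters:
    def test_centroid_at_population_mean_assigned_distance_zero(self, reference_db):
        panel = pk.pidot_panel()
        mean = reference_db.means["nk_cells"]
        values = np.zeros((20, 14))
        for j, marker in enumerate(panel.fluorescence_names):
            values[:, panel.index(marker)] = mean[j]
        values[:, panel.index("FSC-A")] = mean[11] * 10_000
        values[:, panel.index("SSC-A")] = mean[12] * 10_000
        values[:, panel.index("FSC-H")] = values[:, panel.index("FSC-A")]
        events = pk.EventMatrix(values, panel=panel, scale="transformed",
                                cofactor=150.0)
        out = pk.classify_clusters(events, np.zeros(20, int), reference_db)
        assert out[0].population == "nk_cells"
        assert out[0].distance == pytest.approx(0.0, abs=1e-9)

    def test_remote_centroid_unassigned_with_three_candidates(self, reference_db):
        panel = pk.pidot_panel()
        values = np.full((10, 14), 0.0)
        # 10 standardized units high on every marker: far from everything
        for marker in panel.fluorescence_names:
            values[:, panel.index(marker)] = 10.0
        values[:, panel.index("FSC-A")] = 55_000
        values[:, panel.index("FSC-H")] = 55_000
        values[:, panel.index("SSC-A")] = 12_000
        events = pk.EventMatrix(values, panel=panel, scale="transformed",
                                cofactor=150.0)
        out = pk.classify_clusters(events, np.zeros(10, int), reference_db)
        a = out[0]
        assert a.population is None
        assert len(a.candidates) == 3
        dists = [d for _, d in a.candidates]
        assert dists == sorted(dists)
        # the chi-square cutoff itself
        assert a.distance > chi2.ppf(0.999, df=13)

    def test_cutoff_is_chi_square_quantile(self, reference_db, hd_transformed):
        # borderline check: a cluster sitting exactly at a population mean is
        # accepted even at a tiny cutoff quantile
        events, _ = hd_transformed
        sub = pk.EventMatrix(
            events.values[:200], panel=events.panel, scale="transformed",
            cofactor=events.cofactor,
        )
        out_hi = pk.classify_clusters(sub, np.zeros(200, int), reference_db,
                                      cutoff_quantile=0.999)
        out_lo = pk.classify_clusters(sub, np.zeros(200, int), reference_db,
                                      cutoff_quantile=0.001)
        # lowering the quantile can only lose assignments
        assert sum(a.assigned for a in out_lo) <= sum(a.assigned for a in out_hi)

    def test_tie_breaks_to_larger_training_count(self, reference_db):
        import copy

        db = copy.deepcopy(reference_db)
        # make two populations identical: tie at distance 0
        db.means["aaa_clone"] = db.means["nk_cells"].copy()
        db.covariances["aaa_clone"] = db.covariances["nk_cells"].copy()
        db.train_counts["aaa_clone"] = db.train_counts["nk_cells"] - 1
        panel = pk.pidot_panel()
        mean = db.means["nk_cells"]
        values = np.zeros((5, 14))
        for j, marker in enumerate(panel.fluorescence_names):
            values[:, panel.index(marker)] = mean[j]
        values[:, panel.index("FSC-A")] = mean[11] * 10_000
        values[:, panel.index("SSC-A")] = mean[12] * 10_000
        values[:, panel.index("FSC-H")] = values[:, panel.index("FSC-A")]
        events = pk.EventMatrix(values, panel=panel, scale="transformed",
                                cofactor=150.0)
        out = pk.classify_clusters(events, np.zeros(5, int), db)
        assert out[0].population == "nk_cells"  # larger n_train wins
        db.train_counts["aaa_clone"] = db.train_counts["nk_cells"]
        out = pk.classify_clusters(events, np.zeros(5, int), db)
        assert out[0].population == "aaa_clone"  # then lexicographic


class TestResolveChecks:
    def _assignments(self):
        return [
            pk.ClusterAssignment(0, np.arange(10), "nk_cells", 1.0, []),
            pk.ClusterAssignment(1, np.arange(10, 14), None, 99.0,
                                 [("tcrgd_pos_t", 99.0)]),
        ]

    def test_empty_map_unchanged(self):
        a = self._assignments()
        out = pk.resolve_checks(a, {})
        assert [x.population for x in out] == ["nk_cells", None]

    def test_check_mapped_and_flagged(self):
        out = pk.resolve_checks(self._assignments(), {1: "tcrgd_pos_t"})
        assert out[1].population == "tcrgd_pos_t"
        assert out[1].expert_resolved

    def test_discard_keeps_partition_with_excluded_bucket(self):
        out = pk.resolve_checks(self._assignments(), {1: "discard"})
        assert out[1].discarded and not out[1].assigned
        total = sum(len(x.event_indices) for x in out)
        assert total == 14  # no events vanish

    def test_touching_auto_assignment_requires_override(self):
        with pytest.raises(InputError):
            pk.resolve_checks(self._assignments(), {0: "tcrgd_pos_t"})
        out = pk.resolve_checks(
            self._assignments(), {0: "tcrgd_pos_t"}, allow_override=True
        )
        assert out[0].population == "tcrgd_pos_t"


class TestAutogateSample:
    def test_deterministic_report(self, hd_transformed, reference_db, hd_meta,
                                  reference_ranges):
        events, _ = hd_transformed
        sub = pk.EventMatrix(
            events.values[:30_000], panel=events.panel, sample_meta=hd_meta,
            scale="transformed", cofactor=events.cofactor,
        )
        r1, _, l1 = pk.autogate_sample(sub, reference_db, hd_meta,
                                       reference_ranges, seed=5)
        r2, _, l2 = pk.autogate_sample(sub, reference_db, hd_meta,
                                       reference_ranges, seed=5)
        assert (l1 == l2).all()
        assert r1.table.equals(r2.table)

    def test_partition_into_assigned_check_excluded(self, hd_transformed,
                                                    reference_db, hd_meta):
        events, _ = hd_transformed
        report, assignments, labels = pk.autogate_sample(
            events, reference_db, hd_meta, None, seed=2
        )
        lymphoid = ~np.isin(labels, ["doublet", "debris", "non_lymphoid"])
        n_assigned = sum(
            a.event_indices.size for a in assignments if a.assigned
        )
        n_check = sum(
            a.event_indices.size
            for a in assignments if not a.assigned and not a.discarded
        )
        assert n_assigned + n_check == lymphoid.sum()

    def test_unaberrated_hd_low_checks(self, hd_transformed, reference_db, hd_meta):
        events, _ = hd_transformed
        report, _, _ = pk.autogate_sample(events, reference_db, hd_meta, seed=2)
        assert report.checks_fraction < 0.01
        assert report.checks_fraction_total <= report.checks_fraction

    def test_below_p5_triggers_remark(self, hd_transformed, reference_db,
                                      reference_ranges):
        events, _ = hd_transformed
        # absurdly high WBC scales every absolute count above p95
        meta = pk.SampleMeta("HI", 35.0, 400_000.0, group="HD")
        inflated = pk.EventMatrix(
            events.values, panel=events.panel, sample_meta=meta,
            scale="transformed", cofactor=events.cofactor,
        )
        report, _, _ = pk.autogate_sample(
            inflated, reference_db, meta, reference_ranges, seed=2
        )
        assert report.table["remark"].all()
        assert (report.table["status"] == "above_p95").all()

    def test_normal_sample_no_remarks(self, hd_transformed, reference_db,
                                      reference_ranges, hd_meta):
        events, _ = hd_transformed
        report, _, _ = pk.autogate_sample(
            events, reference_db, hd_meta, reference_ranges, seed=2
        )
        assert not report.table["remark"].any()
        assert (report.table["status"] == "in_range").all()

    def test_checks_fraction_monotone_in_cutoff(self, hd_transformed,
                                                reference_db, hd_meta):
        events, _ = hd_transformed
        sub = pk.EventMatrix(
            events.values[:30_000], panel=events.panel, sample_meta=hd_meta,
            scale="transformed", cofactor=events.cofactor,
        )
        fractions = []
        for q in (0.5, 0.9, 0.99, 0.999):
            report, _, _ = pk.autogate_sample(
                sub, reference_db, hd_meta, None, seed=11, cutoff_quantile=q
            )
            fractions.append(report.checks_fraction)
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
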