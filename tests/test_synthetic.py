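"""Synthetic cohort generator: determinism, structure, recovery properties."""

import numpy as np
import pandas as pd
import pytest

import ssp50 as s
from ssp50.classifier import ClassifierConfig

from _oracles import spearman_brute
from conftest import accuracy


class TestMakeCentroids:
    def test_pairwise_rho_below_threshold(self):
        cs = s.make_centroids(n_genes=50, n_subtypes=5, separation=1.0, seed=3)
        cols = cs.values.to_numpy().T
        for i in range(5):
            for j in range(i + 1, 5):
                assert spearman_brute(cols[i], cols[j]) < 0.3

    def test_same_seed_identical(self):
        a = s.make_centroids(seed=9)
        b = s.make_centroids(seed=9)
        pd.testing.assert_frame_equal(a.values, b.values, check_exact=True)

    def test_single_subtype_unconstrained(self):
        cs = s.make_centroids(n_genes=10, n_subtypes=1, seed=0)
        assert cs.values.shape == (10, 1)


class TestGenerateCohort:
    def test_same_seed_bit_identical_different_seed_not(self, centroids):
        a = s.generate_cohort(s.SyntheticCohortSpec(seed=5), centroids)
        b = s.generate_cohort(s.SyntheticCohortSpec(seed=5), centroids)
        c = s.generate_cohort(s.SyntheticCohortSpec(seed=6), centroids)
        pd.testing.assert_frame_equal(
            a.expr_platform_A.values, b.expr_platform_A.values, check_exact=True
        )
        assert not a.expr_platform_B.values.equals(c.expr_platform_B.values)
        assert [r.followup_time for r in a.clinical] == [r.followup_time for r in b.clinical]

    def test_noisy_recovery_at_default_conditions(self, centroids):
        """noise_sd = 0.5 with 50 samples per subtype: platform-A SSP recovers
        >= 95% of true labels."""
        spec = s.SyntheticCohortSpec(
            n_per_subtype={t: 50 for t in s.SUBTYPES_4}, noise_sd=0.5, seed=21
        )
        cohort = s.generate_cohort(spec, centroids)
        calls = s.classify_cohort(cohort.expr_platform_A, centroids, ClassifierConfig(mode="SSP2"))
        assert accuracy(calls, cohort.true_labels) >= 0.95

    def test_missingness_applied_at_requested_rate(self, centroids):
        spec = s.SyntheticCohortSpec(missing_rate=0.1, seed=4)
        cohort = s.generate_cohort(spec, centroids)
        frac = cohort.expr_platform_A.values.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15

    def test_clinical_records_align_with_samples(self, default_cohort):
        ids = {r.sample_id for r in default_cohort.clinical}
        assert ids == set(default_cohort.expr_platform_A.samples)
        assert all(r.followup_time <= 11.6 for r in default_cohort.clinical)

    def test_invalid_spec_rejected(self, centroids):
        with pytest.raises(s.SSP50Error):
            s.generate_cohort(s.SyntheticCohortSpec(missing_rate=1.5), centroids)


class TestExpandToProbes:
    def test_single_probe_round_trip_exact(self, centroids, default_cohort):
        probes, ann = s.expand_to_probes(default_cohort.expr_platform_B, probes_per_gene=1, seed=0)
        collapsed = s.collapse_probes(probes, ann)
        assert np.array_equal(
            collapsed.values.to_numpy(), default_cohort.expr_platform_B.values.to_numpy()
        )

    def test_faithful_probe_selected_for_most_genes(self, default_cohort):
        probes, ann = s.expand_to_probes(default_cohort.expr_platform_B, probes_per_gene=3, seed=1)
        collapsed = s.collapse_probes(probes, ann)
        exact = (
            (collapsed.values - default_cohort.expr_platform_B.values).abs().max(axis=1) < 1e-12
        )
        assert exact.mean() >= 0.95

    def test_deterministic_under_seed(self, default_cohort):
        p1, _ = s.expand_to_probes(default_cohort.expr_platform_B, seed=7)
        p2, _ = s.expand_to_probes(default_cohort.expr_platform_B, seed=7)
        pd.testing.assert_frame_equal(p1.values, p2.values, check_exact=True)


class TestNormalPairs:
    def test_noiseless_normals_all_normal_like(self, centroids):
        spec = s.SyntheticCohortSpec(noise_sd=0.0, n_normal_pairs=10, seed=3)
        cohort = s.generate_cohort(spec, centroids)
        s.generate_normal_pairs(spec, centroids, cohort)
        calls = s.classify_cohort(cohort.normals_A, centroids, ClassifierConfig(mode="SSP5"))
        assert all(c.label == "Normal-like" for c in calls)

    def test_pairing_round_trips_through_summary(self, centroids):
        spec = s.SyntheticCohortSpec(noise_sd=1.5, n_normal_pairs=24, seed=13)
        cohort = s.generate_cohort(spec, centroids)
        s.generate_normal_pairs(spec, centroids, cohort)
        cfg5 = ClassifierConfig(mode="SSP5")
        normal_calls = s.classify_cohort(cohort.normals_A, centroids, cfg5)
        tumor_ids = [cohort.normal_pairing[c.sample_id] for c in normal_calls]
        tumor_sub = s.ExpressionMatrix(cohort.expr_platform_A.values[tumor_ids])
        tumor_calls = s.classify_cohort(tumor_sub, centroids, cfg5)
        out = s.normal_pair_summary(normal_calls, tumor_calls)
        assert out["n_pairs"] == 24
        assert 0 <= out["n_normal_like"] <= 24

    def test_missing_normal_centroid_errors(self, centroids):
        spec = s.SyntheticCohortSpec(seed=1)
        cohort = s.generate_cohort(spec, centroids)
        four = centroids.subset(list(s.SUBTYPES_4))
        with pytest.raises(s.SSP50Error, match="Normal-like"):
            s.generate_normal_pairs(spec, four, cohort)


class TestDigitalCountEmulation:
    def test_count_pipeline_recovers_log2_values_up_to_gene_constant(self, default_cohort):
        counts, neg_ids = s.emulate_digital_counts(default_cohort.expr_platform_A, seed=2)
        body = s.background_subtract(counts, neg_ids)
        norm = s.housekeeping_normalize(body)
        recovered = norm.values.loc[default_cohort.expr_platform_A.genes]
        diff = recovered - default_cohort.expr_platform_A.values
        # per-gene constant offset only: rows are constant across samples
        assert float((diff.max(axis=1) - diff.min(axis=1)).max()) < 1e-6

    def test_centered_counts_route_matches_centered_direct_route(self, default_cohort):
        counts, neg_ids = s.emulate_digital_counts(default_cohort.expr_platform_A, seed=2)
        norm = s.housekeeping_normalize(s.background_subtract(counts, neg_ids))
        via_counts = s.center_genes(
            s.ExpressionMatrix(norm.values.loc[default_cohort.expr_platform_A.genes])
        )
        direct = s.center_genes(default_cohort.expr_platform_A)
        assert np.allclose(
            via_counts.values.to_numpy(), direct.values.to_numpy(), atol=1e-6
        )


def test_cross_platform_kappa_increases_as_shift_shrinks(centroids):
    """Mean cross-platform kappa over replicates rises monotonically as the
    platform shift drops across a 3-point grid."""
    cfg = ClassifierConfig(mode="SSP2")
    mean_kappas = []
    for shift in (6.0, 3.0, 0.0):
        kappas = []
        for rep in range(20):
            spec = s.SyntheticCohortSpec(
                n_per_subtype={t: 15 for t in s.SUBTYPES_4},
                platform_shift_sd=shift,
                platform_scale_range=(1.0, 1.0),
                noise_sd=1.0,
                seed=100 + rep,
            )
            cohort = s.generate_cohort(spec, centroids)
            calls_A = s.classify_cohort(cohort.expr_platform_A, centroids, cfg)
            calls_B = s.classify_cohort(cohort.expr_platform_B, centroids, cfg)
            res = s.cohens_kappa(s.confusion_matrix(calls_A, calls_B))
            kappas.append(res.kappa if res.kappa is not None else 0.0)
        mean_kappas.append(np.mean(kappas))
    assert mean_kappas[0] < mean_kappas[1] < mean_kappas[2]
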