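"""Paired-call agreement statistics and IHC crosstabs."""

import numpy as np
import pandas as pd
import pytest

import ssp50 as s
from ssp50.concordance import phenotype_fraction
from ssp50.core import IHC_MISSING, UNCLASSIFIED, ClinicalRecord, SubtypeCall
from ssp50.fixtures import table2_calls, table4_calls, table_ihc_calls

from _oracles import kappa_brute


def make_calls(labels, prefix="P", mode="SSP2"):
    return [
        SubtypeCall(sample_id=f"{prefix}{i}", label=lab, mode=mode)
        for i, lab in enumerate(labels)
    ]


class TestConfusionMatrix:
    def test_identical_lists_give_diagonal(self):
        labels = ["Basal-like"] * 3 + ["LuminalA"] * 4
        res = s.confusion_matrix(make_calls(labels), make_calls(labels))
        M = res.matrix.to_numpy()
        assert M.sum() == 7 and np.trace(M) == 7

    def test_unclassified_pair_excluded_from_body(self):
        ref = make_calls(["LuminalA", "LuminalA", "LuminalB"])
        test = make_calls([UNCLASSIFIED, "LuminalA", "LuminalB"])
        res = s.confusion_matrix(ref, test)
        assert res.body_total == 2
        assert res.n_unclassified_excluded == 1
        assert res.n_pairs_total == 3

    def test_random_pairs_match_bruteforce_tally(self, rng):
        labs = list(s.SUBTYPES_4) + [UNCLASSIFIED]
        ref_labels = [labs[i] for i in rng.integers(0, 5, 200)]
        test_labels = [labs[i] for i in rng.integers(0, 5, 200)]
        res = s.confusion_matrix(make_calls(ref_labels), make_calls(test_labels))
        for t in res.matrix.index:
            for r in res.matrix.columns:
                expected = sum(
                    1 for a, b in zip(ref_labels, test_labels) if a == r and b == t
                )
                assert res.matrix.loc[t, r] == expected
        n_excl = sum(
            1 for a, b in zip(ref_labels, test_labels) if UNCLASSIFIED in (a, b)
        )
        assert res.n_unclassified_excluded == n_excl

    def test_unpaired_sample_errors(self):
        with pytest.raises(s.SSP50Error, match="unpaired"):
            s.confusion_matrix(make_calls(["LuminalA"]), make_calls(["LuminalA"], prefix="X"))


class TestAgreementAndKappa:
    def test_diagonal_only_matrix_has_unit_accuracy_everywhere(self):
        labels = ["Basal-like", "HER2-enriched", "LuminalA"] * 5
        res = s.per_class_accuracy(s.confusion_matrix(make_calls(labels), make_calls(labels)))
        for _, (_, _, p) in res.per_class_accuracy.items():
            assert p == 1.0

    def test_zero_diagonal_matrix_has_zero_agreement(self):
        ref = make_calls(["LuminalA", "LuminalB"])
        test = make_calls(["LuminalB", "LuminalA"])
        res = s.overall_agreement(s.confusion_matrix(ref, test))
        assert res.agreement == (0, 0.0)

    def test_perfect_agreement_kappa_is_one(self):
        labels = ["LuminalA"] * 3 + ["LuminalB"] * 3
        res = s.cohens_kappa(s.confusion_matrix(make_calls(labels), make_calls(labels)))
        assert res.kappa == pytest.approx(1.0)

    def test_chance_level_table_gives_zero_kappa(self):
        # 2x2 body [[1,1],[1,1]]: p_o = 1/2 = p_e
        ref = make_calls(["LuminalA", "LuminalA", "LuminalB", "LuminalB"])
        test = make_calls(["LuminalA", "LuminalB", "LuminalA", "LuminalB"])
        res = s.cohens_kappa(s.confusion_matrix(ref, test))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_matches_sklearn_on_random_tables(self, rng):
        for _ in range(10):
            labs = list(s.SUBTYPES_4)
            ref_labels = [labs[i] for i in rng.integers(0, 4, 100)]
            test_labels = [labs[i] for i in rng.integers(0, 4, 100)]
            res = s.cohens_kappa(s.confusion_matrix(make_calls(ref_labels), make_calls(test_labels)))
            # columns are ref: transpose for the pairwise expansion
            expected = kappa_brute(res.matrix.to_numpy().T)
            assert res.kappa == pytest.approx(expected, abs=1e-12)

    def test_permutation_of_class_order_leaves_statistics_unchanged(self, rng):
        labs = list(s.SUBTYPES_4)
        ref_labels = [labs[i] for i in rng.integers(0, 4, 120)]
        test_labels = [labs[i] for i in rng.integers(0, 4, 120)]
        res1 = s.concordance_report(make_calls(ref_labels), make_calls(test_labels))
        relabel = dict(zip(labs, ["W", "X", "Y", "Z"]))
        res2 = s.concordance_report(
            make_calls([relabel[l] for l in ref_labels]),
            make_calls([relabel[l] for l in test_labels]),
        )
        assert res1.agreement == res2.agreement
        assert res1.kappa == pytest.approx(res2.kappa, abs=1e-12)


class TestIHCCrosstab:
    def test_fractions_exclude_missing_ihc(self):
        calls = make_calls(["Basal-like"] * 6)
        clin = [
            ClinicalRecord(sample_id=f"P{i}", hr_status=hr, her2_status=h2)
            for i, (hr, h2) in enumerate(
                [("negative", "negative")] * 3
                + [("positive", "negative")] * 2
                + [(IHC_MISSING, IHC_MISSING)]
            )
        ]
        tab = s.ihc_crosstab(calls, clin)
        num, denom, frac = phenotype_fraction(tab, "Basal-like", ["HR-/HER2-"])
        assert (num, denom) == (3, 5)
        assert frac == pytest.approx(0.6)

    def test_all_missing_ihc_gives_undefined_fraction(self):
        calls = make_calls(["LuminalA"] * 3)
        clin = [ClinicalRecord(sample_id=f"P{i}") for i in range(3)]
        tab = s.ihc_crosstab(calls, clin)
        assert phenotype_fraction(tab, "LuminalA", ["HR+/HER2-"])[2] is None

    def test_unmatched_sample_errors(self):
        with pytest.raises(s.SSP50Error, match="clinical"):
            s.ihc_crosstab(make_calls(["LuminalA"]), [])


class TestNormalPairSummary:
    def test_all_normal_like_gives_vacuous_match_part(self):
        normals = make_calls(["Normal-like"] * 4, prefix="N", mode="SSP5")
        tumors = make_calls(["LuminalA"] * 4, prefix="T", mode="SSP5")
        out = s.normal_pair_summary(normals, tumors)
        assert out["n_normal_like"] == 4
        assert out["n_not_normal_like"] == 0
        assert out["frac_matching_tumor"] is None

    def test_ssp2_normal_calls_rejected(self):
        normals = make_calls(["LuminalA"], prefix="N", mode="SSP2")
        tumors = make_calls(["LuminalA"], prefix="T", mode="SSP2")
        with pytest.raises(s.SSP50Error, match="SSP5"):
            s.normal_pair_summary(normals, tumors)


class TestFixtureTables:
    """The transcribed study tables validate and regenerate printed counts."""

    @pytest.mark.parametrize("table_id, total", [("T1", 109), ("T2", 24), ("T3", 144), ("T4", 64)])
    def test_totals_validate(self, table_id, total):
        from ssp50.fixtures import load_fixture

        assert int(load_fixture(table_id).to_numpy().sum()) == total

    def test_t4_pairs_roundtrip_through_concordance(self):
        ref, test = table4_calls()
        res = s.concordance_report(ref, test)
        assert res.n_pairs_total == 64
        assert res.body_total == 63

    def test_t2_pairs_roundtrip_through_summary(self):
        normals, tumors = table2_calls()
        out = s.normal_pair_summary(normals, tumors)
        assert out["n_pairs"] == 24

    def test_t1_crosstab_counts(self):
        calls, clin = table_ihc_calls("T1")
        tab = s.ihc_crosstab(calls, clin)
        assert int(tab.to_numpy().sum()) == 109
        # the one unclassified case sits in the HR+/HER2- row
        assert tab.loc["HR+/HER2-", UNCLASSIFIED] == 1
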