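"""Response classification, concordance, and clinical-table statistics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from fltpet.errors import (
    DegenerateTestError,
    InvalidBackgroundError,
    SchemaError,
)
from fltpet.response import (
    ResponseLabel,
    chi_square_2x2,
    cohen_kappa,
    cohen_kappa_from_counts,
    cohort_summary,
    load_table1,
    load_table2,
    mrecist_binary,
    percent_change,
    pet_mrecist_concordance,
    pet_response,
    wilcoxon_rank,
)


class TestPercentChange:
    def test_no_change(self):
        assert percent_change(7.0, 7.0) == 0.0

    def test_threshold_boundary_case(self):
        assert percent_change(10.0, 8.0) == pytest.approx(-20.0)

    def test_clinical_magnitude(self):
        # a -55.5% change from any positive baseline
        assert percent_change(10.0, 4.45) == pytest.approx(-55.5)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InvalidBackgroundError):
            percent_change(0.0, 5.0)


class TestResponseLabels:
    @pytest.mark.parametrize("change,expected", [
        (-55.5, ResponseLabel.RESPONDER),
        (-12.2, ResponseLabel.NONRESPONDER),
        (-20.0, ResponseLabel.RESPONDER),   # inclusive threshold
        (-19.99, ResponseLabel.NONRESPONDER),
        (None, ResponseLabel.NOT_EVALUABLE),
    ])
    def test_pet_response(self, change, expected):
        assert pet_response(change) is expected

    def test_monotone_in_post_suv(self):
        """A lower posttreatment SUV can never flip responder -> nonresponder."""
        pre = 8.0
        posts = np.linspace(12.0, 0.1, 60)
        labels = [pet_response(percent_change(pre, p)) for p in posts]
        seen_responder = False
        for lab in labels:
            if lab is ResponseLabel.RESPONDER:
                seen_responder = True
            assert not (seen_responder and lab is ResponseLabel.NONRESPONDER)

    @pytest.mark.parametrize("cat,expected", [
        ("CR", ResponseLabel.RESPONDER), ("PR", ResponseLabel.RESPONDER),
        ("SD", ResponseLabel.NONRESPONDER), ("PD", ResponseLabel.NONRESPONDER),
        ("NE", ResponseLabel.NOT_EVALUABLE),
    ])
    def test_mrecist_binary(self, cat, expected):
        assert mrecist_binary(cat) is expected

    def test_unknown_category_rejected(self):
        with pytest.raises(SchemaError):
            mrecist_binary("XX")


class TestCohenKappa:
    def test_perfect_agreement(self):
        labels = ["r", "n", "r", "n", "r"]
        assert cohen_kappa(labels, labels).kappa == pytest.approx(1.0)

    def test_observed_crosstab(self):
        """The 12/2/2/8 agreement table gives kappa 0.657 (prints as 0.66)."""
        res = cohen_kappa_from_counts(12, 2, 2, 8)
        # brute-force arithmetic oracle
        po = 20 / 24
        pe = (14 / 24) * (14 / 24) + (10 / 24) * (10 / 24)
        assert res.kappa == pytest.approx((po - pe) / (1 - pe), rel=1e-12)
        assert res.kappa == pytest.approx(0.657, abs=5e-4)
        assert round(res.kappa, 2) == 0.66
        assert res.p_value < 0.005
        assert res.ci95[0] == pytest.approx(0.35, abs=0.01)
        assert res.ci95[1] == pytest.approx(0.96, abs=0.01)

    def test_matches_sklearn(self):
        a = ["r"] * 12 + ["r"] * 2 + ["n"] * 2 + ["n"] * 8
        b = ["r"] * 12 + ["n"] * 2 + ["r"] * 2 + ["n"] * 8
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_chance_level_agreement_is_zero(self):
        # po == pe by construction: counts (9, 3, 6, 2)
        res = cohen_kappa_from_counts(9, 3, 6, 2)
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_label_swap_invariance(self):
        a = ["r", "r", "n", "n", "r", "n", "r", "n"]
        b = ["r", "n", "n", "r", "r", "n", "n", "n"]
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa(b, a).kappa)
        swap = {"r": "n", "n": "r"}
        assert cohen_kappa([swap[x] for x in a], [swap[x] for x in b]).kappa == \
            pytest.approx(cohen_kappa(a, b).kappa)


class TestWilcoxon:
    def test_identical_groups_not_significant(self):
        out = wilcoxon_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert out["p_value"] >= 0.99

    def test_full_separation_exact_p(self):
        """n=5 vs n=5 with complete separation: exact two-sided p = 2/252."""
        out = wilcoxon_rank([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert out["p_value"] == pytest.approx(2 / 252, rel=1e-9)

    def test_paired_all_ties_rejected(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_rank([1, 2, 3], [1, 2, 3], paired=True)

    def test_small_groups_rejected(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_rank([1, 2], [3, 4, 5])


class TestChiSquare:
    def test_balanced_table_zero(self):
        assert chi_square_2x2([5, 5, 5, 5])["statistic"] == pytest.approx(0.0)

    def test_perfect_association(self):
        assert chi_square_2x2([10, 0, 0, 10])["statistic"] == pytest.approx(20.0)

    def test_matches_brute_force(self):
        a, b, c, d = 12, 2, 2, 8
        n = a + b + c + d
        obs = np.array([[a, b], [c, d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / n
        expected = ((obs - exp) ** 2 / exp).sum()
        assert chi_square_2x2([a, b, c, d])["statistic"] == pytest.approx(expected)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateTestError):
            chi_square_2x2([0, 0, 3, 4])


class TestLoaders:
    def test_lesion_table_counts(self):
        records = load_table1()
        assert len(records) == 26
        assert len({r.patient_id for r in records}) == 16

    def test_lesion_values_round_trip(self):
        records = load_table1()
        most_conspicuous = [r for r in records if r.patient_id == 10][0]
        assert most_conspicuous.suv60_mean_pre == 8.1
        assert most_conspicuous.suv60_max_pre == 20.4
        assert most_conspicuous.background_suv_mean == 7.7

    def test_not_evaluable_preserved(self):
        records = load_table1()
        ne = [r for r in records if r.pct_change_mean is None]
        assert len(ne) == 1 and ne[0].patient_id == 7

    def test_kinetic_table_counts_and_flags(self):
        records = load_table2()
        assert len(records) == 14
        flagged = {r.patient_id: r for r in records if r.flag}
        assert not flagged[1].vb_valid          # vb printed as 5.0E-0
        assert flagged[1].vb_raw == "5.0E-0"
        assert 18 in flagged                    # subject absent from lesion table

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(SchemaError):
            load_table1(p)


class TestCohortSummary:
    def test_published_aggregates(self):
        s = cohort_summary(load_table1())
        assert s["suv60_mean_pre"]["mean"] == pytest.approx(6.48, abs=0.005)
        assert s["suv60_max_pre"]["mean"] == pytest.approx(9.68, abs=0.005)
        assert s["pct_change_mean"]["mean"] == pytest.approx(-29.5, abs=0.05)
        assert s["pct_change_mean"]["n"] == 25

    def test_adding_not_evaluable_changes_nothing(self):
        from dataclasses import replace

        records = load_table1()
        extra = replace(records[0], mrecist="NE", pct_change_mean=None,
                        pct_change_max=None)
        a = cohort_summary(records)
        b = cohort_summary(records + [extra])
        for key in ("pct_change_mean", "pct_change_max"):
            assert a[key] == b[key]
        assert a["pet_responders"] == b["pet_responders"]
        assert a["mrecist_responders"] == b["mrecist_responders"]

    def test_single_record(self):
        records = [r for r in load_table1() if r.patient_id == 2]
        s = cohort_summary(records)
        assert s["suv60_mean_pre"]["mean"] == 4.3
        assert s["suv60_mean_pre"]["sd"] == 0.0


class TestFullTablePipeline:
    def test_responder_counts_and_concordance(self):
        """The complete lesion table yields 15/25 PET responders, 14/24
        conventional-imaging responders, and kappa 0.657 on the 24
        dual-evaluable lesions."""
        records = load_table1()
        s = cohort_summary(records)
        assert (s["pet_responders"]["count"], s["pet_responders"]["n"]) == (15, 25)
        assert (s["mrecist_responders"]["count"], s["mrecist_responders"]["n"]) == (14, 24)
        conc = pet_mrecist_concordance(records)
        assert conc.counts == (12, 2, 2, 8)
        assert conc.kappa == pytest.approx(0.657, abs=5e-4)
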