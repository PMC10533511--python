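"""Glycemic classification, exclusion cascade, subgroups, HOMA, outcome labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from faocohort.screening import (CC_DEFAULTS, ExclusionLog, GlycemicStatus,
                                 LgaReference, OGTTPanel, PregnancyRecord,
                                 apply_exclusions, assign_subgroup,
                                 classify_glycemic_status,
                                 default_lga_reference, homa_indices,
                                 label_outcomes)


def make_record(**kw):
    base = dict(id="r", age_years=30.0, prepreg_weight_kg=55.0, height_m=1.62,
                gct_mgdl=110.0)
    base.update(kw)
    return PregnancyRecord(**base)


class TestClassify:
    def test_screen_negative_needs_no_ogtt(self):
        res = classify_glycemic_status(make_record(gct_mgdl=120.0))
        assert res.status is GlycemicStatus.NGT_SCREEN_NEGATIVE

    def test_positive_without_ogtt_unclassifiable(self):
        res = classify_glycemic_status(make_record(gct_mgdl=140.0))
        assert res.status is GlycemicStatus.UNCLASSIFIABLE

    def test_one_value_abnormality(self):
        res = classify_glycemic_status(make_record(
            gct_mgdl=150.0, ogtt=OGTTPanel(90, 185, 150, 135)))
        assert res.status is GlycemicStatus.ONE_VALUE_ABNORMALITY
        assert res.n_abnormal == 1

    def test_gdm_three_abnormal(self):
        res = classify_glycemic_status(make_record(
            gct_mgdl=150.0, ogtt=OGTTPanel(100, 190, 160, 120)))
        assert res.status is GlycemicStatus.GDM
        assert res.n_abnormal == 3

    def test_missing_gct_raises(self):
        with pytest.raises(ValueError, match="missing GCT"):
            classify_glycemic_status(make_record(gct_mgdl=None))

    @pytest.mark.parametrize("pattern", list(itertools.product([0, 1], repeat=4)))
    def test_matches_bruteforce_threshold_count(self, pattern):
        """Inclusive exceedance count over all 2^4 abnormality patterns."""
        vals = [t + 5.0 if abn else t - 5.0
                for abn, t in zip(pattern, CC_DEFAULTS)]
        res = classify_glycemic_status(make_record(
            gct_mgdl=150.0, ogtt=OGTTPanel(*vals)))
        n = sum(pattern)
        expected = (GlycemicStatus.NGT_OGTT if n == 0 else
                    GlycemicStatus.ONE_VALUE_ABNORMALITY if n == 1 else
                    GlycemicStatus.GDM)
        assert res.status is expected
        if n != 1:
            assert res.n_abnormal == (n if n >= 2 else 0)

    def test_threshold_value_counts_as_abnormal(self):
        res = classify_glycemic_status(make_record(
            gct_mgdl=150.0, ogtt=OGTTPanel(95.0, 100, 100, 100)))
        assert res.status is GlycemicStatus.ONE_VALUE_ABNORMALITY


class TestExclusions:
    def test_empty_cohort(self):
        included, log = apply_exclusions([])
        assert included == []
        assert all(n_in == 0 and n_ex == 0 for _, n_in, n_ex, _ in log.stages)
        assert log.final_n == 0

    def test_planted_counts(self):
        cohort = (
            [make_record(id=f"pih{i}", pih_before_24gw=True) for i in range(5)]
            + [make_record(id=f"mw{i}", prepreg_weight_kg=None) for i in range(3)]
            + [make_record(id=f"mg{i}", gct_mgdl=None) for i in range(2)]
            + [make_record(id=f"gdm{i}", gct_mgdl=160.0,
                           ogtt=OGTTPanel(100, 190, 160, 120)) for i in range(4)]
            + [make_record(id=f"el{i}", delivered_elsewhere=True) for i in range(1)]
            + [make_record(id=f"ok{i}") for i in range(85)]
        )
        included, log = apply_exclusions(cohort)
        assert len(included) == 85
        by_stage = {s: e for s, _, e, _ in log.stages}
        assert by_stage["pih_before_24gw"] == 5
        assert by_stage["missing_weight"] == 3
        assert by_stage["missing_gct"] == 2
        assert by_stage["gdm"] == 4
        assert by_stage["delivered_elsewhere"] == 1

    @given(hst.lists(hst.tuples(hst.booleans(), hst.booleans(), hst.booleans(),
                                hst.booleans()), max_size=60))
    def test_log_telescopes_to_final_n(self, flags):
        """Stage-wise n_in/n_excluded conservation for arbitrary cohorts."""
        cohort = [
            make_record(id=str(i), pih_before_24gw=pih,
                        prepreg_weight_kg=None if mw else 55.0,
                        gct_mgdl=None if mg else 120.0,
                        delivered_elsewhere=el)
            for i, (pih, mw, mg, el) in enumerate(flags)
        ]
        included, log = apply_exclusions(cohort)
        assert log.stages[0][1] == len(cohort)
        for prev, cur in zip(log.stages, log.stages[1:]):
            assert cur[1] == prev[1] - prev[2]
        assert log.final_n == len(included)

    def test_log_rejects_non_telescoping_stage(self):
        log = ExclusionLog()
        log.add("a", 10, 2, "r")
        with pytest.raises(ValueError):
            log.add("b", 9, 0, "r")


class TestSubgroups:
    @pytest.mark.parametrize("age,bmi,expected", [
        (31.0, 20.0, "G1"),
        (35.0, 25.0, "G4"),       # both boundaries inclusive
        (36.0, 21.0, "G3"),
        (30.0, 25.0, "G2"),
        (34.999, 24.999, "G1"),
    ])
    def test_boundaries(self, age, bmi, expected):
        assert assign_subgroup(age, bmi) == expected

    @given(hst.floats(16.0, 50.0), hst.floats(14.0, 45.0))
    def test_partition(self, age, bmi):
        assert assign_subgroup(age, bmi) in {"G1", "G2", "G3", "G4"}

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError):
            assign_subgroup(None, 22.0)


class TestHoma:
    @pytest.mark.parametrize("glucose,insulin,ir,beta", [
        (90.0, 7.2, 1.60, 96.0),
        (81.0, 5.0, 1.00, 100.0),
    ])
    def test_closed_forms(self, glucose, insulin, ir, beta):
        got_ir, got_beta = homa_indices(glucose, insulin)
        assert got_ir == pytest.approx(ir, rel=1e-9)
        assert got_beta == pytest.approx(beta, rel=1e-9)

    def test_beta_undefined_at_singular_glucose(self):
        got_ir, got_beta = homa_indices(63.0, 5.0)
        assert got_ir == pytest.approx(63.0 * 5.0 / 405.0, rel=1e-9)
        assert got_beta is None

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            homa_indices(0.0, 5.0)


class TestOutcomeLabels:
    @pytest.fixture
    def ref(self):
        return LgaReference(pd.DataFrame(
            {"ga_week": [39, 39], "sex": ["male", "female"],
             "p90_g": [3600.0, 3550.0]}))

    def test_macrosomia_inclusive_at_4kg(self, ref):
        rec = make_record(birth_weight_g=4000.0, ga_delivery_days=39 * 7.0)
        assert label_outcomes(rec, ref)["macrosomia"] is True

    def test_lga_inclusive_at_p90(self, ref):
        rec = make_record(birth_weight_g=3600.0, ga_delivery_days=39 * 7.0,
                          infant_sex="male")
        assert label_outcomes(rec, ref)["lga"] is True

    def test_below_p90_not_lga(self, ref):
        rec = make_record(birth_weight_g=3500.0, ga_delivery_days=39 * 7.0,
                          infant_sex="male")
        assert label_outcomes(rec, ref)["lga"] is False

    def test_ga_outside_reference_flags_lga_missing(self, ref):
        rec = make_record(birth_weight_g=4200.0, ga_delivery_days=33 * 7.0)
        out = label_outcomes(rec, ref)
        assert out["lga"] is None
        assert out["macrosomia"] is True

    def test_default_reference_covers_term_window(self):
        ref = default_lga_reference()
        for w in range(34, 41):
            for sex in ("male", "female"):
                assert ref.p90(w, sex) is not None
                assert ref.p90(w, sex) < 4000.0
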