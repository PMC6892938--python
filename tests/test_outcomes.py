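"""Outcome labels, contingency tables and exact binomial intervals."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from sibcnv.outcomes import (
    ContingencyTable,
    OutcomeError,
    PsychometricRecord,
    assign_outcome_label,
    build_contingency,
    clopper_pearson,
    diagnostic_stats,
    round2,
)


def rec(**kw):
    defaults = dict(individual_id="S1", clinician_asd_flag=False)
    defaults.update(kw)
    return PsychometricRecord(**defaults)


class TestBsrcLabels:
    def test_clinician_flag_drives_asd(self):
        out = assign_outcome_label(rec(clinician_asd_flag=True, ados_css=7))
        assert out.label == "ASD"
        assert "ados_css>=4" in out.criteria_met

    def test_all_scores_normal_is_typical(self):
        out = assign_outcome_label(rec(ados_css=1, msel_elc=100, vabs_abc=100))
        assert out.label == "typical"

    @pytest.mark.parametrize(
        "fields,criterion",
        [
            (dict(msel_elc=80), "developmental_delay"),
            (dict(msel_expressive_language=82), "language_delay_expressive"),
            (dict(msel_receptive_language=84), "language_delay_receptive"),
            (dict(vabs_abc=80), "adaptive_behavior_deficit"),
            (dict(vabs_subscale_min=83), "adaptive_behavior_deficit"),
            (dict(ados_css=3, adir_positive=True), "elevated_asd_symptoms"),
            (dict(clinician_atypical_flag=True), "clinician_atypical_pattern"),
        ],
    )
    def test_subthreshold_criteria_give_atypical(self, fields, criterion):
        out = assign_outcome_label(rec(**fields))
        assert out.label == "atypical"
        assert criterion in out.criteria_met

    def test_css3_without_support_is_not_atypical(self):
        out = assign_outcome_label(rec(ados_css=3))
        assert out.label == "typical"

    def test_missing_clinician_flag_is_error(self):
        with pytest.raises(OutcomeError, match="clinician_asd_flag"):
            assign_outcome_label(PsychometricRecord("S1", msel_elc=100), "BSRC")


class TestSscLabels:
    def test_single_instrument_above_cutoff(self):
        out = assign_outcome_label(rec(srs_t=62, cbcl_t=55, vabs_abc=100), "SSC")
        assert out.label == "atypical"
        assert out.criteria_met == ("srs_t>60",)

    def test_cutoffs_are_strict(self):
        out = assign_outcome_label(rec(srs_t=60, cbcl_t=60, vabs_abc=85), "SSC")
        assert out.label == "typical"

    def test_vabs_below_85(self):
        assert assign_outcome_label(rec(vabs_abc=84.5), "SSC").label == "atypical"

    def test_no_instrument_is_error(self):
        with pytest.raises(OutcomeError, match="at least one"):
            assign_outcome_label(rec(), "SSC")


class TestContingency:
    def test_bsrc_fixture_counts_both_conditions(self):
        """13 carriers (6 ASD / 5 atypical / 2 typical) among 103/54/131."""
        labels, carrier = {}, {}
        idx = 0
        for label, total, carriers in (("ASD", 103, 6), ("atypical", 54, 5),
                                       ("typical", 131, 2)):
            for i in range(total):
                sid = f"s{idx}"
                idx += 1
                labels[sid] = label
                carrier[sid] = i < carriers
        asd = build_contingency(carrier, labels, "ASD")
        assert (asd.tp, asd.fp, asd.fn, asd.tn) == (6, 7, 97, 178)
        both = build_contingency(carrier, labels, "ASD_or_atypical")
        assert (both.tp, both.fp, both.fn, both.tn) == (11, 2, 146, 129)
        assert asd.total == both.total == 288

    def test_empty_cohort(self):
        t = build_contingency({}, {}, "ASD")
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 0)

    def test_unlabeled_individual_is_error(self):
        with pytest.raises(OutcomeError, match="unlabeled"):
            build_contingency({"a": True}, {}, "ASD")


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [(6, 13, 0.19, 0.75), (3, 6, 0.12, 0.88), (11, 13, 0.55, 0.98)],
    )
    def test_reference_intervals(self, k, n, lo, hi):
        got_lo, got_hi = clopper_pearson(k, n)
        assert round2(got_lo) == lo
        assert round2(got_hi) == hi

    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    @pytest.mark.parametrize("k,n", [(0, 7), (1, 30), (17, 40), (288, 288), (97, 275)])
    def test_agrees_with_statsmodels_beta_method(self, k, n):
        lo, hi = clopper_pearson(k, n)
        ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(ref_lo, abs=1e-12)
        assert hi == pytest.approx(ref_hi, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(OutcomeError):
            clopper_pearson(1, 0)
        with pytest.raises(OutcomeError):
            clopper_pearson(5, 4)

    def test_coverage_is_conservative(self):
        """95% intervals cover the true p in >= 95% of simulated binomials."""
        rng = np.random.default_rng(42)
        p, n, reps = 0.46, 13, 2000
        ks = rng.binomial(n, p, size=reps)
        covered = 0
        for k in np.unique(ks):
            lo, hi = clopper_pearson(int(k), n)
            if lo <= p <= hi:
                covered += int((ks == k).sum())
        assert covered / reps >= 0.95


class TestDiagnosticStats:
    def test_reference_table_column(self):
        s = diagnostic_stats(ContingencyTable(6, 7, 97, 178))
        assert round2(s.ppv.point) == 0.46
        assert round2(s.sensitivity.point) == 0.06
        assert round2(s.specificity.point) == 0.96
        assert round2(s.npv.point) == 0.65

    def test_strict_column(self):
        s = diagnostic_stats(ContingencyTable(5, 1, 152, 130))
        assert round2(s.ppv.point) == 0.83
        assert round2(s.sensitivity.point) == 0.03
        assert round2(s.specificity.point) == 0.99
        assert round2(s.npv.point) == 0.46

    def test_degenerate_table(self):
        s = diagnostic_stats(ContingencyTable(1, 0, 0, 1))
        assert s.sensitivity.point == 1.0
        assert s.specificity.point == 1.0

    def test_zero_denominator_reported_undefined(self):
        s = diagnostic_stats(ContingencyTable(0, 0, 5, 5))
        assert s.ppv is None  # no carriers: PPV undefined, not 0
        assert s.sensitivity is not None

    def test_ci_bounds_bracket_point(self):
        s = diagnostic_stats(ContingencyTable(6, 7, 97, 178))
        for e in (s.sensitivity, s.specificity, s.ppv, s.npv):
            assert e.lo <= e.point <= e.hi
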