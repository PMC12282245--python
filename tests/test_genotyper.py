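"""Ratio measurement, copy-number classification, evidence rules and
genotype assembly."""

import dataclasses
from itertools import combinations_with_replacement

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cefacall as cc
from cefacall.genotyper import (
    CONTROL_AMEL_MISSING,
    CONTROL_GAPDH_MISSING,
    NO_CALL,
    ZYGOSITY_UNRESOLVED,
)


def _binding(panel, sample):
    return cc.bind_peaks(sample.peak_table.peaks, panel)


def _measurement(a1, a2, y1, y2):
    absent = frozenset(
        t for t, h in zip(("a1", "a2", "Y1", "Y2"), (a1, a2, y1, y2)) if h == 0
    )
    return cc.genotyper.RatioMeasurement(
        h_a1=a1, h_a2=a2, h_y1=y1, h_y2=y2,
        a_ratio=a1 / a2 if a2 else None,
        y_ratio=y1 / y2 if y2 else None,
        absent=absent,
    )


class TestComputeRatios:
    def test_typical_wildtype_heights(self, panel, zero_params):
        """Heights constructed to reproduce the typical measured wild-type
        ratios (1.04 and 0.92)."""
        peaks = [
            cc.Peak(dye="NED", size=85.0, height=1040.0),   # a1
            cc.Peak(dye="NED", size=91.0, height=1000.0),   # a2
            cc.Peak(dye="VIC", size=91.0, height=920.0),    # Y1
            cc.Peak(dye="VIC", size=97.0, height=1000.0),   # Y2
            cc.Peak(dye="FAM", size=85.0, height=2000.0),   # GAPDH
            cc.Peak(dye="VIC", size=85.0, height=2000.0),   # AMEL
        ]
        m = cc.compute_ratios(cc.bind_peaks(peaks, panel), panel)
        assert m.a_ratio == pytest.approx(1.04)
        assert m.y_ratio == pytest.approx(0.92)
        assert m.absent == frozenset()

    def test_zero_denominator_is_undefined(self, panel, zero_params):
        sample = cc.simulate_peak_table("-a3.7/-a4.2;bN/bN", panel, zero_params)
        m = cc.compute_ratios(_binding(panel, sample), panel)
        assert m.a_ratio is None
        assert "a2" in m.absent

    def test_equal_heights_give_unit_ratios(self, panel, zero_params):
        sample = cc.simulate_peak_table("aa/aa;bN/bN", panel, zero_params)
        m = cc.compute_ratios(_binding(panel, sample), panel)
        assert m.a_ratio == 1.0 and m.y_ratio == 1.0

    def test_subthreshold_peak_counts_as_absent(self, panel):
        peaks = [
            cc.Peak(dye="NED", size=85.0, height=1000.0),
            cc.Peak(dye="NED", size=91.0, height=50.0),  # below threshold
        ]
        m = cc.compute_ratios(cc.bind_peaks(peaks, panel), panel)
        assert m.a_ratio is None and "a2" in m.absent


class TestClassifyCnv:
    @pytest.mark.parametrize("a, y, expected", [
        (2.02, 0.48, "-a3.7/aa"),     # the measured cohort means
        (1.0, 1.0, "aa/aa"),
        (1.88, 2.05, "-a4.2/aa"),
        (0.74, 1.52, "aaa_anti3.7/aa"),
        (0.57, 0.53, "aaa_anti4.2/aa"),
        (0.97, 0.35, "HKaa/aa"),
    ])
    def test_measured_means_classify_correctly(self, panel, a, y, expected):
        m = _measurement(1000 * a, 1000, 1000 * y, 1000)
        assert cc.classify_cnv(m, panel).class_name == expected

    def test_far_from_all_classes_is_no_call(self, panel):
        call = cc.classify_cnv(_measurement(5000, 1000, 5000, 1000), panel)
        assert call.class_name == NO_CALL
        assert call.reason in ("ABOVE_MAX_Z", "TIE")

    def test_absence_pattern_routes_to_extended_class(self, panel):
        m = _measurement(2000, 0, 1000, 1000)  # a2 absent: -a3.7/-a4.2 pattern
        call = cc.classify_cnv(m, panel)
        assert call.is_call
        cls = next(c for c in panel.ratio_classes if c.name == call.class_name)
        assert cls.zero_pattern == frozenset({"a2"})

    def test_total_absence_called_by_pattern_alone(self, panel):
        call = cc.classify_cnv(_measurement(0, 0, 0, 0), panel)
        assert call.is_call
        cls = next(c for c in panel.ratio_classes if c.name == call.class_name)
        assert cls.zero_pattern == frozenset({"a1", "a2", "Y1", "Y2"})

    @given(c=st.floats(0.2, 50.0))
    def test_scale_invariance(self, panel, c):
        base = (2000.0, 1000.0, 1000.0, 2000.0)
        ref = cc.classify_cnv(_measurement(*base), panel)
        scaled = cc.classify_cnv(_measurement(*(h * c for h in base)), panel)
        assert scaled.class_name == ref.class_name == "-a3.7/aa"


class TestControlsQc:
    def test_wildtype_has_no_flags(self, panel, zero_params):
        sample = cc.simulate_peak_table("aa/aa;bN/bN", panel, zero_params)
        assert cc.check_controls(_binding(panel, sample), panel) == []

    def test_missing_gapdh_is_uninterpretable(self, panel, zero_params):
        sample = cc.simulate_peak_table("aa/aa;bN/bN", panel, zero_params)
        peaks = [p for p in sample.peak_table.peaks
                 if not (p.dye == "FAM" and abs(p.size - 85.0) < 1)]
        table = cc.PeakTable(sample_id="s", peaks=peaks)
        call = cc.call_sample(table, panel)
        assert call.status == "UNINTERPRETABLE"
        assert CONTROL_GAPDH_MISSING in call.qc_flags
        assert call.genotypes == []

    def test_global_dropout_flags_both_controls(self, panel, zero_params):
        sample = cc.simulate_peak_table("aa/aa;bN/bN", panel, zero_params)
        peaks = [dataclasses.replace(p, height=p.height * 0.01)
                 for p in sample.peak_table.peaks]
        flags = cc.check_controls(cc.bind_peaks(peaks, panel), panel)
        assert set(flags) == {CONTROL_GAPDH_MISSING, CONTROL_AMEL_MISSING}

    @given(seed=st.integers(0, 2**20))
    def test_removing_a_control_never_yields_a_genotype(self, panel, seed):
        rng = np.random.default_rng(seed)
        labels = ["aa/aa;bN/bN", "-a3.7/aa;bCD17/bN", "aWSa/--SEA;bCD37/bN"]
        label = labels[int(rng.integers(len(labels)))]
        control = ["GAPDH", "AMEL"][int(rng.integers(2))]
        sample = cc.simulate_peak_table(label, panel, seed=seed)
        target = cc.default_panel().target(control)
        peaks = [p for p in sample.peak_table.peaks
                 if not (p.dye == target.dye and abs(p.size - target.expected_size) < 1.4)]
        call = cc.call_sample(cc.PeakTable(sample_id="s", peaks=peaks), panel)
        assert call.status == "UNINTERPRETABLE"
        assert call.genotypes == []


class TestCallMutations:
    def _zygosity(self, panel, zero_params, label):
        sample = cc.simulate_peak_table(label, panel, zero_params)
        return cc.call_mutations(_binding(panel, sample), panel)

    def test_het_with_wildtype_control(self, panel, zero_params):
        z = self._zygosity(panel, zero_params, "aa/aa;bCD17/bN")
        assert z["bCD17"] == "HET"

    def test_hom_when_control_absent(self, panel, zero_params):
        z = self._zygosity(panel, zero_params, "aa/aa;bCD17/bCD17")
        assert z["bCD17"] == "HOM"

    def test_het_or_hom_without_control(self, panel, zero_params):
        z = self._zygosity(panel, zero_params, "aa/aa;bCD37/bN")
        assert z["bCD37"] == "HET_OR_HOM"

    def test_deletion_in_trans_mimics_hom(self, panel, zero_params):
        """A whole-gene deletion removes the wild-type site, so a single
        mutant allele shows the homozygous peak pattern."""
        z = self._zygosity(panel, zero_params, "aWSa/--SEA;bN/bN")
        assert z["aWS"] == "HOM"

    def test_wildtype_sample_is_all_absent(self, panel, zero_params):
        z = self._zygosity(panel, zero_params, "aa/aa;bN/bN")
        assert set(z.values()) == {"ABSENT"}


class TestAssembleGenotype:
    def _call(self, panel, catalog, label, seed=0):
        sample = cc.simulate_peak_table(label, panel, cc.zero_noise_params(), seed=seed)
        return cc.call_sample(sample.peak_table, panel, catalog)

    def test_compound_deletion_with_two_point_mutations(self, panel, catalog):
        call = self._call(panel, catalog, "aCD74a/-a4.2;bCD17/bN")
        assert call.status == "OK"
        assert call.labels(panel) == ["aCD74a/-a4.2;bCD17/bN"]
        assert call.measurement.a_ratio == 2.0
        assert call.measurement.y_ratio == 2.0

    def test_irreducible_zygosity_ambiguity(self, panel, catalog):
        call = self._call(panel, catalog, "aWSa/--SEA;bCD37/bN")
        assert call.status == "AMBIGUOUS"
        assert sorted(call.labels(panel)) == [
            "aWSa/--SEA;bCD37/bCD37",
            "aWSa/--SEA;bCD37/bN",
        ]
        assert ZYGOSITY_UNRESOLVED in call.qc_flags
        assert call.measurement.a_ratio == 1.0
        assert call.measurement.y_ratio == 1.0

    def test_wildtype_parsimonious_first(self, panel, catalog):
        """Wild-type dosage also fits trans deletion+triplication compounds;
        all are reported, simplest interpretation first."""
        call = self._call(panel, catalog, "aa/aa;bN/bN")
        assert call.status == "AMBIGUOUS"
        assert call.labels(panel)[0] == "aa/aa;bN/bN"
        assert set(call.labels(panel)) == {
            "aa/aa;bN/bN",
            "-a3.7/aaa_anti3.7;bN/bN",
            "-a4.2/aaa_anti4.2;bN/bN",
        }

    def test_conflicting_evidence_is_no_call(self, panel, catalog):
        # SEA breakpoint with clean 2:1 / 1:2 dosage: no genotype predicts both
        sample = cc.simulate_peak_table(
            "-a3.7/aa;bN/bN", panel, cc.zero_noise_params()
        )
        sea = panel.target("SEA")
        peaks = sample.peak_table.peaks + [
            cc.Peak(dye=sea.dye, size=sea.expected_size, height=2000.0)
        ]
        call = cc.call_sample(cc.PeakTable(sample_id="s", peaks=peaks), panel, catalog)
        assert call.status == NO_CALL
        assert "alpha_evidence" in call.explanation["failed_constraint"]

    @given(seed=st.integers(0, 2**20))
    def test_no_false_concordance(self, panel, catalog, seed):
        """Every reported candidate predicts exactly the observed mutation and
        marker peaks (checked against the independent peak-set oracle)."""
        rng = np.random.default_rng(seed)
        alpha = sorted(a.name for a in panel.alleles_in_cluster("alpha"))
        beta = sorted(a.name for a in panel.alleles_in_cluster("beta"))
        genotype = cc.Genotype(
            alpha=tuple(rng.choice(alpha, 2)), beta=tuple(rng.choice(beta, 2))
        )
        sample = cc.simulate_peak_table(genotype, panel, seed=seed)
        call = cc.call_sample(sample.peak_table, panel, catalog)
        if call.status not in ("OK", "AMBIGUOUS"):
            return
        evidence_targets = {
            t.name for t in panel.targets
            if t.role in ("point_mutation", "deletion_breakpoint")
        }
        observed = (
            call.evidence.mutations_present | call.evidence.markers_present
        )
        for candidate in call.genotypes:
            predicted = cc.expected_peak_set(candidate, panel) & evidence_targets
            assert predicted == observed
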