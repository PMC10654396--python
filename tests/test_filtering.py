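"""Consensus merge, filter cascade, rescue and TMB."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmexome.core import FunctionalClass, Preservation, SampleMeta, SiteType
from lmexome.filtering import (
    FilterConfig,
    FilterReason,
    PurityStratum,
    ReadThresholds,
    apply_filters,
    compute_tmb,
    merge_callers,
    purity_stratum,
    rescue_cross_sample,
    vaf_threshold,
)

from conftest import make_call


def meta(sample_id="S1", purity=0.6, preservation=Preservation.CFDNA, patient="P1"):
    return SampleMeta(
        sample_id=sample_id,
        patient=patient,
        site_type=SiteType.CSF,
        preservation=preservation,
        purity_model=purity,
        ploidy_model=2.0,
        purity=purity,
        ploidy=2.0,
    )


class TestMerge:
    def test_single_caller_variant_excluded(self):
        merged = merge_callers({"mutect2": [make_call(callers=("mutect2",))]})
        assert merged == []

    def test_two_caller_variant_retained(self):
        per_caller = {
            "muse": [make_call(callers=("muse",))],
            "lofreq": [make_call(callers=("lofreq",), germline=None)],
        }
        merged = merge_callers(per_caller)
        assert len(merged) == 1
        assert merged[0].callers == {"muse", "lofreq"}

    def test_read_counts_max_reconciled(self):
        per_caller = {
            c: [make_call(callers=(c,), alt_reads=a, depth=d)]
            for c, a, d in [
                ("mutect2", 8, 40),
                ("muse", 9, 42),
                ("strelka", 10, 39),
                ("lofreq", 7, 41),
            ]
        }
        for calls in per_caller.values():
            for i, c in enumerate(calls):
                calls[i] = dataclasses.replace(c, vaf=c.tumour_alt_reads / c.depth)
        (m,) = merge_callers(per_caller)
        assert m.tumour_alt_reads == 10
        assert m.depth == 42
        assert m.vaf == pytest.approx(10 / 42)

    def test_germline_unavailable_only_when_no_caller_reports(self):
        both_none = merge_callers(
            {
                "lofreq": [make_call(callers=("lofreq",), germline=None)],
                "muse": [make_call(callers=("muse",), germline=None)],
            }
        )
        assert both_none[0].germline_alt_reads is None
        one_reports = merge_callers(
            {
                "lofreq": [make_call(callers=("lofreq",), germline=None)],
                "muse": [make_call(callers=("muse",), germline=1)],
            }
        )
        assert one_reports[0].germline_alt_reads == 1

    def test_duplicate_key_within_caller_max_merged(self, caplog):
        with caplog.at_level("WARNING"):
            merged = merge_callers(
                {
                    "muse": [
                        make_call(callers=("muse",), alt_reads=5, depth=50),
                        make_call(callers=("muse",), alt_reads=9, depth=50),
                    ],
                    "strelka": [make_call(callers=("strelka",), alt_reads=6, depth=50)],
                }
            )
        assert merged[0].tumour_alt_reads == 9
        assert "duplicate" in caplog.text


class TestVafThreshold:
    @pytest.mark.parametrize(
        "purity,preservation,substitution,expected",
        [
            (0.6, Preservation.CFDNA, "C>T", 0.05),
            (0.6, Preservation.FFPE, "C>T", 0.07),
            (0.15, Preservation.CFDNA, "C>T", 0.01),
            (0.15, Preservation.FFPE, "C>T", 0.03),
            (0.35, Preservation.FFPE, "T>A", 0.03),  # non-artifact class: standard
            (0.35, Preservation.FFPE, "C>T", 0.05),
            (0.35, Preservation.CFDNA, "C>T", 0.03),
            (0.5, Preservation.CFDNA, "C>A", 0.03),  # 0.5 is intermediate, not high
            (0.2, Preservation.CFDNA, "C>A", 0.01),  # 0.2 is low stratum
            (1.0, Preservation.FFPE, "INDEL", 0.05),  # indels never artifact class
        ],
    )
    def test_threshold_table(self, purity, preservation, substitution, expected):
        assert vaf_threshold(purity, preservation, substitution) == expected

    def test_purity_domain_error(self):
        with pytest.raises(ValueError):
            vaf_threshold(0.0, Preservation.CFDNA, "C>T")
        with pytest.raises(ValueError):
            vaf_threshold(1.2, Preservation.CFDNA, "C>T")

    def test_strata_partition_unit_interval(self):
        assert purity_stratum(0.51) is PurityStratum.HIGH
        assert purity_stratum(0.5) is PurityStratum.INTERMEDIATE
        assert purity_stratum(0.21) is PurityStratum.INTERMEDIATE
        assert purity_stratum(0.2) is PurityStratum.LOW

    def test_artifact_threshold_never_below_standard(self):
        with pytest.raises(ValueError):
            FilterConfig(
                vaf_thresholds={
                    (PurityStratum.HIGH, False): 0.05,
                    (PurityStratum.HIGH, True): 0.04,
                    (PurityStratum.INTERMEDIATE, False): 0.03,
                    (PurityStratum.INTERMEDIATE, True): 0.05,
                    (PurityStratum.LOW, False): 0.01,
                    (PurityStratum.LOW, True): 0.03,
                }
            )


class TestApplyFilters:
    def test_low_tumour_reads_rejected(self):
        (v,) = apply_filters([make_call(alt_reads=4, depth=40)], meta())
        assert not v.kept and v.reasons == {FilterReason.LOW_TUMOUR_READS}

    def test_override_sample_reduced_thresholds(self):
        config = FilterConfig(per_sample_overrides={"S1": ReadThresholds(3, 1, 7)})
        call = make_call(alt_reads=3, depth=7, germline=1)
        (v,) = apply_filters([call], meta(), config)
        assert v.kept
        # the same call fails under default thresholds
        (v2,) = apply_filters([call], meta(), FilterConfig())
        assert v2.reasons == {FilterReason.LOW_TUMOUR_READS, FilterReason.LOW_DEPTH}

    def test_germline_unavailable_waives_filter(self):
        call = make_call(callers=("lofreq", "muse"), germline=None)
        (v,) = apply_filters([call], meta())
        assert v.kept

    def test_high_germline_rejected(self):
        (v,) = apply_filters([make_call(germline=3)], meta())
        assert v.reasons == {FilterReason.HIGH_GERMLINE_READS}

    def test_intronic_rejected(self):
        (v,) = apply_filters([make_call(fclass=FunctionalClass.OTHER)], meta())
        assert v.reasons == {FilterReason.NON_EXONIC}

    def test_synonymous_kept_through_filtering(self):
        (v,) = apply_filters([make_call(fclass=FunctionalClass.EXONIC_SYNONYMOUS)], meta())
        assert v.kept

    def test_vaf_inclusive_boundary(self):
        call = make_call(alt_reads=5, depth=100)  # vaf exactly 0.05
        (v,) = apply_filters([call], meta(purity=0.6))
        assert v.kept

    def test_missing_purity_is_precondition_error(self):
        m = meta()
        m.purity = None
        with pytest.raises(ValueError, match="purity"):
            apply_filters([make_call()], m)

    def test_idempotent_on_kept_set(self):
        calls = [make_call(pos=p) for p in (100, 200, 300)]
        verdicts = apply_filters(calls, meta())
        kept = [v.call for v in verdicts if v.kept]
        again = apply_filters(kept, meta())
        assert all(v.kept for v in again)
        assert [v.call for v in again] == kept

    @given(
        alt=st.integers(0, 60),
        depth=st.integers(1, 200),
        germline=st.one_of(st.none(), st.integers(0, 10)),
        purity=st.floats(0.05, 1.0),
        extra_tumour=st.integers(0, 5),
        extra_depth=st.integers(0, 5),
    )
    @settings(max_examples=150, deadline=None)
    def test_threshold_monotonicity(self, alt, depth, germline, purity, extra_tumour, extra_depth):
        """Raising any read threshold never turns a rejected call into a kept one."""
        alt = min(alt, depth)
        call = make_call(alt_reads=alt, depth=depth, germline=germline)
        m = meta(purity=purity)
        base = FilterConfig()
        stricter = FilterConfig(
            read_thresholds=ReadThresholds(
                base.read_thresholds.min_tumour_reads + extra_tumour,
                base.read_thresholds.max_germline_reads,
                base.read_thresholds.min_depth + extra_depth,
            )
        )
        kept_base = apply_filters([call], m, base)[0].kept
        kept_strict = apply_filters([call], m, stricter)[0].kept
        assert kept_strict <= kept_base


class TestRescue:
    def _verdicts(self, sample_id, calls, purity=0.6, patient="P1"):
        return apply_filters(calls, meta(sample_id=sample_id, purity=purity, patient=patient))

    def test_failing_variant_rescued_when_passing_elsewhere(self):
        passing = make_call(alt_reads=20, depth=80)
        failing = make_call(alt_reads=8, depth=9)  # same key, low depth
        verdicts = {
            "CSF": self._verdicts("CSF", [passing]),
            "primary": self._verdicts("primary", [failing]),
        }
        final = rescue_cross_sample(verdicts)
        assert {c.key for c in final["CSF"]} == {passing.key}
        assert {c.key for c in final["primary"]} == {failing.key}
        assert verdicts["primary"][0].rescued

    def test_no_invention_when_never_called(self):
        passing = make_call()
        verdicts = {
            "CSF": self._verdicts("CSF", [passing]),
            "primary": self._verdicts("primary", []),
        }
        final = rescue_cross_sample(verdicts)
        assert final["primary"] == []

    def test_failing_everywhere_stays_out(self):
        failing = make_call(alt_reads=2, depth=80)
        verdicts = {
            "CSF": self._verdicts("CSF", [failing]),
            "primary": self._verdicts("primary", [failing]),
        }
        final = rescue_cross_sample(verdicts)
        assert final == {"CSF": [], "primary": []}

    def test_rescue_monotone_in_added_samples(self):
        """Adding a sample where the variant passes never shrinks final sets."""
        failing = make_call(alt_reads=8, depth=9)
        base = {"A": self._verdicts("A", [failing])}
        final_before = rescue_cross_sample({k: list(v) for k, v in base.items()})
        base["B"] = self._verdicts("B", [make_call(alt_reads=20, depth=80)])
        # re-apply on fresh verdicts (rescue mutates)
        with_extra = {
            "A": self._verdicts("A", [failing]),
            "B": self._verdicts("B", [make_call(alt_reads=20, depth=80)]),
        }
        final_after = rescue_cross_sample(with_extra)
        for sid, calls in final_before.items():
            assert {c.key for c in calls} <= {c.key for c in final_after[sid]}


class TestTmb:
    def test_mutations_per_megabase(self):
        calls = [make_call(pos=p) for p in range(1000, 1120)]
        tmb, high = compute_tmb(calls)
        assert tmb == pytest.approx(2.0)
        assert not high

    def test_empty_set(self):
        assert compute_tmb([]) == (0.0, False)

    def test_high_flag_above_ten(self):
        calls = [make_call(pos=1000 + p) for p in range(660)]
        tmb, high = compute_tmb(calls)
        assert tmb == pytest.approx(11.0)
        assert high

    def test_invalid_panel_size(self):
        with pytest.raises(ValueError):
            compute_tmb([make_call()], FilterConfig(target_panel_mb=0))
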