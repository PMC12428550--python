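import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from dxtrust.decision import (
    BatchError,
    CaseRecord,
    Gate,
    Reason,
    TransparencyLevel,
    TransparencyProfile,
    batch_decide,
    decide,
    default_profiles,
    final_score,
    length_score,
    normalize_confidence,
    with_thresholds,
)


class TestTransparencyLevel:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("Minimal", TransparencyLevel.LOW),
            ("low", TransparencyLevel.LOW),
            ("Moderate", TransparencyLevel.MODERATE),
            ("High", TransparencyLevel.HIGH),
            ("HIGH CONFIDENCE", TransparencyLevel.HIGH),
            (
                "High Explainability + High Confidence",
                TransparencyLevel.HIGH,
            ),
        ],
    )
    def test_label_mapping(self, label, expected):
        assert TransparencyLevel.from_label(label) is expected

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            TransparencyLevel.from_label("opaque")


class TestDefaultProfiles:
    def test_deployed_parameter_sets(self, profiles):
        high = profiles[TransparencyLevel.HIGH]
        assert (high.wc, high.ws, high.wl, high.threshold) == (
            0.50,
            0.30,
            0.20,
            0.55,
        )
        mod = profiles[TransparencyLevel.MODERATE]
        assert (mod.wc, mod.ws, mod.wl, mod.threshold) == (
            0.60,
            0.30,
            0.10,
            0.65,
        )
        low = profiles[TransparencyLevel.LOW]
        assert (low.wc, low.ws, low.wl, low.threshold) == (
            0.40,
            0.50,
            0.10,
            0.70,
        )

    def test_weights_sum_to_one(self, profiles):
        for p in profiles.values():
            assert p.wc + p.ws + p.wl == pytest.approx(1.0, abs=1e-12)

    def test_threshold_ordering_encodes_conservatism(self, profiles):
        assert (
            profiles[TransparencyLevel.LOW].threshold
            > profiles[TransparencyLevel.MODERATE].threshold
            > profiles[TransparencyLevel.HIGH].threshold
        )

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            TransparencyProfile(
                TransparencyLevel.HIGH, wc=0.6, ws=0.3, wl=0.2, threshold=0.5
            )
        with pytest.raises(ValueError):
            TransparencyProfile(
                TransparencyLevel.HIGH, wc=0.5, ws=0.3, wl=0.2, threshold=1.0
            )


class TestNormalizeConfidence:
    @pytest.mark.parametrize(
        "conf,expected", [(70, 0.5), (99, 1.0), (84.5, 0.75)]
    )
    def test_affine_map(self, conf, expected):
        assert normalize_confidence(conf) == pytest.approx(expected)

    def test_monotone(self):
        grid = np.linspace(70, 99, 59)
        vals = [normalize_confidence(c) for c in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("conf", [69.9, 100.0, 0.0])
    def test_outside_band_rejected(self, conf):
        with pytest.raises(ValueError):
            normalize_confidence(conf)

    def test_fraction_mode(self):
        assert normalize_confidence(84, mode="fraction") == pytest.approx(0.84)
        assert normalize_confidence(30, mode="fraction") == 0.5
        assert normalize_confidence(99.9, mode="fraction") == pytest.approx(
            0.999
        )


class TestLengthScore:
    def test_band_rewarded(self):
        assert length_score("x" * 65) == 1.0
        assert length_score("shortname!") == 0.7

    @pytest.mark.parametrize("n,expected", [(29, 0.7), (30, 1.0), (100, 1.0), (101, 0.7)])
    def test_inclusive_boundaries(self, n, expected):
        assert length_score("x" * n) == expected

    def test_whitespace_collapsed_before_counting(self):
        # 29 visible chars padded with extra spaces must still score 0.7
        raw = "  aa   " + "b" * 26 + "  "
        assert length_score(raw) == 0.7

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            length_score("   ")


class TestFinalScore:
    def test_hand_computed_examples(self, profiles):
        mod = profiles[TransparencyLevel.MODERATE]
        assert final_score(0.8, 0.5, 1.0, mod) == pytest.approx(0.73)
        high = profiles[TransparencyLevel.HIGH]
        assert final_score(0.5, 0.0, 0.7, high) == pytest.approx(0.39)
        for p in profiles.values():
            assert final_score(1.0, 1.0, 1.0, p) == pytest.approx(1.0)

    def test_component_range_enforced(self, profiles):
        p = profiles[TransparencyLevel.HIGH]
        with pytest.raises(ValueError):
            final_score(0.4, 0.5, 1.0, p)
        with pytest.raises(ValueError):
            final_score(0.8, 1.2, 1.0, p)
        with pytest.raises(ValueError):
            final_score(0.8, 0.5, 0.9, p)

    def test_matches_dot_product_oracle(self, profiles):
        """1000 random component triples agree with an independent oracle."""
        rng = np.random.default_rng(123)
        plist = list(profiles.values())
        for _ in range(1000):
            s_conf = rng.uniform(0.5, 1.0)
            s_sim = rng.uniform(0.0, 1.0)
            s_len = float(rng.choice([0.7, 1.0]))
            p = plist[rng.integers(len(plist))]
            want = float(
                np.dot([p.wc, p.ws, p.wl], [s_conf, s_sim, s_len])
            )
            assert final_score(s_conf, s_sim, s_len, p) == pytest.approx(
                want, abs=1e-12
            )


class TestDecide:
    def test_low_confidence_gate(self, case_factory):
        d = decide(case_factory(confidence_pct=65.0), similarity=1.0)
        assert d.override == 1
        assert d.reason is Reason.LOW_CONFIDENCE_GATE
        assert Gate.LOW_CONFIDENCE in d.breakdown.gates

    def test_gate_dominance_no_rescue(self, case_factory):
        """No similarity/length/transparency combination accepts sub-70%."""
        for level in TransparencyLevel:
            d = decide(
                case_factory(confidence_pct=69.9, transparency=level),
                similarity=1.0,
            )
            assert d.override == 1
            assert d.reason is Reason.LOW_CONFIDENCE_GATE

    def test_low_similarity_hard_gate(self, case_factory):
        d = decide(case_factory(confidence_pct=99.0), similarity=0.05)
        assert d.reason is Reason.LOW_SIMILARITY_GATE
        # strict cut: exactly 0.10 passes the gate
        d = decide(case_factory(confidence_pct=99.0), similarity=0.10)
        assert d.reason is not Reason.LOW_SIMILARITY_GATE

    def test_clamp_mode_floors_similarity(self, case_factory):
        d = decide(
            case_factory(confidence_pct=99.0),
            similarity=0.02,
            gate_mode="clamp",
        )
        assert d.breakdown.s_sim == 0.10
        assert d.reason is not Reason.LOW_SIMILARITY_GATE

    def test_accept_above_threshold(self, case_factory):
        # s_conf=0.75, sim=0.9, len band -> 0.6*.75+0.3*.9+0.1 = 0.82 >= 0.65
        d = decide(case_factory(confidence_pct=84.5), similarity=0.9)
        assert d.override == 0
        assert d.reason is Reason.ACCEPTED
        assert d.breakdown.s_final == pytest.approx(0.82)

    def test_below_threshold_overrides(self, case_factory):
        # 0.6*.75+0.3*0.2+0.1 = 0.61 < 0.65
        d = decide(case_factory(confidence_pct=84.5), similarity=0.2)
        assert d.override == 1
        assert d.reason is Reason.BELOW_THRESHOLD

    def test_equality_at_threshold_accepts(self, case_factory, profiles):
        mod = profiles[TransparencyLevel.MODERATE]
        # solve for sim giving s_final exactly at the threshold
        sim = (mod.threshold - mod.wc * 0.75 - mod.wl * 1.0) / mod.ws
        d = decide(case_factory(confidence_pct=84.5), similarity=sim)
        assert d.breakdown.s_final == pytest.approx(mod.threshold, abs=1e-12)
        assert d.override == 0

    def test_confidence_above_ceiling_clamped_with_warning(self, case_factory):
        with pytest.warns(UserWarning, match="clamped"):
            d = decide(case_factory(confidence_pct=99.7), similarity=0.9)
        assert d.breakdown.s_conf == 1.0

    def test_missing_profile_is_an_error(self, case_factory, profiles):
        partial = {
            k: v for k, v in profiles.items() if k is not TransparencyLevel.LOW
        }
        with pytest.raises(KeyError):
            decide(
                case_factory(transparency=TransparencyLevel.LOW),
                profiles=partial,
                similarity=0.5,
            )

    def test_no_similarity_and_no_backend(self, case_factory):
        with pytest.raises(ValueError, match="no backend"):
            decide(case_factory())

    def test_backend_computes_similarity(self, case_factory):
        d = decide(
            case_factory(
                ai_dx="acute heart failure with volume overload present",
                human_dx="acute heart failure with volume overload present",
            ),
            backend="token-cosine",
        )
        assert d.breakdown.s_sim == 1.0

    @given(
        conf=st.floats(min_value=70, max_value=99),
        sim_lo=st.floats(min_value=0.1, max_value=1.0),
        bump=st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(deadline=None, derandomize=True, max_examples=200,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_monotone_in_similarity(self, case_factory, conf, sim_lo, bump):
        """Raising any component never flips an accepted case to overridden."""
        sim_hi = min(1.0, sim_lo + bump)
        d_lo = decide(case_factory(confidence_pct=conf), similarity=sim_lo)
        d_hi = decide(case_factory(confidence_pct=conf), similarity=sim_hi)
        assert d_hi.breakdown.s_final >= d_lo.breakdown.s_final - 1e-12
        assert d_hi.override <= d_lo.override

    @given(
        c1=st.floats(min_value=70, max_value=99),
        bump=st.floats(min_value=0.0, max_value=29.0),
        sim=st.floats(min_value=0.1, max_value=1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=200,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_monotone_in_confidence(self, case_factory, c1, bump, sim):
        c2 = min(99.0, c1 + bump)
        d1 = decide(case_factory(confidence_pct=c1), similarity=sim)
        d2 = decide(case_factory(confidence_pct=c2), similarity=sim)
        assert d2.breakdown.s_final >= d1.breakdown.s_final - 1e-12
        assert d2.override <= d1.override

    @given(
        conf=st.floats(min_value=70, max_value=99),
        sim=st.floats(min_value=0.0, max_value=1.0),
        short=st.booleans(),
    )
    @settings(deadline=None, derandomize=True, max_examples=200,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_score_range(self, case_factory, conf, sim, short):
        text = "short dx here" if short else "x" * 50
        d = decide(
            case_factory(confidence_pct=conf, ai_dx=text), similarity=sim
        )
        assert 0.0 < d.breakdown.s_final <= 1.0


class TestBatchDecide:
    def test_empty_sequence(self):
        assert batch_decide([]) == []

    def test_pointwise_equivalence(self, case_factory):
        cases = [
            case_factory(case_id=f"C{i}", confidence_pct=70 + i * 3)
            for i in range(8)
        ]
        batch = batch_decide(cases, backend="token-cosine")
        singles = [decide(c, backend="token-cosine") for c in cases]
        assert [d.case_id for d in batch] == [d.case_id for d in singles]
        assert [d.override for d in batch] == [d.override for d in singles]
        assert [d.reason for d in batch] == [d.reason for d in singles]

    def test_strict_mode_aborts_naming_case(self, case_factory):
        cases = [case_factory(case_id="OK", similarity_override=0.9),
                 case_factory(case_id="BAD")]
        with pytest.raises(BatchError, match="BAD"):
            batch_decide(cases)  # no similarity, no backend for BAD

    def test_fail_soft_keeps_remainder(self, case_factory):
        cases = [case_factory(case_id="OK", similarity_override=0.9),
                 case_factory(case_id="BAD"),
                 case_factory(case_id="OK2", similarity_override=0.8)]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = batch_decide(cases, strict=False)
        assert [d.case_id for d in out] == ["OK", "OK2"]
        assert any("BAD" in str(w.message) for w in caught)

    def test_audit_called_once_per_decision(self, case_factory):
        seen = []
        cases = [
            case_factory(case_id=f"C{i}", similarity_override=0.9)
            for i in range(5)
        ]
        batch_decide(cases, audit=seen.append)
        assert [d.case_id for d in seen] == [c.case_id for c in cases]

    def test_cohort_rate_equals_count_oracle(self, study_decisions):
        k = sum(d.override for d in study_decisions)
        rate = k / len(study_decisions)
        assert len(study_decisions) == 6689
        assert rate == pytest.approx(
            sum(1 for d in study_decisions if d.override == 1) / 6689
        )


def test_with_thresholds_replaces_only_given_levels(profiles):
    tuned = with_thresholds(profiles, {TransparencyLevel.LOW: 0.8})
    assert tuned[TransparencyLevel.LOW].threshold == 0.8
    assert tuned[TransparencyLevel.LOW].wc == profiles[TransparencyLevel.LOW].wc
    assert (
        tuned[TransparencyLevel.HIGH].threshold
        == profiles[TransparencyLevel.HIGH].threshold
    )
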