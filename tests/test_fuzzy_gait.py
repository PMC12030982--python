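"""Fuzzy gait-phase engine: normalization, membership, rules, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exogait.fuzzy_gait import (
    PHASES,
    PLACEMENTS,
    FsrVector,
    FuzzyConfig,
    Rule,
    RuleBase,
    classify_sequence,
    default_rules,
    dump_rules_yaml,
    evaluate_rules,
    linguistic_grades,
    load_rules_yaml,
    membership,
    mirror_rules,
    normalize_fsr,
    rules_eq5_variant,
)
from exogait.sensor_stream import RecordingSession, SensorFrame


def vec(**kwargs) -> dict:
    base = {p: 0.0 for p in PLACEMENTS}
    base.update(kwargs)
    return base


class TestNormalize:
    def test_per_foot_scaling(self):
        out = normalize_fsr(vec(LH=2, L5M=1, L1M=1, RH=3, R5M=3, R1M=6), "per_foot")
        assert out.normalized["LH"] == pytest.approx(0.5)
        assert out.normalized["L5M"] == pytest.approx(0.25)
        assert out.normalized["R1M"] == pytest.approx(0.5)
        assert sum(out.normalized[p] for p in ("RH", "R5M", "R1M")) == pytest.approx(1.0)

    def test_zero_foot_yields_zeros_not_nan(self):
        out = normalize_fsr(vec(RH=1, R5M=1, R1M=2), "per_foot")
        assert [out.normalized[p] for p in ("LH", "L5M", "L1M")] == [0.0, 0.0, 0.0]

    def test_global_scope_with_equal_readings(self):
        out = normalize_fsr({p: 4.0 for p in PLACEMENTS}, "global")
        assert all(out.normalized[p] == pytest.approx(1 / 6) for p in PLACEMENTS)

    def test_negative_reading_rejected(self):
        with pytest.raises(ValueError):
            normalize_fsr(vec(LH=-1.0))


class TestMembership:
    def test_threshold_maps_to_exactly_half(self):
        assert membership(0.45) == 0.5

    def test_value_at_one_matches_closed_form(self):
        # 1 / (1 + exp(-0.15 * 0.55))
        assert membership(1.0) == pytest.approx(0.520613, abs=1e-6)

    def test_limits_and_monotonicity(self):
        assert membership(-1e9) < 1e-12
        grid = np.linspace(-2, 2, 201)
        grades = [membership(float(f)) for f in grid]
        assert all(b > a for a, b in zip(grades, grades[1:]))

    @settings(derandomize=True, max_examples=100)
    @given(f=st.floats(-10, 10), delta=st.floats(0.001, 5))
    def test_high_low_complement_and_symmetry(self, f, delta):
        high, low = linguistic_grades(f)
        assert high + low == pytest.approx(1.0, abs=1e-15)
        cfg = FuzzyConfig()
        hi_plus, _ = linguistic_grades(cfg.f0 + delta, cfg)
        _, lo_minus = linguistic_grades(cfg.f0 - delta, cfg)
        assert hi_plus == pytest.approx(lo_minus, abs=1e-12)


def brute_force_grades(normalized: dict, rules: RuleBase, cfg: FuzzyConfig) -> dict:
    """Independent oracle: naive per-rule, per-condition evaluation."""
    out = {}
    for rule in rules.rules:
        grades = []
        for placement, required in rule.conditions.items():
            mu = 1.0 / (1.0 + math.exp(
                -cfg.s * (normalized[placement] * cfg.input_scale - cfg.f0)))
            grades.append(mu if required == "High" else 1.0 - mu)
        out[rule.phase] = min(grades)
    return out


class TestEvaluateRules:
    def test_each_crisp_pattern_maps_to_its_phase(self):
        rules = default_rules()
        for rule in rules.rules:
            raw = {p: (1.0 if v == "High" else 0.0) for p, v in rule.conditions.items()}
            result = evaluate_rules(normalize_fsr(raw, "per_foot"), rules)
            assert result.predicted_phase == rule.phase

    def test_symmetric_input_keeps_grades_near_half(self):
        out = evaluate_rules(normalize_fsr({p: 1.0 for p in PLACEMENTS}, "per_foot"))
        assert out.predicted_grade <= 0.5 + 1e-9
        assert len(set(np.round(list(out.grades.values()), 15))) <= 2

    def test_matches_brute_force_oracle_on_random_inputs(self, rng):
        rules = default_rules()
        cfg = FuzzyConfig()
        for _ in range(10_000):
            raw = {p: float(v) for p, v in zip(PLACEMENTS, rng.uniform(0, 100, 6))}
            fsr = normalize_fsr(raw, "per_foot")
            got = evaluate_rules(fsr, rules, cfg).grades
            want = brute_force_grades(fsr.normalized, rules, cfg)
            for phase in PHASES:
                assert got[phase] == pytest.approx(want[phase], abs=1e-12)

    def test_grades_always_within_unit_interval(self, rng):
        rules = default_rules()
        for _ in range(1000):
            raw = {p: float(v) for p, v in zip(PLACEMENTS, rng.uniform(0, 500, 6))}
            out = evaluate_rules(normalize_fsr(raw, "per_foot"), rules)
            assert all(0.0 <= g <= 1.0 for g in out.grades.values())
            assert out.predicted_grade == max(out.grades.values())

    def test_unnormalized_vector_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            evaluate_rules(FsrVector(raw={p: 1.0 for p in PLACEMENTS}))

    def test_rule_base_must_have_eight_distinct_outcomes(self):
        rules = default_rules().rules
        with pytest.raises(ValueError, match="8 rules"):
            RuleBase(rules=rules[:7])
        with pytest.raises(ValueError, match="distinct"):
            RuleBase(rules=rules[:7] + (rules[0],))


class TestMirror:
    def test_heel_strike_row_swaps_sides(self):
        right = default_rules()
        left = mirror_rules(right)
        assert left.side == "left"
        hs_right = right.rules[0].conditions
        hs_left = left.rules[0].conditions
        assert hs_left["RH"] == hs_right["LH"]
        assert hs_left["LH"] == hs_right["RH"]
        assert hs_left["L1M"] == hs_right["R1M"]

    def test_mirror_is_an_involution_with_distinct_outcomes(self):
        rules = default_rules()
        twice = mirror_rules(mirror_rules(rules))
        assert twice == rules
        assert len({r.phase for r in mirror_rules(rules).rules}) == 8

    def test_classification_equivariant_under_mirroring(self, rng):
        rules = default_rules()
        mirrored = mirror_rules(rules)
        swap = {"LH": "RH", "L5M": "R5M", "L1M": "R1M",
                "RH": "LH", "R5M": "L5M", "R1M": "L1M"}
        for _ in range(200):
            raw = {p: float(v) for p, v in zip(PLACEMENTS, rng.uniform(0, 10, 6))}
            flipped = {swap[p]: v for p, v in raw.items()}
            a = evaluate_rules(normalize_fsr(raw, "per_foot"), rules)
            b = evaluate_rules(normalize_fsr(flipped, "per_foot"), mirrored)
            for phase in PHASES:
                assert a.grades[phase] == pytest.approx(b.grades[phase], abs=1e-15)

    def test_eq5_variant_differs_only_on_heel_strike_r1m(self):
        base, variant = default_rules(), rules_eq5_variant()
        assert variant.rules[0].conditions["R1M"] == "Low"
        assert base.rules[0].conditions["R1M"] == "High"
        assert variant.rules[1:] == base.rules[1:]


class TestClassifySequence:
    def test_noiseless_cycle_visits_all_phases_in_order(self, noiseless_run):
        session, truth = noiseless_run
        labels = classify_sequence(session)
        assert len(labels) == len(session.frames)
        seen = [l.phase for l in labels]
        # collapse to sustained runs (>= 5 frames, ~38 ms) so the handful of
        # frames inside each template crossfade do not register as visits
        runs: list[tuple[str, int]] = []
        for phase in seen:
            if runs and runs[-1][0] == phase:
                runs[-1] = (phase, runs[-1][1] + 1)
            else:
                runs.append((phase, 1))
        order = [phase for phase, length in runs if length >= 5]
        first_hs = order.index("Heel Strike")
        assert order[first_hs:first_hs + 8] == list(PHASES)

    def test_all_incomplete_frames_yield_no_labels(self):
        frames = [SensorFrame(timestamp=i / 130, channels={}, complete=False)
                  for i in range(10)]
        session = RecordingSession(frames=frames, nominal_rate=130,
                                   active_peripherals=("left_insole", "right_insole"))
        assert classify_sequence(session) == []

    def test_constant_pattern_gives_constant_labels(self):
        # Heel Strike row: both feet carry intra-foot High/Low contrast, which
        # per-foot normalization preserves (a uniformly loaded foot would not).
        rules = default_rules()
        raw = {p: (800.0 if v == "High" else 40.0)
               for p, v in rules.rules[0].conditions.items()}
        channels = {
            "left_insole_fsr_heel": raw["LH"], "left_insole_fsr_m1": raw["L1M"],
            "left_insole_fsr_m5": raw["L5M"], "right_insole_fsr_heel": raw["RH"],
            "right_insole_fsr_m1": raw["R1M"], "right_insole_fsr_m5": raw["R5M"],
        }
        frames = [SensorFrame(timestamp=i / 130, channels=dict(channels), complete=True)
                  for i in range(100)]
        session = RecordingSession(frames=frames, nominal_rate=130,
                                   active_peripherals=("left_insole", "right_insole"))
        labels = classify_sequence(session)
        assert len(labels) == 100
        assert {l.phase for l in labels} == {"Heel Strike"}

    def test_rescaled_config_restores_nominal_consistency(self):
        """Percent-scale membership makes the phase-grade sum sit near 1."""
        rules = default_rules()
        raw = {p: (800.0 if v == "High" else 40.0)
               for p, v in rules.rules[0].conditions.items()}
        fsr = normalize_fsr(raw, "per_foot")
        literal = evaluate_rules(fsr, rules, FuzzyConfig())
        rescaled = evaluate_rules(fsr, rules, FuzzyConfig.rescaled())
        assert literal.consistency > 3.0  # shallow sigmoid: grades pile near 0.5
        assert 0.5 < rescaled.consistency < 1.5
        assert rescaled.predicted_phase == literal.predicted_phase == "Heel Strike"


def test_rules_yaml_round_trip(tmp_path):
    path = tmp_path / "rules.yaml"
    dump_rules_yaml(default_rules(), path)
    assert load_rules_yaml(path) == default_rules()
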