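import itertools

import pytest
from hypothesis import given, settings, strategies as st

from framen400.config import ConfigError, RunConfig
from framen400.frames import Chain, Feature
from framen400.model import (
    ComponentReport,
    RoleFeature,
    RoleProfile,
    evaluate,
    n400_index,
    role_typicality,
    scenario_role_typicality,
)
from framen400.typicality import DiagnosticityProfile

WEIGHTS = [(0.25, 0.75), (0.5, 0.5), (0.75, 0.25)]


class TestN400Index:
    def test_best_completion_zero(self):
        assert n400_index(0.433, 0.433, 1.0) == 0.0

    def test_worst_completion_one(self):
        assert n400_index(0.0, 0.433, 0.0) == 1.0

    def test_degenerate_no_reduction_possible(self):
        # nothing to reduce: index collapses to the plausibility term
        assert n400_index(0.0, 0.0, 0.6, weights=(0.5, 0.5)) == pytest.approx(0.2)

    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigError):
            n400_index(0.1, 0.4, 0.5, weights=(0.7, 0.7))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            n400_index(0.5, 0.4, 0.5)
        with pytest.raises(ValueError):
            n400_index(0.1, 0.4, 1.5)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.01, 2.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0),
           st.floats(0.0, 1.0), st.sampled_from(WEIGHTS))
    def test_monotone(self, hmax, frac1, frac2, typ, weights):
        lo, hi = sorted((frac1 * hmax, frac2 * hmax))
        assert n400_index(hi, hmax, typ, weights) <= n400_index(lo, hmax, typ, weights) + 1e-12
        t_lo, t_hi = sorted((frac1, frac2))
        assert n400_index(lo, hmax, t_hi, weights) <= n400_index(lo, hmax, t_lo, weights) + 1e-12


class TestEvaluate:
    def test_birthday_sweet_cake_report(self, birthday):
        r = evaluate(birthday, "cake", prenominal="sweet")
        assert r.typicality_raw == pytest.approx(0.937, abs=5e-5)
        assert not r.failed

    def test_resort_palms_report(self, resort):
        r = evaluate(resort, "palms")
        assert r.delta_h == pytest.approx(0.433, abs=0.005)
        assert r.h_t2 == 0.0
        assert r.partition_sizes == (2, 0, 0)

    def test_drawer_failed_max_index(self, seaside_hc):
        r = evaluate(seaside_hc, "drawer")
        assert r.failed
        assert r.n400_index == 1.0
        assert r.typicality_raw is None
        assert r.h_t1 is None
        assert "sentient" in r.failing_chains

    def test_failed_index_dominates(self, seaside_hc):
        failed = evaluate(seaside_hc, "drawer").n400_index
        for cw in ("swimmers", "trainees"):
            assert evaluate(seaside_hc, cw).n400_index <= failed

    @pytest.mark.parametrize("alpha,beta", WEIGHTS)
    def test_resort_ordering_all_weights(self, resort, alpha, beta):
        cfg = RunConfig(alpha=alpha, beta=beta)
        idx = {cw: evaluate(resort, cw, cfg).n400_index
               for cw in ("palms", "pines", "tulips")}
        assert idx["palms"] < idx["pines"] < idx["tulips"]

    @pytest.mark.parametrize("alpha,beta", WEIGHTS)
    def test_birthday_ordering_all_weights(self, birthday, alpha, beta):
        cfg = RunConfig(alpha=alpha, beta=beta)
        conditions = [("sweet", "cake"), ("healthy", "cake"),
                      ("healthy", "veggies"), ("sweet", "veggies")]
        typs = [evaluate(birthday, cw, cfg, prenominal=pre).typicality_raw
                for pre, cw in conditions]
        assert typs == sorted(typs, reverse=True)  # 0.937 > 0.6815 > 0.4815 > 0.12

    def test_unknown_cw_raises(self, resort):
        with pytest.raises(KeyError):
            evaluate(resort, "cactus")

    def test_unknown_prenominal_raises(self, birthday):
        with pytest.raises(KeyError):
            evaluate(birthday, "cake", prenominal="stale")

    def test_threshold_override(self, resort):
        # r above every probability: no defaults, nothing confirmed
        r = evaluate(resort, "palms", RunConfig(threshold_r=0.95))
        assert r.partition_sizes == (0, 0, 0)

    def test_hc_lc_compensation_demo(self, seaside_hc, seaside_lc):
        # a weight setting under which the HC and LC indices for the
        # low-cloze word approximately coincide (demonstrated, not asserted
        # as an invariant)
        cfg = RunConfig(alpha=0.25, beta=0.75)
        hc = evaluate(seaside_hc, "trainees", cfg).n400_index
        lc = evaluate(seaside_lc, "trainees", cfg).n400_index
        assert hc == pytest.approx(lc, abs=0.1)
        # and the two components move in opposite directions
        assert evaluate(seaside_hc, "trainees").delta_h > \
            evaluate(seaside_lc, "trainees").delta_h
        assert evaluate(seaside_hc, "trainees").typicality_raw < \
            evaluate(seaside_lc, "trainees").typicality_raw

    def test_report_serialization(self, resort):
        r = evaluate(resort, "pines")
        d = r.to_dict()
        assert d["cw"] == "pines"
        assert d["partition_sizes"] == [1, 0, 1]
        row = r.to_tsv_row().split("\t")
        assert row[0] == "pines"
        assert len(row) == 11


class TestRoleTypicality:
    def test_prescription_ordering(self, prescription):
        scores = {cw: scenario_role_typicality(prescription, cw)
                  for cw in prescription.critical_words}
        assert scores["psychiatrist"] > scores["schizophrenic"] > scores["guard"] \
            > scores["pill"] > scores["fence"]

    def test_single_role_reduces_to_plain_typicality(self, birthday):
        from framen400.typicality import typicality
        arg = birthday.argument_concept()
        cake = birthday.concept("cake")
        profile = birthday.diagnosticity_profile(arg)
        rf = [RoleFeature("theme", f, 1.0)
              for f in [Feature(Chain.parse("taste"), "sweet")]]
        got = role_typicality(rf, cake, {"theme": RoleProfile(arg, profile)})
        assert got == pytest.approx(typicality(arg, cake, profile).raw)

    def test_undefined_restriction_contributes_zero(self, prescription):
        # pill lacks both animacy chains: only the theme role scores
        pill = prescription.cw_concept("pill")
        got = scenario_role_typicality(prescription, "pill")
        theme = next(r for r in prescription.roles if r.name == "theme")
        from framen400.typicality import typicality
        concept = prescription.concept(theme.category)
        profile = DiagnosticityProfile(weights=dict(theme.profile), source="stipulated")
        assert got == pytest.approx(theme.weight * typicality(concept, pill, profile).raw)

    def test_undischarged_match_beats_discharged_violation(self, prescription):
        # the undischarged actor role carries the largest weight; a word
        # matching it (psychiatrist) outscores one whose only match sits on a
        # discharged role with a violated restriction elsewhere (pill)
        assert scenario_role_typicality(prescription, "psychiatrist") > \
            scenario_role_typicality(prescription, "pill")

    def test_unnormalized_weights_rejected(self, birthday):
        arg = birthday.argument_concept()
        profile = birthday.diagnosticity_profile(arg)
        rf = [RoleFeature("a", Feature(Chain.parse("taste"), "sweet"), 0.4)]
        with pytest.raises(ConfigError):
            role_typicality(rf, birthday.concept("cake"),
                            {"a": RoleProfile(arg, profile)})


class TestRunConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            RunConfig(alpha=0.6, beta=0.6)

    def test_bad_variant(self):
        with pytest.raises(ConfigError):
            RunConfig(typicality_variant="exotic")

    def test_bad_log_base(self):
        with pytest.raises(ConfigError):
            RunConfig(log_base=1.0)
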