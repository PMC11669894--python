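import numpy as np
import pytest

from kellvar.annotate import (
    CONDITION_KEYS,
    AnnotationResources,
    RuleConfig,
    annotate_variant,
    evaluate_conditions,
    predict_phenotype,
    screen_cohort,
)
from kellvar.conservation import ConservationProfile
from kellvar.properties import build_substitution_profile
from kellvar.structure import ResidueContext


def make_context(burial, position=1, membrane_proximal=None):
    rsa = {"buried": 0.02, "half_buried": 0.15, "exposed": 0.6}[burial]
    return ResidueContext(
        position=position, aa="A", ca_coord=np.zeros(3), asa_abs=10.0,
        rsa=rsa, burial=burial, domain="extracellular_unassigned",
        membrane_proximal=membrane_proximal,
    )


def conditions_for(key, burial, *, pct=None, struct=None, catalog=None,
                   config=None, mpc=None, scales=None, membrane_proximal=None):
    position = key[0]
    ctx = make_context(burial, position, membrane_proximal)
    cons = (
        None if pct is None
        else ConservationProfile(position, pct, struct)
    )
    profile = build_substitution_profile(position, key[1], key[2], ctx, scales)
    cfg = config or RuleConfig()
    return evaluate_conditions(key, ctx, cons, profile, catalog, cfg, mpc), ctx, profile, cfg


class TestEvaluateConditions:
    def test_known_site_from_catalog(self, catalog, scales):
        # position 193 carries antigenic and expression-modifying variants
        conds, *_ = conditions_for((193, "T", "R"), "buried", pct=100.0,
                                   catalog=catalog, scales=scales)
        assert conds["c1_known_site"] is True
        conds2, *_ = conditions_for((5, "A", "G"), "buried", pct=100.0,
                                    catalog=catalog, scales=scales)
        assert conds2["c1_known_site"] is False

    def test_conservation_cutoff(self, scales):
        conds, *_ = conditions_for((1, "L", "P"), "buried", pct=95.0, scales=scales)
        assert conds["c2_seq_conserved"] is True
        conds, *_ = conditions_for((1, "L", "P"), "buried", pct=50.0, scales=scales)
        assert conds["c2_seq_conserved"] is False

    def test_structural_count_tristate(self, scales):
        conds, *_ = conditions_for((1, "L", "P"), "buried", pct=95.0, struct=2, scales=scales)
        assert conds["c3_struct_conserved"] is True
        conds, *_ = conditions_for((1, "L", "P"), "buried", pct=95.0, struct=0, scales=scales)
        assert conds["c3_struct_conserved"] is False
        conds, *_ = conditions_for((1, "L", "P"), "buried", pct=95.0, struct=None, scales=scales)
        assert conds["c3_struct_conserved"] is None

    def test_missing_inputs_yield_unknown_not_false(self, scales):
        conds, *_ = conditions_for((500, "A", "G"), "exposed", scales=scales)
        assert conds["c2_seq_conserved"] is None
        assert conds["c3_struct_conserved"] is None
        assert conds["c7_mpc_above"] is None
        # empty cavity list and no membrane plane: location unknown
        assert conds["c6a_not_cavity_or_proximal"] is None

    def test_cavity_membership_decides_alone(self, scales):
        cfg = RuleConfig(cavity_positions={500})
        conds, *_ = conditions_for((500, "A", "G"), "exposed", config=cfg, scales=scales)
        assert conds["c6a_not_cavity_or_proximal"] is False

    def test_membrane_proximity_certifies_location(self, scales):
        conds, *_ = conditions_for((10, "A", "G"), "exposed",
                                   membrane_proximal=False, scales=scales)
        assert conds["c6a_not_cavity_or_proximal"] is True
        conds, *_ = conditions_for((10, "A", "G"), "exposed",
                                   membrane_proximal=True, scales=scales)
        assert conds["c6a_not_cavity_or_proximal"] is False

    def test_epitope_segment_membership(self, scales):
        cfg = RuleConfig(epitope_segments=[(244, 260)])
        conds, *_ = conditions_for((248, "R", "Q"), "exposed", config=cfg, scales=scales)
        assert conds["c6b_in_epitope"] is True
        conds, *_ = conditions_for((700, "A", "G"), "exposed", config=cfg, scales=scales)
        assert conds["c6b_in_epitope"] is False

    def test_mpc_threshold(self, scales):
        conds, *_ = conditions_for((1, "A", "G"), "exposed", mpc=0.41, scales=scales)
        assert conds["c7_mpc_above"] is True
        conds, *_ = conditions_for((1, "A", "G"), "exposed", mpc=0.4, scales=scales)
        assert conds["c7_mpc_above"] is False

    def test_all_condition_keys_present(self, scales):
        conds, *_ = conditions_for((1, "A", "G"), "exposed", scales=scales)
        assert set(conds) == set(CONDITION_KEYS)


class TestPredictPhenotype:
    def test_buried_conserved_proline_is_destabilizing(self, scales):
        conds, ctx, prof, cfg = conditions_for((1, "L", "P"), "buried",
                                               pct=100.0, scales=scales)
        verdict = predict_phenotype(conds, ctx, prof, cfg, key=(1, "L", "P"))
        assert verdict.prediction == "destabilizing"
        assert verdict.trace

    def test_exposed_arginine_loss_in_epitope_is_antigenic(self, scales):
        cfg = RuleConfig(epitope_segments=[(1, 10)])
        conds, ctx, prof, _ = conditions_for((5, "R", "Q"), "exposed",
                                             pct=50.0, config=cfg, scales=scales)
        verdict = predict_phenotype(conds, ctx, prof, cfg, key=(5, "R", "Q"))
        assert verdict.prediction == "antigenic"

    def test_unconserved_conservative_exchange_is_neutral(self, scales):
        conds, ctx, prof, cfg = conditions_for((5, "A", "S"), "exposed",
                                               pct=10.0, scales=scales)
        verdict = predict_phenotype(conds, ctx, prof, cfg, key=(5, "A", "S"))
        assert verdict.prediction == "neutral"

    def test_all_unknown_is_indeterminate_never_neutral(self):
        conds = {k: None for k in CONDITION_KEYS}
        verdict = predict_phenotype(conds, None, None, RuleConfig(), key=(1, "A", "G"))
        assert verdict.prediction == "indeterminate"

    def test_membrane_proximal_blocks_antigenic_call(self, scales):
        conds, ctx, prof, cfg = conditions_for((5, "R", "Q"), "exposed", pct=50.0,
                                               membrane_proximal=True, scales=scales)
        verdict = predict_phenotype(conds, ctx, prof, cfg, key=(5, "R", "Q"))
        assert verdict.prediction != "antigenic"

    def test_supporting_conditions_never_flip_to_neutral(self, scales):
        """Turning any unknown condition true keeps non-neutral verdicts."""
        conds, ctx, prof, cfg = conditions_for((1, "L", "P"), "buried",
                                               pct=100.0, scales=scales)
        base = predict_phenotype(conds, ctx, prof, cfg, key=(1, "L", "P"))
        assert base.prediction == "destabilizing"
        for key, value in conds.items():
            if value is None:
                upgraded = dict(conds, **{key: True})
                after = predict_phenotype(upgraded, ctx, prof, cfg, key=(1, "L", "P"))
                assert after.prediction != "neutral"

    def test_c1_and_c7_add_evidence_but_do_not_decide(self, scales):
        conds, ctx, prof, cfg = conditions_for((5, "A", "S"), "exposed",
                                               pct=10.0, scales=scales)
        neutral = predict_phenotype(conds, ctx, prof, cfg, key=(5, "A", "S"))
        boosted = dict(conds, c1_known_site=True, c7_mpc_above=True)
        after = predict_phenotype(boosted, ctx, prof, cfg, key=(5, "A", "S"))
        assert after.prediction == neutral.prediction == "neutral"
        assert after.evidence_score > neutral.evidence_score


class TestScreenCohort:
    def _resources(self, catalog, scales):
        contexts = {
            pos: make_context(burial, pos)
            for pos, burial in [(193, "buried"), (300, "exposed"), (400, "buried")]
        }
        conservation = {
            300: ConservationProfile(300, 20.0, None),
            400: ConservationProfile(400, 100.0, None),
        }
        return AnnotationResources(
            catalog=catalog, contexts=contexts, conservation=conservation,
            scales=scales,
        )

    def test_known_variant_routed_not_screened(self, catalog, scales):
        report = screen_cohort(["Thr193Met"], self._resources(catalog, scales), RuleConfig())
        assert report.known == [(193, "T", "M")]
        assert report.verdicts == []

    def test_empty_list_empty_report(self, catalog, scales):
        report = screen_cohort([], self._resources(catalog, scales), RuleConfig())
        assert report.verdicts == [] and report.known == [] and report.unresolved == []

    def test_unparseable_input_listed_with_reason(self, catalog, scales):
        report = screen_cohort(["Thr193"], self._resources(catalog, scales), RuleConfig())
        assert len(report.unresolved) == 1
        assert "Thr193" in report.unresolved[0][0]

    def test_ranked_by_evidence_then_position(self, catalog, scales):
        report = screen_cohort(
            ["Ala300Ser", "Leu400Pro"], self._resources(catalog, scales), RuleConfig()
        )
        scores = [v.evidence_score for v in report.verdicts]
        assert scores == sorted(scores, reverse=True)
        assert report.verdicts[0].substitution == "Leu400Pro"

    def test_deterministic_report(self, catalog, scales):
        res = self._resources(catalog, scales)
        r1 = screen_cohort(["Ala300Ser", "Leu400Pro"], res, RuleConfig())
        r2 = screen_cohort(["Ala300Ser", "Leu400Pro"], res, RuleConfig())
        assert r1.to_frame().to_csv() == r2.to_frame().to_csv()

    def test_variant_without_context_is_indeterminate(self, catalog, scales):
        report = screen_cohort(["Ala600Ser"], self._resources(catalog, scales), RuleConfig())
        assert report.verdicts[0].prediction == "indeterminate"

    def test_mpc_passthrough(self, catalog, scales):
        res = self._resources(catalog, scales)
        report = screen_cohort([((300, "A", "S"), 0.9)], res, RuleConfig())
        assert report.verdicts[0].conditions["c7_mpc_above"] is True
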