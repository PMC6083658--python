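import numpy as np
import pandas as pd
import pytest

import groomchoice as gc
from groomchoice.model import (ChoiceModelSpec, ConvergenceError,
                               PartnerChoiceModel, SpecificationError,
                               full_null_comparison, stability_check,
                               term_tests, vif_report)
from groomchoice.simulate import BETA_FIELDS

TERMS = tuple(BETA_FIELDS)


@pytest.fixture(scope="module")
def study():
    return gc.simulate_choice_study(300, gc.TrueBeta(), seed=5)


@pytest.fixture(scope="module")
def study_fit(study):
    return PartnerChoiceModel(study, ChoiceModelSpec(TERMS, name="t")).fit()


class TestConditionalLogitCore:
    def test_baseline_loglike_identity(self, study):
        m = PartnerChoiceModel(study, ChoiceModelSpec(TERMS, name="t"))
        expected = np.log(
            1.0 / study.groupby("session")["n_candidates"].first()).sum()
        assert m.baseline_loglike() == pytest.approx(expected, abs=1e-10)

    def test_fitted_probabilities_sum_to_one_per_session(self, study,
                                                         study_fit):
        sums = study_fit.fittedvalues.groupby(study["session"]).sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_agrees_with_statsmodels_conditional_logit(self, study,
                                                       study_fit):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        sm_fit = ConditionalLogit(study["chosen"], study[list(TERMS)],
                                  groups=study["session"]).fit(disp=0)
        assert np.allclose(study_fit.params.to_numpy(), sm_fit.params,
                           atol=1e-3)
        assert np.allclose(study_fit.bse.to_numpy(), sm_fit.bse, atol=1e-3)
        assert study_fit.llf == pytest.approx(sm_fit.llf, abs=1e-3)

    def test_two_candidate_sessions_equal_paired_logistic(self):
        import statsmodels.api as sm

        df = gc.simulate_choice_study(400, gc.TrueBeta(), party_size=(3, 3),
                                      seed=8)
        res = PartnerChoiceModel(df, ChoiceModelSpec(TERMS, name="p")).fit()
        # in 2-candidate sessions each candidate is the other's only
        # bystander, so max_bystander_ddsi is session-constant and absorbed
        assert "max_bystander_ddsi" in res.meta["absorbed"]
        # conditional logit on 2-candidate sets == Bernoulli logit on
        # within-pair covariate differences, no intercept
        cols = list(res.params.index)
        wide = df.sort_values(["session", "candidate"])
        first = wide.groupby("session").nth(0)
        second = wide.groupby("session").nth(1)
        X = first[cols].to_numpy() - second[cols].to_numpy()
        y = first["chosen"].to_numpy()
        glm = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(res.params.to_numpy(), glm.params, atol=1e-5)

    def test_complete_separation_raises(self):
        rows = []
        for s in range(30):
            rows.append({"session": s, "chosen": 1, "x": 1.0,
                         "n_candidates": 2})
            rows.append({"session": s, "chosen": 0, "x": 0.0,
                         "n_candidates": 2})
        df = pd.DataFrame(rows)
        with pytest.raises(ConvergenceError):
            PartnerChoiceModel(df, ChoiceModelSpec(("x",), name="sep")).fit()

    def test_aliased_columns_are_dropped_not_divergent(self, study):
        # a covariate that only varies inside a single group is exactly
        # collinear with its group interaction after stratification; the
        # fit must drop one copy instead of running along the flat ridge
        df = study.copy()
        df["dup"] = df["rel_rank"]
        spec = ChoiceModelSpec(TERMS + ("dup",), name="alias")
        res = PartnerChoiceModel(df, spec).fit()
        assert res.converged
        dropped = set(res.meta["aliased"])
        assert dropped == {"dup"} or dropped == {"rel_rank"}
        assert len(res.params) == len(TERMS)

    def test_session_constant_columns_are_absorbed(self, study):
        df = study.copy()
        df["focal_trait"] = df.groupby("session")["rel_rank"].transform(
            "mean")
        spec = ChoiceModelSpec(TERMS + ("focal_trait",), name="a")
        res = PartnerChoiceModel(df, spec).fit()
        assert "focal_trait" not in res.params.index
        assert "focal_trait" in res.meta["absorbed"]


class TestFullNull:
    def test_full_equals_null_gives_zero_chisq(self, study):
        spec = ChoiceModelSpec(TERMS, name="t")
        res = PartnerChoiceModel(study, spec).fit()
        lrt = res.lrt(res)
        assert lrt.chisq == pytest.approx(0.0, abs=1e-9)
        assert lrt.pvalue == 1.0

    def test_df_equals_dropped_parameter_count(self, study):
        full_spec = ChoiceModelSpec(TERMS, name="t")
        null_spec = ChoiceModelSpec((), name="n")
        lrt, full, null = full_null_comparison(study, full_spec, null_spec)
        assert lrt.df == full.df_model - null.df_model == len(TERMS)

    def test_non_nested_specs_rejected(self, study):
        with pytest.raises(SpecificationError):
            full_null_comparison(study, ChoiceModelSpec(("rel_rank",)),
                                 ChoiceModelSpec(("ddsi",)))

    def test_strong_preference_detected(self):
        df = gc.simulate_choice_study(
            500, gc.TrueBeta(rel_rank=1.5, ddsi=0, max_bystander_ddsi=0,
                             infant=0, tumescent=0, prior_aggression=0),
            seed=9)
        lrt, _, _ = full_null_comparison(df, ChoiceModelSpec(TERMS),
                                         ChoiceModelSpec(()))
        assert lrt.pvalue < 0.001


class TestTermTests:
    def test_dropping_unknown_term_errors(self):
        with pytest.raises(SpecificationError):
            ChoiceModelSpec(TERMS).drop_term("z_moon_phase")

    def test_marginality_protects_lower_order_terms(self):
        spec = ChoiceModelSpec.model1("global")
        droppable = spec.droppable_terms()
        three_way = "z_focal_rank_global:z_cand_rank_global_sq:group"
        assert three_way in droppable
        # constituents of the retained three-way are not droppable
        assert "z_focal_rank_global:z_cand_rank_global_sq" not in droppable
        assert "z_cand_rank_global_sq:group" not in droppable
        assert "z_cand_rank_global_sq" not in droppable

    def test_drop1_returns_one_result_per_droppable_term(self, study,
                                                         study_fit):
        spec = ChoiceModelSpec(TERMS, name="t")
        results = term_tests(study, spec, full_result=study_fit)
        assert {r.description for r in results} == set(TERMS)
        assert all(r.chisq >= -1e-6 and r.df == 1 for r in results)


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame({
            "session": np.repeat(np.arange(n // 2), 2),
            "chosen": np.tile([1, 0], n // 2),
            "a": rng.normal(size=n), "b": rng.normal(size=n),
        })
        rep = vif_report(df, ChoiceModelSpec(("a", "b")))
        assert np.allclose(rep.table["vif"], 1.0, atol=0.05)

    def test_known_correlation_gives_closed_form_vif(self):
        rng = np.random.default_rng(1)
        n = 20000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = rng.normal(size=n)
        df = pd.DataFrame({"session": np.repeat(np.arange(n // 2), 2),
                           "chosen": np.tile([1, 0], n // 2),
                           "a": a, "b": b, "c": c})
        rep = vif_report(df, ChoiceModelSpec(("a", "b", "c")))
        vif_a = rep.table.set_index("predictor").loc["a", "vif"]
        # 1/(1 - 0.9^2) = 5.26
        assert vif_a == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_duplicated_column_flagged_infinite(self):
        df = pd.DataFrame({"session": [0, 0, 1, 1], "chosen": [1, 0, 1, 0],
                           "a": [1.0, 2.0, 3.0, 4.0]})
        df["b"] = df["a"]
        rep = vif_report(df, ChoiceModelSpec(("a", "b")))
        assert np.isinf(rep.max_vif)
        assert rep.warnings


class TestStability:
    def test_homogeneous_data_is_stable(self, study):
        spec = ChoiceModelSpec(("rel_rank", "ddsi"), name="s")
        rep = stability_check(study, spec, "focal")
        assert not rep.failures
        full = rep.ranges["full"]
        # no single focal's exclusion moves a clearly estimated
        # coefficient by more than 20%
        for col in full.index:
            spread = (rep.estimates[col] - full[col]).abs().max()
            assert spread <= 0.2 * abs(full[col]) + 0.1

    def test_planted_sign_flip_is_flagged(self):
        rows = []
        # focal OUT's sessions carry a strong positive x effect; the other
        # focals mostly mild-negative (with enough positive cases to keep
        # the leave-OUT fit finite), so excluding OUT flips the sign
        for s in range(20):
            rows.append({"session": s, "focal": "OUT", "chosen": 1, "x": 1.0})
            rows.append({"session": s, "focal": "OUT", "chosen": 0, "x": 0.0})
        for s in range(20, 56):
            focal = f"F{s % 4}"
            lo = s % 3 == 0  # 1/3 of sessions go the other way
            rows.append({"session": s, "focal": focal, "chosen": 1,
                         "x": 0.55 if lo else 0.45})
            rows.append({"session": s, "focal": focal, "chosen": 0,
                         "x": 0.45 if lo else 0.55})
        df = pd.DataFrame(rows)
        rep = stability_check(df, ChoiceModelSpec(("x",), name="p"), "focal")
        assert "OUT" in rep.flagged_levels

    def test_single_level_effect_rejected(self):
        df = pd.DataFrame({"session": [0, 0], "chosen": [1, 0],
                           "x": [1.0, 0.0], "focal": ["F", "F"]})
        with pytest.raises(SpecificationError):
            stability_check(df, ChoiceModelSpec(("x",)), "focal")


class TestMixedBackend:
    def test_glmer_agrees_with_conditional_logit(self):
        df = gc.simulate_choice_study(150, gc.TrueBeta(), seed=13)
        df["dyad"] = df["focal"] + "~" + df["candidate"]
        spec = ChoiceModelSpec(TERMS, name="mix")
        clog = PartnerChoiceModel(df, spec).fit()
        mixed = PartnerChoiceModel(df, spec).fit(backend="mixed")
        assert mixed.backend == "mixed-glmer"
        shared = [t for t in TERMS if t in mixed.params.index]
        assert len(shared) == len(TERMS)
        assert np.allclose(mixed.params[shared], clog.params[shared],
                           atol=0.35)


class TestSummary:
    def test_summary_mentions_key_quantities(self, study_fit):
        text = study_fit.summary()
        assert "clogit" in text
        assert "rel_rank" in text
        assert "Log-likelihood" in text
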