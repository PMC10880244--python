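import numpy as np
import pandas as pd
import pytest

from icibench import (
    AginomeModel,
    BaselineModel,
    DukeLKB1Model,
    FicanOscarModel,
    GeneSet,
    IMiracleModel,
    NetpharModel,
    TrialDataset,
    make_model,
    score_dataset,
)
from icibench.models import (
    ModelContext,
    ModelInputError,
    aginome_score,
    fican_oscar_score,
    imiracle_score,
    netphar_score,
)

from conftest import make_clinical


# 9-patient cohort with distinct TMB values 10..90; upper tertile sits
# between 60 and 70 (linear interpolation gives 63.33)
TOY_TMB = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0]


def toy_context():
    ctx = ModelContext()
    ctx.tmb_upper_tertile = float(np.quantile(TOY_TMB, 2 / 3))
    return ctx


class TestNetphar:
    @pytest.mark.parametrize("tmb,pdl1,expected", [
        (100, 80, 0.0),     # conservative TMB-low branch
        (243, 0, 10.0),     # boundary: cut is inclusive
        (300, 50, 60.0),
        (None, 90, 0.0),    # missing TMB -> low branch
    ])
    def test_rule(self, tmb, pdl1, expected):
        assert netphar_score(tmb, pdl1) == expected

    def test_missing_pdl1_rejected(self):
        with pytest.raises(ModelInputError):
            netphar_score(300, None)

    def test_zero_iff_tmb_low(self):
        for tmb in (0, 100, 242, 243, 400):
            score = netphar_score(tmb, 25.0)
            assert (score == 0) == (tmb < 243)

    def test_estimator_imputes_missing_pdl1(self):
        clin = make_clinical(6)
        clin["tmb"] = [300.0, 100, 250, 50, 280, 90]
        clin.loc[0, "pdl1"] = np.nan
        model = NetpharModel().fit(TrialDataset(clin))
        values = model.predict(TrialDataset(clin))
        assert np.isfinite(values).all()
        # imputed patient got the cohort median PD-L1 on the high branch
        assert values[0] == pytest.approx(10 + clin["pdl1"].median())


class TestIMiracle:
    @pytest.mark.parametrize("tmb,pdl1,expected", [
        (90.0, 60.0, 3),   # top-tertile TMB, PD-L1 >= 50
        (10.0, 10.0, 1),   # both low
        (90.0, 10.0, 2),   # TMB high only
        (10.0, 60.0, 2),   # PD-L1 high only
    ])
    def test_rule_on_nine_patient_cohort(self, tmb, pdl1, expected):
        assert imiracle_score(tmb, pdl1, None, None, toy_context()) == expected

    def test_proliferation_proxy_when_tmb_missing(self):
        ctx = toy_context()
        ctx.proliferation_upper_tertile = 1.0
        assert imiracle_score(None, 60.0, 1.5, None, ctx) == 3
        assert imiracle_score(None, 60.0, 0.5, None, ctx) == 2

    def test_icr_proxy_when_pdl1_missing(self):
        ctx = toy_context()
        ctx.icr_upper_tertile = 0.5
        assert imiracle_score(90.0, None, None, 0.7, ctx) == 3

    def test_both_of_a_proxy_pair_missing_rejected(self):
        with pytest.raises(ModelInputError):
            imiracle_score(None, 60.0, None, None, toy_context())

    def test_monotone_in_tmb_and_pdl1(self):
        ctx = toy_context()
        grid = [(t, p) for t in TOY_TMB for p in (0.0, 30.0, 50.0, 90.0)]
        for t, p in grid:
            s = imiracle_score(t, p, None, None, ctx)
            assert s in (1, 2, 3)
            assert imiracle_score(t + 50, p, None, None, ctx) >= s
            assert imiracle_score(t, min(p + 50, 100), None, None, ctx) >= s

    def test_estimator_scores_after_tmb_masking(self, predictive_trial):
        """Proxy rule keeps every patient scoreable at 30% missing TMB."""
        from icibench import inject_missingness, signature_gene_sets
        from icibench.synthetic import SimulationConfig

        blocks = {gs.name: gs for gs in signature_gene_sets(SimulationConfig())}
        masked = inject_missingness(predictive_trial, tmb_fraction=0.3, seed=5)
        model = IMiracleModel(
            proliferation_genes=blocks["proliferation_signature"],
            icr_genes=blocks["immune_signature"])
        values = model.fit(masked).predict(masked)
        assert len(values) == masked.n_patients
        assert set(np.unique(values)) <= {1.0, 2.0, 3.0}


class TestAginome:
    def _ctx(self):
        return ModelContext(tmb_median=100.0, pdl1_median=50.0,
                            tmb_bounds=(0.0, 200.0), pdl1_bounds=(0.0, 100.0))

    def test_group1_whenever_pdl1_below_median(self):
        for tmb in (0.0, 150.0, 200.0):
            score = aginome_score(tmb, 10.0, self._ctx())
            assert 10.0 <= score < 20.0  # group-1 band

    def test_group_ordering_3_1_2(self):
        ctx = self._ctx()
        g3 = aginome_score(150.0, 90.0, ctx)
        g1 = aginome_score(150.0, 10.0, ctx)
        g2 = aginome_score(50.0, 90.0, ctx)
        assert g3 > g1 > g2

    def test_group3_within_score(self):
        # TMB_norm = 1, PD-L1_norm = 0.5 -> 2.0 within-group, offset 20
        score = aginome_score(200.0, 50.0, self._ctx())
        assert score == pytest.approx(22.0)

    def test_cross_group_pairs_strictly_ordered(self, null_trial):
        model = AginomeModel().fit(null_trial)
        values = model.predict(null_trial)
        clin = null_trial.clinical
        tmb = clin["tmb"].fillna(model.context_.tmb_median)
        pdl1 = clin["pdl1"].fillna(model.context_.pdl1_median)
        group = np.where(pdl1 < model.context_.pdl1_median, 1,
                         np.where(tmb < model.context_.tmb_median, 2, 3))
        assert values[group == 3].min() > values[group == 1].max()
        assert values[group == 1].min() > values[group == 2].max()

    def test_missing_values_rejected_when_imputation_off(self):
        clin = make_clinical(5)
        clin.loc[0, "tmb"] = np.nan
        with pytest.raises(ModelInputError):
            AginomeModel(impute_missing=False).fit(TrialDataset(clin))


class TestFicanOscar:
    def _ctx(self):
        return ModelContext(tmb_upper_tertile=100.0)

    def test_zero_input_scores_zero(self):
        got = fican_oscar_score("female", "nonsquamous", "never", 1,
                                50.0, 0.0, 0.0, self._ctx())
        assert got == 0.0

    def test_panel_coefficient(self):
        got = fican_oscar_score("female", "nonsquamous", "never", 1,
                                50.0, 0.0, 1.0, self._ctx())
        assert got == pytest.approx(-0.693)

    def test_four_indicator_sum(self):
        # male + eversmoker + ECOG0 + TMB-high, nonsquamous, panel 0
        got = fican_oscar_score("male", "nonsquamous", "ever", 0,
                                150.0, 0.0, 0.0, self._ctx())
        assert got == pytest.approx(-(0.357 + 0.105 + 0.223 + 0.105))

    def test_squamous_pdl1_interaction(self):
        ctx = self._ctx()
        low = fican_oscar_score("female", "squamous", "never", 1, 0.0, 5.0, 0.0, ctx)
        high = fican_oscar_score("female", "squamous", "never", 1, 0.0, 5.1, 0.0, ctx)
        assert high - low == pytest.approx(-0.05)

    def test_linear_in_disjoint_indicators(self):
        ctx = self._ctx()
        zero = fican_oscar_score("female", "nonsquamous", "never", 1, 0, 0, 0.0, ctx)
        a = fican_oscar_score("male", "nonsquamous", "never", 1, 0, 0, 0.0, ctx)
        b = fican_oscar_score("female", "nonsquamous", "ever", 1, 0, 0, 0.0, ctx)
        ab = fican_oscar_score("male", "nonsquamous", "ever", 1, 0, 0, 0.0, ctx)
        assert a + b - zero == pytest.approx(ab)

    def test_estimator_declares_benefit_low(self, predictive_trial):
        score = score_dataset(FicanOscarModel(), predictive_trial, "OS")
        assert score.direction == "benefit_low"


class TestDukeLKB1:
    def _dataset(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        clin = make_clinical(n, rng)
        expr = pd.DataFrame(rng.standard_normal((20, n)),
                            index=[f"G{i}" for i in range(20)],
                            columns=clin["patient_id"].tolist())
        sets = {"inflammatory": GeneSet("inf", ["G0", "G1", "G2", "G3"]),
                "lkb1_loss": GeneSet("lkb1", ["G4", "G5"]),
                "nrf2": GeneSet("nrf2", ["G6", "G7"]),
                "neuroendocrine": GeneSet("ne", ["G8", "G9"])}
        return TrialDataset(clin, expr), sets

    def test_tmb_indicator_thresholds(self):
        ds, sets = self._dataset()
        ds.clinical["tmb"] = np.arange(10.0, 130.0, 10.0)  # p67 ~ 84.7
        model = DukeLKB1Model(gene_sets=sets).fit(ds)
        feats = model.features(ds)
        p67 = model.context_.tmb_p67
        assert (feats["tmb_high"] == (ds.clinical["tmb"].to_numpy() > p67)).all()

    def test_constant_expression_zeroes_signatures(self):
        ds, sets = self._dataset()
        ds.expression.iloc[:, :] = 3.14
        model = DukeLKB1Model(gene_sets=sets).fit(ds)
        feats = model.features(ds)
        for col in ("inflammatory", "lkb1_loss", "nrf2", "neuroendocrine"):
            assert (feats[col] == 0).all()

    def test_signature_means_stratified_by_histology(self):
        ds, sets = self._dataset()
        model = DukeLKB1Model(gene_sets=sets).fit(ds)
        feats = model.features(ds)
        clin = ds.clinical.set_index("patient_id")
        for stratum in ("squamous", "nonsquamous"):
            pids = clin.index[clin["histology"] == stratum]
            # z-scoring within stratum: signature means average to ~0 per stratum
            assert feats.loc[pids, "inflammatory"].mean() == pytest.approx(0, abs=1e-9)

    def test_default_weights_signed_sum(self):
        ds, sets = self._dataset()
        model = DukeLKB1Model(gene_sets=sets).fit(ds)
        feats = model.features(ds)
        expected = (feats["tmb_high"] + feats["pdl1_high"] + feats["inflammatory"]
                    - feats["lkb1_loss"] - feats["nrf2"] - feats["neuroendocrine"])
        np.testing.assert_allclose(model.predict(ds), expected.to_numpy())

    def test_small_stratum_rejected(self):
        ds, sets = self._dataset()
        ds.clinical["histology"] = ["squamous"] + ["nonsquamous"] * 11
        with pytest.raises(Exception):
            DukeLKB1Model(gene_sets=sets).fit(ds)


class TestBaselines:
    def test_tmb_identity(self):
        clin = make_clinical(3)
        clin["tmb"] = [10.0, 200.0, 400.0]
        values = BaselineModel("tmb").fit_predict(TrialDataset(clin))
        np.testing.assert_allclose(values, [10, 200, 400])

    def test_missing_imputed_with_cohort_median(self):
        clin = make_clinical(5)
        clin["tmb"] = [10.0, 20.0, np.nan, 40.0, 50.0]
        values = BaselineModel("tmb").fit_predict(TrialDataset(clin))
        assert values[2] == 30.0

    def test_pdl1_baseline(self):
        clin = make_clinical(4)
        values = BaselineModel("pdl1").fit_predict(TrialDataset(clin))
        np.testing.assert_allclose(values, clin["pdl1"].to_numpy())

    def test_entirely_missing_variable_rejected(self):
        clin = make_clinical(4)
        clin["tmb"] = np.nan
        with pytest.raises(ModelInputError):
            BaselineModel("tmb").fit(TrialDataset(clin))


class TestEstimatorApi:
    def test_registry_and_sklearn_params(self):
        model = make_model("imiracle")
        params = model.get_params()
        assert "proliferation_genes" in params
        model.set_params(proliferation_genes=GeneSet("p", ["G1"]))
        assert model.get_params()["proliferation_genes"].name == "p"
        with pytest.raises(ModelInputError):
            make_model("nope")

    def test_predict_before_fit_raises(self, toy_dataset):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            NetpharModel().predict(toy_dataset)

    @pytest.mark.parametrize("name", ["netphar", "aginome", "baseline_tmb",
                                      "baseline_pdl1", "fican_oscar"])
    def test_scores_invariant_to_patient_ordering(self, name, null_trial):
        model = make_model(name)
        forward = score_dataset(model, null_trial, "PFS")
        perm = null_trial.clinical.sample(frac=1.0, random_state=9)
        shuffled = type(null_trial)(perm, null_trial.expression[perm["patient_id"].tolist()])
        backward = score_dataset(make_model(name), shuffled, "PFS")
        for pid in null_trial.patient_ids:
            assert backward.scores[pid] == pytest.approx(forward.scores[pid])
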