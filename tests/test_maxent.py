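"""Maximum-entropy model: optimizer correctness, AUC, contributions."""

import numpy as np
import pandas as pd
import pytest

from forestrisk.maxent import (MaxentRiskModel, SavedModel, auc,
                               _penalized_objective)


def _binary_toy(n_pres=30, n_bg=200, seed=0):
    """One binary feature; presences only where the feature is 1."""
    rng = np.random.default_rng(seed)
    Fb = (rng.random((n_bg, 1)) < 0.3).astype(float)
    Fp = np.ones((n_pres, 1))
    return Fp, Fb


class TestFitOracle:
    def test_constant_features_give_uniform_model(self):
        Fp = np.full((10, 2), 0.5)
        Fb = np.full((50, 2), 0.5)
        model = MaxentRiskModel.from_features(Fp, Fb, 0.05)
        with pytest.warns(UserWarning, match="constant"):
            res = model.fit()
        q = np.exp(res.score_points(model.background) - res.lnZ)
        np.testing.assert_allclose(q, 1 / 50, rtol=1e-12)
        assert res.entropy == pytest.approx(np.log(50))

    def test_single_feature_matches_brute_force_grid(self):
        Fp, Fb = _binary_toy()
        beta = 1.0
        model = MaxentRiskModel.from_features(Fp, Fb, beta)
        res = model.fit()
        lam_grid = np.arange(-20, 20, 1e-4)
        n1 = Fb.sum()
        n0 = len(Fb) - n1
        # objective(lam) = lam*mean_p(f) - ln(n0 + n1*e^lam) - beta|lam|
        obj = lam_grid - np.log(n0 + n1 * np.exp(lam_grid)) - beta * np.abs(lam_grid)
        lam_star = lam_grid[np.argmax(obj)]
        assert res.params.iloc[0] == pytest.approx(lam_star, abs=1e-3)

    def test_two_feature_fit_matches_refined_grid_search(self):
        rng = np.random.default_rng(4)
        Fb = rng.random((150, 2)).round(1)
        w = np.array([2.0, -1.0])
        p = np.exp(Fb @ w)
        p /= p.sum()
        idx = rng.choice(len(Fb), size=60, p=p)
        Fp = Fb[idx]
        beta = np.array([0.02, 0.02])
        res = MaxentRiskModel.from_features(Fp, Fb, beta).fit()

        def scan(center, half, step):
            g = np.arange(-half, half + step / 2, step)
            best, best_val = None, -np.inf
            for l0 in center[0] + g:
                for l1 in center[1] + g:
                    v = _penalized_objective(np.array([l0, l1]), Fp, Fb, beta)
                    if v > best_val:
                        best, best_val = (l0, l1), v
            return np.array(best)

        coarse = scan(np.zeros(2), 6.0, 0.05)
        fine = scan(coarse, 0.06, 5e-4)
        np.testing.assert_allclose(res.params.to_numpy(), fine, atol=1e-3)

    def test_kkt_slack_condition_on_every_fit(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Fb = rng.random((300, 3))
            Fp = Fb[rng.choice(300, 40, p=np.exp(Fb[:, 0]) / np.exp(Fb[:, 0]).sum())]
            res = MaxentRiskModel.from_features(Fp, Fb, 0.02).fit()
            # |E_q[f_j] - mean_presence[f_j]| <= beta_j for every feature
            assert res.max_kkt_violation <= 1e-4

    def test_objective_non_decreasing_across_iterations(self):
        Fp, Fb = _binary_toy(seed=3)
        res = MaxentRiskModel.from_features(Fp, Fb, 0.1).fit()
        path = np.asarray(res.objective_path)
        assert (np.diff(path) >= -1e-10).all()

    def test_non_finite_features_rejected(self):
        bg = pd.DataFrame({"a": [0.0, 1.0, np.nan]})
        pres = pd.DataFrame({"a": [1.0, 1.0]})
        with pytest.raises(ValueError, match="non-finite"):
            MaxentRiskModel(pres, bg)

    def test_too_few_presences_rejected(self):
        df = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError, match="2 presence"):
            MaxentRiskModel(df, pd.DataFrame({"a": [0.0, 1.0]}))


class TestPredict:
    def test_uniform_model_logistic_is_half(self, pipeline_result):
        stack = pipeline_result.stack
        model = MaxentRiskModel.from_stack(
            stack, pipeline_result.presence, pipeline_result.background,
            ["accessibility"])
        model.Fp = np.full_like(model.Fp, 0.5)
        model.Fb = np.full_like(model.Fb, 0.5)
        with pytest.warns(UserWarning):
            res = model.fit()
        # H = ln N makes q' e^H = 1 for every background-typical cell
        q = 1 / len(model.background)
        assert q * np.exp(res.entropy) == pytest.approx(1.0)

    def test_raw_sums_to_one_over_background(self, pipeline_result):
        res = pipeline_result.results
        raw = res.raw_at(pipeline_result.model.background)
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scales_are_monotone_in_score(self, pipeline_result):
        res = pipeline_result.results
        stack = pipeline_result.stack
        raw = res.predict(stack, scale="raw").values.ravel()
        logi = res.predict(stack, scale="logistic").values.ravel()
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= -1e-12).all()
        assert ((logi >= 0) & (logi <= 1)).all()

    def test_save_load_bit_reproducible_prediction(self, tmp_path, pipeline_result):
        res = pipeline_result.results
        stack = pipeline_result.stack
        res.save(tmp_path / "model.json")
        saved = SavedModel.load(tmp_path / "model.json")
        np.testing.assert_array_equal(saved.predict(stack).values,
                                      res.predict(stack).values)


class TestAUC:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8]), np.array([0.1, 0.2])) == 1.0

    def test_identical_sets_half(self):
        s = np.array([0.3, 0.5, 0.7])
        assert auc(s, s) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, 30) / 10.0
        b = rng.integers(0, 10, 30) / 10.0
        pairs = (a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum()
        assert auc(a, b) == pytest.approx(pairs / (30 * 30), abs=1e-12)


class TestContribution:
    def test_single_variable_gets_all(self, pipeline_result):
        stack = pipeline_result.stack
        model = MaxentRiskModel.from_stack(
            stack, pipeline_result.presence, pipeline_result.background,
            ["accessibility"])
        res = model.fit()
        pc = res.percent_contribution(seed=0)
        assert pc["accessibility"] == pytest.approx(100.0)

    def test_duplicated_variable_shares_contribution(self, pipeline_result):
        stack = pipeline_result.stack
        pres = pipeline_result.presence
        bg = pipeline_result.background
        from forestrisk.maxent import values_at

        dfp = values_at(stack, ["accessibility"], pres)
        dfb = values_at(stack, ["accessibility"], bg)
        dfp["accessibility_copy"] = dfp["accessibility"]
        dfb["accessibility_copy"] = dfb["accessibility"]
        res = MaxentRiskModel(dfp, dfb).fit()
        pc = res.percent_contribution(m=10, seed=0)
        assert abs(pc["accessibility"] - pc["accessibility_copy"]) < 10

    def test_pure_noise_variable_scores_low(self, pipeline_result):
        stack = pipeline_result.stack
        from forestrisk.maxent import values_at

        rng = np.random.default_rng(8)
        dfp = values_at(stack, ["accessibility"], pipeline_result.presence)
        dfb = values_at(stack, ["accessibility"], pipeline_result.background)
        dfp["noise"] = rng.random(len(dfp))
        dfb["noise"] = rng.random(len(dfb))
        res = MaxentRiskModel(dfp, dfb).fit()
        pc = res.percent_contribution(m=10, seed=0)
        assert pc["noise"] < 5.0

    def test_contributions_sum_to_100(self, pipeline_result):
        pc = pipeline_result.results.percent_contribution(seed=3)
        assert pc.sum() == pytest.approx(100.0, abs=0.1)


class TestReplicate:
    def test_single_run_sd_zero_with_warning(self, pipeline_result):
        with pytest.warns(UserWarning, match="single run"):
            rep = pipeline_result.model.replicate(k=1, seed=0)
        assert rep.sd_auc == 0.0

    def test_same_base_seed_identical_report(self, pipeline_result):
        a = pipeline_result.model.replicate(k=3, seed=5)
        b = pipeline_result.model.replicate(k=5, seed=5)
        np.testing.assert_array_equal(a.auc_values, b.auc_values[:3])
        c = pipeline_result.model.replicate(k=3, seed=5)
        assert a.mean_auc == c.mean_auc and a.sd_auc == c.sd_auc

    def test_strong_signal_auc_above_09(self, pipeline_result):
        rep = pipeline_result.model.replicate(k=8, seed=2)
        assert rep.mean_auc > 0.85
        table = rep.to_table()
        assert list(table.columns) == ["variable", "percent_contribution",
                                       "mean_auc", "sd_auc"]
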