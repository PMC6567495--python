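"""Scale scoring, Cronbach's alpha, and the GEE marginal models."""

import numpy as np
import pandas as pd
import pytest

from teamdyn.association import (
    SCALE_PARTICIPATION,
    SCALE_SUPPORT,
    build_gee_data,
    cronbach_alpha,
    fit_gee,
    item_matrix,
    run_association,
    score_scale,
    variance_inflation,
)

from oracles import ols_fit


def _responses(rows):
    return pd.DataFrame(rows, columns=["participant", "group", "item", "value"])


class TestScoreScale:
    def test_all_sevens_score_seven(self):
        resp = _responses([("p1", "g1", i, 7) for i in range(1, 4)])
        participant, group = score_scale(resp)
        assert participant["score"].tolist() == [7.0]
        assert group["score"].tolist() == [7.0]

    def test_item_mean(self):
        resp = _responses([("p1", "g1", 1, 4), ("p1", "g1", 2, 5), ("p1", "g1", 3, 6)])
        participant, _ = score_scale(resp)
        assert participant["score"].item() == pytest.approx(5.0)

    def test_row_order_invariance(self):
        rows = [("p1", "g1", 1, 2), ("p2", "g1", 1, 6), ("p3", "g2", 1, 4)]
        a, _ = score_scale(_responses(rows))
        b, _ = score_scale(_responses(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_group_mean_recovery(self):
        """Observed group means recover each group's latent mean (generated
        around 5.7 with noise 0.3) to well within 0.3 on average."""
        from teamdyn.synthetic import StudyGenConfig, generate_study

        errs = []
        for seed in range(5):
            ds = generate_study(
                StudyGenConfig(n_groups=10, events_mean=60, events_sd=10,
                               beta0_participation=5.7, beta_participation_rr=0.0,
                               noise_sd_group=0.3, seed=seed)
            )
            sub = ds.responses[ds.responses["scale"] == SCALE_PARTICIPATION]
            _, group = score_scale(sub)
            latent = ds.truth["latent_group_means"]
            for _, row in group.iterrows():
                errs.append(abs(row["score"] - latent[row["group"]][SCALE_PARTICIPATION]))
        assert np.mean(errs) < 0.3

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            score_scale(pd.DataFrame({"participant": ["p1"], "value": [3]}))


class TestCronbachAlpha:
    def test_duplicated_items_give_one(self):
        col = np.array([1.0, 4, 6, 2, 7])
        assert cronbach_alpha(np.column_stack([col, col, col])) == pytest.approx(1.0)

    def test_matches_direct_variance_formula(self):
        x = np.array([[2, 3, 4], [4, 4, 5], [6, 5, 6], [1, 2, 2]], dtype=float)
        k = 3
        expected = k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / x.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(x) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(12)
        latent = rng.normal(size=(40, 1))
        x = latent + rng.normal(scale=0.8, size=(40, 5))
        ref = pg.cronbach_alpha(data=pd.DataFrame(x))[0]
        assert cronbach_alpha(x) == pytest.approx(ref, abs=1e-10)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2000, 4))
        assert abs(cronbach_alpha(x)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cronbach_alpha(np.full((5, 3), 4.0))

    def test_item_matrix_requires_complete_responses(self):
        resp = _responses([("p1", "g1", 1, 3), ("p2", "g1", 2, 4)])
        with pytest.raises(ValueError, match="incomplete"):
            item_matrix(resp)


def _gee_frame(rng, n_groups=20, group_size=4, slope_rr=0.0):
    rows = []
    for g in range(n_groups):
        rr, det, ent = rng.uniform(5, 20), rng.uniform(20, 50), rng.uniform(0.3, 1.5)
        for p in range(group_size):
            rows.append(
                {"group": f"g{g}", "participant": f"g{g}p{p}",
                 "score": 4 + slope_rr * rr + rng.normal(0, 0.5),
                 "rr": rr, "det": det, "ent": ent}
            )
    return pd.DataFrame(rows)


class TestFitGEE:
    def test_independence_equals_pooled_ols(self):
        """With the working correlation fixed at zero the GEE point estimates
        are ordinary least squares on the pooled data."""
        rng = np.random.default_rng(21)
        data = _gee_frame(rng, slope_rr=0.02)
        fit = fit_gee(data, cov_struct="independence")
        x_rows = [[1.0, r.rr, r.det, r.ent] for r in data.itertuples()]
        beta = ols_fit(x_rows, data["score"].tolist())
        for term, b_ref in zip(fit.terms, beta):
            assert term.b == pytest.approx(b_ref, abs=1e-8)

    def test_single_member_clusters_match_ols(self):
        rng = np.random.default_rng(22)
        data = _gee_frame(rng, group_size=1, n_groups=40)
        fit = fit_gee(data)  # exchangeable degenerates with singleton clusters
        x_rows = [[1.0, r.rr, r.det, r.ent] for r in data.itertuples()]
        beta = ols_fit(x_rows, data["score"].tolist())
        for term, b_ref in zip(fit.terms, beta):
            assert term.b == pytest.approx(b_ref, abs=1e-8)

    def test_constant_outcome_gives_flat_model(self):
        rng = np.random.default_rng(23)
        data = _gee_frame(rng)
        data["score"] = 5.5
        fit = fit_gee(data)
        assert fit.term("(Intercept)").b == pytest.approx(5.5, abs=1e-8)
        for name in ("Stability", "Determinism", "Complexity"):
            assert fit.term(name).b == pytest.approx(0.0, abs=1e-8)

    def test_ci_brackets_estimate_and_wald_consistent(self):
        rng = np.random.default_rng(24)
        fit = fit_gee(_gee_frame(rng))
        for term in fit.terms:
            assert term.ci_low <= term.b <= term.ci_high
            assert term.wald == pytest.approx((term.b / term.se) ** 2)
            assert 0 <= term.p <= 1

    def test_estimated_rho_in_valid_range(self):
        rng = np.random.default_rng(25)
        fit = fit_gee(_gee_frame(rng))
        assert -1 / 3 < fit.rho < 1

    def test_rank_deficiency_detected(self):
        rng = np.random.default_rng(26)
        data = _gee_frame(rng)
        data["ent"] = data["rr"] * 2  # exactly collinear
        with pytest.raises(ValueError, match="rank deficient"):
            fit_gee(data)

    def test_too_few_clusters_rejected(self):
        data = _gee_frame(np.random.default_rng(27), n_groups=1)
        with pytest.raises(ValueError):
            fit_gee(data)


class TestQIC:
    def test_finite_for_nested_models(self):
        rng = np.random.default_rng(31)
        data = _gee_frame(rng, slope_rr=0.03)
        full = fit_gee(data)
        reduced = fit_gee(data, predictors=("rr",))
        assert np.isfinite(full.qic) and np.isfinite(reduced.qic)

    def test_trace_penalty_positive(self):
        rng = np.random.default_rng(32)
        data = _gee_frame(rng)
        fit_ind = fit_gee(data, cov_struct="independence")
        # QIC = -2 QL + 2 trace; under independence trace > 0 always
        import statsmodels.api as sm

        exog = sm.add_constant(data[["rr", "det", "ent"]])
        res = sm.GEE(data["score"], exog, groups=data["group"],
                     family=sm.families.Gaussian(),
                     cov_struct=sm.cov_struct.Independence()).fit()
        qic, qicu = res.qic(scale=res.scale)
        trace = (qic - qicu) / 2 + len(res.params)  # qicu uses 2p in place of 2 trace
        assert trace > 0

    def test_trace_approaches_parameter_count_under_independence_truth(self):
        """With truly independent observations the QIC penalty trace(Omega V)
        is close to the parameter count p."""
        import statsmodels.api as sm

        rng = np.random.default_rng(33)
        rows = []
        for g in range(200):
            rr, det, ent = rng.uniform(5, 20), rng.uniform(20, 50), rng.uniform(0.3, 1.5)
            rows.append({"group": f"g{g}", "score": 4 + rng.normal(),
                         "rr": rr, "det": det, "ent": ent})
        data = pd.DataFrame(rows)
        exog = sm.add_constant(data[["rr", "det", "ent"]])
        res = sm.GEE(data["score"], exog, groups=data["group"],
                     family=sm.families.Gaussian(),
                     cov_struct=sm.cov_struct.Independence()).fit()
        qic, qicu = res.qic(scale=res.scale)
        p = len(res.params)
        trace = (qic - qicu) / 2 + p
        assert trace == pytest.approx(p, rel=0.3)


class TestRunAssociation:
    def test_two_models_times_four_terms(self, small_study):
        table, details = run_association(small_study.measures_frame(), small_study.responses)
        assert len(table) == 8
        assert set(table["Outcome"]) == {SCALE_PARTICIPATION, SCALE_SUPPORT}
        assert list(table["Parameter"][:4]) == [
            "(Intercept)", "Stability", "Determinism", "Complexity"
        ]
        assert set(details["alpha"]) == {SCALE_PARTICIPATION, SCALE_SUPPORT}

    def test_vif_reported_per_predictor(self, small_study):
        participant, _ = score_scale(
            small_study.responses[small_study.responses["scale"] == SCALE_SUPPORT]
        )
        data = build_gee_data(small_study.measures_frame(), participant)
        vif = variance_inflation(data)
        assert set(vif) == {"rr", "det", "ent"}
        assert all(v >= 1 for v in vif.values())

    def test_null_simulation_type_i_error(self):
        """With zero true slopes each term is declared significant at the
        5% level in only a small fraction of replicates."""
        from teamdyn.synthetic import StudyGenConfig, generate_study

        flags = {"Stability": 0, "Determinism": 0, "Complexity": 0}
        n_reps = 20
        for rep in range(n_reps):
            ds = generate_study(
                StudyGenConfig(n_groups=28, events_mean=80, events_sd=20,
                               beta_support_rr=0.0, beta_support_det=0.0, seed=7000 + rep)
            )
            sub = ds.responses[ds.responses["scale"] == SCALE_SUPPORT]
            participant, _ = score_scale(sub)
            fit = fit_gee(build_gee_data(ds.measures_frame(), participant))
            for name in flags:
                if fit.term(name).p < 0.05:
                    flags[name] += 1
        for name, count in flags.items():
            assert count <= 0.25 * n_reps, f"{name} rejected too often under the null"
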