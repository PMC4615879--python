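"""Gamma/log-link GLM fitting and least-squares means."""

import numpy as np
import pytest

from gdft_impact import (CollinearityError, NotConvergedError, fit_gamma_glm,
                         ls_means)

from conftest import make_record


def simulate_glm_records(n, beta, shape=1.2, seed=0, procedures=("colectomy",)):
    """Records whose costs follow a gamma GLM with known coefficients."""
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < 0.4
    age = np.clip(rng.normal(65, 15, n), 18, None)
    cci = rng.poisson(1.8, n)
    male = rng.random(n) < 0.4
    elective = rng.random(n) < 0.55
    proc = rng.choice(procedures, n)
    eta = (beta.get("intercept", 9.0)
           + beta.get("complication", 0.0) * comp
           + beta.get("age", 0.0) * age
           + beta.get("cci", 0.0) * cci
           + beta.get("gender_male", 0.0) * male
           + beta.get("elective", 0.0) * elective)
    cost = rng.gamma(shape, np.exp(eta) / shape)
    return [make_record(patient_id=f"g{i}", procedure=str(proc[i]),
                        age=float(age[i]),
                        gender="male" if male[i] else "female",
                        elective=bool(elective[i]), cci=int(cci[i]),
                        complication=bool(comp[i]), cost=float(cost[i]))
            for i in range(n)]


class TestFitGammaGlm:
    def test_intercept_only_recovers_sample_mean(self):
        # the gamma/log score equation forces fitted mean == sample mean
        rng = np.random.default_rng(4)
        costs = rng.gamma(2.0, 5000, 300)
        records = [make_record(patient_id=f"c{i}", cost=float(c))
                   for i, c in enumerate(costs)]
        model = fit_gamma_glm(records, terms=[])
        assert np.exp(model.coefficients["intercept"]) == pytest.approx(
            costs.mean(), rel=1e-6)

    def test_two_group_effect_equals_ratio_of_means(self):
        rng = np.random.default_rng(5)
        with_costs = rng.gamma(1.5, 20_000, 400)
        without_costs = rng.gamma(1.5, 10_000, 600)
        records = ([make_record(patient_id=f"w{i}", complication=True,
                                cost=float(c))
                    for i, c in enumerate(with_costs)]
                   + [make_record(patient_id=f"o{i}", complication=False,
                                  cost=float(c))
                      for i, c in enumerate(without_costs)])
        model = fit_gamma_glm(records, terms=["complication"])
        ratio = with_costs.mean() / without_costs.mean()
        assert np.exp(model.coefficients["complication"]) == pytest.approx(ratio, rel=1e-6)

    def test_parameter_recovery_within_3_se(self):
        beta = {"intercept": 9.2, "complication": np.log(1.75), "age": 0.004,
                "cci": 0.05, "gender_male": 0.02, "elective": -0.05}
        records = simulate_glm_records(20_000, beta, seed=7)
        model = fit_gamma_glm(records)
        assert model.converged
        est = model.coefficients["complication"]
        se = model.std_errors["complication"]
        assert abs(est - np.log(1.75)) < 3 * se

    def test_dispersion_estimates_inverse_shape(self):
        shape = 1.2
        records = simulate_glm_records(20_000, {"complication": 0.5}, shape=shape,
                                       seed=8)
        model = fit_gamma_glm(records)
        assert model.dispersion == pytest.approx(1 / shape, rel=0.05)

    def test_score_equations_satisfied_at_fit(self):
        # IRLS fixed point: for gamma/log, residuals (y - mu) / mu are
        # orthogonal to every design column
        records = simulate_glm_records(2_000, {"complication": 0.4, "age": 0.01},
                                       seed=9)
        model = fit_gamma_glm(records)
        from gdft_impact.adjusted import design_matrix
        X, y = design_matrix(records)
        beta = np.array([model.coefficients[c] for c in X.columns])
        mu = np.exp(X.to_numpy() @ beta)
        score = X.to_numpy().T @ ((y - mu) / mu)
        assert np.max(np.abs(score)) / len(y) < 1e-6

    def test_collinear_design_names_columns(self):
        records = simulate_glm_records(200, {"complication": 0.4}, seed=10)
        for r in records:  # elective duplicates gender exactly
            r.elective = r.gender == "male"
        with pytest.raises(CollinearityError, match="collinear"):
            fit_gamma_glm(records)

    def test_zero_cost_records_excluded(self, caplog):
        records = simulate_glm_records(500, {"complication": 0.4}, seed=11)
        records[0].cost = 0.0
        with caplog.at_level("WARNING"):
            model = fit_gamma_glm(records)
        assert model.n_dropped_zero_cost == 1
        assert model.n_used == 499

    def test_procedure_covariate_preserves_effect_sign(self):
        beta = {"intercept": 9.3, "complication": 0.5, "age": 0.003}
        records = simulate_glm_records(
            5_000, beta, seed=12,
            procedures=("colectomy", "gastrectomy", "cystectomy"))
        base = fit_gamma_glm(records, include_procedure=False)
        sens = fit_gamma_glm(records, include_procedure=True)
        assert base.coefficients["complication"] > 0
        assert sens.coefficients["complication"] > 0
        assert any(t.startswith("procedure[") for t in sens.terms)


class TestLsMeans:
    def test_zero_effect_gives_equal_means(self):
        records = simulate_glm_records(3_000, {"complication": 0.0, "age": 0.005},
                                       seed=13)
        model = fit_gamma_glm(records)
        model.coefficients["complication"] = 0.0
        res = ls_means(model)
        assert res.mean_with == pytest.approx(res.mean_without)
        assert res.difference == pytest.approx(0.0)

    def test_no_covariate_model_matches_raw_group_means(self):
        rng = np.random.default_rng(14)
        with_costs = rng.gamma(2, 12_000, 300)
        without_costs = rng.gamma(2, 6_000, 500)
        records = ([make_record(patient_id=f"w{i}", complication=True, cost=float(c))
                    for i, c in enumerate(with_costs)]
                   + [make_record(patient_id=f"o{i}", complication=False, cost=float(c))
                      for i, c in enumerate(without_costs)])
        model = fit_gamma_glm(records, terms=["complication"])
        res = ls_means(model)  # reference grid collapses to the group factor
        assert res.mean_with == pytest.approx(with_costs.mean(), rel=1e-6)
        assert res.mean_without == pytest.approx(without_costs.mean(), rel=1e-6)

    def test_unconverged_model_rejected(self):
        records = simulate_glm_records(500, {"complication": 0.4}, seed=15)
        model = fit_gamma_glm(records)
        model.converged = False
        with pytest.raises(NotConvergedError):
            ls_means(model)

    def test_ls_means_bounded_by_grid_extremes(self):
        beta = {"intercept": 9.2, "complication": 0.5, "age": 0.004,
                "gender_male": 0.1, "elective": -0.2}
        records = simulate_glm_records(5_000, beta, seed=16)
        model = fit_gamma_glm(records)
        res = ls_means(model)
        b = model.coefficients
        age_term = b["age"] * model.covariate_means["age"]
        cci_term = b["cci"] * model.covariate_means["cci"]
        cells = [np.exp(b["intercept"] + b["complication"] + age_term + cci_term
                        + g * b["gender_male"] + e * b["elective"])
                 for g in (0, 1) for e in (0, 1)]
        assert min(cells) <= res.mean_with <= max(cells)

    def test_recovers_injected_adjusted_difference(self):
        """With effects injected so the true balanced-grid difference is
        ~$10,549, the fitted LS-means difference lands within 15%."""
        target_ratio = 25_390 / 14_841
        beta = {"intercept": 8.0, "complication": np.log(target_ratio),
                "age": 0.006, "cci": 0.08, "gender_male": 0.02,
                "elective": -0.10}
        records = simulate_glm_records(20_000, beta, seed=17)
        model = fit_gamma_glm(records)
        # true LS-means on the same grid, from the generating coefficients
        means = model.covariate_means
        cont = beta["age"] * means["age"] + beta["cci"] * means["cci"]
        cells = np.array([g * beta["gender_male"] + e * beta["elective"]
                          for g in (0, 1) for e in (0, 1)])
        true_without = float(np.exp(beta["intercept"] + cont + cells).mean())
        scale_adjust = 14_841 / true_without  # put the baseline on the $ scale
        res = ls_means(model)
        true_diff = true_without * scale_adjust * (target_ratio - 1)
        assert true_diff == pytest.approx(10_549, rel=0.01)
        assert res.difference * scale_adjust == pytest.approx(true_diff, rel=0.15)
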