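import numpy as np
import pandas as pd
import pytest

from hullbsp.calibration_fit import (
    PairedDataset,
    Phylogeny,
    bm_covariance,
    build_calibration,
    fit_ols,
    fit_pgls_bm,
    loocv_rmse,
    select_model,
    transform_values,
)
from hullbsp.synthetic_data import (
    SimulationConfig,
    generate_paired_dataset,
    simulate_bm,
    simulate_tree,
)


def star_tree(n: int, depth: float = 1.0) -> Phylogeny:
    labels = [f"t{i}" for i in range(n)]
    newick = "(" + ",".join(f"{lab}:{depth}" for lab in labels) + ");"
    return Phylogeny.from_newick(newick)


class TestTransformValues:
    def test_mass_log10(self):
        np.testing.assert_allclose(
            transform_values([1.0, 10.0, 100.0], "mass"), [0.0, 1.0, 2.0]
        )

    def test_cm_x_identity(self):
        values = [-0.2, 0.0, 0.7]
        np.testing.assert_array_equal(transform_values(values, "cm_x"), values)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            transform_values([1.0, 0.0, 2.0], "mass")

    @pytest.mark.parametrize("parameter", ["mass", "ixx", "iyy", "izz"])
    def test_log_parameters(self, parameter):
        assert transform_values([10.0], parameter)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("parameter", ["cm_x", "cm_y", "cm_z", "ixy", "ixz", "iyz"])
    def test_linear_parameters(self, parameter):
        assert transform_values([-3.5], parameter)[0] == -3.5


class TestFitOls:
    def test_two_point_plus_midpoint_exact(self):
        fit = fit_ols([0.0, 0.5, 1.0], [2.0, 2.5, 3.0])
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_y(self):
        fit = fit_ols([0.0, 1.0, 2.0, 3.0], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = 0.4 + 1.3 * x + rng.normal(size=30) * 0.2
        fit = fit_ols(x, y)
        X = np.column_stack([np.ones(30), x])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y  # independent closed form
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_loglik_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = 1.0 + 0.5 * x + rng.normal(size=20) * 0.3
        fit = fit_ols(x, y)
        resid = y - fit.intercept - fit.slope * x
        sigma2 = np.mean(resid**2)
        expected = float(
            np.sum(-0.5 * np.log(2 * np.pi * sigma2) - resid**2 / (2 * sigma2))
        )
        assert fit.loglik == pytest.approx(expected, rel=1e-10)
        assert fit.aic == pytest.approx(6 - 2 * expected, rel=1e-10)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        y = 2.0 - 0.7 * x + rng.normal(size=15) * 0.1
        fit = fit_ols(x, y)
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_ols([0.0, 1.0], [0.0, 1.0])


class TestBmCovariance:
    def test_star_tree_diagonal(self):
        tree = star_tree(5, depth=2.5)
        V = bm_covariance(tree, [f"t{i}" for i in range(5)])
        np.testing.assert_allclose(V, 2.5 * np.eye(5), atol=1e-12)

    def test_two_tip_tree(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        V = bm_covariance(tree, ["a", "b"])
        np.testing.assert_allclose(V, np.eye(2), atol=1e-12)

    def test_balanced_four_tip(self):
        tree = Phylogeny.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        V = bm_covariance(tree, ["a", "b", "c", "d"])
        expected = np.array([
            [2, 1, 0, 0],
            [1, 2, 0, 0],
            [0, 0, 2, 1],
            [0, 0, 1, 2],
        ], dtype=float)
        np.testing.assert_allclose(V, expected, atol=1e-12)

    def test_missing_species(self):
        tree = star_tree(3)
        with pytest.raises(KeyError, match="nosuch"):
            bm_covariance(tree, ["t0", "nosuch"])

    def test_simulated_tree_psd(self):
        tree = simulate_tree(16, 3)
        V = bm_covariance(tree, sorted(tree.tip_labels))
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) > 0)


class TestFitPglsBm:
    def test_star_tree_equals_ols(self):
        rng = np.random.default_rng(2)
        n = 12
        tree = star_tree(n, depth=3.0)
        x = rng.normal(size=n)
        y = 0.3 + 0.9 * x + rng.normal(size=n) * 0.2
        species = [f"t{i}" for i in range(n)]
        ols = fit_ols(x, y)
        pgls = fit_pgls_bm(x, y, tree, species)
        assert pgls.intercept == pytest.approx(ols.intercept, abs=1e-10)
        assert pgls.slope == pytest.approx(ols.slope, abs=1e-10)

    def test_identity_covariance_equal_loglik(self):
        # star with unit depth has V = I exactly: logliks must coincide
        rng = np.random.default_rng(9)
        n = 10
        tree = star_tree(n, depth=1.0)
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n) * 0.5
        species = [f"t{i}" for i in range(n)]
        ols = fit_ols(x, y)
        pgls = fit_pgls_bm(x, y, tree, species)
        assert pgls.loglik == pytest.approx(ols.loglik, abs=1e-10)
        assert pgls.aic == pytest.approx(ols.aic, abs=1e-10)

    def test_no_r2_reported(self):
        tree = star_tree(6)
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        y = x + rng.normal(size=6) * 0.1
        pgls = fit_pgls_bm(x, y, tree, [f"t{i}" for i in range(6)])
        assert pgls.r2 is None
        assert pgls.method == "PGLS-BM"

    def test_parameter_recovery_coverage(self):
        # slope CI should cover the truth in >= 90% of BM-noise replicates
        tree = simulate_tree(32, 77)
        species = sorted(tree.tip_labels)
        rng = np.random.default_rng(5)
        x = rng.uniform(-2, 2, size=32)
        covered = 0
        reps = 60  # fast subset; the 200-rep version runs in acceptance
        for rep in range(reps):
            eps = simulate_bm(tree, 0.5, 1000 + rep)
            y = 0.3 + 0.9 * x + np.array([eps[s] for s in species])
            fit = fit_pgls_bm(x, y, tree, species)
            if fit.slope_ci[0] <= 0.9 <= fit.slope_ci[1]:
                covered += 1
        assert covered / reps >= 0.85


class TestSelectModel:
    def _fit(self, aic):
        from hullbsp.calibration_fit import RegressionFit

        return RegressionFit(
            method="OLS" if aic is not None else "OLS",
            intercept=0.0, slope=1.0, sigma2=1.0, loglik=0.0, aic=aic,
            intercept_ci=(0, 0), slope_ci=(0, 0), n=10,
        )

    def test_lower_aic_wins(self):
        from dataclasses import replace

        ols = self._fit(10.0)
        pgls = replace(self._fit(12.0), method="PGLS-BM")
        assert select_model(ols, pgls).method == "OLS"
        assert select_model(replace(ols, aic=12.0), replace(pgls, aic=10.0)).method == "PGLS-BM"

    def test_tie_goes_to_ols(self):
        from dataclasses import replace

        ols = self._fit(10.0)
        pgls = replace(self._fit(10.0), method="PGLS-BM")
        assert select_model(ols, pgls).method == "OLS"

    def test_mismatched_n(self):
        from dataclasses import replace

        with pytest.raises(ValueError):
            select_model(self._fit(1.0), replace(self._fit(1.0), n=11))


class TestLoocvRmse:
    def test_collinear_zero(self):
        x = np.arange(5.0)
        assert loocv_rmse(x, 2 * x + 1) == pytest.approx(0.0, abs=1e-12)

    def test_refit_equals_hat_shortcut(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=25)
        y = 0.5 + 1.1 * x + rng.normal(size=25) * 0.3
        assert loocv_rmse(x, y, "refit") == pytest.approx(
            loocv_rmse(x, y, "hat"), abs=1e-10
        )

    def test_nonnegative(self):
        rng = np.random.default_rng(33)
        for _ in range(5):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            assert loocv_rmse(x, y) >= 0.0

    def test_too_few(self):
        with pytest.raises(ValueError):
            loocv_rmse([1, 2, 3], [1, 2, 3])


class TestBuildCalibration:
    def test_noiseless_recovery(self):
        config = SimulationConfig(
            n_species=30, seed=17, noise_sd=0.0,
            true_intercepts={("thigh", "mass"): 0.55},
            true_slopes={("thigh", "mass"): 0.94},
        )
        table, report = build_calibration(generate_paired_dataset(config))
        model = table.get("thigh", "mass")
        assert model.intercept == pytest.approx(0.55, abs=1e-10)
        assert model.slope == pytest.approx(0.94, abs=1e-10)

    def test_full_dataset_yields_130_models(self):
        config = SimulationConfig(n_species=8, seed=2, noise_sd=0.01)
        table, report = build_calibration(generate_paired_dataset(config))
        assert len(table) == 130
        assert len(report.rows) == 130

    def test_without_tree_all_ols(self):
        config = SimulationConfig(n_species=6, seed=5, noise_sd=0.05)
        table, _ = build_calibration(generate_paired_dataset(config))
        assert all(m.method == "OLS" for m in table.models.values())

    def test_with_tree_selects_by_aic(self):
        tree = simulate_tree(10, 40)
        config = SimulationConfig(n_species=10, seed=41, noise_sd=0.05)
        dataset = generate_paired_dataset(config, tree)
        table, report = build_calibration(dataset, tree)
        frame = report.to_frame()
        assert frame["aic_pgls"].notna().all()
        assert set(frame["chosen"]) <= {"OLS", "PGLS-BM"}

    def test_insufficient_cells_absent(self):
        config = SimulationConfig(
            n_species=5, seed=1, noise_sd=0.01, segments=("thigh",), parameters=("mass",)
        )
        dataset = generate_paired_dataset(config)
        frame = dataset.frame.copy()
        # add a second segment with only 2 species: too few to fit
        extra = frame.iloc[:2].copy()
        extra["segment"] = "shank"
        dataset2 = PairedDataset(pd.concat([frame, extra], ignore_index=True))
        table, _ = build_calibration(dataset2)
        table.get("thigh", "mass")
        with pytest.raises(KeyError):
            table.get("shank", "mass")

    def test_right_side_folding(self):
        # left and mirrored right rows must yield the same fit as left alone
        config = SimulationConfig(
            n_species=12, seed=9, noise_sd=0.02, segments=("arm",), parameters=("cm_y",)
        )
        dataset = generate_paired_dataset(config)
        left_fit, _ = build_calibration(dataset)
        flipped = dataset.frame.copy()
        flipped["side"] = "right"
        flipped[["hull_value", "soft_value"]] *= -1.0
        flipped["species"] = flipped["species"] + "_r"
        both = PairedDataset(pd.concat([dataset.frame, flipped], ignore_index=True))
        both_fit, _ = build_calibration(both)
        assert both_fit.get("arm", "cm_y").slope == pytest.approx(
            left_fit.get("arm", "cm_y").slope, rel=1e-9
        )

    def test_empty_dataset(self):
        empty = PairedDataset(pd.DataFrame(columns=[
            "species", "segment", "side", "parameter", "hull_value", "soft_value",
        ]))
        with pytest.raises(ValueError):
            build_calibration(empty)

    def test_parameter_recovery_within_2se(self):
        tree = simulate_tree(30, 13)
        config = SimulationConfig(
            n_species=30, seed=14, noise_sd=0.05, noise_mode="brownian",
            true_intercepts={("thigh", "mass"): 0.55},
            true_slopes={("thigh", "mass"): 0.94},
            segments=("thigh",), parameters=("mass",),
        )
        dataset = generate_paired_dataset(config, tree)
        table, report = build_calibration(dataset, tree)
        model = table.get("thigh", "mass")
        half_width = (model.slope_ci[1] - model.slope_ci[0]) / 2.0
        se = half_width / 2.0484  # t_{0.975, 28}
        assert abs(model.slope - 0.94) <= 2.5 * se
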