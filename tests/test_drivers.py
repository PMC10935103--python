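"""Correlation and path analysis: formula oracles and structural recovery."""

import numpy as np
import pandas as pd
import pytest

from bambooflux.drivers import (
    CHAINS,
    FACTORS,
    PATH_EDGES,
    fit_path_model,
    indirect_effects,
    pearson_matrix,
    simulate_path_data,
)

# a fixed coefficient set on the causal graph used across recovery tests
TRUE_PCS = {
    ("vpd", "pmax"): -0.15,
    ("prec", "pmax"): 0.05,
    ("par", "pmax"): 0.20,
    ("lai", "pmax"): 0.30,
    ("ta", "pmax"): 0.25,
    ("ts", "pmax"): 0.40,
    ("vpd", "re"): 0.10,
    ("prec", "re"): 0.05,
    ("par", "re"): 0.05,
    ("lai", "re"): 0.15,
    ("ta", "re"): 0.30,
    ("ts", "re"): 0.45,
    ("pmax", "gep"): 0.80,
    ("gep", "nee"): -0.85,
    ("re", "nee"): 0.40,
}


def _r_formula(x, y):
    """Pearson r from its definition (the independent oracle)."""
    xd = x - x.mean()
    yd = y - y.mean()
    return float(np.sum(xd * yd) / np.sqrt(np.sum(xd**2) * np.sum(yd**2)))


class TestPearson:
    @staticmethod
    def _table(x, y):
        frame = pd.DataFrame({f: np.nan for f in FACTORS} | {"nee": y}, dtype=float)
        frame["vpd"] = x
        for r in ("re", "gep", "pmax", "alpha"):
            frame[r] = np.nan
        return frame

    def test_identical_series_has_r_one(self):
        x = np.arange(10.0)
        table = self._table(x, x)
        out = pearson_matrix(table)
        r = out[(out.factor == "vpd") & (out.response == "nee")]["r"].iloc[0]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative_linearity(self):
        out = pearson_matrix(self._table([1.0, 2.0, 3.0], [6.0, 4.0, 2.0]))
        r = out[(out.factor == "vpd") & (out.response == "nee")]["r"].iloc[0]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        out = pearson_matrix(self._table(x, y))
        r = out[(out.factor == "vpd") & (out.response == "nee")]["r"].iloc[0]
        assert r == pytest.approx(_r_formula(x, y), abs=1e-12)

    def test_zero_variance_reported_as_undefined(self):
        out = pearson_matrix(self._table(np.ones(10), np.arange(10.0)))
        r = out[(out.factor == "vpd") & (out.response == "nee")]["r"].iloc[0]
        assert np.isnan(r)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r_xy = _r_formula(x, y)
        out = pearson_matrix(self._table(3.0 * x + 7.0, -2.0 * y + 1.0))
        r = out[(out.factor == "vpd") & (out.response == "nee")]["r"].iloc[0]
        assert abs(r) == pytest.approx(abs(r_xy), abs=1e-12)
        assert np.sign(r) == -np.sign(r_xy)

    def test_significance_stars_follow_p_thresholds(self):
        data = simulate_path_data(TRUE_PCS, n=300, seed=1)
        out = pearson_matrix(data, responses=("nee", "re", "gep", "pmax"))
        for _, row in out.iterrows():
            if not np.isfinite(row["p"]):
                continue
            expected = "**" if row["p"] < 0.01 else ("*" if row["p"] < 0.05 else "")
            assert row["sig"] == expected


class TestPathModel:
    def test_single_predictor_pc_equals_pearson_r(self):
        data = simulate_path_data(TRUE_PCS, n=200, seed=2)
        result = fit_path_model(data)
        r = _r_formula(data["pmax"].to_numpy(), data["gep"].to_numpy())
        assert result.coefficient("pmax", "gep") == pytest.approx(r, abs=1e-12)

    def test_recovery_within_three_monte_carlo_ses(self):
        """Estimates from one n=500 draw fall within 3 MC standard errors."""
        replicates = {edge: [] for edge in PATH_EDGES}
        for seed in range(40):
            result = fit_path_model(simulate_path_data(TRUE_PCS, n=500, seed=100 + seed))
            for edge in PATH_EDGES:
                replicates[edge].append(result.direct[edge])
        single = fit_path_model(simulate_path_data(TRUE_PCS, n=500, seed=7))
        for edge in PATH_EDGES:
            se = np.std(replicates[edge], ddof=1)
            assert abs(single.direct[edge] - TRUE_PCS[edge]) < 3 * se, edge

    def test_recovery_bias_small_over_replicates(self):
        """Mean absolute bias < 0.05 at n=500 across seeds."""
        sums = {edge: 0.0 for edge in PATH_EDGES}
        n_rep = 40
        for seed in range(n_rep):
            result = fit_path_model(simulate_path_data(TRUE_PCS, n=500, seed=200 + seed))
            for edge in PATH_EDGES:
                sums[edge] += result.direct[edge]
        for edge in PATH_EDGES:
            assert abs(sums[edge] / n_rep - TRUE_PCS[edge]) < 0.05, edge

    def test_orthogonal_factors_give_marginal_correlations(self):
        data = simulate_path_data(TRUE_PCS, n=4000, seed=9)
        # force exactly orthogonal, mean-zero factor columns (QR of a
        # centered matrix lies in the orthocomplement of the ones vector)
        x = data[list(FACTORS)].to_numpy()
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        q *= np.sqrt(len(data))
        for i, f in enumerate(FACTORS):
            data[f] = q[:, i]
        coefs = np.array([TRUE_PCS[(f, "pmax")] for f in FACTORS])
        data["pmax"] = q @ coefs  # deterministic, exactly linear
        result = fit_path_model(data)
        for f in FACTORS:
            r = _r_formula(data[f].to_numpy(), data["pmax"].to_numpy())
            assert result.coefficient(f, "pmax") == pytest.approx(r, abs=1e-9)

    def test_small_stratum_refused(self):
        data = simulate_path_data(TRUE_PCS, n=10, seed=1)
        with pytest.raises(ValueError, match="n=10"):
            fit_path_model(data)

    def test_collinear_design_flagged_not_fatal(self):
        data = simulate_path_data(TRUE_PCS, n=200, seed=3)
        data["ts"] = data["ta"]  # perfectly collinear factors
        result = fit_path_model(data)
        assert any("ridge" in f for f in result.flags)

    def test_r2_between_zero_and_one(self):
        result = fit_path_model(simulate_path_data(TRUE_PCS, n=300, seed=5))
        for child, r2 in result.r2.items():
            assert 0.0 <= r2 <= 1.0, child

    def test_matches_statsmodels_ols_oracle(self):
        """Dual route: normal equations vs an independent OLS implementation."""
        import statsmodels.api as sm

        data = simulate_path_data(TRUE_PCS, n=300, seed=11)
        z = (data - data.mean()) / data.std(ddof=0)
        result = fit_path_model(data)
        fit = sm.OLS(z["pmax"].to_numpy(), z[list(FACTORS)].to_numpy()).fit()
        for f, b in zip(FACTORS, fit.params):
            assert result.coefficient(f, "pmax") == pytest.approx(b, abs=1e-10)


class TestIndirectEffects:
    def test_chain_products_exact(self):
        result = fit_path_model(simulate_path_data(TRUE_PCS, n=300, seed=6))
        table = indirect_effects(result).set_index("factor")
        for f in FACTORS:
            photo = (
                result.coefficient(f, "pmax")
                * result.coefficient("pmax", "gep")
                * result.coefficient("gep", "nee")
            )
            resp = result.coefficient(f, "re") * result.coefficient("re", "nee")
            assert table.loc[f, "photosynthetic"] == pytest.approx(photo, abs=1e-12)
            assert table.loc[f, "respiration"] == pytest.approx(resp, abs=1e-12)
            assert table.loc[f, "total"] == pytest.approx(photo + resp, abs=1e-12)

    def test_zero_link_zeroes_the_chain(self):
        result = fit_path_model(simulate_path_data(TRUE_PCS, n=300, seed=6))
        result.direct[("pmax", "gep")] = 0.0
        table = indirect_effects(result).set_index("factor")
        assert (table["photosynthetic"] == 0.0).all()

    def test_unit_coefficients_give_unit_chains(self):
        result = fit_path_model(simulate_path_data(TRUE_PCS, n=300, seed=6))
        for edge in result.direct:
            result.direct[edge] = 1.0
        table = indirect_effects(result)
        assert (table["photosynthetic"] == 1.0).all()
        assert (table["respiration"] == 1.0).all()
        assert (table["total"] == 2.0).all()


class TestSimulator:
    def test_population_standardization_holds_in_sample(self):
        data = simulate_path_data(TRUE_PCS, n=200000, seed=8)
        sds = data.std(ddof=0)
        np.testing.assert_allclose(sds, 1.0, atol=0.02)

    def test_inadmissible_structural_variance_rejected(self):
        bad = dict(TRUE_PCS)
        for f in FACTORS:
            bad[(f, "pmax")] = 0.9
        with pytest.raises(ValueError, match=">= 1"):
            simulate_path_data(bad, n=10, seed=0)
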