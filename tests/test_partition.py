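"""Lloyd-Taylor fitting, model filling, partitioning and aggregation."""

import numpy as np
import pandas as pd
import pytest

from bambooflux.lightresponse import fit_year
from bambooflux.partition import (
    MG_CO2_TO_GC,
    aggregate,
    derive_re_gep,
    fill_nee,
    fit_lloyd_taylor,
)
from bambooflux.synthetic import (
    TrueParameterTrajectory,
    generate_dataset,
    generate_fluxes,
    generate_meteorology,
)

from conftest import make_series


class TestLloydTaylorFit:
    def test_noiseless_parameter_recovery(self, noiseless_quarter):
        records, _, truth = noiseless_quarter
        fit = fit_lloyd_taylor(records)
        assert fit.converged
        assert fit.r_ref == pytest.approx(truth.r_ref, rel=1e-6)
        assert fit.e0 == pytest.approx(truth.e0, rel=1e-6)

    def test_prediction_at_reference_temperature_is_r_ref(self, noiseless_quarter):
        fit = fit_lloyd_taylor(noiseless_quarter[0])
        assert fit.predict(10.0) == pytest.approx(fit.r_ref, rel=1e-12)

    def test_constant_soil_temperature_flagged_unidentifiable(self):
        records = make_series(np.zeros(20 * 48), ustar=0.5)
        records["ts"] = 12.0
        records["nee"] = 0.1
        records["qc"] = "observed"
        fit = fit_lloyd_taylor(records)
        assert not fit.converged
        assert "unidentifiable" in fit.message

    def test_undersampled_window_flagged(self, noiseless_quarter):
        records, _, _ = noiseless_quarter
        fit = fit_lloyd_taylor(records.iloc[:4])
        assert not fit.converged

    def test_prediction_strictly_increases_with_temperature(self, noiseless_quarter):
        fit = fit_lloyd_taylor(noiseless_quarter[0])
        ts = np.linspace(-5, 35, 200)
        assert (np.diff(fit.predict(ts)) > 0).all()

    def test_rref_bias_small_under_noise(self):
        """Median r_ref estimate over noisy replicates stays within 5%."""
        estimates = []
        for seed in range(30):
            met = generate_meteorology(60, seed=seed)
            truth = TrueParameterTrajectory.constant(
                60, r_ref=0.08, e0=309.0, noise_sd=0.05, seed=seed
            )
            records, _ = generate_fluxes(met, truth)
            fit = fit_lloyd_taylor(records)
            assert fit.converged
            estimates.append(fit.r_ref)
        bias = abs(np.median(estimates) - 0.08) / 0.08
        assert bias < 0.05


@pytest.fixture(scope="module")
def filled_noiseless():
    days = 60
    truth = TrueParameterTrajectory.constant(
        days,
        alpha=0.003,
        pmax=0.7,
        r_ref=0.08,
        e0=309.0,
        noise_sd=0.0,
        gap_spec=[("nee", 100, 4), ("nee", 500, 48), ("nee", 1500, 144)],
        seed=21,
    )
    records, truth_df, mask = generate_dataset(days, seed=21, truth=truth)
    lt = fit_lloyd_taylor(records)
    fits = [f for f in fit_year(records, 2011)[:12]]
    filled, report = fill_nee(records, lt, fits)
    return records, truth_df, filled, report


class TestFillNee:
    def test_gap_free_input_is_identity(self, noiseless_quarter):
        records, _, _ = noiseless_quarter
        lt = fit_lloyd_taylor(records)
        fits = fit_year(records, 2011)[:18]
        filled, report = fill_nee(records, lt, fits)
        pd.testing.assert_frame_equal(filled, records)
        assert report["night_filled"] == report["day_filled"] == 0

    def test_series_becomes_gap_free_with_model_flag(self, filled_noiseless):
        records, _, filled, report = filled_noiseless
        assert filled["nee"].notna().all()
        n_filled = report["night_filled"] + report["day_filled"]
        assert n_filled == records["nee"].isna().sum() == 196
        assert (filled.loc[records["nee"].isna(), "qc"] == "gapfilled_model").all()

    def test_filled_values_match_truth_on_noiseless_data(self, filled_noiseless):
        records, truth_df, filled, _ = filled_noiseless
        punched = records["nee"].isna()
        night = records["par"] < 5.0
        # nighttime fill comes straight from the recovered Lloyd-Taylor model
        np.testing.assert_allclose(
            filled.loc[punched & night, "nee"],
            truth_df.loc[punched & night, "nee_true"],
            rtol=1e-5,
            atol=1e-6,
        )
        # daytime fill carries the window-constant RE offset, so it can only
        # match the Ts-varying truth to within that offset's within-window
        # variation (~0.01 mg m-2 s-1 here)
        np.testing.assert_allclose(
            filled.loc[punched & ~night, "nee"],
            truth_df.loc[punched & ~night, "nee_true"],
            atol=0.03,
        )

    def test_nighttime_fill_at_reference_temperature(self):
        records = make_series(np.zeros(4), ustar=0.5, par=0.0)
        records["ts"] = 10.0
        records["nee"] = np.nan
        records["qc"] = "missing"
        from bambooflux.partition import LloydTaylorFit

        lt = LloydTaylorFit(r_ref=0.08, e0=309.0, n_obs=100, rmse=0.0, converged=True)
        filled, _ = fill_nee(records, lt, [])
        np.testing.assert_allclose(filled["nee"], 0.08, rtol=1e-12)


class TestDeriveReGep:
    def test_night_gep_is_exactly_zero(self, noiseless_quarter):
        records, _, _ = noiseless_quarter
        lt = fit_lloyd_taylor(records)
        flux = derive_re_gep(records, lt)
        night = flux["par"] < 5.0
        assert (flux.loc[night, "gep"] == 0.0).all()

    def test_day_partition_is_subtraction(self):
        # NEE = -0.4, RE = 0.1 => GEP = 0.5
        records = make_series(np.zeros(1), ustar=0.5, par=800.0)
        records["ts"] = 10.0
        records["nee"] = -0.4
        from bambooflux.partition import LloydTaylorFit

        lt = LloydTaylorFit(r_ref=0.1, e0=309.0, n_obs=50, rmse=0.0, converged=True)
        flux = derive_re_gep(records, lt)
        assert flux["gep"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_gep_series_matches_generator_truth(self, noiseless_quarter):
        records, truth_df, truth = noiseless_quarter
        lt = fit_lloyd_taylor(records)
        flux = derive_re_gep(records, lt)
        np.testing.assert_allclose(
            flux["gep"], truth_df["gep_true"], rtol=1e-5, atol=1e-6
        )

    def test_identity_holds_at_every_record(self, noiseless_quarter):
        records, _, _ = noiseless_quarter
        lt = fit_lloyd_taylor(records)
        flux = derive_re_gep(records, lt)
        np.testing.assert_allclose(
            flux["gep"], flux["re"] - flux["nee"], rtol=0, atol=1e-12
        )


class TestAggregate:
    def test_constant_flux_unit_conversion(self):
        records = make_series(np.zeros(96), ustar=0.5, par=0.0)
        records["nee"] = 0.1
        records["qc"] = "observed"
        daily = aggregate(records, "daily")
        # 0.1 mg m-2 s-1 * 86400 s * 12/44 / 1000 = 2.3564 gC m-2 d-1
        expected = 0.1 * 86400 * (12.0 / 44.0) / 1000.0
        assert expected == pytest.approx(2.3564, abs=5e-5)
        np.testing.assert_allclose(daily["nee"], expected, rtol=1e-12)

    def test_zero_series_sums_to_zero_everywhere(self):
        records = make_series(np.zeros(10 * 48), ustar=0.5)
        records["nee"] = 0.0
        records["qc"] = "observed"
        for level in ("daily", "5day", "annual"):
            out = aggregate(records, level)
            assert (out["nee"] == 0).all()

    def test_partial_days_excluded(self):
        records = make_series(np.zeros(100), ustar=0.5)  # 2 full days + 4 records
        records["nee"] = 0.1
        records["qc"] = "observed"
        assert len(aggregate(records, "daily")) == 2

    def test_identity_preserved_at_all_levels(self, noiseless_quarter):
        records, _, _ = noiseless_quarter
        lt = fit_lloyd_taylor(records)
        flux = derive_re_gep(records, lt)
        for level in ("daily", "5day", "annual"):
            out = aggregate(flux, level)
            np.testing.assert_allclose(
                out["gep"], out["re"] - out["nee"], rtol=0, atol=1e-9
            )

    def test_annual_nee_of_pure_sink_year_is_negative(self, noisy_year):
        records, _, _ = noisy_year
        lt = fit_lloyd_taylor(records)
        fits = fit_year(records, 2011)
        filled, _ = fill_nee(records, lt, fits)
        flux = derive_re_gep(filled, lt)
        annual = aggregate(flux, "annual")
        assert (annual["nee"] < 0).all()
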