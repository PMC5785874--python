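"""Residual tables, VPC behaviour and bootstrap mechanics."""

import numpy as np
import pytest

from fenofed import (MBPKModel, ModelParameters, TrialDesign, bootstrap,
                     generate_trial, residual_table, vpc)
from fenofed.datagen import fixture_dataset
from fenofed.foce import EstimationError


class TestResidualTable:
    def test_zero_noise_self_fit_gives_zero_cwres(self, noiseless_params):
        trial = generate_trial(TrialDesign(n_subjects=3), noiseless_params,
                               seed=1)
        # data are noise-free typical profiles; judge them under a model
        # with a finite residual SD and no IIV: residuals must vanish
        judge = noiseless_params.replace(sigma_prop=0.1)
        model = MBPKModel(trial.dataset, judge)
        tab = residual_table(model)
        assert np.all(np.abs(tab["CWRES"]) < 1e-6)
        assert np.allclose(tab["IPRED"], tab["DV"], rtol=1e-9)

    def test_cwres_distribution_under_correct_model(self, params):
        # correctly specified model: CWRES approximately standard normal
        trial = generate_trial(TrialDesign(n_subjects=24), params, seed=6)
        model = MBPKModel(trial.dataset, params)
        cwres = residual_table(model)["CWRES"].to_numpy()
        assert len(cwres) >= 500
        assert abs(cwres.mean()) < 0.1
        assert 0.8 < cwres.var(ddof=1) < 1.2

    def test_invariant_to_subject_order(self, params):
        import pandas as pd
        data = fixture_dataset("small")
        tab1 = residual_table(MBPKModel(data, params))
        reordered = pd.concat(
            [data.frame[data.frame["ID"] == s] for s in (3, 1, 2, 6, 5, 4)],
            ignore_index=True)
        from fenofed import PKDataset
        tab2 = residual_table(MBPKModel(PKDataset(reordered), params))
        key = ["ID", "OCC", "TIME"]
        merged = tab1.merge(tab2, on=key, suffixes=("_a", "_b"))
        assert np.allclose(merged["CWRES_a"], merged["CWRES_b"], atol=1e-9)
        assert np.allclose(merged["PRED_a"], merged["PRED_b"], atol=1e-12)


@pytest.fixture(scope="module")
def small_data():
    return fixture_dataset("small")


class TestVPC:
    def test_percentile_bands_are_ordered(self, small_data, params):
        res = vpc(small_data, params, n_replicates=50, seed=1)
        for tab in res.strata.values():
            assert (tab["obs_p5"] <= tab["obs_p50"]).all()
            assert (tab["obs_p50"] <= tab["obs_p95"]).all()
            for q in (5, 50, 95):
                assert (tab[f"lo_p{q}"] <= tab[f"hi_p{q}"]).all()

    def test_stratified_by_food_type(self, small_data, params):
        res = vpc(small_data, params, n_replicates=20, seed=1)
        assert set(res.strata) == {"FASTED", "STANDARD", "HIGH_FAT"}
        for tab in res.strata.values():
            assert (tab["n_obs"] == 6).all()     # 6 subjects per time bin

    def test_degenerate_variability_gives_zero_width_bands(self, small_data,
                                                           params):
        frozen = params.zero_random_effects()
        res = vpc(small_data, frozen, n_replicates=2, seed=3)
        for tab in res.strata.values():
            for q in (5, 50, 95):
                assert np.allclose(tab[f"lo_p{q}"], tab[f"hi_p{q}"],
                                   rtol=1e-9)

    def test_bands_widen_with_residual_error(self, small_data, params):
        # with IIV/IOV frozen the band width is driven by sigma alone
        base = params.zero_random_effects()
        narrow = vpc(small_data, base.replace(sigma_prop=0.2),
                     n_replicates=60, seed=5)
        wide = vpc(small_data, base.replace(sigma_prop=0.7),
                   n_replicates=60, seed=5)
        def width(r):
            return np.mean([np.mean(t["hi_p50"] - t["lo_p50"])
                            for t in r.strata.values()])
        assert width(wide) > width(narrow)

    def test_custom_bins_must_be_populated(self, small_data, params):
        with pytest.raises(ValueError, match="empty VPC bins"):
            vpc(small_data, params, n_replicates=5, seed=1,
                bins=[0.0, 12.0, 13.0, 14.0, 80.0])

    def test_replicate_floor(self, small_data, params):
        with pytest.raises(ValueError):
            vpc(small_data, params, n_replicates=1)

    def test_to_frame_and_determinism(self, small_data, params):
        a = vpc(small_data, params, n_replicates=10, seed=2)
        b = vpc(small_data, params, n_replicates=10, seed=2)
        assert a.to_frame().equals(b.to_frame())


class TestBootstrap:
    def test_full_fraction_deterministic_fit_zero_width(self, params):
        data = fixture_dataset("small")
        res = bootstrap(data, params, free=("tv_kg",), n_replicates=3,
                        fraction=1.0, seed=4,
                        fit_kwargs={"maxiter": 30})
        tab = res.summary_frame()
        assert res.n_success == 3
        assert np.allclose(tab["ci_lo"], tab["ci_hi"], rtol=1e-12)
        values = res.replicates["value"].to_numpy()
        assert np.allclose(values, values[0], rtol=1e-12)

    def test_different_seeds_draw_different_subsets(self, params):
        data = fixture_dataset("small")
        a = bootstrap(data, params, free=("tv_kg",), n_replicates=2,
                      fraction=0.5, seed=1, fit_kwargs={"maxiter": 10})
        b = bootstrap(data, params, free=("tv_kg",), n_replicates=2,
                      fraction=0.5, seed=2, fit_kwargs={"maxiter": 10})
        assert not np.allclose(a.replicates["value"], b.replicates["value"])

    def test_median_brackets_full_data_estimate(self, params):
        # calibration: the subsample bootstrap is centred on the full-data
        # estimate (which itself absorbs the realization's mean eta_kg),
        # so its median must sit within two interval-half-widths of it
        trial = generate_trial(TrialDesign(n_subjects=12), params, seed=31)
        full = MBPKModel(trial.dataset, params).fit(free=("tv_kg",),
                                                    maxiter=40)
        res = bootstrap(trial.dataset, params, free=("tv_kg",),
                        n_replicates=50, fraction=0.9, seed=8,
                        fit_kwargs={"maxiter": 40})
        tab = res.summary_frame().set_index("parameter")
        med = tab.loc["tv_kg", "median"]
        half = 0.5 * (tab.loc["tv_kg", "ci_hi"] - tab.loc["tv_kg", "ci_lo"])
        assert half > 0
        assert abs(med - full.estimates["tv_kg"]) <= 2 * half

    def test_validation_errors(self, params):
        data = fixture_dataset("small")
        with pytest.raises(ValueError):
            bootstrap(data, params, free=("tv_kg",), fraction=0.0)
        with pytest.raises(ValueError):
            bootstrap(data.subset([1, 2]), params, free=("tv_kg",))
        with pytest.raises(ValueError):
            bootstrap(data, params, free=("tv_kg",), method="jackknife")

    def test_majority_failures_raise(self, params):
        data = fixture_dataset("small")
        with pytest.raises(EstimationError, match="replicates"):
            bootstrap(data, params, free=("tv_kg",), n_replicates=2,
                      fraction=0.9, seed=1, fit_kwargs={"maxiter": 0})
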