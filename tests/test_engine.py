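"""Fitting engine: NLLS oracle behaviour, MCMC estimator, volume fitting."""

import numpy as np
import pytest

import fibromap as fm
from fibromap.engine import (monoexp_model, ivim_model, t2star_model,
                             spgr_model, nlls_fit, mcmc_fit, fit_volume)

B = np.array(fm.B_VALUES)


class TestNlls:
    def test_monoexp_noiseless_recovery(self):
        model = monoexp_model(s0_max=1e4)
        truth = np.array([1000.0, 1e-3])
        sig = model.forward(truth, np.array([200.0, 400.0, 800.0]))
        res = nlls_fit(model, [200, 400, 800], sig, [800.0, 2e-3])
        assert np.all(np.abs(res.point_estimate - truth) / truth < 1e-6)
        assert res.rss < 1e-12

    def test_ivim_noiseless_recovery_at_protocol_bvalues(self):
        model = ivim_model(s0_max=1e4)
        truth = np.array([1000.0, 0.15, 1e-3, 20e-3])
        sig = model.forward(truth, B)
        res = nlls_fit(model, B, sig, [900.0, 0.1, 0.8e-3, 10e-3])
        assert np.all(np.abs(res.point_estimate - truth) / truth < 1e-6)

    def test_constant_signal_drives_decay_to_lower_bound(self):
        model = monoexp_model(s0_max=1e4)
        sig = np.full(5, 500.0)
        res = nlls_fit(model, [0, 100, 200, 400, 800], sig, [500.0, 1e-3])
        assert res["ADC"] < 5 * model.bounds[1, 0]
        assert res.rss > 0  # a decaying model cannot match a constant exactly

    @pytest.mark.parametrize("bad", [
        dict(design=[1, 2], signal=[1, 2, 3], init=[1.0, 1e-3]),
        dict(design=[1], signal=[1], init=[1.0, 1e-3]),
        dict(design=[1, 2, 3], signal=[1, np.nan, 3], init=[1.0, 1e-3]),
        dict(design=[1, 2, 3], signal=[1, 2, 3], init=[1.0, 1.0]),  # out of bounds
    ])
    def test_validation_errors(self, bad):
        with pytest.raises(ValueError):
            nlls_fit(monoexp_model(), **bad)

    def test_estimates_respect_bounds(self):
        model = ivim_model(s0_max=2e3)
        rng = np.random.default_rng(0)
        for _ in range(10):
            sig = np.abs(rng.normal(500, 200, size=B.size)) + 1
            sig = np.sort(sig)[::-1]
            res = nlls_fit(model, B, sig, [sig[0], 0.1, 1e-3, 10e-3])
            assert np.all(res.point_estimate >= model.bounds[:, 0] - 1e-12)
            assert np.all(res.point_estimate <= model.bounds[:, 1] + 1e-12)


class TestMcmc:
    def test_seeded_determinism(self):
        model = monoexp_model(s0_max=1e4)
        sig = model.forward(np.array([1000.0, 1e-3]), B)
        a = mcmc_fit(model, B, sig, [900, 2e-3], chain_length=2000, seed=4)
        b = mcmc_fit(model, B, sig, [900, 2e-3], chain_length=2000, seed=4)
        assert np.array_equal(a.point_estimate, b.point_estimate)
        assert np.array_equal(a.posterior_spread, b.posterior_spread)

    def test_noiseless_agrees_with_nlls(self):
        """At infinite SNR the posterior median tracks the NLLS optimum."""
        for model, truth, init in [
            (monoexp_model(1e4), [1000.0, 1e-3], [800, 2e-3]),
            (ivim_model(1e4), [1000.0, 0.15, 1e-3, 20e-3], [950, 0.1, 0.9e-3, 12e-3]),
        ]:
            design = B
            sig = model.forward(np.array(truth), design)
            ref = nlls_fit(model, design, sig, init).point_estimate
            est = mcmc_fit(model, design, sig, init, seed=1).point_estimate
            assert np.all(np.abs(est - ref) / np.abs(ref) < 0.01), model.name

    def test_pure_noise_inflates_posterior_spread(self):
        model = monoexp_model(s0_max=1e4)
        clean = model.forward(np.array([1000.0, 1e-3]), B)
        r_clean = mcmc_fit(model, B, clean, [1000, 1e-3], seed=0)
        rng = np.random.default_rng(3)
        noise = np.abs(rng.normal(0, 50, size=B.size)) + 1.0
        r_noise = mcmc_fit(model, B, noise, [500, 1e-3], seed=0)
        assert np.all(r_noise.posterior_spread >
                      10 * r_clean.posterior_spread)

    def test_rejects_short_chain_and_zero_signal(self):
        model = monoexp_model()
        sig = model.forward(np.array([100.0, 1e-3]), B)
        with pytest.raises(ValueError):
            mcmc_fit(model, B, sig, [100, 1e-3], chain_length=500)
        with pytest.raises(ValueError):
            mcmc_fit(model, B, np.zeros_like(B), [100, 1e-3])

    def test_rss_decreases_with_noise_in_expectation(self):
        model = monoexp_model(s0_max=1e4)
        truth = np.array([1000.0, 1e-3])
        clean = model.forward(truth, B)
        rng = np.random.default_rng(9)
        rss = {s: [] for s in (5.0, 50.0)}
        for sigma in rss:
            for _ in range(20):
                sig = np.abs(clean + rng.normal(0, sigma, size=B.size))
                rss[sigma].append(nlls_fit(model, B, sig,
                                           [900, 2e-3]).rss)
        assert np.mean(rss[5.0]) < np.mean(rss[50.0])


class TestFitVolume:
    def test_single_voxel_mask_equals_single_fit(self, phantom, bvalues):
        stack = fm.simulate_dwi(phantom)
        mask = np.zeros(phantom.roi.shape, dtype=bool)
        mask[5, 5, 2] = True
        model = ivim_model(s0_max=1e5)
        maps = fit_volume(model, stack, mask)
        sig = stack.data[5, 5, 2]
        lone = nlls_fit(model, bvalues, sig,
                        [sig[0], 0.5, 0.5 * (1e-5 + 4e-3), 0.5 * (1e-3 + 0.5)])
        for j, name in enumerate(model.parameter_names):
            assert np.isclose(maps[name][5, 5, 2], lone.point_estimate[j])

    def test_two_region_noiseless_maps_are_piecewise_constant(self):
        gt = fm.make_phantom(fm.PhantomSpec(grid_shape=(8, 8, 2),
                                            n_regions=2, seed=12))
        stack = fm.simulate_dwi(gt)
        maps = fm.ivim_maps(stack, np.ones(gt.roi.shape, dtype=bool))
        for name in ("f", "D", "Dstar"):
            for region in np.unique(gt.region_labels):
                sel = gt.region_labels == region
                assert np.ptp(maps[name][sel]) < 1e-6 * np.abs(
                    np.median(maps[name][sel])), (name, region)

    def test_empty_mask_rejected(self, phantom):
        stack = fm.simulate_dwi(phantom)
        with pytest.raises(ValueError):
            fit_volume(ivim_model(), stack, np.zeros(phantom.roi.shape, bool))

    def test_spgr_and_t2star_models_roundtrip(self):
        tr = 0.015
        model = spgr_model(tr)
        flips = np.deg2rad([4.0, 24.0])
        sig = model.forward(np.array([1000.0, 1.2]), flips)
        res = nlls_fit(model, flips, sig, [900.0, 1.0])
        assert np.allclose(res.point_estimate, [1000.0, 1.2], rtol=1e-6)

        t2m = t2star_model(1e4)
        te = np.array([7.16, 11.64, 16.12, 20.60])
        sig = t2m.forward(np.array([800.0, 20.0]), te)
        res = nlls_fit(t2m, te, sig, [700.0, 15.0])
        assert np.allclose(res.point_estimate, [800.0, 20.0], rtol=1e-6)
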