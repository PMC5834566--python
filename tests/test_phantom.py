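"""Synthetic phantom generator: determinism, forward models, noise."""

import numpy as np
import pytest

import fibromap as fm
from fibromap.phantom import PhantomSpec, make_phantom, delta_from_mtr


class TestMakePhantom:
    def test_seeded_determinism(self):
        a = make_phantom(PhantomSpec(seed=7))
        b = make_phantom(PhantomSpec(seed=7))
        assert np.array_equal(a.roi, b.roi)
        assert np.array_equal(a.region_labels, b.region_labels)
        for k in a.maps:
            assert np.array_equal(a.maps[k], b.maps[k])

    def test_single_region_is_spatially_constant(self):
        gt = make_phantom(PhantomSpec(n_regions=1, seed=3))
        for k, arr in gt.maps.items():
            assert np.ptp(arr) == 0, k

    def test_degenerate_range_forces_constant(self):
        gt = make_phantom(PhantomSpec(
            n_regions=4, seed=1, parameter_ranges={"D": (1e-3, 1e-3)}))
        assert np.all(gt.maps["D"] == 1e-3)

    @pytest.mark.parametrize("kwargs", [
        {"grid_shape": (0, 4, 4)},
        {"n_regions": 0},
        {"noise_sigma": -1.0},
        {"parameter_ranges": {"D": (2e-3, 1e-3)}},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)

    def test_internal_identities(self, phantom):
        m = phantom.maps
        assert np.allclose(m["ka"], m["MTR"] / m["T1s"])
        assert np.allclose(m["fDstar"], m["f"] * m["Dstar"])
        assert np.allclose(m["S0l"], m["S0s"] * (1 - m["ratio"]))
        assert np.all(m["Dstar"] > m["D"])
        assert np.all((m["f"] >= 0) & (m["f"] <= 1))
        for k in ("D", "Dstar", "T2s_short", "T2s_long", "T1", "T1s"):
            assert np.all(m[k] > 0), k


class TestSimulateDwi:
    def test_b0_returns_s0(self, phantom):
        stack = fm.simulate_dwi(phantom, [0.0, 100.0, 800.0])
        assert np.allclose(stack.data[..., 0], phantom.maps["S0"])

    def test_direct_substitution(self):
        gt = make_phantom(PhantomSpec(
            grid_shape=(1, 1, 1), n_regions=1, seed=0,
            parameter_ranges={"S0": (1000, 1000), "f": (0.1, 0.1),
                              "D": (1e-3, 1e-3), "Dstar": (10e-3, 10e-3)}))
        stack = fm.simulate_dwi(gt, [0.0, 800.0])
        expect = 1000 * (0.1 * np.exp(-8.0) + 0.9 * np.exp(-0.8))
        assert np.allclose(stack.data[0, 0, 0, 1], expect)

    def test_f_zero_is_monoexponential(self, bvalues):
        gt = make_phantom(PhantomSpec(
            grid_shape=(2, 2, 1), n_regions=1, seed=0,
            parameter_ranges={"f": (0.0, 0.0)}))
        stack = fm.simulate_dwi(gt, bvalues)
        mono = gt.maps["S0"][..., None] * np.exp(-bvalues * gt.maps["D"][..., None])
        assert np.allclose(stack.data, mono)

    def test_rejects_bad_bvalues(self, phantom):
        with pytest.raises(ValueError):
            fm.simulate_dwi(phantom, [0.0, 100.0, 100.0])
        with pytest.raises(ValueError):
            fm.simulate_dwi(phantom, [-10.0, 0.0])


class TestSimulateUte:
    def test_te_to_zero_limit_is_total_amplitude(self, phantom):
        stack = fm.simulate_ute(phantom, [1e-9, 7.16])
        assert np.allclose(stack.data[..., 0], phantom.maps["S0s"])

    def test_short_pool_dead_at_conventional_echoes(self):
        gt = make_phantom(PhantomSpec(
            grid_shape=(1, 1, 1), n_regions=1, seed=0,
            parameter_ranges={"T2s_short": (0.5, 0.5)}))
        stack = fm.simulate_ute(gt, [20.6])
        short_amp = float((gt.maps["S0s"] - gt.maps["S0l"]).ravel()[0])
        long_part = float((gt.maps["S0l"]
                           * np.exp(-20.6 / gt.maps["T2s_long"])).ravel()[0])
        assert stack.data[0, 0, 0, 0] - long_part < 1e-10 * short_amp

    def test_equal_relaxation_times_degenerates_to_monoexp(self, echo_times):
        gt = make_phantom(PhantomSpec(
            grid_shape=(1, 1, 1), n_regions=1, seed=2,
            parameter_ranges={"T2s_short": (15.0, 15.0), "T2s_long": (15.0, 15.0)}))
        stack = fm.simulate_ute(gt, echo_times)
        mono = gt.maps["S0s"][..., None] * np.exp(-echo_times / 15.0)
        assert np.allclose(stack.data, mono)


class TestSimulateMt:
    def test_zero_mtr_means_no_mt_effect(self):
        gt = make_phantom(PhantomSpec(
            grid_shape=(2, 2, 1), n_regions=1, seed=0,
            parameter_ranges={"MTR": (0.0, 0.0), "T1s": (1.2, 1.2),
                              "T1": (1.2, 1.2)}))
        stack = fm.simulate_mt(gt)
        assert np.allclose(stack.data[..., 0], stack.data[..., 2])
        assert np.allclose(stack.data[..., 1], stack.data[..., 3])

    def test_small_flip_fraction_lost_equals_mtr(self, phantom):
        stack = fm.simulate_mt(phantom)
        s_ref, s_mt = stack.data[..., 0], stack.data[..., 2]
        assert np.allclose((s_ref - s_mt) / s_ref, phantom.maps["MTR"])

    def test_rejects_bad_inputs(self, phantom):
        with pytest.raises(ValueError):
            fm.simulate_mt(phantom, flip_angles_deg=(4.0, 95.0))
        with pytest.raises(ValueError):
            fm.simulate_mt(phantom, tr=-1.0)

    def test_delta_mtr_consistency(self):
        mtr = np.array([0.1, 0.3])
        d = delta_from_mtr(mtr, t1=1.0)
        a = np.deg2rad(4.0)
        back = d / (0.015 / 1.0 + a * a / 2 + d)
        assert np.allclose(back, mtr)


class TestAddNoise:
    def test_sigma_zero_identity(self, phantom):
        stack = fm.simulate_dwi(phantom, [0.0, 800.0])
        out = fm.add_noise(stack, 0.0, seed=1)
        assert np.array_equal(out.data, stack.data)

    def test_seeded_determinism(self, phantom):
        stack = fm.simulate_dwi(phantom, [0.0, 800.0])
        a = fm.add_noise(stack, 10.0, seed=5)
        b = fm.add_noise(stack, 10.0, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_rayleigh_mean_at_zero_signal(self):
        stack = fm.SignalStack(np.zeros((50, 50, 40, 1)),
                               fm.AcquisitionSpec("dwi", bvalues=(0.0,)))
        sigma = 3.0
        noisy = fm.add_noise(stack, sigma, seed=11)
        expect = sigma * np.sqrt(np.pi / 2)
        assert abs(noisy.data.mean() - expect) < 0.01 * expect

    def test_rician_noise_floor(self, phantom):
        """Mean noisy magnitude exceeds the noiseless value at low SNR."""
        truth = 5.0
        stack = fm.SignalStack(np.full((40, 40, 20, 1), truth),
                               fm.AcquisitionSpec("dwi", bvalues=(0.0,)))
        noisy = fm.add_noise(stack, 10.0, seed=2)
        assert noisy.data.mean() > truth * 1.5

    def test_negative_sigma_rejected(self, phantom):
        stack = fm.simulate_dwi(phantom, [0.0, 800.0])
        with pytest.raises(ValueError):
            fm.add_noise(stack, -1.0, seed=0)
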