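"""Synthetic-experiment generator: forward-model consistency, determinism,
noise statistics, and the designed background-cancellation structure."""

import dataclasses

import numpy as np
import pytest

import lovkin as lk
from lovkin.exceptions import InputError
from lovkin.simulate import (
    _mean_pool_fractions,
    _pool_taus,
    _tau_delta_for_set,
    _abs475,
    _phi,
    phos_set_edges,
    triplet_curve_times,
)

from conftest import collect_net_traces


class TestTripletGenerator:
    def test_noiseless_curves_equal_forward_model(self, c450a_noiseless_curves):
        cfg, curves = c450a_noiseless_curves
        assert len(curves) == 18
        for curve in curves:
            fr = lk.pool_fractions(cfg, curve.irradiation_time)
            amps = [float(fr[p][0]) for p in cfg.pools]
            model = lk.triplet_absorbance(curve.t, amps, _pool_taus(cfg, curve.irradiation_time))
            assert np.array_equal(curve.absorbance, model)

    def test_amplitudes_track_scheme1_populations(self, c450a_noiseless_curves):
        cfg, curves = c450a_noiseless_curves
        times = triplet_curve_times(cfg)
        traj = lk.scheme1_populations(times, cfg.rates)
        # initial values of the curves decompose into the pool fractions
        for curve, fp, fps, fw in zip(curves, traj.f_prot, traj.f_protstar, traj.f_water):
            assert curve.absorbance[0] == pytest.approx(fp + fps + fw, rel=1e-12)

    def test_same_seed_bit_identical_different_seed_not(self):
        a = lk.generate_triplet_experiment(lk.default_config("C450A", seed=5))
        b = lk.generate_triplet_experiment(lk.default_config("C450A", seed=5))
        c = lk.generate_triplet_experiment(lk.default_config("C450A", seed=6))
        for x, y in zip(a, b):
            assert np.array_equal(x.absorbance, y.absorbance)
        assert not np.array_equal(a[0].absorbance, c[0].absorbance)

    def test_protstar_lifetime_schedule(self):
        cfg = lk.default_config("C450A", 0)
        taus = [_pool_taus(cfg, t)[1] for t in triplet_curve_times(cfg)]
        assert taus[0] == pytest.approx(32.0, abs=0.3)
        assert taus[-1] == pytest.approx(23.0, abs=0.3)
        assert np.all(np.diff(taus) < 0)


class TestPhosphorescenceGenerator:
    def test_noiseless_mid_window_is_profile_and_flanks_zero(self):
        cfg = lk.default_config("C450A", 0).silenced()
        traces = lk.generate_phosphorescence_experiment(cfg)
        assert len(traces) == 18  # 6 sets x 3 windows
        edges = phos_set_edges(cfg)
        for tr in traces:
            j = tr.meta["set_index"]
            fr = _mean_pool_fractions(cfg, edges[j], edges[j + 1])
            amps = [cfg.noise.phos_scale * _phi(cfg, p) * _abs475(cfg, p) * fr[p]
                    for p in cfg.pools]
            profile = lk.phosphorescence_profile(
                tr.t, amps, _pool_taus(cfg, tr.irradiation_time),
                _tau_delta_for_set(cfg, j))
            if tr.filter_window == "1250-1300":
                assert np.array_equal(tr.counts, profile)
            else:
                assert np.all(tr.counts == 0.0)

    def test_noiseless_subtraction_recovers_profile_exactly(self):
        cfg = lk.default_config("C450A", 0)
        cfg = dataclasses.replace(cfg, noise=dataclasses.replace(
            lk.NoiseConfig.silent(), background_amp=250.0))
        nets = collect_net_traces(lk.generate_phosphorescence_experiment(cfg))
        silent = lk.default_config("C450A", 0).silenced()
        ref = [tr for tr in lk.generate_phosphorescence_experiment(silent)
               if tr.filter_window == "1250-1300"]
        for net, mid in zip(nets, ref):
            assert np.allclose(net.value, mid.counts, atol=1e-9)

    def test_integrated_signal_grows_with_irradiation(self):
        nets = collect_net_traces(
            lk.generate_phosphorescence_experiment(lk.default_config("C450A", 1)))
        assert nets[-1].value.sum() > nets[0].value.sum()

    def test_poisson_calibration(self):
        """Pooled variance/mean of per-bin counts near 1 over a 20-seed ensemble."""
        stacks = []
        for seed in range(20):
            traces = lk.generate_phosphorescence_experiment(
                lk.default_config("C450A", seed))
            mid_last = [tr for tr in traces if tr.filter_window == "1250-1300"][-1]
            stacks.append(mid_last.counts)
        arr = np.stack(stacks)
        m, v = arr.mean(axis=0), arr.var(axis=0, ddof=1)
        mask = m >= 50
        assert mask.sum() > 100
        ratio = v[mask].sum() / m[mask].sum()
        assert 0.8 < ratio < 1.2

    def test_tau_delta_schedule_endpoints(self):
        cfg = lk.default_config("C450A", 0)
        assert _tau_delta_for_set(cfg, 0) == 2.7
        assert _tau_delta_for_set(cfg, 5) == 3.0


class TestEmissionGenerator:
    def test_release_zero_returns_bound_basis(self):
        cfg = lk.default_config("C450A", 0, release_fraction=0.0).silenced()
        spectra = lk.generate_emission_spectra(cfg)
        assert np.allclose(spectra["post_irradiation"].intensity,
                           spectra["bound_basis"].intensity)

    def test_wt_bound_emission_quenched_relative_to_c450a(self):
        wt = lk.generate_emission_spectra(lk.default_config("wt", 0).silenced())
        mut = lk.generate_emission_spectra(lk.default_config("C450A", 0).silenced())
        at500 = lambda s: s.intensity[np.argmin(np.abs(s.wavelength - 500.0))]
        assert at500(wt["pre_irradiation"]) < at500(mut["pre_irradiation"])

    def test_noiseless_roundtrip_through_decomposition(self):
        cfg = lk.default_config("wt", 0).silenced()
        spectra = lk.generate_emission_spectra(cfg)
        dec = lk.decompose_emission_spectrum(spectra["post_irradiation"],
                                             spectra["free_fmn"],
                                             spectra["bound_basis"])
        assert dec.fraction_free == pytest.approx(cfg.release_fraction, abs=1e-6)


class TestAdductGenerator:
    def test_competent_fraction_one_gives_identical_traces(self):
        cfg = lk.default_config("wt", 0, adduct_fraction=1.0).silenced()
        pre, post = lk.generate_adduct_traces(cfg)
        assert np.array_equal(pre.value, post.value)

    def test_amplitude_ratio_by_construction(self):
        cfg = lk.default_config("wt", 0).silenced()
        pre, post = lk.generate_adduct_traces(cfg)
        base = pre.value[0]
        assert (post.value[-1] - base) / (pre.value[-1] - base) == pytest.approx(0.4, abs=1e-6)

    def test_rejected_for_cysteine_free_variant(self):
        with pytest.raises(InputError, match="cysteine"):
            lk.generate_adduct_traces(lk.default_config("C450A", 0))


class TestBleachingControl:
    def test_noiseless_amplitudes_on_exponential(self):
        cfg = lk.default_config("free_FMN_control", 0).silenced()
        data = lk.generate_bleaching_control(cfg)
        amps = np.array([c.absorbance[0] for c in data["triplet_curves"]])
        times = np.array([c.irradiation_time for c in data["triplet_curves"]])
        assert np.allclose(amps, np.exp(-cfg.rates.k3 * times), rtol=1e-12)
        # constant aqueous lifetime: value at t=tau equals amp/e
        c0 = data["triplet_curves"][0]
        idx = np.argmin(np.abs(c0.t - 2.7))
        assert c0.absorbance[idx] == pytest.approx(c0.absorbance[0] / np.e, rel=1e-3)

    def test_endpoint_amplitude(self):
        cfg = lk.default_config("free_FMN_control", 0).silenced()
        data = lk.generate_bleaching_control(cfg)
        last = data["triplet_curves"][-1]
        # block midpoint of the final curve sits at 4375 s
        assert last.absorbance[0] == pytest.approx(np.exp(-4375.0 / 3260.0), rel=1e-9)

    def test_wrong_variant_rejected(self):
        with pytest.raises(InputError):
            lk.generate_bleaching_control(lk.default_config("C450A", 0))


class TestAmplitudeSeries:
    def test_noiseless_series_equal_populations(self, paper_rates):
        cfg = lk.default_config("C450A", 0)
        series = lk.generate_amplitude_series(cfg, rel_noise=0.0)
        times = triplet_curve_times(cfg)
        traj = lk.scheme1_populations(times, paper_rates)
        assert np.allclose(series["prot"].value, traj.f_prot)
        assert np.allclose(series["water"].value, traj.f_water)

    def test_relative_noise_scale(self):
        cfg = lk.default_config("C450A", 3)
        noisy = lk.generate_amplitude_series(cfg, rel_noise=0.05)
        clean = lk.generate_amplitude_series(cfg, rel_noise=0.0)
        rel = noisy["prot"].value / clean["prot"].value - 1.0
        assert 0.01 < np.std(rel) < 0.12


class TestConfigValidation:
    def test_bad_variant(self):
        with pytest.raises(InputError):
            lk.default_config("unknown")

    def test_yields_bounded(self):
        with pytest.raises(InputError):
            lk.default_config("C450A", phi_prot=1.5)

    def test_wt_requires_scheme2(self):
        with pytest.raises(InputError):
            lk.ExperimentConfig(variant="wt", rates=lk.REFERENCE_RATES,
                                lifetimes=lk.LifetimeSet(tau_T_prot=1.5))
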