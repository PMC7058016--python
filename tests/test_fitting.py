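"""Inference machinery: noiseless round trips, constraint honoring, staged
rate fits, unmixing, single-exponential fits."""

import dataclasses
import warnings

import numpy as np
import pytest

import lovkin as lk
from lovkin import KineticTrace
from lovkin.exceptions import FitError, InputError
from lovkin.fitting import (
    c450a_fit_spec,
    fit_phosphorescence_global,
    single_pool_fit_spec,
    wt_fit_spec,
)
from lovkin.simulate import _pool_taus, triplet_curve_times

from conftest import collect_net_traces


class TestGlobalTripletFit:
    def test_noiseless_recovery_and_constraints(self, c450a_noiseless_curves):
        cfg, curves = c450a_noiseless_curves
        res = lk.fit_triplet_decays_global(curves, c450a_fit_spec())
        # shared intact-protein lifetime to < 0.1%
        assert res.shared_lifetime("prot") == pytest.approx(57.0, rel=1e-3)
        # shared parameter: exactly one value across the series
        assert np.ptp(res.lifetimes["prot"]) == 0.0
        # fixed parameter echoed unchanged with zero uncertainty
        assert np.all(res.lifetimes["water"] == 2.7)
        assert np.all(res.lifetime_stderr["water"] == 0.0)
        # per-curve oxidized lifetime tracks the generating 32 -> 23 drift
        star = res.lifetimes["protstar"]
        assert star[2] == pytest.approx(_pool_taus(cfg, curves[2].irradiation_time)[1],
                                        rel=2e-3)
        assert star[-1] == pytest.approx(23.0, rel=0.05)
        # amplitudes reproduce the pool fractions
        traj = lk.scheme1_populations(triplet_curve_times(cfg), cfg.rates)
        assert np.allclose(res.amplitudes["prot"].to_numpy(), traj.f_prot, atol=1e-4)

    def test_noiseless_wt_recovery(self):
        cfg = lk.default_config("wt", 0).silenced()
        curves = lk.generate_triplet_experiment(cfg)
        res = lk.fit_triplet_decays_global(curves, wt_fit_spec())
        assert res.shared_lifetime("prot") == pytest.approx(1.50, rel=1e-3)

    def test_noisy_recovery_within_reported_band(self):
        """Median recovered shared lifetime lands in the 57 +/- 2 us band."""
        taus = []
        for seed in range(5):
            curves = lk.generate_triplet_experiment(lk.default_config("C450A", seed))
            res = lk.fit_triplet_decays_global(curves, c450a_fit_spec())
            taus.append(res.shared_lifetime("prot"))
        assert abs(np.median(taus) - 57.0) < 2.0

    def test_spread_consistent_with_reported_stderr(self):
        """Empirical spread within a factor 3 of the per-fit standard error."""
        taus, errs = [], []
        for seed in range(8):
            curves = lk.generate_triplet_experiment(lk.default_config("C450A", seed))
            res = lk.fit_triplet_decays_global(curves, c450a_fit_spec())
            taus.append(res.shared_lifetime("prot"))
            errs.append(res.shared_lifetime_stderr("prot"))
        spread = np.std(taus)
        stderr = np.nanmedian(errs)
        assert stderr / 3.0 < spread < stderr * 3.0

    def test_extra_pool_driven_to_zero_boundary(self):
        """Fitting wt (two-pool) data with the three-pool model pins the
        spurious pool's amplitude at 0, never negative."""
        cfg = lk.default_config("wt", 1)
        curves = lk.generate_triplet_experiment(cfg)
        spec = lk.TripletFitSpec((
            lk.LifetimeConstraint("prot", "shared", 2.0, (0.2, 20.0)),
            lk.LifetimeConstraint("protstar", "shared", 150.0, (100.0, 500.0)),
            lk.LifetimeConstraint("water", "fixed", 2.7),
        ))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lk.fit_triplet_decays_global(curves, spec)
        star = res.amplitudes["protstar"].to_numpy()
        assert np.all(star >= 0.0)
        assert np.median(star) < 2e-3
        assert any("protstar" in f for f in res.flags)

    def test_requires_two_curves(self, c450a_noiseless_curves):
        with pytest.raises(InputError):
            lk.fit_triplet_decays_global(c450a_noiseless_curves[1][:1], c450a_fit_spec())


class TestGlobalPhosphorescenceFit:
    def _net_and_taus(self, cfg):
        nets = collect_net_traces(lk.generate_phosphorescence_experiment(cfg))
        taus = [_pool_taus(cfg, nt.irradiation_time) for nt in nets]
        return nets, taus

    def test_noiseless_round_trip(self):
        cfg = lk.default_config("C450A", 0).silenced()
        nets, taus = self._net_and_taus(cfg)
        res = fit_phosphorescence_global(nets, taus, cfg.pools)
        for j, s in enumerate(res.sets):
            true_tau = 2.7 + 0.3 * j / 5
            assert s.tau_delta == pytest.approx(true_tau, rel=1e-3)
            mid = lk.generate_phosphorescence_experiment(cfg)[3 * j + 1]
            for pool, a_true in zip(cfg.pools, mid.meta["true_amplitudes"]):
                if a_true > 1.0:
                    assert s.amplitudes[pool] == pytest.approx(a_true, rel=1e-3)

    def test_tau_delta_trend_recovered_at_noise(self):
        cfg = lk.default_config("C450A", 2)
        nets, taus = self._net_and_taus(cfg)
        res = fit_phosphorescence_global(nets, taus, cfg.pools)
        td = res.tau_delta_series()
        assert td[-1] > td[0]
        assert td[0] == pytest.approx(2.7, abs=0.3)
        assert td[-1] == pytest.approx(3.0, abs=0.3)

    def test_wt_protein_contribution_negligible(self):
        """The wt signal is explained by solution-phase production: the
        protein-pool amplitude stays statistically indistinguishable from zero
        (variance-weighted fit) and a negligible share of the total."""
        for seed in range(4):
            cfg = lk.default_config("wt", seed)
            nets, taus = self._net_and_taus(cfg)
            res = fit_phosphorescence_global(nets, taus, cfg.pools, weighted=True)
            A = res.amplitude_series("prot").value
            E = np.array([s.amplitude_stderr["prot"] for s in res.sets])
            assert np.all(A <= 3.0 * np.maximum(E, 1e-9))
            assert A.sum() < 0.05 * res.amplitude_series("water").value.sum()

    def test_low_signal_set_flagged_not_fitted(self):
        cfg = lk.default_config("C450A", 0).silenced()
        nets, taus = self._net_and_taus(cfg)
        dead = dataclasses.replace(nets[0], value=np.zeros_like(nets[0].value))
        res = fit_phosphorescence_global([dead] + nets[1:], taus, cfg.pools)
        assert res.skipped == [0]
        assert "low_signal_not_fitted" in res.sets[0].flags


class TestRateConstantFits:
    def test_noiseless_staged_recovery_exact(self, paper_rates):
        cfg = lk.default_config("C450A", 0)
        series = lk.generate_amplitude_series(cfg, rel_noise=0.0)
        res = lk.fit_rate_constants(series, scheme=1, k3_external=paper_rates.k3)
        assert res.characteristic_times["1/k1"] == pytest.approx(9000.0, rel=1e-6)
        assert res.characteristic_times["1/k2"] == pytest.approx(1000.0, rel=1e-6)
        assert res.characteristic_times["1/k3"] == pytest.approx(3260.0, rel=1e-12)

    def test_noisy_staged_recovery(self, paper_rates):
        """Median relative error of each characteristic time < 10% at 5% noise."""
        err1, err2 = [], []
        for seed in range(20):
            series = lk.generate_amplitude_series(lk.default_config("C450A", seed),
                                                  rel_noise=0.05)
            res = lk.fit_rate_constants(series, scheme=1, k3_external=paper_rates.k3)
            err1.append(abs(res.characteristic_times["1/k1"] - 9000.0) / 9000.0)
            err2.append(abs(res.characteristic_times["1/k2"] - 1000.0) / 1000.0)
        assert np.median(err1) < 0.10
        assert np.median(err2) < 0.10

    def test_staged_vs_joint_consistency(self, paper_rates):
        series = lk.generate_amplitude_series(lk.default_config("C450A", 11),
                                              rel_noise=0.02)
        staged = lk.fit_rate_constants(series, scheme=1, k3_external=paper_rates.k3)
        joint = lk.fit_rate_constants(series, scheme=1, k3_external=paper_rates.k3,
                                      joint_refine=True)
        for key in ("1/k1", "1/k2"):
            gap = abs(staged.characteristic_times[key] - joint.characteristic_times[key])
            sig = staged.stderr[key]
            assert gap < max(3 * sig, 0.05 * staged.characteristic_times[key])

    def test_k3_from_bleach_control_series(self):
        cfg = lk.default_config("free_FMN_control", 0)
        times = triplet_curve_times(cfg)
        series = {"bleach_control": KineticTrace(times, np.exp(-times / 3260.0), "ctrl"),
                  "prot": KineticTrace(times, np.exp(-times / 9000.0), "prot"),
                  "protstar": KineticTrace(times, lk.scheme1_populations(times, cfg.rates).f_protstar, "star"),
                  "water": KineticTrace(times, lk.scheme1_populations(times, cfg.rates).f_water, "water")}
        res = lk.fit_rate_constants(series, scheme=1)
        assert res.characteristic_times["1/k3"] == pytest.approx(3260.0, rel=1e-6)

    def test_missing_series_is_input_error(self, paper_rates):
        with pytest.raises(InputError, match="prot"):
            lk.fit_rate_constants({}, scheme=1, k3_external=paper_rates.k3)
        with pytest.raises(InputError, match="k3"):
            lk.fit_rate_constants({"prot": KineticTrace(np.arange(5.0), np.ones(5), "p")},
                                  scheme=1)

    def test_scheme2_slope_recovery(self, paper_rates):
        cfg = lk.default_config("wt", 0)
        series = lk.generate_amplitude_series(cfg, rel_noise=0.0)
        res = lk.fit_rate_constants(series, scheme=2, k3_external=paper_rates.k3)
        assert res.stages["depletion_slope"]["slope"] == pytest.approx(0.5 / 4500, rel=1e-6)


class TestSpectralUnmixing:
    def test_pure_free_spectrum(self):
        sp = lk.generate_emission_spectra(lk.default_config("wt", 0).silenced())
        dec = lk.decompose_emission_spectrum(sp["free_fmn"], sp["free_fmn"],
                                             sp["bound_basis"])
        assert dec.fraction_free == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("variant,frac", [("wt", 0.45), ("C450A", 0.25)])
    def test_constructed_fraction_recovered(self, variant, frac):
        sp = lk.generate_emission_spectra(lk.default_config(variant, 0).silenced())
        obs = lk.emission_spectrum_mixture(frac, sp["free_fmn"], sp["bound_basis"], 1.7)
        dec = lk.decompose_emission_spectrum(obs, sp["free_fmn"], sp["bound_basis"])
        assert dec.fraction_free == pytest.approx(frac, abs=1e-9)
        assert dec.fraction_free + dec.fraction_bound == pytest.approx(1.0)

    def test_noisy_recovery_within_two_points(self):
        """1% multiplicative noise, 20 seeds: free fraction within +/- 0.02."""
        sp = lk.generate_emission_spectra(lk.default_config("wt", 0).silenced())
        for seed in range(20):
            rng = np.random.default_rng(seed)
            obs = lk.emission_spectrum_mixture(0.45, sp["free_fmn"], sp["bound_basis"])
            noisy = lk.EmissionSpectrum(obs.wavelength,
                                        obs.intensity * (1 + rng.normal(0, 0.01, obs.intensity.shape)))
            dec = lk.decompose_emission_spectrum(noisy, sp["free_fmn"], sp["bound_basis"])
            assert abs(dec.fraction_free - 0.45) < 0.02

    def test_collinear_bases_flagged(self):
        wl = np.linspace(460, 640, 181)
        a = np.exp(-((wl - 510) / 30) ** 2)
        near = lk.EmissionSpectrum(wl, a * 1.001 + 1e-4)
        dec = lk.decompose_emission_spectrum(lk.EmissionSpectrum(wl, a),
                                             lk.EmissionSpectrum(wl, a), near)
        assert dec.ill_conditioned


class TestSingleExponential:
    def test_noiseless_decay_exact(self):
        t = np.linspace(0, 250, 60)
        fit = lk.fit_single_exponential(KineticTrace(t, np.exp(-t / 50.0), "d"),
                                        model="decay", fix_baseline=0.0)
        assert fit.tau == pytest.approx(50.0, rel=1e-8)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-8)

    def test_recovery_round_trip(self):
        cfg = lk.default_config("wt", 0).silenced()
        pre, _ = lk.generate_adduct_traces(cfg)
        fit = lk.fit_single_exponential(pre, model="recovery")
        assert fit.tau == pytest.approx(cfg.tau_rec_s, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.10, rel=1e-6)
        assert fit.baseline == pytest.approx(0.25, rel=1e-6)

    def test_adduct_amplitude_ratio_distribution(self):
        """Post/pre amplitude ratio 0.40 +/- 0.03 across 20 seeds."""
        ratios = []
        for seed in range(20):
            pre, post = lk.generate_adduct_traces(lk.default_config("wt", seed))
            fp = lk.fit_single_exponential(pre, model="recovery")
            fq = lk.fit_single_exponential(post, model="recovery")
            ratios.append(fq.amplitude / fp.amplitude)
        ratios = np.array(ratios)
        assert np.all(np.abs(ratios - 0.40) < 0.03)

    def test_shared_tau_recovered_within_5pct(self):
        taus = []
        for seed in range(20):
            pre, post = lk.generate_adduct_traces(lk.default_config("wt", seed))
            taus.append(lk.fit_single_exponential(pre, model="recovery").tau)
            taus.append(lk.fit_single_exponential(post, model="recovery").tau)
        assert np.all(np.abs(np.array(taus) / 70.0 - 1.0) < 0.05)

    def test_flat_trace_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 10, 40)
        fit = lk.fit_single_exponential(
            KineticTrace(t, 1.0 + rng.normal(0, 0.05, t.size), "flat"), model="decay")
        assert fit.degenerate

    def test_too_few_points(self):
        with pytest.raises(InputError):
            lk.fit_single_exponential(KineticTrace(np.arange(3.0), np.ones(3), "x"))
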