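"""Synthetic laser-laboratory experiments with the statistical structure the
analysis assumes.

The generator emulates one 75-minute blue-light irradiation run on a 25 uM
LOV-domain sample (10 Hz pulsed excitation at 475 nm):

* 18 flash-photolysis transient-absorption curves (633 nm probe), one per
  consecutive block of 2500 averaged pulses, with Gaussian oscilloscope noise;
* 6 singlet-oxygen phosphorescence measurement sets, each consisting of three
  consecutive band-pass windows (signal window 1250-1300 nm flanked by two
  background windows), Poisson photon counting over 2500 pulses per window,
  on top of a smooth optical background whose wavelength dependence across the
  windows is linear (optionally quadratic, to stress the subtraction scheme);
* steady-state FMN emission spectra before/after irradiation plus a free-FMN
  reference spectrum;
* pre/post-irradiation dark-state adduct-recovery traces (wild type only);
* a free-FMN + apoprotein bleaching control run.

Pool populations evolve according to the Scheme 1 chain (C450A) or the
Scheme 2 release model (wild type); with every noise source disabled the
generated records reproduce the forward models of ``lovkin.signals`` exactly.
All randomness flows through ``ExperimentConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from .exceptions import InputError
from .kinetics import (
    PopulationTrajectory,
    RateConstants,
    Scheme2Config,
    bleaching_fraction,
    scheme1_populations,
    scheme2_populations,
)
from .signals import (
    FILTER_WINDOWS,
    EmissionSpectrum,
    KineticTrace,
    LifetimeSet,
    PhosphorescenceTrace,
    TripletDecayCurve,
    adduct_recovery_model,
    emission_spectrum_mixture,
    phosphorescence_profile,
    triplet_absorbance,
)

__all__ = [
    "NoiseConfig",
    "ExperimentConfig",
    "default_config",
    "generate_triplet_experiment",
    "generate_phosphorescence_experiment",
    "generate_emission_spectra",
    "generate_adduct_traces",
    "generate_bleaching_control",
    "generate_amplitude_series",
    "pool_fractions",
]

# Substream tags so each generator draws from an independent, reproducible stream.
_STREAMS = {"triplet": 1, "phos": 2, "emission": 3, "adduct": 4, "bleach": 5, "series": 6}


def _rng(cfg: "ExperimentConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


@dataclass(frozen=True)
class NoiseConfig:
    """Noise amplitudes of the synthetic instruments.

    ``abs_sigma`` is the per-point Gaussian noise of the averaged transient
    absorbance, in OD (the signal amplitude scale is 1 OD of total initial
    triplet absorption).  ``phos_scale`` converts phosphorescence amplitudes
    (quantum yield x absorbance x pool fraction) into expected counts per
    50 ns bin.  The optical background is an exponentially decaying count rate
    shared by the three windows, with a linear tilt across the windows; in
    quadratic mode the signal window additionally sits above the flanking
    average by ``background_curvature`` (relative), which the linear
    subtraction cannot remove.
    """

    abs_sigma: float = 0.012
    poisson: bool = True
    phos_scale: float = 30000.0
    background_amp: float = 300.0       # counts per bin at t = 0
    background_tau_us: float = 8.0
    background_tilt: float = 0.10       # +/- relative offset of flanking windows
    background_shape: Literal["linear", "quadratic"] = "linear"
    background_curvature: float = 0.01  # used only in quadratic mode
    spectrum_sigma_rel: float = 0.01    # of the observed peak intensity
    adduct_sigma: float = 0.001         # OD

    @classmethod
    def silent(cls) -> "NoiseConfig":
        """All noise sources off, background removed; generator output is the
        noiseless forward model."""
        return cls(abs_sigma=0.0, poisson=False, background_amp=0.0,
                   spectrum_sigma_rel=0.0, adduct_sigma=0.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one synthetic irradiation experiment."""

    variant: Literal["wt", "C450A", "free_FMN_control"]
    rates: RateConstants
    lifetimes: LifetimeSet
    scheme2_cfg: Optional[Scheme2Config] = None
    tau_protstar_schedule: Optional[tuple] = None   # (start, end) us over the run
    tau_delta_schedule: tuple = (2.7, 3.0)          # (first set, last set) us
    n_absorption_curves: int = 18
    n_phos_sets: int = 6
    total_irradiation_s: float = 4500.0
    phi_prot: float = 0.07          # 1O2 yield of FMN inside the intact protein
    phi_protstar: float = 0.20      # inside the oxidized protein (C450A only)
    phi_water_ref: float = 0.57     # aqueous-FMN reference yield
    abs_ratio_475: float = 1.0      # bound/free absorbance ratio at 475 nm
    release_fraction: float = 0.25  # free fraction of the post-irradiation emission
    adduct_fraction: float = 0.40   # adduct-competent fraction after irradiation (wt)
    tau_rec_s: float = 70.0         # dark-state recovery time constant
    bound_emission_amp: float = 0.9
    free_emission_amp: float = 1.0
    abs_time_range_us: tuple = (0.0, 400.0, 0.1)    # start, stop, step
    phos_time_range_us: tuple = (0.0, 80.0, 0.05)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("wt", "C450A", "free_FMN_control"):
            raise InputError(f"unknown variant {self.variant!r}")
        for name in ("phi_prot", "phi_protstar", "phi_water_ref"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name}={v!r} must lie in [0, 1]")
        if not (0.0 <= self.release_fraction <= 1.0):
            raise InputError("release_fraction must lie in [0, 1]")
        if not (0.0 <= self.adduct_fraction <= 1.0):
            raise InputError("adduct_fraction must lie in [0, 1]")
        if self.n_absorption_curves < 1 or self.n_phos_sets < 1:
            raise InputError("curve/set counts must be positive")
        if self.total_irradiation_s <= 0:
            raise InputError("total_irradiation_s must be positive")
        if self.abs_ratio_475 <= 0:
            raise InputError("abs_ratio_475 must be positive")
        if self.variant == "wt" and self.scheme2_cfg is None:
            raise InputError("wt experiments require a Scheme2Config")

    def silenced(self) -> "ExperimentConfig":
        """Copy with all noise sources disabled."""
        return replace(self, noise=NoiseConfig.silent())

    @property
    def pools(self) -> tuple:
        if self.variant == "C450A":
            return ("prot", "protstar", "water")
        if self.variant == "wt":
            return ("prot", "water")
        return ("water",)


def default_config(variant: str, seed: int = 0, **overrides) -> ExperimentConfig:
    """Study-condition defaults for each sample variant.

    C450A: Scheme 1 at 1/k1 = 9000 s, 1/k2 = 1000 s, 1/k3 = 3260 s; triplet
    lifetimes 57 us (intact), 32 -> 23 us (oxidized, drifting), 2.7 us (water);
    singlet-oxygen lifetime drifting 2.7 -> 3.0 us across the six sets;
    protein-pool yield 0.07; post-irradiation free emission fraction 0.25.

    wt: linear depletion of the intact pool by 50% over the 75 min run, free
    FMN bleaching at 1/k3 = 3260 s; lifetimes 1.50 us (protein) and 2.7 us
    (water); tau_delta 2.6 -> 3.3 us; zero protein-pool yield (the observed
    phosphorescence is fully explained by solution-phase production); free
    emission fraction 0.45; 40% of FMN adduct-competent after irradiation.

    free_FMN_control: 25 uM FMN + apoprotein, single aqueous pool bleaching at
    1/k3 = 3260 s with constant 2.7 us triplet lifetime.
    """
    rates = RateConstants.from_characteristic_times(9000.0, 1000.0, 3260.0)
    if variant == "C450A":
        base = ExperimentConfig(
            variant="C450A",
            rates=rates,
            lifetimes=LifetimeSet(tau_T_prot=57.0, tau_T_protstar=32.0),
            tau_protstar_schedule=(32.0, 23.0),
            tau_delta_schedule=(2.7, 3.0),
            release_fraction=0.25,
            seed=seed,
        )
    elif variant == "wt":
        base = ExperimentConfig(
            variant="wt",
            rates=rates,
            lifetimes=LifetimeSet(tau_T_prot=1.50),
            scheme2_cfg=Scheme2Config(mode="empirical_linear",
                                      depletion_slope=0.5 / 4500.0),
            tau_delta_schedule=(2.6, 3.3),
            phi_prot=0.0,   # wt signal fully explained by solution-phase production
            release_fraction=0.45,
            seed=seed,
        )
    elif variant == "free_FMN_control":
        base = ExperimentConfig(
            variant="free_FMN_control",
            rates=rates,
            lifetimes=LifetimeSet(),
            tau_delta_schedule=(2.7, 3.0),
            seed=seed,
        )
    else:
        raise InputError(f"unknown variant {variant!r}")
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# population bookkeeping
# ---------------------------------------------------------------------------

def pool_fractions(cfg: ExperimentConfig, t) -> dict:
    """Pool fractions of the configured scheme at irradiation time(s) ``t``."""
    t = np.atleast_1d(np.asarray(t, float))
    if cfg.variant == "C450A":
        traj = scheme1_populations(t, cfg.rates)
        return {"prot": traj.f_prot, "protstar": traj.f_protstar, "water": traj.f_water}
    if cfg.variant == "wt":
        traj = scheme2_populations(t, cfg.rates, cfg.scheme2_cfg)
        return {"prot": traj.f_prot, "water": traj.f_water}
    return {"water": bleaching_fraction(t, cfg.rates.k3)}


def _mean_pool_fractions(cfg: ExperimentConfig, t0: float, t1: float) -> dict:
    grid = np.linspace(t0, t1, 129)
    fr = pool_fractions(cfg, grid)
    return {k: float(np.trapezoid(v, grid) / (t1 - t0)) for k, v in fr.items()}


def _tau_protstar_at(cfg: ExperimentConfig, t: float) -> float:
    lo, hi = cfg.tau_protstar_schedule
    return lo + (hi - lo) * t / cfg.total_irradiation_s


def _tau_delta_for_set(cfg: ExperimentConfig, j: int) -> float:
    lo, hi = cfg.tau_delta_schedule
    n = cfg.n_phos_sets
    return lo if n == 1 else lo + (hi - lo) * j / (n - 1)


def _pool_taus(cfg: ExperimentConfig, t_irr: float) -> list:
    taus = []
    for pool in cfg.pools:
        if pool == "prot":
            taus.append(cfg.lifetimes.tau_T_prot)
        elif pool == "protstar":
            taus.append(_tau_protstar_at(cfg, t_irr))
        else:
            taus.append(cfg.lifetimes.tau_T_water)
    return taus


def _phi(cfg: ExperimentConfig, pool: str) -> float:
    return {"prot": cfg.phi_prot, "protstar": cfg.phi_protstar,
            "water": cfg.phi_water_ref}[pool]


def _abs475(cfg: ExperimentConfig, pool: str) -> float:
    # protein-bound pools share the bound absorbance; water is the reference
    return cfg.abs_ratio_475 if pool in ("prot", "protstar") else 1.0


def triplet_curve_times(cfg: ExperimentConfig) -> np.ndarray:
    """Midpoints of the consecutive 2500-pulse acquisition blocks (s)."""
    block = cfg.total_irradiation_s / cfg.n_absorption_curves
    return block * (np.arange(cfg.n_absorption_curves) + 0.5)


def phos_set_edges(cfg: ExperimentConfig) -> np.ndarray:
    return np.linspace(0.0, cfg.total_irradiation_s, cfg.n_phos_sets + 1)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_triplet_experiment(cfg: ExperimentConfig) -> list:
    """Transient-absorption curves across the irradiation run.

    Per-curve pool amplitudes are the scheme's pool fractions at the block
    midpoint (unit proportionality constant per pool: equal triplet extinction
    at the 633 nm probe is the default study condition).
    """
    rng = _rng(cfg, "triplet")
    start, stop, step = cfg.abs_time_range_us
    t_us = np.arange(start, stop, step)
    curves = []
    for t_irr in triplet_curve_times(cfg):
        fracs = pool_fractions(cfg, t_irr)
        amps = [float(fracs[p][0]) for p in cfg.pools]
        taus = _pool_taus(cfg, t_irr)
        model = triplet_absorbance(t_us, amps, taus)
        if cfg.noise.abs_sigma > 0:
            model = model + rng.normal(0.0, cfg.noise.abs_sigma, size=model.shape)
        curves.append(
            TripletDecayCurve(
                irradiation_time=float(t_irr),
                t=t_us,
                absorbance=model,
                noise_sigma=cfg.noise.abs_sigma,
                meta={"variant": cfg.variant, "seed": cfg.seed,
                      "pools": cfg.pools, "true_taus": tuple(taus)},
            )
        )
    return curves


def _background_rate(cfg: ExperimentConfig, t_us: np.ndarray) -> np.ndarray:
    n = cfg.noise
    if n.background_amp == 0:
        return np.zeros_like(t_us)
    return n.background_amp * np.exp(-t_us / n.background_tau_us)


def _window_factor(cfg: ExperimentConfig, window: str) -> float:
    """Relative background level of each window.

    Window centers are equally spaced in wavelength, so a linear spectral
    background gives factors (1 - tilt, 1, 1 + tilt) and cancels exactly in
    the subtraction; the quadratic option raises the central window by the
    curvature, which survives the subtraction.
    """
    n = cfg.noise
    pos = {FILTER_WINDOWS[0]: -1.0, FILTER_WINDOWS[1]: 0.0, FILTER_WINDOWS[2]: 1.0}[window]
    factor = 1.0 + n.background_tilt * pos
    if n.background_shape == "quadratic":
        factor += n.background_curvature * (1.0 - pos**2)
    return factor


def generate_phosphorescence_experiment(cfg: ExperimentConfig) -> list:
    """Photon-counting traces: ``n_phos_sets`` sets x three band-pass windows.

    The signal (middle) window carries the phosphorescence profile built from
    the pool fractions averaged over the set interval, with amplitudes
    A_i = phos_scale * Phi_i * absorbance_i(475 nm) * <f_i>; the flanking
    windows carry background only.
    """
    rng = _rng(cfg, "phos")
    start, stop, step = cfg.phos_time_range_us
    t_us = np.arange(start, stop, step) + step / 2.0  # bin centers
    edges = phos_set_edges(cfg)
    traces = []
    for j in range(cfg.n_phos_sets):
        t0, t1 = float(edges[j]), float(edges[j + 1])
        mid_t = 0.5 * (t0 + t1)
        fracs = _mean_pool_fractions(cfg, t0, t1)
        amps = [cfg.noise.phos_scale * _phi(cfg, p) * _abs475(cfg, p) * fracs[p]
                for p in cfg.pools]
        taus = _pool_taus(cfg, mid_t)
        tau_d = _tau_delta_for_set(cfg, j)
        profile = phosphorescence_profile(t_us, amps, taus, tau_d)
        bg = _background_rate(cfg, t_us)
        for window in FILTER_WINDOWS:
            expected = bg * _window_factor(cfg, window)
            if window == "1250-1300":
                expected = expected + profile
            counts = rng.poisson(expected).astype(np.int64) if cfg.noise.poisson else expected
            traces.append(
                PhosphorescenceTrace(
                    irradiation_time=mid_t,
                    filter_window=window,
                    t=t_us,
                    counts=counts,
                    n_pulses=2500,
                    meta={"variant": cfg.variant, "seed": cfg.seed, "set_index": j,
                          "true_tau_delta": tau_d, "true_amplitudes": tuple(amps),
                          "pools": cfg.pools, "expectation": not cfg.noise.poisson},
                )
            )
    return traces


def _lognormal_band(wl: np.ndarray, peak_nm: float, width: float) -> np.ndarray:
    """Unit-peak, flavin-like asymmetric emission band (synthetic shape)."""
    return np.exp(-np.log(wl / peak_nm) ** 2 / (2.0 * width**2))


def generate_emission_spectra(cfg: ExperimentConfig) -> dict:
    """Emission spectra: free-FMN reference, pre- and post-irradiation sample.

    The basis shapes are synthetic log-normal bands (protein-bound peak at
    500 nm, free FMN at 520 nm); the wild type's bound emission is strongly
    quenched by adduct formation.  The post-irradiation spectrum is the
    two-component mixture at the configured release fraction plus Gaussian
    noise.
    """
    rng = _rng(cfg, "emission")
    wl = np.arange(460.0, 640.0 + 1e-9, 1.0)
    bound_amp = cfg.bound_emission_amp * (0.25 if cfg.variant == "wt" else 1.0)
    free = EmissionSpectrum(wl, cfg.free_emission_amp * _lognormal_band(wl, 520.0, 0.060),
                            label="free_basis")
    bound = EmissionSpectrum(wl, bound_amp * _lognormal_band(wl, 500.0, 0.055),
                             label="bound_basis")
    post = emission_spectrum_mixture(cfg.release_fraction, free, bound)
    sigma = cfg.noise.spectrum_sigma_rel
    pre_int = bound.intensity.copy()
    post_int = post.intensity.copy()
    if sigma > 0:
        pre_int = pre_int + rng.normal(0.0, sigma * pre_int.max(), size=wl.shape)
        post_int = post_int + rng.normal(0.0, sigma * max(post_int.max(), 1e-12),
                                         size=wl.shape)
    return {
        "free_fmn": free,
        "bound_basis": bound,
        "pre_irradiation": EmissionSpectrum(wl, pre_int, label="pre_irradiation"),
        "post_irradiation": EmissionSpectrum(wl, post_int, label="post_irradiation"),
    }


def generate_adduct_traces(cfg: ExperimentConfig):
    """Pre- and post-irradiation dark-state recovery traces at 447 nm (wt only).

    Both traces share the recovery time constant; the post-irradiation
    amplitude is scaled by the adduct-competent FMN fraction.
    """
    if cfg.variant != "wt":
        raise InputError(
            "adduct formation requires the reactive cysteine: only the wt variant "
            "forms the light-induced cysteinyl-flavin bond"
        )
    rng = _rng(cfg, "adduct")
    t = np.arange(0.0, 400.0 + 1e-9, 2.0)
    baseline, amp_pre = 0.25, 0.10
    traces = []
    for label, amp in (("pre", amp_pre), ("post", amp_pre * cfg.adduct_fraction)):
        y = adduct_recovery_model(t, amp, cfg.tau_rec_s, baseline)
        if cfg.noise.adduct_sigma > 0:
            y = y + rng.normal(0.0, cfg.noise.adduct_sigma, size=y.shape)
        traces.append(KineticTrace(t, y, label=label,
                                   meta={"true_amplitude": amp, "true_tau": cfg.tau_rec_s,
                                         "baseline": baseline, "seed": cfg.seed}))
    return tuple(traces)


def generate_bleaching_control(cfg: ExperimentConfig) -> dict:
    """Free-FMN + apoprotein control: a single aqueous pool bleaching away.

    Returns the transient-absorption series (constant 2.7 us lifetime,
    amplitudes on exp(-k3 t)) and the matching phosphorescence sets.
    """
    if cfg.variant != "free_FMN_control":
        raise InputError("bleaching control requires variant='free_FMN_control'")
    curves = generate_triplet_experiment(cfg)
    phos = generate_phosphorescence_experiment(cfg)
    return {"triplet_curves": curves, "phos_traces": phos}


def generate_amplitude_series(cfg: ExperimentConfig, rel_noise: float = 0.05,
                              stream: str = "series") -> dict:
    """Noisy per-pool initial-amplitude series at the curve timestamps.

    Emulates the output of per-curve triplet fits without running them:
    pool fractions at the block midpoints with multiplicative Gaussian noise.
    Used for the staged rate-constant fits.
    """
    if rel_noise < 0:
        raise InputError("rel_noise must be non-negative")
    rng = _rng(cfg, stream)
    times = triplet_curve_times(cfg)
    fracs = pool_fractions(cfg, times)
    out = {}
    for pool in cfg.pools:
        values = np.asarray(fracs[pool], float)
        if rel_noise > 0:
            values = values * (1.0 + rng.normal(0.0, rel_noise, size=values.shape))
        out[pool] = KineticTrace(times, values, label=pool,
                                 meta={"seed": cfg.seed, "rel_noise": rel_noise})
    return out
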