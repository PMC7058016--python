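"""Microsecond-timescale forward models of the laser observables.

Three measurement channels are modelled:

* **Triplet transient absorption** at 633 nm after each excitation pulse: a sum
  of exponential decays, one per FMN pool, with initial amplitudes Abs0_i
  proportional to the pool populations at that point of the irradiation.
* **Singlet-oxygen phosphorescence** near 1270 nm: each triplet pool feeds the
  singlet-oxygen population, giving the classic rise-and-decay profile

      P(t) = sum_i A_i * tau_d / (tau_d - tau_Ti) * (e^{-t/tau_d} - e^{-t/tau_Ti})

  with a single singlet-oxygen lifetime tau_d shared by all contributions
  (singlet oxygen spends essentially all of its lifetime in water regardless of
  where it was produced).  The tau_Ti = tau_d singular point is the analytic
  limit A * (t/tau) * e^{-t/tau} and is handled by a stable kernel, not a
  branch on exact equality.
* **Dark-state adduct recovery** at 447 nm (wild type only): single-exponential
  return of the cysteinyl-flavin adduct absorbance.

Instrument response is treated as a delta function: the 5-7 ns excitation
pulses are three orders of magnitude shorter than the shortest modelled
lifetime, so no reconvolution is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad

from ._stable import expdd1
from .exceptions import InputError

__all__ = [
    "FILTER_WINDOWS",
    "TAU_T_WATER_US",
    "LifetimeSet",
    "TripletDecayCurve",
    "PhosphorescenceTrace",
    "NetPhosphorescenceTrace",
    "PhosAmplitudes",
    "EmissionSpectrum",
    "KineticTrace",
    "phosphorescence_profile",
    "phosphorescence_integral",
    "phosphorescence_peak_time",
    "triplet_absorbance",
    "subtract_filter_background",
    "emission_spectrum_mixture",
    "adduct_recovery_model",
]

#: Band-pass windows (nm) of the phosphorescence detection: the signal window
#: flanked by the two background windows.
FILTER_WINDOWS = ("1200-1250", "1250-1300", "1300-1350")
SIGNAL_WINDOW = "1250-1300"

#: Triplet lifetime of free FMN in aerated aqueous solution (us); fixed, not
#: fitted, in all analyses.
TAU_T_WATER_US = 2.7


def _pos(name, value):
    if value is None:
        return None
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise InputError(f"{name} must be positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LifetimeSet:
    """Triplet and singlet-oxygen lifetimes (us) of one experiment.

    ``tau_T_protstar`` and ``tau_delta`` may be scalars or per-curve/per-set
    sequences (they are allowed to evolve with irradiation); ``tau_T_water``
    defaults to the fixed aqueous value 2.7 us.
    """

    tau_T_prot: Optional[float] = None
    tau_T_protstar: Optional[Sequence[float] | float] = None
    tau_T_water: float = TAU_T_WATER_US
    tau_delta: Optional[Sequence[float] | float] = None

    def __post_init__(self):
        _pos("tau_T_prot", self.tau_T_prot)
        _pos("tau_T_protstar", self.tau_T_protstar)
        _pos("tau_T_water", self.tau_T_water)
        _pos("tau_delta", self.tau_delta)


@dataclass(frozen=True)
class TripletDecayCurve:
    """One flash-photolysis transient-absorption record (633 nm probe)."""

    irradiation_time: float        # s since irradiation start
    t: np.ndarray                  # within-pulse time grid, us
    absorbance: np.ndarray         # transient OD
    noise_sigma: float = 0.0       # per-point Gaussian scale, OD
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.t, float)
        a = np.asarray(self.absorbance, float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise InputError("time grid must be strictly increasing, starting at >= 0")
        if a.shape != t.shape or not np.all(np.isfinite(a)):
            raise InputError("absorbance must be finite and match the time grid")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class PhosphorescenceTrace:
    """Photon-counting record of one band-pass window of one measurement set.

    Counts are non-negative integers for any measured (or Poisson-simulated)
    trace.  A noiseless *expectation* trace -- the continuous model a silent
    generator emits -- carries float counts and must be flagged with
    ``meta["expectation"] = True``.
    """

    irradiation_time: float        # s, set midpoint
    filter_window: str             # one of FILTER_WINDOWS
    t: np.ndarray                  # time-bin centers, us
    counts: np.ndarray             # photons per bin
    n_pulses: int = 2500
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.filter_window not in FILTER_WINDOWS:
            raise InputError(
                f"filter_window must be one of {FILTER_WINDOWS}, got {self.filter_window!r}"
            )
        t = np.asarray(self.t, float)
        c = np.asarray(self.counts)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise InputError("time grid must be strictly increasing, starting at >= 0")
        if c.shape != t.shape:
            raise InputError("counts must match the time grid")
        if np.any(c < 0):
            raise InputError("photon counts must be non-negative")
        if np.issubdtype(c.dtype, np.integer):
            c = c.astype(np.int64)
        elif np.array_equal(c, np.rint(c)):
            c = np.rint(c).astype(np.int64)
        elif not self.meta.get("expectation"):
            raise InputError("photon counts must be integers")
        else:
            c = c.astype(float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class NetPhosphorescenceTrace:
    """Background-subtracted phosphorescence; per-bin values may be negative."""

    irradiation_time: float
    t: np.ndarray
    value: np.ndarray
    n_pulses: int = 2500
    meta: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class PhosAmplitudes:
    """Per-pool phosphorescence amplitudes and the shared tau_delta of one set."""

    irradiation_time: float
    amplitudes: dict                      # pool name -> A_i (>= 0)
    tau_delta: float                      # us, shared within the set
    amplitude_stderr: Optional[dict] = None
    tau_delta_stderr: Optional[float] = None
    flags: tuple = ()

    def __post_init__(self):
        for pool, a in self.amplitudes.items():
            if a < 0:
                raise InputError(f"amplitude for pool {pool!r} must be non-negative")
        _pos("tau_delta", self.tau_delta)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Steady-state fluorescence emission spectrum (arbitrary intensity units)."""

    wavelength: np.ndarray     # nm, strictly increasing
    intensity: np.ndarray      # >= 0 for basis spectra; observed may dip below 0
    label: str = "observed"

    def __post_init__(self):
        w = np.asarray(self.wavelength, float)
        i = np.asarray(self.intensity, float)
        if w.ndim != 1 or w.size < 2 or np.any(np.diff(w) <= 0):
            raise InputError("wavelength grid must be strictly increasing")
        if i.shape != w.shape or not np.all(np.isfinite(i)):
            raise InputError("intensity must be finite and match the wavelength grid")
        object.__setattr__(self, "wavelength", w)
        object.__setattr__(self, "intensity", i)

    def resampled(self, wavelength: np.ndarray) -> "EmissionSpectrum":
        """Linear interpolation onto ``wavelength`` (must lie inside the support)."""
        wavelength = np.asarray(wavelength, float)
        if wavelength[0] < self.wavelength[0] - 1e-9 or wavelength[-1] > self.wavelength[-1] + 1e-9:
            raise InputError(
                "requested wavelength range extends beyond the spectrum support"
            )
        return EmissionSpectrum(
            wavelength, np.interp(wavelength, self.wavelength, self.intensity), self.label
        )


@dataclass(frozen=True)
class KineticTrace:
    """Generic slow (seconds-scale) absorbance trace, e.g. adduct recovery."""

    t: np.ndarray                  # s
    value: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.t, float)
        v = np.asarray(self.value, float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise InputError("time grid must be strictly increasing")
        if v.shape != t.shape:
            raise InputError("values must match the time grid")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def phosphorescence_profile(t, amplitudes, tau_T_list, tau_delta):
    """Singlet-oxygen phosphorescence intensity from multiple triplet pools.

    Each pool i contributes A_i tau_d/(tau_d - tau_Ti) (e^{-t/tau_d} - e^{-t/tau_Ti});
    the expression is evaluated as A_i (t/tau_Ti) exp[-t/tau_d, -t/tau_Ti]
    (a first divided difference of exp), which passes smoothly through
    tau_Ti = tau_d where the profile becomes A_i (t/tau) e^{-t/tau}.

    Parameters
    ----------
    t : array
        Time after the excitation pulse, us (>= 0).
    amplitudes, tau_T_list : sequences of equal length
        Pool amplitudes (>= 0) and triplet lifetimes (us).
    tau_delta : float
        Singlet-oxygen lifetime (us), shared by all pools.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("times must be non-negative")
    A = np.asarray(amplitudes, dtype=float)
    tau_T = np.asarray(tau_T_list, dtype=float)
    if A.shape != tau_T.shape:
        raise InputError("amplitudes and lifetimes must have matching lengths")
    if np.any(A < 0):
        raise InputError("amplitudes must be non-negative")
    _pos("tau_T_list", tau_T)
    _pos("tau_delta", tau_delta)
    out = np.zeros_like(t, dtype=float)
    for a, tau in zip(A, tau_T):
        out += a * (t / tau) * expdd1(-t / tau_delta, -t / tau)
    return out


def phosphorescence_integral(amplitudes, tau_T_list, tau_delta):
    """Time integral of the phosphorescence profile: sum_i A_i * tau_delta.

    The triplet lifetimes drop out of the closed form; they are accepted (and
    validated) so the signature mirrors ``phosphorescence_profile``.
    """
    A = np.asarray(amplitudes, dtype=float)
    tau_T = np.asarray(tau_T_list, dtype=float)
    if A.shape != tau_T.shape:
        raise InputError("amplitudes and lifetimes must have matching lengths")
    if np.any(A < 0):
        raise InputError("amplitudes must be non-negative")
    _pos("tau_T_list", tau_T)
    _pos("tau_delta", tau_delta)
    return float(A.sum() * tau_delta)


def phosphorescence_peak_time(tau_T: float, tau_delta: float) -> float:
    """Closed-form peak time of a single-pool profile (us).

    ln(tau_T/tau_d) * tau_T * tau_d / (tau_T - tau_d); equal lifetimes give tau.
    """
    _pos("tau_T", tau_T)
    _pos("tau_delta", tau_delta)
    if tau_T == tau_delta:
        return float(tau_T)
    return float(np.log(tau_T / tau_delta) * tau_T * tau_delta / (tau_T - tau_delta))


def _quadrature_integral(amplitudes, tau_T_list, tau_delta):
    """Numerical cross-check of ``phosphorescence_integral`` (tests only)."""
    upper = 60.0 * max(float(np.max(tau_T_list)), float(tau_delta))
    val, _err = quad(
        lambda x: float(phosphorescence_profile(np.array([x]), amplitudes, tau_T_list, tau_delta)[0]),
        0.0, upper, limit=200,
    )
    return val


def triplet_absorbance(t, amplitudes, taus):
    """Multi-exponential triplet transient absorbance: sum_i Abs0_i e^{-t/tau_i}."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("times must be non-negative")
    A = np.asarray(amplitudes, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if A.shape != tau.shape:
        raise InputError("amplitudes and lifetimes must have matching lengths")
    _pos("taus", tau)
    return np.sum(A[:, None] * np.exp(-t[None, :] / tau[:, None]), axis=0)


def subtract_filter_background(
    mid: PhosphorescenceTrace,
    low: PhosphorescenceTrace,
    high: PhosphorescenceTrace,
) -> NetPhosphorescenceTrace:
    """Net phosphorescence: signal window minus the mean of the flanking windows.

    The optical-train background is assumed to vary slowly (to first order,
    linearly) with wavelength across the three windows, so the average of the
    two flanking windows estimates the background inside the signal window and
    any wavelength-linear background cancels exactly.  The net trace may be
    negative per bin; counting statistics are no longer Poisson after the
    subtraction.
    """
    if mid.filter_window != SIGNAL_WINDOW:
        raise InputError(f"mid trace must be the {SIGNAL_WINDOW} window")
    if low.filter_window != FILTER_WINDOWS[0] or high.filter_window != FILTER_WINDOWS[2]:
        raise InputError("low/high traces must be the flanking windows, in order")
    for other in (low, high):
        if other.t.shape != mid.t.shape or not np.allclose(other.t, mid.t):
            raise InputError("all three traces must share one time grid")
    net = mid.counts.astype(float) - 0.5 * (low.counts + high.counts)
    return NetPhosphorescenceTrace(
        irradiation_time=mid.irradiation_time,
        t=mid.t.copy(),
        value=net,
        n_pulses=mid.n_pulses,
        meta={
            **mid.meta,
            "background_subtraction": "mid - (low + high)/2",
            # propagated Poisson variance of the net value, per bin
            "variance": (mid.counts + 0.25 * (low.counts + high.counts)).astype(float),
        },
    )


def emission_spectrum_mixture(
    fraction_free: float,
    basis_free: EmissionSpectrum,
    basis_bound: EmissionSpectrum,
    scale: float = 1.0,
) -> EmissionSpectrum:
    """Two-component emission spectrum: free and protein-bound FMN fluorescence.

    Returns scale * (fraction_free * free + (1 - fraction_free) * bound) on the
    overlap of the two wavelength grids.
    """
    if not (0.0 <= fraction_free <= 1.0):
        raise InputError("fraction_free must lie in [0, 1]")
    lo = max(basis_free.wavelength[0], basis_bound.wavelength[0])
    hi = min(basis_free.wavelength[-1], basis_bound.wavelength[-1])
    if lo >= hi:
        raise InputError("basis spectra have disjoint wavelength ranges")
    grid = basis_free.wavelength
    if not np.array_equal(basis_free.wavelength, basis_bound.wavelength):
        grid = basis_free.wavelength[(basis_free.wavelength >= lo) & (basis_free.wavelength <= hi)]
    free = basis_free.resampled(grid).intensity
    bound = basis_bound.resampled(grid).intensity
    mix = scale * (fraction_free * free + (1.0 - fraction_free) * bound)
    return EmissionSpectrum(grid, mix, label="observed")


def adduct_recovery_model(t, amplitude: float, tau_rec: float, baseline: float):
    """Dark-state recovery of the cysteinyl-flavin adduct at 447 nm.

    baseline + amplitude * (1 - e^{-t/tau_rec}): the flash depletes the
    dark-state absorbance, which recovers single-exponentially as the adduct
    decays thermally.
    """
    _pos("tau_rec", tau_rec)
    t = np.asarray(t, dtype=float)
    return baseline + amplitude * (-np.expm1(-t / tau_rec))
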