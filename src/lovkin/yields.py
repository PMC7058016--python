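"""Derived photophysical quantities: singlet-oxygen quantum yield of the
protein-bound FMN pool, released-FMN fractions, and the wild-type/C450A
release-ratio comparison.

The quantum yield of the intact-protein pool is referenced to aqueous FMN
(Phi = 0.57): the phosphorescence amplitude of pool i is proportional to
Phi_i x absorbance_i(475 nm) x [FMN]_i, so the ratio of the
amplitude-vs-population proportionality slopes of the protein and water
pools, corrected by the 475 nm absorbance ratio, converts the aqueous
reference yield into the protein-pool yield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import InputError
from .kinetics import PopulationTrajectory

__all__ = [
    "PHI_DELTA_WATER",
    "YieldInputs",
    "quantum_yield_from_slopes",
    "amplitude_population_slope",
    "release_fraction_at",
    "release_ratio",
    "combine_release_estimates",
]

#: Reference singlet-oxygen quantum yield of FMN in aerated water.
PHI_DELTA_WATER = 0.57


@dataclass(frozen=True)
class YieldInputs:
    """Ingredients of the slope-ratio quantum-yield formula.

    ``slope_prot`` and ``slope_water`` link the fitted phosphorescence
    amplitudes A_prot, A_water to the corresponding FMN pool fractions;
    ``abs_ratio_475`` is the bound/free absorbance ratio per unit concentration
    at the 475 nm excitation.
    """

    slope_prot: float
    slope_water: float
    abs_ratio_475: float = 1.0
    phi_water_ref: float = PHI_DELTA_WATER

    def __post_init__(self):
        if self.slope_prot < 0 or self.slope_water < 0:
            raise InputError("slopes must be non-negative")
        if self.abs_ratio_475 <= 0:
            raise InputError("abs_ratio_475 must be positive")
        if not (0.0 < self.phi_water_ref <= 1.0):
            raise InputError("phi_water_ref must lie in (0, 1]")


def quantum_yield_from_slopes(inputs: YieldInputs) -> float:
    """Singlet-oxygen quantum yield of the intact-protein pool.

    Phi_prot = phi_water_ref * (slope_prot / slope_water) / abs_ratio_475,
    clipped to [0, 1] with a warning if the raw value exceeds 1.  Invariant
    under joint rescaling of both slopes (only their ratio matters).
    """
    if inputs.slope_water == 0:
        raise InputError("slope_water = 0: the aqueous reference slope is undefined")
    phi = inputs.phi_water_ref * (inputs.slope_prot / inputs.slope_water) / inputs.abs_ratio_475
    if phi > 1.0:
        warnings.warn(f"quantum yield {phi:.3g} exceeds 1; clipping", stacklevel=2)
        return 1.0
    return float(phi)


def amplitude_population_slope(amplitudes, fractions) -> tuple:
    """Proportionality slope of an amplitude series on its pool fractions.

    Least squares through the origin: slope = sum(A f) / sum(f^2).  Returns
    (slope, stderr).
    """
    A = np.asarray(amplitudes, float)
    f = np.asarray(fractions, float)
    if A.shape != f.shape or A.ndim != 1:
        raise InputError("amplitudes and fractions must be 1-D and matched")
    denom = float(f @ f)
    if denom == 0:
        raise InputError("all pool fractions are zero; slope is undefined")
    slope = float(A @ f) / denom
    resid = A - slope * f
    dof = max(A.size - 1, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / denom))
    return slope, stderr


def release_fraction_at(t: float, trajectory: PopulationTrajectory) -> float:
    """Fraction of FMN released from the protein by irradiation time ``t``:
    intact FMN in water plus bleached FMN, interpolated on the trajectory."""
    ts = np.asarray(trajectory.t, float)
    if not (ts[0] <= t <= ts[-1]):
        raise InputError(
            f"t={t!r} outside the trajectory span [{ts[0]}, {ts[-1]}]; refusing to extrapolate"
        )
    released = np.asarray(trajectory.f_water) + np.asarray(trajectory.f_bleached)
    return float(np.interp(t, ts, released))


def release_ratio(frac_a: float, frac_b: float) -> float:
    """Ratio of two released fractions (e.g. wild type over C450A)."""
    if frac_b <= 0:
        raise InputError("denominator release fraction must be positive")
    return float(frac_a) / float(frac_b)


def combine_release_estimates(estimates, uncertainties=None) -> dict:
    """Report per-method release estimates plus an inverse-variance-weighted mean.

    ``estimates`` maps method name -> released fraction; ``uncertainties``
    (same keys, optional) supplies 1-sigma errors for the weighting.  Without
    uncertainties the mean is unweighted.  The combination method is a
    package choice; the individual estimates are always reported alongside.
    """
    names = list(estimates)
    vals = np.array([estimates[k] for k in names], float)
    if uncertainties:
        sig = np.array([uncertainties[k] for k in names], float)
        if np.any(sig <= 0):
            raise InputError("uncertainties must be positive")
        w = 1.0 / sig**2
        mean = float((w * vals).sum() / w.sum())
        mean_err = float(np.sqrt(1.0 / w.sum()))
    else:
        mean = float(vals.mean())
        mean_err = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return {
        "per_method": dict(zip(names, vals.tolist())),
        "weighted_mean": mean,
        "weighted_mean_stderr": mean_err,
        "weighted": bool(uncertainties),
    }
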