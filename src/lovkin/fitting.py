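"""Constrained global fitting of the irradiation series.

The inference chain mirrors the experimental analysis:

1. **Global multi-exponential fit** of all transient-absorption curves at once.
   Each triplet lifetime is declared *shared* (one value for the whole series),
   *per-curve* (free to evolve with irradiation) or *fixed* (e.g. the aqueous
   2.7 us lifetime).  Amplitudes are per curve, per pool, constrained
   non-negative.  Internally the solver uses variable projection: for a given
   lifetime vector the amplitudes are the exact NNLS solution, so the nonlinear
   search runs over the (few) lifetimes only, from a coarse multi-start grid.
2. **Global phosphorescence fit**: with triplet lifetimes held fixed, each
   measurement set gets non-negative pool amplitudes and one free
   singlet-oxygen lifetime (allowed to evolve across sets).
3. **Staged rate-constant fits**: k3 from the free-FMN bleaching control, k1
   from a single-exponential fit of the intact-protein amplitude series, k2
   from the sequential-chain (Bateman) curves fitted to the oxidized-protein
   and water series with k1 and k3 held fixed.
4. **Spectral unmixing**: non-negative least squares of an observed emission
   spectrum on the free/bound basis pair.

Least squares is unweighted by default; for net (background-subtracted)
phosphorescence the subtraction-propagated Poisson variances are available as
optional weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares, nnls

from .exceptions import FitError, InputError
from .kinetics import RateConstants, scheme1_populations, scheme2_populations, Scheme2Config
from .signals import (
    EmissionSpectrum,
    KineticTrace,
    NetPhosphorescenceTrace,
    PhosAmplitudes,
    TripletDecayCurve,
    TAU_T_WATER_US,
)

__all__ = [
    "LifetimeConstraint",
    "TripletFitSpec",
    "c450a_fit_spec",
    "wt_fit_spec",
    "single_pool_fit_spec",
    "GlobalFitResult",
    "fit_triplet_decays_global",
    "PhosFitResult",
    "fit_phosphorescence_global",
    "RateFitResult",
    "fit_rate_constants",
    "DecompositionResult",
    "decompose_emission_spectrum",
    "SingleExpFit",
    "fit_single_exponential",
]


# ---------------------------------------------------------------------------
# constraint specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifetimeConstraint:
    """How one pool's triplet lifetime enters the global fit."""

    pool: str
    mode: Literal["shared", "per_curve", "fixed"]
    value: float               # initial guess (shared/per_curve) or fixed value
    bounds: Tuple[float, float] = (0.1, 1000.0)   # us

    def __post_init__(self):
        if self.mode not in ("shared", "per_curve", "fixed"):
            raise InputError(f"unknown constraint mode {self.mode!r}")
        if self.value <= 0:
            raise InputError("lifetime value/guess must be positive")


@dataclass(frozen=True)
class TripletFitSpec:
    """Ordered pool constraints of one global transient-absorption fit."""

    constraints: Tuple[LifetimeConstraint, ...]

    def __post_init__(self):
        if len(self.constraints) < 1:
            raise InputError("at least one pool is required")
        pools = [c.pool for c in self.constraints]
        if len(set(pools)) != len(pools):
            raise InputError("duplicate pool names in constraint spec")

    @property
    def pools(self) -> List[str]:
        return [c.pool for c in self.constraints]


def c450a_fit_spec(tau_prot_guess: float = 60.0,
                   tau_protstar_guess: float = 25.0) -> TripletFitSpec:
    """Three-pool constraint set of the adduct-incompetent variant: shared
    intact-protein lifetime, unrestricted per-curve oxidized-protein lifetime,
    aqueous lifetime fixed at 2.7 us."""
    return TripletFitSpec((
        LifetimeConstraint("prot", "shared", tau_prot_guess, (5.0, 500.0)),
        LifetimeConstraint("protstar", "per_curve", tau_protstar_guess, (4.0, 200.0)),
        LifetimeConstraint("water", "fixed", TAU_T_WATER_US),
    ))


def wt_fit_spec(tau_prot_guess: float = 2.0) -> TripletFitSpec:
    """Two-pool wild-type constraint set: shared protein lifetime, aqueous
    lifetime fixed at 2.7 us; both assumed constant during irradiation."""
    return TripletFitSpec((
        LifetimeConstraint("prot", "shared", tau_prot_guess, (0.2, 100.0)),
        LifetimeConstraint("water", "fixed", TAU_T_WATER_US),
    ))


def single_pool_fit_spec(pool: str = "water", guess: float = TAU_T_WATER_US,
                         mode: str = "shared") -> TripletFitSpec:
    return TripletFitSpec((LifetimeConstraint(pool, mode, guess, (0.2, 100.0)),))


# ---------------------------------------------------------------------------
# global transient-absorption fit
# ---------------------------------------------------------------------------

@dataclass
class GlobalFitResult:
    """Outcome of a constrained global multi-exponential fit."""

    pools: List[str]
    lifetimes: Dict[str, np.ndarray]          # pool -> per-curve values (shared/fixed broadcast)
    lifetime_stderr: Dict[str, np.ndarray]    # zeros for fixed parameters
    amplitudes: pd.DataFrame                  # index: curve, columns: irradiation_time + pools
    amplitude_stderr: pd.DataFrame
    residual_rms: np.ndarray
    converged: bool
    config_echo: TripletFitSpec
    n_starts: int = 1
    flags: List[str] = field(default_factory=list)
    cost: float = np.nan

    def shared_lifetime(self, pool: str) -> float:
        return float(self.lifetimes[pool][0])

    def shared_lifetime_stderr(self, pool: str) -> float:
        return float(self.lifetime_stderr[pool][0])


def _design_matrix(t: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    return np.exp(-t[:, None] / np.asarray(taus)[None, :])


def _nnls_amplitudes(curve: TripletDecayCurve, taus: Sequence[float]):
    X = _design_matrix(curve.t, taus)
    amps, _ = nnls(X, curve.absorbance)
    resid = curve.absorbance - X @ amps
    return amps, resid, X


def _unpack_theta(theta: np.ndarray, spec: TripletFitSpec, n_curves: int):
    """Map the log-lifetime parameter vector onto per-curve lifetime lists."""
    taus_per_curve = [[0.0] * len(spec.pools) for _ in range(n_curves)]
    k = 0
    for j, c in enumerate(spec.constraints):
        if c.mode == "fixed":
            for i in range(n_curves):
                taus_per_curve[i][j] = c.value
        elif c.mode == "shared":
            v = float(np.exp(theta[k])); k += 1
            for i in range(n_curves):
                taus_per_curve[i][j] = v
        else:  # per_curve
            for i in range(n_curves):
                taus_per_curve[i][j] = float(np.exp(theta[k])); k += 1
    return taus_per_curve


def _theta_layout(spec: TripletFitSpec, n_curves: int):
    """Initial theta (log lifetimes) and bounds respecting the constraint modes."""
    theta0, lo, hi, labels = [], [], [], []
    for c in spec.constraints:
        if c.mode == "fixed":
            continue
        reps = 1 if c.mode == "shared" else n_curves
        for i in range(reps):
            theta0.append(np.log(c.value))
            lo.append(np.log(c.bounds[0]))
            hi.append(np.log(c.bounds[1]))
            labels.append((c.pool, None if c.mode == "shared" else i))
    return np.array(theta0), np.array(lo), np.array(hi), labels


def fit_triplet_decays_global(
    curves: Sequence[TripletDecayCurve],
    constraints: TripletFitSpec,
    n_starts: int = 8,
    per_curve_smoothness: float = 0.0,
) -> GlobalFitResult:
    """Fit all transient-absorption curves simultaneously.

    Multi-start: the shared lifetimes are scanned on a log-spaced grid of
    ``n_starts`` points inside their bounds (holding other guesses at their
    spec values) and the nonlinear refinement starts from the best grid point.

    ``per_curve_smoothness`` (off by default) adds a trend regularizer on each
    per-curve lifetime sequence: penalty residuals proportional to the second
    differences of log-lifetime across the irradiation series.  A smooth
    (e.g. linear) lifetime drift is essentially unpenalized, while a lifetime
    that is unidentifiable on one curve (a nearly empty pool) is pulled onto
    the trend of its neighbours instead of wandering into collinearity with
    another pool.

    Raises
    ------
    FitError
        If the trust-region solver does not converge from any start; the
        exception carries the best-so-far diagnostics.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise InputError("global fit requires at least two curves")
    spec = constraints
    n_curves = len(curves)
    theta0, lo, hi, labels = _theta_layout(spec, n_curves)
    # index blocks of per-curve parameters, in curve order, per pool
    pc_blocks = []
    if per_curve_smoothness > 0:
        for c in spec.constraints:
            if c.mode == "per_curve":
                idx = [k for k, (pool, ci) in enumerate(labels) if pool == c.pool]
                if len(idx) >= 3:
                    pc_blocks.append(np.asarray(idx))

    def residuals(theta):
        taus_pc = _unpack_theta(theta, spec, n_curves)
        parts = []
        for curve, taus in zip(curves, taus_pc):
            _, resid, _ = _nnls_amplitudes(curve, taus)
            parts.append(resid)
        for idx in pc_blocks:
            block = theta[idx]
            parts.append(per_curve_smoothness * np.diff(block, n=2))
        return np.concatenate(parts)

    # coarse multi-start over the shared lifetimes only
    shared_idx = [i for i, (pool, ci) in enumerate(labels) if ci is None]
    best_theta0, best_cost = theta0.copy(), np.inf
    if shared_idx and n_starts > 1:
        for i in shared_idx:
            grid = np.linspace(lo[i] + 0.05, hi[i] - 0.05, n_starts)
            costs = []
            for g in grid:
                trial = best_theta0.copy()
                trial[i] = g
                r = residuals(trial)
                costs.append(0.5 * float(r @ r))
            j = int(np.argmin(costs))
            best_theta0[i] = grid[j]
            best_cost = costs[j]

    if theta0.size == 0:
        sol_x = theta0
        success = True
        jac = None
        final_res = residuals(theta0)
        cost = 0.5 * float(final_res @ final_res)
    else:
        sol = least_squares(residuals, best_theta0, bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if not sol.success:
            raise FitError(
                f"global triplet fit did not converge: {sol.message}",
                best={"theta": np.exp(sol.x), "cost": sol.cost, "labels": labels},
            )
        sol_x, success, jac, final_res, cost = sol.x, True, sol.jac, sol.fun, sol.cost

    taus_pc = _unpack_theta(sol_x, spec, n_curves)

    # parameter uncertainties from the Gauss-Newton covariance (log scale,
    # mapped by the delta method)
    n_obs = sum(c.t.size for c in curves)
    n_par = sol_x.size + n_curves * len(spec.pools)
    dof = max(n_obs - n_par, 1)
    s2 = float(final_res @ final_res) / dof
    theta_err = np.full(sol_x.size, np.nan)
    if jac is not None and sol_x.size:
        JTJ = jac.T @ jac
        try:
            cov = np.linalg.inv(JTJ) * s2
            theta_err = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            pass

    lifetimes = {c.pool: np.empty(n_curves) for c in spec.constraints}
    stderr = {c.pool: np.zeros(n_curves) for c in spec.constraints}
    for j, c in enumerate(spec.constraints):
        for i in range(n_curves):
            lifetimes[c.pool][i] = taus_pc[i][j]
    for k, (pool, ci) in enumerate(labels):
        err = theta_err[k] * lifetimes[pool][ci if ci is not None else 0]
        if ci is None:
            stderr[pool][:] = err
        else:
            stderr[pool][ci] = err

    amp_rows, amp_err_rows, rms = [], [], []
    flags: List[str] = []
    for i, (curve, taus) in enumerate(zip(curves, taus_pc)):
        amps, resid, X = _nnls_amplitudes(curve, taus)
        sigma2 = float(resid @ resid) / max(curve.t.size - len(taus), 1)
        try:
            amp_cov = np.linalg.inv(X.T @ X) * sigma2
            amp_err = np.sqrt(np.clip(np.diag(amp_cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            amp_err = np.full(len(taus), np.nan)
        amp_rows.append([curve.irradiation_time, *amps])
        amp_err_rows.append([curve.irradiation_time, *amp_err])
        rms.append(np.sqrt(np.mean(resid**2)))

    cols = ["irradiation_time", *spec.pools]
    amplitudes = pd.DataFrame(amp_rows, columns=cols)
    amplitude_stderr = pd.DataFrame(amp_err_rows, columns=cols)

    # over-parameterization diagnostic: a pool pinned at (or within noise of)
    # zero amplitude on nearly every curve is not resolved by the data
    totals = amplitudes[spec.pools].sum(axis=1).to_numpy()
    for pool in spec.pools:
        vals = amplitudes[pool].to_numpy()
        errs = amplitude_stderr[pool].to_numpy()
        floor = np.maximum(np.where(np.isfinite(errs), errs, 0.0), 5e-3 * totals)
        if np.mean(vals <= floor) >= 0.9:
            flags.append(f"pool '{pool}' amplitude at the zero boundary on nearly "
                         "all curves; the model may have more pools than the data resolve")
            warnings.warn(flags[-1], stacklevel=2)

    return GlobalFitResult(
        pools=spec.pools,
        lifetimes=lifetimes,
        lifetime_stderr=stderr,
        amplitudes=amplitudes,
        amplitude_stderr=amplitude_stderr,
        residual_rms=np.asarray(rms),
        converged=success,
        config_echo=spec,
        n_starts=n_starts,
        flags=flags,
        cost=cost,
    )


# ---------------------------------------------------------------------------
# global phosphorescence fit
# ---------------------------------------------------------------------------

@dataclass
class PhosFitResult:
    """Per-set amplitudes and singlet-oxygen lifetimes of one irradiation run."""

    sets: List[PhosAmplitudes]
    pools: List[str]
    skipped: List[int] = field(default_factory=list)

    def tau_delta_series(self) -> np.ndarray:
        return np.array([s.tau_delta for s in self.sets])

    def amplitude_series(self, pool: str) -> KineticTrace:
        t = np.array([s.irradiation_time for s in self.sets])
        v = np.array([s.amplitudes[pool] for s in self.sets])
        return KineticTrace(t, v, label=pool)


def _phos_design(t: np.ndarray, taus: Sequence[float], tau_d: float) -> np.ndarray:
    from .signals import phosphorescence_profile

    cols = [phosphorescence_profile(t, [1.0], [tau], tau_d) for tau in taus]
    return np.stack(cols, axis=1)


def fit_phosphorescence_global(
    net_traces: Sequence[NetPhosphorescenceTrace],
    tau_T_sets: Sequence[Sequence[float]],
    pools: Sequence[str],
    tau_delta_guess: float = 3.0,
    tau_delta_bounds: Tuple[float, float] = (0.5, 20.0),
    min_total_counts: float = 50.0,
    weighted: bool = False,
) -> PhosFitResult:
    """Fit each background-subtracted set with fixed triplet lifetimes.

    One singlet-oxygen lifetime is free per measurement set (it is allowed to
    evolve with irradiation); pool amplitudes are the exact NNLS solution at
    each trial lifetime, so the per-set problem is a 1-D bounded search.  Sets
    whose total net signal falls below ``min_total_counts`` are flagged and
    skipped, not fitted.
    """
    if len(net_traces) != len(tau_T_sets):
        raise InputError("one triplet-lifetime list per net trace is required")
    pools = list(pools)
    results: List[PhosAmplitudes] = []
    skipped: List[int] = []
    for j, (trace, taus) in enumerate(zip(net_traces, tau_T_sets)):
        if len(taus) != len(pools):
            raise InputError("lifetime list length must match the pool list")
        y = np.asarray(trace.value, float)
        if float(y.sum()) < min_total_counts:
            skipped.append(j)
            results.append(PhosAmplitudes(trace.irradiation_time,
                                          {p: 0.0 for p in pools},
                                          tau_delta_guess,
                                          flags=("low_signal_not_fitted",)))
            continue
        w = None
        if weighted:
            var = np.asarray(trace.meta.get("variance", np.ones_like(y)), float)
            w = 1.0 / np.sqrt(np.clip(var, 1.0, np.inf))

        def residuals(logtau):
            tau_d = float(np.exp(logtau[0]))
            X = _phos_design(trace.t, taus, tau_d)
            Xw = X * w[:, None] if w is not None else X
            yw = y * w if w is not None else y
            amps, _ = nnls(Xw, yw)
            return yw - Xw @ amps

        sol = least_squares(residuals, [np.log(tau_delta_guess)],
                            bounds=([np.log(tau_delta_bounds[0])],
                                    [np.log(tau_delta_bounds[1])]),
                            method="trf", xtol=1e-12, ftol=1e-12)
        if not sol.success:
            raise FitError(f"phosphorescence fit of set {j} did not converge: {sol.message}")
        tau_d = float(np.exp(sol.x[0]))
        X = _phos_design(trace.t, taus, tau_d)
        Xw = X * w[:, None] if w is not None else X
        yw = y * w if w is not None else y
        amps, _ = nnls(Xw, yw)
        resid = yw - Xw @ amps
        dof = max(y.size - len(pools) - 1, 1)
        s2 = float(resid @ resid) / dof
        try:
            amp_cov = np.linalg.inv(Xw.T @ Xw) * s2
            amp_err = np.sqrt(np.clip(np.diag(amp_cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            amp_err = np.full(len(pools), np.nan)
        JTJ = float((sol.jac.T @ sol.jac).item())
        tau_err = tau_d * np.sqrt(s2 / JTJ) if JTJ > 0 else np.nan
        results.append(PhosAmplitudes(
            irradiation_time=trace.irradiation_time,
            amplitudes={p: float(a) for p, a in zip(pools, amps)},
            tau_delta=tau_d,
            amplitude_stderr={p: float(e) for p, e in zip(pools, amp_err)},
            tau_delta_stderr=float(tau_err),
        ))
    return PhosFitResult(sets=results, pools=pools, skipped=skipped)


# ---------------------------------------------------------------------------
# staged rate-constant fits
# ---------------------------------------------------------------------------

@dataclass
class RateFitResult:
    rates: RateConstants
    characteristic_times: Dict[str, float]    # "1/k1" etc., s
    stderr: Dict[str, float]
    stages: Dict[str, dict]                   # stage name -> diagnostics
    scheme: int
    scheme2_cfg: Optional[Scheme2Config] = None


def _scale_through_origin(model: np.ndarray, data: np.ndarray,
                          sigma: Optional[np.ndarray] = None) -> float:
    w = np.ones_like(model) if sigma is None else 1.0 / np.asarray(sigma) ** 2
    denom = float((w * model) @ model)
    return float((w * model) @ data) / denom if denom > 0 else 0.0


def _series_sigma(series: KineticTrace) -> Optional[np.ndarray]:
    """Per-point uncertainties attached by an upstream fit, floored away from 0."""
    sig = series.meta.get("sigma")
    if sig is None:
        return None
    sig = np.asarray(sig, float)
    floor = max(1e-3 * float(np.abs(series.value).max()), 1e-12)
    return np.maximum(sig, floor)


def _series_r2(model: np.ndarray, data: np.ndarray) -> float:
    ss_res = float(np.sum((data - model) ** 2))
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


def fit_rate_constants(
    amplitude_series: Mapping[str, KineticTrace],
    scheme: int,
    k3_external: Optional[float] = None,
    joint_refine: bool = False,
) -> RateFitResult:
    """Staged estimation of the irradiation-scale rate constants.

    Scheme 1 staging mirrors the experimental order: k3 is supplied externally
    (from the free-FMN bleaching control) or fitted from a ``bleach_control``
    series; k1 comes from a single-exponential fit of the ``prot`` series; k2
    from least squares of the sequential-chain curves to the ``protstar`` and
    ``water`` series with k1 and k3 held fixed.  Per-pool proportionality
    constants (triplet extinction x detection efficiency) are profiled out as
    linear scale factors.  Scheme 2 replaces the k1/k2 stages with a linear
    depletion-slope fit of the ``prot`` series and reuses k3 for ``water``.
    """
    stages: Dict[str, dict] = {}

    # --- stage k3 -----------------------------------------------------------
    if k3_external is not None:
        if k3_external <= 0:
            raise InputError("k3_external must be positive")
        k3 = float(k3_external)
        k3_err = 0.0
        stages["k3"] = {"source": "external", "value": k3}
    elif "bleach_control" in amplitude_series:
        tr = amplitude_series["bleach_control"]
        f = fit_single_exponential(tr, model="decay", fix_baseline=0.0)
        k3 = 1.0 / f.tau
        k3_err = f.tau_stderr / f.tau**2
        stages["k3"] = {"source": "bleach_control", "tau_s": f.tau,
                        "tau_stderr": f.tau_stderr, "r2": f.r2}
    else:
        raise InputError(
            "k3 stage needs k3_external or a 'bleach_control' amplitude series"
        )

    if scheme == 1:
        for name in ("prot", "protstar", "water"):
            if name not in amplitude_series:
                raise InputError(f"Scheme 1 staged fit requires the '{name}' series")

        # --- stage k1: single-exponential decay of the intact-protein pool --
        prot = amplitude_series["prot"]
        f1 = fit_single_exponential(prot, model="decay", fix_baseline=0.0,
                                    robust=True, sigma=_series_sigma(prot))
        k1 = 1.0 / f1.tau
        stages["k1"] = {"series": "prot", "tau_s": f1.tau,
                        "tau_stderr": f1.tau_stderr, "r2": f1.r2}

        # --- stage k2: Bateman curves on protstar + water, k1 & k3 fixed ----
        star, water = amplitude_series["protstar"], amplitude_series["water"]
        star_sig, water_sig = _series_sigma(star), _series_sigma(water)

        def k2_residuals(logk2):
            k2 = float(np.exp(logk2[0]))
            rates = RateConstants(k1, k2, k3, check_scale=False)
            parts = []
            for series, pool, sig in ((star, "f_protstar", star_sig),
                                      (water, "f_water", water_sig)):
                traj = scheme1_populations(series.t, rates)
                model = getattr(traj, pool)
                c = _scale_through_origin(model, series.value, sig)
                resid = series.value - c * model
                parts.append(resid if sig is None else resid / sig)
            return np.concatenate(parts)

        if star_sig is None and water_sig is None:
            k2_scale = max(0.05 * float(np.abs(np.concatenate(
                [star.value, water.value])).max()), 1e-12)
        else:
            k2_scale = 2.0   # residuals are in sigma units
        sol = least_squares(k2_residuals, [np.log(k3)], bounds=(np.log(1e-7), np.log(1.0)),
                            method="trf", xtol=1e-14, ftol=1e-14,
                            loss="soft_l1", f_scale=k2_scale)
        if not sol.success:
            raise FitError(f"k2 stage did not converge: {sol.message}")
        k2 = float(np.exp(sol.x[0]))
        dof = max(star.t.size + water.t.size - 3, 1)
        s2 = 2.0 * sol.cost / dof
        JTJ = float((sol.jac.T @ sol.jac).item())
        k2_err = k2 * np.sqrt(s2 / JTJ) if JTJ > 0 else np.nan
        rates = RateConstants(k1, k2, k3, check_scale=False)
        traj = scheme1_populations(star.t, rates)
        stages["k2"] = {
            "series": ["protstar", "water"],
            "r2_protstar": _series_r2(
                _scale_through_origin(traj.f_protstar, star.value) * traj.f_protstar,
                star.value),
            "r2_water": _series_r2(
                _scale_through_origin(scheme1_populations(water.t, rates).f_water,
                                      water.value)
                * scheme1_populations(water.t, rates).f_water, water.value),
        }

        if joint_refine:
            def joint_res(logk):
                r = RateConstants(float(np.exp(logk[0])), float(np.exp(logk[1])), k3,
                                  check_scale=False)
                parts = []
                for series, pool in ((prot, "f_prot"), (star, "f_protstar"),
                                     (water, "f_water")):
                    model = getattr(scheme1_populations(series.t, r), pool)
                    c = _scale_through_origin(model, series.value)
                    parts.append(series.value - c * model)
                return np.concatenate(parts)

            joint_scale = max(0.05 * float(np.abs(np.concatenate(
                [prot.value, star.value, water.value])).max()), 1e-12)
            sol_j = least_squares(joint_res, [np.log(k1), np.log(k2)],
                                  method="trf", xtol=1e-14, ftol=1e-14,
                                  loss="soft_l1", f_scale=joint_scale)
            if sol_j.success:
                k1, k2 = float(np.exp(sol_j.x[0])), float(np.exp(sol_j.x[1]))
                stages["joint"] = {"cost": float(sol_j.cost)}

        k1_err = f1.tau_stderr / f1.tau**2
        return RateFitResult(
            rates=RateConstants(k1, k2, k3, check_scale=False),
            characteristic_times={"1/k1": 1.0 / k1, "1/k2": 1.0 / k2, "1/k3": 1.0 / k3},
            stderr={"1/k1": f1.tau_stderr, "1/k2": k2_err / k2**2, "1/k3": k3_err},
            stages=stages,
            scheme=1,
        )

    if scheme == 2:
        if "prot" not in amplitude_series:
            raise InputError("Scheme 2 staged fit requires the 'prot' series")
        prot = amplitude_series["prot"]
        # linear depletion: value = c * (1 - s t); fit by linear regression
        A = np.stack([np.ones_like(prot.t), prot.t], axis=1)
        coef, *_ = np.linalg.lstsq(A, prot.value, rcond=None)
        c0, c1 = coef
        if c0 <= 0:
            raise FitError("Scheme 2 prot series has non-positive intercept")
        slope = max(-c1 / c0, 0.0)
        resid = prot.value - A @ coef
        s2 = float(resid @ resid) / max(prot.t.size - 2, 1)
        cov = np.linalg.inv(A.T @ A) * s2
        # delta method for s = -c1/c0
        g = np.array([c1 / c0**2, -1.0 / c0])
        slope_err = float(np.sqrt(g @ cov @ g))
        stages["depletion_slope"] = {"series": "prot", "slope": slope,
                                     "stderr": slope_err, "r2": _series_r2(A @ coef, prot.value)}
        cfg = Scheme2Config(mode="empirical_linear", depletion_slope=slope)
        diag = {}
        if "water" in amplitude_series:
            water = amplitude_series["water"]
            model = scheme2_populations(water.t, RateConstants(1e-9, 1e-9, k3, check_scale=False),
                                        cfg).f_water
            c = _scale_through_origin(model, water.value)
            diag["r2_water"] = _series_r2(c * model, water.value)
        stages["water_check"] = diag
        return RateFitResult(
            rates=RateConstants(slope if slope > 0 else 1e-12, 1e12, k3, check_scale=False),
            characteristic_times={"1/k3": 1.0 / k3, "1/slope": np.inf if slope == 0 else 1.0 / slope},
            stderr={"1/k3": k3_err, "slope": slope_err},
            stages=stages,
            scheme=2,
            scheme2_cfg=cfg,
        )

    raise InputError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# spectral unmixing
# ---------------------------------------------------------------------------

@dataclass
class DecompositionResult:
    fraction_free: float
    fraction_bound: float
    scale: float                 # total basis weight (overall intensity factor)
    residual_rms: float
    ill_conditioned: bool = False

    def __post_init__(self):
        if self.fraction_free < 0 or self.fraction_bound < 0:
            raise InputError("fractions must be non-negative")


def decompose_emission_spectrum(
    observed: EmissionSpectrum,
    basis_free: EmissionSpectrum,
    basis_bound: EmissionSpectrum,
) -> DecompositionResult:
    """Unmix an emission spectrum into free and protein-bound FMN fractions.

    Non-negative least squares for the two basis weights; the reported
    fractions are the weights normalized by their sum.  Near-collinear bases
    (cosine similarity > 0.999) set the ``ill_conditioned`` flag.
    """
    lo = max(basis_free.wavelength[0], basis_bound.wavelength[0], observed.wavelength[0])
    hi = min(basis_free.wavelength[-1], basis_bound.wavelength[-1], observed.wavelength[-1])
    if lo >= hi:
        raise InputError("observed spectrum and bases have disjoint wavelength ranges")
    mask = (observed.wavelength >= lo) & (observed.wavelength <= hi)
    grid = observed.wavelength[mask]
    y = observed.intensity[mask]
    F = basis_free.resampled(grid).intensity
    B = basis_bound.resampled(grid).intensity
    cos = float(F @ B / (np.linalg.norm(F) * np.linalg.norm(B)))
    X = np.stack([F, B], axis=1)
    w, _ = nnls(X, y)
    total = float(w.sum())
    if total <= 0:
        raise FitError("both basis weights vanished; observed spectrum is not "
                       "explained by the bases")
    resid = y - X @ w
    return DecompositionResult(
        fraction_free=float(w[0] / total),
        fraction_bound=float(w[1] / total),
        scale=total,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        ill_conditioned=cos > 0.999,
    )


# ---------------------------------------------------------------------------
# single-exponential fits
# ---------------------------------------------------------------------------

@dataclass
class SingleExpFit:
    amplitude: float
    tau: float
    baseline: float
    amplitude_stderr: float
    tau_stderr: float
    baseline_stderr: float
    model: str
    r2: float
    degenerate: bool = False


def fit_single_exponential(
    trace: KineticTrace,
    model: Literal["decay", "recovery"] = "decay",
    fix_baseline: Optional[float] = None,
    robust: bool = False,
    sigma: Optional[np.ndarray] = None,
) -> SingleExpFit:
    """Least-squares fit of A e^{-t/tau} + c (decay) or c + A (1 - e^{-t/tau})
    (recovery).

    Used for the adduct dark-state recovery, the free-FMN bleaching series and
    the k1 stage of the rate fits.  A fitted amplitude indistinguishable from
    zero at 3 sigma sets the ``degenerate`` flag.  With ``robust=True`` a
    soft-L1 loss down-weights isolated outliers (amplitude series distilled
    from global fits occasionally contain an unresolved-pool point).
    """
    t = np.asarray(trace.t, float)
    y = np.asarray(trace.value, float)
    if t.size < 5:
        raise InputError("single-exponential fit requires at least 5 points")
    span = t[-1] - t[0]
    if model == "decay":
        c0 = float(y[-1]) if fix_baseline is None else fix_baseline
        a0 = float(y[0]) - c0
    elif model == "recovery":
        c0 = float(y[0]) if fix_baseline is None else fix_baseline
        a0 = float(y[-1]) - c0
    else:
        raise InputError(f"unknown model {model!r}")
    if a0 == 0:
        a0 = max(abs(y).max(), 1e-12)
    tau0 = span / 3.0

    if model == "decay":
        def func(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c
    else:
        def func(tt, a, tau, c):
            return c + a * (-np.expm1(-tt / tau))

    if fix_baseline is None:
        p0 = [a0, tau0, c0]
        lower = [-np.inf, span * 1e-6, -np.inf]
        upper = [np.inf, span * 1e3, np.inf]
        wrapped, n_par = func, 3
    else:
        p0 = [a0, tau0]
        lower = [-np.inf, span * 1e-6]
        upper = [np.inf, span * 1e3]
        n_par = 2

        def wrapped(tt, a, tau):
            return func(tt, a, tau, fix_baseline)

    kw = {}
    if sigma is not None:
        kw["sigma"] = np.asarray(sigma, float)
        kw["absolute_sigma"] = True
    if robust:
        kw["loss"] = "soft_l1"
        kw["f_scale"] = (2.0 if sigma is not None
                         else max(0.05 * float(np.abs(y).max()), 1e-12))
    try:
        popt, pcov = curve_fit(wrapped, t, y, p0=p0, bounds=(lower, upper),
                               maxfev=20000, **kw)
    except RuntimeError as exc:
        raise FitError(f"single-exponential fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if fix_baseline is None:
        a, tau, c = popt
        a_err, tau_err, c_err = perr
    else:
        a, tau = popt
        a_err, tau_err = perr
        c, c_err = fix_baseline, 0.0
    fitted = wrapped(t, *popt)
    return SingleExpFit(
        amplitude=float(a), tau=float(tau), baseline=float(c),
        amplitude_stderr=float(a_err), tau_stderr=float(tau_err),
        baseline_stderr=float(c_err),
        model=model,
        r2=_series_r2(fitted, y),
        degenerate=bool(np.isfinite(a_err) and abs(a) < 3.0 * a_err),
    )
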