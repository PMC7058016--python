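"""Constrained global fit of a synthetic flash-photolysis series.

Generates the 18-curve C450A transient-absorption experiment at the reference
lifetimes and recovers the shared intact-protein triplet lifetime with the
three-pool constraint set (shared / per-curve / fixed).
"""

import warnings

import numpy as np

import lovkin as lk
from lovkin.fitting import c450a_fit_spec

warnings.filterwarnings("ignore")

cfg = lk.default_config("C450A", seed=0)
curves = lk.generate_triplet_experiment(cfg)
print(f"generated {len(curves)} curves, {curves[0].t.size} points each, "
      f"noise sigma {cfg.noise.abs_sigma} OD")

res = lk.fit_triplet_decays_global(curves, c450a_fit_spec())
tau = res.shared_lifetime("prot")
err = res.shared_lifetime_stderr("prot")
print(f"shared intact-protein lifetime: {tau:.2f} +/- {err:.2f} us "
      "(generator truth 57 us)")
star = res.lifetimes["protstar"]
print(f"oxidized-protein lifetime drifts {star[0]:.1f} -> {star[-1]:.1f} us "
      "(truth 32 -> 23 us; per-curve, unrestricted)")
print("aqueous lifetime fixed at "
      f"{res.lifetimes['water'][0]} us (not fitted)")

amp = res.amplitudes
print("\ninitial-amplitude series (first/last curve):")
for pool in res.pools:
    print(f"  {pool:9s} {amp[pool].iloc[0]:.3f} -> {amp[pool].iloc[-1]:.3f}")
print("-> the intact-protein amplitude decays while the free-FMN amplitude grows:")
print("   irradiation releases the cofactor to the solvent")
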