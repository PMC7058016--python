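"""FMN pool kinetics under sustained blue-light irradiation.

Evaluates the Scheme 1 chain (C450A: intact protein -> oxidized protein ->
free in water -> bleached) at the reference rate constants, compares it with
the numerical oracle, and prints the released-FMN fraction at the end of a
75-minute run.
"""

import numpy as np

import lovkin as lk

rates = lk.REFERENCE_RATES      # 1/k1 = 9000 s, 1/k2 = 1000 s, 1/k3 = 3260 s
t = np.linspace(0.0, 4500.0, 10)

traj = lk.scheme1_populations(t, rates)
print("t_s     f_prot  f_prot*  f_water  f_bleached")
for i in range(len(t)):
    s = traj.at(i)
    print(f"{s.t:7.0f}  {s.f_prot:.4f}  {s.f_protstar:.4f}   {s.f_water:.4f}   {s.f_bleached:.4f}")

oracle = lk.populations_ode_oracle(1, rates, t_grid=t[1:])
gap = max(np.max(np.abs(getattr(traj, n)[1:] - getattr(oracle, n)))
          for n in ("f_prot", "f_protstar", "f_water", "f_bleached"))
print(f"\nmax |closed form - ODE oracle| = {gap:.2e}")

released = lk.release_fraction_at(4500.0, traj)
print(f"released fraction after 75 min (water + bleached): {released:.3f}")
print("-> about a third of the cofactor has left the C450A protein by the end of the run")
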