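# lovkin

Photokinetics of blue-light-driven FMN release from LOV domains.

Flavin mononucleotide (FMN) is one of the most efficient endogenous
singlet-oxygen (¹O₂) photosensitizers (Φ_Δ ≈ 0.57 in water), but inside a
LOV-domain protein pocket the surrounding residues quench its excited states
and throttle oxygen access, collapsing the yield roughly eight-fold.
Sustained blue-light irradiation oxidizes residues near the flavin, the
cofactor dissociates into the solvent, and ¹O₂ production climbs — a
mechanism of interest for genetically encoded photosensitizers that act as
targetable *carriers* of a releasable chromophore.

`lovkin` implements the quantitative analysis of this process for the
*Avena sativa* phototropin LOV2 domain (AsLOV2) and its adduct-incompetent
C450A variant, together with a synthetic-experiment generator that stands in
for the laser-laboratory raw data, so that every stage of the analysis is
testable end to end.

## The models

**Irradiation-scale pool kinetics (seconds–hours).** For C450A the cofactor
migrates through a sequential first-order chain (Scheme 1),

```
intact protein --k1--> oxidized protein --k2--> FMN in water --k3--> bleached FMN
```

whose populations are the classical Bateman solutions, e.g.
f_prot(t) = e^(−k1 t) and f_prot*(t) = k1/(k2−k1)·(e^(−k1 t) − e^(−k2 t)).
Reference conditions: 1/k1 = 9000 s, 1/k2 = 1000 s, 1/k3 = 3260 s.
For the wild type no oxidized-protein pool is resolved (release after
oxidation is effectively instantaneous) and the intact pool drains
quasi-linearly; both an empirical linear-depletion model and an explicit
autocatalytic ODE (free FMN accelerating its own release) are provided.

**Microsecond-scale observables.** Triplet transient absorption at 633 nm is
a constrained multi-exponential, Σᵢ Abs⁰ᵢ e^(−t/τ_T,i); the ¹O₂
phosphorescence near 1270 nm is the rise-and-decay profile

```
P(t) = Σ_i A_i · τ_Δ/(τ_Δ − τ_T,i) · (e^(−t/τ_Δ) − e^(−t/τ_T,i))
```

with one singlet-oxygen lifetime τ_Δ shared by all pools (¹O₂ spends its
lifetime in water wherever it was born).  Both are evaluated through
`expm1`-stable divided differences, so the τ_T = τ_Δ singularity is an
ordinary point.

**Inference.** Global fits with shared / per-curve / fixed lifetimes
(trust-region least squares over the lifetimes, exact non-negative
least-squares amplitudes per curve), band-pass background subtraction
(signal window minus the mean of two flanking windows), staged rate-constant
estimation (k3 from a free-FMN control, k1 from the intact-pool amplitude
decay, k2 from the chain curves), non-negative spectral unmixing of emission
spectra into free/bound FMN, and the slope-ratio quantum yield

```
Φ_prot = Φ_water · (slope_prot / slope_water) / r_475,   Φ_water = 0.57
```

where the slopes link phosphorescence amplitudes to pool populations and
r_475 is the bound/free absorbance ratio at the 475 nm excitation.

## Worked example

```python
import lovkin as lk
from lovkin.fitting import c450a_fit_spec

cfg = lk.default_config("C450A", seed=0)          # reference study conditions
curves = lk.generate_triplet_experiment(cfg)      # 18 synthetic decay curves
res = lk.fit_triplet_decays_global(curves, c450a_fit_spec())
print(res.shared_lifetime("prot"))
```

Running `python examples/rate_constants_and_yield.py` (the full chain on a
synthetic C450A run, seed 1) prints:

```
shared triplet lifetime: 57.1 us (truth 57)
1/k1 = 9096 s, 1/k2 = 931 s, 1/k3 = 3260 s (truth 9000 / 1000 / 3260)
singlet-oxygen lifetime per set: 2.54, 2.78, 2.78, 2.93, 2.93, 3.00 us (drifts up as the protein oxidizes)
protein-pool 1O2 quantum yield: 0.073 (aqueous reference 0.57, truth 0.07)
released FMN: kinetic model 0.322, spectral unmixing 0.250
```

The shared lifetime is the intact-protein ³FMN lifetime; the per-set τ_Δ
series shows the singlet-oxygen lifetime lengthening as the protein oxidizes;
the yield says an FMN buried in intact C450A converts absorbed photons to
¹O₂ about eight times less efficiently than free FMN; and the two release
estimates (kinetic model vs. fluorescence unmixing) agree that roughly a
quarter to a third of the cofactor has left the protein after 75 minutes.

The other scripts in `examples/` each exercise one capability (population
kinetics, the phosphorescence model, the global fit, unmixing + adduct
recovery).  A thin CLI mirrors the stages: `lovkin simulate`, `lovkin
fit-triplet`, `lovkin fit-phos`, `lovkin fit-rates`, `lovkin unmix`,
`lovkin yield`, `lovkin run`.

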