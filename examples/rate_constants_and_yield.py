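"""End-to-end pipeline: simulate, fit, and derive the singlet-oxygen yield.

Runs the complete synthetic C450A analysis (triplet global fit ->
phosphorescence global fit -> staged rate fits -> spectral unmixing -> yield
and release summary) and prints the headline numbers.
"""

import json
import logging
import tempfile
import warnings
from pathlib import Path

from lovkin.pipeline import run_pipeline

warnings.filterwarnings("ignore")
logging.basicConfig(level=logging.INFO, format="%(message)s")

with tempfile.TemporaryDirectory() as out:
    run_pipeline({"variant": "C450A", "simulate": True, "seed": 1}, out_dir=out)
    report = json.loads((Path(out) / "report.json").read_text())

tf = report["triplet_fit"]
print(f"\nshared triplet lifetime: {tf['tau_T_prot_us']:.1f} us (truth 57)")
ct = report["rate_fit"]["characteristic_times_s"]
print(f"1/k1 = {ct['1/k1']:.0f} s, 1/k2 = {ct['1/k2']:.0f} s, 1/k3 = {ct['1/k3']:.0f} s "
      "(truth 9000 / 1000 / 3260)")
td = report["phos_fit"]["tau_delta_us"]
print(f"singlet-oxygen lifetime per set: {', '.join(f'{x:.2f}' for x in td)} us "
      "(drifts up as the protein oxidizes)")
qy = report["quantum_yield"]
print(f"protein-pool 1O2 quantum yield: {qy['phi_prot']:.3f} "
      f"(aqueous reference {qy['phi_water_ref']}, truth 0.07)")
rel = report["release"]
print(f"released FMN: kinetic model {rel['per_method']['kinetic_model']:.3f}, "
      f"spectral unmixing {rel['per_method']['spectral_unmixing']:.3f}")
print("-> the buried cofactor is a ~8x poorer 1O2 producer than free FMN;")
print("   its release is what boosts singlet-oxygen production under irradiation")
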