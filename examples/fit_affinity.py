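"""Extract dissociation constants from a simulated two-ligand titration.

Simulates a 12-point titration of a compacting receptor at 20 uM against a
tight and a weak ligand, computes V_R curves against the averaged apo
reference, fits the two-state binding model globally, and estimates
sigma(log10 K_D) by single-point removal.
"""

import numpy as np

from vrscreen import SynthSpec, simulate_titration, uncertainty_jackknife
from vrscreen.pipeline import analyze_experiment

true_kd = {"tight": 2e-6, "weak": 60e-6}
spec = SynthSpec(true_K_D=true_kd, relative_noise=0.023, seed=42)
synth = simulate_titration(spec)

curves, fit = analyze_experiment(synth.experiment, metric="V_R")
sigmas, _ = uncertainty_jackknife(curves, receptor_concentration=20e-6)

print("ligand   true K_D    fitted K_D   sigma(log10)   |error| (decades)")
for name, kd in true_kd.items():
    lf = fit.ligands[name]
    err = abs(lf.log10_KD - np.log10(kd))
    print(f"{name:8s} {kd: .1e}   {lf.K_D: .2e}   {sigmas[name]:.3f}          {err:.2f}")
print("\nThe fitted values should sit within ~0.3 decades of truth for")
print("affinities within an order of magnitude of the 20 uM receptor.")
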