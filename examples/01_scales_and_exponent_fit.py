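"""Hydropathy scales and the power-law exponent that defines MZ-type scales.

Builds a noise-free segment-SASA table for one residue, fits
log SASA(L) = const - psi * log L over L in [9, 35], and recovers the
exponent exactly.
"""

from hydrolevel import SasaSegmentTable, fit_psi_exponent, load_scale

mz = load_scale("MZ")
kd = load_scale("KD")

print("MZ (fractal SASA exponents, x1000) — hydrophobic residues at the top:")
top = sorted(mz.values, key=mz.values.get, reverse=True)[:5]
bottom = sorted(mz.values, key=mz.values.get)[:3]
print("  most hydrophobic:", {aa: mz.values[aa] for aa in top})
print("  most hydrophilic:", {aa: mz.values[aa] for aa in bottom})
print("KD most hydrophobic:", max(kd.values, key=kd.values.get),
      kd.values["I"])

# a residue whose segment SASA decays as L^-0.197 (leucine's MZ exponent)
psi_true = mz.values["L"] / 1000.0
rows = tuple((L, 150.0 * L ** (-psi_true)) for L in range(3, 46, 2))
fit = fit_psi_exponent(SasaSegmentTable("L", rows), l_min=9, l_max=35)
print(f"\nfitted psi = {fit.psi:.6f} (true {psi_true}), "
      f"intercept = {fit.intercept:.4f}")
print("The fitted exponent is the residue's hydropathicity: faster SASA"
      " decay with segment length = more hydrophobic.")
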