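"""Size a native protein by Ferguson-plot analysis of gel mobilities.

Simulates noiseless native-PAGE runs at four gel concentrations for five
standards plus an AHb2-like unknown (17.871 kDa), extracts each protein's
retardation coefficient Kr, fits the log-log standard curve and inverts it
for the unknown's mass.
"""

import hemequil as hq

standards = [("a-lactalbumin", 14.2), ("carbonic anhydrase", 29.0),
             ("ovalbumin", 45.0), ("BSA monomer", 66.0), ("BSA dimer", 132.0)]
table = hq.simulate_gel_runs(standards, unknown_mw_kda=17.871,
                             percent_t_list=[8, 9, 10, 12], unknown_id="AHb2")
model, masses = hq.ferguson_mass_pipeline(table, dict(standards), ["AHb2"])

print(f"{'protein':>18} {'Kr':>8}")
for pid, kr in model.kr_by_protein.items():
    print(f"{pid:>18} {kr:>8.3f}")
print(f"\nstandard curve: log10 Kr = {model.curve_intercept:.3f} "
      f"+ {model.curve_slope:.3f} * log10 MW,  R^2 = {model.r_squared:.4f}")
print(f"estimated AHb2 mass = {masses['AHb2']:.2f} kDa (truth 17.871 kDa)")
# ~18 kDa confirms a monomer: a dimer would sieve like a ~36 kDa species.
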