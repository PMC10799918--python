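# quenchbind

Fluorescence-titration analysis of small-molecule binding to proteins,
built around the workflow used to characterise pesticide–serum-albumin
interactions: Stern–Volmer quenching, double-logarithmic binding-constant
estimation, van't Hoff thermodynamics with binding-force classification,
Förster resonance energy transfer (FRET) distance estimation,
synchronous-scan peak-shift analysis and site-probe competitive
displacement — plus a seeded forward simulator of titration experiments
with known ground truth.

It is intended for spectroscopists and computational chemists who have
steady-state emission/absorbance titrations (CSV + JSON metadata) and want
the full derived-parameter chain with explicit uncertainties, unit
bookkeeping and reproducible reports.

## The models

For a fluorophore (e.g. bovine serum albumin, BSA) titrated with a
quencher Q at concentration [Q]:

* **Quenching:** `F0/F = 1 + K_sv[Q] = 1 + k_q τ0 [Q]`. The temperature
  trend of K_sv, together with whether `k_q = K_sv/τ0` exceeds the
  diffusion-controlled limit (~2×10¹⁰ M⁻¹ s⁻¹), distinguishes static
  (ground-state complex) from dynamic (collisional) quenching.
* **Binding:** `log10((F0−F)/F) = log10 K_a + n log10[Q]` gives the
  binding constant K_a and site number n.
* **Thermodynamics:** `ln K_a = −ΔH/RT + ΔS/R`, `ΔG = ΔH − TΔS`; the
  (ΔH, ΔS) sign pattern identifies the dominant intermolecular force.
* **FRET:** `J = ∫Fελ⁴dλ/∫Fdλ`, `R0 = 0.211(κ²Φ_D η⁻⁴ J)^{1/6}`,
  `E = 1 − F/F0 = R0⁶/(R0⁶+r⁶)` locate the bound ligand at distance r
  from the protein fluorophore.
* **Displacement:** the fold-decrease of K_a in the presence of a
  site-specific probe (warfarin → Sudlow site I, ibuprofen → site II)
  identifies the binding pocket.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
from quenchbind import (SimulationConfig, simulate_titration,
                        stern_volmer_fit, vant_hoff, forster_radius,
                        donor_acceptor_distance)

# Stern-Volmer fit of a simulated titration (K_sv truth 1.92e4, 1% noise)
cfg = SimulationConfig(quenching_model="stern_volmer_linear",
                       K_sv_M=1.92e4, noise_rel=0.01, seed=42)
fit = stern_volmer_fit(simulate_titration(cfg))
print(f"K_sv = {fit.K_sv_M:.3e} M^-1 (r^2 = {fit.r_squared:.4f}), "
      f"k_q = {fit.k_q_M_s:.3e} M^-1 s^-1")

# van't Hoff analysis of measured binding constants
pf = vant_hoff({290.0: 2354.0, 300.0: 3425.0, 310.0: 3897.0})
print(f"dH = {pf.dH_kJ_mol:.2f} kJ/mol, dS = {pf.dS_J_mol_K:.2f} J/mol/K, "
      f"dG(310) = {pf.dG_kJ_mol_by_T[310.0]:.2f} kJ/mol, "
      f"force = {pf.force_label.value}")

# FRET geometry from an overlap integral and a single-point efficiency
print("R0 =", round(forster_radius(0.476, 0.15, 0.3139, 1.33e14), 2), "nm;",
      "r =", round(donor_acceptor_distance(0.077, 2.53), 2), "nm")
```

prints

```
K_sv = 1.921e+04 M^-1 (r^2 = 0.9989), k_q = 3.099e+12 M^-1 s^-1
dH = 18.93 kJ/mol, dS = 130.14 J/mol/K, dG(310) = -21.41 kJ/mol, force = hydrophobic
R0 = 2.53 nm; r = 3.83 nm
```

The quenching rate two orders of magnitude above the diffusion limit
marks the quenching as complex-driven; positive ΔH and ΔS with negative
ΔG mean spontaneous, hydrophobically driven binding; the 3.83 nm
donor–acceptor distance is short enough for efficient energy transfer.

## Command line

```sh
quenchbind simulate --out-dir sim --seed 3        # synthetic study + truth.json
quenchbind quench --series sim                    # Stern-Volmer fits per temperature
quenchbind bind --series sim                      # double-log binding fits
quenchbind thermo --ka-json ka.json               # van't Hoff from a T -> K_a map
quenchbind run --config analysis.json             # full pipeline -> report.json
```

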