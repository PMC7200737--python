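# gpcrdyn

Quantitative analysis of backbone ¹H/¹⁵N NMR dynamics of detergent-solubilized
G-protein-coupled receptors (GPCRs).

Large membrane-protein–detergent complexes tumble slowly (τc of tens of ns),
so their ¹⁵N resonances are broad and weak; receptor function is encoded in
conformational equilibria spanning microseconds to milliseconds that appear as
exchange broadening (R_ex), ligand-dependent chemical-shift trajectories and
resolved minor states. This package implements the quantitative machinery
needed to analyze such data end to end:

- **Theoretical ¹⁵N relaxation rates** for a backbone amide — R₁(N_z),
  in-phase R₂(N⁺), anti-phase R₂(N⁺H_z), selective R₁,sel(H_z), the
  dipole/CSA cross-correlation rate η and the TROSY rate
  R₂(N⁺H_β) = (R₂(N⁺) + R₂(N⁺H_z) + R₁,sel(H_z))/2 − η —
  on a Lipari–Szabo spectral density J(ω) = (2/5)S²τc/(1+(ωτc)²), plus
  numerical inversion of R₁ or η for τc.
- **Micelle hydrodynamics**: τc = 4πη_S r_H³/(3kT) of the
  protein–detergent complex from its SEC-MALS mass, component partial
  specific volumes, hydration shell and solvent viscosity.
- **2D time-domain line-shape fitting**: resonances synthesized as
  exponentially damped sinusoids, processed (apodization, one-time zero
  fill, FT) identically to the data, and least-squares fitted in the
  frequency domain; parameter errors from seeded Monte-Carlo refits of
  noise-perturbed replicas. 1D exponential decay fits and η extraction
  from in-phase/anti-phase intensity ratios.
- **Exchange analysis**: R_ex = R₂,obs − R₂,0, order-of-magnitude k_ex
  bands from CPMG quenching of R_ex (Luz–Meiboom), minor-state populations
  from intensity ratios and lifetime bounds from shift separations.
- **Two-parameter receptor description**: PCA of a ligands × observables
  table (chemical shifts + pK_D, efficacy, head-group substituent volume
  V_om) and prediction of all observables from any well-conditioned pair.
- **Amide H-bond geometry** on multi-model PDB ensembles: d(H_i···O_{i−3})
  vs d(H_i···O_{i−4}) distinguishing 3₁₀- from α-helical H-bonding, with
  broken bonds flagged at d_HO > 3.0 Å.
- **Synthetic-data generators** (seeded, with ground-truth files) for every
  input: 2D FIDs at a target signal-to-noise, relaxation decay series,
  rank-2 ligand tables with pharmacology-like groups, ideal α/3₁₀/extended
  backbones and jittered coordinate ensembles.

## Worked example

```python
import gpcrdyn as g

# tumbling time of a 101 kDa receptor-detergent complex
micelle = g.MicelleModel(
    mass=101.0,
    components=[("protein", 0.735, 0.36), ("DM", 0.815, 0.64)],
    hydration_thickness=3.2, viscosity=0.840, temperature=304.0)
print(f"Stokes-Einstein tau_c = {micelle.tau_c():.1f} ns")

# exchange-free rates for that tumbler and the Rex of a broadened residue
p = g.SpinParams(tau_c=38.0)
f14 = g.FieldConditions(b0=14.1)
print(f"R2(N+) at 14.1 T = {g.rate_R2_inphase(p, f14):.1f} s^-1")
rec = g.rex_apparent(60.0, p, f14, rate_type="inphase")
print(f"Rex(spin echo)   = {rec.Rex_app:.1f} s^-1")

# tau_c from the measured field-average R1
print(f"tau_c from R1    = {g.invert_tauc_from_R1(0.34, p, f14):.1f} ns")
```

prints

```
Stokes-Einstein tau_c = 35.3 ns
R2(N+) at 14.1 T = 45.9 s^-1
Rex(spin echo)   = 14.1 s^-1
tau_c from R1    = 36.7 ns
```

i.e. the 101-kDa micelle is predicted to tumble at ~35 ns, in agreement with
the ~37 ns obtained independently by inverting the measured R₁; a spin-echo
R₂ of 60 s⁻¹ then carries a ~14 s⁻¹ exchange contribution on top of the
45.9 s⁻¹ exchange-free rate — direct evidence of µs–ms conformational
motion.

The same functionality is exposed on the command line:

```bash
gpcrdyn rates --tauc 38 --field 14.1
gpcrdyn tauc --mass 101
gpcrdyn simulate-helix --kind three_ten --n-res 16 --out helix.pdb
gpcrdyn hbond --pdb helix.pdb --select A:6-12
```

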