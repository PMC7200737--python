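# Methods

## Relaxation model

Rates are computed for an isolated backbone ¹H–¹⁵N spin pair with an axially
symmetric ¹⁵N CSA tensor, using the Lipari–Szabo (model-free) spectral
density in the limit of a vanishing internal correlation time,

    J(ω) = (2/5) S² τc / (1 + (ω τc)²).

Prefactors follow the standard Abragam convention with the dipolar coupling
d = (μ0/4π) ħ γH γN / r³ and the CSA coupling c = |γN| B0 Δσ/√3; the
transverse cross-correlation rate is
η = (d·c / 2√3) P₂(cos θ) [4J(0) + 3J(ωN)], which is exactly the
normalization under which the two TROSY doublet relaxation contributions
cancel at the well-known optimum near 1 GHz ¹H frequency for
Δσ_N ≈ 170 ppm. Different published transcriptions of these expressions use
incompatible prefactor/J normalizations; the convention here is anchored by
the requirement that the in-phase R₂(N⁺) of a 38 ns tumbler evaluate to
46 s⁻¹ at 14.1 T and 61 s⁻¹ at 21.2 T (this package: 45.9 and 61.1 s⁻¹),
and that R₁ match the measured 0.34/0.20 s⁻¹ field averages at the same τc
(this package: 0.33/0.19 s⁻¹). γN is negative; magnitudes are used
throughout and η is reported positive below the magic angle, the sign under
which it narrows the TROSY line.

Default spin parameters: r_NH = 1.02 Å, r_HH = 2.05 Å (effective distance
lumping all protons adjacent to the amide proton in helical structure),
S² = 0.85, Δσ_N = 170 ppm, θ = 20°. A ¹H CSA of 15 ppm is carried on the
parameter object for completeness but enters none of the six implemented
rates. All of these can be overridden from a flat YAML config; effective
values are logged.

τc inversion brackets the root on [5, 200] ns — the slow-tumbling branch on
which R₁ is strictly decreasing and η strictly increasing, so the root is
unique — and solves with Brent's method to 0.01 ns. Rates outside the
achievable interval raise an error naming that interval.

Out of scope by design: per-residue model-free fitting (τe, R_ex as free
parameters), anisotropic diffusion, nuclei other than backbone ¹⁵N/¹H.

## Hydrodynamics

τc of the protein–detergent complex is the Stokes–Einstein–Debye time
τc = 4π η_S r_H³/(3kT) of a sphere of hydrated radius r_H = r_NH + r_W,
where r_NH is the radius of the sphere holding the molecular volume
M·v̄/N_A and v̄ is the mass-fraction-weighted mean of the component partial
specific volumes. Defaults: hydration shell r_W = 3.2 Å, viscosity
0.840 cP, 304 K. The sphere assumption is hard-coded; no shape factors.

## Line-shape fitting

2D resonances are modeled in the time domain as exponentially damped complex
sinusoids A·exp(i2πν₁t₁ − R₂,₁t₁)·exp(i2πν₂t₂ − R₂,₂t₂) on the acquisition
grid (default 120 × 1024 complex points, 24 ms ¹⁵N / 42 ms ¹H acquisition;
the 80 × 1024, 16 ms variant is provided). Model and data pass through the
*same* deterministic processing — apodization (default squared-cosine bell;
configurable, including none), one-time zero fill, 2D FFT — so window and
truncation bias cancel and the fit is unbiased on noise-free input for any
window (verified by test). The least-squares residual is the complex
difference over a fit box of ±5 natural linewidths around each initial peak
(configurable); optimization uses trust-region least squares with numeric
Jacobian, decay constants bounded to [0, 1000] s⁻¹, and largest-amplitude-
first output ordering. Non-convergence and active bounds are flagged on the
result, never silent.

Monte-Carlo errors: the fitted model plus fresh complex Gaussian noise of
the experimental time-domain rms is refit n times (default 20, replica k
seeded as seed+k); the per-parameter SD over replicas is the reported error.
At the working signal-to-noise of 10 this 20-replica SD agrees with the
empirical scatter of fully independent refits within a factor of 1.5
(acceptance test).

Signal-to-noise convention: SNR of a synthetic dataset is the tallest peak
height of the processed spectrum divided by twice the rms baseline noise of
its real part — the convention of common spectrometer software (Bruker
SINO), which is what a quoted working S/N of ~10 for the analyzed peaks
refers to. The generator calibrates the time-domain noise rms empirically
against a unit-noise probe processed with the same scheme.

1D decays are fitted as A·exp(−Rt): the two-point closed form
R = ln(A₁/A₂)/(t₂−t₁) when only two delays exist (the R₁ grids 20/2004 ms
and 20/3004 ms), otherwise a log-domain linear fit (exact on noise-free
data); errors again by Monte-Carlo perturbation. η is extracted from the
anti-phase/in-phase intensity ratio after a cross-relaxation delay T
(12 ms in the measurements) through the standard forward model
ratio = tanh(η·T), an implementation choice documented here because the
cited experiment does not restate it.

Not modeled: phase/baseline correction, solvent artefacts, B0-inhomogeneity
broadening (<1 s⁻¹ in the measurements), vendor data formats, assignment.

## Exchange analysis

R_ex = R₂,observed − R₂,0 with the exchange-free reference chosen by rate
type (TROSY for line-shape-derived rates, in-phase for spin-echo rates).
Negative R_ex is retained and flagged when below −2 Monte-Carlo SDs.

CPMG quenching: with ν_CP defined as the inverse 180°-pulse spacing (0.5 ms
spacing → ν_CP = 2 kHz), the fast-exchange Luz–Meiboom profile
R_ex(ν_CP)/R_ex(0) = (2ν_CP/k_ex)·tanh(k_ex/2ν_CP) is inverted for the
observed quench fraction and the result reported as the decade bracket
containing it — an order-of-magnitude band, never a point estimate,
matching the qualitative use this model supports (a 50 % quench at 2 kHz
lands in [10³, 10⁴] s⁻¹). Optional rate uncertainties widen the band. No
quench flags the fast regime (unbounded above); full quench the slow one.

Slow exchange: a resolved resonance pair separated by Δν Hz requires
exchange slower than the coalescence rate k = πΔν/√2, i.e. a state lifetime
above 1/k. For a 7 ppm ¹⁵N separation at 21.2 T this bound is ~0.7 ms; it
is a *minimum* lifetime from the resolved-lines criterion and is not claimed
to reproduce bounds derived by other (unstated) criteria. Minor-state
population is the intensity ratio p = I_minor/(I_minor + I_major).

Pearson correlations use the standard estimator; the permutation p-value is
exhaustive for n ≤ 7 (720 orderings at n = 6) and seeded Monte-Carlo above.

## Two-parameter receptor description

The ligands × observables table (in the motivating application 6 ligand
complexes × 31 variables = 14 ¹H/¹⁵N shift pairs + pK_D + Gs efficacy +
V_om, 186 entries) is column-centered and z-scored — the columns carry ppm,
%, Å³ and pK units, so unit-variance scaling is the defensible default; a
center-only mode is exposed for sensitivity checks since the choice can move
the two-component variance share by a few points. The SVD retains at most
n−1 components for n rows, with a deterministic sign convention (largest
|loading| per component positive).

Two-observable prediction solves the 2×2 standardized-loading system of the
chosen pair for the two scores, reconstructs all columns and
un-standardizes with the training statistics. Near-singular pairs
(condition number > 10⁶) are rejected with advice to choose another pair;
score values outside the training range are allowed but logged as
extrapolations. On noiseless rank-2 tables this reconstruction is exact
(machine precision), which is the testable content of the claim that two
linearly independent observations determine all others. Score-plane
clustering by pharmacology is emitted as coordinates plus labels only — no
algorithmic clustering claim is made.

V_om is an input descriptor; computing it from ligand structures is out of
scope, as are missing-data PCA variants.

## H-bond geometry

For residue i the distances d(H_i···O_{i−3}) and d(H_i···O_{i−4}) identify
3₁₀- versus α-helical H-bonding; a bond is broken when the mean distance
exceeds 3.0 Å (strict inequality, configurable threshold), and the
per-residue broken flag tests the *closer* of the two acceptors. Acceptors
are located by residue sequence number, so chain gaps give missing values,
never distances to the wrong residue. Ensemble statistics (mean, population
SD over models) are computed separately per chain; single-model input gives
SD 0.

Missing amide protons are placed 1.02 Å from N (the r_NH of the relaxation
model), in the C(i−1)–N–CA plane, anti to the preceding C=O direction;
native protons are kept when present, so refined H positions are used if a
file provides them. PDB reading/writing is backed by gemmi, with alternate
locations reduced to a single conformer and multi-MODEL files mapped to
ensembles.

## Synthetic data

Generators emulate: 2D FIDs of damped resonances with complex Gaussian
noise at a target SNR (SINO convention, default 10); exponential decay
series on the measurement delay grids; rank-2 ligand tables
X = scores·loadingsᵀ + noise whose latent scores form three
pharmacology-like groups (centers (2.5, 1), (−2, 1.5), (0, −2.5), within-
group SD 0.3 — chosen once to give clearly separated clusters at realistic
score magnitudes); ideal backbones from standard dihedrals (α: −57/−47,
3₁₀: −49/−26, extended: 180/180) and standard covalent geometry; and
coordinate ensembles as Gaussian-jittered copies of a base model. Every
generator is driven by one integer seed and returns a machine-readable
truth record; identical seeds give identical artifacts.

What the generators do *not* emulate — and hence what passing recovery
tests do not certify on real data: spin physics during pulses and
relaxation-time evolution of multiplets, non-Gaussian/correlated noise,
baseline and phase distortions, peak-shape deviations from Lorentzian
(conformational exchange line shapes are fitted as *apparent* single
Lorentzians, exactly as the analysis intends), non-rank-2 structure in real
ligand tables, and real ensemble-refinement coordinate distributions.

## Numerical choices and problem sizes

- τc root finding: Brent on [5, 200] ns, xtol 0.01 ns.
- Peak fitting: scipy trust-region reflective least squares, xtol/ftol
  1e-10, max 2000 function evaluations; residuals scaled by the box
  maximum for conditioning.
- Statistical tests run at sizes chosen to exercise the estimators while
  keeping the default suite quick: 50 seeded spectra for the R₂ recovery
  study on the full 120 × 1024 grid, 30 independent refits for the
  empirical-vs-MC SD comparison (MC SD averaged over two datasets), unit
  tests on a 48 × 256 grid.
- Degenerate inputs fail loudly: fraction sums, zero-variance PCA columns
  (named), singular predictor pairs, out-of-bracket rates (achievable
  interval reported), empty noise regions, topology mismatches across
  ensemble models.

## Known limitations

- The Luz–Meiboom inversion assumes fast exchange; the returned k_ex band
  is an order-of-magnitude statement only.
- The coalescence-based lifetime bound is one of several possible criteria;
  other conventions shift the bound by small factors.
- The exchange-free R₂ reference assumes the global τc and uniform S²;
  residue-specific fast dynamics would bias R_ex slightly.
- H placement is idealized when no protons are present; refined proton
  positions, when available, take precedence.
- PCA on n = 6 rows estimates at most 5 components; variance shares at this
  n carry substantial sampling noise.
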