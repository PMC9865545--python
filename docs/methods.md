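# Methods

This note documents the models implemented in `collamat`, the defaults they
ship with, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Titration model of atelocollagen

One collagen type I triple helix (atelocollagen, telopeptides removed) is
treated as a set of independent ionizable group classes: Asp (90), Glu
(150), three C-terminal proline carboxyls, His (14), Arg (162), Lys (89)
and three N-terminal glycine amines. Each class is a two-state
Henderson–Hasselbalch equilibrium; the expected number of negative charges
is Σ N_i·θ_i over the carboxyl classes and of positive charges
Σ N_j·(1−θ_j) over the amine/guanidinium classes, with θ the deprotonated
fraction. The net charge is reported with the sign convention "positive
below the isoelectric point". Site–site interactions, charge regulation
against the Donnan potential, and hydroxyl ionization (Ser/Thr/Tyr) are
deliberately outside the model.

**pKa corrections.** Reference pKa values are tabulated at 25 °C and zero
ionic strength and corrected in two steps:

* temperature, van't Hoff: ΔpKa = −(ΔH_ion/R ln10)(1/298.15 − 1/T), with
  standard ionization enthalpies (kJ/mol): carboxyls 1.0, His 29.5,
  Arg 51.9, Lys 53.0, N-terminal amine 45.0;
* ionic strength, Davies: ΔpKa = −A(T)·f(I)·(1 − Z) with
  f(I) = √I/(1+√I) − 0.3I, A(T) the Debye–Hückel slope, and Z = −1 for
  –COOH/–COO⁻ pairs, +1 for –NH₃⁺/–NH₂ pairs. This is the standard
  activity-coefficient result (−2Af shift for neutral-acid pairs, no shift
  for cationic-acid pairs) written so the sign follows Z.

**Calibration.** Protein-environment pKa values are not transferable from
free amino acids, so the shipped reference table was calibrated once: Asp
(4.10) and His (6.23) were solved for so that, after correction to 37 °C
and I = 0.180, the 24%-deamidated composition carries |N_net| = 17.6 at
pH 7.40 and an isoelectric point of 5.50; the remaining entries (Glu 4.25,
C-terminal 3.60, Arg 12.10, Lys 10.67, N-terminal 9.00) are standard
textbook values. All entries stay within literature ranges and the whole
table is user-overridable (CSV fixture / constructor argument). The
non-deamidated composition then has its isoelectric point at 9.3, well
above 8.

**Deamidation.** A degree d converts round(d·46) Asn to Asp and
round(d·75) Gln to Glu (round-half-up, because whole residues convert).
The pool sizes 46/75 are the smallest integers for which d = 0.24 yields
the +11/+18 supplements that shift the isoelectric point to 5.5.

**Isoelectric point.** Root of the strictly decreasing net-charge curve on
pH ∈ [1, 13] by bracketed root finding to 10⁻⁴ pH units; a missing sign
change raises rather than extrapolates.

## Swelling, Donnan equilibrium and crosslink density

**Buffer.** PBS (10 mM phosphate, 154 mM NaCl) with HPO₄²⁻:H₂PO₄⁻ = 1.6 at
pH 7.40. The phosphate contribution to ionic strength counts sodium as
2×total phosphate (a Na₂HPO₄-type stock) with a chloride makeweight closing
the charge balance, giving I_phosphate = 0.026 and I_total = 0.180; this
sodium convention is reverse-engineered from the reported contribution and
is documented and overridable. The equivalent-NaCl picture gives
c_e = I/2 = 0.090 M for the Donnan calculation. Buffer density at the
working temperature scales the measured 20 °C value by the ratio of
handbook water densities (1.098 → 1.093 g·cm⁻³ at 37 °C).

**Capillary correction.** Porous sponges mechanically hold buffer in
macro-pores; the pore volume per gram (ethanol pycnometry) times the buffer
density is subtracted from the raw gravimetric uptake, floored at 1 g/g
(a sample cannot weigh less than dry). For the collagen-only preset the raw
maximum ≈ 111.3 g/g corrects to a 6.80 g/g network plateau.

**Volume fractions.** Released limiting case (both antimicrobials out of
the network): Q_v,coll = 1 + (Q_w − 1)ρ_coll/ρ_buffer and ν₂eq = 1/Q_v,coll
with ρ_coll = 1.195 g·cm⁻³. Loaded limiting case: the matrix-referenced
ratio uses the pycnometric ρ_matrix; the collagen-referenced ratio divides
total swollen volume by collagen dry volume from the composition mass
fractions. No volume-additive convention reproduces the published
loaded-case collagen ratios better than ~2%, so the printed ν₂eq is taken
as authoritative for that case and the residual is documented rather than
forced.

**Donnan imbalance.** Δc = √(c_p² + 4c_e²) − 2c_e for a 1:1 mobile
electrolyte with equal mean ionic activity coefficients inside and outside
the gel; c_p = |N_net|·ν₂eq·ρ_coll/M with M = 3×10⁵ g·mol⁻¹. Concentrations
are carried in mol·cm⁻³ internally (mol·L⁻¹ ×10⁻³ at interfaces).

**Crosslink density.** Numerator V₁Δc − [ln(1−ν) + ν + χ₁ν²]; denominator
V₁(ν^⅓ − ν/2) (Flory, bulk-crosslinked) or V₁ν₂₀[(ν/ν₂₀)^⅓ − ν/2ν₂₀]
(Bray–Merrill/Ofner–Bubnis, solution-crosslinked), the latter reducing
exactly to the former at ν₂₀ = 1. Defaults: χ₁ = 0.49 (gelatin–water at
high humidity), ν₂₀ = 0.20 (moisture/collagen content of fresh hide),
V₁ = 18.07 cm³·mol⁻¹ (water near 37 °C; this value is verified by
reproducing the published crosslink densities and is overridable). A
non-positive denominator (ν₂eq too large against ν₂₀) raises with a
diagnostic instead of returning a sign-flipped density.

## Release kinetics

**Forward models** for a cylinder of radius a with sealed end faces
(radial transport only), x = (D/a²)t:

* Fickian: M_t/M_∞ = (4/√π)√x − x − x^{3/2}/(3√π), the small-time
  expansion of the radial diffusion equation, valid to ~60% release. The
  test suite checks it against an independent Crank–Nicolson
  finite-difference solution of the PDE (agreement ≤ 1% below 60%).
* Case II: M_t/M_∞ = 2x − x², the cylinder (N = 2) member of the general
  relaxation-front family 1 − (1 − x)^N; x > 1 saturates at 1 with a
  warning.

Analyte defaults D/a² = 1/1440 min⁻¹ (TA, 24 h to equilibrium) and
1/4320 min⁻¹ (CHDG, 72 h), overridable per series.

**Power-law fits.** M_t/M_∞ = k·tⁿ by nonlinear least squares on
untransformed fractions (a log–log fit would overweight early points and
bias n), initial guesses k = f₁/√t₁, n = 0.5, standard errors from the
covariance of the fit. The reference constants are produced by fitting the
exact forward models on a uniform 1-min grid from t = 1 to the 60%
crossing; the original sampling grid behind the published constants is
unstated, and the 1-min grid reproduces them within their printed standard
errors (k = 6.62×10⁻² vs 6.569±0.087×10⁻², n = 0.4480 vs 0.4497±0.0030
Fickian; k = 2.34×10⁻³, n = 0.88713 Case II, R² = 0.99938). Fitting is
restricted to the first 60% of release by default (`window="first60"`),
where both forward models are valid.

**Decomposition.** Observed release (truncated to ≤ 60%) is modeled as
a·k_F·t^n_F + b·k_II·t^n_II with a, b ≥ 0 by non-negative least squares; no
sum constraint is imposed and the Case II share is 100·b/(a+b). A
time-integrated share estimator would also be defensible; the weight-ratio
form is the default because the weights are what the model fits.

**Classification.** Cylinder thresholds: n ≤ 0.45 Fickian (boundary
inclusive), 0.89 ± 0.01 Case II (the tolerance covers the reference
exponent 0.88703), between them anomalous, above super-Case II; slab
thresholds 0.5/1.0, sphere 0.43/0.85.

## Two-wavelength UV-VIS quantification

TA is monitored at 325 nm, CHDG at 260 nm; both absorb at both wavelengths,
so absorbances are the additive Beer–Lambert superposition. The
ratio-matrix algorithm tables the extinction-corrected ratio
(A₃₂₅/A₂₆₀)·(ε_CHDG,260/ε_TA,325) over a geometric grid of candidate
compositions (25 points per analyte over two decades — ratio resolution
scales multiplicatively), matches an observed reading to the nearest cell
(ties break toward lower TA, the conservative release estimate), and then
converts absorbance to concentration with an ordinary least-squares
calibration line at the matched composition ratio. The direct 2×2 linear
solve of the extinction system is implemented alongside as the algebraic
cross-check; noise propagates through the inversion with an amplification
set by the conditioning of the extinction matrix (< 2× for the shipped
coefficients).

The shipped extinction coefficients are synthetic placeholders (measured
values are unpublished), qualitatively faithful: TA absorbs at both
wavelengths, CHDG is dominated by 260 nm. Every algorithmic guarantee
tested is relative or round-trip and independent of the specific values.
Negative absorbances from blank subtraction are clipped to zero and
flagged. Release fractions are c_t·V/load, clipped to [0, 1] with a
warning above 1.

## Synthetic-data generator

Pure functions of (parameters, seed); no global random state. Noise is
multiplicative Gaussian truncated at ±3σ with RSD defaults 0.10 (release,
spectra) and 0.15 (swelling) — the only noise descriptors available for
the original measurements. Release curves are convex combinations of the
two forward models, monotonized by cumulative maximum after noise
injection (fractional release is physically non-decreasing) and clipped to
[0, 1]. Swelling series are a saturating exponential rise to q_eq (default
rate constant 0.05 min⁻¹, plateau within ~100 min) plus a constant
capillary term, sampled every 5 min for the first 30 min and every 15 min
thereafter. Spectrum readings are the Beer–Lambert forward model of two
ground-truth release curves sharing a time grid.

Matrix presets carry Fickian/Case-II weight pairs per analyte chosen so the
noiseless 660-min release fractions land in the observed windows (0.7–0.9
TA, 0.4–0.6 CHDG) with Case II shares of 63–76%; the exact per-matrix
shares of the original study are unpublished and these presets are loose
interpretations, not measurements.

**What the generator does not emulate:** solubilization kinetics of the
HTAB micellar carrier, TA–CHDG complexation, matrix erosion and
disintegration (the collagen-only sponge physically falls apart after
~2 h), turbidity/scattering in the spectra, and replicate-to-replicate
correlations. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to these real
phenomena.

## Problem sizes and determinism

The deterministic chains (charge, swelling, reference fits) run in
milliseconds to seconds. Stochastic validation uses 20–30 seeds for
recovery loops and 100–200 draws for round-trip bounds; the PDE oracle uses
a 400-point radial grid with Crank–Nicolson stepping. All stochastic tests
are seeded and derandomised.

## Known limitations

* The charge model's calibrated pKa table is one consistent solution, not a
  unique one; other tables within literature ranges can satisfy the same
  anchors.
* The loaded-case collagen-referenced volume ratio is convention-dependent
  (~2% residual against published values).
* The Fickian expansion is meaningless beyond ~60% release; fits on full
  windows are provided only to demonstrate the induced downward bias in n.
* The phosphate sodium-counting convention is reverse-engineered; use a
  custom `BufferSpec` for media with a different sodium inventory.
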