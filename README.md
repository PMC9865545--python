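# collamat

Physico-chemical characterization of antimicrobial-loaded collagen
matrices — the computations behind a release study of tannic acid (TA) and
chlorhexidine digluconate (CHDG) from porous atelocollagen sponges into a
PBS–HTAB medium (pH 7.40, 37 °C).

The package is a library of four analysis stages plus a synthetic-data
generator, aimed at researchers working on drug release from swellable
biopolymer matrices:

1. **Charge model** (`collamat.charge`) — the expected net charge of an
   atelocollagen molecule as a function of pH from per-residue
   Henderson–Hasselbalch equilibria,

   N_net = Σ_j N_j/(1+10^(pH−pKa_j)) − Σ_i N_i·10^(pH−pKa_i)/(1+10^(pH−pKa_i)),

   with pKa values corrected to temperature (van't Hoff) and ionic strength
   (Davies), Asn/Gln deamidation, the isoelectric point, and the
   fixed-charge concentration c_p = |N_net|·ν₂eq·ρ_coll/M of the swollen
   network.
2. **Swelling / crosslink density** (`collamat.swelling`) — capillary
   correction of gravimetric uptake, volume swelling ratios and polymer
   volume fraction ν₂eq, the Donnan mobile-ion imbalance
   Δc = √(c_p² + 4c_e²) − 2c_e, and the crosslink density

   DC = { V₁Δc − [ln(1−ν₂eq) + ν₂eq + χ₁ν₂eq²] } / { V₁ν₂₀[(ν₂eq/ν₂₀)^⅓ − ν₂eq/2ν₂₀] }

   (Bray–Merrill/Ofner–Bubnis; the Flory bulk-crosslinked form is the
   ν₂₀ = 1 special case).
3. **Release kinetics** (`collamat.kinetics`) — Fickian
   (small-time cylinder expansion) and Case II (relaxation front, 2x − x²)
   forward models, Korsmeyer–Peppas power-law fits M_t/M_∞ = k·tⁿ on the
   first 60% of release, non-negative least-squares decomposition of
   observed curves into Fickian/Case-II weights, and mechanism
   classification by the cylinder thresholds n = 0.45 / 0.89.
4. **Spectra** (`collamat.spectra`) — two-wavelength (325/260 nm)
   Beer–Lambert quantification of TA and CHDG via the ratio-matrix
   algorithm, calibration lines, and release-fraction accounting.

`collamat.synthetic` generates seeded synthetic uptake, release and
absorbance series with the noise structure of the original measurements
(multiplicative Gaussian, RSD ≤ 10–15%), so every stage can be exercised
and validated without laboratory data.

## Worked example

```sh
python examples/crosslink_table.py
```

```text
                      system   q_w  nu2eq    cp_e8  delta_c_e7   dc_e5  verified
                    Collagen 6.800  0.136  954.967       2.531  57.941      True
             Collagen-TA(5%) 5.660  0.164 1150.256       3.672 102.949      True
            Collagen-TA(10%) 4.300  0.217 1521.425       6.418 260.219      True
            Collagen-TA(15%) 4.110  0.227 1593.251       7.037 306.081      True
 Collagen-TA(5%)-CHDG(9.09%) 4.060  0.230 1613.293       7.215 320.023      True
Collagen-TA(10%)-CHDG(9.09%) 4.020  0.232 1629.694       7.362 331.826      True
Collagen-TA(15%)-CHDG(9.09%) 4.160  0.224 1573.700       6.866 292.977      True
```

Each row converts an equilibrium buffer uptake `q_w` (g solvent per g dry
matrix) into the polymer volume fraction `nu2eq`, the fixed-charge
concentration `cp_e8` (×10⁻⁸ mol·cm⁻³), the Donnan mobile-ion difference
`delta_c_e7` (×10⁻⁷ mol·cm⁻³) and the crosslink density `dc_e5`
(×10⁻⁵ mol·cm⁻³). The collagen-only sponge is essentially uncrosslinked
(DC ≈ 58×10⁻⁵); loading with tannic acid crosslinks the network and drives
DC past 300×10⁻⁵ as swelling drops. `verified` flags agreement with the
fixture's reference column within 1.5%.

```sh
python examples/release_kinetics.py
```

```text
Fickian reference:  k = 6.621e-2, n = 0.4480
Case II reference:  k = 2.34e-3, n = 0.88713

synthetic 30/70 mixture, 5% noise:
  fitted exponent n = 0.634 -> anomalous
  recovered Case II share = 69% (truth 70%)
```

The two reference fits recover the canonical cylinder exponents (~0.45
Fickian, ~0.89 Case II); a noisy synthetic mixture is classified as
anomalous transport and its relaxational share is recovered to within one
point.

The other examples cover the charge model (`charge_titration.py`: net
charge −17.6 at pH 7.40, IEP 5.50 after 24% deamidation), UV-VIS
quantification (`spectra_quantification.py`) and the end-to-end synthetic
pipeline (`synthetic_pipeline.py`).

A thin CLI mirrors the library: `collamat charge`, `collamat crosslink`,
`collamat kinetics`, `collamat quantify`, `collamat simulate`,
`collamat buffer` (see `collamat --help`).

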