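"""Release-kinetics analysis: power-law fits and mechanism decomposition.

Fits the Korsmeyer-Peppas power law to the exact Fickian and Case II
forward models for a cylinder (reference constants), then generates a noisy
synthetic 30/70 Fickian/Case-II release curve and recovers its mechanism
split.
"""

import numpy as np

from collamat.kinetics import (
    ANALYTE_D_OVER_A2,
    DecompositionWeights,
    ReferenceCurve,
    Regime,
    classify_mechanism,
    decompose_release,
    fit_power_law,
    reference_fit,
)
from collamat.synthetic import GeneratorConfig, gen_release_series

d = ANALYTE_D_OVER_A2["TA"]  # 1/1440 min^-1: tannic acid equilibrates in 24 h
fick = reference_fit(ReferenceCurve(d, Regime.FICKIAN))
case2 = reference_fit(ReferenceCurve(d, Regime.CASE2))
print(f"Fickian reference:  k = {fick.k * 1e2:.3f}e-2, n = {fick.n:.4f}")
print(f"Case II reference:  k = {case2.k * 1e3:.2f}e-3, n = {case2.n:.5f}")

truth = DecompositionWeights(0.3, 0.7)
series, _ = gen_release_series(
    truth, d, GeneratorConfig(seed=42, noise_rsd_release=0.05),
    time=np.arange(5.0, 660.0, 5.0), analyte="TA",
)
fit = fit_power_law(series, window="first60")
w = decompose_release(series, fick, case2)
print(f"\nsynthetic 30/70 mixture, 5% noise:")
print(f"  fitted exponent n = {fit.n:.3f} -> {classify_mechanism(fit.n).value}")
print(f"  recovered Case II share = {w.pct_case2:.0f}% (truth 70%)")

# n between 0.45 and 0.89 marks anomalous transport for a cylinder; the
# non-negative least-squares split quantifies how much of the release is
# carried by polymer-network relaxation (Case II) vs ordinary diffusion.
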