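"""Two-wavelength UV-VIS quantification of tannic acid (TA) and
chlorhexidine digluconate (CHDG) released into a PBS-HTAB medium.

TA is monitored at ~325 nm and CHDG at ~260 nm.  Because both analytes
absorb at both wavelengths, a single reading (A₃₂₅, A₂₆₀) is resolved by a
ratio-matrix algorithm: a grid of candidate TA/CHDG compositions is tabled
with its expected extinction-corrected absorbance ratio, the observed
corrected ratio is matched to the nearest cell, and a Beer–Lambert
calibration line at that fixed composition ratio converts absorbance to
concentration.  A direct two-wavelength linear solve of the Beer–Lambert
system is also provided as the algebraic cross-check.

The shipped extinction coefficients are synthetic placeholders (the measured
values are not published); they are qualitatively faithful — TA absorbs at
both wavelengths, CHDG is dominated by 260 nm — and every algorithm here is
ratio/round-trip based, so its behaviour does not depend on the specific
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExtinctionSet",
    "RatioMatrix",
    "SpectrumReading",
    "CalibrationLine",
    "DEFAULT_EXTINCTIONS",
    "predict_reading",
    "build_ratio_matrix",
    "match_composition",
    "calibrate_and_quantify",
    "solve_two_wavelength",
    "fraction_released",
]


@dataclass(frozen=True)
class ExtinctionSet:
    """Molar extinction coefficients (L·mol⁻¹·cm⁻¹) at 325 and 260 nm."""

    eps_ta_325: float
    eps_ta_260: float
    eps_chdg_325: float
    eps_chdg_260: float
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        if min(self.eps_ta_325, self.eps_ta_260, self.eps_chdg_325, self.eps_chdg_260) < 0:
            raise ValueError("extinction coefficients must be non-negative")
        if self.eps_ta_325 <= 0 or self.eps_chdg_260 <= 0:
            raise ValueError("eps_TA,325 and eps_CHDG,260 must be positive")

    def matrix(self) -> np.ndarray:
        """2x2 Beer-Lambert matrix mapping (c_TA, c_CHDG) -> (A325, A260)."""
        return self.path_length * np.array(
            [[self.eps_ta_325, self.eps_chdg_325],
             [self.eps_ta_260, self.eps_chdg_260]]
        )


# Synthetic placeholder coefficients (see module docstring).
DEFAULT_EXTINCTIONS = ExtinctionSet(
    eps_ta_325=22000.0,
    eps_ta_260=9000.0,
    eps_chdg_325=800.0,
    eps_chdg_260=28000.0,
)


@dataclass(frozen=True)
class SpectrumReading:
    """Background-referenced absorbances at the two working wavelengths.

    Small negative values from blank subtraction are clipped to zero and
    flagged via ``clipped``.
    """

    a325: float
    a260: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.a325 < 0 or self.a260 < 0:
            object.__setattr__(self, "a325", max(self.a325, 0.0))
            object.__setattr__(self, "a260", max(self.a260, 0.0))
            object.__setattr__(self, "clipped", True)


@dataclass(frozen=True)
class RatioMatrix:
    """Grid of candidate compositions with expected corrected A₃₂₅/A₂₆₀.

    ``expected_ratio[i, j]`` corresponds to TA concentration ``ta_grid[i]``
    and CHDG concentration ``chdg_grid[j]``.  Cells with A₂₆₀ = 0 hold NaN
    and are unusable.
    """

    ta_grid: np.ndarray
    chdg_grid: np.ndarray
    expected_ratio: np.ndarray
    correction: float  # extinction-coefficient correction factor applied


@dataclass(frozen=True)
class CalibrationLine:
    """OLS Beer-Lambert calibration at one fixed TA:CHDG ratio."""

    slope: float
    intercept: float
    r_squared: float
    wavelength: str

    def invert(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


def predict_reading(c_ta: float, c_chdg: float, eps: ExtinctionSet = DEFAULT_EXTINCTIONS) -> SpectrumReading:
    """Beer–Lambert forward model: additive two-component absorbances."""
    if c_ta < 0 or c_chdg < 0:
        raise ValueError("concentrations must be non-negative")
    a325 = eps.path_length * (eps.eps_ta_325 * c_ta + eps.eps_chdg_325 * c_chdg)
    a260 = eps.path_length * (eps.eps_ta_260 * c_ta + eps.eps_chdg_260 * c_chdg)
    return SpectrumReading(a325=a325, a260=a260)


def _corrected_ratio(a325: float, a260: float, eps: ExtinctionSet) -> float:
    """A325/A260 normalized by the pure-component extinction ratio.

    The correction factor ε_CHDG,260/ε_TA,325 is constant over compositions,
    making the corrected ratio a dimensionless composition coordinate.
    """
    if a260 <= 0:
        return float("nan")
    return (a325 / a260) * (eps.eps_chdg_260 / eps.eps_ta_325)


def build_ratio_matrix(
    ta_grid: np.ndarray,
    chdg_grid: np.ndarray,
    eps: ExtinctionSet = DEFAULT_EXTINCTIONS,
) -> RatioMatrix:
    """Expected corrected-ratio table over a composition grid."""
    ta = np.asarray(ta_grid, dtype=float)
    ch = np.asarray(chdg_grid, dtype=float)
    if ta.size == 0 or ch.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(ta) <= 0) or np.any(np.diff(ch) <= 0):
        raise ValueError("grids must be strictly increasing")
    ratio = np.empty((ta.size, ch.size))
    for i, cta in enumerate(ta):
        for j, cch in enumerate(ch):
            r = predict_reading(cta, cch, eps)
            ratio[i, j] = _corrected_ratio(r.a325, r.a260, eps)
    return RatioMatrix(
        ta_grid=ta, chdg_grid=ch, expected_ratio=ratio,
        correction=eps.eps_chdg_260 / eps.eps_ta_325,
    )


def default_grids(n: int = 25, lo: float = 1e-6, hi: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Geometric composition grids spanning two decades (mol/L)."""
    g = np.geomspace(lo, hi, n)
    return g, g.copy()


def match_composition(
    reading: SpectrumReading,
    matrix: RatioMatrix,
    eps: ExtinctionSet = DEFAULT_EXTINCTIONS,
) -> tuple[float, tuple[int, int]]:
    """Nearest-ratio cell of the matrix for an observed reading.

    Returns ``(ta:chdg concentration ratio, (i, j))``.  Ties break toward
    the lower-TA cell (conservative release estimate).  Raises if A₂₆₀ is
    (numerically) zero.
    """
    if reading.a260 <= 0:
        raise ArithmeticError("A260 is zero: composition cannot be classified")
    obs = _corrected_ratio(reading.a325, reading.a260, eps)
    diff = np.abs(matrix.expected_ratio - obs)
    diff = np.where(np.isnan(diff), np.inf, diff)
    # argmin over row-major order with rows = TA ascending gives the
    # lowest-TA cell among ties
    flat = int(np.argmin(diff))
    i, j = np.unravel_index(flat, diff.shape)
    ratio = matrix.ta_grid[i] / matrix.chdg_grid[j]
    return float(ratio), (int(i), int(j))


def calibrate_line(concentrations, absorbances, wavelength: str) -> CalibrationLine:
    """OLS straight line through a dilution series at fixed composition."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 dilution points")
    slope, intercept = np.polyfit(c, a, 1)
    resid = a - (slope * c + intercept)
    ss_tot = float(((a - a.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    if slope <= 0:
        raise ArithmeticError("non-positive calibration slope")
    return CalibrationLine(slope=float(slope), intercept=float(intercept),
                           r_squared=r2, wavelength=wavelength)


def calibrate_and_quantify(
    dilution_total_conc,
    readings: list[SpectrumReading],
    ta_mole_fraction: float,
    unknown: SpectrumReading,
    eps: ExtinctionSet = DEFAULT_EXTINCTIONS,
) -> tuple[dict[str, CalibrationLine], dict[str, float]]:
    """Calibration lines at a fixed TA:CHDG ratio plus unknown concentrations.

    The dilution series shares the composition ``ta_mole_fraction`` (TA
    moles / total moles).  Each wavelength yields a line A vs total
    concentration; the unknown's total concentration is the inverse of each
    line, and the two estimates plus their relative discrepancy are reported
    alongside the split into c_TA and c_CHDG.
    """
    if not 0.0 <= ta_mole_fraction <= 1.0:
        raise ValueError("ta_mole_fraction must lie in [0, 1]")
    totals = np.asarray(dilution_total_conc, dtype=float)
    lines = {
        "325": calibrate_line(totals, [r.a325 for r in readings], "325"),
        "260": calibrate_line(totals, [r.a260 for r in readings], "260"),
    }
    c_tot_325 = lines["325"].invert(unknown.a325)
    c_tot_260 = lines["260"].invert(unknown.a260)
    c_tot = 0.5 * (c_tot_325 + c_tot_260)
    denom = c_tot if c_tot != 0 else 1.0
    result = {
        "c_total": c_tot,
        "c_total_325": c_tot_325,
        "c_total_260": c_tot_260,
        "consistency_rel_diff": abs(c_tot_325 - c_tot_260) / abs(denom),
        "c_ta": c_tot * ta_mole_fraction,
        "c_chdg": c_tot * (1.0 - ta_mole_fraction),
    }
    return lines, result


def solve_two_wavelength(
    reading: SpectrumReading, eps: ExtinctionSet = DEFAULT_EXTINCTIONS
) -> tuple[float, float]:
    """Direct inversion of the 2x2 Beer–Lambert system for (c_TA, c_CHDG).

    Algebraic counterpart of the ratio-matrix + calibration route; small
    negative solutions from noise are clipped to zero.
    """
    c = np.linalg.solve(eps.matrix(), np.array([reading.a325, reading.a260]))
    return float(max(c[0], 0.0)), float(max(c[1], 0.0))


def fraction_released(
    c_t: float,
    loaded_mass_mg: float,
    vessel_volume_L: float = 1.0,
    molar_mass: float | None = None,
) -> float:
    """Fraction of the initial load found in the vessel at time t.

    ``c_t`` is mol/L if ``molar_mass`` (g/mol) is given, else mg/L.  Values
    above 1 are clipped with a warning (measurement noise / loss accounting).
    """
    if loaded_mass_mg <= 0:
        raise ValueError("loaded mass must be positive")
    mass_mg = c_t * vessel_volume_L * (molar_mass * 1000.0 if molar_mass else 1.0)
    frac = mass_mg / loaded_mass_mg
    if frac > 1.0:
        warnings.warn(f"fraction released {frac:.3f} > 1 clipped to 1", stacklevel=2)
    return float(np.clip(frac, 0.0, 1.0))
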