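"""pH-dependent net fixed charge of atelocollagen and fixed-charge concentration.

The collagen type I triple helix carries ionizable side chains (Asp, Glu,
His, Arg, Lys) plus terminal groups (three N-terminal glycines, three
C-terminal prolines).  Treating each residue class as an independent
Henderson–Hasselbalch acid/base pair gives the expected number of negative
and positive charges per molecule as a function of pH, from which the
isoelectric point (IEP) and the fixed-charge concentration ``c_p`` of a
swollen matrix follow.

Alkaline extraction partially deamidates Asn/Gln to Asp/Glu; this is modelled
by :func:`deamidate`, which converts a fraction of the amide pool into extra
carboxylates and thereby shifts the IEP into the acidic range.

Reference pKa values are tabulated at 25 °C and zero ionic strength and
corrected to operating conditions by a van't Hoff temperature term and a
Davies-type ionic-strength term (see :func:`correct_pka`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "IonizableGroupClass",
    "IonizableComposition",
    "ChargeState",
    "FixedChargeResult",
    "correct_pka",
    "deamidate",
    "net_charge",
    "titration_curve",
    "find_iep",
    "fixed_charge_concentration",
    "default_composition",
    "load_composition_csv",
]

R_GAS = 8.314462618  # J mol^-1 K^-1
LN10 = np.log(10.0)
T_REF_K = 298.15

# Debye-Hückel limiting slope A (molal scale) vs temperature, CRC values.
_A_DH_T = np.array([0.0, 10.0, 20.0, 25.0, 30.0, 37.0, 40.0, 50.0])
_A_DH_V = np.array([0.4918, 0.4989, 0.5070, 0.5114, 0.5161, 0.5221, 0.5262, 0.5373])


@dataclass(frozen=True)
class IonizableGroupClass:
    """One class of identical ionizable groups on the molecule.

    ``pair_sign`` is −1 for –COOH/–COO⁻ pairs and +1 for –NH₃⁺/–NH₂ pairs.
    ``ionization_enthalpy`` is the standard ionization enthalpy in kJ/mol,
    used for the van't Hoff temperature correction of ``pka_ref``.
    """

    name: str
    count: int
    pka_ref: float
    pair_sign: int
    ionization_enthalpy: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.pair_sign not in (-1, +1):
            raise ValueError(f"pair_sign must be -1 or +1, got {self.pair_sign}")


@dataclass(frozen=True)
class IonizableComposition:
    """Full ionizable-group inventory of one atelocollagen molecule."""

    groups: tuple[IonizableGroupClass, ...]
    asn_count: int = 46
    gln_count: int = 75
    deamidation_degree: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deamidation_degree <= 1.0:
            raise ValueError("deamidation_degree must be in [0, 1]")
        if self.asn_count < 0 or self.gln_count < 0:
            raise ValueError("Asn/Gln counts must be non-negative")

    def group(self, name: str) -> IonizableGroupClass:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass(frozen=True)
class ChargeState:
    """Expected charge counts of one molecule at a given pH.

    ``n_net`` is signed positive below the IEP (cationic molecule) and
    negative above it: ``n_net = n_positive - n_negative``.
    """

    pH: float
    n_negative: float
    n_positive: float

    @property
    def n_net(self) -> float:
        return self.n_positive - self.n_negative


@dataclass(frozen=True)
class FixedChargeResult:
    """Fixed-charge concentration of a swollen matrix, mol·cm⁻³."""

    c_p: float


# Reference table at 25 degC, I = 0. Asp and His were calibrated against the
# three charge anchors (|N_net| = 17.6 at pH 7.40, IEP 5.5 deamidated,
# IEP > 8 non-deamidated); the rest are standard textbook values.
DEFAULT_PKA_TABLE: dict[str, tuple[float, int, float]] = {
    # name: (pka_ref, pair_sign, ionization_enthalpy kJ/mol)
    "Asp": (4.10, -1, 1.0),
    "Glu": (4.25, -1, 1.0),
    "Pro-Cterm": (3.60, -1, 1.0),
    "His": (6.23, +1, 29.5),
    "Arg": (12.10, +1, 51.9),
    "Lys": (10.67, +1, 53.0),
    "Gly-Nterm": (9.00, +1, 45.0),
}

# Residue counts per atelocollagen triple helix (bovine collagen type I).
DEFAULT_COUNTS: dict[str, int] = {
    "Asp": 90,
    "Glu": 150,
    "Pro-Cterm": 3,
    "His": 14,
    "Arg": 162,
    "Lys": 89,
    "Gly-Nterm": 3,
}


def default_composition(
    pka_table: dict[str, tuple[float, int, float]] | None = None,
    counts: dict[str, int] | None = None,
) -> IonizableComposition:
    """The shipped atelocollagen composition, optionally with overrides."""
    table = dict(DEFAULT_PKA_TABLE)
    if pka_table:
        table.update(pka_table)
    cts = dict(DEFAULT_COUNTS)
    if counts:
        cts.update(counts)
    groups = tuple(
        IonizableGroupClass(name, cts.get(name, 0), pka, sign, dh)
        for name, (pka, sign, dh) in table.items()
    )
    return IonizableComposition(groups=groups)


def load_composition_csv(path=None) -> IonizableComposition:
    """Load a composition fixture from CSV.

    Columns: name, count, pka_ref, pair_sign, ionization_enthalpy.
    Defaults to the packaged atelocollagen fixture.
    """
    import pandas as pd

    if path is None:
        ref = resources.files("collamat.data") / "atelocollagen_groups.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    groups = tuple(
        IonizableGroupClass(
            str(r["name"]), int(r["count"]), float(r["pka_ref"]),
            int(r["pair_sign"]), float(r["ionization_enthalpy"]),
        )
        for _, r in df.iterrows()
    )
    return IonizableComposition(groups=groups)


def _davies_term(ionic_strength: float) -> float:
    s = np.sqrt(ionic_strength)
    return s / (1.0 + s) - 0.3 * ionic_strength


def correct_pka(
    group: IonizableGroupClass,
    temperature_C: float,
    ionic_strength: float,
) -> float:
    """pKa at operating temperature and ionic strength.

    Temperature: van't Hoff with the group's ionization enthalpy,
    ``ΔpKa_T = -(ΔH/R ln10)(1/T_ref - 1/T)``.  Ionic strength: Davies-type,
    ``ΔpKa_I = -A(T)·f(I)·(1 - Z)`` with ``f(I) = √I/(1+√I) - 0.3 I``, which
    reduces to the standard −2Af shift for carboxyl pairs (Z = −1) and zero
    for cationic-acid pairs (Z = +1).  Both terms vanish at 25 °C, I = 0.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if not 0.0 < temperature_C < 100.0:
        raise ValueError("temperature must be in (0, 100) degC")
    T = temperature_C + 273.15
    dpk_T = -(group.ionization_enthalpy * 1000.0 / (R_GAS * LN10)) * (
        1.0 / T_REF_K - 1.0 / T
    )
    A = float(np.interp(temperature_C, _A_DH_T, _A_DH_V))
    dpk_I = -A * _davies_term(ionic_strength) * (1.0 - group.pair_sign)
    return group.pka_ref + dpk_T + dpk_I


def deamidate(comp: IonizableComposition, degree: float) -> IonizableComposition:
    """Convert a fraction of the Asn/Gln pool to Asp/Glu.

    Increments are rounded half-up to integers (the supplements are whole
    residues).  The input composition is not modified.
    """
    if not 0.0 <= degree <= 1.0:
        raise ValueError("deamidation degree must be in [0, 1]")
    extra_asp = int(np.floor(degree * comp.asn_count + 0.5))
    extra_glu = int(np.floor(degree * comp.gln_count + 0.5))
    groups = []
    for g in comp.groups:
        if g.name == "Asp":
            groups.append(replace(g, count=g.count + extra_asp))
        elif g.name == "Glu":
            groups.append(replace(g, count=g.count + extra_glu))
        else:
            groups.append(g)
    return replace(comp, groups=tuple(groups), deamidation_degree=degree)


def net_charge(
    comp: IonizableComposition,
    pH: float,
    temperature_C: float = 37.0,
    ionic_strength: float = 0.180,
) -> ChargeState:
    """Expected charge state at one pH under operating conditions.

    Acidic pairs contribute ``N_i · 10^(pH-pKa)/(1+10^(pH-pKa))`` negative
    charges, basic pairs ``N_j / (1+10^(pH-pKa))`` positive charges, with
    the pKa of every class corrected via :func:`correct_pka`.
    """
    n_neg = 0.0
    n_pos = 0.0
    for g in comp.groups:
        pk = correct_pka(g, temperature_C, ionic_strength)
        x = 10.0 ** (pH - pk)
        if g.pair_sign < 0:
            n_neg += g.count * x / (1.0 + x)
        else:
            n_pos += g.count / (1.0 + x)
    return ChargeState(pH=pH, n_negative=n_neg, n_positive=n_pos)


def titration_curve(
    comp: IonizableComposition,
    pH_grid: Sequence[float],
    temperature_C: float = 37.0,
    ionic_strength: float = 0.180,
) -> list[ChargeState]:
    """Charge states along a strictly increasing pH grid."""
    grid = np.asarray(pH_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("pH grid must be 1-D and strictly increasing")
    return [net_charge(comp, p, temperature_C, ionic_strength) for p in grid]


def find_iep(
    comp: IonizableComposition,
    temperature_C: float = 37.0,
    ionic_strength: float = 0.180,
    bracket: tuple[float, float] = (1.0, 13.0),
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: the root of the net-charge curve.

    Bisection (via Brent's method, which contains it) on ``bracket`` to an
    absolute pH tolerance ``tol``; raises if the net charge does not change
    sign on the bracket.
    """

    def f(p: float) -> float:
        return net_charge(comp, p, temperature_C, ionic_strength).n_net

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ArithmeticError("net charge does not change sign on the bracket")
    return float(brentq(f, lo, hi, xtol=tol))


def fixed_charge_concentration(
    nu2eq: float,
    rho_coll: float,
    molar_mass: float,
    n_net_abs: float,
) -> FixedChargeResult:
    """Fixed-charge concentration of the swollen matrix, mol·cm⁻³.

    ``c_p = |N_net| · ν_2eq · ρ_coll / M`` with ρ_coll in g·cm⁻³ and the
    collagen molar mass M in g·mol⁻¹.
    """
    if not 0.0 < nu2eq < 1.0:
        raise ValueError("nu2eq must be in (0, 1)")
    if rho_coll <= 0 or molar_mass <= 0:
        raise ValueError("densities and molar mass must be positive")
    return FixedChargeResult(c_p=n_net_abs * nu2eq * rho_coll / molar_mass)
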