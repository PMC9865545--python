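"""CSV/JSON readers-writers and table renderers.

The table renderers reproduce the layout of the equilibrium-swelling /
crosslink tables (one row per matrix, intermediate quantities in the
conventional scalings ×10⁸ / ×10⁷ / ×10⁵) and the kinetics summary
(k ± se, n ± se, R² per transport regime), so outputs diff cleanly against
the published values.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .charge import fixed_charge_concentration
from .kinetics import (
    Geometry,
    PowerLawFit,
    ReleaseSeries,
    classify_mechanism,
    decompose_release,
    fit_power_law,
)
from .swelling import (
    CrosslinkMethod,
    CrosslinkParams,
    MatrixComposition,
    ReleaseCase,
    crosslink_density,
    donnan_delta_c,
    equilibrium_volume_fractions,
)

__all__ = [
    "read_series",
    "write_series",
    "load_matrix_table",
    "run_crosslink_table",
    "run_kinetics_report",
]

_SERIES_COLUMNS = ("time_min", "fraction")


def read_series(path) -> ReleaseSeries:
    """Read a release series CSV with columns time_min, fraction[, analyte]."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time_min"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-monotone time at data line {bad[0] + 3}"
        )
    analyte = str(df["analyte"].iloc[0]) if "analyte" in df.columns else "other"
    return ReleaseSeries(
        time=t, fraction=df["fraction"].to_numpy(dtype=float), analyte=analyte
    )


def write_series(series: ReleaseSeries, path) -> Path:
    """Write a release series CSV (round-trips through :func:`read_series`)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_min": series.time,
            "fraction": series.fraction,
            "analyte": series.analyte,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_matrix_table(which: str = "released", path=None) -> pd.DataFrame:
    """Load a matrix-metadata fixture (the equilibrium-swelling tables).

    ``which`` selects the packaged fixture: "loaded" (neither analyte
    released at equilibrium) or "released" (both analytes released).
    """
    if path is None:
        name = {"loaded": "matrices_loaded.csv", "released": "matrices_released.csv"}[which]
        ref = resources.files("collamat.data") / name
        with resources.as_file(ref) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def run_crosslink_table(
    fixture: pd.DataFrame,
    case: ReleaseCase = ReleaseCase.RELEASED,
    params: CrosslinkParams = CrosslinkParams(),
    n_net_abs: float = 17.6,
    molar_mass: float = 3e5,
    rho_buffer: float = 1.093,
    c_e: float = 9.0e-5,
    verify_tolerance: float | None = None,
) -> pd.DataFrame:
    """Per-row swelling → charge → Donnan → crosslink-density chain.

    Required fixture columns: system, rho_matrix, q_w.  Output columns use
    the conventional scalings (c_p ×10⁸, Δc ×10⁷, DC ×10⁵ mol·cm⁻³).  If
    ``verify_tolerance`` is given and the fixture carries reference columns
    (nu2eq_ref, cp_ref, delta_c_ref, dc_ref), rows deviating by more than
    the tolerance are flagged in a boolean ``verified`` column.
    """
    required = ["system", "rho_matrix", "q_w"]
    missing = [c for c in required if c not in fixture.columns]
    if missing:
        raise ValueError(f"fixture missing columns: {missing}")
    rows = []
    for _, row in fixture.iterrows():
        comp = MatrixComposition(
            ta_pct=float(row.get("ta_pct", 0.0)),
            chdg_pct=float(row.get("chdg_pct", 0.0)),
            rho_matrix=float(row["rho_matrix"]),
        )
        sw = equilibrium_volume_fractions(float(row["q_w"]), comp, rho_buffer, case)
        cp = fixed_charge_concentration(sw.nu2eq, comp.rho_coll, molar_mass, n_net_abs).c_p
        dc_donnan = donnan_delta_c(cp, c_e)
        res = crosslink_density(sw.nu2eq, dc_donnan, params, CrosslinkMethod.BRAY_MERRILL, c_p=cp)
        rows.append(
            {
                "system": row["system"],
                "rho_matrix": comp.rho_matrix,
                "q_w": sw.q_w,
                "q_v_matrix": sw.q_v_matrix,
                "q_v_coll": sw.q_v_coll,
                "nu2eq": sw.nu2eq,
                "cp_e8": cp * 1e8,
                "delta_c_e7": dc_donnan * 1e7,
                "dc_e5": res.dc * 1e5,
            }
        )
    out = pd.DataFrame(rows)
    if verify_tolerance is not None:
        ref_cols = {
            "nu2eq_ref": "nu2eq",
            "cp_ref": "cp_e8",
            "delta_c_ref": "delta_c_e7",
            "dc_ref": "dc_e5",
        }
        ok = np.ones(len(out), dtype=bool)
        for ref, col in ref_cols.items():
            if ref in fixture.columns:
                rel = np.abs(out[col].to_numpy() - fixture[ref].to_numpy()) / np.abs(
                    fixture[ref].to_numpy()
                )
                ok &= rel <= verify_tolerance
        out["verified"] = ok
    return out


def run_kinetics_report(
    series_list: list[ReleaseSeries],
    fickian_ref: PowerLawFit,
    case2_ref: PowerLawFit,
    geometry: Geometry = Geometry.CYLINDER,
) -> pd.DataFrame:
    """Fit + decomposition summary, one record per series.

    Columns echo the kinetics table layout (k ± se, n ± se, R²) for the
    first-60% window, plus decomposition weights, the Case II percentage
    and the mechanism class.
    """
    records = []
    for i, s in enumerate(series_list):
        fit = fit_power_law(s, window="first60")
        weights = decompose_release(s, fickian_ref, case2_ref)
        records.append(
            {
                "series": i,
                "analyte": s.analyte,
                "k": fit.k,
                "stderr_k": fit.stderr_k,
                "n": fit.n,
                "stderr_n": fit.stderr_n,
                "r_squared": fit.r_squared,
                "w_fickian": weights.w_fickian,
                "w_case2": weights.w_case2,
                "pct_case2": weights.pct_case2,
                "mechanism": classify_mechanism(fit.n, geometry).value,
            }
        )
    return pd.DataFrame(records)


def write_report(df: pd.DataFrame, path, fmt: str = "csv") -> Path:
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
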