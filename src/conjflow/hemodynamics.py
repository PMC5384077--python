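"""Per-vessel hemodynamics: Vs, Q, WSR, viscosity and WSS.

Units follow the reporting convention of the analysis: D in um, axial
velocity V in mm/s, mean cross-sectional velocity Vs in mm/s, flow Q in
pl/s, wall shear rate WSR in 1/s, viscosity eta in mPa*s, wall shear stress
WSS in dyne/cm^2.

Vs = V / k with a configurable velocity-profile factor k (default 1.6, the
axial-to-mean conversion for microvessels with blunted profiles).
Q = Vs * pi * D^2 / 4, WSR = 8 Vs / D (Vs expressed in um/s), and
WSS = eta * WSR * 0.01 (mPa*s * 1/s -> dyne/cm^2).

Viscosity uses the in-vitro diameter-dependent relative-viscosity law for
blood in narrow tubes (Fahraeus-Lindqvist effect):

    eta_rel = 1 + (eta*_0.45 - 1) * ((1 - HCT)^C - 1) / ((1 - 0.45)^C - 1)
    eta*_0.45 = 220 e^(-1.3 D) + 3.2 - 2.44 e^(-0.06 D^0.645)
    C = (0.8 + e^(-0.075 D)) * (-1 + 1/(1 + 1e-11 D^12)) + 1/(1 + 1e-11 D^12)

scaled by a configurable plasma viscosity (default 1.2 mPa*s).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import DiametryConfig, HemodynamicsConfig

HEMODYNAMIC_COLUMNS = [
    "subject_id", "vessel_id", "segment_id", "vessel_type", "length_um",
    "n_stations", "D", "V", "Vs", "Q", "WSR", "eta", "WSS",
]


def _check_diameter(d_um: float) -> None:
    if not 6.0 <= d_um <= 75.0:
        raise ValueError(f"diameter {d_um} um outside the measurable 6-75 um range")


def cross_section_velocity(v_mm_s: float, d_um: float,
                           profile_factor: float = 1.6) -> float:
    """Mean cross-sectional velocity Vs = V / k."""
    if v_mm_s <= 0:
        raise ValueError("axial velocity must be positive")
    _check_diameter(d_um)
    if profile_factor <= 0:
        raise ValueError("velocity-profile factor must be positive")
    return v_mm_s / profile_factor


def blood_flow(vs_mm_s: float, d_um: float) -> float:
    """Q [pl/s] = Vs[um/s] * pi * D^2 / 4 * 1e-3 (1 pl = 1000 um^3)."""
    if vs_mm_s <= 0:
        raise ValueError("cross-sectional velocity must be positive")
    if d_um <= 0:
        raise ValueError("diameter must be positive")
    return vs_mm_s * 1000.0 * math.pi * d_um ** 2 / 4.0 * 1e-3


def wall_shear_rate(vs_mm_s: float, d_um: float) -> float:
    """WSR [1/s] = 8 * Vs[um/s] / D[um]."""
    if vs_mm_s <= 0 or d_um <= 0:
        raise ValueError("Vs and D must be positive")
    return 8.0 * (vs_mm_s * 1000.0) / d_um


def relative_viscosity(hct: float, d_um: float,
                       reference_hct: float = 0.45) -> float:
    """In-vitro relative apparent viscosity of blood in a tube of diameter D."""
    if not 0.0 < hct < 1.0:
        raise ValueError("hematocrit must be a fraction in (0, 1)")
    _check_diameter(d_um)
    d = float(d_um)
    eta_star = 220.0 * math.exp(-1.3 * d) + 3.2 - 2.44 * math.exp(-0.06 * d ** 0.645)
    damp = 1.0 / (1.0 + 1e-11 * d ** 12)
    c = (0.8 + math.exp(-0.075 * d)) * (-1.0 + damp) + damp
    num = (1.0 - hct) ** c - 1.0
    den = (1.0 - reference_hct) ** c - 1.0
    return 1.0 + (eta_star - 1.0) * num / den


def viscosity(hct: float, d_um: float,
              cfg: HemodynamicsConfig | None = None) -> float:
    """Dynamic viscosity eta [mPa*s] = eta_plasma * eta_rel(D, HCT)."""
    cfg = cfg or HemodynamicsConfig()
    return cfg.plasma_viscosity_mpa_s * relative_viscosity(
        hct, d_um, reference_hct=cfg.reference_hct)


def wall_shear_stress(eta_mpa_s: float, wsr_per_s: float) -> float:
    """WSS [dyne/cm^2] = eta[mPa*s] * WSR[1/s] * 0.01."""
    if eta_mpa_s <= 0 or wsr_per_s <= 0:
        raise ValueError("eta and WSR must be positive")
    return eta_mpa_s * wsr_per_s * 0.01


def compute_map(sbp_mmhg: float, dbp_mmhg: float) -> float:
    """Mean arterial pressure MAP = (SBP + 2 DBP) / 3."""
    if dbp_mmhg <= 0 or sbp_mmhg < dbp_mmhg:
        raise ValueError("require SBP >= DBP > 0")
    return (sbp_mmhg + 2.0 * dbp_mmhg) / 3.0


def hemodynamic_record(subject_id: str, vessel_id, segment_id: int,
                       vessel_type: str, d_um: float, v_mm_s: float,
                       hct: float, length_um: float, n_stations: int = 0,
                       cfg: HemodynamicsConfig | None = None) -> dict:
    """One vessel's full descriptor set from (D, V, HCT)."""
    cfg = cfg or HemodynamicsConfig()
    vs = cross_section_velocity(v_mm_s, d_um, cfg.velocity_profile_factor)
    q = blood_flow(vs, d_um)
    wsr = wall_shear_rate(vs, d_um)
    eta = viscosity(hct, d_um, cfg)
    wss = wall_shear_stress(eta, wsr)
    return {"subject_id": subject_id, "vessel_id": vessel_id,
            "segment_id": segment_id, "vessel_type": vessel_type,
            "length_um": length_um, "n_stations": n_stations,
            "D": d_um, "V": v_mm_s, "Vs": vs, "Q": q, "WSR": wsr,
            "eta": eta, "WSS": wss}


def dedupe_longest(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (subject, vessel): the longest centerline.

    Ties are broken by larger station count, then by lowest segment id.
    """
    if records.empty:
        return records
    df = records.copy()
    if "n_stations" not in df.columns:
        df["n_stations"] = 0
    keys = [k for k in ("subject_id", "vessel_id") if k in df.columns]
    df = df.sort_values(["length_um", "n_stations", "segment_id"],
                        ascending=[False, False, True], kind="mergesort")
    df = df.drop_duplicates(subset=keys, keep="first")
    return df.sort_index().reset_index(drop=True)


def audit_records(records: pd.DataFrame, rtol: float = 1e-9) -> None:
    """Assert the formula identities hold on every emitted record."""
    if records.empty:
        return
    vs_um = records["Vs"].to_numpy() * 1000.0
    d = records["D"].to_numpy()
    q = vs_um * np.pi * d ** 2 / 4.0 * 1e-3
    wsr = 8.0 * vs_um / d
    wss = records["eta"].to_numpy() * wsr * 0.01
    for name, expect in (("Q", q), ("WSR", wsr), ("WSS", wss)):
        got = records[name].to_numpy()
        if not np.allclose(got, expect, rtol=rtol, atol=0):
            raise AssertionError(f"hemodynamic identity violated for {name}")
    cfg = DiametryConfig()
    if ((d < cfg.min_diameter_um) | (d > cfg.max_diameter_um)).any():
        raise AssertionError("record outside measurable diameter range")
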