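"""Thermal-comfort indices, intermediate physiological state, and heat fluxes.

All public functions accept scalars or numpy arrays (broadcasting) and are
deterministic.  Batch mode over a :class:`pandas.DataFrame` is provided by
:func:`compute_features`.

Units: temperatures in degC, RH in percent (0-100], wind speed U in m/s,
solar radiation Qsr in W/m^2, fluxes in W/m^2 of body surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalConstants",
    "ThermalState",
    "HeatFluxes",
    "dew_point",
    "thi",
    "bghi",
    "athi",
    "cci",
    "dhli",
    "etic",
    "stic",
    "thermal_state",
    "heat_fluxes",
    "compute_features",
    "INDEX_NAMES",
    "FLUX_NAMES",
]

INDEX_NAMES = ("THI", "BGHI", "ATHI", "CCI", "DHLI", "ETIC", "STIC")
FLUX_NAMES = ("Qresp", "Qevap", "Qconv", "Qrad", "Qlat", "Qsens")


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the cow-environment heat exchange model.

    Attributes
    ----------
    S : body surface area, m^2
    rho_cp : volumetric specific heat capacity of air, J m^-3 K^-1
    gamma : psychrometer constant, kPa K^-1
    lam : latent heat of vaporization, J g^-1
    sigma : Stefan-Boltzmann constant, W m^-2 K^-4
    epsilon : emissivity
    d : body diameter (cylinder model), m
    k_a : thermal conductivity of air, W m^-1 K^-1
    nu_air : kinematic viscosity of air, m^2/s
    vt_floor : lower guard for tidal volume, m^3 (the printed linear model
        goes negative at low respiratory frequency)
    ambient_vapor_actual : if True the respiratory flux uses the actual
        ambient vapor pressure RH/100 * Pe_sat(Ta); if False the literal
        saturation-at-Ta reading.
    """

    S: float = 5.4
    rho_cp: float = 1220.0
    gamma: float = 0.066
    lam: float = 2260.0
    sigma: float = 5.67e-8
    epsilon: float = 0.95
    d: float = 0.8
    k_a: float = 0.025
    nu_air: float = 1.5e-5
    vt_floor: float = 1e-4
    ambient_vapor_actual: bool = True

    def __post_init__(self) -> None:
        for name in ("S", "rho_cp", "gamma", "lam", "sigma", "epsilon", "d", "k_a", "nu_air"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name!r} must be strictly positive")


@dataclass
class ThermalState:
    """Intermediate physiological quantities feeding the flux equations."""

    Ts: np.ndarray | float
    Tc: np.ndarray | float
    Tex: np.ndarray | float
    Rsw: np.ndarray | float
    Pe_a: np.ndarray | float
    Pe_b: np.ndarray | float
    Fr: np.ndarray | float
    Vt: np.ndarray | float
    rr: np.ndarray | float
    Nu: np.ndarray | float
    Trad: np.ndarray | float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class HeatFluxes:
    """Sensible/latent heat-flux partition, W/m^2 of body surface."""

    Qresp: np.ndarray | float
    Qevap: np.ndarray | float
    Qconv: np.ndarray | float
    Qrad: np.ndarray | float
    Qlat: np.ndarray | float
    Qsens: np.ndarray | float

    def as_dict(self) -> dict:
        return asdict(self)


def _check_rh(RH) -> None:
    RH = np.asarray(RH, dtype=float)
    if np.any(RH <= 0) or np.any(RH > 100):
        raise ValueError("RH must lie in (0, 100] percent")


def _check_u(U) -> None:
    if np.any(np.asarray(U, dtype=float) < 0):
        raise ValueError("wind speed U must be >= 0")


# ---------------------------------------------------------------------------
# thermal comfort indices
# ---------------------------------------------------------------------------

# Magnus constants for dew point; standard meteorological values.
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04


def dew_point(Ta, RH):
    """Dew point temperature (degC) from the Magnus formula."""
    _check_rh(RH)
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    g = np.log(RH / 100.0) + _MAGNUS_A * Ta / (_MAGNUS_B + Ta)
    out = _MAGNUS_B * g / (_MAGNUS_A - g)
    return out if out.ndim else float(out)


def thi(Ta, RH):
    """Temperature-humidity index."""
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    out = 1.8 * Ta + 32.0 - (0.55 - 0.0055 * RH) * (1.8 * Ta - 26.0)
    return out if out.ndim else float(out)


def bghi(Tbg, Tdp):
    """Black globe humidity index."""
    out = np.asarray(Tbg, dtype=float) + 0.36 * np.asarray(Tdp, dtype=float) + 41.5
    return out if out.ndim else float(out)


def athi(Ta, RH, U, Qsr):
    """Adjusted THI with wind and solar-radiation corrections."""
    _check_u(U)
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    out = (
        4.51
        + (0.8 * Ta + (RH / 100.0) * (Ta - 14.4) + 46.4)
        - 1.992 * np.asarray(U, dtype=float)
        + 0.0068 * np.asarray(Qsr, dtype=float)
    )
    return out if out.ndim else float(out)


def _cci_eq_u(U):
    # wind correction; log base 0.3 of (2.26 U + 0.33)
    U = np.asarray(U, dtype=float)
    log03 = np.log(2.26 * U + 0.33) / np.log(0.3)
    expo = (1.0 / (2.26 * U + 0.23)) ** 0.45 * (2.9 + 1.14e-6 * U**2.5 - log03) ** -2.0
    return -6.56 / np.exp(expo) - 0.00566 * U**2 + 3.33


def _cci_eq_qsr(Qsr, Ta):
    Qsr = np.asarray(Qsr, dtype=float)
    Ta = np.asarray(Ta, dtype=float)
    return 0.0076 * Qsr - 0.00002 * Qsr * Ta + 0.00005 * Ta**2 * np.sqrt(Qsr) + 0.1 * Ta - 2.0


def _cci_eq_rh(RH, Ta):
    RH = np.asarray(RH, dtype=float)
    Ta = np.asarray(Ta, dtype=float)
    return (
        np.exp(0.00182 * RH + 1.8e-5 * Ta * RH)
        * (0.000054 * Ta**2 + 0.00192 * Ta - 0.0246)
        * (RH - 30.0)
    )


def cci(Ta, RH, U, Qsr):
    """Comprehensive climate index: Ta plus wind/radiation/humidity corrections."""
    _check_u(U)
    out = np.asarray(Ta, dtype=float) + _cci_eq_u(U) + _cci_eq_qsr(Qsr, Ta) + _cci_eq_rh(RH, Ta)
    return out if out.ndim else float(out)


def dhli(Tbg, RH):
    """Dairy heat load index on a 0-100-type scale.

    ``RH`` is accepted in percent and converted to a fraction internally
    (the underlying Gompertz-type model takes humidity on [0, 1]).
    """
    _check_rh(RH)
    Tbg = np.asarray(Tbg, dtype=float)
    rh = np.asarray(RH, dtype=float) / 100.0
    core = 1.681813 * (1.0 - np.exp(-np.exp(-8.50749 + 0.206149 * Tbg + 4.088399 * rh)))
    out = (core - 0.0002) / (1.6812 - 0.0002) * 100.0
    return out if out.ndim else float(out)


def etic(Ta, RH, U, Qsr):
    """Equivalent temperature index for cattle (degC-equivalent)."""
    _check_u(U)
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    U = np.asarray(U, dtype=float)
    out = (
        Ta
        - 0.0038 * Ta * (100.0 - RH)
        - 0.1173 * U**0.707 * (39.2 - Ta)
        + 1.86e-4 * Ta * np.asarray(Qsr, dtype=float)
    )
    return out if out.ndim else float(out)


def stic(Ta, RH, U, Qsr):
    """Skin temperature index for cows (degC-equivalent)."""
    _check_u(U)
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    U = np.asarray(U, dtype=float)
    wind = 0.116 * U**0.53
    num = (
        1.73 * Ta
        - (1.0 - RH / 100.0) * 10.0 ** (7.5 * Ta / (237.0 + Ta))
        + wind * (10.0 * Ta - 300.0)
        + 0.05 * np.asarray(Qsr, dtype=float)
        + 16.08
    )
    out = num / (wind + 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# physiological state
# ---------------------------------------------------------------------------


def saturation_vapor_pressure(T):
    """Saturation vapor pressure (kPa) at air temperature T (degC)."""
    T = np.asarray(T, dtype=float)
    out = 0.611 * 10.0 ** (7.5 * T / (T + 237.3))
    return out if out.ndim else float(out)


def _skin_temperature(Ta, RH, U, Qsr):
    wind = 0.116 * np.asarray(U, dtype=float) ** 0.53
    num = (
        0.173 * Ta
        - (0.1 - RH / 1000.0) * 10.0 ** (7.5 * Ta / (237.5 + Ta))
        + wind * (Ta + 5.0 * Qsr / 1000.0)
        + 31.608
    )
    return num / (wind + 1.0)


def _sweating_rate(Ts):
    Ts = np.asarray(Ts, dtype=float)
    quad = 1.1665 * Ts**2 - 64.166 * Ts + 894.35
    lin = 4.2976 * Ts - 71.289
    return np.where(Ts < 35.0, quad, lin)  # Ts == 35 goes to the linear branch


# Hilpert cylinder-in-crossflow bands: (Re upper bound, C, m).  Re below the
# first tabulated band reuses the lowest band; Re = 0 yields Nu = 0 (forced
# convection only).
_HILPERT_BANDS = (
    (4.0, 0.989, 0.330),
    (40.0, 0.911, 0.385),
    (4000.0, 0.683, 0.466),
    (40000.0, 0.193, 0.618),
    (np.inf, 0.027, 0.805),
)
_PRANDTL_AIR = 0.71


def nusselt(U, constants: PhysicalConstants = PhysicalConstants()):
    """Nusselt number for the cow-as-cylinder crossflow model (0 at U = 0)."""
    _check_u(U)
    U = np.asarray(U, dtype=float)
    Re = U * constants.d / constants.nu_air
    out = np.zeros_like(Re)
    lower = 0.0
    for upper, C, m in _HILPERT_BANDS:
        mask = (Re > lower) & (Re <= upper)
        if np.any(mask):
            out = np.where(mask, C * Re ** m * _PRANDTL_AIR ** (1.0 / 3.0), out)
        lower = upper
    return out if out.ndim else float(out)


def thermal_state(Ta, RH, U, Qsr, constants: PhysicalConstants = PhysicalConstants()) -> ThermalState:
    """Compute the intermediate physiological quantities for each observation."""
    _check_rh(RH)
    _check_u(U)
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    U = np.asarray(U, dtype=float)
    Qsr = np.asarray(Qsr, dtype=float)

    Ts = _skin_temperature(Ta, RH, U, Qsr)
    Tc = 18.76 + 0.908 * Ta - 0.011 * Ta**2
    Tex = 17.0 + 0.3 * Ta + np.exp(0.01611 * RH + 0.0387 * Ta)
    Rsw = _sweating_rate(Ts)
    Pe_a = saturation_vapor_pressure(Ta)
    Pe_b = saturation_vapor_pressure(Tex)
    # respiratory frequency as printed (two linear Ta terms)
    Fr = np.exp(2.966 + 0.0218 * Ta + 0.00069 * Ta)
    Vt = np.maximum(0.0189 * Fr - 0.463, constants.vt_floor)
    rr = 100.0 / (2.7e-4 * Fr + 5e-3)
    Nu = nusselt(U, constants)
    Trad = Ta  # mean radiant temperature approximated by air temperature
    squeeze = Ta.ndim == 0
    vals = [Ts, Tc, Tex, Rsw, Pe_a, Pe_b, Fr, Vt, rr, Nu, Trad]
    if squeeze:
        vals = [float(np.asarray(v)) for v in vals]
    return ThermalState(*vals)


def heat_fluxes(
    state: ThermalState,
    Ta,
    RH,
    constants: PhysicalConstants = PhysicalConstants(),
) -> HeatFluxes:
    """Latent and sensible heat fluxes from a :class:`ThermalState`."""
    _check_rh(RH)
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    c = constants

    if c.ambient_vapor_actual:
        Pe_ambient = (RH / 100.0) * np.asarray(state.Pe_a)
    else:
        Pe_ambient = np.asarray(state.Pe_a)

    Qresp = (
        np.asarray(state.Fr) * np.asarray(state.Vt) * c.rho_cp * (np.asarray(state.Tex) - Ta)
        / (60.0 * c.S)
        + c.rho_cp * (np.asarray(state.Pe_b) - Pe_ambient) / (c.gamma * np.asarray(state.rr))
    )
    Qevap = np.asarray(state.Rsw) * c.lam / 3600.0
    Qconv = (np.asarray(state.Tc) - Ta) * c.k_a * np.asarray(state.Nu) / c.d
    Tbar_k = (np.asarray(state.Tc) + np.asarray(state.Trad)) / 2.0 + 273.15
    Qrad = (np.asarray(state.Tc) - np.asarray(state.Trad)) * 4.0 * c.sigma * c.epsilon * Tbar_k**3
    Qlat = Qresp + Qevap
    Qsens = Qconv + Qrad
    squeeze = Ta.ndim == 0 and np.asarray(state.Tc).ndim == 0
    vals = [Qresp, Qevap, Qconv, Qrad, Qlat, Qsens]
    if squeeze:
        vals = [float(np.asarray(v)) for v in vals]
    return HeatFluxes(*vals)


# ---------------------------------------------------------------------------
# batch mode
# ---------------------------------------------------------------------------


def compute_features(
    table: pd.DataFrame,
    constants: PhysicalConstants = PhysicalConstants(),
) -> pd.DataFrame:
    """Append the seven comfort indices and six heat fluxes to ``table``.

    Requires columns Ta, Tbg, RH, U, Qsr.  Returns a new DataFrame.
    """
    required = ["Ta", "Tbg", "RH", "U", "Qsr"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing environment columns: {missing}")
    out = table.copy()
    Ta = out["Ta"].to_numpy(float)
    Tbg = out["Tbg"].to_numpy(float)
    RH = out["RH"].to_numpy(float)
    U = out["U"].to_numpy(float)
    Qsr = out["Qsr"].to_numpy(float)

    Tdp = dew_point(Ta, RH)
    out["THI"] = thi(Ta, RH)
    out["BGHI"] = bghi(Tbg, Tdp)
    out["ATHI"] = athi(Ta, RH, U, Qsr)
    out["CCI"] = cci(Ta, RH, U, Qsr)
    out["DHLI"] = dhli(Tbg, RH)
    out["ETIC"] = etic(Ta, RH, U, Qsr)
    out["STIC"] = stic(Ta, RH, U, Qsr)

    state = thermal_state(Ta, RH, U, Qsr, constants)
    fluxes = heat_fluxes(state, Ta, RH, constants)
    for name, arr in fluxes.as_dict().items():
        out[name] = arr
    return out
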