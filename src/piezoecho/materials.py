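"""Acoustic material properties and pointwise acoustic quantities.

Materials are described by their longitudinal velocity ``v`` (m/s), density
``rho`` (kg/m^3) and, for soft tissues, a power-law attenuation model

    alpha(f) = a * f**y      [dB/cm, f in MHz]

with constant ``a`` (dB MHz^-y cm^-1) and exponent ``y``.  The complex
propagation coefficient in a lossy medium is gamma = alpha + i*beta with
alpha in Np/m and beta the phase constant in rad/m, including the power-law
dispersion correction.  Interface behaviour is governed by the specific
acoustic impedance Z = rho*v (reported in MRayls = 1e6 kg m^-2 s^-1).

The built-in table (``load_material_table``) ships the tissue and
piezoelectric rows used throughout the package; users may load their own
delimited file with the same column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MaterialProperties",
    "PropagationCoefficient",
    "ContrastMaps",
    "load_material_table",
    "get_material",
    "propagation_coefficient",
    "contrast_maps",
    "acoustic_impedance",
    "reflection_coefficient",
    "DB_PER_NEPER",
]

#: 20*log10(e): decibels per neper for amplitude quantities.
DB_PER_NEPER = 8.6859


class MaterialError(ValueError):
    """Raised when a material lacks the fields an operation needs."""


@dataclass(frozen=True)
class MaterialProperties:
    """One row of the acoustic property table.

    Solid (piezoelectric) rows carry elastic constants E (Young's modulus,
    GPa), eta (Poisson ratio) and G (shear modulus, GPa) instead of an
    attenuation law.
    """

    name: str
    v: float                      # longitudinal velocity, m/s
    rho: float                    # density, kg/m^3
    a: Optional[float] = None     # attenuation constant, dB MHz^-y cm^-1
    y: Optional[float] = None     # attenuation exponent
    E: Optional[float] = None     # Young's modulus, GPa
    eta: Optional[float] = None   # Poisson ratio
    G: Optional[float] = None     # shear modulus, GPa

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError(f"{self.name}: velocity must be positive")
        if not self.rho > 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.a is not None and self.a < 0:
            raise ValueError(f"{self.name}: attenuation constant must be >= 0")
        if self.y is not None and not 0 < self.y <= 2:
            raise ValueError(f"{self.name}: attenuation exponent outside (0, 2]")

    @property
    def is_tissue_like(self) -> bool:
        """True when the row carries a power-law attenuation model."""
        return self.a is not None and self.y is not None


@dataclass(frozen=True)
class PropagationCoefficient:
    """Complex propagation coefficient gamma = alpha + i*beta."""

    alpha: float  # attenuation, Np/m
    beta: float   # phase constant, rad/m

    @property
    def gamma(self) -> complex:
        return complex(self.alpha, self.beta)


@dataclass(frozen=True)
class ContrastMaps:
    """Per-cell contrast of density and propagation coefficient.

    delta_rho = (rho0 - rho)/rho (dimensionless) and
    delta_gamma = gamma0**2 - (rho0/rho)*gamma**2 (m^-2, complex), both zero
    wherever the medium equals the background.
    """

    delta_rho: np.ndarray
    delta_gamma: np.ndarray
    rho0: float
    gamma0: complex


def _row_to_material(row: pd.Series) -> MaterialProperties:
    def opt(key: str) -> Optional[float]:
        val = row.get(key)
        return None if val is None or (isinstance(val, float) and np.isnan(val)) else float(val)

    return MaterialProperties(
        name=str(row["name"]), v=float(row["v"]), rho=float(row["rho"]),
        a=opt("a"), y=opt("y"), E=opt("E"), eta=opt("eta"), G=opt("G"),
    )


def load_material_table(path: Optional[str] = None) -> Dict[str, MaterialProperties]:
    """Load a material table (tab-delimited; built-in table by default)."""
    if path is None:
        with resources.files("piezoecho.data").joinpath("materials.tsv").open("r") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return {m.name: m for m in (_row_to_material(r) for _, r in df.iterrows())}


_TABLE: Optional[Dict[str, MaterialProperties]] = None


def get_material(name: str) -> MaterialProperties:
    """Fetch a material from the built-in table by name (case-sensitive)."""
    global _TABLE
    if _TABLE is None:
        _TABLE = load_material_table()
    try:
        return _TABLE[name]
    except KeyError:
        raise MaterialError(f"unknown material {name!r}; known: {sorted(_TABLE)}") from None


def power_law_attenuation_np_per_m(a, y, frequency: float):
    """Power-law attenuation a*f**y (f in MHz) converted dB/cm -> Np/m."""
    f_mhz = frequency / 1e6
    return np.asarray(a) * f_mhz ** np.asarray(y) * 100.0 / DB_PER_NEPER


def _dispersion_np_per_m(a, y, frequency: float):
    # Power-law dispersion correction, in the same table units as alpha
    # (a*f^y scaled by tan(pi*y/2)), converted dB/cm -> Np/m.  The tan form is
    # singular at y = 1; the correction is dropped there (see docs/methods.md).
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    f_mhz = frequency / 1e6
    with np.errstate(over="ignore", invalid="ignore"):
        term = a * np.tan(np.pi * y / 2.0) * f_mhz ** y * 100.0 / DB_PER_NEPER
    return np.where(np.abs(y - 1.0) < 1e-9, 0.0, term)


def propagation_coefficient(material: MaterialProperties, frequency: float) -> PropagationCoefficient:
    """Complex propagation coefficient of a tissue-like material at ``frequency`` (Hz).

    alpha follows the power law a*f**y (f in MHz, converted to Np/m); beta is
    omega/v plus the power-law dispersion correction in the same units.
    """
    if not frequency > 0:
        raise ValueError("frequency must be positive")
    if material.a is None or material.y is None:
        raise MaterialError(
            f"material {material.name!r} has no attenuation law (a, y); "
            "only tissue-like rows define a propagation coefficient"
        )
    alpha = float(power_law_attenuation_np_per_m(material.a, material.y, frequency))
    omega = 2.0 * np.pi * frequency
    beta = omega / material.v + float(_dispersion_np_per_m(material.a, material.y, frequency))
    return PropagationCoefficient(alpha=alpha, beta=beta)


def propagation_coefficient_map(a, y, v, frequency: float) -> np.ndarray:
    """Vectorised gamma = alpha + i*beta over per-cell (a, y, v) arrays."""
    alpha = power_law_attenuation_np_per_m(a, y, frequency)
    omega = 2.0 * np.pi * frequency
    beta = omega / np.asarray(v, dtype=float) + _dispersion_np_per_m(a, y, frequency)
    return alpha + 1j * beta


def contrast_maps(scene_rho: np.ndarray, scene_gamma: np.ndarray,
                  rho0: float, gamma0: complex) -> ContrastMaps:
    """Density and propagation-coefficient contrast relative to the background."""
    rho = np.asarray(scene_rho, dtype=float)
    gamma = np.asarray(scene_gamma, dtype=complex)
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(gamma.view(float)))):
        raise ValueError("non-finite per-cell property encountered")
    bad = np.flatnonzero(rho <= 0)
    if bad.size:
        raise ValueError(f"non-positive density at cell index {bad[0]}")
    delta_rho = (rho0 - rho) / rho
    delta_gamma = gamma0 ** 2 - (rho0 / rho) * gamma ** 2
    return ContrastMaps(delta_rho=delta_rho, delta_gamma=delta_gamma,
                        rho0=float(rho0), gamma0=complex(gamma0))


def acoustic_impedance(material: MaterialProperties) -> float:
    """Specific acoustic impedance Z = rho*v, in MRayls."""
    return material.rho * material.v / 1e6


def reflection_coefficient(z1: float, z2: float) -> float:
    """Normal-incidence pressure reflection coefficient (z2 - z1)/(z2 + z1).

    Positive when the second medium is acoustically harder (z2 > z1).
    """
    if not (z1 > 0 and z2 > 0):
        raise ValueError("impedances must be positive")
    return (z2 - z1) / (z2 + z1)
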