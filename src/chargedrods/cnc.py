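"""Mapping the reduced rod model onto cellulose-nanocrystal suspensions.

A suspension of rods of length ``a`` (nm) with line valency density
``xi = Z/a`` (effective elementary charges per nm) that is concentrated by
water removal, under the assumption that only the rods' own dissociated
monovalent counterions screen, follows the evaporation relation

    kappa^2 = 4 pi l_B c,   c = Z rho = xi rho* / a^2   (per nm^3)

so the reduced screening parameter along the curve is
``kappa* = sqrt(4 pi l_B xi rho*)``. If the counterions are protons the
counterion molarity sets the pH directly. The electrostatic swelling of the
excluded volume is captured by effective dimensions
``a' = a + 2/kappa`` and ``d' = d + 2/kappa``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AVOGADRO",
    "SuspensionParams",
    "evaporation_kappa",
    "rho_star_from_kappa",
    "counterion_molarity",
    "ph_from_state",
    "effective_aspect_ratio",
    "line_valency_from_material",
    "barrier_to_line_charge",
    "coupling_parameters",
    "evaporation_curve",
]

AVOGADRO = 6.02214076e23
_NM3_TO_L = 1e-24


@dataclass(frozen=True)
class SuspensionParams:
    """Physical rod-suspension parameters (lengths in nm)."""

    a_nm: float
    xi: float  # line valency density Z/a, 1/nm
    d_nm: float = 0.0  # rod width; 0 = volumeless model
    l_B_nm: float = 0.71
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if self.a_nm <= 0 or self.xi < 0 or self.d_nm < 0 or self.l_B_nm <= 0 or self.temperature_K <= 0:
            raise ValueError("suspension parameters must be positive")

    @property
    def Z(self) -> float:
        return self.xi * self.a_nm


def _check_positive(**kw: float) -> None:
    for name, val in kw.items():
        if val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")


def evaporation_kappa(xi: float, a_nm: float, l_B_nm: float, rho_star: float) -> float:
    """Reduced inverse screening length kappa* along an evaporation curve."""
    _check_positive(a_nm=a_nm, l_B_nm=l_B_nm, rho_star=rho_star)
    if xi < 0:
        raise ValueError("xi must be >= 0")
    return math.sqrt(4.0 * math.pi * l_B_nm * xi * rho_star)


def rho_star_from_kappa(kappa_star: float, xi: float, a_nm: float, l_B_nm: float) -> float:
    """Inverse of :func:`evaporation_kappa`."""
    _check_positive(a_nm=a_nm, l_B_nm=l_B_nm, xi=xi, kappa_star=kappa_star)
    return kappa_star**2 / (4.0 * math.pi * l_B_nm * xi)


def counterion_molarity(xi: float, a_nm: float, rho_star: float) -> float:
    """Dissociated monovalent counterion concentration in mol/L."""
    _check_positive(a_nm=a_nm, rho_star=rho_star)
    if xi < 0:
        raise ValueError("xi must be >= 0")
    c_per_nm3 = xi * rho_star / a_nm**2
    return c_per_nm3 / (AVOGADRO * _NM3_TO_L)


def ph_from_state(xi: float, a_nm: float, rho_star: float) -> float:
    """pH when the counterions are protons: -log10 of their molarity."""
    c = counterion_molarity(xi, a_nm, rho_star)
    if c <= 0:
        raise ValueError("no counterions: pH undefined in this model")
    return -math.log10(c)


def effective_aspect_ratio(a_nm: float, d_nm: float, debye_nm: float) -> float:
    """Electrostatically swollen aspect ratio (a + 2/kappa)/(d + 2/kappa)."""
    _check_positive(a_nm=a_nm, d_nm=d_nm)
    if debye_nm < 0:
        raise ValueError("debye_nm must be >= 0")
    return (a_nm + 2.0 * debye_nm) / (d_nm + 2.0 * debye_nm)


def line_valency_from_material(
    dims_nm: tuple[float, float, float],
    site_density: float,
    basis: str,
    mass_density_kg_m3: float | None = None,
) -> float:
    """Line valency density xi from material data for a rectangular rod.

    dims_nm = (width, height, length). ``basis='area'`` interprets
    ``site_density`` as charges per nm^2 on the four lateral faces;
    ``basis='mass'`` as ionizable sites in mol per gram of material
    (requires the mass density in kg/m^3). Returns charges per nm of rod
    length, assuming full ionization.
    """
    w, h, length = dims_nm
    _check_positive(width=w, height=h, length=length)
    if site_density < 0:
        raise ValueError("site_density must be >= 0")
    if basis == "area":
        lateral_area = 2.0 * (w + h) * length
        z_total = site_density * lateral_area
    elif basis == "mass":
        if mass_density_kg_m3 is None or mass_density_kg_m3 <= 0:
            raise ValueError("mass basis requires a positive mass_density_kg_m3")
        volume_m3 = w * h * length * 1e-27
        mass_g = mass_density_kg_m3 * volume_m3 * 1e3
        z_total = site_density * mass_g * AVOGADRO
    else:
        raise ValueError(f"basis must be 'area' or 'mass', got {basis!r}")
    return z_total / length


def barrier_to_line_charge(delta_u_reduced: float, a_nm: float, l_B_nm: float) -> float:
    """Line valency at which a reduced barrier equals the thermal energy.

    ``delta_u_reduced`` is a barrier in units of ``Z^2 l_B / a`` (the
    lattice-scan convention); solving ``Z^2 (l_B/a) du = 1`` gives the rod
    valency whose barrier is exactly k_B T, returned as xi = Z/a per nm.
    """
    _check_positive(a_nm=a_nm, l_B_nm=l_B_nm)
    if delta_u_reduced <= 0:
        raise ValueError("barrier must be positive")
    z = math.sqrt(a_nm / (l_B_nm * delta_u_reduced))
    return z / a_nm


def coupling_parameters(
    xi: float, a_nm: float, l_B_nm: float, rho_star: float, kappa_star: float
) -> dict[str, float]:
    """Electrostatic-to-thermal coupling Lambda = Z^2 l_B / ell for the
    three natural length choices ell = 1/kappa, mean spacing a rho*^(-1/3),
    and a. All three scale as xi^2 a at fixed (rho*, kappa*)."""
    _check_positive(a_nm=a_nm, l_B_nm=l_B_nm, rho_star=rho_star, kappa_star=kappa_star)
    z2lb = (xi * a_nm) ** 2 * l_B_nm
    return {
        "lambda_debye": z2lb * kappa_star / a_nm,
        "lambda_spacing": z2lb * rho_star ** (1.0 / 3.0) / a_nm,
        "lambda_rodlength": z2lb / a_nm,
    }


def evaporation_curve(
    xi: float,
    a_nm: float,
    l_B_nm: float,
    rho_stars: np.ndarray,
):
    """Evaporation path in (rho*, kappa*) with pH and coupling columns."""
    import pandas as pd

    rows = []
    for rho in np.asarray(rho_stars, dtype=float):
        ks = evaporation_kappa(xi, a_nm, l_B_nm, rho)
        row = {"rho_star": rho, "kappa_star": ks, "pH": ph_from_state(xi, a_nm, rho)}
        row.update(coupling_parameters(xi, a_nm, l_B_nm, rho, ks))
        rows.append(row)
    return pd.DataFrame(rows)
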