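"""Closed-form conduction solutions: validation oracles for the FEM and
direct implementations of the analytic field-amplification claims.

Two classic results are housed here.

*Inclusion in a uniform field.*  A homogeneous circular (2D) or spherical
(3D) inclusion of conductivity ``sigma_in`` in a medium ``sigma_out`` under
a uniform applied field E0 has a uniform interior field and a surface field
whose pole enhancement is

    sphere3D:    3 sigma_in / (sigma_in + 2 sigma_out)   (-> 3 as sigma_in -> inf)
    cylinder2D:  2 sigma_in / (sigma_in + sigma_out)     (-> 2)

The conductor limit of the 3D result is the often-quoted "factor of 3"
near-field amplification of a conductive nanoparticle.  The 2D value (2) is
the analogue consistent with a 2D plane model; reports must state the
dimensionality to avoid conflating the two.

*Shelled cylinder (2D cell).*  A cytoplasm disc of conductivity sigma_i,
membrane shell (thickness d, sigma_m) and exterior sigma_e in a uniform
field: the potential in each region is a cos(theta) harmonic
(A r, B r + C/r, -E0 r + D/r) and the four coefficients follow from
potential and normal-current continuity at the two interfaces.  The induced
transmembrane voltage is TMV(theta) = TMV(0) cos(theta) with
TMV(0) -> 2 E0 R as sigma_m -> 0.  This is the exact no-NP limit of the
plane cell model and the oracle the FEM baseline is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InclusionSolution", "ShelledCylinderSolution",
    "inclusion_in_uniform_field", "shelled_cylinder", "shelled_cylinder_fd",
    "membrane_field_from_tmv", "relative_np_contribution",
]

V_PER_M_TO_V_PER_CM = 1e-2


class OracleError(ValueError):
    pass


# --------------------------------------------------------------------------
# Inclusion in a uniform field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InclusionSolution:
    geometry: str          # "cylinder2D" | "sphere3D"
    sigma_in: float
    sigma_out: float
    E0: float

    @property
    def _beta(self) -> float:
        si, so = self.sigma_in, self.sigma_out
        if self.geometry == "sphere3D":
            return (si - so) / (si + 2 * so)
        return (si - so) / (si + so)

    @property
    def interior_field(self) -> float:
        """Uniform field magnitude inside the inclusion."""
        si, so = self.sigma_in, self.sigma_out
        if self.geometry == "sphere3D":
            return 3 * so / (si + 2 * so) * self.E0
        return 2 * so / (si + so) * self.E0

    def surface_field(self, theta) -> np.ndarray:
        """|E| on the outer surface vs polar angle from the field axis."""
        b = self._beta
        k = 2 if self.geometry == "sphere3D" else 1
        er = (1 + k * b) * np.cos(theta)
        et = (1 - b) * np.sin(theta)
        return self.E0 * np.hypot(er, et)

    @property
    def pole_enhancement(self) -> float:
        si, so = self.sigma_in, self.sigma_out
        if self.geometry == "sphere3D":
            return 3 * si / (si + 2 * so)
        return 2 * si / (si + so)

    @property
    def max_enhancement(self) -> float:
        """max over the surface of |E|/E0 (pole for a conductive inclusion,
        equator for an insulating one)."""
        b = self._beta
        k = 2 if self.geometry == "sphere3D" else 1
        return max(abs(1 + k * b), abs(1 - b))


def inclusion_in_uniform_field(geometry: str, sigma_in: float,
                               sigma_out: float, E0: float) -> InclusionSolution:
    if geometry not in ("cylinder2D", "sphere3D"):
        raise OracleError(f"unknown geometry {geometry!r}")
    if sigma_in < 0 or sigma_out < 0 or (sigma_in == 0 and sigma_out == 0):
        raise OracleError("conductivities must be >= 0 and not both zero")
    if sigma_out == 0:
        raise OracleError("sigma_out = 0 leaves no conduction path")
    if E0 < 0:
        raise OracleError("E0 must be >= 0")
    return InclusionSolution(geometry=geometry, sigma_in=sigma_in,
                             sigma_out=sigma_out, E0=E0)


# --------------------------------------------------------------------------
# Shelled cylinder (2D cell in a uniform field)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShelledCylinderSolution:
    R: float
    d: float
    sigma_i: float
    sigma_m: float
    sigma_e: float
    E0: float
    A: float
    B: float
    C: float
    D: float

    def potential(self, r, theta) -> np.ndarray:
        """Potential of the cos(theta) harmonic solution (V)."""
        r = np.asarray(r, float)
        R1 = self.R - self.d
        f = np.where(r <= R1, self.A * r,
                     np.where(r <= self.R, self.B * r + self.C / np.maximum(r, 1e-300),
                              -self.E0 * r + self.D / np.maximum(r, 1e-300)))
        return f * np.cos(theta)

    def tmv(self, theta) -> np.ndarray:
        """Transmembrane voltage V(outer surface) - V(inner surface)."""
        R1 = self.R - self.d
        t0 = (self.B * self.R + self.C / self.R) - self.A * R1
        return t0 * np.cos(np.asarray(theta, float))

    def membrane_radial_field(self, theta) -> np.ndarray:
        """Thickness-averaged radial field in the membrane, = TMV/d (V/m)."""
        return self.tmv(theta) / self.d

    @property
    def tmv_peak(self) -> float:
        return float(abs(self.tmv(0.0)))


def shelled_cylinder(R: float, d: float, sigma_i: float, sigma_m: float,
                     sigma_e: float, E0: float) -> ShelledCylinderSolution:
    """Exact three-region cos(theta) harmonic solution.

    The 4x4 interface system enforces continuity of potential and of radial
    current sigma dV/dr at r = R-d and r = R.
    """
    if not 0 < d < R:
        raise OracleError("need 0 < d < R")
    if min(sigma_i, sigma_m, sigma_e) <= 0:
        raise OracleError("conductivities must be positive")
    R1 = R - d
    M = np.array([
        [R1, -R1, -1 / R1, 0],
        [sigma_i, -sigma_m, sigma_m / R1 ** 2, 0],
        [0, R, 1 / R, -1 / R],
        [0, sigma_m, -sigma_m / R ** 2, sigma_e / R ** 2],
    ])
    b = np.array([0.0, 0.0, -E0 * R, -sigma_e * E0])
    A, B, C, D = np.linalg.solve(M, b)
    return ShelledCylinderSolution(R=R, d=d, sigma_i=sigma_i, sigma_m=sigma_m,
                                   sigma_e=sigma_e, E0=E0, A=A, B=B, C=C, D=D)


def shelled_cylinder_fd(R: float, d: float, sigma_i: float, sigma_m: float,
                        sigma_e: float, E0: float, far_factor: float = 200.0,
                        n_bulk: int = 8000) -> float:
    """Independent brute-force check: the radial profile f(r) of the
    cos(theta) harmonic satisfies (r sigma f')' - sigma f / r = 0; solve it
    by conservative finite differences and return |TMV(0)|.

    Kept deliberately separate from :func:`shelled_cylinder` (different
    discretisation, no shared code) so it can serve as an oracle for the
    oracle.
    """
    from scipy.sparse import diags
    from scipy.sparse.linalg import spsolve

    R1, Rfar = R - d, far_factor * R
    r = np.unique(np.concatenate([
        np.linspace(R / n_bulk, R1, n_bulk // 4),
        np.linspace(R1, R, 2001),
        R + (Rfar - R) * np.linspace(0, 1, n_bulk // 2) ** 3,
    ]))
    n = len(r)
    sig_node = np.where(r <= R1, sigma_i, np.where(r <= R, sigma_m, sigma_e))
    rm = 0.5 * (r[:-1] + r[1:])
    sig_face = np.where(rm <= R1, sigma_i, np.where(rm <= R, sigma_m, sigma_e))
    h = np.diff(r)
    main = np.zeros(n)
    lo = np.zeros(n - 1)
    up = np.zeros(n - 1)
    rhs = np.zeros(n)
    wl = rm[:-1] * sig_face[:-1] / h[:-1]
    wr = rm[1:] * sig_face[1:] / h[1:]
    main[1:-1] = -(wl + wr) - sig_node[1:-1] * 0.5 * (h[:-1] + h[1:]) / r[1:-1]
    lo[:-1] = wl
    up[1:] = wr
    main[0] = 1.0
    main[-1] = 1.0
    rhs[-1] = -E0 * Rfar
    f = spsolve(diags([lo, main, up], [-1, 0, 1], format="csc"), rhs)
    iR1 = int(np.searchsorted(r, R1))
    iR = int(np.searchsorted(r, R))
    return float(abs(f[iR] - f[iR1]))


# --------------------------------------------------------------------------
# Scalar conversions
# --------------------------------------------------------------------------

def membrane_field_from_tmv(tmv: float, thickness: float) -> float:
    """Uniform-field estimate of the in-membrane field, in V/cm.

    0.5 V across a 5 nm membrane gives 1e6 V/cm -- the scale against which
    any nanoparticle gap-field amplification must be judged.
    """
    if thickness <= 0:
        raise OracleError("thickness must be positive")
    return tmv / thickness * V_PER_M_TO_V_PER_CM


def relative_np_contribution(gap_peak_field: float, membrane_field: float) -> float:
    """Gap-field peak as a percentage of the in-membrane field."""
    if membrane_field <= 0:
        raise OracleError("membrane_field must be positive")
    return 100.0 * gap_peak_field / membrane_field
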