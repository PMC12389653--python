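"""Analytic 2D geometry for the cell/membrane/nanoparticle model.

The geometry is deliberately kept analytic (circles, a capsule, a rectangle)
rather than polygonal: region membership, signed distances and interface
curves are all evaluated in closed form, and the mesher places nodes exactly
on the analytic interfaces.  Regions:

* ``exterior``      extracellular medium (rectangle minus cell minus NP)
* ``membrane``      the thin annulus R-d <= r <= R (minus any embedded NP)
* ``cytoplasm``     r < R-d
* ``nanoparticle``  disc or capsule, absent in the baseline

In embedded mode the NP overlaps the membrane annulus; the membrane region is
the annulus minus the NP, i.e. the membrane is locally thinned to
``membrane_thickness - embed_depth`` beneath the NP centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (NPShape, PlacementMode, ScenarioSpec)

REGIONS = ("exterior", "membrane", "cytoplasm", "nanoparticle")
REGION_ID = {name: i for i, name in enumerate(REGIONS)}


class GeometryError(ValueError):
    """Raised for geometrically impossible scenarios."""


@dataclass(frozen=True)
class NPGeometry:
    """Resolved nanoparticle placement: a disc (segment of length 0) or a
    capsule around the axis segment ``p1``--``p2`` with radius ``radius``."""

    shape: NPShape
    radius: float
    p1: np.ndarray
    p2: np.ndarray
    center: np.ndarray
    mode: PlacementMode

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the NP surface (< 0 inside)."""
        pts = np.atleast_2d(pts)
        d = self.p2 - self.p1
        L2 = float(d @ d)
        if L2 == 0.0:
            return np.hypot(*(pts - self.p1).T) - self.radius
        t = np.clip(((pts - self.p1) @ d) / L2, 0.0, 1.0)
        proj = self.p1 + t[:, None] * d
        return np.hypot(*(pts - proj).T) - self.radius

    def boundary_points(self, spacing: float) -> np.ndarray:
        """Points along the NP surface at approximately uniform arc spacing."""
        a = self.radius
        d = self.p2 - self.p1
        L = math.hypot(*d)
        if L == 0.0:
            n = max(12, int(round(2 * math.pi * a / spacing)))
            th = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
            return self.center + a * np.c_[np.cos(th), np.sin(th)]
        u = d / L
        phi = math.atan2(u[1], u[0])
        n_cap = max(4, int(round(math.pi * a / spacing)))
        n_side = max(2, int(round(L / spacing)))
        th1 = phi + np.linspace(math.pi / 2, 3 * math.pi / 2, n_cap + 1)
        cap1 = self.p1 + a * np.c_[np.cos(th1), np.sin(th1)]
        th2 = phi + np.linspace(-math.pi / 2, math.pi / 2, n_cap + 1)
        cap2 = self.p2 + a * np.c_[np.cos(th2), np.sin(th2)]
        nvec = np.array([-u[1], u[0]])
        t = np.linspace(0.0, 1.0, n_side + 1)[1:-1, None]
        side1 = self.p1 + t * d - a * nvec
        side2 = self.p1 + t * d + a * nvec
        return np.vstack([cap1, side1, cap2, side2])

    def area(self) -> float:
        a = self.radius
        L = math.hypot(*(self.p2 - self.p1))
        return math.pi * a * a + 2 * a * L


@dataclass(frozen=True)
class Geometry:
    """Fully resolved scenario geometry (a window thereof for submodels)."""

    spec: ScenarioSpec
    R: float
    d: float
    width: float
    height: float
    np_geom: Optional[NPGeometry] = None
    #: (xmin, xmax, ymin, ymax) of the meshed box; full domain by default.
    window: tuple[float, float, float, float] = field(default=None)  # type: ignore

    def __post_init__(self):
        if self.window is None:
            object.__setattr__(
                self, "window",
                (-self.width / 2, self.width / 2, -self.height / 2, self.height / 2))

    @property
    def is_window(self) -> bool:
        full = (-self.width / 2, self.width / 2, -self.height / 2, self.height / 2)
        return self.window != full

    def region_of(self, pts: np.ndarray) -> np.ndarray:
        """Region id for each point (NP wins overlaps -> embedded thinning)."""
        pts = np.atleast_2d(pts)
        r = np.hypot(pts[:, 0], pts[:, 1])
        out = np.full(len(pts), REGION_ID["exterior"], dtype=np.int32)
        out[r <= self.R] = REGION_ID["membrane"]
        out[r < self.R - self.d] = REGION_ID["cytoplasm"]
        if self.np_geom is not None:
            out[self.np_geom.signed_distance(pts) < 0.0] = REGION_ID["nanoparticle"]
        return out

    def min_np_membrane_distance(self) -> float:
        """Closest NP-surface to membrane-outer-surface distance (negative if
        the NP penetrates the membrane)."""
        if self.np_geom is None:
            raise GeometryError("baseline geometry has no nanoparticle")
        g = self.np_geom
        # distance from cell centre to the axis segment
        d = g.p2 - g.p1
        L2 = float(d @ d)
        if L2 == 0.0:
            dist_axis = math.hypot(*g.p1)
        else:
            t = min(1.0, max(0.0, float((-g.p1) @ d) / L2))
            p = g.p1 + t * d
            dist_axis = math.hypot(*p)
        return dist_axis - g.radius - self.R

    def membrane_thickness_at(self, theta: float) -> float:
        """Local membrane thickness along the radial direction at angle
        ``theta`` (thinned where an embedded NP dips into the annulus)."""
        n = np.array([math.cos(theta), math.sin(theta)])
        lo, hi = self.R - self.d, self.R
        if self.np_geom is not None:
            # bisect for the NP surface along the ray between lo and hi
            f = lambda r: float(self.np_geom.signed_distance((r * n)[None])[0])
            if f(hi) < 0.0:
                a, b = lo, hi
                if f(a) < 0.0:
                    return 0.0
                for _ in range(80):
                    mid = 0.5 * (a + b)
                    if f(mid) < 0.0:
                        b = mid
                    else:
                        a = mid
                hi = 0.5 * (a + b)
        return hi - lo

    def region_areas(self) -> dict[str, float]:
        """Analytic region areas (full-domain geometry only)."""
        total = self.width * self.height
        a_cyt = math.pi * (self.R - self.d) ** 2
        a_mem = math.pi * self.R ** 2 - a_cyt
        a_np = 0.0
        overlap = 0.0
        if self.np_geom is not None:
            a_np = self.np_geom.area()
            if self.np_geom.mode is PlacementMode.EMBEDDED:
                overlap = _disc_annulus_overlap(self)
        return {
            "cytoplasm": a_cyt,
            "membrane": a_mem - overlap,
            "nanoparticle": a_np,
            "exterior": total - a_cyt - a_mem - (a_np - overlap),
        }


def _disc_annulus_overlap(geom: Geometry) -> float:
    """Area of NP-annulus overlap for an embedded disc (circle-circle lens
    between the NP and the outer membrane circle; the inner circle is not
    reached because embed_depth < membrane thickness)."""
    g = geom.np_geom
    if g.shape is not NPShape.DISC:  # pragma: no cover - only discs embed here
        raise GeometryError("embedded capsules are not supported analytically")
    D = math.hypot(*g.center)
    return _lens_area(geom.R, g.radius, D)


def _lens_area(r1: float, r2: float, D: float) -> float:
    if D >= r1 + r2:
        return 0.0
    if D <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = math.acos((D * D + r1 * r1 - r2 * r2) / (2 * D * r1))
    a2 = math.acos((D * D + r2 * r2 - r1 * r1) / (2 * D * r2))
    return (r1 * r1 * (a1 - math.sin(2 * a1) / 2)
            + r2 * r2 * (a2 - math.sin(2 * a2) / 2))


def build_geometry(spec: ScenarioSpec) -> Geometry:
    """Resolve a validated scenario into exact analytic curves.

    Coordinate convention: cell centre at the origin, electrode normal along
    +x, NP at ``angular_position`` measured from +x.
    """
    R = spec.cell.radius
    d = spec.cell.membrane_thickness
    W, H = spec.domain.width, spec.domain.height
    np_geom = None
    ns = spec.nanoparticle
    if ns is not None:
        theta = ns.angular_position
        nvec = np.array([math.cos(theta), math.sin(theta)])
        if ns.placement_mode is PlacementMode.GAP:
            r_axis = R + ns.gap_distance + ns.radius
        else:
            r_axis = R - ns.embed_depth + ns.radius
        if ns.shape is NPShape.DISC:
            c = r_axis * nvec
            p1 = p2 = c
        else:
            h = ns.length / 2 - ns.radius  # axis segment half-length
            phi = ns.orientation
            disc = r_axis * r_axis - (h * math.sin(phi)) ** 2
            if disc <= 0:
                raise GeometryError("capsule cannot reach the required clearance")
            # nearest axis point to the cell centre: an endpoint when the
            # perpendicular foot falls outside the segment, else the foot
            D = h * math.cos(phi) + math.sqrt(disc)
            if abs(D * math.cos(phi)) > h:
                pass  # endpoint case, D already solves |c - h u| = r_axis
            else:
                D = r_axis / abs(math.sin(phi))
            c = D * nvec
            tvec = np.array([-nvec[1], nvec[0]])
            u = math.cos(phi) * nvec + math.sin(phi) * tvec
            p1, p2 = c - h * u, c + h * u
        geom_np = NPGeometry(shape=ns.shape, radius=ns.radius,
                             p1=np.asarray(p1, float), p2=np.asarray(p2, float),
                             center=np.asarray(c, float), mode=ns.placement_mode)
        extent = max(math.hypot(*geom_np.p1), math.hypot(*geom_np.p2)) + ns.radius
        if extent >= min(W, H) / 2 * 0.5:
            raise GeometryError("nanoparticle too close to the domain wall")
        np_geom = geom_np
    return Geometry(spec=spec, R=R, d=d, width=W, height=H, np_geom=np_geom)


def extract_submodel(geom: Geometry, window_halfwidth: Optional[float] = None) -> Geometry:
    """Local rectangular window centred on the NP for two-stage submodeling.

    The window boundary is intended to carry Dirichlet data interpolated from
    a global solve (see :func:`nanofield.fem.solve_submodel`).  Default
    half-width: 20 NP radii.
    """
    if geom.np_geom is None:
        raise GeometryError("submodel extraction requires a nanoparticle")
    if window_halfwidth is None:
        window_halfwidth = 20.0 * geom.np_geom.radius
    cx, cy = geom.np_geom.center
    w = window_halfwidth
    xmin, xmax, ymin, ymax = cx - w, cx + w, cy - w, cy + w
    if (xmin < -geom.width / 2 or xmax > geom.width / 2
            or ymin < -geom.height / 2 or ymax > geom.height / 2):
        raise GeometryError("submodel window exceeds the domain")
    return Geometry(spec=geom.spec, R=geom.R, d=geom.d, width=geom.width,
                    height=geom.height, np_geom=geom.np_geom,
                    window=(xmin, xmax, ymin, ymax))


def baseline_geometry(geom: Geometry) -> Geometry:
    """The same geometry with the NP removed (for matched re-tagging)."""
    return Geometry(spec=geom.spec, R=geom.R, d=geom.d, width=geom.width,
                    height=geom.height, np_geom=None, window=geom.window)
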