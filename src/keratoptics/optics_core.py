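"""Surface geometry and exact vector refraction for sequential ray tracing.

The kernel works on three surface families that nest into each other:

* ``biconic`` — independent radii/conics in the two principal planes,

  .. math::

     z(x, y) = \\frac{c_x x^2 + c_y y^2}
                     {1 + \\sqrt{1 - (1+k_x) c_x^2 x^2 - (1+k_y) c_y^2 y^2}}

  with curvatures :math:`c_x = 1/R_x`, :math:`c_y = 1/R_y`;
* ``aspheric`` — the rotationally symmetric special case
  (:math:`R_x = R_y`, :math:`k_x = k_y`);
* ``spherical`` — additionally :math:`k = 0`; and ``plane``.

Conventions: the optical axis is z, increasing toward the retina; y is the
sagittal/meridional direction; a positive radius puts the center of
curvature on the +z side.  All lengths are millimetres.

Scalar entry points (:func:`sag`, :func:`surface_normal`, :func:`refract`,
:func:`intersect`) mirror vectorized bundle routines used by the system
tracer; both share the same math.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "SurfaceSpec",
    "Ray",
    "ApertureError",
    "SagDomainError",
    "ALIVE",
    "VIGNETTED",
    "TIR",
    "MISSED",
    "sag",
    "sag_bundle",
    "sag_gradient_bundle",
    "surface_normal",
    "intersect",
    "intersect_bundle",
    "refract",
    "refract_bundle",
]

# ray status codes (kept as small ints so bundles are plain integer arrays)
ALIVE = 0
VIGNETTED = 1
TIR = 2
MISSED = 3

_STATUS_NAMES = {ALIVE: "alive", VIGNETTED: "vignetted", TIR: "tir", MISSED: "missed"}


class ApertureError(ValueError):
    """Point lies outside the surface's semi-aperture."""


class SagDomainError(ValueError):
    """Point beyond surface definition (sqrt argument negative)."""


@dataclass(frozen=True)
class SurfaceSpec:
    """One refracting (or terminating) interface.

    Parameters
    ----------
    kind : {"plane", "spherical", "aspheric", "biconic"}
    Ry, Rx : float or None
        Signed radii (mm) in the sagittal (y) and transverse (x) planes.
        ``None`` for planes.
    ky, kx : float
        Conic constants (dimensionless).
    semi_aperture : float
        Clear semi-diameter in mm.
    vertex_z : float
        Axial position of the vertex.
    """

    kind: str
    Ry: Optional[float] = None
    Rx: Optional[float] = None
    ky: float = 0.0
    kx: float = 0.0
    semi_aperture: float = 5.0
    vertex_z: float = 0.0
    is_stop: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "spherical", "aspheric", "biconic"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.kind == "plane":
            return
        if self.Ry is None or self.Rx is None:
            raise ValueError(f"{self.kind} surface requires radii")
        if self.Ry == 0.0 or self.Rx == 0.0:
            raise ValueError("|R| must be > 0 for curved surfaces")
        if self.kind == "spherical":
            if self.Ry != self.Rx or self.ky != 0.0 or self.kx != 0.0:
                raise ValueError("spherical requires Ry=Rx and ky=kx=0")
        elif self.kind == "aspheric":
            if self.Ry != self.Rx or self.ky != self.kx:
                raise ValueError("aspheric requires Ry=Rx and ky=kx")

    # curvature accessors (0 for planes)
    @property
    def cy(self) -> float:
        return 0.0 if self.kind == "plane" else 1.0 / self.Ry

    @property
    def cx(self) -> float:
        return 0.0 if self.kind == "plane" else 1.0 / self.Rx

    def with_vertex(self, z: float) -> "SurfaceSpec":
        return replace(self, vertex_z=z)

    def scaled_Ry(self, factor: float) -> "SurfaceSpec":
        """Return a copy with Ry (and Rx, for rotationally symmetric kinds)
        multiplied by ``factor``; used by the mold-tolerance analysis."""
        if self.kind == "plane":
            return self
        if self.kind == "biconic":
            return replace(self, Ry=self.Ry * factor)
        return replace(self, Ry=self.Ry * factor, Rx=self.Rx * factor)


@dataclass
class Ray:
    """A single ray: position, unit direction, accumulated optical path."""

    origin: np.ndarray
    direction: np.ndarray
    opl: float = 0.0
    status: int = ALIVE

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            self.direction = self.direction / norm

    @property
    def status_name(self) -> str:
        return _STATUS_NAMES[self.status]


# ---------------------------------------------------------------------------
# sag and normals
# ---------------------------------------------------------------------------

def _sag_core(surface: SurfaceSpec, x, y):
    """Sag and sqrt-argument arrays; arg < 0 marks out-of-domain points."""
    if surface.kind == "plane":
        z = np.zeros_like(np.asarray(x, dtype=float) + np.asarray(y, dtype=float))
        return z, np.ones_like(z)
    cx, cy = surface.cx, surface.cy
    kx, ky = surface.kx, surface.ky
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    arg = 1.0 - (1.0 + kx) * cx * cx * x * x - (1.0 + ky) * cy * cy * y * y
    with np.errstate(invalid="ignore"):
        z = (cx * x * x + cy * y * y) / (1.0 + np.sqrt(np.maximum(arg, 0.0)))
    return z, arg


def sag_bundle(surface: SurfaceSpec, x, y):
    """Vectorized sag; returns (z, valid_mask)."""
    z, arg = _sag_core(surface, x, y)
    return z, arg >= 0.0


def sag(surface: SurfaceSpec, x: float, y: float) -> float:
    """Axial height of the surface above its vertex tangent plane (mm)."""
    z, arg = _sag_core(surface, x, y)
    if np.any(arg < 0.0):
        raise SagDomainError("point beyond surface definition")
    return float(z)


def sag_gradient_bundle(surface: SurfaceSpec, x, y):
    """Partial derivatives (dz/dx, dz/dy) of the sag, vectorized."""
    if surface.kind == "plane":
        x = np.asarray(x, dtype=float)
        return np.zeros_like(x), np.zeros_like(x)
    cx, cy = surface.cx, surface.cy
    kx, ky = surface.kx, surface.ky
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    arg = 1.0 - (1.0 + kx) * cx * cx * x * x - (1.0 + ky) * cy * cy * y * y
    s = np.sqrt(np.maximum(arg, 1e-300))
    denom = 1.0 + s
    u = cx * x * x + cy * y * y
    fx = 2.0 * cx * x / denom + u * (1.0 + kx) * cx * cx * x / (s * denom * denom)
    fy = 2.0 * cy * y / denom + u * (1.0 + ky) * cy * cy * y / (s * denom * denom)
    return fx, fy


def surface_normal(surface: SurfaceSpec, x: float, y: float) -> np.ndarray:
    """Unit surface normal at (x, y), oriented toward -z (against incoming
    light travelling in +z); at the vertex it is (0, 0, 1) up to sign
    convention — we return the +z-pointing normal for convenience."""
    r = float(np.hypot(x, y))
    if r > surface.semi_aperture * (1.0 + 1e-12):
        raise ApertureError("point outside semi-aperture")
    _, arg = _sag_core(surface, x, y)
    if np.any(arg < 0.0):
        raise SagDomainError("point beyond surface definition")
    fx, fy = sag_gradient_bundle(surface, x, y)
    n = np.array([-float(fx), -float(fy), 1.0])
    return n / np.linalg.norm(n)


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

def intersect_bundle(P, D, surface: SurfaceSpec, status=None,
                     tol: float = 1e-12, max_iter: int = 60,
                     clip_aperture: bool = True):
    """Intersect a bundle of rays with a surface (Newton from the
    tangent-plane solution, bisection-style damping on domain exits).

    Parameters
    ----------
    P, D : (N, 3) arrays — positions and unit directions.
    status : (N,) int array, updated in place semantics (a copy is returned).

    Returns
    -------
    points : (N, 3) intersection points (NaN where dead),
    t : (N,) path lengths,
    status : (N,) updated status codes.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    n = P.shape[0]
    status = np.zeros(n, dtype=int) if status is None else np.array(status, dtype=int)
    alive = status == ALIVE
    t = np.zeros(n)
    dz = D[:, 2]
    bad = alive & (np.abs(dz) < 1e-14)
    status[bad] = MISSED
    alive = status == ALIVE
    # tangent-plane start
    t[alive] = (surface.vertex_z - P[alive, 2]) / D[alive, 2]
    if surface.kind != "plane":
        act = alive.copy()
        for _ in range(max_iter):
            if not act.any():
                break
            x = P[act, 0] + t[act] * D[act, 0]
            y = P[act, 1] + t[act] * D[act, 1]
            z = P[act, 2] + t[act] * D[act, 2]
            zs, arg = _sag_core(surface, x, y)
            out = arg < 0.0
            if out.any():
                # pull out-of-domain rays halfway back toward the vertex plane
                idx = np.where(act)[0][out]
                t0 = (surface.vertex_z - P[idx, 2]) / D[idx, 2]
                tnew = 0.5 * (t[idx] + t0)
                stuck = np.abs(tnew - t[idx]) < 1e-15
                t[idx] = tnew
                if stuck.any():
                    status[idx[stuck]] = MISSED
                    act[idx[stuck]] = False
                continue
            g = z - surface.vertex_z - zs
            fx, fy = sag_gradient_bundle(surface, x, y)
            gp = D[act, 2] - (fx * D[act, 0] + fy * D[act, 1])
            small = np.abs(gp) < 1e-14
            step = np.where(small, 0.0, g / np.where(small, 1.0, gp))
            t[act] = t[act] - step
            conv = np.abs(g) < tol
            done = np.where(act)[0][conv | small]
            status[np.where(act)[0][small & ~conv]] = MISSED
            act[done] = False
        still = act & (status == ALIVE)
        status[still] = MISSED
    alive = status == ALIVE
    # negative path: surface behind the ray
    status[alive & (t < -1e-9)] = MISSED
    alive = status == ALIVE
    pts = np.full_like(P, np.nan)
    pts[alive] = P[alive] + t[alive, None] * D[alive]
    if clip_aperture:
        r = np.hypot(pts[alive, 0], pts[alive, 1])
        vig = np.where(alive)[0][r > surface.semi_aperture * (1.0 + 1e-12)]
        status[vig] = VIGNETTED
    return pts, t, status


def intersect(ray: Ray, surface: SurfaceSpec, n_medium: float = 1.0
              ) -> Tuple[np.ndarray, Ray]:
    """Scalar intersection; returns (point, ray advanced to the surface with
    opl accumulated as n_medium * geometric path)."""
    pts, t, status = intersect_bundle(ray.origin[None, :], ray.direction[None, :],
                                      surface, np.array([ray.status]))
    st = int(status[0])
    if st != ALIVE:
        return pts[0], Ray(ray.origin, ray.direction, ray.opl, st)
    new = Ray(pts[0], ray.direction, ray.opl + n_medium * float(t[0]), ALIVE)
    return pts[0], new


# ---------------------------------------------------------------------------
# refraction
# ---------------------------------------------------------------------------

def refract_bundle(D, N, n1, n2, status=None):
    """Vector Snell refraction for direction/normal bundles.

    ``n1`` / ``n2`` may be scalars or per-ray arrays (the latter is needed
    at gradient-index boundaries).  Normals are re-oriented per ray so they
    oppose the incident direction; rays with sin(theta2) > 1 are flagged
    TIR.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    N = np.atleast_2d(np.asarray(N, dtype=float))
    n = D.shape[0]
    status = np.zeros(n, dtype=int) if status is None else np.array(status, dtype=int)
    alive = status == ALIVE
    out = D.copy()
    with np.errstate(invalid="ignore"):
        cosi = -np.einsum("ij,ij->i", D, N)
        flip = cosi < 0.0
        N = np.where(flip[:, None], -N, N)
        cosi = np.abs(cosi)
        eta = np.broadcast_to(np.asarray(n1, dtype=float)
                              / np.asarray(n2, dtype=float), (n,))
        k = 1.0 - eta * eta * (1.0 - cosi * cosi)
        tir = alive & (k < 0.0)
        status[tir] = TIR
        ok = status == ALIVE
        T = (eta[ok, None] * D[ok]
             + (eta[ok] * cosi[ok] - np.sqrt(k[ok]))[:, None] * N[ok])
        T /= np.linalg.norm(T, axis=1)[:, None]
        out[ok] = T
    return out, status


def refract(direction, normal, n1: float, n2: float) -> np.ndarray:
    """Scalar refraction; raises on total internal reflection via status.

    Returns the transmitted unit direction.  n1 = n2 returns the input
    direction unchanged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    D = np.asarray(direction, dtype=float)[None, :]
    N = np.asarray(normal, dtype=float)[None, :]
    out, status = refract_bundle(D, N, n1, n2)
    if status[0] == TIR:
        ray = Ray(np.zeros(3), direction, 0.0, TIR)
        raise TotalInternalReflection(ray)
    return out[0]


class TotalInternalReflection(ValueError):
    """sin(theta2) would exceed 1; carries the dead ray."""

    def __init__(self, ray: Ray):
        super().__init__("total internal reflection")
        self.ray = ray
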