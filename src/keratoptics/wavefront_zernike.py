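"""Pupil wavefront sampling and OSA/ANSI Zernike decomposition.

The wavefront error of a prescription at one field angle is sampled by
tracing a bundle of real rays through a regular grid of aperture-stop
coordinates (iterative ray aiming), referencing each ray's optical path to
the chief ray on the exit-pupil sphere centered at the chief ray's retinal
intersection.  The resulting optical path difference (OPD) map is fitted by
linear least squares against the first 15 OSA-normalized Zernike modes
(radial order n <= 4).

OSA conventions: normalization N_n^m = sqrt(2(n+1)/(1+delta_m0)),
cosine azimuthal dependence for m >= 0 and sine for m < 0, single index
j = (n(n+2)+m)/2.  Modes with n-|m| odd vanish identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .eye_model import EyePrescription, trace_system
from .optics_core import ALIVE

__all__ = [
    "OSA_MODES", "OPTIMIZED_MODES", "osa_index", "zernike_eval",
    "zernike_design_matrix", "OPDMap", "ZernikeCoefficients",
    "sample_opd", "fit_zernike", "named_aberrations",
    "wavefront_from_coeffs", "DEFAULT_FIELDS",
]

#: the five field angles (degrees, along the meridian) used throughout.
DEFAULT_FIELDS = (10.0, 5.0, 0.0, -5.0, -10.0)

#: first 15 OSA modes (n, m), ordered by the OSA single index j.
OSA_MODES: List[Tuple[int, int]] = [
    (n, m) for n in range(5) for m in range(-n, n + 1, 2)
]

#: modes retained as optimization operands: piston, tip and tilt excluded
#: (they are artifacts of the aberrometry reference, not image-quality
#: terms).
OPTIMIZED_MODES = [(n, m) for (n, m) in OSA_MODES if n >= 2]


def osa_index(n: int, m: int) -> int:
    """OSA/ANSI single index j = (n(n+2)+m)/2."""
    return (n * (n + 2) + m) // 2


def _radial(n: int, am: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k) * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)))
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_eval(n: int, m: int, rho, theta):
    """OSA-normalized Zernike polynomial Z_n^m(rho, theta).

    Returns 0 identically when n - |m| is odd (vanishing radial part).
    Raises for rho outside [0, 1].
    """
    if abs(m) > n:
        raise ValueError("|m| must not exceed n")
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < -1e-12) or np.any(rho > 1.0 + 1e-12):
        raise ValueError("rho outside [0, 1]")
    if (n - abs(m)) % 2 == 1:
        return np.zeros(np.broadcast(rho, theta).shape)
    norm = math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
    rad = _radial(n, abs(m), rho)
    if m >= 0:
        ang = np.cos(m * theta)
    else:
        ang = np.sin(-m * theta)
    val = norm * rad * ang
    return val


def zernike_design_matrix(rho: np.ndarray, theta: np.ndarray,
                          modes=None) -> np.ndarray:
    modes = OSA_MODES if modes is None else modes
    return np.column_stack([zernike_eval(n, m, rho, theta)
                            for (n, m) in modes])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OPDMap:
    """OPD samples on a square grid over the unit pupil disk.

    ``opd`` is in micrometres relative to the chief ray; NaN outside the
    mask.  ``px, py`` are normalized stop coordinates in [-1, 1].
    """

    px: np.ndarray
    py: np.ndarray
    opd: np.ndarray
    mask: np.ndarray
    field_angle: float
    wavelength_nm: float
    pupil_diameter: float = 4.0
    meta: dict = field(default_factory=dict)

    @property
    def grid_n(self) -> int:
        return self.opd.shape[0]


@dataclass
class ZernikeCoefficients:
    """Fitted coefficients (micrometres) for the 15 OSA modes of one field."""

    coeffs: Dict[Tuple[int, int], float]
    field_angle: float = 0.0
    wavelength_nm: float = 589.0
    rms_residual: float = 0.0

    def get(self, n: int, m: int) -> float:
        return self.coeffs.get((n, m), 0.0)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.coeffs.get(nm, 0.0) for nm in OSA_MODES])

    @classmethod
    def from_vector(cls, vec, field_angle: float = 0.0,
                    wavelength_nm: float = 589.0,
                    rms_residual: float = 0.0) -> "ZernikeCoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.size != len(OSA_MODES):
            raise ValueError("expected one coefficient per OSA mode")
        return cls({nm: float(v) for nm, v in zip(OSA_MODES, vec)},
                   field_angle, wavelength_nm, rms_residual)

    def optimized_vector(self) -> np.ndarray:
        """The 12 image-quality modes (piston/tip/tilt dropped)."""
        return np.array([self.coeffs.get(nm, 0.0) for nm in OPTIMIZED_MODES])


def named_aberrations(z: ZernikeCoefficients) -> Dict[str, float]:
    """The four headline terms: defocus Z(2,0), vertical astigmatism Z(2,2),
    horizontal coma Z(3,1), spherical aberration Z(4,0), in micrometres."""
    return {
        "defocus": z.get(2, 0),
        "vertical_astigmatism": z.get(2, 2),
        "horizontal_coma": z.get(3, 1),
        "spherical": z.get(4, 0),
    }


def wavefront_from_coeffs(coeffs, grid_n: int = 128):
    """Reconstruct a wavefront grid (um) from a 15-vector or coefficient
    object; returns (px, py, W, mask)."""
    if isinstance(coeffs, ZernikeCoefficients):
        vec = coeffs.vector
    else:
        vec = np.asarray(coeffs, dtype=float)
    u = np.linspace(-1.0, 1.0, grid_n)
    px, py = np.meshgrid(u, u)
    rho = np.hypot(px, py)
    mask = rho <= 1.0 + 1e-12
    theta = np.arctan2(py, px)
    W = np.zeros_like(px)
    A = zernike_design_matrix(np.clip(rho[mask], 0, 1), theta[mask])
    W[mask] = A @ vec
    W[~mask] = np.nan
    return px, py, W, mask


# ---------------------------------------------------------------------------
# wavefront sampling by ray aiming
# ---------------------------------------------------------------------------

def _field_direction(field_angle_deg: float) -> np.ndarray:
    # fields sweep the transverse (x-z) plane: this is the plane the
    # aberration-versus-angle analysis uses, and it makes the cosine modes
    # (vertical astigmatism Z(2,2), horizontal coma Z(3,1)) the
    # field-driven terms while the sine modes vanish by y-symmetry.
    th = math.radians(field_angle_deg)
    return np.array([math.sin(th), 0.0, math.cos(th)])


class _Launcher:
    """Maps launch-plane coordinates Q=(qx,qy) to rays with a common phase
    origin, for either an infinite or a finite object conjugate."""

    def __init__(self, eye: EyePrescription, field_angle: float,
                 object_vergence_D: float):
        self.d0 = _field_direction(field_angle)
        surfs = eye.positioned_surfaces()
        self.z_launch = surfs[0].vertex_z - 5.0
        if object_vergence_D == 0.0:
            self.obj = None
        else:
            L = 1000.0 / abs(object_vergence_D)
            self.obj = np.array([0.0, 0.0, surfs[0].vertex_z]) - L * self.d0

    def rays(self, Q: np.ndarray):
        nq = Q.shape[0]
        P = np.column_stack([Q[:, 0], Q[:, 1], np.full(nq, self.z_launch)])
        if self.obj is None:
            D = np.tile(self.d0, (nq, 1))
            opl0 = P @ self.d0 - self.z_launch * self.d0[2]
        else:
            D = P - self.obj
            D /= np.linalg.norm(D, axis=1)[:, None]
            opl0 = np.zeros(nq)  # common phase at the object point
            P = np.tile(self.obj, (nq, 1))
        return P, D, opl0


def _aim_chief(eye: EyePrescription, launcher: _Launcher,
               tol: float = 1e-9, max_iter: int = 30):
    """Newton-aim a single ray to the stop center; returns (Q, Jacobian)."""
    surfs = eye.positioned_surfaces()
    z_stop = surfs[eye.stop_index].vertex_z
    d0 = launcher.d0
    qx0 = -d0[0] / d0[2] * (z_stop - launcher.z_launch)
    Q = np.array([[qx0, 0.0]])
    delta = 0.05
    J = None
    for it in range(max_iter):
        probe = np.vstack([Q, Q + [delta, 0.0], Q + [0.0, delta]])
        P, D, opl0 = launcher.rays(probe)
        res = trace_system(eye, P, D, opl0)
        hits = res.stop_hits
        if not np.all(np.isfinite(hits[0])):
            raise RuntimeError("chief ray failed to trace")
        err = hits[0]
        if np.hypot(*err) < tol:
            if J is None:
                J = np.column_stack([(hits[1] - hits[0]) / delta,
                                     (hits[2] - hits[0]) / delta])
            return Q[0], J
        J = np.column_stack([(hits[1] - hits[0]) / delta,
                             (hits[2] - hits[0]) / delta])
        Q = Q - np.linalg.solve(J, err)[None, :]
    raise RuntimeError("chief ray aiming did not converge")


def _exit_pupil_z(eye: EyePrescription, object_vergence_D: float) -> float:
    """Axial exit-pupil position: image-space chief ray of a small field,
    extrapolated back to its axis crossing."""
    launcher = _Launcher(eye, 0.25, object_vergence_D)
    Q, _ = _aim_chief(eye, launcher)
    P, D, opl0 = launcher.rays(Q[None, :])
    res = trace_system(eye, P, D, opl0)
    p, d = res.P[0], res.D[0]
    t = -p[0] / d[0]
    return float(p[2] + t * d[2])


def sample_opd(eye: EyePrescription, field_angle: float, grid_n: int = 64,
               object_vergence_D: float = 0.0, aim_tol: float = 1e-8,
               grin_step: float = 0.01, _apply_plate: bool = True) -> OPDMap:
    """Sample the wavefront OPD over the pupil at one field angle.

    A collimated bundle (or a diverging one for a finite object vergence,
    e.g. -1.4 D near focus) is aimed through a ``grid_n`` x ``grid_n`` grid
    of aperture-stop coordinates.  OPD is in micrometres, positive where a
    ray's optical path to the exit-pupil reference sphere exceeds the chief
    ray's.
    """
    if grid_n < 32:
        raise ValueError("grid_n must be >= 32")
    launcher = _Launcher(eye, field_angle, object_vergence_D)
    Qc, J = _aim_chief(eye, launcher)
    Jinv = np.linalg.inv(J)

    r_stop = eye.pupil_diameter / 2.0
    u = np.linspace(-1.0, 1.0, grid_n)
    px, py = np.meshgrid(u, u)
    disk = np.hypot(px, py) <= 1.0 + 1e-12
    targets = np.column_stack([px[disk], py[disk]]) * r_stop
    ntar = targets.shape[0]

    Q = Qc[None, :] + targets @ Jinv.T
    res = None
    good = np.zeros(ntar, dtype=bool)
    for _ in range(15):
        P, D, opl0 = launcher.rays(Q)
        res = trace_system(eye, P, D, opl0, grin_step=grin_step)
        hits = res.stop_hits
        finite = np.all(np.isfinite(hits), axis=1)
        err = np.where(finite[:, None], hits - targets, 0.0)
        good = finite & (np.hypot(err[:, 0], err[:, 1]) < aim_tol)
        if np.all(good | ~finite):
            break
        upd = finite & ~good
        Q[upd] -= err[upd] @ Jinv.T

    # chief ray: exit state and retinal image point
    Pc, Dc, oplc = launcher.rays(Qc[None, :])
    chief_exit = trace_system(eye, Pc, Dc, oplc, grin_step=grin_step)
    chief_img = trace_system(eye, Pc, Dc, oplc, to_image=True,
                             grin_step=grin_step)
    if chief_img.status[0] != ALIVE:
        raise RuntimeError("chief ray failed to reach the retina")
    C = chief_img.P[0]

    if abs(field_angle) < 1e-9:
        z_exp = _exit_pupil_z(eye, object_vergence_D)
    else:
        p, d = chief_exit.P[0], chief_exit.D[0]
        z_exp = float(p[2] - p[0] / d[0] * d[2])
    R_ref = float(np.linalg.norm(C - np.array([0.0, 0.0, z_exp])))

    n_img = eye.n_image

    def opl_to_sphere(P, D, opl):
        PC = P - C
        b = np.einsum("ij,ij->i", D, PC)
        disc = b * b - (np.einsum("ij,ij->i", PC, PC) - R_ref * R_ref)
        with np.errstate(invalid="ignore"):
            t = -b - np.sqrt(disc)
        return opl + n_img * t

    opl_chief = float(opl_to_sphere(chief_exit.P, chief_exit.D,
                                    chief_exit.opl)[0])
    alive = res.status == ALIVE
    opl_tot = opl_to_sphere(res.P, res.D, res.opl)
    opd_flat = np.full(ntar, np.nan)
    ok = alive & good & np.isfinite(opl_tot)
    opd_flat[ok] = (opl_tot[ok] - opl_chief) * 1000.0  # mm -> um

    opd = np.full(px.shape, np.nan)
    opd[disk] = opd_flat
    mask = np.zeros(px.shape, dtype=bool)
    mask[disk] = ok

    if _apply_plate and eye.phase_plate is not None:
        vec = None
        for k, v in eye.phase_plate.items():
            if abs(k - field_angle) < 1e-9:
                vec = np.asarray(v, dtype=float)
                break
        if vec is None:
            raise KeyError(f"phase plate has no record for field "
                           f"{field_angle} deg")
        rho = np.clip(np.hypot(px[mask], py[mask]), 0.0, 1.0)
        theta = np.arctan2(py[mask], px[mask])
        A = zernike_design_matrix(rho, theta)
        opd[mask] = opd[mask] - A @ vec

    return OPDMap(px=px, py=py, opd=opd, mask=mask, field_angle=field_angle,
                  wavelength_nm=eye.wavelength_nm,
                  pupil_diameter=eye.pupil_diameter,
                  meta={"chief_image_point": C, "exit_pupil_z": z_exp,
                        "object_vergence_D": object_vergence_D,
                        "n_rays": int(mask.sum())})


def fit_zernike(opd: OPDMap, max_n: int = 4) -> ZernikeCoefficients:
    """Least-squares fit of the masked OPD samples to the OSA basis."""
    modes = [(n, m) for (n, m) in OSA_MODES if n <= max_n]
    m = opd.mask
    if m.sum() < len(modes):
        raise ValueError("too few unmasked samples for a stable fit")
    rho = np.clip(np.hypot(opd.px[m], opd.py[m]), 0.0, 1.0)
    theta = np.arctan2(opd.py[m], opd.px[m])
    A = zernike_design_matrix(rho, theta, modes)
    vals = opd.opd[m]
    sol, *_ = np.linalg.lstsq(A, vals, rcond=None)
    resid = vals - A @ sol
    rms = float(np.sqrt(np.mean(resid ** 2)))
    coeffs = {nm: float(c) for nm, c in zip(modes, sol)}
    for nm in OSA_MODES:
        coeffs.setdefault(nm, 0.0)
    return ZernikeCoefficients(coeffs, opd.field_angle, opd.wavelength_nm,
                               rms_residual=rms)
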