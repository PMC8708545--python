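"""Fourier-optics image quality: PSF, OTF, Strehl ratio, phase-plate
baseline correction, and simulated retinal images.

The pupil function is uniform in amplitude over the disk with phase
2*pi*OPD/lambda; the point spread function is its zero-padded FFT power
spectrum (Fraunhofer propagation to the retina), sum-normalized.  The
Strehl ratio is the conventional orientation — aberrated peak over
aberration-free peak — so it lies in [0, 1] for pure phase aberrations.

The "standard Zernike phase plate" baseline correction is an ideal OPD
screen conjugate to the pupil: a fixed per-field Zernike wavefront captured
from a reference system (including the -1.4 D near-focus vergence) and
subtracted from every subsequent wavefront, so the reference system itself
maps to a flat wavefront and any modified-cornea system shows exactly its
aberration difference from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .eye_model import EyePrescription, trace_system
from .wavefront_zernike import (DEFAULT_FIELDS, OPDMap, ZernikeCoefficients,
                                fit_zernike, sample_opd,
                                wavefront_from_coeffs)

__all__ = [
    "ImagingResult", "NEAR_FOCUS_D", "compute_psf", "compute_otf",
    "strehl_ratio", "strehl_from_opd", "strehl_from_coeffs",
    "phase_plate_correction",
    "capture_baseline", "simulate_retinal_image", "retinal_scale_mm_per_rad",
    "psf_pixel_pitch_mm", "imaging_result",
]

#: accommodation state used when capturing baseline wavefront data:
#: the near focus is -1.4 D (object at ~714 mm).
NEAR_FOCUS_D = -1.4


@dataclass
class ImagingResult:
    """PSF / OTF / Strehl / retinal image bundle for one configuration."""

    psf: np.ndarray
    otf: np.ndarray
    strehl: float
    retinal_image: Optional[np.ndarray] = None
    pitch_mm: Optional[float] = None
    provenance: dict = field(default_factory=dict)


def _pupil_grids(opd_grid: np.ndarray, mask: np.ndarray, wavelength_nm: float,
                 padding: int):
    n = opd_grid.shape[0]
    if padding < 2:
        raise ValueError("zero-padding factor must be >= 2 to avoid aliasing")
    lam_um = wavelength_nm / 1000.0
    phase = np.zeros_like(opd_grid)
    phase[mask] = 2.0 * np.pi * opd_grid[mask] / lam_um
    pupil = np.zeros((n, n), dtype=complex)
    pupil[mask] = np.exp(1j * phase[mask])
    big = np.zeros((n * padding, n * padding), dtype=complex)
    big[:n, :n] = pupil
    return big


def compute_psf(opd: OPDMap | np.ndarray, mask: Optional[np.ndarray] = None,
                wavelength_nm: float = 589.0, padding: int = 4) -> np.ndarray:
    """Diffraction PSF intensity grid (sum-normalized, centered).

    Accepts an :class:`OPDMap` or a raw (grid, mask) pair with OPD in um.
    """
    if isinstance(opd, OPDMap):
        grid, mask, wavelength_nm = opd.opd, opd.mask, opd.wavelength_nm
    else:
        grid = np.asarray(opd, dtype=float)
        if mask is None:
            raise ValueError("mask required with a raw OPD grid")
    big = _pupil_grids(grid, mask, wavelength_nm, padding)
    amp = np.fft.fftshift(np.fft.fft2(big))
    psf = np.abs(amp) ** 2
    return psf / psf.sum()


def compute_otf(psf: np.ndarray) -> np.ndarray:
    """Complex OTF of a centered, normalized PSF; OTF(0,0) = 1."""
    otf = np.fft.fft2(np.fft.ifftshift(psf))
    return otf / otf[0, 0]


def strehl_ratio(psf: np.ndarray, psf_ideal: np.ndarray) -> float:
    """Peak ratio of an aberrated PSF to the aberration-free PSF computed
    with identical pupil sampling and normalization."""
    if psf.shape != psf_ideal.shape:
        raise ValueError("PSF grids must share shape and sampling")
    return float(psf.max() / psf_ideal.max())


def strehl_from_opd(opd: OPDMap, padding: int = 4) -> float:
    """Strehl ratio of one OPD map against the unaberrated pupil."""
    psf = compute_psf(opd, padding=padding)
    flat = np.zeros_like(opd.opd)
    psf0 = compute_psf(flat, opd.mask, opd.wavelength_nm, padding)
    return strehl_ratio(psf, psf0)


def strehl_from_coeffs(coeffs, mask_grid_n: int = 128,
                       wavelength_nm: float = 589.0, padding: int = 4,
                       drop_piston_tilt: bool = True) -> float:
    """Strehl ratio from a 15-mode Zernike wavefront (um).

    Piston and tilt are removed by default: they displace the PSF without
    degrading it, and retaining them merely shifts the peak off-grid.
    """
    if isinstance(coeffs, ZernikeCoefficients):
        vec = coeffs.vector.copy()
    else:
        vec = np.asarray(coeffs, dtype=float).copy()
    if drop_piston_tilt:
        vec[:3] = 0.0
    _, _, W, mask = wavefront_from_coeffs(vec, mask_grid_n)
    W = np.where(mask, W, 0.0)
    psf = compute_psf(W, mask, wavelength_nm, padding)
    psf0 = compute_psf(np.zeros_like(W), mask, wavelength_nm, padding)
    return strehl_ratio(psf, psf0)


# ---------------------------------------------------------------------------
# phase-plate baseline correction
# ---------------------------------------------------------------------------

def capture_baseline(eye: EyePrescription,
                     fields: Iterable[float] = DEFAULT_FIELDS,
                     grid_n: int = 64,
                     object_vergence_D: float = NEAR_FOCUS_D
                     ) -> Dict[float, np.ndarray]:
    """Fit the reference system's wavefront at each field angle; returns
    the per-field 15-mode coefficient vectors (um) for the phase plate."""
    out: Dict[float, np.ndarray] = {}
    for f in fields:
        z = fit_zernike(sample_opd(eye, f, grid_n,
                                   object_vergence_D=object_vergence_D,
                                   _apply_plate=False))
        out[float(f)] = z.vector
    return out


def phase_plate_correction(eye: EyePrescription,
                           baseline: Dict[float, np.ndarray] | ZernikeCoefficients
                           ) -> EyePrescription:
    """Return a copy of the prescription with a fixed Zernike phase plate
    that subtracts the baseline wavefront (per field) from every
    subsequently sampled OPD map."""
    if isinstance(baseline, ZernikeCoefficients):
        baseline = {baseline.field_angle: baseline.vector}
    plate = {}
    for f, vec in baseline.items():
        vec = np.asarray(vec, dtype=float)
        if vec.size != 15:
            raise ValueError("phase plate requires all 15 mode coefficients")
        plate[float(f)] = vec.copy()
    new = eye.copy()
    new.phase_plate = plate
    new.label = eye.label + "+plate"
    return new


# ---------------------------------------------------------------------------
# retinal image simulation
# ---------------------------------------------------------------------------

def retinal_scale_mm_per_rad(eye: EyePrescription) -> float:
    """Retinal image height per radian of field angle, from a real chief
    ray at a small field angle."""
    from .wavefront_zernike import _Launcher, _aim_chief
    ang = 0.2
    launcher = _Launcher(eye, ang, 0.0)
    Q, _ = _aim_chief(eye, launcher)
    P, D, opl0 = launcher.rays(Q[None, :])
    res = trace_system(eye, P, D, opl0, to_image=True)
    h = float(res.P[0, 0])
    return abs(h) / np.radians(ang)


def psf_pixel_pitch_mm(eye: EyePrescription, grid_n: int,
                       padding: int = 4) -> float:
    """Retinal-plane pixel pitch of the padded PSF grid (mm/pixel)."""
    lam_mm = eye.wavelength_nm * 1e-6
    dpupil = eye.pupil_diameter / grid_n      # mm per pupil sample
    dtheta = lam_mm / (grid_n * padding * dpupil)   # rad per PSF pixel
    return retinal_scale_mm_per_rad(eye) * dtheta


def simulate_retinal_image(scene: np.ndarray, otf: np.ndarray) -> np.ndarray:
    """Incoherent imaging of an intensity scene through the system OTF.

    The scene must be sampled at the PSF pixel pitch and share the OTF's
    grid shape.  Output is clipped at zero (FFT ringing only).
    """
    if scene.shape != otf.shape:
        raise ValueError("scene and OTF grids must match")
    img = np.fft.ifft2(np.fft.fft2(scene) * otf).real
    return np.clip(img, 0.0, None)


def imaging_result(eye: EyePrescription, field_angle: float = 0.0,
                   grid_n: int = 128, padding: int = 4,
                   object_vergence_D: float = 0.0,
                   scene: Optional[np.ndarray] = None) -> ImagingResult:
    """End-to-end image quality at one field: sample the wavefront, build
    the PSF/OTF from the fitted 15-mode reconstruction, and optionally
    image a scene sampled at the PSF pitch."""
    opd = sample_opd(eye, field_angle, grid_n,
                     object_vergence_D=object_vergence_D)
    z = fit_zernike(opd)
    vec = z.vector.copy()
    vec[:3] = 0.0  # piston/tip/tilt: measurement artifacts, not blur
    _, _, W, mask = wavefront_from_coeffs(vec, grid_n)
    W = np.where(mask, W, 0.0)
    psf = compute_psf(W, mask, eye.wavelength_nm, padding)
    psf0 = compute_psf(np.zeros_like(W), mask, eye.wavelength_nm, padding)
    otf = compute_otf(psf)
    image = None
    pitch = psf_pixel_pitch_mm(eye, grid_n, padding)
    if scene is not None:
        image = simulate_retinal_image(scene, otf)
    return ImagingResult(psf=psf, otf=otf,
                         strehl=strehl_ratio(psf, psf0),
                         retinal_image=image, pitch_mm=pitch,
                         provenance={"label": eye.label,
                                     "field_angle": field_angle,
                                     "grid_n": grid_n, "padding": padding,
                                     "object_vergence_D": object_vergence_D,
                                     "coeffs_um": z.vector.tolist()})
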