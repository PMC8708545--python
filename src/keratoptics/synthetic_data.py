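"""Synthetic inputs: defective patient eyes, letter stimuli, and OPD maps
with known Zernike content.

Every generator is a pure function of its arguments (and seed), so test
fixtures and pipeline demonstrations need no data files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .eye_model import (EQUIVALENT_LENS_INDEX, EyePrescription,
                        build_baseline_eye)
from .wavefront_zernike import (OPDMap, ZernikeCoefficients, fit_zernike,
                                sample_opd, zernike_design_matrix)

__all__ = ["DefectSpec", "generate_defective_eye", "generate_letter_scene",
           "generate_synthetic_opd", "GLYPHS"]


@dataclass(frozen=True)
class DefectSpec:
    """Requested refractive defect, expressed as aberration increments over
    the unperturbed baseline (um of OSA Zernike coefficient at 4 mm pupil,
    on axis): ``defocus_um`` adds Z(2,0), ``astigmatism_um`` adds Z(2,2).

    ``channel`` selects which anatomical parameters carry the perturbation.
    Perturbations are capped at +/-10% of the baseline anatomy.
    """

    seed: int = 0
    defocus_um: float = 0.0
    astigmatism_um: float = 0.0
    channel: str = "cornea_radii"  # cornea_radii | conics | chamber_depth

    def __post_init__(self):
        if self.channel not in ("cornea_radii", "conics", "chamber_depth"):
            raise ValueError(f"unknown channel {self.channel!r}")


_MAX_FRAC = 0.10  # anatomical plausibility cap on any perturbed parameter


def _perturbed(baseline: EyePrescription, channel: str, s: float,
               g: float) -> EyePrescription:
    """Apply the common (s) and differential (g) perturbations."""
    from dataclasses import replace
    eye = baseline.copy()
    i = eye.cornea_index
    ant = eye.surfaces[i]
    post = eye.surfaces[i + 1]
    if channel == "cornea_radii":
        eye.surfaces[i] = replace(ant, Ry=ant.Ry * (1 + s + g),
                                  Rx=ant.Rx * (1 + s))
        eye.surfaces[i + 1] = replace(post, Ry=post.Ry * (1 + s + g),
                                      Rx=post.Rx * (1 + s))
    elif channel == "conics":
        eye.surfaces[i] = replace(ant, ky=ant.ky + s + g, kx=ant.kx + s)
    elif channel == "chamber_depth":
        eye.thicknesses[i + 1] = eye.thicknesses[i + 1] * (1 + s)
    eye.label = baseline.label + "+defect"
    return eye


def _measure(eye: EyePrescription, grid_n: int) -> tuple:
    z = fit_zernike(sample_opd(eye, 0.0, grid_n))
    return z.get(2, 0), z.get(2, 2)


def generate_defective_eye(spec: DefectSpec,
                           baseline: Optional[EyePrescription] = None,
                           grid_n: int = 32, rel_tol: float = 0.10
                           ) -> EyePrescription:
    """Calibrate a perturbed prescription whose on-axis defocus/astigmatism
    increments match the requested targets (secant iteration on the
    perturbation magnitudes, measured through the wavefront pipeline).

    Deterministic under ``spec.seed``.  Raises if the target cannot be
    reached within +/-10% anatomical perturbations.
    """
    if baseline is None:
        baseline = build_baseline_eye(lens_index=EQUIVALENT_LENS_INDEX)
    if spec.defocus_um == 0.0 and spec.astigmatism_um == 0.0:
        return baseline.copy()
    if spec.channel == "chamber_depth" and spec.astigmatism_um != 0.0:
        raise ValueError("astigmatism target unreachable through the "
                         "chamber-depth channel")
    rng = np.random.default_rng(spec.seed)
    d0, a0 = _measure(baseline, grid_n)

    def err(s, g):
        d, a = _measure(_perturbed(baseline, spec.channel, s, g), grid_n)
        return (d - d0) - spec.defocus_um, (a - a0) - spec.astigmatism_um

    tol_d = max(rel_tol * abs(spec.defocus_um) / 2, 1e-4)
    tol_a = max(rel_tol * abs(spec.astigmatism_um) / 2, 1e-4)
    s, g = 0.0, 0.0
    for _ in range(3):  # alternate 1-D secants; coupling is weak
        if spec.defocus_um != 0.0 or s != 0.0:
            s = _secant(lambda v: err(v, g)[0], s,
                        s + 0.01 * (1 + 0.1 * rng.random()), tol_d)
        if spec.astigmatism_um != 0.0 or g != 0.0:
            g = _secant(lambda v: err(s, v)[1], g,
                        g + 0.01 * (1 + 0.1 * rng.random()), tol_a)
        ed, ea = err(s, g)
        if abs(ed) <= 2 * tol_d and abs(ea) <= 2 * tol_a:
            break
    if abs(s) > _MAX_FRAC or abs(g) > _MAX_FRAC:
        raise ValueError("requested defect unreachable within +/-10% anatomy")
    return _perturbed(baseline, spec.channel, s, g)


def _secant(f, x0, x1, tol, max_iter=12, cap=_MAX_FRAC):
    f0, f1 = f(x0), f(x1)
    for _ in range(max_iter):
        if abs(f1) <= tol:
            return x1
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        x2 = float(np.clip(x2, -cap, cap))
        x0, f0, x1 = x1, f1, x2
        f1 = f(x1)
    if abs(f1) > tol:
        raise ValueError("secant calibration did not converge")
    return x1


# ---------------------------------------------------------------------------
# letter stimuli
# ---------------------------------------------------------------------------

#: 5x7 stroke glyphs (rows top to bottom); deterministic across platforms,
#: no font dependency.
GLYPHS = {
    "F": ["11111", "10000", "10000", "11110", "10000", "10000", "10000"],
    "E": ["11111", "10000", "10000", "11110", "10000", "10000", "11111"],
    "L": ["10000", "10000", "10000", "10000", "10000", "10000", "11111"],
    "T": ["11111", "00100", "00100", "00100", "00100", "00100", "00100"],
    "H": ["10001", "10001", "10001", "11111", "10001", "10001", "10001"],
    "I": ["11111", "00100", "00100", "00100", "00100", "00100", "11111"],
    "P": ["11110", "10001", "10001", "11110", "10000", "10000", "10000"],
    " ": ["00000"] * 7,
}


def generate_letter_scene(letter: str, size_mm: float = 0.025,
                          grid_n: int = 256,
                          pitch_mm: Optional[float] = None,
                          supersample: int = 4) -> np.ndarray:
    """Antialiased high-contrast letter on a black background.

    The glyph's vertical extent is ``size_mm`` (0.025 mm matches a 20/20
    Snellen optotype on the retina).  With ``pitch_mm`` unset the grid
    spans twice the letter height; otherwise the grid is ``grid_n`` pixels
    at the given physical pitch (e.g. the PSF pixel pitch, for imaging).
    """
    if letter not in GLYPHS:
        raise ValueError(f"no glyph for {letter!r}")
    rows = GLYPHS[letter]
    if pitch_mm is None:
        pitch_mm = 2.0 * size_mm / grid_n
    ss = supersample
    n_fine = grid_n * ss
    pitch_fine = pitch_mm / ss
    half = n_fine / 2.0
    # physical coordinates of fine-pixel centers, origin at grid center
    coords = (np.arange(n_fine) - half + 0.5) * pitch_fine
    X, Y = np.meshgrid(coords, -coords)  # +y up
    h = size_mm
    w = size_mm * 5.0 / 7.0
    col = np.floor((X + w / 2.0) / (w / 5.0)).astype(int)
    row = np.floor((h / 2.0 - Y) / (h / 7.0)).astype(int)
    inside = (col >= 0) & (col < 5) & (row >= 0) & (row < 7)
    fine = np.zeros((n_fine, n_fine))
    bitmap = np.array([[c == "1" for c in r] for r in rows])
    fine[inside] = bitmap[row[inside], col[inside]]
    # box-filter down to the output grid
    scene = fine.reshape(grid_n, ss, grid_n, ss).mean(axis=(1, 3))
    return scene


# ---------------------------------------------------------------------------
# synthetic OPD maps
# ---------------------------------------------------------------------------

def generate_synthetic_opd(coeffs, grid_n: int = 64, noise_sd: float = 0.0,
                           seed: int = 0, field_angle: float = 0.0,
                           wavelength_nm: float = 589.0) -> OPDMap:
    """OPD map synthesized from a 15-mode coefficient vector (um) plus
    seeded Gaussian noise on the pupil disk."""
    if isinstance(coeffs, ZernikeCoefficients):
        vec = coeffs.vector
        field_angle = coeffs.field_angle
        wavelength_nm = coeffs.wavelength_nm
    else:
        vec = np.asarray(coeffs, dtype=float)
    u = np.linspace(-1.0, 1.0, grid_n)
    px, py = np.meshgrid(u, u)
    rho = np.hypot(px, py)
    mask = rho <= 1.0 + 1e-12
    theta = np.arctan2(py, px)
    opd = np.full(px.shape, np.nan)
    A = zernike_design_matrix(np.clip(rho[mask], 0, 1), theta[mask])
    vals = A @ vec
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, vals.shape)
    opd[mask] = vals
    return OPDMap(px=px, py=py, opd=opd, mask=mask, field_angle=field_angle,
                  wavelength_nm=wavelength_nm,
                  meta={"synthetic": True, "noise_sd": noise_sd,
                        "seed": seed})
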