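"""Merit-function optimization of artificial-cornea shapes and the
mold-tolerance sweep.

The design functional is a normalized weighted least-squares merit,

    F = sqrt( sum_i W_i (V_i - T_i)^2 / sum_i W_i ),

whose operands are the 12 image-quality Zernike coefficients (piston, tip
and tilt excluded) at the five field angles (weight 10 each), plus one
structural operand per design parameter class (radii and thicknesses at
weight 1e6, conic constants at weight 1).  Structural operands are
range-violation penalties: zero inside the design ranges, the distance to
the range outside.  The ranges are additionally imposed as hard bounds on
the optimizer, so a feasible design always has zero structural
contribution.

Two clinical design cases are supported: ``with_glasses`` (targets are the
baseline eye-plus-spectacles aberrations — the implant should behave like
the natural cornea under the patient's existing correction) and
``without_glasses`` (all targets zero — the implant itself corrects the
eye).

Optimization is bounded local least squares (scipy ``least_squares``,
trust-region reflective) with seeded multi-start jitter, which reproduces
the qualitative stall behaviour of weighted least-squares lens design: the
large low-order operands (defocus, astigmatism) dominate the descent and
high-order terms improve only marginally afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .diffraction_imaging import capture_baseline, strehl_from_coeffs
from .eye_model import (DESIGN_BOUNDS, CorneaDesign, EyePrescription,
                        Material, attach_glasses, replace_cornea)
from .wavefront_zernike import (DEFAULT_FIELDS, OPTIMIZED_MODES,
                                fit_zernike, sample_opd)

__all__ = [
    "WITH_GLASSES", "WITHOUT_GLASSES", "DesignCase", "MeritSpec",
    "ZERNIKE_WEIGHT", "merit", "merit_terms", "merit_from_operands",
    "make_design_case",
    "design_aberrations", "optimize_cornea", "apply_tolerance",
    "tolerance_sweep", "case_system", "case_strehl",
    "design_from_params", "params_from_design", "reference_design",
]

WITH_GLASSES = "with_glasses"
WITHOUT_GLASSES = "without_glasses"

#: weight on every Zernike operand at every field angle.
ZERNIKE_WEIGHT = 10.0


@dataclass(frozen=True)
class DesignCase:
    """Clinical design case and where its aberration targets come from."""

    case_id: str  # WITH_GLASSES | WITHOUT_GLASSES

    def __post_init__(self):
        if self.case_id not in (WITH_GLASSES, WITHOUT_GLASSES):
            raise ValueError(f"unknown design case {self.case_id!r}")

    @property
    def wears_glasses(self) -> bool:
        return self.case_id == WITH_GLASSES


@dataclass
class MeritSpec:
    """Operand table for the merit functional."""

    case: DesignCase
    fields: Tuple[float, ...]
    targets: np.ndarray          # (n_fields, 12) um
    zernike_weight: float = ZERNIKE_WEIGHT
    grid_n: int = 32
    object_vergence_D: float = 0.0

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (len(self.fields), len(OPTIMIZED_MODES)):
            raise ValueError("targets must be (n_fields, 12)")

    @property
    def structural_weights(self) -> Dict[str, float]:
        return {name: w for name, (_lo, _hi, w) in DESIGN_BOUNDS.items()}


def make_design_case(case: DesignCase | str, baseline: EyePrescription,
                     fields: Sequence[float] = DEFAULT_FIELDS,
                     grid_n: int = 32,
                     object_vergence_D: float = 0.0) -> MeritSpec:
    """Build the operand table for a design case from the baseline eye."""
    if isinstance(case, str):
        case = DesignCase(case)
    fields = tuple(float(f) for f in fields)
    if case.wears_glasses:
        ref = attach_glasses(baseline)
        rows = [fit_zernike(sample_opd(ref, f, grid_n,
                                       object_vergence_D=object_vergence_D)
                            ).optimized_vector()
                for f in fields]
        targets = np.vstack(rows)
    else:
        targets = np.zeros((len(fields), len(OPTIMIZED_MODES)))
    return MeritSpec(case=case, fields=fields, targets=targets,
                     grid_n=grid_n, object_vergence_D=object_vergence_D)


def case_system(baseline: EyePrescription, design: CorneaDesign,
                case: DesignCase | str) -> EyePrescription:
    """The evaluable system for a design under a case (spectacles attached
    for the with-glasses case)."""
    if isinstance(case, str):
        case = DesignCase(case)
    sys_ = replace_cornea(baseline, design, validate=False)
    if case.wears_glasses:
        sys_ = attach_glasses(sys_)
    return sys_


def design_aberrations(baseline: EyePrescription, design: CorneaDesign,
                       spec: MeritSpec) -> np.ndarray:
    """Current operand values V: (n_fields, 12) fitted coefficients."""
    sys_ = case_system(baseline, design, spec.case)
    rows = [fit_zernike(sample_opd(sys_, f, spec.grid_n,
                                   object_vergence_D=spec.object_vergence_D)
                        ).optimized_vector()
            for f in spec.fields]
    return np.vstack(rows)


def _structural_violations(design: CorneaDesign) -> Dict[str, float]:
    """Distance of each structural parameter class outside its range."""
    groups = {
        "anterior_radius": (design.anterior.Ry, design.anterior.Rx),
        "posterior_radius": (design.posterior.Ry, design.posterior.Rx),
        "anterior_conic": (design.anterior.ky, design.anterior.kx),
        "posterior_conic": (design.posterior.ky, design.posterior.kx),
        "cornea_thickness": (design.thickness,),
        "chamber_thickness": (design.chamber_depth,),
    }
    out = {}
    for name, vals in groups.items():
        lo, hi, _w = DESIGN_BOUNDS[name]
        out[name] = max(max(lo - v, v - hi, 0.0) for v in vals)
    return out


def merit_terms(baseline: EyePrescription, design: CorneaDesign,
                spec: MeritSpec, V: Optional[np.ndarray] = None):
    """All operands as flat (weights, values, targets) arrays."""
    if V is None:
        V = design_aberrations(baseline, design, spec)
    W = [spec.zernike_weight] * V.size
    vals = list(V.ravel())
    tgts = list(spec.targets.ravel())
    for name, viol in _structural_violations(design).items():
        W.append(DESIGN_BOUNDS[name][2])
        vals.append(viol)
        tgts.append(0.0)
    return np.array(W), np.array(vals), np.array(tgts)


def merit_from_operands(W, V, T) -> float:
    """F = sqrt(sum W (V-T)^2 / sum W) for raw operand arrays."""
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    T = np.asarray(T, dtype=float)
    return float(np.sqrt(np.sum(W * (V - T) ** 2) / np.sum(W)))


def merit(baseline: EyePrescription, design: CorneaDesign,
          spec: MeritSpec, V: Optional[np.ndarray] = None) -> float:
    """The scalar merit F >= 0; zero iff every operand hits its target."""
    W, vals, tgts = merit_terms(baseline, design, spec, V)
    return merit_from_operands(W, vals, tgts)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

_SHAPE_PARAMS = {
    "biconic": ["ant_Ry", "ant_Rx", "ant_ky", "ant_kx",
                "post_Ry", "post_Rx", "post_ky", "post_kx",
                "thickness", "chamber"],
    "aspherical": ["ant_R", "ant_k", "post_R", "post_k",
                   "thickness", "chamber"],
    "spherical": ["ant_R", "post_R", "thickness", "chamber"],
}

_PARAM_BOUND = {
    "ant_Ry": "anterior_radius", "ant_Rx": "anterior_radius",
    "ant_R": "anterior_radius",
    "post_Ry": "posterior_radius", "post_Rx": "posterior_radius",
    "post_R": "posterior_radius",
    "ant_ky": "anterior_conic", "ant_kx": "anterior_conic",
    "ant_k": "anterior_conic",
    "post_ky": "posterior_conic", "post_kx": "posterior_conic",
    "post_k": "posterior_conic",
    "thickness": "cornea_thickness", "chamber": "chamber_thickness",
}


def design_from_params(shape: str, material: Material,
                       x: Sequence[float]) -> CorneaDesign:
    x = list(map(float, x))
    if shape == "biconic":
        aRy, aRx, aky, akx, pRy, pRx, pky, pkx, t, ch = x
    elif shape == "aspherical":
        aR, ak, pR, pk, t, ch = x
        aRy = aRx = aR
        aky = akx = ak
        pRy = pRx = pR
        pky = pkx = pk
    elif shape == "spherical":
        aR, pR, t, ch = x
        aRy = aRx = aR
        pRy = pRx = pR
        aky = akx = pky = pkx = 0.0
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return CorneaDesign.from_params(shape, material, aRy, aRx, aky, akx,
                                    pRy, pRx, pky, pkx, t, ch)


def params_from_design(design: CorneaDesign) -> np.ndarray:
    a, p = design.anterior, design.posterior
    if design.shape == "biconic":
        x = [a.Ry, a.Rx, a.ky, a.kx, p.Ry, p.Rx, p.ky, p.kx,
             design.thickness, design.chamber_depth]
    elif design.shape == "aspherical":
        x = [a.Ry, a.ky, p.Ry, p.ky, design.thickness, design.chamber_depth]
    else:
        x = [a.Ry, p.Ry, design.thickness, design.chamber_depth]
    return np.array(x, dtype=float)


def _shape_bounds(shape: str):
    lo, hi = [], []
    for pname in _SHAPE_PARAMS[shape]:
        l, h, _w = DESIGN_BOUNDS[_PARAM_BOUND[pname]]
        lo.append(l)
        hi.append(h)
    return np.array(lo), np.array(hi)


def _default_start(shape: str) -> np.ndarray:
    """Human-cornea geometry clipped into the design ranges."""
    human = {"biconic": [7.480, 7.517, -0.130, -0.136,
                         6.287, 6.704, -0.005, -0.300, 0.500, 3.639],
             "aspherical": [7.480, -0.130, 6.287, -0.005, 0.500, 3.639],
             "spherical": [7.480, 6.287, 0.500, 3.639]}[shape]
    lo, hi = _shape_bounds(shape)
    return np.clip(np.array(human), lo, hi)


def optimize_cornea(baseline: EyePrescription, shape: str,
                    material: Material, case: DesignCase | str,
                    seed: int = 0, n_starts: int = 2,
                    spec: Optional[MeritSpec] = None,
                    grid_n: int = 32, max_nfev: int = 200,
                    x0: Optional[np.ndarray] = None,
                    jitter: float = 0.25):
    """Bounded multi-start least-squares search for a cornea design.

    Returns ``(design, log)``; the log records every merit evaluation as
    ``(start_index, nfev, merit)``.  Deterministic for a given seed; among
    starts the lowest final merit wins, ties broken by the
    lexicographically smallest parameter vector.
    """
    if isinstance(case, str):
        case = DesignCase(case)
    if spec is None:
        spec = make_design_case(case, baseline, grid_n=grid_n)
    lo, hi = _shape_bounds(shape)
    rng = np.random.default_rng(seed)
    sqw = np.sqrt(spec.zernike_weight)
    norm = None  # sqrt(sum W) including structural weights, fixed
    log: List[Tuple[int, int, float]] = []

    def residuals(x, start_idx, counter):
        design = design_from_params(shape, material, x)
        V = design_aberrations(baseline, design, spec)
        r = sqw * (V - spec.targets).ravel()
        counter[0] += 1
        log.append((start_idx, counter[0],
                    merit(baseline, design, spec, V=V)))
        return r

    starts = []
    base_x = _default_start(shape) if x0 is None else np.clip(x0, lo, hi)
    starts.append(base_x)
    for _ in range(max(0, n_starts - 1)):
        x = base_x + jitter * (rng.random(base_x.size) - 0.5) * (hi - lo)
        starts.append(np.clip(x, lo, hi))

    results = []
    scale = np.where(hi - lo > 0.5, 0.2, 0.05)
    for si, x0_ in enumerate(starts):
        counter = [0]
        sol = least_squares(residuals, x0_, bounds=(lo, hi),
                            args=(si, counter), max_nfev=max_nfev,
                            x_scale=scale, diff_step=1e-4, method="trf")
        d = design_from_params(shape, material, sol.x)
        results.append((merit(baseline, d, spec), tuple(sol.x), d))
    results.sort(key=lambda r: (r[0], r[1]))
    best = results[0][2]
    if best.violations():
        raise RuntimeError("optimizer returned an out-of-bounds design")
    return best, log


# ---------------------------------------------------------------------------
# reference prescriptions
# ---------------------------------------------------------------------------

#: previously optimized artificial-cornea prescriptions for the two design
#: cases (per material and shape), used as regression inputs for the
#: mold-tolerance radius arithmetic and available as optimizer warm
#: starts.  Tuples: (ant_Ry, ant_Rx, ant_ky, ant_kx, post_Ry, post_Rx,
#: post_ky, post_kx, thickness, chamber).  A few conic constants sit
#: slightly outside the design search range; they are kept verbatim.
_REFERENCE_PARAMS = {
    WITH_GLASSES: {
        "P407DA_PHEMA": {
            "biconic": (7.408, 7.407, -0.112, -0.092,
                        6.505, 6.572, 2.3e-4, -0.033, 0.532, 3.567),
            "aspherical": (7.407, 7.407, -0.094, -0.094,
                           6.533, 6.533, -0.026, -0.026, 0.551, 3.520),
            "spherical": (7.428, 7.428, 0.0, 0.0,
                          6.479, 6.479, 0.0, 0.0, 0.554, 3.633),
        },
        "P407DA_PAA": {
            "biconic": (7.516, 7.516, -0.144, -0.130,
                        6.052, 6.284, -0.065, -0.300, 0.507, 3.646),
            "aspherical": (7.572, 7.572, -0.126, -0.126,
                           6.852, 6.852, -0.217, -0.217, 0.500, 3.633),
            "spherical": (7.595, 7.595, 0.0, 0.0,
                          6.818, 6.818, 0.0, 0.0, 0.500, 3.650),
        },
    },
    WITHOUT_GLASSES: {
        "P407DA_PHEMA": {
            "biconic": (7.483, 7.482, -0.283, -0.285,
                        6.050, 6.050, -0.326, -0.325, 0.560, 3.650),
            "aspherical": (7.526, 7.526, -0.213, -0.213,
                           6.258, 6.258, -0.090, -0.090, 0.500, 3.645),
            "spherical": (7.501, 7.501, 0.0, 0.0,
                          6.076, 6.076, 0.0, 0.0, 0.500, 3.638),
        },
        "P407DA_PAA": {
            "biconic": (7.793, 7.792, -0.278, -0.283,
                        6.050, 6.051, -0.308, -0.309, 0.560, 3.650),
            "aspherical": (7.802, 7.802, -0.330, -0.330,
                           6.860, 6.860, -0.304, -0.304, 0.500, 3.650),
            "spherical": (7.850, 7.850, 0.0, 0.0,
                          6.827, 6.827, 0.0, 0.0, 0.500, 3.650),
        },
    },
}


def reference_design(case: str, material: Material | str,
                     shape: str) -> CorneaDesign:
    """Packaged reference prescription for (case, material, shape)."""
    from .eye_model import MATERIALS
    if isinstance(material, str):
        material = MATERIALS[material]
    p = _REFERENCE_PARAMS[case][material.name][shape]
    return CorneaDesign.from_params(shape, material, *p)


# ---------------------------------------------------------------------------
# mold tolerance
# ---------------------------------------------------------------------------

def apply_tolerance(design: CorneaDesign, tol: float) -> CorneaDesign:
    """Scale the anterior and posterior sagittal radii Ry by (1 + tol).

    Mold tolerance is quoted as a fraction (|tol| <= 0.01, i.e. +/-1%);
    thickness and conics are unchanged.  For rotationally symmetric shapes
    Rx scales with Ry so the shape kind is preserved.
    """
    if abs(tol) > 0.01 + 1e-12:
        raise ValueError("mold tolerance limited to +/-1%")
    from dataclasses import replace as _replace
    return _replace(design,
                    anterior=design.anterior.scaled_Ry(1.0 + tol),
                    posterior=design.posterior.scaled_Ry(1.0 + tol))


def case_strehl(baseline: EyePrescription, design: CorneaDesign,
                case: DesignCase | str,
                plate: Optional[dict] = None,
                grid_n: int = 64, psf_grid_n: int = 128,
                object_vergence_D: float = 0.0) -> float:
    """On-axis Strehl ratio of a design under its case protocol.

    ``with_glasses``: the phase plate captured from the baseline
    eye-plus-spectacles reference is applied, so the Strehl measures the
    residual difference from the reference system.  ``without_glasses``:
    no plate; the Strehl measures the design system's own aberrations
    against the diffraction limit.
    """
    if isinstance(case, str):
        case = DesignCase(case)
    sys_ = case_system(baseline, design, case)
    if case.wears_glasses:
        if plate is None:
            ref = attach_glasses(baseline)
            plate = capture_baseline(ref, fields=(0.0,), grid_n=grid_n,
                                     object_vergence_D=object_vergence_D)
        from .diffraction_imaging import phase_plate_correction
        sys_ = phase_plate_correction(sys_, plate)
    z = fit_zernike(sample_opd(sys_, 0.0, grid_n,
                               object_vergence_D=object_vergence_D))
    return strehl_from_coeffs(z, mask_grid_n=psf_grid_n)


def tolerance_sweep(design: CorneaDesign, baseline: EyePrescription,
                    case: DesignCase | str,
                    tols: Iterable[float] = (0.01, 0.0, -0.01),
                    grid_n: int = 64, psf_grid_n: int = 128):
    """Strehl-versus-mold-tolerance table.

    Returns a list of dicts with keys ``tolerance``, ``anterior_Ry``,
    ``posterior_Ry``, ``strehl`` — one row per tolerance value.
    """
    if isinstance(case, str):
        case = DesignCase(case)
    plate = None
    if case.wears_glasses:
        ref = attach_glasses(baseline)
        plate = capture_baseline(ref, fields=(0.0,), grid_n=grid_n,
                                 object_vergence_D=0.0)
    rows = []
    for tol in tols:
        d = apply_tolerance(design, tol)
        s = case_strehl(baseline, d, case, plate=plate, grid_n=grid_n,
                        psf_grid_n=psf_grid_n)
        rows.append({"tolerance": float(tol),
                     "anterior_Ry": float(d.anterior.Ry),
                     "posterior_Ry": float(d.posterior.Ry),
                     "strehl": s})
    return rows
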