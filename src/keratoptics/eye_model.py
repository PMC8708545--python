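"""Schematic-eye assembly and paraxial properties.

Builds the wide-field schematic eye used throughout the package (biconic
cornea, conic lens and vitreous surfaces, spherical retina), optionally
with spectacles in front or with the human cornea replaced by a hydrogel
artificial-cornea design, and provides the sequential system ray tracer
and real-ray paraxial power.

The crystalline lens may be a polynomial GRIN medium or a homogeneous
equivalent-index medium.  The numeric GRIN coefficients for this
model are cited to an external age-dependent family and are therefore a
user-supplied configuration record here; the homogeneous fallback uses the
classic schematic-eye equivalent lens index 1.420.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import yaml

from .grin_media import GrinMedium, grin_index, trace_grin_bundle
from .optics_core import (ALIVE, VIGNETTED, SurfaceSpec, intersect_bundle,
                          refract_bundle, sag_gradient_bundle)

__all__ = [
    "Material", "MATERIALS", "EyePrescription", "CorneaDesign",
    "DESIGN_BOUNDS", "EQUIVALENT_LENS_INDEX", "GrinUnsetError",
    "build_baseline_eye", "attach_glasses", "detach_glasses",
    "replace_cornea", "human_cornea_design", "paraxial_power",
    "trace_system", "TraceResult", "prescription_to_yaml",
    "prescription_from_yaml",
]


@dataclass(frozen=True)
class Material:
    """Homogeneous optical medium; index quoted at 589 nm."""

    name: str
    index_589: float
    transmittance: Optional[float] = None  # %, metadata only

    def __post_init__(self):
        if not (1.0 <= self.index_589 <= 2.0):
            raise ValueError(f"index {self.index_589} outside [1, 2]")


#: material table: measured hydrogel indices, human ocular media at 589 nm,
#: and the spectacle crown glass (N-BK7 catalog value at 589 nm).
MATERIALS = {
    "air": Material("air", 1.0),
    "cornea": Material("cornea", 1.376, 87.0),
    "aqueous": Material("aqueous", 1.3374),
    "vitreous": Material("vitreous", 1.336),
    "NBK7": Material("NBK7", 1.5168),
    "P407DA_PAA": Material("P407DA_PAA", 1.3574, 95.45),
    "P407DA_PHEMA": Material("P407DA_PHEMA", 1.4232, 91.92),
}

#: classic equivalent refractive index of the crystalline lens, used as the
#: homogeneous stand-in when no GRIN coefficient record is supplied.
EQUIVALENT_LENS_INDEX = 1.420

Medium = Union[Material, GrinMedium]


class GrinUnsetError(ValueError):
    """Raised when the baseline eye is built with neither GRIN coefficients
    nor an explicit homogeneous lens index."""


# ---------------------------------------------------------------------------
# prescription container
# ---------------------------------------------------------------------------

@dataclass
class EyePrescription:
    """Ordered sequential system: surface i is followed by ``media[i]`` over
    ``thicknesses[i]`` mm; the last surface is the image surface (retina)
    and has no following medium.  ``stop_index`` marks the aperture stop."""

    surfaces: List[SurfaceSpec]
    media: List[Medium]
    thicknesses: List[float]
    stop_index: int
    pupil_diameter: float = 4.0
    wavelength_nm: float = 589.0
    object_medium: Material = MATERIALS["air"]
    cornea_index: int = 0
    has_glasses: bool = False
    label: str = "eye"
    phase_plate: Optional[dict] = None  # field angle -> 15-vector of um coeffs

    def __post_init__(self):
        ns = len(self.surfaces)
        if len(self.media) != ns - 1 or len(self.thicknesses) != ns - 1:
            raise ValueError("need one medium/thickness per gap")
        if any(t < 0 for t in self.thicknesses):
            raise ValueError("thicknesses must be >= 0")

    # -- geometry ----------------------------------------------------------
    def positioned_surfaces(self) -> List[SurfaceSpec]:
        """Surfaces with vertex_z assigned cumulatively (first vertex at 0)
        and GRIN media origins resolved."""
        out = []
        z = 0.0
        for i, s in enumerate(self.surfaces):
            out.append(s.with_vertex(z))
            if i < len(self.thicknesses):
                z += self.thicknesses[i]
        return out

    def positioned_media(self) -> List[Medium]:
        surfs = self.positioned_surfaces()
        out = []
        for i, m in enumerate(self.media):
            if isinstance(m, GrinMedium):
                m = m.with_origin(surfs[i].vertex_z, self.thicknesses[i])
            out.append(m)
        return out

    @property
    def retina(self) -> SurfaceSpec:
        return self.surfaces[-1]

    @property
    def n_image(self) -> float:
        m = self.media[-1]
        return m.index_589 if isinstance(m, Material) else m.n0

    def copy(self) -> "EyePrescription":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def surf_d(s: SurfaceSpec) -> dict:
            return {"kind": s.kind, "Ry": s.Ry, "Rx": s.Rx, "ky": s.ky,
                    "kx": s.kx, "semi_aperture": s.semi_aperture,
                    "name": s.name}

        def med_d(m: Medium) -> dict:
            if isinstance(m, GrinMedium):
                return {"grin": {k: getattr(m, k) for k in
                                 ("n0", "nr2", "nr4", "nr6",
                                  "nz1", "nz2", "nz3", "nz4")}}
            return {"material": m.name, "index_589": m.index_589}

        return {
            "label": self.label,
            "pupil_mm": self.pupil_diameter,
            "wavelength_nm": self.wavelength_nm,
            "stop_index": self.stop_index,
            "cornea_index": self.cornea_index,
            "has_glasses": self.has_glasses,
            "surfaces": [surf_d(s) for s in self.surfaces],
            "media": [med_d(m) for m in self.media],
            "thicknesses_mm": [float(t) for t in self.thicknesses],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyePrescription":
        surfaces = [SurfaceSpec(kind=s["kind"], Ry=s["Ry"], Rx=s["Rx"],
                                ky=s["ky"], kx=s["kx"],
                                semi_aperture=s["semi_aperture"],
                                is_stop=(i == d["stop_index"]),
                                name=s.get("name", ""))
                    for i, s in enumerate(d["surfaces"])]
        media: List[Medium] = []
        for m in d["media"]:
            if "grin" in m:
                media.append(GrinMedium(**m["grin"]))
            else:
                name = m["material"]
                if name in MATERIALS and MATERIALS[name].index_589 == m["index_589"]:
                    media.append(MATERIALS[name])
                else:
                    media.append(Material(name, m["index_589"]))
        return cls(surfaces=surfaces, media=media,
                   thicknesses=list(d["thicknesses_mm"]),
                   stop_index=d["stop_index"],
                   pupil_diameter=d["pupil_mm"],
                   wavelength_nm=d["wavelength_nm"],
                   cornea_index=d.get("cornea_index", 0),
                   has_glasses=d.get("has_glasses", False),
                   label=d.get("label", "eye"))


def prescription_to_yaml(eye: EyePrescription) -> str:
    return yaml.safe_dump(eye.to_dict(), sort_keys=False)


def prescription_from_yaml(text: str) -> EyePrescription:
    return EyePrescription.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# baseline eye and variants
# ---------------------------------------------------------------------------

def build_baseline_eye(*, lens_index: Optional[float] = None,
                       grin: Optional[GrinMedium] = None,
                       pupil_diameter: float = 4.0,
                       wavelength_nm: float = 589.0) -> EyePrescription:
    """Assemble the baseline wide-field schematic eye.

    The crystalline lens medium must be specified: either a
    :class:`GrinMedium` coefficient record, or ``lens_index`` for a
    homogeneous equivalent lens (:data:`EQUIVALENT_LENS_INDEX` is the
    conventional choice).
    """
    if grin is None and lens_index is None:
        raise GrinUnsetError(
            "GRIN coefficients unset: pass grin=GrinMedium(...) or a "
            "homogeneous fallback lens_index (e.g. EQUIVALENT_LENS_INDEX)")
    lens: Medium = grin if grin is not None else Material(
        "lens_equivalent", lens_index)
    r_pupil = pupil_diameter / 2.0
    surfaces = [
        SurfaceSpec("biconic", Ry=7.480, Rx=7.517, ky=-0.130, kx=-0.136,
                    semi_aperture=5.0, name="cornea_anterior"),
        SurfaceSpec("biconic", Ry=6.287, Rx=6.704, ky=-0.005, kx=-0.303,
                    semi_aperture=5.0, name="cornea_posterior"),
        SurfaceSpec("plane", semi_aperture=r_pupil, is_stop=True,
                    name="pupil"),
        SurfaceSpec("aspheric", Ry=9.533, Rx=9.533, ky=-3.203, kx=-3.203,
                    semi_aperture=4.5, name="lens_anterior"),
        SurfaceSpec("aspheric", Ry=-5.736, Rx=-5.736, ky=-0.278, kx=-0.278,
                    semi_aperture=4.5, name="lens_posterior"),
        SurfaceSpec("spherical", Ry=-13.0, Rx=-13.0, ky=0.0, kx=0.0,
                    semi_aperture=11.0, name="retina"),
    ]
    media: List[Medium] = [MATERIALS["cornea"], MATERIALS["aqueous"],
                           MATERIALS["aqueous"], lens, MATERIALS["vitreous"]]
    thicknesses = [0.500, 3.639, 0.0, 3.690, 16.000]
    return EyePrescription(surfaces=surfaces, media=media,
                           thicknesses=thicknesses, stop_index=2,
                           pupil_diameter=pupil_diameter,
                           wavelength_nm=wavelength_nm,
                           cornea_index=0, label="baseline_eye")


#: spectacle prescription: concave asymmetric N-BK7 lens, center thickness
#: 0.600 mm, worn 5.000 mm in front of the cornea (the air-gap row of the
#: spectacle table).
GLASSES_ANTERIOR = SurfaceSpec("biconic", Ry=-15.399, Rx=-15.936,
                               ky=-2.007, kx=-2.007, semi_aperture=15.0,
                               name="glasses_anterior")
GLASSES_POSTERIOR = SurfaceSpec("biconic", Ry=-16.340, Rx=-17.026,
                                ky=-2.096, kx=-2.096, semi_aperture=15.0,
                                name="glasses_posterior")
GLASSES_CENTER_THICKNESS = 0.600
DEFAULT_VERTEX_DISTANCE = 5.000


def attach_glasses(eye: EyePrescription,
                   vertex_distance: float = DEFAULT_VERTEX_DISTANCE
                   ) -> EyePrescription:
    """Prepend the spectacle lens ``vertex_distance`` mm before the cornea."""
    if vertex_distance <= 0:
        raise ValueError("vertex_distance must be > 0")
    if eye.has_glasses:
        raise ValueError("glasses already attached")
    new = eye.copy()
    new.surfaces = [GLASSES_ANTERIOR, GLASSES_POSTERIOR] + new.surfaces
    new.media = [MATERIALS["NBK7"], MATERIALS["air"]] + new.media
    new.thicknesses = [GLASSES_CENTER_THICKNESS, vertex_distance] + new.thicknesses
    new.stop_index += 2
    new.cornea_index += 2
    new.has_glasses = True
    new.label = eye.label + "+glasses"
    return new


def detach_glasses(eye: EyePrescription) -> EyePrescription:
    """Inverse of :func:`attach_glasses`."""
    if not eye.has_glasses:
        raise ValueError("no glasses attached")
    new = eye.copy()
    new.surfaces = new.surfaces[2:]
    new.media = new.media[2:]
    new.thicknesses = new.thicknesses[2:]
    new.stop_index -= 2
    new.cornea_index -= 2
    new.has_glasses = False
    new.label = new.label.replace("+glasses", "")
    return new


# ---------------------------------------------------------------------------
# artificial-cornea designs
# ---------------------------------------------------------------------------

#: hard design ranges for the artificial-cornea shape search (mm /
#: dimensionless), with the merit weight attached to each structural bound.
DESIGN_BOUNDS = {
    "anterior_radius": (7.00, 8.16, 1e6),
    "posterior_radius": (6.00, 6.90, 1e6),
    "anterior_conic": (-0.3, 0.0, 1.0),
    "posterior_conic": (-0.3, 0.0, 1.0),
    "cornea_thickness": (0.50, 0.56, 1e6),
    "chamber_thickness": (2.91, 3.65, 1e6),
}


@dataclass(frozen=True)
class CorneaDesign:
    """Artificial-cornea prescription: anterior/posterior surface shapes,
    central thickness, and the post-cornea chamber depth."""

    shape: str  # biconic | aspherical | spherical
    anterior: SurfaceSpec
    posterior: SurfaceSpec
    thickness: float
    chamber_depth: float
    material: Material

    @classmethod
    def from_params(cls, shape: str, material: Material,
                    ant_Ry: float, ant_Rx: float, ant_ky: float, ant_kx: float,
                    post_Ry: float, post_Rx: float, post_ky: float,
                    post_kx: float, thickness: float, chamber_depth: float,
                    semi_aperture: float = 5.0) -> "CorneaDesign":
        kind = {"biconic": "biconic", "aspherical": "aspheric",
                "spherical": "spherical"}[shape]
        if shape == "spherical" and (ant_ky != 0 or ant_kx != 0
                                     or post_ky != 0 or post_kx != 0):
            raise ValueError("spherical design requires zero conic constants")
        ant = SurfaceSpec(kind, Ry=ant_Ry, Rx=ant_Rx, ky=ant_ky, kx=ant_kx,
                          semi_aperture=semi_aperture, name="cornea_anterior")
        post = SurfaceSpec(kind, Ry=post_Ry, Rx=post_Rx, ky=post_ky,
                           kx=post_kx, semi_aperture=semi_aperture,
                           name="cornea_posterior")
        return cls(shape, ant, post, thickness, chamber_depth, material)

    def violations(self) -> List[str]:
        """Names of design-range bounds this prescription violates."""
        checks = [
            ("anterior_radius", self.anterior.Ry),
            ("anterior_radius", self.anterior.Rx),
            ("posterior_radius", self.posterior.Ry),
            ("posterior_radius", self.posterior.Rx),
            ("anterior_conic", self.anterior.ky),
            ("anterior_conic", self.anterior.kx),
            ("posterior_conic", self.posterior.ky),
            ("posterior_conic", self.posterior.kx),
            ("cornea_thickness", self.thickness),
            ("chamber_thickness", self.chamber_depth),
        ]
        out = []
        for name, val in checks:
            lo, hi, _w = DESIGN_BOUNDS[name]
            if not (lo - 1e-12 <= val <= hi + 1e-12):
                out.append(f"{name}={val} outside [{lo}, {hi}]")
        return out


def human_cornea_design() -> CorneaDesign:
    """The baseline eye's own cornea expressed as a design record (its
    posterior transverse conic sits outside the artificial design range, so
    replacing with it requires validate=False)."""
    return CorneaDesign.from_params(
        "biconic", MATERIALS["cornea"],
        7.480, 7.517, -0.130, -0.136,
        6.287, 6.704, -0.005, -0.303,
        0.500, 3.639)


def replace_cornea(eye: EyePrescription, design: CorneaDesign,
                   validate: bool = True) -> EyePrescription:
    """Swap the cornea surfaces/medium and the chamber depth; everything
    downstream of the pupil is untouched."""
    if validate:
        v = design.violations()
        if v:
            raise ValueError("design outside bounds: " + "; ".join(v))
    new = eye.copy()
    i = eye.cornea_index
    new.surfaces[i] = design.anterior
    new.surfaces[i + 1] = design.posterior
    new.thicknesses[i] = design.thickness
    new.thicknesses[i + 1] = design.chamber_depth
    new.media[i] = design.material
    new.label = eye.label + f"[{design.shape}:{design.material.name}]"
    return new


# ---------------------------------------------------------------------------
# sequential bundle tracer
# ---------------------------------------------------------------------------

@dataclass
class TraceResult:
    P: np.ndarray        # (N, 3) final positions
    D: np.ndarray        # (N, 3) final unit directions
    opl: np.ndarray      # (N,) accumulated optical path (mm)
    status: np.ndarray   # (N,) status codes
    stop_hits: np.ndarray  # (N, 2) x, y at the aperture stop


def _surface_normals(surface: SurfaceSpec, pts: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        fx, fy = sag_gradient_bundle(surface, pts[:, 0], pts[:, 1])
        N = np.stack([-fx, -fy, np.ones_like(fx)], axis=1)
        N /= np.linalg.norm(N, axis=1)[:, None]
    return N


def trace_system(eye: EyePrescription, P, D, opl=None, status=None, *,
                 to_image: bool = False, grin_step: float = 0.01
                 ) -> TraceResult:
    """Trace a ray bundle sequentially through the prescription.

    Rays start in the object medium before the first surface.  With
    ``to_image=False`` the trace stops after refraction at the last surface
    before the retina (rays left in the image-space medium); with
    ``to_image=True`` rays are additionally intersected with the retina.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float)).copy()
    D = np.atleast_2d(np.asarray(D, dtype=float)).copy()
    nrays = P.shape[0]
    opl = np.zeros(nrays) if opl is None else np.asarray(opl, dtype=float).copy()
    status = (np.zeros(nrays, dtype=int) if status is None
              else np.asarray(status, dtype=int).copy())
    surfs = eye.positioned_surfaces()
    media = eye.positioned_media()
    stop_hits = np.full((nrays, 2), np.nan)
    n_surf = len(surfs)
    last = n_surf if to_image else n_surf - 1
    prev_medium: Medium = eye.object_medium
    on_surface = False  # True when a GRIN trace already delivered rays here
    for i in range(last):
        s = surfs[i]
        if isinstance(prev_medium, GrinMedium):
            if not on_surface:
                raise RuntimeError("GRIN gap must deliver rays onto surface")
            n1 = np.atleast_1d(grin_index(prev_medium, P[:, 0], P[:, 1], P[:, 2]))
        else:
            pts, t, status = intersect_bundle(P, D, s, status)
            alive = status == ALIVE
            opl[alive] += prev_medium.index_589 * t[alive]
            P[alive] = pts[alive]
            n1 = np.full(nrays, prev_medium.index_589)
        if i == eye.stop_index:
            alive = status == ALIVE
            stop_hits[alive] = P[alive, :2]
            r = np.hypot(P[:, 0], P[:, 1])
            status[alive & (r > eye.pupil_diameter / 2.0 * (1 + 1e-12))] = VIGNETTED
        if i == n_surf - 1:
            break  # image surface: no refraction
        nxt = media[i]
        if isinstance(nxt, GrinMedium):
            n2 = np.atleast_1d(grin_index(nxt, P[:, 0], P[:, 1], P[:, 2]))
        else:
            n2 = np.full(nrays, nxt.index_589)
        if not (isinstance(prev_medium, Material) and isinstance(nxt, Material)
                and prev_medium.index_589 == nxt.index_589):
            N = _surface_normals(s, P)
            D, status = refract_bundle(D, N, n1, n2, status)
        if isinstance(nxt, GrinMedium):
            P, D, opl, status = trace_grin_bundle(
                P, D, opl, nxt, surfs[i + 1], grin_step, status)
            on_surface = True
        else:
            on_surface = False
        prev_medium = nxt
    return TraceResult(P, D, opl, status, stop_hits)


# ---------------------------------------------------------------------------
# paraxial power
# ---------------------------------------------------------------------------

def paraxial_power(eye: EyePrescription, h: float = 1e-3) -> float:
    """Optical power in diopters from real rays at two small heights.

    Two rays parallel to the axis at heights h and 2h are traced; the
    image-space slope gives phi(h) = -n' u'/h, Richardson-extrapolated in
    h^2 to the paraxial limit.  Power is quoted as n'/EFL in diopters.
    """
    surfs = eye.positioned_surfaces()
    z0 = surfs[0].vertex_z - 5.0

    def phi(hh: float) -> float:
        P = np.array([[0.0, hh, z0]])
        D = np.array([[0.0, 0.0, 1.0]])
        res = trace_system(eye, P, D)
        if res.status[0] != ALIVE:
            raise RuntimeError("paraxial probe ray failed to trace")
        u = res.D[0, 1] / res.D[0, 2]
        return -eye.n_image * u / hh * 1000.0  # mm^-1 -> D

    p1, p2 = phi(h), phi(2 * h)
    power = (4.0 * p1 - p2) / 3.0
    if abs(power) < 1e-9 and abs(p1) < 1e-9:
        return 0.0
    return power
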