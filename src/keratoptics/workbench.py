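"""End-to-end case experiments: optimize cornea shapes, tabulate
aberrations and tolerance Strehl ratios, render retinal images, and write
a reproducible report bundle."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .design_optimizer import (WITHOUT_GLASSES, DesignCase, case_system,
                               make_design_case, optimize_cornea,
                               tolerance_sweep)
from .diffraction_imaging import imaging_result, psf_pixel_pitch_mm
from .eye_model import (EQUIVALENT_LENS_INDEX, MATERIALS, build_baseline_eye,
                        prescription_to_yaml, replace_cornea)
from .synthetic_data import generate_letter_scene
from .wavefront_zernike import (DEFAULT_FIELDS, OSA_MODES, fit_zernike,
                                sample_opd)

__all__ = ["RunConfig", "run_case_experiment", "aberration_table",
           "save_image_pgm"]


@dataclass
class RunConfig:
    """Configuration of one case experiment; defaults reproduce the study
    settings (589 nm, 4 mm pupil, fields +/-10, +/-5, 0 deg, +/-1% mold
    tolerance)."""

    case: str = WITHOUT_GLASSES
    shapes: Tuple[str, ...] = ("biconic", "aspherical", "spherical")
    materials: Tuple[str, ...] = ("P407DA_PHEMA", "P407DA_PAA")
    fields: Tuple[float, ...] = DEFAULT_FIELDS
    wavelength_nm: float = 589.0
    pupil_mm: float = 4.0
    lens_index: float = EQUIVALENT_LENS_INDEX
    grid_n: int = 32            # pupil grid for optimization operands
    report_grid_n: int = 64     # pupil grid for reported aberrations/Strehl
    psf_grid_n: int = 128
    tolerances: Tuple[float, ...] = (0.01, 0.0, -0.01)
    letter: str = "F"
    letter_size_mm: float = 0.025
    seed: int = 0
    n_starts: int = 1
    max_nfev: int = 200
    outdir: str = "kerato_out"


def aberration_table(eye, fields: Sequence[float], grid_n: int = 64
                     ) -> pd.DataFrame:
    """Fitted 15-mode coefficients (um) per field angle."""
    rows = []
    for f in fields:
        z = fit_zernike(sample_opd(eye, f, grid_n))
        rows.append([f] + list(z.vector))
    cols = ["field_deg"] + [f"Z({n},{m})" for (n, m) in OSA_MODES]
    return pd.DataFrame(rows, columns=cols)


def save_image_pgm(path: Path, img: np.ndarray) -> None:
    """8-bit portable graymap writer (plain text format, max-normalized)."""
    arr = np.asarray(img, dtype=float)
    mx = arr.max() if arr.max() > 0 else 1.0
    pix = np.clip(arr / mx * 255.0, 0, 255).astype(int)
    lines = ["P2", f"{pix.shape[1]} {pix.shape[0]}", "255"]
    lines += [" ".join(map(str, row)) for row in pix]
    Path(path).write_text("\n".join(lines) + "\n")


def run_case_experiment(config: RunConfig) -> dict:
    """Run one full design case; returns the manifest (also written to
    ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    baseline = build_baseline_eye(lens_index=config.lens_index,
                                  pupil_diameter=config.pupil_mm,
                                  wavelength_nm=config.wavelength_nm)
    case = DesignCase(config.case)
    spec = make_design_case(case, baseline, fields=config.fields,
                            grid_n=config.grid_n)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "designs": {},
        "files": [],
    }
    float_fmt = "%.6g"
    for mi, mat_name in enumerate(config.materials):
        material = MATERIALS[mat_name]
        for si, shape in enumerate(config.shapes):
            key = f"{mat_name}_{shape}"
            seed = config.seed * 1000 + mi * 10 + si
            design, log = optimize_cornea(
                baseline, shape, material, case, seed=seed,
                n_starts=config.n_starts, spec=spec,
                max_nfev=config.max_nfev)
            sys_ = case_system(baseline, design, case)
            # prescription
            p_path = out / f"prescription_{key}.yaml"
            p_path.write_text(prescription_to_yaml(
                replace_cornea(baseline, design, validate=False)))
            # aberration table
            ab = aberration_table(sys_, config.fields, config.report_grid_n)
            ab_path = out / f"aberrations_{key}.csv"
            ab.to_csv(ab_path, index=False, float_format=float_fmt)
            # tolerance sweep
            tol = pd.DataFrame(tolerance_sweep(
                design, baseline, case, config.tolerances,
                grid_n=config.report_grid_n, psf_grid_n=config.psf_grid_n))
            tol_path = out / f"tolerance_{key}.csv"
            tol.to_csv(tol_path, index=False, float_format=float_fmt)
            # retinal image of the letter stimulus
            pitch = psf_pixel_pitch_mm(sys_, config.psf_grid_n, padding=4)
            scene = generate_letter_scene(config.letter,
                                          config.letter_size_mm,
                                          config.psf_grid_n * 4,
                                          pitch_mm=pitch)
            res = imaging_result(sys_, 0.0, config.psf_grid_n, scene=scene)
            img_path = out / f"retina_{key}.pgm"
            save_image_pgm(img_path, res.retinal_image)
            manifest["designs"][key] = {
                "seed": seed,
                "shape": shape,
                "material": mat_name,
                "params": {
                    "anterior_Ry": design.anterior.Ry,
                    "anterior_Rx": design.anterior.Rx,
                    "anterior_ky": design.anterior.ky,
                    "anterior_kx": design.anterior.kx,
                    "posterior_Ry": design.posterior.Ry,
                    "posterior_Rx": design.posterior.Rx,
                    "posterior_ky": design.posterior.ky,
                    "posterior_kx": design.posterior.kx,
                    "thickness_mm": design.thickness,
                    "chamber_mm": design.chamber_depth,
                },
                "final_merit": min(l[2] for l in log),
                "n_merit_evals": len(log),
                "strehl_rows": tol.to_dict("records"),
            }
            manifest["files"] += [str(p) for p in
                                  (p_path, ab_path, tol_path, img_path)]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
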