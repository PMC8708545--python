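# keratoptics

Physiological-optics toolkit for designing **customized artificial corneas**
(keratoprostheses) made from IPN hydrogels, and for predicting the visual
quality they deliver inside a schematic human eye.

A diseased cornea can be replaced by a molded hydrogel implant; because the
cornea supplies most of the eye's ~60 D of power, the implant's anterior and
posterior *shape* (radius, conic constant, thickness, chamber depth)
determines whether the patient sees sharply.  `keratoptics` answers the
design question numerically:

* **Sequential real ray tracing** through a wide-field schematic eye —
  biconic cornea, conic crystalline-lens and vitreous surfaces, spherical
  retina — with the lens modelled either as a polynomial gradient-index
  (GRIN) medium `n = n0 + nr2 r² + nr4 r⁴ + nr6 r⁶ + nz1 z + … + nz4 z⁴`
  (integrated with a 4th-order RK scheme) or as a homogeneous
  equivalent-index medium.
* **Wavefront analysis**: ray-aimed pupil sampling of the optical path
  difference and least-squares decomposition into the first 15 OSA/ANSI
  Zernike modes `Z_n^m(ρ,θ) = N_n^m R_n^{|m|}(ρ) · {cos, sin}(mθ)`,
  at field angles ±10°, ±5°, 0°.
* **Diffraction imaging**: pupil-function FFT point spread functions,
  OTF/MTF, Strehl ratios, Zernike phase-plate baseline correction, and
  simulated retinal images of a 0.025 mm (20/20 Snellen) letter "F".
* **Shape optimization** of spherical / aspherical / biconic hydrogel
  corneas under the weighted least-squares merit
  `F = √(Σ Wᵢ(Vᵢ−Tᵢ)² / Σ Wᵢ)` (12 Zernike modes × 5 fields at weight 10,
  structural range operands at weight 10⁶), for two clinical cases —
  the patient keeps wearing spectacles, or the implant itself corrects the
  eye — plus the ±1% mold-tolerance Strehl analysis.
* **Synthetic data**: defective "patient" eyes with calibrated injected
  defocus/astigmatism, letter stimuli, and OPD maps with known Zernike
  content, so the whole pipeline runs without any external files.

## Worked example

```python
from keratoptics.eye_model import (build_baseline_eye, attach_glasses,
                                   EQUIVALENT_LENS_INDEX, MATERIALS,
                                   paraxial_power)
from keratoptics.wavefront_zernike import sample_opd, fit_zernike, named_aberrations
from keratoptics.design_optimizer import (optimize_cornea, case_strehl,
                                          WITHOUT_GLASSES)

eye = build_baseline_eye(lens_index=EQUIVALENT_LENS_INDEX)
print(f"power: {paraxial_power(eye):+.2f} D")

for system, tag in [(eye, "bare eye"), (attach_glasses(eye), "with glasses")]:
    z = named_aberrations(fit_zernike(sample_opd(system, 0.0, 64)))
    print(tag, {k: round(v, 3) for k, v in z.items()})

design, log = optimize_cornea(eye, "aspherical", MATERIALS["P407DA_PHEMA"],
                              WITHOUT_GLASSES, seed=1, max_nfev=220)
print(f"on-axis Strehl of the optimized implant: "
      f"{case_strehl(eye, design, WITHOUT_GLASSES):.3f}")
```

prints

```
power: +62.35 D
bare eye {'defocus': -1.524, 'vertical_astigmatism': -0.087, 'horizontal_coma': -0.0, 'spherical': -0.145}
with glasses {'defocus': -0.342, 'vertical_astigmatism': 0.003, 'horizontal_coma': 0.0, 'spherical': -0.153}
on-axis Strehl of the optimized implant: 0.222
```

Read: the bare model eye is ~1.4 D myopic with mild astigmatism (the
wavefront coefficients are in µm over a 4 mm pupil); concave spectacles
remove most of the defocus and astigmatism but slightly *increase* the
spherical aberration — spectacles cannot correct high-order aberrations.
An optimized aspherical hydrogel cornea removes the defocus and
astigmatism at the source; the remaining Strehl loss is residual spherical
aberration (see `docs/methods.md` for why the homogeneous-lens eye model
bounds this).

The same experiments are scriptable from the shell:

```bash
kerato report
kerato aberrations --fields -10,-5,0,5,10 --out aberrations.csv
kerato optimize --shape biconic --material P407DA_PHEMA --case without_glasses --seed 1
kerato tolerance --shape biconic --case without_glasses --out tolerance.csv
kerato run-case --case without_glasses --seed 1 --outdir out/
```

## Layout

| module | contents |
| --- | --- |
| `optics_core` | surface sag/normals (plane→sphere→aspheric→biconic), Newton ray–surface intersection, vector Snell refraction |
| `grin_media` | polynomial GRIN medium, analytic index gradient, RK4 ray integration |
| `eye_model` | materials, prescriptions (build/serialize), glasses, cornea replacement, paraxial power |
| `wavefront_zernike` | ray-aimed OPD sampling, OSA Zernike basis and fitting |
| `diffraction_imaging` | PSF/OTF/Strehl, phase plate, retinal image simulation |
| `design_optimizer` | merit functional, design cases, bounded optimization, mold tolerance |
| `synthetic_data` | defective eyes, letter stimuli, synthetic OPD maps |
| `workbench` / `cli` | end-to-end case experiments and the `kerato` command |
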