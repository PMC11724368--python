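# ipdtplan

Photosensitizer spatial heterogeneity — quantified from structured-light
fluorescence imaging — and its consequences for interstitial
photodynamic therapy (iPDT) treatment planning.

## The problem

In iPDT, cylindrical fiber diffusers implanted in a tumor deliver light
that activates a photosensitizer (PS).  Treatment planning tools usually
assume the PS concentration [PS] is uniform across the tumor, but
quantitative imaging shows it is not: tumors carry a *bimodal*
concentration distribution — a drug-poor core and a drug-rich rim — with
strong variability on top.  This package implements the full analysis
chain needed to quantify that heterogeneity and to ask the planning
question it raises: *at what spatial scale does [PS] heterogeneity
change the optimal light plan?*

The chain, module by module:

| module | what it does |
| --- | --- |
| `ipdtplan.sfdi` | quantitative spatial-frequency-domain imaging: 3-phase demodulation `MAC = (sqrt(2)/3) sqrt(sum of squared frame differences)` and diffusion-theory concentration recovery `[PS] = k_PS mu_a,x Fm / D` |
| `ipdtplan.heterostats` | ROI histograms, histogram-counts Otsu threshold, two-component Gaussian-mixture fits (EM), per-mode CV, 10–90% range, mode fold-range |
| `ipdtplan.texture` | sliding-window gray-level co-occurrence (GLCM) Haralick features: contrast, energy, homogeneity at window sizes {3, 5, 15, 20} |
| `ipdtplan.meshmodels` | synthetic tetrahedral brain/tumor meshes (sphere-union tumors, layered head) with seeded [PS] heterogeneity scenarios |
| `ipdtplan.transport` | Monte Carlo photon-packet transport on tetrahedral meshes (numba kernel), validated against the diffusion closed form `phi(r)=e^{-mu_eff r}/(4 pi D r)` |
| `ipdtplan.planning` | threshold-dose plan evaluation (`dose = phi x [PS]-multiplier >= T`), power allocation pinned at 98% tumor destruction, simulated-annealing source placement, plan comparison |
| `ipdtplan.synthetic` | ground-truth generators for every pipeline input |
| `ipdtplan.cli`, `ipdtplan.meshio_vtk` | umbrella CLI and VTK/VTU tetrahedral mesh I/O |

## Worked example

Generate a bimodal tumor map, push it through the imaging chain, and
summarize its heterogeneity:

```python
import numpy as np
import ipdtplan as ip

refs = ip.ReferenceSet(mac_ref=500.0, rx_ref=0.6, rm_ref=0.5)
cal = ip.Calibration(k_ps=50.0, mu_a_x=0.02)

ps_map, truth = ip.gen_bimodal_tumor_map(shape=(96, 96), tumor_radius_px=36, seed=11)
triplet, fm = ip.gen_sfdi_frames(ps_map, refs, cal, seed=11)
recovered = ip.quantify_ps(fm, ip.demodulate(triplet), refs, cal)

fit = ip.fit_bimodal(ps_map.roi_values(), seed=0)
summary = ip.summarize(ps_map.roi_values(), fit)
print(f"mode 1: {fit.mean_1:.2f} +/- {fit.sd_1:.2f} ug/mL  (CV {summary.cv_mode1:.2f})")
print(f"mode 2: {fit.mean_2:.2f} +/- {fit.sd_2:.2f} ug/mL  (CV {summary.cv_mode2:.2f})")
print(f"IQR(10-90%): {summary.iqr_10_90:.2f} ug/mL")
```

prints (seed 11):

```
mode 1: 3.22 +/- 1.35 ug/mL  (CV 0.42)
mode 2: 8.54 +/- 3.06 ug/mL  (CV 0.36)
IQR(10-90%): 9.15 ug/mL
```

i.e. the fit recovers the generator's core mode (3.03, 1.25) and rim
mode (7.97, 3.37) from a finite pixel sample, and both modes have CVs
around 0.4 — the level of intra-tumor variability that motivates
heterogeneity-aware planning.

A planning run on the synthetic head fixture (about two minutes: a
Monte Carlo fluence field at 3x10^5 packets plus power optimization):

```python
mesh, surface = ip.make_brain_fixture(preset="low", seed=1)
sources = ip.place_sources(mesh, 1, surface=surface, length_mm=4.0)
field = ip.mc_fluence(mesh, ip.TABLE_OPTICS_635NM, sources[0], n_packets=300_000, seed=1)
model = ip.ThresholdModel(ip.DEFAULT_THRESHOLDS)
powers = ip.optimize_power(mesh, [field], model, seed=1)
sol = ip.evaluate_plan(mesh, [field], powers, model, sources=sources)
print(f"destruction: {100*sol.destruction_fraction:.2f}%")
```

```
destruction: 98.02%
```

— the optimizer pins tumor destruction at the 98% planning contract (up
to one mesh-cell volume quantum).  Re-optimizing under the heterogeneity
scenarios (`ip.assign_ps_scenario`, scenarios 1–3) shows the headline
result: the homogeneous scenario demands the most power, coarse core/rim
heterogeneity shifts the plan by well over 5%, and sub-element
("fine-grained") heterogeneity leaves it unchanged within Monte Carlo
tolerance.

There is also a CLI: `ipdtplan gen`, `quantify`, `stats`, `texture`,
`mesh-gen`, `simulate`, `plan` (see `ipdtplan --help`).

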