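# dualspect

Simultaneous Tl-201/Tc-99m dual-isotope SPECT reconstruction with
Monte-Carlo scatter and cross-talk correction.

In simultaneous dual-isotope myocardial perfusion SPECT the 140 keV Tc-99m
photons that Compton-scatter in the patient are detected in the ~72 keV
Tl-201 energy window. This *down-scatter* dominates the Tl-201 data — a
single scatter cannot fall below the 90.4 keV Compton floor, but multiple
scatters and the detector's energy resolution put abundant Tc-99m counts
into the 66.6–77.4 keV window — and erases perfusion-defect contrast
unless corrected. `dualspect` implements an OS-EM reconstruction that
corrects it in three steps:

1. reconstruct Tc-99m with attenuation, distance-dependent collimator
   response and MC self-scatter correction:
   `x ← x · [Aₛᵀ(yₛ / (Aₛx + sₛ + ε))] / Aₛᵀ1`;
2. run a fast Monte-Carlo simulation of Tc-99m down-scatter into the
   Tl-201 window from the reconstructed Tc-99m volume;
3. reconstruct Tl-201 with the frozen down-scatter estimate added to its
   self-scatter term `s`.

The MC engine is accelerated by coarse-grid folding of the input image,
intermittent scatter updates (only the first OS-EM iterations refresh the
estimate) and forced detection, so the full dual reconstruction runs in
minutes on one CPU. The package also ships the digital phantoms
(parametric cardiac torso and a cylindrical cardiac-insert phantom), the
study simulator (analytic primaries + MC scatter + Poisson noise) and the
equal-area-ROI contrast analysis used to validate the method. Audience:
researchers in emission-tomography reconstruction who want a transparent,
fully scripted testbed for dual-isotope cross-talk correction.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a dual-isotope study of the standard cardiac phantom
configuration 3 (anterior defect at 20% of myocardial activity), run the
three-step reconstruction at the optimised settings, and measure contrast:

```python
import dualspect as d
from dualspect.mcscatter import McConfig, simulate_downscatter
from dualspect.phantom import StudySpec
from dualspect.reconstruct import ReconConfig, SelfScatterProvider, osem

ph = d.build_cardiac_phantom(d.cardiac_phantom_spec(3))
study = StudySpec(count_scale=0.1)          # desk-scale counts
geo, col = study.geometry(), d.CollimatorModel()
sim = d.simulate_study(ph, study, col, McConfig(photons=1_000_000, seed=0),
                       seed=0)

cfg = ReconConfig(iterations=10, subsets=8, scatter_update_iters=2,
                  mc=McConfig(photons=100_000, coarse_factor=2, seed=1),
                  postfilter_fwhm_cm=0.9)
prov = SelfScatterProvider(ph.mu_map, d.TC99M, d.TC_WINDOW, geo, col, cfg.mc,
                           resolution_frac=0.099)
tc_vol, _ = osem(sim.tc, ph.mu_map, geo, col, cfg, prov,
                 emission=d.TC99M, window=d.TC_WINDOW)
res = d.evaluate_contrast(tc_vol, ph, "anterior")
print(f"defect contrast {res.contrast_myocardium_defect:.2f}, "
      f"LV contrast {res.contrast_myocardium_lv:.2f}")
```

This prints (seed 0):

```
defect contrast 0.75, LV contrast 0.94
```

A defect contrast of 0.75 means the anterior-defect ROI holds 25% of the
healthy-wall counts after reconstruction — the 20% residual activity plus
partial-volume spill; the LV contrast measures how cold the ventricular
cavity reads against the wall. The same pipeline is available from the
shell:

```sh
dualspect run --seed 0 --out run1           # full pipeline + manifest
dualspect phantom build --phantom-id 3 --out ph3
dualspect recon dual --tc proj_tc.nii.gz --tl proj_tl_dual.nii.gz \
    --mu mu_map.nii.gz --photons 100000 --ds-photons 1000000 --out recon
dualspect analyze contrast --volume recon/recon_tl.nii.gz --sector anterior
```

Volumes are NIfTI; projection sets are NIfTI stacks with a JSON geometry
sidecar; specs and run configurations are YAML.

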