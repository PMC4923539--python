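# perifem

Voxel micro-finite-element (µFE) analysis of peri-implant bone load
transfer: how does explicitly modeling the trabecular microstructure of
cancellous bone — instead of homogenizing it into a solid block — change the
stress and strain a dental implant transmits to the surrounding bone?

The package is aimed at computational biomechanics work where paired
"refined" (microstructural) and "simplified" (homogenized) models of the
same implanted bone segment must be built, solved and compared. Because
suitable micro-CT/CBCT scans of implanted bone are rarely shareable, the
package includes a first-class synthetic-specimen generator: a cortical
shell with a rod-like trabecular interior at a controlled bone volume
fraction (BV/TV), embedded threaded Ø4.1 mm × 8 mm implants, and emulated
micro-CT-like (high-resolution, noisy, metal-artifact-shaded) and CBCT-like
(blurred, downsampled) intensity volumes.

## What it computes

Both models share one voxel lattice and one load case — mesial/distal faces
fixed, 50 N axial load on each implant top, perfectly bonded (node-sharing)
implant-bone interface:

* **refined** — bone recovered from the micro-CT-like image by Otsu
  (discriminant-analysis) thresholding plus seeded graph-cut refinement;
  trabecular and cortical bone share one material (E = 14.4 GPa, ν = 0.309;
  implant 110 GPa, 0.35).
* **simplified** — cortical shell + solid cancellous block + implants
  (cortical 14.4 GPa/0.309, cancellous block 0.48 GPa/0.225, implant
  110 GPa/0.35).

Each foreground voxel becomes one 8-node hexahedral element; the linear
elastic system is solved by Jacobi-preconditioned conjugate gradients. At
the implant-bone interface (bone elements face-adjacent to implant
elements) the package reports maximum and mean of six measures: equivalent
(von Mises) stress σ_vM = √(3/2 s:s), tensile (first principal) and
compressive (magnitude of third principal) stress, and the strain
analogues (equivalent strain √(2/3 e:e)), plus the per-measure percent
change 100·(refined − simplified)/simplified.

## Worked example

```python
from perifem import PipelineConfig, build_truth, run_refined_branch, \
    run_simplified_branch, compare_models

cfg = PipelineConfig(master_seed=1)      # default two-implant specimen
truth = build_truth(cfg)
refined = run_refined_branch(cfg, truth=truth)
simplified = run_simplified_branch(cfg, truth=truth)
print(compare_models(refined.summary, simplified.summary).to_table())
```

prints (units: stress MPa, strain dimensionless):

```
measure             refined_max  simplified_max  pct_change_max  refined_mean  simplified_mean  pct_change_mean
equivalent_stress   10.6189      9.2322          15.0201         1.54361       0.420017         267.512
tensile_stress      7.10775      5.5581          27.8811         0.638689      0.181169         252.538
compressive_stress  6.2638       5.09826         22.8615         1.1606        0.31491          268.551
equivalent_strain   0.000643525  0.00205695      -68.7146        9.35458e-05   0.0003812        -75.4602
tensile_strain      0.000592885  0.00166714      -64.4371        6.83287e-05   0.000287513      -76.2346
compressive_strain  0.000520649  0.00221604      -76.5055        9.04045e-05   0.000361496      -75.46
```

Read: resolving the trabecular microstructure *raises* interface stress
(load is carried by a sparse strut network instead of a compliant
continuum) and *lowers* interface strain (the struts are made of stiff bone
tissue, whereas the homogenized block deforms heavily). The peak equivalent
stress sits in trabecular bone in the refined model but at the cortical
neck in the simplified model.

The same pipeline is available from the shell:

```bash
perifem run --out run1/ --seed 1          # comparison.tsv, summary.json, VTK fields
perifem generate --out specimen/          # truth + homogenized + micro/CBCT images
perifem segment --image specimen/micro_image.raw --seeds seeds.txt --out labels.raw
```

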