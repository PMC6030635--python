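# crownct

Tooth-crown tomography analysis for palaeontological specimens: tissue
segmentation of reconstructed CT volumes, enamel-thickness mapping between
opposing surface meshes, and a fracture-mechanics model that turns crown
geometry and enamel properties into critical-load and bite-force estimates.

## Who this is for

Vertebrate palaeontologists and dental biomechanists working with
tomographic scans (neutron or X-ray) of fossil teeth.  A typical specimen —
here, an unworn posterior dentary tooth of an herbivorous rhynchocephalian —
shows three attenuation populations (enamel, dentine, pulp-cavity infill)
that can be separated by thresholding when the windows are distinct, as they
are under neutron attenuation.  Because raw scans of such specimens are
rarely redistributable, the package ships a seeded phantom generator that
builds crown-shaped three-tissue volumes with exact ground truth, so every
stage of the pipeline is testable end to end.

## What it computes

**Segmentation.**  A five-step threshold protocol: whole-tooth mask;
dentine above the enamel–dentine attenuation boundary; spatial split of the
remainder into the outer shell (enamel) and the cavity enclosed by the
dentine ring; island reabsorption; closure of the pulp cavity at the plane
of the ventralmost enamel.  Tissue volumes are voxel counts times the cubed
voxel size.

**Enamel thickness.**  Outer and inner enamel surfaces are extracted by
marching cubes at the 0.5 level of the tissue indicator; thickness is the
distance from each outer surface element along its inward normal to the
first opposing intersection with the inner surface (nearest-opposing
triangle as fallback).  Results are binned at the voxel size (0.026 mm by
default) into a surface-element histogram whose peak is the modal enamel
thickness.

**Fracture mechanics.**  The crown is a brittle enamel shell on a compliant
dentine core.  The peak sustainable force before a margin crack (failure
low on the crown under a spread load) is

    F = c · K_c · √t · R

with shape coefficient *c* (a monotone function of crown height over base
radius, *h/R*: 6–8 for bunodont crowns, plateauing at 50–55 for hypsodont
ones), enamel fracture toughness *K_c* (MPa·m^0.5), enamel thickness *t*
and crown-base radius *R*.  Radial cracks (concentrated loads) halve the
resistance regardless of toughness.  All parameters may be intervals;
because *F* is strictly increasing in each, interval propagation by corner
evaluation is exact (and is checked against a brute-force grid in the
tests).  Critical-load ranges of two taxa combine into resistance ratios
and, via a measured reference bite force, into a bite-force prediction.

## Worked example

The built-in demo generates a seeded 128³ neutron-mode phantom (26 µm
voxels, apex enamel 0.10 mm, basal enamel 0.20 mm, ridged up to 0.45 mm),
filters it (despeckle + five iterations of six-neighbour edge-stopping
diffusion, stop criterion 3327 grey levels), segments it, maps enamel
thickness, and evaluates the fracture scenario for a fossil crown
(*h/R* 1.9–2.1, *K_c* 0.21–0.32 MPa·m^0.5, *t* 0.20 mm, *R* 2.0 mm)
against an extant reference (bite force 275 N, critical load ≈ 32.9–143 N):

```bash
crownct run --seed 1 --outdir demo-run
```

prints (abridged) the consolidated report:

```
"segment":   "dice_vs_truth": {"enamel": 0.9982, "dentine": 0.999, "pulp": 0.9994}
"thickness": "modal_thickness_mm": 0.195, "median_thickness_mm": 0.199438
"biomech":   "critical_load_n": [100.974848, 325.834805]
             "resistance_ratio_low_high": [3.064545, 2.278565]
             "bite_force": {"predicted_n": [626.605394, 842.749828],
                            "ratio_to_highest": 1.923077, "ratio_to_lowest": 8.346136}
```

Reading: segmentation recovers each tissue with Dice ≥ 0.998 against the
phantom's ground truth; the modal enamel thickness lands within one
histogram bin of the constructed 0.20 mm; the fossil crown sustains
101–326 N per tooth before margin cracking — 2.3–3.1 times the reference
taxon — and scaling the reference's 275 N bite force by the endpoint
ratios predicts a 627–843 N maximum anterior bite force.  Artefacts (16-bit
TIFF slice stacks, 8-bit label stacks, PLY meshes, per-element CSVs,
`report.json`) are written under `demo-run/`.

Library use mirrors the CLI:

```python
from crownct import (PhantomSpec, generate_phantom, build_attenuation_model,
                     despeckle, anisotropic_diffusion, segment_tooth,
                     extract_surfaces, measure_thickness, thickness_histogram)

volume, truth = generate_phantom(PhantomSpec(seed=1))
model = build_attenuation_model("neutron")
labels = segment_tooth(anisotropic_diffusion(despeckle(volume)), model)
outer, inner = extract_surfaces(labels, tissue=1)
hist = thickness_histogram(measure_thickness(outer, inner))
print(hist.modal_thickness_mm)   # 0.195
```

## Layout

```
src/crownct/
  phantom.py     synthetic crowns + attenuation models (windows, boundaries)
  preprocess.py  despeckle, edge-stopping six-neighbour diffusion
  segment.py     five-step threshold protocol, tissue volumes, Dice
  thickness.py   surface extraction, opposing-surface thickness, histogram
  biomech.py     shape coefficient, crack loads, intervals, bite force
  pipeline.py    configured runs, report schema, validation
  cli.py         crownct {run,phantom,filter,segment,thickness,biomech,validate}
```
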