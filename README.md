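# fetalecho

Digital fetal heart models with a virtual ultrasound function.

Fetal echocardiography is the standard prenatal screen for congenital
heart disease, and the hardest part of learning it is relating the 2D
standard planes to the 3D anatomy.  `fetalecho` builds that training
loop entirely in software: it procedurally generates multi-structure
fetal heart models (blood-pool geometry in the style of a cardiovascular
cast), emulates the cast-CT digitisation and segmentation workflow, and
simulates B-mode ultrasound images for arbitrary probe poses, with
presets and automatic verification for the eight standard fetal
echocardiography views and for lesion-sensitive views of two congenital
malformations.

It is aimed at researchers building ultrasound-training or
image-analysis pipelines who need a fully synthetic, fully reproducible
stand-in for scarce fetal cardiac specimens.

## The simulation model

A heart model is a set of named, closed triangle surfaces
$S_1, \dots, S_k$ (one per cardiovascular structure: LA, RA, LV, RV,
AO, PA, DA, SVC, ...) in a common anatomical frame, each with a display
material and an overlap priority.  A probe pose is a rigid homogeneous
transform $T \in SE(3)$ from image to heart coordinates.  One frame is
simulated as:

1. transform the model into image coordinates with $T^{-1}$;
2. lay out virtual scan lines from the transducer geometry (parallel
   for a linear array; radial over the field of view for a curvilinear
   array);
3. for each scan line (a ray $o + t\,d$), find all crossings with the
   structure surfaces using a bounding-volume hierarchy whose query
   results are contractually identical to brute force over every
   triangle (watertight Möller–Trumbore with a shared $10^{-9}$ epsilon
   rule);
4. fill the segments between crossings with the material grey value of
   the highest-priority structure containing each sample (even–odd
   parity per closed surface, with the state at the probe face resolved
   by a point-in-mesh test), optionally decayed by
   $\exp(-\int \mu\, \mathrm{d}s)$ for depth attenuation;
5. scan-convert the filled lines onto the Cartesian pixel grid (polar
   resampling for curved arrays; pixels outside the fan are black).

Alongside each B-mode frame the simulator emits a ground-truth
*label slice* (structure id per pixel), which drives the automatic view
verification: a view passes when every required structure covers at
least a threshold area in the slice.

Three study cases ship as generator presets: a normal heart, a double
aortic arch (the ascending aorta splits into left and right limbs that
rejoin the descending aorta, ringing the trachea), and a hypoplastic
right heart complex (small RV, ventricular septal defect, aorta arising
from the RV, atretic pulmonary trunk fed only through the ductus).

## Worked example

```python
from fetalecho import (SyntheticHeartSpec, generate_heart, simulate,
                       standard_views, verify_view, ProbeConfig)

heart = generate_heart(SyntheticHeartSpec.preset("normal"))
print(f"{len(heart.structures)} structures:", ", ".join(heart.names))

spec = standard_views()["four_chamber"]
image, labels = simulate(heart, spec.pose, ProbeConfig())
report = verify_view(labels, spec)
print("four-chamber view pass:", report["pass"])
for name in sorted(spec.required_structures):
    mm2 = report["counts"][name] * 0.2 ** 2
    print(f"  {name}: {report['counts'][name]} px ({mm2:.1f} mm^2)")
```

prints

```
17 structures: LV, RV, LA, RA, LAA, RAA, AO, Arch, DAO, AoBs, PA, lPA, rPA, DA, SVC, IVC, Trachea
four-chamber view pass: True
  LA: 1229 px (49.2 mm^2)
  LV: 2504 px (100.2 mm^2)
  RA: 1348 px (53.9 mm^2)
  RV: 2530 px (101.2 mm^2)
```

`image.pixels` is the 300x300 8-bit B-mode frame (0.2 mm pixels): all
four chambers are visible simultaneously, which is precisely the
clinical definition of the four-chamber plane, and the pixel counts are
the chamber cross-section areas in that plane.

The same pipeline is scriptable from the shell:

```
fetalecho genheart --case double_aortic_arch --out model/ --rasterize
fetalecho views --model model/ --case double_aortic_arch --out views/
fetalecho simulate --model model/ --pose pose.json --label --out frame.png
fetalecho sweep --model model/ --poses path.json --steps 10 --out cine/
```

`fetalecho views` writes one PNG per view plus `report.json` with the
per-structure pixel counts and pass flags; every command records a
`provenance.json` (seed, config hash, version) sufficient to reproduce
its outputs byte for byte.

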