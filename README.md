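# calcatlas

A statistical, morphometric shape model (atlas) pipeline for the calcaneus
(heel bone), for researchers in musculoskeletal imaging and orthopaedic
biomechanics.  From CT-like volumes or pre-extracted 3D point clouds it
produces: seeded region-growing contours, landmark-based canonical pose,
a real spherical-harmonics (SPHARM) radius expansion with MDL order
selection, hypothesis-reduced per-group coefficient atlases with quartile
shape reconstructions, left/right symmetry correlation, and the seven
classical landmark morphometrics (Böhler and Gissane angles among them).

## Model

Each bone surface, placed in a canonical frame by its anatomical landmarks
(E → origin, C → +x axis, the C–D–E plane → z = 0) and recentred at its
centre of mass, is treated as a star-shaped radius function and expanded in
real spherical harmonics:

    R(θ, φ) / R_s = Σ_{l=0..L} Σ_{m=−l..l}  c_lm  y_lm(θ, φ),     R_s = max R_d

with y_lm the orthonormal real basis built from N_lm and the associated
Legendre functions P_lm, and the coefficients c_lm estimated by linear
least squares from the contour samples.  The truncation order L minimizes
Rissanen's MDL criterion `(D/2) ln(RSS_L/D) + ((L+1)²/2) ln D`; a complete
expansion at L = 11 has (L+1)² = 144 coefficients.  A population of bones
then yields per-coefficient statistics (mean, SD, quartiles), quartile
shapes, a Benjamini–Hochberg-reduced set of representative coefficients,
and the left/right symmetry r² of the group-mean coefficient vectors.

## Worked example

```python
import numpy as np
from calcatlas import atlas, pose, spharm
from calcatlas.synthetic import PopulationSpec, generate_population

cohort = generate_population(PopulationSpec(n_bones=18, seed=1, mirror=True))
rows = {"left": [], "right": []}
for bone in cohort:
    canonical, _, _ = pose.canonicalize(bone.cloud, bone.landmarks)
    fit = spharm.fit_coefficients(spharm.to_spherical(canonical), 4)
    rows[bone.side].append(fit.values)

left = np.vstack(rows["left"]).mean(axis=0)
right = np.vstack(rows["right"]).mean(axis=0)
r2_full, _ = atlas.symmetry_correlation(left, right, exclude_top=0)
r2_red, _ = atlas.symmetry_correlation(left, right, exclude_top=3)
print(f"symmetry r2: {r2_full:.3f} (all), {r2_red:.3f} (top 3 excluded)")
```

prints

```
symmetry r2: 0.998 (all), 0.582 (top 3 excluded)
```

With every coefficient included, the mirrored pairs' dominant low-order
terms make left and right means almost perfectly correlated; removing the
three largest-magnitude coefficients exposes the moderate residual
correlation carried by the sign-flipping higher-order terms — the same
qualitative picture seen in real two-sided cohorts.

The same pipeline is scriptable from the shell (`calcatlas simulate`,
`segment`, `fit`, `atlas`, `report`); see `calcatlas --help`.

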