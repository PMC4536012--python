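# Methods

`calcatlas` builds a statistical shape model (atlas) of the calcaneus from
CT-like volumes or 3D point clouds.  This note records the model, the
numerical choices, the synthetic study conditions, and the limits of what
the test suite can show.

## Pipeline model

**Slice conditioning.**  A volume `I` of size `(m, n, o)` with voxel spacing
`(xt, yt, zt)` mm is decomposed into sagittal slices `I_k`.  Each slice is
min–max normalized in two steps, `I ← I − min(I)`, `I ← I / max(I)`, and
contrast-enhanced with the logistic map `S(I) = 1 / (1 + exp(g (c − I)))`.
Defaults `g = 0.4`, `c = 0.7` are the empirical settings used for calcaneal
CT; both are configurable.  Normalization is per slice, over the whole
slice (no region of interest), so each image uses its full dynamic range.
A constant slice maps to all zeros — such slices contain no bone and the
convention keeps the pipeline total.

**Contour extraction.**  Seeded region growing with 4-connectivity: a
candidate pixel joins when `|I(p) − mean(region)| ≤ τ` against the running
region mean at the moment of the test.  Because the running mean drifts,
the visiting order matters; expansion is breadth-first in a fixed FIFO
order, which makes the output deterministic.  The default `τ = 0.2`
(post-sigmoid units) suits high-contrast bone/soft-tissue boundaries; for
the synthetic rasterized volumes, whose enhanced dynamic range is
compressed to roughly `[S(0), S(1)] ≈ [0.430, 0.530]` by the shallow
default gain, the rasterizer suggests `τ = 0.04` (≈ 40 % of that gap) with
its planted seed, large enough to absorb in-class noise and small enough to
stop at the blurred cortex.  Region growing runs on the enhanced slice —
the pipeline order (conditioning, then contours) implies it, though the
alternative of growing on the raw slice would only need a different `τ`.
Contour pixels are mask pixels with a background 4-neighbour (the image
border counts as background).  Pixel `(row r, col c)` of 0-based slice `k`
maps to `(c·xt, r·yt, k·zt)` mm; per-slice contours concatenate into the
cloud `W`.

**Pose normalization.**  The canonical frame is defined by landmarks C, D,
E: translate by `−E`; rotate the oriented normal `(C−E) × (D−E)` of the
C–D–E plane onto `+z` by the dihedral angle `α` about the line of nodes;
rotate about `z` by `β` so C lands on the `+x` half-axis.  Two points of
care:

* a single rotation about the *x* axis cannot map an arbitrary plane
  normal onto `+z`; the implemented `r_α` is the minimal (axis-angle)
  rotation about the line of nodes and reduces to the elementary x-rotation
  exactly when the line of nodes is the x axis.  `r_β` is a z-rotation — a
  rotation about x could never change the angle to the x axis.
* orientation conventions must be intrinsic.  Deciding the normal's sign
  from its z-component in the *scanner* frame would make the canonical
  frame depend on how the bone happened to lie in the scanner; the oriented
  cross product co-rotates with the landmarks and gives exact rigid-motion
  invariance (verified to 1e−6 mm over 100 random motions).
* `β` is computed from C *after* the `α` rotation — the only order under
  which the post-conditions (E at origin, C on `+x`, D in `z = 0`) are all
  achievable.

Both operations are isometric; no scaling is applied.  A useful corollary:
a mirrored (left) bone canonicalizes to the z-flip of its right twin, so
paired coefficients obey `c'_{lm} = (−1)^{l+m} c_{lm}` — the sign-flip
pattern visible in left/right atlas comparisons.

**SPHARM expansion.**  The canonical cloud is recentred at its centre of
mass (unit masses; the best-fit sphere of Eq-style diagnostics supplies
`R_BS` but not the final origin), converted to azimuth/elevation/radius,
and scaled by `R_s = max(R_d)`.  The radius ratio is expanded in real,
fully normalized spherical harmonics with the Condon–Shortley phase kept
inside `P_lm`; the basis is evaluated at polar angle `π/2 − elevation`.
`P_lm` uses the stable fully normalized three-term recurrence — direct
differentiation of the Rodrigues formula overflows near `l ≈ 11`.
Coefficients are ordered `q = 1..(L+1)²` with `l` ascending and `m` from
`−l` to `l` (the CSV header records `(q, l, m)` so other orderings can be
re-indexed).  Least squares is solved by SVD (`gelsd`), with a warning
above condition 1e8 and a hard error on rank deficiency.  Orthonormality
is exact to ~4e−15 on a Gauss–Legendre × uniform-azimuth product
quadrature at `L = 11`.

**Order selection and reduction.**  The truncation order minimizes the
Rissanen MDL criterion in its standard Gaussian linear-model form
`MDL(L) = (D/2) ln(RSS_L/D) + ((L+1)²/2) ln D`, with an RSS floor of
`1e−12·D` so noiseless fits stay finite; ties resolve to the smaller
order.  When several bones are fitted, per-bone selections aggregate by
majority vote.  Population reduction tests each coefficient for zero mean
across bones (one-sample t), adjusted by Benjamini–Hochberg at level 0.05
(both configurable); identically-zero columns are excluded, constant
nonzero columns retained with p = 0.  The procedure behind the reference
cohort's retained counts (41 right / 47 left) is not specified anywhere
recoverable, so those counts are treated as context, not as a target.

**Atlas statistics.**  Column-wise mean, sample SD and quartiles
(linear-interpolation convention, `numpy.quantile` default) over bones;
quartile shapes are reconstructed from the per-coefficient Q1/median/Q3
vectors at the group-mean `R_s`.  Box-plot exports mark outliers by the
1.5·IQR rule.  Left/right symmetry is the squared Pearson correlation of
the two group-mean coefficient vectors; the "exclude top" variant removes
the largest coefficients ranked by the absolute pooled (left+right)/2 mean
(signed-value ranking is available via `rank_by="pooled_value"`), since the
few dominant low-order terms otherwise swamp the correlation.  Raw
(signed) means are correlated, not absolute values.

**Morphometrics.**  Seven landmark measures: LCA = |G−E| with G the C–D
midpoint; HPF = distance from A to the *infinite* line through G and E;
LPF = |A−B|; LAP = |B−C|; HAP = |C−D|; GA = angle ABC; BA = 180° − angle
CAF.  Angles are computed in radians and reported in degrees; degenerate
configurations yield NaN per measure rather than an error.  Group
comparison uses Welch's two-sample t-test, with p = 1 short-circuited for
identical samples.

## Synthetic study conditions

The generator emulates a two-sided cohort of 18 bones per side.  Each bone
draws coefficients `base + N(0, σ_c²)` per coefficient (default
`σ_c = 0.01`), a scale radius `N(34, 2²)` mm, surface samples at 2500
deterministic Fibonacci-spiral directions with radial noise
`σ_r = 0.005` (ratio units), six landmarks planted on the noiseless
surface at fixed well-separated directions, and a uniformly random rigid
misorientation.  Non-star-shaped draws are rejected and resampled (error
after 100 rejections).  Mirrored twins negate x before misorientation and
share the coefficient draw.  The base shape is a handcrafted degree-4
coefficient vector — elongated along x, flattened in z, fore/aft and
top/bottom asymmetric — scaled so the synthetic calcaneal axis is ≈ 80 mm
and the landmark geometry lands within about one cohort SD of published
calcaneal ranges (LCA ≈ 82 mm, GA ≈ 125°, BA ≈ 37°).  Everything is
reproducible bit-for-bit from the spec's seed.

The rasterizer voxelizes the analytic surface (interior 1, background 0)
over the bounding sphere plus a 3 mm margin, blurs with a 0.6-voxel
Gaussian and adds configurable noise; radius lookups go through a dense
(θ, φ) interpolation table, whose error is far below voxel size for the
low-order shapes used.  The planted seed sits at the shape origin and is
interior by star-shapedness.

What the generator does *not* emulate: Hounsfield calibration and CT
physics, trabecular texture, neighbouring bones and soft tissue, partial
scans, or anatomically detected landmarks (planting is by direction, not
by anatomy).  Passing tests therefore demonstrate the correctness and
stability of the geometry/statistics pipeline, not clinical segmentation
or landmarking performance on real scans.

## Problem sizes in the checked runs

The shipped checks use: degree-4 cohorts of 18 bones at 2500 directions;
MDL recovery at D = 3000 samples, orders 0–4, 10 seeds each; basis
orthonormality at L = 11 on a 552-node exact product quadrature;
segmentation-to-fit consistency on a 20 mm-scale bone at 0.5 mm and
0.25 mm isotropic spacing.  These sizes keep every stage comfortably
deterministic and fast while leaving all estimators well inside their
asymptotic regimes.

## Known limitations

* The unit normalization divides by `R_s = max(R_d)`, a noisy extreme
  statistic.  Radial noise and population variability therefore induce a
  small common multiplicative jitter on every fitted coefficient vector:
  the fitted `c_00` of a σ_c = 0.01 cohort has sampling SD ≈ 0.028, and
  its cohort mean carries a sub-percent downward shift relative to a
  noiseless reference.  Shape comparisons in mm (coefficients × `R_s`) are
  free of this coupling; per-coefficient ratio-unit comparisons at tight
  multiples of the nominal σ_c are sensitive to it.
* The `(l, m)` ordering and the real-basis conventions are internally
  consistent and unit-tested, but external coefficient tables must be
  re-indexed to this ordering before comparison.
* Region growing has no leak-recovery: a tolerance too large for the local
  contrast floods through blurred boundaries (the tests quantify the
  usable range for the synthetic volumes).
* Pose canonicalization requires non-collinear C, D, E; landmark noise
  propagates directly into frame orientation and is not averaged out.
* The supplementary-style workbook reader accepts `.xlsx`/`.csv`; the
  legacy binary `.xls` container is not parsed.
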