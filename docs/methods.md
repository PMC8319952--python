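# Methods

## Problem

In image-guided cervical brachytherapy with a tandem-and-ovoid
applicator, per-fraction organ-at-risk constraints (bladder D2cm3 <
5.2 Gy; rectum, sigmoid colon and small intestine D2cm3 < 4.7 Gy at a
7 Gy prescription) compete with target coverage. How much dose an organ
*must* receive is largely fixed by anatomy: an organ pressed against
the high-risk clinical target volume (HR-CTV) sits in the steep
inverse-square falloff of the implant and cannot be spared arbitrarily.
`brachyqa` quantifies that geometric component and uses it two ways:

1. **Prediction** — estimate an organ's D2cm3/Dprescription before
   planning, from contours alone.
2. **QA** — flag a finished plan whose actual organ dose deviates from
   the anatomy-based prediction by more than a threshold (default
   delta = 0.10), i.e. plans that are outliers relative to what the
   anatomy warrants.

## Features: ring-shell sub-OAR volumes

The HR-CTV is expanded outward into concentric shells of width 0.5 cm,
up to 10 shells. Shell membership is half-open in the distance `d` from
the HR-CTV surface: voxel centers with `(k−1)·5 mm < d ≤ k·5 mm` belong
to ring `k`, so the rings partition the 5 cm expansion margin. The
intersection of ring `k` with an organ is *sub-OAR k*; its volume (cm^3)
measures how much of the organ lies at that distance band.

Each organ model consumes six features: a global volume plus the first
five sub-OAR volumes. The global volume is the HR-CTV volume for
bladder, rectum and sigmoid colon, and the *bladder* volume for the
small intestine — a full bladder displaces bowel away from the implant,
so bladder filling is the dominant anatomic knob for intestinal dose.

### Distance convention

Distances are Euclidean, in millimetres, honoring anisotropic voxel
spacing, from each outside voxel center to the HR-CTV *surface*. The
surface is estimated at subvoxel resolution: the binary mask is
smoothed with a Gaussian (sigma = one voxel), the 0.5 level set is
extracted with marching cubes (scikit-image), and each voxel takes its
distance to the nearest level-set vertex (KD-tree query, restricted to
the 5 cm band that can matter for ring membership).

Why not the plain center-to-center distance transform? Measuring to
the nearest structure-voxel *center* overestimates the distance to the
organ boundary by roughly a quarter voxel on average. That bias does
not shrink with resolution relative to the innermost ring's width: on a
20 mm sphere with a 20–40 mm shell organ, center-to-center distances
misestimate the first ring volume by ~4.5% at 1 mm voxels. The
level-set distance reduces that to 1.4% at 1 mm and 0.3% at 0.5 mm and
converges to the analytic surface distance — it models what a planning
system's margin tool expands (the contoured surface, not a voxel point
cloud). Structures too small to carry a smoothed surface (a few voxels;
the smoothed field never reaches 0.5) fall back to the distance to the
nearest voxel's rectangular cell.

## Dosimetry

Cumulative DVHs are computed bin-free from the sorted voxel-dose
multiset: one row per distinct dose level with the volume receiving at
least that dose. `D2cm3` (minimum dose to the hottest 2 cm^3) and `D90`
(dose covering 90% of the structure) interpolate that curve linearly in
volume; both agree with a brute-force sort-and-accumulate oracle to
1e-9 relative. Biological weighting uses the linear-quadratic EQD2,
`n·d·(d + α/β)/(2 + α/β)`, with α/β = 10 Gy for the target and 3 Gy for
organs at risk. Constraint checks are strict inequalities, and organs
missing from a plan are reported as `missing` rather than silently
passing.

The regression target is the dimensionless `D2cm3/Dprescription` with
`Dprescription = 7 Gy`; plans are normalized so the HR-CTV D90 equals
the prescription exactly, matching clinical normalization practice.

## Model

One ε-SVR with an RBF kernel `exp(−γ‖x−y‖²)` per organ. Features are
z-scored; `C ∈ {0.1, 1, 10, 100, 1000}` and `γ ∈ {0.001, 0.01, 0.1, 1,
10}` are selected by 5-fold cross-validated MSE on the training plans
only, with deterministic folds and ties broken toward the smaller `C`,
then smaller `γ` (flatter, smoother models). ε is 0.01 — one percent of
the prescription, below which residuals are clinically irrelevant.
The fitted model is stored as standardized support vectors, dual
coefficients and intercept in plain JSON, so prediction needs no
scikit-learn at load time and is bit-reproducible. The test suite
verifies the fit against an independent dual quadratic-program solve
(SLSQP) to 1e-4.

Evaluation reports per-organ training/validation MSE and R², the delta
summary (mean ± SD of |actual − predicted| ratio), per-feature Pearson
correlations against the actual ratio, and a paired t-test between
predicted and actual ratios (a significant result indicates systematic
bias, not just noise).

## Synthetic cohort

Real planning CTs cannot be redistributed, so experiments run on a
seeded synthetic cohort of 200 plans (160 train / 40 validation, split
by plan). Design goals, in order: (a) realize the volume-dose mechanism
the method exploits, (b) span realistic volume and dose ranges, (c) be
exactly reproducible and fast on one CPU.

* **Grid** — 80×96×80 voxels at 2.5 mm (20×24×20 cm), HR-CTV centered
  at fractional position (0.5, 0.4, 0.5) so the anterior bladder fits.
* **Anatomy** — ellipsoidal HR-CTV (mean semi-axis U(19, 27) mm with
  ±2 mm per-axis aspect jitter, ~8–80 cm^3); bladder: anterior
  ellipsoid (r, r, 0.8r), r ~ U(28, 42) mm, standoff gap U(1, 12) mm;
  rectum: posterior z-tube, radius U(10, 16) mm, gap U(0.5, 10) mm;
  sigmoid: superior-posterior tube, radius U(8, 14) mm, gap
  U(1, 12) mm; small intestine: four-blob cluster at an *absolute*
  height U(42, 52) mm above the pelvic floor, raised 1.2 mm per mm of
  bladder radius above its midpoint (a full bladder pushes bowel up;
  this reproduces the positive bladder-volume / intestine-dose
  correlation). Organs are carved to be disjoint from the target;
  draws that leave an organ under 2 cm^3 (D2cm3 undefined) are retried
  with fresh randomness, at most 20 times.
* **Dose** — point-source inverse-square engine: five tandem dwells
  along the HR-CTV axis plus two ovoid dwells ±12 mm, dwell weights
  jittered ±5%, radii clipped at 1 mm. No tissue attenuation or
  anisotropy: ring features only claim to capture the geometric
  falloff, and inverse square *is* that falloff.
* **Determinism** — per-plan generators are spawned as
  `default_rng([seed, plan_index])` (structures) and
  `default_rng([seed, plan_index, 1])` (dwells), so any plan can be
  regenerated in isolation and cohorts are byte-identical across runs
  and platforms.

Generator parameters were fixed at design time by requiring the
mechanism (more organ volume in the near rings ⇒ higher ratio, Pearson
r > 0 with p < 0.05) and the headline training bar (MSE < 0.05,
R² > 0.9 for every organ) to hold across several unrelated seeds,
not tuned to any single evaluation seed.

## Limitations

* The dose engine omits source anisotropy, attenuation and applicator
  shielding; absolute D2cm3 values are optimistic, though the
  *relative* anatomy-dose relationship the model learns is the real
  inverse-square mechanism.
* Synthetic anatomy is convex-ish and smooth; real sigmoid loops and
  bowel folding produce noisier ring features, so validation deltas on
  clinical data should be expected to exceed the synthetic ones
  (~1–2% of prescription).
* Training R² is reported on the training set to match the headline
  quality bar; validation metrics are reported alongside and are the
  honest generalization numbers.
* The QA threshold (delta = 0.10) is a policy default, not a learned
  quantity; clinics should calibrate it to their own plan population.
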