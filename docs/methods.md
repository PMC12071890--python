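# Methods

`sctselect` implements an expedited photon-vs-proton treatment-modality
comparison that runs from a diagnostic CT (dCT) instead of waiting for the
planning CT (pCT).  A registration network predicts, from the dCT alone, the
deformation that maps the diagnostic anatomy onto a planning-like geometry;
warping the dCT by that field yields a synthetic CT (sCT).  Photon and proton
dose distributions are then evaluated on the sCT, organ-at-risk DVH metrics
and LKB complication probabilities are compared between the two modalities,
and the question asked is: *does the sCT-based comparison point at the same
advantageous modality as the pCT-based one?*

## The registration model

The network is a 3D encoder–decoder (a compact U-Net) mapping a
single-channel HU volume to a 3-channel displacement field u(x) in mm with
the same spatial size as the input.  Each level applies a same-padded 3³
convolution, batch normalization, and a PReLU nonlinearity; downsampling is
2× average pooling with channel doubling, upsampling is nearest-neighbour
with skip concatenation; a zero-initialized 1³ head emits the field, so an
untrained model predicts the identity transform — the standard safe start
for registration networks.  The default configuration uses 3 resolution
levels and 32 initial channels (7 conv blocks: 3 encoding, a bottom block,
3 decoding); tests and the bundled pipeline use a 2-level, 8-channel variant
on 32×32×16 grids so experiments complete in seconds on one CPU core.

The sCT is produced by *backward warping*: the output voxel at x samples the
dCT at x + u(x) trilinearly, with border values outside the grid.
Displacements are stored in millimetres and converted to voxel units through
the grid spacing, so a field survives resampling between grids; a predicted
field is also reused (nearest-neighbour) to carry target and organ contours
onto the sCT.

The training objective is

    loss = (1 − SSIM(warp(dCT, u), pCT)) + λ · R(u)

with SSIM evaluated over sliding 7³ windows on intensities normalized to
[0, 1] by a fixed [−1000, 1000] HU window (constants C1 = 0.01², C2 = 0.03²),
and R the diffusion regularizer — the mean squared forward-difference
spatial gradient of each displacement component, in dimensionless strain
units.  Optimization is Adam; the reference configuration is learning rate
1e−5, batch size 2, 1500 epochs, λ = 0.01.  Desk-scale runs in this
repository use learning rate 2e−3 and 40–150 epochs.

The network and its training loop are implemented directly over numpy with a
small reverse-mode autodifferentiation engine (`sctselect.dvfnet.autodiff`):
convolution via sliding-window tensor contractions, custom backward passes
for pooling, batch normalization, PReLU, the box filters inside SSIM, and
the warp's gradient with respect to the displacement.  Everything is float64
and free of hidden nondeterminism, so a seeded training run reproduces its
loss history bit-for-bit — a property the pipeline's reproducibility
contract relies on.  All custom gradients are finite-difference checked in
the test suite.

### Choice of λ at desk scale

λ trades image match against field smoothness.  The synthetic ground-truth
deformations used here are very smooth (Gaussian blobs of 30–60 mm width,
≤ 8 mm amplitude); on 8–10 mm voxels with σ = 5 HU noise, weak
regularization (λ ≈ 0.01) lets the network fit noise by inventing
deformation inside homogeneous regions: the image loss keeps falling while
the mean end-point error against the true field rises above its
pre-training value.  With λ = 1.0 the recovered field tracks the true one
(mean end-point error 0.8–1.2 mm for fields averaging 1.0–1.3 mm inside the
body) while the image error still improves.  The desk-scale pipeline and
the recovery experiments therefore default to λ = 1.0; λ remains a TrainSpec
parameter for other regimes.

## Preprocessing

- **Couch removal.**  Foreground = voxels above −250 HU; morphological
  closing (5 mm ball, edge-replicated padding so anatomy running off the
  grid is not eroded), largest 3D connected component, hole filling;
  everything outside is set to −1000 HU.  Idempotent by construction.
- **Truncation QA.**  A scan whose body is cut by the field of view is
  flagged, not repaired: the flag fires when the body touches ≥ 3 of the 4
  lateral volume faces, or when the body's lateral area profile stays flat
  (end-plane area > 80% of the plane one step inward, and > 5% of the peak
  cross-section) instead of tapering — smooth anatomy shrinks toward its
  lateral extremes, a reconstruction cut does not.  The pipeline excludes
  flagged cases from comparison.
- **HU normalization.**  Classical histogram (quantile) matching of the dCT
  to the pCT, restricted to body voxels (air and couch would dominate
  otherwise), 256 quantile knots, monotone by construction, applied with
  linear interpolation and identity-slope extrapolation tails.
- **Rigid alignment.**  Translation-only: initialized at the body-centroid
  difference, refined by exhaustive normalized-cross-correlation search
  (±10 mm at 2 mm steps, then a ±1.5 mm local pass at 0.5 mm) over the body
  union, applied by trilinear resampling.  Rotation is assumed negligible
  for supine thorax positioning.  Integer-voxel candidate shifts use exact
  slicing, so constructed voxel-aligned shifts are recovered exactly.
- **Resampling** to the network grid preserves the physical extent
  (spacing rescaled, voxel centers mapped center-to-center); masks resample
  nearest-neighbour.  **Augmentation** provides in-plane 45° clockwise
  rotation (air-padded) and left–right flip, applied jointly to a pair and
  its masks.

## Dosimetry and the LKB model

Cumulative DVHs are computed from the voxel dose multiset inside each
structure on uniform 0.1 Gy bins, with VxGy the percentage of structure
volume receiving ≥ x Gy (relative volumes; linear interpolation between
edges).  The compared panel is esophagus (mean, V35Gy, V60Gy), total lung
(mean, V10Gy, V20Gy), heart (mean, max, V30Gy).  Mean and gEUD are evaluated
from the differential curve at bin centers — unbiased for continuous dose
distributions; fixtures that need edge-exact values use finer bins.

The LKB model reduces a DVH to the generalized equivalent uniform dose
Deff = (Σ v_i d_i^{1/n})^n and maps it through the probit response
NTCP = Φ((Deff − TD50)/(m·TD50)).  Parameters ship in a YAML file
(`sctselect/data/lkb_defaults.yaml`) with the classical Burman/Emami fits —
heart pericarditis (48 Gy, 0.10, 0.35), lung pneumonitis (24.5 Gy, 0.18,
0.87), esophagus perforation (68 Gy, 0.11, 0.06) — and are meant to be
overridden by institution-specific values.  Physical dose is used directly;
no fractionation (EQD2) conversion is applied.

Per endpoint and case the workflow forms ΔNTCP = NTCP_proton − NTCP_photon
separately on sCT and pCT; a negative value favors the proton plan.
Endpoint-cases whose four NTCP values (2 modalities × 2 CTs) all stay at or
below 0.05% are excluded as irrelevant to the decision; inclusion requires
only one value above threshold, since requiring all four would drop one side
of a paired comparison.  Zero differences count as concordant with either
sign.  The report carries per-pair concordance, the overall trend accuracy,
Lin's CCC over the paired differences, and per-structure mean |Δ^(sCT−pCT)|
and medians.

Agreement statistics: MAE in HU (all voxels by default; body-masked variant
available), the Wang–Bovik UQI (global formula by default, windowed mode
available — both are reported because whole-volume QA tables do not fix the
choice), and Lin's CCC with population moments, with the qualitative bands
≥ 0.99 near-perfect, 0.95–0.99 substantial, 0.90–0.95 moderate, < 0.90 poor
(lower edges closed).

## The synthetic cohort

Real paired dCT/pCT data are not redistributable, so the phantom module
generates them: an elliptic body with fat/muscle/soft-tissue layers, two
lung ellipsoids, heart, esophagus, spine, and a CTV lesion in the upper
lung; HU assignments use standard CT ranges (air −1000, lung −700, fat −90,
soft tissue 20, muscle 40, bone 400, couch 200), all configurable, with
additive Gaussian noise (σ = 5 HU default).  A case pairs a pCT (flat
treatment couch) with a dCT derived from the same anatomy by a smooth
random displacement (sum of Gaussian blobs, amplitudes capped below the
blob widths so the field stays diffeomorphic — verified by the Jacobian
determinant), plus a curved scanner bed, a +30 HU protocol offset inside
the body, and vessel contrast present only at diagnosis.  The ground-truth
field a perfect network would predict is the numerical (fixed-point)
inverse of the generating field.

Dose fields are geometric, not physics-based: the target receives the
prescription exactly; photon-like fields fall off exponentially with
distance from the target (28 mm length) and add an entrance channel along
the anterior beam axis; proton-like fields fall off sharply (9 mm) and are
zero beyond a distal margin.  Swapping the falloff roles produces
photon-favoring cases, so the sign of every organ-level comparison is known
by construction — this gives the end-to-end tests their ground truth.  At
the default geometry only the lung endpoint (which contains the target)
exceeds the 0.05% relevance threshold; the distant serial organs fall below
it and exercise the exclusion path.

What the phantoms do *not* emulate: real tissue heterogeneity and texture,
bony-anatomy detail, breathing motion, arm-position differences, scanner
reconstruction kernels, or physical beam transport.  Passing tests
demonstrate that the algorithms are implemented correctly and that the
workflow's decision logic is sound under controlled conditions — not that
the network generalizes to clinical image statistics.

## Numerical and design choices

- Grids are index-ordered (x, y, z) with world coordinate
  origin + index·spacing; axis 1 points anterior→posterior; volumes, masks,
  doses and fields round-trip through NIfTI.
- Problem sizes: tests and the acceptance script run 10-case cohorts at
  32×32×16 (8×8×10 mm voxels), training on 2 pairs for 40–150 epochs with
  the 2-level/8-channel network — the package's desk-scale reference
  configuration; every size is a config parameter.
- The histogram LUT collapses duplicate quantile knots and enforces
  monotonicity by a running maximum; out-of-domain HU clamp to
  identity-slope tails.
- The relevance threshold comparison is strict (> 0.05%); ties at the
  threshold are excluded.
- All randomness flows from one root seed through named substreams; JSON
  reports are written with sorted keys so reproducibility can be checked
  byte-wise.

## Known limitations

- The dose model cannot produce range-uncertainty or motion-robustness
  effects; conclusions about those clinical questions are out of scope.
- NTCP magnitudes depend entirely on the LKB parameter file; only the
  proton-vs-photon *trend* logic is parameter-robust.
- Translation-only rigid alignment will under-correct rotated acquisitions.
- The windowed UQI skips windows with vanishing denominators, which slightly
  biases it upward on large air regions; use the body-masked global variant
  when that matters.
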