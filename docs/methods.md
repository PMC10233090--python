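# Methods

This note documents the models, algorithms and numerical choices behind
`octowound`, in the order data flows through the pipeline.

## Scan model and units

A 3D OCT scan is an ordered stack of `n_frames` cross-sectional B-scan
frames, each a depth-by-lateral grayscale image. Frame `i` is centred at
lateral position `(i + 0.5) * frame_spacing`. The default geometry is the
acquisition protocol the package targets: 120 frames at 0.05 mm spacing
(6.0 mm lateral span) over a 3 mm punch-biopsy wound, with an isotropic
in-frame pixel pitch of 5 µm. All lengths are mm, areas mm², volumes mm³;
intensities live in [0, 1]. The in-frame pixel dimensions of the scanner
are not fixed by the protocol, so frame size and pitch are fully
configurable; the full-scale default is 256 × 700 px (1.28 mm deep ×
3.5 mm wide — wide enough to contain the 3 mm crater with margin).

Tissue classes use a fixed integer code table (0 NON_TISSUE,
1 INTACT_TISSUE, 2 EARLY_GRANULATION, 3 LATE_GRANULATION,
4 NEO_EPIDERMIS, 5 BLOOD_CLOT, 6 ACTIVE_BLEEDING). NON_TISSUE doubles as
the background above the skin surface and as the code for pixels excluded
from analysis. The quantified subset is classes 2–5.

## Synthetic wound phantoms

The phantom generator exists so that every downstream stage — training,
prediction, cleaning, volumetry, agreement statistics — can be tested
against exact ground truth without patient data.

**Geometry.** An undulating skin surface (sum of low-frequency sinusoids
with seeded random phases, default mean depth 0.35 mm, amplitude 0.05 mm)
separates dark non-tissue from speckled tissue. A vertical-walled crater
of `wound_diameter` (default 3 mm) is centred in plan view.

**Voxel-exact carving.** Target volumes for the four wound classes are
converted to voxel counts and assigned inside the crater by sorted depth
below the local surface: early granulation fills the bottom, late
granulation the middle. The depth ordering carries a mild central bias
(`depth + 0.3 × (R − r)`), so that as granulation resolves the residual
volume remains a coherent pocket at the wound centre — mirroring healing
that advances inward from the margins — rather than degrading into
scattered one-voxel sheets whose lateral extent would be an unstable
max-statistic. The residual top shell is split into
neo-epidermal tongues that wrap in from the crater rim (score
`depth + (radius − r)`, lowest first) and a central blood-clot cap.
Realised class volumes therefore match the requested targets to within
one voxel — tighter than any downstream tolerance. If the targets exceed
the crater capacity (depth capped at 0.95 mm so the wound stays inside
the 1 mm analysis depth) a geometry error names the worst-offending
class.

**Healing trajectory.** Default targets interpolate linearly between
day-2-like anchors (EGT 1.56, LGT 2.12, NE 0.90, CLOT 1.28 mm³) and
day-7-like anchors (EGT 0.09, LGT 0.87, NE 1.46, CLOT 2.68 mm³) — the
placebo set-1 cohort means of the study the package re-implements — via a
stage parameter in [0, 1]. Early granulation is thus non-increasing and
clot non-decreasing in stage. Anchors are overridable.

**Appearance model.** Intensity = class mean reflectivity × exponential
depth attenuation (default 0.5 mm⁻¹ below the local surface) ×
multiplicative gamma speckle (mean 1, per-class shape), followed by a
0.6 px lateral Gaussian blur emulating finite speckle grain, clipped to
[0, 1]. The class signatures are deliberately distinct in both mean and
texture — dark disorganised immature granulation (0.25, shape 3),
intermediate homogeneous maturing granulation (0.42, shape 10), bright
smooth neo-epidermis (0.78, shape 12), bright strongly heterogeneous
clot/scab (0.92, shape 2), intact dermis 0.60 (shape 4 default) — because
the premise being emulated is that the tissue morphologies are visually
distinguishable on OCT. Active bleeding is omitted from default phantoms
(rare in practice); an override injects it for class-coverage tests.

**What the phantom does not model:** wave-optics (refraction, shadowing,
multiple scattering), polarisation, motion artefacts, inter-patient
texture variability, and annotation noise — real ground truth is a human
judgement, the phantom's is exact. Passing the surrogate reliability
checks therefore demonstrates the pipeline's internal consistency at
realistic geometry and noise, not clinical-grade accuracy on patient
scans.

**Cohorts** derive per-scan seeds from a base seed and jitter crater
diameter (±5%) and surface undulation (±30%) so cohorts are
non-degenerate; generation is bit-reproducible.

## Segmentation network and training

The segmenter is the classical u-net: `depth` encoder levels of two 3×3
same-padding convolutions + ReLU, 2×2 max-pooling between levels,
channels doubling from `base_channels`; a mirrored decoder with 2×
nearest-neighbour upsampling and skip concatenation; a 1×1 convolution to
7 per-pixel logits. It is implemented directly in NumPy (im2col
convolutions, analytically derived gradients, verified against central
differences in the test suite), which keeps the package dependency-light
and the arithmetic fully inspectable.

Training follows the reference regime: stochastic gradient descent with
momentum 0.9 at a learning rate of 0.05, L2 regularisation 1e-4,
mini-batches of 16 whole frames, data reshuffled every epoch under the
run seed; the loss is unweighted pixel-wise cross-entropy. "Mini-batch
accuracy" is the fraction of correctly classified pixels in the current
training batch; the final iteration's value summarises a run.

Three numerical choices keep this hot regime stable:

* inputs are min-max scaled per frame and then mean-centred
  (zero-centred inputs prevent first-layer ReLU death);
* weights use Glorot initialisation (biases zero);
* gradients are globally norm-clipped at 1.0. Healthy steps have norms
  around 0.1–0.8; rare spike events (observed norms ~50) otherwise
  capsize the weights under momentum and strand training at a
  constant-predictor plateau.

Class imbalance (wound tissue is a small fraction of each scan) is not
addressed by loss weighting but by the training-frame selection, which
stratifies across healing stages; whole frames are used rather than
random crops. Prediction is per-pixel argmax (ties to the lowest class
code), frame by frame; frames not divisible by `2**depth` are
reflect-padded and cropped back.

**Desk scale.** The package's default experiment scale — used by the test
suite and the acceptance script — is 64×64 px frames at 50 µm pitch, 12
frames per scan at 0.5 mm spacing (same 6 mm span), 18 training scans
(216 frames, ≥ 200), u-net depth 3 with 16 base channels (~487 k
parameters), 20 epochs. This trains in a few minutes on one CPU while
preserving every structural property of the full-scale problem
(full-scale: depth 4, 16–64 base channels, 100 epochs).

## Post-processing

Raw per-frame predictions are cleaned per frame, in a fixed order:

1. **Isolated pixels** (no same-class neighbour under 8-connectivity by
   default) are reassigned to the modal neighbour class, ties to the
   lowest code.
2. **Small islands**: per-class connected components smaller than a
   physical area threshold (default 0.0016 mm², i.e. 64 px at 5 µm
   pitch, converted by pitch²) are absorbed into the modal class of
   their boundary ring.
3. **Boundary smoothing**: each wound-class component's outer contour is
   expanded in Kuhl–Giardina elliptic Fourier descriptors, truncated to
   `n_fourier_harmonics` (default 16), re-rasterised; pixels lost revert
   to their nearest surrounding class, pixels gained take the class.
   Interior holes are preserved; contours under 8 points pass through.
   With enough harmonics the operation is the identity.
4. **Surface detection**: first supra-threshold pixel per column (Otsu
   threshold over the frame), median-filtered across columns (window 15);
   columns with no supra-threshold pixel fall to the frame bottom and are
   logged.
5. **Depth truncation**: pixels more than 1 mm (configurable) below the
   detected surface become NON_TISSUE, reflecting the physical
   penetration limit of OCT.

Truncation is placed last so the 1 mm cut is exact. Every operator
reassigns labels and never drops pixels. The pipeline is strictly 2D per
frame; no inter-frame smoothing is applied.

## Volumetry

Per frame and class, area = pixel count × pitch²; per scan,
volume = Σ areas × frame spacing — an identity that holds to machine
precision and is asserted as such. Two caliper-style measurements mirror
single-frame manual measurements: wound width (longest contiguous
lateral span of early granulation in any single frame; an alternative
bounding-box definition is available by flag) and clot depth (longest
contiguous vertical run of clot in any single column). Replicate scans
of one biopsy are averaged arithmetically.

## Agreement statistics

Reliability between paired series uses ICC(2,1) — two-way random
effects, absolute agreement, single measures — computed from the ANOVA
mean squares (formula in the docstring); the form is stated prominently
because "ICC" alone is ambiguous. Bland–Altman limits of agreement are
bias ± 2 × SD of the differences — exactly 2 by convention here, not
1.96. Pearson and Spearman coefficients carry two-sided p-values;
p-values are reported, never used for gating. Zero-variance inputs
return NaN sentinels rather than raising.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` train the desk-scale model
once (216 frames, 20 epochs ≈ 270 iterations) and evaluate on an
independent 30-phantom cohort with stages spread over [0, 1]. Property
suites (oracle equivalences, identities, determinism) run on small
frames (20×20 to 64×192). The demo CLI verb uses 6 scans × 8 frames and
4 epochs.

## Known limitations

* The NumPy network trains on CPU only and at desk scale; it is not a
  performance-parity reimplementation of a GPU training stack.
* Phantom realism is first-order (see above); in particular speckle is
  spatially near-white, whereas real OCT speckle has scanner-specific
  correlation structure.
* Surface detection assumes the air–tissue interface is the first bright
  return; immersion gel or strong specular artefacts would need a
  different detector.
* The biopsy pairing that maps scans to averaged samples is user-supplied
  metadata; no pairing heuristic is attempted.
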