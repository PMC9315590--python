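# Methods

This note records the models, parameter choices and numerical decisions
behind `collateral4d`, and what the synthetic experiments can and cannot
say about clinical data.

## The synthetic dynamic study

### Acquisition protocol

A study is one baseline non-contrast volume at 0 s followed by 18 timed
contrast volumes: 2 s intermittent sampling through the arterial window
(11, 13, …, 35 s) and 5 s sampling through the venous window (40, 45, …,
60 s) — 19 volumes over 60 s. This is the only sampling grid whose
arterial window (11–36 s at 2 s) and venous window (40–60 s at 5 s) sum
to 19 volumes with the baseline, so it is fixed as `make_protocol()`.

### Bolus model

Compartment enhancement follows a gamma-variate,

```
C(t) = A · ((t − t0)/(αβ))^α · exp(α − (t − t0)/β),   t > t0,
```

parameterised so the peak value is exactly `A` at `t = t0 + αβ`. The
gamma-variate is the standard closed-form model of a contrast bolus and
guarantees the single-peaked "bell" shape the landmark logic assumes.
Default parameter ranges (drawn per study):

| compartment | t0 (s) | α | β (s) | A (HU) | analytic peak |
| --- | --- | --- | --- | --- | --- |
| artery | U(8, 10.5) | 3 | U(3.0, 3.8) | U(180, 260) | 17–22 s |
| vein | U(27.5, 29) | 3 | U(4.2, 4.8) | U(110, 150) | 40–43 s |
| collateral | artery t0 + U(1.5, 3.5) | 2.5 | artery β + U(1, 2) | 0.7–0.9 × artery A | delayed, broader |

The venous ranges were chosen so that the peak lands inside the venous
window and the curve falls below half its peak with a flat forward slope
before 60 s, i.e. the late-venous plateau is reachable within the
acquisition for most draws.

### Anatomy and rendering

The phantom is deliberately minimal: an ellipsoidal bone shell at
1000 HU around a parenchyma ellipsoid at 30 HU (air at −1000 HU);
crude tubular arterial trees (trunk plus lateral branches) in each
hemisphere; midline venous sinus tubes; and short scattered collateral
tubes confined to the occluded territory. The occluded territory is the
lateral half of the brain on the occluded side of the sagittal
mid-plane; mirroring across that plane defines the contralateral
territory. Compartments are kept voxel-disjoint so an ROI dropped on a
vessel measures exactly one compartment's time course. Optional
zero-mean Gaussian noise (default σ = 2 HU; σ = 1 HU in the
high-contrast experiment preset; σ = 0 for landmark-recovery checks) is
added independently per volume. Arterial vessels on the occluded side
never opacify (the occlusion); the contralateral tree follows the
arterial curve.

### Collateral filling and grading

Ground truth per study is the fraction of collateral vessels opacified
at each of the four phases, non-decreasing in [0, 1]. Each collateral
segment gets a uniform quantile `u`; inverting the piecewise-linear fill
schedule gives the segment's opacification onset, after which it follows
its own gamma-variate started at that onset — so late-filling
collaterals are bright late, as in real delayed filling. The 0–4 grade
discretises the schedule with two configurable thresholds, `few = 0.1`
and `complete = 0.9` (the clinical scale's "few/partial/complete"
wording is qualitative; these cut-offs are a modelling choice, not an
inferred quantity):

* 0 — maximum fill < few at every phase;
* 4 — fill ≥ complete before the venous phase (read at the
  arteriovenous entry);
* 3 — fill ≥ complete by the late venous phase;
* 2 — fill ≥ few before the venous phase;
* 1 — otherwise (partial filling only by the late venous phase).

Evaluating the branches in the order 0, 4, 3, 2, 1 makes the grade
monotone in the fill vector (property-tested). Good = grade ≥ 3.

Cohort generation draws grades within each requested class either
uniformly or from a "strong" preset (good {4: 0.7, 3: 0.3}, poor
{0: 0.5, 1: 0.5}) used by the desk-scale experiment, where the
separation between classes is intentionally high: grade 2 is excluded
there because its filling fractions run up to just below the
`complete` threshold, so grade-2-poor and grade-3-good montages
overlap by construction and belong to the harder uniform regime, not
the easy one. Covariates (age, sex,
NIHSS, onset bin, occluded artery, TOAST type, treatment, hemorrhagic
transformation) are drawn from per-class distributions qualitatively
matching a 92-patient anterior-circulation LVO cohort profile; a
`group_effect=False` switch pools the distributions for type-I-error
calibration.

## Landmark detection

TDCs are ROI means per contrast frame minus the NCCT ROI mean. Quality
control requires a single interior local maximum with prominence ≥ 10 %
of the global maximum ("bell-shaped"). Landmarks resolve to acquired
frames because the clinical procedure picks *volumes*:

* peaks are global-maximum samples, no sub-frame interpolation; ties
  break to the earlier frame (earlier reperfusion information wins);
* the artery–vein crossing is the first sign change (≥ 0 → < 0) of the
  linearly interpolated difference after the arterial peak, clamped to
  at most the venous peak time; the crossing time snaps to the nearest
  frame, bumped one frame forward if snapping would collide with the
  arterial-peak frame (the phase ordering must stay strict). If the
  curves never cross, the frame minimising |difference| in the window
  is returned and flagged;
* the late venous frame is the first post-peak frame with value ≤ 50 %
  of the venous peak **and** forward finite-difference slope ≤ 5 HU/s;
  if none qualifies the last frame is returned and flagged. Both knobs
  are exposed. The last frame itself has no forward difference and is
  never a regular candidate.

Whether the crossing should be computed on raw or smoothed curves is
not specified by the clinical procedure; raw curves with first-crossing
semantics are used here.

## Subtraction and montage

Phase volumes are `max(frame − NCCT, 0)` with voxels at NCCT ≥ 150 HU
zeroed. Negative differences are clipped because noise-induced negative
values would otherwise survive into the maximum projections. The
simulation renders co-registered frames, so no motion correction or
registration is attempted. Subtracted volumes are windowed linearly to
[0, 1] over 0–300 HU (vessel-contrast range), projected along z (axial
MIP), and stitched row-major into a 2×2 montage (arterial,
arteriovenous / venous, late venous). The 2×2 layout keeps the
classifier input square; quadrant crops are bit-identical to the source
MIPs.

## Networks

Both variants share one backbone: 3×3 convolution stem (stride 1, pad
1), 3×3 max pool (stride 2), four residual stages with (3, 4, 6, 3)
basic blocks — each block two 3×3 convolutions with batch norm and an
elementwise skip addition, with a strided 1×1 projection when the shape
changes — global average pooling and a 2-way fully connected softmax
head. The 3×3 stem (rather than the canonical 7×7) is deliberate.
Stage widths are (w, 2w, 4w, 8w); `w = 64` is the full-scale network
and `w = 8` the desk-scale default, chosen from a CPU runtime benchmark
of the conv stack so the five-iteration experiment for both variants
completes in minutes on one core.

The implementation is a self-contained numpy layer stack with
hand-written backprop (shifted-slice matmul convolutions, exact batch
norm gradients), verified against central-difference numerical
gradients in the test suite. Convolution weights are He-initialised
from the config seed; the final linear head is zero-initialised, so
training moves the logits along the class-discriminative direction from
the first step — with few optimisation steps this makes the *ranking*
of test scores informative long before the absolute probabilities
calibrate.

Training: Adam (lr 1e-4, β = 0.9/0.999), batch 16, softmax
cross-entropy (the natural loss for the 2-way softmax head), epoch cap
10, early stop after 2 epochs without an epoch-mean-loss improvement
> 1e-4. The multi-input variant trains its four branches independently,
one per phase MIP, and averages the four probability vectors at
inference with uniform weights (exposed in the config). Prediction is
the class with the larger probability; an exact tie predicts poor — the
conservative call, since a poor-collateral label flags the patient for
urgent review. A pretrained-initialisation hook exists in the config
but no weights are bundled; initialisation is random and seeded.

## Evaluation

Monte Carlo cross-validation draws independent 70/30 splits (train size
= ⌈0.7 n⌉, forced by 92 → 65/27), stratified by class so desk-scale
test sets always contain both classes. Metrics use good collateral as
the positive class (configurable): accuracy, precision, recall, F1;
metrics with zero denominators are reported missing rather than
imputed. ROC curves enumerate all score thresholds with ties grouped;
AUC is trapezoidal and equals pairwise concordance (property-tested
against the Mann–Whitney formulation). Aggregation reports mean ±
sample (n−1) SD per metric and a vertically averaged ROC on a 0–1 FPR
grid at step 0.01 with a ±1 SD band clipped to [0, 1].

At desk scale the experiment is 40 + 40 studies at 16 × 64 × 64 voxels,
five iterations, width-8 networks — sizes chosen so the whole
experiment is a few CPU-minutes. With ≤ 40 gradient steps per split at
the fixed learning rate, threshold-dependent metrics (accuracy)
mature much more slowly than ranking metrics (AUC); the single-input
desk-scale experiment is therefore summarised primarily by its mean
AUC.

## Cohort statistics

Continuous covariates route through a per-group Shapiro–Wilk gate at
α = 0.05: normal → pooled-variance two-sample t-test (computable from
raw values or (n, mean, SD) summaries), non-normal → Mann–Whitney U
(exact enumeration for tie-free samples with both n ≤ 20, otherwise
the tie-corrected normal approximation). Categorical covariates use
Pearson χ² **without** continuity correction — the uncorrected variant
is the one that reproduces the bundled reference table's p values
(gender 0.341, onset 0.132, treatment 0.729, hemorrhage 0.025, age via
pooled t 0.038); the Yates-corrected hemorrhage p (≈ 0.048) serves as
a negative control in the tests. Kruskal–Wallis and one-way ANOVA are
provided for multi-group comparisons. No multiple-testing adjustment is
applied (the table reports unadjusted p values).

Two reference rows do not reproduce from their printed counts under any
uncorrected Pearson χ² (occluded artery: recomputed ≈ 0.038 vs printed
0.041; TOAST: ≈ 0.156 vs 0.126) — plausibly category merging or an
exact test was used; these rows are retained in the fixture but are not
validation targets. The NIHSS row is printed as median (IQR) only,
which under-determines the rank test, so it is likewise not a numeric
target.

## What passing tests do and do not show

The generator produces geometrically crude, perfectly co-registered,
noise-stationary studies whose class signal (collateral opacification
in one hemisphere) is far cleaner than clinical reality: no motion, no
beam hardening, no anatomical variation, no borderline grades read by
human raters. Passing the desk-scale experiment therefore demonstrates
that the pipeline is wired correctly end to end and that the
architecture can learn the intended image feature — not that the
clinical performance figures would be matched on real patients. The
published clinical metrics were measured on a private cohort and are
out of reach by construction; the in-package targets are the protocol
arithmetic, the split geometry, the reference-table statistics,
landmark recovery, and a high-AUC bar on the easy synthetic cohort.

## Known limitations

* Vessel geometry is non-anatomical by design (no Willis circle, no
  perfusion maps, no deconvolution).
* Grade thresholds (`few`, `complete`) are modelling constants, not
  estimates.
* The multi-input variant trains branches independently; end-to-end
  joint training through the averaged probability is not implemented.
* Desk-scale accuracy is threshold-limited (see above); only the
  ranking behaviour is asserted.
* Automatic artery/vein ROI detection is out of scope; ROIs come from
  the generator's ground truth or the caller.
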