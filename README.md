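# collateral4d

Synthetic-data pipeline for assessing **collateral circulation** in acute
ischemic stroke from dynamic 4D CT angiography (4D-CTA).

In large-vessel-occlusion stroke, the quality of collateral blood supply to
the occluded territory — graded 0–4 on the modified ASITN/SIR scale and
dichotomised as *good* (3–4) vs *poor* (0–2) — drives treatment selection and
prognosis. One-stop dynamic CT perfusion acquisitions yield a time-resolved
angiogram from which four hemodynamic phases can be read off the arterial and
venous time–density curves (TDCs):

* **arterial phase** — the frame at the arterial TDC peak,
* **arteriovenous phase** — the frame at the artery–vein curve crossing,
* **venous phase** — the frame at the venous TDC peak,
* **late venous phase** — the first frame after the venous curve settles into
  its plateau.

Subtracting the baseline non-contrast CT (NCCT) from each phase volume,
removing bone, taking axial maximum intensity projections (MIPs) and
stitching the four phases into one 2×2 montage produces a single image that a
residual convolutional network can classify as good vs poor collateral
circulation. Because clinical 4D-CTA datasets of this kind are not public,
this package ships a first-class synthetic-study generator so the entire
analysis is reproducible from nothing but a seed.

## What is in the box

| module | role |
| --- | --- |
| `collateral4d.synthetic` | 19-volume acquisition protocol (0 s baseline; 2 s sampling at 11–35 s; 5 s sampling at 40–60 s), gamma-variate bolus model, vessel/bone/parenchyma phantom renderer, 0–4 collateral grading from per-phase filling fractions, cohort generator with clinically plausible covariates |
| `collateral4d.landmarks` | TDC extraction from caller-supplied ROIs, bell-shape quality control, the four phase-landmark finders |
| `collateral4d.subtraction` | phase volume selection, NCCT subtraction with clipping, bone removal at 150 HU |
| `collateral4d.montage` | HU windowing to [0, 1], axial MIP, 2×2 four-phase montage |
| `collateral4d.networks` | ResNet34-style residual classifier (3×3 stem, (3, 4, 6, 3) basic blocks) in pure numpy with hand-written backprop; single-montage and four-branch (probability-averaging) variants; Adam, lr 1e-4, batch 16, ≤10 epochs with early stopping |
| `collateral4d.evaluation` | stratified Monte Carlo cross-validation (70/30), accuracy/precision/recall/F1, ROC + trapezoidal AUC, mean ± SD aggregation with a vertically averaged ROC band |
| `collateral4d.cohort_stats` | pooled t-test, uncorrected Pearson χ², Mann–Whitney U, Kruskal–Wallis, one-way ANOVA, and the normal/non-normal routing that produces a baseline-characteristics table |

A thin `collateral4d` CLI (`simulate`, `preprocess`, `train`, `evaluate`,
`stats`) wraps the library.

## Worked example

```python
import collateral4d as c4

# one synthetic poor-collateral study: NCCT + 18 contrast frames
study = c4.generate_study("poor", size=(16, 64, 64), seed=3, noise_sigma=0.0)
gt = study.ground_truth

art = c4.extract_tdc(study, gt.arterial_roi, "artery")
ven = c4.extract_tdc(study, gt.venous_roi, "vein")
print(c4.qc_curve(art).is_bell_shaped)     # True
lm = c4.landmarks(art, ven)
print(lm.times)            # (19.0, 33.284, 40.0, 55.0)
print(lm.frame_indices)    # (4, 11, 13, 16)

phases = c4.build_phase_set(study, lm)
montage, mips = c4.montage_from_phase_set(phases)
print(montage.values.shape)  # (128, 128)
```

The landmark times say: arterial peak at 19 s (frame 4), artery–vein crossing
interpolated to 33.3 s and snapped to the 33 s frame (11), venous peak at
40 s (frame 13), plateau reached at 55 s (frame 16) — all consistent with the
generating gamma-variate parameters (analytic arterial peak 19.2 s, venous
41.4 s).

A full classification experiment (80 studies, five Monte Carlo 70/30 splits):

```bash
collateral4d evaluate --variant single --seed 1 --out-dir scratch/run1
```

which writes per-iteration and aggregate metrics CSVs, ROC coordinates, and a
ROC figure (dashed per-iteration curves, solid mean, ±1 SD band).

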