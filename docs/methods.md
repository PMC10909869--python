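# Methods

`neurofuse` re-implements, as a tested and fully synthetic-data-driven
pipeline, a multi-modal deep-learning workflow for detecting Alzheimer's
disease from T1-weighted MRI and amyloid PET: longitudinal diagnosis-label
curation, brain-extraction preprocessing, eight CNN classification variants
(2D/3D, uni-/multi-modal), and Grad-CAM attribution of decisions to atlas
regions. Real cohorts of this kind are access-controlled, so the package
ships a generator that emulates their structure with known ground truth;
every quantitative claim the package makes is measured on that generator.

## The synthetic cohort generator

**Atlas.** An ellipsoidal "brain" (semi-axes 40% of each grid dimension)
partitioned into `n_regions` connected regions by multi-source
breadth-first growth from randomly placed seed voxels — a geodesic Voronoi
tessellation. A thin bright shell just outside the brain plays the role of
scalp/fat (T1) or scalp tracer uptake (PET). Default desk grid: 32x32x32,
10 regions.

**Volumes.** Each scan is: per-region baseline intensity (1.0 plus a small
deterministic region offset, shell at 2.5), plus — for positive disease
states — an additive effect of size `effect_size` in the modality's
`affected_regions`, plus a per-scan brain-wide intensity offset
(`brain_offset_sd`, default 0.2), plus i.i.d. Gaussian voxel noise
(`noise_sd`, default 0.2; effect-to-noise 5 at the default effect 1.0).
PET scans carry a time axis of `n_frames` frames whose per-voxel mean is
the 3D target; `noise_sd` denotes the noise of the frame *average* (frames
are drawn at sqrt(T) times that), so a stated effect-to-noise ratio means
the same thing for both modalities. MRI and PET effects default to
*disjoint* regions (3 and 8), making the modalities complementary by
construction.

Two generator features exist specifically so that attribution is a
meaningful question, and they matter for interpreting results:

* *The shell pins the intensity maximum.* Volumes are min-max normalized
  per volume before the model. Without a bright class-independent
  structure, the positive class's higher maximum (baseline + effect) would
  rescale every other region downward, smearing the planted effect into a
  global intensity signature — an artifact of normalization, not disease.
* *The brain-wide offset removes the global-mean shortcut.* With identical
  anatomy across subjects, a focal additive effect shifts the global brain
  mean into a perfectly separable feature, and a CNN will classify from it
  without ever localizing. Real cohorts have inter-subject and
  inter-session intensity variability far larger than any focal effect's
  global footprint; the offset (sd 0.2 vs the effect's ~0.07 global-mean
  footprint) restores that property. This was verified directly: without
  the offset, a perfectly accurate desk model showed spatially diffuse
  sensitivity; with it, occluding the planted region collapses the logit
  (drop ~3.0) while occluding any other region moves it by at most ~0.6.

**Timelines.** Per-subject visit schedules with gaps uniform in
`day_gap_range` (default 180-420 days). Negative subjects stay negative;
converters (probability = cohort prevalence) switch to positive at a
uniformly drawn onset visit. Each recorded diagnosis is independently
flipped with probability `flip_prob` (default 0.1) — the isolated errors
the label-correction stage exists to undo. Scan volumes are generated from
the *true* state; diagnosis events carry the corrupted labels, and the true
state is retained in scan metadata for evaluation only.

What the generator does **not** model: anatomy (gyri, tissue classes),
partial-volume effects, scanner physics and resolution harmonization,
registration error, longitudinal atrophy trajectories, or per-subject
effect-size heterogeneity. Passing tests therefore demonstrate that the
pipeline's logic is correct and that its statistical machinery behaves as
designed under controlled signal — not that comparable accuracy would be
reached on a real cohort.

## Label curation

A subject's time-ordered diagnosis labels are corrected in one simultaneous
pass over the original sequence: a negative flips to positive iff at least
one of the up-to-two preceding AND one of the up-to-two following original
labels is positive; symmetrically for positive to negative. Positions with
no neighbour on a side never change, and corrections do not cascade (the
pass reads only original labels), which makes the operation
order-independent. Note the rule is symmetric by construction: in
`[0,1,0,1,1]` both the isolated positive (position 1) and the sandwiched
negative (position 2) qualify, giving `[0,0,1,1,1]`.

Scans take the label of the temporally closest corrected diagnosis (exact
ties resolve to the earlier event). Repeat positives — consecutive positive
visits per subject and modality — keep only their earliest scan. Class
balance is restored by seeded uniform under-sampling of negatives and by
augmenting positives with compositions of in-plane 90-degree rotations and
left-right mirroring (the seven non-identity rigid transforms; each
augmented record keeps its source subject and transform tag, and the voxel
multiset is preserved exactly). Augmentation is applied only after the
patient-wise split and only to training data. Splits and stratified k-folds
operate on subjects, never scans, so no subject contributes to both sides.

On the default desk timelines correction is a modest win (scan-label error
~9% to ~8% at 5 visits): flips adjacent to a subject's true onset are
genuinely ambiguous under the rule and remain, as do flips at timeline
ends. With 2-visit timelines the rule is vacuous (no interior positions),
so the correction-quality measurement uses 5-visit cohorts.

## Preprocessing

4D PET stacks are collapsed to the per-voxel time average (in float64, so
noise-free frames reproduce the target bit-exactly). Each axial slice is
smoothed with a truncated, renormalized Gaussian — kernel 13x13, sigma 150
at paper scale; at sigma >> kernel the taps are uniform to within 1e-3, and
the operation is applied exactly as specified regardless — and thresholded
by Otsu's method (256 bins over the slice's own range; mathematically tied
splits, e.g. across empty bins, resolve to the lower threshold). One
guard was added: a slice contributes foreground only if its blurred maximum
exceeds the volume-wide Otsu threshold. Otsu always splits a histogram, so
slices containing only background noise would otherwise produce spurious
foreground and inflate the bounding box to the whole grid; the guard uses
the same primitive at volume level and leaves the per-slice threshold in
charge wherever brain is actually present.

The tightest box containing all foreground across slices is cropped,
resized bilinearly in-plane (no resampling along the slice axis), reduced
to the central `n` axial slices (floor(D/2)-centred, biased low on odd
remainders; 50 at paper scale, 12 at desk scale), and min-max normalized to
[0, 1] per volume. The desk configuration (3x3 blur, 32x32 in-plane, 12
slices) scales the paper-scale parameters proportionally to the grid.

## Models and training

All variants share one backbone: four convolutional blocks (3^d kernels,
stride 1, same padding; ReLU; max-pool 2; batch normalization) with
strictly increasing filter counts, then flatten, a dense stack, dropout
0.30, and a single sigmoid unit. Desk-scale filters are (4, 8, 16, 32)
with one 32-unit dense layer; paper scale (16, 32, 64, 128) with 128.
The eight variants: 2D MRI, 2D PET (slices as independent images), 3D MRI,
3D PET, transfer in both directions (feature blocks frozen bit-exactly,
classifier retrained), combined-input (one 3D branch trained on strictly
alternating MRI/PET batches, shorter stream recycled), and fusion (two
independent, non-weight-shared 3D branches whose flattened features are
concatenated before a shared classifier; prediction requires a scan pair).

Training: Adam, initial learning rate 5e-5 with exponential decay 0.96,
binary cross-entropy (computed in logit form for stability), early stopping
when validation accuracy fails to improve for 35 epochs, and restoration of
the best-validation weights. Implementation notes, with the reasoning:

* *Decay granularity.* The schedule is `5e-5 * 0.96^(epoch/decay_epochs)`.
  A strictly per-epoch decay extinguishes the rate within ~200 epochs,
  which cannot be reconciled with a training budget of up to 10,000 epochs;
  the desk configuration uses `decay_epochs = 100`, keeping the rate
  meaningful over long runs while preserving the stated decay constant.
  (`decay_epochs = 1` reproduces the strict per-epoch reading.)
* *Desk batch size 4.* The desk training set is ~40x smaller than a
  realistic cohort's, so with batch 8 an "epoch" is only ~10 optimizer
  updates and every epoch-denominated element of the protocol (patience,
  decay) sees far fewer updates than intended; batch 4 halves the gap.
* *Best-weights restoration ties.* On a small validation set, accuracy is
  coarse (steps of 1/n) and many epochs tie; ties are broken by lower
  validation loss. Without the tie-break, restoration routinely locked in
  a lucky, nearly-untrained early epoch (observed: held-out accuracy 0.62
  restored vs 0.88 at the final epoch of the same run).
* Classification threshold 0.5 on the sigmoid output; batch-norm uses
  running statistics at inference, dropout is inference-inactive, and a
  seeded run reproduces its history exactly.

The engine itself (convolution via im2col + BLAS matmul, with the input
gradient computed as a flipped-kernel convolution; max-pooling with
argmax routing; batch normalization; Adam) is a compact numpy
implementation with hand-written backward passes, gradient-checked against
finite differences in the test suite. This keeps intermediate activations
and their gradients directly addressable, which is exactly what Grad-CAM
consumes.

## Grad-CAM and region attribution

For a chosen convolutional layer with feature maps `A^k` and the positive
class score taken as the pre-sigmoid logit, the neuron importance weights
are the spatially pooled gradients `alpha_k = (1/Z) sum d(score)/dA^k`
(Z = number of spatial positions; for 3D models the pooling runs over all
three axes and Z is the voxel count), and the relevance map is
`L = ReLU(sum_k alpha_k A^k)` at the layer's resolution. The default layer
is the last convolutional one, per standard practice. Maps are upsampled
linearly (corner-aligned) to the input grid, mapped back through the
recorded crop/resize/slice geometry onto the scan grid, and overlaid on the
atlas: per-region mean relevance, with regions at or above the 90th
percentile of region means flagged as critical (ties at the cut included).
Because the central-slice window discards part of the brain, region means
can be restricted to the voxels the model actually saw (`mask=` argument);
regions with no seen voxel are excluded rather than scored zero. Group
attribution averages upsampled per-scan maps over all scans of a class
(optionally only correctly classified ones), computes the selection on the
group-mean map, and also reports each region's per-scan selection
frequency. Fusion models yield one map per branch.

## Desk-scale study conditions

The experiments module fixes one set of desk conditions and does not tune
them per run: 32x32x32 grid, 10 regions, 60 subjects at 50% prevalence,
2 visits per subject, diagnosis flip rate 0.1, effect 1.0 with noise 0.2
(effect-to-noise 5), MRI effect in region 3, PET in region 8, patient-wise
80/20 split with a further 25% of training subjects held out for
validation, desk architecture, batch 4, up to 60 epochs. The
complementarity study halves both effects and uses 48 subjects. Held-out
metrics are computed against the generator's true disease states, so
residual diagnosis noise affects training realism but not measurement.
These sizes were chosen so a full multi-seed experiment remains a
minutes-scale computation on one CPU.

## Known limitations

* **Attribution at desk scale.** The desk-trained models provably localize
  the planted region (occlusion: logit drop ~3.0 for the planted region,
  <= 0.6 for every other), yet vanilla Grad-CAM usually fails to surface
  it: with an easy-margin task the loss saturates long before the
  convolutional filters become class-selective, discrimination lives in
  the dense head's spatial weights, and Grad-CAM's spatial pooling of
  gradients erases exactly that information — the rectified combination
  then reflects anatomy-driven activation structure (bright regions)
  instead of class evidence. The attribution machinery itself is verified
  against closed forms, finite differences, and hand-built class-selective
  models (where planted regions are recovered exactly); recovering planted
  regions *through training* at desk scale is an open gap, documented
  rather than patched, and should be expected to require feature
  extractors trained well past the point the early-stopping protocol
  reaches on an easily separable task.
* Fusion's advantage over the better uni-modal arm is a trend in means but
  often a tie in medians at desk test-set sizes (20 pairs: accuracy
  granularity 0.05); the fusion model is the most *consistent* arm across
  seeds rather than uniformly the best.
* The rank AUC, metrics, splits and correction rule are exact; everything
  downstream of training inherits training's seed-to-seed variability,
  which at these cohort sizes is substantial (a single unlucky
  training/validation draw can cost tens of accuracy points).
* Lenient-mode preprocessing (volumes with fewer slices than requested)
  returns all slices rather than erroring; callers mixing strict and
  lenient outputs must handle ragged depths themselves.
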