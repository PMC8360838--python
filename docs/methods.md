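# Methods

## The detection problem

A FaST (focal source and trigger) site is declared when a 5-s recording
shows (i) sustained bipolar periodicity at an atrial cycle length (CL) and
(ii) a dominant unipolar QS morphology: R/S amplitude ratio < 0.1 in more
than 90% of annotated complexes.  The package implements both the
rule-based detector and a learned classifier of the same label, plus the
synthetic data needed to exercise them end to end with known ground truth.

## Rule-based algorithm

**Envelope and periodicity.**  The bipolar trace is bandpassed 40–250 Hz,
full-wave rectified, then bandpassed 0.5–20 Hz (Botteron-style).  All
filters are 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), so they are zero-phase and preserve activation timing;
the ordering (rectification between the two passes) is one of two readings
of the published phrase and is fixed here as a design choice.  Periodicity
uses the FFT of the envelope: the dominant peak over the 0.5–20 Hz band is
found, its power is summed over the peak bin ± 1 adjacent bin (a 5-s
record gives 0.2 Hz resolution), and the fraction is taken against the
total 0.5–20 Hz power.  The recording is periodic iff that fraction is
≥ 0.10 *and* CL = 1000/f_peak lies in [100, 250] ms.  Searching the global
peak first and gating on the CL window second matters: a 2 Hz train has a
4 Hz harmonic inside the atrial window that a window-restricted search
would wrongly promote.

**Candidates and graph search.**  Candidate activations are local maxima
of |bipolar| separated by ≥ 50 ms (below half the minimum CL, so
fractionated deflections are not double-counted), with amplitude
> 0.05 mV and maximum |dV/dt| within ±10 ms above 0.014 mV/ms.  Both
thresholds act on the recorded trace (hardware-bandpassed at acquisition);
no additional filtering is applied at this stage.  The periodic train is
the longest chain of candidates whose consecutive intervals deviate from
the extracted CL by strictly less than 25% of the CL, computed by dynamic
programming over ordered candidate pairs; ties are broken by minimal total
cost Σ|interval − CL|, then earliest start.  The DP is verified against
exhaustive enumeration over all increasing subsequences in the tests.  The
strict (exclusive) tolerance boundary is pinned by a worked example in
which an interval of exactly CL + 25% must not join the chain.

**Morphology and decision.**  Chain times are transposed onto the unipolar
trace.  Per complex, baseline is the median of the 10 ms preceding the
[−20, +80] ms morphology window; R is the maximum positive and S the
maximum negative deviation from baseline in the window.  A complex is QS
iff S > 0 and R/S < 0.1; complexes with S below the 0.05 mV noise floor
are flagged indeterminate and excluded from the QS-fraction denominator
(counting them as non-QS would penalize genuine low-amplitude QS sources
near the pulmonary-vein ostium).  The recording is *sustained* when the
chain covers ≥ 90% of the beats expected over the recording
(duration/CL), and FaST iff periodic ∧ sustained ∧ QS fraction > 0.9.
Non-periodic recordings short-circuit to a negative call.

## Synthetic generator

Each record is 5 s at 1,000 Hz, paired unipolar/bipolar.  The unipolar
channel sums morphology templates at jittered periodic onsets (Gaussian
jitter, sd 3 ms, truncated at ±10 ms), optional far-field ventricular
complexes, sinusoidal baseline wander (0.05 mV at 0.4 Hz) and white
amplifier noise (5 µV RMS, a typical clinical amplifier noise floor — and
deliberately low enough that extreme-value noise peaks rarely masquerade
as R waves inside a 100 ms morphology window).  Templates: QS is an
inverted raised-cosine dip (30–50 ms; 60–90 ms for the slurred variant),
RS/rS a positive lobe followed by a negative lobe with an exactly
controlled sampled-peak ratio, fractionated complexes are 2–4 jittered
sub-deflections within 60 ms, and ventricular far-field is a 120-ms-wide,
dominantly negative wave (QS-like, as far-field ventricular complexes
appear on atrial unipolar recordings) at CL 600–1,000 ms, attenuated and
slow in the bipolar channel so it fails both candidate thresholds.

The bipolar channel is generated independently of the unipolar trace as a
derivative-of-Gaussian kernel (σ = 5 ms, ≈ 40 ms deflection — the
clinically typical width) at each onset, scaled 0.3–0.8 mV, so detection
thresholds can be exercised in isolation.  Narrower kernels make the
envelope spectrum a flat harmonic comb whose second harmonic can beat the
fundamental for CL ≥ 200 ms; the chosen width keeps the fundamental
dominant without any change to the detector.

Nine classes span the phenotypes: three FaST-positive (sustained QS,
low-amplitude QS at 0.15–0.35 mV, slurred QS) and six negative (periodic
RS with R/S 0.3–0.8, small-r rS with R/S 0.15–0.3, switching — RS before
1.4 s then QS, giving QS fraction 18/25 = 0.72 at CL 200 ms —
non-sustained QS covering only 45–60% of the record, fractionated,
aperiodic).  The default class mix places 9.2% of records in the FaST
classes, reproducing the clinical prevalence, with the negative mass
dominated by periodic RS.  Records are grouped into synthetic patients
(default 50 records each) with a lognormal per-patient amplitude scale
(sd 0.15), making patient-level splits meaningful.  All generation is
bit-reproducible from (class, config, seed).

**What the generator does not emulate:** electrode geometry and contact
variation, non-stationary cycle lengths, wavefront collision/fusion
morphologies, real fractionation statistics, and correlated noise.  A
detector/classifier that is perfect here can still be imperfect on
clinical recordings; passing tests demonstrate internal consistency of the
pipeline, cycle-length recovery, threshold enforcement and learnability of
the label — not clinical performance.

## Classifier

Input is the unipolar trace FFT-downsampled to 200 Hz (1,000 samples) and
min-max scaled to [0, 1] (constant traces map to 0.5).  Four augmentations
are each applied independently with probability 0.5 during training, with
scaling applied last: baseline shift (one normal constant, sd 0.1),
Gaussian noise (sd 0.05), cropping (zeroing a contiguous 5–15% segment)
and resampling (deleting a 5–15% segment and Fourier-stretching back to
length, which scales frequencies by the kept fraction).  Magnitudes are
package defaults; the source describes the mechanisms but not magnitudes.

The network is the standard 18-layer residual arrangement with 1-D
filters: stem (kernel 7, stride 2, 64 channels) with 3/2 max pooling, four
stages of two residual blocks (two 3-tap convolutions + batch
normalization each, 1×1-convolution shortcuts at stage entries), global
average pooling, dropout 0.2, and one fully connected unit with logistic
output.  Published descriptions of the topology disagree on the block
count ("five residual convolutional blocks" vs a four-block figure); the
standard stem + 4×2-block arrangement is shipped.  He initialization,
Adam (lr 1e-3, batch 64, reduce-on-plateau factor 0.5 / patience 3,
30 epochs by default), binary cross-entropy without class re-weighting; a
grid-search utility covers batch {32, 64, 128} × lr {1e-2, 1e-3, 1e-4} ×
{plateau, cosine}.  The epoch checkpoint with the best validation AUC is
kept.  Everything — shuffling, augmentation draws, dropout, init — flows
from one seeded generator, so runs are reproducible to floating point.

The forward/backward passes are written directly in numpy (im2col
convolutions, standard batch-norm backward), with gradients verified
against central finite differences in the tests.  Keeping backpropagation
explicit is also what makes intermediate-layer gradients available to
Grad-CAM without any framework hooks.

Scaled-down experiment sizes used by the tests and the acceptance script:
2,000 records (prevalence 0.10), quarter-width stages (16, 32, 64, 128),
5 epochs, patient-level 75/25 split.  These are the package's standard
reduced-scale conditions; at that scale the network reaches held-out
AUC ≥ 0.95 and exceeds the logistic-regression baseline trained on the
identical vectors.

## Interpretability

For a probed residual block (default `stage3.block0`, the first block of
the third stage), channel weights are the time-averaged gradients of the
logit with respect to the block's activation maps; the importance trace is
the rectified weighted sum of the maps, linearly interpolated to input
length and max-normalized.  By default the trace is multiplied by a
rectified guided-backpropagation saliency (guided Grad-CAM).  This default
was chosen after measuring both variants: the plain layer-level map
localizes only as finely as the probed stage's ≈ 80 ms stride and its peak
placement varies across training seeds (peak-to-onset hit fractions
0.45–0.86), while the guided product restores sample-level sharpness and
tracks QS onsets consistently.  The plain map remains available
(`guided=False`).  Peaks are local maxima above 0.5 of the normalized
trace with ≥ 50 ms separation; alignment is summarized as the fraction of
peaks within a window (CL/4 in the tests) of a true onset, the symmetric
onset recall, and the median peak-to-onset distance.

## Evaluation

AUC is the Mann–Whitney ranking probability (ties at half), with a seeded
2,000-resample percentile bootstrap over records for the 95% CI; across-
seed standard deviations are additionally reported by the cross-validation
harness, since a CI can be resampled over records or over seeds.
Operating points use the closed rule score ≥ threshold ⇒ FaST; the
threshold at a target sensitivity is the k-th largest positive score,
k = ⌈target · n_pos⌉ — the largest threshold whose achieved sensitivity
meets the target.  Two identities hold exactly for every report:
F1 = 2·PPV·sens/(PPV + sens) and
accuracy = prevalence·sens + (1 − prevalence)·spec.  Cohen's kappa uses
marginal-product chance agreement, with κ ≡ 1 when both raters are
constant and identical.  Cross-validation assigns whole patients to folds
(3 folds × 5 seeds by default; each seed reshuffles folds and
re-initializes the network) and can re-run training on nested patient
subsets for a training-size curve.

## Numerical and degenerate-input conventions

Times are ms from record start, sample 0 at t = 0; intervals half-open.
All-zero envelopes are non-periodic with fraction 0 (not an error).  Empty
candidate lists give an empty chain.  Edge complexes are clipped to
available samples.  Constant signals min-max scale to 0.5.  An
all-positive label set degenerates the sensitivity threshold to the
minimum score.  Importance traces with no peaks report a missing hit
fraction rather than failing.  Record files round-trip headers exactly and
samples to within 1e-9 mV.

## Known limitations

The cost-matrix construction of the original graph search is not public;
the DP here honors the stated objective (longest consecutive chain at the
extracted CL, lowest total deviation) and is proven equal to exhaustive
enumeration, but may differ from the original in unstated tie cases.  The
morphology window, baseline convention and the ">90% of EGMs" counting
unit (complexes, here) are likewise fixed by choice where the source is
silent.  Synthetic amplitudes and widths are stated defaults, not clinical
claims; clinical performance numbers from the private cohort are not
reproducible here and are never asserted by the tests.
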