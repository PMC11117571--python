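# Methods

This note documents the models implemented in synergykit, their
parameter defaults, the design of the synthetic cohort, and the
numerical and design choices made where the underlying protocol leaves
room. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Signal model and preprocessing

Surface EMG is treated as an amplitude-modulated broadband carrier. The
envelope pipeline applies, per channel and in order: a 50 Hz IIR notch
(quality factor Q = 30), a 30 Hz Butterworth high-pass, full-wave
rectification, and a 5 Hz Butterworth low-pass. Butterworth filters are
4th-order designs applied forward-backward (`sosfiltfilt`), so the
effective order is 8 and the pipeline is zero-phase — envelope peaks are
not lagged relative to the raw bursts. The notch is also applied
forward-backward for consistency. The filter realizations are not
dictated by the protocol; these are field-standard choices and all
corners/orders are configurable through `FilterConfig`.

The MVC envelope peak (the same pipeline applied to a
maximal-voluntary-contraction recording) defines 100 % activation per
muscle. Task envelopes are divided by it; ratios above 1 (task EMG can
transiently exceed MVC) are capped at 1.0 by default (`clip_mvc`)
because the downstream activation model assumes inputs in [0, 1].

Landing-phase segmentation is out of scope: trials are expected
pre-segmented, and the generator emits segmented phases. Time
normalization to the 101-point phase grid (0–100 %) uses linear
interpolation with exact endpoint preservation.

## Activation dynamics

Neural activation follows the second-order recursion
`u(t) = α e(t−d) − β₁ u(t−1) − β₂ u(t−2)` with zero initial state,
β₁ = C₁ + C₂, β₂ = C₁C₂, and the gain tied by α − β₁ − β₂ = 1, which
makes the DC gain exactly 1 for every admissible pair (C₁, C₂):
sustained full excitation settles at full activation. Stability needs
both recursion roots inside the unit circle, i.e. |C₁| < 1 and
|C₂| < 1 (enforced as magnitude bounds). The recursion coefficients are
not specified by the protocol; the default C₁ = C₂ = −0.5 places a real
double pole at 0.5 (critically-damped-like, no overshoot, non-negative
impulse response — hence order-preserving in the input). The
electromechanical delay defaults to 10 ms, rounded to the nearest
sample at the native rate. Activation is computed at the native
sampling rate first — the delay is physical — and time-normalized to
101 points afterwards.

The exponential shaping `a(u) = (e^{Au} − 1)/(e^A − 1)` (shape factor
A = 1.5 by default, A ≠ 0) is a strictly increasing bijection of [0, 1]
with exact endpoints; its inverse is provided and round-trips to 1e-12.
Transient recursion output outside [0, 1] is clipped before shaping.

## Synergy extraction

The per-subject data matrix V concatenates the 3 time-normalized
activation trials column-wise (10 × 303). Factorization V ≈ W C uses
Lee–Seung multiplicative updates on the squared Frobenius cost:
numerators V Cᵀ and Wᵀ V, denominators W C Cᵀ and Wᵀ W C, with a
1e-12 guard in the denominators; each step first updates W, then C with
the updated W, so the cost is non-increasing. Initialization is uniform
random in (0, 1]; the best of 20 restarts (lowest final cost) is kept;
convergence is declared when the relative cost drop falls below 1e-6 or
after 1000 iterations. Columns of W are reported with unit Euclidean
norm, with the scale absorbed into C (the product W C is unchanged, as
are all VAF values).

The synergy number N is the smallest k (searched k = 1..8) whose global
VAF is at least 90 % while every per-muscle VAF is at least 75 %;
comparisons are non-strict within 1e-12 (a strict mode exists). If no k
qualifies, k_max is returned with an explicit flag. Muscles with an
all-zero row have undefined local VAF (NaN, warned, ignored by the
thresholds).

## Synergy sorting

All synergy vectors of the reference (healthy) group are pooled into
D (10 × k_total) and clustered by K-means: Lloyd iterations on squared
Euclidean distance, centroid update as cluster mean, distortion-change
tolerance 1e-8, at most 300 iterations, best of 50 random
initializations; an emptied cluster is re-seeded at the point farthest
from its centroid; assignment ties break to the lowest cluster index.
The cluster count i is chosen in 2..8 to maximize the mean silhouette
coefficient s = (b − a)/max(a, b), where b is the *minimum* over other
clusters of the mean distance (the standard nearest-cluster reading);
singleton clusters and coincident points score 0; ties go to the
smallest i.

Each subject's synergy columns are classified against the centroids by
Pearson correlation and assigned to the best-correlated centroid when
r > 0.6, else left unclassified; activation-coefficient rows inherit
the assignment. The similarity rate is reported per synergy (share of
classified synergies per group), one of two defensible readings of a
group-level match percentage; the per-subject alternative is not
implemented. When a subject has several synergies classified to the
same reference, the highest-r one represents the subject in weight
comparisons.

## Group statistics

Scalar weight comparisons route by assumptions at α = 0.05:
Shapiro–Wilk on each group and Levene's test (mean-centered) across
groups; both passing selects the pooled-variance two-sample t-test,
otherwise the Wilcoxon rank-sum test (exact null when both n ≤ 25
without ties, normal approximation with tie correction otherwise), all
two-sided. Cohen's d uses the pooled SD with the group1 − group2 sign
convention. Magnitude labels follow the conventional bands, with the
0.5–0.8 interval labeled "medium-large" since some conventions leave it
unnamed. No multiple-comparison correction is applied across the
synergy × muscle grid by default, matching common practice in this
literature.

Curve comparisons use permutation SPM: the pointwise pooled-variance t
statistic over the 101 phase nodes, with the critical threshold taken
from the permutation distribution of the field-wide max |t| under
group-label exchange (Nichols–Holmes convention: the observed labeling
is a member of the null set, and the threshold is the conservative
order statistic at 1 − α). Supra-threshold clusters are reported as
phase intervals with permutation tail probabilities of cluster extent.
Default n_perm = 10,000 (tests use scaled-down values). A random-field
-theory mode delegates to the optional `spm1d` package when installed
and raises a clear error otherwise; the permutation mode is the
default and is assumption-free and self-contained.

## Synthetic cohort

The generator emulates the study design the analysis targets: two
groups (healthy-like and CAI-like) of 22 subjects, 3 landing trials
each, 10 muscles, 101-point phases. Ground truth has four modules with
block-structured spatial templates — hip (BF, GM), knee (RF dominant
with VM, VL, MG, LG, SL), initial-contact ankle (TA, MG, LG), and
whole-limb (PL dominant with GM, VM, VL and lighter RF, LG, SL) — and
Gaussian-bump activation profiles centered at 28, 50, 8 and 78 % of the
phase (widths 7, 10, 5, 7 %). The ankle module peaking inside the first
20 % of the phase reflects initial-contact ankle control; the whole-limb
module dominates late landing.

Variability has four layers, each with a purpose:

* small seeded template jitter (σ = 0.03) so no two ground truths are
  bit-identical;
* between-subject weight jitter, σ = 0.08 for the healthy-like and
  σ = 0.20 for the CAI-like group — patients organize their modules
  more heterogeneously, and this single asymmetry is what lowers their
  similarity rate against healthy-derived references;
* subject-level profile scaling (log-normal, σ = 0.10);
* independent per-trial module-amplitude jitter (log-normal, σ = 0.5).
  This models trial-to-trial recruitment variability and is the
  ingredient that makes the four-module subspace identifiable from
  three concatenated trials: without it the smooth bump profiles are
  too collinear and rank selection collapses.

The CAI-like group additionally applies additive deltas on specific
(module, muscle) weight cells before renormalization (e.g. +0.18 on GM
in the hip module, −0.22 on PL in the whole-limb module), reproducing
the kind of group mean shifts such studies report as significant.
Trial noise is multiplicative log-normal (σ = 0.10) plus additive
Gaussian, with the additive variance set so total perturbation power
matches the target SNR (default 20 dB). A trial whose amplitude draw
would push activation above 1 is rescaled as a whole — elementwise
clipping would silently break the exact V = W C structure that the
zero-noise recovery contract relies on. At SNR = ∞ the generative model
therefore coincides exactly with the factorization model.

Surrogate raw EMG (for exercising the envelope and activation stages)
is a 30–450 Hz band-limited Gaussian carrier amplitude-modulated by the
activation envelope, plus a 50 Hz mains component (amplitude 0.05) and
baseline noise (σ = 0.01); the envelope pipeline recovers the
modulating profile with correlation above 0.95.

What the generator does *not* emulate: nonstationary carrier spectra,
electrode crosstalk between neighboring muscles, movement artifact
below 30 Hz, within-trial waveform deformation of the module profiles,
and any kinematic/kinetic coupling. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative assumptions,
not robustness to every artifact of real recordings.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full default cohort (22 healthy-like
subjects) for synergy extraction and clustering. The test suite uses
the same cohort session-wide, 500 null simulations with n_perm = 1000
for the SPM error calibration, and smaller cohorts (6–10 per group) for
the end-to-end pipeline checks. These sizes were chosen to keep the
suite fast while leaving every statistical conclusion stable across
seeds.

## Known limitations

* The dual-VAF rule is sensitive to the restart budget at small
  separations between modules; with the default 20 restarts a small
  fraction of subjects (about 1 in 10 at SNR 20 dB) selects 3 modules.
  This mirrors the behavior reported for real cohorts, where the
  modal synergy number is 4 but individual subjects vary.
* K-means with random-point initialization can in principle return a
  local optimum; 50 initializations make this unobserved in practice
  on pooled synergy data.
* The Wilcoxon route uses the Mann–Whitney U formulation of the
  rank-sum test; p-values are identical to the classical rank-sum
  statistic's.
* `similarity_rate` implements the per-synergy definition; published
  percentages of this kind are occasionally per-subject, which would
  differ when subjects contribute unequal synergy counts.
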