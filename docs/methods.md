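# Methods

This note documents the models and procedures the package implements, the
design choices made where several readings were defensible, what the
synthetic data does and does not emulate, and the numerical conventions
that affect results.

## Trial labeling from response times

A trial comprises four response times; the fourth question probes the
hidden rule. Per participant, the DRT series (question 4) and the URT
series (mean of questions 1–3) are median-filtered in trial order with a
centered window of 5 (windows truncate at the series edges — the filter
shrinks rather than pads). A trial is labeled Fast iff its filtered DRT
lies below the lower bound of the participant's 95% interval of filtered
URTs.

Two interval constructions are provided. The default is a normal-theory
*distribution* interval, mean − z₀.₉₇₅·SD of the URT sample — a tolerance
interval on individual URTs, not a confidence interval on their mean,
because the target is "individually fast responses against this person's
baseline spread". `method="percentile"` switches to the empirical 2.5th
percentile. Both are subject-specific, which normalizes away baseline
speed differences between participants.

A consequence worth stating: an *isolated* one-trial RT drop is removed by
the median filter — by design, since the filter exists to suppress
outliers. Only sustained accelerations (≥ 3 consecutive fast trials)
survive to be labeled. The synthetic generator therefore produces
temporally contiguous Fast blocks (learning onset), under which the
labeling pipeline recovers 93–97% of ground-truth labels at the default RT
parameters.

## EEG features: sample entropy and multiscale entropy

`sample_entropy(x, m=2, r=0.15)` counts template matches under the
Chebyshev (max-norm) distance with tolerance r·SD(x), excluding
self-matches, using the first N−m templates for both lengths so A and B
range over the same index set. SampEn = −log(A/B); A = B gives 0 exactly
(constant and strictly periodic series), and A = 0 (or B = 0) returns +∞
as a sentinel. Because the tolerance is SD-relative, SampEn is invariant
to amplitude rescaling. The O(N²) counting loop is JIT-compiled; the test
suite checks it for exact (A, B) agreement against an independent
pure-Python counter, and against the analytic iid-Gaussian limit
−ln(erf(r/2)) ≈ 2.47.

Multiscale entropy applies SampEn to block-averaged copies of the series
at scales τ = 1…20. By default the tolerance is recomputed from each
coarse-grained series' own SD (each scale is its own SampEn problem);
`recompute_r=False` reuses the scale-1 absolute tolerance, which is the
convention under which the canonical "white noise declines with scale"
ordering holds. A 3 s epoch at 1 kHz supports τ = 20 at the recommended
minimum of 150 points per coarse-grained series.

Band decomposition uses the conventional clinical edges — Delta 0.5–4,
Theta 4–8, Alpha 8–13, Beta 13–30, Gamma 30–50 Hz — consistent with the
0.5–50 Hz preprocessing window.

### Filtering convention

Preprocessing (0.5–50 Hz bandpass, 60 Hz notch) and band filtering apply
the **squared magnitude response of the corresponding Butterworth/notch
design spectrally**: the epoch's FFT is multiplied by |H(f)|² and
inverse-transformed. This is exactly the steady state of forward–backward
(zero-phase) IIR filtering, without its finite-epoch boundary transients:
with a 0.5 Hz corner on a 3 s epoch, reflection-padded time-domain
filtering leaves >10% broadband transient residual no matter the padding
scheme, swamping the stopband attenuation the filter is meant to deliver.
The price is a periodic-boundary assumption, negligible for the zero-mean
epochs this pipeline consumes. Order: 4 (8th-order effective magnitude).

Degenerate cases in extraction: zero-variance band epochs and matchless
(infinite-SampEn) scales contribute 0 to the feature matrix and emit a
warning, keeping the matrix rectangular and finite for the classifiers.

## fNIRS features: db8 wavelet decomposition

HbO2 epochs (30 s at 10 Hz; long enough that L6 contains several cycles of
its band) are decomposed to level 6 with the Daubechies-8 wavelet. Detail
level L at sampling rate fs occupies the dyadic band (fs/2^(L+1), fs/2^L):
at 10 Hz, L5 = 0.156–0.3125 Hz and L6 = 0.078–0.156 Hz, jointly the
~0.07–0.31 Hz task-related hemodynamic band; cardiac pulsation (~1 Hz) and
slow drifts fall outside. No other fNIRS preprocessing is applied — the
level selection is the de facto filter.

The signal extension mode is the **periodized DWT**, under which the
transform is orthogonal: level energies partition the signal energy
(exactly so when the epoch length is divisible by 2^max_level), and
perfect reconstruction holds at any length. Level selection diagnostics
(energy, Shannon entropy of the normalized squared coefficients, their
ratio) are exposed via `level_diagnostics`.

Each (channel, level) group carries three scalar sub-features — detail
reconstruction energy, energy/entropy ratio (0 when the coefficient
distribution is degenerate), and peak absolute amplitude — chosen to make
the feature vector independent of trial length; raw coefficient vectors
remain available through `WaveletCoeffs`.

## The binary multi-neighbor colony

Masks over d feature groups are food sources; fitness is classification
accuracy in [0, 1]. Per iteration: employed phase (one candidate per bee,
moving toward the randomized average personal best of its far
neighborhood), onlooker phase (n fitness-proportional draws, each moving
the drawn bee toward the current position of its best near neighbor),
scout phase (bees whose abandonment counter exceeds the limit are
re-randomized; personal bests survive). Far neighbors are those strictly
beyond the bee's mean Hamming distance; degenerate cases force the single
farthest (or nearest) neighbor into the empty role. Candidates update all
d dimensions; replacement is greedy with strict improvement, and ties
increment the abandonment counter (preventing drift on plateaus). The
all-zero mask is assigned fitness 0 without invoking the classifier. φ is
drawn independently per dimension.

Defaults: n = 20 bees, 100 iterations, abandonment limit 10.

**The temperature T** (default 0.01) deserves its own paragraph. T sets
the stagnation flip floor 1 − exp(−AC·T) of the transfer function. Once a
colony has converged, onlooker perturbations toward identical neighbors
are zero and this floor is the *only* repair mechanism, proposing
Binomial(d, floor) simultaneous flips. For the floor to propose few-bit
repairs rather than mask-scale shuffles, T must be commensurate with 1/d:
at T = 0.01 and the limit, the floor is ≈ 0.1 (a handful of flips at
d ≈ 60), and the optimizer recovers a hidden 63-bit mask in 20/20 seeded
runs; at T = 0.05 the floor reaches 0.39 (~25 simultaneous flips) and
recovery collapses to 0/20. T is exposed in `ColonyConfig`.

## Fitness evaluation

A mask's columns are z-scored with training-split statistics only, then
scored by stratified k-fold CV or repeated stratified hold-out (fraction
0.2–0.25). Supported classifiers: cosine-kNN (k = 5), Gaussian-kernel SVM
with the median-heuristic bandwidth, polynomial SVMs of degree 2 and 3,
and a 100-tree random forest. For cosine-kNN — the workhorse of the
wrapper search, where a stage-1 study performs ~10⁴–10⁵ tiny fits — the
hot path uses a vectorized nearest-neighbor vote asserted in the tests to
predict identically to the scikit-learn estimator it replaces; all other
classifiers are scikit-learn estimators directly. Hold-out splits are
cached per seed, and mask→fitness evaluations are memoized within a run
(they are deterministic given the protocol seed).

## Stage 1: NWS prioritization loop

Per cycle, N_run independent colony runs (each with fresh split
randomization) are restricted to the active groups. The normalized
weighted sum of group j is

    NWS_j = Σ_r acc_r · mask_rj / Σ_r acc_r ,

accuracy-weighted selection frequency in [0, 1] (1 iff selected by every
run). The cycle's best masks are re-scored by repeated stratified
hold-outs to form an accuracy distribution; a two-sided Mann–Whitney gate
compares it with the previous valid cycle's distribution and **fails only
on degradation** (p ≤ α *and* a lower median — improvements never fail;
identical constant samples pass with p = 1). On a pass the threshold rises
by 0.1 and groups below it are removed permanently; on a failure the
previous active set is restored and the loop stops. The loop also stops
when no group falls below the raised threshold, when removal would empty
the set, and at a hard cap of ⌈1/T_step⌉ + 2 cycles. The gate is validated
*before* the threshold increment (validate-then-increment).

## Stage 2: recursive backward sensor elimination

Sites own their surviving feature groups (co-located montage: a site's EEG
bands and fNIRS levels are removed together). Each iteration evaluates,
for every active site, the hold-out accuracy distribution *without* that
site; the least critical site is the one whose absence leaves the highest
median (ties break on the canonical site order AF3 < AF4 < … < FZ; a site
owning no groups is free to remove). The candidate configuration is gated
against the full-montage baseline distribution: the median must stay at or
above the 85% floor, and — the elbow rule — a drop must be both
statistically insignificant (Mann–Whitney p > 0.05) *and* within a 5%
margin. A configuration whose median meets or beats the baseline always
passes the elbow. `stop_mode` selects floor, elbow, or (default) both;
`elbow_rule="or"` relaxes the conjunction. The first rejected removal is
reinstated and the loop terminates, so the final configuration provably
passes the gate while the next-smaller one failed it.

## Synthetic data: what it emulates, what it does not

The signal-level generator (`generate_dataset`) emulates the study
conditions: 10 participants × 35 trials, balanced 175/175 (per-participant
Fast counts alternate ⌊·⌋/⌈·⌉ so totals are exact); EEG 9 channels × 3 s
at 1 kHz; fNIRS 9 channels × 30 s at 10 Hz; four RTs per trial with URT ~
N(1027.9, 99.8²) ms and Fast DRT ~ N(666.7, 155.3²) ms (truncated
positive). The three undetermined questions share a per-trial
momentary-speed component with 50 ms within-trial jitter, so per-question
marginals keep the stated spread while the trial-level URT spread stays
comparable to the Slow DRT spread. Slow trials precede Fast trials within
a participant (learning onset), making the median filter well-behaved.

Planted effects: in a planted (channel, band) the band-limited component
is a mixture of a narrowband tone and band-filtered noise whose mixing
fraction differs by class (entropy effect at matched amplitude); in a
planted (channel, level) a tone at the level's band center differs in
amplitude by class. Non-planted combinations are statistically identical
across classes (verified by a nominal-rejection-rate Monte-Carlo). Not
emulated: volume conduction, optical forward models, artifacts (blinks,
motion), inter-channel correlation structure, non-stationarity across the
session. Passing recovery tests therefore demonstrates that the pipeline
finds the kind of localized spectral/hemodynamic class structure it was
designed for — not that it is robust to real-world confounds.

The feature-domain generator (`generate_feature_dataset`) emits the same
63-group layout directly as Gaussian features with planted mean shifts and
is what the selection-stage studies use. Its key design axis is
**complementarity**: with global shifts, informative groups are mutually
redundant (accuracy grows as √k), so no individual group or site is
necessary and neither a wrapper nor a statistical gate can be expected to
keep all of them. Stratified modes make planted information unique — each
planted group (stage-1 design), site (stage-2 design), or modality
(fusion design) is the sole signal carrier for its own round-robin stratum
of trials — so each unit's marginal contribution is large. The planted
separations (6 SD per group for the 6-way group strata, 5 SD for the 3-way
site strata and 2-way modality strata) are sized so the pooled
cosine-kNN reaches ~0.93–0.96 accuracy with all units present and loses
~7–15% when one is removed, a regime where an 85% floor and a 5% margin
are meaningful.

## Scaled problem sizes

The multi-seed recovery studies in `bmnabc.experiments` (used by the tests
and `scripts/acceptance.py`) run the full algorithms at reduced sizes —
10 bees × 25 iterations (limit 5), 10 colony runs per stage-1 cycle, 20
hold-out repetitions per mask, 5 × 20 hold-out scores per stage-2
distribution, 140-trial feature matrices — chosen so a ten-master-seed
study of either stage completes in one to two minutes on a single CPU.
The optimizer benchmarks (OneMax, hidden-mask recovery) run at the full
20-bee × 100-iteration settings.

## Known limitations

- The wrapper search optimizes a noisy accuracy estimate; with few
  hold-out repetitions the selected masks overfit the splits used during
  search (the stage-1 gate re-scores them on fresh splits, which bounds
  but does not eliminate the optimism).
- NWS is computed per classifier; no cross-classifier consensus is
  implemented.
- The spectral filter convention assumes periodic epochs; for real
  continuous recordings, filter before epoching and feed the epochs in.
- Sensor elimination removes a site's EEG and fNIRS groups jointly;
  per-modality site pruning exists (`site_groups` can be edited) but is
  not the default path.
- Scout re-initialization preserves personal bests; clearing them is not
  implemented.
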