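# bmnabc

Two-stage feature selection and sensor optimization for hybrid EEG–fNIRS
brain–computer interfaces, built around a **binary multi-neighbor artificial
bee colony** (BMNABC) wrapper search, with a synthetic multimodal trial
generator that plants recoverable ground truth.

## The problem

Detecting *implicit learning events* — the moment a hidden rule starts
driving behavior before the learner can verbalize it — from simultaneous
EEG and fNIRS recordings poses two coupled problems:

1. **Feature selection.** Nine frontal sites × five EEG bands (multiscale
   entropy features) plus nine co-located fNIRS optodes × two wavelet
   detail levels give 63 candidate feature *groups*; most are redundant or
   irrelevant, and the informative ones are only known through the
   classifier they feed.
2. **Sensor minimization.** A deployable headset cannot carry the full
   montage; the question is which physical sites the accuracy actually
   needs.

This package implements the full pipeline for researchers who want to study
or reuse the method: RT-based trial labeling, entropy and wavelet feature
extraction, the binary colony optimizer, the two reduction stages, and a
generator of synthetic multimodal datasets with planted, recoverable
structure for validation.

## The method

**Labeling.** Each trial has four response times. The fourth question's RT
is the *determined* RT (DRT); the mean of the rest is the *undetermined* RT
(URT). After a window-5 moving-median filter, a trial is **Fast** iff its
DRT falls below the lower bound of the participant's 95% interval of URTs.

**EEG features.** Per channel and band (Delta…Gamma), sample entropy

    SampEn(m, r, N) = −log(A/B)

with m = 2, r = 0.15·SD, where B counts length-m template matches and A
length-(m+1) matches (Chebyshev distance, self-matches excluded), extended
to scales τ = 1…20 by coarse-graining (multiscale entropy).

**fNIRS features.** db8 discrete wavelet decomposition; detail levels L5
(0.156–0.3125 Hz) and L6 (0.078–0.156 Hz) jointly isolate the ~0.07–0.31 Hz
task-related hemodynamic band. Per (channel, level): reconstruction energy,
energy/entropy ratio, peak amplitude.

**The optimizer.** Food sources are binary masks over feature groups;
fitness is the masked feature set's classification accuracy. Employed bees
explore toward the randomized *average personal best* (APB) of their far
(Hamming-distance) neighborhood; onlookers exploit toward their best near
neighbor; a continuous perturbation `a = φ(x − target)` becomes a bit flip
with probability

    S(a) = (1 − exp(−AC·T)) + |tanh(a)|

where AC is the bee's abandonment counter — stagnating bees mutate more.
Scouts re-randomize bees that exceed the abandonment limit.

**Stage 1 (feature prioritization).** Batches of independent colony runs
score every group by its *normalized weighted sum* — accuracy-weighted
selection frequency across the batch's best masks. Groups under an
incrementally raised threshold (step 0.1) are removed permanently; a
Mann–Whitney gate on hold-out accuracy distributions reverts and stops on
the first significant degradation.

**Stage 2 (sensor elimination).** Recursive backward elimination of whole
sites: repeatedly drop the site whose removal leaves the highest median
accuracy, while the median stays above an 85% floor and any drop vs the
full-montage baseline is both statistically insignificant and within a 5%
margin. The first rejected removal is reinstated.

## Worked example

`examples/06_stage2_sensor_pruning.py` builds a 9-site synthetic dataset in
which AF3, F7 and FZ carry complementary class signal and the other six
sites carry noise, then runs backward elimination:

```
 step removed_site   median      p_value  accepted  n_sites
    0         None 0.964286          NaN      True        9
    1           F3 0.964286 7.497338e-01      True        8
    2           F4 1.000000 2.299809e-08      True        7
    3           F5 1.000000 1.731276e-09      True        6
    4          AF4 1.000000 8.476836e-07      True        5
    5           F6 1.000000 1.549557e-15      True        4
    6           F8 1.000000 6.156164e-15      True        3
    7          AF3 0.821429 8.693583e-31     False        3

final sites: ['AF3', 'F7', 'FZ']  (66.7% fewer sensors)
```

Reading the trace: the full montage scores a median hold-out accuracy of
0.964; the six noise sites fall one by one with no accuracy cost (removals
whose median stays at or above baseline always pass); the first attempt to
remove a signal-bearing site (AF3) drops the median to 0.821 — below the
85% floor, a significant >5% drop — so it is reinstated and the loop stops
with a 66.7% sensor reduction and exactly the three planted sites.

The other scripts in `examples/` walk through each capability: simulation
and labeling (01), entropy features (02), wavelet features (03), the raw
optimizer (04), stage-1 prioritization (05), and the modality-fusion
comparison (07).

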