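# Methods

This note documents the models, numerical choices, and limitations behind
`microdyn`. Nothing here is an empirical claim beyond what the test suite
and `scripts/acceptance.py` compute.

## The microstate model and its observables

The package treats resting EEG as a sequence of discrete states, each a
fixed scalp topography modulated in amplitude, with abrupt transitions.
Topographies are compared by Pearson correlation across channels
(*spatial correlation*); by default a map and its sign-flipped version are
the same state (*polarity invariance*), the convention for resting-state
microstates. Global field power (GFP) is the population standard deviation
across electrodes of one average-referenced sample; all map extraction and
labelling happens at GFP local maxima, where the topographic
signal-to-noise ratio is highest. Global explained variance,

GEV = Σ_t (GFP_t · corr(map_t, template_t))² / Σ_t GFP_t²,

weights each time point's fit by its field strength.

## Synthetic data: what is emulated, and what is not

`simulate_microstate_eeg` draws a hidden label sequence with **geometric
run lengths** (per-sample switch probability (1000/fs)/dwell_mean_ms,
uniformly random different successor). Geometric dwell is the memoryless
null consistent with "transiently stable, then abruptly switching", and
its mean is analytically checkable; real microstate sequences show
long-range dependence that this generator deliberately lacks.

Within a run the active template is driven by a rectified sinusoidal
envelope |sin(2π·carrier·(t − t_onset))| whose **phase restarts at each
state onset**. This makes field power dip at transitions and peak inside
every state — the regime the microstate model itself assumes (topography
changes near GFP minima) — so every run longer than one sample carries at
least one GFP peak and peak-based back-fitting can recover dwell times
without systematic merging bias. In the long-dwell limit the GFP peak rate
is 2·carrier (two field-strength maxima per oscillation cycle); at the
default 80 ms dwell the restarts add boundary maxima and the rate is
somewhat higher, which mirrors the empirical situation where peak rate and
occurrence rate need not coincide. The amplitude dynamics *within* a state
in real EEG are not characterized by this generator; the AM sinusoid is a
stand-in.

Noise is spatially white Gaussian, re-referenced to the average per sample
so that generated recordings stay exactly average-referenced. SNR is
defined as RMS(noiseless signal)/RMS(noise) over all channels and samples —
unambiguous and directly testable. Templates are Gaussian random fields
over a deterministic planar (sunflower) sensor layout with
squared-exponential spatial covariance (length scale 0.35 of the layout
radius), average-referenced, unit RMS, and redrawn until all pairwise
|correlations| are below 0.5. Real electrode geometry, volume conduction,
cortical sources, and artefacts (blinks, EMG) are not modelled; epoch
selection with an amplitude threshold is exercised as plumbing only.

`simulate_network_timecourses` draws zero-mean Gaussians whose covariance
switches between positive-definite state matrices with geometric dwell in
volumes. It emulates state-switching connectivity, not haemodynamics.

Passing tests on these generators demonstrate that the *algorithms* recover
planted structure under the model's own assumptions; they do not establish
performance on real recordings.

## Conditioning

Filtering uses the stated Butterworth band-pass design applied
forward–backward (`sosfiltfilt`), i.e. zero phase: microstate timing must
not be phase-shifted, at the cost of squaring the magnitude response.
Epochs are half-open sample intervals, 0-based, contiguous and
non-overlapping; an epoch is rejected when any sample exceeds the
amplitude threshold (default 500 µV), and the first `n_keep` survivors are
used. A subject with fewer clean epochs raises, mirroring cohort exclusion
rules.

## TAAHC and model order

TAAHC starts from singleton clusters. The *worst* cluster minimizes the
sum of member-to-centroid |spatial correlations| (the natural quality
measure under polarity invariance; the algorithm's name specifies the
atomize/agglomerate scheme but not the disband rule, so the rule is stated
here explicitly). Freed maps join the surviving cluster with maximal
|correlation|; affected centroids are recomputed as the first principal
component of member maps (sign-consistent centroid), renormalized to unit
GFP; ties in the worst-cluster search go to the lowest cluster index. A
solution is recorded at every k on the way down, so nested solutions from
one pass cover the whole search range. Maps are normalized to unit GFP
before clustering (whether to normalize is a genuinely open choice; unit
GFP makes the correlation algebra exact and is adopted throughout), while
GEV bookkeeping keeps the original GFP weights.

The number of classes is chosen by a configurable criterion bank voting on
the GFP²-weighted unexplained-variance curve W(k); the lower median of the
votes wins (ties favour fewer classes). Default bank:

* **Krzanowski–Lai** — ratio of successive dimension-corrected drops of
  W(k); votes where improvement collapses.
* **Cross-validation criterion** — residual variance inflated by
  ((C−1)/(C−1−k))²; votes its minimum.
* **Dispersion curvature** — discrete second difference of the normalized
  dispersion W(k)/W_total; votes the elbow.

If W is already ~0 at the lower end of the range (no structure beyond
k_min classes) k_min is returned directly. At least two criteria must be
enabled. The bank is a documented stand-in: it follows the meta-criterion
*idea* (median vote over standard validity indices) without claiming to
reproduce any specific published composition.

## Group maps and back-fitting

Group maps are the unit-GFP mean of subject templates after iterative
relabelling: each subject's classes are permuted (Hungarian assignment on
the |correlation| matrix) and sign-flipped to best match the current mean,
then the mean is recomputed, until no assignment changes (cap 100
iterations; the first subject seeds the mean).

Back-fitting labels each GFP peak with the argmax-|correlation| template.
Samples between consecutive peaks p_i < p_j take the nearer peak's label
with the boundary at b = (p_i + p_j + 1)//2, so the equidistant sample of
an even gap joins the later peak's segment; GFP plateaus contribute their
left-centre sample as the peak. Samples before the first and after the
last peak inherit that peak's label, and the first and last run of every
epoch are flagged truncated. Epochs with fewer than two GFP peaks are
skipped with a warning. The `all_samples` mode labels every non-flat
sample independently (robustness variant).

Temporal metrics exclude truncated runs. "Analyzed time" is the assigned,
non-truncated time, which makes the identity
duration_ms × occurrence_s⁻¹ = coverage × 1000 hold exactly per class.
Mean duration pools all non-truncated runs. A class with no runs reports
NaN duration (with a warning) and zero occurrence/coverage.

## Transition statistics

Transitions are counted between consecutive distinct non-truncated runs
within an epoch, never across epochs (epochs are discontinuous excerpts).
The expectation under independent syntax is
expected(i, j) = occ_j / Σ_{l≠i} occ_l with zero diagonal. The
non-randomness test shuffles the run order within each epoch; a
permutation that places two runs of one class side by side is the same
physical sequence with those runs merged, so shuffles are collapsed before
scoring and per-class run counts are preserved up to that merging. Both
the observed and every shuffled ordering are scored identically — a
chi-square-style sum and a max-cell deviation against the ordering's own
independence expectation — and p-values use the add-one permutation
convention (never exactly 0). Scoring each ordering against its own
expectation is what keeps the null calibrated (measured type-I ≈ 0.045 at
α = 0.05 over 400 simulations); scoring against the observed expectation
alone was measurably conservative. This whole test is a reconstruction of
an analysis whose original definition is not publicly specified; it
captures "transition probabilities deviate from independence" in a
standard way.

## TANOVA

Maps are normalized to unit GFP on entry (making all p-values invariant to
global scaling). Global map dissimilarity between two normalized maps is
their RMS channel difference. Effect sizes sum the dissimilarity between
each factor-level mean map and the grand mean; the class main effect
permutes class labels within subjects, the group main effect permutes
subjects across groups, and the interaction permutes group membership of
double-centred residual maps (both main effects removed). The interaction
null is a standard two-factor randomization choice, documented because the
original software's definition is not public. Type-I error of the group
effect is verified at α = 0.05 over 500 simulated null datasets.

## Spectral and dFC stages

Welch estimates use 2-s Hann segments (50% overlap for band power),
matching the epoch grain; dominant frequency is the argmax bin in 4–15 Hz
of the channel-average, estimated per epoch and averaged. Band powers
integrate the electrode-averaged PSD over half-open bands so adjacent
bands partition the axis; relative mode divides by the union power.
Whether the original band powers were absolute or relative is not stated;
both are provided, absolute by default.

Sliding-window connectivity uses Pearson correlation in a
rectangle-convolved-Gaussian tapered window (defaults: 22 volumes, step 1,
σ = 3 volumes — the common convention; the defaults are configurable and
logged, not claimed as a reproduction of any specific study's settings).
Zero-variance segments yield NaN correlations with a warning, never silent
zeros. Variability is the SD over windows per connection (optionally after
Fisher z), and a target network is summarized by the mean SD over its
connections, which is then Pearson-correlated with mean microstate
duration across subjects, with FDR or Bonferroni control over the
per-connection family.

## Pipeline, seeds, problem sizes

`run_pipeline` derives all per-subject and per-stage seeds from one master
seed via `SeedSequence` spawning, so identical configurations give
byte-identical outputs. Subject-level k is chosen automatically per
subject and the cohort is re-fit at the lower median of the subject
optima (mirroring a cohort-level decision to fix k), or at a fixed k.

The test suite and the acceptance script run at desk scale by design:
recovery cohorts use 3–20 subjects with 15–30 2-s epochs at 64 channels /
256 Hz, calibration studies use 200–500 simulated datasets with 199–1000
permutations, and dFC simulations use 300–600 volumes of 4 networks.
These sizes were chosen once as realistic-but-small study conditions.

## Known limitations

* Geometric dwell and AM-sinusoid carriers are idealizations; recovery
  results bound algorithmic, not physiological, validity.
* The k-selection bank, the transition test, and the TANOVA interaction
  null are documented reconstructions of under-specified originals.
* Modified k-means clustering, microstate syntax beyond first-order
  transitions, source localization, fMRI preprocessing/ICA, and
  Cartool/Ragu/EEGLAB file compatibility are out of scope.
* EDF files are read (via mne) but not written; the native format is the
  delimited matrix + JSON sidecar.
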