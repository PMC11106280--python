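# Methods

`trajrsa` implements a representational-similarity pipeline that treats
time-resolved mouse-cursor trajectories as a behavioural read-out of
unfolding stimulus representations, and compares their representational
geometry with time-resolved M/EEG geometries and static fMRI ROI
geometries. This note documents the models, the estimation choices, what
the synthetic generator does and does not emulate, and the limits of what
the test suite shows.

## Movement preprocessing

Raw cursor logs are per-trial time-stamped samples (ms since trial
initiation, pixel coordinates). Preprocessing follows four steps:

1. **Trial exclusion.** A trial is dropped when less than 100 ms of cursor
   data was recorded (time span of the samples, robust to dropped frames)
   or the cursor moved less than 50 px. "Moved" is measured as total
   Euclidean path length rather than net displacement — stricter, and
   robust to back-and-forth jitter; both thresholds are parameters.
2. **Scoring and participant exclusion.** A trial is correct when the
   final cursor position falls on the correct response box's side of the
   screen midline; a final position exactly on the midline counts
   incorrect (conservative). Participants below 70% accuracy (strictly
   below) over their retained trials are removed.
3. **Canonical decision frame.** The response boxes swap sides halfway
   through the session and the initial arrangement alternates across
   participants, so raw horizontal positions from the two arrangements
   would cancel in a group mean. Every trial whose face/animal box is on
   the left is mirrored about the midline before averaging, making
   positive displacement uniformly face/animal-ward. Scoring is unaffected
   (the correct side is flipped along with the coordinates).
4. **Interpolation and two-level averaging.** Each trial is linearly
   interpolated onto a uniform 1 ms grid from 1 to 800 ms; grid points
   before the first sample (late movement onset) or after the last (early
   box click) are missing-coded, never extrapolated. Positions are then
   averaged per image — across trials within each participant, then
   across participants — with available-case means at every timepoint (no
   listwise deletion) and the number of contributing participants
   recorded. Both correct and incorrect completed trials contribute.

Pixel coordinates are used as recorded; no rescaling across screen
resolutions is attempted (the inputs carry the midline per trial, and the
movement dissimilarities below are differences of group means, so a global
scale only rescales the RDM units).

## RDMs

A representational dissimilarity matrix (RDM) is square, symmetric,
zero-diagonal and non-negative; a series stacks RDMs over a strictly
increasing time grid with a fixed label set. Constructors:

- **Movement RDMs** — at every millisecond, the absolute difference in
  group-mean horizontal cursor position between each pair of images
  (horizontal position is the decision axis of the task). Cells involving
  an image with no data yet are missing.
- **Binary models** — the *task* model groups face/animal against
  everything else (lookalikes with objects, as instructed); the
  *lookalike* model groups lookalikes with their confusable category.
  Entries are 0 within group, 1 between.
- **Execution-time RDM** — pairwise absolute differences of per-image
  mean time to reach a response box, computed within then across
  participants from box-reaching trials only (a trial reaching the 800 ms
  deadline has no execution time).
- **Pattern RDMs** — 1 − Spearman correlation between per-stimulus
  feature vectors (used for synthetic "neural" patterns and for any
  externally supplied activation patterns).

Vectorization uses the strictly-upper triangle for full symmetric RDMs and
all cells for rectangular cross-category blocks (e.g. Lookalike × Object,
32 × 32 or 9 × 9 depending on the study). All cross-source operations
re-index by stimulus label, never by position.

## Rank correlations and partial correlations

All comparisons are Spearman correlations over vectorized RDM entries with
average-rank tie handling. Partial correlation rank-transforms every
vector, residualizes the two vectors of interest on the covariate ranks by
least squares with an intercept (QR-based), and returns the Pearson
correlation of the residuals; with no covariates this is exactly plain
Spearman. The same construction is verified in the test suite against two
independent oracles: naive rank-residual regression and the inverse of the
full rank-correlation matrix (agreement to 1e-10 over random instances of
12–500 entries and 0–3 covariates).

Missing entries are handled pairwise-complete, with ranks recomputed
within each complete subset; series-level correlations require at least
10 complete pairs (3 for scalar calls), otherwise the output cell is
missing. Degenerate inputs — a constant vector (e.g. a movement RDM
before the cursor has moved), or a covariate absorbing all rank variance —
produce missing cells in maps and explicit errors in scalar calls, never
silent zeros.

## Time–time maps

The temporal-generalization map correlates the neural RDM at every neural
timepoint (0–500 ms, 4/5 ms native grid) with the group movement RDM at
every movement timepoint. Computation happens at the neural series' native
grid crossed with a movement lattice (1 ms native; inference defaults to a
10 ms lattice — a cosmetic nearest-neighbour upsampling is available for
display only, so no duplicated cells enter any test). The movement series
enters only at the group level; the neural participants are the sole
source of variance, so a map is computed per neural participant.
Covariates (task model, execution time, external behavioural RDMs, ROI
RDMs) are static and partialled cell-wise as above.

## Commonality analysis

For ROI *i* among a set of static fMRI ROI RDMs, the unique commonality at
a time–time cell is

    C_i = rho_p(mov, neural | ROIs except i, task)^2
        − rho_p(mov, neural | all ROIs, task)^2

with rho_p the partial Spearman correlation; the task model is always in
the background covariate set. C is in rho² units, may be negative
(suppression) and is reported unclipped. Exactly duplicated ROI RDMs are
collapsed inside the covariate sets (a duplicate carries no unique
variance, and would otherwise make the design singular). Per-participant
C maps feed the same cluster test as the raw maps.

## Inference

**Bootstrap bands.** Group-level model-correlation timecourses get
percentile bands from participant resampling with replacement (the
trajectory participants — recomputing group means, RDMs and correlations
per resample — or the neural participants, re-averaging their RDM
series). The 5th/95th percentiles form the band; one-tailed significance
against zero holds where at most 5% of resampled correlations are ≤ 0;
between-model differences are two-tailed on the resampled difference. A
leave-one-out jackknife is available but not the default. 10,000
resamples by default; the analysis scripts use 1,000.

**Cluster-based sign permutation.** Per-participant maps are tested
against zero with a one-sample t per cell; cells above the cluster-forming
threshold (α = 0.05, one-tailed positive by default — negative
representational overlap is not meaningful here; a two-sided option
exists) join 4-connected clusters scored by their t-sum. The null is the
maximum cluster sum over sign-flip permutations, each participant's whole
map multiplied by ±1 (10,000 by default; 1,000 in the calibration runs). A
cluster is significant when its Monte-Carlo p-value
(1 + #{null ≥ stat}) / (n_perm + 1) is at most the family-wise α = 0.05 —
the inclusive version of "beats 95% of the null", which guarantees the
family-wise error is controlled. Cells missing for any participant are
excluded from clustering. An exact variant enumerates all 2^P sign
patterns and is checked against the Monte-Carlo null at P = 8.

## Synthetic generator

The generator produces every input with planted, recoverable structure.
Trajectories: per trial, a jittered movement onset (30–150 ms), an early
face/animal-ward bias ramp (30 px), a logistic divergence toward the
correct box (midpoint 325 ms, scale 35 ms, amplitude 600 px), a delayed
and initially confusable course for lookalikes (extra delay 75 ms and pull
0.12 in the face-like preset; 110 ms and 0.45 in the animal-like preset,
which is what makes the lookalike model dominate early there), smooth
noise (25 px), per-participant offsets, a 16% lapse rate that sends trials
to the wrong box (group accuracy ≈ 0.83), and early termination at a
jittered arrival time with a per-image offset (the planted execution-time
structure). Boxes swap after two of four blocks; the initial arrangement
alternates across participants.

A per-image *image component* — a static part plus a slowly drifting part
(Gaussian-smoothed noise, 40 ms kernel), gated by an onset envelope —
is injected identically into the trajectories and the neural series, with
the movement expression lagging the neural expression by a configurable
lag (250 ms by default). The drifting part is what localizes each movement
time to one neural time and makes the lag recoverable from the time–time
map; the static part is what static ROI RDMs can share. Neural series mix
the task model, the lookalike model and the pairwise distances of the
image component, each with its own onset ramp, plus per-participant
symmetric noise on a constant baseline (clipped non-negative). ROI RDMs
mix the time-integrated expressed image geometry (the way a slow
haemodynamic measurement integrates a fast response) at a per-ROI weight
with iid independent structure and noise. The independent structure is
deliberately *not* a low-dimensional distance matrix: distance matrices of
low-dimensional configurations correlate with every other distance RDM
through shared stimulus indices, which would contaminate null ROIs.

Planted degenerate trials are constructed to make exclusion reasons
disjoint and countable: "short" trials carry a <100 ms sample window
placed mid-movement (so they still travel >50 px); "low-movement" trials
span the full window at a fixed position. Low-accuracy participants lapse
at 50%.

All randomness derives from one integer seed through fixed named streams;
identical seed and config reproduce every output bit for bit, and the
latent image component is shared across the three generators called with
the same seed. Ground truth is returned as a sidecar object; recovery
tests read only the sidecar.

### Problem sizes and power

The test suite and the calibration script run desk-scale studies: a
12-stimulus miniature (4 per category) for unit tests; 18–24 stimuli for
lag and covariate studies; 20 synthetic neural participants, 60 × 80
time–time lattices, 200 null datasets and 1,000 permutations for the
family-wise-error calibration.

The ROI variance-partitioning study uses a face-study-sized set (96
stimuli) under a dedicated preset (`SimulationConfig.commonality_study`):
with 4,560 RDM entries, sampling noise of an RDM-vector correlation
(~0.015) sits well below the weakest planted ROI's shared-geometry
correlation, which a smaller set cannot achieve. Two further choices in
this preset are load-bearing and worth recording. First, the shared image
component is almost entirely static there — a static ROI snapshot can
only share the static part, and commonality power for a weight-0.1 ROI
comes entirely through that chain. Second, single-participant neural noise
is set large relative to the common structure (as is realistic for
single-subject M/EEG RDMs). This is not only realism: with a *fixed*
group-level movement series and *fixed* ROI RDMs, the participant-level
sign-flip test is sensitive to any fixed realization-level bias in the
commonality maps, and is only calibrated for a null (weight-0) ROI when
between-participant variability dominates those fixed spurious
correlations. At low neural noise the procedure flags weight-0 ROIs at
well above the nominal rate — a genuine property of the design (fixed
covariates, common signal), not an implementation artefact; the pure-noise
calibration (no shared signal at all) is clean at any noise level.

## What the generator does not emulate

Real cursor dynamics (biomechanics, velocity profiles, submovements),
browser frame-drop patterns, screen-resolution heterogeneity, true M/EEG
noise spectra and spatial leakage, task effects on neural RDMs, and
session-level nonstationarity are all absent. Passing recovery tests
therefore shows the *pipeline* recovers planted structure under its own
assumptions — unbiased preprocessing, calibrated inference, correct
partial-correlation algebra — not that real mouse-tracking data contain
such structure.

## Numerical choices

- Average ranks everywhere; rank degeneracy threshold is relative to the
  rank variance of untied entries (1e-12).
- Collinear covariates raise; a covariate collinear with an input raises
  in scalar calls and yields missing cells in maps.
- Correlations are clipped into [−1, 1] against floating-point overshoot.
- MDS embeddings run SMACOF stress majorization initialised from the
  classical (Torgerson) eigendecomposition — deterministic given the
  seed, and exact for Euclidean-realizable inputs; an all-zero RDM maps
  to coincident points. Embeddings are illustrative only.
- HDF5 containers are written without timestamps so identical runs are
  byte-identical (the pipeline manifest hashes every output).

## Known limitations

- Partial Spearman via residualized ranks is the standard construction
  but not the only one (Kendall-based or copula partial correlations are
  out of scope).
- The cluster test's one-tailed default is a design choice; the maps it
  supports show positive representational overlap only.
- Commonality is first-order only: unique contributions per ROI, no
  higher-order shared terms among ROI pairs or triples.
- No noise-ceiling estimation and no cross-validated RDM distances.
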