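# Methods

## Signal model and preprocessing

A movement trial is modeled as a burst of band-limited (5–100 Hz) muscle
vibration riding on a low noise floor, sampled at 250 Hz on four channels.
The band-pass filter is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`): zero phase, so detected segment boundaries are not shifted
relative to the raw recording, at the cost of doubling the effective filter
order. Inputs with energy at the Nyquist edge are rejected rather than
silently aliased.

Segmentation follows the short-time-energy scheme: the channel-averaged
mean-square amplitude in a moving window (default 32 samples = 128 ms, hop
16 = 50 % overlap) is compared with a *relative* threshold, 0.1 × the
maximum window energy. A relative threshold makes segmentation invariant to
overall gain — multiplying the recording by any positive constant yields
identical boundaries — which matters because accelerometer sensitivities
differ between sites and sessions. Runs of above-threshold windows closer
than 0.2 s are merged (bursts briefly dip at movement reversal) and
segments shorter than 0.3 s are dropped (shorter events are artifacts at
this protocol's movement pace). Window length, hop, threshold fraction and
both durations are parameters; none of these values is dictated by the
underlying acquisition protocol, which leaves them unspecified.

## Feature definitions

Ten time-domain features use the standard EMG/MMG definitions (see
`extract_td`). The dead-band thresholds of ZC and SSC default to 0 — pure
sign/slope changes — because any nonzero dead-band couples the counts to
the amplitude scale; they are exposed for users who need noise-robust
counts. The v-order statistic uses v = 3 by default since v = 2 duplicates
RMS exactly. LOG floors |x| at machine epsilon so a single zero sample does
not collapse the geometric mean.

Frequency features come from a Welch PSD (Hann window, segment length
min(256, n), 50 % overlap): MPF is the spectral centroid, MF the smallest
frequency reaching half the cumulative power. A zero-power signal has no
spectrum and is rejected as degenerate.

Wavelet-packet energies use a 4-level db4 decomposition. At 250 Hz the 16
terminal bands are 7.8125 Hz wide; the 11 bands wholly inside the 5–100 Hz
passband (7.8125–93.75 Hz) become features — the lowest band overlaps the
filtered-out drift region and the top four lie beyond the passband, and
keeping them would only add columns the filter already emptied. Node energy
is the summed squared amplitude of the node's solo reconstruction. Signals
are zero-padded to a multiple of 2^level and decomposed with periodized
extension, which keeps the transform exactly orthogonal: the 16 node
energies sum to the signal energy to machine precision, whereas symmetric
extension was measured to drift by up to ~1 % for awkward lengths. The
wavelet and level are parameters.

The regularity statistics use the field-standard m = 2 and tolerance
r = 0.2 × SD of the segment; expressing r in SD units makes all three
entropies amplitude-scale invariant. Approximate entropy includes
self-matches (as its definition requires); sample entropy excludes them and
counts pairs over the first n − m templates at both lengths; fuzzy entropy
removes each template's own mean and uses exponential membership
exp(−(d/r)^2). If no template pair matches at length m + 1, sample entropy
is unbounded; the implementation returns the finite ceiling ln(B) (B the
m-length match count) with a warning instead of raising or returning
infinity, so one pathological segment cannot abort a batch extraction.
Lempel–Ziv complexity binarizes at the median, parses with the LZ76 scheme
and normalizes by n/log2(n). All four are verified against independent
brute-force template-counting oracles to 1e−12 in the test suite.

Feature columns are ordered channel-major with family order TD, FD, WE,
NLD, so any channel/family subset has a deterministic, documented layout.
No normalization happens at extraction time: z-scoring is done inside
cross-validation from training-fold statistics only, because scaling with
full-dataset statistics leaks held-out information into training (the test
suite includes a shuffled-label control demonstrating chance-level accuracy,
which a leaky pipeline would fail).

## Optimizers

Both metaheuristics maximize an arbitrary callback over a box, clamp
positions to the violated bound after every update (the simplest rule that
keeps the swarm inside the feasible region without reflecting artifacts),
and draw all randomness from one seeded generator, so runs are
deterministic per seed.

**CSA** runs three phases per iteration. The search phase mixes an
exploitation step p1·r2(P − G) + p2·r1(G − X) with exploration jumps scaled
by μ = exp(−(αt/T)³), which decays from 1 toward 0 so late iterations
exploit; defaults p1 = p2 = 2.0, Pp = 0.1, α = 4.0, c1 = 2.0, c2 = 1.8
follow the algorithm's original reference. The eye-rotation phase applies a
planar Givens rotation in two random dimensions about the individual's
coordinate centroid (angle uniform on [−π, π]); an isometry, so it
redistributes but does not grow the individual's spread. The hunt phase is
a PSO-like velocity update with inertia ω = (1 − t/T)^{p·t/T} and the
kinematic position step (v′² − v²)/2a with a = 2590(1 − e^(−log10 t));
a(1) = 0, so a is floored at 1e−6 to keep the first step finite while
leaving the formula intact elsewhere. Initialization is uniform
Lb + r(Ub − Lb).

**GOA** moves each individual to the current best solution plus a summed
pairwise social term: per dimension, c·Σ_j c·(ub−lb)/2·s(d_ij)·sgn(x_j −
x_i), with s(r) = f·e^(−r/l) − e^(−r) (f = 0.5, l = 1.5) and c decaying
linearly from 1 to 1e−5. Distances are remapped into [2, 4) via
2 + |d| mod 2 before s(·), following the original reference: without the
remap the zero-range repulsion s(0) = f − 1 keeps blowing apart a
collapsing swarm and final accuracy on smooth benchmarks is an order of
magnitude worse (measured on the 10-D sphere). Exact coordinate ties
contribute zero force.

Both record best-so-far traces (monotone by construction) and evaluate the
population once at initialization and once per iteration.

## Wrapper selection

Positions live in [0, 1] per feature. With the S1 sigmoid this confines
transformed values to [0.5, 0.731]: thresholds T ≤ 0.45 select everything,
T ∈ [0.5, 0.6] spans dense-to-sparse selection — exactly the interesting
regime of the threshold sweep. The V-family transfers take absolute values
(tanh and x/√(1+x²) are negative for x < 0 while T ∈ (0, 1)). Decoding is
interpret-only: optimizer dynamics stay continuous and masks exist only at
evaluation time. An all-zero decode is repaired by keeping the single
largest-transfer feature, since the fitness is undefined at R = 0 and a
classifier with no inputs is meaningless; ties at transfer(x) = T are not
selected (strict inequality). Fitness weights accuracy at α = 0.99 against
the fraction of features dropped.

One fixed stratified K-fold partition (seeded) is used for every fitness
call within a run, so mask comparisons are consistent; a single-holdout
mode exists for large runs. Identical masks are evaluated once and cached —
continuous positions frequently decode to the same mask, especially for
GOA's collapsing swarm, and the cache changes no reported value. The final
report re-evaluates the best mask on the same folds and carries per-fold
accuracies, the pooled row-normalized percent confusion matrix and
per-class recognition rates (its diagonal). The fold-wise selected count is
constant per mask, so the reported mean count equals R.

The classifier contract is scikit-learn's soft-margin RBF SVC with
one-vs-one voting, C = 10 and the data-driven kernel width
γ = 1/(n_features · Var[X]) ("scale"). No nested hyperparameter search runs
inside the wrapper: it would multiply the already-dominant CV cost and the
selection method does not depend on it.

## Synthetic data

The MMG generator emulates the study structure: 4 classes × 100 repetitions
× 4 channels at 250 Hz, one 1 s burst per trial between 0.75 s rest pads.
Class identity is carried by per-channel gain ratios (which muscles
co-activate) and a per-class spectral centroid (28/36/44/52 Hz), both
jittered per trial (lognormal gain jitter σ = 0.4, centroid jitter ± 6 Hz)
so classes overlap realistically. The rest floor is 5 % of burst RMS, low
enough for the relative-threshold segmenter to recover every planted burst
exactly — `generate_dataset` pushes each trial through the real filtering
and segmentation path and errors if the recovered burst count is not 1,
treating generator/segmenter disagreement as a bug rather than data. The
default separations were chosen to put full-feature 10-fold accuracy in the
high 0.8s: hard enough that feature selection has work to do, comparable to
typical human 4-class MMG performance.

What the generator does *not* model: inter-subject variability, electrode/
sensor placement drift, motion artifacts beyond the passband, muscle
fatigue, co-contraction dynamics, or any biomechanics — it matches the
statistical structure the pipeline exploits, not physiology. Passing tests
therefore show the pipeline is correct and behaves as designed on signals
with this structure; they do not certify recognition rates on human
recordings.

The planted-feature generator draws per-class means from N(0, effect²) in
k informative columns and standard normal noise elsewhere, giving a ground
truth against which selector recovery is measured.

## Experiment designs and problem sizes

The three experiment runners mirror the study designs at synthetic scale:
seven feature-set combinations, the four 3-channel subsets plus the full
montage, and the threshold grid {0.3, 0.35, …, 0.6}. Seeds play the role
subjects play in the original per-subject analysis: results aggregate over
seeds as the study aggregates over subjects. Between-condition significance
testing is out of scope. The threshold-sweep checks in the test suite run
at a reduced wrapper budget (population 10, 20 iterations, 5 seeds) and the
acceptance script samples the sweep at T ∈ {0.3, 0.6} with 2 seeds —
problem sizes chosen to exercise every code path at meaningful scale while
keeping a full verification run in the minutes range.

## Known limitations

- Recognition rates on real MMG cannot be validated here; the human
  recordings behind the original study are not public.
- The printed form of several update rules in the source literature is
  ambiguous (random-coefficient pairings, an exploration-exponent sign, the
  GOA distance argument); this implementation resolves them toward the
  cited original algorithm papers and documents each choice above.
- The wrapper's fitness CV cost grows linearly in population × iterations ×
  folds; the mask cache helps most when swarms converge, least in the first
  iterations.
- `fitness_history` records best-so-far values, so per-iteration raw swarm
  fitness is not exposed.
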