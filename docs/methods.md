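# Methods

This note records the model assumptions, the numerical choices that were
genuinely open, and what the synthetic benchmarks do and do not establish.

## Signal model and band decomposition

The pipeline treats scalp EEG as a superposition of band-limited
oscillatory processes over a 1/f background.  Eight rhythms are fixed
(δ 0.5–4, θ 4–8, α₁ 8–10, α₂ 10–13, β₁ 13–20, β₂ 20–30, γ₁ 30–48,
γ₂ 52–70 Hz).  Band extraction is a 3rd-order Butterworth applied
forward–backward: zero phase lag at the price of an effective 6th-order
magnitude response, so a tone at a band edge sits at −6 dB (this is why
validation tones are placed mid-band).  The first/last ⌈fs/f_lo⌉ samples
of each band are treated as filter transient; sliding windows are laid
out with a margin that keeps them clear of both edges.

Artifact handling: PCA to 95% variance, FastICA, then the moment-based
rule — a component is removed when more than 30% of its 1-s-windowed
kurtosis *or* skewness z-scores fall outside ±2.  The z-scoring is done
against the pooled distribution over all components' windows: scoring a
component against its own windows can never place more than 25% of them
beyond 2 SD (Chebyshev), so only the population-relative reading of the
rule is operative.  Reconstruction is back-projection to full sensor
space without the flagged sources.  The 1-s moment window and the 60 Hz
notch default are configuration values.

## The coupling estimator and its null

iPLV = |Im⟨e^{iΔφ}⟩| discards the real part of the mean phasor, hence
zero-lag (volume-conduction-like) synchrony.  A consequence accepted
throughout: genuinely zero-lag physiological coupling is invisible, and
planted couplings in the generator default to a π/2 lag.

Cross-frequency (phase-to-amplitude) coupling is measured as iPLV between
the slow band's phase on one channel and the phase of the slow-band
component of the fast band's envelope on the other.  Both directions are
evaluated; the larger observed iPLV represents the pair.  Because that is
a selection over two tests, significance uses the max-statistic
correction: the max over directions is applied to the surrogate
statistics too, which keeps the test exact without raising the p-value
floor (a Bonferroni doubling would collide with the floor at 200
surrogates).

Surrogates are circular time-shifts of the second series.  Three details
matter for calibration, all verified empirically against near-nominal
false-positive rates:

* the *full windowed span* is shifted, not the window content — within a
  short window, narrowband phases are so autocorrelated that
  window-internal shifts understate the null by a factor of several;
* the roll domain is restricted to exactly the span the windows cover, so
  filter transients outside it can never rotate into a window;
* a surrogate whose wrap seam falls inside a window is excluded for that
  window (the seam is a phase discontinuity the observed data cannot
  have).  Offsets are uniform with a minimum of one slowest-band cycle.

Shift offsets are drawn once per sensor pair (deterministically from the
master seed) and shared across windows and the 36 candidate modes, so
mode comparison happens on identical surrogates.

Per-mode significance defaults to α = 0.05 uncorrected with a
Bonferroni-over-36 option; with 200 surrogates the p-value floor
(≈ 1/170 after seam exclusion) makes the Bonferroni option unusable —
it requires ≳ 700 surrogates.  The dominant mode is the significant
candidate with maximal iPLV, ties to the lowest label, and label 0 with
strength 0 when nothing is significant.

Window geometry is a required configuration.  The default is 2.5 s width
with a 20 ms step; the planted-recovery benchmark uses 6 s windows,
because a 2-Hz-wide band (α₁) offers only ~1 independent phase sample per
second and per-window detection at α = 0.01 needs several.

## OMST filtering and network metrics

Statistical filtering (mode 0 edges dropped) precedes topological
filtering.  OMST extracts successive edge-disjoint MSTs on distances
1/weight and keeps the union of the first m\* rounds, m\* = argmax
J(m) = GE(union) − Cost(union), Cost being retained weight over total
weight.  Open choices fixed here: at most ⌊(N−1)/2⌋ rounds, early stop
after two consecutive J decreases, per-connected-component operation on
disconnected inputs (unreachable pairs contribute zero efficiency).
Distances are exact Dijkstra on the inverted weights; nodal global
efficiency is the mean inverse distance to the other N−1 nodes.

## Microstates

The NNMF rank r (default 8) and the codebook size k are independent
knobs.  NNMF uses coordinate-descent updates, tolerance 1e−10, up to
1,000 iterations, and 5 seeded random restarts keeping the lowest
Frobenius error (multiplicative updates stall well short of the exact
low-rank recovery the contract demands); a deterministic SVD-based
initialization is available and makes the factorization equivariant to
sensor permutation.  Neural gas runs 100 passes with λ decaying
exponentially from k/2 to 0.01 and the learning rate from 0.5 to 0.005,
prototypes initialized at random data points.  k is the smallest value in
the configured range whose codebook rebuilds the input with relative
Frobenius error < 4%; when none qualifies the largest is kept with a
warning.  Seriation is a nearest-neighbor chain started at the
highest-occupancy prototype (ties to the lower index), so neighboring
symbols denote similar states; encoded labels are reported in seriated
order.

## Chronnectomic features

All entropies are in bits.  The transition matrix is normalized by the
total number of observed transitions (it sums to 1 overall and is *not*
row-stochastic); the Markov chain kernel used for trajectory entropy is
the separate row-normalized empirical matrix, restricted to the states
actually visited (and further to the recurrent class if the empirical
chain is reducible).  Trajectory entropy follows the Ekroot–Cover
construction H = K − K′ + HΔ, K = (I − P + A)⁻¹(H\* − HΔ) with A's rows
equal to the stationary distribution.  Two facts established numerically
and used as tests: the diagonal identity H_ii = H(X)/μ_i holds by
construction (K − K′ cancels on the diagonal), and H is invariant to
transposing A — the two printed conventions for A induce only per-column
offsets in K, which cancel.  Off-diagonal correctness is pinned instead
by a geometric-path closed form (2-state chains) and a Monte-Carlo
first-passage oracle (sampled path log-probabilities).

The flexibility index counts a change to or from label 0 as a
reconfiguration.  The complexity index counts distinct contiguous
substrings up to word length 7 (default), z-scored against 1,000 seeded
shuffles, 0 when the shuffle distribution is degenerate.  Sample entropy
uses m = 2, r = 0.2 · SD, strict `< r` Chebyshev matching, self-matches
excluded, and the same n − m template start positions for both lengths
(so a constant series gives exactly 0); an undefined ratio returns +∞
with a warning, and the cohort runner drops non-finite feature columns.
The canonical feature layout TR + TM + FI + comodulogram + Z(CI) + ERT +
SampEn has 1 + k² + N² + 36 + 1 + k² + 1 entries — 4,263 at k = 8,
N = 64.

## Prediction

Feature selection is nested inside every leave-one-out fold by default; a
cohort-level mode (selection once, before cross-validation) exists for
comparability with studies that describe it, and is optimistic by
construction — the nested null tests (shuffled targets → R² ≤ 0.1,
accuracy at chance) are the leakage guard.  Open hyperparameters fixed
here: SVR linear kernel, C = 1, ε = 0.1, per-fold standardization;
ELM with 100 sigmoid hidden units, input weights uniform on [−1, 1],
ridge 1e−6; Laplacian-score permutation threshold mean + 2.5 SD over 200
label permutations; dominant-set extraction by replicator dynamics from a
near-uniform start with a 1e−4 index tilt (deterministic tie-breaking for
exactly symmetric clusters), support threshold 1e−5 of the peak,
leftovers as singletons.

## What the synthetic data emulates — and what it does not

`gen_coupled_eeg` produces 1/f background noise plus planted couplings:
within-band coupling as a shared narrowband source injected into both
channels at a fixed phase lag (band-filtered white noise, whose phase
diffuses as fast as the bandwidth allows — the property the surrogate
null relies on), and PAC as a constant-amplitude drifting-phase
oscillator pair, the slow one's phase-shifted copy modulating the fast
one's envelope with depth equal to the coupling strength.  SNR in dB is
the in-band amplitude ratio of oscillation to background.  Piecewise
epochs give state switching.

Not emulated: volume conduction and sensor mixing, nonstationary
artifacts, true microstate topographies, inter-subject variability of
spectra.  Passing the planted-recovery benchmarks therefore shows the
estimator chain is correct and calibrated under its own assumptions — not
that real cohort-level effects (e.g. age prediction accuracy on real EEG)
are reproduced.  Cohort-scale claims are exercised only on
`gen_feature_cohort`, which plants a linear age effect with correlated
nuisance blocks directly in feature space.

## Benchmark problem sizes

The reference checks run at desk scale: planted-coupling recovery uses 8
channels × 30 s at 160 Hz (41 six-second windows, 200 surrogates,
α = 0.01, fully coupled pairs at 10 dB SNR); the expected false-positive
rate for "any of 36 modes significant" is 1 − (1 − α)³⁶ ≈ 0.30, and the
observed rate is compared against it with slack computed on the effective
number of non-overlapping windows (overlapping windows share most of
their samples).  Microstate recovery uses 16 sensors × 300 windows at 1%
noise; ML recovery uses 50-subject cohorts.  Determinism: every stochastic
step (surrogates, NNMF restarts, neural gas, shuffles, permutations, ELM
weights) derives from an explicit seed, and per-subject seeds derive from
the master seed and subject index.

## Known limitations

* The surrogate null assumes within-span stationarity; strongly
  nonstationary recordings (e.g. unremoved movement artifacts) will
  inflate detections.
* δ-band couplings are hard to resolve at the default window widths (a
  2.5 s window holds ~1 δ cycle); widen the window for slow-band claims.
* The 4% microstate reconstruction target is often unreachable on noisy
  NMTS with small k ranges; the implementation then warns and keeps the
  largest k rather than failing.
* EDF output is 16-bit with per-channel scaling: amplitudes are
  quantized to ~1/65,535 of each channel's range on round-trip.
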