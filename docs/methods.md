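# Methods

This note records the models, defaults, and design choices behind
`sleepuq`, in the order data flows through the package.

## Synthetic polysomnography

**Hypnogram model.** Ground-truth stage sequences are first-order Markov
chains over the fixed stage order (W, REM, N1, N2, N3). The default base
transition matrix is strongly diagonal (self-transitions 0.80–0.90) with
physiologically ordered off-diagonal mass: wake drifts into N1, N1 deepens
into N2, N2 exchanges with N3 and REM, N3 lightens through N2. These values
are stylized package constants, not fits to any cohort — published sleep
studies rarely report their subjects' transition statistics, so the matrix
is documented here and exposed in `SyntheticStudyConfig` rather than
presented as empirical. Nights start in W or N1
(`initial_distribution = [0.85, 0, 0.15, 0, 0]`).

**Fragmentation.** Sleep-disordered breathing fragments sleep; the
simulator models this with a single scalar `fragmentation` w that mixes the
base chain toward the uniform chain, T = (1−w)·T_base + w·U, clipped at
w = 1. This raises the transition count per night monotonically and
degrades stager performance with "severity", without modelling respiration,
arousals, or apnea events (explicitly out of scope, as is any AHI
computation). Severity grades used by the cohort driver: normal 0.0, mild
0.1, moderate 0.25, severe 0.4 — chosen once to span a gentle-to-marked
fragmentation range.

**EEG model.** Each stage has a relative band-power profile over the
classical bands (delta 0.5–4, theta 4–8, alpha 8–12, sigma 12–16, beta
16–30 Hz): wake is alpha/beta rich, REM and N1 are both theta-dominant (and
therefore deliberately close, as in real recordings), N2 carries sigma
spindle power, N3 is three-quarters delta. Band activity is *filtered
Gaussian noise* (4th-order Butterworth, zero-phase), not sinusoids, so
multitaper estimates have realistic variance; band processes are normalised
to unit variance and weighted by the square roots of the profile entries,
plus a broadband white floor (relative power 0.05).

**Epoch-to-epoch variability.** Real sleep EEG shows large within-stage
power fluctuation; without it, 30-s epochs average away almost all spectral
variance and staging becomes trivially perfect, which makes every
uncertainty question degenerate. Each epoch therefore draws an independent
log-normal amplitude gain per band, sigma = `band_variability` (default
0.5, in log-amplitude units, i.e. roughly ±4 dB per band per epoch). This
is the single knob that sets task difficulty; the default was chosen to
place automated performance in the substantial-agreement range (kappa
~0.6–0.9 across severities with a 15–35% review burden), the regime where
targeted review is actually interesting.

**Randomness.** Everything derives from one integer seed through
`numpy.random.SeedSequence`; the hypnogram and the EEG consume separate
child streams, so each is independently bit-reproducible.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: artifacts (movement, electrode pops, sweat),
non-stationarity within an epoch, inter-subject amplitude differences,
second-order stage dynamics (e.g. REM periodicity across the night), and
any non-EEG channel. Results here demonstrate the *mechanics* of
uncertainty-guided review, not clinical performance.

## Features

The signal is bandpass filtered 0.1–50 Hz with a zero-phase
forward–backward 4th-order Butterworth filter, cut into half-open 30-s
windows [kL, (k+1)L) (trailing partial epochs dropped with a warning), and
each epoch is reduced to log band powers from a multitaper PSD. Multitaper
settings: time-bandwidth 4, 7 DPSS tapers, equal-weight averaging, one PSD
per epoch (no sub-epoch sliding window) — standard sleep-EEG practice,
exposed as parameters. Default bands: 0.5–4, 4–8, 8–12, 12–16, 16–30,
30–50 Hz (six features), matching the simulator's band structure plus a
high band, and low-dimensional enough for kernel density estimation. Band
power is floored at 1e-12 before 10·log10 so silent epochs stay finite.
The PSD is one-sided and Parseval-consistent (integrating it recovers the
epoch variance to within sampling error; the suite checks 15% on white
noise).

## Stagers

**KDE-HMM.** Transition probabilities are training-label bigram frequencies
with add-one pseudocounts, row-normalised; the initial distribution uses
the same smoothing on unigram frequencies so no stage ever has exactly zero
initial mass (a −inf in the log-domain forward pass). Emissions are
Gaussian kernel density estimates per stage: features are standardised per
dimension and a single Scott-rule factor n^(−1/(d+4)) is applied in the
scaled space (equivalently, a diagonal bandwidth matrix proportional to the
per-dimension spread); Silverman's rule or a numeric factor are accepted
alternatives. Emission log-densities are floored at −700; a stage absent
from training gets a flat emission with a warning. Decoding uses the
forward–backward algorithm entirely in the log domain with per-step
log-sum-exp, producing exact smoothed marginals; the suite verifies
equality with brute-force path enumeration to 1e-10. The reported
hypnogram is the per-epoch arg-max of the smoothed marginals (ties to the
lowest stage code); a Viterbi path would optimise a different criterion
(joint sequence probability) and is deliberately not the default output.
Baum–Welch unsupervised training is out of scope.

**MLP.** `sklearn` MLPClassifier with hidden layers [32, 64, 32], ReLU,
softmax outputs, inputs standardised with training statistics, seeded and
deterministic; `max_iter = 500` as a fixed training budget. Training with
fewer than two stages present is rejected.

## Uncertainty

Rényi entropy is evaluated in bits with three special branches: α within
1e-9 of 1 routes to the Shannon formula under the 0·log 0 = 0 convention;
α = ∞ evaluates −log2 max p; other α > 0 drop zero-probability terms
before the power sum. Values are clamped to [0, log2 5] to absorb float
dust. Rows off the simplex by ≤ 1e-6 are renormalised (floating-point
drift from the smoother); larger violations are rejected. Note the exact
Rényi functional has slope −(ln2/2)·Var_p[log2 p] in α at α = 1, so its
distance from Shannon at α = 1 ± ε is O(ε), not arbitrarily small; the
suite checks continuity at that scale.

Posterior *variance* is defined as the population variance of the five
probability masses, mean((p_i − 1/5)²) — 0 at the uniform posterior, 0.16
at a one-hot. The definition is one admissible reading (the variance of
the stage *index* was rejected because stage codes are nominal, not
ordinal); it is reported as a measure but not used for flagging, since its
orientation is opposite to entropy.

Flagging uses a strict inequality, S_epoch > threshold, default 1 bit: an
epoch at exactly the threshold stays automated. In the evaluation's
certain/uncertain stratification, at-threshold epochs accordingly fall in
the certain stratum.

## Targeted review

Four scoring methods per night: automated; automated + review; automated +
clinically-relevant review; automated + substitution. Substitution replaces
flagged epochs with ground truth — the upper bound on review benefit, and
provably never worse than automated (per-epoch replacement with truth
cannot lower the match rate).

The *clinical-relevance filter* keeps a flag only when the epoch's two
most probable posterior stages form a relevant pair. Relevance is judged
from the posterior, never from truth: truth is what review is trying to
establish and is unavailable at review time. The default relevant set is
all 10 unordered pairs minus {W, N1} and {N1, N2} — the two light-sleep
boundaries that are notoriously ambiguous even between human experts. This
default is a package choice (only the W-vs-N1 exclusion and REM-vs-N3
inclusion have clear clinical precedent) and is fully configurable.

The *simulated reviewer* is imperfect by design: a flagged wrong epoch is
corrected with probability `reviewer_accuracy` (default 0.8, in the range
of human inter-scorer agreement), a flagged correct epoch is corrupted to a
uniformly random other stage with probability `reviewer_error_rate`
(default 0.15). With a nonzero error rate, review can *lower* Cohen's
Kappa on a night — reproducing the qualitative finding that expert review
is itself fraught with uncertainty. Truth is used only as the simulation
oracle; a deployment would substitute a human.

## Evaluation

Cohen's Kappa is computed from the standard formula with the degenerate
p_e = 1 case (both raters constant) returning 1 for identical sequences
and 0 otherwise, with a warning. Confusion matrices are stratified by flag
into certain/uncertain, rows = true stage, columns = estimate, row
percentages at full precision (integer rounding only at display); empty
rows are NaN (undefined), never zeros. Entropy-distribution summaries
group epochs by correctness and by *true* stage, report population
standard deviations (the convention is stated because the ± convention in
figure captions is often left implicit), and fit a 1-D Gaussian KDE over
[0, 2.32] bits when a group has ≥ 2 distinct values. The paired t test is
the classic df = n−1 test on per-night kappa differences; zero-variance
differences return a (nan, nan) sentinel with a warning rather than an
infinite statistic.

## Cohort scale

The default study is 4 training nights (one per severity grade) and 10
test nights (4 normal / 2 mild / 2 moderate / 2 severe) of 960 epochs
(8 h) at 250 Hz — a severity-stratified train/test split at a size that a
complete run, including EEG synthesis and feature extraction for all 14
nights, finishes in about a minute. Per-night seeds, the stager seed and
per-night reviewer seeds are all spawned from the single study seed.

## Known limitations

* The simulator's stage spectra and transition matrix are stylized; no
  claim is made that absolute kappas transfer to recorded PSG.
* KDE emissions assume a fixed low-dimensional feature space; hundreds of
  features would require a different emission family.
* The relevance filter's default pair set encodes a simple judgment call;
  clinical deployments should set it explicitly.
* EDF ingest is read-only and minimal (one channel via `mne`); Spike2 and
  other proprietary formats are unsupported.
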