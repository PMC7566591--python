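# Methods note

This note documents the models and estimators implemented in `fnpag`, the
parameter defaults and their rationale, what the synthetic generator does
and does not emulate, the numerical choices, and known limitations.

## Behavioral state from gyroscope signals

The motor signal is the Euclidean norm of the three gyroscope axes
(deg/s). It is smoothed with a Gaussian kernel of standard deviation 64 ms,
truncated at ±4 s.d. and renormalized near the edges (the kernel mass that
falls outside the recording is redistributed by dividing by the convolved
kernel support, so constants are preserved everywhere including the first
and last samples). Samples with smoothed norm below 12 deg/s are *immobile*
(state 1); 12 deg/s and above is *active*. Immobility episodes are maximal
runs of immobile samples as half-open intervals; the offset is one sample
period past the last immobile sample. Freezing from video is the fraction
of frames whose pixel-change is below 0.5%, aggregated per event interval.

Defaults: smoothing s.d. 64 ms, threshold 12 deg/s, freezing threshold
0.5%. These are standard operating points for head-mounted inertial sensors
and background-subtraction freezing scores; they are exposed as arguments
everywhere.

## Event-triggered responses

PSTHs average spike counts in fixed-width bins across event repetitions,
with a bin edge at t = 0 and half-open bins. Spikes are assigned to bins by
direct index computation with a tolerance of 1e-9 of a bin width, so spikes
that fall exactly on a bin edge (common with synthetic, grid-aligned spike
times) are never pushed into the previous bin by floating-point
representation error. z-scores use the mean and population s.d. (ddof 0) of
the pre-event baseline bins; a zero baseline s.d. raises an error rather
than producing infinities. Response latency is the left edge of the first
bin inside (0, 50 ms] whose z exceeds the threshold; the default threshold
is 4.1 s.d., with any other value (e.g. 4.0) available as an argument.
Optogenetic analyses use 2 ms bins; immobility-onset analyses use 100 ms
bins.

Immobility-profile classification: each cell's immobility-onset PSTH
(±2 s, 100 ms bins) is divided by its own mean, and cells are partitioned
by K-means (K = 2, 10 restarts, fixed random state). Labels are permuted so
cluster 1 is the cluster whose centroid drops more from the pre-onset to
the post-onset window — i.e. cells suppressed during immobility. Cells with
all-zero PSTHs cannot be mean-normalized and are excluded and reported.

State-conditioned rates use the zero-order-hold state at each spike time;
the modulation index is (immobile − active)/(immobile + active).

## Transfer entropy

Series are binned at 10 ms. Spike trains become binary (default) or
capped-count sequences; the motor state is resampled by taking its value at
each bin's left edge (zero-order hold). Transfer entropy from source S to
target T with history h and lag l (defaults 1 and 1) is the plug-in
estimate of I(T_t ; S_{t−l} | T_{t−1..t−h}) in bits: joint symbol counts
are accumulated over all valid time points, and the conditional mutual
information is summed over observed cells with the 0·log 0 = 0 convention.
The estimate is clipped at 0 (it is non-negative in exact arithmetic) and
flagged degenerate when either series is constant.

The plug-in estimator is positively biased on independent data (bias
~ (cells − 1)/(2N ln 2)); with binary series, lag 1, and N = 10⁴ bins the
null mean is below 0.01 bits and decreases with N, which the tests verify.
No bias correction or surrogate normalization is applied; comparisons
between directions use equal N by construction, so the shared bias cancels
at the level of orderings.

## Partial information decomposition

For sources S1 (an FN cell), S2 (the motor state) and target T (a PAG
cell, taken `lag` bins later), the joint distribution over
(S1_{t−l}, S2_{t−l}, T_t) is estimated by counting. Redundancy is the
Williams–Beer minimum specific information:
R = Σ_t p(t) · min_i I_spec(T = t; S_i), with
I_spec = Σ_s p(s|t) [log2 p(t|s) − log2 p(t)]. Unique information of each
source is its mutual information minus R, and synergy is the joint mutual
information minus the three other atoms. All four atoms are non-negative
and satisfy the lattice identities by construction; proportions (atoms
divided by the joint mutual information) are reported per protocol stage
and are undefined (None) when the joint mutual information is 0. This
redundancy measure is the standard closed-form choice for two discrete
sources; unlike estimator families that require iterative optimization it
is exactly reproducible and testable against hand-enumerated cases (XOR →
pure synergy, duplicated source → pure redundancy, single informative
source → pure unique).

Stage analysis slices the 10 ms bin grid by the stage windows derived from
the event schedule (baseline: up to 300 s before the first CS;
conditioning: first CS onset to last stimulus offset; after: the following
300 s) and requires at least 100 bins per stage.

## Synthetic generator

What it emulates:

- two-state (active/immobile) behavior as an alternating renewal process
  with exponential dwells (defaults 20 s active / 15 s immobile, starting
  active), sampled at 100 Hz;
- gyroscope magnitude as a state-dependent level (100 vs 5 deg/s) plus
  Gaussian noise (s.d. 2 deg/s, clipped at 0) on a random isotropic axis;
- spiking as Bernoulli on a 1 ms grid: p = base rate × (immobility gain if
  immobile) × 1 ms. Default base rate 10 Hz, default gain 0.2
  (suppression); gains > 0.5 mark ground-truth cluster 2, ≤ 0.5 cluster 1;
- directed coupling: each PAG cell couples to one FN cell (cyclic
  assignment). An FN spike in 10 ms bin b adds the coupling strength
  (default 0.3) to the PAG spike probability, spread uniformly over the
  1 ms sub-bins of bin b + lag (default lag 1). A per-millisecond scale
  array can vary the coupling across stages. Probabilities are clipped to
  [0, 1] and clipping is flagged in the ground truth;
- optogenetic responses: baseline Poisson train plus at most one evoked
  spike per pulse at pulse + latency + Gaussian jitter, with a per-pulse
  response probability;
- video pixel-change: constant active level (2%) and frozen level (0.1%)
  around the immobile bouts, at 25 fps;
- a conditioning event schedule (default: 180 s acclimation, 5 × 30 s CS
  with a 0.5 s US in the last 0.5 s, 120 s ITI) and an extinction variant
  (25 CS, no US).

Parameter rationale: the 100 vs 5 deg/s levels with s.d. 2 put the
immobile level ~3.5 s.d. below the 12 deg/s threshold and the active level
far above it, so state errors come only from the ~90 ms smoothing smear at
transitions; with 20 s/15 s dwells that yields ≈99.5% per-sample
agreement. Coupling 0.3 at 10 Hz base rate gives a transfer-entropy excess
that is detectable in 300 s (30,000 bins) on essentially every seed while
remaining far from probability clipping.

What it does not emulate: refractory periods, bursting, or non-Poisson
interval statistics; graded (non-binary) behavioral states; measurement
noise on spike times; shared common input other than the motor state;
electrode drift or unit loss; and any within-session learning dynamics
beyond an externally imposed coupling scale.

Determinism: a session expands one seed into independent child streams for
behavior, gyroscope, spikes, and video, so regenerating with the same
configuration is bit-identical.

## Numerical and I/O choices

- All times are seconds on one session clock; intervals are half-open
  [onset, offset). Analysis bins place an edge at the span start.
- Entropies use log2 throughout (bits) with 0·log 0 = 0; PID atoms are
  clipped at −1e-12 before the non-negativity projection to absorb
  round-off.
- TSV output uses 17 significant digits (`%.17g`), which round-trips
  float64 exactly; session readers parse with pandas' round-trip float
  precision. Result directories include a JSON manifest with SHA-256
  checksums, and re-runs are byte-identical.
- K-means uses scikit-learn with a fixed random state and 10 restarts;
  adjusted Rand index (scikit-learn) scores cluster recovery in the tests.

## Limitations

- The plug-in TE/PID estimators are for short symbol alphabets and the
  desk-scale regime (≤ a few × 10⁵ bins); no debiasing, surrogate testing,
  or continuous-valued estimation is provided.
- The Williams–Beer redundancy can overstate redundancy relative to newer
  pointwise or optimization-based PID measures; stage comparisons within
  one measure are unaffected.
- Latency detection reports the first threshold crossing only; it does not
  model multi-phasic responses or correct for the multiple comparisons
  across bins, so with sparse baselines a 4.1 s.d. crossing can occur by
  chance in a pre-response bin.
- The state binarization assumes a bimodal motor signal; slow, low-
  amplitude movements below 12 deg/s are scored immobile by design.
- The generator's coupling acts on 10 ms bins (matching the analysis
  resolution), not on continuous synaptic timescales.
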