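# Methods notes

This note documents the models, numerical choices and open design
decisions behind `neoms`, and what the validation experiments do and do
not establish.

## Preprocessing

The band-pass is a cascade of separate 7th-order high-pass and low-pass
Butterworth filters, each applied forward and backward (zero phase), in
second-order sections — the 7th-order transfer-function form is
ill-conditioned at a 0.15 Hz cutoff relative to a 100 Hz rate.  Reflect
padding is sized at `max(6·order samples, 3 periods of the cutoff)`,
clamped to the epoch length: a 0.15 Hz high-pass settles over seconds, so
sample-count padding alone leaves visible transients on anything shorter
than a few minutes.  The analytic squared Butterworth magnitude
(`butterworth_attenuation`) is used in tests as a conservative stop-band
bound; the digital (bilinear) filter is steeper, and at attenuations
beyond ~1e-4 the forward–backward residual is dominated by the numerical
floor rather than the transfer function.  Down-sampling is polyphase
(anti-aliased); common-average referencing is exact and idempotent.
Artifact handling is limited to a caller-supplied keep-mask of pre-marked
clean samples; microstate runs never span clip boundaries because each
retained contiguous block is analyzed as its own epoch.

## Clustering

Maps are centered and norm-normalized; the polarity-invariant objective is
the mean squared spatial correlation with the assigned template
(equivalently, minimizing `1 − r²`).  The template update — the dominant
eigenvector of the assigned maps' outer-product sum — is the closed-form
maximizer of the summed `r²`.  Three numerical choices matter:

* **Initialization.** Restarts are seeded k-means++-style with the
  sign-agnostic distance `1 − r²`.  Plain random-row initialization covers
  7 well-separated clusters with probability `7!/7⁷ ≈ 0.6%` per restart
  and routinely stalls the dispersion curve; the ++ seeding makes coverage
  near-certain.
* **Exchange refinement.** The Lloyd-style alternation can only terminate
  at partitions consistent with their own templates' nearest-template
  assignment, and the global optimum need not be such a partition.  Each
  restart is therefore polished by Hartigan-style single-map exchanges
  (accepted when the summed dominant eigenvalues increase).  The sweep
  costs O(n·k) eigendecompositions, while its benefit vanishes for large
  well-populated clusters (one map cannot move the eigenvector), so it is
  auto-enabled only for small inputs (`n·k ≤ 512`) and exposed as a flag.
  On ≤8-map, k=2 instances this attains the exhaustive-partition optimum
  to machine precision.
* **Convergence.** Relative objective change below 1e-6, 300 iterations
  max, 20 restarts by default; an emptied cluster is re-seeded from the
  worst-fit map.  All defaults are configurable.

**KL criterion.** `W(k)` is the summed within-cluster `1 − r²` (the same
geometry the clustering minimizes), `DIFF(k) = (k−1)^{2/C}W(k−1) −
k^{2/C}W(k)`, `KL(k) = |DIFF(k)/DIFF(k+1)|`, defined on the interior of
the scanned k-range.  "First/second maximum" ranks the *local maxima of
the KL curve by value*: the first maximum is the largest local maximum,
the second the runner-up.  The alternative reading (maxima in ascending-k
order) is dominated by tiny wiggles of the `DIFF` ratio around 1 below the
true K and proved useless even on strongly separated planted clusters.
With fewer than two local maxima the second-max rule falls back to
first-max with a warning.  Whether per-subject clustering should use a
fixed K or per-subject selection is genuinely open; the pipeline uses a
fixed K at both steps (selection is exposed separately via `kl_select`).

**Template ordering.** Labels A, B, … are assigned by descending total
coverage on the pooled data after backfitting (`order_by_coverage`);
matching of templates across bands, states or to a planted truth uses
greedy maximal-|r| assignment.

## Backfitting and metrics

Labels are categorical, so "interpolating" between peak labels is realized
as nearest-peak assignment — boundaries at midpoints between consecutive
peaks, ties to the earlier peak (the established toolbox behavior).  The
first and last runs of an epoch are flagged boundary-truncated and
excluded from mean duration by default (a clipped run biases duration
downward); occurrence counts all run starts per labeled second and
coverage partitions the labeled samples, so
`Σ_k occurrence_k · duration_k = 1000 ms/s` exactly when the truncation
rule is off.  GEV is computed over GFP peaks by default (the domain the
templates were fitted on); an all-samples variant is exposed.  Occurrence
uses labeled time, not gross epoch time, so clipped epochs are comparable.

## Syntax statistics

Transitions are counted on the run sequence, making self-transitions
structurally impossible — which is exactly why the expected-transition
formula carries the `1/(1 − P_X)` normalization.  Two caveats are worth
stating explicitly:

* The occurrence-driven null chain `P(Y|X) = P_Y/(1 − P_X)` is
  self-consistent (its stationary run distribution equals P) **only for
  uniform P**.  For non-uniform occurrences the formula's null is
  structurally biased, and the randomization test rejects it reliably —
  a property of the statistic, not a bug.  Calibration experiments
  therefore use the uniform chain, where the test's type-I error is
  compatible with its nominal level; with strongly skewed occurrences the
  test should be read as "transitions deviate from the occurrence-driven
  formula", not "transitions are history-dependent".
* The randomization p-value is `#(D_rand ≥ D_obs)/n_reps`.  A strict `>`
  degenerates to p = 0 when every randomized distance equals the observed
  one (e.g. observed ≡ expected); `≥` is the standard permutation
  convention and almost surely identical for continuous D.  A conservative
  `(r+1)/(n+1)` variant is exposed.  The exchangeability unit is the
  epoch (each epoch's observed/expected pair is swapped independently);
  with unbalanced epochs per subject, matrices are averaged within subject
  first.

Directional predominance is tested per template pair with a two-sided
one-sample t against zero, Benjamini–Hochberg-corrected across the
K(K−1)/2 pairs; constant-zero pairs are reported degenerate rather than
tested.

## Topographic statistics

GD is evaluated on average-referenced, GFP-normalized maps and satisfies
`GD² = 2(1 − r)` exactly for zero-mean maps.  TANOVA's effect size is the
GD between group-mean maps; because polarity-invariant clustering leaves
each subject's template sign arbitrary, maps are sign-aligned before
averaging to the dominant eigenvector of the **pooled** (both-group)
outer-product sum — pooled so the reference is permutation-invariant (a
validity requirement) and common to both groups (per-group references
carry an arbitrary eigenvector sign that can anti-align the two means).
The permutation scheme is paired (within-subject condition swaps) by
default, matching a within-subject sleep-state design; group sizes,
pairing and permutation count are parameters.

## Group statistics

The two-way fully-within ANOVA is computed from the direct
sums-of-squares decomposition (each within factor's error term is its
interaction with subjects); Greenhouse–Geisser epsilon comes from the
orthonormal-contrast covariance (Kronecker contrast for the interaction)
and multiplies both degrees of freedom; effects with one numerator degree
of freedom skip the correction.  Effect size is partial η² =
SS_effect/(SS_effect + SS_error).  The implementation is cross-checked in
the test suite against an independently written SS oracle and against
`pingouin.rm_anova`.  Because coverage sums to 100% for every subject and
state, the sleep-state main effect for coverage is reported as not
applicable.  Missing cells are an error (no imputation).

## Synthetic cohorts

An epoch is a concatenation of segments: label from a planted zero-diagonal
Markov chain; duration from a truncated lognormal (default mean 120 ms,
log-sd 0.4, floor 30 ms — strictly positive and right-skewed, in the
50–500 ms range of observed neonatal microstate runs) or a fixed law;
topography = template × half-sine amplitude envelope (so GFP peaks near
segment centers — the structure peak-based clustering needs), optionally ×
a sinusoidal carrier for narrow-band scenarios; segment polarity random;
plus spatially correlated (Toeplitz, lag-1 coefficient 0.3) `1/f^α` noise
(default α = 1, matching the 1/f shape of the neonatal EEG spectrum)
scaled to a stated signal-to-noise RMS ratio.  Noise is re-referenced
before mixing so every sample stays average-referenced.  Default study
scenario: shared templates across states, AS-like mean duration 110 ms vs
QS-like 150 ms, SNR 5, 19-channel 10–20 montage.

What the generator does **not** emulate: biophysical sources (no head
model — templates are random separated maps, not dipolar fields),
artifacts (ECG/EOG/movement), non-stationarity across the recording,
imperfect sleep-state scoring, and overlapping/transitional topographies.
Passing recovery tests therefore establishes correctness of the
*algorithms* under the stated generative assumptions, not performance on
real neonatal EEG.

## Validation experiment sizes

The experiments in `neoms.validation` (used by `scripts/acceptance.py`
and the heavier tests) run on deliberately moderate problem sizes chosen
to give stable statistics on a single CPU: template recovery on
20 subjects × 2 states × 60 s at SNR 5; KL selection over 20 seeded runs;
calibration over 200 null cohorts with 500 randomizations/permutations
each; the sleep-state effect at 30 subjects; duration scaling over the
five bands at 5 subjects per band.  Recovery correlations ≈ 0.9999 and
GEV ≈ 98–99% on these cohorts reflect the generator's clean geometry, not
an expectation for real data.

## Known limitations

* EDF support is minimal: 16-bit quantization, one data record per file on
  write; reading goes through MNE.
* The gamma band's upper edge (45 Hz) coincides with the broad-band edge
  and sits just below the 50 Hz Nyquist of the 100 Hz pipeline rate.
* The "median" frequencies of the five bands are band midpoints
  (2.25, 6, 10.5, 19, 35 Hz), kept for comparability with common usage.
* No temporal smoothing / minimum-duration rejection is applied to label
  sequences beyond the boundary conventions above.
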