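# Methods

This note documents the models, conventions and study conditions behind
ecokit's pipeline and its validation suite. It states only what the tests
and `scripts/acceptance.py` themselves compute.

## Trace preprocessing

Pupil and locomotion signals are uniformly sampled (20 Hz by default).
The pupil chain is: blink removal → Savitzky-Golay smoothing → epoching →
prestimulus normalization → window scoring → 0 μA subtraction. Locomotion
skips blink removal and uses baseline subtraction instead of z-scoring.

**Blink removal.** The absolute first difference of the trace is median
filtered (default 0.25 s, i.e. 5 samples at 20 Hz — the kernel length is a
package choice; it removes single-sample derivative noise while preserving
multi-sample artifact signatures) and min-max normalized per trace. Samples
adjacent to normalized differences exceeding 0.2 (both endpoints of the
offending difference, a conservative choice) are replaced by linear
interpolation between the nearest valid neighbours; edges extrapolate the
nearest valid value. A degenerate derivative track (max = min, e.g. a
linear ramp) yields no flags: a constant-slope trace contains no blinks.
Normalization is per trace, not per trial.

*Known limitation.* Because the threshold is relative to the per-trace
maximum slope, the rule is only idempotent when artifact slopes dominate
the trace: on an artifact-free signal a second pass re-normalizes to the
steepest remaining physiological slope and flags around it. The cleaning
step is therefore applied exactly once, and the idempotence property is
tested on artifact-dominated fixtures.

**Smoothing.** Savitzky-Golay with polynomial order 6 and a 1.5 s window;
the window in samples is `round(window_s × rate)`, incremented to odd
(31 samples at 20 Hz).

**Epoching and scoring.** Epochs run from 1 s before to 4 s after onset;
the onset sample belongs to the post-stimulus segment. Responses are the
mean of the half-open window 1 ≤ t < 2 s (exactly 20 samples at 20 Hz).
Trials excluded upstream (saccades, eye closures, detection failures) are
accepted as an index→reason mapping and logged, so epochs out equal events
in minus explicit exclusions.

**Normalization.** z-scoring uses the prestimulus population standard
deviation; an epoch with zero prestimulus variance is an error, never
silently zeroed. On deterministic synthetic sessions the prestimulus
baseline is exactly constant, so the scale-preserving `subtract_mean` mode
is the well-defined normalization for noiseless calibration studies; the
generator emits amplitudes in z-units, which makes the two modes coincide
up to the (unit) nominal prestimulus scale.

## Synthetic sessions

A session is an ascending-then-descending shock ladder
(0/50/150/300/500 μA, each sweep starting again from 0), repeated so that
every level occurs six times, with 60 s between stimuli. Each stimulus
adds an evoked transient with peak amplitude
`sigmoid(intensity; b=0.05, L=0.9, k=0.02/μA, x0=250 μA)` plus Gaussian
amplitude jitter (`noise_sd`, default 0.05 z-units). The transient has a
0.2 s latency, a 0.5 s smoothstep rise, a flat plateau to 2.9 s and a 2 s
smoothstep decay: the plateau spans the scoring window plus the smoothing
half-width, so the full chain returns the planted amplitude to <0.3%
(a peaked kernel would return a shape-dependent fraction of it, making
"response = sigmoid value" ill-posed). Blink artifacts are 2–5-sample
V-shaped drops (default 5 z-units, 2/min) with a slightly off-center apex
so no adjacent pair of depths ties — a flat-bottomed notch would hide from
the median-filtered derivative track.

What the generator does *not* emulate: slow pupil drift and hippus,
correlated (pink) measurement noise, saccade/eye-closure artifacts, and
response habituation. Passing tests therefore show that the chain and fit
are correct and calibrated for the modelled signal structure, not that
they are robust to every feature of real recordings.

## Psychometric fitting

Responses per animal are min-max scaled to [0, 1] and intensities
max-scaled; the sigmoid `b + L/(1+exp(−k(x−x0)))` is fitted by bounded
nonlinear least squares (trust-region reflective), and `k`, `x0` are
reported back on the μA scale. Initial values: `b = min(y)`,
`L = range(y)`, `x0` at the level nearest half-maximum, `k = 4/range(x)`.
Bounds: `L ∈ [0, 1.5]`, `x0` within the tested range, `k ∈ [0, 1]` per μA,
and `b ∈ [−1, 1]` on the scaled axis — after min-max scaling the lowest
response maps to 0, which lies above the sigmoid's lower asymptote, so the
true scaled baseline is slightly negative and clamping it at 0 biases the
threshold by over 1 μA even on noiseless data. Thresholds are fitted in
normalized intensity space and back-transformed; this convention (rather
than fitting directly in μA) is a documented package choice and is
equivalent up to floating point. Non-convergent fits carry
`converged=False` and are excluded from group statistics with a count.

## Exact small-sample tests

Mann-Whitney and Wilcoxon p-values are computed by tie-aware enumeration
of the full null (rank splits / sign assignments) when the pooled sample
size is ≤ 12, matching the study's 6–7 animals per group; Spearman p is
exact by permutation for n ≤ 8. Above the cutoffs, scipy's tie-corrected
asymptotics are used. Two-sided p = min(1, 2·min(lower tail, upper tail)).
Benjamini-Hochberg adjustment is scipy's step-up implementation.

## c-Fos screens and co-activation

Density = count / region volume. Differential activation is one two-sided
Mann-Whitney test per region at α = 0.05 with *no* multiple-comparison
correction — an exploratory screen at n = 6–7 where correction would cost
most of the power; the exact test's attainable level just below 0.05 is
~0.041 at these sizes, which the null-calibration test accounts for.
Co-activation is the Pearson correlation of regional densities across the
animals of one group; zero-variance regions yield missing (never zero)
correlations, excluded and counted in distribution comparisons. Region
universes are caller-defined; a region blacklist (e.g. hindbrain areas) is
supported but not imposed.

The synthetic c-Fos generator draws per-animal log-densities as Gaussian
(baseline mean log 300 cells/mm³, log-sd 0.4 — lognormal is a modelling
choice for a positive, right-skewed density, not an empirical claim) with
an additive log-fold effect in activated regions. Dyad coupling is one
latent Gaussian factor per dyad loading on every coupled region of both
animals; the loading is analytically compensated
(`r* = ln(1 + r(e^{s²}−1))/s²` on the log scale) so the density-scale
within-dyad Pearson correlation equals the requested value. A dyad-level
factor (rather than one per region) also produces interregional
co-activation among coupled regions, emulating a shared arousal state.
Counts are `round(density × volume)` and the stored density is recomputed
from the rounded count, keeping the table internally consistent.

## Dyad-coupling surrogate test

For the selected regions (those significantly *increased* vs control in
both OBS and DEM), the observed per-region correlation across the 7 true
pairs is compared with 42 surrogate re-pairings drawn without replacement
from the 1854 derangements of 7 items (re-pairings in which no observer
keeps its true demonstrator; "42 shuffles" is interpreted as 42 distinct
pairing-level permutations). The flag threshold is the 95th percentile of
the region's surrogate distribution using Weibull plotting positions —
for 42 values the threshold interpolates between the 40th and 41st order
statistics — and the flag requires strictly greater, positive-direction
only. A pooled-across-regions threshold is available as an option.

**Calibration.** This rule is anticonservative by construction: given the
data, the expected surrogate correlation is ≈ −r_obs/(n_dyads − 1), so
surrogates shift away from a high observed value and the effective null
flag rate at 7 dyads with 42 surrogates is ≈ 9–10%, not 5%. The validation
suite therefore checks the implementation against the rule's *own* nominal
level, estimated at run time by an independent Monte-Carlo oracle (iid
lognormal data, full derangement set, direct numpy computation), rather
than against 5%; with planted coupling r = 0.9 the rule flags the coupled
region in ≈ 95% of simulated studies. Users comparing against a strict 5%
level should prefer more surrogates and a pooled threshold, and should
treat flags as exploratory.

## Network analysis

The connectome is a weighted directed graph over named regions;
self-connections are removed at construction and counted. Community
detection is Leiden on directed modularity (RB-configuration objective,
resolution 1 by default, seed-controlled, run to convergence) via
igraph/leidenalg. HITS scores are the mutually-reinforcing fixed point
(authority ← in-weights from hubs, hub ← out-weights to authorities),
normalized so each score vector sums to 1; the public API uses networkx,
and the bootstrap uses an in-package batched power iteration on induced
adjacency submatrices (same fixed point, tested for agreement and against
an independent oracle) for speed.

**Bootstrap significance.** For each target region, 1000 node sets of the
observed network's size — always containing the target — are sampled from
the region pool; the subgraph is induced from the full edge table, the
target's scores recorded, and `z = (observed − mean)/sd` converted to a
one-tailed upper-tail normal p (two-tailed optional). Zero bootstrap sd is
reported explicitly. An edgeless sampled subnetwork contributes zero
scores (no edges, no hubness). The pool is the full region set, including
other observed-network members.

Because the p-value is a normal tail on a bootstrap z, its calibration
depends on the bootstrap score distribution being approximately normal.
The validation suite's exchangeable null uses a 60-region random graph
with edge probability 0.4 and 20-region subnetworks, where the
approximation holds (KS distance from uniform ≈ 0.04); in very sparse
graphs the score distribution is skewed and the normal-tail p is visibly
non-uniform. Likewise, the planted-hub detection study uses a competitive
background — G(150, 0.25) with lognormal weights, a hub broadcasting to 30
authorities at twice the typical weight, observed network = hub plus 20 of
its authorities — because against a near-empty background the normalized
hub score saturates at 1 in random subnetworks too and the bootstrap
cannot separate a genuine hub from chance. Reported hub/authority
significance on real, sparse connectomes should be read with this in mind.

**Display filtering.** `top_edge_filter` keeps the `ceil(fraction × E)`
largest-weight edges (default 5%), ties broken deterministically by the
graph's edge-iteration order; it is for display only.

## Stimulus frame transforms

Phase scrambling draws a fresh random phase field per frame as the phase
of the FFT of white noise (conjugate-symmetric by construction, so the
output is real), adds it to the frame's phases, and keeps the amplitude
spectrum bit-for-bit; the zero-frequency offset is forced to 0 so mean
luminance is unchanged. Vertical inversion reverses row order and is an
exact involution.

## Validation study sizes

The acceptance studies use: 100 sessions (threshold recovery), one
deterministic session (chain fidelity), exhaustive enumeration for all
rank-test sizes ≤ 5, 1000 null dyad studies of 44 regions plus a
30 000-draw nominal-level oracle, 500 planted-coupling studies, ~50 random
graphs ≤ 8 nodes (HITS oracle), 500 bootstrap calibration replicates at
300 iterations, 100 planted-hub runs at 1000 iterations, and 50 seeds per
Leiden condition. These sizes give sampling error comfortably below each
property's acceptance margin while keeping the whole suite to a few
minutes on one CPU.
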