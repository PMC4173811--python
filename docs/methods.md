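# Methods

This note records the models, the parameter choices that matter, the
numerical decisions, and what the desk-scale validation battery does and
does not establish.

## Phase pipeline

The instantaneous phase of each signal is the angle of its analytic signal
`s + iH[s]`; phases are unwrapped **per signal** and then subtracted.  The
joint arctangent form of the pairwise difference is implemented as a
cross-check (`phase_difference_arctan`) and agrees with the main path
modulo 2π on smooth signals; separate unwrapping avoids stacking 2π
ambiguities when the difference itself is analysed over long records.  The
rate of change is the plain one-sample first difference — DFA is invariant
to the 1/fs scale factor, and any smoothing would colour the very
fluctuations under study.  No edge samples are trimmed by default (long
records dilute the analytic-signal edge artifact); a `trim` option exists.
Constant signals raise an error: their phase is undefined, and in the sweep
drivers such pairs are counted as invalid ("fully synchronized") rather
than crashing the sweep.

The optional bandpass is a forward–backward (zero-phase) 2nd-order
Butterworth, i.e. 4 effective poles per band edge, specified by half-power
corners.  Zero-phase filtering preserves the phase relationships everything
downstream depends on.  With this response, re-filtering already-filtered
white noise still sheds ~10 % RMS near the half-power corners; a mid-band
tone is passed unchanged.  This is the expected behaviour of the chosen
order, not an artifact.

## DFA

Order of operations: global mean removal, cumulative summation, per-window
linear detrending (the standard formulation the exponent tables in the
literature assume).  Windows are non-overlapping, start at the first
sample, and a trailing partial window is discarded.  Window sizes: 20
log-spaced integers from the minimum (8 samples for simulated series; 1 s
of samples for physiological ones; 600 samples for the cosine surrogates,
matching their nominal rate) up to N/10; duplicates after rounding are
dropped.  Logs are base 10 throughout; the slope is base-invariant.

## ML-DFA

The fluctuation plot is judged by model selection, not by r² of a line.
log-fluctuations are min–max scaled to y ∈ [0, 100] (the scaled vector
always attains 0 and 100).  Thirteen candidate families are fitted —
polynomial degree 1–5 (2–6 parameters), root `a1(x+a2)^(1/K)+a3` for
K = 2, 3, 4, logarithmic `a1 log(x+a2)+a3`, exponential `a1 e^(a2 x)+a3`
(3 parameters each), and continuous piecewise-linear splines with M = 2, 3,
4 segments parameterized as intercept + M slopes + M−1 ordered interior
breakpoints (4/6/8 parameters, minimum breakpoint separation of one
inter-point gap).  Each fit maximizes the pseudo-log-likelihood

    L = Σᵢ yᵢ log pᵢ,   pᵢ = |f(xᵢ)| / Σⱼ |f(xⱼ)|,

which weights small windows more than the (least robust) large-window
points.  A fit whose f is negative at any design point is infeasible, as is
a model whose optimizer never leaves the penalty region.  Fits are compared
by the small-sample-corrected AICc = −2L + 2k + 2k(k+1)/(n−k−1) (n ≈ 20
plot points makes the correction material).  The exponent is **valid** iff
the straight line attains the strict minimum AICc; an exact tie with a
non-linear model is conservatively judged invalid.  The exponent itself is
always the OLS slope of the unscaled log–log plot.

Optimization is a seeded multi-start Nelder–Mead compiled with numba
(10 starts per model by default; polynomial starts from OLS, root/log/exp
from OLS on the transformed regressor over a shift grid, splines from
per-segment OLS).  Stopping: relative simplex spread < 1e-8, an iteration
cap of 5000, a stall cutoff (best value improving < 0.02 nats per 20
iterations) that truncates the slow crawl along near-degenerate valleys
(e.g. a root curve with a growing shift mimicking a straight line — the
shift is also bounded so the curve stays distinguishable from a line over
the plot's x-range), and pruning of starts stranded > 100 nats above the
best optimum found.  These cutoffs are orders of magnitude below the ≈1.1
nat log-likelihood margin at which an AICc comparison between a 2- and a
3-parameter model can flip, and verdicts were observed to be identical for
8–40 starts over a varied plot corpus.  The budget matters because the
model sweeps run this selection tens of thousands of times.

Verdict sensitivity: for fluctuation plots with *mild* genuine curvature
(oscillator pairs near the synchronization transition) the linear-vs-curved
decision rides on a few nats of AICc margin.  A weaker optimizer — e.g. a
single-start simplex with loose tolerances — under-fits the curved
alternatives and therefore accepts more plots as linear, with somewhat
higher mean exponents among the accepted plots.  This implementation
optimizes all candidates well and is accordingly conservative; comparisons
with validity percentages produced by other ML-DFA implementations should
keep this in mind.

## FARIMA surrogates

FARIMA(0, d, 0) is fractional Gaussian noise with H = d + 1/2.  The
fractional core is sampled exactly from its autocovariance
γ(0) = Γ(1−2d)/Γ(1−d)², γ(k) = γ(k−1)(k−1+d)/(k−d), by circulant embedding
(Davies–Harte; O(n log n)); a Durbin–Levinson recursion on the same
autocovariances is provided (`method="hosking"`) and used in tests as an
independent small-n cross-check — the two generators match in variance and
lag-1 autocorrelation.  AR(1)/MA(1) parts are applied as filters after
fractional integration; |d| < 1/2, |φ| < 1, |θ| < 1 are enforced.  The top
of the recovery grid, H = 1.0, sits exactly on the open boundary d = 1/2
where γ(0) diverges; it is generated at d = 0.4999.

Surrogate pairs are `x1 = cos(ωt + Σ X/2fs)`, `x2 = cos(ωt − Σ X/2fs)` with
ω = 1 rad/sample and nominal fs = 600, so the unwrapped phase difference is
exactly `Σ X/fs` and its rate of change is X/fs.  The carrier keeps each
signal oscillatory — without it the analytic phase cannot track the slow
phase drift at all.  The carrier leaves a high-frequency ripple in the
one-sample rate (raw correlation with X ≈ 0.87 at d = 0.3) that averages
out within a few samples and is invisible to DFA at the ≥600-sample
windows used for surrogates.  Additive Gaussian amplitude noise is applied
to x1 only, before phase extraction.  Recovery slope over H = 0.50…1.00 is
computed from per-H means of the ML-DFA-valid exponents.

## Ising model

Random-site Metropolis on an L×L periodic lattice (J = k = 1): one sweep is
L² single-site proposals at uniformly random sites, acceptance
min(1, e^(−ΔH/T)); one block-mean sample per sweep is recorded after a
2,000-sweep burn-in; spins start aligned or random (`init`).  Deterministic
full-lattice passes (checkerboard/typewriter) are deliberately avoided: at
high temperature their acceptance approaches 1, every spin flips every
pass, and the recorded series acquire a spurious period-2 alternation
(lag-1 autocorrelation −1).  Sub-lattice series are 8×8 block means, run
through the full pipeline including the Hilbert step, with minimum DFA
window 8.

The high-temperature exponent asymptote depends on the per-sample
correlation of the block series and hence on the (nowhere standardized)
number of proposals per recorded innovation: with the canonical L² the
lag-1 correlation is e⁻² ≈ 0.135 and the mean valid exponent at T = 10⁵
measures ≈ 0.52; halving or quartering the recording interval raises it to
≈ 0.54/0.56.  The canonical convention is used.

## Kuramoto model

200 oscillators, natural frequencies drawn once per seed from
N(2π·22 Hz, σω = 15 rad/s) (Kc = 2σω√(2/π) ≈ 23.94), noise SD 0.32 rad
with per-step increments of SD σ√dt (continuous covariance σ²/T, T = 1 s),
Euler–Maruyama at dt = 1 ms for 6,100 steps.  The pair interaction is
evaluated through the exact mean-field identity
Σⱼ sin(φⱼ−φᵢ) = N·r·sin(ψ−φᵢ), making each step O(N); results are
dt-converged (identical mean r at dt = 10⁻⁴).  Oscillator phases are used
directly (no Hilbert step); the first 10 % of steps are discarded before
pairwise analysis and the mean order parameter.  Sweeps analyse a seeded
random pair subset (default 2,000 per coupling, split across seeds when
pooling) and Δ(Kr) is the first difference of K·r̄ along the sorted grid,
aligned to the right endpoint.

Note that a single 200-draw frequency sample realizes a spread σ̂ that can
deviate from 15 by ±10 %, and the finite-size synchronization flux peaks
near the *realized* 2σ̂√(2/π) rather than the nominal Kc; pooled sweeps
average over draws.

## Delayed network model

66 oscillators on a row-normalized weight matrix C (zero diagonal; rows
with any connection sum to 1) with per-edge delays D = 〈D〉·L/〈L〉, where
〈L〉 averages the nonzero off-diagonal distances of connected pairs and
〈D〉 = 11 integration steps by default; delays are rounded to whole steps
(0 = instantaneous).  Natural frequencies N(2π·60 Hz, 5 rad/s), noise SD
1.25 rad, dt = 1 ms, 10⁵ steps by default (the longer original runs are a
flag away), K/N prefactor with N = 66.  History before t = 0 is backfilled
by rotating the random initial phases backwards at each oscillator's
natural frequency; the first 10 % of recorded steps are discarded.
Normalization happens once on input; hemisphere disconnection and
randomization deliberately do **not** renormalize, preserving all surviving
elements exactly.

Randomization is outgoing-stub matching: each directed edge contributes an
(origin, weight) stub; random stub pairs from distinct, not-yet-connected
nodes become reciprocal edges carrying their own origins' weights.  This
preserves each node's out-degree and outgoing-weight multiset exactly;
dead ends restart the pass, and exhausting the restart budget raises an
error rather than returning a near-miss.

The synthetic connectome stands in for the empirical 66-region matrices
(which users can supply as CSV): two mirrored 33-node hemispheres, planted
clusters of sizes 11/5/8/14/5/11 plus 12 unclustered nodes laid out on the
empirical index ranges, the central 14-node cluster given the heaviest
weights and strong homologous cross-hemisphere links, distances from
mirrored random 3-D coordinates.  Cluster weight/degree summaries
(`cluster_summary`) are computed on the raw pre-normalization weights,
where "weight per node" is informative (after row normalization every
connected row sums to 1 by construction).  The generator reproduces the
qualitative structure that matters to the disruption experiments — a
dominant trans-hemispheric central cluster — not the empirical weight
values.

## Desk-scale battery: sizes and what it shows

Tests and the acceptance script run scaled-down versions of the original
experiments, sized to a single core: surrogate recovery at n = 2¹⁸ with 10
repetitions per exponent (not n = 2²² × 100), Ising at 48×48 × 16,000
sweeps (not 96×96 × 64,000), Kuramoto sweeps pooling 2,000 pairs per
coupling over 5 seeds (not all 19,900 pairs), network runs at 10⁵ steps.
Passing at this scale demonstrates that the pipeline recovers engineered
exponents, that validity collapses under full synchronization, and that
exponents rise near the critical regimes of the test models; it does not
certify exponent values on real neurophysiological data, where filtering
choices, nonstationarity and artifacts add variance the battery does not
emulate.  Known desk-scale deviations (documented honestly rather than
tuned away): the surrogate recovery slope measures ≈ 0.98–0.99 at n = 2¹⁸
(the shorter series underestimate high exponents slightly more than the
full-length experiment would); the Ising high-T asymptote measures ≈ 0.52
against the literature value 0.57 (sampling-interval-dependent, see
above); and near the Kuramoto transition this implementation's stricter
ML-DFA accepts fewer slip-curved plots than weaker optimizers would,
lowering the peak mean exponent (≈ 0.58–0.59) and the validity percentage
at the peak.  The synthetic connectome reproduces the qualitative hub
structure but not the empirical weight concentration, and its
clustered-vs-randomized exponent contrast at the synchronization-flux peak
is within noise at these run lengths.
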