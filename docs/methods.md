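# Methods

## The measure

For two simultaneously recorded signals X and Y, transfer entropy (TE)
quantifies how much the past of X improves prediction of Y's next value
beyond Y's own past.  `phasete` computes TE on the *instantaneous phase* of
one frequency band: signals are band-pass filtered (zero-phase FIR), the
analytic-signal angle is taken as the phase series θ (wrapped to [−π, π)),
and

    TEθ(X→Y) = H(θ^y_past, θ^x_past) − H(θ^y_now, θ^y_past, θ^x_past)
             + H(θ^y_now, θ^y_past) − H(θ^y_past)        [nats]

where θ^x_past is the delay embedding of the source phase at interaction lag
u (samples) and θ^y_past the target's own past anchored one sample back.
Trial-based recordings are handled with the *ensemble* approach: delay
vectors from all repetition trials are pooled before any counting, neighbor
search or kernel evaluation, and embedding windows never straddle trial
boundaries.  This accommodates nonstationary single trials at the cost of
assuming trials are exchangeable realizations of one condition.

All estimators are biased, so the directional statistic is the differential
TE, dTE = TE(X→Y) − TE(Y→X), each direction maximized over a lag grid
(`δ̂ = argmax_u TE(u)`).  Positive dTE means net information flow X→Y.

### Estimator backends

* **bin** — plug-in Shannon entropies on equal-width circular histograms.
  One bin width for every coordinate of every marginal space, from Scott's
  rule `h = 3.5 σ / N^(1/3)` with σ the Fisher circular standard deviation
  `sqrt(−2 ln R̄)` of the pooled target phase; bins anchored at −π.
  Embedding dimension fixed at 1.  The plug-in form makes the estimate a
  finite-sample conditional mutual information, hence exactly ≥ 0.
* **ksg** — Kraskov algorithm 1: ε_i is the k-th nearest-neighbor distance
  in the joint space (k = 4), marginal "strip" counts use strictly-less
  comparisons, and the digamma correction ψ(k) + ⟨ψ(n+1)···⟩ is averaged
  over points.  All distances are max-norm with the wrapped per-coordinate
  angular difference; neighbor queries run on periodic (toroidal) k-d trees.
  Embedding (d, τ) per variable from the Ragwitz–Kantz criterion: the
  candidate minimizing the leave-one-out locally-constant one-step
  prediction error (circular mean of the 4 nearest neighbors' successors,
  mean squared wrapped difference), grids d, τ ∈ {1..5}, ties to the
  smallest (d, τ).
* **sym** — permutation TE: embedded windows are mapped to ordinal patterns
  (stable argsort; ties broken by order of occurrence) and the TE is the
  plug-in estimate on symbol triples (ŷ_t, ŷ_{t−1}, x̂_{t−u}).  Exactly
  invariant under monotone transforms.  (d, τ) from the C–C method: τ at
  the first interior local minimum of the averaged correlation-integral
  statistic ΔS̄(τ) (flat curves default to τ = 1), embedding window from
  the S_cor minimum; the same (d, τ) is used for both channels so the two
  symbol alphabets coincide.
* **kalpha** — matrix-based Rényi α-entropy (α = 3): Gaussian Gram matrices
  with median-distance bandwidth, joint entropies via normalized Hadamard
  products, `H_α = ln tr(M^α) / (1−α)`.  Angles enter through the chordal
  map θ ↦ (cos θ, sin θ) so the kernel respects periodicity.  For integer α
  the trace power is computed by matrix products; the eigen-decomposition
  path is kept and cross-checked in tests.  Each H_α lies in [0, ln N].

### Significance testing

The null is built from trial-shuffle surrogates: the assignment of source
trials to target trials is permuted (never the identity), preserving every
trial's internal dynamics.  Because the observed statistic is a maximum over
lags, each surrogate re-runs the complete lag scan in both directions.  The
two-sided rank p-value includes the observed value, p = (1 + #{|dte_surr| ≥
|dte_obs|}) / (1 + n_surr), making the test exact under exchangeability.
The smallest attainable p is 1/(n_surr+1); when a requested level α is
below that floor (reduced surrogate counts), the decision threshold is the
floor itself — the reduced-scale analogue of "observed beyond all 200
surrogates at the 1% level".  Repeated estimations are aggregated with a
one-sided binomial tail test at the per-test level.

A consequence worth stating plainly: when source and target ensembles are
truly independent, the trial-shuffle test is an exact permutation test, so
no estimator's false positive rate can exceed the nominal level by more
than sampling noise — *regardless of sample size or estimator bias*.
Reported FPR inflation under clean conditions at large sample counts can
only arise from a non-exchangeable surrogate scheme (e.g. within-trial
sample shuffling), which this package deliberately does not use.

## The simulator

Each region is a Jansen–Rit neural mass: three populations (pyramidal,
excitatory, inhibitory interneurons), second-order synaptic kinetics,
sigmoidal rate function S(v) = 2e₀ / (1 + exp(r(v₀ − v))).  The classical
parameter set is time-rescaled by ×4.2 — rate constants a = 420 s⁻¹,
b = 210 s⁻¹ *and* synaptic gains He = 13.65 mV, Hi = 92.4 mV scaled
together, which is an exact rescaling of the dynamics — so the autonomous
rhythm sits in the beta band (measured Welch peak ≈ 26 Hz; ≈ 70 % of output
power in 15–35 Hz).  Remaining constants are the standard ones (C = 135
with C1 = C, C2 = 0.8C, C3 = C4 = 0.25C; e₀ = 2.5 s⁻¹, v₀ = 6 mV,
r = 0.56 mV⁻¹).

Directed interaction: the presynaptic pyramidal spike density Z_X(t),
delayed by δ and scaled by the coupling weight ω ∈ [0, 70], enters the
postsynaptic input rate as g·ω·Z_X(t−δ) on top of the Gaussian input noise
(mean 220, s.d. 100 pulses/s per step).  The weight-to-gain constant
g = 0.3 is the single calibration constant of the benchmark: it was fixed
once so that the binning estimator's coupling detection threshold at the
reference conditions (clean, δ = 20 ms, 100-pair sets) sits near 17.5, and
is not adjusted per experiment.

Integration is fixed-step Euler at 2000 Hz with per-pair noise streams
spawned from the master seed (pair i is reproducible independent of batch
size), 1 s discarded burn-in, output anti-alias-decimated to 100 Hz.  At
100 Hz, 2 s trials give 200 samples and lags of 10–70 ms are 1–7 samples.
The analysis band for simulated pairs is 15–35 Hz with a fixed order-15
FIR; LFP bands use the order rule 3·⌊fs/f_low⌋.

Corruption: measurement noise is white Gaussian per trial at a prescribed
SNR in dB; linear mixing is the symmetric instantaneous form
x' = (1−m)x + my, y' = (1−m)y + mx, m ∈ [0, 0.5].  Mixing (volume
conduction between sources) is applied first, then sensor noise.  The order
matters: with noise first, m = 0.5 collapses both channels onto one
identical signal and every asymmetry measure is identically zero; with
sensor noise last the m = 0.5 condition remains informative, though the
channels are still so strongly shared that the direction of dTE is close to
random and surrogate tests reject far above nominal — the qualitative
volume-conduction failure mode, with the symbolic estimator worst affected.

## The synthetic LFP generator

`generate_synthetic_lfp` emulates a trial-based two-region recording
session: 2000 Hz, ~30 repeated 7 s epochs, theta/beta/gamma narrow-band
components on a pink (1/f above 4 Hz, flat below) background, plus a
directed coupling imposed in one band — the receiver's band component is a
lag-shifted, strength-weighted copy of the driver's plus independent
narrow-band noise, optionally confined to a time window within the epoch.
Designated trial fractions carry box-car movement artifacts or a dominant
0.5–4 Hz component.  What it does *not* emulate: multi-channel electrode
geometry (one channel per region — the pipeline's "pairs" are therefore
trial subsets, drawn without replacement; duplicated trials would place
identical aligned pairs in the observed set and invalidate the
trial-shuffle null), cross-frequency coupling, nonstationary rhythms, or
behaviorally locked dynamics.  Passing pipeline tests therefore demonstrate
parameter recovery (direction, band, time bin, lag) under a known,
idealized ground truth, not performance on real recordings.

## Benchmark design and problem sizes

One "estimation" is the full pipeline on a set of trials: lag scan 10–70 ms
in both directions, surrogate null, two-sided decision at the effective
level.  Sensitivity counts only *correctly signed* significant results; the
coupling detection threshold (CDT) is the first upward 0.8-crossing of the
sensitivity curve by linear interpolation (flagged "not reached"
otherwise); lag accuracy is the fraction of estimations whose argmax lag
equals the true lag exactly on the grid.

The full design (200 sets × 20 repeats × 200 surrogates from 1000-pair
pools) is available but not the default anywhere; the package's own
reduced scale divides set/repeat/surrogate counts by 4 (50/5/50) and draws
from 300-pair pools, which keeps a full sweep on one desk CPU.  Two
further desk-scale caps apply to the expensive backends and are reported
with every run: the KSG backend pools at most 1200 embedded points and
halves the surrogate count; the kernel backend pools at most 300 points
(its Gram-matrix cost is cubic; a hard guard refuses N > 6000).  The caps
leave permutation-test validity (FPR calibration) untouched — they raise
the variance of the TE estimates, so CDT statements for these two backends
are specific to the capped scale.

## Numerical choices and degenerate inputs

* Logarithms are natural throughout (nats); the digamma form of the KSG
  estimator is natural-log native.
* Zero-phase filtering applies the Hamming windowed-sinc FIR forward and
  backward with even (reflecting) padding of 3×order samples.
* Phase convention: angle of the analytic signal wrapped to [−π, π); all
  circular distances are the wrapped difference min(|Δ|, 2π − |Δ|).
* Lag scans break ties toward the smallest lag; embedding selections break
  ties toward the smallest (d, τ).
* TE evaluations within one scan/surrogate run share a fixed valid time
  range t₀ = max(1 + target history, u_max + source history), so every lag
  and every surrogate uses the same pooled point count.
* Degenerate inputs raise typed errors: antipodal phase sets (undefined
  circular dispersion), zero-dispersion bins, all-tied symbol windows are
  handled by the stable-sort tie rule, duplicate KSG points by
  strictly-less strip counts, rank-deficient Gram matrices by eigenvalue
  clipping at 0.
* The binning backend accepts a fixed `n_bins` override for distributions
  where Scott's rule is undefined (two-point phase alphabets).

## Known limitations

* The symbolic backend's lag scan oscillates with the oscillation period
  (spurious secondary peaks at δ ± one period), but with the C–C-selected
  embedding its modal argmax still lands on the true lag in our
  simulations; estimator-specific systematic lag displacements reported
  elsewhere depend on symbolization conventions that published descriptions
  under-determine.
* Under clean independence the trial-shuffle null is exact, so
  sample-size-driven FPR inflation of any backend cannot occur here (see
  above); claims of such inflation are tied to other surrogate schemes.
* At m = 0.5 mixing with 20 dB sensor noise the two channels share ≈ 99 %
  of their variance; directional claims in that regime are unreliable for
  every backend, and measured FPR inflation is severe rather than moderate.
* The neural-mass parameterization is a documented constant of this
  package, not a fit to any reference implementation; only its spectral
  band and the calibrated weight-to-gain mapping are load-bearing.
* Morlet-wavelet phase extraction, multivariate/conditional TE, and
  amplitude TE are out of scope.
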