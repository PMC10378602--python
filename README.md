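# phasete

Ensemble **phase transfer entropy** (TEθ) for detecting directed
interactions between trial-based neural signals, with four interchangeable
estimator backends, surrogate significance testing with interaction-lag
scanning, a coupled neural-mass simulator for ground-truth benchmarking,
and a trial-based LFP analysis pipeline.

## Who this is for

Electrophysiologists and methods researchers who record two brain regions
simultaneously across repeated trials (LFP/EEG-type signals) and want to
ask: *does the phase of band-limited activity in region X predict region Y
beyond Y's own history — in which direction, at which lag, and is it
significant?*  Single trials of such data are short and nonstationary; the
ensemble approach pools delay-embedded phase samples across trials to
estimate one transfer-entropy value per condition.

## The measure

With θ^x, θ^y the instantaneous phases (band-pass filter + Hilbert
transform) of the two signals,

    TEθ(X→Y, f) = H(θ^y_past, θ^x_past) − H(θ^y_now, θ^y_past, θ^x_past)
                + H(θ^y_now, θ^y_past) − H(θ^y_past)        [nats]

where θ^x_past is delay-embedded at interaction lag u and probabilities are
estimated from samples pooled over all trials.  The directional statistic
is the differential TE, `dTE = max_u TE(X→Y, u) − max_u TE(Y→X, u)`;
its significance is assessed against trial-shuffle surrogates (the trial
pairing is permuted, within-trial dynamics preserved), and the lag estimate
is `δ̂ = argmax_u TE(u)`.

Four estimator backends share this interface and differ in how they
estimate the entropies: `bin` (circular histograms, Scott/Fisher bin
width), `ksg` (Kraskov k-nearest-neighbor with circular max-norm), `sym`
(ordinal-pattern/permutation symbols), `kalpha` (matrix-based Rényi
α-order entropy on Gaussian Gram matrices, α = 3).  See
`docs/methods.md` for the full model description and numerical choices.

## Worked example

Simulate 100 coupled signal pairs (neural-mass model, coupling weight 40
from X to Y at a 20 ms lag), then test for directed coupling in the beta
band:

```python
from phasete import (NMMConfig, simulate_batch, extract_phase,
                     significance_test)

x, y = simulate_batch(NMMConfig(w_xy=40, delta_ms=20, seed=7), 100)
px = extract_phase(x, (15, 35), order=15)
py = extract_phase(y, (15, 35), order=15)
res = significance_test("bin", px, py, u_grid_ms=[10, 20, 30, 40, 50, 60, 70],
                        n_surr=200, alpha_sig=0.01, seed=1)
print(f"dTE = {res.dte_obs:+.4f} nats, p = {res.p_value:.4f}, "
      f"lag = {res.delta_hat_xy_ms:.0f} ms")
```

```
dTE = +0.0291 nats, p = 0.0050, lag = 10 ms
```

The positive differential TE says information flows preferentially X→Y;
p = 1/201 means the observed value exceeded all 200 trial-shuffle
surrogates, significant at the 1 % level.  The lag scan here reads 10 ms,
one grid step below the simulated 20 ms: the TE-versus-lag profile of
narrowband phase is nearly flat for lags up to the true delay (phase
evolves almost deterministically over one sample), so single-set lag
estimates can land one step early — the benchmark therefore reports the
modal lag over repeated sets, which recovers 20 ms.

The same objects drive the command line:

```sh
phasete simulate --w-xy 40 --delta-ms 20 --n-pairs 100 --seed 7 --out pairs.h5
phasete estimate --method bin --x pairs.h5 --y pairs.h5 --band 15,35 \
                 --surrogates 200 --seed 1 --out result.json
phasete benchmark --suite accuracy --scale reduced --seed 0 --out metrics.csv
```

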