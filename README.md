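# phasecrit

Detecting signatures of critical dynamics in the **fluctuations of
phase synchronization** between two oscillatory time series.

Neural synchrony is weak and fluctuates from moment to moment.  Rather than
averaging those fluctuations away (as coherence-style measures do), this
package asks whether they carry **long-range temporal correlations (LRTCs)**
— the power-law autocorrelation structure expected of systems operating near
a critical regime.  It is aimed at researchers analysing paired
EEG/MEG/EMG-like recordings or oscillator-model output.

## Method

For two uniformly sampled signals `s1(t)`, `s2(t)`:

1. (optional) zero-phase bandpass to the band of interest;
2. instantaneous phases `φ1, φ2` via the analytic signal `s + iH[s]`
   (Hilbert transform), unwrapped;
3. the **rate of change of the phase difference**,
   `Δ(t) = d/dt [φ1(t) − φ2(t)]` (one-sample first difference) — a bounded
   series whose temporal structure tracks how synchronization reorganizes;
4. **DFA**: mean-centre, cumulatively sum, split into `n`-sample windows,
   linearly detrend each, pool the RMS residual `F(n)`; the exponent `H` is
   the slope of `log10 F(n)` vs `log10 n` over 20 log-spaced window sizes
   (minimum 8 samples for model data, 1 s for physiological ones, maximum
   N/10).  `H ≈ 0.5` is memoryless, `0.5 < H < 1` indicates LRTCs,
   `H = 1.5` is Brownian;
5. **ML-DFA validation**: the fluctuation plot (scaled to [0, 100]) is
   fitted by 13 candidate curve families (polynomials of degree 1–5, K-th
   roots K = 2–4, logarithmic, exponential, 2/3/4-segment linear splines) by
   maximizing the pseudo-log-likelihood `Σᵢ yᵢ log pᵢ`,
   `pᵢ = |f(xᵢ)|/Σⱼ|f(xⱼ)|`, and compared with the small-sample-corrected
   Akaike criterion (AICc).  The exponent is reported **only when the
   straight line wins**; otherwise the plot has crossovers or curvature and
   no scaling exponent is claimed.

The package ships the validation battery alongside the pipeline: FARIMA
surrogate pairs with a known phase-difference exponent, the 2-D Ising model
(sub-lattice block-mean series), the noisy mean-field Kuramoto model
(`Kc = 2σω√(2/π)`), and a delayed 66-node connectome-network Kuramoto
variant with hemisphere-disconnection and degree/weight-preserving
randomization experiments plus a synthetic-connectome generator.

## Worked example

```python
import numpy as np
from phasecrit import (FarimaSpec, SurrogatePairSpec, surrogate_pair,
                       AnalysisConfig, analyze_pair)

# a cosine pair engineered so the rate of change of its phase difference
# is FARIMA(0, 0.25, 0), i.e. true exponent H = 0.75
spec = SurrogatePairSpec(farima=FarimaSpec(d=0.25, n=2**17, seed=21))
s1, s2, _ = surrogate_pair(spec)

result = analyze_pair(s1, s2, AnalysisConfig(min_window=600, seed=1))
print(result.valid, round(result.exponent, 3))
```

prints

```
True 0.797
```

— the fluctuation plot was judged linear by ML-DFA and the recovered
exponent 0.797 sits within a few percent of the engineered 0.75 (single
realizations scatter around the true exponent; averaged over repetitions the
recovery is slightly conservative, which guards against false LRTC claims).
Running a
coupling sweep of the noisy Kuramoto model,

```bash
phasecrit sweep-kuramoto --couplings 0,15,22,30 --pairs 400 --seed 1 \
    --out sweep.csv
```

```
K=0: mean H=0.505 validity=99.0% r=0.072
K=15: mean H=0.583 validity=42.5% r=0.135
K=22: mean H=0.524 validity=17.0% r=0.412
K=30: mean H=0.471 validity=14.0% r=0.814
```

shows the signature the method is built to detect: near-random phase
fluctuations (H ≈ 0.5, ~100 % valid plots) when uncoupled, rising exponents
as the synchronization transition is approached, and collapsing validity as
pairs fully synchronize and their phase-difference fluctuations vanish.

A CLI covers every experiment: `phasecrit analyze-pair | surrogate-validate
| sweep-ising | sweep-kuramoto | sweep-network | fixtures` (all seeded and
bit-reproducible; outputs are CSV plus a JSON sidecar).

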