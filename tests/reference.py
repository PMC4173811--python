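"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: plain loops, one
window at a time, np.polyfit for every fit.  Slow but unambiguous.
"""

import numpy as np


def dfa_reference(x, window_sizes):
    """Naive DFA: F(n) per window size by per-window polyfit detrending."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - x.mean())
    fluctuations = []
    for n in window_sizes:
        n = int(n)
        n_boxes = len(profile) // n
        sq = []
        for b in range(n_boxes):
            seg = profile[b * n : (b + 1) * n]
            t = np.arange(n, dtype=float)
            coeffs = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coeffs, t)
            sq.extend(resid**2)
        fluctuations.append(np.sqrt(np.mean(sq)))
    return np.asarray(fluctuations)


def linear_pseudo_loglik_grid(x, y, a1_range, a2_range, n_grid=201):
    """Coarse grid search of the linear-model pseudo-log-likelihood.

    Maximizes sum_i y_i*log(|a1 + a2*x_i| / sum_j |a1 + a2*x_j|) over an
    (intercept, slope) grid; independent check of the package optimizer.
    """
    best = -np.inf
    for a1 in np.linspace(*a1_range, n_grid):
        for a2 in np.linspace(*a2_range, n_grid):
            f = np.abs(a1 + a2 * x)
            total = f.sum()
            if total <= 0 or np.any((f == 0) & (y > 0)):
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.sum(np.where(y > 0, y * np.log(f), 0.0)) - y.sum() * np.log(
                    total
                )
            if ll > best:
                best = ll
    return best
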