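"""Detrended fluctuation analysis and ML-DFA linearity validation.

DFA estimates a self-similarity exponent H from the scaling of detrended
fluctuations: the series is mean-centred, cumulatively summed, split into
non-overlapping windows of size n, linearly detrended per window, and the
pooled RMS residual F(n) is regressed against n in log10–log10 space.  The
slope is the DFA exponent: 0.5 for white noise, (0.5, 1) for long-range
temporal correlations, 1.5 for Brownian noise.

An exponent is only meaningful when the fluctuation plot actually is a
straight line.  ML-DFA decides this by model selection: the plot (scaled to
[0, 100]) is fitted by 13 candidate curve families — polynomials of degree
1–5, K-th roots for K = 2–4, logarithmic, exponential, and continuous
piecewise-linear splines with 2–4 segments — each by maximizing the
pseudo-log-likelihood

    L(a) = sum_i y_i * log p_i,    p_i = |f(x_i)| / sum_j |f(x_j)|,

and the fits are compared with the small-sample-corrected Akaike criterion
AICc = -2 L + 2k + 2k(k+1)/(n-k-1).  The DFA exponent is accepted as valid
only when the straight line attains the strict minimum AICc.  The log in L
naturally down-weights the large windows, whose F(n) estimates rest on the
fewest boxes.

The candidate fits run inside a numba-compiled multi-start Nelder–Mead so
that the validation step stays cheap enough to apply to tens of thousands
of signal pairs in the model sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import DegeneratePlotError, ParameterError, SeriesTooShortError
from .phase import RateSeries

__all__ = [
    "WindowScheme",
    "FluctuationPlot",
    "CandidateModel",
    "ModelFit",
    "MLDFAResult",
    "CANDIDATE_MODELS",
    "make_windows",
    "dfa_profile",
    "dfa_fluctuations",
    "dfa_exponent",
    "dfa",
    "mldfa_validate",
]

DEFAULT_N_WINDOWS = 20
DEFAULT_MIN_WINDOW = 8  # samples; simulated data convention


# --------------------------------------------------------------------------
# Window scheme and fluctuation plot
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowScheme:
    """Logarithmically spaced integer window sizes for DFA."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.sizes, dtype=np.int64)
        if arr.size < 3:
            raise ParameterError("window scheme needs at least 3 sizes")
        if np.any(np.diff(arr) <= 0):
            raise ParameterError("window sizes must be strictly increasing")
        if arr[0] < 4:
            raise ParameterError("minimum window must be at least 4 samples")
        object.__setattr__(self, "sizes", arr)

    def __len__(self) -> int:
        return self.sizes.size

    @property
    def min_window(self) -> int:
        return int(self.sizes[0])

    @property
    def max_window(self) -> int:
        return int(self.sizes[-1])


@dataclass(frozen=True)
class FluctuationPlot:
    """Paired (window size, RMS fluctuation) values on which ML-DFA rules."""

    window_sizes: np.ndarray
    fluctuations: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.window_sizes, dtype=np.int64)
        fl = np.asarray(self.fluctuations, dtype=float)
        if sizes.size != fl.size:
            raise ParameterError("window_sizes and fluctuations differ in length")
        object.__setattr__(self, "window_sizes", sizes)
        object.__setattr__(self, "fluctuations", fl)

    def __len__(self) -> int:
        return self.window_sizes.size

    @property
    def degenerate(self) -> bool:
        """True when any fluctuation is zero (no log–log plot exists)."""
        return bool(np.any(self.fluctuations <= 0.0))

    @property
    def log_sizes(self) -> np.ndarray:
        return np.log10(self.window_sizes.astype(float))

    @property
    def log_fluctuations(self) -> np.ndarray:
        return np.log10(self.fluctuations)


def make_windows(
    n_samples: int,
    min_window: int = DEFAULT_MIN_WINDOW,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> WindowScheme:
    """Log-spaced integer window sizes from ``min_window`` to N/10.

    Duplicate sizes after integer rounding are dropped, so the scheme may
    hold fewer than ``n_windows`` entries.
    """
    if min_window < 4:
        raise ParameterError("min_window must be at least 4 samples")
    max_window = n_samples // 10
    if max_window < min_window:
        raise SeriesTooShortError(
            f"series of {n_samples} samples supports a maximum window of "
            f"{max_window} < requested minimum {min_window}"
        )
    raw = np.logspace(np.log10(min_window), np.log10(max_window), n_windows)
    sizes = np.unique(np.round(raw).astype(np.int64))
    return WindowScheme(sizes=sizes)


# --------------------------------------------------------------------------
# DFA proper
# --------------------------------------------------------------------------


def _series_values(x) -> np.ndarray:
    if isinstance(x, RateSeries):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ParameterError("expected a one-dimensional series")
    return arr


def dfa_profile(x) -> np.ndarray:
    """Cumulative sum of the mean-centred series (the DFA 'profile')."""
    values = _series_values(x)
    if values.size < 2:
        raise ParameterError("series must hold at least 2 samples")
    return np.cumsum(values - values.mean())


def _rms_fluctuation(profile: np.ndarray, n: int) -> float:
    """Pooled RMS residual after per-window linear detrending at size n."""
    m = profile.size // n
    y = profile[: m * n].reshape(m, n)
    t = np.arange(n, dtype=float)
    t -= t.mean()
    denom = float(np.dot(t, t))
    y_mean = y.mean(axis=1, keepdims=True)
    slope = (y @ t) / denom
    resid = y - y_mean - slope[:, None] * t
    return float(np.sqrt(np.mean(resid * resid)))


def dfa_fluctuations(x, scheme: WindowScheme) -> FluctuationPlot:
    """Fluctuation plot: F(n) for every window size of the scheme.

    Windows are non-overlapping, start at the first sample, and a trailing
    partial window is discarded.
    """
    values = _series_values(x)
    if scheme.max_window > values.size:
        raise SeriesTooShortError(
            f"max window {scheme.max_window} exceeds series length {values.size}"
        )
    profile = np.cumsum(values - values.mean())
    flucts = np.array([_rms_fluctuation(profile, int(n)) for n in scheme.sizes])
    return FluctuationPlot(window_sizes=scheme.sizes.copy(), fluctuations=flucts)


def dfa_exponent(plot: FluctuationPlot) -> float:
    """OLS slope of log10 F versus log10 n over all scheme sizes."""
    if len(plot) < 3:
        raise ParameterError("need at least 3 points to fit a slope")
    if plot.degenerate:
        raise DegeneratePlotError(
            "fluctuation plot contains zero fluctuations; exponent undefined"
        )
    slope, _ = np.polyfit(plot.log_sizes, plot.log_fluctuations, 1)
    return float(slope)


def dfa(
    x,
    min_window: int = DEFAULT_MIN_WINDOW,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> tuple[FluctuationPlot, float]:
    """Convenience wrapper: window scheme + fluctuation plot + exponent."""
    values = _series_values(x)
    scheme = make_windows(values.size, min_window=min_window, n_windows=n_windows)
    plot = dfa_fluctuations(values, scheme)
    return plot, dfa_exponent(plot)


# --------------------------------------------------------------------------
# ML-DFA candidate models
# --------------------------------------------------------------------------

# family codes used inside the jitted kernels
_POLY, _ROOT, _LOG, _EXP, _SPLINE = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class CandidateModel:
    """One curve family entered in the AIC comparison."""

    name: str
    family: str
    order: int  # degree (poly), K (root), M segments (spline); 0 otherwise
    param_count: int
    code: int = field(repr=False, default=0)


CANDIDATE_MODELS: tuple[CandidateModel, ...] = tuple(
    [
        CandidateModel(f"poly{k}", "polynomial", k, k + 1, _POLY)
        for k in range(1, 6)
    ]
    + [CandidateModel(f"root{k}", "root", k, 3, _ROOT) for k in (2, 3, 4)]
    + [
        CandidateModel("log", "logarithmic", 0, 3, _LOG),
        CandidateModel("exp", "exponential", 0, 3, _EXP),
    ]
    + [
        CandidateModel(f"spline{m}", "spline", m, 2 * m, _SPLINE)
        for m in (2, 3, 4)
    ]
)

LINEAR_MODEL = CANDIDATE_MODELS[0]


@dataclass(frozen=True)
class ModelFit:
    """Best pseudo-likelihood fit of one candidate model to one plot."""

    model: CandidateModel
    params: np.ndarray
    loglik: float
    aic: float
    feasible: bool


@dataclass(frozen=True)
class MLDFAResult:
    """Verdict of ML-DFA on a fluctuation plot.

    ``valid`` is True iff the linear model attains the strict minimum AICc
    among feasible fits; ``exponent`` is present exactly when valid.
    """

    valid: bool
    exponent: float | None
    best_model: str
    fits: tuple[ModelFit, ...]
    scaled_fluctuations: np.ndarray
    diagnostic: str = ""


# --------------------------------------------------------------------------
# Jitted fitting kernels
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _eval_model(code, order, p, x, f):
    """Evaluate a candidate model at the design points.

    Fills ``f`` and returns a non-negative domain-violation penalty
    (0.0 when the parameters are admissible).
    """
    n = x.size
    penalty = 0.0
    if code == 0:  # polynomial of degree `order`, ascending coefficients
        for i in range(n):
            acc = 0.0
            xp = 1.0
            for j in range(order + 1):
                acc += p[j] * xp
                xp *= x[i]
            f[i] = acc
    elif code == 1:  # a1*(x+a2)^(1/K) + a3
        # bound the shift: for x[0]+a2 beyond ~60 the curve is numerically
        # indistinguishable from a straight line over the plot's x-range
        if x[0] + p[1] > 20.0:
            penalty += x[0] + p[1] - 20.0
        for i in range(n):
            base = x[i] + p[1]
            if base < 0.0:
                penalty += -base
                base = 0.0
            if order == 2:
                f[i] = p[0] * np.sqrt(base) + p[2]
            elif order == 3:
                f[i] = p[0] * np.cbrt(base) + p[2]
            else:
                f[i] = p[0] * np.sqrt(np.sqrt(base)) + p[2]
    elif code == 2:  # a1*log(x+a2) + a3
        if x[0] + p[1] > 20.0:
            penalty += x[0] + p[1] - 20.0
        for i in range(n):
            base = x[i] + p[1]
            if base < 1e-10:
                penalty += 1e-10 - base
                base = 1e-10
            f[i] = p[0] * np.log(base) + p[2]
    elif code == 3:  # a1*exp(a2*x) + a3
        for i in range(n):
            arg = p[1] * x[i]
            if arg > 50.0:
                penalty += arg - 50.0
                arg = 50.0
            f[i] = p[0] * np.exp(arg) + p[2]
    else:  # continuous piecewise-linear spline with `order` segments
        m = order
        x0 = x[0]
        x1 = x[n - 1]
        gap = (x1 - x0) / (n - 1)
        # ordered interior breakpoints with minimum separation of one gap
        prev = x0
        for j in range(m - 1):
            b = p[m + 1 + j]
            if b < prev + gap:
                penalty += prev + gap - b
            prev = b
        if prev > x1 - gap:
            penalty += prev - (x1 - gap)
        for i in range(n):
            xi = x[i]
            acc = p[0]
            seg_start = x0
            for j in range(m):
                seg_end = x1 if j == m - 1 else p[m + 1 + j]
                if xi <= seg_end or j == m - 1:
                    acc += p[1 + j] * (xi - seg_start)
                    break
                acc += p[1 + j] * (seg_end - seg_start)
                seg_start = seg_end
            f[i] = acc
    return penalty


@njit(cache=True, fastmath=True)
def _neg_loglik(code, order, p, x, y, ysum, f):
    pen = _eval_model(code, order, p, x, f)
    if pen > 0.0:
        return 1e8 * (1.0 + pen)
    total = 0.0
    for i in range(x.size):
        total += abs(f[i])
    if total <= 0.0:
        return 1e12
    ll = 0.0
    for i in range(x.size):
        if y[i] > 0.0:
            a = abs(f[i])
            if a < 1e-290:
                return 1e12
            ll += y[i] * np.log(a)
    ll -= ysum * np.log(total)
    return -ll


@njit(cache=True, fastmath=True)
def _nelder_mead(code, order, x0, x, y, ysum, maxiter, tol, fbar):
    """Derivative-free local minimization of the negative pseudo-LL.

    Standard Nelder–Mead with three stopping rules: objective spread of
    the simplex below ``tol`` (relative); a stall — improvement of the
    best value below 0.02 nats over a 20-iteration stretch — which cuts
    off the slow crawl along near-degenerate valleys (e.g. a shifted root
    mimicking a straight line as its shift grows without bound); and a
    prune — after 30 iterations, a start stuck more than 100 nats above
    the best optimum already found (``fbar``) is abandoned, far outside
    any AIC decision margin.
    """
    k = x0.size
    f = np.empty(x.size)
    simplex = np.empty((k + 1, k))
    fvals = np.empty(k + 1)
    for j in range(k):
        simplex[0, j] = x0[j]
    fvals[0] = _neg_loglik(code, order, simplex[0], x, y, ysum, f)
    for i in range(k):
        for j in range(k):
            simplex[i + 1, j] = x0[j]
        step = 0.05 * abs(x0[i]) + 0.05
        simplex[i + 1, i] += step
        fvals[i + 1] = _neg_loglik(code, order, simplex[i + 1], x, y, ysum, f)

    xr = np.empty(k)
    xc = np.empty(k)
    cen = np.empty(k)
    it = 0
    checkpoint = fvals.min()
    while it < maxiter:
        it += 1
        # locate best, worst and second-worst vertices
        i_lo = 0
        i_hi = 0
        for i in range(1, k + 1):
            if fvals[i] < fvals[i_lo]:
                i_lo = i
            if fvals[i] > fvals[i_hi]:
                i_hi = i
        f_sh = -np.inf
        for i in range(k + 1):
            if i != i_hi and fvals[i] > f_sh:
                f_sh = fvals[i]
        if fvals[i_hi] - fvals[i_lo] < tol * (1.0 + abs(fvals[i_lo])):
            break
        if it % 20 == 0:
            if checkpoint - fvals[i_lo] < 0.02:
                break
            if it >= 30 and fvals[i_lo] > fbar + 100.0:
                break
            checkpoint = fvals[i_lo]
        for j in range(k):
            s = 0.0
            for i in range(k + 1):
                s += simplex[i, j]
            cen[j] = (s - simplex[i_hi, j]) / k
        for j in range(k):
            xr[j] = cen[j] + (cen[j] - simplex[i_hi, j])
        fr = _neg_loglik(code, order, xr, x, y, ysum, f)
        if fr < fvals[i_lo]:
            # expansion
            for j in range(k):
                xc[j] = cen[j] + 2.0 * (cen[j] - simplex[i_hi, j])
            fe = _neg_loglik(code, order, xc, x, y, ysum, f)
            if fe < fr:
                for j in range(k):
                    simplex[i_hi, j] = xc[j]
                fvals[i_hi] = fe
            else:
                for j in range(k):
                    simplex[i_hi, j] = xr[j]
                fvals[i_hi] = fr
        elif fr < f_sh:
            for j in range(k):
                simplex[i_hi, j] = xr[j]
            fvals[i_hi] = fr
        else:
            if fr < fvals[i_hi]:
                for j in range(k):
                    xc[j] = cen[j] + 0.5 * (xr[j] - cen[j])
            else:
                for j in range(k):
                    xc[j] = cen[j] + 0.5 * (simplex[i_hi, j] - cen[j])
            fc = _neg_loglik(code, order, xc, x, y, ysum, f)
            if fc < min(fr, fvals[i_hi]):
                for j in range(k):
                    simplex[i_hi, j] = xc[j]
                fvals[i_hi] = fc
            else:  # shrink toward the best vertex
                for i in range(k + 1):
                    if i == i_lo:
                        continue
                    for j in range(k):
                        simplex[i, j] = simplex[i_lo, j] + 0.5 * (
                            simplex[i, j] - simplex[i_lo, j]
                        )
                    fvals[i] = _neg_loglik(
                        code, order, simplex[i], x, y, ysum, f
                    )
    best = np.argmin(fvals)
    return simplex[best].copy(), fvals[best]


@njit(cache=True, fastmath=True)
def _fit_model(code, order, starts, x, y, ysum, maxiter, tol):
    """Multi-start fit; returns the best *feasible* optimum.

    Feasibility requires the fitted f to be non-negative at every design
    point.  Returns (negative log-likelihood, params, feasible flag).
    """
    k = starts.shape[1]
    f = np.empty(x.size)
    best_val = np.inf
    best_params = np.zeros(k)
    feasible = False
    for s in range(starts.shape[0]):
        params, val = _nelder_mead(
            code, order, starts[s], x, y, ysum, maxiter, tol, best_val
        )
        if val >= 1e8:  # never left the penalty region
            continue
        pen = _eval_model(code, order, params, x, f)
        if pen > 0.0:
            continue
        ok = True
        for i in range(x.size):
            if f[i] < 0.0:
                ok = False
                break
        if ok and val < best_val:
            best_val = val
            best_params = params.copy()
            feasible = True
    return best_val, best_params, feasible


# --------------------------------------------------------------------------
# Start-point construction (seeded, per model family)
# --------------------------------------------------------------------------


def _ols_line(u, y):
    """Closed-form simple OLS (slope, intercept); avoids polyfit overhead."""
    um = u.mean()
    ym = y.mean()
    du = u - um
    var = float(np.dot(du, du))
    if var <= 0.0:
        return 0.0, ym
    slope = float(np.dot(du, y - ym)) / var
    return slope, ym - slope * um


def _ols_rows(U, y):
    """Row-wise simple OLS of y on each row of U -> (slopes, intercepts)."""
    um = U.mean(axis=1, keepdims=True)
    ym = y.mean()
    dU = U - um
    var = np.einsum("ij,ij->i", dU, dU)
    var[var <= 0.0] = np.inf
    slopes = (dU @ (y - ym)) / var
    return slopes, ym - slopes * um[:, 0]


def _poly_starts(rng, x, y, degree, n_starts):
    base = np.polyfit(x, y, degree)[::-1]  # ascending order
    starts = np.empty((n_starts, degree + 1))
    starts[0] = base
    scale = np.abs(base) + 1.0
    starts[1:] = base + rng.normal(0.0, 0.3, (n_starts - 1, degree + 1)) * scale
    return starts


def _shifted_basis_starts(rng, x, y, transform, a2_lo, a2_hi, n_starts):
    """Starts for root/log families via OLS on a transformed regressor."""
    n_grid = min(4, n_starts)
    a2 = np.empty(n_starts)
    a2[:n_grid] = np.linspace(a2_lo, min(a2_hi, a2_lo + 3.0), n_grid)
    a2[n_grid:] = rng.uniform(a2_lo, a2_hi, n_starts - n_grid)
    a1, a3 = _ols_rows(transform(x[None, :] + a2[:, None]), y)
    jitter = np.ones(n_starts)
    jitter[n_grid:] += rng.normal(0.0, 0.2, n_starts - n_grid)
    return np.column_stack((a1 * jitter, a2, a3))


def _exp_starts(rng, x, y, n_starts):
    span = max(x[-1] - x[0], 1e-6)
    grid = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]) / span
    n_grid = min(grid.size, n_starts)
    a2 = np.empty(n_starts)
    a2[:n_grid] = grid[:n_grid]
    a2[n_grid:] = rng.uniform(-4.0, 4.0, n_starts - n_grid) / span
    U = np.exp(np.clip(a2[:, None] * x[None, :], -50.0, 50.0))
    a1, a3 = _ols_rows(U, y)
    return np.column_stack((a1, a2, a3))


def _spline_starts(rng, x, y, m, n_starts):
    slope_global, _ = _ols_line(x, y)
    starts = np.empty((n_starts, 2 * m))
    x0, x1 = x[0], x[-1]
    # reference start: even breakpoints, per-segment OLS slopes
    breaks0 = np.linspace(x0, x1, m + 1)[1:-1]
    edges = np.concatenate(([x0], breaks0, [x1]))
    slopes0 = np.empty(m)
    for j in range(m):
        mask = (x >= edges[j]) & (x <= edges[j + 1])
        slopes0[j] = _ols_line(x[mask], y[mask])[0] if mask.sum() >= 2 else slope_global
    starts[0, 0] = y[0]
    starts[0, 1 : m + 1] = slopes0
    starts[0, m + 1 :] = breaks0
    starts[1:, 0] = y[0] + rng.normal(0.0, 5.0, n_starts - 1)
    starts[1:, 1 : m + 1] = slopes0 * (
        1.0 + rng.normal(0.0, 0.2, (n_starts - 1, m))
    )
    starts[1:, m + 1 :] = np.sort(rng.uniform(x0, x1, (n_starts - 1, m - 1)), axis=1)
    return starts


def _model_starts(rng, model: CandidateModel, x, y, n_starts):
    if model.code == _POLY:
        return _poly_starts(rng, x, y, model.order, n_starts)
    if model.code == _ROOT:
        lo = -x[0] + 0.05
        return _shifted_basis_starts(
            rng, x, y, lambda u: u ** (1.0 / model.order), lo, lo + 10.0, n_starts
        )
    if model.code == _LOG:
        lo = -x[0] + 0.05
        return _shifted_basis_starts(rng, x, y, np.log, lo, lo + 10.0, n_starts)
    if model.code == _EXP:
        return _exp_starts(rng, x, y, n_starts)
    return _spline_starts(rng, x, y, model.order, n_starts)


# --------------------------------------------------------------------------
# ML-DFA driver
# --------------------------------------------------------------------------


def scaled_log_fluctuations(plot: FluctuationPlot) -> np.ndarray:
    """log10 fluctuations min–max scaled onto [0, 100]."""
    lf = plot.log_fluctuations
    lo, hi = lf.min(), lf.max()
    if hi <= lo:
        raise DegeneratePlotError("fluctuation plot is flat; cannot scale")
    return 100.0 * (lf - lo) / (hi - lo)


def mldfa_validate(
    plot: FluctuationPlot,
    seed: int = 0,
    n_starts: int = 10,
    maxiter: int = 5000,
    tol: float = 1e-8,
) -> MLDFAResult:
    """Judge the linearity of a DFA fluctuation plot by AICc model selection.

    Parameters
    ----------
    plot
        Fluctuation plot with at least 10 points (so the 8-parameter spline
        stays identifiable).
    seed
        Seed for the multi-start initialization; fixed seed gives a
        reproducible verdict.
    n_starts, maxiter, tol
        Local-search budget per candidate model.

    Returns
    -------
    MLDFAResult
        ``valid`` iff the linear fit attains the strict minimum AICc among
        feasible candidate fits; ``exponent`` (from the unscaled plot) is
        present exactly when valid.  Optimizer failure for a model marks
        that model infeasible rather than raising.
    """
    if len(plot) < 10:
        raise ParameterError("ML-DFA needs at least 10 fluctuation-plot points")
    if plot.degenerate:
        return MLDFAResult(
            valid=False,
            exponent=None,
            best_model="",
            fits=(),
            scaled_fluctuations=np.array([]),
            diagnostic="degenerate plot: zero fluctuations (no variability)",
        )
    x = plot.log_sizes
    try:
        y = scaled_log_fluctuations(plot)
    except DegeneratePlotError:
        return MLDFAResult(
            valid=False,
            exponent=None,
            best_model="",
            fits=(),
            scaled_fluctuations=np.array([]),
            diagnostic="degenerate plot: flat fluctuations",
        )
    ysum = float(y.sum())
    n = x.size
    rng = np.random.default_rng(seed)

    fits = []
    for model in CANDIDATE_MODELS:
        starts = np.ascontiguousarray(
            _model_starts(rng, model, x, y, n_starts), dtype=np.float64
        )
        negll, params, feasible = _fit_model(
            model.code, model.order, starts, x, y, ysum, maxiter, tol
        )
        k = model.param_count
        if feasible and n - k - 1 > 0:
            aic = 2.0 * negll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
            fits.append(ModelFit(model, params, -negll, float(aic), True))
        else:
            fits.append(ModelFit(model, params, -np.inf, np.inf, False))

    feasible_fits = [f for f in fits if f.feasible]
    if not feasible_fits:
        return MLDFAResult(
            valid=False,
            exponent=None,
            best_model="",
            fits=tuple(fits),
            scaled_fluctuations=y,
            diagnostic="all candidate models infeasible",
        )
    best = min(feasible_fits, key=lambda f: f.aic)
    linear = fits[0]
    # strict minimum: any exact AIC tie with a non-linear model invalidates
    valid = (
        linear.feasible
        and all(
            linear.aic < f.aic for f in feasible_fits if f.model is not linear.model
        )
    )
    exponent = dfa_exponent(plot) if valid else None
    return MLDFAResult(
        valid=valid,
        exponent=exponent,
        best_model=best.model.name,
        fits=tuple(fits),
        scaled_fluctuations=y,
    )


def plot_fluctuation(plot: FluctuationPlot, result: MLDFAResult | None = None, ax=None):
    """Diagnostic log–log rendering of a fluctuation plot (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(plot.log_sizes, plot.log_fluctuations, "o-", ms=4)
    ax.set_xlabel("log10 window size")
    ax.set_ylabel("log10 F(n)")
    if result is not None and result.valid:
        ax.set_title(f"valid, H = {result.exponent:.3f}")
    elif result is not None:
        ax.set_title(f"invalid (best model: {result.best_model})")
    return ax
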