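"""Classical criticality models: 2-D Ising and the noisy Kuramoto model.

Both serve as testbeds whose control parameter (temperature T, coupling K)
drives the system through a critical regime.  Sub-lattice block-mean spin
series (Ising) or oscillator phases (Kuramoto) are paired, the rate of
change of the pairwise phase difference is formed, and DFA + ML-DFA judge
the presence of long-range temporal correlations as the control parameter
is swept.

Ising: Metropolis Monte Carlo on an L x L periodic lattice with the
4-nearest-neighbour Hamiltonian H = -J sum p_i p_j (J = k = 1); one sweep
is L^2 single-site proposals at uniformly random sites, one block-mean
sample recorded per sweep after burn-in.  The critical temperature is
Tc = 2/ln(1 + sqrt(2)) ~ 2.269.

Kuramoto (noisy): N phase oscillators

    dphi_i = [omega_i + (K/N) sum_j sin(phi_j - phi_i)] dt + sigma sqrt(dt) xi

integrated by Euler–Maruyama using the mean-field identity
sum_j sin(phi_j - phi_i) = N r sin(psi - phi_i), with r e^{i psi} the order
parameter.  The infinite-N critical coupling for a zero-centred normal
frequency distribution of SD sigma_omega is Kc = 2/(pi g(0)) =
2 sigma_omega sqrt(2/pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dfa import DEFAULT_MIN_WINDOW, dfa_fluctuations, make_windows, mldfa_validate
from .errors import ParameterError
from .phase import SampledSignal, phase_difference, rate_of_change

__all__ = [
    "ISING_TC",
    "IsingSpec",
    "KuramotoSpec",
    "SweepRecord",
    "ising_simulate",
    "ising_sweep",
    "kuramoto_simulate",
    "order_parameter",
    "critical_coupling",
    "kuramoto_sweep",
    "analyze_phase_pairs",
    "analyze_signal_pairs",
    "pair_count",
]

#: Onsager critical temperature of the 2-D Ising model (J = k = 1)
ISING_TC = 2.0 / np.log(1.0 + np.sqrt(2.0))


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IsingSpec:
    """Seeded 2-D Ising simulation with sub-lattice extraction."""

    temperature: float
    lattice_size: int = 96
    n_sweeps: int = 64_000
    burn_in: int = 2_000
    block: int = 8
    seed: int = 0
    init: str = "random"  # "random" or "aligned"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")
        if self.lattice_size % self.block != 0:
            raise ParameterError(
                f"lattice size {self.lattice_size} not divisible by block {self.block}"
            )
        if self.init not in ("random", "aligned"):
            raise ParameterError("init must be 'random' or 'aligned'")

    @property
    def n_blocks(self) -> int:
        side = self.lattice_size // self.block
        return side * side


@dataclass(frozen=True)
class KuramotoSpec:
    """Seeded noisy Kuramoto simulation.

    ``freq_sd`` and the derived critical coupling are in radian-rate units;
    the natural frequencies are drawn from N(2*pi*mean_freq_hz, freq_sd).
    ``noise_sd`` is the SD (radians) of the continuous noise process with
    covariance sigma^2/T, T = 1 s.
    """

    coupling: float
    n_osc: int = 200
    mean_freq_hz: float = 22.0
    freq_sd: float = 15.0
    noise_sd: float = 0.32
    dt: float = 1e-3
    n_steps: int = 6100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_osc < 2:
            raise ParameterError("need at least 2 oscillators")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class SweepRecord:
    """Aggregate of one control-parameter value in a sweep."""

    control: float
    mean_exponent: float
    sd_exponent: float
    validity_fraction: float
    n_pairs_analyzed: int
    n_valid: int
    mean_order_r: float = np.nan
    delta_kr: float = np.nan
    exponents: np.ndarray = field(default=None, repr=False)


def pair_count(n_series: int) -> int:
    """Number of unordered pairs, C(n, 2)."""
    return n_series * (n_series - 1) // 2


# --------------------------------------------------------------------------
# Ising model
# --------------------------------------------------------------------------


@njit(cache=True)
def _ising_run(spins, T, n_sweeps, burn_in, block, uniforms_seed, record,
               proposals, acceptances):
    """Random-site Metropolis; records block means once per sweep.

    One sweep = L^2 single-site proposals at uniformly random sites.
    (Deterministic full-lattice passes are ruled out: with acceptance
    probabilities approaching 1 at high temperature they flip every spin
    each pass, imprinting a spurious period-2 alternation on the series.)
    ``record`` is (n_blocks^2, n_sweeps) filled in place.  Returns the
    final lattice.
    """
    L = spins.shape[0]
    side = L // block
    n_sites = L * L
    np.random.seed(uniforms_seed)
    for sweep in range(burn_in + n_sweeps):
        for _ in range(n_sites):
            i = np.random.randint(0, L)
            j = np.random.randint(0, L)
            s = spins[i, j]
            nn = (
                spins[(i + 1) % L, j]
                + spins[(i - 1) % L, j]
                + spins[i, (j + 1) % L]
                + spins[i, (j - 1) % L]
            )
            dE = 2.0 * s * nn
            cls = int(dE + 8.0) // 4  # dE in {-8,-4,0,4,8} -> class 0..4
            proposals[cls] += 1
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                spins[i, j] = -s
                acceptances[cls] += 1
        if sweep >= burn_in:
            t = sweep - burn_in
            for bi in range(side):
                for bj in range(side):
                    acc = 0.0
                    for ii in range(block):
                        for jj in range(block):
                            acc += spins[bi * block + ii, bj * block + jj]
                    record[bi * side + bj, t] = acc / (block * block)
    return spins


def ising_simulate(spec: IsingSpec, return_acceptance: bool = False):
    """Simulate and return block-mean spin series, shape (n_blocks, n_sweeps).

    Spins start aligned (+1) or random per ``spec.init``; ``burn_in``
    sweeps are discarded before recording one sample per sweep.  With
    ``return_acceptance`` also returns (proposals, acceptances) counts per
    energy-change class dE in {-8, -4, 0, 4, 8}, for detailed-balance
    checks against min(1, exp(-dE/T)).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.lattice_size
    if spec.init == "aligned":
        spins = np.ones((L, L), dtype=np.int8)
    else:
        spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L))
    record = np.empty((spec.n_blocks, spec.n_sweeps))
    proposals = np.zeros(5, dtype=np.int64)
    acceptances = np.zeros(5, dtype=np.int64)
    metropolis_seed = int(rng.integers(0, 2**31 - 1))
    _ising_run(
        spins.astype(np.float64),
        float(spec.temperature),
        spec.n_sweeps,
        spec.burn_in,
        spec.block,
        metropolis_seed,
        record,
        proposals,
        acceptances,
    )
    if return_acceptance:
        return record, proposals, acceptances
    return record


# --------------------------------------------------------------------------
# Pairwise phase analysis shared by the sweeps
# --------------------------------------------------------------------------


def _select_pairs(n_series: int, pair_subset, rng) -> np.ndarray:
    """All or a seeded random subset of the C(n,2) index pairs."""
    iu = np.triu_indices(n_series, k=1)
    pairs = np.column_stack(iu)
    if pair_subset is not None and pair_subset < pairs.shape[0]:
        keep = rng.choice(pairs.shape[0], size=pair_subset, replace=False)
        pairs = pairs[np.sort(keep)]
    return pairs


def _judge_rate(rate_values, min_window, mldfa_seed):
    """DFA + ML-DFA on one rate series; (valid, exponent or NaN)."""
    if np.ptp(rate_values) == 0.0:
        return False, np.nan  # fully synchronized: no fluctuations
    try:
        scheme = make_windows(rate_values.size, min_window=min_window)
    except Exception:
        return False, np.nan
    plot = dfa_fluctuations(rate_values, scheme)
    result = mldfa_validate(plot, seed=mldfa_seed)
    if result.valid:
        return True, float(result.exponent)
    return False, np.nan


def analyze_phase_pairs(
    phases: np.ndarray,
    pairs: np.ndarray,
    min_window: int = DEFAULT_MIN_WINDOW,
    mldfa_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Judge the rate of change of phase difference for given index pairs.

    ``phases``: (n_series, n_steps) unwrapped phases.  Returns boolean
    validity and exponent (NaN when invalid) arrays over pairs.
    """
    n_pairs = pairs.shape[0]
    valid = np.zeros(n_pairs, dtype=bool)
    expo = np.full(n_pairs, np.nan)
    for k in range(n_pairs):
        i, j = pairs[k]
        rate = np.diff(phases[i] - phases[j])
        valid[k], expo[k] = _judge_rate(rate, min_window, mldfa_seed + k)
    return valid, expo


def analyze_signal_pairs(
    series: np.ndarray,
    sampling_rate: float,
    pairs: np.ndarray,
    min_window: int = DEFAULT_MIN_WINDOW,
    mldfa_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline (Hilbert phase included) over pairs of raw series.

    Constant series (frozen sub-lattices) yield invalid pairs rather than
    errors: full synchronization leaves no fluctuations to analyse.
    """
    from .phase import analytic_phase, unwrap

    n_series = series.shape[0]
    phases = np.full(series.shape, np.nan)
    usable = np.zeros(n_series, dtype=bool)
    for i in range(n_series):
        if np.ptp(series[i]) == 0.0:
            continue  # frozen series: phase undefined
        sig = SampledSignal(values=series[i], sampling_rate=sampling_rate)
        phases[i] = unwrap(analytic_phase(sig)).values
        usable[i] = True
    n_pairs = pairs.shape[0]
    valid = np.zeros(n_pairs, dtype=bool)
    expo = np.full(n_pairs, np.nan)
    for k in range(n_pairs):
        i, j = pairs[k]
        if not (usable[i] and usable[j]):
            continue
        rate = np.diff(phases[i] - phases[j])
        valid[k], expo[k] = _judge_rate(rate, min_window, mldfa_seed + k)
    return valid, expo


def _aggregate(control, valid, expo, mean_r=np.nan) -> SweepRecord:
    n_valid = int(valid.sum())
    vals = expo[valid]
    return SweepRecord(
        control=float(control),
        mean_exponent=float(vals.mean()) if n_valid else np.nan,
        sd_exponent=float(vals.std(ddof=1)) if n_valid > 1 else np.nan,
        validity_fraction=float(valid.mean()) if valid.size else 0.0,
        n_pairs_analyzed=int(valid.size),
        n_valid=n_valid,
        mean_order_r=float(mean_r),
        exponents=vals,
    )


def ising_sweep(
    temperatures,
    spec: IsingSpec,
    pair_subset: int | None = None,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> list[SweepRecord]:
    """Sweep temperature; analyze sub-lattice pairs at each value.

    For each T the lattice is simulated, all (or a seeded subset of) block
    pairs are run through the Hilbert-phase pipeline, and the ML-DFA
    verdicts are aggregated into a SweepRecord.
    """
    records = []
    for t_idx, T in enumerate(temperatures):
        run_spec = IsingSpec(
            temperature=float(T),
            lattice_size=spec.lattice_size,
            n_sweeps=spec.n_sweeps,
            burn_in=spec.burn_in,
            block=spec.block,
            seed=spec.seed + t_idx,
            init=spec.init,
        )
        series = ising_simulate(run_spec)
        rng = np.random.default_rng((spec.seed, t_idx))
        pairs = _select_pairs(series.shape[0], pair_subset, rng)
        valid, expo = analyze_signal_pairs(
            series,
            sampling_rate=1.0,
            pairs=pairs,
            min_window=min_window,
            mldfa_seed=spec.seed + 7919 * t_idx,
        )
        rec = _aggregate(T, valid, expo, mean_r=np.abs(series.mean(axis=0)).mean())
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# Kuramoto model
# --------------------------------------------------------------------------


@njit(cache=True)
def _kuramoto_run(phi0, omega, K, sigma_dt, dt, n_steps, noise_seed):
    """Euler–Maruyama via the mean-field identity; returns (N, n_steps)."""
    N = phi0.size
    out = np.empty((N, n_steps))
    phi = phi0.copy()
    np.random.seed(noise_seed)
    for t in range(n_steps):
        re = 0.0
        im = 0.0
        for i in range(N):
            re += np.cos(phi[i])
            im += np.sin(phi[i])
        re /= N
        im /= N
        # K*r*sin(psi - phi_i) = K*(im*cos(phi_i) - re*sin(phi_i))
        for i in range(N):
            drift = omega[i] + K * (im * np.cos(phi[i]) - re * np.sin(phi[i]))
            phi[i] += drift * dt + sigma_dt * np.random.standard_normal()
            out[i, t] = phi[i]
    return out


def kuramoto_simulate(spec: KuramotoSpec) -> np.ndarray:
    """Integrate the noisy Kuramoto model; returns unwrapped phases.

    Natural frequencies are drawn once per seed from
    N(2*pi*mean_freq_hz, freq_sd); initial phases are uniform on
    [-pi, pi).  The per-step noise increment has SD noise_sd*sqrt(dt)
    (continuous covariance sigma^2/T with T = 1 s).
    """
    rng = np.random.default_rng(spec.seed)
    omega = rng.normal(2.0 * np.pi * spec.mean_freq_hz, spec.freq_sd, spec.n_osc)
    phi0 = rng.uniform(-np.pi, np.pi, spec.n_osc)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    sigma_dt = spec.noise_sd * np.sqrt(spec.dt)
    return _kuramoto_run(
        phi0, omega, float(spec.coupling), sigma_dt, spec.dt, spec.n_steps, noise_seed
    )


def order_parameter(phases: np.ndarray) -> tuple[np.ndarray, float]:
    """Kuramoto order parameter r(t) and its mean.

    r(t) e^{i psi(t)} = (1/N) sum_j e^{i phi_j(t)}; r = 1 means full
    entrainment, r = 0 complete incoherence.
    """
    if phases.ndim == 1:
        phases = phases[None, :]
    z = np.exp(1j * phases).mean(axis=0)
    r = np.abs(z)
    return r, float(r.mean())


def critical_coupling(freq_sd: float) -> float:
    """Infinite-N critical coupling Kc = 2/(pi g(0)) = 2*sigma*sqrt(2/pi)."""
    if freq_sd <= 0:
        raise ParameterError("freq_sd must be > 0")
    return 2.0 * freq_sd * np.sqrt(2.0 / np.pi)


def _transient(n_steps: int) -> int:
    """First 10% of recorded steps are discarded as initialization."""
    return n_steps // 10


def kuramoto_sweep(
    couplings,
    spec: KuramotoSpec,
    pair_subset: int | None = 2000,
    n_seeds: int = 1,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> list[SweepRecord]:
    """Sweep coupling K; DFA/ML-DFA over oscillator pairs at each value.

    ``couplings`` must be sorted ascending (Delta(Kr) is their first
    difference of K * mean r, aligned to the right endpoint).  With
    ``n_seeds > 1`` the verdicts are pooled over independent realizations
    and the per-seed pair budget is ``pair_subset // n_seeds``.
    """
    couplings = list(couplings)
    if any(b < a for a, b in zip(couplings, couplings[1:])):
        raise ParameterError("couplings must be sorted ascending")
    per_seed = None
    if pair_subset is not None:
        per_seed = max(1, pair_subset // n_seeds)
    records = []
    for k_idx, K in enumerate(couplings):
        all_valid, all_expo, r_means = [], [], []
        for s in range(n_seeds):
            run_spec = KuramotoSpec(
                coupling=float(K),
                n_osc=spec.n_osc,
                mean_freq_hz=spec.mean_freq_hz,
                freq_sd=spec.freq_sd,
                noise_sd=spec.noise_sd,
                dt=spec.dt,
                n_steps=spec.n_steps,
                seed=spec.seed + s,
            )
            phases = kuramoto_simulate(run_spec)
            skip = _transient(phases.shape[1])
            post = phases[:, skip:]
            _, r_mean = order_parameter(post)
            r_means.append(r_mean)
            rng = np.random.default_rng((spec.seed, k_idx, s))
            pairs = _select_pairs(spec.n_osc, per_seed, rng)
            valid, expo = analyze_phase_pairs(
                post,
                pairs,
                min_window=min_window,
                mldfa_seed=spec.seed + 104729 * k_idx + 7919 * s,
            )
            all_valid.append(valid)
            all_expo.append(expo)
        rec = _aggregate(
            K,
            np.concatenate(all_valid),
            np.concatenate(all_expo),
            mean_r=float(np.mean(r_means)),
        )
        records.append(rec)
    # Delta(Kr): first difference of K * mean r along the sorted grid
    for prev, cur in zip(records, records[1:]):
        cur.delta_kr = cur.control * cur.mean_order_r - prev.control * prev.mean_order_r
    return records
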