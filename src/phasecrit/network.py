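"""Delayed, weighted-network Kuramoto model on a connectome-like graph.

Sixty-six oscillators sit on a directed weighted connectivity matrix C
(row-normalized fiber-count weights, zero diagonal) with conduction delays
derived from a fiber-distance matrix L:

    dphi_i = [omega_i + K sum_j C_ij sin(phi_j(t - D_ij) - phi_i(t))] dt
             + sigma sqrt(dt) xi_i,
    D_ij = <D> * L_ij / <L>,

(K multiplies the row-normalized weights directly: each connected node
receives unit total weight, so K is the per-node coupling budget)

with <L> the mean distance over connected pairs and <D> the prescribed
mean delay (in integration steps).  Natural frequencies are normally
distributed around 60 Hz (gamma band), the noise SD is 1.25 rad.

Connectivity-disruption experiments: hemisphere disconnection (zero every
cross-hemisphere weight, leave the rest untouched) and degree/weight-
preserving randomization (outgoing-stub matching: per-node out-degree and
outgoing-weight multiset preserved exactly, placement random, no self
loops or duplicate edges).

A synthetic connectome generator stands in for the empirical 66-region
matrices: two mirrored 33-node hemispheres, six planted clusters with the
empirical cluster sizes (11, 5, 8, 14, 5, 11) plus 12 unclustered nodes,
the central cluster spanning both hemispheres through strong homologous
links, and distances from mirrored 3-D coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .critical_models import SweepRecord, _aggregate, _select_pairs, order_parameter
from .dfa import DEFAULT_MIN_WINDOW
from .errors import ParameterError, RandomizationError

__all__ = [
    "NetworkSpec",
    "DelayMatrix",
    "delays_from_distances",
    "network_simulate",
    "disconnect_hemispheres",
    "randomize_connectivity",
    "cluster_summary",
    "synthetic_connectome",
    "network_sweep",
    "row_normalize",
]


def row_normalize(C: np.ndarray) -> np.ndarray:
    """Scale each row with any connection to unit sum (zero rows kept)."""
    C = np.asarray(C, dtype=float).copy()
    np.fill_diagonal(C, 0.0)
    sums = C.sum(axis=1, keepdims=True)
    nonzero = sums[:, 0] > 0
    C[nonzero] /= sums[nonzero]
    return C


@dataclass(frozen=True)
class NetworkSpec:
    """Delayed-network Kuramoto configuration.

    ``mean_delay`` is expressed in integration steps (a delay of 11 steps
    at dt = 1 ms is 11 ms); per-edge step counts are the scaled distances
    rounded to the nearest step.
    """

    C: np.ndarray
    L: np.ndarray
    hemisphere: np.ndarray  # label per node
    clusters: np.ndarray  # label per node ("individual" for unclustered)
    coupling: float = 0.0
    mean_delay: float = 11.0
    mean_freq_hz: float = 60.0
    freq_sd: float = 5.0
    noise_sd: float = 1.25
    dt: float = 1e-3
    n_steps: int = 100_000
    seed: int = 0
    raw_weights: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        L = np.asarray(self.L, dtype=float)
        n = C.shape[0]
        if C.shape != (n, n) or L.shape != (n, n):
            raise ParameterError("C and L must be square matrices of equal size")
        if np.any(np.diag(C) != 0) or np.any(np.diag(L) != 0):
            raise ParameterError("C and L must have zero diagonals")
        if np.any(C < 0):
            raise ParameterError("C must be non-negative")
        if not np.allclose(L, L.T):
            raise ParameterError("L must be symmetric")
        sums = C.sum(axis=1)
        connected = sums > 0
        if not np.allclose(sums[connected], 1.0):
            raise ParameterError("rows of C with connections must sum to 1")
        if len(self.hemisphere) != n or len(self.clusters) != n:
            raise ParameterError("labels must cover all nodes")
        if self.mean_delay < 0:
            raise ParameterError("mean_delay must be >= 0")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere))
        object.__setattr__(self, "clusters", np.asarray(self.clusters))

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class DelayMatrix:
    """Per-edge conduction delays and their integer step counts."""

    values: np.ndarray  # delay in steps (continuous)
    step_counts: np.ndarray  # rounded to integration steps

    @property
    def max_steps(self) -> int:
        return int(self.step_counts.max())


def delays_from_distances(
    L: np.ndarray, mean_delay: float, connectivity: np.ndarray | None = None
) -> DelayMatrix:
    """Scale distances so the mean delay over connected pairs is <D>.

    D_ij = <D> * L_ij / <L>, with <L> the mean of L over nonzero
    off-diagonal entries (restricted to pairs connected in
    ``connectivity`` when given).  Doubling L leaves D unchanged.
    """
    L = np.asarray(L, dtype=float)
    if mean_delay == 0.0:
        z = np.zeros_like(L)
        return DelayMatrix(values=z, step_counts=z.astype(np.int64))
    mask = L > 0
    np.fill_diagonal(mask, False)
    if connectivity is not None:
        mask &= np.asarray(connectivity) > 0
    if not mask.any():
        raise ParameterError("distance matrix has no nonzero connected entries")
    mean_L = L[mask].mean()
    values = mean_delay * L / mean_L
    return DelayMatrix(
        values=values, step_counts=np.round(values).astype(np.int64)
    )


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


@njit(cache=True)
def _network_run(phi_hist, omega, K, C, dsteps, sigma_dt, dt, n_steps, hist, seed):
    """Euler–Maruyama with per-edge delayed phase lookups.

    ``phi_hist`` is an (N, hist + n_steps) buffer whose first ``hist``
    columns hold the backfilled pre-history; filled in place.
    """
    N = omega.size
    np.random.seed(seed)
    for t in range(n_steps):
        col = hist + t
        for i in range(N):
            coupling = 0.0
            for j in range(N):
                w = C[i, j]
                if w > 0.0:
                    phj = phi_hist[j, col - 1 - dsteps[i, j]]
                    coupling += w * np.sin(phj - phi_hist[i, col - 1])
            drift = omega[i] + K * coupling
            phi_hist[i, col] = (
                phi_hist[i, col - 1]
                + drift * dt
                + sigma_dt * np.random.standard_normal()
            )


def network_simulate(spec: NetworkSpec) -> np.ndarray:
    """Integrate the delayed-network model; returns unwrapped phases.

    History before t = 0 is backfilled by rotating the random initial
    phases backwards at each oscillator's natural frequency; the caller is
    expected to discard an initial transient (the sweep drivers drop the
    first 10% of steps).
    """
    if np.any(spec.C > 0):
        delays = delays_from_distances(
            spec.L, spec.mean_delay, connectivity=spec.C
        )
        dsteps = delays.step_counts
    else:  # no connections: delays are irrelevant
        dsteps = np.zeros_like(spec.C, dtype=np.int64)
    hist = max(int(dsteps.max()) + 1, 1)
    if hist >= spec.n_steps:
        raise ParameterError(
            f"max delay of {hist} steps exceeds run length {spec.n_steps}"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    omega = rng.normal(2.0 * np.pi * spec.mean_freq_hz, spec.freq_sd, n)
    phi0 = rng.uniform(-np.pi, np.pi, n)
    buf = np.empty((n, hist + spec.n_steps))
    t_back = np.arange(-hist + 1, 1, dtype=float) * spec.dt
    buf[:, :hist] = phi0[:, None] + omega[:, None] * t_back[None, :]
    noise_seed = int(rng.integers(0, 2**31 - 1))
    _network_run(
        buf,
        omega,
        float(spec.coupling),
        spec.C,
        dsteps,
        spec.noise_sd * np.sqrt(spec.dt),
        spec.dt,
        spec.n_steps,
        hist,
        noise_seed,
    )
    return buf[:, hist:]


# --------------------------------------------------------------------------
# Connectivity disruptions
# --------------------------------------------------------------------------


def disconnect_hemispheres(C: np.ndarray, hemisphere) -> np.ndarray:
    """Zero every cross-hemisphere weight; leave the rest untouched.

    No renormalization is applied: all within-hemisphere elements are
    preserved exactly.
    """
    hemisphere = np.asarray(hemisphere)
    labels = np.unique(hemisphere)
    if labels.size < 2:
        raise ParameterError("need two hemisphere labels")
    same = hemisphere[:, None] == hemisphere[None, :]
    out = np.asarray(C, dtype=float).copy()
    out[~same] = 0.0
    return out


def randomize_connectivity(
    C: np.ndarray, seed: int = 0, max_restarts: int = 50
) -> np.ndarray:
    """Random rewiring preserving each node's out-degree and outgoing weights.

    Outgoing-stub matching: every directed edge (i -> j, w) contributes a
    stub (i, w); two stubs (u, wu), (v, wv) drawn at random form the edge
    pair u -> v (weight wu) and v -> u (weight wv), rejected if u == v or
    the pair is already connected.  Dead ends trigger a restart; running
    out of restarts raises RandomizationError rather than returning a
    silently invalid matrix.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    src, dst = np.nonzero(C)
    weights = C[src, dst]
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        order = rng.permutation(src.size)
        nodes = list(src[order])
        ws = list(weights[order])
        out = np.zeros_like(C)
        connected = np.zeros((n, n), dtype=bool)
        failed = False
        while nodes:
            placed = False
            for attempt in range(200):
                if len(nodes) < 2:
                    failed = True
                    break
                a, b = rng.choice(len(nodes), size=2, replace=False)
                u, v = nodes[a], nodes[b]
                if u == v or connected[u, v]:
                    continue
                out[u, v] = ws[a]
                out[v, u] = ws[b]
                connected[u, v] = connected[v, u] = True
                for idx in sorted((a, b), reverse=True):
                    nodes.pop(idx)
                    ws.pop(idx)
                placed = True
                break
            if failed or not placed:
                failed = True
                break
        if not failed:
            return out
    raise RandomizationError(
        f"stub matching failed after {max_restarts} restarts"
    )


def cluster_summary(C: np.ndarray, clusters) -> "pd.DataFrame":
    """Per-cluster mean outgoing weight per node and mean out-degree."""
    import pandas as pd

    C = np.asarray(C, dtype=float)
    clusters = np.asarray(clusters)
    if clusters.size != C.shape[0]:
        raise ParameterError("cluster labels must cover all nodes")
    weight_per_node = C.sum(axis=1)
    degree = (C > 0).sum(axis=1)
    rows = []
    for label in pd.unique(clusters):
        mask = clusters == label
        rows.append(
            {
                "cluster": label,
                "n_nodes": int(mask.sum()),
                "mean_weight_per_node": float(weight_per_node[mask].mean()),
                "mean_degree": float(degree[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Synthetic connectome fixture
# --------------------------------------------------------------------------

#: cluster sizes of the empirical 66-region parcellation (the 12 remaining
#: nodes are unclustered "individual" oscillators)
CLUSTER_SIZES = (11, 5, 8, 14, 5, 11)


def synthetic_connectome(seed: int = 0) -> NetworkSpec:
    """Synthetic stand-in for the empirical 66-region connectome.

    66 nodes in two mirrored 33-node hemispheres.  Cluster labels follow
    the empirical layout: cluster 1 nodes 7-17, cluster 2 18-22, cluster 3
    23-26 & 41-44, cluster 4 27-40 (central, spanning both hemispheres
    through strong homologous links), cluster 5 45-49, cluster 6 50-60;
    nodes 1-6 and 61-66 are individual (1-based numbering).  Cluster 4
    carries the largest weights.  Distances derive from random 3-D
    coordinates with the right hemisphere mirrored from the left; C is
    row-normalized.
    """
    rng = np.random.default_rng(seed)
    n = 66
    clusters = np.array(["individual"] * n, dtype=object)
    spans = {
        "cluster1": list(range(6, 17)),
        "cluster2": list(range(17, 22)),
        "cluster3": list(range(22, 26)) + list(range(40, 44)),
        "cluster4": list(range(26, 40)),
        "cluster5": list(range(44, 49)),
        "cluster6": list(range(49, 60)),
    }
    for name, nodes in spans.items():
        clusters[nodes] = name
    hemisphere = np.array(["L"] * 33 + ["R"] * 33, dtype=object)

    # mirrored coordinates: node i on the left, 65 - i its homologue.
    # cluster-4 members sit near the midline (|x| small), like the
    # posteromedial hub regions they emulate, so their homologous
    # cross-hemisphere links are short (short conduction delays)
    left = rng.uniform(0.0, 10.0, size=(33, 3)) + np.array([2.0, 0.0, 0.0])
    c4_left = [i for i in spans["cluster4"] if i < 33]
    left[c4_left, 0] = rng.uniform(0.5, 2.5, size=len(c4_left))
    left[c4_left, 1:] = 4.0 + rng.uniform(0.0, 3.0, size=(len(c4_left), 2))
    right = left.copy()
    right[:, 0] *= -1.0
    coords = np.vstack([left, right[::-1]])
    diff = coords[:, None, :] - coords[None, :, :]
    L = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(L, 0.0)

    # base sparse background connectivity
    W = np.zeros((n, n))
    base = rng.random((n, n)) < 0.12
    W[base] = rng.gamma(2.0, 0.5, size=int(base.sum()))
    # planted clusters: dense, heavier edges; cluster 4 heaviest
    for name, nodes in spans.items():
        idx = np.ix_(nodes, nodes)
        dense = rng.random((len(nodes), len(nodes))) < 0.75
        scale = 4.0 if name == "cluster4" else 1.6
        W[idx] = np.where(dense, rng.gamma(3.0, scale, dense.shape), W[idx])
    # strong homologous cross-hemisphere links for cluster 4
    for i in spans["cluster4"]:
        j = 65 - i
        w = rng.gamma(4.0, 4.0)
        W[i, j] = max(W[i, j], w)
        W[j, i] = max(W[j, i], w)
    np.fill_diagonal(W, 0.0)
    W = np.maximum(W, 0.0)
    # symmetrize support before row normalization (fibers are undirected)
    W = (W + W.T) / 2.0
    C = row_normalize(W)
    return NetworkSpec(
        C=C,
        L=L,
        hemisphere=hemisphere,
        clusters=clusters,
        seed=seed,
        raw_weights=W,
    )


# --------------------------------------------------------------------------
# Sweep
# --------------------------------------------------------------------------


def network_sweep(
    couplings,
    spec: NetworkSpec,
    pair_subset: int | None = None,
    min_window: int = DEFAULT_MIN_WINDOW,
    n_seeds: int = 1,
) -> list[SweepRecord]:
    """Sweep coupling K on the network; DFA/ML-DFA over node pairs."""
    from .critical_models import analyze_phase_pairs

    couplings = list(couplings)
    if any(b < a for a, b in zip(couplings, couplings[1:])):
        raise ParameterError("couplings must be sorted ascending")
    records = []
    for k_idx, K in enumerate(couplings):
        all_valid, all_expo, r_means = [], [], []
        for s in range(n_seeds):
            run_spec = replace(spec, coupling=float(K), seed=spec.seed + s)
            phases = network_simulate(run_spec)
            skip = phases.shape[1] // 10
            post = phases[:, skip:]
            _, r_mean = order_parameter(post)
            r_means.append(r_mean)
            rng = np.random.default_rng((spec.seed, k_idx, s))
            pairs = _select_pairs(spec.n_nodes, pair_subset, rng)
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
    for prev, cur in zip(records, records[1:]):
        cur.delta_kr = cur.control * cur.mean_order_r - prev.control * prev.mean_order_r
    return records
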