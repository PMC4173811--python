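"""End-to-end orchestration: configuration, pair analysis, file I/O, fixtures.

The analysis pipeline runs the stages in order: optional bandpass (stage
2), analytic-signal phase (3), unwrapping (4), phase difference (5), rate
of change (6), DFA fluctuation plot (7) and the ML-DFA linearity verdict.
Any stage failure is re-raised with the stage at which it occurred.

All randomness in a run descends from one root seed; per-component child
seeds are derived deterministically, so results with an explicit seed are
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

# the convenience function `dfa` shadows the submodule in the package
# namespace, so import the needed names directly
from .dfa import (
    DEFAULT_MIN_WINDOW,
    DEFAULT_N_WINDOWS,
    FluctuationPlot,
    dfa_fluctuations,
    make_windows,
    mldfa_validate,
)
from .errors import DegeneratePlotError, PhasecritError, ShapeError
from .phase import (
    SampledSignal,
    analytic_phase,
    bandpass,
    phase_difference,
    rate_of_change,
    unwrap,
)

__all__ = [
    "AnalysisConfig",
    "PairResult",
    "analyze_pair",
    "read_signal_csv",
    "write_signal_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_pair_result",
    "make_fixtures",
]

logger = logging.getLogger("phasecrit")

PIPELINE_STAGES = {
    2: "bandpass filtering",
    3: "instantaneous phase extraction",
    4: "phase unwrapping",
    5: "phase difference",
    6: "rate of change",
    7: "DFA fluctuation plot",
    8: "ML-DFA validation",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pair analysis.

    ``min_window`` is in samples; alternatively ``min_window_seconds``
    (converted as round(seconds * sampling rate) — the physiological
    convention, e.g. 1 s at 512 Hz = 512 samples).  ``trim`` drops that
    many samples per edge of the phase difference before differencing, to
    shed analytic-signal edge artifacts.
    """

    band: tuple[float, float] | None = None
    min_window: int | None = None
    min_window_seconds: float | None = None
    n_windows: int = DEFAULT_N_WINDOWS
    trim: int = 0
    seed: int = 0

    def resolve_min_window(self, sampling_rate: float) -> int:
        if self.min_window is not None:
            return int(self.min_window)
        if self.min_window_seconds is not None:
            return int(round(self.min_window_seconds * sampling_rate))
        return DEFAULT_MIN_WINDOW

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load a config from a YAML or JSON file."""
        import yaml

        with Path(path).open() as fh:
            data = yaml.safe_load(fh)  # JSON is a YAML subset
        if "band" in data and data["band"] is not None:
            data["band"] = tuple(data["band"])
        return cls(**data)


@dataclass(frozen=True)
class PairResult:
    """Outcome of the pipeline on one signal pair, with provenance."""

    valid: bool
    exponent: float | None
    best_model: str
    plot: FluctuationPlot
    labels: tuple[str, str]
    config_hash: str
    seed: int
    diagnostic: str = ""


def _stage(n: int, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PhasecritError as exc:
        raise type(exc)(
            f"[stage {n}: {PIPELINE_STAGES[n]}] {exc}"
        ) from exc


def analyze_pair(
    s1: SampledSignal, s2: SampledSignal, config: AnalysisConfig | None = None
) -> PairResult:
    """Run the full pipeline on an aligned signal pair.

    Raises a stage-labelled error on failure; a pair whose phase
    difference has no fluctuations at all (full synchronization) raises a
    DegeneratePlotError explaining that no exponent is defined.
    """
    config = config or AnalysisConfig()
    if len(s1) != len(s2) or s1.sampling_rate != s2.sampling_rate:
        raise ShapeError("signals must share length and sampling rate")
    if config.band is not None:
        s1 = _stage(2, bandpass, s1, *config.band)
        s2 = _stage(2, bandpass, s2, *config.band)
    p1 = _stage(4, unwrap, _stage(3, analytic_phase, s1))
    p2 = _stage(4, unwrap, _stage(3, analytic_phase, s2))
    from .phase import PhaseDifference

    diff = PhaseDifference(
        values=p1.values - p2.values,
        sampling_rate=s1.sampling_rate,
        labels=(s1.label, s2.label),
    )
    rate = _stage(6, rate_of_change, diff, trim=config.trim)
    if np.ptp(rate.values) == 0.0:
        raise DegeneratePlotError(
            f"[stage 7: {PIPELINE_STAGES[7]}] signals are fully "
            "synchronized: the rate of change of phase difference has no "
            "fluctuations and no exponent is defined"
        )
    min_window = config.resolve_min_window(s1.sampling_rate)
    scheme = _stage(
        7, make_windows, rate.values.size, min_window, config.n_windows
    )
    plot = _stage(7, dfa_fluctuations, rate, scheme)
    result = _stage(8, mldfa_validate, plot, config.seed)
    logger.debug(
        "pair (%s, %s): valid=%s best=%s exponent=%s",
        s1.label,
        s2.label,
        result.valid,
        result.best_model,
        result.exponent,
    )
    return PairResult(
        valid=result.valid,
        exponent=result.exponent,
        best_model=result.best_model,
        plot=plot,
        labels=(s1.label, s2.label),
        config_hash=config.hash(),
        seed=config.seed,
        diagnostic=result.diagnostic,
    )


# --------------------------------------------------------------------------
# File I/O: single/two-column signal CSV, square matrix CSV, label CSV
# --------------------------------------------------------------------------


def write_signal_csv(path, signal: SampledSignal, header: bool = True) -> None:
    """One value per row; optional single-cell header row with the label."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(f"{signal.label or 'signal'}\n")
        np.savetxt(fh, signal.values, fmt="%.12g")


def read_signal_csv(path, sampling_rate: float, label: str | None = None) -> SampledSignal:
    """Read a single-column (optionally headed) CSV/TSV signal.

    The sampling rate is always supplied by the caller, never inferred.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        rows = fh.read().split()
    try:
        values = [float(first.replace(",", " ").split()[0])]
        header_label = None
    except ValueError:
        values = []
        header_label = first
    values.extend(float(v) for v in rows)
    return SampledSignal(
        values=np.asarray(values),
        sampling_rate=sampling_rate,
        label=label or header_label or path.stem,
    )


def write_matrix_csv(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.12g")


def read_matrix_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def write_labels_csv(path, labels) -> None:
    with Path(path).open("w") as fh:
        fh.write("node_index,label\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i},{lab}\n")


def read_labels_csv(path) -> np.ndarray:
    import pandas as pd

    table = pd.read_csv(path)
    return table.sort_values("node_index")["label"].to_numpy()


def write_pair_result(stem, result: PairResult) -> None:
    """CSV of the fluctuation plot + JSON sidecar with the verdict."""
    stem = Path(stem)
    with open(f"{stem}.csv", "w") as fh:
        fh.write("window_size,fluctuation\n")
        for n, f in zip(result.plot.window_sizes, result.plot.fluctuations):
            fh.write(f"{n},{f:.12g}\n")
    sidecar = {
        "valid": result.valid,
        "exponent": result.exponent,
        "best_model": result.best_model,
        "labels": list(result.labels),
        "config_hash": result.config_hash,
        "seed": result.seed,
        "diagnostic": result.diagnostic,
    }
    with open(f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


# --------------------------------------------------------------------------
# Fixture generation
# --------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def make_fixtures(seed: int, out_dir) -> dict:
    """Write a deterministic fixture set and its manifest.

    Contents: FARIMA surrogate pairs (3 exponents x 2 noise levels), a
    small Ising run (48 x 48, 8,000 sweeps, 3 temperatures), a Kuramoto
    run (N = 50, 3 couplings), and a synthetic connectome with labels.
    Same seed, same bytes.
    """
    from .critical_models import IsingSpec, KuramotoSpec, ising_simulate, kuramoto_simulate
    from .network import synthetic_connectome
    from .surrogates import FarimaSpec, SurrogatePairSpec, surrogate_pair

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    def register(path, **params):
        manifest["files"][Path(path).name] = {
            "sha256": _sha256(path),
            **params,
        }

    root = np.random.default_rng(seed)
    for h_true in (0.55, 0.7, 0.85):
        for noise in (0.0, 0.5):
            sub = int(root.integers(0, 2**31 - 1))
            spec = SurrogatePairSpec(
                farima=FarimaSpec(d=h_true - 0.5, n=20_000, seed=sub),
                noise_sigma=noise,
            )
            s1, s2, _ = surrogate_pair(spec)
            name = f"surrogate_h{h_true:.2f}_noise{noise:.1f}"
            for tag, sig in (("x1", s1), ("x2", s2)):
                path = out / f"{name}_{tag}.csv"
                write_signal_csv(path, sig)
                register(path, true_H=h_true, noise_sigma=noise, seed=sub,
                         fs=spec.fs, omega=spec.omega)

    for T in (2.0, 2.4, 5.0):
        sub = int(root.integers(0, 2**31 - 1))
        series = ising_simulate(
            IsingSpec(temperature=T, lattice_size=48, n_sweeps=8000,
                      burn_in=1000, seed=sub)
        )
        path = out / f"ising_T{T:.1f}.csv"
        np.savetxt(path, series, delimiter=",", fmt="%.6g")
        register(path, temperature=T, lattice_size=48, n_sweeps=8000, seed=sub)

    for K in (0.0, 20.0, 40.0):
        sub = int(root.integers(0, 2**31 - 1))
        phases = kuramoto_simulate(
            KuramotoSpec(coupling=K, n_osc=50, n_steps=4000, seed=sub)
        )
        path = out / f"kuramoto_K{K:.0f}.csv"
        np.savetxt(path, phases, delimiter=",", fmt="%.8g")
        register(path, coupling=K, n_osc=50, n_steps=4000, seed=sub)

    conn_seed = int(root.integers(0, 2**31 - 1))
    spec = synthetic_connectome(conn_seed)
    write_matrix_csv(out / "connectome_C.csv", spec.C)
    write_matrix_csv(out / "connectome_L.csv", spec.L)
    write_labels_csv(out / "connectome_hemisphere.csv", spec.hemisphere)
    write_labels_csv(out / "connectome_clusters.csv", spec.clusters)
    for name in ("connectome_C.csv", "connectome_L.csv",
                 "connectome_hemisphere.csv", "connectome_clusters.csv"):
        register(out / name, seed=conn_seed, n_nodes=66)

    manifest_path = out / "manifest.json"
    with manifest_path.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote %d fixture files to %s", len(manifest["files"]), out)
    return manifest
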