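"""Synthetic concept manifolds with known ground-truth geometry.

Each concept is a Gaussian cloud in a ``V``-dimensional ambient space:
``x = center + B diag(sqrt(lambda)) z`` with ``z`` standard normal, ``B`` a
``V x k`` orthonormal basis and ``lambda`` an intrinsic variance spectrum.
This is exactly the low-rank anisotropic structure the geometric theory
describes, and it stands in for encoding-model or trial-averaged fMRI
activity patterns.  Because centers, spectra and bases are known,
:func:`ground_truth_geometry` provides the analytic (population) twin of
the estimation pipeline, used for recovery tests.

A measurement-noise model replicates each exemplar over trials with
additive Gaussian noise whose strength is set by the measurement SNR
(``SNR_m``): the variance of the noise-free activity across exemplars
divided by the mean trial-to-trial noise variance.  Noise can be
uncorrelated across units or share a random (Wishart-sampled) covariance;
trial averaging reduces its effective variance by the number of samples
averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ActivityDataset
from .exceptions import InputError
from .geometry import (
    ManifoldSummary,
    PairGeometry,
    geometry_grid,
    pair_geometry,
    summary_from_spectrum,
)

__all__ = [
    "ConceptSpec",
    "ManifoldSpec",
    "materialize",
    "sample_manifolds",
    "ground_truth_summary",
    "ground_truth_geometry",
    "add_measurement_noise",
    "trial_average",
    "noise_distortion_experiment",
]

RANDOM_BASIS = "random"


@dataclass
class ConceptSpec:
    """Generative description of one concept manifold."""

    center: np.ndarray
    spectrum: np.ndarray
    basis: np.ndarray | str = RANDOM_BASIS
    n_exemplars: int = 100

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if np.any(self.spectrum < 0):
            raise InputError("spectrum must be nonnegative")
        if self.n_exemplars < 1:
            raise InputError("n_exemplars must be >= 1")
        if not isinstance(self.basis, str):
            self.basis = np.asarray(self.basis, dtype=float)

    @property
    def intrinsic_dim(self) -> int:
        return int(self.spectrum.shape[0])


@dataclass
class ManifoldSpec:
    """Ground-truth description of a set of concept manifolds plus the
    trial-to-trial measurement-noise model."""

    ambient_dim: int
    concepts: dict = field(default_factory=dict)
    measurement_snr: float | None = None
    noise_correlated: bool = False
    n_trials: int = 1

    def __post_init__(self) -> None:
        if self.ambient_dim < 1:
            raise InputError("ambient_dim must be >= 1")
        if self.measurement_snr is not None and self.measurement_snr <= 0:
            raise InputError("measurement_snr must be > 0 when noise is enabled")
        if self.n_trials < 1:
            raise InputError("n_trials must be >= 1")
        for name, c in self.concepts.items():
            if c.center.shape != (self.ambient_dim,):
                raise InputError(f"concept {name!r}: center length != ambient_dim")
            if c.intrinsic_dim > self.ambient_dim:
                raise InputError(f"concept {name!r}: spectrum longer than ambient_dim")
            if not isinstance(c.basis, str):
                if c.basis.shape != (self.ambient_dim, c.intrinsic_dim):
                    raise InputError(f"concept {name!r}: basis shape mismatch")
                gram = c.basis.T @ c.basis
                if not np.allclose(gram, np.eye(c.intrinsic_dim), atol=1e-8):
                    raise InputError(f"concept {name!r}: basis not orthonormal")

    # -- JSON round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        concepts = {}
        for name, c in self.concepts.items():
            concepts[str(name)] = {
                "center": c.center.tolist(),
                "spectrum": c.spectrum.tolist(),
                "basis": c.basis if isinstance(c.basis, str) else c.basis.tolist(),
                "n_exemplars": c.n_exemplars,
            }
        return {
            "ambient_dim": self.ambient_dim,
            "concepts": concepts,
            "measurement_snr": self.measurement_snr,
            "noise_correlated": self.noise_correlated,
            "n_trials": self.n_trials,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ManifoldSpec":
        concepts = {
            name: ConceptSpec(
                center=c["center"],
                spectrum=c["spectrum"],
                basis=c.get("basis", RANDOM_BASIS),
                n_exemplars=int(c.get("n_exemplars", 100)),
            )
            for name, c in data["concepts"].items()
        }
        return cls(
            ambient_dim=int(data["ambient_dim"]),
            concepts=concepts,
            measurement_snr=data.get("measurement_snr"),
            noise_correlated=bool(data.get("noise_correlated", False)),
            n_trials=int(data.get("n_trials", 1)),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "ManifoldSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def random_orthonormal_basis(V: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish V-by-k orthonormal basis (QR with a deterministic sign fix)."""
    A = rng.standard_normal((V, k))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def _seed_streams(seed):
    """(basis, sampling, noise) seed streams derived from one master seed.

    The basis stream is drawn first, so :func:`materialize` followed by
    :func:`sample_manifolds` with the same seed reproduces a direct
    :func:`sample_manifolds` call on the un-materialized spec.
    """
    if isinstance(seed, np.random.SeedSequence):
        # fresh copy so repeated derivations are stateless and identical
        seed = np.random.SeedSequence(seed.entropy, spawn_key=seed.spawn_key)
    else:
        seed = np.random.SeedSequence(seed)
    return seed.spawn(3)


def materialize(spec: ManifoldSpec, seed=None) -> ManifoldSpec:
    """Resolve every ``"random"`` basis token into an explicit orthonormal
    basis, deterministically under ``seed``.  Explicit bases pass through
    unchanged."""
    basis_seq, _, _ = _seed_streams(seed)
    rng = np.random.default_rng(basis_seq)
    concepts = {}
    for name, c in spec.concepts.items():
        basis = c.basis
        if isinstance(basis, str):
            if basis != RANDOM_BASIS:
                raise InputError(f"unknown basis token {basis!r}")
            basis = random_orthonormal_basis(spec.ambient_dim, c.intrinsic_dim, rng)
        concepts[name] = ConceptSpec(
            center=c.center.copy(),
            spectrum=c.spectrum.copy(),
            basis=basis,
            n_exemplars=c.n_exemplars,
        )
    return ManifoldSpec(
        ambient_dim=spec.ambient_dim,
        concepts=concepts,
        measurement_snr=spec.measurement_snr,
        noise_correlated=spec.noise_correlated,
        n_trials=spec.n_trials,
    )


def sample_manifolds(spec: ManifoldSpec, seed=None) -> ActivityDataset:
    """Draw noiseless exemplars for every concept in the spec.

    Exemplars are ``center + B diag(sqrt(lambda)) z`` with ``z`` standard
    normal.  Reproducible under ``seed``; random bases are resolved with the
    same seed convention as :func:`materialize`.
    """
    mspec = materialize(spec, seed=seed)
    _, sample_seq, _ = _seed_streams(seed)
    streams = sample_seq.spawn(len(mspec.concepts))
    blocks, labels = [], []
    for (name, c), child in zip(mspec.concepts.items(), streams):
        rng = np.random.default_rng(child)
        Z = rng.standard_normal((c.n_exemplars, c.intrinsic_dim))
        X = c.center + (Z * np.sqrt(c.spectrum)) @ c.basis.T
        blocks.append(X)
        labels.append(np.repeat(name, c.n_exemplars))
    return ActivityDataset(
        patterns=np.vstack(blocks), labels=np.concatenate(labels)
    )


def ground_truth_summary(spec: ManifoldSpec, concept, seed=None) -> ManifoldSummary:
    """Population manifold summary computed directly from the spec."""
    if concept not in spec.concepts:
        raise InputError(f"unknown concept {concept!r}")
    c = spec.concepts[concept]
    if isinstance(c.basis, str):
        c = materialize(spec, seed=seed).concepts[concept]
    return summary_from_spectrum(c.center, c.spectrum, c.basis, n_exemplars=0)


def ground_truth_geometry(
    spec: ManifoldSpec, concept_a, concept_b, m: int, seed=None
) -> PairGeometry:
    """Analytic pairwise geometry from the spec's population quantities.

    Uses the same formulas and radii convention as the estimation pipeline
    (population radii ``r_i^2 = lambda_i``), so sample estimates converge to
    these values as the exemplar count grows.  If the spec carries
    ``"random"`` basis tokens, pass the same ``seed`` given to
    :func:`sample_manifolds`.
    """
    if any(isinstance(spec.concepts[c].basis, str) for c in (concept_a, concept_b) if c in spec.concepts):
        spec = materialize(spec, seed=seed)
    A = ground_truth_summary(spec, concept_a)
    B = ground_truth_summary(spec, concept_b)
    return pair_geometry(A, B, m)


def _noise_covariance_factor(
    V: int, target_var: float, correlated: bool, rng: np.random.Generator
) -> np.ndarray | float:
    """Return either a scalar std (uncorrelated) or a Cholesky-like factor L
    with noise = z @ L.T (correlated), mean unit variance scaled to target."""
    if not correlated:
        return float(np.sqrt(target_var))
    # Wishart-sampled full covariance with the trace matched to V*target_var.
    A = rng.standard_normal((V, V)) / np.sqrt(V)
    C = A @ A.T
    C *= target_var / np.mean(np.diag(C))
    # jitter keeps the Cholesky stable for near-singular draws
    L = np.linalg.cholesky(C + np.eye(V) * target_var * 1e-10)
    return L


def add_measurement_noise(
    dataset: ActivityDataset,
    measurement_snr: float,
    correlated: bool = False,
    n_trials: int = 1,
    seed=None,
) -> ActivityDataset:
    """Replicate exemplars over trials with additive Gaussian noise.

    The mean noise variance per unit equals (mean signal variance across
    exemplars) / ``measurement_snr``.  The signal is fixed per exemplar;
    noise is fresh per trial.  ``trial_id`` groups the trials of each
    exemplar.
    """
    if measurement_snr is None or measurement_snr <= 0:
        raise InputError("measurement_snr must be > 0")
    n_trials = int(n_trials)
    if n_trials < 1:
        raise InputError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = dataset.patterns
    n, V = X.shape
    signal_var = float(X.var(axis=0, ddof=0).mean())
    if signal_var <= 0:
        raise InputError("dataset has zero signal variance; SNR_m is undefined")
    target_var = signal_var / measurement_snr
    factor = _noise_covariance_factor(V, target_var, correlated, rng)
    reps = np.repeat(X, n_trials, axis=0)
    Z = rng.standard_normal((n * n_trials, V))
    noise = Z @ factor.T if isinstance(factor, np.ndarray) else Z * factor
    return ActivityDataset(
        patterns=reps + noise,
        labels=np.repeat(dataset.labels, n_trials),
        trial_id=np.repeat(np.arange(n), n_trials),
        unit_ids=None if dataset.unit_ids is None else list(dataset.unit_ids),
    )


def trial_average(dataset: ActivityDataset, n_samples: int, seed=None) -> ActivityDataset:
    """Average ``n_samples`` seed-selected trials of each exemplar into one
    row; residual noise variance drops by the factor ``n_samples``."""
    if dataset.trial_id is None:
        raise InputError("dataset has no trial_id column")
    n_samples = int(n_samples)
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = pd.unique(dataset.trial_id)
    rows, labels = [], []
    for t in order:
        idx = np.flatnonzero(dataset.trial_id == t)
        if idx.size < n_samples:
            raise InputError(
                f"exemplar {t} has {idx.size} trials, fewer than n_samples={n_samples}"
            )
        pick = idx if idx.size == n_samples else rng.choice(idx, size=n_samples, replace=False)
        rows.append(dataset.patterns[pick].mean(axis=0))
        labels.append(dataset.labels[idx[0]])
    return ActivityDataset(
        patterns=np.asarray(rows),
        labels=np.asarray(labels),
        trial_id=None,
        unit_ids=None if dataset.unit_ids is None else list(dataset.unit_ids),
    )


_EST_PROPS = ["snr", "signal", "bias", "combined_overlap"]


def noise_distortion_experiment(
    spec: ManifoldSpec,
    snr_grid,
    n_samples_list,
    m: int,
    seed=None,
    correlated_flags=(False, True),
) -> pd.DataFrame:
    """Estimated vs true geometry across a measurement-noise grid.

    For each (measurement SNR, trial-average count, correlated flag) cell,
    the same noiseless exemplars are corrupted with trial noise, trial
    averaged, and run through the estimation pipeline.  Estimates are
    averaged over ordered concept pairs (Dimensionality over concepts) and
    reported alongside the population ground-truth values.
    """
    snr_grid = list(snr_grid)
    n_samples_list = list(n_samples_list)
    if not snr_grid or not n_samples_list:
        raise InputError("snr_grid and n_samples_list must be nonempty")
    max_trials = max(n_samples_list)
    mspec = materialize(spec, seed=seed)
    _, _, noise_seq = _seed_streams(seed)
    base = sample_manifolds(mspec, seed=seed)

    names = list(mspec.concepts)
    true_pairs = [
        ground_truth_geometry(mspec, a, b, m)
        for a in names
        for b in names
        if a != b
    ]
    truth = {
        "true_snr": float(np.mean([p.snr for p in true_pairs])),
        "true_signal": float(np.mean([p.signal for p in true_pairs])),
        "true_bias": float(np.mean([p.bias for p in true_pairs])),
        "true_combined_overlap": float(
            np.mean([p.combined_overlap for p in true_pairs])
        ),
        "true_dimensionality": float(
            np.mean([ground_truth_summary(mspec, c).dimensionality for c in names])
        ),
    }

    cells = [
        (corr, s)
        for corr in correlated_flags
        for s in snr_grid
    ]
    cell_seqs = noise_seq.spawn(len(cells) * 2)
    rows = []
    for i, (corr, snr_m) in enumerate(cells):
        noisy = add_measurement_noise(
            base, snr_m, correlated=corr, n_trials=max_trials,
            seed=np.random.default_rng(cell_seqs[2 * i]),
        )
        avg_rng = np.random.default_rng(cell_seqs[2 * i + 1])
        for n_s in n_samples_list:
            averaged = trial_average(noisy, n_s, seed=avg_rng)
            grid = geometry_grid(averaged, m)
            row = {
                "measurement_snr": float(snr_m),
                "n_samples": int(n_s),
                "correlated": bool(corr),
            }
            for prop in _EST_PROPS:
                row[f"est_{prop}"] = float(grid.pairs[prop].mean())
            row["est_dimensionality"] = float(grid.concepts["dimensionality"].mean())
            row.update(truth)
            rows.append(row)
    return pd.DataFrame(rows)
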