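"""Probabilistic sleep stagers emitting per-epoch five-class posteriors.

Two stagers are provided, both returning a :class:`PosteriorMatrix` whose
rows live on the probability simplex:

* a hidden Markov model whose per-stage emission densities are Gaussian
  kernel density estimates over the spectral feature space, decoded with the
  forward–backward algorithm into exact smoothed marginals
  ``P(stage_t | all epochs)``;
* a multilayer perceptron (hidden layers ``[32, 64, 32]``, ReLU) whose
  softmax outputs provide per-epoch probabilities directly.

The HMM's transition and initial distributions are estimated from labelled
training data as add-one-smoothed bigram/unigram frequencies.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.neighbors import KernelDensity
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .exceptions import FormatError, ValidationError
from .features import SpectralFeatures
from .stages import N_STAGES, STAGE_LABELS, Hypnogram, require_same_length

SERIALIZATION_VERSION = 1

#: Emission log-densities are floored here so one outlying epoch cannot
#: poison the whole forward pass with -inf.
LOG_DENSITY_FLOOR = -700.0

POSTERIOR_COLUMNS = ["p_W", "p_REM", "p_N1", "p_N2", "p_N3"]


@dataclass
class PosteriorMatrix:
    """T×5 per-epoch class probabilities; every row sums to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_STAGES:
            raise ValidationError(f"posterior matrix must be T x {N_STAGES}, got {self.probs.shape}")
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-9).any():
            raise ValidationError("posterior entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"posterior row {int(bad[0])} sums to {sums[bad[0]]:.12f}, not 1"
            )
        np.clip(self.probs, 0.0, 1.0, out=self.probs)

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[0]

    def __len__(self) -> int:
        return self.n_epochs

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.probs, columns=POSTERIOR_COLUMNS)
        frame.insert(0, "epoch_index", np.arange(self.n_epochs))
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorMatrix":
        frame = pd.read_csv(path)
        missing = [c for c in ["epoch_index", *POSTERIOR_COLUMNS] if c not in frame.columns]
        if missing:
            raise FormatError(f"posterior CSV {path} is missing column(s) {missing}")
        frame = frame.sort_values("epoch_index")
        return cls(probs=frame[POSTERIOR_COLUMNS].to_numpy(dtype=float))


class StageDensity:
    """Gaussian KDE over one stage's feature rows, per-dimension bandwidth.

    Features are standardised per dimension and a single Scott/Silverman
    bandwidth factor is applied in the scaled space, which is equivalent to a
    diagonal bandwidth matrix proportional to the per-dimension spread.  A
    log-Jacobian term converts scored densities back to the original scale.
    """

    def __init__(self, data: np.ndarray, bandwidth_rule: str | float = "scott") -> None:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        n, d = data.shape
        if n < 1:
            raise ValidationError("cannot fit a density to zero samples")
        self.loc_ = data.mean(axis=0)
        self.scale_ = np.maximum(data.std(axis=0), 1e-6)
        if isinstance(bandwidth_rule, str):
            if bandwidth_rule == "scott":
                factor = n ** (-1.0 / (d + 4))
            elif bandwidth_rule == "silverman":
                factor = (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))
            else:
                raise ValidationError(f"unknown bandwidth rule {bandwidth_rule!r}")
        else:
            factor = float(bandwidth_rule)
            if factor <= 0:
                raise ValidationError("bandwidth factor must be positive")
        self._kde = KernelDensity(kernel="gaussian", bandwidth=factor)
        self._kde.fit((data - self.loc_) / self.scale_)
        self._log_jacobian = float(np.log(self.scale_).sum())

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._kde.score_samples((X - self.loc_) / self.scale_) - self._log_jacobian


@dataclass
class HmmModel:
    """KDE-emission HMM over the five sleep stages.

    ``emissions[i]`` is the fitted density for stage ``i`` or ``None`` when
    the stage was absent from training, in which case a flat (constant
    log-density 0) fallback is used.
    """

    transition: np.ndarray
    initial: np.ndarray
    emissions: list  # list[StageDensity | None]
    bandwidth_rule: str | float = "scott"

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-12:
            raise ValidationError("HMM transition rows must sum to 1")
        if abs(self.initial.sum() - 1) > 1e-12:
            raise ValidationError("HMM initial distribution must sum to 1")
        if len(self.emissions) != N_STAGES:
            raise ValidationError(f"need {N_STAGES} emission densities")

    def log_likelihoods(self, features: SpectralFeatures) -> np.ndarray:
        """T×5 emission log-densities, floored at :data:`LOG_DENSITY_FLOOR`."""
        out = np.zeros((features.n_epochs, N_STAGES), dtype=float)
        for stage, density in enumerate(self.emissions):
            if density is not None:
                out[:, stage] = density.score_samples(features.matrix)
        return np.maximum(out, LOG_DENSITY_FLOOR)

    def predict_posteriors(self, features: SpectralFeatures) -> PosteriorMatrix:
        return forward_backward(self.log_likelihoods(features), self.transition, self.initial)


def fit_hmm(
    features: SpectralFeatures,
    labels: Hypnogram,
    bandwidth_rule: str | float = "scott",
) -> HmmModel:
    """Fit the KDE-emission HMM from one or more labelled nights.

    Transition probabilities are label bigram frequencies with add-one
    pseudocounts, row-normalised; the initial distribution uses the same
    smoothing on unigram frequencies (so no stage ever gets exactly zero
    initial mass).  One kernel density estimate is fitted per stage on that
    stage's feature rows; a stage absent from training gets a flat emission
    fallback and a warning.
    """
    T = require_same_length(features.matrix, labels.stages, what="features and labels")
    if T == 0:
        raise ValidationError("cannot fit an HMM to zero epochs")
    codes = labels.stages
    transition_counts = np.ones((N_STAGES, N_STAGES), dtype=float)
    np.add.at(transition_counts, (codes[:-1], codes[1:]), 1.0)
    transition = transition_counts / transition_counts.sum(axis=1, keepdims=True)
    initial_counts = np.ones(N_STAGES, dtype=float) + np.bincount(codes, minlength=N_STAGES)
    initial = initial_counts / initial_counts.sum()

    emissions: list[StageDensity | None] = []
    for stage in range(N_STAGES):
        rows = features.matrix[codes == stage]
        if rows.shape[0] == 0:
            warnings.warn(
                f"stage {STAGE_LABELS[stage]} absent from training; using flat emission fallback",
                stacklevel=2,
            )
            emissions.append(None)
        else:
            emissions.append(StageDensity(rows, bandwidth_rule=bandwidth_rule))
    return HmmModel(transition=transition, initial=initial, emissions=emissions,
                    bandwidth_rule=bandwidth_rule)


def forward_backward(
    log_likelihoods: np.ndarray,
    transition: np.ndarray,
    initial: np.ndarray,
) -> PosteriorMatrix:
    """Exact smoothed state marginals ``P(stage_t | all epochs)``.

    Implemented entirely in the log domain with per-step log-sum-exp, so
    arbitrarily small emission likelihoods cannot underflow.
    """
    log_likelihoods = np.asarray(log_likelihoods, dtype=float)
    transition = np.asarray(transition, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if log_likelihoods.ndim != 2 or log_likelihoods.shape[1] != N_STAGES:
        raise ValidationError("log_likelihoods must be T x 5")
    if not np.isfinite(log_likelihoods).all():
        raise ValidationError("log_likelihoods must be finite")
    row_sums = transition.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValidationError(f"transition row {int(np.argmin(row_sums))} sums to zero")
    if np.abs(row_sums - 1).max() > 1e-9 or abs(initial.sum() - 1) > 1e-9:
        raise ValidationError("transition rows and initial distribution must sum to 1")

    T = log_likelihoods.shape[0]
    with np.errstate(divide="ignore"):
        log_transition = np.log(transition)
        log_initial = np.log(initial)

    log_alpha = np.empty((T, N_STAGES))
    log_alpha[0] = log_initial + log_likelihoods[0]
    for t in range(1, T):
        log_alpha[t] = (
            logsumexp(log_alpha[t - 1][:, None] + log_transition, axis=0) + log_likelihoods[t]
        )
    log_beta = np.zeros((T, N_STAGES))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(
            log_transition + (log_likelihoods[t + 1] + log_beta[t + 1])[None, :], axis=1
        )
    log_posterior = log_alpha + log_beta
    log_posterior -= logsumexp(log_posterior, axis=1, keepdims=True)
    return PosteriorMatrix(probs=np.exp(log_posterior))


def estimate_hypnogram(posteriors: PosteriorMatrix, epoch_seconds: float = 30.0) -> Hypnogram:
    """Per-epoch arg-max of the posterior rows; ties go to the lowest code."""
    return Hypnogram(stages=np.argmax(posteriors.probs, axis=1), epoch_seconds=epoch_seconds)


@dataclass
class MlpModel:
    """Standardised-input MLP stager (hidden layers [32, 64, 32], ReLU)."""

    scaler: StandardScaler
    classifier: MLPClassifier
    classes: np.ndarray = field(default_factory=lambda: np.arange(N_STAGES))

    def predict_posteriors(self, features: SpectralFeatures) -> PosteriorMatrix:
        scaled = self.scaler.transform(features.matrix)
        proba = self.classifier.predict_proba(scaled)
        full = np.zeros((proba.shape[0], N_STAGES), dtype=float)
        full[:, self.classifier.classes_.astype(int)] = proba
        return PosteriorMatrix(probs=full)


def fit_mlp(
    features: SpectralFeatures,
    labels: Hypnogram,
    seed: int = 0,
    hidden_layer_sizes: tuple[int, ...] = (32, 64, 32),
    max_iter: int = 500,
) -> MlpModel:
    """Train the softmax MLP stager; deterministic for a fixed seed."""
    require_same_length(features.matrix, labels.stages, what="features and labels")
    present = np.unique(labels.stages)
    if present.size < 2:
        raise ValidationError(
            f"MLP training requires at least two stages; got only {STAGE_LABELS[present[0]]}"
            if present.size else "MLP training requires non-empty data"
        )
    scaler = StandardScaler().fit(features.matrix)
    classifier = MLPClassifier(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        random_state=int(seed),
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        # non-convergence at max_iter is acceptable for a fixed-budget fit
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        classifier.fit(scaler.transform(features.matrix), labels.stages)
    return MlpModel(scaler=scaler, classifier=classifier)


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted stager to a single version-tagged archive."""
    payload = {
        "format": "sleepuq-model",
        "version": SERIALIZATION_VERSION,
        "kind": type(model).__name__,
        "model": model,
    }
    with open(path, "wb") as handle:
        pickle.dump(payload, handle)


def load_model(path: str | Path):
    try:
        with open(path, "rb") as handle:
            payload = pickle.load(handle)
    except (pickle.UnpicklingError, EOFError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path} is not a sleepuq model archive: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "sleepuq-model":
        raise FormatError(f"{path} is not a sleepuq model archive")
    if payload.get("version") != SERIALIZATION_VERSION:
        raise FormatError(f"unsupported model archive version {payload.get('version')}")
    return payload["model"]
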