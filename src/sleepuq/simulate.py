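"""Synthetic polysomnography: Markov hypnograms and stage-structured EEG.

The simulator produces, for one "study night", a ground-truth hypnogram drawn
from a five-state Markov chain and a matching single-channel EEG trace whose
spectral content depends on the current stage.  It exists so that every
downstream step — feature extraction, staging, uncertainty flagging, targeted
review, agreement scoring — can be exercised end to end without any recorded
data.

Two knobs shape the night:

* ``stage_spectra`` gives each stage a relative band-power profile over the
  classical EEG bands (delta 0.5–4, theta 4–8, alpha 8–12, sigma 12–16, beta
  16–30 Hz).  The defaults follow textbook sleep EEG: wake is alpha/beta rich,
  REM and N1 are theta dominant (and hence spectrally close, as they are in
  real recordings), N2 carries sigma-band spindle power, N3 is overwhelmingly
  delta.
* ``fragmentation`` mixes the base transition matrix toward a near-uniform
  one, ``(1 - w)·T_base + w·T_frag`` with ``w = min(fragmentation, 1)``.
  Higher values yield more stage transitions per night, the hallmark of
  sleep-fragmenting disease such as obstructive sleep apnea, and serve as a
  severity proxy without modelling respiration itself.

Band-limited activity is realised as filtered Gaussian noise (not sinusoids)
so that multitaper spectral estimates carry realistic variance.  All
randomness flows from the single integer ``seed`` through a splittable
:class:`numpy.random.SeedSequence`: the hypnogram and the EEG consume
independent child streams, so regenerating either is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from .exceptions import ValidationError
from .stages import N_STAGES, STAGE_LABELS, Hypnogram

BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "sigma", "beta")
SIM_BAND_EDGES: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 16.0),
    (16.0, 30.0),
)

# Stylized base architecture: strong self-transitions with physiologically
# ordered off-diagonal mass (W drifts to N1, N1 deepens to N2, N2 to N3 or
# REM, N3 lightens through N2).  Rows follow the W, REM, N1, N2, N3 order.
DEFAULT_TRANSITION = np.array(
    [
        [0.90, 0.01, 0.07, 0.02, 0.00],
        [0.02, 0.90, 0.04, 0.04, 0.00],
        [0.06, 0.04, 0.80, 0.10, 0.00],
        [0.02, 0.03, 0.04, 0.86, 0.05],
        [0.01, 0.01, 0.00, 0.08, 0.90],
    ]
)

# Fragmentation target: the maximally unstructured (uniform) chain.
FRAGMENTED_TRANSITION = np.full((N_STAGES, N_STAGES), 1.0 / N_STAGES)

# Nights begin awake or in light sleep.
DEFAULT_INITIAL = np.array([0.85, 0.00, 0.15, 0.00, 0.00])

# Relative band power per stage over (delta, theta, alpha, sigma, beta).
DEFAULT_STAGE_SPECTRA = np.array(
    [
        [0.05, 0.10, 0.50, 0.05, 0.30],  # W: posterior alpha + beta arousal
        [0.10, 0.50, 0.10, 0.05, 0.25],  # REM: theta with beta admixture
        [0.15, 0.55, 0.15, 0.05, 0.10],  # N1: theta, close to REM
        [0.25, 0.20, 0.10, 0.40, 0.05],  # N2: sigma spindles over mixed slow
        [0.75, 0.12, 0.05, 0.05, 0.03],  # N3: delta dominated
    ]
)

DEFAULT_NOISE_FLOOR = 0.05


def _check_simplex(vector: np.ndarray, name: str, atol: float = 1e-12) -> None:
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (N_STAGES,):
        raise ValidationError(f"{name} must have shape ({N_STAGES},), got {vector.shape}")
    if (vector < 0).any():
        raise ValidationError(f"{name} has negative entries")
    if abs(vector.sum() - 1.0) > atol:
        raise ValidationError(f"{name} must sum to 1 (got {vector.sum():.15f})")


def _check_stochastic(matrix: np.ndarray, name: str, atol: float = 1e-12) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_STAGES, N_STAGES):
        raise ValidationError(f"{name} must be {N_STAGES}x{N_STAGES}, got {matrix.shape}")
    if (matrix < 0).any():
        raise ValidationError(f"{name} has negative entries")
    sums = matrix.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > atol)[0]
    if bad.size:
        row = int(bad[0])
        raise ValidationError(
            f"{name} row {row} ({STAGE_LABELS[row]}) sums to {sums[row]:.15f}, not 1"
        )


@dataclass
class SyntheticStudyConfig:
    """Parameters of one simulated study night.

    Attributes
    ----------
    n_epochs
        Number of 30-s epochs to simulate (a full night is ~960).
    transition_matrix, initial_distribution
        Base Markov-chain parameters over the fixed stage order.
    stage_spectra
        5×5 relative band powers, rows = stages, columns = (delta, theta,
        alpha, sigma, beta).  Units are relative: only ratios matter.
    noise_floor
        Relative broadband white-noise power added to every epoch.
    band_variability
        Standard deviation of the per-epoch, per-band log-normal amplitude
        gain.  Real sleep EEG shows large epoch-to-epoch power fluctuations
        within a stage; 0 makes every epoch of a stage spectrally identical
        (and staging unrealistically easy), the default 0.5 yields the
        within-stage spread and between-stage overlap that make
        single-channel staging genuinely imperfect.
    fragmentation
        Convex mixing weight (≥ 0, clipped at 1) toward the uniform
        transition matrix; 0 = consolidated sleep, larger = more fragmented.
    sample_rate_hz, epoch_seconds
        Signal sampling rate (250 Hz default) and epoch duration (30 s).
    seed
        Single integer seed; all randomness derives from it.
    """

    n_epochs: int = 960
    transition_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    initial_distribution: np.ndarray = field(default_factory=lambda: DEFAULT_INITIAL.copy())
    stage_spectra: np.ndarray = field(default_factory=lambda: DEFAULT_STAGE_SPECTRA.copy())
    noise_floor: float = DEFAULT_NOISE_FLOOR
    band_variability: float = 0.5
    fragmentation: float = 0.0
    sample_rate_hz: float = 250.0
    epoch_seconds: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.stage_spectra = np.asarray(self.stage_spectra, dtype=float)

    def validate(self) -> None:
        if self.n_epochs < 0:
            raise ValidationError("n_epochs must be non-negative")
        _check_stochastic(self.transition_matrix, "transition_matrix")
        _check_simplex(self.initial_distribution, "initial_distribution")
        if self.stage_spectra.shape != (N_STAGES, len(BAND_NAMES)):
            raise ValidationError(
                f"stage_spectra must be {N_STAGES}x{len(BAND_NAMES)}, got {self.stage_spectra.shape}"
            )
        if (self.stage_spectra < 0).any():
            raise ValidationError("stage_spectra band powers must be non-negative")
        if self.noise_floor < 0:
            raise ValidationError("noise_floor must be non-negative")
        if self.band_variability < 0:
            raise ValidationError("band_variability must be non-negative")
        if self.fragmentation < 0:
            raise ValidationError("fragmentation must be >= 0")
        if not self.sample_rate_hz > 0 or not self.epoch_seconds > 0:
            raise ValidationError("sample_rate_hz and epoch_seconds must be positive")

    @property
    def effective_transition(self) -> np.ndarray:
        """Fragmentation-mixed transition matrix ``(1-w)·T_base + w·T_frag``."""
        w = min(float(self.fragmentation), 1.0)
        return (1.0 - w) * self.transition_matrix + w * FRAGMENTED_TRANSITION

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_seconds * self.sample_rate_hz))

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        for key in ("transition_matrix", "initial_distribution", "stage_spectra"):
            raw[key] = np.asarray(raw[key]).tolist()
        return raw

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticStudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticStudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_hypnogram(config: SyntheticStudyConfig) -> Hypnogram:
    """Draw a ground-truth hypnogram from the configured Markov chain.

    The chain uses the fragmentation-mixed transition matrix; an identical
    config (including seed) always yields the identical stage sequence.
    """
    config.validate()
    rng, _ = _rng_children(config.seed, 2)
    transition = config.effective_transition
    cumulative = np.cumsum(transition, axis=1)
    initial_cumulative = np.cumsum(config.initial_distribution)

    n = config.n_epochs
    stages = np.empty(n, dtype=np.int64)
    if n == 0:
        return Hypnogram(stages=stages, epoch_seconds=config.epoch_seconds)
    draws = rng.random(n)
    stages[0] = np.searchsorted(initial_cumulative, draws[0], side="right")
    for t in range(1, n):
        stages[t] = np.searchsorted(cumulative[stages[t - 1]], draws[t], side="right")
    np.clip(stages, 0, N_STAGES - 1, out=stages)  # guard searchsorted edge at u ~ 1
    return Hypnogram(stages=stages, epoch_seconds=config.epoch_seconds)


def generate_eeg(hypnogram: Hypnogram, config: SyntheticStudyConfig) -> np.ndarray:
    """Synthesize single-channel EEG matching a hypnogram.

    Each epoch is a weighted sum of five band-limited Gaussian processes
    (weights = the square roots of that stage's relative band powers) plus a
    broadband white-noise floor.  Band processes are produced by zero-phase
    Butterworth filtering of full-length white noise and normalised to unit
    variance before weighting, so relative powers translate directly into
    relative band variance.

    Returns
    -------
    numpy.ndarray
        Signal of length ``n_epochs * epoch_seconds * sample_rate_hz`` in
        arbitrary units.
    """
    config.validate()
    present = np.unique(hypnogram.stages)
    for stage in present:
        if config.stage_spectra[stage].sum() <= 0:
            raise ValidationError(
                f"stage {STAGE_LABELS[stage]} is present but has zero total band power"
            )
    epoch_len = config.epoch_samples
    n_samples = hypnogram.n_epochs * epoch_len
    if n_samples == 0:
        return np.empty(0, dtype=float)

    _, rng = _rng_children(config.seed, 2)
    nyquist = config.sample_rate_hz / 2.0
    # per-epoch amplitude gains emulate within-stage power fluctuation
    gains = rng.lognormal(
        mean=0.0,
        sigma=config.band_variability,
        size=(hypnogram.n_epochs, len(SIM_BAND_EDGES)),
    )
    out = np.zeros(n_samples, dtype=float)
    for band_index, (low, high) in enumerate(SIM_BAND_EDGES):
        weights = np.sqrt(config.stage_spectra[:, band_index])
        if not weights.any():
            continue
        high = min(high, 0.99 * nyquist)
        sos = sps.butter(4, (low, high), btype="bandpass", output="sos", fs=config.sample_rate_hz)
        band_noise = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
        scale = band_noise.std()
        if scale > 0:
            band_noise /= scale
        amplitude = weights[hypnogram.stages] * gains[:, band_index]
        out += np.repeat(amplitude, epoch_len) * band_noise
    if config.noise_floor > 0:
        out += np.sqrt(config.noise_floor) * rng.standard_normal(n_samples)
    return out


def simulate_night(config: SyntheticStudyConfig) -> tuple[Hypnogram, np.ndarray]:
    """Convenience wrapper: one call for (ground-truth hypnogram, EEG)."""
    hypnogram = generate_hypnogram(config)
    return hypnogram, generate_eeg(hypnogram, config)
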