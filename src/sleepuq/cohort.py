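"""End-to-end simulated studies: train a stager, score a cohort of nights.

A "study" mirrors the canonical evaluation protocol: a training set of
simulated nights stratified by sleep-fragmentation severity (the OSA-severity
proxy), a held-out test set with the same stratification, and — per test
night — the four scoring methods, Cohen's Kappa for each, the review burden,
the entropy trace and the certain/uncertain stratification.  The default
cohort is 4 training nights (one per severity grade) and 10 test nights
(4 normal, 2 per OSA grade), each 960 thirty-second epochs at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import (
    EntropyDistributionSummary,
    certainty_confusion,
    cohens_kappa,
    entropy_distribution_summary,
)
from .exceptions import ValidationError
from .features import (
    DEFAULT_BAND_EDGES,
    SpectralFeatures,
    bandpass_zero_phase,
    multitaper_epoch_features,
)
from .review import ALL_METHODS, ReviewPolicy, apply_scoring_methods
from .simulate import SyntheticStudyConfig, generate_eeg, generate_hypnogram
from .stages import Hypnogram
from .stagers import PosteriorMatrix, estimate_hypnogram, fit_hmm, fit_mlp
from .uncertainty import FlagSequence, UncertaintyTrace, flag_uncertain, uncertainty_trace

#: Fragmentation grades standing in for OSA severity classes.
SEVERITY_FRAGMENTATION = {"HN": 0.0, "mild": 0.1, "moderate": 0.25, "severe": 0.4}

DEFAULT_TRAIN_FRAGMENTATIONS = (0.0, 0.1, 0.25, 0.4)
DEFAULT_TEST_FRAGMENTATIONS = (0.0, 0.0, 0.0, 0.0, 0.1, 0.1, 0.25, 0.25, 0.4, 0.4)


@dataclass
class CohortConfig:
    """Study-level configuration: who is simulated and how they are staged."""

    train_fragmentations: tuple = DEFAULT_TRAIN_FRAGMENTATIONS
    test_fragmentations: tuple = DEFAULT_TEST_FRAGMENTATIONS
    n_epochs: int = 960
    stager: str = "hmm"  # "hmm" or "mlp"
    measure: str = "shannon"
    night_config: SyntheticStudyConfig = field(default_factory=SyntheticStudyConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stager not in ("hmm", "mlp"):
            raise ValidationError(f"stager must be 'hmm' or 'mlp', got {self.stager!r}")


@dataclass
class NightResult:
    """Everything computed for one held-out test night."""

    fragmentation: float
    truth: Hypnogram
    automated: Hypnogram
    posteriors: PosteriorMatrix
    trace: UncertaintyTrace
    flags: FlagSequence
    methods: dict  # method name -> ReviewedHypnogram
    kappas: dict  # method name -> float
    n_flagged: int
    burden: float


@dataclass
class StudyResult:
    """Per-night results plus pooled summaries for a whole study."""

    nights: list
    config: CohortConfig
    policy: ReviewPolicy

    def kappa_frame(self) -> pd.DataFrame:
        rows = []
        for i, night in enumerate(self.nights):
            rows.append(
                {
                    "night": i,
                    "fragmentation": night.fragmentation,
                    "n_flagged": night.n_flagged,
                    "burden": night.burden,
                    **{m: night.kappas[m] for m in ALL_METHODS},
                }
            )
        return pd.DataFrame(rows)

    def pooled_entropy_summary(self, fit_kde: bool = False) -> EntropyDistributionSummary:
        trace = UncertaintyTrace(
            values=np.concatenate([n.trace.values for n in self.nights]),
            measure=self.nights[0].trace.measure,
        )
        truth = Hypnogram(np.concatenate([n.truth.stages for n in self.nights]))
        estimate = Hypnogram(np.concatenate([n.automated.stages for n in self.nights]))
        return entropy_distribution_summary(trace, truth, estimate, fit_kde=fit_kde)

    def pooled_certainty_confusion(self):
        truth = Hypnogram(np.concatenate([n.truth.stages for n in self.nights]))
        estimate = Hypnogram(np.concatenate([n.automated.stages for n in self.nights]))
        flags = FlagSequence(
            flags=np.concatenate([n.flags.flags for n in self.nights]),
            threshold=self.policy.threshold,
        )
        return certainty_confusion(truth, estimate, flags)

    def flagged_vs_unflagged_accuracy(self) -> tuple[float, float]:
        """Per-epoch accuracy among flagged and among unflagged epochs, pooled."""
        correct = np.concatenate(
            [n.truth.stages == n.automated.stages for n in self.nights]
        )
        flagged = np.concatenate([n.flags.flags for n in self.nights]).astype(bool)
        flagged_acc = float(correct[flagged].mean()) if flagged.any() else float("nan")
        unflagged_acc = float(correct[~flagged].mean()) if (~flagged).any() else float("nan")
        return flagged_acc, unflagged_acc


def simulate_and_featurize(
    config: SyntheticStudyConfig,
) -> tuple[Hypnogram, SpectralFeatures]:
    """One night: hypnogram + EEG + filtered multitaper features."""
    hypnogram = generate_hypnogram(config)
    signal = generate_eeg(hypnogram, config)
    filtered = bandpass_zero_phase(
        signal, 0.1, 50.0, sample_rate_hz=config.sample_rate_hz
    )
    features = multitaper_epoch_features(
        filtered, config.sample_rate_hz, epoch_seconds=config.epoch_seconds
    )
    return hypnogram, features


def _night_configs(config: CohortConfig, fragmentations, seeds) -> list[SyntheticStudyConfig]:
    return [
        replace(
            config.night_config,
            n_epochs=config.n_epochs,
            fragmentation=float(frag),
            seed=int(seed),
        )
        for frag, seed in zip(fragmentations, seeds)
    ]


def run_study(
    config: CohortConfig | None = None,
    policy: ReviewPolicy | None = None,
) -> StudyResult:
    """Train on the training nights, evaluate all four methods on each test night."""
    config = config or CohortConfig()
    policy = policy or ReviewPolicy()
    n_train = len(config.train_fragmentations)
    n_test = len(config.test_fragmentations)
    seed_seq = np.random.SeedSequence(config.seed)
    # one 32-bit seed per night, plus one for the stager and one per-night reviewer
    raw = seed_seq.generate_state(n_train + 2 * n_test + 1).astype(np.int64) % (2**31)
    train_seeds = raw[:n_train]
    test_seeds = raw[n_train : n_train + n_test]
    reviewer_seeds = raw[n_train + n_test : n_train + 2 * n_test]
    stager_seed = int(raw[-1])

    train_feature_blocks = []
    train_label_blocks = []
    for night_cfg in _night_configs(config, config.train_fragmentations, train_seeds):
        hypnogram, features = simulate_and_featurize(night_cfg)
        train_feature_blocks.append(features.matrix)
        train_label_blocks.append(hypnogram.stages)
    train_features = SpectralFeatures(
        matrix=np.vstack(train_feature_blocks),
        freq_bins=np.array([(lo + hi) / 2 for lo, hi in DEFAULT_BAND_EDGES]),
        band_edges=DEFAULT_BAND_EDGES,
        epoch_seconds=config.night_config.epoch_seconds,
    )
    train_labels = Hypnogram(np.concatenate(train_label_blocks))

    if config.stager == "hmm":
        model = fit_hmm(train_features, train_labels)
    else:
        model = fit_mlp(train_features, train_labels, seed=stager_seed)

    nights = []
    for night_cfg, reviewer_seed in zip(
        _night_configs(config, config.test_fragmentations, test_seeds), reviewer_seeds
    ):
        truth, features = simulate_and_featurize(night_cfg)
        posteriors = model.predict_posteriors(features)
        automated = estimate_hypnogram(posteriors, epoch_seconds=night_cfg.epoch_seconds)
        trace = uncertainty_trace(posteriors, config.measure)
        flags = flag_uncertain(trace, policy.threshold)
        night_policy = replace(policy, seed=int(reviewer_seed))
        methods = apply_scoring_methods(automated, posteriors, flags, truth, night_policy)
        kappas = {
            name: cohens_kappa(reviewed, truth).kappa for name, reviewed in methods.items()
        }
        nights.append(
            NightResult(
                fragmentation=night_cfg.fragmentation,
                truth=truth,
                automated=automated,
                posteriors=posteriors,
                trace=trace,
                flags=flags,
                methods=methods,
                kappas=kappas,
                n_flagged=flags.n_flagged,
                burden=flags.burden,
            )
        )
    return StudyResult(nights=nights, config=config, policy=policy)
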