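"""Targeted-review scoring methods for flagged (uncertain) epochs.

Four scoring methods are materialised for every night:

1. **automated** — the stager's hypnogram, untouched;
2. **automated + review** — a (simulated) expert revisits every flagged
   epoch;
3. **automated + clinically relevant review** — review restricted to flagged
   epochs whose two most probable stages form a clinically relevant pair
   (e.g. REM vs N3 matters; W vs N1 is notoriously ambiguous even between
   human scorers and is excluded by default);
4. **automated + substitution** — flagged epochs take the ground-truth
   label, the best-case ceiling on what review could achieve.

The simulated reviewer is imperfect on purpose: flagged epochs the stager
got wrong are corrected only with probability ``reviewer_accuracy``, and
flagged epochs the stager had right are corrupted with probability
``reviewer_error_rate``.  With a nonzero error rate, review can *lower*
agreement with ground truth — exactly the behaviour real expert review
exhibits on ambiguous epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .exceptions import ValidationError
from .stages import N_STAGES, STAGES, Hypnogram, ReviewedHypnogram, require_same_length
from .stagers import PosteriorMatrix
from .uncertainty import FlagSequence

METHOD_AUTOMATED = "automated"
METHOD_REVIEW = "automated+review"
METHOD_RELEVANT = "automated+relevant_review"
METHOD_SUBSTITUTION = "automated+substitution"
ALL_METHODS = (METHOD_AUTOMATED, METHOD_REVIEW, METHOD_RELEVANT, METHOD_SUBSTITUTION)

ALL_STAGE_PAIRS = frozenset(frozenset(pair) for pair in combinations(range(N_STAGES), 2))

#: Default clinical-relevance set: every stage pair except the two light
#: transitions that are routinely ambiguous even between human experts
#: (W vs N1, N1 vs N2).  A package default, not clinical ground truth;
#: override per deployment.
DEFAULT_RELEVANT_PAIRS = frozenset(
    pair
    for pair in ALL_STAGE_PAIRS
    if pair not in (
        frozenset({STAGES.code("W"), STAGES.code("N1")}),
        frozenset({STAGES.code("N1"), STAGES.code("N2")}),
    )
)


def pairs_from_labels(pairs) -> frozenset:
    """Convert ``[("W", "N1"), ...]`` label pairs to code pairs."""
    out = set()
    for a, b in pairs:
        out.add(frozenset({STAGES.code(a), STAGES.code(b)}))
    return frozenset(out)


@dataclass
class ReviewPolicy:
    """Everything that parameterises targeted review for one run."""

    threshold: float = 1.0
    relevant_pairs: frozenset = field(default_factory=lambda: DEFAULT_RELEVANT_PAIRS)
    reviewer_accuracy: float = 0.8
    reviewer_error_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.reviewer_accuracy <= 1:
            raise ValidationError("reviewer_accuracy must lie in [0, 1]")
        if not 0 <= self.reviewer_error_rate <= 1:
            raise ValidationError("reviewer_error_rate must lie in [0, 1]")
        if self.threshold < 0:
            raise ValidationError("threshold must be non-negative")
        self.relevant_pairs = frozenset(frozenset(p) for p in self.relevant_pairs)
        if not self.relevant_pairs <= ALL_STAGE_PAIRS:
            raise ValidationError("relevant_pairs must be unordered pairs of stage codes 0-4")


def substitute_with_truth(
    automated: Hypnogram, flags: FlagSequence, truth: Hypnogram
) -> ReviewedHypnogram:
    """Replace flagged epochs with the ground-truth stage (best case)."""
    require_same_length(automated.stages, flags.flags, truth.stages, what="hypnograms and flags")
    stages = np.where(flags.flags == 1, truth.stages, automated.stages)
    return ReviewedHypnogram(
        stages=stages,
        epoch_seconds=automated.epoch_seconds,
        method=METHOD_SUBSTITUTION,
        n_reviewed=flags.n_flagged,
    )


def top_two_stages(row: np.ndarray) -> frozenset:
    """The epoch's two most probable stages; ties break toward lower codes."""
    order = np.argsort(-np.asarray(row), kind="stable")
    return frozenset(int(c) for c in order[:2])


def clinically_relevant_filter(
    flags: FlagSequence,
    posteriors: PosteriorMatrix,
    relevant_pairs: frozenset = DEFAULT_RELEVANT_PAIRS,
) -> FlagSequence:
    """Keep only flags whose top-2 posterior stages form a relevant pair.

    Relevance is judged from the *model's* posterior (the information
    available a priori, before any human looks at the epoch), never from
    ground truth.  The output flags are always a subset of the input flags.
    """
    require_same_length(flags.flags, posteriors.probs, what="flags and posteriors")
    relevant_pairs = frozenset(frozenset(p) for p in relevant_pairs)
    if not relevant_pairs:
        warnings.warn("empty relevant_pairs: all flags removed", stacklevel=2)
    kept = flags.flags.copy()
    for t in np.flatnonzero(flags.flags):
        if top_two_stages(posteriors.probs[t]) not in relevant_pairs:
            kept[t] = 0
    return FlagSequence(flags=kept, threshold=flags.threshold)


def simulate_reviewer(
    automated: Hypnogram,
    flags: FlagSequence,
    truth: Hypnogram,
    policy: ReviewPolicy,
) -> ReviewedHypnogram:
    """Simulate imperfect expert review of every flagged epoch.

    For each flagged epoch: if the automated stage is wrong, it is corrected
    to truth with probability ``reviewer_accuracy``; if it is right, it is
    corrupted to a uniformly random *other* stage with probability
    ``reviewer_error_rate``.  Unflagged epochs are never touched.  Seeded
    and reproducible through ``policy.seed``.
    """
    require_same_length(automated.stages, flags.flags, truth.stages, what="hypnograms and flags")
    rng = np.random.default_rng(policy.seed)
    stages = automated.stages.copy()
    for t in np.flatnonzero(flags.flags):
        if stages[t] != truth.stages[t]:
            if rng.random() < policy.reviewer_accuracy:
                stages[t] = truth.stages[t]
        else:
            if rng.random() < policy.reviewer_error_rate:
                others = [s for s in range(N_STAGES) if s != stages[t]]
                stages[t] = rng.choice(others)
    return ReviewedHypnogram(
        stages=stages,
        epoch_seconds=automated.epoch_seconds,
        method=METHOD_REVIEW,
        n_reviewed=flags.n_flagged,
    )


def review_burden(flags: FlagSequence) -> tuple[int, float]:
    """(number of epochs targeted for review, fraction of the study)."""
    if len(flags) == 0:
        raise ValidationError("cannot compute review burden of an empty flag sequence")
    return flags.n_flagged, flags.burden


def apply_scoring_methods(
    automated: Hypnogram,
    posteriors: PosteriorMatrix,
    flags: FlagSequence,
    truth: Hypnogram,
    policy: ReviewPolicy,
) -> dict[str, ReviewedHypnogram]:
    """Materialise all four scoring methods for one night.

    The relevant-review method applies the simulated reviewer to the
    relevance-filtered flags; substitution uses the raw flags.
    """
    relevant_flags = clinically_relevant_filter(flags, posteriors, policy.relevant_pairs)
    reviewed = simulate_reviewer(automated, flags, truth, policy)
    relevant_policy = ReviewPolicy(
        threshold=policy.threshold,
        relevant_pairs=policy.relevant_pairs,
        reviewer_accuracy=policy.reviewer_accuracy,
        reviewer_error_rate=policy.reviewer_error_rate,
        seed=policy.seed + 1,  # independent reviewer stream
    )
    relevant = simulate_reviewer(automated, relevant_flags, truth, relevant_policy)
    relevant.method = METHOD_RELEVANT
    return {
        METHOD_AUTOMATED: ReviewedHypnogram(
            stages=automated.stages.copy(),
            epoch_seconds=automated.epoch_seconds,
            method=METHOD_AUTOMATED,
            n_reviewed=0,
        ),
        METHOD_REVIEW: reviewed,
        METHOD_RELEVANT: relevant,
        METHOD_SUBSTITUTION: substitute_with_truth(automated, flags, truth),
    }
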