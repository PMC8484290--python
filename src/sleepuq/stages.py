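"""The five-class sleep-stage label space and per-night hypnograms.

Sleep is scored on fixed 30-second epochs into one of five stages: wake (W),
rapid-eye-movement sleep (REM), and the three non-REM depths N1 (light), N2,
and N3 (slow-wave).  The stage order is fixed package-wide — ``W, REM, N1,
N2, N3`` — and stage *codes* are 0-based indices into that order.  Every
matrix in the package (transition matrices, posterior matrices, confusion
matrices) uses this row/column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

STAGE_LABELS: tuple[str, ...] = ("W", "REM", "N1", "N2", "N3")
N_STAGES: int = 5

DEFAULT_EPOCH_SECONDS: float = 30.0


@dataclass(frozen=True)
class StageSet:
    """The ordered five-class stage label space.

    A single shared instance :data:`STAGES` covers normal use; the class
    exists so code can pass the label space around explicitly.
    """

    labels: tuple[str, ...] = STAGE_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != N_STAGES:
            raise ValidationError(
                f"stage set must have exactly {N_STAGES} labels, got {len(self.labels)}"
            )

    @property
    def n_stages(self) -> int:
        return len(self.labels)

    def code(self, label: str) -> int:
        """Return the 0-based code of a stage label."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown stage label {label!r}; expected one of {self.labels}")

    def label(self, code: int) -> str:
        if not 0 <= code < self.n_stages:
            raise ValidationError(f"stage code {code} outside [0, {self.n_stages - 1}]")
        return self.labels[code]


STAGES = StageSet()


@dataclass
class Hypnogram:
    """Per-epoch stage codes for one study night.

    Parameters
    ----------
    stages
        Integer stage codes, one per 30-s epoch, each in ``[0, 4]``.
    epoch_seconds
        Epoch duration in seconds (30 by convention).
    """

    stages: np.ndarray
    epoch_seconds: float = DEFAULT_EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int64)
        if self.stages.ndim != 1:
            raise ValidationError("hypnogram stages must be a 1-D sequence")
        if self.stages.size and (self.stages.min() < 0 or self.stages.max() >= N_STAGES):
            raise ValidationError(
                f"stage codes must lie in [0, {N_STAGES - 1}]; "
                f"found range [{self.stages.min()}, {self.stages.max()}]"
            )
        if not self.epoch_seconds > 0:
            raise ValidationError("epoch_seconds must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    def labels(self) -> list[str]:
        """Stage labels (strings) for every epoch."""
        return [STAGE_LABELS[c] for c in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_index": np.arange(self.n_epochs), "stage_label": self.labels()}
        )

    def to_csv(self, path: str | Path) -> None:
        """Write ``epoch_index, stage_label`` rows (labels as strings, never codes)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, epoch_seconds: float = DEFAULT_EPOCH_SECONDS) -> "Hypnogram":
        frame = pd.read_csv(path)
        for column in ("epoch_index", "stage_label"):
            if column not in frame.columns:
                raise FormatError(f"hypnogram CSV {path} is missing column {column!r}")
        frame = frame.sort_values("epoch_index")
        codes = np.array([STAGES.code(str(lbl)) for lbl in frame["stage_label"]], dtype=np.int64)
        return cls(stages=codes, epoch_seconds=epoch_seconds)

    def __len__(self) -> int:
        return self.n_epochs


@dataclass
class ReviewedHypnogram(Hypnogram):
    """A hypnogram after one of the targeted-review scoring methods.

    ``method`` tags which scoring method produced it (``automated``,
    ``automated+review``, ``automated+relevant_review``,
    ``automated+substitution``); ``n_reviewed`` counts epochs that were
    actually routed to review.
    """

    method: str = "automated"
    n_reviewed: int = 0

    def to_frame(self) -> pd.DataFrame:
        frame = super().to_frame()
        frame["method"] = self.method
        return frame


def require_same_length(*sequences, what: str = "inputs") -> int:
    """Validate that all sequences share one length and return it."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValidationError(f"{what} must have equal lengths, got {sorted(lengths)}")
    return lengths.pop()
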