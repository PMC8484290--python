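"""Per-epoch uncertainty from posterior rows, and threshold flagging.

For an epoch with stage probabilities ``p = [p_1, …, p_5]`` the Rényi
entropy of order ``α`` is

    S_α(p) = 1/(1-α) · log2( Σ_i p_i^α )        [bits]

with the special cases α = 1 (Shannon entropy, ``-Σ p_i log2 p_i`` under the
0·log 0 = 0 convention), α = 2 (collision entropy) and α = ∞ (min-entropy,
``-log2 max_i p_i``).  With five classes every entropy lies between 0 bits
(absolute certainty) and log2 5 ≈ 2.32 bits (absolute uncertainty).

An epoch is flagged "uncertain" — routed to targeted clinician review —
whenever its uncertainty strictly exceeds a threshold, by default 1 bit: the
entropy of a posterior splitting its mass evenly between two stages
(``p = [~0, ~0, ~0, ~0.5, ~0.5]``), the canonical two-way-ambiguous epoch.
A value exactly at the threshold stays automated.

Posterior *variance* is also offered as a non-entropy measure: the
population variance of the five probability masses, which is 0 for the
uniform posterior and maximal (0.16) for a one-hot posterior.  Note its
orientation is opposite to entropy — large variance means *certainty* — so
it is reported but not used for flagging by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .stages import N_STAGES
from .stagers import PosteriorMatrix

MAX_ENTROPY_BITS = math.log2(N_STAGES)  # 2.3219...

#: Measure aliases accepted by :func:`measure_from_name`.
MEASURE_ALIASES = {
    "shannon": 1.0,
    "collision": 2.0,
    "min": math.inf,
    "variance": "variance",
}

VARIANCE = "variance"

#: Rows whose mass differs from 1 by more than this are rejected.
SIMPLEX_ATOL = 1e-6


@dataclass(frozen=True)
class EntropyMeasureSpec:
    """Selects an uncertainty measure: a Rényi order α > 0 or ``"variance"``."""

    alpha: Union[float, str] = 1.0

    def __post_init__(self) -> None:
        if self.alpha == VARIANCE:
            return
        if not isinstance(self.alpha, (int, float)) or not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0 or 'variance', got {self.alpha!r}")

    @property
    def is_entropy(self) -> bool:
        return self.alpha != VARIANCE

    @property
    def name(self) -> str:
        if self.alpha == VARIANCE:
            return "variance"
        if math.isinf(self.alpha):
            return "min"
        if abs(self.alpha - 1.0) < 1e-9:
            return "shannon"
        if self.alpha == 2.0:
            return "collision"
        return f"renyi_{self.alpha:g}"


def measure_from_name(name: str) -> EntropyMeasureSpec:
    try:
        return EntropyMeasureSpec(alpha=MEASURE_ALIASES[name])
    except KeyError:
        raise ValidationError(
            f"unknown measure {name!r}; expected one of {sorted(MEASURE_ALIASES)}"
        )


def _validate_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (N_STAGES,):
        raise ValidationError(f"probability vector must have length {N_STAGES}, got {p.shape}")
    if (p < -1e-12).any():
        raise ValidationError("probability vector has negative entries")
    total = p.sum()
    if abs(total - 1.0) > SIMPLEX_ATOL:
        raise ValidationError(f"probability vector sums to {total:.8f}, not 1")
    return np.clip(p, 0.0, None) / total


def renyi_entropy(p: np.ndarray, alpha: float = 1.0) -> float:
    """Rényi entropy of order ``alpha`` in bits.

    ``alpha`` within 1e-9 of 1 is routed to the Shannon branch; ``alpha =
    inf`` evaluates the min-entropy ``-log2 max(p)``.  Zero-probability terms
    are dropped (the 0·log 0 = 0 convention), which keeps every branch finite
    on the simplex boundary.
    """
    p = _validate_simplex(p)
    if not alpha > 0:
        raise ValidationError(f"alpha must be positive, got {alpha}")
    if math.isinf(alpha):
        value = -math.log2(p.max())
    elif abs(alpha - 1.0) < 1e-9:
        nonzero = p[p > 0]
        value = float(-(nonzero * np.log2(nonzero)).sum())
    else:
        nonzero = p[p > 0]
        value = float(math.log2((nonzero**alpha).sum()) / (1.0 - alpha))
    # clamp float dust at the boundaries
    return min(max(value, 0.0), MAX_ENTROPY_BITS)


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits (Rényi order 1)."""
    return renyi_entropy(p, alpha=1.0)


def posterior_variance(p: np.ndarray) -> float:
    """Population variance of the five probability masses.

    Equals ``mean((p_i - 1/5)^2)`` since the masses always average 1/5:
    0 for the uniform posterior, 0.16 for a one-hot posterior.
    """
    p = _validate_simplex(p)
    return float(np.mean((p - 1.0 / N_STAGES) ** 2))


@dataclass
class UncertaintyTrace:
    """Length-T per-epoch uncertainty values for one measure."""

    values: np.ndarray
    measure: EntropyMeasureSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("uncertainty trace must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValidationError("uncertainty trace contains non-finite values")
        if self.measure.is_entropy and (
            (self.values < -1e-9).any() or (self.values > MAX_ENTROPY_BITS + 1e-9).any()
        ):
            raise ValidationError(f"entropy values must lie in [0, {MAX_ENTROPY_BITS:.4f}] bits")

    @property
    def n_epochs(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.n_epochs


@dataclass
class FlagSequence:
    """Binary per-epoch review flags: 1 = uncertain, 0 = certain."""

    flags: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.ndim != 1 or not np.isin(self.flags, (0, 1)).all():
            raise ValidationError("flags must be a 1-D binary sequence")

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def burden(self) -> float:
        """Fraction of the night targeted for review."""
        return float(self.flags.mean()) if self.flags.size else 0.0

    def __len__(self) -> int:
        return self.flags.size


def uncertainty_trace(
    posteriors: PosteriorMatrix, measure: EntropyMeasureSpec | str = "shannon"
) -> UncertaintyTrace:
    """Apply one uncertainty measure to every posterior row."""
    if isinstance(measure, str):
        measure = measure_from_name(measure)
    values = np.empty(posteriors.n_epochs, dtype=float)
    for t, row in enumerate(posteriors.probs):
        try:
            if measure.alpha == VARIANCE:
                values[t] = posterior_variance(row)
            else:
                values[t] = renyi_entropy(row, alpha=measure.alpha)
        except ValidationError as exc:
            raise ValidationError(f"epoch {t}: {exc}") from exc
    return UncertaintyTrace(values=values, measure=measure)


def flag_uncertain(trace: UncertaintyTrace, threshold: float = 1.0) -> FlagSequence:
    """Flag every epoch whose uncertainty *strictly* exceeds the threshold."""
    if threshold < 0:
        raise ValidationError(f"threshold must be non-negative, got {threshold}")
    return FlagSequence(flags=(trace.values > threshold).astype(np.int8), threshold=threshold)


def write_trace_csv(
    trace: UncertaintyTrace, flags: FlagSequence, path: str | Path
) -> None:
    """Write ``epoch_index, value_bits, flagged`` plus a JSON sidecar.

    The sidecar (same stem, ``.json``) records the measure and threshold so
    the trace file is self-describing.
    """
    path = Path(path)
    pd.DataFrame(
        {
            "epoch_index": np.arange(trace.n_epochs),
            "value_bits": trace.values,
            "flagged": flags.flags,
        }
    ).to_csv(path, index=False)
    sidecar = {
        "measure": trace.measure.name,
        "alpha": None if trace.measure.alpha == VARIANCE else (
            "inf" if math.isinf(trace.measure.alpha) else trace.measure.alpha
        ),
        "threshold": flags.threshold,
        "n_epochs": trace.n_epochs,
        "n_flagged": flags.n_flagged,
        "burden": flags.burden,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
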