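"""Agreement scoring and uncertainty diagnostics.

Cohen's Kappa measures chance-corrected agreement between two hypnograms:

    K = (p_o - p_e) / (1 - p_e)

with ``p_o`` the observed fraction of matching epochs and ``p_e`` the
agreement expected from the two raters' stage marginals.  The module also
builds the certain/uncertain stratified confusion matrices (row = true
stage, column = estimate, row-normalised percentages), summarises Shannon
entropy distributions by correctness and by true stage, and compares
scoring methods across nights with a paired-samples t test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .stages import N_STAGES, STAGE_LABELS, Hypnogram, require_same_length
from .uncertainty import MAX_ENTROPY_BITS, FlagSequence, UncertaintyTrace


@dataclass
class KappaReport:
    """Cohen's Kappa with its ingredients."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "n_epochs": self.n_epochs,
        }


def cohens_kappa(a: Hypnogram, b: Hypnogram) -> KappaReport:
    """Chance-corrected agreement between two stage sequences.

    Degenerate case: when ``p_e = 1`` (both raters constant) the formula is
    0/0; we return K = 1 if the sequences are identical, else 0, with a
    warning.
    """
    T = require_same_length(a.stages, b.stages, what="hypnograms")
    if T < 1:
        raise ValidationError("kappa requires at least one epoch")
    observed = float(np.mean(a.stages == b.stages))
    marg_a = np.bincount(a.stages, minlength=N_STAGES) / T
    marg_b = np.bincount(b.stages, minlength=N_STAGES) / T
    expected = float(np.dot(marg_a, marg_b))
    if expected >= 1.0 - 1e-15:
        warnings.warn("degenerate kappa: expected agreement is 1", stacklevel=2)
        kappa = 1.0 if observed == 1.0 else 0.0
    else:
        kappa = (observed - expected) / (1.0 - expected)
    return KappaReport(
        kappa=float(kappa),
        observed_agreement=observed,
        expected_agreement=expected,
        n_epochs=T,
    )


@dataclass
class CertaintyConfusion:
    """5×5 row-percentage confusion matrices stratified by review flag.

    Rows index the true stage, columns the estimate, both in the fixed
    stage order.  A row with no epochs in a stratum is undefined and stored
    as NaN, never as zeros.  Counts are kept alongside the percentages.
    """

    certain_matrix: np.ndarray
    uncertain_matrix: np.ndarray
    certain_counts: np.ndarray
    uncertain_counts: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        index = pd.Index(STAGE_LABELS, name="true_stage")
        columns = pd.Index(STAGE_LABELS, name="estimate")
        return (
            pd.DataFrame(self.certain_matrix, index=index, columns=columns),
            pd.DataFrame(self.uncertain_matrix, index=index, columns=columns),
        )


def _row_percentages(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * counts / totals
    percent[totals[:, 0] == 0] = np.nan
    return percent


def certainty_confusion(
    truth: Hypnogram, estimate: Hypnogram, flags: FlagSequence
) -> CertaintyConfusion:
    """Cross-tabulate true × estimated stage, split by certain/uncertain.

    The certain stratum holds unflagged epochs (uncertainty at or below
    threshold), the uncertain stratum the flagged ones.  The certain
    matrix's diagonal is per-stage accuracy where the stager was confident;
    the uncertain matrix's diagonal is the fraction of flagged epochs that
    were nonetheless correct (review false-negatives, in the sense that the
    flag suggested a problem that was not there).
    """
    require_same_length(truth.stages, estimate.stages, flags.flags, what="inputs")
    certain_counts = np.zeros((N_STAGES, N_STAGES), dtype=float)
    uncertain_counts = np.zeros((N_STAGES, N_STAGES), dtype=float)
    certain = flags.flags == 0
    np.add.at(certain_counts, (truth.stages[certain], estimate.stages[certain]), 1.0)
    np.add.at(uncertain_counts, (truth.stages[~certain], estimate.stages[~certain]), 1.0)
    return CertaintyConfusion(
        certain_matrix=_row_percentages(certain_counts),
        uncertain_matrix=_row_percentages(uncertain_counts),
        certain_counts=certain_counts,
        uncertain_counts=uncertain_counts,
    )


@dataclass
class GroupStats:
    """Moments and an optional kernel-density fit for one entropy group."""

    count: int
    mean: float  # NaN when count == 0
    sd: float  # population standard deviation; NaN when count == 0
    kde_grid: Optional[np.ndarray] = None
    kde_density: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {"count": self.count, "mean": self.mean, "sd": self.sd}


def _group_stats(values: np.ndarray, fit_kde: bool, grid_points: int = 256) -> GroupStats:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return GroupStats(count=0, mean=math.nan, sd=math.nan)
    stats_obj = GroupStats(
        count=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std()),  # population convention
    )
    if fit_kde and values.size >= 2 and values.std() > 0:
        grid = np.linspace(0.0, MAX_ENTROPY_BITS, grid_points)
        kde = stats.gaussian_kde(values)
        stats_obj.kde_grid = grid
        stats_obj.kde_density = kde(grid)
    return stats_obj


@dataclass
class EntropyDistributionSummary:
    """Entropy moments for all/correct/incorrect epochs, overall and per true stage."""

    overall: dict  # {"all" | "correct" | "incorrect": GroupStats}
    per_stage: dict  # {stage label: {"all" | "correct" | "incorrect": GroupStats}}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, groups in [("all", self.overall), *self.per_stage.items()]:
            for group, gs in groups.items():
                rows.append(
                    {"stage": stage, "group": group, **gs.to_dict()}
                )
        return pd.DataFrame(rows)


def entropy_distribution_summary(
    trace: UncertaintyTrace,
    truth: Hypnogram,
    estimate: Hypnogram,
    fit_kde: bool = True,
) -> EntropyDistributionSummary:
    """Summarise per-epoch entropy by correctness and by true stage.

    Correctness is ``estimate == truth`` per epoch.  Per-stage panels are
    keyed on the *true* stage.  Means and (population) standard deviations
    are reported per group together with a Gaussian kernel-density fit over
    ``[0, log2 5]`` whenever the group has at least two distinct values.
    """
    require_same_length(trace.values, truth.stages, estimate.stages, what="inputs")
    correct = truth.stages == estimate.stages

    def build(mask: np.ndarray) -> dict:
        return {
            "all": _group_stats(trace.values[mask], fit_kde),
            "correct": _group_stats(trace.values[mask & correct], fit_kde),
            "incorrect": _group_stats(trace.values[mask & ~correct], fit_kde),
        }

    everything = np.ones(len(trace), dtype=bool)
    per_stage = {
        STAGE_LABELS[s]: build(truth.stages == s) for s in range(N_STAGES)
    }
    return EntropyDistributionSummary(overall=build(everything), per_stage=per_stage)


def paired_t_test(kappas_a, kappas_b) -> tuple[float, float]:
    """Classic paired-samples t test on per-night agreement values.

    Returns ``(t, two-sided p)`` with ``df = n - 1``.  Zero-variance
    differences (including identical inputs) are degenerate: the sentinel
    ``(nan, nan)`` is returned with a warning rather than an infinite or
    undefined statistic.
    """
    a = np.asarray(kappas_a, dtype=float)
    b = np.asarray(kappas_b, dtype=float)
    n = require_same_length(a, b, what="kappa vectors")
    if n < 2:
        raise ValidationError("paired t test requires n >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences: t test degenerate", stacklevel=2)
        return (math.nan, math.nan)
    result = stats.ttest_rel(a, b)
    return (float(result.statistic), float(result.pvalue))


def plot_entropy_distributions(summary: EntropyDistributionSummary, path=None):
    """Histogram-free density overlays of correct vs incorrect entropy.

    Requires matplotlib (optional ``plot`` extra).  Returns the figure;
    saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, color in (("correct", "tab:blue"), ("incorrect", "tab:red")):
        gs = summary.overall[group]
        if gs.kde_grid is not None:
            ax.plot(gs.kde_grid, gs.kde_density, color=color,
                    label=f"{group} (n={gs.count}, {gs.mean:.2f}±{gs.sd:.2f} bits)")
    ax.set_xlabel("Shannon entropy (bits)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
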