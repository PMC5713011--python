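"""Statistical characterization of noise amplitude and label agreement.

Three analyses live here:

* **Conditional histograms** — the per-sample naive noise amplitude is
  histogrammed separately for each clinical severity level, so the marginal
  amplitude distribution decomposes as a mixture
  ``p(n) = sum_l p(n | l) P(l)`` with priors given by the share of labeled
  time each level occupies. Counts are scaled by the sampling period so the
  vertical axis reads in seconds of signal.
* **Duration summaries** — per-level total durations and their percentage
  of the labeled total.
* **Inter-observer concordance** — duration-weighted confusion matrices
  between two labelers, summarized by unweighted Cohen's kappa, with class
  merging (e.g. pooling noise-free with low) for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .mapping import NoiseMap
from .severity import SEVERITY_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionalHistogram",
    "DurationSummary",
    "ConfusionMatrix",
    "conditional_histograms",
    "duration_summary",
    "cohens_kappa",
    "merge_classes",
]


# ---------------------------------------------------------------------------
# Conditional amplitude histograms
# ---------------------------------------------------------------------------

@dataclass
class ConditionalHistogram:
    """Per-level amplitude histograms scaled to signal duration.

    ``counts_by_level[l][j]`` is the number of seconds of level-``l`` signal
    whose amplitude falls in bin ``j`` (sample count x sampling period).
    ``priors[l]`` is the fraction of labeled time carrying level ``l``; the
    per-bin sum over levels equals the marginal histogram exactly.
    """

    component: str
    bin_edges: np.ndarray
    counts_by_level: dict[int, np.ndarray]
    priors: dict[int, float]

    def marginal(self) -> np.ndarray:
        """Mixture over levels: the histogram of all labeled samples."""
        return np.sum(list(self.counts_by_level.values()), axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, counts in sorted(self.counts_by_level.items()):
            for j, seconds in enumerate(counts):
                rows.append(
                    {
                        "bin_left": self.bin_edges[j],
                        "bin_right": self.bin_edges[j + 1],
                        "level": level,
                        "seconds": seconds,
                    }
                )
        return pd.DataFrame(rows)


def conditional_histograms(
    amplitude,
    clinical_map: NoiseMap,
    fs: float,
    bin_edges=None,
    t0: float | None = None,
    component: str = "sdn",
) -> ConditionalHistogram:
    """Histogram a naive-amplitude series conditioned on a severity map.

    Each sample is assigned the level of the map segment covering its start
    time; samples not covered by any segment are excluded (their count is
    logged). ``bin_edges`` defaults to Freedman-Diaconis edges on the
    covered amplitudes.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.ndim != 1:
        raise ValidationError("amplitude must be a 1-D series")
    start = clinical_map.start_s if t0 is None else t0
    times = start + np.arange(amplitude.size) / fs

    levels = np.full(amplitude.size, -1, dtype=np.int64)
    for s0, s1, level in clinical_map.segments:
        levels[(times >= s0) & (times < s1)] = level
    covered = levels >= 0
    n_uncovered = int(np.count_nonzero(~covered))
    if n_uncovered:
        logger.info("conditional_histograms: excluded %d uncovered samples", n_uncovered)
    if not covered.any():
        raise ValidationError("severity map does not cover any amplitude sample")

    if bin_edges is None:
        bin_edges = np.histogram_bin_edges(amplitude[covered], bins="fd")
    bin_edges = np.asarray(bin_edges, dtype=float)

    counts_by_level: dict[int, np.ndarray] = {}
    for level in sorted(set(levels[covered].tolist())):
        sel = amplitude[covered & (levels == level)]
        counts, _ = np.histogram(sel, bins=bin_edges)
        counts_by_level[level] = counts / fs  # sample counts -> seconds
    total = sum(c.sum() for c in counts_by_level.values())
    priors = {level: float(c.sum() / total) for level, c in counts_by_level.items()}
    return ConditionalHistogram(
        component=component, bin_edges=bin_edges, counts_by_level=counts_by_level, priors=priors
    )


def render_histograms(hist: ConditionalHistogram, log_scale: bool = True, ax=None):
    """Plot the conditional histograms, one curve per severity level."""
    import matplotlib.pyplot as plt

    from .mapping import LINESTYLES, PALETTE

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 3.5))
    else:
        fig = ax.get_figure()
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
    for level, counts in sorted(hist.counts_by_level.items()):
        ax.plot(
            centers, counts, color=PALETTE[level], ls=LINESTYLES[level],
            label=f"{level}: {SEVERITY_NAMES[level]}",
        )
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel(f"{hist.component} amplitude (mV)")
    ax.set_ylabel("duration (s)")
    ax.legend(fontsize="x-small")
    return fig


# ---------------------------------------------------------------------------
# Duration summaries
# ---------------------------------------------------------------------------

@dataclass
class DurationSummary:
    """Per-level total labeled duration and percentage of the labeled total."""

    seconds: dict[int, float]
    percent: dict[int, float]

    @classmethod
    def from_totals(cls, seconds: dict[int, float]) -> "DurationSummary":
        total = sum(seconds.values())
        if total <= 0:
            raise ValidationError("total labeled duration must be positive")
        return cls(
            seconds=dict(seconds),
            percent={level: 100.0 * s / total for level, s in seconds.items()},
        )

    @property
    def total_s(self) -> float:
        return sum(self.seconds.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.seconds),
                "name": [SEVERITY_NAMES.get(level, "?") for level in self.seconds],
                "seconds": list(self.seconds.values()),
                "percent": [self.percent[level] for level in self.seconds],
            }
        )


def duration_summary(nmap: NoiseMap) -> DurationSummary:
    """Total duration and percentage of labeled time per severity level."""
    if not nmap.segments:
        raise ValidationError("cannot summarize an empty map")
    seconds: dict[int, float] = {}
    for start, end, level in nmap.segments:
        seconds[level] = seconds.get(level, 0.0) + (end - start)
    return DurationSummary.from_totals(dict(sorted(seconds.items())))


# ---------------------------------------------------------------------------
# Inter-observer concordance
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Duration-weighted cross-tabulation of two observers' labels.

    Rows are observer 1, columns observer 2; entries are non-negative
    durations (conventionally minutes). Cohen's kappa is scale-invariant,
    so any non-negative weighting works.
    """

    class_names: list[str]
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        k = len(self.class_names)
        if self.durations.shape != (k, k):
            raise ValidationError(
                f"matrix shape {self.durations.shape} does not match {k} class names"
            )
        if k < 2:
            raise ValidationError("need at least 2 classes")
        if (self.durations < 0).any():
            raise ValidationError("confusion-matrix entries must be non-negative")


def cohens_kappa(matrix: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa, ``(Po - Pe) / (1 - Pe)``.

    ``Po`` is the observed agreement (trace / total) and ``Pe`` the
    agreement expected by chance from the row and column margins.
    """
    M = matrix.durations
    total = M.sum()
    if total <= 0:
        raise ValidationError("confusion matrix is empty")
    p_obs = np.trace(M) / total
    p_exp = float(M.sum(axis=1) @ M.sum(axis=0)) / total**2
    if np.isclose(p_exp, 1.0):
        raise ValidationError("chance agreement Pe = 1; kappa is undefined")
    return float((p_obs - p_exp) / (1.0 - p_exp))


def merge_classes(matrix: ConfusionMatrix, groups: list[list[int]]) -> ConfusionMatrix:
    """Merge classes by summing rows and columns within each group.

    ``groups`` must partition the class indices. Merged class names are
    joined with an en dash (e.g. ``"noise-free–low"``).
    """
    k = len(matrix.class_names)
    flat = sorted(i for group in groups for i in group)
    if flat != list(range(k)):
        raise ValidationError(f"groups must partition indices 0..{k - 1}, got {groups}")
    if len(groups) < 2:
        raise ValidationError("merging all classes leaves a 1x1 matrix; kappa is undefined")
    names = ["–".join(matrix.class_names[i] for i in group) for group in groups]
    out = np.zeros((len(groups), len(groups)))
    for i, rows in enumerate(groups):
        for j, cols in enumerate(groups):
            out[i, j] = matrix.durations[np.ix_(rows, cols)].sum()
    return ConfusionMatrix(class_names=names, durations=out)
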