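"""Noise maps and noise bars: the time characterization of severity labels.

A *noise map* is a run-length representation of a severity-labeled
recording: ordered, non-overlapping, maximal segments (adjacent segments
carry different levels), possibly with gaps where no signal was stored.

*Noise bars* summarize a map in fixed-duration windows: within each bar the
per-level labeled durations are normalized by the bar's total labeled
duration, giving the fraction of each severity level in that time slice.
Bars with no labeled time (e.g. wholly inside a storage gap) are blank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io import SegmentLabelTrack
from .severity import SEVERITY_NAMES

__all__ = [
    "NoiseMap",
    "Bar",
    "NoiseBarSeries",
    "map_from_levels",
    "map_from_track",
    "expand_to_levels",
    "build_noise_bars",
    "render_map",
    "render_bars",
    "PALETTE",
]

# Shared 5-level palette: noise-free blue, low green, moderate yellow,
# hard red, other black. Quantitative maps only ever use levels 0-3.
PALETTE = {0: "#1f77b4", 1: "#2ca02c", 2: "#e6b800", 3: "#d62728", 4: "#000000"}
LINESTYLES = {0: "-", 1: "--", 2: ":", 3: ":", 4: "-."}


@dataclass
class NoiseMap:
    """Run-length severity map: sorted, non-overlapping, maximal segments."""

    segments: list[tuple[float, float, int]]
    source: str = "clinical"  # clinical | bw | pli | sdn

    def __post_init__(self) -> None:
        if self.source not in ("clinical", "bw", "pli", "sdn"):
            raise ValidationError(f"unknown map source {self.source!r}")
        prev_end = -np.inf
        prev_level = None
        for start, end, level in self.segments:
            if not start < end:
                raise ValidationError(f"segment ({start}, {end}) has non-positive duration")
            if start < prev_end:
                raise ValidationError(f"segment starting at {start} overlaps previous end {prev_end}")
            if start == prev_end and level == prev_level:
                raise ValidationError(
                    f"adjacent segments at t={start} share level {level}; merge them (maximality)"
                )
            prev_end, prev_level = end, level

    @property
    def start_s(self) -> float:
        return self.segments[0][0] if self.segments else 0.0

    @property
    def end_s(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    @property
    def labeled_duration_s(self) -> float:
        return sum(end - start for start, end, _ in self.segments)

    def coverage_gaps(self) -> list[tuple[float, float]]:
        """Intervals between consecutive segments with no label."""
        gaps = []
        for (_, end, _), (start, _, _) in zip(self.segments, self.segments[1:]):
            if start > end:
                gaps.append((end, start))
        return gaps

    def level_at(self, t: float) -> int | None:
        """Level covering time ``t`` (half-open segments), or None."""
        for start, end, level in self.segments:
            if start <= t < end:
                return level
        return None


@dataclass
class Bar:
    """One fixed-duration bar: per-level duration and fraction of labeled time."""

    start_s: float
    is_blank: bool
    fractions: dict[int, float]
    durations: dict[int, float] = field(default_factory=dict)


@dataclass
class NoiseBarSeries:
    """Consecutive fixed-duration bars covering a map's extent."""

    bar_s: float
    bars: list[Bar]

    def __post_init__(self) -> None:
        for bar in self.bars:
            if bar.is_blank:
                continue
            total = sum(bar.fractions.values())
            if bar.fractions and abs(total - 1.0) > 1e-9:
                raise ValidationError(f"bar at {bar.start_s}s: fractions sum to {total}, not 1")
            if any(f < 0 for f in bar.fractions.values()):
                raise ValidationError(f"bar at {bar.start_s}s: negative fraction")


def map_from_levels(levels, fs: float, t0: float = 0.0, source: str = "clinical") -> NoiseMap:
    """Run-length encode a per-sample level series into a NoiseMap.

    Segment boundaries fall at level-change sample times; sample ``i``
    covers ``[t0 + i/fs, t0 + (i+1)/fs)``.
    """
    levels = np.asarray(levels)
    if levels.size == 0:
        raise ValidationError("cannot build a map from an empty level series")
    change = np.flatnonzero(np.diff(levels)) + 1
    bounds = np.concatenate([[0], change, [levels.size]])
    segments = [
        (t0 + a / fs, t0 + b / fs, int(levels[a])) for a, b in zip(bounds, bounds[1:])
    ]
    return NoiseMap(segments=segments, source=source)


def map_from_track(track: SegmentLabelTrack, source: str = "clinical") -> NoiseMap:
    """Convert a label track into a maximal NoiseMap.

    Adjacent same-label segments are merged; gaps between non-contiguous
    segments are preserved (see :meth:`NoiseMap.coverage_gaps`).
    """
    merged: list[list] = []
    for _, start, end, label in track.entries:
        if merged and merged[-1][1] == start and merged[-1][2] == label:
            merged[-1][1] = end
        else:
            merged.append([start, end, label])
    return NoiseMap(segments=[tuple(m) for m in merged], source=source)


def expand_to_levels(nmap: NoiseMap, fs: float) -> tuple[np.ndarray, float]:
    """Expand a sample-aligned, gap-free map back to a per-sample series.

    Returns ``(levels, t0)``. Inverse of :func:`map_from_levels` for maps
    whose boundaries are aligned to the sampling grid.
    """
    if not nmap.segments:
        raise ValidationError("cannot expand an empty map")
    if nmap.coverage_gaps():
        raise ValidationError("cannot expand a map with coverage gaps to a dense series")
    t0 = nmap.start_s
    n = round((nmap.end_s - t0) * fs)
    levels = np.empty(n, dtype=np.int64)
    for start, end, level in nmap.segments:
        a = round((start - t0) * fs)
        b = round((end - t0) * fs)
        if not np.isclose(a, (start - t0) * fs) or not np.isclose(b, (end - t0) * fs):
            raise ValidationError(f"segment boundary {start}..{end} is not sample-aligned at fs={fs}")
        levels[a:b] = level
    return levels, t0


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def build_noise_bars(
    nmap: NoiseMap, bar_s: float, gaps: list[tuple[float, float]] | None = None
) -> NoiseBarSeries:
    """Aggregate a NoiseMap into fixed-duration normalized bars.

    Bar phase is anchored at the map's first labeled instant. Within each
    bar, per-level durations are normalized by the bar's labeled (non-gap)
    duration; a bar with no labeled time at all — e.g. wholly inside a
    declared storage gap — is blank. A partial final bar is kept and
    normalized by its actual labeled duration.
    """
    if bar_s <= 0:
        raise ValidationError(f"bar duration must be positive, got {bar_s}")
    gaps = list(gaps or [])
    if not nmap.segments:
        return NoiseBarSeries(bar_s=bar_s, bars=[])
    t_start, t_end = nmap.start_s, nmap.end_s
    n_bars = int(np.ceil((t_end - t_start) / bar_s - 1e-12))
    bars: list[Bar] = []
    for k in range(n_bars):
        b0 = t_start + k * bar_s
        b1 = min(b0 + bar_s, t_end)
        durations: dict[int, float] = {}
        for s0, s1, level in nmap.segments:
            d = _overlap(b0, b1, s0, s1)
            if d > 0:
                durations[level] = durations.get(level, 0.0) + d
        labeled = sum(durations.values())
        if labeled <= 0:
            bars.append(Bar(start_s=b0, is_blank=True, fractions={}))
            continue
        fractions = {level: d / labeled for level, d in sorted(durations.items())}
        bars.append(Bar(start_s=b0, is_blank=False, fractions=fractions, durations=durations))
    return NoiseBarSeries(bar_s=bar_s, bars=bars)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_map(nmap: NoiseMap, record=None, lead: int | str = 0, ax=None):
    """Render a noise map as level-height colored spans; optional ECG panel.

    Returns the matplotlib Figure. With ``record`` given, the signal is
    drawn in a panel above the map (the classic excerpt-plus-map layout).
    """
    import matplotlib.pyplot as plt

    if ax is not None:
        fig = ax.get_figure()
        map_ax = ax
    elif record is not None:
        fig, (sig_ax, map_ax) = plt.subplots(
            2, 1, sharex=True, figsize=(10, 4), height_ratios=[2, 1]
        )
        sig_ax.plot(record.times(), record.lead(lead), lw=0.5, color="k")
        sig_ax.set_ylabel("ECG (mV)")
    else:
        fig, map_ax = plt.subplots(figsize=(10, 1.8))
    seen = set()
    for start, end, level in nmap.segments:
        map_ax.hlines(
            level, start, end, colors=PALETTE[level], linewidth=6,
            label=None if level in seen else f"{level}: {SEVERITY_NAMES[level]}",
        )
        seen.add(level)
    map_ax.set_ylim(-0.5, 4.5)
    map_ax.set_yticks(range(5))
    map_ax.set_xlabel("time (s)")
    map_ax.set_ylabel("severity")
    if seen:
        handles, labels = map_ax.get_legend_handles_labels()
        order = np.argsort([int(lbl.split(":")[0]) for lbl in labels])
        map_ax.legend(
            [handles[i] for i in order], [labels[i] for i in order],
            loc="upper right", fontsize="x-small", ncols=len(labels),
        )
    return fig


def render_bars(bars: NoiseBarSeries, ax=None, title: str | None = None):
    """Render noise bars as stacked columns (lower levels at the bottom).

    Blank bars are left empty, visually separating non-contiguous stored
    segments. Returns the matplotlib Figure.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(10, 2.5))
    else:
        fig = ax.get_figure()
    seen = set()
    for bar in bars.bars:
        if bar.is_blank:
            continue
        bottom = 0.0
        for level in sorted(bar.fractions):
            frac = bar.fractions[level]
            ax.bar(
                bar.start_s, frac, width=bars.bar_s, bottom=bottom, align="edge",
                color=PALETTE[level], edgecolor="none",
                label=None if level in seen else f"{level}: {SEVERITY_NAMES[level]}",
            )
            seen.add(level)
            bottom += frac
    if bars.bars:
        ax.set_xlim(bars.bars[0].start_s, bars.bars[-1].start_s + bars.bar_s)
    ax.set_ylim(0, 1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fraction")
    if title:
        ax.set_title(title)
    if seen:
        handles, labels = ax.get_legend_handles_labels()
        order = np.argsort([int(lbl.split(":")[0]) for lbl in labels])
        ax.legend(
            [handles[i] for i in order], [labels[i] for i in order],
            loc="upper right", fontsize="x-small", ncols=len(labels),
        )
    return fig
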