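"""Quantitative noise estimators for ambulatory ECG.

Three per-sample noise amplitude estimates are computed from a raw lead:

* **Baseline wander (BW)** — a cubic spline through per-window nodes
  (median of each non-overlapping 0.8 s window, placed at the window
  center) tracks the slow drift of the isoelectric line.
* **Powerline interference (PLI)** — the residual removed by a zero-phase
  second-order IIR notch centered on the mains frequency (50 Hz default).
* **Standard-deviation noise (SDN)** — a block statistic designed for
  disconnection/saturation-like corruption: the signal standard deviation
  is computed in 0.5 s blocks; every 10 blocks the mean and standard
  deviation of those block values are taken, and mean + 2·std is assigned
  to every block in the group.

All estimators are positively homogeneous (``estimate(c·x) = c·estimate(x)``
for ``c > 0``) and length-preserving. They are exposed both as sklearn-style
transformers operating on ``(n_samples, n_leads)`` arrays and as plain
functions on a single lead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import filtfilt, iirnotch
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError
from .io import ECGRecord

__all__ = [
    "NoiseEstimate",
    "DecompositionResult",
    "BaselineWanderEstimator",
    "PowerlineInterferenceEstimator",
    "BlockStdNoiseEstimator",
    "estimate_bw",
    "estimate_pli",
    "estimate_sdn",
    "naive_amplitude",
    "decompose",
]


@dataclass
class NoiseEstimate:
    """Per-sample estimated noise amplitude for one component.

    ``values`` has the same length and sampling rate as the source lead and
    is expressed in millivolts.
    """

    component: str  # "bw" | "pli" | "sdn"
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.component not in ("bw", "pli", "sdn"):
            raise ValidationError(f"unknown noise component {self.component!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("noise estimate contains non-finite values")


@dataclass
class DecompositionResult:
    """Additive decomposition of one lead into noise components.

    ``residual = lead - bw.values - pli.values``. The SDN component is a
    block-wise envelope statistic rather than an additive waveform, so it is
    reported but never subtracted.
    """

    bw: NoiseEstimate
    pli: NoiseEstimate
    sdn: NoiseEstimate
    residual: np.ndarray


def _as_column_array(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValidationError(f"expected 1-D or 2-D signal array, got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("signal contains NaN or infinite samples")
    return X


class _PerLeadTransformer(TransformerMixin, BaseEstimator):
    """Stateless column-wise transformer over (n_samples, n_leads) arrays."""

    component: str

    def fit(self, X, y=None):
        X = _as_column_array(X)
        self._check_config(X.shape[0])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_column_array(X)
        self._check_config(X.shape[0])
        return np.column_stack([self._transform_lead(X[:, j]) for j in range(X.shape[1])])

    def estimate(self, lead) -> NoiseEstimate:
        """Single-lead convenience: returns a :class:`NoiseEstimate`."""
        lead = np.asarray(lead, dtype=float)
        if lead.ndim != 1:
            raise ValidationError("estimate() expects a single 1-D lead")
        self._check_config(lead.size)
        return NoiseEstimate(component=self.component, values=self._transform_lead(lead), fs=self.fs)

    def _check_config(self, n: int) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def _transform_lead(self, lead: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BaselineWanderEstimator(_PerLeadTransformer):
    """Cubic-spline baseline-wander estimate.

    One node per non-overlapping ``window_s`` window (median of the window,
    placed at the window center); a cubic spline through the nodes is
    evaluated at every sample. Outside the node span the spline is clamped
    to the first/last node value to avoid cubic blow-up at the edges. A
    trailing partial window shorter than half a window is dropped; a longer
    one contributes a node at its own center.

    Parameters
    ----------
    fs : float
        Sampling rate (Hz).
    window_s : float, default 0.8
        Node-estimation window in seconds.
    """

    component = "bw"

    def __init__(self, fs: float = 200.0, window_s: float = 0.8):
        self.fs = fs
        self.window_s = window_s

    def _check_config(self, n: int) -> None:
        if self.fs <= 0 or self.window_s <= 0:
            raise ConfigurationError("fs and window_s must be positive")
        w = int(round(self.window_s * self.fs))
        if n < 3 * w:
            raise InsufficientDataError(
                f"need at least {3 * w} samples (3 windows of {self.window_s} s); got {n}"
            )

    def _transform_lead(self, lead: np.ndarray) -> np.ndarray:
        w = int(round(self.window_s * self.fs))
        n = lead.size
        starts = np.arange(0, n - w + 1, w)
        node_t = (starts + (w - 1) / 2) / self.fs
        node_v = np.array([np.median(lead[s : s + w]) for s in starts])
        tail_start = starts[-1] + w
        tail = n - tail_start
        if tail >= w / 2:
            node_t = np.append(node_t, (tail_start + (tail - 1) / 2) / self.fs)
            node_v = np.append(node_v, np.median(lead[tail_start:]))
        spline = CubicSpline(node_t, node_v)
        t = np.arange(n) / self.fs
        return spline(np.clip(t, node_t[0], node_t[-1]))


class PowerlineInterferenceEstimator(_PerLeadTransformer):
    """Mains-interference estimate as a notch-filter residual.

    The lead is filtered with a second-order IIR notch (center ``f0``,
    −3 dB bandwidth ``bandwidth``) applied forward and backward
    (zero-phase), and the estimate is ``lead − filtered``: whatever the
    notch removes is, by construction, time-aligned with the input.
    """

    component = "pli"

    def __init__(self, fs: float = 200.0, f0: float = 50.0, bandwidth: float = 1.0):
        self.fs = fs
        self.f0 = f0
        self.bandwidth = bandwidth

    def _check_config(self, n: int) -> None:
        if self.f0 <= 0 or self.bandwidth <= 0:
            raise ConfigurationError("f0 and bandwidth must be positive")
        if self.fs <= 2 * self.f0:
            raise ConfigurationError(
                f"fs={self.fs} Hz cannot represent a {self.f0} Hz notch (need fs > {2 * self.f0})"
            )
        # filtfilt default padding needs > 3*max(len(a), len(b)) samples
        if n < 10:
            raise InsufficientDataError(f"need at least 10 samples for the notch filter; got {n}")

    def _transform_lead(self, lead: np.ndarray) -> np.ndarray:
        b, a = iirnotch(self.f0, self.f0 / self.bandwidth, fs=self.fs)
        return lead - filtfilt(b, a, lead)


class BlockStdNoiseEstimator(_PerLeadTransformer):
    """Block standard-deviation noise (SDN) statistic.

    Steps: (a) the standard deviation of the signal is computed in blocks of
    ``block_s`` seconds; (b) every ``group`` blocks, the mean and standard
    deviation of those block values are computed; (c) mean + 2·std is used
    as the noise measure for every block of the group. The per-block series
    is expanded back to per-sample resolution piecewise-constantly.

    Sample standard deviations (denominator N−1) are used throughout.
    Leftover samples that do not fill a block are folded into the final
    block; a trailing group with fewer than ``group`` blocks is processed
    with its actual count if it has at least 2 blocks, otherwise it is
    merged into the previous group.
    """

    component = "sdn"

    def __init__(self, fs: float = 200.0, block_s: float = 0.5, group: int = 10):
        self.fs = fs
        self.block_s = block_s
        self.group = group

    def _check_config(self, n: int) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        block = int(round(self.block_s * self.fs))
        if block < 2:
            raise ConfigurationError(
                f"block of {self.block_s} s at fs={self.fs} Hz has {block} samples; need >= 2"
            )
        if self.group < 1:
            raise ConfigurationError("group must be a positive block count")
        if n < block:
            raise InsufficientDataError(f"need at least one {self.block_s} s block ({block} samples)")

    def _transform_lead(self, lead: np.ndarray) -> np.ndarray:
        block = int(round(self.block_s * self.fs))
        n = lead.size
        n_blocks = n // block
        bounds = [i * block for i in range(n_blocks)] + [n]  # leftover folds into last block
        stds = np.array([np.std(lead[a:b], ddof=1) for a, b in zip(bounds, bounds[1:])])

        group_slices = [slice(i, min(i + self.group, n_blocks)) for i in range(0, n_blocks, self.group)]
        if len(group_slices) > 1 and (group_slices[-1].stop - group_slices[-1].start) < 2:
            last = group_slices.pop()
            prev = group_slices[-1]
            group_slices[-1] = slice(prev.start, last.stop)

        per_block = np.empty(n_blocks)
        for sl in group_slices:
            vals = stds[sl]
            spread = np.std(vals, ddof=1) if vals.size > 1 else 0.0
            per_block[sl] = np.mean(vals) + 2.0 * spread

        out = np.repeat(per_block, block)
        if out.size < n:  # leftover samples extend the final block's value
            out = np.append(out, np.full(n - out.size, per_block[-1]))
        return out[:n]


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def estimate_bw(lead, fs: float, window_s: float = 0.8) -> NoiseEstimate:
    """Baseline-wander estimate for one lead (see :class:`BaselineWanderEstimator`)."""
    return BaselineWanderEstimator(fs=fs, window_s=window_s).estimate(lead)


def estimate_pli(lead, fs: float, f0: float = 50.0, bandwidth: float = 1.0) -> NoiseEstimate:
    """Powerline-interference estimate for one lead (notch residual)."""
    return PowerlineInterferenceEstimator(fs=fs, f0=f0, bandwidth=bandwidth).estimate(lead)


def estimate_sdn(lead, fs: float, block_s: float = 0.5, group: int = 10) -> NoiseEstimate:
    """Block standard-deviation noise statistic for one lead."""
    return BlockStdNoiseEstimator(fs=fs, block_s=block_s, group=group).estimate(lead)


def naive_amplitude(estimate: NoiseEstimate | np.ndarray) -> np.ndarray:
    """Absolute value of the estimated instantaneous noise.

    This is the quantity that is histogrammed and thresholded downstream.
    """
    values = estimate.values if isinstance(estimate, NoiseEstimate) else np.asarray(estimate, float)
    return np.abs(values)


def decompose(record: ECGRecord, lead: int | str = 0, **params) -> DecompositionResult:
    """Run the three estimators on one lead of a record.

    Keyword arguments ``window_s``, ``f0``, ``bandwidth``, ``block_s`` and
    ``group`` override the estimator defaults. The residual is
    ``x − bw − pli``; SDN is an envelope statistic and is not subtracted.
    """
    x = record.lead(lead)
    bw = estimate_bw(x, record.fs, window_s=params.get("window_s", 0.8))
    pli = estimate_pli(
        x, record.fs, f0=params.get("f0", 50.0), bandwidth=params.get("bandwidth", 1.0)
    )
    sdn = estimate_sdn(
        x, record.fs, block_s=params.get("block_s", 0.5), group=params.get("group", 10)
    )
    residual = x - bw.values - pli.values
    return DecompositionResult(bw=bw, pli=pli, sdn=sdn, residual=residual)
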