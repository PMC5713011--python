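"""Clinical severity taxonomy and quantization of noise amplitudes.

The clinical taxonomy grades ECG segments by what can still be read from
them:

====  ==========  =====================================================
code  name        meaning
====  ==========  =====================================================
0     noise-free  no visible noise
1     low         P and T waves and QRS complexes readable
2     moderate    only QRS complexes reliably identified (>= 3 beats)
3     hard        QRS hardly recognizable or unrecognizable
4     other       calibration pulses, flat line, amplifier saturation
====  ==========  =====================================================

Codes 0-3 are totally ordered by severity; code 4 is a separate category
and is never produced by amplitude quantization (it is detectable only from
a clinical label track or synthetic ground truth).

Quantitative noise amplitudes are mapped onto levels 0-3 by three
thresholds per component. The thresholds were set manually in the original
workflow from pooled amplitude histograms; here they are a first-class
configurable object with a reproducible quantile-based default (noise-free
threshold holding the near-zero mass, hard threshold isolating the heavy
tail, middle threshold halfway between) and a manual override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError

__all__ = [
    "SEVERITY_NAMES",
    "SEVERITY_CODES",
    "ThresholdSet",
    "quantize_levels",
    "derive_thresholds",
    "SeverityQuantizer",
    "thresholds_from_config",
]

SEVERITY_NAMES = {0: "noise-free", 1: "low", 2: "moderate", 3: "hard", 4: "other"}
SEVERITY_CODES = {name: code for code, name in SEVERITY_NAMES.items()}

COMPONENTS = ("bw", "pli", "sdn")


@dataclass(frozen=True)
class ThresholdSet:
    """Three amplitude cut points (mV) defining levels 0-3 for one component.

    Intervals are closed on the left threshold: an amplitude exactly equal
    to a threshold maps to the lower level.
    """

    component: str
    t_free: float
    t_mid: float
    t_hard: float

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValidationError(f"unknown component {self.component!r}; expected one of {COMPONENTS}")
        if not (0 < self.t_free < self.t_mid < self.t_hard):
            raise ValidationError(
                f"thresholds must satisfy 0 < t_free < t_mid < t_hard, got "
                f"({self.t_free}, {self.t_mid}, {self.t_hard})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.t_free, self.t_mid, self.t_hard])


def quantize_levels(amplitude, thresholds: ThresholdSet) -> np.ndarray:
    """Map non-negative noise amplitudes onto levels 0-3.

    level 0 if a <= t_free; 1 if t_free < a <= t_mid; 2 if t_mid < a <=
    t_hard; 3 if a > t_hard.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.size and amplitude.min() < 0:
        raise ValidationError(
            "amplitudes must be non-negative; apply naive_amplitude() to signed noise first"
        )
    return np.searchsorted(thresholds.as_array(), amplitude, side="left").astype(np.int64)


def derive_thresholds(
    amplitudes,
    component: str = "sdn",
    q_free: float = 0.25,
    q_hard: float = 0.95,
) -> ThresholdSet:
    """Derive a ThresholdSet from pooled amplitudes via quantiles.

    ``t_free`` is the ``q_free`` quantile (holds the near-zero mass),
    ``t_hard`` the ``q_hard`` quantile (isolates the heavy tail), and
    ``t_mid`` their midpoint. For expert-chosen values construct
    :class:`ThresholdSet` directly instead.
    """
    amplitudes = np.asarray(amplitudes, dtype=float).ravel()
    if amplitudes.size < 100:
        raise ValidationError(f"need >= 100 pooled amplitude samples, got {amplitudes.size}")
    if amplitudes.min() < 0:
        raise ValidationError("amplitudes must be non-negative")
    if not 0 < q_free < q_hard < 1:
        raise ValidationError(f"need 0 < q_free < q_hard < 1, got ({q_free}, {q_hard})")
    t_free = float(np.quantile(amplitudes, q_free))
    t_hard = float(np.quantile(amplitudes, q_hard))
    if not t_free < t_hard or t_free <= 0:
        raise ValidationError(
            "degenerate amplitude distribution (quantiles coincide or are zero); "
            "set thresholds manually via ThresholdSet"
        )
    return ThresholdSet(component=component, t_free=t_free, t_mid=(t_free + t_hard) / 2, t_hard=t_hard)


class SeverityQuantizer(TransformerMixin, BaseEstimator):
    """Quantile-calibrated severity quantizer, sklearn style.

    ``fit`` pools the training amplitudes and derives thresholds (or adopts
    the manual ``thresholds`` override verbatim); ``transform`` maps
    amplitudes onto levels 0-3 column-wise. Derive once on a reference
    corpus, apply anywhere.

    Attributes
    ----------
    thresholds_ : ThresholdSet
        The cut points in effect after ``fit``.
    """

    def __init__(
        self,
        component: str = "sdn",
        q_free: float = 0.25,
        q_hard: float = 0.95,
        thresholds: ThresholdSet | None = None,
    ):
        self.component = component
        self.q_free = q_free
        self.q_hard = q_hard
        self.thresholds = thresholds

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.thresholds is not None:
            self.thresholds_ = self.thresholds
        else:
            self.thresholds_ = derive_thresholds(
                X, component=self.component, q_free=self.q_free, q_hard=self.q_hard
            )
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            raise ValidationError("SeverityQuantizer must be fitted before transform")
        return quantize_levels(np.asarray(X, dtype=float), self.thresholds_)


def thresholds_from_config(source, amplitudes_by_component: dict | None = None) -> dict[str, ThresholdSet]:
    """Build per-component ThresholdSets from a YAML file, stream or dict.

    Accepted entry shapes per component::

        sdn: {t_free: 0.1, t_mid: 0.5, t_hard: 1.0}   # manual
        bw:  {q_free: 0.25, q_hard: 0.95}             # quantile rule

    Quantile entries need pooled amplitudes supplied in
    ``amplitudes_by_component``.
    """
    if isinstance(source, dict):
        config = source
    elif hasattr(source, "read"):
        config = yaml.safe_load(source)
    else:
        with open(source) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError("threshold config must be a mapping of component -> settings")
    out: dict[str, ThresholdSet] = {}
    for component, entry in config.items():
        if {"t_free", "t_mid", "t_hard"} <= set(entry):
            out[component] = ThresholdSet(component=component, **{
                k: float(entry[k]) for k in ("t_free", "t_mid", "t_hard")
            })
        elif {"q_free", "q_hard"} <= set(entry):
            if not amplitudes_by_component or component not in amplitudes_by_component:
                raise ValidationError(
                    f"quantile thresholds for {component!r} need pooled amplitudes"
                )
            out[component] = derive_thresholds(
                amplitudes_by_component[component],
                component=component,
                q_free=float(entry["q_free"]),
                q_hard=float(entry["q_hard"]),
            )
        else:
            raise ValidationError(
                f"component {component!r}: give either t_free/t_mid/t_hard or q_free/q_hard"
            )
    return out
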