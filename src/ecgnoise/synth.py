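"""Synthetic labeled ECG recordings with scheduled noise episodes.

The generator emulates the two ambulatory scenarios this toolkit targets:
event-recorder bursts (200 Hz, 30-300 s) and Holter-style long recordings
(128 Hz, hours). A clean template ECG (Gaussian bumps for the P wave, QRS
complex and T wave, mild RR jitter) is corrupted by a schedule of episodes:

* additive — ``bw_drift`` (slow sinusoidal baseline drift), ``pli_tone``
  (mains-frequency sinusoid), ``emg_burst`` (band-limited Gaussian noise);
* replacement — ``flatline``, ``saturation``, ``calibration_pulse``
  (1 mV / 200 ms rectangular pulses at 1 Hz), which overwrite the signal.

Every episode carries a ground-truth severity derived from fixed magnitude
cut-offs that operationalize the clinical taxonomy: replacement episodes
are "other" (4); additive noise at >= 3x the R-peak amplitude obliterates
the QRS (hard, 3); noise strong enough to mask P/T waves but not the QRS is
moderate (2); any weaker visible noise is low (1). These constants are
documented configuration, not a claim to replicate expert judgment.

Output is fully determined by (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt

from .exceptions import ConfigurationError, ValidationError
from .io import ECGRecord, SegmentLabelTrack

__all__ = [
    "Episode",
    "NoiseSchedule",
    "LabeledSynthRecording",
    "generate_clean_ecg",
    "apply_schedule",
    "load_scenario",
    "generate_scenario",
    "eer_like_scenario",
    "holter_like_scenario",
]

ADDITIVE_KINDS = ("bw_drift", "pli_tone", "emg_burst")
REPLACE_KINDS = ("flatline", "saturation", "calibration_pulse")

# Template morphology (mV) and severity cut-offs for additive noise.
R_AMPLITUDE = 1.0
P_AMPLITUDE = 0.15
T_AMPLITUDE = 0.30
HARD_NOISE_MV = 3.0 * R_AMPLITUDE  # QRS no longer recognizable
MODERATE_NOISE_MV = 2.0 * P_AMPLITUDE  # P/T masked, QRS still visible
LOW_NOISE_MV = 0.03  # below this the noise is not considered visible

SATURATION_LEVEL_MV = 5.0
CAL_PULSE_MV = 1.0
CAL_PULSE_WIDTH_S = 0.2
CAL_PULSE_RATE_HZ = 1.0


@dataclass(frozen=True)
class Episode:
    start_s: float
    end_s: float
    kind: str
    magnitude: float = 0.0  # mV (std for emg_burst, amplitude otherwise)

    def __post_init__(self) -> None:
        if self.kind not in ADDITIVE_KINDS + REPLACE_KINDS:
            raise ValidationError(f"unknown episode kind {self.kind!r}")
        if not self.start_s < self.end_s:
            raise ValidationError(f"episode {self.kind}: start {self.start_s} >= end {self.end_s}")
        if self.magnitude < 0:
            raise ValidationError(f"episode {self.kind}: negative magnitude")


@dataclass
class NoiseSchedule:
    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.episodes = [e if isinstance(e, Episode) else Episode(**e) for e in self.episodes]
        replace = sorted(
            (e for e in self.episodes if e.kind in REPLACE_KINDS), key=lambda e: e.start_s
        )
        for prev, cur in zip(replace, replace[1:]):
            if cur.start_s < prev.end_s:
                raise ValidationError(
                    f"replacement episodes overlap: {prev.kind} until {prev.end_s} vs "
                    f"{cur.kind} from {cur.start_s}"
                )


@dataclass
class LabeledSynthRecording:
    """A corrupted recording plus its ground-truth severity track."""

    record: ECGRecord
    truth: SegmentLabelTrack
    schedule: NoiseSchedule
    seed: int


def generate_clean_ecg(
    fs: float,
    duration_s: float,
    hr_bpm: float = 60.0,
    seed: int = 0,
    n_leads: int = 1,
    rr_jitter: float = 0.03,
) -> ECGRecord:
    """Template-beat ECG: Gaussian bumps for P, QRS and T with RR jitter.

    The R peak is 1 mV; the second and further leads are scaled copies
    (0.8, 0.64, ...) so multi-lead plumbing can be exercised. This is a
    signal-processing test harness, not a physiological simulator.
    """
    if fs <= 0 or duration_s <= 0:
        raise ConfigurationError("fs and duration_s must be positive")
    if not 30.0 <= hr_bpm <= 200.0:
        raise ConfigurationError(f"heart rate {hr_bpm} bpm outside the supported 30-200 range")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    x = np.zeros(n)
    rr = 60.0 / hr_bpm
    beat = 0.4 * rr  # first R peak, leaving room for its P wave
    # (offset_s, amplitude_mV, width_s) per wave of the template beat
    waves = (
        (-0.20 * rr / 1.0, P_AMPLITUDE, 0.025),  # P
        (0.0, R_AMPLITUDE, 0.012),  # R
        (0.30 * rr / 1.0, T_AMPLITUDE, 0.060),  # T
    )
    while beat < duration_s + rr:
        for offset, amp, width in waves:
            center = beat + offset
            lo = max(0, int((center - 5 * width) * fs))
            hi = min(n, int((center + 5 * width) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / width) ** 2)
        beat += rr * (1.0 + rr_jitter * rng.standard_normal())
    samples = np.column_stack([x * 0.8**j for j in range(n_leads)])
    names = [f"lead{j + 1}" for j in range(n_leads)]
    return ECGRecord(samples=samples, fs=fs, lead_names=names)


def _severity_of(episode: Episode) -> int:
    if episode.kind in REPLACE_KINDS:
        return 4
    if episode.magnitude >= HARD_NOISE_MV:
        return 3
    if episode.magnitude >= MODERATE_NOISE_MV:
        return 2
    if episode.magnitude > LOW_NOISE_MV:
        return 1
    return 0


def _emg_noise(n: int, fs: float, magnitude: float, rng) -> np.ndarray:
    """Band-limited Gaussian noise normalized to the requested std (mV)."""
    white = rng.standard_normal(n)
    if n < 30:
        noise = white
    else:
        sos = butter(4, min(15.0, 0.4 * fs), btype="highpass", fs=fs, output="sos")
        noise = sosfiltfilt(sos, white)
    sd = noise.std()
    return noise * (magnitude / sd) if sd > 0 else noise


def apply_schedule(
    record: ECGRecord, schedule: NoiseSchedule, seed: int = 0, pli_f0: float = 50.0
) -> LabeledSynthRecording:
    """Corrupt a record according to a schedule and label the ground truth.

    Additive episodes sum into the signal; replacement episodes overwrite
    it. The per-sample severity is the maximum over active episodes
    (replacements force level 4), run-length encoded into the truth track.
    """
    rng = np.random.default_rng(seed)
    n, fs = record.n_samples, record.fs
    end_time = record.t0 + record.duration_s
    for ep in schedule.episodes:
        if ep.start_s < record.t0 - 1e-9 or ep.end_s > end_time + 1e-9:
            raise ValidationError(
                f"episode {ep.kind} [{ep.start_s}, {ep.end_s}) outside record extent "
                f"[{record.t0}, {end_time})"
            )
    samples = record.samples.copy()
    severity = np.zeros(n, dtype=np.int64)
    t = record.times()

    for ep in schedule.episodes:
        a = int(round((ep.start_s - record.t0) * fs))
        b = int(round((ep.end_s - record.t0) * fs))
        a, b = max(a, 0), min(b, n)
        if b <= a:
            continue
        seg_t = t[a:b]
        if ep.kind == "bw_drift":
            f_drift = rng.uniform(0.1, 0.3)
            phase = rng.uniform(0, 2 * np.pi)
            noise = ep.magnitude * np.sin(2 * np.pi * f_drift * seg_t + phase)
            samples[a:b] += noise[:, None]
        elif ep.kind == "pli_tone":
            phase = rng.uniform(0, 2 * np.pi)
            noise = ep.magnitude * np.sin(2 * np.pi * pli_f0 * seg_t + phase)
            samples[a:b] += noise[:, None]
        elif ep.kind == "emg_burst":
            noise = _emg_noise(b - a, fs, ep.magnitude, rng)
            samples[a:b] += noise[:, None]
        elif ep.kind == "flatline":
            samples[a:b] = 0.0
        elif ep.kind == "saturation":
            samples[a:b] = SATURATION_LEVEL_MV
        elif ep.kind == "calibration_pulse":
            pulse = (np.mod(seg_t - seg_t[0], 1.0 / CAL_PULSE_RATE_HZ) < CAL_PULSE_WIDTH_S)
            samples[a:b] = CAL_PULSE_MV * pulse[:, None]
        level = _severity_of(ep)
        if ep.kind in REPLACE_KINDS:
            severity[a:b] = 4
        else:
            severity[a:b] = np.maximum(severity[a:b], level)

    # run-length encode the per-sample severity into the truth track
    change = np.flatnonzero(np.diff(severity)) + 1
    bounds = np.concatenate([[0], change, [n]])
    entries = [
        (i + 1, record.t0 + lo / fs, record.t0 + hi / fs, int(severity[lo]))
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
    ]
    out = ECGRecord(
        samples=samples, fs=fs, lead_names=list(record.lead_names), t0=record.t0,
        gaps=list(record.gaps),
    )
    return LabeledSynthRecording(
        record=out, truth=SegmentLabelTrack(entries=entries), schedule=schedule, seed=seed
    )


# ---------------------------------------------------------------------------
# Scenario files and canned profiles
# ---------------------------------------------------------------------------

def load_scenario(source) -> dict:
    """Load a YAML scenario (fs, duration_s, hr_bpm, seed, episodes)."""
    if isinstance(source, dict):
        config = source
    elif hasattr(source, "read"):
        config = yaml.safe_load(source)
    else:
        with open(source) as fh:
            config = yaml.safe_load(fh)
    for key in ("fs", "duration_s"):
        if key not in config:
            raise ValidationError(f"scenario is missing required key {key!r}")
    return config


def generate_scenario(source, seed: int | None = None) -> LabeledSynthRecording:
    """Generate a labeled recording from a scenario dict/YAML file.

    ``seed`` overrides the scenario's own seed when given.
    """
    config = load_scenario(source)
    use_seed = int(config.get("seed", 0)) if seed is None else int(seed)
    record = generate_clean_ecg(
        fs=float(config["fs"]),
        duration_s=float(config["duration_s"]),
        hr_bpm=float(config.get("hr_bpm", 60.0)),
        seed=use_seed,
        n_leads=int(config.get("n_leads", 1)),
    )
    schedule = NoiseSchedule(episodes=config.get("episodes", []))
    return apply_schedule(record, schedule, seed=use_seed + 1)


def eer_like_scenario(duration_s: float = 120.0, seed: int = 0) -> dict:
    """Event-recorder-style burst: 200 Hz, seconds-to-minutes long.

    Mixes baseline drift, a mains tone, EMG bursts of three intensities and
    a short flat-line, scaled to the recording length.
    """
    d = duration_s
    return {
        "fs": 200.0,
        "duration_s": d,
        "hr_bpm": 72.0,
        "seed": seed,
        "episodes": [
            {"start_s": 0.05 * d, "end_s": 0.35 * d, "kind": "bw_drift", "magnitude": 0.4},
            {"start_s": 0.20 * d, "end_s": 0.40 * d, "kind": "pli_tone", "magnitude": 0.15},
            {"start_s": 0.45 * d, "end_s": 0.55 * d, "kind": "emg_burst", "magnitude": 0.10},
            {"start_s": 0.60 * d, "end_s": 0.70 * d, "kind": "emg_burst", "magnitude": 0.8},
            {"start_s": 0.75 * d, "end_s": 0.85 * d, "kind": "emg_burst", "magnitude": 4.0},
            {"start_s": 0.90 * d, "end_s": 0.95 * d, "kind": "flatline"},
        ],
    }


def holter_like_scenario(duration_s: float = 7200.0, seed: int = 0) -> dict:
    """Holter-style stretch: 128 Hz, hours long, sparse severe episodes."""
    d = duration_s
    return {
        "fs": 128.0,
        "duration_s": d,
        "hr_bpm": 65.0,
        "seed": seed,
        "episodes": [
            {"start_s": 0.00 * d, "end_s": 0.50 * d, "kind": "bw_drift", "magnitude": 0.2},
            {"start_s": 0.10 * d, "end_s": 0.12 * d, "kind": "emg_burst", "magnitude": 0.5},
            {"start_s": 0.30 * d, "end_s": 0.31 * d, "kind": "emg_burst", "magnitude": 3.5},
            {"start_s": 0.55 * d, "end_s": 0.555 * d, "kind": "calibration_pulse"},
            {"start_s": 0.70 * d, "end_s": 0.72 * d, "kind": "saturation"},
            {"start_s": 0.85 * d, "end_s": 0.90 * d, "kind": "pli_tone", "magnitude": 0.1},
        ],
    }
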