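"""Rule-based crackle and wheeze candidate detection.

The rules operationalize the classical time-domain criteria for
adventitious lung sounds:

crackle
    an explosive discontinuous transient shorter than 20 ms whose peak
    magnitude exceeds twice the signal's average (peak) magnitude;
wheeze
    a sustained musical sound of at least 500 ms, found where the peak of
    the 200 ms Hamming-smoothed magnitude envelope over a sliding 160 ms
    window stays above a multiple of the envelope's mean.

Both thresholds are pure amplitude ratios, so detection is invariant to
positive rescaling of the input.

Magnitude reference
-------------------
"Average magnitude" is operationalized as the running mean of the
short-time peak magnitude: the rectified signal is peak-held over 20 ms
and averaged over a sliding 1 s window. Referencing average *peak*
magnitude rather than average absolute amplitude keeps the 2x criterion
selective on noisy backgrounds — for a Gaussian background the mean
absolute amplitude sits near 0.8 sigma, and the background's own envelope
crosses twice that level hundreds of times per recording, whereas twice
the average peak magnitude (~4-5 sigma) is crossed only by genuine
transients. The sliding window keeps the reference insensitive to the
breath-cycle amplitude modulation; ``reference="global"`` restores a
single whole-recording reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hamming

from .audio_io import Recording
from .simulate import AnnotatedEvent


@dataclasses.dataclass
class DetectorConfig:
    """Tunable parameters of the rule-based detector (times in seconds)."""

    crackle_max_duration: float = 0.020
    crackle_peak_ratio: float = 2.0
    wheeze_min_duration: float = 0.500
    wheeze_peak_window: float = 0.160
    wheeze_margin: float = 2.0
    lowpass_window: float = 0.200  # Hamming smoothing of the wheeze envelope
    bandpass: tuple[float, float] = (100.0, 2000.0)
    merge_gap: float = 0.050  # wheeze runs closer than this merge
    crackle_envelope_window: float = 0.001  # peak-hold envelope follower
    crackle_merge_gap: float = 0.002  # closes carrier-frequency dips
    magnitude_peak_window: float = 0.020  # short-time peak magnitude
    reference: str = "windowed"  # "windowed" | "global"
    reference_window: float = 1.0

    def validate(self, sample_rate: int | None = None) -> None:
        for name in ("crackle_max_duration", "crackle_peak_ratio",
                     "wheeze_min_duration", "wheeze_peak_window",
                     "lowpass_window", "merge_gap",
                     "crackle_envelope_window", "magnitude_peak_window",
                     "reference_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.crackle_max_duration >= self.wheeze_min_duration:
            raise ValueError("crackle_max_duration must be < wheeze_min_duration")
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise ValueError("bandpass must satisfy 0 < low < high")
        if sample_rate is not None and hi >= sample_rate / 2:
            raise ValueError(
                f"bandpass high edge {hi} Hz infeasible at {sample_rate} Hz sampling"
            )
        if self.reference not in ("windowed", "global"):
            raise ValueError("reference must be 'windowed' or 'global'")


def preprocess(rec: Recording, cfg: DetectorConfig | None = None) -> np.ndarray:
    """Zero-phase band-pass filter the recording and remove the mean.

    Output has the same length as the input.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate(rec.sample_rate)
    sos = butter(4, cfg.bandpass, btype="bandpass", fs=rec.sample_rate, output="sos")
    y = sosfiltfilt(sos, rec.samples)
    return y - y.mean()


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True values."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _magnitude_reference(signal: np.ndarray, sample_rate: int,
                         cfg: DetectorConfig) -> np.ndarray:
    """Average peak magnitude, windowed or global (as a constant array)."""
    peak_mag = maximum_filter1d(
        np.abs(signal), max(1, int(cfg.magnitude_peak_window * sample_rate))
    )
    if cfg.reference == "global":
        return np.full_like(signal, peak_mag.mean())
    return uniform_filter1d(peak_mag, max(1, int(cfg.reference_window * sample_rate)))


def detect_crackles(
    signal: np.ndarray, sample_rate: int, cfg: DetectorConfig | None = None
) -> list[AnnotatedEvent]:
    """Find crackle candidates on a preprocessed signal.

    Maximal runs where the 1 ms peak-hold envelope exceeds
    ``crackle_peak_ratio`` times the magnitude reference are kept when
    shorter than ``crackle_max_duration``. Events are sorted by onset and
    non-overlapping; each carries its measured peak ratio.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        return []
    env = maximum_filter1d(
        np.abs(signal), max(1, int(cfg.crackle_envelope_window * sample_rate))
    )
    ref = _magnitude_reference(signal, sample_rate, cfg)
    runs = _merge_runs(_runs(env > cfg.crackle_peak_ratio * ref),
                       max(1, int(cfg.crackle_merge_gap * sample_rate)))
    events = []
    for s, e in runs:
        dur = (e - s) / sample_rate
        if dur >= cfg.crackle_max_duration:
            continue
        seg = slice(s, e)
        ratio = float(np.max(np.abs(signal[seg])) / np.mean(ref[seg]))
        events.append(AnnotatedEvent("crackle", s / sample_rate, dur, ratio))
    return events


def detect_wheezes(
    signal: np.ndarray, sample_rate: int, cfg: DetectorConfig | None = None
) -> list[AnnotatedEvent]:
    """Find wheeze candidates on a preprocessed signal.

    The rectified signal is smoothed with a 200 ms Hamming-window moving
    average; a sample is wheeze-active when the peak of that envelope in
    the 160 ms window centred on it exceeds ``wheeze_margin`` times the
    envelope's global mean. Active runs closer than ``merge_gap`` merge,
    and runs of at least ``wheeze_min_duration`` become events.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        return []
    win = hamming(max(3, int(cfg.lowpass_window * sample_rate)), sym=True)
    win /= win.sum()
    env = np.convolve(np.abs(signal), win, mode="same")
    peak = maximum_filter1d(env, max(1, int(cfg.wheeze_peak_window * sample_rate)))
    threshold = cfg.wheeze_margin * env.mean()
    if threshold <= 0:
        return []
    runs = _merge_runs(_runs(peak > threshold),
                       max(1, int(cfg.merge_gap * sample_rate)))
    events = []
    for s, e in runs:
        dur = (e - s) / sample_rate
        if dur < cfg.wheeze_min_duration:
            continue
        ratio = float(np.max(env[s:e]) / env.mean())
        events.append(AnnotatedEvent("wheeze", s / sample_rate, dur, ratio))
    return events


def detect_events(
    rec: Recording, cfg: DetectorConfig | None = None
) -> list[AnnotatedEvent]:
    """Preprocess a recording and run both detectors.

    A recording yielding both crackle and wheeze candidates is not
    rejected here; labelling is left to the classifier stage.
    """
    cfg = cfg or DetectorConfig()
    y = preprocess(rec, cfg)
    events = detect_crackles(y, rec.sample_rate, cfg)
    events += detect_wheezes(y, rec.sample_rate, cfg)
    events.sort(key=lambda ev: ev.onset)
    return events
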