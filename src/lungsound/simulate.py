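"""Seeded synthetic auscultation recordings with ground-truth event logs.

The generator emulates the statistical structure the rule-based detector
assumes: a breath-cycle-modulated noise background, short explosive
crackle transients (< 20 ms, peak well above the background magnitude)
and sustained narrowband wheeze tones (>= 500 ms). Each recording carries
an exact log of the injected events, which downstream stages use as the
oracle for recall/false-alarm measurement and as classifier labels.

Model summary
-------------
background
    Pink-weighted Gaussian noise band-passed to ``background_band``
    (default 100-1000 Hz), amplitude-modulated by a raised-sinusoid
    breath envelope of period ``breath_cycle`` with a relative floor of
    0.4 (breathing is audible in both phases; the floor keeps the trough
    from falling silent).
crackle
    Exponentially damped sinusoid ``A exp(-t/tau) sin(2 pi f t)`` with
    ``tau = duration / 5`` and carrier drawn uniformly from 200-2000 Hz,
    normalized to unit peak then scaled to ``10^(snr_db/20)`` times the
    local background RMS at the onset (never less than the global RMS,
    so the logged peak ratio always meets the requested bound). Crackle
    loudness tracking the local breath phase mirrors the flow dependence
    of real crackles.
wheeze
    Monophonic tone at the requested frequency with 50 ms raised-cosine
    on/off ramps, scaled the same way against the global background RMS.

A recording never mixes crackles and wheezes: recordings with both kinds
of finding are excluded from study corpora, and the simulator enforces
the same rule.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .audio_io import Recording, Sex, write_manifest, write_wav

#: Relative amplitude of the breath envelope at the trough.
ENVELOPE_FLOOR = 0.4

#: Length of the raised-cosine on/off ramps on wheeze tones (seconds).
WHEEZE_RAMP = 0.050

#: Window around a crackle onset used to estimate the local background RMS.
LOCAL_RMS_WINDOW = 0.5


@dataclasses.dataclass(frozen=True)
class AnnotatedEvent:
    """A detected or injected adventitious event.

    ``peak_ratio`` is the event's peak magnitude divided by the average
    magnitude of the background (injection) or the detector's magnitude
    reference (detection).
    """

    kind: str  # "crackle" | "wheeze"
    onset: float
    duration: float
    peak_ratio: float

    def __post_init__(self) -> None:
        if self.kind not in ("crackle", "wheeze"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0 or self.peak_ratio <= 0:
            raise ValueError("duration and peak_ratio must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclasses.dataclass
class SimSpec:
    """Parameters of one synthetic recording."""

    duration: float = 9.0
    sample_rate: int = 8000
    breath_cycle: float = 3.0
    background_band: tuple[float, float] = (100.0, 1000.0)
    snr_db: float = 20.0
    n_crackles: int = 0
    crackle_duration: float = 0.010
    wheeze_segments: tuple[tuple[float, float, float], ...] = ()
    contaminant_bursts: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.duration / self.breath_cycle < 2:
            raise ValueError("duration must cover at least two breathing cycles")
        if not self.crackle_duration < 0.020:
            raise ValueError("crackle_duration must be < 20 ms")
        for onset, dur, freq in self.wheeze_segments:
            if dur < 0.5:
                raise ValueError("every wheeze duration must be >= 0.5 s")
            if onset < 0 or onset + dur > self.duration:
                raise ValueError("wheeze segment must lie inside the recording")
            if freq <= 0:
                raise ValueError("wheeze frequency must be positive")
        if self.n_crackles > 0 and self.wheeze_segments:
            raise ValueError(
                "recordings mixing crackles and wheezes are excluded by design"
            )


def _pink_bandpassed_noise(rng: np.random.Generator, n: int, fs: int,
                           band: tuple[float, float]) -> np.ndarray:
    """Gaussian noise with 1/f power weighting, band-passed to `band`."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(freqs[1:])
    x = np.fft.irfft(spec, n)
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def breath_envelope(t: np.ndarray, breath_cycle: float,
                    floor: float = ENVELOPE_FLOOR) -> np.ndarray:
    """Raised-sinusoid amplitude envelope with one peak per breath cycle."""
    return floor + (1.0 - floor) * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / breath_cycle))


def crackle_waveform(duration: float, carrier_hz: float, fs: int) -> np.ndarray:
    """Unit-peak exponentially damped sinusoid (tau = duration / 5)."""
    t = np.arange(int(round(duration * fs))) / fs
    tau = duration / 5.0
    w = np.exp(-t / tau) * np.sin(2.0 * np.pi * carrier_hz * t)
    return w / np.max(np.abs(w))


def _wheeze_waveform(duration: float, freq: float, fs: int) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    tone = np.sin(2.0 * np.pi * freq * t)
    n_ramp = min(int(WHEEZE_RAMP * fs), len(tone) // 2)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    tone[:n_ramp] *= ramp
    tone[-n_ramp:] *= ramp[::-1]
    return tone


def simulate_recording(
    spec: SimSpec, recording_id: str = "sim", **metadata
) -> tuple[Recording, list[AnnotatedEvent]]:
    """Synthesize one recording and its exact event log.

    Identical specs (including the seed) produce bit-identical output.
    """
    spec.validate()
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)

    bg = _pink_bandpassed_noise(rng, n, fs, spec.background_band)
    t = np.arange(n) / fs
    bg = bg * breath_envelope(t, spec.breath_cycle)
    bg_rms = float(np.sqrt(np.mean(bg**2)))
    bg_mean_mag = float(np.mean(np.abs(bg)))
    amp_target = 10.0 ** (spec.snr_db / 20.0)

    x = bg.copy()
    events: list[AnnotatedEvent] = []

    if spec.n_crackles > 0:
        onsets = _spaced_onsets(rng, spec.n_crackles, spec.duration,
                                spec.crackle_duration, margin=0.25)
        half = int(LOCAL_RMS_WINDOW / 2 * fs)
        for onset in onsets:
            carrier = rng.uniform(200.0, 2000.0)
            wave = crackle_waveform(spec.crackle_duration, carrier, fs)
            i = int(round(onset * fs))
            local = np.sqrt(np.mean(bg[max(0, i - half): i + half] ** 2))
            amp = amp_target * max(float(local), bg_rms)
            x[i: i + len(wave)] += amp * wave
            events.append(
                AnnotatedEvent("crackle", onset, spec.crackle_duration,
                               amp / bg_mean_mag)
            )

    for onset, dur, freq in spec.wheeze_segments:
        wave = _wheeze_waveform(dur, freq, fs)
        amp = amp_target * bg_rms
        i = int(round(onset * fs))
        x[i: i + len(wave)] += amp * wave
        events.append(AnnotatedEvent("wheeze", onset, dur, amp / bg_mean_mag))

    # Optional crying/speech-like contaminant: short tone bursts too brief
    # to qualify as wheezes, off by default.
    for _ in range(spec.contaminant_bursts):
        dur = rng.uniform(0.10, 0.30)
        onset = rng.uniform(0.0, spec.duration - dur)
        freq = rng.uniform(300.0, 600.0)
        wave = _wheeze_waveform(dur, freq, fs)
        i = int(round(onset * fs))
        x[i: i + len(wave)] += amp_target * bg_rms * wave

    x = x / np.max(np.abs(x))
    rec = Recording(recording_id=recording_id, samples=x, sample_rate=fs, **metadata)
    events.sort(key=lambda e: e.onset)
    return rec, events


def _spaced_onsets(rng: np.random.Generator, count: int, duration: float,
                   event_duration: float, margin: float) -> np.ndarray:
    """Draw non-overlapping onsets away from the recording edges."""
    lo, hi = margin, duration - margin - event_duration
    for _ in range(1000):
        onsets = np.sort(rng.uniform(lo, hi, count))
        if count == 1 or np.min(np.diff(onsets)) > 2 * event_duration + 0.010:
            return onsets
    raise RuntimeError("could not place non-overlapping events")


CLASSES = ("crackle", "wheeze", "normal")


def build_corpus(
    out_dir: str | Path,
    n_per_class: int,
    snr_db: float = 20.0,
    seed: int = 0,
    duration: float = 9.0,
    sample_rate: int = 8000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a balanced three-class corpus of WAVs plus CSV metadata.

    Produces ``manifest.csv`` (recording_id, age_months, sex,
    chest_location, path), ``labels.csv`` (recording_id, label) and
    ``events.csv`` (recording_id, kind, onset_s, duration_s, peak_ratio)
    under ``out_dir``. Crackle recordings carry 3-8 crackles; wheeze
    recordings one tone of 0.8-2.0 s at 200-800 Hz; normal recordings no
    events. Returns (manifest, labels) data frames.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = corpus_specs(n_per_class, snr_db, seed, duration, sample_rate)

    meta_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA9]))
    manifest_rows, label_rows, event_rows = [], [], []
    for rec_id, label, spec in specs:
        rec, events = simulate_recording(spec, recording_id=rec_id)
        rec.age_months = float(np.round(meta_rng.uniform(1, 120), 1))
        rec.sex = Sex("male" if meta_rng.random() < 0.5 else "female")
        rec.chest_location = int(meta_rng.integers(1, 7))
        wav_path = out_dir / f"{rec_id}.wav"
        write_wav(wav_path, rec)
        manifest_rows.append(
            {"recording_id": rec_id, "age_months": rec.age_months,
             "sex": rec.sex.value, "chest_location": rec.chest_location,
             "path": wav_path.name}
        )
        label_rows.append({"recording_id": rec_id, "label": label})
        for ev in events:
            event_rows.append(
                {"recording_id": rec_id, "kind": ev.kind, "onset_s": ev.onset,
                 "duration_s": ev.duration, "peak_ratio": ev.peak_ratio}
            )

    manifest = pd.DataFrame(manifest_rows)
    labels = pd.DataFrame(label_rows)
    write_manifest(out_dir / "manifest.csv", manifest)
    labels.to_csv(out_dir / "labels.csv", index=False)
    pd.DataFrame(
        event_rows, columns=["recording_id", "kind", "onset_s", "duration_s", "peak_ratio"]
    ).to_csv(out_dir / "events.csv", index=False)
    return manifest, labels


def corpus_specs(
    n_per_class: int,
    snr_db: float = 20.0,
    seed: int = 0,
    duration: float = 9.0,
    sample_rate: int = 8000,
) -> list[tuple[str, str, SimSpec]]:
    """Deterministic (recording_id, label, SimSpec) triples for a corpus.

    Exposed separately so in-memory pipelines (tests, cross-validation)
    can simulate without touching the filesystem.
    """
    ss = np.random.SeedSequence([seed, 0x51])
    draw = np.random.default_rng(ss)
    out = []
    for i in range(n_per_class * len(CLASSES)):
        label = CLASSES[i % len(CLASSES)]
        rec_seed = int(draw.integers(0, 2**31 - 1))
        spec = SimSpec(duration=duration, sample_rate=sample_rate,
                       snr_db=snr_db, seed=rec_seed)
        if label == "crackle":
            spec.n_crackles = int(draw.integers(3, 9))
        elif label == "wheeze":
            wdur = float(draw.uniform(0.8, 2.0))
            onset = float(draw.uniform(0.5, duration - wdur - 0.5))
            freq = float(draw.uniform(200.0, 800.0))
            spec.wheeze_segments = ((onset, wdur, freq),)
        out.append((f"rec{i:04d}", label, spec))
    return out


def events_to_frame(recording_id: str, events: list[AnnotatedEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"recording_id": recording_id, "kind": e.kind, "onset_s": e.onset,
          "duration_s": e.duration, "peak_ratio": e.peak_ratio} for e in events],
        columns=["recording_id", "kind", "onset_s", "duration_s", "peak_ratio"],
    )
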