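"""Reading, writing and validity screening of auscultation recordings.

A :class:`Recording` bundles the mono waveform with the clinical metadata
that travels with every chest auscultation: patient age and sex plus the
chest location index (1-4 posterior, 5-6 anterior). Recordings shorter
than the nominal capture length, clipped recordings and dead channels are
screened out by :func:`validate_recording` before any analysis.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical internal sample rate. Lung-sound energy lies well below 4 kHz,
#: so recordings at other rates are resampled to 8 kHz on load.
CANONICAL_RATE = 8000

#: Samples with |amplitude| at or above this are counted as clipped.
CLIP_LEVEL = 0.999

#: Signals with RMS below this are treated as a dead channel.
DEAD_RMS = 1e-5


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class RejectReason(str, enum.Enum):
    OK = "ok"
    TOO_SHORT = "too_short"
    LOW_QUALITY = "low_quality"


@dataclasses.dataclass(frozen=True)
class ValidationResult:
    accepted: bool
    reason: RejectReason

    def __post_init__(self) -> None:
        if self.accepted != (self.reason is RejectReason.OK):
            raise ValueError("accepted must hold exactly when reason is 'ok'")


@dataclasses.dataclass
class Recording:
    """A mono auscultation recording plus clinical metadata.

    Samples are float64 in [-1, 1]; time coordinates throughout the
    package are seconds from recording start, with events as half-open
    intervals [onset, onset + duration).
    """

    recording_id: str
    samples: np.ndarray
    sample_rate: int
    age_months: float = float("nan")
    sex: Sex = Sex.UNKNOWN
    chest_location: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.chest_location not in range(1, 7):
            raise ValueError(f"chest_location must be in 1..6, got {self.chest_location}")
        if isinstance(self.sex, str) and not isinstance(self.sex, Sex):
            self.sex = Sex(self.sex)

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.sample_rate


class AudioFormatError(ValueError):
    """The file could not be decoded as a supported WAV."""


def _to_float(data: np.ndarray) -> np.ndarray:
    """Map integer PCM to [-1, 1); pass floats through."""
    if data.dtype == np.int16:
        return data / 32768.0
    if data.dtype == np.int32:
        return data / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    raise AudioFormatError(f"unsupported WAV sample format: {data.dtype}")


def read_wav(
    path: str | Path,
    recording_id: str | None = None,
    *,
    target_rate: int | None = CANONICAL_RATE,
    **metadata,
) -> Recording:
    """Read a WAV file as a normalized mono :class:`Recording`.

    Multi-channel input is averaged to mono. Samples are rescaled so the
    maximum absolute amplitude is at most 1. When ``target_rate`` is set
    (the default 8 kHz) recordings at other rates are resampled.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on corrupt RIFF
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"empty audio in {path}")
    x = _to_float(np.atleast_1d(data))
    if x.ndim == 2:
        x = x.mean(axis=1)
    if target_rate is not None and rate != target_rate:
        from math import gcd

        g = gcd(int(target_rate), int(rate))
        x = resample_poly(x, target_rate // g, rate // g)
        rate = target_rate
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return Recording(
        recording_id=recording_id or path.stem,
        samples=x,
        sample_rate=int(rate),
        **metadata,
    )


def write_wav(path: str | Path, rec: Recording, *, dtype: str = "float32") -> None:
    """Write a recording as IEEE-float (default) or 16-bit PCM WAV."""
    if dtype == "float32":
        wavfile.write(path, rec.sample_rate, rec.samples.astype(np.float32))
    elif dtype == "int16":
        scaled = np.clip(rec.samples, -1.0, 1.0) * 32767.0
        wavfile.write(path, rec.sample_rate, np.round(scaled).astype(np.int16))
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")


def validate_recording(
    rec: Recording,
    min_duration: float = 9.0,
    clip_fraction_max: float = 0.01,
) -> ValidationResult:
    """Screen a recording for the rejection rules applied before analysis.

    A recording is rejected as ``too_short`` when its duration is below
    ``min_duration`` (nominally 9 s, two full breathing cycles), and as
    ``low_quality`` when more than ``clip_fraction_max`` of samples sit at
    full scale, or when the signal is essentially dead (RMS < 1e-5).
    """
    if rec.duration_seconds < min_duration:
        return ValidationResult(False, RejectReason.TOO_SHORT)
    clipped = np.mean(np.abs(rec.samples) >= CLIP_LEVEL)
    if clipped > clip_fraction_max:
        return ValidationResult(False, RejectReason.LOW_QUALITY)
    if np.sqrt(np.mean(rec.samples**2)) < DEAD_RMS:
        return ValidationResult(False, RejectReason.LOW_QUALITY)
    return ValidationResult(True, RejectReason.OK)


MANIFEST_COLUMNS = ["recording_id", "age_months", "sex", "chest_location", "path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a recording manifest CSV (UTF-8, header row required)."""
    df = pd.read_csv(path, dtype={"recording_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    if df["chest_location"].isna().any():
        raise ValueError("chest_location is required for every manifest row")
    return df[MANIFEST_COLUMNS]


def write_manifest(path: str | Path, rows: pd.DataFrame) -> None:
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_manifest_recordings(
    manifest: pd.DataFrame, base_dir: str | Path | None = None
) -> list[Recording]:
    """Load every recording referenced by a manifest table."""
    recs = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        sex = row.sex if isinstance(row.sex, str) and row.sex in Sex._value2member_map_ else "unknown"
        age = float(row.age_months) if pd.notna(row.age_months) else float("nan")
        recs.append(
            read_wav(
                p,
                recording_id=str(row.recording_id),
                age_months=age,
                sex=Sex(sex),
                chest_location=int(row.chest_location),
            )
        )
    return recs
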