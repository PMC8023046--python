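"""Wavelet-packet-decomposition features for recording classification.

A full wavelet-packet tree of depth ``d`` with an orthogonal wavelet
(db6 by default) splits the signal into ``2^d`` uniform subbands; each
terminal node contributes its log subband energy and the normalized
Shannon entropy of its squared coefficients, giving a fixed-length
vector of ``2 * 2^d`` values independent of signal length. Nodes are
ordered by natural (frequency) ordering, so feature ``k`` always refers
to the same frequency slot. The zero-extension signal mode keeps the
transform energy-conserving, which the tests assert (Parseval).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt

#: Subband energies are floored at this value before taking the log.
ENERGY_FLOOR = 1e-12

DEFAULT_WAVELET = "db6"
DEFAULT_DEPTH = 4


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    recording_id: str
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def feature_names(depth: int = DEFAULT_DEPTH) -> tuple[str, ...]:
    """Names of the ``2 * 2^depth`` features, frequency-ordered."""
    n_bands = 2**depth
    return tuple(
        f"{stat}_band{i:02d}" for i in range(n_bands) for stat in ("logE", "entropy")
    )


def wpd_features(
    signal: np.ndarray,
    sample_rate: int,
    recording_id: str = "",
    wavelet: str = DEFAULT_WAVELET,
    depth: int = DEFAULT_DEPTH,
) -> FeatureVector:
    """Per-subband log-energy and normalized entropy at the given depth.

    Raises ``ValueError`` for signals shorter than ``2**depth`` samples or
    unknown wavelet identifiers.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or len(signal) < 2**depth:
        raise ValueError(f"signal must be 1-D with at least {2**depth} samples")
    try:
        wavelet_obj = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet identifier {wavelet!r}") from exc
    if not wavelet_obj.orthogonal:
        raise ValueError(f"wavelet {wavelet!r} is not orthogonal")

    wp = pywt.WaveletPacket(signal, wavelet_obj, mode="zero", maxlevel=depth)
    nodes = wp.get_level(depth, order="freq")
    values = []
    for node in nodes:
        coeffs = np.asarray(node.data, dtype=np.float64)
        sq = coeffs**2
        energy = float(sq.sum())
        values.append(np.log(max(energy, ENERGY_FLOOR)))
        values.append(_normalized_entropy(sq, energy))
    return FeatureVector(recording_id, np.asarray(values), feature_names(depth))


def _normalized_entropy(sq: np.ndarray, energy: float) -> float:
    """Shannon entropy of the squared-coefficient distribution, in [0, 1]."""
    if energy <= 0.0 or len(sq) < 2:
        return 0.0
    p = sq / energy
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(sq)))


def subband_energies(
    signal: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    depth: int = DEFAULT_DEPTH,
) -> np.ndarray:
    """Raw (unlogged) terminal subband energies, frequency-ordered."""
    wp = pywt.WaveletPacket(np.asarray(signal, dtype=np.float64),
                            wavelet, mode="zero", maxlevel=depth)
    return np.array(
        [float(np.sum(np.asarray(n.data) ** 2)) for n in wp.get_level(depth, order="freq")]
    )


def features_to_frame(features: list[FeatureVector]):
    """Feature table with recording_id plus one named column per feature."""
    import pandas as pd

    if not features:
        return pd.DataFrame(columns=["recording_id"])
    names = features[0].feature_names
    for fv in features:
        if fv.feature_names != names:
            raise ValueError("inconsistent feature_names across vectors")
    rows = [{"recording_id": fv.recording_id, **dict(zip(names, fv.values))}
            for fv in features]
    return pd.DataFrame(rows, columns=["recording_id", *names])
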