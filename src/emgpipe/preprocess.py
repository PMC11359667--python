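"""Band-pass filtering, normalization, rectification, envelope extraction and
segmentation of labeled recordings into fixed-length per-channel windows.

The chain is: zero-phase Butterworth band-pass per channel, per-channel
normalization over the whole recording, raw-window extraction around each
event center, symmetric trim to the kept window, then rectification and a
moving-RMS envelope.  Segments retain the pre-rectification track because the
zero-crossing feature is defined on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError, DegenerateInputError, SegmentationError
from .synth import Recording


@dataclass
class PreprocessConfig:
    band: tuple[float, float] = (20.0, 99.0)
    filter_order: int = 4
    zero_phase: bool = True
    normalization: str = "zscore"  # or "maxabs"
    envelope_window: int = 25
    raw_window: int = 200
    kept_window: int = 150

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0.0 < low < high:
            raise ConfigurationError(f"band must satisfy 0 < low < high, got {self.band}")
        if high >= fs / 2.0:
            raise ConfigurationError(
                f"upper band edge {high} Hz must be strictly below Nyquist {fs / 2.0} Hz "
                f"(at fs={fs} an edge at Nyquist is undesignable)"
            )
        if self.kept_window > self.raw_window:
            raise ConfigurationError("kept_window must be <= raw_window")
        if (self.raw_window - self.kept_window) % 2 != 0:
            raise ConfigurationError("raw_window - kept_window must be even (symmetric trim)")
        if self.envelope_window < 1:
            raise ConfigurationError("envelope_window must be >= 1")
        if self.normalization not in ("zscore", "maxabs"):
            raise ConfigurationError(f"unknown normalization mode {self.normalization!r}")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")


@dataclass
class Segment:
    """One gesture instance: per-channel filtered, rectified and envelope tracks.

    All three tracks are channels x kept_window.  ``filtered`` is the
    pre-rectification signal needed by the zero-crossing feature.
    """

    label: int
    filtered: np.ndarray
    rectified: np.ndarray
    envelope: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.filtered.shape[0]

    @property
    def n_samples(self) -> int:
        return self.filtered.shape[1]


def design_bandpass(fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Second-order-sections coefficients of the configured Butterworth band-pass."""
    cfg.validate(fs)
    return sps.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=fs, output="sos")


def bandpass(signal: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Apply the configured band-pass along the last axis.

    With ``zero_phase`` on, the filter runs forward and backward so the output
    has zero group delay; output length always equals input length.
    """
    signal = np.asarray(signal, dtype=float)
    sos = design_bandpass(fs, cfg)
    if signal.shape[-1] <= 3 * cfg.filter_order:
        raise ConfigurationError(
            f"signal length {signal.shape[-1]} too short for order-{cfg.filter_order} filter"
        )
    if cfg.zero_phase:
        return sps.sosfiltfilt(sos, signal, axis=-1)
    return sps.sosfilt(sos, signal, axis=-1)


def normalize(signal: np.ndarray, mode: str = "zscore") -> np.ndarray:
    """Normalize a 1-D signal: ``zscore`` to mean 0 / sample SD 1 (denominator
    N-1), or ``maxabs`` to peak magnitude 1.

    A constant signal is degenerate under zscore; under maxabs an all-zero
    signal is returned unchanged with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    if mode == "zscore":
        sd = np.std(signal, ddof=1) if signal.size > 1 else 0.0
        if sd == 0:
            raise DegenerateInputError("cannot z-score a constant signal (zero variance)")
        return (signal - np.mean(signal)) / sd
    if mode == "maxabs":
        peak = np.max(np.abs(signal)) if signal.size else 0.0
        if peak == 0:
            warnings.warn("maxabs normalization of an all-zero signal: returned unchanged")
            return signal.copy()
        return signal / peak
    raise ConfigurationError(f"unknown normalization mode {mode!r}")


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    return np.abs(np.asarray(signal, dtype=float))


def envelope(rectified: np.ndarray, window: int) -> np.ndarray:
    """Centered moving RMS of a 1-D rectified signal with truncated edge windows.

    Output length equals input length and every value is >= 0; ``window=1``
    returns the input itself.
    """
    rectified = np.asarray(rectified, dtype=float)
    n = rectified.shape[-1]
    if window < 1:
        raise ConfigurationError("envelope window must be >= 1")
    if window > n:
        raise ConfigurationError(f"envelope window {window} exceeds signal length {n}")
    sq = rectified**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    half = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx - half + window, n)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def write_segments(segments: list[Segment], path) -> None:
    """Segments CSV: one row per (segment, channel, track) with columns
    segment_id,label,channel,track,s1..sN."""
    import pandas as pd

    rows = []
    for sid, seg in enumerate(segments):
        for c in range(seg.n_channels):
            for track, data in (
                ("filtered", seg.filtered[c]),
                ("rectified", seg.rectified[c]),
                ("envelope", seg.envelope[c]),
            ):
                rows.append([sid, seg.label, c + 1, track, *data])
    n = segments[0].n_samples if segments else 0
    cols = ["segment_id", "label", "channel", "track", *(f"s{i + 1}" for i in range(n))]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_segments(path) -> list[Segment]:
    """Read a segments CSV written by :func:`write_segments`."""
    import pandas as pd

    from .exceptions import FormatError

    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"segment_id", "label", "channel", "track"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: line 1: missing columns {sorted(required - set(frame.columns))}")
    sample_cols = [c for c in frame.columns if c.startswith("s") and c[1:].isdigit()]
    segments = []
    for sid, group in frame.groupby("segment_id", sort=True):
        tracks = {}
        for track_name, sub in group.groupby("track"):
            sub = sub.sort_values("channel")
            tracks[track_name] = sub[sample_cols].to_numpy(dtype=float)
        for name in ("filtered", "rectified", "envelope"):
            if name not in tracks:
                raise FormatError(f"{path}: segment {sid}: missing track {name!r}")
        segments.append(
            Segment(
                label=int(group["label"].iloc[0]),
                filtered=tracks["filtered"],
                rectified=tracks["rectified"],
                envelope=tracks["envelope"],
            )
        )
    return segments


def segment_recording(rec: Recording, cfg: PreprocessConfig) -> list[Segment]:
    """Cut a recording into one labeled :class:`Segment` per event.

    Channels are band-passed and normalized over the whole recording (so
    relative burst amplitude across segments is preserved), then a raw window
    is extracted around each event center and trimmed symmetrically to the
    kept window before the rectified and envelope tracks are computed.
    """
    cfg.validate(rec.fs)
    filtered_full = bandpass(rec.signal, rec.fs, cfg)
    filtered_full = np.stack([normalize(ch, cfg.normalization) for ch in filtered_full])

    half = cfg.raw_window // 2
    trim = (cfg.raw_window - cfg.kept_window) // 2
    n = rec.n_samples
    segments: list[Segment] = []
    for i, (cid, center) in enumerate(rec.events):
        start = center - half
        end = start + cfg.raw_window
        if start < 0 or end > n:
            raise SegmentationError(
                f"event {i} (class {cid}, center {center}) needs samples [{start}, {end}) "
                f"but the recording has {n}"
            )
        filt = filtered_full[:, start + trim : end - trim]
        rect = rectify(filt)
        env = np.stack([envelope(ch, cfg.envelope_window) for ch in rect])
        segments.append(Segment(label=cid, filtered=filt.copy(), rectified=rect, envelope=env))
    return segments
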