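"""Ten time-domain feature operators and assembly of the per-segment
feature matrix (10 features x n_channels columns, fixed order).

Conventions: the zero-crossing count is computed on the pre-rectification
filtered track; every magnitude feature (min, max, sd, rms, aac, afb, mav,
len, wamp) on the rectified track.  Column ``j*10 + k`` holds feature ``k``
of channel ``j``; the order is the one in :data:`FEATURE_ORDER`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ShapeError
from .preprocess import Segment

#: Fixed feature order within each channel block.
FEATURE_ORDER: tuple[str, ...] = (
    "min",
    "max",
    "sd",
    "zc",
    "rms",
    "aac",
    "afb",
    "mav",
    "len",
    "wamp",
)

#: Features evaluated on the pre-rectification track rather than the rectified one.
PRERECT_FEATURES: frozenset[str] = frozenset({"zc"})


@dataclass
class FeatureConfig:
    """Thresholds and window of the threshold-based features.

    ``wamp_threshold`` and ``afb_threshold`` are in the (normalized) amplitude
    units of the segment tracks; ``afb_window`` is the number of samples
    searched for the peak after the first threshold crossing.
    """

    wamp_threshold: float = 0.05
    afb_threshold: float = 0.05
    afb_window: int = 40
    feature_order: tuple[str, ...] = field(default=FEATURE_ORDER)

    def validate(self) -> None:
        if self.wamp_threshold <= 0 or self.afb_threshold <= 0:
            raise ConfigurationError("thresholds must be > 0")
        if self.afb_window < 1:
            raise ConfigurationError("afb_window must be >= 1")
        if tuple(self.feature_order) != FEATURE_ORDER:
            raise ConfigurationError(f"feature order is fixed to {FEATURE_ORDER}")


def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ShapeError("feature operators take a non-empty 1-D window")
    return x


def f_min(x) -> float:
    """Smallest value in the window."""
    return float(np.min(_as_window(x)))


def f_max(x) -> float:
    """Largest value in the window."""
    return float(np.max(_as_window(x)))


def f_sd(x) -> float:
    """Sample standard deviation (denominator N-1)."""
    x = _as_window(x)
    if x.size < 2:
        raise ShapeError("sd needs at least 2 samples")
    return float(np.std(x, ddof=1))


def f_zc(x_prerect) -> int:
    """Zero crossings: count of i with x(t_i) * x(t_{i+1}) < 0.

    Strict product rule — samples exactly at zero contribute nothing.  Must be
    fed the pre-rectification track.
    """
    x = _as_window(x_prerect)
    return int(np.count_nonzero(x[:-1] * x[1:] < 0))


def f_rms(x) -> float:
    """Root mean square of the window."""
    x = _as_window(x)
    return float(np.sqrt(np.mean(x**2)))


def f_aac(x) -> float:
    """Average amplitude change: mean absolute first difference."""
    x = _as_window(x)
    if x.size < 2:
        raise ShapeError("aac needs at least 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


def f_afb(x, cfg: FeatureConfig | None = None) -> float:
    """Amplitude of first burst: peak within ``afb_window`` samples after the
    signal first reaches ``afb_threshold``; 0 if it never does."""
    cfg = cfg or FeatureConfig()
    x = _as_window(x)
    above = np.nonzero(x >= cfg.afb_threshold)[0]
    if above.size == 0:
        return 0.0
    tc = int(above[0])
    return float(np.max(x[tc : tc + cfg.afb_window]))


def f_mav(x) -> float:
    """Mean absolute value of the window."""
    x = _as_window(x)
    return float(np.mean(np.abs(x)))


def f_len(x) -> float:
    """Waveform length: cumulative sum of absolute first differences."""
    x = _as_window(x)
    if x.size < 2:
        raise ShapeError("len needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def f_wamp(x, cfg: FeatureConfig | None = None) -> int:
    """Willison amplitude: count of consecutive-sample differences whose
    magnitude reaches ``wamp_threshold``."""
    cfg = cfg or FeatureConfig()
    x = _as_window(x)
    return int(np.count_nonzero(np.abs(np.diff(x)) >= cfg.wamp_threshold))


def _evaluate(name: str, track_rect: np.ndarray, track_filt: np.ndarray, cfg: FeatureConfig) -> float:
    x = track_filt if name in PRERECT_FEATURES else track_rect
    if name == "min":
        return f_min(x)
    if name == "max":
        return f_max(x)
    if name == "sd":
        return f_sd(x)
    if name == "zc":
        return float(f_zc(x))
    if name == "rms":
        return f_rms(x)
    if name == "aac":
        return f_aac(x)
    if name == "afb":
        return f_afb(x, cfg)
    if name == "mav":
        return f_mav(x)
    if name == "len":
        return f_len(x)
    if name == "wamp":
        return float(f_wamp(x, cfg))
    raise ConfigurationError(f"unknown feature {name!r}")


@dataclass
class FeatureMatrix:
    """Rows = segments, columns = (channel, feature) in fixed order."""

    values: np.ndarray
    labels: np.ndarray
    columns: list[str]

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.columns)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "segment_id", np.arange(self.n_segments))
        return frame

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path, float_precision="round_trip")
        labels = frame["label"].to_numpy(dtype=int)
        cols = [c for c in frame.columns if c not in ("segment_id", "label")]
        return cls(values=frame[cols].to_numpy(dtype=float), labels=labels, columns=cols)


def column_names(n_channels: int) -> list[str]:
    return [f"ch{c + 1}_{name}" for c in range(n_channels) for name in FEATURE_ORDER]


def extract_features(segments: list[Segment], cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Assemble the segments x (10 * n_channels) feature matrix with labels."""
    cfg = cfg or FeatureConfig()
    cfg.validate()
    if not segments:
        return FeatureMatrix(values=np.empty((0, 0)), labels=np.empty(0, dtype=int), columns=[])
    n_channels = segments[0].n_channels
    values = np.empty((len(segments), n_channels * len(FEATURE_ORDER)))
    labels = np.empty(len(segments), dtype=int)
    for i, seg in enumerate(segments):
        if seg.n_channels != n_channels:
            raise ShapeError(
                f"segment {i} has {seg.n_channels} channels, expected {n_channels}"
            )
        labels[i] = seg.label
        col = 0
        for c in range(n_channels):
            rect = seg.rectified[c]
            filt = seg.filtered[c]
            for name in FEATURE_ORDER:
                values[i, col] = _evaluate(name, rect, filt, cfg)
                col += 1
    return FeatureMatrix(values=values, labels=labels, columns=column_names(n_channels))
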