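"""Seeded synthetic eight-channel sEMG recordings with labeled gesture bursts.

The generator produces a continuous multi-channel signal in which each gesture
event is a band-limited noise burst, amplitude-modulated by a raised-cosine
window and scaled per channel by a class-specific activation profile.  Events
sit on a regular grid of raw windows separated by seeded jitter gaps that
contain baseline noise only.  The same configuration and seed always yield a
bit-identical recording.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigurationError, EmptyRecordingError, FormatError

#: Per-class segment counts of the seven-gesture dataset composition
#: (classes 1..7: index, middle, ring, little, thumb, victory, relaxed).
GESTURE_COUNTS: dict[int, int] = {
    1: 1039,
    2: 1017,
    3: 1045,
    4: 1084,
    5: 1016,
    6: 726,
    7: 895,
}


def default_activation_profile(
    n_classes: int = 7,
    n_channels: int = 8,
    gain: float = 1.5,
    spread: float = 1.0,
) -> np.ndarray:
    """Class-by-channel burst gain matrix with class-specific dominant channels.

    Each class activates one dominant electrode with smooth Gaussian leakage to
    its ring neighbours, mimicking electrode-position specificity of a
    circumferential armband.
    """
    profile = np.zeros((n_classes, n_channels))
    chan = np.arange(n_channels)
    for k in range(n_classes):
        d = np.abs(chan - k)
        d = np.minimum(d, n_channels - d)  # electrodes form a ring
        profile[k] = gain * np.exp(-(d**2) / (2.0 * spread**2))
    return profile


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording generator."""

    n_channels: int = 8
    fs: float = 200.0
    segment_raw_len: int = 200
    class_counts: dict[int, int] = field(default_factory=lambda: dict(GESTURE_COUNTS))
    activation_profile: np.ndarray | None = None
    burst_duration: float = 1.0
    baseline_sd: float = 0.5
    burst_band: tuple[float, float] = (20.0, 95.0)
    gap_jitter: tuple[int, int] = (10, 50)
    amplitude_jitter: float = 0.0  # sigma of a per-event lognormal strength multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation_profile is None:
            self.activation_profile = default_activation_profile(
                n_classes=len(self.class_counts), n_channels=self.n_channels
            )
        self.activation_profile = np.asarray(self.activation_profile, dtype=float)

    def validate(self) -> None:
        low, high = self.burst_band
        if not (0.0 < low < high):
            raise ConfigurationError(f"burst_band must satisfy 0 < low < high, got {self.burst_band}")
        if high >= self.fs / 2.0:
            raise ConfigurationError(
                f"upper burst_band edge {high} Hz must be below Nyquist {self.fs / 2.0} Hz"
            )
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigurationError("class counts must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise EmptyRecordingError("all class counts are zero: nothing to generate")
        prof = self.activation_profile
        if prof.shape != (len(self.class_counts), self.n_channels):
            raise ConfigurationError(
                f"activation_profile shape {prof.shape} != "
                f"({len(self.class_counts)} classes, {self.n_channels} channels)"
            )
        if not np.all(np.isfinite(prof)) or np.any(prof < 0):
            raise ConfigurationError("activation_profile entries must be finite and >= 0")
        if self.segment_raw_len < 2:
            raise ConfigurationError("segment_raw_len must be >= 2")
        if self.baseline_sd < 0:
            raise ConfigurationError("baseline_sd must be >= 0")
        lo, hi = self.gap_jitter
        if not (0 <= lo <= hi):
            raise ConfigurationError("gap_jitter must satisfy 0 <= lo <= hi")
        if self.amplitude_jitter < 0:
            raise ConfigurationError("amplitude_jitter must be >= 0")


@dataclass
class Recording:
    """A multi-channel signal with a sampling rate and labeled gesture events.

    ``signal`` is channels x samples; ``events`` is an ordered list of
    ``(class_id, center_index)`` pairs, one per gesture instance.
    """

    signal: np.ndarray
    fs: float
    events: list[tuple[int, int]]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for cid, _ in self.events:
            counts[cid] = counts.get(cid, 0) + 1
        return counts


def generate_recording(cfg: SynthConfig) -> Recording:
    """Generate a seeded synthetic recording per ``cfg``.

    Each event window holds baseline Gaussian noise plus a burst: band-limited
    Gaussian carrier noise (independent per channel, normalized to unit RMS)
    modulated by a Hann window of ``burst_duration`` seconds centered on the
    event, scaled by ``activation_profile[class, channel]``.  The event order
    is a seeded random permutation of the class multiset.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    class_ids = sorted(cfg.class_counts)
    class_seq = np.repeat(class_ids, [cfg.class_counts[c] for c in class_ids])
    rng.shuffle(class_seq)
    n_events = class_seq.size

    lo, hi = cfg.gap_jitter
    gaps = rng.integers(lo, hi + 1, size=n_events + 1)

    raw = cfg.segment_raw_len
    starts = np.empty(n_events, dtype=np.int64)
    pos = int(gaps[0]) + raw  # leading margin so the first raw window fits
    for i in range(n_events):
        starts[i] = pos
        pos += raw + int(gaps[i + 1])
    total = pos + raw  # trailing margin
    centers = starts + raw // 2

    signal = cfg.baseline_sd * rng.standard_normal((cfg.n_channels, total))

    burst_len = int(round(cfg.burst_duration * cfg.fs))
    burst_len = max(burst_len, 2)
    window = sps.windows.hann(burst_len, sym=True)
    sos = sps.butter(4, cfg.burst_band, btype="bandpass", fs=cfg.fs, output="sos")

    class_row = {c: k for k, c in enumerate(class_ids)}
    for i in range(n_events):
        gains = cfg.activation_profile[class_row[class_seq[i]]]
        # per-event contraction-strength variability, class-independent
        strength = rng.lognormal(0.0, cfg.amplitude_jitter) if cfg.amplitude_jitter > 0 else 1.0
        gains = gains * strength
        carrier = rng.standard_normal((cfg.n_channels, burst_len))
        if np.all(gains == 0):
            continue  # draw kept above so the stream is class-independent
        carrier = sps.sosfiltfilt(sos, carrier, axis=1)
        rms = np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
        rms[rms == 0] = 1.0
        carrier /= rms
        b0 = int(centers[i]) - burst_len // 2
        b1 = b0 + burst_len
        s0, s1 = max(b0, 0), min(b1, total)
        signal[:, s0:s1] += gains[:, None] * window[s0 - b0 : s1 - b0] * carrier[:, s0 - b0 : s1 - b0]

    events = [(int(class_seq[i]), int(centers[i])) for i in range(n_events)]
    return Recording(signal=signal, fs=float(cfg.fs), events=events)


# ---------------------------------------------------------------------------
# On-disk format: signal CSV (header ch1..chN), events sidecar CSV
# (header class_id,center_index) and a small JSON sidecar carrying fs.
# ---------------------------------------------------------------------------


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    events = path.with_suffix(".events.csv")
    meta = path.with_suffix(".meta.json")
    return events, meta


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as a signal CSV plus events/meta sidecars; returns the signal path."""
    path = Path(path)
    events_path, meta_path = _sidecar_paths(path)
    header = ",".join(f"ch{i + 1}" for i in range(rec.n_channels))
    np.savetxt(path, rec.signal.T, fmt="%.17g", delimiter=",", header=header, comments="")
    with open(events_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_id", "center_index"])
        writer.writerows(rec.events)
    with open(meta_path, "w") as fh:
        json.dump({"fs": rec.fs, "n_channels": rec.n_channels, "n_samples": rec.n_samples}, fh)
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`; validates bounds."""
    path = Path(path)
    events_path, meta_path = _sidecar_paths(path)
    for p in (path, events_path, meta_path):
        if not p.exists():
            raise FormatError(f"missing recording artifact: {p}")

    with open(meta_path) as fh:
        meta = json.load(fh)
    fs = float(meta["fs"])

    frame = pd.read_csv(path, float_precision="round_trip")
    expected = [f"ch{i + 1}" for i in range(frame.shape[1])]
    if list(frame.columns) != expected:
        raise FormatError(f"{path}: line 1: header must be {','.join(expected)}, got {','.join(frame.columns)}")
    if int(meta.get("n_channels", frame.shape[1])) != frame.shape[1]:
        raise FormatError(
            f"{path}: line 1: {frame.shape[1]} channel columns but metadata declares {meta['n_channels']}"
        )
    signal = frame.to_numpy(dtype=float).T
    n_samples = signal.shape[1]

    events: list[tuple[int, int]] = []
    with open(events_path, newline="") as fh:
        reader = csv.reader(fh)
        head = next(reader, None)
        if head != ["class_id", "center_index"]:
            raise FormatError(f"{events_path}: line 1: expected header class_id,center_index")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                cid, center = int(row[0]), int(row[1])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{events_path}: line {lineno}: malformed event row {row!r}") from exc
            if not 0 <= center < n_samples:
                raise FormatError(
                    f"{events_path}: line {lineno}: center_index {center} outside recording "
                    f"of {n_samples} samples"
                )
            events.append((cid, center))
    return Recording(signal=signal, fs=fs, events=events)
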