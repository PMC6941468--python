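"""Signal conditioning for ictal scalp EEG.

The pipeline expects seizure epochs recorded at 256, 512 or 1024 Hz. Before
any source analysis the data are (i) down-sampled to 256 Hz, (ii) band-pass
filtered 1-25 Hz with a zero-phase fourth-order Butterworth filter, and
(iii) cut into consecutive non-overlapping 16-s segments of exactly 4096
samples. Seizures shorter than 16 s are rejected, mirroring the study's
inclusion criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

TARGET_FS = 256.0
SEGMENT_SAMPLES = 4096  # 16 s at 256 Hz
BAND = (1.0, 25.0)
FILTER_ORDER = 4


@dataclass
class EEGRecording:
    """A channels x samples scalp EEG matrix (microvolts) with its metadata.

    ``t0`` is the epoch start offset in seconds relative to the source
    recording, carried through resampling unchanged.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One 16-s analysis window: channels x 4096 samples at 256 Hz."""

    data: np.ndarray
    index: int
    fs: float = TARGET_FS
    channel_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[1] != SEGMENT_SAMPLES:
            raise ValueError(
                f"segment must have exactly {SEGMENT_SAMPLES} samples, "
                f"got {self.data.shape[1]}"
            )
        if self.fs != TARGET_FS:
            raise ValueError(f"segment sampling rate must be {TARGET_FS} Hz")


def resample_to_256(rec: EEGRecording) -> EEGRecording:
    """Down-sample a recording to 256 Hz with polyphase anti-alias filtering.

    Recordings already at 256 Hz are returned unchanged. 512 and 1024 Hz
    decimate by an integer factor; any other rate above 256 Hz is resampled
    by the nearest rational factor with a warning. Upsampling is refused.
    """
    if rec.fs == TARGET_FS:
        return rec
    if rec.fs < TARGET_FS:
        raise ValueError("upsampling not supported: recording below 256 Hz")
    if rec.fs in (512.0, 1024.0):
        down = int(rec.fs // TARGET_FS)
        up = 1
    else:
        frac = Fraction(TARGET_FS / rec.fs).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
        warnings.warn(
            f"non-standard rate {rec.fs} Hz: polyphase resampling by {up}/{down}",
            stacklevel=2,
        )
    out = signal.resample_poly(rec.data, up, down, axis=1)
    return replace(rec, data=out, fs=TARGET_FS)


def _bandpass_sos(fs: float) -> np.ndarray:
    return signal.butter(
        FILTER_ORDER, BAND, btype="bandpass", fs=fs, output="sos"
    )


def bandpass_1_25(rec: EEGRecording) -> EEGRecording:
    """Zero-phase 1-25 Hz band-pass (4th-order Butterworth, forward-backward).

    Forward-backward application squares the magnitude response (effective
    8th-order roll-off) and cancels the phase response exactly, which matters
    downstream because connectivity is computed from instantaneous phases.
    """
    if rec.fs != TARGET_FS:
        raise ValueError("bandpass expects a 256 Hz recording; resample first")
    sos = _bandpass_sos(rec.fs)
    # reflect padding of 3x the filter's state length, standard practice
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise ValueError("too short to filter")
    out = signal.sosfiltfilt(sos, rec.data, axis=1, padlen=padlen)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values after filtering")
    return replace(rec, data=out)


def segment_16s(rec: EEGRecording) -> list[Segment]:
    """Split a 256 Hz recording into consecutive non-overlapping 16-s segments.

    The trailing remainder shorter than 4096 samples is discarded. A
    recording shorter than one segment is rejected ("seizure too short"),
    mirroring the >=16 s seizure inclusion criterion.
    """
    if rec.fs != TARGET_FS:
        raise ValueError("segmentation expects a 256 Hz recording")
    n_seg = rec.n_samples // SEGMENT_SAMPLES
    if n_seg < 1:
        raise ValueError("seizure too short: need at least 16 s (4096 samples)")
    return [
        Segment(
            data=rec.data[:, i * SEGMENT_SAMPLES : (i + 1) * SEGMENT_SAMPLES],
            index=i,
            channel_labels=rec.channel_labels,
        )
        for i in range(n_seg)
    ]


def preprocess(rec: EEGRecording) -> list[Segment]:
    """Full conditioning chain: resample -> band-pass -> segment."""
    return segment_16s(bandpass_1_25(resample_to_256(rec)))
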