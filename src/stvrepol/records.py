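"""Core data containers: sampled waveforms and per-beat ground truth.

Conventions used throughout the package: all times are milliseconds from the
start of the record, sample indices are 0-based, and windows are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, ParameterError

__all__ = ["SignalRecord", "GroundTruth", "BEAT_LABELS"]

#: Valid per-beat labels.
BEAT_LABELS = ("normal", "ectopic", "paced")


@dataclass
class SignalRecord:
    """A multichannel sampled waveform.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array of amplitudes in mV.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel (e.g. ``"V2"`` for a precordial ECG lead or
        ``"I2"`` for an electrogram pole counted from the catheter tip).
    units
        Amplitude units; the package works in mV internally.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ParameterError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain non-finite values")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def dt_ms(self) -> float:
        """Sample period in ms."""
        return 1000.0 / self.fs

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def time_ms(self) -> np.ndarray:
        """Sample times in ms from record start."""
        return np.arange(self.n_samples) * self.dt_ms

    # -- channel access -------------------------------------------------
    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array (a view, not a copy)."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.samples[idx]

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample at or immediately before ``t_ms``."""
        return int(np.floor(t_ms / self.dt_ms))


@dataclass
class GroundTruth:
    """Per-beat truth exported by the synthetic generator.

    Every array has one entry per beat; ``rr_prev`` is NaN for the first
    beat.  ``true_repol_interval`` is the programmed repolarization
    determinant: the QT interval (``t_end - qrs_onset``) for ECG-style
    records, and the same landmark distance for EGM-style ones.
    """

    sense_time: np.ndarray
    label: list[str]
    qrs_onset: np.ndarray
    r_peak: np.ndarray
    t_end: np.ndarray
    true_repol_interval: np.ndarray
    rr_prev: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sense_time = np.asarray(self.sense_time, dtype=float)
        self.qrs_onset = np.asarray(self.qrs_onset, dtype=float)
        self.r_peak = np.asarray(self.r_peak, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        self.true_repol_interval = np.asarray(self.true_repol_interval, dtype=float)
        if self.rr_prev is None:
            self.rr_prev = np.concatenate([[np.nan], np.diff(self.sense_time)])
        self.rr_prev = np.asarray(self.rr_prev, dtype=float)
        n = len(self.sense_time)
        for name in ("qrs_onset", "r_peak", "t_end", "true_repol_interval", "rr_prev"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"{name} length mismatch ({n} beats)")
        if len(self.label) != n:
            raise ParameterError("label length mismatch")
        for lab in self.label:
            if lab not in BEAT_LABELS:
                raise ParameterError(f"unknown beat label {lab!r}")
        if n > 1 and not np.all(np.diff(self.sense_time) > 0):
            raise ParameterError("sense times must be strictly increasing")
        bad = ~((self.qrs_onset < self.r_peak) & (self.r_peak < self.t_end))
        if np.any(bad):
            raise ParameterError(
                f"landmark ordering violated at beats {np.flatnonzero(bad).tolist()}"
            )

    @property
    def n_beats(self) -> int:
        return len(self.sense_time)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per beat, times in ms."""
        return pd.DataFrame(
            {
                "beat_index": np.arange(self.n_beats),
                "sense_time_ms": self.sense_time,
                "label": self.label,
                "qrs_onset_ms": self.qrs_onset,
                "r_peak_ms": self.r_peak,
                "t_end_ms": self.t_end,
                "true_repol_interval_ms": self.true_repol_interval,
                "rr_prev_ms": self.rr_prev,
            }
        )
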