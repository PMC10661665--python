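"""Device-style ventricular sensing: beat detection and RR intervals.

Sensing emulates what an implanted device provides — a reference time per
ventricular depolarization.  It is an *input* to the repolarization
analysis, not its contribution, so the detector is deliberately simple: a
robust amplitude threshold with a refractory period, with an
annotation-driven bypass for externally supplied beat times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .records import SignalRecord

__all__ = ["SenseSeries", "detect_senses", "rr_intervals",
           "senses_from_annotations", "detect_pace_spikes"]

#: window after a threshold crossing in which the sense time is refined to
#: the local rectified maximum (ms)
REFINE_WINDOW_MS = 50.0


@dataclass
class SenseSeries:
    """Detected (or supplied) beat times in ms, sorted ascending."""

    times: np.ndarray
    channel: str = ""
    refractory_ms: float = 250.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1:
            d = np.diff(self.times)
            if np.any(d <= 0):
                raise ParameterError("sense times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def detect_senses(
    record: SignalRecord,
    channel: str,
    threshold_frac: float = 0.5,
    refractory_ms: float = 250.0,
    mode: str = "slope",
    mask_pace_spikes: bool = True,
) -> SenseSeries:
    """Detect beats on one channel by threshold crossing of a rectified
    detection signal.

    In the default ``slope`` mode the detection signal is the rectified
    first derivative of a lightly smoothed (5 ms moving average) waveform —
    ventricular depolarization is an order of magnitude steeper than the
    T-wave, which an amplitude threshold alone cannot reject.  In
    ``amplitude`` mode the detection signal is the rectified waveform
    itself.  The threshold is ``threshold_frac`` times a robust high
    percentile of the detection signal (99th for slope, 95th for
    amplitude), so a single artefact spike cannot silence real beats.  A
    sense is emitted at each upward crossing, suppressed within
    ``refractory_ms`` of the previous sense, and refined to the local
    rectified-waveform maximum within 50 ms after the crossing — the R
    peak.  With ``mask_pace_spikes`` (default) samples inside detected
    stimulus artefacts are excluded from the refinement, so a pace spike
    and its QRS merge into a single sensed event *timed on the R peak*,
    which keeps RR and ST-segment measurements meaningful on paced rhythms.

    A flat or empty channel yields an empty series, not an exception.
    """
    if not (0 < threshold_frac < 1):
        raise ParameterError("threshold_frac must be in (0, 1)")
    if refractory_ms <= 0:
        raise ParameterError("refractory_ms must be positive")
    if mode not in ("slope", "amplitude"):
        raise ParameterError("mode must be 'slope' or 'amplitude'")

    raw = record.channel(channel)
    x = np.abs(raw)
    if mode == "slope":
        k = max(1, int(round(5.0 / record.dt_ms)) | 1)  # odd, ~5 ms
        smooth = np.convolve(raw, np.ones(k) / k, mode="same")
        det = np.abs(np.gradient(smooth)) * record.fs / 1000.0  # mV/ms
        level = threshold_frac * np.percentile(det, 99)
    else:
        det = x
        level = threshold_frac * np.percentile(det, 95)
    if level <= 0:
        return SenseSeries(times=np.empty(0), channel=channel,
                           refractory_ms=refractory_ms)

    above = det > level
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])

    dt = record.dt_ms
    refine = x.copy()
    if mask_pace_spikes:
        for spike in detect_pace_spikes(record, channel):
            i0 = max(0, int((spike - 4.0) / dt))
            i1 = min(len(refine), int((spike + 4.0) / dt) + 1)
            refine[i0:i1] = 0.0

    refine_n = int(round(REFINE_WINDOW_MS / dt))
    times = []
    last = -np.inf
    for c in crossings:
        t_c = c * dt
        if t_c - last < refractory_ms:
            continue
        seg = refine[c: c + refine_n + 1]
        peak = c + int(np.argmax(seg))
        times.append(peak * dt)
        last = times[-1]
    return SenseSeries(times=np.asarray(times), channel=channel,
                       refractory_ms=refractory_ms)


def detect_pace_spikes(
    record: SignalRecord,
    channel: str,
    slope_min_mV_per_ms: float = 1.0,
    merge_gap_ms: float = 5.0,
) -> np.ndarray:
    """Times (ms) of pacing-spike-like events: very high slope transients.

    Samples whose absolute first derivative exceeds ``slope_min_mV_per_ms``
    are clustered (gaps above ``merge_gap_ms`` separate events); each event
    is reported at its maximum-slope sample.  Physiological deflections at
    these sampling rates stay well below 1 mV/ms; stimulus artefacts exceed it.
    """
    x = record.channel(channel)
    d = np.abs(np.diff(x)) * record.fs / 1000.0
    hot = np.flatnonzero(d > slope_min_mV_per_ms)
    if len(hot) == 0:
        return np.empty(0)
    dt = record.dt_ms
    gap_n = max(1, int(round(merge_gap_ms / dt)))
    events = []
    start = hot[0]
    prev = hot[0]
    for i in hot[1:]:
        if i - prev > gap_n:
            seg = np.arange(start, prev + 1)
            events.append(seg[np.argmax(d[seg])] * dt)
            start = i
        prev = i
    seg = np.arange(start, prev + 1)
    events.append(seg[np.argmax(d[seg])] * dt)
    return np.asarray(events)


def senses_from_annotations(times_ms, channel: str = "annotation") -> SenseSeries:
    """Annotation-driven mode: wrap externally supplied beat times."""
    return SenseSeries(times=np.sort(np.asarray(times_ms, dtype=float)),
                       channel=channel, refractory_ms=0.0)


def rr_intervals(senses: SenseSeries) -> np.ndarray:
    """Consecutive sense-to-sense intervals in ms (length ``n_senses - 1``)."""
    if len(senses) < 2:
        raise InsufficientDataError(
            f"need >= 2 senses for RR intervals, got {len(senses)}"
        )
    return np.diff(senses.times)
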