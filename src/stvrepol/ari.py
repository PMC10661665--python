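"""Automatic activation-recovery-interval (ARI) measurement on unipolar
electrograms.

Per beat, the method takes a dynamic analysis window anchored on the
ventricular sense and scaled by the beat's RR interval, blanks the QRS (first
200 ms after the sense by default), computes the first time-derivative of the
remaining signal, squares it (making the detection independent of T-wave
polarity and emphasising slope changes), and defines the repolarization
offset as the time at which the running area under the squared derivative
reaches 60 % of its total.  The ARI is that offset minus the sense time.

The 60 % crossing is linearly interpolated between samples by default, which
removes sampling-rate bias; an exact-sample mode (``interpolate=False``)
emulates a device accumulator that reports the first sample whose running
area meets the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .records import SignalRecord
from .sensing import SenseSeries, detect_pace_spikes

__all__ = [
    "AlgoParams",
    "ARISeries",
    "beat_window",
    "measure_ari",
    "measure_ari_series",
    "detect_pace_spikes",
]

#: minimum number of samples for a usable analysis window
_MIN_WINDOW_SAMPLES = 4

#: flag values, in order of precedence (first match wins)
FLAGS = ("window_truncated", "pacing_interference", "noisy", "low_t_amplitude", "ok")


@dataclass
class AlgoParams:
    """Tunable parameters of the automatic ARI pipeline.

    ``blanking_ms``
        Post-sense interval removed before analysis so the QRS cannot
        contaminate T-wave end detection (default 200 ms).
    ``auc_fraction``
        Fraction of the total area under the squared derivative at which the
        repolarization offset is declared (default 0.60).
    ``window_guard_ms``
        Gap kept between the window end and the next expected sense, so the
        following complex stays out of the window at any heart rate.
    ``t_amp_min_mV``
        Minimum peak-to-peak amplitude of the windowed signal for the beat
        (and, channel-wise, the electrogram pole) to be considered
        measurable (default 0.5 mV).
    ``n_beats_stv``
        Number of consecutive beats over which the short-term variability
        statistic is defined (default 31).
    """

    blanking_ms: float = 200.0
    auc_fraction: float = 0.60
    window_guard_ms: float = 50.0
    t_amp_min_mV: float = 0.5
    n_beats_stv: int = 31
    st_ceiling_mV: float = 0.3
    interpolate: bool = True
    cumulative: str = "rect"  # "rect" (device-style running sum) or "trap"
    spike_slope_mV_per_ms: float = 1.0
    spike_halfwidth_ms: float = 5.0  # artefact extent incl. recharge tail

    def __post_init__(self) -> None:
        if not (0 < self.auc_fraction < 1):
            raise ParameterError("auc_fraction must be in (0, 1)")
        if self.blanking_ms <= 0:
            raise ParameterError("blanking_ms must be positive")
        if self.n_beats_stv < 2:
            raise ParameterError("n_beats_stv must be >= 2")
        if self.cumulative not in ("rect", "trap"):
            raise ParameterError("cumulative must be 'rect' or 'trap'")


@dataclass
class ARISeries:
    """Per-beat ARI values with quality flags (NaN where unmeasurable)."""

    sense_times: np.ndarray
    ari_ms: np.ndarray
    flags: list[str]
    channel: str = ""

    def __post_init__(self) -> None:
        self.sense_times = np.asarray(self.sense_times, dtype=float)
        self.ari_ms = np.asarray(self.ari_ms, dtype=float)
        if not (len(self.sense_times) == len(self.ari_ms) == len(self.flags)):
            raise ParameterError("sense_times, ari_ms and flags must align")

    def __len__(self) -> int:
        return len(self.ari_ms)

    def ok_values(self) -> np.ndarray:
        """ARI series with non-``ok`` beats replaced by NaN."""
        out = self.ari_ms.copy()
        out[[f != "ok" for f in self.flags]] = np.nan
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "beat_index": np.arange(len(self)),
                "sense_ms": self.sense_times,
                "ari_ms": self.ari_ms,
                "flag": self.flags,
            }
        )


def beat_window(sense: float, rr: float, params: AlgoParams) -> tuple[float, float]:
    """Dynamic per-beat analysis window ``[sense + blanking, sense + rr - guard)``.

    The window scales with the beat's own RR so the entire T-wave is inside
    while the next complex stays out.  Degenerate windows (short RR) are
    returned as-is; callers flag such beats ``window_truncated``.
    """
    return sense + params.blanking_ms, sense + rr - params.window_guard_ms


def _window_samples(record: SignalRecord, channel: str,
                    window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Samples and their times (ms) inside a half-open window."""
    start, end = window
    dt = record.dt_ms
    i0 = int(np.ceil(start / dt - 1e-9))
    i1 = int(np.ceil(end / dt - 1e-9))  # exclusive
    i0 = max(i0, 0)
    i1 = min(i1, record.n_samples)
    x = record.channel(channel)[i0:i1]
    return x, np.arange(i0, i1) * dt


def measure_ari(
    record: SignalRecord,
    channel: str,
    sense: float,
    window: tuple[float, float],
    params: AlgoParams | None = None,
) -> tuple[float, str]:
    """ARI of one beat: squared-derivative area method inside ``window``.

    Returns ``(ari_ms, flag)``.  ``ari_ms`` is NaN when the window is
    degenerate (``window_truncated``) or carries no derivative energy
    (``noisy``).  A measurable beat whose windowed peak-to-peak amplitude is
    below ``t_amp_min_mV`` keeps its value but is flagged
    ``low_t_amplitude``.
    """
    params = params or AlgoParams()
    x, times = _window_samples(record, channel, window)
    if len(x) < _MIN_WINDOW_SAMPLES:
        return np.nan, "window_truncated"

    g = np.diff(x) * record.fs / 1000.0  # mV/ms
    s = g * g
    if params.cumulative == "trap":
        c = np.concatenate([[0.0], np.cumsum((s[:-1] + s[1:]) / 2.0)])
    else:
        c = np.cumsum(s)
    total = c[-1]
    if total <= 0:
        return np.nan, "noisy"

    target = params.auc_fraction * total
    j = int(np.searchsorted(c, target))
    j = min(j, len(c) - 1)
    dt = record.dt_ms
    if params.cumulative == "trap":
        # c[j] is area up to derivative-sample j (centred times)
        t_lo = times[0] + (j - 0.5) * dt if j > 0 else times[0] + 0.5 * dt
        prev = c[j - 1] if j > 0 else 0.0
        seg = c[j] - prev
        frac = (target - prev) / seg if seg > 0 else 1.0
        t_star = t_lo + frac * dt if params.interpolate else times[0] + (j + 0.5) * dt
    else:
        # c[j] is area accumulated by the right edge of interval j,
        # i.e. at sample time times[j + 1]
        prev = c[j - 1] if j > 0 else 0.0
        seg = c[j] - prev
        if params.interpolate:
            frac = (target - prev) / seg if seg > 0 else 1.0
            t_star = times[j] + frac * dt
        else:
            t_star = times[j + 1]

    flag = "ok"
    if np.ptp(x) < params.t_amp_min_mV:
        flag = "low_t_amplitude"
    return t_star - sense, flag




def measure_ari_series(
    record: SignalRecord,
    channel: str,
    senses: SenseSeries,
    params: AlgoParams | None = None,
    beat_labels: list[str] | None = None,
) -> ARISeries:
    """Per-beat ARI over a sensed record.

    Each beat's window is built from its own RR (the last beat uses the
    record's median RR).  Beats with a detected pacing spike in their
    T-wave segment — anywhere between the end of QRS blanking and the next
    sense, the spike's extent (``spike_halfwidth_ms`` either side of its
    centre) included — are flagged ``pacing_interference`` and left
    unmeasured; when ``beat_labels`` are supplied only beats labelled
    ``paced`` are subject to that rule.
    """
    params = params or AlgoParams()
    if len(senses) < 2:
        raise InsufficientDataError("need >= 2 senses to build RR-scaled windows")
    times = senses.times
    rr = np.diff(times)
    median_rr = float(np.median(rr))
    rr_per_beat = np.concatenate([rr, [median_rr]])

    spikes = detect_pace_spikes(record, channel, params.spike_slope_mV_per_ms)

    ari = np.full(len(times), np.nan)
    flags: list[str] = []
    for k, (sense, rr_k) in enumerate(zip(times, rr_per_beat)):
        if rr_k <= params.blanking_ms + params.window_guard_ms:
            flags.append("window_truncated")
            continue
        window = beat_window(sense, rr_k, params)
        paced = beat_labels is None or (k < len(beat_labels)
                                        and beat_labels[k] == "paced")
        if paced and len(spikes):
            lo = spikes - params.spike_halfwidth_ms
            hi = spikes + params.spike_halfwidth_ms
            # interference region: blanking end up to the next sense
            if np.any((lo < sense + rr_k) & (hi > window[0])):
                flags.append("pacing_interference")
                continue
        value, flag = measure_ari(record, channel, sense, window, params)
        ari[k] = value
        flags.append(flag)
    return ARISeries(sense_times=times, ari_ms=ari, flags=flags, channel=channel)
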