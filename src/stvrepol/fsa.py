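"""Fiducial segment averaging (FSA): per-beat QT from cross-correlation
alignment at three fiducials.

Each beat is aligned against the average of all *other* beats (leave-one-out
template, recomputed every sweep) by maximizing normalized cross-correlation
over integer-sample shifts within a search radius.  The procedure runs three
times — around the R peak, around QRS onset, and around the T-wave end — and
the per-beat QT interval is the distance between the QRS-onset and T-end
fiducials.  Because all beats share any template placement error, a biased
template shifts every QT by the same constant, which cancels in beat-to-beat
variability.

Instead of a visual check of alignment quality, beats whose final
correlation with the leave-one-out template falls below 0.8 are flagged
``noisy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .records import SignalRecord
from .sensing import SenseSeries

__all__ = ["FSAConfig", "QTSeries", "align_fiducial", "measure_qt_fsa",
           "estimate_template_landmarks"]

#: final leave-one-out correlation below which a beat is flagged ``noisy``
MIN_ALIGNMENT_CORR = 0.8


@dataclass
class FSAConfig:
    """Alignment windows (half-widths, ms) and search parameters."""

    r_window_ms: float = 60.0
    q_window_ms: float = 40.0
    t_window_ms: float = 80.0
    search_radius_ms: float = 20.0
    max_iters: int = 10

    def __post_init__(self) -> None:
        for name in ("r_window_ms", "q_window_ms", "t_window_ms"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.search_radius_ms <= 0:
            raise ParameterError("search_radius_ms must be positive")
        if self.max_iters < 1:
            raise ParameterError("max_iters must be >= 1")


@dataclass
class QTSeries:
    """Per-beat QT intervals with the fiducial shifts that produced them."""

    qt_ms: np.ndarray
    rr_prev_ms: np.ndarray
    shifts: np.ndarray  # (n_beats, 3): r, q_onset, t_end shifts in ms
    flags: list[str]
    r_times: np.ndarray

    def __post_init__(self) -> None:
        self.qt_ms = np.asarray(self.qt_ms, dtype=float)
        self.rr_prev_ms = np.asarray(self.rr_prev_ms, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.r_times = np.asarray(self.r_times, dtype=float)

    def __len__(self) -> int:
        return len(self.qt_ms)

    def ok_values(self) -> np.ndarray:
        out = self.qt_ms.copy()
        out[[f != "ok" for f in self.flags]] = np.nan
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "beat_index": np.arange(len(self)),
                "r_time_ms": self.r_times,
                "qt_ms": self.qt_ms,
                "rr_prev_ms": self.rr_prev_ms,
                "shift_r_ms": self.shifts[:, 0],
                "shift_q_ms": self.shifts[:, 1],
                "shift_t_ms": self.shifts[:, 2],
                "flag": self.flags,
            }
        )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean, unit-norm correlation; 0 for a constant input."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _best_shift(scores: np.ndarray, radius: int) -> int:
    """Index of the best candidate shift in ``[-radius, radius]``.

    Ties break toward the smallest absolute shift, then toward the negative
    one.
    """
    cands = np.arange(-radius, radius + 1)
    best = np.max(scores)
    tied = cands[scores >= best - 1e-12]
    tied = tied[np.lexsort((tied, np.abs(tied)))]
    return int(tied[0])


def align_fiducial(beat_segments, config: FSAConfig, fs: float = 1000.0
                   ) -> np.ndarray:
    """Leave-one-out circular alignment of equal-length segments.

    Returns per-beat corrective shifts in ms: a segment whose content is
    delayed by ``d`` ms relative to the others receives a shift of ``-d``.
    Iterates until no shift changes or ``config.max_iters`` sweeps.
    """
    segs = [np.asarray(s, dtype=float) for s in beat_segments]
    if len(segs) < 3:
        raise InsufficientDataError("alignment needs >= 3 segments")
    length = len(segs[0])
    if any(len(s) != length for s in segs):
        raise ParameterError("segments must all have the same length")

    dt = 1000.0 / fs
    radius = max(1, int(round(config.search_radius_ms / dt)))
    shifts = np.zeros(len(segs), dtype=int)
    cands = np.arange(-radius, radius + 1)

    for _ in range(config.max_iters):
        changed = False
        for k, seg in enumerate(segs):
            aligned_others = [np.roll(segs[j], shifts[j])
                             for j in range(len(segs)) if j != k]
            template = np.mean(aligned_others, axis=0)
            scores = np.array([_ncc(np.roll(seg, c), template) for c in cands])
            new = _best_shift(scores, radius)
            if new != shifts[k]:
                shifts[k] = new
                changed = True
        if not changed:
            break
    return shifts * dt


def _align_windows(x: np.ndarray, dt: float, centers_ms: np.ndarray,
                   half_ms: float, config: FSAConfig, valid: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Align record windows around ``centers_ms`` by sliding extraction.

    Returns ``(shifts_ms, final_corr)`` where the per-beat fiducial is
    ``center + shift``.  Beats with ``valid`` False are ignored (shift 0,
    corr NaN).
    """
    half = max(1, int(round(half_ms / dt)))
    radius = max(1, int(round(config.search_radius_ms / dt)))
    win_len = 2 * half + 1
    centers = np.round(centers_ms / dt).astype(int)

    idx = np.flatnonzero(valid)
    if len(idx) < 3:
        raise InsufficientDataError("alignment needs >= 3 analysable beats")

    # candidate windows per beat: rows = shift -radius..radius
    views = {}
    for k in idx:
        base = centers[k] - half - radius
        seg = x[base: base + win_len + 2 * radius]
        views[k] = np.lib.stride_tricks.sliding_window_view(seg, win_len)

    shifts = np.zeros(len(centers), dtype=int)
    corr = np.full(len(centers), np.nan)
    for _ in range(config.max_iters):
        changed = False
        for k in idx:
            others = np.array([views[j][shifts[j] + radius] for j in idx if j != k])
            template = others.mean(axis=0)
            template = template - template.mean()
            tn = np.linalg.norm(template)
            w = views[k] - views[k].mean(axis=1, keepdims=True)
            wn = np.linalg.norm(w, axis=1)
            denom = wn * tn
            with np.errstate(invalid="ignore", divide="ignore"):
                scores = np.where(denom > 0, w @ template / denom, 0.0)
            new = _best_shift(scores, radius)
            corr[k] = scores[new + radius]
            if new != shifts[k]:
                shifts[k] = new
                changed = True
        if not changed:
            break
    return shifts * dt, corr


def estimate_template_landmarks(record: SignalRecord, channel: str,
                                senses: SenseSeries,
                                blanking_ms: float = 150.0
                                ) -> tuple[float, float]:
    """Rough ``(q_onset, t_end)`` template offsets (ms, relative to the
    sense) from the average beat.

    QRS onset: last pre-sense point where the rectified average stays below
    5 % of the R amplitude.  T end: last point after ``blanking_ms`` where
    the rectified average exceeds 5 % of the T peak.  Only used to seed the
    alignment windows; any common-mode error cancels in beat-to-beat
    variability.
    """
    x = record.channel(channel)
    dt = record.dt_ms
    rr_med = float(np.median(np.diff(senses.times)))
    pre = int(round(100.0 / dt))
    post = int(round((rr_med - 60.0) / dt))
    beats = []
    for s in senses.times:
        i = int(round(s / dt))
        if i - pre >= 0 and i + post < record.n_samples:
            beats.append(x[i - pre: i + post])
    if len(beats) < 3:
        raise InsufficientDataError("too few complete beats for a template")
    avg = np.abs(np.mean(beats, axis=0))

    r_amp = avg[pre]
    below = np.flatnonzero(avg[:pre] < 0.05 * r_amp)
    q_idx = below[-1] if len(below) else 0
    q_onset = (q_idx - pre) * dt

    t_region = avg[pre + int(round(blanking_ms / dt)):]
    t_peak = np.max(t_region)
    above = np.flatnonzero(t_region >= 0.05 * t_peak)
    t_end = (above[-1] + int(round(blanking_ms / dt))) * dt
    return float(q_onset), float(t_end)


def measure_qt_fsa(
    record: SignalRecord,
    channel: str,
    senses: SenseSeries,
    config: FSAConfig | None = None,
    initial_landmarks: tuple[float, float] | None = None,
) -> QTSeries:
    """Per-beat QT intervals by three-stage fiducial segment averaging.

    ``initial_landmarks`` are template ``(q_onset, t_end)`` offsets in ms
    relative to the R peak (negative q_onset); if omitted they are estimated
    from the average beat.  Stage 1 aligns around each sense to fix R times;
    stages 2 and 3 align around ``R + q_onset`` and ``R + t_end``;
    ``qt = t_end_fiducial - q_onset_fiducial``.

    Beats whose alignment windows (including the search radius) would leave
    the record are flagged ``window_truncated``; beats with a final
    correlation below 0.8 at any stage are flagged ``noisy``.
    """
    config = config or FSAConfig()
    if len(senses) < 3:
        raise InsufficientDataError("FSA needs >= 3 beats")
    x = record.channel(channel)
    dt = record.dt_ms
    n = len(senses)

    if initial_landmarks is None:
        initial_landmarks = estimate_template_landmarks(record, channel, senses)
    q_off, t_off = initial_landmarks

    def in_bounds(centers: np.ndarray, half_ms: float) -> np.ndarray:
        margin = half_ms + config.search_radius_ms + 2 * dt
        return (centers - margin >= 0) & (centers + margin <= record.duration_ms - dt)

    valid = in_bounds(senses.times, config.r_window_ms)
    valid &= in_bounds(senses.times + q_off, config.q_window_ms)
    valid &= in_bounds(senses.times + t_off, config.t_window_ms)

    s_r, c_r = _align_windows(x, dt, senses.times, config.r_window_ms, config, valid)
    r_times = senses.times + s_r

    s_q, c_q = _align_windows(x, dt, r_times + q_off, config.q_window_ms, config, valid)
    q_times = r_times + q_off + s_q

    s_t, c_t = _align_windows(x, dt, r_times + t_off, config.t_window_ms, config, valid)
    t_times = r_times + t_off + s_t

    qt = np.where(valid, t_times - q_times, np.nan)
    rr_prev = np.concatenate([[np.nan], np.diff(r_times)])
    rr_prev[~valid] = np.nan

    flags = []
    for k in range(n):
        if not valid[k]:
            flags.append("window_truncated")
        elif min(c_r[k], c_q[k], c_t[k]) < MIN_ALIGNMENT_CORR:
            flags.append("noisy")
        else:
            flags.append("ok")

    shifts = np.column_stack([s_r, s_q, s_t])
    return QTSeries(qt_ms=qt, rr_prev_ms=rr_prev, shifts=shifts,
                    flags=flags, r_times=r_times)
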