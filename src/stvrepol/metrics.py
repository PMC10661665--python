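"""Short-term variability of repolarization and its quality/exclusion rules.

The central statistic is

    STV = sum |D_{n+1} - D_n| / ((N - 1) * sqrt(2))

over ``N`` consecutive beats (31 in the reference protocol, giving the
``30 * sqrt(2)`` denominator), where ``D`` is the per-beat repolarization
determinant — the QT interval on the surface ECG or the activation recovery
interval on the intracardiac electrogram.  Geometrically this is the mean
perpendicular distance to the identity line of the Poincaré plot of
``D_{n+1}`` against ``D_n``.

Also here: the ectopy exclusion rule (an ectopic beat is removed together
with the beat before and the two beats after it), Bazett rate correction,
caliper-style ST-deviation, electrogram channel selection, percentage change
from baseline, and segment quality assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ari import AlgoParams, beat_window, detect_pace_spikes
from .errors import InsufficientDataError, NoChannelError, ParameterError
from .records import SignalRecord
from .sensing import SenseSeries

__all__ = [
    "STVResult",
    "SegmentQuality",
    "stv",
    "ectopy_exclusion_mask",
    "qtc_bazett",
    "st_deviation",
    "select_egm_channel",
    "percent_change",
    "segment_quality",
]

SQRT2 = np.sqrt(2.0)


@dataclass
class STVResult:
    """STV value with provenance: which determinant, how many beat pairs,
    and how many beats were excluded."""

    value: float
    determinant: str = ""  # "QT" or "ARI"
    n_pairs: int = 0
    n_excluded: int = 0
    beat_span: tuple[int, int] = (0, 0)


@dataclass
class SegmentQuality:
    """Noise, morphology stability, ectopy burden and pacing status of a
    segment, plus the resulting measurability verdict for T-wave metrics."""

    noise_rms: float
    morphology_stability: float
    ectopy_fraction: float
    pacing_present: bool
    measurable: bool


def stv(
    determinants,
    expected_n: int = 31,
    strict: bool = False,
    determinant: str = "",
) -> STVResult:
    """Short-term variability of a per-beat determinant series.

    NaN entries mark excluded/unmeasurable beats; pairs spanning a gap are
    dropped and the denominator uses the retained pair count.  In ``strict``
    mode the series must consist of exactly ``expected_n`` consecutive
    usable values (the reference protocol's 31-beat segment).
    """
    d = np.asarray(determinants, dtype=float)
    usable = ~np.isnan(d)
    n_usable = int(usable.sum())
    if n_usable < 2:
        raise InsufficientDataError(
            f"STV needs >= 2 usable determinants, got {n_usable}"
        )
    if strict:
        runs = _longest_true_run(usable)
        if n_usable != expected_n or (runs[1] - runs[0]) != expected_n:
            raise ParameterError(
                f"strict mode requires exactly {expected_n} consecutive "
                f"usable values (got {n_usable} usable, longest run "
                f"{runs[1] - runs[0]})"
            )
    pair_ok = usable[:-1] & usable[1:]
    n_pairs = int(pair_ok.sum())
    if n_pairs < 1:
        raise InsufficientDataError("no consecutive usable beat pairs")
    diffs = np.abs(np.diff(d))[pair_ok]
    value = float(diffs.sum() / (n_pairs * SQRT2))
    span = (int(np.flatnonzero(usable)[0]), int(np.flatnonzero(usable)[-1]))
    return STVResult(value=value, determinant=determinant, n_pairs=n_pairs,
                     n_excluded=int(len(d) - n_usable), beat_span=span)


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """Half-open ``[start, end)`` of the longest run of True values."""
    best = (0, 0)
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(mask) - start > best[1] - best[0]:
        best = (start, len(mask))
    return best


def longest_clean_run(mask) -> tuple[int, int]:
    """Public helper: longest half-open run of usable beats in a mask."""
    return _longest_true_run(np.asarray(mask, dtype=bool))


def ectopy_exclusion_mask(labels, exclude_paced: bool = True) -> np.ndarray:
    """Boolean keep-mask implementing the ectopy exclusion rule.

    Each ectopic beat is excluded together with its predecessor and its two
    successors (clipped at the series ends).  ``paced`` beats are excluded
    too when the determinant is T-wave based (``exclude_paced=True``).
    """
    labels = list(labels)
    if not labels:
        raise ParameterError("label list must be non-empty")
    n = len(labels)
    keep = np.ones(n, dtype=bool)
    for i, lab in enumerate(labels):
        if lab == "ectopic":
            keep[max(i - 1, 0): min(i + 3, n)] = False
        elif lab == "paced" and exclude_paced:
            keep[i] = False
    return keep


def qtc_bazett(qt: float, rr: float):
    """Bazett rate-corrected QT: ``QT / sqrt(RR in seconds)`` (both ms)."""
    qt = np.asarray(qt, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ParameterError("qt and rr must be positive")
    out = qt / np.sqrt(rr / 1000.0)
    return float(out) if out.ndim == 0 else out


def percent_change(value: float, baseline: float) -> float:
    """Percentage change from baseline: ``100 * (value - baseline) / baseline``."""
    if baseline <= 0:
        raise ParameterError(f"baseline must be positive, got {baseline}")
    return 100.0 * (value - baseline) / baseline


def st_deviation(
    record: SignalRecord,
    channel: str,
    senses: SenseSeries,
    j_offset_ms: float = 60.0,
    baseline_offset_ms: float = 80.0,
) -> float:
    """Caliper-style ST-segment deviation in mV.

    Per beat: ST level is the mean over a 10 ms window starting
    ``j_offset_ms`` after the sense; the isoelectric reference is the mean
    over a 20 ms window ending ``baseline_offset_ms`` before the sense.  The
    record's ST-deviation is the median over beats of (ST - reference),
    which makes it immune to DC offsets and robust to the odd bad beat.
    """
    x = record.channel(channel)
    dt = record.dt_ms
    values = []
    for s in senses.times:
        st_lo = int(round((s + j_offset_ms) / dt))
        st_hi = int(round((s + j_offset_ms + 10.0) / dt))
        ref_lo = int(round((s - baseline_offset_ms - 20.0) / dt))
        ref_hi = int(round((s - baseline_offset_ms) / dt))
        if ref_lo < 0 or st_hi > record.n_samples:
            continue  # beat not fully inside the record
        values.append(float(np.mean(x[st_lo:st_hi]) - np.mean(x[ref_lo:ref_hi])))
    if not values:
        raise InsufficientDataError("no beat fully inside the record")
    return float(np.median(values))


def _t_window_ptp(record: SignalRecord, channel: str, senses: SenseSeries,
                  params: AlgoParams) -> float:
    """Median peak-to-peak amplitude over the per-beat analysis windows."""
    rr = np.diff(senses.times)
    median_rr = float(np.median(rr))
    x = record.channel(channel)
    dt = record.dt_ms
    ptps = []
    for s in senses.times:
        lo, hi = beat_window(s, median_rr, params)
        i0, i1 = int(np.ceil(lo / dt)), int(np.ceil(hi / dt))
        if i0 < 0 or i1 > record.n_samples or i1 - i0 < 2:
            continue
        ptps.append(float(np.ptp(x[i0:i1])))
    return float(np.median(ptps)) if ptps else 0.0


def select_egm_channel(
    record: SignalRecord,
    senses: SenseSeries,
    params: AlgoParams | None = None,
) -> tuple[str, dict]:
    """Pick the analysis pole of a multichannel electrogram.

    Channels are assumed ordered most-apical first (pole I1 at the catheter
    tip).  The first channel whose T-wave peak-to-peak amplitude in the
    analysis window reaches ``t_amp_min_mV`` *and* whose absolute
    ST-deviation stays within ``st_ceiling_mV`` is selected — the tip pole
    typically falls to the injury-current criterion.  Raises
    :class:`NoChannelError` (with per-channel reasons) if nothing qualifies.
    """
    params = params or AlgoParams()
    if len(senses) < 2:
        raise InsufficientDataError("channel selection needs >= 2 senses")
    report: dict[str, dict] = {}
    chosen = None
    for label in record.channel_labels:
        t_amp = _t_window_ptp(record, label, senses, params)
        st = st_deviation(record, label, senses)
        ok_amp = t_amp >= params.t_amp_min_mV
        ok_st = abs(st) <= params.st_ceiling_mV
        reason = None
        if not ok_amp:
            reason = (f"T-wave amplitude {t_amp:.3f} mV below "
                      f"{params.t_amp_min_mV} mV")
        elif not ok_st:
            reason = (f"|ST-deviation| {abs(st):.3f} mV above ceiling "
                      f"{params.st_ceiling_mV} mV")
        report[label] = {"t_amplitude_mV": t_amp, "st_deviation_mV": st,
                         "selected": False, "reason": reason}
        if chosen is None and reason is None:
            chosen = label
            report[label]["selected"] = True
    if chosen is None:
        raise NoChannelError(
            "no electrogram channel passes the quality gates",
            reasons={lab: rep["reason"] for lab, rep in report.items()},
        )
    return chosen, report


def segment_quality(
    record: SignalRecord,
    channel: str,
    senses: SenseSeries,
    labels=None,
    stability_min: float = 0.9,
    ectopy_max: float = 0.1,
    params: AlgoParams | None = None,
) -> SegmentQuality:
    """Assess whether a segment is fit for T-wave-based STV measurement.

    ``noise_rms`` is measured in beat-free pre-QRS gaps (after removing each
    gap's mean); ``morphology_stability`` is the mean correlation of beat
    windows with their average; a segment is ``measurable`` when stability
    >= ``stability_min``, the ectopy fraction <= ``ectopy_max`` and no
    pacing spikes are present.
    """
    params = params or AlgoParams()
    if len(senses) < 3:
        raise InsufficientDataError("segment quality needs >= 3 beats")
    x = record.channel(channel)
    dt = record.dt_ms

    # noise from pre-QRS baseline gaps (sense - 100 .. sense - 60 ms)
    noise_vals = []
    beats = []
    rr_med = float(np.median(np.diff(senses.times)))
    pre = int(round(60.0 / dt))
    post = int(round(min(350.0, rr_med - 100.0) / dt))
    for s in senses.times:
        g0 = int(round((s - 100.0) / dt))
        g1 = int(round((s - 60.0) / dt))
        if g0 >= 0 and g1 <= record.n_samples and g1 > g0:
            gap = x[g0:g1]
            noise_vals.append(float(np.sqrt(np.mean((gap - gap.mean()) ** 2))))
        i = int(round(s / dt))
        if i - pre >= 0 and i + post <= record.n_samples:
            beats.append(x[i - pre: i + post])
    noise_rms = float(np.median(noise_vals)) if noise_vals else np.nan

    if len(beats) >= 2:
        mat = np.asarray(beats)
        avg = mat.mean(axis=0)
        avg0 = avg - avg.mean()
        n_avg = np.linalg.norm(avg0)
        corrs = []
        for b in mat:
            b0 = b - b.mean()
            nb = np.linalg.norm(b0)
            corrs.append(float(b0 @ avg0 / (nb * n_avg)) if nb * n_avg > 0 else 0.0)
        stability = float(np.mean(corrs))
    else:
        stability = np.nan

    if labels is not None:
        ectopy_fraction = sum(1 for lab in labels if lab == "ectopic") / len(labels)
    else:
        ectopy_fraction = 0.0

    spikes = detect_pace_spikes(record, channel, params.spike_slope_mV_per_ms)
    pacing_present = len(spikes) > 0

    measurable = (
        (not np.isnan(stability) and stability >= stability_min)
        and ectopy_fraction <= ectopy_max
        and not pacing_present
    )
    return SegmentQuality(
        noise_rms=noise_rms,
        morphology_stability=stability,
        ectopy_fraction=float(ectopy_fraction),
        pacing_present=pacing_present,
        measurable=measurable,
    )
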