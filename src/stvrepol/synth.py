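"""Synthetic cardiac signal generator with exact per-beat ground truth.

The generator emulates the signal *statistics* that matter to beat-to-beat
repolarization variability analysis — beat trains with a programmable RR
series, per-beat repolarization-interval jitter (Gaussian, alternans, linear
trend), ST-segment deviation, ectopic beats with altered morphology, pacing
spikes, and additive noise — not torso biophysics.  Every landmark used to
build the waveform is exported, so downstream estimators (beat sensing, the
automatic ARI method, fiducial segment averaging) have an exact oracle.

Beat morphology is a piecewise analytic template:

* QRS: biphasic, the difference of two Gaussians with the dominant (positive)
  lobe centred on the R peak;
* T-wave: an asymmetric raised-cosine bump of total width ``t_width``, with
  compact support, placed so that its 1 %-of-peak point on the falling lobe
  coincides with the programmed repolarization offset;
* ST segment: a cosine-tapered plateau of height ``st_deviation`` between the
  end of the QRS and the foot of the T-wave;
* pace spike: a narrow (~1 ms sigma) Gaussian of amplitude twice the QRS,
  20 ms before QRS onset.

Ectopic beats get a twice-widened QRS, an inverted T-wave, and a shortened
coupling interval of ``0.6 * rr_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GenerationError, ParameterError
from .records import GroundTruth, SignalRecord

__all__ = [
    "PacingConfig",
    "SynthConfig",
    "make_interval_series",
    "synthesize_record",
]

# Geometry constants of the beat template (ms unless noted).
QRS_ONSET_BEFORE_R_MS = 30.0     # QRS onset precedes the R peak by this much
QRS_SIGMA_MS = 7.0               # width of the dominant QRS lobe
QRS_SECOND_LOBE_LAG_MS = 14.0    # S-lobe centre after R
QRS_SECOND_LOBE_FRAC = 0.45      # S-lobe amplitude relative to R lobe
T_RISE_FRAC = 0.55               # fraction of t_width on the rising limb
SPIKE_BEFORE_QRS_ONSET_MS = 20.0
SPIKE_SIGMA_MS = 1.0
SPIKE_AMPLITUDE_FRAC = 2.0       # spike amplitude relative to qrs_amplitude
ST_TAPER_MS = 15.0
ECTOPIC_COUPLING_FRAC = 0.6

# Falling-lobe fraction at which the raised-cosine T drops to 1 % of its
# peak; the template is built backward from this so that the exported T-end
# is exact: 0.5*(1+cos(pi*x)) = 0.01  =>  x = acos(2*0.01 - 1)/pi.
_T_END_FRAC_OF_FALL = float(np.arccos(2 * 0.01 - 1.0) / np.pi)


@dataclass
class PacingConfig:
    """Atrial high-rate pacing: drive the rhythm faster than sinus and stamp
    a pace spike before every QRS."""

    enabled: bool = False
    rate_offset_bpm: float = 20.0


@dataclass
class SynthConfig:
    """Parameters of one synthetic record.

    Times in ms, amplitudes in mV, rates in Hz.  ``repol_mean`` is the true
    repolarization determinant (QT for ECG-style records, the same landmark
    distance for EGM-style ones); per-beat values are
    ``repol_mean + repol_trend*k + repol_alternans*(-1)^k + N(0, repol_jitter_sd)``.
    """

    fs: float = 1000.0
    n_beats: int = 33
    rr_mean: float = 750.0
    rr_jitter_sd: float = 20.0
    repol_mean: float = 400.0
    repol_jitter_sd: float = 1.0
    repol_alternans: float = 0.0
    repol_trend: float = 0.0
    t_amplitude: float = 0.8
    t_width: float = 160.0
    qrs_amplitude: float = 1.5
    st_deviation: float = 0.0
    ectopic_indices: Sequence[int] = field(default_factory=list)
    pacing: PacingConfig = field(default_factory=PacingConfig)
    noise_sd: float = 0.0
    seed: int = 0
    channel_labels: list[str] = field(default_factory=lambda: ["V2"])
    #: per-channel overrides, label -> {"t_amplitude", "st_deviation",
    #: "t_polarity"}; used to emulate electrogram poles with differing
    #: T-wave amplitude and injury current.
    channel_overrides: dict = field(default_factory=dict)
    #: time of the first sense, ms from record start
    lead_in_ms: float = 400.0

    def __post_init__(self) -> None:
        if isinstance(self.pacing, dict):
            self.pacing = PacingConfig(**self.pacing)
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.n_beats < 1:
            raise ParameterError("n_beats must be >= 1")
        if not (self.rr_mean > self.repol_mean > 0):
            raise ParameterError(
                f"need rr_mean > repol_mean > 0, got {self.rr_mean}, {self.repol_mean}"
            )
        if self.t_width <= 0:
            raise ParameterError("t_width must be positive")
        for name in ("rr_jitter_sd", "repol_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for e in self.ectopic_indices:
            if not 0 <= e < self.n_beats:
                raise ParameterError(f"ectopic index {e} outside [0, {self.n_beats})")

    # Convenience constructors for the two recorder styles.
    @classmethod
    def ecg(cls, **kw) -> "SynthConfig":
        """Surface-ECG style: 1200 Hz, lead V2."""
        kw.setdefault("fs", 1200.0)
        kw.setdefault("channel_labels", ["V2"])
        return cls(**kw)

    @classmethod
    def egm(cls, **kw) -> "SynthConfig":
        """Intracardiac-electrogram style: 1000 Hz, poles I1..I3 counted from
        the catheter tip; I1 carries a large injury current (ST offset)."""
        kw.setdefault("fs", 1000.0)
        kw.setdefault("channel_labels", ["I1", "I2", "I3"])
        kw.setdefault(
            "channel_overrides",
            {"I1": {"st_deviation": 0.8}},
        )
        return cls(**kw)


def make_interval_series(
    n: int,
    mean: float,
    jitter_sd: float = 0.0,
    alternans: float = 0.0,
    trend: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Per-beat interval series ``mean + trend*k + alternans*(-1)^k + eps_k``.

    ``eps_k`` is iid Gaussian with standard deviation ``jitter_sd``.
    Reproducible for a fixed integer ``seed``; a ``numpy.random.Generator``
    may be passed directly to share a stream.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if mean <= 0:
        raise ParameterError(f"mean must be positive, got {mean}")
    if jitter_sd < 0:
        raise ParameterError("jitter_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = np.arange(n)
    eps = rng.normal(0.0, jitter_sd, size=n) if jitter_sd > 0 else np.zeros(n)
    return mean + trend * k + alternans * ((-1.0) ** k) + eps


# ---------------------------------------------------------------------------
# waveform assembly helpers
# ---------------------------------------------------------------------------

def _add_gaussian(sig: np.ndarray, t: np.ndarray, center: float, sigma: float,
                  amp: float) -> None:
    """Add ``amp * exp(-(t-center)^2 / 2 sigma^2)`` in place, windowed to 6 sigma."""
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    lo = max(0, int((center - 6 * sigma) / dt))
    hi = min(len(t), int((center + 6 * sigma) / dt) + 2)
    if lo >= hi:
        return
    x = t[lo:hi] - center
    sig[lo:hi] += amp * np.exp(-0.5 * (x / sigma) ** 2)


def _add_qrs(sig: np.ndarray, t: np.ndarray, r_peak: float, amp: float,
             widen: float = 1.0) -> None:
    """Biphasic QRS: dominant positive lobe at the R peak, smaller negative
    lobe after it.  ``widen`` scales both lobe widths (ectopy)."""
    _add_gaussian(sig, t, r_peak, QRS_SIGMA_MS * widen, amp)
    _add_gaussian(sig, t, r_peak + QRS_SECOND_LOBE_LAG_MS * widen,
                  QRS_SIGMA_MS * 1.3 * widen, -QRS_SECOND_LOBE_FRAC * amp)


def t_wave_geometry(t_end: float, t_width: float) -> tuple[float, float, float]:
    """Return ``(peak_time, rise_halfwidth, fall_halfwidth)`` of the T
    template whose 1 %-of-peak falling point lies at ``t_end``."""
    w_up = T_RISE_FRAC * t_width
    w_down = (1.0 - T_RISE_FRAC) * t_width
    peak = t_end - _T_END_FRAC_OF_FALL * w_down
    return peak, w_up, w_down


def _add_t_wave(sig: np.ndarray, t: np.ndarray, t_end: float, t_width: float,
                amp: float) -> None:
    """Asymmetric raised-cosine T-wave with compact support, ending (at the
    1 % level) exactly at ``t_end``."""
    peak, w_up, w_down = t_wave_geometry(t_end, t_width)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    lo = max(0, int((peak - w_up) / dt))
    hi = min(len(t), int((peak + w_down) / dt) + 2)
    if lo >= hi:
        return
    x = t[lo:hi] - peak
    w = np.where(x < 0, w_up, w_down)
    phase = np.clip(x / w, -1.0, 1.0)
    sig[lo:hi] += amp * 0.5 * (1.0 + np.cos(np.pi * phase)) * (np.abs(x / w) < 1.0)


def _add_st_plateau(sig: np.ndarray, t: np.ndarray, start: float, end: float,
                    level: float) -> None:
    """Cosine-tapered plateau of height ``level`` on [start, end]."""
    if level == 0.0 or end <= start:
        return
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    taper = min(ST_TAPER_MS, (end - start) / 2.0)
    lo = max(0, int(start / dt))
    hi = min(len(t), int(end / dt) + 2)
    if lo >= hi:
        return
    x = t[lo:hi]
    env = np.ones_like(x)
    rising = x < start + taper
    falling = x > end - taper
    env[rising] = 0.5 * (1 - np.cos(np.pi * (x[rising] - start) / taper))
    env[falling] = 0.5 * (1 - np.cos(np.pi * (end - x[falling]) / taper))
    env[(x < start) | (x > end)] = 0.0
    sig[lo:hi] += level * env


# ---------------------------------------------------------------------------
# record synthesis
# ---------------------------------------------------------------------------

def _beat_schedule(cfg: SynthConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Sense times, labels and per-beat repolarization intervals."""
    rr_mean = cfg.rr_mean
    if cfg.pacing.enabled:
        # pacing drives the rate `rate_offset_bpm` above the sinus rate
        rr_mean = 60000.0 / (60000.0 / cfg.rr_mean + cfg.pacing.rate_offset_bpm)

    labels = ["paced" if cfg.pacing.enabled else "normal"] * cfg.n_beats
    for e in cfg.ectopic_indices:
        labels[e] = "ectopic"

    rr_draws = make_interval_series(
        max(cfg.n_beats - 1, 1), rr_mean, cfg.rr_jitter_sd, seed=rng
    )
    senses = np.empty(cfg.n_beats)
    senses[0] = cfg.lead_in_ms
    for k in range(1, cfg.n_beats):
        if labels[k] == "ectopic":
            senses[k] = senses[k - 1] + ECTOPIC_COUPLING_FRAC * cfg.rr_mean
        else:
            senses[k] = senses[k - 1] + rr_draws[k - 1]

    repol = make_interval_series(
        cfg.n_beats, cfg.repol_mean, cfg.repol_jitter_sd,
        cfg.repol_alternans, cfg.repol_trend, seed=rng,
    )

    for k in range(cfg.n_beats - 1):
        if senses[k + 1] - senses[k] <= repol[k]:
            raise GenerationError(
                f"beat {k}: RR interval {senses[k+1]-senses[k]:.1f} ms does not "
                f"exceed its repolarization interval {repol[k]:.1f} ms"
            )
    return senses, labels, repol


def synthesize_record(config: SynthConfig) -> tuple[SignalRecord, GroundTruth]:
    """Build a multichannel record and its exact per-beat ground truth.

    Deterministic: identical ``config`` (including ``seed``) yields
    bit-identical output.  Raises :class:`GenerationError`, naming the beat,
    if a drawn RR interval cannot contain its repolarization interval.
    """
    rng = np.random.default_rng(config.seed)
    senses, labels, repol = _beat_schedule(config, rng)

    r_peaks = senses.copy()
    widen = np.array([2.0 if lab == "ectopic" else 1.0 for lab in labels])
    qrs_onsets = r_peaks - QRS_ONSET_BEFORE_R_MS * widen
    t_ends = qrs_onsets + repol

    tail = max(config.rr_mean, repol[-1] + 2 * config.t_width)
    n_samples = int(np.ceil((senses[-1] + tail + 200.0) * config.fs / 1000.0))
    t = np.arange(n_samples) * (1000.0 / config.fs)

    n_ch = len(config.channel_labels)
    samples = np.zeros((n_ch, n_samples))
    for ci, lab in enumerate(config.channel_labels):
        ov = config.channel_overrides.get(lab, {})
        t_amp = ov.get("t_amplitude", config.t_amplitude)
        st_dev = ov.get("st_deviation", config.st_deviation)
        t_pol = ov.get("t_polarity", 1.0)
        sig = samples[ci]
        for k in range(config.n_beats):
            ect = labels[k] == "ectopic"
            _add_qrs(sig, t, r_peaks[k], config.qrs_amplitude,
                     widen=2.0 if ect else 1.0)
            amp_k = -t_amp if ect else t_pol * t_amp
            _add_t_wave(sig, t, t_ends[k], config.t_width, amp_k)
            peak_k, w_up, _ = t_wave_geometry(t_ends[k], config.t_width)
            _add_st_plateau(sig, t, r_peaks[k] + 3.0 * QRS_SIGMA_MS * widen[k],
                            peak_k - w_up, st_dev)
            if labels[k] == "paced":
                _add_gaussian(sig, t, qrs_onsets[k] - SPIKE_BEFORE_QRS_ONSET_MS,
                              SPIKE_SIGMA_MS,
                              SPIKE_AMPLITUDE_FRAC * config.qrs_amplitude)
        if config.noise_sd > 0:
            sig += rng.normal(0.0, config.noise_sd, size=n_samples)

    record = SignalRecord(samples=samples, fs=config.fs,
                          channel_labels=list(config.channel_labels))
    truth = GroundTruth(
        sense_time=senses,
        label=labels,
        qrs_onset=qrs_onsets,
        r_peak=r_peaks,
        t_end=t_ends,
        true_repol_interval=repol,
    )
    return record, truth
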