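"""Agreement between the two STV modalities: Spearman correlation and
Bland-Altman bias with limits of agreement.

Spearman's rho is the Pearson correlation of mid-ranks; the p-value is an
exact permutation probability for n <= 9 and the usual t approximation
otherwise.  Bland-Altman limits are ``bias +/- 1.96 * sd`` of the pairwise
differences (sample sd, n-1 denominator), so the limits are symmetric about
the bias by construction: ``loa_low + loa_high = 2 * bias``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError
from .metrics import percent_change

__all__ = ["AgreementResult", "spearman_rho", "bland_altman", "agreement_report"]

#: exact permutation p-value cut-over (9! = 362880 permutations)
_EXACT_PERM_MAX_N = 9


@dataclass
class AgreementResult:
    rho: float = np.nan
    p_value: float = np.nan
    bias: float = np.nan
    loa_low: float = np.nan
    loa_high: float = np.nan
    n: int = 0


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns ``(rho, p_value)``; the p-value is two-sided, exact by full
    permutation for n <= 9 and via the t approximation with n - 2 degrees of
    freedom otherwise.  A constant input has no rank ordering and raises
    :class:`ParameterError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("Spearman needs n >= 3")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ParameterError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for a constant input")

    rx = sps.rankdata(x)  # mid-ranks for ties
    ry = sps.rankdata(y)
    rho = _pearson(rx, ry)

    if n <= _EXACT_PERM_MAX_N:
        # rank means and norms are permutation-invariant, so |rho_perm| is a
        # monotone function of |sum(rx_i * ry_perm_i) - n*mean(rx)*mean(ry)|
        c = n * rx.mean() * ry.mean()
        obs = abs(float(rx @ ry) - c)
        rx_t = tuple(rx)
        count = 0
        total = 0
        for perm in permutations(ry):
            s = sum(a * b for a, b in zip(rx_t, perm))
            if abs(s - c) >= obs - 1e-9:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    return float(rho), float(min(p, 1.0))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement of two paired series (same units).

    ``d = a - b``; bias = mean(d); limits of agreement = bias +/- 1.96 *
    sample sd(d).  Identical series give (0, 0, 0); a constant offset gives
    zero-width limits equal to the offset.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("a and b must be 1-D and the same length")
    if len(a) < 3:
        raise InsufficientDataError("Bland-Altman needs n >= 3")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd, n=len(d))


def _pool(stv_a: dict, stv_b: dict, baseline_key: str):
    """Pool paired (value, percent-change) observations across one subject's
    timepoint map or a nested subject -> timepoint map."""
    nested = any(isinstance(v, dict) for v in stv_a.values())
    subjects = list(stv_a) if nested else [None]
    raw_a, raw_b, pct_a, pct_b = [], [], [], []
    for subj in subjects:
        ma = stv_a[subj] if nested else stv_a
        mb = stv_b[subj] if nested else stv_b
        if baseline_key not in ma or baseline_key not in mb:
            raise KeyError(f"baseline key {baseline_key!r} missing"
                           + (f" for subject {subj!r}" if subj else ""))
        base_a, base_b = ma[baseline_key], mb[baseline_key]
        shared = [k for k in ma if k != baseline_key and k in mb
                  and ma[k] is not None and mb[k] is not None]
        for k in shared:
            raw_a.append(ma[k])
            raw_b.append(mb[k])
            pct_a.append(percent_change(ma[k], base_a))
            pct_b.append(percent_change(mb[k], base_b))
    return (np.asarray(raw_a), np.asarray(raw_b),
            np.asarray(pct_a), np.asarray(pct_b))


def agreement_report(
    stv_qt: dict,
    stv_ari: dict,
    baseline_key: str = "baseline",
    bland_altman_on: str = "raw",
    spearman_on: str = "percent_change",
) -> AgreementResult:
    """Agreement between QT-derived and ARI-derived STV across timepoints.

    ``stv_qt`` / ``stv_ari`` map timepoint label -> STV in ms, or subject ->
    {timepoint -> STV} for a pooled cohort.  Both series are converted to
    percentage change from ``baseline_key``; by default Spearman correlation
    is computed on the percentage changes and Bland-Altman on the raw ms
    values at the pooled non-baseline timepoints (both choices are
    flag-controlled via ``bland_altman_on`` / ``spearman_on``).
    """
    for name, v in (("bland_altman_on", bland_altman_on),
                    ("spearman_on", spearman_on)):
        if v not in ("raw", "percent_change"):
            raise ParameterError(f"{name} must be 'raw' or 'percent_change'")
    raw_q, raw_a, pct_q, pct_a = _pool(stv_qt, stv_ari, baseline_key)
    if len(raw_q) < 2:
        raise InsufficientDataError(
            "need >= 2 shared non-baseline timepoints for agreement"
        )
    sx, sy = (pct_q, pct_a) if spearman_on == "percent_change" else (raw_q, raw_a)
    bx, by = (raw_q, raw_a) if bland_altman_on == "raw" else (pct_q, pct_a)
    rho, p = spearman_rho(sx, sy)
    ba = bland_altman(bx, by)
    return AgreementResult(rho=rho, p_value=p, bias=ba.bias,
                           loa_low=ba.loa_low, loa_high=ba.loa_high, n=ba.n)
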