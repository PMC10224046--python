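"""Agreement statistics between ECG- and SCG-derived inter-beat intervals.

Paired intervals are compared by ordinary least squares (SCG on ECG), the
squared Pearson correlation, and Bland-Altman analysis: the bias is the mean
of the differences (oriented SCG - ECG), the limits of agreement are
bias +- 1.96 x sample SD (n-1 denominator), and the bias significance is a
two-sided one-sample t-test of the differences against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .errors import DegenerateDataError, InsufficientDataError

__all__ = ["IbiPairSet", "AgreementResult", "regress_correlate", "bland_altman"]

LOA_MULTIPLIER = 1.96


@dataclass
class IbiPairSet:
    """Matched (ECG, SCG) inter-beat intervals in milliseconds."""

    ecg_ibi_ms: np.ndarray
    scg_ibi_ms: np.ndarray

    def __post_init__(self) -> None:
        self.ecg_ibi_ms = np.asarray(self.ecg_ibi_ms, dtype=np.float64)
        self.scg_ibi_ms = np.asarray(self.scg_ibi_ms, dtype=np.float64)
        if self.ecg_ibi_ms.shape != self.scg_ibi_ms.shape or self.ecg_ibi_ms.ndim != 1:
            raise InsufficientDataError("paired interval lists must have equal length")
        if len(self.ecg_ibi_ms) and (
            np.any(self.ecg_ibi_ms <= 0) or np.any(self.scg_ibi_ms <= 0)
        ):
            raise DegenerateDataError("intervals must be positive")

    @property
    def n(self) -> int:
        return len(self.ecg_ibi_ms)


@dataclass
class AgreementResult:
    slope: float
    intercept_ms: float
    r_squared: float
    bias_ms: float
    loa_halfwidth_ms: float
    bias_p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept_ms": self.intercept_ms,
            "r_squared": self.r_squared,
            "bias_ms": self.bias_ms,
            "loa_halfwidth_ms": self.loa_halfwidth_ms,
            "bias_p_value": self.bias_p_value,
            "n": self.n,
        }


def regress_correlate(pairs: IbiPairSet) -> tuple[float, float, float]:
    """OLS of SCG intervals on ECG intervals; returns (slope, intercept, R^2)."""
    if pairs.n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {pairs.n}")
    x, y = pairs.ecg_ibi_ms, pairs.scg_ibi_ms
    if float(np.var(x)) == 0.0:
        raise DegenerateDataError("ECG intervals are constant; regression undefined")
    if float(np.var(y)) == 0.0:
        # Pearson r undefined; a constant response is perfectly fit by slope 0
        slope, intercept = 0.0, float(np.mean(y))
        return slope, intercept, 1.0
    res = sp_stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(pairs: IbiPairSet) -> AgreementResult:
    """Full agreement analysis (regression + correlation + Bland-Altman)."""
    if pairs.n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {pairs.n}")
    d = pairs.scg_ibi_ms - pairs.ecg_ibi_ms
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else 0.0
    else:
        p = float(sp_stats.ttest_1samp(d, 0.0).pvalue)
    try:
        slope, intercept, r2 = regress_correlate(pairs)
    except DegenerateDataError:
        slope = intercept = r2 = float("nan")
    return AgreementResult(
        slope=slope,
        intercept_ms=intercept,
        r_squared=r2,
        bias_ms=bias,
        loa_halfwidth_ms=LOA_MULTIPLIER * sd,
        bias_p_value=p,
        n=pairs.n,
    )
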