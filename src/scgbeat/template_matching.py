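"""Heartbeat detection by normalized cross-correlation template matching.

A single-heartbeat SCG snippet (the template) is slid over the band-passed
SCG signal; at every lag ``k`` the similarity is

    NCC(k) = sum_n (s[n] - mu_s(k)) (t[n - k] - mu_t)
             / sqrt( sum_n (s[n] - mu_s(k))^2 * sum_n (t[n] - mu_t)^2 )

where the sums run over the template's support, ``mu_t`` is the template mean
and ``mu_s(k)`` the signal mean over the shifted template window.  NCC(k)
aligns the template start with signal sample ``k`` and is computed for valid
lags only (template fully inside the signal).  Local NCC maxima filtered by
topographic prominence and a minimum peak distance mark the heartbeats.

Case 1 templates span both the systolic and diastolic complexes; case 2
templates cover the systolic complex only (used when no clear diastolic
complex is visible).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal

from .errors import (
    BoundsError,
    ConfigurationError,
    DegenerateTemplateError,
    InsufficientDataError,
    LengthError,
)
from .io_records import BeatAnnotations, SignalRecord

__all__ = [
    "Template",
    "NccSeries",
    "select_template",
    "suggest_template",
    "compute_ncc",
    "compute_ncc_record",
    "find_ncc_peaks",
    "beats_from_peaks",
]

DEFAULT_MIN_PROMINENCE = 0.5  # legal range 0.3-0.7 for case-2 templates
DEFAULT_MIN_DISTANCE_S = 0.5

# case 1 spans systole + diastole, case 2 the systolic complex only
_SUGGEST_PRE_S = 0.10
_SUGGEST_POST_S = {1: 0.45, 2: 0.15}


@dataclass
class Template:
    """A single-heartbeat SCG snippet used as the morphological reference."""

    samples: np.ndarray
    case_label: int
    start_index: int
    systolic_peak_offset: int
    source_record_id: str = ""
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.case_label not in (1, 2):
            raise ConfigurationError(f"case_label must be 1 or 2, got {self.case_label}")
        if len(self.samples) < 2:
            raise DegenerateTemplateError("template must contain at least 2 samples")
        if float(np.var(self.samples)) == 0.0:
            raise DegenerateTemplateError("template is constant (zero variance)")
        if not 0 <= self.systolic_peak_offset < len(self.samples):
            raise ConfigurationError("systolic_peak_offset outside template")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class NccSeries:
    """NCC values over all valid lags plus (optionally) the selected peaks."""

    values: np.ndarray
    fs: float
    lag_zero_time_s: float = 0.0
    peak_lags: np.ndarray | None = None
    min_prominence: float | None = None
    min_distance_s: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) and (
            self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise ConfigurationError("NCC values must lie in [-1, 1]")
        if self.peak_lags is not None:
            self.peak_lags = np.asarray(self.peak_lags, dtype=np.int64)

    def peak_times_s(self) -> np.ndarray:
        if self.peak_lags is None:
            raise ConfigurationError("peaks not localized yet")
        return self.peak_lags / self.fs + self.lag_zero_time_s


def select_template(
    record: SignalRecord,
    bounds: tuple[float, float],
    case_label: int,
    scg: np.ndarray | None = None,
) -> Template:
    """Cut a template out of the (band-passed) SCG between ``bounds`` seconds.

    The systolic-peak offset is the arg-max of the snippet.
    """
    x = record.scg if scg is None else np.asarray(scg, dtype=np.float64)
    start_s, end_s = bounds
    if not (0 <= start_s < end_s):
        raise BoundsError(f"invalid bounds ({start_s}, {end_s})")
    i0 = int(round(start_s * record.fs))
    i1 = int(round(end_s * record.fs))
    if i1 > len(x) or i0 < 0:
        raise BoundsError(
            f"bounds ({start_s}, {end_s}) s fall outside the {len(x) / record.fs:.3f} s record"
        )
    snippet = x[i0:i1]
    if len(snippet) < 2 or float(np.var(snippet)) == 0.0:
        raise DegenerateTemplateError("selected region is constant or too short")
    return Template(
        samples=snippet.copy(),
        case_label=case_label,
        start_index=i0,
        systolic_peak_offset=int(np.argmax(snippet)),
        source_record_id=record.record_id,
    )


def compute_ncc(
    scg: np.ndarray,
    template: Template,
    fs: float = 1.0,
    lag_zero_time_s: float = 0.0,
) -> NccSeries:
    """Normalized cross-correlation of the template against every valid lag.

    Lags where the signal window has zero variance carry no similarity
    evidence and yield NCC = 0 (never NaN).
    """
    s = np.asarray(scg, dtype=np.float64)
    t = template.samples
    L, N = len(t), len(s)
    if L > N:
        raise LengthError(f"template ({L}) longer than signal ({N})")
    t0 = t - t.mean()
    norm_t = float(np.sqrt(np.sum(t0**2)))

    # centering the signal leaves NCC unchanged but conditions the sums
    sc = s - s.mean()

    # numerator: sum over window of s * t0 (the mu_s term cancels: sum(t0)=0)
    if N * L <= 4_000_000:
        num = np.correlate(sc, t0, mode="valid")
        # exact windowed variance, free of cumsum cancellation
        win = np.lib.stride_tricks.sliding_window_view(sc, L)
        var_term = np.sum((win - win.mean(axis=1, keepdims=True)) ** 2, axis=1)
        win_sum2 = np.sum(win**2, axis=1)
    else:
        num = sp_signal.fftconvolve(sc, t0[::-1], mode="valid")
        csum = np.concatenate([[0.0], np.cumsum(sc)])
        csum2 = np.concatenate([[0.0], np.cumsum(sc**2)])
        win_sum = csum[L:] - csum[:-L]
        win_sum2 = csum2[L:] - csum2[:-L]
        var_term = win_sum2 - win_sum**2 / L
        np.maximum(var_term, 0.0, out=var_term)
    degenerate = var_term <= 1e-12 * np.maximum(win_sum2, 1e-300)
    den = np.sqrt(var_term) * norm_t
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(degenerate, 0.0, num / np.where(den == 0, 1.0, den))
    return NccSeries(values=values, fs=float(fs), lag_zero_time_s=lag_zero_time_s)


def compute_ncc_record(record: SignalRecord, template: Template) -> NccSeries:
    """Convenience wrapper attaching the record's sampling frequency."""
    return compute_ncc(record.scg, template, fs=record.fs)


def find_ncc_peaks(
    ncc: NccSeries,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
) -> NccSeries:
    """Localize NCC peaks by topographic prominence and minimum distance.

    Candidates are all local maxima with prominence >= ``min_prominence``;
    the minimum distance is enforced greedily, accepting candidates in
    decreasing NCC order (ties: earlier lag wins).
    """
    cand, _ = sp_signal.find_peaks(ncc.values, prominence=min_prominence)
    min_gap = min_distance_s * ncc.fs
    order = np.lexsort((cand, -ncc.values[cand]))
    accepted: list[int] = []
    for i in order:
        lag = int(cand[i])
        if all(abs(lag - a) >= min_gap - 1e-9 for a in accepted):
            accepted.append(lag)
    return replace(
        ncc,
        peak_lags=np.asarray(sorted(accepted), dtype=np.int64),
        min_prominence=min_prominence,
        min_distance_s=min_distance_s,
    )


def beats_from_peaks(ncc: NccSeries, template: Template) -> BeatAnnotations:
    """Convert NCC peak lags to beat timestamps.

    The template's systolic-peak offset is added so detections align with the
    beats they mark; inter-beat intervals are unaffected by this constant
    shift.
    """
    if ncc.peak_lags is None:
        raise ConfigurationError("run find_ncc_peaks first")
    times = (ncc.peak_lags + template.systolic_peak_offset) / ncc.fs + ncc.lag_zero_time_s
    return BeatAnnotations(times_s=times, label="NCC")


def suggest_template(
    record: SignalRecord,
    r_peaks: BeatAnnotations,
    case_label: int,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
    max_candidates: int = 12,
) -> Template:
    """Automate template selection using reference beats as candidates.

    For each candidate beat a template is cut around its systolic peak and the
    full NCC detection is run; the candidate maximizing the median NCC peak
    height (median over the expected cycle count, missing cycles scored 0)
    wins.  Deterministic: ties resolve to the earliest candidate.  If the best
    median stays below ``min_prominence`` the returned template carries
    ``low_confidence=True``.
    """
    if len(r_peaks) < 10:
        raise InsufficientDataError(f"need >= 10 reference beats, got {len(r_peaks)}")
    fs = record.fs
    scg = record.scg
    inner = r_peaks.times_s[1:-1]
    take = np.unique(np.linspace(0, len(inner) - 1, min(max_candidates, len(inner))).astype(int))
    expected_cycles = len(r_peaks) - 1

    best: tuple[float, int, Template] | None = None
    for rank, ci in enumerate(take):
        r_time = inner[ci]
        w0 = int(round((r_time + 0.01) * fs))
        w1 = min(len(scg), int(round((r_time + 0.20) * fs)))
        if w1 - w0 < 2:
            continue
        peak_idx = w0 + int(np.argmax(scg[w0:w1]))
        i0 = max(0, peak_idx - int(round(_SUGGEST_PRE_S * fs)))
        i1 = min(len(scg), peak_idx + int(round(_SUGGEST_POST_S[case_label] * fs)))
        snippet = scg[i0:i1]
        if len(snippet) < 2 or float(np.var(snippet)) == 0.0:
            continue
        tpl = Template(
            samples=snippet.copy(),
            case_label=case_label,
            start_index=i0,
            systolic_peak_offset=int(np.argmax(snippet)),
            source_record_id=record.record_id,
        )
        series = find_ncc_peaks(
            compute_ncc_record(record, tpl), min_prominence, min_distance_s
        )
        heights = np.sort(series.values[series.peak_lags])[::-1]
        padded = np.zeros(max(expected_cycles, len(heights)))
        padded[: len(heights)] = heights
        score = float(np.median(padded))
        if best is None or score > best[0]:
            best = (score, rank, tpl)
    if best is None:
        raise DegenerateTemplateError("no usable template candidate found")
    score, _, tpl = best
    if score < min_prominence:
        tpl.low_confidence = True
    return tpl
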