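"""Per-cycle scoring of SCG detections against reference R-peaks.

Each cardiac cycle is the half-open interval [R_i, R_{i+1}); detected peaks
before the first or after the last R-peak are ignored, and cycles overlapping
motion-artifact intervals are excluded together with their peaks.  Within a
cycle the peak nearest to R_i plus the record's median systole latency is the
candidate heartbeat: a true positive (TP) if within the tolerance, a
detection error (DE) otherwise; every further peak in the cycle is a false
positive (FP), and a cycle with no peak at all is a false negative (FN).
DEs count against both sensitivity and PPV:

    sensitivity = 100 * TP / (TP + FN + DE)
    PPV         = 100 * TP / (TP + FP + DE)

Inter-beat-interval pairs are formed from runs of consecutive TP cycles;
any intervening FN/DE/excluded cycle breaks the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, UndefinedMetricError
from .io_records import BeatAnnotations
from .stats import IbiPairSet

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionReport",
    "classify_detections",
    "sensitivity",
    "ppv",
    "extract_ibi_pairs",
]

DEFAULT_TOLERANCE_S = 0.150
IBI_MIN_S = 0.25
IBI_MAX_S = 3.0

TP, FP, FN, DE, EXCLUDED = "TP", "FP", "FN", "DE", "EXCLUDED"


@dataclass
class DetectionReport:
    """Per-cycle classification counts and labels.

    Invariants: ``tp + fn + de == n_reference`` (non-excluded cycles) and the
    detected peaks in non-excluded cycles number ``tp + fp + de``.
    """

    tp: int
    fp: int
    fn: int
    de: int
    n_reference: int
    cycle_labels: list[str] = field(default_factory=list)
    fp_per_cycle: list[int] = field(default_factory=list)
    matched_pairs: list[tuple[float, float]] = field(default_factory=list)
    matched_ncc_per_cycle: list[float | None] = field(default_factory=list)
    expected_offset_s: float = float("nan")
    tolerance_s: float = DEFAULT_TOLERANCE_S

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "de", "n_reference"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fn + self.de != self.n_reference:
            raise ValueError(
                f"count conservation violated: tp+fn+de = "
                f"{self.tp + self.fn + self.de} != n_reference = {self.n_reference}"
            )

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, de: int) -> "DetectionReport":
        """Build a counts-only report (e.g. from published totals)."""
        return cls(tp=tp, fp=fp, fn=fn, de=de, n_reference=tp + fn + de)

    @property
    def n_detected(self) -> int:
        """Detected peaks in non-excluded cycles."""
        return self.tp + self.fp + self.de

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "de": self.de,
            "n_reference": self.n_reference,
            "n_detected": self.n_detected,
            "sensitivity_pct": sensitivity(self),
            "ppv_pct": ppv(self),
            "expected_offset_s": self.expected_offset_s,
            "tolerance_s": self.tolerance_s,
            "cycle_labels": self.cycle_labels,
            "fp_per_cycle": self.fp_per_cycle,
        }


def _cycle_overlaps(start: float, end: float, intervals) -> bool:
    return any(a < end and b > start for a, b in intervals)


def classify_detections(
    r_peaks: BeatAnnotations,
    ncc_beats: BeatAnnotations,
    artifact_intervals: list[tuple[float, float]] | None = None,
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> DetectionReport:
    """Label every cardiac cycle TP/FN/DE/EXCLUDED and count extra peaks as FP.

    The expected systole latency is the median, over non-excluded cycles
    containing at least one peak, of (first peak time - R_i).
    """
    r = np.asarray(r_peaks.times_s, dtype=np.float64)
    if len(r) < 2:
        raise InsufficientDataError("need >= 2 reference beats to form a cycle")
    det = np.sort(np.asarray(ncc_beats.times_s, dtype=np.float64))
    intervals = artifact_intervals or []

    n_cycles = len(r) - 1
    in_range = det[(det >= r[0]) & (det < r[-1])]
    cycle_of = np.searchsorted(r, in_range, side="right") - 1
    peaks_by_cycle: list[np.ndarray] = [
        in_range[cycle_of == i] for i in range(n_cycles)
    ]
    excluded = [
        _cycle_overlaps(r[i], r[i + 1], intervals) for i in range(n_cycles)
    ]

    offsets = [
        peaks_by_cycle[i][0] - r[i]
        for i in range(n_cycles)
        if not excluded[i] and len(peaks_by_cycle[i])
    ]
    if not offsets:
        raise InsufficientDataError("no cycle contains a detected peak")
    expected_offset = float(np.median(offsets))

    tp = fp = fn = de = 0
    labels: list[str] = []
    fp_counts: list[int] = []
    matched: list[tuple[float, float]] = []
    matched_per_cycle: list[float | None] = []
    for i in range(n_cycles):
        if excluded[i]:
            labels.append(EXCLUDED)
            fp_counts.append(0)
            matched_per_cycle.append(None)
            continue
        peaks = peaks_by_cycle[i]
        if len(peaks) == 0:
            fn += 1
            labels.append(FN)
            fp_counts.append(0)
            matched_per_cycle.append(None)
            continue
        target = r[i] + expected_offset
        cand_idx = int(np.argmin(np.abs(peaks - target)))
        cand = float(peaks[cand_idx])
        fp += len(peaks) - 1
        fp_counts.append(len(peaks) - 1)
        if abs(cand - target) <= tolerance_s:
            tp += 1
            labels.append(TP)
            matched.append((float(r[i]), cand))
            matched_per_cycle.append(cand)
        else:
            de += 1
            labels.append(DE)
            matched_per_cycle.append(None)

    return DetectionReport(
        tp=tp,
        fp=fp,
        fn=fn,
        de=de,
        n_reference=n_cycles - sum(excluded),
        cycle_labels=labels,
        fp_per_cycle=fp_counts,
        matched_pairs=matched,
        matched_ncc_per_cycle=matched_per_cycle,
        expected_offset_s=expected_offset,
        tolerance_s=tolerance_s,
    )


def sensitivity(report: DetectionReport) -> float:
    """100 * TP / (TP + FN + DE), in percent."""
    denom = report.tp + report.fn + report.de
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined: no reference cycles")
    return 100.0 * report.tp / denom


def ppv(report: DetectionReport) -> float:
    """100 * TP / (TP + FP + DE), in percent."""
    denom = report.tp + report.fp + report.de
    if denom == 0:
        raise UndefinedMetricError("PPV undefined: no detected peaks")
    return 100.0 * report.tp / denom


def extract_ibi_pairs(
    report: DetectionReport,
    r_peaks: BeatAnnotations,
    ncc_beats: BeatAnnotations,
) -> IbiPairSet:
    """Matched (ECG, SCG) inter-beat intervals from consecutive TP cycles.

    ``ncc_beats`` is accepted for interface symmetry; the matched detection
    times are already recorded per cycle in the report.  Intervals outside
    the (0.25, 3.0) s sanity window are dropped (and logged).
    """
    r = np.asarray(r_peaks.times_s, dtype=np.float64)
    labels = report.cycle_labels
    matched = report.matched_ncc_per_cycle
    if len(labels) != len(r) - 1:
        raise InsufficientDataError("report does not match the reference annotations")
    ecg_ms: list[float] = []
    scg_ms: list[float] = []
    n_dropped = 0
    for i in range(len(labels) - 1):
        if labels[i] == TP and labels[i + 1] == TP:
            e = r[i + 1] - r[i]
            s = matched[i + 1] - matched[i]
            if IBI_MIN_S < e < IBI_MAX_S and IBI_MIN_S < s < IBI_MAX_S:
                ecg_ms.append(e * 1000.0)
                scg_ms.append(s * 1000.0)
            else:
                n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d IBI pairs outside the sanity bounds", n_dropped)
    return IbiPairSet(
        ecg_ibi_ms=np.asarray(ecg_ms), scg_ibi_ms=np.asarray(scg_ms)
    )
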