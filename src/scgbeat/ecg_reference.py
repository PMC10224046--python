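"""Reference R-peak detection (Pan-Tompkins).

Classic stage chain — band-pass (5-15 Hz), five-point derivative, squaring,
150 ms moving-window integration — followed by dual adaptive thresholds with
search-back, a 200 ms refractory period and T-wave rejection for candidates
closer than 360 ms to the previous QRS.  All linear stages are applied with
zero delay (forward-backward filtering / centered kernels) so the integrator
fiducial lands near the R wave; each fiducial is then refined to the local
ECG maximum within +-40 ms.

The first 2 s serve as the learning phase that initializes the signal and
noise levels; the detector therefore requires at least 2 s of input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, LengthError
from .io_records import BeatAnnotations

__all__ = ["RPeakResult", "detect_r_peaks"]

REFRACTORY_S = 0.200
TWAVE_WINDOW_S = 0.360
INTEGRATION_S = 0.150
LEARNING_S = 2.0
REFINE_S = 0.040


@dataclass
class RPeakResult:
    """Detected R-peaks plus the adaptive threshold in force at each one."""

    peaks: BeatAnnotations
    thresholds_trace: np.ndarray
    artifact_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.thresholds_trace = np.asarray(self.thresholds_trace, dtype=np.float64)
        if len(self.thresholds_trace) != len(self.peaks):
            raise ConfigurationError("thresholds_trace must align with peaks")


def _stages(ecg: np.ndarray, fs: float):
    """Return (bandpassed, derivative, moving-window-integrated) signals."""
    sos = signal.butter(2, [5.0, min(15.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg, padtype="odd")
    # five-point derivative, centered (zero group delay)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    sq = deriv**2
    w = max(1, int(round(INTEGRATION_S * fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")
    return bp, deriv, mwi


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    artifact_mask: np.ndarray | None = None,
) -> RPeakResult:
    """Locate R-peaks in a pre-processed single-lead ECG.

    Peaks inside ``artifact_mask`` regions are flagged (not deleted);
    downstream scoring excludes the corresponding cycles.
    """
    if fs < 100:
        raise ConfigurationError(f"fs must be >= 100 Hz, got {fs}")
    ecg = np.asarray(ecg, dtype=np.float64)
    n = len(ecg)
    learn_n = int(LEARNING_S * fs)
    if n < learn_n:
        raise LengthError(f"need >= {LEARNING_S} s of ECG ({learn_n} samples), got {n}")

    _, deriv, mwi = _stages(ecg, fs)
    refractory = max(1, int(round(REFRACTORY_S * fs)))
    cand, _ = signal.find_peaks(mwi, distance=refractory)

    seg = mwi[:learn_n]
    spki = 0.25 * float(seg.max())
    npki = 0.5 * float(seg.mean())
    thr1 = npki + 0.25 * (spki - npki)
    thr2 = 0.5 * thr1

    def slope_around(idx: int) -> float:
        half = int(round(0.075 * fs))
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        return float(np.max(np.abs(deriv[lo:hi]))) if hi > lo else 0.0

    qrs: list[int] = []
    thr_at_qrs: list[float] = []
    rr_recent: list[float] = []

    def accept(idx: int, searchback: bool = False) -> None:
        nonlocal spki, thr1, thr2
        if searchback:
            spki = 0.25 * mwi[idx] + 0.75 * spki
        else:
            spki = 0.125 * mwi[idx] + 0.875 * spki
        if qrs:
            rr_recent.append((idx - qrs[-1]) / fs)
            del rr_recent[:-8]
        # keep the list ordered even when a search-back fills an older gap
        pos = len(qrs)
        while pos > 0 and qrs[pos - 1] > idx:
            pos -= 1
        qrs.insert(pos, idx)
        thr_at_qrs.insert(pos, thr1)
        thr1 = npki + 0.25 * (spki - npki)
        thr2 = 0.5 * thr1

    def reject(idx: int) -> None:
        nonlocal npki, thr1, thr2
        npki = 0.125 * mwi[idx] + 0.875 * npki
        thr1 = npki + 0.25 * (spki - npki)
        thr2 = 0.5 * thr1

    rejected: list[int] = []
    for idx in cand:
        pk = mwi[idx]
        is_qrs = pk > thr1
        if is_qrs and qrs:
            since = (idx - qrs[-1]) / fs
            if since < REFRACTORY_S:
                is_qrs = False
            elif since < TWAVE_WINDOW_S:
                # T-wave discrimination: slope under half of the previous QRS's
                if slope_around(idx) < 0.5 * slope_around(qrs[-1]):
                    is_qrs = False
        if is_qrs:
            accept(idx)
        else:
            reject(idx)
            rejected.append(idx)
        # search-back when a whole expected cycle has elapsed without a QRS
        if qrs and len(rr_recent) >= 2:
            rr_avg = float(np.mean(rr_recent))
            if (idx - qrs[-1]) / fs > 1.66 * rr_avg:
                window = [
                    j
                    for j in rejected
                    if qrs[-1] + refractory < j < idx - refractory and mwi[j] > thr2
                ]
                if window:
                    best = max(window, key=lambda j: mwi[j])
                    accept(best, searchback=True)
                    rejected = [j for j in rejected if j > best]

    # refine each integrator fiducial to the local ECG maximum within +-40 ms
    half = int(round(REFINE_S * fs))
    refined: list[int] = []
    thresholds: list[float] = []
    for idx, thr in zip(qrs, thr_at_qrs):
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        r = lo + int(np.argmax(ecg[lo:hi]))
        if refined and r - refined[-1] < refractory:
            if ecg[r] > ecg[refined[-1]]:
                refined[-1], thresholds[-1] = r, thr
            continue
        refined.append(r)
        thresholds.append(thr)

    times = np.asarray(refined, dtype=np.float64) / fs
    flags = None
    if artifact_mask is not None:
        mask = np.asarray(artifact_mask, dtype=bool)
        flags = np.array([mask[i] for i in refined], dtype=bool)
    return RPeakResult(
        peaks=BeatAnnotations(times, label="R"),
        thresholds_trace=np.asarray(thresholds, dtype=np.float64),
        artifact_flags=flags,
    )
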