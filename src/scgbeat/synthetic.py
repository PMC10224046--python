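"""Synthetic SCG + ECG records with known beat times.

The generator produces the statistical structure the detector assumes: a
quasi-periodic RR series with respiratory sinus-arrhythmia modulation and
Gaussian jitter, an ECG built from beat-locked P/R/T waves, and an SCG in
which every beat is a damped oscillation (the systolic complex) optionally
followed by a weaker, delayed damped oscillation (the diastolic complex).
Both channels share a slow respiratory amplitude modulation and additive
noise at a configured SNR.  Ground-truth R times and systolic-peak times are
returned alongside the record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .io_records import BeatAnnotations, SignalRecord

__all__ = ["SynthConfig", "SyntheticRecord", "generate_record", "truth_ibis"]


@dataclass
class SynthConfig:
    """Parameters of the simulated record.

    ``dia_amp_ratio = 0`` yields beats with no diastolic complex ("case 2"-like
    morphology); ``snr_db = math.inf`` disables additive noise.  With
    ``noise_band`` set, the noise is band-limited to that band instead of
    white, which stresses the matcher inside its own passband.
    """

    duration_s: float = 60.0
    fs: float = 256.0
    mean_hr_bpm: float = 70.0
    rr_jitter_sd_ms: float = 20.0
    resp_rate_hz: float = 0.25
    rsa_depth_ms: float = 25.0
    sys_freq_hz: float = 18.0
    sys_decay_ms: float = 40.0
    sys_delay_ms: float = 30.0
    dia_delay_ms: float = 380.0
    dia_amp_ratio: float = 0.45
    resp_am_depth: float = 0.2
    snr_db: float = 40.0
    seed: int = 0
    noise_band: tuple[float, float] | None = None

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be positive")
        if not self.fs >= 100:
            raise ConfigurationError("fs must be >= 100 Hz")
        if not 20 < self.mean_hr_bpm < 240:
            raise ConfigurationError("mean_hr_bpm must lie in (20, 240)")
        if not 0 <= self.dia_amp_ratio <= 1:
            raise ConfigurationError("dia_amp_ratio must lie in [0, 1]")
        if not 0 <= self.resp_am_depth < 1:
            raise ConfigurationError("resp_am_depth must lie in [0, 1)")
        if self.rr_jitter_sd_ms < 0 or self.rsa_depth_ms < 0:
            raise ConfigurationError("RR modulation amplitudes must be >= 0")


@dataclass
class SyntheticRecord:
    record: SignalRecord
    truth_r: BeatAnnotations
    truth_sys_peak: BeatAnnotations

    def __post_init__(self) -> None:
        if len(self.truth_r) != len(self.truth_sys_peak):
            raise ConfigurationError("truth series must have equal counts")


def _add_gaussian(y: np.ndarray, fs: float, center_s: float, amp: float, sd_s: float) -> None:
    """Add a Gaussian bump in place, evaluated only on a +-5 sd window."""
    n = len(y)
    i0 = max(0, int((center_s - 5 * sd_s) * fs))
    i1 = min(n, int((center_s + 5 * sd_s) * fs) + 1)
    if i0 >= i1:
        return
    t = np.arange(i0, i1) / fs
    y[i0:i1] += amp * np.exp(-0.5 * ((t - center_s) / sd_s) ** 2)


def _add_damped_osc(
    y: np.ndarray, fs: float, onset_s: float, amp: float, freq_hz: float, tau_s: float
) -> None:
    """Add amp * exp(-u/tau) * sin(2 pi f u) for u >= 0, truncated at 1e-3 decay."""
    n = len(y)
    u_max = tau_s * math.log(1000.0)
    i0 = max(0, int(math.ceil(onset_s * fs)))
    i1 = min(n, int((onset_s + u_max) * fs) + 1)
    if i0 >= i1:
        return
    u = np.arange(i0, i1) / fs - onset_s
    y[i0:i1] += amp * np.exp(-u / tau_s) * np.sin(2 * np.pi * freq_hz * u)


def systolic_peak_latency_s(config: SynthConfig) -> float:
    """Time from R to the systolic complex's highest maximum (closed form).

    The first maximum of ``exp(-u/tau) sin(2 pi f u)`` sits at
    ``u* = atan(2 pi f tau) / (2 pi f)``; the latency adds the systole delay.
    """
    w = 2 * np.pi * config.sys_freq_hz
    tau = config.sys_decay_ms / 1000.0
    return config.sys_delay_ms / 1000.0 + math.atan(w * tau) / w


def generate_record(config: SynthConfig) -> SyntheticRecord:
    """Simulate one record; identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = float(config.fs)
    n = int(round(config.duration_s * fs))
    times = np.arange(n) / fs

    # Beat times: RR_i = base + RSA * sin(2 pi f_resp t_i) + jitter
    rr_base_ms = 60000.0 / config.mean_hr_bpm
    beat_times = []
    t = 0.3
    margin = 0.4  # leave room for the last beat's waveform
    while t < config.duration_s - margin:
        beat_times.append(t)
        rr_ms = (
            rr_base_ms
            + config.rsa_depth_ms * math.sin(2 * math.pi * config.resp_rate_hz * t)
            + (rng.normal(0.0, config.rr_jitter_sd_ms) if config.rr_jitter_sd_ms > 0 else 0.0)
        )
        rr_ms = max(rr_ms, 250.0)
        t = t + rr_ms / 1000.0
    beat_times = np.asarray(beat_times)
    if len(beat_times) < 2:
        raise ConfigurationError("duration too short to place at least 2 beats")

    ecg = np.zeros(n)
    scg = np.zeros(n)
    tau = config.sys_decay_ms / 1000.0
    for bt in beat_times:
        _add_gaussian(ecg, fs, bt - 0.18, 0.12, 0.025)  # P
        _add_gaussian(ecg, fs, bt, 1.0, 0.010)  # R
        _add_gaussian(ecg, fs, bt + 0.26, 0.30, 0.050)  # T
        _add_damped_osc(scg, fs, bt + config.sys_delay_ms / 1000.0, 1.0, config.sys_freq_hz, tau)
        if config.dia_amp_ratio > 0:
            _add_damped_osc(
                scg,
                fs,
                bt + config.dia_delay_ms / 1000.0,
                config.dia_amp_ratio,
                config.sys_freq_hz,
                tau,
            )

    am = 1.0 + config.resp_am_depth * np.sin(2 * np.pi * config.resp_rate_hz * times)
    ecg *= am
    scg *= am

    if np.isfinite(config.snr_db):
        for x in (scg, ecg):
            p_clean = float(np.mean(x**2))
            sd = math.sqrt(p_clean / 10 ** (config.snr_db / 10.0))
            noise = rng.normal(0.0, 1.0, n)
            if config.noise_band is not None:
                from .preprocess import FilterSpec, bandpass_zero_phase

                noise = bandpass_zero_phase(
                    noise, fs, FilterSpec("bandpass", 4, *config.noise_band)
                )
                noise /= np.std(noise)
            x += sd * noise

    record = SignalRecord(
        record_id=f"synth-seed{config.seed}", fs=fs, scg=scg, ecg=ecg
    )
    lat = systolic_peak_latency_s(config)
    return SyntheticRecord(
        record=record,
        truth_r=BeatAnnotations(beat_times, label="R"),
        truth_sys_peak=BeatAnnotations(beat_times + lat, label="SYS"),
    )


def truth_ibis(synth: SyntheticRecord) -> np.ndarray:
    """Consecutive R-to-R differences of the ground truth, in milliseconds."""
    if len(synth.truth_r) < 2:
        raise InsufficientDataError("need at least 2 beats for IBIs")
    return np.diff(synth.truth_r.times_s) * 1000.0
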