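"""Record and annotation I/O.

Two-channel records (SCG acceleration + ECG) are normalized into
:class:`SignalRecord` regardless of the on-disk format.  Supported formats:

* CSV with a header row; columns ``scg``, ``ecg`` and optionally ``t``/``time``
  (case-insensitive, comma-separated, ``.`` decimal).
* WFDB record pairs (``<name>.hea`` + ``<name>.dat``).  Only the subset needed
  here is implemented: a single ``.dat`` per record, sample formats 16 and 32,
  interleaved channels.

Beat annotations round-trip through CSV (columns ``time_s,label``) or JSON
(list of ``{"time_s": ..., "label": ...}``).  Timestamps are seconds from
record start; sample index ``i`` maps to time ``i / fs`` (0-based).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, ConfigurationError, FormatError, SamplingError

__all__ = [
    "SignalRecord",
    "BeatAnnotations",
    "read_record_csv",
    "write_record_csv",
    "read_record_wfdb",
    "write_record_wfdb",
    "read_annotations",
    "write_annotations",
    "read_artifact_intervals",
    "write_artifact_intervals",
    "intervals_to_mask",
    "mask_to_intervals",
]

_TIME_NAMES = {"t", "time", "time_s"}


@dataclass
class SignalRecord:
    """Uniformly sampled two-channel record (SCG + ECG).

    ``artifact_mask`` marks motion-artifact regions (``True`` = corrupted);
    it defaults to all-``False``.
    """

    record_id: str
    fs: float
    scg: np.ndarray
    ecg: np.ndarray
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scg = np.asarray(self.scg, dtype=np.float64)
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        if not self.fs > 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        self.fs = float(self.fs)
        if self.scg.ndim != 1 or self.ecg.ndim != 1:
            raise FormatError("scg and ecg must be 1-D sample vectors")
        if len(self.scg) != len(self.ecg):
            raise FormatError(
                f"channel length mismatch: scg={len(self.scg)} ecg={len(self.ecg)}"
            )
        if len(self.scg) < 2:
            raise FormatError("record must contain at least 2 samples")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.scg), dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if len(self.artifact_mask) != len(self.scg):
                raise FormatError("artifact_mask length must equal signal length")

    @property
    def n_samples(self) -> int:
        return len(self.scg)

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class BeatAnnotations:
    """Strictly increasing beat timestamps (seconds) with a common label."""

    times_s: np.ndarray
    label: str = "R"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.times_s.ndim != 1:
            raise FormatError("times_s must be a 1-D vector")
        if len(self.times_s) and self.times_s[0] < 0:
            raise FormatError("annotation times must be non-negative")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise FormatError("annotation times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    """Map canonical names (scg/ecg/time) to actual column names, case-insensitively."""
    out: dict[str, str] = {}
    for col in columns:
        low = col.strip().lower()
        if low == "scg":
            out["scg"] = col
        elif low == "ecg":
            out["ecg"] = col
        elif low in _TIME_NAMES:
            out.setdefault("time", col)
    return out


def read_record_csv(
    path: str | Path,
    fs: float | None = None,
    record_id: str | None = None,
) -> SignalRecord:
    """Read a two-channel record from CSV.

    The sampling frequency is taken from an explicit ``fs`` or derived from a
    uniform time column (relative spacing tolerance 1e-6).  The reader never
    resamples: output length and fs are determined solely by the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = _resolve_columns(list(df.columns))
    for need in ("scg", "ecg"):
        if need not in cols:
            raise FormatError(f"{path}: missing required column '{need}'")
    scg = df[cols["scg"]].to_numpy(dtype=np.float64)
    ecg = df[cols["ecg"]].to_numpy(dtype=np.float64)

    fs_eff = fs
    if "time" in cols:
        t = df[cols["time"]].to_numpy(dtype=np.float64)
        if len(t) < 2:
            raise FormatError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        dt_med = float(np.median(dt))
        if dt_med <= 0 or np.any(np.abs(dt - dt_med) > 1e-6 * abs(dt_med)):
            raise SamplingError(f"{path}: time column is not uniformly sampled")
        fs_file = (len(t) - 1) / (t[-1] - t[0])
        if fs is not None and abs(fs - fs_file) > 1e-6 * fs_file:
            raise ConfigurationError(
                f"{path}: explicit fs={fs} conflicts with time column ({fs_file:.6g} Hz)"
            )
        fs_eff = fs_file
    if fs_eff is None:
        raise ConfigurationError(
            f"{path}: sampling frequency not resolvable (no time column and no fs given)"
        )

    mask = None
    sidecar = path.with_name(path.stem + ".artifacts.csv")
    if sidecar.exists():
        mask = intervals_to_mask(read_artifact_intervals(sidecar), len(scg), fs_eff)
    return SignalRecord(
        record_id=record_id or path.stem,
        fs=float(fs_eff),
        scg=scg,
        ecg=ecg,
        artifact_mask=mask,
    )


def write_record_csv(record: SignalRecord, path: str | Path, include_time: bool = True) -> Path:
    path = Path(path)
    data = {}
    if include_time:
        data["t"] = record.times()
    data["scg"] = record.scg
    data["ecg"] = record.ecg
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    if record.artifact_mask is not None and record.artifact_mask.any():
        write_artifact_intervals(
            mask_to_intervals(record.artifact_mask, record.fs),
            path.with_name(path.stem + ".artifacts.csv"),
        )
    return path


# ---------------------------------------------------------------------------
# Minimal WFDB support (header + single interleaved .dat, formats 16/32).
# The wfdb reference library is not a runtime dependency, so the small subset
# of the format used here is read/written directly.
# ---------------------------------------------------------------------------

_SIG_LINE = re.compile(
    r"^(?P<fname>\S+)\s+(?P<fmt>\d+)\s+"
    r"(?P<gain>[-+0-9.eE]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?"
    r"(?:\s+(?P<rest>.*))?$"
)

_WFDB_DTYPES = {16: np.dtype("<i2"), 32: np.dtype("<i4")}


def write_record_wfdb(record: SignalRecord, path: str | Path) -> Path:
    """Write the record as WFDB ``<name>.hea`` + ``<name>.dat`` (format 32).

    Per-channel gain is chosen so that int32 quantization stays below 1e-9 of
    the channel's full scale.
    """
    path = Path(path)
    name = path.name
    n = record.n_samples
    channels = [("SCG", record.scg), ("ECG", record.ecg)]
    gains, raws = [], []
    for _, x in channels:
        amax = float(np.max(np.abs(x)))
        gain = (2.0**30) / amax if amax > 0 else 1.0
        raw = np.rint(x * gain).astype(np.int64)
        raw = np.clip(raw, -(2**31), 2**31 - 1).astype(np.int32)
        gains.append(gain)
        raws.append(raw)

    lines = [f"{name} {len(channels)} {record.fs!r} {n}"]
    for (desc, _), gain, raw in zip(channels, gains, raws):
        checksum = int(np.sum(raw, dtype=np.int64) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(f"{name}.dat 32 {gain!r}(0)/au 32 0 {int(raw[0])} {checksum} 0 {desc}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")

    interleaved = np.empty(n * len(channels), dtype=np.int32)
    for j, raw in enumerate(raws):
        interleaved[j :: len(channels)] = raw
    path.with_suffix(".dat").write_bytes(interleaved.astype("<i4").tobytes())
    return path


def read_record_wfdb(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
) -> SignalRecord:
    """Read a WFDB record.

    ``channel_map`` assigns channel indices, e.g. ``{"scg": 0, "ecg": 1}``;
    when absent, channels are inferred from signal descriptions containing
    "scg"/"accel" and "ecg".
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: malformed record line")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    if n_sig < 2:
        raise FormatError(f"{hea}: need >= 2 channels, found {n_sig}")
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea}: missing signal specification lines")

    specs = []
    for ln in lines[1 : 1 + n_sig]:
        m = _SIG_LINE.match(ln)
        if not m:
            raise FormatError(f"{hea}: malformed signal line: {ln!r}")
        rest = (m.group("rest") or "").split(None, 5)
        desc = rest[5] if len(rest) >= 6 else ""
        specs.append(
            {
                "fname": m.group("fname"),
                "fmt": int(m.group("fmt")),
                "gain": float(m.group("gain")),
                "baseline": int(m.group("baseline") or 0),
                "desc": desc,
            }
        )
    fnames = {s["fname"] for s in specs}
    if len(fnames) != 1:
        raise FormatError(f"{hea}: multi-file records are not supported")
    fmt = specs[0]["fmt"]
    if any(s["fmt"] != fmt for s in specs) or fmt not in _WFDB_DTYPES:
        raise FormatError(f"{hea}: unsupported sample format(s)")

    dat = path.parent / specs[0]["fname"]
    raw = np.frombuffer(dat.read_bytes(), dtype=_WFDB_DTYPES[fmt])
    raw = raw[: n_samples * n_sig].reshape(n_samples, n_sig)

    if channel_map is None:
        channel_map = {}
        for j, s in enumerate(specs):
            low = s["desc"].lower()
            if "scg" in low or "accel" in low:
                channel_map.setdefault("scg", j)
            elif "ecg" in low or "ekg" in low:
                channel_map.setdefault("ecg", j)
        if set(channel_map) != {"scg", "ecg"}:
            raise ConfigurationError(
                f"{hea}: cannot infer scg/ecg channels from descriptions "
                f"{[s['desc'] for s in specs]}; pass channel_map"
            )
    out = {}
    for key in ("scg", "ecg"):
        j = channel_map[key]
        if not 0 <= j < n_sig:
            raise ConfigurationError(f"channel index {j} out of range for {key}")
        s = specs[j]
        out[key] = (raw[:, j].astype(np.float64) - s["baseline"]) / s["gain"]
    return SignalRecord(record_id=path.name, fs=fs, scg=out["scg"], ecg=out["ecg"])


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def write_annotations(ann: BeatAnnotations, path: str | Path, fmt: str | None = None) -> Path:
    """Write annotations as CSV (``time_s,label``) or JSON.

    Full float precision is preserved so the read-back is exact.
    """
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write("time_s,label\n")
            for t in ann.times_s:
                fh.write(f"{float(t)!r},{ann.label}\n")
    elif fmt == "json":
        payload = [{"time_s": float(t), "label": ann.label} for t in ann.times_s]
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ConfigurationError(f"unknown annotation format: {fmt}")
    return path


def read_annotations(path: str | Path) -> BeatAnnotations:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        times = [row["time_s"] for row in payload]
        labels = {row["label"] for row in payload}
    else:
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise FormatError(f"{path}: missing 'time_s' column")
        times = df["time_s"].to_numpy(dtype=np.float64)
        labels = set(df["label"].astype(str)) if "label" in df.columns else set()
    label = labels.pop() if len(labels) == 1 else "R"
    return BeatAnnotations(times_s=np.asarray(times, dtype=np.float64), label=label)


# ---------------------------------------------------------------------------
# Artifact intervals (sidecar CSV: start_s,end_s)
# ---------------------------------------------------------------------------


def read_artifact_intervals(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    for need in ("start_s", "end_s"):
        if need not in df.columns:
            raise FormatError(f"{path}: missing '{need}' column")
    out = []
    for s, e in zip(df["start_s"], df["end_s"]):
        if e < s:
            raise FormatError(f"{path}: interval end {e} before start {s}")
        out.append((float(s), float(e)))
    return out


def write_artifact_intervals(intervals: list[tuple[float, float]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("start_s,end_s\n")
        for s, e in intervals:
            fh.write(f"{float(s)!r},{float(e)!r}\n")
    return path


def intervals_to_mask(
    intervals: list[tuple[float, float]], n: int, fs: float
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        i0 = max(0, int(np.floor(s * fs)))
        i1 = min(n, int(np.ceil(e * fs)) + 1)
        if i0 >= n or i1 <= 0:
            raise BoundsError(f"artifact interval ({s}, {e}) outside record")
        mask[i0:i1] = True
    return mask


def mask_to_intervals(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2] - 1
    return [(float(s / fs), float(e / fs)) for s, e in zip(starts, ends)]
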