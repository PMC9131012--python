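"""Recording container, file IO, and the filtering/referencing primitives.

The central container is :class:`EEGRecording`: an amplitude matrix
(channels x samples, microvolts) plus sampling rate, channel labels,
optional unit-sphere electrode positions, and a list of half-open sample
intervals marking contiguous artifact-free runs.  All downstream stages
(filtering, Hilbert phases, back-fitting) operate *per segment* so that
nothing is ever computed across an artifact gap.

Supported file dialects: EDF and EEGLAB ``.set`` (read-only, via MNE), and
an internal exchange format -- a ``.npy`` matrix next to a JSON sidecar
with sampling rate, channels, positions and segments -- used for bit-exact
fixtures and pipeline artifacts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal


class FormatError(ValueError):
    """Raised when a file cannot be parsed as a supported EEG format."""


class StructuralError(ValueError):
    """Raised when file pieces disagree (e.g. channel-count mismatch)."""


class ParameterError(ValueError):
    """Raised for out-of-range analysis parameters."""


def _validate_segments(segments: list[tuple[int, int]], n_samples: int) -> list[tuple[int, int]]:
    segs = [(int(a), int(b)) for a, b in segments]
    if not segs:
        raise StructuralError("recording must have at least one segment")
    prev_end = -1
    for a, b in segs:
        if not (0 <= a < b <= n_samples):
            raise StructuralError(f"segment ({a}, {b}) outside [0, {n_samples})")
        if a < prev_end:
            raise StructuralError("segments must be sorted and disjoint")
        prev_end = b
    return segs


@dataclass
class EEGRecording:
    """Multichannel EEG with segment annotations.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels, same order as the rows of ``data``.
    positions : ndarray, shape (n_channels, 3), optional
        Unit-sphere electrode coordinates (needed for the surface
        Laplacian; everything else works without them).
    segments : list of (start, end)
        Half-open sample intervals of artifact-free data, 0-based.
        Defaults to one segment covering the whole recording.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    positions: np.ndarray | None = None
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise StructuralError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise StructuralError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel labels"
            )
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 3):
                raise StructuralError("positions must be (n_channels, 3)")
            norms = np.linalg.norm(self.positions, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise StructuralError("positions must lie on the unit sphere (|r| = 1 within 1e-6)")
        if not self.segments:
            self.segments = [(0, self.data.shape[1])]
        self.segments = _validate_segments(self.segments, self.data.shape[1])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def iter_segments(self):
        """Yield ``(start, end, view)`` for each artifact-free segment."""
        for a, b in self.segments:
            yield a, b, self.data[:, a:b]


# ---------------------------------------------------------------------------
# internal exchange format: <stem>.npy + <stem>.json sidecar


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as ``<stem>.npy`` + ``<stem>.json``; returns the sidecar path."""
    path = Path(path)
    stem = path.with_suffix("")
    np.save(stem.with_suffix(".npy"), rec.data)
    sidecar = {
        "fs": rec.fs,
        "channels": list(rec.channels),
        "positions": None if rec.positions is None else rec.positions.tolist(),
        "segments": [list(s) for s in rec.segments],
    }
    out = stem.with_suffix(".json")
    out.write_text(json.dumps(sidecar))
    return out


def _read_internal(path: Path) -> EEGRecording:
    stem = path.with_suffix("")
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy"))
    pos = sidecar.get("positions")
    return EEGRecording(
        data=data,
        fs=sidecar["fs"],
        channels=sidecar["channels"],
        positions=None if pos is None else np.asarray(pos),
        segments=[tuple(s) for s in sidecar["segments"]],
    )


def _read_mne(path: Path, kind: str) -> EEGRecording:
    import mne

    try:
        if kind == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalize to FormatError
        raise FormatError(f"cannot parse {path} as {kind}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    positions = None
    montage = raw.get_montage()
    if montage is not None:
        pos_map = montage.get_positions()["ch_pos"]
        pts = [pos_map.get(ch) for ch in raw.ch_names]
        if all(p is not None and np.all(np.isfinite(p)) for p in pts):
            pts = np.asarray(pts, dtype=float)
            norms = np.linalg.norm(pts, axis=1)
            if np.all(norms > 0):
                positions = pts / norms[:, None]
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]), channels=list(raw.ch_names),
                        positions=positions)


def read_recording(path: str | Path, format_hint: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF, EEGLAB ``.set``, or the internal format.

    ``format_hint`` may be ``"edf"``, ``"eeglab"`` or ``"internal"``; by
    default the file extension decides.
    """
    path = Path(path)
    if not path.exists() and not path.with_suffix(".json").exists():
        raise FormatError(f"no such file: {path}")
    kind = format_hint
    if kind is None:
        suffix = path.suffix.lower()
        kind = {".edf": "edf", ".set": "eeglab", ".json": "internal", ".npy": "internal"}.get(suffix)
    if kind is None:
        raise FormatError(f"cannot infer format of {path}; pass format_hint")
    if kind == "internal":
        return _read_internal(path)
    if kind in ("edf", "eeglab"):
        return _read_mne(path, kind)
    raise FormatError(f"unknown format hint {kind!r}")


# ---------------------------------------------------------------------------
# minimal EDF writer (16-bit), used to produce round-trip fixtures


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to EDF (one data record per second, 16-bit).

    Quantization limits fidelity to ~16 bits of the physical range; this
    writer exists so EDF round-trip fixtures can be generated in-process.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    spr = fs  # samples per record (1 s records)
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data

    pmins = padded.min(axis=1)
    pmaxs = padded.max(axis=1)
    span = np.where(pmaxs - pmins < 1e-12, 1.0, pmaxs - pmins)
    dmin, dmax = -32768, 32767

    def pad(text: str, n: int) -> bytes:
        return text[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        [pad(ch, 16) for ch in rec.channels],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{v:.6g}", 8) for v in pmins],
        [pad(f"{v:.6g}", 8) for v in pmaxs],
        [pad(str(dmin), 8)] * n_ch,
        [pad(str(dmax), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(col) for col in fields)

    gain = (dmax - dmin) / span
    digital = np.round((padded - pmins[:, None]) * gain[:, None] + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


# ---------------------------------------------------------------------------
# group metadata


def read_group_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited group table (columns: id, group, optional time, score).

    Scores (e.g. FMAL, 0-34) are validated to their range when present;
    ids must be unique per time label.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"id", "group"}
    if not required.issubset(df.columns):
        raise StructuralError(f"group table needs columns {sorted(required)}")
    key = ["id", "time"] if "time" in df.columns else ["id"]
    if df.duplicated(subset=key).any():
        raise StructuralError("recording ids must be unique per time label")
    if "score" in df.columns:
        sc = df["score"].dropna()
        if ((sc < 0) | (sc > 34)).any():
            raise StructuralError("clinical scores must lie in [0, 34]")
    return df


def write_group_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# filtering / referencing primitives


def _band_sos(low_hz: float, high_hz: float, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ParameterError(f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyq}) Hz")
    if low_hz == 0:
        return signal.butter(order, high_hz / nyq, btype="lowpass", output="sos")
    return signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")


def bandpass_zero_phase(rec: EEGRecording, low_hz: float, high_hz: float,
                        order: int = 4) -> EEGRecording:
    """Zero-phase band filter, applied to each artifact-free segment independently.

    A Butterworth filter of the given order is run forward-backward
    (``sosfiltfilt``), which doubles the effective order and cancels the
    phase response. Segment boundaries are unchanged; no sample is ever
    filtered across a boundary.
    """
    sos = _band_sos(low_hz, high_hz, rec.fs, order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    out = rec.data.copy()
    for a, b, seg in rec.iter_segments():
        if b - a <= padlen:
            warnings.warn(f"segment [{a}, {b}) too short to filter; left unchanged")
            continue
        out[:, a:b] = signal.sosfiltfilt(sos, seg, axis=1)
    return replace(rec, data=out)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: per-sample channel mean becomes 0."""
    if rec.n_channels < 2:
        raise ParameterError("average reference needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))
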