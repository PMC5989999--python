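"""EDF input/output, montage referencing, band filtering and segment extraction.

Recordings are held as channels x samples arrays in microvolts.  Quantitative
analysis operates on an average montage (each channel referenced to the mean
scalp activity) and on six standard frequency bands: broadband (0.1-60 Hz),
delta (1-4), theta (4-8), alpha (8-13), beta (13-30) and gamma (30-60 Hz).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "BandSpec",
    "Segment",
    "BANDS",
    "STANDARD_1020_LABELS",
    "read_edf",
    "write_edf",
    "average_reference",
    "bandpass_filter",
    "extract_segments",
]

#: The 19 electrode labels of the International 10-20 system used by default.
STANDARD_1020_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

#: Zero-phase Butterworth order (applied forward-backward, so the effective
#: attenuation is that of a squared order-4 response).
FILTER_ORDER = 4


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with half-open passband edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: {self.low}-{self.high} Hz")


#: Canonical analysis bands, in canonical order.
BANDS = {
    "broadband": BandSpec("broadband", 0.1, 60.0),
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 60.0),
}

BAND_ORDER = tuple(BANDS)


@dataclass
class EEGRecording:
    """Multichannel scalp EEG: channels x samples, microvolts.

    ``reference`` tracks the montage state so that average referencing is
    explicit and cannot silently be applied twice.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = "as_recorded"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """A fixed-duration analysis excerpt of a recording (canonically 10 s)."""

    parent_id: str
    data: np.ndarray
    fs: float
    band: BandSpec | None = None  # None = raw / not band-filtered
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be channels x samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def segment_id(self) -> str:
        return f"{self.parent_id}@{self.offset_s:g}s"


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    All channels must share one sampling rate; mixed-rate files raise rather
    than being silently resampled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    # mne resamples mixed-rate EDF channels on load; reject from the header
    # before loading rather than silently resampling.
    header_rates = _edf_channel_rates(path)
    if len(set(header_rates)) > 1:
        raise ValueError(
            f"channels with mismatched sampling rates in {path.name}: "
            f"{sorted(set(header_rates))}"
        )
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads SI volts
    return EEGRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        reference="as_recorded",
        record_id=path.stem,
    )


def _edf_channel_rates(path: Path) -> list[float]:
    """Per-channel sampling rates straight from the EDF header."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        record_dur = float(hdr[244:252])
        ns = int(hdr[252:256])
        sig = f.read(256 * ns)
    off = 216 * ns  # past labels, transducer, dim, ranges and prefilter
    spr = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
    return [s / record_dur for s in spr]


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a minimal EDF file (16-bit, microvolts).

    Uses one-second data records, so ``fs`` and the duration must both be
    whole numbers of samples per second.  The physical range is symmetric
    around zero and sized to the signal, giving a quantization step of
    ``2*max|x| / 65535`` microvolts.
    """
    path = Path(path)
    data = np.asarray(rec.data, dtype=float)
    n, total = data.shape
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if total % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_records = total // fs
    pmax = float(np.ceil(np.max(np.abs(data)))) + 1.0
    pmin = -pmax
    dmin, dmax = -32768, 32767

    def _field(values, width):
        out = b""
        for v in values:
            s = str(v).encode("ascii")[:width]
            out += s.ljust(width)
        return out

    hdr = b"0".ljust(8)
    hdr += b"X X X X".ljust(80)           # patient id (anonymous)
    hdr += b"Startdate X X X X".ljust(80)  # recording id
    hdr += b"01.01.00" + b"00.00.00"
    hdr += str(256 * (1 + n)).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(n_records).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(n).encode().ljust(4)
    hdr += _field(rec.channel_labels, 16)
    hdr += _field([""] * n, 80)            # transducer
    hdr += _field(["uV"] * n, 8)
    hdr += _field([f"{pmin:g}"] * n, 8)
    hdr += _field([f"{pmax:g}"] * n, 8)
    hdr += _field([dmin] * n, 8)
    hdr += _field([dmax] * n, 8)
    hdr += _field([""] * n, 80)            # prefiltering
    hdr += _field([fs] * n, 8)             # samples per record
    hdr += _field([""] * n, 32)            # reserved

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin) * scale + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_records):
            f.write(np.ascontiguousarray(digital[:, r * fs:(r + 1) * fs]).tobytes())


# ---------------------------------------------------------------------------
# Montage and filtering
# ---------------------------------------------------------------------------

def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference every channel to the mean across all scalp channels.

    Raises if the recording is already average-referenced; re-applying the
    montage must be an explicit decision, not a silent no-op.
    """
    if rec.reference == "average":
        raise ValueError("recording is already average-referenced")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, rec.fs, list(rec.channel_labels),
                        reference="average", record_id=rec.record_id)


def _band_sos(band: BandSpec, fs: float):
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band '{band.name}' upper edge {band.high} Hz >= Nyquist {nyq} Hz"
        )
    return signal.butter(FILTER_ORDER, [band.low, band.high],
                         btype="bandpass", fs=fs, output="sos")


def bandpass_filter(rec: EEGRecording, band: BandSpec) -> EEGRecording:
    """Zero-phase Butterworth band-pass (order 4, forward-backward)."""
    sos = _band_sos(band, rec.fs)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    out = EEGRecording(data, rec.fs, list(rec.channel_labels),
                       reference=rec.reference, record_id=rec.record_id)
    return out


def bandpass_filter_segment(seg: Segment, band: BandSpec) -> Segment:
    """Band-filter a raw segment, tagging it with the band."""
    sos = _band_sos(band, seg.fs)
    data = signal.sosfiltfilt(sos, seg.data, axis=1)
    return Segment(seg.parent_id, data, seg.fs, band=band, offset_s=seg.offset_s)


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def extract_segments(rec: EEGRecording, duration: float = 10.0,
                     count: int = 5, seed: int = 0) -> list[Segment]:
    """Extract ``count`` non-overlapping segments at pseudorandom offsets.

    Mirrors pseudorandom selection of artefact-free epochs from a longer
    recording.  Deterministic given ``seed``.
    """
    if count == 0:
        return []
    seg_len = int(round(duration * rec.fs))
    needed = count * seg_len
    if rec.n_samples < needed:
        raise ValueError(
            f"recording too short: {rec.n_samples} samples < required "
            f"{needed} ({count} x {duration} s at {rec.fs} Hz)"
        )
    rng = np.random.default_rng(seed)
    # Distribute the slack pseudorandomly between consecutive segments.
    slack = rec.n_samples - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=count))
    starts = [int(cuts[i] + i * seg_len) for i in range(count)]
    return [
        Segment(rec.record_id, rec.data[:, s:s + seg_len].copy(), rec.fs,
                band=None, offset_s=s / rec.fs)
        for s in starts
    ]


def write_segment_sidecar(seg: Segment, path: str | Path) -> None:
    """Write the JSON sidecar describing a segment."""
    meta = {
        "parent_id": seg.parent_id,
        "offset_s": seg.offset_s,
        "duration_s": seg.duration,
        "band": seg.band.name if seg.band else None,
    }
    Path(path).write_text(json.dumps(meta, indent=2))
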