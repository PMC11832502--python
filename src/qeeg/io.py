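"""Reading, writing and segmenting multichannel EEG recordings.

Recordings are held as channels × samples arrays in microvolts with a
sampling rate and the 10/20 channel labels. Two on-disk formats are
supported: European Data Format (EDF, read through :mod:`mne`, written by a
small built-in 16-bit writer) and a plain delimited-text dialect that is
trivially inspectable::

    fs=250
    Fp1,Fp2,...,O2
    1.25,-0.33,...,4.1
    ...

Artifact handling is a per-sample boolean mask (``True`` = clean); the
analysis segment is the longest run of consecutive clean samples, trimmed
across a cohort to the common minimum length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

#: The 19 scalp electrodes of the international 10/20 montage used here.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "T3", "T4", "T5", "T6",
    "P3", "P4", "Pz", "O1", "O2",
)

GROUPS = ("TD", "ASD")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected on-disk format."""


@dataclass
class EEGRecording:
    """A multichannel EEG recording in microvolts.

    Parameters
    ----------
    participant_id : str
        Identifier of the participant the recording belongs to.
    group : str or None
        Diagnostic group label, ``"TD"`` or ``"ASD"`` (or ``None`` if unknown).
    fs : float
        Sampling rate in Hz, strictly positive.
    channels : tuple of str
        Ordered, unique channel labels.
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    artifact_mask : ndarray of bool, optional
        Per-sample mask, ``True`` where the signal is clean.
    """

    participant_id: str
    group: str | None
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples array")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("number of labels does not match number of channels")
        if len(set(c.lower() for c in self.channels)) != len(self.channels):
            raise FormatError("duplicate channel labels")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.data.shape[1],):
                raise ValueError("artifact mask length does not match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Segment:
    """A contiguous artifact-free window of a recording.

    Indexing is 0-based and half-open: samples ``[start, start + n_samples)``.
    """

    recording: EEGRecording = field(repr=False)
    start: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.n_samples < 1:
            raise ValueError("segment must have start >= 0 and n_samples >= 1")
        if self.start + self.n_samples > self.recording.n_samples:
            raise ValueError("segment exceeds recording length")
        mask = self.recording.artifact_mask
        if mask is not None and not mask[self.start:self.start + self.n_samples].all():
            raise ValueError("segment window overlaps masked (artifact) samples")

    @property
    def data(self) -> np.ndarray:
        """View of the windowed channels × samples data."""
        return self.recording.data[:, self.start:self.start + self.n_samples]

    @property
    def fs(self) -> float:
        return self.recording.fs


# ---------------------------------------------------------------------------
# montage / segmentation
# ---------------------------------------------------------------------------

def validate_montage(rec: EEGRecording) -> list[str]:
    """Report deviations from the 19-channel 10/20 montage.

    Returns an empty list iff the 19 standard labels are each present exactly
    once (case-insensitive). Otherwise returns human-readable entries of the
    form ``"missing: Pz"`` / ``"extra: EOG"`` / ``"duplicate: Cz"``.
    """
    want = {c.lower(): c for c in MONTAGE_10_20}
    seen: dict[str, int] = {}
    problems: list[str] = []
    for label in rec.channels:
        key = label.lower()
        seen[key] = seen.get(key, 0) + 1
        if key not in want:
            problems.append(f"extra: {label}")
    for key, canonical in want.items():
        if key not in seen:
            problems.append(f"missing: {canonical}")
        elif seen[key] > 1:
            problems.append(f"duplicate: {canonical}")
    return problems


def longest_clean_run(rec: EEGRecording) -> Segment:
    """Longest run of consecutive clean samples; ties go to the earliest start.

    With no artifact mask the whole recording is treated as clean.
    """
    if rec.artifact_mask is None:
        return Segment(rec, 0, rec.n_samples)
    mask = rec.artifact_mask
    if not mask.any():
        raise ValueError("recording has no clean samples")
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2]
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax returns the first maximum: earliest
    return Segment(rec, int(starts[best]), int(lengths[best]))


def trim_to_common_length(segments: list[Segment]) -> list[Segment]:
    """Trim every segment to the cohort-wide minimum length, keeping each
    segment's own first samples. Idempotent."""
    if not segments:
        raise ValueError("no segments to trim")
    n = min(s.n_samples for s in segments)
    return [Segment(s.recording, s.start, n) for s in segments]


# ---------------------------------------------------------------------------
# recording-chain filters
# ---------------------------------------------------------------------------

def apply_recording_filters(rec: EEGRecording) -> EEGRecording:
    """Zero-phase 0.53–50 Hz band-pass plus 45–55 Hz band-stop, per channel.

    Mirrors a typical clinical amplifier chain (0.53 Hz low-frequency cutoff,
    50 Hz high-frequency cutoff, 45–55 Hz mains notch). Both stages are
    6th-order Butterworth filters applied forward–backward, so signal length
    and phase are preserved; the order is chosen so mains-range components
    a decade-fraction above the 50 Hz edge are suppressed below 5 % RMS.
    """
    if rec.fs <= 2 * 55.0:
        raise ValueError(f"sampling rate {rec.fs} Hz too low for 55 Hz band edge")
    sos_bp = butter(6, [0.53, 50.0], btype="bandpass", fs=rec.fs, output="sos")
    sos_notch = butter(6, [45.0, 55.0], btype="bandstop", fs=rec.fs, output="sos")
    y = sosfiltfilt(sos_notch, sosfiltfilt(sos_bp, rec.data, axis=1), axis=1)
    return replace(rec, data=y)


# ---------------------------------------------------------------------------
# delimited-text dialect
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    return "edf" if path.suffix.lower() == ".edf" else "delimited_text"


def read_recording(
    path: str | Path,
    format: str | None = None,
    participant_id: str | None = None,
    group: str | None = None,
) -> EEGRecording:
    """Read a recording from EDF or the delimited-text dialect.

    ``participant_id`` defaults to the file stem; ``group`` is metadata not
    carried by either format and may be supplied by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "edf":
        fs, channels, data = _read_edf(path)
    elif fmt == "delimited_text":
        fs, channels, data = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return EEGRecording(
        participant_id=participant_id or path.stem,
        group=group,
        fs=fs,
        channels=channels,
        data=data,
    )


def _read_delimited(path: Path) -> tuple[float, tuple[str, ...], np.ndarray]:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("fs="):
            raise FormatError(f"{path}: first line must be 'fs=<Hz>', got {first!r}")
        try:
            fs = float(first[3:])
        except ValueError as e:
            raise FormatError(f"{path}: unparseable sampling rate {first!r}") from e
        channels = tuple(c.strip() for c in fh.readline().strip().split(","))
        rows = np.loadtxt(fh, delimiter=",", ndmin=2)
    if rows.shape[1] != len(channels):
        raise FormatError(
            f"{path}: {rows.shape[1]} columns but {len(channels)} channel labels"
        )
    return fs, channels, rows.T.copy()


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write in the delimited-text dialect (header, labels, one row/sample)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"fs={rec.fs:g}\n")
        fh.write(",".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.6f")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> tuple[float, tuple[str, ...], np.ndarray]:
    import mne  # deferred: only needed on the EDF path

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    channels = tuple(raw.ch_names)
    data = raw.get_data() * 1e6  # mne holds volts; we work in microvolts
    return fs, channels, data


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The recording must contain a whole number of seconds of data and an
    integer sampling rate (both hold for the cohorts generated here).
    """
    fs = int(round(rec.fs))
    if fs != rec.fs:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_samples = rec.n_samples
    if n_samples % fs:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = n_samples // fs
    n_sig = len(rec.channels)

    # round the physical range outward so no sample clips
    phys_min = np.floor(rec.data.min(axis=1) * 100) / 100
    phys_max = np.ceil(rec.data.max(axis=1) * 100) / 100
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"field {text!r} exceeds {width} bytes")
        return b.ljust(width)

    header = b"".join([
        f("0", 8),
        f(rec.participant_id[:80], 80),
        f("qeeg synthetic" if rec.group else "qeeg", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(str(256 * (1 + n_sig)), 8),
        f("", 44),
        f(str(n_records), 8),
        f("1", 8),
        f(str(n_sig), 4),
    ])
    per_sig = b"".join([
        b"".join(f(c[:16], 16) for c in rec.channels),
        b"".join(f("", 80) for _ in rec.channels),
        b"".join(f("uV", 8) for _ in rec.channels),
        b"".join(f(f"{lo:.2f}"[:8], 8) for lo in phys_min),
        b"".join(f(f"{hi:.2f}"[:8], 8) for hi in phys_max),
        b"".join(f(str(dig_min), 8) for _ in rec.channels),
        b"".join(f(str(dig_max), 8) for _ in rec.channels),
        b"".join(f("", 80) for _ in rec.channels),
        b"".join(f(str(fs), 8) for _ in rec.channels),
        b"".join(f("", 32) for _ in rec.channels),
    ])

    # physical -> digital, using the header values as written (2-decimal text)
    lo = np.array([float(f"{v:.2f}"[:8]) for v in phys_min])
    hi = np.array([float(f"{v:.2f}"[:8]) for v in phys_max])
    gain = (dig_max - dig_min) / (hi - lo)
    digital = np.rint((rec.data - lo[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())  # per signal sequentially within record


__all__ = [
    "MONTAGE_10_20", "GROUPS", "EEGRecording", "Segment", "FormatError",
    "read_recording", "write_recording", "write_edf", "validate_montage",
    "longest_clean_run", "trim_to_common_length", "apply_recording_filters",
]
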