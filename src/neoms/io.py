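"""Reading and writing multichannel EEG epochs.

Two on-disk formats are supported:

* **EDF** — the clinical interchange format (16-bit quantized).  Reading is
  delegated to :func:`mne.io.read_raw_edf`; writing uses a minimal
  single-record EDF writer.
* **matrix dialect** — a trivially hand-writable plain-text format: first
  line comma-separated channel names, second line the sampling rate in Hz,
  then one row per time sample with one µV value per channel.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: 19-channel 10-20 montage used throughout neonatal scalp EEG studies.
CHANNELS_1020_19 = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "T7", "T8",
    "C3", "C4", "Cz", "P3", "P4", "P7", "P8", "Pz", "O1", "O2",
]


@dataclass
class EEGEpoch:
    """One contiguous multichannel EEG epoch.

    Attributes
    ----------
    data : ndarray, shape (C, T)
        Scalp potentials in µV, one row per channel.
    channels : list of str
        Channel names, ordered as the rows of ``data``.
    fs : float
        Sampling rate in Hz.
    subject_id, state_tag, band_tag : str
        Provenance tags; ``state_tag`` is ``"AS"`` or ``"QS"`` for sleep
        states, ``band_tag`` names the frequency band (``"broad"`` for the
        full 0.15–45 Hz band).
    """

    data: np.ndarray
    channels: list[str]
    fs: float
    subject_id: str = ""
    state_tag: str = ""
    band_tag: str = "broad"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        c, t = self.data.shape
        if c < 2:
            raise ValueError(f"need at least 2 channels, got {c}")
        if t < 2:
            raise ValueError(f"need at least 2 samples, got {t}")
        if len(self.channels) != c:
            raise ValueError("channel-name count does not match data rows")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or infinite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def copy_with(self, **kwargs) -> "EEGEpoch":
        """Return a copy with selected fields replaced (data is copied)."""
        if "data" not in kwargs:
            kwargs["data"] = self.data.copy()
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# matrix dialect
# ---------------------------------------------------------------------------

def write_matrix(epoch: EEGEpoch, path: str | Path) -> None:
    """Write an epoch in the plain-text matrix dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(epoch.channels) + "\n")
        fh.write(f"{epoch.fs:.10g}\n")
        np.savetxt(fh, epoch.data.T, fmt="%.8g", delimiter=",")


def read_matrix(path: str | Path, **tags) -> EEGEpoch:
    """Read an epoch from the matrix dialect; ``tags`` set provenance fields."""
    path = Path(path)
    with path.open() as fh:
        channels = [c.strip() for c in fh.readline().strip().split(",")]
        if len(channels) < 2 or any(not c for c in channels):
            raise ValueError(f"{path}: malformed channel-name header")
        fs_line = fh.readline().strip()
        try:
            fs = float(fs_line)
        except ValueError as exc:
            raise ValueError(f"{path}: missing or invalid sampling rate") from exc
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[1] != len(channels):
        raise ValueError(f"{path}: column count does not match channel header")
    return EEGEpoch(data=data.T, channels=channels, fs=fs, **tags)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(epoch: EEGEpoch, path: str | Path) -> None:
    """Write an epoch as a minimal EDF file (one data record, 16-bit).

    Quantization step per channel is ``(phys_max - phys_min) / 65535``;
    the round trip through :func:`read_edf` is exact to that step.
    """
    path = Path(path)
    data = epoch.data
    c, t = data.shape
    # physical range padded slightly so extreme samples are representable
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmax = np.where(flat, pmax + 1.0, pmax)
    pmin = np.where(flat, pmin - 1.0, pmin)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    record_dur = t / epoch.fs

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join([
        pad("0", 8),
        pad(f"X X X {epoch.subject_id or 'X'}", 80),
        pad(f"Startdate X X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + 256 * c), 8),
        pad("", 44),
        pad("1", 8),                       # number of data records
        pad(f"{record_dur:.6g}", 8),
        pad(str(c), 4),
    ])
    sig = b"".join([
        b"".join(pad(name, 16) for name in epoch.channels),
        b"".join(pad("AgAgCl electrode", 80) for _ in range(c)),
        b"".join(pad("uV", 8) for _ in range(c)),
        b"".join(pad(f"{v:.8g}", 8) for v in pmin),
        b"".join(pad(f"{v:.8g}", 8) for v in pmax),
        b"".join(pad(str(dmin), 8) for _ in range(c)),
        b"".join(pad(str(dmax), 8) for _ in range(c)),
        b"".join(pad("", 80) for _ in range(c)),
        b"".join(pad(str(t), 8) for _ in range(c)),
        b"".join(pad("", 32) for _ in range(c)),
    ])
    with path.open("wb") as fh:
        fh.write(hdr)
        fh.write(sig)
        fh.write(digital.tobytes())       # record: all samples ch1, then ch2, ...


def read_edf(path: str | Path, **tags) -> EEGEpoch:
    """Read an EDF file via MNE; returns potentials in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6           # MNE loads EEG in volts
    return EEGEpoch(data=data, channels=list(raw.ch_names),
                    fs=float(raw.info["sfreq"]), **tags)


def read_epoch(path: str | Path, format: str | None = None, **tags) -> EEGEpoch:
    """Dispatch on ``format`` (``"edf"`` | ``"matrix"``) or the file suffix."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return read_edf(path, **tags)
    if format == "matrix":
        return read_matrix(path, **tags)
    raise ValueError(f"unknown format {format!r}")
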