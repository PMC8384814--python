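"""Preprocessing chain: zero-phase band-pass, down-sampling, common average.

The band-pass is realized as a cascade of separate 7th-order high-pass and
low-pass Butterworth filters, each applied forward and backward
(zero-phase), so the effective magnitude response is the squared one-pass
response.  Filters run as second-order sections: the 7th-order
transfer-function form is numerically ill-conditioned at a 0.15 Hz cutoff
relative to a 100 Hz rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import EEGEpoch


@dataclass(frozen=True)
class FilterSpec:
    """Band edges and order of the zero-phase Butterworth cascade."""

    low_cut: float
    high_cut: float
    order: int = 7
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut < self.high_cut):
            raise ValueError("need 0 <= low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.family != "butterworth":
            raise ValueError("only Butterworth filters are supported")

    def validate_for(self, fs: float) -> None:
        if self.high_cut >= fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz is at or above Nyquist ({fs / 2} Hz)")


#: Broad-band spec of the study pipeline.
BROADBAND = FilterSpec(low_cut=0.15, high_cut=45.0)


def _filtfilt(sos: np.ndarray, data: np.ndarray, fs: float,
              cutoff: float, order: int) -> np.ndarray:
    # reflect-pad enough to let the slowest pole settle: ~3 periods of the
    # cutoff frequency (a 0.15 Hz high-pass needs seconds, not samples),
    # never less than 3x the doubled filter order, clamped to the epoch
    padlen = int(min(data.shape[-1] - 1,
                     max(3 * 2 * order, round(3 * fs / cutoff))))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen,
                              padtype="even")


def bandpass(epoch: EEGEpoch, spec: FilterSpec = BROADBAND) -> EEGEpoch:
    """Apply the high-pass + low-pass forward-backward Butterworth cascade."""
    spec.validate_for(epoch.fs)
    data = epoch.data
    if spec.low_cut > 0:
        sos_hp = signal.butter(spec.order, spec.low_cut, "highpass",
                               fs=epoch.fs, output="sos")
        data = _filtfilt(sos_hp, data, epoch.fs, spec.low_cut, spec.order)
    sos_lp = signal.butter(spec.order, spec.high_cut, "lowpass",
                           fs=epoch.fs, output="sos")
    data = _filtfilt(sos_lp, data, epoch.fs, spec.high_cut, spec.order)
    return epoch.copy_with(data=data)


def butterworth_attenuation(freq: float, cutoff: float, order: int = 7,
                            kind: str = "lowpass") -> float:
    """Closed-form squared (forward-backward) Butterworth power gain at ``freq``.

    Returns ``|H(f)|^2`` for one forward+backward pass, i.e. the analog
    prototype ``1 / (1 + (f/fc)^(2n))`` squared for a low-pass (inverted
    ratio for a high-pass).  Used as the analytic oracle for stop-band
    attenuation tests; the digital (bilinear) response is slightly steeper,
    so the analog value is a conservative bound below half Nyquist.
    """
    ratio = freq / cutoff if kind == "lowpass" else cutoff / freq
    one_pass = 1.0 / (1.0 + ratio ** (2 * order))
    return one_pass ** 2


def resample(epoch: EEGEpoch, target_fs: float) -> EEGEpoch:
    """Polyphase anti-aliased down-sampling to ``target_fs``."""
    if target_fs > epoch.fs:
        raise ValueError("upsampling is not supported by this pipeline")
    if target_fs == epoch.fs:
        return epoch.copy_with()
    frac = Fraction(target_fs / epoch.fs).limit_denominator(1000)
    data = signal.resample_poly(epoch.data, frac.numerator, frac.denominator,
                                axis=-1)
    return epoch.copy_with(data=data, fs=target_fs)


def rereference_common_average(epoch: EEGEpoch) -> EEGEpoch:
    """Subtract the instantaneous mean across channels (common average)."""
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return epoch.copy_with(data=data)


def preprocess(epoch: EEGEpoch, spec: FilterSpec = BROADBAND,
               target_fs: float = 100.0,
               keep_mask: np.ndarray | None = None) -> EEGEpoch:
    """Full chain: band-pass -> down-sample -> common average.

    ``keep_mask`` is an optional boolean per-sample mask at the *target*
    rate marking samples to retain (pre-marked artefact-free segments);
    masked-out samples are dropped after filtering so filter transients do
    not leak across clip boundaries of the retained signal.
    """
    out = rereference_common_average(resample(bandpass(epoch, spec), target_fs))
    if keep_mask is not None:
        keep_mask = np.asarray(keep_mask, dtype=bool)
        if keep_mask.shape != (out.n_samples,):
            raise ValueError("keep_mask length must match the resampled epoch")
        out = out.copy_with(data=out.data[:, keep_mask])
    return out
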