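"""Band filtering and power spectral density for epoched EEG.

The canonical band set follows clinical convention: broadband 0.5-45 Hz and
the five sub-bands delta 0.5-4, theta 4-8, alpha 8-12, beta 12-30 and gamma
30-45 Hz.  Filtering is a 4th-order Butterworth applied forward-backward
(zero phase), so band-limiting does not distort the phase relations that
synchronization measures depend on.  PSDs are Welch estimates with 2-s Hann
windows at 50% overlap (0.5 Hz resolution, matching the lowest band edge),
averaged over epochs within subject and then over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EpochedRecording

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "BROADBAND",
    "bandpass",
    "compute_psd",
    "PSDResult",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band with edges in Hz (0 < f_lo < f_hi)."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: need 0 < f_lo < f_hi")

    def validate_for_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name}: f_hi={self.f_hi} Hz must be below the "
                f"Nyquist frequency {fs / 2} Hz"
            )


BROADBAND = FrequencyBand("broadband", 0.5, 45.0)

CANONICAL_BANDS = {
    b.name: b
    for b in (
        BROADBAND,
        FrequencyBand("delta", 0.5, 4.0),
        FrequencyBand("theta", 4.0, 8.0),
        FrequencyBand("alpha", 8.0, 12.0),
        FrequencyBand("beta", 12.0, 30.0),
        FrequencyBand("gamma", 30.0, 45.0),
    )
}


def bandpass(recording: EpochedRecording, band: FrequencyBand) -> EpochedRecording:
    """Zero-phase 4th-order Butterworth band-pass copy of a recording.

    Forward-backward application (``sosfiltfilt``) squares the magnitude
    response and cancels the phase response; epoch shapes are unchanged.
    """
    band.validate_for_fs(recording.fs)
    sos = signal.butter(
        4, [band.f_lo, band.f_hi], btype="bandpass", fs=recording.fs, output="sos"
    )
    filtered = [signal.sosfiltfilt(sos, e, axis=1) for e in recording.epochs]
    return EpochedRecording(
        recording.subject_id, recording.channel_labels, recording.fs, filtered
    )


@dataclass
class PSDResult:
    """Group-level Welch PSD restricted to an analysis band.

    ``absolute_power`` is the subject-mean of epoch-averaged spectra
    (signal-units^2/Hz, channels x frequencies); ``relative_power`` is each
    subject's spectrum normalized to unit sum over the in-band grid before
    subject averaging, so every channel row sums to 1.
    """

    frequencies: np.ndarray
    absolute_power: np.ndarray
    relative_power: np.ndarray


def compute_psd(
    recordings: list[EpochedRecording],
    band_limits: FrequencyBand = BROADBAND,
    window_seconds: float = 2.0,
) -> PSDResult:
    """Welch PSD averaged over epochs then subjects, inside ``band_limits``.

    All recordings must share the sampling rate and channel count; epochs
    shorter than one window raise ``ValueError``.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    fs = recordings[0].fs
    n_ch = recordings[0].n_channels
    for rec in recordings:
        if rec.fs != fs:
            raise ValueError("recordings must share sampling frequency")
        if rec.n_channels != n_ch:
            raise ValueError("recordings must share channel count")

    nperseg = int(round(window_seconds * fs))
    abs_acc = None
    rel_acc = None
    freqs_band = None
    for rec in recordings:
        if rec.n_samples < nperseg:
            raise ValueError(
                f"epoch length {rec.n_samples} shorter than one PSD window "
                f"({nperseg} samples)"
            )
        per_epoch = []
        for epoch in rec.epochs:
            freqs, pxx = signal.welch(
                epoch, fs=fs, window="hann", nperseg=nperseg,
                noverlap=nperseg // 2, axis=1,
            )
            per_epoch.append(pxx)
        subj_abs = np.mean(per_epoch, axis=0)
        mask = (freqs >= band_limits.f_lo) & (freqs <= band_limits.f_hi)
        freqs_band = freqs[mask]
        subj_abs = subj_abs[:, mask]
        subj_rel = subj_abs / subj_abs.sum(axis=1, keepdims=True)
        abs_acc = subj_abs if abs_acc is None else abs_acc + subj_abs
        rel_acc = subj_rel if rel_acc is None else rel_acc + subj_rel

    n = len(recordings)
    return PSDResult(
        frequencies=freqs_band,
        absolute_power=abs_acc / n,
        relative_power=rel_acc / n,
    )
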