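"""Digital preprocessing: band-pass and notch filtering, SNR arithmetic,
AWGN contamination, and disjoint windowing.

Filtering happens on the whole trial before segmentation, so windows carry
no per-window filter transients.  The band-pass is a 4th-order Butterworth
(20-500 Hz by default) and the power-line notch a second-order IIR notch
(Q = 30), both applied forward-backward for zero phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthio import TrialRecording

__all__ = [
    "WindowSegment",
    "bandpass",
    "notch",
    "preprocess",
    "segment_disjoint",
    "snr_db",
    "add_awgn",
]


@dataclass(frozen=True)
class WindowSegment:
    """One disjoint analysis window (all channels) with provenance."""

    samples: np.ndarray  # (window_len, n_channels)
    window_ms: float
    movement: str
    trial_index: int
    window_index: int
    subject_id: str = "synthetic"

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def _bandpass_sos(low_hz: float, high_hz: float, fs: float, order: int = 4):
    if not (0 < low_hz < high_hz):
        raise ValueError(f"invalid band ({low_hz}, {high_hz})")
    if high_hz >= fs / 2:
        raise ValueError(f"high edge {high_hz} Hz >= Nyquist {fs / 2} Hz")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: TrialRecording, low_hz: float = 20.0, high_hz: float = 500.0,
             order: int = 4) -> TrialRecording:
    """Zero-phase Butterworth band-pass, per channel."""
    sos = _bandpass_sos(low_hz, high_hz, rec.fs, order)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=0)
    return rec.with_samples(filtered)


def notch(rec: TrialRecording, f0_hz: float = 50.0, q: float = 30.0) -> TrialRecording:
    """Zero-phase second-order IIR notch at ``f0_hz`` (power-line removal)."""
    if not (0 < f0_hz < rec.fs / 2):
        raise ValueError(f"notch frequency {f0_hz} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(f0_hz, q, fs=rec.fs)
    filtered = signal.filtfilt(b, a, rec.samples, axis=0)
    return rec.with_samples(filtered)


def preprocess(rec: TrialRecording, low_hz: float = 20.0, high_hz: float = 500.0,
               notch_hz: float | None = 50.0) -> TrialRecording:
    """Standard front end: band-pass then notch."""
    out = bandpass(rec, low_hz, high_hz)
    if notch_hz is not None:
        out = notch(out, notch_hz)
    return out


def segment_disjoint(rec: TrialRecording, window_ms: float) -> list[WindowSegment]:
    """Split a trial into contiguous non-overlapping windows from sample 0.

    Returns ``floor(n_samples / window_len)`` windows; the trailing remainder
    is discarded.  A 5 s trial at 2000 Hz with 250 ms windows yields exactly
    20 windows of 500 samples.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    window_len = round(window_ms / 1000.0 * rec.fs)
    if window_len > rec.n_samples:
        raise ValueError(
            f"window of {window_len} samples longer than trial ({rec.n_samples})"
        )
    n_windows = rec.n_samples // window_len
    return [
        WindowSegment(
            samples=rec.samples[i * window_len:(i + 1) * window_len],
            window_ms=window_ms,
            movement=rec.movement,
            trial_index=rec.trial_index,
            window_index=i,
            subject_id=rec.subject_id,
        )
        for i in range(n_windows)
    ]


def snr_db(raw_rms: float, noise_rms: float) -> float:
    """Signal-to-noise ratio in dB, removing the noise power from the raw
    measurement: ``20·log10(sqrt(raw_rms² − noise_rms²) / noise_rms)``."""
    if noise_rms <= 0:
        raise ValueError("noise_rms must be positive")
    if raw_rms <= noise_rms:
        raise ValueError(
            f"raw RMS ({raw_rms}) must exceed noise RMS ({noise_rms}): "
            "no real signal component"
        )
    return 20.0 * np.log10(np.sqrt(raw_rms**2 - noise_rms**2) / noise_rms)


def add_awgn(rec: TrialRecording, snr_db: float, seed: int) -> TrialRecording:
    """Contaminate a trial with white Gaussian noise at a requested SNR.

    Noise power per channel is the channel's *measured* mean-square power
    divided by ``10^(snr_db/10)`` — the semantics of MATLAB
    ``awgn(x, snr, 'measured')``.  Deterministic for a fixed seed.
    """
    power = np.mean(rec.samples**2, axis=0)
    if np.any(power <= 0):
        raise ValueError("add_awgn requires nonzero signal power on every channel")
    noise_rms = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, abs(hash(rec.movement)) % (2**31), rec.trial_index])
    )
    noise = rng.standard_normal(rec.samples.shape) * noise_rms[None, :]
    return rec.with_samples(rec.samples + noise)
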