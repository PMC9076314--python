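"""Synthetic surface-EMG dataset generation and per-trial file I/O.

Emulates a two-channel, ten-movement, six-trial finger-movement protocol:
each trial is five seconds of band-limited (20-500 Hz) activity at 2000 Hz,
amplitude-coded per movement and per channel, plus additive white Gaussian
noise.  Amplitude is the dominant class-discriminating property, matching
what is visually observable in steady-state surface EMG; two movements are
deliberately weak (near the noise floor) to exercise features designed for
low-amplitude discrimination.

Real recordings stored as delimited text (one row per sample, one column
per channel) can be ingested through :func:`read_trial` / :func:`read_dataset`
with a JSON/YAML metadata sidecar per trial.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "TrialRecording",
    "SynthConfig",
    "DEFAULT_MOVEMENTS",
    "DEFAULT_AMPLITUDES",
    "generate_dataset",
    "generate_trial",
    "write_trial",
    "read_trial",
    "write_dataset",
    "read_dataset",
]

#: Ten finger movements: five individual (Thumb, Index, Middle, Ring, Little),
#: four thumb-combined, and hand close.
DEFAULT_MOVEMENTS: tuple[str, ...] = (
    "T", "I", "M", "R", "L", "TI", "TM", "TR", "TL", "HC",
)

#: Per-movement (channel-1, channel-2) RMS amplitudes, normalized units.
#: Chosen so that, with the default noise RMS of 0.03, per-channel SNRs span
#: roughly 2-23 dB; movements T and I sit near the noise floor ("weak").
DEFAULT_AMPLITUDES: Mapping[str, tuple[float, ...]] = {
    "T": (0.05, 0.04),
    "I": (0.04, 0.06),
    "M": (0.09, 0.06),
    "R": (0.07, 0.10),
    "L": (0.13, 0.08),
    "TI": (0.16, 0.12),
    "TM": (0.20, 0.15),
    "TR": (0.25, 0.19),
    "TL": (0.31, 0.24),
    "HC": (0.40, 0.30),
}


@dataclass(frozen=True)
class TrialRecording:
    """One labelled contraction trial.

    Attributes
    ----------
    samples
        Signal matrix, shape ``(n_samples, n_channels)``, volts or
        normalized units.
    fs
        Sampling rate in Hz.
    movement
        Movement label, one of the dataset's declared movement set.
    trial_index
        1-based repetition index of this movement.
    subject_id
        Subject identifier.
    """

    samples: np.ndarray
    fs: float
    movement: str
    trial_index: int = 1
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        if samples.ndim != 2:
            raise ValueError("samples must be a (n_samples, n_channels) matrix")
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "TrialRecording":
        """Copy of this trial with the signal matrix replaced."""
        return replace(self, samples=samples)


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration for one synthetic subject.

    ``amplitudes`` maps each movement to one nonnegative RMS amplitude per
    channel; the noiseless channel RMS equals that amplitude (the carrier is
    normalized to unit RMS before scaling).  ``noise_rms`` is the RMS of the
    white Gaussian noise added on top.
    """

    n_channels: int = 2
    movements: tuple[str, ...] = DEFAULT_MOVEMENTS
    n_trials: int = 6
    duration_s: float = 5.0
    fs: float = 2000.0
    amplitudes: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    band: tuple[float, float] = (20.0, 500.0)
    noise_rms: float = 0.03
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 <= low < high):
            raise ValueError(f"invalid band {self.band}: need 0 <= low < high")
        if high >= self.fs / 2:
            raise ValueError(
                f"band upper edge {high} Hz must be below Nyquist {self.fs / 2} Hz"
            )
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be nonnegative")
        for mov in self.movements:
            if mov not in self.amplitudes:
                raise ValueError(f"movement {mov!r} has no amplitude entry")
            amps = self.amplitudes[mov]
            if len(amps) != self.n_channels:
                raise ValueError(
                    f"movement {mov!r} needs {self.n_channels} amplitudes, got {len(amps)}"
                )
            if any(a < 0 for a in amps):
                raise ValueError(f"movement {mov!r} has a negative amplitude")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.fs)


def _carrier(rng: np.random.Generator, n: int, fs: float,
             band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian carrier, normalized to unit empirical RMS."""
    from .preprocess import _bandpass_sos  # same design as the analysis filter
    from scipy.signal import sosfiltfilt

    white = rng.standard_normal(n)
    sos = _bandpass_sos(band[0], band[1], fs)
    x = sosfiltfilt(sos, white)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0:
        x = x / rms
    return x


def generate_trial(config: SynthConfig, movement: str, trial_index: int) -> TrialRecording:
    """Generate a single trial; its random stream depends only on
    (config.seed, movement position, trial_index), so regenerating one trial
    never perturbs the others."""
    m_idx = config.movements.index(movement)
    n = config.n_samples
    amps = config.amplitudes[movement]
    channels = []
    for ch in range(config.n_channels):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, m_idx, trial_index, ch])
        )
        sig = amps[ch] * _carrier(rng, n, config.fs, config.band)
        if config.noise_rms > 0:
            sig = sig + config.noise_rms * rng.standard_normal(n)
        channels.append(sig)
    return TrialRecording(
        samples=np.column_stack(channels),
        fs=config.fs,
        movement=movement,
        trial_index=trial_index,
        subject_id=config.subject_id,
    )


def generate_dataset(config: SynthConfig) -> list[TrialRecording]:
    """Generate the full ``n_movements x n_trials`` synthetic dataset.

    Every (movement, trial_index) pair appears exactly once; the result is
    deterministic for a fixed ``config`` (including its seed).
    """
    return [
        generate_trial(config, movement, trial)
        for movement in config.movements
        for trial in range(1, config.n_trials + 1)
    ]


# ---------------------------------------------------------------------------
# per-trial text I/O
# ---------------------------------------------------------------------------

_DELIMS = (",", "\t", None)  # None = any whitespace


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trial(rec: TrialRecording, path: str | Path) -> Path:
    """Write one trial as headerless CSV (rows = samples, cols = channels)
    plus a JSON metadata sidecar carrying fs/movement/trial/subject."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.samples, delimiter=",", fmt="%.10g")
    meta = {
        "fs": rec.fs,
        "movement": rec.movement,
        "trial_index": rec.trial_index,
        "subject_id": rec.subject_id,
        "n_channels": rec.n_channels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


class TrialParseError(ValueError):
    """Malformed per-trial signal file (names the offending line)."""


def _parse_rows(text: str, path: Path, n_channels: int | None) -> np.ndarray:
    rows: list[list[float]] = []
    width: int | None = n_channels
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for delim in _DELIMS:
            parts = [p for p in re.split(r"\s+" if delim is None else re.escape(delim), line) if p]
            if len(parts) > 1 or delim is _DELIMS[-1]:
                break
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise TrialParseError(f"{path}: non-numeric cell on line {lineno}") from exc
        if width is None:
            width = len(values)
        if len(values) != width:
            raise TrialParseError(
                f"{path}: line {lineno} has {len(values)} columns, expected {width}"
            )
        rows.append(values)
    if not rows:
        raise TrialParseError(f"{path}: no sample rows found")
    return np.asarray(rows, dtype=float)


def read_trial(
    path: str | Path,
    fs: float | None = None,
    movement: str | None = None,
    trial_index: int | None = None,
    subject_id: str | None = None,
    n_channels: int | None = None,
) -> TrialRecording:
    """Read a delimited-text trial (comma, tab or whitespace separated).

    Metadata comes from the ``<file>.meta.json`` / ``.meta.yaml`` sidecar when
    present; explicit arguments override the sidecar.  A declared
    ``n_channels`` that contradicts the file raises :class:`TrialParseError`.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        yml = path.with_suffix(path.suffix + ".meta.yaml")
        if yml.exists():
            meta = yaml.safe_load(yml.read_text()) or {}
    samples = _parse_rows(path.read_text(), path, n_channels)
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError(f"{path}: sampling rate not given and no sidecar found")
    return TrialRecording(
        samples=samples,
        fs=float(fs),
        movement=movement if movement is not None else meta.get("movement", "unknown"),
        trial_index=int(trial_index if trial_index is not None else meta.get("trial_index", 1)),
        subject_id=subject_id if subject_id is not None else meta.get("subject_id", "unknown"),
    )


def write_dataset(recordings: Sequence[TrialRecording], out_dir: str | Path) -> list[Path]:
    """Write a dataset under ``out_dir/<subject>/<movement>_<trial>.csv``."""
    paths = []
    for rec in recordings:
        p = Path(out_dir) / rec.subject_id / f"{rec.movement}_{rec.trial_index}.csv"
        paths.append(write_trial(rec, p))
    return paths


def read_dataset(in_dir: str | Path) -> list[TrialRecording]:
    """Read every ``*.csv`` trial below ``in_dir`` (sidecars supply metadata)."""
    in_dir = Path(in_dir)
    recs = [read_trial(p) for p in sorted(in_dir.rglob("*.csv"))]
    if not recs:
        raise FileNotFoundError(f"no trial files found under {in_dir}")
    return recs
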