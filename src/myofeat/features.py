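"""Time-domain EMG feature registry.

The two nonlinear scaling features are the centrepiece:

* **LMAV** — the natural log of a window's mean absolute value,
  ``ln((1/N)·Σ|x_i|)``.  The log compresses dynamic range, so equal *ratios*
  of contraction amplitude map to equal feature differences: weak
  contractions become as discriminable as strong ones.
* **NSV** — the nonlinear scaled value, ``ln((1/N)·Σ ((x̄ − x_i)^{1/3})²)``
  with ``x̄`` the window's mean absolute value and a real signed cube root,
  so each term equals ``|x̄ − x_i|^{2/3}``.  It measures the nonlinearly
  scaled deviation of each sample from the window's rectified mean,
  again emphasising low-amplitude structure.

Around them sits the classical time-domain inventory (MAV, IEMG, RMS, VAR,
WL, ZC, SSC, WAMP, MYOP, log detector, DAMV, DASDV, skewness, Hjorth
mobility/complexity, maximum fractal length, AR coefficients) plus the
spectral-moment descriptor sets estimated in the time domain (TD-PSD, TSD),
organised into the named feature sets FS1-FS4 and PROPOSED.

All features operate on a single-channel window; :func:`extract` applies a
:class:`FeatureSetSpec` per channel and concatenates, producing a
:class:`FeatureMatrix` whose rows are windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz

from .preprocess import WindowSegment

__all__ = [
    "EPS",
    "lmav",
    "nsv",
    "mav", "iemg", "rms", "var", "wl", "zc", "ssc", "wamp", "myop",
    "log_detector", "damv", "dasdv", "skw", "mob", "com", "mfl", "ssi", "kurt",
    "ar_coeffs", "tdpsd_features", "tsd_features",
    "FeatureSetSpec", "FeatureMatrix", "FEATURE_SETS", "feature_set",
    "compute_feature", "extract", "SCALAR_FEATURES",
]

#: Zero-guard applied inside every logarithm so that all-zero or constant
#: windows still yield finite features (keeps downstream ULDA well-posed).
EPS = 1e-12


def _x(window: np.ndarray, min_n: int, name: str) -> np.ndarray:
    x = np.asarray(window, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"{name}: window of {x.size} samples too short (need >= {min_n})")
    return x


# ---------------------------------------------------------------------------
# proposed nonlinear features
# ---------------------------------------------------------------------------

def lmav(window: np.ndarray) -> float:
    """Log of the mean absolute value: ``ln(max(ε, mean|x|))``."""
    x = _x(window, 1, "lmav")
    return float(np.log(max(EPS, np.mean(np.abs(x)))))


def nsv(window: np.ndarray, inner_square: bool = False) -> float:
    """Nonlinear scaled value.

    Default reading: ``ln(mean(((x̄ − x_i)^{1/3})²)) = ln(mean |x̄ − x_i|^{2/3})``
    with ``x̄ = mean|x|``.  ``inner_square=True`` selects the alternative
    bracketing ``ln(mean((x̄ − x_i)²)^{1/3}·…)``, i.e. the square taken
    inside the cube root: ``ln(mean ((x̄ − x_i)²)^{1/3})``.
    """
    x = _x(window, 1, "nsv")
    xbar = np.mean(np.abs(x))
    dev = xbar - x
    if inner_square:
        terms = np.cbrt(dev**2)
    else:
        terms = np.cbrt(dev) ** 2
    return float(np.log(max(EPS, np.mean(terms))))


# ---------------------------------------------------------------------------
# classical time-domain features
# ---------------------------------------------------------------------------

def mav(window: np.ndarray) -> float:
    """Mean absolute value."""
    return float(np.mean(np.abs(_x(window, 1, "mav"))))


def iemg(window: np.ndarray) -> float:
    """Integrated EMG: sum of absolute values."""
    return float(np.sum(np.abs(_x(window, 1, "iemg"))))


def rms(window: np.ndarray) -> float:
    """Root mean square."""
    x = _x(window, 1, "rms")
    return float(np.sqrt(np.mean(x**2)))


def var(window: np.ndarray) -> float:
    """Sample variance (N−1 denominator)."""
    x = _x(window, 2, "var")
    return float(np.var(x, ddof=1))


def ssi(window: np.ndarray) -> float:
    """Simple square integral: sum of squared values."""
    return float(np.sum(_x(window, 1, "ssi") ** 2))


def wl(window: np.ndarray) -> float:
    """Waveform length: cumulative absolute first difference."""
    x = _x(window, 2, "wl")
    return float(np.sum(np.abs(np.diff(x))))


def zc(window: np.ndarray, thr: float = 0.0) -> float:
    """Zero crossings: sign changes whose jump ``|x_{i+1} − x_i|`` >= thr."""
    x = _x(window, 2, "zc")
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(np.diff(x)) >= thr
    return float(np.count_nonzero(sign_change & big_enough))


def ssc(window: np.ndarray, thr: float = 0.0) -> float:
    """Slope-sign changes: interior samples where
    ``(x_i − x_{i−1})·(x_i − x_{i+1}) > thr``."""
    x = _x(window, 3, "ssc")
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return float(np.count_nonzero(prod > thr))


def wamp(window: np.ndarray, thr: float = 0.01) -> float:
    """Wilson amplitude: first differences with magnitude >= thr."""
    x = _x(window, 2, "wamp")
    return float(np.count_nonzero(np.abs(np.diff(x)) >= thr))


def myop(window: np.ndarray, thr: float = 0.016) -> float:
    """Myopulse percentage rate: fraction of samples with ``|x_i| >= thr``."""
    x = _x(window, 1, "myop")
    return float(np.mean(np.abs(x) >= thr))


def log_detector(window: np.ndarray) -> float:
    """Log detector: ``exp(mean(ln|x_i|))`` (geometric mean amplitude)."""
    x = _x(window, 1, "log_detector")
    return float(np.exp(np.mean(np.log(np.maximum(EPS, np.abs(x))))))


def damv(window: np.ndarray) -> float:
    """Difference absolute mean value: mean |Δx|."""
    x = _x(window, 2, "damv")
    return float(np.mean(np.abs(np.diff(x))))


def dasdv(window: np.ndarray) -> float:
    """Difference absolute standard deviation value: ``sqrt(mean(Δx²))``."""
    x = _x(window, 2, "dasdv")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def skw(window: np.ndarray) -> float:
    """Central-moment skewness ``m3 / m2^{3/2}``; 0 for degenerate windows."""
    x = _x(window, 2, "skw")
    c = x - np.mean(x)
    m2 = np.mean(c**2)
    if m2 <= EPS**2:
        return 0.0
    return float(np.mean(c**3) / m2**1.5)


def kurt(window: np.ndarray) -> float:
    """Central-moment kurtosis ``m4 / m2²``; 0 for degenerate windows."""
    x = _x(window, 2, "kurt")
    c = x - np.mean(x)
    m2 = np.mean(c**2)
    if m2 <= EPS**2:
        return 0.0
    return float(np.mean(c**4) / m2**2)


def mob(window: np.ndarray) -> float:
    """Hjorth mobility: ``sqrt(var(Δx) / var(x))`` — a time-domain proxy for
    mean frequency.  0 for constant windows."""
    x = _x(window, 3, "mob")
    v = np.var(x)
    if v <= EPS**2:
        return 0.0
    return float(np.sqrt(np.var(np.diff(x)) / v))


def com(window: np.ndarray) -> float:
    """Hjorth complexity: mobility of the first difference over mobility of
    the signal — tracks change in frequency content.  0 when degenerate."""
    x = _x(window, 4, "com")
    m_sig = mob(x)
    if m_sig == 0.0:
        return 0.0
    return float(mob(np.diff(x)) / m_sig)


def mfl(window: np.ndarray) -> float:
    """Maximum fractal length: ``log10(sqrt(Σ(Δx)²))`` with zero guard."""
    x = _x(window, 2, "mfl")
    return float(np.log10(max(EPS, np.sqrt(np.sum(np.diff(x) ** 2)))))


def ar_coeffs(window: np.ndarray, order: int = 4) -> np.ndarray:
    """Autoregressive coefficients by Yule-Walker.

    Sign convention: coefficients ``a_k`` of the linear prediction
    ``x_i ≈ Σ_k a_k · x_{i−k}``, so an AR(1) process with parameter 0.8
    yields ``a_1 ≈ 0.8``.  Degenerate (zero-variance) windows yield zeros.
    """
    x = _x(window, order + 1, f"ar_coeffs(order={order})")
    x = x - np.mean(x)
    n = x.size
    # biased autocorrelation estimates r_0 .. r_order
    r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(order + 1)])
    if r[0] <= EPS**2:
        return np.zeros(order)
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return np.zeros(order)
    return np.asarray(a, dtype=float)


# ---------------------------------------------------------------------------
# spectral-moment descriptors estimated in the time domain
# ---------------------------------------------------------------------------

#: Power-transform exponent applied to the root-squared spectral moments
#: before log compression (range normalisation of the moment magnitudes).
MOMENT_POWER = 0.1


def _log_moments(x: np.ndarray) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Power-transformed root-squared moments m0, m2, m4 from successive
    differences, plus the differences themselves."""
    d1 = np.diff(x)
    d2 = np.diff(d1)
    lam = MOMENT_POWER
    m0 = max(EPS, np.sqrt(np.sum(x**2))) ** lam / lam
    m2 = max(EPS, np.sqrt(np.sum(d1**2))) ** lam / lam
    m4 = max(EPS, np.sqrt(np.sum(d2**2))) ** lam / lam
    return m0, m2, m4, d1, d2


def tdpsd_features(window: np.ndarray) -> np.ndarray:
    """Six time-dependent power-spectrum descriptors.

    From the time-domain moment estimates (m0 from Σx², m2 from Σ(Δx)²,
    m4 from Σ(Δ²x)², each root-squared then power-transformed):
    [log m0, log(m0−m2), log(m0−m4), log sparseness, log irregularity
    factor, log waveform-length ratio].  The irregularity factor
    ``m2/sqrt(m0·m4)`` equals 1 in the narrowband (single-line) limit.
    """
    x = _x(window, 3, "tdpsd")
    m0, m2, m4, d1, d2 = _log_moments(x)
    sparseness = m0 / max(EPS, np.sqrt(abs((m0 - m2) * (m0 - m4))))
    irregularity = m2 / max(EPS, np.sqrt(m0 * m4))
    wl_ratio = np.sum(np.abs(d1)) / max(EPS, np.sum(np.abs(d2)))
    raw = np.array([m0, m0 - m2, m0 - m4, sparseness, irregularity, wl_ratio])
    return np.log(np.maximum(EPS, np.abs(raw)))


def tsd_features(window: np.ndarray) -> np.ndarray:
    """Seven temporal-spatial descriptors for one channel.

    The first five coincide with the TD-PSD moments/irregularity/sparseness;
    the last two are the coefficient of variation (sample SD over mean
    absolute value) and the summed Teager-Kaiser energy, both
    log-compressed.
    """
    x = _x(window, 3, "tsd")
    m0, m2, m4, d1, d2 = _log_moments(x)
    sparseness = m0 / max(EPS, np.sqrt(abs((m0 - m2) * (m0 - m4))))
    irregularity = m2 / max(EPS, np.sqrt(m0 * m4))
    cov = np.std(x, ddof=1) / max(EPS, np.mean(np.abs(x)))
    tkeo = np.sum(x[1:-1] ** 2 - x[:-2] * x[2:])
    raw = np.array([m0, m0 - m2, m0 - m4, sparseness, irregularity, cov, tkeo])
    return np.log(np.maximum(EPS, np.abs(raw)))


# ---------------------------------------------------------------------------
# registry and named feature sets
# ---------------------------------------------------------------------------

#: Scalar feature name -> callable(window, **params).
SCALAR_FEATURES: dict[str, Callable[..., float]] = {
    "LMAV": lmav,
    "NSV": nsv,
    "MAV": mav,
    "IEMG": iemg,
    "RMS": rms,
    "VAR": var,
    "SSI": ssi,
    "WL": wl,
    "ZC": zc,
    "SSC": ssc,
    "WAMP": wamp,
    "MYOP": myop,
    "LOGDET": log_detector,
    "DAMV": damv,
    "DASDV": dasdv,
    "SKW": skw,
    "KURT": kurt,
    "MOB": mob,
    "COM": com,
    "MFL": mfl,
}

_TDPSD_NAMES = ["TDPSD_M0", "TDPSD_M0M2", "TDPSD_M0M4",
                "TDPSD_SPARSE", "TDPSD_IRF", "TDPSD_WLR"]
_TSD_NAMES = ["TSD_M0", "TSD_M0M2", "TSD_M0M4",
              "TSD_SPARSE", "TSD_IRF", "TSD_COV", "TSD_TKEO"]

_THRESHOLD_PARAM = {"ZC": "thr", "SSC": "thr", "WAMP": "thr", "MYOP": "thr"}


@dataclass(frozen=True)
class FeatureSetSpec:
    """An ordered, parameterised list of per-channel features.

    ``features`` holds registry names; ``AR1``..``AR6`` denote individual
    autoregressive coefficients (estimated jointly at ``ar_order``),
    ``TDPSD_*`` / ``TSD_*`` the grouped spectral-moment descriptors.
    Thresholds for ZC/SSC/WAMP/MYOP live in ``params`` keyed
    ``"<FEATURE>.thr"``.
    """

    name: str
    features: tuple[str, ...]
    ar_order: int = 4
    params: dict = field(default_factory=dict)
    nsv_inner_square: bool = False

    @property
    def n_per_channel(self) -> int:
        return len(self.features)

    def with_extra(self, extra: Sequence[str], name: str | None = None) -> "FeatureSetSpec":
        """Copy with additional features appended (duplicates dropped)."""
        new = tuple(self.features) + tuple(f for f in extra if f not in self.features)
        return replace(self, name=name or f"{self.name}+{'+'.join(extra)}", features=new)


def _ar_names(order: int) -> list[str]:
    return [f"AR{k}" for k in range(1, order + 1)]


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    # six AR coefficients + RMS
    "FS1": FeatureSetSpec("FS1", tuple(_ar_names(6)) + ("RMS",), ar_order=6),
    # Hudgins-style energy/complexity set
    "FS2": FeatureSetSpec("FS2", ("IEMG", "WL", "WAMP", "ZC", "SSC", "VAR")),
    # time-dependent power spectrum descriptors
    "FS3": FeatureSetSpec("FS3", tuple(_TDPSD_NAMES)),
    # temporal-spatial descriptors
    "FS4": FeatureSetSpec("FS4", tuple(_TSD_NAMES)),
    # the proposed 13-feature set: LMAV + NSV + 11 classical features
    "PROPOSED": FeatureSetSpec(
        "PROPOSED",
        ("LMAV", "NSV", "WL", "WAMP", "SSC", "ZC", "MOB", "COM", "SKW")
        + tuple(_ar_names(4)),
        ar_order=4,
    ),
    # the proposed set minus its two nonlinear features (11 classical ones)
    "PROPOSED11": FeatureSetSpec(
        "PROPOSED11",
        ("WL", "WAMP", "SSC", "ZC", "MOB", "COM", "SKW") + tuple(_ar_names(4)),
        ar_order=4,
    ),
}


def feature_set(name: str) -> FeatureSetSpec:
    """Look up a named feature set (case-insensitive)."""
    try:
        return FEATURE_SETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown feature set {name!r}; known: {sorted(FEATURE_SETS)}"
        ) from None


def compute_feature(name: str, window: np.ndarray, spec: FeatureSetSpec) -> float:
    """Compute a single named scalar feature on a one-channel window."""
    if name.startswith("AR"):
        k = int(name[2:])
        return float(ar_coeffs(window, spec.ar_order)[k - 1])
    if name.startswith("TDPSD_"):
        return float(tdpsd_features(window)[_TDPSD_NAMES.index(name)])
    if name.startswith("TSD_"):
        return float(tsd_features(window)[_TSD_NAMES.index(name)])
    fn = SCALAR_FEATURES[name]
    kwargs = {}
    if name in _THRESHOLD_PARAM and f"{name}.thr" in spec.params:
        kwargs["thr"] = spec.params[f"{name}.thr"]
    if name == "NSV":
        kwargs["inner_square"] = spec.nsv_inner_square
    return float(fn(window, **kwargs))


@dataclass
class FeatureMatrix:
    """Windows x (feature, channel) values with labels and provenance."""

    values: np.ndarray          # (n_windows, n_features * n_channels)
    columns: list[str]          # "<FEATURE>_ch<k>"
    labels: np.ndarray          # movement per window
    trial_index: np.ndarray     # trial provenance per window
    window_index: np.ndarray
    spec_name: str = "custom"

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df["label"] = self.labels
        df["trial"] = self.trial_index
        df["window"] = self.window_index
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spec_name: str = "custom") -> "FeatureMatrix":
        meta = ["label", "trial", "window"]
        cols = [c for c in df.columns if c not in meta]
        return cls(
            values=df[cols].to_numpy(dtype=float),
            columns=cols,
            labels=df["label"].to_numpy(),
            trial_index=df["trial"].to_numpy(dtype=int),
            window_index=df["window"].to_numpy(dtype=int),
            spec_name=spec_name,
        )


def _window_row(seg: WindowSegment, spec: FeatureSetSpec) -> np.ndarray:
    per_channel: list[np.ndarray] = []
    for ch in range(seg.n_channels):
        x = seg.samples[:, ch]
        ar = ar_coeffs(x, spec.ar_order) if any(f.startswith("AR") for f in spec.features) else None
        td = tdpsd_features(x) if any(f.startswith("TDPSD_") for f in spec.features) else None
        ts = tsd_features(x) if any(f.startswith("TSD_") for f in spec.features) else None
        vals = []
        for name in spec.features:
            if name.startswith("AR"):
                vals.append(ar[int(name[2:]) - 1])
            elif name.startswith("TDPSD_"):
                vals.append(td[_TDPSD_NAMES.index(name)])
            elif name.startswith("TSD_"):
                vals.append(ts[_TSD_NAMES.index(name)])
            else:
                vals.append(compute_feature(name, x, spec))
        per_channel.append(np.asarray(vals, dtype=float))
    return np.concatenate(per_channel)


def extract(windows: Sequence[WindowSegment], spec: FeatureSetSpec | str) -> FeatureMatrix:
    """Convert window segments to a feature matrix.

    Rows follow window order; columns are features x channels in spec order,
    channel-major (all features of channel 1, then channel 2, ...), named
    ``<FEATURE>_ch<k>``.  Raises if any cell is non-finite, identifying the
    window and feature.
    """
    if isinstance(spec, str):
        spec = feature_set(spec)
    if not windows:
        raise ValueError("no windows to extract from")
    n_ch = windows[0].n_channels
    if any(w.n_channels != n_ch for w in windows):
        raise ValueError("all windows must share channel count")
    if len({w.samples.shape[0] for w in windows}) != 1:
        raise ValueError("all windows must share length")
    columns = [f"{name}_ch{ch + 1}" for ch in range(n_ch) for name in spec.features]
    rows = np.empty((len(windows), len(columns)))
    for i, seg in enumerate(windows):
        row = _window_row(seg, spec)
        if not np.all(np.isfinite(row)):
            j = int(np.flatnonzero(~np.isfinite(row))[0])
            raise ValueError(
                f"non-finite value for feature {columns[j]!r} on window {i} "
                f"(movement {seg.movement}, trial {seg.trial_index})"
            )
        rows[i] = row
    return FeatureMatrix(
        values=rows,
        columns=columns,
        labels=np.array([w.movement for w in windows]),
        trial_index=np.array([w.trial_index for w in windows]),
        window_index=np.array([w.window_index for w in windows]),
        spec_name=spec.name,
    )
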