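"""The six acoustic parameters used to track porcine voice recovery.

Evaluation A uses two parameters: Q50, the frequency splitting the event's
energy spectrum into two equal-energy halves, and Flux1, the average
spectral change between neighboring analysis windows.  Evaluation B adds
Flux2 (an alternative spectral-flux formulation), Spread (energy-weighted
deviation of Mel components about the spectral centroid), P60 (the Mel
frequency at which cumulative energy reaches 60%) and LPC8 (the 8th of 16
linear-prediction coefficients, sensitive to vocal-tract changes).

All parameters are reported on their natural scale; the conventional
Flux1 x 10^3 / Flux2 x 10^1 display scaling is applied only when formatting
tables (see :func:`display_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .io_audio import AudioRecording

__all__ = [
    "FrameConfig",
    "FeatureConfig",
    "FEATURE_NAMES",
    "energy_spectrum",
    "spectral_quantile",
    "q50",
    "frame_spectra",
    "flux1",
    "flux2",
    "mel_filterbank",
    "mel_spectrum",
    "spread",
    "p60",
    "lpc_coefficients",
    "compute_features",
    "compute_feature_table",
    "display_table",
    "SquealFeatureExtractor",
]

FEATURE_NAMES = ["q50", "flux1", "flux2", "spread", "p60", "lpc8"]

#: Display-scale factors used in published tables (Flux1 x 10^3, Flux2 x 10^1).
DISPLAY_SCALE = {"flux1": 1e3, "flux2": 1e1}


@dataclass(frozen=True)
class FrameConfig:
    """Short-time framing for the flux parameters.

    1024-sample frames (~23 ms at 44.1 kHz) with 50% hop and a Hann window;
    short enough to resolve frame-to-frame squeal instabilities.
    """

    frame_length: int = 1024
    hop: int = 512
    window: str = "hann"


@dataclass(frozen=True)
class FeatureConfig:
    """Shared configuration for all six parameters."""

    frame: FrameConfig = field(default_factory=FrameConfig)
    normalize_frames: bool = True       # unit-energy frames before flux differencing
    n_mel_bands: int = 64
    mel_fmin: float = 50.0
    mel_fmax: float | None = None       # None -> Nyquist
    lpc_order: int = 16
    lpc_index: int = 8                  # 1-based coefficient index reported
    spread_mode: Literal["std", "mad"] = "std"
    window: str = "hann"                # whole-event spectrum window


def _next_pow2(n: int) -> int:
    return 1 << max(int(n) - 1, 0).bit_length()


# ---------------------------------------------------------------------------
# Spectra


def energy_spectrum(
    signal: np.ndarray, sample_rate: int, window: str = "hann"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided squared-magnitude spectrum of the whole event.

    The signal is windowed and zero-padded to the next power of two.
    Returns ``(freqs_hz, energy)``.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    w = get_window(window, x.size, fftbins=True)
    nfft = _next_pow2(x.size)
    spec = np.fft.rfft(x * w, n=nfft)
    energy = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    return freqs, energy


def spectral_quantile(freqs: np.ndarray, energy: np.ndarray, q: float) -> float:
    """Smallest frequency where cumulative energy reaches q of the total.

    Linear interpolation is used inside the crossing bin, treating each
    bin's energy as accumulating linearly across its width.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    energy = np.asarray(energy, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    csum = np.cumsum(energy)
    total = float(csum[-1])
    if total <= 0:
        raise ValueError("zero-energy spectrum: quantile undefined")
    target = q * total
    # relative tolerance keeps exactly-split spectra (e.g. two equal tones)
    # from landing in the flat plateau between peaks by float noise
    k = int(np.searchsorted(csum, target - 1e-12 * total))
    prev = csum[k - 1] if k > 0 else 0.0
    frac = (target - prev) / energy[k] if energy[k] > 0 else 0.0
    f_lo = freqs[k - 1] if k > 0 else 0.0
    return float(f_lo + frac * (freqs[k] - f_lo))


def q50(signal: np.ndarray, sample_rate: int, window: str = "hann") -> float:
    """50% energy spectrum quantile (Hz) of the whole event."""
    freqs, energy = energy_spectrum(signal, sample_rate, window)
    return spectral_quantile(freqs, energy, 0.5)


def frame_spectra(
    signal: np.ndarray, cfg: FrameConfig = FrameConfig()
) -> np.ndarray:
    """Per-frame one-sided energy spectra, frames in rows.

    Frames shorter than ``frame_length`` at the tail are dropped.
    """
    x = np.asarray(signal, dtype=np.float64)
    n = cfg.frame_length
    if x.size < n + cfg.hop:
        raise ValueError("signal too short: need at least 2 frames")
    n_frames = 1 + (x.size - n) // cfg.hop
    idx = np.arange(n)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    frames = x[idx] * get_window(cfg.window, n, fftbins=True)[None, :]
    return np.abs(np.fft.rfft(frames, axis=1)) ** 2


def flux1(
    signal: np.ndarray,
    sample_rate: int | None = None,
    cfg: FrameConfig = FrameConfig(),
    normalize: bool = True,
) -> float:
    """Average spectral change: mean over neighboring frame pairs of the
    mean absolute difference of their (unit-total-energy) spectra."""
    spectra = frame_spectra(signal, cfg)
    if normalize:
        totals = spectra.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        spectra = spectra / totals
    diffs = np.abs(np.diff(spectra, axis=0))
    return float(diffs.mean())


def flux2(
    signal: np.ndarray,
    sample_rate: int | None = None,
    cfg: FrameConfig = FrameConfig(),
) -> float:
    """Alternative spectral-flux formulation: RMS Euclidean distance between
    consecutive unit-L2-norm magnitude spectra."""
    spectra = np.sqrt(frame_spectra(signal, cfg))
    norms = np.linalg.norm(spectra, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    spectra = spectra / norms
    dists_sq = np.sum(np.diff(spectra, axis=0) ** 2, axis=1)
    return float(np.sqrt(dists_sq.mean()))


# ---------------------------------------------------------------------------
# Mel features


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    freqs: np.ndarray, n_bands: int, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel filterbank (HTK Mel formula) on a frequency grid.

    Returns ``(center_freqs_hz, weights)`` with ``weights`` of shape
    ``(n_bands, len(freqs))``.  Band edges are equally spaced in Mel.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if not 0 <= fmin < fmax:
        raise ValueError("require 0 <= fmin < fmax")
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_bands + 2))
    centers = edges_hz[1:-1]
    weights = np.zeros((n_bands, freqs.size))
    for k in range(n_bands):
        lo, c, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        up = (freqs - lo) / (c - lo)
        down = (hi - freqs) / (hi - c)
        weights[k] = np.clip(np.minimum(up, down), 0.0, None)
    return centers, weights


def mel_spectrum(
    signal: np.ndarray,
    sample_rate: int,
    n_bands: int = 64,
    fmin: float = 50.0,
    fmax: float | None = None,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Mel band energies of the whole event: ``(center_freqs_hz, band_energy)``."""
    nyquist = sample_rate / 2
    fmax = nyquist if fmax is None else fmax
    if fmax > nyquist:
        raise ValueError("fmax above Nyquist")
    freqs, energy = energy_spectrum(signal, sample_rate, window)
    centers, weights = mel_filterbank(freqs, n_bands, fmin, fmax)
    return centers, weights @ energy


def spread(
    centers: np.ndarray,
    band_energy: np.ndarray,
    mode: Literal["std", "mad"] = "std",
) -> float:
    """Energy-weighted deviation of Mel components about the centroid.

    ``std`` (default) is the weighted standard deviation; ``mad`` the
    weighted mean absolute deviation.  Units follow the band centers (Hz).
    """
    e = np.asarray(band_energy, dtype=np.float64)
    c = np.asarray(centers, dtype=np.float64)
    total = e.sum()
    if total <= 0:
        raise ValueError("zero-energy Mel spectrum")
    w = e / total
    centroid = float(np.sum(w * c))
    if mode == "std":
        return float(np.sqrt(np.sum(w * (c - centroid) ** 2)))
    if mode == "mad":
        return float(np.sum(w * np.abs(c - centroid)))
    raise ValueError(f"unknown mode {mode!r}")


def p60(centers: np.ndarray, band_energy: np.ndarray, q: float = 0.6) -> float:
    """Smallest band center at which cumulative Mel energy reaches ``q``.

    Unlike Q50 this is discrete: band centers are the spectrum's "frequency
    components", so no interpolation between bands is done.
    """
    e = np.asarray(band_energy, dtype=np.float64)
    total = e.sum()
    if total <= 0:
        raise ValueError("zero-energy Mel spectrum")
    csum = np.cumsum(e)
    k = int(np.searchsorted(csum, q * total - 1e-12 * total))
    return float(np.asarray(centers, dtype=np.float64)[k])


# ---------------------------------------------------------------------------
# Linear predictive coding


def lpc_coefficients(signal: np.ndarray, order: int = 16) -> np.ndarray:
    """Autocorrelation-method LPC via the Levinson–Durbin recursion.

    Returns the predictor coefficients ``a[1..order]`` in the convention
    ``x̂[n] = sum_k a_k x[n-k]`` (positive coefficients multiply past
    samples).  Raises on degenerate (constant or all-zero) input.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size <= order:
        raise ValueError("signal shorter than LPC order")
    # biased sample autocorrelation, lags 0..order
    r = np.array([x[: x.size - k] @ x[k:] for k in range(order + 1)]) / x.size
    if r[0] <= 0 or not np.isfinite(r).all():
        raise ValueError("degenerate signal: singular autocorrelation")
    a = np.zeros(order)
    err = r[0]
    for i in range(order):
        acc = r[i + 1] - a[:i] @ r[i:0:-1] if i > 0 else r[1]
        k = acc / err
        a_new = a.copy()
        a_new[i] = k
        if i > 0:
            a_new[:i] = a[:i] - k * a[i - 1 :: -1]
        a = a_new
        err *= 1.0 - k * k
        if err <= 0:
            raise ValueError("degenerate signal: non-positive prediction error")
    return a


def lpc_prediction_error(signal: np.ndarray, order: int) -> float:
    """Final prediction-error power from the Levinson recursion (for
    diagnostics; non-increasing in order)."""
    x = np.asarray(signal, dtype=np.float64)
    r = np.array([x[: x.size - k] @ x[k:] for k in range(order + 1)]) / x.size
    a = lpc_coefficients(signal, order)
    return float(r[0] - a @ r[1:])


# ---------------------------------------------------------------------------
# Per-squeal feature vector


def compute_features(
    signal: np.ndarray,
    sample_rate: int,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """All six parameters of one squeal, from its event samples only.

    Returns a dict keyed by :data:`FEATURE_NAMES`, natural scale.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty event")
    freqs, energy = energy_spectrum(x, sample_rate, config.window)
    if energy.sum() <= 0:
        raise ValueError("all-zero event: features undefined")
    centers, bands = mel_spectrum(
        x, sample_rate, config.n_mel_bands, config.mel_fmin, config.mel_fmax,
        config.window,
    )
    a = lpc_coefficients(x, config.lpc_order)
    return {
        "q50": spectral_quantile(freqs, energy, 0.5),
        "flux1": flux1(x, sample_rate, config.frame, config.normalize_frames),
        "flux2": flux2(x, sample_rate, config.frame),
        "spread": spread(centers, bands, config.spread_mode),
        "p60": p60(centers, bands),
        "lpc8": float(a[config.lpc_index - 1]),
    }


def compute_feature_table(
    recordings: Mapping[str, AudioRecording],
    labels: pd.DataFrame,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature table: one row per labeled squeal, metadata + six features.

    ``labels`` follows the label-file schema (recording_id, start_s, end_s,
    pig_id, recording_date, days_from_surgery, optionally phase).
    """
    rows = []
    for _, rec in labels.iterrows():
        recording = recordings[rec["recording_id"]]
        i0 = int(round(rec["start_s"] * recording.sample_rate))
        i1 = int(round(rec["end_s"] * recording.sample_rate))
        x = recording.samples[i0:i1]
        try:
            feats = compute_features(x, recording.sample_rate, config)
        except ValueError as exc:
            raise ValueError(
                f"feature computation failed for squeal "
                f"{rec['recording_id']}[{rec['start_s']}-{rec['end_s']}]: {exc}"
            ) from exc
        row = dict(rec)
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows)


def display_table(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the conventional display scaling (Flux1 x 10^3, Flux2 x 10^1)."""
    out = feature_table.copy()
    for name, scale in DISPLAY_SCALE.items():
        if name in out.columns:
            out[name] = out[name] * scale
            out = out.rename(columns={name: f"{name}_x{scale:g}"})
    return out


# ---------------------------------------------------------------------------
# sklearn-style transformer


class SquealFeatureExtractor:
    """Transformer mapping squeal waveforms to the six-parameter vectors.

    sklearn-compatible: ``fit`` validates the configuration, ``transform``
    maps an iterable of ``(samples, sample_rate)`` pairs (or
    :class:`~vocalfold.io_audio.AudioRecording` objects) to an
    ``(n_squeals, 6)`` array in :data:`FEATURE_NAMES` order.
    """

    def __init__(self, config: FeatureConfig = FeatureConfig()):
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "SquealFeatureExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: Iterable, y=None) -> "SquealFeatureExtractor":
        if self.config.lpc_index > self.config.lpc_order:
            raise ValueError("lpc_index exceeds lpc_order")
        self.feature_names_ = list(FEATURE_NAMES)
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        rows = []
        for item in X:
            if isinstance(item, AudioRecording):
                samples, sr = item.samples, item.sample_rate
            else:
                samples, sr = item
            feats = compute_features(samples, sr, self.config)
            rows.append([feats[name] for name in self.feature_names_])
        return np.asarray(rows, dtype=np.float64)

    def fit_transform(self, X: Iterable, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)
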