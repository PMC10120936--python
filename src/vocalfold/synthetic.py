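"""Synthetic squeal cohorts and fiber phantoms with known ground truth.

The audio generator produces harmonic-stack squeals whose two controllable
axes mirror what vocal-fold surgery does to pig phonation: the spectral
tilt (dB/octave) sets how much high-frequency energy survives — more
negative tilt emulates the post-surgery loss of high frequencies — and the
per-frame multiplicative jitter sets frame-to-frame spectral instability.
Cohorts arrange squeals over multi-date recording sessions spanning the
pre/post windows, with per-date parameter variability and an optional
recovery model pulling post-surgery parameters back toward the pre-surgery
profile over time.

The image generator renders two-channel fiber phantoms: smooth-profile
line-segment fibers with 180-degree-periodic axial orientations (wrapped
normal sampling, parameterized by a von Mises concentration through the
exact circular-SD equivalence), a programmed inter-channel orientation
offset, background noise and optional sub-threshold specks for testing the
particle filter.

All generators are pure functions of spec + seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .io_audio import AudioRecording, phase_of_day

__all__ = [
    "SquealGenSpec",
    "CohortSpec",
    "FiberPhantomSpec",
    "spec_to_yaml",
    "spec_from_yaml",
    "DEFAULT_PRE_SPEC",
    "DEFAULT_POST_SPEC",
    "generate_squeal",
    "generate_cohort",
    "generate_fiber_phantom",
    "generate_null_feature_table",
    "angular_sd_from_kappa",
    "kappa_from_angular_sd",
]

#: Master seed for fixture suites; every derived stream is spawned from it.
DEFAULT_MASTER_SEED = 20230421


# ---------------------------------------------------------------------------
# Squeal generation


@dataclass(frozen=True)
class SquealGenSpec:
    """Generative parameters of one squeal profile.

    ``spectral_tilt_db_per_octave``: per-octave decay of harmonic
    amplitudes above f0; more negative = duller, post-surgery-like.
    ``frame_instability``: amplitude of per-frame multiplicative spectral
    jitter (0 = perfectly stationary harmonics).
    """

    f0_range: tuple[float, float] = (900.0, 1500.0)
    f0_drift_frac: float = 0.04     # slow within-squeal drift around the center f0
    n_harmonics: int = 24
    spectral_tilt_db_per_octave: float = -2.0
    frame_instability: float = 0.05
    duration_s: float = 0.8
    attack_s: float = 0.015
    decay_tau_s: float = 0.35
    decay_inflection_frac: float = 0.6
    noise_floor_db: float = -45.0
    peak_amplitude: float = 16000.0
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.f0_range
        if not (100.0 < lo <= hi < 8000.0):
            raise ValueError("f0_range must lie within (100, 8000) Hz")
        if self.duration_s < 0.5:
            raise ValueError("squeals last at least 0.5 s")
        if self.frame_instability < 0:
            raise ValueError("frame_instability must be >= 0")


#: Pre-surgery profile: bright spectrum, stable frames.
DEFAULT_PRE_SPEC = SquealGenSpec(
    spectral_tilt_db_per_octave=-2.0, frame_instability=0.05
)
#: Early post-surgery profile: steep high-frequency loss, unstable frames.
DEFAULT_POST_SPEC = SquealGenSpec(
    spectral_tilt_db_per_octave=-16.0, frame_instability=0.45
)


def generate_squeal(
    spec: SquealGenSpec, seed: int | None = None, source_id: str = "synthetic"
) -> AudioRecording:
    """Render one squeal: drifting-f0 harmonic stack with tilt, jitter,
    sharp onset, exponential-then-linear decay and a noise floor."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sr = spec.sample_rate
    n = int(round(spec.duration_s * sr))
    t = np.arange(n) / sr

    # f0 trajectory: a per-squeal center frequency with slow relative drift
    f_lo, f_hi = spec.f0_range
    f0_center = rng.uniform(f_lo, f_hi)
    n_knots = max(int(spec.duration_s * 4), 3)
    knots = f0_center * (
        1.0 + spec.f0_drift_frac * rng.uniform(-1.0, 1.0, size=n_knots)
    )
    f0 = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, n_knots), knots)

    # per-frame multiplicative jitter, interpolated to samples
    frame_len = int(0.023 * sr)
    n_frames = max(n // frame_len + 1, 2)
    frame_pos = np.linspace(0, n - 1, n_frames)

    # unstable phonation is rough in pitch as well as amplitude: the same
    # instability knob drives per-frame multiplicative f0 jitter, the
    # dominant spectral-flux contribution of a hoarse voice
    f0_gain = 1.0 + 0.25 * spec.frame_instability * rng.standard_normal(n_frames)
    f0 = f0 * np.clip(np.interp(np.arange(n), frame_pos, f0_gain), 0.3, None)
    phase0 = 2 * np.pi * np.cumsum(f0) / sr

    nyquist = sr / 2
    signal = np.zeros(n)
    max_f0 = f0.max()
    for h in range(1, spec.n_harmonics + 1):
        if h * max_f0 >= nyquist:
            break
        amp = 10.0 ** (spec.spectral_tilt_db_per_octave * np.log2(h) / 20.0)
        gains = np.clip(
            1.0 + spec.frame_instability * rng.standard_normal(n_frames), 0.0, None
        )
        gain_t = np.interp(np.arange(n), frame_pos, gains)
        signal += amp * gain_t * np.sin(h * phase0 + rng.uniform(0, 2 * np.pi))

    # envelope: linear attack, exponential decay to an inflection, then linear
    env = np.ones(n)
    attack = max(int(spec.attack_s * sr), 1)
    env[:attack] = np.linspace(0, 1, attack)
    t_inf = spec.decay_inflection_frac * spec.duration_s
    decay = np.where(
        t <= t_inf,
        np.exp(-t / spec.decay_tau_s),
        np.exp(-t_inf / spec.decay_tau_s)
        * np.clip(1 - (t - t_inf) / (spec.duration_s - t_inf), 0.05, 1.0),
    )
    env *= decay
    signal *= env

    peak = np.abs(signal).max()
    if peak > 0:
        signal *= spec.peak_amplitude / peak
    noise = rng.standard_normal(n) * spec.peak_amplitude * 10.0 ** (
        spec.noise_floor_db / 20.0
    )
    return AudioRecording(signal + noise, sr, source_id)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """A multi-date, multi-pig synthetic recording campaign.

    ``recovery_model`` interpolates generation parameters from
    ``post_spec`` back toward ``pre_spec`` over post-surgery days:
    ``none`` keeps the post profile, ``linear`` recovers linearly by
    ``recovery_day``, ``logistic`` recovers along a logistic curve centered
    at ``recovery_day / 2``.  ``between_date_variability`` scales random
    per-date offsets of tilt and instability, emulating the strong
    session-to-session variation of spontaneous phonation.
    """

    pig_ids: tuple[str, ...] = ("pig_a", "pig_b")
    surgery_day: int = 0
    recording_days: tuple[int, ...] = (-30, -20, -10, 3, 8, 13)
    squeals_per_day: int = 12
    pre_spec: SquealGenSpec = field(default_factory=lambda: DEFAULT_PRE_SPEC)
    post_spec: SquealGenSpec = field(default_factory=lambda: DEFAULT_POST_SPEC)
    recovery_model: Literal["none", "linear", "logistic"] = "none"
    recovery_day: int = 150
    between_date_variability: float = 0.15
    surgery_date: _dt.date = _dt.date(2022, 6, 1)
    gap_s: float = 0.6
    seed: int = DEFAULT_MASTER_SEED

    def __post_init__(self) -> None:
        days = np.asarray(self.recording_days)
        if not ((days < self.surgery_day).any() and (days >= self.surgery_day).any()):
            raise ValueError("need at least one PRE and one post-surgery day")


def _recovered_fraction(day: int, spec: CohortSpec) -> float:
    if day < spec.surgery_day or spec.recovery_model == "none":
        return 0.0
    rel = day - spec.surgery_day
    if spec.recovery_model == "linear":
        return float(np.clip(rel / spec.recovery_day, 0.0, 1.0))
    if spec.recovery_model == "logistic":
        mid, scale = spec.recovery_day / 2, spec.recovery_day / 8
        return float(1.0 / (1.0 + np.exp(-(rel - mid) / scale)))
    raise ValueError(f"unknown recovery model {spec.recovery_model!r}")


def _day_spec(day: int, spec: CohortSpec, rng: np.random.Generator) -> SquealGenSpec:
    """Generation profile for one recording day: pre/post interpolation plus
    per-date random offsets."""
    if day < spec.surgery_day:
        base = spec.pre_spec
    else:
        r = _recovered_fraction(day, spec)
        pre, post = spec.pre_spec, spec.post_spec
        base = replace(
            post,
            spectral_tilt_db_per_octave=(
                post.spectral_tilt_db_per_octave
                + r * (pre.spectral_tilt_db_per_octave - post.spectral_tilt_db_per_octave)
            ),
            frame_instability=(
                post.frame_instability
                + r * (pre.frame_instability - post.frame_instability)
            ),
        )
    v = spec.between_date_variability
    if v > 0:
        f_lo, f_hi = base.f0_range
        shift = rng.normal(0, v) * 0.15 * (f_hi - f_lo)
        base = replace(
            base,
            spectral_tilt_db_per_octave=base.spectral_tilt_db_per_octave
            + rng.normal(0, 1.5 * v),
            frame_instability=max(
                base.frame_instability * float(np.exp(rng.normal(0, v))), 0.0
            ),
            f0_range=(f_lo + shift, f_hi + shift),
        )
    return base


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, AudioRecording], pd.DataFrame]:
    """Generate per-day recordings with embedded squeals plus a label table.

    Returns ``(recordings, labels)`` where ``recordings`` maps recording_id
    to audio (squeals separated by silent gaps) and ``labels`` follows the
    label-file schema with a ``phase`` column.
    """
    root = np.random.SeedSequence(spec.seed)
    recordings: dict[str, AudioRecording] = {}
    rows = []
    pig_seqs = root.spawn(len(spec.pig_ids))
    for pig_id, pig_seq in zip(spec.pig_ids, pig_seqs):
        day_seqs = pig_seq.spawn(len(spec.recording_days))
        for day, day_seq in zip(spec.recording_days, day_seqs):
            rng = np.random.default_rng(day_seq)
            day_profile = _day_spec(day, spec, rng)
            rec_id = f"{pig_id}_d{day:+04d}"
            sr = day_profile.sample_rate
            gap = int(spec.gap_s * sr)
            chunks = [np.zeros(gap)]
            pos = gap
            for k in range(spec.squeals_per_day):
                squeal = generate_squeal(
                    day_profile,
                    seed=int(rng.integers(2**31)),
                    source_id=rec_id,
                )
                chunks.append(squeal.samples)
                rows.append(
                    {
                        "recording_id": rec_id,
                        "start_s": pos / sr,
                        "end_s": (pos + squeal.samples.size) / sr,
                        "pig_id": pig_id,
                        "recording_date": (
                            spec.surgery_date + _dt.timedelta(days=int(day))
                        ).isoformat(),
                        "days_from_surgery": int(day),
                        "rater_id": "synthetic",
                    }
                )
                pos += squeal.samples.size
                chunks.append(np.zeros(gap))
                pos += gap
            recordings[rec_id] = AudioRecording(
                np.concatenate(chunks), sr, rec_id
            )
    labels = pd.DataFrame(rows)
    labels["phase"] = [phase_of_day(d) for d in labels["days_from_surgery"]]
    return recordings, labels


def generate_null_feature_table(
    n_dates_a: int = 3,
    n_dates_b: int = 3,
    squeals_per_date: int = 12,
    n_features: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table with NO pre/post effect (identical distributions).

    Used for type-I-error calibration of the balanced-sampling test
    machinery without synthesizing audio: every squeal's feature values are
    iid standard normal in both phases.  Phase-A dates land in the PRE
    window, phase-B dates in POST_EARLY.
    """
    rng = np.random.default_rng(seed)
    rows = []
    days_a = [-30 + 3 * i for i in range(n_dates_a)]
    days_b = [1 + 3 * i for i in range(n_dates_b)]
    for day in days_a + days_b:
        date = (_dt.date(2022, 6, 1) + _dt.timedelta(days=day)).isoformat()
        for _ in range(squeals_per_date):
            row = {
                "recording_date": date,
                "days_from_surgery": day,
                "phase": phase_of_day(day),
            }
            for j in range(n_features):
                row[f"f{j}"] = rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fiber phantoms


def angular_sd_from_kappa(kappa: float) -> float:
    """Circular SD (degrees) of the axial orientation distribution whose
    doubled angles follow a von Mises with concentration ``kappa``."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    r = i1e(kappa) / i0e(kappa)  # scaled Bessels avoid overflow at large kappa
    return float(0.5 * np.sqrt(-2.0 * np.log(r)) * 180.0 / np.pi)


def kappa_from_angular_sd(sd_deg: float) -> float:
    """Inverse of :func:`angular_sd_from_kappa` (numeric)."""
    if not 0 < sd_deg < 60:
        raise ValueError("angular SD must be in (0, 60) degrees")
    return float(
        brentq(lambda k: angular_sd_from_kappa(k) - sd_deg, 1e-3, 1e6)
    )


@dataclass(frozen=True)
class FiberPhantomSpec:
    """Two-channel fiber phantom parameters.

    Fiber axial orientations are 180-degree-periodic: doubled angles are
    drawn from a von Mises with concentration ``kappa`` (use
    :func:`kappa_from_angular_sd` to set a target angular SD).  The elastin
    channel's mean orientation is the collagen mean plus
    ``channel_offset_deg``.
    """

    image_size_px: int = 768
    pixel_size_um: float = 0.5
    n_fibers: int = 500
    fiber_width_um: float = 1.5
    fiber_length_um: tuple[float, float] = (25.0, 70.0)
    mean_orientation_deg: float = 40.0
    kappa: float = 16.0
    channel_offset_deg: float = 0.0
    fiber_intensity: float = 0.8
    background_noise_sd: float = 0.02
    speck_density: float = 0.0        # specks per pixel
    seed: int = DEFAULT_MASTER_SEED

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 <= self.channel_offset_deg <= 90:
            raise ValueError("channel_offset_deg in [0, 90]")
        if self.fiber_width_um / self.pixel_size_um >= self.image_size_px:
            raise ValueError("fibers wider than the image")


def _render_fibers(
    size: int,
    n_fibers: int,
    mean_deg: float,
    kappa: float,
    width_px: float,
    length_px: tuple[float, float],
    intensity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accumulate Gaussian-profile line segments; returns float image."""
    img = np.zeros((size, size))
    half_sigma = max(width_px / 2.0, 0.5)
    margin = int(np.ceil(3 * half_sigma)) + 1
    # axial sampling: wrapped normal with the circular SD equivalent to the
    # requested von Mises concentration (matches the normal-curve readout;
    # at these SDs the two shapes are close, but the wrapped normal keeps
    # the programmed SD exactly recoverable by the fit)
    sd_deg = angular_sd_from_kappa(kappa)
    thetas = (mean_deg + rng.normal(0.0, sd_deg, size=n_fibers)) % 180.0
    lengths = rng.uniform(*length_px, size=n_fibers)
    centers = rng.uniform(0, size, size=(n_fibers, 2))  # (row, col)
    for theta, length, (r0, c0) in zip(thetas, lengths, centers):
        th = np.radians(theta)
        # y-up convention: row decreases along +y
        d_row, d_col = -np.sin(th), np.cos(th)
        half = length / 2.0
        r_ends = (r0 - half * d_row, r0 + half * d_row)
        c_ends = (c0 - half * d_col, c0 + half * d_col)
        rmin = max(int(np.floor(min(r_ends))) - margin, 0)
        rmax = min(int(np.ceil(max(r_ends))) + margin, size - 1)
        cmin = max(int(np.floor(min(c_ends))) - margin, 0)
        cmax = min(int(np.ceil(max(c_ends))) + margin, size - 1)
        if rmin > rmax or cmin > cmax:
            continue
        rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
        # distance to the segment
        vr, vc = rr - r0, cc - c0
        t_par = np.clip(vr * d_row + vc * d_col, -half, half)
        d2 = (vr - t_par * d_row) ** 2 + (vc - t_par * d_col) ** 2
        img[rmin : rmax + 1, cmin : cmax + 1] += intensity * np.exp(
            -0.5 * d2 / half_sigma**2
        )
    return img


def generate_fiber_phantom(
    spec: FiberPhantomSpec,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Render the collagen and elastin channels plus a ground-truth record.

    Returns ``(collagen, elastin, truth)`` with float images clipped to
    [0, 1] and ``truth`` holding the programmed per-channel mean
    orientations, the angular SD (degrees) and the channel offset.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_c, rng_e, rng_noise = (np.random.default_rng(s) for s in root.spawn(3))
    width_px = spec.fiber_width_um / spec.pixel_size_um
    length_px = (
        spec.fiber_length_um[0] / spec.pixel_size_um,
        spec.fiber_length_um[1] / spec.pixel_size_um,
    )
    mean_e = (spec.mean_orientation_deg + spec.channel_offset_deg) % 180.0
    channels = []
    for mean_deg, rng in ((spec.mean_orientation_deg, rng_c), (mean_e, rng_e)):
        img = _render_fibers(
            spec.image_size_px,
            spec.n_fibers,
            mean_deg,
            spec.kappa,
            width_px,
            length_px,
            spec.fiber_intensity,
            rng,
        )
        if spec.speck_density > 0:
            n_specks = rng.poisson(spec.speck_density * spec.image_size_px**2)
            for _ in range(n_specks):
                r = rng.integers(0, spec.image_size_px)
                c = rng.integers(0, spec.image_size_px)
                img[r, c] += spec.fiber_intensity
        if spec.background_noise_sd > 0:
            img += np.abs(rng_noise.normal(0, spec.background_noise_sd, img.shape))
        channels.append(np.clip(img, 0.0, 1.0))
    truth = {
        "mean_orientation_collagen_deg": spec.mean_orientation_deg % 180.0,
        "mean_orientation_elastin_deg": mean_e,
        "angular_sd_deg": angular_sd_from_kappa(spec.kappa),
        "channel_offset_deg": spec.channel_offset_deg,
    }
    return channels[0], channels[1], truth


# ---------------------------------------------------------------------------
# Spec serialization


def spec_to_yaml(spec: SquealGenSpec | CohortSpec | FiberPhantomSpec,
                 path: str | Path) -> None:
    """Write a generator spec as YAML (lists for tuples, ISO dates)."""
    payload = {"kind": type(spec).__name__, "params": asdict(spec)}

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        if isinstance(obj, _dt.date):
            return obj.isoformat()
        return obj

    Path(path).write_text(yaml.safe_dump(_clean(payload), sort_keys=False))


_SPEC_KINDS = {
    "SquealGenSpec": None,  # filled below; forward refs
    "CohortSpec": None,
    "FiberPhantomSpec": None,
}


def spec_from_yaml(path: str | Path):
    """Load a generator spec written by :func:`spec_to_yaml`."""
    payload = yaml.safe_load(Path(path).read_text())
    kind = payload["kind"]
    params = payload["params"]

    def _squeal(p: dict) -> SquealGenSpec:
        p = dict(p)
        p["f0_range"] = tuple(p["f0_range"])
        return SquealGenSpec(**p)

    if kind == "SquealGenSpec":
        return _squeal(params)
    if kind == "CohortSpec":
        p = dict(params)
        p["pig_ids"] = tuple(p["pig_ids"])
        p["recording_days"] = tuple(p["recording_days"])
        p["pre_spec"] = _squeal(p["pre_spec"])
        p["post_spec"] = _squeal(p["post_spec"])
        p["surgery_date"] = _dt.date.fromisoformat(p["surgery_date"])
        return CohortSpec(**p)
    if kind == "FiberPhantomSpec":
        p = dict(params)
        p["fiber_length_um"] = tuple(p["fiber_length_um"])
        return FiberPhantomSpec(**p)
    raise ValueError(f"unknown spec kind {kind!r}")
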