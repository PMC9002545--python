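"""Synthetic EEG with known spectral and fractal ground truth.

Real resting/task EEG from the VR-immersion protocol this package analyses
is not publicly deposited, so validation runs on synthetic surrogates built
from three ingredients:

* **Fractal oracle signals** (:func:`gen_fractal_signal`) with known
  theoretical dimension — Weierstrass cosine sums and fractional Brownian
  motion (FD = 2 - Hurst), plus white noise (FD -> 2) and a straight line
  (FD = 1) — used to validate the Higuchi estimator.
* **EEG-like epochs** (:func:`gen_epoch`): per channel, a sum of
  band-limited Gaussian noise components (one per canonical band, amplitude
  set per scalp region), a 1/f^beta background whose exponent controls
  signal complexity, and occasional large raised-cosine transients.
* **Whole studies** (:func:`gen_study`): n subjects x three conditions
  (EO eyes-open baseline, 2D screen task, immersive 3D VR task) with
  consistent per-subject random offsets, so within-subject contrasts
  reflect the configured condition differences.

Default condition profiles are derived from published group-mean relative
band powers and fractal dimensions for the nine-site frontal/central/
parietal montage, so the generator's defaults reproduce the reported effect
directions: delta up and theta/alpha down under immersion, gamma up during
the screen task, and higher signal complexity (FD ~1.65 vs ~1.58) in both
task conditions.  Amplitudes are arbitrary units throughout — only relative
power is analysed downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .signal_io import CONDITIONS, EEGSegment, save_segment
from .spectral import DEFAULT_CHANNELS, BandScheme

__all__ = [
    "FractalSpec",
    "ConditionProfile",
    "SyntheticStudyConfig",
    "gen_fractal_signal",
    "gen_epoch",
    "gen_study",
    "default_profiles",
    "save_study",
    "REFERENCE_BAND_POWER",
    "REFERENCE_FD",
]

REGIONS = ("frontal", "central", "parietal")

# Published group-mean relative band power (nine 10-20 sites, three
# conditions) used as design targets for the default condition profiles.
# Layout: band -> channel -> (EO, 2D, 3D).
REFERENCE_BAND_POWER: dict[str, dict[str, tuple[float, float, float]]] = {
    "delta": {
        "F3": (0.370, 0.338, 0.422), "F4": (0.358, 0.355, 0.397), "Fz": (0.366, 0.349, 0.365),
        "C3": (0.325, 0.341, 0.374), "C4": (0.329, 0.342, 0.352), "Cz": (0.348, 0.363, 0.375),
        "P3": (0.346, 0.326, 0.359), "P4": (0.322, 0.344, 0.338), "Pz": (0.352, 0.365, 0.388),
    },
    "theta": {
        "F3": (0.169, 0.166, 0.132), "F4": (0.180, 0.159, 0.149), "Fz": (0.192, 0.165, 0.155),
        "C3": (0.191, 0.167, 0.145), "C4": (0.191, 0.152, 0.172), "Cz": (0.196, 0.173, 0.172),
        "P3": (0.203, 0.172, 0.164), "P4": (0.201, 0.158, 0.148), "Pz": (0.180, 0.147, 0.148),
    },
    "alpha": {
        "F3": (0.126, 0.111, 0.074), "F4": (0.115, 0.107, 0.081), "Fz": (0.114, 0.098, 0.088),
        "C3": (0.139, 0.109, 0.090), "C4": (0.146, 0.117, 0.106), "Cz": (0.132, 0.109, 0.096),
        "P3": (0.128, 0.112, 0.102), "P4": (0.144, 0.101, 0.100), "Pz": (0.127, 0.099, 0.089),
    },
    "beta": {
        "F3": (0.157, 0.175, 0.138), "F4": (0.166, 0.175, 0.148), "Fz": (0.157, 0.184, 0.160),
        "C3": (0.186, 0.188, 0.174), "C4": (0.174, 0.180, 0.183), "Cz": (0.166, 0.173, 0.161),
        "P3": (0.158, 0.190, 0.175), "P4": (0.181, 0.181, 0.199), "Pz": (0.169, 0.179, 0.150),
    },
    "gamma": {
        "F3": (0.058, 0.085, 0.061), "F4": (0.066, 0.082, 0.066), "Fz": (0.060, 0.082, 0.073),
        "C3": (0.061, 0.082, 0.074), "C4": (0.061, 0.076, 0.077), "Cz": (0.056, 0.073, 0.066),
        "P3": (0.060, 0.089, 0.078), "P4": (0.059, 0.085, 0.086), "Pz": (0.064, 0.080, 0.068),
    },
}

# Published group-mean Higuchi FD per site and condition (EO, 2D, 3D);
# targets for the complexity (background-exponent) calibration.
REFERENCE_FD: dict[str, tuple[float, float, float]] = {
    "F3": (1.58, 1.66, 1.65), "F4": (1.61, 1.65, 1.66), "Fz": (1.56, 1.67, 1.66),
    "C3": (1.57, 1.65, 1.67), "C4": (1.58, 1.64, 1.65), "Cz": (1.56, 1.63, 1.62),
    "P3": (1.58, 1.64, 1.65), "P4": (1.57, 1.66, 1.67), "Pz": (1.57, 1.65, 1.67),
}


def channel_region(label: str) -> str:
    """Map a 10-20 label to its scalp region by its leading letter."""
    head = label.strip()[:1].upper()
    region = {"F": "frontal", "C": "central", "P": "parietal"}.get(head)
    if region is None:
        raise ValueError(f"cannot map channel label {label!r} to a region")
    return region


# ---------------------------------------------------------------------------
# fractal oracle signals


@dataclass(frozen=True)
class FractalSpec:
    """Recipe for a signal of known theoretical fractal dimension."""

    kind: str
    n_samples: int
    hurst: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("weierstrass", "fbm", "white", "line"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.n_samples < 100:
            raise ValueError(f"n_samples={self.n_samples} too short for FD estimation")
        needs_h = self.kind in ("weierstrass", "fbm")
        if needs_h:
            if self.hurst is None:
                raise ValueError(f"kind {self.kind!r} requires a hurst exponent")
            if not 0 < self.hurst <= 1:
                raise ValueError(f"hurst must be in (0, 1], got {self.hurst}")
        elif self.hurst is not None:
            raise ValueError(f"kind {self.kind!r} takes no hurst exponent")

    @property
    def theoretical_fd(self) -> float | None:
        if self.kind in ("weierstrass", "fbm"):
            return 2.0 - self.hurst
        return {"white": 2.0, "line": 1.0}[self.kind]


def _weierstrass(n: int, hurst: float, rng: np.random.Generator, lam: float = 5.0) -> np.ndarray:
    # enough terms that the top component saturates the sampling resolution
    n_terms = int(np.ceil(np.log(n) / np.log(lam)))
    t = np.arange(n) / n
    j = np.arange(n_terms + 1)
    phases = rng.uniform(0, 2 * np.pi, size=j.size)
    comps = lam ** (-j[:, None] * hurst) * np.cos(
        2 * np.pi * lam ** j[:, None] * t[None, :] + phases[:, None]
    )
    return comps.sum(axis=0)


def _fbm(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    # circulant-embedding (Davies-Harte style) fractional Gaussian noise,
    # integrated to fBm; final unit-variance rescaling makes the absolute
    # scale irrelevant, only the covariance shape matters
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.clip(np.fft.fft(circ).real, 0.0, None)
    z = rng.standard_normal(lam.size) + 1j * rng.standard_normal(lam.size)
    fgn = np.real(np.fft.ifft(np.sqrt(lam) * z))[:n]
    return np.cumsum(fgn)


def gen_fractal_signal(spec: FractalSpec) -> np.ndarray:
    """Generate the series described by ``spec``; unit variance except 'line'."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "line":
        return np.linspace(0.0, 1.0, spec.n_samples)
    if spec.kind == "white":
        x = rng.standard_normal(spec.n_samples)
    elif spec.kind == "weierstrass":
        x = _weierstrass(spec.n_samples, spec.hurst, rng)
    else:
        x = _fbm(spec.n_samples, spec.hurst, rng)
    sd = x.std()
    if sd == 0:
        raise RuntimeError("degenerate zero-variance draw")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# EEG-like epochs


@dataclass(frozen=True)
class ConditionProfile:
    """Spectral recipe for one experimental condition.

    band_amplitudes
        band name -> region -> component SD (arbitrary units).
    background_exponent
        Slope beta of the 1/f^beta background; larger = smoother signal =
        lower fractal dimension.
    background_amplitude
        SD of the background component (0 disables it).
    artifact_rate
        Expected transient artifacts per second per channel.
    """

    condition: str
    band_amplitudes: Mapping[str, Mapping[str, float]]
    background_exponent: float = 1.7
    background_amplitude: float = 1.0
    artifact_rate: float = 0.05

    def __post_init__(self) -> None:
        for band, regions in self.band_amplitudes.items():
            for region, amp in regions.items():
                if region not in REGIONS:
                    raise ValueError(f"unknown region {region!r} in band {band!r}")
                if not np.isfinite(amp) or amp < 0:
                    raise ValueError(f"bad amplitude {amp!r} for {band}/{region}")
        if self.background_exponent < 0:
            raise ValueError("background_exponent must be >= 0")
        if self.background_amplitude < 0:
            raise ValueError("background_amplitude must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, slope: float = 0.0
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi) Hz by FFT masking.

    ``slope`` tilts the in-band spectrum as 1/f^slope, so oscillatory
    components ride on the same spectral decay as the background instead of
    being flat within their band; the band's *total* power (what relative
    band power measures) is unaffected by the tilt.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    inband = (freqs >= lo) & (freqs < hi)
    spec[~inband] = 0.0
    if slope > 0:
        spec[inband] *= np.maximum(freqs[inband], 1.0) ** (-slope / 2.0)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise (flat below 1 Hz to avoid divergence)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-beta / 2.0)
    shape[0] = 0.0
    spec = np.fft.rfft(rng.standard_normal(n)) * shape
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def background_band_fractions(
    beta: float, fs: float = 128.0, epoch_seconds: float = 20.0, scheme: BandScheme | None = None
) -> dict[str, float]:
    """Fraction of the background's 1-45 Hz power falling in each band.

    Computed from the exact discrete spectral shape used by the generator;
    used when solving band amplitudes for target relative powers.
    """
    scheme = scheme or BandScheme()
    n = int(round(fs * epoch_seconds))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-beta / 2.0)
    shape[0] = 0.0
    power = shape**2
    total_mask = (freqs >= scheme.total_range[0]) & (freqs <= scheme.total_range[1])
    # normalise by *total* background power so fractions are of unit variance
    power = power / power.sum()
    masks = scheme.masks(freqs)
    return {name: float(power[mask].sum()) for name, mask in masks.items()} | {
        "_total_1_45": float(power[total_mask].sum())
    }


def gen_epoch(
    profile: ConditionProfile,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    fs: float = 128.0,
    epoch_seconds: float = 20.0,
    seed: int = 0,
    scheme: BandScheme | None = None,
) -> EEGSegment:
    """One multichannel epoch drawn from a condition profile.

    Per channel: sum over bands of amplitude(band, region) x band-limited
    Gaussian noise, plus the 1/f^beta background, plus Poisson-placed 0.1 s
    raised-cosine transients of 10x the clean channel SD.  Deterministic in
    all arguments including seed.
    """
    scheme = scheme or BandScheme()
    for name, lo, hi in scheme.bands:
        if hi > fs / 2:
            raise ValueError(f"band {name!r} upper edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
    missing = set(scheme.names) - set(profile.band_amplitudes)
    if missing:
        raise ValueError(f"profile missing amplitudes for bands {sorted(missing)}")
    regions = [channel_region(ch) for ch in channels]
    n = int(round(fs * epoch_seconds))
    rng = np.random.default_rng(seed)
    data = np.zeros((len(channels), n))
    for ci, region in enumerate(regions):
        x = np.zeros(n)
        for band, lo, hi in scheme.bands:
            amp = float(profile.band_amplitudes[band][region])
            if amp > 0:
                x += amp * _band_noise(rng, n, fs, lo, hi, slope=profile.background_exponent)
        if profile.background_amplitude > 0:
            x += profile.background_amplitude * _background(
                rng, n, fs, profile.background_exponent
            )
        if profile.artifact_rate > 0:
            n_events = rng.poisson(profile.artifact_rate * epoch_seconds)
            width = max(int(round(0.1 * fs)), 2)
            pulse = np.hanning(width)
            clean_sd = x.std() if x.std() > 0 else 1.0
            for _ in range(n_events):
                start = rng.integers(0, n - width)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                x[start : start + width] += sign * 10.0 * clean_sd * pulse
        data[ci] = x
    return EEGSegment(
        data=data,
        fs=fs,
        channel_labels=tuple(channels),
        condition=profile.condition,
    )


# ---------------------------------------------------------------------------
# whole studies


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """A full n-subject, three-condition synthetic study."""

    n_subjects: int = 15
    profiles: tuple[ConditionProfile, ...] = ()
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = 128.0
    epoch_seconds: float = 20.0
    between_subject_sd: float = 0.15
    between_subject_beta_sd: float = 0.08
    seed: int = 0
    scheme: BandScheme = field(default_factory=BandScheme)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 for paired statistics")
        if not self.channels or len(set(self.channels)) != len(self.channels):
            raise ValueError("channels must be nonempty and unique")
        top_edge = max(hi for _, _, hi in self.scheme.bands)
        if self.fs <= 2 * top_edge:
            raise ValueError(f"fs={self.fs} must exceed twice the top band edge {top_edge}")
        if self.between_subject_sd < 0 or self.between_subject_beta_sd < 0:
            raise ValueError("between-subject SDs must be >= 0")
        if not self.profiles:
            object.__setattr__(self, "profiles", default_profiles())
        conds = [p.condition for p in self.profiles]
        if sorted(conds) != sorted(CONDITIONS):
            raise ValueError(f"profiles must cover conditions {CONDITIONS}, got {conds}")


def _subject_profile(
    profile: ConditionProfile,
    band_factors: Mapping[str, float],
    bg_factor: float,
    beta_offset: float,
) -> ConditionProfile:
    amps = {
        band: {region: amp * band_factors[band] for region, amp in regions.items()}
        for band, regions in profile.band_amplitudes.items()
    }
    return replace(
        profile,
        band_amplitudes=amps,
        background_amplitude=profile.background_amplitude * bg_factor,
        background_exponent=max(profile.background_exponent + beta_offset, 0.0),
    )


def gen_study(config: SyntheticStudyConfig) -> list[EEGSegment]:
    """Generate n_subjects x 3 condition-labelled segments.

    Each subject gets log-normal band/background amplitude factors (SD =
    ``between_subject_sd``) and a Gaussian background-exponent offset, drawn
    once and applied to all three of that subject's conditions, so the
    within-subject contrasts carry only the configured profile differences.
    """
    master = np.random.default_rng(config.seed)
    segments: list[EEGSegment] = []
    band_names = config.scheme.names
    for si in range(config.n_subjects):
        subject_id = f"S{si + 1:02d}"
        band_factors = {
            b: float(np.exp(master.normal(0.0, config.between_subject_sd))) for b in band_names
        }
        bg_factor = float(np.exp(master.normal(0.0, config.between_subject_sd)))
        beta_offset = float(master.normal(0.0, config.between_subject_beta_sd))
        for profile in config.profiles:
            epoch_seed = int(master.integers(0, 2**31 - 1))
            subj_profile = _subject_profile(profile, band_factors, bg_factor, beta_offset)
            seg = gen_epoch(
                subj_profile,
                channels=config.channels,
                fs=config.fs,
                epoch_seconds=config.epoch_seconds,
                seed=epoch_seed,
                scheme=config.scheme,
            )
            segments.append(replace(seg, subject_id=subject_id, condition=profile.condition))
    return segments


def default_profiles(
    artifact_rate: float = 0.05,
    scheme: BandScheme | None = None,
    fs: float = 128.0,
    epoch_seconds: float = 20.0,
) -> tuple[ConditionProfile, ...]:
    """Condition profiles targeting the published group-mean levels.

    For each condition the band amplitudes are solved, per region, so that
    the expected relative band powers match the region-averaged reference
    values: with background variance fraction g_b(beta) in band b and
    target share T_b, amplitudes satisfy a_b^2 = c*T_b - g_b with c chosen
    so every a_b^2 is nonnegative.  Background exponents are calibrated so
    the windowed Higuchi FD of the composite signal lands at the reference
    complexity levels (~1.58 at rest, ~1.65 under task immersion).
    """
    scheme = scheme or BandScheme()
    # complexity calibration: beta per condition (EO smoother than tasks),
    # set so windowed Higuchi FD of preprocessed default epochs matches the
    # REFERENCE_FD condition means (~1.58 / 1.65 / 1.66)
    betas = {"EO": 2.0, "2D": 1.7, "3D": 1.62}
    region_channels = {
        "frontal": ("F3", "Fz", "F4"),
        "central": ("C3", "Cz", "C4"),
        "parietal": ("P3", "Pz", "P4"),
    }
    profiles = []
    for ci, cond in enumerate(CONDITIONS):
        beta = betas[cond]
        g = background_band_fractions(beta, fs=fs, epoch_seconds=epoch_seconds, scheme=scheme)
        amps: dict[str, dict[str, float]] = {b: {} for b in scheme.names}
        for region, chans in region_channels.items():
            targets = {
                b: float(np.mean([REFERENCE_BAND_POWER[b][ch][ci] for ch in chans]))
                for b in scheme.names
            }
            total = sum(targets.values())
            targets = {b: t / total for b, t in targets.items()}
            c = 1.05 * max(g[b] / targets[b] for b in scheme.names)
            for b in scheme.names:
                amps[b][region] = float(np.sqrt(max(c * targets[b] - g[b], 0.0)))
        profiles.append(
            ConditionProfile(
                condition=cond,
                band_amplitudes=amps,
                background_exponent=beta,
                background_amplitude=1.0,
                artifact_rate=artifact_rate,
            )
        )
    return tuple(profiles)


def null_profiles(artifact_rate: float = 0.05) -> tuple[ConditionProfile, ...]:
    """Three conditions sharing one spectral recipe (no true effect)."""
    base = default_profiles(artifact_rate=artifact_rate)[0]
    return tuple(replace(base, condition=c) for c in CONDITIONS)


def save_study(segments: Sequence[EEGSegment], out_dir: str | Path) -> list[Path]:
    """Write each segment as a CSV+JSON fixture pair under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for seg in segments:
        stem = out_dir / f"{seg.subject_id}_{seg.condition}"
        paths.append(save_segment(seg, stem))
    return paths
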