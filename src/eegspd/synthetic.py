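"""Synthetic EEG-like trial cohorts with planted band-power class structure.

The generator emulates the statistical structure that covariance-based
decoders exploit in motor EEG: class-dependent oscillatory power in narrow
frequency bands at specific electrodes, riding on spatially correlated
1/f-plus-white broadband noise.  Oscillations are narrowband-filtered
noise, not pure sinusoids, so the class signal lives in the covariance
(band power), not in phase — exactly what covariance pooling can see.

Canonical fixtures (:func:`make_fixture`) plant known ground truth so that
filter-recovery and relevance analyses can be scored:

``easy4``
    four classes in disjoint alpha/beta/low-gamma/high-gamma bands at
    distinct electrode pairs, high SNR;
``hard4``
    overlapping bands on shared electrodes at low SNR;
``singleband``
    all class information confined to one band (graded power), for
    filterbank-search recovery;
``multiband``
    a 2x2 power design over two disjoint bands, so that a single filter
    must pass both bands to separate all four classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import TrialSet

__all__ = ["PlantedBand", "SynthConfig", "FixtureTruth", "generate", "make_fixture", "make_cohort"]


@dataclass(frozen=True)
class PlantedBand:
    """One class-specific oscillation: electrodes, band (Hz), relative power."""

    electrodes: tuple[int, ...]
    band: tuple[float, float]
    rel_power: float = 1.0


@dataclass
class SynthConfig:
    """Study conditions of a synthetic cohort.

    ``planted_bands[c]`` lists the oscillations added to trials of class
    ``c``.  ``snr`` scales the oscillation RMS relative to the broadband
    noise RMS inside the same band at the same electrode; the noise floor
    is 1/f (exponent ``noise_exponent``) plus a white floor ``white_floor_db``
    below the 1 Hz level; ``mixing_rho`` sets uniform inter-electrode noise
    correlation.
    """

    Ne: int = 8
    Nt: int = 500
    fs: float = 250.0
    n_classes: int = 4
    n_trials_per_class: int = 40
    planted_bands: dict[int, list[PlantedBand]] = field(default_factory=dict)
    noise_exponent: float = 1.0
    white_floor_db: float = -20.0
    mixing_rho: float = 0.2
    snr: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.fs / 2.0
        for c, bands in self.planted_bands.items():
            if not (0 <= c < self.n_classes):
                raise ValueError(f"planted class {c} outside [0, {self.n_classes})")
            for pb in bands:
                lo, hi = pb.band
                if not (0.0 < lo < hi < nyq):
                    raise ValueError(f"band {pb.band} outside (0, fs/2) at fs={self.fs}")
                if any(e < 0 or e >= self.Ne for e in pb.electrodes):
                    raise ValueError(f"electrode index out of range in {pb}")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not (0.0 <= self.mixing_rho < 1.0):
            raise ValueError("mixing_rho must lie in [0, 1)")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground-truth descriptor shipped with each canonical fixture."""

    bands: tuple[tuple[float, float], ...]
    electrodes: tuple[int, ...]
    description: str


def _noise_amplitude(freqs: np.ndarray, exponent: float, floor_db: float) -> np.ndarray:
    """Amplitude spectral profile: 1/f^(a/2) power law plus a white floor."""
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    floor = 10.0 ** (floor_db / 20.0)  # relative to the 1 Hz amplitude
    amp[pos] = np.sqrt(freqs[pos] ** (-exponent) + floor**2)
    return amp


def _spectral_noise(
    rng: np.random.Generator, n_rows: int, Nt: int, amp: np.ndarray
) -> np.ndarray:
    """Gaussian noise rows with the given one-sided amplitude profile."""
    n_bins = amp.size
    coeffs = (rng.standard_normal((n_rows, n_bins)) + 1j * rng.standard_normal((n_rows, n_bins)))
    coeffs *= amp
    x = np.fft.irfft(coeffs, n=Nt, axis=-1)
    return x / (x.std(axis=-1, keepdims=True) + 1e-30)


def _narrowband_noise(
    rng: np.random.Generator, n_rows: int, Nt: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS random-phase oscillation confined to ``band``."""
    freqs = np.fft.rfftfreq(Nt, d=1.0 / fs)
    mask = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
    return _spectral_noise(rng, n_rows, Nt, mask)


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """RMS of the band-limited content of each row (FFT mask)."""
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~mask] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1], axis=-1).std(axis=-1)


def generate(config: SynthConfig) -> TrialSet:
    """Generate a balanced, fully seeded synthetic trial set."""
    rng = np.random.default_rng(config.seed)
    Ne, Nt, fs = config.Ne, config.Nt, config.fs
    n_total = config.n_classes * config.n_trials_per_class
    freqs = np.fft.rfftfreq(Nt, d=1.0 / fs)
    amp = _noise_amplitude(freqs, config.noise_exponent, config.white_floor_db)

    # uniform-correlation mixing: C = (1-rho) I + rho J, applied via Cholesky
    mix = (1.0 - config.mixing_rho) * np.eye(Ne) + config.mixing_rho * np.ones((Ne, Ne))
    L = np.linalg.cholesky(mix)

    y = np.repeat(np.arange(config.n_classes), config.n_trials_per_class)
    X = np.empty((n_total, Ne, Nt))
    for i, c in enumerate(y):
        noise = L @ _spectral_noise(rng, Ne, Nt, amp)
        trial = noise.copy()
        for pb in config.planted_bands.get(int(c), []):
            target = config.snr * pb.rel_power
            if target == 0.0:
                continue
            osc = _narrowband_noise(rng, len(pb.electrodes), Nt, fs, pb.band)
            ref = _band_rms(noise[list(pb.electrodes)], fs, pb.band)
            trial[list(pb.electrodes)] += osc * (target * ref)[:, None]
        X[i] = trial
    # deterministic interleaved order: shuffle once, seeded
    order = rng.permutation(n_total)
    return TrialSet(X=X[order], y=y[order], fs=fs)


_FIXTURES = {
    "easy4": dict(
        planted={
            0: [PlantedBand((0, 1), (8.0, 12.0))],
            1: [PlantedBand((2, 3), (18.0, 26.0))],
            2: [PlantedBand((4, 5), (35.0, 45.0))],
            3: [PlantedBand((6, 7), (60.0, 80.0))],
        },
        snr=4.0,
        truth=FixtureTruth(
            bands=((8.0, 12.0), (18.0, 26.0), (35.0, 45.0), (60.0, 80.0)),
            electrodes=(0, 1, 2, 3, 4, 5, 6, 7),
            description="four classes in disjoint bands at distinct electrode pairs",
        ),
    ),
    "hard4": dict(
        planted={
            0: [PlantedBand((0, 1, 2), (8.0, 14.0))],
            1: [PlantedBand((1, 2, 3), (12.0, 18.0))],
            2: [PlantedBand((2, 3, 4), (16.0, 24.0))],
            3: [PlantedBand((3, 4, 5), (20.0, 30.0))],
        },
        snr=0.75,
        truth=FixtureTruth(
            bands=((8.0, 14.0), (12.0, 18.0), (16.0, 24.0), (20.0, 30.0)),
            electrodes=(0, 1, 2, 3, 4, 5),
            description="overlapping bands on shared electrodes at low SNR",
        ),
    ),
    "singleband": dict(
        planted={
            0: [PlantedBand((0, 1), (20.0, 30.0), rel_power=0.0)],
            1: [PlantedBand((0, 1), (20.0, 30.0), rel_power=0.5)],
            2: [PlantedBand((0, 1), (20.0, 30.0), rel_power=1.0)],
            3: [PlantedBand((0, 1), (20.0, 30.0), rel_power=2.0)],
        },
        snr=4.0,
        truth=FixtureTruth(
            bands=((20.0, 30.0),),
            electrodes=(0, 1),
            description="graded power in a single informative band",
        ),
    ),
    "multiband": dict(
        planted={
            # 2x2 power design over two disjoint bands: both bands needed
            0: [PlantedBand((0, 1, 2, 3), (10.0, 14.0), 0.25), PlantedBand((0, 1, 2, 3), (60.0, 70.0), 0.25)],
            1: [PlantedBand((0, 1, 2, 3), (10.0, 14.0), 1.0), PlantedBand((0, 1, 2, 3), (60.0, 70.0), 0.25)],
            2: [PlantedBand((0, 1, 2, 3), (10.0, 14.0), 0.25), PlantedBand((0, 1, 2, 3), (60.0, 70.0), 1.0)],
            3: [PlantedBand((0, 1, 2, 3), (10.0, 14.0), 1.0), PlantedBand((0, 1, 2, 3), (60.0, 70.0), 1.0)],
        },
        snr=4.0,
        truth=FixtureTruth(
            bands=((10.0, 14.0), (60.0, 70.0)),
            electrodes=(0, 1, 2, 3),
            description="2x2 power design over two disjoint bands",
        ),
    ),
}


def make_fixture(
    name: str,
    seed: int = 0,
    n_trials_per_class: int = 40,
    Ne: int = 8,
    Nt: int = 500,
    fs: float = 250.0,
) -> tuple[TrialSet, FixtureTruth]:
    """Build a canonical fixture and its ground-truth descriptor."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    entry = _FIXTURES[name]
    cfg = SynthConfig(
        Ne=Ne,
        Nt=Nt,
        fs=fs,
        n_classes=4,
        n_trials_per_class=n_trials_per_class,
        planted_bands=entry["planted"],
        snr=entry["snr"],
        seed=seed,
    )
    return generate(cfg), entry["truth"]


def make_cohort(
    name: str,
    n_participants: int,
    seed: int = 0,
    n_trials_per_class: int = 40,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """A cohort of independently generated participants of one fixture kind.

    Participant-to-participant variability comes from independent noise and
    oscillation draws (seeded per participant).
    """
    cohort: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for p in range(n_participants):
        trials, _ = make_fixture(
            name, seed=seed * 10_000 + p, n_trials_per_class=n_trials_per_class
        )
        cohort[f"P{p + 1:02d}"] = (trials.X, trials.y)
    return cohort
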