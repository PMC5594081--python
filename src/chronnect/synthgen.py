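"""Synthetic data with planted ground truth for every pipeline stage.

Three generators:

* :func:`gen_coupled_eeg` — multichannel surrogate EEG: 1/f background
  noise plus planted couplings.  Within-band coupling is realized as a
  shared narrowband oscillator injected into both channels with a constant
  phase lag (nonzero by default, so the imaginary PLV sees it); a
  cross-frequency mode as a slow narrowband modulator on one channel whose
  phase-shifted copy amplitude-modulates the fast band of the other.
  Epochs make the coupling structure piecewise-stationary.
* :func:`gen_markov_sequence` — symbolic sequences from a known transition
  kernel.
* :func:`gen_feature_cohort` — a cohort feature table with a planted
  linear age effect, correlated nuisance blocks and pure-noise columns.

All generators are pure functions of (specification, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .coupling import CouplingModeTable
from .preprocess import DEFAULT_BANDS, BandSpec, Recording

__all__ = [
    "PlantedCoupling",
    "Epoch",
    "CouplingSpecification",
    "gen_markov_sequence",
    "gen_coupled_eeg",
    "gen_feature_cohort",
    "worked_example_sequences",
]


@dataclass(frozen=True)
class PlantedCoupling:
    """One planted interaction.

    ``pair`` is (i, j) channel indices; ``label`` the coupling-mode label
    (1..36); ``strength`` in [0, 1] the shared-source mixing (within-band)
    or modulation depth (cross-frequency); ``phase_lag`` the imposed phase
    offset in radians (keep away from 0 and pi — zero-lag coupling is
    invisible to the imaginary PLV by design).  For cross-frequency modes
    the low-frequency phase comes from ``pair[0]``.
    """

    pair: tuple[int, int]
    label: int
    strength: float = 0.9
    phase_lag: float = np.pi / 2


@dataclass(frozen=True)
class Epoch:
    duration_s: float
    couplings: tuple[PlantedCoupling, ...] = ()


@dataclass(frozen=True)
class CouplingSpecification:
    """Recording-level plan: epochs tile the recording; background is 1/f noise."""

    epochs: tuple[Epoch, ...]
    noise_exponent: float = 1.0
    snr_db: float = 10.0


def gen_markov_sequence(P: np.ndarray, T: int, seed: int = 0,
                        init: int | None = None) -> np.ndarray:
    """Length-T realization of the chain P (labels 1..k), reproducible by seed."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8) or (P < 0).any():
        raise ValueError("P must be row-stochastic")
    k = P.shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty(T, dtype=int)
    state = init if init is not None else int(rng.integers(k))
    cum = np.cumsum(P, axis=1)
    for t in range(T):
        out[t] = state + 1
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
        state = min(state, k - 1)
    return out


def _onef_noise(n_channels: int, n_samples: int, exponent: float, rng) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    noise = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    return noise / noise.std(axis=1, keepdims=True)


def _narrowband(n: int, band: BandSpec, fs: float, rng) -> np.ndarray:
    """Unit-RMS narrowband noise: band-filtered white noise.

    Its phase diffuses as fast as the bandwidth allows (decorrelation
    ~1/bandwidth), which keeps the circular-shift surrogate null of
    within-band coupling honest; its Rayleigh-like envelope makes it
    unsuitable as a PAC carrier (see :func:`_oscillator`).
    """
    sos = sps.butter(3, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillator(n: int, band: BandSpec, fs: float, rng) -> np.ndarray:
    """Unit-amplitude narrowband oscillator with a drifting phase.

    cos(2 pi integral of f(t)) with instantaneous frequency wandering
    around the band center (smoothed frequency noise, SD = bandwidth/4,
    clipped inside the band).  Constant amplitude keeps planted envelope
    modulations exact, while the phase drift decorrelates time-shifted
    copies — the property the surrogate null relies on.
    """
    f_c = 0.5 * (band.f_lo + band.f_hi)
    bw = band.f_hi - band.f_lo
    # frequency noise smoothed over ~one center-period
    smooth = max(1, int(round(fs / f_c)))
    dev = np.convolve(rng.standard_normal(n + smooth), np.ones(smooth) / smooth,
                      mode="valid")[:n]
    sd = dev.std()
    if sd > 0:
        dev = dev / sd * (bw / 4.0)
    freq = np.clip(f_c + dev, band.f_lo, band.f_hi)
    phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Shift the instantaneous phase of a narrowband signal by ``lag`` radians."""
    return np.real(sps.hilbert(x) * np.exp(-1j * lag))


def _band_rms(noise_row: np.ndarray, band: BandSpec, fs: float) -> float:
    sos = sps.butter(3, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    return float(sps.sosfiltfilt(sos, noise_row).std())


def gen_coupled_eeg(
    spec: CouplingSpecification,
    n_channels: int = 8,
    fs: float = 160.0,
    seed: int = 0,
    bands=DEFAULT_BANDS,
    table: CouplingModeTable | None = None,
) -> tuple[Recording, np.ndarray]:
    """Generate a Recording realizing ``spec``; also return per-sample epoch ids.

    Planted oscillation amplitudes are scaled so that the in-band
    oscillation-to-background amplitude ratio matches ``spec.snr_db``.
    """
    if table is None:
        table = CouplingModeTable(bands)
    band_by_name = {b.name: b for b in bands}
    rng = np.random.default_rng(seed)
    seg_lens = [int(round(ep.duration_s * fs)) for ep in spec.epochs]
    n = int(sum(seg_lens))
    data = _onef_noise(n_channels, n, spec.noise_exponent, rng)
    epoch_id = np.zeros(n, dtype=int)
    amp_ratio = 10.0 ** (spec.snr_db / 20.0)

    pos = 0
    for e_idx, (ep, seg) in enumerate(zip(spec.epochs, seg_lens)):
        sl = slice(pos, pos + seg)
        epoch_id[sl] = e_idx
        for pc in ep.couplings:
            if not 1 <= pc.label <= table.n_modes:
                raise ValueError(f"mode label {pc.label} outside 1..{table.n_modes}")
            i, j = pc.pair
            lo_name, hi_name = table.mode(pc.label)
            lo_band, hi_band = band_by_name[lo_name], band_by_name[hi_name]
            rms = 1.0 / np.sqrt(2.0)  # unit-amplitude oscillator RMS
            if not table.is_cross(pc.label):
                src = _narrowband(seg, lo_band, fs, rng)
                indep = _narrowband(seg, lo_band, fs, rng)
                amp = amp_ratio * _band_rms(data[i], lo_band, fs)
                data[i, sl] += amp * src
                mix = pc.strength * _phase_shift(src, pc.phase_lag)
                mix += np.sqrt(max(1 - pc.strength**2, 0.0)) * indep
                data[j, sl] += amp * mix
            else:
                mod = _oscillator(seg, lo_band, fs, rng)
                amp_lo = amp_ratio * _band_rms(data[i], lo_band, fs) / rms
                data[i, sl] += amp_lo * mod
                carrier = _oscillator(seg, hi_band, fs, rng)
                # unit-amplitude modulator: envelope = 1 + depth * shifted copy
                envelope = 1.0 + pc.strength * np.clip(
                    _phase_shift(mod, pc.phase_lag), -1, 1)
                amp_hi = amp_ratio * _band_rms(data[j], hi_band, fs) / rms
                data[j, sl] += amp_hi * envelope * carrier
        pos += seg

    labels = [f"SYN{c:03d}" for c in range(n_channels)]
    return Recording(data=data, fs=fs, labels=labels), epoch_id


def gen_feature_cohort(
    n_subjects: int = 100,
    age_range: tuple[float, float] = (18.0, 60.0),
    n_informative: int = 5,
    slope: float = 1.0,
    noise_sd: float = 0.1,
    n_nuisance_blocks: int = 3,
    block_size: int = 5,
    n_noise: int = 20,
    young_max: float = 37.0,
    middle_min: float = 40.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Cohort feature table with a planted linear age effect.

    Informative columns are ``slope * standardized(age) + N(0, noise_sd)``;
    nuisance blocks share a latent factor (exercising the dominant-set
    clustering) but carry no age signal; the rest is pure noise.  Group
    labels split young (age <= young_max) from middle-aged
    (age >= middle_min), subjects in between joining the nearer group.

    Returns (features, ages, groups).
    """
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n_subjects)
    age_z = (ages - ages.mean()) / ages.std()
    cols = {}
    for f in range(n_informative):
        cols[f"info_{f}"] = slope * age_z + noise_sd * rng.standard_normal(n_subjects)
    for b in range(n_nuisance_blocks):
        latent = rng.standard_normal(n_subjects)
        for f in range(block_size):
            cols[f"block{b}_{f}"] = latent + 0.1 * rng.standard_normal(n_subjects)
    for f in range(n_noise):
        cols[f"noise_{f}"] = rng.standard_normal(n_subjects)
    features = pd.DataFrame(cols)
    midpoint = (young_max + middle_min) / 2.0
    groups = np.where(ages <= midpoint, "young", "middle")
    return features, ages, groups


def worked_example_sequences() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three printed 10-symbol worked examples for the complexity index."""
    return (
        np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2]),
        np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 1]),
        np.array([1, 2, 2, 1, 2, 2, 1, 2, 1, 1]),
    )
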