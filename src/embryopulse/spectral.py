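"""Fourier power spectra of PIV velocities and the oscillation call.

Periodic cortical contractions show up as a peak in the per-embryo power
spectrum of PIV velocity time series. The per-embryo spectrum is the mean
of the discrete-Fourier power spectra of every vector's u and v components
(mean-detrended, DC excluded), which preserves out-of-phase pulsations
across the cortex. An embryo is called oscillating when the peak power in
the 50–120 s period band reaches 1.7 times the spectrum's mean power.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .piv import VelocityField

#: period band (s) in which wild-type embryos pulse, and the call threshold
DEFAULT_BAND = (50.0, 120.0)
DEFAULT_THRESHOLD = 1.7


@dataclass
class PowerSpectrum:
    """Mean velocity power per period for one embryo (DC bin excluded)."""

    periods: np.ndarray  # s, descending
    power: np.ndarray
    embryo_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class OscillationCall:
    amplitude: float      # peak power in the band
    peak_period: float    # s
    background: float     # mean power of the whole spectrum
    ratio: float
    is_oscillating: bool
    embryo_id: str = ""


def embryo_spectrum(field: VelocityField,
                    keep: np.ndarray | None = None,
                    embryo_id: str = "") -> PowerSpectrum:
    """Average DFT power spectrum across vectors and both components.

    ``keep`` optionally restricts the (ny, nx) grid to in-embryo vectors.
    Each retained time series is mean-detrended before the transform, so a
    constant drift contributes nothing.
    """
    n_t = field.n_pairs
    if n_t < 32:
        raise ValueError("need at least 32 time points to resolve the band")
    comps = []
    for c in (field.u, field.v):
        series = c.reshape(n_t, -1) if keep is None else c[:, keep]
        comps.append(series)
    series = np.concatenate(comps, axis=1)  # (n_t, 2 * n_vectors)
    if series.shape[1] == 0:
        raise ValueError("no vectors to analyse")
    series = series - series.mean(axis=0, keepdims=True)
    spec = np.fft.rfft(series, axis=0)
    power = (np.abs(spec) ** 2).mean(axis=1) / n_t
    freqs = np.fft.rfftfreq(n_t, d=field.frame_interval)
    # drop the DC bin
    return PowerSpectrum(periods=1.0 / freqs[1:], power=power[1:],
                         embryo_id=embryo_id)


def call_oscillation(spectrum: PowerSpectrum,
                     band: tuple[float, float] = DEFAULT_BAND,
                     threshold: float = DEFAULT_THRESHOLD) -> OscillationCall:
    """Peak-over-background oscillation decision.

    Amplitude is the maximal power at periods within ``band`` (inclusive);
    background is the mean power of the whole DC-excluded spectrum. The
    embryo oscillates when amplitude/background >= threshold (the boundary
    case counts as oscillating).
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError("band low must be below band high")
    in_band = (spectrum.periods >= lo) & (spectrum.periods <= hi)
    if not in_band.any():
        raise ValueError("no spectral bins inside the period band")
    band_power = spectrum.power[in_band]
    amplitude = float(band_power.max())
    peak_period = float(spectrum.periods[in_band][int(np.argmax(band_power))])
    background = float(spectrum.power.mean())
    ratio = amplitude / background if background > 0 else (
        np.inf if amplitude > 0 else 1.0)
    return OscillationCall(
        amplitude=amplitude,
        peak_period=peak_period,
        background=background,
        ratio=float(ratio),
        is_oscillating=bool(ratio >= threshold),
        embryo_id=spectrum.embryo_id,
    )


def genotype_spectrum(spectra: Sequence[PowerSpectrum]) -> pd.DataFrame:
    """Pointwise mean ± SEM spectrum across embryos of one genotype.

    All spectra must share the period grid. With a single embryo the SEM is
    undefined and reported as NaN.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].periods
    for s in spectra[1:]:
        if s.periods.shape != grid.shape or not np.allclose(s.periods, grid):
            raise ValueError("spectra must share an identical period grid")
    powers = np.stack([s.power for s in spectra])
    mean = powers.mean(axis=0)
    n = powers.shape[0]
    sem = powers.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full_like(
        mean, np.nan)
    return pd.DataFrame({"period_s": grid, "power_mean": mean,
                         "power_sem": sem, "n": n})


def calls_to_frame(calls: Sequence[OscillationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": [c.embryo_id for c in calls],
            "amplitude": [c.amplitude for c in calls],
            "peak_period_s": [c.peak_period for c in calls],
            "background": [c.background for c in calls],
            "ratio": [c.ratio for c in calls],
            "oscillating": [c.is_oscillating for c in calls],
        }
    )
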