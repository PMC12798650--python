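"""Power spectral density estimation and rhythm-band peak detection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .neural_mass import BANDS

__all__ = ["PSD", "BandPeak", "welch_psd", "band_peak", "average_psds"]


@dataclass
class PSD:
    freqs: np.ndarray  # Hz, monotone increasing
    power: np.ndarray  # density, mV^2/Hz
    fs: float
    window_s: float
    overlap_frac: float

    def total_power(self) -> float:
        """Integral of the density (approximates the signal variance)."""
        return float(np.trapezoid(self.power, self.freqs))


class BandPeak(NamedTuple):
    freq: float
    band: str | None
    dominant: bool


def welch_psd(signal, fs: float, window_s: float = 2.0, overlap_frac: float = 0.5) -> PSD:
    """Welch-averaged periodogram (Hann window, density scaling)."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("welch_psd expects a single channel")
    nperseg = round(window_s * fs)
    if nperseg < 8:
        raise ValueError(f"window of {window_s} s at fs={fs} is too short ({nperseg} < 8 samples)")
    if nperseg > x.size:
        raise ValueError(f"window ({nperseg} samples) longer than signal ({x.size})")
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=round(overlap_frac * nperseg), scaling="density")
    return PSD(freqs=f, power=p, fs=fs, window_s=window_s, overlap_frac=overlap_frac)


def average_psds(psds) -> PSD:
    """Average spectral densities over trials (identical frequency grids)."""
    psds = list(psds)
    if not psds:
        raise ValueError("no PSDs to average")
    ref = psds[0]
    for q in psds[1:]:
        if not np.array_equal(q.freqs, ref.freqs):
            raise ValueError("PSDs have different frequency grids")
    power = np.mean([q.power for q in psds], axis=0)
    return PSD(freqs=ref.freqs.copy(), power=power, fs=ref.fs,
               window_s=ref.window_s, overlap_frac=ref.overlap_frac)


def band_peak(psd: PSD, bands: dict[str, tuple[float, float]] = BANDS,
              fmin: float = 2.0, prominence_db: float = 6.0) -> BandPeak:
    """Frequency of the global PSD maximum above ``fmin`` and its band.

    A peak less than ``prominence_db`` above the median power of the searched
    range is flagged as non-dominant (no clear rhythm); a peak outside every
    band returns ``band=None``.
    """
    if not bands:
        raise ValueError("empty band set")
    sel = psd.freqs >= fmin
    if not sel.any():
        raise ValueError(f"no frequencies above fmin={fmin}")
    f = psd.freqs[sel]
    p = psd.power[sel]
    k = int(np.argmax(p))
    fpk = float(f[k])
    med = float(np.median(p))
    dominant = med > 0 and 10.0 * np.log10(p[k] / med) >= prominence_db
    label = None
    for name, (lo, hi) in bands.items():
        if lo <= fpk <= hi:
            label = name
            break
    return BandPeak(freq=fpk, band=label, dominant=bool(dominant))


def band_power_fraction(psd: PSD, band: tuple[float, float]) -> float:
    """Fraction of total power (above 0 Hz) inside ``band``."""
    lo, hi = band
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    tot = psd.total_power()
    if tot <= 0:
        raise ValueError("PSD has no power")
    return float(np.trapezoid(psd.power[sel], psd.freqs[sel]) / tot)
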