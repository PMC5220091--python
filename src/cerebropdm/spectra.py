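"""Frequency-domain kernel representations and very-low-frequency band power.

The candidate linear biomarkers are the mean spectral power of the
first-order BP and CO2 kernels over the very-low-frequency (VLF) band
below 0.03 Hz, reported on a log10 scale.  Second-order kernels are
summarized by the mean squared magnitude of their 2-D DFT over the square
region f1, f2 < 0.03 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpectrum",
    "Kernel2Spectrum",
    "BandPowerFeature",
    "kernel_power_spectrum",
    "kernel2_magnitude_spectrum",
    "band_average_power",
    "VLF_BAND",
    "DEFAULT_NFFT",
]

#: VLF band in Hz, DC inclusive (the high-pass preprocessing removes
#: content below 0.005 Hz, so the DC bin carries negligible raw-signal power)
VLF_BAND = (0.0, 0.03)

#: default transform length at fs = 1 Hz: ~0.00098 Hz resolution,
#: >= 30 bins below 0.03 Hz
DEFAULT_NFFT = 1024


@dataclass(frozen=True)
class KernelSpectrum:
    """One-sided power spectrum |DFT(k)|^2 of a first-order kernel."""

    freqs: np.ndarray
    power: np.ndarray
    nfft: int
    fs: float


@dataclass(frozen=True)
class BandPowerFeature:
    band: tuple[float, float]
    mean_power: float
    log10_mean_power: float


@dataclass(frozen=True)
class Kernel2Spectrum:
    """Two-sided 2-D magnitude spectrum of a second-order kernel with the
    mean squared magnitude over the low-frequency square band."""

    freqs: np.ndarray          # full fftfreq grid (length nfft)
    magnitude: np.ndarray      # (nfft, nfft) |2-D DFT|
    band: tuple[float, float]
    band_mean_power: float


def kernel_power_spectrum(k, fs: float = 1.0,
                          nfft: int = DEFAULT_NFFT) -> KernelSpectrum:
    """Power spectrum of a zero-padded first-order kernel."""
    k = np.asarray(k, float)
    if nfft < k.size:
        raise ValueError(f"nfft={nfft} would truncate kernel of length {k.size}")
    spec = np.fft.rfft(k, nfft)
    return KernelSpectrum(freqs=np.fft.rfftfreq(nfft, d=1.0 / fs),
                          power=np.abs(spec) ** 2, nfft=nfft, fs=fs)


def band_average_power(spec: KernelSpectrum, f_lo: float = VLF_BAND[0],
                       f_hi: float = VLF_BAND[1]) -> BandPowerFeature:
    """Arithmetic mean of spectral power over bins f_lo <= f < f_hi."""
    if not 0 <= f_lo < f_hi <= spec.fs / 2:
        raise ValueError("band must satisfy 0 <= f_lo < f_hi <= fs/2")
    mask = (spec.freqs >= f_lo) & (spec.freqs < f_hi)
    if not mask.any():
        raise ValueError("no frequency bins in band; increase nfft")
    mean_power = float(spec.power[mask].mean())
    with np.errstate(divide="ignore"):
        log10p = float(np.log10(mean_power)) if mean_power > 0 else -np.inf
    return BandPowerFeature(band=(f_lo, f_hi), mean_power=mean_power,
                            log10_mean_power=log10p)


def kernel2_magnitude_spectrum(k2, fs: float = 1.0, nfft: int = DEFAULT_NFFT,
                               band: tuple[float, float] = VLF_BAND
                               ) -> Kernel2Spectrum:
    """|2-D DFT| of a zero-padded second-order kernel plus its band summary.

    The band summary is the mean of the squared magnitude over the square
    region ``band[0] <= f1, f2 < band[1]`` on the nonnegative-frequency
    quadrant.
    """
    k2 = np.asarray(k2, float)
    if k2.ndim != 2 or k2.shape[0] != k2.shape[1]:
        raise ValueError("k2 must be a square matrix")
    if nfft < k2.shape[0]:
        raise ValueError(f"nfft={nfft} would truncate kernel of size {k2.shape}")
    mag = np.abs(np.fft.fft2(k2, s=(nfft, nfft)))
    freqs = np.fft.fftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not sel.any():
        raise ValueError("no frequency bins in band; increase nfft")
    band_mean = float((mag[np.ix_(sel, sel)] ** 2).mean())
    return Kernel2Spectrum(freqs=freqs, magnitude=mag, band=band,
                           band_mean_power=band_mean)
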