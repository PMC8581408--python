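"""Passive cavitation detection (PCD) spectral metrics.

During focused-ultrasound blood-brain-barrier disruption, circulating
microbubbles oscillate in the acoustic field and re-radiate sound that a
wideband hydrophone records pulse by pulse. Microbubble activation (MBA) is
quantified here as a band ratio on the magnitude spectrum of the appended
(concatenated) pulse waveforms: the mean of the top-``k`` peak amplitudes in a
narrow band around the second harmonic of the transmit frequency, divided by
the same statistic in an equally narrow reference band placed where the
hydrophone is insensitive, so the denominator tracks the electronic noise
floor. MBA is dimensionless; a value near 1 means no harmonic emission above
noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


class ResolutionError(ValueError):
    """The acquisition is too short for the requested spectral band."""


@dataclass
class WaveformRecord:
    """Hydrophone voltage traces for one sonication session.

    Parameters
    ----------
    pulses
        Ordered per-pulse traces (volts). All pulses must have equal length.
    fs
        Sampling rate in Hz.
    """

    pulses: List[np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.pulses) == 0:
            raise ValueError("waveform record contains no pulses")
        self.pulses = [np.asarray(p, dtype=float) for p in self.pulses]
        lengths = {p.shape[0] for p in self.pulses}
        if len(lengths) != 1 or 0 in lengths:
            raise ValueError("all pulses must share the same nonzero length")

    @property
    def n_samples(self) -> int:
        return sum(p.shape[0] for p in self.pulses)


@dataclass
class SpectralConfig:
    """Band placement for the MBA ratio.

    ``reference_center`` has no default on purpose: the insensitive broadband
    region depends on the hydrophone hardware and must be stated explicitly.
    """

    reference_center: float
    harmonic_center: float = 2.22e6
    band_width: float = 200.0
    n_peaks: int = 5
    window: str = "rectangular"  # or "hann"

    def __post_init__(self) -> None:
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.window not in ("rectangular", "hann"):
            raise ValueError(f"unknown window {self.window!r}")
        lo1 = self.harmonic_center - self.band_width / 2
        hi1 = self.harmonic_center + self.band_width / 2
        lo2 = self.reference_center - self.band_width / 2
        hi2 = self.reference_center + self.band_width / 2
        if lo1 < hi2 and lo2 < hi1:
            raise ValueError("harmonic and reference bands must be disjoint")


@dataclass
class MBAResult:
    """MBA ratio and the band statistics it was formed from."""

    mba: float
    harmonic_top_mean: float
    reference_top_mean: float
    n_bins_harmonic: int
    n_bins_reference: int


def appended_spectrum(rec: WaveformRecord, window: str = "rectangular") -> Tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of the concatenated pulse train.

    Pulses are appended in acquisition order with no gap samples, giving a bin
    width of ``fs / total_samples``. Amplitudes are scaled so a full-length
    sinusoid of amplitude A at a bin-aligned frequency appears as A in its bin.

    Returns
    -------
    freqs, amps
        Frequency axis (Hz) and magnitude per bin.
    """
    x = np.concatenate(rec.pulses)
    n = x.shape[0]
    if window == "hann":
        x = x * np.hanning(n)
    elif window != "rectangular":
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(x)
    amps = np.abs(spec) / n
    # one-sided: double everything except DC (and Nyquist when n is even)
    if n % 2 == 0:
        amps[1:-1] *= 2.0
    else:
        amps[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    return freqs, amps


def band_top_peaks(
    freqs: np.ndarray,
    amps: np.ndarray,
    center: float,
    width: float,
    k: int,
) -> np.ndarray:
    """The ``k`` largest peak amplitudes in ``[center - width/2, center + width/2]``.

    A peak is a local maximum of the magnitude spectrum within the band
    (strictly greater than both neighbours). If the band holds fewer than
    ``k`` local maxima — e.g. a flat noise floor — the list is padded with the
    largest remaining bin amplitudes, so exactly ``k`` values are always
    returned, in descending order.
    """
    lo, hi = center - width / 2.0, center + width / 2.0
    idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if idx.size < k:
        needed = int(np.ceil(k * (freqs[1] - freqs[0]) / width * len(freqs))) if len(freqs) > 1 else k
        raise ResolutionError(
            f"band [{lo:g}, {hi:g}] Hz contains only {idx.size} bins (< {k}); "
            f"acquire a longer appended waveform so that fs / total_samples <= "
            f"{width / k:g} Hz (needed: at least {needed} total spectrum bins)"
        )
    band = amps[idx]
    interior = np.arange(1, band.size - 1)
    is_max = (band[interior] > band[interior - 1]) & (band[interior] > band[interior + 1])
    peak_pos = interior[is_max]
    peaks = np.sort(band[peak_pos])[::-1][:k]
    if peaks.size < k:
        rest = np.delete(band, peak_pos)
        pad = np.sort(rest)[::-1][: k - peaks.size]
        peaks = np.concatenate([peaks, pad])
        peaks = np.sort(peaks)[::-1]
    return peaks


def compute_mba(rec: WaveformRecord, cfg: SpectralConfig) -> MBAResult:
    """MBA = mean(top-k harmonic-band peaks) / mean(top-k reference-band peaks)."""
    nyquist = rec.fs / 2.0
    for name, c in (("harmonic", cfg.harmonic_center), ("reference", cfg.reference_center)):
        if not (0 < c - cfg.band_width / 2 and c + cfg.band_width / 2 < nyquist):
            raise ValueError(f"{name} band must lie within (0, fs/2) = (0, {nyquist:g}) Hz")
    freqs, amps = appended_spectrum(rec, window=cfg.window)
    lo = np.flatnonzero((freqs >= cfg.harmonic_center - cfg.band_width / 2) & (freqs <= cfg.harmonic_center + cfg.band_width / 2))
    ro = np.flatnonzero((freqs >= cfg.reference_center - cfg.band_width / 2) & (freqs <= cfg.reference_center + cfg.band_width / 2))
    harmonic = band_top_peaks(freqs, amps, cfg.harmonic_center, cfg.band_width, cfg.n_peaks)
    reference = band_top_peaks(freqs, amps, cfg.reference_center, cfg.band_width, cfg.n_peaks)
    ref_mean = float(np.mean(reference))
    if ref_mean == 0.0:
        raise ValueError("reference band is exactly zero (degenerate noiseless input)")
    harm_mean = float(np.mean(harmonic))
    return MBAResult(
        mba=harm_mean / ref_mean,
        harmonic_top_mean=harm_mean,
        reference_top_mean=ref_mean,
        n_bins_harmonic=int(lo.size),
        n_bins_reference=int(ro.size),
    )
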