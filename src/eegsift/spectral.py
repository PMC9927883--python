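"""Absolute and relative band power from Hamming-windowed periodograms.

PSDs are estimated on 4-s epochs with 50% overlap (0.25 Hz resolution at
128 Hz), log10-transformed with a small floor. Absolute band power is the
mean log-power over a band's bins, epoch-averaged; relative band power is the
linear in-band power over the total 2-44 Hz linear power, epoch-averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import ANALYSIS_DOMAIN, BandSpec, CANONICAL_BANDS, EpochSet, epoch

#: Floor applied before the log transform so zero bins stay finite.
LOG_FLOOR = 1e-20


@dataclass
class PsdEstimate:
    """Single-epoch power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    linear_power: np.ndarray
    log_power: np.ndarray


def psd_epoch(ep: np.ndarray, fs: float) -> PsdEstimate:
    """Hamming-windowed periodogram of one epoch, log10-transformed.

    Frequency resolution is ``fs / len(ep)`` (0.25 Hz for 4-s epochs). An
    all-zero epoch triggers the log floor and a warning.
    """
    ep = np.asarray(ep, dtype=float)
    if ep.ndim != 1:
        raise ValueError("psd_epoch expects a 1-D epoch")
    freqs, pxx = sps.periodogram(ep, fs=fs, window="hamming", detrend=False)
    if not np.any(pxx > 0):
        warnings.warn("all-zero epoch: PSD log floor applied", RuntimeWarning)
    logp = np.log10(np.maximum(pxx, LOG_FLOOR))
    return PsdEstimate(freqs=freqs, linear_power=pxx, log_power=logp)


def band_bins(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    """Boolean mask of bins in the closed interval [f_low, f_high]."""
    # tiny tolerance so grid values like 3.7500000000000004 are included
    return (freqs >= band.f_low - 1e-9) & (freqs <= band.f_high + 1e-9)


def band_power(psd: PsdEstimate, band: BandSpec) -> float:
    """Mean log-power over the band's frequency bins (one epoch)."""
    mask = band_bins(psd.freqs, band)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    return float(psd.log_power[mask].mean())


def absolute_psd(
    ts: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    epoch_length_s: float = 4.0,
    overlap_fraction: float = 0.5,
) -> dict[str, float]:
    """Per-band absolute PSD of one region's time course.

    Mean log10 power over the band bins, averaged across the overlapping
    epochs (149 epochs for the default 300 s at 128 Hz).
    """
    es: EpochSet = epoch(ts, epoch_length_s, overlap_fraction, fs)
    acc = {b.name: 0.0 for b in bands}
    for ep in es.epochs:
        psd = psd_epoch(ep, fs)
        for b in bands:
            acc[b.name] += band_power(psd, b)
    return {k: v / es.n_epochs for k, v in acc.items()}


def relative_psd(
    ts: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    epoch_length_s: float = 4.0,
    overlap_fraction: float = 0.5,
    domain: tuple[float, float] = ANALYSIS_DOMAIN,
) -> dict[str, float]:
    """Per-band relative PSD: in-band linear power over total-domain power.

    Computed per epoch on linear power (band sum over the 2-44 Hz total sum),
    then epoch-averaged. With the canonical bands the six values sum to 1 for
    every epoch since the bands tile the domain on the closed-bin convention.
    Raises if an epoch carries no power in the analysis domain.
    """
    es: EpochSet = epoch(ts, epoch_length_s, overlap_fraction, fs)
    dom = BandSpec("_domain", domain[0], domain[1])
    acc = {b.name: 0.0 for b in bands}
    for ep in es.epochs:
        psd = psd_epoch(ep, fs)
        total = psd.linear_power[band_bins(psd.freqs, dom)].sum()
        if total <= 0:
            raise ValueError("zero total power in analysis domain; relative PSD undefined")
        for b in bands:
            acc[b.name] += psd.linear_power[band_bins(psd.freqs, b)].sum() / total
    return {k: v / es.n_epochs for k, v in acc.items()}
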