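"""Frequency-band definitions, Chebyshev type-II band-pass filtering, epoching.

The six canonical resting-state bands tile the 2-44 Hz analysis domain:
delta (2-3.75), theta (4-7.75), alpha (8-11.75), beta1 (12-17.75),
beta2 (18-29.75) and gamma (30-44 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"invalid band edges: {self.f_low}-{self.f_high} Hz")


CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 2.0, 3.75),
    BandSpec("theta", 4.0, 7.75),
    BandSpec("alpha", 8.0, 11.75),
    BandSpec("beta1", 12.0, 17.75),
    BandSpec("beta2", 18.0, 29.75),
    BandSpec("gamma", 30.0, 44.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

#: Full analysis domain in Hz (total power for relative PSD).
ANALYSIS_DOMAIN: tuple[float, float] = (2.0, 44.0)


def get_band(name: str, bands: tuple[BandSpec, ...] = CANONICAL_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band: {name!r}")


def design_bandpass(
    band: BandSpec,
    fs: float,
    order: int = 12,
    stopband_db: float = 40.0,
    transition_hz: float = 0.5,
) -> np.ndarray:
    """Design a Chebyshev type-II band-pass filter as second-order sections.

    The stop-band edges are placed ``transition_hz`` beyond the band edges so
    attenuation reaches ``stopband_db`` outside the band with a short
    transition. Applied forward-backward (zero phase), so the effective
    stop-band attenuation doubles.
    """
    nyq = fs / 2.0
    if band.f_high >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.f_high} Hz >= Nyquist {nyq} Hz"
        )
    lo = max(band.f_low - transition_hz, 0.05)
    hi = min(band.f_high + transition_hz, nyq * 0.999)
    sos = sps.cheby2(order, stopband_db, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sos


def bandpass(
    ts: np.ndarray,
    band: BandSpec,
    fs: float,
    order: int = 12,
    stopband_db: float = 40.0,
    transition_hz: float = 0.5,
) -> np.ndarray:
    """Zero-phase Chebyshev-II band-pass of a signal (last axis = time).

    Forward-backward application (``sosfiltfilt``) cancels the filter's phase
    response so downstream instantaneous-phase estimates are undistorted.
    Output length equals input length.
    """
    ts = np.asarray(ts, dtype=float)
    sos = design_bandpass(band, fs, order=order, stopband_db=stopband_db,
                          transition_hz=transition_hz)
    if ts.shape[-1] <= 24:  # shorter than any sensible warm-up
        raise ValueError("signal too short for band-pass filtering")
    return sps.sosfiltfilt(sos, ts, axis=-1)


@dataclass
class EpochSet:
    """Epochs cut from one signal: matrix [n_epochs, epoch_samples]."""

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    overlap_fraction: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def n_epochs_for(n_samples: int, epoch_samples: int, hop: int) -> int:
    if n_samples < epoch_samples:
        return 0
    return (n_samples - epoch_samples) // hop + 1


def epoch(ts: np.ndarray, epoch_length_s: float, overlap_fraction: float,
          fs: float) -> EpochSet:
    """Segment a 1-D signal into (possibly overlapping) fixed-length epochs.

    The hop is ``epoch_samples * (1 - overlap_fraction)``; a trailing partial
    epoch is discarded. Raises ``ValueError`` if the signal is shorter than
    one epoch.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 1:
        raise ValueError("epoch() expects a 1-D signal")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    epoch_samples = int(round(epoch_length_s * fs))
    if epoch_samples < 1:
        raise ValueError("epoch length must be at least one sample")
    if len(ts) < epoch_samples:
        raise ValueError(
            f"signal of {len(ts)} samples shorter than one {epoch_samples}-sample epoch"
        )
    hop = int(round(epoch_samples * (1.0 - overlap_fraction)))
    hop = max(hop, 1)
    n = n_epochs_for(len(ts), epoch_samples, hop)
    starts = np.arange(n) * hop
    mat = np.stack([ts[s : s + epoch_samples] for s in starts])
    return EpochSet(mat, fs, epoch_length_s, overlap_fraction)
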