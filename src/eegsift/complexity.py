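"""Lempel-Ziv complexity of band-limited signals on 20-s epochs.

The band-filtered signal is binarized against the epoch mean of its Hilbert
envelope (instantaneous amplitude), parsed with the exhaustive-history LZ76
scheme, and the word count is normalized by ``log2(n) / n`` so values from
different epoch lengths are comparable (random sequences approach 1).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert

from .bands import epoch

try:  # jitted inner loop; plain Python fallback keeps the dependency soft
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


def binarize_envelope(band_ts_epoch: np.ndarray) -> np.ndarray:
    """Binarize one band-filtered epoch against its mean instantaneous amplitude.

    ``bit[t] = 1`` iff the modulus of the analytic signal at *t* exceeds its
    mean over the epoch. Invariant to positive rescaling of the input. A
    constant-zero epoch yields all zeros with a warning.
    """
    x = np.asarray(band_ts_epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("binarize_envelope expects a 1-D epoch")
    env = np.abs(hilbert(x))
    m = env.mean()
    if m == 0.0:
        warnings.warn("constant-zero epoch: binarized to all zeros", RuntimeWarning)
        return np.zeros(len(x), dtype=np.uint8)
    return (env > m).astype(np.uint8)


@njit(cache=False)
def _lz76_count(bits: np.ndarray) -> int:  # pragma: no cover - exercised via wrapper
    n = bits.shape[0]
    c = 1
    l = 1
    i = 0
    k = 1
    k_max = 1
    while True:
        if bits[i + k - 1] == bits[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lz76_complexity(bits: np.ndarray) -> int:
    """Number of words in the exhaustive-history LZ76 parse of a bit sequence."""
    b = np.ascontiguousarray(np.asarray(bits).ravel(), dtype=np.uint8)
    if len(b) < 2:
        raise ValueError("LZ76 requires a sequence of length >= 2")
    if not np.isin(b, (0, 1)).all():
        raise ValueError("LZ76 input must be binary")
    return int(_lz76_count(b))


def normalized_lzc(bits: np.ndarray) -> float:
    """LZ76 word count times ``log2(n) / n`` (asymptotic normalizer)."""
    n = len(bits)
    return lz76_complexity(bits) * np.log2(n) / n


def lzc_feature(
    band_ts: np.ndarray,
    fs: float,
    epoch_length_s: float = 20.0,
) -> float:
    """Normalized LZC of one region's band-filtered signal.

    Computed per consecutive non-overlapping 20-s epoch and averaged
    (15 epochs for the default 300 s recording).
    """
    es = epoch(band_ts, epoch_length_s, 0.0, fs)
    vals = [normalized_lzc(binarize_envelope(ep)) for ep in es.epochs]
    return float(np.mean(vals))
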