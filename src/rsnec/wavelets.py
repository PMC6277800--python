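"""Undecimated (stationary) wavelet transform.

Implements the à-trous stationary wavelet transform (SWT) with orthonormal
filter banks. Filters are applied by circular convolution with zero-upsampled
kernels, so every level produces a full-length coefficient series. The
filters are *not* renormalized between levels: the equivalent analysis filter
at every level has unit norm, which means white noise of variance ``s**2``
yields detail coefficients of variance ``s**2`` at every level. This is the
convention assumed by MAD-based noise estimation and BayesShrink
thresholding.

Perfect reconstruction holds exactly (up to float rounding) for circular
boundary handling because the conjugate quadrature pair satisfies
``|H(w)|**2 + |G(w)|**2 == 2`` pointwise.

Signals whose length is not a multiple of ``2**levels`` are extended at the
end by symmetric reflection; the padded region is trimmed from all returned
coefficient series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FILTERS",
    "SWTResult",
    "swt",
    "iswt",
    "swt_decompose",
    "band_for_level",
    "equivalent_filter_support",
]

# Orthonormal scaling (low-pass) decomposition filters. Values are the
# standard published coefficients; orthonormality and vanishing moments are
# asserted by the test suite to ~1e-12.
FILTERS: dict[str, np.ndarray] = {
    "db4": np.array(
        [
            -0.010597401784997278,
            0.032883011666982945,
            0.030841381835986965,
            -0.18703481171888114,
            -0.02798376941698385,
            0.6308807679295904,
            0.7148465705525415,
            0.23037781330885523,
        ]
    ),
    "sym8": np.array(
        [
            -0.0033824159510061256,
            -0.0005421323317911481,
            0.03169508781149298,
            0.007607487324917605,
            -0.1432942383508097,
            -0.061273359067658524,
            0.4813596512583722,
            0.7771857517005235,
            0.3644418948353314,
            -0.051945838107709037,
            -0.027219029917056003,
            0.049137179673607506,
            0.003808752013890615,
            -0.01495225833704823,
            -0.0003029205147213668,
            0.0018899503327594609,
        ]
    ),
}


def _filter_pair(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass/high-pass decomposition pair for a named wavelet."""
    try:
        h = FILTERS[wavelet]
    except KeyError:
        raise ValueError(
            f"unknown wavelet {wavelet!r}; available: {sorted(FILTERS)}"
        ) from None
    # Conjugate quadrature mirror: g[k] = (-1)^k h[L-1-k]
    L = len(h)
    g = np.array([(-1.0) ** k * h[L - 1 - k] for k in range(L)])
    return h, g


def _upsampled_kernel(filt: np.ndarray, step: int, n: int) -> np.ndarray:
    """Zero-upsampled filter kernel of length ``n`` for circular convolution."""
    span = (len(filt) - 1) * step + 1
    if span > n:
        raise ValueError(
            f"upsampled filter support {span} exceeds signal length {n}"
        )
    k = np.zeros(n)
    k[0 : span : step] = filt
    return k


def _cconv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution via the FFT."""
    return np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(kernel), n=len(x))


def _cconv_adjoint(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Adjoint (correlation) of :func:`_cconv`."""
    return np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(kernel)), n=len(x))


@dataclass
class SWTResult:
    """Full-length SWT coefficients.

    ``details[j-1]`` and ``approxs[j-1]`` hold the level-``j`` detail and
    approximation series (level 1 = finest). Series are trimmed to the
    original, unpadded signal length; ``padded_details``/``padded_approxs``
    retain the full padded-domain series for exact-reconstruction checks.
    """

    details: list[np.ndarray]
    approxs: list[np.ndarray]
    wavelet: str
    n_orig: int
    padded_details: list[np.ndarray]
    padded_approxs: list[np.ndarray]

    @property
    def levels(self) -> int:
        return len(self.details)


def swt(x: np.ndarray, levels: int, wavelet: str = "sym8") -> SWTResult:
    """Stationary wavelet transform of a 1-D series.

    Parameters
    ----------
    x
        Input series. Must have at least ``2**levels`` samples.
    levels
        Number of decomposition levels (>= 1).
    wavelet
        Filter-bank name (``"sym8"`` or ``"db4"``).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("swt expects a 1-D series")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n_orig = len(x)
    if n_orig < 2**levels:
        raise ValueError(
            f"series of length {n_orig} too short for {levels} SWT levels "
            f"(need >= {2 ** levels})"
        )
    h, g = _filter_pair(wavelet)

    block = 2**levels
    pad = (-n_orig) % block
    if pad:
        x = np.pad(x, (0, pad), mode="symmetric")
    n = len(x)
    # the coarsest upsampled kernel must fit inside the (padded) signal
    span = (len(h) - 1) * 2 ** (levels - 1) + 1
    if span > n:
        raise ValueError(
            f"series of length {n_orig} too short for {levels} levels of the "
            f"{wavelet} filter (support {span})"
        )

    details: list[np.ndarray] = []
    approxs: list[np.ndarray] = []
    a = x
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        kh = _upsampled_kernel(h, step, n)
        kg = _upsampled_kernel(g, step, n)
        d = _cconv(a, kg)
        a = _cconv(a, kh)
        details.append(d)
        approxs.append(a)
    return SWTResult(
        details=[d[:n_orig] for d in details],
        approxs=[a_[:n_orig] for a_ in approxs],
        wavelet=wavelet,
        n_orig=n_orig,
        padded_details=details,
        padded_approxs=approxs,
    )


def iswt(res: SWTResult) -> np.ndarray:
    """Invert :func:`swt` exactly on the padded domain, trimmed to the input.

    Uses the adjoint filter pair: because ``|H|**2 + |G|**2 == 2`` for the
    conjugate quadrature pair, one half of the sum of adjoint-filtered
    approximation and detail recovers the previous approximation exactly.
    """
    h, g = _filter_pair(res.wavelet)
    n = len(res.padded_approxs[-1])
    a = res.padded_approxs[-1]
    for j in range(res.levels, 0, -1):
        step = 2 ** (j - 1)
        kh = _upsampled_kernel(h, step, n)
        kg = _upsampled_kernel(g, step, n)
        a = 0.5 * (
            _cconv_adjoint(a, kh) + _cconv_adjoint(res.padded_details[j - 1], kg)
        )
    return a[: res.n_orig]


def swt_decompose(x: np.ndarray, levels: int, wavelet: str = "sym8") -> SWTResult:
    """Alias of :func:`swt` (kept as the public decomposition entry point)."""
    return swt(x, levels, wavelet)


def band_for_level(level: int, tr: float) -> tuple[float, float]:
    """Dyadic frequency band ``[f_N / 2**j, f_N / 2**(j-1)]`` of level ``j``.

    ``f_N = 1 / (2 * TR)`` is the Nyquist frequency in Hz.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    f_nyq = 1.0 / (2.0 * tr)
    return f_nyq / 2**level, f_nyq / 2 ** (level - 1)


def equivalent_filter_support(wavelet: str, level: int) -> int:
    """Support (in samples) of the equivalent level-``j`` analysis filter.

    For an ``L``-tap base filter the cascade of ``j`` zero-upsampled stages
    has support ``(L - 1) * (2**j - 1) + 1``.
    """
    L = len(_filter_pair(wavelet)[0])
    return (L - 1) * (2**level - 1) + 1
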