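"""Wavelet-based regularity (sample entropy) of ROI time series.

The regularity of a single ROI series is measured per dyadic wavelet scale:
the series is decomposed with an undecimated SWT, the noise level is
estimated from the finest detail subband (robust MAD estimator), each
scale's tolerance is ``r = r0 * sigma + t`` with ``t`` a BayesShrink-style
scale-dependent threshold, and sample entropy is computed over lagged
patterns of the detail coefficients (lag ``2**j`` at level ``j`` by
default). Patterns touching motion-contaminated coefficients — identified
by transforming the binary scrub-flag series with the same wavelet — are
excluded. The ROI's entropy is the mean over the selected scales, and
network entropies are unweighted means over each network's ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import NetworkMap
from .wavelets import band_for_level, swt

__all__ = [
    "EntropyParams",
    "SampleEntropyResult",
    "estimate_noise_sigma",
    "bayes_shrink_threshold",
    "build_patterns",
    "contaminate_indices",
    "count_matches",
    "sample_entropy",
    "select_scales",
    "roi_entropy",
    "rsn_entropy",
    "select_r0",
    "R0_GRID",
]

#: Candidate tolerance scalings for the range-maximization selection rule.
R0_GRID = (0.10, 0.15, 0.20, 0.25, 0.30)

MIN_PATTERNS = 50
CONTAMINATION_EPS = 1e-10


@dataclass
class EntropyParams:
    """Tunable parameters of the regularity analysis."""

    m: int = 1
    r0: float = 0.2
    wavelet: str = "sym8"
    band: tuple[float, float] = (0.01, 0.10)
    n_scales: int = 2
    min_patterns: int = MIN_PATTERNS
    #: per-level pattern lags; ``None`` means ``delta_j = 2**j``
    lags: Mapping[int, int] | None = None

    def lag(self, level: int) -> int:
        if self.lags is not None and level in self.lags:
            d = int(self.lags[level])
        else:
            d = 2**level
        if d < 1:
            raise ValueError("pattern lag must be >= 1")
        return d


def estimate_noise_sigma(finest_details: np.ndarray) -> float:
    """Robust noise level: ``median(|coeffs|) / 0.6745``."""
    c = np.asarray(finest_details, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient series")
    return float(np.median(np.abs(c)) / 0.6745)


def bayes_shrink_threshold(level_coeffs: np.ndarray, sigma_noise: float) -> float:
    """Scale-dependent threshold ``t = sigma_noise**2 / sigma_signal``.

    ``sigma_signal**2 = max(var(coeffs) - sigma_noise**2, 0)``; when the
    subband is all noise (``sigma_signal == 0``) the threshold falls back to
    ``max(|coeffs|)``.
    """
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be >= 0")
    c = np.asarray(level_coeffs, dtype=float)
    if sigma_noise == 0.0:
        return 0.0
    var = float(np.var(c))
    sig2 = max(var - sigma_noise**2, 0.0)
    if sig2 > 0.0:
        return sigma_noise**2 / np.sqrt(sig2)
    return float(np.max(np.abs(c)))


def build_patterns(
    coeffs: np.ndarray,
    m: int,
    delta: int,
    contaminated: np.ndarray | Sequence[int] | None = None,
) -> np.ndarray:
    """Admissible lagged patterns as an ``N_m x m`` matrix.

    Pattern ``i`` is ``(coeffs[i], coeffs[i + delta], ...,
    coeffs[i + (m-1) * delta])``; it is inadmissible if any of its indices is
    contaminated.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    c = np.asarray(coeffs, dtype=float)
    n = len(c)
    span = (m - 1) * delta
    if n - span <= 0:
        return np.empty((0, m))
    starts = np.arange(n - span)
    cols = np.stack([c[starts + j * delta] for j in range(m)], axis=1)
    if contaminated is not None:
        bad = np.zeros(n, dtype=bool)
        bad[np.asarray(list(contaminated), dtype=int)] = True
        keep = ~np.any(
            np.stack([bad[starts + j * delta] for j in range(m)], axis=1), axis=1
        )
        cols = cols[keep]
    return cols


def contaminate_indices(
    flags: np.ndarray, levels: int, wavelet: str = "sym8"
) -> list[np.ndarray]:
    """Per-level contaminated coefficient indices from a binary flag series.

    The flag series is run through the same SWT; an index is contaminated at
    level j when either the detail or the approximation channel at that
    level is non-zero there (conservative: both channels are used).
    """
    f = np.asarray(flags, dtype=float)
    if not f.any():
        return [np.empty(0, dtype=int) for _ in range(levels)]
    res = swt(f, levels, wavelet)
    out = []
    for j in range(levels):
        hit = (np.abs(res.details[j]) > CONTAMINATION_EPS) | (
            np.abs(res.approxs[j]) > CONTAMINATION_EPS
        )
        out.append(np.flatnonzero(hit))
    return out


def count_matches(patterns: np.ndarray, r: float, chunk: int = 512) -> int:
    """Ordered pairs (p != q) with Chebyshev distance strictly below ``r``."""
    p = np.asarray(patterns, dtype=float)
    n = len(p)
    if n < 2 or r <= 0:
        return 0
    if p.shape[1] == 1:
        s = np.sort(p[:, 0])
        lo = np.searchsorted(s, s - r, side="right")
        hi = np.searchsorted(s, s + r, side="left")
        return int((hi - lo - 1).sum())
    cols = [np.ascontiguousarray(p[:, k]) for k in range(p.shape[1])]
    total = 0
    for start in range(0, n, chunk):
        blk = slice(start, min(start + chunk, n))
        ok = np.abs(cols[0][blk, None] - cols[0][None, :]) < r
        for c in cols[1:]:
            ok &= np.abs(c[blk, None] - c[None, :]) < r
        total += int(ok.sum()) - (blk.stop - blk.start)  # remove self-pairs
    return total


@dataclass
class SampleEntropyResult:
    h: float | None
    cm: float
    cm1: float
    n_m: int
    n_m1: int
    reliable: bool = True

    @property
    def defined(self) -> bool:
        return self.h is not None


def sample_entropy(
    patterns_m: np.ndarray,
    patterns_m1: np.ndarray,
    r: float,
    min_patterns: int = MIN_PATTERNS,
) -> SampleEntropyResult:
    """Sample entropy ``H = -ln(Cm1 / Cm)`` from two pattern sets.

    ``Cm`` is the fraction of ordered admissible pairs within Chebyshev
    distance ``r`` (strict inequality) among the length-``m`` patterns,
    ``Cm1`` the analogue at length ``m + 1``. Fewer than ``min_patterns``
    patterns at either length marks the estimate unreliable; a zero match
    count leaves ``H`` undefined (never a numeric sentinel).
    """
    n_m, n_m1 = len(patterns_m), len(patterns_m1)
    if n_m < min_patterns or n_m1 < min_patterns:
        return SampleEntropyResult(None, 0.0, 0.0, n_m, n_m1, reliable=False)
    cm = count_matches(patterns_m, r) / (n_m * (n_m - 1))
    cm1 = count_matches(patterns_m1, r) / (n_m1 * (n_m1 - 1))
    if cm == 0.0 or cm1 == 0.0:
        return SampleEntropyResult(None, cm, cm1, n_m, n_m1)
    return SampleEntropyResult(float(-np.log(cm1 / cm)), cm, cm1, n_m, n_m1)


def select_scales(
    tr: float,
    band: tuple[float, float] = (0.01, 0.10),
    n_scales: int | None = 2,
) -> list[tuple[int, tuple[float, float]]]:
    """Dyadic levels most sensitive to a target frequency band.

    A level qualifies when its band ``[f_N / 2**j, f_N / 2**(j-1)]``
    overlaps the target band by at least half of the level band's width;
    of the qualifying levels the ``n_scales`` finest are returned
    (``None`` keeps them all). For TR = 2 s and band [0.01, 0.10] Hz this
    selects levels 2 (0.0625-0.125 Hz) and 3 (0.03125-0.0625 Hz).
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi):
        raise ValueError("band must satisfy 0 <= f_lo < f_hi")
    qualifying: list[tuple[int, tuple[float, float]]] = []
    j = 1
    while True:
        lo, hi = band_for_level(j, tr)
        overlap = max(0.0, min(hi, f_hi) - max(lo, f_lo))
        if overlap >= 0.5 * (hi - lo):
            qualifying.append((j, (lo, hi)))
        if hi <= f_lo:  # level bands now entirely below the target band
            break
        j += 1
        if j > 60:
            break
    if not qualifying:
        raise ValueError(
            f"no dyadic level overlaps band {band} at TR {tr} by >= 50%"
        )
    if n_scales is not None:
        qualifying = qualifying[:n_scales]
    return qualifying


@dataclass
class ROIEntropy:
    h: float | None  # mean over levels with defined entropy
    per_level: dict[int, SampleEntropyResult] = field(default_factory=dict)


def roi_entropy(
    ts: np.ndarray,
    flags: np.ndarray | None,
    tr: float,
    params: EntropyParams | None = None,
) -> ROIEntropy:
    """Wavelet-regularity entropy of one ROI series.

    For each selected level: detail coefficients, coefficient sigma,
    BayesShrink threshold (noise sigma from the finest subband), tolerance
    ``r = r0 * sigma + t``, lagged patterns at m and m+1 with motion
    contamination masking, and sample entropy. The ROI value is the mean
    over levels with a defined estimate; all-undefined gives ``None``.
    """
    params = params or EntropyParams()
    x = np.asarray(ts, dtype=float)
    selected = select_scales(tr, params.band, params.n_scales)
    max_level = max(j for j, _ in selected)
    dec = swt(x, max_level, params.wavelet)
    sigma_noise = estimate_noise_sigma(dec.details[0])

    if flags is not None and np.asarray(flags).any():
        contaminated = contaminate_indices(
            np.asarray(flags), max_level, params.wavelet
        )
    else:
        contaminated = [None] * max_level

    per_level: dict[int, SampleEntropyResult] = {}
    values = []
    scale = max(float(np.abs(x).max()), 1.0)
    for j, _band in selected:
        c = dec.details[j - 1]
        sigma = float(np.std(c))
        if sigma <= 1e-10 * scale:
            continue  # degenerate level: skipped, entropy missing here
        t = bayes_shrink_threshold(c, sigma_noise)
        r = params.r0 * sigma + t
        delta = params.lag(j)
        bad = contaminated[j - 1]
        pm = build_patterns(c, params.m, delta, bad)
        pm1 = build_patterns(c, params.m + 1, delta, bad)
        res = sample_entropy(pm, pm1, r, params.min_patterns)
        per_level[j] = res
        if res.defined:
            values.append(res.h)
    h = float(np.mean(values)) if values else None
    return ROIEntropy(h=h, per_level=per_level)


@dataclass
class EntropyProfile:
    subject_id: str
    networks: tuple[str, ...]
    values: np.ndarray  # per-network mean entropy, NaN where missing
    roi_h: np.ndarray  # per-ROI entropy, NaN where missing

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()


def rsn_entropy(
    ts: np.ndarray,
    flags: np.ndarray | None,
    network_map: NetworkMap,
    tr: float,
    params: EntropyParams | None = None,
    subject_id: str = "",
) -> EntropyProfile:
    """Per-network mean entropy profile for one subject's ROI table."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[1] != network_map.n_rois:
        raise ValueError("ROI count does not match network map")
    roi_h = np.full(ts.shape[1], np.nan)
    for i in range(ts.shape[1]):
        roi_h[i] = _nan(roi_entropy(ts[:, i], flags, tr, params).h)
    values = np.full(len(network_map.networks), np.nan)
    for k, net in enumerate(network_map.networks):
        hs = roi_h[network_map.indices_for(net)]
        hs = hs[~np.isnan(hs)]
        if hs.size:
            values[k] = hs.mean()
    return EntropyProfile(
        subject_id=subject_id,
        networks=network_map.networks,
        values=values,
        roi_h=roi_h,
    )


def _nan(v: float | None) -> float:
    return np.nan if v is None else v


def select_r0(
    profiles_by_r0: Mapping[float, np.ndarray],
    prefer: float = 0.2,
) -> float:
    """Tolerance scaling maximizing the cohort-wide entropy range.

    ``profiles_by_r0`` maps each candidate r0 to a subjects x networks
    matrix of entropies (NaNs ignored). Ties go to the candidate closest to
    ``prefer`` (then to the smaller r0).
    """
    if not profiles_by_r0:
        raise ValueError("no candidate r0 values")
    ranges = {}
    for r0, mat in profiles_by_r0.items():
        mat = np.asarray(mat, dtype=float)
        finite = mat[np.isfinite(mat)]
        ranges[r0] = float(finite.max() - finite.min()) if finite.size else -np.inf
    best = max(ranges.values())
    ties = [r0 for r0, rg in ranges.items() if abs(rg - best) <= 1e-12]
    ties.sort(key=lambda r0: (abs(r0 - prefer), r0))
    return ties[0]


def normal_iid_entropy(r0: float) -> float:
    """Closed-form large-sample entropy of iid normal data at ``r = r0*sigma``.

    With m = 1, lag 1 and no threshold inflation the conditional match
    probability of independent standard-normal coordinates is
    ``2 * Phi(r0 / sqrt(2)) - 1``; the entropy limit is its negative log.
    """
    return float(-np.log(2.0 * stats.norm.cdf(r0 / np.sqrt(2.0)) - 1.0))
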