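"""Functional connectivity, RSN-level reduction, and the primary component.

Per subject: Pearson correlations between all ROI time series over unflagged
frames, reduced to an ``K x K`` network summary (mean within-network pair
correlation on the diagonal, mean between-network correlation off it) and
vectorized into a fixed slot layout (``K`` intra slots in canonical network
order, then the upper triangle row-major). Cohort feature vectors are
compiled into a matrix ``M`` whose centered SVD yields component scores; the
primary score ``c1`` carries a documented sign convention (mean sensory
intra-network loading positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NetworkMap
from .networks import SENSORY_NETWORKS, n_feature_slots

__all__ = [
    "FCError",
    "compute_fc",
    "reduce_to_rsn",
    "vectorize",
    "devectorize",
    "slot_names",
    "PCAResult",
    "compile_and_pca",
]

MIN_USABLE_FRAMES = 30


class FCError(ValueError):
    """Subject-level FC computation failure (propagates as an exclusion)."""


def compute_fc(ts: np.ndarray, flags: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation matrix over unflagged frames.

    Raises :class:`FCError` if fewer than 30 usable frames remain.
    """
    ts = np.asarray(ts, dtype=float)
    if flags is not None:
        flags = np.asarray(flags)
        if len(flags) != ts.shape[0]:
            raise FCError("flag series length does not match frame count")
        ts = ts[flags == 0]
    if ts.shape[0] < MIN_USABLE_FRAMES:
        raise FCError(
            f"only {ts.shape[0]} usable frames (< {MIN_USABLE_FRAMES})"
        )
    fc = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc


def reduce_to_rsn(fc: np.ndarray, network_map: NetworkMap) -> np.ndarray:
    """Network-level summary matrix of an ROI-level FC matrix.

    Diagonal entry k: mean over unordered within-network-k ROI pairs
    (self-correlations excluded). Off-diagonal (k, l): mean over all cross
    pairs. A network with fewer than 2 ROIs makes the intra average
    undefined and raises.
    """
    fc = np.asarray(fc)
    if fc.shape[0] != network_map.n_rois:
        raise FCError(
            f"FC matrix size {fc.shape[0]} != mapped ROI count {network_map.n_rois}"
        )
    nets = network_map.networks
    k = len(nets)
    out = np.empty((k, k))
    idx = [network_map.indices_for(n) for n in nets]
    for a in range(k):
        if len(idx[a]) < 2:
            raise FCError(f"network {nets[a]} has < 2 ROIs; intra average undefined")
        block = fc[np.ix_(idx[a], idx[a])]
        iu = np.triu_indices(len(idx[a]), 1)
        out[a, a] = block[iu].mean()
        for b in range(a + 1, k):
            cross = fc[np.ix_(idx[a], idx[b])]
            out[a, b] = out[b, a] = cross.mean()
    return out


def slot_names(networks: tuple[str, ...]) -> list[str]:
    """Feature-slot labels in the fixed layout order."""
    names = [f"{n}:{n}" for n in networks]
    k = len(networks)
    for a in range(k):
        for b in range(a + 1, k):
            names.append(f"{networks[a]}:{networks[b]}")
    return names


def vectorize(rsn: np.ndarray) -> np.ndarray:
    """Flatten a network summary matrix into the fixed slot layout."""
    rsn = np.asarray(rsn)
    k = rsn.shape[0]
    iu = np.triu_indices(k, 1)
    return np.concatenate([np.diag(rsn), rsn[iu]])


def devectorize(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    vec = np.asarray(vec)
    # solve k + k(k-1)/2 == len(vec)
    k = int(round((np.sqrt(8 * len(vec) + 1) - 1) / 2))
    if n_feature_slots(k) != len(vec):
        raise ValueError(f"vector length {len(vec)} is not a valid slot count")
    out = np.zeros((k, k))
    np.fill_diagonal(out, vec[:k])
    iu = np.triu_indices(k, 1)
    out[iu] = vec[k:]
    out.T[iu] = vec[k:]
    return out


@dataclass
class PCAResult:
    m: np.ndarray  # N x F compiled feature matrix (uncentered)
    u: np.ndarray
    s: np.ndarray  # singular values
    vt: np.ndarray
    scores: np.ndarray  # N x n_components, scores = U @ diag(S)
    variance_explained: np.ndarray
    column_means: np.ndarray
    centered: bool

    @property
    def c1(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def v1(self) -> np.ndarray:
        return self.vt[0]


def compile_and_pca(
    vectors: np.ndarray,
    networks: tuple[str, ...],
    n_components: int | None = None,
    center: bool = True,
    sensory_networks: tuple[str, ...] = SENSORY_NETWORKS,
) -> PCAResult:
    """Compile per-subject feature vectors and extract principal components.

    Columns are mean-centered (configurable), the centered matrix is
    decomposed by SVD, and scores are ``U @ diag(S)``. The primary loading
    vector is oriented so that the mean of its intra-network loadings over
    the sensory network set is positive (ties broken by forcing the
    largest-magnitude loading positive); remaining components get the
    largest-magnitude-positive convention.
    """
    m = np.asarray(vectors, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected an N x F matrix of feature vectors")
    n, f = m.shape
    if n < 3:
        raise ValueError(f"PCA needs at least 3 subjects, got {n}")
    if f != n_feature_slots(len(networks)):
        raise ValueError(
            f"feature length {f} does not match {len(networks)} networks"
        )
    means = m.mean(axis=0) if center else np.zeros(f)
    mc = m - means
    u, s, vt = np.linalg.svd(mc, full_matrices=False)
    if n_components is not None:
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]

    total = (s**2).sum()
    var_exp = s**2 / total if total > 0 else np.zeros_like(s)

    # sign conventions
    sensory_idx = [i for i, net in enumerate(networks) if net in sensory_networks]
    for comp in range(vt.shape[0]):
        if comp == 0 and sensory_idx:
            key = vt[0, sensory_idx].mean()
            if key == 0.0:
                key = vt[0, np.argmax(np.abs(vt[0]))]
        else:
            key = vt[comp, np.argmax(np.abs(vt[comp]))]
        if key < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0

    scores = u * s
    return PCAResult(
        m=m,
        u=u,
        s=s,
        vt=vt,
        scores=scores,
        variance_explained=var_exp,
        column_means=means,
        centered=center,
    )
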