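"""Synthetic cohort generator with planted, recoverable structure.

Each subject gets a latent score ``z`` that (i) shifts their ROI-pair
correlation targets along a signed per-network contrast and (ii) modulates
the temporal regularity (AR(1) coefficient) of each network's signals with a
group-specific coupling strength. Severity scores for cases follow a planted
linear model on the subject's entropy score, so every downstream statistic
has a known ground truth.

Signals are AR(1) processes whose innovations share a block-structured
correlation matrix (imposed via the Cholesky factor, so stationary
cross-correlations equal the target exactly when AR coefficients match
within a block), optionally band-pass filtered to the slow-fluctuation band
the analysis pipeline assumes, then standardized per ROI.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import io as rio
from .networks import CANONICAL_NETWORKS, DEFAULT_NETWORK_SIGNS, n_feature_slots

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "slot_weights",
    "build_block_covariance",
    "effective_phi",
    "generate_subject_series",
    "simulate_cohort",
    "generate_cohort",
]

PSD_TOL = 1e-8


@dataclass
class SimulationConfig:
    n_control: int = 30
    n_case: int = 30
    n_frames: int = 300
    tr: float = 2.0
    networks: tuple[str, ...] = CANONICAL_NETWORKS
    rois_per_network: tuple[int, ...] = (24,) * 11  # 264 ROIs total
    intra_corr: float = 0.25
    inter_corr: float = 0.05
    network_weights: tuple[float, ...] | None = None  # default: signed preset
    latent_sd: float = 0.10
    group_fc_shift: float = 0.05
    entropy_base: tuple[float, ...] | float = 0.45  # AR(1) phi per network
    coupling_control: float = 0.25
    coupling_case: float = 0.08
    severity_intercept: float = 12.0
    severity_slope: float = -10.0
    severity_noise_sd: float = 1.0
    flag_rate: float = 0.0
    fd_threshold: float = 0.3
    bandpass: tuple[float, float] | None = (0.01, 0.10)
    noise_sd: float = 0.05  # broadband measurement noise, relative units
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.networks)
        if len(self.rois_per_network) != k:
            raise ValueError("rois_per_network length must match networks")
        if any(n < 2 for n in self.rois_per_network):
            raise ValueError("every network needs at least 2 ROIs")
        if self.network_weights is None:
            self.network_weights = tuple(
                DEFAULT_NETWORK_SIGNS.get(n, 1.0) for n in self.networks
            )
        if len(self.network_weights) != k:
            raise ValueError("network_weights length must match networks")
        if np.isscalar(self.entropy_base):
            self.entropy_base = (float(self.entropy_base),) * k
        if len(self.entropy_base) != k:
            raise ValueError("entropy_base length must match networks")
        if any(not (0.0 <= p < 1.0) for p in self.entropy_base):
            raise ValueError("entropy_base coefficients must lie in [0, 1)")
        if not (0.0 <= self.flag_rate < 1.0):
            raise ValueError("flag_rate must lie in [0, 1)")
        if self.bandpass is not None:
            lo, hi = self.bandpass
            if not (0.0 < lo < hi < 1.0 / (2.0 * self.tr)):
                raise ValueError("bandpass must satisfy 0 < lo < hi < Nyquist")
        # baseline correlation target must be PSD
        base = build_block_covariance(self, 0.0, 0, _check_only=True)
        if np.linalg.eigvalsh(base).min() < -PSD_TOL:
            raise ValueError(
                "baseline intra/inter correlation structure is not positive "
                "semidefinite"
            )

    @property
    def n_rois(self) -> int:
        return int(sum(self.rois_per_network))

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_case

    def roi_networks(self) -> np.ndarray:
        """Per-ROI network index array."""
        return np.repeat(np.arange(len(self.networks)), self.rois_per_network)


@dataclass
class GroundTruth:
    subject_ids: list[str]
    groups: np.ndarray
    latent: np.ndarray  # standard-normal latent per subject
    fc_latent: np.ndarray  # latent_sd * latent (units of correlation shift)
    entropy_score: np.ndarray  # coupling_g * latent
    modulation: np.ndarray  # N x K per-network entropy modulation
    coupling_control: float
    coupling_case: float
    severity_intercept: float
    severity_slope: float
    severity: np.ndarray  # NaN for controls
    network_weights: tuple[float, ...]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, np.ndarray):
                d[key] = val.tolist()
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        for key in ("groups", "latent", "fc_latent", "entropy_score",
                    "modulation", "severity"):
            d[key] = np.asarray(d[key])
        d["network_weights"] = tuple(d["network_weights"])
        return cls(**d)


def slot_weights(config: SimulationConfig) -> np.ndarray:
    """Signed contrast over the feature slots (intra then upper-triangle).

    Intra slot of network k carries the network weight ``u_k``; the (k, l)
    inter slot carries ``(u_k + u_l) / 2``.
    """
    u = np.asarray(config.network_weights, dtype=float)
    k = len(u)
    w = np.empty(n_feature_slots(k))
    w[:k] = u
    pos = k
    for a in range(k):
        for b in range(a + 1, k):
            w[pos] = 0.5 * (u[a] + u[b])
            pos += 1
    return w


def _nearest_correlation(a: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped projection to a PSD matrix with unit diagonal."""
    vals, vecs = np.linalg.eigh(a)
    vals = np.clip(vals, PSD_TOL, None)
    b = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(b))
    b = b / np.outer(d, d)
    np.fill_diagonal(b, 1.0)
    return 0.5 * (b + b.T)


def build_block_covariance(
    config: SimulationConfig,
    subject_latent: float,
    group: int,
    _check_only: bool = False,
) -> np.ndarray:
    """ROI x ROI correlation target with planted block structure.

    Within-network blocks sit at ``intra_corr + shift``, between-network
    blocks at ``inter_corr + shift``, where the shift for a slot is
    ``(group_fc_shift * group + subject_latent)`` times that slot's contrast
    weight. Entries are clipped to [-0.95, 0.95]; if the result is not PSD it
    is projected to the nearest PSD correlation matrix.
    """
    k = len(config.networks)
    u = np.asarray(config.network_weights, dtype=float)
    amp = config.group_fc_shift * group + subject_latent
    block = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            if a == b:
                block[a, b] = config.intra_corr + amp * u[a]
            else:
                block[a, b] = config.inter_corr + amp * 0.5 * (u[a] + u[b])
    block = np.clip(block, -0.95, 0.95)
    idx = config.roi_networks()
    cov = block[np.ix_(idx, idx)]
    np.fill_diagonal(cov, 1.0)
    if _check_only:
        return cov
    if np.linalg.eigvalsh(cov).min() < PSD_TOL:
        cov = _nearest_correlation(cov)
        if np.linalg.eigvalsh(cov).min() < -PSD_TOL:
            raise ValueError("correlation target not PSD after projection")
    return cov


def effective_phi(config: SimulationConfig, modulation: np.ndarray) -> np.ndarray:
    """Per-network AR(1) coefficients under an entropy modulation.

    Higher modulation lowers phi (less repetitive signal); monotone
    non-increasing in the modulation, clipped to [0, 0.95].
    """
    base = np.asarray(config.entropy_base, dtype=float)
    return np.clip(base - np.asarray(modulation, dtype=float), 0.0, 0.95)


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_subject_series(
    cov_target: np.ndarray,
    config: SimulationConfig,
    entropy_modulation: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's (frames x ROIs) series and framewise-displacement series.

    Every ROI in network k follows AR(1) with the network's effective
    coefficient; innovations are drawn jointly with a PSD factor of
    ``cov_target``. The series is optionally band-pass filtered and
    standardized per ROI. FD values exceed ``fd_threshold`` exactly on
    frames drawn at ``flag_rate``.
    """
    t, r = config.n_frames, cov_target.shape[0]
    phi_net = effective_phi(config, entropy_modulation)
    phi = phi_net[config.roi_networks()]

    burn = 100
    innov = rng.standard_normal((t + burn, r)) @ _psd_factor(cov_target).T
    x = np.empty((t + burn, r))
    for k in range(r):
        x[:, k] = sps.lfilter([1.0], [1.0, -phi[k]], innov[:, k])
    x = x[burn:]

    if config.bandpass is not None:
        lo, hi = config.bandpass
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=1.0 / config.tr,
                         output="sos")
        x = sps.sosfiltfilt(sos, x, axis=0)

    if config.noise_sd > 0:
        # broadband measurement noise keeps the finest subband
        # noise-dominated, as the regularity analysis assumes
        x = x / x.std(axis=0)
        x = x + config.noise_sd * rng.standard_normal(x.shape)

    x = (x - x.mean(axis=0)) / x.std(axis=0)

    flagged = rng.random(t) < config.flag_rate
    fd = rng.uniform(0.02, 0.95 * config.fd_threshold, size=t)
    if flagged.any():
        fd[flagged] = config.fd_threshold + rng.exponential(0.08, flagged.sum()) + 1e-6
    return x, fd


def simulate_cohort(config: SimulationConfig) -> tuple[rio.Cohort, GroundTruth]:
    """Generate an in-memory cohort plus its ground truth (deterministic)."""
    rng = np.random.default_rng(config.seed)
    k = len(config.networks)
    n = config.n_subjects
    groups = np.concatenate(
        [np.zeros(config.n_control, dtype=int), np.ones(config.n_case, dtype=int)]
    )
    ids = [
        f"{'case' if g else 'ctl'}{i:04d}" for i, g in enumerate(groups)
    ]
    z = rng.standard_normal(n)
    coupling = np.where(groups == 1, config.coupling_case, config.coupling_control)
    fc_latent = config.latent_sd * z
    entropy_score = coupling * z
    u = np.asarray(config.network_weights, dtype=float)
    modulation = entropy_score[:, None] * u[None, :]

    severity = np.full(n, np.nan)
    case_idx = np.flatnonzero(groups == 1)
    noise = rng.normal(0.0, config.severity_noise_sd, size=len(case_idx))
    severity[case_idx] = np.maximum(
        0.0,
        config.severity_intercept
        + config.severity_slope * entropy_score[case_idx]
        + noise,
    )

    timeseries: dict[str, np.ndarray] = {}
    fd: dict[str, np.ndarray] = {}
    records = []
    for i, sid in enumerate(ids):
        cov = build_block_covariance(config, fc_latent[i], int(groups[i]))
        x, m = generate_subject_series(cov, config, modulation[i], rng)
        timeseries[sid] = x
        fd[sid] = m
        records.append(
            rio.SubjectRecord(
                subject_id=sid,
                group=int(groups[i]),
                severity=None if np.isnan(severity[i]) else float(severity[i]),
                tr=config.tr,
                n_frames=config.n_frames,
                timeseries_path=f"timeseries/{sid}.tsv",
                motion_path=f"motion/{sid}.tsv",
            )
        )

    roi_ids = np.arange(config.n_rois)
    labels = np.array(
        [config.networks[j] for j in config.roi_networks()], dtype=object
    )
    cohort = rio.Cohort(
        manifest=rio.CohortManifest(records),
        network_map=rio.NetworkMap(roi_ids, labels),
        timeseries=timeseries,
        fd=fd,
        fd_threshold=config.fd_threshold,
    )
    truth = GroundTruth(
        subject_ids=ids,
        groups=groups,
        latent=z,
        fc_latent=fc_latent,
        entropy_score=entropy_score,
        modulation=modulation,
        coupling_control=config.coupling_control,
        coupling_case=config.coupling_case,
        severity_intercept=config.severity_intercept,
        severity_slope=config.severity_slope,
        severity=severity,
        network_weights=tuple(float(w) for w in config.network_weights),
    )
    return cohort, truth


def strong_effect_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset with large planted effects, sized for recovery testing.

    Effect sizes are chosen for statistical power at desk scale, not for
    physiological realism.
    """
    base: dict = dict(
        n_control=30,
        n_case=30,
        n_frames=500,
        rois_per_network=(4,) * 11,
        latent_sd=0.12,
        group_fc_shift=0.08,
        coupling_control=0.45,
        coupling_case=0.10,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[rio.Cohort, GroundTruth]:
    """Generate a cohort and write it to ``out_dir`` (TSV + ground_truth.json)."""
    cohort, truth = simulate_cohort(config)
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(parents=True, exist_ok=True)
    rio.write_manifest(cohort.manifest, out / "manifest.tsv")
    rio.write_network_map(cohort.network_map, out / "roi_map.tsv")
    for rec in cohort.manifest.subjects:
        sid = rec.subject_id
        rio.write_timeseries(
            cohort.timeseries[sid], cohort.network_map.roi_ids,
            out / rec.timeseries_path,
        )
        rio.write_motion(cohort.fd[sid], out / rec.motion_path)
    (out / "ground_truth.json").write_text(truth.to_json())
    return cohort, truth
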