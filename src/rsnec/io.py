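"""Tabular I/O and validation for cohorts, ROI maps, time series and motion.

All interchange files are TSV with a single header line. Frames are
0-indexed on disk and in memory. Motion flags are always *derived* from the
framewise-displacement series at a configured threshold, never trusted from
disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .networks import CANONICAL_NETWORKS

__all__ = [
    "CohortValidationError",
    "SubjectRecord",
    "CohortManifest",
    "NetworkMap",
    "Cohort",
    "motion_flags",
    "read_manifest",
    "write_manifest",
    "read_network_map",
    "write_network_map",
    "read_timeseries",
    "write_timeseries",
    "read_motion",
    "write_motion",
    "read_cohort",
    "apply_exclusions",
    "extract_roi_means",
]

DEFAULT_FD_THRESHOLD = 0.3  # mm
DEFAULT_MAX_FLAG_FRACTION = 0.10

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "severity",
    "tr_s",
    "n_frames",
    "timeseries_path",
    "motion_path",
]


class CohortValidationError(ValueError):
    """Raised for structural problems in cohort artifacts."""


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: int  # 0 = control, 1 = case
    severity: float | None
    tr: float
    n_frames: int
    timeseries_path: str
    motion_path: str


@dataclass
class CohortManifest:
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortValidationError(
                f"duplicate subject_id(s) in manifest: {sorted(dupes)}"
            )
        for s in self.subjects:
            if s.group not in (0, 1):
                raise CohortValidationError(
                    f"subject {s.subject_id}: group must be 0 or 1, got {s.group}"
                )
            if s.tr <= 0:
                raise CohortValidationError(
                    f"subject {s.subject_id}: TR must be > 0, got {s.tr}"
                )
            if s.n_frames < 1:
                raise CohortValidationError(
                    f"subject {s.subject_id}: n_frames must be positive"
                )
            if s.severity is not None and s.severity < 0:
                raise CohortValidationError(
                    f"subject {s.subject_id}: severity must be non-negative"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects], dtype=int)

    def severities(self) -> np.ndarray:
        """Severity scores with NaN where absent."""
        return np.array(
            [np.nan if s.severity is None else s.severity for s in self.subjects]
        )


@dataclass
class NetworkMap:
    """ROI -> network assignment.

    ``roi_ids`` and ``labels`` are parallel arrays; ``networks`` fixes the
    network ordering used for all downstream slot layouts. Maps with fewer
    than 11 networks are permitted for toy analyses; ``require_canonical``
    at read time enforces the full 11-network convention.
    """

    roi_ids: np.ndarray
    labels: np.ndarray
    networks: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.roi_ids = np.asarray(self.roi_ids)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.roi_ids) != len(self.labels):
            raise CohortValidationError("roi_ids and labels length mismatch")
        ids, counts = np.unique(self.roi_ids, return_counts=True)
        dupes = ids[counts > 1]
        if dupes.size:
            raise CohortValidationError(
                f"ROI(s) assigned to more than one network: {list(dupes)}"
            )
        present = set(self.labels.tolist())
        # canonical networks first, in canonical order; extras appended sorted
        ordered = [n for n in CANONICAL_NETWORKS if n in present]
        ordered += sorted(present - set(CANONICAL_NETWORKS))
        self.networks = tuple(ordered)
        if len(self.networks) < 2:
            raise CohortValidationError("network map needs at least 2 networks")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def indices_for(self, network: str) -> np.ndarray:
        """Positional indices (column order) of the ROIs in ``network``."""
        return np.flatnonzero(self.labels == network)

    def validate_canonical(self) -> None:
        missing = set(CANONICAL_NETWORKS) - set(self.labels.tolist())
        extra = set(self.labels.tolist()) - set(CANONICAL_NETWORKS)
        if missing or extra:
            raise CohortValidationError(
                f"non-canonical network map (missing {sorted(missing)}, "
                f"unknown {sorted(extra)})"
            )
        for net in CANONICAL_NETWORKS:
            if len(self.indices_for(net)) < 2:
                raise CohortValidationError(
                    f"network {net} has fewer than 2 ROIs"
                )


@dataclass
class Cohort:
    """Validated in-memory cohort."""

    manifest: CohortManifest
    network_map: NetworkMap
    timeseries: dict[str, np.ndarray]  # subject_id -> (T, R)
    fd: dict[str, np.ndarray]  # subject_id -> (T,)
    fd_threshold: float = DEFAULT_FD_THRESHOLD
    rejections: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.manifest.subjects)

    def flags(self, subject_id: str) -> np.ndarray:
        return motion_flags(self.fd[subject_id], self.fd_threshold)

    def flag_fraction(self, subject_id: str) -> float:
        return float(self.flags(subject_id).mean())


def motion_flags(fd: np.ndarray, threshold: float = DEFAULT_FD_THRESHOLD) -> np.ndarray:
    """Binary scrub flags: 1 exactly where FD exceeds ``threshold``."""
    return (np.asarray(fd, dtype=float) > threshold).astype(int)


# ---------------------------------------------------------------------------
# readers / writers


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     float_precision="round_trip")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"manifest missing column(s): {missing}")
    subjects = []
    for _, row in df.iterrows():
        sev = row["severity"]
        severity = None if pd.isna(sev) else float(sev)
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=int(row["group"]),
                severity=severity,
                tr=float(row["tr_s"]),
                n_frames=int(row["n_frames"]),
                timeseries_path=str(row["timeseries_path"]),
                motion_path=str(row["motion_path"]),
            )
        )
    return CohortManifest(subjects)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    rows = [dataclasses.asdict(s) for s in manifest.subjects]
    df = pd.DataFrame(rows)
    df = df.rename(columns={"tr": "tr_s"})[MANIFEST_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_network_map(path: str | Path) -> NetworkMap:
    df = pd.read_csv(path, sep="\t")
    for col in ("roi_id", "network_label"):
        if col not in df.columns:
            raise CohortValidationError(f"roi map missing column: {col}")
    return NetworkMap(df["roi_id"].to_numpy(), df["network_label"].to_numpy())


def write_network_map(nm: NetworkMap, path: str | Path) -> None:
    pd.DataFrame({"roi_id": nm.roi_ids, "network_label": nm.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_timeseries(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a frames x ROIs table; returns (matrix, roi_ids from header)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    roi_ids = np.array([int(c) for c in df.columns])
    x = df.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise CohortValidationError(f"missing values in time series {path}")
    return x, roi_ids


def write_timeseries(x: np.ndarray, roi_ids: Iterable[int], path: str | Path) -> None:
    # %.17g guarantees bit-exact float round-trips
    pd.DataFrame(np.asarray(x), columns=[str(i) for i in roi_ids]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_motion(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("frame", "fd_mm"):
        if col not in df.columns:
            raise CohortValidationError(f"motion file missing column: {col}")
    return df["fd_mm"].to_numpy(dtype=float)


def write_motion(fd: np.ndarray, path: str | Path) -> None:
    fd = np.asarray(fd)
    pd.DataFrame({"frame": np.arange(len(fd)), "fd_mm": fd}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


MIN_FRAMES = 64  # minimum frames for 3 SWT levels with meaningful pattern counts


def read_cohort(
    manifest_path: str | Path,
    map_path: str | Path,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    require_canonical: bool = True,
) -> Cohort:
    """Read and validate a full cohort.

    Structural problems (bad headers, duplicate ids/ROIs, non-canonical map)
    raise :class:`CohortValidationError`. Per-subject data problems (missing
    file, frame-count mismatch, NaNs, ROI mismatch with the map) demote the
    subject to a rejection record with a reason.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    nm = read_network_map(map_path)
    if require_canonical:
        nm.validate_canonical()

    base = manifest_path.parent
    kept: list[SubjectRecord] = []
    timeseries: dict[str, np.ndarray] = {}
    fd: dict[str, np.ndarray] = {}
    rejections: list[tuple[str, str]] = []
    map_ids = set(int(i) for i in nm.roi_ids)

    for rec in manifest.subjects:
        sid = rec.subject_id
        ts_path = base / rec.timeseries_path
        mo_path = base / rec.motion_path
        try:
            if not ts_path.exists():
                raise CohortValidationError(f"time-series file not found: {ts_path}")
            if not mo_path.exists():
                raise CohortValidationError(f"motion file not found: {mo_path}")
            x, roi_ids = read_timeseries(ts_path)
            if set(int(i) for i in roi_ids) != map_ids:
                raise CohortValidationError(
                    "time-series ROI columns do not match the network map"
                )
            if x.shape[0] != rec.n_frames:
                raise CohortValidationError(
                    f"expected {rec.n_frames} frames, found {x.shape[0]}"
                )
            if x.shape[0] < MIN_FRAMES:
                raise CohortValidationError(
                    f"fewer than {MIN_FRAMES} frames ({x.shape[0]})"
                )
            m = read_motion(mo_path)
            if len(m) != x.shape[0]:
                raise CohortValidationError(
                    f"motion length {len(m)} != n_frames {x.shape[0]}"
                )
            # reorder columns to the map's ROI order
            order = {int(r): k for k, r in enumerate(roi_ids)}
            cols = [order[int(r)] for r in nm.roi_ids]
            timeseries[sid] = x[:, cols]
            fd[sid] = m
            kept.append(rec)
        except CohortValidationError as exc:
            rejections.append((sid, str(exc)))

    return Cohort(
        manifest=CohortManifest(kept),
        network_map=nm,
        timeseries=timeseries,
        fd=fd,
        fd_threshold=fd_threshold,
        rejections=rejections,
    )


def apply_exclusions(
    cohort: Cohort,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    max_flag_fraction: float = DEFAULT_MAX_FLAG_FRACTION,
) -> Cohort:
    """Drop subjects whose flagged-frame fraction exceeds ``max_flag_fraction``.

    Flags are recomputed from FD at ``fd_threshold``. Idempotent; an empty
    result is allowed (warning-level condition, not an error).
    """
    kept: list[SubjectRecord] = []
    rejections = list(cohort.rejections)
    for rec in cohort.manifest.subjects:
        frac = float(motion_flags(cohort.fd[rec.subject_id], fd_threshold).mean())
        if frac > max_flag_fraction:
            rejections.append(
                (rec.subject_id, f"flagged-frame fraction {frac:.3f} > {max_flag_fraction}")
            )
        else:
            kept.append(rec)
    return Cohort(
        manifest=CohortManifest(kept),
        network_map=cohort.network_map,
        timeseries={r.subject_id: cohort.timeseries[r.subject_id] for r in kept},
        fd={r.subject_id: cohort.fd[r.subject_id] for r in kept},
        fd_threshold=fd_threshold,
        rejections=rejections,
    )


def extract_roi_means(
    volume_path: str | Path,
    coordinates: Iterable[tuple[float, float, float]],
    radius: float = 5.0,
) -> np.ndarray:
    """Mean time series over spherical ROIs of a 4-D NIfTI volume.

    A voxel belongs to an ROI when its center lies within ``radius`` mm
    (Euclidean, after the image affine) of the ROI coordinate; ``radius`` 0
    degenerates to the single nearest voxel. Returns a frames x ROIs matrix.
    """
    import nibabel as nib  # optional dependency

    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise CohortValidationError("expected a 4-D volume")
    affine = img.affine
    nx, ny, nz, _ = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    mm = (affine @ vox)[:3].T  # voxel centers in mm

    out = []
    for r, (x, y, z) in enumerate(coordinates):
        d = np.linalg.norm(mm - np.array([x, y, z]), axis=1)
        if radius > 0:
            sel = d <= radius
        else:
            sel = np.zeros(len(d), dtype=bool)
            sel[np.argmin(d)] = True
        if not sel.any():
            raise CohortValidationError(
                f"ROI {r} at ({x}, {y}, {z}) has no voxels within {radius} mm"
            )
        if d.min() > radius > 0:
            raise CohortValidationError(
                f"ROI {r} at ({x}, {y}, {z}) lies outside the volume"
            )
        flat = data.reshape(-1, data.shape[3])
        out.append(flat[sel].mean(axis=0))
    return np.column_stack(out)
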