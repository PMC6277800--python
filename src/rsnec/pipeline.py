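"""End-to-end orchestration: simulate -> validate -> FC -> entropy -> model.

A run is a pure function of (inputs, config, seed). Randomness derivation:
the cohort simulation uses the root seed itself; CV fold assignment uses
``seed + 1``. Stage failures abort with the stage name and, where relevant,
subject context.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import entropy as ent
from . import fc as rfc
from . import io as rio
from . import model as rmodel
from .synthetic import SimulationConfig, generate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_model_stage"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    cohort_dir: str | None = None  # existing cohort (manifest.tsv + roi_map.tsv)
    simulate: SimulationConfig | None = None
    fd_threshold: float = 0.3
    max_flag_fraction: float = 0.10
    band: tuple[float, float] = (0.01, 0.10)
    r0: float | str = 0.2  # numeric, or "auto" for grid selection
    wavelet: str = "sym8"
    m: int = 1
    alpha_grid: tuple[float, ...] | None = None
    n_lambda: int = 100
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_dir is None and self.simulate is None:
            raise ValueError("either cohort_dir or simulate must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            for key in ("networks", "rois_per_network", "entropy_base",
                        "network_weights", "bandpass"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "alpha_grid" in raw and raw["alpha_grid"] is not None:
            raw["alpha_grid"] = tuple(raw["alpha_grid"])
        return cls(simulate=sim, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _entropy_params(cfg: RunConfig, r0: float) -> ent.EntropyParams:
    return ent.EntropyParams(m=cfg.m, r0=r0, wavelet=cfg.wavelet, band=cfg.band)


def _entropy_matrix(cohort: rio.Cohort, cfg: RunConfig, r0: float) -> np.ndarray:
    rows = []
    for rec in cohort.manifest.subjects:
        sid = rec.subject_id
        prof = ent.rsn_entropy(
            cohort.timeseries[sid],
            cohort.flags(sid),
            cohort.network_map,
            rec.tr,
            _entropy_params(cfg, r0),
            subject_id=sid,
        )
        rows.append(prof.values)
    return np.vstack(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report (also written to report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.echo(), "stages": {}}

    # --- simulate -----------------------------------------------------------
    cohort_dir = config.cohort_dir
    if config.simulate is not None:
        try:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            cohort_dir = str(out / "cohort")
            generate_cohort(sim, cohort_dir)
            report["stages"]["simulate"] = {"cohort_dir": cohort_dir,
                                            "n_subjects": sim.n_subjects}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", str(exc)) from exc

    # --- validate -----------------------------------------------------------
    try:
        cohort = rio.read_cohort(
            Path(cohort_dir) / "manifest.tsv",
            Path(cohort_dir) / "roi_map.tsv",
            fd_threshold=config.fd_threshold,
        )
        n_read = cohort.n_subjects
        cohort = rio.apply_exclusions(
            cohort, config.fd_threshold, config.max_flag_fraction
        )
        report["stages"]["validate"] = {
            "n_read": n_read,
            "n_after_motion_exclusion": cohort.n_subjects,
            "rejections": [list(r) for r in cohort.rejections],
        }
    except rio.CohortValidationError as exc:
        raise PipelineError("validate", str(exc)) from exc
    if cohort.n_subjects == 0:
        raise PipelineError("validate", "no subjects left after exclusions")

    # --- per-subject FC features -------------------------------------------
    features: dict[str, np.ndarray] = {}
    fc_excluded: list[tuple[str, str]] = []
    try:
        for rec in cohort.manifest.subjects:
            sid = rec.subject_id
            try:
                fcm = rfc.compute_fc(cohort.timeseries[sid], cohort.flags(sid))
                features[sid] = rfc.vectorize(
                    rfc.reduce_to_rsn(fcm, cohort.network_map)
                )
            except rfc.FCError as exc:
                fc_excluded.append((sid, str(exc)))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fc", str(exc)) from exc

    # --- entropy ------------------------------------------------------------
    try:
        sub_ids = [r.subject_id for r in cohort.manifest.subjects
                   if r.subject_id in features]
        kept = rio.Cohort(
            manifest=rio.CohortManifest(
                [r for r in cohort.manifest.subjects if r.subject_id in features]
            ),
            network_map=cohort.network_map,
            timeseries={s: cohort.timeseries[s] for s in sub_ids},
            fd={s: cohort.fd[s] for s in sub_ids},
            fd_threshold=config.fd_threshold,
        )
        if config.r0 == "auto":
            grid = {
                r0: _entropy_matrix(kept, config, r0) for r0 in ent.R0_GRID
            }
            chosen_r0 = ent.select_r0(grid)
            xh_all = grid[chosen_r0]
        else:
            chosen_r0 = float(config.r0)
            xh_all = _entropy_matrix(kept, config, chosen_r0)
        complete = ~np.isnan(xh_all).any(axis=1)
        entropy_excluded = [
            (sub_ids[i], "incomplete entropy profile")
            for i in np.flatnonzero(~complete)
        ]
        report["stages"]["entropy"] = {
            "chosen_r0": chosen_r0,
            "n_complete": int(complete.sum()),
            "excluded": [list(e) for e in entropy_excluded],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("entropy", str(exc)) from exc

    # --- PCA on the final subject set --------------------------------------
    try:
        final_ids = [s for s, ok in zip(sub_ids, complete) if ok]
        if len(final_ids) < 3:
            raise ValueError(f"only {len(final_ids)} analyzable subjects")
        feat = np.vstack([features[s] for s in final_ids])
        xh = xh_all[complete]
        pca = rfc.compile_and_pca(feat, cohort.network_map.networks)
        report["stages"]["fc"] = {
            "n_subjects": len(final_ids),
            "n_features": feat.shape[1],
            "excluded": [list(e) for e in fc_excluded],
            "variance_explained": [float(v) for v in pca.variance_explained],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fc", str(exc)) from exc

    rec_by_id = {r.subject_id: r for r in cohort.manifest.subjects}
    groups = np.array([rec_by_id[s].group for s in final_ids])
    severity = np.array(
        [np.nan if rec_by_id[s].severity is None else rec_by_id[s].severity
         for s in final_ids]
    )

    # --- model --------------------------------------------------------------
    try:
        fit = rmodel.fit_elastic_net(
            xh, pca.c1,
            alpha_grid=config.alpha_grid,
            n_lambda=config.n_lambda,
            n_folds=config.folds,
            seed=config.seed + 1,
        )
        report["stages"]["model"] = {
            "alpha": fit.alpha,
            "lambda": fit.lam,
            "cv_mse_mean": fit.cv_mse_mean,
            "cv_mse_sd": fit.cv_mse_sd,
            "beta": {n: float(b) for n, b in
                     zip(cohort.network_map.networks, fit.beta)},
            "intercept": fit.intercept,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("model", str(exc)) from exc

    # --- statistics ---------------------------------------------------------
    try:
        stats_report: dict = {}
        for name, vals in (("c1", pca.c1), ("c1h", fit.c1h)):
            res = rmodel.rank_sum_test(vals, groups)
            stats_report[f"rank_sum_{name}"] = {
                "W": res.w, "U": res.u, "p": res.p, "method": res.method,
            }
        if np.ptp(fit.c1h) > 0:
            inter = rmodel.interaction_regression(pca.c1, fit.c1h, groups)
            stats_report["interaction"] = {
                "gamma": [float(v) for v in inter.gamma],
                "se": [float(v) for v in inter.se],
                "t": [float(v) for v in inter.t],
                "p": [float(v) for v in inter.p],
            }
        else:  # fully shrunk model: interaction undefined, recorded as such
            stats_report["interaction"] = {"skipped": "c1h is constant"}
        for name, vals in (("c1h", fit.c1h), ("c1", pca.c1)):
            if np.isfinite(severity).sum() >= 5:
                sev = rmodel.severity_correlation(vals, severity)
                stats_report[f"severity_{name}"] = {
                    "r": sev.r, "p": sev.p, "n": sev.n,
                }
        report["stages"]["stats"] = stats_report
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", str(exc)) from exc

    _write_outputs(out, cohort, final_ids, feat, xh, pca, fit, groups,
                   severity, report)
    return report


def _write_outputs(out, cohort, final_ids, feat, xh, pca, fit, groups,
                   severity, report) -> None:
    nets = cohort.network_map.networks
    pd.DataFrame(feat, columns=rfc.slot_names(nets)).assign(
        subject_id=final_ids
    ).set_index("subject_id").to_csv(out / "features.tsv", sep="\t")
    pd.DataFrame(xh, columns=list(nets)).assign(
        subject_id=final_ids
    ).set_index("subject_id").to_csv(out / "entropy.tsv", sep="\t")
    pd.DataFrame(
        pca.scores,
        columns=[f"c{i + 1}" for i in range(pca.scores.shape[1])],
    ).assign(subject_id=final_ids).set_index("subject_id").to_csv(
        out / "pca_scores.tsv", sep="\t"
    )
    pd.DataFrame(
        pca.vt, columns=rfc.slot_names(nets),
        index=[f"V{i + 1}" for i in range(pca.vt.shape[0])],
    ).to_csv(out / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(
        {
            "subject_id": final_ids,
            "group": groups,
            "c1": pca.c1,
            "c1h": fit.c1h,
            "severity": severity,
        }
    ).to_csv(out / "scores.tsv", sep="\t", index=False)
    (out / "model_fit.json").write_text(
        json.dumps(
            {
                "alpha": fit.alpha,
                "lambda": fit.lam,
                "cv_mse_mean": fit.cv_mse_mean,
                "cv_mse_sd": fit.cv_mse_sd,
                "intercept": fit.intercept,
                "beta": {n: float(b) for n, b in zip(nets, fit.beta)},
                "cv_curve": fit.cv_curve,
            },
            indent=1, sort_keys=True,
        )
    )
    (out / "stats_report.json").write_text(
        json.dumps(report["stages"]["stats"], indent=1, sort_keys=True)
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))


def run_model_stage(
    features_path: str | Path,
    entropy_path: str | Path,
    out_dir: str | Path,
    alpha_grid: tuple[float, ...] | None = None,
    n_lambda: int = 100,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Model + statistics from stage outputs on disk (CLI entry point)."""
    for stage, path in (("fc", features_path), ("entropy", entropy_path)):
        if not Path(path).exists():
            raise PipelineError(stage, f"missing stage output: {path}")
    feat = pd.read_csv(features_path, sep="\t", index_col="subject_id")
    xh = pd.read_csv(entropy_path, sep="\t", index_col="subject_id")
    common = [s for s in feat.index if s in set(xh.index)]
    if len(common) < 3:
        raise PipelineError("model", "fewer than 3 subjects shared by stages")
    nets = tuple(xh.columns)
    pca = rfc.compile_and_pca(feat.loc[common].to_numpy(), nets)
    fit = rmodel.fit_elastic_net(
        xh.loc[common].to_numpy(), pca.c1,
        alpha_grid=alpha_grid, n_lambda=n_lambda, n_folds=folds, seed=seed,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "alpha": fit.alpha,
        "lambda": fit.lam,
        "cv_mse_mean": fit.cv_mse_mean,
        "cv_mse_sd": fit.cv_mse_sd,
        "beta": {n: float(b) for n, b in zip(nets, fit.beta)},
        "intercept": fit.intercept,
        "n_subjects": len(common),
    }
    (out / "model_fit.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    pd.DataFrame({"subject_id": common, "c1": pca.c1, "c1h": fit.c1h}).to_csv(
        out / "scores.tsv", sep="\t", index=False
    )
    return summary
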