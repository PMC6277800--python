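"""Elastic-net coupling model and cohort statistics.

The coupling model regresses the primary FC component score on the 11
network entropies over the pooled cohort (group labels are never part of the
design). Penalty parameterization follows the common coordinate-descent
convention::

    (1 / 2N) * ||y - b0 - X b||^2 + lam * ((1 - alpha)/2 * ||b||^2 + alpha * ||b||_1)

Predictors are standardized inside each training fold; reported coefficients
are on the original scale. Model selection minimizes the mean 10-fold CV MSE
over an (alpha, lambda) grid with seeded, deterministic fold assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

__all__ = [
    "CouplingModelFit",
    "fit_elastic_net",
    "predict_scores",
    "GroupTestResult",
    "rank_sum_test",
    "InteractionFit",
    "interaction_regression",
    "SeverityResult",
    "severity_correlation",
    "cv_folds",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass
class CouplingModelFit:
    beta: np.ndarray  # coefficients on the original predictor scale
    intercept: float
    alpha: float
    lam: float
    cv_mse_mean: float
    cv_mse_sd: float
    c1h: np.ndarray  # in-sample fitted scores
    residuals: np.ndarray
    cv_curve: dict  # {"alpha": [...], "lambda": [...], "mse": [...]} flattened grid
    n_folds: int
    seed: int


def cv_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic fold assignment: a function of (seed, n) only."""
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), n_folds)]


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column; cannot standardize")
    return (x - mu) / sd, mu, sd


def _solve_standardized(
    xs: np.ndarray, yc: np.ndarray, lam: float, alpha: float
) -> np.ndarray:
    """Coefficients on standardized predictors for centered response."""
    n = len(yc)
    if lam == 0.0:
        return np.linalg.lstsq(xs, yc, rcond=None)[0]
    if alpha == 0.0:
        g = xs.T @ xs + n * lam * np.eye(xs.shape[1])
        return np.linalg.solve(g, xs.T @ yc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        en = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False,
            max_iter=100_000, tol=1e-10,
        )
        en.fit(xs, yc)
    return en.coef_


def _lambda_path(
    xs: np.ndarray, yc: np.ndarray, alpha: float,
    n_lambda: int, min_ratio: float,
) -> np.ndarray:
    n = len(yc)
    lam_max = np.max(np.abs(xs.T @ yc)) / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def fit_elastic_net(
    x: np.ndarray,
    y: np.ndarray,
    alpha_grid: tuple[float, ...] | None = None,
    n_lambda: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    lambda_min_ratio: float = 1e-4,
) -> CouplingModelFit:
    """Grid-searched, cross-validated elastic-net fit of ``y`` on ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n <= n_folds:
        raise ValueError(f"need more than {n_folds} observations, got {n}")
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID

    folds = cv_folds(n, n_folds, seed)
    if min(len(f) for f in folds) <= 1:
        raise ValueError("degenerate CV folds (a fold with <= 1 subject)")

    xs_full, _, _ = _standardize(x)
    yc_full = y - y.mean()

    best = None  # (mean_mse, alpha, lam, fold_mses)
    curve = {"alpha": [], "lambda": [], "mse": []}
    for alpha in alpha_grid:
        lams = _lambda_path(xs_full, yc_full, alpha, n_lambda, lambda_min_ratio)
        fold_mse = np.empty((len(lams), len(folds)))
        for fi, val_idx in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[val_idx] = False
            xtr, ytr = x[mask], y[mask]
            xs, mu, sd = _standardize(xtr)
            ytr_mean = ytr.mean()
            xva = (x[val_idx] - mu) / sd
            yva = y[val_idx]
            for li, lam in enumerate(lams):
                b = _solve_standardized(xs, ytr - ytr_mean, lam, alpha)
                pred = ytr_mean + xva @ b
                fold_mse[li, fi] = np.mean((yva - pred) ** 2)
        mean_mse = fold_mse.mean(axis=1)
        curve["alpha"].extend([float(alpha)] * len(lams))
        curve["lambda"].extend(map(float, lams))
        curve["mse"].extend(map(float, mean_mse))
        li = int(np.argmin(mean_mse))
        if best is None or mean_mse[li] < best[0]:
            best = (float(mean_mse[li]), float(alpha), float(lams[li]),
                    fold_mse[li].copy())

    assert best is not None
    _, alpha, lam, fold_mses = best
    xs, mu, sd = _standardize(x)
    b_std = _solve_standardized(xs, y - y.mean(), lam, alpha)
    beta = b_std / sd
    intercept = float(y.mean() - beta @ mu)
    c1h = x @ beta + intercept
    return CouplingModelFit(
        beta=beta,
        intercept=intercept,
        alpha=alpha,
        lam=lam,
        cv_mse_mean=float(fold_mses.mean()),
        cv_mse_sd=float(fold_mses.std(ddof=1)),
        c1h=c1h,
        residuals=y - c1h,
        cv_curve=curve,
        n_folds=n_folds,
        seed=seed,
    )


def predict_scores(fit: CouplingModelFit, x: np.ndarray) -> np.ndarray:
    """Linear prediction ``x @ beta + intercept``."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != len(fit.beta):
        raise ValueError(
            f"predictor count {x.shape[1]} != fitted coefficients {len(fit.beta)}"
        )
    return x @ fit.beta + fit.intercept


@dataclass
class GroupTestResult:
    w: float  # rank sum of group 1
    u: float  # Mann-Whitney U of group 1 (W - n1(n1+1)/2)
    p: float
    method: str
    n0: int
    n1: int


def rank_sum_test(values: np.ndarray, groups: np.ndarray) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test (group 1 vs group 0).

    Mid-ranks for ties; exact enumeration when both groups have <= 20
    observations and there are no ties, normal approximation with tie
    correction otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    x1 = values[groups == 1]
    x0 = values[groups == 0]
    if len(x1) == 0 or len(x0) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n0 = len(x1), len(x0)
    ranks = stats.rankdata(values)
    w = float(ranks[groups == 1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(values)) < len(values)
    if np.ptp(values) == 0:  # every value tied
        return GroupTestResult(w, u, 1.0, "degenerate", n0, n1)
    if n1 <= 20 and n0 <= 20 and not has_ties:
        res = stats.mannwhitneyu(x1, x0, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x1, x0, alternative="two-sided", method="asymptotic"
        )
        method = "asymptotic"
    return GroupTestResult(w, u, float(res.pvalue), method, n0, n1)


@dataclass
class InteractionFit:
    gamma: np.ndarray  # (g0, g1, g2, g3)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    term_names: tuple[str, ...] = ("intercept", "group", "c1h", "group:c1h")


def interaction_regression(
    c1: np.ndarray, c1h: np.ndarray, groups: np.ndarray
) -> InteractionFit:
    """OLS of ``c1`` on group, entropy-model score, and their interaction."""
    import statsmodels.api as sm

    c1 = np.asarray(c1, dtype=float)
    c1h = np.asarray(c1h, dtype=float)
    g = np.asarray(groups, dtype=float)
    if len(c1) < 8:
        raise ValueError("need at least 8 subjects")
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be present")
    design = np.column_stack([np.ones_like(c1), g, c1h, g * c1h])
    rank = np.linalg.matrix_rank(design)
    if rank < 4:
        names = ("intercept", "group", "c1h", "group:c1h")
        # identify the first column that does not increase the rank
        for k in range(1, 5):
            if np.linalg.matrix_rank(design[:, :k]) < k:
                raise ValueError(f"collinear design: term '{names[k - 1]}'")
        raise ValueError("collinear design")
    fit = sm.OLS(c1, design).fit()
    return InteractionFit(
        gamma=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        t=np.asarray(fit.tvalues),
        p=np.asarray(fit.pvalues),
        residuals=np.asarray(fit.resid),
    )


@dataclass
class SeverityResult:
    r: float | None
    p: float | None
    n: int
    defined: bool


def severity_correlation(scores: np.ndarray, severity: np.ndarray) -> SeverityResult:
    """Pearson correlation over subjects with a severity score present."""
    scores = np.asarray(scores, dtype=float)
    severity = np.asarray(severity, dtype=float)
    mask = np.isfinite(severity)
    s, v = scores[mask], severity[mask]
    if len(s) < 5:
        raise ValueError("need at least 5 scored subjects")
    if np.ptp(s) == 0 or np.ptp(v) == 0:
        return SeverityResult(None, None, len(s), defined=False)
    r, p = stats.pearsonr(s, v)
    return SeverityResult(float(r), float(p), len(s), defined=True)
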