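"""Covariate-adjusted regressions, FDR sensor maps, and bootstrap mediation.

This stage relates subject covariates (VO2 max, IQ, sex, head surface,
relative band power) to the network metrics computed upstream:

* :func:`fit_linear` — ordinary least squares with a t-based 95% CI and
  two-sided p-value for a named predictor, adjusted for covariates.
* :func:`sensor_map` — one regression per sensor for a per-sensor metric,
  with the Benjamini-Hochberg step-up procedure controlling the false
  discovery rate across sensors.
* :func:`mediate` — the classic three-regression mediation decomposition
  (x -> mediator path a; mediator -> y path b and direct path c' from
  y ~ x + mediator; total path c from y ~ x), with a case-resampling
  bootstrap percentile CI for the indirect effect a*b. For OLS with a
  shared covariate set the identity c = c' + a*b holds exactly.

Rows with missing values in any modelled column are dropped (the count is
recorded on the result). Standardised coefficients are obtained by
z-scoring x, mediator, and y before fitting (covariates are left on their
own scale; standardisation of the modelled variables alone determines the
standardised path coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "SensorStatMap",
    "MediationResult",
    "fit_linear",
    "fdr_bh",
    "sensor_map",
    "mediate",
    "group_ttest",
]


@dataclass
class RegressionResult:
    coefficient: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    covariate_names: tuple[str, ...]
    t_value: float = float("nan")
    n_dropped: int = 0


@dataclass
class SensorStatMap:
    """Per-sensor association statistics with a BH-FDR rejection mask."""

    b: np.ndarray
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    q_level: float
    sensor_ids: list[str]


@dataclass
class MediationResult:
    path_a: float
    path_b: float
    total_c: float
    direct_c_prime: float
    indirect_ab: float
    boot_ci95: tuple[float, float]
    n_boot: int
    seed: int
    n: int
    p_a: float = float("nan")
    p_b: float = float("nan")
    p_total: float = float("nan")
    p_direct: float = float("nan")


def _design(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    return np.column_stack(cols)


def fit_linear(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
) -> RegressionResult:
    """OLS of ``y`` on ``x`` plus covariates; inference on the x slope."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    n_cov = 0 if covariates is None else covariates.shape[1]
    if y.shape[0] != x.shape[0] or (covariates is not None and covariates.shape[0] != y.shape[0]):
        raise ValueError("y, x, and covariates must have matching length")
    if y.shape[0] <= n_cov + 3:
        raise ValueError(f"n={y.shape[0]} too small for {n_cov + 1} predictors")
    design = _design(x, covariates)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return RegressionResult(
        coefficient=float(fit.params[1]),
        ci95=(float(ci[0]), float(ci[1])),
        p_value=float(fit.pvalues[1]),
        n=int(y.shape[0]),
        covariate_names=tuple(covariate_names),
        t_value=float(fit.tvalues[1]),
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``.

    Sort the m p-values ascending, find the largest i with
    p_(i) <= (i/m) q, and reject all hypotheses at or below it.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _modelled_columns(
    records: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, int]:
    """Drop rows with missing values in the modelled columns."""
    sub = records[columns]
    keep = sub.notna().all(axis=1)
    return records.loc[keep], int((~keep).sum())


def sensor_map(
    records: pd.DataFrame,
    metric_name: str,
    predictor: str,
    covariates: list[str] = (),
    q: float = 0.05,
) -> SensorStatMap:
    """Per-sensor regression map with BH-FDR correction across sensors.

    Per-sensor metrics are wide columns named ``<metric_name>_<sensor>``
    (e.g. ``between_conn_beta_ch003``); one :func:`fit_linear` is run per
    sensor and the rejection mask is the BH step-up set at ``q``.
    """
    prefix = metric_name + "_"
    sensor_cols = sorted(c for c in records.columns if c.startswith(prefix))
    if not sensor_cols:
        raise ValueError(f"no per-sensor columns with prefix {prefix!r}")
    records, _ = _modelled_columns(records, [predictor, *covariates, *sensor_cols])
    cov = records[list(covariates)].to_numpy(float) if covariates else None
    x = records[predictor].to_numpy(float)
    b = np.empty(len(sensor_cols))
    t = np.empty(len(sensor_cols))
    p = np.empty(len(sensor_cols))
    for j, col in enumerate(sensor_cols):
        res = fit_linear(records[col].to_numpy(float), x, cov, tuple(covariates))
        b[j], t[j], p[j] = res.coefficient, res.t_value, res.p_value
    mask = fdr_bh(p, q)
    sensor_ids = [c[len(prefix):] for c in sensor_cols]
    return SensorStatMap(b, t, p, mask, q, sensor_ids)


def _ols_beta(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(design, y, rcond=None)[0]


def mediate(
    records: pd.DataFrame,
    x: str,
    mediator: str,
    y: str,
    covariates: list[str] = (),
    n_boot: int = 5000,
    seed: int = 0,
    ci_type: str = "percentile",
    standardize: bool = False,
) -> MediationResult:
    """Mediation decomposition with a case-resampling bootstrap CI on a*b.

    ``ci_type`` selects the percentile interval (default) or the
    bias-corrected variant ("bc"), which adjusts the percentile endpoints
    by the normal quantile of the fraction of bootstrap draws below the
    point estimate. Deterministic given ``seed``.
    """
    if ci_type not in ("percentile", "bc"):
        raise ValueError("ci_type must be 'percentile' or 'bc'")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for a stable CI")
    cols = [x, mediator, y, *covariates]
    records, _ = _modelled_columns(records, cols)
    n = len(records)
    if n < 20:
        raise ValueError(f"mediation needs n >= 20 subjects, got {n}")
    xv = records[x].to_numpy(float)
    mv = records[mediator].to_numpy(float)
    yv = records[y].to_numpy(float)
    if np.ptp(mv) == 0:
        raise ValueError("mediator is constant")
    if standardize:
        xv = (xv - xv.mean()) / xv.std(ddof=1)
        mv = (mv - mv.mean()) / mv.std(ddof=1)
        yv = (yv - yv.mean()) / yv.std(ddof=1)
    cov = records[list(covariates)].to_numpy(float) if covariates else None

    def paths(xa, ma, ya, ca):
        d_x = _design(xa, ca)
        a = _ols_beta(d_x, ma)[1]
        d_xm = np.column_stack([d_x[:, :2], ma, d_x[:, 2:]])
        bet = _ols_beta(d_xm, ya)
        b, c_prime = bet[2], bet[1]
        c = _ols_beta(d_x, ya)[1]
        return a, b, c, c_prime

    d_x = _design(xv, cov)
    if np.linalg.matrix_rank(np.column_stack([d_x, mv])) < d_x.shape[1] + 1:
        raise ValueError("collinear design in mediation model")
    a, b, c, c_prime = paths(xv, mv, yv, cov)

    # p-values for the point fits (t-based, via statsmodels)
    fa = sm.OLS(mv, d_x).fit()
    d_xm = np.column_stack([d_x[:, :2], mv, d_x[:, 2:]])
    fb = sm.OLS(yv, d_xm).fit()
    fc = sm.OLS(yv, d_x).fit()

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab = np.empty(n_boot)
    for i in range(n_boot):
        rows = idx[i]
        ca = cov[rows] if cov is not None else None
        ai, bi, _, _ = paths(xv[rows], mv[rows], yv[rows], ca)
        ab[i] = ai * bi

    if ci_type == "percentile":
        lo, hi = np.percentile(ab, [2.5, 97.5])
    else:
        prop = np.mean(ab < a * b)
        prop = min(max(prop, 1.0 / n_boot), 1.0 - 1.0 / n_boot)
        z0 = sps.norm.ppf(prop)
        zc = sps.norm.ppf([0.025, 0.975])
        lo, hi = np.percentile(ab, 100 * sps.norm.cdf(2 * z0 + zc))

    return MediationResult(
        path_a=float(a),
        path_b=float(b),
        total_c=float(c),
        direct_c_prime=float(c_prime),
        indirect_ab=float(a * b),
        boot_ci95=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
        n=n,
        p_a=float(fa.pvalues[1]),
        p_b=float(fb.pvalues[2]),
        p_total=float(fc.pvalues[1]),
        p_direct=float(fb.pvalues[1]),
    )


def group_ttest(records: pd.DataFrame, value: str, group: str) -> tuple[float, float]:
    """Two-sample Student's t-test of ``value`` between the two levels of
    ``group`` (convenience wrapper for cohort-description tables)."""
    levels = sorted(records[group].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{group!r} must have exactly 2 levels, found {levels}")
    g0 = records.loc[records[group] == levels[0], value].dropna()
    g1 = records.loc[records[group] == levels[1], value].dropna()
    t, p = sps.ttest_ind(g0, g1, equal_var=True)
    return float(t), float(p)
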