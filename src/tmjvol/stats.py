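"""Repeated-measures time-course analysis of joint-space volumes.

Marginal linear model with one fixed effect per visit (cell-means coding)
and an unstructured 4x4 covariance across the visits of a joint, estimated
by restricted maximum likelihood (REML) on all available observations.
Under the missing-at-random likelihood the partially observed visit (T1)
gets a model-based estimated mean.  Post-hoc pairwise visit contrasts are
Bonferroni-adjusted.

With complete balanced data the REML solution is closed form (per-visit
sample means, sample covariance with divisor n-1); otherwise the profiled
REML objective is optimized over a Cholesky parametrization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm, t as t_dist

from .reference_values import PAIRS, TIMEPOINTS

__all__ = [
    "ConvergenceError",
    "TimeCourseFit",
    "Contrast",
    "fit_time_course",
    "pairwise_contrasts",
    "make_results_table",
    "format_results_text",
    "format_p",
    "read_records",
]

RECORD_COLUMNS = ("patient_id", "joint_id", "timepoint", "outcome", "value_mm3")


class ConvergenceError(RuntimeError):
    """REML optimization failed to converge."""

    def __init__(self, message: str, last_loglik: float = np.nan):
        super().__init__(message)
        self.last_loglik = last_loglik


@dataclass
class TimeCourseFit:
    """Fitted time course for one outcome."""

    outcome: str
    means: np.ndarray  # (4,) estimated visit means
    ses: np.ndarray  # (4,) standard errors of the means
    cov_means: np.ndarray  # (4, 4) covariance of the estimated means
    covariance: np.ndarray  # (4, 4) estimated within-joint covariance
    overall_stat: float
    overall_p: float
    loglik: float
    ll_history: list
    n_joints: int
    n_obs: np.ndarray  # (4,) observations per visit
    cov_structure: str
    reml: bool
    converged: bool

    def __post_init__(self):
        if not np.all(np.isfinite(self.means)):
            raise ValueError("estimated means are not finite")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("estimated covariance is not symmetric")
        if np.min(np.linalg.eigvalsh((self.covariance + self.covariance.T) / 2)) < -1e-6:
            raise ValueError("estimated covariance is not positive semi-definite")


@dataclass
class Contrast:
    """One pairwise visit contrast (difference = later minus earlier)."""

    earlier: str
    later: str
    difference: float
    se: float
    p_raw: float
    p_adjusted: float


def read_records(path) -> pd.DataFrame:
    """Read a long-format volume CSV and validate its columns."""
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _outcome_matrix(records: pd.DataFrame, outcome: str):
    df = records[records["outcome"] == outcome]
    if df.empty:
        raise ValueError(f"no records for outcome {outcome!r}")
    dup = df.duplicated(subset=["joint_id", "timepoint"])
    if dup.any():
        raise ValueError(f"duplicate (joint, timepoint) records for outcome {outcome!r}")
    wide = df.pivot(index="joint_id", columns="timepoint", values="value_mm3")
    wide = wide.reindex(columns=list(TIMEPOINTS))
    patients = df.groupby("joint_id")["patient_id"].first().reindex(wide.index)
    return wide.to_numpy(dtype=float), wide.index.to_numpy(), patients.to_numpy()


def _theta_to_sigma(theta: np.ndarray) -> np.ndarray:
    L = np.zeros((4, 4))
    L[np.diag_indices(4)] = np.exp(theta[:4])
    L[np.tril_indices(4, -1)] = theta[4:10]
    return L @ L.T


def _sigma_to_theta(sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(sigma)
    return np.concatenate([np.log(np.diag(L)), L[np.tril_indices(4, -1)]])


def _cs_theta_to_sigma(theta: np.ndarray) -> np.ndarray:
    """Diagonal variances plus a common correlation (fallback structure)."""
    sd = np.exp(theta[:4])
    rho = -1.0 / 3.0 + (4.0 / 3.0) / (1.0 + np.exp(-theta[4]))
    R = np.full((4, 4), rho)
    np.fill_diagonal(R, 1.0)
    return np.outer(sd, sd) * R


_BIG = 1e12


def _profile_nll(sigma: np.ndarray, patterns, reml: bool):
    """Negative REML/ML log-likelihood with the visit means profiled out.

    ``patterns`` is a list of ``(obs_index_array, Y_block)`` groups of
    joints sharing an observation pattern.  Returns ``(nll, beta, Ainv)``.
    """
    A = np.zeros((4, 4))
    b = np.zeros(4)
    cache = []
    logdet_sum = 0.0
    for idx, Yp in patterns:
        So = sigma[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(So)
        if sign <= 0:
            return _BIG, None, None
        try:
            W = np.linalg.inv(So)
        except np.linalg.LinAlgError:
            return _BIG, None, None
        k = len(Yp)
        A[np.ix_(idx, idx)] += k * W
        b[idx] += W @ Yp.sum(axis=0)
        logdet_sum += k * logdet
        cache.append((idx, Yp, W))
    signA, logdetA = np.linalg.slogdet(A)
    if signA <= 0:
        return _BIG, None, None
    beta = np.linalg.solve(A, b)
    quad = 0.0
    for idx, Yp, W in cache:
        R = Yp - beta[idx]
        quad += float(np.einsum("ij,jk,ik->", R, W, R))
    nll = 0.5 * (logdet_sum + quad + (logdetA if reml else 0.0))
    return nll, beta, np.linalg.inv(A)


def _initial_sigma(Y: np.ndarray) -> np.ndarray:
    """Pairwise-complete covariance, eigenvalue-clipped to be PD."""
    S = pd.DataFrame(Y).cov(min_periods=2).to_numpy()
    if np.any(~np.isfinite(S)):
        v = np.nanvar(Y, axis=0, ddof=1)
        v = np.where(np.isfinite(v) & (v > 0), v, np.nanvar(Y))
        S = np.diag(v)
    S = (S + S.T) / 2
    w, V = np.linalg.eigh(S)
    floor = max(w.max(), 1.0) * 1e-4
    return V @ np.diag(np.maximum(w, floor)) @ V.T


def fit_time_course(
    records: pd.DataFrame,
    outcome: str,
    cov_structure: str = "unstructured",
    reml: bool = True,
    complete_case: bool = False,
    patient_intercept: bool = False,
    max_iter: int = 500,
) -> TimeCourseFit:
    """Fit the repeated-measures model for one outcome.

    ``complete_case=True`` drops joints with any missing visit instead of
    using the MAR likelihood.  ``patient_intercept=True`` adds a shared
    patient-level random intercept across a patient's two joints (off by
    default).  On a singular unstructured covariance the fit falls back to
    a diagonal-plus-common-correlation structure with a warning.
    """
    Y, joint_ids, patient_ids = _outcome_matrix(records, outcome)
    if complete_case:
        keep = ~np.any(np.isnan(Y), axis=1)
        Y, joint_ids, patient_ids = Y[keep], joint_ids[keep], patient_ids[keep]
    n = len(Y)
    if n < 2:
        raise ValueError("need at least 2 joints")
    obs_per_joint = np.sum(~np.isnan(Y), axis=1)
    if np.any(obs_per_joint < 2):
        bad = joint_ids[obs_per_joint < 2]
        raise ValueError(f"joints with fewer than 2 observed timepoints: {list(bad)}")
    n_obs = np.sum(~np.isnan(Y), axis=0)
    if np.any(n_obs == 0):
        raise ValueError("every timepoint needs at least one observation")

    if patient_intercept:
        return _fit_patient_intercept(Y, patient_ids, outcome, reml, n_obs, max_iter)

    # group joints by observation pattern
    mask = ~np.isnan(Y)
    patterns = []
    for pat in np.unique(mask, axis=0):
        rows = np.all(mask == pat, axis=1)
        idx = np.flatnonzero(pat)
        patterns.append((idx, Y[np.ix_(rows, idx)]))

    complete = np.all(mask)
    if complete and cov_structure == "unstructured":
        # closed-form REML: saturated means, (n-1)-divisor covariance
        beta = Y.mean(axis=0)
        Rc = Y - beta
        sigma = Rc.T @ Rc / (n - 1 if reml else n)
        nll, _, Ainv = _profile_nll(sigma, patterns, reml)
        cov_means = sigma / n
        ll_history = [-nll]
        converged = True
    else:
        sigma, ll_history, converged = _optimize_sigma(
            Y, patterns, reml, cov_structure, max_iter
        )
        if cov_structure == "unstructured" and (
            not converged or np.linalg.cond(sigma) > 1e10
        ):
            warnings.warn(
                f"{outcome}: unstructured covariance is singular or did not converge; "
                "falling back to diagonal-plus-common-correlation",
                stacklevel=2,
            )
            return fit_time_course(
                records, outcome, cov_structure="cs", reml=reml,
                complete_case=complete_case, max_iter=max_iter,
            )
        nll, beta, Ainv = _profile_nll(sigma, patterns, reml)
        if beta is None:
            raise ConvergenceError(f"{outcome}: likelihood is degenerate at the optimum")
        cov_means = Ainv

    ses = np.sqrt(np.diag(cov_means))
    stat, p = _overall_test(beta, cov_means)
    return TimeCourseFit(
        outcome=outcome,
        means=beta,
        ses=ses,
        cov_means=cov_means,
        covariance=sigma,
        overall_stat=stat,
        overall_p=p,
        loglik=-nll,
        ll_history=ll_history,
        n_joints=n,
        n_obs=n_obs,
        cov_structure=cov_structure,
        reml=reml,
        converged=converged,
    )


def _optimize_sigma(Y, patterns, reml, cov_structure, max_iter):
    if cov_structure == "unstructured":
        to_sigma = _theta_to_sigma
        theta0 = _sigma_to_theta(_initial_sigma(Y))
    elif cov_structure == "cs":
        to_sigma = _cs_theta_to_sigma
        v = np.nanvar(Y, axis=0, ddof=1)
        v = np.where(np.isfinite(v) & (v > 0), v, max(np.nanvar(Y), 1.0))
        theta0 = np.concatenate([0.5 * np.log(v), [0.0]])
    else:
        raise ValueError(f"unknown covariance structure {cov_structure!r}")

    def objective(theta):
        nll, _, _ = _profile_nll(to_sigma(theta), patterns, reml)
        return nll

    ll_history = [-objective(theta0)]

    def callback(xk):
        ll_history.append(-objective(xk))

    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B", callback=callback,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
    if not converged and not np.isfinite(res.fun):
        raise ConvergenceError(
            f"REML optimization diverged after {res.nit} iterations", last_loglik=-res.fun
        )
    return to_sigma(res.x), ll_history, converged


def _fit_patient_intercept(Y, patient_ids, outcome, reml, n_obs, max_iter):
    """Unstructured joint-level covariance plus a patient-level intercept."""
    groups = []
    for pid in pd.unique(patient_ids):
        rows = np.flatnonzero(patient_ids == pid)
        obs = [(r, np.flatnonzero(~np.isnan(Y[r]))) for r in rows]
        groups.append([(Y[r, idx], idx) for r, idx in obs])

    def assemble(theta):
        sigma = _theta_to_sigma(theta[:10])
        tau2 = np.exp(2 * theta[10])
        return sigma, tau2

    def objective(theta):
        sigma, tau2 = assemble(theta)
        A = np.zeros((4, 4))
        b = np.zeros(4)
        cache = []
        logdet_sum = 0.0
        for g in groups:
            p = sum(len(idx) for _, idx in g)
            V = np.zeros((p, p)) + tau2
            X = np.zeros((p, 4))
            y = np.empty(p)
            at = 0
            for yv, idx in g:
                k = len(idx)
                V[at : at + k, at : at + k] += sigma[np.ix_(idx, idx)]
                X[np.arange(at, at + k), idx] = 1.0
                y[at : at + k] = yv
                at += k
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                return _BIG
            W = np.linalg.inv(V)
            A += X.T @ W @ X
            b += X.T @ W @ y
            logdet_sum += logdet
            cache.append((X, W, y))
        signA, logdetA = np.linalg.slogdet(A)
        if signA <= 0:
            return _BIG
        beta = np.linalg.solve(A, b)
        quad = sum(float((y - X @ beta) @ W @ (y - X @ beta)) for X, W, y in cache)
        objective.state = (beta, np.linalg.inv(A))
        return 0.5 * (logdet_sum + quad + (logdetA if reml else 0.0))

    theta0 = np.concatenate([_sigma_to_theta(_initial_sigma(Y)), [0.0]])
    ll_history = [-objective(theta0)]
    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B",
        callback=lambda xk: ll_history.append(-objective(xk)),
        options={"maxiter": max_iter, "ftol": 1e-12},
    )
    objective(res.x)
    beta, cov_means = objective.state
    sigma, _ = assemble(res.x)
    stat, p = _overall_test(beta, cov_means)
    return TimeCourseFit(
        outcome=outcome,
        means=beta,
        ses=np.sqrt(np.diag(cov_means)),
        cov_means=cov_means,
        covariance=sigma,
        overall_stat=stat,
        overall_p=p,
        loglik=-res.fun,
        ll_history=ll_history,
        n_joints=len(Y),
        n_obs=n_obs,
        cov_structure="unstructured+patient",
        reml=reml,
        converged=bool(res.success),
    )


def _overall_test(means: np.ndarray, cov_means: np.ndarray):
    """Wald chi-square test of equal means across the four visits (df=3)."""
    C = np.array([[1, -1, 0, 0], [1, 0, -1, 0], [1, 0, 0, -1]], dtype=float)
    delta = C @ means
    W = C @ cov_means @ C.T
    stat = float(delta @ np.linalg.solve(W, delta))
    return stat, float(chi2.sf(stat, df=3))


def pairwise_contrasts(fit: TimeCourseFit, n_comparisons: int = 6, df=None):
    """The six ordered visit contrasts with Bonferroni adjustment.

    Differences follow the published table orientation: later visit minus
    earlier visit (so T0-vs-T1 is positive when T1 exceeds T0, and
    T1-vs-T2 is negative after the volume recedes).  ``df=None`` uses the
    normal approximation; a numeric ``df`` switches to a t reference.
    """
    ti = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    out = []
    for a, b in PAIRS:
        ia, ib = ti[a], ti[b]
        diff = float(fit.means[ib] - fit.means[ia])
        var = fit.cov_means[ia, ia] + fit.cov_means[ib, ib] - 2 * fit.cov_means[ia, ib]
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            z = diff / se
            p_raw = float(2 * (t_dist.sf(abs(z), df) if df else norm.sf(abs(z))))
        out.append(Contrast(a, b, diff, se, p_raw, min(1.0, n_comparisons * p_raw)))
    return out


def format_p(p: float, star_threshold: float = 1e-4) -> str:
    """Display rule for p-values: 4 decimals with < .0001 / > .9999 caps.

    Values at or below the study's significance threshold are starred.
    """
    star = "*" if p <= star_threshold else ""
    if p < 1e-4:
        return "< .0001" + star
    if p >= 0.9999:
        return "> .9999"
    return f"{p:.4f}" + star


def make_results_table(fit: TimeCourseFit, contrasts=None) -> pd.DataFrame:
    """Results table mirroring the published layout.

    Six rows: the first four carry the per-visit estimated means (SE) and
    the overall p-value on the first row; all six carry the post-hoc
    contrasts.  Numeric cells are rounded to 2 decimals so a CSV
    round-trip reproduces them exactly; p-values are display strings.
    """
    if contrasts is None:
        contrasts = pairwise_contrasts(fit)
    rows = []
    for i in range(6):
        c = contrasts[i]
        rows.append(
            {
                "outcome": fit.outcome if i == 0 else "",
                "time": TIMEPOINTS[i] if i < 4 else "",
                "estimated_mean": round(float(fit.means[i]), 2) if i < 4 else np.nan,
                "mean_se": round(float(fit.ses[i]), 2) if i < 4 else np.nan,
                "overall_p": format_p(fit.overall_p) if i == 0 else "",
                "posthoc": f"{c.earlier} versus {c.later}",
                "difference": round(c.difference, 2),
                "diff_se": round(c.se, 2),
                "p_bonferroni": format_p(c.p_adjusted),
            }
        )
    return pd.DataFrame(rows)


def format_results_text(table: pd.DataFrame) -> str:
    """Aligned-text rendition of a results table."""
    headers = [
        "Outcome", "Time", "Estimated mean (SE)", "Overall p-value",
        "Post-hoc", "Differences (SE)", "p-value (bonferroni)",
    ]
    lines = []
    for _, r in table.iterrows():
        mean_se = (
            f"{r['estimated_mean']:.2f} ({r['mean_se']:.2f})"
            if pd.notna(r["estimated_mean"])
            else ""
        )
        lines.append(
            [
                str(r["outcome"]), str(r["time"]), mean_se, str(r["overall_p"]),
                str(r["posthoc"]), f"{r['difference']:.2f} ({r['diff_se']:.2f})",
                str(r["p_bonferroni"]),
            ]
        )
    widths = [max(len(h), *(len(row[i]) for row in lines)) for i, h in enumerate(headers)]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    out = [fmt.format(*headers)]
    out += [fmt.format(*row) for row in lines]
    return "\n".join(out) + "\n"
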