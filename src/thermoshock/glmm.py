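"""Logistic mixed-effects model with a per-patient random intercept.

Repeated images from the same child are not independent, so shock status at
a horizon is modeled as

    logit P(y_ij = 1) = b0 + b1 * cpd_percent + b2 * age + b3 * pulse + u_i,
    u_i ~ Normal(0, sigma_u^2),

with the marginal likelihood integrated over u_i by fixed Gauss–Hermite
quadrature and maximized by a derivative-free bounded optimizer (Powell).
Covariates enter on their raw scales (percent, months, beats/min); they are
standardized internally for optimization and the estimates mapped back, so
the reported coefficients are raw-scale log-odds per unit.

Out-of-sample risk for an unseen patient uses the population-mean random
effect (zero): evaluation partitions are patient-disjoint by design, so no
subject-specific intercept is available at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

log = logging.getLogger("thermoshock.glmm")

DEFAULT_FEATURES = ("cpd_percent", "age_months", "pulse_rate")
_BETA_BOUND = 20.0       # on the standardized scale
_SEPARATION_LIMIT = 12.0  # |standardized beta| beyond this flags separation


@dataclass
class MixedLogitFit:
    """Raw-scale fixed effects, random-intercept SD and diagnostics."""

    beta: np.ndarray           # (1 + n_features,) intercept first
    se: np.ndarray             # matching standard errors (NaN if unavailable)
    sigma_u: float
    converged: bool
    message: str
    n_obs: int
    n_groups: int
    loglik: float
    feature_names: Tuple[str, ...]
    horizon: Optional[int] = None

    @property
    def sigma_u2(self) -> float:
        return self.sigma_u ** 2

    def coef(self, name: str) -> float:
        if name == "intercept":
            return float(self.beta[0])
        return float(self.beta[1 + self.feature_names.index(name)])

    def to_dict(self) -> dict:
        return {"beta": list(map(float, self.beta)),
                "se": list(map(float, self.se)),
                "sigma_u": float(self.sigma_u), "converged": self.converged,
                "message": self.message, "n_obs": self.n_obs,
                "n_groups": self.n_groups, "loglik": float(self.loglik),
                "feature_names": list(self.feature_names),
                "horizon": self.horizon}


def _group_codes(ids) -> Tuple[np.ndarray, int]:
    codes, uniq = pd.factorize(np.asarray(ids), sort=True)
    return codes, len(uniq)


def _nll_factory(X: np.ndarray, y: np.ndarray, codes: np.ndarray,
                 n_groups: int, n_quad: int):
    """Negative marginal log-likelihood over (beta_std, sigma_u)."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(weights / np.sqrt(np.pi))
    order = np.argsort(codes, kind="stable")
    Xo, yo, co = X[order], y[order], codes[order]
    starts = np.searchsorted(co, np.arange(n_groups))
    sign = np.where(yo == 1, 1.0, -1.0)[:, None]

    def nll(params: np.ndarray) -> float:
        beta, sigma = params[:-1], params[-1]
        eta = Xo @ beta
        # log p(y_j | u=node_k) for every obs x node
        z = sign * (eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :])
        ll_obs = log_expit(z)
        grp = np.add.reduceat(ll_obs, starts, axis=0) + logw[None, :]
        m = grp.max(axis=1)
        return -float(np.sum(m + np.log(np.sum(np.exp(grp - m[:, None]), axis=1))))

    return nll


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
    return H


def fit_glmm(records: pd.DataFrame, outcome: str = "outcome",
             group: str = "patient_id",
             features: Sequence[str] = DEFAULT_FEATURES,
             n_quad: int = 15, horizon: Optional[int] = None,
             ftol: float = 1e-6, max_evals: int = 10_000) -> MixedLogitFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Requires >= 2 patients and both outcome classes.  Non-convergence or
    (quasi-)separation yields a flagged fit (``converged=False``) with a
    diagnostic message rather than silent estimates.
    """
    df = records.dropna(subset=[outcome, group, *features])
    if len(df) < len(records):
        log.warning("fit_glmm: dropped %d rows with missing fields",
                    len(records) - len(df))
    y = df[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(
            f"outcome must contain both classes 0 and 1, got {classes}")
    codes, n_groups = _group_codes(df[group])
    if n_groups < 2:
        raise ValueError("need >= 2 patients for a random intercept")

    raw = df[list(features)].to_numpy(dtype=float)
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.column_stack([np.ones(len(df)), (raw - mu) / sd])

    nll = _nll_factory(Xs, y, codes, n_groups, n_quad)

    # initialize from an ordinary logistic fit (ignore clustering)
    import statsmodels.api as sm
    with np.errstate(all="ignore"):
        try:
            init = sm.Logit(y, Xs).fit(disp=0, maxiter=200)
            beta0 = np.clip(init.params, -_BETA_BOUND / 2, _BETA_BOUND / 2)
        except Exception:  # noqa: BLE001 - separation etc.; start from zero
            beta0 = np.zeros(Xs.shape[1])
    x0 = np.append(beta0, 0.5)

    bounds = [(-_BETA_BOUND, _BETA_BOUND)] * Xs.shape[1] + [(0.0, 10.0)]
    res = minimize(nll, x0, method="Powell", bounds=bounds,
                   options={"ftol": ftol, "xtol": 1e-6, "maxfev": max_evals})
    beta_std, sigma = res.x[:-1], float(res.x[-1])

    converged = bool(res.success)
    message = str(res.message)
    if np.max(np.abs(beta_std)) >= _SEPARATION_LIMIT:
        converged = False
        message = ("(quasi-)separation suspected: a standardized coefficient "
                   f"reached {np.max(np.abs(beta_std)):.1f}; estimates are "
                   "not trustworthy")

    # raw-scale back-transform (linear map) and delta-method covariance
    k = len(features)
    J = np.zeros((k + 1, k + 1))
    J[0, 0] = 1.0
    for j in range(k):
        J[0, j + 1] = -mu[j] / sd[j]
        J[j + 1, j + 1] = 1.0 / sd[j]
    beta_raw = J @ beta_std

    se_raw = np.full(k + 1, np.nan)
    if converged:
        try:
            H = _numerical_hessian(nll, res.x)
            cov_all = np.linalg.inv(H)
            cov_beta = cov_all[:k + 1, :k + 1]
            if np.any(np.diag(cov_beta) <= 0):
                raise np.linalg.LinAlgError("non-PD covariance")
        except np.linalg.LinAlgError:
            try:  # fall back to the beta block at fixed sigma
                Hb = _numerical_hessian(
                    lambda b: nll(np.append(b, sigma)), beta_std)
                cov_beta = np.linalg.inv(Hb)
            except np.linalg.LinAlgError:
                cov_beta = np.full((k + 1, k + 1), np.nan)
        cov_raw = J @ cov_beta @ J.T
        with np.errstate(invalid="ignore"):
            se_raw = np.sqrt(np.diag(cov_raw))

    return MixedLogitFit(beta=beta_raw, se=se_raw, sigma_u=sigma,
                         converged=converged, message=message,
                         n_obs=len(df), n_groups=n_groups,
                         loglik=-float(res.fun),
                         feature_names=tuple(features), horizon=horizon)


def predict_risk(fit: MixedLogitFit, rows: pd.DataFrame) -> np.ndarray:
    """Population-level risk (random effect = 0) for unseen patients."""
    if not fit.converged:
        raise ValueError(f"cannot predict from a non-converged fit: {fit.message}")
    missing = [f for f in fit.feature_names if f not in rows.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    X = np.column_stack([np.ones(len(rows)),
                         rows[list(fit.feature_names)].to_numpy(dtype=float)])
    if np.isnan(X).any():
        raise ValueError("missing covariate values in prediction rows")
    return expit(X @ fit.beta)


def assemble_records(cpd: pd.DataFrame, labels: pd.DataFrame,
                     horizon: int) -> pd.DataFrame:
    """One modeling row per image: CPD + covariates + outcome at ``horizon``.

    Joins on (patient_id, image reference time); the pulse-rate covariate is
    the imaging-time (horizon 0) window median — prediction is from a
    snapshot, so later vitals never enter the covariates.  Rows with missing
    CPD or missing label are dropped and counted.
    """
    lab_h = labels[labels.horizon_h == horizon]
    lab_0 = labels[labels.horizon_h == 0][
        ["image_id", "pulse_rate_median"]].rename(
        columns={"pulse_rate_median": "pulse_rate"})
    usable = cpd if "usable" not in cpd.columns else cpd[cpd.usable]
    merged = usable.merge(
        lab_h[["image_id", "patient_id", "label", "age_months"]],
        on=["image_id", "patient_id"], how="inner")
    merged = merged.merge(lab_0, on="image_id", how="left")
    out = merged[["image_id", "patient_id", "cpd_percent", "age_months",
                  "pulse_rate", "label"]].rename(columns={"label": "outcome"})
    n0 = len(out)
    out = out.dropna(subset=["cpd_percent", "pulse_rate", "outcome"])
    dropped = (len(cpd) - len(out))
    if dropped:
        log.info("assemble_records(horizon=%d): %d of %d images excluded "
                 "(missing CPD, label or pulse rate)", horizon, dropped, len(cpd))
    if out.empty:
        raise ValueError(f"empty join between CPD and labels at horizon {horizon}")
    out = out.copy()
    out["horizon"] = horizon
    out.attrs["n_dropped"] = dropped
    return out


def simulate_glmm_dataset(n_patients: int, obs_per_patient: int,
                          beta: Sequence[float], sigma_u: float,
                          seed: int = 0) -> pd.DataFrame:
    """Draw a dataset from the model itself (for parameter-recovery checks).

    ``beta`` is (intercept, cpd, age, pulse) on raw scales.  Covariates are
    drawn from plausible cohort ranges: CPD% ~ N(12, 15), age ~ U(0.2, 144)
    months, pulse ~ N(120, 20) beats/min.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    rows = []
    for i in range(n_patients):
        u = rng.normal(0.0, sigma_u)
        for _ in range(obs_per_patient):
            cpd_v = rng.normal(12.0, 15.0)
            age = rng.uniform(0.2, 144.0)
            pulse = rng.normal(120.0, 20.0)
            eta = beta[0] + beta[1] * cpd_v + beta[2] * age + beta[3] * pulse + u
            rows.append({"patient_id": f"S{i:04d}", "cpd_percent": cpd_v,
                         "age_months": age, "pulse_rate": pulse,
                         "outcome": int(rng.random() < expit(eta))})
    return pd.DataFrame(rows)
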