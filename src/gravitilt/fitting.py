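"""Hierarchical fitting of the modified utricular shear model and
error-based model comparison.

The response model for roll tilt is

    theta_per = rho_i + K * sin(theta) * [1 + M * (G - 1)] + eps

with a subject-specific intercept ``rho_i``.  The model is linear after the
reparameterization ``P = K * M``:

    theta_per = rho_i + K * sin(theta) + P * sin(theta) * (G - 1)

so it is estimated as a linear mixed model (random subject intercept, REML)
and ``M = P / K`` is recovered with a delta-method standard error.  Reported
columns mirror the published table: estimate, standard error, z-value,
two-sided p-value.

Model comparison uses the coefficient of determination computed on
*perceptual errors* (perceived minus actual angle), per condition mean:
``R^2 = 1 - SS_res / SS_tot``; values below zero mean the model fits worse
than the global mean error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, UndefinedRSquaredError, UnidentifiableModelError
from .static_models import MODEL_REGISTRY, TiltCondition, evaluate_model

__all__ = [
    "RESPONSE_COLUMNS",
    "Coefficient",
    "FitResult",
    "validate_response_table",
    "fit_modified_shear",
    "predict_errors",
    "r_squared_errors",
    "compare_models",
]

RESPONSE_COLUMNS = ["subject_id", "axis", "angle_deg", "g_level", "reported_deg", "rep"]


@dataclass(frozen=True)
class Coefficient:
    """One fitted coefficient with its Wald test."""

    estimate: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class FitResult:
    """Output of the hierarchical modified-shear fit."""

    K: Coefficient
    M: Coefficient
    rho: Coefficient
    subject_intercepts: dict
    cov: np.ndarray          # covariance of (rho, K, P), P = K*M
    loglik: float
    n_obs: int
    method: str              # "mixedlm" or "ols"

    def table(self) -> pd.DataFrame:
        """Coefficient table mirroring the published layout."""
        rows = []
        for name, c in (("rho_i", self.rho), ("K", self.K), ("M", self.M)):
            rows.append((name, c.estimate, c.se, c.z, _format_p(c.p)))
        return pd.DataFrame(
            rows, columns=["Coefficient", "Estimate", "Standard error",
                           "Z-values", "p-Values"])

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {"estimate": c.estimate, "se": c.se, "z": c.z, "p": c.p}
                for name, c in (("rho", self.rho), ("K", self.K), ("M", self.M))
            },
            "subject_intercepts": dict(self.subject_intercepts),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "method": self.method,
        }


def _format_p(p: float) -> str:
    return "<0.0005" if p < 5e-4 else f"{p:.3g}"


def validate_response_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check the response-table schema and return a clean copy."""
    missing = [c for c in RESPONSE_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"response table missing columns {missing}")
    df = data.loc[:, RESPONSE_COLUMNS].copy()
    if df["reported_deg"].isna().any():
        raise SchemaError("response table contains missing reported_deg values")
    bad_axis = set(df["axis"].unique()) - {"roll", "pitch"}
    if bad_axis:
        raise SchemaError(f"unknown axis values {sorted(bad_axis)}")
    return df


def fit_modified_shear(data: pd.DataFrame) -> FitResult:
    """Fit the modified utricular shear model to a roll response table.

    Requires roll-axis data spanning at least two gravity levels and two
    angles.  With fewer than two subjects the random-intercept variance is
    fixed to zero (plain least squares) with a warning.
    """
    df = validate_response_table(data)
    df = df[df["axis"] == "roll"]
    if df.empty:
        raise UnidentifiableModelError("no roll-axis rows to fit")
    if df["g_level"].nunique() < 2:
        raise UnidentifiableModelError(
            "M multiplies (G - 1): data at a single gravity level cannot "
            "identify it")
    if df["angle_deg"].nunique() < 2:
        raise UnidentifiableModelError("need at least two distinct tilt angles")

    y = df["reported_deg"].to_numpy(dtype=float)
    s = np.sin(np.radians(df["angle_deg"].to_numpy(dtype=float)))
    x2 = s * (df["g_level"].to_numpy(dtype=float) - 1.0)
    X = np.column_stack([np.ones_like(s), s, x2])
    groups = df["subject_id"].astype(str).to_numpy()
    n_subjects = len(np.unique(groups))

    method = "mixedlm"
    result = None
    if n_subjects < 2:
        warnings.warn("single subject: random-intercept variance fixed to 0",
                      stacklevel=2)
        method = "ols"
    else:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(y, X, groups=groups)
                result = model.fit(reml=True)
                if not np.all(np.isfinite(result.bse_fe)):
                    result = None
                    method = "ols"
            except (np.linalg.LinAlgError, ValueError):
                result = None
                method = "ols"

    if method == "mixedlm":
        beta = np.asarray(result.fe_params, dtype=float)
        cov = np.asarray(result.cov_params())[:3, :3]
        loglik = float(result.llf)
        re = result.random_effects
        intercepts = {k: float(np.asarray(v)[0]) for k, v in re.items()}
    else:
        beta, cov, loglik = _ols(y, X)
        mean_rho = beta[0]
        resid = y - X @ beta
        intercepts = {
            g: float(np.mean(resid[groups == g])) for g in np.unique(groups)
        }
        intercepts = {k: v for k, v in intercepts.items()}

    rho_hat, K_hat, P_hat = beta
    M_hat = P_hat / K_hat
    # delta method for M = P / K on (K, P) block of the covariance
    gvec = np.array([-P_hat / K_hat**2, 1.0 / K_hat])
    sub = cov[1:3, 1:3]
    var_M = float(gvec @ sub @ gvec)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se_M = float(np.sqrt(max(var_M, 0.0)))

    def coef(est, s_e):
        z = est / s_e if s_e > 0 else np.inf * np.sign(est) if est != 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        return Coefficient(float(est), float(s_e), float(z), float(p))

    return FitResult(
        K=coef(K_hat, se[1]),
        M=coef(M_hat, se_M),
        rho=coef(rho_hat, se[0]),
        subject_intercepts=intercepts,
        cov=cov,
        loglik=loglik,
        n_obs=len(y),
        method=method,
    )


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, k = X.shape
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    cov = sigma2 * XtX_inv
    with np.errstate(divide="ignore"):
        ll = -0.5 * n * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1.0)
    return beta, cov, float(ll)


def predict_errors(model: str, conditions, params=None) -> pd.DataFrame:
    """Per-condition predicted perceptual error (perceived - actual, deg)."""
    rows = []
    for cond in conditions:
        perceived = evaluate_model(model, cond, params)
        rows.append((cond.axis, cond.angle_deg, cond.g_level, perceived,
                     perceived - cond.angle_deg))
    return pd.DataFrame(rows, columns=["axis", "angle_deg", "g_level",
                                       "predicted_deg", "predicted_error_deg"])


def r_squared_errors(predicted_errors, observed_mean_errors) -> float:
    """Coefficient of determination on condition-mean perceptual errors.

    ``R^2 = 1 - sum (obs - pred)^2 / sum (obs - mean(obs))^2``; may be
    negative (model worse than the global mean); never clamped.
    """
    pred = np.asarray(predicted_errors, dtype=float)
    obs = np.asarray(observed_mean_errors, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-d vectors")
    if pred.size < 2:
        raise ValueError("need at least two conditions")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError(
            "observed mean errors are constant: R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def compare_models(data: pd.DataFrame, models=None, params_by_model=None) -> dict:
    """R^2 (on condition-mean errors) of each named static model.

    Only the conditions present in ``data`` enter the comparison; the
    observed errors are per-(axis, angle, G) means of reported - actual.
    """
    df = validate_response_table(data)
    models = list(models or MODEL_REGISTRY)
    params_by_model = params_by_model or {}
    grouped = (
        df.assign(error_deg=df["reported_deg"] - df["angle_deg"])
          .groupby(["axis", "angle_deg", "g_level"], as_index=False)["error_deg"]
          .mean()
    )
    conds = [TiltCondition(r.axis, r.angle_deg, r.g_level)
             for r in grouped.itertuples()]
    out = {}
    for m in models:
        pred = predict_errors(m, conds, params_by_model.get(m))
        out[m] = r_squared_errors(pred["predicted_error_deg"].to_numpy(),
                                  grouped["error_deg"].to_numpy())
    return out
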