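"""Binary logistic regression with the clinical reporting surface.

Maximum-likelihood fits (Newton/IRLS via statsmodels) reported the way
clinical journals print them: per-term coefficient B, standard error, Wald
statistic (B/SE)^2, odds ratio with a 95% Wald interval exp(B +/- 1.96 SE),
the Omnibus likelihood-ratio test of the whole model against intercept-only,
and Nagelkerke's rescaled Cox-Snell pseudo-R^2

    R2_CS = 1 - exp(2 (l0 - l1) / n),      R2_N = R2_CS / (1 - exp(2 l0 / n)).

Categorical predictors use treatment (reference-level) dummy coding.  The
multivariable pCR model enters four prespecified terms simultaneously
("Enter" method, no selection): TIPI risk group (high vs low), hormone
receptor negativity, histological grade (G3 vs G2) and clinical stage (IIB
and III vs IIA) — the stage term additionally gets an overall multi-df Wald
test since its per-level contrasts are rarely of individual interest.

Quasi-complete separation is detected (diverging coefficients or failed
convergence) and flagged on the result rather than silently reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "WaldLogit",
    "fit_logistic",
    "omnibus_lr_test",
    "nagelkerke_r2",
    "univariable_screen",
    "multivariable_model",
    "MULTIVARIABLE_TERMS",
]

#: Coefficient magnitude beyond which quasi-complete separation is suspected.
SEPARATION_BETA = 15.0

#: Fixed multivariable design, in reporting order.
MULTIVARIABLE_TERMS = ("tipi_high", "hr_negative", "grade3", "stage_IIB", "stage_III")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic model with Wald, omnibus and pseudo-R^2 reporting."""

    terms: tuple[str, ...]  # includes "intercept" first
    beta: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    or_: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    p_values: np.ndarray
    loglik_null: float
    loglik_model: float
    omnibus_chi2: float
    omnibus_df: int
    omnibus_p: float
    nagelkerke_r2: float
    n_obs: int
    converged: bool
    n_iter: int
    cov_params: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    group_wald: dict = field(default_factory=dict)  # term-group -> (wald, df, p)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "B": self.beta,
                "SE": self.se,
                "Wald": self.wald,
                "OR": self.or_,
                "OR_ci_low": self.or_ci_low,
                "OR_ci_high": self.or_ci_high,
                "p": self.p_values,
            }
        )


class WaldLogit(BaseEstimator, ClassifierMixin):
    """Unpenalized ML logistic regression with Wald-style clinical reporting.

    scikit-learn estimator facade over a Newton-Raphson (IRLS) fit.  ``fit``
    accepts a design matrix (DataFrame columns become term names) and a
    binary outcome; an intercept is always added internally.  Fitted
    attributes mirror the printed reporting surface: ``beta_``, ``se_``,
    ``wald_``, ``or_``, ``or_ci_``, ``p_values_``, ``omnibus_`` (chi2, df, p),
    ``nagelkerke_r2_``, ``converged_``.

    Parameters
    ----------
    max_iter : int, default 100
        Newton iteration cap.
    tol : float, default 1e-10
        Relative log-likelihood convergence tolerance.
    z_crit : float, default 1.96
        Critical value for the 95% Wald interval (kept at the conventional
        1.96 rather than the exact quantile, matching clinical reporting).
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10, z_crit: float = 1.96):
        self.max_iter = max_iter
        self.tol = tol
        self.z_crit = z_crit

    def fit(self, X, y, term_groups: dict | None = None) -> "WaldLogit":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
            if X_arr.ndim == 1:
                X_arr = X_arr[:, None]
            names = [f"x{i}" for i in range(X_arr.shape[1])]
        y_arr = np.asarray(y).astype(float)
        if y_arr.ndim != 1 or X_arr.shape[0] != y_arr.shape[0]:
            raise ValueError("X and y must have matching first dimensions")
        if not np.all(np.isin(y_arr, (0.0, 1.0))):
            raise ValueError("outcome must be binary")
        n, k = X_arr.shape
        if n <= k + 1:
            raise ValueError("need more observations than parameters")
        col_var = X_arr.var(axis=0)
        if np.any(col_var == 0):
            bad = [names[i] for i in np.flatnonzero(col_var == 0)]
            raise ValueError(f"constant predictor column(s): {bad} (intercept is added internally)")

        design = sm.add_constant(X_arr, has_constant="add")
        hessian_failed = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y_arr, design)
            try:
                res = model.fit(
                    method="newton", maxiter=self.max_iter, tol=self.tol, disp=0, warn_convergence=False
                )
            except np.linalg.LinAlgError:
                # Newton's Hessian went singular (typically quasi-complete
                # separation); fall back to BFGS and flag the fit.
                hessian_failed = True
                res = model.fit(method="bfgs", maxiter=max(self.max_iter, 500), disp=0, warn_convergence=False)
        beta = np.asarray(res.params, dtype=float)
        converged = (
            not hessian_failed
            and bool(res.mle_retvals.get("converged", True))
            and bool(np.all(np.abs(beta) <= SEPARATION_BETA))
        )
        if not converged:
            logger.warning("logistic fit flagged: non-convergence or quasi-complete separation suspected")

        se = np.asarray(res.bse, dtype=float)
        wald = (beta / se) ** 2
        p_vals = 2.0 * stats.norm.sf(np.abs(beta / se))
        ll1 = float(res.llf)
        p_hat = y_arr.mean()
        ll0 = float(n * (p_hat * np.log(p_hat) + (1 - p_hat) * np.log(1 - p_hat))) if 0 < p_hat < 1 else 0.0
        chi2 = max(0.0, 2.0 * (ll1 - ll0))
        df = k
        omnibus_p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
        r2_max = 1.0 - np.exp(2.0 * ll0 / n)
        r2_n = float(np.clip(r2_cs / r2_max, 0.0, 1.0)) if r2_max > 0 else 0.0

        terms = ("intercept",) + tuple(names)
        cov = np.asarray(res.cov_params(), dtype=float)
        group_wald: dict = {}
        if term_groups:
            for gname, members in term_groups.items():
                idx = np.array([terms.index(m) for m in members])
                b = beta[idx]
                v = cov[np.ix_(idx, idx)]
                w = float(b @ np.linalg.solve(v, b))
                group_wald[gname] = (w, len(idx), float(stats.chi2.sf(w, len(idx))))

        with np.errstate(over="ignore"):  # separation-flagged fits can overflow to inf
            or_point = np.exp(beta)
            or_low = np.exp(beta - self.z_crit * se)
            or_high = np.exp(beta + self.z_crit * se)
        self.fit_ = LogisticFit(
            terms=terms,
            beta=beta,
            se=se,
            wald=wald,
            or_=or_point,
            or_ci_low=or_low,
            or_ci_high=or_high,
            p_values=p_vals,
            loglik_null=ll0,
            loglik_model=ll1,
            omnibus_chi2=chi2,
            omnibus_df=df,
            omnibus_p=omnibus_p,
            nagelkerke_r2=r2_n,
            n_obs=n,
            converged=converged,
            n_iter=int(res.mle_retvals.get("iterations", -1)),
            cov_params=cov,
            group_wald=group_wald,
        )
        self.coef_ = beta[1:][None, :]
        self.intercept_ = beta[:1]
        self.beta_ = beta
        self.se_ = se
        self.wald_ = wald
        self.or_ = or_point
        self.or_ci_ = np.stack([or_low, or_high], axis=1)
        self.p_values_ = p_vals
        self.omnibus_ = (chi2, df, omnibus_p)
        self.nagelkerke_r2_ = r2_n
        self.converged_ = converged
        self.classes_ = np.array([0, 1])
        self._n_features = k
        return self

    def predict_proba(self, X) -> np.ndarray:
        X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if X_arr.ndim == 1:
            X_arr = X_arr[:, None]
        eta = self.intercept_[0] + X_arr @ self.beta_[1:]
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.stack([1 - p, p], axis=1)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def fit_logistic(outcome, design, term_groups: dict | None = None, **kwargs) -> LogisticFit:
    """Fit a logistic model and return its :class:`LogisticFit` report."""
    est = WaldLogit(**kwargs)
    est.fit(design, outcome, term_groups=term_groups)
    return est.fit_


def omnibus_lr_test(fit: LogisticFit) -> tuple[float, int, float]:
    """Omnibus likelihood-ratio test: chi2 = 2(l_model - l_null), df = #slopes."""
    return fit.omnibus_chi2, fit.omnibus_df, fit.omnibus_p


def nagelkerke_r2(fit: LogisticFit) -> float:
    return fit.nagelkerke_r2


def design_matrix(df: pd.DataFrame, terms=MULTIVARIABLE_TERMS) -> pd.DataFrame:
    """Treatment-coded design for the prespecified pCR model.

    Reference levels: low TIPI group, HR-positive, grade 2, stage IIA.
    Expects ``tipi_group`` (from scoring), ``hr_status``, ``grade`` and
    ``clinical_stage`` columns.
    """
    cols = {}
    for term in terms:
        if term == "tipi_high":
            cols[term] = (df["tipi_group"] == "high").astype(float)
        elif term == "hr_negative":
            cols[term] = (df["hr_status"] == "negative").astype(float)
        elif term == "grade3":
            cols[term] = (df["grade"].astype(int) == 3).astype(float)
        elif term == "stage_IIB":
            cols[term] = (df["clinical_stage"] == "IIB").astype(float)
        elif term == "stage_III":
            cols[term] = (df["clinical_stage"] == "III").astype(float)
        else:
            cols[term] = df[term].astype(float)
    return pd.DataFrame(cols, index=df.index)


def univariable_screen(df: pd.DataFrame, terms=MULTIVARIABLE_TERMS) -> pd.DataFrame:
    """One single-predictor logistic model per term; rows in input order.

    Multi-level categorical terms that expand to several dummies (clinical
    stage) are screened jointly in one model.  Separation is flagged per term
    in the ``converged`` column.
    """
    y = df["pcr"].astype(int).to_numpy()
    full = design_matrix(df)
    rows = []
    # stage dummies are screened together in one model
    grouped = []
    seen_stage = False
    for t in terms:
        if t.startswith("stage_"):
            if not seen_stage:
                grouped.append(("clinical_stage", [u for u in terms if u.startswith("stage_")]))
                seen_stage = True
        else:
            grouped.append((t, [t]))
    for name, members in grouped:
        fit = fit_logistic(y, full[members])
        for i, member in enumerate(members, start=1):
            rows.append(
                {
                    "term": member,
                    "B": fit.beta[i],
                    "SE": fit.se[i],
                    "Wald": fit.wald[i],
                    "OR": fit.or_[i],
                    "OR_ci_low": fit.or_ci_low[i],
                    "OR_ci_high": fit.or_ci_high[i],
                    "p": fit.p_values[i],
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def multivariable_model(df: pd.DataFrame) -> LogisticFit:
    """Enter-method multivariable pCR model with the four prespecified terms.

    All terms are entered simultaneously; clinical stage is expanded as a
    3-level categorical (reference IIA) and additionally reported with an
    overall 2-df Wald test in ``group_wald["clinical_stage"]``.
    """
    y = df["pcr"].astype(int).to_numpy()
    X = design_matrix(df)
    return fit_logistic(y, X, term_groups={"clinical_stage": ["stage_IIB", "stage_III"]})
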