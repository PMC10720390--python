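"""Logistic-regression association analyses.

Fits the six-category joint model (PRS tertile x carrier status, reference =
intermediate-PRS non-carrier), the marginal carrier-only and PRS-only models,
and the multiplicative-interaction tests (likelihood ratio and Wald), all
adjusted for age, study indicators and the first 10 ancestry principal
components. Fits are plain maximum likelihood (Newton, log-likelihood
tolerance 1e-8, max 100 iterations) with an optional Firth-type penalized
alternative for sparse cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .io_cohort import JOINT_CATEGORIES, PRS_LEVELS, REFERENCE_CATEGORY, logger

OUTCOMES = ("overall", "aggressive", "nonaggressive", "metastatic")

_OUTCOME_CASE_CLASSES = {
    "overall": {"aggressive", "nonaggressive", "metastatic-aggressive", "unclassified"},
    "aggressive": {"aggressive", "metastatic-aggressive"},
    "nonaggressive": {"nonaggressive"},
    "metastatic": {"metastatic-aggressive"},
}

ZSCORE_95 = 1.959963984540054  # Phi^{-1}(0.975)


class ConvergenceError(RuntimeError):
    """The ML fit failed to converge within the iteration budget."""


@dataclass
class ORTable:
    """Per-category odds ratios with the underlying coefficients.

    ``beta``/``cov`` cover only the category coefficients (in ``categories``
    order, reference omitted); estimable ORs satisfy OR = exp(beta).
    Categories flagged in ``flags`` (zero cases or zero controls) have
    undefined (NaN) ORs.
    """

    outcome: str
    categories: list
    reference: str
    or_: pd.Series
    ci_lo: pd.Series
    ci_hi: pd.Series
    p: pd.Series
    beta: pd.Series
    cov: pd.DataFrame
    counts: pd.DataFrame  # index category, columns n_cases / n_controls
    flags: dict = field(default_factory=dict)
    loglik: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.categories:
            rows.append(
                {
                    "outcome": self.outcome,
                    "category": c,
                    "n_cases": int(self.counts.loc[c, "n_cases"]),
                    "n_controls": int(self.counts.loc[c, "n_controls"]),
                    "OR": 1.0 if c == self.reference else self.or_.get(c, np.nan),
                    "ci_lo": np.nan if c == self.reference else self.ci_lo.get(c, np.nan),
                    "ci_hi": np.nan if c == self.reference else self.ci_hi.get(c, np.nan),
                    "p": np.nan if c == self.reference else self.p.get(c, np.nan),
                    "flag": self.flags.get(c, "reference" if c == self.reference else ""),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class InteractionTestResult:
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    wald_stat: float
    wald_df: int
    wald_p: float


def _outcome_mask(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """Boolean case indicator restricted to the outcome's contrast; rows not
    in the contrast (e.g. nonaggressive cases in the aggressive analysis, or
    unclassified cases outside the overall analysis) are excluded (NaN)."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")
    y = pd.Series(np.nan, index=cohort.index)
    y[cohort["outcome"] == "control"] = 0.0
    y[cohort["outcome"].isin(_OUTCOME_CASE_CLASSES[outcome])] = 1.0
    return y


def _covariate_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Age (continuous, years), study indicators (first level dropped) and
    any pc* columns."""
    X = pd.DataFrame(index=df.index)
    X["age"] = df["age"].astype(float)
    studies = sorted(df["study"].unique())
    for s in studies[1:]:
        X[f"study_{s}"] = (df["study"] == s).astype(float)
    for c in sorted(c for c in df.columns if c.startswith("pc")):
        X[c] = df[c].astype(float)
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame, firth: bool = False):
    """ML logistic fit; returns the statsmodels result object."""
    Xc = sm.add_constant(X, has_constant="add")
    if firth:
        return _fit_firth(y, Xc)
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except Exception as e:  # singular hessian etc.
            raise ConvergenceError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge in 100 iterations")
    return res


class _FirthResult:
    """Minimal result shim exposing params/cov_params/llf like statsmodels."""

    def __init__(self, params, cov, llf, names):
        self.params = pd.Series(params, index=names)
        self._cov = pd.DataFrame(cov, index=names, columns=names)
        self.llf = llf

    def cov_params(self):
        return self._cov


def _fit_firth(y: np.ndarray, Xc: pd.DataFrame, maxiter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior score correction)."""
    X = Xc.to_numpy(dtype=float)
    names = list(Xc.columns)
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        XtWX = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"Firth fit: singular information matrix: {e}") from e
        h = np.einsum("ij,jk,ik->i", X * W[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        eta = X @ beta
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))) + 0.5 * np.linalg.slogdet(XtWX)[1])
        if abs(ll - ll_old) < tol:
            ll_old = ll
            break
        ll_old = ll
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    return _FirthResult(beta, cov, ll_old, names)


def _category_or_table(res, outcome, categories, reference, counts, flags) -> ORTable:
    est = [c for c in categories if c != reference and c not in flags]
    beta = res.params.reindex(est)
    cov = res.cov_params().reindex(index=est, columns=est)
    se = pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=est) if est else pd.Series(dtype=float)
    or_ = np.exp(beta)
    return ORTable(
        outcome=outcome,
        categories=list(categories),
        reference=reference,
        or_=or_,
        ci_lo=np.exp(beta - ZSCORE_95 * se),
        ci_hi=np.exp(beta + ZSCORE_95 * se),
        p=pd.Series(2 * st.norm.sf(np.abs(beta / se)), index=est),
        beta=beta,
        cov=cov,
        counts=counts,
        flags=flags,
        loglik=float(res.llf),
    )


def _prepare(cohort, outcome, category_col, categories, reference, adjust):
    y = _outcome_mask(cohort, outcome)
    df = cohort.loc[y.notna()].copy()
    yv = y.loc[df.index]
    if yv.sum() == 0 or (1 - yv).sum() == 0:
        raise ValueError(f"outcome {outcome!r}: need at least one case and one control")
    counts = pd.DataFrame(0, index=pd.Index(categories, name="category"), columns=["n_cases", "n_controls"])
    for c in categories:
        m = df[category_col] == c
        counts.loc[c, "n_cases"] = int((yv[m] == 1).sum())
        counts.loc[c, "n_controls"] = int((yv[m] == 0).sum())
    flags = {}
    for c in categories:
        if c == reference:
            continue
        if counts.loc[c, "n_cases"] == 0 or counts.loc[c, "n_controls"] == 0:
            flags[c] = "undefined: zero cases or controls"
            logger.warning("%s: category %s has an empty cell; OR undefined", outcome, c)
        elif min(counts.loc[c, "n_cases"], counts.loc[c, "n_controls"]) < 5:
            logger.warning("%s: category %s has <5 cases or controls; ML estimate may be unstable", outcome, c)
    # rows in flagged categories cannot contribute a contrast; drop them
    drop = [c for c in flags]
    if drop:
        keep = ~df[category_col].isin(drop)
        df, yv = df.loc[keep], yv.loc[keep]
    X = pd.DataFrame(index=df.index)
    for c in categories:
        if c == reference or c in flags:
            continue
        X[c] = (df[category_col] == c).astype(float)
    if adjust:
        X = pd.concat([X, _covariate_matrix(df)], axis=1)
    return yv.to_numpy(dtype=float), X, counts, flags


def fit_joint_model(cohort: pd.DataFrame, outcome: str = "overall", adjust: bool = True,
                    firth: bool = False) -> ORTable:
    """Six-category joint logistic model of the outcome on PRS-tertile x
    carrier indicators (reference intermediate-PRS non-carrier) plus
    adjustment covariates. Returns ORs with Wald 95% CIs, p-values and the
    category coefficient vector/covariance for absolute-risk propagation."""
    y, X, counts, flags = _prepare(cohort, outcome, "joint_category",
                                   JOINT_CATEGORIES, REFERENCE_CATEGORY, adjust)
    res = _fit_logit(y, X, firth=firth)
    return _category_or_table(res, outcome, JOINT_CATEGORIES, REFERENCE_CATEGORY, counts, flags)


def fit_marginal_models(cohort: pd.DataFrame, outcome: str = "overall", adjust: bool = True,
                        firth: bool = False) -> tuple[ORTable, ORTable]:
    """Marginal fits: carrier status alone (non-carrier reference) and PRS
    category alone (intermediate reference), same covariates as the joint fit."""
    work = cohort.copy()
    work["carrier_cat"] = np.where(work["carrier"], "carrier", "noncarrier")
    y, X, counts, flags = _prepare(work, outcome, "carrier_cat",
                                   ["noncarrier", "carrier"], "noncarrier", adjust)
    carrier_table = _category_or_table(_fit_logit(y, X, firth=firth), outcome,
                                       ["noncarrier", "carrier"], "noncarrier", counts, flags)
    y, X, counts, flags = _prepare(work, outcome, "prs_category",
                                   PRS_LEVELS, "intermediate", adjust)
    prs_table = _category_or_table(_fit_logit(y, X, firth=firth), outcome,
                                   PRS_LEVELS, "intermediate", counts, flags)
    return carrier_table, prs_table


def test_interaction(cohort: pd.DataFrame, outcome: str = "overall", adjust: bool = True,
                     continuous_prs: bool = False) -> InteractionTestResult:
    """Multiplicative PRS x carrier interaction.

    Default parameterization: main effects (2 PRS-tertile indicators +
    carrier) versus those plus the 2 tertile-x-carrier product terms; the LRT
    statistic is 2*(ll_full - ll_reduced) on df = number of product terms and
    the Wald test is the joint chi-square on the product coefficients. With
    ``continuous_prs``, a single standardized-PRS x carrier product is tested
    (df = 1). Product columns that are identically zero (empty cells) are
    dropped with a warning and the df reduced.
    """
    y = _outcome_mask(cohort, outcome)
    df = cohort.loc[y.notna()].copy()
    yv = y.loc[df.index].to_numpy(dtype=float)
    X = pd.DataFrame(index=df.index)
    carrier = df["carrier"].astype(float)
    if continuous_prs:
        z = (df["prs_score"] - df["prs_score"].mean()) / df["prs_score"].std()
        X["prs_z"] = z
        X["carrier"] = carrier
        products = {"prs_z_x_carrier": z * carrier}
    else:
        X["low"] = (df["prs_category"] == "low").astype(float)
        X["high"] = (df["prs_category"] == "high").astype(float)
        X["carrier"] = carrier
        products = {
            "low_x_carrier": X["low"] * carrier,
            "high_x_carrier": X["high"] * carrier,
        }
    kept = {}
    for name, col in products.items():
        on = col != 0
        # a product term is estimable only when its nonzero rows contain both
        # cases and controls (otherwise the cell is empty / separated)
        if not on.any() or on.all() or yv[on.to_numpy()].std() == 0:
            logger.warning("test_interaction: product term %s has an empty cell; dropped (df reduced)", name)
        else:
            kept[name] = col
    if not kept:
        raise ValueError("no estimable interaction terms (all product cells empty)")
    if adjust:
        X = pd.concat([X, _covariate_matrix(df)], axis=1)
    res_reduced = _fit_logit(yv, X)
    Xf = X.copy()
    for name, col in kept.items():
        Xf[name] = col
    res_full = _fit_logit(yv, Xf)
    k = len(kept)
    lrt = max(0.0, 2.0 * (res_full.llf - res_reduced.llf))
    b = res_full.params.reindex(list(kept)).to_numpy()
    V = res_full.cov_params().reindex(index=list(kept), columns=list(kept)).to_numpy()
    wald = float(b @ np.linalg.solve(V, b))
    return InteractionTestResult(
        lrt_stat=float(lrt), lrt_df=k, lrt_p=float(st.chi2.sf(lrt, k)),
        wald_stat=wald, wald_df=k, wald_p=float(st.chi2.sf(wald, k)),
    )


def write_or_table(table: ORTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_covariance(table: ORTable, path) -> None:
    table.cov.to_csv(path, sep="\t")
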