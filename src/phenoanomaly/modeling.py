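"""OLS fitting, AICc model selection and the regression diagnostics suite.

The response (standardized Annual Anomaly) is regressed on the year number
and 13 standardized windowed climate covariates. Model choice is by
exhaustive all-subsets enumeration ranked by AICc, cross-checked with a
stepwise-backward AIC pass; diagnostics cover variance inflation factors,
Type-II partial R², a linear-vs-quadratic functional-form comparison,
leave-one-covariate residual checks and residual normality.

Conventions
-----------
* The parameter count ``k`` entering AIC/AICc includes the intercept, every
  slope coefficient, and the residual variance.
* AICc = AIC + 2k(k+1)/(n-k-1); AIC = -2*loglik + 2k at the Gaussian MLE.
* Selection ties break deterministically: fewer terms first, then
  lexicographic term order.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AnalysisError

_LOG2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass
class FittedModel:
    """An OLS fit with the quantities the reports need."""

    terms: tuple[str, ...]
    params: pd.Series           # includes "Intercept"
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2: float               # MLE residual variance, RSS/n
    log_likelihood: float
    r_squared: float
    adj_r_squared: float

    @property
    def k(self) -> int:
        """Estimated parameters: intercept + slopes + residual variance."""
        return len(self.terms) + 2

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc_from_aic(self.aic, self.k, self.n)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1 - alpha / 2, df=self.n - len(self.terms) - 1)
        return pd.DataFrame(
            {"lower": self.params - tcrit * self.se,
             "upper": self.params + tcrit * self.se}
        )


@dataclasses.dataclass
class ModelSelectionResult:
    """Ranked candidate ledger plus the chosen best model."""

    ledger: pd.DataFrame        # columns: terms, n_terms, aicc, delta_aicc
    best: FittedModel
    method: str
    skipped: list[tuple[tuple[str, ...], str]] = dataclasses.field(default_factory=list)
    path: list[tuple[str, float]] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class LinQuadComparison:
    """AICc comparison of a single covariate entered linearly vs quadratically."""

    variable: str
    aicc_linear: float
    aicc_quadratic: float
    choice: str

    @property
    def delta_aicc(self) -> float:
        return self.aicc_quadratic - self.aicc_linear


@dataclasses.dataclass
class ResidualDiagnostics:
    """Residual-vs-fitted and normal-quantile material plus a normality test."""

    fitted: np.ndarray
    residuals: np.ndarray
    theoretical_quantiles: np.ndarray
    sample_quantiles: np.ndarray
    normality_statistic: float
    normality_p: float
    degenerate: bool


def gaussian_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood at the MLE variance sigma^2 = RSS/n."""
    if rss <= 0:
        raise AnalysisError("zero residual sum of squares: saturated fit")
    return -0.5 * n * (_LOG2PI + math.log(rss / n) + 1.0)


def aicc_from_aic(aic: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise AnalysisError(f"AICc undefined: n={n}, k={k} leaves n-k-1 <= 0")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(model: FittedModel) -> float:
    """Small-sample corrected AIC of a fitted model."""
    return model.aicc


def _design_matrix(design: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    X = design[list(terms)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(design)), X])


def fit_ols(
    response, design: pd.DataFrame, terms: Sequence[str] | None = None
) -> FittedModel:
    """Exact least squares of the response on the named covariate columns."""
    if terms is None:
        terms = tuple(design.columns)
    terms = tuple(terms)
    y = np.asarray(response, dtype=float)
    n = y.size
    p = len(terms)
    if n <= p + 1:
        raise AnalysisError(f"n={n} too small for {p} covariates plus intercept")
    X = _design_matrix(design, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _find_collinear(design, terms)
        raise AnalysisError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(y, X).fit()
    names = ["Intercept", *terms]
    resid = np.asarray(res.resid)
    rss = float(resid @ resid)
    return FittedModel(
        terms=terms,
        params=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        n=n,
        residuals=resid,
        fitted=np.asarray(res.fittedvalues),
        sigma2=rss / n,
        log_likelihood=float(res.llf),
        r_squared=float(res.rsquared) if p else 0.0,
        adj_r_squared=float(res.rsquared_adj) if p else 0.0,
    )


def _find_collinear(design: pd.DataFrame, terms: Sequence[str]) -> list[str]:
    bad = []
    cols = list(terms)
    X = design[cols].to_numpy(dtype=float)
    base_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(design)), X]))
    for i, name in enumerate(cols):
        Xi = np.delete(X, i, axis=1)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(design)), Xi])) == base_rank:
            bad.append(name)
    return bad


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each covariate against all the others."""
    cols = list(design.columns)
    if len(cols) < 2:
        raise AnalysisError("VIF needs at least 2 covariates")
    out = {}
    for col in cols:
        others = [c for c in cols if c != col]
        fm = fit_ols(design[col], design, others)
        r2 = fm.r_squared
        if r2 >= 1.0 - 1e-12:
            raise AnalysisError(f"perfect collinearity: infinite VIF for {col!r}")
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def _subset_rss(y: np.ndarray, X: np.ndarray, subsets: list[tuple[int, ...]]) -> np.ndarray:
    """RSS of the intercept+subset regressions, batched per subset size.

    Uses the Gram-matrix identity RSS = y'y - c_S' G_S^{-1} c_S with
    G = A'A, c = A'y for the interceptful design A, solving all same-size
    subsets in one batched call.
    """
    A = np.column_stack([np.ones(y.size), X])
    G = A.T @ A
    c = A.T @ y
    yy = float(y @ y)
    rss = np.empty(len(subsets))
    by_size: dict[int, list[int]] = {}
    for i, s in enumerate(subsets):
        by_size.setdefault(len(s), []).append(i)
    for size, idxs in by_size.items():
        # column indices into A: intercept is column 0, covariate j is j+1
        sel = np.array(
            [(0, *[j + 1 for j in subsets[i]]) for i in idxs], dtype=int
        )
        Gs = G[sel[:, :, None], sel[:, None, :]]
        cs = c[sel]
        try:
            sol = np.linalg.solve(Gs, cs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.stack([np.linalg.lstsq(g, v, rcond=None)[0]
                            for g, v in zip(Gs, cs)])
        rss[idxs] = yy - np.einsum("ij,ij->i", cs, sol)
    return np.maximum(rss, 0.0)


def all_subsets_selection(
    response, design: pd.DataFrame, candidates: Sequence[str] | None = None
) -> ModelSelectionResult:
    """Exhaustively rank every covariate subset (including intercept-only) by AICc."""
    if candidates is None:
        candidates = tuple(design.columns)
    candidates = tuple(candidates)
    y = np.asarray(response, dtype=float)
    n = y.size
    X = design[list(candidates)].to_numpy(dtype=float)

    subsets = [
        tuple(c)
        for r in range(len(candidates) + 1)
        for c in itertools.combinations(range(len(candidates)), r)
    ]
    rss = _subset_rss(y, X, subsets)

    records, skipped = [], []
    for s, r in zip(subsets, rss):
        terms = tuple(candidates[i] for i in s)
        k = len(s) + 2
        if n - k - 1 <= 0:
            skipped.append((terms, f"n-k-1 <= 0 (n={n}, k={k})"))
            continue
        if r <= 1e-300:
            skipped.append((terms, "saturated fit (zero residual SS)"))
            continue
        aic = -2.0 * gaussian_loglik(float(r), n) + 2.0 * k
        records.append((terms, len(s), aicc_from_aic(aic, k, n)))
    if not records:
        raise AnalysisError("no candidate model satisfied the AICc preconditions")

    ledger = pd.DataFrame(records, columns=["terms", "n_terms", "aicc"])
    ledger = ledger.sort_values(
        by=["aicc", "n_terms", "terms"], kind="mergesort"
    ).reset_index(drop=True)
    ledger["delta_aicc"] = ledger["aicc"] - ledger["aicc"].iloc[0]
    best = fit_ols(y, design, ledger["terms"].iloc[0])
    return ModelSelectionResult(ledger=ledger, best=best, method="all_subsets",
                                skipped=skipped)


def stepwise_backward(
    response, design: pd.DataFrame, candidates: Sequence[str] | None = None
) -> ModelSelectionResult:
    """Backward elimination by AIC from the full model to a local minimum."""
    if candidates is None:
        candidates = tuple(design.columns)
    current = tuple(sorted(candidates))
    y = np.asarray(response, dtype=float)
    fm = fit_ols(y, design, current)
    path: list[tuple[str, float]] = [("<full>", fm.aic)]
    records = [(current, len(current), fm.aicc)]
    while current:
        best_drop, best_aic, best_fm = None, fm.aic, None
        for term in current:  # lexicographic scan fixes tie-breaking
            reduced = tuple(t for t in current if t != term)
            cand = fit_ols(y, design, reduced)
            if cand.aic < best_aic - 1e-12:
                best_drop, best_aic, best_fm = term, cand.aic, cand
        if best_drop is None:
            break
        current = best_fm.terms
        fm = best_fm
        path.append((best_drop, best_aic))
        records.append((current, len(current), fm.aicc))
    ledger = pd.DataFrame(records, columns=["terms", "n_terms", "aicc"])
    ledger["delta_aicc"] = ledger["aicc"] - ledger["aicc"].min()
    return ModelSelectionResult(ledger=ledger, best=fm, method="stepwise_backward",
                                path=path)


def partial_r2(model: FittedModel, design: pd.DataFrame, response) -> pd.Series:
    """Type-II partial R² per term: SS_j / (SS_j + SS_res).

    SS_j is the increase in residual sum of squares when term j alone is
    dropped from the model.
    """
    if not model.terms:
        raise AnalysisError("partial R² needs at least one term")
    y = np.asarray(response, dtype=float)
    rss_full = model.rss
    out = {}
    for term in model.terms:
        reduced = tuple(t for t in model.terms if t != term)
        if reduced:
            rss_red = fit_ols(y, design, reduced).rss
        else:
            rss_red = float(np.sum((y - y.mean()) ** 2))
        ss_j = max(rss_red - rss_full, 0.0)
        denom = ss_j + rss_full
        out[term] = ss_j / denom if denom > 0 else 0.0
    return pd.Series(out)


def choose_functional_form(delta_aicc: float, threshold: float = -2.0) -> str:
    """Prefer the quadratic form only when it beats linear by more than 2 AICc."""
    return "quadratic" if delta_aicc < threshold else "linear"


def compare_linear_quadratic(response, covariate, name: str = "x") -> LinQuadComparison:
    """AICc comparison of y ~ x against y ~ x + x² for one covariate."""
    x = np.asarray(covariate, dtype=float)
    design = pd.DataFrame({name: x, f"{name}^2": x * x})
    lin = fit_ols(response, design, (name,))
    quad = fit_ols(response, design, (name, f"{name}^2"))
    cmp_ = LinQuadComparison(
        variable=name,
        aicc_linear=lin.aicc,
        aicc_quadratic=quad.aicc,
        choice="",
    )
    cmp_.choice = choose_functional_form(cmp_.delta_aicc)
    return cmp_


def leave_one_covariate_residual_check(
    response, design: pd.DataFrame, terms: Sequence[str]
) -> pd.DataFrame:
    """Overfitting check: residuals of each (p-1)-term fit against the omitted term.

    For every term j the model is refitted without it and its residuals are
    regressed on term j; a clear slope matching the full-model coefficient
    sign indicates the term's inclusion is supported by the data, not by an
    outlier.
    """
    terms = tuple(terms)
    if len(terms) < 2:
        raise AnalysisError("leave-one-covariate check needs >= 2 terms")
    y = np.asarray(response, dtype=float)
    rows = []
    for term in terms:
        reduced = tuple(t for t in terms if t != term)
        fm = fit_ols(y, design, reduced)
        aux = fit_ols(fm.residuals, design, (term,))
        rows.append(
            dict(term=term, slope=aux.params[term], t=aux.tvalues[term],
                 p=aux.pvalues[term])
        )
    return pd.DataFrame(rows)


def residual_diagnostics(model: FittedModel) -> ResidualDiagnostics:
    """Residual-vs-fitted and QQ material plus a Shapiro-Wilk normality test."""
    resid = model.residuals
    degenerate = bool(np.allclose(resid, 0.0))
    order = np.argsort(resid)
    probs = (np.arange(1, resid.size + 1) - 0.5) / resid.size
    theo = stats.norm.ppf(probs)
    if degenerate:
        w, p = np.nan, np.nan
    else:
        w, p = stats.shapiro(resid)
    return ResidualDiagnostics(
        fitted=model.fitted,
        residuals=resid,
        theoretical_quantiles=theo,
        sample_quantiles=resid[order],
        normality_statistic=float(w),
        normality_p=float(p),
        degenerate=degenerate,
    )


def model_report(
    model: FittedModel, design: pd.DataFrame, response,
    full_design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-term report: estimate, SE, t, p, VIF (in the full model) and partial R²."""
    pr2 = partial_r2(model, design, response)
    vif_design = full_design if full_design is not None else design[list(model.terms)]
    vifs = vif(vif_design) if len(vif_design.columns) >= 2 else pd.Series(dtype=float)
    rows = []
    for term in model.terms:
        rows.append(
            dict(term=term,
                 estimate=model.params[term],
                 se=model.se[term],
                 t=model.tvalues[term],
                 p=model.pvalues[term],
                 vif=vifs.get(term, np.nan),
                 partial_r2=pr2[term])
        )
    return pd.DataFrame(rows)
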