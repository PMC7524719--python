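"""All-subsets OLS with AICc multimodel averaging and variance decomposition.

Candidate models are every subset of the predictors, intercept-only model
included. Each is scored by AICc (small-sample corrected AIC, with k counting
intercept, slopes and the Gaussian residual variance) and given an Akaike
weight proportional to exp(-dAICc/2). Model-averaged coefficients use the
zero-fill convention: a predictor absent from a model contributes zero, which
shrinks effect sizes of predictors that only appear in poorly supported
models. Unconditional standard errors use the revised squared-term
model-averaging variance estimator. An alternative averaging mode rescales
each candidate's coefficients by the predictor's partial standard deviation
(SD discounted by VIF and degrees of freedom) before averaging, reducing the
influence of collinearity on averaged effect sizes.

Relative importance of predictors in the full model is measured by the LMG
decomposition: each predictor's share of R^2 is its incremental R^2 averaged
over all orderings of entry, computed exactly from subset R^2 values with
combinatorial weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class OlsFit:
    """A single OLS fit with the pieces needed for AICc and averaging."""

    predictors: tuple[str, ...]
    params: pd.Series          # includes "const"
    bse: pd.Series
    loglik: float              # Gaussian ML log-likelihood
    r2: float
    resid: np.ndarray
    n: int

    @property
    def k(self) -> int:
        """Parameter count: intercept + slopes + residual variance."""
        return len(self.predictors) + 2


def fit_ols(y, X: pd.DataFrame | None = None) -> OlsFit:
    """Fit y ~ X by OLS; X=None or empty means the intercept-only model."""
    y = np.asarray(y, dtype=float)
    if X is None or X.shape[1] == 0:
        design = pd.DataFrame({"const": np.ones(len(y))})
        predictors: tuple[str, ...] = ()
    else:
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
            raise ValueError("rank-deficient design matrix")
        design = sm.add_constant(X, has_constant="add")
        predictors = tuple(X.columns)
    if len(y) <= len(predictors) + 2:
        raise ValueError("need n > p + 2 observations")
    res = sm.OLS(y, design).fit()
    r2 = 0.0 if not predictors else float(res.rsquared)
    return OlsFit(predictors=predictors, params=res.params, bse=res.bse,
                  loglik=float(res.llf), r2=r2, resid=np.asarray(res.resid),
                  n=len(y))


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC corrected for small samples: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized exp(-dAICc/2); invariant to adding a constant to all values."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    w = np.exp(-(a - a.min()) / 2.0)
    return w / w.sum()


@dataclass
class CandidateSet:
    """All-subsets candidate models with AICc and Akaike weights."""

    fits: list[OlsFit]
    table: pd.DataFrame  # one row per model: predictors, loglik, k, aicc, weight


def all_subsets(y, X: pd.DataFrame) -> CandidateSet:
    """Fit all 2^p predictor subsets (null model included) and weight them."""
    fits = []
    cols = list(X.columns)
    for r in range(len(cols) + 1):
        for subset in combinations(cols, r):
            fits.append(fit_ols(y, X[list(subset)] if subset else None))
    ic = np.array([aicc(f.loglik, f.k, f.n) for f in fits])
    w = akaike_weights(ic)
    table = pd.DataFrame({
        "predictors": ["+".join(f.predictors) if f.predictors else "(intercept)"
                       for f in fits],
        "loglik": [f.loglik for f in fits],
        "k": [f.k for f in fits],
        "aicc": ic,
        "weight": w,
    })
    return CandidateSet(fits=fits, table=table)


@dataclass
class ModelAverageResult:
    """Zero-filled averaged coefficients with unconditional uncertainty."""

    coef: pd.Series
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    mode: str                 # "unit-variance" | "partial-sd"
    candidates: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se,
                             "ci_lower": self.ci_lower, "ci_upper": self.ci_upper})


def _average(coefs: pd.DataFrame, ses: pd.DataFrame, weights: np.ndarray,
             mode: str, table: pd.DataFrame) -> ModelAverageResult:
    w = weights[:, None]
    beta_bar = (w * coefs).sum(axis=0)
    # revised unconditional variance estimator, zero-filled terms included
    spread = (coefs - beta_bar) ** 2
    se = (w * np.sqrt(ses**2 + spread)).sum(axis=0)
    z = 1.959963984540054
    return ModelAverageResult(coef=beta_bar, se=se,
                              ci_lower=beta_bar - z * se, ci_upper=beta_bar + z * se,
                              mode=mode, candidates=table)


def model_average(y, X: pd.DataFrame,
                  candidates: CandidateSet | None = None) -> ModelAverageResult:
    """AICc-weighted average of zero-filled coefficients over all subsets."""
    cs = candidates if candidates is not None else all_subsets(y, X)
    cols = list(X.columns)
    coefs = pd.DataFrame(0.0, index=range(len(cs.fits)), columns=cols)
    ses = pd.DataFrame(0.0, index=range(len(cs.fits)), columns=cols)
    for m, f in enumerate(cs.fits):
        for p in f.predictors:
            coefs.loc[m, p] = f.params[p]
            ses.loc[m, p] = f.bse[p]
    return _average(coefs, ses, cs.table["weight"].to_numpy(),
                    "unit-variance", cs.table)


def partial_sd(x: pd.Series, others: pd.DataFrame, n: int, p: int) -> float:
    """Partial SD of a predictor: SD(x) * sqrt(1/VIF) * sqrt((n-1)/(n-p)).

    ``p`` is the number of slope predictors in the model the coefficient
    comes from; the VIF is computed among that model's predictors.
    """
    v = 1.0
    if others.shape[1] > 0:
        r2 = fit_ols(x.to_numpy(), others).r2
        if r2 > 1 - 1e-12:
            raise ValueError("VIF undefined: predictor collinear within model")
        v = 1.0 / (1.0 - r2)
    return float(x.std(ddof=1) * np.sqrt(1.0 / v) * np.sqrt((n - 1) / (n - p)))


def partial_sd_standardize(y, X: pd.DataFrame,
                           candidates: CandidateSet | None = None) -> ModelAverageResult:
    """Average coefficients standardized by partial SDs within each candidate.

    Each model's coefficient for predictor j is multiplied by the partial SD
    of x_j (among that model's predictors) and divided by SD(y) before the
    zero-filled weighted average; SEs are rescaled by the same factor.
    """
    cs = candidates if candidates is not None else all_subsets(y, X)
    cols = list(X.columns)
    sd_y = float(np.std(np.asarray(y, dtype=float), ddof=1))
    n = len(y)
    coefs = pd.DataFrame(0.0, index=range(len(cs.fits)), columns=cols)
    ses = pd.DataFrame(0.0, index=range(len(cs.fits)), columns=cols)
    for m, f in enumerate(cs.fits):
        p = len(f.predictors)
        for j in f.predictors:
            others = X[[c for c in f.predictors if c != j]]
            scale = partial_sd(X[j], others, n, p) / sd_y
            coefs.loc[m, j] = f.params[j] * scale
            ses.loc[m, j] = f.bse[j] * scale
    return _average(coefs, ses, cs.table["weight"].to_numpy(),
                    "partial-sd", cs.table)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors 1/(1-R^2_j) from regressing each predictor
    on all the others; raises on (near-)perfect collinearity."""
    out = {}
    for j in X.columns:
        others = X.drop(columns=[j])
        if others.shape[1] == 0:
            out[j] = 1.0
            continue
        r2 = fit_ols(X[j].to_numpy(), others).r2
        if r2 > 1 - 1e-10:
            raise ValueError(f"perfect collinearity involving predictor {j!r}")
        out[j] = 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class VarianceShares:
    """LMG allocation of the full-model R^2 across predictors."""

    shares: pd.Series
    r2_full: float


def lmg_shares(y, X: pd.DataFrame) -> VarianceShares:
    """Exact LMG decomposition via subset R^2 with combinatorial weights.

    Predictor j's share is the average over all p! orderings of its
    incremental R^2, equal to
    sum over subsets S not containing j of |S|!(p-|S|-1)!/p! * (R^2(S+j) - R^2(S)).
    Shares are order-invariant and sum to the full-model R^2.
    """
    cols = list(X.columns)
    p = len(cols)
    if p > 10:
        raise ValueError("LMG enumeration limited to p <= 10 predictors")
    r2 = {(): 0.0}
    for r in range(1, p + 1):
        for subset in combinations(cols, r):
            r2[subset] = fit_ols(y, X[list(subset)]).r2
    shares = {}
    for j in cols:
        rest = [c for c in cols if c != j]
        total = 0.0
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for subset in combinations(rest, r):
                with_j = tuple(sorted(subset + (j,), key=cols.index))
                total += w * (r2[with_j] - r2[subset])
        shares[j] = total
    return VarianceShares(shares=pd.Series(shares), r2_full=r2[tuple(cols)])
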