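"""Regression layer: imputation, OLS, BH-FDR and bootstrap CIs.

Behavioural outcomes (cognition, executive function, social cognition,
emotion recognition) are regressed on dummy-coded diagnosis, the mean
ACW-50 of the significant electrode cluster, age, sex, education and site
(optionally plus HEP modulation).  Missing neuropsychology cells are filled
by chained-equations imputation with a Bayesian-ridge estimator.  Predictor
p-values are Benjamini-Hochberg FDR-corrected within each model (intercept
excluded), and every model is accompanied by case-resampling bootstrap
coefficients, SEs and percentile 95% CIs.

Dummy coding follows the convention control=0/patient=1, male=0/female=1,
first site=0/second=1, so worse patient scores yield negative diagnosis
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import ConfigError

__all__ = [
    "RegressionFit",
    "impute_iterative",
    "fit_ols",
    "bh_fdr",
    "bootstrap_ols",
    "behavioural_regression",
    "DEFAULT_PREDICTORS",
]

DEFAULT_PREDICTORS = ["diagnosis", "acw_cluster_mean", "age", "sex",
                      "education", "site"]


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_iterative(table: pd.DataFrame, columns: list[str] | None = None,
                     max_iter: int = 10, tol: float = 1e-3,
                     seed: int = 0) -> pd.DataFrame:
    """Chained-equations imputation with a Bayesian-ridge estimator.

    Each incomplete column is iteratively regressed on all others,
    initialised at column means, until the largest change falls below
    ``tol`` or ``max_iter`` rounds.  Observed cells are untouched;
    non-numeric columns pass through unchanged.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import BayesianRidge

    out = table.copy()
    if columns is None:
        columns = [c for c in out.columns
                   if pd.api.types.is_numeric_dtype(out[c])]
    sub = out[columns]
    if sub.isna().all(axis=0).any():
        bad = [c for c in columns if sub[c].isna().all()]
        raise ConfigError(f"all-missing columns cannot be imputed: {bad}")
    frac = sub.isna().mean()
    if (frac >= 0.5).any():
        bad = frac[frac >= 0.5].index.tolist()
        raise ConfigError(f"columns with >= 50% missingness: {bad}")
    if not sub.isna().any().any():
        return out
    imputer = IterativeImputer(
        estimator=BayesianRidge(), max_iter=max_iter, tol=tol,
        initial_strategy="mean", sample_posterior=False,
        random_state=int(seed) & 0x7FFFFFFF)
    out[columns] = imputer.fit_transform(sub.to_numpy(float))
    # restore observed cells exactly (imputer may round-trip floats)
    observed = ~sub.isna()
    for c in columns:
        out.loc[observed[c], c] = sub.loc[observed[c], c]
    return out


# ---------------------------------------------------------------------------
# OLS + FDR
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """A fitted behavioural model with FDR and bootstrap columns."""

    outcome: str
    params: pd.DataFrame  # index: const + predictors; columns below
    f_stat: float
    f_p: float
    r2: float
    df_model: float
    df_resid: float
    n: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.params.copy()
        df.insert(0, "outcome", self.outcome)
        return df


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _design(predictors: pd.DataFrame) -> pd.DataFrame:
    X = predictors.copy()
    for c in X.columns:
        if not pd.api.types.is_numeric_dtype(X[c]):
            codes, uniq = pd.factorize(X[c], sort=True)
            if len(uniq) > 2:
                raise ConfigError(
                    f"categorical predictor {c!r} has > 2 levels; "
                    "dummy-code it explicitly")
            X[c] = codes.astype(float)
    return X.astype(float)


def fit_ols(y, predictors: pd.DataFrame, fdr: bool = True
            ) -> RegressionFit:
    """OLS with per-coefficient t-tests and within-model BH-FDR.

    Two-level categorical predictors are dummy-coded 0/1 (sorted levels).
    The intercept is excluded from the FDR family; its p is reported
    uncorrected.
    """
    y = np.asarray(y, float)
    X = _design(pd.DataFrame(predictors))
    n, p = X.shape
    if n <= p + 1:
        raise ConfigError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = Xc.iloc[:, 1:].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ConfigError(
            f"design is rank deficient (rank {rank} < {Xc.shape[1]}); "
            f"most collinear pair: {worst}")
    res = sm.OLS(y, Xc).fit()
    params = pd.DataFrame({
        "coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })
    if fdr:
        mask = params.index != "const"
        q = np.full(len(params), np.nan)
        q[mask] = bh_fdr(params.loc[mask, "p"].to_numpy())
        params["q"] = q
    return RegressionFit(
        outcome=getattr(y, "name", "y"), params=params,
        f_stat=float(res.fvalue), f_p=float(res.f_pvalue),
        r2=float(res.rsquared), df_model=float(res.df_model),
        df_resid=float(res.df_resid), n=n)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ols(y, predictors: pd.DataFrame, B: int = 5000, seed: int = 0
                  ) -> pd.DataFrame:
    """Case-resampling bootstrap of the OLS coefficients.

    Rows are resampled with replacement ``B`` times and the model refitted;
    singular resamples are redrawn (their count is logged in the result's
    ``attrs``).  Returns per-coefficient bootstrap mean, SD and percentile
    2.5/97.5% CI bounds, deterministic given ``seed``.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    y = np.asarray(y, float)
    X = _design(pd.DataFrame(predictors))
    Xc = sm.add_constant(X, has_constant="add")
    names = list(Xc.columns)
    A = Xc.to_numpy(float)
    n, p = A.shape
    if n <= p:
        raise ConfigError("need n > number of coefficients")

    coefs = np.empty((B, p))
    n_singular = 0
    max_singular = max(1, int(0.10 * B))
    filled = 0
    while filled < B:
        draw = min(B - filled, 1024)
        idx = rng.integers(0, n, size=(draw, n))
        Ab = A[idx]                     # (draw, n, p)
        yb = y[idx]                     # (draw, n)
        XtX = np.einsum("bni,bnj->bij", Ab, Ab)
        Xty = np.einsum("bni,bn->bi", Ab, yb)
        ev = np.linalg.eigvalsh(XtX)
        good = ev[:, 0] > 1e-10 * np.maximum(ev[:, -1], 1e-300)
        n_singular += int((~good).sum())
        if n_singular > max_singular:
            raise ConfigError(
                f"more than 10% singular bootstrap resamples ({n_singular})")
        if good.any():
            beta = np.linalg.solve(XtX[good], Xty[good][..., None])[..., 0]
            take = min(beta.shape[0], B - filled)
            coefs[filled:filled + take] = beta[:take]
            filled += take

    lo, hi = np.percentile(coefs, [2.5, 97.5], axis=0)
    out = pd.DataFrame({
        "boot_coef": coefs.mean(axis=0),
        "boot_se": coefs.std(axis=0, ddof=1),
        "ci_low": lo,
        "ci_high": hi,
    }, index=names)
    out.attrs["n_singular_redrawn"] = n_singular
    out.attrs["B"] = B
    out.attrs["seed"] = int(seed)
    return out


# ---------------------------------------------------------------------------
# high-level behavioural model
# ---------------------------------------------------------------------------

def behavioural_regression(table: pd.DataFrame, outcome: str,
                           predictors: list[str] | None = None,
                           impute: bool = True, B: int = 5000,
                           seed: int = 0) -> RegressionFit:
    """Fit one behavioural model end to end.

    Imputes missing numeric cells (optional), dummy-codes two-level
    categorical predictors, fits OLS, FDR-corrects the predictor p-values
    within the model, and appends bootstrap coefficients/SEs/95% CIs.
    """
    if predictors is None:
        predictors = [c for c in DEFAULT_PREDICTORS if c in table.columns]
    cols = [outcome] + predictors
    missing = set(cols) - set(table.columns)
    if missing:
        raise ConfigError(f"table lacks columns: {sorted(missing)}")
    df = table[cols].copy()
    # dummy-code before imputing so categorical predictors (diagnosis, sex,
    # site) inform the imputation model rather than being dropped from it
    df[predictors] = _design(df[predictors])
    if impute:
        df = impute_iterative(df, seed=seed)
    df = df.dropna(subset=[outcome])
    y = df[outcome].to_numpy(float)
    X = df[predictors]
    fit = fit_ols(y, X)
    fit.outcome = outcome
    boot = bootstrap_ols(y, X, B=B, seed=seed)
    fit.params = fit.params.join(boot)
    fit.seed = int(seed)
    fit.meta["B"] = B
    fit.meta["n_singular_redrawn"] = boot.attrs["n_singular_redrawn"]
    return fit
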