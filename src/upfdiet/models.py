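"""ANCOVA-style cohort modeling, interaction screening and index comparison.

The modeling convention follows the analysis of maternal/neonatal outcomes
against a focal dietary index (PEI-UPF by default): ordinary least squares
of the outcome on the focal term, the covariate set, a *forced*
focal-by-obesity interaction (lean and obese subjects get their own slope
and intercept), and any *candidate* interactions retained by a p < alpha
screen.  Wald confidence intervals use the t distribution with residual
degrees of freedom, appropriate at the small cohort sizes this design
targets.

Categorical covariates enter as treatment-coded dummies with reference
levels Caucasian race, low-income clinic, and lean weight status.  All
terms are uncentered by default; set ``center=True`` to center continuous
terms before products are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelFit",
    "ComparisonRecord",
    "DiagnosticsReport",
    "RankDeficientError",
    "encode_design",
    "build_design_matrix",
    "fit_ancova",
    "screen_interactions",
    "compare_indices",
    "pearson_ci",
    "diagnostics",
    "diagnostics_from_arrays",
    "MATERNAL_COVARIATES",
    "NEONATAL_COVARIATES",
    "DEFAULT_CANDIDATE_INTERACTIONS",
]


class RankDeficientError(ValueError):
    """The design matrix is not full column rank."""


#: Dummy codings applied by :func:`encode_design` (reference level first).
_DUMMY_CODING = {
    "race": ("Caucasian", "AfricanAmerican_other", "race_aa"),
    "clinic": ("low_income", "high_income", "clinic_high"),
    "weight_status": ("lean", "obese", "obese"),
}

MATERNAL_COVARIATES = ("age", "race_aa", "clinic_high", "obese",
                       "energy_kcal_per_day", "fat_g_per_day",
                       "moderate_pa_pct")
NEONATAL_COVARIATES = MATERNAL_COVARIATES + ("gestational_age_at_measure",)

#: Interactions of the focal index screened for inclusion, besides the
#: forced focal-by-obesity product.
DEFAULT_CANDIDATE_INTERACTIONS = (
    "age", "race_aa", "clinic_high", "energy_kcal_per_day", "fat_g_per_day",
    "moderate_pa_pct",
)


def encode_design(table: pd.DataFrame) -> pd.DataFrame:
    """Add 0/1 dummy columns for the two-level categorical covariates."""
    out = table.copy()
    for col, (ref, other, dummy) in _DUMMY_CODING.items():
        if col in out.columns and dummy not in out.columns:
            levels = set(out[col].dropna().unique())
            bad = levels - {ref, other}
            if bad:
                raise ValueError(f"{col}: unexpected levels {sorted(bad)}")
            out[dummy] = (out[col] == other).astype(float)
    return out


def _term_column(table: pd.DataFrame, term: str, center: bool) -> pd.Series:
    parts = term.split(":")
    col = pd.Series(1.0, index=table.index)
    for p in parts:
        if p not in table.columns:
            raise KeyError(f"unknown model term {p!r}")
        x = table[p].astype(float)
        if center and x.nunique() > 2:
            x = x - x.mean()
        col = col * x
    return col


def build_design_matrix(table: pd.DataFrame, terms: Sequence[str],
                        center: bool = False) -> pd.DataFrame:
    """Intercept + one column per term; ``a:b`` terms are products."""
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for t in terms:
        X[t] = _term_column(table, t, center)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the dependent columns via rank-revealing QR pivoting
        from scipy.linalg import qr
        _, r, piv = qr(arr, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        bad += [X.columns[p] for p in piv[len(diag):]]
        raise RankDeficientError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms include {bad}")


@dataclass
class ModelFit:
    """A fitted OLS model with the reporting quantities of interest."""

    outcome: str
    terms: list[str]
    params: pd.Series
    conf_int: pd.DataFrame  # columns ci_low, ci_high
    pvalues: pd.Series
    r_squared: float
    adj_r_squared: float
    resid: np.ndarray
    fitted: np.ndarray
    n: int
    df_resid: float
    ssr: float
    design: dict = field(default_factory=dict)
    results: object = None  # underlying statsmodels results

    def table(self) -> pd.DataFrame:
        """Term table in the β / 95% CI / p reporting layout."""
        return pd.DataFrame({
            "beta": self.params,
            "ci_low": self.conf_int["ci_low"],
            "ci_high": self.conf_int["ci_high"],
            "p": self.pvalues,
        })


def _ols(table: pd.DataFrame, outcome: str, terms: Sequence[str],
         center: bool = False, alpha_ci: float = 0.05) -> ModelFit:
    if table[list(dict.fromkeys(
            [p for t in terms for p in t.split(":")] + [outcome]))].isna() \
            .any().any():
        raise ValueError("missing values in modeling columns; impute first")
    X = build_design_matrix(table, terms, center=center)
    if len(table) <= X.shape[1]:
        raise ValueError(
            f"n={len(table)} too small for {X.shape[1]} design columns")
    _check_rank(X)
    y = table[outcome].astype(float)
    res = sm.OLS(y, X).fit()
    if res.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    ci = res.conf_int(alpha=alpha_ci)
    ci.columns = ["ci_low", "ci_high"]
    return ModelFit(
        outcome=outcome, terms=list(terms), params=res.params,
        conf_int=ci, pvalues=res.pvalues, r_squared=res.rsquared,
        adj_r_squared=res.rsquared_adj, resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues), n=int(res.nobs),
        df_resid=res.df_resid, ssr=float(res.ssr), results=res,
    )


def screen_interactions(table: pd.DataFrame, outcome: str,
                        base_terms: Sequence[str], focal: str,
                        candidates: Sequence[str], alpha: float = 0.05,
                        forced_interactions: Sequence[str] = (),
                        center: bool = False) -> list[str]:
    """Retain each candidate ``focal:candidate`` interaction iff p < alpha.

    Every candidate is tested against the same base design (base terms plus
    forced interactions), so the screen is order independent.
    """
    table = encode_design(table)
    retained = []
    base = list(dict.fromkeys([focal, *base_terms, *forced_interactions]))
    for cand in candidates:
        term = f"{focal}:{cand}"
        fit = _ols(table, outcome, base + [term], center=center)
        if fit.pvalues[term] < alpha:
            retained.append(term)
    return retained


def fit_ancova(table: pd.DataFrame, outcome: str,
               covariates: Sequence[str] = MATERNAL_COVARIATES,
               focal: str = "pei_upf",
               forced_interactions: Sequence[str] = ("pei_upf:obese",),
               candidate_interactions: Sequence[str] = (),
               alpha: float = 0.05, center: bool = False) -> ModelFit:
    """Fit the ANCOVA-style model for one outcome.

    ``candidate_interactions`` are covariate names; each ``focal:cov``
    product is screened at ``alpha`` and retained only if significant.
    ``forced_interactions`` are full term strings included unconditionally.
    """
    table = encode_design(table)
    retained = screen_interactions(
        table, outcome, covariates, focal, candidate_interactions,
        alpha=alpha, forced_interactions=forced_interactions, center=center)
    terms = list(dict.fromkeys(
        [focal, *covariates, *forced_interactions, *retained]))
    fit = _ols(table, outcome, terms, center=center)
    fit.design = {
        "focal": focal,
        "forced_interactions": list(forced_interactions),
        "retained_interactions": retained,
        "alpha": alpha,
        "center": center,
    }
    return fit


@dataclass
class ComparisonRecord:
    """Adjusted-R² and extra-sum-of-squares comparison of two indices."""

    outcome: str
    index_a: str
    index_b: str
    adj_r2_a: float
    adj_r2_b: float
    f_stat: float      # for adding index_b's terms to the index_a model
    p_value: float
    df_num: int
    df_den: float
    fit_a: ModelFit = None
    fit_b: ModelFit = None


def compare_indices(table: pd.DataFrame, outcome: str, index_a: str,
                    index_b: str,
                    covariates: Sequence[str] = MATERNAL_COVARIATES,
                    interactions_a: Sequence[str] = (),
                    interactions_b: Sequence[str] = ()) -> ComparisonRecord:
    """Compare two dietary indices as predictors of one outcome.

    Fits the adjusted model per index (covariates + index + that index's
    interaction terms), reports each adjusted R², and the extra-SS F test
    for adding ``index_b``'s terms to the ``index_a`` model:

        F = [(RSS_reduced − RSS_full)/Δdf] / [RSS_full/df_full].
    """
    table = encode_design(table)
    terms_a = list(dict.fromkeys([index_a, *covariates, *interactions_a]))
    terms_b = list(dict.fromkeys([index_b, *covariates, *interactions_b]))
    fit_a = _ols(table, outcome, terms_a)
    fit_b = _ols(table, outcome, terms_b)
    added = [t for t in [index_b, *interactions_b] if t not in terms_a]
    # the union design may be collinear (e.g. index_b duplicating index_a);
    # use a rank-aware least-squares fit so that case yields ΔRSS = 0, F = 0
    Xu = build_design_matrix(table, terms_a + added).to_numpy()
    y = table[outcome].astype(float).to_numpy()
    beta, rss_arr, rank_u, _ = np.linalg.lstsq(Xu, y, rcond=None)
    rss_u = float(((y - Xu @ beta) ** 2).sum())
    rank_a = len(terms_a) + 1  # fit_a passed the full-rank check
    d_df = rank_u - rank_a
    df_den = len(y) - rank_u
    if df_den <= 0:
        raise ValueError("zero residual degrees of freedom in union model")
    if d_df <= 0:
        f, p = 0.0, 1.0
        d_df = 0
    else:
        f = max(((fit_a.ssr - rss_u) / d_df) / (rss_u / df_den), 0.0)
        p = float(stats.f.sf(f, d_df, df_den))
    return ComparisonRecord(
        outcome=outcome, index_a=index_a, index_b=index_b,
        adj_r2_a=fit_a.adj_r_squared, adj_r2_b=fit_b.adj_r_squared,
        f_stat=f, p_value=p, df_num=d_df, df_den=df_den,
        fit_a=fit_a, fit_b=fit_b)


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(len(x) - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return r, (float(lo), float(hi))


@dataclass
class DiagnosticsReport:
    """Residual diagnostics with pass/warn flags at the 0.05 level.

    Each component is (statistic, p) or ``None`` when not computable for
    the given sample.
    """

    normality: tuple[float, float] | None
    heteroscedasticity: tuple[float, float] | None
    linearity: tuple[float, float] | None
    autocorrelation: tuple[float, float] | None
    flags: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("normality", "heteroscedasticity", "linearity",
                     "autocorrelation"):
            val = getattr(self, name)
            rows.append({
                "test": name,
                "statistic": np.nan if val is None else val[0],
                "p": np.nan if val is None else val[1],
                "flag": self.flags.get(name, "not_computable"),
            })
        return pd.DataFrame(rows)


def diagnostics_from_arrays(resid, fitted,
                            alpha: float = 0.05) -> DiagnosticsReport:
    """Diagnostics on raw residual/fitted arrays.

    Normality by Shapiro–Wilk; heteroscedasticity by the Breusch–Pagan
    regression of squared residuals on fitted values; linearity by the
    quadratic-in-fitted coefficient of a residual regression; independence
    by a Ljung–Box test of the lag-1 residual autocorrelation.
    """
    from statsmodels.stats.diagnostic import acorr_ljungbox, het_breuschpagan

    resid = np.asarray(resid, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = len(resid)
    report: dict[str, tuple[float, float] | None] = {}

    if n >= 3 and np.ptp(resid) > 0:
        sw = stats.shapiro(resid)
        report["normality"] = (float(sw.statistic), float(sw.pvalue))
    else:
        report["normality"] = None

    if n >= 4 and np.ptp(resid) > 0 and np.ptp(fitted) > 0:
        exog = np.column_stack([np.ones(n), fitted])
        lm, lm_p, fval, f_p = het_breuschpagan(resid, exog)
        report["heteroscedasticity"] = (float(fval), float(f_p))
    else:
        report["heteroscedasticity"] = None

    if n >= 5 and np.ptp(resid) > 0 and np.ptp(fitted) > 0:
        X = np.column_stack([np.ones(n), fitted, fitted ** 2])
        if np.linalg.matrix_rank(X) == 3:
            res = sm.OLS(resid, X).fit()
            report["linearity"] = (float(res.tvalues[2]),
                                   float(res.pvalues[2]))
        else:
            report["linearity"] = None
    else:
        report["linearity"] = None

    if n >= 5 and np.ptp(resid) > 0:
        lb = acorr_ljungbox(resid, lags=[1])
        report["autocorrelation"] = (float(lb["lb_stat"].iloc[0]),
                                     float(lb["lb_pvalue"].iloc[0]))
    else:
        report["autocorrelation"] = None

    flags = {}
    for name, val in report.items():
        if val is None:
            flags[name] = "not_computable"
        else:
            flags[name] = "warn" if val[1] < alpha else "pass"
    return DiagnosticsReport(flags=flags, **report)


def diagnostics(fit: ModelFit, alpha: float = 0.05) -> DiagnosticsReport:
    """Residual diagnostics of a fitted model (see array variant)."""
    return diagnostics_from_arrays(fit.resid, fit.fitted, alpha=alpha)
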