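"""Evaluation metrics and inferential machinery.

Covers performance summaries (Pearson R, adjusted R², MAE, RMSE, RSS-form
AIC/BIC), the comparison of overlapping dependent correlations (Zou's
modified-asymptotic confidence interval and the Hittner-May-Silver
backtransformed-average Z test), Benjamini-Hochberg FDR, covariate-adjusted
marginal-mean contrasts between prediction cells, per-cell sex differences,
a site mixed model with the training version as random intercept, and paired
t-tests on per-feature correlation vectors.

AIC and BIC use the Gaussian residual-sum-of-squares form without additive
constants, ``AIC = n ln(RSS/n) + 2k`` and ``BIC = n ln(RSS/n) + k ln n``, with
``k`` the number of model features (204 by default) and ``n`` the evaluation
sample size; hence the exact identity ``BIC - AIC = k (ln n - 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PerformanceSummary", "CorrComparison", "ContrastResult", "PairedTestResult",
    "SiteModelResult", "compute_metrics", "zou_interval", "hittner_test",
    "fdr_adjust", "corr_comparison", "comparison_table", "marginal_contrasts",
    "sex_difference", "site_mixed_model", "paired_correlation_test",
]


@dataclass
class PerformanceSummary:
    R: float
    R2_adj: float
    R2_adj_corrected: Optional[float]
    MAE: float
    RMSE: float
    AIC: float
    BIC: float
    n: int
    k: int

    def as_dict(self) -> dict:
        return {
            "R": self.R, "R2_adj": self.R2_adj,
            "R2_adj_corrected": self.R2_adj_corrected,
            "MAE": self.MAE, "RMSE": self.RMSE,
            "AIC": self.AIC, "BIC": self.BIC, "n": self.n, "k": self.k,
        }


@dataclass
class CorrComparison:
    r_jk: float
    r_jh: float
    r_kh: float
    r_diff: float
    CI_lower: float
    CI_upper: float
    Z: float
    p: float
    n: int
    p_FDR: Optional[float] = None


@dataclass
class ContrastResult:
    label: str
    estimate: float
    SE: float
    df: float
    t: float
    p: float
    p_FDR: Optional[float] = None


@dataclass
class PairedTestResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    d: float
    n: int


@dataclass
class SiteModelResult:
    site_coefficients: dict
    wald_chi2: float
    wald_df: int
    p: float
    group_variance: float
    boundary: bool  # True when the random-intercept variance hit ~0 or the
    # model collapsed to a single group (plain OLS fallback)


def compute_metrics(
    y: np.ndarray,
    yhat: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    k: int = 204,
) -> PerformanceSummary:
    """Performance summary of one prediction vector against true ages.

    ``R2_adj`` is the adjusted R² of the linear model ``age ~ predicted``;
    ``R2_adj_corrected`` adds sex and site to that model (requires
    ``covariates`` with those columns).  MAE/RMSE come from the raw residuals
    ``y - yhat``, not from the calibration regression.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(yhat) == 0:
        raise ValueError("constant predictions: correlation undefined")
    r = float(np.corrcoef(y, yhat)[0, 1])
    r2 = r * r
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    r2_adj_corr = None
    if covariates is not None:
        frame = pd.DataFrame(
            {"age": y, "predicted": yhat,
             "sex": np.asarray(covariates["sex"]),
             "site": np.asarray(covariates["site"])}
        )
        fit = smf.ols("age ~ predicted + C(sex) + C(site)", data=frame).fit()
        r2_adj_corr = float(fit.rsquared_adj)
    resid = y - yhat
    mae = float(np.mean(np.abs(resid)))
    rss = float(np.sum(resid**2))
    rmse = float(np.sqrt(rss / n))
    aic = n * np.log(rss / n) + 2 * k
    bic = n * np.log(rss / n) + k * np.log(n)
    return PerformanceSummary(
        R=r, R2_adj=float(r2_adj), R2_adj_corrected=r2_adj_corr,
        MAE=mae, RMSE=rmse, AIC=float(aic), BIC=float(bic), n=n, k=k,
    )


# ---------------------------------------------------------------------------
# Overlapping dependent correlations (shared variable j = age)


def _check_triple(r_jk: float, r_jh: float, r_kh: float, n: int) -> None:
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r_jk, r_jh, r_kh):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    mat = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise ValueError("correlation triple is not positive semi-definite")


def _corr_of_corrs(r_jk: float, r_jh: float, r_kh: float) -> float:
    """Pearson correlation between the sampling errors of r_jk and r_jh."""
    num = (r_kh - 0.5 * r_jk * r_jh) * (1 - r_jk**2 - r_jh**2 - r_kh**2) + r_kh**3
    den = (1 - r_jk**2) * (1 - r_jh**2)
    return num / den


def zou_interval(
    r_jk: float, r_jh: float, r_kh: float, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Zou's (2007) modified-asymptotic CI for r_jk - r_jh (overlapping case).

    Fisher-z confidence limits are computed for each correlation separately
    and recombined with the correlation-of-correlations term, which depends on
    r_kh (the correlation between the two non-shared variables).
    """
    _check_triple(r_jk, r_jh, r_kh, n)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    se = 1.0 / np.sqrt(n - 3)

    def limits(r: float) -> tuple[float, float]:
        z = np.arctanh(r)
        return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))

    l1, u1 = limits(r_jk)
    l2, u2 = limits(r_jh)
    c = _corr_of_corrs(r_jk, r_jh, r_kh)
    diff = r_jk - r_jh
    lower = diff - np.sqrt((r_jk - l1) ** 2 + (u2 - r_jh) ** 2 - 2 * c * (r_jk - l1) * (u2 - r_jh))
    upper = diff + np.sqrt((u1 - r_jk) ** 2 + (r_jh - l2) ** 2 - 2 * c * (u1 - r_jk) * (r_jh - l2))
    return float(lower), float(upper)


def hittner_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Hittner, May & Silver's backtransformed-average Fisher-z statistic.

    The correlation between the two Fisher z's is evaluated at the
    backtransformed average of r_jk and r_jh; the two-sided p comes from the
    standard normal.
    """
    _check_triple(r_jk, r_jh, r_kh, n)
    z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
    rm = float(np.tanh((z1 + z2) / 2.0))
    c = (r_kh * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r_kh**2)) / (1 - rm**2) ** 2
    Z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - c)))
    p = 2.0 * sps.norm.sf(abs(Z))
    return float(Z), float(p)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def corr_comparison(
    y: np.ndarray, yhat_a: np.ndarray, yhat_b: np.ndarray, alpha: float = 0.05
) -> CorrComparison:
    """Compare corr(age, prediction_a) against corr(age, prediction_b).

    Both prediction vectors must cover the same participants in the same
    order; r_kh is the correlation between the two prediction vectors on
    that common sample.
    """
    y = np.asarray(y, float)
    a = np.asarray(yhat_a, float)
    b = np.asarray(yhat_b, float)
    if not len(y) == len(a) == len(b):
        raise ValueError("length mismatch")
    r_jk = float(np.corrcoef(y, a)[0, 1])
    r_jh = float(np.corrcoef(y, b)[0, 1])
    r_kh = float(np.corrcoef(a, b)[0, 1])
    lo, hi = zou_interval(r_jk, r_jh, r_kh, len(y), alpha=alpha)
    Z, p = hittner_test(r_jk, r_jh, r_kh, len(y))
    return CorrComparison(
        r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, r_diff=r_jk - r_jh,
        CI_lower=lo, CI_upper=hi, Z=Z, p=p, n=len(y),
    )


def comparison_table(
    y: np.ndarray,
    predictions: dict[str, np.ndarray],
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Zou/Hittner comparisons for a family of prediction pairs, FDR-adjusted
    across the family."""
    rows = []
    for a, b in pairs:
        cmp_ = corr_comparison(y, predictions[a], predictions[b], alpha=alpha)
        rows.append(
            {"modelling_pair": f"{a} & {b}", "r_diff": cmp_.r_diff,
             "CI_lower": cmp_.CI_lower, "CI_upper": cmp_.CI_upper,
             "Z": cmp_.Z, "p": cmp_.p}
        )
    table = pd.DataFrame(rows)
    table["p_FDR"] = fdr_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Marginal means, sex differences, site mixed model


def _stacked_frame(records: pd.DataFrame) -> pd.DataFrame:
    frame = records.copy()
    frame["female"] = (frame["sex"].astype(str) == "F").astype(float)
    return frame


def marginal_contrasts(records: pd.DataFrame) -> list[ContrastResult]:
    """Pairwise marginal-mean differences of predicted age between cells.

    ``records`` is a stacked table with columns (cell, participant_id,
    predicted_age, age, sex, site) in which every cell covers the same
    participants.  One OLS of predicted age on the cell indicator plus age,
    sex and site is fitted over the stack; every pairwise cell difference is
    returned with its SE, residual-df t test, and raw/FDR-adjusted p (family =
    all pairwise contrasts in the call).
    """
    cells = sorted(records["cell"].unique())
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    counts = records.groupby("cell").size()
    if (counts < 2).any():
        raise ValueError("singleton cells cannot be contrasted")
    participant_sets = records.groupby("cell")["participant_id"].apply(frozenset)
    if len(set(participant_sets)) != 1:
        raise ValueError("all cells must cover the same participants")
    frame = _stacked_frame(records)
    fit = smf.ols("predicted_age ~ C(cell) + age + female + C(site)", data=frame).fit()
    names = list(fit.params.index)

    def cell_vector(cell: str) -> np.ndarray:
        vec = np.zeros(len(names))
        name = f"C(cell)[T.{cell}]"
        if name in names:
            vec[names.index(name)] = 1.0
        return vec

    results = []
    for a, b in combinations(cells, 2):
        contrast = cell_vector(a) - cell_vector(b)
        tt = fit.t_test(contrast)
        results.append(
            ContrastResult(
                label=f"{a} & {b}", estimate=float(tt.effect[0]),
                SE=float(tt.sd[0, 0]), df=float(fit.df_resid),
                t=float(tt.tvalue[0, 0]), p=float(tt.pvalue),
            )
        )
    for res, p_adj in zip(results, fdr_adjust([r.p for r in results])):
        res.p_FDR = float(p_adj)
    return results


def sex_difference(records: pd.DataFrame) -> list[ContrastResult]:
    """Per-cell marginal sex difference in predicted age.

    For each (train source, test target) cell, fits
    ``predicted_age ~ age + sex + site`` and reports the sex coefficient with
    the convention b > 0 <=> higher predicted age in females.  FDR is applied
    across the cells in the call.
    """
    results = []
    for cell, sub in records.groupby("cell", sort=True):
        if sub["sex"].nunique() < 2:
            raise ValueError(f"cell {cell!r} contains a single sex")
        frame = _stacked_frame(sub)
        fit = smf.ols("predicted_age ~ age + female + C(site)", data=frame).fit()
        results.append(
            ContrastResult(
                label=str(cell), estimate=float(fit.params["female"]),
                SE=float(fit.bse["female"]), df=float(fit.df_resid),
                t=float(fit.tvalues["female"]), p=float(fit.pvalues["female"]),
            )
        )
    for res, p_adj in zip(results, fdr_adjust([r.p for r in results])):
        res.p_FDR = float(p_adj)
    return results


def site_mixed_model(records: pd.DataFrame) -> SiteModelResult:
    """Random-intercept model of predicted age grouped by training version.

    Fixed effects: site (categorical), age, sex.  Returns the site
    coefficients and their joint Wald test.  With a single training-version
    group, or a boundary (zero) group variance, the fit degenerates towards
    plain OLS; the result is flagged rather than rejected.
    """
    frame = _stacked_frame(records)
    if frame["site"].nunique() < 2:
        raise ValueError("need at least two sites")
    n_groups = frame["train_source"].nunique()
    formula = "predicted_age ~ age + female + C(site)"
    if n_groups < 2:
        fit = smf.ols(formula, data=frame).fit()
        params, cov = fit.params, fit.cov_params()
        boundary, group_var = True, 0.0
    else:
        model = smf.mixedlm(formula, data=frame, groups=frame["train_source"])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        params, cov = fit.fe_params, fit.cov_params().iloc[: len(fit.fe_params), : len(fit.fe_params)]
        group_var = float(np.asarray(fit.cov_re).ravel()[0])
        boundary = group_var < 1e-8 or not fit.converged
    site_names = [name for name in params.index if name.startswith("C(site)")]
    est = params[site_names].to_numpy()
    vcv = cov.loc[site_names, site_names].to_numpy()
    wald = float(est @ np.linalg.solve(vcv, est))
    df = len(site_names)
    p = float(sps.chi2.sf(wald, df))
    return SiteModelResult(
        site_coefficients={name: float(params[name]) for name in site_names},
        wald_chi2=wald, wald_df=df, p=p, group_variance=group_var, boundary=boundary,
    )


def paired_correlation_test(
    r_vector_a: Sequence[float], r_vector_b: Sequence[float]
) -> PairedTestResult:
    """Paired t-test on per-feature correlation vectors, with paired Cohen's d."""
    a = np.asarray(r_vector_a, float)
    b = np.asarray(r_vector_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be one-dimensional and equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 features")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t, p = sps.ttest_rel(a, b)
    d = float(diff.mean() / sd)
    return PairedTestResult(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t=float(t), p=float(p), d=d, n=len(a),
    )
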