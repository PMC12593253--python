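"""Group-level and individual-differences statistical analyses.

Covers the analysis battery downstream of the hierarchical sensitivity
estimates: linear mixed models for looking time and saccadic latency at
the group level, a 3-SD outlier screen on the sensitivity measure, and
the curiosity-to-IQ models (preregistered-style linear fit, penalized
spline additive fit, constrained exponential fit, tertile-stratified
fits, hierarchical variance partitioning, and per-subindex fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .gam import GamResult, fit_gam
from .hier import prepare_model_frame

OUTLIER_SD_DEFAULT = 3.0


@dataclass(frozen=True)
class LmmResult:
    """Fixed-effect table of a mixed (or plain linear) model fit."""

    table: pd.DataFrame  # term, estimate, se, tstat, df, pvalue
    n_obs: int
    n_groups: int
    aic: float | None = None
    converged: bool = True

    def coef(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in {list(self.table['term'])}")
        return row.iloc[0]


@dataclass(frozen=True)
class StratifiedResult:
    group: str  # Low / Medium / High
    n: int
    result: GamResult


def remove_outliers(
    values, k_sd: float = OUTLIER_SD_DEFAULT
) -> tuple[list[int], list[int]]:
    """Indices kept/removed by a one-pass k-SD screen.

    The mean and (sample) SD are computed once on the full input; a value
    is removed iff it lies strictly more than ``k_sd`` SDs from that mean.
    With all-equal input nothing is removed. Order-invariant.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"need >= 3 values for the outlier screen, got {v.size}")
    sd = v.std(ddof=1)
    dev = np.abs(v - v.mean())
    removed = dev > k_sd * sd
    return list(np.flatnonzero(~removed)), list(np.flatnonzero(removed))


def screen_sensitivity(
    sensitivity: pd.DataFrame, k_sd: float = OUTLIER_SD_DEFAULT
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the k-SD screen to the slope_z column of a sensitivity table."""
    kept, removed = remove_outliers(sensitivity["slope_z"].to_numpy(), k_sd=k_sd)
    return sensitivity.iloc[kept].copy(), sensitivity.iloc[removed].copy()


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the columns involved in near-exact linear dependence
        corr = np.corrcoef(mat, rowvar=False)
        pairs = [
            (X.columns[i], X.columns[j])
            for i in range(len(X.columns))
            for j in range(i + 1, len(X.columns))
            if abs(corr[i, j]) > 0.999999
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {pairs or 'unknown'}")


def _mixedlm_result(fit, terms: list[str]) -> LmmResult:
    n_obs = int(fit.nobs)
    n_groups = len(fit.model.group_labels)
    k = len(terms)
    # residual-style degrees of freedom after fixed effects and group means
    df = max(n_obs - k - n_groups + 1, 1)
    rows = []
    for t in terms:
        est = float(fit.params[t])
        se = float(fit.bse[t])
        tval = est / se
        rows.append(
            {
                "term": t,
                "estimate": est,
                "se": se,
                "tstat": tval,
                "df": df,
                "pvalue": float(2 * stats.t.sf(abs(tval), df)),
            }
        )
    return LmmResult(
        table=pd.DataFrame(rows),
        n_obs=n_obs,
        n_groups=n_groups,
        aic=None,  # REML AICs are not comparable across fixed-effect sets
        converged=bool(fit.converged),
    )


def fit_looking_lmm(records: pd.DataFrame, metrics: pd.DataFrame) -> LmmResult:
    """Looking time ~ zIG + zSurprise + zPredictability + saccadic latency
    + trial number, with a per-infant random intercept (REML)."""
    df = prepare_model_frame(records, metrics)
    if df["infant_id"].nunique() < 2:
        raise ValueError("need >= 2 infants for a mixed model")
    terms = [
        "information_gain_z",
        "surprise_z",
        "predictability_z",
        "saccadic_latency",
        "trial_index",
    ]
    _check_rank(df[terms])
    model = smf.mixedlm(
        "looking_time ~ information_gain_z + surprise_z + predictability_z"
        " + saccadic_latency + trial_index",
        data=df,
        groups=df["infant_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    return _mixedlm_result(fit, ["Intercept"] + terms)


def fit_latency_lmm(records: pd.DataFrame) -> LmmResult:
    """Saccadic latency ~ trial type (predictable vs unpredictable) + trial
    number, with a per-infant random intercept (REML).

    The reported ``unpredictable`` coefficient is the latency slow-down on
    trials where the target misses the high-probability location.
    """
    df = records.copy()
    if df["trial_predictable"].nunique() < 2:
        raise ValueError(
            "trial type has a single level: design contains only "
            "predictable (or only unpredictable) trials"
        )
    if df["infant_id"].nunique() < 2:
        raise ValueError("need >= 2 infants for a mixed model")
    df["unpredictable"] = (~df["trial_predictable"].astype(bool)).astype(float)
    model = smf.mixedlm(
        "saccadic_latency ~ unpredictable + trial_index",
        data=df,
        groups=df["infant_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    return _mixedlm_result(fit, ["Intercept", "unpredictable", "trial_index"])


def _merge(sensitivity: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    df = sensitivity.merge(outcomes, on="infant_id", how="inner")
    if df.empty:
        raise ValueError("no overlapping infant_id between sensitivity and outcomes")
    return df


def _ols_result(y: np.ndarray, X: pd.DataFrame) -> LmmResult:
    _check_rank(X)
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    rows = []
    for t in Xc.columns:
        rows.append(
            {
                "term": "intercept" if t == "const" else t,
                "estimate": float(fit.params[t]),
                "se": float(fit.bse[t]),
                "tstat": float(fit.tvalues[t]),
                "df": float(fit.df_resid),
                "pvalue": float(fit.pvalues[t]),
            }
        )
    return LmmResult(
        table=pd.DataFrame(rows),
        n_obs=int(fit.nobs),
        n_groups=int(fit.nobs),
        aic=float(fit.aic),
    )


def fit_linear_outcome(
    sensitivity: pd.DataFrame, outcomes: pd.DataFrame, outcome_col: str = "fsiq"
) -> LmmResult:
    """Ordinary least squares: IQ ~ sensitivity (slope_z) + SES."""
    df = _merge(sensitivity, outcomes)
    if len(df) < 4:
        raise ValueError(f"need >= 4 infants for the linear model, got {len(df)}")
    return _ols_result(df[outcome_col].to_numpy(float), df[["slope_z", "ses"]])


def fit_gam_outcome(
    sensitivity: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_col: str = "fsiq",
    k: int = 10,
) -> GamResult:
    """Additive model: IQ ~ s(slope_z) + SES, REML-selected smoothness."""
    df = _merge(sensitivity, outcomes)
    if len(df) < 10:
        raise ValueError(f"need >= 10 infants for the additive model, got {len(df)}")
    return fit_gam(
        df[outcome_col].to_numpy(float),
        df["slope_z"].to_numpy(float),
        covariates={"ses": df["ses"].to_numpy(float)},
        k=k,
    )


def fit_exponential_outcome(
    sensitivity: pd.DataFrame, outcomes: pd.DataFrame, outcome_col: str = "fsiq"
) -> LmmResult:
    """Constrained convex model: IQ ~ exp(slope_z) + SES (least squares).

    Standardized sensitivity keeps exp() bounded; the coefficient on
    exp(slope_z) is the reported estimate. Adjusted R^2 is attached to
    the result table attrs.
    """
    df = _merge(sensitivity, outcomes)
    if len(df) < 4:
        raise ValueError(f"need >= 4 infants, got {len(df)}")
    z = df["slope_z"].to_numpy(float)
    if np.abs(z).max() > 20:
        raise ValueError("slope_z must be standardized (|z| <= 20) to avoid overflow")
    X = pd.DataFrame({"exp_slope_z": np.exp(z), "ses": df["ses"].to_numpy(float)})
    res = _ols_result(df[outcome_col].to_numpy(float), X)
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(df[outcome_col].to_numpy(float), Xc).fit()
    res.table.attrs["adjusted_r2"] = float(fit.rsquared_adj)
    return res


def tertile_split(values) -> np.ndarray:
    """Rank-based Low/Medium/High split with sizes as equal as possible.

    Sizes differ by at most one; a remainder of two goes to the outer
    groups (e.g., 20/19/20 at n = 59) and a remainder of one to the
    middle group. Ties are broken by stable input order.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    base, rem = divmod(n, 3)
    if rem == 0:
        sizes = (base, base, base)
    elif rem == 1:
        sizes = (base, base + 1, base)
    else:
        sizes = (base + 1, base, base + 1)
    order = np.argsort(v, kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = np.cumsum((0,) + sizes)
    for lab, lo, hi in zip(("Low", "Medium", "High"), bounds[:-1], bounds[1:]):
        labels[order[lo:hi]] = lab
    return labels


def stratify_and_fit(
    sensitivity: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_col: str = "fsiq",
    k: int = 10,
) -> list[StratifiedResult]:
    """Fit the additive model separately in Low/Medium/High curiosity
    tertiles of the sensitivity distribution."""
    df = _merge(sensitivity, outcomes)
    if len(df) < 9:
        raise ValueError(f"need >= 9 infants for tertile stratification, got {len(df)}")
    labels = tertile_split(df["slope_z"].to_numpy(float))
    out = []
    for group in ("Low", "Medium", "High"):
        sub = df[labels == group]
        res = fit_gam(
            sub[outcome_col].to_numpy(float),
            sub["slope_z"].to_numpy(float),
            covariates={"ses": sub["ses"].to_numpy(float)},
            k=k,
        )
        out.append(StratifiedResult(group=group, n=len(sub), result=res))
    return out


def partial_r2(
    sensitivity: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_col: str = "fsiq",
    k: int = 10,
) -> dict[str, float]:
    """Hierarchical partitioning of adjusted R^2 over {smooth, ses}.

    Each term's unique share is its incremental adjusted R^2 averaged
    over the two orders of entry; the two shares sum to the full model's
    adjusted R^2 by construction of the 2-term partition.
    """
    df = _merge(sensitivity, outcomes)
    y = df[outcome_col].to_numpy(float)
    full = fit_gam(
        y, df["slope_z"].to_numpy(float),
        covariates={"ses": df["ses"].to_numpy(float)}, k=k,
    )
    smooth_only = fit_gam(y, df["slope_z"].to_numpy(float), k=k)
    ses_fit = sm.OLS(y, sm.add_constant(df[["ses"]].to_numpy(float))).fit()
    r2_full = full.adjusted_r2
    r2_smooth = smooth_only.adjusted_r2
    r2_ses = float(ses_fit.rsquared_adj)
    return {
        "smooth": 0.5 * ((r2_full - r2_ses) + r2_smooth),
        "ses": 0.5 * ((r2_full - r2_smooth) + r2_ses),
        "total": r2_full,
    }


SUBINDICES = ("vci", "vsi", "wmi")


def fit_subindex_models(
    sensitivity: pd.DataFrame, outcomes: pd.DataFrame, k: int = 10
) -> dict[str, GamResult]:
    """One additive model per intelligence subindex (exploratory; no
    multiplicity correction is applied, mirroring the analysis plan)."""
    return {
        idx: fit_gam_outcome(sensitivity, outcomes, outcome_col=idx, k=k)
        for idx in SUBINDICES
    }
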