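"""Biomarker statistics: ROC curves, linear models, cohort summaries.

AUC is the Mann-Whitney probability that a random positive outranks a
random negative (ties count one half) and equals the trapezoidal area
under the empirical ROC curve. Pain-interference models are ordinary
least squares; multivariable models admit exactly the predictors whose
univariate p falls below an entry threshold (0.10 by default). Cohort
summaries use t tests / one-way ANOVA for continuous variables and
Pearson chi-square without continuity correction for dichotomous ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diffexp import chi2_2x2

# per-drink gram conversions (wine 4 oz, beer 12 oz, liquor 1.5 oz)
ALCOHOL_GRAMS = {"wine": 10.8, "beer": 13.2, "liquor": 15.1}
CIGARETTES_PER_PACK = 20
ENTRY_P = 0.10


# --------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray            # 1 - specificity
    tpr: np.ndarray            # sensitivity
    auc: float


def roc_auc(values: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Empirical ROC curve and rank-based AUC.

    ``labels`` are binary (1 = positive). AUC is computed from midranks,
    so tied marker values contribute one half, and equals the trapezoidal
    area under the returned curve exactly.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and labels differ in length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")

    ranks = stats.rankdata(v)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-v, kind="stable")
    vs, ys = v[order], y[order]
    # one ROC point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(vs))[0], len(vs) - 1]
    tps = np.cumsum(ys)[distinct]
    fps = np.cumsum(1 - ys)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, vs[distinct]]
    return RocCurve(thresholds, fpr, tpr, float(auc))


def combined_roc(marker_a: Sequence[float], marker_b: Sequence[float],
                 labels: Sequence[int], maxiter: int = 100) -> RocCurve:
    """ROC of the fitted two-marker logistic score.

    A logistic model with both markers is fitted by maximum likelihood
    (iteration-capped; perfect separation produces a warning, not an
    error) and the linear predictor is scored by :func:`roc_auc`.
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    X = sm.add_constant(np.column_stack([a, b]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
        except np.linalg.LinAlgError:
            # collinear or perfectly separating markers leave the Hessian
            # singular; the first marker alone then carries the score
            return roc_auc(a, y)
    score = X @ fit.params
    return roc_auc(score, y)


# --------------------------------------------------------------------------
# Linear models

@dataclass
class LinearModelFit:
    predictors: list[str]
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    model_p: float
    r_squared: float
    n: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "p": self.pvalues.to_dict(),
            "model_p": self.model_p,
            "r_squared": self.r_squared,
            "n": self.n,
            "note": self.note,
        }


def _ols(y: pd.Series, X: pd.DataFrame, note: str = "") -> LinearModelFit:
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    model_p = float(fit.f_pvalue) if X.shape[1] else float("nan")
    return LinearModelFit(
        predictors=list(X.columns),
        coef=fit.params,
        se=fit.bse,
        pvalues=fit.pvalues,
        model_p=model_p,
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        note=note,
    )


def univariate_fits(outcome: pd.Series,
                    predictors: pd.DataFrame) -> dict[str, LinearModelFit]:
    """One OLS fit of the outcome per single predictor (complete cases).

    Constant predictors are flagged and excluded. Dichotomous predictors
    must already be coded 0/1.
    """
    fits: dict[str, LinearModelFit] = {}
    for name in predictors.columns:
        x = pd.to_numeric(predictors[name], errors="coerce")
        df = pd.DataFrame({"y": outcome, name: x}).dropna()
        if len(df) < 3:
            fits[name] = LinearModelFit([name], pd.Series(dtype=float),
                                        pd.Series(dtype=float),
                                        pd.Series(dtype=float),
                                        float("nan"), float("nan"),
                                        len(df), note="insufficient_n")
            continue
        if df[name].nunique() < 2:
            fits[name] = LinearModelFit([name], pd.Series(dtype=float),
                                        pd.Series(dtype=float),
                                        pd.Series(dtype=float),
                                        float("nan"), float("nan"),
                                        len(df), note="constant_predictor")
            continue
        fits[name] = _ols(df["y"], df[[name]])
    return fits


def multivariable_fit(outcome: pd.Series, predictors: pd.DataFrame,
                      entry_p: float = ENTRY_P,
                      univariate: Mapping[str, LinearModelFit] | None = None,
                      ) -> LinearModelFit:
    """Joint OLS on the predictors passing the univariate entry gate.

    Includes exactly the predictors whose univariate p is below
    ``entry_p``; with none qualifying, returns an intercept-only fit with
    a note.
    """
    if univariate is None:
        univariate = univariate_fits(outcome, predictors)
    selected = [
        name for name in predictors.columns
        if name in univariate
        and not univariate[name].note
        and float(univariate[name].pvalues.get(name, np.nan)) < entry_p
    ]
    if not selected:
        df = pd.DataFrame({"y": outcome}).dropna()
        fit = sm.OLS(df["y"], np.ones(len(df))).fit()
        return LinearModelFit([], fit.params.rename({"const": "const"}),
                              fit.bse, fit.pvalues, float("nan"),
                              0.0, len(df), note="no_predictor_qualified")
    df = pd.concat([outcome.rename("y"), predictors[selected]],
                   axis=1).dropna()
    return _ols(df["y"], df[selected])


# --------------------------------------------------------------------------
# Covariates

def lifetime_alcohol_grams(wine_glasses: float, beers: float,
                           liquor_shots: float) -> float:
    """Grams of alcohol from lifetime drink counts."""
    for q in (wine_glasses, beers, liquor_shots):
        if q < 0:
            raise ValueError("drink counts must be non-negative")
    return (wine_glasses * ALCOHOL_GRAMS["wine"]
            + beers * ALCOHOL_GRAMS["beer"]
            + liquor_shots * ALCOHOL_GRAMS["liquor"])


def pack_years(packs_per_day: float, years: float) -> float:
    if packs_per_day < 0 or years < 0:
        raise ValueError("smoking quantities must be non-negative")
    return packs_per_day * years


def is_smoker(lifetime_packs: float = 0.0, cigarettes_per_day: float = 0.0,
              years_smoked: float = 0.0) -> bool:
    """Smoker definition: >= 20 lifetime packs, or >= 1 cigarette/day for
    at least 1 year."""
    if min(lifetime_packs, cigarettes_per_day, years_smoked) < 0:
        raise ValueError("smoking quantities must be non-negative")
    return (lifetime_packs >= 20
            or (cigarettes_per_day >= 1 and years_smoked >= 1))


def derive_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive alcohol grams, pack-years and smoker status from raw fields.

    Expects columns ``wine_glasses``, ``beers``, ``liquor_shots``,
    ``packs_per_day``, ``years_smoked`` (missing columns default to 0).
    """
    def col(name):
        return pd.to_numeric(raw.get(name, pd.Series(0.0, index=raw.index)),
                             errors="coerce").fillna(0.0)

    wine, beer, liquor = col("wine_glasses"), col("beers"), col("liquor_shots")
    ppd, yrs = col("packs_per_day"), col("years_smoked")
    for s in (wine, beer, liquor, ppd, yrs):
        if (s < 0).any():
            raise ValueError("negative questionnaire quantities")
    out = pd.DataFrame(index=raw.index)
    out["alcohol_grams"] = (wine * ALCOHOL_GRAMS["wine"]
                            + beer * ALCOHOL_GRAMS["beer"]
                            + liquor * ALCOHOL_GRAMS["liquor"])
    out["pack_years"] = ppd * yrs
    lifetime_packs = ppd * yrs * 365.25
    out["smoker"] = ((lifetime_packs >= 20)
                     | ((ppd * CIGARETTES_PER_PACK >= 1) & (yrs >= 1))
                     ).astype(int)
    return out


# --------------------------------------------------------------------------
# Cohort summaries

def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Size-weighted mean across groups (the summary-table total column)."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (ns <= 0).any():
        raise ValueError("group sizes must be positive")
    return float((means * ns).sum() / ns.sum())


def pooled_percent(counts: Sequence[int], ns: Sequence[int]) -> float:
    """Overall percentage from per-group counts and group sizes."""
    counts = np.asarray(counts, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (counts > ns).any() or (counts < 0).any():
        raise ValueError("counts must lie in [0, n] per group")
    return float(100.0 * counts.sum() / ns.sum())


@dataclass
class SummaryRow:
    variable: str
    kind: str                       # "continuous" or "dichotomous"
    per_group: dict[str, str]
    total: str
    p: float
    test: str


def cohort_summary(table: pd.DataFrame, group_col: str,
                   continuous: Sequence[str] = (),
                   dichotomous: Sequence[str] = ()) -> pd.DataFrame:
    """Per-group characteristic summary with comparison tests.

    Continuous variables report mean ± SD and a two-sample t test (two
    groups) or one-way ANOVA; dichotomous variables report n (%) and a
    Pearson chi-square without continuity correction.
    """
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    parts = {g: table[table[group_col] == g] for g in groups}
    for g, part in parts.items():
        if part.empty:
            raise ValueError(f"group {g!r} is empty")

    rows: list[dict] = []
    for var in continuous:
        arrays = [pd.to_numeric(parts[g][var], errors="coerce").dropna()
                  for g in groups]
        if len(groups) == 2:
            if all(a.var(ddof=1) == 0 for a in arrays) and \
                    arrays[0].mean() == arrays[1].mean():
                p, test = 1.0, "t"
            else:
                _, p = stats.ttest_ind(arrays[0], arrays[1])
                test = "t"
        else:
            _, p = stats.f_oneway(*arrays)
            test = "anova"
        rec = {"variable": var, "kind": "continuous", "test": test,
               "p": float(p)}
        for g, a in zip(groups, arrays):
            rec[str(g)] = f"{a.mean():.2f} ± {a.std(ddof=1):.2f}"
        rec["total"] = f"{pooled_mean([a.mean() for a in arrays], [len(a) for a in arrays]):.2f}"
        rows.append(rec)
    for var in dichotomous:
        counts = [int(pd.to_numeric(parts[g][var]).sum()) for g in groups]
        ns = [len(parts[g]) for g in groups]
        ctab = np.array([[c, n - c] for c, n in zip(counts, ns)], dtype=float)
        if all(c == 0 for c in counts) or all(c == n
                                              for c, n in zip(counts, ns)):
            p = 1.0
        else:
            _, p = chi2_2x2(ctab) if len(groups) == 2 else (
                stats.chi2_contingency(ctab, correction=False)[:2])
        rec = {"variable": var, "kind": "dichotomous", "test": "chi2",
               "p": float(p)}
        for g, c, n in zip(groups, counts, ns):
            rec[str(g)] = f"{c} ({100.0 * c / n:.1f})"
        rec["total"] = f"{pooled_percent(counts, ns):.1f}"
        rows.append(rec)
    return pd.DataFrame(rows)
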