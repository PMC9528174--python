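"""Health-risk indices and the BA association batteries.

Indices
-------
* ABSI (A Body Shape Index): ``WC / (BMI**(2/3) * Height**(1/2))`` with waist
  and height in metres and BMI in kg/m² — waist circumference adjusted for
  the body size explained by height and weight.
* WHtR: waist-to-height ratio.

Batteries (each under a crude Model 1 and an adjusted Model 2)
--------------------------------------------------------------
1. risk indicators — linear model of BA on the continuous index, plus a
   quintile version reporting per-quintile BA increments against Q1
   (Model 2 adjusts for CA, BMI and family disease status);
2. disease counts — (a) linear model of BA on the three-level count category
   (0 / 1 / 2+) giving BA increments, and (b) Poisson regression of the raw
   count on BA (Model 2 adjusts for CA and family disease status);
3. specific diseases — one logistic regression per disease flag on BA,
   reporting the odds ratio per year of BA with its Wald 95% CI (same
   Model 2 covariates as the count battery).

All estimation is maximum likelihood via statsmodels; P-values two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import DISEASES, assert_no_oracle

__all__ = [
    "absi", "whtr", "add_risk_indices", "quintile_groups", "disease_count",
    "disease_count_category", "AssociationResult", "risk_indicator_battery",
    "disease_count_battery", "per_disease_battery", "results_frame",
]


def absi(waist, bmi, height):
    """A Body Shape Index: WC / (BMI^(2/3) · Height^(1/2)); coherent units
    (waist and height in the same length unit, BMI = weight/height²)."""
    waist = np.asarray(waist, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(waist <= 0) or np.any(bmi <= 0) or np.any(height <= 0):
        raise ValueError("ABSI inputs must be positive")
    return waist / (bmi ** (2.0 / 3.0) * height ** 0.5)


def whtr(waist, height):
    """Waist-to-height ratio (dimensionless; any common length unit)."""
    waist = np.asarray(waist, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0) or np.any(waist <= 0):
        raise ValueError("WHtR inputs must be positive")
    return waist / height


def add_risk_indices(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["absi"] = absi(cohort["waist"], cohort["bmi"], cohort["height"])
    out["whtr"] = whtr(cohort["waist"], cohort["height"])
    return out


def quintile_groups(values: pd.Series, n_groups: int = 5) -> np.ndarray:
    """Empirical quantile groups 0..n_groups-1 (Q1..Qn); ties broken by
    stable input order so group sizes differ by at most one."""
    ranks = values.rank(method="first")
    return pd.qcut(ranks, n_groups, labels=False).to_numpy()


def disease_count(cohort: pd.DataFrame) -> np.ndarray:
    cols = [d for d in DISEASES if d in cohort.columns]
    return cohort[cols].to_numpy().sum(axis=1)


def disease_count_category(counts: np.ndarray) -> np.ndarray:
    """Three-level category: 0 diseases, 1 disease, 2 or more."""
    counts = np.asarray(counts)
    return np.minimum(counts, 2)


@dataclass(frozen=True)
class AssociationResult:
    ba_tag: str
    outcome: str
    model_kind: str      # linear | poisson | logistic
    adjustment: str      # model1 | model2
    term: str
    coefficient: float
    se: float
    statistic: float     # t (linear) or z (poisson/logistic)
    p_value: float
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    diagnostic: str | None = None


def _check_adjustment(adjustment: str) -> None:
    if adjustment not in ("model1", "model2"):
        raise ValueError("adjustment must be 'model1' or 'model2'")


def _design(cohort: pd.DataFrame, main: pd.DataFrame, adjustment: str,
            covariates: list[str]) -> pd.DataFrame:
    X = main.copy()
    if adjustment == "model2":
        for c in covariates:
            X[c] = cohort[c].to_numpy()
    return sm.add_constant(X, has_constant="add")


def _results_from_fit(fit, terms, ba_tag, outcome, model_kind, adjustment,
                      logistic=False, diagnostic=None) -> list[AssociationResult]:
    out = []
    ci = fit.conf_int()
    for term in terms:
        coef = float(fit.params[term])
        res = AssociationResult(
            ba_tag=ba_tag, outcome=outcome, model_kind=model_kind,
            adjustment=adjustment, term=term,
            coefficient=coef, se=float(fit.bse[term]),
            statistic=float(fit.tvalues[term]), p_value=float(fit.pvalues[term]),
            odds_ratio=float(np.exp(coef)) if logistic else None,
            or_ci_low=float(np.exp(ci.loc[term, 0])) if logistic else None,
            or_ci_high=float(np.exp(ci.loc[term, 1])) if logistic else None,
            diagnostic=diagnostic)
        out.append(res)
    return out


def risk_indicator_battery(
    ba: np.ndarray,
    cohort: pd.DataFrame,
    indicator: str = "absi",
    adjustment: str = "model1",
    ba_tag: str = "STK",
    n_groups: int = 5,
) -> list[AssociationResult]:
    """Linear model of BA on a health-risk indicator, continuous and by
    quantile group (increments vs Q1).  Model 2 adjusts for CA, BMI and
    family disease status."""
    _check_adjustment(adjustment)
    assert_no_oracle(cohort, "association analysis")
    if indicator not in cohort.columns:
        cohort = add_risk_indices(cohort)
    y = np.asarray(ba, dtype=float)
    covars = ["chronological_age", "bmi", "family_disease"]

    X = _design(cohort, pd.DataFrame({indicator: cohort[indicator].to_numpy()}),
                adjustment, covars)
    fit = sm.OLS(y, X).fit()
    results = _results_from_fit(fit, [indicator], ba_tag, indicator, "linear",
                                adjustment)

    groups = quintile_groups(cohort[indicator], n_groups)
    sizes = np.bincount(groups, minlength=n_groups)
    if sizes.min() < 2:
        raise ValueError("a quantile group has fewer than 2 rows")
    dummies = pd.DataFrame({f"Q{g + 1}": (groups == g).astype(float)
                            for g in range(1, n_groups)})
    Xq = _design(cohort, dummies, adjustment, covars)
    fitq = sm.OLS(y, Xq).fit()
    results += _results_from_fit(fitq, list(dummies.columns), ba_tag,
                                 f"{indicator}_quintile", "linear", adjustment)
    return results


def disease_count_battery(
    ba: np.ndarray,
    cohort: pd.DataFrame,
    adjustment: str = "model1",
    ba_tag: str = "STK",
) -> list[AssociationResult]:
    """(a) BA increments per disease-count category (linear, BA dependent);
    (b) Poisson regression of the raw count on BA.  Model 2 adjusts for CA
    and family disease status."""
    _check_adjustment(adjustment)
    assert_no_oracle(cohort, "association analysis")
    y = np.asarray(ba, dtype=float)
    counts = disease_count(cohort)
    cat = disease_count_category(counts)
    if len(np.unique(cat)) < 3:
        raise ValueError("a disease-count category is empty")
    covars = ["chronological_age", "family_disease"]

    dummies = pd.DataFrame({"count_1": (cat == 1).astype(float),
                            "count_2plus": (cat == 2).astype(float)})
    X = _design(cohort, dummies, adjustment, covars)
    fit = sm.OLS(y, X).fit()
    results = _results_from_fit(fit, list(dummies.columns), ba_tag,
                                "disease_count_category", "linear", adjustment)

    Xp = _design(cohort, pd.DataFrame({"ba": y}), adjustment, covars)
    pois = sm.GLM(counts, Xp, family=sm.families.Poisson()).fit()
    results += _results_from_fit(pois, ["ba"], ba_tag, "disease_count",
                                 "poisson", adjustment)
    return results


def per_disease_battery(
    ba: np.ndarray,
    cohort: pd.DataFrame,
    adjustment: str = "model1",
    ba_tag: str = "STK",
    diseases: list[str] | None = None,
) -> list[AssociationResult]:
    """One logistic regression per disease flag on BA: OR per 1-year BA with
    Wald 95% CI.  Perfect separation is reported as a diagnostic on the
    result rather than raised."""
    _check_adjustment(adjustment)
    assert_no_oracle(cohort, "association analysis")
    y = np.asarray(ba, dtype=float)
    covars = ["chronological_age", "family_disease"]
    results = []
    for d in (diseases or [c for c in DISEASES if c in cohort.columns]):
        flag = cohort[d].to_numpy()
        if flag.min() == flag.max():
            raise ValueError(f"{d}: only one class present")
        X = _design(cohort, pd.DataFrame({"ba": y}), adjustment, covars)
        diagnostic = None
        try:
            fit = sm.Logit(flag, X).fit(disp=0)
            if not fit.mle_retvals.get("converged", True):
                diagnostic = "non-convergence"
        except Exception as exc:  # perfect separation and friends
            results.append(AssociationResult(
                ba_tag=ba_tag, outcome=d, model_kind="logistic",
                adjustment=adjustment, term="ba", coefficient=float("nan"),
                se=float("nan"), statistic=float("nan"), p_value=float("nan"),
                diagnostic=f"separation/{type(exc).__name__}"))
            continue
        results += _results_from_fit(fit, ["ba"], ba_tag, d, "logistic",
                                     adjustment, logistic=True,
                                     diagnostic=diagnostic)
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
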