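"""Two-step feature screen ahead of BA model fitting.

Step 1 shrinks standardized candidate features against chronological age with
a cross-validated lasso; exactly-zero coefficients are dropped.  Step 2 tests
each survivor's Pearson correlation with chronological age (two-tailed;
binary features reduce to the point-biserial form, which is the same
statistic) and drops features with P above the significance threshold.  A
feature is kept iff its lasso coefficient is nonzero *and* its correlation is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LassoCV

from .cohort import CANDIDATE_FEATURES, assert_no_oracle

__all__ = ["SelectionConfig", "SelectionReport", "lasso_screen",
           "correlation_screen", "select_features", "selection_accounting"]


def selection_accounting(n_candidates: int, n_dropped: int) -> int:
    """Feature-screen bookkeeping: candidates entering the two-step screen
    minus those the screen excluded."""
    if n_candidates < 0 or n_dropped < 0:
        raise ValueError("counts must be nonnegative")
    if n_dropped > n_candidates:
        raise ValueError("cannot drop more features than there are candidates")
    return n_candidates - n_dropped


@dataclass(frozen=True)
class SelectionConfig:
    lambda_grid: tuple[float, ...] | None = None   # None: data-driven path
    cv_folds: int = 10
    alpha_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_grid is not None:
            if len(self.lambda_grid) == 0 or min(self.lambda_grid) <= 0:
                raise ValueError("lambda_grid must be nonempty and positive")
        if not 0.0 < self.alpha_threshold < 1.0:
            raise ValueError("alpha_threshold must lie in (0, 1)")


@dataclass
class SelectionReport:
    """Per-feature screen outcome; ``kept = lasso-nonzero AND P <= alpha``."""

    table: pd.DataFrame
    chosen_lambda: float | None = None
    degenerate: list[str] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.table)

    @property
    def kept_features(self) -> list[str]:
        if "kept" not in self.table.columns:
            raise ValueError("correlation screen has not run yet")
        return list(self.table.loc[self.table["kept"], "feature"])

    @property
    def n_kept(self) -> int:
        return len(self.kept_features)

    @property
    def n_dropped(self) -> int:
        return self.n_candidates - self.n_kept


def lasso_screen(
    table: pd.DataFrame,
    features: list[str] | None = None,
    response: str = "chronological_age",
    config: SelectionConfig | None = None,
) -> SelectionReport:
    """Cross-validated lasso of standardized features against the response.

    The penalty is chosen by the minimum-CV-error rule; features whose
    coefficient shrinks exactly to zero are marked dropped.  Constant columns
    cannot be standardized and are flagged as degenerate (reported, kept out
    of the fit, marked not-kept)."""
    assert_no_oracle(table, "feature selection")
    config = config or SelectionConfig()
    feats = list(features) if features is not None else \
        [c for c in CANDIDATE_FEATURES if c in table.columns]
    X = table[feats].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)

    sd = X.std(axis=0)
    degenerate = [f for f, s in zip(feats, sd) if s == 0.0]
    active = [f for f in feats if f not in degenerate]
    Xz = (table[active].to_numpy(dtype=float) - table[active].to_numpy(dtype=float).mean(axis=0))
    Xz /= Xz.std(axis=0)

    kwargs = {"alphas": list(config.lambda_grid)} if config.lambda_grid else {}
    lasso = LassoCV(
        cv=config.cv_folds,
        random_state=config.seed,
        max_iter=50_000,
        **kwargs,
    ).fit(Xz, y)
    coefs = dict(zip(active, lasso.coef_))

    rows = [{
        "feature": f,
        "lasso_coefficient": coefs.get(f, 0.0),
        "degenerate": f in degenerate,
        "kept_lasso": (f in coefs) and (coefs[f] != 0.0),
    } for f in feats]
    return SelectionReport(table=pd.DataFrame(rows), chosen_lambda=float(lasso.alpha_),
                           degenerate=degenerate)


def correlation_screen(
    table: pd.DataFrame,
    report: SelectionReport,
    response: str = "chronological_age",
    alpha: float = 0.05,
) -> SelectionReport:
    """Two-tailed Pearson test of each lasso survivor against the response."""
    y = table[response].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows for a correlation test")
    rs, ps = [], []
    for _, row in report.table.iterrows():
        f = row["feature"]
        if row["degenerate"]:
            rs.append(np.nan)
            ps.append(np.nan)
            continue
        r, p = sps.pearsonr(table[f].to_numpy(dtype=float), y)
        rs.append(r)
        ps.append(p)
    out = report.table.copy()
    out["pearson_r"] = rs
    out["p_value"] = ps
    out["kept"] = out["kept_lasso"] & (out["p_value"] <= alpha)
    return SelectionReport(table=out, chosen_lambda=report.chosen_lambda,
                           degenerate=report.degenerate)


def select_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    response: str = "chronological_age",
    config: SelectionConfig | None = None,
) -> SelectionReport:
    """Run both screens and return the final report."""
    config = config or SelectionConfig()
    report = lasso_screen(table, features, response, config)
    return correlation_screen(table, report, response, config.alpha_threshold)
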