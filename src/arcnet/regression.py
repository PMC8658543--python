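"""Stepwise linear regression for the Arc-positive percentage.

Forward/backward selection by partial-F p-values over a candidate list of
per-culture predictors (firing rates initial/final/change, network CI
initial/final/change, refinement status), with the Arc-positive fraction
as the response.  Entry and removal criteria default to p_enter = 0.05
and p_remove = 0.10.  Underlying OLS fits come from statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidParameterError

CANDIDATE_TERMS = (
    "rate_initial",
    "rate_final",
    "rate_change",
    "ci_initial",
    "ci_final",
    "ci_change",
    "refined",
)


@dataclass
class StepwiseModel:
    """Selected terms, fitted OLS results and the model ANOVA table."""

    selected: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    anova: dict[str, float]
    adj_r2: float
    results: object = field(repr=False, default=None)


def _partial_f_pvalue(rss_reduced, rss_full, df_resid_full) -> float:
    """p-value of the partial F test for one added term."""
    if rss_full <= 0:
        return 0.0
    F = (rss_reduced - rss_full) / (rss_full / df_resid_full)
    return float(stats.f.sf(max(F, 0.0), 1, df_resid_full))


def _fit(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_linear_model(
    table: pd.DataFrame,
    response: str = "arc_fraction",
    candidates: tuple[str, ...] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseModel:
    """Forward/backward stepwise OLS by partial-F p-values.

    At each forward step the candidate with the smallest partial-F
    p-value below ``p_enter`` enters; after every entry, any included term
    whose partial-F p-value exceeds ``p_remove`` leaves.  Candidates whose
    inclusion would make the design rank-deficient (perfectly collinear
    duplicates) are never co-selected.
    """
    if candidates is None:
        candidates = tuple(c for c in CANDIDATE_TERMS if c in table.columns)
    if not candidates:
        raise InvalidParameterError("no candidate terms present in the table")
    n = len(table)
    if n < len(candidates) + 3:
        raise InvalidParameterError(
            "need at least 3 more observations than candidate terms"
        )
    y = table[response].to_numpy(dtype=float)
    X_all = table.loc[:, list(candidates)].astype(float)

    selected: list[str] = []
    while True:
        changed = False
        current = _fit(y, X_all[selected]) if selected else _fit(
            y, pd.DataFrame(index=table.index)
        )
        rss_current = float(np.sum(current.resid**2))
        # forward step
        best_p, best_term, best_fit = None, None, None
        for term in candidates:
            if term in selected:
                continue
            trial_X = X_all[selected + [term]]
            design = sm.add_constant(trial_X, has_constant="add").to_numpy()
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue  # collinear with terms already in the model
            trial = _fit(y, trial_X)
            p = _partial_f_pvalue(
                rss_current, float(np.sum(trial.resid**2)), trial.df_resid
            )
            if best_p is None or p < best_p:
                best_p, best_term, best_fit = p, term, trial
        if best_p is not None and best_p < p_enter:
            selected.append(best_term)
            changed = True
        # backward step(s)
        while len(selected) > 1:
            full = _fit(y, X_all[selected])
            rss_full = float(np.sum(full.resid**2))
            worst_p, worst_term = None, None
            for term in selected:
                reduced = _fit(y, X_all[[t for t in selected if t != term]])
                p = _partial_f_pvalue(
                    float(np.sum(reduced.resid**2)), rss_full, full.df_resid
                )
                if worst_p is None or p > worst_p:
                    worst_p, worst_term = p, term
            if worst_p is not None and worst_p > p_remove:
                selected.remove(worst_term)
                changed = True
            else:
                break
        if not changed:
            break

    final = _fit(y, X_all[selected]) if selected else _fit(
        y, pd.DataFrame(index=table.index)
    )
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_error = float(np.sum(final.resid**2))
    ss_reg = ss_total - ss_error
    df_reg = len(selected)
    df_err = int(final.df_resid)
    anova = {
        "df_regression": df_reg,
        "df_error": df_err,
        "df_total": n - 1,
        "ss_regression": ss_reg,
        "ss_error": ss_error,
        "ss_total": ss_total,
        "ms_regression": ss_reg / df_reg if df_reg else np.nan,
        "ms_error": ss_error / df_err if df_err else np.nan,
        "F": (ss_reg / df_reg) / (ss_error / df_err)
        if df_reg and df_err and ss_error > 0
        else np.nan,
    }
    if np.isfinite(anova["F"]):
        anova["p"] = float(stats.f.sf(anova["F"], df_reg, df_err))
    else:
        anova["p"] = np.nan
    return StepwiseModel(
        selected=selected,
        params=final.params,
        bse=final.bse,
        tvalues=final.tvalues,
        pvalues=final.pvalues,
        anova=anova,
        adj_r2=float(final.rsquared_adj) if selected else 0.0,
        results=final,
    )
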