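"""Iterative ensemble-of-trees imputation of categorical FFQ responses.

Re-implementation of the missForest algorithm: missing cells are seeded
with the column mode (categorical) or mean (numeric), variables are visited
in order of increasing missingness, and for each a random forest is fitted
on the rows where that variable is observed and used to predict the missing
rows.  The sweep repeats until the change metric between successive
imputations first increases, at which point the *previous* iterate is
returned.  Observed cells are never modified and imputed categories always
come from the variable's observed category set (a property of tree
prediction).  The forests themselves come from scikit-learn; the iteration
and stopping logic is this module's.

Imputation operates on the option-index representation of the responses
(ordinal integers), never on derived grams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .instrument import FoodKind, ItemResponse, ResponseSet

__all__ = [
    "ImputationResult",
    "impute_responses",
    "impute_frame",
    "responses_to_frame",
    "frame_to_responses",
]


@dataclass
class ImputationResult:
    """Completed table plus bookkeeping from the iterative fit."""

    completed: pd.DataFrame
    oob_error: pd.Series  # per imputed variable; NaN when not estimable
    n_iter: int
    converged: bool


def _mode(series: pd.Series):
    # lowest value wins ties, for determinism
    counts = series.value_counts()
    top = counts[counts == counts.max()].index
    return min(top)


def impute_frame(frame: pd.DataFrame, seed: int, max_iter: int = 10,
                 n_trees: int = 100,
                 categorical: Sequence[str] | None = None,
                 ) -> ImputationResult:
    """Impute missing cells of a mixed categorical/numeric DataFrame.

    ``categorical`` names the columns to treat as classes (default: all).
    Deterministic for a fixed ``seed``: tree randomness is derived from it
    and classifier ties resolve to the lowest class index.
    """
    df = frame.copy()
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise TypeError(f"column {col!r} is not numeric; encode options "
                            "as integer indices before imputing")
    categorical = set(df.columns if categorical is None else categorical)
    unknown = categorical - set(df.columns)
    if unknown:
        raise KeyError(f"categorical columns not in frame: {sorted(unknown)}")

    mask = df.isna()
    all_missing = [c for c in df.columns if mask[c].all()]
    if all_missing:
        raise ValueError(f"columns with no observed values: {all_missing}")
    target_cols = [c for c in df.columns if mask[c].any()]
    if not target_cols:
        return ImputationResult(df, pd.Series(dtype=float), 0, True)
    # visit order: increasing missingness
    target_cols.sort(key=lambda c: (int(mask[c].sum()), c))

    current = df.copy()
    for col in df.columns:
        if mask[col].any():
            fill = _mode(df[col].dropna()) if col in categorical \
                else df[col].mean()
            current.loc[mask[col], col] = fill

    oob = pd.Series(np.nan, index=target_cols, dtype=float)
    rng_base = int(seed) % (2**31 - 1)
    prev = current.copy()
    prev_change = np.inf
    n_iter = 0
    converged = False
    import warnings as _warnings

    for it in range(1, max_iter + 1):
        new = current.copy()
        for j, col in enumerate(target_cols):
            obs = ~mask[col]
            X = new.drop(columns=[col])
            y_obs = new.loc[obs, col]
            rs = (rng_base + 1000003 * it + 7919 * j) % (2**31 - 1)
            cls = (RandomForestClassifier if col in categorical
                   else RandomForestRegressor)
            est = cls(n_estimators=n_trees, random_state=rs,
                      oob_score=len(y_obs) >= 10, n_jobs=1)
            with _warnings.catch_warnings():
                # small ensembles may leave some rows without OOB votes
                _warnings.filterwarnings(
                    "ignore", message=".*OOB scores.*",
                    category=UserWarning)
                if col in categorical:
                    est.fit(X.loc[obs], y_obs.astype(int))
                else:
                    est.fit(X.loc[obs], y_obs)
            if hasattr(est, "oob_score_"):
                err = 1.0 - est.oob_score_
                oob[col] = err if col in categorical else max(0.0, err)
            new.loc[mask[col], col] = est.predict(X.loc[mask[col]])

        # missForest change metric between successive imputed matrices
        cat_cols = [c for c in target_cols if c in categorical]
        num_cols = [c for c in target_cols if c not in categorical]
        change = 0.0
        if cat_cols:
            n_imp = sum(int(mask[c].sum()) for c in cat_cols)
            n_chg = sum(int((new.loc[mask[c], c] != current.loc[mask[c], c])
                            .sum()) for c in cat_cols)
            change += n_chg / n_imp
        if num_cols:
            num = sum(float(((new[c] - current[c]) ** 2).sum())
                      for c in num_cols)
            den = sum(float((new[c] ** 2).sum()) for c in num_cols)
            change += num / den if den > 0 else 0.0

        n_iter = it
        if change > prev_change:
            converged = True
            break  # degraded: keep the previous iterate
        prev = current
        current = new
        prev_change = change
        if change == 0.0:
            converged = True
            break

    completed = current
    # observed cells are untouched, by construction; assert cheaply anyway
    touched = (completed != df) & ~mask
    assert not touched.any().any(), "observed cells were modified"
    return ImputationResult(completed, oob, n_iter, converged)


def responses_to_frame(responses: Sequence[ResponseSet],
                       food_items) -> pd.DataFrame:
    """Wide option-index frame: one row per subject.

    Foods/beverages contribute ``<item>__freq`` and ``<item>__amount``
    columns; condiments ``<item>__amount`` and ``<item>__cond``.  Missing
    answers are NaN; structurally absent fields are simply not columns.
    """
    cols: list[str] = []
    for it in food_items:
        if it.kind is FoodKind.CONDIMENT:
            cols += [f"{it.item_id}__amount", f"{it.item_id}__cond"]
        else:
            cols += [f"{it.item_id}__freq", f"{it.item_id}__amount"]
    rows = {}
    for rs in responses:
        row = {}
        for it in food_items:
            ans = rs.answers.get(it.item_id, ItemResponse())
            if it.kind is FoodKind.CONDIMENT:
                row[f"{it.item_id}__amount"] = ans.amount_opt
                row[f"{it.item_id}__cond"] = ans.cond_frac_opt
            else:
                row[f"{it.item_id}__freq"] = ans.freq_opt
                row[f"{it.item_id}__amount"] = ans.amount_opt
        rows[rs.subject_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)[cols]


def frame_to_responses(frame: pd.DataFrame, food_items) -> list[ResponseSet]:
    """Inverse of :func:`responses_to_frame` (NaN back to missing)."""
    def as_opt(v):
        return None if pd.isna(v) else int(v)

    out = []
    for sid, row in frame.iterrows():
        answers = {}
        for it in food_items:
            if it.kind is FoodKind.CONDIMENT:
                answers[it.item_id] = ItemResponse(
                    amount_opt=as_opt(row[f"{it.item_id}__amount"]),
                    cond_frac_opt=as_opt(row[f"{it.item_id}__cond"]))
            else:
                answers[it.item_id] = ItemResponse(
                    freq_opt=as_opt(row[f"{it.item_id}__freq"]),
                    amount_opt=as_opt(row[f"{it.item_id}__amount"]))
        out.append(ResponseSet(subject_id=str(sid), answers=answers))
    return out


def impute_responses(responses: Sequence[ResponseSet], food_items,
                     seed: int, max_iter: int = 10,
                     n_trees: int = 100) -> tuple[list[ResponseSet],
                                                  ImputationResult]:
    """Impute missing FFQ answers; returns completed responses + result."""
    frame = responses_to_frame(responses, food_items)
    result = impute_frame(frame, seed=seed, max_iter=max_iter,
                          n_trees=n_trees)
    completed = result.completed.round().astype(float)
    # rounding guard: classifier output is already integral, regressor path
    # is unused for option columns (all categorical by default)
    result = ImputationResult(completed, result.oob_error, result.n_iter,
                              result.converged)
    return frame_to_responses(completed, food_items), result
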