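"""Reliability and descriptive battery: Cronbach's alpha, split-half,
age-group descriptives, and evaluator-homogeneity ANOVA.

Age groups follow the study's 14 month-bins partitioning 0-60 months
(0-2, 2-4, 4-6, 6-9, 9-12, 12-15, 15-18, 18-24, then 6-month bins to 60).
Days convert to months at 30.4375 d/month (365.25/12); intervals are
left-closed/right-open with the last bin closed at 60 months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, pearsonr

from .item_bank import ItemBank

DAYS_PER_MONTH = 30.4375

AGE_GROUP_EDGES_MONTHS = (0, 2, 4, 6, 9, 12, 15, 18, 24, 30, 36, 42, 48, 54, 60)
AGE_GROUP_LABELS = tuple(
    f"{lo}-{hi}" for lo, hi in zip(AGE_GROUP_EDGES_MONTHS[:-1], AGE_GROUP_EDGES_MONTHS[1:])
)

DEFAULT_MIN_GROUP_N = 5  # below this a group's descriptives are flagged unreliable


class ReliabilityError(ValueError):
    pass


def assign_age_group(age_days: float) -> str:
    """Map an age in days to its month-bin label (e.g. 200 d -> '6-9')."""
    if not 0 <= age_days <= 1825:
        raise ReliabilityError(f"age_days must lie in [0, 1825], got {age_days}")
    months = age_days / DAYS_PER_MONTH
    for lo, hi, label in zip(
        AGE_GROUP_EDGES_MONTHS[:-1], AGE_GROUP_EDGES_MONTHS[1:], AGE_GROUP_LABELS
    ):
        if lo <= months < hi:
            return label
    return AGE_GROUP_LABELS[-1]  # months == 60 exactly: last bin is closed


def age_groups_series(age_days: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_age_group` returning an ordered Categorical."""
    months = age_days / DAYS_PER_MONTH
    idx = np.searchsorted(AGE_GROUP_EDGES_MONTHS[1:], months, side="right")
    idx = np.minimum(idx, len(AGE_GROUP_LABELS) - 1)
    labels = pd.Categorical.from_codes(idx, categories=list(AGE_GROUP_LABELS), ordered=True)
    return pd.Series(labels, index=age_days.index, name="age_group")


def cronbach_alpha(matrix: np.ndarray | pd.DataFrame) -> float:
    """Internal-consistency alpha: (k/(k-1)) * (1 - sum(item var)/var(total)).

    Invariant to the variance-denominator convention as long as one ddof is
    used throughout (ddof=1 here).
    """
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    if k < 2 or n < 2:
        raise ReliabilityError("alpha needs at least 2 items and 2 children")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ReliabilityError("total-score variance is zero; alpha undefined")
    item_vars = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def split_half_reliability(
    matrix: np.ndarray | pd.DataFrame,
    scheme: str = "odd_even",
    seed: int | None = None,
) -> tuple[float, float]:
    """Half-score correlation and its Spearman-Brown full-length correction.

    Halves are formed from 1-based item positions: ``odd_even`` (default),
    ``first_last``, or ``random`` (requires a seed). Returns
    ``(raw_r, 2*raw_r / (1 + raw_r))``.
    """
    X = np.asarray(matrix, dtype=float)
    k = X.shape[1]
    if k < 4:
        raise ReliabilityError("need at least 2 items per half")
    pos = np.arange(k)
    if scheme == "odd_even":
        first, second = pos[::2], pos[1::2]
    elif scheme == "first_last":
        first, second = pos[: k // 2], pos[k // 2 :]
    elif scheme == "random":
        if seed is None:
            raise ReliabilityError("random split requires a seed")
        perm = np.random.default_rng(seed).permutation(k)
        first, second = np.sort(perm[: k // 2]), np.sort(perm[k // 2 :])
    else:
        raise ReliabilityError(f"unknown split scheme {scheme!r}")
    h1, h2 = X[:, first].sum(axis=1), X[:, second].sum(axis=1)
    if h1.var() == 0 or h2.var() == 0:
        raise ReliabilityError("a half has zero score variance; correlation undefined")
    raw_r = float(pearsonr(h1, h2).statistic)
    return raw_r, spearman_brown(raw_r)


def spearman_brown(r: float) -> float:
    """Full-length reliability predicted from a half-test correlation."""
    return 2.0 * r / (1.0 + r)


def reliability_report(
    scored: pd.DataFrame, bank: ItemBank, split_scheme: str = "odd_even", seed: int | None = None
) -> pd.DataFrame:
    """Per-domain alpha and split-half (raw + Spearman-Brown) coefficients."""
    rows = []
    for domain in bank.domains:
        ids = [it.item_id for it in bank.items_for(domain)]
        X = scored[ids]
        raw_r, sb = split_half_reliability(X, scheme=split_scheme, seed=seed)
        rows.append(
            {
                "domain": domain,
                "cronbach_alpha": cronbach_alpha(X),
                "split_half_raw": raw_r,
                "split_half_spearman_brown": sb,
                "n_children": len(X),
                "k_items": len(ids),
            }
        )
    return pd.DataFrame(rows)


def descriptives_by_group(
    scores: pd.DataFrame,
    age_days: pd.Series,
    min_group_n: int = DEFAULT_MIN_GROUP_N,
) -> pd.DataFrame:
    """n, mean, SD of each score column per age group (SD uses n-1).

    Groups with fewer than ``min_group_n`` children are flagged unreliable,
    not dropped. ``scores`` holds one column per domain total.
    """
    if len(scores) == 0:
        raise ReliabilityError("empty dataset")
    groups = age_groups_series(age_days)
    rows = []
    for label in AGE_GROUP_LABELS:
        sel = scores.loc[(groups == label).to_numpy()]
        row: dict = {"age_group": label, "n": len(sel), "unreliable": len(sel) < min_group_n}
        for col in scores.columns:
            row[f"{col}_mean"] = sel[col].mean() if len(sel) else np.nan
            row[f"{col}_sd"] = sel[col].std(ddof=1) if len(sel) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def evaluator_anova(
    scores: pd.DataFrame,
    age_days: pd.Series,
    evaluator_id: pd.Series,
    min_cell_n: int = 2,
) -> pd.DataFrame:
    """One-way between-evaluator ANOVA per (age group x domain) cell.

    Within each age group, each domain's total scores are compared across
    evaluators that contribute at least ``min_cell_n`` children; cells with
    fewer than two such evaluators are flagged insufficient rather than
    raising. Used as the homogeneity check that no evaluator systematically
    scores children differently.
    """
    groups = age_groups_series(age_days)
    rows = []
    for label in AGE_GROUP_LABELS:
        in_group = (groups == label).to_numpy()
        evs = evaluator_id[in_group]
        for col in scores.columns:
            vals = scores.loc[in_group, col]
            samples = [
                vals[(evs == e).to_numpy()].to_numpy()
                for e in evs.unique()
                if (evs == e).sum() >= min_cell_n
            ]
            row = {"age_group": label, "domain": col, "n_evaluators": len(samples)}
            if len(samples) >= 2 and any(s.var() > 0 for s in samples):
                f, p = f_oneway(*samples)
                row.update(F=float(f), p_value=float(p), sufficient=True)
            else:
                row.update(F=np.nan, p_value=np.nan, sufficient=False)
            rows.append(row)
    return pd.DataFrame(rows)
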