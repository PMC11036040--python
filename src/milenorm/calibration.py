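"""Per-item logistic calibration and inverse-logit age thresholds.

Each item is calibrated independently by a logistic regression of item
success (0/1) on age in days:

    P(Y=1 | x) = 1 / (1 + exp(-(alpha + beta * x)))

Maximum likelihood is obtained by Newton iteration (through statsmodels'
Logit); ages enter in raw days, uncentred, so alpha is the logit of the pass
probability at birth and beta is in logit units per day. Inverting the fitted
curve at a probability p gives the age threshold

    age_at(p) = (logit(p) - alpha) / beta,

computed here at p = .25, .50, .75, .90; the .90 threshold drives item
reordering and the four together define the norm bands. Model fit is
assessed by a likelihood-ratio test of the age model against the
intercept-only model (a Wald p-value on beta is reported alongside, since
either could stand behind a published "good fit, p < .05").

Items with no response variation (degenerate) or with complete separation
(no finite MLE) are flagged and retained rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import chi2
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .item_bank import ItemBank

PROBABILITY_LEVELS = (0.25, 0.50, 0.75, 0.90)

_MAX_ITER = 100
_GRAD_TOL = 1e-8
# Estimates beyond these magnitudes are treated as diverging (separation):
# |beta| > 5 logit/day means the pass curve jumps 0->1 within ~2 days.
_DIVERGENCE_BETA = 5.0
_DIVERGENCE_ALPHA = 500.0


class DegenerateItemError(ValueError):
    """Responses are all 0 or all 1; the logistic model is not identifiable."""


class NonInvertibleError(ValueError):
    """The fitted curve cannot be inverted (beta <= 0 or p outside (0,1))."""


@dataclass
class ItemCalibration:
    """Fitted logistic parameters and age thresholds for one item."""

    item_id: str
    domain: str = ""
    index: int = 0
    alpha_hat: float = np.nan
    beta_hat: float = np.nan
    se_alpha: float = np.nan
    se_beta: float = np.nan
    fit_p_value: float = np.nan  # likelihood-ratio test vs intercept-only
    wald_p_value: float = np.nan
    converged: bool = False
    separation_flag: bool = False
    degenerate: bool = False
    n_obs: int = 0
    age_at: dict[float, float] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        """Usable for norms: converged, not separated/degenerate, beta > 0."""
        return (
            self.converged
            and not self.separation_flag
            and not self.degenerate
            and np.isfinite(self.beta_hat)
            and self.beta_hat > 0
        )

    @property
    def good_fit(self) -> bool:
        return np.isfinite(self.fit_p_value) and self.fit_p_value < 0.05


def invert_probability(alpha_hat: float, beta_hat: float, p: float) -> float:
    """Age (days) at which the fitted curve reaches pass probability ``p``."""
    if not 0 < p < 1:
        raise NonInvertibleError(f"probability must lie in (0, 1), got {p}")
    if not np.isfinite(beta_hat) or beta_hat <= 0:
        raise NonInvertibleError(f"slope must be positive to invert, got {beta_hat}")
    return (logit(p) - alpha_hat) / beta_hat


def _log_likelihood(alpha: float, beta: float, ages: np.ndarray, y: np.ndarray) -> float:
    eta = alpha + beta * ages
    # log P(y) = y*eta - log(1+exp(eta)), numerically stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_item_logistic(
    ages_days: np.ndarray, responses: np.ndarray, item_id: str = ""
) -> ItemCalibration:
    """Maximum-likelihood logistic fit of one item's success on age in days.

    Newton iteration, gradient tolerance 1e-8, at most 100 iterations.
    Raises :class:`DegenerateItemError` when responses show no variation;
    sets ``separation_flag`` when the MLE diverges (complete separation).
    """
    ages = np.asarray(ages_days, dtype=float)
    y = np.asarray(responses, dtype=float)
    if ages.shape != y.shape:
        raise ValueError(f"length mismatch: {ages.shape} ages vs {y.shape} responses")
    if ages.size < 3:
        raise ValueError("need at least 3 observations to calibrate an item")
    if y.min() == y.max():
        raise DegenerateItemError(
            f"item {item_id or '<unnamed>'}: all responses are {int(y[0])}; nothing to fit"
        )

    cal = ItemCalibration(item_id=item_id, n_obs=int(ages.size))
    X = sm.add_constant(ages)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=PerfectSeparationWarning)
            warnings.simplefilter("ignore", category=ConvergenceWarning)  # flagged via .converged
            warnings.simplefilter("ignore", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=_MAX_ITER, tol=_GRAD_TOL, disp=0
            )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        cal.separation_flag = True
        return cal

    alpha_hat, beta_hat = res.params
    if abs(beta_hat) > _DIVERGENCE_BETA or abs(alpha_hat) > _DIVERGENCE_ALPHA:
        cal.separation_flag = True
        return cal

    cal.alpha_hat = float(alpha_hat)
    cal.beta_hat = float(beta_hat)
    cal.se_alpha, cal.se_beta = (float(s) for s in res.bse)
    cal.converged = bool(res.mle_retvals.get("converged", False))
    cal.wald_p_value = float(res.pvalues[1])
    if cal.converged:
        cal.fit_p_value = model_fit_test(cal, ages, y)
        if cal.beta_hat > 0:
            cal.age_at = {p: invert_probability(cal.alpha_hat, cal.beta_hat, p)
                          for p in PROBABILITY_LEVELS}
    return cal


def model_fit_test(cal: ItemCalibration, ages_days: np.ndarray, responses: np.ndarray) -> float:
    """Likelihood-ratio p-value of the age model against intercept-only.

    The null model's MLE intercept is logit(mean(y)); the statistic
    2*(ll_full - ll_null) is referred to chi-square with 1 df.
    """
    if not cal.converged and not np.isfinite(cal.alpha_hat):
        raise ValueError("model_fit_test requires a fitted, converged calibration")
    ages = np.asarray(ages_days, dtype=float)
    y = np.asarray(responses, dtype=float)
    ll_full = _log_likelihood(cal.alpha_hat, cal.beta_hat, ages, y)
    pbar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    ll_null = _log_likelihood(logit(pbar), 0.0, ages, y)
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    return float(chi2.sf(stat, df=1))


def calibrate_all(
    scores: pd.DataFrame,
    ages_days: pd.Series | np.ndarray,
    bank: ItemBank,
    provenance: pd.DataFrame | None = None,
    use_imputed: bool = True,
) -> list[ItemCalibration]:
    """Calibrate every bank item; per-item failures are flagged, never raised.

    ``scores`` is the children x items 0/1 matrix (imputation-completed).
    With ``use_imputed=False`` a ``provenance`` matrix is required and only
    cells marked ``observed`` enter each item's regression — the non-circular
    mode, since imputed cells presuppose the item ordering being validated.
    """
    if not use_imputed and provenance is None:
        raise ValueError("observed-only calibration requires a provenance matrix")
    ages = np.asarray(ages_days, dtype=float)
    out: list[ItemCalibration] = []
    for item in bank:
        col = scores[item.item_id].to_numpy(dtype=float)
        mask = np.ones(col.shape, dtype=bool)
        if not use_imputed:
            mask = provenance[item.item_id].to_numpy() == "observed"
        a, yv = ages[mask], col[mask]
        try:
            cal = fit_item_logistic(a, yv, item_id=item.item_id)
        except (DegenerateItemError, ValueError):
            cal = ItemCalibration(item_id=item.item_id, degenerate=True, n_obs=int(mask.sum()))
        cal.domain = item.domain
        cal.index = item.index
        out.append(cal)
    return out


def calibrations_to_frame(calibrations: list[ItemCalibration]) -> pd.DataFrame:
    """Flatten calibrations to the CSV layout (ages blank when non-invertible)."""
    rows = []
    for c in calibrations:
        rows.append(
            {
                "item_id": c.item_id,
                "domain": c.domain,
                "index": c.index,
                "alpha": c.alpha_hat,
                "beta": c.beta_hat,
                "se_alpha": c.se_alpha,
                "se_beta": c.se_beta,
                "p_value": c.fit_p_value,
                "wald_p": c.wald_p_value,
                "converged": c.converged,
                "separation": c.separation_flag,
                "degenerate": c.degenerate,
                "n_obs": c.n_obs,
                **{f"age_p{int(p * 100)}": c.age_at.get(p, np.nan) for p in PROBABILITY_LEVELS},
            }
        )
    return pd.DataFrame(rows)
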