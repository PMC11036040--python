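"""Synthetic cohorts with logistic age structure.

Generates ground-truth item parameters, child profiles, and full (oracle)
response matrices under the model the calibration stage assumes: for each
item the probability of success at age ``x`` days is

    P(Y=1 | x) = 1 / (1 + exp(-(alpha + beta * x))),   beta > 0,

so the age at 50% pass probability is ``-alpha/beta`` and steeper slopes give
narrower mastery windows. True per-item P50 ages increase strictly with the
item index within each domain, emulating a subscale arranged in ascending
difficulty. This gives every downstream stage (adaptive administration,
imputation, calibration, norming) a testbed with a known answer.

All randomness flows from a single integer seed through named substreams so
that parameters, cohort, and responses can be varied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .item_bank import ItemBank

# Defaults reflect the validation-study conditions: n=948 children aged 0-60
# months, CAIPI:CAFI = 36:64, 45.1% girls, 40 field evaluators. The age floor
# is 60 days because the service provider enrols almost no younger infants.
DEFAULT_N_CHILDREN = 948
DEFAULT_AGE_RANGE_DAYS = (60, 1825)
DEFAULT_FEMALE_SHARE = 0.451
DEFAULT_CAIPI_SHARE = 0.36
DEFAULT_N_EVALUATORS = 40
# P50 ages span 30 days to ~46 months. The upper end is set so that the top
# item's P90 age (p50 + logit(.9)/beta, ~410 d above P50 at the shallowest
# default slope) lands near the instrument's 60-month ceiling: the oldest age
# group then scores near-ceiling on every subscale, as validation cohorts for
# such screeners do, instead of failing top items the instrument is supposed
# to cover.
DEFAULT_P50_SPAN_DAYS = (30.0, 1400.0)
DEFAULT_SLOPE_RANGE = (0.005, 0.05)  # logit per day, log-uniform

_SUBSTREAMS = {"params": 0, "cohort": 1, "responses": 2}

COHORT_COLUMNS = ["child_id", "age_days", "sex", "service", "evaluator_id"]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named, independent substream of a single master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SUBSTREAMS[stream]]))


@dataclass
class TrueItemParams:
    """Ground-truth logistic parameters, aligned with the bank's item order."""

    item_ids: list[str]
    domains: list[str]
    alpha: np.ndarray  # intercept, logit units
    beta: np.ndarray  # slope, logit per day (> 0)

    @property
    def p50_days(self) -> np.ndarray:
        return -self.alpha / self.beta

    def age_at(self, p: float) -> np.ndarray:
        """Age (days) at which each item's true pass probability equals ``p``."""
        return (np.log(p / (1.0 - p)) - self.alpha) / self.beta

    def pass_probability(self, age_days: np.ndarray) -> np.ndarray:
        """n_children x n_items matrix of true pass probabilities."""
        x = np.asarray(age_days, dtype=float)[:, None]
        return expit(self.alpha[None, :] + self.beta[None, :] * x)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.beta <= 0):
            raise ValueError("all true slopes must be positive")


def generate_true_params(
    bank: ItemBank,
    p50_span_days: tuple[float, float] = DEFAULT_P50_SPAN_DAYS,
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
    seed: int = 0,
) -> TrueItemParams:
    """Draw per-item (alpha, beta) with strictly increasing P50 ages per domain.

    P50 ages are evenly spaced over ``p50_span_days``, so strict monotonicity
    in the item index holds by construction and adjacent items stay separated
    by a constant, identifiable margin — the generator is a recovery testbed,
    and even spacing keeps "how well does the pipeline recover the truth" from
    being confounded with "was the truth recoverable at all".
    Slopes are log-uniform over ``slope_range`` and assigned in
    decreasing order along the subscale: mastery windows widen with age (a
    robust feature of real milestone data), and since the age at any fixed
    probability p is ``p50 + logit(p)/beta``, decreasing slopes make every
    age-at-p threshold — including the P90 age that drives item ordering —
    strictly increasing with the item index, so the subscale is ascending in
    difficulty under any probability criterion. The intercept is
    ``alpha = -beta * p50``.
    """
    lo, hi = slope_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError(f"slope_range must be positive and ordered, got {slope_range}")
    if not (0 <= p50_span_days[0] < p50_span_days[1] <= 1825):
        raise ValueError(f"p50_span_days must lie within [0, 1825], got {p50_span_days}")
    rng = _rng(seed, "params")
    item_ids: list[str] = []
    domains: list[str] = []
    alphas: list[np.ndarray] = []
    betas: list[np.ndarray] = []
    for domain in bank.domains:
        items = bank.items_for(domain)
        k = len(items)
        p50 = np.linspace(p50_span_days[0], p50_span_days[1], k)
        beta = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=k)))[::-1]
        item_ids += [it.item_id for it in items]
        domains += [domain] * k
        alphas.append(-beta * p50)
        betas.append(beta)
    return TrueItemParams(item_ids, domains, np.concatenate(alphas), np.concatenate(betas))


def sample_cohort(
    n: int = DEFAULT_N_CHILDREN,
    age_range_days: tuple[int, int] = DEFAULT_AGE_RANGE_DAYS,
    female_share: float = DEFAULT_FEMALE_SHARE,
    caipi_share: float = DEFAULT_CAIPI_SHARE,
    n_evaluators: int = DEFAULT_N_EVALUATORS,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample child profiles: id, age in days, sex, service type, evaluator.

    Ages are uniform integers over ``age_range_days`` (inclusive); sex and
    service are Bernoulli draws with the configured shares; evaluators are
    assigned round-robin. Returns one row per child with columns
    ``child_id, age_days, sex, service, evaluator_id``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lo, hi = age_range_days
    if not (0 <= lo <= hi <= 1825):
        raise ValueError(f"age range must be a non-empty subrange of [0, 1825], got {age_range_days}")
    for name, share in (("female_share", female_share), ("caipi_share", caipi_share)):
        if not 0 <= share <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {share}")
    rng = _rng(seed, "cohort")
    ages = rng.integers(lo, hi + 1, size=n)
    sex = np.where(rng.random(n) < female_share, "female", "male")
    service = np.where(rng.random(n) < caipi_share, "CAIPI", "CAFI")
    return pd.DataFrame(
        {
            "child_id": [f"C{i:05d}" for i in range(1, n + 1)],
            "age_days": ages.astype(int),
            "sex": sex,
            "service": service,
            "evaluator_id": np.arange(n) % n_evaluators + 1,
        }
    )


def simulate_full_responses(
    params: TrueItemParams, cohort: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Draw the full (oracle) binary response matrix, children x items.

    Every cell is an independent Bernoulli draw with the logistic success
    probability at the child's age — the complete matrix the adaptive
    administration only partially observes.
    """
    rng = _rng(seed, "responses")
    probs = params.pass_probability(cohort["age_days"].to_numpy())
    draws = (rng.random(probs.shape) < probs).astype(np.int8)
    return pd.DataFrame(draws, index=cohort["child_id"].to_numpy(), columns=params.item_ids)


def write_dataset(cohort: pd.DataFrame, responses: pd.DataFrame, path) -> None:
    """Serialize cohort + responses as one CSV row per child."""
    out = cohort.set_index("child_id").join(responses.rename_axis("child_id"))
    out.reset_index().to_csv(path, index=False)


def read_dataset(path, item_ids: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_dataset`; returns (cohort, responses)."""
    df = pd.read_csv(path)
    cohort = df[COHORT_COLUMNS].copy()
    responses = df.set_index("child_id")[item_ids].astype(np.int8)
    return cohort, responses
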