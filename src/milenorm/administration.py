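"""Age-adaptive administration: start rule, basal/ceiling rules, imputation.

The screener never shows a child the whole subscale. It starts at the item
whose norm age (age at 90% pass probability by default) is the largest one at
or below the child's age, walks backward until the child passes three items
in a row (the *basal*), then walks forward from the start until the child
misses three items in a row (the *ceiling*). Items below the basal are scored
1 without being shown (the child is assumed to have mastered them); items
above the ceiling are scored 0 (the child is assumed not ready). The result
is a complete 0/1 vector per subscale with a provenance flag per cell.

The backward stopping rule is interpreted as three *consecutive* passes,
mirroring the explicitly consecutive forward rule; a cumulative variant
(any three passes during the backward walk) is available via
``backward_rule="cumulative"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .item_bank import ItemBank

OBSERVED = "observed"
IMPUTED_PASS = "imputed_pass"
IMPUTED_FAIL = "imputed_fail"

_RUN_LENGTH = 3  # passes to establish a basal / misses to establish a ceiling


class AdministrationError(ValueError):
    """Invalid administration input or inconsistent record."""


@dataclass
class AdministrationRecord:
    """Trace of one adaptive subscale administration.

    ``presented`` lists (1-based index, observed 0/1) in presentation order:
    the backward walk from ``start_index`` down, then the forward walk from
    ``start_index + 1`` up. The presented indices always form a contiguous
    block containing the start item.
    """

    domain: str
    start_index: int
    presented: list[tuple[int, int]]
    basal_reached: bool
    ceiling_reached: bool

    @property
    def lowest_observed(self) -> int:
        return min(i for i, _ in self.presented)

    @property
    def highest_observed(self) -> int:
        return max(i for i, _ in self.presented)

    def observed_map(self) -> dict[int, int]:
        return dict(self.presented)

    def validate(self) -> None:
        indices = sorted(i for i, _ in self.presented)
        if indices != list(range(indices[0], indices[-1] + 1)):
            raise AdministrationError(f"presented indices not contiguous: {indices}")
        if not (self.lowest_observed <= self.start_index <= self.highest_observed):
            raise AdministrationError("start index outside the presented block")


@dataclass
class ScoredVector:
    """Imputation-completed 0/1 vector for one subscale, with provenance."""

    domain: str
    values: np.ndarray  # shape (k,), int 0/1
    provenance: np.ndarray  # shape (k,), one of observed|imputed_pass|imputed_fail

    @property
    def score(self) -> int:
        return int(self.values.sum())


def select_start_item(age_p90_days: np.ndarray, age_days: float) -> int:
    """Largest 1-based index whose norm (P90) age is <= the child's age; 1 if none.

    ``age_p90_days`` is the subscale's per-item norm age vector in original
    item order; non-finite entries (items without a valid norm) never qualify.
    """
    ages = np.asarray(age_p90_days, dtype=float)
    if ages.size == 0:
        raise AdministrationError("empty norm table for start-item selection")
    qualifies = np.flatnonzero(np.isfinite(ages) & (ages <= age_days))
    return int(qualifies[-1]) + 1 if qualifies.size else 1


def administer_subscale(
    oracle: np.ndarray,
    start_index: int,
    domain: str = "",
    backward_rule: str = "consecutive",
) -> AdministrationRecord:
    """Run the backward-then-forward adaptive walk against an oracle vector.

    ``oracle`` holds the child's would-be response (0/1) to every item. The
    backward phase presents ``start_index, start_index - 1, ...`` until the
    basal run is observed or item 1 has been presented; the forward phase
    resumes at ``start_index + 1`` and continues until three consecutive
    misses or the last item. The start item's own outcome counts toward the
    backward run.
    """
    oracle = np.asarray(oracle)
    k = oracle.shape[0]
    if not 1 <= start_index <= k:
        raise AdministrationError(f"start_index {start_index} out of range 1..{k}")
    if backward_rule not in ("consecutive", "cumulative"):
        raise AdministrationError(f"unknown backward rule {backward_rule!r}")

    presented: list[tuple[int, int]] = []
    basal = False
    run = 0  # consecutive passes (or cumulative pass count) in the backward walk
    i = start_index
    while True:
        r = int(oracle[i - 1])
        presented.append((i, r))
        if backward_rule == "consecutive":
            run = run + 1 if r == 1 else 0
        else:
            run += r
        if run >= _RUN_LENGTH:
            basal = True
            break
        if i == 1:
            break
        i -= 1

    ceiling = False
    miss_run = 0
    j = start_index + 1
    while j <= k:
        r = int(oracle[j - 1])
        presented.append((j, r))
        miss_run = miss_run + 1 if r == 0 else 0
        if miss_run >= _RUN_LENGTH:
            ceiling = True
            break
        j += 1

    record = AdministrationRecord(domain, start_index, presented, basal, ceiling)
    record.validate()
    return record


def impute_and_score(record: AdministrationRecord, k: int) -> tuple[ScoredVector, int]:
    """Complete a subscale vector from an administration trace.

    Indices below the lowest presented item are imputed as passes only when a
    basal was established; indices above the highest presented item are
    imputed as fails only when a ceiling was established. (When the walk hits
    the subscale floor without a basal, or the top without a ceiling, there is
    nothing unobserved on that side, so the guard is exact, not a choice.)
    """
    record.validate()
    if record.highest_observed > k:
        raise AdministrationError("record references items beyond the subscale")
    values = np.zeros(k, dtype=np.int8)
    provenance = np.empty(k, dtype=object)
    provenance[:] = OBSERVED
    for idx, r in record.observed_map().items():
        values[idx - 1] = r
    lo, hi = record.lowest_observed, record.highest_observed
    if lo > 1:
        if not record.basal_reached:
            raise AdministrationError("unobserved low items without an established basal")
        values[: lo - 1] = 1
        provenance[: lo - 1] = IMPUTED_PASS
    if hi < k:
        if not record.ceiling_reached:
            raise AdministrationError("unobserved high items without an established ceiling")
        values[hi:] = 0
        provenance[hi:] = IMPUTED_FAIL
    vec = ScoredVector(record.domain, values, provenance)
    return vec, vec.score


def administer_cohort(
    responses: pd.DataFrame,
    cohort: pd.DataFrame,
    age_p90_by_domain: dict[str, np.ndarray],
    bank: ItemBank,
    backward_rule: str = "consecutive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Administer every subscale to every child; deterministic batch driver.

    ``responses`` is the full oracle matrix (children x 133 items, columns in
    bank order); ``age_p90_by_domain`` supplies the start-rule norm ages per
    domain in original item order. Returns ``(scored, provenance)`` DataFrames
    with the same shape and labels as ``responses``.
    """
    ages = cohort.set_index("child_id")["age_days"].reindex(responses.index).to_numpy()
    scored_blocks: list[pd.DataFrame] = []
    prov_blocks: list[pd.DataFrame] = []
    for domain in bank.domains:
        ids = [it.item_id for it in bank.items_for(domain)]
        k = len(ids)
        oracle_block = responses[ids].to_numpy()
        norm_ages = np.asarray(age_p90_by_domain[domain], dtype=float)
        vals = np.empty((len(responses), k), dtype=np.int8)
        provs = np.empty((len(responses), k), dtype=object)
        for row in range(len(responses)):
            start = select_start_item(norm_ages, float(ages[row]))
            record = administer_subscale(
                oracle_block[row], start, domain=domain, backward_rule=backward_rule
            )
            vec, _ = impute_and_score(record, k)
            vals[row] = vec.values
            provs[row] = vec.provenance
        scored_blocks.append(pd.DataFrame(vals, index=responses.index, columns=ids))
        prov_blocks.append(pd.DataFrame(provs, index=responses.index, columns=ids))
    scored = pd.concat(scored_blocks, axis=1)[list(responses.columns)]
    prov = pd.concat(prov_blocks, axis=1)[list(responses.columns)]
    return scored, prov


def domain_scores(scored: pd.DataFrame, bank: ItemBank) -> pd.DataFrame:
    """Per-child subscale totals (sum of the completed 0/1 vector per domain)."""
    out = {}
    for domain in bank.domains:
        ids = [it.item_id for it in bank.items_for(domain)]
        out[domain] = scored[ids].sum(axis=1).astype(int)
    return pd.DataFrame(out, index=scored.index)
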