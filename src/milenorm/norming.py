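"""Age-standardized norm bands and data-driven item reordering.

From each item's fitted logistic curve the ages at 25/50/75/90% pass
probability define three plotted bands (.25-.50, .50-.75, .75-.90); by the
symmetry of the logit, the .25-.50 and .50-.75 bands always have equal
width. The new presentation order sorts items within each domain by the age
at 90% pass probability (ties broken by the P50 age, then original index);
items whose calibration is invalid keep their original positions, flagged,
rather than being re-sorted on meaningless estimates.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .calibration import ItemCalibration, PROBABILITY_LEVELS
from .item_bank import ItemBank
from .reliability import DAYS_PER_MONTH

BAND_COLORS = {  # probability band -> figure colour convention
    (0.25, 0.50): "#40E0D0",  # turquoise
    (0.50, 0.75): "#D62728",  # red
    (0.75, 0.90): "#FFD700",  # yellow
}


def compute_norm_bands(calibrations: list[ItemCalibration]) -> pd.DataFrame:
    """Per-item age thresholds (days and display months) and validity flag.

    Invalid items (non-converged, separated, degenerate, or beta <= 0) carry
    ``valid=False`` and NaN thresholds.
    """
    rows = []
    for c in calibrations:
        row = {"item_id": c.item_id, "domain": c.domain, "index": c.index, "valid": c.valid}
        for p in PROBABILITY_LEVELS:
            age = c.age_at.get(p, np.nan) if c.valid else np.nan
            row[f"age_p{int(p * 100)}_days"] = age
            row[f"age_p{int(p * 100)}_months"] = age / DAYS_PER_MONTH if np.isfinite(age) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def reorder_items(calibrations: list[ItemCalibration], bank: ItemBank) -> pd.DataFrame:
    """New within-domain presentation order sorted by the P90 age.

    Valid items are sorted ascending by ``age_at(.90)``, ties broken by
    ``age_at(.50)`` then original index (a stable sort). Invalid items retain
    their original positions; valid items fill the remaining positions in
    sorted order.
    """
    by_id = {c.item_id: c for c in calibrations}
    rows = []
    for domain in bank.domains:
        items = bank.items_for(domain)
        k = len(items)
        cals = [by_id[it.item_id] for it in items]
        invalid_pos = {c.index for c in cals if not c.valid}
        valid_sorted = sorted(
            (c for c in cals if c.valid),
            key=lambda c: (c.age_at[0.90], c.age_at[0.50], c.index),
        )
        free_positions = [i for i in range(1, k + 1) if i not in invalid_pos]
        new_index = {c.item_id: pos for c, pos in zip(valid_sorted, free_positions)}
        for c in cals:
            if not c.valid:
                new_index[c.item_id] = c.index
        for c in cals:
            rows.append(
                {
                    "domain": domain,
                    "item_id": c.item_id,
                    "original_index": c.index,
                    "new_index": new_index[c.item_id],
                    "age_p90_days": c.age_at.get(0.90, np.nan) if c.valid else np.nan,
                    "age_p50_days": c.age_at.get(0.50, np.nan) if c.valid else np.nan,
                    "valid": c.valid,
                }
            )
    return pd.DataFrame(rows)


def _format_age_axis(ax, max_months: float) -> None:
    """Month ticks up to 24 months, year ticks beyond (as in growth charts)."""
    month_ticks = [t for t in (0, 3, 6, 9, 12, 18, 24) if t <= max_months]
    year_ticks = [t for t in (36, 48, 60) if t <= max_months + 6]
    ticks = month_ticks + year_ticks
    labels = [f"{t}m" for t in month_ticks] + [f"{t // 12}y" for t in year_ticks]
    ax.set_xticks(ticks, labels)
    ax.axvline(24, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("age (months to 24m, then years)")


def plot_norm_bands(
    norms: pd.DataFrame, ordering: pd.DataFrame, domain: str, path: str | Path
) -> None:
    """Horizontal probability-band chart for one domain, items in new order."""
    dom_norms = norms[norms["domain"] == domain].set_index("item_id")
    dom_order = ordering[ordering["domain"] == domain].sort_values("new_index")
    fig, ax = plt.subplots(figsize=(8, 0.28 * len(dom_order) + 1.5))
    max_months = 0.0
    for y, row in enumerate(dom_order.itertuples(index=False)):
        if not row.valid:
            continue
        n = dom_norms.loc[row.item_id]
        for (p_lo, p_hi), color in BAND_COLORS.items():
            lo = n[f"age_p{int(p_lo * 100)}_months"]
            hi = n[f"age_p{int(p_hi * 100)}_months"]
            ax.barh(y, hi - lo, left=lo, height=0.7, color=color, edgecolor="none")
            max_months = max(max_months, float(hi))
    ax.set_yticks(range(len(dom_order)), dom_order["item_id"])
    ax.invert_yaxis()
    _format_age_axis(ax, max_months)
    ax.set_title(f"Age reference bands — {domain.replace('_', ' ')}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def export_norms(
    norms: pd.DataFrame,
    ordering: pd.DataFrame,
    outdir: str | Path,
    bank: ItemBank,
    charts: bool = True,
) -> list[Path]:
    """Write the norm-band table, before/after ordering table, and band charts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    norms_path = outdir / "norm_bands.csv"
    norms.to_csv(norms_path, index=False)
    written.append(norms_path)
    order_path = outdir / "item_ordering.csv"
    ordering.to_csv(order_path, index=False)
    written.append(order_path)
    if charts:
        for domain in bank.domains:
            chart_path = outdir / f"bands_{domain}.png"
            plot_norm_bands(norms, ordering, domain, chart_path)
            written.append(chart_path)
    return written
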