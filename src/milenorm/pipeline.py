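"""End-to-end pipeline driver: simulate (or load) -> administer -> calibrate
-> reliability -> norms -> reorder -> report.

A run is fully reproducible from a :class:`PipelineConfig` plus its seed; the
manifest written at the end records the config and a SHA-256 checksum of
every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import administration, calibration, norming, reliability, synthetic_cohort
from .item_bank import ItemBank, default_bank

log = logging.getLogger("milenorm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (serializable to YAML/JSON)."""

    seed: int = 0
    n_children: int = synthetic_cohort.DEFAULT_N_CHILDREN
    age_range_days: tuple[int, int] = synthetic_cohort.DEFAULT_AGE_RANGE_DAYS
    female_share: float = synthetic_cohort.DEFAULT_FEMALE_SHARE
    caipi_share: float = synthetic_cohort.DEFAULT_CAIPI_SHARE
    n_evaluators: int = synthetic_cohort.DEFAULT_N_EVALUATORS
    p50_span_days: tuple[float, float] = synthetic_cohort.DEFAULT_P50_SPAN_DAYS
    slope_range: tuple[float, float] = synthetic_cohort.DEFAULT_SLOPE_RANGE
    backward_rule: str = "consecutive"
    start_rule_probability: float = 0.90
    use_imputed: bool = True
    split_scheme: str = "odd_even"
    min_group_n: int = reliability.DEFAULT_MIN_GROUP_N
    input_csv: str | None = None  # when set, load scored data instead of simulating
    field_map: dict | None = None
    outdir: str = "milenorm_run"
    charts: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        for key in ("age_range_days", "p50_span_days", "slope_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    config: PipelineConfig
    bank: ItemBank
    cohort: pd.DataFrame
    scored: pd.DataFrame
    provenance: pd.DataFrame | None
    true_params: synthetic_cohort.TrueItemParams | None
    calibrations: list[calibration.ItemCalibration]
    reliability_report: pd.DataFrame
    descriptives: pd.DataFrame
    anova: pd.DataFrame
    norms: pd.DataFrame
    ordering: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def load_dataset(
    path: str | Path, field_map: dict | None, bank: ItemBank
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a scored dataset CSV into (cohort, scores).

    ``field_map`` maps the standard field names (``child_id``, ``age_days``,
    optionally ``sex``/``service``/``evaluator_id``, and each item_id) to the
    file's column names; identity mapping by default. Item values must be 0/1.
    """
    df = pd.read_csv(path)
    fmap = dict(field_map or {})
    def col(name: str) -> str:
        return fmap.get(name, name)

    for required in ("child_id", "age_days"):
        if col(required) not in df.columns:
            raise ValueError(f"input file has no column for required field {required!r}")
    missing_items = [it.item_id for it in bank if col(it.item_id) not in df.columns]
    if missing_items:
        raise ValueError(f"input file missing item columns: {missing_items[:5]}...")

    cohort = pd.DataFrame({"child_id": df[col("child_id")], "age_days": df[col("age_days")]})
    for optional, default in (("sex", "unknown"), ("service", "unknown"), ("evaluator_id", 0)):
        cohort[optional] = df[col(optional)] if col(optional) in df.columns else default
    score_cols = {}
    for it in bank:
        vals = df[col(it.item_id)].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-binary item value {vals[r]!r} at row {r}, column {col(it.item_id)!r}"
            )
        score_cols[it.item_id] = vals.astype(np.int8)
    scores = pd.DataFrame(score_cols, index=cohort["child_id"].to_numpy())
    return cohort, scores


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, bank: ItemBank | None = None) -> RunResult:
    """Execute the full analysis and write all artifacts under config.outdir."""
    bank = bank or default_bank()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    true_params = None
    provenance = None

    try:
        if config.input_csv:
            stage = "load"
            cohort, scored = load_dataset(config.input_csv, config.field_map, bank)
        else:
            stage = "simulate"
            true_params = synthetic_cohort.generate_true_params(
                bank, config.p50_span_days, config.slope_range, seed=config.seed
            )
            cohort = synthetic_cohort.sample_cohort(
                config.n_children,
                config.age_range_days,
                config.female_share,
                config.caipi_share,
                config.n_evaluators,
                seed=config.seed,
            )
            oracle = synthetic_cohort.simulate_full_responses(true_params, cohort, seed=config.seed)
            p = outdir / "oracle_responses.csv"
            synthetic_cohort.write_dataset(cohort, oracle, p)
            written.append(p)

            stage = "administer"
            start_norms = _start_norms_from_params(true_params, bank, config.start_rule_probability)
            scored, provenance = administration.administer_cohort(
                oracle, cohort, start_norms, bank, backward_rule=config.backward_rule
            )
            p = outdir / "scored_responses.csv"
            synthetic_cohort.write_dataset(cohort, scored, p)
            written.append(p)
            p = outdir / "provenance.csv"
            provenance.rename_axis("child_id").reset_index().to_csv(p, index=False)
            written.append(p)

        stage = "calibrate"
        ages = cohort.set_index("child_id")["age_days"].reindex(scored.index)
        calibrations = calibration.calibrate_all(
            scored, ages, bank, provenance=provenance, use_imputed=config.use_imputed
        )
        p = outdir / "calibrations.csv"
        calibration.calibrations_to_frame(calibrations).to_csv(p, index=False)
        written.append(p)

        stage = "reliability"
        rel = reliability.reliability_report(
            scored, bank, split_scheme=config.split_scheme, seed=config.seed
        )
        totals = administration.domain_scores(scored, bank)
        desc = reliability.descriptives_by_group(totals, ages, min_group_n=config.min_group_n)
        anova = reliability.evaluator_anova(
            totals, ages, cohort.set_index("child_id")["evaluator_id"].reindex(scored.index)
        )
        for name, frame in (("reliability.csv", rel), ("descriptives.csv", desc), ("evaluator_anova.csv", anova)):
            p = outdir / name
            frame.to_csv(p, index=False)
            written.append(p)

        stage = "norms"
        norms = norming.compute_norm_bands(calibrations)
        ordering = norming.reorder_items(calibrations, bank)
        written += norming.export_norms(norms, ordering, outdir, bank, charts=config.charts)

        stage = "report"
        report = {
            "n_children": int(len(scored)),
            "reliability": rel.to_dict(orient="records"),
            "n_items_good_fit": int(sum(c.good_fit for c in calibrations)),
            "n_items_valid": int(sum(c.valid for c in calibrations)),
        }
        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2))
        written.append(p)

        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "artifacts": {f.name: _sha256(f) for f in written},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:  # annotate with the failing stage
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    return RunResult(
        config=config,
        bank=bank,
        cohort=cohort,
        scored=scored,
        provenance=provenance,
        true_params=true_params,
        calibrations=calibrations,
        reliability_report=rel,
        descriptives=desc,
        anova=anova,
        norms=norms,
        ordering=ordering,
        manifest=manifest,
    )


def _start_norms_from_params(
    params: synthetic_cohort.TrueItemParams, bank: ItemBank, probability: float
) -> dict[str, np.ndarray]:
    """Start-rule norm ages per domain, derived from the generating model.

    Emulates the instrument being configured with prior norms (the field
    study used an earlier tool's norms for its initial trial); in simulation
    the generator's truth plays that role.
    """
    ages = params.age_at(probability)
    out: dict[str, np.ndarray] = {}
    offset = 0
    for domain in bank.domains:
        k = bank.domain_size(domain)
        out[domain] = ages[offset : offset + k]
        offset += k
    return out
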