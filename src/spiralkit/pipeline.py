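"""End-to-end orchestration: simulate/load -> indices -> statistics -> report.

The report bundle mirrors the structure of a case-control spiral-analysis
study: a demographics table, the 12-row index comparison table (six
dominant-hand rows, six between-hand-difference rows), per-index mixed-model
fits, the combined-index ROC with Youden cut and three-fold cross-validated
AUCs, the early-disease subset analysis, and an optional male-only
sensitivity analysis. Every output embeds the seed and a hash of the
configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import IndexConfig, DEFAULT_CONFIG, DEFAULT_SEED
from .io import SpiralTrace, SubjectMeta, read_traces, read_cohort_meta
from .indices import (IndexSet, SubjectRecord, compute_index_set,
                      aggregate_subject, INDEX_NAMES)
from .groupstats import comparison_table, demographics_table, fit_mixed_model
from .discrimination import (feature_table, analyze_features,
                             early_pd_analysis, FEATURE_COLUMNS)
from .simulate import generate_cohort


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    seed: int = DEFAULT_SEED
    n_pd: int = 138
    n_control: int = 150
    n_early_pd: int = 50
    trials_per_hand: int = 10
    max_early_duration: float = 5.0
    cv_folds: int = 3
    men_only_sensitivity: bool = False
    index: IndexConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    #: if set, load this cohort instead of simulating
    cohort_csv: Optional[str] = None
    traces_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def index_table(traces: Sequence[SpiralTrace],
                config: IndexConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-trial index table: one row per (subject, hand, trial)."""
    rows = []
    for tr in traces:
        iset = compute_index_set(tr, config=config)
        rows.append({"subject_id": tr.subject_id, "hand": tr.hand,
                     "trial": int(tr.trial), **iset.as_dict()})
    return pd.DataFrame(rows)


def subject_records(metas: Sequence[SubjectMeta],
                    trial_table: pd.DataFrame) -> list[SubjectRecord]:
    """Aggregate the per-trial table into per-subject records."""
    by_id = {m.subject_id: m for m in metas}
    records = []
    for sid, grp in trial_table.groupby("subject_id", sort=True):
        if sid not in by_id:
            raise ValueError(f"trace subject {sid!r} missing from cohort metadata")
        sets = {}
        for row in grp.itertuples(index=False):
            sets[(row.hand, int(row.trial))] = IndexSet(
                **{n: getattr(row, n) for n in INDEX_NAMES})
        records.append(aggregate_subject(by_id[sid], sets))
    return records


def subject_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Wide per-subject table with dom_/nondom_/diff_ feature columns."""
    return feature_table(records)


def mixed_model_table(trial_table: pd.DataFrame,
                      metas: Sequence[SubjectMeta],
                      hand: str = "dominant") -> pd.DataFrame:
    """Covariate-adjusted mixed-model group effect for each index.

    One model per index on the per-trial observations of the given hand,
    with a random intercept per subject, adjusting for age, sex and
    handedness.
    """
    meta_df = pd.DataFrame([{
        "subject_id": m.subject_id, "group": m.group, "age": m.age,
        "sex": m.sex, "handedness": m.handedness} for m in metas])
    data = trial_table[trial_table["hand"] == hand].merge(
        meta_df, on="subject_id", validate="many_to_one")
    rows = []
    for name in INDEX_NAMES:
        d = data.rename(columns={name: "value"})[
            ["subject_id", "group", "age", "sex", "handedness", "value"]]
        fit = fit_mixed_model(d)
        rows.append({"index": name, **fit})
    return pd.DataFrame(rows)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to config.out_dir.

    Stages: cohort acquisition (simulation by default, or CSV inputs),
    per-trial index computation, per-subject aggregation, demographic and
    index comparison tables, mixed models, discrimination analysis with
    cross-validation and early-disease subset, optional male-only tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-cohort"
    try:
        if config.cohort_csv:
            metas = read_cohort_meta(config.cohort_csv)
            traces = []
            tdir = Path(config.traces_dir or Path(config.cohort_csv).parent / "traces")
            for m in metas:
                traces.extend(read_traces(tdir / f"{m.subject_id}.csv"))
        else:
            metas, traces, _ = generate_cohort(
                n_pd=config.n_pd, n_control=config.n_control,
                n_early_pd=config.n_early_pd, seed=config.seed,
                trials_per_hand=config.trials_per_hand)

        stage = "indices"
        trial_df = index_table(traces, config=config.index)
        records = subject_records(metas, trial_df)
        trial_df.to_csv(out / "trial_indices.csv", index=False)
        subject_table(records).to_csv(out / "subject_indices.csv", index=False)

        stage = "group-stats"
        demo = demographics_table(records)
        demo.to_csv(out / "demographics.csv", index=False)
        comp = comparison_table(records)
        comp.to_csv(out / "comparison.csv", index=False)
        (out / "comparison.md").write_text(comp.to_markdown(index=False))
        mm = mixed_model_table(trial_df, metas)
        mm.to_csv(out / "mixed_models.csv", index=False)

        stage = "discrimination"
        features = feature_table(records)
        disc = analyze_features(features, seed=config.seed)
        early = early_pd_analysis(features, seed=config.seed,
                                  max_duration=config.max_early_duration)
        analysis = {
            "auc": disc.auc, "youden_cut": disc.youden_cut,
            "sensitivity": disc.sensitivity, "specificity": disc.specificity,
            "cv": {"fold_aucs": disc.cv.fold_aucs, "mean": disc.cv.mean_auc},
            "early_pd": {"auc": early.auc,
                         "cv": {"fold_aucs": early.cv.fold_aucs,
                                "mean": early.cv.mean_auc},
                         "n_pd": early.n_pd, "n_control": early.n_control},
            "n_pd": disc.n_pd, "n_control": disc.n_control,
        }
        with open(out / "discrimination.json", "w") as fh:
            json.dump(analysis, fh, indent=1, default=_json_default)

        men_table = None
        if config.men_only_sensitivity:
            stage = "men-only-sensitivity"
            men = [r for r in records if r.meta.sex == "M"]
            men_table = comparison_table(men)
            men_table.to_csv(out / "comparison_men_only.csv", index=False)

        stage = "report"
        log = {"version": __version__, "seed": config.seed,
               "config_hash": config.config_hash(),
               "config": dataclasses.asdict(config),
               "n_subjects": len(records), "n_traces": len(traces)}
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {"records": records, "trial_indices": trial_df,
            "demographics": demo, "comparison": comp, "mixed_models": mm,
            "discrimination": analysis, "men_only": men_table,
            "out_dir": str(out)}
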