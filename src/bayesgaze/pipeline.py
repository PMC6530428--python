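"""Dataset loading/validation and report generation.

Ties the stages together: answer and fixation logs (CSV) plus scenario
definitions (JSON) go in; out comes a report bundle with solution-rate
tables by visualization x format x inference class, an error tally by
strategy, AOI indicator tables per query, and heat maps stratified by
classification outcome.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .scenario import (
    NATURAL_FREQUENCY,
    PROBABILITY,
    Answer,
    InferenceQuery,
    Scenario,
    ScenarioError,
    parse_quantity,
    scenario_from_dict,
)
from .strategies import (
    Classification,
    ClassifierConfig,
    classify_answer,
    tally_errors,
)
from .gaze import (
    AOILayout,
    CanvasSpec,
    FixationEvent,
    HeatMapGrid,
    Trial,
    aoi_indicators,
    build_layout,
    heatmap,
)

__all__ = [
    "Dataset",
    "DatasetValidationError",
    "ReportBundle",
    "load_dataset",
    "run_report",
    "write_report",
    "trials_from_fixation_log",
]

_ANSWER_COLUMNS = {"participant_id", "context_id", "trial_index",
                   "query_code", "format", "visualization"}
_FIXATION_COLUMNS = {"participant_id", "context_id", "trial_index",
                     "query_code", "format", "visualization",
                     "t_start_ms", "duration_ms", "x_px", "y_px"}


class DatasetValidationError(ValueError):
    """Schema or consistency violations, with row-level locations."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "\n".join(self.problems[:20])
        super().__init__(f"{len(self.problems)} validation problem(s):\n"
                         f"{preview}")


@dataclass(frozen=True)
class Dataset:
    answers: pd.DataFrame
    fixations: pd.DataFrame
    scenarios: Mapping[str, Scenario]


def load_dataset(
    answer_csv: str | Path,
    fixation_csv: str | Path,
    scenario_jsons: Sequence[str | Path],
) -> Dataset:
    """Load and validate the CSV/JSON inputs of one analysis run."""
    answers = pd.read_csv(answer_csv)
    fixations = pd.read_csv(fixation_csv)
    scenarios: dict[str, Scenario] = {}
    for path in scenario_jsons:
        s = scenario_from_dict(json.loads(Path(path).read_text()))
        scenarios[s.context_id] = s

    problems: list[str] = []
    for name, df, req in (("answers", answers, _ANSWER_COLUMNS),
                          ("fixations", fixations, _FIXATION_COLUMNS)):
        missing = req - set(df.columns)
        if missing:
            problems.append(f"{name}: missing column(s) {sorted(missing)}")
    if problems:
        raise DatasetValidationError(problems)

    for i, row in answers.iterrows():
        loc = f"answers row {i}"
        try:
            parse_quantity(row["query_code"])
        except ScenarioError as exc:
            problems.append(f"{loc}: {exc}")
            continue
        if row["format"] not in (PROBABILITY, NATURAL_FREQUENCY):
            problems.append(f"{loc}: unknown format {row['format']!r}")
            continue
        if row["context_id"] not in scenarios:
            problems.append(f"{loc}: unknown context {row['context_id']!r}")
        has_prob = pd.notna(row.get("answer_prob"))
        has_freq = pd.notna(row.get("answer_num")) and \
            pd.notna(row.get("answer_den"))
        if row["format"] == PROBABILITY and not has_prob:
            problems.append(f"{loc}: probability query without answer_prob")
        if row["format"] == PROBABILITY and has_freq:
            problems.append(f"{loc}: frequency pair given for a probability "
                            f"query")
        if row["format"] == NATURAL_FREQUENCY and not has_freq:
            problems.append(f"{loc}: frequency query without "
                            f"answer_num/answer_den")
        if row["format"] == NATURAL_FREQUENCY and has_prob:
            problems.append(f"{loc}: answer_prob given for a frequency query")
    for i, row in fixations.iterrows():
        if row["duration_ms"] <= 0:
            problems.append(f"fixations row {i}: non-positive duration")
        if row["context_id"] not in scenarios:
            problems.append(f"fixations row {i}: unknown context "
                            f"{row['context_id']!r}")
    if problems:
        raise DatasetValidationError(problems)
    return Dataset(answers=answers, fixations=fixations, scenarios=scenarios)


def _answer_from_row(row) -> Answer:
    if row["format"] == PROBABILITY:
        return Answer.probability(float(row["answer_prob"]) / 100.0)
    return Answer.frequency(int(row["answer_num"]), int(row["answer_den"]))


def trials_from_fixation_log(
    fixations: pd.DataFrame,
    layout_for: Mapping[tuple[str, str], AOILayout] | None = None,
) -> dict[tuple, Trial]:
    """Group a fixation log into Trial objects keyed by
    (participant_id, trial_index)."""
    trials: dict[tuple, Trial] = {}
    for key, grp in fixations.groupby(["participant_id", "trial_index"]):
        grp = grp.sort_values("t_start_ms")
        first = grp.iloc[0]
        fixes = tuple(
            FixationEvent(t_start=float(r.t_start_ms),
                          duration=float(r.duration_ms),
                          x=float(r.x_px), y=float(r.y_px))
            for r in grp.itertuples(index=False))
        trials[key] = Trial(
            participant_id=str(first["participant_id"]),
            query=InferenceQuery(first["query_code"], first["format"],
                                 first["context_id"]),
            visualization=first["visualization"],
            fixations=fixes)
    return trials


@dataclass
class ReportBundle:
    solution_rates: pd.DataFrame
    error_tally: pd.DataFrame
    classifications: pd.DataFrame
    aoi_tables: dict[tuple[str, str, str], pd.DataFrame]
    heatmaps: dict[tuple[str, str, str], HeatMapGrid]
    metadata: dict


def run_report(
    dataset: Dataset,
    cfg: ClassifierConfig | None = None,
    *,
    heatmap_grid_step: int = 4,
    heatmap_sigma: float = 30.0,
    seed: int | None = None,
) -> ReportBundle:
    """Classify every answered trial and compute all report tables.

    Deterministic for identical inputs; ``seed`` is recorded in the
    metadata only (no stage here is stochastic).
    """
    cfg = cfg or ClassifierConfig()
    if dataset.answers.empty:
        raise ValueError("empty dataset")

    cls_rows = []
    records = []
    cls_by_trial: dict[tuple, Classification] = {}
    for _, row in dataset.answers.iterrows():
        scenario = dataset.scenarios[row["context_id"]]
        query = InferenceQuery(row["query_code"], row["format"],
                               row["context_id"])
        result = classify_answer(_answer_from_row(row), scenario, query, cfg)
        key = (row["participant_id"], row["trial_index"])
        cls_by_trial[key] = result
        records.append({"visualization": row["visualization"],
                        "format": row["format"], "classification": result})
        cls_rows.append({
            "participant_id": row["participant_id"],
            "trial_index": row["trial_index"],
            "context_id": row["context_id"],
            "query_code": row["query_code"],
            "format": row["format"],
            "visualization": row["visualization"],
            "inference_class": query.inference_class,
            "assigned": result.assigned,
            "assigned_base": result.assigned_base,
            "correct": result.is_correct,
            "ambiguous": result.ambiguous,
            "misread_flag": result.misread_flag,
            "n_candidates": len(result.candidates),
        })
    classifications = pd.DataFrame(cls_rows)

    solution_rates = (
        classifications
        .groupby(["visualization", "format", "inference_class"])
        .agg(n=("correct", "size"), n_correct=("correct", "sum"))
        .reset_index())
    solution_rates["solution_rate"] = (
        solution_rates["n_correct"] / solution_rates["n"])

    error_tally = tally_errors(records)

    trials = trials_from_fixation_log(dataset.fixations)
    aoi_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    by_query: dict[tuple[str, str, str], list[tuple[tuple, Trial]]] = {}
    for tk, trial in trials.items():
        k = (trial.query.context_id, trial.query.quantity_code,
             trial.query.format)
        by_query.setdefault(k, []).append((tk, trial))
    layouts: dict[tuple[str, str], AOILayout] = {}
    for k, ts in sorted(by_query.items()):
        vis = ts[0][1].visualization
        layout = layouts.setdefault((vis, k[2]), build_layout(vis, k[2]))
        aoi_tables[k] = aoi_indicators([t for _, t in ts], layout)

    heatmaps: dict[tuple[str, str, str], HeatMapGrid] = {}
    for k, ts in sorted(by_query.items()):
        strata: dict[str, list[Trial]] = {"correct": [], "incorrect": []}
        for tk, t in ts:
            cls = cls_by_trial.get(tk)
            stratum = ("correct" if cls is not None and cls.is_correct
                       else "incorrect")
            strata[stratum].append(t)
        for stratum, sub in strata.items():
            if sub:
                heatmaps[(k[0], k[1] + "|" + k[2], stratum)] = heatmap(
                    sub, grid_step=heatmap_grid_step, sigma=heatmap_sigma)

    metadata = {
        "n_trials": int(len(dataset.answers)),
        "n_participants": int(dataset.answers["participant_id"].nunique()),
        "seed": seed,
        "classifier_config": {
            "probability_tolerance": cfg.probability_tolerance,
            "frequency_match_mode": cfg.frequency_match_mode,
            "generate_misreads": cfg.generate_misreads,
        },
        "input_hash": _hash_frames(dataset.answers, dataset.fixations),
    }
    return ReportBundle(solution_rates=solution_rates,
                        error_tally=error_tally,
                        classifications=classifications,
                        aoi_tables=aoi_tables,
                        heatmaps=heatmaps,
                        metadata=metadata)


def _hash_frames(*frames: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for df in frames:
        h.update(df.to_csv(index=False).encode())
    return h.hexdigest()[:16]


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the bundle as diffable CSV/JSON plus grayscale heat-map PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.solution_rates.to_csv(out / "solution_rates.csv", index=False)
    bundle.error_tally.to_csv(out / "error_tally.csv", index=False)
    bundle.classifications.to_csv(out / "classifications.csv", index=False)
    aoi_dir = out / "aoi_tables"
    aoi_dir.mkdir(exist_ok=True)
    for (ctx, code, fmt), table in bundle.aoi_tables.items():
        safe = code.replace("P(", "").replace(")", "").replace("|", "_given_")
        table.to_csv(aoi_dir / f"{ctx}__{safe}__{fmt}.csv")
    hm_dir = out / "heatmaps"
    hm_dir.mkdir(exist_ok=True)
    for (ctx, qf, stratum), grid in bundle.heatmaps.items():
        safe = (qf.replace("P(", "").replace(")", "")
                  .replace("|", "_given_").replace("&", "and"))
        base = hm_dir / f"{ctx}__{safe}__{stratum}"
        np.savetxt(f"{base}.csv", grid.values, delimiter=",", fmt="%.6g")
        norm = grid.normalized().values
        img = Image.fromarray((norm * 255).astype("uint8"), mode="L")
        img.save(f"{base}.png")
    (out / "manifest.json").write_text(
        json.dumps(bundle.metadata, indent=2, default=str) + "\n")
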