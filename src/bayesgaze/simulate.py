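"""Synthetic experiment generator.

Simulates the full two-block design -- 24 participants, a tree-diagram
block (mammography context) followed by a 2x2-table block (economics
context), ten inferences per block with the six non-Bayesian inferences
randomized before the four Bayesian ones -- with a latent answering
strategy per trial that drives both the numeric answer and a
strategy-conditioned fixation sequence under the 30 s trial cap.

The gaze model is deliberately simple: an initial look at the question
strip, an orientation sweep over the stimulus in reading order, an
execution phase concentrated (with a configurable weight ratio) on the
AOIs referenced by the latent strategy's formula, and question revisits
that are more likely for Bayesian queries.  Fixation durations are
lognormal; positions are jittered around AOI centres so some fixations
land on whitespace.  These are synthetic stand-ins, not estimates of any
real cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scenario import (
    NATURAL_FREQUENCY,
    PROBABILITY,
    Answer,
    InferenceQuery,
    Scenario,
    enumerate_design_queries,
    format_percent,
    packaged_scenarios,
    parse_quantity,
)
from .strategies import (
    BAYESIAN_STRATEGY_NAMES,
    Strategy,
    StrategyError,
    candidate_space,
    predict_answer,
    strategy_applicable,
)
from .gaze import (
    QUESTION,
    TABLE,
    TREE,
    TRIAL_TIME_LIMIT_MS,
    WHITESPACE,
    AOILayout,
    CanvasSpec,
    FixationEvent,
    Trial,
    build_layout,
    relevant_aois,
    _TABLE_CELL,
    _TABLE_MARGIN,
    _TREE_NODE_OF_CELL,
    _TREE_NODE_OF_MARGIN,
)

__all__ = [
    "GazeParams",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_design",
    "simulate_answer",
    "simulate_gaze",
    "simulate_experiment",
    "strategy_relevant_aois",
    "DEFAULT_STRATEGY_MIXTURE",
]

CONTEXT_VISUALIZATION = {"mammography": TREE, "economics": TABLE}


@dataclass(frozen=True)
class GazeParams:
    """Tunable parameters of the fixation generator (units noted)."""

    n_question_initial: int = 2          # fixations on the question first
    orientation_sweep: bool = True       # one pass in reading order
    n_execution_mean: float = 14.0       # Poisson mean, execution fixations
    duration_ln_mean: float = math.log(260.0)  # lognormal of duration (ms)
    duration_ln_sigma: float = 0.45
    relevant_weight: float = 4.0         # relevant:irrelevant dwell ratio
    question_revisit_prob: float = 0.12  # per execution fixation
    bayesian_question_boost: float = 2.5 # multiplies revisit prob
    jitter_sd: float = 28.0              # px around AOI centres
    saccade_gap_ms: float = 30.0
    time_limit_ms: float = TRIAL_TIME_LIMIT_MS


def _mixture(**kv: float) -> dict[str, float]:
    total = sum(kv.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture must sum to 1, got {total}")
    return dict(kv)


#: Latent strategy mixtures per (inference_class, format).  Non-Bayesian
#: errors are modelled as quantity confusions; the Bayesian mixtures place
#: most error mass on joint occurrence and the Fisherian confusion, heavier
#: for probability-format questions.
DEFAULT_STRATEGY_MIXTURE: dict[tuple[str, str], dict[str, float]] = {
    ("marginal", PROBABILITY): _mixture(correct=0.70, quantity_confusion=0.30),
    ("marginal", NATURAL_FREQUENCY): _mixture(correct=0.92,
                                              quantity_confusion=0.08),
    ("conjoint", PROBABILITY): _mixture(correct=0.65, quantity_confusion=0.35),
    ("conjoint", NATURAL_FREQUENCY): _mixture(correct=0.70,
                                              quantity_confusion=0.30),
    ("conditional", PROBABILITY): _mixture(correct=0.60,
                                           quantity_confusion=0.40),
    ("conditional", NATURAL_FREQUENCY): _mixture(correct=0.80,
                                                 quantity_confusion=0.20),
    ("bayesian", PROBABILITY): _mixture(
        correct=0.20, joint_occurrence=0.35, fisherian=0.25,
        likelihood_subtraction=0.07, evidence_only=0.06,
        likelihood_addition=0.07),
    ("bayesian", NATURAL_FREQUENCY): _mixture(
        correct=0.60, joint_occurrence=0.17, fisherian=0.15, pre_bayes=0.08),
}

# Default quantity-confusion targets: the structurally adjacent quantity a
# participant most plausibly reads off instead (complement for marginals,
# the matching conditional for conjoints and vice versa).
_CONFUSION_TARGET = {
    "P(B)": "P(notB)", "P(notB)": "P(B)",
    "P(A)": "P(notA)", "P(notA)": "P(A)",
    "P(A&B)": "P(B|A)", "P(A&notB)": "P(notB|A)",
    "P(notA&B)": "P(B|notA)", "P(notA&notB)": "P(notB|notA)",
    "P(B|A)": "P(A&B)", "P(notB|A)": "P(A&notB)",
    "P(B|notA)": "P(notA&B)", "P(notB|notA)": "P(notA&notB)",
    "P(A|B)": "P(B|A)", "P(notA|B)": "P(notB|A)",
    "P(A|notB)": "P(B|notA)", "P(notA|notB)": "P(notB|notA)",
}


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 24
    contexts: tuple[str, ...] = ("mammography", "economics")
    strategy_mixture: Mapping[tuple[str, str], Mapping[str, float]] = \
        field(default_factory=lambda: dict(DEFAULT_STRATEGY_MIXTURE))
    answer_noise: float = 0.0
    answer_rounding: str = "one_decimal"  # or "integer_percent" | "none"
    gaze: GazeParams = field(default_factory=GazeParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.answer_noise <= 1.0):
            raise ValueError("answer_noise must be in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for key, mix in self.strategy_mixture.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"mixture for {key} must sum to 1")


@dataclass(frozen=True)
class SimulatedDataset:
    """Answer log, fixation log and latent truth table of one run."""

    answers: pd.DataFrame
    fixations: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------


def simulate_design(config: SimulationConfig, seed: int | None = None
                    ) -> pd.DataFrame:
    """The randomized trial plan: one row per participant x trial.

    Block order is fixed (tree/mammography then table/economics); within a
    block the six non-Bayesian inferences are shuffled, then the four
    Bayesian ones.  Formats are balanced 5/5 per block by construction.
    """
    seed = config.master_seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    rows = []
    for p_idx, child in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        pid = f"p{p_idx + 1:02d}"
        trial_idx = 0
        for context_id in config.contexts:
            queries = enumerate_design_queries(
                context_id, known_contexts=config.contexts)
            non_bayes = [q for q in queries if q.inference_class != "bayesian"]
            bayes = [q for q in queries if q.inference_class == "bayesian"]
            order = [non_bayes[i] for i in rng.permutation(len(non_bayes))]
            order += [bayes[i] for i in rng.permutation(len(bayes))]
            for q in order:
                rows.append({
                    "participant_id": pid,
                    "trial_index": trial_idx,
                    "context_id": context_id,
                    "visualization": CONTEXT_VISUALIZATION.get(context_id,
                                                               TREE),
                    "query_code": q.quantity_code,
                    "format": q.format,
                    "inference_class": q.inference_class,
                })
                trial_idx += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# answers
# --------------------------------------------------------------------------


def _round_answer(answer: Answer, mode: str) -> Answer:
    if answer.format != PROBABILITY or mode == "none":
        return answer
    if mode == "one_decimal":
        return Answer.probability(format_percent(answer.value, 1) / 100.0)
    if mode == "integer_percent":
        return Answer.probability(format_percent(answer.value, 0) / 100.0)
    raise ValueError(f"unknown rounding mode: {mode!r}")


def simulate_answer(
    strategy: Strategy,
    scenario: Scenario,
    query: InferenceQuery,
    noise: float,
    rng: np.random.Generator,
    *,
    rounding: str = "one_decimal",
) -> Answer:
    """The spoken answer: the strategy's prediction, or (with probability
    ``noise``) a distractor drawn uniformly from other quantities'
    answers."""
    prediction = _round_answer(
        predict_answer(strategy, scenario, query), rounding)
    if noise <= 0.0 or rng.random() >= noise:
        return prediction
    pool = []
    for cand in candidate_space(scenario, query):
        a = _round_answer(cand.answer, rounding)
        if a.format == PROBABILITY:
            if abs(a.value - prediction.value) > 1e-9:
                pool.append(a)
        elif (a.numerator, a.denominator) != (prediction.numerator,
                                              prediction.denominator):
            pool.append(a)
    if not pool:  # degenerate scenario where every candidate coincides
        return prediction
    return pool[rng.integers(len(pool))]


def _draw_strategy(
    mixture: Mapping[str, float],
    query: InferenceQuery,
    rng: np.random.Generator,
) -> Strategy:
    names = list(mixture)
    probs = np.array([mixture[n] for n in names])
    name = names[rng.choice(len(names), p=probs / probs.sum())]
    if name == "quantity_confusion":
        return Strategy("quantity_confusion",
                        quantity=_CONFUSION_TARGET[query.quantity_code])
    if name != "correct" and query.inference_class != "bayesian":
        raise StrategyError(f"{name} cannot generate answers for "
                            f"{query.inference_class} queries")
    if not strategy_applicable(name, query.format):
        raise StrategyError(f"{name} is not applicable in {query.format}")
    return Strategy(name)


# --------------------------------------------------------------------------
# gaze
# --------------------------------------------------------------------------


def strategy_relevant_aois(
    strategy: Strategy,
    query: InferenceQuery,
    layout: AOILayout,
) -> set[str]:
    """AOIs referenced by the strategy's formula (execution-phase focus)."""
    if strategy.name == "correct":
        return relevant_aois(query, layout)
    if strategy.name == "quantity_confusion":
        conf = InferenceQuery(strategy.quantity, query.format,
                              query.context_id)
        return relevant_aois(conf, layout)
    if strategy.name == "complement_misread":
        misread = InferenceQuery(strategy.misread_code, query.format,
                                 query.context_id)
        return strategy_relevant_aois(strategy.wrapped, misread, layout)

    q = query.quantity
    if q.kind != "bayesian":
        raise StrategyError(f"{strategy.name} needs an inverted-conditional "
                            f"query")
    from .scenario import _COMPLEMENT
    x, y = q.target[0], q.given
    notx = _COMPLEMENT[x]
    tree_like = layout.visualization == TREE
    cell = _TREE_NODE_OF_CELL if tree_like else _TABLE_CELL
    marg = _TREE_NODE_OF_MARGIN if tree_like else _TABLE_MARGIN
    total = "A" if tree_like else "total"

    def c(ax: str) -> str:
        key = (ax, y) if ax in ("A", "notA") else (y, ax)
        return cell[key]

    name = strategy.name
    if name == "joint_occurrence":
        return {c(x), total}
    if name == "fisherian":
        return {c(x), marg[x]}
    if name == "likelihood_subtraction":
        return {c(x), c(notx), marg[x], marg[notx]}
    if name == "base_rate_only":
        return {marg[x], total}
    if name == "evidence_only":
        return {c(x), c(notx), total}
    if name == "pre_bayes":
        return {marg[x], c(x), c(notx)}
    if name == "cpr_fpr_ratio":
        return {c(x), marg[x], c(notx), marg[notx]}
    if name == "likelihood_addition":
        return {c(x), c(notx)}
    raise StrategyError(f"unknown strategy: {name!r}")


def simulate_gaze(
    strategy: Strategy,
    scenario: Scenario,
    query: InferenceQuery,
    layout: AOILayout,
    params: GazeParams,
    rng: np.random.Generator,
) -> list[FixationEvent]:
    """Strategy-conditioned fixation sequence for one trial."""
    question = layout.aoi(QUESTION)
    focus = strategy_relevant_aois(strategy, query, layout)
    is_bayesian = query.inference_class == "bayesian"
    revisit_p = min(params.question_revisit_prob *
                    (params.bayesian_question_boost if is_bayesian else 1.0),
                    0.9)

    def duration() -> float:
        return float(rng.lognormal(params.duration_ln_mean,
                                   params.duration_ln_sigma))

    def jitter_into(aoi, clamp: bool) -> tuple[float, float]:
        cx, cy = aoi.center
        x = cx + rng.normal(0.0, params.jitter_sd)
        y = cy + rng.normal(0.0, params.jitter_sd)
        if clamp:
            x0, y0, x1, y1 = aoi.rect
            x = min(max(x, x0 + 1), x1 - 1)
            y = min(max(y, y0 + 1), y1 - 1)
        return x, y

    plan: list[tuple[object, bool]] = []
    for _ in range(max(params.n_question_initial, 1)):
        plan.append((question, True))
    if params.orientation_sweep:
        for aoi_id in layout.reading_order:
            if aoi_id != QUESTION:
                plan.append((layout.aoi(aoi_id), False))
    stimulus = [a for a in layout.aois if a.aoi_id != QUESTION]
    weights = np.array([params.relevant_weight if a.aoi_id in focus else 1.0
                        for a in stimulus])
    weights /= weights.sum()
    n_exec = int(rng.poisson(params.n_execution_mean))
    for _ in range(n_exec):
        if rng.random() < revisit_p:
            plan.append((question, True))
        plan.append((stimulus[rng.choice(len(stimulus), p=weights)], False))

    fixations: list[FixationEvent] = []
    t = 0.0
    for aoi, clamp in plan:
        d = duration()
        if t + d > params.time_limit_ms:
            d = params.time_limit_ms - t
            if d < 1.0:
                break
        x, y = jitter_into(aoi, clamp)
        fixations.append(FixationEvent(t_start=t, duration=d, x=x, y=y))
        t += d + params.saccade_gap_ms
        if t >= params.time_limit_ms:
            break
    return fixations


# --------------------------------------------------------------------------
# full experiment
# --------------------------------------------------------------------------


def simulate_experiment(
    config: SimulationConfig | None = None,
    scenarios: Mapping[str, Scenario] | None = None,
) -> SimulatedDataset:
    """Draw latent strategies and emit answer + fixation logs + truth table.

    Bit-identical for identical ``config.master_seed``: every participant
    gets an independent child stream of the master seed, so per-participant
    results do not depend on simulation order.
    """
    config = config or SimulationConfig()
    scenarios = scenarios or packaged_scenarios()
    plan = simulate_design(config)
    layouts = {(vis, fmt): build_layout(vis, fmt)
               for vis in (TREE, TABLE)
               for fmt in (PROBABILITY, NATURAL_FREQUENCY)}

    participant_rngs = {
        f"p{i + 1:02d}": np.random.default_rng(child)
        for i, child in enumerate(
            np.random.SeedSequence((config.master_seed, 1)).spawn(
                config.n_participants))
    }

    answer_rows, fixation_rows, truth_rows = [], [], []
    for row in plan.itertuples(index=False):
        rng = participant_rngs[row.participant_id]
        scenario = scenarios[row.context_id]
        query = InferenceQuery(row.query_code, row.format, row.context_id)
        mixture = config.strategy_mixture[(row.inference_class, row.format)]
        strategy = _draw_strategy(mixture, query, rng)
        answer = simulate_answer(strategy, scenario, query,
                                 config.answer_noise, rng,
                                 rounding=config.answer_rounding)
        layout = layouts[(row.visualization, row.format)]
        fixations = simulate_gaze(strategy, scenario, query, layout,
                                  config.gaze, rng)
        rt = (fixations[-1].t_start + fixations[-1].duration
              if fixations else 0.0)

        answer_rows.append({
            "participant_id": row.participant_id,
            "context_id": row.context_id,
            "trial_index": row.trial_index,
            "query_code": row.query_code,
            "format": row.format,
            "visualization": row.visualization,
            "answer_prob": (round(answer.value * 100.0, 6)
                            if answer.format == PROBABILITY else np.nan),
            "answer_num": (answer.numerator
                           if answer.format == NATURAL_FREQUENCY else np.nan),
            "answer_den": (answer.denominator
                           if answer.format == NATURAL_FREQUENCY else np.nan),
            "response_time_ms": round(rt, 3),
        })
        for f in fixations:
            fixation_rows.append({
                "participant_id": row.participant_id,
                "context_id": row.context_id,
                "trial_index": row.trial_index,
                "query_code": row.query_code,
                "format": row.format,
                "visualization": row.visualization,
                "t_start_ms": round(f.t_start, 3),
                "duration_ms": round(f.duration, 3),
                "x_px": round(f.x, 2),
                "y_px": round(f.y, 2),
            })
        truth_rows.append({
            "participant_id": row.participant_id,
            "trial_index": row.trial_index,
            "context_id": row.context_id,
            "query_code": row.query_code,
            "format": row.format,
            "visualization": row.visualization,
            "strategy": strategy.label,
        })

    return SimulatedDataset(
        answers=pd.DataFrame(answer_rows),
        fixations=pd.DataFrame(fixation_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )
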