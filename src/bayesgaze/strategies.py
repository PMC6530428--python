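"""Predicted answers for correct and erroneous Bayesian reasoning
strategies, and classification of observed answers against them.

The catalog covers the documented error strategies for inverted-conditional
("Bayesian") questions.  Written for a query P(X|Y) with target atom X and
conditioning atom Y (Y on the second split of the tree), each strategy is a
structural rule:

=====================  =====================================================
correct                cell(X∩Y) / margin(Y)
joint_occurrence       cell(X∩Y) / population (the conjoint probability)
fisherian              the inverse conditional P(Y|X)
likelihood_subtraction P(Y|X) − P(Y|¬X), floored at 0 (probability only)
base_rate_only         P(X) (conservatism)
evidence_only          margin(Y) / population
pre_bayes              margin(X) out of margin(Y) (frequency only)
cpr_fpr_ratio          P(Y|X) / P(Y|¬X), capped at 1 (probability only)
likelihood_addition    P(Y|X) + P(Y|¬X), capped at 1 (probability only)
quantity_confusion(q)  the correct answer to a *different* quantity q
complement_misread(s)  strategy s applied to a misread query in which one
                       or both negations were overlooked
=====================  =====================================================

Classification builds the full candidate space for a query (all applicable
strategies, quantity confusions over the 16 quantities, reference-class
variants of frequency answers, and optional misread variants), matches the
observed answer within a tolerance, and assigns the best-matching strategy,
with ties broken by a configurable priority order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .scenario import (
    NATURAL_FREQUENCY,
    PROBABILITY,
    ALL_QUANTITY_CODES,
    Answer,
    InferenceQuery,
    Quantity,
    Scenario,
    ScenarioError,
    UndefinedConditionalError,
    answer_query,
    frequency_tree,
    parse_quantity,
    round_half_away,
)

__all__ = [
    "Strategy",
    "StrategyError",
    "ClassifierConfig",
    "Classification",
    "Candidate",
    "BAYESIAN_STRATEGY_NAMES",
    "ESTABLISHED_ERROR_NAMES",
    "predict_answer",
    "candidate_space",
    "classify_answer",
    "tally_errors",
    "separability_report",
]


class StrategyError(ValueError):
    """Strategy not applicable to the given query or format."""


@dataclass(frozen=True)
class Strategy:
    """A named answering strategy.

    ``quantity`` parametrizes quantity_confusion; ``wrapped`` and
    ``misread_code`` parametrize complement_misread (the strategy actually
    executed, on the quantity the participant thought was asked).
    """

    name: str
    quantity: str | None = None
    wrapped: "Strategy | None" = None
    misread_code: str | None = None

    def __post_init__(self) -> None:
        if self.name == "quantity_confusion" and self.quantity is None:
            raise StrategyError("quantity_confusion needs a quantity code")
        if self.name == "complement_misread" and (
                self.wrapped is None or self.misread_code is None):
            raise StrategyError("complement_misread needs wrapped strategy "
                                "and misread quantity code")

    @property
    def label(self) -> str:
        if self.name == "quantity_confusion":
            return f"quantity_confusion[{self.quantity}]"
        if self.name == "complement_misread":
            return f"complement_misread[{self.wrapped.label}@{self.misread_code}]"
        return self.name

    @property
    def base_name(self) -> str:
        return self.name


#: Composite strategies defined for inverted-conditional queries.
BAYESIAN_STRATEGY_NAMES: tuple[str, ...] = (
    "correct",
    "joint_occurrence",
    "fisherian",
    "likelihood_subtraction",
    "base_rate_only",
    "evidence_only",
    "pre_bayes",
    "cpr_fpr_ratio",
    "likelihood_addition",
)

#: The documented ("established") error strategies, i.e. everything in the
#: catalog except the correct rule and the generic confusion/misread labels.
ESTABLISHED_ERROR_NAMES: frozenset[str] = frozenset(
    BAYESIAN_STRATEGY_NAMES[1:])

_PROBABILITY_ONLY = {"likelihood_subtraction", "cpr_fpr_ratio",
                     "likelihood_addition"}
_FREQUENCY_ONLY = {"pre_bayes"}

_DEFAULT_PRIORITY: tuple[str, ...] = (
    "correct",
    "fisherian",
    "joint_occurrence",
    "evidence_only",
    "base_rate_only",
    "pre_bayes",
    "likelihood_subtraction",
    "likelihood_addition",
    "cpr_fpr_ratio",
    "quantity_confusion",
    "complement_misread",
)


def strategy_applicable(name: str, fmt: str) -> bool:
    if name in _PROBABILITY_ONLY:
        return fmt == PROBABILITY
    if name in _FREQUENCY_ONLY:
        return fmt == NATURAL_FREQUENCY
    return True


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def _roles(query: InferenceQuery) -> tuple[str, str, str, str]:
    """(X, notX, Y, notY) atoms for an inverted-conditional query."""
    q = query.quantity
    if q.kind != "bayesian":
        raise StrategyError(
            f"{query.quantity_code} is not an inverted-conditional query")
    from .scenario import _COMPLEMENT  # module-private but stable
    x, y = q.target[0], q.given
    return x, _COMPLEMENT[x], y, _COMPLEMENT[y]


def _cell(scenario: Scenario, atom_x: str, atom_y: str) -> float:
    if atom_x in ("A", "notA"):
        return scenario.cell(atom_x, atom_y)
    return scenario.cell(atom_y, atom_x)


def _cell_count(tree, atom_x: str, atom_y: str) -> int:
    if atom_x in ("A", "notA"):
        return tree.cell_count(atom_x, atom_y)
    return tree.cell_count(atom_y, atom_x)


def predict_answer(
    strategy: Strategy,
    scenario: Scenario,
    query: InferenceQuery,
    *,
    likelihood_addition_mode: str = "conditional",
) -> Answer:
    """The answer a strategy produces for a query.

    ``likelihood_addition_mode`` selects between adding the two
    likelihoods P(Y|X) + P(Y|¬X) (default) and adding the two conjoint
    probabilities of the conditioning column (``"conjoint"``, which
    coincides with evidence_only).
    """
    name, fmt = strategy.name, query.format

    if name == "quantity_confusion":
        conf = InferenceQuery(strategy.quantity, fmt, query.context_id)
        return answer_query(scenario, conf)
    if name == "complement_misread":
        misread = InferenceQuery(strategy.misread_code, fmt, query.context_id)
        return predict_answer(strategy.wrapped, scenario, misread,
                              likelihood_addition_mode=likelihood_addition_mode)
    if name == "correct":
        return answer_query(scenario, query)

    if not strategy_applicable(name, fmt):
        raise StrategyError(f"{name} is not applicable in format {fmt}")
    x, notx, y, noty = _roles(query)

    def p(code: str) -> float:
        return scenario.value(code)

    inv = f"P({y}|{x})"           # the non-inverted conditional
    inv_c = f"P({y}|{notx})"

    if fmt == PROBABILITY:
        if name == "joint_occurrence":
            return Answer.probability(_cell(scenario, x, y))
        if name == "fisherian":
            return Answer.probability(p(inv))
        if name == "likelihood_subtraction":
            return Answer.probability(max(p(inv) - p(inv_c), 0.0))
        if name == "base_rate_only":
            return Answer.probability(scenario.margin(x))
        if name == "evidence_only":
            return Answer.probability(scenario.margin(y))
        if name == "cpr_fpr_ratio":
            denom = p(inv_c)
            if denom <= 0.0:
                raise StrategyError("cpr_fpr_ratio undefined: zero false-"
                                    "positive-type rate")
            return Answer.probability(min(p(inv) / denom, 1.0))
        if name == "likelihood_addition":
            if likelihood_addition_mode == "conjoint":
                total = _cell(scenario, x, y) + _cell(scenario, notx, y)
            else:
                total = p(inv) + p(inv_c)
            return Answer.probability(min(total, 1.0))
        raise StrategyError(f"unknown strategy: {name!r}")

    tree = frequency_tree(scenario)
    if name == "joint_occurrence":
        return Answer.frequency(_cell_count(tree, x, y), tree.A)
    if name == "fisherian":
        return Answer.frequency(_cell_count(tree, x, y), tree.margin_count(x))
    if name == "base_rate_only":
        return Answer.frequency(tree.margin_count(x), tree.A)
    if name == "evidence_only":
        return Answer.frequency(tree.margin_count(y), tree.A)
    if name == "pre_bayes":
        return Answer.frequency(tree.margin_count(x), tree.margin_count(y))
    raise StrategyError(f"unknown strategy: {name!r}")


# --------------------------------------------------------------------------
# candidate space
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierConfig:
    """Matching rules for answer classification.

    A probability answer matches a prediction if both round to the same
    integer percent or if they differ by at most ``probability_tolerance``
    percentage points -- the operationalization of a "one percent interval"
    that accepts 7.0-8.0% for a correct value of 7.8%.
    """

    probability_tolerance: float = 0.5     # percentage points
    frequency_match_mode: str = "exact_pair"  # or "ratio_equivalent"
    priority_order: tuple[str, ...] = _DEFAULT_PRIORITY
    generate_misreads: bool = True
    likelihood_addition_mode: str = "conditional"

    def __post_init__(self) -> None:
        if self.probability_tolerance < 0:
            raise ValueError("probability_tolerance must be >= 0")
        if self.frequency_match_mode not in ("exact_pair", "ratio_equivalent"):
            raise ValueError(f"unknown frequency_match_mode: "
                             f"{self.frequency_match_mode!r}")
        missing = set(_DEFAULT_PRIORITY) - set(self.priority_order)
        if missing:
            raise ValueError(f"priority_order is missing: {sorted(missing)}")

    def priority(self, base_name: str) -> int:
        return self.priority_order.index(base_name)


@dataclass
class Candidate:
    """One distinct predicted answer with every strategy that produces it."""

    answer: Answer
    strategies: list[Strategy] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strategies]

    @property
    def has_non_misread(self) -> bool:
        return any(s.name != "complement_misread" for s in self.strategies)


def _answer_key(answer: Answer):
    if answer.format == PROBABILITY:
        return ("p", round(answer.value, 10))
    return ("f", answer.numerator, answer.denominator)


def _misread_variants(query: InferenceQuery) -> list[str]:
    """Quantity codes a participant may actually have answered after
    overlooking a negation in the question."""
    q = query.quantity
    out = []
    try:
        out.append(q.complement_target().code)
    except ScenarioError:
        pass
    if q.given is not None:
        out.append(q.complement_given().code)
        out.append(q.complement_target().complement_given().code)
    return [c for c in out if c != q.code]


def candidate_space(
    scenario: Scenario,
    query: InferenceQuery,
    cfg: ClassifierConfig | None = None,
) -> list[Candidate]:
    """All labeled predictions an answer may be matched against.

    Contains every applicable composite strategy (for inverted-conditional
    queries), the correct answer for any query, quantity confusions over
    the 16 quantities (frequency-format quantities offered both with their
    natural conditioning set and with the whole population as denominator,
    covering reference-class errors), and misread variants when enabled.
    Identical predictions are collapsed into one candidate with merged
    strategy labels.
    """
    cfg = cfg or ClassifierConfig()
    groups: dict[object, Candidate] = {}

    def add(strategy: Strategy, answer: Answer) -> None:
        key = _answer_key(answer)
        if key not in groups:
            groups[key] = Candidate(answer=answer)
        cand = groups[key]
        if strategy.label not in cand.labels:
            cand.strategies.append(strategy)

    def try_add(strategy: Strategy) -> None:
        try:
            add(strategy, predict_answer(
                strategy, scenario, query,
                likelihood_addition_mode=cfg.likelihood_addition_mode))
        except (StrategyError, UndefinedConditionalError, ScenarioError):
            pass

    is_bayesian = query.inference_class == "bayesian"
    if is_bayesian:
        for name in BAYESIAN_STRATEGY_NAMES:
            if strategy_applicable(name, query.format):
                try_add(Strategy(name))
    else:
        try_add(Strategy("correct"))

    # quantity confusions (the query's own quantity is the correct answer
    # already; adding it again would only duplicate that label)
    tree = frequency_tree(scenario) if query.format == NATURAL_FREQUENCY else None
    for code in ALL_QUANTITY_CODES:
        if code == query.quantity_code:
            continue
        strat = Strategy("quantity_confusion", quantity=code)
        try_add(strat)
        if tree is not None:
            # reference-class variant: same target subset over the whole
            # population instead of its natural conditioning set
            q = parse_quantity(code)
            if q.kind in ("conditional", "bayesian"):
                t = q.target[0]
                num = (tree.cell_count(t, q.given) if t in ("A", "notA")
                       else tree.cell_count(q.given, t))
                add(strat, Answer.frequency(num, tree.A))

    if cfg.generate_misreads:
        wrapped_names = ([n for n in BAYESIAN_STRATEGY_NAMES
                          if strategy_applicable(n, query.format)]
                         if is_bayesian else ["correct"])
        for code in _misread_variants(query):
            mis_class = parse_quantity(code).inference_class
            for name in wrapped_names:
                # the wrapped strategy must make sense for the misread query
                if name != "correct" and mis_class != "bayesian":
                    continue
                try_add(Strategy("complement_misread",
                                 wrapped=Strategy(name), misread_code=code))

    return list(groups.values())


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Classification:
    """Outcome of matching one answer against the candidate space."""

    assigned: str                      # strategy label or "unclassified"
    candidates: tuple[tuple[str, float], ...]  # (label, distance) matches
    ambiguous: bool
    misread_flag: bool

    @property
    def assigned_base(self) -> str:
        return self.assigned.split("[", 1)[0]

    @property
    def is_correct(self) -> bool:
        return self.assigned == "correct"


def _prob_match(a: float, b: float, tol_pp: float) -> tuple[bool, float]:
    """Match rule for probability answers; distance in percentage points."""
    dist = abs(a - b) * 100.0
    same_int = round_half_away(a * 100.0) == round_half_away(b * 100.0)
    return (same_int or dist <= tol_pp), dist


def classify_answer(
    answer: Answer,
    scenario: Scenario,
    query: InferenceQuery,
    cfg: ClassifierConfig | None = None,
) -> Classification:
    cfg = cfg or ClassifierConfig()
    if answer.format != query.format:
        raise StrategyError(
            f"answer format {answer.format!r} does not match query format "
            f"{query.format!r}")

    matches: list[tuple[Candidate, float, bool]] = []  # (cand, dist, exact)
    for cand in candidate_space(scenario, query, cfg):
        if query.format == PROBABILITY:
            ok, dist = _prob_match(answer.value, cand.answer.value,
                                   cfg.probability_tolerance)
            exact = dist < 1e-9
        else:
            same_pair = (answer.numerator == cand.answer.numerator
                         and answer.denominator == cand.answer.denominator)
            if cfg.frequency_match_mode == "exact_pair":
                ok, exact = same_pair, same_pair
                dist = 0.0 if same_pair else math.inf
            else:
                ok = math.isclose(answer.as_ratio, cand.answer.as_ratio,
                                  rel_tol=0, abs_tol=1e-12)
                exact = ok and same_pair
                dist = 0.0 if same_pair else (0.5 if ok else math.inf)
        if ok:
            matches.append((cand, dist, exact))

    if not matches:
        return Classification("unclassified", (), False, False)

    def best_label(cand: Candidate) -> Strategy:
        return min(cand.strategies, key=lambda s: cfg.priority(s.base_name))

    exact_matches = [m for m in matches if m[2]]
    pool = exact_matches if exact_matches else matches
    pool.sort(key=lambda m: (m[1], cfg.priority(best_label(m[0]).base_name)))
    winner = best_label(pool[0][0])

    flat = tuple((s.label, dist) for cand, dist, _ in matches
                 for s in cand.strategies)
    # distinct alternatives: non-misread labels, plus candidate groups that
    # only a misread variant explains
    n_alt = len({s.label for cand, _, _ in matches for s in cand.strategies
                 if s.name != "complement_misread"})
    n_alt += sum(1 for cand, _, _ in matches if not cand.has_non_misread)
    only_misreads = all(not cand.has_non_misread for cand, _, _ in matches)

    return Classification(
        assigned=winner.label,
        candidates=flat,
        ambiguous=n_alt > 1,
        misread_flag=only_misreads,
    )


# --------------------------------------------------------------------------
# tallies and diagnostics
# --------------------------------------------------------------------------


def tally_errors(records: Iterable[dict]) -> pd.DataFrame:
    """Error counts by visualization x format x strategy.

    ``records`` are dicts with keys ``visualization``, ``format`` and
    ``classification`` (a :class:`Classification`).  Correct answers are
    excluded; each cell also reports the subtotal of established
    (documented) error strategies versus all errors.
    """
    rows = []
    for rec in records:
        cls: Classification = rec["classification"]
        if cls.is_correct:
            continue
        rows.append({
            "visualization": rec["visualization"],
            "format": rec["format"],
            "strategy": cls.assigned_base if cls.assigned != "unclassified"
                        else "unclassified",
        })
    if not rows:
        return pd.DataFrame(
            columns=["visualization", "format", "strategy", "count"])
    df = pd.DataFrame(rows)
    tally = (df.groupby(["visualization", "format", "strategy"])
               .size().rename("count").reset_index())
    totals = []
    for (vis, fmt), grp in tally.groupby(["visualization", "format"]):
        established = grp.loc[
            grp["strategy"].isin(ESTABLISHED_ERROR_NAMES), "count"].sum()
        totals.append({"visualization": vis, "format": fmt,
                       "strategy": "established_subtotal",
                       "count": int(established)})
        totals.append({"visualization": vis, "format": fmt,
                       "strategy": "total_errors",
                       "count": int(grp["count"].sum())})
    return pd.concat([tally, pd.DataFrame(totals)], ignore_index=True)


def separability_report(
    scenario: Scenario,
    queries: Iterable[InferenceQuery],
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Which composite-strategy pairs are non-separable per query.

    Two strategies are non-separable when their noise-free predictions
    match each other under the configured tolerance; answers matching such
    a prediction are always flagged ambiguous, never silently assigned.
    """
    cfg = cfg or ClassifierConfig()
    rows = []
    for query in queries:
        if query.inference_class != "bayesian":
            continue
        preds = {}
        for name in BAYESIAN_STRATEGY_NAMES:
            if not strategy_applicable(name, query.format):
                continue
            try:
                preds[name] = predict_answer(
                    Strategy(name), scenario, query,
                    likelihood_addition_mode=cfg.likelihood_addition_mode)
            except (StrategyError, UndefinedConditionalError):
                continue
        names = sorted(preds)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pa, pb = preds[a], preds[b]
                if query.format == PROBABILITY:
                    ok, _ = _prob_match(pa.value, pb.value,
                                        cfg.probability_tolerance)
                else:
                    ok = (pa.numerator, pa.denominator) == \
                         (pb.numerator, pb.denominator)
                if ok:
                    rows.append({
                        "context_id": scenario.context_id,
                        "query_code": query.quantity_code,
                        "format": query.format,
                        "strategy_a": a,
                        "strategy_b": b,
                        "value_a": str(pa),
                        "value_b": str(pb),
                    })
    return pd.DataFrame(rows, columns=[
        "context_id", "query_code", "format",
        "strategy_a", "strategy_b", "value_a", "value_b"])
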