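"""Two-binary-event statistical situations.

A *scenario* is a joint distribution over two binary events A and B
(e.g. A = "has breast cancer", B = "positive mammogram") together with a
reference population size N.  From the four conjoint cells every quantity
used in diagnostic-test reasoning can be derived: the 4 marginal
probabilities, the 4 conjoint probabilities and the 8 conditional
probabilities (16 in total), the branch probabilities of the tree diagram
that first splits on A, and the expected-frequency tree (counts A..G).

Conventions
-----------
* The tree's first split is always on event A.  A conditional probability
  whose condition is A or not-A can be read along the tree branches and is
  called *conditional* here; conditioning on B or not-B runs against the
  tree direction and requires Bayes' rule, hence *bayesian*.
* Quantity codes are compact strings over the grammar::

      code        := "P(" expr ")"
      expr        := atom | atom "&" atom | atom "|" atom
      atom        := "A" | "notA" | "B" | "notB"

  e.g. ``"P(A|B)"``, ``"P(notA&notB)"``.  A conjoint's two atoms must
  refer to different events; a conditional's atoms likewise.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ScenarioError",
    "UndefinedConditionalError",
    "Scenario",
    "BranchProbabilities",
    "FrequencyTree",
    "ProbabilitySet",
    "InferenceQuery",
    "Answer",
    "Quantity",
    "parse_quantity",
    "ALL_QUANTITY_CODES",
    "build_from_branches",
    "branch_probabilities",
    "probability_set",
    "frequency_tree",
    "answer_query",
    "enumerate_design_queries",
    "load_packaged_scenario",
    "packaged_scenarios",
    "scenario_from_dict",
    "scenario_to_dict",
    "round_half_away",
    "format_percent",
]

_ATOL = 1e-12

PROBABILITY = "probability"
NATURAL_FREQUENCY = "natural_frequency"
FORMATS = (PROBABILITY, NATURAL_FREQUENCY)

ATOMS = ("A", "notA", "B", "notB")
_EVENT_OF_ATOM = {"A": "A", "notA": "A", "B": "B", "notB": "B"}
_COMPLEMENT = {"A": "notA", "notA": "A", "B": "notB", "notB": "B"}


class ScenarioError(ValueError):
    """Invalid scenario parameters or malformed quantity code."""


class UndefinedConditionalError(ScenarioError):
    """A conditional probability whose conditioning margin is zero."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_percent(p: float, decimals: int = 1) -> float:
    """Probability -> percent, rounded half-away at ``decimals`` places.

    ``format_percent(0.0776...)`` -> ``7.8``.
    """
    scale = 10 ** decimals
    return round_half_away(p * 100.0 * scale) / scale


# --------------------------------------------------------------------------
# quantity codes
# --------------------------------------------------------------------------

_CODE_RE = re.compile(
    r"^P\((A|notA|B|notB)(?:(&|\|)(A|notA|B|notB))?\)$"
)


@dataclass(frozen=True)
class Quantity:
    """A parsed quantity code.

    ``target`` is the queried atom (for conjoints, the pair in canonical
    A-event-first order); ``given`` is the conditioning atom or ``None``.
    """

    kind: str  # "marginal" | "conjoint" | "conditional" | "bayesian"
    target: tuple[str, ...]
    given: str | None = None

    @property
    def code(self) -> str:
        if self.kind == "conjoint":
            return f"P({self.target[0]}&{self.target[1]})"
        if self.given is None:
            return f"P({self.target[0]})"
        return f"P({self.target[0]}|{self.given})"

    @property
    def inference_class(self) -> str:
        return self.kind

    def complement_target(self) -> "Quantity":
        """Negate the target atom(s) -- a 'misread the queried event'."""
        flipped = tuple(_COMPLEMENT[a] for a in self.target)
        return parse_quantity(self._rebuild(flipped, self.given))

    def complement_given(self) -> "Quantity":
        if self.given is None:
            raise ScenarioError(f"{self.code} has no conditioning event")
        return parse_quantity(self._rebuild(self.target, _COMPLEMENT[self.given]))

    def _rebuild(self, target: tuple[str, ...], given: str | None) -> str:
        if len(target) == 2:
            return f"P({target[0]}&{target[1]})"
        if given is None:
            return f"P({target[0]})"
        return f"P({target[0]}|{given})"


def parse_quantity(code: str) -> Quantity:
    m = _CODE_RE.match(code.replace(" ", ""))
    if not m:
        raise ScenarioError(f"malformed quantity code: {code!r}")
    first, sep, second = m.groups()
    if sep is None:
        return Quantity("marginal", (first,))
    if _EVENT_OF_ATOM[first] == _EVENT_OF_ATOM[second]:
        raise ScenarioError(f"{code!r}: both atoms refer to event "
                            f"{_EVENT_OF_ATOM[first]}")
    if sep == "&":
        # canonical order: the A-event atom first
        pair = (first, second) if _EVENT_OF_ATOM[first] == "A" else (second, first)
        return Quantity("conjoint", pair)
    kind = "conditional" if _EVENT_OF_ATOM[second] == "A" else "bayesian"
    return Quantity(kind, (first,), second)


def _all_codes() -> tuple[str, ...]:
    marg = [f"P({a})" for a in ATOMS]
    conj = [f"P({a}&{b})" for a in ("A", "notA") for b in ("B", "notB")]
    cond = [f"P({b}|{a})" for a in ("A", "notA") for b in ("B", "notB")]
    baye = [f"P({a}|{b})" for b in ("B", "notB") for a in ("A", "notA")]
    return tuple(marg + conj + cond + baye)


#: The 16 quantity codes of a two-binary-event situation.
ALL_QUANTITY_CODES: tuple[str, ...] = _all_codes()


# --------------------------------------------------------------------------
# Scenario
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Joint distribution of two binary events plus a reference population.

    Cells: ``p11`` = P(A∩B), ``p10`` = P(A∩¬B), ``p01`` = P(¬A∩B),
    ``p00`` = P(¬A∩¬B).
    """

    context_id: str
    event_a_label: str
    event_b_label: str
    p11: float
    p10: float
    p01: float
    p00: float
    population_n: int

    def __post_init__(self) -> None:
        cells = (self.p11, self.p10, self.p01, self.p00)
        for c in cells:
            if c < -_ATOL:
                raise ScenarioError(f"negative cell probability: {c}")
        if abs(sum(cells) - 1.0) > 1e-12:
            raise ScenarioError(f"cells must sum to 1, got {sum(cells)!r}")
        if not (isinstance(self.population_n, int) and self.population_n >= 1):
            raise ScenarioError("population_n must be an integer >= 1")

    # cell / margin accessors -------------------------------------------------

    def cell(self, atom_a: str, atom_b: str) -> float:
        """Conjoint probability of an (A-event atom, B-event atom) pair."""
        key = (atom_a, atom_b)
        table = {
            ("A", "B"): self.p11,
            ("A", "notB"): self.p10,
            ("notA", "B"): self.p01,
            ("notA", "notB"): self.p00,
        }
        if key not in table:
            raise ScenarioError(f"not a cell: {key}")
        return table[key]

    def margin(self, atom: str) -> float:
        if atom == "A":
            return self.p11 + self.p10
        if atom == "notA":
            return self.p01 + self.p00
        if atom == "B":
            return self.p11 + self.p01
        if atom == "notB":
            return self.p10 + self.p00
        raise ScenarioError(f"unknown atom: {atom}")

    def value(self, quantity: Quantity | str) -> float:
        """Exact probability of any of the 16 quantities."""
        q = parse_quantity(quantity) if isinstance(quantity, str) else quantity
        if q.kind == "marginal":
            return self.margin(q.target[0])
        if q.kind == "conjoint":
            return self.cell(q.target[0], q.target[1])
        # conditional or bayesian
        denom = self.margin(q.given)
        if denom <= 0.0:
            raise UndefinedConditionalError(
                f"{q.code}: conditioning margin P({q.given}) is zero")
        t = q.target[0]
        if _EVENT_OF_ATOM[t] == "A":
            num = self.cell(t, q.given)
        else:
            num = self.cell(q.given, t)
        return num / denom


# --------------------------------------------------------------------------
# branch probabilities and Bayes' rule (tree form)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchProbabilities:
    """Branch labels of the probability tree that first splits on A.

    b = P(A), c = P(¬A), d = P(B|A), e = P(¬B|A), f = P(B|¬A), g = P(¬B|¬A).
    """

    b: float
    c: float
    d: float
    e: float
    f: float
    g: float

    def __post_init__(self) -> None:
        for lo, hi in ((self.b, self.c), (self.d, self.e), (self.f, self.g)):
            if abs(lo + hi - 1.0) > 1e-12:
                raise ScenarioError("branch pairs must sum to 1")
            if lo < -_ATOL or hi < -_ATOL:
                raise ScenarioError("branch probabilities must be >= 0")

    def posterior(self, quantity: Quantity | str) -> float:
        """Bayes' rule evaluated from the branch labels.

        For P(A|B): b·d / (b·d + c·f), and analogously for the other
        three inverted conditionals.  Independent of the cell-ratio route
        through :func:`probability_set`, which makes it usable as an
        oracle identity.
        """
        q = parse_quantity(quantity) if isinstance(quantity, str) else quantity
        if q.kind != "bayesian":
            raise ScenarioError(f"{q.code} is not an inverted conditional")
        # conjoint masses along the branches
        mass = {
            ("A", "B"): self.b * self.d,
            ("A", "notB"): self.b * self.e,
            ("notA", "B"): self.c * self.f,
            ("notA", "notB"): self.c * self.g,
        }
        t, giv = q.target[0], q.given
        num = mass[(t, giv)]
        denom = mass[("A", giv)] + mass[("notA", giv)]
        if denom <= 0.0:
            raise UndefinedConditionalError(
                f"{q.code}: conditioning margin P({giv}) is zero")
        return num / denom


def build_from_branches(
    base_rate: float,
    hit_rate: float,
    false_alarm_rate: float,
    population_n: int,
    *,
    context_id: str = "scenario",
    event_a_label: str = "A",
    event_b_label: str = "B",
) -> Scenario:
    """Scenario from prevalence, sensitivity and false-alarm rate.

    ``base_rate`` = P(A), ``hit_rate`` = P(B|A), ``false_alarm_rate`` =
    P(B|¬A).  The mammography situation is ``build_from_branches(0.01,
    0.80, 0.096, 10000)``.
    """
    for name, r in (("base_rate", base_rate), ("hit_rate", hit_rate),
                    ("false_alarm_rate", false_alarm_rate)):
        if not (0.0 <= r <= 1.0):
            raise ScenarioError(f"{name} must be in [0, 1], got {r!r}")
    if not (isinstance(population_n, int) and population_n >= 1):
        raise ScenarioError("population_n must be an integer >= 1")
    p11 = base_rate * hit_rate
    p10 = base_rate * (1.0 - hit_rate)
    p01 = (1.0 - base_rate) * false_alarm_rate
    p00 = (1.0 - base_rate) * (1.0 - false_alarm_rate)
    # guard against accumulated float error in the normalization invariant
    drift = 1.0 - (p11 + p10 + p01 + p00)
    p00 += drift
    return Scenario(context_id, event_a_label, event_b_label,
                    p11, p10, p01, p00, population_n)


def branch_probabilities(scenario: Scenario) -> BranchProbabilities:
    b = scenario.margin("A")
    c = scenario.margin("notA")
    if b <= 0.0 or c <= 0.0:
        raise UndefinedConditionalError(
            "branch probabilities undefined: a first-split margin is zero")
    d = scenario.p11 / b
    f = scenario.p01 / c
    return BranchProbabilities(b=b, c=c, d=d, e=1.0 - d, f=f, g=1.0 - f)


# --------------------------------------------------------------------------
# the 16 probabilities
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbabilitySet:
    """All defined quantities of a scenario, keyed by quantity code.

    Conditionals whose conditioning margin is zero are *not* present in
    ``values``; their codes are listed in ``undefined`` instead.
    """

    values: Mapping[str, float]
    undefined: frozenset[str] = frozenset()

    def __getitem__(self, code: str) -> float:
        if code in self.undefined:
            raise UndefinedConditionalError(f"{code} is undefined")
        return self.values[code]

    def __contains__(self, code: str) -> bool:
        return code in self.values


def probability_set(scenario: Scenario) -> ProbabilitySet:
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for code in ALL_QUANTITY_CODES:
        try:
            values[code] = scenario.value(code)
        except UndefinedConditionalError:
            undefined.add(code)
    return ProbabilitySet(values=values, undefined=frozenset(undefined))


# --------------------------------------------------------------------------
# expected-frequency tree
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyTree:
    """Expected counts of the frequency tree (A = total, first split on A).

    B/C: counts with/without event A; D/E: A-branch split by B;
    F/G: ¬A-branch split by B.
    """

    A: int
    B: int
    C: int
    D: int
    E: int
    F: int
    G: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D, self.E, self.F, self.G) < 0:
            raise ScenarioError("frequency-tree counts must be non-negative")
        if self.B + self.C != self.A or self.D + self.E != self.B \
                or self.F + self.G != self.C:
            raise ScenarioError("frequency-tree additivity violated")

    def margin_count(self, atom: str) -> int:
        return {"A": self.B, "notA": self.C,
                "B": self.D + self.F, "notB": self.E + self.G}[atom]

    def cell_count(self, atom_a: str, atom_b: str) -> int:
        return {("A", "B"): self.D, ("A", "notB"): self.E,
                ("notA", "B"): self.F, ("notA", "notB"): self.G}[(atom_a, atom_b)]


def frequency_tree(scenario: Scenario) -> FrequencyTree:
    """Expected frequencies: rounded top-down, with lower levels closed by
    subtraction so the additivity invariants hold exactly.

    Each branch count is the rounded expected value (half away from zero);
    its sibling is the parent minus it, mirroring how the natural-frequency
    wording rounds 9,900 x 9.6% to 950.
    """
    n = scenario.population_n
    A = n
    B = min(round_half_away(scenario.margin("A") * n), n)
    C = A - B
    D = min(round_half_away(scenario.p11 * n), B)
    E = B - D
    F = min(round_half_away(scenario.p01 * n), C)
    G = C - F
    return FrequencyTree(A=A, B=B, C=C, D=D, E=E, F=F, G=G)


# --------------------------------------------------------------------------
# queries and answers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InferenceQuery:
    """One posed inference: a quantity, an answer format and a context."""

    quantity_code: str
    format: str
    context_id: str = ""

    def __post_init__(self) -> None:
        parse_quantity(self.quantity_code)  # validates
        if self.format not in FORMATS:
            raise ScenarioError(f"unknown format: {self.format!r}")

    @property
    def quantity(self) -> Quantity:
        return parse_quantity(self.quantity_code)

    @property
    def inference_class(self) -> str:
        return self.quantity.inference_class


@dataclass(frozen=True)
class Answer:
    """A response: a probability in [0,1] or an "x out of y" count pair."""

    format: str
    value: float | None = None
    numerator: int | None = None
    denominator: int | None = None

    def __post_init__(self) -> None:
        if self.format == PROBABILITY:
            if self.value is None or not (-_ATOL <= self.value <= 1.0 + _ATOL):
                raise ScenarioError(f"probability answer outside [0,1]: "
                                    f"{self.value!r}")
        elif self.format == NATURAL_FREQUENCY:
            if self.numerator is None or self.denominator is None:
                raise ScenarioError("frequency answer needs numerator and "
                                    "denominator")
            if self.numerator < 0 or self.denominator < 1:
                raise ScenarioError("frequency pair must be non-negative with "
                                    "denominator >= 1")
        else:
            raise ScenarioError(f"unknown format: {self.format!r}")

    @classmethod
    def probability(cls, p: float) -> "Answer":
        return cls(format=PROBABILITY, value=float(p))

    @classmethod
    def frequency(cls, numerator: int, denominator: int) -> "Answer":
        return cls(format=NATURAL_FREQUENCY, numerator=int(numerator),
                   denominator=int(denominator))

    @property
    def as_ratio(self) -> float:
        if self.format == PROBABILITY:
            return float(self.value)
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Value in percent rounded to one decimal (display convention)."""
        return format_percent(self.as_ratio)

    def __str__(self) -> str:
        if self.format == PROBABILITY:
            return f"{self.percent}%"
        return f"{self.numerator:,} out of {self.denominator:,}"


def answer_query(scenario: Scenario, query: InferenceQuery) -> Answer:
    """The correct answer to a query, in the query's format.

    Probability answers are exact cell/margin ratios.  Frequency answers
    pair the target-subset count with its conditioning-set count from the
    expected-frequency tree; marginal and conjoint queries condition on
    the whole population.
    """
    q = query.quantity
    if query.format == PROBABILITY:
        return Answer.probability(scenario.value(q))
    tree = frequency_tree(scenario)
    if q.kind == "marginal":
        return Answer.frequency(tree.margin_count(q.target[0]), tree.A)
    if q.kind == "conjoint":
        return Answer.frequency(tree.cell_count(*q.target), tree.A)
    # conditional / bayesian
    if scenario.margin(q.given) <= 0.0:
        raise UndefinedConditionalError(
            f"{q.code}: conditioning margin P({q.given}) is zero")
    t = q.target[0]
    if _EVENT_OF_ATOM[t] == "A":
        num = tree.cell_count(t, q.given)
    else:
        num = tree.cell_count(q.given, t)
    den = tree.margin_count(q.given)
    if den < 1:
        raise UndefinedConditionalError(
            f"{q.code}: conditioning count is zero at N={scenario.population_n}")
    return Answer.frequency(num, den)


# --------------------------------------------------------------------------
# the experimental design's query lists
# --------------------------------------------------------------------------

# Ten inferences per context: one probability- and one frequency-format
# query per non-Bayesian pair, and a 2/2 format split over the four
# inverted conditionals.  The base rates P(A)/P(notA) served as practice
# items and are not part of the design.
_DESIGN: tuple[tuple[str, str], ...] = (
    ("P(B)", PROBABILITY),
    ("P(notB)", NATURAL_FREQUENCY),
    ("P(A&B)", PROBABILITY),
    ("P(A&notB)", NATURAL_FREQUENCY),
    ("P(B|A)", NATURAL_FREQUENCY),
    ("P(notB|A)", PROBABILITY),
    ("P(A|B)", PROBABILITY),
    ("P(notA|B)", NATURAL_FREQUENCY),
    ("P(A|notB)", NATURAL_FREQUENCY),
    ("P(notA|notB)", PROBABILITY),
)


def enumerate_design_queries(
    context_id: str,
    known_contexts: Iterable[str] = ("mammography", "economics"),
) -> list[InferenceQuery]:
    """The ten inferences posed per context in the experimental design."""
    if context_id not in set(known_contexts):
        raise ScenarioError(f"unknown context: {context_id!r}")
    return [InferenceQuery(code, fmt, context_id) for code, fmt in _DESIGN]


# --------------------------------------------------------------------------
# serialization and packaged fixtures
# --------------------------------------------------------------------------


def scenario_from_dict(d: Mapping) -> Scenario:
    labels = d.get("labels", {})
    common = dict(
        context_id=d["context_id"],
        event_a_label=labels.get("event_a", "A"),
        event_b_label=labels.get("event_b", "B"),
        population_n=int(d["population_n"]),
    )
    if "cells" in d:
        p11, p10, p01, p00 = (float(x) for x in d["cells"])
        return Scenario(p11=p11, p10=p10, p01=p01, p00=p00, **common)
    if "branches" in d:
        base, hit, fa = (float(x) for x in d["branches"])
        return build_from_branches(
            base, hit, fa, common["population_n"],
            context_id=common["context_id"],
            event_a_label=common["event_a_label"],
            event_b_label=common["event_b_label"])
    raise ScenarioError("scenario dict needs 'cells' or 'branches'")


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "context_id": s.context_id,
        "labels": {"event_a": s.event_a_label, "event_b": s.event_b_label},
        "cells": [s.p11, s.p10, s.p01, s.p00],
        "population_n": s.population_n,
    }


def load_packaged_scenario(context_id: str) -> Scenario:
    """Load one of the shipped scenario fixtures by context id."""
    path = resources.files("bayesgaze.data").joinpath(f"{context_id}.json")
    try:
        payload = json.loads(path.read_text())
    except FileNotFoundError:
        raise ScenarioError(f"no packaged scenario {context_id!r}") from None
    return scenario_from_dict(payload)


def packaged_scenarios() -> dict[str, Scenario]:
    return {cid: load_packaged_scenario(cid)
            for cid in ("mammography", "economics")}
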