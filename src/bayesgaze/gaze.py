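"""AOI layouts, fixation assignment, gaze descriptives and heat maps.

Stimuli are a tree diagram (mammography context) or a 2x2 table (economics
context) on a 1280x1024 px canvas, with the requested inference shown in a
strip at the top.  Areas of interest (AOIs):

* tree with frequencies: 7 equal-sized node AOIs (counts A..G) + question;
* tree with probabilities: 7 equal-sized node-plus-branch AOIs (the branch
  carries the probability label) + question;
* 2x2 table (both formats): 4 inner cells, 4 event-label cells, 2 marginal
  cells and 1 total cell (11 equal-sized AOIs) + question.

Only one marginal distribution (the first-split event A) is displayed, so
inverted and non-inverted conditionals stay distinguishable.  Everything
outside the AOIs is "whitespace".  Rectangles are half-open
[x0, x1) x [y0, y1), origin top-left, y increasing downward, so boundary
ownership is deterministic.

The exact pixel geometry is parametric with documented defaults; all
semantics are carried by the AOI symbols, not by the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scenario import (
    NATURAL_FREQUENCY,
    PROBABILITY,
    InferenceQuery,
    ScenarioError,
)

__all__ = [
    "CanvasSpec",
    "AOI",
    "AOILayout",
    "FixationEvent",
    "Trial",
    "HeatMapGrid",
    "WHITESPACE",
    "QUESTION",
    "build_layout",
    "relevant_aois",
    "assign_fixations",
    "trial_scanpath",
    "aoi_indicators",
    "heatmap",
]

WHITESPACE = "whitespace"
QUESTION = "question"

TREE = "tree"
TABLE = "table"

TRIAL_TIME_LIMIT_MS = 30_000


@dataclass(frozen=True)
class CanvasSpec:
    width: int = 1280
    height: int = 1024

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")


@dataclass(frozen=True)
class AOI:
    aoi_id: str
    role: str  # node | node_plus_branch | cell | event_label_cell |
               # marginal_cell | total_cell | question
    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1), half-open
    symbol: str | None = None

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return x0 <= x < x1 and y0 <= y < y1

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.rect
        return (x0 + x1) / 2.0, (y0 + y1) / 2.0

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)


@dataclass(frozen=True)
class AOILayout:
    visualization: str
    format: str
    canvas: CanvasSpec
    aois: tuple[AOI, ...]

    @property
    def symbol_map(self) -> dict[str, str]:
        return {a.aoi_id: a.symbol for a in self.aois if a.symbol is not None}

    def aoi(self, aoi_id: str) -> AOI:
        for a in self.aois:
            if a.aoi_id == aoi_id:
                return a
        raise KeyError(aoi_id)

    def locate(self, x: float, y: float) -> str:
        """AOI owning (x, y), or whitespace (also for off-canvas points)."""
        if not (0 <= x < self.canvas.width and 0 <= y < self.canvas.height):
            return WHITESPACE
        for a in self.aois:
            if a.contains(x, y):
                return a.aoi_id
        return WHITESPACE

    @property
    def reading_order(self) -> list[str]:
        """AOI ids sorted top-to-bottom, then left-to-right."""
        return [a.aoi_id for a in
                sorted(self.aois, key=lambda a: (a.rect[1], a.rect[0]))]


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: onset (ms from trial start), duration (ms), position."""

    t_start: float
    duration: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")
        if self.t_start < 0:
            raise ValueError("fixation onset must be non-negative")
        if self.t_start + self.duration > TRIAL_TIME_LIMIT_MS:
            raise ValueError("fixation exceeds the 30 s trial time limit")


@dataclass(frozen=True)
class Trial:
    """One participant x inference: a time-ordered fixation sequence."""

    participant_id: str
    query: InferenceQuery
    visualization: str
    fixations: tuple[FixationEvent, ...]
    answer: object | None = None

    def __post_init__(self) -> None:
        prev_end = -1.0
        for f in self.fixations:
            if f.t_start < prev_end:
                raise ValueError("fixations must be time-ordered and "
                                 "non-overlapping")
            prev_end = f.t_start + f.duration

    @property
    def total_fixation_ms(self) -> float:
        return sum(f.duration for f in self.fixations)


# --------------------------------------------------------------------------
# layout construction
# --------------------------------------------------------------------------


def build_layout(
    visualization: str,
    fmt: str,
    canvas: CanvasSpec | None = None,
) -> AOILayout:
    """Default parametric AOI layout for a stimulus variant."""
    canvas = canvas or CanvasSpec()
    if fmt not in (PROBABILITY, NATURAL_FREQUENCY):
        raise ScenarioError(f"unknown format: {fmt!r}")
    if visualization == TREE:
        aois = _tree_aois(fmt, canvas)
    elif visualization == TABLE:
        aois = _table_aois(fmt, canvas)
    else:
        raise ScenarioError(f"unknown visualization: {visualization!r}")
    return AOILayout(visualization=visualization, format=fmt,
                     canvas=canvas, aois=tuple(aois))


def _question_aoi(canvas: CanvasSpec) -> AOI:
    # full-width strip at the top; deliberately larger than any other AOI
    return AOI(QUESTION, "question",
               (canvas.width * 0.03, canvas.height * 0.02,
                canvas.width * 0.97, canvas.height * 0.16), symbol="q")


def _tree_aois(fmt: str, canvas: CanvasSpec) -> list[AOI]:
    w, h = canvas.width, canvas.height
    node_w = w * 0.14
    # node-plus-branch AOIs stretch upward to cover the incoming branch
    # label (probability trees put the number on the branch)
    node_h = h * 0.09 if fmt == NATURAL_FREQUENCY else h * 0.15
    role = "node" if fmt == NATURAL_FREQUENCY else "node_plus_branch"
    centers = {
        "A": (0.50, 0.26),
        "B": (0.30, 0.50), "C": (0.70, 0.50),
        "D": (0.16, 0.78), "E": (0.40, 0.78),
        "F": (0.62, 0.78), "G": (0.86, 0.78),
    }
    # symbols: counts A..G on the frequency tree; on the probability tree
    # each non-root AOI carries its incoming-branch probability b..g
    prob_symbols = {"A": "root", "B": "b", "C": "c",
                    "D": "d", "E": "e", "F": "f", "G": "g"}
    aois = [_question_aoi(canvas)]
    for aoi_id, (cx, cy) in centers.items():
        x0 = cx * w - node_w / 2
        y0 = cy * h - node_h / 2
        sym = aoi_id if fmt == NATURAL_FREQUENCY else prob_symbols[aoi_id]
        aois.append(AOI(aoi_id, role, (x0, y0, x0 + node_w, y0 + node_h),
                        symbol=sym))
    return aois


def _table_aois(fmt: str, canvas: CanvasSpec) -> list[AOI]:
    w, h = canvas.width, canvas.height
    cell_w = w * 0.17
    cell_h = h * 0.15
    x_origin = w * 0.14
    y_origin = h * 0.24
    # grid: row 0 = column labels (event B), rows 1-2 = event-A rows with
    # label, two conjoint cells and the displayed (A) marginal; row 3 =
    # grand total bottom-right.  Only the A margin is displayed.
    freq_symbols = {"cell_AB": "D", "cell_AnotB": "E",
                    "cell_notAB": "F", "cell_notAnotB": "G",
                    "margin_A": "B", "margin_notA": "C", "total": "A"}
    prob_symbols = {"cell_AB": "h", "cell_AnotB": "i",
                    "cell_notAB": "j", "cell_notAnotB": "k",
                    "margin_A": "b", "margin_notA": "c", "total": "total"}
    symbols = freq_symbols if fmt == NATURAL_FREQUENCY else prob_symbols
    grid = {
        "label_B": (1, 0, "event_label_cell"),
        "label_notB": (2, 0, "event_label_cell"),
        "label_A": (0, 1, "event_label_cell"),
        "cell_AB": (1, 1, "cell"),
        "cell_AnotB": (2, 1, "cell"),
        "margin_A": (3, 1, "marginal_cell"),
        "label_notA": (0, 2, "event_label_cell"),
        "cell_notAB": (1, 2, "cell"),
        "cell_notAnotB": (2, 2, "cell"),
        "margin_notA": (3, 2, "marginal_cell"),
        "total": (3, 3, "total_cell"),
    }
    # shared edge arrays keep adjacent rectangles exactly edge-to-edge,
    # which the half-open convention then resolves deterministically
    x_edges = [x_origin + k * cell_w for k in range(5)]
    y_edges = [y_origin + k * cell_h for k in range(5)]
    aois = [_question_aoi(canvas)]
    for aoi_id, (col, row, role) in grid.items():
        aois.append(AOI(aoi_id, role,
                        (x_edges[col], y_edges[row],
                         x_edges[col + 1], y_edges[row + 1]),
                        symbol=symbols.get(aoi_id)))
    return aois


# --------------------------------------------------------------------------
# relevant AOIs per query
# --------------------------------------------------------------------------

_TREE_NODE_OF_CELL = {("A", "B"): "D", ("A", "notB"): "E",
                      ("notA", "B"): "F", ("notA", "notB"): "G"}
_TREE_NODE_OF_MARGIN = {"A": "B", "notA": "C"}
_TABLE_CELL = {("A", "B"): "cell_AB", ("A", "notB"): "cell_AnotB",
               ("notA", "B"): "cell_notAB", ("notA", "notB"): "cell_notAnotB"}
_TABLE_MARGIN = {"A": "margin_A", "notA": "margin_notA"}


def _cell_key(target: str, given: str) -> tuple[str, str]:
    return (target, given) if target in ("A", "notA") else (given, target)


def relevant_aois(query: InferenceQuery, layout: AOILayout) -> set[str]:
    """AOIs whose symbols appear in the correct-solution formula.

    For frequency answers the reference-set AOI (total count) is included
    where the denominator is the whole population.
    """
    q = query.quantity
    vis, fmt = layout.visualization, layout.format
    if vis == TREE:
        return _tree_relevant(q, fmt)
    return _table_relevant(q, fmt)


def _tree_relevant(q, fmt: str) -> set[str]:
    if fmt == NATURAL_FREQUENCY:
        if q.kind == "marginal":
            a = q.target[0]
            if a in ("A", "notA"):
                return {_TREE_NODE_OF_MARGIN[a], "A"}
            # B-event margin: sum of two leaves over the total
            leaves = {_TREE_NODE_OF_CELL[(x, a)] for x in ("A", "notA")}
            return leaves | {"A"}
        if q.kind == "conjoint":
            return {_TREE_NODE_OF_CELL[q.target], "A"}
        if q.kind == "conditional":
            return {_TREE_NODE_OF_CELL[_cell_key(q.target[0], q.given)],
                    _TREE_NODE_OF_MARGIN[q.given]}
        # bayesian: target leaf out of the two leaves of the conditioning
        # column
        return {_TREE_NODE_OF_CELL[(x, q.given)] for x in ("A", "notA")}
    # probability tree: branch products
    if q.kind == "marginal":
        a = q.target[0]
        if a in ("A", "notA"):
            return {_TREE_NODE_OF_MARGIN[a]}
        return {_TREE_NODE_OF_MARGIN[x] for x in ("A", "notA")} | \
               {_TREE_NODE_OF_CELL[(x, a)] for x in ("A", "notA")}
    if q.kind == "conjoint":
        a, b = q.target
        return {_TREE_NODE_OF_MARGIN[a], _TREE_NODE_OF_CELL[(a, b)]}
    if q.kind == "conditional":
        # readable directly from the branch label
        return {_TREE_NODE_OF_CELL[_cell_key(q.target[0], q.given)]}
    # bayesian, Bayes' rule over all four symbols of the rule
    return {_TREE_NODE_OF_MARGIN[x] for x in ("A", "notA")} | \
           {_TREE_NODE_OF_CELL[(x, q.given)] for x in ("A", "notA")}


def _table_relevant(q, fmt: str) -> set[str]:
    freq = fmt == NATURAL_FREQUENCY
    if q.kind == "marginal":
        a = q.target[0]
        if a in ("A", "notA"):
            return {_TABLE_MARGIN[a]} | ({"total"} if freq else set())
        cells = {_TABLE_CELL[(x, a)] for x in ("A", "notA")}
        return cells | ({"total"} if freq else set())
    if q.kind == "conjoint":
        return {_TABLE_CELL[q.target]} | ({"total"} if freq else set())
    if q.kind == "conditional":
        return {_TABLE_CELL[_cell_key(q.target[0], q.given)],
                _TABLE_MARGIN[q.given]}
    return {_TABLE_CELL[(x, q.given)] for x in ("A", "notA")}


# --------------------------------------------------------------------------
# fixation assignment and descriptives
# --------------------------------------------------------------------------


def assign_fixations(
    trial: Trial, layout: AOILayout,
) -> list[tuple[FixationEvent, str]]:
    """Label each fixation with the AOI owning its position."""
    return [(f, layout.locate(f.x, f.y)) for f in trial.fixations]


def trial_scanpath(labeled: Sequence[tuple[FixationEvent, str]]) -> list[str]:
    """Collapse consecutive same-AOI fixations into a scan-path sequence."""
    path: list[str] = []
    for _, aoi_id in labeled:
        if not path or path[-1] != aoi_id:
            path.append(aoi_id)
    return path


def aoi_indicators(
    trials: Sequence[Trial],
    layout: AOILayout,
    *,
    per_trial_pct: bool = False,
) -> pd.DataFrame:
    """Gaze performance indicators per AOI across a set of trials.

    Columns: ``order_in_sequence`` (mean 1-based rank of the AOI's first
    appearance in the collapsed scan path, over trials that visited it;
    NaN if never visited), ``dwell_time_s``, ``dwell_time_pct`` (pooled
    over trials by default; per-trial averaged when ``per_trial_pct``),
    ``fixation_count`` and ``hit_ratio`` (fraction of trials with at least
    one fixation in the AOI).  A ``whitespace`` row closes the dwell-time
    budget to 100%.
    """
    if not trials:
        raise ValueError("aoi_indicators needs at least one trial")
    ids = [a.aoi_id for a in layout.aois] + [WHITESPACE]
    dwell = {i: 0.0 for i in ids}
    count = {i: 0 for i in ids}
    hits = {i: 0 for i in ids}
    ranks: dict[str, list[int]] = {i: [] for i in ids}
    trial_pcts: dict[str, list[float]] = {i: [] for i in ids}

    total_time = 0.0
    for trial in trials:
        labeled = assign_fixations(trial, layout)
        t_dwell = {i: 0.0 for i in ids}
        for f, aoi_id in labeled:
            t_dwell[aoi_id] += f.duration
            count[aoi_id] += 1
        t_total = sum(t_dwell.values())
        total_time += t_total
        for i in ids:
            dwell[i] += t_dwell[i]
            if t_dwell[i] > 0:
                hits[i] += 1
            if t_total > 0:
                trial_pcts[i].append(100.0 * t_dwell[i] / t_total)
        # first-visit rank per AOI in this trial's collapsed path
        seen: set[str] = set()
        for rank, aoi_id in enumerate(trial_scanpath(labeled), start=1):
            if aoi_id not in seen:
                seen.add(aoi_id)
                ranks[aoi_id].append(rank)

    rows = []
    for i in ids:
        if per_trial_pct:
            pct = float(np.mean(trial_pcts[i])) if trial_pcts[i] else 0.0
        else:
            pct = 100.0 * dwell[i] / total_time if total_time > 0 else 0.0
        rows.append({
            "aoi_id": i,
            "order_in_sequence": float(np.mean(ranks[i])) if ranks[i]
                                 else np.nan,
            "dwell_time_s": dwell[i] / 1000.0,
            "dwell_time_pct": pct,
            "fixation_count": count[i],
            "hit_ratio": hits[i] / len(trials),
        })
    return pd.DataFrame(rows).set_index("aoi_id")


# --------------------------------------------------------------------------
# heat maps
# --------------------------------------------------------------------------


@dataclass
class HeatMapGrid:
    """Duration-weighted Gaussian aggregation of fixations on a grid."""

    values: np.ndarray  # shape (ny, nx)
    grid_step: int
    sigma: float
    canvas: CanvasSpec

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "HeatMapGrid":
        peak = self.values.max()
        vals = self.values / peak if peak > 0 else self.values.copy()
        return HeatMapGrid(vals, self.grid_step, self.sigma, self.canvas)

    def __add__(self, other: "HeatMapGrid") -> "HeatMapGrid":
        if self.values.shape != other.values.shape:
            raise ValueError("heat-map grids have different shapes")
        return HeatMapGrid(self.values + other.values, self.grid_step,
                           self.sigma, self.canvas)


def heatmap(
    trials: Sequence[Trial],
    canvas: CanvasSpec | None = None,
    grid_step: int = 4,
    sigma: float = 30.0,
    *,
    normalize: bool = False,
) -> HeatMapGrid:
    """Aggregate fixations into a heat map.

    Each fixation deposits a 2-D Gaussian kernel centred on its position,
    weighted by its duration (ms); the kernel is renormalized over its
    (canvas-clipped) support so the unnormalized grid mass equals the
    summed fixation durations exactly.
    """
    canvas = canvas or CanvasSpec()
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if grid_step < 1:
        raise ValueError("grid_step must be >= 1 px")
    nx = canvas.width // grid_step
    ny = canvas.height // grid_step
    grid = np.zeros((ny, nx))
    half = max(int(np.ceil(4 * sigma / grid_step)), 1)
    for trial in trials:
        for f in trial.fixations:
            cx = min(max(int(f.x // grid_step), 0), nx - 1)
            cy = min(max(int(f.y // grid_step), 0), ny - 1)
            x0, x1 = max(cx - half, 0), min(cx + half + 1, nx)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, ny)
            xs = (np.arange(x0, x1) + 0.5) * grid_step
            ys = (np.arange(y0, y1) + 0.5) * grid_step
            kx = np.exp(-0.5 * ((xs - f.x) / sigma) ** 2)
            ky = np.exp(-0.5 * ((ys - f.y) / sigma) ** 2)
            kernel = np.outer(ky, kx)
            kernel *= f.duration / kernel.sum()
            grid[y0:y1, x0:x1] += kernel
    hm = HeatMapGrid(grid, grid_step, sigma, canvas)
    return hm.normalized() if normalize else hm
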