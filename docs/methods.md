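# Methods

## Scenario model

A scenario is the joint distribution of two binary events A and B given by
four conjoint cells (p11, p10, p01, p00) summing to 1, plus an integer
reference population N ≥ 1. Scenarios can be built directly from cells or
from the branch parameterization (prevalence, sensitivity, false-alarm
rate); the two routes are mutually inverse up to 1e-12. Two fixtures ship
with the package:

* **mammography** — branches (1%, 80%, 9.6%), N = 10,000; cells
  (0.008, 0.002, 0.09504, 0.89496).
* **economics** — cells (0.20, 0.05, 0.30, 0.45), N = 1,000. The cells are
  reconstructed from the published summary values (conjoints 20% and 5%,
  cell 45%, counts 300 and 200 of 1,000) with the fourth cell fixed by
  normalization.

Conventions: the tree's first split is on A; conditioning on A/¬A is a
*conditional* inference, conditioning on B/¬B is *bayesian* (inverted).
Quantity codes use a compact grammar (`P(A|B)`, `P(notA&notB)`, …) with
conjoints canonicalized A-event-first.

**Expected-frequency tree.** Counts are expected frequencies rounded half
away from zero, computed top-down with each sibling closed by subtraction
(C = A−B, E = B−D, G = C−F) so the additivity invariants hold exactly even
when the expectation is fractional (9,900 × 9.6% = 950.4 → F = 950,
G = 8,950). D and F are clamped to their parents so degenerate populations
(N = 1) stay consistent.

**Undefined conditionals.** A conditional whose conditioning margin is
exactly zero raises a typed `UndefinedConditionalError` rather than
returning NaN; silent propagation would corrupt downstream strategy
classification. `probability_set` lists such codes in a separate
`undefined` set.

**Display rounding.** Probabilities are reported at one decimal of a
percent (half away from zero); full precision is kept internally. The
mammography negative-direction posterior is exactly 99.777…%, reported as
99.8%.

## Design enumeration

Each context poses 10 inferences: 2 marginal, 2 conjoint, 2 conditional
and all 4 inverted conditionals, with each non-Bayesian pair split one
probability / one frequency and the Bayesian four split 2/2, giving 5/5
formats per block. The base rates P(A)/P(¬A) are practice items and not
part of the design. The fixed format assignment follows the published
per-question answers (e.g. P(B) in probability format, P(¬B) in
frequency). One deliberate choice: the published economics conditional is
reported against an inconsistent target value; the only quantity
consistent with every other published number is P(¬B|A), which is what the
design list uses (see the design-decision list below).

## Strategy engine

Strategies are structural rules over the roles of a Bayesian query P(X|Y):
target cell X∩Y, conditioning margin Y, inverse conditional P(Y|X). This
generalizes the canonical-catalog formulas to all four Bayesian queries
and both contexts. Applicability: pre-Bayes exists only in frequency
format; likelihood subtraction/addition and the CPR/FPR ratio only in
probability format. The ratio is capped at 1 for probability output;
likelihood subtraction is floored at 0. `likelihood_addition` defaults to
adding the two conditionals P(Y|X)+P(Y|¬X) — the variant that reproduces
the characteristic 80% + 9.6% = 89.6% answers — with a conjoint-addition
mode available behind `likelihood_addition_mode="conjoint"` (which
coincides with evidence-only).

**Candidate space.** For a query the classifier considers: every
applicable composite strategy; quantity confusions over the other 15
quantities (in frequency format each conditional additionally offered with
the whole population as denominator, covering reference-class errors like
"20 out of 100" vs "20 out of 10,000"); and, when enabled, misread
variants — each strategy applied to the query with the target, the
conditioning event, or both negated, modeling an overlooked negation.
Identical predictions are collapsed into one candidate with merged labels.

**Matching.** A probability answer matches a prediction if both round to
the same integer percent *or* differ by ≤ 0.5 percentage points; this
operationalizes a "one percent interval" that accepts 7–8% for a correct
7.8%. Frequency answers match by exact pair by default;
`ratio_equivalent` mode also accepts reduced ratios and flags them.
Assignment prefers exact matches, then minimal distance, with ties broken
by a priority order that follows the observed frequency of the errors
(correct, Fisherian, joint occurrence, evidence-only, …). An answer
matched by more than one distinct non-misread strategy (or by disjoint
misread-only candidates) is flagged `ambiguous`; `separability_report`
enumerates the colliding pairs per query — e.g. Fisherian (90.4%) and
evidence-only (89.7%) both round to 90% on the mammography
negative-direction question — so such answers are never silently uniquely
attributed. `misread_flag` is set only when *no* non-misread candidate
matches.

## AOI layouts and gaze descriptives

Layouts are parametric on a 1280×1024 canvas (the experiment's screen
resolution). The published AOI *counts* and roles are fixed — tree: 7
equal-sized node AOIs (node-plus-branch for probability trees) plus a
larger question strip, 8 in total; table: 4 conjoint cells, 4 event-label
cells, 2 marginal cells (only the first-split margin is displayed) and 1
total cell, 11 equal-sized AOIs plus the question, 12 in total — but the
exact pixel geometry is not published, so the defaults here are the
package's own (question strip across the top; tree levels at 26/50/78% of
canvas height; table grid from shared edge arrays). All semantics ride on
the AOI symbol map, not on the geometry.

Rectangles are half-open [x0,x1)×[y0,y1), origin top-left: boundary
fixations have a deterministic owner. Fixations off-canvas or outside
every AOI are whitespace.

`relevant_aois` returns the AOIs whose symbols appear in the correct
solution's formula for the query, per visualization and format (frequency
answers include the reference-set AOI when the denominator is the whole
population; conditional probabilities on the probability tree are a
single branch read). Indicators per AOI: order in sequence (mean 1-based
rank of first appearance in the collapsed scan path over trials that
visited the AOI; missing if never visited), dwell time in seconds and
percent, fixation count, hit ratio. Dwell percentages are pooled over
trials by default (per-trial averaging available via `per_trial_pct`);
pooled was chosen because it weights trials by looking time and keeps the
whitespace-closed budget exactly 100%.

Heat maps deposit one 2-D Gaussian per fixation (default grid step 4 px,
σ = 30 px), weighted by duration and renormalized over the canvas-clipped
kernel support, so the unnormalized grid mass equals the summed fixation
durations exactly and grids are summable across participants and strata.

## Synthetic cohort

The simulator reproduces the experimental design: 24 participants; a
fixed block order (tree/mammography then table/economics, matching the
original procedure); within each block the six non-Bayesian inferences in
random order followed by the four Bayesian ones in random order; 30 s
trial cap. 24 × 20 = 480 trials, 192 of them Bayesian.

Each trial draws a latent strategy from a mixture per (inference class,
format). Defaults place most non-Bayesian error mass on structurally
adjacent quantity confusions and most Bayesian error mass on joint
occurrence and the Fisherian confusion, heavier in probability format —
qualitatively mirroring the observed error pattern; they are simulator
settings, not estimates of any real cohort. Answers are the strategy's
prediction (probability answers rounded to one decimal of a percent by
default, mimicking spoken responses; integer-percent mode available), or
with probability `answer_noise` a uniform draw from other quantities'
answers.

The gaze generator has four phases: initial fixations on the question
strip; an orientation sweep over the stimulus in reading order
(top-to-bottom, left-to-right); an execution phase whose AOI choice is
weighted 4:1 toward the AOIs referenced by the *latent strategy's* formula
(positions jittered N(0, 28 px) around AOI centres, so some fixations land
on whitespace); and question revisits with probability 0.12 per execution
fixation, boosted 2.5× for Bayesian queries. Durations are lognormal
(median 260 ms, σ_log = 0.45), truncated at the 30 s cap. Distributions
of fixation counts and durations are not published; these defaults are
synthetic stand-ins chosen to give plausible trial lengths (~10–15 s) and
they are exactly what the relevant-vs-irrelevant dwell property tests
verify — passing tests show the analytics recover what the generator
encodes, not that real gaze behaves this way.

Randomness: one master seed spawns independent per-participant
substreams (`numpy` `SeedSequence`), so participant-level results are
order-independent and the full pipeline is byte-identical across runs
with the same seed.

## Pipeline

`load_dataset` validates answer/fixation CSVs against the documented
dialects and reports schema violations with row numbers. `run_report`
classifies every answered trial, then computes solution rates by
visualization × format × inference class, an error tally by strategy with
an established-errors subtotal, AOI indicator tables per (context, query,
format), and heat maps stratified by classification outcome
(correct/incorrect), whose per-stratum trial counts partition the cohort.
Everything is deterministic given inputs; outputs are diffable CSV/JSON
plus grayscale PNGs.

## Design decisions where the ground truth is open

* The economics conditional inference is implemented as P(¬B|A): the
  published target value for that item is inconsistent with every joint
  distribution satisfying the other published numbers, while P(¬B|A)
  matches it exactly. The fixture query list uses P(¬B|A); nothing else is
  silently corrected.
* The published conjoint reference-class error quotes a denominator of
  1,000 where the situation's population is 10,000; since the intent is
  undecidable, the classifier generates both denominators as candidates.
* The CPR/FPR frequency form can exceed 1 and has no published output
  convention; the strategy is treated as probability-only and capped at 1.
* The two-decimal print "99.80%" for the negative-direction mammography
  posterior is not reproducible from the exact value (99.777…% → 99.78);
  the package reports the one-decimal 99.8%, which matches every other
  occurrence of that quantity.

## Problem sizes and runtime

The packaged analyses are desk-scale: one simulated cohort (480 trials,
~13k fixations) generates in well under a second, and a full report with
heat maps takes a few seconds. The mixture-recovery check simulates 20
cohorts (20 × 192 Bayesian trials). Acceptance-script targets are exact
closed-form computations.

## Known limitations

* Fixation-level input only: no raw-sample parsing, saccade detection,
  calibration or vendor file formats.
* The gaze generator does not model oculomotor dynamics, learning across
  blocks, or inter-participant variability beyond seeded randomness.
* Gaze evidence is reported as metadata (indicator tables, heat maps,
  separability flags) and is not fused into the answer-based strategy
  label automatically.
* Classification is only as identifiable as the scenario allows; for
  near-colliding predictions the honest output is an ambiguous flag, not
  a forced unique label.
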