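# bayesgaze

Tools for studying how people reason about statistical situations with two
binary events — a disease and a diagnostic test result, a course choice and
a personality trait — when the situation is shown as a **tree diagram** or a
**2×2 table**, with either **probabilities** or **natural frequencies**.

The package is aimed at researchers in statistics education and cognitive
psychology who want to (1) derive every quantity such a situation defines,
(2) predict what answers common *erroneous* Bayesian reasoning strategies
produce and classify observed answers against them, (3) compute AOI-based
eye-tracking descriptives (dwell time, fixation counts, hit ratios, scan
paths, heat maps), and (4) simulate a complete experimental cohort —
answers *and* fixation sequences driven by latent strategies — so every
stage of the analysis is testable without access to participant data.

## The model

A scenario is a joint distribution over two binary events A and B plus a
reference population of size N. With prevalence P(A), sensitivity P(B|A)
and false-alarm rate P(B|¬A), the four conjoint cells follow, and from them
all 16 quantities: 4 marginals, 4 conjoints and 8 conditionals. A
conditional that conditions on A or ¬A can be read along the tree that
first splits on A; conditioning on B or ¬B runs against the tree and
requires Bayes' rule,

    P(A|B) = P(B|A)·P(A) / (P(B|A)·P(A) + P(B|¬A)·P(¬A)),

which is why those four inverted conditionals are the notoriously hard
"Bayesian" questions. In natural-frequency form the same answer is a pair
of counts from the expected-frequency tree ("D out of D+F").

The error-strategy catalog maps each documented mistake — joint occurrence,
Fisherian (inverse-conditional) confusion, likelihood subtraction/addition,
base-rate only, evidence only, pre-Bayes, correct-positive/false-positive
ratio, quantity confusions and negation misreadings — to a structural rule
over the same cells and margins, so predictions generalize to all four
Bayesian queries in both formats.

## Worked example

```python
from bayesgaze import (build_from_branches, answer_query, frequency_tree,
                       InferenceQuery, Strategy, predict_answer,
                       classify_answer, Answer)

mam = build_from_branches(0.01, 0.80, 0.096, 10_000,
                          context_id="mammography")

print(frequency_tree(mam))
print(answer_query(mam, InferenceQuery("P(A|B)", "probability", "mammography")))
print(answer_query(mam, InferenceQuery("P(A|B)", "natural_frequency", "mammography")))
print(predict_answer(Strategy("fisherian"), mam,
                     InferenceQuery("P(notA|notB)", "probability", "mammography")))
print(classify_answer(Answer.frequency(950, 10_000), mam,
                      InferenceQuery("P(notA|B)", "natural_frequency",
                                     "mammography")).assigned)
```

prints

```
FrequencyTree(A=10000, B=100, C=9900, D=80, E=20, F=950, G=8950)
7.8%
80 out of 1,030
90.4%
joint_occurrence
```

Reading: in a population of 10,000 women, 100 have the disease, of whom 80
test positive; 950 of the 9,900 healthy women also test positive. The
probability of disease given a positive test is therefore 80/(80+950) =
7.8% — "80 out of 1,030". A participant who answers the negative-direction
question with 90.4% has simply read off the inverse conditional P(¬B|¬A)
(the Fisherian error); one who answers "950 out of 10,000" reports the
conjoint count over the whole population (joint occurrence).

## Command line

```
bayesgaze simulate --seed 1 --out-dir runs/sim          # synthetic cohort
bayesgaze classify --answers runs/sim/answers.csv \
                   --fixations runs/sim/fixations.csv --out-dir runs/cls
bayesgaze gaze-metrics --fixations runs/sim/fixations.csv --out-dir runs/gm
bayesgaze heatmap --fixations runs/sim/fixations.csv --out-dir runs/hm
bayesgaze report --answers runs/sim/answers.csv \
                 --fixations runs/sim/fixations.csv --out-dir runs/report
```

`simulate` emulates the full design — 24 participants, a tree-diagram
block (mammography context) then a 2×2-table block (economics context),
ten inferences each with a 30 s cap — and writes answer, fixation and
latent-truth CSV logs. `report` produces solution-rate tables by
visualization × format × inference type, an error tally by strategy, AOI
indicator tables per query and correctness-stratified heat maps.

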