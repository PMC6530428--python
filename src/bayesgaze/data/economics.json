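{
  "context_id": "economics",
  "labels": {"event_a": "attends the economics course", "event_b": "career-oriented"},
  "cells": [0.20, 0.05, 0.30, 0.45],
  "population_n": 1000
}
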