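#!/usr/bin/env python
"""Simulate the synthetic multi-school cohort and persist the traces.

Generates the default study design at a desk scale of 5 schools x 60
students x 20 sequenced cases, writes the full trace stream (bulky,
scratch/) plus the ground-truth generating parameters (results/), and
prints what was produced.
"""

from pathlib import Path
import json
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH, SEED  # noqa: E402

from vpdx.cohort import SimConfig, iter_study
from vpdx.model import write_traces

cfg = SimConfig(seed=SEED, n_schools=5, n_students_per_school=60, n_cases=20)
traces_path = SCRATCH / "traces.jsonl"
n = write_traces(iter_study(cfg), traces_path)
(RESULTS / "truth.json").write_text(json.dumps(cfg.for_cohort().truth(), indent=2) + "\n")
(SCRATCH / "sim_config.json").write_text(cfg.model_dump_json(indent=2) + "\n")

print(f"simulated {n} traces ({cfg.n_schools} schools x "
      f"{cfg.n_students_per_school} students x {cfg.n_cases} cases)")
print(f"traces  -> {traces_path}")
print(f"truth   -> {RESULTS / 'truth.json'}")
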