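#!/usr/bin/env python
"""Score the simulated trace stream against the expert scorecards.

Reads scratch/traces.jsonl, scores every trace (component percents,
penalties, navigation metrics, cognitive-error flags), writes the long
cohort table to scratch/ and a compact per-sequence summary to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH  # noqa: E402

from vpdx.cases import make_case_library
from vpdx.model import read_traces, scores_to_frame, write_cohort
from vpdx.scoring import score_stream

traces_path = SCRATCH / "traces.jsonl"
if not traces_path.exists():
    sys.exit("run 01_simulate_cohort.py first (no scratch/traces.jsonl)")

traces = list(read_traces(traces_path))
cases, cards = make_case_library(20)
scores = score_stream(traces, cases, cards)
df = scores_to_frame(scores)
write_cohort(df, SCRATCH / "scores.csv")

summary = (
    df.assign(misdiagnosed=1 - df["correct"].astype(int))
    .groupby("sequence_index")[
        ["ddx_pct", "dxj_pct", "inv_pct", "error_count", "misdiagnosed",
         "n_tests", "n_rounds", "total_penalty_points"]
    ]
    .mean()
    .round(3)
)
summary.to_csv(RESULTS / "sequence_means.csv")

print(f"scored {len(df)} traces -> {SCRATCH / 'scores.csv'}")
print(f"misdiagnosis rate overall: {1 - df['correct'].mean():.3f}")
print("first vs last case means:")
print(summary.loc[[1, 20]].to_string())
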