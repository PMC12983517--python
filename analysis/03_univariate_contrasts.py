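#!/usr/bin/env python
"""Correct-vs-misdiagnosed univariate contrasts over the score table.

Produces the bivariate table: group means/SDs, percent differences, and
Wilcoxon/t p-values per score-table variable.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH, SEED  # noqa: E402

from vpdx import analysis as an
from vpdx.model import read_cohort

scores_path = SCRATCH / "scores.csv"
if not scores_path.exists():
    sys.exit("run 02_score_cases.py first (no scratch/scores.csv)")

df = read_cohort(scores_path)
tab = an.compare_groups(df, seed=SEED)
tab.to_csv(RESULTS / "table_univariate.csv", index=False, float_format="%.6g")

print(f"{len(tab)} variables contrasted -> {RESULTS / 'table_univariate.csv'}")
show = tab.set_index("variable").loc[
    ["dxj_pct", "inv_pct", "ddx_pct", "error_count", "time_history"],
    ["mean_correct", "mean_incorrect", "percent_difference", "test", "p_value"],
]
print(show.round(3).to_string())
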