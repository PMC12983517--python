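#!/usr/bin/env python
"""Mixed-effects learning curves across the 20-case sequence.

Fits per-metric generalized mixed models (random student intercept,
log-sequence fixed trend) for Ddx, DxJ, test ordering, error counts and
diagnostic accuracy, and writes the fitted trend table and figure.
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
curves = an.fit_learning_curves(df)
an.render_report({"curves": curves}, RESULTS, seed=SEED)

for metric, c in curves.items():
    t = c.trend
    print(
        f"{metric:12s} ({c.family:8s}) fitted {t['fitted'].iloc[0]:7.3f} -> "
        f"{t['fitted'].iloc[-1]:7.3f}   empirical {t['empirical_mean'].iloc[0]:7.3f} -> "
        f"{t['empirical_mean'].iloc[-1]:7.3f}"
    )
print(f"trend table + figure -> {RESULTS}")
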