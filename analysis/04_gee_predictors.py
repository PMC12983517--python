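#!/usr/bin/env python
"""Clustered GEE: which reasoning components predict a correct diagnosis.

Marginal logistic regression of correctness on the component point
scores and error counts, clustered by student with an AR(1) working
correlation over the case sequence and school as a fixed covariate.
Positive estimates predict correct diagnoses.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH, SEED  # noqa: E402

from vpdx import analysis as an
from vpdx.model import read_cohort

scores_path = SCRATCH / "scores.csv"
if not scores_path.exists():
    sys.exit("run 02_score_cases.py first (no scratch/scores.csv)")

df = read_cohort(scores_path)
res = an.fit_gee(df)
tab = pd.DataFrame(
    {"estimate": res.estimates, "robust_se": res.std_errors, "p": res.p_values}
).rename_axis("term").reset_index()
tab.to_csv(RESULTS / "table_gee.csv", index=False, float_format="%.6g")
an.render_report({"gee": res}, RESULTS, seed=SEED)

print(f"GEE ({res.working_correlation}; clusters={res.cluster}, "
      f"n={res.n_obs} obs / {res.n_clusters} students)")
print(tab[tab["term"].isin(an.DEFAULT_PREDICTORS)].round(3).to_string(index=False))
print(f"tables/figures -> {RESULTS}")
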