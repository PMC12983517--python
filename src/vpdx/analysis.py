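"""Clustered longitudinal analysis of a cohort score table.

Four stages, mirroring the study design of a multi-school repeated-cases
curriculum:

1. :func:`compare_groups` — univariate correct-vs-misdiagnosed contrasts
   per score-table variable, Wilcoxon rank-sum for non-normal variables
   and t-tests for normal ones (Shapiro-Wilk on a capped subsample
   decides), with percent differences.
2. :func:`fit_gee` — a marginal logistic model of correctness on the CR
   component scores via generalized estimating equations: clusters are
   students, school enters as a fixed covariate, and the working
   correlation is first-order autoregressive over the case sequence
   (adjacent cases more alike than distant ones).  Time variables are
   log-transformed and highly skewed counts dichotomized before fitting;
   robust (sandwich) standard errors are reported.
3. :func:`fit_learning_curves` — per-metric generalized mixed-effects
   trends over sequence position 1..20 with a random student intercept.
4. :func:`compare_cohorts` — M1-vs-M2 contrasts at curriculum start and
   end of pre-clerkship.

Component percents enter regressions on the 0-10 point scale
(pct / 10), the scale on which the reference estimates are reported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "TABLE1_VARIABLES",
    "UnivariateResult",
    "GEEResult",
    "LearningCurveResult",
    "compare_groups",
    "percent_difference",
    "fit_gee",
    "fit_learning_curves",
    "compare_cohorts",
    "render_report",
]

#: the score-table variables contrasted between outcome groups
TABLE1_VARIABLES = [
    "ddx_pct",
    "dxj_pct",
    "inv_pct",
    "error_count",
    "time_history",
    "time_physical",
    "time_investigations",
    "views_history",
    "views_physical",
    "views_investigations",
    "n_tests",
    "n_rounds",
    "unused_results_count",
    "inappropriate_tests_count",
    "excess_tests",
    "excess_rounds",
    "total_penalty_points",
]

TIME_VARIABLES = ("time_history", "time_physical", "time_investigations")


@dataclass
class UnivariateResult:
    variable: str
    mean_correct: float
    sd_correct: float
    mean_incorrect: float
    sd_incorrect: float
    percent_difference: float
    test: str  # "t" | "wilcoxon" | "skipped"
    p_value: float
    normality_note: str = ""


@dataclass
class GEEResult:
    estimates: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    working_correlation: str
    cluster: str
    transformations: dict[str, str]
    excluded: dict[str, str]
    n_obs: int
    n_clusters: int
    dep_params: str = ""


@dataclass
class LearningCurveResult:
    metric: str
    family: str
    trend: pd.DataFrame  # sequence_index, fitted, lo, hi, empirical_mean
    params: pd.Series
    random_intercept_var: float


def percent_difference(mean_correct: float, mean_incorrect: float) -> float:
    """(mean_correct - mean_incorrect) / mean_incorrect * 100."""
    if mean_incorrect == 0:
        return float("nan")
    return (mean_correct - mean_incorrect) / mean_incorrect * 100.0


def _is_normal(x: np.ndarray, alpha: float, cap: int, rng: np.random.Generator) -> bool:
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 3:
        return False
    sample = x if len(x) <= cap else rng.choice(x, size=cap, replace=False)
    try:
        return stats.shapiro(sample).pvalue > alpha
    except ValueError:
        return False


def compare_groups(
    df: pd.DataFrame,
    variables: list[str] | None = None,
    normality_alpha: float = 0.05,
    shapiro_cap: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Correct-vs-misdiagnosed univariate contrasts, one row per variable."""
    variables = variables or [v for v in TABLE1_VARIABLES if v in df.columns]
    correct = df[df["correct"].astype(bool)]
    wrong = df[~df["correct"].astype(bool)]
    if len(correct) < 2 or len(wrong) < 2:
        raise ValueError("need >=2 cases in each outcome group")
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        a = correct[var].astype(float).to_numpy()
        b = wrong[var].astype(float).to_numpy()
        res = UnivariateResult(
            variable=var,
            mean_correct=float(a.mean()),
            sd_correct=float(a.std(ddof=1)),
            mean_incorrect=float(b.mean()),
            sd_incorrect=float(b.std(ddof=1)),
            percent_difference=percent_difference(float(a.mean()), float(b.mean())),
            test="skipped",
            p_value=float("nan"),
        )
        if np.ptp(np.concatenate([a, b])) == 0:
            res.normality_note = "constant variable; test skipped"
        else:
            normal = _is_normal(a, normality_alpha, shapiro_cap, rng) and _is_normal(
                b, normality_alpha, shapiro_cap, rng
            )
            if normal:
                res.test = "t"
                res.p_value = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                res.normality_note = f"Shapiro p>{normality_alpha} in both groups"
            else:
                res.test = "wilcoxon"
                res.p_value = float(stats.mannwhitneyu(a, b).pvalue)
                res.normality_note = "non-normal by Shapiro-Wilk"
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


DEFAULT_PREDICTORS = ["dxj_points", "inv_points", "ddx_points", "error_count"]


def prepare_model_frame(
    df: pd.DataFrame,
    skew_cutoff: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Derive regression columns: 0-10 points, log-times, dichotomized counts."""
    out = df.copy()
    transforms: dict[str, str] = {}
    for pct, pts in (
        ("dxj_pct", "dxj_points"),
        ("inv_pct", "inv_points"),
        ("ddx_pct", "ddx_points"),
    ):
        if pct in out:
            out[pts] = out[pct] / 10.0
            transforms[pts] = f"{pct} / 10"
    for var in TIME_VARIABLES:
        if var in out:
            out[f"log_{var}"] = np.log1p(out[var])
            transforms[f"log_{var}"] = f"log(1 + {var})"
    for var in ("n_tests", "n_rounds", "unused_results_count", "inappropriate_tests_count"):
        if var in out:
            sk = float(stats.skew(out[var].astype(float)))
            if abs(sk) > skew_cutoff:
                out[f"{var}_any"] = (out[var] > 0).astype(int)
                transforms[f"{var}_any"] = f"{var} dichotomized at 0 (skew {sk:.1f})"
    out["correct"] = out["correct"].astype(int)
    return out, transforms


def fit_gee(
    df: pd.DataFrame,
    predictors: list[str] | None = None,
    working_correlation: str = "ar",
    school_fixed: bool = True,
    cluster: str = "student",
    drop_nonsignificant: bool = False,
    alpha: float = 0.05,
) -> GEEResult:
    """Marginal logistic regression of correctness on CR components.

    ``working_correlation``: "ar" (first-order autoregressive over the
    case sequence, the primary specification), "exchangeable" or
    "independence".  ``cluster``: "student" (default; school then enters
    as a fixed covariate) or "school".
    """
    predictors = list(predictors or DEFAULT_PREDICTORS)
    data, transforms = prepare_model_frame(df)
    data = data.sort_values(["student_id", "sequence_index"], kind="mergesort")

    excluded: dict[str, str] = {}
    for p in list(predictors):
        if data[p].nunique() < 2:
            predictors.remove(p)
            excluded[p] = "constant column"
    rhs = list(predictors)
    if school_fixed and cluster == "student" and data["school_id"].nunique() > 1:
        rhs.append("C(school_id)")
    formula = "correct ~ " + " + ".join(rhs)

    # collinearity guard: names the offending columns instead of a
    # cryptic singular-matrix failure
    X = data[predictors].astype(float)
    rank = np.linalg.matrix_rank(np.c_[np.ones(len(X)), X.to_numpy()])
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"singular design; near-collinear columns: {worst}")

    groups = data["student_id"] if cluster == "student" else data["school_id"]
    if working_correlation == "ar":
        cov = sm.cov_struct.Autoregressive(grid=True)
        label = "AR(1) over case sequence"
    elif working_correlation == "exchangeable":
        cov = sm.cov_struct.Exchangeable()
        label = "exchangeable"
    else:
        cov = sm.cov_struct.Independence()
        label = "independence"
    model = smf.gee(
        formula,
        groups=groups,
        time=data["sequence_index"].to_numpy(),
        data=data,
        family=sm.families.Binomial(),
        cov_struct=cov,
    )
    try:
        fit = model.fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - surfaced with context
        raise RuntimeError(f"GEE failed to converge: {exc}") from exc

    if drop_nonsignificant:
        keep = [p for p in predictors if fit.pvalues.get(p, 0.0) <= alpha]
        if keep != predictors:
            refit = fit_gee(
                df,
                keep,
                working_correlation,
                school_fixed,
                cluster,
                drop_nonsignificant=False,
            )
            for p in predictors:
                if p not in keep:
                    refit.excluded[p] = "Not significant, removed"
            refit.excluded.update(excluded)
            return refit

    return GEEResult(
        estimates=fit.params,
        std_errors=fit.bse,
        p_values=fit.pvalues,
        working_correlation=label,
        cluster=cluster,
        transformations=transforms,
        excluded=excluded,
        n_obs=int(fit.nobs),
        n_clusters=int(groups.nunique()),
        dep_params=str(cov.summary()),
    )


LEARNING_METRICS = ["ddx_pct", "dxj_pct", "inv_pct", "error_count", "correct"]


def _metric_family(metric: str) -> str:
    if metric == "correct":
        return "binomial"
    if metric == "error_count":
        return "poisson"
    return "gaussian"


def fit_learning_curves(
    df: pd.DataFrame,
    metrics: list[str] | None = None,
) -> dict[str, LearningCurveResult]:
    """Mixed-effects learning trends over case sequence, per metric.

    Gaussian metrics use a linear mixed model with a random student
    intercept; correctness and error counts use Bayes-variational
    binomial / Poisson mixed GLMs.  The fixed-effect trend is over
    log(sequence), matching curves that rise steeply then slow.
    """
    metrics = metrics or [m for m in LEARNING_METRICS if m in df.columns]
    if df["sequence_index"].nunique() < 2:
        raise ValueError("learning curves need >=2 distinct sequence positions")
    data = df.copy()
    data["log_seq"] = np.log(data["sequence_index"].astype(float))
    data["correct"] = data["correct"].astype(int)
    tgrid = np.sort(df["sequence_index"].unique())
    results: dict[str, LearningCurveResult] = {}
    for metric in metrics:
        family = _metric_family(metric)
        empirical = data.groupby("sequence_index")[metric].mean().reindex(tgrid)
        try:
            if family == "gaussian":
                model = smf.mixedlm(
                    f"{metric} ~ log_seq", data, groups=data["student_id"]
                )
                md = model.fit(reml=True)
                params = md.fe_params
                cov = md.cov_params().loc[params.index, params.index]
                re_var = float(md.cov_re.iloc[0, 0])
                X = np.c_[np.ones(len(tgrid)), np.log(tgrid)]
                fitted = X @ params.to_numpy()
                se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov.to_numpy(), X))
                lo, hi = fitted - 1.96 * se, fitted + 1.96 * se
            else:
                cls = (
                    sm.BinomialBayesMixedGLM
                    if family == "binomial"
                    else sm.PoissonBayesMixedGLM
                )
                md = cls.from_formula(
                    f"{metric} ~ log_seq", {"student": "0 + C(student_id)"}, data
                ).fit_vb()
                params = pd.Series(md.fe_mean, index=md.model.exog_names)
                se_fe = pd.Series(md.fe_sd, index=md.model.exog_names)
                re_var = float(np.exp(2 * md.vcp_mean[0]))
                X = np.c_[np.ones(len(tgrid)), np.log(tgrid)]
                lin = X @ params.to_numpy()
                se = np.sqrt((X**2) @ (se_fe.to_numpy() ** 2))
                link = (
                    (lambda z: 1 / (1 + np.exp(-z))) if family == "binomial" else np.exp
                )
                fitted, lo, hi = link(lin), link(lin - 1.96 * se), link(lin + 1.96 * se)
        except Exception as exc:
            raise RuntimeError(f"learning-curve fit failed for {metric}: {exc}") from exc
        results[metric] = LearningCurveResult(
            metric=metric,
            family=family,
            trend=pd.DataFrame(
                {
                    "sequence_index": tgrid,
                    "fitted": fitted,
                    "lo": lo,
                    "hi": hi,
                    "empirical_mean": empirical.to_numpy(),
                }
            ),
            params=params,
            random_intercept_var=re_var,
        )
    return results


COHORT_METRICS = ["dxj_pct", "inv_pct", "error_count", "misdiagnosed"]


def compare_cohorts(df: pd.DataFrame) -> pd.DataFrame:
    """M1-vs-M2 contrasts at curriculum start and end of pre-clerkship.

    Start is sequence position 1; end is each cohort's own final case
    (cohorts complete different numbers of cases).  Binary metrics use a
    two-proportion z-test, continuous ones the univariate machinery.
    """
    cohorts = sorted(df["cohort"].unique())
    if len(cohorts) < 2:
        raise ValueError(f"need both cohorts, found {cohorts}")
    data = df.copy()
    data["misdiagnosed"] = 1 - data["correct"].astype(int)
    rows = []
    for point in ("start", "end"):
        subsets = {}
        for coh in ("M1", "M2"):
            block = data[data["cohort"] == coh]
            t = 1 if point == "start" else int(block["sequence_index"].max())
            subsets[coh] = block[block["sequence_index"] == t]
            if point == "end" and t == 1:
                subsets[coh] = subsets[coh].assign(_degenerate=True)
        for metric in COHORT_METRICS:
            a = subsets["M1"][metric].astype(float).to_numpy()
            b = subsets["M2"][metric].astype(float).to_numpy()
            if metric == "misdiagnosed":
                from statsmodels.stats.proportion import proportions_ztest

                count = np.array([a.sum(), b.sum()])
                nobs = np.array([len(a), len(b)])
                p = float(proportions_ztest(count, nobs)[1]) if nobs.min() else float("nan")
                test = "two-proportion z"
            elif np.ptp(np.concatenate([a, b])) == 0:
                p, test = float("nan"), "skipped"
            else:
                p = float(stats.mannwhitneyu(a, b).pvalue)
                test = "wilcoxon"
            rows.append(
                {
                    "timepoint": point,
                    "metric": metric,
                    "mean_m1": float(a.mean()),
                    "mean_m2": float(b.mean()),
                    "n_m1": len(a),
                    "n_m2": len(b),
                    "test": test,
                    "p_value": p,
                    "note": "start==end (single case)"
                    if "_degenerate" in subsets["M1"].columns
                    or "_degenerate" in subsets["M2"].columns
                    else "",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def render_report(
    results: dict,
    out_dir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> list[Path]:
    """Write tables (CSV), figures (PDF) and a JSON run manifest.

    ``results`` may hold any of: "univariate" (DataFrame), "gee"
    (GEEResult), "curves" (dict of LearningCurveResult), "cohorts"
    (DataFrame).  Empty results are an error; nothing is written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no results to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(frame: pd.DataFrame, name: str):
        p = out / name
        frame.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    if "univariate" in results:
        save_csv(results["univariate"], "table_univariate.csv")
        fig, ax = plt.subplots(figsize=(7, 5))
        tab = results["univariate"].dropna(subset=["percent_difference"])
        ax.barh(tab["variable"], tab["percent_difference"], color="steelblue")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("% difference, correct vs misdiagnosed")
        fig.tight_layout()
        p = out / "fig_univariate.pdf"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    if "gee" in results:
        g: GEEResult = results["gee"]
        frame = pd.DataFrame(
            {"estimate": g.estimates, "se": g.std_errors, "p": g.p_values}
        ).rename_axis("term").reset_index()
        save_csv(frame, "table_gee.csv")
        mask = frame["term"].isin(DEFAULT_PREDICTORS)
        sub = frame[mask]
        fig, ax = plt.subplots(figsize=(6, 4))
        y = np.arange(len(sub))
        ax.errorbar(sub["estimate"], y, xerr=1.96 * sub["se"], fmt="o", color="firebrick")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_yticks(y, sub["term"])
        ax.set_xlabel("GEE estimate (logit scale) ± 95% CI")
        ax.set_title("Predictors of correct diagnosis")
        fig.tight_layout()
        p = out / "fig_gee_forest.pdf"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    if "curves" in results:
        curves: dict[str, LearningCurveResult] = results["curves"]
        stacked = pd.concat(
            [c.trend.assign(metric=m) for m, c in curves.items()], ignore_index=True
        )
        save_csv(stacked, "table_learning_curves.csv")
        fig, axes = plt.subplots(1, len(curves), figsize=(3.2 * len(curves), 3.2))
        axes = np.atleast_1d(axes)
        for ax, (m, c) in zip(axes, curves.items()):
            ax.plot(c.trend["sequence_index"], c.trend["fitted"], color="navy")
            ax.fill_between(
                c.trend["sequence_index"], c.trend["lo"], c.trend["hi"], alpha=0.25
            )
            ax.plot(
                c.trend["sequence_index"],
                c.trend["empirical_mean"],
                ".",
                color="gray",
                ms=4,
            )
            ax.set_title(m)
            ax.set_xlabel("case sequence")
        fig.tight_layout()
        p = out / "fig_learning_curves.pdf"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    if "cohorts" in results:
        save_csv(results["cohorts"], "table_cohort_contrast.csv")
        tab = results["cohorts"]
        fig, axes = plt.subplots(1, len(COHORT_METRICS), figsize=(3.0 * len(COHORT_METRICS), 3.2))
        for ax, metric in zip(np.atleast_1d(axes), COHORT_METRICS):
            sub = tab[tab["metric"] == metric]
            x = np.arange(len(sub))
            ax.bar(x - 0.18, sub["mean_m1"], width=0.34, label="M1")
            ax.bar(x + 0.18, sub["mean_m2"], width=0.34, label="M2")
            ax.set_xticks(x, sub["timepoint"])
            ax.set_title(metric)
        axes = np.atleast_1d(axes)
        axes[0].legend()
        fig.tight_layout()
        p = out / "fig_cohort_contrast.pdf"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config or {}),
        "outputs": [p.name for p in written],
    }
    mp = out / "run_manifest.json"
    mp.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(mp)
    return written
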