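"""Population-level analyses over many scored models.

A *model record* is one model's class label (static / contextual) together
with its per-task t scores — one data point in the population scatterplots.
Two analyses are provided:

* ``correlate_tasks`` — Pearson correlation plus unweighted OLS regression
  of one task's t score on another's, within one model class.  Both r (with
  two-sided p) and the regression slope are always reported: a correlation
  can be statistically significant while its slope is nearly flat, in which
  case improving semantic performance buys essentially no inference
  performance — the two-criterion reading used throughout the experiment
  suite (flat-slope threshold configurable, default 0.15).
* ``anova_task_by_model`` — 2x2 mixed ANOVA with model class as the
  between-models factor and task as the within-model (repeated) factor,
  with Scheffe-adjusted pairwise comparisons of the four cells and t-based
  95% confidence intervals on the cell means.

``run_experiment_suite`` composes these into the four-experiment report:
semantics-inference correlations per class for each semantic measure
(experiments 1-2) and the inference-pair and semantic-pair ANOVAs
(experiments 3-4), along with the per-figure scatter data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelRecord",
    "CorrelationResult",
    "AnovaResult",
    "ZeroVarianceError",
    "correlate_tasks",
    "anova_task_by_model",
    "run_experiment_suite",
    "write_report",
]

MODEL_CLASSES = ("static", "contextual")


class ZeroVarianceError(ValueError):
    """A correlation input has no variance; r is undefined."""


@dataclass(frozen=True)
class ModelRecord:
    """One model's task performance: a point in the population analyses."""

    model_name: str
    model_class: str
    t_scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model_class {self.model_class!r}")
        if not self.t_scores:
            raise ValueError("t_scores must be nonempty")
        for task, t in self.t_scores.items():
            if not math.isfinite(t):
                raise ValueError(f"non-finite t score for task {task!r}: {t}")


@dataclass(frozen=True)
class CorrelationResult:
    x_task: str
    y_task: str
    model_class: str
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float


@dataclass
class AnovaResult:
    """2x2 mixed-ANOVA table, cell means with 95% CIs, and Scheffe post hoc."""

    effects: dict[str, dict[str, float]]  # task / model / interaction -> F, df1, df2, p
    cell_means: dict[str, dict[str, float]]  # "<class>:<task>" -> mean, ci_low, ci_high, n
    posthoc: list[dict]


def _class_records(records: list[ModelRecord], model_class: str) -> list[ModelRecord]:
    return [r for r in records if r.model_class == model_class]


def correlate_tasks(
    records: list[ModelRecord], x_task: str, y_task: str, model_class: str
) -> CorrelationResult:
    """Pearson r and OLS slope/intercept of y-task t scores on x-task t scores."""
    sub = _class_records(records, model_class)
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 {model_class!r} records for correlation, got {len(sub)}"
        )
    x = np.array([r.t_scores[x_task] for r in sub])
    y = np.array([r.t_scores[y_task] for r in sub])
    if np.ptp(x) == 0.0:
        raise ZeroVarianceError(f"zero variance in x task {x_task!r}")
    if np.ptp(y) == 0.0:
        raise ZeroVarianceError(f"zero variance in y task {y_task!r}")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        x_task=x_task,
        y_task=y_task,
        model_class=model_class,
        n=len(sub),
        pearson_r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    # closed-form slope; well-defined whenever x varies, even if y is constant
    xc = x - x.mean()
    return float(np.dot(xc, y) / np.dot(xc, xc))


def _cell_mean_ci(values: np.ndarray, alpha: float = 0.05) -> dict[str, float]:
    n = values.size
    mean = float(values.mean())
    if n > 1 and np.ptp(values) > 0.0:
        half = float(stats.t.ppf(1 - alpha / 2, n - 1) * values.std(ddof=1) / np.sqrt(n))
    else:
        half = 0.0
    return {"mean": mean, "ci_low": mean - half, "ci_high": mean + half, "n": n}


def _scheffe_p(t: float, df: float, k: int = 4) -> float:
    """Scheffe-adjusted p for a pairwise contrast among k cell means.

    The contrast's t is referred to (k-1) * F(k-1, df); always at least as
    large as the unadjusted two-sided t p value (conservative).
    """
    return float(stats.f.sf(t * t / (k - 1), k - 1, df))


def anova_task_by_model(
    records: list[ModelRecord], task_pair: tuple[str, str]
) -> AnovaResult:
    """2x2 mixed ANOVA: model class (between) x task (within, repeated).

    Degenerate input where every score is identical is handled explicitly
    (all F = 0, p = 1).  Post hoc comparisons use paired t within a class
    and Welch t between classes, each Scheffe-adjusted over the four cells.
    """
    task_a, task_b = task_pair
    by_class = {c: _class_records(records, c) for c in MODEL_CLASSES}
    for c, sub in by_class.items():
        if len(sub) < 2:
            raise ValueError(f"need >= 2 {c!r} records for the mixed ANOVA, got {len(sub)}")

    rows = []
    for rec in records:
        for task in task_pair:
            if task not in rec.t_scores:
                raise ValueError(f"model {rec.model_name!r} lacks task {task!r}")
            rows.append(
                {
                    "subject": rec.model_name,
                    "model_class": rec.model_class,
                    "task": task,
                    "t_score": rec.t_scores[task],
                }
            )
    data = pd.DataFrame(rows)

    n_models = data["subject"].nunique()
    if np.ptp(data["t_score"].to_numpy()) == 0.0:
        effects = {
            name: {"F": 0.0, "df1": 1, "df2": df2, "p": 1.0}
            for name, df2 in (
                ("model", n_models - 2),
                ("task", n_models - 2),
                ("interaction", n_models - 2),
            )
        }
    else:
        import pingouin as pg

        table = pg.mixed_anova(
            data=data,
            dv="t_score",
            within="task",
            subject="subject",
            between="model_class",
        ).set_index("Source")
        effects = {}
        for name, source in (
            ("model", "model_class"),
            ("task", "task"),
            ("interaction", "Interaction"),
        ):
            row = table.loc[source]
            p_col = "p_unc" if "p_unc" in table.columns else "p-unc"
            effects[name] = {
                "F": float(row["F"]),
                "df1": int(row["DF1"]),
                "df2": int(row["DF2"]),
                "p": float(row[p_col]),
            }

    cells: dict[str, np.ndarray] = {}
    for c in MODEL_CLASSES:
        for task in task_pair:
            key = f"{c}:{task}"
            cells[key] = np.array([r.t_scores[task] for r in by_class[c]])
    cell_means = {key: _cell_mean_ci(vals) for key, vals in cells.items()}

    posthoc = []
    keys = list(cells)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ka, kb = keys[i], keys[j]
            ca, ta = ka.split(":")
            cb, tb = kb.split(":")
            a, b = cells[ka], cells[kb]
            if ca == cb:  # within-class: the same models under both tasks
                diff = a - b
                if np.ptp(diff) == 0.0:
                    t, p, df = (0.0, 1.0, a.size - 1) if diff[0] == 0.0 else (
                        math.copysign(math.inf, diff[0]), 0.0, a.size - 1)
                else:
                    t, p = stats.ttest_rel(a, b)
                    df = a.size - 1
            else:  # between classes: independent models, Welch correction
                if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
                    t, p, df = (0.0, 1.0, a.size + b.size - 2) if a[0] == b[0] else (
                        math.copysign(math.inf, a[0] - b[0]), 0.0, a.size + b.size - 2)
                else:
                    res = stats.ttest_ind(a, b, equal_var=False)
                    t, p, df = res.statistic, res.pvalue, res.df
            posthoc.append(
                {
                    "cell_a": ka,
                    "cell_b": kb,
                    "t": float(t),
                    "df": float(df),
                    "p_unadjusted": float(p),
                    "p_scheffe": _scheffe_p(float(t), float(df))
                    if math.isfinite(t)
                    else 0.0,
                }
            )
    return AnovaResult(effects=effects, cell_means=cell_means, posthoc=posthoc)


def run_experiment_suite(
    records: list[ModelRecord],
    semantic_tasks: tuple[str, str] = ("chwilla_sem", "metusalem_sem"),
    inference_tasks: tuple[str, str] = ("metusalem_inf", "mckoon_inf"),
    flat_slope_threshold: float = 0.15,
) -> dict:
    """Run the four population experiments and return a serializable report.

    Experiments 1 and 2 correlate each semantic measure with each inference
    measure within each model class; experiment 3 is the inference-pair
    mixed ANOVA and experiment 4 the semantic-pair one.  A class whose
    inference scores have no variance (e.g., order-blind models on
    multiset-matched word-order items, which score exactly zero) gets a
    correlation entry with the OLS slope (well-defined and zero) and an
    undefined r, annotated rather than erroring the whole suite.
    """
    if not records:
        raise ValueError("empty record list")

    def _corr_entry(x_task: str, y_task: str, model_class: str) -> dict:
        try:
            res = correlate_tasks(records, x_task, y_task, model_class)
            entry = {
                "x_task": res.x_task,
                "y_task": res.y_task,
                "model_class": res.model_class,
                "n": res.n,
                "pearson_r": res.pearson_r,
                "p_value": res.p_value,
                "slope": res.slope,
                "intercept": res.intercept,
                "note": "",
            }
        except ZeroVarianceError as exc:
            sub = _class_records(records, model_class)
            x = np.array([r.t_scores[x_task] for r in sub])
            y = np.array([r.t_scores[y_task] for r in sub])
            slope = _ols_slope(x, y) if np.ptp(x) > 0.0 else float("nan")
            entry = {
                "x_task": x_task,
                "y_task": y_task,
                "model_class": model_class,
                "n": len(sub),
                "pearson_r": float("nan"),
                "p_value": float("nan"),
                "slope": slope,
                "intercept": float(np.mean(y) - slope * np.mean(x))
                if math.isfinite(slope)
                else float("nan"),
                "note": f"undefined correlation: {exc}",
            }
        if math.isfinite(entry["slope"]):
            entry["effective"] = bool(
                entry.get("p_value", 1.0) < 0.05
                and abs(entry["slope"]) >= flat_slope_threshold
            ) if math.isfinite(entry["p_value"]) else False
        else:
            entry["effective"] = False
        return entry

    def _anova_entry(task_pair: tuple[str, str]) -> dict:
        res = anova_task_by_model(records, task_pair)
        return {
            "task_pair": list(task_pair),
            "effects": res.effects,
            "cell_means": res.cell_means,
            "posthoc": res.posthoc,
        }

    report: dict = {"n_records": len(records)}
    for exp, sem_task in (("experiment1", semantic_tasks[0]), ("experiment2", semantic_tasks[1])):
        report[exp] = {
            "semantic_task": sem_task,
            "correlations": [
                _corr_entry(sem_task, inf_task, cls)
                for cls in MODEL_CLASSES
                for inf_task in inference_tasks
            ],
        }
    report["experiment3"] = _anova_entry(inference_tasks)
    report["experiment4"] = _anova_entry(semantic_tasks)

    scatter = []
    for rec in records:
        row = {"model_name": rec.model_name, "model_class": rec.model_class}
        row.update(rec.t_scores)
        scatter.append(row)
    report["scatter"] = scatter
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the suite report as JSON plus per-figure scatter CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    pd.DataFrame(report["scatter"]).to_csv(out_dir / "model_scores.csv", index=False)
    return out_dir
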