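"""Per-trial scores and t-statistic performance measures for the four tasks.

Each task maps one embedding backend and one stimulus set to a
:class:`TaskResult`.  The per-trial quantity is always a (difference of)
cosine similarity, under the linking hypothesis that cosine similarity is
inversely related to the human N400 amplitude (semantic-priming and
discourse tasks) or to reaction time (the word-order inference task):

* ``chwilla_sem``      — per pair:   CosSim(prime, target);
  performance = two-sample t, related vs unrelated pairs.
* ``metusalem_sem``    — per item:   CosSim(S, E) - (CosSim(S, R) + CosSim(S, U)) / 2
  where S is the averaged/encoded final sentence and E/R/U the expected,
  discourse-related and unrelated completions; paired t of the expected
  similarity against the mean unexpected similarity.
* ``metusalem_inf``    — per item:   [CosSim(C, R) - CosSim(C, U)] - [CosSim(S, R) - CosSim(S, U)]
  where C embeds the discourse followed by the sentence: the *rescue* of
  the discourse-related word by the extended context; paired t of the
  context difference against the sentence difference.  Also emits the
  six-condition similarity profile (sentence/discourse x E/R/U).
* ``mckoon_inf``       — per item:   CosSim(context, target) - CosSim(control, target);
  paired t of context vs control similarities.  Because the two sentences
  are built from (near-)identical word multisets, an order-blind averaging
  backend cancels this score exactly; separating the conditions requires
  word-order sensitivity.

A positive t always points in the direction the linking hypothesis
requires (related > unrelated, expected > unexpected, context > control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .backends import Backend, StaticLexicon, TokenizerConfig, embed_target, embed_text
from .population import ModelRecord
from .stimuli import StimulusSet

__all__ = [
    "TASKS",
    "DegenerateDataError",
    "TrialScore",
    "ConditionProfile",
    "TaskResult",
    "score_chwilla",
    "score_metusalem_semantics",
    "score_metusalem_inference",
    "score_mckoon_inference",
    "run_task_battery",
]

TASKS = ("chwilla_sem", "metusalem_sem", "metusalem_inf", "mckoon_inf")


class DegenerateDataError(ValueError):
    """Trial scores have zero variance with a nonzero effect (t would be infinite)."""


@dataclass(frozen=True)
class TrialScore:
    """One trial's named cosine components and their arithmetic combination."""

    item_id: str
    components: dict[str, float]
    score: float


@dataclass(frozen=True)
class ConditionProfile:
    """Mean cosine similarity per condition for the discourse-inference task.

    Keys: S/D for sentence-alone vs discourse+sentence context, crossed with
    E/R/U for expected, discourse-related and unrelated target words.
    """

    means: dict[str, float]

    KEYS = ("S-E", "S-R", "S-U", "D-E", "D-R", "D-U")


@dataclass
class TaskResult:
    task: str
    model_name: str
    model_class: str
    trial_scores: list[TrialScore]
    t_stat: float
    p_value: float
    df: int
    test_kind: str
    profile: ConditionProfile | None = None

    @property
    def n(self) -> int:
        return len(self.trial_scores)

    def summary(self) -> dict:
        return {
            "task": self.task,
            "model_name": self.model_name,
            "model_class": self.model_class,
            "n_trials": self.n,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "test_kind": self.test_kind,
        }


def _model_meta(backend: Backend) -> tuple[str, str]:
    if isinstance(backend, StaticLexicon):
        return backend.name, "static"
    return backend.name, "contextual"


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Two-sided paired t test of a vs b.

    Zero-variance differences with zero mean are an exact null (t = 0,
    p = 1); with nonzero mean the t statistic is unbounded and we raise.
    """
    diff = a - b
    n = diff.size
    if n < 2:
        raise ValueError(f"paired t test needs >= 2 trials, got {n}")
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return 0.0, 1.0, n - 1
        raise DegenerateDataError(
            "zero variance in paired differences with nonzero mean"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), n - 1


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[float, float, int]:
    """Two-sided two-sample t test (pooled variance by default, Welch optional)."""
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t test needs >= 2 trials per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return 0.0, 1.0, a.size + b.size - 2
        raise DegenerateDataError("zero within-group variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = int(res.df) if welch else a.size + b.size - 2
    return float(res.statistic), float(res.pvalue), df


def score_chwilla(
    backend: Backend,
    pairs: StimulusSet,
    config: TokenizerConfig = TokenizerConfig(),
    welch: bool = False,
) -> TaskResult:
    """Semantic-priming score: prime-target cosine, related vs unrelated pairs."""
    _require_protocol(pairs, "chwilla")
    related, unrelated, scores = [], [], []
    for i, pair in enumerate(pairs.items):
        try:
            sim = _cos(embed_target(backend, pair.prime), embed_target(backend, pair.target))
        except Exception as exc:
            raise type(exc)(
                f"pair {i} ({pair.prime!r}, {pair.target!r}): {exc}"
            ) from exc
        (related if pair.related else unrelated).append(sim)
        scores.append(
            TrialScore(
                item_id=f"pair-{i}",
                components={"cos_prime_target": sim, "related": float(pair.related)},
                score=sim,
            )
        )
    t, p, df = _two_sample_t(np.array(related), np.array(unrelated), welch=welch)
    name, cls = _model_meta(backend)
    return TaskResult("chwilla_sem", name, cls, scores, t, p, df, "two_sample")


def score_metusalem_semantics(
    backend: Backend,
    items: StimulusSet,
    config: TokenizerConfig = TokenizerConfig(),
) -> TaskResult:
    """Expected-word advantage of the final sentence over both unexpected words."""
    _require_protocol(items, "metusalem")
    expected_sims, unexpected_sims, scores = [], [], []
    for item in items.items:
        sent = embed_text(backend, item.sentence, config)
        c_e = _cos(sent, embed_target(backend, item.expected))
        c_r = _cos(sent, embed_target(backend, item.related))
        c_u = _cos(sent, embed_target(backend, item.unrelated))
        score = c_e - (c_r + c_u) / 2.0
        expected_sims.append(c_e)
        unexpected_sims.append((c_r + c_u) / 2.0)
        scores.append(
            TrialScore(
                item_id=item.item_id,
                components={
                    "cos_sentence_expected": c_e,
                    "cos_sentence_related": c_r,
                    "cos_sentence_unrelated": c_u,
                },
                score=score,
            )
        )
    t, p, df = _paired_t(np.array(expected_sims), np.array(unexpected_sims))
    name, cls = _model_meta(backend)
    return TaskResult("metusalem_sem", name, cls, scores, t, p, df, "paired")


def score_metusalem_inference(
    backend: Backend,
    items: StimulusSet,
    config: TokenizerConfig = TokenizerConfig(),
) -> TaskResult:
    """Discourse rescue of the related word relative to the sentence alone.

    The context condition embeds the discourse and the final sentence joined
    by a single space; the sentence condition embeds the sentence alone.
    """
    _require_protocol(items, "metusalem")
    ctx_diffs, sent_diffs, scores = [], [], []
    profile_acc = {k: 0.0 for k in ConditionProfile.KEYS}
    for item in items.items:
        sent = embed_text(backend, item.sentence, config)
        context_text = (item.discourse + " " + item.sentence) if item.discourse.strip() else item.sentence
        ctx = embed_text(backend, context_text, config)
        vecs = {
            "E": embed_target(backend, item.expected),
            "R": embed_target(backend, item.related),
            "U": embed_target(backend, item.unrelated),
        }
        comp = {}
        for label, vec in vecs.items():
            comp[f"S-{label}"] = _cos(sent, vec)
            comp[f"D-{label}"] = _cos(ctx, vec)
        ctx_diff = comp["D-R"] - comp["D-U"]
        sent_diff = comp["S-R"] - comp["S-U"]
        score = ctx_diff - sent_diff
        ctx_diffs.append(ctx_diff)
        sent_diffs.append(sent_diff)
        for k in ConditionProfile.KEYS:
            profile_acc[k] += comp[k]
        scores.append(TrialScore(item_id=item.item_id, components=comp, score=score))
    t, p, df = _paired_t(np.array(ctx_diffs), np.array(sent_diffs))
    n = len(items)
    profile = ConditionProfile({k: v / n for k, v in profile_acc.items()})
    name, cls = _model_meta(backend)
    return TaskResult(
        "metusalem_inf", name, cls, scores, t, p, df, "paired", profile=profile
    )


def score_mckoon_inference(
    backend: Backend,
    items: StimulusSet,
    config: TokenizerConfig = TokenizerConfig(),
) -> TaskResult:
    """Context-over-control advantage in similarity to the inferable target word."""
    _require_protocol(items, "mckoon")
    ctx_sims, ctl_sims, scores = [], [], []
    for item in items.items:
        target = embed_target(backend, item.target)
        c_ctx = _cos(embed_text(backend, item.context_sentence, config), target)
        c_ctl = _cos(embed_text(backend, item.control_sentence, config), target)
        ctx_sims.append(c_ctx)
        ctl_sims.append(c_ctl)
        scores.append(
            TrialScore(
                item_id=item.item_id,
                components={"cos_context_target": c_ctx, "cos_control_target": c_ctl},
                score=c_ctx - c_ctl,
            )
        )
    t, p, df = _paired_t(np.array(ctx_sims), np.array(ctl_sims))
    name, cls = _model_meta(backend)
    return TaskResult("mckoon_inf", name, cls, scores, t, p, df, "paired")


_SCORERS = {
    "chwilla_sem": score_chwilla,
    "metusalem_sem": score_metusalem_semantics,
    "metusalem_inf": score_metusalem_inference,
    "mckoon_inf": score_mckoon_inference,
}

_TASK_PROTOCOL = {
    "chwilla_sem": "chwilla",
    "metusalem_sem": "metusalem",
    "metusalem_inf": "metusalem",
    "mckoon_inf": "mckoon",
}


def run_task_battery(
    backend: Backend,
    stimulus_sets: dict[str, StimulusSet],
    config: TokenizerConfig = TokenizerConfig(),
    tasks: tuple[str, ...] = TASKS,
) -> ModelRecord:
    """Score one backend on the requested tasks and collect its t scores.

    ``stimulus_sets`` maps protocol name (chwilla / metusalem / mckoon) to a
    stimulus set; both semantic-and-inference discourse tasks share the
    metusalem set.  Task failures propagate annotated with the task name.
    """
    name, cls = _model_meta(backend)
    t_scores: dict[str, float] = {}
    for task in tasks:
        proto = _TASK_PROTOCOL[task]
        if proto not in stimulus_sets:
            raise ValueError(f"task {task!r}: missing stimulus set {proto!r}")
        try:
            result = _SCORERS[task](backend, stimulus_sets[proto], config)
        except Exception as exc:
            raise RuntimeError(f"task {task!r} failed for model {name!r}: {exc}") from exc
        t_scores[task] = result.t_stat
    return ModelRecord(model_name=name, model_class=cls, t_scores=t_scores)


def _require_protocol(stimulus_set: StimulusSet, protocol: str) -> None:
    if stimulus_set.protocol != protocol:
        raise ValueError(
            f"expected a {protocol!r} stimulus set, got {stimulus_set.protocol!r}"
        )


def _cos(u, v) -> float:
    from .backends import cosine_similarity

    return cosine_similarity(u, v)
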