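"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written as plain loops and closed-form
textbook formulas, sharing no code path with the package: brute-force
per-trial scores, t statistics, correlation/regression normal equations,
and a balanced two-group repeated-measures (mixed) ANOVA decomposition.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def cos_brute(u, v) -> float:
    num = sum(float(a) * float(b) for a, b in zip(u, v))
    nu = math.sqrt(sum(float(a) ** 2 for a in u))
    nv = math.sqrt(sum(float(b) ** 2 for b in v))
    return num / (nu * nv)


def mean_vector_brute(vectors) -> list[float]:
    dim = len(vectors[0])
    n = len(vectors)
    return [sum(float(v[d]) for v in vectors) / n for d in range(dim)]


def text_vector_brute(lexicon, text) -> list[float]:
    """Order-canonical mean of in-vocabulary word vectors (static pathway)."""
    words = sorted(w.lower().strip(".,;:!?'\"()") for w in text.split())
    vecs = [lexicon.vectors[w] for w in words if w in lexicon.vectors]
    return mean_vector_brute(vecs)


def chwilla_scores_brute(lexicon, pairs):
    rel, unr = [], []
    for p in pairs.items:
        c = cos_brute(lexicon.vectors[p.prime], lexicon.vectors[p.target])
        (rel if p.related else unr).append(c)
    return rel, unr


def metusalem_sem_scores_brute(lexicon, items):
    out = []
    for it in items.items:
        s = text_vector_brute(lexicon, it.sentence)
        c_e = cos_brute(s, lexicon.vectors[it.expected])
        c_r = cos_brute(s, lexicon.vectors[it.related])
        c_u = cos_brute(s, lexicon.vectors[it.unrelated])
        out.append(c_e - (c_r + c_u) / 2.0)
    return out


def metusalem_inf_scores_brute(lexicon, items):
    out = []
    for it in items.items:
        s = text_vector_brute(lexicon, it.sentence)
        c = text_vector_brute(lexicon, (it.discourse + " " + it.sentence).strip())
        r, u = lexicon.vectors[it.related], lexicon.vectors[it.unrelated]
        out.append(
            (cos_brute(c, r) - cos_brute(c, u)) - (cos_brute(s, r) - cos_brute(s, u))
        )
    return out


def mckoon_scores_brute(lexicon, items):
    out = []
    for it in items.items:
        t = lexicon.vectors[it.target]
        ctx = text_vector_brute(lexicon, it.context_sentence)
        ctl = text_vector_brute(lexicon, it.control_sentence)
        out.append(cos_brute(ctx, t) - cos_brute(ctl, t))
    return out


# --- statistics -----------------------------------------------------------


def paired_t_brute(a, b):
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, p, n - 1


def two_sample_t_brute(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p, df


def pearson_ols_brute(x, y):
    """r, slope, intercept via the normal equations."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    slope = sxy / sxx
    return r, slope, my - slope * mx


def mixed_anova_brute(static_scores, contextual_scores):
    """Balanced 2 (group, between) x 2 (task, within) mixed ANOVA.

    ``*_scores`` are (n, 2) arrays: one row per subject, one column per
    task level.  Returns F and df for the between factor, the within
    factor, and their interaction, plus the SS decomposition.
    """
    g = np.stack([np.asarray(static_scores), np.asarray(contextual_scores)])
    n_groups, n_subj, n_tasks = g.shape
    assert n_tasks == 2 and g[0].shape == g[1].shape
    grand = g.mean()

    subj_means = g.mean(axis=2)  # (groups, subjects)
    group_means = g.mean(axis=(1, 2))  # (groups,)
    task_means = g.mean(axis=(0, 1))  # (tasks,)
    cell_means = g.mean(axis=1)  # (groups, tasks)

    ss_total = ((g - grand) ** 2).sum()
    ss_between_subj = n_tasks * ((subj_means - grand) ** 2).sum()
    ss_group = n_subj * n_tasks * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_task = n_groups * n_subj * ((task_means - grand) ** 2).sum()
    ss_inter = n_subj * (
        (cell_means - group_means[:, None] - task_means[None, :] + grand) ** 2
    ).sum()
    ss_error = ss_total - ss_between_subj - ss_task - ss_inter

    df_group = n_groups - 1
    df_subj = n_groups * (n_subj - 1)
    df_task = n_tasks - 1
    df_inter = df_group * df_task
    df_error = df_subj * df_task

    f_group = (ss_group / df_group) / (ss_subj_within / df_subj)
    f_task = (ss_task / df_task) / (ss_error / df_error)
    f_inter = (ss_inter / df_inter) / (ss_error / df_error)
    return {
        "model": (f_group, df_group, df_subj),
        "task": (f_task, df_task, df_error),
        "interaction": (f_inter, df_inter, df_error),
        "ss": {
            "total": ss_total,
            "group": ss_group,
            "subj_within": ss_subj_within,
            "task": ss_task,
            "interaction": ss_inter,
            "error": ss_error,
        },
    }
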