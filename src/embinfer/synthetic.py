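"""Synthetic worlds with planted, analytically controlled effect sizes.

Everything the evaluation pipeline consumes — a static lexicon, contextual
encoders, and stimulus sets for all four protocols — can be generated here
with known ground truth, so every stage is testable without downloading any
pretrained model.  The generator plants three effects:

``related_gap``
    Mean cosine advantage of related over unrelated word pairs in the
    lexicon (the semantic-priming effect), and equally the expected-word
    advantage in the discourse items (the sentence-level semantic effect).
``rescue_delta``
    The discourse-rescue effect: adding the discourse context raises the
    similarity of the discourse-related target relative to the unrelated
    one by this amount, while the sentence alone does not separate them.
``order_effect``
    The word-order effect: each word-order item's context and control
    sentences are permutations of the *same* word multiset, so an
    order-blind averaging backend cancels their difference exactly; a
    position-sensitive synthetic encoder separates them by this amount.

Geometry: all word vectors live on the unit sphere (normalized Gaussian
draws); planted pairwise cosines are achieved by interpolating toward
shared anchor directions, which keeps the cosine targets analytically
controllable.  Synthetic "words" are generated tokens, not English, so no
behaviour can accidentally depend on a real lexicon.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .backends import ContextualEncoder, StaticLexicon, tokenize
from .stimuli import ChwillaPair, McKoonItem, MetusalemItem, StimulusSet

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "SyntheticModel",
    "OrderAwareEncoder",
    "OrderBlindEncoder",
    "generate_world",
    "generate_model_population",
    "evaluate_population",
]

PROTOCOLS = ("chwilla", "metusalem", "mckoon")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world.

    Trial counts default to the canonical sizes of the human protocols the
    tasks emulate: 40 related + 40 unrelated priming pairs, 72 discourse
    items, 32 word-order items.
    """

    dim: int = 16
    vocab_size: int = 200  # filler words beyond the stimulus vocabulary
    related_gap: float = 0.3
    rescue_delta: float = 0.3
    order_effect: float = 0.3
    noise_sigma: float = 0.05
    n_chwilla_pairs: int = 40  # per group (related / unrelated)
    n_metusalem_items: int = 72
    n_mckoon_items: int = 32
    n_sentence_tokens: int = 6
    n_discourse_tokens: int = 14
    n_mckoon_tokens: int = 8  # per sentence, cue word included
    seed: int = 0
    encoder_decay: float = 0.8
    encoder_hash_scale: float = 0.05
    deterministic_trials: bool = False
    # per-item heterogeneity of the word-order effect; defaults to noise_sigma
    mckoon_noise_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        for name in ("related_gap", "rescue_delta", "order_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mckoon_noise_sigma is not None and self.mckoon_noise_sigma < 0:
            raise ValueError("mckoon_noise_sigma must be >= 0")
        if not 0 < self.encoder_decay <= 1:
            raise ValueError("encoder_decay must lie in (0, 1]")


class OrderBlindEncoder(ContextualEncoder):
    """Mean of lexicon word vectors: a contextual-interface wrapper around
    the order-blind static pathway (a control encoder)."""

    def __init__(self, lexicon: StaticLexicon, name: str = "synthetic-order-blind"):
        self.lexicon = lexicon
        self.dim = lexicon.dim
        self.name = name

    def encode(self, text: str) -> np.ndarray:
        from .backends import discourse_vector

        return discourse_vector(self.lexicon, text)


class OrderAwareEncoder(ContextualEncoder):
    """Position-decay weighted word-vector sum plus a bigram-hash term.

    The weight of the i-th token is ``decay**i`` (earlier words dominate),
    and each adjacent word pair contributes a small deterministic
    pseudo-random direction keyed by the pair — the simplest mechanism that
    breaks permutation invariance while remaining a pure function of the
    token sequence.
    """

    def __init__(
        self,
        lexicon: StaticLexicon,
        decay: float = 0.8,
        hash_scale: float = 0.05,
        name: str = "synthetic-order-aware",
    ):
        self.lexicon = lexicon
        self.decay = decay
        self.hash_scale = hash_scale
        self.dim = lexicon.dim
        self.name = name
        self._hash_cache: dict[tuple[str, str], np.ndarray] = {}

    def _bigram_direction(self, w1: str, w2: str) -> np.ndarray:
        key = (w1, w2)
        cached = self._hash_cache.get(key)
        if cached is None:
            digest = hashlib.blake2b(f"{w1}|{w2}".encode(), digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            cached = vec / np.linalg.norm(vec)
            self._hash_cache[key] = cached
        return cached

    def encode(self, text: str) -> np.ndarray:
        tokens = tokenize(text)
        if not tokens:
            raise ValueError("cannot encode empty text")
        weights = self.decay ** np.arange(len(tokens))
        vecs = np.stack([self.lexicon.lookup(t) for t in tokens])
        out = weights @ vecs / weights.sum()
        if len(tokens) > 1 and self.hash_scale > 0:
            bigrams = np.stack(
                [self._bigram_direction(a, b) for a, b in zip(tokens, tokens[1:])]
            )
            out = out + self.hash_scale * bigrams.mean(axis=0)
        return out


@dataclass
class SyntheticModel:
    """One member of a synthetic model population: a backend of graded
    quality together with the stimulus sets it is evaluated on."""

    name: str
    model_class: str
    backend: object
    stimulus_sets: dict[str, StimulusSet]
    quality_semantics: float
    quality_inference: float


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    lexicon: StaticLexicon
    order_aware_encoder: OrderAwareEncoder
    order_blind_encoder: OrderBlindEncoder
    stimulus_sets: dict[str, StimulusSet]
    truth: dict[str, float]

    def self_audit(self) -> dict[str, float]:
        """Measure the planted effects on the generated material.

        Returns planted-vs-measured pairs: the mean related/unrelated
        cosine gap, the mean sentence-level expected advantage, the mean
        discourse-rescue score, the mean word-order score under the
        order-aware encoder, and the largest |score| of the order-blind
        static path on the word-order items (exactly 0 by construction).
        """
        from .scoring import (
            score_chwilla,
            score_mckoon_inference,
            score_metusalem_inference,
            score_metusalem_semantics,
        )

        audit: dict[str, float] = {}
        if "chwilla" in self.stimulus_sets:
            res = score_chwilla(self.lexicon, self.stimulus_sets["chwilla"])
            rel = [s.score for s in res.trial_scores if s.components["related"]]
            unr = [s.score for s in res.trial_scores if not s.components["related"]]
            audit["related_gap_planted"] = self.truth["related_gap"]
            audit["related_gap_measured"] = float(np.mean(rel) - np.mean(unr))
        if "metusalem" in self.stimulus_sets:
            sem = score_metusalem_semantics(self.lexicon, self.stimulus_sets["metusalem"])
            inf = score_metusalem_inference(self.lexicon, self.stimulus_sets["metusalem"])
            audit["expected_advantage_planted"] = self.truth["related_gap"]
            audit["expected_advantage_measured"] = float(
                np.mean([s.score for s in sem.trial_scores])
            )
            audit["rescue_delta_planted"] = self.truth["rescue_delta"]
            audit["rescue_delta_measured"] = float(
                np.mean([s.score for s in inf.trial_scores])
            )
        if "mckoon" in self.stimulus_sets:
            aware = score_mckoon_inference(
                self.order_aware_encoder, self.stimulus_sets["mckoon"]
            )
            blind = score_mckoon_inference(self.lexicon, self.stimulus_sets["mckoon"])
            audit["order_effect_planted"] = self.truth["order_effect"]
            audit["order_effect_measured"] = float(
                np.mean([s.score for s in aware.trial_scores])
            )
            audit["order_blind_max_abs_score"] = float(
                max(abs(s.score) for s in blind.trial_scores)
            )
        return audit


def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _unit_orthogonal(rng: np.random.Generator, v: np.ndarray) -> np.ndarray:
    u = rng.standard_normal(v.size)
    u -= (u @ v) * v
    return u / np.linalg.norm(u)


def _plant_cosine(rng: np.random.Generator, v: np.ndarray, c: float) -> np.ndarray:
    """Unit vector with exact cosine ``c`` to the unit vector ``v``."""
    c = float(np.clip(c, -0.999, 0.999))
    u = _unit_orthogonal(rng, v)
    return c * v + np.sqrt(1.0 - c * c) * u


def _noisy_token(rng: np.random.Generator, direction: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return direction.copy()
    v = direction + sigma * rng.standard_normal(direction.size)
    return v / np.linalg.norm(v)


def _trial_deviations(
    rng: np.random.Generator, n: int, cfg: SyntheticConfig, sigma: float | None = None
) -> np.ndarray:
    """Per-trial deviations around a planted effect.

    In the default mode these are i.i.d. N(0, sigma^2) draws, so task t
    statistics carry honest trial-level sampling noise (as needed for null
    calibration studies).  In ``deterministic_trials`` mode the draws are
    standardized to exact mean 0 and exact sample sd sigma (ddof=1), which
    makes a model's t statistic an exact function of its planted effect —
    the mode used for model populations, where between-model correlations
    must equal the planted latent coupling rather than an attenuated
    version of it.
    """
    z = rng.standard_normal(n)
    if cfg.deterministic_trials and n >= 2:
        z = (z - z.mean()) / z.std(ddof=1)
    return (cfg.noise_sigma if sigma is None else sigma) * z


def generate_world(
    config: SyntheticConfig, protocols: tuple[str, ...] = PROTOCOLS
) -> SyntheticWorld:
    """Generate a fully self-contained world with the configured planted effects.

    Deterministic given ``config.seed`` (bit-identical on repetition).
    Raises if the requested geometry is infeasible (e.g., a rescue effect
    larger than the discourse/sentence token ratio can produce).
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    vectors: dict[str, np.ndarray] = {}
    sets: dict[str, StimulusSet] = {}

    for i in range(cfg.vocab_size):
        vectors[f"w{i:04d}"] = _unit(rng, cfg.dim)

    if "chwilla" in protocols:
        sets["chwilla"] = _generate_chwilla(cfg, rng, vectors)
    if "metusalem" in protocols:
        sets["metusalem"] = _generate_metusalem(cfg, rng, vectors)

    lexicon = StaticLexicon(
        vectors=vectors,
        dim=cfg.dim,
        oov_policy="skip",
        case_policy="lower",
        name=f"synthetic-lexicon-seed{cfg.seed}",
    )
    aware = OrderAwareEncoder(
        lexicon, decay=cfg.encoder_decay, hash_scale=cfg.encoder_hash_scale
    )
    if "mckoon" in protocols:
        # mutate the lexicon's own dict: word-order item words must be
        # visible to both the lexicon and the encoders built on it
        sets["mckoon"] = _generate_mckoon(cfg, rng, lexicon.vectors, aware)

    world = SyntheticWorld(
        config=cfg,
        lexicon=lexicon,
        order_aware_encoder=aware,
        order_blind_encoder=OrderBlindEncoder(lexicon),
        stimulus_sets=sets,
        truth={
            "related_gap": cfg.related_gap,
            "rescue_delta": cfg.rescue_delta,
            "order_effect": cfg.order_effect,
            "noise_sigma": cfg.noise_sigma,
        },
    )
    return world


def _generate_chwilla(
    cfg: SyntheticConfig, rng: np.random.Generator, vectors: dict[str, np.ndarray]
) -> StimulusSet:
    pairs = []
    for related, gap, tag in ((True, cfg.related_gap, "rel"), (False, 0.0, "unr")):
        deviations = _trial_deviations(rng, cfg.n_chwilla_pairs, cfg)
        for i in range(cfg.n_chwilla_pairs):
            prime, target = f"{tag}{i:03d}a", f"{tag}{i:03d}b"
            v1 = _unit(rng, cfg.dim)
            vectors[prime] = v1
            vectors[target] = _plant_cosine(rng, v1, gap + deviations[i])
            pairs.append(ChwillaPair(prime=prime, target=target, related=related))
    return StimulusSet("chwilla", pairs, provenance="synthetic priming pairs")


def _metusalem_theta(cfg: SyntheticConfig, rescue: float) -> float:
    """Discourse-token tilt angle that yields the requested rescue effect.

    With n_s sentence tokens along the sentence anchor e1 and n_d discourse
    tokens along cos(theta) e1 + sin(theta) e2 (e2 = the related-target
    direction), the context mean has cosine
    n_d sin(theta) / ||n_s e1 + n_d u_theta|| to the related target, while
    the sentence mean stays orthogonal to both related and unrelated
    targets; that cosine is the planted rescue effect.
    """
    if rescue == 0.0:
        return 0.0
    n_s, n_d = cfg.n_sentence_tokens, cfg.n_discourse_tokens

    def achieved(theta: float) -> float:
        m_e1 = n_s + n_d * np.cos(theta)
        m_e2 = n_d * np.sin(theta)
        return m_e2 / np.hypot(m_e1, m_e2)

    max_rescue = achieved(np.pi / 2)
    if abs(rescue) > max_rescue:
        raise ValueError(
            f"rescue effect {rescue} infeasible: with "
            f"{n_s} sentence and {n_d} discourse tokens the maximum "
            f"achievable rescue is {max_rescue:.3f}; lower rescue_delta or "
            f"raise n_discourse_tokens"
        )
    return brentq(lambda th: achieved(th) - rescue, -np.pi / 2, np.pi / 2)


def _generate_metusalem(
    cfg: SyntheticConfig, rng: np.random.Generator, vectors: dict[str, np.ndarray]
) -> StimulusSet:
    if cfg.dim < 5:
        raise ValueError(
            "discourse items need dim >= 5 (four anchor directions plus noise)"
        )
    n = cfg.n_metusalem_items
    base_theta = _metusalem_theta(cfg, cfg.rescue_delta)
    if cfg.deterministic_trials:
        # plant per-item effects exactly; no token noise
        rescues = cfg.rescue_delta + _trial_deviations(rng, n, cfg)
        advs = np.clip(cfg.related_gap + _trial_deviations(rng, n, cfg), -0.99, 0.99)
        thetas = np.array([_metusalem_theta(cfg, r) for r in rescues])
        token_sigma = 0.0
    else:
        advs = np.full(n, cfg.related_gap)
        thetas = np.full(n, base_theta)
        token_sigma = cfg.noise_sigma
    items = []
    for i in range(n):
        basis, _ = np.linalg.qr(rng.standard_normal((cfg.dim, 4)))
        e1, e2, e3, e4 = basis.T  # sentence / related / unrelated / expected-residual
        adv, theta = float(advs[i]), float(thetas[i])
        u_theta = np.cos(theta) * e1 + np.sin(theta) * e2

        sent_words, disc_words = [], []
        for j in range(cfg.n_sentence_tokens):
            w = f"m{i:03d}s{j}"
            vectors[w] = _noisy_token(rng, e1, token_sigma)
            sent_words.append(w)
        for j in range(cfg.n_discourse_tokens):
            w = f"m{i:03d}d{j}"
            vectors[w] = _noisy_token(rng, u_theta, token_sigma)
            disc_words.append(w)
        expected, related, unrelated = f"m{i:03d}e", f"m{i:03d}r", f"m{i:03d}u"
        vectors[expected] = adv * e1 + np.sqrt(1.0 - adv * adv) * e4
        vectors[related] = e2
        vectors[unrelated] = e3
        items.append(
            MetusalemItem(
                item_id=f"syn-met-{i:03d}",
                discourse=" ".join(disc_words),
                sentence=" ".join(sent_words),
                expected=expected,
                related=related,
                unrelated=unrelated,
            )
        )
    return StimulusSet("metusalem", items, provenance="synthetic discourse items")


def _generate_mckoon(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    vectors: dict[str, np.ndarray],
    encoder: OrderAwareEncoder,
) -> StimulusSet:
    """Word-order items: context and control sentences share one word
    multiset; the cue word leads the context sentence and trails the
    control sentence.  The cue's projection onto the target is calibrated
    per item so the order-aware encoder's context-minus-control cosine
    difference equals the planted (noisy) per-item effect exactly."""
    n_tok = cfg.n_mckoon_tokens
    if n_tok < 2:
        raise ValueError("word-order items need at least 2 tokens per sentence")
    deviations = _trial_deviations(rng, cfg.n_mckoon_items, cfg, cfg.mckoon_noise_sigma)
    items = []
    for i in range(cfg.n_mckoon_items):
        target_word, cue_word = f"k{i:03d}t", f"k{i:03d}c"
        other_words = [f"k{i:03d}o{j}" for j in range(n_tok - 1)]
        target = _unit(rng, cfg.dim)
        vectors[target_word] = target
        for w in other_words:
            vectors[w] = _unit_orthogonal(rng, target)
        u_res = _unit_orthogonal(rng, target)  # cue residual direction

        ctx_tokens = [cue_word] + other_words
        ctl_tokens = other_words + [cue_word]
        weights = cfg.encoder_decay ** np.arange(n_tok)
        wsum = weights.sum()
        others = np.stack([vectors[w] for w in other_words])
        base_ctx = weights[1:] @ others / wsum  # others occupy positions 1..n-1
        base_ctl = weights[:-1] @ others / wsum  # others occupy positions 0..n-2
        hash_ctx = _bigram_term(encoder, ctx_tokens)
        hash_ctl = _bigram_term(encoder, ctl_tokens)
        w_cue_ctx, w_cue_ctl = weights[0] / wsum, weights[-1] / wsum

        planted = float(np.clip(cfg.order_effect + deviations[i], -0.9, 0.9))

        def diff(a: float) -> float:
            cue = a * target + np.sqrt(1.0 - a * a) * u_res
            s_ctx = base_ctx + w_cue_ctx * cue + hash_ctx
            s_ctl = base_ctl + w_cue_ctl * cue + hash_ctl
            return float(
                s_ctx @ target / np.linalg.norm(s_ctx)
                - s_ctl @ target / np.linalg.norm(s_ctl)
            )

        lo, hi = -0.999, 0.999
        if not (diff(lo) <= planted <= diff(hi)):
            raise ValueError(
                f"order_effect={cfg.order_effect} infeasible for item {i}: the "
                f"achievable range is [{diff(lo):.3f}, {diff(hi):.3f}]; lower "
                f"order_effect or raise encoder_decay contrast"
            )
        a = brentq(lambda x: diff(x) - planted, lo, hi, xtol=1e-12)
        vectors[cue_word] = a * target + np.sqrt(1.0 - a * a) * u_res
        items.append(
            McKoonItem(
                item_id=f"syn-mck-{i:03d}",
                context_sentence=" ".join(ctx_tokens),
                control_sentence=" ".join(ctl_tokens),
                target=target_word,
            )
        )
    return StimulusSet("mckoon", items, provenance="synthetic word-order items")


def _bigram_term(encoder: OrderAwareEncoder, tokens: list[str]) -> np.ndarray:
    if len(tokens) < 2 or encoder.hash_scale <= 0:
        return np.zeros(encoder.dim)
    dirs = np.stack(
        [encoder._bigram_direction(a, b) for a, b in zip(tokens, tokens[1:])]
    )
    return encoder.hash_scale * dirs.mean(axis=0)


# ---------------------------------------------------------------------------
# Model populations
# ---------------------------------------------------------------------------


ORDER_EFFECT_SCALE = 0.3  # keeps the word-order effect inside the encoder's range
# Per-item heterogeneity of the word-order effect in population worlds.  The
# word-order effect is geometrically capped well below the rescue effect, so
# with a common heterogeneity an order-aware model's word-order t would sit
# an order of magnitude below its discourse t; this tighter value gives the
# two inference tasks comparable t scales for order-aware models, matching
# the scenario the population emulates (order-aware models perform
# comparably on both inference tasks; order-blind models collapse on one).
POPULATION_MCKOON_SIGMA = 0.01


def generate_model_population(
    config: SyntheticConfig,
    n_static: int = 22,
    n_contextual: int = 23,
    quality_range: tuple[float, float] = (0.1, 0.75),
    coupling: float = 0.85,
    protocols: tuple[str, ...] = PROTOCOLS,
) -> list[SyntheticModel]:
    """Generate backends of graded quality for correlation experiments.

    Each model draws a latent (semantic quality, inference quality) pair
    from a bivariate normal with the given per-class ``coupling``
    correlation; the semantic quality becomes the model's planted pairwise
    gap and expected-word advantage, the inference quality its rescue
    effect and (scaled) word-order effect.  Population worlds use
    deterministic trials, so each model's t score is an exact function of
    its qualities and the between-model coupling is exactly the planted
    correlation.  Static models expose the order-blind lexicon pathway
    (and therefore null out on the word-order task); contextual models
    expose the order-aware encoder.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must lie in [-1, 1], got {coupling}")
    lo, hi = quality_range
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("quality_range must satisfy 0 <= lo < hi <= 1")
    if min(n_static, n_contextual) < 3:
        raise ValueError("need >= 3 models per class")

    root = np.random.SeedSequence(config.seed)
    latent_seed, *world_seeds = root.spawn(1 + n_static + n_contextual)
    rng = np.random.default_rng(latent_seed)
    cov = np.array([[1.0, coupling], [coupling, 1.0]])
    mu, sd = (lo + hi) / 2.0, (hi - lo) / 6.0

    # one shared quality ladder: the i-th model of each class gets the same
    # latent qualities, so class contrasts reflect architecture (order-blind
    # vs order-aware) rather than sampling luck of the quality draws
    ladder = rng.multivariate_normal(
        np.zeros(2), cov, size=max(n_static, n_contextual)
    )

    models: list[SyntheticModel] = []
    specs = [("static", i) for i in range(n_static)] + [
        ("contextual", i) for i in range(n_contextual)
    ]
    for (model_class, idx), wseed in zip(specs, world_seeds):
        z = ladder[idx]
        q_sem = float(np.clip(mu + sd * z[0], lo, hi))
        q_inf = float(np.clip(mu + sd * z[1], lo, hi))
        sub_cfg = replace(
            config,
            related_gap=q_sem,
            rescue_delta=q_inf,
            order_effect=ORDER_EFFECT_SCALE * q_inf,
            mckoon_noise_sigma=POPULATION_MCKOON_SIGMA,
            deterministic_trials=True,
            seed=int(wseed.generate_state(1)[0] % (2**31)),
        )
        world = generate_world(sub_cfg, protocols=protocols)
        name = f"{model_class}-lm-{idx:02d}"
        if model_class == "static":
            backend = world.lexicon
            backend.name = name
        else:
            backend = world.order_aware_encoder
            backend.name = name
        models.append(
            SyntheticModel(
                name=name,
                model_class=model_class,
                backend=backend,
                stimulus_sets=world.stimulus_sets,
                quality_semantics=q_sem,
                quality_inference=q_inf,
            )
        )
    return models


def evaluate_population(
    models: list[SyntheticModel], tasks: tuple[str, ...] | None = None
):
    """Run the task battery for every model; returns the model records."""
    from .scoring import TASKS, run_task_battery

    return [
        run_task_battery(m.backend, m.stimulus_sets, tasks=tasks or TASKS)
        for m in models
    ]
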