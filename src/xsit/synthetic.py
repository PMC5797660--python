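"""Synthetic caregiver--infant corpora with planted gold lexicons.

Real transcribed interaction data couples each utterance with a handful of
visible objects and one jointly-attended object, and the attended object's
name occurs in only a fraction of utterances, surrounded by frequent but
irrelevant words.  The generator reproduces that structure so that every
learner and metric in the package can be exercised without external data:

* each planted *referent word* names exactly one object (several words may
  name the same object, as with "kitty"/"kittycats");
* each situation shows 1..max_visible objects, one of them attended;
* with probability ``p_referent_word`` one of the attended object's names is
  inserted into the utterance; remaining tokens are fillers (Zipf-skewed,
  mimicking frequent function words) or, occasionally, names of other
  objects;
* with prosody on, referent-word positions get pitch-prominence values drawn
  around ``prominence_mean`` while other words scatter around zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, GoldLexicon, Situation


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus generator.

    Defaults give a desk-scale corpus that is reliably learnable in minutes.
    ``hard_mode()`` lowers ``p_referent_word`` to the 23% referent-naming
    rate observed in transcribed mother-infant play sessions.
    """

    n_objects: int = 17
    n_referent_words: int = 37
    n_filler_words: int = 380
    n_situations: int = 600
    max_visible: int = 7
    p_referent_word: float = 0.7
    utterance_length: tuple[int, int] = (2, 6)
    p_other_gold: float = 0.1
    zipf_exponent: float = 1.0
    uniform_fillers: bool = False
    p_misattention: float = 0.0
    prosody_mode: bool = False
    prominence_mean: float = 30.0
    prominence_sd: float = 5.0
    baseline_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1 or self.n_referent_words < 1 or self.n_situations < 1:
            raise ValueError("object, referent-word and situation counts must be positive")
        if self.n_filler_words < 0:
            raise ValueError("n_filler_words must be non-negative")
        if self.max_visible < 1:
            raise ValueError("max_visible must be >= 1")
        for name in ("p_referent_word", "p_other_gold", "p_misattention"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.utterance_length
        if lo < 1 or hi < lo:
            raise ValueError("utterance_length must satisfy 1 <= min <= max")
        if self.n_referent_words < self.n_objects:
            raise ValueError("need at least one referent word per object")

    @classmethod
    def hard_mode(cls, **overrides) -> "GeneratorConfig":
        overrides.setdefault("p_referent_word", 0.23)
        return cls(**overrides)


def planted_lexicon(config: GeneratorConfig) -> tuple[GoldLexicon, dict[str, str], dict[str, list[str]]]:
    """The gold lexicon implied by a config, before any corpus is drawn.

    Referent words are assigned to objects round-robin, so every object has
    at least one name and each name maps to exactly one object.  Returns the
    lexicon plus word->object and object->words maps.
    """
    objects = [f"obj{j:02d}" for j in range(config.n_objects)]
    words = [f"name{i:02d}" for i in range(config.n_referent_words)]
    word_to_object = {w: objects[i % config.n_objects] for i, w in enumerate(words)}
    object_words: dict[str, list[str]] = {o: [] for o in objects}
    for w, o in word_to_object.items():
        object_words[o].append(w)
    gold = GoldLexicon({(w, o) for w, o in word_to_object.items()})
    return gold, word_to_object, object_words


def generate_prosody(
    situation: Situation,
    gold: GoldLexicon,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[float, ...]:
    """Per-word prosodic feature values for one situation.

    Positions whose token names the attended object draw from
    Normal(prominence_mean, prominence_sd); all other positions from
    Normal(0, baseline_sd).  Units are Hz (pitch-percentile differences).
    """
    attended_names = {w for w, o in gold.pairs if o == situation.attended_object}
    values = []
    for token in situation.words:
        if token in attended_names:
            values.append(config.prominence_mean + config.prominence_sd * rng.standard_normal())
        else:
            values.append(config.baseline_sd * rng.standard_normal())
    return tuple(values)


def _filler_weights(config: GeneratorConfig) -> np.ndarray | None:
    if config.n_filler_words == 0:
        return None
    if config.uniform_fillers:
        w = np.ones(config.n_filler_words)
    else:
        w = 1.0 / np.arange(1, config.n_filler_words + 1) ** config.zipf_exponent
    return w / w.sum()


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GoldLexicon]:
    """Draw a corpus and its planted gold lexicon, deterministically by seed."""
    rng = np.random.default_rng(config.seed)
    gold, word_to_object, object_words = planted_lexicon(config)
    objects = [f"obj{j:02d}" for j in range(config.n_objects)]
    fillers = [f"filler{i:03d}" for i in range(config.n_filler_words)]
    filler_p = _filler_weights(config)
    all_gold_words = list(word_to_object)
    lo, hi = config.utterance_length

    situations: list[Situation] = []
    for i in range(1, config.n_situations + 1):
        n_visible = int(rng.integers(1, min(config.max_visible, config.n_objects) + 1))
        visible = [objects[j] for j in rng.choice(config.n_objects, n_visible, replace=False)]
        attended = visible[int(rng.integers(n_visible))]
        if config.p_misattention > 0 and rng.random() < config.p_misattention:
            attended = visible[int(rng.integers(n_visible))]
        length = int(rng.integers(lo, hi + 1))

        include_referent = rng.random() < config.p_referent_word
        referent_word = None
        if include_referent:
            names = object_words[attended]
            referent_word = names[int(rng.integers(len(names)))]

        n_noise = length - (1 if referent_word else 0)
        tokens: list[str] = []
        other_gold = [w for w in all_gold_words if word_to_object[w] != attended]
        for _ in range(max(n_noise, 0)):
            use_gold = other_gold and (
                filler_p is None or rng.random() < config.p_other_gold
            )
            if use_gold:
                tokens.append(other_gold[int(rng.integers(len(other_gold)))])
            elif filler_p is not None:
                tokens.append(fillers[int(rng.choice(config.n_filler_words, p=filler_p))])
        if referent_word is not None:
            pos = int(rng.integers(len(tokens) + 1))
            tokens.insert(pos, referent_word)
        if not tokens:  # degenerate draw: keep utterances non-empty
            tokens = [fillers[0]] if fillers else [other_gold[0]]

        sit = Situation(
            index=i,
            words=tuple(tokens),
            visible_objects=frozenset(visible),
            attended_object=attended,
        )
        if config.prosody_mode:
            sit = Situation(
                index=i,
                words=sit.words,
                visible_objects=sit.visible_objects,
                attended_object=sit.attended_object,
                prosody=generate_prosody(sit, gold, config, rng),
            )
        situations.append(sit)

    corpus = Corpus(situations, objects)
    return corpus, gold


def micro_corpus(
    n_situations: int = 40, p_other: float = 0.5, seed: int = 0
) -> tuple[Corpus, GoldLexicon]:
    """Tiny two-object, two-word corpus for exact recovery checks.

    Every utterance contains the attended object's name; with probability
    ``p_other`` it also contains the other object's name, so a policy mapping
    both objects to the same word (or swapping names) cannot stay consistent.
    Both objects are always visible.
    """
    rng = np.random.default_rng(seed)
    objects = ["objA", "objB"]
    names = {"objA": "wordA", "objB": "wordB"}
    situations = []
    for i in range(1, n_situations + 1):
        attended = objects[int(rng.integers(2))]
        other = objects[1 - objects.index(attended)]
        tokens = [names[attended]]
        if rng.random() < p_other:
            tokens.append(names[other])
            rng.shuffle(tokens)
        situations.append(
            Situation(
                index=i,
                words=tuple(tokens),
                visible_objects=frozenset(objects),
                attended_object=attended,
            )
        )
    gold = GoldLexicon({(names[o], o) for o in objects})
    return Corpus(situations, objects), gold
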