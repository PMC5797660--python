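"""Lexicon readout and scoring: normalization, confusion matrix, referent
selection, thresholded lexicons, precision/recall/F sweeps, and the
co-occurrence baseline.

The learned word-object matrix QW is first normalized per object row (each
row divided by its own maximum) so objects are comparable regardless of how
often they were attended.  A lexicon at threshold t is every (word, object)
pair whose normalized value is at least t; precision, recall and F-score are
computed over *pairs* against the gold lexicon, and a threshold sweep picks
the best-F operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, GoldLexicon, Vocabulary
from .tabular import QWMatrix


@dataclass
class NormalizedQW:
    """Row-normalized word-object matrix (each object row's max is 1)."""

    values: np.ndarray
    objects: list[str]
    words: list[str]

    def word_column(self, word: str) -> np.ndarray:
        try:
            j = self.words.index(word)
        except ValueError:
            raise KeyError(f"word {word!r} not in vocabulary") from None
        return self.values[:, j]


@dataclass
class EvalScores:
    """Scores of one thresholded lexicon against the gold standard."""

    lexicon: set[tuple[str, str]]
    precision: float
    recall: float
    f_score: float
    threshold: float


@dataclass
class SweepCurve:
    """Scores across an increasing threshold grid, plus the best-F point."""

    points: list[EvalScores]
    best: EvalScores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [p.threshold for p in self.points],
                "precision": [p.precision for p in self.points],
                "recall": [p.recall for p in self.points],
                "f": [p.f_score for p in self.points],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def normalize_qw(qw: QWMatrix) -> NormalizedQW:
    """Divide each object row by its own maximum; all-zero rows stay zero."""
    values = np.array(qw.values, dtype=float)
    row_max = values.max(axis=1, keepdims=True)
    safe = np.where(row_max != 0.0, row_max, 1.0)
    return NormalizedQW(values / safe, list(qw.objects), list(qw.words))


def confusion_matrix(
    nqw: NormalizedQW, gold: GoldLexicon, vocab: Vocabulary
) -> pd.DataFrame:
    """Gold-words x objects slice of the normalized matrix.

    Row per gold word, column per object; entry = the word's normalized value
    for that object.  Raises if any gold word is missing from the vocabulary.
    """
    missing = [w for w in gold.gold_words if w not in vocab]
    if missing:
        raise KeyError(f"gold words not in vocabulary: {missing}")
    rows = [nqw.word_column(w) for w in gold.gold_words]
    return pd.DataFrame(np.stack(rows), index=gold.gold_words, columns=nqw.objects)


def select_referent(nqw: NormalizedQW, word: str) -> str:
    """Object with the maximal normalized value for ``word`` (ties -> lowest
    object index)."""
    column = nqw.word_column(word)
    return nqw.objects[int(np.argmax(column))]


def extract_lexicon(nqw: NormalizedQW, threshold: float) -> set[tuple[str, str]]:
    """Every (word, object) pair whose normalized value is >= threshold."""
    rows, cols = np.nonzero(nqw.values >= threshold)
    return {(nqw.words[c], nqw.objects[r]) for r, c in zip(rows, cols)}


def score_lexicon(
    lexicon: set[tuple[str, str]],
    gold: GoldLexicon,
    threshold: float = float("nan"),
    recall_denominator: str = "pairs",
) -> EvalScores:
    """Pair-level precision, recall, and F-score against the gold lexicon.

    An empty predicted lexicon scores 0 on all three by convention; F is the
    harmonic mean 2PR/(P+R) when P+R > 0, else 0.  Recall divides by the
    number of gold pairs by default; ``recall_denominator="words"`` divides
    by the number of distinct gold words instead (the two differ only when a
    word has several referents).
    """
    if recall_denominator not in ("pairs", "words"):
        raise ValueError("recall_denominator must be 'pairs' or 'words'")
    correct = len(lexicon & gold.pairs)
    denom_n = (
        len(gold.pairs) if recall_denominator == "pairs" else len(gold.gold_words)
    )
    precision = correct / len(lexicon) if lexicon else 0.0
    recall = correct / denom_n if denom_n else 0.0
    denom = precision + recall
    f_score = 2.0 * precision * recall / denom if denom > 0 else 0.0
    return EvalScores(set(lexicon), precision, recall, f_score, threshold)


def threshold_sweep(
    nqw: NormalizedQW,
    gold: GoldLexicon,
    thresholds: Sequence[float] | None = None,
) -> SweepCurve:
    """Score lexicons across a strictly-increasing threshold grid.

    Defaults to 0, 0.01, ..., 1.  Best point = maximum F-score, lowest
    threshold on ties.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    points = [
        score_lexicon(extract_lexicon(nqw, t), gold, threshold=t)
        for t in thresholds
    ]
    best = max(points, key=lambda p: (p.f_score, -p.threshold))
    return SweepCurve(points, best)


def cooc_baseline(
    corpus: Corpus, vocab: Vocabulary, count_visible: bool = False
) -> QWMatrix:
    """Co-occurrence association baseline (COOC).

    Entry (object j, word w) counts the situations in which w occurs in the
    utterance while j is the attended object (a word occurring twice in one
    utterance counts once).  With ``count_visible`` every visible object of
    the situation is credited instead of only the attended one.  The result
    feeds the same normalize/sweep path as learned QW matrices.
    """
    qw = QWMatrix(corpus.object_inventory, vocab.words)
    counts = np.zeros(qw.shape)
    for sit in corpus:
        word_idx = sorted({vocab[t] for t in sit.words})
        targets = sorted(sit.visible_objects) if count_visible else [sit.attended_object]
        for label in targets:
            counts[corpus.object_index(label), word_idx] += 1.0
    qw.values = counts
    qw.counts = counts.sum(axis=1).astype(int)
    return qw


def evaluation_report(sweep: SweepCurve) -> dict:
    """JSON-serializable report of the best operating point."""
    best = sweep.best
    return {
        "threshold": best.threshold,
        "precision": best.precision,
        "recall": best.recall,
        "f_score": best.f_score,
        "lexicon": sorted(best.lexicon),
    }
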