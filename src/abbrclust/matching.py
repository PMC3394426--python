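"""Candidate-pair construction and threshold-sweep evaluation.

Full forms sharing an abbreviation are candidates for being the same
concept.  Matching is cast as a binary decision: a pair is predicted
same-concept when its score clears a cutoff (strictly below a threshold
for distance measures, strictly above for similarity measures), and the
prediction set is evaluated against gold concept identifiers by
precision, recall and F-measure.  This module provides:

* :func:`generate_candidates` — unordered pairs within abbreviation groups,
* :func:`score_pairs` — apply one of the registered measures,
* :func:`evaluate_at`, :func:`sweep`, :func:`best_threshold` — P/R/F at
  one or many thresholds, and the F-maximizing cutoff,
* :func:`pr_curve`, :func:`threshold_at_recall` — ranked prefix scans,
* :func:`compare_split_vs_mixed` — per-subset thresholds vs a single
  pooled threshold at a fixed target recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np

from . import measures as M

Direction = Literal["distance", "similarity"]

#: measure identifier -> whether smaller or larger scores indicate a match
MEASURE_DIRECTIONS: dict[str, Direction] = {
    "edit": "distance",
    "weighted_edit": "distance",
    "monge_elkan": "similarity",
    "soft_tfidf": "similarity",
    "bigram_dice": "similarity",
}

MEASURES: tuple[str, ...] = tuple(MEASURE_DIRECTIONS)


@dataclass(frozen=True)
class APair:
    """One abbreviation / full-form record with its gold concept id."""

    abbreviation: str
    full_form: str
    concept_id: str
    is_chemical: bool = False


@dataclass(frozen=True)
class CandidatePair:
    """Two A-pairs sharing an abbreviation, labeled by concept equality."""

    left: APair
    right: APair
    gold: bool
    score: float | None = None


@dataclass(frozen=True)
class SweepPoint:
    """Precision/recall/F at one threshold of one measure."""

    threshold: float
    precision: float
    recall: float
    f_measure: float
    n_predicted: int


class FixedRecallResult(NamedTuple):
    threshold: float
    precision: float
    recall: float
    n_selected: int


@dataclass(frozen=True)
class SplitComparison:
    """Per-subset vs pooled-threshold matching at a fixed target recall.

    ``chemical`` and ``others`` hold the per-subset operating points;
    ``all_precision``/``all_recall`` evaluate the union of the two
    per-subset prediction sets against the pooled gold; ``mixed`` is the
    single-threshold operating point on the concatenated set.
    """

    chemical: FixedRecallResult
    others: FixedRecallResult
    all_precision: float
    all_recall: float
    mixed: FixedRecallResult


def generate_candidates(apairs: Sequence[APair]) -> list[CandidatePair]:
    """All unordered pairs of A-pairs sharing an abbreviation.

    A group of k A-pairs yields k*(k-1)/2 candidates; the gold label is
    concept-id equality.  Output order is deterministic: sorted by
    abbreviation, then by the two full forms.
    """
    groups: dict[str, list[APair]] = {}
    for p in apairs:
        groups.setdefault(p.abbreviation, []).append(p)
    out: list[CandidatePair] = []
    for abbr in sorted(groups):
        members = sorted(
            groups[abbr], key=lambda p: (p.full_form, p.concept_id)
        )
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                left, right = members[i], members[j]
                out.append(
                    CandidatePair(
                        left=left,
                        right=right,
                        gold=(left.concept_id == right.concept_id),
                    )
                )
    return out


def score_pairs(
    pairs: Sequence[CandidatePair],
    measure: str,
    *,
    weights: M.WeightVector | None = None,
    me_params: M.MongeElkanParams | None = None,
    stats: M.CorpusStats | None = None,
    soft_tfidf_cutoff: float = 0.9,
    ngram_n: int = 2,
    dice_denominator: str = "length",
    per_group_stats: bool = False,
) -> list[CandidatePair]:
    """Score every pair's (lowercased) full forms with one measure.

    For ``soft_tfidf`` the corpus statistics default to the union of all
    full forms in the input; ``per_group_stats=True`` instead builds one
    corpus per abbreviation group.  Input order is preserved.
    """
    if measure not in MEASURE_DIRECTIONS:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")

    def forms(pair: CandidatePair) -> tuple[str, str]:
        return pair.left.full_form.lower(), pair.right.full_form.lower()

    if measure == "edit":
        fn = lambda a, b, _: M.normalized_edit_distance(a, b)
    elif measure == "weighted_edit":
        w = weights or M.WeightVector()
        fn = lambda a, b, _: M.weighted_edit_distance(a, b, w)
    elif measure == "monge_elkan":
        params = me_params or M.MongeElkanParams()
        fn = lambda a, b, _: M.monge_elkan(a, b, params)
    elif measure == "bigram_dice":
        fn = lambda a, b, _: M.ngram_dice(a, b, ngram_n, dice_denominator)
    else:  # soft_tfidf
        if stats is not None:
            global_stats = stats
        elif not per_group_stats:
            corpus = {f for p in pairs for f in forms(p)}
            global_stats = M.build_corpus_stats(sorted(corpus)) if corpus else None
        else:
            global_stats = None
        group_cache: dict[str, M.CorpusStats] = {}

        def fn(a: str, b: str, pair: CandidatePair) -> float:
            if per_group_stats and stats is None:
                abbr = pair.left.abbreviation
                if abbr not in group_cache:
                    corpus = sorted(
                        {f for p in pairs if p.left.abbreviation == abbr for f in forms(p)}
                    )
                    group_cache[abbr] = M.build_corpus_stats(corpus)
                st = group_cache[abbr]
            else:
                st = global_stats
            return M.soft_tfidf(a, b, st, soft_tfidf_cutoff)

    return [replace(p, score=float(fn(*forms(p), p))) for p in pairs]


def _score_gold_arrays(pairs: Sequence[CandidatePair]) -> tuple[np.ndarray, np.ndarray]:
    if any(p.score is None for p in pairs):
        raise ValueError("all pairs must be scored before evaluation")
    scores = np.array([p.score for p in pairs], dtype=np.float64)
    gold = np.array([p.gold for p in pairs], dtype=bool)
    return scores, gold


def _point(threshold: float, tp: int, n_pred: int, n_pos: int) -> SweepPoint:
    precision = tp / n_pred if n_pred > 0 else 0.0
    recall = tp / n_pos if n_pos > 0 else 0.0
    f = (
        2.0 * precision * recall / (precision + recall)
        if precision > 0.0 and recall > 0.0
        else 0.0
    )
    return SweepPoint(float(threshold), precision, recall, f, n_pred)


def evaluate_at(
    pairs: Sequence[CandidatePair], threshold: float, direction: Direction
) -> SweepPoint:
    """P/R/F of the strict-cutoff decision at one threshold.

    A pair is predicted same-concept iff ``score < threshold`` (distance)
    or ``score > threshold`` (similarity).  Precision is 0 when nothing is
    predicted; recall is 0 when there are no gold positives.
    """
    scores, gold = _score_gold_arrays(pairs)
    if direction == "distance":
        pred = scores < threshold
    elif direction == "similarity":
        pred = scores > threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    tp = int(np.count_nonzero(pred & gold))
    return _point(threshold, tp, int(pred.sum()), int(gold.sum()))


def coarse_grid(step: float = 0.05) -> list[float]:
    """Thresholds 0.00, step, ..., 1.00."""
    n = round(1.0 / step)
    return [round(i * step, 10) for i in range(n + 1)]


def fine_grid(lo: float = 0.9, hi: float = 0.995, step: float = 0.005) -> list[float]:
    """The finer grid used where the F peak sits close to 1 (SoftTFIDF)."""
    n = round((hi - lo) / step)
    return [round(lo + i * step, 10) for i in range(n + 1)]


def observed_grid(pairs: Sequence[CandidatePair], direction: Direction) -> list[float]:
    """Every distinct score as a candidate threshold, plus one sentinel.

    With strict cutoffs, a distance threshold equal to an observed score v
    predicts exactly the pairs scoring below v; the +inf (distance) or
    -inf (similarity) sentinel realizes the all-predicted set.
    """
    scores = sorted({float(p.score) for p in pairs})
    if direction == "distance":
        return scores + [math.inf]
    return [-math.inf] + scores


def sweep(
    pairs: Sequence[CandidatePair], direction: Direction, grid: Sequence[float]
) -> list[SweepPoint]:
    """One :class:`SweepPoint` per threshold of a sorted grid."""
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    return [evaluate_at(pairs, t, direction) for t in grid]


def best_threshold(
    sweep_result: Sequence[SweepPoint], direction: Direction = "distance"
) -> SweepPoint:
    """The F-maximizing point; ties go to the stricter threshold
    (smaller for distances, larger for similarities)."""
    if not sweep_result:
        raise ValueError("sweep result must be non-empty")
    stricter = min if direction == "distance" else max
    best = sweep_result[0]
    for pt in sweep_result[1:]:
        if pt.f_measure > best.f_measure or (
            pt.f_measure == best.f_measure
            and stricter(pt.threshold, best.threshold) == pt.threshold
        ):
            best = pt
    return best


def _ranked(
    pairs: Sequence[CandidatePair], direction: Direction
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Scores and gold labels sorted best-first, plus tie-group end indices."""
    scores, gold = _score_gold_arrays(pairs)
    order = np.argsort(scores, kind="stable")
    if direction == "similarity":
        order = order[::-1]
    elif direction != "distance":
        raise ValueError(f"unknown direction {direction!r}")
    s = scores[order]
    g = gold[order]
    ends: list[int] = []
    n = len(s)
    for i in range(n):
        if i == n - 1 or s[i] != s[i + 1]:
            ends.append(i + 1)  # prefix length ending this tie group
    return s, g, ends


def pr_curve(
    pairs: Sequence[CandidatePair], direction: Direction
) -> list[tuple[float, float]]:
    """(recall, precision) after each tie group of the best-score-first ranking.

    Ties in score are grouped so every point is realizable by a strict
    threshold (plus the all-predicted sentinel).
    """
    s, g, ends = _ranked(pairs, direction)
    n_pos = int(g.sum())
    if n_pos == 0:
        raise ValueError("pr_curve requires at least one gold-positive pair")
    cum_tp = np.cumsum(g)
    return [(float(cum_tp[e - 1] / n_pos), float(cum_tp[e - 1] / e)) for e in ends]


def _prefix_at_recall(
    pairs: Sequence[CandidatePair], direction: Direction, target_recall: float
) -> tuple[FixedRecallResult, int, int]:
    """Closest-recall prefix; returns (result, tp_selected, n_gold_positive)."""
    if not (0.0 < target_recall <= 1.0):
        raise ValueError("target recall must be in (0, 1]")
    s, g, ends = _ranked(pairs, direction)
    n_pos = int(g.sum())
    if n_pos == 0:
        raise ValueError("fixed-recall scan requires at least one gold positive")
    cum_tp = np.cumsum(g)
    # empty prefix: the strict cutoff at the best observed score predicts nothing
    empty_threshold = float(s[0])
    best_prefix = 0
    best_gap = abs(0.0 - target_recall)
    for e in ends:
        gap = abs(cum_tp[e - 1] / n_pos - target_recall)
        if gap < best_gap:
            best_gap = gap
            best_prefix = e
    if best_prefix == 0:
        return FixedRecallResult(empty_threshold, 0.0, 0.0, 0), 0, n_pos
    tp = int(cum_tp[best_prefix - 1])
    threshold = float(s[best_prefix - 1])  # score of the last included pair
    return (
        FixedRecallResult(threshold, tp / best_prefix, tp / n_pos, best_prefix),
        tp,
        n_pos,
    )


def threshold_at_recall(
    pairs: Sequence[CandidatePair], direction: Direction, target_recall: float
) -> FixedRecallResult:
    """Operating point whose recall is closest to ``target_recall``.

    Scans ranked tie-group prefixes as :func:`pr_curve` does and returns
    the prefix minimizing ``|recall - target|`` (ties toward the smaller
    prefix).  The reported threshold is the score of the last included
    pair.
    """
    result, _, _ = _prefix_at_recall(pairs, direction, target_recall)
    return result


def compare_split_vs_mixed(
    chemical_pairs: Sequence[CandidatePair],
    other_pairs: Sequence[CandidatePair],
    target_recall: float = 0.8,
    direction: Direction = "distance",
) -> SplitComparison:
    """Discriminative-split experiment at a fixed target recall.

    Selects per-subset thresholds for the chemical and non-chemical pair
    sets separately, evaluates the union of the two prediction sets
    against the pooled gold, and compares with the single threshold chosen
    on the concatenated set.  Both subsets must contain gold positives.
    """
    if not chemical_pairs or not other_pairs:
        raise ValueError("both subsets must be non-empty")
    chem, tp_c, pos_c = _prefix_at_recall(chemical_pairs, direction, target_recall)
    oth, tp_o, pos_o = _prefix_at_recall(other_pairs, direction, target_recall)
    n_sel = chem.n_selected + oth.n_selected
    tp = tp_c + tp_o
    all_precision = tp / n_sel if n_sel > 0 else 0.0
    all_recall = tp / (pos_c + pos_o)
    mixed = threshold_at_recall(
        list(chemical_pairs) + list(other_pairs), direction, target_recall
    )
    return SplitComparison(
        chemical=chem,
        others=oth,
        all_precision=all_precision,
        all_recall=all_recall,
        mixed=mixed,
    )
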