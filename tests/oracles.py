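"""Brute-force reference implementations used to validate the package.

Everything here recomputes quantities from first principles — recursive
enumeration of edit scripts, enumeration of monotone alignments,
definitional transliterations, exhaustive prefix/threshold scans — and is
deliberately independent of the dynamic-programming / vectorized code
paths in ``abbrclust``.
"""

from __future__ import annotations

import functools
import math
from collections import Counter

from abbrclust.matching import CandidatePair
from abbrclust.measures import MongeElkanParams


def lev_recursive(s1: str, s2: str) -> int:
    """Levenshtein distance by plain memoized recursion over edit scripts."""

    @functools.lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(s1):
            return len(s2) - j
        if j == len(s2):
            return len(s1) - i
        best = go(i + 1, j + 1) + (0 if s1[i] == s2[j] else 1)
        best = min(best, go(i + 1, j) + 1)  # delete s1[i]
        best = min(best, go(i, j + 1) + 1)  # insert s2[j]
        return best

    return go(0, 0)


def weighted_script_min_cost(s1: str, s2: str, wmap: dict[str, float]) -> float:
    """Minimum edit-script cost with per-letter insertion/deletion costs."""

    def cost(c: str) -> float:
        return wmap.get(c, 1.0) if "a" <= c <= "z" else 1.0

    @functools.lru_cache(maxsize=None)
    def go(i: int, j: int) -> float:
        if i == len(s1):
            return sum(cost(c) for c in s2[j:])
        if j == len(s2):
            return sum(cost(c) for c in s1[i:])
        best = go(i + 1, j + 1) + (0.0 if s1[i] == s2[j] else 1.0)
        best = min(best, go(i + 1, j) + cost(s1[i]))
        best = min(best, go(i, j + 1) + cost(s2[j]))
        return best

    return go(0, 0)


def monge_elkan_enumeration(
    s1: str, s2: str, params: MongeElkanParams | None = None
) -> float:
    """Monge-Elkan score by enumerating every monotone character matching.

    A local alignment is a set of matched position pairs (i1,j1)<...<(ik,jk);
    its score is the sum of the character scores of the matched pairs minus
    an affine penalty alpha + beta*k for every internal run of unmatched
    characters between consecutive matches.  Leading and trailing unmatched
    characters are free (local alignment).
    """
    p = params or MongeElkanParams()
    n1, n2 = len(s1), len(s2)

    def char_score(a: str, b: str) -> float:
        if a == b:
            return p.match_score
        ca, cb = p.class_of(a), p.class_of(b)
        if ca >= 0 and ca == cb:
            return p.class_score
        return p.mismatch_score

    alpha, beta = p.gap_open_alpha, p.gap_extend_beta
    best = 0.0

    def rec(i: int, j: int, prev: tuple[int, int] | None, acc: float) -> None:
        nonlocal best
        if acc > best:
            best = acc
        for i2 in range(i, n1):
            for j2 in range(j, n2):
                pen = 0.0
                if prev is not None:
                    k1 = i2 - prev[0] - 1
                    k2 = j2 - prev[1] - 1
                    if k1 > 0:
                        pen += alpha + beta * k1
                    if k2 > 0:
                        pen += alpha + beta * k2
                rec(i2 + 1, j2 + 1, (i2, j2), acc + char_score(s1[i2], s2[j2]) - pen)

    rec(0, 0, None, 0.0)
    return max(0.0, best) / (p.match_score * min(n1, n2))


def jaro_definitional(s1: str, s2: str) -> float:
    """Direct transliteration of the windowed-matching Jaro definition."""
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return 0.0
    window = min(n1, n2) // 2
    used = [False] * n2
    seq1 = []
    for i in range(n1):
        for j in range(n2):
            if used[j] or abs(i - j) > window:
                continue
            if s1[i] == s2[j]:
                used[j] = True
                seq1.append(s1[i])
                break
    m = len(seq1)
    if m == 0:
        return 0.0
    seq2 = [s2[j] for j in range(n2) if used[j]]
    transposed = sum(a != b for a, b in zip(seq1, seq2))
    t = transposed / 2
    return (m / n1 + m / n2 + (m - t) / m) / 3


def jaro_winkler_definitional(s1: str, s2: str) -> float:
    j = jaro_definitional(s1, s2)
    p = 0
    while p < min(len(s1), len(s2)) and s1[p] == s2[p]:
        p += 1
    return j + min(p, 4) / 10 * (1 - j)


def soft_tfidf_definitional(
    s1: str, s2: str, corpus: list[str], a: float = 0.9
) -> float:
    """SoftTFIDF recomputed from scratch: DF by corpus scan, log-TF * log-IDF
    weights with L2 normalization, Jaro-Winkler max pairing above cutoff."""

    def df(word: str) -> int:
        return max(1, sum(word in s.split() for s in corpus))

    def weights(s: str) -> dict[str, float]:
        tf = Counter(s.split())
        raw = {
            w: math.log(c + 1) * math.log(len(corpus) / df(w)) for w, c in tf.items()
        }
        norm = math.sqrt(sum(v * v for v in raw.values()))
        return {w: (v / norm if norm else 0.0) for w, v in raw.items()}

    v1, v2 = weights(s1), weights(s2)
    total = 0.0
    for w in v1:
        sims = {wi: jaro_winkler_definitional(w, wi) for wi in set(s2.split())}
        best = max(sims.values())
        if best >= a:
            # deterministic argmax: highest similarity, lexicographically first
            w_star = min(wi for wi, s in sims.items() if s == best)
            total += v1[w] * v2[w_star] * best
    return total


def dice_greedy(s1: str, s2: str, n: int = 2, denominator: str = "length") -> float:
    """n-gram Dice with capped occurrence matching done greedily on lists."""
    if len(s1) < n or len(s2) < n:
        return 0.0
    g1 = [s1[i : i + n] for i in range(len(s1) - n + 1)]
    g2 = [s2[i : i + n] for i in range(len(s2) - n + 1)]
    used = [False] * len(g2)
    c = 0
    for g in g1:
        for j, h in enumerate(g2):
            if not used[j] and g == h:
                used[j] = True
                c += 1
                break
    denom = len(s1) + len(s2) if denominator == "length" else len(g1) + len(g2)
    return 2 * c / denom


def confusion_counts(
    pairs: list[CandidatePair], threshold: float, direction: str
) -> tuple[int, int, int]:
    """(TP, FP, FN) by explicit per-pair counting under a strict cutoff."""
    tp = fp = fn = 0
    for p in pairs:
        pred = p.score < threshold if direction == "distance" else p.score > threshold
        if pred and p.gold:
            tp += 1
        elif pred:
            fp += 1
        elif p.gold:
            fn += 1
    return tp, fp, fn


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * prec * rec / (prec + rec) if prec and rec else 0.0
    return prec, rec, f


def best_f_scan(
    pairs: list[CandidatePair], direction: str
) -> tuple[float, float, float, float]:
    """(threshold, P, R, F) maximizing F over every distinct score plus the
    all-predicted sentinel; F ties resolved toward the stricter threshold."""
    thresholds = sorted({p.score for p in pairs})
    thresholds = thresholds + [math.inf] if direction == "distance" else [-math.inf] + thresholds
    best = None
    for t in thresholds:
        p, r, f = prf(*confusion_counts(pairs, t, direction))
        if best is None:
            best = (t, p, r, f)
            continue
        better = f > best[3] or (
            f == best[3] and (t < best[0] if direction == "distance" else t > best[0])
        )
        if better:
            best = (t, p, r, f)
    return best


def ranked_prefixes(
    pairs: list[CandidatePair], direction: str
) -> list[tuple[int, float, float, float]]:
    """Tie-grouped prefix scan: (prefix size, last score, recall, precision)."""
    reverse = direction == "similarity"
    ordered = sorted(pairs, key=lambda p: (-p.score if reverse else p.score))
    n_pos = sum(p.gold for p in pairs)
    out = []
    tp = 0
    for i, p in enumerate(ordered, start=1):
        tp += p.gold
        if i == len(ordered) or ordered[i].score != p.score:
            out.append((i, p.score, tp / n_pos, tp / i))
    return out
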