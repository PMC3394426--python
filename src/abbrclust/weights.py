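"""Coordinate-descent learning of per-letter edit costs.

The weighted edit distance assigns each letter 'a'..'z' its own cost for
insertion and deletion.  Starting from the all-ones vector, the optimizer
visits the letters once in alphabetical order; for each letter it tries a
grid of candidate costs (0.0 to 1.0 in steps of 0.1 by default), rescores
every candidate pair, takes the best F-measure over the observed-score
threshold sweep, and fixes the F-maximizing cost before moving on.  A
single pass is performed — no convergence iteration.

The F-measure after each coordinate step can never drop, because the
incumbent cost is always among the candidates evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import weighted_edit_kernel
from .matching import CandidatePair, SweepPoint, _point
from .measures import ALPHABET, WeightVector


@dataclass(frozen=True)
class CoordinateStep:
    """Search record for one letter: candidates tried, winner, F reached."""

    character: str
    candidates: tuple[float, ...]
    f_values: tuple[float, ...]
    best_value: float
    best_f: float


@dataclass(frozen=True)
class OptimizationTrace:
    steps: tuple[CoordinateStep, ...]

    def best_f_sequence(self) -> list[float]:
        return [s.best_f for s in self.steps]


def _encode_pairs(
    pairs: Sequence[CandidatePair],
) -> tuple[list[tuple[np.ndarray, np.ndarray, int]], np.ndarray]:
    enc = []
    gold = np.empty(len(pairs), dtype=bool)
    for i, p in enumerate(pairs):
        a = p.left.full_form.lower()
        b = p.right.full_form.lower()
        enc.append(
            (
                np.array([ord(c) for c in a], dtype=np.int64),
                np.array([ord(c) for c in b], dtype=np.int64),
                max(len(a), len(b)),
            )
        )
        gold[i] = p.gold
    return enc, gold


def _rescore(enc, warr: np.ndarray) -> np.ndarray:
    out = np.empty(len(enc), dtype=np.float64)
    for i, (a, b, n) in enumerate(enc):
        out[i] = weighted_edit_kernel(a, b, warr) / n if n > 0 else 0.0
    return out


def _best_f_distance(scores: np.ndarray, gold: np.ndarray) -> SweepPoint:
    """F-maximizing strict distance cutoff over the observed-score grid.

    Candidate thresholds are the distinct scores (each predicts the pairs
    strictly below it) plus +inf; ties in F go to the smaller threshold.
    """
    n = scores.shape[0]
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    g = gold[order]
    n_pos = int(g.sum())
    cum_tp = np.cumsum(g)
    # prefix sizes realized by thresholds: start of every tie group, plus n
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    prefixes = np.r_[starts, n]
    thresholds = np.r_[s[starts], np.inf]
    best: SweepPoint | None = None
    for k, t in zip(prefixes, thresholds):
        tp = int(cum_tp[k - 1]) if k > 0 else 0
        pt = _point(float(t), tp, int(k), n_pos)
        if best is None or pt.f_measure > best.f_measure:
            best = pt
    return best


def evaluate_weight_vector(
    pairs: Sequence[CandidatePair], w: WeightVector
) -> SweepPoint:
    """Best-F operating point of the weighted edit distance under ``w``.

    Rescores all pairs and maximizes F over the observed-score threshold
    grid, exactly as :func:`abbrclust.matching.sweep` +
    :func:`abbrclust.matching.best_threshold` would.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    enc, gold = _encode_pairs(pairs)
    return _best_f_distance(_rescore(enc, w.as_array()), gold)


def optimize_weights(
    pairs: Sequence[CandidatePair],
    grid_step: float = 0.1,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[WeightVector, OptimizationTrace]:
    """Single-pass coordinate descent over the 26 per-letter edit costs.

    For each letter in alphabetical order the candidate costs are the
    ``grid_step`` grid over ``value_range`` (plus the incumbent cost, so a
    step can never lose F).  Each candidate is scored by the best
    F-measure of the weighted edit distance over the observed-score
    threshold sweep; ties prefer the cost closest to 1.0 (then the larger
    one), which keeps the optimizer from drifting on flat regions.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    lo, hi = value_range
    if not (0.0 <= lo < hi):
        raise ValueError("value_range must satisfy 0 <= lo < hi")
    enc, gold = _encode_pairs(pairs)
    if len(pairs) == 0 or not gold.any():
        raise ValueError("optimization requires at least one gold-positive pair")
    n_grid = round((hi - lo) / grid_step)
    grid = [round(lo + i * grid_step, 10) for i in range(n_grid + 1)]
    warr = np.ones(26, dtype=np.float64)
    steps: list[CoordinateStep] = []
    for idx, ch in enumerate(ALPHABET):
        incumbent = float(warr[idx])
        candidates = sorted(set(grid) | {incumbent})
        best_v = None
        best_f = -1.0
        f_values = []
        for v in candidates:
            warr[idx] = v
            pt = _best_f_distance(_rescore(enc, warr), gold)
            f_values.append(pt.f_measure)
            if (
                best_v is None
                or pt.f_measure > best_f
                or (
                    pt.f_measure == best_f
                    and (
                        abs(v - 1.0) < abs(best_v - 1.0)
                        or (abs(v - 1.0) == abs(best_v - 1.0) and v > best_v)
                    )
                )
            ):
                best_v = v
                best_f = pt.f_measure
        warr[idx] = best_v
        steps.append(
            CoordinateStep(
                character=ch,
                candidates=tuple(candidates),
                f_values=tuple(f_values),
                best_value=best_v,
                best_f=best_f,
            )
        )
    return WeightVector(warr), OptimizationTrace(tuple(steps))


def trace_to_rows(trace: OptimizationTrace) -> list[dict]:
    """Flatten a trace for TSV logging (one row per character)."""
    return [
        {
            "character": s.character,
            "best_value": s.best_value,
            "best_f": s.best_f,
            "candidates": ",".join(f"{v:g}" for v in s.candidates),
            "f_values": ",".join(f"{f:.6f}" for f in s.f_values),
        }
        for s in trace.steps
    ]
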