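"""TSV readers and writers for A-pairs, scored pairs and sweep results.

File formats (all UTF-8, tab-separated, with header):

* A-pairs: ``abbreviation  full_form  concept_id  is_chemical`` with
  is_chemical in {0, 1}.
* Scored pairs: ``abbreviation  full_form_1  full_form_2  concept_id_1
  concept_id_2  gold  score``.  The chemical flag is not part of this
  format; chemical and non-chemical pair sets live in separate files.
* Sweeps: ``threshold  precision  recall  f_measure  n_predicted``.
"""

from __future__ import annotations

import csv
from typing import Sequence

from .matching import APair, CandidatePair, SweepPoint

APAIR_COLUMNS = ("abbreviation", "full_form", "concept_id", "is_chemical")
SCORED_COLUMNS = (
    "abbreviation",
    "full_form_1",
    "full_form_2",
    "concept_id_1",
    "concept_id_2",
    "gold",
    "score",
)
SWEEP_COLUMNS = ("threshold", "precision", "recall", "f_measure", "n_predicted")


def read_apairs(path) -> list[APair]:
    """Parse an A-pair TSV, validating every row.

    Malformed rows (wrong column count, empty fields, is_chemical outside
    {0, 1}) are collected and reported together with their line numbers.
    """
    out: list[APair] = []
    errors: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != APAIR_COLUMNS:
            raise ValueError(
                f"{path}: expected header {list(APAIR_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                errors.append(f"line {lineno}: expected 4 columns, got {len(row)}")
                continue
            abbr, form, cid, flag = row
            if not abbr or not form or not cid:
                errors.append(f"line {lineno}: empty field")
                continue
            if flag not in ("0", "1"):
                errors.append(f"line {lineno}: is_chemical must be 0 or 1, got {flag!r}")
                continue
            out.append(APair(abbr, form, cid, flag == "1"))
    if errors:
        raise ValueError(f"{path}: malformed A-pair rows: " + "; ".join(errors))
    return out


def write_apairs(apairs: Sequence[APair], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(APAIR_COLUMNS)
        for p in apairs:
            writer.writerow(
                [p.abbreviation, p.full_form, p.concept_id, int(p.is_chemical)]
            )


def write_scored_pairs(pairs: Sequence[CandidatePair], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SCORED_COLUMNS)
        for p in pairs:
            writer.writerow(
                [
                    p.left.abbreviation,
                    p.left.full_form,
                    p.right.full_form,
                    p.left.concept_id,
                    p.right.concept_id,
                    int(p.gold),
                    "" if p.score is None else repr(p.score),
                ]
            )


def read_scored_pairs(path, is_chemical: bool = False) -> list[CandidatePair]:
    """Read a scored-pair TSV back into candidate pairs.

    The format does not carry the chemical flag; pass ``is_chemical`` to
    set it on the reconstructed A-pairs (it defaults to False).
    """
    out: list[CandidatePair] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != SCORED_COLUMNS:
            raise ValueError(
                f"{path}: expected header {list(SCORED_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns")
            abbr, f1, f2, c1, c2, gold, score = row
            out.append(
                CandidatePair(
                    left=APair(abbr, f1, c1, is_chemical),
                    right=APair(abbr, f2, c2, is_chemical),
                    gold=gold == "1",
                    score=float(score) if score else None,
                )
            )
    return out


def write_sweep(points: Sequence[SweepPoint], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SWEEP_COLUMNS)
        for pt in points:
            writer.writerow(
                [
                    repr(pt.threshold),
                    f"{pt.precision:.6f}",
                    f"{pt.recall:.6f}",
                    f"{pt.f_measure:.6f}",
                    pt.n_predicted,
                ]
            )
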