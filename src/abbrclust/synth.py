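"""Synthetic A-pair benchmark generator.

Real abbreviation dictionaries pose two coupled difficulties for
string-similarity clustering: the same abbreviation collides across
distinct concepts, and each concept surfaces through several spelling
variants.  For chemical names the problem is sharper — nomenclature
systems build names from a small morpheme inventory, so a single-character
edit (monoethyl vs monomethyl) can switch the concept entirely, while for
ordinary biomedical phrases small edits are almost always benign variants.

This module generates miniature datasets with exactly that structure:

* chemical concept names concatenated from nomenclature-like morphemes
  (multiplier prefixes, alkyl stems, suffixes, connector words);
* non-chemical names drawn from a packaged biomedical word list;
* same-concept spelling variants (hyphen/space swaps, plural inflection,
  benign character insertions) — for chemical names the benign edits never
  touch the discriminative stem characters;
* near-miss chemical neighbors: different-concept names at edit distance
  1-2 from an existing name, sharing its abbreviation (hard negatives);
* abbreviation collision groups of configurable mean size, so distinct
  concepts compete under one abbreviation.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .matching import APair

MULTIPLIERS = ("mono", "di", "tri", "tetra", "penta")
STEMS = ("meth", "eth", "prop", "but", "pent")
SUFFIXES = ("yl", "ol", "ane", "ene", "oxy")
CONNECTORS = ("glycol", "ether", "acid", "amine", "benzene")

#: morpheme swaps that change the concept while staying within edit distance 2
_NEAR_MISS_SWAPS: dict[str, tuple[str, ...]] = {
    "meth": ("eth",),
    "eth": ("meth",),
    "di": ("tri",),
    "tri": ("di",),
    "yl": ("ol",),
    "ol": ("yl", "oxy"),
    "oxy": ("ol",),
    "ane": ("ene",),
    "ene": ("ane",),
}

_ALT = lambda xs: "|".join(xs)
CHEM_TOKEN_RE = re.compile(
    rf"^(?:{_ALT(MULTIPLIERS)})?(?:(?:{_ALT(STEMS)})(?:{_ALT(SUFFIXES)})){{1,2}}$"
)
_DECOMP_RE = re.compile(
    rf"^(?P<mult>{_ALT(MULTIPLIERS)})?"
    rf"(?P<stem1>{_ALT(STEMS)})(?P<suf1>{_ALT(SUFFIXES)})"
    rf"(?:(?P<stem2>{_ALT(STEMS)})(?P<suf2>{_ALT(SUFFIXES)}))?$"
)


def is_chemical_grammar_name(name: str) -> bool:
    """True when every token is a connector or a well-formed morpheme compound."""
    tokens = name.split()
    if not tokens:
        return False
    return all(t in CONNECTORS or CHEM_TOKEN_RE.match(t) for t in tokens)


#: packaged biomedical-English word list for non-chemical full forms
WORDS = (
    "growth", "factor", "receptor", "protein", "binding", "clinical",
    "response", "gene", "expression", "tumor", "cell", "signal", "pathway",
    "acute", "chronic", "disease", "syndrome", "therapy", "treatment",
    "analysis", "assay", "blood", "plasma", "serum", "tissue", "liver",
    "kidney", "cardiac", "neural", "immune", "antibody", "antigen",
    "enzyme", "kinase", "transcription", "translation", "membrane",
    "nuclear", "mitochondrial", "oxidative", "stress", "inflammation",
    "infection", "bacterial", "viral", "human", "patient", "cohort",
    "trial", "randomized", "controlled", "dose", "inhibition",
    "activation", "regulation", "development", "differentiation",
    "proliferation", "apoptosis", "migration", "adhesion", "matrix",
    "collagen", "fibroblast", "epithelial", "endothelial", "muscle",
    "bone", "marrow", "stem", "progenitor", "lymphocyte", "macrophage",
    "cytokine", "hormone", "insulin", "glucose", "lipid", "cholesterol",
    "index", "rate",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``near_miss_rate`` is the probability that a chemical concept gets a
    distinct-concept neighbor within edit distance 2 sharing its
    abbreviation; ``variant_noise_rate`` is the per-character probability
    of a benign insertion inside a spelling variant.  The default sizes
    emulate, in miniature, a corpus with thousands of candidate pairs per
    subset; ``noise_chars_*`` are the letters whose insertions are benign
    within each subset, i.e. the characters a learned weight vector should
    discount.
    """

    n_concepts_chemical: int = 300
    n_concepts_other: int = 300
    variants_per_concept: float = 3.0
    collision_group_size: float = 3.0
    near_miss_rate: float = 0.3
    variant_noise_rate: float = 0.05
    noise_chars_chemical: tuple[str, ...] = ("e", "h", "p")
    noise_chars_other: tuple[str, ...] = ("x", "z", "u")
    match_letter_frequencies: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_concepts_chemical < 0 or self.n_concepts_other < 0:
            raise ValueError("concept counts must be >= 0")
        if self.variants_per_concept < 1:
            raise ValueError("variants_per_concept must be >= 1")
        if self.collision_group_size < 1:
            raise ValueError("collision_group_size must be >= 1")
        for p in (self.near_miss_rate, self.variant_noise_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("rates must be probabilities in [0, 1]")


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _chem_token(rng: np.random.Generator) -> str:
    t = _pick(rng, MULTIPLIERS) if rng.random() < 0.5 else ""
    units = 2 if rng.random() < 0.2 else 1
    for _ in range(units):
        t += _pick(rng, STEMS) + _pick(rng, SUFFIXES)
    return t


def generate_chemical_name(rng: np.random.Generator) -> str:
    """A 2-5 token nomenclature-style name, e.g. 'diethylol glycol ether'.

    Every name carries at least one morpheme compound (the concept's
    discriminative core) and at least one connector word.
    """
    n_tokens = int(rng.integers(2, 6))
    n_compound = int(rng.integers(1, n_tokens))
    tokens = [_chem_token(rng) for _ in range(n_compound)]
    tokens += [_pick(rng, CONNECTORS) for _ in range(n_tokens - n_compound)]
    perm = rng.permutation(len(tokens))
    return " ".join(tokens[i] for i in perm)


def _letter_probs(names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical letter distribution (a-z) of a name collection."""
    text = "".join(names).replace(" ", "").replace("-", "")
    letters, counts = np.unique(list(text), return_counts=True)
    return letters, counts / counts.sum()


def generate_nonchemical_name(
    rng: np.random.Generator,
    letter_probs: tuple[np.ndarray, np.ndarray] | None = None,
) -> str:
    """A 2-5 token phrase from the packaged word list.

    When ``letter_probs`` is given (letters, probabilities), tokens are
    instead pseudowords sampled letter-by-letter from that distribution,
    which matches aggregate letter frequencies to the chemical names while
    leaving the sequence structure entirely different.
    """
    n_tokens = int(rng.integers(2, 6))
    if letter_probs is None:
        idx = rng.choice(len(WORDS), size=n_tokens, replace=False)
        return " ".join(WORDS[int(i)] for i in idx)
    letters, probs = letter_probs
    tokens = []
    for _ in range(n_tokens):
        length = int(rng.integers(3, 9))
        tokens.append("".join(rng.choice(letters, size=length, p=probs)))
    return " ".join(tokens)


def _is_connector_token(token: str) -> bool:
    base = token.rstrip("s") if token.endswith("s") else token
    return token in CONNECTORS or base in CONNECTORS


def make_variants(
    name: str,
    is_chemical: bool,
    k: int,
    rng: np.random.Generator,
    *,
    noise_rate: float = 0.05,
    noise_chars: tuple[str, ...] = ("e", "h"),
) -> list[str]:
    """k same-concept spelling variants of ``name`` (the first is the name).

    Variants arise from hyphen/space swaps, a plural 's' on one token, and
    benign single-character insertions (one of ``noise_chars``) at rate
    ``noise_rate`` per character.  For chemical names the insertions are
    confined to connector words so that the morpheme compounds — the
    characters distinguishing near-miss concepts — stay intact.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = [name]
    for _ in range(k - 1):
        v = name
        seps = [i for i, c in enumerate(v) if c in " -"]
        if seps and rng.random() < 0.3:
            i = _pick(rng, seps)
            v = v[:i] + ("-" if v[i] == " " else " ") + v[i + 1 :]
        parts = re.split(r"([ -])", v)
        if rng.random() < 0.3:
            word_idx = [i for i in range(0, len(parts), 2) if parts[i]]
            i = _pick(rng, word_idx)
            if not parts[i].endswith("s"):
                parts[i] = parts[i] + "s"
        if noise_rate > 0 and noise_chars:
            for i in range(0, len(parts), 2):
                token = parts[i]
                if not token:
                    continue
                if is_chemical and not _is_connector_token(token):
                    continue
                new = []
                for ch in token:
                    new.append(ch)
                    if rng.random() < noise_rate:
                        new.append(_pick(rng, noise_chars))
                parts[i] = "".join(new)
        out.append("".join(parts))
    return out


def make_near_miss(name: str, rng: np.random.Generator) -> str:
    """A different-concept chemical name within edit distance 2 of ``name``.

    Swaps one morpheme of one compound token for a near neighbor in the
    nomenclature (meth<->eth, di<->tri, yl<->ol, ol<->oxy, ane<->ene), the
    synthetic analogue of one-character edits that change the compound.
    """
    tokens = name.split()
    options: list[tuple[int, str, str]] = []  # (token index, component, replacement)
    for ti, tok in enumerate(tokens):
        if tok in CONNECTORS:
            continue
        m = _DECOMP_RE.match(tok)
        if not m:
            continue
        for comp in ("mult", "stem1", "suf1", "stem2", "suf2"):
            val = m.group(comp)
            if val and val in _NEAR_MISS_SWAPS:
                for repl in _NEAR_MISS_SWAPS[val]:
                    options.append((ti, comp, repl))
    if not options:
        raise ValueError(f"no near-miss swap applicable to {name!r}")
    ti, comp, repl = _pick(rng, options)
    m = _DECOMP_RE.match(tokens[ti])
    pieces = {c: (m.group(c) or "") for c in ("mult", "stem1", "suf1", "stem2", "suf2")}
    pieces[comp] = repl
    tokens[ti] = "".join(pieces[c] for c in ("mult", "stem1", "suf1", "stem2", "suf2"))
    return " ".join(tokens)


def _distinct_name(draw, used: set[str], max_tries: int = 1000) -> str:
    for _ in range(max_tries):
        name = draw()
        if name not in used:
            used.add(name)
            return name
    raise RuntimeError("could not draw a distinct name; name space exhausted")


def generate_dataset(config: GeneratorConfig) -> list[APair]:
    """Full synthetic A-pair dataset under ``config``; reproducible from seed.

    Concepts are created (chemical ones optionally paired with a near-miss
    neighbor concept), grouped into abbreviation collision groups of the
    configured mean size — a near-miss neighbor always shares its source's
    abbreviation — and expanded into spelling variants, one A-pair per
    variant.
    """
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()

    # units: concepts that must share an abbreviation (source + near miss)
    chem_units: list[list[tuple[str, str]]] = []
    for i in range(config.n_concepts_chemical):
        name = _distinct_name(lambda: generate_chemical_name(rng), used)
        unit = [(f"CHEM{i:04d}", name)]
        if rng.random() < config.near_miss_rate:
            for _ in range(50):
                nm = make_near_miss(name, rng)
                if nm not in used:
                    used.add(nm)
                    unit.append((f"CHEM{i:04d}N", nm))
                    break
        chem_units.append(unit)
    # the frequency-matched mode mimics the chemical letters actually drawn
    letter_probs = (
        _letter_probs([name for unit in chem_units for _, name in unit])
        if config.match_letter_frequencies and chem_units
        else None
    )
    other_units: list[list[tuple[str, str]]] = []
    for i in range(config.n_concepts_other):
        name = _distinct_name(
            lambda: generate_nonchemical_name(rng, letter_probs), used
        )
        other_units.append([(f"OTH{i:04d}", name)])

    target = max(1, round(config.collision_group_size))
    used_abbrs: set[str] = set()
    apairs: list[APair] = []

    def emit(units: list[list[tuple[str, str]]], is_chem: bool,
             noise_chars: tuple[str, ...]) -> None:
        perm = rng.permutation(len(units))
        units = [units[int(i)] for i in perm]
        group: list[tuple[str, str]] = []
        groups: list[list[tuple[str, str]]] = []
        for unit in units:
            group.extend(unit)
            if len(group) >= target:
                groups.append(group)
                group = []
        if group:
            groups.append(group)
        for members in groups:
            initials = "".join(t[0] for t in members[0][1].split())
            keep = (
                int(rng.integers(2, len(initials) + 1))
                if len(initials) > 2
                else len(initials)
            )
            abbr = initials[:keep].upper()
            while abbr in used_abbrs:
                abbr += chr(int(rng.integers(65, 91)))
            used_abbrs.add(abbr)
            for cid, name in members:
                k = 1 + int(rng.poisson(config.variants_per_concept - 1.0))
                for form in make_variants(
                    name,
                    is_chem,
                    k,
                    rng,
                    noise_rate=config.variant_noise_rate,
                    noise_chars=noise_chars,
                ):
                    apairs.append(APair(abbr, form, cid, is_chem))

    emit(chem_units, True, config.noise_chars_chemical)
    emit(other_units, False, config.noise_chars_other)
    return apairs
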