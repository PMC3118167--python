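"""Synthetic labelled hairpin and pseudo-hairpin structures.

The generator emulates the two classes the classifier must separate:

* **positive** records mimic genuine pre-miRNA precursors — one long
  imperfect stem (18-25 base pairs) closed by a small terminal loop
  (3-10 nt), interrupted by occasional 1-3 nt bulges (probability 0.1
  per stem position);
* **negative** records mimic pseudo hairpins and hairpin-bearing
  fragments of other ncRNAs — 2-4 short stem fragments of 3-8 bp with
  large loops, separated by 5-15 nt unpaired spacers, wrapped in a
  multibranch junction with probability 0.5.

Structures are generated directly as dot-brackets (no folding engine
involved), so class structure is under exact control and every record is
valid by construction.  Paired positions receive Watson-Crick-compatible
bases (A-U, G-C, with a 10% chance of a G·U wobble).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import pair_table
from .records import HairpinError, RnaRecord

_WC = ("AU", "UA", "GC", "CG")
_WOBBLE = ("GU", "UG")
_BASES = "ACGU"


@dataclass(frozen=True)
class GeneratorParams:
    """Structural parameters of the two synthetic classes (bounds inclusive)."""

    stem_len: tuple[int, int] = (18, 25)        # positive: stem base pairs
    loop_len: tuple[int, int] = (3, 10)         # positive: terminal loop nt
    bulge_prob: float = 0.1                     # per stem position
    bulge_len: tuple[int, int] = (1, 3)
    neg_fragments: tuple[int, int] = (2, 4)     # negative: stem fragments
    neg_stem_len: tuple[int, int] = (3, 8)
    neg_spacer_len: tuple[int, int] = (5, 15)
    multibranch_prob: float = 0.5
    gu_prob: float = 0.1

    def __post_init__(self):
        for lo, hi in (self.stem_len, self.loop_len, self.bulge_len,
                       self.neg_fragments, self.neg_stem_len,
                       self.neg_spacer_len):
            if lo <= 0 or hi < lo:
                raise HairpinError("generator bounds must be positive and "
                                   "ordered")
        for p in (self.bulge_prob, self.multibranch_prob, self.gu_prob):
            if not 0.0 <= p <= 1.0:
                raise HairpinError("generator probabilities must be in [0,1]")


def _uniform(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _positive_structure(rng: np.random.Generator, p: GeneratorParams) -> str:
    stem = _uniform(rng, p.stem_len)
    loop = _uniform(rng, p.loop_len)
    left, right = [], []
    for _ in range(stem):
        left.append("(")
        right.append(")")
        if rng.random() < p.bulge_prob:
            bulge = "." * _uniform(rng, p.bulge_len)
            if rng.random() < 0.5:
                left.append(bulge)
            else:
                right.append(bulge)
    return "".join(left) + "." * loop + "".join(reversed(right))


def _negative_structure(rng: np.random.Generator, p: GeneratorParams) -> str:
    n_frag = _uniform(rng, p.neg_fragments)
    frags = []
    for _ in range(n_frag):
        stem = _uniform(rng, p.neg_stem_len)
        loop = _uniform(rng, p.neg_spacer_len)
        frags.append("(" * stem + "." * loop + ")" * stem)
    parts = [frags[0]]
    for frag in frags[1:]:
        parts.append("." * _uniform(rng, p.neg_spacer_len))
        parts.append(frag)
    inner = "".join(parts)
    if rng.random() < p.multibranch_prob:
        stem = _uniform(rng, p.neg_stem_len)
        inner = "(" * stem + inner + ")" * stem
    dang5 = "." * int(rng.integers(2, 8))
    dang3 = "." * int(rng.integers(2, 8))
    return dang5 + inner + dang3


def _sequence_for(structure: str, rng: np.random.Generator,
                  gu_prob: float) -> str:
    seq = [""] * len(structure)
    table = pair_table(structure)
    for i in range(1, len(structure) + 1):
        j = table[i]
        if j == 0:
            seq[i - 1] = _BASES[int(rng.integers(4))]
        elif j > i:
            pool = _WOBBLE if rng.random() < gu_prob else _WC
            pair = pool[int(rng.integers(len(pool)))]
            seq[i - 1], seq[j - 1] = pair[0], pair[1]
    return "".join(seq)


def make_record(label: str, rng: np.random.Generator,
                params: GeneratorParams | None = None,
                rec_id: str | None = None) -> RnaRecord:
    """Draw one labelled synthetic record from the given class."""
    params = params or GeneratorParams()
    if label == "positive":
        structure = _positive_structure(rng, params)
    elif label == "negative":
        structure = _negative_structure(rng, params)
    else:
        raise HairpinError(f"unknown class {label!r}")
    sequence = _sequence_for(structure, rng, params.gu_prob)
    return RnaRecord(rec_id or f"{label}_record", sequence, structure, label)


def make_dataset(n_pos: int, n_neg: int, seed: int,
                 params: GeneratorParams | None = None) -> list[RnaRecord]:
    """A reproducible labelled dataset: positives first, then negatives."""
    if n_pos < 0 or n_neg < 0:
        raise HairpinError("record counts must be >= 0")
    rng = np.random.default_rng(seed)
    params = params or GeneratorParams()
    records = [make_record("positive", rng, params, f"pos_{k:05d}")
               for k in range(n_pos)]
    records += [make_record("negative", rng, params, f"neg_{k:05d}")
                for k in range(n_neg)]
    return records


def random_structure(length: int, rng: np.random.Generator,
                     min_loop: int = 3, p_open: float = 0.35,
                     p_close: float = 0.35) -> str:
    """A uniform-ish random valid dot-bracket of exactly ``length`` chars.

    Used for property testing: brackets are always balanced, properly
    nested, and hairpin loops are at least ``min_loop`` nt — the regime
    real folding output lives in (and the regime in which structure
    graphs are triangle-free).
    """
    if length < 1:
        raise HairpinError("length must be >= 1")
    out: list[str] = []
    stack: list[int] = []
    for pos in range(length):
        remaining = length - pos
        nopen = len(stack)
        need = 0
        if stack:
            need = max(0, min_loop - (pos - stack[-1] - 1))
        slack = remaining - nopen - need
        can_close = stack and need == 0
        can_open = remaining >= nopen + min_loop + 2
        if slack <= 0:
            ch = "." if need > 0 else ")"
        else:
            r = rng.random()
            if can_open and r < p_open:
                ch = "("
            elif can_close and r < p_open + p_close:
                ch = ")"
            else:
                ch = "."
        out.append(ch)
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            stack.pop()
    return "".join(out)
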