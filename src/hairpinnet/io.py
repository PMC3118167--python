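"""Readers and writers: Vienna dot-bracket files, CT files, feature tables.

The dot-bracket dialect is the FASTA-like one emitted by RNAfold and
friends: a ``>id`` header, one sequence line, one structure line.  A
trailing free-energy annotation after the structure (``(((...))) ( -3.2)``
or ``(((...)))( -3.2)``) is stripped.  Labels ride along in the header as
``>id|label=positive``.

CT files are the connectivity tables written by UNAfold/mfold: a header
line starting with the record length, then one line per nucleotide whose
fifth column is the 1-based pairing partner (0 = unpaired).  UNAfold emits
suboptimal foldings as repeated blocks with the same name; only the first
block per name is kept.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .records import HairpinError, RnaRecord, StructureError

logger = logging.getLogger(__name__)

# trailing "( -3.2)" / "(-3.20)" style free-energy annotation
_ENERGY_RE = re.compile(r"\s*\(\s*[+-]?\d+(?:\.\d+)?\s*\)\s*$")


def _strip_energy(structure_line: str) -> str:
    return _ENERGY_RE.sub("", structure_line.strip())


def read_dot_bracket(path: str | os.PathLike, strict: bool = True) -> list[RnaRecord]:
    """Read a Vienna-style dot-bracket file.

    Parameters
    ----------
    path : path
        File with ``>header`` / sequence / structure triplets.  Lines
        starting with ``#`` and blank lines are ignored.
    strict : bool
        If True (default) any malformed record aborts the whole read;
        if False malformed records are skipped with a logged warning.
    """
    lines: list[tuple[int, str]] = []
    with open(path) as fh:
        for no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lines.append((no, line.strip()))

    records: list[RnaRecord] = []
    i = 0
    while i < len(lines):
        no, line = lines[i]
        if not line.startswith(">"):
            raise StructureError("expected '>' header", line=no)
        rec_id, label = _parse_header(line)
        if i + 2 >= len(lines):
            raise StructureError("truncated entry (need sequence and "
                                 "structure lines)", record_id=rec_id, line=no)
        seq = lines[i + 1][1]
        struct_no, struct_line = lines[i + 2]
        structure = _strip_energy(struct_line)
        try:
            records.append(RnaRecord(rec_id, seq, structure, label))
        except StructureError as exc:
            err = StructureError(str(exc), line=struct_no)
            if strict:
                raise err from None
            logger.warning("skipping %s", err)
        i += 3
    return records


def _parse_header(line: str) -> tuple[str, str | None]:
    header = line[1:].strip()
    fields = header.split("|")
    rec_id = fields[0].split()[0] if fields[0].split() else fields[0]
    label = None
    for f in fields[1:]:
        if f.startswith("label="):
            label = f[len("label="):]
    return rec_id, label


def write_dot_bracket(records: Iterable[RnaRecord], path: str | os.PathLike,
                      header_comment: str | None = None) -> None:
    """Write records in the dot-bracket dialect read by :func:`read_dot_bracket`."""
    out = []
    if header_comment:
        out.append(f"# {header_comment}")
    for rec in records:
        head = f">{rec.id}"
        if rec.label is not None:
            head += f"|label={rec.label}"
        out += [head, rec.sequence, rec.structure]
    _atomic_write(path, "\n".join(out) + "\n")


def read_ct(path: str | os.PathLike, strict: bool = True) -> list[RnaRecord]:
    """Read a CT (connectivity table) file, reconstructing dot-brackets.

    The pairing column must be symmetric (``i`` pairs ``j`` implies ``j``
    pairs ``i``) and pseudoknot-free; violations raise
    :class:`StructureError` naming the offending pair.  For files holding
    several structures of the same record (UNAfold suboptimal folds) only
    the first structure per name is returned.
    """
    with open(path) as fh:
        raw = [(no, line.rstrip("\n")) for no, line in enumerate(fh, start=1)]
    raw = [(no, line) for no, line in raw if line.strip()]

    records: list[RnaRecord] = []
    seen: set[str] = set()
    i = 0
    count = 0
    while i < len(raw):
        no, header = raw[i]
        toks = header.split()
        try:
            n = int(toks[0])
        except (ValueError, IndexError):
            raise StructureError("expected CT header starting with the "
                                 "record length", line=no) from None
        count += 1
        rec_id = toks[-1] if len(toks) > 1 else f"structure_{count}"
        body = raw[i + 1:i + 1 + n]
        if len(body) < n:
            raise StructureError(f"truncated CT block ({len(body)} of {n} "
                                 "lines)", record_id=rec_id, line=no)
        try:
            rec = _ct_block_to_record(rec_id, body)
        except StructureError as exc:
            if strict:
                raise
            logger.warning("skipping %s", exc)
            rec = None
        if rec is not None and rec_id not in seen:
            seen.add(rec_id)
            records.append(rec)
        i += 1 + n
    return records


def _ct_block_to_record(rec_id: str, body: list[tuple[int, str]]) -> RnaRecord:
    n = len(body)
    seq = []
    partner = [0] * (n + 1)  # 1-based
    for k, (no, line) in enumerate(body, start=1):
        toks = line.split()
        if len(toks) < 5:
            raise StructureError("CT line needs >= 5 columns",
                                 record_id=rec_id, line=no)
        idx, base, pair = int(toks[0]), toks[1], int(toks[4])
        if idx != k:
            raise StructureError(f"CT index {idx} out of order (expected {k})",
                                 record_id=rec_id, line=no)
        if pair < 0 or pair > n:
            raise StructureError(f"pairing partner {pair} out of range",
                                 record_id=rec_id, line=no)
        seq.append(base)
        partner[k] = pair
    # consistency: i pairs j  =>  j pairs i, and no self pairing
    for k in range(1, n + 1):
        j = partner[k]
        if j == 0:
            continue
        if j == k:
            raise StructureError(f"position {k} pairs with itself",
                                 record_id=rec_id)
        if partner[j] != k:
            raise StructureError(
                f"inconsistent pairing: {k} pairs {j} but {j} pairs "
                f"{partner[j]}", record_id=rec_id)
    pairs = sorted((k, partner[k]) for k in range(1, n + 1) if partner[k] > k)
    # pseudoknot check: no two pairs (i,j), (k,l) with i < k < j < l
    opens = []
    for (a, b) in pairs:
        for (c, d) in opens:
            if c < a < d < b:
                raise StructureError(
                    f"pseudoknot: pair ({a},{b}) crosses pair ({c},{d})",
                    record_id=rec_id)
        opens.append((a, b))
    structure = ["."] * n
    for (a, b) in pairs:
        structure[a - 1] = "("
        structure[b - 1] = ")"
    return RnaRecord(rec_id, "".join(seq), "".join(structure))


def write_ct(records: Iterable[RnaRecord], path: str | os.PathLike) -> None:
    """Write records as concatenated CT blocks (round-trips via :func:`read_ct`)."""
    from .graph import pair_table  # local import to avoid a cycle

    out = []
    for rec in records:
        n = len(rec)
        table = pair_table(rec.structure)
        out.append(f"{n}\t{rec.id}")
        for k in range(1, n + 1):
            nxt = k + 1 if k < n else 0
            out.append(f"{k}\t{rec.sequence[k - 1]}\t{k - 1}\t{nxt}"
                       f"\t{table[k]}\t{k}")
    _atomic_write(path, "\n".join(out) + "\n")


def write_features(matrix, path: str | os.PathLike,
                   header_comment: str | None = None) -> None:
    """Write a :class:`~hairpinnet.features.FeatureMatrix` as TSV.

    Columns: ``id``, the 24 canonical feature names, ``label``.  Raises
    :class:`HairpinError` on an empty matrix.
    """
    if len(matrix) == 0:
        raise HairpinError("refusing to write an empty feature matrix")
    df = matrix.to_frame()
    text = ""
    if header_comment:
        text += f"# {header_comment}\n"
    text += df.to_csv(sep="\t", index=False)
    _atomic_write(path, text)


def read_features(path: str | os.PathLike):
    """Read a TSV feature table written by :func:`write_features`."""
    from .features import FeatureMatrix

    df = pd.read_csv(path, sep="\t", comment="#")
    return FeatureMatrix.from_frame(df)


def read_any(path: str | os.PathLike, strict: bool = True) -> list[RnaRecord]:
    """Dispatch on extension: ``.ct`` -> CT reader, otherwise dot-bracket."""
    if str(path).lower().endswith(".ct"):
        return read_ct(path, strict=strict)
    return read_dot_bracket(path, strict=strict)


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
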