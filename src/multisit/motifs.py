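"""Consensus-motif compilation, scanning and alignment conservation profiling.

Silicon-transporter work leans on short exact consensus motifs — CMLD, GXQ,
YQXDXVYL, DXDID — written in a tiny grammar: fixed residues, ``X`` wildcards
and bracketed residue classes (``C[MI]LD``).  Patterns are matched on
gap-free protein sequence; helpers map hits back into alignment coordinates
when the input rows are gapped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."

__all__ = [
    "MotifPattern",
    "MotifHit",
    "ConservationProfile",
    "PatternError",
    "GappedSequenceError",
    "compile_pattern",
    "scan",
    "scan_alignment_row",
    "column_conservation",
    "motif_presence",
    "degap",
]


class PatternError(ValueError):
    """Raised for a pattern string the motif grammar cannot parse."""


class GappedSequenceError(ValueError):
    """Raised when a gapped sequence is handed to a residue-space scanner."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled consensus pattern.

    ``elements`` holds one frozenset of admissible residues per position;
    ``X`` compiles to the full 20-residue set.  Gap characters never match.
    """

    name: str
    elements: tuple[frozenset, ...]
    source_text: str

    def __len__(self) -> int:
        return len(self.elements)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.elements):
            return False
        return all(c in e for c, e in zip(window, self.elements))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; coordinates are 1-based inclusive."""

    pattern_name: str
    sequence_id: str
    start: int
    end: int
    matched_text: str


def compile_pattern(text: str, name: str | None = None) -> MotifPattern:
    """Compile a consensus string such as ``"DXDID"`` or ``"C[MI]LD"``.

    Raises :class:`PatternError` naming the 0-based offset of the first
    offending character for unbalanced brackets, empty classes or letters
    outside the 20-residue alphabet.
    """
    if not text:
        raise PatternError("empty pattern")
    elements: list[frozenset] = []
    i = 0
    full = frozenset(AMINO_ACIDS)
    while i < len(text):
        c = text[i]
        if c == "X":
            elements.append(full)
            i += 1
        elif c in AMINO_ACIDS:
            elements.append(frozenset(c))
            i += 1
        elif c == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternError(f"unbalanced '[' at offset {i} in {text!r}")
            members = text[i + 1 : j]
            if not members:
                raise PatternError(f"empty residue class at offset {i} in {text!r}")
            bad = [k for k, m in enumerate(members) if m not in AMINO_ACIDS]
            if bad:
                raise PatternError(
                    f"illegal character {members[bad[0]]!r} at offset {i + 1 + bad[0]} in {text!r}"
                )
            elements.append(frozenset(members))
            i = j + 1
        elif c == "]":
            raise PatternError(f"unbalanced ']' at offset {i} in {text!r}")
        else:
            raise PatternError(f"illegal character {c!r} at offset {i} in {text!r}")
    return MotifPattern(name=name or text, elements=tuple(elements), source_text=text)


def _as_pattern(pattern: MotifPattern | str) -> MotifPattern:
    return pattern if isinstance(pattern, MotifPattern) else compile_pattern(pattern)


def degap(seq: str) -> str:
    """Remove alignment gap characters (``-`` and ``.``)."""
    return seq.translate({ord(g): None for g in GAP_CHARS})


def scan(
    seq: str,
    pattern: MotifPattern | str,
    sequence_id: str = "",
    allow_overlap: bool = True,
) -> list[MotifHit]:
    """Exhaustively scan a gap-free protein sequence for a consensus motif.

    Hits are 1-based inclusive and sorted by start.  With
    ``allow_overlap=False`` only leftmost non-overlapping hits are kept
    (the convention used by counting operations).
    """
    pattern = _as_pattern(pattern)
    if any(g in seq for g in GAP_CHARS):
        raise GappedSequenceError(
            "sequence contains gap characters; degap() it before scanning "
            "(or use scan_alignment_row for alignment coordinates)"
        )
    m = len(pattern)
    hits: list[MotifHit] = []
    last_end = 0
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if pattern.matches(window):
            if not allow_overlap and i < last_end:
                continue
            hits.append(
                MotifHit(pattern.name, sequence_id, start=i + 1, end=i + m, matched_text=window)
            )
            last_end = i + m
    return hits


def scan_alignment_row(
    row: str,
    pattern: MotifPattern | str,
    sequence_id: str = "",
    allow_overlap: bool = True,
) -> list[MotifHit]:
    """Scan one gapped alignment row, reporting hits in alignment columns.

    The row is degapped, scanned in residue space, and the hit coordinates
    are mapped back through the row's gap map.
    """
    pattern = _as_pattern(pattern)
    residue_to_column = [i + 1 for i, c in enumerate(row) if c not in GAP_CHARS]
    hits = scan(degap(row), pattern, sequence_id, allow_overlap=allow_overlap)
    return [
        MotifHit(
            h.pattern_name,
            h.sequence_id,
            start=residue_to_column[h.start - 1],
            end=residue_to_column[h.end - 1],
            matched_text=h.matched_text,
        )
        for h in hits
    ]


@dataclass
class ConservationProfile:
    """Per-column conservation summary of a multiple alignment.

    Columns are 1-based alignment coordinates.  A column is *absolutely
    conserved* when every row carries the same residue and no row has a gap.
    """

    consensus: list[str]
    fraction: np.ndarray
    non_gap: np.ndarray
    n_sequences: int
    absolutely_conserved: np.ndarray = field(repr=False)

    @property
    def alignment_length(self) -> int:
        return len(self.consensus)

    def column(self, col: int) -> dict:
        """1-based single-column view."""
        i = col - 1
        return {
            "column": col,
            "consensus": self.consensus[i],
            "fraction": float(self.fraction[i]),
            "non_gap": int(self.non_gap[i]),
            "absolutely_conserved": bool(self.absolutely_conserved[i]),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.alignment_length + 1),
                "consensus": self.consensus,
                "fraction": self.fraction,
                "non_gap": self.non_gap,
                "absolutely_conserved": self.absolutely_conserved,
            }
        )


def column_conservation(alignment: Mapping[str, str] | Sequence[str]) -> ConservationProfile:
    """Profile per-column conservation of an aligned set of sequences."""
    rows = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    n = len(rows)
    length = lengths.pop()
    consensus: list[str] = []
    fraction = np.zeros(length)
    non_gap = np.zeros(length, dtype=int)
    absolute = np.zeros(length, dtype=bool)
    for j in range(length):
        column = [r[j] for r in rows if r[j] not in GAP_CHARS]
        non_gap[j] = len(column)
        if not column:
            consensus.append("-")
            continue
        counts = Counter(column)
        top = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))  # ties: alphabetical
        consensus.append(top[0])
        fraction[j] = top[1] / len(column)
        absolute[j] = top[1] == n
    return ConservationProfile(consensus, fraction, non_gap, n, absolute)


def motif_presence(
    sequences: Mapping[str, str],
    pattern: MotifPattern | str,
) -> tuple[dict[str, int], list[str]]:
    """Count motif occurrences per sequence and list the sequences lacking it.

    Rows may be gapped (they are degapped first).  Counts use the leftmost
    non-overlapping convention so tandem copies are not double-counted.
    """
    pattern = _as_pattern(pattern)
    counts: dict[str, int] = {}
    absent: list[str] = []
    for sid, seq in sequences.items():
        n = len(scan(degap(seq), pattern, sid, allow_overlap=False))
        counts[sid] = n
        if n == 0:
            absent.append(sid)
    return counts, absent


def hits_to_dataframe(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.sequence_id, h.pattern_name, h.start, h.end, h.matched_text) for h in hits],
        columns=["sequence_id", "pattern", "start", "end", "match"],
    )
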