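"""Degenerate PCR primer design by back-translation and nucleotide consensus.

The classic route to fishing an unknown SIT gene out of a genome is a
degenerate primer pair anchored on the nucleotide context of the conserved
CMLD peptide across known species: back-translate the peptide (or take the
column-wise IUPAC consensus of aligned coding sequences), keep the overall
degeneracy under a cap, and take the reverse complement of the downstream
window as the reverse primer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import prod
from typing import Iterator, Sequence

from Bio.Data import CodonTable

#: IUPAC nucleotide ambiguity codes -> base sets.
IUPAC_SETS: dict[str, frozenset] = {
    code: frozenset(bases)
    for code, bases in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }.items()
}
_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}
_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

__all__ = [
    "DegeneratePrimer",
    "PrimerDesignError",
    "back_translate",
    "consensus_degenerate",
    "reverse_complement_iupac",
    "iupac_degeneracy",
    "expand_iupac",
    "design_primer_pair",
]


class PrimerDesignError(ValueError):
    pass


def iupac_code_for(bases: set[str] | frozenset) -> str:
    try:
        return _SET_TO_CODE[frozenset(bases)]
    except KeyError:
        raise PrimerDesignError(f"not a nucleotide base set: {sorted(bases)}") from None


def iupac_degeneracy(s: str) -> int:
    """Number of exact sequences encoded = product of per-position set sizes."""
    try:
        return prod(len(IUPAC_SETS[c]) for c in s.upper())
    except KeyError as exc:
        raise PrimerDesignError(f"illegal IUPAC character {exc.args[0]!r}") from None


def expand_iupac(s: str) -> Iterator[str]:
    """Enumerate every exact sequence a degenerate string encodes."""
    sets = [sorted(IUPAC_SETS[c]) for c in s.upper()]
    for combo in itertools.product(*sets):
        yield "".join(combo)


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-degenerate oligo.

    ``degeneracy`` is the IUPAC-expansion count (product of per-position
    ambiguity-set sizes).  Note this can exceed the codon-count degeneracy
    from :func:`back_translate` when a residue's codon set is not a full
    IUPAC cross-product (e.g. Leu: 6 codons but YTN spans 8 triplets).
    """

    name: str
    iupac_sequence: str
    direction: str  # "forward" | "reverse"
    degeneracy: int = field(default=0)
    source: str = ""

    def __post_init__(self) -> None:
        if self.direction not in {"forward", "reverse"}:
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")
        d = iupac_degeneracy(self.iupac_sequence)
        if self.degeneracy == 0:
            object.__setattr__(self, "degeneracy", d)
        elif self.degeneracy != d:
            raise ValueError(
                f"declared degeneracy {self.degeneracy} != IUPAC product {d}"
            )

    def __len__(self) -> int:
        return len(self.iupac_sequence)


def _codons_by_residue(table_id: int) -> dict[str, list[str]]:
    fwd = CodonTable.unambiguous_dna_by_id[table_id].forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


def back_translate(peptide: str, table_id: int = 1) -> tuple[str, int]:
    """Peptide -> minimal covering IUPAC string + codon-count degeneracy.

    Each residue becomes the smallest IUPAC triplet covering all its codons;
    the returned degeneracy is the product of per-residue codon counts
    (CMLD -> 2 x 1 x 6 x 2 = 24 under the standard table).
    """
    by_aa = _codons_by_residue(table_id)
    out: list[str] = []
    degeneracy = 1
    for aa in peptide.upper():
        if aa not in by_aa:
            raise PrimerDesignError(f"unknown residue {aa!r}")
        codons = by_aa[aa]
        degeneracy *= len(codons)
        for k in range(3):
            out.append(iupac_code_for({c[k] for c in codons}))
    return "".join(out), degeneracy


def consensus_degenerate(rows: Sequence[str]) -> tuple[str, int, list[float]]:
    """Column-wise IUPAC consensus of an aligned, gap-free nucleotide block.

    Returns the consensus string, its IUPAC degeneracy and the per-column
    persistence (fraction of rows showing the modal base).
    """
    if not rows:
        raise PrimerDesignError("empty alignment block")
    rows = [r.upper() for r in rows]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise PrimerDesignError(f"ragged block: row lengths {sorted(lengths)}")
    consensus: list[str] = []
    persistence: list[float] = []
    for j in range(lengths.pop()):
        column = [r[j] for r in rows]
        if any(c in "-." for c in column):
            raise PrimerDesignError(
                f"gap in primer window at column {j + 1}; shift the window off the indel"
            )
        bad = set(column) - set("ACGT")
        if bad:
            raise PrimerDesignError(f"non-ACGT base {sorted(bad)} at column {j + 1}")
        observed = set(column)
        consensus.append(iupac_code_for(observed))
        modal = max(observed, key=lambda b: (column.count(b), b))
        persistence.append(column.count(modal) / len(column))
    text = "".join(consensus)
    return text, iupac_degeneracy(text), persistence


def reverse_complement_iupac(s: str) -> str:
    """Reverse complement honouring ambiguity codes (an involution)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(s.upper()))
    except KeyError:
        bad = next(c for c in s.upper() if c not in _COMPLEMENT)
        raise PrimerDesignError(f"illegal IUPAC character {bad!r}") from None


def design_primer_pair(
    block: Sequence[str],
    max_degeneracy: int = 128,
    min_len: int = 17,
    max_len: int = 29,
    name: str = "UniPrimer",
) -> tuple[DegeneratePrimer, DegeneratePrimer]:
    """Design a forward/reverse degenerate pair from an aligned coding block.

    The forward primer is the IUPAC consensus of the leftmost window (up to
    ``max_len`` columns); the reverse primer is the reverse complement of
    the consensus of the rightmost window.  While a primer exceeds the
    degeneracy cap its 5' end is trimmed (for the reverse primer the 5' end
    corresponds to the rightmost block column) down to ``min_len``; if no
    compliant window exists the error reports the best achievable
    degeneracy.
    """
    if not block:
        raise PrimerDesignError("empty alignment block")
    width = len(block[0])
    if width < min_len:
        raise PrimerDesignError(f"block width {width} < min primer length {min_len}")

    def trim(window_cols: tuple[int, int], from_left: bool) -> str:
        lo, hi = window_cols  # 0-based half-open
        best = None
        while hi - lo >= min_len:
            cons, deg, _ = consensus_degenerate([r[lo:hi] for r in block])
            best = min(best, deg) if best is not None else deg
            if deg <= max_degeneracy:
                return cons
            if from_left:
                lo += 1
            else:
                hi -= 1
        raise PrimerDesignError(
            f"no window of length >= {min_len} meets degeneracy cap "
            f"{max_degeneracy}; best achievable {best}"
        )

    fwd_cons = trim((0, min(max_len, width)), from_left=True)
    rev_cons = trim((max(0, width - max_len), width), from_left=False)
    fwd = DegeneratePrimer(f"{name}F", fwd_cons, "forward", source="block 5' window")
    rev = DegeneratePrimer(
        f"{name}R", reverse_complement_iupac(rev_cons), "reverse", source="block 3' window"
    )
    return fwd, rev
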