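"""Nucleotide-level analysis: ORFs, translation, spacers, paralogs, in-silico PCR.

Multi-SIT genes are single uninterrupted reading frames, so gene finding
reduces to ORF calling; the tandem SuSIT-style cluster questions (how far
apart are the copies, are they byte-identical — the gene-conversion
signature) reduce to interval arithmetic and global-alignment identity; and
the degenerate-primer experiment is mirrored by an exhaustive in-silico PCR
over IUPAC-coded primer sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import edlib
from Bio.Seq import Seq

from .primers import IUPAC_SETS, reverse_complement_iupac

START_CODON = "ATG"
STOP_CODONS = {"TAA", "TAG", "TGA"}

__all__ = [
    "GeneLocus",
    "Amplicon",
    "InternalStopError",
    "find_orfs",
    "translate",
    "reverse_complement",
    "intergenic_distance",
    "paralog_identity",
    "in_silico_pcr",
]


@dataclass(frozen=True)
class GeneLocus:
    """A located gene/ORF; 1-based inclusive coordinates on the + strand."""

    contig_id: str
    start: int
    end: int
    strand: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product delimited by a forward and a reverse primer site."""

    template_id: str
    fwd_site: GeneLocus
    rev_site: GeneLocus
    product_length: int


class InternalStopError(ValueError):
    """Raised in strict translation when a premature stop codon is met."""


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _validate_dna(dna: str) -> None:
    bad = set(dna.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")


def _orfs_one_strand(dna: str, min_length: int, longest_per_stop: bool) -> list[tuple[int, int]]:
    """0-based half-open (start, end) ATG->stop spans on the given string."""
    n = len(dna)
    spans: list[tuple[int, int]] = []
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = dna[i : i + 3]
            if codon == START_CODON:
                open_starts.append(i)
            elif codon in STOP_CODONS:
                for s in open_starts:
                    if i + 3 - s >= min_length:
                        spans.append((s, i + 3))
                        if longest_per_stop:
                            break
                open_starts = []
    return spans


def find_orfs(
    dna: str,
    min_length: int = 300,
    both_strands: bool = True,
    longest_per_stop: bool = False,
    contig_id: str = "",
) -> list[GeneLocus]:
    """Report every start-to-stop ORF of at least ``min_length`` bp.

    Coordinates are 1-based inclusive on the forward strand and include the
    stop codon.  With ``longest_per_stop`` only the longest ORF sharing a
    stop codon (the most upstream in-frame ATG) is kept.  Minus-strand ORFs
    are found on the reverse complement and reported in forward coordinates
    with strand ``-``.
    """
    dna = dna.upper()
    _validate_dna(dna)
    n = len(dna)
    loci = [
        GeneLocus(contig_id, s + 1, e, "+")
        for s, e in _orfs_one_strand(dna, min_length, longest_per_stop)
    ]
    if both_strands:
        rc = reverse_complement(dna)
        for s, e in _orfs_one_strand(rc, min_length, longest_per_stop):
            loci.append(GeneLocus(contig_id, n - e + 1, n - s, "-"))
    return sorted(loci, key=lambda g: (g.start, g.end, g.strand))


def translate(dna: str, table: int = 1, strict: bool = True, trim_incomplete: bool = False) -> str:
    """Translate a coding sequence; the terminal stop is not part of the protein.

    In strict mode an internal stop raises :class:`InternalStopError` with
    its 1-based residue position.  ``trim_incomplete`` drops a trailing
    partial codon instead of erroring.
    """
    dna = dna.upper()
    _validate_dna(dna)
    if len(dna) % 3:
        if trim_incomplete:
            dna = dna[: len(dna) - len(dna) % 3]
        else:
            raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    protein = str(Seq(dna).translate(table=table))
    if protein.endswith("*"):
        protein = protein[:-1]
    if strict and "*" in protein:
        raise InternalStopError(f"internal stop codon at residue {protein.index('*') + 1}")
    return protein


def intergenic_distance(a: GeneLocus, b: GeneLocus) -> int:
    """Bases strictly between two non-overlapping loci on one contig."""
    if a.contig_id != b.contig_id:
        raise ValueError(f"loci on different contigs: {a.contig_id!r} vs {b.contig_id!r}")
    first, second = (a, b) if a.start <= b.start else (b, a)
    if second.start <= first.end:
        raise ValueError(f"loci overlap: {first.start}..{first.end} and {second.start}..{second.end}")
    return second.start - first.end - 1


def paralog_identity(a: str, b: str) -> tuple[float, bool]:
    """Global-alignment identity in [0, 1] plus a byte-identity flag.

    Identity is matched columns over alignment columns (unit-cost global
    alignment; dual-gap columns cannot occur in a pairwise alignment).
    An exact-equality flag accompanies it because the gene-conversion
    argument rests on the copies being literally identical.
    """
    if not a or not b:
        raise ValueError("paralog_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0, True
    result = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for count, op in _parse_cigar(result["cigar"]):
        columns += count
        if op == "=":
            matches += count
    return matches / columns, False


def _parse_cigar(cigar: str) -> Iterable[tuple[int, str]]:
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def _iupac_match_count(site: str, template_window: str) -> tuple[int, int]:
    """(total mismatches, mismatches in the first 3 positions of the window)."""
    mism = head = 0
    for k, (code, base) in enumerate(zip(site, template_window)):
        if base not in IUPAC_SETS[code]:
            mism += 1
            if k < 3:
                head += 1
    return mism, head


def _find_sites(
    template: str, site: str, max_mismatch: int, protect: str
) -> list[int]:
    """0-based starts where an IUPAC site matches; ``protect`` = 'head'/'tail'
    forbids mismatches in the first/last 3 positions (the primer 3' end)."""
    m = len(site)
    hits = []
    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        mism = sum(1 for code, base in zip(site, window) if base not in IUPAC_SETS[code])
        if mism > max_mismatch:
            continue
        if protect == "tail":
            guarded = zip(site[-3:], window[-3:])
        else:
            guarded = zip(site[:3], window[:3])
        if any(base not in IUPAC_SETS[code] for code, base in guarded):
            continue
        hits.append(i)
    return hits


def in_silico_pcr(
    template: str,
    fwd,
    rev,
    max_product: int = 5000,
    max_mismatch: int = 0,
    template_id: str = "",
) -> list[Amplicon]:
    """Predict PCR products of a degenerate primer pair on one template.

    The forward primer is matched on the + strand; the reverse primer binds
    the − strand, so its reverse complement is matched on the + strand
    downstream of the forward site.  IUPAC codes match their base sets;
    up to ``max_mismatch`` mismatches are tolerated outside each primer's
    3'-terminal 3 bases.  Product length spans the forward site start to the
    reverse site end, inclusive.
    """
    fwd_seq = getattr(fwd, "iupac_sequence", fwd).upper()
    rev_seq = getattr(rev, "iupac_sequence", rev).upper()
    if not fwd_seq or not rev_seq:
        raise ValueError("primers must be non-empty")
    template = template.upper()
    _validate_dna(template)
    rev_site_seq = reverse_complement_iupac(rev_seq)
    fwd_starts = _find_sites(template, fwd_seq, max_mismatch, protect="tail")
    rev_starts = _find_sites(template, rev_site_seq, max_mismatch, protect="head")
    amplicons: list[Amplicon] = []
    for f in fwd_starts:
        for r in rev_starts:
            rev_end = r + len(rev_site_seq)  # 0-based exclusive
            if r < f + len(fwd_seq):
                continue  # reverse site must lie downstream of the forward site
            product = rev_end - f
            if product > max_product:
                continue
            amplicons.append(
                Amplicon(
                    template_id,
                    fwd_site=GeneLocus(template_id, f + 1, f + len(fwd_seq), "+", "fwd"),
                    rev_site=GeneLocus(template_id, r + 1, rev_end, "-", "rev"),
                    product_length=product,
                )
            )
    return amplicons
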