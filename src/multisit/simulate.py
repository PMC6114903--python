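"""Synthetic multi-SIT sequence generator with planted ground truth.

Diatom silicon transporters (SITs) are ~440-residue, 10-transmembrane-domain
membrane proteins carrying one CMLD motif, four GXQ motifs, one YQXDXVYL
motif and a handful of invariant residues.  Some genomes instead encode
*multi-SITs*: two or three such units fused head-to-tail in one reading
frame, with aspartate-rich DXDID motifs in the inter-unit linkers (the
candidate proteolysis sites), and the genes can sit as identical tandem
copies separated by a non-coding spacer.

Everything downstream of this module (scanning, segmentation, topology,
primers, PCR, trees) is tested against the coordinates planted here, so
each generator returns its sequence together with a :class:`SyntheticTruth`
record, and the default parameters reproduce the architecture summarised
above: a 441-residue unit, a 1416-residue triplicate protein, a 5239-bp
spacer between two identical gene copies plus one diverged paralog.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import motifs as _motifs
from .motifs import AMINO_ACIDS, compile_pattern, scan

#: Hydrophobic alphabet used to fill planted transmembrane stretches.
#: Draw weights mirror the composition of real transmembrane helices,
#: which are dominated by Leu/Ile/Val/Phe with Ala/Met common and Trp
#: rare and interfacial; the resulting stretches have a mean Kyte-Doolittle
#: index of ~3.4, so a planted helix is a genuine hydrophobic signal rather
#: than a marginal one.
HYDROPHOBIC = "AILFVMW"
HYDROPHOBIC_WEIGHTS = (0.25, 6, 5, 1, 6, 0.25, 0.25)
#: Charged/polar residues drawn immediately N- and C-terminal of each
#: planted membrane stretch, mimicking the charged loop ends (the
#: "positive-inside" rule) that delimit real transmembrane helices.
TM_FLANK = "KRDENQ"
TM_FLANK_WIDTH = 6
NUCLEOTIDES = "ACGT"

# Default planted architecture of one mature unit (1-based, inclusive).
# Ten 27-residue hydrophobic stretches delimited by charged flanks and
# separated by >=14-residue loops (so a window-19 hydropathy profile does
# not bridge adjacent stretches); the first and last stretches sit flush
# with the termini.  CMLD abuts the second stretch (the motif sits at the
# edge of a hydrophobic region).  GXQ x4, YQXDXVYL and the six invariant
# loop residues all sit in loops, clear of every stretch.
DEFAULT_TM_SEGMENTS: tuple[tuple[int, int], ...] = (
    (1, 27), (47, 70), (116, 142), (159, 185), (202, 228),
    (245, 271), (288, 314), (331, 357), (374, 400), (415, 441),
)
DEFAULT_CONSERVED = {104: "Q", 115: "N", 190: "H", 193: "Y", 229: "S", 372: "S"}

__all__ = [
    "UnitSpec",
    "MultiSitSpec",
    "ClusterSpec",
    "SyntheticTruth",
    "ancestral_unit",
    "make_mature_unit",
    "make_multi_sit",
    "make_gene_cluster",
    "make_unit_family",
    "make_unit_alignment",
    "make_multisit_panel",
    "mutate",
    "reverse_translate",
    "write_truth",
    "read_truth",
]


class SpecError(ValueError):
    """Raised for an internally inconsistent generator specification."""


@dataclass(frozen=True)
class UnitSpec:
    """Blueprint of one planted mature SIT unit."""

    length: int = 441
    cmld_offset: int = 71
    gxq_offsets: tuple[int, ...] = (146, 233, 278, 360)
    yq_offset: int = 318
    conserved_positions: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CONSERVED)
    )
    tm_segments: tuple[tuple[int, int], ...] = DEFAULT_TM_SEGMENTS

    def feature_spans(self) -> list[tuple[str, int, int]]:
        spans = [("CMLD", self.cmld_offset, self.cmld_offset + 3)]
        for g in self.gxq_offsets:
            spans.append(("GXQ", g, g + 2))
        spans.append(("YQXDXVYL", self.yq_offset, self.yq_offset + 7))
        for pos, res in self.conserved_positions.items():
            spans.append((f"conserved_{res}{pos}", pos, pos))
        for k, (s, e) in enumerate(self.tm_segments):
            spans.append((f"TM{k + 1}", s, e))
        return spans

    def validate(self) -> None:
        if len(self.tm_segments) != 10:
            raise SpecError(f"expected 10 tm_segments, got {len(self.tm_segments)}")
        for s, e in self.tm_segments:
            if e - s + 1 < 15:
                raise SpecError(f"tm segment {s}..{e} shorter than 15 residues")
        spans = self.feature_spans()
        for name, s, e in spans:
            if s < 1 or e > self.length or s > e:
                raise SpecError(f"feature {name} ({s}..{e}) outside [1, {self.length}]")
        ordered = sorted(spans, key=lambda t: t[1])
        for (na, sa, ea), (nb, sb, eb) in zip(ordered, ordered[1:]):
            if sb <= ea:
                raise SpecError(
                    f"planted features overlap: {na} ({sa}..{ea}) and {nb} ({sb}..{eb})"
                )


@dataclass(frozen=True)
class MultiSitSpec:
    """Blueprint of a concatenated multi-SIT protein."""

    n_units: int = 3
    unit_spec: UnitSpec = field(default_factory=UnitSpec)
    linker_length: int = 15
    linker_motif: str = "DSDID"
    nterm_length: int = 30   # defaults give 3*441 + 2*15 + 63 = 1416 residues
    cterm_length: int = 33
    mutation_rate: float = 0.0
    protect_anchors: bool = True
    boundary_pattern: str = "DXDID"
    anchor_pattern: str = "CMLD"
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise SpecError("n_units must be >= 1")
        if not 0 <= self.mutation_rate < 1:
            raise SpecError("mutation_rate must lie in [0, 1)")
        if self.linker_length < len(self.linker_motif):
            raise SpecError(
                f"linker_length {self.linker_length} shorter than the boundary motif "
                f"{self.linker_motif!r}"
            )
        if not compile_pattern(self.boundary_pattern).matches(self.linker_motif):
            raise SpecError(
                f"linker_motif {self.linker_motif!r} does not satisfy the boundary "
                f"pattern {self.boundary_pattern!r}"
            )
        self.unit_spec.validate()


@dataclass(frozen=True)
class ClusterSpec:
    """Blueprint of a tandem gene cluster plus one diverged paralog."""

    spacer_length: int = 5239
    duplicate_identical: bool = True
    third_gene_divergence: float = 0.1
    codon_table_id: int = 1
    flank_length: int = 100
    orf_floor: int = 300  # spacer must not host an ORF this long or longer

    def validate(self) -> None:
        if self.spacer_length < 0:
            raise SpecError("spacer_length must be >= 0")
        if not 0 <= self.third_gene_divergence < 1:
            raise SpecError("third_gene_divergence must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted coordinates emitted alongside every simulated dataset.

    All coordinates are 1-based inclusive in the emitted sequence (for
    proteins) or contig (for genes).
    """

    unit_envelopes: list[tuple[int, int]] = field(default_factory=list)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)
    tm_segments: list[list[tuple[int, int]]] = field(default_factory=list)
    boundary_positions: list[int] = field(default_factory=list)
    gene_loci: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    spacer_length: int | None = None

    def validate(self) -> None:
        env = self.unit_envelopes
        for (s1, e1), (s2, e2) in zip(env, env[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise SpecError("unit envelopes must be disjoint and ordered")


# ---------------------------------------------------------------------------
# low-level helpers

def _draw(rng: np.random.Generator, alphabet: str, n: int) -> np.ndarray:
    return rng.choice(list(alphabet), size=n)


def _draw_tm(rng: np.random.Generator, n: int) -> np.ndarray:
    w = np.array(HYDROPHOBIC_WEIGHTS, dtype=float)
    return rng.choice(list(HYDROPHOBIC), size=n, p=w / w.sum())


def mutate(
    seq: str,
    rate: float,
    seed: int,
    protected: Sequence[tuple[int, int]] = (),
    alphabet: str | None = None,
) -> str:
    """Apply i.i.d. point substitutions outside protected intervals.

    Each unprotected position is substituted with probability ``rate`` by a
    uniform draw over the alphabet minus the current character, so the
    expected substituted fraction equals ``rate`` exactly.  ``protected``
    intervals are 1-based inclusive.  Deterministic per seed.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0 or not seq:
        return seq
    if alphabet is None:
        alphabet = NUCLEOTIDES if set(seq) <= set("ACGTN") else AMINO_ACIDS
    rng = np.random.default_rng(seed)
    mask = rng.random(len(seq)) < rate
    for s, e in protected:
        mask[s - 1 : e] = False
    out = list(seq)
    letters = list(alphabet)
    for i in np.flatnonzero(mask):
        choices = [c for c in letters if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _sanitize_spurious(
    seq: list[str],
    rng: np.random.Generator,
    pattern_texts: Sequence[str],
    planted: set[int],
    protected: set[int],
    alphabet: str = AMINO_ACIDS,
) -> None:
    """Destroy chance motif matches the background may have created.

    Any match of a listed pattern whose start is not a planted position is
    broken by redrawing one of its non-protected residues.  Keeps planted
    counts exact (e.g. exactly three CMLD motifs in a triplicate).
    """
    patterns = [compile_pattern(t) for t in pattern_texts]
    for _ in range(100):  # convergence is fast; bound the loop defensively
        dirty = False
        text = "".join(seq)
        for pat in patterns:
            for hit in scan(text, pat):
                if hit.start in planted:
                    continue
                editable = [i for i in range(hit.start - 1, hit.end) if i + 1 not in protected]
                if not editable:
                    continue
                i = editable[int(rng.integers(len(editable)))]
                current = seq[i]
                choices = [c for c in alphabet if c != current]
                seq[i] = choices[int(rng.integers(len(choices)))]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not sanitize spurious motif matches")


# ---------------------------------------------------------------------------
# protein-level generators

def make_mature_unit(spec: UnitSpec, seed: int) -> tuple[str, SyntheticTruth]:
    """Generate one mature SIT unit with its planted coordinates.

    Background residues are uniform over the 20 amino acids, transmembrane
    stretches are uniform over the hydrophobic alphabet, and the motifs and
    invariant residues are written at their planted offsets.  Chance extra
    CMLD matches in the background are removed so the unit carries exactly
    one.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    seq = list(_draw(rng, AMINO_ACIDS, spec.length))
    in_tm = np.zeros(spec.length, dtype=bool)
    for s, e in spec.tm_segments:
        in_tm[s - 1 : e] = True
    for s, e in spec.tm_segments:  # charged loop ends delimit each helix
        for p in list(range(s - TM_FLANK_WIDTH, s)) + list(range(e + 1, e + 1 + TM_FLANK_WIDTH)):
            if 1 <= p <= spec.length and not in_tm[p - 1]:
                seq[p - 1] = str(_draw(rng, TM_FLANK, 1)[0])
    for s, e in spec.tm_segments:
        seq[s - 1 : e] = _draw_tm(rng, e - s + 1)
    _write_unit_motifs(seq, spec, rng, offset=0)
    protected = _unit_protected_positions(spec, offset=0)
    _sanitize_spurious(seq, rng, ["CMLD"], planted={spec.cmld_offset}, protected=protected)
    truth = SyntheticTruth(
        unit_envelopes=[(1, spec.length)],
        motif_positions={
            "CMLD": [spec.cmld_offset],
            "GXQ": list(spec.gxq_offsets),
            "YQXDXVYL": [spec.yq_offset],
        },
        tm_segments=[list(spec.tm_segments)],
    )
    return "".join(seq), truth


def _write_unit_motifs(seq: list[str], spec: UnitSpec, rng: np.random.Generator, offset: int) -> None:
    c = offset + spec.cmld_offset - 1
    seq[c : c + 4] = "CMLD"
    for g in spec.gxq_offsets:
        i = offset + g - 1
        seq[i] = "G"
        seq[i + 1] = str(_draw(rng, AMINO_ACIDS, 1)[0])
        seq[i + 2] = "Q"
    y = offset + spec.yq_offset - 1
    yq = list("YQXDXVYL")
    for k, ch in enumerate(yq):
        seq[y + k] = str(_draw(rng, AMINO_ACIDS, 1)[0]) if ch == "X" else ch
    for pos, res in spec.conserved_positions.items():
        seq[offset + pos - 1] = res


def _unit_protected_positions(spec: UnitSpec, offset: int) -> set[int]:
    """1-based positions (in parent coordinates) of planted motifs/residues."""
    pos: set[int] = set()
    pos.update(range(offset + spec.cmld_offset, offset + spec.cmld_offset + 4))
    for g in spec.gxq_offsets:
        pos.update(range(offset + g, offset + g + 3))
    pos.update(range(offset + spec.yq_offset, offset + spec.yq_offset + 8))
    pos.update(offset + p for p in spec.conserved_positions)
    return pos


def make_multi_sit(spec: MultiSitSpec) -> tuple[str, SyntheticTruth]:
    """Concatenate unit copies head-to-tail with boundary-motif linkers.

    Layout: N-flank (starting with M) + unit + linker + ... + unit + C-flank.
    Each linker carries exactly one centred boundary motif; the flanks are
    rescanned so they carry none.  Point-substitution noise at
    ``mutation_rate`` is applied last; with ``protect_anchors`` (default) it
    never touches planted motifs, invariant residues or the initiator M.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    u = spec.unit_spec
    unit_seq, _ = make_mature_unit(u, seed=int(rng.integers(2**31)))

    parts: list[str] = []
    planted_boundaries: list[int] = []
    envelopes: list[tuple[int, int]] = []
    pos = 0  # 0-based length so far

    # flank/linker residues touching a unit are charged/polar, consistent
    # with the charged loop ends inside the units and with the
    # aspartate-rich character of the real inter-unit linkers
    nterm = "M" + "".join(_draw(rng, AMINO_ACIDS, max(spec.nterm_length - 1 - TM_FLANK_WIDTH, 0)))
    nterm += "".join(_draw(rng, TM_FLANK, min(TM_FLANK_WIDTH, spec.nterm_length - len(nterm))))
    parts.append(nterm)
    pos += len(nterm)

    pad_left = (spec.linker_length - len(spec.linker_motif)) // 2
    pad_right = spec.linker_length - len(spec.linker_motif) - pad_left
    for k in range(spec.n_units):
        envelopes.append((pos + 1, pos + u.length))
        parts.append(unit_seq)
        pos += u.length
        if k < spec.n_units - 1:
            linker = (
                "".join(_draw(rng, TM_FLANK, pad_left))
                + spec.linker_motif
                + "".join(_draw(rng, TM_FLANK, pad_right))
            )
            planted_boundaries.append(pos + pad_left + 1)
            parts.append(linker)
            pos += len(linker)
    n_polar = min(TM_FLANK_WIDTH, spec.cterm_length)
    cterm = "".join(_draw(rng, TM_FLANK, n_polar)) + "".join(
        _draw(rng, AMINO_ACIDS, spec.cterm_length - n_polar)
    )
    parts.append(cterm)

    seq = list("".join(parts))
    planted_anchor_starts = {s - 1 + u.cmld_offset for s, _ in envelopes}
    protected = {1}  # keep the initiator Met (position 1) for CDS construction
    for s, _ in envelopes:
        protected |= _unit_protected_positions(u, offset=s - 1)
    for b in planted_boundaries:
        protected.update(range(b, b + len(spec.linker_motif)))
    # no chance anchor or boundary matches outside the planted ones
    _sanitize_spurious(
        seq,
        rng,
        [spec.anchor_pattern, spec.boundary_pattern],
        planted=planted_anchor_starts | set(planted_boundaries),
        protected=protected,
    )
    text = "".join(seq)
    if spec.mutation_rate > 0:
        prot = (
            sorted((p, p) for p in protected)
            if spec.protect_anchors
            else []
        )
        text = mutate(
            text,
            spec.mutation_rate,
            seed=int(rng.integers(2**31)),
            protected=prot,
            alphabet=AMINO_ACIDS,
        )

    truth = SyntheticTruth(
        unit_envelopes=envelopes,
        motif_positions={
            "CMLD": [s - 1 + u.cmld_offset for s, _ in envelopes],
            "GXQ": [s - 1 + g for s, _ in envelopes for g in u.gxq_offsets],
            "YQXDXVYL": [s - 1 + u.yq_offset for s, _ in envelopes],
            spec.boundary_pattern: list(planted_boundaries),
        },
        tm_segments=[
            [(s - 1 + a, s - 1 + b) for a, b in u.tm_segments] for s, _ in envelopes
        ],
        boundary_positions=planted_boundaries,
    )
    truth.validate()
    return text, truth


def ancestral_unit(spec: MultiSitSpec) -> str:
    """The clean (pre-noise) unit copy a multi-SIT was built from.

    Reproduces the internal seed derivation of :func:`make_multi_sit`, so
    it is the natural reference for envelope trimming in segmentation.
    """
    rng = np.random.default_rng(spec.seed)
    unit_seq, _ = make_mature_unit(spec.unit_spec, seed=int(rng.integers(2**31)))
    return unit_seq


def make_unit_family(
    unit_spec: UnitSpec | None = None,
    seed: int = 0,
    recent_rate: float = 0.02,
    ancient_rate: float = 0.08,
    outgroup_rate: float = 0.2,
) -> dict[str, str]:
    """Units related by nested duplications: A and B split after C.

    Emulates the observed pattern that units A and B of a triplicate are
    highly similar to each other but relatively distant from unit C.  The
    returned ``OUT`` sequence is a far diverged relative usable as an
    outgroup.  All sequences are equal length (substitutions only), so they
    are mutually aligned as-is.
    """
    u = unit_spec or UnitSpec()
    rng = np.random.default_rng(seed)
    root, _ = make_mature_unit(u, seed=int(rng.integers(2**31)))
    prot = sorted((p, p) for p in _unit_protected_positions(u, offset=0))

    def mut(s: str, r: float) -> str:
        return mutate(s, r, seed=int(rng.integers(2**31)), protected=prot, alphabet=AMINO_ACIDS)

    ab_ancestor = mut(root, ancient_rate)
    return {
        "A": mut(ab_ancestor, recent_rate),
        "B": mut(ab_ancestor, recent_rate),
        "C": mut(root, ancient_rate),
        "OUT": mut(root, outgroup_rate),
    }


# ---------------------------------------------------------------------------
# nucleotide-level generators

_FIRST_CODON: dict[str, str] = {}


def _first_codon_table(table_id: int = 1) -> dict[str, str]:
    """Deterministic residue -> codon map (lexicographically first codon)."""
    if not _FIRST_CODON:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[table_id].forward_table
        by_aa: dict[str, list[str]] = {}
        for codon, aa in fwd.items():
            by_aa.setdefault(aa, []).append(codon)
        for aa, codons in by_aa.items():
            _FIRST_CODON[aa] = min(codons)
    return _FIRST_CODON


def reverse_translate(protein: str, table_id: int = 1) -> str:
    """Back-translate deterministically (first codon of the table per residue)."""
    table = _first_codon_table(table_id)
    try:
        return "".join(table[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate residue {exc.args[0]!r}") from exc


# stop codons in all three forward frames (TAA at offsets 0, 4, 8) and,
# via its reverse complement, in all three reverse frames as well
_STOP_PAD = "TAAATAAATAA"


def _noncoding(rng: np.random.Generator, length: int, orf_floor: int) -> str:
    """Random non-coding DNA guaranteed to host no ORF >= orf_floor."""
    from .genes import find_orfs

    if length == 0:
        return ""
    seq = list(_draw(rng, NUCLEOTIDES, length))
    for _ in range(200):
        hits = find_orfs("".join(seq), min_length=orf_floor, both_strands=True)
        if not hits:
            return "".join(seq)
        loc = hits[0]
        # break the ORF by rewriting its start codon's middle base
        mid = loc.start + 1 if loc.strand == "+" else loc.end - 2
        seq[mid - 1] = "C" if seq[mid - 1] != "C" else "G"
    raise RuntimeError("could not purge ORFs from the non-coding spacer")


def _synonyms(table_id: int = 1) -> dict[str, list[str]]:
    from Bio.Data import CodonTable

    fwd = CodonTable.unambiguous_dna_by_id[table_id].forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(fwd.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


_STOP_TRIPLETS = {"TAA", "TAG", "TGA"}
_RC_STOP_TRIPLETS = {"TTA", "CTA", "TCA"}  # plus-strand text of a minus-strand stop


def _seed_offframe_stops(cds: str, floor: int, table_id: int = 1) -> str:
    """Guarantee stops at least every ``floor`` bases in non-coding frames.

    A deterministically back-translated CDS can lack stop codons in a
    shifted or reverse reading frame over its whole length, which would
    surface as a spurious gene-length ORF.  Long stop-free runs in the five
    non-genuine frames are split at their midpoints by substituting a
    synonymous codon pair that creates a stop there; the encoded protein is
    untouched and the procedure is deterministic.
    """
    from .genes import translate as _translate

    syn = _synonyms(table_id)
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]  # excludes final stop
    terminal = cds[len(cds) - 3 :]

    def stop_free_runs(seq: str) -> list[tuple[str, int, int, int]]:
        """(strand, frame_offset, run_start, run_end) in plus coordinates,
        for stop-free stretches long enough to host an ORF >= floor."""
        n = len(seq)
        runs = []
        for strand in "+-":
            for off in range(3):
                if strand == "+" and off == 0:
                    continue  # the genuine frame
                if strand == "+":
                    stop_at = [p for p in range(off, n - 2, 3) if seq[p : p + 3] in _STOP_TRIPLETS]
                else:
                    # minus-frame `off` codons occupy plus [n-q-3, n-q-1]
                    stop_at = sorted(
                        n - q - 3
                        for q in range(off, n - 2, 3)
                        if seq[n - q - 3 : n - q] in _RC_STOP_TRIPLETS
                    )
                bounds = [-3] + stop_at + [n]
                for a, b in zip(bounds, bounds[1:]):
                    if b - (a + 3) >= floor:
                        runs.append((strand, off, a + 3, b))
        return runs

    def try_swap(i: int, strand: str, off: int) -> bool:
        """Synonymously rewrite codon pair (i, i+1) to host a stop of the
        given frame inside the hexamer; keep the genuine frame stop-free."""
        aa1 = _translate(codons[i], strict=False)
        aa2 = _translate(codons[i + 1], strict=False)
        for c1 in syn[aa1]:
            for c2 in syn[aa2]:
                hexamer = c1 + c2
                if strand == "+":
                    ok = hexamer[off : off + 3] in _STOP_TRIPLETS
                else:
                    n = len(codons) * 3 + 3
                    ok = any(
                        hexamer[(n - q - 3) - 3 * i : (n - q - 3) - 3 * i + 3]
                        in _RC_STOP_TRIPLETS
                        for q in range(off, n - 2, 3)
                        if 0 <= (n - q - 3) - 3 * i <= 3
                    )
                if ok:
                    codons[i], codons[i + 1] = c1, c2
                    return True
        return False

    for _ in range(100):
        seq = "".join(codons) + terminal
        runs = stop_free_runs(seq)
        if not runs:
            return seq
        strand, off, a, b = runs[0]
        mid_codon = ((a + b) // 2) // 3
        for delta in range(0, (b - a) // 6 + 2):
            for i in (mid_codon - delta, mid_codon + delta):
                if 0 <= i < len(codons) - 1 and try_swap(i, strand, off):
                    break
            else:
                continue
            break
        else:
            raise RuntimeError(f"could not split stop-free run {a}..{b} ({strand}{off})")
    raise RuntimeError("off-frame stop seeding did not converge")


def make_gene_cluster(
    spec: ClusterSpec,
    multi_spec: MultiSitSpec | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Emit a tandem two-gene cluster contig plus a diverged-paralog contig.

    The ``cluster`` contig holds gene1 and gene2 — reverse-translated CDSs of
    one multi-SIT protein, identical when ``duplicate_identical`` — separated
    by ``spacer_length`` bp of non-coding DNA.  The ``paralog`` contig holds
    a third copy diverged at ``third_gene_divergence`` substitutions/site
    (internal stops repaired so it stays one open reading frame).
    """
    spec.validate()
    multi_spec = multi_spec or MultiSitSpec()
    rng = np.random.default_rng(multi_spec.seed)
    protein, _ = make_multi_sit(multi_spec)
    cds = reverse_translate(protein, spec.codon_table_id) + "TAA"
    cds = _seed_offframe_stops(cds, spec.orf_floor, spec.codon_table_id)

    def flank(n: int) -> str:
        return _noncoding(rng, max(n - len(_STOP_PAD), 0), spec.orf_floor)

    gene2 = cds
    if not spec.duplicate_identical:
        gene2 = _diverge_cds(cds, 0.01, rng)
    spacer = _STOP_PAD + _noncoding(
        rng, max(spec.spacer_length - 2 * len(_STOP_PAD), 0), spec.orf_floor
    ) + _STOP_PAD
    spacer = spacer[: spec.spacer_length]
    contig = flank(spec.flank_length) + _STOP_PAD + cds + spacer + gene2 + _STOP_PAD + flank(
        spec.flank_length
    )
    g1_start = spec.flank_length + 1
    g1_end = g1_start + len(cds) - 1
    g2_start = g1_end + spec.spacer_length + 1
    g2_end = g2_start + len(gene2) - 1

    gene3 = _diverge_cds(cds, spec.third_gene_divergence, rng)
    paralog_contig = flank(spec.flank_length) + _STOP_PAD + gene3 + _STOP_PAD + flank(
        spec.flank_length
    )
    g3_start = spec.flank_length + 1

    truth = SyntheticTruth(
        gene_loci=[
            ("cluster", g1_start, g1_end, "+", "gene1"),
            ("cluster", g2_start, g2_end, "+", "gene2"),
            ("paralog", g3_start, g3_start + len(gene3) - 1, "+", "gene3"),
        ],
        spacer_length=spec.spacer_length,
    )
    return {"cluster": contig, "paralog": paralog_contig}, truth


def _diverge_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate a CDS keeping it a single ORF (start/stop intact, no internal stops)."""
    if rate == 0:
        return cds
    body = mutate(
        cds,
        rate,
        seed=int(rng.integers(2**31)),
        protected=[(1, 3), (len(cds) - 2, len(cds))],
        alphabet=NUCLEOTIDES,
    )
    out = list(body)
    stops = {"TAA", "TAG", "TGA"}
    for i in range(3, len(out) - 3, 3):
        if "".join(out[i : i + 3]) in stops:
            out[i + 2] = "C"  # TAC/TGC are not stops
    return "".join(out)


# ---------------------------------------------------------------------------
# synthetic stand-ins for the published supplementary alignments

_SPECIES = ["Sa", "Pd", "Pa", "Ns", "Np", "Pp", "Pau", "Cw", "Ld", "Ch", "Mp", "Es", "Ac", "Cc", "Pm"]


def make_unit_alignment(
    seed: int = 0,
    n_records: int = 87,
    n_cmld_absent: int = 3,
    conserved_w_column: int = 466,
    mutation_rate: float = 0.15,
) -> tuple[dict[str, str], dict]:
    """Synthetic stand-in for a published 87-way mature-SIT alignment.

    Builds an alignment of mature units from many nominal species in which,
    by construction: the nine *Synedra ulna* units (``SuSIT1A`` ...
    ``SuSIT3C``) are present and mutually similar; exactly
    ``n_cmld_absent`` records lack the CMLD motif (two ``Es``, one ``Ld``
    record, mirroring the real data's species split); a tryptophan column at
    alignment position ``conserved_w_column`` is absolutely conserved; and
    every row's degapped length lies in [436, 446] (441 base residues, up to
    5 deletions and up to 5 filled insertion slots per row).

    Returns ``(alignment, info)`` where ``info`` lists the planted facts.
    """
    if n_cmld_absent != 3:
        raise SpecError("the stand-in plants exactly 2 Es + 1 Ld CMLD-free rows")
    rng = np.random.default_rng(seed)
    w_base = 404  # loop position between the last two planted TM stretches
    u = UnitSpec(conserved_positions={**DEFAULT_CONSERVED, w_base: "W"})
    base, _ = make_mature_unit(u, seed=int(rng.integers(2**31)))

    # Insertion slots between base positions; all lie before the planted W
    # so it lands exactly at alignment column 404 + 62 = conserved_w_column.
    insert_after = [103] * 20 + [315] * 20 + [400] * 22
    if w_base + len(insert_after) != conserved_w_column:
        raise SpecError("conserved_w_column must equal 466 for the default slot layout")
    deletable = [p for p in range(90, 101)]  # featureless loop residues

    protected = sorted((p, p) for p in _unit_protected_positions(u, offset=0))

    ids: list[str] = []
    su = [f"SuSIT{g}{c}" for g in (1, 2, 3) for c in "ABC"]
    ids.extend(su)
    per_species = {"Sa": 5, "Pd": 6, "Pa": 6, "Ns": 6, "Np": 6, "Pp": 6, "Pau": 6,
                   "Cw": 6, "Ld": 6, "Ch": 5, "Mp": 5, "Es": 7, "Ac": 4, "Cc": 2, "Pm": 2}
    for sp in _SPECIES:
        ids.extend(f"{sp}_SIT{i + 1}" for i in range(per_species[sp]))
    ids = ids[:n_records]
    assert len(ids) == n_records

    cmld_free = {"Es_SIT1", "Es_SIT2", "Ld_SIT1"}
    alignment: dict[str, str] = {}
    for sid in ids:
        rate = 0.02 if sid in su else mutation_rate
        for attempt in range(50):
            row_seed = int(rng.integers(2**31))
            seq = mutate(base, rate, seed=row_seed, protected=protected)
            chars = list(seq)
            if sid in cmld_free:
                chars[u.cmld_offset - 1] = "S"  # CMLD -> SMLD: motif ablated
                if scan("".join(chars), "CMLD"):
                    continue  # a chance CMLD elsewhere; redraw this row
            row = _place_in_alignment(chars, insert_after, deletable, rng)
            alignment[sid] = row
            break
        else:
            raise RuntimeError(f"could not build CMLD-free row {sid}")

    info = {
        "w_column": conserved_w_column,
        "cmld_absent": sorted(cmld_free),
        "synedra_ids": su,
        "length_window": (436, 446),
    }
    return alignment, info


def _place_in_alignment(
    chars: list[str],
    insert_after: list[int],
    deletable: list[int],
    rng: np.random.Generator,
) -> str:
    n_del = int(rng.integers(0, 6))
    n_ins = int(rng.integers(0, 6))
    deleted = set(rng.choice(deletable, size=n_del, replace=False)) if n_del else set()
    filled = set(rng.choice(len(insert_after), size=n_ins, replace=False)) if n_ins else set()
    out: list[str] = []
    slot = 0
    for p, c in enumerate(chars, start=1):
        out.append("-" if p in deleted else c)
        while slot < len(insert_after) and insert_after[slot] == p:
            out.append(str(_draw(rng, AMINO_ACIDS, 1)[0]) if slot in filled else "-")
            slot += 1
    return "".join(out)


def make_multisit_panel(
    seed: int = 0,
    n_records: int = 48,
    n_boundary_positive: int = 43,
) -> tuple[dict[str, str], dict]:
    """Synthetic stand-in for a published panel of full-length multi-SITs.

    ``n_boundary_positive`` sequences carry a DXDID-matching motif in every
    inter-unit linker; the remainder use a linker with no DXDID match
    anywhere between their CMLD anchors.  A mix of duplicates (2 units) and
    triplicates (3 units) across nominal species.
    """
    rng = np.random.default_rng(seed)
    positive_motifs = ["DSDID", "DADID", "DTDID", "DGDID", "DNDID"]
    alignment: dict[str, str] = {}
    positives: list[str] = []
    species = (_SPECIES * ((n_records // len(_SPECIES)) + 1))[:n_records]
    for i in range(n_records):
        positive = i < n_boundary_positive
        n_units = 2 if i % 3 == 0 else 3
        motif = positive_motifs[i % len(positive_motifs)] if positive else "ESEIE"
        for attempt in range(50):
            spec = MultiSitSpec(
                n_units=n_units,
                linker_motif=motif,
                boundary_pattern="DXDID" if positive else "EXEIE",
                mutation_rate=0.05,
                seed=int(rng.integers(2**31)),
            )
            seq, _ = make_multi_sit(spec)
            if positive or not _has_internal_boundary(seq):
                break
        else:
            raise RuntimeError("could not build a boundary-negative multi-SIT")
        sid = f"{species[i]}_mSIT{i + 1}"
        alignment[sid] = seq
        if positive:
            positives.append(sid)
    return alignment, {"boundary_positive": positives}


def _has_internal_boundary(seq: str) -> bool:
    anchors = scan(seq, "CMLD")
    if len(anchors) < 2:
        return False
    dxdid = compile_pattern("DXDID")
    for a, b in zip(anchors, anchors[1:]):
        if any(a.start < h.start < b.start for h in scan(seq, dxdid)):
            return True
    return False


# ---------------------------------------------------------------------------
# truth sidecar serialization (TSV: record_id, feature_type, start, end, payload)

def write_truth(truth: SyntheticTruth, path: str | Path, record_id: str = "synthetic") -> None:
    rows: list[tuple[str, str, int, int, str]] = []
    for i, (s, e) in enumerate(truth.unit_envelopes):
        rows.append((record_id, "unit_envelope", s, e, str(i)))
    for name, positions in truth.motif_positions.items():
        for p in positions:
            rows.append((record_id, "motif", p, p, name))
    for i, segs in enumerate(truth.tm_segments):
        for s, e in segs:
            rows.append((record_id, "tm_segment", s, e, str(i)))
    for b in truth.boundary_positions:
        rows.append((record_id, "boundary", b, b, ""))
    for contig, s, e, strand, label in truth.gene_loci:
        rows.append((contig, "gene_locus", s, e, f"{label}|{strand}"))
    if truth.spacer_length is not None:
        rows.append((record_id, "spacer", 0, 0, str(truth.spacer_length)))
    with open(path, "w") as fh:
        fh.write("record_id\tfeature_type\tstart\tend\tpayload\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    truth = SyntheticTruth()
    envelopes: dict[int, tuple[int, int]] = {}
    tm: dict[int, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_id"):
            raise ValueError(f"not a truth file: {path}")
        for line in fh:
            rid, ftype, s, e, payload = line.rstrip("\n").split("\t")
            s, e = int(s), int(e)
            if ftype == "unit_envelope":
                envelopes[int(payload)] = (s, e)
            elif ftype == "motif":
                truth.motif_positions.setdefault(payload, []).append(s)
            elif ftype == "tm_segment":
                tm.setdefault(int(payload), []).append((s, e))
            elif ftype == "boundary":
                truth.boundary_positions.append(s)
            elif ftype == "gene_locus":
                label, strand = payload.rsplit("|", 1)
                truth.gene_loci.append((rid, s, e, strand, label))
            elif ftype == "spacer":
                truth.spacer_length = int(payload)
            else:
                raise ValueError(f"unknown feature_type {ftype!r}")
    truth.unit_envelopes = [envelopes[i] for i in sorted(envelopes)]
    truth.tm_segments = [tm[i] for i in sorted(tm)]
    return truth
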