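"""Dissection of multi-SIT proteins into putative mature units.

A multi-SIT is segmented by anchoring on its CMLD motifs (one per unit) and
cleaving between consecutive anchors at a DXDID boundary motif — the
aspartate-rich candidate proteolysis site.  The first residue of the
boundary motif starts the downstream fragment, matching the convention used
when measuring CMLD-cysteine to DXDID distances.  Raw inter-boundary
segments can then be trimmed to a mature-unit envelope either by global
alignment to a reference mature unit (free end gaps on the segment) or by
fixed margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .motifs import MotifHit, MotifPattern, compile_pattern, scan

__all__ = [
    "SegmentationConfig",
    "MatureUnit",
    "DistanceRecord",
    "NotSitLikeError",
    "segment_multi_sit",
    "choose_boundary",
    "cmld_dxdid_distances",
    "map_reference_positions",
    "identity_similarity",
    "boundary_positive",
    "distance_histogram",
    "plot_distance_histogram",
]


class NotSitLikeError(ValueError):
    """Raised when a protein carries no anchor motif at all."""


@dataclass(frozen=True)
class SegmentationConfig:
    anchor_pattern: str = "CMLD"
    boundary_pattern: str = "DXDID"
    target_unit_length: int = 441
    valid_length_window: tuple[int, int] = (436, 446)
    envelope_margins: tuple[int, int] = (0, 0)
    require_gxq: int = 4
    gxq_pattern: str = "GXQ"
    # pairwise-alignment scoring used for reference trimming / position mapping
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    histogram_bin_width: int = 5
    # "analogue" motifs: additional accepted anchor/boundary consensus patterns
    extra_anchor_patterns: tuple[str, ...] = ()
    extra_boundary_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.valid_length_window
        if not lo <= self.target_unit_length <= hi:
            raise ValueError("valid_length_window must bracket target_unit_length")
        if min(self.envelope_margins) < 0:
            raise ValueError("envelope_margins must be >= 0")


@dataclass(frozen=True)
class MatureUnit:
    """One dissected putative mature unit, in parent coordinates (1-based)."""

    parent_id: str
    ordinal: str            # A, B, C, ... in N->C order
    start: int
    end: int
    sequence: str
    raw_start: int          # inter-boundary segment before envelope trimming
    raw_end: int
    cmld_count: int
    gxq_count: int
    length_ok: bool
    boundary_motif_found: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DistanceRecord:
    """CMLD cysteine to DXDID first residue, within one protein."""

    sequence_id: str
    unit_ordinal: str
    cmld_cys_pos: int
    dxdid_first_pos: int

    @property
    def distance(self) -> int:
        return self.dxdid_first_pos - self.cmld_cys_pos


def _aligner(config: SegmentationConfig, free_target_ends: bool = False) -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(config.substitution_matrix)
    al.open_gap_score = -config.gap_open
    al.extend_gap_score = -config.gap_extend
    al.mode = "global"
    if free_target_ends:
        # let target (segment) overhangs dangle unaligned for free: the
        # dashes sit in the query row at the alignment boundaries
        try:
            al.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            al.query_end_gap_score = 0.0
    return al


def _scan_multi(seq: str, patterns: Sequence[str], sequence_id: str = "") -> list[MotifHit]:
    hits: list[MotifHit] = []
    for p in patterns:
        hits.extend(scan(seq, p, sequence_id))
    return sorted(hits, key=lambda h: h.start)


def choose_boundary(
    candidates: Sequence[MotifHit],
    config: SegmentationConfig,
    upstream_unit_start: int = 1,
) -> MotifHit:
    """Pick the boundary hit whose cleavage best matches the target length.

    Cleaving at hit start ``b`` gives an upstream unit of ``b −
    upstream_unit_start`` residues; the hit minimising the deviation from
    ``target_unit_length`` wins, ties going to the leftmost.
    """
    if not candidates:
        raise ValueError("choose_boundary requires at least one candidate")
    return min(
        candidates,
        key=lambda h: (
            abs((h.start - upstream_unit_start) - config.target_unit_length),
            h.start,
        ),
    )


def segment_multi_sit(
    protein: str,
    config: SegmentationConfig = SegmentationConfig(),
    reference: str | None = None,
    sequence_id: str = "",
) -> list[MatureUnit]:
    """Dissect a multi-SIT protein into one putative mature unit per anchor.

    Between consecutive anchors the cleavage point is the first residue of
    the selected boundary-motif hit; with no candidate the cleavage is
    placed to give the upstream unit ``target_unit_length`` residues and the
    unit is flagged ``boundary_motif_found=False``.  Terminal units extend
    to the sequence ends.  When ``reference`` (a gap-free mature unit) is
    supplied each raw segment is trimmed to the region aligning to the full
    reference; otherwise ``envelope_margins`` are trimmed from the raw
    segment ends.
    """
    anchor_patterns = (config.anchor_pattern, *config.extra_anchor_patterns)
    boundary_patterns = (config.boundary_pattern, *config.extra_boundary_patterns)
    anchors = _scan_multi(protein, anchor_patterns, sequence_id)
    if not anchors:
        raise NotSitLikeError(
            f"{sequence_id or 'sequence'}: no {'/'.join(anchor_patterns)} anchor motif; "
            "not a SIT-like protein"
        )
    boundary_hits = _scan_multi(protein, boundary_patterns, sequence_id)

    cuts: list[int] = [1]
    boundary_found: list[bool] = []
    for a, b in zip(anchors, anchors[1:]):
        candidates = [h for h in boundary_hits if a.start < h.start <= b.start]
        if candidates:
            chosen = choose_boundary(candidates, config, upstream_unit_start=cuts[-1])
            cuts.append(chosen.start)
            boundary_found.append(True)
        else:
            cuts.append(min(cuts[-1] + config.target_unit_length, b.start))
            boundary_found.append(False)
    cuts.append(len(protein) + 1)
    # the flag belongs to the unit upstream of each cleavage; the last unit
    # has no downstream boundary to find, so it is trivially satisfied
    unit_flags = boundary_found + [True]

    gxq = compile_pattern(config.gxq_pattern)
    anchor_pat = compile_pattern(config.anchor_pattern)
    units: list[MatureUnit] = []
    lo, hi = config.valid_length_window
    for k in range(len(anchors)):
        raw_start, raw_end = cuts[k], cuts[k + 1] - 1
        if reference is not None:
            start, end = _reference_envelope(protein, raw_start, raw_end, reference, config)
        else:
            up, down = config.envelope_margins
            start, end = raw_start + up, raw_end - down
            if start > end:
                start, end = raw_start, raw_end
        seq = protein[start - 1 : end]
        units.append(
            MatureUnit(
                parent_id=sequence_id,
                ordinal=chr(ord("A") + k),
                start=start,
                end=end,
                sequence=seq,
                raw_start=raw_start,
                raw_end=raw_end,
                cmld_count=len(scan(seq, anchor_pat, allow_overlap=False)),
                gxq_count=len(scan(seq, gxq, allow_overlap=False)),
                length_ok=lo <= len(seq) <= hi,
                boundary_motif_found=unit_flags[k],
            )
        )
    return units


def _reference_envelope(
    protein: str,
    raw_start: int,
    raw_end: int,
    reference: str,
    config: SegmentationConfig,
) -> tuple[int, int]:
    """Trim a raw segment to the span aligning to the full reference unit."""
    if any(g in reference for g in "-."):
        raise ValueError("reference mature unit must be gap-free")
    segment = protein[raw_start - 1 : raw_end]
    aligner = _aligner(config, free_target_ends=True)
    aln = aligner.align(segment, reference)[0]
    blocks = aln.aligned[0]  # aligned blocks on the segment (target)
    first = int(blocks[0][0])       # 0-based inclusive
    last = int(blocks[-1][1]) - 1   # 0-based inclusive
    return raw_start + first, raw_start + last


def cmld_dxdid_distances(
    protein: str,
    config: SegmentationConfig = SegmentationConfig(),
    sequence_id: str = "",
) -> list[DistanceRecord]:
    """Distance from each CMLD cysteine to the nearest downstream DXDID start.

    Anchors with no downstream boundary hit yield no record (the last unit
    of a multi-SIT has no following linker).
    """
    anchors = _scan_multi(protein, (config.anchor_pattern, *config.extra_anchor_patterns), sequence_id)
    boundaries = _scan_multi(
        protein, (config.boundary_pattern, *config.extra_boundary_patterns), sequence_id
    )
    records: list[DistanceRecord] = []
    for k, a in enumerate(anchors):
        downstream = [h.start for h in boundaries if h.start > a.start]
        if not downstream:
            continue
        records.append(
            DistanceRecord(
                sequence_id=sequence_id,
                unit_ordinal=chr(ord("A") + k),
                cmld_cys_pos=a.start,
                dxdid_first_pos=min(downstream),
            )
        )
    return records


def distance_histogram(
    records: Sequence[DistanceRecord], bin_width: int = 5
) -> pd.DataFrame:
    """Bin CMLD->DXDID distances into fixed-width bins (bin edges inclusive-left)."""
    if not records:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    d = np.array([r.distance for r in records])
    lo = (d.min() // bin_width) * bin_width
    hi = ((d.max() // bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:] - 1, "count": counts}
    )


def plot_distance_histogram(records: Sequence[DistanceRecord], bin_width: int = 5, ax=None):
    """Bar plot of the binned CMLD->DXDID distance distribution."""
    import matplotlib.pyplot as plt

    table = distance_histogram(records, bin_width)
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(table["bin_start"], table["count"], width=bin_width, align="edge", edgecolor="k")
    ax.set_xlabel("CMLD cysteine to DXDID first residue (residues)")
    ax.set_ylabel("count")
    return ax


def boundary_positive(
    protein: str, config: SegmentationConfig = SegmentationConfig()
) -> bool:
    """True iff every inter-anchor region carries a boundary-motif hit.

    Requires at least two anchors (a single-unit protein has no inter-unit
    boundary to test).
    """
    anchors = _scan_multi(protein, (config.anchor_pattern, *config.extra_anchor_patterns))
    if len(anchors) < 2:
        return False
    hits = _scan_multi(protein, (config.boundary_pattern, *config.extra_boundary_patterns))
    for a, b in zip(anchors, anchors[1:]):
        if not any(a.start < h.start < b.start for h in hits):
            return False
    return True


def map_reference_positions(
    unit: str,
    reference: str,
    positions: Sequence[int],
    config: SegmentationConfig = SegmentationConfig(),
) -> dict[int, tuple[str, int | None, str | None]]:
    """Map reference residue positions onto a unit via global alignment.

    Returns ``{ref_pos: (ref_residue, unit_pos | None, unit_residue | None)}``;
    a ``None`` unit position means the reference residue is deleted in the
    unit.  Positions are 1-based.
    """
    if not unit or not reference:
        raise ValueError("map_reference_positions requires non-empty sequences")
    if any(g in reference for g in "-."):
        raise ValueError("reference must be gap-free")
    aln = _aligner(config).align(reference, unit)[0]
    ref_blocks, unit_blocks = aln.aligned
    ref_to_unit: dict[int, int] = {}
    for (rs, re), (us, _) in zip(ref_blocks, unit_blocks):
        for off in range(re - rs):
            ref_to_unit[rs + off + 1] = us + off + 1
    out: dict[int, tuple[str, int | None, str | None]] = {}
    for p in positions:
        if not 1 <= p <= len(reference):
            raise ValueError(f"reference position {p} outside 1..{len(reference)}")
        up = ref_to_unit.get(p)
        out[p] = (reference[p - 1], up, unit[up - 1] if up else None)
    return out


def identity_similarity(
    a: str, b: str, config: SegmentationConfig = SegmentationConfig()
) -> tuple[float, float]:
    """Percent identity and similarity of two sequences under global alignment.

    Identity counts identical aligned residues; similarity additionally
    counts residue pairs with a positive substitution score.  Both are
    percentages of alignment columns (dual-gap columns cannot occur).
    """
    if not a or not b:
        raise ValueError("identity_similarity requires non-empty sequences")
    matrix = substitution_matrices.load(config.substitution_matrix)
    aln = _aligner(config).align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    columns = len(sa)
    ident = sim = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            sim += 1
        elif matrix[x, y] > 0:
            sim += 1
    return 100.0 * ident / columns, 100.0 * sim / columns
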