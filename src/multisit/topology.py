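"""Hydropathy-based transmembrane-segment prediction.

A single-pass Kyte–Doolittle heuristic: window-averaged hydropathy,
thresholded into candidate runs, with short-dip merging and a minimum
segment length.  A canonical mature SIT unit shows ten such segments, and
the CMLD motif sits at the edge of one hydrophobic region — the
``motif_membrane_context`` call labels a motif hit accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .motifs import MotifHit

__all__ = ["TMTopology", "hydropathy_profile", "predict_tm_segments", "motif_membrane_context"]


@dataclass(frozen=True)
class TMTopology:
    sequence_id: str
    segments: tuple[tuple[int, int], ...]  # 1-based inclusive, disjoint, ordered
    profile: np.ndarray = field(repr=False, compare=False)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Centred sliding-window mean of the Kyte–Doolittle index.

    ``window`` must be odd and no longer than the sequence; windows shrink
    symmetrically-as-possible at the termini (the mean is taken over the
    in-range part of the window).
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    n = len(protein)
    if window > n:
        raise ValueError(f"window {window} longer than sequence ({n})")
    values = np.array([KYTE_DOOLITTLE[aa] for aa in protein])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _threshold_runs(mask: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    for i in np.flatnonzero(mask):
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return runs


def predict_tm_segments(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    merge_gap: int = 3,
    max_len: int = 25,
    sequence_id: str = "",
) -> TMTopology:
    """Call transmembrane segments from the windowed hydropathy profile.

    Maximal runs with profile >= ``threshold`` are found; runs separated by
    <= ``merge_gap`` residues are merged; runs shorter than ``min_len`` are
    discarded.  A run longer than ``max_len`` is split recursively at its
    interior profile minimum, but only when both halves can still reach
    ``min_len`` — a marginally over-long run (< 2*min_len + 1) is kept whole
    rather than shattered into sub-threshold fragments.
    """
    profile = hydropathy_profile(protein, window)
    runs = _threshold_runs(profile >= threshold)
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = [r for r in merged if r[1] - r[0] + 1 >= min_len]

    def split(s: int, e: int) -> list[tuple[int, int]]:
        if e - s + 1 <= max_len or e - s + 1 < 2 * min_len + 1:
            return [(s, e)]
        # cut at the profile minimum among positions leaving both halves
        # at least min_len wide (a bridged double-helix dips mid-run)
        lo, hi = s + min_len, e - min_len
        cut = lo + int(np.argmin(profile[lo : hi + 1]))
        return split(s, cut - 1) + split(cut + 1, e)

    segments: list[tuple[int, int]] = []
    for s, e in kept:
        segments.extend(split(s, e))
    return TMTopology(
        sequence_id=sequence_id,
        segments=tuple((s + 1, e + 1) for s, e in segments),
        profile=profile,
    )


def motif_membrane_context(
    topology: TMTopology, hit: MotifHit, edge_margin: int = 5
) -> str:
    """Classify a motif hit as ``inside-TM``, ``edge-of-TM`` or ``extramembrane``.

    Edge-of-TM means the hit overlaps a segment boundary +- ``edge_margin``
    residues; inside-TM means it lies fully within a segment without
    touching an edge zone.
    """
    n = len(topology.profile)
    if not 1 <= hit.start <= hit.end <= n:
        raise ValueError(f"hit {hit.start}..{hit.end} outside sequence 1..{n}")
    for s, e in topology.segments:
        for boundary in (s, e):
            if hit.start <= boundary + edge_margin and hit.end >= boundary - edge_margin:
                return "edge-of-TM"
    for s, e in topology.segments:
        if s <= hit.start and hit.end <= e:
            return "inside-TM"
    return "extramembrane"
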