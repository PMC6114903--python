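"""End-to-end annotation of multi-SIT candidate proteins.

Chains the toolkit's stages in fixed order — motif scan, segmentation into
mature units, CMLD->DXDID distances, per-unit transmembrane prediction —
into a deterministic, fail-soft report: a record without an anchor motif is
flagged "not SIT-like" and the run continues.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .motifs import hits_to_dataframe, scan
from .segment import (
    NotSitLikeError,
    SegmentationConfig,
    cmld_dxdid_distances,
    segment_multi_sit,
)
from .topology import predict_tm_segments

__all__ = ["AnnotationReport", "annotate"]

#: motifs scanned for the per-record motif table
REPORT_MOTIFS = ("CMLD", "GXQ", "YQXDXVYL", "DXDID")


@dataclass
class AnnotationReport:
    """Tables + run metadata for one annotation run.

    All coordinates are 1-based inclusive in the input sequences; the report
    carries no timestamps so identical inputs and config give byte-identical
    output.
    """

    units: pd.DataFrame
    distances: pd.DataFrame
    tm: pd.DataFrame
    motifs: pd.DataFrame
    failures: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return len(self.failures)

    def write_tsv(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("units", self.units),
            ("distances", self.distances),
            ("tm", self.tm),
            ("motifs", self.motifs),
        ]:
            path = prefix.with_name(prefix.name + f".{name}.tsv")
            with open(path, "w") as fh:
                fh.write("# coordinates are 1-based inclusive\n")
                df.to_csv(fh, sep="\t", index=False)
            written.append(path)
        return written

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "failures": self.failures,
            "units": self.units.to_dict(orient="records"),
            "distances": self.distances.to_dict(orient="records"),
            "tm": self.tm.to_dict(orient="records"),
            "motifs": self.motifs.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def annotate(
    sequences: Mapping[str, str],
    config: SegmentationConfig = SegmentationConfig(),
    reference: str | None = None,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
    tm_min_len: int = 15,
    seed: int | None = None,
) -> AnnotationReport:
    """Annotate each protein: units, distances, TM counts, motif hits.

    Per-record hard failures (no anchor motif) are collected and the run
    continues; they are listed in ``report.failures``.
    """
    unit_rows, dist_rows, tm_rows, motif_frames, failures = [], [], [], [], []
    for sid, seq in sequences.items():
        for pat in REPORT_MOTIFS:
            hits = scan(seq, pat, sequence_id=sid)
            if hits:
                motif_frames.append(hits_to_dataframe(hits))
        try:
            units = segment_multi_sit(seq, config, reference=reference, sequence_id=sid)
        except NotSitLikeError as exc:
            failures.append({"sequence_id": sid, "error": "not SIT-like", "detail": str(exc)})
            continue
        for u in units:
            topo = predict_tm_segments(
                u.sequence,
                window=tm_window,
                threshold=tm_threshold,
                min_len=tm_min_len,
                sequence_id=f"{sid}:{u.ordinal}",
            )
            unit_rows.append(
                {
                    "sequence_id": sid,
                    "ordinal": u.ordinal,
                    "start": u.start,
                    "end": u.end,
                    "length": u.length,
                    "cmld_count": u.cmld_count,
                    "gxq_count": u.gxq_count,
                    "length_ok": u.length_ok,
                    "boundary_found": u.boundary_motif_found,
                    "tm_segments": topo.n_segments,
                }
            )
            tm_rows.extend(
                {"sequence_id": sid, "ordinal": u.ordinal, "tm_start": s, "tm_end": e}
                for s, e in topo.segments
            )
        dist_rows.extend(
            {
                "sequence_id": r.sequence_id,
                "unit_ordinal": r.unit_ordinal,
                "cmld_cys_pos": r.cmld_cys_pos,
                "dxdid_first_pos": r.dxdid_first_pos,
                "distance": r.distance,
            }
            for r in cmld_dxdid_distances(seq, config, sequence_id=sid)
        )

    unit_cols = ["sequence_id", "ordinal", "start", "end", "length", "cmld_count",
                 "gxq_count", "length_ok", "boundary_found", "tm_segments"]
    dist_cols = ["sequence_id", "unit_ordinal", "cmld_cys_pos", "dxdid_first_pos", "distance"]
    tm_cols = ["sequence_id", "ordinal", "tm_start", "tm_end"]
    motif_cols = ["sequence_id", "pattern", "start", "end", "match"]
    return AnnotationReport(
        units=pd.DataFrame(unit_rows, columns=unit_cols),
        distances=pd.DataFrame(dist_rows, columns=dist_cols),
        tm=pd.DataFrame(tm_rows, columns=tm_cols),
        motifs=(
            pd.concat(motif_frames, ignore_index=True)
            if motif_frames
            else pd.DataFrame(columns=motif_cols)
        ),
        failures=failures,
        metadata={
            "version": __version__,
            "seed": seed,
            "config": dataclasses.asdict(config),
            "tm": {"window": tm_window, "threshold": tm_threshold, "min_len": tm_min_len},
        },
    )
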