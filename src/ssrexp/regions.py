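"""Assignment of SSRs to transcribed regions and positional/GC descriptors.

Transcripts are sense-oriented with 1-based inclusive coordinates.  A
protein-coding transcript is partitioned into 5'-UTR, CDS and 3'-UTR by
its CDS interval; SSRs straddling a junction fall into boundary
categories and are excluded from region-level statistics downstream.
lncRNAs form their own category (the whole transcript is the "region");
transcripts with neither a CDS nor an lncRNA flag are "other".

The relative position of an SSR inside its region is
``(ssr_start - region_start + 1) / region_length``, which lies in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .miner import SSRRecord


class Region(str, Enum):
    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"
    FIVE_UTR_CDS_BOUNDARY = "5UTR-CDS"
    CDS_THREE_UTR_BOUNDARY = "CDS-3UTR"
    LNCRNA = "lncRNA"
    OTHER = "other"


#: Categories for which a relative position is defined.
POSITIONAL_REGIONS = {Region.FIVE_UTR, Region.CDS, Region.THREE_UTR, Region.LNCRNA}

#: The three transcribed regions used in region-level statistics.
CORE_REGIONS = (Region.FIVE_UTR, Region.CDS, Region.THREE_UTR)


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    length: int
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    is_lncrna: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("transcript length must be >= 1")
        has_start = self.cds_start is not None
        has_end = self.cds_end is not None
        if has_start != has_end:
            raise ValueError("cds_start and cds_end must be given together")
        if has_start:
            if not 1 <= self.cds_start <= self.cds_end <= self.length:
                raise ValueError(
                    f"invalid CDS {self.cds_start}-{self.cds_end} for length {self.length}"
                )
            if self.is_lncrna:
                raise ValueError("an lncRNA cannot carry a CDS")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None


@dataclass(frozen=True)
class RegionAssignment:
    region: Region
    relative_position: Optional[float] = None


def relative_position(ssr_start: int, region_start: int, region_length: int) -> float:
    """Relative position of an SSR start inside its region, in (0, 1]."""
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if not region_start <= ssr_start <= region_start + region_length - 1:
        raise ValueError(
            f"SSR start {ssr_start} outside region "
            f"[{region_start}, {region_start + region_length - 1}]"
        )
    return (ssr_start - region_start + 1) / region_length


def region_bounds(ann: TranscriptAnnotation) -> dict[Region, tuple[int, int]]:
    """Map each positional region of a transcript to (start, length)."""
    if ann.is_lncrna:
        return {Region.LNCRNA: (1, ann.length)}
    if not ann.has_cds:
        return {}
    bounds: dict[Region, tuple[int, int]] = {}
    if ann.cds_start > 1:
        bounds[Region.FIVE_UTR] = (1, ann.cds_start - 1)
    bounds[Region.CDS] = (ann.cds_start, ann.cds_end - ann.cds_start + 1)
    if ann.cds_end < ann.length:
        bounds[Region.THREE_UTR] = (ann.cds_end + 1, ann.length - ann.cds_end)
    return bounds


def assign_region(ssr: SSRRecord, ann: TranscriptAnnotation) -> RegionAssignment:
    """Assign one SSR to a transcribed region by full containment.

    An SSR overlapping a UTR/CDS junction gets the corresponding boundary
    category (no relative position).
    """
    if ssr.start < 1 or ssr.end > ann.length:
        raise ValueError(
            f"SSR {ssr.start}-{ssr.end} outside transcript "
            f"{ann.transcript_id} of length {ann.length}"
        )
    if ann.is_lncrna:
        return RegionAssignment(Region.LNCRNA, relative_position(ssr.start, 1, ann.length))
    if not ann.has_cds:
        return RegionAssignment(Region.OTHER, None)
    cs, ce = ann.cds_start, ann.cds_end
    if ssr.end < cs:
        return RegionAssignment(
            Region.FIVE_UTR, relative_position(ssr.start, 1, cs - 1)
        )
    if ssr.start >= cs and ssr.end <= ce:
        return RegionAssignment(
            Region.CDS, relative_position(ssr.start, cs, ce - cs + 1)
        )
    if ssr.start > ce:
        return RegionAssignment(
            Region.THREE_UTR, relative_position(ssr.start, ce + 1, ann.length - ce)
        )
    # straddles at least one junction; classify by the 5'-most junction hit
    if ssr.start < cs:
        return RegionAssignment(Region.FIVE_UTR_CDS_BOUNDARY, None)
    return RegionAssignment(Region.CDS_THREE_UTR_BOUNDARY, None)


def gc_content(sequence: str) -> float:
    """GC percentage of a sequence; ``N`` bases are excluded from the denominator."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    counts = {c: seq.count(c) for c in "ACGTN"}
    if sum(counts[c] for c in "ACGTN") != len(seq):
        raise ValueError("sequence must contain only A/C/G/T/N")
    denom = len(seq) - counts["N"]
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def excise(sequence: str, spans: Sequence[tuple[int, int]]) -> str:
    """Remove 1-based inclusive spans from a sequence (spans may touch)."""
    keep = np.ones(len(sequence), dtype=bool)
    for s, e in spans:
        keep[max(s - 1, 0) : e] = False
    return "".join(c for c, k in zip(sequence, keep) if k)


def background_gc(
    transcript_seq: str,
    ann: TranscriptAnnotation,
    region: Region,
    ssr_spans: Sequence[tuple[int, int]],
) -> float:
    """GC% of the host region with all SSR tracts in that region excised.

    Returns NaN when the region is fully covered by SSR tracts.
    """
    bounds = region_bounds(ann)
    if region not in bounds:
        raise ValueError(f"transcript {ann.transcript_id} has no region {region}")
    rs, rlen = bounds[region]
    region_seq = transcript_seq[rs - 1 : rs - 1 + rlen]
    local = [
        (max(s - rs + 1, 1), min(e - rs + 1, rlen))
        for s, e in ssr_spans
        if e >= rs and s <= rs + rlen - 1
    ]
    rest = excise(region_seq, local)
    if not rest or set(rest) == {"N"}:
        return float("nan")
    return gc_content(rest)


# ---------------------------------------------------------------------------
# tabular layer


def read_annotation_table(path) -> dict[str, TranscriptAnnotation]:
    """Read the coordinate TSV: transcript_id, length, cds_start, cds_end, is_lncrna.

    Empty CDS fields are allowed (non-coding transcripts).
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    anns = {}
    for row in df.itertuples(index=False):
        cs = None if pd.isna(row.cds_start) else int(row.cds_start)
        ce = None if pd.isna(row.cds_end) else int(row.cds_end)
        lnc = bool(row.is_lncrna) if not pd.isna(row.is_lncrna) else False
        anns[row.transcript_id] = TranscriptAnnotation(
            transcript_id=row.transcript_id,
            length=int(row.length),
            cds_start=cs,
            cds_end=ce,
            is_lncrna=lnc,
        )
    return anns


def write_annotation_table(anns: Mapping[str, TranscriptAnnotation], path) -> None:
    rows = [
        (
            a.transcript_id,
            a.length,
            a.cds_start if a.cds_start is not None else "",
            a.cds_end if a.cds_end is not None else "",
            int(a.is_lncrna),
        )
        for a in anns.values()
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "length", "cds_start", "cds_end", "is_lncrna"]
    ).to_csv(path, sep="\t", index=False)


def annotate_ssrs(
    ssr_df: pd.DataFrame,
    annotations: Mapping[str, TranscriptAnnotation],
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Build the assignment table: SSR rows + region, relative position, GC.

    ``ssr_gc``/``background_gc`` are only filled when sequences are given.
    """
    regions: list[str] = []
    relpos: list[float] = []
    ssr_gc: list[float] = []
    bg_gc: list[float] = []

    spans_by_tid_region: dict[tuple[str, Region], list[tuple[int, int]]] = {}
    assigned: list[RegionAssignment] = []
    for row in ssr_df.itertuples(index=False):
        ann = annotations.get(row.transcript_id)
        if ann is None:
            raise KeyError(f"no annotation for transcript {row.transcript_id}")
        rec = SSRRecord(
            transcript_id=row.transcript_id,
            motif=row.motif,
            canonical_motif=row.canonical_motif,
            motif_size=int(row.motif_size),
            repeat_count=int(row.repeat_count),
            start=int(row.start),
            end=int(row.end),
            tract_length=int(row.tract_length),
        )
        asg = assign_region(rec, ann)
        assigned.append(asg)
        regions.append(asg.region.value)
        relpos.append(asg.relative_position if asg.relative_position is not None else float("nan"))
        spans_by_tid_region.setdefault((row.transcript_id, asg.region), []).append(
            (rec.start, rec.end)
        )

    if sequences is not None:
        for row, asg in zip(ssr_df.itertuples(index=False), assigned):
            seq = sequences[row.transcript_id]
            ssr_gc.append(gc_content(seq[int(row.start) - 1 : int(row.end)]))
            ann = annotations[row.transcript_id]
            if asg.region in POSITIONAL_REGIONS:
                bg_gc.append(
                    background_gc(
                        seq,
                        ann,
                        asg.region,
                        spans_by_tid_region[(row.transcript_id, asg.region)],
                    )
                )
            else:
                bg_gc.append(float("nan"))
    else:
        ssr_gc = [float("nan")] * len(ssr_df)
        bg_gc = [float("nan")] * len(ssr_df)

    out = ssr_df.copy()
    out["region"] = regions
    out["relative_position"] = relpos
    out["ssr_gc"] = ssr_gc
    out["background_gc"] = bg_gc
    return out
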