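"""Map the databank to the target genome and distill unique anchors.

An anchor is an HCE with exactly one accepted placement on the reference
(established by the databank) and exactly one on the target.  The final step
re-expresses every anchor as a gapless scaffold-to-chromosome alignment so
the chaining stage can operate purely in the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import aligner as al
from .databank import DatabankEntry
from .io_formats import GenomeSequences, PSLRecord

__all__ = ["Anchor", "AnchorParams", "map_databank", "filter_anchors",
           "transfer_to_reference"]


@dataclass
class AnchorParams:
    """Thresholds for admitting target placements.

    ``min_identity`` is applied during alignment; ``min_ali`` is the minimum
    fraction of the element covered by aligned blocks (typically 0.95,
    relaxable to 0.80 for divergent genome pairs).  ``strict_unique`` counts
    all reported target hits toward multiplicity instead of only those
    passing the coverage filter.
    """

    min_identity: float = 0.90
    min_ali: float = 0.95
    strict_unique: bool = False

    def __post_init__(self) -> None:
        if not (0.5 <= self.min_ali <= 1):
            raise ValueError(f"min_ali must be in [0.5, 1], got {self.min_ali}")


@dataclass
class Anchor:
    """One HCE bridging a reference interval and a target interval."""

    hce_id: str
    ref: tuple[str, int, int, str]  # (chromosome, start, end, strand)
    tgt: tuple[str, int, int, str]  # (scaffold, start, end, strand)
    tgt_alignment: PSLRecord
    ref_alignment: PSLRecord
    identity: float
    coverage: float


def map_databank(
    databank: list[DatabankEntry],
    target: GenomeSequences,
    params: AnchorParams | None = None,
    index: al.SeedIndex | None = None,
    aligner_params: al.AlignerParams | None = None,
    cores: int = 1,
) -> list[PSLRecord]:
    """Align every databank element against the target genome.

    Raw records are returned sorted by (tName, tStart); filtering to anchors
    happens separately so relaxed thresholds can be explored cheaply.
    """
    params = params or AnchorParams()
    if not databank:
        raise ValueError("databank is empty")
    if len(target) == 0 or target.total_length == 0:
        raise ValueError("target genome is empty")
    ap = aligner_params or al.AlignerParams()
    ap = al.AlignerParams(
        min_identity=params.min_identity, fast_mode=ap.fast_mode,
        match=ap.match, mismatch=ap.mismatch, gap_open=ap.gap_open,
        gap_extend=ap.gap_extend, band_width=ap.band_width,
    )
    if index is None:
        index = al.build_index(target)
    queries = {e.hce.hce_id: e.hce.sequence for e in databank}
    records = al.align_queries(queries, index, target, ap, cores=cores)
    records.sort(key=lambda r: (r.tName, r.tStart, r.qName, r.strand))
    return records


def filter_anchors(
    records: list[PSLRecord],
    databank: list[DatabankEntry],
    params: AnchorParams | None = None,
) -> list[Anchor]:
    """Keep HCE with exactly one target placement above the coverage threshold.

    Records below ``min_ali`` coverage are dropped first; any element with two
    or more surviving placements is removed entirely.  Survivors are joined
    back to their databank entry and returned sorted by (scaffold, start).
    """
    params = params or AnchorParams()
    by_entry = {e.hce.hce_id: e for e in databank}
    surviving: dict[str, list[PSLRecord]] = {}
    multiplicity: dict[str, int] = {}
    for rec in records:
        if rec.qName not in by_entry:
            raise ValueError(
                f"alignment for {rec.qName!r} has no databank entry"
            )
        counts_toward_unique = params.strict_unique or al.coverage(rec) >= params.min_ali
        if counts_toward_unique:
            multiplicity[rec.qName] = multiplicity.get(rec.qName, 0) + 1
        if al.coverage(rec) >= params.min_ali:
            surviving.setdefault(rec.qName, []).append(rec)
    anchors: list[Anchor] = []
    for hce_id, recs in surviving.items():
        if multiplicity.get(hce_id, 0) != 1 or len(recs) != 1:
            continue
        rec = recs[0]
        entry = by_entry[hce_id]
        anchors.append(
            Anchor(
                hce_id=hce_id,
                ref=entry.ref_placement,
                tgt=(rec.tName, rec.tStart, rec.tEnd, rec.strand),
                tgt_alignment=rec,
                ref_alignment=entry.ref_alignment,
                identity=al.identity(rec),
                coverage=al.coverage(rec),
            )
        )
    anchors.sort(key=lambda a: (a.tgt[0], a.tgt[1]))
    return anchors


def _compose_strand(a: str, b: str) -> str:
    return "+" if a == b else "-"


def transfer_to_reference(anchors: list[Anchor]) -> list[PSLRecord]:
    """Re-express each anchor as one gapless scaffold-vs-chromosome alignment.

    The target side of the output is the anchor's reference placement; the
    query side is its scaffold interval.  The strand is the composition of
    the two placements' strands.  When the two spans differ (a gapped element
    alignment), the block takes the shorter span, anchored at the interval
    starts after orientation; base-level structure inside the element is
    deliberately collapsed.  Output is one record per anchor.
    """
    out: list[PSLRecord] = []
    for a in anchors:
        chrom, rs, re_, ref_strand = a.ref
        scaf, ts, te, tgt_strand = a.tgt
        strand = _compose_strand(ref_strand, tgt_strand)
        length = min(re_ - rs, te - ts)
        q_size = a.tgt_alignment.tSize  # scaffold length
        t_size = a.ref_alignment.tSize  # chromosome length
        t_start = rs
        if strand == "+":
            q_fwd_start = ts
            q_block_start = ts
        else:
            # block occupies the high end of the scaffold interval so that it
            # starts at the interval start on the reversed strand
            q_fwd_start = te - length
            q_block_start = q_size - te
        matches = round(a.identity * length)
        rec = PSLRecord(
            matches=matches, misMatches=length - matches, repMatches=0,
            nCount=0, qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
            strand=strand, qName=scaf, qSize=q_size,
            qStart=q_fwd_start, qEnd=q_fwd_start + length,
            tName=chrom, tSize=t_size, tStart=t_start, tEnd=t_start + length,
            blockCount=1, blockSizes=[length],
            qStarts=[q_block_start], tStarts=[t_start],
        )
        rec.validate()
        out.append(rec)
    out.sort(key=lambda r: (r.tName, r.tStart, r.qName))
    return out
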