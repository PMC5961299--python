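"""Build a reference-specific databank of highly conserved elements (HCE).

An HCE enters the databank only if it places on the reference genome
perfectly (zero mismatches inside aligned blocks), near-full-length
(>= 99% of the element aligned), and uniquely (exactly one such placement).
Elements failing any filter are counted but excluded; the survivors are the
potential anchors for the target-mapping stages.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from . import aligner as al
from .io_formats import GenomeSequences, PSLRecord, read_bed, read_fasta

__all__ = [
    "HCERecord",
    "DatabankEntry",
    "DatabankParams",
    "filter_min_length",
    "split_long_hce",
    "build_databank",
    "load_hces",
    "MIN_HCE_LENGTH",
]

# Shortest element worth keeping as a mapping landmark.
MIN_HCE_LENGTH = 40


@dataclass
class HCERecord:
    """A highly conserved element: id, sequence, optional source coordinates."""

    hce_id: str
    sequence: str
    source_coords: tuple[str, int, int] | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DatabankEntry:
    """An HCE with its single perfect placement on the reference."""

    hce: HCERecord
    ref_placement: tuple[str, int, int, str]  # (chromosome, start, end, strand)
    ref_alignment: PSLRecord


@dataclass
class DatabankParams:
    """Filters applied when admitting HCE to the databank.

    ``min_coverage`` is the fraction of the element that must sit inside
    aligned blocks.  ``strict_unique`` counts *all* reported reference
    alignments toward multiplicity rather than only those passing the
    identity/coverage filters.
    """

    min_coverage: float = 0.99
    strict_unique: bool = False
    aligner: al.AlignerParams = field(
        default_factory=lambda: al.AlignerParams(min_identity=0.90)
    )


def load_hces(fasta_path, bed_path=None) -> list[HCERecord]:
    """Read an HCE multi-FASTA, optionally joining source coordinates from BED."""
    genome = read_fasta(fasta_path)
    coords: dict[str, tuple[str, int, int]] = {}
    if bed_path is not None:
        for iv in read_bed(bed_path):
            if len(iv) >= 4:
                coords.setdefault(iv[3], (iv[0], iv[1], iv[2]))
    return [
        HCERecord(name, seq, coords.get(name)) for name, seq in genome
    ]


def filter_min_length(
    hces: list[HCERecord], min_len: int = MIN_HCE_LENGTH
) -> list[HCERecord]:
    """Keep only elements of at least ``min_len`` bp, preserving order."""
    return [h for h in hces if len(h) >= min_len]


def split_long_hce(
    hces: list[HCERecord],
    max_len: int = 500,
    piece: int = 250,
    min_len: int = MIN_HCE_LENGTH,
) -> list[HCERecord]:
    """Cut elements longer than ``max_len`` into consecutive ``piece``-bp fragments.

    A final remainder of at least ``min_len`` becomes its own fragment; a
    shorter remainder is appended to the last piece.  Fragment ids are
    ``<id>__partN`` and source coordinates are offset accordingly.
    """
    if piece < min_len:
        raise ValueError(f"piece ({piece}) must be >= min_len ({min_len})")
    out: list[HCERecord] = []
    for h in hces:
        if len(h) <= max_len:
            out.append(h)
            continue
        cuts = list(range(0, len(h), piece))
        bounds = [(c, min(c + piece, len(h))) for c in cuts]
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < min_len:
            s, e = bounds.pop()
            bounds[-1] = (bounds[-1][0], e)
        for n, (s, e) in enumerate(bounds, start=1):
            coords = None
            if h.source_coords is not None:
                c, cs, _ = h.source_coords
                coords = (c, cs + s, cs + e)
            out.append(HCERecord(f"{h.hce_id}__part{n}", h.sequence[s:e], coords))
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def build_databank(
    hces: list[HCERecord],
    reference: GenomeSequences,
    params: DatabankParams | None = None,
    index: al.SeedIndex | None = None,
) -> tuple[list[DatabankEntry], dict]:
    """Align every HCE to the reference and keep the unique perfect placements.

    Returns the databank entries (in HCE id order) and a stats dict with the
    mapped / uniquely-mapped counts, length summaries of the admitted
    elements, and the fraction of the reference covered by their placements.
    """
    params = params or DatabankParams()
    if len(reference) == 0 or reference.total_length == 0:
        raise ValueError("reference genome is empty")
    ids = [h.hce_id for h in hces]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate HCE ids: {dup[:5]}")
    if index is None:
        index = al.build_index(reference)

    entries: list[DatabankEntry] = []
    n_mapped = n_multi = n_unmapped = 0
    for h in sorted(hces, key=lambda x: x.hce_id):
        recs = al.align_query(
            h.sequence, index, reference, params.aligner, qname=h.hce_id
        )
        passing = [
            r
            for r in recs
            if r.misMatches == 0 and al.coverage(r) >= params.min_coverage
        ]
        multiplicity = len(recs) if params.strict_unique else len(passing)
        if not passing:
            n_unmapped += 1
            continue
        n_mapped += 1
        if multiplicity > 1:
            n_multi += 1
            continue
        best = passing[0]
        entries.append(
            DatabankEntry(
                hce=h,
                ref_placement=(best.tName, best.tStart, best.tEnd, best.strand),
                ref_alignment=best,
            )
        )

    lengths = [len(e.hce) for e in entries]
    placements: dict[str, list[tuple[int, int]]] = {}
    for e in entries:
        chrom, s, t, _ = e.ref_placement
        placements.setdefault(chrom, []).append((s, t))
    covered = sum(_union_length(ivs) for ivs in placements.values())
    stats = {
        "n_input": len(hces),
        "n_mapped": n_mapped,
        "n_unmapped": n_unmapped,
        "n_multi_mapped": n_multi,
        "n_unique": len(entries),
        "total_length": sum(lengths),
        "min_length": min(lengths) if lengths else 0,
        "max_length": max(lengths) if lengths else 0,
        "median_length": statistics.median(lengths) if lengths else 0.0,
        "genome_fraction": covered / reference.total_length,
    }
    return entries, stats
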