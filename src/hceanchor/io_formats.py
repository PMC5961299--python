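"""Readers and writers for the plain-text formats the anchoring pipeline touches.

All coordinates are 0-based half-open internally and on disk (PSL/BED
convention).  Genome input and output is multi-FASTA; pairwise alignments are
21-column PSL; chained alignments use the UCSC ``chain`` text layout; the
per-chromosome hierarchy of chains uses the UCSC ``net`` text layout.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomeSequences",
    "PSLRecord",
    "ChainRecord",
    "NetNode",
    "read_fasta",
    "write_fasta",
    "compute_sizes",
    "read_psl",
    "write_psl",
    "read_bed",
    "write_bed",
    "write_chain",
    "read_chain",
    "write_net",
    "read_net",
]

# IUPAC nucleotide codes accepted on input; everything is stored uppercased.
_IUPAC = set("ACGTNRYSWKMBDHV")


class FormatError(ValueError):
    """A file or record violates its format contract."""


def _open_text(path, mode: str = "rt"):
    """Open a path, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequences:
    """An ordered collection of named DNA sequences (a genome assembly).

    ``entries`` maps sequence name to uppercase DNA string.  Names are the
    first whitespace-delimited token of each FASTA header and must be unique.
    """

    entries: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries.items())

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.entries.items()}


def read_fasta(path) -> GenomeSequences:
    """Read a (possibly gzipped) multi-FASTA file into a :class:`GenomeSequences`.

    Sequence names are the first whitespace-delimited header token; sequences
    are uppercased and validated against the IUPAC nucleotide alphabet.
    """
    entries: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.id
            if name in entries:
                raise FormatError(f"duplicate sequence name {name!r} in {path}")
            seq = str(rec.seq).upper()
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(
                    f"record {name!r} in {path} contains non-IUPAC "
                    f"characters: {sorted(bad)}"
                )
            entries[name] = seq
    if not entries:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequences(entries)


def write_fasta(genome: GenomeSequences, path, width: int = 60) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in genome:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def compute_sizes(genome: GenomeSequences) -> pd.DataFrame:
    """Per-sequence length table, one row per entry in input order."""
    return pd.DataFrame(
        {"name": list(genome.entries), "length": [len(s) for _, s in genome]}
    )


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

_PSL_HEADER = (
    "psLayout version 3\n\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        "
    "\tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes "
    "\tqStarts\t tStarts\n"
)


@dataclass
class PSLRecord:
    """One gapped local alignment in 21-column PSL layout.

    ``qStart``/``qEnd`` are always forward-strand query coordinates; when
    ``strand`` is ``"-"`` the per-block ``qStarts`` are coordinates on the
    reverse-complemented query (standard PSL convention).
    """

    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: list[int]
    qStarts: list[int]
    tStarts: list[int]

    def validate(self, index: int | None = None) -> None:
        where = "" if index is None else f" (record {index})"
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}{where}")
        if not (0 <= self.qStart < self.qEnd <= self.qSize):
            raise FormatError(
                f"query interval {self.qStart}-{self.qEnd} invalid for "
                f"size {self.qSize}{where}"
            )
        if not (0 <= self.tStart < self.tEnd <= self.tSize):
            raise FormatError(
                f"target interval {self.tStart}-{self.tEnd} invalid for "
                f"size {self.tSize}{where}"
            )
        n = self.blockCount
        if not (len(self.blockSizes) == len(self.qStarts) == len(self.tStarts) == n):
            raise FormatError(f"block list lengths disagree with blockCount{where}")
        if sum(self.blockSizes) != self.matches + self.misMatches + self.nCount:
            raise FormatError(
                f"sum(blockSizes) != matches + misMatches + nCount{where}"
            )
        for lst in (self.qStarts, self.tStarts):
            for i in range(1, n):
                if lst[i] < lst[i - 1] + self.blockSizes[i - 1]:
                    raise FormatError(f"blocks unsorted or overlapping{where}")

    def to_line(self) -> str:
        def csv(xs: Sequence[int]) -> str:
            return "".join(f"{x}," for x in xs)

        fields = [
            self.matches, self.misMatches, self.repMatches, self.nCount,
            self.qNumInsert, self.qBaseInsert, self.tNumInsert, self.tBaseInsert,
            self.strand, self.qName, self.qSize, self.qStart, self.qEnd,
            self.tName, self.tSize, self.tStart, self.tEnd, self.blockCount,
            csv(self.blockSizes), csv(self.qStarts), csv(self.tStarts),
        ]
        return "\t".join(str(f) for f in fields)

    @classmethod
    def from_line(cls, line: str, index: int | None = None) -> "PSLRecord":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 21:
            raise FormatError(
                f"expected 21 PSL columns, got {len(parts)}"
                + ("" if index is None else f" (record {index})")
            )

        def ints(s: str) -> list[int]:
            return [int(x) for x in s.rstrip(",").split(",")] if s.strip(",") else []

        rec = cls(
            matches=int(parts[0]), misMatches=int(parts[1]),
            repMatches=int(parts[2]), nCount=int(parts[3]),
            qNumInsert=int(parts[4]), qBaseInsert=int(parts[5]),
            tNumInsert=int(parts[6]), tBaseInsert=int(parts[7]),
            strand=parts[8], qName=parts[9], qSize=int(parts[10]),
            qStart=int(parts[11]), qEnd=int(parts[12]),
            tName=parts[13], tSize=int(parts[14]),
            tStart=int(parts[15]), tEnd=int(parts[16]),
            blockCount=int(parts[17]),
            blockSizes=ints(parts[18]), qStarts=ints(parts[19]),
            tStarts=ints(parts[20]),
        )
        rec.validate(index)
        return rec


def read_psl(path) -> list[PSLRecord]:
    """Read a PSL file; a ``psLayout`` header block, if present, is skipped."""
    records: list[PSLRecord] = []
    with _open_text(path) as handle:
        lines = handle.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        # header block ends at the dashed separator line
        for i, line in enumerate(lines):
            if line.startswith("---"):
                start = i + 1
                break
        else:
            start = len(lines)
    for i, line in enumerate(lines[start:]):
        if not line.strip():
            continue
        records.append(PSLRecord.from_line(line, index=i))
    return records


def write_psl(records: Iterable[PSLRecord], path) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            rec.validate()
            out.write(rec.to_line() + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> list[tuple]:
    """Read BED3/BED4(+strand) intervals as tuples.

    Returns ``(chrom, start, end)``, plus ``name`` and ``strand`` when those
    columns are present.  Coordinates are 0-based half-open.
    """
    out: list[tuple] = []
    with _open_text(path) as handle:
        for ln, line in enumerate(handle):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {ln + 1}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end or start < 0:
                raise FormatError(f"BED line {ln + 1}: invalid interval {start}-{end}")
            out.append(tuple([chrom, start, end] + parts[3:6]))
    return out


def write_bed(intervals: Iterable[Sequence], path) -> None:
    with _open_text(path, "wt") as out:
        for iv in intervals:
            out.write("\t".join(str(x) for x in iv) + "\n")


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------


@dataclass
class ChainRecord:
    """A scored co-linear series of gapless blocks (UCSC chain layout).

    ``blocks`` is a list of ``(size, dt, dq)`` triples: block size, then gap
    on target and on query before the next block.  The last block's gaps are
    zero.  ``qStart``/``qEnd`` follow the chain convention: coordinates on the
    reverse-complemented query when ``qStrand`` is ``"-"``.
    """

    score: float
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    qName: str
    qSize: int
    qStrand: str
    qStart: int
    qEnd: int
    chain_id: int
    blocks: list[tuple[int, int, int]]
    tStrand: str = "+"

    def validate(self) -> None:
        sizes = [b[0] for b in self.blocks]
        dts = [b[1] for b in self.blocks]
        dqs = [b[2] for b in self.blocks]
        if any(s <= 0 for s in sizes) or any(d < 0 for d in dts + dqs):
            raise FormatError(f"chain {self.chain_id}: bad block size or gap")
        if dts and (dts[-1] != 0 or dqs[-1] != 0):
            raise FormatError(f"chain {self.chain_id}: last block has trailing gaps")
        if sum(sizes) + sum(dts) != self.tEnd - self.tStart:
            raise FormatError(f"chain {self.chain_id}: target span != blocks + gaps")
        if sum(sizes) + sum(dqs) != self.qEnd - self.qStart:
            raise FormatError(f"chain {self.chain_id}: query span != blocks + gaps")

    def q_forward_interval(self) -> tuple[int, int]:
        """The chain's query extent in forward-strand coordinates."""
        if self.qStrand == "+":
            return self.qStart, self.qEnd
        return self.qSize - self.qEnd, self.qSize - self.qStart


def write_chain(chains: Iterable[ChainRecord], path) -> None:
    with _open_text(path, "wt") as out:
        for ch in chains:
            ch.validate()
            out.write(
                f"chain {ch.score:g} {ch.tName} {ch.tSize} {ch.tStrand} "
                f"{ch.tStart} {ch.tEnd} {ch.qName} {ch.qSize} {ch.qStrand} "
                f"{ch.qStart} {ch.qEnd} {ch.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(ch.blocks):
                if i == len(ch.blocks) - 1:
                    out.write(f"{size}\n")
                else:
                    out.write(f"{size} {dt} {dq}\n")
            out.write("\n")


def read_chain(path) -> list[ChainRecord]:
    chains: list[ChainRecord] = []
    with _open_text(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        head = lines[i].split()
        if head[0] != "chain" or len(head) != 13:
            raise FormatError(f"bad chain header at line {i + 1}")
        blocks: list[tuple[int, int, int]] = []
        i += 1
        while i < len(lines) and lines[i].strip():
            parts = lines[i].split()
            if len(parts) == 3:
                blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
            elif len(parts) == 1:
                blocks.append((int(parts[0]), 0, 0))
            else:
                raise FormatError(f"bad chain block at line {i + 1}")
            i += 1
        ch = ChainRecord(
            score=float(head[1]), tName=head[2], tSize=int(head[3]),
            tStart=int(head[5]), tEnd=int(head[6]), qName=head[7],
            qSize=int(head[8]), qStrand=head[9], qStart=int(head[10]),
            qEnd=int(head[11]), chain_id=int(head[12]), blocks=blocks,
            tStrand=head[4],
        )
        ch.validate()
        chains.append(ch)
    return chains


# ---------------------------------------------------------------------------
# net
# ---------------------------------------------------------------------------


@dataclass
class NetNode:
    """One ``fill`` or ``gap`` line of a net hierarchy.

    ``tStart``/``tEnd`` are reference-chromosome coordinates; ``qStart``/
    ``qEnd`` are forward-strand query (scaffold) coordinates.  ``level`` is 1
    for top-level fills; a fill's gap children share its level, and fills
    inside those gaps are one level deeper.
    """

    level: int
    kind: str  # "fill" | "gap"
    tStart: int
    tEnd: int
    qName: str = ""
    qStrand: str = "+"
    qStart: int = 0
    qEnd: int = 0
    chain_id: int = 0
    score: float = 0.0
    type_label: str = ""
    children: list["NetNode"] = field(default_factory=list)

    def validate(self) -> None:
        if self.kind not in ("fill", "gap"):
            raise FormatError(f"bad net node kind {self.kind!r}")
        if self.tStart >= self.tEnd:
            raise FormatError(f"empty net node interval {self.tStart}-{self.tEnd}")
        fills = sorted(
            (c for c in self.children if c.kind == "fill"),
            key=lambda c: c.tStart,
        )
        for a, b in zip(fills, fills[1:]):
            if a.tEnd > b.tStart:
                raise FormatError(
                    f"overlapping sibling fills {a.tStart}-{a.tEnd} and "
                    f"{b.tStart}-{b.tEnd}"
                )
        for c in self.children:
            if c.tStart < self.tStart or c.tEnd > self.tEnd:
                raise FormatError("child net node extends outside its parent")
            c.validate()

    def walk(self) -> Iterator["NetNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


def _write_net_node(node: NetNode, depth: int, out: io.TextIOBase) -> None:
    node.validate()
    size = node.tEnd - node.tStart
    if node.kind == "fill":
        extra = f" id {node.chain_id} score {node.score:g}"
        if node.type_label:
            extra += f" type {node.type_label}"
        out.write(
            f"{' ' * depth}fill {node.tStart} {size} {node.qName} "
            f"{node.qStrand} {node.qStart} {node.qEnd - node.qStart}{extra}\n"
        )
    else:
        out.write(
            f"{' ' * depth}gap {node.tStart} {size} {node.qName} {node.qStrand}\n"
        )
    for child in node.children:
        _write_net_node(child, depth + 1, out)


def write_net(nets: dict[str, tuple[int, list[NetNode]]], path) -> None:
    """Write nets: mapping chromosome -> (chromosome size, top-level fills)."""
    with _open_text(path, "wt") as out:
        for chrom, (size, fills) in nets.items():
            out.write(f"net {chrom} {size}\n")
            top = sorted(fills, key=lambda f: f.tStart)
            for a, b in zip(top, top[1:]):
                if a.tEnd > b.tStart:
                    raise FormatError(
                        f"overlapping top-level fills on {chrom}: "
                        f"{a.tStart}-{a.tEnd} vs {b.tStart}-{b.tEnd}"
                    )
            for fill in top:
                _write_net_node(fill, 1, out)


def read_net(path) -> dict[str, tuple[int, list[NetNode]]]:
    nets: dict[str, tuple[int, list[NetNode]]] = {}
    stack: list[tuple[int, NetNode]] = []
    chrom = None
    with _open_text(path) as handle:
        for ln, raw in enumerate(handle):
            if not raw.strip():
                continue
            depth = len(raw) - len(raw.lstrip(" "))
            parts = raw.split()
            if parts[0] == "net":
                chrom = parts[1]
                nets[chrom] = (int(parts[2]), [])
                stack = []
                continue
            if chrom is None:
                raise FormatError(f"net line {ln + 1} before any 'net' header")
            tStart, size = int(parts[1]), int(parts[2])
            if parts[0] == "fill":
                node = NetNode(
                    level=0, kind="fill", tStart=tStart, tEnd=tStart + size,
                    qName=parts[3], qStrand=parts[4],
                    qStart=int(parts[5]), qEnd=int(parts[5]) + int(parts[6]),
                )
                kv = parts[7:]
                for key, val in zip(kv[::2], kv[1::2]):
                    if key == "id":
                        node.chain_id = int(val)
                    elif key == "score":
                        node.score = float(val)
                    elif key == "type":
                        node.type_label = val
            elif parts[0] == "gap":
                node = NetNode(
                    level=0, kind="gap", tStart=tStart, tEnd=tStart + size,
                    qName=parts[3], qStrand=parts[4],
                )
            else:
                raise FormatError(f"unexpected net line {ln + 1}: {raw!r}")
            while stack and stack[-1][0] >= depth:
                stack.pop()
            if stack:
                stack[-1][1].children.append(node)
                parent = stack[-1][1]
                node.level = parent.level + 1 if node.kind == "fill" else parent.level
            else:
                nets[chrom][1].append(node)
                node.level = 1
            stack.append((depth, node))
    for size, fills in nets.values():
        for f in fills:
            f.validate()
    return nets
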