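"""Co-linear chaining of anchor blocks, hierarchical netting, and reporting.

Chaining groups gapless anchor blocks by (chromosome, scaffold, orientation)
and finds maximum-score co-linear subsets by sparse dynamic programming,
extracting chains greedily best-first.  Netting places chains on each
reference chromosome in descending score order, letting lower-scoring chains
fill gaps left by higher ones.  The scaffold report summarises, per target
scaffold, where and how confidently it anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import ChainRecord, NetNode, PSLRecord

__all__ = [
    "GapModel",
    "ChainParams",
    "chain_blocks",
    "net_chains",
    "annotate_syntenic",
    "scaffold_report",
]


@dataclass
class GapModel:
    """Piecewise-linear gap cost plus a per-base reward for aligned bases.

    The cost of a gap is a function of ``max(dt, dq)`` — the larger of the
    target-side and query-side gap — accumulated over breakpoints with
    decreasing marginal cost, plus a fixed opening cost whenever both sides
    gap at once.  Two presets are provided: ``"loose"`` (cheap long gaps, used
    for anchor chaining where anchors are sparse) and ``"medium"`` (3x the
    marginal costs).
    """

    per_base_score: float = 100.0
    open_cost: float = 400.0
    breakpoints: tuple[float, ...] = (0.0, 100.0, 1000.0, 10000.0)
    slopes: tuple[float, ...] = (30.0, 3.0, 1.0, 0.3)

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.slopes):
            raise ValueError("breakpoints and slopes must have equal length")
        # cumulative cost at each breakpoint
        cum = [0.0]
        for i in range(1, len(self.breakpoints)):
            cum.append(
                cum[-1]
                + (self.breakpoints[i] - self.breakpoints[i - 1]) * self.slopes[i - 1]
            )
        self._cum = cum

    @classmethod
    def preset(cls, name: str) -> "GapModel":
        if name == "loose":
            return cls()
        if name == "medium":
            base = cls()
            return cls(
                per_base_score=base.per_base_score,
                open_cost=base.open_cost,
                breakpoints=base.breakpoints,
                slopes=tuple(s * 3 for s in base.slopes),
            )
        raise ValueError(f"unknown gap model preset {name!r}")

    def gap_cost(self, dt: int, dq: int) -> float:
        g = max(dt, dq, 0)
        if g == 0:
            return 0.0
        i = 0
        for j in range(len(self.breakpoints) - 1, -1, -1):
            if g >= self.breakpoints[j]:
                i = j
                break
        cost = self._cum[i] + (g - self.breakpoints[i]) * self.slopes[i]
        if min(dt, dq) > 0:
            cost += self.open_cost
        return cost


@dataclass
class ChainParams:
    min_score: float = 3000.0
    gap_model: GapModel = field(default_factory=GapModel)
    max_gap: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


@dataclass
class _Block:
    t_start: int
    t_end: int
    q_start: int  # orientation-adjusted (reverse-strand coords when "-")
    q_end: int
    source: int  # index of the source PSL record


def _blocks_from_records(records: list[PSLRecord]):
    """Group gapless records into (tName, tSize, qName, qSize, strand) buckets."""
    groups: dict[tuple, list[_Block]] = {}
    meta: dict[tuple, tuple[int, int]] = {}
    for i, rec in enumerate(records):
        if rec.blockCount != 1:
            raise ValueError(
                "chain_blocks expects gapless single-block records; "
                f"record {i} has {rec.blockCount} blocks"
            )
        if rec.strand == "+":
            q_s, q_e = rec.qStart, rec.qEnd
        else:
            q_s, q_e = rec.qSize - rec.qEnd, rec.qSize - rec.qStart
        key = (rec.tName, rec.qName, rec.strand)
        groups.setdefault(key, []).append(
            _Block(rec.tStart, rec.tEnd, q_s, q_e, i)
        )
        meta[key] = (rec.tSize, rec.qSize)
    return groups, meta


def _score_chain(blocks: list[_Block], model: GapModel) -> float:
    score = sum((b.t_end - b.t_start) * model.per_base_score for b in blocks)
    for a, b in zip(blocks, blocks[1:]):
        score -= model.gap_cost(b.t_start - a.t_end, b.q_start - a.q_end)
    return score


def _best_chain(blocks: list[_Block], params: ChainParams) -> list[int] | None:
    """Max-score co-linear subset via O(n^2) DP; returns indices into blocks."""
    n = len(blocks)
    if n == 0:
        return None
    order = sorted(range(n), key=lambda i: (blocks[i].t_start, blocks[i].q_start))
    model = params.gap_model
    best_score = [0.0] * n
    prev = [-1] * n
    for ii, i in enumerate(order):
        bi = blocks[i]
        s = (bi.t_end - bi.t_start) * model.per_base_score
        best_score[ii] = s
        for jj in range(ii):
            j = order[jj]
            bj = blocks[j]
            if not (
                bj.t_start < bi.t_start
                and bj.t_end < bi.t_end
                and bj.q_start < bi.q_start
                and bj.q_end < bi.q_end
            ):
                continue
            dt = bi.t_start - bj.t_end
            dq = bi.q_start - bj.q_end
            if max(dt, dq) > params.max_gap:
                continue
            cand = best_score[jj] + s - model.gap_cost(dt, dq)
            if cand > best_score[ii]:
                best_score[ii] = cand
                prev[ii] = jj
    end = max(range(n), key=lambda ii: best_score[ii])
    chain_rev = []
    ii = end
    while ii != -1:
        chain_rev.append(order[ii])
        ii = prev[ii]
    return chain_rev[::-1]


def _trim_overlaps(blocks: list[_Block]) -> list[_Block]:
    """Trim consecutive overlapping blocks at the midpoint of the overlap.

    Blocks are gapless diagonals, so a trim shortens target and query sides
    by the same amount; the larger of the target- and query-side overlaps
    decides the trim size.
    """
    out = [
        _Block(b.t_start, b.t_end, b.q_start, b.q_end, b.source) for b in blocks
    ]
    for i in range(1, len(out)):
        a, b = out[i - 1], out[i]
        overlap = max(a.t_end - b.t_start, a.q_end - b.q_start, 0)
        if overlap == 0:
            continue
        trim_a = overlap // 2
        trim_b = overlap - trim_a
        a.t_end -= trim_a
        a.q_end -= trim_a
        b.t_start += trim_b
        b.q_start += trim_b
    return [b for b in out if b.t_end > b.t_start]


def chain_blocks(
    records: list[PSLRecord], params: ChainParams | None = None
) -> list[ChainRecord]:
    """Chain gapless reference-frame anchor records into scored chains.

    Within each (chromosome, scaffold, orientation) group, the maximum-score
    chain is extracted, its blocks removed, and the process repeats until no
    chain reaches ``min_score``.  Each block belongs to at most one chain.
    Chain ids are assigned in descending score order.  Each returned chain
    carries the source-record indices of its blocks in ``.block_sources``.
    """
    params = params or ChainParams()
    groups, meta = _blocks_from_records(records)
    raw: list[tuple[float, tuple, list[_Block]]] = []
    for key, blocks in groups.items():
        pool = list(blocks)
        while pool:
            picked = _best_chain(pool, params)
            if picked is None:
                break
            chosen = [pool[i] for i in picked]
            trimmed = _trim_overlaps(chosen)
            score = _score_chain(trimmed, params.gap_model)
            picked_set = set(picked)
            pool = [b for i, b in enumerate(pool) if i not in picked_set]
            if score < params.min_score or not trimmed:
                continue
            raw.append((score, key, trimmed))
    raw.sort(key=lambda x: (-x[0], x[1]))
    chains: list[ChainRecord] = []
    for cid, (score, key, blocks) in enumerate(raw, start=1):
        tname, qname, strand = key
        t_size, q_size = meta[key]
        triples = []
        for a, b in zip(blocks, blocks[1:]):
            triples.append(
                (a.t_end - a.t_start, b.t_start - a.t_end, b.q_start - a.q_end)
            )
        last = blocks[-1]
        triples.append((last.t_end - last.t_start, 0, 0))
        ch = ChainRecord(
            score=score, tName=tname, tSize=t_size,
            tStart=blocks[0].t_start, tEnd=last.t_end,
            qName=qname, qSize=q_size, qStrand=strand,
            qStart=blocks[0].q_start, qEnd=last.q_end,
            chain_id=cid, blocks=triples,
        )
        ch.validate()
        ch.block_sources = [b.source for b in blocks]  # type: ignore[attr-defined]
        chains.append(ch)
    return chains


# ---------------------------------------------------------------------------
# netting
# ---------------------------------------------------------------------------


def _chain_abs_blocks(ch: ChainRecord) -> list[tuple[int, int, int]]:
    """(t_start, t_end, q_start) of each block, q in orientation coords."""
    out = []
    t, q = ch.tStart, ch.qStart
    for size, dt, dq in ch.blocks:
        out.append((t, t + size, q))
        t += size + dt
        q += size + dq
    return out


def _project_q(ch: ChainRecord, t_lo: int, t_hi: int) -> tuple[int, int]:
    """Query sub-interval (forward coords) corresponding to [t_lo, t_hi)."""
    blocks = _chain_abs_blocks(ch)

    def q_at(t: int, left: bool) -> int:
        for ts, te, qs in blocks:
            if t < ts:
                return qs
            if t < te:
                return qs + (t - ts)
        last = blocks[-1]
        return last[2] + (last[1] - last[0])

    q_lo = q_at(t_lo, True)
    q_hi = q_at(t_hi, False)
    if q_hi <= q_lo:
        q_hi = q_lo + 1
    if ch.qStrand == "+":
        return q_lo, q_hi
    return ch.qSize - q_hi, ch.qSize - q_lo


def net_chains(
    chains: list[ChainRecord],
    ref_sizes: dict[str, int],
    min_space: int = 25,
) -> dict[str, tuple[int, list[NetNode]]]:
    """Greedy hierarchical netting of chains per reference chromosome.

    Chains are placed in descending score order.  Each chain contributes the
    pieces of its reference span that land in currently unfilled gaps of at
    least ``min_space`` bases; each piece becomes a fill node (child of the
    enclosing gap node, or top-level), with the chain's internal block gaps
    becoming gap children that lower-scoring chains may later fill.  Chains
    contributing nothing are omitted.
    """
    nets: dict[str, tuple[int, list[NetNode]]] = {
        chrom: (size, []) for chrom, size in ref_sizes.items()
    }
    # open slot: (start, end, parent gap node or None, fill level of would-be child)
    slots: dict[str, list] = {
        chrom: [[0, size, None, 1]] for chrom, size in ref_sizes.items()
    }
    for ch in sorted(chains, key=lambda c: (-c.score, c.chain_id)):
        if ch.tName not in nets:
            continue
        chrom_slots = slots[ch.tName]
        new_slots = []
        placed = []
        for slot in chrom_slots:
            s, e, parent, level = slot
            if e - s < min_space or e <= ch.tStart or s >= ch.tEnd:
                new_slots.append(slot)
                continue
            lo, hi = max(s, ch.tStart), min(e, ch.tEnd)
            if hi <= lo:
                new_slots.append(slot)
                continue
            q_lo, q_hi = _project_q(ch, lo, hi)
            fill = NetNode(
                level=level, kind="fill", tStart=lo, tEnd=hi,
                qName=ch.qName, qStrand=ch.qStrand, qStart=q_lo, qEnd=q_hi,
                chain_id=ch.chain_id, score=ch.score,
            )
            # internal gaps of the chain clipped to this piece
            t = ch.tStart
            for size, dt, dq in ch.blocks:
                gs, ge = t + size, t + size + dt
                t = ge
                if dt <= 0:
                    continue
                gs, ge = max(gs, lo), min(ge, hi)
                if ge - gs <= 0:
                    continue
                gq_lo, gq_hi = _project_q(ch, gs, ge)
                gap = NetNode(
                    level=level, kind="gap", tStart=gs, tEnd=ge,
                    qName=ch.qName, qStrand=ch.qStrand,
                    qStart=gq_lo, qEnd=gq_hi,
                )
                fill.children.append(gap)
                if ge - gs >= min_space:
                    new_slots.append([gs, ge, gap, level + 1])
            placed.append((fill, parent))
            # residual free space in this slot stays open
            if lo - s > 0:
                new_slots.append([s, lo, parent, level])
            if e - hi > 0:
                new_slots.append([hi, e, parent, level])
        if placed:
            for fill, parent in placed:
                if parent is None:
                    nets[ch.tName][1].append(fill)
                else:
                    parent.children.append(fill)
            slots[ch.tName] = new_slots
    for chrom, (size, fills) in nets.items():
        fills.sort(key=lambda f: f.tStart)
        for f in fills:
            _sort_children(f)
            f.validate()
    return nets


def _sort_children(node: NetNode) -> None:
    node.children.sort(key=lambda c: (c.tStart, c.kind))
    for c in node.children:
        _sort_children(c)


def annotate_syntenic(
    nets: dict[str, tuple[int, list[NetNode]]]
) -> dict[str, tuple[int, list[NetNode]]]:
    """Label fills: top fills "top"; child fills "syn"/"inv"/"nonSyn" vs parent.

    A child fill on the same scaffold and orientation as its nearest ancestor
    fill is syntenic; same scaffold with flipped orientation is an inversion;
    a different scaffold is non-syntenic.
    """

    def visit(node: NetNode, parent_fill: NetNode | None) -> None:
        if node.kind == "fill":
            if parent_fill is None:
                node.type_label = "top"
            elif node.qName != parent_fill.qName:
                node.type_label = "nonSyn"
            elif node.qStrand == parent_fill.qStrand:
                node.type_label = "syn"
            else:
                node.type_label = "inv"
            parent_fill = node
        for c in node.children:
            visit(c, parent_fill)

    for size, fills in nets.values():
        for f in fills:
            visit(f, None)
    return nets


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total, end = 0, -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def scaffold_report(
    nets: dict[str, tuple[int, list[NetNode]]],
    anchors,
    scaffold_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One row per (scaffold, chromosome) pair appearing in any fill.

    Columns: scaffold, chromosome, ref_start, ref_end, strand (majority by
    covered bases), n_anchors supporting the placement, scaffold_length,
    covered_fraction of the scaffold inside fills, and split_flag marking
    scaffolds assigned to more than one chromosome.
    """
    if scaffold_sizes is None:
        scaffold_sizes = {}
        for a in anchors:
            scaffold_sizes.setdefault(a.tgt[0], a.tgt_alignment.tSize)

    fills: dict[tuple[str, str], list[NetNode]] = {}
    for chrom, (size, tops) in nets.items():
        for top in tops:
            for node in top.walk():
                if node.kind == "fill":
                    fills.setdefault((node.qName, chrom), []).append(node)

    anchors_by_scaffold: dict[str, list] = {}
    for a in anchors:
        anchors_by_scaffold.setdefault(a.tgt[0], []).append(a)

    chrom_count: dict[str, set] = {}
    for scaf, chrom in fills:
        chrom_count.setdefault(scaf, set()).add(chrom)

    rows = []
    for (scaf, chrom), nodes in sorted(fills.items()):
        ref_ivs = [(n.tStart, n.tEnd) for n in nodes]
        q_ivs = [(n.qStart, n.qEnd) for n in nodes]
        strand_bases: dict[str, int] = {}
        for n in nodes:
            strand_bases[n.qStrand] = (
                strand_bases.get(n.qStrand, 0) + n.tEnd - n.tStart
            )
        strand = max(strand_bases, key=lambda s: (strand_bases[s], s == "+"))
        n_anchors = 0
        for a in anchors_by_scaffold.get(scaf, []):
            if a.ref[0] != chrom:
                continue
            mid = (a.ref[1] + a.ref[2]) // 2
            if any(s <= mid < e for s, e in ref_ivs):
                n_anchors += 1
        length = scaffold_sizes.get(scaf, 0)
        rows.append(
            {
                "scaffold": scaf,
                "chromosome": chrom,
                "ref_start": min(s for s, _ in ref_ivs),
                "ref_end": max(e for _, e in ref_ivs),
                "strand": strand,
                "n_anchors": n_anchors,
                "scaffold_length": length,
                "covered_fraction": (
                    _merged_length(q_ivs) / length if length else math.nan
                ),
                "split_flag": len(chrom_count[scaf]) > 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "chromosome", "ref_start", "ref_end", "strand",
            "n_anchors", "scaffold_length", "covered_fraction", "split_flag",
        ],
    )
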