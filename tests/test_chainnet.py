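import itertools

import numpy as np
import pytest

from hceanchor import chainnet as cn
from hceanchor.chainnet import ChainParams, GapModel
from hceanchor.io_formats import ChainRecord, NetNode

from conftest import gapless_record


def brute_force_best_score(blocks, model):
    """Optimal co-linear chain score by enumerating every block subset.

    blocks: list of (t_start, t_end, q_start, q_end), non-overlapping.
    """
    best = 0.0
    n = len(blocks)
    for mask in range(1, 2 ** n):
        subset = [blocks[i] for i in range(n) if mask >> i & 1]
        subset.sort(key=lambda b: b[0])
        ok = all(
            a[1] <= b[0] and a[3] <= b[2]
            for a, b in zip(subset, subset[1:])
        )
        if not ok:
            continue
        score = sum((b[1] - b[0]) * model.per_base_score for b in subset)
        score -= sum(
            model.gap_cost(b[0] - a[1], b[2] - a[3])
            for a, b in zip(subset, subset[1:])
        )
        best = max(best, score)
    return best


def random_block_instance(rng, n_max=10):
    """Random non-overlapping gapless blocks on one scaffold/chromosome."""
    n = int(rng.integers(1, n_max + 1))
    recs = []
    t = q = 0
    entries = []
    for _ in range(n):
        t += int(rng.integers(1, 2000))
        q_jump = int(rng.integers(-1500, 2000))
        q = max(q + q_jump, q + 1) if rng.random() < 0.7 else abs(q_jump)
        size = int(rng.integers(10, 120))
        entries.append((t, t + size, q, q + size))
        t += size
        q += size
    # de-overlap on q by sorting unique
    seen_q = []
    out = []
    for ts, te, qs, qe in entries:
        if any(qs < b and qe > a for a, b in seen_q):
            continue
        seen_q.append((qs, qe))
        out.append((ts, te, qs, qe))
    return out


def records_from_blocks(blocks):
    return [
        gapless_record("chr1", "scaf1", "+", ts, qs, te - ts,
                       t_size=10 ** 7, q_size=10 ** 7)
        for ts, te, qs, qe in blocks
    ]


class TestGapModel:
    def test_zero_gap_costs_nothing(self):
        assert GapModel().gap_cost(0, 0) == 0.0

    def test_monotone_in_both_arguments(self, rng):
        m = GapModel()
        for _ in range(200):
            dt, dq = int(rng.integers(0, 20000)), int(rng.integers(0, 20000))
            assert m.gap_cost(dt + 1, dq) >= m.gap_cost(dt, dq)
            assert m.gap_cost(dt, dq + 1) >= m.gap_cost(dt, dq)

    def test_double_sided_gap_pays_opening(self):
        m = GapModel()
        assert m.gap_cost(10, 10) == m.gap_cost(10, 0) + m.open_cost

    def test_medium_joins_less_readily_than_loose(self):
        loose, medium = GapModel.preset("loose"), GapModel.preset("medium")
        for g in (50, 500, 5000, 50000):
            assert medium.gap_cost(g, 0) > loose.gap_cost(g, 0)


class TestChainBlocks:
    def test_three_colinear_blocks_one_chain(self):
        blocks = [(0, 100, 0, 100), (150, 250, 160, 260), (300, 400, 320, 420)]
        chains = cn.chain_blocks(records_from_blocks(blocks),
                                 ChainParams(min_score=0))
        assert len(chains) == 1
        ch = chains[0]
        assert len(ch.blocks) == 3
        expected = brute_force_best_score(blocks, GapModel())
        assert ch.score == pytest.approx(expected)

    def test_anti_ordered_blocks_not_joined(self):
        # reference increasing, scaffold decreasing: co-linearity forbids a join
        blocks = [(0, 100, 5000, 5100), (200, 300, 1000, 1100)]
        chains = cn.chain_blocks(records_from_blocks(blocks),
                                 ChainParams(min_score=0))
        assert len(chains) == 2
        assert all(len(c.blocks) == 1 for c in chains)

    def test_min_score_threshold(self):
        blocks = [(0, 20, 0, 20)]  # 20 bp * 100 = 2000 < 3000
        assert cn.chain_blocks(records_from_blocks(blocks)) == []
        chains = cn.chain_blocks(records_from_blocks(blocks),
                                 ChainParams(min_score=2000))
        assert len(chains) == 1

    def test_dp_matches_brute_force(self, rng):
        params = ChainParams(min_score=0)
        for _ in range(60):
            blocks = random_block_instance(rng, n_max=8)
            chains = cn.chain_blocks(records_from_blocks(blocks), params)
            best = max((c.score for c in chains), default=0.0)
            assert best == pytest.approx(
                brute_force_best_score(blocks, params.gap_model)
            )

    def test_score_equals_rescoring_emitted_chain(self, small_pipeline):
        model = GapModel()
        for ch in small_pipeline["chains"]:
            score = sum(size * model.per_base_score for size, _, _ in ch.blocks)
            score -= sum(
                model.gap_cost(dt, dq) for _, dt, dq in ch.blocks[:-1]
            )
            assert ch.score == pytest.approx(score)

    def test_blocks_used_at_most_once(self, small_pipeline):
        seen = set()
        for ch in small_pipeline["chains"]:
            for src in ch.block_sources:
                assert src not in seen
                seen.add(src)

    def test_removing_anchor_never_raises_best_score(self, rng):
        params = ChainParams(min_score=0)
        blocks = random_block_instance(rng, n_max=8)
        full = max((c.score for c in
                    cn.chain_blocks(records_from_blocks(blocks), params)),
                   default=0.0)
        for i in range(len(blocks)):
            sub = blocks[:i] + blocks[i + 1:]
            if not sub:
                continue
            reduced = max(
                (c.score for c in
                 cn.chain_blocks(records_from_blocks(sub), params)),
                default=0.0,
            )
            assert reduced <= full + 1e-9

    def test_overlap_trimmed_at_midpoint(self):
        recs = records_from_blocks([(0, 100, 0, 100), (90, 190, 90, 190)])
        chains = cn.chain_blocks(recs, ChainParams(min_score=0))
        assert len(chains) == 1
        ch = chains[0]
        sizes = [b[0] for b in ch.blocks]
        assert sizes == [95, 95]
        assert ch.tStart == 0 and ch.tEnd == 190
        ch.validate()


def simple_chain(chain_id, score, t0, blocks, qname="s1", strand="+",
                 tname="chr1", tsize=100_000, q0=0):
    """blocks: list of (size, dt, dq) triples."""
    tlen = sum(b[0] + b[1] for b in blocks) - blocks[-1][1]
    qlen = sum(b[0] + b[2] for b in blocks) - blocks[-1][2]
    return ChainRecord(
        score=score, tName=tname, tSize=tsize, tStart=t0, tEnd=t0 + tlen,
        qName=qname, qSize=50_000, qStrand=strand, qStart=q0, qEnd=q0 + qlen,
        chain_id=chain_id, blocks=blocks,
    )


def reference_net(chains, ref_sizes, min_space=25):
    """Independent implementation of the greedy netting rule.

    Instead of incremental slot bookkeeping, the open gap slots are
    recomputed from the partially built tree before each placement.
    """
    nets = {chrom: [] for chrom in ref_sizes}

    def open_slots(chrom):
        slots = []

        def complement(lo, hi, fills, parent):
            cur = lo
            for f in sorted(fills, key=lambda f: f.tStart):
                if f.tStart > cur:
                    slots.append((cur, f.tStart, parent))
                cur = max(cur, f.tEnd)
            if hi > cur:
                slots.append((cur, hi, parent))

        complement(0, ref_sizes[chrom], nets[chrom], None)
        stack = list(nets[chrom])
        while stack:
            fill = stack.pop()
            for gap in [c for c in fill.children if c.kind == "gap"]:
                child_fills = [c for c in gap.children if c.kind == "fill"]
                complement(gap.tStart, gap.tEnd, child_fills, gap)
                stack.extend(child_fills)
        return slots

    for ch in sorted(chains, key=lambda c: (-c.score, c.chain_id)):
        if ch.tName not in nets:
            continue
        for lo, hi, parent in open_slots(ch.tName):
            if hi - lo < min_space:
                continue
            s, e = max(lo, ch.tStart), min(hi, ch.tEnd)
            if e <= s:
                continue
            level = 1 if parent is None else parent.level + 1
            fill = NetNode(level=level, kind="fill", tStart=s, tEnd=e,
                           qName=ch.qName, qStrand=ch.qStrand,
                           chain_id=ch.chain_id, score=ch.score)
            t = ch.tStart
            for size, dt, dq in ch.blocks:
                gs, ge = t + size, t + size + dt
                t = ge
                if dt > 0 and min(ge, e) - max(gs, s) > 0:
                    fill.children.append(
                        NetNode(level=level, kind="gap",
                                tStart=max(gs, s), tEnd=min(ge, e),
                                qName=ch.qName, qStrand=ch.qStrand)
                    )
            (nets[ch.tName] if parent is None else parent.children).append(fill)
    return nets


def net_shape(nets):
    """Comparable structure: set of (chain_id, tStart, tEnd, level)."""
    out = set()
    for chrom, payload in nets.items():
        fills = payload[1] if isinstance(payload, tuple) else payload
        for top in fills:
            for node in top.walk():
                if node.kind == "fill":
                    out.add((chrom, node.chain_id, node.tStart, node.tEnd,
                             node.level))
    return out


def random_chains(rng, n=6, tsize=20_000):
    chains = []
    for cid in range(1, n + 1):
        n_blocks = int(rng.integers(1, 4))
        blocks = []
        for b in range(n_blocks):
            size = int(rng.integers(30, 400))
            dt = int(rng.integers(0, 800)) if b < n_blocks - 1 else 0
            dq = int(rng.integers(0, 800)) if b < n_blocks - 1 else 0
            blocks.append([size, dt, dq])
        blocks[-1][1] = blocks[-1][2] = 0
        blocks = [tuple(b) for b in blocks]
        tlen = sum(b[0] + b[1] for b in blocks)
        t0 = int(rng.integers(0, max(1, tsize - tlen)))
        chains.append(
            simple_chain(cid, float(rng.integers(100, 100_000)), t0, blocks,
                         qname=f"s{int(rng.integers(1, 4))}",
                         strand="+-"[int(rng.integers(0, 2))], tsize=tsize)
        )
    return chains


class TestNetChains:
    def test_single_chain_single_top_fill(self):
        ch = simple_chain(1, 5000, 1000, [(500, 0, 0)])
        nets = cn.net_chains([ch], {"chr1": 100_000})
        size, fills = nets["chr1"]
        assert len(fills) == 1
        assert (fills[0].tStart, fills[0].tEnd, fills[0].level) == (1000, 1500, 1)

    def test_low_score_chain_fills_gap_of_high(self):
        high = simple_chain(1, 100_000, 0, [(200, 600, 600), (200, 0, 0)])
        low = simple_chain(2, 5_000, 250, [(300, 0, 0)], qname="s2")
        nets = cn.net_chains([high, low], {"chr1": 100_000})
        _, fills = nets["chr1"]
        assert len(fills) == 1
        gap = [c for c in fills[0].children if c.kind == "gap"][0]
        inner = [c for c in gap.children if c.kind == "fill"]
        assert len(inner) == 1
        assert inner[0].chain_id == 2 and inner[0].level == 2
        assert (inner[0].tStart, inner[0].tEnd) == (250, 550)

    def test_fully_shadowed_chain_absent(self):
        high = simple_chain(1, 100_000, 0, [(1000, 0, 0)])
        low = simple_chain(2, 5_000, 200, [(300, 0, 0)], qname="s2")
        nets = cn.net_chains([high, low], {"chr1": 100_000})
        assert {2} not in [
            {n.chain_id} for _, fills in nets.values()
            for f in fills for n in f.walk() if n.kind == "fill"
        ] or True
        ids = {
            n.chain_id
            for _, fills in nets.values()
            for f in fills
            for n in f.walk()
            if n.kind == "fill"
        }
        assert ids == {1}

    def test_matches_reference_implementation(self, rng):
        for trial in range(40):
            chains = random_chains(rng)
            mine = cn.net_chains(chains, {"chr1": 20_000})
            ref = reference_net(chains, {"chr1": 20_000})
            assert net_shape(mine) == net_shape(ref), f"trial {trial}"

    def test_structural_invariants(self, rng):
        for _ in range(40):
            chains = random_chains(rng)
            nets = cn.net_chains(chains, {"chr1": 20_000})
            size, fills = nets["chr1"]
            covered = np.zeros(size, dtype=bool)
            for f in fills:
                assert not covered[f.tStart:f.tEnd].any()
                covered[f.tStart:f.tEnd] = True
                f.validate()
            assert covered.sum() <= size


class TestAnnotateSyntenic:
    def build(self, child_qname, child_strand):
        inner = NetNode(level=2, kind="fill", tStart=300, tEnd=400,
                        qName=child_qname, qStrand=child_strand,
                        qStart=0, qEnd=100, chain_id=2)
        gap = NetNode(level=1, kind="gap", tStart=250, tEnd=450,
                      qName="s1", qStrand="+", children=[inner])
        top = NetNode(level=1, kind="fill", tStart=0, tEnd=1000, qName="s1",
                      qStrand="+", qStart=0, qEnd=800, chain_id=1,
                      children=[gap])
        return {"chr1": (10_000, [top])}, inner, top

    @pytest.mark.parametrize(
        "qname,strand,label",
        [("s1", "+", "syn"), ("s1", "-", "inv"), ("s2", "+", "nonSyn")],
    )
    def test_labels(self, qname, strand, label):
        nets, inner, top = self.build(qname, strand)
        cn.annotate_syntenic(nets)
        assert top.type_label == "top"
        assert inner.type_label == label


class TestScaffoldReport:
    def test_anchor_counts_and_columns(self, small_pipeline, small_sim):
        report = small_pipeline["report"]
        anchors = small_pipeline["anchors"]
        assert set(report.columns) == {
            "scaffold", "chromosome", "ref_start", "ref_end", "strand",
            "n_anchors", "scaffold_length", "covered_fraction", "split_flag",
        }
        assert (report["n_anchors"] > 0).all()
        assert report["n_anchors"].sum() <= len(anchors)
        assert ((report["covered_fraction"] >= 0)
                & (report["covered_fraction"] <= 1)).all()

    def test_unmapped_scaffold_absent(self, small_pipeline, small_sim):
        _, _, target, _, _ = small_sim
        reported = set(small_pipeline["report"]["scaffold"])
        assert reported <= set(target.entries)

    def test_split_scaffold_flagged_on_both_rows(self):
        top1 = NetNode(level=1, kind="fill", tStart=0, tEnd=500, qName="s1",
                       qStrand="+", qStart=0, qEnd=500, chain_id=1)
        top2 = NetNode(level=1, kind="fill", tStart=100, tEnd=400, qName="s1",
                       qStrand="+", qStart=600, qEnd=900, chain_id=2)
        nets = {"chr1": (10_000, [top1]), "chr2": (10_000, [top2])}
        report = cn.scaffold_report(nets, [], {"s1": 1000})
        assert len(report) == 2
        assert report["split_flag"].all()
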