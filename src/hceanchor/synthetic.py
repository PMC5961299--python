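"""Synthetic reference/target/HCE triples with known ground truth.

The generator emulates the statistical structure that conserved-element
anchoring exploits: short elements embedded in background sequence, where
the background diverges substantially between the two genomes (~8%
substitutions by default) while the elements stay nearly identical (~1%).
The target genome is the reference after substitutions, small indels,
inversions and translocations, fragmented into scaffolds.  Every edit is
tracked through a segment map, so the true chromosome, span and orientation
of each scaffold — and the target location of every planted element — are
known exactly.

Conservation is modeled purely as a differential substitution rate (indels
are suppressed inside elements); there is no repeat landscape or gene
structure.  That is sufficient to exercise every pipeline filter but is not
a substitute for real genome complexity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .databank import HCERecord
from .io_formats import GenomeSequences

__all__ = [
    "SimParams",
    "GroundTruth",
    "generate_reference",
    "evolve_target",
    "simulate",
    "score_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Simulation conditions.

    Lengths are in bases, rates are per-base probabilities.  Defaults give a
    two-chromosome, 10 Mb genome pair with 2,000 planted elements at 8%
    background / 1% element divergence, a handful of large rearrangements,
    and scaffolds around a 150 kb N50 — a desk-scale analog of a closely
    related mammalian genome pair.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_hce: int = 2000
    hce_len_min: int = 40
    hce_len_median: int = 200
    hce_len_max: int = 2000
    hce_len_sigma: float = 0.6
    hce_spacing_min: int = 100
    dup_fraction: float = 0.02
    repeat_fraction: float = 0.01
    background_divergence: float = 0.08
    hce_divergence: float = 0.01
    indel_rate: float = 5e-4
    indel_max_len: int = 20
    n_inversions: int = 5
    n_translocations: int = 2
    rearrangement_min_len: int = 50_000
    rearrangement_max_len: int = 500_000
    scaffold_n50_target: int = 150_000

    def __post_init__(self) -> None:
        if not (0 <= self.hce_divergence < 1 and 0 <= self.background_divergence < 1):
            raise ValueError("divergence rates must be in [0, 1)")
        if self.hce_divergence >= self.background_divergence:
            raise ValueError("hce_divergence must be below background_divergence")


@dataclass
class _Seg:
    """One piece of a target chromosome: a reference slice or an insertion."""

    chrom: str | None  # None for inserted sequence
    ref_s: int
    ref_e: int
    strand: str
    ins: str | None = None

    @property
    def length(self) -> int:
        return len(self.ins) if self.ins is not None else self.ref_e - self.ref_s


@dataclass
class GroundTruth:
    """Everything the generator knows about the emitted pair."""

    # hce_id -> list of reference placements (chrom, start, end); duplicated
    # elements have two entries under the same id
    hce_ref: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    # hce_id -> canonical target placement (scaffold, start, end, strand)
    hce_tgt: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    # scaffold -> list of (chrom, ref_start, ref_end, strand) segments
    scaffolds: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    rearrangements: list[dict] = field(default_factory=list)

    def primary_assignment(self, scaffold: str):
        """(chromosome, (ref_start, ref_end), strand) carrying most bases."""
        segs = [s for s in self.scaffolds.get(scaffold, []) if s[0] is not None]
        if not segs:
            return None
        by_chrom: dict[str, int] = {}
        for chrom, s, e, _ in segs:
            by_chrom[chrom] = by_chrom.get(chrom, 0) + e - s
        chrom = max(by_chrom, key=lambda c: by_chrom[c])
        csegs = [s for s in segs if s[0] == chrom]
        by_strand: dict[str, int] = {}
        for _, s, e, st in csegs:
            by_strand[st] = by_strand.get(st, 0) + e - s
        strand = max(by_strand, key=lambda s: by_strand[s])
        span = (min(s for _, s, _, _ in csegs), max(e for _, _, e, _ in csegs))
        return chrom, span, strand

    def hce_count(self, scaffold: str) -> int:
        return sum(1 for v in self.hce_tgt.values() if v[0] == scaffold)

    def to_json(self, path) -> None:
        payload = {
            "hce_ref": {k: [list(p) for p in v] for k, v in self.hce_ref.items()},
            "hce_tgt": {k: list(v) for k, v in self.hce_tgt.items()},
            "scaffolds": {
                k: [list(s) for s in v] for k, v in self.scaffolds.items()
            },
            "scaffold_lengths": self.scaffold_lengths,
            "rearrangements": self.rearrangements,
        }
        with open(path, "w") as out:
            json.dump(payload, out, indent=1, default=int)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as handle:
            d = json.load(handle)
        return cls(
            hce_ref={k: [tuple(p) for p in v] for k, v in d["hce_ref"].items()},
            hce_tgt={k: tuple(v) for k, v in d["hce_tgt"].items()},
            scaffolds={
                k: [tuple(s) for s in v] for k, v in d["scaffolds"].items()
            },
            scaffold_lengths=d["scaffold_lengths"],
            rearrangements=d["rearrangements"],
        )


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _sample_lengths(rng, params: SimParams, n: int) -> np.ndarray:
    raw = rng.lognormal(np.log(params.hce_len_median), params.hce_len_sigma, n)
    return np.clip(raw.astype(np.int64), params.hce_len_min, params.hce_len_max)


def generate_reference(
    params: SimParams,
) -> tuple[GenomeSequences, list[HCERecord], GroundTruth]:
    """Random background chromosomes with planted conserved elements.

    A configurable fraction of elements is duplicated to a second locus (so
    the uniqueness filter has something to remove) and a fraction is made of
    a shared tandem repeat (so over-representation masking has targets).
    Element placements respect ``hce_spacing_min`` and never overlap.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_hce
    n_dup = int(round(params.dup_fraction * n))
    n_rep = int(round(params.repeat_fraction * n))

    lengths = _sample_lengths(rng, params, n)
    dup_of = rng.choice(n - n_rep, size=n_dup, replace=False) if n_dup else []
    slot_lengths = list(lengths) + [int(lengths[i]) for i in dup_of]
    n_slots = len(slot_lengths)

    chrom_names = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    chrom_of_slot = rng.integers(0, params.n_chromosomes, n_slots)
    placements: list[tuple[str, int, int] | None] = [None] * n_slots
    seqs: dict[str, np.ndarray] = {}
    for ci, cname in enumerate(chrom_names):
        slot_ids = [i for i in range(n_slots) if chrom_of_slot[i] == ci]
        need = sum(slot_lengths[i] for i in slot_ids) + (
            (len(slot_ids) + 1) * params.hce_spacing_min
        )
        L = params.chromosome_length
        if need > L:
            raise ValueError(
                f"requested element mass ({need} bp incl. spacing) exceeds "
                f"chromosome capacity ({L} bp) on {cname}"
            )
        extra = L - need
        order = rng.permutation(len(slot_ids))
        gaps = rng.multinomial(extra, np.full(len(slot_ids) + 1, 1 / (len(slot_ids) + 1)))
        pos = 0
        for k, oi in enumerate(order):
            slot = slot_ids[oi]
            pos += params.hce_spacing_min + int(gaps[k])
            placements[slot] = (cname, int(pos), int(pos + slot_lengths[slot]))
            pos += int(slot_lengths[slot])
        seqs[cname] = _BASES[rng.integers(0, 4, L)]

    # a single repeat motif shared by all repetitive elements
    motif = _BASES[rng.integers(0, 4, 7)]
    rep_ids = set(range(n - n_rep, n))
    for i in rep_ids:
        cname, s, e = placements[i]
        tile = np.tile(motif, (e - s) // len(motif) + 1)[: e - s]
        seqs[cname][s:e] = tile
    # duplicated elements copy their primary's bases
    for j, src in enumerate(dup_of):
        cname, s, e = placements[n + j]
        sc, ss, se = placements[src]
        seqs[cname][s:e] = seqs[sc][ss:se]

    reference = GenomeSequences({c: _decode(seqs[c]) for c in chrom_names})
    width = len(str(n))
    hces: list[HCERecord] = []
    truth = GroundTruth()
    for i in range(n):
        hid = f"hce{str(i + 1).zfill(width)}"
        cname, s, e = placements[i]
        hces.append(HCERecord(hid, reference[cname][s:e], (cname, s, e)))
        truth.hce_ref[hid] = [(cname, s, e)]
    for j, src in enumerate(dup_of):
        hid = hces[src].hce_id
        truth.hce_ref[hid].append(placements[n + j])
    return reference, hces, truth


# ---------------------------------------------------------------------------
# target evolution
# ---------------------------------------------------------------------------


def _split_at(segs: list[_Seg], t: int) -> int:
    """Split the segment list at target coordinate ``t``; return the index."""
    pos = 0
    for i, seg in enumerate(segs):
        if pos == t:
            return i
        if pos + seg.length > t:
            off = t - pos
            if seg.ins is not None:
                left = _Seg(None, 0, 0, seg.strand, seg.ins[:off])
                right = _Seg(None, 0, 0, seg.strand, seg.ins[off:])
            elif seg.strand == "+":
                left = _Seg(seg.chrom, seg.ref_s, seg.ref_s + off, "+")
                right = _Seg(seg.chrom, seg.ref_s + off, seg.ref_e, "+")
            else:
                left = _Seg(seg.chrom, seg.ref_e - off, seg.ref_e, "-")
                right = _Seg(seg.chrom, seg.ref_s, seg.ref_e - off, "-")
            segs[i : i + 1] = [left, right]
            return i + 1
        pos += seg.length
    return len(segs)


def _rc_str(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _invert(segs: list[_Seg], a: int, b: int) -> None:
    i = _split_at(segs, a)
    j = _split_at(segs, b)
    mid = segs[i:j][::-1]
    for seg in mid:
        seg.strand = "-" if seg.strand == "+" else "+"
    segs[i:j] = mid


def evolve_target(
    reference: GenomeSequences,
    truth: GroundTruth,
    params: SimParams,
) -> tuple[GenomeSequences, GroundTruth]:
    """Mutate, rearrange and fragment the reference into a scaffold assembly.

    Substitutions are applied at ``background_divergence`` outside planted
    elements and ``hce_divergence`` inside them; indels (suppressed inside
    elements) and then inversions/translocations follow; finally the edited
    chromosomes are cut into scaffolds whose N50 lands within 20% of
    ``scaffold_n50_target``.  The returned ground truth carries every
    scaffold's true reference placement(s) and each element's target
    location.
    """
    rng = np.random.default_rng([params.seed, 1])
    chrom_names = list(reference.entries)

    hce_ivs: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for places in truth.hce_ref.values():
        for chrom, s, e in places:
            hce_ivs[chrom].append((s, e))

    # 1. substitutions on a mutable copy of the reference
    mutated: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        arr = np.frombuffer(reference[chrom].encode(), dtype=np.uint8).copy()
        rates = np.full(len(arr), params.background_divergence)
        for s, e in hce_ivs[chrom]:
            rates[s:e] = params.hce_divergence
        hit = np.nonzero(rng.random(len(arr)) < rates)[0]
        if len(hit):
            enc = np.zeros(len(hit), dtype=np.uint8)
            for v, b in enumerate(b"ACGT"):
                enc[arr[hit] == b] = v
            arr[hit] = _BASES[(enc + rng.integers(1, 4, len(hit))) % 4]
        mutated[chrom] = arr

    # 2. indels, avoiding element interiors
    segs_by_chrom: dict[str, list[_Seg]] = {}
    for chrom in chrom_names:
        L = len(reference[chrom])
        n_events = rng.poisson(L * params.indel_rate)
        events = []
        ivs = sorted(hce_ivs[chrom])
        starts = [s for s, _ in ivs]
        import bisect

        for _ in range(n_events):
            pos = int(rng.integers(0, L))
            i = bisect.bisect_right(starts, pos) - 1
            if 0 <= i < len(ivs) and ivs[i][0] <= pos < ivs[i][1]:
                continue  # conserved element: indel suppressed
            is_ins = rng.random() < 0.5
            ln = min(int(rng.geometric(0.5)), params.indel_max_len)
            events.append((pos, is_ins, ln))
        events.sort()
        segs: list[_Seg] = []
        cursor = 0
        for pos, is_ins, ln in events:
            if pos < cursor:
                continue
            if is_ins:
                if pos > cursor:
                    segs.append(_Seg(chrom, cursor, pos, "+"))
                ins_seq = _decode(_BASES[rng.integers(0, 4, ln)])
                segs.append(_Seg(None, 0, 0, "+", ins_seq))
                cursor = pos
            else:
                end = min(pos + ln, L)
                if pos > cursor:
                    segs.append(_Seg(chrom, cursor, pos, "+"))
                cursor = end
        if cursor < L:
            segs.append(_Seg(chrom, cursor, L, "+"))
        segs_by_chrom[chrom] = segs

    # 3. rearrangements in target coordinates
    def total_len(segs: list[_Seg]) -> int:
        return sum(s.length for s in segs)

    for _ in range(params.n_inversions):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        segs = segs_by_chrom[chrom]
        T = total_len(segs)
        ln = int(rng.integers(params.rearrangement_min_len,
                              min(params.rearrangement_max_len, T // 2)))
        a = int(rng.integers(0, T - ln))
        _invert(segs, a, a + ln)
        truth.rearrangements.append(
            {"type": "inversion", "chrom": chrom, "t_start": a, "t_end": a + ln}
        )

    for _ in range(params.n_translocations):
        src = chrom_names[int(rng.integers(0, len(chrom_names)))]
        segs = segs_by_chrom[src]
        T = total_len(segs)
        ln = int(rng.integers(params.rearrangement_min_len,
                              min(params.rearrangement_max_len, T // 2)))
        a = int(rng.integers(0, T - ln))
        i = _split_at(segs, a)
        j = _split_at(segs, a + ln)
        moved = segs[i:j]
        del segs[i:j]
        dst = chrom_names[int(rng.integers(0, len(chrom_names)))]
        dsegs = segs_by_chrom[dst]
        pos = int(rng.integers(0, total_len(dsegs)))
        k = _split_at(dsegs, pos)
        dsegs[k:k] = moved
        truth.rearrangements.append(
            {"type": "translocation", "src": src, "dst": dst,
             "t_start": a, "length": ln, "dst_pos": pos}
        )

    # 4. render target chromosomes
    def render(segs: list[_Seg]) -> str:
        parts = []
        for seg in segs:
            if seg.ins is not None:
                parts.append(seg.ins if seg.strand == "+" else _rc_str(seg.ins))
            else:
                piece = _decode(mutated[seg.chrom][seg.ref_s : seg.ref_e])
                parts.append(piece if seg.strand == "+" else _rc_str(piece))
        return "".join(parts)

    target_seq = {chrom: render(segs_by_chrom[chrom]) for chrom in chrom_names}

    # 5. fragmentation into scaffolds with N50 close to target
    all_lengths: list[list[int]] = []
    for attempt in range(100):
        all_lengths = []
        frags: list[int] = []
        for chrom in chrom_names:
            T = len(target_seq[chrom])
            cuts = []
            remaining = T
            while remaining > 0:
                ln = int(
                    rng.lognormal(np.log(params.scaffold_n50_target * 0.55), 0.7)
                )
                ln = max(1000, min(ln, remaining))
                if remaining - ln < 1000:
                    ln = remaining
                cuts.append(ln)
                remaining -= ln
            all_lengths.append(cuts)
            frags.extend(cuts)
        frags.sort(reverse=True)
        total = sum(frags)
        acc, n50 = 0, 0
        for ln in frags:
            acc += ln
            if acc * 2 >= total:
                n50 = ln
                break
        if abs(n50 - params.scaffold_n50_target) <= 0.2 * params.scaffold_n50_target:
            break

    n_scaf = sum(len(c) for c in all_lengths)
    width = len(str(n_scaf))
    order = rng.permutation(n_scaf)
    names = [f"scaffold_{str(i + 1).zfill(width)}" for i in range(n_scaf)]
    scaffolds: dict[str, str] = {}
    scaf_segs: dict[str, list[_Seg]] = {}
    idx = 0
    for ci, chrom in enumerate(chrom_names):
        pos = 0
        for ln in all_lengths[ci]:
            name = names[order[idx]]
            idx += 1
            scaffolds[name] = target_seq[chrom][pos : pos + ln]
            segs = [
                _Seg(s.chrom, s.ref_s, s.ref_e, s.strand, s.ins)
                for s in segs_by_chrom[chrom]
            ]
            i = _split_at(segs, pos)
            j = _split_at(segs, pos + ln)
            scaf_segs[name] = segs[i:j]
            pos += ln

    target = GenomeSequences(dict(sorted(scaffolds.items())))
    for name in target.entries:
        truth.scaffold_lengths[name] = len(target[name])
        truth.scaffolds[name] = [
            (s.chrom, s.ref_s, s.ref_e, s.strand)
            for s in scaf_segs[name]
            if s.ins is None
        ]

    # 6. project each element's primary reference placement into the target
    seg_table: list[tuple[str, int, str, int, int, str]] = []
    for name in target.entries:
        pos = 0
        for s in scaf_segs[name]:
            if s.ins is None:
                seg_table.append((name, pos, s.chrom, s.ref_s, s.ref_e, s.strand))
            pos += s.length
    by_chrom: dict[str, list] = {}
    for row in seg_table:
        by_chrom.setdefault(row[2], []).append(row)

    for hid, places in truth.hce_ref.items():
        chrom, hs, he = places[0]
        best = None
        for name, t0, _, rs, re_, strand in by_chrom.get(chrom, []):
            lo, hi = max(hs, rs), min(he, re_)
            if hi - lo <= 0:
                continue
            if strand == "+":
                ts = t0 + (lo - rs)
            else:
                ts = t0 + (re_ - hi)
            cand = (hi - lo, name, ts, ts + (hi - lo), strand)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is not None:
            truth.hce_tgt[hid] = (best[1], best[2], best[3], best[4])
    return target, truth


def simulate(params: SimParams):
    """Generate a full reference/target/HCE triple with ground truth."""
    reference, hces, truth = generate_reference(params)
    target, truth = evolve_target(reference, truth, params)
    return reference, target, hces, truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def score_recovery(report, truth: GroundTruth, min_len: int = 10000) -> dict:
    """Score a scaffold report against ground truth.

    Considers truth scaffolds of at least ``min_len`` bases containing at
    least two planted elements; reports the fraction assigned to the correct
    chromosome, the fraction also correctly oriented, and the ordering
    concordance (fraction of concordant scaffold pairs per chromosome,
    pooled) among correctly assigned scaffolds.
    """
    hce_per_scaffold: dict[str, int] = {}
    for scaf, *_ in truth.hce_tgt.values():
        hce_per_scaffold[scaf] = hce_per_scaffold.get(scaf, 0) + 1
    eligible = [
        s
        for s, L in truth.scaffold_lengths.items()
        if L >= min_len and hce_per_scaffold.get(s, 0) >= 2
    ]
    if not eligible:
        return {"n_eligible": 0, "assignment": 0.0, "orientation": 0.0,
                "ordering": 0.0}

    primary_rows: dict[str, dict] = {}
    if len(report):
        for scaf, grp in report.groupby("scaffold"):
            best = grp.sort_values(
                ["n_anchors", "covered_fraction"], ascending=False
            ).iloc[0]
            primary_rows[scaf] = best

    n_assigned = n_oriented = 0
    placed: dict[str, list[tuple[float, float]]] = {}
    for scaf in eligible:
        expected = truth.primary_assignment(scaf)
        if expected is None:
            continue
        chrom, span, strand = expected
        row = primary_rows.get(scaf)
        if row is None or row["chromosome"] != chrom:
            continue
        n_assigned += 1
        if row["strand"] == strand:
            n_oriented += 1
        placed.setdefault(chrom, []).append(
            (float(row["ref_start"]), float(span[0]))
        )

    concordant = total_pairs = 0
    for pairs in placed.values():
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                total_pairs += 1
                if (pairs[i][0] - pairs[j][0]) * (pairs[i][1] - pairs[j][1]) > 0:
                    concordant += 1
    n = len(eligible)
    return {
        "n_eligible": n,
        "assignment": n_assigned / n,
        "orientation": n_oriented / n,
        "ordering": concordant / total_pairs if total_pairs else 1.0,
    }
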