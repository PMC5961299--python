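"""Seed-and-extend local alignment of short conserved queries against a genome.

The aligner targets the regime the pipeline lives in: queries of 40 bp – 5 Kb
that are ≥ 80–90% identical to their genomic locus.  Seeding uses a sampled
k-mer index; candidate loci are grouped by diagonal band and each locus is
extended once into a gapped alignment (edit-distance optimal, via edlib) or a
gapless one in fast mode.  Results are PSL records.

Two accelerations mirror common practice for this class of aligner: an
occurrence threshold that drops over-represented k-mers from seeding, and a
fast (gapless) mode limited to queries of at most 5 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_formats import GenomeSequences, PSLRecord

__all__ = [
    "AlignerError",
    "SeedIndex",
    "AlignerParams",
    "build_index",
    "align_query",
    "align_queries",
    "identity",
    "coverage",
    "alignment_score",
    "revcomp",
    "FAST_MODE_MAX_QUERY",
]

# Longest query fast (gapless) mode accepts; longer queries must be split.
FAST_MODE_MAX_QUERY = 5000

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[b + 32] = i

_COMP = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")


class AlignerError(ValueError):
    """Invalid aligner input (query too short, fast-mode limit, empty genome)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA to int8: A=0 C=1 G=2 T=3, anything else 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window contains a non-ACGT base."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    e = enc.astype(np.int64)
    bad = enc >= 4
    for j in range(k):
        codes = codes * 4 + np.where(bad[j : j + n], 0, e[j : j + n])
        invalid |= bad[j : j + n]
    codes[invalid] = -1
    return codes


@dataclass
class SeedIndex:
    """Sampled k-mer index over a genome.

    Positions are stored in a single concatenated coordinate space;
    ``offsets`` maps back to individual sequences.  k-mers whose *total*
    genome occurrence count (at stride 1) exceeds ``occ_threshold`` are
    removed entirely, the analog of masking over-represented seeds.
    """

    k: int
    step: int
    occ_threshold: int | None
    names: list[str]
    offsets: np.ndarray  # len(names)+1 cumulative start of each sequence
    sorted_codes: np.ndarray
    sorted_pos: np.ndarray  # global positions, parallel to sorted_codes

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, code, "left")
        hi = np.searchsorted(self.sorted_codes, code, "right")
        return self.sorted_pos[lo:hi]

    def positions_of(self, kmer: str) -> list[tuple[str, int]]:
        """Sampled (sequence name, offset) positions of an exact k-mer."""
        enc = encode(kmer)
        if len(enc) != self.k or (enc >= 4).any():
            return []
        code = 0
        for b in enc:
            code = code * 4 + int(b)
        out = []
        for g in self.lookup(code):
            si = int(np.searchsorted(self.offsets, g, "right")) - 1
            out.append((self.names[si], int(g - self.offsets[si])))
        return out


def build_index(
    genome: GenomeSequences,
    k: int = 11,
    step: int = 5,
    occ_threshold: int | None = None,
) -> SeedIndex:
    """Index every N-free k-mer sampled at ``step`` across all sequences."""
    if not (4 <= k <= 16):
        raise AlignerError(f"k must be in [4, 16], got {k}")
    if step < 1:
        raise AlignerError(f"step must be >= 1, got {step}")
    if len(genome) == 0 or genome.total_length == 0:
        raise AlignerError("cannot index an empty genome")

    names = list(genome.entries)
    lengths = np.array([len(genome[n]) for n in names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    all_codes: list[np.ndarray] = []
    samp_codes: list[np.ndarray] = []
    samp_pos: list[np.ndarray] = []
    for si, name in enumerate(names):
        enc = encode(genome[name])
        codes = _kmer_codes(enc, k)
        if len(codes) == 0:
            continue
        valid = codes >= 0
        all_codes.append(codes[valid])
        pos = np.arange(0, len(codes), step, dtype=np.int64)
        keep = valid[pos]
        samp_codes.append(codes[pos[keep]])
        samp_pos.append(pos[keep] + offsets[si])

    codes = np.concatenate(samp_codes) if samp_codes else np.empty(0, np.int64)
    pos = np.concatenate(samp_pos) if samp_pos else np.empty(0, np.int64)

    if occ_threshold is not None and len(all_codes):
        genome_codes = np.concatenate(all_codes)
        uniq, counts = np.unique(genome_codes, return_counts=True)
        frequent = uniq[counts > occ_threshold]
        if len(frequent):
            drop = np.isin(codes, frequent)
            codes, pos = codes[~drop], pos[~drop]

    order = np.argsort(codes, kind="stable")
    return SeedIndex(
        k=k, step=step, occ_threshold=occ_threshold, names=names,
        offsets=offsets, sorted_codes=codes[order], sorted_pos=pos[order],
    )


@dataclass
class AlignerParams:
    """Alignment thresholds and extension scoring.

    ``min_identity`` filters reported alignments on matches/(matches +
    mismatches).  ``fast_mode`` restricts extension to gapless blocks and
    queries to 5 kb.  The match/gap scores are used to score alignments (and
    by the chaining stage downstream); extension itself is edit-distance
    optimal.
    """

    min_identity: float = 0.90
    fast_mode: bool = False
    match: int = 1
    mismatch: int = -1
    gap_open: int = -3
    gap_extend: int = -1
    band_width: int = 32

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise AlignerError(
                f"min_identity must be in (0, 1], got {self.min_identity}"
            )


def identity(rec: PSLRecord) -> float:
    """Fraction of aligned non-N columns that match: matches/(matches+misMatches)."""
    denom = rec.matches + rec.misMatches
    return rec.matches / denom if denom else 1.0


def coverage(rec: PSLRecord) -> float:
    """Fraction of the query inside aligned blocks (N columns included)."""
    return (rec.matches + rec.misMatches + rec.nCount) / rec.qSize


def alignment_score(rec: PSLRecord, params: AlignerParams) -> float:
    """Score a PSL record under the aligner's match/gap scheme.

    Gap penalty is ``gap_open + gap_extend * (len - 1)`` per gap run; N
    columns score zero.
    """
    score = rec.matches * params.match + rec.misMatches * params.mismatch

    def gap_pen(n_runs: int, n_bases: int) -> float:
        return n_runs * params.gap_open + (n_bases - n_runs) * params.gap_extend

    score += gap_pen(rec.qNumInsert, rec.qBaseInsert)
    score += gap_pen(rec.tNumInsert, rec.tBaseInsert)
    return score


# ---------------------------------------------------------------------------
# seeding and clustering
# ---------------------------------------------------------------------------


def _seed_hits(enc_query: np.ndarray, index: SeedIndex):
    """(query offsets, global target positions) of all sampled seed matches."""
    codes = _kmer_codes(enc_query, index.k)
    valid = np.nonzero(codes >= 0)[0]
    if len(valid) == 0:
        return None
    q_codes = codes[valid]
    lo = np.searchsorted(index.sorted_codes, q_codes, "left")
    hi = np.searchsorted(index.sorted_codes, q_codes, "right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return None
    qoffs = np.repeat(valid, counts)
    base = np.repeat(lo, counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    gpos = index.sorted_pos[base + within]
    return qoffs, gpos


def _cluster_loci(qoffs, gpos, index: SeedIndex, qlen: int, band: int):
    """Group seed hits into candidate loci and merge overlapping windows.

    Returns a list of (sequence index, window start, window end, diagonals)
    in local sequence coordinates.
    """
    seq_idx = np.searchsorted(index.offsets, gpos, "right") - 1
    toff = gpos - index.offsets[seq_idx]
    diag = toff - qoffs
    order = np.lexsort((toff, diag, seq_idx))
    seq_idx, toff, diag, qoffs = seq_idx[order], toff[order], diag[order], qoffs[order]

    pad = band + 8 + qlen // 8
    windows: list[list] = []  # [seq, start, end, diag_counts]
    cs = 0
    n = len(toff)
    for i in range(1, n + 1):
        if (
            i == n
            or seq_idx[i] != seq_idx[cs]
            or diag[i] - diag[i - 1] > band
            or toff[i] - toff[i - 1] > 2 * qlen + band
        ):
            lo = int((toff[cs:i] - qoffs[cs:i]).min()) - pad
            hi = int((toff[cs:i] + (qlen - qoffs[cs:i])).max()) + pad
            diags: dict[int, int] = {}
            for d in diag[cs:i]:
                diags[int(d)] = diags.get(int(d), 0) + 1
            windows.append([int(seq_idx[cs]), lo, hi, diags])
            cs = i

    # merge overlapping windows on the same sequence into one locus
    windows.sort(key=lambda w: (w[0], w[1]))
    merged: list[list] = []
    for w in windows:
        if merged and merged[-1][0] == w[0] and w[1] <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], w[2])
            for d, c in w[3].items():
                merged[-1][3][d] = merged[-1][3].get(d, 0) + c
        else:
            merged.append(w)
    return merged


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------


def _cigar_runs(cigar: str):
    runs = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            runs.append((int(num), ch))
            num = ""
    return runs


_MAX_REALIGN_CELLS = 4_000_000


def _affine_realign(seq, window, params):
    """Gotoh alignment of the full query inside a window, free target end-gaps.

    Used to consolidate gaps when the edit-distance extension reports indels:
    unit costs fragment a long gap into equal-cost pieces that an affine
    scheme would never choose.  Row-wise numpy DP; the horizontal-gap state
    is computed with a running-max scan, exact because a gap immediately
    following a gap on the same side is never affine-optimal.
    Returns (t_offset, blocks) with blocks as (q_start, t_start, length),
    or None when the problem is too large.
    """
    n, m = len(seq), len(window)
    if n == 0 or m == 0 or (n + 1) * (m + 1) > _MAX_REALIGN_CELLS:
        return None
    match, mis = float(params.match), float(params.mismatch)
    go, ge = float(params.gap_open), float(params.gap_extend)
    NEG = np.float32(-1e8)
    q_enc = encode(seq)
    w_enc = encode(window)
    H = np.empty((n + 1, m + 1), dtype=np.float32)
    E = np.empty((n + 1, m + 1), dtype=np.float32)
    F = np.empty((n + 1, m + 1), dtype=np.float32)
    H[0, :] = 0.0
    E[0, :] = NEG
    F[:, 0] = NEG
    js = np.arange(m + 1, dtype=np.float32)
    for i in range(1, n + 1):
        E[i, :] = np.maximum(H[i - 1, :] + go, E[i - 1, :] + ge)
        s = np.where(
            (q_enc[i - 1] == w_enc) & (q_enc[i - 1] < 4) & (w_enc < 4),
            match, mis,
        ).astype(np.float32)
        h0 = np.empty(m + 1, dtype=np.float32)
        h0[0] = go + (i - 1) * ge
        h0[1:] = np.maximum(H[i - 1, :-1] + s, E[i, 1:])
        p = h0 - ge * js
        run = np.maximum.accumulate(p)
        F[i, 1:] = (go - ge) + ge * js[1:] + run[:-1]
        F[i, 0] = NEG
        H[i, :] = np.maximum(h0, F[i, :])
    j = int(np.argmax(H[n, :]))
    i = n
    cols: list[tuple[int, int]] = []
    while i > 0 and j >= 0:
        if j > 0 and H[i, j] == F[i, j]:
            # horizontal gap: walk left to its origin
            jj = j - 1
            while jj > 0 and H[i, jj] + go + ge * (j - jj - 1) != F[i, j]:
                jj -= 1
            j = jj
        elif H[i, j] == E[i, j]:
            ii = i - 1
            while ii > 0 and H[ii, j] + go + ge * (i - ii - 1) != E[i, j]:
                ii -= 1
            i = ii
        else:
            if j == 0:
                i -= 1
                continue
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
    if not cols:
        return None
    cols.reverse()
    blocks: list[tuple[int, int, int]] = []
    t0 = cols[0][1]
    for qi, ti in cols:
        if blocks and blocks[-1][0] + blocks[-1][2] == qi and blocks[-1][1] + blocks[-1][2] == ti - t0:
            blocks[-1] = (blocks[-1][0], blocks[-1][1], blocks[-1][2] + 1)
        else:
            blocks.append((qi, ti - t0, 1))
    return t0, blocks


def _extend_gapped(seq, enc_seq, tseq, wstart, wend, params, min_span):
    """Edit-optimal alignment of the whole query inside a window.

    Returns (t_start, blocks, counts) in window-local coordinates or None.
    blocks are (q_start, t_start, length); counts = (match, mismatch, n).
    """
    window = tseq[wstart:wend]
    qlen = len(seq)
    max_k = int(qlen * (1 - params.min_identity)) + max(10, qlen // 12)
    res = edlib.align(seq, window, mode="HW", task="path", k=max_k)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t0 = res["locations"][0][0]
    q = t = 0
    blocks: list[tuple[int, int, int]] = []
    runs = _cigar_runs(res["cigar"])
    # drop terminal indels, tracking offsets
    while runs and runs[0][1] in "ID":
        n, op = runs.pop(0)
        if op == "I":
            q += n
        else:
            t += n
    while runs and runs[-1][1] in "ID":
        runs.pop()
    for n, op in runs:
        if op in ("=", "X", "M"):
            if blocks and blocks[-1][0] + blocks[-1][2] == q and blocks[-1][1] + blocks[-1][2] == t:
                blocks[-1] = (blocks[-1][0], blocks[-1][1], blocks[-1][2] + n)
            else:
                blocks.append((q, t, n))
            q += n
            t += n
        elif op == "I":
            q += n
        elif op == "D":
            t += n
    if len(blocks) > 1:
        # indels present: unit-cost extension may fragment gaps; realign the
        # located region under the affine scheme to consolidate them
        t_extent = blocks[-1][1] + blocks[-1][2]
        pad = 16 + sum(b[2] for b in blocks) // 10
        sub_lo = max(0, t0 - pad)
        sub_hi = min(len(window), t0 + t_extent + pad)
        realigned = _affine_realign(seq, window[sub_lo:sub_hi], params)
        if realigned is not None:
            t0_rel, new_blocks = realigned
            t0 = sub_lo + t0_rel
            blocks = new_blocks
    anchor = wstart + t0
    blocks = _local_trim(seq, tseq, anchor, blocks, params)
    if not blocks:
        return None
    if sum(b[2] for b in blocks) < min_span:
        return None
    return anchor, blocks, _count_columns(seq, tseq, anchor, blocks)


def _count_columns(seq, tseq, anchor, blocks):
    match = mismatch = ncount = 0
    for qb, tb, ln in blocks:
        for a, b in zip(seq[qb : qb + ln], tseq[anchor + tb : anchor + tb + ln]):
            if a == "N" or b == "N":
                ncount += 1
            elif a == b:
                match += 1
            else:
                mismatch += 1
    return match, mismatch, ncount


def _local_trim(seq, tseq, anchor, blocks, params):
    """Restrict an alignment to its maximum-scoring contiguous sub-path.

    The extension aligns the whole query, so ends that wandered into
    unrelated sequence (chance matches in a truncated or flanking region)
    would otherwise be retained.  A Kadane pass over per-column scores, with
    inter-block gap penalties charged between columns, recovers the local
    alignment a Smith-Waterman would report on the same path.
    """
    cols: list[tuple[int, int]] = []  # (q, t) absolute positions
    pen: list[float] = []  # penalty charged before each column
    for bi, (qb, tb, ln) in enumerate(blocks):
        gap = 0.0
        if bi > 0:
            pq, pt, pl = blocks[bi - 1]
            for g in (qb - (pq + pl), tb - (pt + pl)):
                if g > 0:
                    gap += params.gap_open + (g - 1) * params.gap_extend
        for off in range(ln):
            pen.append(gap if off == 0 else 0.0)
            cols.append((qb + off, tb + off))
    if not cols:
        return []
    scores = []
    for q, t in cols:
        a, b = seq[q], tseq[anchor + t]
        if a == "N" or b == "N":
            scores.append(0.0)
        else:
            scores.append(float(params.match if a == b else params.mismatch))
    best_sum = cur = scores[0]
    best_i = best_j = cur_i = 0
    for j in range(1, len(cols)):
        extended = cur + pen[j] + scores[j]
        if extended >= scores[j]:
            cur = extended
        else:
            cur = scores[j]
            cur_i = j
        if cur > best_sum:
            best_sum, best_i, best_j = cur, cur_i, j
    if best_sum <= 0:
        return []
    kept = cols[best_i : best_j + 1]
    out: list[tuple[int, int, int]] = []
    for q, t in kept:
        if out and out[-1][0] + out[-1][2] == q and out[-1][1] + out[-1][2] == t:
            out[-1] = (out[-1][0], out[-1][1], out[-1][2] + 1)
        else:
            out.append((q, t, 1))
    return out


def _extend_gapless(seq, tseq, diags, min_span, params):
    """Best single-diagonal (gapless) full-query alignment over seeded diagonals."""
    qlen = len(seq)
    best = None
    for d in sorted(diags, key=lambda x: (-diags[x], x)):
        qs = max(0, -d)
        qe = min(qlen, len(tseq) - d)
        if qe - qs < min_span:
            continue
        anchor = d + qs
        blocks = _local_trim(seq, tseq, anchor, [(qs, 0, qe - qs)], params)
        if not blocks or sum(b[2] for b in blocks) < min_span:
            continue
        counts = _count_columns(seq, tseq, anchor, blocks)
        cand = (counts[0], -anchor, (anchor, blocks, counts))
        if best is None or cand[:2] > best[:2]:
            best = cand
    return best[2] if best is not None else None


def _ext_score(ext, params: AlignerParams) -> float:
    """Score an extension result under the aligner's match/gap scheme."""
    _, blocks, (match, mismatch, _) = ext
    score = match * params.match + mismatch * params.mismatch
    for a, b in zip(blocks, blocks[1:]):
        for gap in (b[0] - (a[0] + a[2]), b[1] - (a[1] + a[2])):
            if gap > 0:
                score += params.gap_open + (gap - 1) * params.gap_extend
    return score


def _make_psl(
    qname, qlen, tname, tlen, strand, t_anchor, blocks, counts
) -> PSLRecord:
    """Assemble a PSL record from window-anchored blocks.

    ``blocks`` are (q_start, t_start, length) with q on the aligned strand
    (reverse-complement coordinates when strand is "-") and t relative to
    ``t_anchor``.
    """
    match, mismatch, ncount = counts
    q_starts = [b[0] for b in blocks]
    t_starts = [t_anchor + b[1] for b in blocks]
    sizes = [b[2] for b in blocks]
    q_lo, q_hi = q_starts[0], q_starts[-1] + sizes[-1]
    q_num = q_base = t_num = t_base = 0
    for i in range(1, len(blocks)):
        dq = q_starts[i] - (q_starts[i - 1] + sizes[i - 1])
        dt = t_starts[i] - (t_starts[i - 1] + sizes[i - 1])
        if dq > 0:
            q_num += 1
            q_base += dq
        if dt > 0:
            t_num += 1
            t_base += dt
    if strand == "+":
        q_start, q_end = q_lo, q_hi
    else:
        q_start, q_end = qlen - q_hi, qlen - q_lo
    return PSLRecord(
        matches=match, misMatches=mismatch, repMatches=0, nCount=ncount,
        qNumInsert=q_num, qBaseInsert=q_base, tNumInsert=t_num,
        tBaseInsert=t_base, strand=strand, qName=qname, qSize=qlen,
        qStart=q_start, qEnd=q_end, tName=tname, tSize=tlen,
        tStart=t_starts[0], tEnd=t_starts[-1] + sizes[-1],
        blockCount=len(blocks), blockSizes=sizes, qStarts=q_starts,
        tStarts=t_starts,
    )


def align_query(
    query: str,
    index: SeedIndex,
    genome: GenomeSequences,
    params: AlignerParams | None = None,
    qname: str = "query",
) -> list[PSLRecord]:
    """Align one query against an indexed genome; both strands are searched.

    Every candidate locus (a diagonal-band cluster of exact seed matches)
    yields at most one PSL record; records below ``min_identity`` or spanning
    fewer than ``2k`` aligned bases are discarded.  Output is sorted by
    (tName, tStart, strand).
    """
    params = params or AlignerParams()
    query = query.upper()
    qlen = len(query)
    k = index.k
    if qlen < 2 * k:
        raise AlignerError(
            f"query {qname!r} is {qlen} bp; the aligner requires >= 2k = {2 * k} bp"
        )
    if params.fast_mode and qlen > FAST_MODE_MAX_QUERY:
        raise AlignerError(
            f"query {qname!r} is {qlen} bp; fast mode handles at most "
            f"{FAST_MODE_MAX_QUERY} bp — split the query first"
        )
    min_span = 2 * k
    out: list[PSLRecord] = []
    seen: set[tuple] = set()
    for strand in ("+", "-"):
        seq = query if strand == "+" else revcomp(query)
        enc_seq = encode(seq)
        hits = _seed_hits(enc_seq, index)
        if hits is None:
            continue
        loci = _cluster_loci(hits[0], hits[1], index, qlen, params.band_width)
        for si, lo, hi, diags in loci:
            tname = index.names[si]
            tseq = genome[tname]
            wstart = max(0, lo)
            wend = min(len(tseq), hi)
            if wend - wstart < min_span:
                continue
            ext_l = _extend_gapless(seq, tseq, diags, min_span, params)
            if params.fast_mode:
                ext = ext_l
            else:
                ext_g = _extend_gapped(
                    seq, enc_seq, tseq, wstart, wend, params, min_span
                )
                # prefer the higher-scoring interpretation; gapless wins ties
                # so substitution-only loci never acquire spurious indels
                if ext_g is None:
                    ext = ext_l
                elif ext_l is None:
                    ext = ext_g
                else:
                    ext = (
                        ext_l
                        if _ext_score(ext_l, params) >= _ext_score(ext_g, params)
                        else ext_g
                    )
            if ext is None:
                continue
            t_anchor, blocks, counts = ext
            match, mismatch, _ = counts
            denom = match + mismatch
            if denom and match / denom < params.min_identity:
                continue
            rec = _make_psl(
                qname, qlen, tname, len(tseq), strand, t_anchor, blocks, counts
            )
            key = (rec.tName, rec.tStart, rec.tEnd, rec.strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(rec)
    out.sort(key=lambda r: (r.tName, r.tStart, r.strand))
    return out


def align_queries(
    queries: dict[str, str],
    index: SeedIndex,
    genome: GenomeSequences,
    params: AlignerParams | None = None,
    cores: int = 1,
) -> list[PSLRecord]:
    """Align many queries; output canonically ordered by (qName, tName, tStart).

    With ``cores > 1`` queries are partitioned across forked workers; the
    canonical ordering makes the result independent of the worker count.
    """
    params = params or AlignerParams()
    items = list(queries.items())
    if cores > 1 and len(items) > 1:
        import multiprocessing as mp

        ctx = mp.get_context("fork")
        chunks = [items[i::cores] for i in range(cores)]
        with ctx.Pool(cores) as pool:
            parts = pool.starmap(
                _align_chunk, [(c, index, genome, params) for c in chunks]
            )
        records = [r for part in parts for r in part]
    else:
        records = _align_chunk(items, index, genome, params)
    records.sort(key=lambda r: (r.qName, r.tName, r.tStart, r.strand))
    return records


def _align_chunk(items, index, genome, params):
    out = []
    for name, seq in items:
        out.extend(align_query(seq, index, genome, params, qname=name))
    return out
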