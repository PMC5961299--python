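import numpy as np
import pytest

from hceanchor import aligner as al
from hceanchor.io_formats import GenomeSequences

from conftest import random_dna


def sw_local_score(q, t, match=1, mismatch=-1, gap_open=-3, gap_extend=-1):
    """Plain O(nm) Smith-Waterman with affine gaps; independent scoring oracle."""
    n, m = len(q), len(t)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (consumes q)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes t)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def make_genome(rng, length=6000, name="chr1"):
    return GenomeSequences({name: random_dna(rng, length)})


def mutate(rng, seq, n_subs):
    out = list(seq)
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


class TestIndex:
    def test_kmer_positions_enumerated(self):
        g = GenomeSequences({"s": "ACGTACGT"})
        idx = al.build_index(g, k=4, step=1)
        assert idx.positions_of("ACGT") == [("s", 0), ("s", 4)]
        assert idx.positions_of("CGTA") == [("s", 1)]

    def test_occ_threshold_masks_frequent_kmers(self):
        g = GenomeSequences({"s": "ACGTACGT"})
        idx = al.build_index(g, k=4, step=1, occ_threshold=1)
        assert idx.positions_of("ACGT") == []  # occurs twice -> removed
        assert idx.positions_of("CGTA") == [("s", 1)]

    def test_n_kmers_never_indexed(self):
        g = GenomeSequences({"s": "ACGTNACGT"})
        idx = al.build_index(g, k=4, step=1)
        for name, off in idx.positions_of("ACGT"):
            assert "N" not in g["s"][off : off + 4]
        assert idx.positions_of("GTNA") == []

    def test_empty_genome_rejected(self):
        with pytest.raises(al.AlignerError):
            al.build_index(GenomeSequences({}))

    def test_step_sampling(self):
        g = GenomeSequences({"s": "ACGTACGTACGT"})
        idx = al.build_index(g, k=4, step=4)
        # only offsets 0,4,8 sampled
        assert idx.positions_of("ACGT") == [("s", 0), ("s", 4), ("s", 8)]
        assert idx.positions_of("CGTA") == []


class TestAlignQuery:
    def test_exact_substring_single_hit(self, rng):
        g = make_genome(rng)
        q = g["chr1"][1000:1200]
        recs = al.align_query(q, al.build_index(g), g)
        assert len(recs) == 1
        r = recs[0]
        assert (r.strand, r.matches, r.misMatches, r.blockCount) == ("+", 200, 0, 1)
        assert (r.tStart, r.tEnd) == (1000, 1200)
        assert al.identity(r) == 1.0 and al.coverage(r) == 1.0

    def test_two_occurrences_two_records(self, rng):
        core = random_dna(rng, 150)
        g = GenomeSequences(
            {"s": random_dna(rng, 1000) + core + random_dna(rng, 1000) + core
             + random_dna(rng, 500)}
        )
        recs = al.align_query(core, al.build_index(g), g)
        assert [(r.tStart, r.tEnd) for r in recs] == [(1000, 1150), (2150, 2300)]

    def test_reverse_complement_flips_strand_same_interval(self, rng):
        g = make_genome(rng)
        q = g["chr1"][2000:2300]
        fwd = al.align_query(q, al.build_index(g), g)
        rev = al.align_query(al.revcomp(q), al.build_index(g), g)
        assert [(r.tStart, r.tEnd) for r in fwd] == [(r.tStart, r.tEnd) for r in rev]
        assert {r.strand for r in fwd} == {"+"} and {r.strand for r in rev} == {"-"}

    def test_planted_substitutions_counted(self, rng):
        g = make_genome(rng)
        q = mutate(rng, g["chr1"][1000:1200], 10)
        recs = al.align_query(q, al.build_index(g), g,
                              al.AlignerParams(min_identity=0.90))
        assert len(recs) == 1
        r = recs[0]
        assert (r.matches, r.misMatches) == (190, 10)
        assert al.identity(r) == pytest.approx(0.95)

    def test_min_identity_filters(self, rng):
        g = make_genome(rng)
        q = mutate(rng, g["chr1"][1000:1200], 30)  # 85% identity
        idx = al.build_index(g)
        assert al.align_query(q, idx, g, al.AlignerParams(min_identity=0.90)) == []
        hits = al.align_query(q, idx, g, al.AlignerParams(min_identity=0.80))
        assert len(hits) == 1

    def test_short_query_rejected(self, rng):
        g = make_genome(rng)
        idx = al.build_index(g)
        with pytest.raises(al.AlignerError, match="2k"):
            al.align_query("ACGTACGTACGTACGTACGT", idx, g)

    def test_fast_mode_query_length_limit(self, rng):
        g = make_genome(rng, 20000)
        idx = al.build_index(g)
        q = g["chr1"][0:5001]
        with pytest.raises(al.AlignerError, match="split"):
            al.align_query(q, idx, g, al.AlignerParams(fast_mode=True))

    def test_indel_produces_multiple_blocks(self, rng):
        g = make_genome(rng)
        region = g["chr1"][1000:1200]
        q = region[:100] + region[107:]  # 7 bp deletion in the query
        recs = al.align_query(q, al.build_index(g), g)
        assert len(recs) == 1
        r = recs[0]
        assert r.blockCount == 2
        assert r.tNumInsert == 1 and r.tBaseInsert == 7
        assert r.matches == 193


class TestOracleAgreement:
    def test_scores_close_to_smith_waterman(self, rng):
        """Reported alignment scores track a full local SW on the same window."""
        params = al.AlignerParams(min_identity=0.85)
        genome = make_genome(rng, 8000)
        idx = al.build_index(genome)
        missed = []
        for trial in range(12):
            start = int(rng.integers(0, 7800 - 150))
            n_subs = int(rng.integers(0, 16))  # up to ~11% divergence
            q = mutate(rng, genome["chr1"][start : start + 140], n_subs)
            recs = al.align_query(q, idx, genome, params)
            planted = [r for r in recs if r.tStart < start + 140 and r.tEnd > start]
            if n_subs <= 14:
                assert planted, f"planted locus missed (trial {trial})"
            for r in planted:
                window = genome["chr1"][max(0, r.tStart - 50) : r.tEnd + 50]
                oracle = sw_local_score(q, window)
                got = al.alignment_score(r, params)
                assert abs(got - oracle) <= abs(params.gap_open)

    def test_strand_symmetry_property(self, rng):
        genome = make_genome(rng, 5000)
        idx = al.build_index(genome)
        for _ in range(8):
            start = int(rng.integers(0, 4800 - 120))
            q = mutate(rng, genome["chr1"][start : start + 120], 6)
            fwd = al.align_query(q, idx, genome)
            rev = al.align_query(al.revcomp(q), idx, genome)
            assert [(r.tName, r.tStart, r.tEnd) for r in fwd] == [
                (r.tName, r.tStart, r.tEnd) for r in rev
            ]
            assert [r.strand for r in rev] == [
                "-" if r.strand == "+" else "+" for r in fwd
            ]


class TestFastMode:
    def test_fast_mode_subset_of_normal(self, rng):
        """On substitution-only loci, fast (gapless) output is contained in
        default output."""
        genome = make_genome(rng, 6000)
        idx = al.build_index(genome)
        normal_p = al.AlignerParams(min_identity=0.85)
        fast_p = al.AlignerParams(min_identity=0.85, fast_mode=True)
        for _ in range(10):
            start = int(rng.integers(0, 5800 - 160))
            q = mutate(rng, genome["chr1"][start : start + 150],
                       int(rng.integers(0, 12)))
            normal = al.align_query(q, idx, genome, normal_p)
            fast = al.align_query(q, idx, genome, fast_p)
            assert all(r.blockCount == 1 for r in fast)
            normal_keys = {
                (r.tName, r.tStart, r.tEnd, r.strand)
                for r in normal
                if r.blockCount == 1
            }
            for r in fast:
                assert (r.tName, r.tStart, r.tEnd, r.strand) in normal_keys


class TestIdentityCoverage:
    def test_arithmetic(self, rng):
        from conftest import random_psl

        rec = random_psl(rng)
        rec.matches, rec.misMatches, rec.nCount = 95, 5, 0
        rec.blockSizes = [100]
        assert al.identity(rec) == pytest.approx(0.95)

    def test_all_n_identity_is_one(self, rng):
        from conftest import random_psl

        rec = random_psl(rng)
        rec.matches, rec.misMatches = 0, 0
        rec.nCount, rec.qSize = 50, 100
        assert al.identity(rec) == 1.0
        assert al.coverage(rec) == pytest.approx(0.5)

    def test_coverage_counts_aligned_bases(self, rng):
        from conftest import random_psl

        rec = random_psl(rng)
        rec.matches, rec.misMatches, rec.nCount, rec.qSize = 190, 8, 0, 200
        assert al.coverage(rec) == pytest.approx(0.99)


def test_worker_count_does_not_change_output(rng):
    genome = make_genome(rng, 5000)
    idx = al.build_index(genome)
    queries = {
        f"q{i}": mutate(rng, genome["chr1"][i * 300 : i * 300 + 150], 5)
        for i in range(10)
    }
    one = al.align_queries(queries, idx, genome)
    two = al.align_queries(queries, idx, genome, cores=2)
    assert one == two
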