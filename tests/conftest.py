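import numpy as np
import pytest

from hceanchor import anchoring, chainnet, databank as dbk
from hceanchor.io_formats import PSLRecord
from hceanchor.synthetic import SimParams, simulate

BASES = "ACGT"


def random_dna(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def random_psl(rng, qname="q", tname="t") -> PSLRecord:
    """A random structurally valid PSL record."""
    n_blocks = int(rng.integers(1, 5))
    sizes = [int(rng.integers(1, 50)) for _ in range(n_blocks)]
    q_gaps = [int(rng.integers(0, 10)) for _ in range(n_blocks - 1)]
    t_gaps = [int(rng.integers(0, 10)) for _ in range(n_blocks - 1)]
    q_starts, t_starts = [], []
    q = int(rng.integers(0, 20))
    t = int(rng.integers(0, 20))
    for i, size in enumerate(sizes):
        q_starts.append(q)
        t_starts.append(t)
        q += size + (q_gaps[i] if i < n_blocks - 1 else 0)
        t += size + (t_gaps[i] if i < n_blocks - 1 else 0)
    aligned = sum(sizes)
    mismatches = int(rng.integers(0, aligned // 4 + 1))
    ncount = int(rng.integers(0, (aligned - mismatches) // 4 + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    q_size = q_starts[-1] + sizes[-1] + int(rng.integers(0, 20))
    t_size = t_starts[-1] + sizes[-1] + int(rng.integers(0, 20))
    q_lo, q_hi = q_starts[0], q_starts[-1] + sizes[-1]
    if strand == "+":
        q_start, q_end = q_lo, q_hi
    else:
        q_start, q_end = q_size - q_hi, q_size - q_lo
    rec = PSLRecord(
        matches=aligned - mismatches - ncount, misMatches=mismatches,
        repMatches=0, nCount=ncount,
        qNumInsert=sum(1 for g in q_gaps if g), qBaseInsert=sum(q_gaps),
        tNumInsert=sum(1 for g in t_gaps if g), tBaseInsert=sum(t_gaps),
        strand=strand, qName=qname, qSize=q_size, qStart=q_start,
        qEnd=q_end, tName=tname, tSize=t_size,
        tStart=t_starts[0], tEnd=t_starts[-1] + sizes[-1],
        blockCount=n_blocks, blockSizes=sizes, qStarts=q_starts,
        tStarts=t_starts,
    )
    rec.validate()
    return rec


def gapless_record(tname, qname, strand, t_start, q_fwd_start, length,
                   t_size=100_000, q_size=100_000, mismatches=0):
    """A single-block reference-frame record, as the anchoring stage emits."""
    if strand == "+":
        q_block = q_fwd_start
        q_start, q_end = q_fwd_start, q_fwd_start + length
    else:
        q_block = q_size - (q_fwd_start + length)
        q_start, q_end = q_fwd_start, q_fwd_start + length
    rec = PSLRecord(
        matches=length - mismatches, misMatches=mismatches, repMatches=0,
        nCount=0, qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
        strand=strand, qName=qname, qSize=q_size, qStart=q_start, qEnd=q_end,
        tName=tname, tSize=t_size, tStart=t_start, tEnd=t_start + length,
        blockCount=1, blockSizes=[length], qStarts=[q_block],
        tStarts=[t_start],
    )
    rec.validate()
    return rec


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated pair exercised by several integration tests."""
    params = SimParams(
        seed=11, n_chromosomes=2, chromosome_length=250_000, n_hce=150,
        scaffold_n50_target=40_000, n_inversions=1, n_translocations=1,
        rearrangement_min_len=30_000, rearrangement_max_len=80_000,
    )
    reference, target, hces, truth = simulate(params)
    return params, reference, target, hces, truth


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Databank, anchors, chains, nets and report for the small pair."""
    _, reference, target, hces, truth = small_sim
    entries, db_stats = dbk.build_databank(hces, reference)
    params = anchoring.AnchorParams()
    records = anchoring.map_databank(entries, target, params)
    anchors = anchoring.filter_anchors(records, entries, params)
    ref_frame = anchoring.transfer_to_reference(anchors)
    chains = chainnet.chain_blocks(ref_frame)
    nets = chainnet.annotate_syntenic(
        chainnet.net_chains(chains, reference.sizes())
    )
    report = chainnet.scaffold_report(nets, anchors, target.sizes())
    return {
        "entries": entries, "db_stats": db_stats, "records": records,
        "anchors": anchors, "ref_frame": ref_frame, "chains": chains,
        "nets": nets, "report": report,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
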