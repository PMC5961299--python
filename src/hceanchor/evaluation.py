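"""Compare an anchor-based mapping against a baseline mapping.

Provides the intersecting-fraction statistic F (the share of baseline
homologous-block bases that the test mapping also recovers), a classifier
for per-scaffold mapping inconsistencies, and standard scaffold summary
statistics (N50, median, totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import NetNode, PSLRecord

__all__ = [
    "BlockSet",
    "FResult",
    "intersecting_fraction",
    "find_inconsistencies",
    "scaffold_stats",
]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersect_len(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class BlockSet:
    """Homologous blocks per scaffold: (chromosome, ref interval, scaffold interval)."""

    blocks: dict[str, list[tuple[str, tuple[int, int], tuple[int, int]]]] = field(
        default_factory=dict
    )

    def add(self, scaffold, chromosome, ref_iv, scaf_iv) -> None:
        if ref_iv[0] >= ref_iv[1] or scaf_iv[0] >= scaf_iv[1]:
            raise ValueError("empty block interval")
        self.blocks.setdefault(scaffold, []).append((chromosome, ref_iv, scaf_iv))

    def scaffold_intervals(self, scaffold: str) -> list[tuple[int, int]]:
        """Merged scaffold-coordinate intervals for one scaffold."""
        return _merge([iv for _, _, iv in self.blocks.get(scaffold, [])])

    @classmethod
    def from_net(cls, nets: dict[str, tuple[int, list[NetNode]]]) -> "BlockSet":
        bs = cls()
        for chrom, (size, fills) in nets.items():
            for top in fills:
                for node in top.walk():
                    if node.kind == "fill":
                        bs.add(
                            node.qName, chrom,
                            (node.tStart, node.tEnd), (node.qStart, node.qEnd),
                        )
        return bs

    @classmethod
    def from_psl(cls, records: list[PSLRecord]) -> "BlockSet":
        """Blocks from reference-frame PSL (query = scaffold, target = chromosome)."""
        bs = cls()
        for rec in records:
            bs.add(
                rec.qName, rec.tName,
                (rec.tStart, rec.tEnd), (rec.qStart, rec.qEnd),
            )
        return bs


@dataclass
class FResult:
    """Intersecting-fraction outcome.

    ``aggregate_F`` is total common bases over total baseline bases
    (sum C / sum Z); ``mean_ratio`` is the unweighted mean of per-scaffold
    C/Z, reported alongside because the two summaries differ when scaffold
    sizes vary.  Scaffolds with Z = 0 are excluded and listed in ``flagged``.
    """

    n: int
    per_scaffold: list[tuple[str, int, int, float]]  # (scaffold, C, Z, C/Z)
    aggregate_F: float
    mean_ratio: float
    flagged: list[str] = field(default_factory=list)


def intersecting_fraction(test: BlockSet, baseline: BlockSet) -> FResult:
    """Fraction of baseline homologous-block bases recovered by the test mapping.

    For each scaffold present in the baseline, C is the number of
    scaffold-coordinate bases covered by blocks of *both* mappings and Z the
    bases covered by baseline blocks.  The comparison is restricted to
    baseline scaffolds.
    """
    if not baseline.blocks:
        raise ValueError("baseline block set is empty")
    if not test.blocks:
        raise ValueError("test block set is empty")
    per: list[tuple[str, int, int, float]] = []
    flagged: list[str] = []
    total_c = total_z = 0
    for scaf in sorted(baseline.blocks):
        base_ivs = baseline.scaffold_intervals(scaf)
        z = sum(e - s for s, e in base_ivs)
        if z == 0:
            flagged.append(scaf)
            continue
        test_ivs = test.scaffold_intervals(scaf)
        c = _intersect_len(test_ivs, base_ivs)
        per.append((scaf, c, z, c / z))
        total_c += c
        total_z += z
    return FResult(
        n=len(per),
        per_scaffold=per,
        aggregate_F=total_c / total_z if total_z else 0.0,
        mean_ratio=sum(r for *_, r in per) / len(per) if per else 0.0,
        flagged=flagged,
    )


def find_inconsistencies(
    test_report: pd.DataFrame,
    baseline_report: pd.DataFrame,
    boundary_tol: int = 1000,
) -> list[tuple[str, str]]:
    """Classify per-scaffold disagreements between two scaffold reports.

    ``FULL_CONFLICT``: both mappings place the scaffold on a single
    chromosome, but different ones.  ``PARTIAL_SPLIT``: one mapping splits
    the scaffold across two or more chromosomes where the other uses one.
    ``BOUNDARY``: same single chromosome and position, but block ends differ
    by more than ``boundary_tol`` bases (the adjacent-alignment-overlap
    artifact).
    """
    def by_scaffold(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        return {s: g for s, g in df.groupby("scaffold")}

    t, b = by_scaffold(test_report), by_scaffold(baseline_report)
    out: list[tuple[str, str]] = []
    for scaf in sorted(set(t) & set(b)):
        tc = set(t[scaf]["chromosome"])
        bc = set(b[scaf]["chromosome"])
        if len(tc) == 1 and len(bc) == 1:
            if tc != bc:
                out.append((scaf, "FULL_CONFLICT"))
                continue
            trow = t[scaf].iloc[0]
            brow = b[scaf].iloc[0]
            if (
                abs(int(trow.ref_start) - int(brow.ref_start)) > boundary_tol
                or abs(int(trow.ref_end) - int(brow.ref_end)) > boundary_tol
            ):
                out.append((scaf, "BOUNDARY"))
        elif len(tc) != len(bc) and (len(tc) == 1 or len(bc) == 1):
            out.append((scaf, "PARTIAL_SPLIT"))
    return out


def scaffold_stats(
    scaffolds: pd.DataFrame,
    mapped: set[str],
    min_len: int = 10000,
) -> dict:
    """Summary statistics over scaffolds of at least ``min_len`` bases.

    ``scaffolds`` needs columns ``name`` and ``length``.  N50 is the largest
    L such that mapped scaffolds of length >= L sum to at least half the
    total mapped length.
    """
    if (scaffolds["length"] <= 0).any():
        raise ValueError("scaffold lengths must be positive")
    sub = scaffolds[scaffolds["length"] >= min_len]
    is_mapped = sub["name"].isin(mapped)
    mlens = sorted(sub.loc[is_mapped, "length"].tolist(), reverse=True)
    total = sum(mlens)
    n50 = 0
    acc = 0
    for ln in mlens:
        acc += ln
        if acc * 2 >= total:
            n50 = ln
            break
    stats = {
        "n_considered": int(len(sub)),
        "n_mapped": int(is_mapped.sum()),
        "n_unmapped": int((~is_mapped).sum()),
        "total_mapped_length": int(total),
        "n50": int(n50),
        "median": float(pd.Series(mlens).median()) if mlens else 0.0,
        "max": int(mlens[0]) if mlens else 0,
        "min": int(mlens[-1]) if mlens else 0,
    }
    return stats
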