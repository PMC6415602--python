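"""Intragenomic ITS spacer allele identification from region-spanning reads.

Alleles are full-region haplotypes observed on single reads that span the
spacer, which sidesteps short-read phasing entirely (the simulator
guarantees spanning reads; on real data this stage needs merged or long
reads).  Low-support haplotypes within ``max_err_distinct`` mismatches of a
major allele are treated as sequencing errors and merged; farther ones are
discarded as noise, never promoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import trees
from .align_call import CallerParams, ReferenceIndex, map_read, revcomp
from .io_formats import ReadRecord, SeqRecord

__all__ = [
    "ITSError",
    "ITSAllele",
    "ITSAlleleTable",
    "extract_spanning_reads",
    "cluster_alleles",
    "classify_specificity",
    "allele_nj_tree",
    "hamming",
]


class ITSError(RuntimeError):
    pass


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotypes must have equal length")
    return sum(x != y for x, y in zip(a, b))


def extract_spanning_reads(
    reads_by_sample: dict[str, list[ReadRecord]],
    its_ref: SeqRecord,
    region: tuple[int, int],
    params: CallerParams | None = None,
) -> dict[str, list[str]]:
    """Project reads that fully cover ``region`` onto region coordinates.

    ``region`` is 0-based half-open on ``its_ref``.  Reads are mapped with
    the ungapped seed-and-extend mapper; minus-strand reads are
    strand-normalized, so a read and its reverse complement yield the same
    haplotype string.
    """
    start, end = region
    if not (0 <= start < end <= len(its_ref)):
        raise ValueError(f"region {region} outside reference of length {len(its_ref)}")
    params = params or CallerParams()
    index = ReferenceIndex([its_ref], k=params.k_seed)
    out: dict[str, list[str]] = {}
    for sample, reads in reads_by_sample.items():
        haplotypes: list[str] = []
        for read in reads:
            aln = map_read(read, index, params)
            if aln is None:
                continue
            if aln.start > start or aln.start + len(read) < end:
                continue  # does not span the region
            oriented = read.seq if aln.strand == "+" else revcomp(read.seq)
            haplotypes.append(oriented[start - aln.start : end - aln.start])
        if not haplotypes:
            raise ITSError(
                f"sample {sample!r}: no reads span region {start + 1}-{end} "
                f"of {its_ref.id!r}"
            )
        out[sample] = haplotypes
    return out


@dataclass
class ITSAllele:
    allele_id: str  # H1, H2, ... in decreasing total-support order
    seq: str
    support: dict[str, int]  # per-sample spanning-read support

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class ITSAlleleTable:
    region: str
    alleles: list[ITSAllele]
    discarded: int  # spanning haplotypes dropped as unattached noise
    pairwise_diffs: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), int))

    def allele(self, allele_id: str) -> ITSAllele:
        for a in self.alleles:
            if a.allele_id == allele_id:
                return a
        raise KeyError(allele_id)

    def samples(self) -> list[str]:
        seen: list[str] = []
        for a in self.alleles:
            for s in a.support:
                if s not in seen:
                    seen.append(s)
        return sorted(seen)


def cluster_alleles(
    haplotypes_by_sample: dict[str, list[str]],
    min_support: int = 3,
    max_err_distinct: int = 1,
    region: str = "ITS",
) -> ITSAlleleTable:
    """Group identical haplotypes into alleles and absorb sequencing noise.

    Haplotype groups with total support >= ``min_support`` become alleles.
    Smaller groups are merged into the nearest major allele when within
    ``max_err_distinct`` mismatches (ties broken by larger support, then
    sequence order), otherwise discarded.  Alleles are labeled H1.. by
    decreasing total support (ties by sequence order), so reruns on
    identical input give identical labels.
    """
    counts: dict[str, dict[str, int]] = {}
    for sample, haplotypes in haplotypes_by_sample.items():
        for hap in haplotypes:
            counts.setdefault(hap, {}).setdefault(sample, 0)
            counts[hap][sample] += 1
    if not counts:
        raise ITSError("no haplotypes to cluster")
    lengths = {len(h) for h in counts}
    if len(lengths) != 1:
        raise ITSError("haplotypes must all have the region length")

    total = {hap: sum(sup.values()) for hap, sup in counts.items()}
    majors = [hap for hap in counts if total[hap] >= min_support]
    minors = [hap for hap in counts if total[hap] < min_support]
    discarded = 0
    merged: dict[str, dict[str, int]] = {hap: dict(counts[hap]) for hap in majors}
    for hap in sorted(minors):
        best: tuple[int, int, str] | None = None
        for major in majors:
            d = hamming(hap, major)
            if d <= max_err_distinct:
                key = (d, -total[major], major)
                if best is None or key < best:
                    best = key
        if best is None:
            discarded += sum(counts[hap].values())
        else:
            target = merged[best[2]]
            for sample, n in counts[hap].items():
                target[sample] = target.get(sample, 0) + n
    if not merged:
        raise ITSError(
            f"all haplotype groups fell below min_support={min_support}; "
            "lower min_support or provide more reads"
        )

    ranked = sorted(merged, key=lambda hap: (-sum(merged[hap].values()), hap))
    alleles = [
        ITSAllele(allele_id=f"H{i + 1}", seq=hap, support=dict(sorted(merged[hap].items())))
        for i, hap in enumerate(ranked)
    ]
    n = len(alleles)
    diffs = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            diffs[i, j] = diffs[j, i] = hamming(alleles[i].seq, alleles[j].seq)
    return ITSAlleleTable(
        region=region, alleles=alleles, discarded=discarded, pairwise_diffs=diffs
    )


@dataclass(frozen=True)
class AlleleSpecificity:
    samples: tuple[str, ...]
    exclusive: bool  # exactly one supporting sample


def classify_specificity(
    table: ITSAlleleTable, min_support: int = 3
) -> dict[str, AlleleSpecificity]:
    """Which samples support each allele; exclusive iff exactly one does."""
    out: dict[str, AlleleSpecificity] = {}
    for allele in table.alleles:
        supported = tuple(
            sorted(s for s, n in allele.support.items() if n >= min_support)
        )
        out[allele.allele_id] = AlleleSpecificity(
            samples=supported, exclusive=len(supported) == 1
        )
    return out


def allele_nj_tree(table: ITSAlleleTable) -> trees.TreeNode:
    """Neighbor-joining tree of the alleles on their pairwise differences."""
    if len(table.alleles) < 2:
        raise ITSError("need at least 2 alleles for a tree")
    names = [a.allele_id for a in table.alleles]
    return trees.neighbor_joining(names, table.pairwise_diffs.astype(float))
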