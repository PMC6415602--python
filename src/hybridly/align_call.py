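"""Ungapped seed-and-extend read mapping and threshold-based diploid calling.

The mapper indexes exact k-mer seeds of the reference (forward strand), maps
each read on both strands by Hamming extension and keeps only unique best
placements — ambiguous reads are discarded so pileups stay deterministic.
The genotype caller is a pure function of a pileup column: no likelihoods,
just depth/count/fraction thresholds surfaced in :class:`CallerParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_formats import ReadRecord, SeqRecord, VariantRecord, VCFData
from .simulate import _BASE_TO_CODE, _CODE_TO_BASE, codes_to_str, str_to_codes

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "CallerParams",
    "Alignment",
    "PileupColumn",
    "ReferenceIndex",
    "CallError",
    "revcomp",
    "map_read",
    "map_read_bruteforce",
    "pileup",
    "sample_pileup_counts",
    "call_genotype",
    "call_genotypes_array",
    "call_all",
]


class CallError(RuntimeError):
    """Raised when calling cannot proceed (e.g. a sample maps no reads)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CallerParams:
    """Mapping and genotype-calling thresholds."""

    k_seed: int = 31
    max_mismatch: int = 5
    min_depth: int = 8
    min_allele_frac: float = 0.2
    min_allele_count: int = 3
    hom_frac: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.min_allele_frac < 0.5 <= self.hom_frac <= 1.0):
            raise ValueError(
                "need 0 < min_allele_frac < 0.5 <= hom_frac <= 1, got "
                f"min_allele_frac={self.min_allele_frac}, hom_frac={self.hom_frac}"
            )
        if self.k_seed < 1:
            raise ValueError("k_seed must be positive")


@dataclass(frozen=True)
class Alignment:
    """An ungapped read placement on the forward strand of a contig."""

    read_id: str
    contig: str
    start: int  # 0-based offset
    strand: str  # "+" or "-"
    n_mismatch: int


@dataclass
class PileupColumn:
    contig: str
    pos: int  # 0-based
    ref_base: str
    base_counts: dict[str, int]
    depth: int

    def __post_init__(self) -> None:
        if self.depth != sum(self.base_counts.values()):
            raise ValueError("depth must equal the sum of base counts")


class ReferenceIndex:
    """Exact k-mer seed index over the forward strand of every contig."""

    def __init__(self, contigs: Sequence[SeqRecord], k: int = 31) -> None:
        if not contigs:
            raise ValueError("no contigs to index")
        self.k = k
        self.names = [c.id for c in contigs]
        self.lengths = [len(c) for c in contigs]
        self.codes: list[np.ndarray] = []
        self.seeds: dict[bytes, list[tuple[int, int]]] = {}
        for ci, contig in enumerate(contigs):
            raw = contig.seq.encode("ascii")
            codes = _BASE_TO_CODE[np.frombuffer(raw, dtype=np.uint8)]
            self.codes.append(codes)
            for pos in range(len(raw) - k + 1):
                self.seeds.setdefault(raw[pos : pos + k], []).append((ci, pos))


def _seed_offsets(read_length: int, k: int) -> list[int]:
    offsets = list(range(0, read_length - k + 1, k))
    last = read_length - k
    if last not in offsets:
        offsets.append(last)
    return offsets


def _candidate_starts(
    seq_bytes: bytes, index: ReferenceIndex, offsets: list[int]
) -> set[tuple[int, int]]:
    k = index.k
    length = len(seq_bytes)
    out: set[tuple[int, int]] = set()
    for off in offsets:
        hits = index.seeds.get(seq_bytes[off : off + k])
        if not hits:
            continue
        for ci, pos in hits:
            start = pos - off
            if 0 <= start <= index.lengths[ci] - length:
                out.add((ci, start))
    return out


def map_read(
    read: ReadRecord | str, index: ReferenceIndex, params: CallerParams = CallerParams()
) -> Alignment | None:
    """Best unique ungapped placement of a read, or None.

    Seeds are exact k-mers at tiled offsets on both strands; extension is a
    full-length Hamming comparison.  Placements tying for fewest mismatches
    make the read ambiguous (None).  A placement whose every seed window
    contains a mismatch can be missed; with r = floor(read_length / k)
    disjoint windows, any placement with <= r - 1 mismatches is guaranteed
    to be found.
    """
    if isinstance(read, ReadRecord):
        read_id, seq = read.id, read.seq
    else:
        read_id, seq = "read", read
    if len(seq) < index.k:
        logger.debug("read %s shorter than seed length %d: unmapped", read_id, index.k)
        return None
    offsets = _seed_offsets(len(seq), index.k)
    best: tuple[int, int, int, str] | None = None
    ambiguous = False
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        seq_bytes = oriented.encode("ascii")
        codes = _BASE_TO_CODE[np.frombuffer(seq_bytes, dtype=np.uint8)]
        for ci, start in sorted(_candidate_starts(seq_bytes, index, offsets)):
            ref_slice = index.codes[ci][start : start + len(seq)]
            nm = int(np.count_nonzero(codes != ref_slice))
            if nm > params.max_mismatch:
                continue
            if best is None or nm < best[0]:
                best = (nm, ci, start, strand)
                ambiguous = False
            elif nm == best[0] and (ci, start, strand) != best[1:]:
                ambiguous = True
    if best is None or ambiguous:
        return None
    nm, ci, start, strand = best
    return Alignment(
        read_id=read_id, contig=index.names[ci], start=start, strand=strand, n_mismatch=nm
    )


def map_read_bruteforce(
    read: ReadRecord | str,
    contigs: Sequence[SeqRecord],
    params: CallerParams = CallerParams(),
) -> Alignment | None:
    """Exhaustive best-Hamming placement over all offsets and strands.

    Independent of the seed index; used as the mapping oracle.  Applies the
    same unique-best and max_mismatch rules as :func:`map_read`.
    """
    if isinstance(read, ReadRecord):
        read_id, seq = read.id, read.seq
    else:
        read_id, seq = "read", read
    length = len(seq)
    best: tuple[int, int, int, str] | None = None
    ambiguous = False
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        codes = _BASE_TO_CODE[np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)]
        for ci, contig in enumerate(contigs):
            ref = _BASE_TO_CODE[
                np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)
            ]
            for start in range(len(contig) - length + 1):
                nm = int(np.count_nonzero(codes != ref[start : start + length]))
                if nm > params.max_mismatch:
                    continue
                if best is None or nm < best[0]:
                    best = (nm, ci, start, strand)
                    ambiguous = False
                elif nm == best[0] and (ci, start, strand) != best[1:]:
                    ambiguous = True
    if best is None or ambiguous:
        return None
    nm, ci, start, strand = best
    return Alignment(
        read_id=read_id,
        contig=contigs[ci].id,
        start=start,
        strand=strand,
        n_mismatch=nm,
    )


def sample_pileup_counts(
    reads: Iterable[ReadRecord],
    index: ReferenceIndex,
    params: CallerParams = CallerParams(),
) -> tuple[dict[str, np.ndarray], int]:
    """Map reads and accumulate per-contig (4, L) base-count matrices.

    Minus-strand reads contribute their reverse complement, so counts are
    always on the forward strand.  Returns the counts and the number of
    uniquely mapped reads.
    """
    counts = {
        name: np.zeros((4, length), dtype=np.uint32)
        for name, length in zip(index.names, index.lengths)
    }
    name_of = index.names
    n_mapped = 0
    for read in reads:
        aln = map_read(read, index, params)
        if aln is None:
            continue
        n_mapped += 1
        oriented = read.seq if aln.strand == "+" else revcomp(read.seq)
        codes = _BASE_TO_CODE[np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)]
        mat = counts[aln.contig]
        positions = np.arange(aln.start, aln.start + len(codes))
        valid = codes < 4  # N bases (if any) are not counted
        np.add.at(mat, (codes[valid], positions[valid]), 1)
    _ = name_of
    return counts, n_mapped


def pileup(
    alignments: Iterable[Alignment],
    reads: Iterable[ReadRecord],
    contigs: Sequence[SeqRecord],
) -> Iterator[PileupColumn]:
    """Stream pileup columns (covered positions only) from explicit alignments."""
    reads_by_id = {r.id: r for r in reads}
    by_contig = {c.id: c for c in contigs}
    counts: dict[str, np.ndarray] = {
        c.id: np.zeros((4, len(c)), dtype=np.uint32) for c in contigs
    }
    for aln in alignments:
        read = reads_by_id[aln.read_id]
        oriented = read.seq if aln.strand == "+" else revcomp(read.seq)
        codes = _BASE_TO_CODE[np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)]
        positions = np.arange(aln.start, aln.start + len(codes))
        valid = codes < 4
        np.add.at(counts[aln.contig], (codes[valid], positions[valid]), 1)
    for contig_id, mat in counts.items():
        depth = mat.sum(axis=0)
        seq = by_contig[contig_id].seq
        for pos in np.flatnonzero(depth):
            base_counts = {
                "ACGT"[b]: int(mat[b, pos]) for b in range(4) if mat[b, pos] > 0
            }
            yield PileupColumn(
                contig=contig_id,
                pos=int(pos),
                ref_base=seq[pos],
                base_counts=base_counts,
                depth=int(depth[pos]),
            )


def call_genotype(
    column: PileupColumn, params: CallerParams = CallerParams()
) -> tuple[str, str] | None:
    """Diploid genotype of one pileup column, or None (missing).

    Rules, applied in order: depth < min_depth -> missing; an allele
    qualifies when its count >= min_allele_count and its fraction >=
    min_allele_frac; if the most frequent base reaches hom_frac of the depth
    the call is homozygous for it; otherwise exactly two qualifying alleles
    give a heterozygous call and anything else is missing.
    """
    if column.depth < params.min_depth:
        return None
    counts = {b: column.base_counts.get(b, 0) for b in "ACGT"}
    depth = column.depth
    qualifying = [
        b
        for b in "ACGT"
        if counts[b] >= params.min_allele_count
        and counts[b] / depth >= params.min_allele_frac
    ]
    top = max("ACGT", key=lambda b: (counts[b], -("ACGT".index(b))))
    if counts[top] / depth >= params.hom_frac:
        return (top, top)
    if len(qualifying) == 2:
        a, b = sorted(qualifying)
        return (a, b)
    return None


def call_genotypes_array(
    counts: np.ndarray, params: CallerParams = CallerParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized caller over a (4, L) count matrix.

    Returns two int8 arrays of base codes (sorted pairs); -1 marks missing.
    Must agree with :func:`call_genotype` column-by-column (property-tested).
    """
    depth = counts.sum(axis=0).astype(np.int64)
    length = counts.shape[1]
    g0 = np.full(length, -1, dtype=np.int8)
    g1 = np.full(length, -1, dtype=np.int8)
    ok = depth >= params.min_depth
    if not np.any(ok):
        return g0, g1
    safe_depth = np.where(depth > 0, depth, 1)
    frac = counts / safe_depth
    qualifying = (counts >= params.min_allele_count) & (frac >= params.min_allele_frac)
    n_qual = qualifying.sum(axis=0)
    top = counts.argmax(axis=0)  # ties -> lowest base code, as in the scalar rule
    top_frac = np.take_along_axis(frac, top[None, :], axis=0)[0]
    hom = ok & (top_frac >= params.hom_frac)
    g0[hom] = top[hom]
    g1[hom] = top[hom]
    het = ok & ~hom & (n_qual == 2)
    if np.any(het):
        idx = np.arange(4)[:, None]
        first = np.min(np.where(qualifying, idx, 4), axis=0)
        second = np.max(np.where(qualifying, idx, -1), axis=0)
        g0[het] = first[het]
        g1[het] = second[het]
    return g0, g1


def call_all(
    reads_by_sample: dict[str, Iterable[ReadRecord]],
    contigs: Sequence[SeqRecord],
    params: CallerParams = CallerParams(),
) -> VCFData:
    """Map and genotype every sample; emit multi-sample SNV calls.

    A row is emitted at every position where at least one sample's called
    genotype contains a non-reference allele; rows where every sample is
    missing cannot occur under that rule and are therefore never emitted.
    """
    if len(reads_by_sample) < 2:
        raise CallError("need at least 2 samples to call jointly")
    index = ReferenceIndex(contigs, k=params.k_seed)
    samples = list(reads_by_sample)
    per_sample_counts: dict[str, dict[str, np.ndarray]] = {}
    for sample, reads in reads_by_sample.items():
        counts, n_mapped = sample_pileup_counts(reads, index, params)
        if n_mapped == 0:
            raise CallError(f"sample {sample!r}: zero reads mapped to the reference")
        per_sample_counts[sample] = counts

    records: list[VariantRecord] = []
    for contig in contigs:
        ref_codes = str_to_codes(contig.seq) if "N" not in contig.seq else None
        if ref_codes is None:
            raw = _BASE_TO_CODE[np.frombuffer(contig.seq.encode(), dtype=np.uint8)]
            ref_codes = raw  # N positions have code 255 and never match a call
        genotypes = {}
        depths = {}
        for sample in samples:
            mat = per_sample_counts[sample][contig.id]
            genotypes[sample] = call_genotypes_array(mat, params)
            depths[sample] = mat.sum(axis=0)
        nonref = np.zeros(len(contig), dtype=bool)
        for sample in samples:
            g0, g1 = genotypes[sample]
            called = g0 >= 0
            nonref |= called & ((g0 != ref_codes) | (g1 != ref_codes))
        for pos in np.flatnonzero(nonref):
            ref_base = contig.seq[pos]
            if ref_base not in "ACGT":
                continue  # no defined ref allele under an N
            alt_set: set[str] = set()
            for sample in samples:
                g0, g1 = genotypes[sample]
                if g0[pos] < 0:
                    continue
                for code in (int(g0[pos]), int(g1[pos])):
                    base = "ACGT"[code]
                    if base != ref_base:
                        alt_set.add(base)
            if not alt_set:
                continue
            alts = sorted(alt_set)
            allele_index = {ref_base: 0, **{b: i + 1 for i, b in enumerate(alts)}}
            row_gts: list[tuple[int, int] | None] = []
            row_dps: list[int | None] = []
            for sample in samples:
                g0, g1 = genotypes[sample]
                if g0[pos] < 0:
                    row_gts.append(None)
                else:
                    pair = tuple(
                        sorted(
                            (
                                allele_index["ACGT"[int(g0[pos])]],
                                allele_index["ACGT"[int(g1[pos])]],
                            )
                        )
                    )
                    row_gts.append((pair[0], pair[1]))
                row_dps.append(int(depths[sample][pos]))
            records.append(
                VariantRecord(
                    contig=contig.id,
                    pos=int(pos) + 1,
                    ref_allele=ref_base,
                    alt_alleles=alts,
                    genotypes=row_gts,
                    depths=row_dps,
                )
            )
    return VCFData(samples=samples, records=records)
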