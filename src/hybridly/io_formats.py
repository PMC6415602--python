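"""Readers and writers for FASTA, FASTQ, VCF (SNV subset) and Newick.

All internal coordinates in this package are 0-based half-open; the single
place 1-based coordinates appear is :class:`VariantRecord.pos`, which mirrors
the VCF convention and is converted exactly once at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from . import trees

logger = logging.getLogger(__name__)

FASTA_ALPHABET = frozenset("ACGTN")
DNA_BASES = ("A", "C", "G", "T")

__all__ = [
    "FormatError",
    "SeqRecord",
    "ReadRecord",
    "VariantRecord",
    "VCFData",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "iter_fastq",
    "write_fastq",
    "read_vcf",
    "write_vcf",
    "write_newick",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class SeqRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred+33 qualities."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class VariantRecord:
    """A single-nucleotide variant row with per-sample diploid genotypes.

    ``pos`` is 1-based (VCF convention).  ``genotypes[i]`` is an ordered pair
    of allele indices into ``[ref_allele] + alt_alleles``, or ``None`` when
    the call is missing.  ``depths[i]`` is the per-sample read depth or None.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    genotypes: list[tuple[int, int] | None]
    depths: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("alt alleles must be disjoint from the ref allele")
        n_alleles = 1 + len(self.alt_alleles)
        for gt in self.genotypes:
            if gt is None:
                continue
            if any(a < 0 or a >= n_alleles for a in gt):
                raise ValueError(f"allele index out of range in genotype {gt}")
        if not self.depths:
            self.depths = [None] * len(self.genotypes)

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele] + list(self.alt_alleles)

    def genotype_bases(self, sample_index: int) -> tuple[str, str] | None:
        """Genotype of one sample as a pair of allele strings (or None)."""
        gt = self.genotypes[sample_index]
        if gt is None:
            return None
        alleles = self.alleles
        return (alleles[gt[0]], alleles[gt[1]])


@dataclass
class VCFData:
    """Parsed multi-sample SNV calls: the currency of all statistics here."""

    samples: list[str]
    records: list[VariantRecord]
    n_skipped_non_snv: int = 0

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise ValueError(
                f"unknown sample {name!r}; VCF samples are {self.samples}"
            ) from None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file, enforcing the {A,C,G,T,N} alphabet (case folded)."""
    records: list[SeqRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(
                f"{path}: record {header!r} (line {header_line}) has no sequence"
            )
        records.append(SeqRecord(id=header, seq=seq))
        header = None
        chunks = []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {line_no}")
                header_line = line_no
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence data before any header at line {line_no}"
                    )
                seq = line.upper()
                bad = set(seq) - FASTA_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}: invalid character(s) {sorted(bad)} at line {line_no}"
                    )
                chunks.append(seq)
        flush(line_no=-1)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a 4-line-per-record FASTQ file."""
    with open(path) as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(
                    f"{path}: record {index}: expected '@' header, got {header[:20]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}: record {index} is truncated")
            if not plus.startswith("+"):
                raise FormatError(
                    f"{path}: record {index}: expected '+' separator line"
                )
            bad = set(seq.upper()) - FASTA_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}: record {index}: invalid base(s) {sorted(bad)}"
                )
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}: record {index}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield ReadRecord(id=header[1:].split()[0], seq=seq.upper(), qual=qual)
            index += 1


def read_fastq(path: str | Path) -> list[ReadRecord]:
    return list(iter_fastq(path))


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


# ---------------------------------------------------------------------------
# VCF


def _parse_gt(token: str, n_alleles: int) -> tuple[int, int] | None:
    """Normalize a GT token to a diploid pair; half-calls become missing."""
    fields = token.replace("|", "/").split("/")
    if len(fields) == 1:
        fields = fields * 2  # haploid call normalized to ploidy 2
    if len(fields) != 2:
        return None
    alleles: list[int] = []
    for f in fields:
        if f == "." or f == "":
            return None
        try:
            a = int(f)
        except ValueError:
            return None
        if a < 0 or a >= n_alleles:
            return None
        alleles.append(a)
    return (alleles[0], alleles[1])


def read_vcf(path: str | Path) -> VCFData:
    """Read SNV records from a VCF v4.x file.

    Non-SNV rows (indels, symbolic alleles, missing ALT) are skipped and
    counted in ``n_skipped_non_snv``.  Genotype ploidy is normalized to 2
    and half-calls are treated as missing.
    """
    samples: list[str] | None = None
    records: list[VariantRecord] = []
    n_skipped = 0
    snv_alleles = set(DNA_BASES)

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:] if len(cols) > 9 else []
                continue
            if samples is None:
                raise FormatError(
                    f"{path}: data line {line_no} before the #CHROM header "
                    "(missing #CHROM header?)"
                )
            cols = line.split("\t")
            if len(cols) < 8:
                raise FormatError(f"{path}: line {line_no}: fewer than 8 columns")
            contig, pos_s, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            ref = ref.upper()
            alts = [a.upper() for a in alt.split(",")]
            if (
                ref not in snv_alleles
                or alt == "."
                or any(a not in snv_alleles for a in alts)
            ):
                n_skipped += 1
                continue
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}: line {line_no}: bad POS {pos_s!r}") from None
            n_alleles = 1 + len(alts)
            genotypes: list[tuple[int, int] | None] = []
            depths: list[int | None] = []
            if samples:
                if len(cols) < 10:
                    raise FormatError(
                        f"{path}: line {line_no}: missing sample columns"
                    )
                fmt = cols[8].split(":")
                gt_idx = fmt.index("GT") if "GT" in fmt else None
                dp_idx = fmt.index("DP") if "DP" in fmt else None
                for token in cols[9 : 9 + len(samples)]:
                    parts = token.split(":")
                    gt = None
                    dp = None
                    if gt_idx is not None and gt_idx < len(parts):
                        gt = _parse_gt(parts[gt_idx], n_alleles)
                    if dp_idx is not None and dp_idx < len(parts):
                        try:
                            dp = int(parts[dp_idx])
                        except ValueError:
                            dp = None
                    genotypes.append(gt)
                    depths.append(dp)
            records.append(
                VariantRecord(
                    contig=contig,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=alts,
                    genotypes=genotypes,
                    depths=depths,
                )
            )
    if samples is None:
        raise FormatError(f"{path}: missing #CHROM header")
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV record(s)", path, n_skipped)
    return VCFData(samples=samples, records=records, n_skipped_non_snv=n_skipped)


def write_vcf(
    vcf: VCFData,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write SNV records as VCF v4.2 with GT:DP per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridly\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if vcf.samples:
            header += ["FORMAT"] + vcf.samples
        fh.write("\t".join(header) + "\n")
        for rec in vcf.records:
            cols = [
                rec.contig,
                str(rec.pos),
                ".",
                rec.ref_allele,
                ",".join(rec.alt_alleles),
                ".",
                "PASS",
                ".",
            ]
            if vcf.samples:
                cols.append("GT:DP")
                for gt, dp in zip(rec.genotypes, rec.depths):
                    gt_s = "./." if gt is None else f"{gt[0]}/{gt[1]}"
                    dp_s = "." if dp is None else str(dp)
                    cols.append(f"{gt_s}:{dp_s}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: trees.TreeNode, path: str | Path) -> None:
    """Write a tree as Newick; labels with spaces or punctuation are quoted."""
    with open(path, "w") as fh:
        fh.write(trees.to_newick(tree) + "\n")
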