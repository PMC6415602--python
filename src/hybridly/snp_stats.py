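"""Per-contig SNP summaries, genome-wide densities and fold-elevation ratios.

Definitions used throughout:

* **intra-sample SNP count**: sites where a sample's called genotype is
  heterozygous (two distinct allele values).  This is the within-individual
  (intragenomic) polymorphism an F1 hybrid inflates; homozygous-alternate
  genotypes measure divergence from the reference assembly, not
  heterozygosity, and are deliberately not counted here.
* **inter-sample SNP count**: sites where the two designated candidate
  samples are both called and share no allele value (fixed differences).

Densities are reported per 10 kb; fold-elevations are the hybrid's total
over each candidate's total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import VCFData

__all__ = [
    "ContigSNPSummary",
    "DensityReport",
    "summarize_contigs",
    "density_report",
    "density_track",
    "fold_elevation",
]


@dataclass
class ContigSNPSummary:
    """One table row: per-sample intra counts plus the candidate-pair inter count."""

    contig: str
    length: int
    intra: dict[str, int]
    inter: int

    def __post_init__(self) -> None:
        if self.length < 0 or self.inter < 0 or any(v < 0 for v in self.intra.values()):
            raise ValueError("counts and lengths must be non-negative")


def _genotype_sets(
    record, sample_indices: dict[str, int]
) -> dict[str, set[str] | None]:
    return {
        name: (
            None
            if record.genotypes[idx] is None
            else set(record.genotype_bases(idx))
        )
        for name, idx in sample_indices.items()
    }


def summarize_contigs(
    vcf: VCFData,
    contig_lengths: dict[str, int],
    candidate_pair: tuple[str, str],
) -> list[ContigSNPSummary]:
    """Tally intra- and inter-sample SNP counts for every contig.

    Sites where a sample's genotype is missing are excluded from that
    sample's intra count; the inter count requires both candidates called.
    """
    for name in candidate_pair:
        vcf.sample_index(name)  # raises on unknown samples
    samples = vcf.samples
    idx_a = vcf.sample_index(candidate_pair[0])
    idx_b = vcf.sample_index(candidate_pair[1])
    intra = {contig: {s: 0 for s in samples} for contig in contig_lengths}
    inter = {contig: 0 for contig in contig_lengths}
    for rec in vcf.records:
        if rec.contig not in intra:
            raise ValueError(f"VCF contig {rec.contig!r} not in contig_lengths")
        for si, sample in enumerate(samples):
            bases = rec.genotype_bases(si)
            if bases is not None and bases[0] != bases[1]:
                intra[rec.contig][sample] += 1
        ga = rec.genotype_bases(idx_a)
        gb = rec.genotype_bases(idx_b)
        if ga is not None and gb is not None and not (set(ga) & set(gb)):
            inter[rec.contig] += 1
    return [
        ContigSNPSummary(
            contig=contig, length=length, intra=intra[contig], inter=inter[contig]
        )
        for contig, length in contig_lengths.items()
    ]


def fold_elevation(hybrid_total: int, candidate_total: int) -> float | None:
    """Hybrid/candidate ratio; None when the candidate total is zero."""
    if candidate_total == 0:
        return None
    return hybrid_total / candidate_total


@dataclass
class DensityReport:
    """Totals, per-10-kb densities and hybrid-vs-candidate fold ratios."""

    hybrid: str
    total_count: dict[str, int]
    total_inter: int
    total_length: int
    density_per_10kb: dict[str, float] = field(init=False)
    fold_vs: dict[str, float | None] = field(init=False)

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total length must be positive")
        if self.hybrid not in self.total_count:
            raise ValueError(f"hybrid {self.hybrid!r} not among totals")
        self.density_per_10kb = {
            s: 1e4 * c / self.total_length for s, c in self.total_count.items()
        }
        hybrid_total = self.total_count[self.hybrid]
        self.fold_vs = {
            s: fold_elevation(hybrid_total, c)
            for s, c in self.total_count.items()
            if s != self.hybrid
        }

    def density_rounded(self, sample: str) -> int:
        return round(self.density_per_10kb[sample])

    def fold_rounded(self, candidate: str) -> float | None:
        fold = self.fold_vs[candidate]
        return None if fold is None else round(fold, 1)

    @classmethod
    def from_totals(
        cls,
        total_count: dict[str, int],
        total_length: int,
        hybrid: str,
        total_inter: int = 0,
    ) -> "DensityReport":
        """Build a report directly from externally supplied column totals."""
        return cls(
            hybrid=hybrid,
            total_count=dict(total_count),
            total_inter=total_inter,
            total_length=total_length,
        )


def density_report(
    summaries: list[ContigSNPSummary], hybrid_name: str
) -> DensityReport:
    """Column-sum the per-contig summaries into a density/fold report."""
    if not summaries:
        raise ValueError("no contig summaries given")
    samples = list(summaries[0].intra)
    totals = {s: sum(summary.intra[s] for summary in summaries) for s in samples}
    return DensityReport(
        hybrid=hybrid_name,
        total_count=totals,
        total_inter=sum(s.inter for s in summaries),
        total_length=sum(s.length for s in summaries),
    )


def density_track(
    vcf: VCFData,
    contig: str,
    contig_length: int,
    window_bp: int = 10_000,
    step: int | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Windowed intra-SNP counts per sample along one contig.

    Windows tile ``[i*step, i*step + window_bp)`` with the last one
    truncated at the contig end.  With ``step == window_bp`` the window
    counts of each sample sum to its contig intra count.  Returns the
    window start positions and a per-sample count array.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    step = window_bp if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = np.arange(0, contig_length, step)
    counts = {s: np.zeros(starts.size, dtype=int) for s in vcf.samples}
    for rec in vcf.records:
        if rec.contig != contig:
            continue
        pos0 = rec.pos - 1  # internal coordinates are 0-based
        lo = max(0, (pos0 - window_bp) // step + 1)
        for wi in range(lo, starts.size):
            if starts[wi] > pos0:
                break
            if pos0 < min(starts[wi] + window_bp, contig_length):
                for si, sample in enumerate(vcf.samples):
                    bases = rec.genotype_bases(si)
                    if bases is not None and bases[0] != bases[1]:
                        counts[sample][wi] += 1
    return starts, counts
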