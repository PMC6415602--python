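"""End-to-end orchestration on simulated data: every analysis stage chained.

This is what ``hybridly run-all`` executes and what the recovery tests
drive: simulate -> map/call -> SNP stats -> allele partition -> organellar
distances -> ITS alleles -> (optionally) k-mer phylogeny -> verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import aaf_phylo, allele_sharing, its_alleles, organelle_distance, snp_stats
from .align_call import CallerParams, call_all
from .io_formats import VCFData
from .its_alleles import ITSAlleleTable
from .simulate import (
    HYBRID,
    NON_PARENT,
    OUTGROUP,
    REF_SPECIES,
    SimConfig,
    SimulationOutput,
    simulate_all,
)
from .trees import TreeNode
from .verdict import HybridVerdict, VerdictParams, decide

__all__ = ["PipelineResult", "run_pipeline"]

CANDIDATES = (REF_SPECIES, NON_PARENT)


@dataclass
class PipelineResult:
    sim: SimulationOutput
    vcf: VCFData
    summaries: list[snp_stats.ContigSNPSummary]
    report: snp_stats.DensityReport
    partition: allele_sharing.AllelePartition
    sharing_tests: dict[str, allele_sharing.SharingTest]
    cp_matrix: organelle_distance.DistanceMatrix
    maternal: organelle_distance.MaternalAssignment
    its_table: ITSAlleleTable | None
    verdict: HybridVerdict
    aaf_tree: TreeNode | None


def run_pipeline(
    cfg: SimConfig,
    caller_params: CallerParams | None = None,
    verdict_params: VerdictParams | None = None,
    include_its: bool = True,
    include_aaf: bool = False,
) -> PipelineResult:
    """Simulate one data set and run the full diagnosis on it."""
    caller_params = caller_params or CallerParams()
    verdict_params = verdict_params or VerdictParams()
    sim = simulate_all(cfg)

    nuclear = {s: sim.reads[s] for s in (REF_SPECIES, NON_PARENT, HYBRID)}
    vcf = call_all(nuclear, sim.contigs, caller_params)

    summaries = snp_stats.summarize_contigs(
        vcf, sim.truth.contig_lengths, candidate_pair=CANDIDATES
    )
    report = snp_stats.density_report(summaries, HYBRID)

    partition = allele_sharing.partition_alleles(vcf, HYBRID, CANDIDATES)
    sharing_tests: dict[str, allele_sharing.SharingTest] = {}
    if partition.informative_sites > 0:
        sharing_tests = {
            c: allele_sharing.half_sharing_test(
                partition, c, confidence=verdict_params.ci_level
            )
            for c in CANDIDATES
        }

    cp_matrix = organelle_distance.cp_pairwise(sim.cp_records)
    maternal = organelle_distance.assign_maternal(
        cp_matrix, HYBRID, CANDIDATES, tie_ratio=verdict_params.tie_ratio
    )

    its_table: ITSAlleleTable | None = None
    if include_its:
        haplotypes = its_alleles.extract_spanning_reads(
            sim.its.reads, sim.its.its_ref, sim.its.region, params=caller_params
        )
        its_table = its_alleles.cluster_alleles(haplotypes, region="ITS")

    aaf_tree: TreeNode | None = None
    if include_aaf:
        profiles = [
            aaf_phylo.build_profile(sim.reads[s], sample=s)
            for s in (REF_SPECIES, NON_PARENT, HYBRID, OUTGROUP)
            if s in sim.reads
        ]
        names, matrix = aaf_phylo.distance_matrix(profiles)
        outgroup = OUTGROUP if OUTGROUP in names else None
        aaf_tree = aaf_phylo.nj_tree(names, matrix, outgroup=outgroup)

    result_verdict = decide(
        report,
        sharing_tests,
        partition,
        maternal,
        its_table=its_table,
        params=verdict_params,
    )
    return PipelineResult(
        sim=sim,
        vcf=vcf,
        summaries=summaries,
        report=report,
        partition=partition,
        sharing_tests=sharing_tests,
        cp_matrix=cp_matrix,
        maternal=maternal,
        its_table=its_table,
        verdict=result_verdict,
        aaf_tree=aaf_tree,
    )
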