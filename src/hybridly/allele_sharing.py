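"""Partition of the hybrid's alleles among candidate parents, plus the
half-sharing test an F1 origin predicts.

Informative sites are those where the hybrid is heterozygous and every
candidate has a called genotype; homozygous hybrid sites carry no phasing
signal.  Sharing is decided on allele *values* (bases), never on VCF allele
indices, so multiallelic records and per-record allele ordering are
irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from .io_formats import VCFData

__all__ = [
    "AllelePartition",
    "SharingTest",
    "partition_alleles",
    "sharing_fractions",
    "half_sharing_test",
]


@dataclass
class AllelePartition:
    """Counts of hybrid allele observations by candidate-subset membership.

    ``region_counts`` maps each subset of candidates (as a frozenset; the
    empty set means private) to the number of hybrid allele observations
    found in exactly that subset.  Conservation: the region counts sum to
    ``2 * informative_sites`` (two observations per diploid site).
    """

    hybrid: str
    candidates: tuple[str, ...]
    region_counts: dict[frozenset[str], int]
    informative_sites: int
    shared_obs: dict[str, int]  # hybrid allele observations present in X
    one_shared_sites: dict[str, int]  # sites with exactly one allele in X
    both_shared_sites: dict[str, int]
    nonref_obs: int  # hybrid non-reference allele observations
    nonref_shared: dict[str, int]  # ... of those, present among X's alleles


@dataclass
class SharingTest:
    """Exact binomial test of the allele-sharing fraction against 0.5.

    Trials are the hybrid's allele observations at informative sites
    (2 per site); successes are observations present in the candidate's
    genotype, so the point estimate is the sharing fraction f.  The
    two-sided p-value uses the minimum-likelihood convention and the CI is
    Clopper-Pearson.
    """

    candidate: str
    n_informative: int
    n_one_allele_shared: int
    n_trials: int
    n_success: int
    point_estimate: float
    p_value: float
    ci_low: float
    ci_high: float

    def ci_covers(self, value: float = 0.5) -> bool:
        return self.ci_low <= value <= self.ci_high


def partition_alleles(
    vcf: VCFData,
    hybrid: str,
    candidates: tuple[str, ...] | list[str],
    min_depth: int = 0,
) -> AllelePartition:
    """Classify each hybrid allele observation by which candidates carry it.

    ``min_depth`` (if > 0) demotes genotypes with a recorded depth below it
    to missing.  Sites where any candidate is missing are skipped entirely:
    absence of evidence is not evidence of non-sharing.  Sites absent from
    the VCF are invariant homozygous-reference for every sample and carry
    no information, so they never enter the partition.
    """
    candidates = tuple(candidates)
    hy_idx = vcf.sample_index(hybrid)
    cand_idx = {c: vcf.sample_index(c) for c in candidates}

    def bases_of(rec, idx: int) -> tuple[str, str] | None:
        if min_depth > 0:
            dp = rec.depths[idx]
            if dp is not None and dp < min_depth:
                return None
        return rec.genotype_bases(idx)

    region_counts: dict[frozenset[str], int] = {}
    shared_obs = {c: 0 for c in candidates}
    one_shared = {c: 0 for c in candidates}
    both_shared = {c: 0 for c in candidates}
    nonref_obs = 0
    nonref_shared = {c: 0 for c in candidates}
    n_informative = 0

    for rec in vcf.records:
        hy = bases_of(rec, hy_idx)
        if hy is None or hy[0] == hy[1]:
            continue
        cand_bases = {c: bases_of(rec, i) for c, i in cand_idx.items()}
        if any(b is None for b in cand_bases.values()):
            continue
        n_informative += 1
        per_cand_shared = {c: 0 for c in candidates}
        for allele in hy:
            subset = frozenset(
                c for c, bases in cand_bases.items() if allele in bases
            )
            region_counts[subset] = region_counts.get(subset, 0) + 1
            for c in subset:
                shared_obs[c] += 1
                per_cand_shared[c] += 1
            if allele != rec.ref_allele:
                nonref_obs += 1
                for c in candidates:
                    if allele in cand_bases[c]:
                        nonref_shared[c] += 1
        for c in candidates:
            if per_cand_shared[c] == 1:
                one_shared[c] += 1
            elif per_cand_shared[c] == 2:
                both_shared[c] += 1

    return AllelePartition(
        hybrid=hybrid,
        candidates=candidates,
        region_counts=region_counts,
        informative_sites=n_informative,
        shared_obs=shared_obs,
        one_shared_sites=one_shared,
        both_shared_sites=both_shared,
        nonref_obs=nonref_obs,
        nonref_shared=nonref_shared,
    )


def sharing_fractions(
    partition: AllelePartition,
) -> tuple[dict[str, float], dict[str, float | None]]:
    """Per-candidate sharing fraction f and alt-sharing fraction g.

    f_X = share of the hybrid's allele observations present in X (0.5
    expected for a true parent whose partner is unsampled); g_X = share of
    the hybrid's non-reference allele observations present in X's genotype
    (near 1 for a sampled second parent, near 0 for a non-parent).  g is
    None when the hybrid carries no non-reference alleles.
    """
    n = partition.informative_sites
    if n < 1:
        raise ValueError(
            "no informative sites (hybrid-heterozygous, all candidates called); "
            "provide more data"
        )
    f = {c: partition.shared_obs[c] / (2 * n) for c in partition.candidates}
    if partition.nonref_obs == 0:
        g: dict[str, float | None] = {c: None for c in partition.candidates}
    else:
        g = {
            c: partition.nonref_shared[c] / partition.nonref_obs
            for c in partition.candidates
        }
    return f, g


def half_sharing_test(
    partition: AllelePartition, candidate: str, confidence: float = 0.95
) -> SharingTest:
    """Exact two-sided binomial test of f_candidate against 0.5.

    Each of the hybrid's ``2 x informative_sites`` allele observations is a
    trial; an observation present in the candidate's genotype is a success.
    """
    if candidate not in partition.candidates:
        raise ValueError(f"{candidate!r} is not a partition candidate")
    n_inf = partition.informative_sites
    if n_inf < 1:
        raise ValueError("no informative sites")
    n_trials = 2 * n_inf
    n_success = partition.shared_obs[candidate]
    result = binomtest(n_success, n_trials, p=0.5)
    ci = result.proportion_ci(confidence_level=confidence, method="exact")
    return SharingTest(
        candidate=candidate,
        n_informative=n_inf,
        n_one_allele_shared=partition.one_shared_sites[candidate],
        n_trials=n_trials,
        n_success=n_success,
        point_estimate=n_success / n_trials,
        p_value=float(result.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )
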