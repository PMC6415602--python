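"""Simulator: determinism, calibrated rates (analytic 3-sigma checks),
truth-set consistency and the diagnostic structure of the synthetic data."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hybridly.io_formats import write_fastq
from hybridly.simulate import (
    HYBRID,
    NON_PARENT,
    OUTGROUP,
    REF_SPECIES,
    ConfigError,
    SimConfig,
    codes_to_str,
    simulate_all,
    simulate_its,
    simulate_organelles,
    simulate_reads,
    simulate_reference,
    simulate_samples,
    str_to_codes,
)


def poisson_3sigma(mean: float) -> tuple[float, float]:
    sd = math.sqrt(mean)
    return mean - 3 * sd, mean + 3 * sd


class TestReference:
    def test_contig_count_and_lengths(self):
        cfg = SimConfig(seed=1, n_contigs=6, contig_length=50_000)
        contigs, _ = simulate_reference(cfg)
        assert len(contigs) == 6
        assert all(len(c) == 50_000 for c in contigs)

    def test_zero_het_rate_homozygous(self):
        cfg = SimConfig(seed=2, het_rate_ref=0.0)
        _, ref_haps = simulate_reference(cfg)
        for h0, h1 in ref_haps:
            assert np.array_equal(h0, h1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_het_sites_within_poisson_3sigma(self, seed):
        # 6 x 50 kb at 2e-4/bp: mean 60 true het sites.
        cfg = SimConfig(seed=seed, n_contigs=6, contig_length=50_000)
        _, ref_haps = simulate_reference(cfg)
        observed = sum(int(np.count_nonzero(h0 != h1)) for h0, h1 in ref_haps)
        low, high = poisson_3sigma(60.0)
        assert low <= observed <= high

    def test_assembly_equals_first_haplotype(self):
        cfg = SimConfig(seed=3)
        contigs, ref_haps = simulate_reference(cfg)
        for contig, (h0, _h1) in zip(contigs, ref_haps):
            assert contig.seq == codes_to_str(h0)


class TestSamples:
    def test_zero_hidden_divergence_degenerates_to_reference(self):
        cfg = SimConfig(seed=4, divergence_hidden_parent=0.0)
        contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, contigs, ref_haps)
        assert truth.het_count(HYBRID) == truth.het_count(REF_SPECIES)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hybrid_het_density_within_3sigma(self, seed):
        cfg = SimConfig(seed=seed)
        contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, contigs, ref_haps)
        total_bp = cfg.n_contigs * cfg.contig_length
        mean = (cfg.divergence_hidden_parent + cfg.het_rate_ref) * total_bp
        low, high = poisson_3sigma(mean)
        assert low <= truth.het_count(HYBRID) <= high

    def test_one_hybrid_allele_equals_reference_base(self):
        # At hybrid het sites driven by hidden-parent divergence, exactly one
        # allele is the reference-haplotype base (construction property).
        cfg = SimConfig(seed=5, het_rate_ref=0.0)
        contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, contigs, ref_haps)
        for ct in truth.sites:
            gt = ct.genotypes[HYBRID]
            het = gt[:, 0] != gt[:, 1]
            matches_ref = (gt[het, 0] == ct.ref_codes[het]).astype(int) + (
                gt[het, 1] == ct.ref_codes[het]
            ).astype(int)
            assert np.all(matches_ref == 1)

    def test_clone_mode_copies_reference_individual(self):
        cfg = SimConfig(seed=6, hybrid_mode="clone")
        contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, contigs, ref_haps)
        for (h0, h1), (r0, r1) in zip(truth.haplotypes[HYBRID], truth.haplotypes[REF_SPECIES]):
            assert np.array_equal(h0, r0) and np.array_equal(h1, r1)

    def test_truthset_consistency(self):
        # Rebuilding each haplotype from the reference plus truth variants
        # reproduces the stored haplotype exactly.
        cfg = SimConfig(seed=7, n_contigs=2, contig_length=5_000)
        contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, contigs, ref_haps)
        for i, contig in enumerate(contigs):
            ref = str_to_codes(contig.seq)
            ct = truth.sites[i]
            for sample, haps in truth.haplotypes.items():
                for hap_idx in (0, 1):
                    rebuilt = ref.copy()
                    rebuilt[ct.positions] = ct.genotypes[sample][:, hap_idx]
                    assert np.array_equal(rebuilt, haps[i][hap_idx])


class TestReads:
    def test_read_count_arithmetic(self):
        cfg = SimConfig(seed=8, n_contigs=1, contig_length=50_000, coverage=20.0)
        sim_contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, sim_contigs, ref_haps)
        reads = simulate_reads(cfg, truth, REF_SPECIES)
        assert len(reads) == 10_000  # 20 * 50000 / 100

    def test_zero_error_reads_match_source(self):
        cfg = SimConfig(seed=9, n_contigs=1, contig_length=2_000, seq_error=0.0, coverage=5.0)
        contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, contigs, ref_haps)
        reads = simulate_reads(cfg, truth, HYBRID)
        haps = truth.haplotypes[HYBRID][0]
        for read in reads:
            # id layout: sample:contig:i:start:strand
            *_, start_s, strand = read.id.split(":")
            start = int(start_s)
            seq = read.seq
            if strand == "-":
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            window = slice(start, start + len(seq))
            assert any(
                codes_to_str(h[window]) == seq for h in haps
            ), f"read {read.id} does not match either source haplotype"

    def test_error_rate_within_3sigma(self):
        rate = 5e-3
        cfg = SimConfig(
            seed=10, n_contigs=1, contig_length=10_000, seq_error=rate, coverage=20.0,
            het_rate_ref=0.0,
        )
        contigs, ref_haps = simulate_reference(cfg)
        truth = simulate_samples(cfg, contigs, ref_haps)
        reads = simulate_reads(cfg, truth, REF_SPECIES)
        ref = ref_haps[0][0]
        mismatches = bases = 0
        for read in reads:
            *_, start_s, strand = read.id.split(":")
            start = int(start_s)
            seq = read.seq
            if strand == "-":
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            codes = str_to_codes(seq)
            mismatches += int(np.count_nonzero(codes != ref[start : start + len(seq)]))
            bases += len(seq)
        assert bases >= 1e5
        mean = bases * rate
        sd = math.sqrt(bases * rate * (1 - rate))
        assert mean - 3 * sd <= mismatches <= mean + 3 * sd

    def test_byte_identical_under_seed(self, tmp_path):
        cfg = SimConfig(seed=12, n_contigs=1, contig_length=3_000)
        paths = []
        for tag in ("a", "b"):
            sim = simulate_all(cfg)
            path = tmp_path / f"{tag}.fastq"
            write_fastq(sim.reads[HYBRID], path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]
        sim2 = simulate_all(SimConfig(seed=13, n_contigs=1, contig_length=3_000))
        other = tmp_path / "c.fastq"
        write_fastq(sim2.reads[HYBRID], other)
        assert other.read_bytes() != paths[0]


class TestOrganelles:
    def test_hybrid_closest_to_maternal(self):
        for seed in range(10):
            records, maternal = simulate_organelles(SimConfig(seed=seed))
            seqs = {r.id: str_to_codes(r.seq) for r in records}
            d_maternal = int(np.count_nonzero(seqs[HYBRID] != seqs[maternal]))
            d_other = int(np.count_nonzero(seqs[HYBRID] != seqs[NON_PARENT]))
            assert d_maternal < d_other

    def test_pairwise_distance_within_3sigma(self):
        cfg = SimConfig(seed=3)
        records, _ = simulate_organelles(cfg)
        seqs = {r.id: str_to_codes(r.seq) for r in records}
        # hybrid vs maternal: private substitutions only
        mean = cfg.cp_private_rate * cfg.cp_length
        low, high = poisson_3sigma(mean)
        d = int(np.count_nonzero(seqs[HYBRID] != seqs[REF_SPECIES]))
        assert low <= d <= high

    def test_zero_rates_identical(self):
        cfg = SimConfig(
            seed=4,
            cp_rates={REF_SPECIES: 0.0, NON_PARENT: 0.0, OUTGROUP: 0.0},
            cp_private_rate=0.0,
        )
        records, _ = simulate_organelles(cfg)
        assert len({r.seq for r in records}) == 1


class TestIts:
    def test_truth_allele_pattern(self):
        # Hybrid shares an allele with the parent species, none with the
        # non-parent (the species-diagnostic pattern).
        its = simulate_its(SimConfig(seed=5))
        hybrid = set(its.truth_alleles[HYBRID])
        assert hybrid & set(its.truth_alleles[REF_SPECIES])
        assert not hybrid & set(its.truth_alleles[NON_PARENT])

    def test_zero_error_single_allele_reads_identical(self):
        cfg = SimConfig(
            seed=6,
            seq_error=0.0,
            its_flank=0,  # reads coincide exactly with the region
            its_read_length=80,
            its_allele_specs=[
                {"sample": REF_SPECIES, "copies": 10, "variants": [(3, 1)]},
                {"sample": HYBRID, "copies": 10, "variants": [(3, 1)]},
            ],
        )
        its = simulate_its(cfg)
        comp = str.maketrans("ACGT", "TGCA")
        for reads in its.reads.values():
            canonical = {min(r.seq, r.seq.translate(comp)[::-1]) for r in reads}
            assert len(canonical) == 1

    def test_support_proportional_to_copies(self):
        # hybrid: two alleles at 15/15 copies -> ~40/40 of 80 reads.
        its = simulate_its(SimConfig(seed=7, seq_error=0.0))
        alleles = its.truth_alleles[HYBRID]
        counts = {a: 0 for a in alleles}
        region = 60, 140
        comp = str.maketrans("ACGT", "TGCA")
        for read in its.reads[HYBRID]:
            for orientation in (read.seq, read.seq.translate(comp)[::-1]):
                for allele in alleles:
                    if allele in orientation:
                        counts[allele] += 1
                        break
                else:
                    continue
                break
        n = len(its.reads[HYBRID])
        p = 0.5
        sd = math.sqrt(n * p * (1 - p))
        for allele in alleles:
            assert n * p - 3 * sd <= counts[allele] <= n * p + 3 * sd
        assert region == its.region

    def test_variant_position_out_of_range_rejected(self):
        with pytest.raises(ConfigError, match="outside region"):
            SimConfig(
                its_allele_specs=[{"sample": HYBRID, "copies": 5, "variants": [(90, 1)]}]
            )


class TestConfig:
    def test_rate_bounds(self):
        with pytest.raises(ConfigError):
            SimConfig(het_rate_ref=0.3)

    def test_read_longer_than_contig(self):
        with pytest.raises(ConfigError):
            SimConfig(contig_length=50, read_length=100)

    def test_unknown_yaml_key(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 3\nbogus_key: 1\n")
        with pytest.raises(ConfigError, match="bogus_key"):
            SimConfig.from_yaml(path)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 42\nn_contigs: 1\ncontig_length: 2000\ncoverage: 5\n")
        cfg = SimConfig.from_yaml(path)
        assert cfg.seed == 42 and cfg.n_contigs == 1 and cfg.coverage == 5
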