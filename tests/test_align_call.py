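"""Mapper and genotype caller: spec'd threshold rules, brute-force mapping
oracle, pileup conservation, scalar/vectorized caller agreement, truth
concordance."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridly.align_call import (
    Alignment,
    CallError,
    CallerParams,
    PileupColumn,
    ReferenceIndex,
    call_all,
    call_genotype,
    call_genotypes_array,
    map_read,
    map_read_bruteforce,
    pileup,
    revcomp,
    sample_pileup_counts,
)
from hybridly.io_formats import ReadRecord, SeqRecord
from hybridly.simulate import (
    HYBRID,
    NON_PARENT,
    REF_SPECIES,
    SimConfig,
    simulate_all,
)


def random_contig(rng, length, name="c1"):
    return SeqRecord(id=name, seq="".join(rng.choice(list("ACGT"), size=length)))


@pytest.fixture(scope="module")
def contig_and_index():
    rng = np.random.default_rng(77)
    contig = random_contig(rng, 1_000)
    return contig, ReferenceIndex([contig], k=31)


class TestMapRead:
    def test_exact_substring(self, contig_and_index):
        contig, index = contig_and_index
        aln = map_read(contig.seq[100:200], index)
        assert aln == Alignment("read", "c1", 100, "+", 0)

    def test_reverse_complement(self, contig_and_index):
        contig, index = contig_and_index
        aln = map_read(revcomp(contig.seq[0:100]), index)
        assert (aln.start, aln.strand, aln.n_mismatch) == (0, "-", 0)

    def test_mismatches_counted(self, contig_and_index):
        contig, index = contig_and_index
        read = list(contig.seq[300:400])
        for pos in (10, 50):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        aln = map_read("".join(read), index)
        assert (aln.start, aln.n_mismatch) == (300, 2)

    def test_ambiguous_duplicate_placement_unmapped(self):
        rng = np.random.default_rng(5)
        block = "".join(rng.choice(list("ACGT"), size=150))
        filler = "".join(rng.choice(list("ACGT"), size=100))
        contig = SeqRecord(id="dup", seq=block + filler + block)
        index = ReferenceIndex([contig], k=31)
        assert map_read(block[10:110], index) is None

    def test_read_shorter_than_seed_unmapped(self, contig_and_index):
        _, index = contig_and_index
        assert map_read("ACGTACGT", index) is None

    def test_too_many_mismatches_unmapped(self, contig_and_index):
        contig, index = contig_and_index
        read = list(contig.seq[500:600])
        for pos in range(0, 31 * 3, 16):  # > max_mismatch scattered mismatches
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        assert map_read("".join(read), index, CallerParams(max_mismatch=2)) is None

    def test_agrees_with_bruteforce(self):
        # Reads with <= 2 planted errors: the tiled-seed guarantee holds, so
        # mapper and exhaustive scan must agree exactly (placement and ties).
        rng = np.random.default_rng(123)
        contigs = [random_contig(rng, 800, "cA"), random_contig(rng, 600, "cB")]
        index = ReferenceIndex(contigs, k=31)
        params = CallerParams()
        for i in range(60):
            src = contigs[i % 2]
            start = int(rng.integers(0, len(src) - 100))
            read = list(src.seq[start : start + 100])
            for pos in rng.choice(100, size=int(rng.integers(0, 3)), replace=False):
                read[pos] = "ACGT"[(("ACGT".index(read[pos])) + 1) % 4]
            seq = "".join(read)
            if rng.integers(0, 2):
                seq = revcomp(seq)
            assert map_read(seq, index, params) == map_read_bruteforce(
                seq, contigs, params
            )


class TestPileup:
    def test_single_error_free_read(self, contig_and_index):
        contig, _ = contig_and_index
        read = ReadRecord(id="r0", seq=contig.seq[50:150], qual="I" * 100)
        aln = Alignment("r0", "c1", 50, "+", 0)
        columns = list(pileup([aln], [read], [contig]))
        assert len(columns) == 100
        for col in columns:
            assert col.depth == 1
            assert col.base_counts == {contig.seq[col.pos]: 1}

    def test_disagreeing_overlap(self):
        contig = SeqRecord(id="c", seq="AAAAACCCCCGGGGGTTTTTAAAAACCCCCGG")
        r1 = ReadRecord(id="r1", seq=contig.seq[0:20], qual="I" * 20)
        seq2 = "T" + contig.seq[11:30]
        r2 = ReadRecord(id="r2", seq=seq2, qual="I" * 20)
        alns = [Alignment("r1", "c", 0, "+", 0), Alignment("r2", "c", 10, "+", 1)]
        columns = {c.pos: c for c in pileup(alns, [r1, r2], [contig])}
        col = columns[10]
        assert col.depth == 2
        assert sorted(col.base_counts.items()) == [("G", 1), ("T", 1)]

    def test_base_conservation(self, contig_and_index):
        contig, index = contig_and_index
        rng = np.random.default_rng(9)
        reads = []
        for i in range(30):
            start = int(rng.integers(0, len(contig) - 100))
            reads.append(ReadRecord(id=f"r{i}", seq=contig.seq[start : start + 100], qual="I" * 100))
        counts, n_mapped = sample_pileup_counts(reads, index)
        assert n_mapped == 30
        assert counts["c1"].sum() == sum(len(r) for r in reads)

    def test_minus_strand_counts_forward_bases(self, contig_and_index):
        contig, index = contig_and_index
        read = ReadRecord(id="r", seq=revcomp(contig.seq[200:300]), qual="I" * 100)
        counts, n_mapped = sample_pileup_counts([read], index)
        assert n_mapped == 1
        region = counts["c1"][:, 200:300]
        assert region.sum() == 100
        for offset in range(100):
            base = "ACGT".index(contig.seq[200 + offset])
            assert region[base, offset] == 1


class TestCallGenotype:
    def test_balanced_het(self):
        col = PileupColumn("c", 0, "A", {"A": 4, "T": 4}, 8)
        assert call_genotype(col) == ("A", "T")

    def test_below_min_depth_missing(self):
        col = PileupColumn("c", 0, "A", {"A": 4, "T": 3}, 7)
        assert call_genotype(col) is None

    def test_hom_ref_with_noise(self):
        col = PileupColumn("c", 0, "G", {"G": 18, "A": 2}, 20)
        assert call_genotype(col) == ("G", "G")

    def test_hom_alt(self):
        col = PileupColumn("c", 0, "A", {"T": 20}, 20)
        assert call_genotype(col) == ("T", "T")

    def test_three_qualifying_alleles_missing(self):
        col = PileupColumn("c", 0, "A", {"A": 5, "C": 5, "G": 5}, 15)
        assert call_genotype(col) is None

    def test_single_qualifying_below_hom_frac_missing(self):
        # depth 8: 6 A / 2 T; T fails min_allele_count, A fails hom_frac.
        col = PileupColumn("c", 0, "A", {"A": 6, "T": 2}, 8)
        assert call_genotype(col) is None

    @settings(max_examples=300, deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=40), min_size=4, max_size=4),
        min_depth=st.integers(min_value=1, max_value=20),
        hom_frac=st.floats(min_value=0.5, max_value=1.0),
    )
    def test_scalar_equals_vectorized(self, counts, min_depth, hom_frac):
        params = CallerParams(min_depth=min_depth, hom_frac=hom_frac)
        mat = np.array(counts, dtype=np.uint32).reshape(4, 1)
        depth = int(mat.sum())
        base_counts = {b: c for b, c in zip("ACGT", counts) if c}
        col = PileupColumn("c", 0, "A", base_counts, depth)
        scalar = call_genotype(col, params)
        g0, g1 = call_genotypes_array(mat, params)
        vector = None if g0[0] < 0 else ("ACGT"[g0[0]], "ACGT"[g1[0]])
        assert scalar == vector


class TestCallAll:
    def test_identical_samples_never_differ(self):
        cfg = SimConfig(seed=20, n_contigs=1, contig_length=3_000, coverage=15.0)
        sim = simulate_all(cfg)
        reads = sim.reads[HYBRID]
        vcf = call_all({"a": reads, "b": list(reads)}, sim.contigs)
        ia, ib = vcf.sample_index("a"), vcf.sample_index("b")
        for rec in vcf.records:
            assert rec.genotypes[ia] == rec.genotypes[ib]

    def test_unmappable_sample_raises_with_name(self):
        cfg = SimConfig(seed=21, n_contigs=1, contig_length=2_000, coverage=5.0)
        sim = simulate_all(cfg)
        rng = np.random.default_rng(1)
        junk = [
            ReadRecord(
                id=f"j{i}", seq="".join(rng.choice(list("ACGT"), size=100)), qual="I" * 100
            )
            for i in range(20)
        ]
        with pytest.raises(CallError, match="junk_sample"):
            call_all({"ok": sim.reads[REF_SPECIES], "junk_sample": junk}, sim.contigs)

    def test_error_free_calls_match_truth(self):
        # With zero sequencing error and deep coverage, every called genotype
        # at a truth site must equal the TruthSet genotype (oracle).
        cfg = SimConfig(
            seed=22, n_contigs=1, contig_length=4_000, coverage=30.0, seq_error=0.0
        )
        sim = simulate_all(cfg)
        vcf = call_all(
            {s: sim.reads[s] for s in (REF_SPECIES, NON_PARENT, HYBRID)}, sim.contigs
        )
        ct = sim.truth.sites[0]
        truth_at = {
            int(pos): {
                s: tuple(sorted(("ACGT"[g[0]], "ACGT"[g[1]])))
                for s, g in ((x, ct.genotypes[x][i]) for x in vcf.samples)
            }
            for i, pos in enumerate(ct.positions)
        }
        checked = 0
        for rec in vcf.records:
            for si, sample in enumerate(vcf.samples):
                bases = rec.genotype_bases(si)
                if bases is None:
                    continue
                expected = truth_at.get(rec.pos - 1, {}).get(
                    sample, (rec.ref_allele, rec.ref_allele)
                )
                assert tuple(sorted(bases)) == expected
                checked += 1
        assert checked > 50

    def test_hybrid_het_recall(self):
        cfg = SimConfig(seed=23, n_contigs=1, contig_length=10_000)
        sim = simulate_all(cfg)
        vcf = call_all(
            {s: sim.reads[s] for s in (REF_SPECIES, NON_PARENT, HYBRID)}, sim.contigs
        )
        hy = vcf.sample_index(HYBRID)
        called_het = {
            rec.pos - 1
            for rec in vcf.records
            if (b := rec.genotype_bases(hy)) is not None and b[0] != b[1]
        }
        truth_het = set(
            int(p) for p in sim.truth.het_positions(HYBRID, sim.contigs[0].id)
        )
        recall = len(called_het & truth_het) / len(truth_het)
        assert recall >= 0.95
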