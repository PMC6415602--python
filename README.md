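# hybridly

Diagnose the F1-hybrid origin of a putative hybrid from sequencing reads (or
a pre-made multi-sample VCF) of the hybrid and candidate parent species:

* **SNP elevation** — per-contig heterozygous-SNP counts, per-10-kb
  densities and hybrid/candidate fold-elevation ratios (an F1 between
  divergent species is heterozygous at every fixed interspecific
  difference, inflating its intragenomic SNP density by an order of
  magnitude or more);
* **allele partition** — a Venn-style partition of the hybrid's alleles at
  its heterozygous sites by presence in each candidate's genotype, with an
  exact binomial test of the F1 half-sharing expectation (Clopper–Pearson
  CI) and an alt-sharing fraction that excludes non-parents;
* **maternal assignment** — pairwise substitution distances over aligned
  organellar sequences; under maternal inheritance the nearest candidate is
  the female parent;
* **ITS alleles** — intragenomic ribosomal spacer haplotypes from
  region-spanning reads, per-sample support, specificity classes and a
  neighbor-joining allele tree;
* **k-mer phylogeny** — assembly- and alignment-free sample tree from
  canonical k-mer containment distances plus neighbor joining;
* **verdict** — all evidence lines integrated into a machine-readable
  parentage decision with a plain-text narrative.

A truth-known simulator generates the full input structure (reference
contigs, per-sample FASTQ, aligned organellar multi-FASTA, ITS tandem-array
reads), so the entire analysis runs end-to-end with no external data.

## CLI

Every stage is a subcommand of `hybridly`; `run-all` chains them on
simulated data:

```bash
# generate a synthetic data set (YAML config optional; see SimConfig)
hybridly simulate --outdir data --seed 1

# map reads and call diploid genotypes into a multi-sample VCF
hybridly call --ref data/ref.fasta \
    --reads ref_species=data/ref_species.fastq \
    --reads non_parent=data/non_parent.fastq \
    --reads hybrid=data/hybrid.fastq \
    --out calls.vcf

# per-contig SNP table + per-window density track
hybridly stats --vcf calls.vcf --ref data/ref.fasta --hybrid hybrid \
    --candidates ref_species,non_parent --out table1.tsv --track fig2.tsv

# allele partition / sharing tests
hybridly share --vcf calls.vcf --hybrid hybrid \
    --candidates ref_species,non_parent --out venn.json

# organellar distances and maternal parent
hybridly cpdist --aln data/cp_aln.fasta --hybrid hybrid \
    --candidates ref_species,non_parent --out cp.json

# ITS spacer alleles (region is 1-based inclusive on the ITS reference)
hybridly its --its-ref data/its_ref.fasta --region ITS1:61-140 \
    --reads ref_species=data/its_ref_species.fastq \
    --reads hybrid=data/its_hybrid.fastq \
    --reads non_parent=data/its_non_parent.fastq \
    --out its_table.tsv --tree its.nwk

# alignment-free k-mer phylogeny
hybridly aaf --reads ref_species=data/ref_species.fastq \
    --reads non_parent=data/non_parent.fastq \
    --reads hybrid=data/hybrid.fastq \
    --reads outgroup=data/outgroup.fastq \
    --outgroup outgroup --out aaf.nwk

# integrate everything
hybridly verdict --stats table1.tsv --share venn.json --cp cp.json \
    --its its_table.tsv --out verdict.json

# or all of the above in one shot on simulated data
hybridly run-all --outdir run1 --seed 1
```

## Notes and conventions

* Internal coordinates are 0-based half-open everywhere; 1-based positions
  appear only in VCF records and CLI region syntax, converted exactly once
  at the I/O boundary.
* "Intra-sample SNP count" means *heterozygous* genotype calls:
  within-individual polymorphism. Homozygous-alternate calls measure
  divergence from the reference assembly and are not intragenomic
  polymorphism. (In the published six-contig table this is the only
  reading consistent with the printed per-species counts, since the
  non-reference species carries hundreds of fixed differences per contig
  but prints only tens of intraspecific SNPs.)
* The published table's reference-species column prints a total of 66
  although its cells sum to 63; the totaling routine reports true column
  sums and never reproduces the printed figure, while the published fold
  ratios (75.8 / 33.8) are defined on the printed totals.
* The genotype caller is threshold-based (depth, allele count, allele
  fraction, homozygosity fraction — all in `CallerParams`), not
  likelihood-based; the mapper is ungapped seed-and-extend with unique-best
  placement and deterministic discarding of ambiguous reads.
* ITS alleles are whole-region haplotypes read off single spanning reads;
  on real short-read data this stage requires merged or long reads.
* The k-mer distance is `-(1/k) ln(|P∩Q| / min(|P|,|Q|))` on canonical
  k-mer sets after a min-count error filter — a transparent containment
  distance, not a reimplementation of any published tool's weighting.
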