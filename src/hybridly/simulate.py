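"""Truth-known synthetic data generator.

Produces the input structure the downstream diagnosis assumes:

* a reference-species individual with low residual heterozygosity whose
  first haplotype *is* the reference assembly,
* a divergent non-parent individual,
* an F1 hybrid carrying one haplotype copied from the reference individual
  and one haplotype from an unsampled, strongly divergent second parent,
* an outgroup individual (used by the k-mer phylogeny),
* maternally inherited organellar sequences (positionally aligned), and
* tandem-array ITS reads carrying species-diagnostic allele variants.

The mutation model is substitution-only, so read mapping stays ungapped and
the organellar "alignment" is positional.  Everything is deterministic under
``SimConfig.seed``: identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .io_formats import ReadRecord, SeqRecord, write_fasta, write_fastq

# Fixed sample names used throughout the pipeline.
REF_SPECIES = "ref_species"
NON_PARENT = "non_parent"
HYBRID = "hybrid"
OUTGROUP = "outgroup"
NUCLEAR_SAMPLES = (REF_SPECIES, NON_PARENT, HYBRID, OUTGROUP)

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i

__all__ = [
    "SimConfig",
    "ConfigError",
    "TruthSet",
    "ContigTruth",
    "ItsSimulation",
    "SimulationOutput",
    "simulate_reference",
    "simulate_samples",
    "simulate_reads",
    "simulate_organelles",
    "simulate_its",
    "simulate_all",
    "write_outputs",
    "default_its_specs",
    "REF_SPECIES",
    "NON_PARENT",
    "HYBRID",
    "OUTGROUP",
]


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    codes = _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        raise ValueError("sequence contains bases outside {A,C,G,T}")
    return codes


def default_its_specs() -> list[dict[str, Any]]:
    """Default ITS allele layout mirroring a diagnostic hybrid pattern.

    The hybrid carries the parent's allele plus a private one; the
    non-parent carries two private alleles one substitution apart; the
    outgroup carries its own distant allele.  Variants are (position,
    shift) pairs: the base at ``position`` is replaced by the reference
    base shifted by 1..3 in A<C<G<T order.
    """
    return [
        {"sample": REF_SPECIES, "copies": 30, "variants": [(10, 1)]},
        {"sample": HYBRID, "copies": 15, "variants": [(10, 1)]},
        {"sample": HYBRID, "copies": 15, "variants": [(30, 2), (50, 1)]},
        {"sample": NON_PARENT, "copies": 20, "variants": [(20, 1), (40, 2), (60, 1)]},
        {
            "sample": NON_PARENT,
            "copies": 10,
            "variants": [(20, 1), (40, 2), (60, 1), (70, 3)],
        },
        {
            "sample": OUTGROUP,
            "copies": 30,
            "variants": [(5, 2), (15, 1), (25, 3), (35, 1), (45, 2)],
        },
    ]


@dataclass
class SimConfig:
    """All knobs of the generator; rates are per-bp substitution rates.

    The heterozygosity and divergence defaults are calibrated so that, per
    10 kb, the reference individual carries ~2 heterozygous sites, the
    non-parent ~5, and the F1 hybrid ~166 — the intragenomic SNP structure
    the diagnosis is designed to detect.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 10_000
    het_rate_ref: float = 2e-4
    het_rate_nonparent: float = 5e-4
    divergence_nonparent: float = 2.8e-3
    divergence_hidden_parent: float = 1.66e-2
    divergence_outgroup: float = 1.0e-2
    # Substitutions shared by the non-parent and outgroup lineages relative
    # to the reference: the internal branch of the unrooted quartet.  If the
    # two diverged fully independently the quartet would be a star no
    # distance method could resolve.
    divergence_shared_stem: float = 1.4e-3
    read_length: int = 100
    coverage: float = 20.0
    seq_error: float = 1e-3
    hybrid_mode: str = "f1"  # "f1" or "clone" (negative control)
    include_outgroup: bool = True
    # Organellar genome.
    cp_length: int = 20_000
    cp_rates: dict[str, float] = field(
        default_factory=lambda: {REF_SPECIES: 1e-3, NON_PARENT: 1.5e-2, OUTGROUP: 3e-2}
    )
    cp_private_rate: float = 5e-4
    maternal_parent: str = REF_SPECIES
    # ITS tandem array.
    its_region_length: int = 80
    its_flank: int = 60
    its_read_length: int = 150
    its_reads_per_sample: int = 80
    its_allele_specs: list[dict[str, Any]] | None = None

    _RATE_FIELDS = (
        "het_rate_ref",
        "het_rate_nonparent",
        "divergence_nonparent",
        "divergence_hidden_parent",
        "divergence_outgroup",
        "divergence_shared_stem",
        "seq_error",
        "cp_private_rate",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._RATE_FIELDS:
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.25:
                raise ConfigError(f"{name}={rate} outside [0, 0.25]")
        for sample, rate in self.cp_rates.items():
            if not 0.0 <= rate <= 0.25:
                raise ConfigError(f"cp_rates[{sample!r}]={rate} outside [0, 0.25]")
        if self.read_length > self.contig_length:
            raise ConfigError("read_length must be <= contig_length")
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ConfigError("need at least one contig of positive length")
        if self.hybrid_mode not in ("f1", "clone"):
            raise ConfigError(f"hybrid_mode must be 'f1' or 'clone', got {self.hybrid_mode!r}")
        if self.its_read_length < self.its_region_length:
            raise ConfigError("its_read_length must be >= its_region_length")
        if self.its_flank > self.its_read_length - self.its_region_length:
            raise ConfigError(
                "its_flank too large: reads could fail to span the region "
                "(need its_flank <= its_read_length - its_region_length)"
            )
        for spec in self.its_allele_specs or default_its_specs():
            for variant in spec["variants"]:
                pos = variant[0]
                if not 0 <= pos < self.its_region_length:
                    raise ConfigError(
                        f"ITS variant position {pos} outside region "
                        f"[0, {self.its_region_length})"
                    )

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(codes.size) < rate
    positions = np.flatnonzero(mask)
    shifts = rng.integers(1, 4, size=positions.size)
    out[positions] = (out[positions] + shifts) % 4
    return out


@dataclass
class ContigTruth:
    """True variant sites of one contig, relative to the reference assembly."""

    contig: str
    positions: np.ndarray  # 0-based
    ref_codes: np.ndarray
    genotypes: dict[str, np.ndarray]  # sample -> (n_sites, 2) base codes


@dataclass
class TruthSet:
    """Everything the simulator knows; the oracle for pipeline tests."""

    contig_names: list[str]
    contig_lengths: dict[str, int]
    haplotypes: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    sites: list[ContigTruth]
    maternal: str
    expected_second_parent_fraction: float = 0.5
    its_alleles: dict[str, list[str]] | None = None

    def het_count(self, sample: str) -> int:
        """Number of truly heterozygous sites for one sample."""
        total = 0
        for truth in self.sites:
            gt = truth.genotypes[sample]
            total += int(np.count_nonzero(gt[:, 0] != gt[:, 1]))
        return total

    def het_positions(self, sample: str, contig: str) -> np.ndarray:
        for truth in self.sites:
            if truth.contig == contig:
                gt = truth.genotypes[sample]
                return truth.positions[gt[:, 0] != gt[:, 1]]
        raise KeyError(contig)

    def to_json_dict(self) -> dict[str, Any]:
        sites = []
        for truth in self.sites:
            sites.append(
                {
                    "contig": truth.contig,
                    "pos_1based": (truth.positions + 1).tolist(),
                    "ref": codes_to_str(truth.ref_codes),
                    "genotypes": {
                        sample: [codes_to_str(pair) for pair in gt]
                        for sample, gt in truth.genotypes.items()
                    },
                }
            )
        return {
            "contig_lengths": self.contig_lengths,
            "maternal": self.maternal,
            "expected_second_parent_fraction": self.expected_second_parent_fraction,
            "het_counts": {s: self.het_count(s) for s in self.haplotypes},
            "haplotypes": {
                sample: [[codes_to_str(h) for h in pair] for pair in haps]
                for sample, haps in self.haplotypes.items()
            },
            "sites": sites,
            "its_alleles": self.its_alleles,
        }


def simulate_reference(
    cfg: SimConfig,
) -> tuple[list[SeqRecord], list[tuple[np.ndarray, np.ndarray]]]:
    """Draw reference contigs plus the reference individual's two haplotypes.

    The assembly equals the individual's first haplotype; the second differs
    at ~``het_rate_ref`` per bp (residual heterozygosity).
    """
    rng = _rng(cfg.seed, 1)
    contigs: list[SeqRecord] = []
    ref_haps: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(cfg.n_contigs):
        hap0 = rng.integers(0, 4, size=cfg.contig_length, dtype=np.uint8)
        hap1 = _mutate(hap0, cfg.het_rate_ref, rng)
        contigs.append(SeqRecord(id=f"contig_{i + 1:02d}", seq=codes_to_str(hap0)))
        ref_haps.append((hap0, hap1))
    return contigs, ref_haps


def simulate_samples(
    cfg: SimConfig,
    contigs: list[SeqRecord],
    ref_haps: list[tuple[np.ndarray, np.ndarray]],
) -> TruthSet:
    """Build all sample haplotypes and derive the true variant table.

    The hybrid's first haplotype is copied verbatim from the reference
    individual's first haplotype (the assembly); its second comes from an
    unsampled parent at ``divergence_hidden_parent``.  In ``clone`` mode the
    hybrid is instead an exact copy of the reference individual (negative
    control).
    """
    rng = _rng(cfg.seed, 2)
    samples = [REF_SPECIES, NON_PARENT, HYBRID]
    if cfg.include_outgroup:
        samples.append(OUTGROUP)
    haplotypes: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        s: [] for s in samples
    }
    stem_rate = min(
        cfg.divergence_shared_stem, cfg.divergence_nonparent, cfg.divergence_outgroup
    )
    for i, _contig in enumerate(contigs):
        ref0, ref1 = ref_haps[i]
        haplotypes[REF_SPECIES].append((ref0.copy(), ref1.copy()))

        stem = _mutate(ref0, stem_rate, rng)
        np_base = _mutate(stem, cfg.divergence_nonparent - stem_rate, rng)
        np_h1 = _mutate(np_base, cfg.het_rate_nonparent, rng)
        haplotypes[NON_PARENT].append((np_base, np_h1))

        # The hidden parent's haplotype descends from the reference
        # individual's second haplotype, so at zero divergence the hybrid
        # degenerates to the reference individual itself.
        if cfg.hybrid_mode == "clone":
            haplotypes[HYBRID].append((ref0.copy(), ref1.copy()))
            # Burn the hidden-parent draw so clone/f1 share all other streams.
            _mutate(ref1, cfg.divergence_hidden_parent, rng)
        else:
            hidden = _mutate(ref1, cfg.divergence_hidden_parent, rng)
            haplotypes[HYBRID].append((ref0.copy(), hidden))

        if cfg.include_outgroup:
            og_base = _mutate(stem, cfg.divergence_outgroup - stem_rate, rng)
            og_h1 = _mutate(og_base, cfg.het_rate_nonparent, rng)
            haplotypes[OUTGROUP].append((og_base, og_h1))

    sites: list[ContigTruth] = []
    for i, contig in enumerate(contigs):
        ref0 = ref_haps[i][0]
        stacked = np.stack(
            [hap for s in samples for hap in haplotypes[s][i]]
        )  # (2 * n_samples, L)
        variant = np.any(stacked != ref0[None, :], axis=0)
        positions = np.flatnonzero(variant)
        genotypes = {
            s: np.stack(
                [haplotypes[s][i][0][positions], haplotypes[s][i][1][positions]],
                axis=1,
            )
            for s in samples
        }
        sites.append(
            ContigTruth(
                contig=contig.id,
                positions=positions,
                ref_codes=ref0[positions],
                genotypes=genotypes,
            )
        )
    return TruthSet(
        contig_names=[c.id for c in contigs],
        contig_lengths={c.id: len(c) for c in contigs},
        haplotypes=haplotypes,
        sites=sites,
        maternal=cfg.maternal_parent,
    )


def _reads_from_haplotypes(
    haps: tuple[np.ndarray, np.ndarray],
    n_reads: int,
    read_length: int,
    seq_error: float,
    rng: np.random.Generator,
    id_prefix: str,
) -> list[ReadRecord]:
    hap_arr = np.stack(haps)
    length = hap_arr.shape[1]
    hap_idx = rng.integers(0, 2, size=n_reads)
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)  # 0 = +, 1 = -
    cols = starts[:, None] + np.arange(read_length)[None, :]
    mat = hap_arr[hap_idx[:, None], cols]
    if seq_error > 0:
        err = rng.random(mat.shape) < seq_error
        shifts = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shifts) % 4
    minus = strands == 1
    mat[minus] = (3 - mat[minus])[:, ::-1]
    qual = "I" * read_length
    sym = np.where(minus, "-", "+")
    ascii_mat = _CODE_TO_BASE[mat]
    return [
        ReadRecord(
            id=f"{id_prefix}:{i}:{starts[i]}:{sym[i]}",
            seq=ascii_mat[i].tobytes().decode("ascii"),
            qual=qual,
        )
        for i in range(n_reads)
    ]


def simulate_reads(cfg: SimConfig, truth: TruthSet, sample: str) -> list[ReadRecord]:
    """Uniform single-end reads from both haplotypes at ``cfg.coverage``.

    Per contig, ``round(coverage * length / read_length)`` reads are drawn;
    substitution errors occur at ``seq_error`` per base and qualities are a
    constant high-quality string.
    """
    if sample not in truth.haplotypes:
        raise KeyError(f"unknown sample {sample!r}")
    rng = _rng(cfg.seed, 3, NUCLEAR_SAMPLES.index(sample))
    reads: list[ReadRecord] = []
    for i, contig in enumerate(truth.contig_names):
        length = truth.contig_lengths[contig]
        n_reads = int(round(cfg.coverage * length / cfg.read_length))
        reads.extend(
            _reads_from_haplotypes(
                truth.haplotypes[sample][i],
                n_reads,
                cfg.read_length,
                cfg.seq_error,
                rng,
                id_prefix=f"{sample}:{contig}",
            )
        )
    return reads


def simulate_organelles(cfg: SimConfig) -> tuple[list[SeqRecord], str]:
    """Positionally aligned organellar sequences with maternal inheritance.

    Each species' sequence derives from a common ancestor at its
    ``cp_rates`` rate; the hybrid copies the maternal parent's sequence and
    adds ``cp_private_rate`` private substitutions.
    """
    maternal = cfg.maternal_parent
    if maternal not in cfg.cp_rates:
        raise ConfigError(f"maternal_parent {maternal!r} has no cp_rates entry")
    rng = _rng(cfg.seed, 4)
    ancestor = rng.integers(0, 4, size=cfg.cp_length, dtype=np.uint8)
    order = [REF_SPECIES, NON_PARENT] + ([OUTGROUP] if cfg.include_outgroup else [])
    seqs: dict[str, np.ndarray] = {}
    for sample in order:
        seqs[sample] = _mutate(ancestor, cfg.cp_rates.get(sample, 0.0), rng)
    seqs[HYBRID] = _mutate(seqs[maternal], cfg.cp_private_rate, rng)
    records = [
        SeqRecord(id=sample, seq=codes_to_str(seqs[sample]))
        for sample in order + [HYBRID]
    ]
    return records, maternal


@dataclass
class ItsSimulation:
    """Reference, region coordinates, reads and true alleles for the ITS stage."""

    its_ref: SeqRecord
    region: tuple[int, int]  # 0-based half-open, on its_ref
    reads: dict[str, list[ReadRecord]]
    truth_alleles: dict[str, list[str]]


def simulate_its(cfg: SimConfig) -> ItsSimulation:
    """Reads from tandem ITS copies; every read spans the spacer region."""
    specs = cfg.its_allele_specs or default_its_specs()
    rng = _rng(cfg.seed, 5)
    flank_l = rng.integers(0, 4, size=cfg.its_flank, dtype=np.uint8)
    region_ref = rng.integers(0, 4, size=cfg.its_region_length, dtype=np.uint8)
    flank_r = rng.integers(0, 4, size=cfg.its_flank, dtype=np.uint8)
    ref_codes = np.concatenate([flank_l, region_ref, flank_r])
    region = (cfg.its_flank, cfg.its_flank + cfg.its_region_length)
    its_ref = SeqRecord(id="its_ref", seq=codes_to_str(ref_codes))

    # Materialize allele sequences per sample.
    alleles: dict[str, list[tuple[str, int]]] = {}
    for spec in specs:
        sample = spec["sample"]
        allele = region_ref.copy()
        for variant in spec["variants"]:
            pos, change = variant[0], variant[1]
            if isinstance(change, str):
                allele[pos] = str_to_codes(change.upper())[0]
            else:
                allele[pos] = (allele[pos] + int(change)) % 4
        alleles.setdefault(sample, []).append((codes_to_str(allele), int(spec["copies"])))

    reads: dict[str, list[ReadRecord]] = {}
    truth_alleles: dict[str, list[str]] = {}
    samples = [s for s in NUCLEAR_SAMPLES if s in alleles]
    samples += [s for s in alleles if s not in samples]
    for sample_index, sample in enumerate(samples):
        entries = alleles[sample]
        truth_alleles[sample] = [seq for seq, _copies in entries]
        copies = np.array([c for _seq, c in entries], dtype=float)
        probs = copies / copies.sum()
        sample_rng = _rng(cfg.seed, 6, sample_index)
        choice = sample_rng.choice(len(entries), size=cfg.its_reads_per_sample, p=probs)
        sample_reads: list[ReadRecord] = []
        for i, allele_idx in enumerate(choice):
            template = np.concatenate(
                [flank_l, str_to_codes(entries[allele_idx][0]), flank_r]
            )
            max_start = template.size - cfg.its_read_length
            start = int(sample_rng.integers(0, max_start + 1))
            mat = template[start : start + cfg.its_read_length].copy()
            if cfg.seq_error > 0:
                err = sample_rng.random(mat.size) < cfg.seq_error
                shifts = sample_rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                mat[err] = (mat[err] + shifts) % 4
            if sample_rng.integers(0, 2) == 1:
                mat = (3 - mat)[::-1]
            sample_reads.append(
                ReadRecord(
                    id=f"its:{sample}:{i}",
                    seq=codes_to_str(mat),
                    qual="I" * cfg.its_read_length,
                )
            )
        reads[sample] = sample_reads
    return ItsSimulation(
        its_ref=its_ref, region=region, reads=reads, truth_alleles=truth_alleles
    )


@dataclass
class SimulationOutput:
    """One full synthetic data set."""

    cfg: SimConfig
    contigs: list[SeqRecord]
    truth: TruthSet
    reads: dict[str, list[ReadRecord]]
    cp_records: list[SeqRecord]
    its: ItsSimulation


def simulate_all(cfg: SimConfig) -> SimulationOutput:
    """Generate the complete data set for one seed."""
    contigs, ref_haps = simulate_reference(cfg)
    truth = simulate_samples(cfg, contigs, ref_haps)
    reads = {
        sample: simulate_reads(cfg, truth, sample) for sample in truth.haplotypes
    }
    cp_records, maternal = simulate_organelles(cfg)
    its = simulate_its(cfg)
    truth.maternal = maternal
    truth.its_alleles = its.truth_alleles
    return SimulationOutput(
        cfg=cfg, contigs=contigs, truth=truth, reads=reads, cp_records=cp_records, its=its
    )


def write_outputs(sim: SimulationOutput, outdir: str | Path) -> None:
    """Emit ref.fasta, per-sample FASTQ, cp_aln.fasta, ITS files and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.contigs, outdir / "ref.fasta")
    for sample, reads in sim.reads.items():
        write_fastq(reads, outdir / f"{sample}.fastq")
    write_fasta(sim.cp_records, outdir / "cp_aln.fasta")
    write_fasta([sim.its.its_ref], outdir / "its_ref.fasta")
    for sample, reads in sim.its.reads.items():
        write_fastq(reads, outdir / f"its_{sample}.fastq")
    truth = sim.truth.to_json_dict()
    truth["its_region_1based"] = [sim.its.region[0] + 1, sim.its.region[1]]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
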