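"""Deterministic synthetic data: genomes, mutation tables, population VCFs
and case/control read sets with panel-neomer spike-ins.

The generator emulates the pipeline's real inputs at desk scale: an i.i.d.
uniform ACGT genome, isolated somatic mutations (each >= k+31 bases from
contig ends and from each other, so per-mutation independence is exact and
the brute-force oracle is unambiguous), gnomAD-style population variants with
jittered per-ancestry allele frequencies, and liquid-biopsy-like read sets in
which case samples carry panel k-mers at a Poisson spike rate over a genomic
background with substitution sequencing errors.

Default scenario: 30 case / 10 control samples per modality, 5000 reads of
150 bp each, k = 15 (the length used for the glioblastoma case study), spike
rate 50 expected panel-k-mer occurrences per case read set.  Every stream of
randomness derives from one integer seed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import kmers
from .errors import ParameterError
from .genome_index import Genome, build_kmer_index
from .germline import (
    POPULATIONS,
    GermlineVariant,
    extract_germline_nullomers,
)
from .panel import apply_confidence_filter, build_panel
from .screen import (
    SampleMeta,
    count_readsets,
    cross_validate,
    panel_features,
    write_labels_tsv,
)
from .somatic import SomaticMutation, extract_neomers, write_neomer_tsv

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# rng stream ids, so artifacts are independently reproducible
_STREAM_GENOME = 0
_STREAM_MUTATIONS = 1
_STREAM_VARIANTS = 2
_STREAM_READS_DNA = 3
_STREAM_READS_RNA = 4

_TUMOR_VOCAB = [("GBM", "Brain"), ("LUAD", "Lung"), ("BRCA", "Breast")]
_STAGES = ["I", "II", "III", "IV"]


@dataclass
class SimulationConfig:
    """The stated world: all generator parameters with their defaults."""

    seed: int = 0
    k: int = 15
    genome_length: int = 20_000
    n_contigs: int = 2
    n_mutations: int = 60
    type_mix: dict[str, float] = field(
        default_factory=lambda: {"SNP": 0.7, "DNP": 0.1, "INS": 0.1, "DEL": 0.1}
    )
    n_tumor_samples: int = 20
    mutation_recurrence: int = 2  # distinct patients carrying each mutation
    n_variants: int = 40
    af_low: float = 0.01
    af_high: float = 0.5
    n_case: int = 30
    n_control: int = 10
    reads_per_sample: int = 5000
    read_length: int = 150
    spike_rate: float = 50.0  # expected panel-k-mer occurrences per case read set
    control_leak_rate: float = 0.0
    error_rate: float = 0.001  # per-base substitution rate
    min_recurrence: int = 2
    min_confidence: float = 0.95
    population: str = "overall"
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ParameterError("type_mix proportions must sum to 1")
        for name in ("genome_length", "n_contigs", "n_case", "n_control",
                     "reads_per_sample", "read_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.spike_rate < 0:
            raise ParameterError("spike_rate must be >= 0")
        if self.read_length < self.k:
            raise ParameterError("read_length must be >= k")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig) -> Genome:
    """i.i.d. uniform ACGT contigs, deterministic under the seed."""
    rng = _rng(config, _STREAM_GENOME)
    per_contig = config.genome_length // config.n_contigs
    contigs = {}
    for i in range(config.n_contigs):
        codes = rng.integers(0, 4, size=per_contig, dtype=np.uint8)
        contigs[f"chr{i + 1}"] = _BASES[codes].tobytes().decode()
    return Genome(contigs, assembly_label=f"sim-seed{config.seed}")


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# somatic mutations + brute-force oracle


def _place_positions(
    genome: Genome, n: int, margin: int, spacing: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Isolated 0-based positions: >= margin from ends, >= spacing apart."""
    names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in names])
    usable = lengths - 2 * margin
    if (usable <= 0).all():
        raise ParameterError("genome too small for the requested placement margin")
    placed: dict[str, list[int]] = {c: [] for c in names}
    out: list[tuple[str, int]] = []
    probs = np.clip(usable, 0, None) / np.clip(usable, 0, None).sum()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ParameterError(
                f"genome too small to place {n} isolated positions "
                f"(spacing {spacing}, margin {margin})"
            )
        ci = rng.choice(len(names), p=probs)
        if usable[ci] <= 0:
            continue
        pos = int(rng.integers(margin, lengths[ci] - margin))
        if all(abs(pos - p) >= spacing for p in placed[names[ci]]):
            placed[names[ci]].append(pos)
            out.append((names[ci], pos))
    return out


def _other_base(base: str, rng: np.random.Generator) -> str:
    i = kmers.BASES.index(base)
    return kmers.BASES[(i + 1 + int(rng.integers(0, 3))) % 4]


def simulate_somatic_mutations(
    genome: Genome, config: SimulationConfig
) -> tuple[list[SomaticMutation], set[tuple[str, str]]]:
    """Isolated mutations with MAF-valid alleles plus the oracle ground truth.

    Each mutation is assigned to ``mutation_recurrence`` distinct tumour
    samples (so a min-recurrence-2 panel is non-empty by construction).  The
    ground truth is the set of (sample_id, k-mer) pairs computed by the
    whole-genome brute-force oracle in canonical mode.
    """
    rng = _rng(config, _STREAM_MUTATIONS)
    k = config.k
    margin = k + 31
    spacing = 2 * (k + 31) + 10
    positions = _place_positions(genome, config.n_mutations, margin, spacing, rng)
    sample_ids = [f"T{i + 1:03d}" for i in range(config.n_tumor_samples)]
    sample_meta = {}
    for sid in sample_ids:
        ct, org = _TUMOR_VOCAB[int(rng.integers(0, len(_TUMOR_VOCAB)))]
        sample_meta[sid] = (ct, org, _STAGES[int(rng.integers(0, len(_STAGES)))])
    types = list(config.type_mix)
    probs = np.array([config.type_mix[t] for t in types], dtype=float)
    mutations: list[SomaticMutation] = []
    truth: set[tuple[str, str]] = set()
    for chrom, pos0 in positions:
        contig = genome.contigs[chrom]
        vtype = types[int(rng.choice(len(types), p=probs))]
        start1 = pos0 + 1
        if vtype == "SNP":
            ref = contig[pos0]
            alt = _other_base(ref, rng)
            end1 = start1
            vclass = "Missense_Mutation"
        elif vtype == "DNP":
            ref = contig[pos0 : pos0 + 2]
            alt = "".join(_other_base(b, rng) for b in ref)
            end1 = start1 + 1
            vclass = "Missense_Mutation"
        elif vtype == "INS":
            length = int(rng.integers(1, 4))
            ref = "-"
            alt = "".join(
                kmers.BASES[int(rng.integers(0, 4))] for _ in range(length)
            )
            end1 = start1 + 1
            vclass = "Frame_Shift_Ins"
        else:  # DEL
            length = int(rng.integers(1, 4))
            ref = contig[pos0 : pos0 + length]
            alt = "-"
            end1 = start1 + length - 1
            vclass = "Frame_Shift_Del"
        carriers = rng.choice(
            len(sample_ids),
            size=min(config.mutation_recurrence, len(sample_ids)),
            replace=False,
        )
        base = SomaticMutation(
            sample_id="",
            chrom=chrom,
            start=start1,
            end=end1,
            ref_allele=ref,
            alt_allele=alt,
            variant_type=vtype,
            variant_class=vclass,
        )
        neo = brute_force_neomers(genome, base, k, canonical=True)
        for ci in sorted(int(c) for c in carriers):
            sid = sample_ids[ci]
            ct, org, stage = sample_meta[sid]
            mutations.append(
                SomaticMutation(
                    sample_id=sid,
                    chrom=chrom,
                    start=start1,
                    end=end1,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_type=vtype,
                    variant_class=vclass,
                    cancer_type=ct,
                    organ=org,
                    stage=stage,
                )
            )
            truth.update((sid, km) for km in neo)
    return mutations, truth


def apply_mutation_to_contig(contig: str, mutation: SomaticMutation) -> str:
    """Apply one edit to a whole contig (independent of the window machinery)."""
    if mutation.variant_type == "INS":
        return contig[: mutation.start] + mutation.alt_allele + contig[mutation.start :]
    alt = "" if mutation.alt_allele == "-" else mutation.alt_allele
    return contig[: mutation.start - 1] + alt + contig[mutation.end :]


def genome_kmer_set(genome: Genome, k: int, canonical: bool) -> set[str]:
    out: set[str] = set()
    for seq in genome.contigs.values():
        out |= kmers.kmer_strings(seq, k, canonical)
    return out


def brute_force_neomers(
    genome: Genome, mutation: SomaticMutation, k: int, canonical: bool = True
) -> set[str]:
    """Oracle: k-mers of the fully mutated genome absent from the reference.

    Enumerates whole-genome k-mer sets by naive sliding windows — no shared
    code with the windowed pipeline beyond the string k-mer helper.
    """
    ref_kmers = genome_kmer_set(genome, k, canonical)
    mutated = dict(genome.contigs)
    mutated[mutation.chrom] = apply_mutation_to_contig(
        genome.contigs[mutation.chrom], mutation
    )
    alt_kmers = genome_kmer_set(Genome(mutated, genome.assembly_label), k, canonical)
    return alt_kmers - ref_kmers


_MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Variant_Classification",
    "Cancer_Type",
    "Organ",
    "Stage",
]


def write_maf(mutations: list[SomaticMutation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#neomerkit simulated MAF\n")
        fh.write("\t".join(_MAF_COLUMNS) + "\n")
        for m in mutations:
            fh.write(
                "\t".join(
                    [
                        m.sample_id,
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        m.ref_allele,
                        m.alt_allele,
                        m.variant_type,
                        m.variant_class,
                        m.cancer_type or "",
                        m.organ or "",
                        m.stage or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# population variants


def simulate_population_variants(
    genome: Genome, config: SimulationConfig
) -> list[GermlineVariant]:
    """gnomAD-style variants: overall AF uniform on [af_low, af_high], per-
    ancestry AFs log-normally jittered around it."""
    rng = _rng(config, _STREAM_VARIANTS)
    k = config.k
    positions = _place_positions(
        genome, config.n_variants, k + 31, 2 * (k + 31) + 10, rng
    )
    variants = []
    for chrom, pos0 in positions:
        contig = genome.contigs[chrom]
        af = float(rng.uniform(config.af_low, config.af_high))
        pops = {
            pop: float(np.clip(af * np.exp(rng.normal(0.0, 0.3)), 0.0, 0.999))
            for pop in POPULATIONS
        }
        kind = rng.random()
        anchor = contig[pos0]
        if kind < 0.8:  # SNV
            ref = contig[pos0]
            alt = _other_base(ref, rng)
            pos1 = pos0 + 1
        elif kind < 0.9:  # insertion (VCF anchor convention)
            ins = "".join(kmers.BASES[int(rng.integers(0, 4))] for _ in range(int(rng.integers(1, 4))))
            ref = anchor
            alt = anchor + ins
            pos1 = pos0 + 1
        else:  # deletion
            length = int(rng.integers(1, 4))
            ref = contig[pos0 : pos0 + 1 + length]
            alt = anchor
            pos1 = pos0 + 1
        variants.append(GermlineVariant(chrom, pos1, ref, alt, af, pops))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def write_vcf(
    variants: list[GermlineVariant], genome: Genome, path: str | Path
) -> None:
    """Valid VCF 4.2 with AF and per-ancestry AF INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=neomerkit-simulate\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n'
        )
        for pop in POPULATIONS:
            fh.write(
                f'##INFO=<ID=AF_{pop.lower()},Number=A,Type=Float,'
                f'Description="Allele frequency in {pop}">\n'
            )
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"AF={v.af_overall:.6f}"
            for pop in POPULATIONS:
                info += f";AF_{pop.lower()}={v.af_by_pop.get(pop, 0.0):.6f}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# read sets

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _contig_codes(genome: Genome) -> list[np.ndarray]:
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(kmers.BASES):
        lut[ord(b)] = i
    return [
        lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        for seq in genome.contigs.values()
    ]


def simulate_readsets(
    genome: Genome,
    panel_kmers: list[str],
    config: SimulationConfig,
    modality: str = "DNA",
) -> tuple[dict[str, list[str]], list[SampleMeta]]:
    """Case/control read sets with panel-k-mer spike-ins.

    Background reads are drawn uniformly from genome positions with per-base
    substitution errors.  Case samples receive Poisson(spike_rate) panel
    k-mer occurrences, each overwriting a random offset of a random read;
    controls receive Poisson(control_leak_rate).  DNA reads land on a random
    strand; RNA reads are sense-strand.  Byte-deterministic under the seed.
    """
    if not panel_kmers and (config.spike_rate > 0 or config.control_leak_rate > 0):
        raise ParameterError("panel must be non-empty when spiking is requested")
    L, k = config.read_length, config.k
    stream = _STREAM_READS_DNA if modality == "DNA" else _STREAM_READS_RNA
    rng = _rng(config, stream)
    contig_codes = _contig_codes(genome)
    starts_avail = np.array([max(len(c) - L + 1, 0) for c in contig_codes])
    if starts_avail.sum() == 0:
        raise ParameterError("read_length exceeds every contig")
    probs = starts_avail / starts_avail.sum()
    panel_codes = [
        np.frombuffer(km.encode(), dtype=np.uint8) for km in panel_kmers
    ]
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(kmers.BASES):
        lut[ord(b)] = i
    panel_codes = [lut[arr] for arr in panel_codes]

    samples = [
        SampleMeta(f"S{i + 1:03d}", "case", modality) for i in range(config.n_case)
    ] + [
        SampleMeta(f"S{config.n_case + i + 1:03d}", "control", modality)
        for i in range(config.n_control)
    ]
    readsets: dict[str, list[str]] = {}
    for meta in samples:
        n = config.reads_per_sample
        which = rng.choice(len(contig_codes), size=n, p=probs)
        out = np.empty((n, L), dtype=np.uint8)
        offs = np.arange(L)
        for ci, codes in enumerate(contig_codes):
            mask = which == ci
            if not mask.any():
                continue
            st = rng.integers(0, starts_avail[ci], size=int(mask.sum()))
            out[mask] = codes[st[:, None] + offs]
        if config.error_rate > 0:
            err = rng.random((n, L)) < config.error_rate
            n_err = int(err.sum())
            if n_err:
                out[err] = (out[err] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
        rate = config.spike_rate if meta.label == "case" else config.control_leak_rate
        n_spikes = int(rng.poisson(rate)) if rate > 0 else 0
        for _ in range(n_spikes):
            row = int(rng.integers(0, n))
            kc = panel_codes[int(rng.integers(0, len(panel_codes)))]
            off = int(rng.integers(0, L - k + 1))
            out[row, off : off + k] = kc
        if modality == "DNA":
            flip = rng.random(n) < 0.5
            out[flip] = 3 - out[flip, ::-1]
        ascii_rows = _ASCII[out]
        readsets[meta.sample_id] = [
            row.tobytes().decode() for row in ascii_rows
        ]
    return readsets, samples


def write_fastq(reads: list[str], sample_id: str, path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{sample_id}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    write_reads: bool = False,
):
    """simulate -> index -> extract -> panel -> count -> classify.

    Returns a dict with the intermediate objects and the CV metrics; when
    ``outdir`` is given, every intermediate artifact is written there in its
    standard text format.
    """
    genome = simulate_genome(config)
    index = build_kmer_index(genome, config.k, canonical=True)
    mutations, truth = simulate_somatic_mutations(genome, config)
    records = extract_neomers(mutations, genome, index, config.k)
    panel = build_panel(records, min_recurrence=config.min_recurrence)
    variants = simulate_population_variants(genome, config)
    germline = extract_germline_nullomers(variants, genome, index, config.k)
    panel = apply_confidence_filter(
        panel, germline, config.min_confidence, config.population
    )
    if not len(panel):
        raise ParameterError("simulated panel is empty; increase n_mutations")
    features = panel_features(panel)
    dna_reads, dna_meta = simulate_readsets(genome, features, config, "DNA")
    rna_reads, rna_meta = simulate_readsets(genome, features, config, "RNA")
    dna_counts = count_readsets(dna_reads, dna_meta, features, config.k, canonical=True)
    rna_counts = count_readsets(rna_reads, rna_meta, features, config.k, canonical=False)
    cv = cross_validate(rna_counts, dna_counts, folds=config.cv_folds, seed=config.seed)
    result = {
        "genome": genome,
        "index": index,
        "mutations": mutations,
        "truth": truth,
        "records": records,
        "panel": panel,
        "variants": variants,
        "germline": germline,
        "rna_counts": rna_counts,
        "dna_counts": dna_counts,
        "cv": cv,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .genome_index import save_index
        from .germline import write_germline_tsv
        from .panel import write_panel

        write_fasta(genome, outdir / "genome.fasta")
        save_index(index, outdir / f"genome.k{config.k}.idx")
        write_maf(mutations, outdir / "mutations.maf")
        write_vcf(variants, genome, outdir / "population.vcf")
        write_neomer_tsv(records, outdir / "neomers.tsv", {"seed": config.seed})
        write_germline_tsv(germline, outdir / "germline.tsv", {"seed": config.seed})
        write_panel(panel, outdir / "panel.tsv", {"seed": config.seed})
        dna_counts.to_tsv(outdir / "counts_dna.tsv", {"seed": config.seed})
        rna_counts.to_tsv(outdir / "counts_rna.tsv", {"seed": config.seed})
        write_labels_tsv(dna_meta + rna_meta, outdir / "labels.tsv")
        cv.to_json(outdir / "metrics.json")
        if write_reads:
            for modality, readsets in (("dna", dna_reads), ("rna", rna_reads)):
                for sid, reads in readsets.items():
                    write_fastq(reads, sid, outdir / f"{modality}_{sid}.fastq")
    return result
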