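"""Somatic mutation parsing, flanking windows and neomer extraction.

For each mutation a window of the edited region plus k+30 bases of flank on
each side is cut from the reference; the same window with the edit applied
gives the mutated sequence.  k-mers present in the mutated window but not the
reference window are candidate neomers; candidates also absent from the
genome-wide index are neomers.  Mutations are treated as independent events —
nearby mutations are never phased onto one haplotype.

MAF coordinates are 1-based inclusive; all internal arithmetic is 0-based
half-open, converted only at the parse/serialize boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import kmers
from .errors import DataIntegrityError, FormatError, ParameterError
from .genome_index import Genome, KmerIndex
from .provenance import read_tsv_with_header, write_tsv_with_header

logger = logging.getLogger(__name__)

FLANK_PAD = 30  # flank length is k + FLANK_PAD on each side

VARIANT_TYPES = ("SNP", "DNP", "TNP", "ONP", "INS", "DEL")

REQUIRED_MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Variant_Classification",
)

_OPTIONAL_MAF_COLUMNS = {
    "Cancer_Type": "cancer_type",
    "Organ": "organ",
    "Stage": "stage",
}


@dataclass
class SomaticMutation:
    """One somatic edit with clinical annotations (1-based inclusive coords)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    variant_class: str = ""
    cancer_type: str | None = None
    organ: str | None = None
    stage: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class SequenceWindow:
    """Reference and mutated flanking windows around one edit."""

    chrom: str
    window_start: int  # 1-based inclusive
    window_end: int
    ref_seq: str
    alt_seq: str
    edit_offset: int  # 0-based offset of the replaced span within ref_seq
    edit_ref_len: int
    edit_alt_len: int


@dataclass
class NeomerRecord:
    """A k-mer absent from the reference genome, created by one mutation."""

    kmer: str
    k: int
    sample_id: str
    chrom: str
    start: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    variant_class: str = ""
    cancer_type: str | None = None
    organ: str | None = None
    stage: str | None = None
    duplicate: bool = False  # same (sample, kmer) already emitted by another mutation


def read_maf(path: str | Path) -> list[SomaticMutation]:
    """Parse a MAF-dialect TSV into mutations, preserving row order.

    Rows with unparseable positions or unknown variant types are skipped and
    counted in the log; a missing required column is a format error naming it.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    for col in REQUIRED_MAF_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"MAF {path} is missing required column {col!r}")
    extra_cols = [
        c
        for c in df.columns
        if c not in REQUIRED_MAF_COLUMNS and c not in _OPTIONAL_MAF_COLUMNS
    ]
    mutations: list[SomaticMutation] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            start = int(rec["Start_Position"])
            end = int(rec["End_Position"])
        except ValueError:
            logger.warning("MAF row %d: non-integer position, skipped", i + 1)
            skipped += 1
            continue
        vtype = rec["Variant_Type"].upper()
        if vtype not in VARIANT_TYPES:
            logger.warning("MAF row %d: unknown Variant_Type %r, skipped", i + 1, vtype)
            skipped += 1
            continue
        mutations.append(
            SomaticMutation(
                sample_id=rec["Tumor_Sample_Barcode"],
                chrom=rec["Chromosome"],
                start=start,
                end=end,
                ref_allele=rec["Reference_Allele"].upper(),
                alt_allele=rec["Tumor_Seq_Allele2"].upper(),
                variant_type=vtype,
                variant_class=rec["Variant_Classification"],
                cancer_type=rec.get("Cancer_Type") or None,
                organ=rec.get("Organ") or None,
                stage=rec.get("Stage") or None,
                extra={c: rec[c] for c in extra_cols},
            )
        )
    if skipped:
        logger.warning("read_maf: skipped %d malformed rows", skipped)
    return mutations


def build_windows(genome: Genome, mutation: SomaticMutation, k: int) -> SequenceWindow:
    """Cut the k+30-flank reference window and apply the edit.

    The reference allele is verified against the genome; a mismatch indicates
    a MAF/assembly mix-up and raises :class:`DataIntegrityError`.
    """
    contig = genome.contigs.get(mutation.chrom)
    if contig is None:
        raise DataIntegrityError(f"unknown contig {mutation.chrom!r}")
    flank = k + FLANK_PAD
    if mutation.variant_type == "INS":
        if mutation.ref_allele != "-":
            raise DataIntegrityError(
                f"{mutation.chrom}:{mutation.start}: INS must have Reference_Allele '-'"
            )
        if mutation.end != mutation.start + 1:
            raise DataIntegrityError(
                f"{mutation.chrom}:{mutation.start}: INS requires End = Start + 1"
            )
        span_lo, span_hi = mutation.start, mutation.start  # 0-based empty span
        ref_part = ""
    else:
        span_lo, span_hi = mutation.start - 1, mutation.end
        if span_lo < 0 or span_hi > len(contig):
            raise DataIntegrityError(
                f"{mutation.chrom}:{mutation.start}-{mutation.end} outside contig"
            )
        ref_part = contig[span_lo:span_hi]
        expected = mutation.ref_allele
        if mutation.variant_type == "DEL" and mutation.alt_allele != "-":
            raise DataIntegrityError(
                f"{mutation.chrom}:{mutation.start}: DEL must have Tumor_Seq_Allele2 '-'"
            )
        if ref_part != expected:
            raise DataIntegrityError(
                f"ref allele mismatch at {mutation.chrom}:{mutation.start}: "
                f"expected {expected!r}, genome has {ref_part!r}"
            )
    alt_part = "" if mutation.alt_allele == "-" else mutation.alt_allele
    ws = max(0, span_lo - flank)
    we = min(len(contig), span_hi + flank)
    ref_seq = contig[ws:we]
    off = span_lo - ws
    alt_seq = ref_seq[:off] + alt_part + ref_seq[off + len(ref_part):]
    return SequenceWindow(
        chrom=mutation.chrom,
        window_start=ws + 1,
        window_end=we,
        ref_seq=ref_seq,
        alt_seq=alt_seq,
        edit_offset=off,
        edit_ref_len=len(ref_part),
        edit_alt_len=len(alt_part),
    )


def candidate_kmers(window: SequenceWindow, k: int, canonical: bool = True) -> set[str]:
    """k-mers of the mutated window absent from the reference window.

    In canonical mode both k-mer sets are canonicalized before differencing,
    so the returned strings are canonical representatives.
    """
    ref = kmers.kmer_strings(window.ref_seq, k, canonical)
    alt = kmers.kmer_strings(window.alt_seq, k, canonical)
    return alt - ref


def extract_neomers(
    mutations: list[SomaticMutation],
    window_genome: Genome,
    index: KmerIndex,
    k: int,
    skip_mismatch: bool = False,
) -> list[NeomerRecord]:
    """Window, difference and membership-check each mutation independently.

    Candidates absent from the index become :class:`NeomerRecord`s carrying
    the mutation's sample and clinical metadata.  A (sample_id, kmer) pair
    produced again by a different mutation is retained but flagged
    ``duplicate``.  Output order is deterministic: mutation order, then
    lexicographic k-mer order within a mutation.
    """
    if index.k != k:
        raise ParameterError(f"index k={index.k} does not match requested k={k}")
    records: list[NeomerRecord] = []
    seen: set[tuple[str, str]] = set()
    n_skipped = 0
    for mut in mutations:
        try:
            window = build_windows(window_genome, mut, k)
        except DataIntegrityError:
            if skip_mismatch:
                n_skipped += 1
                logger.warning(
                    "skipping mutation %s:%s (%s)", mut.chrom, mut.start, mut.sample_id
                )
                continue
            raise
        if len(window.alt_seq) < k and len(window.ref_seq) < k:
            logger.warning(
                "window at %s:%s shorter than k=%d, skipped", mut.chrom, mut.start, k
            )
            n_skipped += 1
            continue
        cands = sorted(candidate_kmers(window, k, index.canonical))
        if not cands:
            continue
        absent = ~index.contains_many(cands)
        for kmer, is_absent in zip(cands, absent):
            if not is_absent:
                continue
            key = (mut.sample_id, kmer)
            records.append(
                NeomerRecord(
                    kmer=kmer,
                    k=k,
                    sample_id=mut.sample_id,
                    chrom=mut.chrom,
                    start=mut.start,
                    ref_allele=mut.ref_allele,
                    alt_allele=mut.alt_allele,
                    variant_type=mut.variant_type,
                    variant_class=mut.variant_class,
                    cancer_type=mut.cancer_type,
                    organ=mut.organ,
                    stage=mut.stage,
                    duplicate=key in seen,
                )
            )
            seen.add(key)
    if n_skipped:
        logger.warning("extract_neomers: skipped %d mutations", n_skipped)
    return records


_NEOMER_COLUMNS = [
    "kmer",
    "k",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_type",
    "variant_class",
    "cancer_type",
    "organ",
    "stage",
    "duplicate",
]


def write_neomer_tsv(
    records: list[NeomerRecord], path: str | Path, provenance: dict | None = None
) -> None:
    rows = [
        {
            "kmer": r.kmer,
            "k": r.k,
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.start,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "variant_type": r.variant_type,
            "variant_class": r.variant_class,
            "cancer_type": r.cancer_type or "",
            "organ": r.organ or "",
            "stage": r.stage or "",
            "duplicate": int(r.duplicate),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_NEOMER_COLUMNS)
    write_tsv_with_header(df, path, provenance or {})


def read_neomer_tsv(path: str | Path) -> list[NeomerRecord]:
    df, _ = read_tsv_with_header(path, dtype=str)
    records = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        records.append(
            NeomerRecord(
                kmer=rec["kmer"],
                k=int(rec["k"]),
                sample_id=rec["sample_id"],
                chrom=rec["chrom"],
                start=int(rec["pos"]),
                ref_allele=rec["ref"],
                alt_allele=rec["alt"],
                variant_type=rec["variant_type"],
                variant_class=rec["variant_class"],
                cancer_type=rec["cancer_type"] or None,
                organ=rec["organ"] or None,
                stage=rec["stage"] or None,
                duplicate=bool(int(rec.get("duplicate", "0") or 0)),
            )
        )
    return records
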