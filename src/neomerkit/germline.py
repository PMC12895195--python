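"""Nullomers creatable by common germline variants, with probability model.

Population variants (gnomAD-style VCF with overall and per-ancestry allele
frequencies) are filtered to "common" (any AF strictly above a threshold,
default 5%), run through the same windowing/set-difference machinery as
somatic mutations, and grouped by k-mer.  For each k-mer the composite
probability that it does NOT arise from germline variation is

    p_not_germline = prod over contributing variants of (1 - AF)

computed separately for the overall cohort and each ancestry under the
assumption that germline variants occur independently.  Products are
accumulated as sums of log1p(-AF) to avoid underflow with many contributors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import FormatError, ParameterError
from .genome_index import Genome, KmerIndex
from .provenance import read_tsv_with_header, write_tsv_with_header
from .somatic import SomaticMutation, build_windows, candidate_kmers

logger = logging.getLogger(__name__)

#: gnomAD ancestry codes carried through the whole pipeline.
POPULATIONS = ("EAS", "AFR", "FIN", "AMI", "AMR", "NFE", "SAS", "ASJ")

DEFAULT_AF_MIN = 0.05


@dataclass
class GermlineVariant:
    """One population variant with overall and per-ancestry allele frequency."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    af_overall: float
    af_by_pop: dict[str, float] = field(default_factory=dict)

    def af(self, population: str) -> float:
        if population == "overall":
            return self.af_overall
        return self.af_by_pop.get(population, 0.0)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class GermlineNullomerRecord:
    """A genome-absent k-mer creatable by >=1 common germline variants."""

    kmer: str
    contributing_variants: list[GermlineVariant]
    p_not_germline_overall: float
    p_not_germline_by_pop: dict[str, float]


def is_common(variant: GermlineVariant, af_min: float = DEFAULT_AF_MIN) -> bool:
    """Retention rule: any AF (overall or per-population) strictly above af_min."""
    top = max([variant.af_overall, *variant.af_by_pop.values()])
    return top > af_min


def _alt_af(value, allele_index: int) -> float | None:
    """Pull the per-ALT allele frequency out of a cyvcf2 INFO value."""
    if value is None:
        return None
    if isinstance(value, (tuple, list, np.ndarray)):
        if allele_index >= len(value):
            return None
        value = value[allele_index]
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(v):
        return None
    # cyvcf2 stores INFO floats as float32; round off the representation noise
    # so thresholds like "strictly > 0.05" behave as written in the VCF
    return float(f"{v:.6g}")


def read_population_vcf(
    path: str | Path, af_min: float = DEFAULT_AF_MIN
) -> list[GermlineVariant]:
    """Read a VCF with AF / AF_<pop> INFO fields, keeping common variants.

    Multi-allelic rows are split into one variant per ALT with allele-matched
    frequencies.  A retained-looking row missing its AF key is logged and
    skipped; missing per-population AFs count as 0 (with a warning total).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"malformed VCF {path}: {exc}") from exc
    variants: list[GermlineVariant] = []
    n_missing_af = 0
    n_missing_pop = 0
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT or []):
            if not alt or any(c not in "ACGT" for c in alt.upper()):
                continue  # symbolic / spanning-deletion alleles
            af = _alt_af(rec.INFO.get("AF"), ai)
            if af is None:
                n_missing_af += 1
                logger.warning("%s:%s missing AF INFO, row skipped", rec.CHROM, rec.POS)
                continue
            pops: dict[str, float] = {}
            for pop in POPULATIONS:
                raw = rec.INFO.get(f"AF_{pop.lower()}")
                if raw is None:
                    raw = rec.INFO.get(f"AF_{pop}")
                v = _alt_af(raw, ai)
                if v is None:
                    n_missing_pop += 1
                    v = 0.0
                pops[pop] = v
            variant = GermlineVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF.upper(),
                alt=alt.upper(),
                af_overall=af,
                af_by_pop=pops,
            )
            if is_common(variant, af_min):
                variants.append(variant)
    if n_missing_pop:
        logger.warning(
            "read_population_vcf: %d missing per-population AFs treated as 0",
            n_missing_pop,
        )
    return variants


def variant_to_mutation(variant: GermlineVariant) -> SomaticMutation:
    """Normalize a VCF allele pair into the somatic edit representation.

    Shared leading bases are stripped (VCF indels carry an anchor base), so
    the somatic windowing machinery applies unchanged.
    """
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if ref and alt:
        if len(ref) != len(alt):
            # unbalanced substitution: treat as delete-then-insert is out of
            # scope; represent as ONP only when lengths match
            raise ParameterError(
                f"{variant.label}: unbalanced substitution not supported"
            )
        vtype = {1: "SNP", 2: "DNP", 3: "TNP"}.get(len(ref), "ONP")
        return SomaticMutation(
            sample_id="germline",
            chrom=variant.chrom,
            start=pos,
            end=pos + len(ref) - 1,
            ref_allele=ref,
            alt_allele=alt,
            variant_type=vtype,
        )
    if not alt:  # deletion
        return SomaticMutation(
            sample_id="germline",
            chrom=variant.chrom,
            start=pos,
            end=pos + len(ref) - 1,
            ref_allele=ref,
            alt_allele="-",
            variant_type="DEL",
        )
    # insertion between pos-1 and pos
    return SomaticMutation(
        sample_id="germline",
        chrom=variant.chrom,
        start=pos - 1,
        end=pos,
        ref_allele="-",
        alt_allele=alt,
        variant_type="INS",
    )


def not_germline_probability(afs) -> float:
    """prod(1 - AF) via a log1p sum; an AF of 1 forces the product to 0."""
    arr = np.asarray(list(afs), dtype=float)
    if arr.size == 0:
        return 1.0
    if np.any((arr < 0) | (arr > 1)):
        raise ParameterError("allele frequencies must lie in [0, 1]")
    if np.any(arr >= 1.0):
        return 0.0
    return float(np.exp(np.log1p(-arr).sum()))


def composite_probabilities(
    variants: list[GermlineVariant],
) -> tuple[float, dict[str, float]]:
    overall = not_germline_probability(v.af_overall for v in variants)
    by_pop = {
        pop: not_germline_probability(v.af_by_pop.get(pop, 0.0) for v in variants)
        for pop in POPULATIONS
    }
    return overall, by_pop


def extract_germline_nullomers(
    variants: list[GermlineVariant],
    genome: Genome,
    index: KmerIndex,
    k: int,
    skip_mismatch: bool = False,
) -> list[GermlineNullomerRecord]:
    """Per-variant windowed set difference, grouped by k-mer with probabilities.

    Reuses the somatic windowing/candidate machinery; each variant is an
    independent event.  Records are sorted by k-mer for determinism.
    """
    if index.k != k:
        raise ParameterError(f"index k={index.k} does not match requested k={k}")
    by_kmer: dict[str, list[GermlineVariant]] = {}
    for variant in variants:
        mut = variant_to_mutation(variant)
        try:
            window = build_windows(genome, mut, k)
        except Exception:
            if skip_mismatch:
                logger.warning("skipping germline variant %s", variant.label)
                continue
            raise
        cands = sorted(candidate_kmers(window, k, index.canonical))
        if not cands:
            continue
        absent = ~index.contains_many(cands)
        for kmer, is_absent in zip(cands, absent):
            if is_absent:
                by_kmer.setdefault(kmer, []).append(variant)
    records = []
    for kmer in sorted(by_kmer):
        contributors = by_kmer[kmer]
        overall, by_pop = composite_probabilities(contributors)
        records.append(
            GermlineNullomerRecord(kmer, contributors, overall, by_pop)
        )
    return records


def flag_common_associated(
    panel_kmers, germline_records: list[GermlineNullomerRecord]
) -> dict[str, bool]:
    """Flag k-mers with any nonzero germline emergence probability.

    A k-mer is "associated with a common variant" iff it appears in the
    germline records with a composite not-from-germline probability < 1 in the
    overall cohort or any ancestry.
    """
    by_kmer = {r.kmer: r for r in germline_records}
    flags = {}
    for kmer in panel_kmers:
        rec = by_kmer.get(kmer)
        flags[kmer] = bool(
            rec is not None
            and (
                rec.p_not_germline_overall < 1.0
                or any(p < 1.0 for p in rec.p_not_germline_by_pop.values())
            )
        )
    return flags


def write_germline_tsv(
    records: list[GermlineNullomerRecord], path: str | Path, provenance: dict | None = None
) -> None:
    rows = []
    for r in records:
        row = {
            "kmer": r.kmer,
            "n_variants": len(r.contributing_variants),
            "p_not_germline_overall": repr(r.p_not_germline_overall),
        }
        for pop in POPULATIONS:
            row[f"p_not_germline_{pop}"] = repr(r.p_not_germline_by_pop.get(pop, 1.0))
        row["variants"] = ";".join(v.label for v in r.contributing_variants)
        rows.append(row)
    cols = (
        ["kmer", "n_variants", "p_not_germline_overall"]
        + [f"p_not_germline_{p}" for p in POPULATIONS]
        + ["variants"]
    )
    write_tsv_with_header(pd.DataFrame(rows, columns=cols), path, provenance or {})


def read_germline_tsv(path: str | Path) -> list[GermlineNullomerRecord]:
    """Read records back; contributing variants are restored as labels only
    (chrom:pos:ref>alt), sufficient for panel confidence filtering."""
    df, _ = read_tsv_with_header(path, dtype=str)
    records = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        contributors = []
        for label in (rec.get("variants") or "").split(";"):
            if not label:
                continue
            chrom, pos, alleles = label.split(":")
            ref, alt = alleles.split(">")
            contributors.append(GermlineVariant(chrom, int(pos), ref, alt, 0.0))
        records.append(
            GermlineNullomerRecord(
                kmer=rec["kmer"],
                contributing_variants=contributors,
                p_not_germline_overall=float(rec["p_not_germline_overall"]),
                p_not_germline_by_pop={
                    pop: float(rec[f"p_not_germline_{pop}"]) for pop in POPULATIONS
                },
            )
        )
    return records
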