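"""Reference genomes and k-mer presence indexes.

A :class:`KmerIndex` answers "does this k-mer occur anywhere in the genome?",
the membership question that decides whether a candidate k-mer is a nullomer.
Internally it is a sorted array of packed 2-bit codes queried by binary
search; in canonical mode a k-mer and its reverse complement share one code,
so presence on either strand counts as present.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from . import kmers
from .errors import FeasibilityError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Largest k for which full 4^k nullomer enumeration is allowed by default.
DEFAULT_ENUMERATION_GUARD = 14

# Uppercase is applied first; any letter outside ACGTN (IUPAC ambiguity
# codes etc.) then maps to N.
_NORMALIZE = str.maketrans(
    {c: "N" for c in "BDEFHIJKLMOPQRSUVWXYZ"}
)


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse non-ACGTN letters to N."""
    return seq.upper().translate(_NORMALIZE)


@dataclass
class Genome:
    """An in-memory reference genome: ordered contigs of normalized sequence."""

    contigs: dict[str, str]
    assembly_label: str = ""

    def __post_init__(self) -> None:
        for name in self.contigs:
            if not name:
                raise FormatError("empty contig name")

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def load_fasta(path: str | Path, assembly_label: str | None = None) -> Genome:
    """Load a (plain or gzipped) FASTA file into a :class:`Genome`.

    Sequences are uppercased and non-ACGTN letters become N; contig order is
    preserved.  A sequence line appearing before any header is reported with
    its line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_leading_sequence(path)
    contigs: dict[str, str] = {}
    try:
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                if rec.name in contigs:
                    raise FormatError(f"duplicate contig name {rec.name!r} in {path}")
                contigs[rec.name] = normalize_sequence(rec.sequence or "")
    except OSError as exc:  # pysam wraps malformed input in OSError/ValueError
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(contigs, assembly_label or path.name)


def _check_leading_sequence(path: Path) -> None:
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: sequence before first FASTA header at line {lineno}"
                )
            return


@dataclass
class KmerIndex:
    """Membership structure over all k-mers occurring in a genome."""

    k: int
    canonical: bool
    codes: np.ndarray  # sorted unique uint64 codes
    source_label: str = ""

    @property
    def mode(self) -> str:
        return "canonical" if self.canonical else "forward"

    @property
    def n_present(self) -> int:
        return int(len(self.codes))

    def contains_codes(self, query: np.ndarray) -> np.ndarray:
        """Vectorized membership for already-canonicalized packed codes."""
        query = np.asarray(query, dtype=np.uint64)
        if self.canonical:
            query = kmers.canonical_codes(query, self.k)
        pos = np.searchsorted(self.codes, query)
        inb = pos < len(self.codes)
        hit = np.zeros(len(query), dtype=bool)
        hit[inb] = self.codes[pos[inb]] == query[inb]
        return hit

    def contains(self, kmer: str) -> bool:
        """True iff ``kmer`` (or its reverse complement, in canonical mode)
        occurs in the source genome."""
        code = kmers.encode_kmer(kmer, self.k)
        return bool(self.contains_codes(np.array([code], dtype=np.uint64))[0])

    def contains_many(self, kmer_list) -> np.ndarray:
        kmer_list = list(kmer_list)
        if not kmer_list:
            return np.empty(0, dtype=bool)
        return self.contains_codes(kmers.encode_kmers(kmer_list, self.k))


def build_kmer_index(genome: Genome, k: int, canonical: bool = True) -> KmerIndex:
    """Index every k-mer occurring in ``genome`` (windows spanning N skipped)."""
    k = kmers.validate_k(k)
    if not genome.contigs or len(genome) == 0:
        raise ParameterError("cannot index an empty genome")
    parts = []
    for seq in genome.contigs.values():
        codes, valid = kmers.kmer_codes(seq, k)
        parts.append(codes[valid])
    allcodes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    if canonical and len(allcodes):
        allcodes = kmers.canonical_codes(allcodes, k)
    return KmerIndex(k, canonical, np.unique(allcodes), genome.assembly_label)


@dataclass
class NullomerSet:
    """k-mers absent from an indexed genome.

    In canonical mode ``codes`` holds one representative per canonical class
    (the representative is the smaller of code and reverse-complement code).
    """

    k: int
    mode: str
    codes: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return int(len(self.codes))

    @property
    def kmers(self) -> set[str]:
        """Materialize the absent k-mers as strings (memory: O(|set|))."""
        return {kmers.decode_kmer(int(c), self.k) for c in self.codes}


def enumerate_nullomers(
    index: KmerIndex,
    guard: int = DEFAULT_ENUMERATION_GUARD,
    force: bool = False,
    chunk: int = 1 << 22,
) -> NullomerSet:
    """Enumerate every k-mer absent from the index.

    Walks the 4^k space in chunks; refuses k above ``guard`` unless ``force``
    is set, since the space grows fourfold per base.
    """
    k = index.k
    if k > guard and not force:
        raise FeasibilityError(
            f"enumerating 4^{k} k-mers exceeds the guard (k <= {guard}); "
            "pass force=True / --force to override"
        )
    total = 1 << (2 * k)
    absent_parts = []
    for lo in range(0, total, chunk):
        codes = np.arange(lo, min(lo + chunk, total), dtype=np.uint64)
        if index.canonical:
            rc = kmers.revcomp_codes(codes, k)
            codes = codes[codes <= rc]  # one representative per class
            if not len(codes):
                continue
        pos = np.searchsorted(index.codes, codes)
        inb = pos < len(index.codes)
        present = np.zeros(len(codes), dtype=bool)
        present[inb] = index.codes[pos[inb]] == codes[inb]
        absent_parts.append(codes[~present])
    codes = (
        np.concatenate(absent_parts) if absent_parts else np.empty(0, dtype=np.uint64)
    )
    return NullomerSet(k, index.mode, codes)


_INDEX_MAGIC = "#neomerkit-index\tv1"


def save_index(index: KmerIndex, path: str | Path) -> None:
    """Serialize an index as sorted decimal codes with a '#' header."""
    digest = hashlib.sha256(index.codes.tobytes()).hexdigest()
    with open(path, "w") as fh:
        fh.write(f"{_INDEX_MAGIC}\n")
        fh.write(f"#k={index.k}\n")
        fh.write(f"#mode={index.mode}\n")
        fh.write(f"#source={index.source_label}\n")
        fh.write(f"#n={index.n_present}\n")
        fh.write(f"#sha256={digest}\n")
        for code in index.codes:
            fh.write(f"{int(code)}\n")


def load_index(path: str | Path) -> KmerIndex:
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _INDEX_MAGIC:
            raise FormatError(f"{path}: not a neomerkit index file")
        meta = {}
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, val = line[1:].rstrip("\n").partition("=")
            meta[key] = val
        fh.seek(pos)
        codes = np.loadtxt(fh, dtype=np.uint64, ndmin=1) if meta.get("n") != "0" else np.empty(0, dtype=np.uint64)
    index = KmerIndex(int(meta["k"]), meta["mode"] == "canonical", codes, meta.get("source", ""))
    digest = hashlib.sha256(index.codes.tobytes()).hexdigest()
    if meta.get("sha256") and meta["sha256"] != digest:
        raise FormatError(f"{path}: index checksum mismatch")
    return index
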