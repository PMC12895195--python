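"""2-bit k-mer codec shared by the index, the extractors and the read counter.

k-mers over {A,C,G,T} are packed into ``uint64`` codes (A=0, C=1, G=2, T=3,
most significant bits = leftmost base), which supports k up to 32.  Any other
character (including N) invalidates every window that overlaps it.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

BASES = "ACGT"
K_MIN, K_MAX = 4, 32

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def validate_k(k: int) -> int:
    if not K_MIN <= int(k) <= K_MAX:
        raise ParameterError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")
    return int(k)


def encode_kmer(kmer: str, k: int) -> int:
    """Pack one k-mer string into its integer code."""
    if len(kmer) != k:
        raise ParameterError(f"expected a {k}-mer, got {len(kmer)} bases: {kmer!r}")
    code = 0
    for ch in kmer:
        b = _CODE[ord(ch)]
        if b == 255:
            raise ParameterError(f"invalid base {ch!r} in k-mer {kmer!r}")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(BASES[(int(code) >> shift) & 3])
    return "".join(out)


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes for every length-k window of ``seq``.

    Returns ``(codes, valid)`` where ``valid[i]`` is False when the window
    starting at i contains any non-ACGT character.  Both arrays have length
    ``max(len(seq) - k + 1, 0)``.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(raw) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    t = _CODE[raw]
    bad = t == 255
    tt = np.where(bad, 0, t).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | tt[j : j + n]
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed codes."""
    mask = np.uint64((1 << (2 * k)) - 1)
    c = (~codes.astype(np.uint64)) & mask
    r = np.zeros_like(c)
    two = np.uint64(2)
    three = np.uint64(3)
    for _ in range(k):
        r = (r << two) | (c & three)
        c = c >> two
    return r


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(codes, revcomp_codes(codes, k))


def encode_kmers(kmers, k: int, canonicalize: bool = False) -> np.ndarray:
    """Pack a sequence of k-mer strings; optionally canonicalize the codes."""
    codes = np.fromiter(
        (encode_kmer(km, k) for km in kmers), dtype=np.uint64, count=len(kmers)
    )
    if canonicalize and len(codes):
        codes = canonical_codes(codes, k)
    return codes


def kmer_strings(seq: str, k: int, canonicalize: bool = False) -> set[str]:
    """All valid k-mer strings of a (short) sequence, as a set.

    Windows containing non-ACGT characters are skipped; in canonical mode each
    k-mer is replaced by its canonical representative.
    """
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        if "N" in sub:
            continue
        out.add(canonical(sub) if canonicalize else sub)
    return out
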