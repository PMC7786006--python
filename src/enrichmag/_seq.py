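"""Low-level nucleotide sequence utilities.

Sequences are handled in two forms: python strings over A/C/G/T and numpy
``uint8`` code arrays (A=0, C=1, G=2, T=3; anything else = 4, treated as
invalid in k-mer space). All k-mer machinery is vectorised; a k-mer is a
base-4 integer in a ``uint64`` (so k <= 31).
"""

from __future__ import annotations

import numpy as np

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[ord(chr(_b).lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

GAP_CODE = 4  # sentinel for non-ACGT / scaffold separators


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (A=0..T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 renders as ``N``."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (invalid codes stay invalid)."""
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def random_codes(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def random_seq(length: int, rng: np.random.Generator) -> str:
    return decode(random_codes(length, rng))


def mutate_codes(
    codes: np.ndarray, n_subs: int, rng: np.random.Generator
) -> np.ndarray:
    """Apply exactly ``n_subs`` substitutions at distinct random positions.

    Each substitution replaces the base with a different one, so Hamming
    distance to the input is exactly ``n_subs``.
    """
    if n_subs == 0:
        return codes.copy()
    if n_subs > codes.size:
        raise ValueError("more substitutions than positions")
    out = codes.copy()
    pos = rng.choice(codes.size, size=n_subs, replace=False)
    shift = rng.integers(1, 4, size=n_subs, dtype=np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes of a code array plus a validity mask.

    Returns ``(kmers, valid)`` of length ``len(codes) - k + 1``; windows
    containing a non-ACGT base are flagged invalid (their code value is
    meaningless).
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    km = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    capped = np.minimum(codes, 3).astype(np.uint64)
    for j in range(k):
        km = km * four + capped[j : j + n]
    bad = np.convolve((codes >= 4).astype(np.int32), np.ones(k, dtype=np.int32), mode="valid") > 0
    return km, ~bad


def canonical_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (min of strand pair) k-mer codes over valid windows only."""
    fwd, valid = kmer_codes(codes, k)
    rev, _ = kmer_codes(revcomp_codes(codes), k)
    rev = rev[::-1]  # align window i on reverse strand with window i forward
    out = np.minimum(fwd, rev)
    return out[valid]


def mix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finaliser: a cheap, deterministic 64-bit hash (vectorised)."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(0x9E3779B97F4A7C15)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


_aligner = None


def _get_aligner():
    global _aligner
    if _aligner is None:
        from Bio.Align import PairwiseAligner

        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 2.0
        a.mismatch_score = -1.0
        a.open_gap_score = -2.5
        a.extend_gap_score = -0.5
        # end-gap-free: terminal gaps are not penalised
        try:
            a.end_insertion_score = 0.0
            a.end_deletion_score = 0.0
        except AttributeError:  # older Biopython attribute names
            a.target_end_gap_score = 0.0
            a.query_end_gap_score = 0.0
        _aligner = a
    return _aligner


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    End-gap-free global alignment; identity = matches / alignment span,
    where the span runs from the first to the last aligned pair and counts
    internal gap columns, but terminal overhangs are excluded.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _get_aligner().align(a, b)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return 0.0
    matches = 0
    aligned_len = 0
    ea = encode(a)
    eb = encode(b)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        matches += int(np.count_nonzero(ea[ts:te] == eb[qs:qe]))
        aligned_len += te - ts
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    span = t_span + q_span - aligned_len
    return matches / span if span else 0.0
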