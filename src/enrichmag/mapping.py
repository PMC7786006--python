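"""Seed-and-verify short-read mapper with a mismatch cap.

Cross-sample presence/absence calling rests on mapping reads against all
recovered genomes and keeping only near-exact placements — at 250 bp reads a
cap of five mismatches corresponds to a 2% error rate. This mapper implements
exactly that contract: end-to-end (unclipped, ungapped) placements, each read
assigned to its single best location (fewest mismatches over both strands),
discarded if even the best location exceeds ``max_mismatches``.

Algorithm: non-overlapping exact k-mer seeds (default k=31) looked up in a
sorted-array index of every scaffold position, then full-read Hamming
verification of each candidate offset. With b = floor(read_length / k)
seed blocks, any placement with <= b - 1 mismatches leaves at least one seed
block intact (pigeonhole), so for 250 bp reads and k=31 the search is exact up
to 7 mismatches — beyond the cap of 5. When reads are too short for that
guarantee the mapper falls back to an exhaustive scan.

Ties (equal mismatch count) break deterministically: lexicographically
smallest scaffold id, then leftmost start, then forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import GAP_CODE, encode, kmer_codes, revcomp_codes

DEFAULT_MAX_MISMATCHES = 5
DEFAULT_SEED_K = 31


@dataclass(frozen=True)
class MappingRecord:
    read_id: str
    scaffold_id: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    mismatches: int
    length: int


class ScaffoldIndex:
    """Exact k-mer position index over a scaffold set.

    Scaffolds are concatenated (lexicographic id order) with k invalid
    separator bases so no k-mer spans two scaffolds; global concatenated
    positions therefore sort identically to (scaffold_id, local_start), which
    the tie-break rule exploits.
    """

    def __init__(self, scaffolds: Mapping[str, str], k: int = DEFAULT_SEED_K):
        if not scaffolds:
            raise ValueError("scaffold set is empty")
        self.k = k
        self.ids: list[str] = sorted(scaffolds)
        parts = []
        starts = []
        pos = 0
        gap = np.full(k, GAP_CODE, dtype=np.uint8)
        for i, sid in enumerate(self.ids):
            if i:
                parts.append(gap)
                pos += k
            arr = encode(scaffolds[sid])
            starts.append(pos)
            parts.append(arr)
            pos += arr.size
        self.concat = np.concatenate(parts)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray([len(scaffolds[sid]) for sid in self.ids], dtype=np.int64)
        km, valid = kmer_codes(self.concat, k)
        positions = np.nonzero(valid)[0]
        codes = km[positions]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._positions = positions[order]

    def lookup_many(self, codes: np.ndarray) -> list[np.ndarray]:
        """Positions for a batch of k-mer codes (uint64, one array per code)."""
        codes = codes.astype(np.uint64, copy=False)
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return [self._positions[a:b] for a, b in zip(lo, hi)]

    def locate(self, gpos: int, length: int) -> tuple[int, int] | None:
        """Map a global start to (scaffold index, local start) if the interval
        [gpos, gpos+length) lies entirely inside one scaffold."""
        i = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        if i < 0:
            return None
        local = gpos - int(self.starts[i])
        if 0 <= local <= int(self.lengths[i]) - length:
            return i, local
        return None


def _verify(concat: np.ndarray, gpos: int, read: np.ndarray) -> int:
    return int(np.count_nonzero(concat[gpos : gpos + read.size] != read))


def _best_placement_indexed(
    index: ScaffoldIndex, arr: np.ndarray, max_mismatches: int
) -> tuple[int, int, int, int] | None:
    """Best placement as (mismatches, scaffold_idx, local_start, strand_rank)."""
    k = index.k
    best: tuple[int, int, int, int] | None = None
    for strand_rank, read in ((0, arr), (1, revcomp_codes(arr))):
        km, valid = kmer_codes(read, k)
        offsets = np.arange(0, read.size - k + 1, k)
        offsets = offsets[valid[offsets]]
        if offsets.size == 0:
            continue
        hits = index.lookup_many(km[offsets])
        starts = np.concatenate(
            [h.astype(np.int64) - off for h, off in zip(hits, offsets)]
        )
        for gstart in np.unique(starts):
            loc = index.locate(int(gstart), read.size)
            if loc is None:
                continue
            mm = _verify(index.concat, int(gstart), read)
            if mm > max_mismatches:
                continue
            cand = (mm, loc[0], loc[1], strand_rank)
            if best is None or cand < best:
                best = cand
    return best


def _best_placement_brute(
    scaffolds_enc: Sequence[tuple[str, np.ndarray]], arr: np.ndarray, max_mismatches: int
) -> tuple[int, int, int, int] | None:
    """Exhaustive all-offsets, both-strand scan (used when reads are too short
    for the seeding guarantee; also the oracle the mapper is tested against)."""
    best = None
    r = arr.size
    for si, (_, scaf) in enumerate(scaffolds_enc):
        if scaf.size < r:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(scaf, r)
        for strand_rank, read in ((0, arr), (1, revcomp_codes(arr))):
            mms = np.count_nonzero(windows != read, axis=1)
            j = int(np.argmin(mms))
            mm = int(mms[j])
            if mm <= max_mismatches:
                # argmin returns the leftmost minimum: matches the tie-break
                cand = (mm, si, j, strand_rank)
                if best is None or cand < best:
                    best = cand
    return best


def map_reads(
    reads: Iterable[tuple[str, str]],
    scaffolds: Mapping[str, str],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    k: int = DEFAULT_SEED_K,
    index: ScaffoldIndex | None = None,
) -> list[MappingRecord]:
    """Map reads end-to-end against scaffolds, keeping the single best
    placement per read if it has at most ``max_mismatches`` substitutions.

    Reads overhanging scaffold ends are unmapped (no clipping); empty reads
    are skipped with a warning. Deterministic: ties break on (scaffold id,
    start, forward strand).
    """
    reads = list(reads)
    if not scaffolds:
        raise ValueError("scaffold set is empty")
    min_len = min((len(s) for _, s in reads if s), default=0)
    k_eff = min(k, min_len // (max_mismatches + 1)) if min_len else k
    use_index = k_eff >= 8
    if use_index:
        if index is None or index.k != k_eff:
            index = ScaffoldIndex(scaffolds, k=k_eff)
        ids = index.ids
    else:
        ids = sorted(scaffolds)
        scaffolds_enc = [(sid, encode(scaffolds[sid])) for sid in ids]

    out: list[MappingRecord] = []
    for rid, seq in reads:
        if not seq:
            warnings.warn(f"read {rid} has empty sequence; skipped")
            continue
        arr = encode(seq)
        if use_index:
            best = _best_placement_indexed(index, arr, max_mismatches)
        else:
            best = _best_placement_brute(scaffolds_enc, arr, max_mismatches)
        if best is None:
            continue
        mm, si, start, strand_rank = best
        out.append(
            MappingRecord(
                read_id=rid,
                scaffold_id=ids[si],
                start=start,
                strand="-" if strand_rank else "+",
                mismatches=mm,
                length=arr.size,
            )
        )
    return out


def depth_from_mappings(
    mappings: Iterable[MappingRecord], scaffold_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-position depth profiles: depth[i] = number of reads covering i."""
    diffs = {sid: np.zeros(L + 1, dtype=np.int64) for sid, L in scaffold_lengths.items()}
    for m in mappings:
        if m.scaffold_id not in diffs:
            raise KeyError(f"mapping references unknown scaffold {m.scaffold_id}")
        d = diffs[m.scaffold_id]
        d[m.start] += 1
        d[m.start + m.length] -= 1
    return {sid: np.cumsum(d[:-1]) for sid, d in diffs.items()}


def mean_scaffold_coverage(profile: np.ndarray) -> float:
    """Arithmetic mean of a per-position depth vector."""
    profile = np.asarray(profile)
    if profile.size == 0:
        raise ValueError("cannot average a zero-length depth profile")
    return float(profile.mean())


# ---------------------------------------------------------------------------
# exports


def write_sam(
    mappings: Iterable[MappingRecord],
    scaffold_lengths: Mapping[str, int],
    path: str | Path,
    read_seqs: Mapping[str, str] | None = None,
) -> None:
    """Emit mappings as minimal valid SAM (ungapped, NM tag for mismatches)."""
    from ._seq import revcomp

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for sid in sorted(scaffold_lengths):
            fh.write(f"@SQ\tSN:{sid}\tLN:{scaffold_lengths[sid]}\n")
        fh.write("@PG\tID:enrichmag\tPN:enrichmag\n")
        for m in mappings:
            flag = 16 if m.strand == "-" else 0
            seq = "*"
            if read_seqs and m.read_id in read_seqs:
                seq = read_seqs[m.read_id]
                if m.strand == "-":
                    seq = revcomp(seq)
            fh.write(
                f"{m.read_id}\t{flag}\t{m.scaffold_id}\t{m.start + 1}\t255\t"
                f"{m.length}M\t*\t0\t0\t{seq}\t*\tNM:i:{m.mismatches}\n"
            )


def depth_to_tsv(profiles: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write depth as TSV (scaffold, position, depth), one row per position."""
    with open(path, "w") as fh:
        fh.write("scaffold_id\tposition\tdepth\n")
        for sid in sorted(profiles):
            for pos, d in enumerate(profiles[sid]):
                fh.write(f"{sid}\t{pos}\t{int(d)}\n")


def depth_from_tsv(path: str | Path) -> dict[str, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = {}
    for sid, g in df.groupby("scaffold_id"):
        g = g.sort_values("position")
        arr = np.zeros(int(g["position"].max()) + 1, dtype=np.int64)
        arr[g["position"].to_numpy()] = g["depth"].to_numpy()
        out[str(sid)] = arr
    return out


def depth_to_bedgraph(profiles: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write depth as bedGraph (run-length encoded, 0-based half-open)."""
    with open(path, "w") as fh:
        for sid in sorted(profiles):
            d = profiles[sid]
            if d.size == 0:
                continue
            change = np.nonzero(np.diff(d))[0] + 1
            bounds = np.concatenate([[0], change, [d.size]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{sid}\t{a}\t{b}\t{int(d[a])}\n")
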