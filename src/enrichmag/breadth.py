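"""Breadth-of-coverage presence/absence calling for genome bins.

Breadth — the fraction of a genome's positions covered at or above a depth
floor — separates "genome truly present in this sample" from "a few reads
cross-mapped to conserved regions", which mean depth alone cannot. Scaffold
ends map unevenly, so 250 bp is truncated from each scaffold end before the
ratio is formed; the breadth of a bin is pooled over its scaffolds (a single
ratio against the total truncated length, not a per-scaffold average).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_TRIM = 250
DEFAULT_DEPTH_MIN = 3
DEFAULT_BREADTH_MIN_PCT = 50.0


@dataclass(frozen=True)
class BreadthResult:
    bin_id: str
    sample_id: str
    breadth_pct: float
    truncated_length: int
    present: bool


def truncate_profile(profile: np.ndarray, trim: int = DEFAULT_TRIM) -> np.ndarray:
    """Drop the first and last ``trim`` positions of a depth profile.

    Scaffolds with length <= 2*trim contribute zero truncated positions.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    profile = np.asarray(profile)
    if trim == 0:
        return profile
    if profile.size <= 2 * trim:
        return profile[:0]
    return profile[trim:-trim]


def genome_breadth(
    bin_scaffolds: Iterable[str],
    profiles: Mapping[str, np.ndarray],
    depth_min: int = DEFAULT_DEPTH_MIN,
    trim: int = DEFAULT_TRIM,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> tuple[float, int]:
    """Pooled breadth of a bin in one sample.

    Returns ``(breadth_pct, truncated_length)`` where breadth_pct is
    100 * (# truncated positions with depth >= depth_min) / truncated length,
    pooled across the bin's scaffolds. A scaffold absent from ``profiles`` is
    treated as all-zero if its length is known via ``scaffold_lengths``.
    Raises if the bin's total truncated length is zero (breadth undefined).
    """
    covered = 0
    total = 0
    for sid in bin_scaffolds:
        if sid in profiles:
            prof = profiles[sid]
        elif scaffold_lengths is not None and sid in scaffold_lengths:
            prof = np.zeros(scaffold_lengths[sid], dtype=np.int64)
        else:
            raise KeyError(f"no depth profile or length for scaffold {sid}")
        t = truncate_profile(prof, trim)
        total += t.size
        covered += int(np.count_nonzero(t >= depth_min))
    if total == 0:
        raise ValueError("bin has zero truncated length; breadth undefined")
    return 100.0 * covered / total, total


def breadth_matrix(
    bins: Mapping[str, Iterable[str]],
    profiles_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    depth_min: int = DEFAULT_DEPTH_MIN,
    trim: int = DEFAULT_TRIM,
    breadth_min_pct: float = DEFAULT_BREADTH_MIN_PCT,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[BreadthResult]:
    """Breadth of every bin in every sample."""
    out = []
    for bin_id in sorted(bins):
        scafs = list(bins[bin_id])
        for sample_id in sorted(profiles_by_sample):
            pct, tlen = genome_breadth(
                scafs, profiles_by_sample[sample_id], depth_min, trim, scaffold_lengths
            )
            out.append(BreadthResult(bin_id, sample_id, pct, tlen, pct >= breadth_min_pct))
    return out


def breadth_frame(results: Iterable[BreadthResult]) -> pd.DataFrame:
    """Breadth results as a bins x samples percentage matrix."""
    rows = [(r.bin_id, r.sample_id, r.breadth_pct) for r in results]
    df = pd.DataFrame(rows, columns=["bin_id", "sample_id", "breadth_pct"])
    return df.pivot(index="bin_id", columns="sample_id", values="breadth_pct")


def call_presence(
    breadth: pd.DataFrame | Iterable[BreadthResult],
    breadth_min_pct: float = DEFAULT_BREADTH_MIN_PCT,
) -> pd.DataFrame:
    """Presence/absence matrix (bins x samples): present iff breadth >= threshold.

    The threshold is this package's documented default (50%); it is a
    configurable detection cutoff, not a community convention.
    """
    if not 0 < breadth_min_pct <= 100:
        raise ValueError("breadth_min_pct must be in (0, 100]")
    if not isinstance(breadth, pd.DataFrame):
        breadth = breadth_frame(breadth)
    return breadth >= breadth_min_pct
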