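"""rpS3 marker-gene community profiling.

The ribosomal protein S3 gene is universal and single-copy, so scaffolds
carrying it act as one-vote-per-organism proxies for community membership.
This module turns per-sample mean coverages of rpS3-carrying scaffolds into:

* library-size-normalised coverages comparable across samples,
* identity-band taxonomy of each marker against its best reference hit
  (species >= 99%, genus [88, 99), phylum [60, 88), domain < 60),
* 99%-identity greedy clustering of marker sequences (cd-hit style) so the
  same organism observed in several samples counts once,
* per-sample rank-abundance tables, and
* replicate-overlap statistics (core / unique / low-abundance fractions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import alignment_identity

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_CLUSTER_IDENTITY = 0.99
DEFAULT_COVERAGE_CUTOFF = 4.1
MIN_MARKER_SCAFFOLD_LENGTH = 1000

RANK_BANDS = (("species", 99.0), ("genus", 88.0), ("phylum", 60.0), ("domain", 0.0))


@dataclass
class OverlapSummary:
    """Replicate-overlap statistics over marker clusters.

    ``unique_pct`` counts clusters detected in exactly one sample;
    ``low_abundance_pct`` counts clusters whose maximum normalised coverage
    over samples is <= ``coverage_cutoff`` (the two notions coincide for
    communities where the rare tail is sample-specific, but are reported
    separately); ``multi_sample_pct_above_cutoff`` counts clusters above the
    cutoff detected in at least two samples; ``core_pct`` counts clusters
    detected in every sample.
    """

    n_taxa: int
    pattern_counts: dict[tuple[str, ...], int]
    core_pct: float
    unique_pct: float
    low_abundance_pct: float
    multi_sample_pct_above_cutoff: float
    coverage_cutoff: float

    def to_dict(self) -> dict:
        return {
            "n_taxa": self.n_taxa,
            "pattern_counts": {"+".join(k): v for k, v in self.pattern_counts.items()},
            "core_pct": self.core_pct,
            "unique_pct": self.unique_pct,
            "low_abundance_pct": self.low_abundance_pct,
            "multi_sample_pct_above_cutoff": self.multi_sample_pct_above_cutoff,
            "coverage_cutoff": self.coverage_cutoff,
        }


def normalize_coverage(
    coverage: pd.DataFrame, sample_read_counts: Mapping[str, int]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scale per-sample coverages to a common library size.

    ``coverage`` is markers x samples (mean scaffold coverage). Each sample's
    column is multiplied by ``reference_reads / sample_reads`` where the
    reference is the sample with the fewest reads, so a sample sequenced twice
    as deep as the reference has its coverages halved. Returns the normalised
    table and the per-sample scale factors.
    """
    counts = {s: int(sample_read_counts[s]) for s in coverage.columns}
    if any(c <= 0 for c in counts.values()):
        raise ValueError("every sample must have a positive read count")
    ref = min(counts.values())
    factors = {s: ref / c for s, c in counts.items()}
    out = coverage.copy().astype(float)
    for s in out.columns:
        out[s] *= factors[s]
    return out, factors


def assign_rank(identity_pct: float, evalue: float = 0.0, evalue_max: float = DEFAULT_EVALUE_MAX) -> str:
    """Taxonomic rank resolvable from best-hit identity.

    Bands: species >= 99, genus [88, 99), phylum [60, 88), domain < 60 —
    half-open so the gaps between the published integer band edges are closed.
    Hits worse than ``evalue_max`` are 'unclassified'.
    """
    if not 0.0 <= identity_pct <= 100.0:
        raise ValueError("identity_pct must be in [0, 100]")
    if evalue > evalue_max:
        return "unclassified"
    for rank, lo in RANK_BANDS:
        if identity_pct >= lo:
            return rank
    return "domain"


def cluster_markers(
    sequences: Mapping[str, str], identity_min: float = DEFAULT_CLUSTER_IDENTITY
) -> dict[str, str]:
    """Greedy incremental clustering of marker sequences (cd-hit style).

    Sequences are visited in decreasing length (ties: lexicographic id); each
    joins the first existing representative it matches at global-alignment
    identity >= ``identity_min``, else founds a new cluster. Returns
    marker id -> representative id. Deterministic.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if any(not s for s in sequences.values()):
        raise ValueError("empty marker sequence")
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for mid in order:
        seq = sequences[mid]
        for rep in reps:
            if alignment_identity(sequences[rep], seq) >= identity_min:
                assign[mid] = rep
                break
        else:
            reps.append(mid)
            assign[mid] = mid
    return assign


def cluster_coverage(
    coverage: pd.DataFrame, assignments: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate marker-level coverage to clusters (sum of member coverages)."""
    df = coverage.copy()
    df.index = [assignments[i] for i in df.index]
    return df.groupby(level=0).sum()


def rank_abundance(coverage: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Rank-abundance table for one sample.

    Rows are the clusters detected in the sample (coverage > 0) sorted by
    descending normalised coverage, with relative abundance as percent of the
    sample's total marker coverage.
    """
    col = coverage[sample]
    col = col[col > 0].sort_values(ascending=False, kind="stable")
    if col.empty:
        raise ValueError(f"no clusters detected in sample {sample}")
    return pd.DataFrame(
        {
            "cluster_id": col.index,
            "normalized_coverage": col.to_numpy(),
            "relative_abundance_pct": 100.0 * col.to_numpy() / col.sum(),
        }
    ).reset_index(drop=True)


def overlap_stats(
    coverage: pd.DataFrame, coverage_cutoff: float = DEFAULT_COVERAGE_CUTOFF
) -> OverlapSummary:
    """Replicate-overlap summary over a clusters x samples coverage table.

    Detection in a sample means normalised coverage > 0. The coverage cutoff
    is applied to each cluster's maximum normalised coverage across samples.
    """
    if coverage.shape[1] < 2:
        raise ValueError("overlap statistics need at least 2 samples")
    n = len(coverage)
    detected = coverage > 0
    n_samples_det = detected.sum(axis=1)
    maxcov = coverage.max(axis=1)

    pattern_counts: dict[tuple[str, ...], int] = {}
    for _, row in detected.iterrows():
        pat = tuple(s for s in coverage.columns if row[s])
        pattern_counts[pat] = pattern_counts.get(pat, 0) + 1

    core = int((n_samples_det == coverage.shape[1]).sum())
    unique = int((n_samples_det == 1).sum())
    low = int((maxcov <= coverage_cutoff).sum())
    multi_above = int(((maxcov > coverage_cutoff) & (n_samples_det >= 2)).sum())
    return OverlapSummary(
        n_taxa=n,
        pattern_counts=pattern_counts,
        core_pct=100.0 * core / n,
        unique_pct=100.0 * unique / n,
        low_abundance_pct=100.0 * low / n,
        multi_sample_pct_above_cutoff=100.0 * multi_above / n,
        coverage_cutoff=coverage_cutoff,
    )


def classify_markers(markers: pd.DataFrame, evalue_max: float = DEFAULT_EVALUE_MAX) -> pd.DataFrame:
    """Add an ``assigned_rank`` column from best-hit identity and e-value."""
    out = markers.copy()
    ev = out["evalue"] if "evalue" in out.columns else 0.0
    out["assigned_rank"] = [
        assign_rank(i, e, evalue_max)
        for i, e in zip(out["ref_identity_pct"], np.broadcast_to(ev, len(out)))
    ]
    return out
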