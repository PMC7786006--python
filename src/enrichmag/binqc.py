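"""Single-copy-gene bin quality control and the hydrocarbon-pathway screen.

Completeness and contamination of a genome bin are estimated from a universe
of 51 universal bacterial single-copy genes (SCGs): completeness is the
fraction of the 51 labels present at least once, contamination the fraction
present in two or more copies (a lineage-aware estimator like CheckM's is
deliberately not reproduced). Bins below 70% completeness or above 10%
contamination are dropped from downstream analyses.

The pathway screen is a keyword search over gene annotation strings: a
pathway is called for a bin iff at least one annotation contains one of the
pathway's keywords (case-insensitive substring) with a bitscore at or above
that pathway's threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .references import SCG_LABELS

DEFAULT_COMPLETENESS_MIN = 70.0
DEFAULT_CONTAMINATION_MAX = 10.0
DEFAULT_BITSCORE_MIN = 100.0

#: Default hydrocarbon-degradation keyword map (MetaCyc-style pathway terms).
#: Keys are pathway names, values are annotation substrings to search for.
DEFAULT_HYDROCARBON_KEYWORDS: dict[str, tuple[str, ...]] = {
    "alkane degradation": ("alkane monooxygenase", "alkane 1-monooxygenase", "rubredoxin reductase"),
    "toluene degradation": ("toluene monooxygenase", "toluene-4-monooxygenase", "benzylsuccinate synthase"),
    "benzene degradation": ("benzene dioxygenase", "benzene 1,2-dioxygenase", "phenol hydroxylase"),
    "xylene degradation": ("xylene monooxygenase",),
    "catechol ring cleavage": ("catechol 1,2-dioxygenase", "catechol 2,3-dioxygenase"),
    "benzoate degradation": ("benzoate-CoA ligase", "benzoate 1,2-dioxygenase"),
    "naphthalene degradation": ("naphthalene dioxygenase",),
}


@dataclass
class GenomeBin:
    bin_id: str
    scaffold_ids: tuple[str, ...]
    total_length: int = 0
    scg_counts: dict[str, int] = field(default_factory=dict)
    completeness_pct: float = 0.0
    contamination_pct: float = 0.0

    @property
    def passes_filter(self) -> bool:
        return (
            self.completeness_pct >= DEFAULT_COMPLETENESS_MIN
            and self.contamination_pct <= DEFAULT_CONTAMINATION_MAX
        )


def scg_completeness(
    scg_counts: Mapping[str, int], scg_universe: Sequence[str] = SCG_LABELS
) -> tuple[float, float]:
    """Completeness/contamination of a bin from its SCG copy counts.

    completeness = 100 * (# distinct universe SCGs present) / |universe|;
    contamination = 100 * (# universe SCGs with copy count >= 2) / |universe|.
    Labels outside the universe are an error.
    """
    universe = set(scg_universe)
    unknown = set(scg_counts) - universe
    if unknown:
        raise ValueError(f"unknown SCG labels: {sorted(unknown)}")
    present = sum(1 for v in scg_counts.values() if v >= 1)
    duplicated = sum(1 for v in scg_counts.values() if v >= 2)
    n = len(universe)
    return 100.0 * present / n, 100.0 * duplicated / n


def scg_counts_from_hits(hits: pd.DataFrame, bin_scaffolds: Iterable[str]) -> dict[str, int]:
    """Tally SCG label copy counts for a bin from a marker/SCG hit table
    (columns: scaffold_id, marker_label), ignoring non-SCG labels (e.g. rpS3)."""
    scafs = set(bin_scaffolds)
    sub = hits[hits["scaffold_id"].isin(scafs) & hits["marker_label"].isin(SCG_LABELS)]
    return sub["marker_label"].value_counts().to_dict()


def evaluate_bins(
    bins: Mapping[str, Iterable[str]],
    scg_hits: pd.DataFrame,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[GenomeBin]:
    """Build :class:`GenomeBin` records with SCG-based QC metrics."""
    out = []
    for bin_id in sorted(bins):
        scafs = tuple(bins[bin_id])
        counts = scg_counts_from_hits(scg_hits, scafs)
        comp, cont = scg_completeness(counts)
        total = sum(scaffold_lengths.get(s, 0) for s in scafs) if scaffold_lengths else 0
        out.append(GenomeBin(bin_id, scafs, total, counts, comp, cont))
    return out


def filter_bins(
    bins: Iterable[GenomeBin],
    completeness_min: float = DEFAULT_COMPLETENESS_MIN,
    contamination_max: float = DEFAULT_CONTAMINATION_MAX,
) -> list[GenomeBin]:
    """Keep bins with completeness >= min and contamination <= max (inclusive)."""
    return [
        b
        for b in bins
        if b.completeness_pct >= completeness_min and b.contamination_pct <= contamination_max
    ]


def qc_frame(bins: Iterable[GenomeBin], completeness_min: float = DEFAULT_COMPLETENESS_MIN,
             contamination_max: float = DEFAULT_CONTAMINATION_MAX) -> pd.DataFrame:
    rows = [
        {
            "bin_id": b.bin_id,
            "n_scaffolds": len(b.scaffold_ids),
            "total_length": b.total_length,
            "completeness_pct": round(b.completeness_pct, 2),
            "contamination_pct": round(b.contamination_pct, 2),
            "passes_filter": b.completeness_pct >= completeness_min
            and b.contamination_pct <= contamination_max,
        }
        for b in bins
    ]
    return pd.DataFrame(rows)


def screen_pathways(
    annotations: pd.DataFrame,
    keyword_map: Mapping[str, Sequence[str]] | None = None,
    bitscore_min: float | Mapping[str, float] = DEFAULT_BITSCORE_MIN,
) -> pd.DataFrame:
    """Keyword + bitscore screen of gene annotations for degradation pathways.

    ``annotations`` columns: protein_id, bin_id, annotation, bitscore.
    ``bitscore_min`` may be a single threshold or a per-pathway mapping.
    Returns the hit table (one row per matching gene) with pathway and
    ``called`` columns; use :func:`pathway_presence` for the bin x pathway
    matrix.
    """
    if keyword_map is None:
        keyword_map = DEFAULT_HYDROCARBON_KEYWORDS
    if not keyword_map:
        raise ValueError("keyword map is empty")
    rows = []
    text = annotations["annotation"].str.lower()
    for pathway, keywords in keyword_map.items():
        thr = bitscore_min[pathway] if isinstance(bitscore_min, Mapping) else float(bitscore_min)
        if thr < 0:
            raise ValueError("bitscore threshold must be >= 0")
        mask = pd.Series(False, index=annotations.index)
        for kw in keywords:
            mask |= text.str.contains(kw.lower(), regex=False)
        for _, hit in annotations[mask].iterrows():
            rows.append(
                {
                    "bin_id": hit["bin_id"],
                    "pathway": pathway,
                    "protein_id": hit["protein_id"],
                    "annotation": hit["annotation"],
                    "bitscore": hit["bitscore"],
                    "called": bool(hit["bitscore"] >= thr),
                }
            )
    return pd.DataFrame(rows, columns=["bin_id", "pathway", "protein_id", "annotation", "bitscore", "called"])


def pathway_presence(calls: pd.DataFrame, bin_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Bin x pathway boolean presence matrix from a screen_pathways table."""
    if calls.empty:
        return pd.DataFrame(index=sorted(bin_ids) if bin_ids else [])
    called = calls[calls["called"]]
    mat = pd.crosstab(called["bin_id"], called["pathway"]) > 0
    if bin_ids is not None:
        mat = mat.reindex(sorted(bin_ids), fill_value=False)
    return mat
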