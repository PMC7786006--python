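"""Coverage-complementation strain deconvolution of "megabins".

When two closely related strains co-occur in one sample, the assembler
typically produces a shared backbone scaffold (the identical fraction of both
genomes) plus separately assembled variant scaffolds for the region where the
strains differ. Such a collapsed bin ("megabin") shows three signatures:

1. the minor scaffolds align to each other at high identity,
2. they carry redundant copies of single-copy genes, and
3. their mean coverages sum to the backbone scaffold's coverage
   ("coverage complementation"), because every read of either strain's
   variant region maps to exactly one of the variant scaffolds while both
   strains contribute to the backbone.

When all three criteria hold, the megabin is split into one strain genome per
variant scaffold: backbone + that variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MAX_COMPLEMENTATION_ERROR = 0.10
MIN_ALIGNED_FRACTION = 0.5
_PREFILTER_K = 21
_PREFILTER_CONTAINMENT = 0.1


@dataclass
class StrainEvidence:
    bin_id: str
    backbone_scaffolds: tuple[str, ...]
    variant_scaffolds: tuple[str, ...]
    variant_identity_pct: float  # minimum pairwise identity among variants
    redundant_scgs: tuple[str, ...]
    cov_backbone: float
    cov_variants: tuple[float, ...]

    @property
    def complementation_error(self) -> float:
        return abs(self.cov_backbone - sum(self.cov_variants)) / self.cov_backbone


@dataclass
class StrainGenome:
    strain_id: str
    scaffold_ids: tuple[str, ...]  # backbone scaffolds + one variant
    total_length: int
    coverage: float  # the variant scaffold's mean coverage


def scaffold_pair_identity(a: str, b: str) -> float:
    """Identity of the shorter scaffold aligned within the longer, in [0, 1].

    A strand-specific k-mer containment pre-filter rejects clearly unrelated
    pairs cheaply and picks the orientation; the surviving orientation is
    aligned end-to-end of the shorter sequence (infix alignment, edit
    distance capped at half its length) and identity is
    1 - edit_distance / len(shorter). The full shorter scaffold participates,
    so an identity above threshold always covers >= 100% of the shorter
    length. Identities below 0.5 are reported as 0.
    """
    from ._seq import encode, kmer_codes, revcomp

    if len(a) < len(b):
        a, b = b, a

    def kmers(seq: str) -> np.ndarray:
        km, valid = kmer_codes(encode(seq), _PREFILTER_K)
        return np.unique(km[valid])

    ka = kmers(a)
    b_rc = revcomp(b)
    best_query, best_cont = None, 0.0
    for query in (b, b_rc):
        kb = kmers(query)
        if kb.size == 0:
            continue
        cont = np.intersect1d(ka, kb, assume_unique=True).size / kb.size
        if cont > best_cont:
            best_query, best_cont = query, cont
    if best_query is None or best_cont < _PREFILTER_CONTAINMENT:
        return 0.0
    res = edlib.align(best_query, a, mode="HW", task="distance", k=len(b) // 2)
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / len(b)


def redundant_scg_labels(scg_hits: pd.DataFrame, scaffolds: Iterable[str]) -> tuple[str, ...]:
    """SCG labels occurring on >= 2 of the given scaffolds."""
    scafs = set(scaffolds)
    sub = scg_hits[scg_hits["scaffold_id"].isin(scafs)]
    per_label = sub.groupby("marker_label")["scaffold_id"].nunique()
    return tuple(sorted(per_label[per_label >= 2].index))


def detect_strain_structure(
    bin_id: str,
    bin_scaffolds: Iterable[str],
    scg_hits: pd.DataFrame,
    sequences: Mapping[str, str],
    mean_coverages: Mapping[str, float],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_complementation_error: float = DEFAULT_MAX_COMPLEMENTATION_ERROR,
) -> StrainEvidence | None:
    """Test a bin for collapsed strain structure.

    Evidence is returned iff (a) at least two minor scaffolds mutually align
    at >= ``min_identity`` over at least half the shorter length, (b) those
    scaffolds share at least one redundant SCG label, and (c) their summed
    mean coverage complements the highest-coverage (backbone) scaffold within
    ``max_complementation_error``. Otherwise returns None.
    """
    scafs = sorted(bin_scaffolds)
    missing = [s for s in scafs if s not in mean_coverages]
    if missing:
        raise KeyError(f"no coverage for bin scaffolds: {missing}")
    if len(scafs) < 3:
        return None

    backbone = max(scafs, key=lambda s: (mean_coverages[s], s))
    minors = [s for s in scafs if s != backbone]

    # mutually aligning group among the minors (greedy, highest coverage first)
    minors.sort(key=lambda s: (-mean_coverages[s], s))
    ident: dict[tuple[str, str], float] = {}

    def pair_identity(x: str, y: str) -> float:
        key = (min(x, y), max(x, y))
        if key not in ident:
            ident[key] = scaffold_pair_identity(sequences[x], sequences[y])
        return ident[key]

    group: list[str] = []
    for s in minors:
        if all(pair_identity(s, g) >= min_identity for g in group):
            group.append(s)
    if len(group) < 2:
        return None

    redundant = redundant_scg_labels(scg_hits, group)
    if not redundant:
        return None

    cov_bb = float(mean_coverages[backbone])
    cov_vars = tuple(float(mean_coverages[s]) for s in sorted(group))
    if cov_bb <= 0:
        return None
    if abs(cov_bb - sum(cov_vars)) / cov_bb > max_complementation_error:
        return None

    variants = tuple(sorted(group))
    min_pair_ident = min(
        pair_identity(x, y) for i, x in enumerate(variants) for y in variants[i + 1 :]
    )
    return StrainEvidence(
        bin_id=bin_id,
        backbone_scaffolds=(backbone,),
        variant_scaffolds=variants,
        variant_identity_pct=100.0 * min_pair_ident,
        redundant_scgs=redundant,
        cov_backbone=cov_bb,
        cov_variants=cov_vars,
    )


def split_strains(
    evidence: StrainEvidence, scaffold_lengths: Mapping[str, int] | None = None
) -> list[StrainGenome]:
    """Split a megabin into one strain genome per variant scaffold."""
    out = []
    bb_len = sum(scaffold_lengths.get(s, 0) for s in evidence.backbone_scaffolds) if scaffold_lengths else 0
    for i, (var, cov) in enumerate(zip(evidence.variant_scaffolds, evidence.cov_variants), start=1):
        var_len = scaffold_lengths.get(var, 0) if scaffold_lengths else 0
        out.append(
            StrainGenome(
                strain_id=f"{evidence.bin_id}_strain{i}",
                scaffold_ids=tuple(evidence.backbone_scaffolds) + (var,),
                total_length=bb_len + var_len,
                coverage=cov,
            )
        )
    return out


def variant_region_report(
    variant_scaffolds: Iterable[str], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Genes that differ between the variant scaffolds of a strain split.

    Lists every gene on a variant scaffold whose annotation string is not
    shared by all variants (backbone genes are out of scope by construction).
    Returns columns: scaffold_id, protein_id, annotation.
    """
    variants = sorted(variant_scaffolds)
    sub = annotations[annotations["scaffold_id"].isin(variants)]
    per_variant = {v: set(sub.loc[sub["scaffold_id"] == v, "annotation"]) for v in variants}
    shared = set.intersection(*per_variant.values()) if per_variant else set()
    diff = sub[~sub["annotation"].isin(shared)]
    return diff[["scaffold_id", "protein_id", "annotation"]].sort_values(
        ["scaffold_id", "protein_id"]
    ).reset_index(drop=True)
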