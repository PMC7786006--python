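"""End-to-end pipeline orchestration and the canonical demo fixture.

``run_pipeline`` executes the full inference chain on a simulated enrichment
community — simulate -> map -> depth -> breadth -> rpS3 profile -> bin QC ->
strain deconvolution -> dereplication -> pathway screen — writing every stage
output (TSV/JSON) plus a manifest recording the seed and all thresholds.

``demo_marker_table`` / ``demo_megabin`` build the deterministic worked
example the package documents: a 40-cluster replicate community (19 unique
clusters at low normalised coverage, 14 shared by two samples, 7 by all
three — a 17.5% core) and a 1.3 Mbp megabin whose scaffold coverages
(149.7 / 75.4 / 76.0) complement, splitting into two 1.06 Mbp strain genomes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import binqc, breadth, derep, io, mapping, rps3, strains, synthetic
from .synthetic import CommunityConfig, StrainPairConfig

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# demo fixture


def demo_marker_table() -> pd.DataFrame:
    """Deterministic 40-cluster x 3-sample normalised-coverage table.

    19 clusters unique to one sample with max coverage <= 4.1, 14 present in
    exactly two samples, 7 in all three; the shared clusters sit above the
    4.1 low-abundance cutoff. No randomness.
    """
    samples = ["S1", "S2", "S3"]
    rows: dict[str, list[float]] = {}
    for i in range(19):
        cov = [0.0, 0.0, 0.0]
        cov[i % 3] = round(1.0 + 0.15 * i, 2)  # max 3.7 <= 4.1
        rows[f"unique{i + 1:02d}"] = cov
    pairs = [(0, 1), (0, 2), (1, 2)]
    for i in range(14):
        cov = [0.0, 0.0, 0.0]
        for s in pairs[i % 3]:
            cov[s] = round(5.0 + 0.5 * i, 2)
        rows[f"dual{i + 1:02d}"] = cov
    for i in range(7):
        rows[f"core{i + 1:02d}"] = [round(10.0 + 2.0 * i + 0.1 * s, 2) for s in range(3)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def demo_megabin(config: StrainPairConfig | None = None) -> dict[str, Any]:
    """The megabin worked example at its published scale.

    820 kbp backbone at 149.7x plus two 240 kbp variant scaffolds at 75.4x
    and 76.0x (complementation error ~1.1%), redundant SCGs on the variants,
    and ten genes differing between the variant regions. Deterministic.
    """
    if config is None:
        config = StrainPairConfig()
    scaffolds, markers, truth = synthetic.generate_strain_pair(config)
    bb = truth.backbone_scaffold
    v1, v2 = truth.variant_scaffolds
    coverages = {bb: 149.7, v1: 75.4, v2: 76.0}
    annotations = synthetic.strain_pair_annotations(truth, config.n_diff_genes)
    return {
        "scaffolds": scaffolds,
        "markers": markers,
        "truth": truth,
        "coverages": coverages,
        "annotations": annotations,
        "bin_id": config.bin_id,
    }


def demo_fixture(include_megabin: bool = True) -> dict[str, Any]:
    """The canonical deterministic fixture: marker table (+ megabin)."""
    out: dict[str, Any] = {"marker_coverage": demo_marker_table()}
    if include_megabin:
        out["megabin"] = demo_megabin()
    return out


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds in one serialisable object."""

    outdir: str = "enrichmag_run"
    seed: int = 0
    community: CommunityConfig = field(default_factory=CommunityConfig)
    include_strain_pair: bool = False
    strain_pair: StrainPairConfig = field(
        default_factory=lambda: StrainPairConfig(backbone_length=40_000, variant_length=12_000)
    )
    strain_depths: tuple[float, float] = (30.0, 32.0)
    max_mismatches: int = mapping.DEFAULT_MAX_MISMATCHES
    seed_k: int = mapping.DEFAULT_SEED_K
    trim: int = breadth.DEFAULT_TRIM
    depth_min: int = breadth.DEFAULT_DEPTH_MIN
    breadth_min_pct: float = breadth.DEFAULT_BREADTH_MIN_PCT
    cluster_identity: float = rps3.DEFAULT_CLUSTER_IDENTITY
    coverage_cutoff: float = rps3.DEFAULT_COVERAGE_CUTOFF
    evalue_max: float = rps3.DEFAULT_EVALUE_MAX
    completeness_min: float = binqc.DEFAULT_COMPLETENESS_MIN
    contamination_max: float = binqc.DEFAULT_CONTAMINATION_MAX
    min_strain_identity: float = strains.DEFAULT_MIN_IDENTITY
    max_complementation_error: float = strains.DEFAULT_MAX_COMPLEMENTATION_ERROR
    primary_ani: float = derep.DEFAULT_PRIMARY_ANI
    secondary_ani: float = derep.DEFAULT_SECONDARY_ANI
    bitscore_min: float = binqc.DEFAULT_BITSCORE_MIN

    def validate(self) -> None:
        self.community.validate()
        self.strain_pair.validate()
        if not 0 < self.breadth_min_pct <= 100:
            raise synthetic.ConfigurationError("breadth_min_pct must be in (0, 100]")
        if self.max_mismatches < 0 or self.trim < 0 or self.depth_min < 0:
            raise synthetic.ConfigurationError("thresholds must be non-negative")
        for name in ("cluster_identity", "min_strain_identity", "primary_ani", "secondary_ani"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise synthetic.ConfigurationError(f"{name} must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "community" in d and isinstance(d["community"], dict):
            c = dict(d["community"])
            if "overlap_design" in c:
                c["overlap_design"] = tuple(
                    (p if isinstance(p, int) else tuple(p), n) for p, n in c["overlap_design"]
                )
            for key in ("genome_length_range", "scaffolds_per_taxon", "marker_identity_range"):
                if key in c:
                    c[key] = tuple(c[key])
            d["community"] = CommunityConfig(**c)
        if "strain_pair" in d and isinstance(d["strain_pair"], dict):
            d["strain_pair"] = StrainPairConfig(**d["strain_pair"])
        if "strain_depths" in d:
            d["strain_depths"] = tuple(d["strain_depths"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full chain on a simulated community; returns a summary dict
    (also written to ``<outdir>/manifest.json`` along with all stage files).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict[str, Any] = {"seed": config.seed}

    # --- simulate ----------------------------------------------------------
    community = replace(config.community, seed=config.seed)
    scaffolds, markers, truth = synthetic.generate_community(community)
    read_sets = synthetic.community_read_sets(scaffolds, truth, community)
    synthetic.write_fixture(outdir / "fixture", scaffolds, markers, truth, read_sets)
    log.append(f"simulate: {len(scaffolds)} scaffolds, {len(truth.taxa)} taxa, "
               f"{ {s: len(r) for s, r in read_sets.items()} } reads")

    scaffold_lengths = {sid: len(s) for sid, s in scaffolds.items()}
    bins = {t.bin_id: list(t.scaffold_ids) for t in truth.taxa}

    # --- map + depth -------------------------------------------------------
    profiles_by_sample: dict[str, dict[str, np.ndarray]] = {}
    mean_cov: dict[str, dict[str, float]] = {}
    read_counts: dict[str, int] = {}
    k_eff = min(config.seed_k, community.read_length // (config.max_mismatches + 1))
    index = mapping.ScaffoldIndex(scaffolds, k=max(k_eff, 8))
    for sample_id, reads in read_sets.items():
        read_counts[sample_id] = len(reads)
        maps = mapping.map_reads(reads, scaffolds, config.max_mismatches, index.k, index=index)
        profiles = mapping.depth_from_mappings(maps, scaffold_lengths)
        profiles_by_sample[sample_id] = profiles
        mean_cov[sample_id] = {sid: mapping.mean_scaffold_coverage(p) for sid, p in profiles.items()}
        mapping.depth_to_bedgraph(profiles, outdir / f"depth_{sample_id}.bedgraph")
        log.append(f"map[{sample_id}]: {len(maps)}/{len(reads)} reads placed")

    # --- breadth + presence ------------------------------------------------
    results = breadth.breadth_matrix(
        bins, profiles_by_sample, config.depth_min, config.trim,
        config.breadth_min_pct, scaffold_lengths,
    )
    bmat = breadth.breadth_frame(results)
    presence = breadth.call_presence(bmat, config.breadth_min_pct)
    io.write_tsv(bmat.round(3), outdir / "breadth_matrix.tsv", index=True)
    io.write_tsv(presence, outdir / "presence_matrix.tsv", index=True)
    summary["bins_present_per_sample"] = presence.sum().to_dict()

    # --- rpS3 profiling ----------------------------------------------------
    rmarkers = markers[markers["marker_label"] == "rpS3"]
    marker_seqs = {
        row["scaffold_id"]: scaffolds[row["scaffold_id"]][row["start"] : row["end"]]
        for _, row in rmarkers.iterrows()
    }
    assignments = rps3.cluster_markers(marker_seqs, config.cluster_identity)
    cov = pd.DataFrame(
        {s: {sid: mean_cov[s].get(sid, 0.0) for sid in marker_seqs} for s in sorted(read_counts)}
    )
    norm, factors = rps3.normalize_coverage(cov, read_counts)
    clustered = rps3.cluster_coverage(norm, assignments)
    for s in clustered.columns:
        io.write_tsv(rps3.rank_abundance(clustered, s), outdir / f"rank_abundance_{s}.tsv")
    summary["n_marker_clusters"] = len(clustered)
    if clustered.shape[1] >= 2:
        overlap = rps3.overlap_stats(clustered, config.coverage_cutoff)
        (outdir / "overlap_summary.json").write_text(json.dumps(overlap.to_dict(), indent=2))
        summary["overlap"] = overlap.to_dict()

    # --- bin QC ------------------------------------------------------------
    qc_bins = binqc.evaluate_bins(bins, markers, scaffold_lengths)
    retained = binqc.filter_bins(qc_bins, config.completeness_min, config.contamination_max)
    io.write_tsv(binqc.qc_frame(qc_bins, config.completeness_min, config.contamination_max),
                 outdir / "bin_qc.tsv")
    log.append(f"binqc: {len(retained)}/{len(qc_bins)} bins pass "
               f">= {config.completeness_min}% completeness, <= {config.contamination_max}% contamination")
    summary["bins_retained"] = len(retained)

    # --- strain deconvolution ---------------------------------------------
    strain_genomes: dict[str, str] = {}
    if config.include_strain_pair:
        sp = replace(config.strain_pair, seed=config.seed)
        sp_scafs, sp_markers, sp_truth = synthetic.generate_strain_pair(sp)
        d1, d2 = config.strain_depths
        depths = {
            sp_truth.backbone_scaffold: d1 + d2,
            sp_truth.variant_scaffolds[0]: d1,
            sp_truth.variant_scaffolds[1]: d2,
        }
        sp_reads = synthetic.simulate_reads(
            sp_scafs, depths, community.read_length, community.per_base_error_rate,
            rng=np.random.default_rng([config.seed, 505]),
        )
        sp_maps = mapping.map_reads(sp_reads, sp_scafs, config.max_mismatches, config.seed_k)
        sp_profiles = mapping.depth_from_mappings(sp_maps, {s: len(q) for s, q in sp_scafs.items()})
        sp_cov = {sid: mapping.mean_scaffold_coverage(p) for sid, p in sp_profiles.items()}
        evidence = strains.detect_strain_structure(
            sp.bin_id, sp_scafs.keys(), sp_markers, sp_scafs, sp_cov,
            config.min_strain_identity, config.max_complementation_error,
        )
        if evidence is not None:
            split = strains.split_strains(evidence, {s: len(q) for s, q in sp_scafs.items()})
            rows = [
                {"strain_id": g.strain_id, "scaffold_id": s, "total_length": g.total_length,
                 "coverage": g.coverage}
                for g in split for s in g.scaffold_ids
            ]
            io.write_tsv(pd.DataFrame(rows), outdir / "strain_membership.tsv")
            (outdir / "strain_evidence.json").write_text(json.dumps(
                {
                    "bin_id": evidence.bin_id,
                    "backbone": list(evidence.backbone_scaffolds),
                    "variants": list(evidence.variant_scaffolds),
                    "variant_identity_pct": evidence.variant_identity_pct,
                    "redundant_scgs": list(evidence.redundant_scgs),
                    "cov_backbone": evidence.cov_backbone,
                    "cov_variants": list(evidence.cov_variants),
                    "complementation_error": evidence.complementation_error,
                }, indent=2))
            summary["n_strain_genomes"] = len(split)
            summary["complementation_error"] = evidence.complementation_error
            for g in split:
                strain_genomes[g.strain_id] = "".join(sp_scafs[s] for s in g.scaffold_ids)
            log.append(f"strains: split {sp.bin_id} into {len(split)} strain genomes "
                       f"(complementation error {evidence.complementation_error:.4f})")
        else:
            summary["n_strain_genomes"] = 0
            log.append(f"strains: no strain structure detected in {sp.bin_id}")

    # --- dereplication -----------------------------------------------------
    genomes = {b.bin_id: "".join(scaffolds[s] for s in b.scaffold_ids) for b in retained}
    genomes.update(strain_genomes)
    completeness = {b.bin_id: b.completeness_pct for b in retained}
    if genomes:
        clusters = derep.cluster_genomes(
            genomes, config.primary_ani, config.secondary_ani, completeness
        )
        io.write_tsv(clusters, outdir / "genome_clusters.tsv")
        summary["n_genome_clusters"] = int(
            clusters.groupby(["primary_cluster", "secondary_cluster"]).ngroups
        )

    # --- pathway screen ----------------------------------------------------
    annotations, pathway_truth = synthetic.simulate_annotations(sorted(bins), seed=config.seed)
    calls = binqc.screen_pathways(annotations, bitscore_min=config.bitscore_min)
    io.write_tsv(calls, outdir / "pathway_calls.tsv")
    io.write_tsv(binqc.pathway_presence(calls, bins), outdir / "pathway_presence.tsv", index=True)
    summary["n_pathway_calls"] = int(calls["called"].sum()) if len(calls) else 0

    manifest = {
        "package": "enrichmag",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in config.to_dict().items()
            if k not in ("community", "strain_pair", "outdir")
        },
        "community": dataclasses.asdict(community),
        "normalization_factors": factors,
        "log": log,
        "summary": json.loads(json.dumps(summary, default=float)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary
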