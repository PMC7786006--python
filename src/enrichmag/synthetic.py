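"""Synthetic enrichment-culture metagenomes with known ground truth.

Emulates the data a diesel-amended groundwater enrichment experiment yields
after assembly: a replicate community of ~40 taxa with log-normal rank
abundance and only partial overlap between replicates, scaffolds carrying one
ribosomal-protein-S3 (rpS3) marker locus and up to 51 single-copy-gene (SCG)
loci per taxon at controlled identity to a bundled reference set, short reads
(default 2x250 nt chemistry simulated as single 250 nt reads) with i.i.d.
substitution errors, and a "megabin" strain pair: two strain genomes sharing a
backbone scaffold whose variant-scaffold depths sum to the backbone depth.

Everything is deterministic under a fixed seed, and every emitted scaffold is
recorded in exactly one truth record, so downstream stages can be scored
against truth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io, references
from ._seq import decode, encode, mutate_codes, random_codes

MIN_MARKER_GAP = 30


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the simulated replicate community.

    ``overlap_design`` entries are ``(pattern, count)`` where pattern is either
    an int k (taxon present in k samples; the concrete sample combinations are
    cycled deterministically) or an explicit tuple of 0-based sample indices.
    Defaults reproduce the replicate structure of a 3-culture enrichment:
    40 taxa, 19 unique to one sample, 14 in exactly two, 7 in all three.
    """

    n_taxa: int = 40
    n_samples: int = 3
    overlap_design: tuple = ((1, 19), (2, 14), (3, 7))
    abundance_mu: float = 2.0
    abundance_sigma: float = 1.0
    genome_length_range: tuple[int, int] = (20_000, 40_000)
    scaffolds_per_taxon: tuple[int, int] = (1, 3)
    read_length: int = 250
    per_base_error_rate: float = 0.002
    n_scg_per_taxon: int = 51
    marker_identity_range: tuple[float, float] = (60.0, 99.8)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.read_length < 1:
            raise ConfigurationError("read_length must be >= 1")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ConfigurationError("per_base_error_rate must be in [0, 1]")
        if not 0 <= self.n_scg_per_taxon <= references.N_SCG:
            raise ConfigurationError(f"n_scg_per_taxon must be in [0, {references.N_SCG}]")
        total = 0
        for pattern, count in self.overlap_design:
            if count < 0:
                raise ConfigurationError("overlap_design counts must be >= 0")
            k = pattern if isinstance(pattern, int) else len(pattern)
            if not 1 <= k <= self.n_samples:
                raise ConfigurationError(f"membership pattern {pattern!r} incompatible with {self.n_samples} samples")
            if not isinstance(pattern, int) and any(not 0 <= s < self.n_samples for s in pattern):
                raise ConfigurationError(f"sample index out of range in pattern {pattern!r}")
            total += count
        if total != self.n_taxa:
            raise ConfigurationError(f"overlap_design counts sum to {total}, expected n_taxa={self.n_taxa}")


@dataclass(frozen=True)
class StrainPairConfig:
    """Parameters of the two-strain "megabin": a shared backbone scaffold plus
    two mutually similar variant scaffolds whose depths sum to the backbone's.

    Defaults follow the worked strain case: 820 kbp backbone + two 240 kbp
    variants (two strain genomes of 1.06 Mbp each, 1.3 Mbp assembled), ~1%
    variant divergence, 37 backbone SCGs + 10 SCGs repeated on both variants
    (47/51 distinct per strain genome, i.e. ~92% complete), and ten genes that
    differ between the variant regions.
    """

    backbone_length: int = 820_000
    variant_length: int = 240_000
    variant_divergence: float = 0.01
    abundance_ratio: float = 1.0
    n_backbone_scg: int = 37
    n_variant_scg: int = 10
    n_diff_genes: int = 10
    bin_id: str = "megabin"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.variant_divergence <= 0.05:
            raise ConfigurationError("variant_divergence must be in (0, 0.05]")
        if self.abundance_ratio <= 0:
            raise ConfigurationError("abundance_ratio must be > 0")
        if self.backbone_length < 1 or self.variant_length < 1:
            raise ConfigurationError("scaffold lengths must be positive")
        if self.n_backbone_scg + self.n_variant_scg > references.N_SCG:
            raise ConfigurationError("backbone + variant SCG counts exceed the 51-label universe")


# ---------------------------------------------------------------------------
# truth records


@dataclass
class TaxonTruth:
    taxon_id: str
    bin_id: str
    membership: tuple[int, ...]
    abundance: tuple[float, ...]  # per sample; 0 where absent
    scaffold_ids: tuple[str, ...]
    rps3_ref: str
    rps3_identity_pct: float


@dataclass
class StrainPairTruth:
    bin_id: str
    backbone_scaffold: str
    variant_scaffolds: tuple[str, str]
    strains: dict[str, tuple[str, ...]]  # strain_id -> scaffold ids
    strain_lengths: dict[str, int]
    variant_divergence: float
    abundance_ratio: float


@dataclass
class TruthTable:
    taxa: list[TaxonTruth] = field(default_factory=list)
    strain_pairs: list[StrainPairTruth] = field(default_factory=list)
    sample_ids: tuple[str, ...] = ()

    @property
    def scaffold_to_taxon(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for t in self.taxa:
            for s in t.scaffold_ids:
                out[s] = t.taxon_id
        return out

    def membership_matrix(self) -> pd.DataFrame:
        """Boolean taxa x samples matrix of true presence."""
        m = pd.DataFrame(
            False,
            index=[t.taxon_id for t in self.taxa],
            columns=list(self.sample_ids),
        )
        for t in self.taxa:
            for s in t.membership:
                m.iloc[m.index.get_loc(t.taxon_id), s] = True
        return m

    def abundance_matrix(self) -> pd.DataFrame:
        """True per-sample expected depth, taxa x samples."""
        return pd.DataFrame(
            [t.abundance for t in self.taxa],
            index=[t.taxon_id for t in self.taxa],
            columns=list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.taxa:
            for s in t.scaffold_ids:
                rows.append(
                    {
                        "scaffold_id": s,
                        "taxon_id": t.taxon_id,
                        "bin_id": t.bin_id,
                        "membership": ",".join(map(str, t.membership)),
                        "rps3_ref": t.rps3_ref,
                        "rps3_identity_pct": t.rps3_identity_pct,
                        **{f"abundance_{sid}": a for sid, a in zip(self.sample_ids, t.abundance)},
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scaffold assembly helpers


def _assemble_scaffold(
    scaffold_id: str,
    target_length: int,
    markers: Sequence[tuple[str, str, np.ndarray, float]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Build a scaffold of ~target_length with marker loci planted at random,
    non-overlapping positions separated by random filler.

    ``markers`` entries are (label, ref_id, codes, identity_pct). Returns the
    scaffold code array and marker-table rows with realised coordinates.
    """
    n = len(markers)
    marker_len = sum(len(m[2]) for m in markers)
    filler_total = max(target_length - marker_len, (n + 1) * MIN_MARKER_GAP)
    # split filler into n+1 chunks, each >= MIN_MARKER_GAP
    cuts = np.sort(rng.integers(0, filler_total - (n + 1) * MIN_MARKER_GAP + 1, size=n)) if n else np.array([], dtype=int)
    chunk_sizes = np.diff(np.concatenate([[0], cuts, [filler_total - (n + 1) * MIN_MARKER_GAP]])) + MIN_MARKER_GAP
    parts: list[np.ndarray] = []
    rows: list[dict] = []
    pos = 0
    order = rng.permutation(n) if n else []
    for i in range(n):
        filler = random_codes(int(chunk_sizes[i]), rng)
        parts.append(filler)
        pos += filler.size
        label, ref_id, codes, ident = markers[order[i]]
        rows.append(
            {
                "scaffold_id": scaffold_id,
                "start": pos,
                "end": pos + codes.size,
                "strand": "+",
                "marker_label": label,
                "ref_id": ref_id,
                "ref_identity_pct": ident,
                "bitscore": round(2.0 * codes.size * ident / 100.0, 1),
                "evalue": 1e-30,
            }
        )
        parts.append(codes)
        pos += codes.size
    parts.append(random_codes(int(chunk_sizes[-1]) if n else max(target_length, 1), rng))
    return np.concatenate(parts), rows


def _mutated_marker(ref_seq: str, identity_pct: float, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Mutate a reference locus to a requested identity (substitutions only).

    Returns the mutated codes and the realised identity (exact, since the
    substitution count is integral).
    """
    codes = encode(ref_seq)
    n_subs = int(round((1.0 - identity_pct / 100.0) * codes.size))
    realised = 100.0 * (1.0 - n_subs / codes.size)
    return mutate_codes(codes, n_subs, rng), realised


def _membership_patterns(config: CommunityConfig) -> list[tuple[int, ...]]:
    """Expand the overlap design into one concrete sample pattern per taxon."""
    patterns: list[tuple[int, ...]] = []
    for pattern, count in config.overlap_design:
        if isinstance(pattern, int):
            combos = itertools.cycle(itertools.combinations(range(config.n_samples), pattern))
            patterns.extend(tuple(next(combos)) for _ in range(count))
        else:
            patterns.extend([tuple(sorted(pattern))] * count)
    return patterns


# ---------------------------------------------------------------------------
# generators


def generate_community(config: CommunityConfig) -> tuple[dict[str, str], pd.DataFrame, TruthTable]:
    """Generate the community: scaffolds, marker table, and ground truth.

    Each taxon receives 1-3 scaffolds, exactly one planted rpS3 locus (on its
    first scaffold) at a controlled identity to a bundled reference, and up to
    51 SCG loci spread round-robin across its scaffolds. Per-sample abundances
    (expected read depths) are independent log-normal draws for the samples
    the taxon belongs to.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    rps3_refs = references.rps3_references(max(48, config.n_taxa))
    rps3_ids = sorted(rps3_refs)
    scg_refs = references.scg_references()
    patterns = _membership_patterns(config)

    scaffolds: dict[str, str] = {}
    marker_rows: list[dict] = []
    truth = TruthTable(sample_ids=tuple(f"S{i + 1}" for i in range(config.n_samples)))

    for i in range(config.n_taxa):
        taxon_id = f"taxon{i + 1:03d}"
        bin_id = f"bin{i + 1:03d}"
        membership = patterns[i]
        abundance = np.zeros(config.n_samples)
        abundance[list(membership)] = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=len(membership))

        lo, hi = config.marker_identity_range
        rps3_ref_id = rps3_ids[i % len(rps3_ids)]
        rps3_codes, rps3_ident = _mutated_marker(rps3_refs[rps3_ref_id], float(rng.uniform(lo, hi)), rng)

        scg_labels = list(references.SCG_LABELS[: config.n_scg_per_taxon])
        scg_markers = []
        for label in scg_labels:
            codes, ident = _mutated_marker(scg_refs[label], float(rng.uniform(96.0, 99.5)), rng)
            scg_markers.append((label, label, codes, ident))

        n_scaf = int(rng.integers(config.scaffolds_per_taxon[0], config.scaffolds_per_taxon[1] + 1))
        genome_len = int(rng.integers(config.genome_length_range[0], config.genome_length_range[1] + 1))
        per_scaffold: list[list] = [[] for _ in range(n_scaf)]
        per_scaffold[0].append(("rpS3", rps3_ref_id, rps3_codes, rps3_ident))
        for j, m in enumerate(scg_markers):
            per_scaffold[j % n_scaf].append(m)

        scaffold_ids = []
        for j in range(n_scaf):
            sid = f"{taxon_id}_scaf{j + 1}"
            codes, rows = _assemble_scaffold(sid, genome_len // n_scaf, per_scaffold[j], rng)
            scaffolds[sid] = decode(codes)
            marker_rows.extend(rows)
            scaffold_ids.append(sid)

        truth.taxa.append(
            TaxonTruth(
                taxon_id=taxon_id,
                bin_id=bin_id,
                membership=membership,
                abundance=tuple(abundance),
                scaffold_ids=tuple(scaffold_ids),
                rps3_ref=rps3_ref_id,
                rps3_identity_pct=rps3_ident,
            )
        )

    return scaffolds, pd.DataFrame(marker_rows), truth


def generate_strain_pair(config: StrainPairConfig) -> tuple[dict[str, str], pd.DataFrame, StrainPairTruth]:
    """Generate the megabin: backbone + two diverged variant scaffolds.

    The two variant scaffolds are copies differing by ``variant_divergence``
    substitutions; both carry the same ``n_variant_scg`` SCG labels (the
    redundant-SCG signal of a collapsed strain pair), while the backbone
    carries a disjoint set. The truth records the two strain genomes
    (backbone + one variant each). Gene annotations for the differing variant
    region are returned via :func:`strain_pair_annotations`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    scg_refs = references.scg_references()

    backbone_id = f"{config.bin_id}_backbone"
    var1_id = f"{config.bin_id}_variant1"
    var2_id = f"{config.bin_id}_variant2"

    backbone_labels = list(references.SCG_LABELS[: config.n_backbone_scg])
    variant_labels = list(references.SCG_LABELS[config.n_backbone_scg : config.n_backbone_scg + config.n_variant_scg])

    def scg_block(labels):
        out = []
        for label in labels:
            codes, ident = _mutated_marker(scg_refs[label], float(rng.uniform(97.0, 99.5)), rng)
            out.append((label, label, codes, ident))
        return out

    marker_rows: list[dict] = []
    bb_codes, rows = _assemble_scaffold(backbone_id, config.backbone_length, scg_block(backbone_labels), rng)
    marker_rows.extend(rows)

    v1_codes, rows = _assemble_scaffold(var1_id, config.variant_length, scg_block(variant_labels), rng)
    marker_rows.extend(rows)

    n_subs = int(round(config.variant_divergence * v1_codes.size))
    if n_subs == 0:
        raise ConfigurationError("variant_divergence too small: variants must differ")
    v2_codes = mutate_codes(v1_codes, n_subs, rng)
    for r in rows:
        r2 = dict(r)
        r2["scaffold_id"] = var2_id
        marker_rows.append(r2)

    scaffolds = {backbone_id: decode(bb_codes), var1_id: decode(v1_codes), var2_id: decode(v2_codes)}
    strain1 = f"{config.bin_id}_strain1"
    strain2 = f"{config.bin_id}_strain2"
    truth = StrainPairTruth(
        bin_id=config.bin_id,
        backbone_scaffold=backbone_id,
        variant_scaffolds=(var1_id, var2_id),
        strains={strain1: (backbone_id, var1_id), strain2: (backbone_id, var2_id)},
        strain_lengths={
            strain1: config.backbone_length + config.variant_length,
            strain2: config.backbone_length + config.variant_length,
        },
        variant_divergence=config.variant_divergence,
        abundance_ratio=config.abundance_ratio,
    )
    return scaffolds, pd.DataFrame(marker_rows), truth


def strain_pair_annotations(truth: StrainPairTruth, n_diff_genes: int = 10) -> pd.DataFrame:
    """Gene annotations for the variant scaffolds of a strain pair.

    Plants ``n_diff_genes`` genes that differ between the two variants (split
    between them), echoing a strain pair whose differing region encodes mostly
    hypothetical proteins plus a Clp protease, a hydro-lyase, and ribosomal
    protein L34.
    """
    named = ["Clp protease", "hydro-lyase", "50S ribosomal subunit protein L34"]
    annos = named + [f"hypothetical protein {i + 1}" for i in range(max(0, n_diff_genes - len(named)))]
    annos = annos[:n_diff_genes]
    v1, v2 = truth.variant_scaffolds
    half = (n_diff_genes + 1) // 2
    rows = []
    for i, a in enumerate(annos):
        scaf = v1 if i < half else v2
        rows.append({"protein_id": f"{scaf}_gene{i + 1}", "scaffold_id": scaf, "bin_id": truth.bin_id, "annotation": a, "bitscore": 150.0})
    return pd.DataFrame(rows)


def simulate_reads(
    scaffolds: Mapping[str, str],
    depths: Mapping[str, float],
    read_length: int = 250,
    per_base_error_rate: float = 0.002,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Simulate shotgun reads for one sample at given expected depths.

    Read counts are Poisson(depth * L / read_length) per scaffold
    (Lander-Waterman), start positions uniform, strands equiprobable,
    substitution errors i.i.d. at ``per_base_error_rate``. Read ids encode the
    true origin as ``scaffold|start|strand|serial``. Scaffolds shorter than
    the read length are skipped with a warning; zero depth yields zero reads.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    reads: list[tuple[str, str]] = []
    for sid in sorted(scaffolds):
        depth = float(depths.get(sid, 0.0))
        if depth < 0:
            raise ValueError(f"negative depth for {sid}")
        if depth == 0.0:
            continue
        codes = encode(scaffolds[sid])
        L = codes.size
        if L < read_length:
            warnings.warn(f"scaffold {sid} shorter than read length; skipped")
            continue
        n = int(rng.poisson(depth * L / read_length))
        if n == 0:
            continue
        starts = rng.integers(0, L - read_length + 1, size=n)
        minus = rng.integers(0, 2, size=n).astype(bool)
        mat = codes[starts[:, None] + np.arange(read_length)]
        if minus.any():
            mat[minus] = 3 - mat[minus][:, ::-1]
        if per_base_error_rate > 0:
            err = rng.random(mat.shape) < per_base_error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
        for i in range(n):
            strand = "-" if minus[i] else "+"
            reads.append((f"{sid}|{starts[i]}|{strand}|{i}", decode(mat[i])))
    return reads


def community_read_sets(
    scaffolds: Mapping[str, str],
    truth: TruthTable,
    config: CommunityConfig,
) -> dict[str, list[tuple[str, str]]]:
    """Simulate one read set per sample from a community's true abundances."""
    out: dict[str, list[tuple[str, str]]] = {}
    for s, sample_id in enumerate(truth.sample_ids):
        depths = {}
        for t in truth.taxa:
            for sid in t.scaffold_ids:
                depths[sid] = t.abundance[s]
        rng = np.random.default_rng([config.seed, 303, s])
        out[sample_id] = simulate_reads(
            scaffolds, depths, config.read_length, config.per_base_error_rate, rng=rng
        )
    return out


def strain_pair_depths(truth: StrainPairTruth, backbone_depth: float) -> dict[str, float]:
    """Expected per-scaffold depths for a strain pair at a given backbone depth.

    The two strains split the backbone depth in ``abundance_ratio``; each
    variant scaffold receives its own strain's depth, so variant depths sum
    to the backbone depth by construction (ratio 1 gives equal depths).
    """
    r = truth.abundance_ratio
    d1 = backbone_depth * r / (1.0 + r)
    v1, v2 = truth.variant_scaffolds
    return {truth.backbone_scaffold: backbone_depth, v1: d1, v2: backbone_depth - d1}


def simulate_annotations(
    bin_ids: Sequence[str],
    seed: int = 0,
    pathway_fraction: float = 0.6,
    keywords: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Synthesize a gene annotation table for the pathway screen.

    A ``pathway_fraction`` of bins receive 1-2 hydrocarbon-degradation genes
    with bitscores straddling the default threshold; every bin also gets
    generic housekeeping annotations. Returns the table and the truth mapping
    bin -> set of pathways planted with bitscore >= 100.
    """
    from .binqc import DEFAULT_BITSCORE_MIN, DEFAULT_HYDROCARBON_KEYWORDS

    if keywords is None:
        keywords = DEFAULT_HYDROCARBON_KEYWORDS
    pathways = sorted(keywords)
    rng = np.random.default_rng([seed, 404])
    rows = []
    truth: dict[str, set[str]] = {b: set() for b in bin_ids}
    gene_no = 0
    for b in sorted(bin_ids):
        for _ in range(2):
            gene_no += 1
            rows.append(
                {
                    "protein_id": f"gene{gene_no:05d}",
                    "bin_id": b,
                    "annotation": "DNA-directed RNA polymerase subunit beta",
                    "bitscore": float(rng.uniform(150, 400)),
                }
            )
        if rng.random() < pathway_fraction:
            for p in rng.choice(pathways, size=int(rng.integers(1, 3)), replace=False):
                gene_no += 1
                kw = keywords[p][int(rng.integers(0, len(keywords[p])))]
                score = float(rng.uniform(50, 300))
                rows.append(
                    {
                        "protein_id": f"gene{gene_no:05d}",
                        "bin_id": b,
                        "annotation": f"{kw} ({p})",
                        "bitscore": score,
                    }
                )
                if score >= DEFAULT_BITSCORE_MIN:
                    truth[b].add(p)
    return pd.DataFrame(rows), truth


def write_fixture(
    outdir: str | Path,
    scaffolds: Mapping[str, str],
    markers: pd.DataFrame,
    truth: TruthTable,
    read_sets: Mapping[str, list[tuple[str, str]]] | None = None,
) -> dict[str, str]:
    """Write a generated fixture to disk (FASTA/FASTQ/TSV). Returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    io.write_fasta(scaffolds, outdir / "scaffolds.fasta")
    paths["scaffolds"] = str(outdir / "scaffolds.fasta")
    io.write_tsv(markers, outdir / "markers.tsv")
    paths["markers"] = str(outdir / "markers.tsv")
    io.write_tsv(truth.to_frame(), outdir / "truth.tsv")
    paths["truth"] = str(outdir / "truth.tsv")
    bins = {t.bin_id: list(t.scaffold_ids) for t in truth.taxa}
    io.write_bin_table(bins, outdir / "bins.tsv")
    paths["bins"] = str(outdir / "bins.tsv")
    if read_sets:
        for sample_id, reads in read_sets.items():
            p = outdir / f"reads_{sample_id}.fastq"
            io.write_fastq(reads, p)
            paths[f"reads_{sample_id}"] = str(p)
    return paths
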