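"""Tests of the synthetic-community generator against its own ground truth."""

import numpy as np
import pytest

import enrichmag as em
from enrichmag import synthetic
from enrichmag._seq import alignment_identity
from enrichmag.references import rps3_references, scg_references
from enrichmag.synthetic import ConfigurationError


class TestCommunityGeneration:
    def test_default_overlap_design_matches_replicate_structure(self):
        """Default config: 40 taxa split 19 unique / 14 in two / 7 in all three."""
        scaffolds, markers, truth = em.generate_community(em.CommunityConfig(seed=1))
        sizes = [len(t.membership) for t in truth.taxa]
        assert len(truth.taxa) == 40
        assert sizes.count(1) == 19
        assert sizes.count(2) == 14
        assert sizes.count(3) == 7
        # exactly one rpS3 per taxon
        rps3 = markers[markers["marker_label"] == "rpS3"]
        assert len(rps3) == 40
        per_taxon = {t.taxon_id: t.scaffold_ids for t in truth.taxa}
        carriers = set(rps3["scaffold_id"])
        for tid, scafs in per_taxon.items():
            assert len(carriers.intersection(scafs)) == 1

    def test_every_scaffold_in_exactly_one_truth_record(self):
        scaffolds, _, truth = em.generate_community(em.CommunityConfig(seed=2))
        seen = [s for t in truth.taxa for s in t.scaffold_ids]
        assert sorted(seen) == sorted(scaffolds)
        assert len(seen) == len(set(seen))

    def test_degenerate_single_taxon_single_sample(self):
        cfg = em.CommunityConfig(n_taxa=1, n_samples=1, overlap_design=((1, 1),), seed=0)
        _, _, truth = em.generate_community(cfg)
        assert truth.taxa[0].membership == (0,)
        assert truth.membership_matrix().to_numpy().all()

    def test_same_seed_is_byte_identical(self):
        cfg = em.CommunityConfig(
            n_taxa=4, overlap_design=((1, 2), (2, 1), (3, 1)), seed=42,
            genome_length_range=(12_000, 15_000),
        )
        a = em.generate_community(cfg)
        b = em.generate_community(cfg)
        assert a[0] == b[0]
        assert a[1].equals(b[1])
        ra = synthetic.community_read_sets(a[0], a[2], cfg)
        rb = synthetic.community_read_sets(b[0], b[2], cfg)
        assert ra == rb

    def test_infeasible_overlap_design_rejected(self):
        with pytest.raises(ConfigurationError):
            em.CommunityConfig(n_taxa=3, overlap_design=((1, 5),)).validate()
        with pytest.raises(ConfigurationError):
            em.CommunityConfig(n_samples=2, n_taxa=1, overlap_design=((3, 1),)).validate()

    def test_planted_marker_identity_recovered_by_alignment(self, small_community):
        """Realigned identity of planted loci within 1 point of the request."""
        _, scaffolds, markers, truth = small_community
        refs = {**rps3_references(), **scg_references()}
        sample = markers.sample(n=12, random_state=0)
        for _, row in sample.iterrows():
            seq = scaffolds[row["scaffold_id"]][row["start"] : row["end"]]
            ident = 100.0 * alignment_identity(seq, refs[row["ref_id"]])
            assert ident == pytest.approx(row["ref_identity_pct"], abs=1.0)


class TestStrainPair:
    def test_printed_scale_yields_two_megabase_strains(self):
        """820 kbp backbone + 240 kbp variants -> two 1.06 Mbp strain genomes."""
        _, _, truth = em.generate_strain_pair(em.StrainPairConfig(seed=0))
        assert set(truth.strain_lengths.values()) == {1_060_000}
        assert len(truth.strains) == 2
        for scafs in truth.strains.values():
            assert truth.backbone_scaffold in scafs

    def test_variants_differ_by_requested_divergence(self, small_megabin):
        cfg, scaffolds, _, truth, _ = small_megabin
        v1, v2 = (scaffolds[s] for s in truth.variant_scaffolds)
        hamming = sum(a != b for a, b in zip(v1, v2))
        assert hamming == round(cfg.variant_divergence * len(v1))

    def test_zero_divergence_rejected(self):
        with pytest.raises(ConfigurationError):
            em.StrainPairConfig(variant_divergence=0.0).validate()

    def test_redundant_scgs_planted_on_both_variants(self, small_megabin):
        _, _, markers, truth, _ = small_megabin
        v1, v2 = truth.variant_scaffolds
        labels = lambda s: set(markers.loc[markers["scaffold_id"] == s, "marker_label"])  # noqa: E731
        assert labels(v1) == labels(v2)
        assert len(labels(v1)) == 10

    def test_equal_abundance_ratio_gives_equal_variant_depths(self):
        _, _, truth = em.generate_strain_pair(
            em.StrainPairConfig(backbone_length=5000, variant_length=2000, abundance_ratio=1.0)
        )
        depths = synthetic.strain_pair_depths(truth, 100.0)
        v1, v2 = truth.variant_scaffolds
        assert depths[v1] == depths[v2] == 50.0
        assert depths[truth.backbone_scaffold] == 100.0


class TestReadSimulation:
    def test_zero_abundance_yields_zero_reads(self):
        scaffolds = {"s1": "ACGT" * 500}
        assert em.simulate_reads(scaffolds, {"s1": 0.0}, read_length=100, seed=0) == []

    def test_zero_error_rate_reads_are_exact_substrings(self):
        rng = np.random.default_rng(5)
        from enrichmag._seq import random_seq, revcomp

        scaffolds = {"s1": random_seq(5000, rng)}
        reads = em.simulate_reads(scaffolds, {"s1": 5.0}, per_base_error_rate=0.0, seed=1)
        assert reads
        for rid, seq in reads:
            sid, start, strand, _ = rid.split("|")
            sub = scaffolds[sid][int(start) : int(start) + len(seq)]
            assert seq == (sub if strand == "+" else revcomp(sub))

    def test_read_count_follows_lander_waterman(self):
        """n ~ Poisson(c L / r): observed count within 3 sigma."""
        rng = np.random.default_rng(11)
        from enrichmag._seq import random_seq

        L, c, r = 50_000, 10.0, 250
        scaffolds = {"s1": random_seq(L, rng)}
        reads = em.simulate_reads(scaffolds, {"s1": c}, read_length=r, seed=2)
        lam = c * L / r
        assert abs(len(reads) - lam) < 3 * np.sqrt(lam)

    def test_realized_depth_converges_to_requested(self):
        """Mean interior depth within 10% of the requested depth at >= 10x."""
        rng = np.random.default_rng(13)
        from enrichmag._seq import random_seq

        L, c = 40_000, 12.0
        scaffolds = {"s1": random_seq(L, rng)}
        reads = em.simulate_reads(scaffolds, {"s1": c}, seed=3)
        depth = np.zeros(L)
        for rid, seq in reads:
            start = int(rid.split("|")[1])
            depth[start : start + len(seq)] += 1
        interior = depth[250:-250]
        assert abs(interior.mean() - c) / c < 0.10

    def test_short_scaffold_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than read length"):
            reads = em.simulate_reads({"tiny": "ACGTACGT"}, {"tiny": 5.0}, read_length=100, seed=0)
        assert reads == []
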