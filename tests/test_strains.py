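"""Strain deconvolution: complementation arithmetic, gates, and splits."""

import numpy as np
import pandas as pd
import pytest

import enrichmag as em
from enrichmag import strains, synthetic
from enrichmag._seq import decode, encode, mutate_codes, random_seq
from enrichmag.strains import StrainEvidence


def _evidence(covs=(149.7, 75.4, 76.0)):
    return StrainEvidence(
        bin_id="mb",
        backbone_scaffolds=("bb",),
        variant_scaffolds=("v1", "v2"),
        variant_identity_pct=99.0,
        redundant_scgs=("SCG40",),
        cov_backbone=covs[0],
        cov_variants=covs[1:],
    )


def test_complementation_error_of_published_coverages():
    """149.7 vs 75.4 + 76.0 = 151.4: error |149.7-151.4|/149.7 ~ 1.14%."""
    ev = _evidence()
    assert ev.complementation_error == pytest.approx(1.7 / 149.7)
    assert ev.complementation_error == pytest.approx(0.01136, abs=1e-4)


class TestDetection:
    def test_megabin_with_all_three_signals_detected(self, small_megabin):
        cfg, scaffolds, markers, truth, coverages = small_megabin
        ev = em.detect_strain_structure(cfg.bin_id, scaffolds, markers, scaffolds, coverages)
        assert ev is not None
        assert ev.backbone_scaffolds == (truth.backbone_scaffold,)
        assert ev.variant_scaffolds == tuple(sorted(truth.variant_scaffolds))
        assert ev.variant_identity_pct >= 95.0
        assert len(ev.redundant_scgs) == 10
        assert ev.complementation_error <= 0.10

    def test_single_and_two_scaffold_bins_return_none(self, small_megabin):
        cfg, scaffolds, markers, truth, coverages = small_megabin
        one = [truth.backbone_scaffold]
        two = [truth.backbone_scaffold, truth.variant_scaffolds[0]]
        assert em.detect_strain_structure(cfg.bin_id, one, markers, scaffolds, coverages) is None
        assert em.detect_strain_structure(cfg.bin_id, two, markers, scaffolds, coverages) is None

    def test_unrelated_variants_fail_the_alignment_gate(self, small_megabin):
        cfg, scaffolds, markers, truth, coverages = small_megabin
        rng = np.random.default_rng(0)
        v2 = truth.variant_scaffolds[1]
        hacked = dict(scaffolds)
        hacked[v2] = random_seq(len(scaffolds[v2]), rng)  # ~50% identity at best
        assert em.detect_strain_structure(cfg.bin_id, hacked, markers, hacked, coverages) is None

    def test_no_redundant_scgs_fails_the_marker_gate(self, small_megabin):
        cfg, scaffolds, markers, truth, coverages = small_megabin
        v2 = truth.variant_scaffolds[1]
        stripped = markers[markers["scaffold_id"] != v2]
        assert em.detect_strain_structure(cfg.bin_id, scaffolds, stripped, scaffolds, coverages) is None

    def test_non_complementing_coverage_fails_the_depth_gate(self, small_megabin):
        cfg, scaffolds, markers, truth, _ = small_megabin
        bad = {truth.backbone_scaffold: 149.7, truth.variant_scaffolds[0]: 20.0,
               truth.variant_scaffolds[1]: 20.0}
        assert em.detect_strain_structure(cfg.bin_id, scaffolds, markers, scaffolds, bad) is None

    def test_missing_coverage_is_an_error(self, small_megabin):
        cfg, scaffolds, markers, truth, coverages = small_megabin
        partial = {truth.backbone_scaffold: 149.7}
        with pytest.raises(KeyError):
            em.detect_strain_structure(cfg.bin_id, scaffolds, markers, scaffolds, partial)

    def test_no_false_positives_on_unrelated_scaffold_bins(self):
        """Bins of mutually unrelated scaffolds with complementing coverages
        never produce strain evidence (the alignment criterion gates)."""
        markers = pd.DataFrame({"scaffold_id": [], "marker_label": []})
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scaffolds = {f"s{i}": random_seq(3000, rng) for i in range(3)}
            coverages = {"s0": 100.0, "s1": 50.0, "s2": 50.0}
            assert em.detect_strain_structure("b", scaffolds, markers, scaffolds, coverages) is None


class TestSplit:
    def test_split_produces_one_strain_per_variant(self):
        lengths = {"bb": 820_000, "v1": 240_000, "v2": 240_000}
        out = em.split_strains(_evidence(), lengths)
        assert len(out) == 2
        assert all(g.total_length == 1_060_000 for g in out)
        assert out[0].coverage == 75.4 and out[1].coverage == 76.0
        # strain scaffold sets overlap exactly in the backbone
        overlap = set(out[0].scaffold_ids) & set(out[1].scaffold_ids)
        assert overlap == {"bb"}

    def test_three_complementing_variants_give_three_strains(self):
        ev = StrainEvidence("mb", ("bb",), ("v1", "v2", "v3"), 99.0, ("SCG40",),
                            90.0, (30.0, 30.0, 30.0))
        assert len(em.split_strains(ev)) == 3

    def test_strain_completeness_at_least_backbone_completeness(self, small_megabin):
        """Adding a variant scaffold never removes SCGs from the genome."""
        from enrichmag import binqc

        cfg, scaffolds, markers, truth, coverages = small_megabin
        ev = em.detect_strain_structure(cfg.bin_id, scaffolds, markers, scaffolds, coverages)
        split = em.split_strains(ev)
        bb_only = binqc.scg_counts_from_hits(markers, ev.backbone_scaffolds)
        bb_comp, _ = em.scg_completeness(bb_only)
        for g in split:
            counts = binqc.scg_counts_from_hits(markers, g.scaffold_ids)
            comp, cont = em.scg_completeness(counts)
            assert comp >= bb_comp
            assert cont == 0.0


class TestVariantReport:
    def test_identical_annotation_sets_give_empty_report(self):
        annotations = pd.DataFrame(
            [
                {"protein_id": "p1", "scaffold_id": "v1", "annotation": "permease"},
                {"protein_id": "p2", "scaffold_id": "v2", "annotation": "permease"},
            ]
        )
        assert em.variant_region_report(["v1", "v2"], annotations).empty

    def test_planted_ten_gene_difference_reported(self, small_megabin):
        cfg, _, _, truth, _ = small_megabin
        annotations = synthetic.strain_pair_annotations(truth, n_diff_genes=10)
        report = em.variant_region_report(truth.variant_scaffolds, annotations)
        assert len(report) == 10

    def test_backbone_genes_out_of_scope(self):
        annotations = pd.DataFrame(
            [
                {"protein_id": "p1", "scaffold_id": "bb", "annotation": "gyrase"},
                {"protein_id": "p2", "scaffold_id": "v1", "annotation": "unique thing"},
                {"protein_id": "p3", "scaffold_id": "v2", "annotation": "other thing"},
            ]
        )
        report = em.variant_region_report(["v1", "v2"], annotations)
        assert "bb" not in set(report["scaffold_id"])
        assert len(report) == 2


def test_detection_recovers_planted_partition_from_simulated_depths():
    """End-to-end on simulated reads: mapped depths complement and the
    planted strain pair is recovered."""
    cfg = em.StrainPairConfig(backbone_length=20_000, variant_length=6_000,
                              abundance_ratio=1.2, seed=9)
    scaffolds, markers, truth = em.generate_strain_pair(cfg)
    depths = synthetic.strain_pair_depths(truth, backbone_depth=40.0)
    reads = em.simulate_reads(scaffolds, depths, seed=10)
    maps = em.map_reads(reads, scaffolds)
    lengths = {s: len(q) for s, q in scaffolds.items()}
    profiles = em.depth_from_mappings(maps, lengths)
    coverages = {s: em.mean_scaffold_coverage(p) for s, p in profiles.items()}
    ev = em.detect_strain_structure(cfg.bin_id, scaffolds, markers, scaffolds, coverages)
    assert ev is not None
    split = em.split_strains(ev, lengths)
    assert {tuple(sorted(g.scaffold_ids)) for g in split} == {
        tuple(sorted(s)) for s in truth.strains.values()
    }
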