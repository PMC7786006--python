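"""rpS3 profiling: normalisation, taxonomy bands, clustering, overlap stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import enrichmag as em
from enrichmag import rps3
from enrichmag._seq import decode, encode, mutate_codes, random_seq


class TestNormalization:
    def test_equal_read_counts_is_identity(self):
        cov = pd.DataFrame({"S1": [10.0, 5.0], "S2": [2.0, 8.0]})
        norm, factors = em.normalize_coverage(cov, {"S1": 1000, "S2": 1000})
        pd.testing.assert_frame_equal(norm, cov)
        assert factors == {"S1": 1.0, "S2": 1.0}

    def test_double_depth_sample_is_halved(self):
        cov = pd.DataFrame({"ref": [10.0], "deep": [10.0]})
        norm, factors = em.normalize_coverage(cov, {"ref": 1000, "deep": 2000})
        assert norm["deep"].iloc[0] == 5.0
        assert norm["ref"].iloc[0] == 10.0
        assert factors["deep"] == 0.5

    def test_zero_read_count_rejected(self):
        cov = pd.DataFrame({"S1": [1.0]})
        with pytest.raises(ValueError):
            em.normalize_coverage(cov, {"S1": 0})

    @given(st.lists(st.floats(0.1, 1e3), min_size=2, max_size=8, unique=True))
    def test_normalization_preserves_within_sample_rank_order(self, covs):
        cov = pd.DataFrame({"S1": covs, "S2": covs[::-1]})
        norm, _ = em.normalize_coverage(cov, {"S1": 123_456, "S2": 7_890})
        for s in cov.columns:
            assert (cov[s].rank() == norm[s].rank()).all()


class TestRankBands:
    @pytest.mark.parametrize(
        "identity,expected",
        [
            (99.5, "species"),
            (99.0, "species"),
            (98.5, "genus"),  # the (98, 99) gap closes into genus
            (88.0, "genus"),
            (87.5, "phylum"),  # the (87, 88) gap closes into phylum
            (60.0, "phylum"),
            (59.9, "domain"),
            (0.0, "domain"),
        ],
    )
    def test_identity_bands(self, identity, expected):
        assert em.assign_rank(identity) == expected

    def test_poor_evalue_is_unclassified(self):
        assert em.assign_rank(99.5, evalue=1e-3) == "unclassified"
        assert em.assign_rank(99.5, evalue=1e-6) == "species"

    def test_identity_domain_checked(self):
        with pytest.raises(ValueError):
            em.assign_rank(101.0)


class TestClustering:
    def test_identical_sequences_form_one_cluster(self):
        rng = np.random.default_rng(0)
        s = random_seq(600, rng)
        assign = em.cluster_markers({"a": s, "b": s})
        assert len(set(assign.values())) == 1

    def test_five_percent_divergence_splits_at_99(self):
        rng = np.random.default_rng(1)
        a = random_seq(600, rng)
        b = decode(mutate_codes(encode(a), 30, rng))  # 95% identity
        two = em.cluster_markers({"a": a, "b": b}, identity_min=0.99)
        assert len(set(two.values())) == 2
        one = em.cluster_markers({"a": a, "b": b}, identity_min=0.90)
        assert len(set(one.values())) == 1

    def test_lowering_threshold_never_increases_cluster_count(self):
        rng = np.random.default_rng(2)
        base = random_seq(500, rng)
        seqs = {
            f"m{i}": decode(mutate_codes(encode(base), int(rng.integers(0, 80)), rng))
            for i in range(8)
        }
        counts = [
            len(set(em.cluster_markers(seqs, t).values())) for t in (0.99, 0.95, 0.90, 0.80)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_clustering_is_deterministic_and_idempotent(self):
        rng = np.random.default_rng(3)
        seqs = {f"m{i}": random_seq(400, rng) for i in range(5)}
        a = em.cluster_markers(seqs)
        b = em.cluster_markers(dict(reversed(list(seqs.items()))))
        assert a == b
        # representatives re-cluster to themselves
        reps = {r: seqs[r] for r in set(a.values())}
        again = em.cluster_markers(reps)
        assert all(again[r] == r for r in reps)

    def test_planted_community_markers_recover_taxon_count(self, small_community):
        """One 99% cluster per taxon when markers derive from distinct refs."""
        _, scaffolds, markers, truth = small_community
        rmarkers = markers[markers["marker_label"] == "rpS3"]
        seqs = {
            r["scaffold_id"]: scaffolds[r["scaffold_id"]][r["start"] : r["end"]]
            for _, r in rmarkers.iterrows()
        }
        assign = em.cluster_markers(seqs, 0.99)
        assert len(set(assign.values())) == len(truth.taxa)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            em.cluster_markers({})
        with pytest.raises(ValueError):
            em.cluster_markers({"a": ""})


class TestRankAbundance:
    def test_single_cluster_is_all_of_the_community(self):
        cov = pd.DataFrame({"S1": [7.0]}, index=["c1"])
        tab = em.rank_abundance(cov, "S1")
        assert tab["relative_abundance_pct"].tolist() == [100.0]

    def test_thirty_ten_split(self):
        cov = pd.DataFrame({"S1": [30.0, 10.0]}, index=["c1", "c2"])
        tab = em.rank_abundance(cov, "S1")
        assert tab["relative_abundance_pct"].tolist() == [75.0, 25.0]
        assert tab["cluster_id"].tolist() == ["c1", "c2"]

    def test_abundances_sum_to_one_hundred(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"S1": rng.lognormal(1, 1, size=30)})
        tab = em.rank_abundance(cov, "S1")
        assert tab["relative_abundance_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(tab["normalized_coverage"]) <= 0).all()


class TestOverlapStats:
    def test_replicate_fixture_fractions(self):
        """The 19/14/7 design: core 17.5%, low-abundance 47.5%, shared 52.5%."""
        from enrichmag.pipeline import demo_marker_table

        s = em.overlap_stats(demo_marker_table(), coverage_cutoff=4.1)
        assert s.n_taxa == 40
        assert s.core_pct == 17.5
        assert s.unique_pct == 47.5
        assert s.low_abundance_pct == 47.5
        assert s.multi_sample_pct_above_cutoff == 52.5
        assert sum(s.pattern_counts.values()) == 40

    def test_everything_everywhere_is_all_core(self):
        cov = pd.DataFrame(np.full((5, 3), 9.0), columns=["S1", "S2", "S3"])
        s = em.overlap_stats(cov)
        assert s.core_pct == 100.0
        assert s.unique_pct == 0.0

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            em.overlap_stats(pd.DataFrame({"S1": [1.0]}))


def test_classify_markers_adds_rank_column():
    df = pd.DataFrame(
        {"ref_identity_pct": [99.5, 90.0, 70.0, 30.0], "evalue": [1e-30, 1e-30, 1e-30, 1e-2]}
    )
    out = rps3.classify_markers(df)
    assert out["assigned_rank"].tolist() == ["species", "genus", "phylum", "unclassified"]
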