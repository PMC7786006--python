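import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import enrichmag as em
from enrichmag._seq import encode, revcomp_codes

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_community():
    """A 6-taxon, 3-sample community small enough for per-test mapping."""
    cfg = em.CommunityConfig(
        n_taxa=6,
        overlap_design=((1, 3), (2, 2), (3, 1)),
        genome_length_range=(14_000, 20_000),
        seed=7,
    )
    scaffolds, markers, truth = em.generate_community(cfg)
    return cfg, scaffolds, markers, truth


@pytest.fixture(scope="session")
def small_megabin():
    """A strain-pair megabin at reduced scale for fast alignment tests."""
    cfg = em.StrainPairConfig(backbone_length=30_000, variant_length=9_000, seed=3)
    scaffolds, markers, truth = em.generate_strain_pair(cfg)
    coverages = dict(
        zip(
            [truth.backbone_scaffold, *truth.variant_scaffolds],
            [149.7, 75.4, 76.0],
        )
    )
    return cfg, scaffolds, markers, truth, coverages


def oracle_best_placement(read: str, scaffolds: dict[str, str], max_mismatches: int):
    """Exhaustive reference mapper: Hamming distance at every offset of every
    scaffold, both strands; ties broken by (scaffold id, start, '+' first).

    Written independently of the package's mapper; returns
    (scaffold_id, start, strand, mismatches) or None.
    """
    arr = encode(read)
    best = None
    for sid in sorted(scaffolds):
        s = encode(scaffolds[sid])
        if s.size < arr.size:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(s, arr.size)
        for strand_rank, query in ((0, arr), (1, revcomp_codes(arr))):
            mms = np.count_nonzero(windows != query, axis=1)
            start = int(np.argmin(mms))  # leftmost minimum
            mm = int(mms[start])
            if mm <= max_mismatches:
                cand = (mm, sid, start, strand_rank)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    mm, sid, start, strand_rank = best
    return sid, start, "-" if strand_rank else "+", mm
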