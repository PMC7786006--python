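"""Bundled marker reference sets.

The package ships a small, deterministic reference collection used by the
synthetic-community generator and the marker classifier:

* ``rps3_references()`` — nucleotide references for the ribosomal protein S3
  marker gene. Planted community markers are derived from these by point
  mutation at a controlled identity, so the identity of a planted marker to
  its reference is known ground truth.
* ``scg_references()`` — 51 distinct loci labelled SCG01..SCG51 standing in
  for the universal bacterial single-copy gene set that underlies
  completeness/contamination estimation. Only the labels and distinctness
  matter downstream.

Both sets are generated from a fixed internal seed, so they are identical
across processes and releases — functionally equivalent to shipping FASTA
files, without the data files.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._seq import random_seq

_REFERENCE_SEED = 715517

RPS3_LENGTH = 651  # typical bacterial rpS3 CDS length, bp
SCG_LENGTH = 240
N_SCG = 51

SCG_LABELS = tuple(f"SCG{i:02d}" for i in range(1, N_SCG + 1))


@lru_cache(maxsize=None)
def rps3_references(n: int = 48, length: int = RPS3_LENGTH) -> dict[str, str]:
    """Return ``n`` distinct rpS3 reference sequences keyed rpS3_ref001.. ."""
    rng = np.random.default_rng([_REFERENCE_SEED, 1])
    return {f"rpS3_ref{i + 1:03d}": random_seq(length, rng) for i in range(n)}


@lru_cache(maxsize=None)
def scg_references(length: int = SCG_LENGTH) -> dict[str, str]:
    """Return the 51 single-copy-gene reference loci keyed by SCG label."""
    rng = np.random.default_rng([_REFERENCE_SEED, 2])
    return {label: random_seq(length, rng) for label in SCG_LABELS}
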