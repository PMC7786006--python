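"""Two-stage genome dereplication (dRep-style).

Recovered genomes from replicate samples are largely redundant; dereplication
groups them into clusters of near-identical genomes and keeps one
representative each. Clustering runs in two stages, like dRep:

1. **primary** — single-linkage at a coarse ANI threshold (default 90%) on a
   fast MinHash bottom-sketch estimate (Mash-style: Jaccard of canonical
   21-mers converted to ANI via the Mash distance transform);
2. **secondary** — within each multi-genome primary cluster, average-linkage
   at a fine threshold (default 99%) on the *exact* k-mer-set Jaccard ANI
   (no sketching).

Secondary cluster id 0 encodes "no refinement performed" (singleton primary
cluster). The representative of each secondary cluster is the genome with the
highest completeness (ties: longest, then lexicographically smallest id).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._seq import canonical_kmers, encode, mix64

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_PRIMARY_ANI = 0.90
DEFAULT_SECONDARY_ANI = 0.99


def sketch(genome: str, k: int = DEFAULT_K, sketch_size: int = DEFAULT_SKETCH_SIZE) -> np.ndarray:
    """Bottom-s MinHash sketch: the ``sketch_size`` smallest hashed canonical
    k-mers of the genome (sorted uint64 array)."""
    if len(genome) < k:
        raise ValueError(f"genome shorter than k={k}")
    hashes = np.unique(mix64(canonical_kmers(encode(genome), k)))
    return hashes[:sketch_size]


def sketch_jaccard(sa: np.ndarray, sb: np.ndarray, sketch_size: int = DEFAULT_SKETCH_SIZE) -> float:
    """Mash-style Jaccard estimate from two bottom sketches: the fraction of
    the bottom-s of the union that is shared."""
    union = np.union1d(sa, sb)[:sketch_size]
    shared = np.intersect1d(sa, sb, assume_unique=True)
    return float(np.isin(union, shared, assume_unique=True).sum() / union.size)


def jaccard_to_ani(j: float, k: int = DEFAULT_K) -> float:
    """Mash distance transform: d = -ln(2j / (1 + j)) / k; ANI = 100(1 - d)."""
    if j <= 0.0:
        return 0.0
    if j >= 1.0:
        return 100.0
    d = -np.log(2.0 * j / (1.0 + j)) / k
    return max(0.0, 100.0 * (1.0 - d))


def sketch_distance(
    genome_a: str,
    genome_b: str,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
) -> float:
    """Estimated ANI (percent) between two genomes from MinHash sketches.

    Symmetric and deterministic; raises for genomes shorter than k.
    """
    sa = sketch(genome_a, k, sketch_size)
    sb = sketch(genome_b, k, sketch_size)
    return jaccard_to_ani(sketch_jaccard(sa, sb, sketch_size), k)


def kmer_ani(genome_a: str, genome_b: str, k: int = DEFAULT_K) -> float:
    """Exact canonical k-mer-set Jaccard ANI (percent), no sketching.

    Used as the secondary (fine) metric; also serves as the sketch-free
    reference the MinHash estimate is validated against.
    """
    ka = np.unique(canonical_kmers(encode(genome_a), k))
    kb = np.unique(canonical_kmers(encode(genome_b), k))
    if ka.size == 0 or kb.size == 0:
        raise ValueError(f"genome shorter than k={k}")
    inter = np.intersect1d(ka, kb, assume_unique=True).size
    j = inter / (ka.size + kb.size - inter)
    return jaccard_to_ani(j, k)


def _single_linkage_groups(dist: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the graph {d <= threshold} (single linkage)."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    # deterministic order: by smallest member index
    return [groups[r] for r in sorted(groups)]


def cluster_genomes(
    genomes: Mapping[str, str],
    primary_ani: float = DEFAULT_PRIMARY_ANI,
    secondary_ani: float = DEFAULT_SECONDARY_ANI,
    completeness: Mapping[str, float] | None = None,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
) -> pd.DataFrame:
    """Two-stage dereplication of a genome set.

    Returns a table (genome_id, primary_cluster, secondary_cluster,
    representative) sorted by genome id. Primary clusters are numbered 1.. in
    order of their lexicographically smallest member; secondary clusters are
    numbered 1.. within each primary cluster (0 = primary was a singleton,
    no refinement performed). The partition is independent of input order.
    """
    if not genomes:
        raise ValueError("no genomes to cluster")
    ids = sorted(genomes)
    n = len(ids)
    sketches = [sketch(genomes[g], k, sketch_size) for g in ids]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ani = jaccard_to_ani(sketch_jaccard(sketches[i], sketches[j], sketch_size), k)
            dist[i, j] = dist[j, i] = 100.0 - ani

    primary_groups = _single_linkage_groups(dist, 100.0 * (1.0 - primary_ani))

    rows = []
    for p_idx, members in enumerate(primary_groups, start=1):
        if len(members) == 1:
            rows.append((ids[members[0]], p_idx, 0))
            continue
        m = len(members)
        sub = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                ani = kmer_ani(genomes[ids[members[a]]], genomes[ids[members[b]]], k)
                sub[a, b] = sub[b, a] = 100.0 - ani
        Z = linkage(squareform(sub, checks=False), method="average")
        labels = fcluster(Z, t=100.0 * (1.0 - secondary_ani), criterion="distance")
        # renumber secondary clusters by smallest member index for determinism
        seen: dict[int, int] = {}
        for a in range(m):
            if labels[a] not in seen:
                seen[labels[a]] = len(seen) + 1
        for a in range(m):
            rows.append((ids[members[a]], p_idx, seen[labels[a]]))

    df = pd.DataFrame(rows, columns=["genome_id", "primary_cluster", "secondary_cluster"])
    df = df.sort_values("genome_id").reset_index(drop=True)

    def score(g: str) -> tuple:
        comp = completeness.get(g, 0.0) if completeness else 0.0
        return (-comp, -len(genomes[g]), g)

    df["representative"] = False
    for _, grp in df.groupby(["primary_cluster", "secondary_cluster"]):
        best = min(grp["genome_id"], key=score)
        df.loc[df["genome_id"] == best, "representative"] = True
    return df
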