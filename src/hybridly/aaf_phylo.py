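"""Assembly- and alignment-free phylogeny from raw read sets.

Each sample is reduced to its set of canonical k-mers (lexicographic
minimum of a k-mer and its reverse complement, encoded in 2 bits/base);
singleton k-mers are dropped as sequencing errors.  The inter-sample
distance is a containment distance on the shared fraction,

    d(P, Q) = -(1/k) * ln( |P & Q| / min(|P|, |Q|) ),

an approximately per-base substitution rate for diverged genomes, followed
by neighbor joining.  This is a transparent reimplementation of the
k-mer-distance idea, not of any published tool's exact weighting; the
meaningful output is the topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import trees
from .io_formats import ReadRecord
from .simulate import _BASE_TO_CODE

__all__ = [
    "KmerProfile",
    "build_profile",
    "aaf_distance",
    "distance_matrix",
    "nj_tree",
]


@dataclass
class KmerProfile:
    sample: str
    k: int
    kmers: np.ndarray  # sorted unique uint64 canonical codes
    min_count: int

    def __len__(self) -> int:
        return int(self.kmers.size)


def _encode_batch(seqs: list[bytes], k: int) -> np.ndarray:
    """Canonical k-mer codes of a batch of equal-length sequences."""
    mat = _BASE_TO_CODE[
        np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(len(seqs), -1)
    ]
    length = mat.shape[1]
    width = length - k + 1
    if width <= 0:
        return np.empty(0, dtype=np.uint64)
    valid_base = mat < 4
    codes = np.where(valid_base, mat, 0).astype(np.uint64)
    fwd = np.zeros((mat.shape[0], width), dtype=np.uint64)
    rev = np.zeros_like(fwd)
    rc_codes = (3 - codes) % 4
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes[:, j : j + width]
        # Reverse complement read, same Horner, then un-reverse the windows.
        rev = (rev << np.uint64(2)) | rc_codes[:, ::-1][:, j : j + width]
    rev = rev[:, ::-1]
    canonical = np.minimum(fwd, rev)
    # Drop windows containing N (or other non-ACGT) bases.
    bad = ~valid_base
    if bad.any():
        cum = np.concatenate(
            [np.zeros((mat.shape[0], 1), dtype=int), np.cumsum(bad, axis=1)], axis=1
        )
        window_bad = (cum[:, k:] - cum[:, :-k]) > 0
        canonical = canonical[~window_bad]
    return canonical.ravel()


def build_profile(
    reads: Iterable[ReadRecord | str],
    sample: str = "sample",
    k: int = 31,
    min_count: int = 2,
) -> KmerProfile:
    """Canonical k-mer set of a read set, after an error-suppression filter.

    k must be odd (no self-reverse-complement k-mers) and <= 31 (2-bit
    packing in 64 bits).  k-mers containing N are dropped; k-mers seen
    fewer than ``min_count`` times are dropped; set semantics thereafter.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    by_length: dict[int, list[bytes]] = {}
    n_reads = 0
    for read in reads:
        seq = read.seq if isinstance(read, ReadRecord) else read
        n_reads += 1
        if len(seq) < k:
            continue
        by_length.setdefault(len(seq), []).append(seq.encode("ascii"))
    if n_reads == 0:
        raise ValueError(f"sample {sample!r}: no reads")
    if not by_length:
        raise ValueError(
            f"sample {sample!r}: k={k} exceeds every read length"
        )
    chunks = [_encode_batch(batch, k) for batch in by_length.values()]
    allk = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    uniq, counts = np.unique(allk, return_counts=True)
    kept = uniq[counts >= min_count]
    return KmerProfile(sample=sample, k=k, kmers=kept, min_count=min_count)


def aaf_distance(p: KmerProfile, q: KmerProfile, d_max: float = 1.0) -> float:
    """Containment distance between two profiles; capped at ``d_max``.

    Zero iff the smaller set is a subset of the larger; an empty
    intersection yields the ``d_max`` cap.
    """
    if p.k != q.k:
        raise ValueError(f"k mismatch: {p.k} != {q.k}")
    if len(p) == 0 or len(q) == 0:
        raise ValueError("profiles must be non-empty (min_count filter too strict?)")
    inter = np.intersect1d(p.kmers, q.kmers, assume_unique=True).size
    if inter == 0:
        return d_max
    ratio = inter / min(len(p), len(q))
    return min(-math.log(ratio) / p.k, d_max)


def distance_matrix(
    profiles: Sequence[KmerProfile], d_max: float = 1.0
) -> tuple[list[str], np.ndarray]:
    names = [p.sample for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = aaf_distance(profiles[i], profiles[j], d_max=d_max)
    return names, d


def nj_tree(
    names: Sequence[str],
    matrix: np.ndarray,
    outgroup: str | None = None,
) -> trees.TreeNode:
    """Neighbor-joining tree; optionally rooted on the outgroup's pendant edge."""
    if len(names) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    tree = trees.neighbor_joining(names, matrix)
    if outgroup is not None:
        tree = trees.root_on_outgroup(tree, outgroup)
    return tree
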