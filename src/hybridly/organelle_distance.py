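"""Pairwise substitution distances over aligned organellar sequences and
maternal-parent assignment.

The input must already be a positional alignment (equal-length sequences,
substitutions only); this module does not align.  Under strictly maternal
organelle inheritance the candidate at minimal distance from the hybrid is
the maternal parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import SeqRecord

__all__ = ["DistanceMatrix", "MaternalAssignment", "cp_pairwise", "assign_maternal"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise substitution counts with per-pair compared-site counts."""

    names: list[str]
    counts: np.ndarray  # (n, n) int, diagonal 0
    n_sites: np.ndarray  # (n, n) int, unambiguous columns per pair

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValueError(f"unknown taxon {name!r}; have {self.names}") from None

    def distance(self, a: str, b: str) -> int:
        return int(self.counts[self.index(a), self.index(b)])

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_sites > 0, self.counts / self.n_sites, 0.0)


def cp_pairwise(records: Sequence[SeqRecord]) -> DistanceMatrix:
    """Count differing unambiguous columns for every pair of aligned sequences.

    Columns where either base is not in {A,C,G,T} (N, ambiguity codes,
    gaps) are skipped for that pair and excluded from ``n_sites``.
    """
    if len(records) < 2:
        raise ValueError("need at least two aligned sequences")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(
            "aligned sequences must all have equal length; supply a positional "
            f"alignment (got lengths {sorted(lengths)})"
        )
    names = [r.id for r in records]
    arrays = [np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8) for r in records]
    unambiguous = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arrays]
    n = len(records)
    counts = np.zeros((n, n), dtype=np.int64)
    n_sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = unambiguous[i] & unambiguous[j]
            diff = int(np.count_nonzero((arrays[i] != arrays[j]) & both))
            counts[i, j] = counts[j, i] = diff
            n_sites[i, j] = n_sites[j, i] = int(np.count_nonzero(both))
    return DistanceMatrix(names=names, counts=counts, n_sites=n_sites)


@dataclass
class MaternalAssignment:
    maternal: str | None  # None when the margin is below tie_ratio
    margin: float  # second-smallest / smallest candidate distance
    distances: dict[str, int]

    @property
    def ambiguous(self) -> bool:
        return self.maternal is None


def assign_maternal(
    matrix: DistanceMatrix,
    hybrid: str,
    candidates: Sequence[str],
    tie_ratio: float = 1.1,
) -> MaternalAssignment:
    """Nearest candidate by organellar distance, with a tie guard.

    The margin is the ratio of the second-smallest to the smallest
    hybrid-candidate distance; a margin below ``tie_ratio`` makes the
    assignment ambiguous (maternal None).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates")
    distances = {c: matrix.distance(hybrid, c) for c in candidates}
    ranked = sorted(candidates, key=lambda c: (distances[c], c))
    smallest = distances[ranked[0]]
    second = distances[ranked[1]]
    if smallest == 0:
        margin = float("inf") if second > 0 else 1.0
    else:
        margin = second / smallest
    maternal = ranked[0] if margin >= tie_ratio else None
    return MaternalAssignment(maternal=maternal, margin=margin, distances=distances)
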