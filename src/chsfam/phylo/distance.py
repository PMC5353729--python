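"""Pairwise evolutionary distances from a protein alignment.

Distances are p-distances (proportion of mismatched compared sites), with an
optional Poisson correction d = -ln(1 - p) for multiple hits.  Two site
rules are supported: ``pairwise_deletion`` compares, for each pair, only the
columns where both rows carry a residue; ``partial_deletion`` first drops
columns whose residue occupancy falls below a coverage threshold (default
95%) and then applies pairwise deletion within the retained columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import GAP, Alignment

__all__ = ["DistanceMatrix", "compute_distances"]

DEFAULT_COVERAGE = 0.95


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # (n, n), substitutions/site

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape disagrees with ids")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def compute_distances(
    aln: Alignment,
    site_rule: str = "partial_deletion",
    *,
    coverage: float = DEFAULT_COVERAGE,
    correction: str | None = None,
) -> DistanceMatrix:
    """Compute the pairwise distance matrix of an alignment.

    ``correction`` is ``None`` (plain p-distance) or ``"poisson"``.  A pair
    with zero comparable sites — or a saturated pair (p = 1) under the
    Poisson correction — is an error naming the pair.
    """
    if site_rule not in {"partial_deletion", "pairwise_deletion"}:
        raise ValueError(f"unknown site rule {site_rule!r}")
    if correction not in {None, "poisson"}:
        raise ValueError(f"unknown distance correction {correction!r}")

    arr = aln.to_array()
    residue = arr != GAP
    if site_rule == "partial_deletion":
        keep = residue.mean(axis=0) >= coverage
        arr, residue = arr[:, keep], residue[:, keep]

    n = aln.n_sequences
    codes = arr.view(np.uint32).reshape(n, -1)  # 'U1' -> codepoints
    both = residue[:, None, :] & residue[None, :, :]
    comp = both.sum(axis=2)
    mism = ((codes[:, None, :] != codes[None, :, :]) & both).sum(axis=2)

    off = ~np.eye(n, dtype=bool)
    if (comp[off] == 0).any():
        i, j = np.argwhere((comp == 0) & off)[0]
        raise ValueError(f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})")
    D = np.where(comp > 0, mism / np.maximum(comp, 1), 0.0)
    if correction == "poisson":
        if (D[off] >= 1.0).any():
            i, j = np.argwhere((D >= 1.0) & off)[0]
            raise ValueError(f"saturated pair ({aln.ids[i]}, {aln.ids[j]}): p = 1")
        D = -np.log1p(-D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ids=aln.ids, values=D)
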