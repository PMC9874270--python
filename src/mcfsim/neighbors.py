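"""Verlet neighbor list built on a k-d tree with a displacement-triggered
rebuild (skin criterion)."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .fibril_geometry import BeadTopology

__all__ = ["NeighborList"]


class NeighborList:
    """Pair list within ``cutoff + skin``, respecting 1-2/1-3 exclusions.

    The list is rebuilt whenever any bead has moved more than skin/2
    since the last build, which guarantees no interacting pair is ever
    missed.  Pairs are lexicographically sorted, so the summation order
    is canonical (identical to the O(N^2) oracle path).
    """

    def __init__(self, topology: BeadTopology, cutoff: float, skin: float = 4.0):
        if cutoff <= 0 or skin < 0:
            raise ValueError("cutoff must be positive, skin non-negative")
        self.cutoff = float(cutoff)
        self.skin = float(skin)
        self.mol = topology.molecule_id
        self.Lz = float(topology.box.lengths[2])
        self.pbc_z = bool(topology.box.periodic[2])
        self.pairs: np.ndarray | None = None
        self._ref_pos: np.ndarray | None = None
        self.n_builds = 0

    def check_cutoff(self, max_interaction_cutoff: float) -> None:
        if self.cutoff < max_interaction_cutoff:
            raise ValueError(
                f"neighbor cutoff {self.cutoff} Å below the largest "
                f"interaction cutoff {max_interaction_cutoff} Å"
            )

    def needs_rebuild(self, positions: np.ndarray) -> bool:
        if self.pairs is None or self._ref_pos is None:
            return True
        d = positions - self._ref_pos
        if self.pbc_z:
            d[:, 2] -= self.Lz * np.round(d[:, 2] / self.Lz)
        return bool((np.einsum("ij,ij->i", d, d) > (self.skin / 2.0) ** 2).any())

    def build(self, positions: np.ndarray) -> np.ndarray:
        r = self.cutoff + self.skin
        if self.pbc_z:
            # toroidal k-d tree in z only: x/y get a box so large that
            # the minimum image is always the direct one
            lo = positions.min(axis=0)
            shifted = positions - lo
            shifted[:, 2] = np.mod(shifted[:, 2], self.Lz)
            span = shifted[:, :2].max() + 10.0 * r
            boxsize = np.array([span, span, self.Lz])
            tree = cKDTree(shifted, boxsize=boxsize)
        else:
            tree = cKDTree(positions)
        pairs = tree.query_pairs(r, output_type="ndarray").astype(np.int64)
        if len(pairs):
            swap = pairs[:, 0] > pairs[:, 1]
            pairs[swap] = pairs[swap][:, ::-1]
            i, j = pairs[:, 0], pairs[:, 1]
            same_mol = (self.mol[i] == self.mol[j]) & (self.mol[i] >= 0)
            keep = ~(same_mol & (np.abs(i - j) <= 2))
            pairs = pairs[keep]
            pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        self.pairs = pairs
        self._ref_pos = positions.copy()
        self.n_builds += 1
        return pairs

    def get(self, positions: np.ndarray) -> np.ndarray:
        if self.needs_rebuild(positions):
            return self.build(positions)
        return self.pairs
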