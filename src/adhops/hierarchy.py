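"""Auxiliary-index bookkeeping for the hierarchy of pure states.

Auxiliary wave functions are labelled by vectors of non-negative integers,
one entry per exponential bath mode.  Index vectors are stored sparsely as
sorted ``(mode, count)`` pairs so that bookkeeping cost scales with the
number of *occupied* modes, never with the total mode count — a requirement
for size-invariant adaptive calculations on mesoscale aggregates.

The finite basis uses the triangular truncation: the summed depth over
non-Markovian modes is bounded by ``k_max``.  Markovian short-time
correction modes do not count toward the depth budget; they are kept only to
first order and only as immediate neighbors of the physical wave function
(index vectors with a non-zero Markovian entry have all other entries zero).
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AuxIndex",
    "HierarchyBasis",
    "triangular_basis",
    "basis_size_closed_form",
    "neighbors",
]


class AuxIndex:
    """Sparse non-negative integer vector indexing an auxiliary wave function.

    Immutable, hashable, and totally ordered by graded lexicographic order
    (depth first, then the dense vector lexicographically).
    """

    __slots__ = ("_pairs", "_depth", "_hash")

    def __init__(self, pairs: Iterable[tuple[int, int]] = ()):
        cleaned = tuple(sorted((m, k) for m, k in pairs if k != 0))
        for m, k in cleaned:
            if k < 0:
                raise ValueError("auxiliary index entries must be non-negative")
            if m < 0:
                raise ValueError("mode labels must be non-negative")
        self._pairs = cleaned
        self._depth = sum(k for _, k in cleaned)
        self._hash = hash(cleaned)

    @classmethod
    def _make(cls, pairs: tuple, depth: int) -> "AuxIndex":
        """Fast path for internally-constructed, already-sorted pairs."""
        obj = object.__new__(cls)
        obj._pairs = pairs
        obj._depth = depth
        obj._hash = hash(pairs)
        return obj

    @classmethod
    def zero(cls) -> "AuxIndex":
        return cls(())

    @classmethod
    def unit(cls, mode: int) -> "AuxIndex":
        return cls(((mode, 1),))

    @classmethod
    def from_dense(cls, vec: Sequence[int]) -> "AuxIndex":
        return cls((m, int(k)) for m, k in enumerate(vec) if k)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return self._pairs

    @property
    def depth(self) -> int:
        return self._depth

    def depth_over(self, mode_subset) -> int:
        """Summed entries restricted to ``mode_subset``."""
        return sum(k for m, k in self._pairs if m in mode_subset)

    def get(self, mode: int) -> int:
        for m, k in self._pairs:
            if m == mode:
                return k
        return 0

    def plus(self, mode: int) -> "AuxIndex":
        """k + e_mode."""
        pairs = self._pairs
        out = []
        placed = False
        for m, k in pairs:
            if m == mode:
                out.append((m, k + 1))
                placed = True
            else:
                if not placed and m > mode:
                    out.append((mode, 1))
                    placed = True
                out.append((m, k))
        if not placed:
            out.append((mode, 1))
        return AuxIndex._make(tuple(out), self._depth + 1)

    def minus(self, mode: int) -> "AuxIndex | None":
        """k - e_mode, or ``None`` if the entry is already zero (such terms
        vanish identically in the hierarchy)."""
        pairs = self._pairs
        out = []
        found = False
        for m, k in pairs:
            if m == mode:
                found = True
                if k > 1:
                    out.append((m, k - 1))
            else:
                out.append((m, k))
        if not found:
            return None
        return AuxIndex._make(tuple(out), self._depth - 1)

    def to_dense(self, n_modes: int) -> np.ndarray:
        vec = np.zeros(n_modes, dtype=np.int64)
        for m, k in self._pairs:
            vec[m] = k
        return vec

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        return isinstance(other, AuxIndex) and self._pairs == other._pairs

    def _gradedlex_key(self):
        # graded-lex on the dense vector == (depth, [(mode, -k)] ascending)
        return (self._depth, tuple((m, -k) for m, k in self._pairs))

    def __lt__(self, other: "AuxIndex") -> bool:
        return self._gradedlex_key() < other._gradedlex_key()

    def __repr__(self) -> str:
        return f"AuxIndex({list(self._pairs)})"


class HierarchyBasis:
    """Ordered collection of auxiliary indices with O(1) membership lookup.

    Position 0 always holds the zero vector (the physical wave function).
    """

    def __init__(self, members: Iterable[AuxIndex]):
        ordered = sorted(set(members))
        if not ordered or ordered[0] != AuxIndex.zero():
            raise ValueError("basis must contain the zero (physical) index")
        self.members: list[AuxIndex] = ordered
        self.position: dict[AuxIndex, int] = {a: i for i, a in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, aux: AuxIndex) -> bool:
        return aux in self.position

    def __iter__(self):
        return iter(self.members)


def markovian_valid(aux: AuxIndex, markovian_modes: frozenset[int], k_max: int) -> bool:
    """Truncation predicate: triangular depth bound over non-Markovian modes,
    Markovian entries at most 1 and exclusive of all other excitation."""
    depth_nm = 0
    depth_mark = 0
    for m, k in aux.pairs:
        if m in markovian_modes:
            if k > 1:
                return False
            depth_mark += k
        else:
            depth_nm += k
    if depth_mark > 1 or (depth_mark and depth_nm):
        return False
    return depth_nm <= k_max


def triangular_basis(
    n_modes: int, k_max: int, markovian_mask: Sequence[bool] | None = None
) -> HierarchyBasis:
    """Full triangular basis for ``n_modes`` exponential modes.

    All index vectors whose non-Markovian depth is at most ``k_max``;
    Markovian modes appear only as pure first-order vectors e_m.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    mask = [False] * n_modes if markovian_mask is None else list(markovian_mask)
    nm_modes = [m for m in range(n_modes) if not mask[m]]
    members: list[AuxIndex] = []

    # enumerate all non-negative integer vectors over nm_modes with sum <= k_max
    def enumerate_rec(idx: int, prefix: list[tuple[int, int]], remaining: int) -> None:
        if idx == len(nm_modes):
            members.append(AuxIndex(prefix))
            return
        mode = nm_modes[idx]
        for k in range(remaining + 1):
            enumerate_rec(idx + 1, prefix + ([(mode, k)] if k else []), remaining - k)

    enumerate_rec(0, [], k_max)
    for m in range(n_modes):
        if mask[m]:
            members.append(AuxIndex.unit(m))
    return HierarchyBasis(members)


def basis_size_closed_form(n_modes: int, k_max: int) -> int:
    """Number of index vectors with depth <= k_max: C(n_modes + k_max, k_max)."""
    return comb(n_modes + k_max, k_max)


def neighbors(basis: HierarchyBasis, aux: AuxIndex, modes: Iterable[int]):
    """Up/down neighbor positions of ``aux`` per mode.

    Returns ``{mode: (up_pos, down_pos)}`` with ``None`` marking an absent
    neighbor (outside the basis, or down past zero).
    """
    if aux not in basis:
        raise KeyError(f"{aux!r} not in basis")
    out = {}
    for m in modes:
        up = basis.position.get(aux.plus(m))
        down_idx = aux.minus(m)
        down = basis.position.get(down_idx) if down_idx is not None else None
        out[m] = (up, down)
    return out
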