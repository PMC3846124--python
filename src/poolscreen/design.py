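"""Multidimensional pooling design and clone <-> pool membership queries.

Each *dimension* partitions the whole clone library into disjoint pools;
every clone belongs to exactly one pool per enabled dimension.  The nine
supported dimensions are:

=====  ==========================================  =====================
code   pool rule (0-based indices)                 count @ defaults
=====  ==========================================  =====================
PP     layer ``L``                                 36  (2304 clones)
RP     cube row ``r``                              48  (1728 clones)
CP     cube column ``c``                           48  (1728 clones)
DP     ``(r + c) mod cube_rows``                   48  (1728 clones)
SP     ``(r + L) mod cube_rows``                   48  (1728 clones)
FP     ``(c + L) mod cube_cols``                   48  (1728 clones)
SA     ``plate mod layers`` (stride groups)        36  (2304 clones)
SB     ``plate mod (n_plates / 8)``                27  (3072 clones)
SG     single plate                                216 (384 clones)
=====  ==========================================  =====================

The SA/SB stride groupings deliberately differ from the consecutive-plate
PP layers so the extra dimensions retain disambiguation value.  The three
modular dimensions partition the library with equal pool sizes for any
geometry; the defaults use a square (48 x 48) cube face.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import CloneCoordinate, LibraryGeometry

__all__ = [
    "DIMENSIONS",
    "CUBE_DIMENSIONS",
    "ConfigurationError",
    "PoolAddress",
    "PoolingDesign",
    "build_design",
    "clone_pools",
    "pool_members",
]

CUBE_DIMENSIONS: tuple[str, ...] = ("PP", "RP", "CP", "DP", "SP", "FP")
DIMENSIONS: tuple[str, ...] = CUBE_DIMENSIONS + ("SA", "SB", "SG")

SB_PLATES_PER_POOL = 8

_POOL_ID_RE = re.compile(r"^([A-Z]{2})(\d+)$")


class ConfigurationError(ValueError):
    """Raised when a design request is inconsistent with the geometry."""


@dataclass(frozen=True)
class PoolAddress:
    """One pool, addressed by dimension code and index within the dimension."""

    dimension: str
    index: int


class PoolingDesign:
    """Clone <-> pool membership maps for a set of enabled dimensions.

    Membership is stored as one dense ``int`` array per dimension mapping
    clone id -> pool index; everything else (pool sizes, member lists,
    reverse lookups) is derived from these arrays.  Construction is
    deterministic: there is no randomness anywhere in the design.
    """

    def __init__(self, geometry: LibraryGeometry, dimensions: Sequence[str]) -> None:
        seen: list[str] = []
        for d in dimensions:
            if d not in DIMENSIONS:
                raise ConfigurationError(f"unknown dimension {d!r}; expected one of {DIMENSIONS}")
            if d not in seen:
                seen.append(d)
        if not seen:
            raise ConfigurationError("at least one dimension must be enabled")
        # keep canonical ordering regardless of request order
        self.dimensions: tuple[str, ...] = tuple(d for d in DIMENSIONS if d in seen)
        self.geometry = geometry
        self._check_divisibility()
        self._pool_index = self._build_arrays()
        self._members_cache: dict[str, list[np.ndarray]] = {}

    # -- construction ----------------------------------------------------

    def _check_divisibility(self) -> None:
        g = self.geometry
        if "SA" in self.dimensions and g.n_plates % g.layers != 0:
            raise ConfigurationError(
                f"SA dimension needs n_plates ({g.n_plates}) divisible by layers ({g.layers})"
            )
        if "SB" in self.dimensions and g.n_plates % SB_PLATES_PER_POOL != 0:
            raise ConfigurationError(
                f"SB dimension needs n_plates ({g.n_plates}) divisible by {SB_PLATES_PER_POOL}"
            )

    def _build_arrays(self) -> dict[str, np.ndarray]:
        g = self.geometry
        ids = np.arange(g.n_clones)
        plate = ids // g.wells_per_plate
        rem = ids % g.wells_per_plate
        row = rem // g.plate_cols
        col = rem % g.plate_cols
        L = plate // g.plates_per_layer
        q = plate % g.plates_per_layer
        r = g.plate_rows * (q // g.blocks_c) + row
        c = g.plate_cols * (q % g.blocks_c) + col

        rules = {
            "PP": L,
            "RP": r,
            "CP": c,
            "DP": (r + c) % g.cube_rows,
            "SP": (r + L) % g.cube_rows,
            "FP": (c + L) % g.cube_cols,
            "SA": plate % g.layers,
            "SB": plate % max(g.n_plates // SB_PLATES_PER_POOL, 1),
            "SG": plate,
        }
        return {d: rules[d] for d in self.dimensions}

    # -- pool bookkeeping ------------------------------------------------

    def n_pools(self, dimension: str) -> int:
        """Number of pools in one dimension."""
        g = self.geometry
        counts = {
            "PP": g.layers,
            "RP": g.cube_rows,
            "CP": g.cube_cols,
            "DP": g.cube_rows,
            "SP": g.cube_rows,
            "FP": g.cube_cols,
            "SA": g.layers,
            "SB": max(g.n_plates // SB_PLATES_PER_POOL, 1),
            "SG": g.n_plates,
        }
        if dimension not in self.dimensions:
            raise ConfigurationError(f"dimension {dimension!r} not enabled in this design")
        return counts[dimension]

    @property
    def total_pools(self) -> int:
        """Total pool count across all enabled dimensions."""
        return sum(self.n_pools(d) for d in self.dimensions)

    def pool_index_array(self, dimension: str) -> np.ndarray:
        """Dense clone id -> pool index map for one dimension (read-only view)."""
        if dimension not in self.dimensions:
            raise ConfigurationError(f"dimension {dimension!r} not enabled in this design")
        arr = self._pool_index[dimension]
        arr.setflags(write=False)
        return arr

    def iter_pools(self) -> Iterable[PoolAddress]:
        for d in self.dimensions:
            for i in range(self.n_pools(d)):
                yield PoolAddress(d, i)

    # -- pool ids at the I/O boundary ------------------------------------

    def pool_id(self, dimension: str, index: int) -> str:
        """Human-readable pool id, e.g. ``"DP07"`` or ``"SG215"``."""
        n = self.n_pools(dimension)
        if not 0 <= index < n:
            raise KeyError(f"pool index {index} out of range [0, {n}) for {dimension}")
        width = max(2, len(str(n - 1)))
        return f"{dimension}{index:0{width}d}"

    def parse_pool_id(self, pool_id: str) -> PoolAddress | None:
        """Parse ``"DP07"`` -> PoolAddress; None if not an enabled pool id."""
        m = _POOL_ID_RE.match(pool_id.strip())
        if m is None:
            return None
        dim, idx = m.group(1), int(m.group(2))
        if dim not in self.dimensions or idx >= self.n_pools(dim):
            return None
        return PoolAddress(dim, idx)

    # -- membership queries ----------------------------------------------

    def clone_pools(self, coord: CloneCoordinate) -> dict[str, int]:
        """Pool index of one clone in every enabled dimension."""
        cid = self.geometry.clone_id(coord)
        return {d: int(self._pool_index[d][cid]) for d in self.dimensions}

    def pool_member_ids(self, address: PoolAddress) -> np.ndarray:
        """Clone ids of one pool's members, sorted ascending."""
        d = address.dimension
        if d not in self.dimensions:
            raise KeyError(f"dimension {d!r} not enabled in this design")
        if not 0 <= address.index < self.n_pools(d):
            raise KeyError(f"pool index {address.index} out of range for {d}")
        if d not in self._members_cache:
            arr = self._pool_index[d]
            order = np.argsort(arr, kind="stable")
            bounds = np.searchsorted(arr[order], np.arange(self.n_pools(d) + 1))
            self._members_cache[d] = [
                np.sort(order[bounds[i] : bounds[i + 1]]) for i in range(self.n_pools(d))
            ]
        return self._members_cache[d][address.index]

    def pool_members(self, address: PoolAddress) -> frozenset[CloneCoordinate]:
        """Member clone coordinates of one pool."""
        g = self.geometry
        return frozenset(g.coordinate(int(i)) for i in self.pool_member_ids(address))


def build_design(
    geometry: LibraryGeometry, dimensions: Sequence[str] = CUBE_DIMENSIONS
) -> PoolingDesign:
    """Construct a :class:`PoolingDesign` for the given geometry and dimensions."""
    return PoolingDesign(geometry, dimensions)


def clone_pools(design: PoolingDesign, coord: CloneCoordinate) -> Mapping[str, int]:
    """Functional alias for :meth:`PoolingDesign.clone_pools`."""
    return design.clone_pools(coord)


def pool_members(design: PoolingDesign, address: PoolAddress) -> frozenset[CloneCoordinate]:
    """Functional alias for :meth:`PoolingDesign.pool_members`."""
    return design.pool_members(address)
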