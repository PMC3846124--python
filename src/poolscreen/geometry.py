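"""Library geometry: microtiter plates conceptually stacked into a cube.

A library of ``n_plates`` plates (each ``plate_rows x plate_cols`` wells) is
arranged into ``layers`` layers of ``plates_per_layer`` plates.  Within a
layer the plates are tiled row-major into a ``blocks_r x blocks_c`` grid, so
the cube face is ``plate_rows * blocks_r`` rows by ``plate_cols * blocks_c``
columns.  Clones are addressed either by :class:`CloneCoordinate`
(plate, well row, well column) or by :class:`CubePosition` (cube row, cube
column, layer); the two are bijective for a fixed geometry.

All indices are 0-based internally.  Bench-style labels ("A1", 1-based
plates) are converted only at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, NamedTuple

__all__ = [
    "GeometryError",
    "CloneCoordinate",
    "CubePosition",
    "LibraryGeometry",
    "well_label",
    "parse_well_label",
]

_ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_WELL_RE = re.compile(r"^([A-Za-z])(\d+)$")


class GeometryError(ValueError):
    """Raised for inconsistent geometry parameters or out-of-range coordinates."""


class CloneCoordinate(NamedTuple):
    """A clone's physical address: plate index and well row/column (0-based)."""

    plate: int
    well_row: int
    well_col: int


class CubePosition(NamedTuple):
    """A clone's position in the conceptual cube: row, column, layer (0-based)."""

    r: int
    c: int
    L: int


def well_label(row: int, col: int) -> str:
    """Format a 0-based (row, col) well as a bench label like ``"A1"``."""
    if not 0 <= row < len(_ROW_LETTERS):
        raise GeometryError(f"well row {row} cannot be expressed as a letter label")
    if col < 0:
        raise GeometryError(f"well column {col} is negative")
    return f"{_ROW_LETTERS[row]}{col + 1}"


def parse_well_label(label: str) -> tuple[int, int]:
    """Parse an ``"A1"``-style well label into 0-based (row, col)."""
    m = _WELL_RE.match(label.strip())
    if m is None:
        raise GeometryError(f"malformed well label {label!r}")
    row = _ROW_LETTERS.index(m.group(1).upper())
    col = int(m.group(2)) - 1
    if col < 0:
        raise GeometryError(f"well column in label {label!r} must be >= 1")
    return row, col


@dataclass(frozen=True)
class LibraryGeometry:
    """Dimensions of the plate library and its cube arrangement.

    Defaults describe a 216-plate, 384-well library arranged as a
    36-layer, 48-row, 48-column cube (82,944 clones).
    """

    n_plates: int = 216
    plate_rows: int = 16
    plate_cols: int = 24
    layers: int = 36
    plates_per_layer: int = 6
    layer_arrangement: tuple[int, int] = (3, 2)

    def __post_init__(self) -> None:
        for name in ("n_plates", "plate_rows", "plate_cols", "layers", "plates_per_layer"):
            if getattr(self, name) < 1:
                raise GeometryError(f"{name} must be a positive count")
        br, bc = self.layer_arrangement
        if br < 1 or bc < 1:
            raise GeometryError("layer_arrangement blocks must be positive")
        if br * bc != self.plates_per_layer:
            raise GeometryError(
                f"layer_arrangement {self.layer_arrangement} does not tile "
                f"{self.plates_per_layer} plates per layer"
            )
        if self.layers * self.plates_per_layer != self.n_plates:
            raise GeometryError(
                f"layers * plates_per_layer = {self.layers * self.plates_per_layer} "
                f"!= n_plates = {self.n_plates}"
            )

    # -- derived sizes ---------------------------------------------------

    @property
    def blocks_r(self) -> int:
        return self.layer_arrangement[0]

    @property
    def blocks_c(self) -> int:
        return self.layer_arrangement[1]

    @property
    def cube_rows(self) -> int:
        return self.plate_rows * self.blocks_r

    @property
    def cube_cols(self) -> int:
        return self.plate_cols * self.blocks_c

    @property
    def wells_per_plate(self) -> int:
        return self.plate_rows * self.plate_cols

    @property
    def n_clones(self) -> int:
        """Total clone capacity of the library."""
        return self.n_plates * self.wells_per_plate

    # -- validation ------------------------------------------------------

    def validate_coordinate(self, coord: CloneCoordinate) -> None:
        plate, row, col = coord
        if not 0 <= plate < self.n_plates:
            raise GeometryError(f"plate {plate} out of range [0, {self.n_plates})")
        if not 0 <= row < self.plate_rows:
            raise GeometryError(f"well row {row} out of range [0, {self.plate_rows})")
        if not 0 <= col < self.plate_cols:
            raise GeometryError(f"well column {col} out of range [0, {self.plate_cols})")

    def validate_cube_position(self, pos: CubePosition) -> None:
        r, c, L = pos
        if not 0 <= r < self.cube_rows:
            raise GeometryError(f"cube row {r} out of range [0, {self.cube_rows})")
        if not 0 <= c < self.cube_cols:
            raise GeometryError(f"cube column {c} out of range [0, {self.cube_cols})")
        if not 0 <= L < self.layers:
            raise GeometryError(f"layer {L} out of range [0, {self.layers})")

    # -- coordinate conversions ------------------------------------------

    def to_cube(self, coord: CloneCoordinate) -> CubePosition:
        """Map a plate/well coordinate to its cube position.

        The layer is ``plate // plates_per_layer``; the within-layer slot
        ``plate % plates_per_layer`` is placed row-major into the
        ``blocks_r x blocks_c`` arrangement.
        """
        self.validate_coordinate(coord)
        plate, row, col = coord
        L = plate // self.plates_per_layer
        q = plate % self.plates_per_layer
        r = self.plate_rows * (q // self.blocks_c) + row
        c = self.plate_cols * (q % self.blocks_c) + col
        return CubePosition(r, c, L)

    def from_cube(self, pos: CubePosition) -> CloneCoordinate:
        """Inverse of :meth:`to_cube`."""
        self.validate_cube_position(pos)
        r, c, L = pos
        q = self.blocks_c * (r // self.plate_rows) + (c // self.plate_cols)
        plate = L * self.plates_per_layer + q
        return CloneCoordinate(plate, r % self.plate_rows, c % self.plate_cols)

    # -- linear clone ids ------------------------------------------------

    def clone_id(self, coord: CloneCoordinate) -> int:
        """Dense 0-based index of a clone (plate-major, then row-major wells)."""
        self.validate_coordinate(coord)
        plate, row, col = coord
        return plate * self.wells_per_plate + row * self.plate_cols + col

    def coordinate(self, clone_id: int) -> CloneCoordinate:
        """Inverse of :meth:`clone_id`."""
        if not 0 <= clone_id < self.n_clones:
            raise GeometryError(f"clone id {clone_id} out of range [0, {self.n_clones})")
        plate, rem = divmod(clone_id, self.wells_per_plate)
        row, col = divmod(rem, self.plate_cols)
        return CloneCoordinate(plate, row, col)

    def iter_clones(self) -> Iterator[CloneCoordinate]:
        """Iterate all clone coordinates in clone-id order."""
        for i in range(self.n_clones):
            yield self.coordinate(i)
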