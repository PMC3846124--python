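"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here re-derive pool membership from first principles
(plain integer arithmetic on plate/well indices) so they stay independent
of the package's vectorised implementation paths.
"""

from __future__ import annotations

import pytest

from poolscreen import CloneCoordinate, LibraryGeometry, build_design
from poolscreen.design import DIMENSIONS, SB_PLATES_PER_POOL


@pytest.fixture(scope="session")
def default_geometry() -> LibraryGeometry:
    return LibraryGeometry()


@pytest.fixture(scope="session")
def scaled_geometry() -> LibraryGeometry:
    # 8 plates of 4x6 wells, 4 layers of 2 plates, 2x1 arrangement: 192 clones
    return LibraryGeometry(
        n_plates=8,
        plate_rows=4,
        plate_cols=6,
        layers=4,
        plates_per_layer=2,
        layer_arrangement=(2, 1),
    )


@pytest.fixture(scope="session")
def scaled_design(scaled_geometry):
    return build_design(scaled_geometry, DIMENSIONS)


@pytest.fixture(scope="session")
def default_design_six(default_geometry):
    return build_design(default_geometry, ("PP", "RP", "CP", "DP", "SP", "FP"))


@pytest.fixture(scope="session")
def default_design_all(default_geometry):
    return build_design(default_geometry, DIMENSIONS)


def oracle_clone_pools(geometry: LibraryGeometry, coord: CloneCoordinate) -> dict[str, int]:
    """Pool indices of one clone, re-derived from scratch (test oracle)."""
    plate, row, col = coord
    L = plate // geometry.plates_per_layer
    q = plate % geometry.plates_per_layer
    br, bc = geometry.layer_arrangement
    r = geometry.plate_rows * (q // bc) + row
    c = geometry.plate_cols * (q % bc) + col
    cube_rows = geometry.plate_rows * br
    cube_cols = geometry.plate_cols * bc
    return {
        "PP": L,
        "RP": r,
        "CP": c,
        "DP": (r + c) % cube_rows,
        "SP": (r + L) % cube_rows,
        "FP": (c + L) % cube_cols,
        "SA": plate % geometry.layers,
        "SB": plate % max(geometry.n_plates // SB_PLATES_PER_POOL, 1),
        "SG": plate,
    }


def oracle_candidates(
    geometry: LibraryGeometry,
    positive: dict[str, set[int]],
) -> set[CloneCoordinate]:
    """Brute-force deconvolution: scan every clone position (test oracle)."""
    out = set()
    for coord in geometry.iter_clones():
        pools = oracle_clone_pools(geometry, coord)
        if all(pools[d] in positive[d] for d in positive):
            out.add(coord)
    return out
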