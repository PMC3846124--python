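"""Clone-coordinate deconvolution from per-pool calls.

A coordinate is *putative* for an allele when, in every screened dimension,
the pool containing it was called positive for that allele (a ``both`` call
counts toward either allele).  A single negative or missing dimension drops
the coordinate entirely — pools with no record are treated as negative and
logged.  An optional relaxation admits coordinates positive in all but
``allow_missing_dims`` dimensions; it is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CUBE_DIMENSIONS, ConfigurationError, PoolingDesign
from .geometry import CloneCoordinate
from .simulate import AssayDefinition

__all__ = [
    "MODES",
    "ScreenResult",
    "CandidateSet",
    "positive_pools",
    "candidates",
    "deconvolve_all",
]

logger = logging.getLogger(__name__)

#: Screening-dimension sets selectable by name.
MODES: dict[str, tuple[str, ...]] = {
    "six_dim": CUBE_DIMENSIONS,
    "opa1_8dim": CUBE_DIMENSIONS + ("SA", "SB"),
    "opa2_7dim": CUBE_DIMENSIONS + ("SG",),
}


@dataclass(frozen=True)
class ScreenResult:
    """Positive pools of one (assay, allele) across the screened dimensions."""

    assay_id: str
    allele: str
    positive_pools: Mapping[str, frozenset[int]]


@dataclass(frozen=True)
class CandidateSet:
    """Putative clone coordinates for one (assay, allele)."""

    assay_id: str
    allele: str
    coordinates: frozenset[CloneCoordinate]

    def __len__(self) -> int:
        return len(self.coordinates)

    def sorted(self) -> list[CloneCoordinate]:
        return sorted(self.coordinates)


def _check_dimensions(design: PoolingDesign, dimensions: Sequence[str]) -> tuple[str, ...]:
    dims = tuple(dimensions)
    if not dims:
        raise ConfigurationError("at least one screening dimension is required")
    missing = [d for d in dims if d not in design.dimensions]
    if missing:
        raise ConfigurationError(f"dimension(s) {missing} not enabled in the design")
    return dims


def positive_pools(
    design: PoolingDesign,
    calls: pd.DataFrame,
    assay_id: str,
    allele: str,
    dimensions: Sequence[str],
) -> ScreenResult:
    """Collect, per dimension, the pool indices called positive for an allele.

    A pool is positive when its call is the allele itself or ``both``.
    Enabled pools of the requested dimensions with no record at all are
    logged and treated as negative.
    """
    if allele not in ("snp1", "snp2"):
        raise ValueError(f"allele must be 'snp1' or 'snp2', got {allele!r}")
    dims = _check_dimensions(design, dimensions)
    sub = calls[calls["assay_id"] == assay_id]
    pos: dict[str, set[int]] = {d: set() for d in dims}
    seen: dict[str, set[int]] = {d: set() for d in dims}
    for sample_id, call in zip(sub["sample_id"], sub["call"]):
        addr = design.parse_pool_id(str(sample_id))
        if addr is None or addr.dimension not in pos:
            continue
        seen[addr.dimension].add(addr.index)
        if call == allele or call == "both":
            pos[addr.dimension].add(addr.index)
    n_missing = sum(design.n_pools(d) - len(seen[d]) for d in dims)
    if n_missing:
        logger.warning(
            "assay %s/%s: %d enabled pool(s) have no call record; treated as negative",
            assay_id,
            allele,
            n_missing,
        )
    return ScreenResult(
        assay_id=assay_id,
        allele=allele,
        positive_pools={d: frozenset(v) for d, v in pos.items()},
    )


def candidates(
    design: PoolingDesign,
    calls: pd.DataFrame,
    assay_id: str,
    allele: str,
    dimensions: Sequence[str],
    allow_missing_dims: int = 0,
) -> CandidateSet:
    """Putative coordinates: positive in every screened dimension.

    Equivalent to brute-force filtering over all clone positions; computed
    as a vectorised conjunction of per-dimension membership masks.  With
    ``allow_missing_dims = k > 0`` a coordinate qualifies when positive in
    at least ``len(dimensions) - k`` dimensions (diagnostic relaxation).
    """
    screen = positive_pools(design, calls, assay_id, allele, dimensions)
    dims = tuple(screen.positive_pools)
    g = design.geometry
    n_ok = np.zeros(g.n_clones, dtype=np.int16)
    for d in dims:
        pos = screen.positive_pools[d]
        if pos:
            mask = np.isin(design.pool_index_array(d), np.fromiter(pos, dtype=np.int64))
            n_ok += mask
    need = len(dims) - max(allow_missing_dims, 0)
    ids = np.nonzero(n_ok >= need)[0]
    coords = frozenset(g.coordinate(int(i)) for i in ids)
    return CandidateSet(assay_id=assay_id, allele=allele, coordinates=coords)


def _alleles_for(assay: AssayDefinition) -> tuple[str, ...]:
    if assay.assay_type == "intergenomic":
        return ("snp1", "snp2")
    # intragenomic / non-discriminating assays track a single allele side
    if assay.allele1_loci and not assay.allele2_loci:
        return ("snp1",)
    if assay.allele2_loci and not assay.allele1_loci:
        return ("snp2",)
    return ("snp1", "snp2")


def deconvolve_all(
    design: PoolingDesign,
    calls: pd.DataFrame,
    assays: Sequence[AssayDefinition],
    mode: str = "six_dim",
    dimensions: Sequence[str] | None = None,
    allow_missing_dims: int = 0,
) -> list[CandidateSet]:
    """Deconvolve every (assay, allele) pair under a screening mode.

    ``mode`` selects the dimension set (``six_dim``, ``opa1_8dim``,
    ``opa2_7dim``); ``mode="custom"`` uses ``dimensions`` directly.
    Intergenomic assays yield two candidate sets, single-gene assays one.
    """
    if mode == "custom":
        if dimensions is None:
            raise ConfigurationError("mode 'custom' requires explicit dimensions")
        dims: Sequence[str] = dimensions
    else:
        if mode not in MODES:
            raise ConfigurationError(f"unknown mode {mode!r}; expected {sorted(MODES)} or 'custom'")
        dims = MODES[mode]
    present = set(calls["assay_id"].unique())
    out = []
    for assay in assays:
        if assay.assay_id not in present:
            continue
        for allele in _alleles_for(assay):
            out.append(
                candidates(
                    design, calls, assay.assay_id, allele, dims, allow_missing_dims
                )
            )
    return out
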