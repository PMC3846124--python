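"""Readers and writers for the flat-file interfaces.

Conventions at the file boundary: plates are 1-based and wells use
"A1"-style labels (bench convention); everything is 0-based internally.
Writers emit TSV except the signal table, which is CSV to match
genotyping-export habits; readers sniff either delimiter.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .deconvolve import CandidateSet
from .design import PoolingDesign
from .geometry import (
    CloneCoordinate,
    GeometryError,
    LibraryGeometry,
    parse_well_label,
    well_label,
)

__all__ = [
    "FormatError",
    "read_signal_table",
    "write_signal_table",
    "read_known_coordinates",
    "write_known_coordinates",
    "write_pool_manifest",
    "write_pool_membership",
    "write_calls",
    "read_calls",
    "write_candidates",
    "read_candidates",
    "write_confirmation_report",
    "write_audit",
]

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["sample_id", "assay_id", "norm_r", "norm_theta"]


class FormatError(ValueError):
    """Raised for files whose structure does not match the expected format."""


def _sniff_sep(path: Path) -> str:
    sample = ""
    with open(path, newline="") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sample = line
                break
    if not sample:
        raise FormatError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_signal_table(path: str | Path, skip_bad: bool = False) -> pd.DataFrame:
    """Read a signal table (CSV or TSV) with the four required columns.

    Malformed numeric rows abort with their line numbers unless
    ``skip_bad`` is set, in which case they are dropped with a log message.
    Extra columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[SIGNAL_COLUMNS].copy()
    for col in ("norm_r", "norm_theta"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["norm_r", "norm_theta"]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        if not skip_bad:
            raise FormatError(f"{path}: non-numeric signal values at line(s) {lines[:10]}")
        logger.warning("%s: dropping %d malformed row(s) at line(s) %s", path, bad.sum(), lines[:10])
        df = df[~bad].reset_index(drop=True)
    df["sample_id"] = df["sample_id"].astype(str)
    df["assay_id"] = df["assay_id"].astype(str)
    return df


def write_signal_table(records: pd.DataFrame, path: str | Path) -> None:
    records[SIGNAL_COLUMNS].to_csv(path, index=False)


def _coordinate_from_row(
    row: Mapping[str, object], geometry: LibraryGeometry, context: str
) -> CloneCoordinate:
    try:
        plate = int(row["plate"]) - 1  # 1-based at the file boundary
    except (TypeError, ValueError):
        raise FormatError(f"{context}: non-integer plate {row['plate']!r}") from None
    if "well" in row and not pd.isna(row["well"]):
        try:
            r, c = parse_well_label(str(row["well"]))
        except GeometryError as exc:
            raise FormatError(f"{context}: {exc}") from None
    elif "row" in row and "col" in row:
        r, c = int(row["row"]), int(row["col"])
    else:
        raise FormatError(f"{context}: need a 'well' label or numeric 'row'/'col' columns")
    coord = CloneCoordinate(plate, r, c)
    try:
        geometry.validate_coordinate(coord)
    except GeometryError as exc:
        raise FormatError(f"{context}: {exc}") from None
    return coord


def read_known_coordinates(
    path: str | Path, geometry: LibraryGeometry
) -> dict[str, frozenset[CloneCoordinate]]:
    """Read a locus -> clone coordinate table (TSV/CSV).

    Requires columns ``locus_id``, ``plate`` (1-based) and either ``well``
    ("A1"-style) or ``row``/``col``.  Duplicate rows are deduplicated with a
    warning; out-of-range coordinates abort with row context.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    if "locus_id" not in df.columns or "plate" not in df.columns:
        raise FormatError(f"{path}: missing required column(s) among ['locus_id', 'plate']")
    out: dict[str, set[CloneCoordinate]] = {}
    n_dup = 0
    for i, row in df.iterrows():
        coord = _coordinate_from_row(row, geometry, f"{path} line {i + 2}")
        bucket = out.setdefault(str(row["locus_id"]), set())
        if coord in bucket:
            n_dup += 1
        bucket.add(coord)
    if n_dup:
        logger.warning("%s: %d duplicate coordinate row(s) deduplicated", path, n_dup)
    return {k: frozenset(v) for k, v in out.items()}


def write_known_coordinates(
    known: Mapping[str, Iterable[CloneCoordinate]], path: str | Path
) -> None:
    """Write a known-coordinates table (plate 1-based, 'A1' well labels)."""
    with open(path, "w") as fh:
        fh.write("# plate numbering is 1-based; wells use letter/number labels\n")
        fh.write("locus_id\tplate\twell\n")
        for locus in sorted(known):
            for coord in sorted(known[locus]):
                fh.write(
                    f"{locus}\t{coord.plate + 1}\t{well_label(coord.well_row, coord.well_col)}\n"
                )


def write_pool_manifest(design: PoolingDesign, path: str | Path) -> None:
    """TSV summary: dimension, pool_index, pool_id, n_clones per pool."""
    with open(path, "w") as fh:
        fh.write("dimension\tpool_index\tpool_id\tn_clones\n")
        for addr in design.iter_pools():
            pid = design.pool_id(addr.dimension, addr.index)
            fh.write(
                f"{addr.dimension}\t{addr.index}\t{pid}\t"
                f"{design.pool_member_ids(addr).size}\n"
            )


def write_pool_membership(design: PoolingDesign, path: str | Path) -> None:
    """Full membership TSV: pool_id, plate (1-based), well label. Large."""
    g = design.geometry
    with open(path, "w") as fh:
        fh.write("# plate numbering is 1-based; wells use letter/number labels\n")
        fh.write("pool_id\tplate\twell\n")
        for addr in design.iter_pools():
            pid = design.pool_id(addr.dimension, addr.index)
            for cid in design.pool_member_ids(addr):
                coord = g.coordinate(int(cid))
                fh.write(
                    f"{pid}\t{coord.plate + 1}\t{well_label(coord.well_row, coord.well_col)}\n"
                )


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("sample_id", "assay_id", "norm_r", "norm_theta", "call") if c in calls]
    calls[cols].to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    for col in ("sample_id", "assay_id", "call"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        df[col] = df[col].astype(str)
    return df


def write_candidates(candidate_sets: Sequence[CandidateSet], path: str | Path) -> None:
    """TSV of putative coordinates (plate 1-based, 'A1' well labels)."""
    with open(path, "w") as fh:
        fh.write("# plate numbering is 1-based; wells use letter/number labels\n")
        fh.write("assay_id\tallele\tplate\twell\n")
        for cs in candidate_sets:
            for coord in cs.sorted():
                fh.write(
                    f"{cs.assay_id}\t{cs.allele}\t{coord.plate + 1}\t"
                    f"{well_label(coord.well_row, coord.well_col)}\n"
                )


def read_candidates(
    path: str | Path, geometry: LibraryGeometry
) -> list[CandidateSet]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("assay_id", "allele", "plate", "well"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    grouped: dict[tuple[str, str], set[CloneCoordinate]] = {}
    for i, row in df.iterrows():
        coord = _coordinate_from_row(row, geometry, f"{path} line {i + 3}")
        grouped.setdefault((str(row["assay_id"]), str(row["allele"])), set()).add(coord)
    return [
        CandidateSet(assay_id, allele, frozenset(coords))
        for (assay_id, allele), coords in sorted(grouped.items())
    ]


def write_confirmation_report(stats: Sequence, path: str | Path) -> None:
    """TSV mirroring the confirmation-statistics layout."""

    def fmt(p):
        return "" if p is None else f"{p}"

    with open(path, "w") as fh:
        fh.write(
            "assay_id\tallele\tn_known\tn_confirmed\tpct_of_known\t"
            "n_putative\tpct_of_putative\n"
        )
        for s in stats:
            fh.write(
                f"{s.assay_id}\t{s.allele}\t{s.n_known}\t{s.n_confirmed}\t"
                f"{fmt(s.pct_of_known)}\t{s.n_putative}\t{fmt(s.pct_of_putative)}\n"
            )


def write_audit(audit: pd.DataFrame, path: str | Path) -> None:
    cols = [
        c
        for c in ("sample_id", "assay_id", "expected", "call", "norm_r", "category")
        if c in audit
    ]
    audit[cols].to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
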