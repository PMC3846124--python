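"""Assessment of screening results against known clone coordinates.

Three layers: per-(assay, allele) confirmation statistics (known vs
putative vs confirmed counts with percentages), a per-pool audit comparing
observed calls with those expected from the known coordinates, and the
two-step plate filter that narrows candidate lists to plates confirmed to
carry a locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import PoolingDesign
from .deconvolve import CandidateSet, MODES, candidates as _candidates
from .geometry import CloneCoordinate, LibraryGeometry
from .scoring import ScoringThresholds, score_table
from .simulate import (
    AssayDefinition,
    LocusPlacement,
    SignalModelParams,
    simulate_screen,
)

__all__ = [
    "AUDIT_CATEGORIES",
    "ConfirmationStats",
    "confirm",
    "expected_calls",
    "audit_pools",
    "plate_filter",
    "recovery_experiment",
]

AUDIT_CATEGORIES = (
    "consistent",
    "both_for_single",
    "conflicting",
    "unexpected_positive",
    "below_threshold",
)


@dataclass(frozen=True)
class ConfirmationStats:
    """Known / confirmed / putative counts for one (assay, allele).

    Percentages are reported to one decimal; a zero denominator leaves the
    percentage as None.
    """

    assay_id: str
    allele: str
    n_known: int
    n_confirmed: int
    n_putative: int
    pct_of_known: float | None
    pct_of_putative: float | None


def _pct(numer: int, denom: int) -> float | None:
    return round(100.0 * numer / denom, 1) if denom else None


def confirm(candidate_set: CandidateSet, known: Iterable[CloneCoordinate]) -> ConfirmationStats:
    """Compare a putative coordinate set with the known carriers of its locus."""
    known_set = frozenset(known)
    confirmed = candidate_set.coordinates & known_set
    return ConfirmationStats(
        assay_id=candidate_set.assay_id,
        allele=candidate_set.allele,
        n_known=len(known_set),
        n_confirmed=len(confirmed),
        n_putative=len(candidate_set.coordinates),
        pct_of_known=_pct(len(confirmed), len(known_set)),
        pct_of_putative=_pct(len(confirmed), len(candidate_set.coordinates)),
    )


def expected_calls(
    design: PoolingDesign,
    known: Mapping[str, Iterable[CloneCoordinate]],
    assay: AssayDefinition,
    dimensions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-pool categories predicted from known coordinates alone.

    For each pool the true carrier counts (a, b) over the assay's on-target
    loci determine the category: a>0,b=0 -> snp1; a=0,b>0 -> snp2; both
    positive -> both; otherwise none.  Cross-reactive loci are deliberately
    excluded — they are what the audit flags as unexpected positives.
    """
    g = design.geometry
    dims = tuple(dimensions) if dimensions is not None else design.dimensions

    def ids_for(loci: Iterable[str]) -> np.ndarray:
        out: set[int] = set()
        for locus in loci:
            if locus not in known:
                raise ValueError(f"assay references locus {locus!r} absent from known coordinates")
            out.update(g.clone_id(c) for c in known[locus])
        return np.array(sorted(out), dtype=np.int64)

    ids1 = ids_for(assay.allele1_loci)
    ids2 = ids_for(assay.allele2_loci)
    rows = []
    for dim in dims:
        pool_of = design.pool_index_array(dim)
        n = design.n_pools(dim)
        a = np.bincount(pool_of[ids1], minlength=n) if ids1.size else np.zeros(n, int)
        b = np.bincount(pool_of[ids2], minlength=n) if ids2.size else np.zeros(n, int)
        for idx in range(n):
            cat = (
                "both"
                if a[idx] and b[idx]
                else "snp1"
                if a[idx]
                else "snp2"
                if b[idx]
                else "none"
            )
            rows.append((design.pool_id(dim, idx), assay.assay_id, cat))
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "expected"])


def audit_pools(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    records: pd.DataFrame,
    thresholds: ScoringThresholds = ScoringThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Categorise every (pool, assay) pair by observed-vs-expected agreement.

    Categories (mutually exclusive, exhaustive):

    * ``consistent`` — observed equals expected;
    * ``unexpected_positive`` — a call where no carrier was expected;
    * ``below_threshold`` — an expected carrier pool whose intensity failed
      ``r_min`` and was therefore not scored;
    * ``both_for_single`` — a ``both`` call where a single SNP was expected
      (does not drop any coordinate, but may enlarge candidate lists);
    * ``conflicting`` — any other disagreement; such calls remove known
      coordinates from candidacy.

    Returns the merged per-pool audit table and per-assay category counts.
    """
    key = ["sample_id", "assay_id"]
    obs = observed[key + ["call"]]
    exp = expected[key + ["expected"]]
    rec = records[key + ["norm_r"]]
    merged = obs.merge(exp, on=key, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        n = int((merged["_merge"] != "both").sum())
        raise ValueError(f"observed and expected tables disagree on {n} (pool, assay) pair(s)")
    merged = merged.drop(columns="_merge").merge(rec, on=key, how="left")

    call = merged["call"].to_numpy(dtype=object)
    exp_cat = merged["expected"].to_numpy(dtype=object)
    r = merged["norm_r"].to_numpy(dtype=float)
    single = np.isin(exp_cat, ("snp1", "snp2"))
    category = np.select(
        [
            call == exp_cat,
            (exp_cat == "none") & (call != "none"),
            (exp_cat != "none") & (call == "none") & (r < thresholds.r_min),
            (call == "both") & single,
        ],
        ["consistent", "unexpected_positive", "below_threshold", "both_for_single"],
        default="conflicting",
    )
    audit = merged.assign(category=category)
    counts = (
        audit.groupby(["assay_id", "category"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(AUDIT_CATEGORIES), fill_value=0)
        .reset_index()
    )
    return audit, counts


def plate_filter(candidate_set: CandidateSet, positive_plates: Iterable[int]) -> CandidateSet:
    """Retain candidates on plates confirmed positive for the locus."""
    plates = set(positive_plates)
    kept = frozenset(c for c in candidate_set.coordinates if c.plate in plates)
    return CandidateSet(candidate_set.assay_id, candidate_set.allele, kept)


def recovery_experiment(
    geometry: LibraryGeometry,
    dimensions: Sequence[str],
    miss_rate: float,
    n_replicates: int = 200,
    loci_per_replicate: int = 10,
    seed: int = 0,
    thresholds: ScoringThresholds = ScoringThresholds(),
) -> float:
    """Measured recovery of single-copy loci under per-pool carrier misses.

    Plants ``loci_per_replicate`` single-copy single-gene loci per
    replicate, injects a per-carrier-pool miss rate (dropout) of
    ``miss_rate``, runs the full simulate -> score -> deconvolve pipeline
    and returns the fraction of planted clones recovered.  For a
    single-copy locus each of the ``d`` screened dimensions fails
    independently, so recovery approaches ``(1 - miss_rate) ** d``.
    """
    from .design import build_design

    design = build_design(geometry, dimensions)
    rng = np.random.default_rng(seed)
    params = SignalModelParams(r_residual_sd=0.0, theta_sd=0.0, dropout_prob=miss_rate)
    n_hit = 0
    n_total = 0
    for _ in range(n_replicates):
        placements = {}
        assays = []
        for j in range(loci_per_replicate):
            locus = f"locus{j}"
            cid = int(rng.integers(geometry.n_clones))
            placements[locus] = LocusPlacement(
                locus, "A", frozenset({geometry.coordinate(cid)})
            )
            assays.append(
                AssayDefinition(f"assay{j}", "intragenomic", allele1_loci=(locus,))
            )
        sim = simulate_screen(design, placements, assays, params, rng=rng)
        calls = score_table(sim.records, thresholds)
        for j in range(loci_per_replicate):
            cand = _candidates(design, calls, f"assay{j}", "snp1", dimensions)
            (planted,) = placements[f"locus{j}"].clones
            n_hit += planted in cand.coordinates
            n_total += 1
    return n_hit / n_total
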