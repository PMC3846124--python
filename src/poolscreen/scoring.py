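"""Threshold-based scoring of pooled genotyping signals.

A record is called ``none`` when its normalized intensity falls below
``r_min``; otherwise Theta at or below ``theta_low`` is ``snp1``, at or
above ``theta_high`` is ``snp2``, and strictly in between is ``both``.

Boundary semantics: Theta exactly equal to ``theta_low`` or ``theta_high``
is a single-SNP call, never ``both``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import PoolingDesign

__all__ = [
    "CALLS",
    "ScoringThresholds",
    "score_record",
    "score_table",
    "fold_theta",
    "cluster_baseline",
    "threshold_sweep",
]

logger = logging.getLogger(__name__)

CALLS = ("none", "snp1", "snp2", "both")


@dataclass(frozen=True)
class ScoringThresholds:
    """Intensity and Theta thresholds of the pool scoring rule."""

    r_min: float = 0.2
    theta_low: float = 0.05
    theta_high: float = 0.95

    def __post_init__(self) -> None:
        if self.r_min <= 0:
            raise ValueError(f"r_min must be positive, got {self.r_min}")
        if not 0.0 <= self.theta_low < self.theta_high <= 1.0:
            raise ValueError(
                f"need 0 <= theta_low < theta_high <= 1, got "
                f"({self.theta_low}, {self.theta_high})"
            )


def _validate_signal(norm_r: float, norm_theta: float) -> None:
    if norm_r < 0 or not np.isfinite(norm_r):
        raise ValueError(f"norm_r = {norm_r} must be a finite non-negative number")
    if not 0.0 <= norm_theta <= 1.0:
        raise ValueError(f"norm_theta = {norm_theta} outside [0, 1]")


def score_record(
    norm_r: float,
    norm_theta: float,
    thresholds: ScoringThresholds = ScoringThresholds(),
) -> str:
    """Call one (norm_r, norm_theta) signal: none / snp1 / snp2 / both."""
    _validate_signal(norm_r, norm_theta)
    if norm_r < thresholds.r_min:
        return "none"
    if norm_theta <= thresholds.theta_low:
        return "snp1"
    if norm_theta >= thresholds.theta_high:
        return "snp2"
    return "both"


def score_table(
    records: pd.DataFrame,
    thresholds: ScoringThresholds = ScoringThresholds(),
) -> pd.DataFrame:
    """Score every record; returns a copy with a ``call`` column appended."""
    for col in ("norm_r", "norm_theta"):
        if col not in records.columns:
            raise ValueError(f"records table lacks required column {col!r}")
    r = records["norm_r"].to_numpy(dtype=float)
    theta = records["norm_theta"].to_numpy(dtype=float)
    bad = (r < 0) | ~np.isfinite(r) | (theta < 0) | (theta > 1) | ~np.isfinite(theta)
    if bad.any():
        idx = records.index[bad][:5].tolist()
        raise ValueError(
            f"{int(bad.sum())} record(s) with invalid norm_r/norm_theta "
            f"(first offending rows: {idx})"
        )
    call = np.select(
        [r < thresholds.r_min, theta <= thresholds.theta_low, theta >= thresholds.theta_high],
        ["none", "snp1", "snp2"],
        default="both",
    )
    out = records.copy()
    out["call"] = call
    return out


def fold_theta(theta):
    """Fold Theta about 0.5: ``0.5 - |0.5 - theta|``, mapping [0,1] onto [0,0.5].

    Symmetric alleles collapse onto one side so the single-SNP /
    both-SNP separation of many assays can be inspected together.
    Accepts scalars or arrays.
    """
    arr = np.asarray(theta, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("theta values must lie in [0, 1]")
    folded = 0.5 - np.abs(0.5 - arr)
    return float(folded) if np.isscalar(theta) else folded


def cluster_baseline(
    records: pd.DataFrame,
    n_components: int = 3,
    thresholds: ScoringThresholds = ScoringThresholds(),
    seed: int = 0,
) -> pd.DataFrame:
    """Clustering stand-in for a genotype-call-area caller.

    Records below ``r_min`` are called ``none``.  The remaining Theta values
    are partitioned into up to ``n_components`` 1-D k-means clusters; after
    ordering the cluster means, the lowest cluster maps to ``snp1``, the
    highest to ``snp2`` and anything in between to ``both``.  This is a
    deliberately simple comparator, not a reproduction of any proprietary
    caller.
    """
    scored = score_table(records, thresholds)  # validates input, gives fallback calls
    r = scored["norm_r"].to_numpy(dtype=float)
    theta = scored["norm_theta"].to_numpy(dtype=float)
    passing = r >= thresholds.r_min
    if passing.sum() < n_components:
        warnings.warn(
            f"only {int(passing.sum())} record(s) pass r_min; "
            "falling back to the threshold rule",
            stacklevel=2,
        )
        return scored
    labels = _kmeans_1d(theta[passing], n_components, seed)
    order = np.argsort([theta[passing][labels == k].mean() for k in range(n_components)])
    rank_of = np.empty(n_components, dtype=int)
    rank_of[order] = np.arange(n_components)
    names = np.array(
        ["snp1"] + ["both"] * (n_components - 2) + ["snp2"]
        if n_components >= 2
        else ["snp1"]
    )
    call = np.full(len(scored), "none", dtype=object)
    call[passing] = names[rank_of[labels]]
    out = records.copy()
    out["call"] = call
    return out


def _kmeans_1d(values: np.ndarray, k: int, seed: int, n_iter: int = 100) -> np.ndarray:
    """Plain Lloyd k-means on 1-D data with quantile initialisation."""
    rng = np.random.default_rng(seed)
    centers = np.quantile(values, np.linspace(0, 1, k)) + rng.normal(0, 1e-9, k)
    for _ in range(n_iter):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[labels == j].mean() if (labels == j).any() else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)


def threshold_sweep(
    records: pd.DataFrame,
    windows: Sequence[tuple[float, float]],
    design: PoolingDesign,
    dimensions: Sequence[str],
    r_min: float = 0.2,
) -> pd.DataFrame:
    """Re-score and deconvolve under each (theta_low, theta_high) window.

    Returns one row per window with the number of pools called ``both`` and
    the total number of putative coordinates across all (assay, allele)
    pairs.  For nested windows the both-pool count is non-decreasing as the
    window widens; non-nested windows are allowed but carry no such
    guarantee.
    """
    from .deconvolve import candidates  # local import to avoid a cycle

    out_rows = []
    for lo, hi in windows:
        th = ScoringThresholds(r_min=r_min, theta_low=lo, theta_high=hi)
        calls = score_table(records, th)
        n_both = int((calls["call"] == "both").sum())
        n_coords = 0
        for assay_id in calls["assay_id"].unique():
            for allele in ("snp1", "snp2"):
                cand = candidates(design, calls, assay_id, allele, dimensions)
                n_coords += len(cand.coordinates)
        out_rows.append((lo, hi, n_both, n_coords))
    return pd.DataFrame(
        out_rows, columns=["theta_low", "theta_high", "n_both_pools", "n_putative_coordinates"]
    )
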