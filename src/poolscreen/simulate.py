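"""Synthetic pooled-genotyping signals for planted loci.

Generates per-pool (normalized R, normalized Theta) tables so that scoring
and deconvolution can be exercised without real genotyping data.  The model:

* pools with no effective carrier give residual intensity
  (``norm_r ~ N(r_residual_mean, r_residual_sd)`` truncated at 0) and an
  uninformative uniform Theta;
* pools with ``a`` allele-1 and ``b`` allele-2 effective carriers give a
  saturating intensity ``r_max * (1 - exp(-kappa * (a + b)))`` plus noise and
  ``theta = b / (a + b)`` plus Gaussian noise, clamped to [0, 1];
* each carrier clone drops out of each pool independently with a per-clone
  probability (representation failure / pooling omission), so a pool with k
  carriers of one allele is lost with probability ``dropout_prob ** k``.

Setting the standard deviations to zero gives fully deterministic signals
("noise off"); dropout_prob = 0 disables representation failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import PoolingDesign
from .geometry import CloneCoordinate

__all__ = [
    "ASSAY_TYPES",
    "GENOTYPES",
    "SignalModelParams",
    "LocusPlacement",
    "AssayDefinition",
    "SimResult",
    "place_locus",
    "simulate_pool_signal",
    "simulate_screen",
    "simulate_plant_sample",
    "noise_free",
]

ASSAY_TYPES = ("intergenomic", "intragenomic", "non_discriminating")
GENOTYPES = ("allele1_homozygous", "allele2_homozygous", "heterozygous_or_both", "null")

SIGNAL_COLUMNS = ["sample_id", "assay_id", "norm_r", "norm_theta"]


@dataclass(frozen=True)
class SignalModelParams:
    """Noise, saturation and dropout parameters of the signal model."""

    r_residual_mean: float = 0.05
    r_residual_sd: float = 0.02
    r_max: float = 1.0
    kappa: float = 1.0
    theta_sd: float = 0.02
    dropout_prob: float = 0.03
    weak_clones: frozenset[CloneCoordinate] = field(default_factory=frozenset)
    weak_dropout_prob: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "weak_dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        for name in ("r_residual_mean", "r_residual_sd", "r_max", "kappa", "theta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def noise_free(params: SignalModelParams | None = None, **overrides) -> SignalModelParams:
    """A copy of ``params`` with all noise and dropout switched off."""
    base = params or SignalModelParams()
    kwargs = {
        "r_residual_sd": 0.0,
        "theta_sd": 0.0,
        "dropout_prob": 0.0,
        "weak_dropout_prob": 0.0,
        "weak_clones": frozenset(),
    }
    kwargs.update(overrides)
    return replace(base, **kwargs)


@dataclass(frozen=True)
class LocusPlacement:
    """A locus planted on a set of library clones."""

    locus_id: str
    genome_class: str  # "A" or "C"
    clones: frozenset[CloneCoordinate]

    @property
    def copy_number(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class AssayDefinition:
    """One SNP assay: which loci light up on which allele side.

    ``off_target_loci`` maps locus id -> "snp1" or "snp2" for loci the assay
    cross-reacts with (spurious signal on the stated allele side).
    """

    assay_id: str
    assay_type: str
    allele1_loci: tuple[str, ...] = ()
    allele2_loci: tuple[str, ...] = ()
    off_target_loci: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"assay_type {self.assay_type!r} not in {ASSAY_TYPES}")
        for locus, side in self.off_target_loci.items():
            if side not in ("snp1", "snp2"):
                raise ValueError(f"off-target side {side!r} for {locus!r} must be snp1/snp2")


@dataclass(frozen=True)
class SimResult:
    """A simulated screen: the observable signal table plus ground truth.

    ``records`` has columns sample_id, assay_id, norm_r, norm_theta.
    ``truth`` additionally carries raw on-target carrier counts (a_true,
    b_true), effective post-dropout counts including cross-reactivity
    (a_eff, b_eff) and the expected category of each pool.
    """

    records: pd.DataFrame
    truth: pd.DataFrame


def place_locus(
    design: PoolingDesign,
    copy_number: int,
    rng: np.random.Generator,
    locus_id: str = "locus",
    genome_class: str = "A",
) -> LocusPlacement:
    """Plant a locus on ``copy_number`` distinct uniformly-chosen clones."""
    if copy_number < 0:
        raise ValueError(f"copy_number must be >= 0, got {copy_number}")
    g = design.geometry
    if copy_number > g.n_clones:
        raise ValueError(f"copy_number {copy_number} exceeds library size {g.n_clones}")
    ids = rng.choice(g.n_clones, size=copy_number, replace=False)
    clones = frozenset(g.coordinate(int(i)) for i in ids)
    return LocusPlacement(locus_id, genome_class, clones)


def _category(a: int, b: int) -> str:
    if a > 0 and b > 0:
        return "both"
    if a > 0:
        return "snp1"
    if b > 0:
        return "snp2"
    return "none"


def simulate_pool_signal(
    a: int,
    b: int,
    params: SignalModelParams,
    rng: np.random.Generator,
    apply_dropout: bool = True,
) -> tuple[float, float]:
    """Signal for a pool with ``a``/``b`` raw carriers of each allele.

    With ``apply_dropout`` each carrier survives independently with
    probability ``1 - dropout_prob`` (binomial thinning) before the signal is
    generated; pass ``apply_dropout=False`` when counts are already thinned.
    """
    if a < 0 or b < 0:
        raise ValueError("carrier counts must be non-negative")
    if apply_dropout and params.dropout_prob > 0:
        a = int(rng.binomial(a, 1.0 - params.dropout_prob)) if a else 0
        b = int(rng.binomial(b, 1.0 - params.dropout_prob)) if b else 0
    total = a + b
    if total == 0:
        norm_r = params.r_residual_mean + (
            rng.normal(0.0, params.r_residual_sd) if params.r_residual_sd > 0 else 0.0
        )
        norm_theta = float(rng.uniform())
    else:
        norm_r = params.r_max * (1.0 - np.exp(-params.kappa * total))
        if params.r_residual_sd > 0:
            norm_r += rng.normal(0.0, params.r_residual_sd)
        norm_theta = b / total
        if params.theta_sd > 0:
            norm_theta += rng.normal(0.0, params.theta_sd)
    return max(float(norm_r), 0.0), min(max(float(norm_theta), 0.0), 1.0)


def _carrier_ids(
    placements: Mapping[str, LocusPlacement],
    loci: Iterable[str],
    design: PoolingDesign,
) -> np.ndarray:
    ids: set[int] = set()
    g = design.geometry
    for locus in loci:
        if locus not in placements:
            raise ValueError(f"assay references unknown locus {locus!r}")
        ids.update(g.clone_id(c) for c in placements[locus].clones)
    return np.array(sorted(ids), dtype=np.int64)


def simulate_screen(
    design: PoolingDesign,
    placements: Mapping[str, LocusPlacement] | Sequence[LocusPlacement],
    assays: Sequence[AssayDefinition],
    params: SignalModelParams,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Simulate one genotyping run over every enabled pool and every assay.

    Returns one record per (pool, assay).  Deterministic for a fixed
    ``params.seed`` (or a caller-supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if not isinstance(placements, Mapping):
        placements = {p.locus_id: p for p in placements}
    g = design.geometry

    weak = np.zeros(g.n_clones, dtype=bool)
    for coord in params.weak_clones:
        weak[g.clone_id(coord)] = True
    keep_prob = np.where(weak, 1.0 - params.weak_dropout_prob, 1.0 - params.dropout_prob)

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for assay in assays:
        on1 = _carrier_ids(placements, assay.allele1_loci, design)
        on2 = _carrier_ids(placements, assay.allele2_loci, design)
        off1 = _carrier_ids(
            placements, (l for l, s in assay.off_target_loci.items() if s == "snp1"), design
        )
        off2 = _carrier_ids(
            placements, (l for l, s in assay.off_target_loci.items() if s == "snp2"), design
        )
        sig1 = np.union1d(on1, off1)
        sig2 = np.union1d(on2, off2)
        for dim in design.dimensions:
            pool_of = design.pool_index_array(dim)
            n = design.n_pools(dim)
            a_true = np.bincount(pool_of[on1], minlength=n) if on1.size else np.zeros(n, int)
            b_true = np.bincount(pool_of[on2], minlength=n) if on2.size else np.zeros(n, int)
            # independent per-(clone, pool) survival: one draw per carrier per dimension
            kept1 = sig1[rng.random(sig1.size) < keep_prob[sig1]] if sig1.size else sig1
            kept2 = sig2[rng.random(sig2.size) < keep_prob[sig2]] if sig2.size else sig2
            a_eff = np.bincount(pool_of[kept1], minlength=n) if kept1.size else np.zeros(n, int)
            b_eff = np.bincount(pool_of[kept2], minlength=n) if kept2.size else np.zeros(n, int)
            for idx in range(n):
                sample = design.pool_id(dim, idx)
                r, theta = simulate_pool_signal(
                    int(a_eff[idx]), int(b_eff[idx]), params, rng, apply_dropout=False
                )
                rows.append((sample, assay.assay_id, r, theta))
                truth_rows.append(
                    (
                        sample,
                        assay.assay_id,
                        dim,
                        idx,
                        int(a_true[idx]),
                        int(b_true[idx]),
                        int(a_eff[idx]),
                        int(b_eff[idx]),
                        _category(int(a_eff[idx]), int(b_eff[idx])),
                    )
                )
    records = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id",
            "assay_id",
            "dimension",
            "pool_index",
            "a_true",
            "b_true",
            "a_eff",
            "b_eff",
            "expected",
        ],
    )
    return SimResult(records=records, truth=truth)


def simulate_plant_sample(
    genotype: str,
    params: SignalModelParams,
    rng: np.random.Generator,
    sample_id: str = "plant",
    assay_id: str = "assay",
) -> pd.DataFrame:
    """Signal for a single plant DNA sample of the given genotype class.

    Theta is centred at 0 / 1 / 0.5 for the homozygous and
    heterozygous-or-both classes; the null genotype gives residual
    intensity only.
    """
    counts = {
        "allele1_homozygous": (1, 0),
        "allele2_homozygous": (0, 1),
        "heterozygous_or_both": (1, 1),
        "null": (0, 0),
    }
    if genotype not in counts:
        raise ValueError(f"genotype {genotype!r} not in {GENOTYPES}")
    a, b = counts[genotype]
    r, theta = simulate_pool_signal(a, b, params, rng, apply_dropout=False)
    return pd.DataFrame([(sample_id, assay_id, r, theta)], columns=SIGNAL_COLUMNS)
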