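"""Evaluation layer: confirmation stats, pool audit, plate filter, recovery."""

import numpy as np
import pandas as pd
import pytest

from poolscreen import (
    AUDIT_CATEGORIES,
    AssayDefinition,
    CandidateSet,
    CloneCoordinate,
    ScoringThresholds,
    audit_pools,
    confirm,
    deconvolve_all,
    expected_calls,
    noise_free,
    place_locus,
    plate_filter,
    recovery_experiment,
    score_table,
    simulate_screen,
)

CUBE = ("PP", "RP", "CP", "DP", "SP", "FP")


def _cs(coords, assay="a", allele="snp1"):
    return CandidateSet(assay, allele, frozenset(coords))


class TestConfirm:
    def test_all_known_in_putative(self):
        known = [CloneCoordinate(0, 0, i) for i in range(10)]
        putative = known + [CloneCoordinate(1, 0, i) for i in range(4)]
        stats = confirm(_cs(putative), known)
        assert (stats.n_known, stats.n_confirmed, stats.n_putative) == (10, 10, 14)
        assert stats.pct_of_known == 100.0
        assert stats.pct_of_putative == 71.4

    def test_large_putative_list(self):
        known = [CloneCoordinate(0, 0, i % 24) if i < 24 else CloneCoordinate(1, i // 24, i % 24)
                 for i in range(62)]
        confirmed = known[:58]
        shadows = [CloneCoordinate(p, r, c)
                   for p in range(30, 180) for r in range(9) for c in range(9)][: 12114 - 58]
        stats = confirm(_cs(confirmed + shadows), known)
        assert (stats.n_known, stats.n_confirmed, stats.n_putative) == (62, 58, 12114)
        assert stats.pct_of_known == 93.5
        assert stats.pct_of_putative == 0.5

    def test_empty_putative(self):
        stats = confirm(_cs([]), [CloneCoordinate(0, 0, 0)])
        assert stats.n_confirmed == 0
        assert stats.pct_of_known == 0.0
        assert stats.pct_of_putative is None

    def test_empty_known(self):
        stats = confirm(_cs([CloneCoordinate(0, 0, 0)]), [])
        assert stats.pct_of_known is None
        assert stats.pct_of_putative == 0.0


@pytest.fixture(scope="module")
def screen(scaled_design):
    rng = np.random.default_rng(31)
    placements = {
        "gA": place_locus(scaled_design, 10, rng, "gA", "A"),
        "gC": place_locus(scaled_design, 15, rng, "gC", "C"),
    }
    assay = AssayDefinition("ig", "intergenomic", ("gA",), ("gC",))
    sim = simulate_screen(scaled_design, placements, [assay], noise_free())
    known = {k: v.clones for k, v in placements.items()}
    return placements, assay, sim, known


class TestExpectedCalls:
    def test_matches_simulator_truth(self, scaled_design, screen):
        placements, assay, sim, known = screen
        exp = expected_calls(scaled_design, known, assay)
        merged = exp.merge(sim.truth, on=["sample_id", "assay_id"], suffixes=("", "_sim"))
        assert len(merged) == len(exp) == len(sim.truth)
        assert (merged["expected"] == merged["expected_sim"]).all()

    def test_pool_with_both_homoeologs(self, scaled_design):
        g = scaled_design.geometry
        c1, c2 = g.coordinate(0), g.coordinate(1)  # same plate: share all pools? no — same PP
        known = {"gA": frozenset({c1}), "gC": frozenset({c2})}
        assay = AssayDefinition("ig", "intergenomic", ("gA",), ("gC",))
        exp = expected_calls(scaled_design, known, assay, dimensions=("PP",))
        assert exp.loc[exp["sample_id"] == "PP00", "expected"].item() == "both"

    def test_empty_pool_is_none(self, scaled_design):
        known = {"gA": frozenset(), "gC": frozenset()}
        assay = AssayDefinition("ig", "intergenomic", ("gA",), ("gC",))
        exp = expected_calls(scaled_design, known, assay)
        assert (exp["expected"] == "none").all()

    def test_unknown_locus_rejected(self, scaled_design):
        assay = AssayDefinition("ig", "intergenomic", ("ghost",), ())
        with pytest.raises(ValueError, match="ghost"):
            expected_calls(scaled_design, {}, assay)


class TestAuditPools:
    def test_noise_free_all_consistent(self, scaled_design, screen):
        _, assay, sim, known = screen
        calls = score_table(sim.records)
        exp = expected_calls(scaled_design, known, assay)
        audit, counts = audit_pools(calls, exp, sim.records)
        assert (audit["category"] == "consistent").all()
        row = counts.set_index("assay_id").loc["ig"]
        assert row["consistent"] == len(audit)

    def test_categories_partition(self, scaled_design, screen):
        placements, assay, sim, known = screen
        rng = np.random.default_rng(0)
        noisy = sim.records.copy()
        noisy["norm_r"] = np.clip(noisy["norm_r"] + rng.normal(0, 0.2, len(noisy)), 0, None)
        noisy["norm_theta"] = np.clip(
            noisy["norm_theta"] + rng.normal(0, 0.2, len(noisy)), 0, 1
        )
        calls = score_table(noisy)
        exp = expected_calls(scaled_design, known, assay)
        audit, counts = audit_pools(calls, exp, noisy)
        assert audit["category"].isin(AUDIT_CATEGORIES).all()
        assert counts[list(AUDIT_CATEGORIES)].to_numpy().sum() == len(audit)

    def test_below_threshold_counts_match_dropout(self, scaled_design, screen):
        placements, assay, sim, known = screen
        # re-simulate with heavy dropout, noise otherwise off
        params = noise_free(dropout_prob=0.5)
        rng = np.random.default_rng(4)
        sim2 = simulate_screen(scaled_design, placements, [assay], params, rng=rng)
        calls = score_table(sim2.records)
        exp = expected_calls(scaled_design, known, assay)
        audit, _ = audit_pools(calls, exp, sim2.records)
        # pools whose carriers all dropped: expected != none but a_eff+b_eff == 0
        truth = sim2.truth.set_index("sample_id")
        lost = audit[audit["category"] == "below_threshold"]["sample_id"]
        for pid in lost:
            assert truth.loc[pid, "a_eff"] + truth.loc[pid, "b_eff"] == 0
        n_all_dropped = (
            (truth["a_true"] + truth["b_true"] > 0)
            & (truth["a_eff"] + truth["b_eff"] == 0)
        ).sum()
        assert len(lost) == n_all_dropped

    def test_conflicting_single_vs_other_single(self):
        observed = pd.DataFrame(
            [("PP00", "a", "snp2")], columns=["sample_id", "assay_id", "call"]
        )
        expected = pd.DataFrame(
            [("PP00", "a", "snp1")], columns=["sample_id", "assay_id", "expected"]
        )
        records = pd.DataFrame(
            [("PP00", "a", 0.8, 0.99)],
            columns=["sample_id", "assay_id", "norm_r", "norm_theta"],
        )
        audit, _ = audit_pools(observed, expected, records)
        assert audit.loc[0, "category"] == "conflicting"

    def test_both_for_single_category(self):
        observed = pd.DataFrame(
            [("PP00", "a", "both")], columns=["sample_id", "assay_id", "call"]
        )
        expected = pd.DataFrame(
            [("PP00", "a", "snp1")], columns=["sample_id", "assay_id", "expected"]
        )
        records = pd.DataFrame(
            [("PP00", "a", 0.8, 0.5)],
            columns=["sample_id", "assay_id", "norm_r", "norm_theta"],
        )
        audit, _ = audit_pools(observed, expected, records)
        assert audit.loc[0, "category"] == "both_for_single"

    def test_unexpected_positive_category(self):
        observed = pd.DataFrame(
            [("PP00", "a", "snp1")], columns=["sample_id", "assay_id", "call"]
        )
        expected = pd.DataFrame(
            [("PP00", "a", "none")], columns=["sample_id", "assay_id", "expected"]
        )
        records = pd.DataFrame(
            [("PP00", "a", 0.8, 0.01)],
            columns=["sample_id", "assay_id", "norm_r", "norm_theta"],
        )
        audit, _ = audit_pools(observed, expected, records)
        assert audit.loc[0, "category"] == "unexpected_positive"

    def test_index_mismatch_rejected(self):
        observed = pd.DataFrame(
            [("PP00", "a", "snp1")], columns=["sample_id", "assay_id", "call"]
        )
        expected = pd.DataFrame(
            [("PP01", "a", "snp1")], columns=["sample_id", "assay_id", "expected"]
        )
        records = pd.DataFrame(
            [("PP00", "a", 0.8, 0.01)],
            columns=["sample_id", "assay_id", "norm_r", "norm_theta"],
        )
        with pytest.raises(ValueError):
            audit_pools(observed, expected, records)


class TestPlateFilter:
    def test_all_plates_identity(self, scaled_geometry):
        coords = [scaled_geometry.coordinate(i) for i in range(0, 192, 13)]
        cs = _cs(coords)
        out = plate_filter(cs, range(scaled_geometry.n_plates))
        assert out.coordinates == cs.coordinates

    def test_empty_plates_empty(self, scaled_geometry):
        cs = _cs([scaled_geometry.coordinate(5)])
        assert len(plate_filter(cs, [])) == 0

    def test_removes_off_plate_shadows(self, scaled_design):
        rng = np.random.default_rng(13)
        placements = {"g": place_locus(scaled_design, 6, rng, "g")}
        assays = [AssayDefinition("sg", "intragenomic", allele1_loci=("g",))]
        sim = simulate_screen(scaled_design, placements, assays, noise_free())
        calls = score_table(sim.records)
        (cand,) = deconvolve_all(scaled_design, calls, assays, mode="six_dim")
        true_plates = {c.plate for c in placements["g"].clones}
        filtered = plate_filter(cand, true_plates)
        assert placements["g"].clones <= filtered.coordinates
        assert all(c.plate in true_plates for c in filtered.coordinates)


class TestRecovery:
    def test_perfect_data_full_recovery(self, scaled_geometry):
        rate = recovery_experiment(
            scaled_geometry, CUBE, miss_rate=0.0, n_replicates=5,
            loci_per_replicate=4, seed=0,
        )
        assert rate == 1.0

    def test_recovery_matches_power_law(self, scaled_geometry):
        # with per-carrier-pool miss rate f, recovery over d dimensions ~ (1-f)^d
        f, d = 0.2, len(CUBE)
        n_rep, per_rep = 120, 10
        rate = recovery_experiment(
            scaled_geometry, CUBE, miss_rate=f, n_replicates=n_rep,
            loci_per_replicate=per_rep, seed=1,
        )
        expected = (1 - f) ** d
        se = np.sqrt(expected * (1 - expected) / (n_rep * per_rep))
        assert abs(rate - expected) < 4 * se
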