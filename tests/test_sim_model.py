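"""Tests for the penetrance disease model and the count-level simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwaspower import (
    InfeasibleTargetError,
    SimConfig,
    SnpDataset,
    calibrate_or,
    expand_to_individuals,
    genotype_dists_given_status,
    hwe_probs,
    paper2024,
    simulate_dataset,
    solve_baseline_odds,
)
from gwaspower.errors import StructuralError
from gwaspower.sim_model import _multinomial_rows


def grid_scan_baseline_odds(p, or_het, or_hom, k, n_grid=4_000_000):
    """Independent oracle: dense grid scan of the prevalence equation."""
    b = np.linspace(1e-8, 2 * k / (1 - k), n_grid)
    w = hwe_probs(p)
    ors = np.array([1.0, or_het, or_hom])
    prev = (w[None, :] * (ors[None, :] * b[:, None]) / (1 + ors[None, :] * b[:, None])).sum(axis=1)
    return b[np.argmin(np.abs(prev - k))]


class TestSolveBaselineOdds:
    def test_no_effect_snp_recovers_prevalence_odds(self):
        model = solve_baseline_odds(0.37, 1.0, 1.0, 0.01)
        assert model.baseline_odds == pytest.approx(0.01 / 0.99, rel=1e-12)
        assert model.penetrances == pytest.approx([0.01, 0.01, 0.01], rel=1e-12)

    def test_matches_grid_scan_oracle(self):
        oracle = grid_scan_baseline_odds(0.5, 2.0, 4.0, 0.01)
        model = solve_baseline_odds(0.5, 2.0, 4.0, 0.01)
        assert model.baseline_odds == pytest.approx(oracle, rel=1e-5)
        assert model.baseline_odds == pytest.approx(4.5e-3, rel=0.02)

    def test_baseline_odds_decreases_with_effect_size(self):
        for p in (0.1, 0.5, 0.9):
            odds = [
                solve_baseline_odds(p, r, r**2, 0.01).baseline_odds for r in (1.0, 1.5, 2.0, 3.0)
            ]
            assert np.all(np.diff(odds) < 0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        p=st.floats(0.0, 1.0),
        or_het=st.floats(0.25, 6.0),
        k=st.floats(0.001, 0.2),
    )
    def test_prevalence_conservation(self, p, or_het, k):
        """HWE-weighted mean penetrance equals the prevalence to 1e-10."""
        model = solve_baseline_odds(p, or_het, or_het**2, k)
        prevalence = float(np.sum(model.hwe_weights * model.penetrances))
        assert prevalence == pytest.approx(k, abs=1e-10)
        # odds-ratio relations hold
        odds = model.penetrances / (1 - model.penetrances)
        assert odds[1] / odds[0] == pytest.approx(or_het, rel=1e-8)
        assert odds[2] / odds[0] == pytest.approx(or_het**2, rel=1e-8)


class TestGenotypeDistributions:
    def test_null_snp_distributions_equal_hwe(self):
        model = solve_baseline_odds(0.3, 1.0, 1.0, 0.01)
        dist = genotype_dists_given_status(model, 0.01)
        hwe = hwe_probs(0.3)
        assert dist.case_probs == pytest.approx(hwe, abs=1e-12)
        assert dist.control_probs == pytest.approx(hwe, abs=1e-12)

    def test_monomorphic_snp(self):
        model = solve_baseline_odds(0.0, 2.0, 4.0, 0.01)
        dist = genotype_dists_given_status(model, 0.01)
        assert dist.case_probs == pytest.approx((1, 0, 0), abs=1e-12)
        assert dist.control_probs == pytest.approx((1, 0, 0), abs=1e-12)

    def test_risk_snp_enriches_cases(self):
        model = solve_baseline_odds(0.5, 2.0, 4.0, 0.01)
        dist = genotype_dists_given_status(model, 0.01)
        assert dist.case_probs[2] > hwe_probs(0.5)[2]
        # exact Bayes value from the solved model
        expected = model.hwe_weights[2] * model.f_hom_risk / 0.01
        assert dist.case_probs[2] == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(p=st.floats(0.01, 0.99), or_het=st.floats(0.5, 5.0))
    def test_mixture_identity(self, p, or_het):
        """K * P(G|case) + (1-K) * P(G|control) recovers HWE(p) to 1e-10."""
        k = 0.01
        model = solve_baseline_odds(p, or_het, or_het**2, k)
        dist = genotype_dists_given_status(model, k)
        mixture = k * np.array(dist.case_probs) + (1 - k) * np.array(dist.control_probs)
        assert mixture == pytest.approx(hwe_probs(p), abs=1e-10)


class TestSimulateDataset:
    def test_study_scale_record_count(self):
        config = SimConfig(n_null=1000, n_disease=40)
        dataset = simulate_dataset(config, 50, 50, seed=0)
        assert len(dataset) == 1040
        assert (dataset.truth == "null").sum() == 1000
        assert (dataset.truth == "disease").sum() == 40

    def test_count_conservation(self, small_dataset):
        assert np.all(small_dataset.case_counts.sum(axis=1) == 120)
        assert np.all(small_dataset.control_counts.sum(axis=1) == 180)

    def test_empty_case_group(self, small_config):
        dataset = simulate_dataset(small_config, 0, 30, seed=3)
        assert np.all(dataset.case_counts == 0)
        assert np.all(dataset.control_counts.sum(axis=1) == 30)

    def test_seed_determinism(self, small_config):
        a = simulate_dataset(small_config, 40, 60, seed=9)
        b = simulate_dataset(small_config, 40, 60, seed=9)
        assert np.array_equal(a.pop_freq, b.pop_freq)
        assert np.array_equal(a.case_counts, b.case_counts)
        assert np.array_equal(a.control_counts, b.control_counts)
        c = simulate_dataset(small_config, 40, 60, seed=10)
        assert not np.array_equal(a.case_counts, c.case_counts)

    def test_frequencies_respect_bounds(self):
        config = SimConfig(n_null=500, n_disease=0, freq_lo=0.2, freq_hi=0.4)
        dataset = simulate_dataset(config, 10, 10, seed=1)
        assert dataset.pop_freq.min() >= 0.2
        assert dataset.pop_freq.max() <= 0.4

    def test_multinomial_sampling_matches_target_probs(self, rng):
        """Observed genotype proportions over 2000 draws sit within 4 SE of
        the target triple (multinomial oracle)."""
        model = solve_baseline_odds(0.4, 2.0, 4.0, 0.01)
        dist = genotype_dists_given_status(model, 0.01)
        probs = np.tile(np.array(dist.case_probs), (2000, 1))
        n = 50
        counts = _multinomial_rows(rng, n, probs)
        assert np.all(counts.sum(axis=1) == n)
        observed = counts.mean(axis=0) / n
        target = np.array(dist.case_probs)
        se = np.sqrt(target * (1 - target) / (2000 * n))
        assert np.all(np.abs(observed - target) < 4 * se)

    def test_dataset_iteration_yields_records(self, small_dataset):
        record = next(iter(small_dataset))
        assert record.snp_id.startswith("null_")
        assert sum(record.case_counts) == 120
        assert record.truth in ("null", "disease")


class TestExpandToIndividuals:
    def test_round_trip_recounts_exactly(self, small_config):
        dataset = simulate_dataset(small_config, 25, 35, seed=2)
        genotypes, phenotypes = expand_to_individuals(dataset, seed=7)
        assert genotypes.shape == (60, len(dataset))
        assert (phenotypes == 2).sum() == 25
        cases = genotypes[phenotypes == 2]
        controls = genotypes[phenotypes == 1]
        for g in range(3):
            assert np.array_equal((cases == g).sum(axis=0), dataset.case_counts[:, g])
            assert np.array_equal((controls == g).sum(axis=0), dataset.control_counts[:, g])

    def test_multiset_recovery(self):
        dataset = SnpDataset(
            snp_ids=np.array(["s1"]),
            truth=np.array(["null"]),
            pop_freq=np.array([0.2]),
            case_counts=np.array([[2, 1, 0]]),
            control_counts=np.array([[0, 0, 2]]),
            n_cases=3,
            n_controls=2,
        )
        genotypes, phenotypes = expand_to_individuals(dataset, seed=0)
        assert sorted(genotypes[phenotypes == 2, 0]) == [0, 0, 1]
        assert sorted(genotypes[phenotypes == 1, 0]) == [2, 2]

    def test_assignments_independent_across_snps(self):
        """Genotype codes of two null SNPs are uncorrelated across individuals
        (no linkage disequilibrium by construction)."""
        config = SimConfig(n_null=2, n_disease=0, freq_lo=0.5, freq_hi=0.5)
        dataset = simulate_dataset(config, 1000, 1000, seed=4)
        genotypes, _ = expand_to_individuals(dataset, seed=4)
        corr = np.corrcoef(genotypes[:, 0], genotypes[:, 1])[0, 1]
        assert abs(corr) < 4 / np.sqrt(2000)

    def test_inconsistent_group_sizes_rejected(self):
        with pytest.raises(StructuralError):
            SnpDataset(
                snp_ids=np.array(["a", "b"]),
                truth=np.array(["null", "null"]),
                pop_freq=np.array([0.5, 0.5]),
                case_counts=np.array([[1, 1, 0], [2, 1, 0]]),
                control_counts=np.array([[1, 0, 0], [1, 0, 0]]),
                n_cases=2,
                n_controls=1,
            )


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"freq_lo": 0.6, "freq_hi": 0.4},
            {"prevalence_k": 0.0},
            {"or_het": -1.0},
            {"maf_threshold": 0.5},
            {"alpha": 1.5},
            {"n_null": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_multiplicative_default(self):
        assert SimConfig(or_het=2.0).resolved_or_hom == 4.0
        assert SimConfig(or_het=2.0, or_hom=3.0).resolved_or_hom == 3.0

    def test_replication_preset_shape(self):
        config = paper2024(or_het=1.8)
        assert config.n_total == 100_400
        assert config.prevalence_k == 0.01
        assert config.resolved_or_hom == pytest.approx(1.8**2)


class TestCalibrateOr:
    def test_small_target_gives_near_null_effect(self):
        config = SimConfig(n_null=0, n_disease=100)
        or_het = calibrate_or(0.002, (200, 200), config, threshold=1e-3)
        assert 1.0 < or_het < 1.2

    def test_calibrated_effect_shrinks_with_sample_size(self):
        config = SimConfig(n_null=0, n_disease=100)
        small_n = calibrate_or(0.5, (300, 300), config, threshold=1e-4)
        large_n = calibrate_or(0.5, (1500, 1500), config, threshold=1e-4)
        assert large_n < small_n

    def test_target_above_retention_ceiling_is_infeasible(self):
        config = SimConfig(n_null=0, n_disease=100, maf_threshold=0.05)
        with pytest.raises(InfeasibleTargetError):
            calibrate_or(0.95, (500, 500), config, threshold=1e-4)
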