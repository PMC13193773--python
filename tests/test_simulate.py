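"""Synthetic herd generator: pedigree structure, breeding values, records."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from caprigen import (
    SimulationConfig,
    calibrate_threshold,
    default_g0,
    default_r0,
    inbreeding_coefficients,
    pedigree_from_records,
    read_pedigree,
    relationship_matrix,
    simulate_breeding_values,
    simulate_dataset,
    simulate_pedigree,
    simulate_records,
)


class TestConfig:
    def test_default_truth_matches_target_parameters(self):
        g0 = default_g0()
        r0 = default_r0()
        h2 = np.diag(g0) / (np.diag(g0) + np.diag(r0))
        assert h2 == pytest.approx([0.25, 0.11, 0.19])
        rg = g0[0, 1] / np.sqrt(g0[0, 0] * g0[1, 1])
        assert rg == pytest.approx(0.23)
        # implied phenotypic correlations close to the target pattern
        p = g0 + r0
        rp = [p[0, 1] / np.sqrt(p[0, 0] * p[1, 1]),
              p[0, 2] / np.sqrt(p[0, 0] * p[2, 2]),
              p[1, 2] / np.sqrt(p[1, 1] * p[2, 2])]
        assert rp == pytest.approx([0.09, -0.07, 0.14], abs=0.005)

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimulationConfig(n_traits=2, g0=bad, r0=np.eye(2))

    def test_bad_incidence_rejected(self):
        with pytest.raises(ValueError, match="incidence"):
            SimulationConfig(incidence_targets=(0.15, 1.2, 0.15))


class TestPedigreeSimulation:
    def test_single_generation_counts(self):
        cfg = SimulationConfig(
            n_founder_sires=2, n_founder_dams=30, n_generations=1,
            offspring_per_dam=1, seed=0,
        )
        ped = simulate_pedigree(cfg)
        assert ped.n == 62
        offspring = [i for i, a in enumerate(ped.ids) if a[0] in "MF"]
        assert len(offspring) == 30
        assert all(ped.sire[i] >= 0 and ped.dam[i] >= 0 for i in offspring)

    def test_seed_determinism(self, small_config):
        p1 = simulate_pedigree(small_config)
        p2 = simulate_pedigree(small_config)
        assert p1.ids == p2.ids
        assert np.array_equal(p1.sire, p2.sire)
        assert np.array_equal(p1.dam, p2.dam)

    def test_later_generations_accumulate_inbreeding(self, random_pedigrees):
        ped = random_pedigrees[0]
        f = inbreeding_coefficients(ped)
        assert (f > 0).mean() > 0


class TestBreedingValues:
    def test_zero_genetic_variance(self, trio):
        bv = simulate_breeding_values(trio, np.zeros((1, 1)), 0)
        assert np.all(bv == 0)

    def test_founder_variance_within_sampling_bound(self):
        ped = pedigree_from_records([(f"A{i}", None, None) for i in range(10_000)])
        bv = simulate_breeding_values(ped, np.array([[0.25]]), 1)
        se = 0.25 * np.sqrt(2 / 10_000)  # SD of a chi-square sample variance
        assert abs(bv.var(ddof=1) - 0.25) < 3 * se

    def test_covariance_matches_kronecker_structure(self):
        """Monte-Carlo covariance of replicate gene drops approximates
        A x G0 on a small pedigree."""
        cfg = SimulationConfig(
            n_founder_sires=3, n_founder_dams=15, n_generations=2, seed=3
        )
        ped = simulate_pedigree(cfg)
        g0 = np.array([[0.5, 0.2], [0.2, 0.4]])
        reps = 2000
        rng = np.random.default_rng(9)
        draws = np.stack(
            [simulate_breeding_values(ped, g0, rng) for _ in range(reps)]
        )  # (reps, n, 2)
        a = relationship_matrix(ped)
        sub = np.arange(min(40, ped.n))
        emp = np.einsum("rit,rjs->ijts", draws[:, sub], draws[:, sub]) / reps
        expected = np.einsum("ij,ts->ijts", a[np.ix_(sub, sub)], g0)
        err = np.abs(emp - expected).max()
        assert err < 0.2  # ~4 MC standard errors at 2000 replicates

    def test_non_psd_g0_rejected(self, trio):
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_breeding_values(trio, np.array([[1.0, 2.0], [2.0, 1.0]]), 0)


class TestThresholdCalibration:
    def test_symmetric_target_half(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(2.0, 1.0, 5000)
        t = calibrate_threshold(0.5, mu, 1.0)
        assert t == pytest.approx(mu.mean(), abs=0.01)

    def test_quantile_closed_form(self):
        t = calibrate_threshold(0.15, np.zeros(10), 1.0)
        assert t == pytest.approx(stats.norm.ppf(0.85), abs=1e-5)

    def test_fixed_point(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(0, 0.7, 2000)
        t = calibrate_threshold(0.3, mu, 1.44)
        realized = stats.norm.sf((t - mu) / 1.2).mean()
        assert realized == pytest.approx(0.3, abs=1e-6)


class TestRecords:
    def test_all_outcomes_one_when_threshold_below_everything(self):
        cfg = SimulationConfig(
            n_founder_sires=2, n_founder_dams=20, n_generations=1, seed=0,
            n_traits=1, g0=np.array([[1e-12]]), r0=np.array([[1e-12]]),
            incidence_targets=(0.999999,), missingness=(1.0,),
            year_effects=(0.5,), season_effects=(0.0,), age_effects=(0.0,),
        )
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, cfg.g0, 0)
        ds = simulate_records(ped, bv, cfg)
        assert (ds.records["outcome"] == 1).all()

    def test_realized_incidence_binomial_bound(self):
        # near-zero genetic variance keeps records independent so the
        # binomial bound is valid (family clustering would widen it)
        cfg = SimulationConfig(
            n_founder_sires=10, n_founder_dams=2500, n_generations=1,
            n_traits=1, g0=np.array([[1e-4]]), r0=np.array([[1.0]]),
            incidence_targets=(0.15,), missingness=(1.0,),
            year_effects=(0.0,), season_effects=(0.0,), age_effects=(0.0,),
            seed=11,
        )
        ds = simulate_dataset(cfg)
        n = len(ds.records)
        assert n >= 2000  # ~half the 5,000 kids are terminal-generation does
        inc = ds.records["outcome"].mean()
        assert abs(inc - 0.15) < 3 * np.sqrt(0.15 * 0.85 / n)

    def test_missingness_declines_counts(self, small_dataset):
        counts = small_dataset.records.groupby("parity").size()
        n_doe = small_dataset.records["doe_id"].nunique()
        for p, keep in zip((1, 2, 3), (1.0, 0.817, 0.596)):
            expect = n_doe * keep
            assert abs(counts[p] - expect) < 3 * np.sqrt(n_doe * keep * (1 - keep) + 1)

    def test_outcome_equals_liability_indicator(self, small_dataset):
        merged = small_dataset.records.merge(
            small_dataset.liabilities, on=["doe_id", "parity"]
        )
        thr = small_dataset.truth["thresholds"]
        expected = (
            merged["liability"].to_numpy()
            > thr[merged["parity"].to_numpy() - 1]
        ).astype(int)
        assert np.array_equal(merged["outcome"].to_numpy(), expected)

    def test_dataset_determinism(self, small_config):
        d1 = simulate_dataset(small_config)
        d2 = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(d1.records, d2.records)

    def test_round_trip_through_files(self, small_dataset, tmp_path):
        small_dataset.write(
            tmp_path / "ped.csv", tmp_path / "phen.csv", tmp_path / "truth.yaml"
        )
        ped = read_pedigree(tmp_path / "ped.csv")
        assert ped.ids == small_dataset.pedigree.ids
        assert np.array_equal(ped.sire, small_dataset.pedigree.sire)
        phen = pd.read_csv(tmp_path / "phen.csv")
        pd.testing.assert_frame_equal(
            phen.assign(doe_id=phen["doe_id"].astype(str)),
            small_dataset.records.reset_index(drop=True),
        )

    def test_mid_parent_regression_recovers_h2(self):
        """Offspring liability on mid-parent liability slope ~ h2."""
        h2 = 0.4
        g = h2 / (1 - h2)
        rng = np.random.default_rng(21)
        n_fam = 4000
        recs = []
        for i in range(n_fam):
            recs += [(f"S{i}", None, None), (f"D{i}", None, None),
                     (f"O{i}", f"S{i}", f"D{i}")]
        ped = pedigree_from_records(recs)
        bv = simulate_breeding_values(ped, np.array([[g]]), rng)
        idx = ped.index_map
        e = rng.normal(0, 1, (n_fam, 3))
        liab = {k: bv[[idx[f"{k}{i}"] for i in range(n_fam)], 0] + e[:, j]
                for j, k in enumerate("SDO")}
        mid = 0.5 * (liab["S"] + liab["D"])
        slope = np.cov(mid, liab["O"])[0, 1] / np.var(mid)
        assert abs(slope - h2) < 0.05
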