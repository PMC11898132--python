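import numpy as np
import pytest
from dataclasses import replace
from scipy.special import ndtr

import parityrrm as prm
from parityrrm.simulate import (
    SimulationScenario, line_scenario, simulate_breeding_values,
    simulate_dataset, simulate_pedigree, simulate_records,
)
from conftest import tabular_a


class TestPedigreeGenerator:
    def test_single_generation_all_founders(self):
        scen = SimulationScenario(n_founders=10, ewes_per_generation=10,
                                  n_generations=0, seed=1)
        ped, meta = simulate_pedigree(scen)
        assert (meta.generation == 0).all()
        assert ped.inbreeding().max() == 0.0

    def test_rotation_prevents_full_sib_matings_in_gen2(self):
        scen = SimulationScenario(n_founders=40, ewes_per_generation=40,
                                  n_generations=2, seed=3)
        ped, meta = simulate_pedigree(scen)
        gen2 = meta[meta.generation == 2]
        parents = {
            a: (s, d) for a, s, d in
            zip(meta.animal, meta.sire, meta.dam)
        }
        for _, row in gen2.iterrows():
            sp_ = parents[row.sire]
            dp = parents[row.dam]
            assert not (sp_ == dp and sp_ != ("0", "0"))

    def test_rotation_lowers_inbreeding_vs_control(self):
        base = SimulationScenario(n_founders=50, ewes_per_generation=50,
                                  n_generations=5, seed=17)
        ped_rot, _ = simulate_pedigree(base)
        ped_fix, _ = simulate_pedigree(replace(base, rotate_families=False))
        assert ped_rot.inbreeding().mean() < ped_fix.inbreeding().mean()

    def test_infeasible_shape_rejected(self):
        scen = SimulationScenario(n_founders=3, ewes_per_generation=3,
                                  n_families=7, n_generations=1)
        with pytest.raises(ValueError):
            simulate_pedigree(scen)


class TestBreedingValues:
    def test_zero_g_gives_zero_effects(self):
        scen = line_scenario("prolific", n_ewes=60, seed=2)
        ped, _ = simulate_pedigree(scen)
        a = simulate_breeding_values(
            ped, np.zeros((3, 3)), np.random.default_rng(0)
        )
        assert not a.any()

    def test_founder_covariance_matches_g(self, rng):
        G = np.array([[0.5, 0.1, 0.0], [0.1, 0.3, 0.05], [0.0, 0.05, 0.2]])
        scen = SimulationScenario(n_founders=5000, ewes_per_generation=7,
                                  n_generations=0, true_G=G, seed=4)
        ped, _ = simulate_pedigree(scen)
        a = simulate_breeding_values(ped, G, rng)
        emp = np.cov(a.T)
        np.testing.assert_allclose(np.diag(emp), np.diag(G), rtol=0.10)

    def test_replicate_covariance_has_kronecker_structure(self, rng):
        """cov(vec a) over replicates of a fixed small pedigree must match
        A (x) G elementwise."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "animal": [f"x{i}" for i in range(10)],
                "sire": ["0", "0", "x0", "x0", "x2", "x2", "x4", "0",
                         "x4", "x6"],
                "dam": ["0", "0", "x1", "x1", "x3", "x3", "x5", "0",
                        "x7", "x8"],
            }
        )
        ped = prm.Pedigree.from_dataframe(df)
        G = np.array([[0.6, 0.2], [0.2, 0.4]])
        reps = np.stack(
            [simulate_breeding_values(ped, G, rng).ravel()
             for _ in range(4000)]
        )
        emp = np.cov(reps.T)
        A = tabular_a(ped.sire, ped.dam)
        expected = np.kron(A, G)
        scale = np.sqrt(
            np.outer(np.diag(expected), np.diag(expected))
        )
        np.testing.assert_allclose(
            emp / scale, expected / scale, atol=0.15
        )


class TestRecordGenerator:
    def test_extreme_thresholds_give_single_category(self):
        scen = replace(line_scenario("prolific", n_ewes=60, seed=5),
                       thresholds=(50.0, 51.0))
        ds = simulate_dataset(scen)
        assert (ds.records.litter_size == 1).all()

    def test_symmetric_binary_split(self):
        scen = SimulationScenario(
            line="conventional", n_founders=3000, ewes_per_generation=7,
            n_generations=0, true_G=np.zeros((3, 3)),
            true_P=np.zeros((3, 3)), true_resid=(1.0, 1.0, 1.0),
            thresholds=(0.0,), beta=np.zeros(3), year_sd=0.0,
            month_effects=(0.0, 0.0, 0.0),
            parity_retention=(0.9,) * 5, n_categories=2, seed=6,
        )
        ds = simulate_dataset(scen)
        frac = (ds.records.litter_size > 1).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_category_frequencies_match_normal_cdf(self):
        """Realized per-record category frequencies must match the
        closed-form probabilities at the simulated record means."""
        scen = line_scenario("prolific", seed=7)
        ds = simulate_dataset(scen)
        eta = (
            ds.truth.year_effect + ds.truth.month_effect
            + ds.truth.fixed_regression + ds.truth.genetic
            + ds.truth.permanent_environment
        ).to_numpy()
        sig = np.sqrt(
            np.array(scen.true_resid)[
                ds.truth.parity.map(scen.class_of).to_numpy() - 1
            ]
        )
        p1 = ndtr((0.0 - eta) / sig)
        p2 = ndtr((1.0 - eta) / sig) - p1
        obs = ds.truth.category.value_counts(normalize=True)
        assert obs[1] == pytest.approx(p1.mean(), abs=0.02)
        assert obs[2] == pytest.approx(p2.mean(), abs=0.02)

    def test_liability_reconstruction_is_exact(self, small_dataset):
        t = small_dataset.truth
        recon = (
            t.year_effect + t.month_effect + t.fixed_regression
            + t.genetic + t.permanent_environment + t.residual
        )
        np.testing.assert_array_equal(recon.to_numpy(),
                                      t.liability.to_numpy())

    def test_every_recorded_ewe_in_pedigree(self, small_dataset):
        assert set(small_dataset.records.ewe) <= set(
            small_dataset.pedigree.ids
        )


class TestLineScenarios:
    def test_prolific_shape(self):
        scen = line_scenario("prolific")
        assert scen.n_categories == 3
        assert prm.assign_residual_class(3, "prolific") == 2
        ds = simulate_dataset(scen)
        # record count close to the real prolific line's 2751
        assert len(ds.records) == pytest.approx(2751, rel=0.15)
        assert 19 <= ds.records.year.nunique() <= 31
        years_per_ewe = ds.records.groupby("ewe").size().mean()
        assert years_per_ewe == pytest.approx(2.8, abs=0.3)

    def test_conventional_shape(self):
        scen = line_scenario("conventional")
        assert scen.n_categories == 2
        ds = simulate_dataset(scen)
        assert len(ds.records) == pytest.approx(2562, rel=0.15)
        assert ds.records.groupby("ewe").size().mean() == pytest.approx(
            3.0, abs=0.3
        )

    def test_seed_reproducibility(self, tmp_path):
        d1 = simulate_dataset(line_scenario("prolific", n_ewes=60, seed=9))
        d2 = simulate_dataset(line_scenario("prolific", n_ewes=60, seed=9))
        assert d1.records.equals(d2.records)
        np.testing.assert_array_equal(d1.a, d2.a)

    def test_roundtrip_files(self, tmp_path, small_dataset):
        paths = small_dataset.write(tmp_path)
        ped = prm.read_pedigree(paths["pedigree"])
        rs = prm.read_records(paths["records"], "conventional")
        assert len(ped) == len(small_dataset.pedigree)
        assert len(rs) == len(small_dataset.records)
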