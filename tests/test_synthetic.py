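"""Synthetic-data generator: reproducibility, calibration, round trips."""

import json

import numpy as np
import pandas as pd
import pytest

from thermnorm.reaction_norms import fit_linear, read_development_csv, to_rates, truncate_to_linear
from thermnorm.synthetic import (
    SimConfig,
    generate_dataset,
    simulate_noisy_replicates,
    simulate_stage_series,
    simulate_traits,
    simulate_tree,
    traits_to_lines,
)
from thermnorm.trees import as_newick, phylo_covariance


class TestSimulateTree:
    def test_seeded_repeatability(self):
        assert as_newick(simulate_tree(6, seed=9)) == as_newick(simulate_tree(6, seed=9))

    def test_minimum_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(2, seed=1)

    def test_fully_bifurcating_node_count(self):
        tree = simulate_tree(50, seed=4)
        internal = sum(1 for n in tree.preorder_node_iter() if not n.is_leaf())
        assert internal == 49

    def test_unit_depth(self):
        tree = simulate_tree(20, seed=5)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) == pytest.approx(1.0)

    def test_full_collapse_gives_star(self):
        tree = simulate_tree(10, seed=6, polytomy_fraction=1.0)
        cov = phylo_covariance(tree)
        off = cov.matrix[~np.eye(10, dtype=bool)]
        assert np.allclose(off, 0.0)


class TestSimulateTraits:
    def test_seeded_repeatability(self):
        t = simulate_tree(8, seed=2)
        a = simulate_traits(t, 0.5, 0.3, seed=7)
        b = simulate_traits(t, 0.5, 0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_star_limit_gives_identity_covariance(self):
        """lambda=0, rho=0 on a unit-depth tree: sample moments near iid normal."""
        t = simulate_tree(12, seed=3)
        draws = np.stack([
            simulate_traits(t, 0.0, 0.0, seed=s).to_numpy() for s in range(200)
        ])  # (200, 12, 2)
        flat = draws.reshape(-1, 2)
        n = flat.shape[0]
        se_var = np.sqrt(2.0 / (n - 1))  # SE of a unit-normal sample variance
        assert np.allclose(flat.var(axis=0, ddof=1), 1.0, atol=3 * se_var)
        r = np.corrcoef(flat[:, 0], flat[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(n)

    def test_near_unit_rho_is_collinear(self):
        t = simulate_tree(25, seed=3)
        x = simulate_traits(t, 1.0, 0.999, seed=9).to_numpy()
        assert np.corrcoef(x[:, 0], x[:, 1])[0, 1] > 0.99


class TestStageSeries:
    def test_noiseless_round_trip_recovers_line(self):
        cfg = SimConfig(n_species=5, noise_cv=0.0, seed=1)
        tree = simulate_tree(5, seed=2)
        traits = simulate_traits(tree, cfg.true_lambda, cfg.true_rho, seed=3)
        lines = traits_to_lines(traits, cfg)
        series = simulate_stage_series(lines, cfg, seed=4)
        for s in series:
            norm = fit_linear(to_rates(s))
            truth = lines.loc[s.species_id]
            assert norm.intercept_a == pytest.approx(truth["intercept_a"], abs=1e-9)
            assert norm.slope_b == pytest.approx(truth["slope_b"], abs=1e-9)
            assert norm.ltt == pytest.approx(truth["ltt"], abs=1e-6)
            assert norm.r_squared == pytest.approx(1.0)

    def test_noise_calibration_keeps_median_r2_above_gate(self):
        """CV = 0.02 multiplicative rate noise leaves most 5-point series 'good'."""
        series = simulate_noisy_replicates(
            -0.1, 0.01, (12.5, 17.5, 22.5, 27.5, 32.5), 0.02, 500, seed=11
        )
        r2 = [fit_linear(to_rates(s)).r_squared for s in series]
        assert float(np.median(r2)) >= 0.98

    def test_sigmoid_ends_truncated_away_when_noiseless(self):
        cfg = SimConfig(n_species=4, noise_cv=0.0, curvature="sigmoid_ends", seed=1)
        tree = simulate_tree(4, seed=2)
        traits = simulate_traits(tree, 0.5, 0.3, seed=3)
        lines = traits_to_lines(traits, cfg)
        series = simulate_stage_series(lines, cfg, seed=4)
        for s in series:
            kept = truncate_to_linear(s)
            temps = set(s.temperatures) - set(kept.temperatures)
            # exactly the two extreme regimens removed
            assert temps == {min(s.temperatures), max(s.temperatures)}

    def test_nonpositive_rate_regimens_omitted(self):
        lines = pd.DataFrame(
            {"intercept_a": [-0.30], "slope_b": [0.01], "ltt": [30.0]}, index=["spX"]
        )
        cfg = SimConfig(n_species=1, temperatures=(15.0, 20.0, 25.0, 31.0, 33.0, 35.0),
                        noise_cv=0.0, seed=1)
        series = simulate_stage_series(lines, cfg, seed=2)
        assert list(series[0].temperatures) == [31.0, 33.0, 35.0]


class TestScenarios:
    def test_parallel_shift_has_equal_slopes(self):
        cfg = SimConfig(n_species=8, scenario="parallel_shift", noise_cv=0.0, seed=5)
        tree = simulate_tree(8, seed=6)
        lines = traits_to_lines(simulate_traits(tree, 0.5, 0.0, seed=7), cfg)
        assert lines["slope_b"].nunique() == 1
        assert lines["ltt"].nunique() > 1

    def test_common_intersection_passes_through_pivot(self):
        cfg = SimConfig(n_species=8, scenario="common_intersection", noise_cv=0.0, seed=5)
        tree = simulate_tree(8, seed=6)
        lines = traits_to_lines(simulate_traits(tree, 0.5, 0.0, seed=7), cfg)
        t_piv, r_piv = cfg.pivot
        at_pivot = lines["intercept_a"] + lines["slope_b"] * t_piv
        assert np.allclose(at_pivot, r_piv)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(scenario="rotating")
        with pytest.raises(ValueError):
            SimConfig(slope_range=(0.01, 0.01))
        with pytest.raises(ValueError):
            SimConfig(true_rho=1.0)


class TestGenerateDataset:
    def test_outputs_load_end_to_end(self, tmp_path):
        cfg = SimConfig(n_species=10, seed=3)
        manifest = generate_dataset(cfg, tmp_path)
        series = read_development_csv(tmp_path / "development.csv")
        assert len(series) == 10
        assert set(manifest["true_lines"]) == {s.species_id for s in series}
        assert (tmp_path / "tree.nwk").exists()

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_species=6, seed=8)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for name in ("development.csv", "tree.nwk", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_manifest_records_config(self, tmp_path):
        cfg = SimConfig(n_species=6, seed=8, true_rho=0.25)
        generate_dataset(cfg, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["true_rho"] == 0.25
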