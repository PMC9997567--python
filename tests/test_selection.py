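"""Selective-plate dynamics: lawn law, clone expansion, plate composition."""

import math

import numpy as np
import pytest

from gdasim import (
    CellClass,
    Population,
    RateConfig,
    lawn_dynamics,
    make_amplicon,
    run_reversion_assay,
    simulate_clone,
    simulate_clones,
    simulate_plate,
)


class TestLawnDynamics:
    def test_printed_anchor_points(self, config):
        assert lawn_dynamics(0, config) == pytest.approx(5e8)
        assert lawn_dynamics(12, config) == pytest.approx(5e7)
        assert lawn_dynamics(21, config) == pytest.approx(5e8)
        assert lawn_dynamics(30, config) == pytest.approx(5e8)

    def test_piecewise_geometric_shape(self, config):
        days = np.arange(0, 22, 1.0)
        values = [lawn_dynamics(d, config) for d in days]
        assert all(b < a for a, b in zip(values[:12], values[1:13]))
        assert all(b > a for a, b in zip(values[12:21], values[13:22]))
        with pytest.raises(ValueError):
            lawn_dynamics(-1, config)


class TestSimulateClone:
    def test_haploid_founder_rejected(self, config, amplicon28):
        with pytest.raises(ValueError):
            simulate_clone(1, amplicon28, 5, config, seed=0)

    def test_non_permissive_amplicon_never_appears(self, config):
        amp = make_amplicon(28.0, permissive=False)
        day, dist = simulate_clone(8, amp, 10, config, seed=1)
        assert day is None
        assert dist == {8: 1.0}

    def test_high_copy_founders_appear_within_four_days(self, config, amplicon28):
        appearance, _ = simulate_clones(15, amplicon28, 6, config, 100, seed=2)
        assert np.nanmedian(appearance) <= 4

    def test_visible_clone_retains_lower_copy_ancestors(self, config, amplicon28):
        day, dist = simulate_clone(8, amplicon28, 12, config, seed=3)
        assert day is not None
        modal = max(dist, key=dist.get)
        assert any(n < modal and count > 0 for n, count in dist.items())

    def test_monotone_delay_in_founder_copy_number(self, config, amplicon28):
        horizons = {3: 30, 8: 12, 15: 6}
        medians = {}
        for n, days in horizons.items():
            appearance, _ = simulate_clones(n, amplicon28, days, config, 60, seed=n)
            medians[n] = np.nanmedian(appearance)
        assert medians[15] < medians[8] < medians[3]

    def test_reduced_temperature_slows_appearance(self, amplicon28):
        warm = RateConfig()
        cool = RateConfig(temp_factor=0.5)
        app_w, _ = simulate_clones(8, amplicon28, 12, warm, 80, seed=5)
        app_c, _ = simulate_clones(8, amplicon28, 12, cool, 80, seed=5)
        visible_w = np.mean(~np.isnan(app_w))
        visible_c = np.mean(~np.isnan(app_c))
        assert np.nanmedian(app_c) > np.nanmedian(app_w) or visible_c < visible_w


class TestSimulatePlate:
    def test_haploid_inoculum_yields_no_colonies(self, config):
        pop = Population([CellClass(1, 5e8)])
        timeline = simulate_plate(pop, 5, config, seed=1)
        assert timeline.visible_colonies.sum() == 0
        assert (timeline.lawn_viable > 0).all()

    def test_input_validation(self, config):
        with pytest.raises(ValueError):
            simulate_plate(Population([]), 5, config)
        with pytest.raises(ValueError):
            simulate_plate(Population([CellClass(1, 1e8)]), 0, config)

    def test_colony_counts_non_decreasing_and_records_sorted(self, config, amplicon28):
        pop = Population([CellClass(1, 5e8), CellClass(8, 30.0, amplicon28)])
        timeline = simulate_plate(pop, 10, config, seed=4)
        assert (np.diff(timeline.visible_colonies) >= 0).all()
        days = [r.appearance_day for r in timeline.colony_records]
        assert days == sorted(days)
        assert all(d >= 1 for d in days)

    def test_adaptive_contrast_counts_are_poisson_like(self):
        # with no pre-existing mutants and constant per-day induction, the
        # per-plate counts show sampling (Poisson) dispersion only; use a
        # contrast config in which induced clones become visible quickly
        cfg = RateConfig(k_half=1.0, plate_induction_rate=4e-9)
        pop = Population([CellClass(1, 5e8)])
        counts = []
        rng_seed = 0
        for i in range(30):
            timeline = simulate_plate(pop, 10, cfg, seed=100 + i)
            counts.append(timeline.visible_colonies[-1])
        counts = np.asarray(counts, dtype=float)
        assert counts.mean() > 1
        assert 0.4 < counts.var() / counts.mean() < 2.5


class TestReversionAssay:
    def test_no_mutation_sources_means_no_revertants(self):
        cfg = RateConfig(k_dup=0.0, culture_final_size=1e5)
        result = run_reversion_assay(cfg, n_plates=2, seed=1, days=3)
        assert result.frequency.sum() == 0.0

    def test_no_colonies_on_the_first_two_days(self, config):
        result = run_reversion_assay(config, n_plates=2, seed=2, days=3)
        assert result.counts[:, 0].sum() == 0
        assert result.counts[:, 1].sum() == 0
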