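"""Generator correctness: closed-form expectations, stochastic convergence,
self-consistent rendered ground truth, seeded reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hacscreen.simulate import (
    ConfigurationError,
    PlacementError,
    SimulationConfig,
    cells_seeded_per_well,
    expected_gfp_fraction,
    expected_hac_fraction,
    make_plate_map,
    render_field,
    simulate_facs_events,
    simulate_growth_curve,
    simulate_mn_counts,
    simulate_plate,
    simulate_population,
    sirna_final_concentration_nm,
    validate_well_id,
)


def _cfg(**kw):
    defaults = dict(
        loss_rate_per_division=0.1,
        n_divisions=4,
        initial_cells=1000,
        initial_hac_fraction=1.0,
        reporter_lag_hours=0.0,
        rng_seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPopulation:
    @pytest.mark.parametrize(
        "rate, n_div, f0, expected",
        [
            (0.0, 4, 1.0, 1.0),          # zero loss keeps everything
            (0.1, 4, 1.0, 0.9**4),       # brute-force product of survivals
            (1.0, 1, 1.0, 0.0),          # certain loss
            (0.2, 4, 1.0, 0.8**4),
        ],
    )
    def test_expectation_mode_matches_closed_form(self, rate, n_div, f0, expected):
        pop = simulate_population(
            _cfg(loss_rate_per_division=rate, n_divisions=n_div,
                 initial_hac_fraction=f0),
            mode="expectation",
        )
        assert pop.hac_fraction == pytest.approx(expected, abs=1e-12)

    def test_expectation_grid_machine_precision(self):
        """Closed form f0*(1-R)^N over the full (R, N) grid."""
        for rate in np.arange(0.0, 1.0001, 0.05):
            for n_div in range(11):
                pop = simulate_population(
                    _cfg(loss_rate_per_division=float(rate), n_divisions=n_div),
                    mode="expectation",
                )
                assert pop.hac_fraction == pytest.approx(
                    (1.0 - rate) ** n_div, abs=1e-12
                )

    def test_stochastic_converges_to_expectation(self):
        """Mean over 200 seeded replicates lands within 3 SE of the closed
        form at n=2000 cells."""
        rate, n_div, n = 0.1, 4, 2000
        expected = (1 - rate) ** n_div
        fracs = [
            simulate_population(
                _cfg(loss_rate_per_division=rate, n_divisions=n_div,
                     initial_cells=n, rng_seed=s)
            ).hac_fraction
            for s in range(200)
        ]
        se = np.sqrt(expected * (1 - expected) / (n * 200))
        assert abs(np.mean(fracs) - expected) < 3 * se

    def test_reporter_lag_keeps_recent_losers_gfp_positive(self):
        # 9 h lag at 24 h doubling = 0.375 generations of grace
        cfg = _cfg(reporter_lag_hours=9.0, doubling_time_hours=24.0)
        pop = simulate_population(cfg, mode="expectation")
        assert pop.gfp_fraction == pytest.approx(0.9 ** (4 - 0.375), abs=1e-12)
        assert pop.n_hac_positive <= pop.n_gfp_positive

    def test_stochastic_ordering_invariant(self):
        pop = simulate_population(
            _cfg(reporter_lag_hours=9.0, rng_seed=11), mode="stochastic"
        )
        assert 0 <= pop.n_hac_positive <= pop.n_gfp_positive <= pop.n_total

    def test_fixed_seed_reproducible(self):
        a = simulate_population(_cfg(rng_seed=5))
        b = simulate_population(_cfg(rng_seed=5))
        assert a.n_hac_positive == b.n_hac_positive
        assert a.generation_log.equals(b.generation_log)

    @pytest.mark.parametrize(
        "kw",
        [
            {"loss_rate_per_division": -0.1},
            {"loss_rate_per_division": 1.1},
            {"n_divisions": -1},
            {"initial_cells": 0},
            {"doubling_time_hours": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        rate=st.floats(0.0, 1.0),
        n_div=st.integers(0, 10),
        f0=st.floats(0.0, 1.0),
    )
    def test_expectation_closed_form_property(self, rate, n_div, f0):
        pop = simulate_population(
            _cfg(loss_rate_per_division=rate, n_divisions=n_div,
                 initial_hac_fraction=f0),
            mode="expectation",
        )
        assert pop.hac_fraction == pytest.approx(f0 * (1 - rate) ** n_div,
                                                 abs=1e-12)


class TestRenderField:
    def test_zero_nuclei_gives_background_only(self):
        dapi, gfp, truth = render_field(1.0, 0, image_shape=(128, 128), seed=0)
        assert truth.empty
        assert dapi.dtype == np.uint16 and gfp.dtype == np.uint16
        assert dapi.mean() < 200  # background only

    def test_requested_count_in_truth(self):
        _, _, truth = render_field(0.5, 20, image_shape=(512, 512), seed=1)
        assert len(truth) == 20
        assert not truth.touches_border.any()

    def test_truth_self_consistent_means(self, small_field):
        """Re-measuring mean GFP in a disk around each truth centroid
        reproduces the recorded class mean within noise tolerance."""
        dapi, gfp, truth = small_field
        for rec in truth.itertuples():
            rr, cc = np.ogrid[: gfp.shape[0], : gfp.shape[1]]
            mask = (rr - rec.row) ** 2 + (cc - rec.col) ** 2 <= (
                rec.equivalent_radius * 0.6
            ) ** 2
            measured = gfp[mask].mean()
            n_pix = mask.sum()
            assert abs(measured - rec.true_mean_gfp) < 3 * 10.0 / np.sqrt(n_pix) + 1.0

    def test_infeasible_density_raises(self):
        with pytest.raises(PlacementError):
            render_field(0.5, 500, image_shape=(128, 128), seed=0,
                         max_tries_per_nucleus=50)

    def test_seeded_rendering_bit_identical(self):
        a = render_field(0.5, 10, image_shape=(256, 256), seed=9)
        b = render_field(0.5, 10, image_shape=(256, 256), seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert a[2].equals(b[2])


class TestPlate:
    def test_gene_without_effect_entry_rejected(self):
        pm = make_plate_map(["A", "B"], replicates_per_gene=2)
        with pytest.raises(ConfigurationError):
            simulate_plate(pm, {"A": 0.1}, SimulationConfig())

    def test_elevated_gene_matches_closed_form(self):
        pm = make_plate_map(["HOT", "COLD"], replicates_per_gene=8)
        cfg = SimulationConfig(
            loss_rate_per_division=0.0, n_divisions=4, initial_cells=20000,
            reporter_lag_hours=0.0,
        )
        df = simulate_plate(pm, {"HOT": 0.2, "COLD": 0.0}, cfg, seed=0)
        hot = df[df.gene == "HOT"].pct_gfp_negative.mean()
        assert hot == pytest.approx(100 * (1 - 0.8**4), abs=1.5)  # 59.04
        cold = df[df.gene == "COLD"].pct_gfp_negative.mean()
        assert cold == pytest.approx(0.0, abs=0.5)

    def test_cytotoxicity_scales_counts(self):
        pm = make_plate_map(["TOX", "OK"], replicates_per_gene=8)
        cfg = SimulationConfig(initial_cells=2000)
        df = simulate_plate(
            pm, {"TOX": 0.0, "OK": 0.0}, cfg, seed=1, cytotoxicity={"TOX": 0.2}
        )
        ctrl_median = df[df.role == "negative_control"].n_cells.median()
        tox_mean = df[df.gene == "TOX"].n_cells.mean()
        assert tox_mean == pytest.approx(0.2 * ctrl_median, rel=0.15)

    def test_control_layout_has_eight_replicates(self):
        pm = make_plate_map(["G"], replicates_per_gene=1)
        assert len(pm.wells_with_role("negative_control")) == 8
        assert len(pm.wells_with_role("positive_control")) == 8

    def test_well_id_validation(self):
        assert validate_well_id("A1") == (0, 0)
        assert validate_well_id("P24") == (15, 23)
        for bad in ("Q1", "A25", "A0", "11", "A"):
            with pytest.raises(ConfigurationError):
                validate_well_id(bad)


class TestFacs:
    def test_all_positive_population_classifies_positive(self):
        ev = simulate_facs_events(1.0, 2000, dead_fraction=0.0, seed=0)
        # any threshold between the two modes separates perfectly
        assert (ev.gfp_intensity >= 200).all()

    def test_gated_fraction_within_binomial_se(self):
        frac = 0.6561
        ev = simulate_facs_events(frac, 10000, dead_fraction=0.05, seed=3)
        live = ev[ev.viability_dye_intensity < 800]
        est = (live.gfp_intensity >= 200).mean()
        se = np.sqrt(frac * (1 - frac) / len(live))
        assert abs(est - frac) < 3 * se

    def test_empty_event_table_rejected(self):
        with pytest.raises(ValueError):
            simulate_facs_events(0.5, 0)

    def test_bad_dead_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_facs_events(0.5, 100, dead_fraction=1.5)


class TestMnCounts:
    def test_binomial_mean(self):
        draws = [
            simulate_mn_counts(1000, 0.01, 19, seed=s)[0] for s in range(100)
        ]
        # Binomial(1000, 0.19) has mean 190, sd ~12.4
        assert np.mean(draws) == pytest.approx(190, abs=4)

    def test_fold_one_is_baseline(self):
        with_event, without = simulate_mn_counts(10000, 0.05, 1.0, seed=2)
        assert with_event + without == 10000
        assert with_event == pytest.approx(500, abs=3 * np.sqrt(10000 * 0.05 * 0.95))

    def test_rate_above_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_mn_counts(100, 0.1, 20)


class TestGrowthCurve:
    def test_exact_doubling_series(self):
        curve = simulate_growth_curve(24.0, n0=100, duration_hours=96,
                                      interval_hours=24, noise_cv=0.0)
        assert curve["count"].iloc[-1] == pytest.approx(1600.0)

    def test_noiseless_slope(self):
        curve = simulate_growth_curve(24.0, duration_hours=210, interval_hours=6,
                                      noise_cv=0.0)
        slope = np.polyfit(curve.time_hours, np.log2(curve["count"]), 1)[0]
        assert slope == pytest.approx(1 / 24, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_growth_curve(24.0, duration_hours=10, interval_hours=10)


class TestProtocolArithmetic:
    def test_sirna_concentration(self):
        assert sirna_final_concentration_nm(2.0, 1.25, 50.0) == pytest.approx(50.0)

    def test_cells_seeded(self):
        assert cells_seeded_per_well(25.0, 18.0) == pytest.approx(450.0)
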