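"""The gonad system: parameter construction, initial primordium, sweeps."""

import numpy as np
import pytest

from gonadcpm import (
    CellKind,
    ConfigurationError,
    GonadModelConfig,
    build_parameters,
    compute_geometry,
    gonad_circularity,
    initial_configuration,
    pair_key,
    phase_sweep,
    preset_config,
)

M, G, S = CellKind.MEDIUM, CellKind.PGC, CellKind.SGP


class TestBuildParameters:
    def test_printed_coefficients(self):
        params = build_parameters(GonadModelConfig())
        assert params.E[pair_key(G, M)] == pytest.approx(1_126_400.0)
        assert params.C[S] == pytest.approx(947.2)
        assert params.E[pair_key(G, S)] == pytest.approx(-102_400.0)
        assert params.C[G] == pytest.approx(870.4)
        assert params.beta == pytest.approx(1.2e-5)

    def test_negative_pgc_sgp_coefficient_favours_contact(self):
        params = build_parameters(GonadModelConfig())
        assert params.E[pair_key(G, S)] < 0

    def test_scale_preserves_dimensionless_products(self):
        full = build_parameters(GonadModelConfig())
        red = build_parameters(GonadModelConfig(scale=0.375))
        # beta * E is the acceptance-controlling product; it is scale-free
        for pair in full.E:
            assert red.beta * red.E[pair] == pytest.approx(
                full.beta * full.E[pair], rel=1e-9
            )

    def test_sgp_unit_option_rescales_only_sgp_classes(self):
        default = build_parameters(GonadModelConfig())
        alt = build_parameters(GonadModelConfig(sgp_energy_unit="sgp"))
        assert alt.E[pair_key(G, M)] == default.E[pair_key(G, M)]
        ratio = alt.E[pair_key(S, M)] / default.E[pair_key(S, M)]
        cfg = GonadModelConfig()
        assert ratio == pytest.approx(
            (cfg.k_s * cfg.v_s0**1.5) / (cfg.k_g * cfg.v_g0**1.5)
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            GonadModelConfig(n_pgc=0)
        with pytest.raises(ConfigurationError):
            GonadModelConfig(initial_aspect_ratio=0.5)
        with pytest.raises(ConfigurationError):
            build_parameters(GonadModelConfig(sgp_energy_unit="bogus"))


class TestInitialConfiguration:
    def test_cell_counts(self):
        state = initial_configuration(GonadModelConfig(scale=0.375))
        assert len(state.cell_ids(G)) == 7
        assert len(state.cell_ids(S)) == 14

    def test_volumes_within_ten_percent_of_favoured(self):
        config = GonadModelConfig(scale=0.375)
        geo = compute_geometry(initial_configuration(config))
        for cid in range(1, 8):
            assert abs(geo.volumes[cid] - config.v_g0_eff) <= 0.1 * config.v_g0_eff
        for cid in range(8, 22):
            assert abs(geo.volumes[cid] - config.v_s0_eff) <= 0.1 * config.v_s0_eff

    def test_elongated_start_below_point_six(self):
        state = initial_configuration(GonadModelConfig(scale=0.375))
        assert gonad_circularity(state) < 0.6

    def test_round_start_above_point_eight(self):
        state = initial_configuration(
            GonadModelConfig(scale=0.375, initial_aspect_ratio=1.0)
        )
        assert gonad_circularity(state) > 0.8

    def test_too_small_lattice_names_minimum(self):
        with pytest.raises(ConfigurationError, match="minimum dims"):
            initial_configuration(GonadModelConfig(scale=0.375, dims=(30, 40)))

    def test_partition_is_exact(self):
        state = initial_configuration(GonadModelConfig(scale=0.375))
        geo = compute_geometry(state)
        assert geo.volumes.sum() == state.labels.size


class TestGonadCircularityExamples:
    def test_rasterized_disc(self):
        labels = np.zeros((101, 101), np.int32)
        yy, xx = np.mgrid[:101, :101]
        labels[(yy - 50) ** 2 + (xx - 50) ** 2 <= 1600] = 1
        assert gonad_circularity(labels) >= 0.95

    def test_rectangle_closed_form(self):
        labels = np.zeros((30, 180), np.int32)
        labels[10:20, 10:170] = 1
        val = gonad_circularity(labels, method="edge")
        assert val == pytest.approx(4 * np.pi * 1600 / 340**2, abs=1e-9)


@pytest.fixture(scope="module")
def tiny_sweep():
    config = GonadModelConfig(scale=0.2)
    return phase_sweep(
        config, [-0.01, 0.0], [0.16], n_trials=2, n_mcs=60,
        mcs_window=(20, 60), record_every=20, seed=5,
    )


class TestPhaseSweep:

    def test_grid_and_trial_table_shape(self, tiny_sweep):
        assert tiny_sweep.mean_circularity.shape == (2, 1)
        assert len(tiny_sweep.trials) == 4
        assert set(tiny_sweep.trials["e_sgp_sgp"]) == {-0.01, 0.0}

    def test_sweep_is_deterministic(self, tiny_sweep):
        config = GonadModelConfig(scale=0.2)
        again = phase_sweep(
            config, [-0.01, 0.0], [0.16], n_trials=2, n_mcs=60,
            mcs_window=(20, 60), record_every=20, seed=5,
        )
        assert np.array_equal(again.mean_circularity, tiny_sweep.mean_circularity)
        assert again.trials.equals(tiny_sweep.trials)

    def test_window_validation(self):
        with pytest.raises(ConfigurationError):
            phase_sweep(GonadModelConfig(scale=0.2), [0.0], [0.16],
                        n_trials=1, n_mcs=10, mcs_window=(5, 50))

    def test_mean_at_lookup(self, tiny_sweep):
        sub = tiny_sweep.trials.query("e_sgp_sgp == -0.01")
        assert tiny_sweep.mean_at(-0.01, 0.16) == pytest.approx(
            sub["mean_circularity"].mean()
        )


def test_presets_cover_published_parameterisations():
    cfg_s4, run = preset_config("movie-s4")
    assert cfg_s4.e_sgp_sgp == -0.01 and cfg_s4.e_sgp_out == 0.16
    assert run["n_mcs"] == 20_000 and tuple(run["mcs_window"]) == (12_000, 20_000)
    cfg_s5, _ = preset_config("movie-s5")
    assert cfg_s5.e_sgp_sgp == 0.0
    with pytest.raises(ConfigurationError):
        preset_config("nope")
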