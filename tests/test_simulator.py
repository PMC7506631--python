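"""Synthetic voltammogram generator: closed forms, designs, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import etongue as et
from etongue.core_data import ValidationError
from etongue.simulator import AnalyteResponse, SensorResponseSpec

# forward grid spacing 0.01 V so the 0.39 V peak sits exactly on a grid point
PROGRAM = et.PotentialProgram(-0.7, 1.2, 0.01, 381)


def single_analyte_spec(sensitivity, k_sat=math.inf, **kwargs):
    return SensorResponseSpec(
        "s",
        {"PA": AnalyteResponse(sensitivity, 0.39, 0.15)},
        baseline_slope_uA_per_V=kwargs.pop("slope", 1.3),
        baseline_offset_uA=kwargs.pop("offset", -0.4),
        k_sat_uM=k_sat,
        **kwargs,
    )


def baseline_of(spec):
    E = PROGRAM.potentials()
    return spec.baseline_offset_uA + spec.baseline_slope_uA_per_V * E


class TestSimulateVoltammogram:
    def test_zero_concentration_gives_pure_baseline(self):
        spec = single_analyte_spec(0.06)
        v = et.simulate_voltammogram(spec, {"PA": 0.0}, PROGRAM)
        assert np.allclose(v.currents, baseline_of(spec))

    @pytest.mark.parametrize("sens,c", [(0.06, 50.0), (0.0598, 100.0), (0.0027, 250.0)])
    def test_linear_peak_height_closed_form(self, sens, c):
        """Peak height above baseline equals sensitivity x concentration."""
        spec = single_analyte_spec(sens)
        v = et.simulate_voltammogram(spec, {"PA": c}, PROGRAM)
        net = v.currents - baseline_of(spec)
        assert np.max(net) == pytest.approx(sens * c, rel=1e-12)

    def test_saturating_amplitude(self):
        spec = single_analyte_spec(0.06, k_sat=100.0)
        v = et.simulate_voltammogram(spec, {"PA": 100.0}, PROGRAM)
        net = v.currents - baseline_of(spec)
        assert np.max(net) == pytest.approx(0.06 * 100.0 * 0.5, rel=1e-12)

    def test_superposition_of_mixture(self, noise_free_specs):
        """Mixture trace = sum of single-analyte traces minus (n-1) baselines."""
        spec = noise_free_specs[0]
        conc = {"PA": 120.0, "AA": 700.0, "UA": 90.0}
        mix = et.simulate_voltammogram(spec, conc, PROGRAM).currents
        singles = [
            et.simulate_voltammogram(
                spec, {a: (conc[a] if a == one else 0.0) for a in conc}, PROGRAM
            ).currents
            for one in conc
        ]
        E = PROGRAM.potentials()
        base = spec.baseline_offset_uA + spec.baseline_slope_uA_per_V * E
        assert np.allclose(mix, sum(singles) - 2 * base, atol=1e-10)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            et.simulate_voltammogram(single_analyte_spec(0.06), {"PA": -1.0}, PROGRAM)

    def test_stochastic_spec_requires_rng(self):
        spec = single_analyte_spec(0.06, noise_sd_uA=0.5)
        with pytest.raises(ValidationError):
            et.simulate_voltammogram(spec, {"PA": 10.0}, PROGRAM)

    def test_drift_shifts_by_sample_index(self):
        spec = single_analyte_spec(0.06, drift_per_sample_uA=0.3)
        v0 = et.simulate_voltammogram(spec, {"PA": 10.0}, PROGRAM, sample_index=0)
        v5 = et.simulate_voltammogram(spec, {"PA": 10.0}, PROGRAM, sample_index=5)
        assert np.allclose(v5.currents - v0.currents, 1.5)


class TestDesigns:
    def test_three_cubed_factorial_has_27_samples(self):
        grid = et.tilted_factorial(et.DesignSpec())
        assert grid.shape == (27, 3)

    def test_zero_tilt_recovers_exact_grid(self):
        d = et.DesignSpec(analytes=("PA",), low_uM=(0.0,), high_uM=(500.0,),
                          levels_per_factor=2, tilt_fraction=0.0)
        assert sorted(et.tilted_factorial(d).ravel()) == [0.0, 500.0]

    def test_tilt_makes_levels_unique_within_bounds(self):
        d = et.DesignSpec(tilt_fraction=0.2)
        grid = et.tilted_factorial(d)
        lows, highs = np.array(d.low_uM), np.array(d.high_uM)
        assert np.all(grid >= lows) and np.all(grid <= highs)
        for f in range(3):
            interior = grid[(grid[:, f] > lows[f]) & (grid[:, f] < highs[f]), f]
            assert len(np.unique(interior)) == len(interior)

    def test_tilted_design_is_deterministic(self):
        d = et.DesignSpec(tilt_fraction=0.15)
        assert np.array_equal(et.tilted_factorial(d), et.tilted_factorial(d))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(levels=st.integers(2, 4), d=st.integers(1, 3),
           tilt=st.floats(0.0, 0.49))
    def test_factorial_size_and_bounds_property(self, levels, d, tilt):
        design = et.DesignSpec(
            analytes=tuple(f"a{i}" for i in range(d)),
            low_uM=(0.0,) * d, high_uM=(100.0,) * d,
            levels_per_factor=levels, tilt_fraction=tilt,
        )
        grid = et.tilted_factorial(design)
        assert grid.shape == (levels**d, d)
        assert np.all((grid >= 0.0) & (grid <= 100.0))

    def test_random_test_points(self):
        d = et.DesignSpec(n_random_test=11, seed=5)
        pts = et.random_test_points(d)
        assert pts.shape == (11, 3)
        assert np.array_equal(pts, et.random_test_points(d))
        lows, highs = np.array(d.low_uM), np.array(d.high_uM)
        assert np.all(pts >= lows) and np.all(pts <= highs)

    def test_uniform_sampling_mean(self):
        d = et.DesignSpec(analytes=("x",), low_uM=(0.0,), high_uM=(1.0,),
                          n_random_test=10_000, seed=1)
        assert abs(et.random_test_points(d).mean() - 0.5) < 0.02


class TestDatasets:
    def test_selection_dataset_shape(self, selection_ds):
        assert len(selection_ds) == 20  # (3 analytes + buffer) x 5 replicates
        assert sorted(set(selection_ds.class_labels())) == ["AA", "PA", "UA", "buffer"]
        assert len(selection_ds.sensor_roster) == 8

    def test_stock_concentration_is_250(self, selection_ds):
        pa = next(s for s in selection_ds if s.class_label == "PA")
        assert pa.concentrations["PA"] == 250.0
        assert pa.concentrations["AA"] == 0.0

    def test_minimal_selection_dataset(self, noise_free_specs):
        ds = et.simulate_selection_dataset(
            noise_free_specs[:1], analytes=["PA"], n_replicates=2,
            include_buffer=False, seed=0,
        )
        assert len(ds) == 2 and set(ds.class_labels()) == {"PA"}

    def test_invalid_replicates_rejected(self, informative_specs):
        with pytest.raises(ValidationError):
            et.simulate_selection_dataset(informative_specs, n_replicates=1)

    def test_seeded_determinism_bit_identical(self, informative_specs):
        a = et.simulate_selection_dataset(informative_specs, seed=3)
        b = et.simulate_selection_dataset(informative_specs, seed=3)
        for sa, sb in zip(a, b):
            for sid in a.sensor_roster:
                assert np.array_equal(
                    sa.voltammograms[sid].currents, sb.voltammograms[sid].currents
                )

    def test_mixture_dataset(self, noise_free_specs):
        conc = np.array([[10.0, 20.0, 30.0], [1.0, 2.0, 3.0]])
        ds = et.simulate_mixture_dataset(
            noise_free_specs, conc, analytes=("PA", "AA", "UA"), seed=0
        )
        assert len(ds) == 2
        assert np.array_equal(ds.concentration_matrix(), conc)


class TestDefaultArraySpecs:
    def test_counts_and_roles(self, array_specs):
        specs, roles = array_specs
        assert len(specs) == 8
        counts = {r: sum(v == r for v in roles.values()) for r in set(roles.values())}
        assert counts == {"informative": 4, "redundant": 2, "noisy": 2}

    def test_seeded_reproducibility(self):
        a, _ = et.default_array_specs(4, 2, 2, seed=1)
        b, _ = et.default_array_specs(4, 2, 2, seed=1)
        assert a == b

    def test_redundant_is_scaled_copy_of_parent(self, array_specs):
        specs, roles = array_specs
        by_id = {s.sensor_id: s for s in specs}
        red = by_id["red1_ZnO"]
        parent = by_id["ZnO"]
        for a in parent.responses:
            assert red.responses[a].sensitivity == pytest.approx(
                0.7 * parent.responses[a].sensitivity
            )
            assert red.responses[a].peak_potential_V == parent.responses[a].peak_potential_V

    def test_noisy_sensors_have_negligible_signal(self, array_specs):
        specs, roles = array_specs
        for s in specs:
            if roles[s.sensor_id] == "noisy":
                assert all(r.sensitivity < 0.002 for r in s.responses.values())
                assert s.noise_sd_uA > 1.0
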