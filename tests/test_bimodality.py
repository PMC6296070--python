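"""Change-of-variables transform of the lumen density through the hysteresis."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from gutswitch import InputDensity, transform_density
from gutswitch.bimodality import LayerMap, monte_carlo_histogram
from gutswitch.continuation import BranchCurve


def _linear_layer(name, x, slope):
    y = slope * x
    return LayerMap(
        name,
        x,
        y,
        PchipInterpolator(x, y),
        PchipInterpolator(y, x) if slope > 0 else PchipInterpolator(y[::-1], x[::-1]),
    )


@pytest.fixture
def empty_branch():
    return BranchCurve("k_Bo", "core", [])


class TestClosedFormMaps:
    def test_identity_map_reproduces_the_input(self, empty_branch):
        x = np.linspace(20.0, 240.0, 200)
        dens = InputDensity(130.0, 40.0)
        dt = transform_density(
            empty_branch,
            dens,
            weights={"lower": 1.0},
            fold_exclusion=0.0,
            layers={"lower": _linear_layer("lower", x, 1.0)},
        )
        inside = (dt.y_grid >= x[0]) & (dt.y_grid <= x[-1])
        assert np.allclose(dt.q_combined[inside], dens.pdf(dt.y_grid[inside]))

    def test_linear_map_rescales_exactly(self, empty_branch):
        x = np.linspace(20.0, 240.0, 200)
        dens = InputDensity(130.0, 40.0)
        dt = transform_density(
            empty_branch,
            dens,
            weights={"lower": 1.0},
            fold_exclusion=0.0,
            layers={"lower": _linear_layer("lower", x, 2.0)},
        )
        inside = (dt.y_grid >= 2 * x[0]) & (dt.y_grid <= 2 * x[-1])
        y_in = dt.y_grid[inside]
        assert np.allclose(dt.q_combined[inside], dens.pdf(y_in / 2.0) / 2.0)
        # change of variables preserves mass: the y-integral of q equals the
        # x-integral of p over the mapped nodes to machine precision
        mass_y = np.trapezoid(dt.q_combined[inside], y_in)
        mass_x = np.trapezoid(dens.pdf(y_in / 2.0), y_in / 2.0)
        assert mass_y == pytest.approx(mass_x, abs=1e-9)


class TestHysteresisTransform:
    def test_straddling_gaussian_becomes_bimodal(self, core_branch):
        dt = transform_density(core_branch, InputDensity(130.0, 40.0))
        modes = dt.modes()
        assert len(modes) == 2
        # one mode below the terminal B of the inflamed layer, one above
        # the terminal B of the healthy layer
        fold_b = sorted(f.state[-1] for f in core_branch.folds)
        assert modes[0] < fold_b[0] and modes[1] > fold_b[1]

    def test_mass_bookkeeping(self, core_branch):
        dt = transform_density(core_branch, InputDensity(130.0, 40.0))
        assert dt.total_mass() == pytest.approx(dt.retained_mass, abs=1e-3)
        assert dt.excluded_mass > 0.0

    def test_matches_monte_carlo_histogram(self, core_branch):
        dens = InputDensity(130.0, 40.0)
        dt = transform_density(core_branch, dens)
        rng = np.random.default_rng(2024)
        bins = np.linspace(dt.y_grid[0], dt.y_grid[-1], 61)
        hist = monte_carlo_histogram(
            dt.layers, dens, dt.weights, dt.excluded_windows, 100_000, rng, bins
        )
        q_mass = np.array(
            [
                np.trapezoid(
                    np.where((dt.y_grid >= a) & (dt.y_grid <= b), dt.q_combined, 0.0),
                    dt.y_grid,
                )
                for a, b in zip(bins[:-1], bins[1:])
            ]
        )
        q_prob = q_mass / q_mass.sum()
        h_prob = hist * np.diff(bins)
        h_prob = h_prob / h_prob.sum()
        tv = 0.5 * np.abs(q_prob - h_prob).sum()
        assert tv <= 0.03

    def test_unimodal_outside_the_bistable_window(self, core_branch):
        # input supported entirely above the fold of the inflamed branch:
        # only the healthy layer carries mass
        dt = transform_density(core_branch, InputDensity(270.0, 8.0))
        assert len(dt.modes()) == 1

    def test_refinement_convergence(self, core_branch, params):
        from gutswitch import StepControl, trace_branch

        fine = trace_branch(
            params, "core", "k_Bo", (10.0, 300.0), StepControl(initial=0.25, max_step=2.5)
        )
        dens = InputDensity(130.0, 40.0)
        q_coarse = transform_density(core_branch, dens)
        q_fine = transform_density(fine, dens)
        resampled = np.interp(q_coarse.y_grid, q_fine.y_grid, q_fine.q_combined)
        assert np.max(np.abs(q_coarse.q_combined - resampled)) <= 1e-3

    def test_csv_and_summary_outputs(self, core_branch, tmp_path):
        import pandas as pd

        dt = transform_density(core_branch, InputDensity(130.0, 40.0))
        path = tmp_path / "density.csv"
        dt.to_csv(path)
        df = pd.read_csv(path)
        assert {"y", "q_lower", "q_upper", "q_combined"} <= set(df.columns)
        summary = dt.summary()
        assert len(summary["modes"]) == 2
        assert 0.9 < summary["retained_mass"] < 1.0


class TestValidation:
    def test_nonmonotone_layer_rejected(self):
        from gutswitch.continuation import BranchPoint

        pts = [
            BranchPoint(p, np.array([0.1, 1.0, 1.0, 0.1, b]), "stable")
            for p, b in zip([100.0, 120.0, 140.0, 160.0, 180.0], [5.0, 9.0, 7.0, 11.0, 13.0])
        ]
        curve = BranchCurve("k_Bo", "core", pts)
        with pytest.raises(ValueError, match="monotone"):
            transform_density(curve, InputDensity(130.0, 40.0))

    def test_weights_must_be_a_distribution(self, core_branch):
        with pytest.raises(ValueError):
            transform_density(
                core_branch, InputDensity(130.0, 40.0), weights={"lower": 0.7, "upper": 0.7}
            )

    def test_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            InputDensity(130.0, 0.0)
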