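"""Transition interpolation, bootstrap, weight sensitivity, mechanism metrics."""

import numpy as np
import pandas as pd
import pytest

from chiasm import (
    GridSpec,
    NoCrossingError,
    ObjectiveWeights,
    bootstrap_transition,
    estimate_transition,
    mechanism_metrics,
    mechanism_scan,
    ofat_sensitivity,
    run_scan,
)
from chiasm.analysis import MECHANISM_ARCHS, reselect_cross
from chiasm.network import enumerate_architectures
from chiasm.scan import ScanCellResult, ScanResult

from conftest import make_trace

ARCHS = enumerate_architectures()


class TestEstimateTransition:
    def test_dense_scan_bracket_interpolation(self):
        est = estimate_transition([(0.45, 0.168), (0.50, 0.677)])
        assert est.theta_c == pytest.approx(0.482613, abs=1e-6)
        assert est.bracket == (0.45, 0.50)

    def test_crossing_exactly_at_a_sample(self):
        est = estimate_transition([(0.4, 0.5), (0.5, 0.9)])
        assert est.theta_c == pytest.approx(0.4)

    def test_no_crossing_raises(self):
        with pytest.raises(NoCrossingError, match="no crossing"):
            estimate_transition([(0.1, 0.9), (0.2, 0.95)])

    def test_descending_crossing_supported(self):
        est = estimate_transition([(0.1, 0.8), (0.2, 0.2)])
        assert est.theta_c == pytest.approx(0.15)

    def test_first_crossing_wins(self):
        est = estimate_transition(
            [(0.1, 0.2), (0.2, 0.8), (0.3, 0.4), (0.4, 0.9)]
        )
        assert est.bracket == (0.1, 0.2)

    def test_degenerate_flat_pair_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_transition([(0.1, 0.5), (0.2, 0.5)])

    def test_malformed_curves_rejected(self):
        with pytest.raises(ValueError, match="two points"):
            estimate_transition([(0.1, 0.4)])
        with pytest.raises(ValueError, match="increasing"):
            estimate_transition([(0.2, 0.4), (0.1, 0.6)])

    def test_accepts_dataframe_curve(self):
        df = pd.DataFrame({"theta": [0.4, 0.6], "cross_freq": [0.25, 0.75]})
        assert estimate_transition(df).theta_c == pytest.approx(0.5)

    def test_matches_brute_force_fine_interpolation(self):
        """Analytic bracketing agrees with a dense numerical scan of the
        piecewise-linear curve to better than 1e-6."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            thetas = np.sort(rng.uniform(0, 1, n))
            thetas += np.arange(n) * 1e-6  # guarantee strictly increasing
            freqs = np.sort(rng.uniform(0, 1, n))  # monotone curve
            if freqs[0] >= 0.5 or freqs[-1] <= 0.5:
                continue
            est = estimate_transition(list(zip(thetas, freqs)))
            fine = np.linspace(thetas[0], thetas[-1], 10_001)
            vals = np.interp(fine, thetas, freqs)
            k = int(np.argmax(vals >= 0.5))
            x0, x1, y0, y1 = fine[k - 1], fine[k], vals[k - 1], vals[k]
            brute = x0 + (0.5 - y0) / (y1 - y0) * (x1 - x0)
            assert est.theta_c == pytest.approx(brute, abs=1e-6)


def synthetic_result(records) -> ScanResult:
    """Build a ScanResult from (d_long, theta, cross) triples."""
    grid = GridSpec((1,), (0.05,), (0.5,), (0.0, 1.0), repetitions=1)
    cells = [
        ScanCellResult(
            d_long=int(d), sigma=0.05, i_inhib=0.5, theta=float(t),
            mean_j=np.arange(8.0), mean_components=np.zeros((8, 5)),
            best_index=4 if c else 0, best_code="c--" if c else "i--",
            cross=int(c), cross_rep_fraction=float(c),
        )
        for d, t, c in records
    ]
    return ScanResult(grid, cells)


class TestBootstrap:
    @staticmethod
    def uniform_records(crossings):
        """Cells whose per-theta cross values are constant: resampling can
        never change the curve."""
        recs = []
        for d in (1, 2, 3):
            for theta, c in crossings:
                recs.extend([(d, theta, c)] * 4)
        return recs

    def test_degenerate_resampling_collapses_to_point_estimate(self):
        res = synthetic_result(self.uniform_records(
            [(0.3, 0), (0.5, 0), (0.7, 1)]
        ))
        boot = bootstrap_transition(res, B=5, seed=0)
        assert boot.theta_c_median == pytest.approx(boot.theta_c_point)
        assert boot.theta_c_ci[0] == boot.theta_c_ci[1]
        assert boot.n_failed_global == 0

    def test_constant_per_delay_curves_give_zero_slope(self):
        res = synthetic_result(self.uniform_records(
            [(0.2, 0), (0.6, 1)]
        ))
        boot = bootstrap_transition(res, B=10, seed=1)
        assert boot.slope_point == pytest.approx(0.0, abs=1e-12)
        assert boot.slope_median == pytest.approx(0.0, abs=1e-12)
        assert len(boot.per_dlong_theta_c) == 3

    def test_bootstrap_is_deterministic_given_seed(self):
        # mixed cells per theta: genuine resampling variability with a
        # guaranteed crossing between 0.3 and 0.7
        frac_ones = {0.3: 2, 0.5: 5, 0.7: 9}
        recs = [(d, t, int(i < k))
                for d in (1, 2) for t, k in frac_ones.items()
                for i in range(10)]
        res = synthetic_result(recs)
        b1 = bootstrap_transition(res, B=50, seed=9)
        b2 = bootstrap_transition(res, B=50, seed=9)
        assert b1.to_dict() == b2.to_dict()

    def test_all_replicates_failing_raises(self):
        res = synthetic_result(self.uniform_records([(0.3, 0), (0.7, 0)]))
        with pytest.raises(NoCrossingError):
            bootstrap_transition(res, B=3, seed=0)


@pytest.fixture(scope="module")
def small_scan():
    grid = GridSpec(
        d_long_values=(2, 8), sigma_values=(0.05, 0.08),
        i_inhib_values=(0.5,), theta_values=(0.25, 0.45, 0.55, 0.85),
        dims="two_d", repetitions=2, base_seed=13,
    )
    return run_scan(grid)


class TestOfat:

    def test_identity_rescale_reproduces_selection(self, small_scan):
        cross = reselect_cross(small_scan, small_scan.grid.weights)
        assert np.array_equal(cross, small_scan.cross)

    def test_table_covers_all_weight_scale_conditions(self, small_scan):
        table = ofat_sensitivity(small_scan, scales=(0.5, 1.0, 1.5))
        assert len(table) == 15
        assert set(table["weight"]) == set(ObjectiveWeights.names)
        base = table[table["scale"] == 1.0]
        assert base["theta_c"].nunique() == 1  # identity perturbation

    def test_rescaled_weights_change_only_one_coefficient(self):
        w = ObjectiveWeights().scaled("lambda_effort", 1.5)
        assert w.lambda_effort == pytest.approx(0.12)
        assert w.lambda_track == 1.0
        with pytest.raises(ValueError, match="weight"):
            ObjectiveWeights().scaled("lambda_speed", 2.0)


class TestMechanism:
    def test_metrics_examples(self):
        T = 6
        perfect = make_trace(np.full(T, 0.5), m_r=np.full(T, 0.5))
        mismatch, align, total = mechanism_metrics(perfect)
        assert mismatch == 0.0 and align == 1.0
        assert total == pytest.approx(T * 0.25)

        opposed = make_trace(np.ones(T), m_l=np.full(T, 0.5))
        mismatch, align, _ = mechanism_metrics(opposed)
        assert mismatch == pytest.approx(1.5) and align == 0.0

    def test_zero_error_counts_as_not_aligned(self):
        tr = make_trace(np.zeros(4), m_r=np.ones(4))
        _, align, total = mechanism_metrics(tr)
        assert align == 0.0 and total == 0.0

    def test_scan_shape_and_pairing(self):
        df = mechanism_scan([0.3, 0.7], repetitions=2, base_seed=4)
        assert len(df) == 6  # 2 thetas x (2 classes + difference)
        assert set(df["arch_class"]) == {
            "ipsilateral", "contralateral", "difference"
        }
        sub = df[df["theta"] == 0.3].set_index("arch_class")
        assert sub.loc["difference", "mismatch"] == pytest.approx(
            sub.loc["ipsilateral", "mismatch"]
            - sub.loc["contralateral", "mismatch"]
        )

    def test_canonical_pair_differs_only_in_routing(self):
        ipsi = MECHANISM_ARCHS["ipsilateral"]
        contra = MECHANISM_ARCHS["contralateral"]
        assert not ipsi.is_contralateral and contra.is_contralateral
        assert ipsi.commissural_excitation and contra.commissural_excitation
        assert ipsi.local_feedback and contra.local_feedback
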