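"""Free-energy estimators: MBAR, BAR, EXP and the replicate bookkeeping."""

import math

import numpy as np
import pytest

import abfekit as ak
from conftest import make_gaussian_pair_table


def make_ladder_table(widths, centers, n, seed):
    rng = np.random.default_rng(seed)
    xs = [rng.normal(c, w, n) for c, w in zip(centers, widths)]
    x = np.concatenate(xs)
    u = np.stack([(x - c) ** 2 / (2 * w * w) for c, w in zip(centers, widths)])
    return ak.ReducedPotentialTable(u=u, n_k=[n] * len(widths))


class TestMBAR:
    def test_indistinguishable_windows_give_zero(self):
        rng = np.random.default_rng(0)
        u_row = rng.normal(5.0, 1.0, 300)
        table = ak.ReducedPotentialTable(
            u=np.stack([u_row, u_row, u_row]), n_k=[100, 100, 100]
        )
        prof = ak.MBAR(table).fit()
        assert prof.converged
        np.testing.assert_allclose(prof.f, 0.0, atol=1e-10)

    def test_harmonic_pair_matches_partition_functions(self):
        # kappa 1 vs 4 <=> widths 1 vs 0.5: delta f = ln 2
        table = make_gaussian_pair_table(widths=(1.0, 0.5), n=4000, seed=2)
        prof = ak.MBAR(table).fit()
        assert prof.delta_f() == pytest.approx(math.log(2.0), abs=0.06)

    def test_three_window_telescoping_is_exact(self):
        table = make_ladder_table((1.0, 0.8, 0.6), (0.0, 0.3, 0.6), 500, seed=3)
        prof = ak.MBAR(table).fit()
        assert prof.delta_f(0, 2) == pytest.approx(
            prof.delta_f(0, 1) + prof.delta_f(1, 2), abs=1e-12
        )

    def test_reduces_to_bar_for_two_windows(self):
        table = make_gaussian_pair_table(widths=(1.0, 0.7), centers=(0.0, 0.5), n=800, seed=4)
        assert ak.MBAR(table).fit().delta_f() == pytest.approx(
            ak.bar_pair(table), abs=1e-8
        )

    def test_gauge_invariance_under_row_offset(self):
        table = make_ladder_table((1.0, 0.8, 0.6), (0.0, 0.3, 0.6), 400, seed=5)
        shifted = ak.ReducedPotentialTable(u=table.u + 7.3, n_k=table.n_k)
        f0 = ak.MBAR(table).fit().f
        f1 = ak.MBAR(shifted).fit().f
        np.testing.assert_allclose(np.diff(f0), np.diff(f1), atol=1e-9)

    def test_bit_stable_across_repeated_solves(self):
        table = make_ladder_table((1.0, 0.9), (0.0, 0.2), 300, seed=6)
        f1 = ak.MBAR(table).fit().f
        f2 = ak.MBAR(table).fit().f
        assert np.array_equal(f1, f2)

    def test_error_decays_with_sample_size(self):
        # absolute error of delta-f shrinks roughly as n^(-1/2)
        truth = math.log(1.0 / 0.6)
        rmse = {}
        for n in (100, 1000, 10000):
            errs = [
                ak.bar_pair(make_gaussian_pair_table(widths=(1.0, 0.6), n=n, seed=s)) - truth
                for s in range(12)
            ]
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[100] > rmse[1000] > rmse[10000]
        assert rmse[100] / rmse[10000] > 3.0

    def test_rejects_empty_and_single_window(self):
        with pytest.raises(ValueError):
            ak.ReducedPotentialTable(u=np.zeros((2, 3)), n_k=[1, 1])
        with pytest.raises(ValueError):
            ak.MBAR(ak.ReducedPotentialTable(u=np.zeros((1, 2)), n_k=[2]))

    def test_no_overlap_flags_warning_channel(self):
        table = make_gaussian_pair_table(widths=(0.1, 0.1), centers=(0.0, 50.0), n=200, seed=7)
        prof = ak.MBAR(table).fit()
        assert prof.overlap_warning


class TestBAR:
    def test_identical_windows_give_zero(self):
        rng = np.random.default_rng(8)
        u_row = rng.normal(1.0, 0.3, 400)
        table = ak.ReducedPotentialTable(u=np.stack([u_row, u_row]), n_k=[200, 200])
        assert ak.bar_pair(table) == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_pair_truth(self):
        table = make_gaussian_pair_table(widths=(1.0, 0.5), n=20000, seed=9)
        assert ak.bar_pair(table) == pytest.approx(math.log(2.0), abs=0.03)

    def test_requires_samples_on_both_sides(self):
        table = ak.ReducedPotentialTable(u=np.zeros((2, 5)), n_k=[5, 0])
        with pytest.raises(ValueError):
            ak.bar_pair(table)


class TestEXP:
    def test_identical_windows_give_zero(self):
        rng = np.random.default_rng(10)
        u_row = rng.normal(0.0, 1.0, 200)
        table = ak.ReducedPotentialTable(u=np.stack([u_row, u_row]), n_k=[100, 100])
        assert ak.exp_pair(table, "forward") == pytest.approx(0.0, abs=1e-12)
        assert ak.exp_pair(table, "reverse") == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_is_recovered_exactly(self):
        rng = np.random.default_rng(11)
        u0 = rng.normal(0.0, 1.0, 300)
        table = ak.ReducedPotentialTable(u=np.stack([u0, u0 + 2.5]), n_k=[150, 150])
        assert ak.exp_pair(table, "forward") == pytest.approx(2.5, rel=1e-12)
        assert ak.exp_pair(table, "reverse") == pytest.approx(2.5, rel=1e-12)

    def test_gaussian_pair_converges_to_truth(self):
        table = make_gaussian_pair_table(widths=(1.0, 0.8), n=20000, seed=12)
        truth = math.log(1.0 / 0.8)
        assert ak.exp_pair(table, "forward") == pytest.approx(truth, abs=0.05)
        assert ak.exp_pair(table, "reverse") == pytest.approx(truth, abs=0.05)

    def test_directions_bracket_bar_in_expectation(self):
        # on a well-overlapped pair the finite-sample biases are opposite:
        # forward EXP high, reverse EXP low, BAR in between (seed average)
        fwd, rev, bar = [], [], []
        for seed in range(300):
            table = make_gaussian_pair_table(
                widths=(1.0, 0.5), centers=(0.0, 1.0), n=60, seed=seed
            )
            fwd.append(ak.exp_pair(table, "forward"))
            rev.append(ak.exp_pair(table, "reverse"))
            bar.append(ak.bar_pair(table))
        assert np.mean(rev) < np.mean(bar) < np.mean(fwd)


class TestDeltasAndSpreads:
    def test_adjacent_deltas_arithmetic(self):
        prof = ak.MBARResults(
            f=np.array([0.0, 1.0, 3.0]), converged=True, iterations=1, tolerance_achieved=0.0
        )
        np.testing.assert_allclose(
            ak.adjacent_deltas(prof, kT=0.5925), [0.5925, 1.185], atol=1e-12
        )

    def test_deltas_telescope_to_total(self):
        f = np.array([0.0, 0.4, -0.3, 1.1])
        prof = ak.MBARResults(f=f, converged=True, iterations=1, tolerance_achieved=0.0)
        deltas = ak.adjacent_deltas(prof, kT=0.6)
        assert deltas.sum() == pytest.approx((f[-1] - f[0]) * 0.6, abs=1e-12)

    def test_refuses_unconverged_profile(self):
        prof = ak.MBARResults(
            f=np.zeros(3), converged=False, iterations=10, tolerance_achieved=1.0
        )
        with pytest.raises(ValueError):
            ak.adjacent_deltas(prof, kT=0.6)

    @pytest.mark.parametrize(
        "values,expected",
        [([1.0, 1.0, 1.0, 1.0, 1.0], 0.0), ([1.0, 2.0, 3.0], 1.0)],
    )
    def test_replicate_spread_examples(self, values, expected):
        assert ak.replicate_spread(np.array(values)) == pytest.approx(expected, abs=1e-12)

    def test_spread_translation_invariance(self):
        x = np.array([0.2, -0.1, 0.5, 0.3, 0.0])
        assert ak.replicate_spread(x + 10.0) == pytest.approx(ak.replicate_spread(x), abs=1e-12)

    def test_spread_needs_two_replicates(self):
        with pytest.raises(ValueError):
            ak.replicate_spread(np.array([1.0]))
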