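"""Adaptive epoch controller: retirement rule, protocols, determinism."""

import numpy as np
import pytest

import abfekit as ak
from abfekit.adaptive import AdaptiveProtocol


def small_spec(slow=(), phi=0.9, inflation=1.0, hardness=1.3):
    """A 10-window double-decoupling ladder (2 coulomb + 3 vdw per leg)."""
    schedule = ak.build_schedule(2, 3)
    centers, widths = [], []
    for idx in schedule.block_indices().values():
        c = 0.0
        for pos in range(len(idx)):
            w = hardness**pos
            centers.append(c)
            widths.append(w)
            c += 0.8 * w
    return ak.GaussianLadderSpec(
        centers=tuple(centers),
        widths=tuple(widths),
        noise=ak.SlowWindowNoiseSpec(slow_windows=slow, phi=phi, variance_inflation=inflation),
        schedule=schedule,
    )


def truth_dg(spec):
    pairs = spec.schedule.adjacent_pairs()
    deltas = spec.truth_pair_deltas(pairs)
    sign = np.array(
        [1.0 if spec.schedule.windows[i].leg == "free" else -1.0 for i, _ in pairs]
    )
    return float((deltas * sign).sum() * spec.kT)


class TestAssessPairs:
    def test_direct_rule_application(self):
        pairs = [(0, 1), (1, 2), (2, 3)]
        active = ak.assess_pairs(np.array([0.05, 0.2, 0.08]), 0.1, pairs)
        assert active == {1, 2}

    def test_infinite_threshold_retires_everything(self):
        pairs = [(0, 1), (1, 2)]
        assert ak.assess_pairs(np.array([5.0, 9.0]), np.inf, pairs) == set()

    def test_zero_threshold_keeps_all_noisy_windows(self):
        pairs = [(0, 1), (1, 2)]
        assert ak.assess_pairs(np.array([1e-6, 1e-9]), 0.0, pairs) == {0, 1, 2}

    def test_rejects_negative_spreads(self):
        with pytest.raises(ValueError):
            ak.assess_pairs(np.array([-0.1]), 0.1, [(0, 1)])


class TestRunAdaptive:
    def test_noiseless_backend_terminates_immediately(self):
        # all windows identical: every pair delta is exactly 0 in every
        # replicate, so spreads are 0 and everything retires at once
        schedule = ak.build_schedule(2, 3)
        spec = ak.GaussianLadderSpec(
            centers=(0.0,) * 10, widths=(1.0,) * 10, schedule=schedule
        )
        cfg = ak.AdaptiveConfig(seed=0, epoch_length=30, min_epochs=1)
        res = ak.run_adaptive(cfg, spec)
        assert res.converged
        assert len(res.records) == 1
        assert max(res.records[0].pair_sigma) == pytest.approx(0.0, abs=1e-12)

    def test_truth_recovery_within_combined_error(self):
        spec = small_spec()
        truth = truth_dg(spec)
        errs, ses = [], []
        for seed in range(20):
            cfg = ak.AdaptiveConfig(seed=seed, epoch_length=150, max_epochs=6)
            res = ak.run_adaptive(cfg, spec)
            errs.append(res.abfe.dg_binding_standard - truth)
            ses.append(res.abfe.sigma / np.sqrt(cfg.n_replicates))
        mean_err = np.mean(errs)
        combined_se = np.sqrt(np.mean(np.square(ses)) / len(ses))
        assert abs(mean_err) <= 3.0 * max(combined_se, 1e-12)

    def test_retired_pairs_never_reactivate_and_ledger_monotone(self):
        spec = small_spec(slow=(3,), phi=0.95, inflation=1.5)
        cfg = ak.AdaptiveConfig(seed=2, epoch_length=100, max_epochs=8)
        res = ak.run_adaptive(cfg, spec)
        prev_retired: set[int] = set()
        prev_cum = np.zeros(10)
        for rec in res.records:
            assert prev_retired <= set(rec.retired_pairs)
            cum = np.array(rec.cumulative_samples)
            assert np.all(cum >= prev_cum)
            prev_retired = set(rec.retired_pairs)
            prev_cum = cum

    def test_determinism_byte_for_byte(self):
        spec = small_spec(slow=(3,), phi=0.9, inflation=1.5)
        cfg = ak.AdaptiveConfig(seed=11, epoch_length=80, max_epochs=5)
        r1 = ak.run_adaptive(cfg, spec)
        r2 = ak.run_adaptive(cfg, spec)
        assert r1.records == r2.records
        assert r1.abfe == r2.abfe

    def test_tau_monotonicity_under_shared_streams(self):
        spec = small_spec(slow=(3,), phi=0.9, inflation=1.5)
        totals = []
        for tau in (0.02, 0.1, 0.5):
            cfg = ak.AdaptiveConfig(tau=tau, seed=5, epoch_length=100, max_epochs=8)
            totals.append(ak.run_adaptive(cfg, spec).total_samples)
        assert totals[0] >= totals[1] >= totals[2]

    def test_resumes_after_backend_failure(self):
        class FlakyBackend(ak.GaussianLadderBackend):
            def __init__(self, *a, **kw):
                super().__init__(*a, **kw)
                self.failures_left = 1

            def sample(self, window, replicate, n):
                if window == 4 and self.failures_left:
                    self.failures_left -= 1
                    raise RuntimeError("engine crashed")
                return super().sample(window, replicate, n)

        spec = small_spec()
        cfg = ak.AdaptiveConfig(seed=3, epoch_length=60, max_epochs=4)
        proto = AdaptiveProtocol(cfg, FlakyBackend(spec, cfg.n_replicates, cfg.seed))
        with pytest.raises(RuntimeError):
            proto.run()
        res = proto.run()  # resumes from the last complete epoch
        assert res.converged
        assert res.total_samples > 0


class TestRunStatic:
    def test_equals_adaptive_with_zero_threshold(self):
        spec = small_spec()
        cfg = ak.AdaptiveConfig(tau=0.0, seed=7, epoch_length=50, max_epochs=3)
        adaptive = ak.run_adaptive(cfg, spec)
        static = ak.run_static(cfg, spec, n_epochs=3)
        assert adaptive.abfe.replicate_values == static.abfe.replicate_values
        assert adaptive.per_window_samples == static.per_window_samples

    def test_budget_matches_schedule_arithmetic(self):
        spec = small_spec()
        cfg = ak.AdaptiveConfig(seed=1, epoch_length=40, profile_every=100)
        res = ak.run_static(cfg, spec, n_epochs=4)
        expected = ak.standard_protocol_budget(
            spec.schedule, ns_per_window=40 * 4, n_replicates=cfg.n_replicates
        )
        assert res.total_samples == expected

    def test_truth_recovery(self):
        spec = small_spec()
        truth = truth_dg(spec)
        cfg = ak.AdaptiveConfig(seed=9, epoch_length=400, profile_every=100)
        res = ak.run_static(cfg, spec, n_epochs=3)
        assert res.abfe.dg_binding_standard == pytest.approx(
            truth, abs=4 * res.abfe.sigma + 0.05
        )


class TestSavings:
    def test_identical_ledgers_give_unity(self):
        spec = small_spec()
        cfg = ak.AdaptiveConfig(seed=0, epoch_length=30, profile_every=10)
        res = ak.run_static(cfg, spec, n_epochs=2)
        assert ak.savings_factor(res, res) == pytest.approx(1.0)

    def test_direct_division(self):
        spec = small_spec()
        cfg = ak.AdaptiveConfig(seed=0, epoch_length=30, profile_every=10)
        r2 = ak.run_static(cfg, spec, n_epochs=2)
        r4 = ak.run_static(cfg, spec, n_epochs=4)
        assert ak.savings_factor(r4, r2) == pytest.approx(2.0)


class TestNoBiasProperty:
    def test_adaptive_statistically_indistinguishable_from_static(self, ladder_comparison):
        """Over 50 seeds on the reference ladder the mean adaptive-static
        difference is within twice the standard error of the difference."""
        d = ladder_comparison.diffs
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean()) < 2.0 * se
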