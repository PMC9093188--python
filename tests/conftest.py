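"""Shared fixtures.

The expensive protocol-comparison simulation (50 seeds of adaptive vs
static on the 76-window ladder) is session-scoped so the acceptance test
and the no-bias property test share one run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import abfekit as ak


@dataclass(frozen=True)
class LadderComparison:
    """Adaptive-vs-static comparison across seeds on the reference ladder."""

    diffs: np.ndarray  # adaptive minus static physical dG, kcal/mol per seed
    savings: np.ndarray  # savings factor per seed
    per_window_adaptive: np.ndarray  # (n_seeds, K) cumulative samples
    slow_windows: tuple[int, ...]
    n_windows: int


def make_gaussian_pair_table(
    widths=(1.0, 0.5),
    centers=(0.0, 0.0),
    n=2000,
    seed=0,
) -> ak.ReducedPotentialTable:
    """Two harmonic windows with exact free-energy difference ln(w0/w1)."""
    rng = np.random.default_rng(seed)
    xs = [rng.normal(c, w, n) for c, w in zip(centers, widths)]
    x = np.concatenate(xs)
    u = np.stack([(x - c) ** 2 / (2.0 * w * w) for c, w in zip(centers, widths)])
    return ak.ReducedPotentialTable(u=u, n_k=[n, n])


@pytest.fixture(scope="session")
def ladder_comparison() -> LadderComparison:
    """50 seeds of the adaptive protocol against the 10-epoch static one."""
    spec = ak.default_ladder_spec()
    diffs, savings, per_window = [], [], []
    for seed in range(50):
        cfg = ak.AdaptiveConfig(seed=seed, profile_every=100)
        res_a = ak.run_adaptive(cfg, spec)
        res_s = ak.run_static(cfg, spec, n_epochs=10)
        diffs.append(res_a.abfe.dg_binding_standard - res_s.abfe.dg_binding_standard)
        savings.append(ak.savings_factor(res_s, res_a))
        per_window.append(res_a.per_window_samples)
    return LadderComparison(
        diffs=np.array(diffs),
        savings=np.array(savings),
        per_window_adaptive=np.array(per_window),
        slow_windows=spec.noise.slow_windows,
        n_windows=spec.n_windows,
    )
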