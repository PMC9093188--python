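"""Adaptive per-window convergence control of a lambda schedule.

The protocol: run replicated sampling (quintuplicate by default) for one
epoch over every active window, estimate the free-energy change of every
neighbouring window pair per replicate from all samples accumulated so
far, and compare the across-replicate spread of each pair against a
threshold ``tau`` (0.100 kcal/mol by default). Pairs whose spread is at
or below ``tau`` retire — both member windows stop sampling once none of
their pairs remains active — while noisy pairs are carried forward to the
next epoch. Iteration ends at ``max_epochs`` or when every pair has
retired. A premature-termination guard requires at least ``min_epochs``
epochs of data before any pair may retire, since a single lucky epoch can
understate the spread.

The static reference protocol runs the identical sampling and estimation
path with retirement disabled, giving the equal-allocation baseline for
bias and resource-savings comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alchemy import ABFEResult, LambdaSchedule, assemble_abfe
from .backends import GaussianLadderBackend, GaussianLadderSpec
from .estimators import MBAR, ReducedPotentialTable, bar_pair, replicate_spread

__all__ = [
    "AdaptiveConfig",
    "EpochRecord",
    "ConvergenceProfile",
    "ProtocolResult",
    "assess_pairs",
    "AdaptiveProtocol",
    "run_adaptive",
    "run_static",
    "savings_factor",
]


@dataclass(frozen=True)
class AdaptiveConfig:
    """Controller parameters.

    ``epoch_length`` is in samples per window per replicate — the
    engine-agnostic stand-in for the 5 ns epoch of an MD implementation
    (one sample playing the role of one saved frame). ``tau`` is in
    kcal/mol and is compared against the across-replicate standard
    deviation (``spread_statistic="sd"``) of each adjacent-pair
    free-energy change.
    """

    tau: float = 0.100
    epoch_length: int = 200
    n_replicates: int = 5
    max_epochs: int = 15
    min_epochs: int = 2
    seed: int = 0
    pair_estimator: str = "bar"  # "bar" (pairwise) or "mbar" (full-leg solve)
    spread_statistic: str = "sd"
    profile_every: int = 1  # static runs: estimate the profile every k-th epoch

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.epoch_length < 1:
            raise ValueError("epoch_length must be >= 1 sample")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates to form a spread")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.min_epochs < 1:
            raise ValueError("min_epochs must be >= 1")
        if self.pair_estimator not in ("bar", "mbar"):
            raise ValueError("pair_estimator must be 'bar' or 'mbar'")
        if self.profile_every < 1:
            raise ValueError("profile_every must be >= 1")


@dataclass(frozen=True)
class EpochRecord:
    """State of the controller after one epoch (all tuples: hashable, comparable)."""

    epoch_index: int
    active_windows: tuple[int, ...]
    pair_mean: tuple[float, ...]  # kcal/mol, per adjacent pair
    pair_sigma: tuple[float, ...]  # kcal/mol, across-replicate spread
    retired_pairs: tuple[int, ...]  # pair indices retired at or before this epoch
    cumulative_samples: tuple[int, ...]  # per window, summed over replicates


@dataclass(frozen=True)
class ConvergenceProfile:
    """Per-epoch trajectory of the physical binding free-energy estimate."""

    epochs: tuple[int, ...]
    dg_mean: tuple[float, ...]  # mean over replicates of (free - bound), kcal/mol
    dg_sd: tuple[float, ...]
    pair_sigma_history: tuple[tuple[float, ...], ...]


@dataclass(frozen=True)
class ProtocolResult:
    """Everything a protocol run produces."""

    abfe: ABFEResult
    profile: ConvergenceProfile
    records: tuple[EpochRecord, ...]
    per_window_samples: tuple[int, ...]  # summed over replicates
    total_samples: int
    converged: bool  # every pair retired before max_epochs (adaptive only)
    pairs: tuple[tuple[int, int], ...] = field(default=(), repr=False)


def assess_pairs(
    sigma: np.ndarray,
    tau: float,
    pairs: list[tuple[int, int]],
) -> set[int]:
    """Windows to carry forward: union over pairs whose spread exceeds tau.

    A pair (i, j) with spread strictly above ``tau`` keeps *both* member
    windows active; pairs at or below ``tau`` retire.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape[0] != len(pairs):
        raise ValueError("one spread per pair required")
    if np.any(sigma < 0):
        raise ValueError("spreads must be non-negative")
    active: set[int] = set()
    for s, (i, j) in zip(sigma, pairs):
        if s > tau:
            active.update((i, j))
    return active


class AdaptiveProtocol:
    """Epoch controller over a sampling backend and a lambda schedule.

    The controller owns all accumulated per-(window, replicate) sample
    streams, so a run interrupted by a backend failure keeps its state
    and ``run()`` may simply be called again to resume.
    """

    def __init__(
        self,
        config: AdaptiveConfig,
        backend: GaussianLadderBackend | GaussianLadderSpec,
        schedule: LambdaSchedule | None = None,
        dg_restraint_on_bound: float = 0.0,
        dg_ss: float = 0.0,
        adaptive: bool = True,
    ):
        if isinstance(backend, GaussianLadderSpec):
            backend = GaussianLadderBackend(backend, config.n_replicates, config.seed)
        self.config = config
        self.backend = backend
        self.schedule = schedule or backend.spec.schedule
        if self.schedule is None:
            raise ValueError("a lambda schedule is required")
        if len(self.schedule) != backend.spec.n_windows:
            raise ValueError("schedule and backend disagree on window count")
        self.adaptive = adaptive
        self.dg_restraint_on_bound = dg_restraint_on_bound
        self.dg_ss = dg_ss

        self.pairs = self.schedule.adjacent_pairs()
        if not self.pairs:
            raise ValueError("schedule defines no adjacent pairs: nothing to control")
        K = len(self.schedule)
        R = config.n_replicates
        self._samples: dict[tuple[int, int], list[np.ndarray]] = {
            (w, r): [] for w in range(K) for r in range(R)
        }
        self._retired = np.zeros(len(self.pairs), dtype=bool)
        # last per-replicate estimate of each pair delta, in kT
        self._pair_est = np.full((len(self.pairs), R), np.nan)
        self._records: list[EpochRecord] = []
        self._epoch = 0
        self._active: set[int] = set(range(K))

    # -- helpers -----------------------------------------------------------

    def _cumulative(self, window: int, replicate: int) -> np.ndarray:
        chunks = self._samples[(window, replicate)]
        return np.concatenate(chunks) if chunks else np.empty(0)

    def _estimate_pair_bar(self, p: int, replicate: int) -> float:
        i, j = self.pairs[p]
        xi = self._cumulative(i, replicate)
        xj = self._cumulative(j, replicate)
        u = self.backend.evaluate_u(np.concatenate([xi, xj]), [i, j])
        table = ReducedPotentialTable(u=u, n_k=np.array([xi.size, xj.size]))
        return bar_pair(table)

    def _estimate_pairs_mbar(self, replicate: int) -> np.ndarray:
        """Full-leg MBAR per (leg, stage) block; pair deltas from f diffs."""
        out = np.full(len(self.pairs), np.nan)
        pair_index = {pair: p for p, pair in enumerate(self.pairs)}
        for idx in self.schedule.block_indices().values():
            xs = [self._cumulative(w, replicate) for w in idx]
            u = self.backend.evaluate_u(np.concatenate(xs), idx)
            table = ReducedPotentialTable(u=u, n_k=np.array([x.size for x in xs]))
            prof = MBAR(table).fit(tol=1e-9)
            for a, b in zip(range(len(idx) - 1), range(1, len(idx))):
                p = pair_index[(idx[a], idx[b])]
                out[p] = prof.f[b] - prof.f[a]
        return out

    def _leg_total(self, leg: str, per_replicate: np.ndarray) -> np.ndarray:
        """Per-replicate telescoped leg total, kT units."""
        pair_index = {pair: p for p, pair in enumerate(self.pairs)}
        rows = [pair_index[pair] for pair in self.schedule.leg_pairs(leg)]
        return per_replicate[rows, :].sum(axis=0)

    # -- main loop ---------------------------------------------------------

    def run(self) -> ProtocolResult:
        cfg = self.config
        kT = self.backend.spec.kT
        R = cfg.n_replicates
        profile_epochs: list[int] = []
        profile_mean: list[float] = []
        profile_sd: list[float] = []
        profile_sigmas: list[tuple[float, ...]] = []
        # resume support: replay profile from prior records
        for rec in self._records:
            profile_epochs.append(rec.epoch_index)
            profile_sigmas.append(rec.pair_sigma)

        while self._epoch < cfg.max_epochs and self._active:
            # draw the whole epoch before committing, so a backend failure
            # mid-epoch leaves the controller at the last complete epoch
            # and run() can simply be called again to resume
            drawn: dict[tuple[int, int], np.ndarray] = {}
            for w in sorted(self._active):
                for r in range(R):
                    drawn[(w, r)] = self.backend.sample(w, r, cfg.epoch_length)
            self._epoch += 1
            for key, x in drawn.items():
                self._samples[key].append(x)

            # static runs may coarsen the profile: the estimates steer
            # nothing, so skip non-profiled epochs (final epoch always runs)
            if not self.adaptive and (
                self._epoch % cfg.profile_every != 0 and self._epoch != cfg.max_epochs
            ):
                continue

            live = np.flatnonzero(~self._retired)
            if cfg.pair_estimator == "mbar":
                est = np.stack([self._estimate_pairs_mbar(r) for r in range(R)], axis=1)
                self._pair_est[live, :] = est[live, :]
            else:
                for p in live:
                    for r in range(R):
                        self._pair_est[p, r] = self._estimate_pair_bar(p, r)

            sigma = np.array(
                [replicate_spread(self._pair_est[p], cfg.spread_statistic) * kT
                 for p in range(len(self.pairs))]
            )
            mean = self._pair_est.mean(axis=1) * kT

            if self.adaptive:
                if self._epoch >= cfg.min_epochs:
                    self._retired |= sigma <= cfg.tau
                # windows stay active only through their non-retired pairs
                self._active = set()
                for p in np.flatnonzero(~self._retired):
                    i, j = self.pairs[p]
                    self._active.update((i, j))
            else:
                self._active = set(range(len(self.schedule)))

            cum = tuple(
                int(sum(c.size for r in range(R) for c in self._samples[(w, r)]))
                for w in range(len(self.schedule))
            )
            totals = self._leg_total("free", self._pair_est) - self._leg_total(
                "bound", self._pair_est
            )
            totals_kcal = totals * kT
            self._records.append(
                EpochRecord(
                    epoch_index=self._epoch,
                    active_windows=tuple(sorted(self._active)),
                    pair_mean=tuple(float(m) for m in mean),
                    pair_sigma=tuple(float(s) for s in sigma),
                    retired_pairs=tuple(int(p) for p in np.flatnonzero(self._retired)),
                    cumulative_samples=cum,
                )
            )
            profile_epochs.append(self._epoch)
            profile_mean.append(float(totals_kcal.mean()))
            profile_sd.append(float(np.std(totals_kcal, ddof=1)))
            profile_sigmas.append(tuple(float(s) for s in sigma))

        # Final estimates: re-estimate every pair from all samples its
        # windows ever accumulated. For pairs whose windows all stopped at
        # retirement this reproduces the frozen value; pairs adjacent to
        # windows that kept sampling benefit from the extra data.
        if cfg.pair_estimator == "mbar":
            final_est = np.stack(
                [self._estimate_pairs_mbar(r) for r in range(R)], axis=1
            )
        else:
            final_est = np.array(
                [[self._estimate_pair_bar(p, r) for r in range(R)]
                 for p in range(len(self.pairs))]
            )
        bound = self._leg_total("bound", final_est) * kT
        free = self._leg_total("free", final_est) * kT
        rep_totals = free - bound - self.dg_restraint_on_bound - self.dg_ss
        abfe = assemble_abfe(
            dg_decouple_bound=float(bound.mean()),
            dg_decouple_free=float(free.mean()),
            dg_restraint_on_bound=self.dg_restraint_on_bound,
            dg_ss=self.dg_ss,
            sigma=float(np.std(rep_totals, ddof=1)),
            replicate_values=tuple(float(v) for v in rep_totals),
        )
        per_window = self._records[-1].cumulative_samples if self._records else ()
        return ProtocolResult(
            abfe=abfe,
            profile=ConvergenceProfile(
                epochs=tuple(profile_epochs),
                dg_mean=tuple(profile_mean),
                dg_sd=tuple(profile_sd),
                pair_sigma_history=tuple(profile_sigmas),
            ),
            records=tuple(self._records),
            per_window_samples=per_window,
            total_samples=int(sum(per_window)),
            converged=bool(self._retired.all()) if self.adaptive else True,
            pairs=tuple(self.pairs),
        )


def run_adaptive(
    config: AdaptiveConfig,
    backend: GaussianLadderBackend | GaussianLadderSpec,
    schedule: LambdaSchedule | None = None,
    dg_restraint_on_bound: float = 0.0,
    dg_ss: float = 0.0,
) -> ProtocolResult:
    """Run the adaptive protocol to convergence or ``max_epochs``."""
    return AdaptiveProtocol(
        config, backend, schedule, dg_restraint_on_bound, dg_ss, adaptive=True
    ).run()


def run_static(
    config: AdaptiveConfig,
    backend: GaussianLadderBackend | GaussianLadderSpec,
    schedule: LambdaSchedule | None = None,
    n_epochs: int | None = None,
    dg_restraint_on_bound: float = 0.0,
    dg_ss: float = 0.0,
) -> ProtocolResult:
    """Equal-allocation reference: every window sampled every epoch."""
    if n_epochs is not None:
        config = AdaptiveConfig(
            tau=config.tau,
            epoch_length=config.epoch_length,
            n_replicates=config.n_replicates,
            max_epochs=n_epochs,
            min_epochs=config.min_epochs,
            seed=config.seed,
            pair_estimator=config.pair_estimator,
            spread_statistic=config.spread_statistic,
        )
    return AdaptiveProtocol(
        config, backend, schedule, dg_restraint_on_bound, dg_ss, adaptive=False
    ).run()


def savings_factor(static: ProtocolResult, adaptive: ProtocolResult) -> float:
    """Resource ratio: total static samples over total adaptive samples."""
    if adaptive.total_samples == 0:
        raise ValueError("adaptive run consumed no samples")
    if len(static.per_window_samples) != len(adaptive.per_window_samples):
        raise ValueError("runs are not over the same schedule")
    return static.total_samples / adaptive.total_samples
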