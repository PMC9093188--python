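"""Free-energy estimators over reduced-potential samples.

The substrate is a :class:`ReducedPotentialTable`: every sample drawn from
any window is evaluated in the Hamiltonian of *every* window, giving the
dimensionless matrix ``u[k, n]`` together with the per-window sample
counts ``n_k``. On top of it sit

* :class:`MBAR` — the multistate Bennett acceptance ratio estimator,
  solved by damped Newton on its convex objective with a self-consistent
  polish;
* :func:`bar_pair` — the two-state Bennett estimator (the K = 2 special
  case of MBAR, solved independently via root finding);
* :func:`exp_pair` — one-sided exponential (Zwanzig) averaging, mainly
  useful as a bracketing cross-check;
* :func:`adjacent_deltas` / :func:`replicate_spread` — the bookkeeping
  used by the adaptive protocol: free-energy changes between successive
  windows and their across-replicate spreads.

Free energies are dimensionless (units of kT) unless a ``kT`` factor is
applied explicitly; the gauge is ``f[0] = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "ReducedPotentialTable",
    "MBAR",
    "MBARResults",
    "bar_pair",
    "exp_pair",
    "adjacent_deltas",
    "replicate_spread",
]


@dataclass(frozen=True)
class ReducedPotentialTable:
    """Samples-by-windows matrix of reduced potentials.

    Parameters
    ----------
    u : ndarray, shape (K, N)
        ``u[k, n]``: reduced potential of sample ``n`` evaluated in window
        ``k``. Columns are grouped in blocks by the window the sample was
        drawn from, in window order.
    n_k : ndarray, shape (K,)
        Number of samples drawn from each window; ``sum(n_k) == N``.
    window_ids : tuple of str, optional
        Labels matching a lambda-schedule segment.
    """

    u: np.ndarray
    n_k: np.ndarray
    window_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        n_k = np.asarray(self.n_k, dtype=int)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "n_k", n_k)
        if u.ndim != 2:
            raise ValueError(f"u must be 2-D (K, N), got shape {u.shape}")
        if not np.all(np.isfinite(u)):
            raise ValueError("reduced potentials must all be finite")
        if n_k.ndim != 1 or n_k.shape[0] != u.shape[0]:
            raise ValueError("n_k must have one entry per window (row of u)")
        if np.any(n_k < 0):
            raise ValueError("sample counts must be non-negative")
        if int(n_k.sum()) != u.shape[1]:
            raise ValueError(
                f"sum(n_k)={int(n_k.sum())} does not match number of samples N={u.shape[1]}"
            )
        if self.window_ids and len(self.window_ids) != u.shape[0]:
            raise ValueError("window_ids length must match number of windows")

    @property
    def n_windows(self) -> int:
        return self.u.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u.shape[1]

    @classmethod
    def from_blocks(
        cls,
        blocks: list[np.ndarray],
        window_ids: tuple[str, ...] = (),
    ) -> "ReducedPotentialTable":
        """Build a table from per-source-window evaluation blocks.

        ``blocks[i]`` has shape (K, n_i): the samples drawn from window
        ``i``, each evaluated at all K windows.
        """
        if not blocks:
            raise ValueError("at least one block required")
        u = np.concatenate(blocks, axis=1)
        n_k = np.array([b.shape[1] for b in blocks], dtype=int)
        if len(blocks) != u.shape[0]:
            raise ValueError("need exactly one block per window")
        return cls(u=u, n_k=n_k, window_ids=window_ids)

    def restrict(self, indices: list[int] | tuple[int, ...]) -> "ReducedPotentialTable":
        """Sub-table over a subset of windows, keeping only their samples."""
        indices = list(indices)
        starts = np.concatenate([[0], np.cumsum(self.n_k)])
        cols = np.concatenate(
            [np.arange(starts[i], starts[i + 1]) for i in indices]
        ).astype(int)
        ids = tuple(self.window_ids[i] for i in indices) if self.window_ids else ()
        return ReducedPotentialTable(
            u=self.u[np.ix_(indices, cols)],
            n_k=self.n_k[indices],
            window_ids=ids,
        )


@dataclass(frozen=True)
class MBARResults:
    """Converged per-window free energies and solver diagnostics.

    Attributes
    ----------
    f : ndarray, shape (K,)
        Dimensionless free energies, gauge ``f[0] = 0``.
    converged : bool
        Whether the self-consistency residual reached the tolerance.
    iterations : int
        Total solver iterations (optimiser + polish).
    tolerance_achieved : float
        Final max-norm of the self-consistent update.
    overlap_warning : bool
        True when some window pair has vanishing configurational overlap
        (results may be unreliable even though the solver converged).
    """

    f: np.ndarray
    converged: bool
    iterations: int
    tolerance_achieved: float
    overlap_warning: bool = False
    model: "MBAR | None" = field(default=None, repr=False, compare=False)

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        """Free-energy difference ``f[j] - f[i]`` in kT."""
        return float(self.f[j] - self.f[i])

    def sample_weights(self) -> np.ndarray:
        """Normalised mixture-distribution weights of every sample.

        ``w[n] = 1 / sum_l n_l exp(f_l - u_ln)``, normalised to sum to 1;
        the weights reweight the pooled samples to the unbiased (lambda-
        independent) target when the table came from biased sampling.
        """
        if self.model is None:
            raise ValueError("results are detached from their model")
        table = self.model.table
        log_denom = logsumexp(
            self.f[:, None] - table.u,
            b=table.n_k[:, None].astype(float),
            axis=0,
        )
        logw = -log_denom - logsumexp(-log_denom)
        return np.exp(logw)

    def summary(self) -> str:
        lines = [
            "MBAR free-energy profile",
            f"  windows:    {len(self.f)}",
            f"  converged:  {self.converged} (residual {self.tolerance_achieved:.2e}, "
            f"{self.iterations} iterations)",
        ]
        if self.overlap_warning:
            lines.append("  WARNING: at least one adjacent pair has near-zero overlap")
        lines.append("  f_k (kT, gauge f[0]=0):")
        for k, fk in enumerate(self.f):
            lines.append(f"    {k:4d}  {fk:+12.6f}")
        return "\n".join(lines)


class MBAR:
    """Multistate Bennett acceptance ratio estimator.

    ``MBAR(table).fit()`` returns :class:`MBARResults` whose ``f`` solves
    the self-consistency equations

        f_k = -ln sum_n exp(-u_kn) / sum_l n_l exp(f_l - u_ln)

    The solve interleaves damped Newton steps on the convex MBAR
    objective with self-consistent sweeps until the max-norm of the
    self-consistent update falls below ``tol``. Deterministic and independent of sample order.
    """

    def __init__(self, table: ReducedPotentialTable):
        if table.n_windows < 2:
            raise ValueError("MBAR needs at least two windows")
        if not np.any(table.n_k > 0):
            raise ValueError("at least one window must have samples")
        if table.n_samples == 0:
            raise ValueError("empty table")
        self.table = table

    # -- internals ---------------------------------------------------------

    def _log_denom(self, f: np.ndarray) -> np.ndarray:
        """log sum_l n_l exp(f_l - u_ln) per sample, ignoring empty windows."""
        t = self.table
        occ = t.n_k > 0
        return logsumexp(
            f[occ, None] - t.u[occ, :],
            b=t.n_k[occ, None].astype(float),
            axis=0,
        )

    def _sc_update(self, f: np.ndarray) -> np.ndarray:
        log_denom = self._log_denom(f)
        f_new = -logsumexp(-self.table.u - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    def _objective(self, f: np.ndarray) -> tuple[float, np.ndarray]:
        t = self.table
        log_denom = self._log_denom(f)
        obj = float(np.sum(log_denom) - np.dot(t.n_k, f))
        # grad_k = n_k * (sum_n exp(f_k - u_kn - log_denom) - 1)
        expected = np.exp(
            logsumexp(f[:, None] - t.u - log_denom[None, :], axis=1)
        )
        grad = t.n_k * expected - t.n_k
        return obj, grad

    def _newton_step(self, f: np.ndarray) -> np.ndarray:
        """One damped Newton step on the convex MBAR objective.

        With B_kn = n_k exp(f_k - u_kn) / D_n, the gradient is
        ``rowsum(B) - n_k`` and the Hessian ``diag(rowsum B) - B B^T``
        (positive semidefinite, singular along the uniform gauge shift).
        """
        t = self.table
        log_denom = self._log_denom(f)
        logB = np.log(t.n_k, where=t.n_k > 0, out=np.full(len(t.n_k), -np.inf))[
            :, None
        ] + (f[:, None] - t.u - log_denom[None, :])
        B = np.exp(logB)
        rowsum = B.sum(axis=1)
        grad = rowsum - t.n_k
        H = np.diag(rowsum) - B @ B.T
        # fix the gauge by pinning f[0]: solve on the trailing block
        try:
            step = np.linalg.solve(H[1:, 1:], grad[1:])
        except np.linalg.LinAlgError:
            return f  # fall back to self-consistent iteration
        f_new = f.copy()
        f_new[1:] -= step
        obj_old = float(np.sum(log_denom) - np.dot(t.n_k, f))
        # damp until the objective does not increase
        for _ in range(20):
            obj_new = float(
                np.sum(self._log_denom(f_new)) - np.dot(t.n_k, f_new)
            )
            if obj_new <= obj_old + 1e-13 * abs(obj_old):
                return f_new
            f_new = 0.5 * (f_new + f)
        return f

    def _overlap_suspect(self, f: np.ndarray) -> bool:
        """Flag adjacent pairs whose forward/reverse EXP estimates disagree wildly."""
        t = self.table
        starts = np.concatenate([[0], np.cumsum(t.n_k)])
        for i in range(t.n_windows - 1):
            if t.n_k[i] == 0 or t.n_k[i + 1] == 0:
                return True
            si, sj = slice(starts[i], starts[i + 1]), slice(starts[i + 1], starts[i + 2])
            fwd = -(logsumexp(-(t.u[i + 1, si] - t.u[i, si])) - np.log(t.n_k[i]))
            rev = logsumexp(-(t.u[i, sj] - t.u[i + 1, sj])) - np.log(t.n_k[i + 1])
            if abs(fwd - rev) > 10.0:  # ~e^10 discrepancy: essentially no overlap
                return True
        return False

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        tol: float = 1e-10,
        max_iter: int = 10_000,
        initial: np.ndarray | None = None,
    ) -> MBARResults:
        t = self.table
        f = np.zeros(t.n_windows) if initial is None else np.array(initial, dtype=float)
        iterations = 0

        # a few self-consistent sweeps stabilise, Newton then converges
        # quadratically; SC alone closes the last digits
        residual = np.inf
        for _ in range(5):
            f_new = self._sc_update(f)
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            iterations += 1
            if residual < tol:
                break
        while residual >= tol and iterations < max_iter:
            f = self._newton_step(f)
            f -= f[0]
            f_new = self._sc_update(f)
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            iterations += 1

        return MBARResults(
            f=f,
            converged=bool(residual < tol),
            iterations=iterations,
            tolerance_achieved=residual,
            overlap_warning=self._overlap_suspect(f),
            model=self,
        )


def bar_pair(table: ReducedPotentialTable, tol: float = 1e-12) -> float:
    """Bennett acceptance ratio estimate of ``f[1] - f[0]`` (kT) for K = 2.

    Solves the Bennett implicit equation by bracketed root finding; the
    root is the fixed point of the two-state MBAR equations, so the result
    agrees with :class:`MBAR` on the same table to solver tolerance.
    """
    if table.n_windows != 2:
        raise ValueError("bar_pair expects a two-window table")
    n0, n1 = int(table.n_k[0]), int(table.n_k[1])
    if n0 == 0 or n1 == 0:
        raise ValueError("both windows need samples for BAR")
    w_f = table.u[1, :n0] - table.u[0, :n0]  # forward work, samples from 0
    w_r = table.u[0, n0:] - table.u[1, n0:]  # reverse work, samples from 1
    m = np.log(n0 / n1)

    def g(df: float) -> float:
        # log sum of Fermi terms, forward minus reverse; root at the BAR estimate
        lhs = logsumexp(-np.logaddexp(0.0, m + w_f - df))
        rhs = logsumexp(-np.logaddexp(0.0, -m + w_r + df))
        return lhs - rhs

    # bracket from the one-sided EXP estimates, padded
    fwd = -(logsumexp(-w_f) - np.log(n0))
    rev = logsumexp(-w_r) - np.log(n1)
    lo, hi = min(fwd, rev) - 1.0, max(fwd, rev) + 1.0
    glo, ghi = g(lo), g(hi)
    width = max(hi - lo, 1.0)
    for _ in range(60):
        if glo * ghi <= 0:
            break
        lo -= width
        hi += width
        width *= 2.0
        glo, ghi = g(lo), g(hi)
    else:
        raise RuntimeError("BAR root bracketing failed: windows may not overlap")
    return float(brentq(g, lo, hi, xtol=tol, rtol=8.9e-16))


def exp_pair(table: ReducedPotentialTable, direction: str = "forward") -> float:
    """Zwanzig exponential-averaging estimate of ``f[1] - f[0]`` (kT).

    ``forward`` averages over samples from window 0, ``reverse`` over
    samples from window 1. On well-overlapped pairs the two directions
    bracket the BAR estimate in expectation. Log-sum-exp guarded.
    """
    if table.n_windows != 2:
        raise ValueError("exp_pair expects a two-window table")
    n0, n1 = int(table.n_k[0]), int(table.n_k[1])
    if direction == "forward":
        if n0 == 0:
            raise ValueError("forward EXP needs samples from the source window 0")
        w_f = table.u[1, :n0] - table.u[0, :n0]
        return float(-(logsumexp(-w_f) - np.log(n0)))
    if direction == "reverse":
        if n1 == 0:
            raise ValueError("reverse EXP needs samples from the source window 1")
        w_r = table.u[0, n0:] - table.u[1, n0:]
        return float(logsumexp(-w_r) - np.log(n1))
    raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")


def adjacent_deltas(profile: MBARResults, kT: float) -> np.ndarray:
    """Free-energy changes between successive windows, in energy units.

    ``deltas[i] = (f[i+1] - f[i]) * kT``; the telescoped sum equals
    ``(f[-1] - f[0]) * kT`` exactly. Refuses unconverged profiles.
    """
    if not profile.converged:
        raise ValueError("refusing to take adjacent deltas of an unconverged profile")
    if kT <= 0:
        raise ValueError("kT must be positive")
    return np.diff(profile.f) * kT


def replicate_spread(estimates: np.ndarray, statistic: str = "sd") -> float:
    """Across-replicate spread of a free-energy estimate.

    ``sd`` (default) is the sample standard deviation (n-1 denominator)
    across per-replicate estimates — the spread the adaptive protocol
    compares against its threshold tau; ``sem`` is sd/sqrt(n).
    """
    x = np.asarray(estimates, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("replicate spread needs at least two replicate estimates")
    sd = float(np.std(x, ddof=1))
    if statistic == "sd":
        return sd
    if statistic == "sem":
        return sd / np.sqrt(x.size)
    raise ValueError(f"unknown spread statistic {statistic!r}")
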