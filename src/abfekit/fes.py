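"""2D free-energy surfaces from umbrella-sampled collective variables.

Estimates a potential of mean force over two collective variables (here:
lid end-to-end distance and lid-core distance, both in angstroms) from
harmonically biased window samples, using binned multistate reweighting.
Two estimator routes solve the same fixed-point equations:

* ``"mbar"`` (default): an MBAR solve over the window bias Hamiltonians
  evaluated at every sample, followed by histogramming the unbiased
  sample weights into bins;
* ``"wham"``: the classic histogram iteration with bias energies taken
  at bin centres.

On visited bins with fine enough binning the two agree closely; unvisited
bins carry NaN sentinels and never enter any partition function.
Macrostate populations are Boltzmann sums of bin free energies inside
user-supplied polygon masks, and uncertainties come from re-estimating
the surface on the first and second halves of every window's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp
from shapely.geometry import Polygon, box

from .backends import UmbrellaDataset
from .estimators import MBAR, ReducedPotentialTable
from .thermo import ThermoConditions

__all__ = [
    "CVSampleSet",
    "FESGrid",
    "MacrostateMask",
    "UmbrellaPMF",
    "PMFResults",
    "macrostate_population",
    "macrostate_gap",
    "split_half_uncertainty",
    "default_macrostate_masks",
]


@dataclass(frozen=True)
class CVSampleSet:
    """Per-window 2D collective-variable samples with their bias parameters.

    ``samples[i]`` has shape (n_i, 2); the bias on window ``i`` is
    ``k/2 * |r - center_i|^2`` with ``k`` in kcal/mol/A^2.
    """

    samples: tuple[np.ndarray, ...]
    bias_centers: tuple[tuple[float, float], ...]
    spring_constant: float

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.bias_centers):
            raise ValueError("one bias centre per window required")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        for i, s in enumerate(self.samples):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 2:
                raise ValueError(f"window {i}: samples must have shape (n, 2)")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"window {i}: collective variables must be finite")

    @classmethod
    def from_dataset(cls, data: UmbrellaDataset) -> "CVSampleSet":
        return cls(
            samples=data.samples,
            bias_centers=data.bias_centers,
            spring_constant=data.spring_constant,
        )

    @property
    def n_windows(self) -> int:
        return len(self.samples)

    def halves(self) -> tuple["CVSampleSet", "CVSampleSet"]:
        """First-half / second-half split of every window's stream."""
        firsts, seconds = [], []
        for i, s in enumerate(self.samples):
            if s.shape[0] < 2:
                raise ValueError(f"window {i} has fewer than 2 samples; cannot split")
            h = s.shape[0] // 2
            firsts.append(s[:h])
            seconds.append(s[h:])
        return (
            CVSampleSet(tuple(firsts), self.bias_centers, self.spring_constant),
            CVSampleSet(tuple(seconds), self.bias_centers, self.spring_constant),
        )

    def bias_energy(self, xy: np.ndarray) -> np.ndarray:
        """Bias energies (kcal/mol) of points ``xy`` (n, 2) at all windows: (W, n)."""
        centers = np.asarray(self.bias_centers)  # (W, 2)
        d2 = ((xy[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
        return 0.5 * self.spring_constant * d2


@dataclass(frozen=True)
class FESGrid:
    """Binned free-energy surface, kcal/mol relative to the visited minimum.

    Bins are half-open ``[lo, hi)`` intervals, 0-based indices; unvisited
    bins hold NaN and an explicit False in ``visited``.
    """

    edges1: np.ndarray
    edges2: np.ndarray
    free_energy: np.ndarray  # (n1, n2), NaN where unvisited
    visited: np.ndarray  # bool (n1, n2)
    temperature: float

    def __post_init__(self) -> None:
        g = np.asarray(self.free_energy, dtype=float)
        if g.shape != (len(self.edges1) - 1, len(self.edges2) - 1):
            raise ValueError("free-energy array does not match grid edges")
        vis = np.asarray(self.visited, dtype=bool)
        if vis.shape != g.shape:
            raise ValueError("visited mask shape mismatch")
        if vis.any() and abs(np.nanmin(g[vis])) > 1e-9:
            raise ValueError("gauge violated: minimum over visited bins must be 0")

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])

    @property
    def coverage(self) -> float:
        """Fraction of bins visited."""
        return float(self.visited.mean())


@dataclass(frozen=True)
class MacrostateMask:
    """A named polygonal region of collective-variable space."""

    label: str
    polygon: Polygon

    def bin_mask(self, grid: FESGrid) -> np.ndarray:
        """Boolean mask over grid bins whose centre lies inside the polygon."""
        c1, c2 = np.meshgrid(grid.centers1, grid.centers2, indexing="ij")
        return shapely.contains_xy(self.polygon, c1.ravel(), c2.ravel()).reshape(c1.shape)

    def region(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-polygon test (for truth-integration oracles)."""
        return shapely.contains_xy(self.polygon, np.asarray(x), np.asarray(y))


def default_macrostate_masks() -> dict[str, MacrostateMask]:
    """Reference contours for the two lid macrostates on the default surface.

    Rectangles in (lid end-to-end, lid-core distance) space: the closed
    and disordered state at small extension, the open and ordered state
    at large extension. Disjoint by construction.
    """
    return {
        "closed_disordered": MacrostateMask("closed_disordered", box(3.0, 0.5, 20.0, 16.0)),
        "open_ordered": MacrostateMask("open_ordered", box(20.0, 10.5, 34.0, 24.0)),
    }


@dataclass(frozen=True)
class PMFResults:
    """Fitted surface plus solver diagnostics."""

    grid: FESGrid
    window_f: np.ndarray  # per-window dimensionless free energies
    estimator: str
    converged: bool
    iterations: int

    def summary(self) -> str:
        g = self.grid
        return "\n".join(
            [
                "2D PMF estimate",
                f"  estimator:  {self.estimator} (converged={self.converged}, "
                f"{self.iterations} iterations)",
                f"  grid:       {g.free_energy.shape[0]} x {g.free_energy.shape[1]} bins, "
                f"coverage {g.coverage:.1%}",
                f"  range:      0 .. {np.nanmax(g.free_energy):.2f} kcal/mol "
                f"(T = {g.temperature} K)",
            ]
        )


class UmbrellaPMF:
    """Binned multistate-reweighting PMF estimator.

    ``UmbrellaPMF(samples, edges1, edges2, cond).fit()`` returns
    :class:`PMFResults`. Raises on a disconnected window graph (no path
    of overlapping sampling between window groups), identifying the
    components.
    """

    def __init__(
        self,
        samples: CVSampleSet,
        edges1: np.ndarray,
        edges2: np.ndarray,
        cond: ThermoConditions | None = None,
        estimator: str = "mbar",
    ):
        if samples.n_windows < 1:
            raise ValueError("need at least one umbrella window")
        if estimator not in ("mbar", "wham"):
            raise ValueError("estimator must be 'mbar' or 'wham'")
        self.samples = samples
        self.edges1 = np.asarray(edges1, dtype=float)
        self.edges2 = np.asarray(edges2, dtype=float)
        if len(self.edges1) < 3 or len(self.edges2) < 3:
            raise ValueError("grid needs at least two bins per axis")
        self.cond = cond or ThermoConditions()
        self.estimator = estimator

    # -- internals ---------------------------------------------------------

    def _bin_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open [lo, hi) bin indices; -1 marks out-of-grid points."""
        i = np.searchsorted(self.edges1, xy[:, 0], side="right") - 1
        j = np.searchsorted(self.edges2, xy[:, 1], side="right") - 1
        i[(xy[:, 0] < self.edges1[0]) | (xy[:, 0] >= self.edges1[-1])] = -1
        j[(xy[:, 1] < self.edges2[0]) | (xy[:, 1] >= self.edges2[-1])] = -1
        return i, j

    def _check_connectivity(self, counts: np.ndarray) -> None:
        """Windows sharing an occupied bin are connected; require one component."""
        W = counts.shape[0]
        adj = np.zeros((W, W), dtype=bool)
        occ = counts > 0  # (W, n_bins)
        for a in range(W):
            shared = (occ[a][None, :] & occ).any(axis=1)
            adj[a] = shared
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp > 1:
            groups = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
            raise ValueError(
                f"umbrella window graph is disconnected into {n_comp} components: {groups}"
            )

    def fit(self, tol: float = 1e-8, max_iter: int = 10_000) -> PMFResults:
        rt = self.cond.rt
        n1, n2 = len(self.edges1) - 1, len(self.edges2) - 1
        xy_all = np.concatenate(self.samples.samples, axis=0)
        n_k = np.array([s.shape[0] for s in self.samples.samples])
        bi, bj = self._bin_index(xy_all)
        inside = (bi >= 0) & (bj >= 0)
        flat = bi * n2 + bj

        # per-window occupancy for the connectivity check
        counts = np.zeros((self.samples.n_windows, n1 * n2), dtype=int)
        start = 0
        for w, n in enumerate(n_k):
            sel = slice(start, start + n)
            ok = inside[sel]
            np.add.at(counts[w], flat[sel][ok], 1)
            start += n
        self._check_connectivity(counts)

        if self.estimator == "mbar":
            u = self.samples.bias_energy(xy_all) / rt  # (W, N), dimensionless
            if self.samples.n_windows == 1:
                # single window: unbias by exp(+bias/kT) directly
                logw = u[0] - logsumexp(u[0])
                w_n = np.exp(logw)
                f_win = np.zeros(1)
                converged, iters = True, 0
            else:
                table = ReducedPotentialTable(u=u, n_k=n_k)
                prof = MBAR(table).fit(tol=tol, max_iter=max_iter)
                w_n = prof.sample_weights()
                f_win = prof.f
                converged, iters = prof.converged, prof.iterations
            weight = np.zeros(n1 * n2)
            np.add.at(weight, flat[inside], w_n[inside])
            with np.errstate(divide="ignore"):
                g = -rt * np.log(weight)
            visited = weight > 0
        else:
            g, f_win, converged, iters = self._fit_wham(counts, tol, max_iter)
            visited = np.isfinite(g)

        g = g.astype(float)
        g[~visited] = np.nan
        g -= np.nanmin(g[visited])
        return PMFResults(
            grid=FESGrid(
                edges1=self.edges1,
                edges2=self.edges2,
                free_energy=g.reshape(n1, n2),
                visited=visited.reshape(n1, n2),
                temperature=self.cond.temperature,
            ),
            window_f=f_win,
            estimator=self.estimator,
            converged=converged,
            iterations=iters,
        )

    def _fit_wham(
        self, counts: np.ndarray, tol: float, max_iter: int
    ) -> tuple[np.ndarray, np.ndarray, bool, int]:
        rt = self.cond.rt
        n2 = len(self.edges2) - 1
        c1 = 0.5 * (self.edges1[:-1] + self.edges1[1:])
        c2 = 0.5 * (self.edges2[:-1] + self.edges2[1:])
        xg, yg = np.meshgrid(c1, c2, indexing="ij")
        centers = np.stack([xg.ravel(), yg.ravel()], axis=1)
        b = self.samples.bias_energy(centers) / rt  # (W, B) bias at bin centres
        n_k = counts.sum(axis=1).astype(float)
        m_b = counts.sum(axis=0).astype(float)  # total counts per bin
        occupied = m_b > 0
        f = np.zeros(len(n_k))
        log_m = np.where(occupied, np.log(np.maximum(m_b, 1)), -np.inf)
        it = 0
        residual = np.inf
        for it in range(1, max_iter + 1):
            # log p_b = log m_b - log sum_i n_i exp(f_i - b_ib)
            log_denom = logsumexp(f[:, None] - b, b=n_k[:, None], axis=0)
            log_p = np.where(occupied, log_m - log_denom, -np.inf)
            f_new = -logsumexp(log_p[None, :] - b, axis=1)
            f_new -= f_new[0]
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            if residual < tol:
                break
        with np.errstate(invalid="ignore"):
            g = np.where(occupied, -rt * log_p, np.nan)
        return g, f, residual < tol, it


# --------------------------------------------------------------------------
# populations and uncertainties
# --------------------------------------------------------------------------


def macrostate_population(
    grid: FESGrid,
    mask: MacrostateMask | np.ndarray,
    cond: ThermoConditions | None = None,
) -> float:
    """Boltzmann population of a masked region of the surface.

    ``p = sum_{bins in mask} exp(-G/RT) / sum_{visited} exp(-G/RT)``;
    unvisited bins are excluded everywhere (never imputed).
    """
    cond = cond or ThermoConditions()
    m = mask.bin_mask(grid) if isinstance(mask, MacrostateMask) else np.asarray(mask, bool)
    if m.shape != grid.free_energy.shape:
        raise ValueError("mask shape does not match grid")
    m = m & grid.visited
    if not m.any():
        raise ValueError("mask covers no visited bins")
    g = grid.free_energy
    log_num = logsumexp(-g[m] / cond.rt)
    log_den = logsumexp(-g[grid.visited] / cond.rt)
    return float(np.exp(log_num - log_den))


def macrostate_gap(
    grid: FESGrid,
    mask_a: MacrostateMask | np.ndarray,
    mask_b: MacrostateMask | np.ndarray,
    cond: ThermoConditions | None = None,
) -> float:
    """Free-energy gap ``G_A - G_B = -RT ln(p_A / p_B)`` in kcal/mol.

    Positive when region A is less stable; antisymmetric under swapping
    the masks. Also usable directly from two populations via
    :func:`gap_from_populations`.
    """
    cond = cond or ThermoConditions()
    pa = macrostate_population(grid, mask_a, cond)
    pb = macrostate_population(grid, mask_b, cond)
    return gap_from_populations(pa, pb, cond)


def gap_from_populations(
    p_a: float, p_b: float, cond: ThermoConditions | None = None
) -> float:
    """``-RT ln(p_A/p_B)`` for two (not necessarily normalised) populations."""
    cond = cond or ThermoConditions()
    if not (p_a > 0 and p_b > 0):
        raise ValueError("both populations must be positive")
    return float(-cond.rt * np.log(p_a / p_b))


@dataclass(frozen=True)
class SplitHalfUncertainty:
    """Half-difference uncertainties: sigma = |half1 - half2| / 2."""

    sigma_grid: np.ndarray  # per-bin, NaN where either half is unvisited
    sigma_populations: dict[str, float] = field(default_factory=dict)
    half1: PMFResults | None = None
    half2: PMFResults | None = None


def split_half_uncertainty(
    samples: CVSampleSet,
    edges1: np.ndarray,
    edges2: np.ndarray,
    cond: ThermoConditions | None = None,
    estimator: str = "mbar",
    masks: dict[str, MacrostateMask] | None = None,
) -> SplitHalfUncertainty:
    """Re-estimate the surface on each half of every window's stream.

    Per-bin sigma is half the absolute difference of the two half-data
    surfaces (NaN where either half leaves the bin unvisited); per-mask
    population sigmas are computed the same way when masks are given.
    """
    cond = cond or ThermoConditions()
    first, second = samples.halves()
    r1 = UmbrellaPMF(first, edges1, edges2, cond, estimator).fit()
    r2 = UmbrellaPMF(second, edges1, edges2, cond, estimator).fit()
    with np.errstate(invalid="ignore"):
        sigma = 0.5 * np.abs(r1.grid.free_energy - r2.grid.free_energy)
    sig_pops: dict[str, float] = {}
    for name, mask in (masks or {}).items():
        p1 = macrostate_population(r1.grid, mask, cond)
        p2 = macrostate_population(r2.grid, mask, cond)
        sig_pops[name] = 0.5 * abs(p1 - p2)
    return SplitHalfUncertainty(
        sigma_grid=sigma, sigma_populations=sig_pops, half1=r1, half2=r2
    )
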