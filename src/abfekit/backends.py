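"""Synthetic sampling backends with analytic ground truth.

These stand in for a molecular-dynamics engine so the estimator and
protocol machinery can be exercised against exactly known answers:

* :class:`GaussianLadderBackend` — a ladder of one-dimensional harmonic
  windows (Gaussian Boltzmann densities) standing in for the alchemical
  lambda windows. Partition functions are closed-form, so every pairwise
  free-energy difference is known exactly:
  ``delta_f[i -> j] = ln(width_i / width_j)`` in kT units. Designated
  "slow" windows emulate the poorly relaxing, partially decoupled
  Lennard-Jones states of a real binding site: their streams follow a
  stationary AR(1) process (reducing the effective sample size by
  ``(1+phi)/(1-phi)``) and sample from a variance-inflated marginal.
* :func:`generate_umbrella_2d` — umbrella-sampling data over a
  two-basin 2D free-energy surface in two collective variables (lid
  end-to-end distance and lid-core distance, angstroms). The truth
  surface is a two-component Gaussian mixture, so the harmonically
  biased window densities are again exact Gaussian mixtures and samples
  are drawn directly (no Markov chain), with truth populations available
  by numerical integration.

All generators are pure functions of (spec, seed): one master seed spawns
an independent stream per (window, replicate), so sampling one window
never perturbs another's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alchemy import LambdaSchedule, build_schedule

__all__ = [
    "SlowWindowNoiseSpec",
    "GaussianLadderSpec",
    "GaussianLadderBackend",
    "default_ladder_spec",
    "Basin",
    "Umbrella2DSpec",
    "UmbrellaDataset",
    "default_umbrella_spec",
    "generate_umbrella_2d",
]


# --------------------------------------------------------------------------
# Gaussian lambda-ladder
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SlowWindowNoiseSpec:
    """Slowly relaxing windows: AR(1) streams with an inflated marginal.

    ``phi`` is the lag-1 autocorrelation of the coordinate stream
    (effective sample size shrinks by ``(1+phi)/(1-phi)``);
    ``variance_inflation`` multiplies the sampled marginal variance,
    emulating a window that explores a broader basin than its nominal
    Hamiltonian (with inflation 1 the stream is exactly unbiased).
    """

    slow_windows: tuple[int, ...] = ()
    phi: float = 0.95
    variance_inflation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"AR(1) phi must lie in [0, 1) for stationarity, got {self.phi}")
        if self.variance_inflation < 1.0:
            raise ValueError("variance inflation must be >= 1")

    @property
    def ess_factor(self) -> float:
        """Factor by which autocorrelation reduces the effective sample size."""
        return (1.0 + self.phi) / (1.0 - self.phi)


@dataclass(frozen=True)
class GaussianLadderSpec:
    """A ladder of harmonic windows ``u_k(x) = (x - c_k)^2 / (2 w_k^2)`` (kT units).

    The analytic truth follows from ``Z_k = sqrt(2 pi) w_k``:
    ``delta_f[i -> j] = ln(w_i / w_j)``.
    """

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    kT: float = 0.59248368  # kcal/mol at 298.15 K
    noise: SlowWindowNoiseSpec = field(default_factory=SlowWindowNoiseSpec)
    schedule: LambdaSchedule | None = None

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.widths):
            raise ValueError("centers and widths must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        bad = [i for i in self.noise.slow_windows if not 0 <= i < len(self.centers)]
        if bad:
            raise ValueError(f"slow window indices out of range: {bad}")
        if self.schedule is not None and len(self.schedule) != len(self.centers):
            raise ValueError("schedule length must match window count")

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    def truth_delta_f(self, i: int, j: int) -> float:
        """Exact free-energy difference f_j - f_i in kT."""
        return float(np.log(self.widths[i] / self.widths[j]))

    def truth_pair_deltas(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        return np.array([self.truth_delta_f(i, j) for i, j in pairs])


class GaussianLadderBackend:
    """Sampling backend over a :class:`GaussianLadderSpec`.

    Maintains one independent RNG stream and one AR(1) state per
    (window, replicate); repeated calls continue the same trajectory, so
    a run is fully reproducible from (spec, seed, call sequence per
    stream) regardless of what other windows do.
    """

    def __init__(self, spec: GaussianLadderSpec, n_replicates: int, seed: int):
        if n_replicates < 1:
            raise ValueError("need at least one replicate")
        self.spec = spec
        self.n_replicates = n_replicates
        self.seed = seed
        children = np.random.SeedSequence(seed).spawn(spec.n_windows * n_replicates)
        self._rngs = {
            (w, r): np.random.Generator(np.random.PCG64(children[w * n_replicates + r]))
            for w in range(spec.n_windows)
            for r in range(n_replicates)
        }
        self._ar_state: dict[tuple[int, int], float] = {}

    def sample(self, window: int, replicate: int, n: int) -> np.ndarray:
        """Draw ``n`` coordinates from the window's sampling distribution."""
        if not 0 <= window < self.spec.n_windows:
            raise ValueError(f"window index {window} out of range")
        if not 0 <= replicate < self.n_replicates:
            raise ValueError(f"replicate index {replicate} out of range")
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = self._rngs[(window, replicate)]
        c = self.spec.centers[window]
        w = self.spec.widths[window]
        noise = self.spec.noise
        if window not in noise.slow_windows:
            return rng.normal(c, w, size=n)
        # stationary AR(1) about the centre with inflated marginal SD
        s = w * np.sqrt(noise.variance_inflation)
        phi = noise.phi
        eps_sd = s * np.sqrt(1.0 - phi * phi)
        key = (window, replicate)
        a = self._ar_state.get(key)
        out = np.empty(n)
        eps = rng.normal(0.0, 1.0, size=n)
        if a is None:
            a = float(rng.normal(0.0, s))
            out[0] = a
            start = 1
        else:
            start = 0
        for t in range(start, n):
            a = phi * a + eps_sd * eps[t]
            out[t] = a
        self._ar_state[key] = a
        return c + out

    def evaluate_u(self, x: np.ndarray, windows: list[int] | None = None) -> np.ndarray:
        """Reduced potentials of coordinates ``x`` at the given windows (K, n)."""
        idx = np.arange(self.spec.n_windows) if windows is None else np.asarray(windows)
        c = np.asarray(self.spec.centers)[idx, None]
        w = np.asarray(self.spec.widths)[idx, None]
        return (np.asarray(x)[None, :] - c) ** 2 / (2.0 * w * w)


def default_ladder_spec(
    schedule: LambdaSchedule | None = None,
    kT: float = 0.59248368,
    slow: bool = True,
) -> GaussianLadderSpec:
    """The package's reference 76-window ladder.

    Within each (leg, stage) block, window widths grow geometrically
    (ratio 1.5) and centres drift by 1.2 widths per step, so every
    neighbouring pair has the same moderate overlap and the same exact
    free-energy change ``ln 1.5`` kT. Two adjacent windows in the middle
    of the bound-leg vdw stage are designated slow (AR(1) phi = 0.95,
    variance inflation 1.5), mirroring how partially decoupled
    Lennard-Jones states dominate the sampling cost of a real binding
    site: their pair spreads start several-fold above the usual 0.1
    kcal/mol threshold while well-behaved pairs start below it.
    """
    schedule = schedule or build_schedule(12, 26)
    centers: list[float] = []
    widths: list[float] = []
    for idx in schedule.block_indices().values():
        c = 0.0
        for pos in range(len(idx)):
            w = 1.5**pos
            centers.append(c)
            widths.append(w)
            c += 1.2 * w
    noise = SlowWindowNoiseSpec()
    if slow:
        vdw_bound = schedule.block_indices()[("bound", "vdw")]
        mid = len(vdw_bound) // 2
        noise = SlowWindowNoiseSpec(
            slow_windows=(vdw_bound[mid - 1], vdw_bound[mid]),
            phi=0.95,
            variance_inflation=1.5,
        )
    return GaussianLadderSpec(
        centers=tuple(centers),
        widths=tuple(widths),
        kT=kT,
        noise=noise,
        schedule=schedule,
    )


# --------------------------------------------------------------------------
# 2D umbrella-sampling generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Basin:
    """One Gaussian basin of the truth surface (diagonal covariance)."""

    center: tuple[float, float]
    sigma: tuple[float, float]
    weight: float

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError("basin sigmas must be positive")
        if self.weight <= 0:
            raise ValueError("basin weights must be positive")


@dataclass(frozen=True)
class Umbrella2DSpec:
    """Umbrella-sampling design over a two-basin truth surface.

    The truth density is ``p(x, y) = sum_b weight_b N(center_b, sigma_b)``
    (weights normalised), and the truth free-energy surface is
    ``G = -kT ln p`` up to a constant. Harmonic umbrella biases
    ``k/2 |r - c|^2`` (kcal/mol/A^2) are centred on a grid of windows.
    """

    basins: tuple[Basin, ...]
    bias_centers: tuple[tuple[float, float], ...]
    spring_constant: float = 0.4
    samples_per_window: int = 400
    kT: float = 0.59248368
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 40.0), (0.0, 28.0))

    def __post_init__(self) -> None:
        if len(self.basins) < 1:
            raise ValueError("need at least one basin")
        if len(self.bias_centers) < 1:
            raise ValueError("need at least one umbrella window")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.samples_per_window < 2:
            raise ValueError("need at least two samples per window")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([b.weight for b in self.basins])
        return w / w.sum()

    def truth_density(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Normalised truth probability density at (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for w, b in zip(self.weights, self.basins):
            sx, sy = b.sigma
            cx, cy = b.center
            out += (
                w
                * np.exp(-0.5 * ((x - cx) / sx) ** 2 - 0.5 * ((y - cy) / sy) ** 2)
                / (2.0 * np.pi * sx * sy)
            )
        return out

    def truth_fes(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Truth free energy -kT ln p (kcal/mol), not gauged."""
        return -self.kT * np.log(self.truth_density(x, y))

    def truth_population(self, region, resolution: int = 600) -> float:
        """Probability mass of a region by Riemann integration on a fine grid.

        ``region`` is a callable mapping flat arrays (x, y) to booleans.
        """
        (x0, x1), (y0, y1) = self.bounds
        xs = np.linspace(x0, x1, resolution)
        ys = np.linspace(y0, y1, resolution)
        xg, yg = np.meshgrid(xs, ys, indexing="ij")
        dens = self.truth_density(xg, yg)
        mask = np.asarray(region(xg.ravel(), yg.ravel())).reshape(xg.shape)
        dx = (x1 - x0) / (resolution - 1)
        dy = (y1 - y0) / (resolution - 1)
        return float(np.sum(dens[mask]) * dx * dy)


@dataclass(frozen=True)
class UmbrellaDataset:
    """Biased CV samples per umbrella window (truth-free: estimator input)."""

    samples: tuple[np.ndarray, ...]  # per window, shape (n, 2)
    bias_centers: tuple[tuple[float, float], ...]
    spring_constant: float
    kT: float

    @property
    def n_windows(self) -> int:
        return len(self.samples)


def generate_umbrella_2d(spec: Umbrella2DSpec, seed: int) -> UmbrellaDataset:
    """Draw exact independent samples from every biased window density.

    Because the truth is a Gaussian mixture and the bias is Gaussian, the
    biased density is again a Gaussian mixture whose component weights,
    means and variances follow from products of Gaussians — so samples
    are exact (no Markov-chain error) and deterministic per seed.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    beta_k = spec.spring_constant / spec.kT  # bias precision per CV dimension, A^-2
    weights = spec.weights
    out: list[np.ndarray] = []
    for cx, cy in spec.bias_centers:
        log_w: list[float] = []
        means: list[tuple[float, float]] = []
        sds: list[tuple[float, float]] = []
        for w, b in zip(weights, spec.basins):
            lw = np.log(w)
            mean = []
            sd = []
            for c_bias, c_t, s_t in ((cx, b.center[0], b.sigma[0]), (cy, b.center[1], b.sigma[1])):
                prec = 1.0 / (s_t * s_t) + beta_k
                var = 1.0 / prec
                mean.append(var * (c_t / (s_t * s_t) + beta_k * c_bias))
                sd.append(np.sqrt(var))
                # Gaussian-product normalisation: N(c_bias; c_t, s_t^2 + 1/beta_k)
                tot = s_t * s_t + 1.0 / beta_k
                lw += -0.5 * (c_bias - c_t) ** 2 / tot - 0.5 * np.log(2.0 * np.pi * tot)
            log_w.append(lw)
            means.append((mean[0], mean[1]))
            sds.append((sd[0], sd[1]))
        p = np.exp(np.array(log_w) - max(log_w))
        p /= p.sum()
        comp = rng.choice(len(p), size=spec.samples_per_window, p=p)
        xy = np.empty((spec.samples_per_window, 2))
        for ci in range(len(p)):
            sel = comp == ci
            n_sel = int(sel.sum())
            if n_sel:
                xy[sel, 0] = rng.normal(means[ci][0], sds[ci][0], size=n_sel)
                xy[sel, 1] = rng.normal(means[ci][1], sds[ci][1], size=n_sel)
        out.append(xy)
    return UmbrellaDataset(
        samples=tuple(out),
        bias_centers=spec.bias_centers,
        spring_constant=spec.spring_constant,
        kT=spec.kT,
    )


def default_umbrella_spec(
    samples_per_window: int = 400,
    gap_kcal: float = 1.4,
    kT: float = 0.59248368,
) -> Umbrella2DSpec:
    """Reference two-basin surface mimicking the lid landscape.

    A broad "closed and disordered" basin at small lid extension and a
    tighter "open and ordered" basin at large extension, separated by
    ``gap_kcal`` between basin integrals (1.4 kcal/mol by default, i.e.
    roughly a 92/8 population split at 298.15 K). Umbrella windows tile
    the region containing both basins.
    """
    w_ratio = np.exp(-gap_kcal / kT)
    basins = (
        Basin(center=(12.0, 8.0), sigma=(3.0, 2.5), weight=1.0),
        Basin(center=(26.0, 17.0), sigma=(2.0, 2.0), weight=float(w_ratio)),
    )
    centers = tuple(
        (float(x), float(y))
        for x in np.linspace(5.0, 33.0, 12)
        for y in np.linspace(2.0, 24.0, 9)
    )
    return Umbrella2DSpec(
        basins=basins,
        bias_centers=centers,
        spring_constant=0.4,
        samples_per_window=samples_per_window,
        kT=kT,
    )


def with_samples(spec: Umbrella2DSpec, samples_per_window: int) -> Umbrella2DSpec:
    """Copy of an umbrella spec with a different per-window sample count."""
    return replace(spec, samples_per_window=samples_per_window)
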