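"""2D PMF estimation, macrostate populations and split-half uncertainties."""

import numpy as np
import pytest
from shapely.geometry import box

import abfekit as ak
from abfekit import fes

KT = 0.59248368
E1 = np.arange(2.0, 38.1, 1.0)
E2 = np.arange(0.0, 27.1, 1.0)


@pytest.fixture(scope="module")
def umbrella_fit():
    """One seed of the default two-basin fixture with its MBAR surface."""
    spec = ak.default_umbrella_spec()
    data = ak.generate_umbrella_2d(spec, seed=11)
    cvs = fes.CVSampleSet.from_dataset(data)
    result = ak.UmbrellaPMF(cvs, E1, E2, estimator="mbar").fit()
    return spec, cvs, result


def flat_grid(n1=4, n2=4, temperature=298.15) -> ak.FESGrid:
    return ak.FESGrid(
        edges1=np.arange(n1 + 1.0),
        edges2=np.arange(n2 + 1.0),
        free_energy=np.zeros((n1, n2)),
        visited=np.ones((n1, n2), dtype=bool),
        temperature=temperature,
    )


class TestPMF:
    def test_single_window_flat_truth_is_flat(self):
        spec = ak.Umbrella2DSpec(
            basins=(ak.Basin(center=(10.0, 10.0), sigma=(300.0, 300.0), weight=1.0),),
            bias_centers=((10.0, 10.0),),
            spring_constant=0.3,
            samples_per_window=20_000,
        )
        data = ak.generate_umbrella_2d(spec, seed=1)
        cvs = fes.CVSampleSet.from_dataset(data)
        e = np.arange(4.0, 16.6, 0.5)
        result = ak.UmbrellaPMF(cvs, e, e, estimator="mbar").fit()
        g = result.grid.free_energy
        counts = np.histogram2d(data.samples[0][:, 0], data.samples[0][:, 1], bins=(e, e))[0]
        well = counts >= 50
        # unbiasing a flat surface leaves only histogram noise
        assert np.nanmax(g[well]) - np.nanmin(g[well]) < 0.5
        assert np.nanstd(g[well]) < 0.12

    def test_double_well_recovery_on_well_sampled_bins(self, umbrella_fit):
        spec, cvs, result = umbrella_fit
        g = result.grid.free_energy
        xg, yg = np.meshgrid(result.grid.centers1, result.grid.centers2, indexing="ij")
        g_true = spec.truth_fes(xg, yg)
        counts = np.zeros_like(g)
        for xy in cvs.samples:
            counts += np.histogram2d(xy[:, 0], xy[:, 1], bins=(E1, E2))[0]
        well = result.grid.visited & (counts >= 100)
        # align gauges with a Boltzmann-weighted offset over compared bins
        w = np.exp(-g[well] / KT)
        offset = np.sum(w * (g[well] - g_true[well])) / np.sum(w)
        assert np.max(np.abs(g[well] - g_true[well] - offset)) <= 0.3

    def test_wham_and_binned_mbar_share_the_fixed_point(self, umbrella_fit):
        # snap samples to bin centres: at matched discretisation the two
        # estimators solve identical equations
        _, cvs, _ = umbrella_fit
        c1 = 0.5 * (E1[:-1] + E1[1:])
        c2 = 0.5 * (E2[:-1] + E2[1:])
        snapped = []
        for xy in cvs.samples:
            i = np.clip(np.searchsorted(E1, xy[:, 0], side="right") - 1, 0, len(c1) - 1)
            j = np.clip(np.searchsorted(E2, xy[:, 1], side="right") - 1, 0, len(c2) - 1)
            snapped.append(np.stack([c1[i], c2[j]], axis=1))
        cvs_snapped = fes.CVSampleSet(
            samples=tuple(snapped),
            bias_centers=cvs.bias_centers,
            spring_constant=cvs.spring_constant,
        )
        gm = ak.UmbrellaPMF(cvs_snapped, E1, E2, estimator="mbar").fit().grid
        gw = ak.UmbrellaPMF(cvs_snapped, E1, E2, estimator="wham").fit().grid
        both = gm.visited & gw.visited
        assert np.max(np.abs(gm.free_energy[both] - gw.free_energy[both])) <= 0.05

    def test_disconnected_window_graph_raises_with_components(self):
        spec = ak.Umbrella2DSpec(
            basins=(
                ak.Basin(center=(5.0, 5.0), sigma=(0.5, 0.5), weight=1.0),
                ak.Basin(center=(30.0, 20.0), sigma=(0.5, 0.5), weight=1.0),
            ),
            bias_centers=((5.0, 5.0), (30.0, 20.0)),
            spring_constant=5.0,
            samples_per_window=100,
        )
        data = ak.generate_umbrella_2d(spec, seed=2)
        cvs = fes.CVSampleSet.from_dataset(data)
        with pytest.raises(ValueError, match="disconnected"):
            ak.UmbrellaPMF(cvs, E1, E2, estimator="mbar").fit()

    def test_grid_gauge_is_validated(self):
        with pytest.raises(ValueError, match="gauge"):
            ak.FESGrid(
                edges1=np.arange(3.0),
                edges2=np.arange(3.0),
                free_energy=np.ones((2, 2)),
                visited=np.ones((2, 2), dtype=bool),
                temperature=298.15,
            )

    def test_unvisited_bins_carry_nan_sentinel(self, umbrella_fit):
        _, _, result = umbrella_fit
        g = result.grid.free_energy
        assert np.all(np.isnan(g[~result.grid.visited]))
        assert np.all(np.isfinite(g[result.grid.visited]))


class TestPopulations:
    def test_flat_grid_half_mask(self):
        grid = flat_grid(4, 4)
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2] = True
        assert fes.macrostate_population(grid, mask) == pytest.approx(0.5, abs=1e-12)

    def test_partition_sums_to_one(self, umbrella_fit):
        _, _, result = umbrella_fit
        half = np.zeros_like(result.grid.visited)
        half[: half.shape[0] // 2] = True
        p1 = fes.macrostate_population(result.grid, half)
        p2 = fes.macrostate_population(result.grid, ~half)
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_truth_recovery_within_two_percent(self, umbrella_fit):
        spec, _, result = umbrella_fit
        for name, mask in ak.default_macrostate_masks().items():
            p_est = fes.macrostate_population(result.grid, mask)
            p_true = spec.truth_population(mask.region)
            assert p_est == pytest.approx(p_true, abs=0.02)

    def test_gap_from_printed_population_midpoints(self):
        # the ordered state at ~7% against the disordered one at ~77.5%
        assert fes.gap_from_populations(0.07, 0.775) == pytest.approx(1.4, abs=0.05)

    def test_gap_antisymmetry(self, umbrella_fit):
        _, _, result = umbrella_fit
        masks = ak.default_macrostate_masks()
        a, b = masks["open_ordered"], masks["closed_disordered"]
        assert fes.macrostate_gap(result.grid, a, b) == pytest.approx(
            -fes.macrostate_gap(result.grid, b, a), abs=1e-12
        )

    def test_equal_populations_give_zero_gap(self):
        assert fes.gap_from_populations(0.3, 0.3) == pytest.approx(0.0, abs=1e-15)

    def test_empty_mask_rejected(self):
        grid = flat_grid()
        with pytest.raises(ValueError):
            fes.macrostate_population(grid, np.zeros((4, 4), dtype=bool))

    def test_masks_are_disjoint(self):
        masks = ak.default_macrostate_masks()
        inter = masks["open_ordered"].polygon.intersection(
            masks["closed_disordered"].polygon
        )
        assert inter.area == 0.0


class TestSplitHalf:
    def test_duplicated_halves_give_zero_sigma(self):
        spec = ak.default_umbrella_spec(samples_per_window=120)
        data = ak.generate_umbrella_2d(spec, seed=3)
        doubled = fes.CVSampleSet(
            samples=tuple(np.concatenate([xy, xy]) for xy in data.samples),
            bias_centers=data.bias_centers,
            spring_constant=data.spring_constant,
        )
        unc = fes.split_half_uncertainty(
            doubled, E1, E2, estimator="wham", masks=ak.default_macrostate_masks()
        )
        finite = np.isfinite(unc.sigma_grid)
        assert np.max(unc.sigma_grid[finite]) == pytest.approx(0.0, abs=1e-8)
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in unc.sigma_populations.values())

    def test_window_with_single_sample_rejected(self):
        cvs = fes.CVSampleSet(
            samples=(np.array([[1.0, 1.0]]),),
            bias_centers=((1.0, 1.0),),
            spring_constant=1.0,
        )
        with pytest.raises(ValueError):
            cvs.halves()


def test_grid_refinement_stability():
    spec = ak.default_umbrella_spec(samples_per_window=300)
    data = ak.generate_umbrella_2d(spec, seed=4)
    cvs = fes.CVSampleSet.from_dataset(data)
    masks = ak.default_macrostate_masks()
    pops = {}
    for width in (1.0, 0.5):
        e1 = np.arange(2.0, 38.0 + width / 2, width)
        e2 = np.arange(0.0, 27.0 + width / 2, width)
        grid = ak.UmbrellaPMF(cvs, e1, e2, estimator="wham").fit().grid
        pops[width] = fes.macrostate_population(grid, masks["open_ordered"])
    assert abs(pops[1.0] - pops[0.5]) < 0.01
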