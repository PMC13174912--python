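import math

import numpy as np
import pytest

from calixtda.chemio import MoleculePointCloud
from calixtda.fixtures import regular_polygon_cloud, synthetic_calixarene
from calixtda.oracle import vr_bars_oracle
from calixtda.topology import (
    TopoConfig,
    compute_diagram,
    h0_persistence,
    h1_persistence,
    pairwise_distances,
)

from _oracles import single_linkage_heights


def finite_bars(features, order):
    return sorted(
        (round(f.birth, 9), round(f.death, 9))
        for f in features
        if f.order == order and math.isfinite(f.death)
    )


class TestPairwiseDistances:
    def test_three_four_five_triangle(self):
        d = pairwise_distances(np.array([[0, 0, 0], [3, 4, 0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_single_atom_zero_matrix(self):
        assert pairwise_distances(np.zeros((1, 3))).shape == (1, 1)

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(10, 3))
        d = pairwise_distances(pts)
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(np.linalg.norm(pts[i] - pts[j]))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestH0:
    def test_collinear_path_deaths(self):
        d = pairwise_distances(np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0]]))
        deaths = [f.death for f in h0_persistence(d, "CCC") if math.isfinite(f.death)]
        assert sorted(deaths) == pytest.approx([1.0, 2.0])

    def test_identical_points_die_at_zero(self):
        d = pairwise_distances(np.zeros((5, 3)))
        bars = [f for f in h0_persistence(d, "CCCCC") if math.isfinite(f.death)]
        assert len(bars) == 4
        assert all(f.death == 0.0 for f in bars)

    def test_exactly_one_infinite_bar(self, random_cloud_factory):
        cloud = random_cloud_factory(8, seed=5)
        bars = h0_persistence(pairwise_distances(cloud.coords), cloud.elements)
        assert sum(math.isinf(f.death) for f in bars) == 1
        assert all(f.birth == 0.0 for f in bars)

    @pytest.mark.parametrize("seed", range(50))
    def test_deaths_match_union_find_single_linkage(self, seed, random_cloud_factory):
        n = 5 + seed % 8
        cloud = random_cloud_factory(n, seed=seed)
        d = pairwise_distances(cloud.coords)
        deaths = sorted(
            f.death for f in h0_persistence(d, cloud.elements) if math.isfinite(f.death)
        )
        assert deaths == pytest.approx(single_linkage_heights(d))

    def test_merge_edges_tagged_with_elements(self):
        cloud = MoleculePointCloud(
            id="co", elements=("C", "O"), coords=[[0, 0, 0], [1.2, 0, 0]]
        )
        bars = h0_persistence(pairwise_distances(cloud.coords), cloud.elements)
        (finite,) = [f for f in bars if math.isfinite(f.death)]
        assert set(finite.element_pair) == {"C", "O"}


class TestH1:
    def test_hexagon_has_one_cycle_born_at_side(self):
        side = 1.4
        cloud = regular_polygon_cloud(6, side)
        d = pairwise_distances(cloud.coords)
        bars = h1_persistence(d, cloud.elements, r_max=3 * side)
        assert len(bars) == 1
        assert bars[0].birth == pytest.approx(side)
        (oracle_bar,) = vr_bars_oracle(d, 3 * side)[1]
        assert (bars[0].birth, bars[0].death) == pytest.approx(oracle_bar)

    def test_triangle_cycle_fills_at_birth(self):
        cloud = regular_polygon_cloud(3, 1.0)
        d = pairwise_distances(cloud.coords)
        assert h1_persistence(d, cloud.elements, r_max=5.0) == []

    def test_tight_cluster_has_no_cycles(self, rng):
        pts = rng.normal(size=(4, 3)) * 0.05
        d = pairwise_distances(pts)
        assert h1_persistence(d, ["C"] * 4, r_max=5.0) == []

    def test_nonpositive_rmax_rejected(self):
        with pytest.raises(ValueError):
            h1_persistence(np.zeros((2, 2)), ["C", "C"], r_max=0.0)

    def test_birth_edge_elements_recorded(self):
        cloud = regular_polygon_cloud(6, 1.4, element="N")
        d = pairwise_distances(cloud.coords)
        (bar,) = h1_persistence(d, cloud.elements, r_max=4.2)
        assert bar.element_pair == ("N", "N")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_bars_match_exhaustive_reduction(self, seed, random_cloud_factory):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        cloud = random_cloud_factory(n, seed=1000 + seed)
        d = pairwise_distances(cloud.coords)
        r_max = 3.0
        assert finite_bars(h0_persistence(d, cloud.elements), 0) == pytest.approx(
            sorted(
                (round(b, 9), round(dd, 9))
                for b, dd in vr_bars_oracle(d)[0]
                if math.isfinite(dd)
            )
        )
        mine = finite_bars(h1_persistence(d, cloud.elements, r_max), 1)
        ref = sorted((round(b, 9), round(dd, 9)) for b, dd in vr_bars_oracle(d, r_max)[1])
        assert mine == pytest.approx(ref)


class TestProperties:
    @pytest.mark.parametrize("scale", [0.5, 2.0, 7.3])
    def test_scale_equivariance(self, scale, random_cloud_factory):
        cloud = random_cloud_factory(9, seed=77)
        d1 = pairwise_distances(cloud.coords)
        d2 = pairwise_distances(cloud.coords * scale)
        b1 = h1_persistence(d1, cloud.elements, r_max=4.0)
        b2 = h1_persistence(d2, cloud.elements, r_max=4.0 * scale)
        assert [(f.birth * scale, f.death * scale) for f in b1] == pytest.approx(
            [(f.birth, f.death) for f in b2]
        )

    def test_stability_under_small_perturbation(self, rng, random_cloud_factory):
        eps = 1e-3
        cloud = random_cloud_factory(10, seed=3)
        pert = cloud.coords + rng.uniform(-eps, eps, size=cloud.coords.shape)
        d1 = pairwise_distances(cloud.coords)
        d2 = pairwise_distances(pert)
        a = sorted(f.death for f in h0_persistence(d1, cloud.elements) if math.isfinite(f.death))
        b = sorted(f.death for f in h0_persistence(d2, cloud.elements) if math.isfinite(f.death))
        assert np.max(np.abs(np.array(a) - np.array(b))) <= 2 * eps + 1e-12


class TestComputeDiagram:
    def test_single_atom_empty_after_dropping_essential(self):
        cloud = MoleculePointCloud(id="one", elements=("C",), coords=[[0, 0, 0]])
        assert compute_diagram(cloud).features == []

    def test_h0_finite_count_is_n_minus_one(self, random_cloud_factory):
        cloud = random_cloud_factory(12, seed=9, scale=0.8)
        diag = compute_diagram(cloud)
        assert len(diag.bars(0)) == cloud.n_atoms - 1

    def test_calixarene_fixture_has_ring_features(self):
        cloud, _ = synthetic_calixarene("cone")
        diag = compute_diagram(cloud)
        assert len(diag.bars(1)) > 0

    def test_hydrogen_filter(self):
        cloud = MoleculePointCloud(
            id="ch", elements=("C", "H", "C"), coords=[[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        )
        diag = compute_diagram(cloud, TopoConfig(include_hydrogens=False))
        assert len(diag.bars(0)) == 1  # two carbons remain

    def test_finite_deaths_respect_window(self, random_cloud_factory):
        cloud = random_cloud_factory(10, seed=42, scale=6.0)
        cfg = TopoConfig(r_max=4.0)
        diag = compute_diagram(cloud, cfg)
        assert all(f.death <= cfg.r_max for f in diag.features)
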