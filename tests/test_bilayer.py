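"""Unit and property tests for the bilayer coordinate metrics."""

import numpy as np
import pandas as pd
import pytest

import nanodomain as nd
from nanodomain.bilayer import AngleSeries, minimum_image, reconstruct_ch_vectors
from nanodomain.errors import SchemaError, StructuralError
from nanodomain.simulate import simulate_bilayer_ensemble

from oracles import brute_contact_count


def simple_ensemble(coords_fn, n_frames=2, box=(10.0, 10.0, 10.0)):
    """Build a one-GM1 ensemble whose headgroup tips come from coords_fn."""
    # atoms: 0 anchor, (1,2) V1, (3,4) V2, (5,6) V3
    coords = np.zeros((n_frames, 7, 3))
    coords[:, 0] = [5.0, 5.0, 2.0]
    for k in range(3):
        base = np.array([5.0, 5.0, 2.0])
        coords[:, 1 + 2 * k] = base
        coords[:, 2 + 2 * k] = base + coords_fn(k)
    atoms = {"P1": 0, "V1A": 1, "V1B": 2, "V2A": 3, "V2B": 4, "V3A": 5, "V3B": 6}
    lip = nd.Lipid(0, "GM1", "upper", 0, atoms, {})
    return nd.BilayerEnsemble(coords, np.array(box), [lip])


class TestHeadgroupAngles:
    def test_vector_along_normal_gives_zero(self):
        ens = simple_ensemble(lambda k: np.array([0.0, 0.0, 1.0]))
        series = nd.headgroup_angle_series(ens, nd.HeadgroupVectorSpec(), [])
        for s in series:
            np.testing.assert_allclose(s.theta_deg, 0.0, atol=1e-10)

    def test_in_plane_vector_gives_ninety(self):
        ens = simple_ensemble(lambda k: np.array([1.0, 0.0, 0.0]))
        series = nd.headgroup_angle_series(ens, nd.HeadgroupVectorSpec(), [])
        for s in series:
            np.testing.assert_allclose(s.theta_deg, 90.0, atol=1e-10)

    def test_unresolvable_atom_names_lipid(self):
        ens = simple_ensemble(lambda k: np.array([0.0, 0.0, 1.0]))
        spec = nd.HeadgroupVectorSpec((("V1A", "MISSING"), ("V2A", "V2B"), ("V3A", "V3B")))
        with pytest.raises(SchemaError, match="MISSING"):
            nd.headgroup_angle_series(ens, spec, [])

    def test_generator_truth_recovered(self):
        truth = nd.BilayerTruth(mean_angle_deg=30.0, sd_unbound_deg=10.0,
                                n_bound=0, with_chains=False)
        ens, rec = simulate_bilayer_ensemble(truth, 10_000, 4, seed=3)
        series = nd.headgroup_angle_series(ens, nd.HeadgroupVectorSpec(), [])
        thetas = np.concatenate([s.theta_deg for s in series])
        assert np.mean(thetas) == pytest.approx(30.0, rel=0.02)
        assert np.std(thetas) == pytest.approx(10.0, rel=0.02)


class TestSigmaTheta:
    def test_constant_series_zero_sd(self):
        s = AngleSeries(0, "V1", np.full(10, 25.0), "unbound")
        res = nd.sigma_theta([s])
        assert res.table["sigma_theta"].iloc[0] == 0.0

    def test_two_frame_sample_sd(self):
        s = AngleSeries(0, "V1", np.array([10.0, 20.0]), "unbound")
        res = nd.sigma_theta([s])
        assert res.table["sigma_theta"].iloc[0] == pytest.approx(np.sqrt(50.0))

    def test_missing_group_flags_ratio_undefined(self):
        s = AngleSeries(0, "V1", np.array([10.0, 20.0]), "unbound")
        res = nd.sigma_theta([s])
        assert np.isnan(res.ratio)
        assert res.undefined_groups

    def test_planted_three_to_one_ratio(self):
        truth = nd.BilayerTruth(sd_bound_deg=4.0, sd_unbound_deg=12.0,
                                n_bound=4, with_chains=False)
        ens, rec = simulate_bilayer_ensemble(truth, 10_000, 8, seed=11)
        series = nd.headgroup_angle_series(ens, nd.HeadgroupVectorSpec(),
                                           rec["bound_ids"])
        res = nd.sigma_theta(series)
        assert res.ratio == pytest.approx(3.0, abs=0.3)


class TestInterdigitation:
    def test_chain_within_own_leaflet_is_zero(self):
        truth = nd.BilayerTruth(crossing_fraction=0.0, crossing_model="fixed")
        ens, _ = simulate_bilayer_ensemble(truth, 5, 4, seed=1)
        for chain in ("sphingosine", "acyl"):
            assert nd.interdigitation_fraction(ens, "GM1", chain).value == 0.0

    def test_planted_half_crossing_exact(self):
        truth = nd.BilayerTruth(crossing_fraction=0.5, crossing_model="fixed",
                                chain_carbons=16)
        ens, _ = simulate_bilayer_ensemble(truth, 5, 9, seed=2)
        assert nd.interdigitation_fraction(ens, "GM1", "acyl").value == 0.5

    def test_binomial_crossing_recovers_mean(self):
        truth = nd.BilayerTruth(crossing_fraction=0.25, crossing_model="binomial")
        ens, _ = simulate_bilayer_ensemble(truth, 1000, 8, seed=4)
        res = nd.interdigitation_fraction(ens, "GM1", "acyl")
        assert res.value == pytest.approx(0.25, abs=0.01)

    def test_absent_species_rejected(self):
        truth = nd.BilayerTruth()
        ens, _ = simulate_bilayer_ensemble(truth, 2, 4, seed=5)
        with pytest.raises(SchemaError):
            nd.interdigitation_fraction(ens, "GB3", "acyl")


class TestContacts:
    def test_no_contacts_when_chains_apart(self):
        truth = nd.BilayerTruth(lattice_spacing_nm=2.0)
        ens, _ = simulate_bilayer_ensemble(truth, 3, 4, seed=6)
        res = nd.transbilayer_contacts(ens, "GM1", "POPS", 0.35)
        assert np.all(res.contacts_per_frame == 0)

    def test_single_constructed_pair(self):
        # one planted pair at 0.2 nm; cutoff 0.35 sees it, cutoff 0.15 does not
        truth = nd.BilayerTruth(contacts_per_frame=1, lattice_spacing_nm=2.0)
        ens, _ = simulate_bilayer_ensemble(truth, 3, 4, seed=7)
        assert np.all(nd.transbilayer_contacts(ens, "GM1", "POPS", 0.35)
                      .contacts_per_frame == 1)
        assert np.all(nd.transbilayer_contacts(ens, "GM1", "POPS", 0.15)
                      .contacts_per_frame == 0)

    def test_matches_brute_force_enumeration(self):
        truth = nd.BilayerTruth(contacts_per_frame=3, lattice_spacing_nm=2.0)
        ens, _ = simulate_bilayer_ensemble(truth, 4, 9, seed=8)
        res = nd.transbilayer_contacts(ens, "GM1", "POPS", 0.4)
        idx_a = [i for lip in ens.lipids_of("GM1", "upper")
                 for c in lip.chains.values() for i in c]
        idx_b = [i for lip in ens.lipids_of("POPS", "lower")
                 for c in lip.chains.values() for i in c]
        for f in range(ens.n_frames):
            expected = brute_contact_count(ens.coords[f, idx_a],
                                           ens.coords[f, idx_b],
                                           ens.box_for(f), 0.4)
            assert res.contacts_per_frame[f] == expected


class TestAreaPerLipid:
    def _lattice_ensemble(self, n_side, spacing, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = n_side * n_side
        gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
        xy = np.column_stack([gx.ravel(), gy.ravel()]) * spacing + spacing / 2
        xy = xy + rng.normal(0, jitter, xy.shape)
        coords = np.zeros((1, n, 3))
        coords[0, :, :2] = xy
        coords[0, :, 2] = 2.0
        lipids = [nd.Lipid(i, "GM1", "upper", i, {"P1": i}, {}) for i in range(n)]
        box = np.array([n_side * spacing, n_side * spacing, 10.0])
        return nd.BilayerEnsemble(coords, box, lipids)

    def test_square_lattice_equal_cells(self):
        ens = self._lattice_ensemble(2, 3.0)
        res = nd.area_per_lipid(ens, "upper")
        np.testing.assert_allclose(res.per_lipid["area"], 9.0, rtol=1e-9)

    def test_areas_sum_to_box_area(self):
        ens = self._lattice_ensemble(10, 1.0, jitter=0.2, seed=3)
        res = nd.area_per_lipid(ens, "upper")
        assert res.per_lipid["area"].sum() == pytest.approx(100.0, rel=1e-6)

    def test_matches_replica_tiling_oracle(self):
        """Cell-by-cell agreement with an independent tessellation of the
        9-replica tiling (shapely polygon areas of clipped cells)."""
        from scipy.spatial import Voronoi
        from shapely.geometry import Polygon

        ens = self._lattice_ensemble(7, 1.0, jitter=0.25, seed=4)
        res = nd.area_per_lipid(ens, "upper")
        xy = ens.coords[0, :, :2]
        box = ens.box_for(0)[:2]
        pts = np.concatenate([xy + np.array([i, j]) * box
                              for i in (-1, 0, 1) for j in (-1, 0, 1)])
        vor = Voronoi(pts)
        # central copy is the block with offset (0, 0): index 4 * n .. 5 * n
        n = len(xy)
        areas = []
        for i in range(4 * n, 5 * n):
            region = vor.regions[vor.point_region[i]]
            poly = Polygon(vor.vertices[region])
            areas.append(poly.convex_hull.area)
        lookup = res.per_lipid.set_index("lipid_id")["area"]
        np.testing.assert_allclose(lookup.loc[np.arange(n)].to_numpy(),
                                   areas, rtol=1e-9)

    def test_coincident_anchors_perturbed(self):
        ens = self._lattice_ensemble(3, 2.0)
        ens.coords[0, 1, :2] = ens.coords[0, 0, :2]  # duplicate anchor
        res = nd.area_per_lipid(ens, "upper")
        assert res.per_lipid["area"].sum() == pytest.approx(36.0, rel=1e-6)

    def test_too_few_lipids_rejected(self):
        ens = self._lattice_ensemble(2, 2.0)
        ens.lipids = ens.lipids[:2]
        with pytest.raises(StructuralError):
            nd.area_per_lipid(ens, "upper")


class TestOrderParameter:
    def test_perpendicular_ch_vectors_give_minus_half(self):
        v = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
        assert nd.scd_from_vectors(v) == pytest.approx(-0.5)

    def test_magic_angle_gives_zero(self):
        theta = np.deg2rad(54.7356103)
        v = np.array([[np.sin(theta), 0.0, np.cos(theta)]])
        assert nd.scd_from_vectors(v) == pytest.approx(0.0, abs=1e-7)

    def test_isotropic_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(100_000, 3))
        assert abs(nd.scd_from_vectors(v)) < 0.02

    def test_aligned_all_trans_chain_exact(self):
        truth = nd.BilayerTruth(crossing_fraction=0.0, crossing_model="fixed")
        ens, _ = simulate_bilayer_ensemble(truth, 2, 4, seed=9)
        prof = nd.chain_order_parameter(ens, "GM1", "acyl")
        np.testing.assert_allclose(prof["s_cd"], -0.5, atol=1e-12)

    def test_short_chain_rejected(self):
        truth = nd.BilayerTruth(chain_carbons=2)
        ens, _ = simulate_bilayer_ensemble(truth, 2, 4, seed=10)
        with pytest.raises(StructuralError):
            nd.chain_order_parameter(ens, "GM1", "acyl")

    def test_reconstructed_hydrogens_are_unit_and_symmetric(self):
        prev = np.array([[0.0, 0.0, 1.0]])
        curr = np.array([[0.05, 0.0, 0.87]])
        nxt = np.array([[0.0, 0.0, 0.74]])
        box = np.array([10.0, 10.0, 10.0])
        h1, h2 = reconstruct_ch_vectors(prev, curr, nxt, box)
        assert np.linalg.norm(h1) == pytest.approx(1.0)
        assert np.linalg.norm(h2) == pytest.approx(1.0)
        cos_hh = float(np.dot(h1[0], h2[0]))
        assert np.degrees(np.arccos(cos_hh)) == pytest.approx(109.47122, abs=1e-3)


class TestPeriodicInvariance:
    def test_translation_by_box_vector_changes_nothing(self):
        truth = nd.BilayerTruth(crossing_fraction=0.25, crossing_model="fixed",
                                n_bound=2, contacts_per_frame=0,
                                lattice_spacing_nm=2.0)
        ens, rec = simulate_bilayer_ensemble(truth, 20, 9, seed=12)
        shifted = nd.BilayerEnsemble(ens.coords + ens.box, ens.box, ens.lipids)
        for e1, e2 in ((ens, shifted),):
            # the terminal-carbon midplane is shift-covariant
            i1 = nd.interdigitation_fraction(e1, "GM1", "acyl")
            i2 = nd.interdigitation_fraction(e2, "GM1", "acyl")
            assert i1.value == pytest.approx(i2.value)
            c1 = nd.transbilayer_contacts(e1, "GM1", "POPS", 0.4)
            c2 = nd.transbilayer_contacts(e2, "GM1", "POPS", 0.4)
            np.testing.assert_array_equal(c1.contacts_per_frame, c2.contacts_per_frame)
            a1 = nd.area_per_lipid(e1, "upper", frames=[0])
            a2 = nd.area_per_lipid(e2, "upper", frames=[0])
            np.testing.assert_allclose(a1.per_lipid["area"], a2.per_lipid["area"],
                                       rtol=1e-9)

    def test_minimum_image_convention(self):
        box = np.array([10.0, 10.0, 10.0])
        v = np.array([[9.0, -9.0, 0.2]])
        np.testing.assert_allclose(minimum_image(v, box), [[-1.0, 1.0, 0.2]])

    def test_metrics_invariant_under_frame_reordering(self):
        truth = nd.BilayerTruth(crossing_fraction=0.3, crossing_model="binomial",
                                n_bound=2, with_chains=True)
        ens, rec = simulate_bilayer_ensemble(truth, 50, 4, seed=13)
        rev = nd.BilayerEnsemble(ens.coords[::-1].copy(), ens.box, ens.lipids)
        v1 = nd.interdigitation_fraction(ens, "GM1", "acyl").value
        v2 = nd.interdigitation_fraction(rev, "GM1", "acyl").value
        assert v1 == pytest.approx(v2)
        s1 = nd.sigma_theta(nd.headgroup_angle_series(
            ens, nd.HeadgroupVectorSpec(), rec["bound_ids"]))
        s2 = nd.sigma_theta(nd.headgroup_angle_series(
            rev, nd.HeadgroupVectorSpec(), rec["bound_ids"]))
        assert s1.ratio == pytest.approx(s2.ratio)
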