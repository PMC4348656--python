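"""CG vesicle construction: lipid template, leaflet tiling, pore, PDB I/O."""

import numpy as np
import pytest

from lipocurv.vesicle import (
    POPC_TEMPLATE,
    build_vesicle,
    fibonacci_sphere,
    leaflet_lipid_count,
    pore_cap_angle,
    read_pdb,
    write_pdb,
)


class TestTemplate:
    def test_bead_census(self):
        t = POPC_TEMPLATE
        assert len(t.beads) == 13
        phob = t.hydrophobic_mask
        assert phob.sum() == 9 and (~phob).sum() == 4

    def test_names_and_classes(self):
        t = POPC_TEMPLATE
        heads = [b.name for b in t.beads if b.hclass == "hydrophilic"]
        assert heads == ["NC3", "PO4", "GL1", "GL2"]
        # 4 + 5 tail split between the two chains
        tails = [b.name for b in t.beads if b.hclass == "hydrophobic"]
        assert sum(n.endswith("A") for n in tails) == 4
        assert sum(n.endswith("B") for n in tails) == 5

    def test_span_is_leaflet_thickness(self):
        assert POPC_TEMPLATE.span == pytest.approx(18.4)

    def test_bond_graph_connected_and_sized(self):
        assert len(POPC_TEMPLATE.bonds) == 12  # a tree on 13 beads

    def test_glycerol_reclassification_at_analysis_level(self):
        from lipocurv.sasa import SASAConfig, shrake_rupley_sasa

        v = build_vesicle(12.0, pore_fraction=0.0, seed=0)
        res = shrake_rupley_sasa(v, SASAConfig(n_sphere_points=60, glycerol_class="hydrophobic"))
        assert res.hydrophobic_mask.sum() == v.n_lipids * 11


class TestCounts:
    def test_reference_leaflet_counts(self):
        assert leaflet_lipid_count(60.0, 65.0) == 696
        assert leaflet_lipid_count(23.2, 65.0) == 104

    def test_scaling_law(self):
        n1 = leaflet_lipid_count(60.0, 65.0)
        n2 = leaflet_lipid_count(120.0, 65.0)
        assert abs(n2 - 4 * n1) <= 2  # rounding

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            leaflet_lipid_count(-1.0, 65.0)
        with pytest.raises(ValueError):
            leaflet_lipid_count(60.0, 0.0)


class TestPoreCapAngle:
    def test_limits(self):
        assert pore_cap_angle(0.0) == 0.0
        assert pore_cap_angle(0.4999999) == pytest.approx(90.0, abs=1e-3)

    def test_reference_value(self):
        assert pore_cap_angle(0.13) == pytest.approx(42.27, abs=0.01)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pore_cap_angle(0.5)
        with pytest.raises(ValueError):
            pore_cap_angle(-0.01)


class TestBuildVesicle:
    def test_reference_12nm_build(self):
        v = build_vesicle(12.0, pore_fraction=0.0, seed=0)
        assert v.n_lipids == 800  # 696 outer + 104 inner
        assert v.n_beads == 10_400
        assert (v.leaflet == "outer").sum() == 696
        assert (v.leaflet == "inner").sum() == 104

    def test_pore_removes_cap_lipids(self):
        v0 = build_vesicle(12.0, pore_fraction=0.0, seed=0)
        v1 = build_vesicle(12.0, pore_fraction=0.13, seed=0)
        # ~13% fewer lipids per leaflet, small-sample cap variation allowed
        for leaf, n_full in (("outer", 696), ("inner", 104)):
            n = (v1.leaflet == leaf).sum()
            assert abs(n - round(0.87 * n_full)) <= max(2, 0.02 * n_full)
        # no lipid head inside the cap (directions in the build frame)
        heads = v1.coords[v1.head_mask]
        heads = heads / np.linalg.norm(heads, axis=1, keepdims=True)
        cap_cos = np.cos(np.radians(pore_cap_angle(0.13)))
        assert np.all(heads @ np.array([0.0, 0.0, 1.0]) < cap_cos + 1e-9)

    def test_head_radii_and_thickness(self):
        v = build_vesicle(12.0, pore_fraction=0.0, seed=1)
        com = v.coords.mean(axis=0)
        r = np.linalg.norm(v.coords - com, axis=1)
        leaf = v.leaflet_of_beads()
        r_out = r[v.head_mask & (leaf == "outer")]
        r_in = r[v.head_mask & (leaf == "inner")]
        assert r_out.mean() == pytest.approx(60.0, abs=0.05)
        assert r_in.mean() == pytest.approx(23.2, abs=0.05)

    def test_center_of_mass_at_origin(self):
        v = build_vesicle(12.0, pore_fraction=0.0, seed=2)
        assert np.linalg.norm(v.coords.mean(axis=0)) < 0.5

    def test_radial_ordering_of_heads_and_tails(self):
        """Hydrophilic heads sit farther out (outer leaflet) / farther in
        (inner leaflet) than their own terminal tail bead."""
        v = build_vesicle(12.0, pore_fraction=0.0, seed=3)
        com = v.coords.mean(axis=0)
        r = np.linalg.norm(v.coords - com, axis=1).reshape(-1, 13)
        leaf = v.leaflet
        nc3, c5b = 0, 12  # template positions: head bead and longest-chain end
        outer = leaf == "outer"
        assert np.all(r[outer, nc3] > r[outer, c5b])
        assert np.all(r[~outer, nc3] < r[~outer, c5b])

    def test_hydrophobic_census(self):
        v = build_vesicle(12.0, pore_fraction=0.13, seed=4)
        assert v.hydrophobic_mask.sum() == v.n_lipids * 9

    def test_fibonacci_min_spacing(self):
        """Outer-leaflet head lattice spacing >= 0.8 * sqrt(area per lipid)."""
        from scipy.spatial import cKDTree

        v = build_vesicle(12.0, pore_fraction=0.0, seed=5)
        heads = v.coords[v.head_mask & (v.leaflet_of_beads() == "outer")]
        d, _ = cKDTree(heads).query(heads, k=2)
        assert d[:, 1].min() >= 0.8 * np.sqrt(65.0)

    def test_too_thick_for_diameter_rejected(self):
        with pytest.raises(ValueError):
            build_vesicle(7.0, thickness=36.8)

    def test_seed_changes_orientation_not_counts(self):
        a = build_vesicle(12.0, pore_fraction=0.0, seed=0)
        b = build_vesicle(12.0, pore_fraction=0.0, seed=1)
        assert a.n_lipids == b.n_lipids
        assert not np.allclose(a.coords, b.coords)


class TestFibonacciSphere:
    def test_unit_norm(self):
        pts = fibonacci_sphere(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_near_uniform_density(self):
        # octant counts of a uniform spherical lattice are near-equal
        pts = fibonacci_sphere(8000)
        signs = (pts > 0).astype(int)
        octant = signs[:, 0] * 4 + signs[:, 1] * 2 + signs[:, 2]
        counts = np.bincount(octant, minlength=8)
        assert counts.min() > 0.9 * 1000


class TestPDBRoundTrip:
    def test_round_trip_preserves_everything(self, tmp_path):
        v = build_vesicle(12.0, pore_fraction=0.13, seed=6)
        path = tmp_path / "v.pdb"
        write_pdb(v, path)
        back = read_pdb(path)
        assert back.n_beads == v.n_beads
        assert back.n_lipids == v.n_lipids
        assert np.array_equal(back.bead_names, v.bead_names)
        assert np.array_equal(back.leaflet, v.leaflet)
        assert np.abs(back.coords - v.coords).max() < 1.5e-3
        assert back.meta["outer_diameter_nm"] == 12.0
        assert back.meta["pore_fraction"] == 0.13
        assert back.meta["seed"] == 6

    def test_large_vesicle_round_trip_with_residue_wrap(self, tmp_path):
        """>10^4 lipids exceed the PDB residue-number field; identity is
        recovered from the fixed 13-bead record order."""
        v = build_vesicle(38.0, pore_fraction=0.0, seed=7)
        assert v.n_lipids > 10_000
        path = tmp_path / "big.pdb"
        write_pdb(v, path)
        back = read_pdb(path)
        assert back.n_lipids == v.n_lipids
        assert np.array_equal(back.lipid_index, v.lipid_index)
        assert np.abs(back.coords - v.coords).max() < 1.5e-3

    def test_malformed_pdb_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  NC3 POP O   1      10.000  10.000\n")
        with pytest.raises(ValueError):
            read_pdb(path)

    def test_wrong_bead_order_names_record(self, tmp_path):
        v = build_vesicle(12.0, pore_fraction=0.0, seed=8)
        path = tmp_path / "v.pdb"
        write_pdb(v, path)
        lines = path.read_text().splitlines()
        # corrupt the atom name of the second ATOM record
        for k, line in enumerate(lines):
            if line.startswith("ATOM") and " PO4 " in line:
                lines[k] = line.replace(" PO4 ", " XXX ")
                break
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="record"):
            read_pdb(path)
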