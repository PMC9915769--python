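"""Shrake-Rupley SASA and interface buried surface area."""

import math

import gemmi
import numpy as np
import pytest

from proppd.bsa import (
    AtomSet,
    InterfaceResult,
    atoms_from_structure,
    buried_surface_area,
    sasa,
    sphere_points,
    total_sasa,
)

CARBON = 1.70
PROBE = 1.4
ISOLATED_C = 4 * math.pi * (CARBON + PROBE) ** 2  # = 4pi * 3.10^2


def atomset(coords, radii=None, chains=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    radii = np.full(n, CARBON) if radii is None else np.asarray(radii)
    chains = np.array(["A"] * n) if chains is None else np.asarray(chains)
    return AtomSet(coords, radii, chains)


def mc_sasa_total(atoms: AtomSet, n_points: int, seed: int = 0) -> float:
    """Monte-Carlo point-sampling oracle for the union surface area."""
    rng = np.random.default_rng(seed)
    expanded = atoms.radii + PROBE
    total = 0.0
    for i in range(len(atoms)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        sphere = atoms.coords[i] + expanded[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            d2 = np.sum((sphere - atoms.coords[j]) ** 2, axis=1)
            r2 = expanded[j] ** 2
            inside = d2 < r2 - 1e-9
            tied = (d2 <= r2 + 1e-9) & (j < i)
            exposed &= ~(inside | tied)
        total += exposed.mean() * 4 * math.pi * expanded[i] ** 2
    return total


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        areas = sasa(atomset([[0, 0, 0]]))
        assert areas[0] == pytest.approx(ISOLATED_C, rel=1e-12)
        assert ISOLATED_C == pytest.approx(120.76, abs=0.01)

    def test_distant_atoms_are_fully_exposed(self):
        areas = sasa(atomset([[0, 0, 0], [10.0, 0, 0]]))  # 10 > 2*(1.7+1.4)
        assert np.allclose(areas, ISOLATED_C)

    def test_coincident_atoms_count_surface_once(self):
        total = sasa(atomset([[0, 0, 0], [0, 0, 0]])).sum()
        assert total == pytest.approx(ISOLATED_C, rel=1e-12)

    def test_overlapping_pair_against_monte_carlo_oracle(self):
        atoms = atomset([[0, 0, 0], [2.0, 0, 0]])
        ours = total_sasa(atoms, n_points=960)
        mc = mc_sasa_total(atoms, n_points=200_000)
        assert ours == pytest.approx(mc, rel=0.02)

    def test_fully_buried_atom_has_zero_area(self):
        # small sphere at the centre of a tight cage of larger spheres
        cage = [
            [2.0, 0, 0], [-2.0, 0, 0], [0, 2.0, 0],
            [0, -2.0, 0], [0, 0, 2.0], [0, 0, -2.0],
        ]
        radii = [1.2] + [2.2] * 6
        areas = sasa(atomset([[0, 0, 0]] + cage, radii=radii))
        assert areas[0] == 0.0

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            atomset([[0, 0, 0]], radii=[0.0])

    def test_empty_atom_set_rejected(self):
        with pytest.raises(ValueError):
            sasa(atomset(np.empty((0, 3))))

    def test_point_density_stability(self, rng):
        coords = rng.normal(scale=4.0, size=(40, 3))
        atoms = atomset(coords)
        coarse = total_sasa(atoms, n_points=240)
        fine = total_sasa(atoms, n_points=960)
        assert abs(coarse - fine) / fine < 0.01

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(scale=4.0, size=(40, 3))
        atoms = atomset(coords)
        theta = 0.9
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = atomset(coords @ rot.T + np.array([5.0, -3.0, 2.0]))
        a = total_sasa(atoms)
        b = total_sasa(moved)
        assert abs(a - b) / a < 0.005

    def test_additivity_bound(self, rng):
        coords = rng.normal(scale=3.0, size=(30, 3))
        chains = np.array(["A"] * 15 + ["B"] * 15)
        atoms = atomset(coords, chains=chains)
        whole = total_sasa(atoms)
        parts = total_sasa(atoms.subset(["A"])) + total_sasa(atoms.subset(["B"]))
        assert whole <= parts + 1e-9


def _toy_structure() -> gemmi.Structure:
    """Two short interlocking 'chains' of carbon atoms with a real interface."""
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    rng = np.random.default_rng(7)
    for chain_name, z in (("A", 0.0), ("B", 2.6)):
        chain = gemmi.Chain(chain_name)
        for i in range(8):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            for j in range(3):
                atom = gemmi.Atom()
                atom.name = "C"
                atom.element = gemmi.Element("C")
                jitter = rng.normal(scale=0.2, size=3)
                atom.pos = gemmi.Position(
                    i * 1.8 + jitter[0], j * 1.8 + jitter[1], z + jitter[2]
                )
            # add atom to residue
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st


class TestBuriedSurfaceArea:
    def test_separated_groups_bury_nothing(self):
        st = _toy_structure()
        # move chain B far away
        for chain in st[0]:
            if chain.name == "B":
                for res in chain:
                    for atom in res:
                        atom.pos = gemmi.Position(
                            atom.pos.x + 100, atom.pos.y, atom.pos.z
                        )
        result = buried_surface_area(st, ["A"], ["B"])
        assert abs(result.bsa) < 1.0

    def test_toy_complex_matches_monte_carlo_oracle(self):
        st = _toy_structure()
        atoms = atoms_from_structure(st)
        ours = buried_surface_area(st, ["A"], ["B"])
        mc = InterfaceResult(
            sasa_A=mc_sasa_total(atoms.subset(["A"]), 100_000),
            sasa_B=mc_sasa_total(atoms.subset(["B"]), 100_000),
            sasa_AB=mc_sasa_total(atoms, 100_000),
        )
        assert ours.bsa > 100  # the interface is real
        assert ours.bsa == pytest.approx(mc.bsa, rel=0.02)

    def test_bsa_identity_and_nonnegativity(self):
        result = buried_surface_area(_toy_structure(), ["A"], ["B"])
        assert result.bsa == pytest.approx(
            result.sasa_A + result.sasa_B - result.sasa_AB
        )
        assert result.bsa >= -1e-9
        assert min(result.sasa_A, result.sasa_B, result.sasa_AB) >= 0

    def test_unknown_chain_lists_available(self):
        with pytest.raises(ValueError, match="available chains"):
            buried_surface_area(_toy_structure(), ["A"], ["Z"])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            buried_surface_area(_toy_structure(), ["A"], ["A"])

    def test_pdb_and_mmcif_round_trip(self, tmp_path):
        st = _toy_structure()
        st.setup_entities()
        pdb_path = tmp_path / "toy.pdb"
        cif_path = tmp_path / "toy.cif"
        st.write_pdb(str(pdb_path))
        st.make_mmcif_document().write_file(str(cif_path))
        ref = buried_surface_area(st, ["A"], ["B"])
        from_pdb = buried_surface_area(pdb_path, ["A"], ["B"])
        from_cif = buried_surface_area(cif_path, ["A"], ["B"])
        # PDB coordinates are written at 3 decimals; allow tiny drift
        assert from_pdb.bsa == pytest.approx(ref.bsa, rel=0.01)
        assert from_cif.bsa == pytest.approx(ref.bsa, rel=0.01)

    def test_waters_and_ligands_excluded_by_default(self):
        st = _toy_structure()
        chain = st[0]["A"]
        res = gemmi.Residue()
        res.name = "HOH"
        res.seqid = gemmi.SeqId(99, " ")
        atom = gemmi.Atom()
        atom.name = "O"
        atom.element = gemmi.Element("O")
        atom.pos = gemmi.Position(50, 50, 50)
        res.add_atom(atom)
        res.het_flag = "H"
        chain.add_residue(res)
        atoms = atoms_from_structure(st, ["A"])
        assert not np.any(np.all(atoms.coords == [50, 50, 50], axis=1))


def test_sphere_points_are_unit_and_deterministic():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.array_equal(pts, sphere_points(960))
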