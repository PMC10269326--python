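import numpy as np
import pytest

from pbcunwrap.core import BoxSeries
from pbcunwrap.gaussian_model import GaussianModelParams, simulate
from pbcunwrap.molecule import (
    AmbiguousBondError,
    MoleculeTopology,
    com_series,
    make_whole,
    unwrap_molecule,
)
from pbcunwrap.unwrap import tor_unwrap
from pbcunwrap.wrap import lattice_wrap


@pytest.fixture(scope="module")
def dimer():
    """Rigid 1D dimer riding a fluctuating-box COM trajectory.

    Atom coordinates are wrapped independently into the cell, as engines
    write them, so the bond frequently straddles the boundary.
    """
    bond = 0.2
    real = simulate(GaussianModelParams(L=1.0, sigma_L=0.1, sigma_w=0.05,
                                        n_steps=2000, seed=21))
    com_w = real.w.positions[:, 0, 0]
    L = real.box.lengths[:, 0]
    atoms = np.stack([com_w - bond / 2, com_w + bond / 2], axis=1)  # (F, 2)
    atoms = lattice_wrap(atoms, L[:, None], 1)
    topo = MoleculeTopology(masses=(1.0, 1.0), bonds=((0, 1),), reference=0)
    return atoms[:, :, None], real.box, topo, bond


class TestTopology:
    def test_disconnected_graph_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            MoleculeTopology(masses=(1.0, 1.0, 1.0), bonds=((0, 1),))

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            MoleculeTopology(masses=(1.0,), bonds=(), reference=3)

    def test_bfs_order_is_deterministic(self):
        topo = MoleculeTopology(masses=(1.0,) * 4, bonds=((0, 2), (0, 1), (2, 3)))
        assert topo._bfs_order() == [(0, 1), (0, 2), (2, 3)]


class TestMakeWhole:
    def test_molecule_inside_box_unchanged(self):
        topo = MoleculeTopology(masses=(1.0, 1.0), bonds=((0, 1),))
        pos = np.array([[0.1], [0.2]])
        out = make_whole(pos, np.array([1.0]), topo)
        assert np.array_equal(out, pos)

    def test_diatomic_across_boundary(self):
        # partner at -0.45 is really the image at +0.55 of the atom at +0.45
        topo = MoleculeTopology(masses=(1.0, 1.0), bonds=((0, 1),))
        out = make_whole(np.array([[0.45], [-0.45]]), np.array([1.0]), topo)
        assert np.allclose(out, [[0.45], [0.55]])

    def test_idempotent_on_random_broken_molecules(self, rng):
        topo = MoleculeTopology(masses=(1.0,) * 5,
                                bonds=((0, 1), (1, 2), (2, 3), (3, 4)))
        L = np.array([2.0, 2.0])
        for _ in range(20):
            chain = np.cumsum(rng.uniform(-0.3, 0.3, size=(5, 2)), axis=0)
            broken = chain - L * np.floor(chain / L + 0.5)
            once = make_whole(broken, L, topo)
            assert np.array_equal(make_whole(once, L, topo), once)

    def test_ambiguous_bond_rejected(self):
        topo = MoleculeTopology(masses=(1.0, 1.0), bonds=((0, 1),))
        with pytest.raises(AmbiguousBondError):
            make_whole(np.array([[0.0], [0.5]]), np.array([1.0]), topo)


class TestComSeries:
    def test_symmetric_atoms_average_to_zero(self):
        topo = MoleculeTopology(masses=(1.0, 1.0), bonds=((0, 1),))
        frames = np.array([[[-0.1], [0.1]]])
        traj = com_series(frames, topo, BoxSeries(np.ones((1, 1))))
        assert np.allclose(traj.positions, 0.0)

    def test_out_of_cell_com_is_wrapped(self):
        topo = MoleculeTopology(masses=(1.0,), bonds=())
        frames = np.array([[[0.6]]])
        traj = com_series(frames, topo, BoxSeries(np.ones((1, 1))), alpha=1)
        assert np.allclose(traj.positions, -0.4)

    def test_single_atom_equals_atom_series(self, rng):
        topo = MoleculeTopology(masses=(2.5,), bonds=())
        frames = 0.3 * rng.uniform(-1, 1, size=(10, 1, 1))
        traj = com_series(frames, topo, BoxSeries(np.ones((10, 1))))
        assert np.array_equal(traj.positions, frames)


class TestUnwrapMolecule:
    def test_rigid_dimer_bond_preserved(self, dimer):
        """The whole->COM->toroidal pipeline keeps the bond length exact."""
        frames, box, topo, bond = dimer
        _, atoms = unwrap_molecule(frames, topo, box)
        lengths = np.abs(atoms[:, 1, 0] - atoms[:, 0, 0])
        assert np.abs(lengths - bond).max() <= 1e-12

    def test_naive_per_atom_unwrapping_stretches_bonds(self, dimer):
        frames, box, topo, bond = dimer
        u = tor_unwrap(frames, box.lengths[:, None, :])
        lengths = np.abs(u[:, 1, 0] - u[:, 0, 0])
        assert lengths.max() > 1.5 * bond

    def test_reconstruction_com_matches_unwrapped_com(self, dimer):
        frames, box, topo, _ = dimer
        u_com, atoms = unwrap_molecule(frames, topo, box)
        masses = np.asarray(topo.masses)
        rec_com = np.einsum("fam,a->fm", atoms, masses) / masses.sum()
        assert np.abs(rec_com - u_com.positions[:, 0, :]).max() <= 1e-12

    def test_single_atom_molecule_is_plain_tor(self, realization):
        topo = MoleculeTopology(masses=(18.0,), bonds=())
        frames = realization.w.positions
        u_com, _ = unwrap_molecule(frames, topo, realization.box)
        expected = tor_unwrap(frames[:, 0, :], realization.box.lengths)
        assert np.allclose(u_com.positions[:, 0, :], expected, atol=1e-12)

    def test_reference_atom_mode_consistent_with_com(self, dimer):
        """Tracking one atom instead of the COM gives the same diffusion."""
        from pbcunwrap.diffusion import cve_fit
        frames, box, topo, _ = dimer
        u_com, _ = unwrap_molecule(frames, topo, box, reference_mode="com")
        u_atom, _ = unwrap_molecule(frames, topo, box, reference_mode="atom")
        f_com, f_atom = cve_fit(u_com), cve_fit(u_atom)
        se = np.hypot(f_com.stderr, f_atom.stderr)
        assert abs(f_com.D - f_atom.D) <= 3 * se
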