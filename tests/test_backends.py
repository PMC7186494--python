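"""Toy energy surface closed forms and invariances; engine file dialect."""

import numpy as np
import pytest

from qmrescore import BackendConfig, ToyBackend, parse_engine_output, toy_energy, write_engine_input
from qmrescore.backends.toy import EPS_LJ, SIGMA_LJ, TAU, V3, ToyTopology, equilibrium_length
from qmrescore.core import Atom, MolecularSystem
from qmrescore.synthetic import make_torsion_chain


def atom(el, xyz, q=0):
    return Atom(el, el, np.asarray(xyz, float), formal_charge=q)


def pair_system(r, q1=0, q2=0):
    return MolecularSystem(atoms=[atom("C", [0, 0, 0], q1), atom("C", [r, 0, 0], q2)])


class TestToyClosedForms:
    def test_single_atom_energy_is_solvation_only(self):
        res = toy_energy(MolecularSystem(atoms=[atom("O", [1.0, 2.0, 3.0], -1)]))
        assert res.converged
        assert res.gas == pytest.approx(0.0, abs=1e-12)
        assert res.total == pytest.approx(-TAU * 1.0)

    def test_lj_minimum_is_minus_epsilon(self):
        res = toy_energy(pair_system(SIGMA_LJ))
        assert res.total == pytest.approx(-EPS_LJ, abs=1e-12)

    def test_neutral_distant_dimer_energy_vanishes(self):
        assert toy_energy(pair_system(500.0)).total == pytest.approx(0.0, abs=1e-9)

    def test_coulomb_distance_dependent_dielectric(self):
        r = 5.0
        res = toy_energy(pair_system(r, q1=1, q2=-1))
        lj = EPS_LJ * ((SIGMA_LJ / r) ** 12 - 2 * (SIGMA_LJ / r) ** 6)
        coulomb = 332.06 * (1 * -1) / (4 * r * r)
        assert res.gas == pytest.approx(lj + coulomb, abs=1e-10)
        assert res.solvation == pytest.approx(-2 * TAU)

    def test_bond_term_quadratic(self):
        r0 = equilibrium_length("C", "C")
        stretched = MolecularSystem(
            atoms=[atom("C", [0, 0, 0]), atom("C", [r0 + 0.1, 0, 0])],
            bonds=[(0, 1, 1)],
        )
        assert toy_energy(stretched).total == pytest.approx(300.0 * 0.1**2, abs=1e-9)

    def test_torsion_scan_three_equal_minima(self, toy_backend):
        from qmrescore.entropy import rotatable_bonds, set_torsions

        chain = make_torsion_chain(1)
        (rotor,) = rotatable_bonds(chain)
        topo = toy_backend.topology(chain)
        angles = np.arange(0.0, 360.0, 1.0)
        energies = np.array(
            [topo.energy(set_torsions(chain.coords, [rotor], np.array([a]))) for a in angles]
        )
        # local minima on the periodic scan
        minima = [
            a
            for k, a in enumerate(angles)
            if energies[k] < energies[k - 1] and energies[k] < energies[(k + 1) % 360]
        ]
        assert len(minima) == 3
        spacing = np.diff(minima)
        # the 1-4 LJ term shifts the pure 3-fold wells by a few degrees
        np.testing.assert_allclose(spacing, [120.0, 120.0], atol=6.0)
        min_vals = [energies[int(a)] for a in minima]
        assert max(min_vals) - min(min_vals) < 0.35

    def test_determinism(self, charged_pocket, toy_backend):
        r1 = toy_backend.single_point(charged_pocket)
        r2 = toy_backend.single_point(charged_pocket)
        assert r1.total == r2.total  # bit identical


@pytest.fixture(scope="module")
def jittered_chain():
    rng = np.random.default_rng(7)
    base = make_torsion_chain(3)
    for a, q in zip(base.atoms, (1, 0, 0, -1, 0, 1)):
        a.formal_charge = q
    base.set_coords(base.coords + rng.normal(scale=0.1, size=(len(base.atoms), 3)))
    return base


class TestToyInvariances:

    def test_translation_rotation_invariance(self, jittered_chain, toy_backend):
        e0 = toy_backend.single_point(jittered_chain).total
        shifted = jittered_chain.copy()
        shifted.set_coords(jittered_chain.coords + np.array([10.0, -5.0, 2.5]))
        assert toy_backend.single_point(shifted).total == pytest.approx(e0, abs=1e-8)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = jittered_chain.copy()
        rotated.set_coords(jittered_chain.coords @ rot.T)
        assert toy_backend.single_point(rotated).total == pytest.approx(e0, abs=1e-8)

    def test_permutation_invariance(self, jittered_chain, toy_backend):
        perm = [3, 1, 0, 2, 5, 4]
        inv = {old: new for new, old in enumerate(perm)}
        shuffled = MolecularSystem(
            atoms=[jittered_chain.atoms[i].copy() for i in perm],
            bonds=[(inv[i], inv[j], o) for i, j, o in jittered_chain.bonds],
        )
        e0 = toy_backend.single_point(jittered_chain).total
        assert toy_backend.single_point(shuffled).total == pytest.approx(e0, abs=1e-8)

    def test_gradient_matches_finite_differences(self, toy_backend):
        rng = np.random.default_rng(11)
        for trial in range(3):
            chain = make_torsion_chain(2)
            chain.set_coords(chain.coords + rng.normal(scale=0.15, size=(5, 3)))
            topo = ToyTopology(chain)
            x = chain.coords
            _, grad = topo.energy_gradient(x)
            h = 1e-6
            fd = np.zeros_like(x)
            for i in range(x.shape[0]):
                for d in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[i, d] += h
                    xm[i, d] -= h
                    fd[i, d] = (topo.energy(xp) - topo.energy(xm)) / (2 * h)
            np.testing.assert_allclose(grad, fd, atol=1e-5)

    def test_overlapping_atoms_fail(self, toy_backend):
        clash = pair_system(0.1)
        res = toy_backend.single_point(clash)
        assert res.status == "failed"
        assert "overlap" in res.reason
        assert res.total is None


class TestEngineDialect:
    def test_writer_matches_golden_files(self, data_dir):
        from qmrescore import assign_formal_charges, make_toy_pocket

        cfg = BackendConfig()
        water = MolecularSystem(
            atoms=[
                Atom("O", "O", [0.0, 0.0, 0.0], res_name="HOH", record_class="water"),
                Atom("H", "H1", [0.9572, 0.0, 0.0], res_name="HOH", record_class="water"),
                Atom("H", "H2", [-0.2399, 0.9266, 0.0], res_name="HOH", record_class="water"),
            ],
            bonds=[(0, 1, 1), (0, 2, 1)],
        )
        assert write_engine_input(water, cfg) == (data_dir / "golden_neutral.mop").read_text()
        pocket = assign_formal_charges(make_toy_pocket(seed=0, n_residues=8))
        assert write_engine_input(pocket, cfg) == (data_dir / "golden_pocket.mop").read_text()

    def test_header_keywords(self):
        cfg = BackendConfig()
        anion = MolecularSystem(
            atoms=[Atom("Cl", "CL", [0.0, 0.0, 0.0], formal_charge=-1, record_class="ion")]
        )
        header = write_engine_input(anion, cfg).splitlines()[0]
        assert "CHARGE=-1" in header
        assert "PM7" in header and "1SCF" in header and "EPS=78.40" in header
        assert "MOZYME" not in header  # small system

    def test_anion_golden(self, data_dir):
        cfg = BackendConfig()
        anion = MolecularSystem(
            atoms=[Atom("Cl", "CL", [0.0, 0.0, 0.0], formal_charge=-1, record_class="ion")]
        )
        assert write_engine_input(anion, cfg) == (data_dir / "golden_anion.mop").read_text()

    def test_linear_scaling_keyword_for_large_systems(self):
        rng = np.random.default_rng(0)
        # well-separated grid, > 300 atoms
        pts = np.stack(np.meshgrid(*[np.arange(7) * 3.0] * 3), axis=-1).reshape(-1, 3)
        atoms = [atom("C", p) for p in pts[:310]]
        big = MolecularSystem(atoms=atoms)
        header = write_engine_input(big, BackendConfig()).splitlines()[0]
        assert "MOZYME" in header

    def test_parser_extracts_energies(self, data_dir):
        res = parse_engine_output((data_dir / "engine_normal.out").read_text())
        assert res.converged
        assert res.total == pytest.approx(-57.79930)
        assert res.solvation == pytest.approx(-0.42158 * 23.060548, rel=1e-6)
        assert res.gas == pytest.approx(res.total - res.solvation)
        assert res.sasa == pytest.approx(194.57)

    def test_parser_flags_truncated_output(self, data_dir):
        res = parse_engine_output((data_dir / "engine_truncated.out").read_text())
        assert res.status == "failed"
        assert res.total is None

    def test_parser_without_solvation_lines(self, data_dir):
        res = parse_engine_output((data_dir / "engine_gasphase.out").read_text())
        assert res.converged
        assert res.total == pytest.approx(-123.45678)
        assert res.solvation == 0.0
        assert res.sasa is None

    def test_write_parse_round_trip_on_fixtures(self, data_dir, tmp_path):
        """The farm-out path: write a job, elide the external run, parse a
        bundled output — no engine binary involved."""
        cfg = BackendConfig()
        water = MolecularSystem(
            atoms=[Atom("O", "O", [0.0, 0.0, 0.0], record_class="water")]
        )
        job = tmp_path / "job.mop"
        job.write_text(write_engine_input(water, cfg))
        assert job.read_text().startswith("PM7 1SCF CHARGE=0")
        res = parse_engine_output((data_dir / "engine_normal.out").read_text())
        assert res.converged

    def test_engine_backend_without_executable_fails_softly(self):
        from qmrescore import EngineBackend

        be = EngineBackend(BackendConfig(backend="engine"))
        res = be.single_point(pair_system(3.0))
        assert res.status == "failed"
        assert "executable" in res.reason
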