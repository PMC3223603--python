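"""Descriptors (monopole volume, shape quadrupole, feature counts) and
conformer eligibility rules."""

import numpy as np
import pytest

from combotan._kernels import bounding_grid, grid_density, kappa_from_radius
from combotan.config import DEFAULT_CONFIG
from combotan.molecules import (
    Atom,
    Conformer,
    FeaturePoint,
    eligibility_check,
    eligibility_from_metadata,
    feature_counts,
    monopole_volume,
    shape_quadrupole,
)

from conftest import make_conformer, random_rigid

CFG = DEFAULT_CONFIG.scoring
R = CFG.atom_radius
SPHERE = 4.0 / 3.0 * np.pi * R**3
KAPPA = kappa_from_radius(R, CFG.amplitude)
# product overlap of two coincident calibrated Gaussians
PAIR_PRODUCT_AT_ZERO = CFG.amplitude**2 * (np.pi / (2 * KAPPA)) ** 1.5


class TestMonopoleVolume:
    def test_single_atom_equals_hard_sphere(self):
        conf = make_conformer(1, [[0, 0, 0]])
        assert monopole_volume(conf) == pytest.approx(SPHERE, rel=1e-12)

    def test_far_separated_atoms_add(self):
        conf = make_conformer(1, [[0, 0, 0], [1e6, 0, 0]])
        assert monopole_volume(conf) == pytest.approx(2 * SPHERE, rel=1e-12)

    def test_coincident_atoms_subtract_product_overlap(self):
        conf = make_conformer(1, [[0, 0, 0], [0, 0, 0]])
        assert monopole_volume(conf) == pytest.approx(2 * SPHERE - PAIR_PRODUCT_AT_ZERO, rel=1e-12)

    def test_empty_conformer_rejected(self):
        with pytest.raises(ValueError, match="no atoms"):
            Conformer(cid=1, atoms=[])

    def test_rigid_motion_invariance(self, population, rng):
        conf = population[0]
        v0 = monopole_volume(conf)
        for _ in range(100):
            t = random_rigid(rng)
            moved = conf.transformed(t.rotation, t.translation)
            assert monopole_volume(moved) == pytest.approx(v0, rel=1e-9)

    def test_far_fragments_additive(self, population):
        a, b = population[0], population[1]
        shifted = [Atom(x.element, x.position + np.array([500.0, 0, 0]), x.radius)
                   for x in b.atoms]
        merged = Conformer(1, list(a.atoms) + shifted)
        assert monopole_volume(merged) == pytest.approx(
            monopole_volume(a) + monopole_volume(b), rel=1e-9
        )


def _grid_volume(conf, spacing=0.1):
    """Quadrature of the first-order inclusion-exclusion integrand."""
    pos = conf.coords()
    kap = np.full(conf.n_atoms, KAPPA)
    grid, cell = bounding_grid(pos, spacing)
    per_atom = np.stack(
        [grid_density(pos[i : i + 1], kap[i : i + 1], CFG.amplitude, grid) for i in range(len(pos))]
    )
    total = per_atom.sum(axis=0)
    pair_sum = (total**2 - (per_atom**2).sum(axis=0)) / 2.0
    return float(np.sum(total - pair_sum) * cell)


def _grid_quadrupole(conf, spacing=0.1):
    pos = conf.coords()
    kap = np.full(conf.n_atoms, KAPPA)
    grid, cell = bounding_grid(pos, spacing)
    rho = grid_density(pos, kap, CFG.amplitude, grid)
    mass = rho.sum() * cell
    centroid = (rho[:, None] * grid).sum(axis=0) * cell / mass
    d = grid - centroid
    m = np.einsum("i,ij,ik->jk", rho, d, d) * cell
    return np.sort(np.linalg.eigvalsh(m))[::-1]


class TestShapeQuadrupole:
    def test_single_atom_isotropic(self):
        q = shape_quadrupole(make_conformer(1, [[0, 0, 0]]))
        assert q[0] == pytest.approx(q[1], rel=1e-12) == pytest.approx(q[2], rel=1e-12)

    def test_frame_invariance(self, population, rng):
        conf = population[2]
        q0 = np.array(shape_quadrupole(conf))
        for _ in range(25):
            t = random_rigid(rng)
            q = np.array(shape_quadrupole(conf.transformed(t.rotation, t.translation)))
            assert np.allclose(q, q0, rtol=1e-9, atol=1e-9)

    def test_linear_chain_ordering_and_quadrature(self):
        conf = make_conformer(1, [[0, 0, 0], [1.54, 0, 0], [3.08, 0, 0]])
        qx, qy, qz = shape_quadrupole(conf)
        assert qx > qy
        assert qy == pytest.approx(qz, rel=1e-9)
        ref = _grid_quadrupole(conf)
        assert np.allclose([qx, qy, qz], ref, rtol=0.01)

    def test_sorted_descending(self, population):
        for conf in population[:5]:
            qx, qy, qz = shape_quadrupole(conf)
            assert qx >= qy >= qz >= 0


def test_descriptors_match_grid_quadrature(small_conformers):
    """Analytic volume and quadrupole agree with 0.1 A quadrature within 1%."""
    for conf in small_conformers[:4]:
        assert monopole_volume(conf) == pytest.approx(_grid_volume(conf), rel=0.01)
        assert np.allclose(shape_quadrupole(conf), _grid_quadrupole(conf), rtol=0.01)


class TestEligibility:
    def test_boundary_values_pass(self):
        positions = np.arange(50)[:, None] * [2.5, 0, 0]
        conf = make_conformer(1, positions)
        ok, reasons = eligibility_check(conf, n_components=1, rotor_count=15, undefined_stereo=5)
        assert ok and reasons == []

    def test_too_many_heavy_atoms(self):
        ok, reasons = eligibility_from_metadata(n_heavy=51, elements=["C"])
        assert not ok
        assert "too many heavy atoms" in reasons

    def test_non_organic_element(self):
        ok, reasons = eligibility_from_metadata(n_heavy=10, elements=["C", "Si"])
        assert not ok
        assert any("non-organic" in r for r in reasons)

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            ({"rotor_count": 16}, "too many effective rotors"),
            ({"undefined_stereo": 6}, "too many undefined stereocenters"),
            ({"n_components": 2}, "multiple covalent components"),
        ],
    )
    def test_each_rule_reported(self, kwargs, expected):
        ok, reasons = eligibility_from_metadata(n_heavy=10, elements=["C"], **kwargs)
        assert not ok and expected in reasons

    def test_all_violations_enumerated(self):
        ok, reasons = eligibility_from_metadata(
            n_heavy=60, elements=["C", "Si"], n_components=2, rotor_count=20, undefined_stereo=9
        )
        assert not ok and len(reasons) == 5


class TestFeatureCounts:
    def test_counts_by_type(self):
        conf = make_conformer(
            1,
            [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]],
            features=[("acceptor", (1,)), ("acceptor", (2,)), ("ring", (1, 2, 3))],
        )
        counts = feature_counts(conf)
        assert counts["acceptor"] == 2
        assert counts["ring"] == 1
        assert counts["donor"] == counts["anion"] == counts["cation"] == counts["hydrophobe"] == 0
        assert counts["total"] == 3

    def test_no_features(self):
        counts = feature_counts(make_conformer(1, [[0, 0, 0]]))
        assert counts["total"] == 0 and all(v == 0 for v in counts.values())

    def test_feature_centroid_of_members(self):
        conf = make_conformer(
            1, [[0, 0, 0], [2.0, 0, 0]], features=[("ring", (1, 2))]
        )
        assert np.allclose(conf.features[0].position, [1.0, 0, 0])

    def test_hydrogens_dropped(self):
        conf = Conformer(
            1, [Atom("C", [0, 0, 0]), Atom("H", [1, 0, 0]), Atom("O", [2, 0, 0])]
        )
        assert conf.n_atoms == 2
        assert {a.element for a in conf.atoms} == {"C", "O"}

    def test_bad_feature_type_rejected(self):
        with pytest.raises(ValueError, match="feature type"):
            FeaturePoint("metal", [0, 0, 0])
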