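"""Conformer generation, inertial-frame normalization and 3D superposition."""

import math

import numpy as np
import pytest

from chempred.superposer import (
    Conformer,
    generate_conformers,
    inertial_frame,
    score_conformer_sets,
    similarity_3d,
    superpose,
)
from oracles import brute_force_superpose


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def test_methane_is_rigid_and_cap_respected(mk_compound):
    methane = mk_compound("C")
    assert len(generate_conformers(methane, 100)) == 1
    butane = mk_compound("CCCC")
    confs = generate_conformers(butane, 100)
    assert len(confs) >= 2  # anti + gauche at least
    assert len(generate_conformers(butane, 1)) == 1
    energies = [c.energy for c in confs]
    assert energies == sorted(energies)


def test_conformers_deterministic_under_seed(mk_compound):
    comp = mk_compound("CCOc1ccc2nc(N)cc(F)c2c1")
    a = generate_conformers(comp, 5, seed=11)
    b = generate_conformers(comp, 5, seed=11)
    assert len(a) == len(b)
    for ca, cb in zip(a, b):
        assert np.allclose(ca.coords, cb.coords)


def test_inertial_frame_centers_single_atom():
    conf = Conformer("x", ["C"], np.array([[5.0, 5.0, 5.0]]))
    framed = inertial_frame(conf)
    assert np.allclose(framed.coords, 0.0)


def test_inertial_frame_aligns_linear_molecule_on_z():
    # three collinear atoms along an arbitrary direction
    direction = np.array([1.0, 2.0, 3.0]) / math.sqrt(14)
    coords = np.outer([-1.2, 0.0, 1.2], direction) + 7.5
    framed = inertial_frame(Conformer("co2", ["O", "C", "O"], coords))
    assert np.allclose(framed.coords[:, :2], 0.0, atol=1e-9)
    assert not np.allclose(framed.coords[:, 2], 0.0)


def test_superpose_identity_is_perfect(mk_compound):
    conf = inertial_frame(generate_conformers(mk_compound("c1ccc2ccccc2c1"), 1)[0])
    res = superpose(conf, conf)
    assert res.n_superposed == len(conf.coords)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert res.score == pytest.approx(1.0)


def test_superpose_beyond_threshold_maps_nothing():
    a = inertial_frame(Conformer("a", ["C", "C"], [[-5.0, 0, 0], [5.0, 0, 0]]))
    b = inertial_frame(Conformer("b", ["C", "C"], [[-1.0, 0, 0], [1.0, 0, 0]]))
    res = superpose(a, b, max_pair_distance=1.0)
    assert res.n_superposed == 0
    assert res.score == 0.0
    assert not res.mapped


def test_optimal_mapping_matches_brute_force_on_toys():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n, m = rng.integers(2, 7), rng.integers(2, 7)
        a = inertial_frame(Conformer("a", ["C"] * n, rng.normal(0, 1.5, (n, 3))))
        b = inertial_frame(Conformer("b", ["C"] * m, rng.normal(0, 1.5, (m, 3))))
        res = superpose(a, b, mapping="optimal")
        n_exp, rmsd_exp = brute_force_superpose(a, b, 1.0)
        assert res.n_superposed == n_exp
        assert res.rmsd == pytest.approx(rmsd_exp, abs=1e-9)


def test_element_matching_flag_restricts_pairs():
    a = inertial_frame(Conformer("a", ["C", "N"], [[-0.7, 0, 0], [0.7, 0, 0]]))
    b = inertial_frame(Conformer("b", ["N", "C"], [[-0.7, 0, 0], [0.7, 0, 0]]))
    loose = superpose(a, b)
    strict = superpose(a, b, match_elements=True)
    assert loose.n_superposed == 2
    assert strict.n_superposed <= loose.n_superposed


def test_similarity_3d_self_and_rotation_invariance(mk_compound):
    comp = mk_compound("CCOc1ccc2nc(N)cc(F)c2c1")
    assert similarity_3d(comp, comp, max_conformers=3) == pytest.approx(1.0)
    confs = [inertial_frame(c) for c in generate_conformers(comp, 3)]
    base = score_conformer_sets(confs, confs)
    rng = np.random.default_rng(3)
    for _ in range(5):
        rot = _random_rotation(rng)
        shift = rng.normal(0, 10, 3)
        moved = [
            Conformer(c.parent_id, c.atom_elements, c.coords @ rot.T + shift)
            for c in confs
        ]
        assert score_conformer_sets(moved, confs) == pytest.approx(base, abs=1e-6)


def test_symmetric_top_self_similarity_still_exact(mk_compound):
    # benzene has a degenerate inertia tensor (two equal in-plane moments)
    benzene = mk_compound("c1ccccc1")
    assert similarity_3d(benzene, benzene, max_conformers=2) == pytest.approx(1.0)


def test_planar_vs_chair_geometry_scores_below_one(mk_compound):
    benzene = mk_compound("c1ccccc1")
    cyclohexane = mk_compound("C1CCCCC1")
    score = similarity_3d(benzene, cyclohexane, max_conformers=3)
    assert 0.0 < score < 1.0


def test_similarity_3d_symmetry(mk_compound):
    a = mk_compound("Cc1ccccc1")
    b = mk_compound("CCc1ccncc1")
    ab = similarity_3d(a, b, max_conformers=3)
    ba = similarity_3d(b, a, max_conformers=3)
    assert ab == pytest.approx(ba, abs=1e-6)
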