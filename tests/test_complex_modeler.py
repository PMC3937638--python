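"""Restraint scoring, clash detection, annealing and ensemble filtering."""

import math

import numpy as np
import pytest

from linkgag.complex_modeler import (
    AnnealConfig,
    DistanceRestraint,
    ModelingError,
    Receptor,
    StackingRestraint,
    anneal_model,
    clash_score,
    default_restraints,
    filter_model,
    generate_and_filter_ensemble,
    load_receptor,
    load_receptor_models,
    restraint_energy,
    ring_contacts,
    validate_receptor,
)
from linkgag.glycan_builder import build_conformer, parse_sequence
from linkgag.synthetic_data import reference_torsions, write_receptor_fixture
from linkgag.torsion_maps import TorsionMap

FAST = AnnealConfig(n_steps=250, polish_maxfev=800)


def flat_maps():
    z = np.zeros((36, 36))
    return {l: TorsionMap(linkage=l, grid=z.copy()) for l in ("beta1,3", "beta1,4")}


def translated(conf, vec):
    return conf.transformed(np.eye(3), np.asarray(vec, dtype=float))


# ---------------------------------------------------------------------------
# receptor I/O


def test_fixture_receptor_has_all_anchor_atoms(receptor, restraints):
    validate_receptor(receptor, restraints)  # must not raise
    for res in (45, 63, 11, 59, 78, 81, 61, 47, 68):
        assert res in receptor.res_nums


def test_multi_model_fixture_file(tmp_path, restraints):
    path = tmp_path / "fixture.pdb"
    write_receptor_fixture(path, n_models=20)
    members = load_receptor_models(path, restraints=restraints)
    assert len(members) == 20
    with pytest.raises(ModelingError, match="out of range"):
        load_receptor(path, model_index=20)
    one = load_receptor(path, model_index=3, restraints=restraints)
    assert np.allclose(one.coords, members[3].coords)


def test_missing_restraint_atoms_reported():
    rec = Receptor(["CA"], ["GLY"], [1], np.zeros((1, 3)), ["C"])
    with pytest.raises(ModelingError, match="45/CG"):
        validate_receptor(rec, default_restraints())


def test_receptor_coordinates_are_immutable(receptor):
    with pytest.raises(ValueError):
        receptor.coords[0, 0] = 99.0


# ---------------------------------------------------------------------------
# restraints


def test_reference_pose_has_zero_restraint_energy(receptor, reference_pose, restraints):
    assert restraint_energy(receptor, reference_pose, restraints) == 0.0


def test_stacking_closed_form(receptor, reference_pose):
    """At 5.0 A centroid distance with parallel planes, k=1: (5.0-3.5)^2."""
    stack = StackingRestraint(receptor_res=45, receptor_ring_atoms=(
        "CG", "ND1", "CE1", "NE2", "CD2"), ligand_ring=1, k=1.0)
    ring = receptor.ring_atoms(45, stack.receptor_ring_atoms)
    normal = reference_pose.ring_normal(1)
    # move the ligand 1.5 A further along the stacking normal
    direction = reference_pose.ring_centroid(1) - ring.mean(axis=0)
    direction /= np.linalg.norm(direction)
    moved = translated(reference_pose, 1.5 * direction)
    assert stack.energy(receptor, moved) == pytest.approx(2.25, abs=1e-9)


def test_distance_restraint_closed_form(receptor, reference_pose):
    rst = DistanceRestraint(receptor_res=61, receptor_atom="CD1",
                            ligand_ring=4, ligand_atom="C8", bound=4.5, k=1.0)
    assert rst.energy(receptor, reference_pose) == 0.0
    p = receptor.atom(61, "CD1")
    q = reference_pose.atom(3, "C8")
    d0 = np.linalg.norm(p - q)
    away = (q - p) / d0
    moved = translated(reference_pose, (6.0 - d0) * away)  # now exactly 6.0 A
    assert rst.energy(receptor, moved) == pytest.approx((6.0 - 4.5) ** 2, abs=1e-9)


def test_restraint_energy_matches_independent_oracle(receptor, reference_pose, restraints):
    """Random rigid placements scored identically by a from-scratch oracle."""

    def oracle(conf):
        total = 0.0
        for rst in restraints:
            if isinstance(rst, StackingRestraint):
                ring = receptor.ring_atoms(rst.receptor_res, rst.receptor_ring_atoms)
                rc = ring.mean(axis=0)
                c = ring - rc
                rn = np.linalg.svd(c)[2][2]
                lring = conf.ring_coords(rst.ligand_ring)
                lc = lring.mean(axis=0)
                ln = np.linalg.svd(lring - lc)[2][2]
                d = np.linalg.norm(lc - rc)
                ang = math.degrees(math.acos(min(1.0, abs(float(np.dot(rn, ln))))))
                total += rst.k * max(0.0, d - rst.target) ** 2
                total += rst.k_angle * max(0.0, math.radians(ang - rst.max_angle_deg)) ** 2
            else:
                d = np.linalg.norm(receptor.atom(rst.receptor_res, rst.receptor_atom)
                                   - conf.atom(rst.ligand_ring - 1, rst.ligand_atom))
                total += rst.k * max(0.0, d - rst.bound) ** 2
        return total

    rng = np.random.default_rng(17)
    for _ in range(25):
        rotvec = rng.normal(0, 0.5, 3)
        from scipy.spatial.transform import Rotation
        r = Rotation.from_rotvec(rotvec).as_matrix()
        t = rng.normal(0, 5.0, 3)
        conf = reference_pose.transformed(r, t)
        assert restraint_energy(receptor, conf, restraints) == pytest.approx(
            oracle(conf), abs=1e-9
        )


# ---------------------------------------------------------------------------
# clashes and contacts


def test_far_ligand_has_no_clashes_or_contacts(receptor, reference_pose, restraints):
    far = translated(reference_pose, [50.0, 0.0, 0.0])
    count, penalty = clash_score(receptor, far, restraints=restraints)
    assert count == 0 and penalty == 0.0
    flags, n = ring_contacts(receptor, far)
    assert n == 0 and not any(flags)


def test_clash_counts_match_brute_force_oracle(receptor, reference_pose, restraints):
    rng = np.random.default_rng(23)
    rr = receptor.radii
    lr = reference_pose.radii
    from linkgag.complex_modeler import _restrained_pairs

    exclude = _restrained_pairs(receptor, reference_pose, restraints)
    scale = 0.7
    for _ in range(100):
        conf = translated(reference_pose, rng.normal(0, 4.0, 3))
        count, _ = clash_score(receptor, conf, scale=scale, restraints=restraints)
        brute = 0
        for i in range(len(receptor.coords)):
            for j in range(len(conf.coords)):
                if (i, j) in exclude:
                    continue
                d = np.linalg.norm(receptor.coords[i] - conf.coords[j])
                if d < scale * (rr[i] + lr[j]):
                    brute += 1
        assert count == brute


def test_contact_count_monotone_in_cutoff(receptor, reference_pose):
    counts = [ring_contacts(receptor, reference_pose, cutoff=c)[1]
              for c in np.arange(3.0, 6.01, 0.5)]
    assert counts == sorted(counts)


def test_reference_pose_contacts_seven_of_eight(receptor, reference_pose):
    flags, n = ring_contacts(receptor, reference_pose, cutoff=4.0)
    assert n == 7
    assert flags[7] is False  # the reducing-end ring hangs free


# ---------------------------------------------------------------------------
# annealing


def test_anneal_is_seed_deterministic(receptor, restraints, maps):
    seq = parse_sequence("HA8^AN")
    m1 = anneal_model(receptor, seq, restraints, maps, seed=42, config=FAST)
    m2 = anneal_model(receptor, seq, restraints, maps, seed=42, config=FAST)
    assert np.array_equal(m1.ligand.coords, m2.ligand.coords)
    assert m1.scores == m2.scores


def test_anneal_leaves_receptor_untouched(receptor, restraints, maps):
    before = receptor.checksum()
    seq = parse_sequence("HA8^AN")
    model = anneal_model(receptor, seq, restraints, maps, seed=1, config=FAST)
    filter_model(model, maps)
    ring_contacts(receptor, model.ligand)
    assert receptor.checksum() == before


def test_empty_restraints_flat_maps_reduce_to_clash_term(receptor):
    seq = parse_sequence("HA4^AN")
    model = anneal_model(receptor, seq, [], flat_maps(), seed=0, config=FAST)
    assert model.scores["restraint"] == 0.0
    assert model.scores["map"] == 0.0
    assert model.total_score == model.scores["clash"]


def test_anneal_satisfies_fixture_restraints(receptor, restraints, maps):
    seq = parse_sequence("HA8^AN")
    model = anneal_model(receptor, seq, restraints, maps, seed=5, config=FAST)
    assert model.converged
    assert model.scores["restraint"] < 0.1
    assert model.clash_count == 0


# ---------------------------------------------------------------------------
# ensemble filter


def test_zero_models_requested(receptor, restraints, maps):
    accepted, report = generate_and_filter_ensemble(
        [receptor], parse_sequence("HA8^AN"), restraints, maps, n_models=0)
    assert accepted == [] and report == []


def test_small_ensemble_accepted_and_rejection_report(receptor, restraints, maps):
    seq = parse_sequence("HA8^AN")
    accepted, report = generate_and_filter_ensemble(
        [receptor], seq, restraints, maps, n_models=3, base_seed=100,
        config=FAST)
    assert len(report) == 3
    assert {row["seed"] for row in report} == {100, 101, 102}
    for model in accepted:
        assert model.clash_count == 0
        assert model.scores["restraint"] < 0.1
        assert model.rejection_reason is None
    # disabling the map filter (infinite cutoff) can only grow the accepted set
    accepted_inf, _ = generate_and_filter_ensemble(
        [receptor], seq, restraints, maps, n_models=3, base_seed=100,
        cutoff=float("inf"), config=FAST)
    assert len(accepted_inf) >= len(accepted)


def test_filter_marks_unfavored_torsions(receptor, reference_pose, restraints, maps):
    from linkgag.complex_modeler import ComplexModel

    seq = reference_pose.sequence
    bad = build_conformer(seq, [(100.0, 100.0)] + reference_torsions(seq)[1:])
    model = ComplexModel(receptor=receptor, ligand=translated(bad, [50, 0, 0]),
                         scores={"restraint": 0.0, "clash": 0.0, "map": 0.0},
                         clash_count=0, converged=True)
    out = filter_model(model, maps)
    assert not out.accept
    assert out.rejection_reason == "unfavored-torsion"
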