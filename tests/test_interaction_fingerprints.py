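"""Typed residue contacts, fingerprint normalization, group contrasts."""

import numpy as np
import pandas as pd
import pytest

from cpfatools.interaction_fingerprints import (
    ACCEPTOR_ATOM_NAMES,
    AROMATIC_RING_ATOMS,
    CHARGED_RESIDUES,
    DONOR_ATOM_NAMES,
    HYDROPHOBIC_RESIDUES,
    LigandPose,
    ReceptorStructure,
    Residue,
    ResidueAtom,
    compare_fingerprints,
    fingerprint,
    residue_contacts,
)
from cpfatools.synthetic_data import SynthConfig, gen_pocket, gen_pose_cloud


def atom(name, element, xyz, backbone=False):
    return ResidueAtom(name, element, np.asarray(xyz, dtype=float), backbone)


def pose_at(points, elements=None, lipid="L", pose_id=0):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if elements is None:
        elements = ["C"] * len(pts)
    return LigandPose(lipid=lipid, pose_id=pose_id, elements=elements, coords=pts)


def test_cutoff_boundary_inclusive_at_4A():
    res = Residue("ALA", 1, atoms=[atom("CB", "C", [3.9, 0, 0])])
    rec = ReceptorStructure([res])
    hit = residue_contacts(pose_at([[0, 0, 0]]), rec, cutoff=4.0)
    assert hit["Ala1"]["contact"] == 1

    res_far = Residue("ALA", 1, atoms=[atom("CB", "C", [4.1, 0, 0])])
    assert residue_contacts(pose_at([[0, 0, 0]]),
                            ReceptorStructure([res_far]), 4.0) == {}

    res_exact = Residue("ALA", 1, atoms=[atom("CB", "C", [4.0, 0, 0])])
    assert "Ala1" in residue_contacts(pose_at([[0, 0, 0]]),
                                      ReceptorStructure([res_exact]), 4.0)


def test_empty_receptor_and_missing_coords():
    assert residue_contacts(pose_at([[0, 0, 0]]), ReceptorStructure([]), 4.0) == {}
    with pytest.raises(ValueError):
        residue_contacts(
            LigandPose("L", 0, [], np.empty((0, 3))), ReceptorStructure([]), 4.0
        )


def brute_force_typed_counts(pose, receptor, cutoff):
    """Independent all-pairs scan with the typing rules written out."""
    out = {}
    for res in receptor.residues:
        counts = {t: 0 for t in (
            "contact", "backbone", "side_chain", "polar", "hydrophobic",
            "acceptor", "donor", "charged", "aromatic")}
        any_hit = False
        for a in res.atoms:
            for lig_el, lig_xyz in zip(pose.elements, pose.coords):
                d = float(np.sqrt(np.sum((lig_xyz - a.coords) ** 2)))
                if d > cutoff:
                    continue
                any_hit = True
                counts["contact"] += 1
                counts["backbone" if a.is_backbone else "side_chain"] += 1
                if a.element in "NOS" or lig_el.upper() in "NOS":
                    counts["polar"] += 1
                if (a.element in "CS" and lig_el.upper() in "CS"
                        and res.resname in HYDROPHOBIC_RESIDUES):
                    counts["hydrophobic"] += 1
                if lig_el.upper() in "NO":
                    if a.name in ACCEPTOR_ATOM_NAMES:
                        counts["acceptor"] += 1
                    if a.name in DONOR_ATOM_NAMES:
                        counts["donor"] += 1
                if (res.resname in CHARGED_RESIDUES and not a.is_backbone
                        and a.element in "NO"):
                    counts["charged"] += 1
                if a.name in AROMATIC_RING_ATOMS.get(res.resname, ()):
                    counts["aromatic"] += 1
        if any_hit:
            out[res.key] = counts
    return out


def test_typed_counts_match_brute_force_on_synthetic_pocket(rng):
    cfg = SynthConfig(seed=21, poses_per_lipid=5, tail_carbons=6)
    cloud = gen_pose_cloud(cfg)
    pocket = gen_pocket(cfg, offset=4.0)
    for pose in cloud.atoms[:40]:
        assert residue_contacts(pose, pocket, 4.0) == brute_force_typed_counts(
            pose, pocket, 4.0
        )


def test_fingerprint_normalization_by_conformers():
    res = Residue("ALA", 1, atoms=[atom("CB", "C", [1.0, 0, 0])])
    rec = ReceptorStructure([res])
    poses = [pose_at([[0, 0, 0]], lipid="L", pose_id=0)]
    fp = fingerprint(poses, rec, {"L": 2}, count_mode="union")
    assert fp.loc["L", "Ala1"] == pytest.approx(0.5)


def test_fingerprint_doubles_with_duplicated_poses():
    res = Residue("ALA", 1, atoms=[atom("CB", "C", [1.0, 0, 0])])
    rec = ReceptorStructure([res])
    poses = [pose_at([[0, 0, 0]], pose_id=i) for i in range(2)]
    one = fingerprint(poses[:1], rec, {"L": 4})
    two = fingerprint(poses, rec, {"L": 4})
    assert np.allclose(two.to_numpy(), 2.0 * one.to_numpy())


def test_fingerprint_unknown_lipid_rejected():
    rec = ReceptorStructure([Residue("ALA", 1, atoms=[atom("CB", "C", [0, 0, 0])])])
    with pytest.raises(ValueError):
        fingerprint([pose_at([[0, 0, 0]], lipid="X")], rec, {"L": 3})


def test_fingerprint_rigid_motion_invariance(rng):
    cfg = SynthConfig(seed=5, poses_per_lipid=4, tail_carbons=5)
    cloud = gen_pose_cloud(cfg)
    pocket = gen_pocket(cfg, offset=4.0)
    counts = {lip: 4 for lip, _ in cfg.lipids}
    base = fingerprint(cloud.atoms, pocket, counts)

    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] = -rot[:, 0]
    shift = np.array([7.0, -3.0, 11.0])
    moved_poses = [
        LigandPose(p.lipid, p.pose_id, p.elements, p.coords @ rot.T + shift)
        for p in cloud.atoms
    ]
    moved_rec = ReceptorStructure(
        [
            Residue(r.resname, r.resnum, r.chain,
                    [ResidueAtom(a.name, a.element, a.coords @ rot.T + shift,
                                 a.is_backbone) for a in r.atoms])
            for r in pocket.residues
        ]
    )
    moved = fingerprint(moved_poses, moved_rec, counts)
    assert np.allclose(base.to_numpy(), moved.to_numpy(), atol=1e-9)


def test_cutoff_monotonicity(rng):
    cfg = SynthConfig(seed=8, poses_per_lipid=4, tail_carbons=5)
    cloud = gen_pose_cloud(cfg)
    pocket = gen_pocket(cfg, offset=4.0)
    counts = {lip: 4 for lip, _ in cfg.lipids}
    small = fingerprint(cloud.atoms, pocket, counts, cutoff=3.5)
    large = fingerprint(cloud.atoms, pocket, counts, cutoff=5.0)
    assert np.all(large.to_numpy() >= small.to_numpy() - 1e-12)


def test_removing_residue_removes_exactly_its_column():
    cfg = SynthConfig(seed=9, poses_per_lipid=3, tail_carbons=4)
    cloud = gen_pose_cloud(cfg)
    pocket = gen_pocket(cfg, offset=4.0)
    counts = {lip: 3 for lip, _ in cfg.lipids}
    full = fingerprint(cloud.atoms, pocket, counts)
    smaller = ReceptorStructure(pocket.residues[1:])
    reduced = fingerprint(cloud.atoms, smaller, counts)
    dropped = pocket.residues[0].key
    assert dropped not in reduced.columns
    assert np.allclose(
        full.drop(columns=dropped).to_numpy(), reduced.to_numpy(), atol=1e-12
    )


def test_contrast_identifies_planted_proximal_vs_distal():
    """Cluster-0-only vs cluster-1-only lipids must be discriminated by the
    residues planted next to each cluster center."""
    cfg = SynthConfig(
        seed=30, poses_per_lipid=40, tail_carbons=4,
        lipids=(("deep", "CpFA"), ("shallow", "SFA")),
        class_cluster_weights={"CpFA": (1.0, 0.0), "SFA": (0.0, 1.0)},
    )
    cloud = gen_pose_cloud(cfg)
    pocket = gen_pocket(cfg, offset=4.0)
    counts = {"deep": 40, "shallow": 40}
    fp = fingerprint(cloud.atoms, pocket, counts)
    contrast = compare_fingerprints(fp, {"deep": "g1", "shallow": "g2"})
    proximal = {r.key for r in pocket.residues[:3]}
    # deep lipids sit at cluster 0 -> proximal residues dominate its mean
    assert fp.loc["deep", sorted(proximal)].sum() > fp.loc[
        "deep", [r.key for r in pocket.residues[3:]]
    ].sum()
    assert (contrast["difference"] > 0).any()


def test_identical_groups_have_zero_difference():
    cfg = SynthConfig(seed=4, poses_per_lipid=3, tail_carbons=3)
    cloud = gen_pose_cloud(cfg)
    pocket = gen_pocket(cfg, offset=4.0)
    counts = {lip: 3 for lip, _ in cfg.lipids}
    fp = fingerprint(cloud.atoms, pocket, counts)
    doubled = fp.copy()
    doubled.index = [f"{i}_copy" for i in fp.index]
    both = pd.concat([fp, doubled])
    grouping = {**{i: "a" for i in fp.index},
                **{i: "b" for i in doubled.index}}
    contrast = compare_fingerprints(both, grouping)
    assert np.allclose(contrast["difference"], 0.0, atol=1e-12)
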