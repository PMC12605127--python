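"""Shape descriptors: analytic fixtures, independent oracles, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from cpfatools.conformer_engine import Conformer
from cpfatools.shape_descriptors import (
    DegenerateGeometryError,
    align_conformer,
    compute_shape_records,
    convex_hull_area,
    end_to_end,
    pooled_pca,
    radius_of_gyration,
    summarize,
    summarize_and_compare,
)


def make_conformer(carbons, ring=None):
    carbons = np.asarray(carbons, dtype=float)
    return Conformer(
        lipid="test", carbons=carbons,
        oxygens=np.zeros((2, 3)), ring_methylene=ring,
    )


def random_rigid_motion(rng):
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] = -rot[:, 0]
    return rot, rng.normal(scale=10.0, size=3)


def test_end_to_end_analytic_cases():
    assert end_to_end(make_conformer([[0, 0, 0], [3, 4, 0]])) == 5.0
    assert end_to_end(make_conformer([[1, 2, 3], [9, 9, 9], [1, 2, 3]])) == 0.0
    with pytest.raises(ValueError):
        end_to_end(make_conformer([[0, 0, 0]]))


def test_end_to_end_excludes_ring_methylene():
    conf = make_conformer([[0, 0, 0], [3, 4, 0]], ring=np.array([100.0, 0, 0]))
    assert end_to_end(conf) == 5.0


def test_radius_of_gyration_analytic_cases():
    assert radius_of_gyration(make_conformer([[2, 2, 2], [2, 2, 2]])) == 0.0
    assert radius_of_gyration(make_conformer([[0, 0, 0], [2, 0, 0]])) == 1.0
    square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
    assert radius_of_gyration(make_conformer(square)) == pytest.approx(
        math.sqrt(0.5), abs=1e-12
    )


def test_radius_of_gyration_includes_ring_methylene():
    conf = make_conformer([[0, 0, 0], [2, 0, 0]], ring=np.array([1.0, 3.0, 0.0]))
    pts = np.array([[0, 0, 0], [2, 0, 0], [1, 3, 0]], float)
    centered = pts - pts.mean(axis=0)
    expect = math.sqrt(np.mean(np.sum(centered**2, axis=1)))
    assert radius_of_gyration(conf) == pytest.approx(expect, abs=1e-12)


def test_hull_area_analytic_fixtures():
    tetra = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
    assert convex_hull_area(np.array(tetra, float)) == pytest.approx(
        1.5 + math.sqrt(3) / 2, abs=1e-8
    )
    cube = [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)]
    assert convex_hull_area(np.array(cube, float)) == pytest.approx(24.0, abs=1e-8)
    square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
    assert convex_hull_area(np.array(square, float)) == pytest.approx(2.0, abs=1e-8)
    with pytest.raises(DegenerateGeometryError):
        convex_hull_area(np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0]], float))


def brute_force_hull_area(pts):
    """Sum of triangle areas over all point triplets that form a hull facet
    (all remaining points strictly on one side)."""
    n = len(pts)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                normal = np.cross(pts[j] - pts[i], pts[k] - pts[i])
                norm = np.linalg.norm(normal)
                if norm < 1e-12:
                    continue
                side = (pts - pts[i]) @ normal
                others = np.delete(side, [i, j, k])
                if np.all(others > 1e-9) or np.all(others < -1e-9):
                    total += norm / 2.0
    return total


def test_hull_area_matches_brute_force_on_random_clouds(rng):
    for _ in range(100):
        pts = rng.normal(size=(20, 3))
        assert convex_hull_area(pts) == pytest.approx(
            brute_force_hull_area(pts), abs=1e-8
        )


def test_descriptors_invariant_under_rigid_motion(rng):
    for _ in range(20):
        pts = rng.normal(size=(18, 3))
        rot, shift = random_rigid_motion(rng)
        orig = make_conformer(pts)
        moved = make_conformer(pts @ rot.T + shift)
        assert end_to_end(moved) == pytest.approx(end_to_end(orig), abs=1e-9)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(orig), abs=1e-9
        )
        assert convex_hull_area(moved.all_carbons) == pytest.approx(
            convex_hull_area(orig.all_carbons), abs=1e-7
        )


def test_hull_area_non_decreasing_with_outside_point(rng):
    pts = rng.normal(size=(15, 3))
    base = convex_hull_area(pts)
    outside = pts.mean(axis=0) + np.array([50.0, 0.0, 0.0])
    assert convex_hull_area(np.vstack([pts, outside])) >= base


def test_pooled_pca_rank2_input_and_symmetry(c18_ensembles):
    pca = pooled_pca(c18_ensembles)
    vf = pca.variance_fractions
    assert np.all(vf >= 0) and vf.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(vf) <= 1e-12)  # non-increasing
    assert len(pca.scores) == len(pca.labels)


def test_pooled_pca_planar_input_captures_all_variance():
    flat = [
        make_conformer(np.column_stack([np.arange(6.0), (np.arange(6.0) % 2),
                                        np.zeros(6)]) + i)
        for i in range(4)
    ]
    from cpfatools.conformer_engine import ConformerEnsemble

    ens = [ConformerEnsemble("flat", flat, seed=0, requested=4)]
    pca = pooled_pca(ens, mode="head_frame")
    assert pca.variance_fractions[:2].sum() == pytest.approx(1.0, abs=1e-9)


def brute_force_two_way_anova(df):
    """Textbook balanced two-factor additive ANOVA sums of squares."""
    grand = df["y"].mean()
    n = len(df)
    ss_a = sum(
        len(g) * (g["y"].mean() - grand) ** 2
        for _, g in df.groupby("lipid_class")
    )
    ss_b = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("position")
    )
    ss_tot = ((df["y"] - grand) ** 2).sum()
    df_a = df["lipid_class"].nunique() - 1
    df_b = df["position"].nunique() - 1
    df_e = n - 1 - df_a - df_b
    ss_e = ss_tot - ss_a - ss_b
    return (ss_a / df_a) / (ss_e / df_e), (ss_b / df_b) / (ss_e / df_e)


def test_anova_f_matches_textbook_oracle(rng):
    rows = []
    group_rows = []
    for cls, shift in (("A", 0.0), ("B", 1.0), ("C", 2.5)):
        for pos in (1, 2):
            group_rows.append(
                {"lipid": f"{cls}{pos}", "lipid_class": cls, "position": pos}
            )
            for rep in range(10):
                rows.append(
                    {"lipid": f"{cls}{pos}", "conformer_index": rep,
                     "d_ee": shift + 0.3 * pos + rng.normal(0, 1.0),
                     "r_g": 0.0, "hull_area": 0.0}
                )
    records = pd.DataFrame(rows)
    groups = pd.DataFrame(group_rows)
    res = summarize_and_compare(records, groups, descriptor="d_ee")
    merged = records.merge(groups, on="lipid").rename(columns={"d_ee": "y"})
    f_a, f_b = brute_force_two_way_anova(merged)
    anova = res["anova"]
    assert anova.loc["C(lipid_class)", "F"] == pytest.approx(f_a, abs=1e-8)
    assert anova.loc["C(position)", "F"] == pytest.approx(f_b, abs=1e-8)


def test_tukey_identical_vs_separated_groups(rng):
    def records_for(shifts):
        rows = []
        for cls, shift in shifts.items():
            for rep in range(15):
                rows.append(
                    {"lipid": cls, "conformer_index": rep,
                     "d_ee": shift + rng.normal(0, 1.0),
                     "r_g": 0.0, "hull_area": 0.0}
                )
        df = pd.DataFrame(rows)
        groups = pd.DataFrame(
            [{"lipid": cls, "lipid_class": cls, "position": 1}
             for cls in shifts]
        )
        return summarize_and_compare(df, groups)["tukey"]

    same = records_for({"A": 0.0, "B": 0.0, "C": 0.0})
    assert not same["reject"].astype(bool).any()
    far = records_for({"A": 0.0, "B": 10.0, "C": 20.0})
    assert far["reject"].astype(bool).all()


def test_summarize_counts_and_sd(c18_ensembles):
    records = compute_shape_records(c18_ensembles)
    summary = summarize(records)
    assert (summary["n_conformers"] > 0).all()
    assert (summary["d_ee_sd"] >= 0).all()
    assert set(summary["lipid"]) == set(records["lipid"])


def test_alignment_removes_rigid_motion(rng, c18_ensembles):
    conf = c18_ensembles[0].conformers[0]
    rot, shift = random_rigid_motion(rng)
    moved = Conformer(
        lipid=conf.lipid, carbons=conf.carbons @ rot.T + shift,
        oxygens=conf.oxygens @ rot.T + shift,
        ring_methylene=None,
    )
    a = align_conformer(conf)
    b = align_conformer(moved)
    assert np.allclose(a, b, atol=1e-8)
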