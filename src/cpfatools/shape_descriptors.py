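"""Per-conformer shape descriptors and ensemble statistics.

Three descriptors quantify how bent or compact a fatty-acid conformer is:

* **end-to-end distance** ``d_ee``: Euclidean distance between the two
  terminal backbone carbons (C1, the carboxyl carbon, and Cn).  For CpFAs
  the ring methylene is a side branch and is excluded;
* **radius of gyration** ``R_g``: RMS distance of all carbons (ring
  methylene included) from their centroid — lower means more compact;
* **convex-hull area**: surface area of the 3D convex hull of the carbon
  cloud, a proxy for conformational spread.  Coplanar conformers return
  the flattened hull (twice the polygon area); colinear inputs are
  degenerate and raise.

At the ensemble level the module pools rigidly aligned conformers for a
per-carbon PCA (how much 2D space the carbon cloud occupies) and runs a
two-factor ANOVA (lipid class x modification position) with Tukey HSD
post-hoc contrasts over per-conformer descriptor records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .conformer_engine import Conformer, ConformerEnsemble


@dataclass
class ShapeRecord:
    """Descriptors of one conformer."""

    lipid: str
    conformer_index: int
    d_ee: float
    r_g: float
    hull_area: float


class DegenerateGeometryError(ValueError):
    """Point set has no 3D (or planar) convex hull: colinear or too few."""


def end_to_end(conformer: Conformer) -> float:
    """Distance between the carboxyl carbon C1 and the last backbone carbon.

    The CpFA ring methylene is a branch off the backbone and does not count
    as a terminus.
    """
    carbons = conformer.carbons
    if len(carbons) < 2:
        raise ValueError("end_to_end requires at least 2 backbone carbons")
    return float(np.linalg.norm(carbons[-1] - carbons[0]))


def radius_of_gyration(conformer: Conformer) -> float:
    """RMS distance of all carbons (ring methylene included) from their centroid."""
    pts = conformer.all_carbons
    if len(pts) < 1:
        raise ValueError("radius_of_gyration requires at least 1 carbon")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def convex_hull_area(conformer_or_points) -> float:
    """Surface area of the 3D convex hull of the carbon coordinates.

    Coplanar point sets are legitimate (extended all-anti chains are nearly
    planar) and return the area of both faces of the flattened hull, i.e.
    twice the polygon area.  Colinear sets raise
    :class:`DegenerateGeometryError`.
    """
    if isinstance(conformer_or_points, Conformer):
        pts = conformer_or_points.all_carbons
    else:
        pts = np.asarray(conformer_or_points, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("convex hull needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # Flat in some direction: try the rank-2 (planar) fallback.
        centered = pts - pts.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        if len(s) < 2 or s[1] < 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError("colinear point set has no hull area")
        flat = centered @ vt[:2].T
        try:
            hull2 = ConvexHull(flat)
        except QhullError as exc:  # pragma: no cover - caught above
            raise DegenerateGeometryError(str(exc))
        return float(2.0 * hull2.volume)  # 2D "volume" is the polygon area
    return float(hull.area)


def compute_shape_records(ensembles: Sequence[ConformerEnsemble]) -> pd.DataFrame:
    """ShapeRecords for every conformer of every ensemble, as a DataFrame."""
    rows = []
    for ens in ensembles:
        for idx, conf in enumerate(ens.conformers):
            rows.append(
                {
                    "lipid": conf.lipid,
                    "conformer_index": idx,
                    "d_ee": end_to_end(conf),
                    "r_g": radius_of_gyration(conf),
                    "hull_area": convex_hull_area(conf),
                }
            )
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-lipid mean +/- SD of each descriptor and the conformer count."""
    g = records.groupby("lipid")
    out = g.agg(
        n_conformers=("conformer_index", "size"),
        d_ee_mean=("d_ee", "mean"),
        d_ee_sd=("d_ee", "std"),
        r_g_mean=("r_g", "mean"),
        r_g_sd=("r_g", "std"),
        hull_area_mean=("hull_area", "mean"),
        hull_area_sd=("hull_area", "std"),
    ).reset_index()
    return out.fillna({"d_ee_sd": 0.0, "r_g_sd": 0.0, "hull_area_sd": 0.0})


# ---------------------------------------------------------------------------
# Pooled per-carbon PCA


def align_conformer(conformer: Conformer, mode: str = "principal_axes") -> np.ndarray:
    """Rigidly align one conformer to a canonical frame; return all carbons.

    ``mode="principal_axes"`` (default) aligns each conformer to its own
    inertia-like principal axes: x = widest spread, z = flattest, with
    deterministic sign rules (chain runs toward +x; C1 sits on the +y
    side).  Pooled clouds then compare molecular *shapes* irrespective of
    how the flexible tail happens to propagate in space.

    ``mode="head_frame"`` anchors the carboxyl head instead: C1 at the
    origin, C2 along +x, C3 in the y > 0 half of the xy plane.
    """
    pts = conformer.all_carbons
    if mode == "principal_axes":
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        rot = vt.copy()
        if np.dot(conformer.carbons[-1] - conformer.carbons[0], rot[0]) < 0:
            rot[0] = -rot[0]
        if np.dot(conformer.carbons[0] - centroid, rot[1]) < 0:
            rot[1] = -rot[1]
        rot[2] = np.cross(rot[0], rot[1])
        return centered @ rot.T
    if mode == "head_frame":
        c1, c2, c3 = conformer.carbons[0], conformer.carbons[1], conformer.carbons[2]
        ex = c2 - c1
        ex /= np.linalg.norm(ex)
        w = c3 - c1
        w = w - np.dot(w, ex) * ex
        nw = np.linalg.norm(w)
        if nw < 1e-9:
            w = np.array([0.0, 1.0, 0.0]) if abs(ex[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
            w = w - np.dot(w, ex) * ex
            nw = np.linalg.norm(w)
        ey = w / nw
        ez = np.cross(ex, ey)
        rot = np.vstack([ex, ey, ez])
        return (pts - c1) @ rot.T
    raise ValueError(f"unknown alignment mode: {mode!r}")


@dataclass
class PooledPCA:
    """Per-carbon 2D PCA scores and the 3-PC variance-explained fractions."""

    scores: np.ndarray  # (total carbons, 2)
    variance_fractions: np.ndarray  # (3,), non-increasing, sums to 1
    labels: pd.DataFrame  # lipid + conformer index per pooled carbon row

    @property
    def pc12_variance(self) -> float:
        """Fraction of total variance captured by PC1 + PC2."""
        return float(self.variance_fractions[:2].sum())


def pooled_pca(ensembles: Sequence[ConformerEnsemble],
               mode: str = "principal_axes") -> PooledPCA:
    """PCA of the pooled carbon coordinates of aligned conformers.

    Every carbon of every conformer contributes one 3D observation after
    rigid alignment to the canonical frame (see :func:`align_conformer`);
    the PCA reduces the pooled cloud to 2D scores and reports the variance
    fraction of each of the three components.
    """
    blocks = []
    label_rows = []
    n_conf = 0
    for ens in ensembles:
        for idx, conf in enumerate(ens.conformers):
            n_conf += 1
            aligned = align_conformer(conf, mode=mode)
            blocks.append(aligned)
            label_rows.extend(
                {"lipid": conf.lipid, "conformer_index": idx, "carbon": c}
                for c in range(len(aligned))
            )
    if n_conf < 2:
        raise ValueError("pooled_pca requires at least 2 conformers in total")
    cloud = np.vstack(blocks)
    pca = PCA(n_components=3)
    scores = pca.fit_transform(cloud)[:, :2]
    return PooledPCA(
        scores=scores,
        variance_fractions=pca.explained_variance_ratio_,
        labels=pd.DataFrame(label_rows),
    )


# ---------------------------------------------------------------------------
# Group statistics (two-factor ANOVA + Tukey HSD)


def summarize_and_compare(records: pd.DataFrame, groups: pd.DataFrame,
                          descriptor: str = "d_ee") -> dict:
    """Two-factor ANOVA (class, position) with Tukey HSD on one descriptor.

    Parameters
    ----------
    records:
        Per-conformer shape records (output of :func:`compute_shape_records`).
    groups:
        One row per lipid with columns ``lipid``, ``lipid_class`` and
        ``position`` (modification position; SFAs may carry a sentinel).
    descriptor:
        Which descriptor column to analyze.

    Returns a dict with the per-lipid summary table, the ANOVA table and
    the Tukey HSD result on the class factor (q-values in ``p-adj``).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = records.merge(groups, on="lipid", how="inner")
    if df["lipid_class"].nunique() < 2:
        raise ValueError("need at least 2 lipid classes to compare")
    small = df.groupby("lipid_class")[descriptor].count()
    if (small < 2).any():
        raise ValueError("every group needs at least 2 observations")
    df = df.rename(columns={descriptor: "y"})
    formula = "y ~ C(lipid_class)"
    if df["position"].nunique() >= 2:
        formula += " + C(position)"
    model = ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(df["y"], df["lipid_class"])
    tukey_table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "summary": summarize(records),
        "anova": anova,
        "tukey": tukey_table,
    }
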