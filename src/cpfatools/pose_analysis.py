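"""Docking-pose ingestion, subsampling, and spatial clustering.

Poses arrive as a delimited table (one row per docked pose) with the two
carboxyl-oxygen coordinates, an Emodel pose-quality score (kcal/mol), an
optional MM-GBSA binding free energy, and a post-docking minimization
convergence flag.  Scores are ingested, never computed here.

The analysis chain mirrors a receptor-pocket occupancy study:

1. keep only poses whose minimization converged;
2. subsample every lipid to the same pose count (seeded, without
   replacement) so no lipid dominates the spatial statistics;
3. collapse each pose's carboxyl group to the midpoint of its two oxygens;
4. k-means the midpoints over k = 1..k_max, selecting k by the WSS elbow
   (discrete second derivative dropping below a threshold) together with
   the mean silhouette width, silhouette winning on disagreement;
5. compare lipid-class composition across clusters (Pearson chi-square)
   and Emodel scores across clusters (Mann-Whitney for two clusters,
   Kruskal-Wallis + Dunn with Holm adjustment for more).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

#: WSS-curve second-derivative threshold below which the curve is treated
#: as flattened (the elbow).  Scale-dependent: presumes squared-angstrom
#: WSS over thousands of poses.
DEFAULT_WSS_THRESHOLD = 10_000.0
DEFAULT_KMAX = 10
#: Seeded k-means restarts per k; best-WSS solution kept.
KMEANS_RESTARTS = 25

OXYGEN_COLUMNS = ["o1x", "o1y", "o1z", "o2x", "o2y", "o2z"]


class PoseShortfallError(ValueError):
    """A lipid has fewer poses than the requested subsample size."""


@dataclass
class ClusterModel:
    """k-means result over carboxyl midpoints.

    Cluster labels are canonicalized by lexicographic centroid order so
    repeated runs (and different restart orders) give identical outputs.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    wss_curve: dict[int, float]
    silhouette_by_k: dict[int, float]
    seed: int
    elbow_k: Optional[int] = None
    silhouette_k: Optional[int] = None


def read_pose_table(path: str, sep: str = ",") -> pd.DataFrame:
    """Read a pose CSV/TSV and validate the ingestion contract."""
    df = pd.read_csv(path, sep=sep)
    required = {"lipid", "pose_id", "converged", *OXYGEN_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pose table missing columns: {sorted(missing)}")
    for col in ("emodel", "mmgbsa"):
        if col in df.columns and not np.all(np.isfinite(df[col].dropna())):
            raise ValueError(f"non-finite values in score column {col!r}")
    return df


def filter_converged(poses: pd.DataFrame) -> pd.DataFrame:
    """Keep only poses whose post-docking minimization converged."""
    if "converged" not in poses.columns:
        raise ValueError("pose table lacks a 'converged' column")
    kept = poses[poses["converged"].astype(bool)].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn("no converged poses retained", stacklevel=2)
    return kept


def subsample_equal(poses: pd.DataFrame, per_lipid: int, seed: int) -> pd.DataFrame:
    """Subsample every lipid to exactly ``per_lipid`` poses, seeded.

    Draws without replacement; raises :class:`PoseShortfallError` naming
    the first lipid that cannot supply enough poses.  Output row order is
    canonical (by lipid, then pose id), so the operation is idempotent on
    its own output.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for lipid, group in poses.groupby("lipid", sort=True):
        if len(group) < per_lipid:
            raise PoseShortfallError(
                f"lipid {lipid!r} has {len(group)} poses, need {per_lipid}"
            )
        take = rng.choice(len(group), size=per_lipid, replace=False)
        parts.append(group.iloc[np.sort(take)])
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["lipid", "pose_id"], kind="stable").reset_index(drop=True)


def carboxyl_centroid(pose_row: pd.Series | pd.DataFrame) -> np.ndarray:
    """Midpoint of the two carboxyl oxygens (component-wise mean).

    Accepts a single pose row (returns shape ``(3,)``) or a whole table
    (returns ``(n, 3)``).
    """
    if isinstance(pose_row, pd.DataFrame):
        vals = pose_row[OXYGEN_COLUMNS].to_numpy(float)
    else:
        if pose_row[OXYGEN_COLUMNS].isna().any():
            raise ValueError("pose is missing a carboxyl oxygen coordinate")
        vals = pose_row[OXYGEN_COLUMNS].to_numpy(float)[None, :]
    if not np.all(np.isfinite(vals)):
        raise ValueError("pose is missing a carboxyl oxygen coordinate")
    mid = (vals[:, :3] + vals[:, 3:]) / 2.0
    return mid[0] if isinstance(pose_row, pd.Series) else mid


def _canonicalize_labels(centroids: np.ndarray,
                         labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters in lexicographic centroid order."""
    order = np.lexsort(centroids.T[::-1])  # sort by x, then y, then z
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    return centroids[order], remap[labels]


def choose_k(points: np.ndarray, k_max: int = DEFAULT_KMAX,
             wss_threshold: float = DEFAULT_WSS_THRESHOLD,
             seed: int = 0, prefer: str = "silhouette") -> ClusterModel:
    """Run k-means over k = 1..k_max and select the cluster count.

    The elbow candidate is the smallest k at which the discrete second
    derivative of the WSS curve, ``WSS(k-1) - 2 WSS(k) + WSS(k+1)``, drops
    below ``wss_threshold``; the silhouette candidate is the k (>= 2) with
    the highest mean silhouette width.  When the two disagree the
    ``prefer`` rule decides (default: the silhouette winner — it is the
    quantitative criterion); both candidates are always reported on the
    model.  Degenerate input (all points identical) yields k = 1.
    """
    points = np.asarray(points, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if len(points) < k_max:
        raise ValueError(f"need at least k_max={k_max} points, got {len(points)}")

    wss: dict[int, float] = {}
    sil: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    n_unique = len(np.unique(points, axis=0))
    for k in range(1, k_max + 1):
        if k > n_unique:
            wss[k] = 0.0
            continue
        km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed & 0x7FFFFFFF)
        km.fit(points)
        wss[k] = float(km.inertia_)
        models[k] = km
        if k >= 2 and n_unique > k:
            sil[k] = float(silhouette_score(points, km.labels_))

    elbow_k: Optional[int] = None
    for k in range(2, k_max):
        if k in wss and (k - 1) in wss and (k + 1) in wss:
            second = wss[k - 1] - 2.0 * wss[k] + wss[k + 1]
            if second < wss_threshold:
                elbow_k = k
                break
    if elbow_k is None:
        elbow_k = 1 if wss.get(1, 0.0) <= wss_threshold else k_max
    silhouette_k = max(sil, key=sil.get) if sil else None

    if silhouette_k is None:
        chosen = 1
    elif prefer == "silhouette":
        chosen = silhouette_k
    elif prefer == "elbow":
        chosen = elbow_k
    else:
        raise ValueError(f"unknown preference rule: {prefer!r}")

    if chosen == 1 or chosen not in models:
        centroid = points.mean(axis=0, keepdims=True)
        return ClusterModel(
            k=1, centroids=centroid, assignments=np.zeros(len(points), dtype=int),
            wss_curve=wss, silhouette_by_k=sil, seed=seed,
            elbow_k=elbow_k, silhouette_k=silhouette_k,
        )
    km = models[chosen]
    centroids, labels = _canonicalize_labels(km.cluster_centers_, km.labels_)
    return ClusterModel(
        k=chosen, centroids=centroids, assignments=labels,
        wss_curve=wss, silhouette_by_k=sil, seed=seed,
        elbow_k=elbow_k, silhouette_k=silhouette_k,
    )


def cluster_composition(model: ClusterModel,
                        classes: Sequence[str]) -> dict:
    """Per-class cluster occupancy and a chi-square enrichment test.

    Returns the contingency table (clusters x classes), the percent of
    each class's poses falling in each cluster, and Pearson's chi-square
    statistic with its p-value.
    """
    classes = np.asarray(classes)
    if len(classes) != len(model.assignments):
        raise ValueError("class labels must match pose assignments")
    if model.k < 2:
        raise ValueError("composition test needs at least 2 clusters")
    table = pd.crosstab(
        pd.Series(model.assignments, name="cluster"),
        pd.Series(classes, name="lipid_class"),
    )
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty cluster in contingency table")
    percent = table.div(table.sum(axis=0), axis=1) * 100.0
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {
        "table": table,
        "percent_of_class": percent,
        "chi2": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
    }


def _dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based post-hoc comparisons with Holm adjustment.

    Mean-rank z statistics with the standard tie correction, following a
    significant Kruskal-Wallis omnibus test.
    """
    n = len(values)
    ranks = stats.rankdata(values)
    uniq = np.unique(groups)
    mean_ranks = {g: ranks[groups == g].mean() for g in uniq}
    sizes = {g: int(np.sum(groups == g)) for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(uniq, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="holm")[1]
    return out


def compact_letter_display(groups: Sequence, sig_pairs: set[tuple]) -> dict:
    """Assign letters so groups sharing a letter are not significantly different.

    Greedy insert-and-absorb algorithm over the significance relation.
    """
    letters: list[set] = []
    for g in groups:
        placed = False
        for letter_set in letters:
            if all((min(g, h), max(g, h)) not in sig_pairs for h in letter_set):
                letter_set.add(g)
                placed = True
        if not placed:
            letters.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display = {g: "" for g in groups}
    for i, letter_set in enumerate(letters):
        for g in letter_set:
            display[g] += alphabet[i % len(alphabet)]
    return display


def compare_scores_by_cluster(poses: pd.DataFrame, model: ClusterModel,
                              score_col: str = "emodel",
                              by_class: bool = True,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Compare pose scores across clusters, per lipid class.

    Two clusters: Mann-Whitney U.  More: Kruskal-Wallis followed by Dunn's
    post-hoc comparisons (Holm-adjusted), summarized as a compact letter
    display per class.
    """
    if score_col not in poses.columns:
        raise ValueError(f"missing score column {score_col!r}")
    df = poses.copy()
    df["cluster"] = model.assignments
    class_iter = df.groupby("class") if (by_class and "class" in df.columns) \
        else [("all", df)]
    rows = []
    for cls, sub in class_iter:
        counts = sub.groupby("cluster")[score_col].count()
        if (counts == 0).any() or len(counts) < 2:
            raise ValueError(f"class {cls!r}: need scores in >= 2 clusters")
        groups = [g[score_col].to_numpy() for _, g in sub.groupby("cluster")]
        cluster_ids = sorted(sub["cluster"].unique())
        if len(groups) == 2:
            u, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            sig = {tuple(sorted(cluster_ids))} if p < alpha else set()
            letters = compact_letter_display(cluster_ids, sig)
            rows.append({
                "class": cls, "test": "mann-whitney", "statistic": float(u),
                "p_value": float(p), "letters": letters,
            })
        else:
            h, p = stats.kruskal(*groups)
            dunn = _dunn_posthoc(sub[score_col].to_numpy(), sub["cluster"].to_numpy())
            sig = {
                (min(r.group_a, r.group_b), max(r.group_a, r.group_b))
                for r in dunn.itertuples()
                if r.p_adjusted < alpha
            } if p < alpha else set()
            letters = compact_letter_display(cluster_ids, sig)
            rows.append({
                "class": cls, "test": "kruskal-dunn", "statistic": float(h),
                "p_value": float(p), "letters": letters, "posthoc": dunn,
            })
    return pd.DataFrame(rows)
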