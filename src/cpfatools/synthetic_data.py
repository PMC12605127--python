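"""Ground-truth synthetic inputs for every downstream analysis.

Three generators emulate the external data sources the pipeline ingests,
each a pure function of its config (seed included) with the planted truth
returned alongside the data:

* :func:`gen_pose_cloud` — docking-pose tables with carboxyl-oxygen pairs
  scattered around planted spatial clusters inside a ~20 Å pocket,
  class-biased cluster membership, per-cluster Emodel score means, and a
  configurable minimization-failure rate;
* :func:`gen_pocket` — a synthetic receptor pocket: named residues with
  backbone and side-chain heavy atoms placed proximal or distal to the
  planted cluster centers, serializable to PDB;
* :func:`gen_plate` — TR-FRET plates from known 4PL parameters: 12-step
  half-dilution series, quadruplicate wells, multiplicative Gaussian
  channel noise, and no-agonist / no-LBD / reference-agonist controls.

The default panel is the study's 14 modeling lipids (five CpFAs, their
five MUFA precursors, four SFAs); default cluster-membership weights echo
the class enrichments reported for the two-cluster receptors (CpFA 60%,
MUFA 45%, SFA 39% in cluster 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .interaction_fingerprints import LigandPose, ReceptorStructure, Residue, ResidueAtom

#: The 14 lipids carried into the modeling / in-vitro arm of the study.
DEFAULT_LIPID_PANEL: tuple[tuple[str, str], ...] = (
    ("C15Δ1 cis-11", "CpFA"),
    ("C16Δ1 cis-9", "CpFA"),
    ("C17Δ1 cis-13", "CpFA"),
    ("C18Δ1 cis-9", "CpFA"),
    ("C18Δ1 cis-11", "CpFA"),
    ("C15:1 cis-11", "MUFA"),
    ("C16:1 cis-9", "MUFA"),
    ("C17:1 cis-13", "MUFA"),
    ("C18:1 cis-9", "MUFA"),
    ("C18:1 cis-11", "MUFA"),
    ("C15", "SFA"),
    ("C16", "SFA"),
    ("C17", "SFA"),
    ("C18", "SFA"),
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Spatial defaults are scaled to a ~20 Å docking box: two planted
    clusters 20 Å apart with 2 Å isotropic spread.  Emodel means differ
    by cluster so score-by-cluster contrasts have planted structure.
    4PL defaults are a mid-potency ligand (EC50 5 μM, E_max 60%) read out
    over a 12-step half-dilution series from 100 μM in quadruplicate with
    5% multiplicative channel noise.
    """

    seed: int = 0
    lipids: tuple[tuple[str, str], ...] = DEFAULT_LIPID_PANEL
    poses_per_lipid: int = 500
    cluster_centers: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0),
        (20.0, 0.0, 0.0),
    )
    cluster_spread: float = 2.0
    #: Per-class probability of each cluster; rows sum to 1.
    class_cluster_weights: dict = field(
        default_factory=lambda: {
            "CpFA": (0.60, 0.40),
            "MUFA": (0.45, 0.55),
            "SFA": (0.39, 0.61),
        }
    )
    emodel_cluster_means: tuple[float, ...] = (-70.0, -60.0)
    emodel_sd: float = 5.0
    oxygen_half_separation: float = 1.1
    convergence_failure_rate: float = 0.1
    tail_carbons: int = 0
    # --- plate parameters -------------------------------------------------
    plate_top_uM: float = 100.0
    plate_n_steps: int = 12
    plate_replicates: int = 4
    #: Common-mode per-well gain noise (dispensing volume, flash energy,
    #: receptor amount): multiplies BOTH emission channels of a well, and
    #: is what the ratiometric 520/495 readout exists to cancel.
    plate_noise_sd: float = 0.05
    #: Independent detector noise per emission channel (photon/readout CV).
    plate_channel_noise_sd: float = 0.015
    plate_truth: dict = field(
        default_factory=lambda: {"lower": 0.0, "upper": 60.0, "ec50": 5.0, "slope": 1.0}
    )
    plate_ratio_0pct: float = 1.0
    plate_ratio_100pct: float = 2.0
    #: Acceptor/donor ratio of the no-LBD background control, as a fraction
    #: of the 0% ratio (no receptor => no recruitment => acceptor floor).
    plate_no_lbd_fraction: float = 0.6
    plate_donor_signal: float = 10_000.0

    def __post_init__(self) -> None:
        if self.cluster_spread <= 0:
            raise ValueError("cluster_spread must be positive")
        if len(self.cluster_centers) < 1:
            raise ValueError("need at least one planted cluster")
        k = len(self.cluster_centers)
        for cls, weights in self.class_cluster_weights.items():
            if len(weights) != k:
                raise ValueError(f"class {cls!r}: need {k} cluster weights")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(f"class {cls!r}: cluster weights must sum to 1")
        if len(self.emodel_cluster_means) != k:
            raise ValueError("need one Emodel mean per planted cluster")


@dataclass
class PoseCloud:
    """Generated pose table with its planted truth."""

    poses: pd.DataFrame
    labels: np.ndarray  # planted cluster index per pose row
    atoms: Optional[list[LigandPose]]
    truth: dict


def gen_pose_cloud(config: SynthConfig) -> PoseCloud:
    """Sample a docking-pose table around the planted cluster centers.

    For each pose: a cluster is drawn from the lipid class's weight
    vector; the carboxyl midpoint is Gaussian around that cluster's
    center; the two oxygens sit symmetrically about the midpoint along a
    random direction; the Emodel score is Gaussian around the cluster's
    planted mean; the convergence flag fails at the configured rate.
    With ``tail_carbons > 0`` each pose also gets that many tail carbon
    atoms marching away from the carboxyl group, for fingerprint work.
    """
    rng = np.random.default_rng(config.seed)
    centers = np.asarray(config.cluster_centers, dtype=float)
    rows = []
    labels = []
    atoms: list[LigandPose] = []
    pose_id = 0
    for lipid, cls in config.lipids:
        weights = np.asarray(config.class_cluster_weights[cls], dtype=float)
        for _ in range(config.poses_per_lipid):
            cluster = int(rng.choice(len(centers), p=weights))
            mid = centers[cluster] + rng.normal(0.0, config.cluster_spread, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            o1 = mid + config.oxygen_half_separation * direction
            o2 = mid - config.oxygen_half_separation * direction
            emodel = rng.normal(config.emodel_cluster_means[cluster], config.emodel_sd)
            converged = bool(rng.random() >= config.convergence_failure_rate)
            rows.append(
                {
                    "lipid": lipid, "class": cls, "pose_id": pose_id,
                    "converged": converged, "emodel": emodel,
                    "mmgbsa": emodel / 2.0,
                    "o1x": o1[0], "o1y": o1[1], "o1z": o1[2],
                    "o2x": o2[0], "o2y": o2[1], "o2z": o2[2],
                }
            )
            labels.append(cluster)
            if config.tail_carbons > 0:
                tail_dir = rng.normal(size=3)
                tail_dir /= np.linalg.norm(tail_dir)
                tail = mid + np.outer(
                    1.53 * np.arange(1, config.tail_carbons + 1), tail_dir
                )
                coords = np.vstack([o1, o2, tail])
                elements = ["O", "O"] + ["C"] * config.tail_carbons
                atoms.append(LigandPose(lipid=lipid, pose_id=pose_id,
                                        elements=elements, coords=coords))
            pose_id += 1
    poses = pd.DataFrame(rows)
    truth = {
        "cluster_centers": centers,
        "k": len(centers),
        "class_cluster_weights": dict(config.class_cluster_weights),
        "emodel_cluster_means": list(config.emodel_cluster_means),
        "failure_rate": config.convergence_failure_rate,
    }
    return PoseCloud(poses=poses, labels=np.asarray(labels),
                     atoms=atoms if config.tail_carbons > 0 else None,
                     truth=truth)


# ---------------------------------------------------------------------------
# Synthetic receptor pocket


#: (resname, resnum, which planted cluster it sits next to)
DEFAULT_POCKET_LAYOUT: tuple[tuple[str, int, int], ...] = (
    ("CYS", 276, 0),
    ("SER", 280, 0),
    ("THR", 279, 0),
    ("TYR", 314, 1),
    ("LEU", 460, 1),
    ("TYR", 464, 1),
)

_SIDE_CHAIN_ATOMS = {
    "CYS": (("CB", "C"), ("SG", "S")),
    "SER": (("CB", "C"), ("OG", "O")),
    "THR": (("CB", "C"), ("OG1", "O"), ("CG2", "C")),
    "TYR": (("CB", "C"), ("CG", "C"), ("CZ", "C"), ("OH", "O")),
    "LEU": (("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")),
    "ALA": (("CB", "C"),),
}


def gen_pocket(config: SynthConfig,
               layout: Sequence[tuple[str, int, int]] = DEFAULT_POCKET_LAYOUT,
               offset: float = 5.0) -> ReceptorStructure:
    """Build a synthetic receptor pocket around the planted cluster centers.

    Each layout entry places one residue ``offset`` Å from its cluster's
    center, side chain pointing inward (toward the poses) and backbone
    behind it.  Residues attached to different clusters are the planted
    proximal/distal sets for fingerprint-contrast tests.  Deterministic
    given the config seed.
    """
    if len(layout) < 2:
        raise ValueError("pocket needs at least 2 residues")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 77]))
    centers = np.asarray(config.cluster_centers, dtype=float)
    residues = []
    for resname, resnum, cluster in layout:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        anchor = centers[cluster] + offset * direction  # CB position
        inward = -direction  # unit vector pointing back at the cluster center
        atoms = [
            ResidueAtom("N", "N", anchor - inward * 2.9 + np.array([0.0, 1.2, 0.0]),
                        True),
            ResidueAtom("CA", "C", anchor - inward * 1.5, True),
            ResidueAtom("C", "C", anchor - inward * 2.9 - np.array([0.0, 1.2, 0.0]),
                        True),
            ResidueAtom("O", "O", anchor - inward * 3.9 - np.array([0.0, 1.4, 0.0]),
                        True),
        ]
        side = _SIDE_CHAIN_ATOMS.get(resname, (("CB", "C"),))
        for i, (name, element) in enumerate(side):
            atoms.append(
                ResidueAtom(name, element, anchor + inward * (1.5 * i), False)
            )
        residues.append(Residue(resname=resname, resnum=resnum, atoms=atoms))
    return ReceptorStructure(residues=residues)


def write_pocket_pdb(receptor: ReceptorStructure, path: str) -> None:
    """Serialize a receptor pocket as standard PDB ATOM records."""
    serial = 1
    with open(path, "w") as fh:
        for res in receptor.residues:
            for atom in res.atoms:
                x, y, z = atom.coords
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.resname:>3s} "
                    f"{res.chain:1s}{res.resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Synthetic TR-FRET plates


@dataclass
class SyntheticPlate:
    """Generated plate table and the 4PL truth that produced it."""

    plate: pd.DataFrame
    truth: dict


def _4pl_percent(conc: np.ndarray, truth: dict) -> np.ndarray:
    lower, upper = truth["lower"], truth["upper"]
    return lower + (upper - lower) / (1.0 + (truth["ec50"] / conc) ** truth["slope"])


def gen_plate(config: SynthConfig,
              ligands: Optional[dict[str, dict]] = None) -> SyntheticPlate:
    """Simulate one TR-FRET plate from known 4PL parameters.

    Test wells follow the half-dilution series in quadruplicate; the true
    % activation is mapped onto a channel ratio between the no-agonist
    ratio (0%) and the reference-agonist top ratio (100%).  Each well gets
    a common-mode gain factor shared by both channels (the noise the
    ratiometric readout cancels) plus small independent per-channel
    detector noise.  Control wells (no agonist, no agonist + no LBD,
    reference agonist at the top concentration) are shared by every ligand
    on the plate, as on a real plate — so ligands fitted from one plate
    share their normalization anchors.

    ``ligands`` maps ligand name -> 4PL truth dict; default is one ligand
    (``test_lipid``) at ``config.plate_truth``.
    """
    if ligands is None:
        ligands = {"test_lipid": dict(config.plate_truth)}
    for name, truth in ligands.items():
        if truth["ec50"] <= 0:
            raise ValueError(f"ligand {name!r}: EC50 truth must be positive")
    if config.plate_n_steps < 5:
        raise ValueError("need at least 5 dilution steps")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 911]))
    conc = config.plate_top_uM / np.power(2.0, np.arange(config.plate_n_steps))
    r0, r100 = config.plate_ratio_0pct, config.plate_ratio_100pct
    donor = config.plate_donor_signal
    gain_sd = config.plate_noise_sd
    ch_sd = config.plate_channel_noise_sd

    def well(ligand_id: str, c: float, rep: int, role: str,
             ratio_true: float) -> dict:
        gain = 1.0 + rng.normal(0.0, gain_sd)  # shared by both channels
        em495 = donor * gain * (1.0 + rng.normal(0.0, ch_sd))
        em520 = donor * gain * ratio_true * (1.0 + rng.normal(0.0, ch_sd))
        return {
            "ligand": ligand_id, "conc_uM": c, "replicate": rep,
            "em495": em495, "em520": em520, "role": role,
        }

    def pct_ratio(percent: float) -> float:
        return r0 + (r100 - r0) * percent / 100.0

    rows = []
    for rep in range(1, config.plate_replicates + 1):
        for ligand, truth in ligands.items():
            percent_true = _4pl_percent(conc, truth)
            for c, pct in zip(conc, percent_true):
                rows.append(well(ligand, float(c), rep, "test",
                                 pct_ratio(float(pct))))
        rows.append(well("none", config.plate_top_uM, rep, "no_agonist",
                         pct_ratio(0.0)))
        rows.append(well("none_no_lbd", config.plate_top_uM, rep,
                         "no_agonist_no_LBD", r0 * config.plate_no_lbd_fraction))
        rows.append(well("reference", config.plate_top_uM, rep,
                         "agonist_reference", pct_ratio(100.0)))
    truth_out = ligands if len(ligands) > 1 else dict(next(iter(ligands.values())))
    return SyntheticPlate(plate=pd.DataFrame(rows), truth=truth_out)
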