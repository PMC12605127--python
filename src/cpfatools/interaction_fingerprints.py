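"""Residue-level ligand-receptor interaction fingerprints.

For every docking pose, each receptor residue with at least one heavy atom
within a distance cutoff (inclusive, default 4.0 Å) of at least one ligand
heavy atom registers typed interactions.  Because the typing scheme of
commercial fingerprint tools is proprietary, this module uses documented,
configurable lookup tables:

* ``contact``      — any heavy-atom pair within the cutoff;
* ``backbone`` / ``side_chain`` — split by the receptor atom's flag;
* ``polar``        — the pair involves an N, O or S atom;
* ``hydrophobic``  — both atoms are C/S and the residue is aliphatic or
  aromatic-hydrophobic (ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO);
* ``acceptor`` / ``donor`` — receptor atom appears in a fixed atom-name
  table and the ligand atom is N/O;
* ``charged``      — side-chain N/O of ASP, GLU, LYS, ARG or HIS;
* ``aromatic``     — receptor atom belongs to the ring of PHE, TYR, TRP
  or HIS.

Per-lipid counts are normalized by the number of conformers evaluated for
that lipid, giving an interactions-per-conformer frequency.  Hydrogens
are ignored throughout (poses and receptors are heavy-atom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 4.0

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
CHARGED_RESIDUES = {"ASP", "GLU", "LYS", "ARG", "HIS"}
AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
#: Receptor atom names acting as hydrogen-bond acceptors / donors.
ACCEPTOR_ATOM_NAMES = {
    "O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
    "ND1", "NE2", "SD",
}
DONOR_ATOM_NAMES = {
    "N", "ND1", "ND2", "NE", "NE1", "NE2", "NH1", "NH2", "NZ",
    "OG", "OG1", "OH", "SG",
}

INTERACTION_TYPES = (
    "contact", "backbone", "side_chain", "polar", "hydrophobic",
    "acceptor", "donor", "charged", "aromatic",
)


@dataclass
class ResidueAtom:
    name: str
    element: str
    coords: np.ndarray
    is_backbone: bool


@dataclass
class Residue:
    """One receptor residue: name, sequence number and heavy atoms."""

    resname: str
    resnum: int
    chain: str = "A"
    atoms: list[ResidueAtom] = field(default_factory=list)

    @property
    def key(self) -> str:
        """Human-readable residue key, e.g. ``Cys276``."""
        return f"{self.resname.capitalize()}{self.resnum}"


@dataclass
class ReceptorStructure:
    """Residue list of one receptor (chain, resnum unique)."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        keys = [(r.chain, r.resnum) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, resnum) in receptor structure")

    @classmethod
    def from_pdb(cls, path: str) -> "ReceptorStructure":
        """Parse a PDB file with Biopython (first model, heavy atoms only)."""
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("receptor", path)
        residues = []
        model = next(structure.get_models())
        for chain in model:
            for res in chain:
                if res.id[0].strip():  # skip heteroatoms/waters
                    continue
                atoms = [
                    ResidueAtom(
                        name=atom.get_name(),
                        element=(atom.element or atom.get_name()[0]).upper(),
                        coords=np.asarray(atom.get_coord(), dtype=float),
                        is_backbone=atom.get_name() in BACKBONE_ATOMS,
                    )
                    for atom in res
                    if (atom.element or "").upper() != "H"
                ]
                residues.append(
                    Residue(resname=res.get_resname(), resnum=res.id[1],
                            chain=chain.id, atoms=atoms)
                )
        return cls(residues=residues)


@dataclass
class LigandPose:
    """Heavy-atom coordinates of one docked ligand pose."""

    lipid: str
    pose_id: int
    elements: list[str]
    coords: np.ndarray


def _classify_pair(residue: Residue, atom: ResidueAtom,
                   ligand_element: str) -> dict[str, int]:
    """Typed interaction counts contributed by one in-cutoff atom pair."""
    counts = dict.fromkeys(INTERACTION_TYPES, 0)
    counts["contact"] = 1
    if atom.is_backbone:
        counts["backbone"] = 1
    else:
        counts["side_chain"] = 1
    polar_elements = {"N", "O", "S"}
    if atom.element in polar_elements or ligand_element in polar_elements:
        counts["polar"] = 1
    if (
        atom.element in {"C", "S"}
        and ligand_element in {"C", "S"}
        and residue.resname in HYDROPHOBIC_RESIDUES
    ):
        counts["hydrophobic"] = 1
    if ligand_element in {"N", "O"}:
        if atom.name in ACCEPTOR_ATOM_NAMES:
            counts["acceptor"] = 1
        if atom.name in DONOR_ATOM_NAMES:
            counts["donor"] = 1
    if (
        residue.resname in CHARGED_RESIDUES
        and not atom.is_backbone
        and atom.element in {"N", "O"}
    ):
        counts["charged"] = 1
    if atom.name in AROMATIC_RING_ATOMS.get(residue.resname, ()):
        counts["aromatic"] = 1
    return counts


def residue_contacts(pose: LigandPose, receptor: ReceptorStructure,
                     cutoff: float = DEFAULT_CUTOFF) -> dict[str, dict[str, int]]:
    """Typed interaction counts per residue for one pose.

    A residue appears in the result iff at least one of its heavy atoms is
    within ``cutoff`` (inclusive) of at least one ligand heavy atom.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = np.asarray(pose.coords, dtype=float)
    if lig.ndim != 2 or lig.shape[1] != 3 or len(lig) == 0:
        raise ValueError("pose lacks ligand atom coordinates")
    out: dict[str, dict[str, int]] = {}
    cut2 = cutoff * cutoff
    for res in receptor.residues:
        counts = dict.fromkeys(INTERACTION_TYPES, 0)
        hit = False
        for atom in res.atoms:
            d2 = np.sum((lig - atom.coords) ** 2, axis=1)
            for lig_idx in np.nonzero(d2 <= cut2)[0]:
                hit = True
                pair = _classify_pair(res, atom, pose.elements[lig_idx].upper())
                for t, v in pair.items():
                    counts[t] += v
        if hit:
            out[res.key] = counts
    return out


def fingerprint(poses: Sequence[LigandPose], receptor: ReceptorStructure,
                conformer_counts: Mapping[str, int],
                cutoff: float = DEFAULT_CUTOFF,
                count_mode: str = "typed_sum") -> pd.DataFrame:
    """Normalized lipid x residue interaction-frequency matrix.

    ``cell(lipid, residue)`` is the total interaction count of that
    lipid's poses with that residue divided by the lipid's conformer
    count.  ``count_mode="typed_sum"`` aggregates all interaction types
    (a pair contributing both a polar and a contact interaction counts
    each); ``count_mode="union"`` counts each in-cutoff atom pair once.
    """
    if count_mode not in {"typed_sum", "union"}:
        raise ValueError(f"unknown count_mode: {count_mode!r}")
    lipids = sorted({p.lipid for p in poses})
    for lipid in lipids:
        if lipid not in conformer_counts:
            raise ValueError(f"pose references unknown lipid {lipid!r}")
        if conformer_counts[lipid] <= 0:
            raise ValueError(f"conformer count for {lipid!r} must be positive")
    residue_keys = [r.key for r in receptor.residues]
    totals = pd.DataFrame(0.0, index=lipids, columns=residue_keys)
    for pose in poses:
        contacts = residue_contacts(pose, receptor, cutoff)
        for res_key, counts in contacts.items():
            value = counts["contact"] if count_mode == "union" else sum(counts.values())
            totals.loc[pose.lipid, res_key] += value
    for lipid in lipids:
        totals.loc[lipid] /= conformer_counts[lipid]
    return totals


def typed_counts_long(poses: Sequence[LigandPose], receptor: ReceptorStructure,
                      cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Long-format typed counts: lipid, pose, residue, interaction type, count."""
    rows = []
    for pose in poses:
        for res_key, counts in residue_contacts(pose, receptor, cutoff).items():
            for itype, count in counts.items():
                if count:
                    rows.append(
                        {"lipid": pose.lipid, "pose_id": pose.pose_id,
                         "residue": res_key, "type": itype, "count": count}
                    )
    return pd.DataFrame(rows, columns=["lipid", "pose_id", "residue", "type", "count"])


def compare_fingerprints(matrix: pd.DataFrame,
                         grouping: Mapping[str, object]) -> pd.DataFrame:
    """Per-residue contrast of mean interaction frequency between groups.

    ``grouping`` maps each lipid (matrix row) to its group (class or
    cluster).  Returns per-residue group means, the max-minus-min
    difference, and rows sorted so the most discriminating residues come
    first.
    """
    groups = pd.Series({lip: grouping[lip] for lip in matrix.index})
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups to contrast")
    means = matrix.groupby(groups).mean()
    if means.isna().any().any():
        raise ValueError("empty group in fingerprint contrast")
    diff = means.max(axis=0) - means.min(axis=0)
    out = means.T
    out.columns = [f"mean_{g}" for g in means.index]
    out["difference"] = diff
    return out.sort_values("difference", ascending=False)
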