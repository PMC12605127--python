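"""Internal-coordinate 3D builder and rotamer sampler for fatty acids.

Geometries are built atom by atom with the natural-extension reference
frame (NeRF) construction from fixed internal-coordinate templates:

* sp3 C-C bonds: 1.53 Å, C-C-C angle 111°;
* cis double bonds (MUFA): C=C 1.33 Å, 120° angles at both sp2 carbons,
  dihedral across the double bond fixed at 0° (cis);
* cyclopropane rings (CpFA): ring C-C 1.51 Å (near-equilateral triangle),
  both chain substituents on the same ring face (cis), which eclipses the
  backbone across the ring bond (dihedral 0°) and tilts the ring methylene
  off the backbone plane.

Conformers are sampled by drawing each rotatable backbone torsion from the
three staggered rotamer states (anti 180°, gauche ±65°) with a Gaussian
perturbation, then rejecting geometries that fail a hard-sphere clash
filter, and finally discarding conformers whose backbone is within an RMSD
redundancy threshold of an already-retained conformer (after optimal
rigid superposition).  Hydrogens are not modeled: every descriptor
downstream uses carbon coordinates only.  The two carboxyl oxygens are
placed in the C1 sp2 plane (1.25 Å, 120°) for pose-centroid work.

Each lipid gets its own deterministic random stream derived from the
user seed and the lipid name, so library-scale runs are independent of
the order in which lipids are processed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lipid_library import LipidClass, LipidSpec, canonical_name, parse_name

# Internal-coordinate templates (Å, degrees)
BOND_SP3 = 1.53
BOND_DOUBLE = 1.33
BOND_RING = 1.51
BOND_CO = 1.25
ANGLE_SP3 = 111.0
ANGLE_SP2 = 120.0
#: Exocyclic substituent-substituent angle at a cyclopropane carbon.
RING_EXO_ANGLE = 115.0

#: Hard-sphere clash threshold for carbon pairs >= 4 bonds apart (Å).
CLASH_MIN_DIST = 2.8
#: Backbone-RMSD threshold below which two conformers count as redundant (Å).
REDUNDANCY_RMSD = 0.5

#: Rotamer states for rotatable sp3 torsions (degrees) and their weights.
#: Weights follow a Boltzmann split at 298 K with a ~0.9 kcal/mol gauche
#: penalty (per-state factor exp(-0.9/0.593) ~ 0.22), mimicking the bias
#: of a low-energy conformer generator toward extended chains.
ROTAMER_STATES = (180.0, 65.0, -65.0)
ROTAMER_WEIGHTS = (0.69, 0.155, 0.155)
#: SD of the Gaussian perturbation applied to each sampled torsion (degrees).
TORSION_JITTER_SD = 10.0
#: Rotamer strain assigned to each gauche torsion when ranking candidates
#: by energy (kcal/mol); anti torsions are strain-free.
GAUCHE_PENALTY_KCAL = 0.9


@dataclass
class Conformer:
    """One 3D conformer: ordered backbone carbons, ring methylene, oxygens.

    ``carbons`` rows are backbone carbons C1..Cn (C1 = carboxyl carbon).
    ``ring_methylene`` is the extra CpFA ring carbon or ``None``.
    ``oxygens`` are the two carboxyl oxygens (2 x 3).
    """

    lipid: str
    carbons: np.ndarray
    oxygens: np.ndarray
    ring_methylene: Optional[np.ndarray] = None
    torsions: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def all_carbons(self) -> np.ndarray:
        """Backbone carbons plus the CpFA ring methylene (if present)."""
        if self.ring_methylene is None:
            return self.carbons
        return np.vstack([self.carbons, self.ring_methylene])

    @property
    def n_backbone(self) -> int:
        return len(self.carbons)


@dataclass
class ConformerEnsemble:
    """Sampled conformers of one lipid with the seed that produced them."""

    lipid: str
    conformers: list[Conformer]
    seed: int
    requested: int

    @property
    def n_produced(self) -> int:
        return len(self.conformers)


class TorsionLengthError(ValueError):
    """Torsion vector does not match the rotatable-bond count."""


def rotatable_torsion_count(spec: LipidSpec) -> int:
    """Number of freely rotatable backbone torsions of one lipid.

    A chain of ``n`` carbons has ``n - 3`` backbone dihedrals; the dihedral
    crossing the double bond or cyclopropane ring (placing carbon ``p+2``)
    is fixed by the cis constraint and is not rotatable.
    """
    n = spec.backbone_length
    count = n - 3
    if spec.lipid_class is not LipidClass.SFA and spec.mod_position <= n - 2:
        count -= 1
    return count


def _nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
                angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C with bond |CD|, angle BCD, dihedral ABCD."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ring_template() -> dict[str, np.ndarray]:
    """Local-frame cyclopropane template with cis exocyclic directions.

    Ring in the xy plane: Cp at the origin, Cq (= Cp+1) on +x, methylene M
    above the ring bond.  The exocyclic chain directions at Cp and Cq lie
    along the external bisector of each ring angle, tilted out of the ring
    plane by half the exocyclic angle — both toward +z, making the two
    chain substituents cis.
    """
    d = BOND_RING
    cp = np.zeros(3)
    cq = np.array([d, 0.0, 0.0])
    m = np.array([d / 2.0, d * math.sqrt(3.0) / 2.0, 0.0])
    phi = math.radians(RING_EXO_ANGLE / 2.0)
    e_p = -((cq - cp) / d + (m - cp) / d)
    e_p /= np.linalg.norm(e_p)
    e_q = -((cp - cq) / d + (m - cq) / d)
    e_q /= np.linalg.norm(e_q)
    z = np.array([0.0, 0.0, 1.0])
    u_prev = math.cos(phi) * e_p + math.sin(phi) * z
    u_next = math.cos(phi) * e_q + math.sin(phi) * z
    return {"cp": cp, "cq": cq, "m": m, "u_prev": u_prev, "u_next": u_next}


_RING = _ring_template()
#: Backbone angle C(p-1)-Cp-C(p+1) implied by the ring template (degrees).
RING_BACKBONE_ANGLE = math.degrees(
    math.acos(float(np.dot(_RING["u_prev"], (_RING["cq"] - _RING["cp"]) / BOND_RING)))
)


def build_geometry(spec: LipidSpec, torsions: Sequence[float]) -> Conformer:
    """Build deterministic 3D coordinates from a rotatable-torsion vector.

    ``torsions`` are the rotatable backbone dihedrals in degrees, in
    backbone order (the dihedral placing C4 first); the cis dihedral
    crossing a double bond or ring is inserted automatically.
    """
    torsions = np.asarray(torsions, dtype=float)
    expected = rotatable_torsion_count(spec)
    if len(torsions) != expected:
        raise TorsionLengthError(
            f"{canonical_name(spec).short_name}: expected {expected} torsions, "
            f"got {len(torsions)}"
        )
    n = spec.backbone_length
    p = spec.mod_position if spec.mod_position is not None else -10
    cls = spec.lipid_class

    def bond_len(i: int) -> float:  # bond C(i)-C(i+1), 1-indexed
        if cls is LipidClass.MUFA and i == p:
            return BOND_DOUBLE
        if cls is LipidClass.CpFA and i == p:
            return BOND_RING
        return BOND_SP3

    def angle_at(j: int) -> float:  # angle C(j-1)-C(j)-C(j+1)
        if cls is LipidClass.MUFA and j in (p, p + 1):
            return ANGLE_SP2
        if cls is LipidClass.CpFA and j in (p, p + 1):
            return RING_BACKBONE_ANGLE
        return ANGLE_SP3

    coords = np.zeros((n, 3))
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (bond_len(1), 0.0, 0.0)
    a2 = math.radians(180.0 - angle_at(2))
    coords[2] = coords[1] + bond_len(2) * np.array([math.cos(a2), math.sin(a2), 0.0])

    ring_m: Optional[np.ndarray] = None
    t_idx = 0  # cursor into the rotatable torsion vector
    ring_next_dir: Optional[np.ndarray] = None

    if cls is LipidClass.CpFA and p == 2:
        # Ring base is C2-C3; C3 is already placed by the third-atom rule.
        ring_m, ring_next_dir = _ring_from_backbone(coords[0], coords[1], coords[2])

    i = 3  # 0-based index of next atom to place (atom number i+1)
    while i < n:
        atom_no = i + 1  # 1-indexed carbon number
        if cls is LipidClass.CpFA and atom_no == p + 1:
            # Place the ring carbon Cq via NeRF (its torsion is rotatable),
            # then transform the ring template to recover the methylene and
            # the cis-constrained direction of the next chain carbon.
            tor = torsions[t_idx]
            t_idx += 1
            coords[i] = _nerf_place(
                coords[i - 3], coords[i - 2], coords[i - 1],
                BOND_RING, RING_BACKBONE_ANGLE, tor,
            )
            ring_m, ring_next_dir = _ring_from_backbone(
                coords[p - 2], coords[p - 1], coords[p]
            )
            i += 1
        elif cls is LipidClass.CpFA and atom_no == p + 2:
            coords[i] = coords[i - 1] + BOND_SP3 * ring_next_dir
            i += 1
        else:
            if atom_no == p + 2 and cls is LipidClass.MUFA:
                tor = 0.0  # cis across the double bond
            else:
                tor = torsions[t_idx]
                t_idx += 1
            coords[i] = _nerf_place(
                coords[i - 3], coords[i - 2], coords[i - 1],
                bond_len(i), angle_at(i), tor,
            )
            i += 1

    # CpFA with the ring at the chain terminus (p = n-1): the loop placed
    # Cq as the last backbone atom; the methylene still needs placing.
    if cls is LipidClass.CpFA and ring_m is None:
        ring_m, _ = _ring_from_backbone(coords[p - 2], coords[p - 1], coords[p])

    oxygens = _place_carboxyl_oxygens(coords)
    return Conformer(
        lipid=canonical_name(spec).short_name,
        carbons=coords,
        oxygens=oxygens,
        ring_methylene=ring_m,
        torsions=torsions.copy(),
    )


def _ring_from_backbone(c_prev: np.ndarray, cp: np.ndarray,
                        cq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recover the ring methylene and next-chain direction from Cp-1, Cp, Cq.

    Aligns the local cyclopropane template so that its Cp->Cq bond and its
    exocyclic Cp->chain direction match the built backbone, then reads off
    the methylene position and the cis exocyclic direction at Cq.
    """
    t = _RING
    # template frame anchored at Cp: ring bond direction + exocyclic dir
    f1 = (t["cq"] - t["cp"]) / np.linalg.norm(t["cq"] - t["cp"])
    f2 = t["u_prev"] - np.dot(t["u_prev"], f1) * f1
    f2 /= np.linalg.norm(f2)
    f3 = np.cross(f1, f2)
    g1 = cq - cp
    g1 /= np.linalg.norm(g1)
    u_prev_g = c_prev - cp
    u_prev_g /= np.linalg.norm(u_prev_g)
    g2 = u_prev_g - np.dot(u_prev_g, g1) * g1
    g2 /= np.linalg.norm(g2)
    g3 = np.cross(g1, g2)
    rot = np.column_stack([g1, g2, g3]) @ np.column_stack([f1, f2, f3]).T
    m = cp + rot @ (t["m"] - t["cp"])
    u_next = rot @ t["u_next"]
    return m, u_next


def _place_carboxyl_oxygens(coords: np.ndarray) -> np.ndarray:
    """Two oxygens in the C1 sp2 plane at 1.25 Å / 120° from the C1-C2 bond."""
    c1, c2 = coords[0], coords[1]
    c3 = coords[2]
    u = c2 - c1
    u /= np.linalg.norm(u)
    w = c3 - c1
    w = w - np.dot(w, u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-9:  # colinear start: any perpendicular will do
        w = np.array([0.0, 1.0, 0.0]) if abs(u[0]) > 0.5 else np.array([1.0, 0.0, 0.0])
        w = w - np.dot(w, u) * u
        nw = np.linalg.norm(w)
    w /= nw
    ang = math.radians(ANGLE_SP2)
    o1 = c1 + BOND_CO * (math.cos(ang) * u + math.sin(ang) * w)
    o2 = c1 + BOND_CO * (math.cos(ang) * u - math.sin(ang) * w)
    return np.vstack([o1, o2])


# ---------------------------------------------------------------------------
# Filters


def _bond_graph_distances(spec: LipidSpec) -> np.ndarray:
    """All-pairs bond-path lengths between the lipid's carbons.

    Atom order matches :attr:`Conformer.all_carbons` (backbone then ring
    methylene).  BFS on the tiny molecular graph.
    """
    n = spec.backbone_length
    total = spec.total_carbons
    adj: list[list[int]] = [[] for _ in range(total)]
    for i in range(n - 1):
        adj[i].append(i + 1)
        adj[i + 1].append(i)
    if spec.lipid_class is LipidClass.CpFA:
        m = total - 1
        p = spec.mod_position
        for ring_c in (p - 1, p):  # 0-based backbone indices of ring base
            adj[m].append(ring_c)
            adj[ring_c].append(m)
    dist = np.full((total, total), total + 1, dtype=int)
    for s in range(total):
        dist[s, s] = 0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[s, v] > dist[s, u] + 1:
                        dist[s, v] = dist[s, u] + 1
                        nxt.append(v)
            queue = nxt
    return dist


def has_clash(conformer: Conformer, spec: LipidSpec,
              min_dist: float = CLASH_MIN_DIST,
              _graph_cache: dict = {}) -> bool:
    """True if any carbon pair >= 4 bonds apart is closer than ``min_dist``.

    Pairs up to 3 bonds apart are excluded: their distances are fixed (or
    nearly fixed) by the bond/angle templates, not by the torsion state.
    """
    key = (spec.lipid_class, spec.backbone_length, spec.mod_position)
    if key not in _graph_cache:
        _graph_cache[key] = _bond_graph_distances(spec)
    graph = _graph_cache[key]
    pts = conformer.all_carbons
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    mask = graph >= 4
    return bool(np.any(d2[mask] < min_dist * min_dist))


def backbone_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two point sets after optimal rigid superposition.

    Standard Kabsch alignment (rotation + translation, no reflection).
    """
    if a.shape != b.shape:
        raise ValueError("conformer size mismatch")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s_signed = s.copy()
    s_signed[-1] *= d
    msd = (np.sum(ac**2) + np.sum(bc**2) - 2.0 * np.sum(s_signed)) / len(a)
    return math.sqrt(max(msd, 0.0))


def _lipid_stream(seed: int, lipid_name: str) -> np.random.Generator:
    """Per-lipid RNG stream, independent of library processing order."""
    tag = zlib.crc32(lipid_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, tag]))


def sample_conformers(spec: LipidSpec, max_conformers: int, seed: int,
                      clash_min_dist: float = CLASH_MIN_DIST,
                      redundancy_rmsd: float = REDUNDANCY_RMSD,
                      max_attempts: Optional[int] = None) -> ConformerEnsemble:
    """Sample up to ``max_conformers`` clash-free, non-redundant conformers.

    Rotatable torsions are drawn from anti/gauche rotamer states with
    Gaussian jitter; candidates failing the hard-sphere clash filter are
    rejected, and candidates within ``redundancy_rmsd`` backbone RMSD of an
    already-accepted conformer are dropped.  Short chains have few rotamer
    states and may legitimately yield fewer conformers than requested.
    """
    if max_conformers < 1:
        raise ValueError("max_conformers must be >= 1")
    name = canonical_name(spec).short_name
    rng = _lipid_stream(seed, name)
    n_rot = rotatable_torsion_count(spec)
    if max_attempts is None:
        max_attempts = max(200, 10 * max_conformers)

    # Draw clash-free candidates, then keep the lowest-strain non-redundant
    # ones: candidates are ranked by a simple rotamer strain energy
    # (GAUCHE_PENALTY_KCAL per gauche torsion) and accepted greedily in
    # energy order, mirroring a low-energy-first conformer generator.
    candidates: list[tuple[float, int, Conformer]] = []
    for attempt in range(max_attempts):
        states = rng.choice(ROTAMER_STATES, size=n_rot, p=ROTAMER_WEIGHTS)
        torsions = states + rng.normal(0.0, TORSION_JITTER_SD, size=n_rot)
        conf = build_geometry(spec, torsions)
        if has_clash(conf, spec, clash_min_dist):
            continue
        energy = GAUCHE_PENALTY_KCAL * float(np.sum(states != ROTAMER_STATES[0]))
        candidates.append((energy, attempt, conf))
    candidates.sort(key=lambda t: (t[0], t[1]))

    accepted: list[Conformer] = []
    accepted_bb: list[np.ndarray] = []
    for _, _, conf in candidates:
        if len(accepted) >= max_conformers:
            break
        bb = conf.carbons
        if any(backbone_rmsd(bb, prev) < redundancy_rmsd for prev in accepted_bb):
            continue
        accepted.append(conf)
        accepted_bb.append(bb)
    return ConformerEnsemble(lipid=name, conformers=accepted, seed=seed,
                             requested=max_conformers)


# ---------------------------------------------------------------------------
# Multi-frame XYZ I/O


def write_xyz(ensembles: Sequence[ConformerEnsemble], path: str) -> None:
    """Write a multi-frame XYZ file (one frame per conformer).

    Frame order within each ensemble is preserved; atoms are backbone
    carbons C1..Cn, then the CpFA ring methylene, then the two carboxyl
    oxygens.  The comment line carries the lipid name and conformer index.
    """
    with open(path, "w") as fh:
        for ens in ensembles:
            for idx, conf in enumerate(ens.conformers):
                pts = [("C", row) for row in conf.carbons]
                if conf.ring_methylene is not None:
                    pts.append(("C", conf.ring_methylene))
                pts.extend(("O", row) for row in conf.oxygens)
                fh.write(f"{len(pts)}\n")
                # spaces in lipid names encoded as underscores (XYZ comment
                # fields are whitespace-delimited)
                fh.write(f"lipid={conf.lipid.replace(' ', '_')} conformer={idx}\n")
                for el, (x, y, z) in pts:
                    fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str) -> list[ConformerEnsemble]:
    """Read a multi-frame XYZ file written by :func:`write_xyz`."""
    frames: dict[str, list[Conformer]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n_atoms = int(lines[i].strip())
        comment = lines[i + 1]
        fields = dict(tok.split("=", 1) for tok in comment.split() if "=" in tok)
        lipid = fields["lipid"].replace("_", " ")
        rows = []
        elements = []
        for line in lines[i + 2: i + 2 + n_atoms]:
            parts = line.split()
            elements.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        i += 2 + n_atoms
        pts = np.array(rows)
        spec = parse_name(lipid)
        nb = spec.backbone_length
        carbons = pts[:nb]
        cursor = nb
        ring = None
        if spec.lipid_class is LipidClass.CpFA:
            ring = pts[cursor]
            cursor += 1
        oxygens = pts[cursor: cursor + 2]
        frames.setdefault(lipid, []).append(
            Conformer(lipid=lipid, carbons=carbons, oxygens=oxygens,
                      ring_methylene=ring)
        )
    return [
        ConformerEnsemble(lipid=lip, conformers=confs, seed=-1,
                          requested=len(confs))
        for lip, confs in frames.items()
    ]
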