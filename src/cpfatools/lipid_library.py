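"""Exhaustive enumeration of single-modification fatty-acid species.

The library covers every saturated fatty acid (SFA), every *cis*
mono-unsaturated fatty acid (MUFA) and every *cis* cyclopropane fatty acid
(CpFA) with a backbone of ``min_len``..``max_len`` carbons.  A MUFA carries
one C=C double bond spanning backbone carbons ``p`` and ``p+1``; a CpFA
carries a cyclopropane ring whose two base carbons are backbone carbons
``p`` and ``p+1`` plus one extra methylene bridging them.  Position ``p``
indexes the backbone starting from the carboxyl carbon (C1), so e.g.
oleic acid is the MUFA (n=18, p=9) and lactobacillic acid the CpFA
(n=18, p=11).

Naming conventions
------------------
* SFA:  ``Cn``            (e.g. ``C18``, stearic acid)
* MUFA: ``Cn:1 cis-p``    (e.g. ``C18:1 cis-9``, oleic acid)
* CpFA: ``CnD1 cis-p`` rendered with a Greek delta, ``CnΔ1 cis-p``; the
  methylene "P" notation is ``p,(p+1)-P-(n+1):0`` — the total carbon
  count (backbone + ring methylene) with the ring-base positions in front.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass
from typing import Iterator, Optional

from rdkit import Chem


class LipidClass(enum.Enum):
    """Fatty-acid class: saturated, mono-unsaturated, or cyclopropane."""

    SFA = "SFA"
    MUFA = "MUFA"
    CpFA = "CpFA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Trivial names for the species discussed most often in the CpFA
#: literature (ring/double-bond position keyed by (class, n, p)).
TRIVIAL_NAMES = {
    (LipidClass.CpFA, 18, 11): "lactobacillic acid",
    (LipidClass.CpFA, 18, 9): "dihydrosterculic acid",
    (LipidClass.CpFA, 16, 9): "CPOA2H",
    (LipidClass.MUFA, 18, 11): "cis-vaccenic acid",
    (LipidClass.MUFA, 18, 9): "oleic acid",
}


@dataclass(frozen=True, order=True)
class LipidSpec:
    """One fatty-acid species: class, backbone length and modification position.

    Parameters
    ----------
    lipid_class:
        SFA, MUFA or CpFA.
    backbone_length:
        Number of backbone carbons ``n`` (carboxyl carbon = C1).  The CpFA
        ring methylene is *not* counted here; a CpFA has ``n + 1`` carbons
        in total.
    mod_position:
        First backbone carbon ``p`` of the double bond (MUFA) or of the
        cyclopropane ring base (CpFA); the modification spans carbons
        ``p`` and ``p+1``.  ``None`` for SFA.
    """

    lipid_class: LipidClass
    backbone_length: int
    mod_position: Optional[int] = None

    def __post_init__(self) -> None:
        n, p = self.backbone_length, self.mod_position
        if n < 2:
            raise ValueError(f"backbone_length must be >= 2, got {n}")
        if self.lipid_class is LipidClass.SFA:
            if p is not None:
                raise ValueError("SFA must not carry a modification position")
        else:
            if p is None:
                raise ValueError(f"{self.lipid_class} requires a modification position")
            if not 2 <= p <= n - 1:
                raise ValueError(
                    f"modification position must satisfy 2 <= p <= n-1; got p={p}, n={n}"
                )

    @property
    def total_carbons(self) -> int:
        """Total carbon count (backbone plus the CpFA ring methylene)."""
        extra = 1 if self.lipid_class is LipidClass.CpFA else 0
        return self.backbone_length + extra

    @property
    def short_name(self) -> str:
        return canonical_name(self).short_name


@dataclass(frozen=True)
class NameRecord:
    """Canonical names of one lipid: short name, P-notation, trivial name."""

    short_name: str
    p_notation: Optional[str]
    trivial_name: Optional[str]


class InvalidRangeError(ValueError):
    """min_len/max_len do not define a valid enumeration range."""


def enumerate_library(min_len: int, max_len: int) -> list[LipidSpec]:
    """Enumerate every SFA, cis-MUFA and cis-CpFA in a backbone-length range.

    For each length ``n`` there is exactly one SFA and ``n - 2`` positional
    isomers each of MUFA and CpFA (positions ``p = 2 .. n-1``).  The
    returned order is canonical and deterministic: by class (SFA, MUFA,
    CpFA), then length, then position.

    >>> len(enumerate_library(12, 24))
    429
    """
    if min_len < 2:
        raise InvalidRangeError(f"min_len must be >= 2, got {min_len}")
    if min_len > max_len:
        raise InvalidRangeError(f"min_len ({min_len}) > max_len ({max_len})")

    specs: list[LipidSpec] = []
    for cls in (LipidClass.SFA, LipidClass.MUFA, LipidClass.CpFA):
        for n in range(min_len, max_len + 1):
            if cls is LipidClass.SFA:
                specs.append(LipidSpec(cls, n))
            else:
                specs.extend(LipidSpec(cls, n, p) for p in range(2, n))
    return specs


def canonical_name(spec: LipidSpec) -> NameRecord:
    """Return the short name, the CpFA "P" notation and any trivial name."""
    n, p = spec.backbone_length, spec.mod_position
    if spec.lipid_class is LipidClass.SFA:
        return NameRecord(f"C{n}", None, None)
    trivial = TRIVIAL_NAMES.get((spec.lipid_class, n, p))
    if spec.lipid_class is LipidClass.MUFA:
        return NameRecord(f"C{n}:1 cis-{p}", None, trivial)
    # CpFA: one ring ("Δ1"), ring base at p..p+1; total carbons n+1.
    p_notation = f"{p},{p + 1}-P-{n + 1}:0"
    return NameRecord(f"C{n}Δ1 cis-{p}", p_notation, trivial)


_SFA_RE = re.compile(r"^C(\d+)$")
_MUFA_RE = re.compile(r"^C(\d+):1 cis-(\d+)$")
_CPFA_RE = re.compile(r"^C(\d+)Δ1 cis-(\d+)$")


def parse_name(short_name: str) -> LipidSpec:
    """Inverse of :func:`canonical_name` for short names."""
    if m := _SFA_RE.match(short_name):
        return LipidSpec(LipidClass.SFA, int(m.group(1)))
    if m := _MUFA_RE.match(short_name):
        return LipidSpec(LipidClass.MUFA, int(m.group(1)), int(m.group(2)))
    if m := _CPFA_RE.match(short_name):
        return LipidSpec(LipidClass.CpFA, int(m.group(1)), int(m.group(2)))
    raise ValueError(f"unrecognized lipid short name: {short_name!r}")


def to_smiles(spec: LipidSpec) -> str:
    """Emit an isomer-explicit SMILES string for one lipid.

    The carboxylic acid is written first, then the backbone from C2 to Cn.
    MUFAs carry explicit cis (Z) double-bond direction marks.  CpFAs
    carry tetrahedral marks on the two ring base carbons chosen so that
    the two chain substituents sit on the same face of the cyclopropane
    ring (cis); the ring methylene is written as a bridging ``C1`` ring
    closure.  Output is canonicalized by RDKit.
    """
    n, p = spec.backbone_length, spec.mod_position
    if spec.lipid_class is LipidClass.SFA:
        smiles = "OC(=O)" + "C" * (n - 1)
    elif spec.lipid_class is LipidClass.MUFA:
        # Backbone C2..C(p-1), then /C=C\ spanning Cp..Cp+1, then the tail.
        head = "C" * (p - 2)  # C2..C(p-1)
        tail = "C" * (n - p - 1)  # C(p+2)..Cn
        if tail:
            smiles = "OC(=O)" + head + "/C=C\\" + tail
        else:  # terminal double bond: no cis/trans isomerism
            smiles = "OC(=O)" + head + "C=C"
    else:
        # cis-1,2-disubstituted cyclopropane: like tetrahedral marks on the
        # two ring base carbons (written as ...[C@H]1C[C@H]1...) put both
        # chain substituents on the same ring face.
        head = "C" * (p - 2)
        tail = "C" * (n - p - 1)
        if tail:
            smiles = "OC(=O)" + head + "[C@H]1C[C@H]1" + tail
        else:  # ring at the chain terminus: Cp+1 is an unsubstituted CH2
            smiles = "OC(=O)" + head + "C1CC1"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - construction is exhaustive-tested
        raise RuntimeError(f"internal SMILES failed to parse: {smiles}")
    return Chem.MolToSmiles(mol)


def write_manifest(specs: list[LipidSpec], path: str) -> None:
    """Write a CSV manifest: class, n, p, short_name, p_notation, smiles."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "n", "p", "short_name", "p_notation", "smiles"])
        for spec in specs:
            rec = canonical_name(spec)
            writer.writerow(
                [
                    spec.lipid_class.value,
                    spec.backbone_length,
                    spec.mod_position if spec.mod_position is not None else "",
                    rec.short_name,
                    rec.p_notation or "",
                    to_smiles(spec),
                ]
            )


def write_smiles_list(specs: list[LipidSpec], path: str) -> None:
    """Write one ``SMILES<TAB>name`` line per lipid."""
    with open(path, "w") as fh:
        for spec in specs:
            fh.write(f"{to_smiles(spec)}\t{canonical_name(spec).short_name}\n")


def iter_class_counts(specs: list[LipidSpec]) -> dict[str, int]:
    """Count library members per class."""
    counts = {cls.value: 0 for cls in LipidClass}
    for spec in specs:
        counts[spec.lipid_class.value] += 1
    return counts
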