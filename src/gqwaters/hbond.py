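"""Donor/acceptor role assignment and hydrogen-bond detection.

Hydrogen bonds are accepted on a donor-acceptor distance cutoff (default
3.25 A) plus, optionally, an angular criterion.  Crystal structures at the
resolutions considered here carry no hydrogen positions, so three angle modes
are offered:

``distance_only``
    the cutoff alone;
``antecedent_proxy`` (default)
    the angle antecedent-donor-acceptor must lie within ``max_angle_deviation``
    of the donor's ideal hybridisation angle (sp2: 120 deg, sp3: 109.5 deg);
``ideal_hydrogen``
    an idealised hydrogen is placed anti to the centroid of the donor's
    covalent antecedents and the donor-H...acceptor angle must deviate from
    linearity by at most ``max_angle_deviation``.

Water oxygens are free rotors with no antecedent and are exempt from any
angle test.

A named preset ``table2`` (3.45 A, distance only) reproduces published
contact tables that list contacts slightly beyond the 3.25 A rule.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_model import Atom, Residue, Structure

__all__ = [
    "HBondCriteria",
    "RoleEntry",
    "RoleTable",
    "BondAtom",
    "HydrogenBond",
    "ContactTableError",
    "assign_roles",
    "detect_hbonds",
    "load_contact_table",
    "write_contact_table",
    "bond_category",
    "CATEGORY_ORDER",
]

IDEAL_ANGLE = {"sp2": 120.0, "sp3": 109.5}

#: kind rank used to orient unordered bonds and name categories
_KIND_RANK = {"ligand": 0, "water": 1, "nucleotide": 2, "dna": 2, "ion": 3, "other": 4}

CATEGORY_ORDER = ["ligand-dna", "ligand-water", "water-water", "water-dna", "dna-dna"]


class ContactTableError(ValueError):
    """Raised when a contact-table record cannot be classified."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance rules for a donor-acceptor contact."""

    max_distance: float = 3.25
    max_angle_deviation: float = 30.0
    angle_mode: str = "antecedent_proxy"

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0 <= self.max_angle_deviation <= 180:
            raise ValueError("max_angle_deviation must be in [0, 180]")
        if self.angle_mode not in ("ideal_hydrogen", "antecedent_proxy", "distance_only"):
            raise ValueError(f"unknown angle_mode {self.angle_mode!r}")

    @classmethod
    def preset(cls, name: str) -> "HBondCriteria":
        if name == "default":
            return cls()
        if name == "table2":
            return cls(max_distance=3.45, angle_mode="distance_only")
        raise ValueError(f"unknown criteria preset {name!r}")


@dataclass(frozen=True)
class RoleEntry:
    """Hydrogen-bonding role of one named atom."""

    role: str  # donor | acceptor | both | none
    hybridization: Optional[str] = None  # sp2 | sp3
    antecedents: tuple[str, ...] = ()

    @property
    def can_donate(self) -> bool:
        return self.role in ("donor", "both")

    @property
    def can_accept(self) -> bool:
        return self.role in ("acceptor", "both")


_NONE = RoleEntry("none")

# Base edges: donors carry their covalent ring-carbon antecedent for the
# angular criteria; backbone oxygens are acceptors on every nucleotide.
_BASE_ROLES: dict[str, dict[str, RoleEntry]] = {
    "DG": {
        "N1": RoleEntry("donor", "sp2", ("C2", "C6")),
        "N2": RoleEntry("donor", "sp2", ("C2",)),
        "O6": RoleEntry("acceptor", "sp2", ("C6",)),
        "N3": RoleEntry("acceptor", "sp2", ("C2", "C4")),
        "N7": RoleEntry("acceptor", "sp2", ("C5", "C8")),
    },
    "DA": {
        "N6": RoleEntry("donor", "sp2", ("C6",)),
        "N1": RoleEntry("acceptor", "sp2", ("C2", "C6")),
        "N3": RoleEntry("acceptor", "sp2", ("C2", "C4")),
        "N7": RoleEntry("acceptor", "sp2", ("C5", "C8")),
    },
    "DT": {
        "N3": RoleEntry("donor", "sp2", ("C2", "C4")),
        "O2": RoleEntry("acceptor", "sp2", ("C2",)),
        "O4": RoleEntry("acceptor", "sp2", ("C4",)),
    },
    "DC": {
        "N4": RoleEntry("donor", "sp2", ("C4",)),
        "N3": RoleEntry("acceptor", "sp2", ("C2", "C4")),
        "O2": RoleEntry("acceptor", "sp2", ("C2",)),
    },
}
_BASE_ROLES["DU"] = _BASE_ROLES["DT"]
for _one, _three in [("G", "DG"), ("A", "DA"), ("T", "DT"), ("C", "DC"), ("U", "DU")]:
    _BASE_ROLES[_one] = _BASE_ROLES[_three]

_BACKBONE_ROLES: dict[str, RoleEntry] = {
    "OP1": RoleEntry("acceptor", "sp3", ("P",)),
    "OP2": RoleEntry("acceptor", "sp3", ("P",)),
    "O1P": RoleEntry("acceptor", "sp3", ("P",)),
    "O2P": RoleEntry("acceptor", "sp3", ("P",)),
    "O4'": RoleEntry("acceptor", "sp3", ("C4'", "C1'")),
    "O5'": RoleEntry("acceptor", "sp3", ("C5'", "P")),
    "O3'": RoleEntry("acceptor", "sp3", ("C3'",)),
}

_WATER_ROLE = RoleEntry("both", None, ())


@dataclass
class RoleTable:
    """Mapping from (residue code, atom name) to a :class:`RoleEntry`.

    Built-in chemistry covers DNA/RNA nucleotides and waters; ligand atoms
    acquire roles only through explicit overrides.
    """

    overrides: dict[tuple[str, str], RoleEntry] = field(default_factory=dict)

    def lookup(self, residue: Residue, atom: Atom) -> RoleEntry:
        key = (residue.name.upper(), atom.name)
        if key in self.overrides:
            return self.overrides[key]
        wild = ("*", atom.name)
        if wild in self.overrides:
            return self.overrides[wild]
        if residue.category == "water":
            return _WATER_ROLE if atom.element.upper() == "O" else _NONE
        if residue.category == "nucleotide":
            base = _BASE_ROLES.get(residue.name.upper(), {})
            if atom.name in base:
                return base[atom.name]
            return _BACKBONE_ROLES.get(atom.name, _NONE)
        return _NONE

    def add(
        self,
        res_code: str,
        atom_name: str,
        role: str,
        hybridization: Optional[str] = None,
        antecedents: Sequence[str] = (),
    ) -> None:
        self.overrides[(res_code.upper(), atom_name)] = RoleEntry(
            role, hybridization, tuple(antecedents)
        )


def assign_roles(
    structure: Structure,
    overrides: Optional[Mapping[tuple[str, str], RoleEntry] | RoleTable] = None,
) -> RoleTable:
    """Build the role table for a structure, applying ligand overrides.

    Overrides naming atoms absent from the structure trigger a warning,
    not a failure.
    """
    if isinstance(overrides, RoleTable):
        table = RoleTable(dict(overrides.overrides))
    else:
        table = RoleTable(dict(overrides or {}))
    present: set[tuple[str, str]] = set()
    for res in structure.residues:
        for atom in res.atoms:
            present.add((res.name.upper(), atom.name))
    for (code, name) in table.overrides:
        if code != "*" and (code, name) not in present:
            warnings.warn(
                f"role override for absent atom {code}/{name}", stacklevel=2
            )
    return table


@dataclass(frozen=True)
class BondAtom:
    """Identity of one hydrogen-bond endpoint, carried into the network stage."""

    label: str  # "W204", "NCH", "OP2 dG10"
    kind: str  # ligand | water | dna | ion | other
    b_factor: Optional[float] = None

    def __str__(self) -> str:
        return self.label


def _atom_kind(residue: Residue) -> str:
    if residue.category == "nucleotide":
        return "dna"
    return residue.category


def _atom_label(residue: Residue, atom: Atom) -> str:
    if residue.category == "water":
        return residue.label
    if residue.category == "nucleotide":
        return f"{atom.name} {residue.label}"
    return atom.name


def bond_category(kind_a: str, kind_b: str) -> str:
    a, b = sorted((kind_a, kind_b), key=lambda k: _KIND_RANK.get(k, 9))
    return f"{a}-{b}"


@dataclass(frozen=True)
class HydrogenBond:
    """An accepted donor-acceptor contact (unordered pair)."""

    atom_a: BondAtom
    atom_b: BondAtom
    distance: float
    angle_deviation: Optional[float] = None
    category: str = ""
    group: Optional[str] = None

    def __post_init__(self) -> None:
        a, b = self.atom_a, self.atom_b
        if (_KIND_RANK.get(a.kind, 9), a.label) > (_KIND_RANK.get(b.kind, 9), b.label):
            object.__setattr__(self, "atom_a", b)
            object.__setattr__(self, "atom_b", a)
        if not self.category:
            object.__setattr__(
                self, "category", bond_category(self.atom_a.kind, self.atom_b.kind)
            )

    @property
    def labels(self) -> frozenset[str]:
        return frozenset((self.atom_a.label, self.atom_b.label))


def _angle_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def _angle_deviation(
    donor_res: Residue,
    donor: Atom,
    entry: RoleEntry,
    acceptor_pos: np.ndarray,
    mode: str,
) -> Optional[float]:
    """Angular deviation from ideality for a candidate donor->acceptor bond.

    Returns ``None`` when the donor is angle-exempt (waters, or donors with
    no located antecedent)."""
    if mode == "distance_only":
        return None
    if donor_res.category == "water":
        return None
    ante = [donor_res.atom(n) for n in entry.antecedents]
    ante_pos = [a.position for a in ante if a is not None]
    if not ante_pos:
        return None
    if mode == "antecedent_proxy":
        ideal = IDEAL_ANGLE.get(entry.hybridization or "sp3", 109.5)
        devs = [
            abs(_angle_deg(p, donor.position, acceptor_pos) - ideal) for p in ante_pos
        ]
        return min(devs)
    # ideal_hydrogen: H placed 0.98 A from the donor, anti to the antecedent
    # centroid; ideality is a linear D-H...A arrangement.
    centroid = np.mean(ante_pos, axis=0)
    direction = donor.position - centroid
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        return None
    h_pos = donor.position + 0.98 * direction / norm
    return 180.0 - _angle_deg(donor.position, h_pos, acceptor_pos)


def detect_hbonds(
    structure: Structure,
    roles: RoleTable,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HydrogenBond]:
    """Find all donor-acceptor pairs satisfying the geometric criteria.

    A pair is accepted when one atom can donate, the other can accept, their
    distance is within the cutoff and the donor passes the angle test in at
    least one donor/acceptor assignment.  Pairs within the same residue are
    excluded.  Results are identical to an all-pairs search (the k-d tree is
    an optimisation only) and are sorted by (category, distance, labels).
    """
    entries: list[tuple[Residue, Atom, RoleEntry]] = []
    for res in structure.residues:
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            entry = roles.lookup(res, atom)
            if entry.role != "none":
                entries.append((res, atom, entry))
    if not entries:
        return []

    coords = np.array([a.position for _, a, _ in entries])
    tree = cKDTree(coords)
    bonds: list[HydrogenBond] = []
    for i, j in sorted(tree.query_pairs(criteria.max_distance)):
        res_i, atom_i, entry_i = entries[i]
        res_j, atom_j, entry_j = entries[j]
        if res_i is res_j:
            continue
        dist = float(np.linalg.norm(atom_i.position - atom_j.position))
        accepted_dev: Optional[float] = None
        ok = False
        for (dres, datom, dentry), (_, aatom, aentry) in (
            ((res_i, atom_i, entry_i), (res_j, atom_j, entry_j)),
            ((res_j, atom_j, entry_j), (res_i, atom_i, entry_i)),
        ):
            if not (dentry.can_donate and aentry.can_accept):
                continue
            dev = _angle_deviation(
                dres, datom, dentry, aatom.position, criteria.angle_mode
            )
            if dev is None or dev <= criteria.max_angle_deviation:
                ok = True
                accepted_dev = dev
                break
        if not ok:
            continue
        bonds.append(
            HydrogenBond(
                atom_a=BondAtom(_atom_label(res_i, atom_i), _atom_kind(res_i), atom_i.b_factor),
                atom_b=BondAtom(_atom_label(res_j, atom_j), _atom_kind(res_j), atom_j.b_factor),
                distance=dist,
                angle_deviation=accepted_dev,
            )
        )
    bonds.sort(key=lambda b: (b.category, b.distance, b.atom_a.label, b.atom_b.label))
    return bonds


_WATER_LABEL = re.compile(r"^W\d+$")
_DNA_LABEL = re.compile(r"^\S+\s+d?[GATCUI]\d+$")


def _classify_label(label: str, ligand_atoms: frozenset[str]) -> str:
    label = label.strip()
    if label in ligand_atoms:
        return "ligand"
    if _WATER_LABEL.match(label):
        return "water"
    if _DNA_LABEL.match(label):
        return "dna"
    raise ContactTableError(
        f"cannot classify contact-table label {label!r}: not a configured ligand "
        "atom, not a W-number, not an atom+residue pair"
    )


def load_contact_table(
    source: Union[str, Path, pd.DataFrame, Iterable[Mapping]],
    ligand_atoms: Iterable[str],
) -> list[HydrogenBond]:
    """Read a published-style contact table into :class:`HydrogenBond` objects.

    Expected columns: ``atom_a``, ``atom_b``, ``distance_A``, optional ``b_a``,
    ``b_b`` and ``group_label``.  Endpoint kinds are inferred from label
    conventions: a W-prefixed number is a water, a name in ``ligand_atoms`` is
    a ligand atom, an "atom residue" pair (``OP2 dG10``) is DNA.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", comment="#")
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.DataFrame(list(source))
    ligand_atoms = frozenset(ligand_atoms)
    bonds: list[HydrogenBond] = []
    for _, row in df.iterrows():
        label_a = str(row["atom_a"]).strip()
        label_b = str(row["atom_b"]).strip()
        kind_a = _classify_label(label_a, ligand_atoms)
        kind_b = _classify_label(label_b, ligand_atoms)
        b_a = float(row["b_a"]) if "b_a" in row and pd.notna(row.get("b_a")) else None
        b_b = float(row["b_b"]) if "b_b" in row and pd.notna(row.get("b_b")) else None
        group = row.get("group_label")
        group = str(group) if pd.notna(group) and group is not None else None
        bonds.append(
            HydrogenBond(
                atom_a=BondAtom(label_a, kind_a, b_a),
                atom_b=BondAtom(label_b, kind_b, b_b),
                distance=float(row["distance_A"]),
                group=group,
            )
        )
    return bonds


def write_contact_table(bonds: Iterable[HydrogenBond], path: str | Path) -> Path:
    """Write bonds as TSV with distances rounded to 1 dp, B factors as printed."""
    rows = []
    for b in bonds:
        rows.append(
            {
                "atom_a": b.atom_a.label,
                "atom_b": b.atom_b.label,
                "distance_A": f"{b.distance:.1f}",
                "b_a": "" if b.atom_a.b_factor is None else f"{b.atom_a.b_factor:.0f}",
                "b_b": "" if b.atom_b.b_factor is None else f"{b.atom_b.b_factor:.0f}",
                "category": b.category,
                "group_label": b.group or "",
            }
        )
    pd.DataFrame(
        rows,
        columns=["atom_a", "atom_b", "distance_A", "b_a", "b_b", "category", "group_label"],
    ).to_csv(path, sep="\t", index=False)
    return Path(path)
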