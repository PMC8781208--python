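"""Crystal-structure data model, PDB/mmCIF I/O and the structure-acceptance filter.

The in-memory model is deliberately small: an :class:`Atom` knows its name,
element, position, B factor, occupancy and altloc; a :class:`Residue` carries a
category (``nucleotide``, ``water``, ``ligand``, ``ion`` or ``other``) assigned
deterministically from its residue code and a user-supplied ligand-code list;
a :class:`Structure` is an ordered residue collection with an id, resolution
and source format.  Parsing and serialisation go through gemmi, so anything
gemmi reads (PDB, mmCIF) is accepted.

Conventions baked in:

* coordinates are Angstroms throughout, no unit layer;
* only model 1 of multi-model files is used (all target structures are X-ray);
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by the alphabetically first altloc code);
* hydrogens are parsed only on request and ignored by default — crystal
  structures at ~2 A resolution do not resolve them;
* waters are displayed as ``W`` + author sequence number (``W204``), matching
  the labelling convention of published contact tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "AcceptanceCriteria",
    "AcceptanceDecision",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "DEFAULT_WATER_CODES",
    "DEFAULT_ION_CODES",
    "NUCLEOTIDE_CODES",
    "read_structure",
    "write_structure",
    "accept_structure",
]


class StructureError(Exception):
    """Base error for structure I/O and validation."""


class FormatError(StructureError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(StructureError):
    """Raised when a coordinate file contains no usable atoms."""


DEFAULT_WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

DEFAULT_ION_CODES = frozenset(
    {"K", "NA", "MG", "CL", "BR", "IOD", "CA", "ZN", "SR", "TL", "MN", "CS", "RB"}
)

NUCLEOTIDE_CODES = frozenset(
    {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "T", "I"}
)

#: single-letter base code used in display labels, e.g. DG -> "dG10"
_BASE_LETTER = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "I",
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T", "I": "I",
}


@dataclass
class Atom:
    """A heavy (or, optionally, hydrogen) atom of a crystal structure."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if self.b_factor < 0:
            raise StructureError(f"atom {self.name}: negative B factor {self.b_factor}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue with a deterministic category."""

    name: str
    seq_number: int
    chain_id: str
    category: str  # nucleotide | water | ligand | ion | other
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        """Display label: ``W204`` for waters, ``dG10`` for nucleotides,
        otherwise ``NAME204``."""
        if self.category == "water":
            return f"W{self.seq_number}"
        if self.category == "nucleotide":
            letter = _BASE_LETTER.get(self.name.upper(), self.name)
            return f"d{letter}{self.seq_number}"
        return f"{self.name}{self.seq_number}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_number)


@dataclass
class Structure:
    """An ordered collection of residues plus file-level metadata."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    resolution: Optional[float] = None
    source_format: str = "PDB"

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def residues_of(self, category: str) -> list[Residue]:
        return [r for r in self.residues if r.category == category]

    @property
    def waters(self) -> list[Residue]:
        return self.residues_of("water")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def find_residue(self, chain_id: str, seq_number: int) -> Optional[Residue]:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_number == seq_number:
                return r
        return None


@dataclass
class AcceptanceCriteria:
    """Filter deciding whether a structure is suitable for water analysis.

    ``max_resolution`` defaults to 2.5 A; ``require_ligand_contacting_water``
    demands at least one accepted ligand-water hydrogen bond.
    """

    max_resolution: float = 2.5
    require_ligand_contacting_water: bool = True

    def __post_init__(self) -> None:
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")


@dataclass
class AcceptanceDecision:
    accepted: bool
    reasons: list[str]

    def __bool__(self) -> bool:
        return self.accepted


def _categorize(
    res_name: str,
    n_heavy: int,
    ligand_codes: frozenset[str],
    water_codes: frozenset[str],
    ion_codes: frozenset[str],
) -> str:
    code = res_name.upper()
    if code in water_codes:
        return "water"
    if code in ligand_codes:
        return "ligand"
    if code in NUCLEOTIDE_CODES:
        return "nucleotide"
    if code in ion_codes and n_heavy <= 1:
        return "ion"
    return "other"


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by the
    alphabetically first altloc code."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _altloc_rank(code: str) -> float:
    # higher rank wins on occupancy ties -> alphabetically first altloc
    return -ord(code) if code else 0.0


def read_structure(
    path: str | Path,
    ligand_codes: Iterable[str] = (),
    water_codes: Iterable[str] = DEFAULT_WATER_CODES,
    ion_codes: Iterable[str] = DEFAULT_ION_CODES,
    keep_hydrogens: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Ligand residues are identified only by the explicit ``ligand_codes`` list,
    never by heuristics.  Altlocs are resolved to a single conformer and, by
    default, hydrogens are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    ligand_codes = frozenset(c.upper() for c in ligand_codes)
    water_codes = frozenset(c.upper() for c in water_codes)
    ion_codes = frozenset(c.upper() for c in ion_codes)

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    source_format = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    structure = Structure(
        id=st.name or path.stem, resolution=resolution, source_format=source_format
    )

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = st[0]  # model 1 only
    for chain in model:
        for res in chain:
            atoms = []
            for at in res:
                if at.is_hydrogen() and not keep_hydrogens:
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_factor=max(float(at.b_iso), 0.0),
                        occupancy=min(max(float(at.occ), 0.0), 1.0),
                        altloc=at.altloc.strip() if at.altloc else "",
                    )
                )
            if not atoms:
                continue
            atoms = _resolve_altlocs(atoms)
            n_heavy = sum(1 for a in atoms if not a.is_hydrogen)
            category = _categorize(res.name, n_heavy, ligand_codes, water_codes, ion_codes)
            structure.residues.append(
                Residue(
                    name=res.name,
                    seq_number=res.seqid.num,
                    chain_id=chain.name,
                    category=category,
                    atoms=atoms,
                )
            )

    if structure.n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    return structure


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Serialise a :class:`Structure` to PDB format via gemmi.

    Round-trips atom names, residue identities, coordinates (3 dp) and
    B factors (2 dp) through :func:`read_structure`.
    """
    if structure.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.id
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    # gemmi's add_* methods copy their argument: build each level fully
    # before attaching it to its parent
    chains: dict[str, gemmi.Chain] = {}
    chain_order: list[str] = []
    for res in structure.residues:
        chain = chains.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = chain
            chain_order.append(res.chain_id)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_number, " ")
        gres.het_flag = "A" if res.category == "nucleotide" else "H"
        for atom in res.atoms:
            if len(atom.name) > 4:
                raise StructureError(
                    f"atom name {atom.name!r} exceeds the 4-character PDB field"
                )
            gat = gemmi.Atom()
            gat.name = atom.name
            gat.element = gemmi.Element(atom.element)
            gat.pos = gemmi.Position(*atom.position)
            gat.b_iso = atom.b_factor
            gat.occ = atom.occupancy
            if atom.altloc:
                gat.altloc = atom.altloc
            gres.add_atom(gat)
        chain.add_residue(gres)
    for chain_id in chain_order:
        model.add_chain(chains[chain_id])
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def accept_structure(
    structure: Structure,
    criteria: AcceptanceCriteria,
    hbonds: Iterable,
) -> AcceptanceDecision:
    """Apply the resolution and mediating-water acceptance rules.

    A structure is accepted iff its resolution is known and <= the cutoff,
    and (when required) at least one hydrogen bond of category
    ``ligand-water`` is present among ``hbonds``.
    """
    reasons: list[str] = []
    if structure.resolution is None:
        reasons.append("unknown resolution")
    elif structure.resolution > criteria.max_resolution:
        reasons.append(
            f"resolution {structure.resolution:.2f} A exceeds cutoff "
            f"{criteria.max_resolution:.2f} A"
        )
    if criteria.require_ligand_contacting_water:
        if not any(getattr(b, "category", None) == "ligand-water" for b in hbonds):
            reasons.append("no water molecule contacting a ligand")
    return AcceptanceDecision(accepted=not reasons, reasons=reasons)
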