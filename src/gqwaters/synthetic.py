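"""Ground-truthed synthetic quadruplex-like scenes for end-to-end testing.

A scene emulates exactly the geometric features the analysis consumes, not
physically realistic quadruplex structure: planar four-fold rings of
pseudo-guanines (real guanine atom names, so the built-in role chemistry
applies unmodified) stacked 3.4 A apart, perimeter phosphate oxygens, a
planar ligand stacked on the top quartet with named basic nitrogens and
carbonyl oxygens, planted ligand -> water^k -> phosphate bridges whose
consecutive contacts sit at a prescribed hydrogen-bond length, decoy waters
placed too far from any polar atom to bond, Gaussian coordinate jitter,
per-category B factors, and a rigid-body "native" copy sharing a chosen
fraction of the waters.

Every generated feature is recorded in a :class:`SceneTruth`, so each
pipeline stage can be checked against planted ground truth with no
downloaded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .structure_model import Atom, Residue, Structure

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "GenerationError",
    "generate_scene",
    "derive_native_copy",
    "random_rotation",
    "scene_role_overrides",
]

#: ligand side-chain nitrogens available as bridge heads, with their covalent
#: antecedent carbons (one per quadruplex groove sector)
LIGAND_NITROGENS = ("NCH", "NCA", "NCE", "NCG")
LIGAND_ANTECEDENTS = {"NCH": "CCH", "NCA": "CCA", "NCE": "CCE", "NCG": "CCG"}

DEFAULT_B_MODEL = {"dna": (25.0, 5.0), "ligand": (50.0, 8.0), "water": (30.0, 6.0)}

_STACK = 3.4  # quartet stacking rise, A
_HB_CUTOFF = 3.25  # default detection cutoff the decoy margin is measured from


class GenerationError(RuntimeError):
    """Raised when a scene cannot be placed under its constraints."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene."""

    n_quartets: int = 3
    waters_per_bridge: int = 2
    n_bridges: int = 2
    n_decoy_waters: int = 10
    hbond_length: float = 2.8
    jitter_sd: float = 0.0
    rigid_transform: Optional[tuple[np.ndarray, np.ndarray]] = None  # (R, t)
    conserved_fraction: float = 1.0
    b_factor_model: dict = field(default_factory=lambda: dict(DEFAULT_B_MODEL))
    decoy_margin: float = 0.5
    seed: int = 0
    ligand_code: str = "LIG"

    def __post_init__(self) -> None:
        if min(self.n_quartets, self.waters_per_bridge, self.n_bridges, self.n_decoy_waters) < 0:
            raise ValueError("scene counts must be non-negative")
        if not 2.4 <= self.hbond_length <= 3.2:
            raise ValueError("hbond_length must lie in [2.4, 3.2] A")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must lie in [0, 1]")
        if self.n_bridges > len(LIGAND_NITROGENS):
            raise ValueError(
                f"at most {len(LIGAND_NITROGENS)} bridges supported (one per groove sector)"
            )
        if self.n_quartets < 1 and self.n_bridges > 0:
            raise ValueError("bridges need at least one quartet for anchors")


@dataclass
class SceneTruth:
    """Planted ground truth of a generated scene."""

    bridges: list[tuple[str, tuple[str, ...], str]] = field(default_factory=list)
    clusters: list[frozenset[str]] = field(default_factory=list)
    shells: dict[str, str] = field(default_factory=dict)
    conserved_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    b_factors: dict[str, float] = field(default_factory=dict)


def scene_role_overrides(ligand_code: str = "LIG"):
    """Hydrogen-bond roles for the synthetic ligand: side-chain nitrogens are
    sp3 donors (emulating protonated basic amines) with their covalent carbon
    as antecedent; the carbonyl oxygens are sp2 acceptors."""
    from .hbond import RoleTable

    table = RoleTable()
    for n in LIGAND_NITROGENS:
        table.add(ligand_code, n, "donor", "sp3", (LIGAND_ANTECEDENTS[n],))
    table.add(ligand_code, "OAF", "acceptor", "sp2", ("C1",))
    table.add(ligand_code, "OAG", "acceptor", "sp2", ("C4",))
    return table


def _guanine_template() -> dict[str, np.ndarray]:
    """Planar pseudo-guanine: regular six-ring fused to a five-ring with O6
    and N2 substituents, bond length 1.39 A, in the xy plane with the O6
    direction along +x (pointing at the quartet centre once placed)."""
    s = 1.39
    hexagon = {}
    names6 = ["C6", "N1", "C2", "N3", "C4", "C5"]
    for i, name in enumerate(names6):
        ang = math.radians(60.0 * i)
        hexagon[name] = np.array([s * math.cos(ang), s * math.sin(ang), 0.0])
    atoms = dict(hexagon)
    # five-ring fused on the C4-C5 edge, on the outside of the hexagon
    p1, p2 = atoms["C4"], atoms["C5"]
    mid = (p1 + p2) / 2
    normal = mid / np.linalg.norm(mid)
    rp = s / (2 * math.sin(math.pi / 5))
    ap = s / (2 * math.tan(math.pi / 5))
    centre = mid + ap * normal
    edge = (p2 - p1) / np.linalg.norm(p2 - p1)
    for name, steps in [("N9", 1), ("C8", 2), ("N7", 3)]:
        # rotate P1 around the pentagon centre by steps*72 deg away from hexagon
        v = p1 - centre
        ang = -math.radians(72.0 * steps)
        cos_a, sin_a = math.cos(ang), math.sin(ang)
        rot = np.array([[cos_a, -sin_a, 0], [sin_a, cos_a, 0], [0, 0, 1.0]])
        cand = centre + rot @ v
        # ensure rotation direction leaves the hexagon interior
        if steps == 1 and np.dot(cand - mid, normal) < 0:
            rot = rot.T
            cand = centre + rot @ v
        atoms[name] = cand
    # substituents point away from the ring centroids
    atoms["O6"] = atoms["C6"] + 1.23 * atoms["C6"] / np.linalg.norm(atoms["C6"])
    atoms["N2"] = atoms["C2"] + 1.34 * atoms["C2"] / np.linalg.norm(atoms["C2"])
    # orient: put O6 direction along +x
    o6_dir = atoms["O6"] / np.linalg.norm(atoms["O6"])
    ang = math.atan2(o6_dir[1], o6_dir[0])
    cos_a, sin_a = math.cos(-ang), math.sin(-ang)
    rot = np.array([[cos_a, -sin_a, 0], [sin_a, cos_a, 0], [0, 0, 1.0]])
    return {n: rot @ p for n, p in atoms.items()}


_TEMPLATE = _guanine_template()

_QUARTET_RADIUS = 5.2  # distance of each base centroid from the quadruplex axis
_PHOSPHATE_RADIUS = 8.6
_LIGAND_N_RADIUS = 7.8

#: jitter vectors are truncated at this many sigma so a planted contact of
#: length `hbond_length` can never drift past the 3.25 A detection cutoff
#: (2.8 + 2 * 1.4 * 0.15 = 3.22 A at the largest supported jitter)
_JITTER_TRUNC = 1.4


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR with sign fix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _place_guanine(sector: int, level: int) -> dict[str, np.ndarray]:
    """Pseudo-guanine in quartet ``level`` at 90 deg sector ``sector``, base
    plane horizontal, O6 pointing at the axis, plus backbone phosphate atoms
    on the perimeter."""
    z = _STACK * level
    angle = math.radians(90.0 * sector)
    rot = _rot_z(angle)
    # base: O6 along +x in template -> flip so O6 points inwards (-radial)
    flip = _rot_z(math.pi)
    centre = rot @ np.array([_QUARTET_RADIUS, 0.0, 0.0]) + np.array([0, 0, z])
    atoms = {n: rot @ (flip @ p) + centre for n, p in _TEMPLATE.items()}
    # backbone anchors on the perimeter, offset from the base sector
    p_dir = rot @ np.array(
        [math.cos(math.radians(25)), math.sin(math.radians(25)), 0.0]
    )
    p_pos = _PHOSPHATE_RADIUS * p_dir + np.array([0, 0, z])
    atoms["P"] = p_pos
    atoms["OP1"] = p_pos + np.array([0.0, 0.0, -1.48])
    atoms["OP2"] = p_pos + 1.48 * p_dir
    # O5' tucked below and behind the phosphate, away from the groove mouth
    # where bridge waters are planted
    atoms["O5'"] = p_pos + rot @ np.array([-0.4, -1.1, -1.1])
    return atoms


def _ligand_atoms() -> dict[str, np.ndarray]:
    """Planar pseudo-ligand: a small carbon core with carbonyl oxygens and
    four side-chain nitrogens (with antecedent carbons) at the groove mouths."""
    atoms: dict[str, np.ndarray] = {}
    for i in range(6):
        ang = math.radians(60.0 * i)
        atoms[f"C{i + 1}"] = np.array([1.4 * math.cos(ang), 1.4 * math.sin(ang), 0.0])
    atoms["OAF"] = np.array([3.0, 0.0, 0.0])
    atoms["OAG"] = np.array([-3.0, 0.0, 0.0])
    for i, name in enumerate(LIGAND_NITROGENS):
        ang = math.radians(45.0 + 90.0 * i)
        direction = np.array([math.cos(ang), math.sin(ang), 0.0])
        atoms[name] = _LIGAND_N_RADIUS * direction
        atoms[LIGAND_ANTECEDENTS[name]] = 6.4 * direction
    return atoms


def _arc_chain(start: np.ndarray, end: np.ndarray, k: int, step: float,
               bulge_dir: np.ndarray) -> list[np.ndarray]:
    """k interior points on a circular arc from start to end such that all
    k+1 consecutive chords have length ``step``; the arc bulges toward
    ``bulge_dir``.  Requires |end - start| < (k+1) * step."""
    chord = end - start
    dist = float(np.linalg.norm(chord))
    if dist >= (k + 1) * step:
        raise GenerationError(
            f"bridge endpoints {dist:.2f} A apart cannot be chained by "
            f"{k} waters at {step:.2f} A steps"
        )
    if k == 0:
        return []
    e1 = chord / dist
    u = bulge_dir - np.dot(bulge_dir, e1) * e1
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        u = np.array([0.0, 0.0, 1.0]) - e1[2] * e1
        nu = np.linalg.norm(u)
    u = u / nu

    def g(theta: float) -> float:
        return dist * math.sin(theta / (2 * (k + 1))) - step * math.sin(theta / 2)

    theta = brentq(g, 1e-9, 2 * math.pi - 1e-9)
    radius = dist / (2 * math.sin(theta / 2))
    c = math.sqrt(max(radius**2 - (dist / 2) ** 2, 0.0))
    mid = (start + end) / 2
    # minor arc: circle centre opposite the bulge; major arc: same side
    if theta <= math.pi:
        centre = mid - c * u
        alpha_start = math.atan2(c, -dist / 2)
    else:
        centre = mid + c * u
        alpha_start = math.atan2(-c, -dist / 2)
    sub = theta / (k + 1)
    points = []
    for i in range(1, k + 1):
        alpha = alpha_start - i * sub
        points.append(centre + radius * (math.cos(alpha) * e1 + math.sin(alpha) * u))
    return points


def _jitter(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Truncated Gaussian displacement: norm capped at ``_JITTER_TRUNC * sd``."""
    v = rng.normal(0.0, sd, size=3) if sd > 0 else np.zeros(3)
    norm = float(np.linalg.norm(v))
    cap = _JITTER_TRUNC * sd
    if norm > cap > 0:
        v = v * (cap / norm)
    return v


def _orient_antecedent(atom: "Atom", donor: np.ndarray, acceptor: np.ndarray) -> None:
    """Move a bridge-head nitrogen's covalent carbon so the antecedent-donor-
    acceptor angle is the sp3 ideal (109.5 deg): planted ligand bonds then
    satisfy the angular criterion by construction."""
    v = acceptor - donor
    v = v / np.linalg.norm(v)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, v)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(v, ref)
    u = u / np.linalg.norm(u)
    ideal = math.radians(109.5)
    atom.position = donor + 1.47 * (math.cos(ideal) * v + math.sin(ideal) * u)


def _draw_b(rng: np.random.Generator, model: dict, category: str) -> float:
    mean, sd = model.get(category, (30.0, 5.0))
    return float(max(rng.normal(mean, sd), 2.0))


def generate_scene(spec: SceneSpec) -> tuple[Structure, SceneTruth]:
    """Generate a scene and its planted truth, deterministically in the seed."""
    rng = np.random.default_rng(spec.seed)
    truth = SceneTruth()
    structure = Structure(id=f"scene-{spec.seed}", resolution=1.95)

    guanine_seq = 0
    anchor_labels: dict[int, str] = {}  # sector -> OP2 label of top-quartet guanine
    for level in range(spec.n_quartets):
        for sector in range(4):
            guanine_seq += 1
            atoms = _place_guanine(sector, level)
            res = Residue(
                name="DG", seq_number=guanine_seq, chain_id="A", category="nucleotide"
            )
            for name, pos in atoms.items():
                element = name[0]
                res.atoms.append(
                    Atom(name=name, element=element, position=pos.copy(),
                         b_factor=_draw_b(rng, spec.b_factor_model, "dna"))
                )
            structure.residues.append(res)
            if level == spec.n_quartets - 1:
                anchor_labels[sector] = f"OP2 dG{guanine_seq}"

    z_top = _STACK * (spec.n_quartets - 1)
    ligand_res = Residue(
        name=spec.ligand_code, seq_number=101, chain_id="B", category="ligand"
    )
    lig_positions = {}
    lig_atoms_by_name: dict[str, Atom] = {}
    for name, pos in _ligand_atoms().items():
        p = pos + np.array([0.0, 0.0, z_top + _STACK])
        lig_positions[name] = p
        atom = Atom(name=name, element=name[0], position=p,
                    b_factor=_draw_b(rng, spec.b_factor_model, "ligand"))
        ligand_res.atoms.append(atom)
        lig_atoms_by_name[name] = atom
    structure.residues.append(ligand_res)

    # planted bridges: one per sector, ligand nitrogen -> k waters -> OP2
    water_seq = 200
    top_guanines = [r for r in structure.residues
                    if r.category == "nucleotide"][-4:] if spec.n_quartets else []
    for b in range(spec.n_bridges):
        nitrogen = LIGAND_NITROGENS[b]
        start = lig_positions[nitrogen]
        anchor_label = anchor_labels[b]
        anchor_res = top_guanines[b]
        end = anchor_res.atom("OP2").position
        radial = (start + end) / 2
        bulge = np.array([radial[0], radial[1], 0.0])
        bulge = bulge / max(np.linalg.norm(bulge), 1e-9) + np.array([0.0, 0.0, 0.8])
        points = _arc_chain(start, end, spec.waters_per_bridge, spec.hbond_length, bulge)
        chain_labels = []
        first_contact = points[0] if points else end
        _orient_antecedent(
            lig_atoms_by_name[LIGAND_ANTECEDENTS[nitrogen]], start, first_contact
        )
        for p in points:
            water_seq += 1
            jittered = p + _jitter(rng, spec.jitter_sd)
            res = Residue(name="HOH", seq_number=water_seq, chain_id="W",
                          category="water")
            res.atoms.append(
                Atom(name="O", element="O", position=jittered,
                     b_factor=_draw_b(rng, spec.b_factor_model, "water"))
            )
            structure.residues.append(res)
            chain_labels.append(res.label)
            truth.b_factors[res.label] = res.atoms[0].b_factor
        truth.bridges.append((nitrogen, tuple(chain_labels), anchor_label))
        if chain_labels:
            truth.clusters.append(frozenset(chain_labels))
            for i, lbl in enumerate(chain_labels):
                edge = i == 0 or i == len(chain_labels) - 1
                truth.shells[lbl] = "first" if edge else "second"

    # decoy waters: beyond bonding reach of every polar atom and of each other
    polar = np.array(
        [a.position for r in structure.residues for a in r.atoms
         if a.element in ("N", "O", "P")]
    ).reshape(-1, 3)
    min_sep = _HB_CUTOFF + spec.decoy_margin
    decoys: list[np.ndarray] = []
    for _ in range(spec.n_decoy_waters):
        placed = False
        for _attempt in range(2000):
            r = rng.uniform(13.0, 19.0)
            ang = rng.uniform(0, 2 * math.pi)
            z = rng.uniform(-4.0, z_top + 7.0)
            cand = np.array([r * math.cos(ang), r * math.sin(ang), z])
            dists = [np.linalg.norm(cand - p) for p in polar]
            if decoys:
                dists += [np.linalg.norm(cand - d) for d in decoys]
            if min(dists) >= min_sep:
                decoys.append(cand)
                placed = True
                break
        if not placed:
            raise GenerationError(
                "could not place a decoy water outside the "
                f"{min_sep:.2f} A exclusion zone after bounded retries"
            )
    for cand in decoys:
        water_seq += 1
        res = Residue(name="HOH", seq_number=water_seq, chain_id="W", category="water")
        res.atoms.append(
            Atom(name="O", element="O", position=cand,
                 b_factor=_draw_b(rng, spec.b_factor_model, "water"))
        )
        structure.residues.append(res)
        truth.clusters.append(frozenset({res.label}))
        truth.shells[res.label] = "bulk-like"
        truth.b_factors[res.label] = res.atoms[0].b_factor

    _validate_planted_geometry(structure, truth, spec)
    return structure, truth


def _validate_planted_geometry(structure: Structure, truth: SceneTruth,
                               spec: SceneSpec) -> None:
    """Planted chains must respect the prescribed step length (up to jitter)."""
    positions = {}
    for res in structure.residues:
        for atom in res.atoms:
            if res.category == "water":
                positions[res.label] = atom.position
            elif res.category == "ligand":
                positions[atom.name] = atom.position
            elif res.category == "nucleotide":
                positions[f"{atom.name} {res.label}"] = atom.position
    slack = 2.0 * _JITTER_TRUNC * spec.jitter_sd + 1e-6
    for ligand_atom, chain, dna_atom in truth.bridges:
        nodes = [ligand_atom, *chain, dna_atom]
        for u, v in zip(nodes, nodes[1:]):
            d = float(np.linalg.norm(positions[u] - positions[v]))
            if abs(d - spec.hbond_length) > slack + 0.01:
                raise GenerationError(
                    f"planted contact {u}-{v} at {d:.2f} A violates the "
                    f"{spec.hbond_length:.2f} A construction"
                )


def derive_native_copy(
    structure: Structure, truth: SceneTruth, spec: SceneSpec
) -> tuple[Structure, SceneTruth]:
    """Build the rigid-transformed "native" counterpart of a scene.

    The copy contains the transformed DNA, a ``conserved_fraction`` of the
    scene's waters (transformed, then jittered) and fresh decoys — no ligand,
    emulating an unliganded deposition of the same fold.  The returned truth
    lists the conserved pairs with their true post-fit displacements.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9001]))
    if spec.rigid_transform is None:
        rot, trans = np.eye(3), np.zeros(3)
    else:
        rot, trans = spec.rigid_transform
        rot = np.asarray(rot, dtype=float)
        trans = np.asarray(trans, dtype=float)

    native = Structure(id=f"{structure.id}-native", resolution=1.85)
    for res in structure.residues:
        if res.category != "nucleotide":
            continue
        copy = Residue(name=res.name, seq_number=res.seq_number,
                       chain_id=res.chain_id, category=res.category)
        for atom in res.atoms:
            copy.atoms.append(
                Atom(name=atom.name, element=atom.element,
                     position=rot @ atom.position + trans,
                     b_factor=atom.b_factor)
            )
        native.residues.append(copy)

    waters = structure.waters
    n_keep = int(round(spec.conserved_fraction * len(waters)))
    keep_idx = sorted(rng.choice(len(waters), size=n_keep, replace=False)) if waters else []
    new_truth = SceneTruth(
        bridges=list(truth.bridges),
        clusters=list(truth.clusters),
        shells=dict(truth.shells),
        b_factors=dict(truth.b_factors),
    )
    seq = 400
    kept_positions = []
    for idx in keep_idx:
        res = waters[idx]
        seq += 1
        jitter = _jitter(rng, spec.jitter_sd)
        pos = rot @ res.atoms[0].position + trans + jitter
        copy = Residue(name="HOH", seq_number=seq, chain_id="W", category="water")
        copy.atoms.append(
            Atom(name="O", element="O", position=pos, b_factor=res.atoms[0].b_factor)
        )
        native.residues.append(copy)
        kept_positions.append(pos)
        new_truth.conserved_pairs.append(
            (res.label, copy.label, float(np.linalg.norm(jitter)))
        )

    # fresh decoys, kept clear of every native atom and of the images of the
    # unmatched originals so they cannot fake a conserved pair
    all_water_images = [rot @ r.atoms[0].position + trans for r in waters]
    obstacles = [a.position for r in native.residues for a in r.atoms]
    obstacles += all_water_images
    min_sep = _HB_CUTOFF + spec.decoy_margin
    z_vals = [p[2] for p in obstacles] or [0.0]
    for _ in range(spec.n_decoy_waters):
        placed = False
        for _attempt in range(2000):
            r = rng.uniform(13.0, 19.0)
            ang = rng.uniform(0, 2 * math.pi)
            z = rng.uniform(min(z_vals) - 4.0, max(z_vals) + 4.0)
            cand = rot @ np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
            cand = cand + np.array([0.0, 0.0, z])
            if min(np.linalg.norm(cand - p) for p in obstacles) >= min_sep:
                obstacles.append(cand)
                seq += 1
                copy = Residue(name="HOH", seq_number=seq, chain_id="W",
                               category="water")
                copy.atoms.append(
                    Atom(name="O", element="O", position=cand,
                         b_factor=_draw_b(rng, spec.b_factor_model, "water"))
                )
                native.residues.append(copy)
                placed = True
                break
        if not placed:
            raise GenerationError(
                "could not place a native-copy decoy outside the exclusion zone"
            )
    return native, new_truth
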