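"""Quartet superposition and conserved-water identification.

Two quadruplex structures are superposed by a least-squares rigid-body fit
(Kabsch/SVD) of their G-quartet guanine base heavy atoms under an explicit
residue correspondence — the pairing of quartet guanines is a scientific
choice made by inspection, never inferred by sequence alignment here.

After superposition, waters of the moving structure are matched to waters of
the reference by mutual nearest neighbours under a distance threshold
(default 1.0 A); matched pairs are the *conserved waters* shared by the two
structures.  An optimal (Hungarian) assignment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .structure_model import Residue, Structure

__all__ = [
    "GUANINE_BASE_ATOMS",
    "ResidueCorrespondence",
    "SuperpositionResult",
    "ConservedWaterPair",
    "DegenerateFitError",
    "kabsch",
    "fit_quartets",
    "match_conserved_waters",
]

#: guanine base heavy atoms used for quartet fitting (backbone excluded:
#: sugar-phosphate conformations vary between native and bound forms)
GUANINE_BASE_ATOMS = (
    "N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9",
)

_GUANINE_CODES = {"DG", "G"}


class DegenerateFitError(ValueError):
    """Raised when a rigid fit is underdetermined (too few or collinear atoms)."""


@dataclass
class ResidueCorrespondence:
    """Ordered guanine pairs (A-residue, B-residue) and the atom names fitted."""

    pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    atom_names: tuple[str, ...] = GUANINE_BASE_ATOMS

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueCorrespondence":
        df = pd.read_csv(path, sep="\t", comment="#")
        pairs = [
            ((str(r.chain_a), int(r.res_a)), (str(r.chain_b), int(r.res_b)))
            for r in df.itertuples()
        ]
        return cls(pairs)


@dataclass
class SuperpositionResult:
    """A proper rigid transform x -> R @ x + t with its fit RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ConservedWaterPair:
    water_a: str
    water_b: str
    distance: float


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares proper rigid transform mapping ``moving`` onto ``fixed``.

    Classic SVD solution with the determinant correction that excludes
    reflections.  Raises :class:`DegenerateFitError` for fewer than three
    pairs or a collinear point set.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateFitError(f"rigid fit needs >= 3 atom pairs, got {n}")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    x = moving - cm
    y = fixed - cf
    # collinearity: the centered cloud must span at least a plane
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateFitError("fitted atoms are collinear; rotation is underdetermined")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cf - rotation @ cm
    moved = x @ rotation.T + cf
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(rotation, translation, rmsd, n)


def _collect_fit_atoms(
    a: Structure,
    b: Structure,
    corr: ResidueCorrespondence,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for (chain_a, seq_a), (chain_b, seq_b) in corr.pairs:
        res_a = a.find_residue(chain_a, seq_a)
        res_b = b.find_residue(chain_b, seq_b)
        if res_a is None or res_b is None:
            missing = (chain_a, seq_a) if res_a is None else (chain_b, seq_b)
            raise ValueError(f"correspondence names absent residue {missing}")
        for res in (res_a, res_b):
            if res.category == "nucleotide" and res.name.upper() not in _GUANINE_CODES:
                raise ValueError(
                    f"correspondence pairs must map guanine to guanine, got {res.name}"
                )
        for name in corr.atom_names:
            at_a = res_a.atom(name)
            at_b = res_b.atom(name)
            if at_a is None or at_b is None:
                continue  # atom not located in one of the structures
            xs.append(at_a.position)
            ys.append(at_b.position)
    if not xs:
        raise DegenerateFitError("no common fitted atoms under the correspondence")
    return np.array(xs), np.array(ys)


def fit_quartets(
    a: Structure,
    b: Structure,
    corr: ResidueCorrespondence,
) -> SuperpositionResult:
    """Superpose structure ``a`` onto ``b`` on their quartet guanine bases.

    The transform is returned, never applied in place: original coordinates
    are preserved and :meth:`SuperpositionResult.apply` maps A-frame
    coordinates into the B frame.
    """
    moving, fixed = _collect_fit_atoms(a, b, corr)
    return kabsch(moving, fixed)


def _water_positions(structure: Structure) -> tuple[list[str], np.ndarray]:
    labels, coords = [], []
    for res in structure.waters:
        oxy = next((at for at in res.atoms if at.element.upper() == "O"), None)
        if oxy is None:
            continue
        labels.append(res.label)
        coords.append(oxy.position)
    return labels, np.asarray(coords).reshape(-1, 3)


def match_conserved_waters(
    a: Structure,
    b: Structure,
    transform: SuperpositionResult,
    threshold: float = 1.0,
    method: str = "mutual",
) -> list[ConservedWaterPair]:
    """Pair waters of ``a`` (mapped through ``transform``) with waters of ``b``.

    ``mutual`` (default): greedy mutual-nearest-neighbour matching by
    ascending distance — each water appears in at most one pair and every
    accepted pair is its partner's nearest available counterpart.
    ``optimal``: minimum-total-distance assignment restricted to pairs within
    the threshold.  Pairs are returned sorted by distance.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels_a, coords_a = _water_positions(a)
    labels_b, coords_b = _water_positions(b)
    if not labels_a or not labels_b:
        return []
    moved = transform.apply(coords_a)
    dmat = np.linalg.norm(moved[:, None, :] - coords_b[None, :, :], axis=2)

    pairs: list[ConservedWaterPair] = []
    if method == "mutual":
        candidates = [
            (dmat[i, j], i, j)
            for i in range(len(labels_a))
            for j in range(len(labels_b))
            if dmat[i, j] <= threshold
        ]
        candidates.sort(key=lambda t: (t[0], labels_a[t[1]], labels_b[t[2]]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, i, j in candidates:
            if i in used_a or j in used_b:
                continue
            pairs.append(ConservedWaterPair(labels_a[i], labels_b[j], float(d)))
            used_a.add(i)
            used_b.add(j)
    elif method == "optimal":
        big = 1e6
        cost = np.where(dmat <= threshold, dmat, big)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if dmat[i, j] <= threshold:
                pairs.append(ConservedWaterPair(labels_a[i], labels_b[j], float(dmat[i, j])))
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return sorted(pairs, key=lambda p: (p.distance, p.water_a, p.water_b))
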