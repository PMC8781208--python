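"""Packaged contact-table fixtures for two published G-quadruplex complexes.

Two edge lists are shipped so the network, counting and mobility stages run
with no structure download:

* ``table_mm41`` — the MM41 naphthalene-diimide complex with a human
  intramolecular telomeric quadruplex (PDB entry 3UYH): ligand side-chain
  nitrogens, chromophore carbonyl oxygens, groove waters and DNA contacts,
  with hydrogen-bond distances (A) and per-atom B factors (A^2), grouped by
  groove.
* ``table_braco19`` — the BRACO19 trisubstituted-acridine complex with a
  bimolecular human telomeric quadruplex (PDB entry 3CE5), same layout.

Ligand atom names follow the deposited entries: MM41 side-chain/ring
nitrogens NCH, NCA, NCE, NCG, NCF and chromophore oxygens OAF, OAG, ODX;
BRACO19 nitrogens N7, N17, N21, N39, N47 and amide carbonyl O52.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .hbond import HydrogenBond, load_contact_table

__all__ = [
    "MM41_LIGAND_ATOMS",
    "MM41_TERMINAL_RING_NITROGENS",
    "BRACO19_LIGAND_ATOMS",
    "table_mm41",
    "table_braco19",
    "mm41_bonds",
    "braco19_bonds",
    "quartet_correspondence_1kf1_3uyh",
    "write_fixture_files",
]

#: MM41 polar atoms appearing in the contact table (ring nitrogens + the
#: chromophore carbonyl oxygens, which count as ligand atoms).
MM41_LIGAND_ATOMS = frozenset(
    {"NCH", "NCA", "NCE", "NCG", "NCF", "OAF", "OAG", "ODX"}
)

#: the five terminal-ring nitrogens whose mobility is summarised as a group
MM41_TERMINAL_RING_NITROGENS = ("NCH", "NCA", "NCE", "NCG", "NCF")

BRACO19_LIGAND_ATOMS = frozenset({"N7", "N17", "N21", "N39", "N47", "O52"})

# (atom_a, atom_b, distance_A, b_a, b_b, groove)
_MM41_ROWS = [
    ("NCH", "W204", 3.2, 64, 32, "groove 1"),
    ("W204", "W203", 3.0, 32, 32, "groove 1"),
    ("W203", "OP2 dG10", 2.9, 32, 32, "groove 1"),
    ("W203", "W227", 3.4, 32, 45, "groove 1"),
    ("W227", "OAF", 2.5, 45, 29, "groove 1"),
    ("W251", "OP2 dG9", 2.9, 27, 30, "groove 1"),
    ("W204", "N2 dG4", 2.9, 32, 20, "groove 1"),
    ("W204", "W251", 2.8, 32, 27, "groove 1"),
    ("NCA", "OP2 dT11", 3.1, 46, 35, "groove 2"),
    ("NCE", "W217", 2.7, 40, 46, "groove 2"),
    ("W217", "W218", 2.6, 46, 48, "groove 2"),
    ("W218", "W219", 3.0, 48, 43, "groove 2"),
    ("W219", "ODX", 2.7, 43, 31, "groove 2"),
    ("W218", "OP2 dG16", 3.4, 48, 45, "groove 2"),
    ("NCG", "W220", 2.9, 48, 50, "groove 3"),
    ("W219", "W220", 2.9, 43, 50, "groove 3"),
    ("NCF", "OP2 dG4", 2.9, 58, 39, "groove 4"),
]

_BRACO19_ROWS = [
    ("N7", "W52", 2.7, 11, 21, "groove 1"),
    ("W52", "N3 dT24", 2.9, 21, 12, "groove 1"),
    ("W52", "O6 dG5", 3.0, 21, 18, "groove 1"),
    ("W52", "W53", 3.1, 21, 33, "groove 1"),
    ("W53", "O2 dT24", 3.3, 33, 18, "groove 1"),
    ("W53", "O52", 3.1, 33, 14, "groove 1"),
    ("W56", "N39", 3.4, 23, 27, "groove 2"),
    ("N17", "W55", 3.0, 14, 38, "groove 2"),
    ("W55", "O2 dT12", 3.3, 38, 17, "groove 2"),
    ("N21", "O4 dT24", 3.0, 13, 17, "groove 4"),
    ("N47", "W41", 3.0, 21, 28, "groove 4"),
    ("W41", "W44", 2.9, 28, 29, "groove 4"),
    ("W44", "OP2 dG23", 2.5, 29, 21, "groove 4"),
    ("W41", "N2 dG17", 2.9, 28, 18, "groove 4"),
]

_COLUMNS = ["atom_a", "atom_b", "distance_A", "b_a", "b_b", "group_label"]


def table_mm41(grooves: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Contact table of the MM41 complex, optionally restricted to grooves."""
    df = pd.DataFrame(_MM41_ROWS, columns=_COLUMNS)
    if grooves is not None:
        df = df[df["group_label"].isin(grooves)].reset_index(drop=True)
    return df


def table_braco19(grooves: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Contact table of the BRACO19 complex, optionally restricted to grooves."""
    df = pd.DataFrame(_BRACO19_ROWS, columns=_COLUMNS)
    if grooves is not None:
        df = df[df["group_label"].isin(grooves)].reset_index(drop=True)
    return df


def mm41_bonds(grooves: tuple[str, ...] | None = None) -> list[HydrogenBond]:
    return load_contact_table(table_mm41(grooves), MM41_LIGAND_ATOMS)


def braco19_bonds(grooves: tuple[str, ...] | None = None) -> list[HydrogenBond]:
    return load_contact_table(table_braco19(grooves), BRACO19_LIGAND_ATOMS)


def quartet_correspondence_1kf1_3uyh() -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Guanine pairing for superposing the native human telomeric quadruplex
    (PDB 1KF1) onto the MM41 complex (PDB 3UYH).

    Both are the 22-mer AGGG(TTAGGG)3 sequence on chain A, so the quartet
    guanines pair identically: quartets (2,8,14,20), (3,9,15,21), (4,10,16,22).
    """
    guanines = [2, 3, 4, 8, 9, 10, 14, 15, 16, 20, 21, 22]
    return [(("A", n), ("A", n)) for n in guanines]


def write_fixture_files(outdir: str | Path) -> list[Path]:
    """Materialise the packaged tables (and the quartet correspondence) as
    TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in [("table_mm41.tsv", table_mm41()), ("table_braco19.tsv", table_braco19())]:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    corr = pd.DataFrame(
        [
            (a_chain, a_seq, b_chain, b_seq)
            for (a_chain, a_seq), (b_chain, b_seq) in quartet_correspondence_1kf1_3uyh()
        ],
        columns=["chain_a", "res_a", "chain_b", "res_b"],
    )
    p = outdir / "correspondence_1kf1_3uyh.tsv"
    corr.to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths
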