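"""Hydrogen-bond detection: roles, geometry criteria, oracle equivalence,
and the published-contact-table reader."""

import itertools
import math

import numpy as np
import pytest

from gqwaters import fixtures as fx
from gqwaters.hbond import (
    ContactTableError,
    HBondCriteria,
    RoleTable,
    assign_roles,
    detect_hbonds,
    load_contact_table,
)
from gqwaters.structure_model import Atom, Residue, Structure


def brute_force_hbonds(structure, roles, criteria):
    """Independent all-pairs reimplementation of the acceptance rules."""
    from gqwaters.hbond import _angle_deviation, _atom_label

    entries = []
    for res in structure.residues:
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            entry = roles.lookup(res, atom)
            if entry.role != "none":
                entries.append((res, atom, entry))
    found = set()
    for (ri, ai, ei), (rj, aj, ej) in itertools.combinations(entries, 2):
        if ri is rj:
            continue
        d = float(np.linalg.norm(ai.position - aj.position))
        if d > criteria.max_distance:
            continue
        ok = False
        for (dr, da, de), (_, aa, ae) in (
            ((ri, ai, ei), (rj, aj, ej)),
            ((rj, aj, ej), (ri, ai, ei)),
        ):
            if not (de.can_donate and ae.can_accept):
                continue
            dev = _angle_deviation(dr, da, de, aa.position, criteria.angle_mode)
            if dev is None or dev <= criteria.max_angle_deviation:
                ok = True
                break
        if ok:
            found.add(frozenset({_atom_label(ri, ai), _atom_label(rj, aj)}))
    return found


def _water(seq, pos, b=30.0):
    return Residue("HOH", seq, "W", "water", [Atom("O", "O", np.asarray(pos, float), b)])


class TestRoles:
    def test_guanine_roles(self):
        res = Residue("DG", 4, "A", "nucleotide",
                      [Atom(n, n[0], np.zeros(3)) for n in
                       ("N1", "N2", "O6", "N3", "N7", "OP1", "OP2", "O4'", "O5'", "C8")])
        st = Structure("x", [res])
        roles = assign_roles(st)
        assert roles.lookup(res, res.atom("N2")).role == "donor"
        for name in ("O6", "N3", "N7", "OP1", "OP2", "O4'", "O5'"):
            assert roles.lookup(res, res.atom(name)).can_accept, name
        assert roles.lookup(res, res.atom("C8")).role == "none"

    def test_water_oxygen_is_both_with_no_antecedent(self):
        res = _water(204, [0, 0, 0])
        roles = assign_roles(Structure("x", [res]))
        entry = roles.lookup(res, res.atoms[0])
        assert entry.role == "both"
        assert entry.antecedents == ()

    def test_ligand_roles_come_only_from_overrides(self):
        res = Residue("LIG", 1, "B", "ligand", [Atom("NCH", "N", np.zeros(3))])
        st = Structure("x", [res])
        assert assign_roles(st).lookup(res, res.atoms[0]).role == "none"
        table = RoleTable()
        table.add("LIG", "NCH", "donor", "sp3", ("CCH",))
        assert assign_roles(st, table).lookup(res, res.atoms[0]).role == "donor"

    def test_override_for_absent_atom_warns(self):
        st = Structure("x", [_water(1, [0, 0, 0])])
        table = RoleTable()
        table.add("LIG", "NZZ", "donor")
        with pytest.warns(UserWarning, match="NZZ"):
            assign_roles(st, table)


class TestDetection:
    def test_distance_cutoff_boundary(self):
        st = Structure("x", [_water(1, [0, 0, 0]), _water(2, [3.30, 0, 0]),
                             _water(3, [0, 3.20, 0])])
        bonds = detect_hbonds(st, assign_roles(st), HBondCriteria())
        assert {b.labels for b in bonds} == {frozenset({"W1", "W3"})}

    def test_angle_mode_rejects_then_distance_only_accepts(self):
        # sp2 donor with antecedent: acceptor placed 35 deg off the 120 ideal
        ang = math.radians(120 + 35)
        donor_res = Residue(
            "DG", 1, "A", "nucleotide",
            [Atom("N2", "N", np.array([0.0, 0.0, 0.0])),
             Atom("C2", "C", np.array([1.34, 0.0, 0.0]))],
        )
        acceptor = _water(7, 2.8 * np.array([math.cos(ang), math.sin(ang), 0.0]))
        st = Structure("x", [donor_res, acceptor])
        roles = assign_roles(st)
        strict = detect_hbonds(st, roles, HBondCriteria(angle_mode="antecedent_proxy"))
        loose = detect_hbonds(st, roles, HBondCriteria(angle_mode="distance_only"))
        # the N2->W assignment fails the angle test, but W is itself an
        # angle-exempt donor toward N2... N2 cannot accept, so the bond drops
        assert strict == []
        assert len(loose) == 1

    def test_waters_exempt_from_angle_test(self):
        st = Structure("x", [_water(1, [0, 0, 0]), _water(2, [2.8, 0, 0])])
        bonds = detect_hbonds(st, assign_roles(st), HBondCriteria(angle_mode="ideal_hydrogen"))
        assert len(bonds) == 1

    def test_symmetric_unordered_pairs(self, small_scene):
        structure, _, roles = small_scene
        bonds = detect_hbonds(structure, roles, HBondCriteria())
        seen = [b.labels for b in bonds]
        assert len(seen) == len(set(seen))

    @pytest.mark.parametrize("mode", ["distance_only", "antecedent_proxy", "ideal_hydrogen"])
    def test_monotone_in_distance_cutoff(self, scene_factory, mode):
        structure, _, roles = scene_factory(
            waters_per_bridge=3, n_bridges=3, n_decoy_waters=4, jitter_sd=0.1, seed=3
        )
        previous = set()
        for cutoff in (2.6, 3.0, 3.25, 3.45):
            bonds = {
                b.labels
                for b in detect_hbonds(
                    structure, roles, HBondCriteria(max_distance=cutoff, angle_mode=mode)
                )
            }
            assert previous <= bonds
            previous = bonds

    @pytest.mark.parametrize("mode", ["distance_only", "antecedent_proxy", "ideal_hydrogen"])
    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_equals_brute_force_oracle(self, scene_factory, mode, seed):
        structure, _, roles = scene_factory(
            n_quartets=2, waters_per_bridge=2, n_bridges=3, n_decoy_waters=6,
            jitter_sd=0.12, seed=seed,
        )
        assert structure.n_atoms <= 200
        criteria = HBondCriteria(angle_mode=mode)
        fast = {b.labels for b in detect_hbonds(structure, roles, criteria)}
        assert fast == brute_force_hbonds(structure, roles, criteria)

    def test_planted_bridge_edges_recovered(self, small_scene):
        structure, truth, roles = small_scene
        bonds = {b.labels for b in detect_hbonds(structure, roles, HBondCriteria())}
        for ligand_atom, chain, dna_atom in truth.bridges:
            nodes = [ligand_atom, *chain, dna_atom]
            for u, v in zip(nodes, nodes[1:]):
                assert frozenset({u, v}) in bonds

    def test_sorted_by_category_then_distance(self, small_scene):
        structure, _, roles = small_scene
        bonds = detect_hbonds(structure, roles, HBondCriteria())
        keys = [(b.category, b.distance) for b in bonds]
        assert keys == sorted(keys)


class TestContactTable:
    def test_mm41_groove1_categories(self):
        bonds = fx.mm41_bonds(grooves=("groove 1",))
        assert len(bonds) == 8
        ligand_water = {b.labels for b in bonds if b.category == "ligand-water"}
        assert frozenset({"NCH", "W204"}) in ligand_water
        assert frozenset({"W227", "OAF"}) in ligand_water

    def test_braco19_category_multiset(self):
        bonds = fx.braco19_bonds()
        assert len(bonds) == 14
        counts = {}
        for b in bonds:
            counts[b.category] = counts.get(b.category, 0) + 1
        # hand classification of the printed table
        assert counts == {
            "ligand-water": 5,   # N7-W52, W53-O52, W56-N39, N17-W55, N47-W41
            "water-water": 2,    # W52-W53, W41-W44
            "water-dna": 6,      # W52-N3 dT24, W52-O6 dG5, W53-O2 dT24,
                                 # W55-O2 dT12, W44-OP2 dG23, W41-N2 dG17
            "ligand-dna": 1,     # N21-O4 dT24
        }

    def test_empty_table(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["atom_a", "atom_b", "distance_A"])
        assert load_contact_table(empty, fx.MM41_LIGAND_ATOMS) == []

    def test_unclassifiable_label_names_the_label(self):
        rows = [{"atom_a": "XQZ9?", "atom_b": "W1", "distance_A": 3.0}]
        with pytest.raises(ContactTableError, match="XQZ9"):
            load_contact_table(rows, fx.MM41_LIGAND_ATOMS)

    def test_b_factors_carried_through(self):
        bonds = fx.mm41_bonds(grooves=("groove 1",))
        nch = next(b for b in bonds if "NCH" in b.labels)
        by_label = {nch.atom_a.label: nch.atom_a.b_factor,
                    nch.atom_b.label: nch.atom_b.b_factor}
        assert by_label == {"NCH": 64.0, "W204": 32.0}
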