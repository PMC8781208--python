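"""Analysis configuration loaded from a single YAML key-value file.

Example::

    ligand_codes: [MM4]
    criteria: default          # or "table2"
    max_waters: 4
    conserved_threshold: 1.0
    ligand_atoms: [NCH, NCA, NCE, NCG, NCF, OAF, OAG, ODX]
    ligand_roles:
      - {residue: MM4, atom: NCH, role: donor, hybridization: sp3, antecedents: [CCH]}
    mobility_groups:
      terminal_ring_nitrogens: [NCH, NCA, NCE, NCG, NCF]
    groove_map: {}

Only the keys a command needs have to be present; everything has a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hbond import HBondCriteria, RoleTable
from .structure_model import DEFAULT_WATER_CODES

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    ligand_codes: list[str] = field(default_factory=list)
    water_codes: list[str] = field(default_factory=lambda: sorted(DEFAULT_WATER_CODES))
    criteria_preset: str = "default"
    max_waters: int = 4
    conserved_threshold: float = 1.0
    max_resolution: float = 2.5
    ligand_atoms: list[str] = field(default_factory=list)
    ligand_roles: list[dict] = field(default_factory=list)
    mobility_groups: dict[str, list[str]] = field(default_factory=dict)
    groove_map: dict[str, str] = field(default_factory=dict)

    @property
    def criteria(self) -> HBondCriteria:
        return HBondCriteria.preset(self.criteria_preset)

    def role_overrides(self) -> RoleTable:
        table = RoleTable()
        for entry in self.ligand_roles:
            table.add(
                entry.get("residue", "*"),
                entry["atom"],
                entry["role"],
                entry.get("hybridization"),
                entry.get("antecedents", ()),
            )
        return table


def load_config(path: str | Path | None) -> AnalysisConfig:
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "ligand_codes": "ligand_codes",
        "water_codes": "water_codes",
        "criteria": "criteria_preset",
        "max_waters": "max_waters",
        "conserved_threshold": "conserved_threshold",
        "max_resolution": "max_resolution",
        "ligand_atoms": "ligand_atoms",
        "ligand_roles": "ligand_roles",
        "mobility_groups": "mobility_groups",
        "groove_map": "groove_map",
    }
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            raise KeyError(f"unknown config key {key!r}")
        kwargs[known[key]] = value
    return AnalysisConfig(**kwargs)
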