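"""Synthetic structure fixtures with known (planted) modification content.

The generator writes matched PDB and mmCIF renderings of the same synthetic
coordinates together with a truth table of every planted modification, so
the identification algorithms can be verified end-to-end without touching
archive data.  Geometry realism is *not* a goal: the bond criterion consults
interatomic distances only, so only the distances relevant to planted (and
decoy) linkages are controlled; everything else sits on an extended-chain
template with 3.8 Angstrom C-alpha spacing.

Layout conventions:

* polymer chain ``i`` runs along +x in the plane ``z = 30 * i``; side chains
  extend in +y;
* cross-link linkage atoms are relocated to a small "site" 5 A above the
  chain plane, at the exact requested pairwise distance;
* attachment groups are placed along +z from the receiving residue's
  linkage atom (or, for groups shared by several residues, at a site 6 A
  above the targets, with each receiving atom placed at its exact distance
  along well-separated outward directions);
* decoy placements reuse the same machinery at ``threshold + 0.2`` A, just
  past the bond criterion, on their own chains.

For a given spec the output is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from modfinder.bonds import BondConfig, CovalentRadiiTable
from modfinder.dictionary import (
    CANONICAL_AMINO_ACIDS,
    ComponentRole,
    Dictionary,
    ModificationCategory,
    ModificationDefinition,
    starter_dictionary,
)

__all__ = [
    "FixtureError",
    "Plant",
    "FixtureSpec",
    "FixtureResult",
    "make_fixture",
    "perturb_fixture",
    "composite_spec",
    "ferredoxin_like_spec",
    "random_spec",
    "rotation_matrix",
]

CA_SPACING = 3.8
_GROUP_CHAIN = "X"
_GROUP_SEQ_START = 901
_SITE_MIN_SEPARATION = 3.2  # just above the largest bond threshold in play


class FixtureError(Exception):
    pass


def _align_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation taking direction ``v`` to +z (identity for degenerate ``v``)."""
    n = np.linalg.norm(v)
    if n < 1e-9:
        return np.eye(3)
    u = v / n
    z = np.array([0.0, 0.0, 1.0])
    c = float(u @ z)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - c) * (k @ k)


# --- residue templates ------------------------------------------------------
# (atom name, element, offset from CA) with side chains stacked in +y;
# lateral x offsets kept small enough that no cross-residue template pair
# comes within any bond threshold at 3.8 A spacing.

_BACKBONE = [
    ("N", "N", (-1.2, -0.8, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, -0.8, 0.0)),
    ("O", "O", (1.2, -2.0, 0.0)),
]

_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (0, 1.4, 0))],
    "SER": [("CB", "C", (0, 1.4, 0)), ("OG", "O", (0, 2.8, 0))],
    "THR": [("CB", "C", (0, 1.4, 0)), ("OG1", "O", (0, 2.8, 0)),
            ("CG2", "C", (0.9, 2.2, 0))],
    "CYS": [("CB", "C", (0, 1.4, 0)), ("SG", "S", (0, 2.9, 0))],
    "MET": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("SD", "S", (0, 4.2, 0)), ("CE", "C", (0, 5.6, 0))],
    "ASN": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("OD1", "O", (0.9, 3.5, 0)), ("ND2", "N", (0, 4.2, 0))],
    "ASP": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("OD1", "O", (0.9, 3.5, 0)), ("OD2", "O", (0, 4.2, 0))],
    "GLN": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD", "C", (0, 4.2, 0)), ("OE1", "O", (0.9, 4.9, 0)),
            ("NE2", "N", (0, 5.6, 0))],
    "GLU": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD", "C", (0, 4.2, 0)), ("OE1", "O", (0.9, 4.9, 0)),
            ("OE2", "O", (0, 5.6, 0))],
    "HIS": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("ND1", "N", (0.9, 3.6, 0)), ("CD2", "C", (-0.9, 3.6, 0)),
            ("CE1", "C", (0.6, 4.9, 0)), ("NE2", "N", (-0.6, 4.9, 0))],
    "LYS": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD", "C", (0, 4.2, 0)), ("CE", "C", (0, 5.6, 0)),
            ("NZ", "N", (0, 7.0, 0))],
    "ARG": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD", "C", (0, 4.2, 0)), ("NE", "N", (0, 5.6, 0)),
            ("CZ", "C", (0, 7.0, 0)), ("NH1", "N", (0.8, 7.8, 0)),
            ("NH2", "N", (-0.8, 7.8, 0))],
    "VAL": [("CB", "C", (0, 1.4, 0)), ("CG1", "C", (0.8, 2.4, 0)),
            ("CG2", "C", (-0.8, 2.4, 0))],
    "LEU": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD1", "C", (0.8, 3.6, 0)), ("CD2", "C", (-0.8, 3.6, 0))],
    "ILE": [("CB", "C", (0, 1.4, 0)), ("CG1", "C", (0.8, 2.4, 0)),
            ("CG2", "C", (-0.8, 2.4, 0)), ("CD1", "C", (0.8, 3.8, 0))],
    "PHE": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD1", "C", (0.9, 3.6, 0)), ("CD2", "C", (-0.9, 3.6, 0)),
            ("CE1", "C", (0.9, 5.0, 0)), ("CE2", "C", (-0.9, 5.0, 0)),
            ("CZ", "C", (0, 5.7, 0))],
    "TYR": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD1", "C", (0.9, 3.6, 0)), ("CD2", "C", (-0.9, 3.6, 0)),
            ("CE1", "C", (0.9, 5.0, 0)), ("CE2", "C", (-0.9, 5.0, 0)),
            ("CZ", "C", (0, 5.7, 0)), ("OH", "O", (0, 7.1, 0))],
    "TRP": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD1", "C", (0.9, 3.6, 0)), ("CD2", "C", (-0.9, 3.6, 0)),
            ("NE1", "N", (0.6, 4.9, 0)), ("CE2", "C", (-0.6, 4.9, 0))],
    "PRO": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0.8, 2.5, 0)),
            ("CD", "C", (-0.8, 2.5, 0))],
    # nonstandard (modified) residues
    "SEP": [("CB", "C", (0, 1.4, 0)), ("OG", "O", (0, 2.8, 0)),
            ("P", "P", (0, 4.2, 0)), ("O1P", "O", (0.8, 5.0, 0)),
            ("O2P", "O", (-0.8, 5.0, 0)), ("O3P", "O", (0, 5.6, 0))],
    "TPO": [("CB", "C", (0, 1.4, 0)), ("OG1", "O", (0, 2.8, 0)),
            ("CG2", "C", (0.9, 2.2, 0)), ("P", "P", (0, 4.2, 0)),
            ("O1P", "O", (0.8, 5.0, 0)), ("O2P", "O", (-0.8, 5.0, 0)),
            ("O3P", "O", (0, 5.6, 0))],
    "PTR": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD1", "C", (0.9, 3.6, 0)), ("CD2", "C", (-0.9, 3.6, 0)),
            ("CE1", "C", (0.9, 5.0, 0)), ("CE2", "C", (-0.9, 5.0, 0)),
            ("CZ", "C", (0, 5.7, 0)), ("OH", "O", (0, 7.1, 0)),
            ("P", "P", (0, 8.5, 0)), ("O1P", "O", (0.8, 9.3, 0)),
            ("O2P", "O", (-0.8, 9.3, 0)), ("O3P", "O", (0, 9.9, 0))],
    "HYP": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0.8, 2.5, 0)),
            ("CD", "C", (-0.8, 2.5, 0)), ("OD1", "O", (0.8, 3.9, 0))],
    "MSE": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("SE", "SE", (0, 4.3, 0)), ("CE", "C", (0, 5.8, 0))],
    "ALY": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD", "C", (0, 4.2, 0)), ("CE", "C", (0, 5.6, 0)),
            ("NZ", "N", (0, 7.0, 0)), ("CH", "C", (0, 8.4, 0)),
            ("OH", "O", (0.8, 9.2, 0)), ("CH3", "C", (-0.8, 9.2, 0))],
    "CSO": [("CB", "C", (0, 1.4, 0)), ("SG", "S", (0, 2.9, 0)),
            ("OD", "O", (0, 4.4, 0))],
    "KCX": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD", "C", (0, 4.2, 0)), ("CE", "C", (0, 5.6, 0)),
            ("NZ", "N", (0, 7.0, 0)), ("CX", "C", (0, 8.4, 0)),
            ("OQ1", "O", (0.8, 9.2, 0)), ("OQ2", "O", (-0.8, 9.2, 0))],
    "M3L": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0, 2.8, 0)),
            ("CD", "C", (0, 4.2, 0)), ("CE", "C", (0, 5.6, 0)),
            ("NZ", "N", (0, 7.0, 0))],
    "PCA": [("CB", "C", (0, 1.4, 0)), ("CG", "C", (0.8, 2.5, 0)),
            ("CD", "C", (-0.8, 2.5, 0)), ("OE", "O", (-0.8, 3.9, 0))],
}

_TETRA = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float)
_TETRA /= np.linalg.norm(_TETRA[0])

# non-polymer group templates: offsets from the group anchor, extending in +z
_GROUP_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "NAG": [("C1", "C", (0, 0, 0)), ("O5", "O", (0, 0.9, 1.0)),
            ("C2", "C", (0, -0.9, 1.0)), ("C3", "C", (0, -0.9, 2.4)),
            ("N2", "N", (0, -2.1, 0.5)), ("C4", "C", (0, 0.0, 3.4)),
            ("C5", "C", (0, 0.9, 2.4)), ("O3", "O", (0, -2.1, 3.0))],
    "NDG": [("C1", "C", (0, 0, 0)), ("O5", "O", (0, 0.9, 1.0)),
            ("C2", "C", (0, -0.9, 1.0))],
    "ZN": [("ZN", "ZN", (0, 0, 0))],
    "SF4": [("FE1", "FE", tuple(1.35 * _TETRA[0])),
            ("FE2", "FE", tuple(1.35 * _TETRA[1])),
            ("FE3", "FE", tuple(1.35 * _TETRA[2])),
            ("FE4", "FE", tuple(1.35 * _TETRA[3])),
            ("S1", "S", tuple(-1.25 * _TETRA[0])),
            ("S2", "S", tuple(-1.25 * _TETRA[1])),
            ("S3", "S", tuple(-1.25 * _TETRA[2])),
            ("S4", "S", tuple(-1.25 * _TETRA[3]))],
    "F3S": [("FE1", "FE", tuple(1.35 * _TETRA[0])),
            ("FE3", "FE", tuple(1.35 * _TETRA[2])),
            ("FE4", "FE", tuple(1.35 * _TETRA[3])),
            ("S1", "S", tuple(-1.25 * _TETRA[0])),
            ("S2", "S", tuple(-1.25 * _TETRA[1])),
            ("S3", "S", tuple(-1.25 * _TETRA[2])),
            ("S4", "S", tuple(-1.25 * _TETRA[3]))],
}

# spread directions for atoms placed around a single-atom group (e.g. ZN)
_SPREAD_DIRECTIONS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0.0, 0.0, 1.0),
     (0.7071, 0.7071, 0), (-0.7071, -0.7071, 0), (0.7071, -0.7071, 0)],
    dtype=float,
)

#: typical bond lengths used when a plant does not request a distance (A)
DEFAULT_BOND_LENGTHS = {
    "disulfide": 2.05,
    "isopeptide-lys-asp": 1.33,
    "isopeptide-lys-asn": 1.33,
    "thioether-cys-tyr": 1.85,
    "n-glycosyl-asparagine": 1.43,
    "o-glycosyl-serine": 1.43,
    "o-glycosyl-threonine": 1.43,
    "zinc-histidine": 2.10,
    "zinc-cysteine": 2.30,
    "zinc-aspartate": 2.05,
    "zinc-glutamate": 2.05,
    "4fe4s-cysteine": 2.30,
    "3fe4s-cysteine": 2.30,
}


@dataclass(frozen=True)
class Plant:
    """One planted modification.

    ``targets`` names the polymer residues filling the definition's
    amino-acid component slots, in definition order, as (chain id, 0-based
    polymer index).  ``distance`` is the planted bond length for every
    linkage (ignored for modified residues; a per-definition typical length
    is used when omitted).  Attachment plants with the same ``group_label``
    share one non-polymer group (e.g. one zinc ion coordinated by several
    residues)."""

    definition_id: str
    targets: tuple[tuple[str, int], ...]
    distance: float | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", tuple((c, int(i)) for c, i in self.targets)
        )


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic structure."""

    seed: int
    chains: tuple[tuple[str, tuple[str, ...]], ...]
    plants: tuple[Plant, ...] = ()
    decoys: int = 0
    entry_id: str = "FIXT"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "chains",
            tuple((cid, tuple(seq)) for cid, seq in self.chains),
        )
        object.__setattr__(self, "plants", tuple(self.plants))

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "entry_id": self.entry_id,
                "chains": [{"id": c, "sequence": list(s)} for c, s in self.chains],
                "plants": [
                    {
                        "definition_id": p.definition_id,
                        "targets": [list(t) for t in p.targets],
                        "distance": p.distance,
                        "group_label": p.group_label,
                    }
                    for p in self.plants
                ],
                "decoys": self.decoys,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        return cls(
            seed=int(d["seed"]),
            entry_id=d.get("entry_id", "FIXT"),
            chains=tuple(
                (c["id"], tuple(c["sequence"])) for c in d["chains"]
            ),
            plants=tuple(
                Plant(
                    definition_id=p["definition_id"],
                    targets=tuple((t[0], int(t[1])) for t in p["targets"]),
                    distance=p.get("distance"),
                    group_label=p.get("group_label"),
                )
                for p in d.get("plants", ())
            ),
            decoys=int(d.get("decoys", 0)),
        )


@dataclass(frozen=True)
class TruthRecord:
    definition_id: str
    residues: tuple[tuple[str, int, str], ...]  # sorted (chain, seq, icode)

    @staticmethod
    def make(definition_id: str, keys) -> "TruthRecord":
        return TruthRecord(definition_id, tuple(sorted(keys)))


@dataclass
class FixtureResult:
    pdb_path: Path
    cif_path: Path
    truth: list[TruthRecord]
    spec: FixtureSpec

    @property
    def truth_set(self) -> frozenset[TruthRecord]:
        return frozenset(self.truth)


# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self, spec: FixtureSpec, dictionary: Dictionary, cfg: BondConfig):
        self.spec = spec
        self.dictionary = dictionary
        self.cfg = cfg
        self.rng = np.random.default_rng(spec.seed)
        # (chain_id, index) -> {atom name: (element, position array)}
        self.residues: dict[tuple[str, int], dict[str, tuple[str, np.ndarray]]] = {}
        self.chain_order: list[tuple[str, list[str]]] = []
        self.groups: list[tuple[str, dict[str, tuple[str, np.ndarray]]]] = []
        self.group_by_label: dict[str, int] = {}
        self.group_attach_count: dict[int, int] = {}
        self.truth: list[TruthRecord] = []
        # atoms moved/created per site, for the cross-site separation check;
        # a shared group and all residues attached to it form one site
        self.site_atoms: list[tuple[tuple, np.ndarray]] = []
        self.geometric_targets: set[tuple[str, int]] = set()
        self._plant_counter = 0

    # -- construction ------------------------------------------------------

    def add_chain(self, chain_id: str, sequence: Sequence[str]) -> None:
        if any(cid == chain_id for cid, _ in self.chain_order):
            raise FixtureError(f"duplicate chain id {chain_id!r}")
        if chain_id == _GROUP_CHAIN:
            raise FixtureError(f"chain id {_GROUP_CHAIN!r} is reserved for groups")
        z = 30.0 * len(self.chain_order)
        for j, code in enumerate(sequence):
            if code not in _SIDE_CHAINS:
                raise FixtureError(f"no residue template for code {code!r}")
            ca = np.array([CA_SPACING * j, 0.0, z])
            atoms = {}
            for name, el, off in _BACKBONE + _SIDE_CHAINS[code]:
                atoms[name] = (el, ca + np.asarray(off, dtype=float))
            self.residues[(chain_id, j)] = atoms
        self.chain_order.append((chain_id, list(sequence)))

    def residue_code(self, chain_id: str, index: int) -> str:
        for cid, seq in self.chain_order:
            if cid == chain_id:
                try:
                    return seq[index]
                except IndexError:
                    raise FixtureError(
                        f"chain {chain_id!r} has no residue index {index}"
                    ) from None
        raise FixtureError(f"unknown chain {chain_id!r}")

    def residue_key(self, chain_id: str, index: int) -> tuple[str, int, str]:
        return (chain_id, index + 1, "")

    def _new_group(self, code: str) -> int:
        if code not in _GROUP_TEMPLATES:
            raise FixtureError(f"no non-polymer template for code {code!r}")
        idx = len(self.groups)
        self.groups.append((code, {}))
        return idx

    def group_key(self, idx: int) -> tuple[str, int, str]:
        return (_GROUP_CHAIN, _GROUP_SEQ_START + idx, "")

    def _mark_site_atom(self, pos: np.ndarray, site: tuple | None = None) -> None:
        if site is None:
            site = ("plant", self._plant_counter)
        self.site_atoms.append((site, pos))

    def _claim_target(self, target: tuple[str, int]) -> None:
        if target in self.geometric_targets:
            raise FixtureError(
                f"residue {target} targeted by more than one geometric plant"
            )
        self.geometric_targets.add(target)

    # -- plant handlers ----------------------------------------------------

    def plant(self, p: Plant, in_truth: bool = True,
              distance_override: float | None = None) -> None:
        self._plant_counter += 1
        defn = self.dictionary.get(p.definition_id)
        if defn.category is ModificationCategory.MODIFIED_RESIDUE:
            self._plant_modified_residue(p, defn, in_truth)
        elif defn.category is ModificationCategory.ATTACHMENT:
            self._plant_attachment(p, defn, in_truth, distance_override)
        else:
            self._plant_crosslink(p, defn, in_truth, distance_override)

    def _check_code(self, target: tuple[str, int], comp) -> None:
        code = self.residue_code(*target)
        if not comp.matches_code(code):
            raise FixtureError(
                f"residue {target} has code {code!r}, expected one of {comp.codes}"
            )

    def _plant_modified_residue(self, p, defn, in_truth: bool) -> None:
        (target,) = p.targets
        self._check_code(target, defn.components[0])
        if in_truth:
            self.truth.append(
                TruthRecord.make(defn.internal_id, [self.residue_key(*target)])
            )

    def _linkage_atom(self, atoms: dict, names: Sequence[str], what: str) -> str:
        for name in names:
            if name in atoms:
                return name
        raise FixtureError(f"{what}: none of atoms {list(names)} present")

    def _bond_distance(self, p: Plant, defn, el1: str, el2: str,
                      override: float | None) -> float:
        if override is not None:
            return override
        if p.distance is not None:
            return p.distance
        if defn.internal_id in DEFAULT_BOND_LENGTHS:
            return DEFAULT_BOND_LENGTHS[defn.internal_id]
        return self.cfg.threshold(el1, el2) - 0.3

    def _plant_attachment(self, p, defn, in_truth: bool,
                          distance_override: float | None) -> None:
        aa_slots = [i for i, c in enumerate(defn.components)
                    if c.role is ComponentRole.AMINO_ACID]
        np_slots = [i for i, c in enumerate(defn.components)
                    if c.role is ComponentRole.NON_POLYMER]
        if len(aa_slots) != 1 or len(np_slots) != 1 or len(defn.linkages) != 1:
            raise FixtureError(
                f"attachment template supports 1 amino-acid + 1 non-polymer "
                f"component and 1 linkage; {defn.internal_id!r} has more"
            )
        (target,) = p.targets
        self._check_code(target, defn.components[aa_slots[0]])
        self._claim_target(target)
        lk = defn.linkages[0]
        aa_names, np_names = (
            (lk.atoms_1, lk.atoms_2) if lk.component_1 == aa_slots[0]
            else (lk.atoms_2, lk.atoms_1)
        )
        res_atoms = self.residues[target]
        aa_atom = self._linkage_atom(res_atoms, aa_names, f"residue {target}")

        group_code = next(
            c for c in defn.components[np_slots[0]].codes if c in _GROUP_TEMPLATES
        )
        template = _GROUP_TEMPLATES[group_code]
        np_atom = self._linkage_atom(
            {n: None for n, _, _ in template}, np_names, f"group {group_code}"
        )
        el_aa = res_atoms[aa_atom][0]
        el_np = next(el for n, el, _ in template if n == np_atom)
        d = self._bond_distance(p, defn, el_aa, el_np, distance_override)

        if p.group_label is None:
            # fresh group straight above the receiving atom, oriented so the
            # anchor is the group atom closest to the residue (the rest of
            # the group points away along +z)
            gidx = self._new_group(group_code)
            anchor = res_atoms[aa_atom][1] + np.array([0.0, 0.0, d])
            np_off = next(np.asarray(o, float) for n, _, o in template if n == np_atom)
            offsets = np.array([o for _, _, o in template], dtype=float)
            v = offsets.mean(axis=0) - np_off
            R = _align_to_z(v)
            gatoms = self.groups[gidx][1]
            for name, el, off in template:
                rel = R @ (np.asarray(off, float) - np_off)
                gatoms[name] = (el, anchor + rel)
                self._mark_site_atom(gatoms[name][1])
        else:
            site = ("group", p.group_label)
            gidx = self.group_by_label.get(p.group_label)
            if gidx is None:
                # shared group: 6 A above its first target residue
                gidx = self._new_group(group_code)
                self.group_by_label[p.group_label] = gidx
                center = self.residues[target]["CA"][1] + np.array([0.0, 0.0, 6.0])
                gatoms = self.groups[gidx][1]
                for name, el, off in template:
                    gatoms[name] = (el, center + np.asarray(off, float))
                    self._mark_site_atom(gatoms[name][1], site)
            gatoms = self.groups[gidx][1]
            if self.groups[gidx][0] not in defn.components[np_slots[0]].codes:
                raise FixtureError(
                    f"group {p.group_label!r} has code {self.groups[gidx][0]!r}, "
                    f"incompatible with {defn.internal_id!r}"
                )
            k = self.group_attach_count.get(gidx, 0)
            self.group_attach_count[gidx] = k + 1
            # pick the k-th candidate group atom (round-robin over the
            # linkage's preference list), then move the receiving residue's
            # atom to the exact distance along a well-separated direction
            present = [n for n in np_names if n in gatoms]
            if not present:
                raise FixtureError(f"group {group_code} lacks atoms {list(np_names)}")
            np_atom = present[k % len(present)]
            base = gatoms[np_atom][1]
            centroid = np.mean([pos for _, pos in gatoms.values()], axis=0)
            outward = base - centroid
            if np.linalg.norm(outward) > 1e-6:
                direction = outward / np.linalg.norm(outward)
            else:
                direction = _SPREAD_DIRECTIONS[k % len(_SPREAD_DIRECTIONS)]
            new_pos = base + direction * d
            res_atoms[aa_atom] = (el_aa, new_pos)
            self._mark_site_atom(new_pos, site)

        if in_truth:
            self.truth.append(
                TruthRecord.make(
                    defn.internal_id,
                    [self.residue_key(*target), self.group_key(gidx)],
                )
            )

    def _plant_crosslink(self, p, defn, in_truth: bool,
                         distance_override: float | None) -> None:
        if len(p.targets) != len(defn.components):
            raise FixtureError(
                f"{defn.internal_id!r} needs {len(defn.components)} targets, "
                f"got {len(p.targets)}"
            )
        for target, comp in zip(p.targets, defn.components):
            self._check_code(target, comp)
            self._claim_target(target)
        # anchored above the first target so distinct plant sites inherit
        # the lateral spacing of their target residues
        center = self.residues[p.targets[0]]["CA"][1] + np.array([0.0, 0.0, 5.0])

        placed: dict[tuple[int, str], np.ndarray] = {}
        site_positions: list[np.ndarray] = []
        axes = [np.array(v, float) for v in
                ((1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, 0, 0), (0, -1, 0))]
        for li, lk in enumerate(defn.linkages):
            t1, t2 = p.targets[lk.component_1], p.targets[lk.component_2]
            a1 = self._linkage_atom(self.residues[t1], lk.atoms_1, f"residue {t1}")
            a2 = self._linkage_atom(self.residues[t2], lk.atoms_2, f"residue {t2}")
            el1 = self.residues[t1][a1][0]
            el2 = self.residues[t2][a2][0]
            d = self._bond_distance(p, defn, el1, el2, distance_override)
            k1, k2 = (lk.component_1, a1), (lk.component_2, a2)
            if k1 in placed and k2 in placed:
                if abs(np.linalg.norm(placed[k1] - placed[k2]) - d) > 1e-6:
                    raise FixtureError(
                        f"{defn.internal_id!r}: conflicting constraints on "
                        f"linkage {li + 1}"
                    )
                continue
            if k1 not in placed and k2 not in placed:
                placed[k1] = center + np.array([0.0, 3.0 * li, 0.0])
                site_positions.append(placed[k1])
            anchor, free = (k1, k2) if k1 in placed else (k2, k1)
            for axis in axes:
                candidate = placed[anchor] + axis * d
                if all(np.linalg.norm(candidate - q) > 1.0 for q in site_positions):
                    placed[free] = candidate
                    site_positions.append(candidate)
                    break
            else:
                raise FixtureError(
                    f"{defn.internal_id!r}: could not place linkage {li + 1}"
                )
        for (slot, name), pos in placed.items():
            target = p.targets[slot]
            el = self.residues[target][name][0]
            self.residues[target][name] = (el, pos)
            self._mark_site_atom(pos)
        if in_truth:
            self.truth.append(
                TruthRecord.make(
                    defn.internal_id, [self.residue_key(*t) for t in p.targets]
                )
            )

    # -- decoys ------------------------------------------------------------

    _DECOY_CHAIN_POOL = "abcdefghijklmnopqrst"

    def add_decoys(self, count: int) -> None:
        """Near-miss placements at threshold + 0.2 A on their own chains."""
        if count > len(self._DECOY_CHAIN_POOL):
            raise FixtureError(f"at most {len(self._DECOY_CHAIN_POOL)} decoys")
        geometric = [
            d for d in self.dictionary
            if d.category is not ModificationCategory.MODIFIED_RESIDUE
            and self._decoy_supported(d)
        ]
        for k in range(count):
            defn = geometric[int(self.rng.integers(0, len(geometric)))]
            cid = self._DECOY_CHAIN_POOL[k]
            lk = defn.linkages[0]
            if defn.category is ModificationCategory.CROSS_LINK:
                codes = [c.codes[0] for c in defn.components]
                self.add_chain(cid, [codes[0], "GLY", "GLY", codes[1]])
                targets = ((cid, 0), (cid, 3))
                el1 = self._template_element(codes[0], lk.atoms_1)
                el2 = self._template_element(codes[1], lk.atoms_2)
                plant = Plant(defn.internal_id, targets)
            else:
                aa_slot = next(
                    i for i, c in enumerate(defn.components)
                    if c.role is ComponentRole.AMINO_ACID
                )
                np_slot = next(
                    i for i, c in enumerate(defn.components)
                    if c.role is ComponentRole.NON_POLYMER
                )
                aa_code = defn.components[aa_slot].codes[0]
                self.add_chain(cid, ["GLY", aa_code, "GLY"])
                aa_names, np_names = (
                    (lk.atoms_1, lk.atoms_2) if lk.component_1 == aa_slot
                    else (lk.atoms_2, lk.atoms_1)
                )
                group_code = next(
                    c for c in defn.components[np_slot].codes
                    if c in _GROUP_TEMPLATES
                )
                el1 = self._template_element(aa_code, aa_names)
                el2 = next(
                    el for n, el, _ in _GROUP_TEMPLATES[group_code]
                    for cand in np_names if n == cand
                )
                plant = Plant(defn.internal_id, ((cid, 1),))
            near_miss = self.cfg.threshold(el1, el2) + 0.2
            self.plant(plant, in_truth=False, distance_override=near_miss)

    def _template_element(self, code: str, names: Sequence[str]) -> str:
        atoms = {n: el for n, el, _ in _BACKBONE + _SIDE_CHAINS.get(code, [])}
        for n in names:
            if n in atoms:
                return atoms[n]
        raise FixtureError(f"template {code!r} lacks atoms {list(names)}")

    def _decoy_supported(self, defn: ModificationDefinition) -> bool:
        try:
            if defn.category is ModificationCategory.CROSS_LINK:
                if len(defn.components) != 2 or len(defn.linkages) != 1:
                    return False
                lk = defn.linkages[0]
                self._template_element(defn.components[0].codes[0], lk.atoms_1)
                self._template_element(defn.components[1].codes[0], lk.atoms_2)
                return True
            aa = [c for c in defn.components if c.role is ComponentRole.AMINO_ACID]
            np_ = [c for c in defn.components if c.role is ComponentRole.NON_POLYMER]
            if len(aa) != 1 or len(np_) != 1 or len(defn.linkages) != 1:
                return False
            if not any(c in _GROUP_TEMPLATES for c in np_[0].codes):
                return False
            if aa[0].codes[0] not in _SIDE_CHAINS:
                return False
            return True
        except FixtureError:
            return False

    # -- checks and emission -----------------------------------------------

    def check_separation(self) -> None:
        """Atoms of distinct planted/decoy sites must stay out of bonding range."""
        for i in range(len(self.site_atoms)):
            si, xi = self.site_atoms[i]
            for j in range(i + 1, len(self.site_atoms)):
                sj, xj = self.site_atoms[j]
                if si != sj and np.linalg.norm(xi - xj) < _SITE_MIN_SEPARATION:
                    raise FixtureError(
                        "infeasible placement: planted sites of different "
                        "modifications come within bonding range"
                    )

    def to_structure(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = self.spec.entry_id
        model = gemmi.Model(1)
        for cid, seq in self.chain_order:
            chain = gemmi.Chain(cid)
            for j, code in enumerate(seq):
                res = gemmi.Residue()
                res.name = code
                res.seqid = gemmi.SeqId(j + 1, " ")
                res.het_flag = "A" if code in CANONICAL_AMINO_ACIDS else "H"
                for name, (el, pos) in self.residues[(cid, j)].items():
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(el)
                    p = np.round(pos, 3)
                    atom.pos = gemmi.Position(*p)
                    atom.occ = 1.0
                    atom.b_iso = 20.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        if self.groups:
            chain = gemmi.Chain(_GROUP_CHAIN)
            for gidx, (code, atoms) in enumerate(self.groups):
                res = gemmi.Residue()
                res.name = code
                res.seqid = gemmi.SeqId(_GROUP_SEQ_START + gidx, " ")
                res.het_flag = "H"
                for name, (el, pos) in atoms.items():
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(el)
                    p = np.round(pos, 3)
                    atom.pos = gemmi.Position(*p)
                    atom.occ = 1.0
                    atom.b_iso = 20.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st


def _write_pair(st: gemmi.Structure, out_dir: Path, stem: str) -> tuple[Path, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{stem}.pdb"
    cif_path = out_dir / f"{stem}.cif"
    st.write_pdb(str(pdb_path))
    st.make_mmcif_document().write_file(str(cif_path))
    return pdb_path, cif_path


def make_fixture(
    spec: FixtureSpec,
    out_dir: str | Path,
    dictionary: Dictionary | None = None,
    bond_config: BondConfig | None = None,
) -> FixtureResult:
    """Emit PDB + mmCIF renderings of a spec and its truth table.

    The truth table lists every planted identification as
    (definition id, sorted residue identity set); decoys never enter it.
    Raises :class:`FixtureError` when a requested placement is infeasible.
    """
    if dictionary is None:
        dictionary = starter_dictionary()
    if bond_config is None:
        bond_config = BondConfig()
    b = _Builder(spec, dictionary, bond_config)
    for cid, seq in spec.chains:
        b.add_chain(cid, seq)
    for p in spec.plants:
        b.plant(p)
    b.add_decoys(spec.decoys)
    b.check_separation()
    st = b.to_structure()
    pdb_path, cif_path = _write_pair(st, Path(out_dir), spec.entry_id.lower())
    truth = sorted(b.truth, key=lambda t: (t.definition_id, t.residues))
    (Path(out_dir) / f"{spec.entry_id.lower()}.truth.json").write_text(
        json.dumps(
            [
                {"definition_id": t.definition_id,
                 "residues": [list(r) for r in t.residues]}
                for t in truth
            ],
            indent=2,
        )
        + "\n"
    )
    return FixtureResult(pdb_path=pdb_path, cif_path=cif_path, truth=truth, spec=spec)


def rotation_matrix(axis: Sequence[float], angle_degrees: float) -> np.ndarray:
    """Rotation about an arbitrary axis (Rodrigues form)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_degrees)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def perturb_fixture(
    source: str | Path,
    out_dir: str | Path,
    rotation: np.ndarray | None = None,
    translation: Sequence[float] | None = None,
    permutation_seed: int | None = None,
) -> tuple[Path, Path]:
    """Apply a rigid motion and/or shuffle record order; truth is unchanged.

    Atom order within residues, chain order, and non-polymer group order are
    shuffled; residue order within polymer chains is preserved because file
    order *is* the polymer sequence.  Writes a PDB + mmCIF pair with the
    same file stem into ``out_dir``.
    """
    source = Path(source)
    st = gemmi.read_structure(str(source))
    st.setup_entities()
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                q = np.round(R @ p + t, 3)
                atom.pos = gemmi.Position(*q)
    if permutation_seed is not None:
        rng = np.random.default_rng(permutation_seed)
        new_model = gemmi.Model(model.num)
        chain_idx = list(rng.permutation(len(model)))
        for ci in chain_idx:
            chain = model[int(ci)]
            new_chain = gemmi.Chain(chain.name)
            polymer = [r for r in chain if r.entity_type == gemmi.EntityType.Polymer]
            others = [r for r in chain if r.entity_type != gemmi.EntityType.Polymer]
            residues = polymer + [others[int(i)] for i in rng.permutation(len(others))]
            for res in residues:
                new_res = gemmi.Residue()
                new_res.name = res.name
                new_res.seqid = res.seqid
                new_res.het_flag = res.het_flag
                atoms = list(res)
                for ai in rng.permutation(len(atoms)):
                    new_res.add_atom(atoms[int(ai)])
                new_chain.add_residue(new_res)
            new_model.add_chain(new_chain)
        st2 = gemmi.Structure()
        st2.name = st.name
        st2.add_model(new_model)
        st2.setup_entities()
        st = st2
    return _write_pair(st, Path(out_dir), source.stem)


# ---------------------------------------------------------------------------
# Ready-made specs


def composite_spec(seed: int = 0, decoys: int = 0, entry_id: str = "CMP1") -> FixtureSpec:
    """One modification per category: phosphoserine, an N-glycosylation
    site, and a disulfide bond."""
    return FixtureSpec(
        seed=seed,
        entry_id=entry_id,
        chains=(("A", ("GLY", "SER", "SEP", "GLY", "ASN", "GLY", "CYS",
                       "GLY", "GLY", "CYS", "GLY")),),
        plants=(
            Plant("phosphoserine", (("A", 2),)),
            Plant("n-glycosyl-asparagine", (("A", 4),), distance=1.43),
            Plant("disulfide", (("A", 6), ("A", 9)), distance=2.05),
        ),
        decoys=decoys,
    )


def ferredoxin_like_spec(seed: int = 0, entry_id: str = "FDX1") -> FixtureSpec:
    """Synthetic stand-in for a two-cluster ferredoxin: one 3Fe-4S and one
    4Fe-4S cluster, each coordinated by cysteines of a single chain.

    This is a synthetic construction, not archive coordinates; it exercises
    the same iron-sulfur attachment definitions a real ferredoxin entry
    would."""
    seq = ["ALA"] * 30
    for i in (3, 6, 9, 12, 18, 21, 24):
        seq[i] = "CYS"
    return FixtureSpec(
        seed=seed,
        entry_id=entry_id,
        chains=(("A", tuple(seq)),),
        plants=(
            Plant("3fe4s-cysteine", (("A", 3),), group_label="f3s"),
            Plant("3fe4s-cysteine", (("A", 6),), group_label="f3s"),
            Plant("3fe4s-cysteine", (("A", 9),), group_label="f3s"),
            Plant("4fe4s-cysteine", (("A", 12),), group_label="sf4"),
            Plant("4fe4s-cysteine", (("A", 18),), group_label="sf4"),
            Plant("4fe4s-cysteine", (("A", 21),), group_label="sf4"),
            Plant("4fe4s-cysteine", (("A", 24),), group_label="sf4"),
        ),
    )


_RANDOM_MODRES = ("phosphoserine", "phosphothreonine", "phosphotyrosine",
                  "hydroxyproline", "selenomethionine", "n6-acetyllysine")
_RANDOM_GEOMETRIC = ("disulfide", "isopeptide-lys-asp", "isopeptide-lys-asn",
                     "n-glycosyl-asparagine", "o-glycosyl-serine",
                     "o-glycosyl-threonine", "zinc-histidine", "zinc-cysteine",
                     "4fe4s-cysteine", "3fe4s-cysteine")
_MODRES_CODE = {"phosphoserine": "SEP", "phosphothreonine": "TPO",
                "phosphotyrosine": "PTR", "hydroxyproline": "HYP",
                "selenomethionine": "MSE", "n6-acetyllysine": "ALY"}
_GEOMETRIC_AA_CODES = {
    "disulfide": ("CYS", "CYS"), "isopeptide-lys-asp": ("LYS", "ASP"),
    "isopeptide-lys-asn": ("LYS", "ASN"), "n-glycosyl-asparagine": ("ASN",),
    "o-glycosyl-serine": ("SER",), "o-glycosyl-threonine": ("THR",),
    "zinc-histidine": ("HIS",), "zinc-cysteine": ("CYS",),
    "4fe4s-cysteine": ("CYS",), "3fe4s-cysteine": ("CYS",),
}
_FILLER = ("ALA", "GLY", "VAL", "LEU", "PRO", "PHE", "ILE", "ARG", "GLN", "TRP")


def random_spec(seed: int) -> FixtureSpec:
    """A random valid fixture spec covering all three categories.

    Chains are random filler sequences; plant target positions are spaced
    at least three residues apart so planted sites cannot interact."""
    rng = np.random.default_rng(seed)
    n_chains = int(rng.integers(1, 3))
    chain_ids = ["A", "B"][:n_chains]
    chains: dict[str, list[str]] = {}
    slots: list[tuple[str, int]] = []
    for cid in chain_ids:
        length = int(rng.integers(10, 18))
        chains[cid] = [str(rng.choice(_FILLER)) for _ in range(length)]
        slots.extend((cid, j) for j in range(1, length - 1, 3))
    order = rng.permutation(len(slots))
    slots = [slots[int(i)] for i in order]

    plants: list[Plant] = []
    n_modres = int(rng.integers(1, 3))
    n_geo = int(rng.integers(1, 4))
    for _ in range(n_modres):
        if not slots:
            break
        def_id = str(rng.choice(_RANDOM_MODRES))
        cid, j = slots.pop()
        chains[cid][j] = _MODRES_CODE[def_id]
        plants.append(Plant(def_id, ((cid, j),)))
    for _ in range(n_geo):
        def_id = str(rng.choice(_RANDOM_GEOMETRIC))
        codes = _GEOMETRIC_AA_CODES[def_id]
        if len(slots) < len(codes):
            break
        targets = []
        for code in codes:
            cid, j = slots.pop()
            chains[cid][j] = code
            targets.append((cid, j))
        jitter = float(rng.uniform(-0.05, 0.05))
        plants.append(
            Plant(def_id, tuple(targets),
                  distance=round(DEFAULT_BOND_LENGTHS[def_id] + jitter, 3))
        )
    decoys = int(rng.integers(0, 4))
    return FixtureSpec(
        seed=seed,
        entry_id=f"RF{seed % 10000:04d}",
        chains=tuple((cid, tuple(chains[cid])) for cid in chain_ids),
        plants=tuple(plants),
        decoys=decoys,
    )
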