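"""Covalent-bond detection from interatomic distances.

Two heavy atoms are considered covalently bonded when their distance does
not exceed the sum of their element covalent radii plus a tolerance
(0.4 Angstrom by default), and is not below a small lower cutoff that
rejects duplicated/overlapping coordinates.  The bundled radii table is a
pinned single-bond compilation; it can be overridden per scan.

``find_close_pairs`` is the workhorse for whole-structure scans: it reports
every bonded pair between two atom selections, accelerated with a KD-tree
so batch scans stay near-linear in atom count.  Its contract is exactly the
brute-force all-pairs scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from modfinder.structure_io import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "CovalentRadiiTable",
    "BondConfig",
    "AtomRef",
    "DetectedBond",
    "is_bonded",
    "find_close_pairs",
    "atom_selection",
]

_REQUIRED_ELEMENTS = frozenset(
    "C N O S P SE FE ZN MG MN CU NI CA NA K CO MO W I CL BR F".split()
)


@dataclass(frozen=True)
class CovalentRadiiTable:
    """Element -> covalent radius (Angstrom), with a fallback for unknowns."""

    radius_by_element: dict[str, float]
    default_radius: float = 1.5

    def __post_init__(self) -> None:
        for el, r in self.radius_by_element.items():
            if not (0.2 < r < 3.0):
                raise ValueError(f"radius for {el} out of range (0.2, 3.0): {r}")
        missing = _REQUIRED_ELEMENTS - set(self.radius_by_element)
        if missing:
            raise ValueError(f"radii table missing required elements: {sorted(missing)}")

    def get(self, element: str) -> float:
        r = self.radius_by_element.get(element.upper())
        if r is None:
            warnings.warn(
                f"no covalent radius for element {element!r}; "
                f"using default {self.default_radius} A",
                stacklevel=2,
            )
            return self.default_radius
        return r

    @property
    def max_radius(self) -> float:
        return max(max(self.radius_by_element.values()), self.default_radius)

    @classmethod
    def from_file(cls, path: str | Path, default_radius: float = 1.5) -> "CovalentRadiiTable":
        """Read a two-column ``ELEMENT radius`` text table ('#' comments)."""
        radii: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"bad radii line: {line!r}")
            radii[parts[0].upper()] = float(parts[1])
        return cls(radius_by_element=radii, default_radius=default_radius)

    @classmethod
    def bundled(cls) -> "CovalentRadiiTable":
        with resources.as_file(
            resources.files("modfinder.data") / "covalent_radii.txt"
        ) as p:
            return cls.from_file(p)


@dataclass(frozen=True)
class BondConfig:
    """Parameters of the distance criterion.

    ``tolerance`` is added to the sum of covalent radii (default 0.4 A);
    ``min_distance`` rejects near-zero distances arising from coordinate
    pathologies such as duplicated atoms (default 0.5 A).
    """

    tolerance: float = 0.4
    radii: CovalentRadiiTable = field(default_factory=CovalentRadiiTable.bundled)
    min_distance: float = 0.5

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be > 0")

    def threshold(self, element_1: str, element_2: str) -> float:
        return self.radii.get(element_1) + self.radii.get(element_2) + self.tolerance


@dataclass(frozen=True, order=True)
class AtomRef:
    """Reference to one atom: residue identity plus atom name."""

    chain_id: str
    seq_id: int
    insertion_code: str
    atom_name: str
    component_code: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)


@dataclass(frozen=True)
class DetectedBond:
    """An unordered atom pair passing the covalent-distance criterion.

    Stored in canonical order: ``atom_1 <= atom_2`` lexicographically on
    (chain, seq, insertion, atom name).
    """

    atom_1: AtomRef
    atom_2: AtomRef
    distance: float
    threshold: float

    @staticmethod
    def make(a: AtomRef, b: AtomRef, distance: float, threshold: float) -> "DetectedBond":
        if (b.chain_id, b.seq_id, b.insertion_code, b.atom_name) < (
            a.chain_id, a.seq_id, a.insertion_code, a.atom_name,
        ):
            a, b = b, a
        return DetectedBond(atom_1=a, atom_2=b, distance=distance, threshold=threshold)

    @property
    def sort_key(self):
        return (
            self.atom_1.chain_id, self.atom_1.seq_id, self.atom_1.insertion_code,
            self.atom_1.atom_name,
            self.atom_2.chain_id, self.atom_2.seq_id, self.atom_2.insertion_code,
            self.atom_2.atom_name,
        )

    def involves(self, residue_key: tuple[str, int, str]) -> bool:
        return self.atom_1.residue_key == residue_key or self.atom_2.residue_key == residue_key


def is_bonded(a: AtomRecord, b: AtomRecord, cfg: BondConfig | None = None) -> bool:
    """Distance criterion: ``min_distance <= |a-b| <= r(a) + r(b) + tolerance``."""
    if cfg is None:
        cfg = BondConfig()
    d = float(np.linalg.norm(a.coords - b.coords))
    return cfg.min_distance <= d <= cfg.threshold(a.element, b.element)


Selection = Sequence[tuple[ResidueRecord, AtomRecord]]


def atom_selection(
    model: StructureModel,
    atom_names: Iterable[str] | None = None,
    component_codes: Iterable[str] | None = None,
    polymer: bool | None = None,
    include_hydrogens: bool = False,
) -> list[tuple[ResidueRecord, AtomRecord]]:
    """Collect (residue, atom) pairs from a model by simple filters."""
    names = set(atom_names) if atom_names is not None else None
    codes = set(component_codes) if component_codes is not None else None
    out: list[tuple[ResidueRecord, AtomRecord]] = []
    for res in model.iter_residues():
        if polymer is not None and res.is_polymer != polymer:
            continue
        if codes is not None and res.component_code not in codes:
            continue
        for atom in res.atoms:
            if not include_hydrogens and atom.is_hydrogen:
                continue
            if names is not None and atom.name not in names:
                continue
            out.append((res, atom))
    return out


def _ref(res: ResidueRecord, atom: AtomRecord) -> AtomRef:
    return AtomRef(
        chain_id=res.chain_id,
        seq_id=res.seq_id,
        insertion_code=res.insertion_code,
        atom_name=atom.name,
        component_code=res.component_code,
    )


def find_close_pairs(
    group_a: Selection,
    group_b: Selection,
    cfg: BondConfig | None = None,
) -> list[DetectedBond]:
    """All bonded pairs (a in group_a, b in group_b), atoms in the same
    residue excluded, each unordered pair reported once, canonically sorted.

    A KD-tree over the larger group limits candidate pairs to those within
    the largest possible threshold ``2 * r_max + tolerance``; every candidate
    is then checked against its exact per-element threshold, so the result
    equals the brute-force all-pairs scan.
    """
    if cfg is None:
        cfg = BondConfig()
    if not group_a or not group_b:
        return []

    coords_a = np.array([a.coords for _, a in group_a])
    coords_b = np.array([b.coords for _, b in group_b])
    search_radius = 2.0 * cfg.radii.max_radius + cfg.tolerance

    tree = cKDTree(coords_b)
    neighbor_lists = tree.query_ball_point(coords_a, r=search_radius)

    seen: set[tuple[AtomRef, AtomRef]] = set()
    bonds: list[DetectedBond] = []
    for i, neighbors in enumerate(neighbor_lists):
        res_a, atom_a = group_a[i]
        for j in neighbors:
            res_b, atom_b = group_b[j]
            if res_a.id_key == res_b.id_key:
                continue
            d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
            thr = cfg.threshold(atom_a.element, atom_b.element)
            if not (cfg.min_distance <= d <= thr):
                continue
            bond = DetectedBond.make(_ref(res_a, atom_a), _ref(res_b, atom_b), d, thr)
            key = (bond.atom_1, bond.atom_2)
            if key in seen:
                continue
            seen.add(key)
            bonds.append(bond)
    bonds.sort(key=lambda b: b.sort_key)
    return bonds
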