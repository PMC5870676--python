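"""Read PDB / mmCIF coordinate files into a uniform structure model.

Parsing is delegated to gemmi; this module reduces its rich structure object
to exactly what modification identification needs: polymer chains as ordered
residue lists, non-polymer groups (ligands, ions, glycans), stripped atom
names, elements and coordinates.  Waters are dropped.  Only one coordinate
model is kept (the first, unless another is selected); for alternate
conformations only the highest-occupancy location of each atom name is kept,
ties broken by the lexicographically smallest altloc, so bond detection sees
one geometry per atom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureError",
    "StructureParseError",
    "StructureFormatError",
    "ChainLookupError",
    "parse_structure",
]

logger = logging.getLogger(__name__)

_WATER_CODES = frozenset({"HOH", "DOD", "WAT"})


class StructureError(Exception):
    pass


class StructureParseError(StructureError):
    """Unreadable or truncated coordinate file."""


class StructureFormatError(StructureError):
    """File is neither PDB nor mmCIF."""


class ChainLookupError(StructureError, KeyError):
    """Requested chain id not present in the model."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: stripped PDB name, element symbol, coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(3)
        )

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class ResidueRecord:
    """One residue or non-polymer group, identified by author numbering."""

    component_code: str
    chain_id: str
    seq_id: int
    insertion_code: str = ""
    is_polymer: bool = True
    polymer_index: int | None = None
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def id_key(self) -> tuple[str, int, str]:
        """(chain, seq, insertion) — unique within one model."""
        return (self.chain_id, self.seq_id, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.component_code} {self.chain_id}{self.seq_id}{self.insertion_code}"

    def find_atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """One coordinate model: polymer chains plus non-polymer groups."""

    entry_id: str
    model_number: int
    chains: list[tuple[str, list[ResidueRecord]]]
    nonpolymer_groups: list[ResidueRecord]
    source_format: str  # "PDB" or "mmCIF"

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def get_chain(self, chain_id: str) -> list[ResidueRecord]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise ChainLookupError(
            f"chain {chain_id!r} not found; available: {self.chain_ids()}"
        )

    def polymer_sequence(self, chain_id: str) -> list[str]:
        """Component codes of one chain in polymer order (modified residues
        appear under their own codes, e.g. SEP)."""
        return [r.component_code for r in self.get_chain(chain_id)]

    def iter_polymer_residues(self) -> Iterator[ResidueRecord]:
        for _, residues in self.chains:
            yield from residues

    def iter_residues(self) -> Iterator[ResidueRecord]:
        yield from self.iter_polymer_residues()
        yield from self.nonpolymer_groups

    def residue_by_key(self, key: tuple[str, int, str]) -> ResidueRecord:
        for r in self.iter_residues():
            if r.id_key == key:
                return r
        raise KeyError(f"no residue {key}")


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy, ties -> smallest altloc."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        name = atom.name.strip()
        if name not in best:
            best[name] = atom
            order.append(name)
        else:
            cur = best[name]
            alt_cur = cur.altloc if cur.altloc != "\0" else ""
            alt_new = atom.altloc if atom.altloc != "\0" else ""
            if (atom.occ, _neg_alt(alt_new)) > (cur.occ, _neg_alt(alt_cur)):
                best[name] = atom
    return [best[n] for n in order]


def _neg_alt(alt: str) -> tuple[int, ...]:
    # larger = preferred; empty altloc or lexicographically smaller wins ties
    return tuple(-ord(c) for c in alt) if alt else (1,)


def _element_symbol(atom: gemmi.Atom) -> str | None:
    el = atom.element
    if el is not None and el.atomic_number > 0:
        return el.name.upper()
    # old PDB files without an element column: first letter run of the name
    name = atom.name.strip()
    letters = "".join(c for c in name if c.isalpha())
    if not letters:
        return None
    # heuristic: single leading letter (C/N/O/S/P/H) unless a two-letter
    # element is plausible from the full name (e.g. FE, ZN, SE, MG)
    two = letters[:2].upper()
    if two in _TWO_LETTER_ELEMENTS:
        return two
    return letters[0].upper()


_TWO_LETTER_ELEMENTS = frozenset(
    "FE ZN SE MG MN CU NI CA NA CL BR MO CO CD HG PB PT AU AL SI AS".split()
)


def _convert_residue(
    res: gemmi.Residue,
    chain_id: str,
    is_polymer: bool,
    polymer_index: int | None,
) -> ResidueRecord:
    atoms: list[AtomRecord] = []
    for atom in _pick_altlocs(res):
        element = _element_symbol(atom)
        if element is None:
            logger.warning(
                "atom %r in %s %s%d has no resolvable element; skipped",
                atom.name, res.name, chain_id, res.seqid.num,
            )
            continue
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        if not np.all(np.isfinite(pos)):
            logger.warning(
                "atom %r in %s %s%d has non-finite coordinates; skipped",
                atom.name, res.name, chain_id, res.seqid.num,
            )
            continue
        altloc = atom.altloc if atom.altloc != "\0" else ""
        atoms.append(
            AtomRecord(
                name=atom.name.strip(),
                element=element,
                coords=pos,
                altloc=altloc,
                occupancy=float(atom.occ),
            )
        )
    icode = res.seqid.icode.strip()
    return ResidueRecord(
        component_code=res.name.strip().upper(),
        chain_id=chain_id,
        seq_id=res.seqid.num,
        insertion_code=icode,
        is_polymer=is_polymer,
        polymer_index=polymer_index,
        atoms=atoms,
    )


def parse_structure(
    path: str | Path,
    model_selector: int | None = None,
    entry_id: str | None = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        Coordinate file; the format is detected from content/extension.
    model_selector:
        Serial number of the coordinate model to keep (NMR ensembles);
        by default the first model is used.
    entry_id:
        Override for the entry identifier; defaults to the uppercased file
        stem, which is format-independent.
    """
    path = Path(path)
    if not path.is_file():
        raise StructureParseError(f"{path}: no such file")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    fmt = st.input_format
    if fmt == gemmi.CoorFormat.Pdb:
        source_format = "PDB"
    elif fmt in (gemmi.CoorFormat.Mmcif, gemmi.CoorFormat.Mmjson):
        source_format = "mmCIF"
    else:
        raise StructureFormatError(f"{path}: unrecognized coordinate format")
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no coordinate model")

    st.setup_entities()

    if model_selector is None:
        model = st[0]
    else:
        model = None
        for m in st:
            if m.num == model_selector:
                model = m
                break
        if model is None:
            raise StructureParseError(
                f"{path}: no model numbered {model_selector} "
                f"(available: {[m.num for m in st]})"
            )

    if model.count_atom_sites() == 0:
        raise StructureParseError(f"{path}: file contains no atom records")

    chains: list[tuple[str, list[ResidueRecord]]] = []
    nonpolymer: list[ResidueRecord] = []
    for chain in model:
        polymer_residues: list[ResidueRecord] = []
        for res in chain:
            code = res.name.strip().upper()
            if code in _WATER_CODES or res.entity_type == gemmi.EntityType.Water:
                continue
            if res.entity_type == gemmi.EntityType.Polymer:
                polymer_residues.append(
                    _convert_residue(res, chain.name, True, len(polymer_residues))
                )
            else:
                nonpolymer.append(_convert_residue(res, chain.name, False, None))
        if polymer_residues:
            chains.append((chain.name, polymer_residues))

    return StructureModel(
        entry_id=entry_id if entry_id is not None else path.stem.upper(),
        model_number=model.num,
        chains=chains,
        nonpolymer_groups=nonpolymer,
        source_format=source_format,
    )
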