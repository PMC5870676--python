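"""The three identification algorithms.

* Modified residues: pure sequence scan — a polymer residue whose
  3-character component code equals a MODIFIED_RESIDUE definition's code is
  a match; no geometry is consulted.
* Attachments: for each ATTACHMENT definition, every (polymer residue,
  non-polymer group) combination whose codes match the definition's
  components and whose listed atom pair passes the covalent-distance
  criterion is reported, one record per bonded pair.
* Cross-links: for each CROSS_LINK definition, residues are assigned to the
  definition's component slots by backtracking over the detected-bond graph
  restricted to the atoms the definition names; every assignment in which
  all linkages are realized by detected bonds is reported once, canonicalized
  on the residue identity set so symmetric definitions (CYS-CYS) do not
  double-report.

Geometry is the sole evidence for attachments and cross-links: SSBOND /
LINK / CONECT metadata is never consulted.  Residues missing a linkage atom
(disorder) simply fail to match.  Categories are reported independently; a
residue may appear in records of more than one category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from modfinder.bonds import (
    AtomRef,
    BondConfig,
    DetectedBond,
    find_close_pairs,
)
from modfinder.dictionary import (
    ComponentRole,
    Dictionary,
    LinkageSpec,
    ModificationCategory,
    ModificationDefinition,
    Terminal,
)
from modfinder.structure_io import ResidueRecord, StructureModel

__all__ = [
    "ScanConfig",
    "IdentifiedModification",
    "ModificationReport",
    "identify_modified_residues",
    "identify_attachments",
    "identify_crosslinks",
    "identify_all",
]

_ALL_CATEGORIES = frozenset(ModificationCategory)

_CATEGORY_ORDER = {
    ModificationCategory.MODIFIED_RESIDUE: 0,
    ModificationCategory.ATTACHMENT: 1,
    ModificationCategory.CROSS_LINK: 2,
}


@dataclass(frozen=True)
class ScanConfig:
    """What to scan for and under which bond criterion."""

    dictionary: Dictionary
    bond_config: BondConfig = field(default_factory=BondConfig)
    categories: frozenset[ModificationCategory] = _ALL_CATEGORIES

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", frozenset(self.categories))
        if not self.categories:
            raise ValueError("categories must be non-empty")


@dataclass(frozen=True)
class IdentifiedModification:
    """A definition matched to concrete residues (and bonds) in a structure.

    ``residues`` is ordered like the definition's component list; ``bonds``
    like its linkage list (empty for modified residues).
    """

    definition: ModificationDefinition
    residues: tuple[ResidueRecord, ...]
    bonds: tuple[DetectedBond, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "bonds", tuple(self.bonds))

    @property
    def category(self) -> ModificationCategory:
        return self.definition.category

    @property
    def residue_keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(r.id_key for r in self.residues)

    @property
    def dedup_key(self) -> tuple[str, tuple[tuple[str, int, str], ...]]:
        """(definition id, sorted residue identity set) — no-double-count key."""
        return (self.definition.internal_id, tuple(sorted(self.residue_keys)))

    @property
    def sort_key(self):
        return (
            _CATEGORY_ORDER[self.category],
            self.definition.internal_id,
            tuple(sorted(self.residue_keys)),
        )


@dataclass
class ModificationReport:
    """All identifications for one entry, canonically ordered."""

    entry_id: str
    identifications: list[IdentifiedModification]
    tolerance: float
    dictionary_version: str

    def by_category(
        self, category: ModificationCategory
    ) -> list[IdentifiedModification]:
        return [m for m in self.identifications if m.category is category]

    def __len__(self) -> int:
        return len(self.identifications)


def _terminal_ok(res: ResidueRecord, terminal: Terminal, chain_len: int) -> bool:
    if terminal is Terminal.ANY:
        return True
    if res.polymer_index is None:
        return False
    if terminal is Terminal.N_TERMINAL:
        return res.polymer_index == 0
    return res.polymer_index == chain_len - 1


def _chain_lengths(model: StructureModel) -> dict[str, int]:
    return {cid: len(residues) for cid, residues in model.chains}


def identify_modified_residues(
    model: StructureModel, cfg: ScanConfig
) -> list[IdentifiedModification]:
    """Sequence scan for nonstandard residue codes on polymer chains."""
    chain_len = _chain_lengths(model)
    defs = cfg.dictionary.by_category(ModificationCategory.MODIFIED_RESIDUE)
    out: list[IdentifiedModification] = []
    for _, residues in model.chains:
        for res in residues:
            for d in defs:
                comp = d.components[0]
                if comp.matches_code(res.component_code) and _terminal_ok(
                    res, comp.terminal, chain_len[res.chain_id]
                ):
                    out.append(IdentifiedModification(definition=d, residues=(res,)))
    out.sort(key=lambda m: m.sort_key)
    return out


# ---------------------------------------------------------------------------
# Geometric matching shared by attachments and cross-links


def _component_candidates(
    model: StructureModel, defn: ModificationDefinition
) -> list[list[ResidueRecord]]:
    chain_len = _chain_lengths(model)
    candidates: list[list[ResidueRecord]] = []
    for comp in defn.components:
        if comp.role is ComponentRole.AMINO_ACID:
            pool: Iterable[ResidueRecord] = model.iter_polymer_residues()
        else:
            pool = model.nonpolymer_groups
        matches = [
            r
            for r in pool
            if comp.matches_code(r.component_code)
            and (
                comp.role is ComponentRole.NON_POLYMER
                or _terminal_ok(r, comp.terminal, chain_len[r.chain_id])
            )
        ]
        matches.sort(key=lambda r: r.id_key)
        candidates.append(matches)
    return candidates


def _linkage_bonds(
    candidates: Sequence[Sequence[ResidueRecord]],
    linkage: LinkageSpec,
    cfg: BondConfig,
) -> dict[tuple[tuple[str, int, str], tuple[str, int, str]], DetectedBond]:
    """Bond per qualifying residue pair for one linkage.

    When several candidate atom pairs are bonded, the pair earliest in the
    linkage's preference order (atoms_1 index, then atoms_2 index) wins.
    """
    cands_1 = candidates[linkage.component_1]
    cands_2 = candidates[linkage.component_2]
    sel_1 = [
        (r, a)
        for r in cands_1
        for name in linkage.atoms_1
        if (a := r.find_atom(name)) is not None and not a.is_hydrogen
    ]
    sel_2 = [
        (r, a)
        for r in cands_2
        for name in linkage.atoms_2
        if (a := r.find_atom(name)) is not None and not a.is_hydrogen
    ]
    raw = find_close_pairs(sel_1, sel_2, cfg)

    pref_1 = {name: i for i, name in enumerate(linkage.atoms_1)}
    pref_2 = {name: i for i, name in enumerate(linkage.atoms_2)}
    keys_1 = {r.id_key for r in cands_1}
    keys_2 = {r.id_key for r in cands_2}

    best: dict[tuple, tuple[tuple[int, int], DetectedBond]] = {}
    for bond in raw:
        # orient the canonical bond back onto (end 1, end 2)
        for a1, a2 in ((bond.atom_1, bond.atom_2), (bond.atom_2, bond.atom_1)):
            if (
                a1.residue_key in keys_1
                and a2.residue_key in keys_2
                and a1.atom_name in pref_1
                and a2.atom_name in pref_2
            ):
                key = (a1.residue_key, a2.residue_key)
                pref = (pref_1[a1.atom_name], pref_2[a2.atom_name])
                if key not in best or pref < best[key][0]:
                    best[key] = (pref, bond)
    return {k: b for k, (_, b) in best.items()}


def _match_definition(
    model: StructureModel, defn: ModificationDefinition, cfg: BondConfig
) -> list[IdentifiedModification]:
    """Backtracking assignment of residues to a definition's component slots."""
    candidates = _component_candidates(model, defn)
    if any(not c for c in candidates):
        return []
    linkage_bonds = [_linkage_bonds(candidates, lk, cfg) for lk in defn.linkages]
    if any(not lb for lb in linkage_bonds):
        return []

    n = len(defn.components)
    results: dict[tuple, IdentifiedModification] = {}
    assignment: list[ResidueRecord | None] = [None] * n

    def linkages_ok(upto: int) -> bool:
        for lk, bonds in zip(defn.linkages, linkage_bonds):
            r1, r2 = assignment[lk.component_1], assignment[lk.component_2]
            if r1 is None or r2 is None:
                continue
            if max(lk.component_1, lk.component_2) != upto:
                continue
            if (r1.id_key, r2.id_key) not in bonds:
                return False
        return True

    def backtrack(slot: int) -> None:
        if slot == n:
            residues = tuple(assignment)  # type: ignore[arg-type]
            bonds = tuple(
                linkage_bonds[i][
                    (assignment[lk.component_1].id_key, assignment[lk.component_2].id_key)
                ]
                for i, lk in enumerate(defn.linkages)
            )
            m = IdentifiedModification(definition=defn, residues=residues, bonds=bonds)
            results.setdefault(m.dedup_key, m)
            return
        used = {r.id_key for r in assignment[:slot] if r is not None}
        for res in candidates[slot]:
            if res.id_key in used:
                continue
            assignment[slot] = res
            if linkages_ok(slot):
                backtrack(slot + 1)
            assignment[slot] = None

    backtrack(0)
    out = list(results.values())
    out.sort(key=lambda m: m.sort_key)
    return out


def identify_attachments(
    model: StructureModel, cfg: ScanConfig
) -> list[IdentifiedModification]:
    """Geometric scan for polymer-residue-to-component attachments.

    A non-polymer group bonded to k residues under one definition yields k
    records (one per bonded pair); records are deduplicated on the
    (definition, residue set) identity.
    """
    out: list[IdentifiedModification] = []
    for d in cfg.dictionary.by_category(ModificationCategory.ATTACHMENT):
        out.extend(_match_definition(model, d, cfg.bond_config))
    out.sort(key=lambda m: m.sort_key)
    return out


def identify_crosslinks(
    model: StructureModel, cfg: ScanConfig
) -> list[IdentifiedModification]:
    """Geometric scan for covalent cross-links between amino-acid residues.

    Intra- and inter-chain links are both reported; each distinct residue
    set is reported once per definition.  Cross-links whose participant is
    itself a nonstandard component are still found by plain code matching,
    exactly like modified residues, because such residues carry their own
    3-character codes.
    """
    out: list[IdentifiedModification] = []
    for d in cfg.dictionary.by_category(ModificationCategory.CROSS_LINK):
        out.extend(_match_definition(model, d, cfg.bond_config))
    out.sort(key=lambda m: m.sort_key)
    return out


def identify_all(model: StructureModel, cfg: ScanConfig) -> ModificationReport:
    """Run the configured category scans and assemble the per-entry report."""
    identifications: list[IdentifiedModification] = []
    if ModificationCategory.MODIFIED_RESIDUE in cfg.categories:
        identifications.extend(identify_modified_residues(model, cfg))
    if ModificationCategory.ATTACHMENT in cfg.categories:
        identifications.extend(identify_attachments(model, cfg))
    if ModificationCategory.CROSS_LINK in cfg.categories:
        identifications.extend(identify_crosslinks(model, cfg))

    # safety net: drop duplicates on (definition, residue set)
    seen: set = set()
    unique: list[IdentifiedModification] = []
    for m in identifications:
        if m.dedup_key not in seen:
            seen.add(m.dedup_key)
            unique.append(m)
    unique.sort(key=lambda m: m.sort_key)
    return ModificationReport(
        entry_id=model.entry_id,
        identifications=unique,
        tolerance=cfg.bond_config.tolerance,
        dictionary_version=cfg.dictionary.version,
    )
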