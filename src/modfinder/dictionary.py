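"""Modification dictionary: domain types, XML reader/writer, validation.

A :class:`Dictionary` is a flat list of :class:`ModificationDefinition`
records, each describing one protein modification in terms of the chemical
components involved (3-character wwPDB component codes) and, for attachments
and cross-links, the atom pairs whose covalent bonding constitutes the
modification.  The dictionary is stored as UTF-8 XML::

    <protein-modifications version="...">
      <modification id="disulfide" category="cross-link">
        <psimod-id>MOD:00034</psimod-id>
        <resid-id>AA0025</resid-id>
        <name>L-cystine (disulfide bond)</name>
        <keyword>redox</keyword>
        <component index="1" role="amino-acid" terminal="any">
          <code>CYS</code>
        </component>
        <component index="2" role="amino-acid" terminal="any">
          <code>CYS</code>
        </component>
        <linkage>
          <end component="1" atoms="SG"/>
          <end component="2" atoms="SG"/>
        </linkage>
      </modification>
      ...
    </protein-modifications>

Atom lists in ``atoms`` are comma-separated, in order of preference; the
first name present in the structure and satisfying the bond criterion wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from lxml import etree

__all__ = [
    "ModificationCategory",
    "ComponentRole",
    "Terminal",
    "ComponentSpec",
    "LinkageSpec",
    "ModificationDefinition",
    "Dictionary",
    "DictionaryError",
    "DictionaryParseError",
    "DictionaryValidationError",
    "load_dictionary",
    "save_dictionary",
    "starter_dictionary",
    "validate_definition",
]

#: The 20 canonical amino-acid component codes.  A modified residue must use
#: a code outside this set (its own CCD code, e.g. SEP for phosphoserine).
CANONICAL_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE
       LEU LYS MET PHE PRO SER THR TRP TYR VAL""".split()
)

_CODE_RE = re.compile(r"^[A-Z0-9]{1,3}$")
_PSIMOD_RE = re.compile(r"^MOD:\d{5}$")
_RESID_RE = re.compile(r"^AA\d{4}$")


class DictionaryError(Exception):
    """Base class for dictionary I/O and validation failures."""


class DictionaryParseError(DictionaryError):
    """Malformed XML; message names the offending line where known."""


class DictionaryValidationError(DictionaryError):
    """A definition violates its category invariants."""


class ModificationCategory(Enum):
    """The three modification categories.

    ``MODIFIED_RESIDUE``: a single nonstandard amino-acid component.
    ``ATTACHMENT``: polymer residue(s) covalently bonded to a separate
    chemical component (glycan, ion, cofactor).
    ``CROSS_LINK``: two or more amino-acid residues joined by non-peptide
    covalent bonds.
    """

    MODIFIED_RESIDUE = "modified-residue"
    ATTACHMENT = "attachment"
    CROSS_LINK = "cross-link"


class ComponentRole(Enum):
    AMINO_ACID = "amino-acid"
    NON_POLYMER = "non-polymer"


class Terminal(Enum):
    """Restriction of an amino-acid component to a chain terminus."""

    ANY = "any"
    N_TERMINAL = "n"
    C_TERMINAL = "c"


@dataclass(frozen=True)
class ComponentSpec:
    """One chemical component slot of a definition.

    ``codes`` lists acceptable 3-character component codes (alternates such
    as anomeric forms may share one slot); ``role`` says whether the slot is
    filled from polymer chains or from non-polymer groups.
    """

    codes: tuple[str, ...]
    role: ComponentRole = ComponentRole.AMINO_ACID
    terminal: Terminal = Terminal.ANY

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))

    def matches_code(self, code: str) -> bool:
        return code in self.codes


@dataclass(frozen=True)
class LinkageSpec:
    """A covalent bond requirement between two component slots.

    Component indices are 0-based positions in the definition's component
    list.  Atom name lists are ordered by preference: when several candidate
    atom pairs are bonded, the first (by ``atoms_1`` then ``atoms_2`` order)
    is reported.
    """

    component_1: int
    atoms_1: tuple[str, ...]
    component_2: int
    atoms_2: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms_1", tuple(self.atoms_1))
        object.__setattr__(self, "atoms_2", tuple(self.atoms_2))


@dataclass(frozen=True)
class ModificationDefinition:
    """One dictionary record: a modification and how to recognize it."""

    internal_id: str
    name: str
    category: ModificationCategory
    components: tuple[ComponentSpec, ...]
    linkages: tuple[LinkageSpec, ...] = ()
    psimod_id: str | None = None
    resid_id: str | None = None
    description: str | None = None
    systematic_name: str | None = None
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "linkages", tuple(self.linkages))
        object.__setattr__(self, "keywords", tuple(self.keywords))

    @property
    def all_codes(self) -> frozenset[str]:
        return frozenset(c for comp in self.components for c in comp.codes)


def _linkage_graph_connected(defn: ModificationDefinition) -> bool:
    """True iff the linkages connect all component slots into one graph."""
    n = len(defn.components)
    if n <= 1:
        return True
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for lk in defn.linkages:
        if 0 <= lk.component_1 < n and 0 <= lk.component_2 < n:
            adj[lk.component_1].add(lk.component_2)
            adj[lk.component_2].add(lk.component_1)
    seen = {0}
    stack = [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


def validate_definition(defn: ModificationDefinition) -> list[str]:
    """Check one definition against its category invariants.

    Returns a list of human-readable violation descriptions; an empty list
    means the definition is valid.  Violations are data, not exceptions.
    """
    v: list[str] = []
    if not defn.internal_id:
        v.append("internal_id must be non-empty")
    if not defn.name:
        v.append("name must be non-empty")
    if defn.psimod_id is not None and not _PSIMOD_RE.match(defn.psimod_id):
        v.append(f"psimod_id {defn.psimod_id!r} does not match MOD:NNNNN")
    if defn.resid_id is not None and not _RESID_RE.match(defn.resid_id):
        v.append(f"resid_id {defn.resid_id!r} does not match AANNNN")

    for i, comp in enumerate(defn.components):
        if not comp.codes:
            v.append(f"component {i + 1}: codes must be non-empty")
        for code in comp.codes:
            if not _CODE_RE.match(code):
                v.append(
                    f"component {i + 1}: code {code!r} is not 1-3 uppercase "
                    "alphanumeric characters"
                )

    n = len(defn.components)
    for j, lk in enumerate(defn.linkages):
        for end, (ci, atoms) in enumerate(
            [(lk.component_1, lk.atoms_1), (lk.component_2, lk.atoms_2)], 1
        ):
            if not (0 <= ci < n):
                v.append(f"linkage {j + 1} end {end}: component index out of range")
            if not atoms:
                v.append(f"linkage {j + 1} end {end}: atom-name list must be non-empty")
            for a in atoms:
                if not a or len(a) > 4 or a != a.strip():
                    v.append(
                        f"linkage {j + 1} end {end}: atom name {a!r} is not a "
                        "stripped PDB atom name of at most 4 characters"
                    )
        if (
            defn.category in (ModificationCategory.CROSS_LINK, ModificationCategory.ATTACHMENT)
            and lk.component_1 == lk.component_2
        ):
            v.append(
                f"linkage {j + 1}: {defn.category.value} linkage must reference "
                "two distinct component entries"
            )

    cat = defn.category
    roles = [c.role for c in defn.components]
    if cat is ModificationCategory.MODIFIED_RESIDUE:
        if n != 1:
            v.append("MODIFIED_RESIDUE requires exactly 1 component")
        if any(r is not ComponentRole.AMINO_ACID for r in roles):
            v.append("MODIFIED_RESIDUE component must have role amino-acid")
        for comp in defn.components:
            for code in comp.codes:
                if code in CANONICAL_AMINO_ACIDS:
                    v.append(
                        f"MODIFIED_RESIDUE code {code!r} is a canonical residue, "
                        "not a nonstandard component"
                    )
        if defn.linkages:
            v.append("MODIFIED_RESIDUE must have 0 linkages")
    elif cat is ModificationCategory.ATTACHMENT:
        if n < 2:
            v.append("ATTACHMENT requires >=2 components")
        if not any(r is ComponentRole.AMINO_ACID for r in roles):
            v.append("ATTACHMENT requires >=1 amino-acid component")
        if not any(r is ComponentRole.NON_POLYMER for r in roles):
            v.append("ATTACHMENT requires >=1 non-polymer component")
        if not defn.linkages:
            v.append("ATTACHMENT requires >=1 linkage")
    elif cat is ModificationCategory.CROSS_LINK:
        if n < 2 or any(r is not ComponentRole.AMINO_ACID for r in roles):
            v.append("CROSS_LINK requires >=2 amino-acid components")
        if not defn.linkages:
            v.append("CROSS_LINK requires >=1 linkage")
        elif not _linkage_graph_connected(defn):
            v.append("CROSS_LINK linkage graph over components must be connected")
    return v


@dataclass
class Dictionary:
    """A validated collection of modification definitions.

    ``index_by_code`` maps every component code mentioned anywhere in the
    dictionary to the definitions that mention it; it is rebuilt from the
    definition list and never stored.
    """

    definitions: list[ModificationDefinition] = field(default_factory=list)
    version: str = "unversioned"
    index_by_code: dict[str, list[ModificationDefinition]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.rebuild_index()

    def rebuild_index(self) -> None:
        index: dict[str, list[ModificationDefinition]] = {}
        for d in self.definitions:
            for code in sorted(d.all_codes):
                index.setdefault(code, []).append(d)
        self.index_by_code = index

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def get(self, internal_id: str) -> ModificationDefinition:
        for d in self.definitions:
            if d.internal_id == internal_id:
                return d
        raise KeyError(f"no definition with id {internal_id!r}")

    def by_category(
        self, category: ModificationCategory
    ) -> list[ModificationDefinition]:
        return [d for d in self.definitions if d.category is category]

    def validate(self) -> None:
        """Raise :class:`DictionaryValidationError` on the first invalid record."""
        seen: set[str] = set()
        for d in self.definitions:
            if d.internal_id in seen:
                raise DictionaryValidationError(
                    f"duplicate internal_id {d.internal_id!r}"
                )
            seen.add(d.internal_id)
            violations = validate_definition(d)
            if violations:
                raise DictionaryValidationError(
                    f"definition {d.internal_id!r}: " + "; ".join(violations)
                )


# ---------------------------------------------------------------------------
# XML serialization


def _parse_atoms(attr: str) -> tuple[str, ...]:
    return tuple(a.strip() for a in attr.split(",") if a.strip())


def _definition_from_element(el: etree._Element) -> ModificationDefinition:
    def text(tag: str) -> str | None:
        child = el.find(tag)
        if child is None or child.text is None:
            return None
        return child.text.strip() or None

    internal_id = el.get("id", "")
    cat_attr = el.get("category", "")
    try:
        category = ModificationCategory(cat_attr)
    except ValueError:
        raise DictionaryParseError(
            f"line {el.sourceline}: unknown category {cat_attr!r} "
            f"in modification {internal_id!r}"
        ) from None

    components: list[ComponentSpec] = []
    for cel in el.findall("component"):
        codes = tuple(
            (c.text or "").strip() for c in cel.findall("code") if (c.text or "").strip()
        )
        try:
            role = ComponentRole(cel.get("role", "amino-acid"))
            terminal = Terminal(cel.get("terminal", "any"))
        except ValueError as exc:
            raise DictionaryParseError(
                f"line {cel.sourceline}: {exc} in modification {internal_id!r}"
            ) from None
        components.append(ComponentSpec(codes=codes, role=role, terminal=terminal))

    linkages: list[LinkageSpec] = []
    for lel in el.findall("linkage"):
        ends = lel.findall("end")
        if len(ends) != 2:
            raise DictionaryParseError(
                f"line {lel.sourceline}: linkage needs exactly 2 ends "
                f"in modification {internal_id!r}"
            )
        try:
            c1 = int(ends[0].get("component", "")) - 1
            c2 = int(ends[1].get("component", "")) - 1
        except ValueError:
            raise DictionaryParseError(
                f"line {lel.sourceline}: non-integer component index "
                f"in modification {internal_id!r}"
            ) from None
        linkages.append(
            LinkageSpec(
                component_1=c1,
                atoms_1=_parse_atoms(ends[0].get("atoms", "")),
                component_2=c2,
                atoms_2=_parse_atoms(ends[1].get("atoms", "")),
            )
        )

    return ModificationDefinition(
        internal_id=internal_id,
        name=text("name") or "",
        category=category,
        components=tuple(components),
        linkages=tuple(linkages),
        psimod_id=text("psimod-id"),
        resid_id=text("resid-id"),
        description=text("description"),
        systematic_name=text("systematic-name"),
        keywords=tuple(
            (k.text or "").strip() for k in el.findall("keyword") if (k.text or "").strip()
        ),
    )


def load_dictionary(path: str | Path) -> Dictionary:
    """Read and validate a modification dictionary from its XML file.

    Raises :class:`DictionaryParseError` on malformed XML (naming the line)
    and :class:`DictionaryValidationError` when a definition violates its
    category invariants (naming the definition and the failed rule).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise DictionaryParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "protein-modifications":
        raise DictionaryParseError(
            f"{path}: root element is <{root.tag}>, expected <protein-modifications>"
        )
    definitions = [_definition_from_element(el) for el in root.findall("modification")]
    d = Dictionary(definitions=definitions, version=root.get("version", "unversioned"))
    d.validate()
    return d


def save_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    """Write a dictionary to XML such that :func:`load_dictionary` round-trips."""
    root = etree.Element("protein-modifications", version=dictionary.version)
    for d in dictionary.definitions:
        el = etree.SubElement(
            root, "modification", id=d.internal_id, category=d.category.value
        )
        for tag, value in (
            ("psimod-id", d.psimod_id),
            ("resid-id", d.resid_id),
            ("name", d.name),
            ("description", d.description),
            ("systematic-name", d.systematic_name),
        ):
            if value is not None:
                etree.SubElement(el, tag).text = value
        for kw in d.keywords:
            etree.SubElement(el, "keyword").text = kw
        for i, comp in enumerate(d.components, 1):
            cel = etree.SubElement(
                el,
                "component",
                index=str(i),
                role=comp.role.value,
                terminal=comp.terminal.value,
            )
            for code in comp.codes:
                etree.SubElement(cel, "code").text = code
        for lk in d.linkages:
            lel = etree.SubElement(el, "linkage")
            etree.SubElement(
                lel, "end", component=str(lk.component_1 + 1), atoms=",".join(lk.atoms_1)
            )
            etree.SubElement(
                lel, "end", component=str(lk.component_2 + 1), atoms=",".join(lk.atoms_2)
            )
    tree = etree.ElementTree(root)
    tree.write(str(path), encoding="UTF-8", xml_declaration=True, pretty_print=True)


def starter_dictionary() -> Dictionary:
    """Load the bundled starter dictionary (~25 common modifications)."""
    with resources.as_file(
        resources.files("modfinder.data") / "starter_dictionary.xml"
    ) as p:
        return load_dictionary(p)
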