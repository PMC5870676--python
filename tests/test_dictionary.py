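"""Dictionary format: loading, validation, round-trip."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modfinder.dictionary import (
    ComponentRole,
    ComponentSpec,
    Dictionary,
    DictionaryParseError,
    DictionaryValidationError,
    LinkageSpec,
    ModificationCategory,
    ModificationDefinition,
    Terminal,
    load_dictionary,
    save_dictionary,
    validate_definition,
)


class TestStarterDictionary:
    def test_contains_disulfide_with_sg_atoms(self, dictionary):
        d = dictionary.get("disulfide")
        assert d.category is ModificationCategory.CROSS_LINK
        assert [c.codes for c in d.components] == [("CYS",), ("CYS",)]
        (lk,) = d.linkages
        assert lk.atoms_1 == ("SG",) and lk.atoms_2 == ("SG",)

    def test_contains_n_glycosylation_nd2_c1(self, dictionary):
        d = dictionary.get("n-glycosyl-asparagine")
        assert d.category is ModificationCategory.ATTACHMENT
        (lk,) = d.linkages
        aa = d.components[lk.component_1]
        sugar = d.components[lk.component_2]
        assert "ASN" in aa.codes and "NAG" in sugar.codes
        assert lk.atoms_1 == ("ND2",) and lk.atoms_2 == ("C1",)

    def test_all_three_categories_present(self, dictionary):
        for cat in ModificationCategory:
            assert dictionary.by_category(cat)

    def test_index_completeness(self, dictionary):
        for d in dictionary:
            for code in d.all_codes:
                assert d in dictionary.index_by_code[code]
        for code, defs in dictionary.index_by_code.items():
            for d in defs:
                assert code in d.all_codes

    def test_every_definition_valid(self, dictionary):
        for d in dictionary:
            assert validate_definition(d) == []

    def test_internal_ids_unique(self, dictionary):
        ids = [d.internal_id for d in dictionary]
        assert len(ids) == len(set(ids))


class TestLoadErrors:
    def test_empty_definitions_file(self, tmp_path):
        p = tmp_path / "empty.xml"
        p.write_text('<?xml version="1.0"?><protein-modifications/>')
        d = load_dictionary(p)
        assert len(d) == 0 and d.index_by_code == {}

    def test_malformed_xml_names_line(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<protein-modifications>\n<modification\n")
        with pytest.raises(DictionaryParseError, match=r"line"):
            load_dictionary(p)

    def test_wrong_root_element(self, tmp_path):
        p = tmp_path / "root.xml"
        p.write_text("<something/>")
        with pytest.raises(DictionaryParseError, match="root element"):
            load_dictionary(p)

    def test_invariant_violation_names_definition(self, tmp_path):
        p = tmp_path / "inv.xml"
        p.write_text(
            """<protein-modifications>
            <modification id="bad-xl" category="cross-link">
              <name>broken</name>
              <component index="1" role="amino-acid"><code>CYS</code></component>
            </modification>
            </protein-modifications>"""
        )
        with pytest.raises(DictionaryValidationError, match="bad-xl"):
            load_dictionary(p)


class TestValidateDefinition:
    def test_crosslink_with_one_component(self):
        d = ModificationDefinition(
            internal_id="x",
            name="x",
            category=ModificationCategory.CROSS_LINK,
            components=(ComponentSpec(codes=("CYS",)),),
            linkages=(LinkageSpec(0, ("SG",), 0, ("SG",)),),
        )
        assert any(">=2 amino-acid components" in v for v in validate_definition(d))

    def test_attachment_without_linkage(self):
        d = ModificationDefinition(
            internal_id="x",
            name="x",
            category=ModificationCategory.ATTACHMENT,
            components=(
                ComponentSpec(codes=("ASN",)),
                ComponentSpec(codes=("NAG",), role=ComponentRole.NON_POLYMER),
            ),
        )
        assert any("linkage" in v for v in validate_definition(d))

    def test_modified_residue_rejects_canonical_code(self):
        d = ModificationDefinition(
            internal_id="x",
            name="x",
            category=ModificationCategory.MODIFIED_RESIDUE,
            components=(ComponentSpec(codes=("SER",)),),
        )
        assert any("canonical" in v for v in validate_definition(d))

    def test_category_partition(self, dictionary):
        """Each starter definition validates under its own category only."""
        import dataclasses

        for d in dictionary:
            assert validate_definition(d) == []
            for other in ModificationCategory:
                if other is d.category:
                    continue
                changed = dataclasses.replace(d, category=other)
                assert validate_definition(changed), (
                    f"{d.internal_id} unexpectedly validates as {other}"
                )


# ---------------------------------------------------------------------------
# Round-trip property over randomly generated valid definitions

_codes = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=3)
_atom_names = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=4)
# XML-safe free text, stripped (the loader strips text nodes)
_free_text = (
    st.text(
        alphabet=st.characters(min_codepoint=32, max_codepoint=126),
        min_size=1,
        max_size=25,
    )
    .map(str.strip)
    .filter(bool)
)
_opt_text = st.one_of(st.none(), _free_text)


@st.composite
def _modified_residue_defs(draw):
    from modfinder.dictionary import CANONICAL_AMINO_ACIDS

    code = draw(_codes.filter(lambda c: c not in CANONICAL_AMINO_ACIDS))
    return ModificationDefinition(
        internal_id=draw(st.uuids()).hex,
        name=draw(_free_text),
        category=ModificationCategory.MODIFIED_RESIDUE,
        components=(ComponentSpec(codes=(code,)),),
        psimod_id=draw(st.one_of(st.none(), st.integers(0, 99999).map(lambda n: f"MOD:{n:05d}"))),
        resid_id=draw(st.one_of(st.none(), st.integers(0, 9999).map(lambda n: f"AA{n:04d}"))),
        description=draw(_opt_text),
        systematic_name=draw(_opt_text),
        keywords=tuple(draw(st.lists(_free_text, max_size=3))),
    )


@st.composite
def _crosslink_defs(draw):
    n = draw(st.integers(2, 4))
    comps = tuple(
        ComponentSpec(
            codes=tuple(draw(st.lists(_codes, min_size=1, max_size=2, unique=True))),
            terminal=draw(st.sampled_from(list(Terminal))),
        )
        for _ in range(n)
    )
    # spanning-tree linkages guarantee connectivity
    linkages = tuple(
        LinkageSpec(
            component_1=i,
            atoms_1=tuple(draw(st.lists(_atom_names, min_size=1, max_size=2, unique=True))),
            component_2=i + 1,
            atoms_2=tuple(draw(st.lists(_atom_names, min_size=1, max_size=2, unique=True))),
        )
        for i in range(n - 1)
    )
    return ModificationDefinition(
        internal_id=draw(st.uuids()).hex,
        name=draw(_free_text),
        category=ModificationCategory.CROSS_LINK,
        components=comps,
        linkages=linkages,
    )


@given(st.lists(st.one_of(_modified_residue_defs(), _crosslink_defs()), max_size=6))
@settings(max_examples=50, deadline=None)
def test_save_load_round_trip(tmp_path_factory, defs):
    """save_dictionary then load_dictionary is the identity, field for field."""
    tmp = tmp_path_factory.mktemp("rt")
    d = Dictionary(definitions=list(defs), version="rt-test")
    d.validate()
    path = tmp / "d.xml"
    save_dictionary(d, path)
    d2 = load_dictionary(path)
    assert d2.version == d.version
    assert d2.definitions == d.definitions
    assert d2.index_by_code == d.index_by_code


def test_round_trip_preserves_absent_optional_fields(tmp_path, dictionary):
    save_dictionary(dictionary, tmp_path / "s.xml")
    d2 = load_dictionary(tmp_path / "s.xml")
    assert d2.definitions == dictionary.definitions
    mse = d2.get("selenomethionine")
    assert mse.resid_id is None and mse.psimod_id is None
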