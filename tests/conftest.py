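"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from modfinder import (
    BondConfig,
    ModificationCategory,
    ScanConfig,
    starter_dictionary,
)


@pytest.fixture(scope="session")
def dictionary():
    return starter_dictionary()


@pytest.fixture(scope="session")
def scan_config(dictionary):
    return ScanConfig(dictionary=dictionary)


@pytest.fixture()
def bond_config():
    return BondConfig()


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no shared code with the package
# beyond the data types they inspect)


def brute_force_pairs(group_a, group_b, cfg):
    """O(n^2) reference for find_close_pairs: all bonded cross-residue pairs
    as a set of frozensets of (residue key, atom name)."""
    out = set()
    for (res_a, atom_a), (res_b, atom_b) in itertools.product(group_a, group_b):
        if res_a.id_key == res_b.id_key:
            continue
        d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
        thr = (
            cfg.radii.get(atom_a.element)
            + cfg.radii.get(atom_b.element)
            + cfg.tolerance
        )
        if cfg.min_distance <= d <= thr:
            out.add(
                frozenset(
                    [(res_a.id_key, atom_a.name), (res_b.id_key, atom_b.name)]
                )
            )
    return out


def exhaustive_crosslinks(model, definition, cfg):
    """Reference cross-link matcher: enumerate every assignment of distinct
    polymer residues to component slots and test all linkages directly.

    Returns the set of (definition id, sorted residue-key tuple).
    """
    polymer = list(model.iter_polymer_residues())
    candidates = [
        [r for r in polymer if comp.matches_code(r.component_code)]
        for comp in definition.components
    ]
    found = set()
    for combo in itertools.product(*candidates):
        keys = [r.id_key for r in combo]
        if len(set(keys)) != len(keys):
            continue
        ok = True
        for lk in definition.linkages:
            r1, r2 = combo[lk.component_1], combo[lk.component_2]
            bonded = False
            for n1, n2 in itertools.product(lk.atoms_1, lk.atoms_2):
                a1, a2 = r1.find_atom(n1), r2.find_atom(n2)
                if a1 is None or a2 is None:
                    continue
                d = float(np.linalg.norm(a1.coords - a2.coords))
                thr = (
                    cfg.radii.get(a1.element)
                    + cfg.radii.get(a2.element)
                    + cfg.tolerance
                )
                if cfg.min_distance <= d <= thr:
                    bonded = True
                    break
            if not bonded:
                ok = False
                break
        if ok:
            found.add((definition.internal_id, tuple(sorted(keys))))
    return found


def report_key_set(report):
    """Canonical comparable form of a report: {(definition id, residue set)}."""
    return {
        (m.definition.internal_id, tuple(sorted(m.residue_keys)))
        for m in report.identifications
    }


def truth_key_set(result):
    return {(t.definition_id, t.residues) for t in result.truth}
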