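"""Report serialization, per-chain sequence tracks, and batch scanning.

The TSV layout is one row per (identification, residue)::

    entry_id  category  internal_id  psimod_id  resid_id  name
    chain  seq_id  insertion  component_code  partner_description

``partner_description`` summarizes the bonds the row's residue takes part
in (own atom, partner atom, partner residue, distance to 2 decimals in
Angstrom), or ``-`` for modified residues.  Absent optional fields are
written as ``-``.  Output bytes are deterministic for identical inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from modfinder.identify import (
    IdentifiedModification,
    ModificationReport,
    ScanConfig,
    identify_all,
)
from modfinder.structure_io import (
    ChainLookupError,
    ResidueRecord,
    StructureModel,
    parse_structure,
)

__all__ = [
    "TSV_COLUMNS",
    "SequenceTrack",
    "BatchSummary",
    "write_tsv",
    "parse_tsv",
    "write_json",
    "report_to_dict",
    "sequence_track",
    "scan_batch",
]

logger = logging.getLogger(__name__)

TSV_COLUMNS = (
    "entry_id",
    "category",
    "internal_id",
    "psimod_id",
    "resid_id",
    "name",
    "chain",
    "seq_id",
    "insertion",
    "component_code",
    "partner_description",
)

_MISSING = "-"


def _partner_description(
    mod: IdentifiedModification, residue: ResidueRecord
) -> str:
    """Bonds of this residue within the identification, rendered compactly."""
    if not mod.bonds:
        return _MISSING
    parts: list[str] = []
    for bond in mod.bonds:
        if bond.atom_1.residue_key == residue.id_key:
            own, other = bond.atom_1, bond.atom_2
        elif bond.atom_2.residue_key == residue.id_key:
            own, other = bond.atom_2, bond.atom_1
        else:
            continue
        other_res = f"{other.component_code} {other.chain_id}{other.seq_id}{other.insertion_code}"
        parts.append(f"{own.atom_name}-{other.atom_name}[{other_res}] {bond.distance:.2f}")
    return "; ".join(parts) if parts else _MISSING


def _tsv_rows(report: ModificationReport) -> list[tuple[str, ...]]:
    rows: list[tuple[str, ...]] = []
    for mod in report.identifications:
        d = mod.definition
        for res in mod.residues:
            rows.append(
                (
                    report.entry_id,
                    mod.category.value,
                    d.internal_id,
                    d.psimod_id or _MISSING,
                    d.resid_id or _MISSING,
                    d.name,
                    res.chain_id,
                    str(res.seq_id),
                    res.insertion_code or _MISSING,
                    res.component_code,
                    _partner_description(mod, res),
                )
            )
    return rows


def write_tsv(report: ModificationReport, path: str | Path) -> None:
    """Write the per-entry annotation table (UTF-8, header row, stable order)."""
    lines = ["\t".join(TSV_COLUMNS)]
    lines += ["\t".join(row) for row in _tsv_rows(report)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def parse_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read back a TSV written by :func:`write_tsv` as a list of row dicts."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln]
    if not lines:
        raise ValueError(f"{path}: empty TSV")
    header = tuple(lines[0].split("\t"))
    if header != TSV_COLUMNS:
        raise ValueError(f"{path}: unexpected header {header!r}")
    out = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(TSV_COLUMNS):
            raise ValueError(f"{path}: bad row {ln!r}")
        out.append(dict(zip(TSV_COLUMNS, fields)))
    return out


def report_to_dict(report: ModificationReport) -> dict:
    """JSON-ready mirror of a report."""
    return {
        "entry_id": report.entry_id,
        "tolerance": report.tolerance,
        "dictionary_version": report.dictionary_version,
        "identifications": [
            {
                "category": m.category.value,
                "internal_id": m.definition.internal_id,
                "psimod_id": m.definition.psimod_id,
                "resid_id": m.definition.resid_id,
                "name": m.definition.name,
                "residues": [
                    {
                        "chain": r.chain_id,
                        "seq_id": r.seq_id,
                        "insertion": r.insertion_code,
                        "component_code": r.component_code,
                    }
                    for r in m.residues
                ],
                "bonds": [
                    {
                        "atom_1": {
                            "chain": b.atom_1.chain_id,
                            "seq_id": b.atom_1.seq_id,
                            "insertion": b.atom_1.insertion_code,
                            "atom": b.atom_1.atom_name,
                            "component_code": b.atom_1.component_code,
                        },
                        "atom_2": {
                            "chain": b.atom_2.chain_id,
                            "seq_id": b.atom_2.seq_id,
                            "insertion": b.atom_2.insertion_code,
                            "atom": b.atom_2.atom_name,
                            "component_code": b.atom_2.component_code,
                        },
                        "distance": round(b.distance, 2),
                        "threshold": round(b.threshold, 2),
                    }
                    for b in m.bonds
                ],
            }
            for m in report.identifications
        ],
    }


def write_json(report: ModificationReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Sequence tracks


@dataclass(frozen=True)
class SequenceMark:
    polymer_index: int
    identification: IdentifiedModification
    n_residues_in_modification: int


@dataclass
class SequenceTrack:
    """Per-chain annotation lane: which polymer positions carry which
    identified modifications.

    ``n_residues_in_modification`` counts the amino-acid residues of the
    identification (2 for a disulfide; 1 for an attachment reported per
    bonded pair), mirroring the multi-edge icon convention of sequence
    viewers.
    """

    chain_id: str
    length: int
    marks: list[SequenceMark]


def sequence_track(
    report: ModificationReport, model: StructureModel, chain_id: str
) -> SequenceTrack:
    """Project a report onto one chain; cross-chain identifications
    contribute only their residues on this chain."""
    residues = model.get_chain(chain_id)  # raises ChainLookupError if absent
    marks: list[SequenceMark] = []
    for mod in report.identifications:
        n_aa = sum(1 for r in mod.residues if r.is_polymer)
        for res in mod.residues:
            if res.is_polymer and res.chain_id == chain_id:
                assert res.polymer_index is not None
                marks.append(
                    SequenceMark(
                        polymer_index=res.polymer_index,
                        identification=mod,
                        n_residues_in_modification=n_aa,
                    )
                )
    marks.sort(key=lambda m: (m.polymer_index, m.identification.sort_key))
    return SequenceTrack(chain_id=chain_id, length=len(residues), marks=marks)


# ---------------------------------------------------------------------------
# Batch scanning


@dataclass
class BatchSummary:
    """Outcome of a directory/file-list scan."""

    n_entries: int
    n_failures: int
    failures: list[tuple[str, str]]  # (path, error message)
    entries_by_definition: dict[str, int]  # definition id -> entries containing it
    entries_by_category: dict[str, int]
    n_entries_with_modifications: int

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "n_failures": self.n_failures,
            "failures": [{"path": p, "error": e} for p, e in self.failures],
            "entries_by_definition": self.entries_by_definition,
            "entries_by_category": self.entries_by_category,
            "n_entries_with_modifications": self.n_entries_with_modifications,
        }


def scan_batch(
    paths: Sequence[str | Path],
    cfg: ScanConfig,
    out_dir: str | Path | None = None,
    formats: Iterable[str] = ("tsv", "json"),
) -> BatchSummary:
    """Scan many entries; write per-entry reports and a summary.

    A failing entry is logged and skipped — it never aborts the batch.
    Summary counts are per entry: a definition seen three times in one entry
    contributes 1 to its count.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("scan_batch requires at least one path")
    formats = set(formats)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    by_definition: dict[str, int] = {}
    by_category: dict[str, int] = {}
    failures: list[tuple[str, str]] = []
    n_ok = 0
    n_with = 0
    for p in paths:
        p = Path(p)
        t0 = time.perf_counter()
        try:
            model = parse_structure(p)
            report = identify_all(model, cfg)
        except Exception as exc:  # resilience contract: log and continue
            logger.warning("entry %s failed: %s", p, exc)
            failures.append((str(p), str(exc)))
            continue
        n_ok += 1
        if report.identifications:
            n_with += 1
        for def_id in {m.definition.internal_id for m in report.identifications}:
            by_definition[def_id] = by_definition.get(def_id, 0) + 1
        for cat in {m.category.value for m in report.identifications}:
            by_category[cat] = by_category.get(cat, 0) + 1
        if out_dir is not None:
            if "tsv" in formats:
                write_tsv(report, out_dir / f"{report.entry_id}.tsv")
            if "json" in formats:
                write_json(report, out_dir / f"{report.entry_id}.json")
        logger.info(
            "scanned %s: %d identifications in %.3f s",
            p, len(report.identifications), time.perf_counter() - t0,
        )

    summary = BatchSummary(
        n_entries=n_ok,
        n_failures=len(failures),
        failures=failures,
        entries_by_definition=dict(sorted(by_definition.items())),
        entries_by_category=dict(sorted(by_category.items())),
        n_entries_with_modifications=n_with,
    )
    if out_dir is not None:
        (out_dir / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        lines = ["definition_id\tn_entries"]
        lines += [f"{k}\t{v}" for k, v in summary.entries_by_definition.items()]
        (out_dir / "summary.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return summary
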