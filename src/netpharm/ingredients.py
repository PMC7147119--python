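"""Multi-source herb ingredient integration.

Herbal formulas are catalogued in several overlapping databases, each
listing the chemical ingredients of each herb under its own identifiers.
Building a formula-wide compound library therefore requires parsing the
per-herb tables (SDF or CSV), canonicalising every structure to a stable
key, and merging records that describe the same molecule while keeping
track of which herbs and which source databases contributed it.

The deduplication key is the full 27-character standard InChIKey, so
stereoisomers remain distinct.  Records whose structure is missing or
unparseable fall back to a normalised-name key (prefixed ``NAME:`` and
flagged), rather than being dropped: traditional-medicine tables are
name-rich and structure-poor, and silently dropping structureless rows
would shrink the catalog.  Name-keyed records never merge with
structure-keyed ones.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "RawIngredientRecord",
    "CompoundRecord",
    "FormulaCatalog",
    "parse_structure_table",
    "canonical_key",
    "merge_catalogs",
    "overlap_partition",
]


@dataclass
class RawIngredientRecord:
    """One row of a source database's ingredient table for one herb."""

    herb: str
    source_db: str
    name: str | None = None
    smiles: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.herb:
            raise ValueError("herb label must be non-empty")
        if not self.source_db:
            raise ValueError("source_db label must be non-empty")
        if not (self.name or self.smiles):
            raise ValueError("record needs at least one of {name, structure}")


@dataclass
class CompoundRecord:
    """A deduplicated compound with herb and database provenance.

    ``canonical_key`` is either a standard InChIKey or, when no structure
    could be interpreted, a flagged normalised-name key (``fallback``).
    """

    compound_id: str
    canonical_key: str
    fallback: bool
    smiles: str | None
    herbs: frozenset[str]
    source_dbs: frozenset[str]
    names: frozenset[str] = frozenset()


@dataclass
class FormulaCatalog:
    """Deduplicated compound library of a multi-herb formula."""

    herbs: list[str]
    compounds: list[CompoundRecord]

    @property
    def per_herb_counts(self) -> dict[str, int]:
        counts = {h: 0 for h in self.herbs}
        for rec in self.compounds:
            for h in rec.herbs:
                counts[h] += 1
        return counts

    def __len__(self) -> int:
        return len(self.compounds)

    def compound_index(self) -> dict[str, CompoundRecord]:
        """Resolution map: compound_id, canonical key, or name key -> record."""
        idx: dict[str, CompoundRecord] = {}
        for rec in self.compounds:
            idx[rec.compound_id] = rec
            idx[rec.canonical_key] = rec
            for name in rec.names:
                idx.setdefault("NAME:" + _normalize_name(name), rec)
        return idx

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(
                ["compound_id", "canonical_key", "fallback", "smiles",
                 "herbs", "source_dbs", "names"]
            )
            for rec in self.compounds:
                writer.writerow(
                    [
                        rec.compound_id,
                        rec.canonical_key,
                        int(rec.fallback),
                        rec.smiles or "",
                        ";".join(sorted(rec.herbs)),
                        ";".join(sorted(rec.source_dbs)),
                        ";".join(sorted(rec.names)),
                    ]
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FormulaCatalog":
        compounds: list[CompoundRecord] = []
        herbs: set[str] = set()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rec = CompoundRecord(
                    compound_id=row["compound_id"],
                    canonical_key=row["canonical_key"],
                    fallback=bool(int(row["fallback"])),
                    smiles=row["smiles"] or None,
                    herbs=frozenset(row["herbs"].split(";")),
                    source_dbs=frozenset(row["source_dbs"].split(";")),
                    names=frozenset(x for x in row["names"].split(";") if x),
                )
                herbs.update(rec.herbs)
                compounds.append(rec)
        return cls(herbs=sorted(herbs), compounds=compounds)


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


def parse_structure_table(
    path: str | Path,
    format: str,
    herb: str,
    source_db: str,
    column_map: dict[str, str] | None = None,
) -> list[RawIngredientRecord]:
    """Read one herb's ingredient table from an SDF or CSV file.

    Parameters
    ----------
    path : file path
        SDF V2000 multi-molecule file or CSV table.
    format : {"sdf", "csv"}
    herb, source_db : str
        Provenance labels attached to every record from this file.
    column_map : dict, optional
        For CSV input, maps the logical fields ``name`` and ``smiles`` to
        the actual column headers (defaults to those names).

    Rows with a blank structure are kept with ``smiles=None``; malformed
    SDF molecule blocks are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ingredient table not found: {path}")
    if format == "sdf":
        return _parse_sdf(path, herb, source_db)
    if format == "csv":
        return _parse_csv(path, herb, source_db, column_map)
    raise ValueError(f"unknown format {format!r}: expected 'sdf' or 'csv'")


def _parse_sdf(path: Path, herb: str, source_db: str) -> list[RawIngredientRecord]:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    records: list[RawIngredientRecord] = []
    skipped = 0
    with open(path, "rb") as fh:
        for mol in Chem.ForwardSDMolSupplier(fh, sanitize=True):
            if mol is None:
                skipped += 1
                continue
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else None
            records.append(
                RawIngredientRecord(
                    herb=herb,
                    source_db=source_db,
                    name=name or None,
                    smiles=Chem.MolToSmiles(mol),
                )
            )
    if skipped:
        logger.warning("%s: skipped %d malformed molecule block(s)", path, skipped)
    return records


def _parse_csv(
    path: Path,
    herb: str,
    source_db: str,
    column_map: dict[str, str] | None,
) -> list[RawIngredientRecord]:
    colmap = {"name": "name", "smiles": "smiles"}
    if column_map:
        colmap.update(column_map)
    records: list[RawIngredientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return records
        for logical, actual in colmap.items():
            if actual not in reader.fieldnames:
                raise ValueError(
                    f"{path}: missing column {actual!r} (for field {logical!r})"
                )
        for row in reader:
            name = (row[colmap["name"]] or "").strip() or None
            smiles = (row[colmap["smiles"]] or "").strip() or None
            records.append(
                RawIngredientRecord(
                    herb=herb, source_db=source_db, name=name, smiles=smiles
                )
            )
    return records


def canonical_key(record: RawIngredientRecord) -> tuple[str, bool]:
    """Structure key for deduplication.

    Returns ``(key, fallback)``: the full standard InChIKey when the
    structure parses, otherwise ``"NAME:" + normalised name`` with
    ``fallback=True``.
    """
    if record.smiles:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        mol = Chem.MolFromSmiles(record.smiles)
        if mol is not None:
            key = Chem.MolToInchiKey(mol)
            if key:
                return key, False
    if not record.name:
        raise ValueError("record has neither a parseable structure nor a name")
    return "NAME:" + _normalize_name(record.name), True


def merge_catalogs(records: list[RawIngredientRecord]) -> FormulaCatalog:
    """Merge raw records into a deduplicated :class:`FormulaCatalog`.

    One compound per distinct canonical key; herb and source sets are the
    unions over merged records.  Compound ids ``M1..Mn`` are assigned in
    ascending lexicographic order of the canonical key, so the catalog is
    independent of input order and merging is idempotent.
    """
    if not records:
        raise ValueError("cannot merge an empty record list")
    by_key: dict[str, dict] = {}
    for rec in records:
        key, fallback = canonical_key(rec)
        entry = by_key.setdefault(
            key,
            {"fallback": fallback, "smiles": None, "herbs": set(),
             "source_dbs": set(), "names": set()},
        )
        entry["herbs"].add(rec.herb)
        entry["source_dbs"].add(rec.source_db)
        if rec.name:
            entry["names"].add(rec.name.strip())
        if entry["smiles"] is None and rec.smiles and not fallback:
            from rdkit import Chem

            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is not None:
                entry["smiles"] = Chem.MolToSmiles(mol)
    compounds = [
        CompoundRecord(
            compound_id=f"M{i + 1}",
            canonical_key=key,
            fallback=entry["fallback"],
            smiles=entry["smiles"],
            herbs=frozenset(entry["herbs"]),
            source_dbs=frozenset(entry["source_dbs"]),
            names=frozenset(entry["names"]),
        )
        for i, (key, entry) in enumerate(sorted(by_key.items()))
    ]
    herbs = sorted({h for rec in compounds for h in rec.herbs})
    return FormulaCatalog(herbs=herbs, compounds=compounds)


def overlap_partition(
    catalog: FormulaCatalog,
) -> tuple[dict[int, int], dict[str, frozenset[str]]]:
    """Cross-herb multiplicity histogram and compound -> herb-set map.

    ``histogram[m]`` counts compounds found in exactly ``m`` herbs; the
    histogram values sum to the catalog size (it is a partition).
    """
    herb_map = {rec.compound_id: rec.herbs for rec in catalog.compounds}
    histogram: dict[int, int] = {}
    for herbs in herb_map.values():
        m = len(herbs)
        histogram[m] = histogram.get(m, 0) + 1
    return histogram, herb_map
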