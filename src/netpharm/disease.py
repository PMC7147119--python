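"""Disease gene sets and herb-level target attribution.

Curates a disease gene set from one-symbol-per-line files, intersects it
with the formula's predicted/known target space, and partitions the
resulting disease-relevant targets by which exact subset of herbs hits
them (the Venn decomposition used to discuss herb synergy).

Gene symbols are normalised by upper-casing and whitespace removal only;
no alias or ortholog resolution is attempted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .ingredients import FormulaCatalog, _normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "CandidateTargetSet",
    "normalize_symbol",
    "load_gene_set",
    "candidate_targets",
    "herb_attribution",
]


def normalize_symbol(symbol: str) -> str:
    """Upper-case, whitespace-free gene symbol."""
    return "".join(symbol.split()).upper()


@dataclass
class GeneSet:
    """A named set of normalised gene symbols with source provenance."""

    name: str
    symbols: frozenset[str]
    provenance: list[str]

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class CandidateTargetSet:
    """Disease-relevant targets attributed to herbs.

    ``venn`` maps each non-empty herb subset to the targets hit by
    exactly that subset; the regions are disjoint and cover ``targets``.
    """

    targets: frozenset[str]
    per_herb: dict[str, frozenset[str]]
    venn: dict[frozenset[str], frozenset[str]]

    def venn_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["herb_subset", "n_targets", "targets"])
            for herbs in sorted(self.venn, key=lambda h: (len(h), sorted(h))):
                ts = self.venn[herbs]
                writer.writerow(
                    [";".join(sorted(herbs)), len(ts), ";".join(sorted(ts))]
                )


def load_gene_set(paths: Iterable[str | Path], name: str) -> GeneSet:
    """Union of one-symbol-per-line files ('#' comments allowed)."""
    symbols: set[str] = set()
    provenance: list[str] = []
    for path in paths:
        path = Path(path)
        provenance.append(path.name)
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.add(normalize_symbol(line))
    if not symbols:
        raise ValueError(f"gene set {name!r} is empty after reading all files")
    return GeneSet(name=name, symbols=frozenset(symbols), provenance=provenance)


def candidate_targets(target_universe: Iterable[str], disease: GeneSet) -> frozenset[str]:
    """Disease-associated members of the formula's target space."""
    universe = {normalize_symbol(t) for t in target_universe}
    if not universe or not disease.symbols:
        raise ValueError("target universe and disease set must be non-empty")
    return frozenset(universe & disease.symbols)


def herb_attribution(
    catalog: FormulaCatalog,
    dti_edges: Iterable[tuple[str, str]],
    disease_targets: Iterable[str],
) -> CandidateTargetSet:
    """Attribute disease targets to herbs through their compounds.

    A herb hits a target if any of its compounds (via a known or
    predicted edge) does.  Edge drug ids are resolved against the catalog
    by compound id, canonical key, or normalised-name key; unresolvable
    ids are skipped with a warning.
    """
    disease_set = {normalize_symbol(t) for t in disease_targets}
    index = catalog.compound_index()
    hit_herbs: dict[str, set[str]] = {}
    unresolved: set[str] = set()
    for drug, target in dti_edges:
        target = normalize_symbol(target)
        if target not in disease_set:
            continue
        rec = index.get(drug) or index.get("NAME:" + _normalize_name(drug))
        if rec is None:
            unresolved.add(drug)
            continue
        hit_herbs.setdefault(target, set()).update(rec.herbs)
    if unresolved:
        logger.warning("skipped %d edge drug id(s) not in catalog: %s",
                       len(unresolved), sorted(unresolved)[:5])
    targets = frozenset(hit_herbs)
    per_herb = {
        h: frozenset(t for t, hs in hit_herbs.items() if h in hs)
        for h in catalog.herbs
    }
    venn: dict[frozenset[str], set[str]] = {}
    for t, hs in hit_herbs.items():
        venn.setdefault(frozenset(hs), set()).add(t)
    return CandidateTargetSet(
        targets=targets,
        per_herb=per_herb,
        venn={k: frozenset(v) for k, v in venn.items()},
    )
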