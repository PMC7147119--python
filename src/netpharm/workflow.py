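"""End-to-end pipeline: bundle directory in, analysis directory out.

Chains the stage modules in their natural order — ingredient merging,
diffusion-based target prediction, disease-gene overlap, herb
attribution, network construction, degree analysis, and enrichment —
reading the file layout the synthetic generator emits (which is also the
layout expected for real inputs).  Every output is a deterministic text
file: running the pipeline twice on the same inputs yields byte-identical
results.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

from . import disease, enrichment, ingredients, networks
from .sdtnbi import SDTNBI, DiffusionParams

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    catalog: ingredients.FormulaCatalog
    model: SDTNBI
    edge_table: "object"  # pandas DataFrame: drug, target, score, provenance
    disease_genes: disease.GeneSet
    candidate: frozenset[str]
    attribution: disease.CandidateTargetSet
    ct_network: networks.BipartiteNetwork
    ht_network: networks.BipartiteNetwork
    degree: networks.DegreeReport
    enrichment: enrichment.EnrichmentReport
    out_dir: Path


def run_pipeline(
    bundle_dir: str | Path,
    out_dir: str | Path,
    params: DiffusionParams | None = None,
    top_L: int = 10,
    min_degree_exclusive: int = 2,
    top_k_terms: int = 20,
    alpha: float = 0.05,
    source_db: str = "SIM",
) -> PipelineResult:
    """Run the whole chain on ``bundle_dir/observed`` into ``out_dir``.

    ``top_L`` is the per-drug cut for turning diffusion scores into
    predicted edges; ``min_degree_exclusive`` the strict degree filter
    applied to disease targets before enrichment.
    """
    params = params or DiffusionParams()
    bundle_dir = Path(bundle_dir)
    obs = bundle_dir / "observed"
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. ingredient catalog
    records: list[ingredients.RawIngredientRecord] = []
    for herb_csv in sorted((obs / "herbs").glob("*.csv")):
        records.extend(
            ingredients.parse_structure_table(
                herb_csv, "csv", herb=herb_csv.stem, source_db=source_db
            )
        )
    catalog = ingredients.merge_catalogs(records)
    catalog.to_csv(out / "catalog.csv")
    histogram, _ = ingredients.overlap_partition(catalog)
    with open(out / "overlap_histogram.csv", "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["n_herbs", "n_compounds"])
        for m in sorted(histogram):
            writer.writerow([m, histogram[m]])

    # 2. target prediction
    model = SDTNBI.from_files(obs / "known_dti.tsv", obs / "fingerprints.csv")
    results = model.fit(params)
    edge_table = results.edge_table(mode="top_L", value=top_L)
    edge_table.to_csv(out / "dti_edges.tsv", sep="\t", index=False,
                      float_format="%.12g")
    results.scores.to_csv(out / "scores.csv")

    # 3. disease overlap and herb attribution
    gene_set = disease.load_gene_set([obs / "disease_genes.txt"], "disease")
    universe = set(edge_table["target_id"])
    candidate = disease.candidate_targets(universe, gene_set)
    (out / "candidate_targets.txt").write_text(
        "".join(f"{t}\n" for t in sorted(candidate))
    )
    all_edges = list(zip(edge_table["drug_id"], edge_table["target_id"]))
    attribution = disease.herb_attribution(catalog, all_edges, candidate)
    attribution.venn_to_csv(out / "venn_partition.csv")

    # 4. networks and degree analysis
    disease_edges = [
        (d, t, p)
        for d, t, p in zip(edge_table["drug_id"], edge_table["target_id"],
                           edge_table["provenance"])
        if t in candidate
    ]
    ct = networks.build_ct_network(catalog, disease_edges)
    ht = networks.build_ht_network(attribution)
    for fmt, suffix in (("graphml", "graphml"), ("sif", "sif"), ("csv", "csv")):
        networks.export_graph(ct, out / f"ct_network.{suffix}", fmt)
    networks.export_graph(ht, out / "ht_network.graphml", "graphml")
    report = networks.degree_report(ct)
    for node_type, table in report.tables.items():
        table.to_csv(out / f"degree_{node_type}.csv", index=False)

    # 5. enrichment of high-degree disease targets
    ann = enrichment.read_gmt(obs / "annotations.gmt")
    query = enrichment.filter_by_degree(ct, min_degree_exclusive)
    enr = enrichment.enrich(query, ann, top_k=top_k_terms, alpha=alpha)
    enr.to_tsv(out / "enrichment.tsv")
    enr.to_tsv(out / "enrichment_retained.tsv", retained_only=True)

    summary = {
        "n_compounds": len(catalog),
        "n_multi_herb_compounds": sum(
            v for m, v in histogram.items() if m > 1
        ),
        "per_herb_counts": catalog.per_herb_counts,
        "n_known_edges": int((edge_table["provenance"] == "known").sum()),
        "n_predicted_edges": int((edge_table["provenance"] == "predicted").sum()),
        "n_disease_genes": len(gene_set),
        "n_candidate_targets": len(candidate),
        "n_ct_edges": ct.n_edges,
        "n_ht_edges": ht.n_edges,
        "n_enrichment_query": len(query),
        "top_term": enr.results[0].term if enr.results else None,
        "params": {"alpha": params.alpha, "beta": params.beta,
                   "gamma": params.gamma, "k": params.k, "top_L": top_L},
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )

    return PipelineResult(
        catalog=catalog, model=model, edge_table=edge_table,
        disease_genes=gene_set, candidate=candidate, attribution=attribution,
        ct_network=ct, ht_network=ht, degree=report, enrichment=enr,
        out_dir=out,
    )
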