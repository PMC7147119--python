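"""Seeded synthetic input bundles for the full analysis chain.

Generates, from a single seed, every input the pipeline consumes:
overlapping per-herb ingredient tables, a binary fingerprint matrix with
a planted pharmacophore signal, a sparse known drug-target interaction
list, a disease gene list, and a GMT annotation collection containing
one planted enriched term.  The planted mechanism is the minimal one
under which substructure-based diffusion provably carries signal: each
target owns a small set of pharmacophore bits, and a drug's fingerprint
sets those bits at a high rate (``p_on``) for the targets it truly
binds, against a low background rate (``p_bg``) elsewhere.  Drugs that
share targets therefore share substructure bits, which is exactly the
regularity the diffusion engine exploits.

All symbols are synthetic (``CPD0001``, ``T001``, ``DEC001``...) so no
accidental biological claim is encoded.  Bundles regenerate
byte-identically from (config, seed); the ground truth (true
interactions, pharmacophore map, planted term) is written under
``truth/``, strictly apart from the ``observed/`` directory the pipeline
reads.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SimConfig", "SimBundle", "VerificationReport", "simulate",
           "verify_bundle"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the standard study conditions.

    ``n_targets_per_drug`` is drawn as 1 + Poisson(``poisson_rate``),
    truncated at ``max_targets_per_drug``.  ``obs`` is the fraction of
    true interactions that make it into the observed known-DTI file, and
    ``dup`` the rate at which a compound is listed under a second herb.
    The disease set is ``disease_fraction`` of the targets plus
    ``n_decoys`` decoy symbols; the planted annotation term is the set of
    disease targets that truly bind at least one drug.
    """

    n_herbs: int = 4
    n_drugs: int = 200
    n_targets: int = 20
    n_bits: int = 256
    pharmacophore_size: int = 8
    poisson_rate: float = 0.5
    max_targets_per_drug: int = 4
    p_on: float = 0.9
    p_bg: float = 0.05
    obs: float = 0.8
    dup: float = 0.1
    disease_fraction: float = 0.5
    n_decoys: int = 30
    n_annotation_terms: int = 50
    term_size_min: int = 5
    term_size_max: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_on", "p_bg", "obs", "dup", "disease_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field {name!r} must be in [0, 1], got {v}")
        for name in ("n_herbs", "n_drugs", "n_targets", "n_bits"):
            if getattr(self, name) < 1:
                raise ValueError(f"config field {name!r} must be >= 1")
        if self.pharmacophore_size > self.n_bits:
            raise ValueError("config field 'pharmacophore_size' exceeds n_bits")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimBundle:
    """Generated files plus the ground truth they were built from."""

    config: SimConfig
    root: Path
    observed: dict[str, Path]
    true_dtis: frozenset[tuple[str, str]]
    pharmacophores: dict[str, list[str]]
    planted_term: str
    planted_genes: frozenset[str]
    drug_herbs: dict[str, list[str]]
    manifest: dict = field(default_factory=dict)


def _drug_ids(D: int) -> list[str]:
    width = max(4, len(str(D)))
    return [f"CPD{i + 1:0{width}d}" for i in range(D)]


def _target_ids(T: int) -> list[str]:
    width = max(3, len(str(T)))
    return [f"T{i + 1:0{width}d}" for i in range(T)]


def simulate(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate a bundle under ``out_dir`` (observed/, truth/, manifest.json)."""
    rng = np.random.default_rng(config.seed)
    root = Path(out_dir)
    obs_dir = root / "observed"
    truth_dir = root / "truth"
    (obs_dir / "herbs").mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    drugs = _drug_ids(config.n_drugs)
    targets = _target_ids(config.n_targets)
    bits = [f"B{i + 1:03d}" for i in range(config.n_bits)]
    herbs = [f"Herb{chr(ord('A') + i)}" if i < 26 else f"Herb{i + 1}"
             for i in range(config.n_herbs)]

    # pharmacophore bits per target (without replacement; overlaps across
    # targets allowed)
    pharma = {
        t: sorted(rng.choice(config.n_bits, config.pharmacophore_size,
                             replace=False).tolist())
        for t in targets
    }

    # true targets per drug: 1 + Poisson, truncated
    true_pairs: set[tuple[str, str]] = set()
    drug_targets: dict[str, list[int]] = {}
    for d in drugs:
        n_t = min(1 + int(rng.poisson(config.poisson_rate)),
                  config.max_targets_per_drug, config.n_targets)
        chosen = sorted(rng.choice(config.n_targets, n_t, replace=False).tolist())
        drug_targets[d] = chosen
        true_pairs.update((d, targets[j]) for j in chosen)

    # fingerprints: background Bernoulli(p_bg); pharmacophore positions of a
    # drug's true targets overwritten by Bernoulli(p_on)
    X = (rng.random((config.n_drugs, config.n_bits)) < config.p_bg).astype(np.int8)
    for i, d in enumerate(drugs):
        pos = sorted({b for j in drug_targets[d] for b in pharma[targets[j]]})
        X[i, pos] = (rng.random(len(pos)) < config.p_on).astype(np.int8)
        if X[i].sum() == 0:  # every drug keeps at least one substructure bit
            X[i, pos[0]] = 1

    # observed known interactions: seeded subsample of the true pairs
    ordered_true = sorted(true_pairs)
    n_known = int(round(config.obs * len(ordered_true)))
    known_idx = sorted(rng.choice(len(ordered_true), n_known, replace=False).tolist())
    known_pairs = [ordered_true[i] for i in known_idx]

    # herb membership: uniform primary herb, second herb at rate dup
    drug_herbs: dict[str, list[str]] = {}
    for d in drugs:
        primary = int(rng.integers(config.n_herbs))
        members = [herbs[primary]]
        if config.n_herbs > 1 and rng.random() < config.dup:
            extra = int(rng.integers(config.n_herbs - 1))
            if extra >= primary:
                extra += 1
            members.append(herbs[extra])
        drug_herbs[d] = sorted(members)

    # disease gene set: half the targets plus decoy symbols
    n_dis = max(1, int(round(config.disease_fraction * config.n_targets)))
    dis_idx = sorted(rng.choice(config.n_targets, n_dis, replace=False).tolist())
    disease_targets = [targets[j] for j in dis_idx]
    decoys = [f"DEC{i + 1:03d}" for i in range(config.n_decoys)]
    disease_genes = sorted(disease_targets + decoys)

    # annotation terms over the target+decoy universe, plus the planted term
    universe = sorted(targets + decoys)
    terms: dict[str, list[str]] = {}
    for i in range(config.n_annotation_terms):
        size = int(rng.integers(config.term_size_min,
                                min(config.term_size_max, len(universe)) + 1))
        genes = sorted(
            np.asarray(universe)[
                rng.choice(len(universe), size, replace=False)
            ].tolist()
        )
        terms[f"TERM{i + 1:03d}"] = genes
    hit_targets = {t for _, t in true_pairs}
    planted_genes = sorted(set(disease_targets) & hit_targets) or disease_targets
    planted_term = "TERM_PLANTED"
    terms[planted_term] = planted_genes

    # ---- write observed files ----
    paths: dict[str, Path] = {}
    for h in herbs:
        p = obs_dir / "herbs" / f"{h}.csv"
        with open(p, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["name", "smiles"])
            for d in drugs:
                if h in drug_herbs[d]:
                    writer.writerow([d, ""])
        paths[f"herb:{h}"] = p

    fp_path = obs_dir / "fingerprints.csv"
    with open(fp_path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug_id", *bits])
        for i, d in enumerate(drugs):
            writer.writerow([d, *X[i].tolist()])
    paths["fingerprints"] = fp_path

    dti_path = obs_dir / "known_dti.tsv"
    with open(dti_path, "w") as fh:
        fh.write("drug_id\ttarget_id\n")
        for d, t in known_pairs:
            fh.write(f"{d}\t{t}\n")
    paths["known_dti"] = dti_path

    dis_path = obs_dir / "disease_genes.txt"
    dis_path.write_text("".join(f"{g}\n" for g in disease_genes))
    paths["disease_genes"] = dis_path

    gmt_path = obs_dir / "annotations.gmt"
    with open(gmt_path, "w") as fh:
        for term in sorted(terms):
            fh.write("\t".join([term, f"synthetic term {term}", *terms[term]]) + "\n")
    paths["annotations"] = gmt_path

    # ---- write ground truth ----
    with open(truth_dir / "true_dti.tsv", "w") as fh:
        fh.write("drug_id\ttarget_id\n")
        for d, t in ordered_true:
            fh.write(f"{d}\t{t}\n")
    (truth_dir / "pharmacophores.json").write_text(
        json.dumps({t: [bits[b] for b in pharma[t]] for t in targets},
                   indent=2, sort_keys=True) + "\n"
    )
    (truth_dir / "planted_term.txt").write_text(
        "\n".join([planted_term, *planted_genes]) + "\n"
    )
    (truth_dir / "herb_assignment.json").write_text(
        json.dumps(drug_herbs, indent=2, sort_keys=True) + "\n"
    )

    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_true_dti": len(ordered_true),
        "n_known_dti": n_known,
        "n_drugs_multi_herb": sum(1 for m in drug_herbs.values() if len(m) > 1),
        "n_disease_targets": len(disease_targets),
        "n_annotation_terms": len(terms),
    }
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    return SimBundle(
        config=config,
        root=root,
        observed=paths,
        true_dtis=frozenset(true_pairs),
        pharmacophores={t: [bits[b] for b in pharma[t]] for t in targets},
        planted_term=planted_term,
        planted_genes=frozenset(planted_genes),
        drug_herbs=drug_herbs,
        manifest=manifest,
    )


@dataclass
class VerificationReport:
    """Realized-rate diagnostics of a generated bundle."""

    ok: bool
    checks: list[tuple[str, bool, str]]
    realized_p_on: float
    realized_p_bg: float
    dti_density: float
    n_duplicates: int

    def summary(self) -> str:
        lines = ["Bundle verification", "==================="]
        for name, passed, detail in self.checks:
            lines.append(f"[{'ok' if passed else 'FAIL'}] {name}: {detail}")
        return "\n".join(lines)


def verify_bundle(bundle: SimBundle) -> VerificationReport:
    """Re-read the observed files and check realized rates against config.

    Realized pharmacophore-on and background bit rates must fall within
    three binomial standard errors of ``p_on`` / ``p_bg``; the observed
    interaction count must equal ``round(obs * n_true)``; every drug row
    must keep at least one set bit.
    """
    import pandas as pd

    cfg = bundle.config
    fp = pd.read_csv(bundle.observed["fingerprints"], index_col=0)
    bit_pos = {b: i for i, b in enumerate(fp.columns)}
    X = fp.to_numpy()

    on_mask = np.zeros(X.shape, dtype=bool)
    true_by_drug: dict[str, set[str]] = {}
    for d, t in bundle.true_dtis:
        true_by_drug.setdefault(d, set()).add(t)
    for i, d in enumerate(fp.index):
        pos = sorted({bit_pos[b] for t in true_by_drug.get(d, ())
                      for b in bundle.pharmacophores[t]})
        on_mask[i, pos] = True

    n_on = int(on_mask.sum())
    n_bg = int((~on_mask).sum())
    realized_on = float(X[on_mask].mean()) if n_on else float("nan")
    realized_bg = float(X[~on_mask].mean()) if n_bg else float("nan")

    checks: list[tuple[str, bool, str]] = []

    def band(p: float, n: int) -> float:
        return 3.0 * np.sqrt(max(p * (1 - p), 1e-12) / max(n, 1))

    if n_on:
        tol = band(cfg.p_on, n_on)
        # forcing >=1 bit per all-zero row can only nudge the rate upward
        ok = abs(realized_on - cfg.p_on) <= tol + 1.0 / max(n_on, 1)
        checks.append(("pharmacophore bit rate", ok,
                       f"realized {realized_on:.4f} vs p_on {cfg.p_on} +/- {tol:.4f}"))
    if n_bg:
        tol = band(cfg.p_bg, n_bg)
        ok = abs(realized_bg - cfg.p_bg) <= tol
        checks.append(("background bit rate", ok,
                       f"realized {realized_bg:.4f} vs p_bg {cfg.p_bg} +/- {tol:.4f}"))

    n_known = sum(1 for _ in open(bundle.observed["known_dti"])) - 1
    expected = int(round(cfg.obs * len(bundle.true_dtis)))
    checks.append(("observed DTI count", n_known == expected,
                   f"{n_known} observed vs round(obs * true) = {expected}"))

    row_ok = bool((X.sum(axis=1) >= 1).all())
    checks.append(("every drug has >= 1 bit", row_ok,
                   f"min row sum {int(X.sum(axis=1).min())}"))

    n_dup = sum(1 for m in bundle.drug_herbs.values() if len(m) > 1)
    density = len(bundle.true_dtis) / (cfg.n_drugs * cfg.n_targets)
    return VerificationReport(
        ok=all(p for _, p, _ in checks),
        checks=checks,
        realized_p_on=realized_on,
        realized_p_bg=realized_bg,
        dti_density=density,
        n_duplicates=n_dup,
    )
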