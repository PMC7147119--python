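"""Substructure-drug-target network-based target prediction.

Candidate protein targets for a compound are ranked by diffusing a unit
of "resource" through a tripartite graph whose node classes are drugs,
their known protein targets, and binary substructure-fingerprint bits.
A drug is linked to the targets it is known to bind and to the
substructure bits set in its fingerprint; targets and bits are together
the *attribute* nodes.  Because a new chemical entity (NCE) carries
fingerprint bits even when it has no known target, diffusion through
shared substructures transfers target information from pharmacologically
characterised drugs to uncharacterised ones.

Four parameters control the diffusion (defaults 0.1, 0.1, -0.5, 2):

``alpha``
    Split of a drug's initial resource between its known targets (mass
    ``alpha``) and its substructure bits (mass ``1 - alpha``).  A drug
    with only one attribute class places all mass there.
``beta``
    Edge-class weight in the drug-to-attribute pass: a drug sends a
    fraction ``beta`` of its mass to its target neighbours and
    ``1 - beta`` to its bit neighbours (renormalised if a class is
    empty).
``gamma``
    Hub-correction exponent.  Within each pass, a receiving neighbour's
    share is proportional to ``degree ** gamma`` (total degree in the
    union graph, fixed at build time), normalised over the eligible
    neighbours.  Negative ``gamma`` damps promiscuous hub nodes.
``k``
    Number of diffusion rounds.  One round is an attribute-to-drug pass
    followed by a drug-to-attribute pass, so the resource vector always
    lives on the attribute nodes.  Per-node normalisation makes every
    round mass-conserving for any ``gamma``.

The final score of (drug, target) is the resource sitting on the target
node after ``k`` rounds started from that drug's initial allocation.

The module is organised like a statsmodels estimator: build an
:class:`SDTNBI` model from a known-interaction table and a fingerprint
matrix, call :meth:`SDTNBI.fit` to obtain :class:`SDTNBIResults` holding
the score matrix, and use the results object to extract predicted edges
or a summary.  :meth:`SDTNBI.evaluate_holdout` measures ranking quality
by hiding a random fraction of known interactions.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionParams",
    "FingerprintMatrix",
    "KnownDTISet",
    "SDTNetwork",
    "ScoreMatrix",
    "RankingEvaluation",
    "SDTNBI",
    "SDTNBIResults",
    "build_sdt_network",
    "initial_resources",
    "diffusion_round",
    "predict",
    "select_predictions",
    "evaluate_holdout",
    "evaluate_rankings",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion hyper-parameters (see module docstring)."""

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = -0.5
    k: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not isinstance(self.k, (int, np.integer)) or self.k < 0:
            raise ValueError(f"k must be a non-negative integer, got {self.k}")


class FingerprintMatrix:
    """Binary drug x substructure-bit matrix.

    Bit semantics are opaque to the diffusion engine: any binary matrix
    (Klekota-Roth, MACCS, custom) is accepted.
    """

    def __init__(self, drug_ids: list[str], bit_ids: list[str], X: np.ndarray):
        X = np.asarray(X)
        if X.shape != (len(drug_ids), len(bit_ids)):
            raise ValueError("fingerprint matrix shape does not match id lists")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")
        self.drug_ids = list(drug_ids)
        self.bit_ids = list(bit_ids)
        self.X = X.astype(np.int8)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FingerprintMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.X, index=self.drug_ids, columns=self.bit_ids).to_csv(
            path, index_label="drug_id"
        )


class KnownDTISet:
    """A set of known drug-target interaction pairs."""

    def __init__(self, pairs: "set[tuple[str, str]] | list[tuple[str, str]]"):
        self.pairs = frozenset((str(d), str(t)) for d, t in pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownDTISet":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "drug_id":  # optional header
                    continue
                pairs.append((parts[0], parts[1]))
        return cls(pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("drug_id\ttarget_id\n")
            for d, t in sorted(self.pairs):
                fh.write(f"{d}\t{t}\n")


class SDTNetwork:
    """The tripartite substructure-drug-target graph.

    Holds the binary drug-target adjacency ``A`` (D x T), the binary
    drug-substructure adjacency ``S`` (D x B), and the fixed total-degree
    vectors of the union graph ``[A | S]``.  Attribute columns with no
    edges are removed at build time, as are drugs with zero total degree
    (logged); every retained attribute node is reachable from a drug.
    """

    def __init__(self, drug_ids: list[str], target_ids: list[str],
                 bit_ids: list[str], A: sp.csr_matrix, S: sp.csr_matrix):
        self.drug_ids = list(drug_ids)
        self.target_ids = list(target_ids)
        self.bit_ids = list(bit_ids)
        self.A = sp.csr_matrix(A, dtype=np.float64)
        self.S = sp.csr_matrix(S, dtype=np.float64)
        self._drug_pos = {d: i for i, d in enumerate(self.drug_ids)}
        self._target_pos = {t: j for j, t in enumerate(self.target_ids)}
        # total degrees in the union graph, fixed at build time
        self.deg_drug = np.asarray(self.A.sum(axis=1)).ravel() + np.asarray(
            self.S.sum(axis=1)
        ).ravel()
        self.deg_target = np.asarray(self.A.sum(axis=0)).ravel()
        self.deg_bit = np.asarray(self.S.sum(axis=0)).ravel()
        self._transfer_cache: dict[tuple[float, float], tuple] = {}

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_bits(self) -> int:
        return len(self.bit_ids)

    @property
    def n_attributes(self) -> int:
        return self.n_targets + self.n_bits

    def degree(self, node: str) -> float:
        if node in self._drug_pos:
            return float(self.deg_drug[self._drug_pos[node]])
        if node in self._target_pos:
            return float(self.deg_target[self._target_pos[node]])
        return float(self.deg_bit[self.bit_ids.index(node)])

    def known_pairs(self) -> KnownDTISet:
        rows, cols = self.A.nonzero()
        return KnownDTISet(
            {(self.drug_ids[i], self.target_ids[j]) for i, j in zip(rows, cols)}
        )

    def fingerprints(self) -> FingerprintMatrix:
        return FingerprintMatrix(
            self.drug_ids, self.bit_ids, self.S.toarray().astype(np.int8)
        )

    # -- diffusion machinery -------------------------------------------------

    def transfer_matrices(self, beta: float, gamma: float):
        """Column-stochastic attr->drug and row-stochastic drug->attr passes.

        ``M_ad`` is (T+B) x D: entry (v, u) is the fraction of attribute
        v's mass delivered to drug u.  ``M_da`` is D x (T+B).  Cached per
        (beta, gamma).
        """
        key = (float(beta), float(gamma))
        if key in self._transfer_cache:
            return self._transfer_cache[key]
        Adj = sp.hstack([self.A, self.S], format="csr")  # D x (T+B)
        w_drug = self.deg_drug ** gamma
        w_attr = np.concatenate([self.deg_target, self.deg_bit]) ** gamma

        # attribute -> drug: weight receiving drugs by deg^gamma,
        # normalise over each attribute's drug neighbours
        R = Adj.multiply(w_drug[:, None]).tocsc()
        colsum = np.asarray(R.sum(axis=0)).ravel()
        inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
        M_ad = (R @ sp.diags(inv)).T.tocsr()  # (T+B) x D

        # drug -> attribute: class weights beta / 1-beta, renormalised if a
        # class is empty; deg^gamma shares within each class
        PT = self.A.multiply(w_attr[: self.n_targets][None, :]).tocsr()
        PS = self.S.multiply(w_attr[self.n_targets:][None, :]).tocsr()
        t_sum = np.asarray(PT.sum(axis=1)).ravel()
        b_sum = np.asarray(PS.sum(axis=1)).ravel()
        has_t, has_b = t_sum > 0, b_sum > 0
        wT = np.where(has_t & has_b, beta, np.where(has_t, 1.0, 0.0))
        wB = np.where(has_t & has_b, 1.0 - beta, np.where(has_b, 1.0, 0.0))
        inv_t = np.divide(wT, t_sum, out=np.zeros_like(t_sum), where=has_t)
        inv_b = np.divide(wB, b_sum, out=np.zeros_like(b_sum), where=has_b)
        M_da = sp.hstack(
            [sp.diags(inv_t) @ PT, sp.diags(inv_b) @ PS], format="csr"
        )
        self._transfer_cache[key] = (M_ad, M_da)
        return M_ad, M_da


def build_sdt_network(dtis: KnownDTISet, fps: FingerprintMatrix) -> SDTNetwork:
    """Assemble the tripartite network from known interactions and fingerprints.

    Drugs come from the union of both inputs; a drug missing from the
    fingerprint matrix simply has no bit edges.  Drugs with zero total
    degree are dropped with a logged count, and attribute columns left
    without any edge are removed.
    """
    drug_ids = sorted(set(fps.drug_ids) | dtis.drugs())
    target_ids = sorted(dtis.targets())
    bit_ids = list(fps.bit_ids)
    dpos = {d: i for i, d in enumerate(drug_ids)}

    A = sp.lil_matrix((len(drug_ids), len(target_ids)))
    tpos = {t: j for j, t in enumerate(target_ids)}
    for d, t in dtis.pairs:
        A[dpos[d], tpos[t]] = 1.0
    A = A.tocsr()

    S = sp.lil_matrix((len(drug_ids), len(bit_ids)))
    for row, d in enumerate(fps.drug_ids):
        S[dpos[d], :] = fps.X[row]
    S = S.tocsr()

    deg = np.asarray(A.sum(axis=1)).ravel() + np.asarray(S.sum(axis=1)).ravel()
    keep = deg > 0
    if not keep.all():
        logger.warning("dropping %d isolated drug(s) with zero total degree",
                       int((~keep).sum()))
        drug_ids = [d for d, k in zip(drug_ids, keep) if k]
        A, S = A[keep], S[keep]

    tkeep = np.asarray(A.sum(axis=0)).ravel() > 0
    target_ids = [t for t, k in zip(target_ids, tkeep) if k]
    A = A[:, tkeep]
    bkeep = np.asarray(S.sum(axis=0)).ravel() > 0
    bit_ids = [b for b, k in zip(bit_ids, bkeep) if k]
    S = S[:, bkeep]

    if not drug_ids:
        raise ValueError("network is empty after dropping isolated drugs")
    return SDTNetwork(drug_ids, target_ids, bit_ids, A, S)


def initial_resources(net: SDTNetwork, drug: str, alpha: float) -> np.ndarray:
    """Initial resource vector over attribute nodes (targets then bits).

    A drug with both known targets and fingerprint bits spreads mass
    ``alpha`` equally over its targets and ``1 - alpha`` equally over its
    bits; a drug with a single attribute class gets all mass there.  The
    vector sums to one exactly.
    """
    if drug not in net._drug_pos:
        raise KeyError(f"unknown drug id {drug!r}")
    i = net._drug_pos[drug]
    t_row = net.A[i].toarray().ravel()
    b_row = net.S[i].toarray().ravel()
    nt, nb = t_row.sum(), b_row.sum()
    f = np.zeros(net.n_attributes)
    if nt > 0 and nb > 0:
        f[: net.n_targets] = alpha * t_row / nt
        f[net.n_targets:] = (1.0 - alpha) * b_row / nb
    elif nt > 0:
        f[: net.n_targets] = t_row / nt
    else:
        f[net.n_targets:] = b_row / nb
    return f


def diffusion_round(net: SDTNetwork, resources: np.ndarray, beta: float,
                    gamma: float) -> np.ndarray:
    """One attribute->drug->attribute diffusion round (mass conserving)."""
    resources = np.asarray(resources, dtype=np.float64)
    if abs(resources.sum() - 1.0) > 1e-9:
        raise ValueError("resource vector must sum to 1")
    M_ad, M_da = net.transfer_matrices(beta, gamma)
    return (resources @ M_ad) @ M_da


@dataclass
class ScoreMatrix:
    """Per-drug target scores with the parameters that produced them."""

    df: pd.DataFrame  # drugs x targets, nonnegative
    params: DiffusionParams

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="drug_id", float_format="%.12g")


def predict(net: SDTNetwork, params: DiffusionParams,
            drugs: list[str] | None = None) -> ScoreMatrix:
    """Run ``k`` diffusion rounds for each drug and collect target scores.

    ``k = 0`` returns the initial target allocation.  Deterministic:
    drugs and targets are kept in the network's sorted order.
    """
    if drugs is None:
        drugs = net.drug_ids
    F = np.vstack([initial_resources(net, d, params.alpha) for d in drugs])
    M_ad, M_da = net.transfer_matrices(params.beta, params.gamma)
    for _ in range(params.k):
        F = (F @ M_ad) @ M_da
    df = pd.DataFrame(F[:, : net.n_targets], index=list(drugs),
                      columns=net.target_ids)
    return ScoreMatrix(df=df, params=params)


def select_predictions(
    scores: ScoreMatrix,
    known: KnownDTISet,
    mode: str = "top_L",
    value: float = 20,
) -> list[tuple[str, str, float]]:
    """Turn the score matrix into a predicted-edge list, excluding knowns.

    ``top_L`` keeps each drug's ``value`` highest-scoring novel targets
    with positive score (ties broken by target id); ``score_cutoff``
    keeps novel pairs with score >= ``value``.
    """
    if mode == "top_L":
        L = int(value)
        if L < 1:
            raise ValueError("top_L requires L >= 1")
    elif mode == "score_cutoff":
        if value < 0:
            raise ValueError("score cutoff must be nonnegative")
    else:
        raise ValueError(f"unknown selection mode {mode!r}")

    out: list[tuple[str, str, float]] = []
    for drug, row in scores.df.iterrows():
        novel = [(t, s) for t, s in row.items() if (drug, t) not in known.pairs]
        if mode == "top_L":
            novel = [(t, s) for t, s in novel if s > 0]
            novel.sort(key=lambda ts: (-ts[1], ts[0]))
            novel = novel[: int(value)]
        else:
            novel = [(t, s) for t, s in novel if s >= value]
            novel.sort(key=lambda ts: (-ts[1], ts[0]))
        out.extend((str(drug), t, float(s)) for t, s in novel)
    return out


@dataclass
class RankingEvaluation:
    """Held-out ranking quality at list length L.

    ``precision_enhancement`` (eP) and ``recall_enhancement`` (eR) are
    the ratios of achieved precision/recall to their expectations under
    random ranking of each drug's candidate targets; ``auc`` is the
    macro-averaged per-drug ROC area with midrank tie handling.
    """

    L: int
    precision: float
    recall: float
    precision_enhancement: float
    recall_enhancement: float
    auc: float
    n_drugs: int
    params: DiffusionParams | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "L": self.L,
            "P": self.precision,
            "R": self.recall,
            "eP": self.precision_enhancement,
            "eR": self.recall_enhancement,
            "AUC": self.auc,
            "n_drugs": self.n_drugs,
            "seed": self.seed,
        }
        if self.params is not None:
            payload["params"] = {
                "alpha": self.params.alpha, "beta": self.params.beta,
                "gamma": self.params.gamma, "k": self.params.k,
            }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def summary(self) -> str:
        lines = [
            "Held-out ranking evaluation",
            "===========================",
            f"drugs evaluated : {self.n_drugs}",
            f"list length L   : {self.L}",
            f"precision @ L   : {self.precision:.4f}",
            f"recall @ L      : {self.recall:.4f}",
            f"eP (vs random)  : {self.precision_enhancement:.2f}",
            f"eR (vs random)  : {self.recall_enhancement:.2f}",
            f"AUC (macro)     : {self.auc:.4f}",
        ]
        if self.params is not None:
            lines.append(
                f"params          : alpha={self.params.alpha} beta={self.params.beta}"
                f" gamma={self.params.gamma} k={self.params.k}"
            )
        return "\n".join(lines)


def evaluate_rankings(
    entries: list[tuple[pd.Series, set[str]]], L: int
) -> RankingEvaluation:
    """Ranking metrics over per-drug (candidate scores, positive set) pairs.

    Each entry scores one drug's candidate targets (a Series indexed by
    target id, already excluding that drug's training targets) against
    its held-out positives.  Ties in the top-L cut are broken by target
    id; AUC uses midranks.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not entries:
        raise ValueError("no drugs to evaluate")
    precisions, recalls, aucs = [], [], []
    prand, n_cands = [], []
    for scores, positives in entries:
        cand = scores.index
        npos = len(positives)
        if npos == 0 or npos > len(cand):
            raise ValueError("positives must be a non-empty subset of candidates")
        order = sorted(cand, key=lambda t: (-scores[t], t))
        hits = sum(1 for t in order[:L] if t in positives)
        precisions.append(hits / L)
        recalls.append(hits / npos)
        prand.append(npos / len(cand))
        n_cands.append(len(cand))
        nneg = len(cand) - npos
        if nneg > 0:
            ranks = rankdata(scores.to_numpy())
            pos_mask = np.fromiter((t in positives for t in cand), bool,
                                   len(cand))
            auc = (ranks[pos_mask].sum() - npos * (npos + 1) / 2) / (npos * nneg)
            aucs.append(auc)
    P = float(np.mean(precisions))
    R = float(np.mean(recalls))
    P_rand = float(np.mean(prand))
    R_rand = L / float(np.mean(n_cands))
    return RankingEvaluation(
        L=L,
        precision=P,
        recall=R,
        precision_enhancement=P / P_rand if P_rand > 0 else float("nan"),
        recall_enhancement=R / R_rand if R_rand > 0 else float("nan"),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        n_drugs=len(entries),
    )


def evaluate_holdout(
    net: SDTNetwork,
    params: DiffusionParams,
    holdout_fraction: float,
    L: int,
    seed: int,
    leave_one_out: bool = False,
) -> RankingEvaluation:
    """Hide a random fraction of known interactions and rank them back.

    The network is rebuilt on the surviving interactions (drugs that lose
    all their targets are scored as NCEs through their fingerprint bits);
    each drug's candidate list is every target of the rebuilt network
    except its own training targets.  Held-out pairs whose target drops
    out of the rebuilt network entirely cannot be ranked and are ignored;
    drugs with no rankable held-out target are excluded from all means.

    With ``leave_one_out`` a single random known interaction per drug is
    held out instead of a global fraction.
    """
    if not 0 < holdout_fraction < 1 and not leave_one_out:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pairs = sorted(net.known_pairs().pairs)
    if leave_one_out:
        by_drug: dict[str, list[tuple[str, str]]] = {}
        for p in pairs:
            by_drug.setdefault(p[0], []).append(p)
        heldout = {ps[rng.integers(len(ps))] for ps in by_drug.values()}
    else:
        n_hold = int(round(holdout_fraction * len(pairs)))
        if n_hold < 1:
            raise ValueError("holdout fraction selects no edges; increase it")
        idx = rng.choice(len(pairs), size=n_hold, replace=False)
        heldout = {pairs[i] for i in idx}
    training = [p for p in pairs if p not in heldout]
    if not training:
        raise ValueError("holdout removed every known interaction")

    sub = build_sdt_network(KnownDTISet(training), net.fingerprints())
    tset = set(sub.target_ids)
    hold_by_drug: dict[str, set[str]] = {}
    for d, t in heldout:
        if d in sub._drug_pos and t in tset:
            hold_by_drug.setdefault(d, set()).add(t)
    if not hold_by_drug:
        raise ValueError(
            "no drug has a rankable held-out target; increase holdout_fraction"
        )
    train_by_drug: dict[str, set[str]] = {}
    for d, t in training:
        train_by_drug.setdefault(d, set()).add(t)

    drugs = sorted(hold_by_drug)
    scores = predict(sub, params, drugs)
    entries = []
    for d in drugs:
        cand = [t for t in sub.target_ids if t not in train_by_drug.get(d, ())]
        entries.append((scores.df.loc[d, cand], hold_by_drug[d]))
    result = evaluate_rankings(entries, L)
    result.params = params
    result.seed = seed
    return result


class SDTNBI:
    """Substructure-drug-target diffusion model.

    Parameters
    ----------
    dtis : KnownDTISet
        Known drug-target interaction pairs.
    fingerprints : FingerprintMatrix
        Binary substructure matrix over (a superset of) the same drugs.

    Examples
    --------
    >>> model = SDTNBI.from_files("dti.tsv", "fingerprints.csv")  # doctest: +SKIP
    >>> res = model.fit()                                          # doctest: +SKIP
    >>> res.predicted_edges(mode="top_L", value=20)                # doctest: +SKIP
    """

    def __init__(self, dtis: KnownDTISet, fingerprints: FingerprintMatrix):
        self.dtis = dtis
        self.fingerprints = fingerprints
        self.network = build_sdt_network(dtis, fingerprints)

    @classmethod
    def from_files(cls, dti_tsv: str | Path, fp_csv: str | Path) -> "SDTNBI":
        return cls(KnownDTISet.from_tsv(dti_tsv), FingerprintMatrix.from_csv(fp_csv))

    def fit(self, params: DiffusionParams | None = None,
            drugs: list[str] | None = None) -> "SDTNBIResults":
        params = params or DiffusionParams()
        return SDTNBIResults(self, params, predict(self.network, params, drugs))

    def evaluate_holdout(self, holdout_fraction: float = 0.2, L: int = 10,
                         seed: int = 0,
                         params: DiffusionParams | None = None,
                         leave_one_out: bool = False) -> RankingEvaluation:
        return evaluate_holdout(self.network, params or DiffusionParams(),
                                holdout_fraction, L, seed,
                                leave_one_out=leave_one_out)


class SDTNBIResults:
    """Fitted diffusion scores plus convenience extractors."""

    def __init__(self, model: SDTNBI, params: DiffusionParams,
                 scores: ScoreMatrix):
        self.model = model
        self.params = params
        self.scores = scores

    def predicted_edges(self, mode: str = "top_L",
                        value: float = 20) -> list[tuple[str, str, float]]:
        """Novel (drug, target, score) edges, known pairs excluded."""
        return select_predictions(self.scores, self.model.dtis, mode, value)

    def edge_table(self, mode: str = "top_L", value: float = 20) -> pd.DataFrame:
        """Known plus predicted edges with a provenance flag."""
        rows = [
            {"drug_id": d, "target_id": t, "score": float("nan"),
             "provenance": "known"}
            for d, t in sorted(self.model.dtis.pairs)
        ]
        rows += [
            {"drug_id": d, "target_id": t, "score": s, "provenance": "predicted"}
            for d, t, s in self.predicted_edges(mode, value)
        ]
        return pd.DataFrame(rows, columns=["drug_id", "target_id", "score",
                                           "provenance"])

    def summary(self) -> str:
        net = self.model.network
        n_pred = int((self.scores.df.to_numpy() > 0).sum()) - len(
            [p for p in self.model.dtis.pairs
             if p[0] in self.scores.df.index]
        )
        lines = [
            "Substructure-drug-target diffusion fit",
            "======================================",
            f"drugs          : {net.n_drugs}",
            f"targets        : {net.n_targets}",
            f"substructures  : {net.n_bits}",
            f"known edges    : {len(self.model.dtis)}",
            f"scored drugs   : {len(self.scores.df)}",
            f"nonzero novel scores : {max(n_pred, 0)}",
            f"params         : alpha={self.params.alpha} beta={self.params.beta}"
            f" gamma={self.params.gamma} k={self.params.k}",
        ]
        return "\n".join(lines)
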