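"""Diffusion engine: network build, resource spreading, scoring, evaluation."""

import numpy as np
import pandas as pd
import pytest

from netpharm.sdtnbi import (
    DiffusionParams,
    FingerprintMatrix,
    KnownDTISet,
    ScoreMatrix,
    build_sdt_network,
    diffusion_round,
    evaluate_holdout,
    evaluate_rankings,
    initial_resources,
    predict,
    select_predictions,
)

from _oracles import dense_diffusion_scores, random_adjacency


def _net_from_arrays(A, S):
    D, T = A.shape
    B = S.shape[1]
    drugs = [f"d{i:02d}" for i in range(D)]
    targets = [f"t{j:02d}" for j in range(T)]
    bits = [f"b{j:02d}" for j in range(B)]
    dtis = KnownDTISet({(drugs[i], targets[j]) for i, j in zip(*np.nonzero(A))})
    fps = FingerprintMatrix(drugs, bits, S.astype(int))
    return build_sdt_network(dtis, fps)


class TestBuild:
    def test_minimal_one_edge_network(self):
        net = build_sdt_network(
            KnownDTISet({("d1", "t1")}), FingerprintMatrix(["d1"], [], [[]])
        )
        assert (net.n_drugs, net.n_targets, net.n_bits) == (1, 1, 0)
        assert net.degree("d1") == 1

    def test_degrees_match_hand_count(self, tiny_network):
        net = tiny_network
        # d1: t1+b1+b2=3, d2: t1+t2+b2=3, d3: b3=1
        assert [net.degree(d) for d in ("d1", "d2", "d3")] == [3, 3, 1]
        assert net.degree("t1") == 2 and net.degree("t2") == 1
        assert net.degree("b2") == 2

    def test_isolated_drug_dropped_with_warning(self, caplog):
        fps = FingerprintMatrix(["d1", "d2"], ["b1"], [[1], [0]])
        with caplog.at_level("WARNING"):
            net = build_sdt_network(KnownDTISet({("d1", "t1")}), fps)
        assert net.drug_ids == ["d1"]
        assert "isolated" in caplog.text

    def test_unreferenced_bit_columns_removed(self):
        fps = FingerprintMatrix(["d1"], ["b1", "b2"], [[1, 0]])
        net = build_sdt_network(KnownDTISet({("d1", "t1")}), fps)
        assert net.bit_ids == ["b1"]

    def test_empty_network_is_fatal(self):
        with pytest.raises(ValueError):
            build_sdt_network(KnownDTISet(set()),
                              FingerprintMatrix(["d1"], ["b1"], [[0]]))


class TestInitialResources:
    def test_alpha_split_between_targets_and_bits(self, tiny_network):
        f = initial_resources(tiny_network, "d1", alpha=0.1)
        t = dict(zip(tiny_network.target_ids, f[: tiny_network.n_targets]))
        b = dict(zip(tiny_network.bit_ids, f[tiny_network.n_targets:]))
        assert t["t1"] == pytest.approx(0.1)
        assert b["b1"] == b["b2"] == pytest.approx(0.45)
        assert f.sum() == pytest.approx(1.0, abs=1e-15)

    def test_two_targets_two_bits(self):
        A = np.array([[1, 1]])
        S = np.array([[1, 1]])
        net = _net_from_arrays(A, S)
        f = initial_resources(net, "d00", alpha=0.1)
        assert list(f) == pytest.approx([0.05, 0.05, 0.45, 0.45])

    def test_nce_gets_all_mass_on_bits(self, tiny_network):
        for alpha in (0.0, 0.3, 1.0):
            f = initial_resources(tiny_network, "d3", alpha)
            assert f[: tiny_network.n_targets].sum() == 0.0
            assert f.sum() == pytest.approx(1.0)

    def test_alpha_one_puts_all_mass_on_targets(self, tiny_network):
        f = initial_resources(tiny_network, "d1", alpha=1.0)
        assert f[tiny_network.n_targets:].sum() == 0.0
        assert f[: tiny_network.n_targets].sum() == pytest.approx(1.0)

    def test_unknown_drug_is_an_error(self, tiny_network):
        with pytest.raises(KeyError):
            initial_resources(tiny_network, "ghost", 0.1)


class TestDiffusionRound:
    def test_single_drug_hand_computation(self):
        # one drug with 1 target and 1 bit, all mass on the bit:
        # bit -> drug (its only neighbour), drug splits beta/1-beta
        net = _net_from_arrays(np.array([[1]]), np.array([[1]]))
        f0 = np.array([0.0, 1.0])
        f1 = diffusion_round(net, f0, beta=0.5, gamma=0.0)
        assert list(f1) == pytest.approx([0.5, 0.5])

    def test_conservation_for_many_gammas(self):
        rng = np.random.default_rng(5)
        A, S = random_adjacency(rng, 12, 6, 10)
        net = _net_from_arrays(A, S)
        for gamma in (-1.0, -0.5, 0.0, 1.0):
            f = initial_resources(net, net.drug_ids[0], 0.1)
            for _ in range(4):
                f = diffusion_round(net, f, beta=0.1, gamma=gamma)
                assert f.sum() == pytest.approx(1.0, abs=1e-12)
                assert (f >= 0).all()

    def test_gamma_irrelevant_on_degree_regular_network(self):
        # 2 drugs x 2 targets complete bipartite: all degrees equal 2
        A = np.ones((2, 2))
        S = np.zeros((2, 0))
        net = _net_from_arrays(A, S)
        f0 = initial_resources(net, "d00", 0.1)
        out0 = diffusion_round(net, f0, beta=0.1, gamma=0.0)
        out1 = diffusion_round(net, f0, beta=0.1, gamma=-0.5)
        np.testing.assert_allclose(out0, out1, atol=1e-15)

    def test_unnormalized_input_rejected(self, tiny_network):
        with pytest.raises(ValueError):
            diffusion_round(tiny_network, np.full(tiny_network.n_attributes, 0.5),
                            0.1, -0.5)


class TestPredict:
    def test_default_params(self):
        p = DiffusionParams()
        assert (p.alpha, p.beta, p.gamma, p.k) == (0.1, 0.1, -0.5, 2)

    def test_k0_returns_initial_target_allocation(self, tiny_network):
        scores = predict(tiny_network, DiffusionParams(alpha=0.1, k=0))
        row = scores.df.loc["d2"]
        assert row["t1"] == pytest.approx(0.05)
        assert row["t2"] == pytest.approx(0.05)
        assert scores.df.loc["d3"].sum() == 0.0  # NCE, k=0: no target mass yet

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, S = random_adjacency(rng, 15, 8, 12)
        net = _net_from_arrays(A, S)
        params = DiffusionParams(0.1, 0.1, -0.5, 2)
        got = predict(net, params).df.to_numpy()
        want = dense_diffusion_scores(A, S, 0.1, 0.1, -0.5, 2)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_nonzero_support_is_monotone_in_k(self):
        rng = np.random.default_rng(11)
        A, S = random_adjacency(rng, 10, 6, 8)
        net = _net_from_arrays(A, S)
        prev = None
        for k in range(4):
            scores = predict(net, DiffusionParams(k=k)).df.to_numpy()
            support = {tuple(r) for r in np.argwhere(scores > 1e-15)}
            if prev is not None:
                assert prev <= support
            prev = support

    def test_invariant_to_id_relabeling(self):
        rng = np.random.default_rng(3)
        A, S = random_adjacency(rng, 8, 5, 6)
        net = _net_from_arrays(A, S)
        scores = predict(net, DiffusionParams()).df
        # relabel so that sorted order changes, then map back
        dmap = {d: f"z{len(net.drug_ids) - i:02d}" for i, d in enumerate(net.drug_ids)}
        tmap = {t: f"y{len(net.target_ids) - j:02d}"
                for j, t in enumerate(net.target_ids)}
        dtis2 = KnownDTISet({(dmap[d], tmap[t]) for d, t in net.known_pairs().pairs})
        fp = net.fingerprints()
        fps2 = FingerprintMatrix([dmap[d] for d in fp.drug_ids], fp.bit_ids, fp.X)
        net2 = build_sdt_network(dtis2, fps2)
        scores2 = predict(net2, DiffusionParams()).df
        for d in net.drug_ids:
            for t in net.target_ids:
                assert scores2.loc[dmap[d], tmap[t]] == pytest.approx(
                    scores.loc[d, t], abs=1e-14
                )


class TestSelectPredictions:
    def _scores(self):
        df = pd.DataFrame(
            [[0.3, 0.2, 0.2, 0.0]], index=["d1"], columns=["t1", "t2", "t3", "t4"]
        )
        return ScoreMatrix(df=df, params=DiffusionParams())

    def test_top_l_tie_broken_by_target_id(self):
        picked = select_predictions(self._scores(), KnownDTISet(set()),
                                    "top_L", 2)
        assert [(d, t) for d, t, _ in picked] == [("d1", "t1"), ("d1", "t2")]

    def test_l_larger_than_targets_saturates_at_positive_scores(self):
        picked = select_predictions(self._scores(), KnownDTISet(set()),
                                    "top_L", 100)
        assert [t for _, t, _ in picked] == ["t1", "t2", "t3"]

    def test_known_pairs_are_excluded(self):
        picked = select_predictions(self._scores(), KnownDTISet({("d1", "t1")}),
                                    "top_L", 2)
        assert [t for _, t, _ in picked] == ["t2", "t3"]

    def test_zero_cutoff_keeps_everything_but_known(self):
        picked = select_predictions(self._scores(), KnownDTISet({("d1", "t1")}),
                                    "score_cutoff", 0.0)
        assert {t for _, t, _ in picked} == {"t2", "t3", "t4"}

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            select_predictions(self._scores(), KnownDTISet(set()), "top_L", 0)
        with pytest.raises(ValueError):
            select_predictions(self._scores(), KnownDTISet(set()),
                               "score_cutoff", -1)
        with pytest.raises(ValueError):
            select_predictions(self._scores(), KnownDTISet(set()), "best", 1)


class TestEvaluation:
    def test_perfect_ranking_limit(self):
        entries = []
        rng = np.random.default_rng(0)
        for _ in range(5):
            cands = [f"t{j}" for j in range(12)]
            pos = set(rng.choice(cands, 3, replace=False))
            scores = pd.Series(
                [1.0 + rng.random() if c in pos else rng.random() * 0.5
                 for c in cands], index=cands)
            entries.append((scores, pos))
        ev = evaluate_rankings(entries, L=10)
        assert ev.auc == pytest.approx(1.0)
        assert ev.recall == pytest.approx(1.0)

    def test_random_scores_are_calibrated(self):
        rng = np.random.default_rng(42)
        aucs, eps, ers = [], [], []
        for _ in range(30):
            entries = []
            for _ in range(25):
                cands = [f"t{j}" for j in range(20)]
                npos = int(rng.integers(1, 4))
                pos = set(rng.choice(cands, npos, replace=False))
                entries.append((pd.Series(rng.random(20), index=cands), pos))
            ev = evaluate_rankings(entries, L=5)
            aucs.append(ev.auc)
            eps.append(ev.precision_enhancement)
            ers.append(ev.recall_enhancement)
        assert 0.45 <= np.mean(aucs) <= 0.55
        assert 0.8 <= np.mean(eps) <= 1.2
        assert 0.8 <= np.mean(ers) <= 1.2

    def test_holdout_round_trip_on_random_network(self):
        rng = np.random.default_rng(8)
        A, S = random_adjacency(rng, 40, 12, 20, p_dt=0.3)
        net = _net_from_arrays(A, S)
        ev = evaluate_holdout(net, DiffusionParams(), 0.2, L=5, seed=3)
        assert 0.0 <= ev.auc <= 1.0
        assert 0.0 <= ev.precision <= 1.0 and 0.0 <= ev.recall <= 1.0
        assert ev.n_drugs > 0

    def test_bad_holdout_fraction(self, tiny_network):
        with pytest.raises(ValueError):
            evaluate_holdout(tiny_network, DiffusionParams(), 1.5, 5, 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DiffusionParams(alpha=1.5)
        with pytest.raises(ValueError):
            DiffusionParams(k=-1)
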