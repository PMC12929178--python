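import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from clpntraj.network import (
    CLPNetwork,
    density,
    edge_or,
    expected_influence,
    fit_clpn,
    network_frame,
)
from clpntraj.panel import BinaryPanel, NODES
from clpntraj.simulate import CLPNTruth, generate_clpn_panel


def small_net(b, nodes=None):
    b = np.asarray(b, float)
    nodes = tuple(nodes or [f"N{i}" for i in range(b.shape[0])])
    return CLPNetwork(nodes=nodes, b=b, intercepts=np.zeros(len(nodes)),
                      lambdas=np.zeros(len(nodes)), wave_pair=(1, 2), n=100)


class TestFitAgainstMLE:
    def test_zero_penalty_equals_unpenalized_mle(self):
        """A 3-symptom toy at lambda = 0 must match statsmodels' Logit MLE."""
        rng = np.random.default_rng(8)
        n = 500
        X1 = rng.integers(0, 2, (n, 16))
        logits = -0.5 + X1[:, :3] @ np.array([1.0, -0.6, 0.4])
        X2 = X1.copy()
        X2[:, 0] = rng.random(n) < 1 / (1 + np.exp(-logits))
        idx = pd.MultiIndex.from_product([range(n), [1, 2]], names=["subject_id", "wave"])
        items = pd.DataFrame(np.stack([X1, X2], axis=1).reshape(-1, 16),
                             columns=list(NODES), index=idx)
        panel = BinaryPanel(items=items)
        net = fit_clpn(panel, (1, 2), fixed_lambdas=0.0)
        ml = sm.Logit(panel.wave(2)["GAD1"], sm.add_constant(panel.wave(1))).fit(disp=0)
        assert np.abs(net.b[:, 0] - ml.params.iloc[1:].to_numpy()).max() < 1e-4
        assert net.intercepts[0] == pytest.approx(ml.params.iloc[0], abs=1e-4)

    def test_small_sample_refused(self, planted_truth):
        panel, _ = generate_clpn_panel(planted_truth, 30, seed=1)
        with pytest.raises(ValueError, match="n=30"):
            fit_clpn(panel, (1, 2))


class TestEdgeOR:
    def test_known_log_odds_map_to_odds_ratios(self):
        net = small_net([[0.0, np.log(2)], [-np.log(4), 0.0]])
        ors = edge_or(net)
        assert ors[0, 0] == 1.0          # zero coefficient: no association
        assert ors[0, 1] == pytest.approx(2.0)
        assert ors[1, 0] == pytest.approx(0.25)

    def test_exp_log_identity(self):
        rng = np.random.default_rng(0)
        pos = np.exp(rng.normal(0, 1, (4, 4)))
        net = small_net(np.log(pos))
        assert np.allclose(edge_or(net), pos)


class TestDensity:
    @pytest.mark.parametrize("n_edges, expected", [(201, 0.785), (50, 0.195)])
    def test_published_edge_counts_give_published_density(self, n_edges, expected):
        b = np.zeros(256)
        b[:n_edges] = 0.3
        net = small_net(b.reshape(16, 16), nodes=NODES)
        total, cross, dens = density(net)
        assert total == n_edges
        assert round(dens, 3) == expected

    def test_empty_matrix(self):
        total, cross, dens = density(small_net(np.zeros((16, 16)), nodes=NODES))
        assert (total, cross, dens) == (0, 0, 0.0)

    def test_cross_lagged_excludes_diagonal(self):
        b = np.eye(16) * 0.5
        b[0, 1] = 0.2
        total, cross, _ = density(small_net(b, nodes=NODES))
        assert total == 17 and cross == 1


class TestExpectedInfluence:
    def test_hand_summed_three_node_oracle(self):
        b = np.array([[2.0, 0.5, 0.25],
                      [0.0, 2.0, 0.0],
                      [0.0, -0.25, 2.0]])
        ei = expected_influence(small_net(b))
        assert ei["raw_out"].tolist() == [0.75, 0.0, -0.25]
        assert ei["raw_in"].tolist() == [0.0, 0.25, 0.25]

    def test_zero_matrix_and_degenerate_standardization(self):
        ei = expected_influence(small_net(np.zeros((16, 16)), nodes=NODES))
        assert (ei[["raw_in", "raw_out", "z_in", "z_out"]] == 0).all().all()
        assert not ei["influential"].any()

    def test_standardized_columns_centred_with_unit_sd(self, planted_net):
        ei = expected_influence(planted_net)
        for col in ("z_in", "z_out"):
            assert ei[col].sum() == pytest.approx(0.0, abs=1e-9)
            assert ei[col].std(ddof=1) == pytest.approx(1.0)

    def test_autoregressive_diagonal_excluded_by_default(self, planted_net):
        with_auto = expected_influence(planted_net, include_autoregressive=True)
        default = expected_influence(planted_net)
        diag = np.diag(planted_net.b)
        assert np.allclose(with_auto["raw_out"] - default["raw_out"], diag)


class TestStructuralProperties:
    def test_node_permutation_permutes_b_consistently(self, planted_panel, planted_net):
        perm = np.random.default_rng(2).permutation(16)
        items = planted_panel.items[[NODES[i] for i in perm]]
        permuted = BinaryPanel(items=items, covariates=planted_panel.covariates)
        net_p = fit_clpn(permuted, (1, 2), fixed_lambdas=planted_net.lambdas[perm])
        # agreement limited by the solver tolerance, not the permutation
        assert np.allclose(net_p.b, planted_net.b[np.ix_(perm, perm)], atol=1e-3)

    def test_penalty_path_monotone_in_edge_count(self, planted_panel):
        counts = []
        for lam in (0.1, 0.03, 0.01, 0.003, 0.001):
            net = fit_clpn(planted_panel, (1, 2), fixed_lambdas=lam)
            counts.append(density(net)[0])
        assert counts == sorted(counts)

    def test_independent_covariates_barely_move_edges(self, planted_truth):
        panel, _ = generate_clpn_panel(
            planted_truth, 4000, seed=9,
            covariate_spec={"sex": ("bernoulli", 0.5), "age": ("uniform_int", 17, 24)},
        )
        plain = fit_clpn(panel, (1, 2), fixed_lambdas=0.01)
        adjusted = fit_clpn(panel, (1, 2), fixed_lambdas=0.01, covariates=["sex", "age"])
        assert np.abs(plain.b - adjusted.b).max() < 0.05

    def test_constant_outcome_yields_zero_column(self, planted_truth, caplog):
        panel, _ = generate_clpn_panel(planted_truth, 200, seed=10)
        items = panel.items.copy()
        items.loc[(slice(None), 2), "PHQ9"] = 1  # saturate one outcome
        forced = BinaryPanel(items=items, covariates=panel.covariates)
        with caplog.at_level("WARNING", logger="clpntraj"):
            net = fit_clpn(forced, (1, 2), fixed_lambdas=0.05)
        j = list(net.nodes).index("PHQ9")
        assert (net.b[:, j] == 0).all()
        assert any("constant" in r.message for r in caplog.records)

    def test_network_frame_round_trip(self, planted_net):
        frame = network_frame(planted_net, "or")
        assert np.allclose(np.log(frame.to_numpy()), planted_net.b)
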