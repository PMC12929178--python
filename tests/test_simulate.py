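import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clpntraj.panel import score_panel
from clpntraj.simulate import (
    CLPNTruth,
    ConfigError,
    GrowthMixtureConfig,
    generate_clpn_panel,
    generate_growth_mixture,
)
from clpntraj.trajectories import growth_matrix


def one_class(alpha_a, beta_a, alpha_d, beta_d, **kw):
    kw.setdefault("item_sd", 0.0)
    return GrowthMixtureConfig(
        class_proportions=(1.0,),
        alpha_anx=(alpha_a,), beta_anx=(beta_a,),
        alpha_dep=(alpha_d,), beta_dep=(beta_d,), **kw,
    )


class TestGrowthMixture:
    def test_degenerate_zero_config_gives_all_zero_scores(self):
        panel, _ = generate_growth_mixture(one_class(0, 0, 0, 0, n_subjects=20))
        assert (panel.items == 0).all().all()

    def test_noiseless_linear_growth_clips_at_scale_maximum(self):
        # integer-valued latent lines: scores equal the line exactly, and a
        # line exceeding the item maximum of 3 is clipped there
        panel, _ = generate_growth_mixture(one_class(1.0, 1.0, 2.0, 1.0, n_subjects=10))
        y = growth_matrix(score_panel(panel))
        assert np.allclose(y[:, :3], [1, 2, 3])
        assert np.allclose(y[:, 3:], [2, 3, 3])

    def test_class_trajectories_match_configured_lines(self):
        cfg = GrowthMixtureConfig(
            n_subjects=5000, seed=11,
            class_proportions=(0.7, 0.27, 0.03),
            alpha_anx=(0.8, 1.4, 2.0), beta_anx=(0.0, 0.2, 0.05),
            alpha_dep=(0.9, 1.5, 2.1), beta_dep=(0.0, 0.25, 0.05),
            item_sd=0.5,
        )
        panel, labels = generate_growth_mixture(cfg)
        y = growth_matrix(score_panel(panel))
        t = np.arange(3)
        for k in range(3):
            m = y[labels == k]
            assert np.abs(m[:, :3].mean(0) - (cfg.alpha_anx[k] + cfg.beta_anx[k] * t)).max() < 0.05
            assert np.abs(m[:, 3:].mean(0) - (cfg.alpha_dep[k] + cfg.beta_dep[k] * t)).max() < 0.05

    def test_class_frequencies_within_binomial_ci(self):
        cfg = GrowthMixtureConfig(n_subjects=10000, seed=12)
        _, labels = generate_growth_mixture(cfg)
        for k, pi in enumerate(cfg.class_proportions):
            count = int((labels == k).sum())
            lo, hi = stats.binom.interval(0.999, cfg.n_subjects, pi)
            assert lo <= count <= hi

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ConfigError):
            GrowthMixtureConfig(class_proportions=(0.5, 0.4))

    def test_fixed_seed_bit_identical(self):
        a, la = generate_growth_mixture(GrowthMixtureConfig(n_subjects=50, seed=9))
        b, lb = generate_growth_mixture(GrowthMixtureConfig(n_subjects=50, seed=9))
        pd.testing.assert_frame_equal(a.items, b.items)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        assert (la == lb).all()


class TestCLPNPanel:
    def test_null_model_gives_half_prevalence_at_wave_two(self):
        truth = CLPNTruth(weights=np.zeros((16, 16)), intercepts=np.zeros(16),
                          p0=np.full(16, 0.2))
        panel, _ = generate_clpn_panel(truth, 20000, seed=1)
        w2 = panel.wave(2).mean()
        assert np.abs(w2 - 0.5).max() < 0.02

    def test_single_edge_closed_form_transition(self):
        W = np.zeros((16, 16))
        W[0, 1] = 2.0
        truth = CLPNTruth(weights=W, intercepts=np.r_[[0.0], [-1.0], np.zeros(14)],
                          p0=np.full(16, 0.5))
        panel, _ = generate_clpn_panel(truth, 40000, seed=2)
        x1 = panel.wave(1)["GAD1"].to_numpy()
        y2 = panel.wave(2)["GAD2"].to_numpy()
        p_on = y2[x1 == 1].mean()
        p_off = y2[x1 == 0].mean()
        expit = lambda z: 1 / (1 + np.exp(-z))
        assert p_on == pytest.approx(expit(1.0), abs=0.01)
        assert p_off == pytest.approx(expit(-1.0), abs=0.01)

    def test_conditional_log_odds_recover_truth(self, planted_truth):
        # brute-force frequency oracle: the log-odds difference for parent i
        # is taken within the stratum where every other parent of j is 0
        # (log-odds are not collapsible over co-parents)
        panel, _ = generate_clpn_panel(planted_truth, 40000, seed=3)
        X = panel.wave(1).to_numpy()
        Y = panel.wave(2).to_numpy()
        W = planted_truth.weights
        logit = lambda p: np.log(p / (1 - p))
        for i, j in zip(*np.nonzero(W * (1 - np.eye(16)))):
            others = [k for k in np.nonzero(W[:, j])[0] if k != i]
            stratum = (X[:, others] == 0).all(axis=1)
            on = Y[stratum & (X[:, i] == 1), j].mean()
            off = Y[stratum & (X[:, i] == 0), j].mean()
            assert logit(on) - logit(off) == pytest.approx(W[i, j], abs=0.1)

    def test_fixed_seed_bit_identical(self, planted_truth):
        a, _ = generate_clpn_panel(planted_truth, 500, seed=5)
        b, _ = generate_clpn_panel(planted_truth, 500, seed=5)
        pd.testing.assert_frame_equal(a.items, b.items)

    def test_invalid_p0_rejected(self):
        with pytest.raises(ConfigError):
            CLPNTruth(weights=np.zeros((16, 16)), intercepts=np.zeros(16),
                      p0=np.full(16, 1.0))
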