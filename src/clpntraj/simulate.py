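"""Synthetic three-wave symptom panels with known ground truth.

Two generators mirror the two halves of the analysis:

* :func:`generate_growth_mixture` draws subjects from latent trajectory
  classes whose anxiety and depression mean scores follow class-specific
  linear growth over waves coded 0, 1, 2, then emits ordinal 0-3 item
  scores around the latent wave mean (discretized clipped normal).
* :func:`generate_clpn_panel` produces binary symptom panels from a known
  lagged logistic transition matrix, the generative twin of the
  cross-lagged panel network estimator.

Default parameters emulate the study design these tools target: three
trajectory classes (a large low-symptom "resistance" class, a moderate
growing class, and a small chronically elevated class) in proportions
0.698 / 0.272 / 0.030, with baseline covariates (sex, age 17-24, four
pandemic-exposure indicators) that have no effect on outcomes unless
configured. One master seed drives per-stage child generators, so a fixed
seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import BinaryPanel, GAD_ITEMS, NODES, PHQ_ITEMS, PanelDataset, WAVES

TIME_SCORES = np.array([0.0, 1.0, 2.0])

#: covariate name -> ("bernoulli", p) | ("uniform_int", lo, hi)
DEFAULT_COVARIATES: dict[str, tuple] = {
    "sex": ("bernoulli", 0.5),
    "age": ("uniform_int", 17, 24),
    "epidemic_severity": ("bernoulli", 0.3),
    "local_cases": ("bernoulli", 0.2),
    "infected_acquaintance": ("bernoulli", 0.1),
    "media_exposure": ("bernoulli", 0.5),
}


class ConfigError(ValueError):
    pass


@dataclass
class GrowthMixtureConfig:
    """Ground truth for the parallel-process latent-class growth generator.

    Intercepts ``alpha`` and slopes ``beta`` live on the 0-3 mean-score
    scale, one per class per process (A = anxiety, D = depression).
    Within-class growth-factor standard deviations default to 0 (pure
    latent-class growth); ``residual_sd`` is wave-level noise on the latent
    mean score and ``item_sd`` the dispersion of individual item scores
    around it.
    """

    n_subjects: int = 2000
    class_proportions: tuple[float, ...] = (0.698, 0.272, 0.030)
    alpha_anx: tuple[float, ...] = (0.20, 0.60, 1.70)
    beta_anx: tuple[float, ...] = (0.02, 0.25, 0.05)
    alpha_dep: tuple[float, ...] = (0.30, 0.75, 1.80)
    beta_dep: tuple[float, ...] = (0.04, 0.30, 0.05)
    intercept_sd: float = 0.0
    slope_sd: float = 0.0
    cross_process_corr: float = 0.0
    residual_sd: float = 0.0
    item_sd: float = 0.55
    item_offsets_anx: tuple[float, ...] = (0.0,) * 7
    item_offsets_dep: tuple[float, ...] = (0.0,) * 9
    covariates: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.class_proportions, float)
        if pi.min() < 0 or abs(pi.sum() - 1.0) > 1e-8:
            raise ConfigError("class_proportions must be a probability simplex")
        k = len(pi)
        for name in ("alpha_anx", "beta_anx", "alpha_dep", "beta_dep"):
            if len(getattr(self, name)) != k:
                raise ConfigError(f"{name} must have one entry per class ({k})")
        if len(self.item_offsets_anx) != 7 or len(self.item_offsets_dep) != 9:
            raise ConfigError("item offsets must have 7 (A) and 9 (D) entries")
        for name in ("intercept_sd", "slope_sd", "residual_sd", "item_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not -1.0 <= self.cross_process_corr <= 1.0:
            raise ConfigError("cross_process_corr must be in [-1, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)


@dataclass
class CLPNTruth:
    """Generative lagged logistic model for 16 binary symptoms.

    ``weights[i, j]`` is the log-odds effect of symptom i present at wave t
    on symptom j at wave t+1; ``intercepts`` are per-outcome log-odds
    offsets, ``p0`` the wave-1 marginal prevalences, and ``covariate_effects``
    an optional (n_covariates x 16) log-odds matrix.
    """

    weights: np.ndarray
    intercepts: np.ndarray
    p0: np.ndarray
    covariate_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.intercepts = np.asarray(self.intercepts, float)
        self.p0 = np.asarray(self.p0, float)
        if self.weights.shape != (16, 16):
            raise ConfigError("weights must be 16x16")
        if not np.all(np.isfinite(self.weights)):
            raise ConfigError("weights must be finite")
        if np.any(self.p0 <= 0) or np.any(self.p0 >= 1):
            raise ConfigError("p0 must lie strictly in (0, 1)")


def _draw_covariates(spec: dict[str, tuple], n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, rule in spec.items():
        kind = rule[0]
        if kind == "bernoulli":
            cols[name] = rng.binomial(1, rule[1], n)
        elif kind == "uniform_int":
            cols[name] = rng.integers(rule[1], rule[2] + 1, n)
        else:
            raise ConfigError(f"unknown covariate rule {kind!r} for {name!r}")
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="subject_id"))


def generate_growth_mixture(config: GrowthMixtureConfig) -> tuple[PanelDataset, np.ndarray]:
    """Draw a panel from the growth-mixture ground truth.

    Returns the ordinal :class:`PanelDataset` and the true class label per
    subject. Subject i falls into class k with probability pi_k; the latent
    wave mean for a process is ``alpha_k + beta_k * t + u_i + v_i * t``
    (time scores t = 0, 1, 2; u, v zero-mean normal with the configured
    within-class sds), clipped to [0, 3]; each item score is
    ``round(clip(Normal(mean + offset, item_sd), 0, 3))``.
    """
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    rng_class, rng_growth, rng_item, rng_cov = (
        np.random.default_rng(s) for s in master.spawn(4)
    )
    n = cfg.n_subjects
    labels = rng_class.choice(cfg.n_classes, size=n, p=cfg.class_proportions)

    # within-class growth-factor deviations, optionally correlated across processes
    def dev_pair(sd: float) -> tuple[np.ndarray, np.ndarray]:
        if sd == 0:
            return np.zeros(n), np.zeros(n)
        z = rng_growth.multivariate_normal(
            [0, 0], [[1, cfg.cross_process_corr], [cfg.cross_process_corr, 1]], size=n
        )
        return sd * z[:, 0], sd * z[:, 1]

    u_a, u_d = dev_pair(cfg.intercept_sd)
    v_a, v_d = dev_pair(cfg.slope_sd)

    frames = []
    for w, t in zip(WAVES, TIME_SCORES):
        m_a = np.take(cfg.alpha_anx, labels) + np.take(cfg.beta_anx, labels) * t + u_a + v_a * t
        m_d = np.take(cfg.alpha_dep, labels) + np.take(cfg.beta_dep, labels) * t + u_d + v_d * t
        if cfg.residual_sd > 0:
            m_a = m_a + rng_growth.normal(0, cfg.residual_sd, n)
            m_d = m_d + rng_growth.normal(0, cfg.residual_sd, n)
        m_a = np.clip(m_a, 0.0, 3.0)
        m_d = np.clip(m_d, 0.0, 3.0)
        block = np.empty((n, 16))
        for j, off in enumerate(cfg.item_offsets_anx):
            block[:, j] = m_a + off
        for j, off in enumerate(cfg.item_offsets_dep):
            block[:, 7 + j] = m_d + off
        if cfg.item_sd > 0:
            block = block + rng_item.normal(0, cfg.item_sd, block.shape)
        scores = np.clip(np.round(np.clip(block, 0.0, 3.0)), 0, 3).astype(int)
        frames.append(
            pd.DataFrame(
                scores,
                columns=list(NODES),
                index=pd.MultiIndex.from_arrays(
                    [np.arange(n), np.full(n, w)], names=["subject_id", "wave"]
                ),
            )
        )
    items = pd.concat(frames).sort_index()
    covariates = _draw_covariates(cfg.covariates, n, rng_cov)
    return PanelDataset(items=items, covariates=covariates), labels


def generate_clpn_panel(
    truth: CLPNTruth,
    n_subjects: int,
    n_waves: int = 3,
    seed: int = 0,
    covariate_spec: dict[str, tuple] | None = None,
) -> tuple[BinaryPanel, CLPNTruth]:
    """Simulate binary symptom waves from a lagged logistic transition model.

    Wave 1 is drawn from the marginal prevalences ``p0``; each later wave is
    drawn symptom-wise from ``P(X_j = 1 | previous wave, covariates) =
    logistic(b_j + sum_i W[i, j] X_i + gamma_j . c)``.
    """
    master = np.random.SeedSequence(seed)
    rng_wave, rng_cov = (np.random.default_rng(s) for s in master.spawn(2))
    n = n_subjects
    cov = _draw_covariates(covariate_spec or {}, n, rng_cov)
    cov_term = 0.0
    if truth.covariate_effects is not None:
        if cov.shape[1] != truth.covariate_effects.shape[0]:
            raise ConfigError("covariate_effects rows must match covariate count")
        cov_term = cov.to_numpy(float) @ truth.covariate_effects

    waves = [(rng_wave.random((n, 16)) < truth.p0).astype(int)]
    for _ in range(n_waves - 1):
        logits = truth.intercepts + waves[-1] @ truth.weights + cov_term
        p = 1.0 / (1.0 + np.exp(-logits))
        waves.append((rng_wave.random((n, 16)) < p).astype(int))

    frames = [
        pd.DataFrame(
            x,
            columns=list(NODES),
            index=pd.MultiIndex.from_arrays(
                [np.arange(n), np.full(n, w + 1)], names=["subject_id", "wave"]
            ),
        )
        for w, x in enumerate(waves)
    ]
    panel = BinaryPanel(items=pd.concat(frames).sort_index(), covariates=cov)
    return panel, truth


def sparse_transition_truth(
    n_edges: int = 12,
    weight_choices: tuple[float, ...] = (0.8, 1.2),
    autoregressive: float = 1.0,
    intercept: float = -1.0,
    p0: float = 0.35,
    seed: int = 0,
    signs: tuple[int, ...] = (1,),
) -> CLPNTruth:
    """Random sparse ground-truth transition matrix for recovery studies.

    Plants ``n_edges`` off-diagonal cross-lagged effects with magnitudes
    drawn from *weight_choices* (signs from *signs*) on top of a constant
    autoregressive diagonal.
    """
    rng = np.random.default_rng(seed)
    W = np.zeros((16, 16))
    np.fill_diagonal(W, autoregressive)
    off = [(i, j) for i in range(16) for j in range(16) if i != j]
    picks = rng.choice(len(off), size=n_edges, replace=False)
    for k in picks:
        i, j = off[k]
        W[i, j] = rng.choice(weight_choices) * rng.choice(signs)
    return CLPNTruth(
        weights=W,
        intercepts=np.full(16, intercept),
        p0=np.full(16, p0),
    )
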