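import numpy as np
import pandas as pd
import pytest

from clpntraj.network import fit_clpn
from clpntraj.panel import NODES, PanelDataset, WAVES
from clpntraj.simulate import generate_clpn_panel, sparse_transition_truth


def make_panel(scores_by_subject: dict[int, list[list[int]]]) -> PanelDataset:
    """Build a PanelDataset from {subject: [wave1 16-vector, wave2, wave3]}."""
    rows, idx = [], []
    for sid, waves in scores_by_subject.items():
        for w, vec in zip(WAVES, waves):
            rows.append(vec)
            idx.append((sid, w))
    items = pd.DataFrame(
        rows, columns=list(NODES),
        index=pd.MultiIndex.from_tuples(idx, names=["subject_id", "wave"]),
    )
    return PanelDataset(items=items)


@pytest.fixture
def tiny_panel() -> PanelDataset:
    zero = [0] * 16
    ones = [1] * 16
    mid = [1] * 7 + [2] * 9
    return make_panel({1: [zero, ones, mid], 2: [mid, ones, zero]})


@pytest.fixture(scope="session")
def planted_truth():
    return sparse_transition_truth(n_edges=10, weight_choices=(1.2, 1.6), seed=21)


@pytest.fixture(scope="session")
def planted_panel(planted_truth):
    panel, _ = generate_clpn_panel(planted_truth, 1500, seed=22)
    return panel


@pytest.fixture(scope="session")
def planted_net(planted_panel):
    return fit_clpn(planted_panel, (1, 2), seed=0, folds=5, n_lambdas=20)


@pytest.fixture(scope="session")
def growth_y() -> np.ndarray:
    """n x 6 mean-score matrix from 3 well-separated trajectory classes."""
    rng = np.random.default_rng(7)
    n = 3000
    labels = rng.choice(3, n, p=[0.6, 0.3, 0.1])
    alphas = np.array([[0.4, 0.5], [1.3, 1.5], [2.2, 2.3]])
    betas = np.array([[0.02, 0.03], [0.25, 0.3], [0.05, 0.05]])
    t = np.arange(3)
    y = np.empty((n, 6))
    y[:, :3] = alphas[labels, :1] + betas[labels, :1] * t + rng.normal(0, 0.3, (n, 3))
    y[:, 3:] = alphas[labels, 1:] + betas[labels, 1:] * t + rng.normal(0, 0.3, (n, 3))
    return y
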