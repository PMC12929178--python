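"""Cross-lagged panel network estimation between two waves of binary symptoms.

A CLPN is estimated nodewise: for each of the 16 symptoms at wave t+1, an
L1-penalized (lasso) logistic regression on all 16 symptom presences at
wave t plus optional baseline covariates. The coefficient matrix B is
oriented [predictor, outcome]: ``B[i, j]`` is the penalized log-odds effect
of symptom i at t on symptom j at t+1; the diagonal holds autoregressive
effects. Edge weights are reported as odds ratios via ``exp(B)``, so a
zero coefficient maps to OR = 1 (no lagged association).

The per-outcome penalty is chosen by stratified K-fold cross-validated
deviance, either at the minimum ("min") or the one-standard-error rule
("1se"). Symptom predictors enter raw as 0/1 (common scale); covariates
are standardized to unit variance and left effectively unpenalized
(implemented by pre-scaling, the penalty-factor device). Expected
influence sums a node's incoming / outgoing cross-lagged coefficients on
the log-odds scale, excluding the autoregressive diagonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .panel import BinaryPanel

logger = logging.getLogger("clpntraj")

#: pre-scaling factor that makes the covariate penalty negligible
COV_SCALE = 1e3
#: intercepts are effectively unpenalized through liblinear's intercept scaling
INTERCEPT_SCALING = 1e3
MIN_SUBJECTS = 50
INFLUENTIAL_Z = 1.0


@dataclass
class CLPNetwork:
    """A fitted cross-lagged panel network.

    ``b`` is the 16 x 16 log-odds coefficient matrix, [predictor, outcome];
    ``covariate_coefs`` holds per-outcome covariate effects on the
    per-standard-deviation log-odds scale.
    """

    nodes: tuple[str, ...]
    b: np.ndarray
    intercepts: np.ndarray
    lambdas: np.ndarray
    wave_pair: tuple[int, int]
    n: int
    covariate_names: tuple[str, ...] = ()
    covariate_coefs: np.ndarray | None = None
    lambda_rule: str = "min"

    @property
    def or_matrix(self) -> np.ndarray:
        return np.exp(self.b)


def edge_or(net: CLPNetwork) -> np.ndarray:
    """Elementwise odds-ratio view of the coefficient matrix (exp(B))."""
    return np.exp(net.b)


try:  # sklearn >= 1.8 spells the lasso penalty via l1_ratio
    LogisticRegression(l1_ratio=1.0, solver="liblinear")
    _L1_KW = {"l1_ratio": 1.0}
except (TypeError, ValueError):  # pragma: no cover - older sklearn
    _L1_KW = {"penalty": "l1"}


def _fit_l1(
    X: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    model = LogisticRegression(
        C=C, solver="liblinear", intercept_scaling=INTERCEPT_SCALING,
        max_iter=500, tol=tol, random_state=0, **_L1_KW,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_[0], float(model.intercept_[0])


def _deviance(coef: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ coef + intercept
    return 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_pen: int, n_lambdas: int) -> np.ndarray:
    n = len(y)
    lam_max = np.abs(X[:, :n_pen].T @ (y - y.mean())).max() / n
    # absolute floor keeps near-constant outcomes from requesting an
    # effectively unpenalized (and very expensive) end of the path
    lam_lo = max(lam_max * 1e-3, 1e-4)
    if lam_lo >= lam_max:
        return np.array([max(lam_max, 1e-4)])
    return np.geomspace(lam_max, lam_lo, n_lambdas)


def fit_clpn(
    panel: BinaryPanel,
    wave_pair: tuple[int, int] = (1, 2),
    covariates: list[str] | None = None,
    penalty: str = "lasso",
    folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    n_lambdas: int = 30,
    fixed_lambdas: float | np.ndarray | None = None,
) -> CLPNetwork:
    """Fit the lagged network for one ordered wave pair.

    Parameters
    ----------
    panel : BinaryPanel
        Presence/absence panel with both waves of *wave_pair*.
    covariates : list of str
        Baseline covariate columns to adjust for (standardized, unpenalized).
    folds, seed, lambda_rule, n_lambdas
        Cross-validation settings for the per-outcome penalty; the fold
        split is stratified on the outcome and seeded.
    fixed_lambdas : float or length-16 array, optional
        Skip cross-validation and fit every outcome at the given penalty
        (0 recovers the unpenalized maximum-likelihood fit); used for
        bootstrap refits and penalty-path diagnostics.
    """
    if penalty != "lasso":
        raise ValueError("only the lasso penalty is supported")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    t0, t1 = wave_pair
    X_items = panel.wave(t0)
    Y_items = panel.wave(t1)
    nodes = tuple(X_items.columns)
    p = len(nodes)
    n = len(X_items)
    if n < MIN_SUBJECTS:
        raise ValueError(f"refusing to fit a network on n={n} < {MIN_SUBJECTS} subjects")

    X = X_items.to_numpy(float)
    cov_names = tuple(covariates or ())
    if cov_names:
        C_raw = panel.covariates.loc[X_items.index, list(cov_names)].to_numpy(float)
        sd = C_raw.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        C_std = (C_raw - C_raw.mean(axis=0)) / sd
        X = np.hstack([X, C_std * COV_SCALE])

    if fixed_lambdas is not None:
        fixed = np.broadcast_to(np.asarray(fixed_lambdas, float), (p,))
    else:
        fixed = None
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    B = np.zeros((p, p))
    intercepts = np.zeros(p)
    lambdas = np.zeros(p)
    cov_coefs = np.zeros((p, len(cov_names))) if cov_names else None
    for j, node in enumerate(nodes):
        y = Y_items[node].to_numpy(float)
        if y.min() == y.max():
            logger.warning("outcome %s constant at wave %d: zero column", node, t1)
            intercepts[j] = np.inf if y[0] == 1 else -np.inf
            continue
        if fixed is not None:
            lam = max(fixed[j], 0.0)
            C = 1e8 if lam == 0 else 1.0 / (lam * n)
        elif min(y.sum(), n - y.sum()) < folds:
            # too few minority cases to stratify: fall back to the strongest
            # penalty on the path rather than cross-validating
            logger.warning("outcome %s nearly constant at wave %d: lambda_max used",
                           node, t1)
            lam = float(_lambda_grid(X, y, p, n_lambdas)[0])
            C = 1.0 / (lam * n)
        else:
            grid = _lambda_grid(X, y, p, n_lambdas)
            splits = list(splitter.split(X, y))
            dev = np.zeros((folds, len(grid)))
            n_eval = 0
            for g, lam_g in enumerate(grid):
                for f, (tr, te) in enumerate(splits):
                    # fold fits only feed the deviance curve: looser tolerance
                    coef, icpt = _fit_l1(X[tr], y[tr], 1.0 / (lam_g * len(tr)), tol=1e-4)
                    dev[f, g] = _deviance(coef, icpt, X[te], y[te])
                n_eval = g + 1
                # early stop descending the path once the CV curve has clearly
                # passed its minimum (patience of 5 grid points, 1-se margin)
                mean_dev = dev[:, :n_eval].mean(axis=0)
                g_min = int(mean_dev.argmin())
                se_min = dev[:, g_min].std(ddof=1) / np.sqrt(folds)
                if g - g_min >= 5 and mean_dev[g] > mean_dev[g_min] + se_min:
                    break
            mean_dev = dev[:, :n_eval].mean(axis=0)
            g_min = int(mean_dev.argmin())
            if lambda_rule == "1se":
                se = dev[:, :n_eval].std(axis=0, ddof=1) / np.sqrt(folds)
                ok = mean_dev <= mean_dev[g_min] + se[g_min]
                g_min = int(np.flatnonzero(ok)[0])  # grid descends: first ok = largest lambda
            lam = float(grid[g_min])
            C = 1.0 / (lam * n)
        coef, icpt = _fit_l1(X, y, C)
        B[:, j] = coef[:p]
        intercepts[j] = icpt
        lambdas[j] = lam
        if cov_names:
            cov_coefs[j] = coef[p:] * COV_SCALE  # back to per-SD log-odds
    return CLPNetwork(
        nodes=nodes, b=B, intercepts=intercepts, lambdas=lambdas,
        wave_pair=wave_pair, n=n, covariate_names=cov_names,
        covariate_coefs=cov_coefs, lambda_rule=lambda_rule if fixed is None else "fixed",
    )


def density(net: CLPNetwork) -> tuple[int, int, float]:
    """(n_edges, n_cross_lagged, density) with density = edges / p^2.

    An estimated edge is any coefficient that survived the penalty
    (nonzero at machine precision); for 16 nodes the maximum is 256.
    """
    nz = net.b != 0.0
    n_edges = int(nz.sum())
    n_auto = int(np.diag(nz).sum())
    return n_edges, n_edges - n_auto, n_edges / net.b.size


def expected_influence(
    net: CLPNetwork, include_autoregressive: bool = False
) -> pd.DataFrame:
    """In/out expected influence per node, raw and standardized.

    Raw out-EI of node i sums row i of B over j != i (its outgoing
    cross-lagged log-odds effects); raw in-EI of node j sums column j over
    i != j. Standardized columns are z-scores across the 16 nodes (sample
    sd); a node is flagged influential when its standardized out-EI
    exceeds 1.
    """
    b = net.b.copy()
    if not include_autoregressive:
        np.fill_diagonal(b, 0.0)
    raw_out = b.sum(axis=1)
    raw_in = b.sum(axis=0)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=1)
        if sd == 0:
            logger.warning("degenerate centrality (zero spread); z-scores set to 0")
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    z_out = z(raw_out)
    return pd.DataFrame(
        {
            "raw_in": raw_in,
            "raw_out": raw_out,
            "z_in": z(raw_in),
            "z_out": z_out,
            "influential": z_out > INFLUENTIAL_Z,
        },
        index=pd.Index(net.nodes, name="node"),
    )


def network_frame(net: CLPNetwork, scale: str = "logodds") -> pd.DataFrame:
    """Adjacency as a labelled DataFrame (predictor rows x outcome columns)."""
    m = net.b if scale == "logodds" else edge_or(net)
    return pd.DataFrame(m, index=list(net.nodes), columns=list(net.nodes))


def plot_network(net: CLPNetwork, ax=None, or_threshold: float = 1.0):
    """Convenience directed-graph drawing of the OR matrix (thresholded)."""
    import matplotlib.pyplot as plt
    import networkx as nx

    ors = edge_or(net)
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for i, src in enumerate(net.nodes):
        for j, dst in enumerate(net.nodes):
            if i != j and ors[i, j] > or_threshold:
                g.add_edge(src, dst, weight=ors[i, j])
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    pos = nx.spring_layout(g, seed=1)
    widths = [g[u][v]["weight"] - or_threshold + 0.2 for u, v in g.edges]
    nx.draw_networkx(g, pos=pos, ax=ax, width=widths, node_color="#c6dbef",
                     font_size=7, arrowsize=8)
    ax.set_axis_off()
    return ax
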