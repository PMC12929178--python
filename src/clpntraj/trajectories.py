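"""Parallel-process growth modelling on wave-level mean scores.

Two related models over the 6-vector per subject (anxiety mean score at
waves 1-3, depression mean score at waves 1-3), with linear growth and
time scores fixed at 0, 1, 2:

* :func:`fit_pp_lgcm` - a single-population parallel-process latent growth
  curve model: y_i ~ MVN(Lambda mu, Lambda Psi Lambda' + Theta), where the
  four growth factors are (anxiety intercept, anxiety slope, depression
  intercept, depression slope), Psi their free covariance and Theta a
  diagonal residual matrix. The intercept-intercept and slope-slope
  correlations quantify co-development.
* :func:`fit_lcga` - latent-class growth analysis: a K-component mixture
  with class-specific growth-factor *means*, zero within-class
  growth-factor variance, and residual variances shared across classes
  (one per process). Fitted by EM with k-means-based multi-start.

Class enumeration (:func:`enumerate_classes`) compares K = 1..K_max on
AIC / BIC / sample-size-adjusted BIC, relative entropy, and a parametric
bootstrap likelihood ratio test (BLRT) of K-1 vs K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .simulate import TIME_SCORES

logger = logging.getLogger("clpntraj")

_Z = np.column_stack([np.ones(3), TIME_SCORES])        # 3x2 growth design
_PINV = np.linalg.inv(_Z.T @ _Z) @ _Z.T                # OLS projector onto (intercept, slope)
_LAMBDA = np.zeros((6, 4))
_LAMBDA[:3, :2] = _Z
_LAMBDA[3:, 2:] = _Z

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-10


class FitError(RuntimeError):
    pass


def growth_matrix(scores: pd.DataFrame) -> np.ndarray:
    """Stack a score table into the n x 6 matrix [A1 A2 A3 D1 D2 D3]."""
    a = scores["gad_mean"].unstack("wave").to_numpy(float)
    d = scores["phq_mean"].unstack("wave").to_numpy(float)
    return np.hstack([a, d])


def _as_matrix(scores) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        return growth_matrix(scores)
    y = np.asarray(scores, float)
    if y.ndim != 2 or y.shape[1] != 6:
        raise ValueError("expected an n x 6 growth matrix or a score table")
    return y


# ---------------------------------------------------------------------------
# Parallel-process latent growth curve model (single population)
# ---------------------------------------------------------------------------

@dataclass
class PPLGCMFit:
    mu: np.ndarray                 # (alpha_A, beta_A, alpha_D, beta_D)
    psi: np.ndarray                # 4x4 growth-factor covariance
    theta: np.ndarray              # 6 residual variances
    loglik: float
    n: int
    t_stat: float                  # LR statistic vs the saturated model
    df: int
    baseline_t: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    r_intercept: float
    r_slope: float
    converged: bool


def _pack(chol: np.ndarray, log_theta: np.ndarray) -> np.ndarray:
    return np.concatenate([chol[np.tril_indices(4)], log_theta])


def _unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = np.zeros((4, 4))
    L[np.tril_indices(4)] = params[:10]
    return L, np.exp(params[10:])


def fit_pp_lgcm(scores, max_restarts: int = 3, seed: int = 0) -> PPLGCMFit:
    """Maximum-likelihood fit of the parallel-process linear growth model.

    Psi is parameterized through its Cholesky factor (hence positive
    semidefinite by construction) and residual variances through their
    logs. The mean vector is profiled out by GLS at each step. Fit indices
    use the likelihood-ratio statistic T against the saturated model and an
    independence baseline (free means, diagonal covariance).
    """
    y = _as_matrix(scores)
    n = y.shape[0]
    if n < 10:
        raise FitError("need at least 10 subjects")
    ybar = y.mean(axis=0)
    S = np.cov(y, rowvar=False, bias=True)
    eig_min = np.linalg.eigvalsh(S).min()
    if eig_min < 1e-12:
        logger.warning("near-singular sample covariance; adding 1e-10 jitter")
        S = S + 1e-10 * np.eye(6)

    sign, logdet_S = np.linalg.slogdet(S)
    ll_sat = -0.5 * n * (6 * _LOG2PI + logdet_S + 6)

    def neg_ll(params: np.ndarray) -> float:
        L, theta = _unpack(params)
        psi = L @ L.T
        sigma = _LAMBDA @ psi @ _LAMBDA.T + np.diag(theta)
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diag(c)).sum()
        sinv = np.linalg.inv(sigma)
        # GLS-profiled mean
        A = _LAMBDA.T @ sinv
        mu = np.linalg.solve(A @ _LAMBDA, A @ ybar)
        d = ybar - _LAMBDA @ mu
        val = logdet + np.trace(sinv @ S) + d @ sinv @ d
        return 0.5 * n * (6 * _LOG2PI + val)

    # starting values from per-subject least-squares growth factors
    b = np.hstack([y[:, :3] @ _PINV.T, y[:, 3:] @ _PINV.T])
    psi0 = np.cov(b, rowvar=False)
    resid = np.hstack([y[:, :3] - b[:, :2] @ _Z.T, y[:, 3:] - b[:, 2:] @ _Z.T])
    theta0 = np.maximum(resid.var(axis=0), 1e-4)
    psi0 = psi0 - np.diag([theta0[:3].mean() * v for v in np.diag(np.linalg.inv(_Z.T @ _Z))] * 2)
    w, V = np.linalg.eigh((psi0 + psi0.T) / 2)
    psi0 = (V * np.maximum(w, 1e-4)) @ V.T

    rng = np.random.default_rng(seed)
    best = None
    x0 = _pack(np.linalg.cholesky(psi0), np.log(theta0))
    for attempt in range(max_restarts):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.05, x0.size)
        res = optimize.minimize(neg_ll, start, method="L-BFGS-B",
                                bounds=[(None, None)] * 10 + [(-18.0, 6.0)] * 6,
                                options={"maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise FitError("PP-LGCM optimisation failed")

    L, theta = _unpack(best.x)
    psi = L @ L.T
    sigma = _LAMBDA @ psi @ _LAMBDA.T + np.diag(theta)
    sinv = np.linalg.inv(sigma)
    A = _LAMBDA.T @ sinv
    mu = np.linalg.solve(A @ _LAMBDA, A @ ybar)
    ll = -float(best.fun)

    t_stat = max(2.0 * (ll_sat - ll), 0.0)
    df = 27 - 20  # saturated (6 means + 21 covariances) minus (4 mu + 10 Psi + 6 Theta)
    ll_base = -0.5 * n * (6 * _LOG2PI + np.log(np.diag(S)).sum() + 6)
    t0 = max(2.0 * (ll_sat - ll_base), 0.0)
    df0 = 27 - 12
    rmsea = float(np.sqrt(max(t_stat - df, 0.0) / (df * max(n - 1, 1))))
    denom = max(t0 - df0, t_stat - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(t_stat - df, 0.0) / denom
    if t0 / df0 > 1.0:
        tli = ((t0 / df0) - (t_stat / df)) / ((t0 / df0) - 1.0)
    else:
        tli = 1.0
    tli = min(tli, 1.0)

    sd = np.sqrt(np.maximum(np.diag(psi), _VAR_FLOOR))
    r_i = float(psi[0, 2] / (sd[0] * sd[2]))
    r_s = float(psi[1, 3] / (sd[1] * sd[3]))
    return PPLGCMFit(
        mu=mu, psi=psi, theta=theta, loglik=ll, n=n,
        t_stat=float(t_stat), df=df, baseline_t=float(t0), baseline_df=df0,
        cfi=float(cfi), tli=float(tli), rmsea=rmsea,
        r_intercept=np.clip(r_i, -1, 1), r_slope=np.clip(r_s, -1, 1),
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# Latent-class growth analysis (EM)
# ---------------------------------------------------------------------------

@dataclass
class ClassSolution:
    """A fitted K-class growth mixture, canonicalized by ascending severity.

    ``means`` is K x 4 with columns (alpha_A, beta_A, alpha_D, beta_D);
    ``sigma2`` the two shared residual variances (anxiety, depression).
    """

    k: int
    pi: np.ndarray
    means: np.ndarray
    sigma2: np.ndarray
    loglik: float
    n: int
    n_params: int
    aic: float
    bic: float
    abic: float
    entropy: float            # NaN for K = 1
    posteriors: np.ndarray    # n x K
    assignments: np.ndarray
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    blrt_p: float | None = None


def relative_entropy(posteriors: np.ndarray) -> float:
    """Classification quality E_K = 1 + sum p log p / (n log K).

    1 for perfectly crisp (0/1) posteriors, 0 for uninformative (uniform)
    posteriors; defined for K >= 2.
    """
    post = np.asarray(posteriors, float)
    n, k = post.shape
    if k < 2:
        raise ValueError("relative entropy requires K >= 2")
    plogp = np.where(post > 0, post * np.log(np.maximum(post, 1e-300)), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(k)))


def _fit_single_class(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form ML for K = 1: OLS growth means + pooled residual variances."""
    n = y.shape[0]
    mbar = y.mean(axis=0)
    theta = np.concatenate([_PINV @ mbar[:3], _PINV @ mbar[3:]])
    fit = np.concatenate([_Z @ theta[:2], _Z @ theta[2:]])
    resid2 = (y - fit) ** 2
    s2 = np.array([resid2[:, :3].sum() / (3 * n), resid2[:, 3:].sum() / (3 * n)])
    ld = _class_logdens(y, theta[None, :], np.maximum(s2, _VAR_FLOOR))[:, 0]
    return theta, s2, float(ld.sum())


def _class_logdens(y: np.ndarray, means: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """n x K log density of the diagonal-normal class model."""
    sA, sD = sigma2
    out = np.empty((y.shape[0], means.shape[0]))
    for k, th in enumerate(means):
        ra = y[:, :3] - _Z @ th[:2]
        rd = y[:, 3:] - _Z @ th[2:]
        out[:, k] = -0.5 * (
            (ra * ra).sum(axis=1) / sA + (rd * rd).sum(axis=1) / sD
            + 3 * (np.log(sA) + np.log(sD)) + 6 * _LOG2PI
        )
    return out


def _em(y, pi0, means0, sigma0, tol, max_iter):
    n = y.shape[0]
    K = len(pi0)
    pi, means, sigma2 = pi0.copy(), means0.copy(), sigma0.copy()
    trace = []
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        ld = _class_logdens(y, means, sigma2) + np.log(pi)
        ll_i = logsumexp(ld, axis=1)
        ll = float(ll_i.sum())
        trace.append(ll)
        post = np.exp(ld - ll_i[:, None])
        w = post.sum(axis=0)
        if w.min() < 1.0:  # empty class: degenerate start
            return None
        pi = w / n
        for k in range(K):
            wk = post[:, k]
            means[k, :2] = _PINV @ (wk @ y[:, :3] / w[k])
            means[k, 2:] = _PINV @ (wk @ y[:, 3:] / w[k])
        ra2 = np.zeros(2)
        for k in range(K):
            fa = _Z @ means[k, :2]
            fd = _Z @ means[k, 2:]
            ra2[0] += post[:, k] @ ((y[:, :3] - fa) ** 2).sum(axis=1)
            ra2[1] += post[:, k] @ ((y[:, 3:] - fd) ** 2).sum(axis=1)
        sigma2 = np.maximum(ra2 / (3 * n), _VAR_FLOOR)
        if ll - ll_prev < tol * max(abs(ll), 1.0) and it > 0:
            converged = True
            break
        ll_prev = ll
    # final E-step quantities at the last parameter values
    ld = _class_logdens(y, means, sigma2) + np.log(pi)
    ll_i = logsumexp(ld, axis=1)
    post = np.exp(ld - ll_i[:, None])
    return float(ll_i.sum()), pi, means, sigma2, post, converged, it + 1, np.array(trace)


def _inits(y, K, n_restarts, rng):
    """k-means on per-subject least-squares growth factors, then random starts."""
    b = np.hstack([y[:, :3] @ _PINV.T, y[:, 3:] @ _PINV.T])
    resid = np.hstack([y[:, :3] - b[:, :2] @ _Z.T, y[:, 3:] - b[:, 2:] @ _Z.T])
    s2 = np.array([max(resid[:, :3].var(), 1e-3) + b[:, :2].var() / 4,
                   max(resid[:, 3:].var(), 1e-3) + b[:, 2:].var() / 4])
    km = KMeans(n_clusters=K, n_init=2, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(b)
    counts = np.bincount(labels, minlength=K).astype(float)
    starts = [(np.maximum(counts, 1.0) / counts.sum(), km.cluster_centers_.copy(), s2)]
    for _ in range(max(n_restarts - 1, 0)):
        centers = b[rng.choice(len(b), K, replace=False)]
        starts.append((np.full(K, 1.0 / K), centers, s2))
    return starts


def _split_inits(sol: "ClassSolution") -> list:
    """Starts for K classes built by splitting each class of a (K-1)-class
    solution along the intercept axis; finds small classes nested in a
    bigger one far more reliably than k-means alone."""
    starts = []
    delta = np.sqrt(sol.sigma2)
    for j in range(sol.k):
        means0 = np.insert(sol.means, j, sol.means[j], axis=0)
        means0[j, [0, 2]] -= delta
        means0[j + 1, [0, 2]] += delta
        pi0 = np.insert(sol.pi, j, sol.pi[j] / 2)
        pi0[j + 1] /= 2
        starts.append((pi0 / pi0.sum(), means0, sol.sigma2.copy()))
    return starts


def fit_lcga(
    scores,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
    init_solution: "ClassSolution | None" = None,
) -> ClassSolution:
    """EM fit of the K-class growth mixture on wave-level mean scores.

    Multi-start: a k-means initialisation from per-subject least-squares
    (intercept, slope) features plus ``n_restarts - 1`` random-subject
    starts; when a fitted (K-1)-class solution is supplied via
    *init_solution*, class-splitting starts are added. The best
    observed-data log-likelihood wins. Classes are relabelled by ascending
    overall severity (alpha_A + alpha_D).
    """
    y = _as_matrix(scores)
    n = y.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        theta, s2, ll = _fit_single_class(y)
        best = (ll, np.ones(1), theta[None, :], np.maximum(s2, _VAR_FLOOR),
                np.ones((n, 1)), True, 1, np.array([ll]))
    else:
        rng = np.random.default_rng(seed)
        starts = _inits(y, k, n_restarts, rng)
        if init_solution is not None and init_solution.k == k - 1:
            starts += _split_inits(init_solution)
        best = None
        for pi0, means0, s0 in starts:
            out = _em(y, pi0, means0, s0, tol, max_iter)
            if out is None:
                continue
            if best is None or out[0] > best[0]:
                best = out
        if best is None:
            raise FitError(f"all {n_restarts} restarts degenerated for K={k}")

    ll, pi, means, sigma2, post, converged, n_iter, trace = best
    order = np.argsort(means[:, 0] + means[:, 2], kind="stable")
    pi, means, post = pi[order], means[order], post[:, order]

    q = 4 * k + 2 + (k - 1)
    aic = -2 * ll + 2 * q
    bic = -2 * ll + q * np.log(n)
    abic = -2 * ll + q * np.log((n + 2) / 24.0)
    entropy = np.nan if k == 1 else relative_entropy(post)
    return ClassSolution(
        k=k, pi=pi, means=means, sigma2=sigma2, loglik=ll, n=n, n_params=q,
        aic=float(aic), bic=float(bic), abic=float(abic), entropy=float(entropy),
        posteriors=post, assignments=post.argmax(axis=1), converged=converged,
        n_iter=n_iter, loglik_trace=trace,
    )


def simulate_from_solution(sol: ClassSolution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an n x 6 growth matrix from a fitted class solution."""
    labels = rng.choice(sol.k, size=n, p=sol.pi)
    y = np.empty((n, 6))
    for k in range(sol.k):
        m = labels == k
        y[m, :3] = _Z @ sol.means[k, :2]
        y[m, 3:] = _Z @ sol.means[k, 2:]
    y[:, :3] += rng.normal(0, np.sqrt(sol.sigma2[0]), (n, 3))
    y[:, 3:] += rng.normal(0, np.sqrt(sol.sigma2[1]), (n, 3))
    return y


def blrt(
    scores,
    k: int,
    reps: int = 99,
    seed: int = 0,
    n_restarts: int = 4,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[float, float]:
    """Parametric bootstrap LRT of K-1 vs K classes.

    Simulates *reps* datasets from the fitted (K-1)-class model, refits
    both models on each, and returns (LR_observed, p) with
    p = (1 + #{LR_b >= LR_obs}) / (reps + 1).
    """
    y = _as_matrix(scores)
    rng = np.random.default_rng(seed)
    small = fit_lcga(y, k - 1, n_restarts=n_restarts, seed=int(rng.integers(2**31)),
                     tol=tol, max_iter=max_iter)
    big = fit_lcga(y, k, n_restarts=n_restarts, seed=int(rng.integers(2**31)),
                   tol=tol, max_iter=max_iter)
    lr_obs = max(2.0 * (big.loglik - small.loglik), 0.0)
    exceed = 0
    for _ in range(reps):
        yb = simulate_from_solution(small, y.shape[0], rng)
        s = fit_lcga(yb, k - 1, n_restarts=n_restarts, seed=int(rng.integers(2**31)),
                     tol=tol, max_iter=max_iter)
        g = fit_lcga(yb, k, n_restarts=n_restarts, seed=int(rng.integers(2**31)),
                     tol=tol, max_iter=max_iter)
        if max(2.0 * (g.loglik - s.loglik), 0.0) >= lr_obs:
            exceed += 1
    return lr_obs, (1 + exceed) / (reps + 1)


def enumerate_classes(
    scores,
    k_max: int = 5,
    n_restarts: int = 10,
    seed: int = 0,
    blrt_reps: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, dict[int, ClassSolution]]:
    """Fit K = 1..k_max and tabulate AIC, BIC, aBIC, entropy, BLRT p, pi.

    The BLRT for each K >= 2 (against K-1) is run only when
    ``blrt_reps > 0``; it dominates runtime.
    """
    y = _as_matrix(scores)
    rng = np.random.default_rng(seed)
    fits: dict[int, ClassSolution] = {}
    rows = []
    for k in range(1, k_max + 1):
        sol = fit_lcga(y, k, n_restarts=n_restarts, seed=int(rng.integers(2**31)),
                       tol=tol, max_iter=max_iter, init_solution=fits.get(k - 1))
        if blrt_reps > 0 and k >= 2:
            _, sol.blrt_p = blrt(y, k, reps=blrt_reps, seed=int(rng.integers(2**31)))
        fits[k] = sol
        rows.append(
            {
                "K": k, "loglik": sol.loglik, "AIC": sol.aic, "BIC": sol.bic,
                "aBIC": sol.abic, "entropy": sol.entropy, "BLRT_p": sol.blrt_p,
                "proportions": "/".join(f"{p:.3f}" for p in sol.pi),
            }
        )
    return pd.DataFrame(rows).set_index("K"), fits
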