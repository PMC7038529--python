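"""Parametric whole-genome regression: GBLUP and Bayes B.

GBLUP fits y = 1 mu + g + e with g ~ N(0, G sigma2_g), where the genomic
relationship matrix G = ZZ'/m is built from centered and standardized
genotypes.  Two modes are offered: a closed form at a fixed variance
ratio lambda = sigma2_e / sigma2_g (exactly equivalent to ridge
regression on markers with penalty m*lambda), and a Gibbs sampler with
scaled-inverse-chi-square priors on both variances.

Bayes B is a marker-effect mixture model: each marker has a null effect
with prior probability pi, or an effect with marker-specific variance
sigma2_bj ~ scaled-inv-chi2(nu, s2), which marginally gives the t-type
prior.  Inference is single-site Gibbs with an exact (Metropolis-free)
inclusion update from the marginal likelihood ratio.  Prediction for new
individuals is mu_hat + X_test b_hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotypes import GenotypeMatrix

__all__ = [
    "GRM",
    "GBLUPConfig",
    "BayesBConfig",
    "PosteriorSummary",
    "FittedGBLUP",
    "FittedBayesB",
    "compute_grm",
    "fit_gblup",
    "fit_bayesb",
]


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    matrix: np.ndarray
    n_markers: int
    samples: list[str]


def standardize_markers(X: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
    """Center and standardize 0/1/2 codes: z = (x - 2p) / sqrt(2 p q)."""
    X = np.asarray(X, dtype=np.float64)
    if p is None:
        p = X.mean(axis=0) / 2.0
    q = 1.0 - p
    denom = np.sqrt(2.0 * p * q)
    if np.any(denom == 0):
        raise ValueError("monomorphic marker: zero-variance column cannot be standardized")
    return (X - 2.0 * p) / denom


def compute_grm(g: GenotypeMatrix | np.ndarray, samples: list[str] | None = None) -> GRM:
    """G = ZZ'/m from standardized genotypes.

    Average diagonal is ~1 for markers in Hardy-Weinberg proportions.
    """
    if isinstance(g, GenotypeMatrix):
        X = g.imputed()
        samples = list(g.samples)
    else:
        X = np.asarray(g, dtype=np.float64)
        samples = samples or [f"ind{i}" for i in range(X.shape[0])]
    Z = standardize_markers(X)
    m = X.shape[1]
    return GRM(matrix=(Z @ Z.T) / m, n_markers=m, samples=samples)


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------


@dataclass
class GBLUPConfig:
    mode: str = "closed_form"
    h2: float = 0.30  # used to fix lambda = (1 - h2)/h2 in closed form / init gibbs
    chain: tuple[int, int, int] = (6000, 1000, 5)  # (n_iter, burn_in, thin)
    jitter: float = 1e-8
    nu_prior: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("closed_form", "gibbs"):
            raise ValueError("mode must be 'closed_form' or 'gibbs'")
        n_iter, burn_in, _ = self.chain
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")


@dataclass
class PosteriorSummary:
    means: dict[str, float | np.ndarray]
    sds: dict[str, float | np.ndarray]
    n_samples: int
    inclusion: np.ndarray | None = None


@dataclass
class FittedGBLUP:
    """Fitted GBLUP handle; predicts via the training-block conditional."""

    mu: float
    g_train: np.ndarray  # BLUP/posterior-mean genomic values of training individuals
    train_ids: list[str]
    grm: GRM
    lam: float
    jitter: float
    posterior: PosteriorSummary | None = None
    _train_pos: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _alpha: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def predict(self, sample_ids: list[str]) -> np.ndarray:
        """g_hat_test = G_test,train (G_tt + lambda I)^-1 (y - 1 mu), plus mu."""
        index = {s: i for i, s in enumerate(self.grm.samples)}
        try:
            rows = np.array([index[s] for s in sample_ids])
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not present in the GRM") from None
        G_xt = self.grm.matrix[np.ix_(rows, self._train_pos)]
        return self.mu + G_xt @ self._alpha


def fit_gblup(
    y_train: np.ndarray,
    grm: GRM,
    config: GBLUPConfig | None = None,
    train_ids: list[str] | None = None,
) -> FittedGBLUP:
    """Fit GBLUP on the training block of a GRM.

    Closed form: with lambda = sigma2_e/sigma2_g fixed from ``config.h2``,
    solves mu by GLS and g = G_tt (G_tt + lambda I)^-1 (y - 1 mu).  Gibbs:
    samples mu, g, sigma2_g, sigma2_e with scaled-inv-chi2 priors and
    returns posterior means (the prediction uses the posterior-mean
    variance ratio).
    """
    config = config or GBLUPConfig()
    y = np.asarray(y_train, dtype=np.float64)
    if train_ids is None:
        if len(y) != len(grm.samples):
            raise ValueError("train_ids required when y does not cover all GRM samples")
        train_ids = list(grm.samples)
    index = {s: i for i, s in enumerate(grm.samples)}
    rows = np.array([index[s] for s in train_ids])
    G = grm.matrix[np.ix_(rows, rows)] + config.jitter * np.eye(len(rows))

    if config.mode == "closed_form":
        lam = (1.0 - config.h2) / config.h2
        mu, g_hat, alpha = _gblup_closed_form(y, G, lam)
        posterior = None
    else:
        lam, mu, g_hat, alpha, posterior = _gblup_gibbs(y, G, config)

    fitted = FittedGBLUP(
        mu=mu, g_train=g_hat, train_ids=list(train_ids), grm=grm, lam=lam,
        jitter=config.jitter, posterior=posterior,
    )
    fitted._train_pos = rows
    fitted._alpha = alpha
    return fitted


def _gblup_closed_form(y: np.ndarray, G: np.ndarray, lam: float):
    n = len(y)
    C = G + lam * np.eye(n)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    Cinv_y = np.linalg.solve(C, y)
    mu = float(np.ones(n) @ Cinv_y / (np.ones(n) @ Cinv_1))
    alpha = np.linalg.solve(C, y - mu)
    g_hat = G @ alpha
    return mu, g_hat, alpha


def _gblup_gibbs(y: np.ndarray, G: np.ndarray, config: GBLUPConfig):
    """Gibbs sampler in the eigenbasis of G: g = U a with a ~ N(0, D sigma2_g)."""
    rng = np.random.default_rng(config.seed)
    n = len(y)
    n_iter, burn_in, thin = config.chain
    w, U = np.linalg.eigh(G)
    w = np.maximum(w, config.jitter)
    yU = U.T @ y
    oneU = U.T @ np.ones(n)

    vy = y.var()
    sigma2_g = max(config.h2 * vy, 1e-6)
    sigma2_e = max((1.0 - config.h2) * vy, 1e-6)
    nu = config.nu_prior
    S_g, S_e = sigma2_g, sigma2_e
    mu = float(y.mean())
    a = np.zeros(n)

    keep_mu = keep_g = keep_e = 0.0
    g_sum = np.zeros(n)
    kept = 0
    for it in range(n_iter):
        # a | rest: diagonal posterior in the eigenbasis
        prec = 1.0 / sigma2_e + 1.0 / (w * sigma2_g)
        mean = (yU - mu * oneU) / (sigma2_e * prec)
        a = mean + rng.standard_normal(n) / np.sqrt(prec)
        # mu | rest
        resid_mean = float((yU - a) @ oneU) / n
        mu = rng.normal(resid_mean, np.sqrt(sigma2_e / n))
        # variances | rest (scaled-inv-chi2)
        ss_g = float(a @ (a / w))
        sigma2_g = _sample_scaled_inv_chi2(rng, nu + n, (nu * S_g + ss_g) / (nu + n))
        e = yU - a - mu * oneU
        ss_e = float(e @ e)
        sigma2_e = _sample_scaled_inv_chi2(rng, nu + n, (nu * S_e + ss_e) / (nu + n))
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            keep_mu += mu
            keep_g += sigma2_g
            keep_e += sigma2_e
            g_sum += U @ a
    mu_hat = keep_mu / kept
    sg, se = keep_g / kept, keep_e / kept
    lam = se / sg
    # prediction path uses the closed form at the posterior-mean ratio
    _, g_hat, alpha = _gblup_closed_form(y, G, lam)
    posterior = PosteriorSummary(
        means={"mu": mu_hat, "sigma2_g": sg, "sigma2_e": se, "g": g_sum / kept},
        sds={},
        n_samples=kept,
    )
    return lam, mu_hat, g_hat, alpha, posterior


def _sample_scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


# ---------------------------------------------------------------------------
# Bayes B
# ---------------------------------------------------------------------------


@dataclass
class BayesBConfig:
    pi: float = 0.95
    nu: float = 5.0
    s2: float | None = None  # default solved from var(y) and mean marker variance
    chain: tuple[int, int, int] = (6000, 1000, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must be in [0, 1)")
        if self.nu <= 2.0:
            raise ValueError("nu must exceed 2 for a finite prior variance")
        n_iter, burn_in, _ = self.chain
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class FittedBayesB:
    mu: float
    b: np.ndarray  # posterior-mean marker effects
    inclusion: np.ndarray  # per-marker posterior inclusion frequency
    sigma2_e: float
    posterior: PosteriorSummary
    config: BayesBConfig

    def predict(self, X_test: np.ndarray) -> np.ndarray:
        X_test = np.asarray(X_test, dtype=np.float64)
        if X_test.shape[1] != len(self.b):
            raise ValueError(
                f"X_test has {X_test.shape[1]} columns; model was trained on {len(self.b)}"
            )
        return self.mu + X_test @ self.b

    def marker_table(self, marker_ids: list[str] | None = None):
        """Per-marker posterior summary (effect mean, inclusion frequency)."""
        import pandas as pd

        ids = marker_ids or [f"m{j}" for j in range(len(self.b))]
        if len(ids) != len(self.b):
            raise ValueError("marker_ids length does not match the fitted markers")
        return pd.DataFrame(
            {"marker": ids, "effect_mean": self.b, "inclusion_freq": self.inclusion}
        )


def default_prior_scale(y: np.ndarray, X: np.ndarray, pi: float, nu: float) -> float:
    """Prior scale s2 such that the implied genetic variance is half of var(y).

    Marginally E[b_j^2] = nu s2 / (nu - 2) for an included marker, so the
    prior genetic variance is (1 - pi) * sum_j var(x_j) * nu s2/(nu - 2).
    """
    sum_vx = float(np.var(X, axis=0).sum())
    if sum_vx <= 0:
        raise ValueError("all markers have zero variance")
    return 0.5 * float(np.var(y)) * (nu - 2.0) / (nu * max(1.0 - pi, 1e-12) * sum_vx)


@njit(cache=False)
def _bayesb_kernel(X, y, pi, nu, s2, n_iter, burn_in, thin, seed, nu_e, S_e):  # pragma: no cover
    n, m = X.shape
    np.random.seed(seed)
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    mu = y.mean()
    b = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    sigma2_b = np.full(m, nu * s2 / (nu - 2.0))
    vy = y.var()
    sigma2_e = vy * 0.5 if vy > 0 else 1.0
    e = y - mu  # residual with all b = 0

    b_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    se_sum = 0.0
    kept = 0
    log_prior_ratio = np.log(1.0 - pi) - np.log(pi) if pi > 0.0 else 0.0

    for it in range(n_iter):
        # mu | rest
        mean_e = 0.0
        for i in range(n):
            mean_e += e[i]
        mean_e /= n
        mu_new = mu + mean_e + np.random.normal() * np.sqrt(sigma2_e / n)
        shift = mu_new - mu
        for i in range(n):  # keep e = y - mu - Xb consistent
            e[i] -= shift
        mu = mu_new

        for j in range(m):
            c = xtx[j]
            if c == 0.0:
                continue
            # rhs with marker j removed from the residual
            r = 0.0
            for i in range(n):
                r += X[i, j] * e[i]
            r += c * b[j]
            # update sigma2_b[j]: posterior if included, prior draw if not
            if delta[j] == 1:
                df = nu + 1.0
                sc = (nu * s2 + b[j] * b[j]) / df
            else:
                df = nu
                sc = s2
            sigma2_b[j] = df * sc / np.random.chisquare(df)
            v = sigma2_b[j]
            # marginal likelihood ratio for inclusion
            var1 = c * c * v + c * sigma2_e
            var0 = c * sigma2_e
            if pi <= 0.0:
                p1 = 1.0
            else:
                log_bf = 0.5 * np.log(var0 / var1) + 0.5 * r * r * (1.0 / var0 - 1.0 / var1)
                t = log_prior_ratio + log_bf
                if t > 35.0:
                    p1 = 1.0
                elif t < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-t))
            b_old = b[j]
            if np.random.random() < p1:
                post_var = sigma2_e / (c + sigma2_e / v)
                post_mean = r / (c + sigma2_e / v)
                b_new = post_mean + np.random.normal() * np.sqrt(post_var)
                delta[j] = 1
            else:
                b_new = 0.0
                delta[j] = 0
            diff = b_new - b_old
            if diff != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * diff
                b[j] = b_new

        # sigma2_e | rest
        ss = 0.0
        for i in range(n):
            ss += e[i] * e[i]
        df_e = nu_e + n
        sigma2_e = df_e * ((nu_e * S_e + ss) / df_e) / np.random.chisquare(df_e)

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            mu_sum += mu
            se_sum += sigma2_e
            for j in range(m):
                b_sum[j] += b[j]
                incl_sum[j] += delta[j]
    return mu_sum / kept, b_sum / kept, incl_sum / kept, se_sum / kept, kept


def fit_bayesb(
    y_train: np.ndarray,
    X_train: np.ndarray,
    config: BayesBConfig | None = None,
) -> FittedBayesB:
    """Single-site Gibbs sampler for the Bayes B mixture model."""
    config = config or BayesBConfig()
    y = np.asarray(y_train, dtype=np.float64)
    X = np.ascontiguousarray(np.asarray(X_train, dtype=np.float64))
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X_train must be 2-D with one row per phenotype")
    if len(y) < 10:
        raise ValueError("Bayes B needs at least 10 training records")
    s2 = config.s2 if config.s2 is not None else default_prior_scale(y, X, config.pi, config.nu)
    n_iter, burn_in, thin = config.chain
    vy = float(np.var(y))
    mu, b, incl, sigma2_e, kept = _bayesb_kernel(
        X, y, config.pi, config.nu, s2, n_iter, burn_in, thin,
        config.seed % (2**31), 4.0, vy * 0.5 if vy > 0 else 1.0,
    )
    if vy > 0 and sigma2_e > 10.0 * vy:
        raise RuntimeError(f"divergent residual variance: {sigma2_e:.3g} > 10 var(y)")
    posterior = PosteriorSummary(
        means={"mu": float(mu), "b": b, "sigma2_e": float(sigma2_e)},
        sds={},
        n_samples=int(kept),
        inclusion=incl,
    )
    return FittedBayesB(
        mu=float(mu), b=b, inclusion=incl, sigma2_e=float(sigma2_e),
        posterior=posterior, config=config,
    )
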