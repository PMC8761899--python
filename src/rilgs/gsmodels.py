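"""Whole-genome regression models for genomic selection.

All four models regress line values on centered allele doses of all
markers simultaneously:

* rrBLUP — ridge regression with the penalty ``lambda = sigma_e^2 /
  sigma_u^2`` estimated by restricted maximum likelihood through a
  spectral decomposition of the marker covariance; equivalent to GBLUP
  with a marker-derived kinship.
* Bayesian A — per-marker effect variances with scaled-inverse-chi^2
  priors (heavy-tailed effect distribution).
* Bayesian C — common effect variance plus a per-marker inclusion
  indicator with prior inclusion probability pi (sampled, Beta prior).
* Bayesian Lasso — double-exponential effect prior via the
  exponential-mixture representation (Park & Casella parameterization).

Markers are centered by training-column means and not scaled, so effects
are in allele-dose units. Matrices must be complete: imputation is an
explicit upstream step, never silently applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

LAMBDA_BOUNDS = (1e-5, 1e5)


@dataclass
class GSModelFit:
    """Fitted whole-genome regression: intercept + per-marker effects."""

    model: str
    intercept: float
    effects: np.ndarray
    col_means: np.ndarray
    hyper: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    marker_ids: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "intercept": self.intercept,
            "effects": self.effects.tolist(),
            "col_means": self.col_means.tolist(),
            "hyper": {k: _jsonable(v) for k, v in self.hyper.items()},
            "diagnostics": {k: _jsonable(v) for k, v in self.diagnostics.items()},
        }


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _check_xy(
    X: np.ndarray, y: np.ndarray, allow_constant: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError("X must be (n_lines, n_markers) matching y")
    if np.isnan(X).any():
        raise ValueError("genotype matrix contains missing values; impute first")
    if np.isnan(y).any():
        raise ValueError("phenotypes contain missing values")
    if y.std() == 0 and not allow_constant:
        raise ValueError("phenotypes have zero variance")
    return X, y


# ---------------------------------------------------------------------------
# rrBLUP
# ---------------------------------------------------------------------------


def fit_rrblup(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    marker_ids: np.ndarray | None = None,
) -> GSModelFit:
    """Ridge-regression BLUP with REML-estimated penalty.

    Solves ``u = Xc' (Xc Xc' + lambda I)^-1 (y - mu)`` in kinship form
    (always efficient when markers outnumber lines); ``lambda`` is the
    REML estimate of sigma_e^2/sigma_u^2 unless given. The intercept is
    the GLS mean under the fitted covariance.
    """
    X, y = _check_xy(X, y)
    n = len(y)
    col_means = X.mean(axis=0)
    Xc = X - col_means
    K = Xc @ Xc.T
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    ones = np.ones(n)
    yt = U.T @ y
    ot = U.T @ ones

    def negloglik(log_lam: float) -> float:
        lam_ = np.exp(log_lam)
        w = d + lam_  # V = K + lam I (up to sigma_u^2)
        xvx = (ot**2 / w).sum()
        beta = (ot * yt / w).sum() / xvx
        r = yt - beta * ot
        quad = (r**2 / w).sum()
        s2 = quad / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(s2) + np.log(w).sum() + np.log(xvx) + (n - 1))
        return -ll

    boundary = False
    if lam is None:
        grid = np.linspace(np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1]), 41)
        vals = [negloglik(g) for g in grid]
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(negloglik, bounds=(lo, hi), method="bounded")
        lam = float(np.exp(res.x))
        if i in (0, len(grid) - 1):
            boundary = True
    w = d + lam
    xvx = (ot**2 / w).sum()
    mu = float((ot * yt / w).sum() / xvx)
    r = yt - mu * ot
    sigma_u2 = float((r**2 / w).sum() / (n - 1))
    sigma_e2 = float(lam * sigma_u2)
    # u = Xc' V^-1 (y - mu) with V = K + lam I
    alpha = U @ (r / w)
    effects = Xc.T @ alpha
    fit = GSModelFit(
        model="rrblup",
        intercept=mu,
        effects=effects,
        col_means=col_means,
        hyper={"lambda": lam, "sigma_u2": sigma_u2, "sigma_e2": sigma_e2},
        diagnostics={"reml_boundary": boundary},
        marker_ids=marker_ids,
    )
    if boundary:
        fit.diagnostics["warning"] = "lambda at search boundary"
    return fit


# ---------------------------------------------------------------------------
# Bayesian samplers
# ---------------------------------------------------------------------------


@dataclass
class ChainConfig:
    """Gibbs chain settings (length includes burn-in)."""

    length: int = 12_000
    burn_in: int = 2_000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.length < self.burn_in:
            raise ValueError("chain length must be >= burn-in")


def _scaled_inv_chi2(rng, df: float, scale: float) -> float:
    """Draw from scaled-inverse-chi^2(df, scale)."""
    return df * scale / rng.chisquare(df)


def fit_bayes(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "C",
    chain: ChainConfig | None = None,
    seed: int | None = None,
    df_prior: float = 4.1,
    h2_prior: float = 0.5,
    pi_prior: tuple[float, float] = (1.0, 9.0),
    marker_ids: np.ndarray | None = None,
) -> GSModelFit:
    """Gibbs sampler for Bayesian A / C / Lasso; returns posterior-mean effects.

    The effect-variance prior scale derives from ``var(y) * h2_prior /
    sum(var(x_j))`` so the prior genomic variance matches a heritability
    guess; all settings are configurable and recorded in ``hyper``.
    """
    model = {"a": "A", "bayesa": "A", "c": "C", "bayesc": "C",
             "lasso": "Lasso", "bl": "Lasso", "bayeslasso": "Lasso"}.get(
        str(model).lower(), model
    )
    if model not in {"A", "C", "Lasso"}:
        raise ValueError(f"unknown Bayesian model: {model}")
    X, y = _check_xy(X, y, allow_constant=True)
    chain = chain or ChainConfig()
    if y.std() == 0:
        # no signal at all: the posterior concentrates at zero effects
        return GSModelFit(
            model=f"bayes{model}",
            intercept=float(y[0]) if len(y) else 0.0,
            effects=np.zeros(X.shape[1]),
            col_means=X.mean(axis=0),
            hyper={"chain": (chain.length, chain.burn_in, chain.thin), "seed": seed},
            diagnostics={"constant_response": True},
            marker_ids=marker_ids,
        )
    rng = np.random.default_rng(seed)
    n, p = X.shape
    col_means = X.mean(axis=0)
    Xc = np.ascontiguousarray(X - col_means)
    xtx = (Xc**2).sum(axis=0)
    active = xtx > 0  # monomorphic columns keep zero effects
    vary = y.var(ddof=1)
    sum_varx = (xtx / max(n - 1, 1)).sum()
    scale_b = vary * h2_prior / max(sum_varx, 1e-12) * (df_prior - 2) / df_prior

    mu = y.mean()
    beta = np.zeros(p)
    resid = y - mu
    sigma_e2 = vary / 2
    nu_e, s_e = 4.0, vary / 2 * (4.0 - 2) / 4.0
    # model-specific state
    var_b = np.full(p, scale_b * df_prior / (df_prior - 2))  # BayesA
    common_var = scale_b * df_prior / (df_prior - 2)  # BayesC
    delta = np.ones(p, dtype=bool)  # BayesC inclusion
    pi = 0.1
    # Bayesian Lasso: under the double-exponential prior Var(b_j) = 2 se2/lam2,
    # so the prior-heritability guess fixes the lambda^2 prior mean; a shape-1
    # gamma hyperprior keeps it diffuse enough for the data to override it.
    lam2_prior_mean = 2.0 * max(sum_varx, 1e-12) * (1 - h2_prior) / h2_prior
    lam2_shape, lam2_rate = 1.0, 1.0 / lam2_prior_mean
    lam2 = lam2_prior_mean
    tau2 = np.full(p, 2.0 / lam2)
    incl_count = np.zeros(p)

    keep_beta = np.zeros(p)
    keep_mu = 0.0
    keep_sigma = []
    n_keep = 0

    for it in range(chain.length):
        # intercept
        resid += mu
        mu = rng.normal(resid.mean(), np.sqrt(sigma_e2 / n))
        resid -= mu
        if model == "A":
            for j in range(p):
                if not active[j]:
                    continue
                xj = Xc[:, j]
                resid += xj * beta[j]
                c = xtx[j] + sigma_e2 / var_b[j]
                mean_j = (xj @ resid) / c
                beta[j] = rng.normal(mean_j, np.sqrt(sigma_e2 / c))
                resid -= xj * beta[j]
                var_b[j] = _scaled_inv_chi2(
                    rng, df_prior + 1.0,
                    (df_prior * scale_b + beta[j] ** 2) / (df_prior + 1.0),
                )
        elif model == "C":
            log_pi, log_1mpi = np.log(pi + 1e-300), np.log(1 - pi + 1e-300)
            for j in range(p):
                if not active[j]:
                    continue
                xj = Xc[:, j]
                resid += xj * beta[j]
                rhs = xj @ resid
                c = xtx[j] + sigma_e2 / common_var
                # log Bayes factor inclusion vs exclusion
                log_odds = (
                    log_pi - log_1mpi
                    + 0.5 * (np.log(sigma_e2 / common_var) - np.log(c))
                    + 0.5 * rhs**2 / (sigma_e2 * c)
                )
                prob = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
                delta[j] = rng.random() < prob
                if delta[j]:
                    beta[j] = rng.normal(rhs / c, np.sqrt(sigma_e2 / c))
                    resid -= xj * beta[j]
                else:
                    beta[j] = 0.0
            m_in = int(delta[active].sum())
            pi = rng.beta(pi_prior[0] + m_in, pi_prior[1] + active.sum() - m_in)
            ssb = (beta[delta] ** 2).sum()
            common_var = _scaled_inv_chi2(
                rng, df_prior + m_in, (df_prior * scale_b + ssb) / (df_prior + m_in)
            )
        else:  # Bayesian Lasso
            for j in range(p):
                if not active[j]:
                    continue
                xj = Xc[:, j]
                resid += xj * beta[j]
                c = xtx[j] + 1.0 / tau2[j]
                mean_j = (xj @ resid) / c
                beta[j] = rng.normal(mean_j, np.sqrt(sigma_e2 / c))
                resid -= xj * beta[j]
            # tau_j^-2 | rest ~ inverse-Gaussian
            b2 = np.maximum(beta[active] ** 2, 1e-30)
            mu_ig = np.sqrt(lam2 * sigma_e2 / b2)
            inv_tau2 = rng.wald(mu_ig, lam2)
            tau2[active] = 1.0 / np.maximum(inv_tau2, 1e-12)
            lam2 = rng.gamma(
                lam2_shape + active.sum(),
                1.0 / (lam2_rate + tau2[active].sum() / 2.0),
            )
        # residual variance
        if model == "Lasso":
            # beta prior variance scales with sigma_e2 in Park-Casella
            ssb_scaled = (beta[active] ** 2 / tau2[active]).sum()
            sse = resid @ resid + ssb_scaled + nu_e * s_e
            dfe = n + active.sum() + nu_e
        else:
            sse = resid @ resid + nu_e * s_e
            dfe = n + nu_e
        sigma_e2 = sse / rng.chisquare(dfe)
        if not np.isfinite(sigma_e2) or sigma_e2 > 1e12:
            raise FloatingPointError(
                f"non-convergent residual variance at iteration {it}: {sigma_e2}"
            )
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            keep_beta += beta
            keep_mu += mu
            keep_sigma.append(sigma_e2)
            incl_count += delta if model == "C" else (beta != 0)
            n_keep += 1

    post_beta = keep_beta / n_keep
    post_mu = keep_mu / n_keep
    hyper = {
        "df_prior": df_prior,
        "scale_prior": scale_b,
        "h2_prior": h2_prior,
        "chain": (chain.length, chain.burn_in, chain.thin),
        "seed": seed,
    }
    if model == "C":
        hyper["pi_prior"] = pi_prior
    diagnostics = {
        "n_samples": n_keep,
        "post_mean_sigma_e2": float(np.mean(keep_sigma)),
        "inclusion_freq": incl_count / n_keep,
    }
    return GSModelFit(
        model=f"bayes{model}",
        intercept=float(post_mu),
        effects=post_beta,
        col_means=col_means,
        hyper=hyper,
        diagnostics=diagnostics,
        marker_ids=marker_ids,
    )


# ---------------------------------------------------------------------------
# prediction and a uniform model handle
# ---------------------------------------------------------------------------


def predict(fit: GSModelFit, X_new: np.ndarray) -> np.ndarray:
    """Intercept + centered allele doses times fitted effects."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != len(fit.effects):
        raise ValueError(
            f"marker mismatch: fit has {len(fit.effects)} markers, "
            f"input has {X_new.shape[1] if X_new.ndim == 2 else 'non-matrix'}"
        )
    if np.isnan(X_new).any():
        raise ValueError("genotype matrix contains missing values; impute first")
    return fit.intercept + (X_new - fit.col_means) @ fit.effects


class GSModel:
    """Uniform fit/predict handle over the four model families."""

    def __init__(self, name: str = "rrblup", **kwargs):
        self.name = name.lower()
        self.kwargs = kwargs
        self.fit_: GSModelFit | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GSModel":
        if self.name in ("rrblup", "ridge"):
            self.fit_ = fit_rrblup(X, y, **self.kwargs)
        else:
            name = self.name.replace("bayes", "")
            self.fit_ = fit_bayes(X, y, model=name, **self.kwargs)
        return self

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        if self.fit_ is None:
            raise RuntimeError("model not fitted")
        return predict(self.fit_, X_new)


MODEL_NAMES = ("rrblup", "bayesA", "bayesC", "bayesLasso")
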