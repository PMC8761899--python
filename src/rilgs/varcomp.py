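"""Variance components, heritability, BLUPs and genetic correlations.

Plot phenotypes come from randomized complete blocks replicated in one or
more environments. For balanced data the estimators are closed-form
expected-mean-squares (EMS) solutions of the mixed ANOVA model

    Y_kijr = m + R_k + G_i(R_k) + E_j + B_r(E_j) + R_k E_j + G_i(R_k) E_j + e_kijr

with environment fixed and all other factors random; an EM-based REML
fallback handles unbalanced layouts. Broad-sense heritability on a
genotype-mean basis is

    single environment:  H^2 = S_G^2 / (S_G^2 + S_e^2 / n)
    multi-environment:   H^2 = S_G^2 / (S_G^2 + S_GE^2/e + S_e^2/(e n))

with e environments and n replicates. Genetic correlation across a pair of
environments is the heritability-adjusted phenotypic correlation of line
means, r_g = r / (H_1 H_2); between traits it comes from the genotypic
covariance of the two-way (genotype, block) MANOVA mean cross-products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLS = ("line", "environment", "block", "trait", "value")


@dataclass
class VarianceComponents:
    """Estimated components of the plot-phenotype model (trait units squared)."""

    m: float
    s_g2: float = 0.0
    s_ge2: float = np.nan
    s_e2: float = 0.0
    s_block2: float = np.nan
    s_r2: float = np.nan
    s_gr2: float = np.nan
    s_re2: float = np.nan
    s_gre2: float = np.nan
    e: int = 1
    n: int = 1
    f_tests: dict = field(default_factory=dict)  # term -> (F, p)
    truncated: list = field(default_factory=list)  # components clipped at zero
    notes: list = field(default_factory=list)

    @property
    def ratio_g_ge(self) -> float:
        """S_G^2 / S_GE^2, the headline signal-to-interaction ratio."""
        return self.s_g2 / self.s_ge2 if self.s_ge2 > 0 else np.inf


@dataclass
class HeritabilityEstimate:
    h2: float
    scope: str
    e: int
    n: int

    @property
    def h(self) -> float:
        return float(np.sqrt(self.h2))


@dataclass
class CorrelationEstimate:
    r: float  # phenotypic (Pearson)
    r_g: float  # genetic, raw (may exceed |1| with noisy H)
    se: float | None = None
    context: str = ""

    @property
    def r_g_clamped(self) -> float:
        return float(np.clip(self.r_g, -1.0, 1.0))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _subset(plots: pd.DataFrame, trait: str, environment: str | None = None) -> pd.DataFrame:
    df = plots[plots["trait"] == trait]
    if environment is not None:
        df = df[df["environment"] == environment]
    if df.empty:
        raise ValueError(f"no records for trait={trait!r} environment={environment!r}")
    if df.duplicated(["line", "environment", "block"]).any():
        raise ValueError("duplicate (line, environment, block) records")
    return df


def _clip(value: float, name: str, vc: VarianceComponents) -> float:
    if value < 0:
        vc.truncated.append(name)
        return 0.0
    return float(value)


def env_line_means(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Line x environment table of plot means."""
    df = _subset(plots, trait)
    return df.pivot_table(index="line", columns="environment", values="value")


# ---------------------------------------------------------------------------
# ANOVA estimators
# ---------------------------------------------------------------------------


def anova_single_env(
    plots: pd.DataFrame, trait: str, environment: str
) -> VarianceComponents:
    """Two-way (genotype, block) random ANOVA for one environment.

    Balanced layout required (one plot per line x block); S_G^2 and the
    block component come from the EMS equations, S_e^2 is the residual
    mean square, and the genotype F-test is MS_G / MS_e.
    """
    df = _subset(plots, trait, environment)
    wide = df.pivot_table(index="line", columns="block", values="value", aggfunc="count")
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError("unbalanced data: use the REML option (reml_components)")
    Y = df.pivot_table(index="line", columns="block", values="value").to_numpy()
    g, n = Y.shape
    if g < 2 or n < 2:
        raise ValueError("need >= 2 lines and >= 2 blocks")
    m = Y.mean()
    line_means = Y.mean(axis=1)
    block_means = Y.mean(axis=0)
    ss_g = n * ((line_means - m) ** 2).sum()
    ss_b = g * ((block_means - m) ** 2).sum()
    ss_tot = ((Y - m) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_b
    df_g, df_b, df_e = g - 1, n - 1, (g - 1) * (n - 1)
    ms_g, ms_b, ms_e = ss_g / df_g, ss_b / df_b, ss_e / df_e
    vc = VarianceComponents(m=float(m), e=1, n=n)
    vc.s_e2 = float(ms_e)
    vc.s_g2 = _clip((ms_g - ms_e) / n, "s_g2", vc)
    vc.s_block2 = _clip((ms_b - ms_e) / g, "s_block2", vc)
    if ms_e > 0:
        f = ms_g / ms_e
        vc.f_tests["genotype"] = (float(f), float(stats.f.sf(f, df_g, df_e)))
        fb = ms_b / ms_e
        vc.f_tests["block"] = (float(fb), float(stats.f.sf(fb, df_b, df_e)))
    else:
        vc.f_tests["genotype"] = (np.inf if ms_g > 0 else np.nan, 0.0 if ms_g > 0 else np.nan)
    return vc


def anova_multi_env(
    plots: pd.DataFrame, trait: str, include_population: bool = False
) -> VarianceComponents:
    """Multi-environment mixed ANOVA (environment fixed, genotype/block random).

    Without the population factor: estimates S_G^2, S_GE^2 and S_e^2 from
    the balanced EMS equations and reports the ratio S_G^2/S_GE^2 along
    with F-tests (genotype against the GEI mean square, GEI against the
    residual). With the flag, genotypes are nested in RIL populations and
    the partition S_R^2, S_G(R)^2, S_RE^2, S_G(R)E^2 is returned; unequal
    population sizes are handled with the mean lines-per-population in the
    EMS coefficients and flagged as approximate.
    """
    df = _subset(plots, trait)
    envs = sorted(df["environment"].unique())
    if len(envs) < 2:
        raise ValueError("multi-environment ANOVA needs >= 2 environments")
    counts = df.pivot_table(
        index="line", columns=["environment", "block"], values="value", aggfunc="count"
    )
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("unbalanced data: use the REML option (reml_components)")
    cube = df.pivot_table(index="line", columns=["environment", "block"], values="value")
    lines = cube.index.to_numpy()
    e = len(envs)
    n = len(cube.columns) // e
    Y = cube.to_numpy().reshape(len(lines), e, n)
    g = len(lines)
    m = Y.mean()

    mean_i = Y.mean(axis=(1, 2))
    mean_j = Y.mean(axis=(0, 2))
    mean_jr = Y.mean(axis=0)
    mean_ij = Y.mean(axis=2)

    ss_e_env = g * n * ((mean_j - m) ** 2).sum()
    ss_b = g * ((mean_jr - mean_j[:, None]) ** 2).sum()
    ss_g = e * n * ((mean_i - m) ** 2).sum()
    ss_ge = n * ((mean_ij - mean_i[:, None] - mean_j[None, :] + m) ** 2).sum()
    ss_tot = ((Y - m) ** 2).sum()
    ss_res = ss_tot - ss_e_env - ss_b - ss_g - ss_ge

    df_g = g - 1
    df_ge = (g - 1) * (e - 1)
    df_res = e * (g - 1) * (n - 1)
    ms_g, ms_ge, ms_res = ss_g / df_g, ss_ge / df_ge, ss_res / df_res

    vc = VarianceComponents(m=float(m), e=e, n=n)
    vc.s_e2 = float(ms_res)
    vc.s_ge2 = _clip((ms_ge - ms_res) / n, "s_ge2", vc)
    vc.s_g2 = _clip((ms_g - ms_ge) / (e * n), "s_g2", vc)
    ms_b = ss_b / (e * (n - 1))
    vc.s_block2 = _clip((ms_b - ms_res) / g, "s_block2", vc)
    if ms_ge > 0:
        f = ms_g / ms_ge
        vc.f_tests["genotype"] = (float(f), float(stats.f.sf(f, df_g, df_ge)))
    if ms_res > 0:
        f = ms_ge / ms_res
        vc.f_tests["gxe"] = (float(f), float(stats.f.sf(f, df_ge, df_res)))

    if include_population:
        pops = (
            df.drop_duplicates("line").set_index("line")["population"].reindex(lines)
        )
        if pops.isna().any():
            raise ValueError("population labels required for the nested analysis")
        pop_names = sorted(pops.unique())
        K = len(pop_names)
        if K < 2:
            raise ValueError("nested analysis needs >= 2 populations")
        sizes = pops.value_counts()
        g_bar = float(sizes.mean())
        if sizes.nunique() > 1:
            vc.notes.append(
                "unequal population sizes: EMS coefficients use the mean size"
            )
        pop_idx = {p: np.flatnonzero((pops == p).to_numpy()) for p in pop_names}
        mean_k = np.array([Y[idx].mean() for idx in pop_idx.values()])
        mean_kj = np.stack([Y[idx].mean(axis=(0, 2)) for idx in pop_idx.values()])
        ss_r = sum(
            len(idx) * e * n * (mk - m) ** 2
            for idx, mk in zip(pop_idx.values(), mean_k)
        )
        ss_gr = ss_g - ss_r  # lines within populations
        ss_re = sum(
            len(idx) * n * ((mean_kj[a] - mean_k[a] - mean_j + m) ** 2).sum()
            for a, idx in enumerate(pop_idx.values())
        )
        ss_gre = ss_ge - ss_re
        df_r = K - 1
        df_gr = g - K
        df_re = (K - 1) * (e - 1)
        df_gre = (g - K) * (e - 1)
        ms_r, ms_gr = ss_r / df_r, ss_gr / df_gr
        ms_re, ms_gre = ss_re / df_re, ss_gre / df_gre
        vc.s_gre2 = _clip((ms_gre - ms_res) / n, "s_gre2", vc)
        vc.s_re2 = _clip((ms_re - ms_gre) / (g_bar * n), "s_re2", vc)
        vc.s_gr2 = _clip((ms_gr - ms_gre) / (e * n), "s_gr2", vc)
        vc.s_r2 = _clip(
            (ms_r - ms_gr - ms_re + ms_gre) / (g_bar * e * n), "s_r2", vc
        )
        for name, (ms_num, ms_den, d1, d2) in {
            "population": (ms_r, ms_gr + ms_re - ms_gre, df_r, df_gr),
            "genotype_within": (ms_gr, ms_gre, df_gr, df_gre),
            "pop_x_env": (ms_re, ms_gre, df_re, df_gre),
            "genotype_within_x_env": (ms_gre, ms_res, df_gre, df_res),
        }.items():
            if ms_den > 0:
                f = ms_num / ms_den
                vc.f_tests[name] = (float(f), float(stats.f.sf(f, d1, d2)))
    return vc


# ---------------------------------------------------------------------------
# EM-REML fallback (small, general; used for unbalanced data and as oracle)
# ---------------------------------------------------------------------------


def reml_em(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """EM-REML for y = X b + sum_i Z_i u_i + e with u_i ~ N(0, s_i^2 I).

    Returns (variance components for each Z_i, residual variance). Meant
    for modest problem sizes; convergence is the usual slow-but-safe EM.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = np.linalg.matrix_rank(X)
    q = [Z.shape[1] for Z in Zs]
    sig = np.full(len(Zs), y.var(ddof=1) / (len(Zs) + 1) + 1e-6)
    sig_e = y.var(ddof=1) / (len(Zs) + 1) + 1e-6
    for _ in range(max_iter):
        V = sig_e * np.eye(n)
        for s2, Z in zip(sig, Zs):
            V += s2 * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
        Py = P @ y
        new = np.empty_like(sig)
        for i, (s2, Z) in enumerate(zip(sig, Zs)):
            ZtPy = Z.T @ Py
            ZtPZ = Z.T @ P @ Z
            new[i] = (s2**2 * (ZtPy @ ZtPy) + s2 * (q[i] - s2 * np.trace(ZtPZ))) / q[i]
        new_e = (sig_e**2 * (Py @ Py) + sig_e * ((n - p) - sig_e * np.trace(P))) / (n - p)
        new = np.maximum(new, 1e-12)
        new_e = max(new_e, 1e-12)
        if np.max(np.abs(np.r_[new, new_e] - np.r_[sig, sig_e])) < tol:
            sig, sig_e = new, new_e
            break
        sig, sig_e = new, new_e
    return sig, float(sig_e)


def reml_components(plots: pd.DataFrame, trait: str) -> VarianceComponents:
    """REML estimation of (S_G^2, S_GE^2, block, S_e^2) on possibly unbalanced data."""
    df = _subset(plots, trait)
    envs = sorted(df["environment"].unique())
    lines = sorted(df["line"].unique())
    y = df["value"].to_numpy()
    env_d = pd.get_dummies(df["environment"]).to_numpy(dtype=float)
    X = env_d  # environment fixed effects (spans the intercept)
    Zg = pd.get_dummies(df["line"]).to_numpy(dtype=float)
    ge = df["line"].astype(str) + ":" + df["environment"].astype(str)
    Zge = pd.get_dummies(ge).to_numpy(dtype=float)
    be = df["environment"].astype(str) + ":" + df["block"].astype(str)
    Zb = pd.get_dummies(be).to_numpy(dtype=float)
    (s_g2, s_ge2, s_b2), s_e2 = reml_em(y, X, [Zg, Zge, Zb])
    n = int(round(len(df) / (len(lines) * len(envs))))
    return VarianceComponents(
        m=float(y.mean()),
        s_g2=float(s_g2),
        s_ge2=float(s_ge2),
        s_block2=float(s_b2),
        s_e2=float(s_e2),
        e=len(envs),
        n=max(n, 1),
        notes=["REML (EM) estimates"],
    )


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------


def cv_g(s_g2: float, m: float) -> float:
    """Genetic coefficient of variation, percent: 100 * S_G / m."""
    if m <= 0:
        raise ValueError("mean must be positive")
    if s_g2 < 0:
        raise ValueError("genotypic variance must be >= 0")
    return 100.0 * float(np.sqrt(s_g2)) / m


def heritability_single_env(s_g2: float, s_e2: float, n: int) -> HeritabilityEstimate:
    """Genotype-mean-basis broad-sense heritability for one environment."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if s_g2 < 0 or s_e2 < 0:
        raise ValueError("components must be >= 0")
    denom = s_g2 + s_e2 / n
    if denom == 0:
        raise ValueError("heritability undefined: all components zero")
    return HeritabilityEstimate(h2=s_g2 / denom, scope="single-environment", e=1, n=n)


def heritability_multi_env(
    s_g2: float, s_ge2: float, s_e2: float, e: int, n: int
) -> HeritabilityEstimate:
    """Genotype-mean-basis H^2 over e environments with n replicates each."""
    if e < 1 or n < 1:
        raise ValueError("e and n must be >= 1")
    if min(s_g2, s_ge2, s_e2) < 0:
        raise ValueError("components must be >= 0")
    denom = s_g2 + s_ge2 / e + s_e2 / (e * n)
    if denom == 0:
        raise ValueError("heritability undefined: all components zero")
    return HeritabilityEstimate(h2=s_g2 / denom, scope="multi-environment", e=e, n=n)


def blup_line_means(
    means: np.ndarray | pd.Series, h2: float, target: float | None = None
) -> np.ndarray | pd.Series:
    """Shrink line means toward the grand mean by the heritability.

    BLUP_i = target + H^2 (mean_i - target) with target defaulting to the
    grand mean of the input means. Preserves ranking; the variance of the
    BLUPs is H^4 times that of the means.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("H^2 must lie in [0, 1]")
    mu = float(np.mean(means)) if target is None else target
    return mu + h2 * (means - mu)


def blups_per_environment(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Line x environment BLUPs: per-environment shrinkage of line means.

    For each environment, S_G^2 and S_e^2 come from the single-environment
    ANOVA, H^2 from the genotype-mean formula, and line means are shrunk
    toward the environment grand mean. These are the phenotype inputs the
    genomic-prediction and GWAS stages expect.
    """
    means = env_line_means(plots, trait)
    out = {}
    for env in means.columns:
        vc = anova_single_env(plots, trait, env)
        h2 = heritability_single_env(vc.s_g2, vc.s_e2, vc.n).h2
        out[env] = blup_line_means(means[env], h2)
    return pd.DataFrame(out)


def phenotypic_correlation(x, y) -> float:
    """Pearson correlation of paired line values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired values must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(np.corrcoef(x, y)[0, 1])


def genetic_correlation_env_pair(
    plots: pd.DataFrame, trait: str, env1: str, env2: str
) -> CorrelationEstimate:
    """Genetic correlation of line values across two environments.

    r_g = r / (H_1 H_2) with r the Pearson correlation of line means and
    H_i the square root of each environment's genotype-mean heritability.
    Values beyond |1| (possible with noisy H) are kept raw; use
    ``r_g_clamped`` for display.
    """
    means = env_line_means(plots, trait)
    for env in (env1, env2):
        if env not in means.columns:
            raise ValueError(f"environment {env!r} absent for trait {trait!r}")
    pair = means[[env1, env2]].dropna()
    r = phenotypic_correlation(pair[env1], pair[env2])
    hs = []
    for env in (env1, env2):
        vc = anova_single_env(plots, trait, env)
        h = heritability_single_env(vc.s_g2, vc.s_e2, vc.n).h
        if h == 0:
            raise ValueError(f"heritability zero in {env!r}: r_g undefined")
        hs.append(h)
    r_g = r / (hs[0] * hs[1])
    se = (1 - min(abs(r_g), 1.0) ** 2) / np.sqrt(max(len(pair) - 2, 1))
    return CorrelationEstimate(r=r, r_g=float(r_g), se=float(se), context=f"{env1}|{env2}")


def genetic_correlation_traits(
    plots: pd.DataFrame, trait_x: str, trait_y: str, environment: str
) -> CorrelationEstimate:
    """Genetic correlation between two traits within one environment.

    Genotypic covariance from the two-way (genotype, block) MANOVA mean
    cross-products, Cov_G = (MCP_G - MCP_e) / n, divided by the genotypic
    standard deviations of each trait. The standard error is a first-order
    delta-method approximation from the sampling variances of the mean
    squares and cross-products.
    """
    dx = _subset(plots, trait_x, environment).pivot_table(
        index="line", columns="block", values="value"
    )
    dy = _subset(plots, trait_y, environment).pivot_table(
        index="line", columns="block", values="value"
    )
    if not dx.index.equals(dy.index) or not dx.columns.equals(dy.columns):
        raise ValueError("both traits must be measured on identical plots")
    Xv, Yv = dx.to_numpy(), dy.to_numpy()
    g, n = Xv.shape
    xm, ym = Xv.mean(), Yv.mean()
    xi, yi = Xv.mean(axis=1), Yv.mean(axis=1)
    xr, yr = Xv.mean(axis=0), Yv.mean(axis=0)
    cp_g = n * ((xi - xm) * (yi - ym)).sum() / (g - 1)
    res_x = Xv - xi[:, None] - xr[None, :] + xm
    res_y = Yv - yi[:, None] - yr[None, :] + ym
    cp_e = (res_x * res_y).sum() / ((g - 1) * (n - 1))
    cov_g = (cp_g - cp_e) / n
    vx = anova_single_env(plots, trait_x, environment)
    vy = anova_single_env(plots, trait_y, environment)
    if vx.s_g2 <= 0 or vy.s_g2 <= 0:
        raise ValueError("genotypic variance non-positive: r_g undefined")
    r_g = cov_g / np.sqrt(vx.s_g2 * vy.s_g2)
    # delta-method SE: Var(MS) ~ 2 MS^2/df, Var(MCP) ~ (MCP^2 + MS_x MS_y)/df
    df_g = g - 1
    ms_gx = n * vx.s_g2 + vx.s_e2
    ms_gy = n * vy.s_g2 + vy.s_e2
    var_cp = (cp_g**2 + ms_gx * ms_gy) / df_g / n**2
    var_vx = 2 * ms_gx**2 / df_g / n**2
    var_vy = 2 * ms_gy**2 / df_g / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (
            var_cp / cov_g**2
            + 0.25 * var_vx / vx.s_g2**2
            + 0.25 * var_vy / vy.s_g2**2
        )
    se = float(abs(r_g) * np.sqrt(rel)) if np.isfinite(rel) else None
    r_ph = phenotypic_correlation(xi, yi)
    return CorrelationEstimate(
        r=r_ph, r_g=float(r_g), se=se, context=f"{trait_x}~{trait_y}@{environment}"
    )
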