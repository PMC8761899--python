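"""Kinship-corrected genome-wide association scan.

Population structure of the stratified multi-population panel is handled
by a marker-derived kinship matrix (Astle-Balding standardized estimator)
as the polygenic covariance plus the leading principal components of the
genotype matrix as fixed covariates. Variance components of the null
model are estimated once by restricted likelihood (the P3D/EMMAX scheme);
each marker is then tested by generalized least squares under the fixed
covariance V = K sigma_g^2 + I sigma_e^2, with two-sided p from the Wald
statistic. Multiple testing uses Bonferroni and Benjamini-Hochberg FDR;
significant markers are grouped into loci by single-linkage clustering of
allelic-correlation R^2 > 0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rilgs.matrix import GenotypeMatrix


# ---------------------------------------------------------------------------
# kinship and covariates
# ---------------------------------------------------------------------------


def kinship(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Standardized (Astle-Balding) kinship from allele doses.

    K = (1/M) sum_m (x_m - 2 p_m)(x_m - 2 p_m)' / (2 p_m (1 - p_m)).
    Requires a complete matrix with every marker polymorphic.
    """
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if np.isnan(X).any():
        raise ValueError("kinship requires a complete genotype matrix")
    p = X.mean(axis=0) / 2.0
    if ((p == 0) | (p == 1)).any():
        raise ValueError("monomorphic markers present; filter before kinship")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = Z @ Z.T / X.shape[1]
    return (K + K.T) / 2.0


def pc_covariates(G: GenotypeMatrix | np.ndarray, n_components: int = 10) -> np.ndarray:
    """Leading principal-component scores of the centered genotype matrix.

    Deterministic up to sign; the sign is fixed so the largest-magnitude
    loading of each component is positive.
    """
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete genotype matrix")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
        n_components = rank
    scores = U[:, :n_components] * s[:n_components]
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] *= -1
    return scores


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------


@dataclass
class GWASResult:
    table: pd.DataFrame  # marker, chrom, pos, effect, p, score, evar_pct, flags
    n_lines: int
    sigma_g2: float
    sigma_e2: float
    bonferroni_p: float
    fdr_threshold: float | None
    ld_r2: pd.DataFrame | None = None
    loci: dict = field(default_factory=dict)  # marker -> locus id

    @property
    def bonferroni_set(self) -> list:
        return self.table.loc[self.table["sig_bonferroni"], "marker"].tolist()

    @property
    def fdr_set(self) -> list:
        return self.table.loc[self.table["sig_fdr"], "marker"].tolist()


def _null_reml(y: np.ndarray, W: np.ndarray, K: np.ndarray) -> tuple[float, float]:
    """REML variance components of y = W a + g + e with g ~ N(0, K sigma_g^2)."""
    n = len(y)
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Wt = U.T @ W
    p = W.shape[1]

    def negll(log_delta: float) -> float:
        delta = np.exp(log_delta)  # sigma_e2 / sigma_g2
        w = d + delta
        WtW = Wt.T @ (Wt / w[:, None])
        beta = np.linalg.solve(WtW, Wt.T @ (yt / w))
        r = yt - Wt @ beta
        quad = (r**2 / w).sum()
        s2 = quad / (n - p)
        _, logdet_wtw = np.linalg.slogdet(WtW)
        return 0.5 * (
            (n - p) * np.log(s2) + np.log(w).sum() + logdet_wtw + (n - p)
        )

    grid = np.linspace(np.log(1e-5), np.log(1e5), 31)
    vals = [negll(g) for g in grid]
    i = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        negll,
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded",
    )
    delta = float(np.exp(res.x))
    w = d + delta
    WtW = Wt.T @ (Wt / w[:, None])
    beta = np.linalg.solve(WtW, Wt.T @ (yt / w))
    r = yt - Wt @ beta
    sigma_g2 = float((r**2 / w).sum() / (n - p))
    return sigma_g2, sigma_g2 * delta


def gwas_scan(
    G: GenotypeMatrix,
    y: np.ndarray | pd.Series,
    K: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    n_pcs: int = 10,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    ld_threshold: float = 0.8,
) -> GWASResult:
    """Single-marker GLS scan with P3D variance components.

    ``y`` is one value per line (typically a BLUP across environments).
    ``K`` defaults to the Astle-Balding kinship of ``G``; ``covariates``
    defaults to the first ``n_pcs`` principal components. Set both ``K``
    to a zero matrix and ``n_pcs=0`` to run an uncorrected scan.
    Explained phenotypic variance per marker is the squared partial
    correlation between marker and phenotype after GLS rotation, x100.
    """
    yv = np.asarray(y, dtype=float)
    if len(yv) != G.n_lines:
        raise ValueError("phenotype length must equal the number of lines")
    if np.isnan(G.values).any():
        raise ValueError("GWAS requires a complete genotype matrix")
    if K is None:
        K = kinship(G)
    if covariates is None:
        covariates = (
            pc_covariates(G, n_pcs) if n_pcs > 0 else np.empty((G.n_lines, 0))
        )
    n = G.n_lines
    W = np.column_stack([np.ones(n), covariates])
    sigma_g2, sigma_e2 = _null_reml(yv, W, K)
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; adding 1e-8 ridge jitter")
        L = np.linalg.cholesky(V + 1e-8 * np.eye(n))
    # rotate so the model becomes ordinary least squares
    from scipy.linalg import solve_triangular

    yt = solve_triangular(L, yv, lower=True)
    Wt = solve_triangular(L, W, lower=True)
    Xt = solve_triangular(L, G.values, lower=True)
    # residualize on covariates
    Q, _ = np.linalg.qr(Wt)
    ry = yt - Q @ (Q.T @ yt)
    RX = Xt - Q @ (Q.T @ Xt)
    sxx = (RX**2).sum(axis=0)
    sxy = RX.T @ ry
    syy = float(ry @ ry)
    dfree = n - W.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, np.nan)
        ss_res = syy - np.where(sxx > 0, sxy**2 / sxx, 0.0)
        tstat = beta * np.sqrt(sxx * dfree / np.maximum(ss_res, 1e-300))
        evar = np.where(sxx > 0, sxy**2 / (sxx * syy), np.nan) * 100.0
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dfree)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    M = int(np.isfinite(pvals).sum())
    bonf = bonferroni_threshold(alpha, M)
    fdr_sel, fdr_thr = fdr_select(pvals[np.isfinite(pvals)], fdr_q)
    finite_idx = np.flatnonzero(np.isfinite(pvals))
    sig_fdr = np.zeros(G.n_markers, dtype=bool)
    sig_fdr[finite_idx[fdr_sel]] = True
    table = pd.DataFrame(
        {
            "marker": G.marker_ids,
            "chrom": G.markers["chrom"].to_numpy(),
            "pos": G.markers["pos"].to_numpy(),
            "effect": beta,
            "p": pvals,
            "score": -np.log10(pvals),
            "evar_pct": evar,
            "sig_bonferroni": pvals <= bonf,
            "sig_fdr": sig_fdr,
        }
    )
    result = GWASResult(
        table=table,
        n_lines=n,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        bonferroni_p=bonf,
        fdr_threshold=fdr_thr,
    )
    sig = table.loc[table["sig_fdr"] | table["sig_bonferroni"], "marker"].tolist()
    if len(sig) >= 2:
        r2, loci = ld_r2(G, sig, threshold=ld_threshold)
        result.ld_r2 = r2
        result.loci = loci
    elif len(sig) == 1:
        result.loci = {sig[0]: 0}
    table["locus_id"] = table["marker"].map(result.loci).astype("Int64")
    return result


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / M."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests


def fdr_select(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up selection.

    Returns (indices of selected p-values, threshold). If no rank passes,
    the threshold is None (undefined) and the selection empty.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    M = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = q * np.arange(1, M + 1) / M
    passing = np.flatnonzero(ranked <= crit)
    if passing.size == 0:
        return np.array([], dtype=int), None
    k = passing[-1]
    return np.sort(order[: k + 1]), float(ranked[k])


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(
    G: GenotypeMatrix, marker_ids, threshold: float = 0.8
) -> tuple[pd.DataFrame, dict]:
    """Pairwise allelic correlation R^2 and single-linkage locus clusters.

    Pairs with R^2 above the threshold are linked; loci are the connected
    components of that graph (single linkage at a fixed cut).
    """
    ids = list(marker_ids)
    pos = pd.Index(G.markers["id"]).get_indexer(ids)
    if (pos < 0).any():
        missing = [m for m, p in zip(ids, pos) if p < 0]
        raise ValueError(f"markers not in matrix: {missing}")
    X = G.values[:, pos]
    if np.isnan(X).any():
        raise ValueError("LD requires complete genotypes for the chosen markers")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant marker among LD candidates")
    R = np.corrcoef(X.T)
    R2 = pd.DataFrame(R**2, index=ids, columns=ids)
    # union-find over high-LD pairs
    parent = {m: m for m in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if R2.loc[a, b] > threshold:
                parent[find(a)] = find(b)
    roots = {}
    loci = {}
    for m in ids:
        r = find(m)
        if r not in roots:
            roots[r] = len(roots)
        loci[m] = roots[r]
    return R2, loci


# ---------------------------------------------------------------------------
# plot-ready tables
# ---------------------------------------------------------------------------


def manhattan_table(result: GWASResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative-coordinate Manhattan table and a QQ table.

    Returns ``(manhattan, qq)``. Unplaced markers are binned into 'chrU'
    with a warning. The Manhattan table carries both threshold levels as
    columns (constant per row) for horizontal-line plotting.
    """
    tab = result.table.copy()
    unplaced = tab["chrom"].isna() | (tab["chrom"] == "")
    if unplaced.any():
        warnings.warn(f"{int(unplaced.sum())} unplaced markers binned into chrU")
        tab.loc[unplaced, "chrom"] = "chrU"
    tab = tab.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    offset, offsets = 0, {}
    for chrom, grp in tab.groupby("chrom", sort=False):
        offsets[chrom] = offset
        offset += int(grp["pos"].max()) + 1
    tab["cum_pos"] = tab["pos"] + tab["chrom"].map(offsets)
    tab["cum_pos"] += np.arange(len(tab)) * 1e-9  # strict monotonicity within table
    tab["bonferroni_line"] = -np.log10(result.bonferroni_p)
    tab["fdr_line"] = (
        -np.log10(result.fdr_threshold) if result.fdr_threshold else np.nan
    )
    M = len(tab)
    observed = np.sort(tab["score"].to_numpy())[::-1]
    expected = -np.log10(np.arange(1, M + 1) / (M + 1))
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    cols = [
        "marker", "chrom", "pos", "cum_pos", "score", "p", "effect",
        "evar_pct", "sig_bonferroni", "sig_fdr", "locus_id",
        "bonferroni_line", "fdr_line",
    ]
    return tab[cols], qq
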