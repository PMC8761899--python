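"""Association scan: kinship, structure correction, multiple testing, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rilgs import gwas
from rilgs.matrix import GenotypeMatrix


def _geno(X, pops=None):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    meta = pd.DataFrame(
        {"id": [f"chr1_{j + 1}" for j in range(p)], "chrom": "chr1",
         "pos": np.arange(1, p + 1)}
    )
    return GenotypeMatrix(
        X,
        np.array([f"l{i}" for i in range(n)]),
        pops if pops is not None else np.full(n, "p"),
        meta,
    )


class TestKinship:
    def test_duplicate_inbred_lines_share_diagonal_entry(self, rng):
        X = rng.choice([0.0, 2.0], size=(10, 400))
        X[1] = X[0]
        K = gwas.kinship(_geno(X))
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-10)

    def test_unrelated_panel_offdiagonal_near_zero(self, rng):
        M = 2000
        X = rng.binomial(2, 0.5, size=(40, M)).astype(float)
        K = gwas.kinship(_geno(X))
        off = K[np.triu_indices(40, 1)]
        assert abs(off.mean()) < 2 / np.sqrt(M)

    def test_symmetric_and_psd(self, filtered_panel):
        G, _, _ = filtered_panel
        K = gwas.kinship(G)
        assert np.array_equal(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_monomorphic_marker_rejected(self, rng):
        X = rng.binomial(2, 0.5, size=(10, 5)).astype(float)
        X[:, 2] = 0.0
        with pytest.raises(ValueError, match="monomorphic"):
            gwas.kinship(_geno(X))


class TestPCs:
    def test_three_populations_separate_in_pc_space(self, filtered_panel):
        from sklearn.metrics import silhouette_score

        G, _, _ = filtered_panel
        scores = gwas.pc_covariates(G, 2)
        assert silhouette_score(scores, G.populations) > 0

    def test_duplicate_lines_identical_scores(self, rng):
        X = rng.binomial(2, 0.5, size=(12, 100)).astype(float)
        X[3] = X[2]
        s = gwas.pc_covariates(_geno(X), 4)
        assert np.allclose(s[2], s[3], atol=1e-9)

    def test_scores_orthogonal(self, filtered_panel):
        G, _, _ = filtered_panel
        s = gwas.pc_covariates(G, 5)
        gram = s.T @ s
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_rank_truncation_warns(self, rng):
        X = rng.binomial(2, 0.5, size=(5, 50)).astype(float)
        with pytest.warns(UserWarning, match="rank"):
            s = gwas.pc_covariates(_geno(X), 10)
        assert s.shape[1] <= 4


class TestScan:
    def test_identity_kinship_matches_ols(self, rng):
        # with K = I the GLS collapses to ordinary regression
        X = np.array([[0.0], [1], [2], [0], [2], [1], [0], [2]])
        y = np.array([0.3, 1.1, 1.8, 0.2, 2.4, 0.9, -0.1, 2.2])
        G = _geno(X)
        res = gwas.gwas_scan(G, y, K=np.eye(8), n_pcs=0)
        # explicit OLS t-test
        xc = X[:, 0] - X[:, 0].mean()
        yc = y - y.mean()
        b = (xc @ yc) / (xc @ xc)
        ssr = (yc - b * xc) @ (yc - b * xc)
        t = b * np.sqrt((xc @ xc) * 6 / ssr)
        p = 2 * stats.t.sf(abs(t), 6)
        assert res.table["p"].iloc[0] == pytest.approx(p, rel=1e-8)
        assert res.table["effect"].iloc[0] == pytest.approx(b, rel=1e-8)

    def test_explained_variance_is_squared_partial_correlation(self, rng):
        X = rng.binomial(2, 0.5, size=(40, 30)).astype(float)
        y = X[:, 5] + rng.normal(0, 1, 40)
        res = gwas.gwas_scan(_geno(X), y, K=np.eye(40), n_pcs=0)
        xc = X[:, 5] - X[:, 5].mean()
        yc = y - y.mean()
        r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc)) * 100
        assert res.table["evar_pct"].iloc[5] == pytest.approx(r2, rel=1e-6)
        assert ((res.table["evar_pct"] >= 0) & (res.table["evar_pct"] <= 100)).all()

    def test_structured_null_is_calibrated_with_correction(self, filtered_panel):
        G, _, _ = filtered_panel
        shift = {p: s for p, s in zip(np.unique(G.populations), (0.0, 0.5, 1.0))}
        base = np.array([shift[p] for p in G.populations])
        frac_corr, frac_raw = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = base + r.normal(size=G.n_lines)
            rc = gwas.gwas_scan(G, y)
            ru = gwas.gwas_scan(G, y, K=np.zeros((G.n_lines,) * 2), n_pcs=0)
            frac_corr.append((rc.table["p"] < 0.05).mean())
            frac_raw.append((ru.table["p"] < 0.05).mean())
        assert 0.03 <= np.mean(frac_corr) <= 0.07
        assert np.mean(frac_raw) > 0.07

    def test_simulated_qtl_rises_to_top(self, filtered_panel):
        G, _, _ = filtered_panel
        K = gwas.kinship(G)
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            maf = G.minor_allele_freq()
            causal = int(r.choice(np.flatnonzero(maf > 0.3)))
            x = G.values[:, causal]
            g = x - x.mean()
            g *= np.sqrt(0.06 / g.var())  # QTL explains ~6% of variance
            y = g + r.normal(0, np.sqrt(0.94), G.n_lines)
            res = gwas.gwas_scan(G, y, K=K)
            top = res.table.nlargest(10, "score").index.to_numpy()
            if causal in top:
                hits += 1
        assert hits >= n_seeds - 2

    def test_bonferroni_subset_of_fdr(self, filtered_panel):
        G, _, _ = filtered_panel
        r = np.random.default_rng(3)
        x = G.values[:, 10]
        y = (x - x.mean()) * 0.8 + r.normal(0, 0.5, G.n_lines)
        res = gwas.gwas_scan(G, y)
        assert set(res.bonferroni_set) <= set(res.fdr_set)


class TestMultipleTesting:
    def test_bonferroni_levels(self):
        assert gwas.bonferroni_threshold(0.05, 1000) == pytest.approx(5e-5)
        assert gwas.bonferroni_threshold(0.05, 1) == 0.05
        assert -np.log10(gwas.bonferroni_threshold(0.05, 1000)) == pytest.approx(
            np.log10(1000 / 0.05)
        )

    def test_bh_hand_example(self):
        # cutoffs kq/M = (0.01, 0.02, 0.03, 0.04, 0.05): ranks 1 and 2 pass
        # (0.001 <= 0.01, 0.008 <= 0.02) but 0.039 > 0.03 and 0.041 > 0.04,
        # so the step-up stops at k = 2
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.9])
        sel, thr = gwas.fdr_select(p, 0.05)
        assert list(sel) == [0, 1]
        assert thr == pytest.approx(0.008)
        # a rank-4 value at its cutoff pulls the earlier misses back in
        p2 = np.array([0.001, 0.008, 0.039, 0.040, 0.9])
        sel2, thr2 = gwas.fdr_select(p2, 0.05)
        assert list(sel2) == [0, 1, 2, 3]
        assert thr2 == pytest.approx(0.040)

    def test_bh_all_ones_undefined(self):
        sel, thr = gwas.fdr_select(np.ones(10), 0.05)
        assert len(sel) == 0 and thr is None

    def test_bh_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            M = int(rng.integers(1, 40))
            p = rng.random(M) ** rng.uniform(0.5, 3.0)
            p = np.clip(p, 1e-12, 1.0)
            sel, _ = gwas.fdr_select(p, 0.05)
            # brute force: largest k over all ranks with p_(k) <= k q / M
            ranked = np.sort(p)
            ks = [k for k in range(1, M + 1) if ranked[k - 1] <= 0.05 * k / M]
            expected = set() if not ks else set(np.argsort(p, kind="stable")[: max(ks)])
            assert set(sel) == expected


class TestLD:
    def test_identical_markers_same_locus(self, rng):
        x = rng.binomial(2, 0.5, 30).astype(float)
        X = np.column_stack([x, x, rng.binomial(2, 0.5, 30)])
        G = _geno(X)
        R2, loci = gwas.ld_r2(G, ["chr1_1", "chr1_2"])
        assert R2.iloc[0, 1] == pytest.approx(1.0)
        assert loci["chr1_1"] == loci["chr1_2"]

    def test_single_linkage_chains_clusters(self):
        # pairwise R2 (0.9, 0.85, 0.6) -> one 3-marker cluster
        n = 400
        rng = np.random.default_rng(2)
        a = rng.normal(size=n)
        b = 0.95 * a + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
        c = 0.92 * b + np.sqrt(1 - 0.92**2) * rng.normal(size=n)
        # quantize into doses while keeping correlation high
        def dose(v):
            return np.digitize(v, np.quantile(v, [0.25, 0.75])).astype(float)

        X = np.column_stack([dose(a), dose(b), dose(c)])
        G = _geno(X)
        R2, loci = gwas.ld_r2(G, list(G.marker_ids), threshold=0.8)
        if R2.iloc[0, 1] > 0.8 and R2.iloc[1, 2] > 0.8:
            assert len(set(loci.values())) == 1

    def test_independent_markers_mean_r2(self, rng):
        n = 50
        X = rng.binomial(2, 0.5, size=(n, 200)).astype(float)
        G = _geno(X)
        R2, _ = gwas.ld_r2(G, list(G.marker_ids), threshold=1.1)
        off = R2.to_numpy()[np.triu_indices(200, 1)]
        assert off.mean() == pytest.approx(1 / (n - 1), rel=0.2)

    def test_constant_marker_rejected(self, rng):
        X = np.column_stack([np.zeros(10), rng.binomial(2, 0.5, 10)])
        with pytest.raises(ValueError, match="constant"):
            gwas.ld_r2(_geno(X), ["chr1_1", "chr1_2"])


class TestManhattan:
    def test_scores_thresholds_and_qq(self, filtered_panel):
        G, _, _ = filtered_panel
        r = np.random.default_rng(0)
        y = r.normal(size=G.n_lines)
        res = gwas.gwas_scan(G, y)
        man, qq = gwas.manhattan_table(res)
        assert man["cum_pos"].is_monotonic_increasing
        M = len(man)
        assert qq["expected"].iloc[0] == pytest.approx(-np.log10(1 / (M + 1)))
        row = res.table[res.table["p"] > 0].iloc[0]
        assert row["score"] == pytest.approx(-np.log10(row["p"]))
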