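"""Variance components, heritability, BLUP shrinkage and genetic correlations."""

import numpy as np
import pandas as pd
import pytest

from rilgs import simulate as sim, varcomp as vc


def _plots(values, trait="t", environment="env1"):
    """Build a plot table from a lines x blocks array."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    rows = []
    for i in range(g):
        for r in range(n):
            rows.append(
                {"line": f"l{i}", "population": "p", "environment": environment,
                 "block": r + 1, "trait": trait, "value": values[i, r]}
            )
    return pd.DataFrame(rows)


class TestSingleEnvAnova:
    def test_constant_data_gives_zero_components(self):
        out = vc.anova_single_env(_plots(np.full((3, 2), 5.0)), "t", "env1")
        assert out.s_g2 == 0.0 and out.s_e2 == 0.0

    def test_hand_computed_six_plot_instance(self):
        # lines (10,12), (12,14), (15,13): MS_G = 4.6667, MS_e = 2.6667
        out = vc.anova_single_env(
            _plots([[10, 12], [12, 14], [15, 13]]), "t", "env1"
        )
        assert out.s_e2 == pytest.approx(8 / 3, abs=1e-12)
        assert out.s_g2 == pytest.approx(1.0, abs=1e-12)  # (14/3 - 8/3)/2
        assert "s_block2" in out.truncated  # MS_B < MS_e here

    def test_unbalanced_data_directed_to_reml(self):
        plots = _plots([[10, 12], [12, 14], [15, 13]])
        with pytest.raises(ValueError, match="REML"):
            vc.anova_single_env(plots.iloc[:-1], "t", "env1")

    def test_generating_variance_recovered_on_average(self, gmap):
        errs = []
        for seed in range(10):
            _, plots, _ = sim.simulate_panel(
                sim.SimConfig(seed=seed), genome_map=gmap, seed=seed
            )
            out = vc.anova_single_env(plots, "protein", "env1")
            errs.append(out.s_g2)
        # single-env genotypic variance confounds GEI: expect S_G^2 + S_GE^2
        assert np.mean(errs) == pytest.approx(0.724 + 0.302, rel=0.15)


class TestMultiEnvAnova:
    @staticmethod
    def _two_env_plots(y1, y2):
        return pd.concat(
            [_plots(y1, environment="env1"), _plots(y2, environment="env2")],
            ignore_index=True,
        )

    def test_parallel_responses_have_zero_gei(self):
        y1 = np.array([[10.0, 10], [12, 12], [14, 14]])
        out = vc.anova_multi_env(self._two_env_plots(y1, y1 + 3.0), "t")
        assert out.s_ge2 == pytest.approx(0.0, abs=1e-12)

    def test_single_environment_rejected(self):
        with pytest.raises(ValueError, match="2 environments"):
            vc.anova_multi_env(_plots(np.ones((3, 2))), "t")

    def test_ems_equals_reml_on_balanced_interior_data(self, rng):
        # 12 lines x 2 envs x 2 blocks with all components well interior
        g = rng.normal(0, 2.0, 12)
        ge = rng.normal(0, 1.0, (12, 2))
        b = np.array([[1.5, -1.5], [-2.0, 2.0]])  # strong block contrasts
        e = rng.normal(0, 1.0, (12, 2, 2))
        rows = []
        for i in range(12):
            for j in range(2):
                for r in range(2):
                    rows.append(
                        {"line": f"l{i}", "population": "p",
                         "environment": f"env{j + 1}", "block": r + 1, "trait": "t",
                         "value": 10 + g[i] + ge[i, j] + b[j, r] + e[i, j, r]}
                    )
        plots = pd.DataFrame(rows)
        ems = vc.anova_multi_env(plots, "t")
        reml = vc.reml_components(plots, "t")
        assert not ems.truncated
        for attr in ("s_g2", "s_ge2", "s_block2", "s_e2"):
            assert getattr(ems, attr) == pytest.approx(
                getattr(reml, attr), abs=1e-6
            )

    def test_quadratic_form_oracle_small_instance(self, rng):
        # explicit EMS algebra on a 4 x 2 x 2 instance
        Y = rng.normal(size=(4, 2, 2))
        rows = []
        for i in range(4):
            for j in range(2):
                for r in range(2):
                    rows.append(
                        {"line": f"l{i}", "population": "p",
                         "environment": f"env{j + 1}", "block": r + 1,
                         "trait": "t", "value": Y[i, j, r]}
                    )
        out = vc.anova_multi_env(pd.DataFrame(rows), "t")
        m = Y.mean()
        mi, mj, mij = Y.mean(axis=(1, 2)), Y.mean(axis=(0, 2)), Y.mean(axis=2)
        ms_g = 4 * ((mi - m) ** 2).sum() / 3
        ms_ge = 2 * ((mij - mi[:, None] - mj[None, :] + m) ** 2).sum() / 3
        mjr = Y.mean(axis=0)
        ss_res = ((Y - m) ** 2).sum() - 4 * ((mi - m) ** 2).sum() \
            - 8 * ((mj - m) ** 2).sum() - 4 * ((mjr - mj[:, None]) ** 2).sum() \
            - 2 * ((mij - mi[:, None] - mj[None, :] + m) ** 2).sum()
        ms_e = ss_res / (2 * 3 * 1)
        assert out.s_e2 == pytest.approx(ms_e, abs=1e-12)
        assert out.s_ge2 == pytest.approx(max((ms_ge - ms_e) / 2, 0), abs=1e-12)
        assert out.s_g2 == pytest.approx(max((ms_g - ms_ge) / 4, 0), abs=1e-12)

    def test_population_partition_sums_to_pooled(self, panel):
        _, plots, _ = panel
        pooled = vc.anova_multi_env(plots, "protein")
        nested = vc.anova_multi_env(plots, "protein", include_population=True)
        # among + within population components track the pooled totals
        assert nested.s_r2 + nested.s_gr2 == pytest.approx(pooled.s_g2, rel=0.15)
        assert nested.s_re2 + nested.s_gre2 == pytest.approx(
            pooled.s_ge2, rel=0.25, abs=0.05
        )

    def test_anova_identity_conserves_total_ss(self, panel):
        _, plots, _ = panel
        df = plots[plots.trait == "yield"]
        cube = df.pivot_table(
            index="line", columns=["environment", "block"], values="value"
        ).to_numpy().reshape(306, 3, 3)
        m = cube.mean()
        mi, mj = cube.mean(axis=(1, 2)), cube.mean(axis=(0, 2))
        mij, mjr = cube.mean(axis=2), cube.mean(axis=0)
        parts = (
            9 * ((mi - m) ** 2).sum()
            + 306 * 3 * ((mj - m) ** 2).sum()
            + 306 * ((mjr - mj[:, None]) ** 2).sum()
            + 3 * ((mij - mi[:, None] - mj[None, :] + m) ** 2).sum()
        )
        resid = ((cube - mij[:, :, None] - mjr[None, :, :] + mj[None, :, None]) ** 2).sum()
        assert parts + resid == pytest.approx(((cube - m) ** 2).sum(), rel=1e-10)


class TestDerivedStatistics:
    @pytest.mark.parametrize(
        "s_g2,m,expected", [(4.0, 20.0, 10.0), (0.0, 5.0, 0.0), (0.724, 24.27, 3.506)]
    )
    def test_cv_g(self, s_g2, m, expected):
        assert vc.cv_g(s_g2, m) == pytest.approx(expected, abs=5e-4)

    def test_cv_g_requires_positive_mean(self):
        with pytest.raises(ValueError):
            vc.cv_g(1.0, 0.0)

    def test_single_env_heritability(self):
        assert vc.heritability_single_env(1.0, 0.0, 3).h2 == 1.0
        assert vc.heritability_single_env(1.0, 1.0, 3).h2 == pytest.approx(0.75)
        assert vc.heritability_single_env(1.0, 1.0, 10**9).h2 == pytest.approx(
            1.0, abs=1e-6
        )
        with pytest.raises(ValueError):
            vc.heritability_single_env(0.0, 0.0, 3)

    def test_multi_env_heritability(self):
        assert vc.heritability_multi_env(1, 1, 1, 2, 3).h2 == pytest.approx(0.6)
        # with no GEI it reduces to the single-env formula with e*n replicates
        a = vc.heritability_multi_env(0.7, 0.0, 0.5, 3, 3).h2
        b = vc.heritability_single_env(0.7, 0.5, 9).h2
        assert a == pytest.approx(b, abs=1e-12)

    def test_multi_env_h2_below_no_gei_h2(self):
        with_gei = vc.heritability_multi_env(0.7, 0.3, 0.5, 3, 3).h2
        without = vc.heritability_multi_env(0.7, 0.0, 0.5, 3, 3).h2
        assert with_gei <= without

    @pytest.mark.parametrize(
        "h2,expected", [(1.0, [8.0, 10, 12]), (0.0, [10, 10, 10]), (0.5, [9, 10, 11])]
    )
    def test_blup_shrinkage(self, h2, expected):
        out = vc.blup_line_means(np.array([8.0, 10.0, 12.0]), h2)
        assert np.allclose(out, expected)

    def test_blup_variance_scales_as_h4(self, rng):
        means = rng.normal(size=50)
        out = vc.blup_line_means(means, 0.6)
        assert np.var(out) == pytest.approx(0.6**2 * np.var(means), rel=1e-12)

    def test_phenotypic_correlation_examples(self):
        x = np.arange(1.0, 6.0)
        assert vc.phenotypic_correlation(x, 2 * x + 3) == pytest.approx(1.0)
        assert vc.phenotypic_correlation(x, [2, 1, 4, 3, 5]) == pytest.approx(0.8)
        y = np.array([2.0, -1, -2, -1, 2])  # orthogonal to centered x
        assert vc.phenotypic_correlation(x, y) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            vc.phenotypic_correlation(x, np.ones(5))


class TestGeneticCorrelations:
    def test_env_pair_formula_consistency(self, panel):
        _, plots, _ = panel
        est = vc.genetic_correlation_env_pair(plots, "protein", "env1", "env2")
        means = vc.env_line_means(plots, "protein")
        r = vc.phenotypic_correlation(means["env1"], means["env2"])
        hs = []
        for env in ("env1", "env2"):
            a = vc.anova_single_env(plots, "protein", env)
            hs.append(vc.heritability_single_env(a.s_g2, a.s_e2, a.n).h)
        assert est.r == pytest.approx(r)
        assert est.r_g == pytest.approx(r / (hs[0] * hs[1]))
        assert -1 <= est.r_g_clamped <= 1

    def test_trait_self_correlation_is_one(self, panel):
        _, plots, _ = panel
        dup = plots[plots.trait == "protein"].copy()
        dup["trait"] = "protein2"
        both = pd.concat([plots, dup], ignore_index=True)
        est = vc.genetic_correlation_traits(both, "protein", "protein2", "env1")
        assert est.r_g == pytest.approx(1.0, abs=1e-9)

    def test_trait_negated_correlation_is_minus_one(self, panel):
        _, plots, _ = panel
        neg = plots[plots.trait == "protein"].copy()
        neg["trait"] = "neg"
        neg["value"] *= -1
        both = pd.concat([plots, neg], ignore_index=True)
        est = vc.genetic_correlation_traits(both, "protein", "neg", "env1")
        assert est.r_g == pytest.approx(-1.0, abs=1e-9)
        assert est.se is None or est.se >= 0
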