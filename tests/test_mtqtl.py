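"""Stage-2 engine: Wald tests, Li-Ji threshold, SIM/CIM, elimination, %GV."""

import numpy as np
import pandas as pd
import pytest

import altqtl as aq
from altqtl.genmap import GenotypeMatrix
from altqtl.mtqtl import ScanResult, wald_pvalue


def make_scores(x_cols, chrom=None, pos=None):
    """Wrap raw score columns into a QTLGenotypeScores on a synthetic grid."""
    x = np.column_stack(x_cols)
    m = x.shape[1]
    grid = aq.ScanGrid(
        table=pd.DataFrame({
            "chromosome": chrom if chrom is not None else ["1"] * m,
            "position_cM": pos if pos is not None else np.arange(m, dtype=float),
        }),
        step=1.0,
    )
    return aq.QTLGenotypeScores(values=x, grid=grid,
                                line_ids=[f"l{i}" for i in range(x.shape[0])])


@pytest.fixture(scope="module")
def null3(cfg, gmap):
    """90 lines, 344 markers, three correlated traits, no QTL."""
    geno = aq.simulate_ril_genotypes(gmap, 90, seed=101)
    cfg0 = cfg.replace(qtl=())
    traits = aq.simulate_traits(geno, gmap, cfg0, seed=102, include_error=True)
    return geno, traits


class TestWaldTest:
    def test_single_trait_wald_equals_t_squared(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        n = 60
        x = (rng.random(n) < 0.5).astype(float)
        y = 0.4 * x + rng.normal(0, 1, n)
        traits = pd.DataFrame({"t1": y})
        res = aq.wald_test_at_position(traits, x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.statistic == pytest.approx(float(ols.tvalues[1]) ** 2, abs=1e-8)
        assert res.p == pytest.approx(float(ols.pvalues[1]), abs=1e-10)
        assert res.effects[0] == pytest.approx(float(ols.params[1]), abs=1e-10)
        assert res.ses[0] == pytest.approx(float(ols.bse[1]), abs=1e-10)

    def test_constant_score_rejected(self):
        traits = pd.DataFrame({"t1": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            aq.wald_test_at_position(traits, np.ones(10))

    def test_collinear_with_cofactor_rejected(self):
        rng = np.random.default_rng(2)
        x = (rng.random(40) < 0.5).astype(float)
        traits = pd.DataFrame({"t1": rng.normal(size=40)})
        with pytest.raises(ValueError, match="collinear"):
            aq.wald_test_at_position(traits, x, cofactor_scores=x)

    def test_null_statistic_mean_near_chi2_df(self, null3, gmap):
        """No-QTL scan: mean Wald across positions is near the trait count."""
        geno, traits = null3
        grid = aq.build_scan_grid(gmap, step=5.0)
        scores = aq.genotype_probabilities(geno, gmap, grid)
        scan = aq.sim_scan(traits, scores)
        mean_w = np.nanmean(scan.table["wald"])
        # exact Hotelling mean is k*nu/(nu-k-1) = 3*88/84 = 3.14 at n = 90
        assert 2.5 < mean_w < 3.9


class TestLiJiCorrection:
    def _geno(self, cols, positions=None):
        cols = np.asarray(cols, dtype=float)
        n, m = cols.shape
        markers = [f"m{i}" for i in range(m)]
        gmap = aq.GeneticMap(pd.DataFrame({
            "marker": markers, "chromosome": "1",
            "position_cM": positions if positions is not None
            else np.arange(m, dtype=float),
        }))
        geno = GenotypeMatrix(pd.DataFrame(
            cols, index=[f"l{i}" for i in range(n)], columns=markers))
        return geno, gmap

    def test_orthogonal_markers_give_m(self):
        # full 2^4 factorial: columns exactly uncorrelated -> M_eff = 4
        levels = np.array(np.meshgrid(*[[0, 1]] * 4)).reshape(4, -1).T
        geno, gmap = self._geno(levels)
        assert aq.effective_number_of_tests(geno, gmap) == pytest.approx(4.0)

    def test_duplicated_markers_give_one(self):
        rng = np.random.default_rng(3)
        col = (rng.random(50) < 0.5).astype(float)
        geno, gmap = self._geno(np.column_stack([col, col]))
        assert aq.effective_number_of_tests(geno, gmap) == pytest.approx(1.0)

    def test_matches_bruteforce_eigendecomposition(self, gmap):
        geno = aq.simulate_ril_genotypes(gmap, 2000, seed=9)
        # independently coded oracle on the chromosome-1 block of 20 markers
        sub_map = aq.GeneticMap(gmap.table[gmap.table["chromosome"] == "1"]
                                .iloc[:20])
        cols = sub_map.table["marker"].tolist()
        sub = GenotypeMatrix(geno.data[cols])
        lam = np.linalg.eigvalsh(np.corrcoef(sub.data.to_numpy(), rowvar=False))
        lam = np.round(np.clip(lam, 0, None), 8)
        expected = np.sum((lam >= 1) + (lam - np.floor(lam)))
        got = aq.effective_number_of_tests(sub, sub_map)
        assert got == pytest.approx(expected, abs=1e-9)
        assert 1.0 < got < 20.0

    def test_threshold_is_sidak_for_independent_markers(self):
        levels = np.array(np.meshgrid(*[[0, 1]] * 4)).reshape(4, -1).T
        geno, gmap = self._geno(levels)
        cutoff = aq.genomewide_threshold(geno, gmap, alpha=0.05)
        assert cutoff == pytest.approx(1 - 0.95 ** (1 / 4))

    def test_invalid_alpha(self, dataset, gmap):
        with pytest.raises(ValueError):
            aq.genomewide_threshold(dataset.genotypes, gmap, alpha=1.5)


class TestCandidateSelection:
    def _scan(self, neglog, pos=None, chrom=None):
        m = len(neglog)
        table = pd.DataFrame({
            "chromosome": chrom if chrom is not None else ["1"] * m,
            "position_cM": pos if pos is not None else np.arange(m, dtype=float),
            "wald": np.nan, "p": np.nan, "neglog10p": neglog,
        })
        return ScanResult(table=table, threshold=3.0)

    def test_subthreshold_profile_gives_empty_set(self):
        assert aq.select_candidates(self._scan([0.5, 1.0, 2.0, 2.9])) == ()

    def test_single_peak_at_argmax(self):
        idx = aq.select_candidates(self._scan([1.0, 4.0, 6.0, 4.0, 1.0]))
        assert idx == (2,)

    def test_two_separated_peaks_both_kept(self):
        pos = np.arange(0.0, 101.0, 10.0)
        v = np.zeros(len(pos))
        v[1] = 6.0   # 10 cM
        v[8] = 5.0   # 80 cM
        idx = aq.select_candidates(self._scan(v, pos=pos), min_separation=30.0)
        assert idx == (1, 8)

    def test_close_peaks_keep_strongest(self):
        pos = np.arange(0.0, 51.0, 10.0)
        v = np.array([0.0, 6.0, 0.0, 5.0, 0.0, 0.0])
        idx = aq.select_candidates(self._scan(v, pos=pos), min_separation=30.0)
        assert idx == (1,)

    def test_tie_broken_toward_lower_cm(self):
        v = np.array([0.0, 5.0, 0.0, 5.0, 0.0])
        idx = aq.select_candidates(self._scan(v), min_separation=10.0)
        assert idx == (1,)


class TestCIM:
    def _two_qtl(self, d_cM, seed=4, n=200, effects=(0.8, 0.5)):
        """Two QTL separated by d_cM on one long chromosome plus traits."""
        markers = np.arange(0.0, 301.0, 10.0)
        gmap = aq.GeneticMap(pd.DataFrame({
            "marker": [f"m{i}" for i in range(len(markers))],
            "chromosome": "1", "position_cM": markers,
        }))
        geno = aq.simulate_ril_genotypes(gmap, n, seed=seed)
        q1, q2 = 100.0, 100.0 + d_cM
        x1 = geno.data.iloc[:, int(q1 // 10)].to_numpy()
        x2 = geno.data.iloc[:, int(q2 // 10)].to_numpy()
        rng = np.random.default_rng(seed + 1)
        y = effects[0] * x1 + effects[1] * x2 + rng.normal(0, 0.5, n)
        traits = pd.DataFrame({"t1": y}, index=geno.line_ids)
        grid = aq.build_scan_grid(gmap, 2.0)
        scores = aq.genotype_probabilities(geno, gmap, grid)
        gpos = grid.table["position_cM"].to_numpy()
        return traits, scores, int(np.argmin(np.abs(gpos - q1))), \
            int(np.argmin(np.abs(gpos - q2)))

    def test_zero_cofactors_identical_to_sim(self, null3, gmap):
        geno, traits = null3
        grid = aq.build_scan_grid(gmap, step=10.0)
        scores = aq.genotype_probabilities(geno, gmap, grid)
        sim = aq.sim_scan(traits, scores)
        cim = aq.cim_scan(traits, scores, cofactors=(), window=30.0)
        pd.testing.assert_frame_equal(sim.table, cim.table)

    def test_cofactor_at_tested_position_is_excluded(self):
        traits, scores, i1, i2 = self._two_qtl(d_cM=150.0)
        sim = aq.sim_scan(traits, scores)
        cim = aq.cim_round(traits, scores, candidates=(i1,), window=30.0)
        # within the window around the cofactor the test reduces to SIM
        assert cim.table["wald"].iloc[i1] == pytest.approx(
            sim.table["wald"].iloc[i1])

    def test_partialling_removes_linked_qtl_inflation(self):
        """Conditioning on a linked QTL shrinks the marginal effect to truth.

        With positively linked QTL the SIM effect at the first position is
        inflated by corr * beta2; the CIM effect partials that out.
        """
        traits, scores, i1, i2 = self._two_qtl(d_cM=40.0, effects=(0.8, 0.8))
        e_sim = aq.wald_test_at_position(traits, scores.values[:, i1]).effects[0]
        e_cim = aq.wald_test_at_position(
            traits, scores.values[:, i1],
            cofactor_scores=scores.values[:, i2]).effects[0]
        assert e_cim < e_sim
        assert abs(e_cim - 0.8) < abs(e_sim - 0.8)

    def test_unlinked_cofactor_leaves_effect_unbiased(self):
        traits, scores, i1, i2 = self._two_qtl(d_cM=180.0)
        e_sim = aq.wald_test_at_position(traits, scores.values[:, i1]).effects[0]
        e_cim = aq.wald_test_at_position(
            traits, scores.values[:, i1],
            cofactor_scores=scores.values[:, i2]).effects[0]
        assert e_cim == pytest.approx(e_sim, abs=0.06)


class TestBackwardElimination:
    def test_strong_qtl_survives(self):
        rng = np.random.default_rng(8)
        n = 120
        x = (rng.random(n) < 0.5).astype(float)
        traits = pd.DataFrame({"t1": 1.0 * x + rng.normal(0, 0.3, n)})
        scores = make_scores([x])
        assert aq.backward_eliminate(traits, scores, (0,), p_cutoff=1e-3) == (0,)

    def test_weaker_collinear_candidate_eliminated(self):
        rng = np.random.default_rng(9)
        n = 150
        x = (rng.random(n) < 0.5).astype(float)
        # nearly collinear spurious copy (2% flipped)
        x2 = x.copy()
        flip = rng.random(n) < 0.02
        x2[flip] = 1 - x2[flip]
        traits = pd.DataFrame({"t1": 1.2 * x + rng.normal(0, 0.3, n)})
        scores = make_scores([x, x2])
        kept = aq.backward_eliminate(traits, scores, (0, 1), p_cutoff=1e-3)
        assert kept == (0,)

    def test_may_return_empty_set(self):
        rng = np.random.default_rng(10)
        n = 80
        x = (rng.random(n) < 0.5).astype(float)
        traits = pd.DataFrame({"t1": rng.normal(size=n)})
        scores = make_scores([x])
        assert aq.backward_eliminate(traits, scores, (0,), p_cutoff=1e-6) == ()


class TestEffectsAndGV:
    def test_high_value_parent_follows_sign(self):
        rng = np.random.default_rng(11)
        n = 200
        x = (rng.random(n) < 0.5).astype(float)
        traits = pd.DataFrame({
            "up": 0.8 * x + rng.normal(0, 0.2, n),
            "down": -0.8 * x + rng.normal(0, 0.2, n),
            "flat": rng.normal(0, 0.2, n),
        })
        scores = make_scores([x])
        qtl = aq.estimate_qtl_effects(traits, scores, (0,), parent_a="BR007",
                                      parent_b="SC283")
        by_trait = qtl.set_index("trait")
        assert by_trait.loc["up", "high_value_allele"] == "SC283"
        assert by_trait.loc["down", "high_value_allele"] == "BR007"
        assert by_trait.loc["flat", "effect"] == pytest.approx(0.0, abs=0.1)
        assert np.isfinite(by_trait["se"]).all()

    def test_no_qtl_gives_empty_gv(self):
        traits = pd.DataFrame({"t1": np.random.default_rng(0).normal(size=30)})
        scores = make_scores([np.zeros(30)])
        base = aq.fit_base_model(traits)
        gv = aq.percent_genetic_variance(traits, scores, (), base)
        assert gv.empty

    def test_engineered_50_percent_gv(self):
        """QTL built to explain half the genetic variance reports ~50%."""
        rng = np.random.default_rng(12)
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        beta = 1.0
        qtl_var = beta**2 * 0.25
        poly = rng.normal(0, np.sqrt(qtl_var), n)  # equal polygenic share
        traits = pd.DataFrame({"t1": beta * x + poly})
        scores = make_scores([x])
        base = aq.fit_base_model(traits)
        gv = aq.percent_genetic_variance(traits, scores, (0,), base)
        assert gv.loc[gv.index[0], "t1"] == pytest.approx(50.0, abs=2.0)

    def test_unlinked_gv_adds_up(self):
        rng = np.random.default_rng(13)
        n = 4000
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
        traits = pd.DataFrame(
            {"t1": 0.8 * x1 + 0.5 * x2 + rng.normal(0, 0.3, n)})
        scores = make_scores([x1, x2], chrom=["1", "2"], pos=[10.0, 10.0])
        base = aq.fit_base_model(traits)
        gv = aq.percent_genetic_variance(traits, scores, (0, 1), base)
        total = gv.loc["Total", "t1"]
        assert total == pytest.approx(gv.iloc[0]["t1"] + gv.iloc[1]["t1"], abs=1.5)


class TestBaseModel:
    def test_uncorrelated_traits_near_zero_offdiagonal(self):
        rng = np.random.default_rng(14)
        traits = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc"))
        fit = aq.fit_base_model(traits)
        off = fit.sigma.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_duplicate_trait_column_takes_ridge_path(self):
        rng = np.random.default_rng(15)
        y = rng.normal(size=50)
        traits = pd.DataFrame({"a": y, "b": y})
        fit = aq.fit_base_model(traits)
        assert np.linalg.matrix_rank(fit.sigma.to_numpy()) == 2

    def test_covariance_recovery(self, cfg, gmap):
        """Polygenic correlations recovered on average at n = 90."""
        target = cfg.polygenic_covariance()
        cfg0 = cfg.replace(qtl=(), blue_error_var=(0.0, 0.0, 0.0))
        geno = aq.simulate_ril_genotypes(gmap, 90, seed=16)
        sigmas = []
        for rep in range(60):
            traits = aq.simulate_traits(geno, gmap, cfg0, seed=1000 + rep)
            sigmas.append(aq.fit_base_model(traits).sigma.to_numpy())
        mean_sigma = np.mean(sigmas, axis=0)
        assert np.abs(mean_sigma - target).max() < 0.02

    def test_too_few_lines_rejected(self):
        traits = pd.DataFrame(np.zeros((3, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            aq.fit_base_model(traits)

    def test_error_floor_subtracted(self):
        rng = np.random.default_rng(17)
        traits = pd.DataFrame({"a": rng.normal(0, 1, 3000)})
        fit = aq.fit_base_model(traits, error_floors={"a": 0.5})
        assert fit.polygenic_var["a"] == pytest.approx(0.5, abs=0.08)


class TestPValueMethods:
    def test_f_and_chi2_agree_at_large_n(self):
        w = 12.0
        assert wald_pvalue(w, 3, 100000, "f") == pytest.approx(
            wald_pvalue(w, 3, 100000, "chi2"), rel=1e-2)

    def test_f_heavier_tail_at_small_n(self):
        assert wald_pvalue(19.0, 3, 88, "f") > wald_pvalue(19.0, 3, 88, "chi2")
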