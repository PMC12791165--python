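"""REML mixed models: BLUPs, variance components, outliers, heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from npqmap.trial import (
    MixedModelSpec,
    TrialFit,
    VarianceComponents,
    detect_outliers,
    fit_reml,
    fit_trait,
    heritability,
    multi_trait_score,
    trait_correlations,
)


def _one_way(n_groups, n_rep, s2g, s2e, seed, mu=0.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2g), n_groups)
    rows = []
    for i in range(n_groups):
        for r in range(n_rep):
            rows.append(
                dict(
                    accession=f"A{i:03d}",
                    set=f"S{r % 2}",
                    block=f"B{r}",
                    row=len(rows) // 24,
                    col=len(rows) % 24,
                    y=mu + g[i] + rng.normal(0, np.sqrt(s2e)),
                )
            )
    return pd.DataFrame(rows)


SPEC_IND = MixedModelSpec(response="y", residual="independent")


class TestREML:
    def test_blup_matches_closed_form_shrinkage(self):
        # balanced one-way model: BLUP_i = n*s2g/(n*s2g+s2e) * (ybar_i - ybar)
        df = _one_way(2, 8, 2.0, 1.0, seed=1)
        fit = fit_reml(df, SPEC_IND)
        s2g, s2e = fit.vc.sigma2["g"], fit.vc.resid
        ybar = df.groupby("accession")["y"].mean()
        shrink = 8 * s2g / (8 * s2g + s2e)
        expected = shrink * (ybar - ybar.mean())
        np.testing.assert_allclose(
            fit.blups.set_index("accession")["blup"], expected, atol=1e-8
        )

    def test_blups_sum_to_zero(self):
        df = _one_way(30, 3, 1.0, 1.0, seed=2)
        fit = fit_reml(df, SPEC_IND)
        assert abs(fit.blups["blup"].sum()) < 1e-6

    def test_component_recovery_balanced(self):
        # sigma_g^2 = sigma_e^2 = 1; average over a few replicates
        ests = []
        for seed in range(6):
            df = _one_way(150, 4, 1.0, 1.0, seed=10 + seed)
            ests.append(fit_reml(df, SPEC_IND).vc.sigma2["g"])
        assert np.mean(ests) == pytest.approx(1.0, abs=0.15)

    def test_null_genetic_variance_at_boundary(self):
        df = _one_way(60, 4, 0.0, 1.0, seed=3)
        fit = fit_reml(df, SPEC_IND)
        assert fit.vc.sigma2["g"] < 0.05
        assert heritability(fit) < 0.15  # ~0 downstream

    def test_shift_invariance_of_blups(self):
        df = _one_way(40, 3, 1.0, 1.0, seed=4)
        fit0 = fit_reml(df, SPEC_IND)
        df2 = df.assign(y=df["y"] + 100.0)
        fit1 = fit_reml(df2, SPEC_IND)
        np.testing.assert_allclose(
            fit0.blups["blup"], fit1.blups["blup"], atol=1e-3
        )
        assert fit1.mu == pytest.approx(fit0.mu + 100.0, abs=1e-3)

    def test_ar1_matches_independent_at_zero_rho(self):
        from npqmap.trial import _REMLProblem, _build_terms, _resid_dists

        df = _one_way(40, 4, 1.0, 1.0, seed=5)
        ind = fit_reml(df, MixedModelSpec(response="y", residual="independent"))
        ar1 = fit_reml(df, MixedModelSpec(response="y", residual="ar1ar1"))
        # with rho pinned at 0 the AR1 likelihood equals the independent one
        y = df["y"].to_numpy() - df["y"].mean()
        spec = MixedModelSpec(response="y", residual="ar1ar1")
        X, Z, ZZt, _, env = _build_terms(df, spec)
        dr, dc, same = _resid_dists(df, spec, env)
        prob_ar1 = _REMLProblem(y, X, ZZt, dr, dc, same, ar1=True)
        prob_ind = _REMLProblem(y, X, ZZt)
        theta = np.log([ind.vc.sigma2["g"], ind.vc.sigma2["s"],
                        ind.vc.sigma2["b"], ind.vc.resid])
        assert prob_ar1.neg_reml(np.concatenate([theta, [0.0, 0.0]])) == (
            pytest.approx(prob_ind.neg_reml(theta), abs=1e-8)
        )
        # and the optimized AR1 fit can only match or exceed it
        assert ar1.vc.loglik >= ind.vc.loglik - 1e-4

    def test_ar1_rho_recovered(self):
        # AR1xAR1 field with rho_row = 0.6 on a 12x14 grid
        rng = np.random.default_rng(6)
        nrow, ncol = 12, 14
        idx = np.arange(nrow)
        Lr = np.linalg.cholesky(0.6 ** np.abs(idx[:, None] - idx[None, :]))
        field = Lr @ rng.standard_normal((nrow, ncol))
        rows = []
        for r in range(nrow):
            for c in range(ncol):
                rows.append(
                    dict(accession=f"A{(r * ncol + c) % 56:03d}", set="S0",
                         block=f"B{c % 4}", row=r, col=c, y=field[r, c])
                )
        df = pd.DataFrame(rows)
        fit = fit_reml(df, MixedModelSpec(response="y", residual="ar1ar1"))
        assert fit.vc.rho_row == pytest.approx(0.6, abs=0.25)

    def test_aic_selects_a_structure(self):
        df = _one_way(30, 4, 1.0, 1.0, seed=7)
        fit = fit_reml(df, MixedModelSpec(response="y", residual="aic"))
        assert fit.vc.structure in ("independent", "ar1ar1")

    def test_joint_model_needs_two_environments(self):
        df = _one_way(20, 2, 1.0, 1.0, seed=8).assign(year="2017")
        with pytest.raises(ValueError, match="environments"):
            fit_reml(df, MixedModelSpec(response="y", env_col="year",
                                        residual="independent"))

    def test_heritability_arithmetic(self):
        vc = VarianceComponents({"g": 2.0}, 1.0, 0, 0, 0.0, 0.0, "independent", True)
        blups = pd.DataFrame({"accession": ["a"], "blup": [0.0],
                              "adjusted_mean": [0.0], "pev": [0.0]})
        fit = TrialFit(SPEC_IND, vc, 0.0, blups, pd.Series(dtype=float), 1)
        assert heritability(fit) == 1.0  # mean PEV = 0
        fit.blups["pev"] = 2.0
        assert heritability(fit) == 0.0  # mean PEV = sigma_g^2


class TestOutliers:
    def test_equal_residuals_no_outliers(self):
        with pytest.warns(UserWarning, match="MAD"):
            out = detect_outliers(pd.Series(np.ones(50)))
        assert out == []

    def test_single_extreme_residual_flagged(self):
        # one residual at 10 re-scaled-MAD units among n=960:
        # Holm-adjusted two-sided normal p = 960 * 2 * sf(10) ~ 1.5e-20 < 0.05
        rng = np.random.default_rng(9)
        r = pd.Series(rng.standard_normal(960))
        mad = 1.4826 * np.median(np.abs(r - r.median()))
        r.iloc[0] = r.median() + 10 * mad
        oracle_p = 960 * 2 * stats.norm.sf(10)
        assert oracle_p < 0.05
        assert r.index[0] in detect_outliers(r)

    def test_null_false_flag_rate(self):
        # clean Gaussian residuals: family-wise flags controlled at 5%
        flagged = 0
        n_rep = 40
        for seed in range(n_rep):
            r = pd.Series(np.random.default_rng(100 + seed).standard_normal(960))
            if detect_outliers(r):
                flagged += 1
        assert flagged / n_rep <= 0.1

    def test_refit_after_outlier_removal(self):
        df = _one_way(40, 4, 1.0, 0.5, seed=10)
        df.loc[df.index[3], "y"] += 25.0
        fit = fit_trait(df, SPEC_IND)
        assert df.index[3] in fit.outliers
        assert fit.n_obs == len(df) - len(fit.outliers)


class TestDownstreamSummaries:
    def test_self_correlation_and_holm_monotonicity(self, rng):
        wide = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        wide["b"] += wide["a"]
        r, p, p_holm = trait_correlations(wide)
        assert np.allclose(np.diag(r), 1.0)
        off = ~np.eye(4, dtype=bool)
        assert (p_holm.to_numpy()[off] >= p.to_numpy()[off] - 1e-15).all()
        assert r.loc["a", "b"] > 0.5

    def test_constant_trait_flagged_nan(self, rng):
        wide = pd.DataFrame({"a": rng.standard_normal(20), "b": np.ones(20)})
        r, p, _ = trait_correlations(wide)
        assert np.isnan(r.loc["a", "b"])

    def test_multi_trait_score_closed_cases(self):
        # panel of 3 engineered so each trait has mean 0, sd 1
        from npqmap.traits import MULTI_TRAIT_SCORE_TRAITS

        wide = pd.DataFrame(
            {t: [-1.0, 0.0, 1.0] for t in MULTI_TRAIT_SCORE_TRAITS},
            index=["low", "mid", "high"],
        )
        score = multi_trait_score(wide)
        assert score.loc["mid", "score"] == pytest.approx(0.0)
        assert score.loc["high", "score"] == pytest.approx(3.0)
        assert score.loc["high", "rank"] == 1

    def test_missing_trait_value_excludes_accession(self):
        from npqmap.traits import MULTI_TRAIT_SCORE_TRAITS

        wide = pd.DataFrame(
            {t: [1.0, 2.0, np.nan] for t in MULTI_TRAIT_SCORE_TRAITS},
            index=["a", "b", "c"],
        )
        assert "c" not in multi_trait_score(wide).index
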