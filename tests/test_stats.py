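"""Beta mixed model, moderation OLS and Johnson-Neyman regions."""

import numpy as np
import pandas as pd
import pytest

from natpipe.connectome import DENSITY_GRID
from natpipe.errors import ContractError, DomainError
from natpipe.stats import (
    GLMMSpec,
    ModerationFit,
    fit_beta_glmm,
    fit_moderation,
    glmm_design,
    johnson_neyman,
    simulate_beta_glmm,
)
from natpipe.synthetic import CohortConfig, generate_cohort, profiles_frame

TRUE_BETA = np.array([-0.5, 0.08, 0.0, 0.01, 0.001, 0.05, 0.6, 0.03, 0.06])
TRUE_PHI, TRUE_SIGMA = 80.0, 0.3


def study_long_frame(seed=3, nat=0.5):
    """22 PD participants x 9 densities with study-like covariates."""
    pf = profiles_frame(generate_cohort(CohortConfig(seed=seed)))
    pf = pf[pf["group"] == "PD"]
    rows = []
    for _, r in pf.iterrows():
        for d in DENSITY_GRID:
            rows.append(dict(participant=r.participant, dat=r.dat, pa=r.pa,
                             education=r.education, age=r.age, sex=r.sex,
                             density=d, sequence=r.sequence, nat=nat))
    return pd.DataFrame(rows)


def simulated_frame(seed=3, beta=TRUE_BETA, rng=None):
    df = study_long_frame(seed)
    X, names, y, groups = glmm_design(df, GLMMSpec())
    rng = rng or np.random.default_rng(seed)
    df["nat"] = simulate_beta_glmm(X, beta, TRUE_PHI, TRUE_SIGMA, groups, rng)
    return df


class TestGLMMDesign:
    def test_198_rows_and_eight_slopes(self):
        X, names, y, groups = glmm_design(study_long_frame(), GLMMSpec())
        assert X.shape == (198, 9)       # intercept + 8 slopes
        assert len(names) == 9
        assert names[0] == "intercept"
        assert len(np.unique(groups)) == 22

    def test_sequence_contrast_requires_observations(self):
        df = study_long_frame()
        df["sequence"] = 1
        with pytest.raises(ContractError, match="sequence"):
            glmm_design(df, GLMMSpec())
        X, names, *_ = glmm_design(df, GLMMSpec(include_sequence=False))
        assert X.shape[1] == 7


class TestFitBetaGLMM:
    def test_recovers_planted_coefficients(self):
        fit = fit_beta_glmm(simulated_frame(seed=3))
        assert fit.converged
        assert fit.n_obs == 198 and fit.n_groups == 22
        # between-participant covariates have only 22 effective observations
        # and asymptotic Wald SEs run anticonservative at that cluster count,
        # so the per-term bound is loose; the within-participant density
        # slope is held to its 95% CI
        for name, truth in zip(fit.table.index[1:], TRUE_BETA[1:]):
            row = fit.table.loc[name]
            assert abs(row.estimate - truth) < 6 * row.se, name
        row = fit.table.loc["density"]
        assert row.ci_low <= TRUE_BETA[6] <= row.ci_high
        assert fit.phi == pytest.approx(TRUE_PHI, rel=0.35)
        assert fit.sigma_u == pytest.approx(TRUE_SIGMA, rel=0.5)
        assert 0 <= fit.pseudo_r2 <= 1

    def test_null_generation_gives_null_slopes(self):
        beta = np.r_[-0.5, np.zeros(8)]
        df = simulated_frame(seed=5, beta=beta)
        fit = fit_beta_glmm(df)
        z = fit.table["z"].iloc[1:].abs()
        assert (z < 4).all()
        assert (z < 2).sum() >= 6

    def test_row_order_invariance(self):
        df = simulated_frame(seed=7)
        fit_a = fit_beta_glmm(df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_b = fit_beta_glmm(shuffled)
        assert np.allclose(fit_a.table["estimate"], fit_b.table["estimate"],
                           rtol=1e-3, atol=1e-4)

    def test_boundary_response_nudged_with_warning(self):
        df = simulated_frame(seed=9)
        df.loc[df.index[0], "nat"] = 1.0
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_beta_glmm(df)
        assert fit.converged

    def test_single_observation_participant_rejected(self):
        df = simulated_frame(seed=3)
        df = df.drop(df[df.participant == "PD01"].index[1:])
        with pytest.raises(ContractError):
            fit_beta_glmm(df)


def moderation_data(n=200, interaction=-0.08, noise=1.0, seed=1):
    r = np.random.default_rng(seed)
    df = pd.DataFrame(dict(
        participant=[f"P{i}" for i in range(n)],
        nat=r.uniform(0.2, 0.8, n),
        pa=r.lognormal(4.0, 0.8, n),
        education=r.normal(15, 3, n),
        dat=r.normal(-3.6, 0.7, n),
        age=r.normal(62, 8, n),
        sex=r.choice(["f", "m"], n),
        sequence=r.choice([1, 2, 3], n),
    ))
    df["gmp"] = (2 + 5 * df.nat + 0.05 * df.pa + interaction * df.nat * df.pa
                 + r.normal(0, noise, n))
    return df


class TestFitModeration:
    def test_recovers_planted_interaction(self):
        fit = fit_moderation(moderation_data(), outcome="gmp")
        row = fit.table.loc[fit.interaction_term]
        assert abs(row.estimate - (-0.08)) < 2 * row.se

    def test_constant_moderator_rejected_by_name(self):
        df = moderation_data(n=50)
        df["pa"] = 40.0
        with pytest.raises(DomainError, match="pa"):
            fit_moderation(df, outcome="gmp")

    def test_missing_outcome_drops_case(self):
        df = moderation_data(n=22)
        df.loc[df.index[0], "gmp"] = np.nan
        fit = fit_moderation(df, outcome="gmp")
        assert fit.n_obs == 21


class TestJohnsonNeyman:
    @staticmethod
    def _manual_fit(b1, b3, v11, v13, v33, df=20.0, lo=0.0, hi=100.0):
        terms = ["Intercept", "nat", "pa", "nat:pa"]
        table = pd.DataFrame(
            {"estimate": [0.0, b1, 0.0, b3]}, index=terms)
        cov = pd.DataFrame(np.zeros((4, 4)), index=terms, columns=terms)
        cov.loc["nat", "nat"] = v11
        cov.loc["nat", "nat:pa"] = cov.loc["nat:pa", "nat"] = v13
        cov.loc["nat:pa", "nat:pa"] = v33
        return ModerationFit(
            outcome="gmp", predictor="nat", moderator="pa", table=table,
            cov=cov, df_resid=df, fvalue=1.0, f_pvalue=0.5, n_obs=24,
            moderator_range=(lo, hi), predictor_term="nat",
            interaction_term="nat:pa")

    def test_zero_interaction_all_or_nothing(self):
        strong = johnson_neyman(self._manual_fit(5.0, 0.0, 1.0, 0.0, 0.0))
        assert strong.status == "everywhere"
        weak = johnson_neyman(self._manual_fit(0.5, 0.0, 1.0, 0.0, 0.0))
        assert weak.status == "nowhere"

    def test_boundaries_match_grid_search_oracle(self):
        """The analytic boundaries agree to 4 decimals with an oracle that
        recomputes the conditional t directly from the OLS output on a
        dense moderator grid (brackets refined by bisection)."""
        from scipy.optimize import brentq
        from scipy.stats import t as t_dist

        fit = fit_moderation(moderation_data(n=60, noise=3.0, seed=4),
                             outcome="gmp")
        region = johnson_neyman(fit)
        b1 = fit.table.loc["nat", "estimate"]
        b3 = fit.table.loc[fit.interaction_term, "estimate"]
        v11 = fit.cov.loc["nat", "nat"]
        v13 = fit.cov.loc["nat", fit.interaction_term]
        v33 = fit.cov.loc[fit.interaction_term, fit.interaction_term]
        t_crit = t_dist.ppf(0.975, fit.df_resid)

        def abs_t_minus_crit(w):
            se = np.sqrt(v11 + 2 * w * v13 + w ** 2 * v33)
            return abs(b1 + b3 * w) / se - t_crit

        lo, hi = fit.moderator_range
        grid = np.linspace(lo, hi, 100_000)
        sig = np.array([abs_t_minus_crit(w) for w in grid]) >= 0
        idx = np.flatnonzero(np.diff(sig.astype(int)))
        crossings = [brentq(abs_t_minus_crit, grid[i], grid[i + 1])
                     for i in idx]
        assert len(crossings) == len(region.boundaries)
        for found, oracle in zip(sorted(region.boundaries), sorted(crossings)):
            assert found == pytest.approx(oracle, abs=1e-4)

    def test_boundary_p_equals_alpha(self):
        from scipy.stats import t as t_dist
        fit = fit_moderation(moderation_data(n=60, noise=3.0, seed=4),
                             outcome="gmp")
        for alpha in (0.05, 0.01):
            region = johnson_neyman(fit, alpha=alpha)
            for b in region.boundaries:
                p = 2 * t_dist.sf(abs(region.t_stat(b)), region.df)
                assert p == pytest.approx(alpha, abs=1e-10)

    def test_below_knot_moderation_yields_lower_interval(self):
        """A moderation planted only below a PA knot is detected as a lower
        interval of the moderator range."""
        r = np.random.default_rng(2)
        n = 300
        pa = r.uniform(0, 100, n)
        nat = r.uniform(0.2, 0.8, n)
        knot = 45.0
        y = 1.0 + 5.0 * nat - 0.08 * nat * np.minimum(pa, knot) \
            + r.normal(0, 1.5, n)
        df = pd.DataFrame(dict(
            participant=[f"P{i}" for i in range(n)], nat=nat, pa=pa,
            education=r.normal(15, 3, n), dat=r.normal(-3.6, 0.7, n),
            age=r.normal(62, 8, n), sex=r.choice(["f", "m"], n),
            sequence=r.choice([1, 2, 3], n), gmp=y))
        region = johnson_neyman(fit_moderation(df, outcome="gmp"))
        assert region.regions
        first = region.regions[0]
        assert first[0] == pytest.approx(region.moderator_range[0])
        assert first[2] == 1
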