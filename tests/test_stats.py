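"""Within-subject ANOVA and mixed regression against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import herdlab as hl

FACTORS = ["A", "B", "C"]


def random_table(rng, n_teams=10, effects=None):
    """Balanced 2x2x2 within-subject table, one value per team x cell."""
    cells = list(itertools.product([0, 1], repeat=3))
    rows = []
    for team in range(n_teams):
        base = rng.normal(scale=1.0)
        for cell in cells:
            val = base + rng.normal()
            if effects:
                for eff, size in effects.items():
                    sign = np.prod([1 if cell[i] == 0 else -1 for i in eff])
                    val += 0.5 * size * sign
            rows.append(
                {"team_id": team, "A": cell[0], "B": cell[1], "C": cell[2], "value": val}
            )
    return pd.DataFrame(rows)


def ss_oracle(df):
    """Sums-of-squares oracle by explicit marginal-mean decomposition."""
    teams = sorted(df["team_id"].unique())
    cells = list(itertools.product([0, 1], repeat=3))
    Y = np.array(
        [
            [
                df[
                    (df.team_id == t) & (df.A == a) & (df.B == b) & (df.C == c)
                ]["value"].mean()
                for (a, b, c) in cells
            ]
            for t in teams
        ]
    )  # (n, 8)
    n = len(teams)

    def marginal(data, cell, sub):
        """Mean of data over cells matching `cell` on the factor subset `sub`."""
        idx = [
            j
            for j, other in enumerate(cells)
            if all(other[i] == cell[i] for i in sub)
        ]
        return data[..., idx].mean(axis=-1)

    out = {}
    for r in (1, 2, 3):
        for eff in itertools.combinations(range(3), r):
            # Moebius / inclusion-exclusion effect term per cell
            def effect_terms(data):
                terms = np.zeros(data.shape[:-1] + (len(cells),))
                for j, cell in enumerate(cells):
                    acc = 0.0
                    for rr in range(len(eff) + 1):
                        for sub in itertools.combinations(eff, rr):
                            acc += (-1) ** (len(eff) - len(sub)) * marginal(
                                data, cell, sub
                            )
                    terms[..., j] = acc
                return terms

            grand_terms = effect_terms(Y.mean(axis=0))
            subj_terms = effect_terms(Y)
            ss_eff = n * float((grand_terms**2).sum())
            ss_err = float(((subj_terms - grand_terms) ** 2).sum())
            F = (ss_eff / 1.0) / (ss_err / (n - 1))
            out[":".join(FACTORS[i] for i in eff)] = (F, ss_eff, ss_err)
    return out


class TestRMAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(5):
            df = random_table(rng, effects={(0,): 0.8, (1, 2): 0.5})
            tab = hl.rm_anova(df, "value", FACTORS, "team_id")
            oracle = ss_oracle(df)
            for eff, (F, ss_eff, ss_err) in oracle.items():
                assert tab.loc[eff, "F"] == pytest.approx(F, rel=1e-10, abs=1e-10)
                assert tab.loc[eff, "ss_effect"] == pytest.approx(ss_eff, rel=1e-9)
                assert tab.loc[eff, "ss_error"] == pytest.approx(ss_err, rel=1e-9)

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        df = random_table(rng, effects={(1,): 1.0}).rename(
            columns={"A": "tn", "B": "vis", "C": "pert"}
        )
        factors = ["tn", "vis", "pert"]
        tab = hl.rm_anova_2x2x2(df, "value", factors, "team_id")
        sm_tab = AnovaRM(
            df, depvar="value", subject="team_id", within=factors
        ).fit().anova_table
        for sm_eff in sm_tab.index:
            assert tab.loc[sm_eff, "F"] == pytest.approx(
                sm_tab.loc[sm_eff, "F Value"], rel=1e-8
            )

    def test_null_factor_gives_zero_F(self, rng):
        df = random_table(rng)
        # force identical values across C's two levels for every team
        piv = df.pivot_table(index=["team_id", "A", "B"], columns="C", values="value")
        piv[1] = piv[0]
        df2 = piv.stack().reset_index().rename(columns={0: "value"})
        tab = hl.rm_anova(df2, "value", FACTORS, "team_id")
        assert tab.loc["C", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_single_factor_F_equals_squared_paired_t(self, rng):
        for _ in range(5):
            n = 12
            df = pd.DataFrame(
                {
                    "team_id": np.repeat(np.arange(n), 2),
                    "A": np.tile([0, 1], n),
                    "value": rng.normal(size=2 * n) + np.tile([0.0, 0.4], n),
                }
            )
            tab = hl.rm_anova(df, "value", ["A"], "team_id")
            wide = df.pivot(index="team_id", columns="A", values="value")
            t, p = sps.ttest_rel(wide[0], wide[1])
            assert tab.loc["A", "F"] == pytest.approx(t**2, rel=1e-8)
            assert tab.loc["A", "p"] == pytest.approx(p, rel=1e-8)

    def test_partial_eta_squared_identity(self, rng):
        tab = hl.rm_anova(random_table(rng, effects={(0,): 1.0}), "value",
                          FACTORS, "team_id")
        for eff, row in tab.iterrows():
            expected = row.F * row.df1 / (row.F * row.df1 + row.df2)
            assert row.partial_eta_sq == pytest.approx(expected, rel=1e-10)

    def test_epsilon_is_one_for_two_level_factors(self, rng):
        tab = hl.rm_anova(random_table(rng), "value", FACTORS, "team_id")
        assert (tab["eps_gg"] == 1.0).all()

    def test_incomplete_design_rejected(self, rng):
        df = random_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            hl.rm_anova(df, "value", FACTORS, "team_id")

    def test_visibility_shift_power(self, rng):
        """A 1-within-SD shift on one factor is detected in >= 80% of runs."""
        hits = 0
        for _ in range(200):
            df = random_table(rng, effects={(1,): 1.0})  # shift of 1 x noise SD
            tab = hl.rm_anova(df, "value", FACTORS, "team_id")
            hits += tab.loc["B", "p"] < 0.05
        assert hits / 200 >= 0.80


class TestBonferroni:
    def test_examples(self):
        assert np.allclose(hl.bonferroni([0.01, 0.04]), [0.02, 0.08])
        assert np.allclose(hl.bonferroni([0.2]), [0.2])
        assert np.allclose(hl.bonferroni([1.0, 0.9]), [1.0, 1.0])

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            hl.bonferroni([1.5])


def _design(rng, n_teams=8, trials=12):
    teams = np.repeat(np.arange(n_teams), trials)
    X = rng.choice([-0.5, 0.5], size=(len(teams), 3))
    return teams, X


class TestMixedRegression:
    def test_matches_ols_without_group_variance(self, rng):
        # covariates, z and noise centered within teams: the team-intercept
        # variance is exactly zero, so the ML mixed fit must reduce to OLS
        teams, X = _design(rng)
        def center(v):
            v = v.copy()
            for g in np.unique(teams):
                v[teams == g] -= v[teams == g].mean(axis=0)
            return v
        X = center(X)
        z = center(rng.normal(size=len(teams)))
        eps = center(rng.normal(scale=0.5, size=len(teams)))
        y = 1.0 + X @ [0.5, -0.3, 0.2] + 2.0 * z + eps
        res = hl.mixed_regression(y, X, z, teams)
        beta_ols = np.linalg.lstsq(
            np.column_stack([np.ones_like(z), X, z]), y, rcond=None
        )[0]
        assert res.beta_z == pytest.approx(beta_ols[-1], abs=1e-6)

    def test_perfect_fit_limit(self, rng):
        teams, X = _design(rng)
        z = rng.normal(size=len(teams))
        y = 2.0 * z
        res = hl.mixed_regression(y, X, z, teams)
        assert res.beta_z == pytest.approx(2.0, abs=1e-6)
        assert res.cohens_f2 > 100.0
        assert res.ci_high - res.ci_low < 1e-4
        assert res.ci_low <= res.beta_z <= res.ci_high

    def test_zero_variance_z_rejected(self, rng):
        teams, X = _design(rng)
        y = rng.normal(size=len(teams))
        with pytest.raises(ValueError, match="variance"):
            hl.mixed_regression(y, X, np.ones_like(y), teams)

    def test_type_i_error_calibrated(self):
        """Unrelated z: |z-stat| < 1.96 in at least 90% of replicates."""
        rng = np.random.default_rng(2024)
        ok = 0
        for _ in range(100):
            teams, X = _design(rng, n_teams=10, trials=16)
            u = rng.normal(scale=1.0, size=10)[teams]
            y = X @ [1.0, 0.5, -0.5] + u + rng.normal(size=len(teams))
            z = rng.normal(size=len(teams))
            res = hl.mixed_regression(y, X, z, teams)
            ok += abs(res.zstat) < 1.96
        assert ok >= 90
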