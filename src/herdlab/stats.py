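"""Inferential machinery: within-subject factorial ANOVA and mixed regression.

``rm_anova`` handles fully crossed within-subject designs whose factors all
have two levels (the study's 2 x 2 x 2).  Every effect is then a single
within-subject contrast, so its F(1, n-1) equals the squared one-sample t on
the per-subject contrast scores; the Greenhouse-Geisser epsilon is exactly 1
(sphericity is vacuous with two levels) and is reported as such.  Partial
eta squared is SS_effect / (SS_effect + SS_error).

``mixed_regression`` fits the random-intercept model

    y_i = b0 + f(X_i, b_X) + z * b_z + u_team + e_i

by maximum likelihood (so the full and reduced likelihood-based fits are
comparable), reports the Wald z and 95% CI for b_z, and Cohen's
f^2 = (R2_full - R2_reduced) / (1 - R2_full) with R2 the squared correlation
between fitted (fixed + BLUP random intercept) and observed values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "rm_anova",
    "rm_anova_2x2x2",
    "MixedModelResult",
    "mixed_regression",
    "bonferroni",
]


def bonferroni(pvals: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def _check_complete(table: pd.DataFrame, subject: str, cells: list[tuple]) -> None:
    for subj, row in table.iterrows():
        missing = [c for c in cells if pd.isna(row[c])]
        if missing:
            raise ValueError(
                f"incomplete design: subject {subj!r} is missing cell(s) {missing}"
            )


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str,
) -> pd.DataFrame:
    """Repeated-measures ANOVA for a balanced all-two-level within design.

    ``data`` is long-format with one or more rows per subject x cell
    (replicates are averaged to one value per cell before analysis).
    Returns a table indexed by effect ('A', 'A:B', ...) with columns
    F, df1, df2, eps_gg, p, p_corrected (Bonferroni over the effect family),
    partial_eta_sq, ss_effect, ss_error.
    """
    within = list(within)
    if not within:
        raise ValueError("need at least one within factor")
    levels = {}
    for f in within:
        lv = sorted(pd.unique(data[f]))
        if len(lv) != 2:
            raise ValueError(
                f"factor {f!r} must have exactly 2 levels, got {lv}"
            )
        levels[f] = lv

    cells = list(itertools.product(*(levels[f] for f in within)))
    table = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean"
    )
    if len(within) == 1:
        table.columns = [(c,) for c in table.columns]
    table = table.reindex(columns=cells)
    n = len(table)
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 subjects")
    _check_complete(table, subject, cells)

    y = table.to_numpy(dtype=float)  # (n, m)
    m = len(cells)
    # +1/-1 contrast code per factor, aligned to sorted level order
    codes = np.array(
        [[1.0 if cell[i] == levels[f][0] else -1.0 for i, f in enumerate(within)]
         for cell in cells]
    )  # (m, k)

    rows = []
    effects = []
    for r in range(1, len(within) + 1):
        effects.extend(itertools.combinations(range(len(within)), r))
    for eff in effects:
        c = codes[:, eff].prod(axis=1)  # (m,)
        L = y @ c / m  # per-subject contrast score
        Lbar = L.mean()
        ss_effect = n * m * Lbar**2
        ss_error = m * ((L - Lbar) ** 2).sum()
        df1, df2 = 1, n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_effect / df1) / (ss_error / df2) if ss_error > 0 else (
                0.0 if ss_effect == 0 else np.inf
            )
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        peta = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0
        rows.append(
            {
                "effect": ":".join(within[i] for i in eff),
                "F": float(F),
                "df1": df1,
                "df2": df2,
                "eps_gg": 1.0,  # exact: every factor has two levels
                "p": p,
                "partial_eta_sq": float(peta),
                "ss_effect": float(ss_effect),
                "ss_error": float(ss_error),
            }
        )
    out = pd.DataFrame(rows).set_index("effect")
    out["p_corrected"] = bonferroni(out["p"].to_numpy())
    return out


def rm_anova_2x2x2(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] = ("target_number", "visibility", "perturbation"),
    subject: str = "team_id",
) -> pd.DataFrame:
    """The study's 2 x 2 x 2 repeated-measures ANOVA (7 effects)."""
    if len(within) != 3:
        raise ValueError("rm_anova_2x2x2 expects exactly three within factors")
    return rm_anova(data, dv, within, subject)


@dataclass
class MixedModelResult:
    """Random-intercept regression summary for the communication term z."""

    beta_z: float
    se: float
    zstat: float
    pvalue: float
    ci_low: float
    ci_high: float
    cohens_f2: float
    intercept: float
    fixed_effects: pd.Series
    group_var: float
    resid_var: float
    r2_full: float
    r2_reduced: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


class _Fit:
    """Minimal adapter over the full or boundary (OLS) fit."""

    def __init__(self, fe_params, bse_fe, group_var, scale, random_effects):
        self.fe_params = np.asarray(fe_params, dtype=float)
        self.bse_fe = np.asarray(bse_fe, dtype=float)
        self.group_var = float(group_var)
        self.scale = float(scale)
        self.random_effects = random_effects  # dict group -> BLUP, or None


def _fit_ml(y, exog, groups) -> _Fit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=False)
            try:
                re = {
                    g: float(np.asarray(v).ravel()[0])
                    for g, v in res.random_effects.items()
                }
            except (ValueError, np.linalg.LinAlgError):
                re = None  # zero team variance: all BLUPs vanish
            return _Fit(
                res.fe_params,
                res.bse_fe,
                np.asarray(res.cov_re).ravel()[0],
                res.scale,
                re,
            )
        except np.linalg.LinAlgError:
            # ML landed on the zero-variance boundary, where the mixed model
            # reduces exactly to ordinary least squares
            ols = sm.OLS(y, exog).fit()
            return _Fit(ols.params, ols.bse, 0.0, ols.scale, None)


def _r2(fit: _Fit, y, exog, groups) -> float:
    fitted = exog @ fit.fe_params
    if fit.random_effects is not None:
        fitted = fitted + np.array([fit.random_effects[g] for g in groups])
    if np.std(fitted) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(fitted, y)[0, 1] ** 2)


def mixed_regression(
    y: np.ndarray,
    design: np.ndarray,
    z: np.ndarray,
    groups: Sequence,
    design_names: Optional[Sequence[str]] = None,
) -> MixedModelResult:
    """Does communication measure ``z`` predict ``y`` beyond the task design?

    ``design`` is the (n, p) matrix of task covariates (main effects and
    interactions, already coded); ``groups`` the team identifier per trial.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != len(y):
        design = design.T
    groups = np.asarray(groups)
    if np.std(z) == 0:
        raise ValueError("communication measure z has zero variance")
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 teams")

    p = design.shape[1]
    names = list(design_names) if design_names is not None else [
        f"x{i}" for i in range(p)
    ]
    const = np.ones((len(y), 1))
    exog_full = np.hstack([const, design, z[:, None]])
    exog_red = np.hstack([const, design])

    res_full = _fit_ml(y, exog_full, groups)
    res_red = _fit_ml(y, exog_red, groups)

    idx_z = p + 1
    beta = float(res_full.fe_params[idx_z])
    se = float(res_full.bse_fe[idx_z])
    if not np.isfinite(se) or se <= 0.0:
        # perfect-fit limit: zero residual variance collapses the Wald SE
        se = 0.0
        zstat = np.inf * np.sign(beta) if beta != 0 else 0.0
        pvalue = 0.0 if beta != 0 else 1.0
        ci_low = ci_high = beta
    else:
        zstat = beta / se
        pvalue = 2.0 * float(sps.norm.sf(abs(zstat)))
        ci_low = beta - 1.959963984540054 * se
        ci_high = beta + 1.959963984540054 * se

    r2_full = _r2(res_full, y, exog_full, groups)
    r2_red = _r2(res_red, y, exog_red, groups)
    f2 = (r2_full - r2_red) / max(1.0 - r2_full, 1e-12)

    fe = pd.Series(
        np.asarray(res_full.fe_params),
        index=["intercept"] + names + ["z"],
    )
    return MixedModelResult(
        beta_z=beta,
        se=se,
        zstat=float(zstat),
        pvalue=pvalue,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        cohens_f2=float(f2),
        intercept=float(res_full.fe_params[0]),
        fixed_effects=fe,
        group_var=res_full.group_var,
        resid_var=res_full.scale,
        r2_full=r2_full,
        r2_reduced=r2_red,
    )
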