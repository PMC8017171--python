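"""Statistical layer of the intervention trial.

Implements baseline z-standardization with confidence intervals, component
scores from a given loading matrix, the linear mixed-effects model with
Group x Time and Lifestyle x Time interactions (random intercept per
subject), Hedges' g effect sizes on pre-post difference scores, and paired
t-tests.  The mixed model is exposed statsmodels-style: build a
:class:`GroupTimeLifestyleModel` from a long-format cohort table, call
``fit()``, and read estimates, F-tests and a ``summary()`` off the returned
:class:`InteractionResults`.

Model
-----
For outcome y of subject i in group g (WLC = reference) at session t
(pre = reference)::

    y_it = b0 + b_g + b_t + (b x)_gt + c L_i + (c x)_t L_i + u_i + e_it

with u_i a subject random intercept.  Training effects are read from the
Group x Time interaction (one F-test pooling both treatment contrasts,
2 numerator df for pre/post) and lifestyle associations from the
Lifestyle x Time interaction (1 df).  Denominator df follow the containment
rule: n_obs - n_subjects - (number of fixed-effect columns varying within
subject), matching the convention of the nlme software family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_REFERENCE = "WLC"
SESSION_REFERENCE = "pre"
LOADING_THRESHOLD = 0.40


# ---------------------------------------------------------------------------
# Baseline standardization and change scores

def baseline_z(values_pre, values_post) -> tuple[np.ndarray, np.ndarray]:
    """Standardize pre and post values by the baseline (pre) mean and SD."""
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.size < 2:
        raise ValueError("need >= 2 subjects with pre values")
    mu, sd = pre.mean(), pre.std(ddof=1)
    if sd == 0:
        raise ValueError("zero baseline SD")
    return (pre - mu) / sd, (post - mu) / sd


def change_ci(z_pre, z_post, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mean standardized change (post - pre) with a t-based confidence interval."""
    d = np.asarray(z_post, dtype=float) - np.asarray(z_pre, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 paired values")
    mean = d.mean()
    se = d.std(ddof=1) / np.sqrt(n)
    half = sps.t.ppf(0.5 + confidence / 2, n - 1) * se
    return float(mean), (float(mean - half), float(mean + half))


# ---------------------------------------------------------------------------
# Component scores from a fixed loading matrix

@dataclass
class ComponentModel:
    """Loading matrix (variables x components) with an inclusion threshold.

    Only variables with |loading| >= threshold contribute to a component.
    ``sign_map`` flips direction-coded variables (e.g. completion times where
    lower is better) before weighting.  Weights are the loadings of the
    included variables, renormalized so their absolute values sum to 1.
    """

    loadings: pd.DataFrame
    threshold: float = LOADING_THRESHOLD
    sign_map: dict[str, int] = field(default_factory=dict)

    def weights(self, component: str) -> pd.Series:
        col = self.loadings[component]
        included = col[col.abs() >= self.threshold]
        if included.empty:
            raise ValueError(f"component {component!r} has no variable at threshold")
        w = included / included.abs().sum()
        return w


def component_scores(data: pd.DataFrame, model: ComponentModel) -> pd.DataFrame:
    """Weighted-average component scores per subject, plus their global mean.

    ``data`` holds z-standardized variables (columns) per subject (rows).
    """
    out = {}
    for component in model.loadings.columns:
        w = model.weights(component)
        signs = pd.Series({v: model.sign_map.get(v, 1) for v in w.index})
        out[component] = (data[w.index] * signs).mul(w).sum(axis=1, min_count=len(w))
    scores = pd.DataFrame(out, index=data.index)
    scores["global"] = scores[list(model.loadings.columns)].mean(axis=1)
    return scores


# ---------------------------------------------------------------------------
# Mixed-effects Group x Time + Lifestyle x Time model

@dataclass
class TermTest:
    """One pooled F-test of an interaction term."""

    name: str
    f_value: float
    df_num: int
    df_den: int
    p_value: float

    def __str__(self) -> str:  # mirrors the field's "F(1,43) = 0.78, p = 0.38" style
        return (f"{self.name}: F({self.df_num},{self.df_den}) = {self.f_value:.2f}, "
                f"p = {self.p_value:.2f}")


@dataclass
class InteractionResults:
    """Fitted Group x Time (+ Lifestyle x Time) mixed model."""

    params: pd.Series
    bse: pd.Series
    group_time: TermTest
    lifestyle_time: TermTest | None
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_subjects: int
    sessions: tuple[str, ...]
    outcome: str
    method: str              # 'reml' | 'ml' | 'ols-fallback'
    singular: bool
    converged: bool

    def summary(self) -> str:
        lines = [
            f"Mixed-effects interaction model  (outcome: {self.outcome})",
            f"  {self.n_obs} observations, {self.n_subjects} subjects, "
            f"sessions: {'/'.join(self.sessions)}; method: {self.method}"
            + ("  [SINGULAR FIT]" if self.singular else ""),
            f"  random-intercept var = {self.random_intercept_var:.6g}, "
            f"residual var = {self.residual_var:.6g}",
            "  " + str(self.group_time),
        ]
        if self.lifestyle_time is not None:
            lines.append("  " + str(self.lifestyle_time))
        lines.append("  Fixed effects:")
        for name, val in self.params.items():
            lines.append(f"    {name:55s} {val:+.4f} (SE {self.bse[name]:.4f})")
        return "\n".join(lines)


class GroupTimeLifestyleModel:
    """Random-intercept model of training and lifestyle effects over time.

    Parameters
    ----------
    table
        Long-format cohort table with columns subject, group, lifestyle,
        session, outcome (one row per subject x session).
    include_lifestyle
        Drop the lifestyle terms to mirror the reduced model used for
        outcomes where only training effects are of interest.
    sessions
        Sessions entering the model; ('pre', 'post') by default, add
        'followup' for the long-term extension.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        outcome: str = "outcome",
        include_lifestyle: bool = True,
        sessions: tuple[str, ...] = ("pre", "post"),
    ):
        required = {"subject", "group", "session", outcome}
        if include_lifestyle:
            required.add("lifestyle")
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
        df = table[table["session"].isin(sessions)].copy()
        df = df.dropna(subset=[outcome] + (["lifestyle"] if include_lifestyle else []))
        counts = df.groupby("subject")["session"].nunique()
        if counts.max() < 2:
            raise ValueError("need >= 2 sessions for at least one subject")
        self.table = df
        self.outcome = outcome
        self.include_lifestyle = include_lifestyle
        self.sessions = tuple(s for s in sessions if s in set(df["session"]))

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "GroupTimeLifestyleModel":
        return cls(table, **kwargs)

    @property
    def formula(self) -> str:
        base = (f"{self.outcome} ~ C(group, Treatment('{GROUP_REFERENCE}'))"
                f" * C(session, Treatment('{SESSION_REFERENCE}'))")
        if self.include_lifestyle:
            base += (f" + lifestyle + lifestyle:C(session, Treatment('{SESSION_REFERENCE}'))")
        return base

    def _containment_df(self, exog_names: list[str], n_obs: int, n_subjects: int) -> int:
        n_within = sum(1 for name in exog_names if "session" in name)
        return n_obs - n_subjects - n_within

    def fit(self, reml: bool = True) -> InteractionResults:
        """Fit by (restricted) maximum likelihood; falls back to OLS on a
        singular fit, reported via ``singular``/``method``."""
        import statsmodels.formula.api as smf

        df = self.table
        n_subjects = df["subject"].nunique()
        singular = False
        method = "reml" if reml else "ml"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(self.formula, df, groups=df["subject"])
                res = model.fit(reml=reml, method="lbfgs")
            converged = bool(res.converged)
            ok = converged and np.isfinite(res.params).all() and np.isfinite(res.bse_fe).all()
        except Exception:
            ok = converged = False
        if not ok:
            # Singular / degenerate fit (e.g. zero residual variance): the
            # fixed effects are still identified; report the OLS solution.
            singular = True
            method = "ols-fallback"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.ols(self.formula, df).fit()
            converged = True

        exog_names = [n for n in res.params.index if n != "Group Var"]
        params = res.params[exog_names]
        if method == "ols-fallback":
            bse = res.bse[exog_names]
            cov = res.cov_params().loc[exog_names, exog_names]
            re_var, resid_var = 0.0, float(getattr(res, "mse_resid", np.nan))
        else:
            bse = res.bse_fe
            cov = res.cov_params().loc[exog_names, exog_names]
            re_var = float(res.cov_re.iloc[0, 0])
            resid_var = float(res.scale)

        df_den = self._containment_df(exog_names, len(df), n_subjects)
        group_time = self._wald_f(params, cov, exog_names, "Group x Time",
                                  lambda n: "group" in n and "session" in n, df_den)
        lifestyle_time = None
        if self.include_lifestyle:
            lifestyle_time = self._wald_f(params, cov, exog_names, "Lifestyle x Time",
                                          lambda n: "lifestyle" in n and "session" in n,
                                          df_den)
        return InteractionResults(
            params=params,
            bse=bse,
            group_time=group_time,
            lifestyle_time=lifestyle_time,
            random_intercept_var=re_var,
            residual_var=resid_var,
            n_obs=len(df),
            n_subjects=n_subjects,
            sessions=self.sessions,
            outcome=self.outcome,
            method=method,
            singular=singular,
            converged=converged,
        )

    @staticmethod
    def _wald_f(params, cov, exog_names, name, selector, df_den) -> TermTest:
        sel = [n for n in exog_names if selector(n)]
        if not sel:
            raise ValueError(f"no parameters found for {name}")
        q = len(sel)
        beta = params[sel].to_numpy()
        v = cov.loc[sel, sel].to_numpy()
        chi2 = float(beta @ np.linalg.solve(v, beta))
        f_value = chi2 / q
        p = float(sps.f.sf(f_value, q, df_den))
        return TermTest(name=name, f_value=f_value, df_num=q, df_den=df_den, p_value=p)


def fit_interaction_model(
    table: pd.DataFrame,
    outcome: str = "outcome",
    sessions: tuple[str, ...] = ("pre", "post"),
    include_lifestyle: bool = True,
    reml: bool = True,
) -> InteractionResults:
    """Convenience wrapper: build and fit the Group x Time (+ Lifestyle x Time) model."""
    model = GroupTimeLifestyleModel(
        table, outcome=outcome, include_lifestyle=include_lifestyle, sessions=sessions
    )
    return model.fit(reml=reml)


# ---------------------------------------------------------------------------
# Effect sizes and paired comparisons

@dataclass
class EffectSize:
    """Hedges' g with its confidence interval; positive = intervention benefit."""

    g: float
    ci: tuple[float, float]
    p_value: float
    n_treatment: int
    n_control: int
    correction_j: float
    ci_method: str = "normal-approximation"

    def __str__(self) -> str:
        return (f"Hedges' g = {self.g:.2f}, 95% CI [{self.ci[0]:.2f}, {self.ci[1]:.2f}], "
                f"p = {self.p_value:.2f}")


def hedges_g(diff_treatment, diff_control, confidence: float = 0.95) -> EffectSize:
    """Small-sample-corrected standardized mean difference of change scores.

    g = J * (mean_t - mean_c) / s_pooled with J = 1 - 3 / (4 (n_t + n_c - 2) - 1).
    The CI uses the normal approximation to the sampling variance of g; the
    p-value is from the two-sample pooled t-test.  Orientation: positive g
    means the treatment group improved more than control.
    """
    t_arr = np.asarray(diff_treatment, dtype=float)
    c_arr = np.asarray(diff_control, dtype=float)
    n_t, n_c = t_arr.size, c_arr.size
    if n_t < 2 or n_c < 2:
        raise ValueError("each group needs >= 2 difference scores")
    dof = n_t + n_c - 2
    s_pooled = np.sqrt(((n_t - 1) * t_arr.var(ddof=1) + (n_c - 1) * c_arr.var(ddof=1)) / dof)
    if s_pooled == 0:
        raise ValueError("zero pooled SD")
    j = 1.0 - 3.0 / (4.0 * dof - 1.0)
    g = j * (t_arr.mean() - c_arr.mean()) / s_pooled
    var_g = (n_t + n_c) / (n_t * n_c) + g**2 / (2.0 * dof)
    half = sps.norm.ppf(0.5 + confidence / 2) * np.sqrt(var_g)
    t_stat = (t_arr.mean() - c_arr.mean()) / (s_pooled * np.sqrt(1 / n_t + 1 / n_c))
    p = float(2 * sps.t.sf(abs(t_stat), dof))
    return EffectSize(g=float(g), ci=(float(g - half), float(g + half)), p_value=p,
                      n_treatment=n_t, n_control=n_c, correction_j=float(j))


def paired_t(pre, post) -> tuple[float, int, float]:
    """Classical paired t-test on raw values; returns (t, df, two-sided p).

    The orientation matches pre-minus-post reporting: positive t means values
    decreased.  A constant non-zero shift (zero variance of the differences)
    is an error; identical pre and post values give t = 0, p = 1.
    """
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if pre_arr.size != post_arr.size or pre_arr.size < 2:
        raise ValueError("need paired samples with n >= 2")
    d = pre_arr - post_arr
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        raise ValueError("zero variance of differences with non-zero shift")
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p
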