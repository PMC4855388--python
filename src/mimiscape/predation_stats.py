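"""Statistical analysis of artificial-prey predation experiments.

Descriptive attack summaries, a chi-square test of predation homogeneity
across sites, binomial GLMs of attack by phenotype (pooled and per morph
set), heterozygote/homozygote attack ratios regressed on phenotypic
distance, and AIC comparison of nested GLMs in the two peak distances.

Unrecovered dummies carry no information about attacks and are excluded
from every count and model. GLMs treat each recovered dummy as an
independent Bernoulli trial (fits are done on role-aggregated binomial
counts, which has the identical likelihood up to a data-dependent
constant); deviance and AIC are reported on the Bernoulli scale, where
the saturated log-likelihood is zero and AIC = deviance + 2·k exactly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cpm import DistanceSet

logger = logging.getLogger(__name__)

__all__ = [
    "AttackSummary",
    "GLMResult",
    "RatioRecord",
    "RegressionResult",
    "ModelComparison",
    "summarize_attacks",
    "chisq_site_homogeneity",
    "palatable_site_counts",
    "fit_attack_glm",
    "per_set_glm",
    "attack_ratio",
    "regress_ratio_on_distance",
    "compare_distance_models",
]


# --------------------------------------------------------------------------
# Descriptive summaries
# --------------------------------------------------------------------------

@dataclass
class AttackSummary:
    """Attack counts per role x site-group and across-group dispersion.

    ``per_group``: one row per (role, site_group) with n_recovered,
    n_attacked and the attack rate. ``per_role``: across site-groups, the
    mean, sample (n-1) standard deviation and standard error of the
    per-group attack counts, plus pooled totals and rate.
    """

    per_group: pd.DataFrame
    per_role: pd.DataFrame

    @property
    def total_attacks(self) -> int:
        return int(self.per_group["n_attacked"].sum())

    @property
    def total_recovered(self) -> int:
        return int(self.per_group["n_recovered"].sum())


def _recovered(table: pd.DataFrame) -> pd.DataFrame:
    rec = table[table["recovered"].astype(bool)].copy()
    rec["attacked"] = rec["attacked"].astype(bool)
    return rec


def summarize_attacks(table: pd.DataFrame) -> AttackSummary:
    """Descriptive attack summary of a PredationTable.

    Counts exclude unrecovered dummies. Groups (stations) missing one or
    more roles are logged and retained. The across-group s.e. is
    s.d./sqrt(n_groups) and is undefined (NaN) with a single site-group.
    """
    if table.empty:
        raise ValueError("predation table is empty")
    n_roles = table["role"].nunique()
    sizes = table.groupby(["site", "group"])["role"].nunique()
    incomplete = int((sizes < n_roles).sum())
    if incomplete:
        logger.warning("%d stations are missing one or more roles; retained",
                       incomplete)

    rec = _recovered(table)
    per_group = (
        rec.groupby(["role", "site_group"], as_index=False)
        .agg(n_recovered=("attacked", "size"), n_attacked=("attacked", "sum"))
    )
    per_group["rate"] = per_group["n_attacked"] / per_group["n_recovered"]

    per_role = (
        per_group.groupby("role", as_index=False)
        .agg(
            n_groups=("site_group", "size"),
            n_recovered=("n_recovered", "sum"),
            n_attacked=("n_attacked", "sum"),
            mean_attacks=("n_attacked", "mean"),
            sd_attacks=("n_attacked", lambda x: x.std(ddof=1)),
        )
    )
    per_role["se_attacks"] = per_role["sd_attacks"] / np.sqrt(per_role["n_groups"])
    per_role["rate"] = per_role["n_attacked"] / per_role["n_recovered"]
    return AttackSummary(per_group=per_group, per_role=per_role)


# --------------------------------------------------------------------------
# Site homogeneity
# --------------------------------------------------------------------------

def palatable_site_counts(table: pd.DataFrame, by: str = "site_group",
                          role: str = "palatable") -> pd.DataFrame:
    """Recovered/attacked counts of the palatable control per site (-group)."""
    rec = _recovered(table[table["role"] == role])
    out = rec.groupby(by, as_index=False).agg(
        n_recovered=("attacked", "size"), n_attacked=("attacked", "sum"))
    return out.rename(columns={by: "site"})


def chisq_site_homogeneity(n_attacked, n_recovered=None) -> tuple[float, int, float]:
    """Chi-square homogeneity of attack proportions across k sites.

    Tests the 2 x k (attacked / not-attacked by site) contingency table
    without continuity correction; df = k - 1. Accepts per-site arrays or
    the DataFrame from :func:`palatable_site_counts` as first argument.
    """
    if isinstance(n_attacked, pd.DataFrame):
        df_counts = n_attacked
        n_recovered = df_counts["n_recovered"].to_numpy()
        n_attacked = df_counts["n_attacked"].to_numpy()
    n_attacked = np.asarray(n_attacked, dtype=float)
    n_recovered = np.asarray(n_recovered, dtype=float)
    if n_attacked.size < 2:
        raise ValueError("homogeneity test needs at least two sites")
    if np.any(n_recovered <= 0):
        raise ValueError("a site has zero recovered dummies")
    if np.any(n_attacked > n_recovered):
        raise ValueError("attacked count exceeds recovered count")
    contingency = np.vstack([n_attacked, n_recovered - n_attacked])
    if n_attacked.sum() == 0 or (n_recovered - n_attacked).sum() == 0:
        return 0.0, int(n_attacked.size - 1), 1.0
    chi2, p, dof, _ = stats.chi2_contingency(contingency, correction=False)
    return float(chi2), int(dof), float(p)


# --------------------------------------------------------------------------
# Binomial GLMs of attack by phenotype
# --------------------------------------------------------------------------

@dataclass
class GLMResult:
    """A fitted one-factor binomial GLM of attack by phenotype.

    ``contrasts`` lists every role pair with the log-odds difference, its
    Wald standard error, z and two-sided p (closed form from the 2 x 2
    margins, which for this saturated model equals the GLM estimate).
    ``anova`` is the analysis-of-deviance chi-square for the phenotype
    factor. Deviance and AIC are on the Bernoulli scale, so
    AIC = deviance + 2·n_params.
    """

    rates: pd.DataFrame                    # role, n_recovered, n_attacked, rate
    contrasts: pd.DataFrame
    deviance: float
    aic: float
    n_params: int
    reference: str
    anova: tuple[float, int, float]        # (chi2, df, p)
    separated_roles: tuple[str, ...] = ()


def _bernoulli_loglike(successes: np.ndarray, trials: np.ndarray,
                       p: np.ndarray) -> float:
    """Sum of per-trial Bernoulli log-likelihoods at fitted probabilities."""
    s = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return float(np.sum(s * np.log(p) + (n - s) * np.log1p(-p)))


def _pairwise_contrasts(counts: pd.DataFrame, separated: set[str]) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(counts["role"], 2):
        ra = counts.loc[counts["role"] == a].iloc[0]
        rb = counts.loc[counts["role"] == b].iloc[0]
        flagged = a in separated or b in separated
        if flagged:
            est = se = z = p = np.nan
        else:
            sa, fa = ra["n_attacked"], ra["n_recovered"] - ra["n_attacked"]
            sb, fb = rb["n_attacked"], rb["n_recovered"] - rb["n_attacked"]
            est = float(np.log(sa / fa) - np.log(sb / fb))
            se = float(np.sqrt(1 / sa + 1 / fa + 1 / sb + 1 / fb))
            z = est / se
            p = 2 * stats.norm.sf(abs(z))
        rows.append({"role_a": a, "role_b": b, "estimate": est, "se": se,
                     "z": z, "p": p, "flagged": flagged})
    return pd.DataFrame(rows)


def fit_attack_glm(table: pd.DataFrame, reference_role: str = "exotic",
                   ) -> GLMResult:
    """Binomial GLM (logit link) of attack with phenotype as sole predictor.

    Roles showing complete separation (zero or all recovered dummies
    attacked) are flagged and their contrasts suppressed. The phenotype
    effect is tested by analysis of deviance (null vs phenotype model,
    chi-square on k - 1 df).
    """
    rec = _recovered(table)
    counts = (
        rec.groupby("role", as_index=False)
        .agg(n_recovered=("attacked", "size"), n_attacked=("attacked", "sum"))
    )
    counts["rate"] = counts["n_attacked"] / counts["n_recovered"]
    if len(counts) < 2:
        raise ValueError("need at least two roles with recovered dummies")
    separated = {
        r["role"] for _, r in counts.iterrows()
        if r["n_attacked"] == 0 or r["n_attacked"] == r["n_recovered"]
    }
    if reference_role not in set(counts["role"]):
        raise ValueError(f"reference role {reference_role!r} absent from table")

    clean = counts[~counts["role"].isin(separated)].reset_index(drop=True)
    k = len(clean)
    endog = np.column_stack([clean["n_attacked"],
                             clean["n_recovered"] - clean["n_attacked"]])
    with warnings.catch_warnings():
        # the one-factor model is saturated (k obs, k params): statsmodels
        # flags the zero residual df; that is by construction, not a defect
        warnings.simplefilter("ignore")
        if k >= 2:
            ref = reference_role if reference_role in set(clean["role"]) \
                else clean["role"].iloc[0]
            order = [ref] + [r for r in clean["role"] if r != ref]
            dummies = pd.get_dummies(
                pd.Categorical(clean["role"], categories=order), drop_first=True)
            exog = sm.add_constant(dummies.to_numpy(dtype=float))
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            fitted_p = fit.predict(exog)
        elif k == 1:
            # degenerate: one clean role, intercept only
            fit = sm.GLM(endog, np.ones((k, 1)),
                         family=sm.families.Binomial()).fit()
            fitted_p = fit.predict(np.ones((k, 1)))
        else:  # every role separated; nothing to fit
            fitted_p = np.empty(0)

    ll_full = _bernoulli_loglike(clean["n_attacked"], clean["n_recovered"], fitted_p)
    p_null = clean["n_attacked"].sum() / clean["n_recovered"].sum() if k else 0.5
    ll_null = _bernoulli_loglike(clean["n_attacked"], clean["n_recovered"],
                                 np.full(k, p_null))
    n_params = k  # saturated one-factor model
    deviance = -2.0 * ll_full
    lr = 2.0 * (ll_full - ll_null)
    anova_df = k - 1
    anova_p = float(stats.chi2.sf(lr, anova_df)) if anova_df > 0 else np.nan

    return GLMResult(
        rates=counts,
        contrasts=_pairwise_contrasts(counts, separated),
        deviance=deviance,
        aic=deviance + 2 * n_params,
        n_params=n_params,
        reference=reference_role,
        anova=(float(lr), anova_df, anova_p),
        separated_roles=tuple(sorted(separated)),
    )


def per_set_glm(table: pd.DataFrame, set_map: dict[str, list[str]],
                reference_role: str = "hom1") -> dict[str, GLMResult]:
    """One attack GLM per morph set, combining its site-groups.

    ``set_map`` maps a set id to the site-groups where that morph set was
    tested (sites testing the same morphs are combined).
    """
    results: dict[str, GLMResult] = {}
    for set_id, site_groups in set_map.items():
        sub = table[table["site_group"].isin(site_groups)]
        if sub.empty:
            raise ValueError(f"no rows for morph set {set_id!r}")
        results[set_id] = fit_attack_glm(sub, reference_role=reference_role)
    return results


# --------------------------------------------------------------------------
# Attack ratios vs phenotypic distance
# --------------------------------------------------------------------------

@dataclass
class RatioRecord:
    """One morph set's heterozygote/dominant-homozygote attack ratio.

    A ratio near 1 means the heterozygote was attacked about as often as
    the local dominant homozygote, i.e. it was protected by that morph's
    warning signal. ``distances`` maps (encoding, observer) to the set's
    DistanceSet.
    """

    set_id: str
    locality: str
    ratio: float
    distances: dict[tuple[str, str], DistanceSet] = field(default_factory=dict)
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("attack ratio must be non-negative")

    def distance(self, encoding: str, observer: str = "",
                 which: str = "het_homD") -> float:
        ds = self.distances[(encoding, observer)]
        return getattr(ds, which)


def attack_ratio(het_attacks: int, hom_attacks: int) -> tuple[float, bool]:
    """Heterozygote-to-homozygote attack ratio.

    With zero homozygote attacks the ratio is undefined; a Haldane-
    Anscombe 0.5 is added to both counts and the record flagged.
    """
    if het_attacks < 0 or hom_attacks < 0:
        raise ValueError("attack counts must be non-negative")
    if hom_attacks == 0:
        return (het_attacks + 0.5) / 0.5, True
    return het_attacks / hom_attacks, False


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    p_value: float
    slope_se: float
    n: int


def regress_ratio_on_distance(records: list[RatioRecord], encoding: str,
                              observer: str = "",
                              which: str = "het_homD") -> RegressionResult:
    """OLS of attack ratio on a phenotypic distance across morph sets.

    ``which`` selects het_homD (distance to the nearest peak, the peak-
    proximity analysis) or hom_hom (distance between peaks, the ridge
    analysis). Reports both plain and adjusted R²; F on (1, n-2) df.
    """
    if len(records) < 3:
        raise ValueError("need at least three records to regress")
    x = np.array([r.distance(encoding, observer, which) for r in records])
    y = np.array([r.ratio for r in records])
    if np.ptp(x) == 0:
        raise ValueError("distances have zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        slope_se=float(fit.bse[1]),
        n=len(records),
    )


# --------------------------------------------------------------------------
# AIC comparison of peak-distance models
# --------------------------------------------------------------------------

_MODEL_TERMS: dict[str, list[str]] = {
    "intercept": [],
    "D": ["het_homD"],
    "R": ["het_homR"],
    "D+R": ["het_homD", "het_homR"],
    "D+R+DxR": ["het_homD", "het_homR", "interaction"],
}


@dataclass
class ModelComparison:
    """Nested binomial GLMs of heterozygote attack on the two peak distances.

    Candidate predictors: distance to the nearest peak (het-homD, "D"),
    distance to the other peak (het-homR, "R"), and their interaction.
    ``table`` lists AIC (Bernoulli scale) and ΔAIC per model; the
    interaction's Wald test comes from the full model.
    """

    table: pd.DataFrame
    best_model: str
    interaction_z: float
    interaction_p: float
    coefficients: dict[str, pd.Series]
    standard_errors: dict[str, pd.Series]


def compare_distance_models(het_data: pd.DataFrame) -> ModelComparison:
    """Fit and compare {1}, {D}, {R}, {D+R}, {D+R+DxR} attack models.

    ``het_data`` holds one row per heterozygote stratum with columns
    ``n_recovered``, ``n_attacked``, ``het_homD``, ``het_homR`` (per-dummy
    rows with an ``attacked`` flag are aggregated automatically).
    """
    df = het_data.copy()
    if "n_recovered" not in df.columns:
        rec = _recovered(df)
        df = (rec.groupby(["het_homD", "het_homR"], as_index=False)
              .agg(n_recovered=("attacked", "size"),
                   n_attacked=("attacked", "sum")))
    if df.empty:
        raise ValueError("no heterozygote rows to model")
    for col in ("het_homD", "het_homR"):
        if col not in df.columns or df[col].isna().any():
            raise ValueError(f"column {col!r} must be present and complete")
    if df["het_homD"].nunique() > 1 and df["het_homR"].nunique() > 1:
        corr = np.corrcoef(df["het_homD"], df["het_homR"])[0, 1]
        if abs(corr) > 0.999:
            warnings.warn("het_homD and het_homR are collinear "
                          f"(r = {corr:.4f})", stacklevel=2)
    df["interaction"] = df["het_homD"] * df["het_homR"]

    endog = np.column_stack([df["n_attacked"],
                             df["n_recovered"] - df["n_attacked"]])
    rows = []
    coefs: dict[str, pd.Series] = {}
    errs: dict[str, pd.Series] = {}
    full_fit = None
    for name, terms in _MODEL_TERMS.items():
        X = df[terms].to_numpy(dtype=float) if terms else np.empty((len(df), 0))
        exog = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            # near-saturated fits (few strata) trigger residual-df warnings
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        ll = _bernoulli_loglike(df["n_attacked"], df["n_recovered"],
                                fit.predict(exog))
        k = exog.shape[1]
        rows.append({"model": name, "n_params": k, "loglike": ll,
                     "aic": -2 * ll + 2 * k})
        coefs[name] = pd.Series(fit.params, index=["const"] + terms)
        errs[name] = pd.Series(fit.bse, index=["const"] + terms)
        if name == "D+R+DxR":
            full_fit = fit
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    out["best"] = out["delta_aic"] == 0
    best = out.loc[out["best"], "model"].iloc[0]
    z = float(full_fit.tvalues[-1])
    return ModelComparison(
        table=out,
        best_model=best,
        interaction_z=z,
        interaction_p=2 * float(stats.norm.sf(abs(z))),
        coefficients=coefs,
        standard_errors=errs,
    )
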