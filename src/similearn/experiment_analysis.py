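"""Statistical analysis of two-urn social-learning experiments.

Reproduces the published analysis chain on any canonical choice-record
table (deposited or synthetic):

* demonstrator optimality: share of group-blocks in which a majority of the
  five demonstrators chose the demonstrator-optimal urn on the fifth trial;
* treatment regressions: logistic models of social-learner choices with
  robust (sandwich) standard errors clustered on social learner — choosing
  left on block index and the centered fifth-trial proportion of
  demonstrators choosing left (x5 = p5 - 0.5), and choosing the social
  optimum on block index, a left-optimal dummy, a concordant dummy, a
  majority-demonstrator-optimal dummy and the interaction;
* Wald tests of linear combinations of coefficients under the clustered
  covariance, reported as F with (1, clusters - 1) degrees of freedom;
* per-learner strategy classification: Min / Maj / U (unconditional) rules
  checked exactly, otherwise a slope-only logistic MLE
  P(left) = exp(beta*x)/(1 + exp(beta*x)) with a 5% Wald significance flag;
* cluster-bootstrap social learning curves: per-demonstrator-count choice
  rates with 95% percentile intervals from resampling learners, which keeps
  intervals inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "LearnerType",
    "social_learning_table",
    "demonstrator_optimal_rate",
    "fit_choice_model",
    "fit_optimum_model",
    "wald_combo",
    "classify_learner",
    "classify_all",
    "bootstrap_curve",
]


@dataclass(frozen=True)
class FitResult:
    """A fitted logistic model with cluster-robust covariance."""

    params: pd.Series
    cov: pd.DataFrame
    n_clusters: int
    loglike: float
    nobs: int
    converged: bool
    separation_flag: bool

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


@dataclass(frozen=True)
class LearnerType:
    """Per-learner strategy label: Min, Maj, U or slope (with estimate)."""

    subject: str
    label: str  # "Min" | "Maj" | "U" | "slope"
    beta: float | None = None
    wald_p: float | None = None
    significant: bool | None = None
    separation_flag: bool = False


def social_learning_table(table: pd.DataFrame) -> pd.DataFrame:
    """One row per social-learner choice with the social context attached.

    Computes, per group-block, the number of demonstrators choosing left on
    the final trial, and derives the regression covariates: ``x5`` (centered
    proportion left), ``chose_left``, ``chose_social_opt``, ``left_optimal``
    (for the social learner), ``concordant`` and ``majority_demo_opt``.
    """
    demo = table[table["role"] == "demonstrator"]
    if len(demo) == 0:
        raise ValueError("table has no demonstrator rows")
    last_trial = demo.groupby(["session", "group", "block"])["trial"].transform("max")
    final = demo[demo["trial"] == last_trial]
    ctx = (
        final.assign(
            left=lambda d: (d["urn_chosen"] == "L").astype(int),
            optimal=lambda d: (d["urn_chosen"] == d["demo_optimal_urn"]).astype(int),
        )
        .groupby(["session", "group", "block"])
        .agg(n_demo=("left", "size"), n_left=("left", "sum"), n_opt=("optimal", "sum"))
        .reset_index()
    )
    social = table[table["role"] == "social_learner"]
    if len(social) == 0:
        raise ValueError("table has no social-learner rows")
    out = social.merge(ctx, on=["session", "group", "block"], how="left", validate="m:1")
    if out["n_demo"].isna().any():
        raise ValueError("social-learner blocks without demonstrator trial rows")
    out["p5"] = out["n_left"] / out["n_demo"]
    out["x5"] = out["p5"] - 0.5
    out["chose_left"] = (out["urn_chosen"] == "L").astype(int)
    out["chose_social_opt"] = (out["urn_chosen"] == out["social_optimal_urn"]).astype(int)
    out["left_optimal"] = (out["social_optimal_urn"] == "L").astype(int)
    out["concordant"] = (out["similarity"] == "concordant").astype(int)
    out["majority_demo_opt"] = (2 * out["n_opt"] > out["n_demo"]).astype(int)
    return out


def demonstrator_optimal_rate(table: pd.DataFrame) -> tuple[float, int]:
    """Proportion of group-blocks whose final trial had a majority of
    demonstrators choosing the demonstrator optimum, and the modal count of
    optimal choosers."""
    demo = table[table["role"] == "demonstrator"]
    if len(demo) == 0:
        raise ValueError("table has no demonstrator rows")
    last_trial = demo.groupby(["session", "group", "block"])["trial"].transform("max")
    final = demo[demo["trial"] == last_trial]
    if len(final) == 0:
        raise ValueError("missing final-trial demonstrator rows")
    counts = (
        final.assign(optimal=(final["urn_chosen"] == final["demo_optimal_urn"]).astype(int))
        .groupby(["session", "group", "block"])
        .agg(n=("optimal", "size"), k=("optimal", "sum"))
    )
    rate = float((2 * counts["k"] > counts["n"]).mean())
    modal = int(counts["k"].value_counts().idxmax())
    return rate, modal


def _cluster_logit(
    y: np.ndarray,
    X: pd.DataFrame,
    clusters: np.ndarray,
    small_sample_correction: bool = True,
) -> FitResult:
    """ML logistic fit with a clustered sandwich covariance.

    The correction factor M/(M-1) (M = number of clusters) is applied by
    default and can be switched off; which correction produced any given
    published table is rarely stated, so both variants are available.
    Perfect separation is flagged (not regularized): the fit is reported at
    the point the optimizer reached, with a warning.
    """
    model = sm.GLM(y, X, family=sm.families.Binomial())
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit()
        for w in caught:
            if "separation" in str(w.message).lower() or "PerfectSeparation" in str(
                w.category
            ):
                separation = True
    mu = res.predict()
    if np.min(mu) < 1e-8 or np.max(mu) > 1 - 1e-8:
        separation = True
    if separation:
        warnings.warn(
            "possible perfect separation: coefficients reported as reached, "
            "standard errors unreliable",
            stacklevel=3,
        )
    # clustered sandwich assembled directly (pinv tolerates the flat Hessian
    # directions that arise under separation): V = H+ (sum_g s_g s_g') H+
    scores = model.score_obs(res.params)
    bread = np.linalg.pinv(-model.hessian(res.params))
    groups, inverse = np.unique(clusters, return_inverse=True)
    m = len(groups)
    meat_half = np.zeros((m, scores.shape[1]))
    np.add.at(meat_half, inverse, scores)
    cov_arr = bread @ (meat_half.T @ meat_half) @ bread
    if small_sample_correction and m > 1:
        cov_arr = cov_arr * m / (m - 1)
    cov = pd.DataFrame(cov_arr, index=X.columns, columns=X.columns)
    return FitResult(
        params=pd.Series(res.params.values, index=X.columns),
        cov=cov,
        n_clusters=m,
        loglike=float(res.llf),
        nobs=int(res.nobs),
        converged=bool(res.converged),
        separation_flag=separation,
    )


def _subset(table: pd.DataFrame, treatment: dict | None) -> pd.DataFrame:
    sl = social_learning_table(table)
    if treatment:
        for col, val in treatment.items():
            sl = sl[sl[col] == val]
    if len(sl) == 0:
        raise ValueError(f"no social-learner rows for treatment {treatment}")
    return sl


def fit_choice_model(
    table: pd.DataFrame,
    treatment: dict | None = None,
    small_sample_correction: bool = True,
) -> FitResult:
    """Logistic model of choosing left on block index (1..20) and the
    centered demonstrator proportion ``x5``, clustered on social learner.

    ``treatment`` filters the social-learner rows first, e.g.
    ``{"design": "within", "similarity": "discordant"}``.
    """
    sl = _subset(table, treatment)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "learning_block": sl["block"].to_numpy(float),
            "prop_left_centered": sl["x5"].to_numpy(float),
        }
    )
    return _cluster_logit(
        sl["chose_left"].to_numpy(float), X, sl["subject"].to_numpy(),
        small_sample_correction,
    )


def fit_optimum_model(
    table: pd.DataFrame,
    treatment: dict | None = None,
    small_sample_correction: bool = True,
) -> FitResult:
    """Logistic model of choosing the social-learner optimum on block index,
    left-optimal dummy, concordant dummy, majority-demonstrator-optimal dummy
    and the concordant x majority interaction, clustered on social learner."""
    sl = _subset(table, treatment)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "trial_block": sl["block"].to_numpy(float),
            "left_optimal_soc": sl["left_optimal"].to_numpy(float),
            "concordant": sl["concordant"].to_numpy(float),
            "majority_demo_opt": sl["majority_demo_opt"].to_numpy(float),
            "concordant_x_majority": (
                sl["concordant"] * sl["majority_demo_opt"]
            ).to_numpy(float),
        }
    )
    return _cluster_logit(
        sl["chose_social_opt"].to_numpy(float), X, sl["subject"].to_numpy(),
        small_sample_correction,
    )


def wald_combo(
    fit: FitResult, weights: dict[str, float] | np.ndarray, as_f: bool = True
) -> tuple[float, float]:
    """Wald test of a linear combination of coefficients under the clustered
    covariance.

    Returns (F, p) with degrees of freedom (1, clusters - 1); with
    ``as_f=False`` the chi-square convention (statistic, p from chi2_1) is
    used instead.
    """
    if isinstance(weights, dict):
        w = np.array([weights.get(name, 0.0) for name in fit.params.index])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(fit.params),):
            raise ValueError("weights not conformable with the fitted parameters")
    est = float(w @ fit.params.to_numpy())
    var = float(w @ fit.cov.to_numpy() @ w)
    if var <= 0:
        if not np.any(w):
            return 0.0, 1.0
        raise np.linalg.LinAlgError("singular clustered covariance for this combination")
    stat = est**2 / var
    if as_f:
        p = float(stats.f.sf(stat, 1, fit.n_clusters - 1))
    else:
        p = float(stats.chi2.sf(stat, 1))
    return stat, p


#: slope magnitude beyond which a no-intercept fit is labelled as separated
#: (e.g. |beta| > 10 implies a jump from <0.007 to >0.993 across one
#: demonstrator; the likelihood is flat beyond that)
SLOPE_CAP = 50.0


def _slope_only_logit(y: np.ndarray, x: np.ndarray) -> tuple[float, float, bool]:
    """MLE of P(y=1) = expit(beta * x), no intercept.

    Returns (beta_hat, se, separation_flag). Perfect separation (all choices
    on the majority side, or strictly on the minority side, for every block
    with x != 0) drives |beta| to infinity; the estimate is then reported at
    +/-SLOPE_CAP with se = inf and the flag set.
    """
    nz = x != 0
    if nz.any():
        signs = (2 * y[nz] - 1) * np.sign(x[nz])
        if np.all(signs > 0):
            return SLOPE_CAP, np.inf, True
        if np.all(signs < 0):
            return -SLOPE_CAP, np.inf, True

    def nll(beta: float) -> float:
        eta = beta * x
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    res = optimize.minimize_scalar(nll, bounds=(-SLOPE_CAP, SLOPE_CAP), method="bounded")
    beta = float(res.x)
    p = 1.0 / (1.0 + np.exp(-beta * x))
    info = float(np.sum(x**2 * p * (1 - p)))
    se = float(np.sqrt(1.0 / info)) if info > 0 else np.inf
    return beta, se, False


def classify_learner(rows: pd.DataFrame) -> LearnerType:
    """Classify one social learner's strategy from her block rows.

    ``rows`` must be the learner's slice of :func:`social_learning_table`.
    Exact rules are checked first over all blocks with a strict demonstrator
    majority: always-minority -> "Min", always-majority -> "Maj"; then
    always-left / always-right -> "U"; otherwise the slope-only logistic MLE
    is fitted, with a 5% Wald significance flag.
    """
    subject = str(rows["subject"].iloc[0])
    y = rows["chose_left"].to_numpy(int)
    x = rows["x5"].to_numpy(float)
    strict = x != 0  # blocks with a strict demonstrator majority
    if strict.any():
        follow = y[strict] == (x[strict] > 0)
        if follow.all():
            return LearnerType(subject, "Maj")
        if (~follow).all():
            return LearnerType(subject, "Min")
    if (y == 1).all() or (y == 0).all():
        return LearnerType(subject, "U")
    if len(np.unique(x)) < 2:
        return LearnerType(subject, "slope", beta=None, wald_p=None, significant=None)
    beta, se, flagged = _slope_only_logit(y, x)
    if np.isfinite(se):
        z = beta / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        p = np.nan
    return LearnerType(
        subject,
        "slope",
        beta=beta,
        wald_p=p,
        significant=bool(p < 0.05) if np.isfinite(p) else None,
        separation_flag=flagged,
    )


def classify_all(
    table: pd.DataFrame, treatment: dict | None = None
) -> pd.DataFrame:
    """Classify every social learner; returns one row per learner."""
    sl = _subset(table, treatment)
    records = []
    for _, rows in sl.groupby("subject", sort=True):
        lt = classify_learner(rows)
        records.append(
            {
                "subject": lt.subject,
                "label": lt.label,
                "beta": lt.beta,
                "wald_p": lt.wald_p,
                "significant": lt.significant,
                "separation_flag": lt.separation_flag,
            }
        )
    return pd.DataFrame(records)


def bootstrap_curve(
    table: pd.DataFrame,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    treatment: dict | None = None,
    outcome: str = "chose_left",
) -> pd.DataFrame:
    """Social learning curve with cluster-bootstrap 95% percentile intervals.

    For each observed demonstrator left-count, the rate at which social
    learners chose left (or another 0/1 ``outcome`` column), with intervals
    from resampling learners (clusters) with replacement ``n_boot`` times.
    Counts never observed are omitted, not imputed. Intervals are percentile
    intervals of a rate, hence always inside [0, 1].
    """
    if rng is None:
        rng = np.random.default_rng()
    sl = _subset(table, treatment)
    subjects = np.sort(sl["subject"].unique())
    counts = np.sort(sl["n_left"].unique())
    point = sl.groupby("n_left")[outcome].agg(["mean", "size"])

    # per-(subject, count) successes and trials, so a bootstrap replicate is
    # two matrix sums over the resampled subject rows
    s_idx = pd.Categorical(sl["subject"], categories=subjects).codes
    c_idx = pd.Categorical(sl["n_left"], categories=counts).codes
    ones = np.ones(len(sl))
    trials = np.zeros((len(subjects), len(counts)))
    successes = np.zeros_like(trials)
    np.add.at(trials, (s_idx, c_idx), ones)
    np.add.at(successes, (s_idx, c_idx), sl[outcome].to_numpy(float))

    draws = rng.integers(len(subjects), size=(n_boot, len(subjects)))
    boot = np.full((n_boot, len(counts)), np.nan)
    for b in range(n_boot):
        t = trials[draws[b]].sum(axis=0)
        s = successes[draws[b]].sum(axis=0)
        np.divide(s, t, out=boot[b], where=t > 0)
        boot[b, t == 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
    return pd.DataFrame(
        {
            "n_left": counts,
            "rate": point["mean"].reindex(counts).to_numpy(),
            "n_obs": point["size"].reindex(counts).to_numpy(int),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
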