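"""Inferential layer: mixed models, variance partitioning, ancestry tests
and the order/laterality regression suite.

All mixed models are random-intercept variance-components models (see
:mod:`glyphcomplexity.varcomp`).  Model comparison refits with ML and uses
ΔAIC = AIC(null) − AIC(test), positive values favoring the test model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

from .varcomp import ModelFit, VarCompModel, delta_aic, fit_varcomp

__all__ = [
    "ModelFit",
    "BayesTestResult",
    "AncestryDifferential",
    "fit_random_intercept",
    "delta_aic",
    "icc",
    "variance_partition",
    "idiosyncratic_model",
    "size_model",
    "jzs_bayes_factor",
    "ancestry_differentials",
    "order_models",
]

DEFAULT_PRIOR_SCALE = np.sqrt(2) / 2  # conventional JZS Cauchy scale


def fit_random_intercept(
    data: pd.DataFrame,
    outcome: str,
    fixed: list[str] | None = None,
    groups: list[str] | None = None,
    reml: bool = True,
) -> ModelFit:
    """Fit a linear mixed model with random intercepts per grouping factor.

    ``groups`` lists column names; crossed factors are simply several
    columns, and nesting is expressed by a column holding the nested
    combination (e.g. ``family_script = family + ":" + script``).  Fixed
    effects must be numeric columns; an intercept is always included.
    REML estimates by default, with Satterthwaite-style approximate df for
    the fixed-effect t-tests.
    """
    if not groups:
        raise ValueError("at least one grouping factor is required")
    return fit_varcomp(data, outcome, fixed, groups, reml=reml)


def icc(values, grouping, log_transform: bool = False) -> float:
    """Intraclass correlation: share of variance at the grouping level.

    One-way random-intercept REML fit; ICC = σ²_b / (σ²_b + σ²_w).
    Negative/zero between-group variance estimates truncate to 0.  Set
    ``log_transform`` for metrics analyzed on the log scale (used for
    algorithmic complexity to tame its skew).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(grouping)
    ok = ~np.isnan(y)
    y, g = y[ok], g[ok]
    if log_transform:
        y = np.log(y)
    df = pd.DataFrame({"y": y, "g": g})
    fit = fit_varcomp(df, "y", [], ["g"], reml=True)
    s2b = max(fit.vcomp["g"], 0.0)
    return float(s2b / (s2b + fit.sigma2_resid))


def variance_partition(values, factors: dict, log_transform: bool = False) -> dict[str, float]:
    """Joint variance decomposition across several grouping factors.

    Fits one variance-components model with all factors simultaneously and
    returns each factor's share σ²_k / (Σ σ² + σ²_e) (plus ``"residual"``).
    Unlike the one-way :func:`icc`, shared variance is attributed where the
    joint fit places it, so a factor that adds nothing on top of the others
    (e.g. script when all structure is at the type level) gets ≈ 0.
    """
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y)
    if log_transform:
        y = np.log(y)
    df = pd.DataFrame({"y": y[ok]})
    for name, codes in factors.items():
        df[name] = np.asarray(codes)[ok]
    fit = fit_varcomp(df, "y", [], list(factors), reml=True)
    total = sum(fit.vcomp.values()) + fit.sigma2_resid
    out = {k: v / total for k, v in fit.vcomp.items()}
    out["residual"] = fit.sigma2_resid / total
    return out


def idiosyncratic_model(
    char_table: pd.DataFrame,
    outcome: str,
    nest_by_script_only: bool = False,
):
    """Test whether recently invented one-author scripts are more complex.

    ``char_table`` needs per-character rows with columns script, type,
    idiosyncratic (bool) and the outcome.  The null model nests characters
    by type and script (family deliberately excluded: idiosyncratic scripts
    have no single ancestral family); the test model adds the idiosyncratic
    indicator as a fixed effect.  ``nest_by_script_only`` drops the type
    factor (the follow-up variant restricted to one family).  Returns
    (null_fit, test_fit, ΔAIC).
    """
    d = char_table.copy()
    d["idio"] = d["idiosyncratic"].astype(float)
    groups = ["script"] if nest_by_script_only else ["type", "script"]
    null_fit = fit_random_intercept(d, outcome, [], groups)
    test_fit = fit_random_intercept(d, outcome, ["idio"], groups)
    return null_fit, test_fit, delta_aic(null_fit, test_fit)


@dataclass(frozen=True)
class BayesTestResult:
    """One-sample Bayesian t-test (JZS) outcome."""

    bf_null: float  # Bayes factor in favor of the null (BF01)
    n: int
    t: float
    prior_scale: float


def jzs_bf_null(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS Bayes factor BF01 for a one-sample t statistic.

    The alternative places a Cauchy(0, prior_scale) prior on the
    standardized effect δ; its marginal likelihood is the noncentral-t
    density averaged over the prior, integrated numerically.  BF01 > 1
    favors the null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    f0 = sps.t.pdf(t, nu)

    def integrand(delta):
        return sps.nct.pdf(t, nu, np.sqrt(n) * delta) * sps.cauchy.pdf(
            delta, 0.0, prior_scale
        )

    f1, _ = integrate.quad(integrand, -np.inf, np.inf, limit=400, epsabs=1e-12, epsrel=1e-10)
    return float(f0 / f1)


def jzs_bayes_factor(diffs, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesTestResult:
    """One-sample JZS Bayesian t-test of the values against zero."""
    x = np.asarray(diffs, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t statistic undefined")
    t = x.mean() / (sd / np.sqrt(n))
    return BayesTestResult(
        bf_null=jzs_bf_null(t, n, prior_scale), n=n, t=float(t), prior_scale=prior_scale
    )


@dataclass
class AncestryDifferential:
    """Complexity drift from one ancestor script to its descendants."""

    ancestor: str
    per_descendant: dict[str, float]

    @property
    def mean_differential(self) -> float:
        return float(np.mean(list(self.per_descendant.values())))


def ancestry_differentials(
    script_means: pd.DataFrame,
    value_col: str = "value",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
):
    """Ancestor→descendant complexity differentials and the null test.

    Parameters
    ----------
    script_means : DataFrame with columns ``script``, ``ancestor`` and the
        value column (per-script mean complexity).  Scripts without a
        measured ancestor are skipped (and logged in the returned list).

    Returns
    -------
    (differentials, bayes_result, regression_fit)
        ``differentials`` — one AncestryDifferential per ancestor, each
        contributing a single averaged value so prolific ancestors carry no
        extra weight; ``bayes_result`` — JZS test of the ancestor-averaged
        differentials against 0; ``regression_fit`` — pair-level intercept
        model with ancestor as a random effect (None if fewer than two
        ancestors with two or more pairs).
    """
    means = script_means.set_index("script")[value_col].to_dict()
    ancestors = script_means.set_index("script")["ancestor"].to_dict()
    per_ancestor: dict[str, dict[str, float]] = {}
    for script, anc in ancestors.items():
        if not anc or (isinstance(anc, float) and np.isnan(anc)):
            continue
        if anc not in means or script not in means:
            continue  # ancestor without measured characters: pair skipped
        if np.isnan(means[anc]) or np.isnan(means[script]):
            continue
        per_ancestor.setdefault(anc, {})[script] = means[script] - means[anc]
    diffs = [AncestryDifferential(a, d) for a, d in sorted(per_ancestor.items())]
    if not diffs:
        raise ValueError("no ancestor-descendant pair with measured characters")
    averaged = np.array([d.mean_differential for d in diffs])
    if len(averaged) < 2:
        bayes = None
    elif averaged.std(ddof=1) == 0:
        # degenerate: no variation in the differentials.  All-zero drift is
        # perfect support for the null; constant nonzero drift the opposite.
        bayes = BayesTestResult(
            bf_null=float("inf") if averaged[0] == 0 else 0.0,
            n=len(averaged),
            t=0.0 if averaged[0] == 0 else float("inf"),
            prior_scale=prior_scale,
        )
    else:
        bayes = jzs_bayes_factor(averaged, prior_scale)
    # pair-level regression controlling for ancestor as a random effect
    pair_rows = [
        {"differential": v, "ancestor": a.ancestor}
        for a in diffs
        for v in a.per_descendant.values()
    ]
    pair_df = pd.DataFrame(pair_rows)
    reg = None
    if pair_df["ancestor"].nunique() >= 2:
        reg = fit_varcomp(pair_df, "differential", [], ["ancestor"], reml=True)
    return diffs, bayes, reg


# ---------------------------------------------------------------------------
# Order / laterality model suite
# ---------------------------------------------------------------------------


def _per_character(half_table: pd.DataFrame) -> pd.DataFrame:
    cols = ["script", "family", "type", "directionality", "codepoint",
            "d_fl_pc", "d_fl_ac", "d_lr_pc", "d_lr_ac"]
    per_char = half_table[cols].drop_duplicates(subset=["script", "codepoint"]).copy()
    per_char["rl"] = (per_char["directionality"] == "RL").astype(float)
    per_char["family_script"] = per_char["family"] + ":" + per_char["script"]
    return per_char


def order_models(half_table: pd.DataFrame, metrics=("pc", "ac")) -> dict:
    """Fit the order/laterality regression suite on a half table.

    For each metric the suite contains:

    * ``first_last_intercept`` — Δ_FL ~ 1 with random intercepts for family
      and script-within-family; a positive intercept means first halves are
      more complex.
    * ``first_last_direction`` — Δ_FL ~ directionality(RL), same grouping.
    * ``order_vs_side_daic`` — ΔAIC between two half-level models (data
      points are halves nested in character, script and family): fixed
      effect order(last) versus fixed effect side(right).  Positive values
      mean reading order explains the half complexities better than
      physical side.
    * ``order_fit`` / ``side_fit`` — the two half-level fits themselves.
    * ``left_right_direction`` — Δ_LR ~ directionality(RL), random family
      and script; a negative RL coefficient means the left-half advantage
      shrinks when the right half is read first.

    One metric-independent fit is included under ``discrepancy``:
    D = z(PC) − z(AC) per half ~ side(right) + order(last), halves nested
    in character, script and type.

    Rows from scripts without an LR/RL directionality are dropped.
    """
    df = half_table[half_table["directionality"].isin(["LR", "RL"])].copy()
    if df.empty:
        raise ValueError("no LR/RL rows in half table")
    df["char_id"] = df["script"] + ":" + df["codepoint"].astype(str)
    df["family_script"] = df["family"] + ":" + df["script"]
    df["order_last"] = (df["order"] == "last").astype(float)
    df["side_right"] = (df["side"] == "right").astype(float)
    per_char = _per_character(df)

    out: dict = {}
    for metric in metrics:
        res: dict = {}
        dfl = f"d_fl_{metric}"
        dlr = f"d_lr_{metric}"
        res["first_last_intercept"] = fit_random_intercept(
            per_char, dfl, [], ["family", "family_script"]
        )
        both_directions = per_char["rl"].nunique() > 1
        if both_directions:
            res["first_last_direction"] = fit_random_intercept(
                per_char, dfl, ["rl"], ["family", "family_script"]
            )
            res["left_right_direction"] = fit_random_intercept(
                per_char, dlr, ["rl"], ["family", "family_script"]
            )
        half_groups = ["char_id", "family_script", "family"]
        order_fit = fit_random_intercept(df, metric, ["order_last"], half_groups)
        side_fit = fit_random_intercept(df, metric, ["side_right"], half_groups)
        res["order_fit"] = order_fit
        res["side_fit"] = side_fit
        res["order_vs_side_daic"] = delta_aic(side_fit, order_fit)
        out[metric] = res

    if "d" in df.columns and df["d"].notna().sum() >= 4:
        # with a single direction in the corpus, order == side and the two
        # indicators are collinear; keep side alone in that case
        disc_fixed = (
            ["side_right", "order_last"]
            if df["directionality"].nunique() > 1
            else ["side_right"]
        )
        out["discrepancy"] = fit_random_intercept(
            df, "d", disc_fixed, ["char_id", "family_script", "type"]
        )
    return out


def size_model(
    script_table: pd.DataFrame,
    outcome: str = "mean_pc",
    exclude_large: bool = False,
    large_threshold: int = 200,
):
    """Character-complexity ~ log(inventory size) mixed model at desk scale.

    ``script_table`` needs columns script, family, type, inventory_size and
    the outcome (a per-character table with those columns repeated also
    works; every row is a data point).  Outcome and size are
    log-transformed.  Random intercepts: type and script-within-family.
    Returns (null_fit, test_fit, ΔAIC).
    """
    d = script_table.copy()
    if exclude_large:
        d = d[d["inventory_size"] < large_threshold]
    d["log_size"] = np.log(d["inventory_size"].astype(float))
    d["log_outcome"] = np.log(d[outcome].astype(float))
    d["family_script"] = d["family"] + ":" + d["script"]
    null_fit = fit_random_intercept(d, "log_outcome", [], ["type", "family_script"])
    test_fit = fit_random_intercept(d, "log_outcome", ["log_size"], ["type", "family_script"])
    return null_fit, test_fit, delta_aic(null_fit, test_fit)
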