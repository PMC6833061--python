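"""Statistical layer: group comparisons, logistic models, ROC, DeLong.

Dispatch mirrors common biostatistical practice for cohort tables: unpaired
Student t for a continuous variable across two groups, one-way ANOVA across
three or more, chi-square (without continuity correction by default) for
categorical variables.  Effect estimates from the logistic fits are reported
as odds ratios with Wald 95% CIs.  ROC curves are compared with the DeLong
placement-value test for correlated (paired) curves.

No multiple-testing correction is applied.  All procedures are deterministic
given their input data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# group-comparison table

@dataclass
class GroupComparisonRow:
    variable: str
    kind: str                 # "continuous" | "categorical"
    summaries: dict           # group -> "mean (lo-hi)" or "n (pct%)"
    p_value: float            # NaN when not computable
    test: str                 # "t" | "ANOVA" | "chi-square"


def _is_categorical(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    if series.dtype == object or series.dtype == bool:
        return True
    return set(np.unique(vals)).issubset({0, 1})


def group_comparison_table(cohort: pd.DataFrame, variables: list[str],
                           group_column: str = "group",
                           chi2_correction: bool = False) -> list[GroupComparisonRow]:
    """One row per variable: per-group summary and the dispatched test's p-value.

    Continuous variables are summarized as mean (95% CI); categorical as
    n (%).  Groups with zero observations cause the variable to be skipped
    with a warning; zero-variance continuous variables get a missing p.
    """
    groups = [g for g in cohort[group_column].dropna().unique()]
    if len(groups) < 2:
        raise StatsError("need at least two non-empty groups")
    rows: list[GroupComparisonRow] = []
    for var in variables:
        per_group = {g: cohort.loc[cohort[group_column] == g, var].dropna()
                     for g in groups}
        if any(len(v) == 0 for v in per_group.values()):
            logger.warning("variable %s skipped: a group has no observations", var)
            continue
        if _is_categorical(cohort[var]):
            counts = {g: int(v.sum()) for g, v in per_group.items()}
            ns = {g: len(v) for g, v in per_group.items()}
            table = np.array([[counts[g], ns[g] - counts[g]] for g in groups])
            if (table.sum(axis=1) > 0).all() and table.sum(axis=0).min() > 0:
                p = float(sps.chi2_contingency(table, correction=chi2_correction)[1])
            else:
                p = float("nan")
            summaries = {g: f"{counts[g]} ({100 * counts[g] / ns[g]:.2f}%)"
                         for g in groups}
            rows.append(GroupComparisonRow(var, "categorical", summaries, p, "chi-square"))
        else:
            arrays = [per_group[g].to_numpy(dtype=float) for g in groups]
            if all(np.var(a) == 0 for a in arrays):
                p, test = float("nan"), "t" if len(groups) == 2 else "ANOVA"
            elif len(groups) == 2:
                p = float(sps.ttest_ind(arrays[0], arrays[1], equal_var=True).pvalue)
                test = "t"
            else:
                p = float(sps.f_oneway(*arrays).pvalue)
                test = "ANOVA"
            summaries = {}
            for g, a in zip(groups, arrays):
                m = float(np.mean(a))
                half = Z95 * float(np.std(a, ddof=1)) / math.sqrt(len(a)) if len(a) > 1 else 0.0
                summaries[g] = f"{m:.3f} ({m - half:.3f}–{m + half:.3f})"
            rows.append(GroupComparisonRow(var, "continuous", summaries, p, test))
    return rows


def comparison_rows_to_frame(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {"variable": r.variable, "kind": r.kind, "test": r.test,
               "p_value": r.p_value}
        rec.update(r.summaries)
        recs.append(rec)
    return pd.DataFrame(recs)


# --------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``table`` has one row per term (const first): estimate, se, odds_ratio,
    ci_low, ci_high, p_value.  ``separation`` flags (quasi-)complete
    separation; estimates are then reported with a warning rather than
    silently diverging.
    """

    outcome: str
    covariates: list[str]
    table: pd.DataFrame
    log_likelihood: float
    converged: bool
    separation: bool = False
    model: object = field(default=None, repr=False)

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "odds_ratio"])

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(cohort[self.covariates].astype(float), has_constant="add")
        return np.asarray(self.model.predict(X))


def fit_logistic(cohort: pd.DataFrame, outcome: str,
                 covariates: list[str], standardize: bool = False) -> LogisticFit:
    """Logistic regression of a binary outcome on the given covariates.

    With ``standardize`` the continuous covariates are scaled to unit SD so
    per-unit odds ratios are comparable across metrics.  Raises on singular
    designs, naming the collinear columns; flags separation instead of
    letting the optimizer run away.
    """
    data = cohort[[outcome] + covariates].dropna()
    y = data[outcome].astype(float).to_numpy()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise StatsError(f"outcome {outcome!r} must contain both classes")
    if len(data) <= len(covariates) + 1:
        raise StatsError(f"n={len(data)} too small for {len(covariates)} covariates")
    X = data[covariates].astype(float).copy()
    constant = [c for c in covariates if X[c].nunique() < 2]
    if constant:
        raise StatsError(f"covariates with no variation: {constant}")
    if standardize:
        for c in covariates:
            sd = X[c].std(ddof=0)
            if sd > 0 and not _is_categorical(X[c]):
                X[c] = (X[c] - X[c].mean()) / sd
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # point at columns whose removal restores full rank
        bad = []
        for c in covariates:
            sub = Xc.drop(columns=[c])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(c)
        raise StatsError(f"singular design; collinear columns: {bad or covariates}")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, Exception) as exc:
            # perfect separation or a singular Hessian: fall back to a
            # weakly-ridged fit and flag, rather than silently diverging
            if isinstance(exc, np.linalg.LinAlgError) or "separation" in str(exc).lower():
                separation = True
                res = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
            else:
                raise
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
    if separation:
        logger.warning("outcome %s: (quasi-)separation detected; estimates unstable",
                       outcome)

    params = np.asarray(res.params, dtype=float)
    try:
        se = np.asarray(res.bse, dtype=float)
    except Exception:
        se = np.full_like(params, np.nan)
    z = np.divide(params, se, out=np.full_like(params, np.nan), where=se > 0)
    pvals = 2 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # CI bounds may saturate under separation
        table = pd.DataFrame(
            {
                "estimate": params,
                "se": se,
                "odds_ratio": np.exp(params),
                "ci_low": np.exp(params - Z95 * se),
                "ci_high": np.exp(params + Z95 * se),
                "p_value": pvals,
            },
            index=list(Xc.columns),
        )
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True)) and not separation
    return LogisticFit(outcome=outcome, covariates=list(covariates), table=table,
                       log_likelihood=float(res.llf), converged=converged,
                       separation=separation, model=res)


def univariate_logistic(cohort: pd.DataFrame, outcome: str,
                        covariates: list[str]) -> pd.DataFrame:
    """One single-covariate fit per term; rows indexed by covariate."""
    recs = []
    for c in covariates:
        try:
            fit = fit_logistic(cohort, outcome, [c])
            row = fit.table.loc[c].to_dict()
        except StatsError as exc:
            logger.warning("univariate fit for %s skipped: %s", c, exc)
            row = {k: float("nan") for k in
                   ("estimate", "se", "odds_ratio", "ci_low", "ci_high", "p_value")}
        row["covariate"] = c
        recs.append(row)
    return pd.DataFrame(recs).set_index("covariate")


# --------------------------------------------------------------------------
# ROC and DeLong

@dataclass
class RocResult:
    """Empirical ROC curve plus the placement values needed for DeLong."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    placements_pos: np.ndarray   # V10, one per positive subject
    placements_neg: np.ndarray   # V01, one per negative subject
    scores: np.ndarray
    labels: np.ndarray


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def roc_auc(scores, labels) -> RocResult:
    """Empirical ROC; AUC via the Mann–Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise StatsError("both outcome classes must be present for a ROC curve")
    # placement values from midranks (DeLong's computation)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    r_pos, r_neg = all_ranks[:m], all_ranks[m:]
    v10 = (r_pos - _midranks(pos)) / n          # P(score > random negative)
    v01 = 1.0 - (r_neg - _midranks(neg)) / m
    auc = float(v10.mean())
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(thresholds=thr, sensitivity=tpr, specificity=1 - fpr,
                     auc=auc, n_pos=m, n_neg=n,
                     placements_pos=v10, placements_neg=v01,
                     scores=scores, labels=labels)


@dataclass
class ModelComparison:
    auc_full: float
    auc_reduced: float
    auc_difference: float
    variance: float
    z: float
    p_value: float


def delong_compare(roc_full: RocResult, roc_reduced: RocResult) -> ModelComparison:
    """DeLong test for two correlated ROC curves on the same subjects.

    The variance of the AUC difference comes from the empirical covariance of
    the paired placement values; identical score vectors give ΔAUC = 0 with
    p = 1 by convention (zero variance).
    """
    if roc_full.n_pos != roc_reduced.n_pos or roc_full.n_neg != roc_reduced.n_neg \
            or not np.array_equal(roc_full.labels, roc_reduced.labels):
        raise StatsError("DeLong comparison requires paired ROCs on identical subjects")
    m, n = roc_full.n_pos, roc_full.n_neg
    v10 = np.vstack([roc_full.placements_pos, roc_reduced.placements_pos])
    v01 = np.vstack([roc_full.placements_neg, roc_reduced.placements_neg])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = roc_full.auc - roc_reduced.auc
    if var <= 0:
        z = 0.0 if delta == 0 else math.inf * np.sign(delta)
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return ModelComparison(auc_full=roc_full.auc, auc_reduced=roc_reduced.auc,
                           auc_difference=float(delta), variance=float(var),
                           z=float(z), p_value=p)


@dataclass
class IncrementalValueResult:
    """Headline output: does adding a spectral metric to the clinical model help?"""

    fit_reduced: LogisticFit
    fit_full: LogisticFit
    roc_reduced: RocResult
    roc_full: RocResult
    comparison: ModelComparison


def incremental_value_analysis(cohort: pd.DataFrame, base_covariates: list[str],
                               added_metric: str, outcome: str) -> IncrementalValueResult:
    """Fit reduced (clinical) and full (clinical + metric) logistic models on
    the same subjects, score both, and compare AUCs with the paired DeLong test.

    An empty ``base_covariates`` list gives an intercept-only reduced model
    whose constant scores yield AUC 0.5 exactly.
    """
    cols = [outcome] + base_covariates + [added_metric]
    data = cohort[cols].dropna().reset_index(drop=True)
    y = data[outcome].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise StatsError(f"outcome {outcome!r} has a single class after dropping NaNs")

    if base_covariates:
        fit_reduced = fit_logistic(data, outcome, base_covariates)
        scores_reduced = fit_reduced.predict(data)
    else:
        # intercept-only: constant fitted probability
        Xc = sm.add_constant(pd.DataFrame(index=data.index), has_constant="add")
        res = sm.Logit(y.astype(float), Xc).fit(disp=0)
        table = pd.DataFrame({"estimate": res.params, "se": res.bse,
                              "odds_ratio": np.exp(res.params),
                              "ci_low": np.exp(res.params - Z95 * res.bse),
                              "ci_high": np.exp(res.params + Z95 * res.bse),
                              "p_value": res.pvalues}, index=["const"])
        fit_reduced = LogisticFit(outcome, [], table, float(res.llf), True, model=res)
        scores_reduced = np.full(len(data), float(y.mean()))
    fit_full = fit_logistic(data, outcome, base_covariates + [added_metric])
    scores_full = fit_full.predict(data)

    roc_reduced = roc_auc(scores_reduced, y)
    roc_full = roc_auc(scores_full, y)
    comparison = delong_compare(roc_full, roc_reduced)
    return IncrementalValueResult(fit_reduced, fit_full, roc_reduced, roc_full,
                                  comparison)


def plot_roc_comparison(result: IncrementalValueResult, path,
                        labels=("full model", "reduced model")) -> None:
    """Optional ROC overlay figure (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for roc, lab in ((result.roc_full, labels[0]), (result.roc_reduced, labels[1])):
        ax.plot(1 - roc.specificity, roc.sensitivity,
                label=f"{lab} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    ax.set_title(f"DeLong p = {result.comparison.p_value:.3g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
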