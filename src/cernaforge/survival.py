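"""Univariate Cox screening, linear risk scores, mean-cutoff stratification,
Kaplan-Meier curves and the log-rank test.

The risk score of a patient is the linear combination of a gene set's
expression values weighted by each gene's univariate Cox regression
coefficient: score = sum_i r_i * Exp_i.  Patients scoring strictly above the
cohort mean form the high-risk group (a score exactly at the mean goes to
low risk), and the two groups are compared by Kaplan-Meier curves with a
log-rank test.  Cox partial likelihoods use Efron tie handling via lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CoxFit:
    """One gene's univariate proportional-hazards fit."""

    gene_id: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    n_events: int
    converged: bool = True


@dataclass
class RiskModel:
    """Gene set with per-gene Cox coefficients; scores are linear in expression."""

    genes: list[str]
    coefs: dict[str, float]

    def score(self, expr: ExpressionMatrix, samples: list[str] | None = None) -> pd.Series:
        return risk_score(self, expr, samples=samples)


@dataclass
class StratifiedCohort:
    scores: pd.Series
    groups: pd.Series  # 'high' / 'low'
    km_curves: dict[str, pd.DataFrame]
    logrank_statistic: float
    logrank_p: float
    fits: list[CoxFit] = field(default_factory=list)


def fit_cox_univariate(expr_vector: pd.Series, clinical: pd.DataFrame) -> CoxFit:
    """Univariate Cox PH fit of survival on one gene's expression.

    Requires >=2 observed events and a non-constant covariate among the
    analysed samples.  A monotone-likelihood failure is returned as a flagged
    fit with an infinite hazard-ratio marker rather than raised.
    """
    gene = str(expr_vector.name) if expr_vector.name is not None else "gene"
    common = clinical.index.intersection(expr_vector.index)
    df = pd.DataFrame(
        {
            "time": clinical.loc[common, "time"].astype(float),
            "event": clinical.loc[common, "event"].astype(int),
            "x": expr_vector.loc[common].astype(float),
        }
    ).dropna()
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError(f"{gene}: need >=2 observed events, got {n_events}")
    if df["x"].nunique() < 2:
        raise ValueError(f"{gene}: no information — covariate is constant")
    cph = CoxPHFitter()
    converged = True
    try:
        import warnings

        from lifelines.exceptions import ConvergenceWarning

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False  # monotone likelihood / separation suspected
    except ConvergenceError:
        direction = float(np.sign(df[["x", "event"]].corr().iloc[0, 1]) or 1.0)
        return CoxFit(
            gene_id=gene, coef=np.inf * direction, hr=np.inf if direction > 0 else 0.0,
            ci_low=np.nan, ci_high=np.nan, p=np.nan,
            n_used=len(df), n_events=n_events, converged=False,
        )
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    with np.errstate(over="ignore"):
        return CoxFit(
            gene_id=gene,
            coef=coef,
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.959963984540054 * se)),
            ci_high=float(np.exp(coef + 1.959963984540054 * se)),
            p=float(cph.summary.loc["x", "p"]),
            n_used=len(df),
            n_events=n_events,
            converged=converged,
        )


def risk_score(
    model: RiskModel, expr: ExpressionMatrix, samples: list[str] | None = None
) -> pd.Series:
    """Per-sample linear risk score sum_i r_i * Exp_i.

    Samples missing expression for any model gene are scored NaN and counted
    in the log.  The score is invariant to gene ordering.
    """
    missing_genes = [g for g in model.genes if g not in expr.values.index]
    if missing_genes:
        raise ValueError(f"model genes absent from expression: {missing_genes[:5]}")
    cols = samples if samples is not None else expr.samples
    sub = expr.values.loc[model.genes, cols]
    coefs = np.array([model.coefs[g] for g in model.genes])
    scores = pd.Series(coefs @ sub.to_numpy(), index=cols, name="risk_score")
    incomplete = sub.isna().any(axis=0)
    if incomplete.any():
        scores[incomplete.to_numpy()] = np.nan
        logger.info("risk_score: %d samples lacked expression for >=1 model gene",
                    int(incomplete.sum()))
    return scores


def stratify_by_mean(scores: pd.Series) -> pd.Series:
    """'high' if score > mean(scores), else 'low' (ties at the mean go low)."""
    scores = scores.dropna()
    if len(scores) < 2:
        raise ValueError("need >=2 scored samples")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no split possible")
    mean = scores.mean()
    groups = pd.Series(np.where(scores > mean, "high", "low"), index=scores.index, name="group")
    if groups.nunique() < 2:
        raise ValueError("degenerate split: one group is empty")
    return groups


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a right-continuous step table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty cohort")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, 1-df p-value)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() < 1:
        raise ValueError("need >=1 event overall")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def compare_expression_groups(
    expr_vector, labels, test: str = "wilcoxon"
) -> tuple[float, float]:
    """Two-sided two-group location test for one gene's expression.

    Default is the Wilcoxon rank-sum (Mann-Whitney U; exact for small
    tie-free groups, normal approximation with tie correction otherwise);
    ``test='t'`` selects Welch's t-test.  Both groups need >=3 samples.
    """
    x = np.asarray(expr_vector, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    a, b = x[labels == uniq[0]], x[labels == uniq[1]]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if min(len(a), len(b)) < 3:
        raise ValueError("each group needs >=3 samples")
    if test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def module_prognosis(
    module_genes: list[str],
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    subset_filter: dict[str, str] | None = None,
) -> StratifiedCohort:
    """Risk-score survival stratification for a module's gene set.

    Fits a univariate Cox model per module gene on the selected sample
    subset, combines the fitted coefficients into a linear risk score,
    splits the subset at the mean score, and compares the two groups by
    Kaplan-Meier curves and a log-rank test.  ``subset_filter`` is a mapping
    of clinical columns to required values (e.g. ``{"subtype": "LumA"}``).
    """
    sub = clinical
    if subset_filter:
        for col, val in subset_filter.items():
            if col not in sub.columns:
                raise ValueError(f"clinical table has no column {col!r}")
            sub = sub[sub[col] == val]
    sub = sub.loc[sub.index.intersection(expr.samples)]
    if len(sub) == 0:
        raise ValueError("subset filter matches zero samples")
    if int(sub["event"].sum()) < 2:
        raise ValueError("subset has <2 observed events")
    fits: list[CoxFit] = []
    for gene in module_genes:
        if gene not in expr.values.index:
            logger.info("module_prognosis: gene %s missing from expression, skipped", gene)
            continue
        try:
            fit = fit_cox_univariate(expr.values.loc[gene, list(sub.index)].rename(gene), sub)
        except ValueError as exc:
            logger.info("module_prognosis: %s", exc)
            continue
        if fit.converged:
            fits.append(fit)
    if not fits:
        raise ValueError("no module gene produced a usable Cox fit")
    model = RiskModel(genes=[f.gene_id for f in fits], coefs={f.gene_id: f.coef for f in fits})
    scores = risk_score(model, expr, samples=list(sub.index))
    groups = stratify_by_mean(scores)
    km_curves = {}
    for label in ("high", "low"):
        ids = groups.index[groups == label]
        km_curves[label] = kaplan_meier(sub.loc[ids, "time"], sub.loc[ids, "event"])
    hi = groups.index[groups == "high"]
    lo = groups.index[groups == "low"]
    statistic, p = logrank_test(
        sub.loc[hi, "time"], sub.loc[hi, "event"], sub.loc[lo, "time"], sub.loc[lo, "event"]
    )
    return StratifiedCohort(
        scores=scores, groups=groups, km_curves=km_curves,
        logrank_statistic=statistic, logrank_p=p, fits=fits,
    )
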