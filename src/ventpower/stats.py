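"""Statistical evaluation of the ventilatory indexes.

Covers the full analysis plan: Spearman correlations with
Fisher-z confidence intervals, ROC/AUROC with Hanley–McNeil intervals,
Youden-index operating thresholds, the derived diagnostic-accuracy panel,
repeated stratified cross-validation of threshold-based prediction,
rank/contingency group comparisons, forward-selection logistic regression
with Hosmer–Lemeshow calibration and Nagelkerke R^2, and a two-way mixed
(split-plot) ANOVA for index trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SpearmanResult", "RocResult", "DiagnosticMetrics", "CVReport",
    "LogisticModel", "AnovaResult", "spearman_with_ci", "auroc",
    "youden_threshold", "diagnostic_metrics", "confusion_at_threshold",
    "repeated_cv_evaluate", "group_compare", "fit_logistic_forward",
    "mixed_anova",
]


# --------------------------------------------------------------------------
# correlation

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float


def spearman_with_ci(x: Sequence[float], y: Sequence[float],
                     alpha: float = 0.05) -> SpearmanResult:
    """Spearman's rho with a Fisher-z confidence interval.

    rho is the Pearson correlation of mid-ranks (average ranks on ties); the
    CI back-transforms ``atanh(rho) ± z_(1−alpha/2)/sqrt(n−3)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    half = zcrit / math.sqrt(n - 3)
    return SpearmanResult(rho=rho, ci_low=math.tanh(z - half),
                          ci_high=math.tanh(z + half), n=n,
                          p_value=float(res.pvalue))


# --------------------------------------------------------------------------
# ROC

def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "higher_is_positive":
        return scores
    if orientation == "lower_is_positive":
        return -scores
    raise ValueError(f"unknown orientation {orientation!r}")


@dataclass(frozen=True)
class RocResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def auroc(scores: Sequence[float], labels: Sequence[int],
          orientation: str = "higher_is_positive",
          alpha: float = 0.05) -> RocResult:
    """AUROC by the Mann–Whitney estimator (ties count one half).

    The confidence interval uses the Hanley–McNeil variance approximation,
    clipped to [0, 1].
    """
    s = _oriented(np.asarray(scores, dtype=float), orientation)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    a = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a)
           + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    zcrit = sps.norm.ppf(1 - alpha / 2)
    return RocResult(auroc=float(a),
                     ci_low=max(0.0, a - zcrit * se),
                     ci_high=min(1.0, a + zcrit * se),
                     n_pos=n1, n_neg=n0)


def youden_threshold(scores: Sequence[float], labels: Sequence[int],
                     orientation: str = "higher_is_positive"
                     ) -> tuple[float, float]:
    """Operating threshold maximising Youden's J = sens + spec − 1.

    Candidates are the midpoints between adjacent sorted unique scores plus
    ±inf; the decision rule is "positive if score >= t" after orientation.
    Ties in J are broken toward the smallest oriented threshold. Returns
    ``(threshold, j)`` on the oriented scale (negate to recover original
    units for a lower-is-positive index).
    """
    s = _oriented(np.asarray(scores, dtype=float), orientation)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    u = np.unique(s)
    candidates = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]))
    # vectorised sens/spec over all candidates
    sens = 1.0 - np.searchsorted(np.sort(pos), candidates, side="left") / len(pos)
    spec = np.searchsorted(np.sort(neg), candidates, side="left") / len(neg)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (smallest) on ties
    return float(candidates[best]), float(j[best])


# --------------------------------------------------------------------------
# diagnostic accuracy

@dataclass(frozen=True)
class DiagnosticMetrics:
    sens: float
    spec: float
    ppv: float
    npv: float
    accuracy: float
    plr: float
    nlr: float
    dor: float
    f1: float
    mcc: float
    threshold: float = math.nan
    flags: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("sens", "spec", "ppv", "npv", "accuracy", "plr", "nlr",
                 "dor", "f1", "mcc", "threshold")}


def _safe_div(num: float, den: float, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def diagnostic_metrics(tp: int, fp: int, fn: int, tn: int,
                       threshold: float = math.nan) -> DiagnosticMetrics:
    """Standard confusion-matrix panel; 0/0 forms are reported as 0, flagged."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("cell counts must be non-negative")
    n = tp + fp + fn + tn
    if n < 1:
        raise ValueError("empty confusion matrix")
    flags: set[str] = set()
    sens = _safe_div(tp, tp + fn, "sens", flags)
    spec = _safe_div(tn, tn + fp, "spec", flags)
    ppv = _safe_div(tp, tp + fp, "ppv", flags)
    npv = _safe_div(tn, tn + fn, "npv", flags)
    acc = (tp + tn) / n
    plr = _safe_div(sens, 1 - spec, "plr", flags)
    nlr = _safe_div(1 - sens, spec, "nlr", flags)
    dor = _safe_div(plr, nlr, "dor", flags)
    f1 = _safe_div(2 * ppv * sens, ppv + sens, "f1", flags)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom, "mcc", flags)
    return DiagnosticMetrics(sens=sens, spec=spec, ppv=ppv, npv=npv,
                             accuracy=acc, plr=plr, nlr=nlr, dor=dor,
                             f1=f1, mcc=mcc, threshold=threshold,
                             flags=frozenset(flags))


def confusion_at_threshold(scores: Sequence[float], labels: Sequence[int],
                           threshold: float,
                           orientation: str = "higher_is_positive"
                           ) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) for the rule "positive if oriented score >= t"."""
    s = _oriented(np.asarray(scores, dtype=float), orientation)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return tp, fp, fn, tn


# --------------------------------------------------------------------------
# repeated stratified cross-validation

_METRIC_KEYS = ("sens", "spec", "ppv", "npv", "accuracy", "plr", "nlr",
                "dor", "f1", "mcc")


@dataclass
class CVReport:
    """Fold-mean diagnostic metrics with t-based 95% CIs, per index."""

    repeats: int
    folds: int
    mean_metrics: dict[str, dict[str, float]]
    ci_low: dict[str, dict[str, float]]
    ci_high: dict[str, dict[str, float]]
    mean_threshold: dict[str, float]
    fold_assignments: pd.DataFrame = field(repr=False, default=None)
    fold_metrics: dict[str, pd.DataFrame] = field(repr=False,
                                                  default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Diagnostic-accuracy table: one row per index."""
        rows = []
        for name, met in self.mean_metrics.items():
            row = {"index": name, "threshold": self.mean_threshold[name]}
            for k in _METRIC_KEYS:
                row[k] = met[k]
                row[f"{k}_ci_low"] = self.ci_low[name][k]
                row[f"{k}_ci_high"] = self.ci_high[name][k]
            rows.append(row)
        return pd.DataFrame(rows)


def _t_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    m = values.mean()
    if len(values) < 2:
        return m, m
    half = sps.t.ppf(1 - alpha / 2, len(values) - 1) * sps.sem(values)
    return m - half, m + half


def repeated_cv_evaluate(values: pd.DataFrame, labels: Sequence[int],
                         orientation: dict[str, str],
                         repeats: int = 2, folds: int = 5,
                         seed: int = 0, alpha: float = 0.05,
                         max_retries: int = 20) -> CVReport:
    """Repeated stratified k-fold evaluation of Youden-threshold prediction.

    Per repeat, a label-stratified random partition into ``folds`` folds;
    per fold, the operating threshold is learned on the training part
    (Youden) and the diagnostic panel is measured on the held-out fold.
    Reports fold-means with t-based CIs and the mean training threshold in
    original index units.
    """
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if min(n1, n0) < folds:
        raise ValueError("each class must have at least `folds` members")
    rng = np.random.default_rng(seed)

    partitions = []  # (repeat, fold, test_idx) with valid folds
    for rep in range(repeats):
        for _attempt in range(max_retries):
            state = int(rng.integers(0, 2**31 - 1))
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=state)
            splits = list(skf.split(np.zeros(len(y)), y))
            if all(len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2
                   for tr, te in splits):
                partitions.append((rep, splits))
                break
        else:
            raise RuntimeError("could not draw a partition with both classes "
                               "in every fold")

    assign_rows = []
    mean_metrics, lo, hi, mean_thr, fold_tables = {}, {}, {}, {}, {}
    for name in values.columns:
        s = values[name].to_numpy(dtype=float)
        orient = orientation[name]
        sign = 1.0 if orient == "higher_is_positive" else -1.0
        rows = []
        for rep, splits in partitions:
            for k, (tr, te) in enumerate(splits):
                thr, _j = youden_threshold(s[tr], y[tr], orient)
                cm = confusion_at_threshold(s[te], y[te], thr, orient)
                met = diagnostic_metrics(*cm, threshold=sign * thr)
                row = {"repeat": rep, "fold": k}
                row.update(met.as_dict())
                rows.append(row)
        tab = pd.DataFrame(rows)
        fold_tables[name] = tab
        mean_metrics[name] = {k: float(tab[k].mean()) for k in _METRIC_KEYS}
        cis = {k: _t_ci(tab[k].to_numpy(), alpha) for k in _METRIC_KEYS}
        lo[name] = {k: float(c[0]) for k, c in cis.items()}
        hi[name] = {k: float(c[1]) for k, c in cis.items()}
        mean_thr[name] = float(tab["threshold"].mean())
    for rep, splits in partitions:
        for k, (_tr, te) in enumerate(splits):
            for i in te:
                assign_rows.append({"repeat": rep, "fold": k,
                                    "subject": int(i)})
    return CVReport(repeats=repeats, folds=folds, mean_metrics=mean_metrics,
                    ci_low=lo, ci_high=hi, mean_threshold=mean_thr,
                    fold_assignments=pd.DataFrame(assign_rows),
                    fold_metrics=fold_tables)


# --------------------------------------------------------------------------
# group comparisons

def group_compare(a, b=None, kind: str = "ranksum") -> tuple[float, float]:
    """Two-group comparison: Mann–Whitney rank sum, chi-square, or Fisher.

    ``ranksum`` takes two value vectors and uses the exact null distribution
    for small samples (both groups <= 8, no ties) and the tie-corrected
    normal approximation otherwise. ``chisq``/``fisher`` take a 2x2 count
    table as ``a``.
    """
    if kind == "ranksum":
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError("empty group")
        pooled = np.concatenate([x, y])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(x), len(y)) <= 8 and not ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    table = np.asarray(a, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("contingency comparisons need a 2x2 table")
    if kind == "chisq":
        res = sps.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "fisher":
        stat, p = sps.fisher_exact(table, alternative="two-sided")
        return float(stat), float(p)
    raise ValueError(f"unknown comparison kind {kind!r}")


# --------------------------------------------------------------------------
# forward-selection logistic regression

@dataclass
class LogisticModel:
    selected: list[str]
    coefficients: dict[str, float]
    odds_ratios: dict[str, tuple[float, float, float]]  # OR, lo, hi (scaled)
    hosmer_lemeshow: tuple[float, int, float]  # statistic, df, p
    nagelkerke_r2: float
    llf: float
    llnull: float


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    import statsmodels.api as sm
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # noqa: BLE001 - report the failing design
        raise RuntimeError(
            f"logistic fit failed for variables {list(X.columns)}: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"logistic fit did not converge for {list(X.columns)} "
            "(possible separation)")
    return res


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray,
                    groups: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit over risk-decile groups."""
    order = np.argsort(p, kind="mergesort")
    y_s, p_s = y[order], p[order]
    edges = np.linspace(0, len(y), groups + 1).astype(int)
    stat = 0.0
    used = 0
    for g in range(groups):
        sl = slice(edges[g], edges[g + 1])
        ng = edges[g + 1] - edges[g]
        if ng == 0:
            continue
        o = y_s[sl].sum()
        e = p_s[sl].sum()
        denom = e * (1 - e / ng)
        if denom > 0:
            stat += (o - e) ** 2 / denom
            used += 1
    df = max(used - 2, 1)
    return float(stat), df, float(sps.chi2.sf(stat, df))


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke's R^2 from model and null log-likelihoods."""
    d, d0 = -2 * llf, -2 * llnull
    cox_snell = 1 - math.exp((d - d0) / n)
    max_cs = 1 - math.exp(-d0 / n)
    return cox_snell / max_cs if max_cs > 0 else 0.0


def fit_logistic_forward(design: pd.DataFrame, outcome: Sequence[int],
                         candidates: Sequence[str],
                         entry_alpha: float = 0.05,
                         unit_scale: Optional[dict[str, float]] = None
                         ) -> LogisticModel:
    """Forward-selected binary logistic regression.

    At each step the candidate with the smallest likelihood-ratio p-value is
    added if p < ``entry_alpha``. Odds ratios are reported per
    ``unit_scale[var]`` units of the variable (default 1), with Wald 95% CIs
    on the same scale.
    """
    y = np.asarray(outcome, dtype=int)
    if design.isna().any().any():
        raise ValueError("design table contains missing values")
    if len(y) <= len(candidates):
        raise ValueError("need more observations than candidates")
    unit_scale = dict(unit_scale or {})
    selected: list[str] = []
    remaining = list(candidates)
    null_res = _fit_logit(design[[]], y)
    cur_llf = null_res.llf
    llnull = null_res.llf
    while remaining:
        best_p, best_var, best_llf = None, None, None
        for var in remaining:
            res = _fit_logit(design[selected + [var]], y)
            lr = 2 * (res.llf - cur_llf)
            p = sps.chi2.sf(max(lr, 0.0), 1)
            if best_p is None or p < best_p:
                best_p, best_var, best_llf = p, var, res.llf
        if best_p is None or best_p >= entry_alpha:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        cur_llf = best_llf

    if selected:
        final = _fit_logit(design[selected], y)
        llf = final.llf
        coefs = {v: float(final.params[v]) for v in selected}
        ors = {}
        zcrit = sps.norm.ppf(0.975)
        for v in selected:
            scale = unit_scale.get(v, 1.0)
            b, se = float(final.params[v]), float(final.bse[v])
            ors[v] = (math.exp(b * scale),
                      math.exp((b - zcrit * se) * scale),
                      math.exp((b + zcrit * se) * scale))
        p_hat = np.asarray(final.predict())
    else:
        llf = llnull
        coefs, ors = {}, {}
        p_hat = np.full(len(y), y.mean(), dtype=float)
    hl = hosmer_lemeshow(y, p_hat)
    return LogisticModel(selected=selected, coefficients=coefs,
                         odds_ratios=ors, hosmer_lemeshow=hl,
                         nagelkerke_r2=nagelkerke_r2(llf, llnull, len(y)),
                         llf=float(llf), llnull=float(llnull))


# --------------------------------------------------------------------------
# mixed (split-plot) ANOVA

@dataclass(frozen=True)
class AnovaResult:
    f_between: float
    df_between: tuple[int, int]
    p_between: float
    f_time: float
    df_time: tuple[int, int]
    p_time: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float


def mixed_anova(data: pd.DataFrame, value: str = "value",
                subject: str = "patient_id", within: str = "quartile",
                between: str = "group") -> AnovaResult:
    """Two-way mixed ANOVA (between: group; within: time quartile).

    Requires a balanced within-factor: every subject contributes every time
    level exactly once. Group sizes may differ. No sphericity correction is
    applied. Uses the standard split-plot sums-of-squares decomposition with
    group-size-weighted cell means.
    """
    d = data[[subject, within, between, value]].dropna()
    times = np.sort(d[within].unique())
    t = len(times)
    counts = d.groupby(subject)[within].nunique()
    per_subj = d.groupby(subject)[within].count()
    if (counts != t).any() or (per_subj != t).any():
        raise ValueError("missing cells: every subject needs every "
                         "within-factor level exactly once")
    groups = np.sort(d[between].unique())
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    n_subj = d[subject].nunique()
    grand = d[value].mean()

    subj_means = d.groupby(subject)[value].mean()
    subj_group = d.groupby(subject)[between].first()
    group_means = d.groupby(between)[value].mean()
    time_means = d.groupby(within)[value].mean()
    cell_means = d.groupby([between, within])[value].mean()
    n_per_group = subj_group.value_counts()

    ss_total = float(((d[value] - grand) ** 2).sum())
    ss_between_subj = float(t * ((subj_means - grand) ** 2).sum())
    ss_group = float(t * sum(n_per_group[gr] * (group_means[gr] - grand) ** 2
                             for gr in groups))
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(n_subj * ((time_means - grand) ** 2).sum())
    ss_cells = float(sum(
        n_per_group[gr] * (cell_means[(gr, ti)] - grand) ** 2
        for gr in groups for ti in times))
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_between_subj - ss_time - ss_inter

    df_group = g - 1
    df_subj = n_subj - g
    df_time = t - 1
    df_inter = df_group * df_time
    df_error = df_subj * df_time

    ms = lambda ss, df: ss / df if df > 0 else math.nan  # noqa: E731
    ms_subj = ms(ss_subj_within, df_subj)
    ms_error = ms(ss_error, df_error)
    f_group = max(ms(ss_group, df_group) / ms_subj, 0.0) if ms_subj > 0 else math.nan
    f_time = max(ms(ss_time, df_time) / ms_error, 0.0) if ms_error > 0 else math.nan
    f_inter = max(ms(ss_inter, df_inter) / ms_error, 0.0) if ms_error > 0 else math.nan
    sf = sps.f.sf
    return AnovaResult(
        f_between=float(f_group), df_between=(df_group, df_subj),
        p_between=float(sf(f_group, df_group, df_subj)),
        f_time=float(f_time), df_time=(df_time, df_error),
        p_time=float(sf(f_time, df_time, df_error)),
        f_interaction=float(f_inter), df_interaction=(df_inter, df_error),
        p_interaction=float(sf(f_inter, df_inter, df_error)),
    )
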