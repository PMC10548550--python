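"""Statistical primitives against independent oracles and worked values."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ventpower.stats import (auroc, confusion_at_threshold,
                             diagnostic_metrics, fit_logistic_forward,
                             group_compare, hosmer_lemeshow, mixed_anova,
                             nagelkerke_r2, repeated_cv_evaluate,
                             spearman_with_ci, youden_threshold)


# --------------------------------------------------------------------------
# Spearman with Fisher-z CI

def test_spearman_perfect_antitone():
    res = spearman_with_ci([1, 2, 3, 4], [4, 3, 2, 1])
    assert res.rho == pytest.approx(-1.0)


@pytest.mark.parametrize("rho,lo,hi", [
    (0.452, 0.345, 0.548),
    (0.252, 0.129, 0.369),
])
def test_fisher_z_interval_at_n237(rho, lo, hi):
    """Fisher-z CI endpoints at n=237 for the two study correlations.

    Endpoints are checked to two units in the third decimal: the input rho is
    itself a 3-decimal display value, and that rounding propagates to ~1e-3
    on the back-transformed endpoint (e.g. the 0.252 upper bound computes to
    0.3676 from the displayed rho but is printed 0.369).
    """
    z = math.atanh(rho)
    half = sps.norm.ppf(0.975) / math.sqrt(237 - 3)
    assert math.tanh(z - half) == pytest.approx(lo, abs=2e-3)
    assert math.tanh(z + half) == pytest.approx(hi, abs=2e-3)


def test_spearman_ci_matches_direct_fisher_formula(rng):
    x = rng.normal(size=60)
    y = 0.5 * x + rng.normal(size=60)
    res = spearman_with_ci(x, y)
    z = math.atanh(res.rho)
    half = sps.norm.ppf(0.975) / math.sqrt(57)
    assert res.ci_low == pytest.approx(math.tanh(z - half), rel=1e-12)
    assert res.ci_high == pytest.approx(math.tanh(z + half), rel=1e-12)
    assert res.ci_low <= res.rho <= res.ci_high


def test_spearman_rejects_constant_input():
    with pytest.raises(ValueError, match="constant"):
        spearman_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


# --------------------------------------------------------------------------
# AUROC

def _auroc_bruteforce(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("scores,labels,expected", [
    ([2, 3, 1], [1, 1, 0], 1.0),
    ([1, 3, 2], [1, 1, 0], 0.5),
    ([1, 2, 2], [1, 1, 0], 0.25),
])
def test_auroc_examples(scores, labels, expected):
    assert auroc(scores, labels).auroc == pytest.approx(expected)


def test_auroc_matches_pairwise_concordance_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 200))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        a = auroc(scores, labels).auroc
        assert a == pytest.approx(_auroc_bruteforce(scores, labels),
                                  rel=1e-12)


def test_auroc_monotone_invariance_and_complement(rng):
    scores = rng.normal(size=80)
    labels = (scores + rng.normal(size=80) > 0).astype(int)
    a = auroc(scores, labels).auroc
    assert auroc(np.exp(scores), labels).auroc == pytest.approx(a, rel=1e-12)
    assert auroc(-scores, labels).auroc == pytest.approx(1 - a, rel=1e-12)
    assert auroc(scores, labels,
                 orientation="lower_is_positive").auroc == pytest.approx(
        1 - a, rel=1e-12)


def test_auroc_single_class_raises():
    with pytest.raises(ValueError, match="class"):
        auroc([1, 2, 3], [1, 1, 1])


# --------------------------------------------------------------------------
# Youden threshold

def _youden_bruteforce(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    u = np.unique(scores)
    candidates = [-np.inf, *((u[:-1] + u[1:]) / 2), np.inf]
    best = None
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-12:
            best = (t, j)
    return best


@pytest.mark.parametrize("scores,labels,expected_t,expected_j", [
    ([8, 9, 10, 1, 2, 3], [1, 1, 1, 0, 0, 0], 5.5, 1.0),
    ([2, 4, 1, 3], [1, 1, 0, 0], 1.5, 0.5),  # tie at 3.5; smallest wins
])
def test_youden_examples(scores, labels, expected_t, expected_j):
    t, j = youden_threshold(scores, labels)
    assert t == pytest.approx(expected_t)
    assert j == pytest.approx(expected_j)


def test_youden_identical_distributions():
    t, j = youden_threshold([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    assert j == pytest.approx(0.0)
    assert t == -np.inf


def test_youden_matches_exhaustive_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(6, 60))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.normal(size=n) + labels, 1)
        t, j = youden_threshold(scores, labels)
        t_ref, j_ref = _youden_bruteforce(scores, labels)
        assert j == pytest.approx(j_ref, rel=1e-12)
        assert t == pytest.approx(t_ref)


# --------------------------------------------------------------------------
# diagnostic metrics

def test_diagnostic_metrics_worked_matrix():
    m = diagnostic_metrics(58, 40, 24, 115)
    assert m.sens == pytest.approx(0.707, abs=5e-4)
    assert m.spec == pytest.approx(0.742, abs=5e-4)
    assert m.ppv == pytest.approx(0.592, abs=5e-4)
    assert m.f1 == pytest.approx(0.645, abs=1e-3)
    assert m.mcc == pytest.approx(0.434, abs=5e-4)
    assert m.accuracy == pytest.approx((58 + 115) / 237)


def test_diagnostic_metrics_perfect_and_degenerate():
    perfect = diagnostic_metrics(5, 0, 0, 5)
    assert perfect.sens == perfect.spec == perfect.mcc == 1.0
    degenerate = diagnostic_metrics(5, 5, 0, 0)
    assert degenerate.spec == 0.0
    assert degenerate.npv == 0.0 and "npv" in degenerate.flags


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60),
       st.integers(0, 60))
def test_diagnostic_metric_identities(tp, fp, fn, tn):
    if tp + fp + fn + tn == 0:
        return
    m = diagnostic_metrics(tp, fp, fn, tn)
    if m.nlr > 0 and "plr" not in m.flags and "nlr" not in m.flags:
        assert m.dor == pytest.approx(m.plr / m.nlr, rel=1e-12)
    # proportional rows => no association => MCC 0
    if tp * (fp + tn) == fp * (tp + fn) and math.isfinite(m.mcc) \
            and "mcc" not in m.flags:
        assert m.mcc == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------------------------
# repeated stratified cross-validation

def _toy_cv_inputs(rng, n1=12, n0=18):
    labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
    values = pd.DataFrame({
        "idx": np.r_[rng.normal(1.0, 1.0, n1), rng.normal(0.0, 1.0, n0)]})
    return values, labels


def test_cv_partition_properties(rng):
    values, labels = _toy_cv_inputs(rng)
    rep = repeated_cv_evaluate(values, labels,
                               {"idx": "higher_is_positive"},
                               repeats=2, folds=5, seed=3)
    counts = rep.fold_assignments.groupby("subject").size()
    assert (counts == 2).all()  # each subject tested once per repeat
    per_repeat = rep.fold_assignments.groupby("repeat")["subject"].nunique()
    assert (per_repeat == len(labels)).all()
    # folds within a repeat are disjoint and cover the cohort
    for _, grp in rep.fold_assignments.groupby("repeat"):
        assert not grp.duplicated("subject").any()


def test_cv_stratification_exact_small_case():
    labels = np.r_[np.ones(4, int), np.zeros(6, int)]
    values = pd.DataFrame({"idx": np.arange(10, dtype=float)})
    rep = repeated_cv_evaluate(values, labels,
                               {"idx": "higher_is_positive"},
                               repeats=1, folds=2, seed=0)
    merged = rep.fold_assignments.assign(
        label=lambda d: labels[d["subject"]])
    by_fold = merged.groupby("fold")["label"].agg(["sum", "count"])
    assert (by_fold["sum"] == 2).all() and (by_fold["count"] == 5).all()


def test_cv_deterministic_under_seed(rng):
    values, labels = _toy_cv_inputs(rng)
    a = repeated_cv_evaluate(values, labels, {"idx": "higher_is_positive"},
                             seed=11)
    b = repeated_cv_evaluate(values, labels, {"idx": "higher_is_positive"},
                             seed=11)
    pd.testing.assert_frame_equal(a.table(), b.table())
    pd.testing.assert_frame_equal(a.fold_assignments, b.fold_assignments)


def test_cv_mean_threshold_in_original_units(rng):
    """For a lower-is-positive index the reported mean threshold must be in
    original units (negated back from the oriented scale)."""
    n1, n0 = 15, 15
    labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
    values = pd.DataFrame(
        {"idx": np.r_[rng.normal(10, 1, n1), rng.normal(14, 1, n0)]})
    rep = repeated_cv_evaluate(values, labels, {"idx": "lower_is_positive"},
                               repeats=2, folds=3, seed=5)
    assert 8 < rep.mean_threshold["idx"] < 16


# --------------------------------------------------------------------------
# group comparisons

def test_ranksum_exact_small_sample():
    stat, p = group_compare([1, 2, 3], [4, 5, 6], kind="ranksum")
    assert p == pytest.approx(0.1)


def test_chisq_flat_table():
    stat, p = group_compare([[10, 10], [10, 10]], kind="chisq")
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_fisher_flat_table():
    _, p = group_compare([[5, 5], [5, 5]], kind="fisher")
    assert p == pytest.approx(1.0)


def test_identical_samples_p_one():
    x = [3.0, 1.0, 2.0, 5.0, 4.0, 9.0, 7.0, 6.0, 8.0]
    _, p = group_compare(x, list(x), kind="ranksum")
    assert p == pytest.approx(1.0)


# --------------------------------------------------------------------------
# forward-selection logistic regression

def test_forward_selection_null_case(rng):
    n = 200
    y = rng.integers(0, 2, n)
    design = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    model = fit_logistic_forward(design, y, ["a", "b"])
    assert model.selected == []
    assert model.nagelkerke_r2 == pytest.approx(0.0, abs=1e-9)


def test_logistic_closed_form_two_by_two():
    """Single binary covariate, event rates 1/4 vs 3/4: the MLE slope is
    the log odds ratio ln 9."""
    x = np.repeat([0, 1], 40)
    y = np.r_[np.tile([1, 0, 0, 0], 10), np.tile([1, 1, 1, 0], 10)]
    design = pd.DataFrame({"x": x.astype(float)})
    model = fit_logistic_forward(design, y, ["x"])
    assert model.selected == ["x"]
    assert model.coefficients["x"] == pytest.approx(math.log(9), abs=1e-4)
    or_, lo, hi = model.odds_ratios["x"]
    assert or_ == pytest.approx(9.0, abs=1e-2)
    assert lo < 9.0 < hi


def test_odds_ratio_unit_scaling(rng):
    n = 300
    x = rng.normal(0, 1000, n)
    p = 1 / (1 + np.exp(-(x / 500 - 0.2)))
    y = (rng.random(n) < p).astype(int)
    design = pd.DataFrame({"x": x})
    scaled = fit_logistic_forward(design, y, ["x"],
                                  unit_scale={"x": 1000.0})
    beta = scaled.coefficients["x"]
    assert scaled.odds_ratios["x"][0] == pytest.approx(
        math.exp(beta * 1000.0), rel=1e-12)


def test_nagelkerke_null_is_zero():
    assert nagelkerke_r2(-10.0, -10.0, 50) == pytest.approx(0.0)


def test_hosmer_lemeshow_well_calibrated(rng):
    n = 2000
    p = rng.uniform(0.05, 0.95, n)
    y = (rng.random(n) < p).astype(int)
    stat, df, pval = hosmer_lemeshow(y, p)
    assert df == 8
    assert pval > 0.01  # well-calibrated probabilities rarely rejected


# --------------------------------------------------------------------------
# mixed ANOVA

def _anova_bruteforce(df):
    """Naive split-plot sums-of-squares via explicit loops."""
    subs = sorted(df.patient_id.unique())
    times = sorted(df.quartile.unique())
    groups = sorted(df.group.unique())
    t, grand = len(times), df.value.mean()
    gm = {g: df[df.group == g].value.mean() for g in groups}
    tm = {q: df[df.quartile == q].value.mean() for q in times}
    sm = {s: df[df.patient_id == s].value.mean() for s in subs}
    sg = {s: df[df.patient_id == s].group.iloc[0] for s in subs}
    ng = {g: sum(1 for s in subs if sg[s] == g) for g in groups}
    cm = {(g, q): df[(df.group == g) & (df.quartile == q)].value.mean()
          for g in groups for q in times}
    ss_total = sum((v - grand) ** 2 for v in df.value)
    ss_bs = t * sum((sm[s] - grand) ** 2 for s in subs)
    ss_g = t * sum(ng[g] * (gm[g] - grand) ** 2 for g in groups)
    ss_sw = ss_bs - ss_g
    ss_t = len(subs) * sum((tm[q] - grand) ** 2 for q in times)
    ss_cells = sum(ng[g] * (cm[(g, q)] - grand) ** 2
                   for g in groups for q in times)
    ss_i = ss_cells - ss_g - ss_t
    ss_e = ss_total - ss_bs - ss_t - ss_i
    df_g, df_s = len(groups) - 1, len(subs) - len(groups)
    df_t = t - 1
    df_i, df_e = df_g * df_t, df_s * df_t
    return ((ss_g / df_g) / (ss_sw / df_s),
            (ss_t / df_t) / (ss_e / df_e),
            (ss_i / df_i) / (ss_e / df_e))


def _toy_trajectories(rng, n_per_group=3, effect=1.0):
    rows = []
    for g in (0, 1):
        for s in range(n_per_group):
            base = rng.normal(g * effect, 0.3)
            for q in range(1, 5):
                rows.append({"patient_id": f"g{g}s{s}", "group": g,
                             "quartile": q,
                             "value": base - 0.1 * q + rng.normal(0, 0.1)})
    return pd.DataFrame(rows)


def test_mixed_anova_matches_bruteforce_oracle(rng):
    df = _toy_trajectories(rng)
    res = mixed_anova(df)
    f_g, f_t, f_i = _anova_bruteforce(df)
    assert res.f_between == pytest.approx(f_g, rel=1e-9)
    assert res.f_time == pytest.approx(f_t, rel=1e-9)
    assert res.f_interaction == pytest.approx(f_i, rel=1e-9)
    assert res.df_between == (1, 4)


def test_mixed_anova_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    df = _toy_trajectories(rng, n_per_group=5)
    res = mixed_anova(df)
    ref = pg.mixed_anova(data=df, dv="value", within="quartile",
                         subject="patient_id", between="group")
    ref = ref.set_index("Source")
    assert res.f_between == pytest.approx(ref.loc["group", "F"], rel=1e-6)
    assert res.f_time == pytest.approx(ref.loc["quartile", "F"], rel=1e-6)
    assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"],
                                              rel=1e-6)


def test_mixed_anova_null_effects(rng):
    # identical per-subject means across groups -> group F ~ 0
    rows = []
    for g in (0, 1):
        for s in range(3):
            for q in range(1, 5):
                rows.append({"patient_id": f"g{g}s{s}", "group": g,
                             "quartile": q, "value": float(s + q)})
    res = mixed_anova(pd.DataFrame(rows))
    assert res.f_between == pytest.approx(0.0, abs=1e-9)
    # balanced Latin-square quartile pattern: every quartile sees the same
    # four offsets, so the time marginal means are equal (SS_time = 0) while
    # the within-subject error stays nonzero -> time F = 0 exactly
    pattern = [1.0, -2.0, 0.5, 0.5]
    rows = [{"patient_id": f"g{g}s{s}", "group": g, "quartile": q,
             "value": float(g * 2 + s) + pattern[(s + q) % 4]}
            for g in (0, 1) for s in range(4) for q in range(1, 5)]
    res2 = mixed_anova(pd.DataFrame(rows))
    assert res2.f_time == pytest.approx(0.0, abs=1e-9)


def test_mixed_anova_rejects_missing_cells(rng):
    df = _toy_trajectories(rng).iloc[1:]
    with pytest.raises(ValueError, match="missing cells"):
        mixed_anova(df)
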