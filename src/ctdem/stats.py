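"""Group comparison, ROC analysis, DeLong, calibration and decision curves.

These are the evaluation primitives behind the diagnostic report: test
routing (t-test vs Mann-Whitney via Shapiro-Wilk and Levene; chi-square vs
Fisher for contingency tables), the rank-statistic AUC, Youden-threshold
operating points, the DeLong test for paired AUCs, the Hosmer-Lemeshow
calibration test, decision-curve net benefit, and a univariate logistic link
turning one feature into class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ConfusionMatrix",
    "RocResult",
    "CalibrationResult",
    "NetBenefitCurve",
    "compare_groups",
    "compare_contingency",
    "auc_mann_whitney",
    "select_features",
    "youden_threshold",
    "metrics_from_confusion",
    "reconstruct_confusion",
    "delong_test",
    "hosmer_lemeshow",
    "decision_curve",
    "probability_from_feature",
]


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparison:
    p_value: float
    test_name: str
    summaries: dict = field(default_factory=dict)
    degenerate: bool = False


def _normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def compare_groups(values0, values1, alpha: float = 0.05) -> GroupComparison:
    """Compare a continuous feature between the two label groups.

    Routes to the independent-samples t-test when both groups pass
    Shapiro-Wilk normality and Levene homogeneity of variance at
    ``alpha``, and to the Mann-Whitney U test otherwise.  Degenerate input
    (all values identical) returns p = 1 with a flag.
    """
    x0 = np.asarray(values0, dtype=float)
    x1 = np.asarray(values1, dtype=float)
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both groups must be non-empty")
    summaries = {
        "mean": (float(x0.mean()), float(x1.mean())),
        "sd": (float(x0.std(ddof=1)) if x0.size > 1 else 0.0,
               float(x1.std(ddof=1)) if x1.size > 1 else 0.0),
        "median": (float(np.median(x0)), float(np.median(x1))),
        "q1": (float(np.percentile(x0, 25)), float(np.percentile(x1, 25))),
        "q3": (float(np.percentile(x0, 75)), float(np.percentile(x1, 75))),
        "n": (int(x0.size), int(x1.size)),
    }
    pooled = np.concatenate([x0, x1])
    if np.ptp(pooled) == 0:
        return GroupComparison(1.0, "degenerate", summaries, degenerate=True)
    if _normal(x0, alpha) and _normal(x1, alpha):
        homo = sps.levene(x0, x1).pvalue > alpha
        if homo:
            p = float(sps.ttest_ind(x0, x1, equal_var=True).pvalue)
            return GroupComparison(p, "t-test", summaries)
    res = sps.mannwhitneyu(x0, x1, alternative="two-sided")
    return GroupComparison(float(res.pvalue), "mann-whitney", summaries)


def compare_contingency(table) -> GroupComparison:
    """Chi-square (Yates-corrected for 2×2) or Fisher's exact test.

    Fisher is used for 2×2 tables with any expected cell below 5; larger
    tables with small expected counts keep the chi-square with a flag.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0:
        raise ValueError("contingency table must be a 2D array of non-negative counts")
    expected = sps.contingency.expected_freq(t)
    small = (expected < 5).any()
    if t.shape == (2, 2) and small:
        p = float(sps.fisher_exact(t).pvalue)
        return GroupComparison(p, "fisher-exact", {"expected_min": float(expected.min())})
    correction = t.shape == (2, 2)
    res = sps.chi2_contingency(t, correction=correction)
    return GroupComparison(
        float(res.pvalue),
        "chi-square" + ("-yates" if correction else ""),
        {"df": int(res.dof), "statistic": float(res.statistic),
         "expected_min": float(expected.min()), "small_expected": bool(small)},
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def auc_mann_whitney(scores, labels) -> float:
    """Tie-corrected rank AUC: P(score⁺ > score⁻) + ½ P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def metrics_from_confusion(c: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV, F1 from counts.

    Rates with a zero denominator come back as NaN (undefined, not 0).
    """
    def rate(num, den):
        return float(num) / den if den > 0 else float("nan")

    return {
        "accuracy": rate(c.tp + c.tn, c.n),
        "sensitivity": rate(c.tp, c.tp + c.fn),
        "specificity": rate(c.tn, c.tn + c.fp),
        "ppv": rate(c.tp, c.tp + c.fp),
        "npv": rate(c.tn, c.tn + c.fn),
        "f1": rate(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def reconstruct_confusion(sensitivity, specificity, n_pos, n_neg) -> ConfusionMatrix:
    """Rebuild integer counts from printed sensitivity/specificity.

    Round-half-up on tp and tn, the convention that reproduces the printed
    derived metrics of the study tables.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("cohort sizes must be positive")
    tp = int(np.floor(sensitivity * n_pos + 0.5))
    tn = int(np.floor(specificity * n_neg + 0.5))
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


@dataclass
class RocResult:
    auc: float
    threshold: float
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def youden_threshold(scores, labels) -> RocResult:
    """Operating point maximising Youden's J = Se + Sp − 1.

    Candidate thresholds are the midpoints between consecutive distinct
    observed scores (classification rule: score ≥ threshold → positive);
    ties in J resolve to the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([uniq[0]])
    best_j, best_t = -np.inf, None
    for t in cands:
        pred = s >= t
        se = (pred & (y == 1)).sum() / n_pos
        sp = (~pred & (y == 0)).sum() / n_neg
        j = se + sp - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    pred = s >= best_t
    cm = ConfusionMatrix(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
        tn=int((~pred & (y == 0)).sum()),
    )
    # empirical ROC points over all cutpoints (score >= t rule)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thr = np.r_[np.inf, s[order][distinct]]
    return RocResult(
        auc=auc_mann_whitney(s, y),
        threshold=float(best_t),
        confusion=cm,
        metrics=metrics_from_confusion(cm),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


def select_features(
    table,
    label_col: str = "label",
    features: list[str] | None = None,
    p_max: float = 0.05,
    auc_min: float = 0.7,
):
    """Apply the study's two-stage filter to a feature table.

    A feature is retained when its group-comparison p-value is ≤ ``p_max``
    AND its orientation-free AUC max(auc, 1−auc) exceeds ``auc_min``.
    Returns ``(retained_names, details)`` where ``details`` is a DataFrame
    with per-feature p, test, auc and the retention decision, in column
    order (deterministic).
    """
    import pandas as pd

    y = np.asarray(table[label_col]).astype(int)
    if features is None:
        features = [c for c in table.columns if c != label_col]
    rows = []
    for name in features:
        x = np.asarray(table[name], dtype=float)
        comp = compare_groups(x[y == 0], x[y == 1])
        auc = auc_mann_whitney(x, y)
        oriented = max(auc, 1.0 - auc)
        keep = (comp.p_value <= p_max) and (oriented > auc_min)
        rows.append(
            {
                "feature": name,
                "p_value": comp.p_value,
                "test": comp.test_name,
                "auc": auc,
                "auc_oriented": oriented,
                "orientation": 1 if auc >= 0.5 else -1,
                "retained": keep,
            }
        )
    details = pd.DataFrame(rows).set_index("feature")
    retained = [r["feature"] for r in rows if r["retained"]]
    return retained, details


# ---------------------------------------------------------------------------
# DeLong


def _placements(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    return psi.mean(), v10, v01


def delong_test(scores_a, scores_b, labels):
    """DeLong test for two correlated (paired) AUCs.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.  A
    zero-variance difference (e.g. identical score vectors) returns
    z = 0, p = 1.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _placements(scores_a, y)
    auc_b, v10_b, v01_b = _placements(scores_b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0 or (delta == 0 and var < 1e-16):
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    statistic: float
    p_value: float
    df: int
    bins: list  # (mean predicted, observed fraction, n) per bin
    n_bins: int
    merged: bool = False


def hosmer_lemeshow(probs, labels, g: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-calibration test over risk deciles.

    Samples are grouped into ``g`` bins by predicted probability (ties kept
    together, so fewer bins may result); the statistic is
    Σ (O − E)² / (E (1 − E/n_b)) with E the expected positives per bin, and
    p comes from χ² with (bins − 2) degrees of freedom.  Bins whose
    denominator vanishes (E = 0 or E = n_b) are merged into their neighbour
    and flagged.
    """
    import pandas as pd

    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if g < 2:
        raise ValueError("need at least 2 bins")
    cats = pd.qcut(p, q=g, duplicates="drop")
    df = pd.DataFrame({"p": p, "y": y, "bin": cats})
    grouped = df.groupby("bin", observed=True)
    obs = grouped["y"].sum().to_numpy(dtype=float)
    exp = grouped["p"].sum().to_numpy(dtype=float)
    nb = grouped.size().to_numpy(dtype=float)
    mean_p = grouped["p"].mean().to_numpy(dtype=float)
    obs_frac = obs / nb

    merged = False
    # merge degenerate bins (zero-variance denominators) into neighbours
    while len(nb) > 2:
        denom = exp * (1.0 - exp / nb)
        bad = np.where(denom <= 1e-12)[0]
        if bad.size == 0:
            break
        i = bad[0]
        j = i - 1 if i > 0 else i + 1
        obs[j] += obs[i]
        exp[j] += exp[i]
        nb[j] += nb[i]
        obs = np.delete(obs, i)
        exp = np.delete(exp, i)
        nb = np.delete(nb, i)
        mean_p = np.delete(mean_p, i)
        obs_frac = obs / nb
        merged = True
    denom = exp * (1.0 - exp / nb)
    denom = np.where(denom <= 1e-12, np.inf, denom)
    stat = float((((obs - exp) ** 2) / denom).sum())
    dof = max(len(nb) - 2, 1)
    p_value = float(sps.chi2.sf(stat, dof))
    bins = list(zip(mean_p.tolist(), obs_frac.tolist(), nb.astype(int).tolist()))
    return CalibrationResult(stat, p_value, dof, bins, n_bins=len(nb), merged=merged)


# ---------------------------------------------------------------------------
# decision curves


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float


def decision_curve(probs, labels, thresholds=None) -> NetBenefitCurve:
    """Net benefit NB(p_t) = tp/n − (fp/n)·p_t/(1−p_t) across thresholds.

    The classification rule is prob ≥ p_t.  Includes the treat-all
    (prevalence − (1−prevalence)·p_t/(1−p_t)) and treat-none (zero)
    reference strategies.  Thresholds must lie strictly inside (0, 1).
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    t = np.asarray(thresholds, dtype=float)
    if (t <= 0).any() or (t >= 1).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    odds = t / (1.0 - t)
    pred = p[None, :] >= t[:, None]
    tp = (pred & (y == 1)[None, :]).sum(axis=1) / n
    fp = (pred & (y == 0)[None, :]).sum(axis=1) / n
    nb = tp - fp * odds
    treat_all = prev - (1.0 - prev) * odds
    return NetBenefitCurve(t, nb, treat_all, np.zeros_like(t), float(prev))


# ---------------------------------------------------------------------------
# probability link


def probability_from_feature(values, labels, clip: float = 1e-6):
    """Univariate logistic link mapping one feature to class probability.

    Maximum-likelihood fit of P(y=1|x) = expit(b0 + b1 x) (statsmodels
    Logit).  Perfect or quasi-perfect separation is caught, flagged and the
    probabilities clipped away from {0, 1}.  Returns ``(probs, info)``.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(x)
    info: dict = {"separation": False}
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation and non-convergence are detected and flagged below
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=200)
        probs = np.asarray(res.predict(X), dtype=float)
        info["params"] = res.params.tolist()
        info["converged"] = bool(res.mle_retvals.get("converged", True))
        if not info["converged"] or np.abs(res.params).max() > 1e3:
            info["separation"] = True
    except Exception:  # perfect separation raises in statsmodels
        info["separation"] = True
        # fall back to a heavily clipped empirical rule
        thr = youden_threshold(x, y).threshold
        probs = np.where(x >= thr, 1.0, 0.0).astype(float)
    probs = np.clip(probs, clip, 1.0 - clip)
    return probs, info
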