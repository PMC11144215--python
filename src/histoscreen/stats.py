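"""Validation statistics and deployment-impact analytics.

Everything downstream of the classifier is closed-form arithmetic over
an operating point (threshold, sensitivity, specificity) and a
screening scenario (prevalence, cohort size):

* expected confusion matrices at a given prevalence,
* the molecular-test-reduction rate — the fraction of screened patients
  predicted negative, spec*(1-prev) + (1-sens)*prev,
* the 3-tier (Low/Mid/High likelihood) stratification induced by a
  high-sensitivity and a high-specificity operating point, with per-tier
  biomarker prevalence by Bayes' rule and enrichment ratios,
* a cost model for molecular testing with and without prescreening,
* exact binomial power for validating sensitivity against a target, and
* ROC/AUC, binomial confidence intervals, and operating-point selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float

    def __post_init__(self):
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity/specificity must lie in [0, 1]")


@dataclass(frozen=True)
class ScreeningScenario:
    prevalence: float
    n_patients: int
    op: OperatingPoint

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


@dataclass(frozen=True)
class ExpectedConfusion:
    TP: float
    FP: float
    TN: float
    FN: float


@dataclass(frozen=True)
class CostInputs:
    n_patients: int
    cost_per_test: float
    prevalence: float

    def __post_init__(self):
        if self.cost_per_test < 0:
            raise ValueError("cost must be >= 0")


@dataclass(frozen=True)
class PowerSpec:
    n: int
    p0: float
    p1: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# empirical metrics


def confusion_metrics(predictions, truth) -> dict:
    """Sensitivity/specificity/PPV/NPV plus raw counts.

    ``predictions`` and ``truth`` are binary (1 = positive). Metrics with
    a zero denominator are reported as None, never as 0.
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth must have equal length")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def ratio(num, den):
        return num / den if den else None

    return {
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def binomial_ci(k: int, n: int, method: str = "wald", level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a binomial proportion.

    ``wald`` is the normal approximation (clipped to [0, 1]); the exact
    ``clopper_pearson`` interval is recommended for small n or extreme
    proportions.
    """
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1.0 - level
    if method == "wald":
        p = k / n
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        half = z * np.sqrt(p * (1.0 - p) / n)
        return max(0.0, p - half), min(1.0, p + half)
    if method == "clopper_pearson":
        lower = sps.beta.ppf(alpha / 2.0, k, n - k + 1) if k > 0 else 0.0
        upper = sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k) if k < n else 1.0
        return float(lower), float(upper)
    raise ValueError(f"unknown method {method!r}")


def roc_curve_auc(scores, labels) -> dict:
    """ROC curve and AUC (Mann-Whitney concordance; ties get half credit)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(y, s)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": float(roc_auc_score(y, s))}


def operating_point_for(scores, labels, target_sensitivity=None, target_specificity=None) -> OperatingPoint:
    """Best operating point under a sensitivity or specificity constraint.

    Maximizes the complementary metric subject to the constraint,
    breaking ties toward the higher threshold. If the constraint is
    unreachable the closest achievable point is returned (flag via the
    returned values). Predictions are positive at score >= threshold.
    """
    if (target_sensitivity is None) == (target_specificity is None):
        raise ValueError("give exactly one of target_sensitivity / target_specificity")
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    cand = np.unique(s)
    rows = []
    for t in cand:
        pred = s >= t
        tp = ((pred) & (y == 1)).sum()
        fn = ((~pred) & (y == 1)).sum()
        tn = ((~pred) & (y == 0)).sum()
        fp = ((pred) & (y == 0)).sum()
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        rows.append((float(t), float(sens), float(spec)))
    if target_sensitivity is not None:
        ok = [r for r in rows if r[1] >= target_sensitivity]
        if ok:
            best = max(ok, key=lambda r: (r[2], r[0]))
        else:
            best = max(rows, key=lambda r: (r[1], r[0]))
    else:
        ok = [r for r in rows if r[2] >= target_specificity]
        if ok:
            best = max(ok, key=lambda r: (r[1], r[0]))
        else:
            best = max(rows, key=lambda r: (r[2], r[0]))
    return OperatingPoint(threshold=best[0], sensitivity=best[1], specificity=best[2])


# ---------------------------------------------------------------------------
# scenario analytics


def expected_confusion(scenario: ScreeningScenario, rounded: bool = False) -> ExpectedConfusion:
    """Expected confusion matrix cells at the scenario prevalence."""
    n, prev = scenario.n_patients, scenario.prevalence
    sens, spec = scenario.op.sensitivity, scenario.op.specificity
    cells = dict(
        TP=n * prev * sens,
        FN=n * prev * (1.0 - sens),
        TN=n * (1.0 - prev) * spec,
        FP=n * (1.0 - prev) * (1.0 - spec),
    )
    if rounded:
        cells = {k: float(round(v)) for k, v in cells.items()}
    return ExpectedConfusion(**cells)


def test_reduction(op: OperatingPoint, prevalence: float) -> float:
    """Fraction of screened patients not sent to molecular testing.

    Equal to the predicted-negative fraction:
    spec*(1-prev) + (1-sens)*prev.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    return op.specificity * (1.0 - prevalence) + (1.0 - op.sensitivity) * prevalence


def tier_prevalences(op_low: OperatingPoint, op_high: OperatingPoint, prevalence: float) -> dict:
    """Three-tier stratification from two operating points.

    ``op_low`` is the high-sensitivity cut (Low vs Mid boundary),
    ``op_high`` the high-specificity cut (Mid vs High boundary). Returns
    per-tier population fractions, per-tier biomarker prevalence (Bayes),
    and enrichment ratios High/Low and High/baseline.
    """
    if op_low.sensitivity < op_high.sensitivity or op_low.threshold > op_high.threshold:
        raise ValueError("op_low must be the more sensitive, lower-threshold operating point")
    prev = prevalence
    p_high = prev * op_high.sensitivity + (1 - prev) * (1 - op_high.specificity)
    p_low = prev * (1 - op_low.sensitivity) + (1 - prev) * op_low.specificity
    p_mid = 1.0 - p_high - p_low
    if p_mid < -1e-12:
        raise ValueError("inconsistent operating points: negative Mid-tier mass")
    p_mid = max(p_mid, 0.0)

    prev_high = prev * op_high.sensitivity / p_high if p_high > 0 else float("nan")
    prev_low = prev * (1 - op_low.sensitivity) / p_low if p_low > 0 else float("nan")
    pos_mid = prev * (op_low.sensitivity - op_high.sensitivity)
    prev_mid = pos_mid / p_mid if p_mid > 0 else float("nan")
    return {
        "fraction": {"Low": p_low, "Mid": p_mid, "High": p_high},
        "prevalence": {"Low": prev_low, "Mid": prev_mid, "High": prev_high},
        "enrichment_high_vs_low": prev_high / prev_low if prev_low else float("inf"),
        "enrichment_high_vs_baseline": prev_high / prev if prev else float("nan"),
    }


def enrichment_ratio(prevalence_high: float, prevalence_low: float) -> float:
    """Fold enrichment between two tier prevalences."""
    if prevalence_low <= 0:
        raise ValueError("reference prevalence must be positive")
    return prevalence_high / prevalence_low


def cost_model(inputs: CostInputs, op: OperatingPoint | None = None) -> dict:
    """Molecular-testing cost with and without AI prescreening.

    Without AI every patient is tested. With AI only patients predicted
    positive are tested; detected positives scale with sensitivity and
    savings are exactly the avoided tests, so
    with-AI cost + savings = without-AI cost.
    """
    n, c, prev = inputs.n_patients, inputs.cost_per_test, inputs.prevalence
    total_no_ai = n * c
    detected_no_ai = n * prev
    out = {
        "total_cost": total_no_ai,
        "detected_positives": detected_no_ai,
        "cost_per_detected_positive": total_no_ai / detected_no_ai if detected_no_ai else float("nan"),
        "savings_vs_no_AI": 0.0,
    }
    if op is None:
        return out
    reduction = test_reduction(op, prev)
    tested = n * (1.0 - reduction)
    detected = n * prev * op.sensitivity
    total = tested * c
    return {
        "total_cost": total,
        "detected_positives": detected,
        "cost_per_detected_positive": total / detected if detected else float("nan"),
        "savings_vs_no_AI": total_no_ai - total,
    }


# ---------------------------------------------------------------------------
# exact binomial power


def _rejection_region(n: int, p0: float, alpha: float, convention: str) -> np.ndarray:
    k = np.arange(n + 1)
    d0 = sps.binom(n, p0)
    cdf = d0.cdf(k)
    sf = d0.sf(k - 1)  # P(X >= k)
    if convention == "central":
        lo = k[cdf <= alpha / 2.0]
        hi = k[sf <= alpha / 2.0]
        region = np.concatenate([lo, hi])
    elif convention == "doubling":
        region = k[2.0 * np.minimum(cdf, sf) <= alpha]
    elif convention == "min_likelihood":
        pmf = d0.pmf(k)
        order = np.argsort(pmf, kind="stable")
        cum = np.cumsum(pmf[order])
        region = order[cum <= alpha]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return np.unique(region)


def exact_binomial_power(spec: PowerSpec, convention: str = "central") -> float:
    """Power of the two-sided exact binomial test.

    The rejection region is built under the null ``p0`` at level
    ``alpha`` — by default the central convention (each tail's null mass
    at most alpha/2; ``doubling`` and ``min_likelihood`` conventions are
    selectable) — and the power is the exact probability of that region
    under the alternative ``p1``. An empty region yields power 0.
    """
    if not (0.0 < spec.p0 < 1.0 and 0.0 < spec.p1 < 1.0):
        raise ValueError("p0 and p1 must lie in (0, 1)")
    region = _rejection_region(spec.n, spec.p0, spec.alpha, convention)
    if region.size == 0:
        return 0.0
    d1 = sps.binom(spec.n, spec.p1)
    return float(d1.pmf(region).sum())


# ---------------------------------------------------------------------------
# deployment accounting


def deployment_accounting(results, molecular_truth: dict | None = None) -> dict:
    """Summarize a batch of device results against molecular outcomes.

    ``results`` are :class:`~histoscreen.device.DeviceResult`-like
    objects; ``molecular_truth`` maps slide_id to "positive"/"negative"
    (slides absent from the map are excluded from sensitivity/
    specificity denominators). Rates undefined by zero denominators are
    None.
    """
    results = list(results)
    if not results:
        raise ValueError("batch must be non-empty")
    n = len(results)
    ok = [r for r in results if r.status == "ok"]
    n_qc_failed = n - len(ok)
    n_neg = sum(1 for r in ok if r.call == "FGFR-")

    sens = spec = prevalence = None
    if molecular_truth:
        paired = [(r, molecular_truth[r.slide_id]) for r in ok if r.slide_id in molecular_truth]
        tp = sum(1 for r, t in paired if r.call == "FGFR+" and t == "positive")
        fn = sum(1 for r, t in paired if r.call == "FGFR-" and t == "positive")
        tn = sum(1 for r, t in paired if r.call == "FGFR-" and t == "negative")
        fp = sum(1 for r, t in paired if r.call == "FGFR+" and t == "negative")
        sens = tp / (tp + fn) if tp + fn else None
        spec = tn / (tn + fp) if tn + fp else None
        prevalence = (tp + fn) / len(paired) if paired else None

    return {
        "received": n,
        "predicted": len(ok),
        "qc_failed": n_qc_failed,
        "prediction_rate_percent": 100.0 * len(ok) / n,
        "predicted_negative_fraction": n_neg / len(ok) if ok else None,
        "sensitivity": sens,
        "specificity": spec,
        "prevalence": prevalence,
    }
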