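"""Screening statistics: metrics, CIs, ROC, scenarios, cost, power."""

import numpy as np
import pytest
from scipy import stats as sps

import histoscreen as hs
from histoscreen.stats import PowerSpec, _rejection_region


OP_VALIDATION = hs.OperatingPoint(threshold=0.5, sensitivity=0.887, specificity=0.318)


# ---------------------------------------------------------------------------
# confusion metrics


def test_confusion_metrics_hand_counted_toy():
    pred = [1, 1, 0, 0, 1, 0]
    truth = [1, 0, 1, 0, 1, 0]
    m = hs.confusion_metrics(pred, truth)
    assert (m["TP"], m["FP"], m["TN"], m["FN"]) == (2, 1, 2, 1)
    assert m["sensitivity"] == pytest.approx(2 / 3)
    assert m["specificity"] == pytest.approx(2 / 3)
    assert m["ppv"] == pytest.approx(2 / 3)
    assert m["npv"] == pytest.approx(2 / 3)


def test_confusion_metrics_degenerate():
    m = hs.confusion_metrics([1, 1, 0], [1, 1, 0])
    assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
    m = hs.confusion_metrics([1, 1, 1, 1], [1, 0, 1, 0])
    assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
    assert m["npv"] is None  # zero denominator flagged, not 0


# ---------------------------------------------------------------------------
# binomial confidence intervals


def test_clopper_pearson_closed_form_k_equals_n():
    lo, hi = hs.binomial_ci(10, 10, method="clopper_pearson")
    assert hi == 1.0
    assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-9)


def test_wald_interval_formula():
    lo, hi = hs.binomial_ci(5, 10, method="wald")
    z = sps.norm.ppf(0.975)
    half = z * np.sqrt(0.025)
    assert lo == pytest.approx(0.5 - half)
    assert hi == pytest.approx(0.5 + half)
    assert hs.binomial_ci(0, 10, method="wald") == (0.0, 0.0)
    with pytest.raises(ValueError):
        hs.binomial_ci(1, 0)


# ---------------------------------------------------------------------------
# ROC / AUC


def _auc_oracle(scores, labels):
    """O(n^2) Mann-Whitney concordance with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_separated_and_tied():
    assert hs.roc_curve_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])["auc"] == 1.0
    assert hs.roc_curve_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])["auc"] == 0.5
    with pytest.raises(ValueError):
        hs.roc_curve_auc([0.1, 0.2], [1, 1])


def test_auc_matches_concordance_oracle():
    toy_scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.7, 0.2, 0.6]
    toy_labels = [0, 0, 1, 1, 0, 1, 0, 1]
    assert hs.roc_curve_auc(toy_scores, toy_labels)["auc"] == pytest.approx(
        _auc_oracle(toy_scores, toy_labels)
    )
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        assert hs.roc_curve_auc(scores, labels)["auc"] == pytest.approx(
            _auc_oracle(list(scores), list(labels))
        )


def test_operating_point_for_matches_bruteforce():
    scores = [0.05, 0.2, 0.3, 0.45, 0.55, 0.6, 0.7, 0.9]
    labels = [0, 0, 1, 0, 1, 1, 0, 1]
    op = hs.operating_point_for(scores, labels, target_sensitivity=0.9)
    # brute force: all thresholds with sens >= 0.9, max spec, then max threshold
    best = None
    for t in sorted(set(scores)):
        pred = [s >= t for s in scores]
        tp = sum(p and l for p, l in zip(pred, labels))
        fn = sum((not p) and l for p, l in zip(pred, labels))
        tn = sum((not p) and (not l) for p, l in zip(pred, labels))
        fp = sum(p and (not l) for p, l in zip(pred, labels))
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        if sens >= 0.9 and (best is None or (spec, t) > (best[1], best[0])):
            best = (t, spec, sens)
    assert op.threshold == best[0] and op.specificity == best[1]

    sep = hs.operating_point_for([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], target_sensitivity=0.9)
    assert sep.specificity == 1.0

    op2 = hs.operating_point_for(scores, labels, target_specificity=0.9)
    assert op2.specificity >= 0.9


# ---------------------------------------------------------------------------
# scenario arithmetic


def test_expected_confusion_at_validation_operating_point():
    scenario = hs.ScreeningScenario(prevalence=0.15, n_patients=1000, op=OP_VALIDATION)
    c = hs.expected_confusion(scenario)
    assert c.TP == pytest.approx(133.05)
    assert c.FN == pytest.approx(16.95)
    assert c.TN == pytest.approx(270.3)
    assert c.FP == pytest.approx(579.7)
    assert c.TP + c.FP + c.TN + c.FN == pytest.approx(1000, abs=1e-9)


def test_expected_confusion_degenerate():
    op = hs.OperatingPoint(threshold=0.5, sensitivity=1.0, specificity=1.0)
    c = hs.expected_confusion(hs.ScreeningScenario(prevalence=0.0, n_patients=100, op=OP_VALIDATION))
    assert c.TP == 0 and c.FN == 0
    c = hs.expected_confusion(hs.ScreeningScenario(prevalence=0.3, n_patients=100, op=op))
    assert c.FP == 0 and c.FN == 0 and c.TP + c.TN == pytest.approx(100)


def test_confusion_identities_on_random_draws():
    rng = np.random.default_rng(1)
    for _ in range(1000):
        sens, spec, prev = rng.random(3)
        op = hs.OperatingPoint(threshold=0.5, sensitivity=sens, specificity=spec)
        c = hs.expected_confusion(hs.ScreeningScenario(prevalence=prev, n_patients=500, op=op))
        assert c.TP + c.FP + c.TN + c.FN == pytest.approx(500, abs=1e-9)
        # reduction equals predicted-negative mass
        assert hs.test_reduction(op, prev) == pytest.approx((c.TN + c.FN) / 500, abs=1e-9)


def test_reduction_values():
    assert hs.test_reduction(OP_VALIDATION, 0.15) == pytest.approx(0.287, abs=5e-4)
    op = hs.OperatingPoint(threshold=0.5, sensitivity=1.0, specificity=1.0)
    assert hs.test_reduction(op, 0.3) == pytest.approx(0.7)
    op = hs.OperatingPoint(threshold=0.5, sensitivity=1.0, specificity=0.0)
    assert hs.test_reduction(op, 0.4) == 0.0


# ---------------------------------------------------------------------------
# tiers


def test_tier_enrichment_from_reported_prevalences():
    # Low 5.9%, High 49.3% -> more than 8-fold enrichment
    assert hs.enrichment_ratio(0.493, 0.059) > 8.0


def test_tier_collapse_when_cuts_coincide():
    op = hs.OperatingPoint(threshold=0.5, sensitivity=0.9, specificity=0.4)
    t = hs.tier_prevalences(op, op, 0.15)
    assert t["fraction"]["Mid"] == pytest.approx(0.0, abs=1e-12)


def test_tier_mixture_reproduces_baseline():
    rng = np.random.default_rng(2)
    count = 0
    while count < 1000:
        prev = rng.uniform(0.01, 0.5)
        sens_low = rng.uniform(0.5, 1.0)
        sens_high = rng.uniform(0.0, sens_low)
        spec_low = rng.uniform(0.0, 0.6)
        spec_high = rng.uniform(spec_low, 1.0)
        op_low = hs.OperatingPoint(threshold=0.2, sensitivity=sens_low, specificity=spec_low)
        op_high = hs.OperatingPoint(threshold=0.8, sensitivity=sens_high, specificity=spec_high)
        t = hs.tier_prevalences(op_low, op_high, prev)
        fr, pv = t["fraction"], t["prevalence"]
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
        mix = sum(fr[k] * pv[k] for k in fr if fr[k] > 0)
        assert mix == pytest.approx(prev, abs=1e-9)
        count += 1


def test_tier_inconsistent_points_rejected():
    op_low = hs.OperatingPoint(threshold=0.2, sensitivity=0.5, specificity=0.5)
    op_high = hs.OperatingPoint(threshold=0.8, sensitivity=0.9, specificity=0.5)
    with pytest.raises(ValueError):
        hs.tier_prevalences(op_low, op_high, 0.15)


# ---------------------------------------------------------------------------
# cost model


def test_cost_without_ai_matches_reported_example():
    out = hs.cost_model(hs.CostInputs(n_patients=24000, cost_per_test=5000, prevalence=0.15))
    assert out["total_cost"] == 120_000_000
    assert out["detected_positives"] == 3600
    assert out["cost_per_detected_positive"] == pytest.approx(33_333.33, abs=1)


def test_cost_with_ai_savings_and_conservation():
    inputs = hs.CostInputs(n_patients=24000, cost_per_test=5000, prevalence=0.15)
    with_ai = hs.cost_model(inputs, OP_VALIDATION)
    no_ai = hs.cost_model(inputs)
    # ~$35M printed; exact arithmetic gives 120M * 0.28725
    assert with_ai["savings_vs_no_AI"] == pytest.approx(120e6 * 0.28725, rel=1e-9)
    assert with_ai["total_cost"] + with_ai["savings_vs_no_AI"] == pytest.approx(
        no_ai["total_cost"], abs=1e-6
    )
    assert with_ai["cost_per_detected_positive"] == pytest.approx(26_786, abs=2)

    zero = hs.cost_model(hs.CostInputs(n_patients=100, cost_per_test=0.0, prevalence=0.2), OP_VALIDATION)
    assert zero["total_cost"] == 0.0 and zero["savings_vs_no_AI"] == 0.0


def test_cost_conservation_random_draws():
    rng = np.random.default_rng(3)
    for _ in range(200):
        sens, spec, prev = rng.random(3)
        op = hs.OperatingPoint(threshold=0.5, sensitivity=sens, specificity=spec)
        inputs = hs.CostInputs(n_patients=int(rng.integers(1, 10000)), cost_per_test=float(rng.uniform(0, 1e4)), prevalence=prev)
        with_ai = hs.cost_model(inputs, op)
        no_ai = hs.cost_model(inputs)
        assert with_ai["total_cost"] + with_ai["savings_vs_no_AI"] == pytest.approx(
            no_ai["total_cost"], rel=1e-12, abs=1e-6
        )


# ---------------------------------------------------------------------------
# exact binomial power


def test_power_matches_validation_design():
    p = hs.exact_binomial_power(PowerSpec(n=150, p0=0.8, p1=0.9, alpha=0.05))
    assert round(100 * p) == 93


def test_power_size_and_monotonicity():
    size = hs.exact_binomial_power(PowerSpec(n=100, p0=0.7, p1=0.7, alpha=0.05))
    assert size <= 0.05
    powers = [
        hs.exact_binomial_power(PowerSpec(n=n, p0=0.8, p1=0.9, alpha=0.05))
        for n in (50, 100, 150, 300)
    ]
    assert powers == sorted(powers)


def test_power_conventions_agree_on_region_validity():
    for conv in ("central", "doubling", "min_likelihood"):
        region = _rejection_region(100, 0.5, 0.05, conv)
        null_mass = sps.binom(100, 0.5).pmf(region).sum()
        assert null_mass <= 0.05 + 1e-12
        p = hs.exact_binomial_power(PowerSpec(n=100, p0=0.5, p1=0.8), convention=conv)
        assert p > 0.99  # large effect, large n


# ---------------------------------------------------------------------------
# deployment accounting


class _FakeResult:
    def __init__(self, slide_id, status, call=None):
        self.slide_id = slide_id
        self.status = status
        self.call = call


def test_deployment_accounting_rates():
    results = [_FakeResult(f"s{i}", "ok", "FGFR+") for i in range(17)]
    results += [_FakeResult(f"s{17 + i}", "ok", "FGFR-") for i in range(5)]
    results += [_FakeResult("q1", "error"), _FakeResult("q2", "error")]
    acc = hs.deployment_accounting(results)
    assert acc["received"] == 24
    assert acc["predicted"] == 22
    assert acc["qc_failed"] == 2
    assert acc["prediction_rate_percent"] == pytest.approx(91.67, abs=0.01)
    assert acc["predicted_negative_fraction"] == pytest.approx(5 / 22)
    assert acc["sensitivity"] is None  # no molecular outcomes supplied


def test_deployment_accounting_with_molecular_truth():
    results = [
        _FakeResult("a", "ok", "FGFR+"),
        _FakeResult("b", "ok", "FGFR+"),
        _FakeResult("c", "ok", "FGFR-"),
        _FakeResult("d", "ok", "FGFR-"),
        _FakeResult("e", "ok", "FGFR+"),  # no molecular result: excluded
    ]
    truth = {"a": "positive", "b": "negative", "c": "negative", "d": "positive"}
    acc = hs.deployment_accounting(results, truth)
    assert acc["sensitivity"] == pytest.approx(0.5)
    assert acc["specificity"] == pytest.approx(0.5)
    assert acc["prevalence"] == pytest.approx(0.5)
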