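"""Validation statistics: published-value fixtures, independent oracles, identities."""

from __future__ import annotations

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from retscreen import diagstats as d
from retscreen.datasets import (
    ALG_VS_OPH,
    PAIRED_ALG_VS_OPH,
    PAIRED_PCP_VS_OPH,
    PCP_VS_OPH,
)

# ---------------------------------------------------------------------------
# published-value fixtures (the bundled study's printed statistics)


def test_alg_accuracy_matches_published():
    acc = d.diagnostic_accuracy(d.to_2x2(ALG_VS_OPH))
    assert acc.table.n == 2496
    assert abs(acc.sensitivity.value - 0.8505) < 5e-5
    assert abs(acc.specificity.value - 0.8067) < 5e-5
    assert abs(acc.ppv.value - 0.5456) < 5e-5
    assert abs(acc.npv.value - 0.9519) < 5e-5
    assert abs(acc.prevalence.value - 0.2143) < 5e-5
    assert abs(acc.lr_pos.value - 4.40) < 5e-3
    assert abs(acc.lr_neg.value - 0.19) < 5e-3
    # printed CIs reproduce to the printed precision (percent, 2 dp)
    assert abs(acc.sensitivity.ci[0] * 100 - 81.93) < 5e-3
    assert abs(acc.sensitivity.ci[1] * 100 - 88.16) < 5e-3
    assert abs(acc.lr_pos.ci[0] - 3.99) < 5e-3
    assert abs(acc.lr_pos.ci[1] - 4.85) < 5e-3


def test_pcp_accuracy_matches_published():
    acc = d.diagnostic_accuracy(d.to_2x2(PCP_VS_OPH))
    assert acc.table.n == 2825
    assert abs(acc.sensitivity.value - 0.6354) < 5e-5
    assert abs(acc.specificity.value - 0.8959) < 5e-5
    assert abs(acc.lr_pos.value - 6.10) < 5e-3


def test_kappas_match_published():
    k_alg = d.cohen_kappa(d.to_2x2(ALG_VS_OPH).as_square())
    k_pcp = d.cohen_kappa(d.to_2x2(PCP_VS_OPH).as_square())
    kg_alg = d.cohen_kappa(d.collapse_gradability(ALG_VS_OPH))
    kg_pcp = d.cohen_kappa(d.collapse_gradability(PCP_VS_OPH))
    assert abs(k_alg.kappa - 0.5462) < 5e-5
    assert abs(k_pcp.kappa - 0.5251) < 5e-5
    assert abs(kg_alg.kappa - 0.3623) < 5e-5
    assert abs(kg_pcp.kappa - 0.3144) < 5e-5
    # the Fleiss-Cohen-Everitt SE reproduces the printed kappa CI
    assert abs(k_alg.ci[0] - 0.5109) < 5e-5
    assert abs(k_alg.ci[1] - 0.5815) < 5e-5


def test_auc_matches_published():
    for table, expected in ((ALG_VS_OPH, 0.8286), (PCP_VS_OPH, 0.7657)):
        t2 = d.to_2x2(table)
        acc = d.diagnostic_accuracy(t2)
        auc = d.single_point_auc(
            acc.sensitivity.value, acc.specificity.value, t2.tp + t2.fn, t2.fp + t2.tn
        )
        assert abs(auc.auc - expected) < 5e-5
    acc = d.diagnostic_accuracy(PAIRED_ALG_VS_OPH)
    auc = d.single_point_auc(
        acc.sensitivity.value,
        acc.specificity.value,
        PAIRED_ALG_VS_OPH.tp + PAIRED_ALG_VS_OPH.fn,
        PAIRED_ALG_VS_OPH.fp + PAIRED_ALG_VS_OPH.tn,
    )
    assert abs(auc.auc - 0.8287) < 5e-5
    # ALG AUC interval as printed
    t2 = d.to_2x2(ALG_VS_OPH)
    acc = d.diagnostic_accuracy(t2)
    auc = d.single_point_auc(
        acc.sensitivity.value, acc.specificity.value, t2.tp + t2.fn, t2.fp + t2.tn
    )
    assert abs(auc.ci[0] - 0.8111) < 5e-5
    assert abs(auc.ci[1] - 0.8461) < 5e-5


def test_fagan_matches_published():
    acc = d.diagnostic_accuracy(d.to_2x2(ALG_VS_OPH))
    prev = acc.prevalence.value
    pos = d.fagan_posttest(prev, acc.lr_pos.value)
    neg = d.fagan_posttest(prev, acc.lr_neg.value)
    assert abs(pos.posttest - 0.55) < 5e-3
    assert abs(neg.posttest - 0.05) < 5e-3
    # Bayes identities: at the sample's own prevalence the post-test
    # probabilities are exactly PPV and 1 - NPV
    assert abs(pos.posttest - acc.ppv.value) < 1e-12
    assert abs(neg.posttest - (1.0 - acc.npv.value)) < 1e-12


def test_paired_sample_matches_published():
    acc = d.diagnostic_accuracy(PAIRED_ALG_VS_OPH)
    assert abs(acc.sensitivity.value - 0.848) < 5e-4
    assert abs(acc.specificity.value - 0.809) < 5e-4
    assert abs(acc.lr_pos.value - 4.45) < 5e-3


def test_paired_auc_comparison_significant():
    aucs = []
    for t in (PAIRED_ALG_VS_OPH, PAIRED_PCP_VS_OPH):
        acc = d.diagnostic_accuracy(t)
        aucs.append(
            d.single_point_auc(
                acc.sensitivity.value, acc.specificity.value, t.tp + t.fn, t.fp + t.tn
            )
        )
    z, p = d.compare_auc(aucs[0], aucs[1])
    assert z > 0  # ALG above PCP
    assert p < 1e-6


# ---------------------------------------------------------------------------
# independent oracles


def test_kappa_against_sklearn():
    from sklearn.metrics import cohen_kappa_score

    tables = [
        d.to_2x2(ALG_VS_OPH).as_square(),
        d.collapse_gradability(PCP_VS_OPH),
        np.array([[10, 2, 1], [3, 20, 4], [0, 5, 15]]),
    ]
    for table in tables:
        k = d.cohen_kappa(table)
        a, b = [], []
        for i in range(table.shape[0]):
            for j in range(table.shape[1]):
                a.extend([i] * int(table[i, j]))
                b.extend([j] * int(table[i, j]))
        assert abs(k.kappa - cohen_kappa_score(a, b)) < 1e-12


def test_kappa_brute_force_small_tables():
    """Direct po/pe computation over exhaustive small 2x2 tables."""
    for tp in range(4):
        for fp in range(4):
            for fn in range(4):
                for tn in range(4):
                    n = tp + fp + fn + tn
                    if n == 0:
                        continue
                    po = (tp + tn) / n
                    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
                    if math.isclose(pe, 1.0, abs_tol=1e-12):
                        continue
                    expected = (po - pe) / (1 - pe)
                    k = d.cohen_kappa(np.array([[tp, fp], [fn, tn]]))
                    assert abs(k.kappa - expected) < 1e-12


def test_kappa_se_against_monte_carlo():
    """The Fleiss-Cohen-Everitt SE matches the sampling SD of kappa."""
    p = d.to_2x2(ALG_VS_OPH).as_square().astype(float)
    p /= p.sum()
    n = 2496
    rng = np.random.default_rng(7)
    kappas = []
    for _ in range(3000):
        sample = rng.multinomial(n, p.ravel()).reshape(2, 2)
        kappas.append(d.cohen_kappa(sample).kappa)
    mc_sd = float(np.std(kappas))
    formula_se = d.cohen_kappa(d.to_2x2(ALG_VS_OPH).as_square()).se_kappa
    assert abs(mc_sd - formula_se) / formula_se < 0.10


def test_two_proportion_against_statsmodels():
    from statsmodels.stats.proportion import proportions_ztest

    z, p = d.two_proportion_test(407, 3520, 461, 3520)
    z_sm, p_sm = proportions_ztest([407, 461], [3520, 3520])
    assert abs(z - z_sm) < 1e-10
    assert abs(p - p_sm) < 1e-10


def test_wald_ci_against_statsmodels_without_correction():
    """Dropping the continuity correction recovers the plain Wald interval."""
    from statsmodels.stats.proportion import proportion_confint

    x, n = 455, 535
    est = d._wald_cc(x, n, alpha=0.05)
    lo, hi = proportion_confint(x, n, alpha=0.05, method="normal")
    cc = 1.0 / (2 * n)
    assert abs((est.ci[0] + cc) - lo) < 1e-12
    assert abs((est.ci[1] - cc) - hi) < 1e-12


# ---------------------------------------------------------------------------
# structure and identities


def test_crosstab_roundtrip():
    test, ref = d.table_to_calls(ALG_VS_OPH)
    t = d.crosstab_raters(test, ref, "ALG", "OPH")
    assert (t.counts == ALG_VS_OPH.counts).all()
    assert t.n == 3520
    grad = d.collapse_gradability(t)
    assert grad.sum() == t.n
    t2 = d.to_2x2(t)
    assert (t2.tp, t2.fp, t2.fn, t2.tn) == (455, 379, 80, 1582)


def test_crosstab_errors():
    with pytest.raises(ValueError):
        d.crosstab_raters(["DR"], ["DR", "NODR"])
    with pytest.raises(ValueError):
        d.crosstab_raters(["MAYBE"], ["DR"])
    with pytest.raises(ValueError):
        d.RaterTable(counts=np.zeros((3, 3), dtype=int))
    with pytest.raises(ValueError):
        d.ContingencyTable2x2(tp=-1, fp=0, fn=0, tn=5)


def test_accuracy_identities():
    acc = d.diagnostic_accuracy(d.to_2x2(ALG_VS_OPH))
    se, sp = acc.sensitivity.value, acc.specificity.value
    assert abs(acc.lr_pos.value - se / (1 - sp)) < 1e-12
    assert abs(acc.lr_neg.value - (1 - se) / sp) < 1e-12


def test_accuracy_requires_both_classes():
    with pytest.raises(ValueError):
        d.diagnostic_accuracy(d.ContingencyTable2x2(tp=0, fp=5, fn=0, tn=10))


def test_perfect_test_degenerate_values():
    acc = d.diagnostic_accuracy(d.ContingencyTable2x2(tp=30, fp=0, fn=0, tn=70))
    assert acc.sensitivity.value == 1.0
    assert acc.specificity.value == 1.0
    assert math.isnan(acc.lr_pos.value)  # Se / 0
    assert acc.lr_neg.value == 0.0
    auc = d.single_point_auc(1.0, 1.0, 30, 70)
    assert auc.auc == 1.0
    assert auc.variance == 0.0


def test_kappa_properties():
    # perfect agreement
    assert d.cohen_kappa(np.array([[50, 0], [0, 50]])).kappa == pytest.approx(1.0)
    # independence: po == pe
    indep = np.array([[25, 25], [25, 25]])
    assert d.cohen_kappa(indep).kappa == pytest.approx(0.0, abs=1e-12)
    # symmetry under transpose
    t = np.array([[40, 9], [3, 48]])
    assert d.cohen_kappa(t).kappa == pytest.approx(d.cohen_kappa(t.T).kappa)
    with pytest.raises(ValueError):
        d.cohen_kappa(np.array([[1, 2, 3], [4, 5, 6]]))
    with pytest.raises(ZeroDivisionError):
        d.cohen_kappa(np.array([[10, 0], [0, 0]]))  # degenerate marginals


def test_kappa_homogeneity_trivials():
    k1 = d.cohen_kappa(np.array([[40, 10], [10, 40]]))
    hom = d.kappa_homogeneity(k1, k1)
    assert hom.chi2 == pytest.approx(0.0, abs=1e-12)
    assert hom.p_value == pytest.approx(1.0)
    assert hom.df == 1
    with pytest.raises(ValueError):
        d.kappa_homogeneity(k1)
    # three kappas give df = 2
    k2 = d.cohen_kappa(np.array([[45, 5], [8, 42]]))
    assert d.kappa_homogeneity(k1, k2, k2).df == 2


def test_homogeneity_two_kappa_closed_form():
    """For two kappas the statistic reduces to (k1-k2)^2 / (v1+v2)."""
    k1 = d.cohen_kappa(d.collapse_gradability(ALG_VS_OPH))
    k2 = d.cohen_kappa(d.collapse_gradability(PCP_VS_OPH))
    hom = d.kappa_homogeneity(k1, k2)
    expected = (k1.kappa - k2.kappa) ** 2 / (k1.se_kappa**2 + k2.se_kappa**2)
    assert hom.chi2 == pytest.approx(expected, rel=1e-12)
    assert hom.p_value == pytest.approx(float(sps.chi2.sf(expected, 1)), rel=1e-12)


@settings(max_examples=60, deadline=None)
@given(
    pretest=st.floats(0.01, 0.99),
    lr=st.floats(0.01, 100.0),
)
def test_fagan_properties(pretest, lr):
    res = d.fagan_posttest(pretest, lr)
    assert 0.0 < res.posttest < 1.0
    if lr > 1.0:
        assert res.posttest > pretest
    elif lr < 1.0:
        assert res.posttest < pretest
    # odds-form round trip
    post_odds = res.posttest / (1 - res.posttest)
    pre_odds = pretest / (1 - pretest)
    assert post_odds == pytest.approx(lr * pre_odds, rel=1e-9)


def test_fagan_errors():
    with pytest.raises(ValueError):
        d.fagan_posttest(0.0, 2.0)
    with pytest.raises(ValueError):
        d.fagan_posttest(0.5, 0.0)


def test_auc_errors():
    with pytest.raises(ValueError):
        d.single_point_auc(1.2, 0.5)
    with pytest.raises(ValueError):
        d.compare_auc(d.AucResult(auc=0.8), d.AucResult(auc=0.7))


def test_two_proportion_trivials():
    z, p = d.two_proportion_test(50, 100, 50, 100)
    assert z == 0.0 and p == 1.0
    # Yates correction shrinks |z|
    z1, _ = d.two_proportion_test(40, 100, 55, 100)
    z2, _ = d.two_proportion_test(40, 100, 55, 100, continuity=True)
    assert abs(z2) < abs(z1)
    with pytest.raises(ValueError):
        d.two_proportion_test(5, 0, 1, 10)
    with pytest.raises(ValueError):
        d.two_proportion_test(11, 10, 1, 10)


def test_validation_report_self_comparison():
    calls, _ = d.table_to_calls(ALG_VS_OPH)
    report = d.validation_report(calls, calls, "A", "A")
    assert report["kappa"].kappa == pytest.approx(1.0)
    assert report["accuracy"].sensitivity.value == 1.0
    assert report["accuracy"].specificity.value == 1.0
    assert report["auc"].auc == 1.0


def test_validation_report_handles_all_gradable_sample():
    """With no UNG calls the gradability kappa is undefined, not an error."""
    test = ["DR", "DR", "NODR", "NODR", "DR", "NODR"]
    ref = ["DR", "NODR", "NODR", "NODR", "DR", "DR"]
    report = d.validation_report(test, ref)
    assert report["gradability"]["kappa"] is None
    blob = d.report_to_json(report)
    json.dumps(blob)
    assert blob["gradability_kappa"] is None
    assert "undefined" in d.report_to_text(report)


def test_validation_report_roundtrip_and_serialization():
    test, ref = d.table_to_calls(ALG_VS_OPH)
    report = d.validation_report(test, ref, "ALG", "OPH")
    blob = d.report_to_json(report)
    json.dumps(blob)  # must be serializable as-is
    assert blob["crosstab"] == ALG_VS_OPH.counts.tolist()
    assert blob["sensitivity_pct"]["value"] == pytest.approx(85.05, abs=5e-3)
    assert blob["kappa"] == pytest.approx(0.5462, abs=5e-5)
    text = d.report_to_text(report)
    assert "Sensitivity" in text and "ALG" in text and "Fagan" in text
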