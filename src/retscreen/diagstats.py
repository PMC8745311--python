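"""Diagnostic-test validation statistics for screening-programme data.

Implements the full validation battery used to benchmark a DR screening
strategy against a reference grader: three-category (DR/NODR/UNG) rater
cross-tabulations, gradability collapse, 2×2 accuracy tables after ungradable
exclusion, sensitivity/specificity/predictive values with Wald
continuity-corrected confidence intervals, likelihood ratios with
log-method (Simel) intervals, Fagan post-test probabilities, Cohen's kappa
with the Fleiss–Cohen–Everitt large-sample variance, an inverse-variance
kappa homogeneity chi-square test, single-operating-point ROC AUC with an
unpaired z comparison, and a pooled two-proportion z-test.

Category labels are fixed to ``("DR", "NODR", "UNG")`` and kept in that order
so cross-tabulations compare cell-for-cell against published tables; rows are
the test rater and columns the reference, with reference DR as the positive
class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

LABELS = ("DR", "NODR", "UNG")


@dataclass
class Estimate:
    """A point estimate with an optional two-sided confidence interval."""

    value: float
    ci: Optional[tuple[float, float]] = None

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class RaterTable:
    """3×3 cross-tabulation of {DR, NODR, UNG} calls, test rows × reference columns."""

    counts: np.ndarray
    test_label: str = "test"
    reference_label: str = "reference"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3) or (c < 0).any() or c.sum() == 0:
            raise ValueError("counts must be a non-negative 3x3 table with total > 0")
        self.counts = c

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ContingencyTable2x2:
    """2×2 diagnostic table; reference-positive (DR) defines the columns."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0 or self.n == 0:
            raise ValueError("cells must be non-negative with total > 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_square(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=int)


@dataclass
class DiagnosticAccuracy:
    prevalence: Estimate
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    table: ContingencyTable2x2
    alpha: float = 0.05


@dataclass
class AgreementResult:
    """Cohen's kappa with observed/expected agreement and a large-sample CI."""

    kappa: float
    p_observed: float
    p_expected: float
    se_kappa: float
    ci: tuple[float, float]
    n: int


@dataclass
class KappaHomogeneityResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class AucResult:
    """Single-operating-point ROC area: the polygon (0,0)→(1−Sp,Se)→(1,1)."""

    auc: float
    ci: Optional[tuple[float, float]] = None
    variance: Optional[float] = None


@dataclass
class PosttestResult:
    pretest: float
    likelihood_ratio: float
    posttest: float


# ---------------------------------------------------------------------------
# cross-tabulation


def crosstab_raters(
    test: Sequence[str],
    reference: Sequence[str],
    test_label: str = "test",
    reference_label: str = "reference",
) -> RaterTable:
    """Exact 3×3 cross-tabulation of two aligned per-patient diagnosis lists."""
    if len(test) != len(reference):
        raise ValueError("test and reference lists must have equal length")
    idx = {lab: i for i, lab in enumerate(LABELS)}
    counts = np.zeros((3, 3), dtype=int)
    for t, r in zip(test, reference):
        if t not in idx or r not in idx:
            raise ValueError(f"unknown diagnosis label in pair ({t!r}, {r!r})")
        counts[idx[t], idx[r]] += 1
    return RaterTable(counts=counts, test_label=test_label, reference_label=reference_label)


def table_to_calls(t: RaterTable) -> tuple[list[str], list[str]]:
    """Reconstruct aligned diagnosis lists whose cross-tab equals ``t``."""
    test: list[str] = []
    reference: list[str] = []
    for i, row_lab in enumerate(LABELS):
        for j, col_lab in enumerate(LABELS):
            k = int(t.counts[i, j])
            test.extend([row_lab] * k)
            reference.extend([col_lab] * k)
    return test, reference


def collapse_gradability(t: RaterTable) -> np.ndarray:
    """Collapse DR+NODR into GRAD: 2×2 [[GG, GU], [UG, UU]] preserving the total."""
    c = t.counts
    grad_rows = c[0:2, :]
    return np.array(
        [
            [int(grad_rows[:, 0:2].sum()), int(grad_rows[:, 2].sum())],
            [int(c[2, 0:2].sum()), int(c[2, 2])],
        ],
        dtype=int,
    )


def to_2x2(t: RaterTable) -> ContingencyTable2x2:
    """Drop pairs where either rater called UNG; tabulate DR/NODR agreement."""
    c = t.counts
    out = ContingencyTable2x2(
        tp=int(c[0, 0]), fp=int(c[0, 1]), fn=int(c[1, 0]), tn=int(c[1, 1])
    )
    if out.n == 0:
        raise ValueError("no gradable pairs remain after UNG exclusion")
    return out


# ---------------------------------------------------------------------------
# accuracy indexes


def _wald_cc(x: int, n: int, alpha: float) -> Estimate:
    """Wald proportion CI with continuity correction, clipped to [0, 1]."""
    if n == 0:
        return Estimate(float("nan"), None)
    p = x / n
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n) + 1.0 / (2.0 * n)
    return Estimate(p, (max(p - half, 0.0), min(p + half, 1.0)))


def _lr_estimate(x1: int, n1: int, x2: int, n2: int, alpha: float) -> Estimate:
    """Ratio of two proportions with the log-method (Simel) CI."""
    if n1 == 0 or n2 == 0 or x2 == 0:
        return Estimate(float("nan"), None)
    p1, p2 = x1 / n1, x2 / n2
    lr = p1 / p2
    if x1 == 0:
        return Estimate(lr, None)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    var = (1.0 - p1) / x1 + (1.0 - p2) / x2
    half = z * math.sqrt(var)
    return Estimate(lr, (lr * math.exp(-half), lr * math.exp(half)))


def diagnostic_accuracy(t: ContingencyTable2x2, alpha: float = 0.05) -> DiagnosticAccuracy:
    """Se/Sp/PPV/NPV/prevalence with Wald-CC CIs; LR± with log-method CIs.

    Indexes with a zero denominator are reported as NaN with no interval
    rather than raised.
    """
    n_pos = t.tp + t.fn
    n_neg = t.fp + t.tn
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both reference-positive and reference-negative patients required")
    return DiagnosticAccuracy(
        prevalence=_wald_cc(n_pos, t.n, alpha),
        sensitivity=_wald_cc(t.tp, n_pos, alpha),
        specificity=_wald_cc(t.tn, n_neg, alpha),
        ppv=_wald_cc(t.tp, t.tp + t.fp, alpha) if t.tp + t.fp else Estimate(float("nan")),
        npv=_wald_cc(t.tn, t.fn + t.tn, alpha) if t.fn + t.tn else Estimate(float("nan")),
        lr_pos=_lr_estimate(t.tp, n_pos, t.fp, n_neg, alpha),
        lr_neg=_lr_estimate(t.fn, n_pos, t.tn, n_neg, alpha),
        table=t,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# agreement


def _fleiss_kappa_variance(p: np.ndarray, n: int) -> float:
    """Large-sample variance of Cohen's kappa (Fleiss, Cohen & Everitt, 1969)."""
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    one_po = 1.0 - p_o
    one_pe = 1.0 - p_e
    term1 = sum(
        p[i, i] * (one_pe - (row[i] + col[i]) * one_po) ** 2 for i in range(len(row))
    )
    term2 = one_po**2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(len(row))
        for j in range(len(row))
        if i != j
    )
    term3 = (p_o * p_e - 2.0 * p_e + p_o) ** 2
    return (term1 + term2 - term3) / (n * one_pe**4)


def cohen_kappa(table: np.ndarray, alpha: float = 0.05) -> AgreementResult:
    """Cohen's kappa of a square agreement table.

    ``p_o`` is the diagonal fraction, ``p_e`` the chance agreement from the
    marginals; the standard error uses the Fleiss–Cohen–Everitt large-sample
    formula (valid under the alternative, hence usable for CIs).
    """
    c = np.asarray(table, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("agreement table must be square")
    n = c.sum()
    if n <= 0 or (c < 0).any():
        raise ValueError("table must be non-negative with total > 0")
    p = c / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        raise ZeroDivisionError("degenerate marginals: chance agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    var = _fleiss_kappa_variance(p, int(n))
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return AgreementResult(
        kappa=kappa,
        p_observed=p_o,
        p_expected=p_e,
        se_kappa=se,
        ci=(kappa - z * se, min(kappa + z * se, 1.0)),
        n=int(n),
    )


def kappa_homogeneity(*results: AgreementResult) -> KappaHomogeneityResult:
    """Chi-square homogeneity test for two or more independent kappas.

    The statistic is ``Σ (k_i − k̄)² / var(k_i)`` with ``k̄`` the
    inverse-variance-weighted mean; df = number of kappas − 1.
    """
    if len(results) == 1 and isinstance(results[0], (list, tuple)):
        results = tuple(results[0])
    if len(results) < 2:
        raise ValueError("at least two kappas are required")
    variances = np.array([r.se_kappa**2 for r in results])
    if (variances <= 0).any():
        raise ZeroDivisionError("a kappa with zero variance cannot be compared")
    kappas = np.array([r.kappa for r in results])
    weights = 1.0 / variances
    k_bar = float((weights * kappas).sum() / weights.sum())
    chi2 = float(((kappas - k_bar) ** 2 * weights).sum())
    df = len(results) - 1
    return KappaHomogeneityResult(
        chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df))
    )


# ---------------------------------------------------------------------------
# ROC, Fagan, proportions


def single_point_auc(
    se: float,
    sp: float,
    n_pos: Optional[int] = None,
    n_neg: Optional[int] = None,
    alpha: float = 0.05,
) -> AucResult:
    """ROC area for a binary classifier with one operating point: (Se+Sp)/2.

    When the group sizes are given, the variance propagates the binomial
    variances of Se and Sp and a Wald CI is attached.
    """
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("se and sp must lie in [0, 1]")
    auc = (se + sp) / 2.0
    if n_pos is None or n_neg is None:
        return AucResult(auc=auc)
    var = (se * (1.0 - se) / n_pos + sp * (1.0 - sp) / n_neg) / 4.0
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(var)
    return AucResult(auc=auc, ci=(auc - half, auc + half), variance=var)


def compare_auc(
    a: AucResult, b: AucResult, paired: bool = False
) -> tuple[float, float]:
    """z-test on the difference of two single-point AUCs (two-sided p).

    The variance of the difference is the sum of the individual variances;
    with ``paired=True`` the same sum is used (the positive correlation
    between paired AUCs is not estimable from the operating points alone, so
    the test is conservative).
    """
    if a.variance is None or b.variance is None:
        raise ValueError("both AUCs need variances; pass group sizes to single_point_auc")
    var = a.variance + b.variance
    if var <= 0:
        raise ZeroDivisionError("zero variance in AUC comparison")
    z = (a.auc - b.auc) / math.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def fagan_posttest(pretest: float, lr: float) -> PosttestResult:
    """Bayes update of a pre-test probability through a likelihood ratio."""
    if not 0.0 < pretest < 1.0:
        raise ValueError("pretest probability must lie strictly in (0, 1)")
    if lr <= 0.0:
        raise ValueError("likelihood ratio must be positive")
    odds = lr * pretest / (1.0 - pretest)
    return PosttestResult(pretest=pretest, likelihood_ratio=lr, posttest=odds / (1.0 + odds))


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test (two-sided).

    With ``continuity=True`` the Yates correction ``1/2·(1/n1 + 1/n2)`` is
    subtracted from the absolute difference.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie within their group sizes")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    diff = p1 - p2
    if continuity:
        corr = 0.5 * (1.0 / n1 + 1.0 / n2)
        diff = math.copysign(max(abs(diff) - corr, 0.0), diff)
    z = diff / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# full report


def validation_report(
    test_calls: Sequence[str],
    reference_calls: Sequence[str],
    test_label: str = "test",
    reference_label: str = "reference",
    alpha: float = 0.05,
) -> dict:
    """End-to-end validation of one grader against a reference.

    Emits the 3×3 cross-tab, the GRAD/UNG collapse and its kappa, the 2×2
    accuracy block after UNG exclusion, the DR/NODR kappa, the
    single-operating-point AUC, and Fagan post-test probabilities at the
    sample's own prevalence, as one dictionary (JSON-serializable via
    :func:`report_to_json`).
    """
    table = crosstab_raters(test_calls, reference_calls, test_label, reference_label)
    grad = collapse_gradability(table)
    # degenerate marginals (e.g. neither rater ever calls UNG) leave kappa
    # undefined; report None rather than fail the whole battery
    try:
        kappa_grad = cohen_kappa(grad, alpha=alpha)
    except ZeroDivisionError:
        kappa_grad = None
    t2 = to_2x2(table)
    acc = diagnostic_accuracy(t2, alpha=alpha)
    try:
        kappa_dr = cohen_kappa(t2.as_square(), alpha=alpha)
    except ZeroDivisionError:
        kappa_dr = None
    auc = single_point_auc(
        acc.sensitivity.value,
        acc.specificity.value,
        n_pos=t2.tp + t2.fn,
        n_neg=t2.fp + t2.tn,
        alpha=alpha,
    )
    prev = acc.prevalence.value
    fagan_pos = (
        fagan_posttest(prev, acc.lr_pos.value)
        if math.isfinite(acc.lr_pos.value)
        else None
    )
    fagan_neg = (
        fagan_posttest(prev, acc.lr_neg.value)
        if math.isfinite(acc.lr_neg.value) and acc.lr_neg.value > 0
        else None
    )
    return {
        "labels": {"test": test_label, "reference": reference_label},
        "crosstab": table,
        "gradability": {"table": grad, "kappa": kappa_grad},
        "accuracy": acc,
        "kappa": kappa_dr,
        "auc": auc,
        "fagan": {"positive": fagan_pos, "negative": fagan_neg},
    }


def _est_json(e: Optional[Estimate], scale: float = 1.0) -> Optional[dict]:
    if e is None or not math.isfinite(e.value):
        return None
    out = {"value": round(e.value * scale, 4)}
    if e.ci is not None:
        out["ci"] = [round(e.ci[0] * scale, 4), round(e.ci[1] * scale, 4)]
    return out


def report_to_json(report: dict) -> dict:
    """Flatten a validation report into plain JSON-serializable types."""
    acc: DiagnosticAccuracy = report["accuracy"]
    kappa: Optional[AgreementResult] = report["kappa"]
    kg: Optional[AgreementResult] = report["gradability"]["kappa"]
    auc: AucResult = report["auc"]
    out = {
        "labels": report["labels"],
        "crosstab": report["crosstab"].counts.tolist(),
        "gradability_table": report["gradability"]["table"].tolist(),
        "gradability_kappa": round(kg.kappa, 4) if kg else None,
        "n_2x2": acc.table.n,
        "counts": {
            "tp": acc.table.tp,
            "fp": acc.table.fp,
            "fn": acc.table.fn,
            "tn": acc.table.tn,
        },
        "prevalence_pct": _est_json(acc.prevalence, 100.0),
        "sensitivity_pct": _est_json(acc.sensitivity, 100.0),
        "specificity_pct": _est_json(acc.specificity, 100.0),
        "ppv_pct": _est_json(acc.ppv, 100.0),
        "npv_pct": _est_json(acc.npv, 100.0),
        "lr_pos": _est_json(acc.lr_pos),
        "lr_neg": _est_json(acc.lr_neg),
        "kappa": round(kappa.kappa, 4) if kappa else None,
        "kappa_ci": [round(x, 4) for x in kappa.ci] if kappa else None,
        "auc": round(auc.auc, 4),
        "auc_ci": [round(x, 4) for x in auc.ci] if auc.ci else None,
    }
    for side in ("positive", "negative"):
        fr = report["fagan"][side]
        out[f"posttest_{side}_pct"] = round(fr.posttest * 100.0, 2) if fr else None
    return out


def report_to_text(report: dict) -> str:
    """Human-readable rendering of a validation report."""
    acc: DiagnosticAccuracy = report["accuracy"]
    lines = [
        f"Validation: {report['labels']['test']} vs {report['labels']['reference']}",
        "",
        "3x3 cross-tabulation (rows = test, cols = reference; DR / NODR / UNG):",
    ]
    for i, lab in enumerate(LABELS):
        row = report["crosstab"].counts[i]
        lines.append(f"  {lab:>5}  {row[0]:>6} {row[1]:>6} {row[2]:>6}")
    g = report["gradability"]["table"]
    kg = report["gradability"]["kappa"]
    kg_txt = f"{kg.kappa:.4f}" if kg else "undefined (degenerate marginals)"
    lines += [
        "",
        f"GRAD/UNG collapse: GG={g[0,0]} GU={g[0,1]} UG={g[1,0]} UU={g[1,1]}"
        f"  kappa={kg_txt}",
        "",
        f"2x2 after UNG exclusion (n={acc.table.n}): "
        f"TP={acc.table.tp} FP={acc.table.fp} FN={acc.table.fn} TN={acc.table.tn}",
    ]

    def fmt(name: str, e: Estimate, pct: bool = True) -> str:
        s = 100.0 if pct else 1.0
        unit = "%" if pct else ""
        txt = f"  {name:<28}{e.value * s:7.2f}{unit}"
        if e.ci:
            txt += f"  ({e.ci[0] * s:.2f}-{e.ci[1] * s:.2f})"
        return txt

    lines += [
        fmt("Prevalence", acc.prevalence),
        fmt("Sensitivity", acc.sensitivity),
        fmt("Specificity", acc.specificity),
        fmt("Positive Predictive Value", acc.ppv),
        fmt("Negative Predictive Value", acc.npv),
        fmt("Likelihood Ratio +", acc.lr_pos, pct=False),
        fmt("Likelihood Ratio -", acc.lr_neg, pct=False),
        "",
        "Cohen kappa (DR/NODR): "
        + (
            f"{report['kappa'].kappa:.4f} "
            f"({report['kappa'].ci[0]:.4f}-{report['kappa'].ci[1]:.4f})"
            if report["kappa"]
            else "undefined (degenerate marginals)"
        ),
        f"Single-point AUC: {report['auc'].auc:.4f}"
        + (
            f" ({report['auc'].ci[0]:.4f}-{report['auc'].ci[1]:.4f})"
            if report["auc"].ci
            else ""
        ),
    ]
    for side in ("positive", "negative"):
        fr = report["fagan"][side]
        if fr:
            lines.append(
                f"Fagan post-test ({side}): {fr.pretest * 100:.0f}% -> "
                f"{fr.posttest * 100:.0f}% (LR {fr.likelihood_ratio:.2f})"
            )
    return "\n".join(lines)
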