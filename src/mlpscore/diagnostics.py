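"""Diagnostic-accuracy evaluation of the severe-MLP vs. outcome dichotomy.

The severe lesion pattern (MLP 3–4) is treated as a binary test for
unfavourable outcome (UO, CPC 3–5).  From the resulting 2×2 table

                 UO        FO
    MLP 3–4      TP        FP
    MLP 1–2      FN        TN

this module computes sensitivity, specificity, predictive values,
likelihood ratios and accuracy, with confidence intervals:

* binomial proportions — Clopper-Pearson exact intervals by default
  (Wilson available), via :mod:`statsmodels`;
* likelihood ratios — the log-normal (Simel) method,
  ``exp(ln LR ± z·SE)`` with the standard SE formulas.

Two false-rate conventions exist in the literature and both are reported:
``fpr_paper`` = FP/(TP+FP) = 1−PPV (the share of severe-MLP calls that had
a favourable outcome) and ``fpr_standard`` = FP/(FP+TN) = 1−specificity;
analogously for the false-negative rate.

``rounding_mode="as_published"`` forms the likelihood ratios from
sensitivity and specificity rounded to two decimals first — the convention
under which a 33/2/2/10 table yields LR⁺ 5.53 rather than the raw-count
5.66 — while ``"raw"`` (the default) uses the exact fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import derive_outcomes
from .errors import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticReport",
    "crosstab",
    "diagnostic_metrics",
    "proportion_ci",
    "lr_ci",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (5 rounds away from zero), as tables print."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN counts for severe MLP (positive) vs. UO (condition)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def crosstab(
    validation_table: pd.DataFrame,
) -> tuple[ContingencyTable2x2, pd.DataFrame]:
    """Cross-tabulate MLP against outcome for a validation cohort.

    Returns the dichotomised 2×2 table (severe MLP 3–4 vs. UO) and the full
    2×4 outcome × MLP count table (rows UO/FO, columns MLP 1..4).  Outcome
    columns are derived from the CPC assessments if not already present.
    Raises ValidationError naming the first subject lacking an MLP.
    """
    df = validation_table
    if "favourable" not in df.columns:
        df = derive_outcomes(df)
    missing = df["mlp"].isna()
    if missing.any():
        sid = df.loc[missing, "subject_id"].iloc[0]
        raise ValidationError(f"subject {sid}: missing MLP score")
    mlp = df["mlp"].astype(int)
    if not mlp.isin([1, 2, 3, 4]).all():
        bad = df.loc[~mlp.isin([1, 2, 3, 4]), "subject_id"].iloc[0]
        raise ValidationError(f"subject {bad}: MLP outside 1..4")

    uo = ~df["favourable"].astype(bool)
    by_cell = pd.DataFrame(
        {
            m: [int(((mlp == m) & uo).sum()), int(((mlp == m) & ~uo).sum())]
            for m in (1, 2, 3, 4)
        },
        index=pd.Index(["UO", "FO"], name="outcome"),
    )
    by_cell.columns.name = "mlp"

    severe = mlp >= 3
    table = ContingencyTable2x2(
        tp=int((severe & uo).sum()),
        fp=int((severe & ~uo).sum()),
        fn=int((~severe & uo).sum()),
        tn=int((~severe & ~uo).sum()),
    )
    return table, by_cell


def proportion_ci(
    successes: int,
    n: int,
    alpha: float = 0.05,
    method: str = "clopper_pearson",
) -> tuple[float, float]:
    """Two-sided (1−alpha) confidence interval for a binomial proportion.

    ``clopper_pearson`` is the exact interval obtained by inverting the
    binomial tail tests (beta-quantile form); ``wilson`` is the score
    interval.  The exact interval's boundaries are closed: low = 0 when
    successes = 0 and high = 1 when successes = n.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if n <= 0 or not 0 <= successes <= n:
        raise ValidationError(f"need 0 <= successes <= n, n > 0; got {successes}/{n}")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValidationError(f"unknown CI method {method!r}")
    low, high = proportion_confint(successes, n, alpha=alpha, method=sm_method)
    if successes == 0:
        low = 0.0
    if successes == n:
        high = 1.0
    return float(low), float(high)


def lr_ci(
    t: ContingencyTable2x2,
    which: str,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Log-normal confidence interval for a likelihood ratio.

    Uses ``exp(ln LR ± z·SE)`` with the standard (Simel) standard errors

        SE⁺ = √(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn))
        SE⁻ = √(1/fn − 1/(tp+fn) + 1/tn − 1/(fp+tn))

    Returns (nan, nan) when a zero cell makes the SE undefined.
    """
    if which not in ("pos", "neg"):
        raise ValidationError(f"which must be 'pos' or 'neg', got {which!r}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    diseased, healthy = tp + fn, fp + tn
    if diseased == 0 or healthy == 0:
        return (math.nan, math.nan)
    if which == "pos":
        if tp == 0 or fp == 0:
            return (math.nan, math.nan)
        lr = (tp / diseased) / (fp / healthy)
        se = math.sqrt(1 / tp - 1 / diseased + 1 / fp - 1 / healthy)
    else:
        if fn == 0 or tn == 0:
            return (math.nan, math.nan)
        lr = (fn / diseased) / (tn / healthy)
        se = math.sqrt(1 / fn - 1 / diseased + 1 / tn - 1 / healthy)
    z = stats.norm.ppf(1 - alpha / 2)
    return (math.exp(math.log(lr) - z * se), math.exp(math.log(lr) + z * se))


@dataclass
class DiagnosticReport:
    """Point estimates, intervals and the conventions used to compute them."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    accuracy_pct: float
    fpr_paper: float
    fnr_paper: float
    fpr_standard: float
    fnr_standard: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    alpha: float = 0.05
    proportion_ci_method: str = "clopper_pearson"
    lr_ci_method: str = "log_wald"
    rounding_mode: str = "raw"

    def to_dict(self) -> dict:
        """JSON-friendly ``{metric: {point, ci_low, ci_high, method}}`` form."""
        def clean(x: float):
            return None if (isinstance(x, float) and math.isnan(x)) else x

        proportion_metrics = {
            "sensitivity", "specificity", "ppv", "npv",
            "fpr_paper", "fnr_paper", "fpr_standard", "fnr_standard",
            "accuracy_pct",
        }
        out: dict = {"metrics": {}}
        for name in (
            "sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg",
            "accuracy_pct", "fpr_paper", "fnr_paper", "fpr_standard",
            "fnr_standard",
        ):
            point = getattr(self, name)
            low, high = self.ci.get(name, (math.nan, math.nan))
            method = (
                self.proportion_ci_method
                if name in proportion_metrics
                else self.lr_ci_method
            )
            out["metrics"][name] = {
                "point": clean(point) if not math.isinf(point) else "inf",
                "ci_low": clean(low),
                "ci_high": clean(high),
                "method": method,
            }
        out["conventions"] = {
            "positive_test": "severe MLP (3-4)",
            "condition": "unfavourable outcome (best CPC 3-5)",
            "fpr_paper": "FP/(TP+FP) = 1 - PPV",
            "fnr_paper": "FN/(FN+TN) = 1 - NPV",
            "fpr_standard": "FP/(FP+TN) = 1 - specificity",
            "fnr_standard": "FN/(FN+TP) = 1 - sensitivity",
            "alpha": self.alpha,
            "proportion_ci_method": self.proportion_ci_method,
            "lr_ci_method": self.lr_ci_method,
            "rounding_mode": self.rounding_mode,
        }
        return out


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def diagnostic_metrics(
    t: ContingencyTable2x2,
    rounding_mode: str = "raw",
    alpha: float = 0.05,
    proportion_ci_method: str = "clopper_pearson",
) -> DiagnosticReport:
    """All diagnostic-performance measures for a 2×2 table.

    In ``raw`` mode the likelihood ratios are formed from the unrounded
    sensitivity and specificity; in ``as_published`` mode those two are
    first rounded half-up to two decimals.  Metrics with a zero denominator
    are reported as NaN (undefined), and LR⁺ with specificity 1 as +inf.
    """
    if rounding_mode not in ("raw", "as_published"):
        raise ValidationError(f"unknown rounding_mode {rounding_mode!r}")
    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    n = t.n

    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    acc = 100.0 * _safe_div(tp + tn, n)

    if rounding_mode == "as_published":
        sens_lr, spec_lr = round_half_up(sens, 2), round_half_up(spec, 2)
    else:
        sens_lr, spec_lr = sens, spec
    if math.isnan(sens_lr) or math.isnan(spec_lr):
        lr_pos = lr_neg = math.nan
    else:
        lr_pos = math.inf if spec_lr == 1 else sens_lr / (1 - spec_lr)
        lr_neg = math.nan if spec_lr == 0 else (1 - sens_lr) / spec_lr

    ci: dict[str, tuple[float, float]] = {}

    def prop_ci(successes: int, total: int) -> tuple[float, float]:
        if total == 0:
            return (math.nan, math.nan)
        return proportion_ci(successes, total, alpha, proportion_ci_method)

    ci["sensitivity"] = prop_ci(tp, tp + fn)
    ci["specificity"] = prop_ci(tn, tn + fp)
    ci["ppv"] = prop_ci(tp, tp + fp)
    ci["npv"] = prop_ci(tn, tn + fn)
    lo, hi = prop_ci(tp + tn, n)
    ci["accuracy_pct"] = (100.0 * lo, 100.0 * hi)
    ci["fpr_paper"] = prop_ci(fp, tp + fp)
    ci["fnr_paper"] = prop_ci(fn, fn + tn)
    ci["fpr_standard"] = prop_ci(fp, fp + tn)
    ci["fnr_standard"] = prop_ci(fn, fn + tp)
    ci["lr_pos"] = lr_ci(t, "pos", alpha)
    ci["lr_neg"] = lr_ci(t, "neg", alpha)

    return DiagnosticReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        accuracy_pct=acc,
        fpr_paper=_safe_div(fp, tp + fp),
        fnr_paper=_safe_div(fn, fn + tn),
        fpr_standard=_safe_div(fp, fp + tn),
        fnr_standard=_safe_div(fn, fn + tp),
        ci=ci,
        alpha=alpha,
        proportion_ci_method=proportion_ci_method,
        rounding_mode=rounding_mode,
    )
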