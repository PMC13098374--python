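"""Normality-gated paired pre/post statistics.

The analysis pipeline compares each variable before and after treatment in
the same subjects.  Paired differences are defined pre − post (so a
treatment-induced decrease is a positive difference).  Routing follows a
Shapiro–Wilk gate at α = 0.05: normal-looking differences go to the paired
t-test, otherwise the Wilcoxon signed-rank test (exact two-sided p for
n ≤ 25 after dropping zero differences, normal approximation with
continuity correction above).  The mean difference with its t-based 95% CI
is always reported alongside, even when the p-value is nonparametric, with
a style flag recording the route.  No multiplicity adjustment is applied;
this mirrors the single-cohort reporting convention and is documented as a
caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phases import PhaseLabel

__all__ = [
    "VariableSummary",
    "PairedComparisonResult",
    "normality_gate",
    "mean_difference_ci",
    "paired_test",
    "summary_difference",
    "summarize_variable",
    "comparison_table",
    "render_report",
]

logger = logging.getLogger(__name__)

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


@dataclass(frozen=True)
class VariableSummary:
    """Mean ± SD (parametric) or median with IQR (nonparametric) summary."""

    style: str
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    def format(self, ndigits: int = 2) -> str:
        if self.style == PARAMETRIC:
            return f"{self.mean:.{ndigits}f} ± {self.sd:.{ndigits}f}"
        return f"{self.median:.{ndigits}f}, {self.q1:.{ndigits}f} - {self.q3:.{ndigits}f}"


@dataclass(frozen=True)
class PairedComparisonResult:
    variable: str
    n: int
    pre_summary: VariableSummary
    post_summary: VariableSummary
    normality_p: float
    test_used: str  # "paired_t" | "wilcoxon"
    mean_difference: float  # pre - post
    ci_low: float
    ci_high: float
    p_value: float
    phase: Optional[PhaseLabel] = None


def summarize_variable(values: Sequence[float], style: str = PARAMETRIC) -> VariableSummary:
    """Summarize a sample as mean ± SD or median with IQR.

    Quantiles use linear interpolation.  A single observation has SD 0
    (degenerate but well defined for rendering).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if style not in (PARAMETRIC, NONPARAMETRIC):
        raise ValueError(f"unknown summary style {style!r}")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    return VariableSummary(style=style, mean=float(np.mean(x)), sd=sd, median=med, q1=q1, q3=q3)


def normality_gate(diffs: Sequence[float], alpha: float = 0.05) -> tuple[str, float]:
    """Route paired differences by Shapiro–Wilk normality at ``alpha``.

    Returns ``("parametric", p)`` when p >= alpha, else
    ``("nonparametric", p)``.  A constant vector is degenerate and routes
    nonparametric with p = 0.
    """
    x = np.asarray(diffs, dtype=float)
    if x.size < 3:
        raise ValueError(f"normality gate requires n >= 3, got n={x.size}")
    if np.ptp(x) == 0:
        return NONPARAMETRIC, 0.0
    p = float(sps.shapiro(x).pvalue)
    return (PARAMETRIC, p) if p >= alpha else (NONPARAMETRIC, p)


def mean_difference_ci(diffs: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Mean of paired differences with the t-based CI: mean ± t_{1−α/2,n−1}·SD/√n."""
    x = np.asarray(diffs, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"CI requires n >= 2, got n={n}")
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1)) / np.sqrt(n)
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, n - 1))
    return mean, mean - tcrit * se, mean + tcrit * se


def _wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p. Zeros dropped (Wilcoxon's rule),
    ties midranked; exact distribution for n <= 25 with untied |d|."""
    d = diffs[diffs != 0]
    if d.size == 0:
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not ties:
        return float(sps.wilcoxon(d, method="exact").pvalue)
    return float(sps.wilcoxon(d, correction=True, method="approx").pvalue)


def _paired_t_p(diffs: np.ndarray) -> float:
    sd = float(np.std(diffs, ddof=1))
    if sd == 0:
        return 1.0 if float(np.mean(diffs)) == 0 else 0.0
    t = float(np.mean(diffs)) / (sd / np.sqrt(diffs.size))
    return 2.0 * float(sps.t.sf(abs(t), diffs.size - 1))


def paired_test(
    pre: Sequence[float],
    post: Sequence[float],
    variable: str = "",
    phase: Optional[PhaseLabel] = None,
    alpha: float = 0.05,
    force: Optional[str] = None,
) -> PairedComparisonResult:
    """Paired pre/post comparison of one variable.

    Differences are pre − post.  The test is routed by the Shapiro–Wilk gate
    unless ``force`` is ``"parametric"`` or ``"nonparametric"``.  All-zero
    differences define p = 1.0.  Summaries follow the route (mean ± SD for
    parametric, median + IQR otherwise); the t-based mean-difference CI is
    reported for every route.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"pre and post must have equal length, got {a.size} and {b.size}")
    if a.size < 3:
        raise ValueError(f"paired test requires n >= 3, got n={a.size}")
    diffs = a - b
    if np.ptp(diffs) == 0 and diffs[0] == 0:
        route, normality_p = NONPARAMETRIC, 0.0
        p_value = 1.0
        test_used = "wilcoxon"
    else:
        if force is None:
            route, normality_p = normality_gate(diffs, alpha=alpha)
        elif force in (PARAMETRIC, NONPARAMETRIC):
            route = force
            normality_p = float("nan")
        else:
            raise ValueError(f"force must be 'parametric' or 'nonparametric', got {force!r}")
        if route == PARAMETRIC:
            test_used = "paired_t"
            p_value = _paired_t_p(diffs)
        else:
            test_used = "wilcoxon"
            p_value = _wilcoxon_p(diffs)
    mean, lo, hi = mean_difference_ci(diffs)
    style = PARAMETRIC if test_used == "paired_t" else NONPARAMETRIC
    return PairedComparisonResult(
        variable=variable,
        n=int(a.size),
        pre_summary=summarize_variable(a, style),
        post_summary=summarize_variable(b, style),
        normality_p=normality_p,
        test_used=test_used,
        mean_difference=mean,
        ci_low=lo,
        ci_high=hi,
        p_value=p_value,
        phase=phase,
    )


def summary_difference(mean_pre: float, mean_post: float) -> float:
    """Difference of summary means, pre − post (consistency check: equals the
    mean of paired differences)."""
    return mean_pre - mean_post


def comparison_table(
    data: pd.DataFrame,
    variables: Optional[Iterable[str]] = None,
    phases: Optional[Iterable[PhaseLabel | str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Publication-style paired-comparison table from long-format metrics.

    ``data`` has columns ``subject_id, visit, variable, value`` and
    optionally ``phase`` (empty/NaN for global variables).  One row of
    results is produced per variable (× phase for annular metrics), with a
    significance flag at p < alpha and no multiplicity adjustment.
    Subjects missing either visit are dropped for that variable with a
    logged count.
    """
    df = data.copy()
    if "phase" not in df.columns:
        df["phase"] = ""
    df["phase"] = df["phase"].fillna("")
    if variables is None:
        variables = list(dict.fromkeys(df["variable"]))
    if phases is not None:
        keep = {str(p) for p in phases} | {""}
        df = df[df["phase"].astype(str).isin(keep)]
    rows = []
    for variable in variables:
        sub = df[df["variable"] == variable]
        for phase_key in dict.fromkeys(sub["phase"]):
            cell = sub[sub["phase"] == phase_key]
            wide = cell.pivot_table(index="subject_id", columns="visit", values="value")
            if not {"pre", "post"}.issubset(wide.columns):
                logger.warning("variable %s phase %s lacks a complete pre/post pair; skipped", variable, phase_key)
                continue
            complete = wide.dropna(subset=["pre", "post"])
            dropped = len(wide) - len(complete)
            if dropped:
                logger.info("variable %s phase %s: dropped %d subject(s) with missing pair", variable, phase_key, dropped)
            phase = PhaseLabel(phase_key) if phase_key else None
            res = paired_test(
                complete["pre"].to_numpy(), complete["post"].to_numpy(),
                variable=variable, phase=phase, alpha=alpha,
            )
            rows.append(
                {
                    "variable": variable,
                    "phase": phase_key,
                    "n": res.n,
                    "pre": res.pre_summary.format(),
                    "post": res.post_summary.format(),
                    "mean_difference": res.mean_difference,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "test": res.test_used,
                    "normality_p": res.normality_p,
                    "significant": res.p_value < alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variable", "phase", "n", "pre", "post", "mean_difference",
            "ci_low", "ci_high", "p_value", "test", "normality_p", "significant",
        ],
    )


def _fmt_p(p: float) -> str:
    return "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0") or "0"


def render_report(table: pd.DataFrame, fmt: str = "tsv", ndigits: int = 2) -> str:
    """Render a comparison table as TSV or Markdown with 2-dp rounding.

    Bit-identical for identical input: formatting is purely deterministic.
    """
    out = table.copy()
    out["MeanDiff"] = out["mean_difference"].map(lambda v: f"{v:.{ndigits}f}")
    out["CI95"] = [f"({lo:.{ndigits}f}, {hi:.{ndigits}f})" for lo, hi in zip(out["ci_low"], out["ci_high"])]
    out["P"] = out["p_value"].map(_fmt_p)
    out["Flag"] = np.where(out["significant"], "*", "")
    cols = ["variable", "phase", "n", "pre", "post", "MeanDiff", "CI95", "P", "test", "Flag"]
    cols += [c for c in ("published_difference",) if c in out.columns]
    out = out[cols].rename(columns={"variable": "Variable", "phase": "Phase", "n": "N",
                                    "pre": "Pre", "post": "Post", "test": "Test"})
    if fmt == "tsv":
        return out.to_csv(sep="\t", index=False)
    if fmt == "markdown":
        header = "| " + " | ".join(out.columns) + " |"
        rule = "|" + "|".join(["---"] * len(out.columns)) + "|"
        body = ["| " + " | ".join(str(v) for v in row) + " |" for row in out.itertuples(index=False)]
        return "\n".join([header, rule, *body]) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
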