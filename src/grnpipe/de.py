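"""Per-timepoint treatment-vs-control differential-expression calls.

For each gene and timepoint the fold change is the ratio of arithmetic means
of normalized linear-scale expression (treatment over control) and the
p-value comes from a two-sided unpaired t-test on the replicate values.  A
gene is called up when FC >= fc_up and p < alpha, down when FC <= fc_down
and p < alpha, otherwise unchanged.

Two built-in threshold presets reflect the two cut-off sets in circulation
for this kind of screen: ``figure`` (1.5 / 0.25) and ``methods``
(1.25 / 0.75), both with alpha 0.05.  ``figure`` is the default since the
headline transcript counts are derived from it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = ["DEThresholds", "DEResult", "fold_change", "unpaired_t_test", "classify_de", "de_table"]

PRESETS = {
    "figure": (1.5, 0.25, 0.05),
    "methods": (1.25, 0.75, 0.05),
}


@dataclass(frozen=True)
class DEThresholds:
    fc_up: float = 1.5
    fc_down: float = 0.25
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_up <= 1:
            raise ValueError("fc_up must be > 1")
        if not (0 < self.fc_down < 1):
            raise ValueError("fc_down must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def preset(cls, name: str) -> "DEThresholds":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(*PRESETS[name])


@dataclass(frozen=True)
class DEResult:
    gene: str
    timepoint: float
    fold_change: float
    log2_fc: float
    p_value: float
    call: str  # up | down | unchanged


def fold_change(m: ExpressionMatrix, gene: str, timepoint: float, treatment: str, control: str) -> float:
    """Ratio of arithmetic means, treatment over control, at one timepoint.

    A zero control mean yields ``inf`` (or ``nan`` when both means are zero)
    rather than raising, so callers see an explicit sentinel.
    """
    t_cols = m.samples_where(condition=treatment, timepoint=timepoint)
    c_cols = m.samples_where(condition=control, timepoint=timepoint)
    if not t_cols or not c_cols:
        raise ValueError(f"empty condition group at timepoint {timepoint}")
    t_mean = float(m.values.loc[gene, t_cols].mean())
    c_mean = float(m.values.loc[gene, c_cols].mean())
    if c_mean == 0:
        return math.nan if t_mean == 0 else math.inf
    return t_mean / c_mean


def unpaired_t_test(a, b, variant: str = "student") -> float:
    """Two-sided unpaired two-sample t-test p-value.

    ``student`` pools variances (the unmarked meaning of "unpaired t-test");
    ``welch`` drops the equal-variance assumption.  Degenerate zero-variance
    groups: equal means -> p = 1; unequal means -> p = 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 1.0
        warnings.warn("zero-variance groups with unequal means: degenerate p=0", RuntimeWarning, stacklevel=2)
        return 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)


def _call(fc: float, p: float, thr: DEThresholds) -> str:
    if p < thr.alpha and fc >= thr.fc_up:
        return "up"
    if p < thr.alpha and fc <= thr.fc_down:
        return "down"
    return "unchanged"


def classify_de(results: pd.DataFrame, thr: DEThresholds) -> list[DEResult]:
    """Classify per-gene FC/p rows (columns gene, timepoint, fold_change, p_value)."""
    out = []
    for r in results.itertuples():
        fc = float(r.fold_change)
        out.append(
            DEResult(
                gene=str(r.gene),
                timepoint=float(r.timepoint),
                fold_change=fc,
                log2_fc=math.log2(fc) if fc > 0 else -math.inf,
                p_value=float(r.p_value),
                call=_call(fc, float(r.p_value), thr),
            )
        )
    return out


def de_table(
    m: ExpressionMatrix,
    thr: DEThresholds,
    treatment: str | None = None,
    control: str | None = None,
    variant: str = "student",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full DE sweep: one row per gene x timepoint.

    Conditions default to the matrix's second (treatment) and first (control)
    declared conditions.  With ``bh_correct`` the calls use
    Benjamini-Hochberg adjusted p-values (raw p is the default, and the raw
    p-values are always reported).
    """
    conds = m.conditions
    if control is None:
        control = conds[0]
    if treatment is None:
        treatment = conds[1] if len(conds) > 1 else conds[0]

    rows = []
    for tp in m.timepoints:
        t_cols = m.samples_where(condition=treatment, timepoint=tp)
        c_cols = m.samples_where(condition=control, timepoint=tp)
        if not t_cols or not c_cols:
            continue
        for gene in m.present_genes():
            a = m.values.loc[gene, t_cols].to_numpy(dtype=float)
            b = m.values.loc[gene, c_cols].to_numpy(dtype=float)
            fc = fold_change(m, gene, tp, treatment, control)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = unpaired_t_test(a, b, variant=variant)
            rows.append({"gene": gene, "timepoint": tp, "fold_change": fc, "p_value": p})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no (treatment, control) pairs found at any timepoint")

    p_for_call = table["p_value"].to_numpy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p_for_call = multipletests(p_for_call, method="fdr_bh")[1]
        table["p_adj"] = p_for_call

    results = classify_de(
        table.assign(p_value=p_for_call)[["gene", "timepoint", "fold_change", "p_value"]], thr
    )
    table["log2_fc"] = [r.log2_fc for r in results]
    table["call"] = [r.call for r in results]
    cols = ["gene", "timepoint", "fold_change", "log2_fc", "p_value"]
    if bh_correct:
        cols.append("p_adj")
    return table[cols + ["call"]].rename(columns={"timepoint": "timepoint_hrs", "fold_change": "fc"})
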