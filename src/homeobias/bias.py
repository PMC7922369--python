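"""Differential expression and homeolog expression-bias classification.

This is the core of the pipeline: given replicated control/treatment
FPKM values and the homeolog components, decide per component whether a
stress response has diverged between homeologs.

DEG calling uses a 2-fold-change + p < 0.05 rule.  The fold change is
pseudocount-stabilized, log2((mean_t + c) / (mean_c + c)); the p-value
comes from a pooled-variance two-sample t-test on log2(FPKM + c) — a
transparent, replicate-honest default for FPKM matrices where counts
are unavailable (the test function is pluggable; Welch's t is provided
as an alternative).  Raw p-values are used by default, to
match the fixed p < 0.05 rule; Benjamini-Hochberg correction is
available via ``fdr=True``.

Component verdicts:

* ``removed``   — every member's mean FPKM over all samples is < 1
  (too weakly expressed to interpret).
* ``unchanged`` — no member differentially expressed.
* ``subfunctionalization_up`` / ``_down`` — every member DE, same
  direction: the homeologs share the response.
* ``neofunctionalization`` — at least one member DE and at least one
  not: the homeologs have diverged.
* ``divergent`` — all members DE but in mixed directions; the classic
  dichotomy does not cover this, so it is reported separately (and
  folded into neofunctionalization in the survey-style summary, where
  divergent response patterns are the operative signal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .components import HomeologComponent

BIAS_STATUSES = (
    "removed",
    "unchanged",
    "subfunctionalization_up",
    "subfunctionalization_down",
    "neofunctionalization",
    "divergent",
)


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) with a control/treatment design.

    ``design`` maps sample id -> (condition, replicate) with condition
    in {"control", "treatment"}.
    """

    values: pd.DataFrame
    design: dict[str, tuple[str, int]]

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if (self.values < 0).any().any():
            raise ValueError("negative FPKM values")
        for s in self.values.columns:
            if s not in self.design:
                raise ValueError(f"sample {s!r} missing from design")
            cond = self.design[s][0]
            if cond not in ("control", "treatment"):
                raise ValueError(f"sample {s!r}: bad condition {cond!r}")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s][0] == condition]


@dataclass(frozen=True)
class DEGResult:
    gene: str
    mean_control: float
    mean_treatment: float
    log2fc: float
    p_value: float
    call: str  # up | down | ns


def _guard_degenerate(lc: np.ndarray, lt: np.ndarray) -> float | None:
    # zero variance in both groups: identical means -> p = 1, else p = 0
    if lc.min() == lc.max() and lt.min() == lt.max():
        return 1.0 if lc[0] == lt[0] else 0.0
    return None


def pooled_log2_test(control: np.ndarray, treatment: np.ndarray,
                     pseudocount: float = 1.0) -> float:
    """Pooled-variance two-sample t-test on log2(FPKM + pseudocount).

    The default DE test: with equal-size replicate groups and
    approximately equal variance on the log scale (the usual situation
    for FPKM replicates), the pooled t is exact under the null, whereas
    Welch's Satterthwaite approximation is markedly conservative at
    n = 2-3 replicates.
    """
    lc = np.log2(control + pseudocount)
    lt = np.log2(treatment + pseudocount)
    p = _guard_degenerate(lc, lt)
    if p is not None:
        return p
    return float(stats.ttest_ind(lt, lc, equal_var=True).pvalue)


def welch_log2_test(control: np.ndarray, treatment: np.ndarray,
                    pseudocount: float = 1.0) -> float:
    """Welch's t-test on log2(FPKM + pseudocount); returns the p-value.

    Alternative to :func:`pooled_log2_test` for unequal-variance
    designs; conservative at minimal replicate counts.
    """
    lc = np.log2(control + pseudocount)
    lt = np.log2(treatment + pseudocount)
    p = _guard_degenerate(lc, lt)
    if p is not None:
        return p
    return float(stats.ttest_ind(lt, lc, equal_var=False).pvalue)


def call_deg(
    m: ExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    test=pooled_log2_test,
    fdr: bool = False,
) -> dict[str, DEGResult]:
    """Per-gene DEG calls: |log2FC| >= log2(fc) (inclusive) and p < alpha.

    Requires >= 2 replicates per condition.  With exactly 2 the t-test
    degrees of freedom are minimal and power is low; a warning is
    emitted but the analysis proceeds (two-replicate stress series are
    common in public wheat datasets).
    """
    ctrl = m.samples("control")
    trt = m.samples("treatment")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if len(ctrl) == 2 or len(trt) == 2:
        warnings.warn(
            "only 2 replicates in a condition: t-test df is minimal, power is low",
            stacklevel=2,
        )
    lfc_cut = math.log2(fc_threshold)
    genes = list(m.values.index)
    pvals = np.empty(len(genes))
    results: list[tuple[str, float, float, float]] = []
    for i, g in enumerate(genes):
        c = m.values.loc[g, ctrl].to_numpy(dtype=float)
        t = m.values.loc[g, trt].to_numpy(dtype=float)
        mc, mt = float(c.mean()), float(t.mean())
        lfc = math.log2((mt + pseudocount) / (mc + pseudocount))
        pvals[i] = test(c, t, pseudocount)
        results.append((g, mc, mt, lfc))
    if fdr:
        pvals = _bh_adjust(pvals)
    out: dict[str, DEGResult] = {}
    for (g, mc, mt, lfc), p in zip(results, pvals):
        if p < alpha and lfc >= lfc_cut:
            call = "up"
        elif p < alpha and lfc <= -lfc_cut:
            call = "down"
        else:
            call = "ns"
        out[g] = DEGResult(gene=g, mean_control=mc, mean_treatment=mt,
                           log2fc=lfc, p_value=float(p), call=call)
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj


@dataclass(frozen=True)
class BiasCall:
    component_id: str
    status: str
    member_calls: dict[str, str]


def classify_bias(
    component: HomeologComponent,
    degs: dict[str, DEGResult],
    m: ExpressionMatrix,
    fpkm_floor: float = 1.0,
    per_sample_floor: bool = False,
) -> BiasCall:
    """Classify one component's expression divergence.

    The removal filter drops components where every member's mean FPKM
    over all samples is below ``fpkm_floor`` (set ``per_sample_floor``
    to require every individual sample below the floor instead).
    """
    missing = [g for g in component.members if g not in degs or g not in m.values.index]
    if missing:
        raise ValueError(f"members missing from DEG/expression data: {missing}")
    if per_sample_floor:
        low = [bool((m.values.loc[g] < fpkm_floor).all()) for g in component.members]
    else:
        low = [float(m.values.loc[g].mean()) < fpkm_floor for g in component.members]
    calls = {g: degs[g].call for g in sorted(component.members)}
    if all(low):
        status = "removed"
    else:
        de = [c for c in calls.values() if c != "ns"]
        if not de:
            status = "unchanged"
        elif len(de) == len(calls):
            if all(c == "up" for c in de):
                status = "subfunctionalization_up"
            elif all(c == "down" for c in de):
                status = "subfunctionalization_down"
            else:
                status = "divergent"
        else:
            status = "neofunctionalization"
    return BiasCall(component_id=component.id, status=status, member_calls=calls)


def summarize_bias(
    calls_per_condition: dict[str, list[BiasCall]],
    condition_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Status counts per condition, plus pooled abiotic/biotic totals.

    ``condition_classes`` maps condition name -> "abiotic" | "biotic";
    pooled rows sum the per-condition counts (a component responding
    under two stresses counts once per stress).  The survey-style
    ``neofunctionalization_total`` column folds ``divergent`` into
    neofunctionalization; ``subfunctionalization_total`` sums both
    directions.
    """
    rows = []

    def _row(label: str, calls: list[BiasCall]) -> dict:
        counts = {s: 0 for s in BIAS_STATUSES}
        for c in calls:
            counts[c.status] += 1
        counts["subfunctionalization_total"] = (
            counts["subfunctionalization_up"] + counts["subfunctionalization_down"]
        )
        counts["neofunctionalization_total"] = (
            counts["neofunctionalization"] + counts["divergent"]
        )
        return {"condition": label, **counts}

    for cond in sorted(calls_per_condition):
        rows.append(_row(cond, calls_per_condition[cond]))
    if condition_classes:
        for cls in ("abiotic", "biotic"):
            pooled = [
                c
                for cond, calls in calls_per_condition.items()
                if condition_classes.get(cond) == cls
                for c in calls
            ]
            if pooled:
                rows.append(_row(f"pooled_{cls}", pooled))
    return pd.DataFrame(rows)
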