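"""Prevalence, trend tests and cross-wave comorbidity rates.

Prevalence is the proportion of subjects above the clinical cutoff at each
wave. The trend across waves is tested with a Pearson chi-square on the
waves x {flagged, not-flagged} contingency table, treating waves as
independent samples, with the contingency effect size
``eta = sqrt(chi2 / N_total)`` where ``N_total`` is the number of cells'
observations (waves x n). Comorbidity rates condition on the depressed
subjects at a wave and report the proportion also above the anxiety cutoff
at the same or a later wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import WAVES


@dataclass
class TrendTestResult:
    chi_square: float
    df: int
    p_value: float
    eta: float


def prevalence(scores: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-wave count and proportion of subjects flagged for *condition*.

    *condition* is ``"anxiety"`` or ``"depression"``; *scores* is the
    output of :func:`clpntraj.panel.score_panel`.
    """
    flag = {"anxiety": "anxious", "depression": "depressed"}[condition]
    if scores.empty:
        raise ValueError("empty score table")
    grouped = scores.groupby(level="wave")[flag]
    out = pd.DataFrame({"count": grouped.sum().astype(int), "n": grouped.size()})
    out["proportion"] = out["count"] / out["n"]
    return out


def trend_chi_square(counts, n_per_wave: int) -> TrendTestResult:
    """Pearson chi-square for a change in the flagged proportion across waves.

    *counts* are the flagged counts per wave out of *n_per_wave* subjects
    each. Expected counts come from the pooled proportion (homogeneity
    null); no continuity correction. df = waves - 1.
    """
    counts = np.asarray(counts, int)
    if np.any(counts > n_per_wave) or np.any(counts < 0):
        raise ValueError("counts must lie in [0, n_per_wave]")
    table = np.column_stack([counts, n_per_wave - counts])
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate table: a column has zero total")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    eta = float(np.sqrt(chi2 / table.sum()))
    return TrendTestResult(chi_square=float(chi2), df=int(df), p_value=float(p), eta=eta)


def comorbidity_rates(scores: pd.DataFrame) -> pd.DataFrame:
    """P(anxious at wave s | depressed at wave t) for every pair s >= t.

    Returns a DataFrame with columns ``depressed_wave``, ``anxiety_wave``,
    ``n_depressed``, ``n_comorbid``, ``proportion``; the proportion is NaN
    (flagged missing) when nobody is depressed at wave t.
    """
    dep = scores["depressed"].unstack("wave")
    anx = scores["anxious"].unstack("wave")
    rows = []
    for t in WAVES:
        base = dep[t]
        n_dep = int(base.sum())
        for s in WAVES:
            if s < t:
                continue
            n_co = int((base & anx[s]).sum())
            rows.append(
                {
                    "depressed_wave": t,
                    "anxiety_wave": s,
                    "n_depressed": n_dep,
                    "n_comorbid": n_co,
                    "proportion": n_co / n_dep if n_dep else np.nan,
                }
            )
    return pd.DataFrame(rows)
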