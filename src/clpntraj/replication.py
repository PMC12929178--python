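"""Replicability of two lagged networks over the same node set.

Compares an earlier and a later cross-lagged network (e.g. waves 1->2
versus waves 2->3) on three aspects: correlation of edge weights, the
percentage of edges replicated in both networks, and the correlation of
expected-influence centralities. Edge summaries are computed on the
odds-ratio scale; an edge is "present" when its coefficient survived the
penalty (OR != 1).

Support conventions (configurable): the "all" and "cross-lagged" rows use
the union of the two networks' supports (an edge absent in one network
enters as OR = 1), the "autoregressive" row uses all 16 diagonal entries,
and the "replicated" row the intersection of supports. Counts and
percentages are reported per network, percentages relative to that
network's total edge count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import CLPNetwork, edge_or
from .stability import _raw_ei

SUBSETS = ("all", "autoregressive", "cross_lagged", "replicated")


@dataclass
class ReplicabilityReport:
    table: pd.DataFrame
    edge_counts: tuple[int, int]
    replicated_count: int
    pct_replicated: tuple[float, float]
    centrality: dict[str, tuple[float, float]]   # index -> (r, p)

    def correlation(self, subset: str) -> float:
        return float(self.table.loc[(subset, "all"), "r"])


def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_networks(
    net_a: CLPNetwork,
    net_b: CLPNetwork,
    support: str = "union",
    scale: str = "or",
) -> ReplicabilityReport:
    """Tabulate similarity between two fitted networks.

    ``support="union"`` correlates over entries present in at least one
    network ("all" / "cross-lagged" rows); ``support="all256"`` uses every
    matrix entry. ``scale`` is ``"or"`` (odds ratios) or ``"logodds"``.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks must share node set and order")
    if support not in ("union", "all256"):
        raise ValueError("support must be 'union' or 'all256'")
    p = len(net_a.nodes)
    ea, eb = edge_or(net_a), edge_or(net_b)
    va, vb = (np.log(ea), np.log(eb)) if scale == "logodds" else (ea, eb)
    absent = 0.0 if scale == "logodds" else 1.0
    pres_a, pres_b = net_a.b != 0, net_b.b != 0
    diag = np.eye(p, dtype=bool)
    union, inter = pres_a | pres_b, pres_a & pres_b
    edges_a, edges_b = int(pres_a.sum()), int(pres_b.sum())

    # (region for r, region for per-network stats)
    corr_region = {
        "all": union if support == "union" else np.ones_like(diag),
        "autoregressive": diag,
        "cross_lagged": (union & ~diag) if support == "union" else ~diag,
        "replicated": inter,
    }
    stat_region = {
        "all": (pres_a, pres_b),
        "autoregressive": (pres_a & diag, pres_b & diag),
        "cross_lagged": (pres_a & ~diag, pres_b & ~diag),
        "replicated": (inter, inter),
    }

    rows = []
    for subset in SUBSETS:
        mask_r = corr_region[subset]
        r, pval = _corr(va[mask_r], vb[mask_r])
        for sign in ("all", "or_gt_1", "or_lt_1"):
            row = {"subset": subset, "sign": sign,
                   "r": r if sign == "all" else np.nan,
                   "p": pval if sign == "all" else np.nan}
            for tag, (region, vals, total) in (
                ("a", (stat_region[subset][0], va, edges_a)),
                ("b", (stat_region[subset][1], vb, edges_b)),
            ):
                m = region.copy()
                if sign == "or_gt_1":
                    m &= vals > absent
                elif sign == "or_lt_1":
                    m &= vals < absent
                sel = vals[m]
                row[f"count_{tag}"] = int(m.sum())
                row[f"pct_{tag}"] = 100.0 * m.sum() / total if total else np.nan
                row[f"mean_{tag}"] = float(sel.mean()) if sel.size else np.nan
                row[f"sd_{tag}"] = float(sel.std(ddof=1)) if sel.size > 1 else np.nan
            rows.append(row)
    table = pd.DataFrame(rows).set_index(["subset", "sign"])

    in_a, out_a = _raw_ei(net_a.b)
    in_b, out_b = _raw_ei(net_b.b)
    centrality = {"in": _corr(in_a, in_b), "out": _corr(out_a, out_b)}
    n_rep = int(inter.sum())
    return ReplicabilityReport(
        table=table,
        edge_counts=(edges_a, edges_b),
        replicated_count=n_rep,
        pct_replicated=(
            100.0 * n_rep / edges_a if edges_a else np.nan,
            100.0 * n_rep / edges_b if edges_b else np.nan,
        ),
        centrality=centrality,
    )
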