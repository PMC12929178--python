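"""End-to-end study pipeline: panel -> descriptives -> trajectory classes ->
per-class lagged networks -> stability -> replicability.

A single :class:`RunConfig` drives every stage; one master seed feeds
deterministic per-stage child seeds, so reruns with the same config are
byte-identical. Per trajectory class, networks are fit on the subjects
modally assigned to it (both wave pairs) provided the class reaches the
minimum size floor; smaller classes are recorded as skipped, since lagged
networks on a few hundred subjects are too unstable to interpret.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comorbidity as desc
from .network import density, expected_influence, fit_clpn, network_frame
from .panel import BinaryPanel, binarize, read_panel, score_panel, write_panel
from .replication import compare_networks
from .simulate import GrowthMixtureConfig, generate_growth_mixture
from .stability import case_drop_stability
from .trajectories import enumerate_classes, growth_matrix

logger = logging.getLogger("clpntraj")

#: networks below this class size are skipped (instability floor)
DEFAULT_CLASS_FLOOR = 200
#: below this size a fitted network is flagged as potentially unstable
STABILITY_WARN_N = 1000


@dataclass
class RunConfig:
    out_dir: str
    input_csv: str | None = None
    covariates: tuple[str, ...] = ()
    simulation: GrowthMixtureConfig | None = None
    cutoff: int = 7
    k_max: int = 4
    n_restarts: int = 10
    blrt_reps: int = 0
    folds: int = 10
    lambda_rule: str = "min"
    case_drop_boots: int = 0
    class_floor: int = DEFAULT_CLASS_FLOOR
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if k == "covariates" else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulation = GrowthMixtureConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            )
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_floats(obj, nd=6):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest.

    The manifest lists each written artifact with a content hash, the
    per-stage seeds, and a compact result summary (also written to
    ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    artifacts: dict[str, str] = {}
    summary: dict = {"seed": int(config.seed)}

    def save_df(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, **kw)
        artifacts[name] = _sha256(path)

    # --- stage 1: ingest or simulate -------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=int(seeds[0]))
        panel, labels = generate_growth_mixture(sim)
        save_df(pd.DataFrame({"true_class": labels}), "true_classes.csv", index_label="subject_id")
        covariates = list(panel.covariates.columns)
    elif config.input_csv is not None:
        covariates = list(config.covariates)
        panel = read_panel(config.input_csv, covariates=covariates)
    else:
        raise ValueError("config must provide input_csv or simulation")
    if config.covariates:
        covariates = list(config.covariates)
    summary["n_subjects"] = panel.n_subjects
    write_panel(panel, out / "panel.csv")
    artifacts["panel.csv"] = _sha256(out / "panel.csv")

    # --- stage 2: scoring and descriptives --------------------------------
    scores = score_panel(panel, cutoff=config.cutoff)
    described = {}
    for cond in ("anxiety", "depression"):
        prev = desc.prevalence(scores, cond)
        trend = desc.trend_chi_square(prev["count"].to_numpy(), panel.n_subjects)
        described[cond] = {
            "counts": prev["count"].tolist(),
            "proportions": prev["proportion"].tolist(),
            "chi_square": trend.chi_square,
            "df": trend.df,
            "p_value": trend.p_value,
            "eta": trend.eta,
        }
    described["comorbidity"] = desc.comorbidity_rates(scores).to_dict("records")
    summary["descriptives"] = described

    # --- stage 3: trajectory classes --------------------------------------
    table, fits = enumerate_classes(
        scores, k_max=config.k_max, n_restarts=config.n_restarts,
        seed=int(seeds[1]), blrt_reps=config.blrt_reps,
    )
    save_df(table, "enumeration.csv")
    k_best = int(table["BIC"].idxmin())
    sol = fits[k_best]
    save_df(pd.DataFrame({"assigned_class": sol.assignments}), "assignments.csv",
            index_label="subject_id")
    summary["classes"] = {
        "selected_k": k_best,
        "bic": sol.bic,
        "entropy": sol.entropy,
        "proportions": sol.pi.tolist(),
        "means": sol.means.tolist(),
    }

    # --- stage 4: per-class networks, stability, replicability ------------
    bpanel = binarize(panel)
    subjects = np.asarray(panel.subjects)
    summary["networks"] = {}
    for k in range(sol.k):
        members = subjects[sol.assignments == k]
        tag = f"class{k + 1}"
        if len(members) < config.class_floor:
            logger.warning("%s has n=%d < floor %d: networks skipped",
                           tag, len(members), config.class_floor)
            summary["networks"][tag] = {"n": int(len(members)), "skipped": True}
            continue
        if len(members) < STABILITY_WARN_N:
            logger.warning("%s has n=%d < %d: expect unstable centralities",
                           tag, len(members), STABILITY_WARN_N)
        sub = BinaryPanel(items=bpanel.items.loc[members], covariates=bpanel.covariates)
        info: dict = {"n": int(len(members)), "skipped": False}
        nets = {}
        for wp in ((1, 2), (2, 3)):
            net = fit_clpn(sub, wp, covariates=covariates, folds=config.folds,
                           seed=int(seeds[2]), lambda_rule=config.lambda_rule)
            nets[wp] = net
            wp_tag = f"{tag}_t{wp[0]}{wp[1]}"
            save_df(network_frame(net, "logodds"), f"net_{wp_tag}_logodds.csv")
            save_df(network_frame(net, "or"), f"net_{wp_tag}_or.csv")
            ei = expected_influence(net)
            save_df(ei, f"centrality_{wp_tag}.csv")
            n_edges, n_cross, dens = density(net)
            info[f"t{wp[0]}{wp[1]}"] = {
                "n_edges": n_edges, "n_cross_lagged": n_cross, "density": dens,
                "influential": ei.index[ei["influential"]].tolist(),
            }
            if config.case_drop_boots > 0:
                cs = case_drop_stability(
                    sub, wp, n_per_prop=config.case_drop_boots,
                    seed=int(seeds[3]), covariates=covariates, net=net,
                )
                info[f"t{wp[0]}{wp[1]}"]["cs"] = cs.cs
        rep = compare_networks(nets[(1, 2)], nets[(2, 3)])
        save_df(rep.table, f"replication_{tag}.csv")
        info["replication"] = {
            "edge_counts": rep.edge_counts,
            "replicated": rep.replicated_count,
            "pct_replicated": rep.pct_replicated,
            "r_all": rep.correlation("all"),
            "r_replicated": rep.correlation("replicated"),
            "centrality": rep.centrality,
        }
        summary["networks"][tag] = info

    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, allow_nan=True))
    artifacts["summary.json"] = _sha256(out / "summary.json")
    manifest = {"config_seed": int(config.seed),
                "stage_seeds": [int(s) for s in seeds],
                "artifacts": artifacts,
                "summary": summary}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
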