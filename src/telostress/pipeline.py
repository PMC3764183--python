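"""End-to-end orchestration: fixture generation, config validation, run-all.

A study directory holds every input the stages read (expression TSVs, an
edge list, a TLM gene list, per-stress screen tables, lane profiles, a ChIP
table) plus a YAML config and — for synthetic studies — a ground-truth
manifest. `run_all` executes the stages in dependency order (telquant ->
screen; expression -> sets -> proximity; chip independent) and writes one
provenance-headed TSV per stage plus a human-readable report. All outputs
are deterministic in the configured seeds.
"""

from __future__ import annotations

import logging
import os
import sys

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import synthetic_data as syn
from .chip_quant import relative_change, summarize_replicates
from .expression_de import extract_de, stress_specific_sets
from .network_proximity import load_network, proximity_test, specificity_control
from .responsiveness_screen import call_outliers, pearson, robust_fit
from .telquant import calibrate, delta_length, estimate_length

__all__ = ["make_fixtures", "validate_config", "run_all", "load_config"]

log = logging.getLogger("telostress")

#: stress panel of the synthetic study: label -> (telomere effect direction,
#: screen slope, screen intercept bp, lane fragment size bp)
STRESS_PANEL = {
    "ethanol": ("elongating", 0.45, -20.0, 1400.0),
    "caffeine": ("shortening", -0.45, 40.0, 1150.0),
    "temp37": ("shortening", -0.70, 70.0, 1100.0),
    "h2o2": ("neutral", 0.0, 0.0, 1250.0),
}
CONTROL_SIZE_BP = 1250.0


def _setup_logging(level: str = "INFO") -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
        log.addHandler(h)
    log.setLevel(level.upper())


def _stage_log(stage: str):
    return logging.LoggerAdapter(log, {"stage": stage})


def make_fixtures(seed: int = 0, out_dir: str = "fixtures") -> dict:
    """Write a complete synthetic study directory plus a truth manifest.

    The study is internally coherent: the network's planted proximal module
    consists of genes planted as ethanol-specific DE in the expression data
    and flagged TLM, so the full pipeline (SAM -> specific sets -> proximity)
    can rediscover it. Additional ethanol-specific DE genes are scattered on
    the network as non-TLM nodes for the specificity control. Returns the
    path map, including the ready-to-run config.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    stresses = list(STRESS_PANEL)

    # --- expression ---------------------------------------------------------
    bundle, expr_truth = syn.gen_expression(
        stresses=stresses, seed=int(seed) % 2**31
    )
    expr_paths = tio.write_expression_bundle(bundle, out_dir)

    # --- network: planted module = ethanol-specific planted DE genes --------
    net, net_truth = syn.gen_network(seed=(seed + 1) % 2**31, stress="ethanol")
    de = expr_truth.de_genes_per_stress
    ethanol_specific = sorted(
        de["ethanol"] - set().union(*(de[s] for s in de if s != "ethanol"))
    )
    never_de = sorted(set(bundle.matrix.index) - set().union(*de.values()))
    planted_nodes = sorted(net_truth.planted_proximal_set)
    other_tlm_nodes = sorted(net.tlm - net_truth.planted_proximal_set)
    plain_nodes = sorted(net.nodes - net.tlm)

    if len(ethanol_specific) < len(planted_nodes) + 15:
        raise ValueError("too few ethanol-specific planted genes to build the network")
    planted_genes = ethanol_specific[: len(planted_nodes)]
    scattered_de_genes = ethanol_specific[
        len(planted_nodes) : len(planted_nodes) + 15
    ]
    quiet_pool = list(rng.permutation(never_de))

    mapping = dict(zip(planted_nodes, planted_genes))
    mapping.update(zip(other_tlm_nodes, quiet_pool))  # TLM, never DE
    quiet_rest = quiet_pool[len(other_tlm_nodes) :]
    scatter_targets = list(rng.permutation(plain_nodes))
    mapping.update(zip(scatter_targets[: len(scattered_de_genes)], scattered_de_genes))
    remaining_nodes = scatter_targets[len(scattered_de_genes) :]
    leftover_genes = sorted(
        set(bundle.matrix.index) - set(mapping.values())
    )
    mapping.update(zip(remaining_nodes, rng.permutation(leftover_genes)))

    import networkx as nx

    relabeled = nx.relabel_nodes(net.graph, mapping)
    tlm_genes = {mapping[n] for n in net.tlm}
    edge_path = os.path.join(out_dir, "network_edges.tsv")
    tlm_path = os.path.join(out_dir, "tlm_genes.txt")
    tio.write_edge_list(relabeled, edge_path, tio.provenance_header("make-fixtures", seed=seed))
    tio.write_gene_set(tlm_genes, tlm_path)

    # --- screens (no screen for the neutral stress: no length change) -------
    screen_paths = {}
    screen_outliers = {}
    for i, stress in enumerate(s for s in stresses if STRESS_PANEL[s][0] != "neutral"):
        _, slope, intercept, _ = STRESS_PANEL[stress]
        screen, truth_s = syn.gen_screen(
            slope=slope,
            intercept=intercept,
            seed=(seed + 10 + i) % 2**31,
            stress=stress,
        )
        p = os.path.join(out_dir, f"screen_{stress}.tsv")
        tio.write_screen_table(
            screen, p, tio.provenance_header("make-fixtures", seed=seed, stress=stress)
        )
        screen_paths[stress] = p
        screen_outliers[stress] = truth_s.screen_outliers

    # --- lanes ---------------------------------------------------------------
    lane_paths = {}
    true_sizes = {"control": CONTROL_SIZE_BP}
    true_sizes.update({s: STRESS_PANEL[s][3] for s in stresses})
    for i, (lane, size) in enumerate(true_sizes.items()):
        profile = syn.gen_lane(
            true_size=size, noise_sd=2.0, seed=(seed + 20 + i) % 2**31
        )
        prof_path = os.path.join(out_dir, f"lane_{lane}.csv")
        marker_path = os.path.join(out_dir, f"lane_{lane}_markers.txt")
        tio.write_lane_profile(profile, prof_path, marker_path)
        lane_paths[lane] = {"profile": prof_path, "markers": marker_path}

    # --- ChIP ----------------------------------------------------------------
    stress_meas, control_meas = syn.gen_chip_counts(seed=(seed + 30) % 2**31)
    chip_path = os.path.join(out_dir, "chip.tsv")
    tio.write_chip_table(
        stress_meas + control_meas, chip_path, tio.provenance_header("make-fixtures", seed=seed)
    )

    # --- truth manifest ------------------------------------------------------
    truth = {
        "seed": seed,
        "planted_proximal_set": set(planted_genes),
        "scattered_de_non_tlm": set(scattered_de_genes),
        "chip_true_fold": 0.5,
    }
    for s in stresses:
        truth[f"de_genes.{s}"] = expr_truth.de_genes_per_stress[s]
    for s, outliers in screen_outliers.items():
        truth[f"screen_outliers.{s}"] = outliers
        truth[f"screen_slope.{s}"] = STRESS_PANEL[s][1]
        truth[f"screen_intercept.{s}"] = STRESS_PANEL[s][2]
    for lane, size in true_sizes.items():
        truth[f"fragment_size.{lane}"] = size
    truth_path = os.path.join(out_dir, "truth.txt")
    tio.write_key_value(truth, truth_path)

    # --- ready-to-run config --------------------------------------------------
    directions = {
        "elongating": [s for s in stresses if STRESS_PANEL[s][0] == "elongating"],
        "shortening": [s for s in stresses if STRESS_PANEL[s][0] == "shortening"],
        "neutral": [s for s in stresses if STRESS_PANEL[s][0] == "neutral"],
    }
    config = {
        "out_dir": os.path.join(out_dir, "results"),
        "telquant": {
            "lanes": lane_paths,
            "control_lane": "control",
            "threshold_fraction": 0.2,
            "background_quantile": 0.1,
        },
        "expression": {
            "matrix": expr_paths["matrix"],
            "calls": expr_paths["calls"],
            "groups": expr_paths["groups"],
            "control": "control",
            "n_perm": 200,
            "fdr_threshold": 0.01,
            "seed": (seed + 40) % 2**31,
        },
        "sets": {"direction_groups": directions},
        "proximity": {
            "edge_list": edge_path,
            "tlm_list": tlm_path,
            "b_definition": "other_tlm",
        },
        "screen": {
            "tables": screen_paths,
            "alpha": 0.05,
            "directions": {
                s: STRESS_PANEL[s][0]
                for s in screen_paths
            },
        },
        "chip": {"table": chip_path, "control_condition": "control"},
    }
    config_path = os.path.join(out_dir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    return {
        "config": config_path,
        "truth": truth_path,
        **expr_paths,
        "edge_list": edge_path,
        "tlm_list": tlm_path,
        "chip": chip_path,
        "screens": screen_paths,
        "lanes": lane_paths,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


_REQUIRED = {
    "telquant": ["lanes", "control_lane"],
    "expression": ["matrix", "calls", "groups", "control", "seed"],
    "sets": ["direction_groups"],
    "proximity": ["edge_list", "tlm_list"],
    "screen": ["tables", "directions"],
    "chip": ["table", "control_condition"],
}


def validate_config(config: dict) -> None:
    """Check schema and that every referenced input path exists, before any stage runs."""
    if "out_dir" not in config:
        raise ValueError("config field missing: out_dir")
    for stage, fields in _REQUIRED.items():
        if stage not in config:
            raise ValueError(f"config field missing: {stage}")
        for f in fields:
            if f not in config[stage]:
                raise ValueError(f"config field missing: {stage}.{f}")

    def check(field: str, path) -> None:
        if not os.path.exists(path):
            raise ValueError(f"config field {field}: path does not exist: {path}")

    for lane, entry in config["telquant"]["lanes"].items():
        check(f"telquant.lanes.{lane}.profile", entry["profile"])
        check(f"telquant.lanes.{lane}.markers", entry["markers"])
    for f in ("matrix", "calls", "groups"):
        check(f"expression.{f}", config["expression"][f])
    check("proximity.edge_list", config["proximity"]["edge_list"])
    check("proximity.tlm_list", config["proximity"]["tlm_list"])
    for stress, path in config["screen"]["tables"].items():
        check(f"screen.tables.{stress}", path)
    check("chip.table", config["chip"]["table"])


def run_all(config: dict, log_level: str = "INFO") -> dict:
    """Run every stage in dependency order; return a summary dict.

    Writes per-stage TSVs and `report.txt` under config['out_dir']. Any stage
    error propagates with the stage name attached.
    """
    _setup_logging(log_level)
    validate_config(config)
    out_dir = config["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    summary: dict = {}
    report: list[str] = []

    def run_stage(name, fn):
        slog = _stage_log(name)
        slog.info("starting")
        try:
            result = fn(slog)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        slog.info("done")
        return result

    # --- telquant -------------------------------------------------------------
    def stage_telquant(slog):
        cfg = config["telquant"]
        rows = []
        estimates = {}
        for lane, entry in cfg["lanes"].items():
            profile = tio.read_lane_profile(entry["profile"], entry["markers"])
            calib = calibrate(profile.marker_positions, profile.marker_sizes)
            est = estimate_length(
                profile,
                calib,
                threshold_fraction=cfg.get("threshold_fraction", 0.2),
                background_quantile=cfg.get("background_quantile", 0.1),
            )
            estimates[lane] = est
            rows.append(
                {
                    "lane": lane,
                    "length_bp": round(est.length, 3),
                    "smear_lo": round(est.smear_lo, 3),
                    "smear_hi": round(est.smear_hi, 3),
                }
            )
        control = estimates[cfg["control_lane"]]
        for row in rows:
            row["delta_bp"] = round(delta_length(estimates[row["lane"]], control), 3)
        df = pd.DataFrame(rows)
        path = os.path.join(out_dir, "telomere_lengths.tsv")
        with open(path, "w") as fh:
            fh.write(tio.provenance_header("telquant", **{
                "threshold_fraction": cfg.get("threshold_fraction", 0.2),
                "background_quantile": cfg.get("background_quantile", 0.1),
            }))
            df.to_csv(fh, sep="\t", index=False)
        slog.info("sized %d lanes", len(rows))
        return {"table": df, "estimates": estimates}

    summary["telquant"] = run_stage("telquant", stage_telquant)

    # --- screen ---------------------------------------------------------------
    def stage_screen(slog):
        cfg = config["screen"]
        alpha = cfg.get("alpha", 0.05)
        out = {}
        for stress, path in cfg["tables"].items():
            screen = tio.read_screen_table(path, stress=stress)
            t = screen.table
            fit = robust_fit(t["initial"], t["delta"])
            corr = pearson(t["initial"], t["delta"])
            calls = call_outliers(
                fit,
                alpha=alpha,
                stress_direction=cfg["directions"][stress],
                mutants=t["mutant"],
            )
            res_path = os.path.join(out_dir, f"screen_{stress}_calls.tsv")
            with open(res_path, "w") as fh:
                fh.write(tio.provenance_header(
                    "screen",
                    stress=stress,
                    slope=f"{fit.slope:.6f}",
                    intercept=f"{fit.intercept:.6f}",
                    scale=f"{fit.scale:.6f}",
                    r=f"{corr.r:.4f}",
                    p=f"{corr.p:.3e}",
                    alpha=alpha,
                ))
                ct = calls.table.copy()
                ct["z"] = ct["z"].round(4)
                ct.to_csv(fh, sep="\t", index=False)
            slog.info(
                "%s: slope=%.3f r=%.3f flagged=%d/%d",
                stress, fit.slope, corr.r, int(calls.table["flagged"].sum()), len(t),
            )
            out[stress] = {"fit": fit, "pearson": corr, "calls": calls}
        return out

    summary["screen"] = run_stage("screen", stage_screen)

    # --- expression + sets ----------------------------------------------------
    def stage_expression(slog):
        cfg = config["expression"]
        bundle = tio.read_expression_bundle(cfg["matrix"], cfg["calls"], cfg["groups"])
        results = extract_de(
            bundle,
            control=cfg.get("control", "control"),
            n_perm=cfg.get("n_perm", 200),
            fdr_threshold=cfg.get("fdr_threshold", 0.01),
            seed=cfg["seed"],
        )
        de = {s: set(r.significant) for s, r in results.items()}
        for s, r in results.items():
            slog.info("%s: %d DE genes (s0=%.4f)", s, len(r.significant), r.s0)
        return {"results": results, "de": de}

    summary["expression"] = run_stage("expression", stage_expression)

    def stage_sets(slog):
        de = summary["expression"]["de"]
        sets = stress_specific_sets(de, config["sets"].get("direction_groups"))
        for s, genes in sorted(sets.de.items()):
            tio.write_gene_set(genes, os.path.join(out_dir, f"de_{s}.txt"))
        tio.write_gmt(
            {f"specific_{s}": g for s, g in sets.specific.items()},
            os.path.join(out_dir, "specific_sets.gmt"),
            description="stress-specific DE",
        )
        if sets.direction_specific:
            tio.write_gmt(
                {f"direction_{d}": g for d, g in sets.direction_specific.items()},
                os.path.join(out_dir, "direction_sets.gmt"),
                description="direction-specific DE",
            )
        slog.info(
            "specific set sizes: %s",
            {s: len(g) for s, g in sorted(sets.specific.items())},
        )
        return sets

    summary["sets"] = run_stage("sets", stage_sets)

    # --- proximity ------------------------------------------------------------
    def stage_proximity(slog):
        cfg = config["proximity"]
        sets = summary["sets"]
        net = load_network(cfg["edge_list"], cfg["tlm_list"], sets)
        rows = []
        results = {}
        for stress in sorted(sets.de):
            for kind, test in (
                ("proximity", lambda s: proximity_test(
                    net, s, b_definition=cfg.get("b_definition", "other_tlm"))),
                ("specificity_control", lambda s: specificity_control(net, s)),
            ):
                try:
                    res = test(stress)
                except ValueError as exc:
                    slog.info("%s %s skipped: %s", stress, kind, exc)
                    rows.append({"stress": stress, "test": kind, "n_a": 0, "n_b": 0,
                                 "statistic": "", "p": "", "excluded_pairs": "",
                                 "note": str(exc)})
                    continue
                rows.append({
                    "stress": stress, "test": kind,
                    "n_a": len(res.dist_a), "n_b": len(res.dist_b),
                    "statistic": f"{res.statistic:.1f}", "p": f"{res.p:.4e}",
                    "excluded_pairs": res.n_excluded_pairs, "note": "",
                })
                results[(stress, kind)] = res
                slog.info("%s %s: p=%.3e", stress, kind, res.p)
        path = os.path.join(out_dir, "proximity.tsv")
        with open(path, "w") as fh:
            fh.write(tio.provenance_header(
                "proximity", b_definition=cfg.get("b_definition", "other_tlm")))
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
        return {"results": results, "table": pd.DataFrame(rows)}

    summary["proximity"] = run_stage("proximity", stage_proximity)

    # --- chip -----------------------------------------------------------------
    def stage_chip(slog):
        cfg = config["chip"]
        measurements = tio.read_chip_table(cfg["table"])
        by_cond: dict = {}
        for m in measurements:
            by_cond.setdefault(m.condition, []).append(m)
        control_label = cfg["control_condition"]
        if control_label not in by_cond:
            raise ValueError(f"no measurements for control condition {control_label!r}")
        summaries = {c: summarize_replicates(ms) for c, ms in by_cond.items()}
        rows = []
        for cond in sorted(summaries):
            s = summaries[cond]
            rel = relative_change(s, summaries[control_label])
            rows.append({
                "condition": cond, "fold": round(s.fold, 4),
                "log2_fold": round(s.log2_fold, 4), "spread": round(s.spread, 4),
                "n": s.n_replicates, "relative_to_control": round(rel, 4),
            })
            slog.info("%s: fold=%.3f relative=%.3f", cond, s.fold, rel)
        df = pd.DataFrame(rows)
        path = os.path.join(out_dir, "chip_enrichment.tsv")
        with open(path, "w") as fh:
            fh.write(tio.provenance_header("chip", control=control_label))
            df.to_csv(fh, sep="\t", index=False)
        return {"table": df, "summaries": summaries}

    summary["chip"] = run_stage("chip", stage_chip)

    # --- report ---------------------------------------------------------------
    report.append("telostress pipeline report")
    report.append("==========================")
    report.append("")
    report.append("[telquant]")
    report.append(summary["telquant"]["table"].to_string(index=False))
    report.append("")
    report.append("[screen]")
    for stress, r in summary["screen"].items():
        fit, corr = r["fit"], r["pearson"]
        n_flag = int(r["calls"].table["flagged"].sum())
        report.append(
            f"  {stress}: slope={fit.slope:.3f} intercept={fit.intercept:.1f} "
            f"r={corr.r:.3f} (p={corr.p:.2e}) flagged={n_flag}"
        )
    report.append("")
    report.append("[expression]")
    for stress, r in summary["expression"]["results"].items():
        report.append(f"  {stress}: {len(r.significant)} DE genes at "
                      f"FDR<{r.fdr_threshold} (s0={r.s0:.4f}, {r.n_perm} permutations)")
    report.append("")
    report.append("[proximity]")
    report.append(summary["proximity"]["table"].to_string(index=False))
    report.append("")
    report.append("[chip]")
    report.append(summary["chip"]["table"].to_string(index=False))
    report.append("")
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        fh.write("\n".join(report))
    return summary
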