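"""End-to-end pipeline stages over a working directory.

Each stage reads the fixture and/or earlier stage outputs from a
working directory and writes plain TSV/JSON outputs plus an updated
YAML run manifest, so stages can be run one by one (via the CLI) or all
at once with :func:`run_all`.  All randomness derives from the single
global seed; the manifest records every derived seed, all thresholds
and the SHA-256 digest of every file written.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import kruskal_wallis_screen
from .signature import BorutaConsensus, build_signature_table
from .splicing import delta_psi, export_signature_bed, filter_events
from .survival import km_curve, survival_contrast, to_years
from .synthetic import Cohort, CohortConfig, generate_cohort, read_fixture, write_fixture
from .transfer import importance_trajectory, run_transfer, scale_per_domain
from .validation import segregation_accuracy, tsne_embed

__all__ = ["DEFAULT_CONFIG", "run_all", "load_config", "STAGES"]

DEFAULT_CONFIG: dict[str, Any] = {
    "cohort": {},  # CohortConfig field overrides; empty = package defaults
    "screen": {
        # alpha differs between published screens (1e-3 heatmaps, 1e-5
        # general, 1e-9 RBPs): it must be stated, never defaulted silently.
        "alpha": 1.0e-3,
        "min_total": 10,
        "per_sample": False,
        "n_draws": 10_000,
        "delta_threshold": 0.1,
        "prob_threshold": 0.95,
    },
    "transfer": {
        "feature_mode": "splicing",      # splicing | expression | mixed
        "n_estimators": 1000,
        "prob_high": 0.6,
        "prob_low": 0.4,
        "per_round_cap_base": 10,
        "max_rounds": 50,
        "cap_mode": "per_round",
        "probability": "mean_leaf",
    },
    "signature": {
        "n_runs": 10,
        "min_hits": 7,
        "n_estimators": 1000,
        "max_iter": 50,
        "alpha": 0.05,
        "perc": 100.0,
        "count_tentative": False,
        "training": "cells_plus_admitted",  # or cells_only
    },
    "validate": {
        "perplexity": 20.0,
        "holdout_n_cell_a": 28,
        "holdout_n_cell_b": 27,
    },
    "survival": {
        "truncation_years": 5.0,
        "time_unit": "years",  # 'days' inputs are converted on ingest
    },
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the defaults (per-stage shallow merge)."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for stage, values in user.items():
            if stage not in cfg:
                raise ValueError(f"unknown config section '{stage}'")
            if not isinstance(values, dict):
                raise ValueError(f"config section '{stage}' must be a mapping")
            cfg[stage].update(values)
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream of the global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _update_manifest(wd: Path, stage: str, info: dict, outputs: list[Path]) -> None:
    mpath = wd / "manifest.yaml"
    manifest = yaml.safe_load(mpath.read_text()) if mpath.exists() else {}
    manifest.setdefault("version", __version__)
    manifest.setdefault("stages", {})
    manifest["stages"][stage] = {
        **info,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))


def _cell_groups(cohort: Cohort) -> dict[str, list[str]]:
    ann = cohort.annotation
    cells = ann[ann["domain"] == "cell_line"]
    groups = {lab: list(cells.index[cells["subtype"] == lab]) for lab in sorted(cells["subtype"].unique())}
    if len(groups) != 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError("expected exactly two non-empty cell-line subtype groups")
    return groups


# ------------------------------------------------------------------ stages


def stage_simulate(config: dict, wd: Path, seed: int) -> Cohort:
    t0 = time.perf_counter()
    cohort_cfg = CohortConfig(**config["cohort"], seed=_stage_seed(seed, "simulate"))
    cohort = generate_cohort(cohort_cfg)
    fx = wd / "fixture"
    write_fixture(cohort, fx)
    _update_manifest(
        wd, "simulate",
        {"config": {**config["cohort"], "seed": cohort_cfg.seed}, "runtime_s": round(time.perf_counter() - t0, 3)},
        sorted(fx.iterdir()),
    )
    return cohort


def stage_screen(config: dict, wd: Path, seed: int) -> pd.DataFrame:
    """Event screen on cell lines: coverage filter, KW test, deltaPSI rule."""
    t0 = time.perf_counter()
    cfg = config["screen"]
    cohort = read_fixture(wd / "fixture")
    groups = _cell_groups(cohort)
    (name_a, cols_a), (name_b, cols_b) = sorted(groups.items())

    passed = filter_events(cohort.cells, cols_a, cols_b, cfg["min_total"], cfg["per_sample"])
    kept = cohort.cells.subset_events(passed.index[passed])
    kw = kruskal_wallis_screen(kept.psi(), groups, alpha=cfg["alpha"])
    dp = delta_psi(
        kept, cols_a, cols_b,
        n_draws=cfg["n_draws"], seed=_stage_seed(seed, "screen"),
        delta_threshold=cfg["delta_threshold"], prob_threshold=cfg["prob_threshold"],
    )
    out = pd.DataFrame(index=cohort.cells.events.index)
    out["pass_filter"] = passed
    out = out.join(kw[["statistic", "p_value", "selected"]].rename(columns={"selected": "kw_selected"}))
    out = out.join(dp[["delta_psi", "probability", "significant"]])
    out["selected"] = out["pass_filter"] & out["kw_selected"].fillna(False) & out["significant"].fillna(False)

    # expression screen for the expression / mixed feature modes
    expr_kw = kruskal_wallis_screen(
        np.log2(cohort.expression[cols_a + cols_b] + 1.0), groups, alpha=cfg["alpha"]
    )

    path = wd / "screen_events.tsv"
    out.to_csv(path, sep="\t", index_label="event_id")
    epath = wd / "screen_expression.tsv"
    expr_kw.to_csv(epath, sep="\t", index_label="gene_id")
    _update_manifest(
        wd, "screen",
        {"config": {**cfg, "mc_seed": _stage_seed(seed, "screen")},
         "n_selected_events": int(out["selected"].sum()),
         "n_selected_genes": int(expr_kw["selected"].sum()),
         "runtime_s": round(time.perf_counter() - t0, 3)},
        [path, epath],
    )
    return out


def _transfer_features(cohort: Cohort, config: dict, screen: pd.DataFrame, expr_screen: pd.DataFrame):
    """Assemble cell/patient feature matrices for the configured mode."""
    mode = config["transfer"]["feature_mode"]
    groups = _cell_groups(cohort)
    cell_ids = [s for cols in groups.values() for s in cols]
    sel_events = list(screen.index[screen["selected"]])
    if mode in ("splicing", "mixed") and not sel_events:
        raise ValueError("no events selected by the screen; cannot build splicing features")
    psi_cells = cohort.cells.psi().loc[sel_events, cell_ids].T if sel_events else None
    psi_pat = cohort.patients.psi().loc[sel_events].T if sel_events else None

    sel_genes = list(expr_screen.index[expr_screen["selected"]])
    pat_ids = cohort.patients.samples
    if mode in ("expression", "mixed"):
        if not sel_genes:
            raise ValueError("no genes selected by the expression screen")
        log_expr = np.log2(cohort.expression.loc[sel_genes] + 1.0)
        ec, ep = scale_per_domain(log_expr[cell_ids].T, log_expr[pat_ids].T)
    if mode == "splicing":
        return psi_cells, psi_pat
    if mode == "expression":
        return ec, ep
    if mode == "mixed":
        sc, sp = scale_per_domain(psi_cells, psi_pat)
        return (
            pd.concat([ec, sc.add_prefix("psi:")], axis=1),
            pd.concat([ep, sp.add_prefix("psi:")], axis=1),
        )
    raise ValueError(f"unknown feature_mode '{mode}'")


def stage_transfer(config: dict, wd: Path, seed: int):
    t0 = time.perf_counter()
    cfg = dict(config["transfer"])
    cohort = read_fixture(wd / "fixture")
    screen = pd.read_csv(wd / "screen_events.tsv", sep="\t", index_col="event_id")
    expr_screen = pd.read_csv(wd / "screen_expression.tsv", sep="\t", index_col="gene_id")
    groups = _cell_groups(cohort)

    mode = cfg.pop("feature_mode")
    cells_X, patients_X = _transfer_features(cohort, config, screen, expr_screen)
    cell_labels = pd.Series(
        {s: lab for lab, cols in groups.items() for s in cols}, name="subtype"
    ).loc[cells_X.index]
    if mode == "mixed":
        # mixed features are harder to separate across domains: relax thresholds
        cfg["prob_high"] = min(cfg["prob_high"], 0.55)
        cfg["prob_low"] = max(cfg["prob_low"], 0.45)
    result = run_transfer(
        cells_X, cell_labels, patients_X,
        scale_per_domain=(mode in ("expression", "mixed")),
        random_state=_stage_seed(seed, "transfer"),
        **cfg,
    )
    apath = wd / "assignments.tsv"
    result.assignments.to_csv(apath, sep="\t")
    ppath = wd / "probability_history.tsv"
    result.probability_history.to_csv(ppath, sep="\t")
    traj = importance_trajectory(result.importance_history)
    tpath = wd / "importance_trajectory.tsv"
    traj["table"].to_csv(tpath, sep="\t", index=False)
    _update_manifest(
        wd, "transfer",
        {"config": {**config["transfer"], "seed": _stage_seed(seed, "transfer")},
         "n_rounds": int(result.estimator.n_rounds_),
         "assignments": result.assignments["assignment"].value_counts().to_dict(),
         "top10_overlap_first_last": traj["overlap"],
         "runtime_s": round(time.perf_counter() - t0, 3)},
        [apath, ppath, tpath],
    )
    return result


def stage_signature(config: dict, wd: Path, seed: int) -> pd.DataFrame:
    t0 = time.perf_counter()
    cfg = dict(config["signature"])
    cohort = read_fixture(wd / "fixture")
    screen = pd.read_csv(wd / "screen_events.tsv", sep="\t", index_col="event_id")
    assignments = pd.read_csv(wd / "assignments.tsv", sep="\t", index_col="patient_id")
    groups = _cell_groups(cohort)
    (name_a, cols_a), (name_b, cols_b) = sorted(groups.items())

    sel_events = list(screen.index[screen["selected"]])
    psi_cells = cohort.cells.psi().loc[sel_events]
    psi_pat = cohort.patients.psi().loc[sel_events]

    train_ids = {name_a: list(cols_a), name_b: list(cols_b)}
    training = cfg.pop("training")
    if training == "cells_plus_admitted":
        for lab, name in ((f"{name_a}_like", name_a), (f"{name_b}_like", name_b)):
            train_ids[name] += list(assignments.index[assignments["assignment"] == lab])
    elif training != "cells_only":
        raise ValueError(f"unknown signature training mode '{training}'")

    psi_all = pd.concat([psi_cells, psi_pat], axis=1)
    X = psi_all[train_ids[name_a] + train_ids[name_b]].T
    y = np.array([name_a] * len(train_ids[name_a]) + [name_b] * len(train_ids[name_b]))
    selector = BorutaConsensus(random_state=_stage_seed(seed, "signature"), **cfg)
    selector.fit(X.to_numpy(dtype=float), y)

    table = build_signature_table(
        selector, sel_events, cohort.cells.events.loc[sel_events], psi_all, train_ids
    )
    spath = wd / "signature.tsv"
    table.to_csv(spath, sep="\t")
    bpath = wd / "signature.bed"
    export_signature_bed(table[table["selected"]], bpath)
    _update_manifest(
        wd, "signature",
        {"config": {**config["signature"], "seed": _stage_seed(seed, "signature")},
         "n_selected": int(table["selected"].sum()),
         "runtime_s": round(time.perf_counter() - t0, 3)},
        [spath, bpath],
    )
    return table


def stage_validate(config: dict, wd: Path, seed: int) -> dict:
    """Embed a held-out synthetic cell-line cohort on the signature events."""
    t0 = time.perf_counter()
    cfg = config["validate"]
    signature = pd.read_csv(wd / "signature.tsv", sep="\t", index_col="event_id")
    sel = list(signature.index[signature["selected"]])
    if not sel:  # fall back to the screen set if the consensus is empty
        sel = list(signature.index)
    holdout_cfg = CohortConfig(
        **{**config["cohort"],
           "n_cell_a": cfg["holdout_n_cell_a"], "n_cell_b": cfg["holdout_n_cell_b"],
           "n_patients": 1},
        seed=_stage_seed(seed, "validate"),
    )
    holdout = generate_cohort(holdout_cfg)
    feats = holdout.cells.psi().loc[[e for e in sel if e in holdout.cells.events.index]].T
    feats = feats.fillna(feats.median())
    emb = tsne_embed(feats, perplexity=cfg["perplexity"], seed=_stage_seed(seed, "validate"))
    truth = holdout.truth.labels.loc[feats.index]
    seg = segregation_accuracy(emb, truth, seed=_stage_seed(seed, "validate"))

    etable = emb.copy()
    etable["predicted_cluster"] = seg["clusters"]
    etable["true_label"] = truth
    epath = wd / "embedding.tsv"
    etable.to_csv(epath, sep="\t", index_label="sample_id")
    report = {
        "accuracy": seg["accuracy"],
        "misclassified": seg["misclassified"],
        "n_signature_events": len(sel),
        "n_holdout_samples": int(len(feats)),
        "perplexity": cfg["perplexity"],
    }
    vpath = wd / "validation.json"
    vpath.write_text(json.dumps(report, indent=1, sort_keys=True))
    _update_manifest(
        wd, "validate",
        {"config": {**cfg, "seed": _stage_seed(seed, "validate")},
         "accuracy": seg["accuracy"],
         "runtime_s": round(time.perf_counter() - t0, 3)},
        [epath, vpath],
    )
    return report


def stage_survival(config: dict, wd: Path, seed: int) -> dict:
    t0 = time.perf_counter()
    cfg = config["survival"]
    cohort = read_fixture(wd / "fixture")
    assignments = pd.read_csv(wd / "assignments.tsv", sep="\t", index_col="patient_id")
    groups = _cell_groups(cohort)
    name_a, name_b = sorted(groups)

    table = cohort.survival.join(assignments["assignment"].rename("group"))
    table["time"] = to_years(table["time"], cfg.get("time_unit", "years"))
    contrast = survival_contrast(
        table, group_a=f"{name_a}_like", group_b=f"{name_b}_like",
        truncation_years=cfg["truncation_years"],
    )
    outputs = []
    for lab in (f"{name_a}_like", f"{name_b}_like"):
        sub = table[table["group"] == lab]
        km = km_curve(sub["time"], sub["event"], truncate_years=cfg["truncation_years"])
        p = wd / f"km_{lab}.tsv"
        km.to_csv(p, sep="\t", index=False)
        outputs.append(p)
    cpath = wd / "contrast.json"
    cpath.write_text(json.dumps(contrast.to_dict(), indent=1, sort_keys=True))
    outputs.append(cpath)
    _update_manifest(
        wd, "survival",
        {"config": dict(cfg), "hazard_ratio": contrast.hazard_ratio,
         "p_value": contrast.p_value,
         "runtime_s": round(time.perf_counter() - t0, 3)},
        outputs,
    )
    return contrast.to_dict()


STAGES = ["simulate", "screen", "transfer", "signature", "validate", "survival"]
_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "screen": stage_screen,
    "transfer": stage_transfer,
    "signature": stage_signature,
    "validate": stage_validate,
    "survival": stage_survival,
}


def run_all(config: dict, outdir: str | Path, seed: int) -> dict:
    """Run the whole pipeline into ``outdir``; returns the final manifest."""
    wd = Path(outdir)
    wd.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        _STAGE_FUNCS[stage](config, wd, seed)
    return yaml.safe_load((wd / "manifest.yaml").read_text())
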