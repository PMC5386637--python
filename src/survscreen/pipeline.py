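"""End-to-end orchestration: simulate -> screen -> permutation null -> FDR
-> clinical utility -> knockdown signature, driven by a YAML config, with a
manifest recording config, seeds and output digests so every published file
is traceable to its run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import SurvScreenError, ValidationError
from .expression import write_clinical, write_matrix
from .screen import PermutationNull, ScreenConfig, ScreenResult, estimate_fdr, permutation_null, rank_features, run_screen
from .signature import (
    cluster_outcome_association,
    cluster_samples,
    correlate_with_feature,
    fold_changes,
    overlap_test,
    select_by_fold_change,
    shared_signature,
)
from .synthetic import CohortConfig, KnockdownConfig, simulate_cohort, simulate_knockdown
from .utility import DEFAULT_HORIZON_DAYS, chaid_tree, compare_models

logger = logging.getLogger("survscreen")

ALL_STAGES = ("simulate", "screen", "null", "fdr", "utility", "signature")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "survscreen_out",
    "simulate": {
        "cohort": {"n_samples": 466, "n_features": 500, "n_prognostic": 1},
        "knockdown": {"n_genes": 1000, "n_affected": 100},
    },
    "screen": {"n_iterations": 100, "p_threshold": 0.001},
    "fdr": {"frequency_cutoff": 0.5},
    "utility": {
        "horizon_days": DEFAULT_HORIZON_DAYS,
        "models": [["stage", "grade"], ["stage", "grade", "marker"]],
    },
    "signature": {"fold_change_cutoff": 1.25, "r_threshold": 0.15, "pseudocount": 0.01},
}


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    failed_stage: str | None = None

    def record(self, stage: str, paths: list[Path]) -> None:
        self.stages.append(stage)
        for p in paths:
            self.outputs[str(p)] = _sha256(p)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "stages": self.stages,
                "outputs": self.outputs,
                "failed_stage": self.failed_stage,
            },
            indent=2, default=str,
        ))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    return _merge(DEFAULT_CONFIG, raw)


class StageFailure(SurvScreenError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict, stages=ALL_STAGES) -> RunManifest:
    """Execute the requested stages in order.

    Re-running with an identical config reproduces identical outputs.  A
    stage failure halts the run; outputs of completed stages are kept and
    the manifest marks the failed stage.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(config=config)
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "screen": _stage_screen,
        "null": _stage_null,
        "fdr": _stage_fdr,
        "utility": _stage_utility,
        "signature": _stage_signature,
    }
    try:
        for stage in stages:
            if stage not in runners:
                raise ValidationError(f"unknown stage {stage!r}")
            logger.info("stage %s: start", stage)
            try:
                paths = runners[stage](config, seed, outdir, state)
            except SurvScreenError:
                raise
            except Exception as exc:  # typed failure naming the stage
                raise StageFailure(stage, exc) from exc
            manifest.record(stage, paths)
            logger.info("stage %s: done", stage)
    except StageFailure as exc:
        manifest.failed_stage = exc.stage
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return manifest


def _require(state: dict, key: str, needed_by: str):
    if key not in state:
        raise ValidationError(f"stage {needed_by!r} needs {key}; run earlier stages or point the config at files")
    return state[key]


def _load_inputs(config: dict, state: dict) -> None:
    """Allow screen/utility stages to run on externally supplied files."""
    from .expression import read_clinical, read_matrix

    paths = config.get("inputs", {}) or {}
    for key, reader in (("matrix", read_matrix), ("clinical", read_clinical)):
        if key in paths and key not in state:
            p = Path(paths[key])
            if not p.exists():
                raise ValidationError(f"input file does not exist: {p}")
            state[key] = reader(p)


def _stage_simulate(config, seed, outdir, state):
    cc = CohortConfig(**config["simulate"]["cohort"], seed=seed)
    matrix, clinical, truth = simulate_cohort(cc)
    kc = KnockdownConfig(**config["simulate"]["knockdown"], seed=seed + 1)
    kd_matrices, kd_truth = simulate_knockdown(kc)
    state.update(matrix=matrix, clinical=clinical, truth=truth,
                 kd_matrices=kd_matrices, kd_truth=kd_truth)
    mpath, cpath = outdir / "matrix.tsv", outdir / "clinical.tsv"
    write_matrix(matrix, mpath)
    write_clinical(clinical, cpath)
    tpath = outdir / "planted_truth.json"
    tpath.write_text(json.dumps({"prognostic_features": list(truth.prognostic_feature_ids),
                                 "log_hrs": truth.log_hrs}, indent=2))
    return [mpath, cpath, tpath]


def _stage_screen(config, seed, outdir, state):
    _load_inputs(config, state)
    matrix = _require(state, "matrix", "screen")
    clinical = _require(state, "clinical", "screen")
    sc = ScreenConfig(n_iterations=int(config["screen"]["n_iterations"]),
                      p_threshold=float(config["screen"]["p_threshold"]), seed=seed)
    result = run_screen(matrix, clinical, sc)
    state["screen_result"] = result
    path = outdir / "screen_result.tsv"
    result.to_frame().to_csv(path, sep="\t")
    return [path]


def _stage_null(config, seed, outdir, state):
    _load_inputs(config, state)
    matrix = _require(state, "matrix", "null")
    clinical = _require(state, "clinical", "null")
    sc = ScreenConfig(n_iterations=int(config["screen"]["n_iterations"]),
                      p_threshold=float(config["screen"]["p_threshold"]), seed=seed)
    null = permutation_null(matrix, clinical, sc)
    state["null"] = null
    path = outdir / "null_validated_counts.tsv"
    pd.DataFrame({"validated_count": null.validated_counts_per_iteration}).to_csv(
        path, sep="\t", index_label="permutation"
    )
    return [path]


def _stage_fdr(config, seed, outdir, state):
    result: ScreenResult = _require(state, "screen_result", "fdr")
    null: PermutationNull = _require(state, "null", "fdr")
    cutoff = float(config["fdr"]["frequency_cutoff"])
    fdr = estimate_fdr(result, null, cutoff)
    path = outdir / "fdr.json"
    path.write_text(json.dumps({
        "frequency_cutoff": cutoff,
        "fdr": fdr,
        "observed_at_cutoff": int((result.validation_frequency >= cutoff).sum()),
        "null_at_cutoff": int((null.null_frequency >= cutoff).sum()),
        "null_mean_validated_per_iteration": null.mean_validated_count,
    }, indent=2))
    return [path]


def _marker_high(state) -> np.ndarray:
    """Marker indicator: top-ranked screen feature dichotomized at its
    cohort median."""
    result: ScreenResult = state["screen_result"]
    top = rank_features(result)[0]
    state["marker_feature"] = top
    row = state["matrix"].loc[top].to_numpy(dtype=float)
    return row > np.median(row)


def _stage_utility(config, seed, outdir, state):
    _load_inputs(config, state)
    clinical = _require(state, "clinical", "utility")
    _require(state, "screen_result", "utility")
    marker_high = _marker_high(state)
    horizon = float(config["utility"]["horizon_days"])
    specs = [list(s) for s in config["utility"]["models"]]
    summary, curves, _ = compare_models(clinical, marker_high, specs, horizon=horizon)

    cov = pd.DataFrame({
        "stage": clinical["stage"].astype(str),
        "grade_band": np.where(clinical["grade"].astype(int) >= 3,
                               clinical["grade"].astype(int).astype(str), "1-2"),
        "marker": np.where(marker_high, "high", "low"),
    }, index=clinical.index)
    tree = chaid_tree(cov, clinical["event"].to_numpy())

    spath = outdir / "utility_auc.tsv"
    summary.to_csv(spath, sep="\t")
    dpath = outdir / "decision_curves.tsv"
    frames = []
    for label, curve in curves.items():
        frames.append(pd.DataFrame({
            "model": label, "threshold": curve.thresholds,
            "net_benefit": curve.net_benefit, "treat_all": curve.treat_all,
        }))
    pd.concat(frames, ignore_index=True).to_csv(dpath, sep="\t", index=False)
    tpath = outdir / "chaid_tree.txt"
    tpath.write_text(tree.render() + "\n")
    state["utility_summary"] = summary
    return [spath, dpath, tpath]


def _stage_signature(config, seed, outdir, state):
    kd = _require(state, "kd_matrices", "signature")
    matrix = _require(state, "matrix", "signature")
    clinical = _require(state, "clinical", "signature")
    marker = state.get("marker_feature") or rank_features(_require(state, "screen_result", "signature"))[0]
    cutoff = float(config["signature"]["fold_change_cutoff"])
    pc = float(config["signature"]["pseudocount"])

    lines = sorted({line for line, _ in kd})
    sirnas = sorted({cond for _, cond in kd if cond != "control"})
    universe = next(iter(kd.values())).shape[0]
    sets, overlap_rows = {}, []
    for line in lines:
        ctrl = kd[(line, "control")].iloc[:, 0]
        per_sirna = {}
        for sirna in sirnas:
            ratios = fold_changes(kd[(line, sirna)].iloc[:, 0], ctrl, pseudocount=pc)
            up, down = select_by_fold_change(ratios, cutoff=cutoff, universe_size=universe)
            sets[(line, sirna, "up")] = up
            sets[(line, sirna, "down")] = down
            per_sirna[sirna] = (up, down)
        if len(sirnas) == 2:
            for direction, pos in (("up", 0), ("down", 1)):
                a, b = (per_sirna[s][pos] for s in sirnas)
                res = overlap_test(a, b, universe)
                overlap_rows.append({"cell_line": line, "direction": direction,
                                     "overlap": res.overlap, "size_a": res.size_a,
                                     "size_b": res.size_b, "p_value": res.p_value})

    shared = shared_signature(sets)
    state["shared_signature"] = shared

    gpath = outdir / "shared_signature.txt"
    with open(gpath, "w") as fh:
        fh.write(f"# universe_size={shared.universe_size}\n")
        for g in sorted(shared.members):
            fh.write(g + "\n")
    opath = outdir / "overlap_tests.tsv"
    pd.DataFrame(overlap_rows).to_csv(opath, sep="\t", index=False)
    paths = [gpath, opath]

    # tumor-side: correlation filter and clustering need the signature genes
    # to exist in the tumor matrix; in a simulated run the cohorts are
    # independent, so cluster on the marker-correlated gene set instead.
    corr = correlate_with_feature(matrix, marker, r_threshold=float(config["signature"]["r_threshold"]))
    cpath = outdir / "correlated_genes.txt"
    with open(cpath, "w") as fh:
        fh.write(f"# universe_size={corr.universe_size}\n")
        for g in sorted(corr.members):
            fh.write(g + "\n")
    paths.append(cpath)

    cluster_genes = sorted(shared.members & set(matrix.index)) or sorted(corr.members)
    if len(cluster_genes) >= 2:
        assignment = cluster_samples(matrix.loc[cluster_genes], k=2, pseudocount=pc)
        row = matrix.loc[marker].to_numpy(dtype=float)
        lr, fisher_p = cluster_outcome_association(assignment, clinical, row > np.median(row))
        apath = outdir / "cluster_assignment.tsv"
        pd.DataFrame({"cluster": assignment.labels},
                     index=pd.Index(assignment.sample_ids, name="sample_id")).to_csv(apath, sep="\t")
        jpath = outdir / "cluster_association.json"
        jpath.write_text(json.dumps({
            "n_cluster_genes": len(cluster_genes),
            "logrank_p": lr.p_value, "fisher_p": fisher_p,
        }, indent=2))
        paths += [apath, jpath]
    return paths
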