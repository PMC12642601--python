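"""Pipeline configuration and the end-to-end report runner.

``PipelineConfig`` gathers every tunable parameter with defaults equal to
the canonical analysis values (windows, fold counts, permutation counts,
thresholds).  ``run_pipeline`` executes the requested stages in dependency
order on one or more session stores, writes CSV/JSON outputs per stage, and
records a manifest (inputs, config echo, seeds, runtimes) so a run is fully
reproducible from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import decoding, geometry, models, responsiveness, rsa, tuning
from .design import INTENTION, OBSERVATION, MAIN
from .session import bin_rates, load_session

log = logging.getLogger("crossformat")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the canonical analysis parameters."""

    seed: int = 0
    stages: Tuple[str, ...] = ("responsiveness", "tuning", "classify", "rsa", "decode", "geometry")
    # binning
    bin_width_s: float = 0.1
    baseline_window_s: Tuple[float, float] = (-0.5, 0.0)
    analysis_window_s: Tuple[float, float] = (0.0, 3.0)
    # responsiveness
    resp_alpha: float = 0.05
    resp_window_len_s: float = 0.2
    resp_step_s: float = 0.1
    resp_min_run: int = 3
    # tuning
    tuning_bin_width_s: float = 0.5
    tuning_alpha: float = 0.05
    tuning_divisor: str = "units"
    # model selection
    model_window_s: Tuple[float, float] = (1.0, 2.0)
    cv_folds: int = 5
    n_perm_models: int = 1000
    fdr_q: float = 0.05
    r2_threshold: float = 0.01
    # rsa
    rsa_n_splits: int = 500
    rsa_n_perm: int = 1000
    rsa_groupings: Tuple[str, ...] = ("action", "hand", "direction")
    # decoding
    decode_folds: int = 10
    decode_var_keep: float = 0.95
    decode_max_pc: int = 50
    crossformat_n_perm: int = 1000
    # geometry
    trajectory_window_s: Tuple[float, float] = (-0.5, 2.5)

    def __post_init__(self) -> None:
        if self.cv_folds < 2 or self.decode_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.n_perm_models < 1 or self.rsa_n_perm < 1 or self.crossformat_n_perm < 1:
            raise ValueError("permutation counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for k in ("baseline_window_s", "analysis_window_s", "model_window_s", "trajectory_window_s"):
            if k in raw:
                raw[k] = tuple(raw[k])
        for k in ("stages", "rsa_groupings"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, session_paths: Sequence, out_dir) -> Path:
    """Run the configured stages over sessions; returns the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "sessions": [str(p) for p in session_paths], "stages": {}}
    for path in session_paths:
        t_all = time.time()
        design, trials, spikes, lfp_sess = load_session(path)
        name = Path(path).stem
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        rates = bin_rates(
            spikes, design, window=config.analysis_window_s,
            bin_width=config.bin_width_s, baseline=config.baseline_window_s,
        )
        stage_times: Dict[str, float] = {}

        def _stage(stage: str) -> bool:
            if stage in config.stages:
                log.info("stage=%s session=%s seed=%d", stage, name, config.seed)
                return True
            return False

        relevant: Optional[List[str]] = None
        if _stage("responsiveness") and design.variant == MAIN:
            t0 = time.time()
            res = {}
            for fmt in (INTENTION, OBSERVATION):
                r = responsiveness.test_responsiveness(
                    rates, trials, design, fmt, units=spikes.units,
                    alpha=config.resp_alpha, window_len=config.resp_window_len_s,
                    step=config.resp_step_s, min_run=config.resp_min_run,
                )
                r.table.to_csv(sdir / f"responsiveness_{fmt}.csv", index=False)
                res[fmt] = r
            responsiveness.format_overlap(res[INTENTION], res[OBSERVATION]).to_csv(
                sdir / "format_overlap.csv", index=False
            )
            stage_times["responsiveness"] = time.time() - t0
        if _stage("tuning") and design.variant == MAIN:
            t0 = time.time()
            for fmt in (INTENTION, OBSERVATION):
                tc = tuning.anova_timecourse(
                    rates, trials, design, format=fmt,
                    alpha=config.tuning_alpha, divisor=config.tuning_divisor,
                    bin_width=config.tuning_bin_width_s,
                )
                tc.table.to_csv(sdir / f"tuning_{fmt}.csv", index=False)
                tc.counts.to_csv(sdir / f"tuning_counts_{fmt}.csv")
            stage_times["tuning"] = time.time() - t0
        if _stage("classify") and design.variant == MAIN:
            t0 = time.time()
            cls = models.classify_population(
                rates, trials, design, window=config.model_window_s,
                folds=config.cv_folds, n_perm=config.n_perm_models,
                q=config.fdr_q, r2_threshold=config.r2_threshold, seed=config.seed,
            )
            cls.table.to_csv(sdir / "unit_classification.csv", index=False)
            relevant = models.task_relevant_subset(cls)
            stage_times["classify"] = time.time() - t0
        if _stage("rsa") and design.variant == MAIN:
            t0 = time.time()
            report = {}
            for grouping in config.rsa_groupings:
                for comparison in rsa.COMPARISONS:
                    pt = rsa.rsa_permutation_test(
                        rates, trials, design, units=relevant, grouping=grouping,
                        comparison=comparison, n_splits=config.rsa_n_splits,
                        n_perm=config.rsa_n_perm, window=config.model_window_s, seed=config.seed,
                    )
                    key = f"{grouping}_{comparison}"
                    np.savetxt(sdir / f"rsa_{key}.csv", pt["result"].matrix, delimiter=",")
                    report[key] = {"structure_stat": pt["observed"], "p": pt["p"]}
            (sdir / "rsa_report.json").write_text(json.dumps(report, indent=2))
            stage_times["rsa"] = time.time() - t0
        if _stage("decode") and design.variant == MAIN:
            t0 = time.time()
            rows = []
            for fmt in (INTENTION, OBSERVATION):
                for label in ("action", "hand", "direction", "condition12"):
                    y = decoding.get_labels(trials, design, label)
                    sel = (trials["format"] == fmt) & trials["included"]
                    min_class = pd.Series(y[sel.to_numpy()]).value_counts().min()
                    r = decoding.decode_timecourse(
                        rates, trials, design, label, format=fmt,
                        folds=min(config.decode_folds, int(min_class)),
                        var_keep=config.decode_var_keep,
                        max_pc=config.decode_max_pc, seed=config.seed,
                    )
                    for c, a in zip(r.window_centers_s, r.accuracies):
                        rows.append({"format": fmt, "label": label, "window_center_s": c, "accuracy": a})
            pd.DataFrame(rows).to_csv(sdir / "decoding_timecourses.csv", index=False)
            for direction in (INTENTION, OBSERVATION):
                gm = decoding.cross_format_decode(
                    rates, trials, design, "action", train_format=direction,
                    n_perm=config.crossformat_n_perm, max_pc=config.decode_max_pc, seed=config.seed,
                )
                np.savetxt(sdir / f"crossformat_accuracy_train_{direction}.csv", gm.matrix, delimiter=",")
                np.savetxt(sdir / f"crossformat_mask_train_{direction}.csv", gm.mask.astype(int), delimiter=",")
            stage_times["decode"] = time.time() - t0
        if _stage("geometry") and design.variant == MAIN:
            t0 = time.time()
            traj_rates = bin_rates(
                spikes, design, window=(config.trajectory_window_s[0], config.analysis_window_s[1]),
                bin_width=config.bin_width_s, baseline=config.baseline_window_s,
            )
            traj = geometry.pca_trajectories(
                traj_rates, trials, design, units=relevant,
                window=config.trajectory_window_s,
            )
            rep = geometry.procrustes_report(traj)
            rep.table.to_csv(sdir / "procrustes.csv", index=False)
            stage_times["geometry"] = time.time() - t0
        manifest["stages"][name] = {"runtimes_s": stage_times, "total_s": time.time() - t_all}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
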