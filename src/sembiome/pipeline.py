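"""End-to-end orchestration: groups -> CLR -> markers -> SEM -> scores -> risk.

All randomness flows from a single root seed, split deterministically per
stage, so re-running with the same configuration reproduces every output
file.  Stage errors propagate annotated with the stage name; if the SEM
modification cannot produce an admissible model the pipeline reports that
and stops before scoring (mirroring a cohort where no latent structure is
supported by the data).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clr_transform, data_model, effect_stability, factor_scores, risk_model, sem_core
from .clr_transform import ClrConfig
from .risk_model import RiskConfig

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

log = logging.getLogger(__name__)

FEATURE_SETS = (("lv1",), ("lv2",), ("lv1", "lv2"))


class StageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    counts_path: str
    metadata_path: str
    output_dir: str
    sex: str = "female"
    seed: int = 1234
    clr_instances: int = 128
    clr_prior: float = 0.5
    selection_reps: int = 500
    selection_k: int = 20
    sem_alpha: float = 0.05
    sem_rmsea_max: float = 0.08
    split_frac: float = 0.8
    smote_k: int = 5
    smote_over_pct: float = 200.0
    smote_under_pct: float = 200.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage_seed(root: int, stage: str) -> int:
    # deterministic per-stage split of the root seed, kept below 2**31
    h = np.random.SeedSequence([root, sum(ord(ch) for ch in stage)])
    return int(h.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow and write every intermediate artifact.

    Returns the machine-readable run report (also written as report.json).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "stages": {}}
    if cfg.selection_reps == 1:
        report["reduced_replication"] = True

    def run_stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        report["stages"][name] = "ok"
        return result

    # --- inputs -----------------------------------------------------------
    def _load():
        counts_path = Path(cfg.counts_path)
        meta_path = Path(cfg.metadata_path)
        for p in (counts_path, meta_path):
            if not p.exists():
                raise FileNotFoundError(f"input file not found: {p}")
        return (data_model.read_count_table(counts_path),
                data_model.read_metadata(meta_path))

    counts, meta = run_stage("load", _load)

    # --- group assignment -------------------------------------------------
    def _groups():
        assignment = data_model.assign_groups(meta, cfg.sex)
        assignment.write_csv(out / "groups.csv")
        return assignment

    assignment = run_stage("assign_groups", _groups)
    group_sizes = {g: len(assignment.members(g)) for g in data_model.GROUP_LABELS}
    report["group_sizes"] = group_sizes

    in_groups = [s for s in counts.samples
                 if assignment.labels.get(s) in data_model.GROUP_LABELS]
    cohort = counts.subset_samples(in_groups)
    nc_as = [s for s in in_groups if assignment.labels[s] in ("NC", "AS")]

    # --- marker selection (NC vs AS only) ---------------------------------
    def _markers():
        sub = cohort.subset_samples(nc_as)
        groups = {s: assignment.labels[s] for s in nc_as}
        markers = effect_stability.stable_marker_selection(
            sub, groups, reps=cfg.selection_reps, k=cfg.selection_k,
            base_seed=_stage_seed(cfg.seed, "selection"),
            clr_cfg=ClrConfig(n_instances=cfg.clr_instances, prior=cfg.clr_prior),
            labels=("NC", "AS"),  # positive effect = higher in AS
        )
        markers.to_frame().to_csv(out / "markers.csv", index=False)
        return markers

    markers = run_stage("select_markers", _markers)
    report["markers"] = markers.signed()

    # --- CLR point estimate for modeling/scoring --------------------------
    def _clr():
        ens = clr_transform.clr_ensemble(
            cohort,
            ClrConfig(n_instances=cfg.clr_instances, prior=cfg.clr_prior,
                      seed=_stage_seed(cfg.seed, "clr")),
        )
        mat = clr_transform.clr_point_estimate(ens)
        mat.to_csv(out / "clr_point_estimate.tsv", sep="\t")
        return mat

    clr_mat = run_stage("clr", _clr)

    # --- SEM on NC + AS ---------------------------------------------------
    ad_label = {s: int(assignment.labels[s] in ("AS", "AM")) for s in in_groups}

    def _sem():
        spec = sem_core.build_model_spec(markers.signed())
        sub = clr_mat.loc[nc_as]
        y = np.array([ad_label[s] for s in nc_as])
        start = sem_core.fit_sem(spec, sub, y)
        final, deletions = sem_core.modify_model(
            start, sub, y, alpha=cfg.sem_alpha, rmsea_max=cfg.sem_rmsea_max
        )
        final.to_csv(out / "sem_parameters.csv")
        (out / "sem_model.txt").write_text(final.spec.to_text() + "\n")
        (out / "fit_indices.json").write_text(
            json.dumps(final.fit.as_dict(), indent=2) + "\n")
        (out / "sem_deletions.json").write_text(json.dumps(deletions, indent=2) + "\n")
        return final, deletions

    try:
        fitted, deletions = run_stage("fit_sem", _sem)
    except StageError as exc:
        if isinstance(exc.original, sem_core.ModelConstructionError):
            report["stages"]["fit_sem"] = "model could not be constructed"
            report["sem_constructed"] = False
            _write_report(out, report)
            return report
        raise
    report["sem_constructed"] = True
    report["fit_indices"] = fitted.fit.as_dict()
    report["sem_deletions"] = deletions
    report["paths"] = fitted.paths().to_dict()

    # --- scores for all four groups ---------------------------------------
    def _scores():
        model = factor_scores.extract_measurement_model(fitted)
        (out / "measurement_model.txt").write_text(model.to_text() + "\n")
        (out / "measurement_model.json").write_text(model.to_json() + "\n")
        table = factor_scores.bartlett_scores(
            model, clr_mat, {s: assignment.labels[s] for s in in_groups}
        )
        table.write_csv(out / "scores.csv")
        comparisons = factor_scores.compare_groups(
            table, [("NC", "AS"), ("NC", "AM"), ("NC", "OD")], variable="lv2"
        )
        return table, comparisons

    scores, comparisons = run_stage("score", _scores)
    report["lv2_group_tests"] = [
        {"pair": list(c.pair), "U": c.u_statistic, "p": c.p_value} for c in comparisons
    ]

    # --- risk model -------------------------------------------------------
    def _risk():
        strata = {s: assignment.labels[s] for s in in_groups}
        split = risk_model.stratified_split(
            strata, frac=cfg.split_frac, seed=_stage_seed(cfg.seed, "split"))
        results = {}
        for features in FEATURE_SETS:
            fname = "_".join(features)
            rcfg = RiskConfig(
                smote_k=cfg.smote_k, over_pct=cfg.smote_over_pct,
                under_pct=cfg.smote_under_pct,
                seed=_stage_seed(cfg.seed, f"smote_{fname}"), features=features,
            )
            train_x = scores.table.loc[split.training, list(features)]
            train_y = pd.Series([ad_label[s] for s in split.training],
                                index=split.training)
            bal_x, bal_y = risk_model.smote_balance(train_x, train_y, rcfg)
            model, coefs, intercept = risk_model.fit_logistic(bal_x, bal_y)
            ver_x = scores.table.loc[split.verification, list(features)]
            ver_y = np.array([ad_label[s] for s in split.verification])
            probs = model.predict_proba(ver_x.to_numpy(dtype=float))[:, 1]
            roc = risk_model.roc_auc(probs, ver_y)
            roc.curve.to_csv(out / f"roc_{fname}.csv", index=False)
            pd.DataFrame({"sample_id": split.verification, "risk": probs}).to_csv(
                out / f"risk_{fname}.csv", index=False)
            results[fname] = {
                "auc": roc.auc, "ci": list(roc.ci),
                "coefficients": coefs.to_dict(), "intercept": intercept,
            }
        pd.DataFrame(
            [{"features": k, "auc": v["auc"], "ci_low": v["ci"][0],
              "ci_high": v["ci"][1]} for k, v in results.items()]
        ).to_csv(out / "auc_summary.csv", index=False)
        return results

    report["risk"] = run_stage("risk", _risk)
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
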