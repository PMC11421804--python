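"""End-to-end orchestration: simulate/ingest → estimate → basis → metrics →
reliability → features → associate.

Every stage writes plain TSV/JSON artifacts into the output directory, the
config is serialized verbatim alongside them, and all randomness flows from
the master seed, so re-running an identical config reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import basis as basis_mod
from . import cap_estimation, neurobehavior, reliability, synthetic, temporal
from . import features as features_mod
from .io_preprocess import (DEFAULT_FD_THRESHOLD, DEFAULT_N_DUMMY, load_cohort,
                            preprocess_runs)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults mirror the documented choices."""

    cohort_path: str | None = None       # None -> simulate
    sim: synthetic.SimConfig = dataclasses.field(default_factory=synthetic.SimConfig)
    n_permutations: int = 50
    k_min: int = 2
    k_max: int = 8
    fd_threshold: float = DEFAULT_FD_THRESHOLD
    n_dummy: int = DEFAULT_N_DUMMY
    run_order: tuple | None = None
    silhouette_subsample: int = cap_estimation.DEFAULT_SILHOUETTE_SUBSAMPLE
    dendrogram_cut: float = features_mod.DEFAULT_DENDROGRAM_CUT
    k_with: int = 5                       # "extra CAP present" solution size
    k_without: int = 4
    n_behavior_perm: int = 200
    n_crossval_perm: int = 50
    seed: int = 0
    out_dir: str = "capdyn_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synthetic.SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns in-memory results and writes artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), default_flow_style=None))
    results: dict = {"config_hash": _config_hash(cfg)}

    # --- stage 1: cohort -------------------------------------------------
    if cfg.cohort_path is None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.sim.seed)
        cohort, gt, behavior, behavior_meta, subjects = synthetic.generate_cohort(sim)
        n_dummy = 0          # synthetic runs are emitted already dummy-trimmed
        results["ground_truth"] = gt
    else:
        cohort, subjects = load_cohort(cfg.cohort_path)
        behavior = behavior_meta = None
        gt = None
        n_dummy = cfg.n_dummy
    cohort = {
        key: preprocess_runs(ts, n_dummy=n_dummy, run_order=cfg.run_order)
        for key, ts in cohort.items()
    }

    # --- stage 2: split-half permutation CAP estimation ------------------
    ledger = cap_estimation.run_permutations(
        cohort, cfg.n_permutations, range(cfg.k_min, cfg.k_max + 1),
        base_seed=cfg.seed, fd_threshold=cfg.fd_threshold,
        silhouette_subsample=cfg.silhouette_subsample,
    )
    results["ledger"] = ledger
    khat = ledger.k_hat_counts()
    results["k_hat_counts"] = khat
    pd.Series(khat, name="count").rename_axis("k_hat").reset_index().to_csv(
        out / "k_hat_counts.tsv", sep="\t", index=False)

    # --- stage 3: basis CAPs ---------------------------------------------
    # label against the richest reproducible solution: k_with when it
    # occurred often enough, else the modal k̂
    modal_k = max(khat, key=lambda k: (khat[k], -k))
    basis_k = cfg.k_with if khat.get(cfg.k_with, 0) >= 2 else modal_k
    basis = basis_mod.label_basis_set(basis_mod.build_basis_set(ledger, basis_k))
    results["basis"] = basis
    pd.DataFrame(basis.patterns.T, columns=basis.labels).to_csv(
        out / "basis_caps.tsv", sep="\t", index=False)

    # --- stage 4: matched temporal metrics --------------------------------
    per_perm = basis_mod.matched_metrics_table(ledger, basis)
    metrics = temporal.aggregate_metrics(per_perm)
    results["metrics"] = metrics
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    # --- stage 5: Δ occurrence -------------------------------------------
    occurrence = basis_mod.occurrence_stats(
        ledger, k_with=cfg.k_with, k_without=cfg.k_without)
    results["occurrence"] = occurrence
    occurrence.to_csv(out / "occurrence.tsv", sep="\t", index=False)

    # --- stage 6: reliability --------------------------------------------
    rel = {
        "icc": reliability.icc_report(metrics),
        "day_r": reliability.day_reliability(metrics),
        "three_axes": reliability.three_axes_table(metrics),
    }
    results["reliability"] = rel
    for name, df in rel.items():
        df.to_csv(out / f"reliability_{name}.tsv", sep="\t", index=False)

    # --- stage 7: feature space ------------------------------------------
    feats = features_mod.build_feature_matrix(metrics)
    subgroup_labels, _ = features_mod.cluster_subgroups(feats, cfg.dendrogram_cut)
    pca_model, loading_rel = features_mod.neural_pca(feats)
    results["features"] = feats
    results["subgroups"] = subgroup_labels
    results["neural_pca"] = pca_model
    results["neural_loading_reliability"] = loading_rel
    feats.to_frame().to_csv(out / "features.tsv", sep="\t")
    subgroup_labels.to_csv(out / "subgroups.tsv", sep="\t")

    # --- stage 8: behavior -----------------------------------------------
    if behavior is not None:
        prepared = neurobehavior.prepare_behavior(behavior, behavior_meta)
        beh_pca = neurobehavior.pca_permutation_test(
            prepared, n_perm=cfg.n_behavior_perm, seed=cfg.seed + 1)
        covariates = subjects.set_index("subject_id")[["age", "sex"]].astype(float)
        neural_scores = pd.DataFrame(
            pca_model.scores[:, :3], index=feats.subject_ids,
            columns=["neural_PC1", "neural_PC2", "neural_PC3"])
        n_sub = len(feats.subject_ids)
        if n_sub >= 15:
            assoc = neurobehavior.fit_association(
                beh_pca["scores"]["PC1"], neural_scores, covariates)
            results["association"] = assoc
            assoc.params.to_csv(out / "association.tsv", sep="\t")
        else:
            logger.warning("cohort too small for the association model; skipped")
            assoc = None
        if cfg.n_crossval_perm > 0 and n_sub >= 20:
            cv = neurobehavior.crossval_predict(
                feats.to_frame(), prepared, covariates,
                n_perm=cfg.n_crossval_perm, seed=cfg.seed + 2)
            results["crossval"] = cv
        else:
            cv = None
        results["behavior_pca"] = beh_pca
        summary_assoc = None if assoc is None else {
            "r_squared": assoc.r_squared,
            "adj_r_squared": assoc.adj_r_squared,
            "f_stat": assoc.f_stat, "f_pvalue": assoc.f_pvalue,
            "heldout_r2_mean": (float(np.mean(cv["heldout_r2"]))
                                if cv is not None and len(cv["heldout_r2"]) else None),
            "null_r2_mean": (float(np.mean(cv["null_r2"]))
                             if cv is not None and len(cv["null_r2"]) else None),
        }
    else:
        summary_assoc = None

    manifest = {
        "config_hash": results["config_hash"],
        "seed": cfg.seed,
        "n_permutations": cfg.n_permutations,
        "n_failed_permutations": ledger.n_failed,
        "k_hat_counts": {int(k): int(v) for k, v in khat.items()},
        "basis_k": int(basis_k),
        "basis_labels": basis.labels,
        "subgroup_sizes": subgroup_labels.value_counts().to_dict(),
        "association": summary_assoc,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
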