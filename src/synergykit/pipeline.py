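"""End-to-end orchestration: data -> activation -> synergies -> statistics.

A run is driven by a :class:`RunConfig` (loadable from YAML) and produces
a directory of per-stage artifacts:

* ``subjects/<id>_W.csv``, ``subjects/<id>_C.csv``, ``subjects/<id>_vaf.csv``
  — per-subject decomposition at the selected synergy number;
* ``reference_synergies.csv``, ``silhouette.csv`` — the clustered
  healthy-group reference set;
* ``matches.csv`` — per subject-synergy classification report;
* ``weight_comparison.csv`` — group comparison of muscle weights per
  reference synergy;
* ``spm.json`` — activation-coefficient curve comparisons per reference
  synergy;
* ``summary.json`` — machine-readable overview of the whole run.

Runs are deterministic for a fixed master seed: per-stage seeds are
derived from it, so a rerun writes byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .activation import ActivationParams, activation_from_emg
from .io import (
    ConfigurationError,
    DataError,
    EMGRecording,
    load_manifest,
    read_trial,
)
from .nnmf import assemble_data_matrix, select_synergy_number
from .preprocess import FilterConfig, compute_mvc_peak, mvc_normalize, preprocess_emg
from .sorting import (
    ReferenceSynergySet,
    match_to_reference,
    select_cluster_number,
    similarity_rate,
)
from .stats import compare_group_weights, spm_compare_curves
from .synthetic import SyntheticDataset, synthesize_dataset

log = logging.getLogger("synergykit")


@dataclass
class RunConfig:
    """All pipeline settings, with defaults reproducing the standard
    landing-analysis protocol (50/30/5 Hz filters, 10 ms delay, A=1.5,
    VAF 90/75 %, r_min 0.6, alpha 0.05, 101 phase points)."""

    out_dir: str = "synergy_run"
    manifest: str | None = None  # None => synthetic dataset
    seed: int = 0
    groups: tuple[str, str] = ("CAI", "healthy")
    reference_group: str = "healthy"
    n_points: int = 101
    # preprocessing
    filters: FilterConfig = field(default_factory=FilterConfig)
    clip_mvc: bool = True
    # activation model
    activation: ActivationParams = field(default_factory=ActivationParams)
    # synergy extraction
    k_max: int = 8
    vaf_g_min: float = 0.90
    vaf_l_min: float = 0.75
    n_restarts: int = 20
    max_iter: int = 1000
    tol: float = 1e-6
    # sorting
    i_range: tuple[int, int] = (2, 8)
    kmeans_n_init: int = 50
    r_min: float = 0.6
    # statistics
    alpha: float = 0.05
    n_perm: int = 10000
    # synthetic dataset (used when manifest is None)
    n_per_group: int = 22
    n_trials: int = 3
    snr_db: float = 20.0

    def validate(self) -> None:
        if not 1 <= self.k_max:
            raise ConfigurationError("k_max must be >= 1")
        if not (0 < self.vaf_g_min <= 1 and 0 < self.vaf_l_min <= 1):
            raise ConfigurationError("VAF thresholds must lie in (0, 1]")
        if self.i_range[0] < 2 or self.i_range[1] < self.i_range[0]:
            raise ConfigurationError(f"bad i_range {self.i_range}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not -1 <= self.r_min <= 1:
            raise ConfigurationError("r_min must lie in [-1, 1]")
        if self.n_points < 2 or self.n_trials < 1 or self.n_per_group < 1:
            raise ConfigurationError("n_points/n_trials/n_per_group out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "filters" in raw:
            raw["filters"] = FilterConfig(**raw["filters"])
        if "activation" in raw:
            raw["activation"] = ActivationParams(**raw["activation"])
        for key in ("groups", "i_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _load_subject_activations(
    cfg: RunConfig,
) -> tuple[dict[str, dict], object | None, tuple[str, ...]]:
    """Build per-subject activation trials either from a manifest of raw
    EMG files or from the synthetic generator. Returns (subjects, ground
    truth or None, muscle names); each subject entry has group + list of
    (m, n_points) matrices."""
    subjects: dict[str, dict] = {}
    if cfg.manifest is None:
        ds: SyntheticDataset = synthesize_dataset(
            n_per_group=cfg.n_per_group,
            n_trials=cfg.n_trials,
            snr_db=cfg.snr_db,
            seed=cfg.seed,
            groups=cfg.groups,
        )
        for sub in ds.subjects:
            subjects[sub.subject_id] = {
                "group": sub.group,
                "trials": [t.values for t in sub.trials],
            }
        return subjects, ds.ground_truth, ds.ground_truth.muscle_names

    manifest = load_manifest(cfg.manifest)
    root = Path(cfg.manifest).parent
    fs = float(manifest.get("fs", 1000.0))
    muscle_names: tuple[str, ...] | None = None
    for sid, entry in manifest["subjects"].items():
        group = entry["group"]
        mvc = read_trial(root / entry["mvc"], fs=fs, subject_id=sid, group=group)
        ref = compute_mvc_peak(mvc, cfg.filters)
        trials = []
        for ti, rel in enumerate(entry["trials"]):
            raw = read_trial(
                root / rel, fs=fs, subject_id=sid, group=group, trial_index=ti
            )
            if muscle_names is None:
                muscle_names = raw.muscle_names
            env = preprocess_emg(raw, cfg.filters)
            norm = mvc_normalize(env, ref, clip_mvc=cfg.clip_mvc)
            act = activation_from_emg(norm, cfg.activation, cfg.n_points)
            trials.append(act.values)
        subjects[sid] = {"group": group, "trials": trials}
    return subjects, None, muscle_names or ()


@dataclass
class PipelineResult:
    """In-memory view of a finished run."""

    config: RunConfig
    rank_results: dict[str, object]
    refs: ReferenceSynergySet
    matches: dict[str, list]
    weight_table: pd.DataFrame
    spm: dict[int, object]
    summary: dict


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage and subject context."""

    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        super().__init__(
            f"stage {stage!r} failed" + (f" for subject {subject}" if subject else "")
            + f": {cause}"
        )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis and write all artifacts to cfg.out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}

    # stage 1: activations ---------------------------------------------------
    t0 = time.time()
    try:
        subjects, gt, muscle_names = _load_subject_activations(cfg)
    except Exception as exc:  # pragma: no cover - error path
        raise StageError("activations", None, exc) from exc
    timings["activations"] = time.time() - t0
    log.info("activations ready for %d subjects (%.1fs)", len(subjects), timings["activations"])

    # stage 2: per-subject NNMF + rank selection -----------------------------
    t0 = time.time()
    ss = np.random.SeedSequence(cfg.seed)
    subject_ids = sorted(subjects)
    stage_seeds = dict(zip(subject_ids, ss.generate_state(len(subject_ids))))
    rank_results = {}
    for sid in subject_ids:
        try:
            V = assemble_data_matrix(subjects[sid]["trials"])
            res = select_synergy_number(
                V,
                k_max=cfg.k_max,
                vaf_g_min=cfg.vaf_g_min,
                vaf_l_min=cfg.vaf_l_min,
                seed=int(stage_seeds[sid] % 2**31),
                n_restarts=cfg.n_restarts,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
                subject_id=sid,
                group=subjects[sid]["group"],
            )
        except Exception as exc:
            raise StageError("nnmf", sid, exc) from exc
        rank_results[sid] = res
        d = res.selected
        pd.DataFrame(d.W, index=list(muscle_names)).to_csv(out / "subjects" / f"{sid}_W.csv")
        pd.DataFrame(d.C).to_csv(out / "subjects" / f"{sid}_C.csv")
        pd.DataFrame(res.vaf_table()).to_csv(out / "subjects" / f"{sid}_vaf.csv", index=False)
    timings["nnmf"] = time.time() - t0
    log.info("NNMF done (%.1fs)", timings["nnmf"])

    # stage 3: reference synergies from the reference group ------------------
    t0 = time.time()
    ref_ids = [s for s in subject_ids if subjects[s]["group"] == cfg.reference_group]
    try:
        D = np.concatenate([rank_results[s].selected.W for s in ref_ids], axis=1)
        refs = select_cluster_number(
            D,
            i_range=range(cfg.i_range[0], cfg.i_range[1] + 1),
            seed=int(ss.generate_state(len(subject_ids) + 1)[-1] % 2**31),
            n_init=cfg.kmeans_n_init,
            muscle_names=muscle_names,
        )
    except Exception as exc:
        raise StageError("sorting", None, exc) from exc
    pd.DataFrame(
        refs.centroids,
        index=list(muscle_names),
        columns=[f"ref{i + 1}" for i in range(refs.n_refs)],
    ).to_csv(out / "reference_synergies.csv")
    pd.DataFrame(
        sorted(refs.silhouette_by_i.items()), columns=["i", "silhouette_mean"]
    ).to_csv(out / "silhouette.csv", index=False)
    timings["sorting"] = time.time() - t0

    # stage 4: classification -----------------------------------------------
    t0 = time.time()
    matches: dict[str, list] = {g: [] for g in cfg.groups}
    rows = []
    for sid in subject_ids:
        d = rank_results[sid].selected
        group = subjects[sid]["group"]
        ms = match_to_reference(
            d.W, refs, r_min=cfg.r_min, C_subject=d.C, subject_id=sid, group=group
        )
        matches[group].extend(ms)
        for m in ms:
            rows.append(
                {
                    "subject": sid,
                    "group": group,
                    "synergy": m.synergy_index + 1,
                    "best_ref": m.best_ref + 1,
                    "r": m.r,
                    "classified": m.classified,
                }
            )
    pd.DataFrame(rows).to_csv(out / "matches.csv", index=False)
    timings["matching"] = time.time() - t0

    # stage 5: group statistics ----------------------------------------------
    t0 = time.time()
    g1, g2 = cfg.groups
    try:
        weight_table = compare_group_weights(
            matches[g1], matches[g2], refs.n_refs, muscle_names,
            alpha=cfg.alpha, group_names=(g1, g2),
        )
    except Exception as exc:
        raise StageError("stats", None, exc) from exc
    weight_table.to_csv(out / "weight_comparison.csv", index=False)

    spm_results = {}
    spm_json: dict[str, dict] = {}
    spm_seed = int(ss.generate_state(len(subject_ids) + 2)[-1] % 2**31)
    for ref in range(refs.n_refs):
        curves = {}
        for g in cfg.groups:
            per_subject = {}
            for m in matches[g]:
                if m.classified and m.best_ref == ref and m.coefficients is not None:
                    cur = per_subject.get(m.subject_id)
                    if cur is None or m.r > cur.r:
                        per_subject[m.subject_id] = m
            curves[g] = np.array(
                [
                    mm.coefficients.reshape(-1, cfg.n_points).mean(axis=0)
                    for mm in per_subject.values()
                ]
            )
        if min(len(curves[g1]), len(curves[g2])) < 3:
            log.warning("reference %d: too few matched subjects for SPM; skipped", ref + 1)
            continue
        res = spm_compare_curves(
            curves[g1], curves[g2], alpha=cfg.alpha, n_perm=cfg.n_perm, seed=spm_seed
        )
        spm_results[ref] = res
        spm_json[f"ref{ref + 1}"] = {
            "threshold": res.threshold,
            "t_curve": [round(v, 6) for v in res.t_curve.tolist()],
            "clusters": [
                {"start_pct": c.start_pct, "end_pct": c.end_pct, "p": c.p}
                for c in res.clusters
            ],
        }
    (out / "spm.json").write_text(json.dumps(spm_json, indent=1, sort_keys=True))
    timings["stats"] = time.time() - t0

    # summary ----------------------------------------------------------------
    summary = {
        "version": _pkg_version,
        "seed": cfg.seed,
        "n_subjects": len(subject_ids),
        "groups": {
            g: sum(1 for s in subject_ids if subjects[s]["group"] == g)
            for g in cfg.groups
        },
        "synergy_numbers": {
            sid: rank_results[sid].n_opt for sid in subject_ids
        },
        "thresholds_not_met": sorted(
            sid for sid in subject_ids if not rank_results[sid].thresholds_met
        ),
        "n_reference_synergies": refs.n_refs,
        "silhouette_by_i": {str(i): round(v, 6) for i, v in refs.silhouette_by_i.items()},
        "similarity_rate": {
            g: round(similarity_rate(matches[g]), 4) for g in cfg.groups if matches[g]
        },
        "significant_weight_cells": int(weight_table["significant"].sum()),
        "spm_significant_refs": sorted(
            int(r) + 1 for r, res in spm_results.items() if res.significant
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("run finished in %.1fs -> %s", time.time() - t_start, out)
    return PipelineResult(
        config=cfg,
        rank_results=rank_results,
        refs=refs,
        matches=matches,
        weight_table=weight_table,
        spm=spm_results,
        summary=summary,
    )
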