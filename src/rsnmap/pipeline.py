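"""End-to-end pipeline: phantom -> templates -> back-reconstruction ->
alteration detection -> lesion overlap -> behaviour models.

A single declarative :class:`RunConfig` (YAML-loadable) drives every stage;
every random operation derives its seed from ``config.seed``, and a manifest
records parameters, seeds and content hashes of every intermediate, so two
runs with the same config produce bit-identical manifests.  Stages write
their outputs under the working directory and are resumable: a stage whose
output file carries the current config hash is loaded instead of recomputed.
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
import yaml

from . import phantom as ph
from .alteration import (
    AlterationResult,
    CSRecord,
    MaskParams,
    build_component_mask,
    control_distribution,
    cosine_similarity,
    patient_alteration_matrix,
    permutation_test,
)
from .backrecon import GigConfig, backreconstruct_all
from .behavior import fit_all_domains
from .grid import write_volume
from .labeling import AtlasPartition, assign_all
from .motion import compare_motion, framewise_displacement
from .overlap import TissuePartition, expected_altered_mask, patient_overlap_report
from .template_ica import GroupDataStack, icasso_stability, reduce_and_concatenate

logger = logging.getLogger("rsnmap")


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one full analysis run."""

    phantom: ph.PhantomConfig = field(default_factory=ph.PhantomConfig)
    n_template_controls: int | None = None  # controls used for the template ICA
    n_icasso_runs: int = 5
    n_subject_pcs: int | None = None  # default: K + 5, capped at T
    z_thresh: float = 1.0
    min_cluster_voxels: int = 10  # phantom-grid scale; full scale uses 200
    exclude_cerebellum: bool = True
    lambda_weight: float = 0.5
    gig_tol: float = 1e-6
    gig_max_iter: int = 1000
    n_perm: int = 50_000
    subsample: int = 200
    sd_mult: float = 3.0
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pcfg = raw.pop("phantom", {})
        lesions = tuple(
            tuple(ph.LesionEffect(**e) for e in patient)
            for patient in pcfg.pop("lesion_spec", [])
        )
        behavior = {
            k: ph.BehaviorSpec(**v) for k, v in pcfg.pop("behavior_spec", {}).items()
        }
        if "grid_shape" in pcfg:
            pcfg["grid_shape"] = tuple(pcfg["grid_shape"])
        phantom_cfg = ph.PhantomConfig(
            lesion_spec=lesions, behavior_spec=behavior, **pcfg
        )
        return cls(phantom=phantom_cfg, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["lesion_spec"] = [
            [dataclasses.asdict(e) for e in patient]
            for patient in self.phantom.lesion_spec
        ]
        d["phantom"]["behavior_spec"] = {
            k: dataclasses.asdict(v) for k, v in self.phantom.behavior_spec.items()
        }
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _hash_array(a: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(str(a.shape).encode())
    h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    config: RunConfig
    truth: ph.PhantomTruth
    templates: list
    assignments: list
    control_cs: list[CSRecord]
    results: list[AlterationResult]
    alteration_matrix: pd.DataFrame
    network_aggregation: pd.DataFrame | None
    overlap_reports: dict[int, dict]
    behavior_models: dict
    motion_pvalue: float
    manifest: dict


def _synthetic_atlas(truth: ph.PhantomTruth) -> AtlasPartition:
    """Partition the brain by the dominant planted network at each voxel.

    Synthetic stand-in for a functional atlas: voxels where some planted map
    exceeds Z = 0.5 are labelled with the argmax component.
    """
    maps = truth.true_maps
    vol = np.zeros(truth.grid.shape, dtype=np.int16)
    strength = truth.grid.devectorize(maps.max(axis=0))
    winner = truth.grid.devectorize((np.argmax(maps, axis=0) + 1).astype(float))
    vol[(strength > 0.5) & truth.grid.mask] = winner[
        (strength > 0.5) & truth.grid.mask
    ].astype(np.int16)
    labels = {k + 1: f"NET{k:02d}" for k in range(maps.shape[0])}
    return AtlasPartition(volume=vol, labels=labels, provenance="phantom argmax atlas")


def run_pipeline(
    config: RunConfig, workdir: str | Path | None = None, resume: bool = False
) -> PipelineResult:
    """Execute every stage on the configured phantom cohort.

    When ``workdir`` is given, volumes, tables and the manifest are written
    beneath it; with ``resume=True`` the expensive back-reconstruction stage
    is reloaded from cache when its config hash matches.
    """
    cfg = config
    out = Path(workdir) if workdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = cfg.content_hash()
    manifest: dict = {"config": cfg.to_dict(), "config_hash": chash, "stages": {}}
    pcfg = cfg.phantom
    K = pcfg.n_components

    # ---- stage: phantom ---------------------------------------------------
    truth = ph.make_template_networks(pcfg)
    controls = [
        truth.grid.vectorize(ph.make_subject_series(truth, "control", i, pcfg))
        for i in range(pcfg.n_controls)
    ]
    patients = [
        truth.grid.vectorize(ph.make_subject_series(truth, "patient", i, pcfg))
        for i in range(pcfg.n_patients)
    ]
    manifest["stages"]["phantom"] = {
        "true_maps": _hash_array(truth.true_maps),
        "controls": [_hash_array(c) for c in controls],
        "patients": [_hash_array(p) for p in patients],
        "planted_altered": {
            str(p): sorted(s) for p, s in truth.true_altered.items()
        },
    }
    if out is not None:
        write_volume(out / "brain_mask.nii", truth.grid.mask, truth.grid)
        write_volume(
            out / "true_maps.nii",
            truth.grid.devectorize(truth.true_maps.T),
            truth.grid,
        )

    # ---- stage: motion QC -------------------------------------------------
    fd_controls = [
        framewise_displacement(ph.make_motion_params(pcfg, "control", i)).mean_fd
        for i in range(pcfg.n_controls)
    ]
    fd_patients = [
        framewise_displacement(ph.make_motion_params(pcfg, "patient", i)).mean_fd
        for i in range(pcfg.n_patients)
    ]
    _, motion_p = compare_motion(np.array(fd_patients), np.array(fd_controls))
    manifest["stages"]["qc_motion"] = {
        "mean_fd_controls": [round(v, 10) for v in fd_controls],
        "mean_fd_patients": [round(v, 10) for v in fd_patients],
        "ranksum_p": round(motion_p, 10),
    }

    # ---- stage: group template ICA ---------------------------------------
    n_tpl = cfg.n_template_controls or pcfg.n_controls
    stack = GroupDataStack(subjects=controls[:n_tpl])
    n_spcs = min(K + 5, pcfg.n_timepoints)
    reduction = reduce_and_concatenate(stack, n_subject_pcs=n_spcs, n_group_pcs=K)
    clusters, templates = icasso_stability(
        reduction.whitened, K, n_runs=cfg.n_icasso_runs, seed=cfg.seed + 101
    )
    manifest["stages"]["template_ica"] = {
        "explained_variance": round(reduction.explained_variance, 10),
        "iq": [round(c.iq, 10) for c in clusters],
        "templates": _hash_array(np.stack([t.map for t in templates])),
    }
    if out is not None:
        write_volume(
            out / "templates.nii",
            truth.grid.devectorize(np.stack([t.map for t in templates]).T),
            truth.grid,
        )
        pd.DataFrame(
            {"id": [t.id for t in templates], "iq": [t.iq for t in templates]}
        ).to_csv(out / "stability.tsv", sep="\t", index=False)

    # ---- stage: network labelling -----------------------------------------
    atlas = _synthetic_atlas(truth)
    assignments = assign_all(templates, [atlas], truth.grid, z_thresh=cfg.z_thresh)
    manifest["stages"]["labeling"] = {
        str(a.component_id): {
            "network": a.network,
            "overlap": round(a.overlap, 10),
            "low_confidence": a.low_confidence,
        }
        for a in assignments
    }

    # ---- stage: back-reconstruction ---------------------------------------
    gig = GigConfig(
        lambda_weight=cfg.lambda_weight,
        tol=cfg.gig_tol,
        max_iter=cfg.gig_max_iter,
        seed=cfg.seed + 202,
    )
    n_pcs = cfg.n_subject_pcs or min(K + 5, pcfg.n_timepoints)
    cache = out / "backrecon_cache.npz" if out is not None else None
    subj_maps: dict[str, np.ndarray] | None = None
    if resume and cache is not None and cache.exists():
        loaded = np.load(cache, allow_pickle=False)
        if str(loaded.get("config_hash")) == chash:
            subj_maps = {
                k[4:]: loaded[k] for k in loaded.files if k.startswith("map:")
            }
            logger.info("back-reconstruction stage loaded from cache")
    if subj_maps is None:
        subj_maps = {}
        for sid, series in [
            (f"control-{i:02d}", c) for i, c in enumerate(controls)
        ] + [(f"patient-{i:02d}", p) for i, p in enumerate(patients)]:
            maps = backreconstruct_all(series, templates, gig, n_pcs=n_pcs)
            subj_maps[sid] = np.stack([m.map for m in maps])
        if cache is not None:
            np.savez(
                cache,
                config_hash=np.array(chash),
                **{f"map:{k}": v for k, v in subj_maps.items()},
            )
    manifest["stages"]["backrecon"] = {
        k: _hash_array(v) for k, v in sorted(subj_maps.items())
    }

    # ---- stage: alteration detection --------------------------------------
    params = MaskParams(
        z_thresh=cfg.z_thresh,
        min_cluster_voxels=cfg.min_cluster_voxels,
        exclusion_mask=truth.cerebellum_mask if cfg.exclude_cerebellum else None,
    )
    cmasks = {t.id: build_component_mask(t, truth.grid, params) for t in templates}
    control_cs: list[CSRecord] = []
    for i in range(pcfg.n_controls):
        sid = f"control-{i:02d}"
        for t in templates:
            if cmasks[t.id].usable:
                control_cs.append(
                    cosine_similarity(
                        t.map, subj_maps[sid][t.id], cmasks[t.id], truth.grid, sid
                    )
                )
    dists = {
        t.id: control_distribution(control_cs, t.id)
        for t in templates
        if cmasks[t.id].usable
    }
    results: list[AlterationResult] = []
    for i in range(pcfg.n_patients):
        sid = f"patient-{i:02d}"
        for t in templates:
            if not cmasks[t.id].usable:
                continue
            rec = cosine_similarity(
                t.map, subj_maps[sid][t.id], cmasks[t.id], truth.grid, sid
            )
            results.append(
                permutation_test(
                    rec,
                    dists[t.id],
                    n_perm=cfg.n_perm,
                    subsample=cfg.subsample,
                    sd_mult=cfg.sd_mult,
                    alpha=cfg.alpha,
                    seed=int(
                        np.random.default_rng(
                            [cfg.seed & 0x7FFFFFFF, 303, i, t.id]
                        ).integers(2**31)
                    ),
                )
            )
    networks = {a.component_id: a.network for a in assignments}
    matrix, aggregation = patient_alteration_matrix(results, networks)
    manifest["stages"]["detect"] = {
        "cs_controls": {
            str(c): round(float(d.mean), 10) for c, d in sorted(dists.items())
        },
        "results": [
            {
                "patient": r.patient_id,
                "component": r.component_id,
                "cs": round(r.cs, 10),
                "delta_cs_sigma": round(r.delta_cs_sigma, 10),
                "flagged_fraction": round(r.flagged_fraction, 10),
                "significant": bool(r.significant),
            }
            for r in results
        ],
    }
    if out is not None:
        matrix.to_csv(out / "alteration_matrix.tsv", sep="\t")
        if aggregation is not None:
            aggregation.to_csv(out / "network_aggregation.tsv", sep="\t")

    # ---- stage: lesion overlap --------------------------------------------
    overlap_reports: dict[int, dict] = {}
    for i in range(pcfg.n_patients):
        sid = f"patient-{i:02d}"
        altered_ids = [
            r.component_id for r in results if r.patient_id == sid and r.significant
        ]
        if i not in truth.lesion_masks:
            logger.info("%s: no lesion mask, overlap stage skipped", sid)
            continue
        if not altered_ids:
            logger.info("%s: no altered components, overlap stage skipped", sid)
            continue
        tm, tm_o = truth.lesion_masks[i]
        partition = TissuePartition(tm=tm, tm_o=tm_o, brain=truth.grid.mask)
        altered = expected_altered_mask(altered_ids, templates, truth.grid, params)
        overlap_reports[i] = patient_overlap_report(altered, partition)
    manifest["stages"]["overlap"] = {
        str(p): {
            name: {k: round(v, 10) for k, v in row.items()}
            for name, row in rep.items()
        }
        for p, rep in overlap_reports.items()
    }

    # ---- stage: behaviour models ------------------------------------------
    behavior_models: dict = {}
    if pcfg.n_patients >= 5 and truth.true_behavior_coefs:
        delta = np.array(
            [
                [
                    r.delta_cs_sigma
                    for r in results
                    if r.patient_id == f"patient-{i:02d}"
                ]
                for i in range(pcfg.n_patients)
            ]
        )
        # planted coefficients are indexed by *truth* components; translate
        # them into template order via map matching
        perm, _ = ph.match_components(
            np.stack([t.map for t in templates]), truth.true_maps
        )
        coef_truth = {
            d: np.asarray(s.coefs, dtype=float)
            for d, s in truth.true_behavior_coefs.items()
        }
        spec_template = {}
        for d, s in truth.true_behavior_coefs.items():
            coefs_t = np.zeros(K)
            coefs_t[perm] = coef_truth[d]
            spec_template[d] = ph.BehaviorSpec(
                coefs=tuple(coefs_t), intercept=s.intercept, noise_sd=s.noise_sd
            )
        scores = ph.make_behavior_scores(_with_coefs(truth, spec_template), delta, pcfg)
        behavior_models = fit_all_domains(
            delta, scores, n_boot=cfg.n_boot, seed=cfg.seed + 404
        )
        manifest["stages"]["behavior"] = {
            d: {
                "support": list(m.support),
                "r_squared": round(m.r_squared, 10),
                "accepted": bool(m.accepted),
            }
            for d, m in behavior_models.items()
        }
    else:
        logger.info(
            "behaviour stage skipped (need >= 5 patients and a behaviour spec)"
        )
        manifest["stages"]["behavior"] = "skipped"

    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)

    return PipelineResult(
        config=cfg,
        truth=truth,
        templates=templates,
        assignments=assignments,
        control_cs=control_cs,
        results=results,
        alteration_matrix=matrix,
        network_aggregation=aggregation,
        overlap_reports=overlap_reports,
        behavior_models=behavior_models,
        motion_pvalue=motion_p,
        manifest=manifest,
    )


def _with_coefs(truth: ph.PhantomTruth, spec: dict) -> ph.PhantomTruth:
    """Shallow copy of the truth with behaviour coefficients replaced."""
    clone = ph.PhantomTruth(
        grid=truth.grid,
        cerebellum_mask=truth.cerebellum_mask,
        node_maps=truth.node_maps,
        true_maps=truth.true_maps,
        lesion_masks=truth.lesion_masks,
        true_altered=truth.true_altered,
        true_behavior_coefs=spec,
        timecourses=truth.timecourses,
    )
    return clone
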