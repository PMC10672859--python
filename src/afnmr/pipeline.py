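"""End-to-end analysis pipeline and run report.

Binds the stages into one workflow:

    calibrate -> baseline -> exclude -> align -> PQN -> bucket
    -> annotate -> unique filter -> score -> promote
    -> Pareto + PCA (annotated buckets) + PLS-DA (winner buckets)
    -> cross-validation + permutation test -> pathway ORA

and produces a machine-readable run report (funnel counts, promoted
metabolites with direction/AUROC/p/VIP, model metrics, pathway table,
and provenance: seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import biomarkers as bm
from . import mvstats, pathway, preprocess
from .pathway import PathwayDB
from .preprocess import SpectraMatrix
from .synth import MetaboliteSpec, build_default_library

__all__ = ["PipelineConfig", "analyze", "run_report_json"]

log = logging.getLogger("afnmr.pipeline")


@dataclass
class PipelineConfig:
    """All tunable parameters of an analysis run."""

    # calibration / baseline
    ref_ppm: float = 0.0
    calib_window: float = 0.2
    baseline_smoothness: float = 1e7
    baseline_asymmetry: float = 1e-3
    # exclusion / alignment
    excluded_regions: list[tuple[float, float]] = field(
        default_factory=lambda: [(4.5, 5.0)]
    )
    align_min_width: float = 0.1
    align_max_shift: int = 25
    # bucketing
    bucket_region: tuple[float, float] = (0.8, 8.5)
    bucket_min_width: float = 0.01
    bucket_max_width: float = 0.5
    snr_min: float = 3.0
    noise_region: tuple[float, float] = (9.5, 10.0)
    # annotation / promotion
    annotation_tolerance: float = 0.02
    auroc_min: float = 0.75
    p_max: float = 0.05
    # multivariate
    ncomp: int = 3
    vip_min: float = 1.0
    cv_folds: int = 10
    n_perm: int = 1000
    # pathway
    pathway_p: float = 0.05
    impact_threshold: float = 0.1
    pathway_family_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.auroc_min < 1.0:
            raise ValueError("auroc_min must be in [0.5, 1)")
        for name in ("p_max", "pathway_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_regions"] = [list(r) for r in self.excluded_regions]
        d["bucket_region"] = list(self.bucket_region)
        d["noise_region"] = list(self.noise_region)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "excluded_regions" in d:
            d["excluded_regions"] = [tuple(r) for r in d["excluded_regions"]]
        for key in ("bucket_region", "noise_region"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def analyze(
    matrix: SpectraMatrix,
    config: PipelineConfig | None = None,
    library: list[MetaboliteSpec] | None = None,
    pathway_db: PathwayDB | None = None,
) -> dict:
    """Run the full analysis on a calibrated-or-raw spectra matrix and
    return the run report as a plain dict (JSON-serializable)."""
    cfg = config or PipelineConfig()
    lib = library or build_default_library()
    db = pathway_db or pathway.build_default_pathway_db()

    from .synth import Spectrum

    @_stage("calibrate")
    def s_calibrate(m: SpectraMatrix) -> SpectraMatrix:
        out = m.copy()
        for i in range(out.intensities.shape[0]):
            sp = Spectrum(out.ppm, out.intensities[i], out.sample_ids[i],
                          out.groups[i])
            out.intensities[i] = preprocess.calibrate_to_reference(
                sp, cfg.ref_ppm, cfg.calib_window
            ).intensity
        return out

    @_stage("baseline")
    def s_baseline(m):
        return preprocess.baseline_correct(
            m, cfg.baseline_smoothness, cfg.baseline_asymmetry
        )

    @_stage("exclude")
    def s_exclude(m):
        return preprocess.exclude_regions(m, cfg.excluded_regions)

    @_stage("align")
    def s_align(m):
        return preprocess.align_spectra(m, cfg.align_min_width, cfg.align_max_shift)

    @_stage("pqn")
    def s_pqn(m):
        return preprocess.pqn_normalize(m)

    @_stage("bucket")
    def s_bucket(m):
        return preprocess.intelligent_bucket(
            m, cfg.bucket_region, cfg.bucket_min_width, cfg.bucket_max_width,
            cfg.snr_min, cfg.noise_region,
        )

    mat = s_pqn(s_align(s_exclude(s_baseline(s_calibrate(matrix)))))[0]
    buckets = s_bucket(mat)

    annotation = bm.annotate_buckets(buckets, lib, cfg.annotation_tolerance)
    unique_idx, n_unique_mets = bm.unique_bucket_filter(annotation)
    records = bm.score_buckets(buckets, annotation)
    promo = bm.promote_biomarkers(records, cfg.auroc_min, cfg.p_max)

    # multivariate overview on all annotated buckets
    ann_idx = sorted(annotation.assignments)
    pca_model = None
    if len(ann_idx) >= 3:
        scaled_ann = mvstats.pareto_scale(buckets.values[:, ann_idx])
        pca_model = mvstats.pca_fit(scaled_ann, ncomp=2)

    # discriminant model on the winner buckets
    winners = sorted(promo.winners.values(), key=lambda r: -r.auroc)
    model_metrics: dict = {}
    perm_p = None
    vip_by_met: dict[str, float] = {}
    if len(winners) >= 2:
        widx = [r.bucket_index for r in winners]
        scaled = mvstats.pareto_scale(buckets.values[:, widx])
        model = mvstats.plsda_fit(scaled, buckets.groups, ncomp=cfg.ncomp)
        folds = min(cfg.cv_folds, buckets.groups.count("preterm"),
                    buckets.groups.count("term"))
        q2, acc = mvstats.cross_validate(
            scaled, buckets.groups, ncomp=cfg.ncomp, folds=folds, seed=cfg.seed
        )
        model.q2_cum, model.cv_accuracy = q2, acc
        perm = mvstats.permutation_test(
            scaled, buckets.groups, ncomp=cfg.ncomp, n_perm=cfg.n_perm,
            seed=cfg.seed,
        )
        perm_p = perm.p_value
        vip_by_met = {r.metabolite: float(v) for r, v in zip(winners, model.vip)}
        model_metrics = {
            "ncomp": model.ncomp,
            "r2x_cum": model.r2x_cum,
            "r2y_cum": model.r2y_cum,
            "q2_cum": q2,
            "cv_accuracy": acc,
            "permutation_p": perm_p,
            "n_perm": cfg.n_perm,
        }

    # pathway ORA on the promoted metabolites
    pathway_rows = []
    if promo.winners:
        query = set(promo.winners) & db.universe
        if query:
            rows = pathway.ora_hypergeometric(query, db)
            table = pathway.pathway_table(
                rows, cfg.pathway_p, cfg.impact_threshold,
                cfg.pathway_family_size,
            )
            pathway_rows = table.to_dict(orient="records")

    funnel = {
        "buckets_total": len(buckets.buckets),
        "buckets_annotated": len(annotation.assignments),
        "buckets_unique": len(unique_idx),
        "unique_metabolites": n_unique_mets,
        "buckets_passing": len(promo.passing),
        "winners": len(promo.winners),
    }
    vals = [funnel["buckets_total"], funnel["buckets_annotated"],
            funnel["buckets_unique"], funnel["buckets_passing"],
            funnel["winners"]]
    assert all(a >= b for a, b in zip(vals, vals[1:])), "funnel must be non-increasing"

    report = {
        "funnel": funnel,
        "promoted": [
            {
                "metabolite": r.metabolite,
                "bucket": list(r.bucket),
                "auroc": r.auroc,
                "p_value": r.p_value,
                "direction": r.direction,
                "vip": vip_by_met.get(r.metabolite),
            }
            for r in winners
        ],
        "model": model_metrics,
        "pca_explained": (
            pca_model.explained_variance_fraction.tolist() if pca_model else None
        ),
        "pathways": pathway_rows,
        "provenance": {
            "seed": cfg.seed,
            "config_sha256": cfg.digest(),
            "n_samples": len(buckets.sample_ids),
            "n_term": buckets.groups.count("term"),
            "n_preterm": buckets.groups.count("preterm"),
        },
    }
    return report


def run_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
        fh.write("\n")
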