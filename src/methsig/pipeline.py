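"""End-to-end orchestration: preprocess -> denoise -> differential
methylation -> module detection -> signature -> validity -> classifier
evaluation, with per-stage accounting in one summary.

A single master seed fans out to the stochastic stages (k-means baseline,
cross-validation) through a fixed seed-sequence derivation, so a rerun
with the same config and inputs is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import denoise as _denoise
from . import diffmeth as _diffmeth
from . import evalclf as _evalclf
from . import methio
from . import netmodules as _netmodules
from . import preprocess as _preprocess
from . import signature as _signature
from . import validity as _validity
from .errors import StageError, ValidationError
from .methio import AnnotationMap, BetaMatrix
from .preprocess import GeneMatrix


@dataclass
class RunConfig:
    """All stage parameters with their reference defaults."""

    # inputs (optional when matrices are passed in memory)
    beta_path: str | None = None
    annotation_path: str | None = None
    labels_path: str | None = None
    beta_format: str | None = None
    gene_column: str = "UCSC_RefGene_Name"
    # preprocess
    id_prefix_blacklist: tuple = ("rs", "ch")
    drop_constant_rows: bool = False
    # denoise
    min_pts: int = 5
    knn_k: int = 4
    derivative_threshold: float = 1.0
    eps: float | None = None
    eps_scale: str = "raw"
    keep_border: bool = True
    # differential methylation
    voom: bool = True
    voom_scale: float = 1e6
    alpha: float = 0.05
    fdr: str | None = None
    # modules
    powers: tuple = tuple(range(1, 21))
    fit_target: float = 0.8
    min_module_size: int = 10
    cut_height: float = 0.99
    # signature
    tie_tol: float = 1e-3
    # evaluation
    cv_k: int = 2
    cv_repeats: int = 10
    # misc
    seed: int = 17
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        for key in ("id_prefix_blacklist", "powers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    gene_matrix: GeneMatrix
    clean_matrix: GeneMatrix
    knee: _denoise.KneeResult | None
    dbscan: _denoise.DbscanResult
    dm_table: pd.DataFrame
    power: _netmodules.PowerSelection
    network: _netmodules.Network
    assignment: _netmodules.ModuleAssignment
    scores: list
    signature: _signature.Signature
    validity: _validity.ValidityReport | None
    validity_kmeans: _validity.ValidityReport | None
    cv: _evalclf.CVReport
    summary: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig, beta: BetaMatrix | None = None,
                 annotation: AnnotationMap | None = None) -> PipelineResult:
    """Run the whole flow; returns the stage objects plus a summary dict.

    Inputs come either from the config's paths or as in-memory objects.
    When ``config.out_dir`` is set, result tables and the JSON summary
    are written there.
    """
    summary: dict = {"parameters": _config_dict(config)}

    beta, annotation = _stage("load")(_load)(config, beta, annotation)

    g, counts = _stage("preprocess")(_preprocess.run_preprocess)(
        beta, annotation, blacklist=config.id_prefix_blacklist,
        drop_constant_rows=config.drop_constant_rows)
    summary["preprocess"] = counts

    clean, dbres, knee = _stage("denoise")(_denoise.run_denoise)(
        g, min_pts=config.min_pts, knn_k=config.knn_k,
        derivative_threshold=config.derivative_threshold,
        eps=config.eps, eps_scale=config.eps_scale,
        keep_border=config.keep_border)
    summary["denoise"] = {
        "eps": dbres.eps,
        "knee_index": None if knee is None else knee.knee_index,
        **dbres.counts(),
        "kept": clean.n_genes,
        "input_genes": g.n_genes,
    }

    design = _stage("diffmeth")(_diffmeth.design_from_matrix)(clean)
    dm_table = _stage("diffmeth")(_diffmeth.run_diffmeth)(
        clean, design, voom=config.voom, alpha=config.alpha,
        fdr=config.fdr, voom_scale=config.voom_scale)
    dm_genes = dm_table.loc[dm_table["dm"], "gene"].tolist()
    directions = dict(zip(dm_table["gene"], dm_table["direction"]))
    n_hyper = int((dm_table["dm"] & (dm_table["direction"] == _diffmeth.HYPER)).sum())
    n_hypo = int((dm_table["dm"] & (dm_table["direction"] == _diffmeth.HYPO)).sum())
    summary["diffmeth"] = {"dm_total": len(dm_genes), "hyper": n_hyper, "hypo": n_hypo}

    dm_matrix = clean.restrict_to(dm_genes)
    power = _stage("modules")(_netmodules.pick_power)(
        dm_matrix, candidates=config.powers, fit_target=config.fit_target)
    network = _stage("modules")(_netmodules.tom_from_matrix)(dm_matrix, power.power)
    assignment = _stage("modules")(_netmodules.cut_modules)(
        network, min_module_size=config.min_module_size,
        cut_height=config.cut_height)
    grey_n = int((assignment.colors == _netmodules.GREY).sum())
    summary["modules"] = {
        "power": power.power,
        "scale_free_r2": power.achieved_r2,
        "sizes": dict(assignment.module_sizes),
        "grey": grey_n,
    }

    scores = _stage("signature")(_signature.score_modules)(dm_matrix, assignment)
    sig = _stage("signature")(_signature.select_signature)(
        scores, assignment, directions, tie_tol=config.tie_tol)
    summary["signature"] = {
        "module": sig.color,
        "size": len(sig.genes),
        "scores": {s.color: s.avg_pcc for s in scores},
        "hyper": sum(1 for d in sig.directions.values() if d == _diffmeth.HYPER),
        "hypo": sum(1 for d in sig.directions.values() if d == _diffmeth.HYPO),
    }

    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2 ** 31)
    validity = validity_km = None
    assigned = assignment.colors != _netmodules.GREY
    labels = assignment.colors[assigned]
    if len(set(labels)) >= 2:
        pts = dm_matrix.values[assigned]
        validity = _stage("validity")(_validity.compute_validity)(pts, labels)
        km_labels = _validity.kmeans_baseline(pts, len(set(labels)), int(seeds[0]))
        if len(set(km_labels)) >= 2:
            validity_km = _stage("validity")(_validity.compute_validity)(pts, km_labels)
        summary["validity"] = {
            "modules": validity.to_dict(),
            "kmeans": None if validity_km is None else validity_km.to_dict(),
        }
    else:
        summary["validity"] = None

    sig_matrix = clean.restrict_to(sig.genes)
    cv = _stage("evaluate")(_evalclf.evaluate_signature)(
        sig_matrix, k=config.cv_k, repeats=config.cv_repeats, seed=int(seeds[1]))
    summary["evaluation"] = cv.to_dict()

    result = PipelineResult(g, clean, knee, dbres, dm_table, power, network,
                            assignment, scores, sig, validity, validity_km,
                            cv, summary)
    if config.out_dir:
        _write(result, config.out_dir, knee)
    return result


def _load(config, beta, annotation):
    if beta is None:
        if config.beta_path is None:
            raise ValidationError("no beta matrix: set beta_path or pass one in memory")
        beta = methio.read_beta_matrix(config.beta_path, format=config.beta_format)
    if beta.groups is None:
        if config.labels_path is None:
            raise ValidationError("beta matrix has no labels and labels_path is unset")
        beta = beta.with_groups(methio.read_labels(config.labels_path))
    if annotation is None:
        if config.annotation_path is None:
            raise ValidationError("no annotation: set annotation_path or pass one in memory")
        annotation = methio.read_annotation(config.annotation_path,
                                            gene_column=config.gene_column)
    return beta, annotation


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["id_prefix_blacklist"] = list(config.id_prefix_blacklist)
    d["powers"] = list(config.powers)
    return d


def _write(result: PipelineResult, out_dir, knee) -> None:
    tables = {
        "dm_stats": result.dm_table,
        "modules": pd.DataFrame({
            "gene": result.assignment.gene_ids,
            "module": result.assignment.colors,
        }),
        "module_scores": pd.DataFrame(
            [{"module": s.color, "size": s.size, "avg_pcc": s.avg_pcc}
             for s in result.scores]),
        "signature": pd.DataFrame({
            "gene": result.signature.genes,
            "direction": [result.signature.directions[g] for g in result.signature.genes],
            "module": result.signature.color,
        }),
        "dbscan_labels": pd.DataFrame({
            "gene": result.gene_matrix.gene_ids,
            "cluster": result.dbscan.labels,
            "point_type": result.dbscan.point_type,
        }),
        "cv_per_repeat": result.cv.per_repeat,
    }
    if knee is not None:
        tables["knn_curve"] = pd.DataFrame({
            "rank": np.arange(knee.sorted_distances.size),
            "distance": knee.sorted_distances,
            "scaled_distance": knee.scaled_distances,
        })
    methio.write_results(tables, out_dir, summary=result.summary)
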