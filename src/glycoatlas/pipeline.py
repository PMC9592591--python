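"""Configuration model and the end-to-end profiling pipeline.

``run_pipeline`` executes the computational stages of the atlas
workflow in order — annotate, quantify, filter, matrix, glycotype,
cluster, classify — from peak lists (real or synthetic) under a single
validated configuration, and optionally writes every artifact with a
manifest (config hash, seed, package versions, stage log).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .annotation import PeakList, Tolerance, CompositionBounds, annotate_peaklist
from .classification import ALGORITHMS, evaluate
from .core import DerivatizationModel, GlycanComposition, ResidueMassTable, parse_composition
from .glycotyping import class_averages, summarize
from .profiling import cut_and_purity, to_newick, ward_cluster, zscore
from .quantification import (
    QuantitationError,
    build_matrix,
    detection_filter,
    profile_summary,
    quant_table,
    quantify,
)

logger = logging.getLogger("glycoatlas")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MassesConfig(_Section):
    hex: float = ResidueMassTable().hex
    hexnac: float = ResidueMassTable().hexnac
    dhex: float = ResidueMassTable().dhex
    neu5ac: float = ResidueMassTable().neu5ac
    neu5gc: float = ResidueMassTable().neu5gc
    water: float = ResidueMassTable().water
    proton: float = ResidueMassTable().proton
    sodium: float = ResidueMassTable().sodium


class DerivatizationConfig(_Section):
    tag_delta: float = 0.0
    methyl_delta: float = 14.01565
    adduct: str = "protonated"
    charge: int = 1


class AnnotationConfig(_Section):
    tolerance: float = 0.1
    tolerance_unit: str = "da"
    h_bounds: tuple[int, int] = (3, 12)
    n_bounds: tuple[int, int] = (2, 10)
    d_bounds: tuple[int, int] = (0, 5)
    a_bounds: tuple[int, int] = (0, 5)
    g_bounds: tuple[int, int] = (0, 5)
    de_novo: bool = True


class QuantificationConfig(_Section):
    is_amount: float = 10.0  # pmol spiked in the glycoblotting step
    min_detections: int = 3
    filter_scope: str = "within-any-group"


class GlycotypingConfig(_Section):
    exceptions: dict[str, str] = Field(default_factory=dict)


class ClusteringConfig(_Section):
    distance: str = "canberra"
    ward_variant: str = "ward.D2"
    k: int = 18


class ClassificationConfig(_Section):
    algorithms: list[str] = Field(default_factory=lambda: list(ALGORITHMS))
    n_reps: int = 1000
    tune: bool = True
    cv_folds: int = 3


class PipelineConfig(_Section):
    """Fully validated pipeline configuration; unknown keys are rejected."""

    masses: MassesConfig = Field(default_factory=MassesConfig)
    derivatization: DerivatizationConfig = Field(default_factory=DerivatizationConfig)
    annotation: AnnotationConfig = Field(default_factory=AnnotationConfig)
    quantification: QuantificationConfig = Field(default_factory=QuantificationConfig)
    glycotyping: GlycotypingConfig = Field(default_factory=GlycotypingConfig)
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)
    classification: ClassificationConfig = Field(default_factory=ClassificationConfig)
    seed: int = 0

    def mass_table(self) -> ResidueMassTable:
        return ResidueMassTable(**self.masses.model_dump())

    def derivatization_model(self) -> DerivatizationModel:
        return DerivatizationModel(**self.derivatization.model_dump())

    def tolerance(self) -> Tolerance:
        return Tolerance(self.annotation.tolerance, self.annotation.tolerance_unit)

    def bounds(self) -> CompositionBounds:
        a = self.annotation
        return CompositionBounds(a.h_bounds, a.n_bounds, a.d_bounds, a.a_bounds, a.g_bounds)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    peaklists: Sequence[PeakList],
    library: Sequence[GlycanComposition] = (),
    out_dir: str | Path | None = None,
) -> dict:
    """Run annotate -> quantify -> filter -> matrix -> glycotype ->
    cluster -> classify and return all artifacts.

    Returns a dict with keys ``quant_table, retained, tally, matrix,
    scaled, glycotype_summary, glycotype_class_averages,
    profile_per_replicate, profile_per_class, clustering, groups,
    purity, evaluation, manifest``.  When *out_dir* is given every
    table is also written there along with ``manifest.json``.
    """
    from .io import write_matrix, write_quant_table

    model = config.derivatization_model()
    masses = config.mass_table()
    tol = config.tolerance()
    bounds = config.bounds()
    stages: list[dict] = []
    artifacts: dict = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s completed", name)
        return result

    def _annotate():
        out = []
        for pl in peaklists:
            anns = annotate_peaklist(
                pl, model, library, tol, bounds, masses,
                de_novo=config.annotation.de_novo,
            )
            out.append((pl, anns))
        n_assigned = sum(1 for _, anns in out for a in anns if a.assigned)
        n_peaks = sum(len(anns) for _, anns in out)
        stages.append({"stage": "annotate", "peaks": n_peaks, "assigned": n_assigned})
        return out

    annotated = stage("annotate", _annotate)

    def _quantify():
        recs = [
            (pl, quantify(pl, anns, is_amount=config.quantification.is_amount))
            for pl, anns in annotated
        ]
        table = quant_table(recs)
        stages.append({"stage": "quantify", "records": len(table)})
        return table

    table = stage("quantify", _quantify)

    def _filter():
        retained, tally = detection_filter(
            table,
            min_detections=config.quantification.min_detections,
            scope=config.quantification.filter_scope,
        )
        stages.append(
            {"stage": "filter", "in": int(tally.shape[0]), "retained": len(retained)}
        )
        return retained, tally

    retained, tally = stage("filter", _filter)

    def _matrix():
        m = build_matrix(table, retained)
        stages.append({"stage": "matrix", "samples": m.n_samples, "glycoforms": m.n_glycoforms})
        return m

    matrix = stage("matrix", _matrix)

    def _glycotype():
        summary = summarize(matrix, config.glycotyping.exceptions)
        stages.append({"stage": "glycotype", "rows": len(summary)})
        return summary

    summary = stage("glycotype", _glycotype)

    def _cluster():
        result = ward_cluster(
            matrix,
            distance=config.clustering.distance,
            variant=config.clustering.ward_variant,
        )
        k = min(config.clustering.k, matrix.n_samples)
        groups, purity = cut_and_purity(result, k)
        stages.append({"stage": "cluster", "k": k, "pure_groups": purity.attrs["n_pure"]})
        return result, groups, purity

    clustering, groups, purity = stage("cluster", _cluster)

    def _classify():
        report = evaluate(
            matrix,
            algorithms=config.classification.algorithms,
            n_reps=config.classification.n_reps,
            seed=config.seed,
            tune=config.classification.tune,
            cv_folds=config.classification.cv_folds,
        )
        stages.append({"stage": "classify", "n_reps": report.n_reps})
        return report

    report = stage("classify", _classify)

    per_replicate, per_class = profile_summary(matrix)
    scaled = zscore(matrix) if matrix.n_samples >= 2 else None

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": stages,
    }
    artifacts.update(
        quant_table=table,
        retained=retained,
        tally=tally,
        matrix=matrix,
        scaled=scaled,
        glycotype_summary=summary,
        glycotype_class_averages=class_averages(summary),
        profile_per_replicate=per_replicate,
        profile_per_class=per_class,
        clustering=clustering,
        groups=groups,
        purity=purity,
        evaluation=report,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_quant_table(table, out / "quant_table.tsv")
        write_matrix(matrix, out / "matrix.csv")
        summary.to_csv(out / "glycotype_summary.csv", index=False)
        per_class.to_csv(out / "profile_per_class.csv", index=False)
        groups.to_csv(out / "cluster_groups.csv", index=False)
        purity.drop(columns=[]).to_csv(out / "cluster_purity.csv", index=False)
        (out / "dendrogram.nwk").write_text(to_newick(clustering))
        report.per_class.to_csv(out / "evaluation_per_class.csv", index=False)
        report.overall.to_csv(out / "evaluation_overall.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts
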