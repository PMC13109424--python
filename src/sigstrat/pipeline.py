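"""End-to-end composition of the stratification stages.

Order of operations: per-caller catalogs -> rare-spectrum removal (computed
on the reference caller's 96-channel catalog, applied to all callers) ->
de novo extraction -> per-caller K-means on relative exposures ->
cross-caller label alignment and stable-sample intersection -> optional
reference-signature attribution with CI pruning on the stable set.

Two modes supply per-caller exposures: ``per_caller_extraction=True`` runs
the full replicated NMF once per caller (the heavyweight, faithful mode);
the default refits each caller's catalog by NNLS against the consensus
de novo signatures extracted from the reference caller, which is
deterministic and an order of magnitude cheaper while exercising the same
cross-caller disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import TranscriptAnnotation, build_catalog, collapse
from .clustering import (
    ClusterAssignment,
    ConsensusAssignment,
    align_and_intersect,
    kmeans_exposures,
)
from .config import RunConfig, log_stage, stage_seed
from .extraction import ExtractionReport, _nnls_exposures, extract
from .outlier_filter import SpectrumClusterReport, remove_rare_spectra
from .refit import FitResult, attribute_catalog
from .types import ExposureMatrix, MutationCatalog, SignatureMatrix, VariantCall


@dataclass
class PipelineResult:
    catalogs: dict[str, MutationCatalog]
    rare_samples: list[str]
    rare_report: SpectrumClusterReport | None
    extraction: ExtractionReport
    assignments: list[ClusterAssignment]
    consensus: ConsensusAssignment
    fit_results: list[FitResult] | None = None
    fit_exposures: ExposureMatrix | None = None


def run_pipeline(caller_calls: dict[str, list[VariantCall]], genome,
                 annotation: TranscriptAnnotation, config: RunConfig,
                 reference: SignatureMatrix | None = None,
                 per_caller_extraction: bool = False,
                 sample_ids: list[str] | None = None) -> PipelineResult:
    """Run catalog -> filter -> extract -> cluster -> consensus (-> refit)."""
    callers = sorted(caller_calls)
    if len(callers) < 2:
        raise ValueError("pipeline needs at least two callers")
    catalogs = {
        c: build_catalog(caller_calls[c], genome, annotation,
                         config.channel_schema, sample_ids=sample_ids)
        for c in callers
    }
    ref_caller = callers[0]
    filtered_ref, rare_report = remove_rare_spectra(
        catalogs[ref_caller], burden_threshold=config.burden_threshold,
        rare_max_size=config.rare_max_size,
        cut_distance=config.cut_distance)
    rare = rare_report.rare_samples if rare_report else []
    catalogs = {c: cat.drop(rare) for c, cat in catalogs.items()}
    log_stage("pipeline", n_rare_removed=len(rare),
              n_samples=catalogs[ref_caller].n_samples)

    report = extract(catalogs[ref_caller], config.ks,
                     n_replicates=config.n_nmf_replicates,
                     seed=stage_seed(config.seed, f"extract:{ref_caller}"),
                     max_iter=config.nmf_max_iter, tol=config.nmf_tol,
                     stability_floor=config.stability_floor,
                     min_cosine_gain=config.min_cosine_gain)
    k = report.chosen_k if config.kmeans_k == "auto" else int(config.kmeans_k)
    signatures = report.chosen.signatures

    assignments = []
    for c in callers:
        if per_caller_extraction and c != ref_caller:
            rep_c = extract(catalogs[c], [report.chosen_k],
                            n_replicates=config.n_nmf_replicates,
                            seed=stage_seed(config.seed, f"extract:{c}"),
                            max_iter=config.nmf_max_iter, tol=config.nmf_tol)
            exposures = rep_c.chosen.exposures
        else:
            keep = catalogs[c].totals() > 0
            kept_ids = [s for s, k_ in zip(catalogs[c].sample_ids, keep) if k_]
            acts = _nnls_exposures(signatures.profiles,
                                   catalogs[c].subset(kept_ids).counts)
            exposures = ExposureMatrix(kept_ids,
                                       list(signatures.signature_ids), acts)
        assignments.append(kmeans_exposures(
            exposures, k, seed=stage_seed(config.seed, f"kmeans:{c}"),
            n_restarts=config.kmeans_restarts, caller_id=c))
    consensus = align_and_intersect(assignments)

    fit_results = fit_exposures = None
    if reference is not None:
        stable_cat = catalogs[ref_caller].subset(consensus.stable_samples)
        if reference.schema.name != stable_cat.schema.name:
            stable_cat = collapse(stable_cat, reference.schema)
        fit_results, fit_exposures = attribute_catalog(
            stable_cat, reference, n_bootstrap=config.n_bootstrap,
            ci_alpha=config.ci_alpha, seed=config.seed)
    return PipelineResult(
        catalogs=catalogs, rare_samples=list(rare), rare_report=rare_report,
        extraction=report, assignments=assignments, consensus=consensus,
        fit_results=fit_results, fit_exposures=fit_exposures)
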