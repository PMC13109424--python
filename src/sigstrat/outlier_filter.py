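"""Detection of rare mutation spectra before signature extraction.

Joint NMF extraction can ascribe a signature present only in a few highly
mutated samples to the whole cohort ("signature bleeding").  To mitigate
this, samples above a mutation-burden threshold are compared pairwise by
cosine similarity of their 96-channel spectra, grouped by average-linkage
hierarchical clustering on 1-cosine distance, and samples falling in groups
smaller than a minimum size are flagged as rare and excluded from the
extraction input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .catalog import collapse
from .config import log_stage
from .types import MutationCatalog, SignatureMatrix


def select_high_burden(catalog: MutationCatalog, threshold: int) -> list[str]:
    """Samples whose total mutation count is strictly above ``threshold``."""
    totals = catalog.totals()
    return [s for s, t in zip(catalog.sample_ids, totals) if t > threshold]


@dataclass
class SpectrumClusterReport:
    """Cosine-clustering of high-burden spectra and the rare-sample flags."""

    high_burden_samples: list[str]
    pairwise_cosine: np.ndarray  # symmetric, unit diagonal
    linkage_matrix: np.ndarray | None
    groups: dict[int, list[str]]  # group id -> member samples
    rare_samples: list[str]
    group_mean_spectra: dict[int, np.ndarray]  # relative 96-channel profiles
    best_reference_match: dict[int, tuple[str, float]] = field(
        default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "high_burden_samples": self.high_burden_samples,
            "groups": {str(k): v for k, v in self.groups.items()},
            "rare_samples": self.rare_samples,
            "best_reference_match": {
                str(k): {"signature": s, "cosine": c}
                for k, (s, c) in self.best_reference_match.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def cosine_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairwise_cosine,
                            index=self.high_burden_samples,
                            columns=self.high_burden_samples)


def cosine_similarity_matrix(spectra: np.ndarray) -> np.ndarray:
    """Pairwise cosine of row spectra; rows must have positive norm."""
    norms = np.linalg.norm(spectra, axis=1)
    unit = spectra / norms[:, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def cosine_cluster(catalog: MutationCatalog,
                   cut_distance: float = 0.25,
                   reference: SignatureMatrix | None = None,
                   ) -> SpectrumClusterReport:
    """Group spectra by average-linkage clustering on 1-cosine distance.

    ``catalog`` should already be restricted to the high-burden samples; a
    96-channel schema is expected (higher-resolution catalogs are collapsed).
    Zero-total samples are excluded with a warning.  The tree is cut at a
    fixed ``cut_distance`` so the number of spectrum groups is an outcome,
    not an input.  If a ``reference`` signature set is given, each group's
    mean spectrum is annotated with its best-cosine reference match (a
    human-review aid only; it never influences flagging).
    """
    if catalog.schema.name != "SBS96":
        catalog = collapse(catalog, "SBS96")
    totals = catalog.totals()
    if (totals == 0).any():
        dropped = [s for s, t in zip(catalog.sample_ids, totals) if t == 0]
        warnings.warn(f"excluding zero-total samples: {dropped}", stacklevel=2)
        catalog = catalog.drop(dropped)
    samples = list(catalog.sample_ids)
    if len(samples) < 2:
        raise ValueError("cosine_cluster needs at least two samples")
    rel = catalog.relative()
    sim = cosine_similarity_matrix(rel)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=cut_distance, criterion="distance")
    groups: dict[int, list[str]] = {}
    for s, lab in zip(samples, labels):
        groups.setdefault(int(lab), []).append(s)
    mean_spectra = {
        g: rel[[samples.index(s) for s in members]].mean(axis=0)
        for g, members in groups.items()
    }
    matches: dict[int, tuple[str, float]] = {}
    if reference is not None:
        ref96 = reference.profiles
        for g, spec in mean_spectra.items():
            cos = (ref96 @ spec) / (
                np.linalg.norm(ref96, axis=1) * np.linalg.norm(spec))
            best = int(np.argmax(cos))
            matches[g] = (reference.signature_ids[best], float(cos[best]))
    log_stage("cosine_cluster", n_samples=len(samples), n_groups=len(groups),
              cut_distance=cut_distance)
    return SpectrumClusterReport(
        high_burden_samples=samples, pairwise_cosine=sim, linkage_matrix=Z,
        groups=groups, rare_samples=[], group_mean_spectra=mean_spectra,
        best_reference_match=matches)


def flag_rare(report: SpectrumClusterReport, min_size: int) -> list[str]:
    """Samples in spectrum groups of size strictly below ``min_size``."""
    if not report.groups:
        raise ValueError("empty cluster report")
    rare = [s for members in report.groups.values() if len(members) < min_size
            for s in members]
    report.rare_samples = sorted(rare)
    log_stage("flag_rare", min_size=min_size, n_rare=len(rare))
    return report.rare_samples


def remove_rare_spectra(catalog: MutationCatalog, burden_threshold: int = 600,
                        rare_max_size: int = 5, cut_distance: float = 0.25,
                        reference: SignatureMatrix | None = None,
                        ) -> tuple[MutationCatalog, SpectrumClusterReport | None]:
    """End-to-end rare-spectrum filter: threshold, cluster, flag, drop."""
    high = select_high_burden(collapse(catalog, "SBS96"), burden_threshold)
    if len(high) < 2:
        log_stage("remove_rare_spectra", n_high_burden=len(high), n_rare=0)
        return catalog, None
    report = cosine_cluster(collapse(catalog.subset(high), "SBS96"),
                            cut_distance=cut_distance, reference=reference)
    rare = flag_rare(report, rare_max_size)
    log_stage("remove_rare_spectra", n_high_burden=len(high), n_rare=len(rare))
    return catalog.drop(rare), report
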