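"""Sample clustering on relative signature exposures and cross-caller consensus.

Samples are clustered by K-means on their relative de novo signature
contributions, once per variant caller.  Because each caller sees a slightly
different variant set, per-caller clusterings disagree on some samples;
labels are aligned across callers by maximum-overlap (Hungarian) matching
and only samples assigned the same aligned label by every caller are kept
as the stable consensus set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .config import log_stage
from .types import ExposureMatrix


@dataclass
class ClusterAssignment:
    """K-means partition of one caller's samples in exposure space."""

    caller_id: str
    sample_ids: list[str]
    labels: np.ndarray  # ints in [0, k)
    k: int
    centroids: np.ndarray  # k x n_signatures, relative-exposure space
    dominant_signature: list[str]  # per cluster

    def label_of(self) -> dict[str, int]:
        return {s: int(l) for s, l in zip(self.sample_ids, self.labels)}


def kmeans_exposures(exposures: ExposureMatrix, k: int, seed: int = 0,
                     n_restarts: int = 50,
                     caller_id: str = "caller") -> ClusterAssignment:
    """Best-of-restarts K-means on relative exposures."""
    X = exposures.relative
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} samples")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    centroids = km.cluster_centers_
    dominant = [exposures.signature_ids[int(np.argmax(c))] for c in centroids]
    if len(set(labels)) < k:
        raise RuntimeError("K-means produced an empty cluster")
    log_stage("kmeans_exposures", caller=caller_id, k=k,
              inertia=round(float(km.inertia_), 6))
    return ClusterAssignment(
        caller_id=caller_id, sample_ids=list(exposures.sample_ids),
        labels=np.asarray(labels, dtype=int), k=k, centroids=centroids,
        dominant_signature=dominant)


@dataclass
class ConsensusAssignment:
    """Cross-caller label alignment and the stable sample intersection."""

    assignments: list[ClusterAssignment]
    matched_labels: dict[str, dict[int, int]]  # caller -> raw -> aligned
    stable_samples: list[str]
    final_labels: dict[str, int]  # stable sample -> aligned label
    instability_rate: float
    overlap_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        stable = set(self.stable_samples)
        for a in self.assignments:
            remap = self.matched_labels[a.caller_id]
            for s, raw in zip(a.sample_ids, a.labels):
                rows.append((s, a.caller_id, int(raw), remap[int(raw)],
                             s in stable))
        return pd.DataFrame(
            rows, columns=["sample", "caller", "raw_label", "aligned_label",
                           "stable"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "stable_samples": self.stable_samples,
                "final_labels": self.final_labels,
                "instability_rate": self.instability_rate,
                "overlap_counts": self.overlap_counts,
            }, fh, indent=2)


def _align_to(reference: dict[str, int], other: ClusterAssignment,
              k: int) -> dict[int, int]:
    """Raw->aligned label map maximizing sample overlap with ``reference``."""
    contingency = np.zeros((k, k))
    for s, raw in zip(other.sample_ids, other.labels):
        if s in reference:
            contingency[int(raw), reference[s]] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def align_and_intersect(assignments: list[ClusterAssignment],
                        ) -> ConsensusAssignment:
    """Align per-caller labels and intersect to the stable sample set.

    Labels are matched against the lexicographically first caller's
    assignment (so the result does not depend on input order); the stable
    set is the samples whose aligned label agrees across all callers that
    scored them.  Samples missing from any caller are unstable by definition.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two caller assignments")
    ks = {a.k for a in assignments}
    if len(ks) != 1:
        raise ValueError(f"caller assignments disagree on k: {sorted(ks)}")
    (k,) = ks
    ordered = sorted(assignments, key=lambda a: a.caller_id)
    ref_assign = ordered[0]
    reference = ref_assign.label_of()
    matched: dict[str, dict[int, int]] = {
        ref_assign.caller_id: {i: i for i in range(k)}}
    for a in ordered[1:]:
        matched[a.caller_id] = _align_to(reference, a, k)
    union: set[str] = set()
    aligned_per_sample: dict[str, set[int]] = {}
    counts: dict[str, int] = {}
    for a in ordered:
        union.update(a.sample_ids)
        remap = matched[a.caller_id]
        for s, raw in zip(a.sample_ids, a.labels):
            aligned_per_sample.setdefault(s, set()).add(remap[int(raw)])
    n_callers = len(ordered)
    per_caller_presence = {s: 0 for s in union}
    for a in ordered:
        for s in a.sample_ids:
            per_caller_presence[s] += 1
    stable = sorted(
        s for s in union
        if per_caller_presence[s] == n_callers
        and len(aligned_per_sample[s]) == 1)
    final = {s: next(iter(aligned_per_sample[s])) for s in stable}
    for lab in range(k):
        counts[f"cluster_{lab}_stable"] = sum(
            1 for s in stable if final[s] == lab)
    instability = 1.0 - len(stable) / len(union) if union else 0.0
    log_stage("align_and_intersect", n_callers=n_callers, n_union=len(union),
              n_stable=len(stable), instability=round(instability, 4))
    return ConsensusAssignment(
        assignments=list(assignments), matched_labels=matched,
        stable_samples=stable, final_labels=final,
        instability_rate=instability, overlap_counts=counts)
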