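"""De novo signature extraction by replicated, resampled KL-NMF.

The count matrix V (channels x samples) is factorized as V ~ W H with W, H
nonnegative, minimizing the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by multiplicative updates, which guarantee a non-increasing objective.  For
each candidate number of signatures k, the factorization is repeated on
multinomial bootstrap resamples of the catalog; replicate signatures are
aligned by Hungarian matching on cosine similarity and summarized by their
per-cluster medoids.  Stability (mean silhouette on 1-cosine) and
reconstruction quality (mean sample cosine) drive the choice of k.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.metrics import silhouette_score

from .config import log_stage, stage_rng, stage_seed
from .types import ExposureMatrix, MutationCatalog, SignatureMatrix

_EPS = 1e-12


def bootstrap_catalog(catalog: MutationCatalog,
                      seed: np.random.Generator | int) -> MutationCatalog:
    """Multinomial resample of each sample's spectrum; totals conserved.

    With an integer ``seed``, each sample draws from a stream keyed by
    ``(seed, sample_id)``, so the resample of a sample does not depend on
    the order samples appear in the catalog.
    """
    counts = np.zeros_like(catalog.counts)
    totals = catalog.totals()
    rel = catalog.relative()
    shared = seed if isinstance(seed, np.random.Generator) else None
    for i, (sample, n, p) in enumerate(zip(catalog.sample_ids, totals, rel)):
        if n > 0:
            rng = shared if shared is not None else \
                stage_rng(int(seed), f"boot:{sample}")
            counts[i] = rng.multinomial(int(n), p)
    return MutationCatalog(catalog.schema, list(catalog.sample_ids), counts)


def _nndsvda(V: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization, zeros filled with the mean."""
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    n, m = V.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        mp, mn = np.linalg.norm(xp) * np.linalg.norm(yp), \
            np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn and mp > 0:
            u, v, sig = xp / np.linalg.norm(xp), yp / np.linalg.norm(yp), mp
        elif mn > 0:
            u, v, sig = xn / np.linalg.norm(xn), yn / np.linalg.norm(yn), mn
        else:
            u, v, sig = np.full(n, 1 / np.sqrt(n)), np.full(m, 1 / np.sqrt(m)), S[j]
        W[:, j] = np.sqrt(S[j] * sig) * u
        H[j, :] = np.sqrt(S[j] * sig) * v
    mean = V.mean()
    W[W <= 0] = mean
    H[H <= 0] = mean
    return W, H


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    WH = W @ H + _EPS
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / WH[mask]))
                 - V.sum() + WH.sum())


def nmf_kl(V: np.ndarray, k: int, seed: int = 0, max_iter: int = 2000,
           tol: float = 1e-6, init: str = "nndsvda",
           return_objective: bool = False):
    """KL-NMF by multiplicative updates.

    ``V`` is channels x samples and must be nonnegative with no all-zero
    columns.  Returns ``(W, H)`` with W columns summing to 1 (the scale moved
    into H); with ``return_objective=True`` also the per-iteration objective,
    which is non-increasing.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    if (V.sum(axis=0) == 0).any():
        raise ValueError("NMF input has an all-zero sample column")
    n, m = V.shape
    if not (1 <= k <= min(n, m)):
        raise ValueError(f"k={k} outside [1, min(channels, samples)={min(n, m)}]")
    if init == "nndsvda":
        W, H = _nndsvda(V, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(V.mean() / k)
        W = scale * rng.uniform(0.1, 1.0, size=(n, k))
        H = scale * rng.uniform(0.1, 1.0, size=(k, m))
    else:
        raise ValueError(f"unknown init {init!r}")
    history = [kl_divergence(V, W, H)]
    for it in range(max_iter):
        WH = W @ H + _EPS
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = W @ H + _EPS
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        obj = kl_divergence(V, W, H)
        history.append(obj)
        prev = history[-2]
        if prev - obj <= tol * max(abs(prev), 1.0):
            break
    col = np.maximum(W.sum(axis=0), _EPS)
    W = W / col
    H = H * col[:, None]
    if return_objective:
        return W, H, np.asarray(history)
    return W, H


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    return An @ Bn.T


def _nnls_exposures(profiles: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """NNLS refit of each sample (rows of ``counts``) on signature profiles."""
    A = profiles.T  # channels x k
    return np.array([nnls(A, y.astype(float))[0] for y in counts])


@dataclass
class KRecord:
    """Consensus result for one candidate signature number."""

    k: int
    signatures: SignatureMatrix
    exposures: ExposureMatrix
    mean_silhouette: float
    mean_sample_cosine: float
    n_replicates_used: int


@dataclass
class ExtractionReport:
    records: dict[int, KRecord]
    chosen_k: int

    @property
    def chosen(self) -> KRecord:
        return self.records[self.chosen_k]

    def summary(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "per_k": {
                k: {"mean_silhouette": r.mean_silhouette,
                    "mean_sample_cosine": r.mean_sample_cosine,
                    "n_replicates_used": r.n_replicates_used}
                for k, r in self.records.items()},
        }


def _extract_one_k(catalog: MutationCatalog, k: int, n_replicates: int,
                   seed: int, max_iter: int, tol: float) -> KRecord:
    V = catalog.counts.T.astype(float)
    replicate_sigs: list[np.ndarray] = []
    for r in range(n_replicates):
        rep_seed = stage_seed(seed, f"extract:k={k}:rep={r}")
        boot = bootstrap_catalog(catalog, rep_seed)
        try:
            W, _ = nmf_kl(boot.counts.T, k, seed=rep_seed,
                          max_iter=max_iter, tol=tol,
                          init="nndsvda" if r == 0 else "random")
        except (ValueError, np.linalg.LinAlgError) as exc:  # replicate failure
            warnings.warn(f"replicate {r} failed at k={k}: {exc}", stacklevel=2)
            continue
        replicate_sigs.append(W.T)  # k x channels
    if len(replicate_sigs) < max(1, n_replicates // 2):
        raise RuntimeError(f"fewer than half the replicates succeeded at k={k}")
    # Align every replicate's signatures to the first by Hungarian matching
    # on cosine similarity; the aligned index is the consensus cluster label.
    ref = replicate_sigs[0]
    aligned: list[np.ndarray] = [ref]
    for sigs in replicate_sigs[1:]:
        cos = _cosine_matrix(ref, sigs)
        rows, cols = linear_sum_assignment(-cos)
        order = np.empty(k, dtype=int)
        order[rows] = cols
        aligned.append(sigs[order])
    pooled = np.vstack(aligned)
    labels = np.tile(np.arange(k), len(aligned))
    if k >= 2 and len(aligned) >= 2:
        dist = np.clip(1.0 - _cosine_matrix(pooled, pooled), 0.0, None)
        np.fill_diagonal(dist, 0.0)
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = 1.0  # degenerate replication/cluster count: stability undefined
    # Medoid per cluster = member minimizing total distance to its cluster.
    medoids = np.empty((k, pooled.shape[1]))
    for j in range(k):
        members = pooled[labels == j]
        d = 1.0 - _cosine_matrix(members, members)
        medoids[j] = members[np.argmin(d.sum(axis=1))]
    activities = _nnls_exposures(medoids, catalog.counts)
    # Stable naming: order consensus signatures by total fitted activity.
    order = np.argsort(-activities.sum(axis=0), kind="stable")
    medoids, activities = medoids[order], activities[:, order]
    letters = string.ascii_uppercase
    ids = [f"{catalog.schema.name}{letters[i % 26] * (i // 26 + 1)}"
           for i in range(k)]
    signatures = SignatureMatrix(catalog.schema, ids, medoids)
    exposures = ExposureMatrix(list(catalog.sample_ids), ids, activities)
    recon = activities @ signatures.profiles
    obs = catalog.counts.astype(float)
    keep = obs.sum(axis=1) > 0
    num = (obs[keep] * recon[keep]).sum(axis=1)
    den = np.linalg.norm(obs[keep], axis=1) * np.maximum(
        np.linalg.norm(recon[keep], axis=1), _EPS)
    mean_cos = float(np.mean(num / den))
    return KRecord(k=k, signatures=signatures, exposures=exposures,
                   mean_silhouette=sil, mean_sample_cosine=mean_cos,
                   n_replicates_used=len(replicate_sigs))


def extract(catalog: MutationCatalog, k_range, n_replicates: int = 30,
            seed: int = 0, max_iter: int = 2000, tol: float = 1e-6,
            stability_floor: float = 0.8, min_cosine_gain: float = 0.01,
            ) -> ExtractionReport:
    """Replicated extraction over candidate k with stability-based selection.

    ``k_range`` is any iterable of candidate signature numbers.  Zero-total
    samples are dropped before factorization.
    """
    totals = catalog.totals()
    if (totals == 0).any():
        dropped = [s for s, t in zip(catalog.sample_ids, totals) if t == 0]
        warnings.warn(f"dropping zero-total samples: {dropped}", stacklevel=2)
        catalog = catalog.drop(dropped)
    if catalog.n_samples == 0:
        raise ValueError("no samples left to extract from")
    records: dict[int, KRecord] = {}
    for k in sorted(set(int(k) for k in k_range)):
        records[k] = _extract_one_k(catalog, k, n_replicates, seed,
                                    max_iter, tol)
        log_stage("extract", k=k,
                  silhouette=round(records[k].mean_silhouette, 4),
                  sample_cosine=round(records[k].mean_sample_cosine, 4))
    chosen = select_k_from_records(records, stability_floor, min_cosine_gain)
    log_stage("extract", chosen_k=chosen)
    return ExtractionReport(records=records, chosen_k=chosen)


def select_k_from_records(records: dict[int, KRecord],
                          stability_floor: float = 0.8,
                          min_cosine_gain: float = 0.01) -> int:
    ks = sorted(records)
    sil = {k: records[k].mean_silhouette for k in ks}
    cos = {k: records[k].mean_sample_cosine for k in ks}
    passing = []
    for i, k in enumerate(ks):
        if sil[k] < stability_floor:
            continue
        if i > 0 and cos[k] - cos[ks[i - 1]] <= min_cosine_gain:
            continue
        passing.append(k)
    if passing:
        return max(passing)
    warnings.warn("no k met the stability floor and cosine-gain rule; "
                  "falling back to the most stable k", stacklevel=2)
    return max(ks, key=lambda k: (sil[k], -k))


def select_k(report: ExtractionReport, stability_floor: float = 0.8,
             min_cosine_gain: float = 0.01) -> int:
    """Largest k that is stable and still improves reconstruction.

    A candidate passes if its mean silhouette is at or above
    ``stability_floor`` and (unless it is the smallest candidate) its mean
    sample cosine improves on the previous candidate by more than
    ``min_cosine_gain``.  If none passes, the most stable k is returned with
    a warning.
    """
    return select_k_from_records(report.records, stability_floor,
                                 min_cosine_gain)
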