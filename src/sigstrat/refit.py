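"""Reference-signature attribution by NNLS with bootstrap CI pruning.

Per-sample refitting solves min ||S a - y||_2 over nonnegative activities a,
where y is the sample's channel count spectrum and the columns of S are
reference signature profiles.  To guard against over-attribution at low
mutation counts, activities are given percentile bootstrap confidence
intervals (multinomial resampling of the observed spectrum, totals
conserved) and any signature whose interval includes zero is pruned; the
reduced set is refit and the prune-and-refit cycle repeats until every
retained signature's interval excludes zero, or nothing is left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .config import log_stage, stage_rng
from .types import ExposureMatrix, MutationCatalog, SignatureMatrix

_ZERO_TOL = 1e-9


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def nnls_fit(spectrum: np.ndarray, reference: SignatureMatrix) -> np.ndarray:
    """Nonnegative least-squares activities of ``reference`` on a spectrum."""
    y = np.asarray(spectrum, dtype=float)
    if y.shape != (reference.schema.n_channels,):
        raise ValueError(
            f"spectrum has {y.shape[0]} channels; reference schema "
            f"{reference.schema.name} expects {reference.schema.n_channels}")
    activities, _ = nnls(reference.profiles.T, y)
    return activities


def decompose_denovo(denovo: SignatureMatrix, reference: SignatureMatrix,
                     ) -> pd.DataFrame:
    """NNLS weights of each de novo signature over reference profiles.

    Returns one row per (de novo, reference) pair with the weight expressed
    as a percentage of the de novo signature's explained mass, plus the
    reconstruction cosine of the de novo profile.
    """
    if denovo.schema.name != reference.schema.name:
        raise ValueError(
            f"schema mismatch: {denovo.schema.name} vs {reference.schema.name}")
    rows = []
    for sig_id, profile in zip(denovo.signature_ids, denovo.profiles):
        w = nnls_fit(profile, reference)
        recon = w @ reference.profiles
        total = w.sum()
        pct = 100.0 * w / total if total > 0 else np.zeros_like(w)
        cos = _cosine(profile, recon)
        for ref_id, p in zip(reference.signature_ids, pct):
            rows.append((sig_id, ref_id, p, cos))
    return pd.DataFrame(
        rows, columns=["denovo", "reference", "weight_pct",
                       "reconstruction_cosine"])


@dataclass
class FitResult:
    """Per-sample attribution with bootstrap CIs and the pruning record."""

    sample_id: str
    signature_ids: list[str]
    activities: np.ndarray  # full candidate order; pruned entries are 0
    ci_low: np.ndarray
    ci_high: np.ndarray
    pruned: list[str]
    residual_cosine: float
    n_bootstrap: int
    ci_alpha: float

    @property
    def retained(self) -> list[str]:
        pruned = set(self.pruned)
        return [s for s in self.signature_ids if s not in pruned]

    def to_frame(self) -> pd.DataFrame:
        pruned = set(self.pruned)
        return pd.DataFrame({
            "sample": self.sample_id,
            "signature": self.signature_ids,
            "activity": self.activities,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pruned": [s in pruned for s in self.signature_ids],
        })


def attribute_with_ci(spectrum: np.ndarray, candidates: SignatureMatrix,
                      n_bootstrap: int = 200, ci_alpha: float = 0.05,
                      seed: int = 0, sample_id: str = "sample",
                      ) -> FitResult:
    """Attribute a spectrum to candidate signatures with zero-in-CI pruning.

    Bootstrap = multinomial resampling of the observed spectrum with the
    total conserved.  Percentile intervals at level ``1 - ci_alpha``; any
    candidate whose lower bound does not exceed zero is pruned (all such
    candidates at once), the reduced set refit, and intervals recomputed on
    the final set.  An empty final set signals an unexplainable spectrum.
    """
    y = np.asarray(spectrum, dtype=float)
    n = y.sum()
    if n <= 0:
        raise ValueError("spectrum total must be positive")
    if n_bootstrap < 50:
        raise ValueError("n_bootstrap must be at least 50")
    rng = stage_rng(seed, f"attribute:{sample_id}")
    p = y / n
    boot = rng.multinomial(int(round(n)), p, size=n_bootstrap).astype(float)
    ids = list(candidates.signature_ids)
    m = len(ids)
    retained = np.arange(m)
    lo_q, hi_q = 100 * ci_alpha / 2, 100 * (1 - ci_alpha / 2)
    point = np.zeros(m)
    ci_low = np.zeros(m)
    ci_high = np.zeros(m)
    while retained.size:
        A = candidates.profiles[retained].T  # channels x retained
        act = nnls(A, y)[0]
        boot_acts = np.array([nnls(A, b)[0] for b in boot])
        # conservative finite-B percentile endpoints: round outward to
        # order statistics instead of interpolating between them
        lo = np.percentile(boot_acts, lo_q, axis=0, method="lower")
        hi = np.percentile(boot_acts, hi_q, axis=0, method="higher")
        # Intervals are reported covering the point estimate.
        lo = np.minimum(lo, act)
        hi = np.maximum(hi, act)
        zero_in = lo <= _ZERO_TOL
        point[:] = 0.0
        ci_low[:] = 0.0
        ci_high[:] = 0.0
        point[retained] = act
        ci_low[retained] = lo
        ci_high[retained] = hi
        if not zero_in.any():
            break
        retained = retained[~zero_in]
        if retained.size == 0:
            point[:] = 0.0
            ci_low[:] = 0.0
            ci_high[:] = 0.0
    retained_set = set(retained.tolist())
    pruned = [ids[i] for i in range(m) if i not in retained_set]
    recon = point @ candidates.profiles
    res_cos = _cosine(y, recon)
    log_stage("attribute_with_ci", sample=sample_id, total=int(n),
              n_retained=len(retained_set), n_pruned=len(pruned),
              residual_cosine=round(res_cos, 4))
    return FitResult(sample_id=sample_id, signature_ids=ids,
                     activities=point, ci_low=ci_low, ci_high=ci_high,
                     pruned=pruned, residual_cosine=res_cos,
                     n_bootstrap=n_bootstrap, ci_alpha=ci_alpha)


def attribute_catalog(catalog: MutationCatalog, candidates: SignatureMatrix,
                      n_bootstrap: int = 200, ci_alpha: float = 0.05,
                      seed: int = 0) -> tuple[list[FitResult], ExposureMatrix]:
    """CI-pruned attribution of every sample in a catalog."""
    if catalog.schema.name != candidates.schema.name:
        raise ValueError(
            f"schema mismatch: catalog {catalog.schema.name} vs "
            f"candidates {candidates.schema.name}")
    fits = []
    acts = np.zeros((catalog.n_samples, candidates.n_signatures))
    for i, sample in enumerate(catalog.sample_ids):
        y = catalog.counts[i]
        if y.sum() == 0:
            fits.append(FitResult(
                sample_id=sample,
                signature_ids=list(candidates.signature_ids),
                activities=np.zeros(candidates.n_signatures),
                ci_low=np.zeros(candidates.n_signatures),
                ci_high=np.zeros(candidates.n_signatures),
                pruned=list(candidates.signature_ids), residual_cosine=0.0,
                n_bootstrap=n_bootstrap, ci_alpha=ci_alpha))
            continue
        fit = attribute_with_ci(y, candidates, n_bootstrap=n_bootstrap,
                                ci_alpha=ci_alpha, seed=seed,
                                sample_id=sample)
        acts[i] = fit.activities
        fits.append(fit)
    exposures = ExposureMatrix(list(catalog.sample_ids),
                               list(candidates.signature_ids), acts)
    return fits, exposures
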