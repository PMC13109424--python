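"""Run configuration and reproducible per-stage seeding.

Every randomized stage of the pipeline draws its generator from
:func:`stage_rng`, which derives an independent stream from ``(seed,
stage-name)``.  Re-running a single stage with the same config therefore
reproduces its output bit-identically, regardless of which other stages ran
before it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

log = logging.getLogger("sigstrat")


def stage_seed(seed: int, stage: str) -> int:
    """Stable 31-bit seed derived from a base seed and a stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


@dataclass
class RunConfig:
    """Tunable parameters of the stratification pipeline.

    Defaults follow the analysis conditions the pipeline was designed for:
    samples above ``burden_threshold`` mutations are screened for rare
    spectra, spectrum groups smaller than ``rare_max_size`` are discarded as
    rare, and signature number is searched over ``k_range`` with
    ``n_nmf_replicates`` resampled NMF runs per candidate.
    """

    burden_threshold: int = 600
    rare_max_size: int = 5
    cut_distance: float = 0.25  # tree-cut height on 1-cosine for rare spectra
    k_range: tuple[int, int] = (2, 10)
    n_nmf_replicates: int = 30
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    stability_floor: float = 0.8
    min_cosine_gain: float = 0.01
    kmeans_k: int | str = "auto"  # "auto" = number of de novo signatures
    kmeans_restarts: int = 50
    n_bootstrap: int = 200
    ci_alpha: float = 0.05
    seed: int = 0
    channel_schema: str = "SBS384"

    def __post_init__(self) -> None:
        if self.burden_threshold <= 0:
            raise ValueError("burden_threshold must be positive")
        if not (0 < self.ci_alpha < 1):
            raise ValueError("ci_alpha must be in (0, 1)")
        lo, hi = self.k_range
        if lo > hi or lo < 1:
            raise ValueError("k_range must be a nonempty range of k >= 1")
        for name in ("rare_max_size", "n_nmf_replicates", "n_bootstrap",
                     "kmeans_restarts", "nmf_max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.channel_schema.upper() not in {"SBS96", "SBS288", "SBS384"}:
            raise ValueError(f"unknown channel_schema {self.channel_schema!r}")
        self.channel_schema = self.channel_schema.upper()

    @property
    def ks(self) -> range:
        lo, hi = self.k_range
        return range(lo, hi + 1)

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["k_range"] = list(d["k_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)


def log_stage(stage: str, **fields) -> None:
    """One structured log line per stage: dimensions, discards, choices."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    log.info("stage=%s %s", stage, payload)
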