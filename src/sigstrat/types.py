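"""Core in-memory containers shared across pipeline stages.

All matrices are numpy arrays wrapped with their axis labels; TSV round-trip
uses the field convention of signature-analysis tools: channels as rows and
samples (or signatures) as columns, first column holding channel labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemas import ChannelSchema, infer_schema


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant as reported by one caller for one sample."""

    sample_id: str
    caller_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    filter_pass: bool = True
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("positions are 1-based")

    @property
    def is_sbs(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Identity of the underlying variant, caller-agnostic."""
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(eq=False)
class MutationCatalog:
    """Samples x channels integer count matrix under a declared schema."""

    schema: ChannelSchema
    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, n_channels), nonnegative ints
    unclassified: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), self.schema.n_channels):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.schema.n_channels} channels"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative(self) -> np.ndarray:
        """Row-normalized spectra; zero-total rows stay zero."""
        tot = self.totals().astype(float)
        out = np.zeros_like(self.counts, dtype=float)
        nz = tot > 0
        out[nz] = self.counts[nz] / tot[nz, None]
        return out

    def subset(self, sample_ids: list[str]) -> "MutationCatalog":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MutationCatalog(self.schema, list(sample_ids), self.counts[idx])

    def drop(self, sample_ids) -> "MutationCatalog":
        drop = set(sample_ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.subset(keep)

    def equals(self, other: "MutationCatalog") -> bool:
        return (
            self.schema.name == other.schema.name
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.T, index=list(self.schema.channels),
            columns=self.sample_ids,
        ).rename_axis("MutationType")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        schema = infer_schema(list(df.index))
        df = df.reindex(list(schema.channels))
        counts = df.to_numpy().T
        if np.isnan(counts).any():
            raise ValueError(f"missing channel rows in catalog {path}")
        return cls(schema, [str(c) for c in df.columns],
                   counts.astype(np.int64))


@dataclass(eq=False)
class SignatureMatrix:
    """Per-signature probability vectors over channels (rows sum to 1)."""

    schema: ChannelSchema
    signature_ids: list[str]
    profiles: np.ndarray  # (n_signatures, n_channels)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.signature_ids), self.schema.n_channels):
            raise ValueError("profiles shape does not match ids x channels")
        if (self.profiles < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        sums = self.profiles.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError("signature profiles must have positive mass")
        self.profiles = self.profiles / sums[:, None]

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def subset(self, signature_ids) -> "SignatureMatrix":
        idx = [self.signature_ids.index(s) for s in signature_ids]
        return SignatureMatrix(self.schema, list(signature_ids), self.profiles[idx])

    def equals(self, other: "SignatureMatrix", tol: float = 1e-12) -> bool:
        return (
            self.schema.name == other.schema.name
            and self.signature_ids == other.signature_ids
            and np.allclose(self.profiles, other.profiles, atol=tol, rtol=0)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles.T, index=list(self.schema.channels),
            columns=self.signature_ids,
        ).rename_axis("MutationType")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        schema = infer_schema(list(df.index))
        df = df.reindex(list(schema.channels))
        profiles = df.to_numpy().T
        if np.isnan(profiles).any():
            raise ValueError("missing channel rows in signature table")
        return cls(schema, [str(c) for c in df.columns], profiles)


@dataclass(eq=False)
class ExposureMatrix:
    """Nonnegative per-sample signature activities, in mutation counts."""

    sample_ids: list[str]
    signature_ids: list[str]
    activities: np.ndarray  # (n_samples, n_signatures)

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.shape != (len(self.sample_ids), len(self.signature_ids)):
            raise ValueError("activities shape does not match samples x signatures")
        if (self.activities < -1e-9).any():
            raise ValueError("activities must be nonnegative")
        self.activities = np.clip(self.activities, 0.0, None)

    @property
    def relative(self) -> np.ndarray:
        tot = self.activities.sum(axis=1)
        out = np.zeros_like(self.activities)
        nz = tot > 0
        out[nz] = self.activities[nz] / tot[nz, None]
        return out

    def to_frame(self, relative: bool = False) -> pd.DataFrame:
        data = self.relative if relative else self.activities
        return pd.DataFrame(
            data, index=self.sample_ids, columns=self.signature_ids,
        ).rename_axis("Sample")

    def to_tsv(self, path, relative: bool = False) -> None:
        self.to_frame(relative).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExposureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy())


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant reported concordantly by at least two callers."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    n_callers: int
    mean_vaf: float | None

    def __post_init__(self) -> None:
        if self.n_callers < 2:
            raise ValueError("consensus requires >= 2 callers")

    @property
    def is_sbs(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"
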