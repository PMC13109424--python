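"""Single-base-substitution channel schemas and conversions between them.

A *channel* is a mutation category in the pyrimidine-normalized convention:
the substituted base is written as C or T (purine substitutions are
reverse-complemented), flanked by its immediate 5' and 3' neighbours, e.g.
``A[C>T]G``.  Strand-aware schemas prefix a transcription-strand category:

* ``SBS96``  — 6 substitution classes x 16 flanking contexts, no strand.
* ``SBS288`` — 96 x {T, U, N}: pyrimidine on the transcribed (template)
  strand, on the untranscribed (coding) strand, or intergenic.
* ``SBS384`` — 96 x {T, U, B, N}: as above plus B for positions covered by
  transcripts on both strands.

Collapsing is only defined toward lower-resolution schemas (384->288,
384->96, 288->96) and always conserves per-sample totals; the B category
folds into N when reducing 384 to 288.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


def _core96() -> tuple[str, ...]:
    return tuple(
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    )


CORE96: tuple[str, ...] = _core96()


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered set of mutation channels with optional strand categories."""

    name: str
    strand_categories: tuple[str, ...]
    channels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.strand_categories:
            chans = tuple(
                f"{cat}:{c}" for cat in self.strand_categories for c in CORE96
            )
        else:
            chans = CORE96
        object.__setattr__(self, "channels", chans)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.channels)}

    def label(self, core: str, category: str | None = None) -> str:
        """Build a channel label from a 96-style core and a strand category."""
        if not self.strand_categories:
            return core
        if category is None:
            raise ValueError(f"{self.name} requires a strand category")
        if category not in self.strand_categories:
            # B is only distinguished in SBS384; fold into N elsewhere.
            if category == "B" and "N" in self.strand_categories:
                category = "N"
            else:
                raise ValueError(f"unknown strand category {category!r}")
        return f"{category}:{core}"


SBS96 = ChannelSchema("SBS96", ())
SBS288 = ChannelSchema("SBS288", ("T", "U", "N"))
SBS384 = ChannelSchema("SBS384", ("T", "U", "B", "N"))

SCHEMAS: dict[str, ChannelSchema] = {s.name: s for s in (SBS96, SBS288, SBS384)}


def get_schema(name: str | ChannelSchema) -> ChannelSchema:
    if isinstance(name, ChannelSchema):
        return name
    try:
        return SCHEMAS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown channel schema {name!r}") from None


def split_label(label: str) -> tuple[str | None, str]:
    """Split ``'T:A[C>G]A'`` into ``('T', 'A[C>G]A')``; no-op for SBS96 labels."""
    if ":" in label:
        cat, core = label.split(":", 1)
        return cat, core
    return None, label


def parse_core(core: str) -> tuple[str, str, str, str]:
    """Parse ``'A[C>T]G'`` into (five, ref, alt, three)."""
    if len(core) != 7 or core[1] != "[" or core[3] != ">" or core[5] != "]":
        raise ValueError(f"malformed channel label {core!r}")
    five, ref, alt, three = core[0], core[2], core[4], core[6]
    if ref not in PYRIMIDINES:
        raise ValueError(f"channel ref must be a pyrimidine: {core!r}")
    return five, ref, alt, three


def infer_schema(labels: list[str] | tuple[str, ...]) -> ChannelSchema:
    """Find the schema whose channel set equals ``labels`` (order-free)."""
    label_set = set(labels)
    for schema in SCHEMAS.values():
        if label_set == set(schema.channels):
            return schema
    raise ValueError(
        f"channel label set (n={len(label_set)}) matches no supported schema"
    )


def collapse_indices(source: ChannelSchema, target: ChannelSchema) -> np.ndarray:
    """Map each source channel index to its target channel index.

    Supported directions: 384->288 (B folds into N), 384->96, 288->96.
    """
    valid = {("SBS384", "SBS288"), ("SBS384", "SBS96"), ("SBS288", "SBS96")}
    if (source.name, target.name) not in valid:
        raise ValueError(
            f"unsupported collapse {source.name}->{target.name}"
        )
    tgt_index = target.index()
    out = np.empty(source.n_channels, dtype=np.intp)
    for i, label in enumerate(source.channels):
        cat, core = split_label(label)
        if not target.strand_categories:
            out[i] = tgt_index[core]
        else:
            out[i] = tgt_index[target.label(core, cat)]
    return out
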