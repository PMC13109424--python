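"""APOBEC3A/3B tetranucleotide context dissection and motif summaries.

APOBEC cytidine deaminases mutate cytosine in a TpC dinucleotide (TCW motif,
W = A or T, producing C>T and C>G changes).  The two dominant enzymes
prefer different bases two positions 5' of the mutated C: APOBEC3A favours
a pyrimidine there (YTCA), APOBEC3B a purine (RTCA).  Counting mutated TCA
sites split by that -2 base therefore separates the two enzymes' footprints.
The -2 base is read on the strand carrying the pyrimidine, consistent with
catalog channel normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import (
    EMPTY_ANNOTATION,
    MotifClass,
    TranscriptAnnotation,
    classify_variant_motif,
    contig_length,
    fetch,
)
from .config import log_stage
from .schemas import COMPLEMENT


@dataclass
class ApobecContextCounts:
    """Per-sample tallies of APOBEC-context mutations."""

    sample_id: str
    ytca: int = 0
    rtca: int = 0
    apobec_like_total: int = 0
    n_unresolved: int = 0  # TCA-context mutations missing the -2 base

    @property
    def tca_total(self) -> int:
        return self.ytca + self.rtca


def _apobec_context(variant, genome) -> tuple[bool, str | None]:
    """(is APOBEC-like TCW mutation, -2 base for TCA context or None)."""
    pos0 = variant.pos - 1
    length = contig_length(genome, variant.chrom)
    if pos0 <= 0 or pos0 >= length - 1:
        return False, None
    context = fetch(genome, variant.chrom, pos0 - 1, pos0 + 2)
    if any(b not in "ACGT" for b in context):
        return False, None
    ref, alt = variant.ref, variant.alt
    if ref in "CT":
        five, three = context[0], context[2]
        sub = f"{ref}>{alt}"
        minus2_pos = pos0 - 2
        on_forward = True
    else:
        five = context[2].translate(COMPLEMENT)
        three = context[0].translate(COMPLEMENT)
        sub = f"{ref.translate(COMPLEMENT)}>{alt.translate(COMPLEMENT)}"
        minus2_pos = pos0 + 2
        on_forward = False
    is_apobec = five == "T" and sub in ("C>T", "C>G") and three in "AT"
    if not is_apobec or three != "A":
        return is_apobec, None
    if minus2_pos < 0 or minus2_pos >= length:
        return True, "edge"
    base = fetch(genome, variant.chrom, minus2_pos, minus2_pos + 1)
    if not on_forward:
        base = base.translate(COMPLEMENT)
    if base not in "ACGT":
        return True, "edge"
    return True, base


def count_tetra(variants, genome) -> dict[str, ApobecContextCounts]:
    """YTCA/RTCA tallies per sample over APOBEC-like (TCW) mutations.

    Only TCA-context mutations are split by the -2 base; TCT-context
    APOBEC-like mutations enter ``apobec_like_total`` only.  TCA mutations
    whose -2 base is unavailable (contig edge, N) are counted as unresolved.
    """
    out: dict[str, ApobecContextCounts] = {}
    for v in variants:
        if not v.is_sbs:
            continue
        counts = out.setdefault(v.sample_id, ApobecContextCounts(v.sample_id))
        is_apobec, minus2 = _apobec_context(v, genome)
        if not is_apobec:
            continue
        counts.apobec_like_total += 1
        if minus2 is None:
            continue  # TCT context: not split by -2 base
        if minus2 == "edge":
            counts.n_unresolved += 1
        elif minus2 in "CT":
            counts.ytca += 1
        else:
            counts.rtca += 1
    log_stage("count_tetra", n_samples=len(out),
              ytca=sum(c.ytca for c in out.values()),
              rtca=sum(c.rtca for c in out.values()))
    return out


def tetra_frame(counts: dict[str, ApobecContextCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.ytca, c.rtca, c.tca_total, c.apobec_like_total,
          c.n_unresolved) for c in counts.values()],
        columns=["sample", "ytca", "rtca", "tca_total", "apobec_like_total",
                 "n_unresolved"]).set_index("sample")


def motif_distribution(variants, genome, grouping: dict[str, object],
                       annotation: TranscriptAnnotation = EMPTY_ANNOTATION,
                       subset=None) -> pd.DataFrame:
    """Per-group fractions of mutations in each motif class.

    ``grouping`` maps sample id to a group label (e.g. a cluster name);
    ``subset`` is an optional predicate on variants (e.g. membership in a
    set of genes under selection).  Fractions sum to one within each group;
    empty groups are omitted.
    """
    class_names = [m.value for m in MotifClass]
    counts: dict[object, np.ndarray] = {}
    for v in variants:
        if v.sample_id not in grouping:
            raise ValueError(f"sample {v.sample_id!r} missing from grouping")
        if subset is not None and not subset(v):
            continue
        group = grouping[v.sample_id]
        motif = classify_variant_motif(v, genome, annotation)
        row = counts.setdefault(group, np.zeros(len(class_names)))
        row[class_names.index(motif.value)] += 1
    rows = {}
    for group, row in counts.items():
        total = row.sum()
        if total == 0:
            continue
        rows[group] = row / total
    df = pd.DataFrame.from_dict(rows, orient="index", columns=class_names)
    df.index.name = "group"
    return df.sort_index()
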