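"""Strand-bias-aware SBS catalogs, caller consensus, and motif classes.

Classification follows the pyrimidine-normalized convention: a substitution
whose reference base is a purine is reverse-complemented before labeling, so
every channel reads C or T at the mutated position.  Transcription-strand
categories are assigned from transcript overlap:

* ``T`` — the pyrimidine lies on the template (transcribed) strand,
* ``U`` — on the coding (untranscribed) strand,
* ``B`` — transcripts overlap the position on both strands,
* ``N`` — intergenic.

Variant coordinates are 1-based (VCF convention); interval overlap is
computed internally on 0-based half-open intervals.
"""

from __future__ import annotations

import enum
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import log_stage
from .schemas import (
    COMPLEMENT,
    ChannelSchema,
    collapse_indices,
    get_schema,
    parse_core,
    split_label,
)
from .types import ConsensusVariant, MutationCatalog, VariantCall

# ---------------------------------------------------------------------------
# Reference sequence and transcript-interval access


def fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) of a contig, uppercased.

    Accepts a plain ``{chrom: sequence}`` mapping or a ``pyfaidx.Fasta``.
    Out-of-range coordinates raise ``KeyError``/``IndexError``.
    """
    seq = genome[chrom]
    if start0 < 0:
        raise IndexError(f"negative coordinate on {chrom}")
    frag = str(seq[start0:end0]).upper()
    if len(frag) != end0 - start0:
        raise IndexError(f"{chrom}:{start0}-{end0} beyond contig end")
    return frag


def contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


class TranscriptAnnotation:
    """Stranded transcript intervals supporting point-overlap queries."""

    def __init__(self, intervals: list[tuple[str, int, int, str]]):
        """``intervals``: (chrom, start0, end0, strand) half-open records."""
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start0, end0, strand in intervals:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if end0 > start0:
                self._trees[chrom].addi(start0, end0, strand)
        self.intervals = list(intervals)

    @classmethod
    def from_bed(cls, path) -> "TranscriptAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
        if df.shape[1] < 6:
            raise ValueError(f"{path}: BED6 with a strand column required")
        return cls([(str(r[0]), int(r[1]), int(r[2]), str(r[5]))
                    for r in df.itertuples(index=False)])

    @classmethod
    def from_gff3(cls, path,
                  features: tuple[str, ...] = ("gene", "transcript", "mRNA"),
                  ) -> "TranscriptAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str},
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attrs"])
        df = df[df["type"].isin(features)]
        # GFF3 is 1-based inclusive; convert to 0-based half-open.
        return cls([(r.chrom, int(r.start) - 1, int(r.end), r.strand)
                    for r in df.itertuples(index=False)])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, s, e, strand) in enumerate(self.intervals):
                fh.write(f"{chrom}\t{s}\t{e}\tgene{i}\t0\t{strand}\n")

    def strands_at(self, chrom: str, pos0: int) -> frozenset:
        tree = self._trees.get(chrom)
        if tree is None:
            return frozenset()
        return frozenset(iv.data for iv in tree.at(pos0))

    def strand_category(self, chrom: str, pos0: int, pyr_strand: str) -> str:
        """Category of a pyrimidine-normalized mutation at ``pos0``.

        ``pyr_strand`` is the genomic strand carrying the pyrimidine.
        """
        strands = self.strands_at(chrom, pos0)
        if not strands:
            return "N"
        if len(strands) == 2:
            return "B"
        (gene_strand,) = strands
        # The template strand is the reverse of the gene's coding strand:
        # a pyrimidine on the opposite strand from the gene is transcribed.
        return "T" if pyr_strand != gene_strand else "U"


EMPTY_ANNOTATION = TranscriptAnnotation([])


# ---------------------------------------------------------------------------
# SBS classification and catalog construction


def normalize_substitution(ref: str, alt: str, context: str,
                           ) -> tuple[str, str, str, str, str]:
    """Pyrimidine-normalize one substitution.

    ``context`` is the genomic trinucleotide centered on the variant (forward
    strand).  Returns (five, ref, alt, three, pyr_strand).
    """
    if context[1] != ref:
        raise ValueError(
            f"reference mismatch: genome has {context[1]!r}, call has {ref!r}")
    if ref in "CT":
        return context[0], ref, alt, context[2], "+"
    return (context[2].translate(COMPLEMENT), ref.translate(COMPLEMENT),
            alt.translate(COMPLEMENT), context[0].translate(COMPLEMENT), "-")


def classify_sbs(call: VariantCall, genome, annotation: TranscriptAnnotation,
                 schema: ChannelSchema | str) -> str | None:
    """Channel label of one SBS call, or ``None`` if unclassifiable.

    Unclassifiable means: context contains a non-ACGT base, or the position
    sits at a contig edge so no trinucleotide exists.  A position outside the
    contig raises ``IndexError``.
    """
    schema = get_schema(schema)
    if not call.is_sbs:
        raise ValueError(f"not a single-base substitution: {call.ref}>{call.alt}")
    pos0 = call.pos - 1
    if pos0 >= contig_length(genome, call.chrom):
        raise IndexError(f"{call.chrom}:{call.pos} outside contig")
    if pos0 == 0 or pos0 == contig_length(genome, call.chrom) - 1:
        return None  # no trinucleotide context at contig edges
    context = fetch(genome, call.chrom, pos0 - 1, pos0 + 2)
    if any(b not in "ACGT" for b in context):
        return None
    five, ref, alt, three, pyr_strand = normalize_substitution(
        call.ref, call.alt, context)
    core = f"{five}[{ref}>{alt}]{three}"
    if not schema.strand_categories:
        return core
    category = annotation.strand_category(call.chrom, pos0, pyr_strand)
    return schema.label(core, category)


def build_catalog(calls: list[VariantCall], genome,
                  annotation: TranscriptAnnotation,
                  schema: ChannelSchema | str,
                  sample_ids: list[str] | None = None) -> MutationCatalog:
    """Count classified SBS calls into a samples x channels catalog.

    Non-SBS calls and unclassifiable contexts are skipped and tallied in the
    catalog's ``unclassified`` ledger.  Samples listed in ``sample_ids`` but
    absent from ``calls`` are retained as zero rows.  Duplicate records count
    twice — caller-level deduplication is :func:`consensus_filter`'s job.
    """
    schema = get_schema(schema)
    if sample_ids is None:
        seen: dict[str, None] = {}
        for c in calls:
            seen.setdefault(c.sample_id, None)
        sample_ids = list(seen)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    chan_index = schema.index()
    counts = np.zeros((len(sample_ids), schema.n_channels), dtype=np.int64)
    unclassified: dict[str, int] = defaultdict(int)
    for call in calls:
        if call.sample_id not in sample_index:
            raise ValueError(f"undeclared sample {call.sample_id!r}")
        if not call.is_sbs:
            unclassified[call.sample_id] += 1
            continue
        label = classify_sbs(call, genome, annotation, schema)
        if label is None:
            unclassified[call.sample_id] += 1
            continue
        counts[sample_index[call.sample_id], chan_index[label]] += 1
    log_stage("build_catalog", schema=schema.name, n_samples=len(sample_ids),
              n_mutations=int(counts.sum()),
              n_unclassified=sum(unclassified.values()))
    return MutationCatalog(schema, list(sample_ids), counts,
                           unclassified=dict(unclassified))


def collapse(catalog: MutationCatalog,
             target: ChannelSchema | str) -> MutationCatalog:
    """Collapse a catalog to a lower-resolution schema, conserving totals."""
    target = get_schema(target)
    if target.name == catalog.schema.name:
        return MutationCatalog(catalog.schema, list(catalog.sample_ids),
                               catalog.counts.copy())
    idx = collapse_indices(catalog.schema, target)
    out = np.zeros((catalog.n_samples, target.n_channels), dtype=np.int64)
    np.add.at(out, (slice(None), idx), catalog.counts)
    return MutationCatalog(target, list(catalog.sample_ids), out,
                           unclassified=dict(catalog.unclassified))


# ---------------------------------------------------------------------------
# Cross-caller consensus


def consensus_filter(calls: list[VariantCall]) -> list[ConsensusVariant]:
    """Retain variants reported by >= 2 distinct callers.

    Variants are keyed by (sample, chrom, pos, ref, alt); the mean VAF is the
    arithmetic mean over callers that reported one.
    """
    groups: dict[tuple, list[VariantCall]] = defaultdict(list)
    for c in calls:
        groups[c.key].append(c)
    out: list[ConsensusVariant] = []
    for key, grp in groups.items():
        callers = {c.caller_id for c in grp}
        if len(callers) < 2:
            continue
        vafs = [c.vaf for c in grp if c.vaf is not None]
        sample_id, chrom, pos, ref, alt = key
        out.append(ConsensusVariant(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            n_callers=len(callers),
            mean_vaf=float(np.mean(vafs)) if vafs else None,
        ))
    out.sort(key=lambda v: (v.sample_id, v.chrom, v.pos, v.ref, v.alt))
    log_stage("consensus_filter", n_in=len(calls), n_consensus=len(out))
    return out


# ---------------------------------------------------------------------------
# Motif-defined mutational process classes


class MotifClass(enum.Enum):
    """Sequence-context classes standing in for mutational processes.

    Precedence: APOBEC_like > SBS1_like > C_to_A > T_to_C > other_sbs;
    non-SBS records are ``indel``.  APOBEC_like is C>T/C>G at TCW (W = A/T);
    SBS1_like is C>T at XCG.
    """

    APOBEC_LIKE = "APOBEC_like"
    SBS1_LIKE = "SBS1_like"
    C_TO_A = "C_to_A"
    T_TO_C = "T_to_C"
    OTHER_SBS = "other_sbs"
    INDEL = "indel"


def classify_motif(label: str) -> MotifClass:
    """Motif class of one channel label (any schema; strand prefix ignored)."""
    _, core = split_label(label)
    five, ref, alt, three = parse_core(core)
    sub = f"{ref}>{alt}"
    if five == "T" and ref == "C" and alt in "TG" and three in "AT":
        return MotifClass.APOBEC_LIKE
    if sub == "C>T" and three == "G":
        return MotifClass.SBS1_LIKE
    if sub == "C>A":
        return MotifClass.C_TO_A
    if sub == "T>C":
        return MotifClass.T_TO_C
    return MotifClass.OTHER_SBS


def classify_variant_motif(variant, genome,
                           annotation: TranscriptAnnotation = EMPTY_ANNOTATION,
                           ) -> MotifClass:
    """Motif class of a variant record (``VariantCall`` or consensus)."""
    if not variant.is_sbs:
        return MotifClass.INDEL
    call = variant if isinstance(variant, VariantCall) else VariantCall(
        sample_id=variant.sample_id, caller_id="consensus",
        chrom=variant.chrom, pos=variant.pos, ref=variant.ref,
        alt=variant.alt, vaf=getattr(variant, "mean_vaf", None))
    label = classify_sbs(call, genome, annotation, "SBS96")
    if label is None:
        warnings.warn(
            f"missing context at {variant.chrom}:{variant.pos}; "
            "classifying as other_sbs", stacklevel=2)
        return MotifClass.OTHER_SBS
    return classify_motif(label)
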