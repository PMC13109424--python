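"""Readers and writers for the pipeline's file formats.

Variant input comes either as VCF 4.x (one file per sample/caller pair, the
pair identity supplied by the caller of this API or parsed from the file
name as ``<sample>.<caller>.vcf``) or as the tabular dialect: a TSV with
header ``sample  caller  chrom  pos  ref  alt  filter  vaf``.  Signature
catalogs are COSMIC-style TSVs (channel labels x signature columns).
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .config import log_stage
from .types import SignatureMatrix, VariantCall

TABULAR_COLUMNS = ["sample", "caller", "chrom", "pos", "ref", "alt", "filter", "vaf"]
PASS_VALUES = {"PASS", "."}


def _ids_from_filename(path) -> tuple[str | None, str | None]:
    stem = Path(path).name
    for suffix in (".vcf.gz", ".vcf", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    parts = stem.split(".")
    if len(parts) >= 2:
        return parts[0], parts[1]
    return None, None


def read_vcf(path, sample_id: str | None = None,
             caller_id: str | None = None) -> list[VariantCall]:
    """Read one per-sample, per-caller VCF; only FILTER-passing records kept."""
    import pysam

    fn_sample, fn_caller = _ids_from_filename(path)
    sample_id = sample_id or fn_sample
    caller_id = caller_id or fn_caller
    if sample_id is None or caller_id is None:
        raise ValueError(
            f"cannot determine sample/caller identity for {path}; pass them "
            "explicitly or name the file <sample>.<caller>.vcf"
        )
    calls: list[VariantCall] = []
    n_filtered = 0
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            filters = set(rec.filter.keys())
            if filters and filters != {"PASS"}:
                n_filtered += 1
                continue
            vaf = rec.info.get("VAF", None)
            if isinstance(vaf, tuple):
                vaf = vaf[0]
            for alt in rec.alts or ():
                calls.append(VariantCall(
                    sample_id=sample_id, caller_id=caller_id,
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    filter_pass=True,
                    vaf=float(vaf) if vaf is not None else None,
                ))
    log_stage("read_vcf", path=str(path), kept=len(calls), filtered=n_filtered)
    return calls


def read_tabular(path) -> list[VariantCall]:
    """Read the tabular variant dialect; only FILTER-passing rows kept."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str,
                                            "caller": str})
    missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    calls: list[VariantCall] = []
    n_filtered = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if str(row.filter) not in PASS_VALUES:
            n_filtered += 1
            continue
        try:
            vaf = None if pd.isna(row.vaf) else float(row.vaf)
            calls.append(VariantCall(
                sample_id=str(row.sample), caller_id=str(row.caller),
                chrom=str(row.chrom), pos=int(row.pos),
                ref=str(row.ref).upper(), alt=str(row.alt).upper(),
                filter_pass=True, vaf=vaf,
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line_no}: malformed record: {exc}") from exc
    log_stage("read_tabular", path=str(path), kept=len(calls),
              filtered=n_filtered)
    return calls


def read_variant_table(path, format: str = "auto", sample_id: str | None = None,
                       caller_id: str | None = None) -> list[VariantCall]:
    """Read variant calls from VCF or the tabular dialect.

    ``format='auto'`` dispatches on the file extension.
    """
    if format == "auto":
        name = str(path)
        format = "vcf" if name.endswith((".vcf", ".vcf.gz")) else "tabular"
    if format == "vcf":
        return read_vcf(path, sample_id=sample_id, caller_id=caller_id)
    if format == "tabular":
        return read_tabular(path)
    raise ValueError(f"unknown variant table format {format!r}")


def write_tabular(calls: list[VariantCall], path) -> None:
    rows = [
        (c.sample_id, c.caller_id, c.chrom, c.pos, c.ref, c.alt,
         "PASS" if c.filter_pass else "fail",
         "" if c.vaf is None else f"{c.vaf:.4f}")
        for c in calls
    ]
    pd.DataFrame(rows, columns=TABULAR_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)


def write_vcf(calls: list[VariantCall], path, contig_lengths: dict[str, int],
              sample_id: str | None = None) -> None:
    """Write calls (one sample/caller) as a minimal VCF 4.2 file."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">')
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(contig=c.chrom, start=c.pos - 1,
                                 alleles=(c.ref, c.alt))
            rec.filter.add("PASS")
            if c.vaf is not None:
                rec.info["VAF"] = c.vaf
            out.write(rec)


def read_signature_catalog(path) -> SignatureMatrix:
    """Read a COSMIC-style signature TSV.

    Channel order is canonicalized to the inferred schema and each signature
    column renormalized to sum to one.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative signature entries")
    sig = SignatureMatrix.from_frame(df)
    log_stage("read_signature_catalog", path=str(path),
              n_signatures=sig.n_signatures, schema=sig.schema.name)
    return sig
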