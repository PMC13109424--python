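import numpy as np
import pytest

from sigstrat import (
    MotifClass,
    TranscriptAnnotation,
    build_catalog,
    classify_motif,
    classify_sbs,
    classify_variant_motif,
    collapse,
    consensus_filter,
)
from sigstrat.schemas import SBS96, SBS384, revcomp
from sigstrat.types import VariantCall


def brute_force_label(genome, annotation, chrom, pos, ref, alt):
    """Independent oracle: derive the 384 label by direct sequence lookup."""
    seq = genome[chrom]
    i = pos - 1
    ctx = seq[i - 1:i + 2]
    assert ctx[1] == ref
    if ref in "CT":
        core = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
        pyr_strand = "+"
    else:
        rc = revcomp(ctx)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        core = f"{rc[0]}[{comp[ref]}>{comp[alt]}]{rc[2]}"
        pyr_strand = "-"
    strands = {s for (c, a, b, s) in annotation.intervals
               if c == chrom and a <= i < b}
    if not strands:
        cat = "N"
    elif strands == {"+", "-"}:
        cat = "B"
    else:
        (g,) = strands
        cat = "T" if g != pyr_strand else "U"
    return f"{cat}:{core}"


def _variant_at(genome, pos, alt_map=None):
    ref = genome["chr1"][pos - 1]
    alt = (alt_map or {"A": "G", "C": "T", "G": "A", "T": "C"})[ref]
    return VariantCall("S", "caller", "chr1", pos, ref, alt)


def test_known_strand_assignments(tiny_genome):
    genome, annotation = tiny_genome
    seq = genome["chr1"]
    # a pyrimidine inside the '+' gene, outside the antisense overlap:
    # pyrimidine on the coding strand -> U
    pos = next(p for p in range(320, 395)
               if seq[p - 1] == "C" and "N" not in seq[p - 2:p + 1])
    label = classify_sbs(_variant_at(genome, pos), genome, annotation, SBS384)
    assert label.startswith("U:") and "[C>" in label
    # a purine at the same region: pyrimidine sits on the template -> T
    pos = next(p for p in range(320, 395) if seq[p - 1] == "G")
    label = classify_sbs(_variant_at(genome, pos), genome, annotation, SBS384)
    assert label.startswith("T:") and "[C>" in label
    # intergenic -> N; dual-strand overlap -> B
    pos = next(p for p in range(1, 99) if seq[p - 1] in "CT")
    assert classify_sbs(_variant_at(genome, pos), genome, annotation,
                        SBS384).startswith("N:")
    pos = next(p for p in range(252, 299))
    v = _variant_at(genome, pos)
    assert classify_sbs(v, genome, annotation, SBS384).startswith("B:")


def test_purine_call_is_reverse_complemented(tiny_genome):
    genome, annotation = tiny_genome
    seq = genome["chr1"]
    pos = next(p for p in range(2, 999) if seq[p - 1] == "G")
    v = VariantCall("S", "c", "chr1", pos, "G", "A")
    label = classify_sbs(v, genome, annotation, SBS96)
    ctx = seq[pos - 2:pos + 1]
    rc = revcomp(ctx)
    assert label == f"{rc[0]}[C>T]{rc[2]}"


def test_twenty_variant_fixture_matches_brute_force_oracle(tiny_genome):
    genome, annotation = tiny_genome
    seq = genome["chr1"]
    rng = np.random.default_rng(77)
    positions = rng.choice(np.arange(2, 999), size=20, replace=False)
    for pos in positions:
        v = _variant_at(genome, int(pos))
        got = classify_sbs(v, genome, annotation, SBS384)
        want = brute_force_label(genome, annotation, "chr1", int(pos),
                                 v.ref, v.alt)
        assert got == want, f"pos {pos}"


def test_contig_edges_and_unknown_bases(tiny_genome):
    genome, annotation = tiny_genome
    g = {"chr1": "ACNTA" + genome["chr1"]}
    assert classify_sbs(VariantCall("S", "c", "chr1", 1, "A", "G"),
                        g, annotation, SBS96) is None
    assert classify_sbs(VariantCall("S", "c", "chr1", 2, "C", "T"),
                        g, annotation, SBS96) is None  # N in context
    with pytest.raises(IndexError):
        classify_sbs(VariantCall("S", "c", "chr1", 5000, "A", "G"),
                     g, annotation, SBS96)


def test_build_catalog_counts_and_zero_rows(tiny_genome):
    genome, annotation = tiny_genome
    seq = genome["chr1"]
    pos_list = [p for p in range(10, 900, 37)][:6]
    calls = [_variant_at(genome, p) for p in pos_list[:3]]
    calls += [VariantCall("S2", "c", "chr1", p, seq[p - 1],
                          {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p - 1]])
              for p in pos_list[3:]]
    cat = build_catalog(calls, genome, annotation, SBS384,
                        sample_ids=["S", "S2", "EMPTY"])
    assert cat.totals().tolist() == [3, 3, 0]
    # duplicates count twice: deduplication is the consensus filter's job
    cat2 = build_catalog(calls + calls[:1], genome, annotation, SBS384,
                         sample_ids=["S", "S2"])
    assert cat2.totals().tolist() == [4, 3]
    # indel goes to the unclassifiable ledger
    cat3 = build_catalog(
        calls + [VariantCall("S", "c", "chr1", 50, "AT", "A")],
        genome, annotation, SBS384, sample_ids=["S", "S2"])
    assert cat3.totals().tolist() == [3, 3]
    assert cat3.unclassified == {"S": 1}


def test_collapse_of_built_catalog_conserves_totals(tiny_genome):
    genome, annotation = tiny_genome
    rng = np.random.default_rng(5)
    calls = [_variant_at(genome, int(p))
             for p in rng.choice(np.arange(2, 999), size=60, replace=False)]
    cat = build_catalog(calls, genome, annotation, SBS384)
    for target in ("SBS288", "SBS96"):
        assert collapse(cat, target).totals().tolist() == cat.totals().tolist()


class TestConsensusFilter:
    def test_mean_vaf_and_two_caller_retention(self):
        calls = [
            VariantCall("S", "mutect", "chr1", 10, "C", "T", vaf=0.30),
            VariantCall("S", "varscan", "chr1", 10, "C", "T", vaf=0.40),
            VariantCall("S", "mutect", "chr1", 20, "G", "A", vaf=0.20),
        ]
        out = consensus_filter(calls)
        assert len(out) == 1
        assert out[0].pos == 10 and out[0].n_callers == 2
        assert out[0].mean_vaf == pytest.approx(0.35)

    def test_same_caller_twice_is_not_consensus(self):
        calls = [
            VariantCall("S", "mutect", "chr1", 10, "C", "T", vaf=0.3),
            VariantCall("S", "mutect", "chr1", 10, "C", "T", vaf=0.3),
        ]
        assert consensus_filter(calls) == []

    def test_simulated_dropout_matches_brute_force_tally(self):
        rng = np.random.default_rng(11)
        callers = ["muse", "mutect", "varscan"]
        truth = [("S", "chr1", int(p), "C", "T")
                 for p in rng.choice(np.arange(10, 100_000), size=1000,
                                     replace=False)]
        reports = {}
        calls = []
        for caller in callers:
            kept = rng.uniform(size=len(truth)) >= 0.4  # dropout 0.4
            reports[caller] = {t for t, k in zip(truth, kept) if k}
            calls += [VariantCall(t[0], caller, t[1], t[2], t[3], t[4],
                                  vaf=0.3) for t in reports[caller]]
        expected = {t for t in truth
                    if sum(t in reports[c] for c in callers) >= 2}
        got = {(v.sample_id, v.chrom, v.pos, v.ref, v.alt)
               for v in consensus_filter(calls)}
        assert got == expected


class TestMotifClasses:
    def test_motif_template_examples(self):
        assert classify_motif("T[C>G]A") is MotifClass.APOBEC_LIKE
        assert classify_motif("A[C>T]G") is MotifClass.SBS1_LIKE
        assert classify_motif("T:A[C>A]C") is MotifClass.C_TO_A
        assert classify_motif("U:G[T>C]G") is MotifClass.T_TO_C
        assert classify_motif("C[T>G]C") is MotifClass.OTHER_SBS

    def test_enumeration_of_all_96_channels(self):
        by_class = {}
        for core in SBS96.channels:
            by_class.setdefault(classify_motif(core), set()).add(core)
        assert by_class[MotifClass.APOBEC_LIKE] == {
            "T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T"}
        assert by_class[MotifClass.SBS1_LIKE] == {
            "A[C>T]G", "C[C>T]G", "G[C>T]G", "T[C>T]G"}
        assert not (by_class[MotifClass.APOBEC_LIKE]
                    & by_class[MotifClass.SBS1_LIKE])
        # every channel maps to exactly one class
        assert sum(len(v) for v in by_class.values()) == 96

    def test_variant_motif_with_indel_and_missing_context(self, tiny_genome):
        genome, annotation = tiny_genome
        indel = VariantCall("S", "c", "chr1", 50, "AT", "A")
        assert classify_variant_motif(indel, genome) is MotifClass.INDEL
        edge = VariantCall("S", "c", "chr1", 1,
                           genome["chr1"][0],
                           "A" if genome["chr1"][0] != "A" else "C")
        with pytest.warns(UserWarning, match="missing context"):
            assert classify_variant_motif(edge, genome) is MotifClass.OTHER_SBS

    def test_motif_counts_partition_total(self, tiny_genome):
        genome, annotation = tiny_genome
        rng = np.random.default_rng(9)
        calls = [_variant_at(genome, int(p)) for p in
                 rng.choice(np.arange(2, 999), size=50, replace=False)]
        classes = [classify_variant_motif(c, genome) for c in calls]
        assert len(classes) == 50
        assert all(isinstance(c, MotifClass) for c in classes)
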