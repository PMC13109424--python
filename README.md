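# sigstrat

Mutational-signature based stratification of tumor cohorts from
multi-caller somatic variant calls.

Somatic mutation spectra are mixtures of the footprints of mutagenic
processes (tobacco carcinogens, APOBEC cytidine deaminases, clock-like CpG
deamination, alcohol-associated damage, ...). `sigstrat` implements the
full analysis path from per-caller variant tables to process-defined
patient subgroups, for cohorts where variant calls come from several
callers (e.g. MuSE, MuTect2, VarScan2) and per-caller disagreement has to
be handled explicitly:

1. **Catalogs** — classify single-base substitutions into
   pyrimidine-normalized trinucleotide channels with transcription-strand
   categories (SBS96 / SBS288 / SBS384), from a FASTA genome and a BED/GFF3
   transcript annotation.
2. **Rare-spectrum filter** — flag and remove samples whose high-burden
   spectra (> 600 mutations) form cosine-similarity groups of fewer than
   5 samples, to prevent signature bleeding during extraction.
3. **De novo extraction** — replicated KL-NMF on bootstrap-resampled
   catalogs, consensus signatures by Hungarian-matched medoids, and the
   number of signatures *k* chosen from replicate stability (mean
   silhouette on 1−cosine) plus reconstruction gain (mean sample cosine).
4. **Clustering & cross-caller consensus** — K-means on relative signature
   exposures per caller, label alignment by maximum-overlap matching, and a
   stable sample set from the intersection of all callers.
5. **Reference refitting with CI pruning** — per-sample NNLS against a
   reference signature catalog, multinomial-bootstrap percentile confidence
   intervals, and iterated removal of any signature whose interval includes
   zero — the guard against low-burden over-attribution of flat, featureless
   signatures.
6. **APOBEC dissection** — YTCA (APOBEC3A-like) vs RTCA (APOBEC3B-like)
   tetranucleotide counting and motif-class summaries (TCW APOBEC-like,
   XCG SBS1-like, C>A, T>C, indel).
7. **Synthetic cohorts** — a generator that plants signatures, burdens,
   cluster structure, outlier spectra and imperfect pseudo-callers on a
   synthetic genome, with a ledger of the ground truth; plus an
   over-attribution benchmark comparing plain NNLS to the CI-pruned fitter.

## The model in brief

A catalog is a nonnegative count matrix `V` (channels × samples).
Extraction factorizes `V ≈ WH` (signatures `W`, activities `H`) by
multiplicative updates minimizing the generalized Kullback–Leibler
divergence.  Refitting solves, per sample spectrum `y`,

    min_{a ≥ 0} || S a − y ||₂

for reference profiles `S`, then prunes any signature whose bootstrap
`1−α` interval for `aᵢ` includes zero, refitting until the retained set is
stable.

## Worked example

Generate a synthetic 80-sample cohort from four planted strand-biased
signatures (three imperfect pseudo-callers) and run the full pipeline:

```python
from sigstrat import (RunConfig, ClusterPlan, SyntheticSpec,
                      generate_cohort, run_pipeline, synthetic_signatures)

pool = synthetic_signatures(4, "SBS384", seed=7)
plan = [ClusterPlan(20, sig, dominant_share=0.7, burden_range=(100, 600))
        for sig in pool.signature_ids]
cohort = generate_cohort(SyntheticSpec(signature_pool=pool,
                                       cluster_plan=plan, seed=7))

cfg = RunConfig(seed=7, k_range=(2, 6), n_nmf_replicates=10)
result = run_pipeline(cohort.caller_calls, cohort.genome,
                      cohort.annotation, cfg)

rec = result.extraction.chosen
print(f"chosen k          : {result.extraction.chosen_k}")
print(f"mean silhouette   : {rec.mean_silhouette:.3f}")
print(f"mean sample cosine: {rec.mean_sample_cosine:.3f}")
print(f"stable samples    : {len(result.consensus.stable_samples)}/80")
print(f"instability rate  : {result.consensus.instability_rate:.3f}")
```

Output:

```
chosen k          : 4
mean silhouette   : 0.995
mean sample cosine: 0.958
stable samples    : 80/80
instability rate  : 0.000
```

The four planted processes are recovered (`chosen k = 4`) with
near-perfect replicate stability (silhouette 0.995); every sample's
spectrum is reconstructed at cosine 0.958 on average, and all 80 samples
receive the same aligned cluster label from all three pseudo-callers
(instability 0), so the full cohort enters the stable consensus set.

The same stages are available from the shell:

```bash
sigstrat simulate --n-signatures 4 --seed 7 --out-dir sim/
sigstrat catalog sim/calls.callerA.tsv --fasta sim/genome.fa \
    --annotation sim/genes.bed --schema SBS384 --out-dir work/
sigstrat filter-rare work/catalog.callerA.SBS384.tsv --out-dir work/
sigstrat extract work/catalog.filtered.tsv --seed 7 --out-dir work/
sigstrat benchmark-overfit --seed 7 --out-dir work/
```

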