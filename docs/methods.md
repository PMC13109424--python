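# Methods

## Channel schemas and catalog construction

Substitutions are classified in the pyrimidine-normalized convention: if
the reference base is a purine, the substitution and its trinucleotide
context are reverse-complemented so the mutated base reads C or T.  The 96
core channels are ordered substitution-major (C>A, C>G, C>T, T>A, T>C,
T>G; within each, 5' then 3' flank over A/C/G/T).

Strand-aware schemas prefix a transcription-strand category derived from
transcript overlap: **T** when the pyrimidine of the normalized
substitution lies on the template (transcribed) strand of the overlapping
transcript, **U** when on the coding strand, **B** when transcripts cover
the position on both strands, **N** when intergenic.  SBS384 = 96 × {T, U,
B, N}; SBS288 = 96 × {T, U, N}.  Collapsing 384→288 assigns B to N — a
declared convention chosen so per-sample totals are conserved exactly
under every collapse (384→288, 384→96, 288→96); splitting B across T and U
would either double-count or fractionate counts.

Calls whose context contains a non-ACGT base or sits at a contig edge are
excluded from catalogs and tallied per sample in an `unclassified` ledger.
Variant coordinates are 1-based (VCF convention); interval overlap is
computed on 0-based half-open intervals internally.  Duplicate records
count twice by design: deduplication across callers is the consensus
filter's job (variants keyed by sample/locus/allele, retained when ≥ 2
distinct callers report them, VAF averaged over reporting callers).

## Rare-spectrum filtering

Joint NMF extraction can ascribe a signature carried by a few hypermutated
samples to the entire cohort ("signature bleeding").  Samples with more
than `burden_threshold` mutations (default 600, strict inequality) are
compared pairwise by cosine similarity of relative 96-channel spectra and
grouped by average-linkage hierarchical clustering on 1−cosine.  The tree
is cut at a fixed distance (`cut_distance`, default 0.25) rather than a
fixed group count, because the number of distinct rare spectra is an
outcome of the data, not an input.  Samples in groups smaller than
`rare_max_size` (default 5, strict) are flagged rare and removed before
extraction.  Group mean spectra can be annotated with their best-cosine
reference-signature match, as a human-review aid only — the annotation
never influences removal.  Linkage and cut threshold are this package's
choices; average linkage is the conventional default for cosine distances
and 0.25 separates multinomial sampling noise (within-process distances
≲ 0.1 at burdens near the threshold) from distinct processes.

## De novo extraction

`V` (channels × samples) is factorized as `V ≈ WH`, `W, H ≥ 0`, minimizing
the generalized Kullback–Leibler divergence by multiplicative updates
(objective non-increasing per iteration; stop at relative change `< 1e-6`
or 2000 iterations).  `W` columns are normalized to sum to one with the
compensating scale moved into `H`, so signatures are probability
distributions and activities are mutation counts.  Initialization is
nonnegative double-SVD (NNDSVDa) for the first replicate and seeded random
restarts for the rest, which reduces local-minimum variance while keeping
replicates diverse.

For each candidate k, `n_nmf_replicates` (default 30) factorizations run
on multinomial bootstrap resamples of the catalog (per-sample totals
conserved; each sample's stream keyed by `(seed, sample_id)` so resamples
are independent of sample order).  Replicate signatures are aligned to the
first replicate by Hungarian matching on cosine similarity; the aligned
index defines consensus clusters, summarized by their medoids
(renormalized).  Stability is the mean silhouette on 1−cosine over pooled
replicate signatures; with one replicate or k = 1 the silhouette is
undefined and reported as the sentinel 1.0.  Exposures are refit on the
*un-resampled* catalog by NNLS against the consensus signatures (not
averaged over replicates) so the report is deterministic.  Reconstruction
quality is the mean over samples of cosine(observed, reconstructed).

k is chosen as the largest candidate whose silhouette is at or above
`stability_floor` (default 0.8) and whose mean sample cosine improves on
the previous candidate by more than `min_cosine_gain` (default 0.01); the
smallest candidate is exempt from the gain rule.  If no candidate passes,
the most stable k is returned with a warning.  The two thresholds are
package choices: the selection *criteria* (stability plus reconstruction
gain) are standard, but no published numeric rule exists.

## Clustering and cross-caller consensus

Samples are clustered by K-means (k-means++ seeding, best of
`kmeans_restarts` = 50 restarts) on relative exposures; k defaults to the
chosen number of de novo signatures.  Because callers disagree on variant
sets, clustering runs once per caller; labels are aligned to the
lexicographically first caller by Hungarian matching on the label
contingency table (so results do not depend on input order), and the
stable set is the samples assigned the same aligned label by every caller.
The instability rate is `1 − |stable| / |union|`.

Per-caller exposures come, by default, from NNLS refitting of each
caller's catalog against the consensus de novo signatures extracted from
the reference caller; full per-caller NMF extraction is available
(`per_caller_extraction=True`) but is several-fold slower and introduces
per-caller signature-matching ambiguity without changing what the
consensus step measures (per-caller disagreement in exposure space).

## Reference refitting with confidence-interval pruning

Per sample, NNLS solves `min ||S a − y||₂, a ≥ 0` over reference profiles
`S`.  Uncertainty comes from a parametric bootstrap: `n_bootstrap`
(default 200) multinomial resamples of the observed spectrum with the
total conserved, each refit by NNLS, and percentile intervals at level
`1 − ci_alpha` (default 95%).  Percentile endpoints round outward to order
statistics (the conservative finite-B convention) rather than
interpolating; with a plug-in multinomial bootstrap, interpolated
endpoints are slightly anticonservative because resampling conditions on
observed zero channels.  Intervals are reported covering the point
estimate.

Any signature whose lower bound does not exceed zero is pruned — all such
signatures simultaneously, which is deterministic and order-free, unlike
one-at-a-time removal — the reduced set is refit, and the cycle repeats
until every retained interval excludes zero or nothing remains (an empty
final set flags an unexplainable spectrum).  Pruning is the defense
against burden-dependent over-attribution: at low mutation counts NNLS
spreads noise mass onto flat, featureless signatures, and those activities
are exactly the ones whose intervals include zero.

Refitting defaults to the 288-channel space when the reference catalog
carries strand-bias versions; a 96-channel mode covers references without
them.  De novo signatures are themselves decomposed into reference
signatures by NNLS with weights reported as percentages plus a
reconstruction cosine.

## Synthetic cohorts and what they do (not) show

The spectrum generator draws signature contributions uniformly on (0,1)
and normalizes them to sum to one (or takes fixed cluster weights:
dominant share `d` for the planted process, the remainder spread
uniformly), computes channel probabilities as the weighted sum of
signature profiles, and samples mutations with replacement (multinomially)
until the assigned burden is reached.

The cohort generator extends this to positioned variants on a synthetic
genome (default 10 contigs × 100 kb, genes tiled on alternating strands
with one antisense overlap per contig so all four strand categories
exist).  Every emitted channel count is realized at a uniformly chosen
genomic site whose trinucleotide context and strand category match the
channel, so the catalog stage must reproduce the generator's ledger
exactly — this round trip is the oracle for the positional stages.
Pseudo-callers re-report the shared truth with per-caller sensitivity
(defaults 0.95/0.90/0.85) and add false calls at a per-variant rate
(0.02–0.03) at uniform random sites; there is no read-level or alignment
simulation.  Synthetic signature pools are sparse Dirichlet draws
(concentration 0.05) with pairwise cosine bounded (default < 0.5) and
per-signature strand asymmetry; outlier spectra use concentration 0.01,
giving the near-monotone extreme profiles that rare-spectrum screening
targets.

Default cohort scale follows the analysis conditions the pipeline targets:
a few hundred samples in four dominant-process clusters with burdens from
tens to ~2 000, nine injected outlier samples across six rare profiles,
and three imperfect callers.  The over-attribution benchmark uses 500
samples per burden over the grid 50/100/200/500/1000, with a uniform
("flat") signature in the candidate pool but excluded from the generating
truth; attributed flat activity is reported in counts and as a fraction of
burden — the fraction is the scale on which over-attribution shrinks with
burden (absolute noise mass grows roughly like √n).

Passing these tests shows the pipeline recovers structure *it generated*:
multinomial spectra, independent caller errors, uniform variant placement.
Real cohorts add context biases, shared caller artifacts, copy-number and
purity effects, and signatures far more collinear than a cosine-bounded
pool — so synthetic recovery bounds correctness of the machinery, not
field performance.

## Numerical choices and degenerate inputs

- KL-NMF guards divisions with ε = 1e-12; k must not exceed
  min(channels, samples); all-zero sample columns are rejected (the
  pipeline drops zero-total samples with a warning first).
- Cosine matrices are clipped to [0, 1] and given an exact unit diagonal
  before linkage; zero-total spectra are excluded with a warning.
- Consensus signature naming orders by total fitted activity
  (largest first) for stable letters across runs.
- NNLS activities within 1e-9 of zero count as zero for pruning.
- Every randomized stage derives its generator from
  `(seed, stage-name)` via SHA-256 (31-bit seeds), so stages are
  independently reproducible and adding a stage never perturbs another.
- Catalog/exposure/signature TSVs round-trip exactly (counts) or to
  1e-12 (probabilities); channel order is canonicalized on read.

## Known limitations

- No indel (ID83) or doublet (DBS) catalogs: indels enter only the
  consensus variant set and the motif tally.
- The 384→288 B→N convention is a package choice; tools that split B
  across T and U will disagree on 288-channel catalogs at
  bidirectionally transcribed loci.
- The rare-spectrum cut distance and the k-selection thresholds are
  heuristics exposed in `RunConfig`; cohorts with genuinely continuous
  spectrum variation have no "correct" cut.
- CI pruning controls over-attribution of signatures distinguishable from
  the truth; it cannot separate near-collinear signatures (e.g. two flat
  signatures in the same pool prune arbitrarily between them).
- Acceptance-scale runs (tests and `scripts/acceptance.py`) use k over
  2..6 with 10 NMF replicates and bootstrap sizes of 100–200 — sizes at
  which the selection and calibration behavior is already stable;
  `RunConfig` defaults (k 2..10, 30 replicates) suit full analyses.
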