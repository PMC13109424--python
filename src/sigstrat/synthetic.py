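"""Synthetic mutation spectra, cohorts, and the over-attribution benchmark.

The spectrum generator follows the simulation design used to probe
signature over-attribution: per sample, signature contributions are drawn
from a uniform distribution and normalized to sum to one (or fixed by a
cluster plan), channel probabilities are the weighted sum of signature
profiles, and mutations are sampled with replacement (multinomially) until
the assigned mutation count is reached.

The cohort generator extends spectrum sampling to positioned variants on a
small synthetic genome so the positional stages (context classification,
strand assignment, caller consensus) are testable: every emitted channel
count is realized as substitutions placed uniformly among genomic sites
whose trinucleotide context and transcription-strand category match the
channel, and three imperfect pseudo-callers re-report the truth with
dropout and false calls.  A ledger records the ground truth for every
sample, so that generator bookkeeping can serve as the oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import TranscriptAnnotation
from .config import log_stage, stage_rng, stage_seed
from .refit import attribute_with_ci, nnls_fit
from .schemas import (
    BASES,
    CORE96,
    ChannelSchema,
    get_schema,
    parse_core,
    split_label,
)
from .types import SignatureMatrix, VariantCall

_B2I = {b: i for i, b in enumerate(BASES)}
_CAT2I = {"T": 0, "U": 1, "B": 2, "N": 3}
_I2CAT = "TUBN"


# ---------------------------------------------------------------------------
# Signature pools


def synthetic_signatures(n: int, schema: ChannelSchema | str = "SBS96",
                         seed: int = 0, concentration: float = 0.05,
                         max_pairwise_cosine: float = 0.5,
                         ids: list[str] | None = None,
                         max_tries: int = 200) -> SignatureMatrix:
    """Random sparse signature profiles with bounded pairwise cosine.

    Core 96-channel profiles are sparse Dirichlet draws (small
    ``concentration`` gives spiky, process-like profiles), re-drawn until
    each new profile's cosine with every accepted one is below
    ``max_pairwise_cosine``.  For strand-aware schemas each signature gets
    its own transcription-strand asymmetry: per-core mass is split across
    the T/U/N categories by a signature-level Dirichlet draw (B mass is
    zero; bidirectionally transcribed sites are rare).
    """
    schema = get_schema(schema)
    rng = np.random.default_rng(stage_seed(seed, "synthetic_signatures"))
    cores: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_tries):
            cand = rng.dirichlet(np.full(96, concentration))
            ok = all(
                cand @ c / (np.linalg.norm(cand) * np.linalg.norm(c))
                < max_pairwise_cosine
                for c in cores)
            if ok:
                cores.append(cand)
                break
        else:
            raise RuntimeError("could not find a sufficiently distinct profile")
    profiles = np.zeros((n, schema.n_channels))
    if not schema.strand_categories:
        profiles[:] = np.array(cores)
    else:
        for i, core in enumerate(cores):
            cat_w = {c: 0.0 for c in "TUBN"}
            w = rng.dirichlet([3.0, 3.0, 1.0])  # T, U, N shares
            # strand asymmetry: tilt the T/U split per signature
            tilt = rng.uniform(0.2, 0.8)
            tu = w[0] + w[1]
            cat_w.update({"T": tu * tilt, "U": tu * (1 - tilt), "N": w[2]})
            for j, label in enumerate(schema.channels):
                cat, corelab = split_label(label)
                profiles[i, j] = core[CORE96.index(corelab)] * cat_w[cat]
    if ids is None:
        ids = [f"SYN{i + 1}" for i in range(n)]
    return SignatureMatrix(schema, ids, profiles)


def flat_signature(schema: ChannelSchema | str = "SBS96",
                   sig_id: str = "FLAT") -> SignatureMatrix:
    """A featureless, uniform signature (the over-attribution magnet)."""
    schema = get_schema(schema)
    return SignatureMatrix(schema, [sig_id],
                           np.full((1, schema.n_channels),
                                   1.0 / schema.n_channels))


# ---------------------------------------------------------------------------
# Spectrum-level generation


def generate_profile(signature_pool: SignatureMatrix,
                     weights, mutation_count: int,
                     rng: np.random.Generator | int = 0,
                     ) -> tuple[np.ndarray, dict]:
    """One synthetic spectrum: weighted mixture, multinomial sampling.

    ``weights`` is a vector over pool signatures or the string ``"random"``
    (uniform(0,1) draws, normalized to sum to one).  Returns the channel
    count vector and a ledger entry recording the weights and counts.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(weights, str):
        if weights != "random":
            raise ValueError(f"unknown weight model {weights!r}")
        w = rng.uniform(0.0, 1.0, size=signature_pool.n_signatures)
    else:
        w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    p = w @ signature_pool.profiles
    counts = (rng.multinomial(int(mutation_count), p)
              if mutation_count > 0
              else np.zeros(signature_pool.schema.n_channels, dtype=np.int64))
    ledger = {
        "weights": dict(zip(signature_pool.signature_ids, w.tolist())),
        "counts": counts,
        "burden": int(mutation_count),
    }
    return counts, ledger


# ---------------------------------------------------------------------------
# Synthetic genome and context site index


def make_genome(n_contigs: int = 10, contig_len: int = 100_000,
                seed: int = 0, gene_len: int = 8_000, gap_len: int = 2_000,
                ) -> tuple[dict[str, str], TranscriptAnnotation]:
    """Random genome with genes tiled on alternating strands.

    Each contig carries a small antisense gene overlapping one sense gene so
    bidirectionally transcribed (B-category) positions exist.
    """
    rng = np.random.default_rng(stage_seed(seed, "make_genome"))
    genome: dict[str, str] = {}
    intervals: list[tuple[str, int, int, str]] = []
    for c in range(n_contigs):
        chrom = f"chr{c + 1}"
        seq = "".join(np.array(list(BASES))[
            rng.integers(0, 4, size=contig_len)])
        genome[chrom] = seq
        pos, gene_i = gap_len, 0
        while pos + gene_len <= contig_len - gap_len:
            strand = "+" if gene_i % 2 == 0 else "-"
            intervals.append((chrom, pos, pos + gene_len, strand))
            pos += gene_len + gap_len
            gene_i += 1
        if gene_i > 0:
            # antisense overlap inside the first gene -> B category sites
            first = intervals[-gene_i]
            anti_strand = "-" if first[3] == "+" else "+"
            mid = first[1] + gene_len // 2
            intervals.append((chrom, mid, mid + 1_000, anti_strand))
    return genome, TranscriptAnnotation(intervals)


class SiteIndex:
    """Genomic sites grouped by (pyrimidine-strand trinucleotide, category)."""

    def __init__(self, genome: dict[str, str],
                 annotation: TranscriptAnnotation):
        self.chroms = list(genome)
        buckets: dict[tuple[int, int], list[np.ndarray]] = {}
        for ci, chrom in enumerate(self.chroms):
            seq = genome[chrom]
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.int8) - 1
            for b, i in _B2I.items():
                lut[ord(b)] = i
            codes = lut[codes]
            L = len(seq)
            plus = np.zeros(L, dtype=bool)
            minus = np.zeros(L, dtype=bool)
            for (ch, s, e, strand) in annotation.intervals:
                if ch == chrom:
                    (plus if strand == "+" else minus)[s:e] = True
            center = codes[1:-1]
            five = codes[:-2]
            three = codes[2:]
            valid = (center >= 0) & (five >= 0) & (three >= 0)
            pyr_fwd = (center == 1) | (center == 3)  # C or T
            tri_fwd = five * 16 + center * 4 + three
            tri_rev = (3 - three) * 16 + (3 - center) * 4 + (3 - five)
            tri = np.where(pyr_fwd, tri_fwd, tri_rev)
            p = plus[1:-1]
            m = minus[1:-1]
            cat = np.full(center.shape, _CAT2I["N"], dtype=np.int8)
            both = p & m
            cat[both] = _CAT2I["B"]
            only_p = p & ~m
            only_m = m & ~p
            # pyrimidine on template strand => T
            cat[only_p & ~pyr_fwd] = _CAT2I["T"]
            cat[only_p & pyr_fwd] = _CAT2I["U"]
            cat[only_m & pyr_fwd] = _CAT2I["T"]
            cat[only_m & ~pyr_fwd] = _CAT2I["U"]
            key = tri.astype(np.int64) * 4 + cat
            key[~valid] = -1
            order = np.argsort(key, kind="stable")
            sorted_key = key[order]
            starts = np.searchsorted(sorted_key, np.arange(0, 64 * 4))
            ends = np.searchsorted(sorted_key, np.arange(0, 64 * 4), "right")
            pos0 = order + 1  # center index within contig
            for kk in range(64 * 4):
                if ends[kk] > starts[kk]:
                    sel = pos0[starts[kk]:ends[kk]]
                    rec = np.empty((sel.size, 3), dtype=np.int64)
                    rec[:, 0] = ci
                    rec[:, 1] = sel
                    rec[:, 2] = pyr_fwd[sel - 1]
                    buckets.setdefault((kk // 4, kk % 4), []).append(rec)
        self.buckets: dict[tuple[int, int], np.ndarray] = {
            k: np.vstack(v) for k, v in buckets.items()}

    @staticmethod
    def _tri_code(five: str, ref: str, three: str) -> int:
        return _B2I[five] * 16 + _B2I[ref] * 4 + _B2I[three]

    def sites_for(self, label: str) -> list[np.ndarray]:
        """Site arrays matching a channel label (all categories for SBS96)."""
        cat, core = split_label(label)
        five, ref, _, three = parse_core(core)
        tri = self._tri_code(five, ref, three)
        if cat is None:
            cats = range(4)
        else:
            cats = [_CAT2I[cat]]
        return [self.buckets[(tri, c)] for c in cats
                if (tri, c) in self.buckets]


# ---------------------------------------------------------------------------
# Cohort specification and generation


@dataclass
class ClusterPlan:
    """One planted cluster: size, dominant process, and burden range."""

    n_samples: int
    dominant_signature: str
    dominant_share: float = 0.7
    burden_range: tuple[int, int] = (100, 500)


@dataclass
class OutlierPlan:
    """Rare spectra injected as extreme, high-burden samples."""

    profiles: SignatureMatrix  # one artificial spectrum per profile
    samples_per_profile: list[int]
    burden: int = 2_000


@dataclass
class CallerModel:
    caller_id: str
    sensitivity: float = 0.9
    false_call_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1):
            raise ValueError("sensitivity must be in [0, 1]")
        if self.false_call_rate < 0:
            raise ValueError("false_call_rate must be nonnegative")


DEFAULT_CALLERS = (
    CallerModel("callerA", 0.95, 0.02),
    CallerModel("callerB", 0.90, 0.03),
    CallerModel("callerC", 0.85, 0.02),
)


@dataclass
class SyntheticSpec:
    """Everything needed to generate one synthetic cohort."""

    signature_pool: SignatureMatrix
    cluster_plan: list[ClusterPlan] | None = None
    n_samples: int = 0  # used when cluster_plan is None (random weights)
    burden_range: tuple[int, int] = (50, 1_000)
    callers: tuple[CallerModel, ...] = DEFAULT_CALLERS
    outlier_plan: OutlierPlan | None = None
    n_contigs: int = 10
    contig_len: int = 100_000
    seed: int = 0


@dataclass
class SampleTruth:
    sample_id: str
    weights: dict[str, float]
    channel_counts: np.ndarray
    burden: int
    cluster_label: int | None
    outlier: bool


@dataclass
class GeneratorLedger:
    """Ground truth of a generated cohort (the oracle for every test)."""

    schema_name: str
    signature_ids: list[str]
    samples: dict[str, SampleTruth]
    caller_reports: dict[str, set] = field(default_factory=dict)

    def cluster_labels(self) -> dict[str, int]:
        return {s: t.cluster_label for s, t in self.samples.items()
                if t.cluster_label is not None}

    def outlier_samples(self) -> list[str]:
        return sorted(s for s, t in self.samples.items() if t.outlier)

    def channel_totals(self) -> np.ndarray:
        return np.sum([t.channel_counts for t in self.samples.values()],
                      axis=0)


@dataclass
class SyntheticCohort:
    genome: dict[str, str]
    annotation: TranscriptAnnotation
    schema: ChannelSchema
    true_variants: list[VariantCall]
    caller_calls: dict[str, list[VariantCall]]
    ledger: GeneratorLedger

    @property
    def all_calls(self) -> list[VariantCall]:
        return [c for calls in self.caller_calls.values() for c in calls]

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _place_sample(sample_id: str, counts: np.ndarray, schema: ChannelSchema,
                  index: SiteIndex, genome: dict[str, str],
                  rng: np.random.Generator, max_tries: int = 100,
                  ) -> list[VariantCall]:
    calls: list[VariantCall] = []
    used: set[tuple[str, int]] = set()
    comp = str.maketrans("ACGT", "TGCA")
    for j in np.nonzero(counts)[0]:
        label = schema.channels[j]
        _, core = split_label(label)
        _, ref, alt, _ = parse_core(core)
        site_arrays = index.sites_for(label)
        if not site_arrays:
            raise RuntimeError(f"no genomic site matches channel {label}")
        sites = site_arrays[0] if len(site_arrays) == 1 \
            else np.vstack(site_arrays)
        for _ in range(int(counts[j])):
            for _ in range(max_tries):
                ci, pos0, fwd = sites[rng.integers(sites.shape[0])]
                chrom = index.chroms[ci]
                if (chrom, int(pos0)) not in used:
                    break
            else:
                raise RuntimeError(
                    f"could not place channel {label} without collision")
            used.add((chrom, int(pos0)))
            if fwd:
                vref, valt = ref, alt
            else:
                vref, valt = ref.translate(comp), alt.translate(comp)
            calls.append(VariantCall(
                sample_id=sample_id, caller_id="truth", chrom=chrom,
                pos=int(pos0) + 1, ref=vref, alt=valt,
                vaf=float(rng.uniform(0.08, 0.6))))
    return calls


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a positioned synthetic cohort with pseudo-caller reports."""
    schema = spec.signature_pool.schema
    genome, annotation = make_genome(spec.n_contigs, spec.contig_len,
                                     seed=spec.seed)
    index = SiteIndex(genome, annotation)
    rng = stage_rng(spec.seed, "generate_cohort")
    pool = spec.signature_pool
    sig_ids = list(pool.signature_ids)
    samples: dict[str, SampleTruth] = {}
    true_variants: list[VariantCall] = []

    def add_sample(sample_id, weights, burden, cluster_label, outlier,
                   profile_override=None):
        if profile_override is None:
            counts, entry = generate_profile(pool, weights, burden, rng)
            wdict = entry["weights"]
        else:
            counts = rng.multinomial(burden, profile_override)
            wdict = {}
        truth = SampleTruth(sample_id=sample_id, weights=wdict,
                            channel_counts=counts, burden=int(burden),
                            cluster_label=cluster_label, outlier=outlier)
        samples[sample_id] = truth
        true_variants.extend(
            _place_sample(sample_id, counts, schema, index, genome, rng))

    if spec.cluster_plan:
        s_idx = 0
        for lab, plan in enumerate(spec.cluster_plan):
            dom = sig_ids.index(plan.dominant_signature)
            for _ in range(plan.n_samples):
                rest = rng.uniform(0.0, 1.0, size=len(sig_ids))
                rest[dom] = 0.0
                rest = (1 - plan.dominant_share) * rest / rest.sum()
                w = rest.copy()
                w[dom] = plan.dominant_share
                burden = int(rng.integers(plan.burden_range[0],
                                          plan.burden_range[1] + 1))
                add_sample(f"S{s_idx:04d}", w, burden, lab, False)
                s_idx += 1
    else:
        for i in range(spec.n_samples):
            burden = int(rng.integers(spec.burden_range[0],
                                      spec.burden_range[1] + 1))
            add_sample(f"S{i:04d}", "random", burden, None, False)

    if spec.outlier_plan:
        o_idx = 0
        op = spec.outlier_plan
        if op.profiles.schema.name != schema.name:
            raise ValueError("outlier profiles must share the cohort schema")
        for pi, n_rep in enumerate(op.samples_per_profile):
            for _ in range(n_rep):
                add_sample(f"OUT{o_idx:02d}", None, op.burden, None, True,
                           profile_override=op.profiles.profiles[pi])
                o_idx += 1

    # pseudo-callers: dropout + false calls over the shared truth
    caller_calls: dict[str, list[VariantCall]] = {}
    caller_reports: dict[str, set] = {}
    contigs = list(genome)
    by_sample: dict[str, list[VariantCall]] = {}
    for v in true_variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    for model in spec.callers:
        crng = stage_rng(spec.seed, f"caller:{model.caller_id}")
        calls: list[VariantCall] = []
        reported: set = set()
        for sample_id, variants in by_sample.items():
            keep = crng.uniform(size=len(variants)) < model.sensitivity
            for v, k in zip(variants, keep):
                if not k:
                    continue
                vaf = float(np.clip(v.vaf + crng.normal(0, 0.02), 0.01, 0.99))
                call = VariantCall(sample_id=sample_id,
                                   caller_id=model.caller_id, chrom=v.chrom,
                                   pos=v.pos, ref=v.ref, alt=v.alt, vaf=vaf)
                calls.append(call)
                reported.add(call.key)
            n_false = crng.binomial(len(variants), model.false_call_rate)
            placed = 0
            while placed < n_false:
                chrom = contigs[crng.integers(len(contigs))]
                pos0 = int(crng.integers(1, len(genome[chrom]) - 1))
                ref = genome[chrom][pos0]
                if ref not in "ACGT":
                    continue
                alt = "ACGT"[crng.integers(4)]
                if alt == ref:
                    continue
                call = VariantCall(sample_id=sample_id,
                                   caller_id=model.caller_id, chrom=chrom,
                                   pos=pos0 + 1, ref=ref, alt=alt,
                                   vaf=float(crng.uniform(0.01, 0.15)))
                calls.append(call)
                reported.add(call.key)
                placed += 1
        caller_calls[model.caller_id] = calls
        caller_reports[model.caller_id] = reported
    ledger = GeneratorLedger(schema_name=schema.name, signature_ids=sig_ids,
                             samples=samples, caller_reports=caller_reports)
    log_stage("generate_cohort", n_samples=len(samples),
              n_true_variants=len(true_variants),
              n_callers=len(spec.callers))
    return SyntheticCohort(genome=genome, annotation=annotation,
                           schema=schema, true_variants=true_variants,
                           caller_calls=caller_calls, ledger=ledger)


# ---------------------------------------------------------------------------
# Planted tetranucleotide (YTCA/RTCA) sample


def generate_tetra_sample(n_mutations: int = 1_000, ytca_fraction: float = 0.7,
                          seed: int = 0, sample_id: str = "APOBEC",
                          genome: dict[str, str] | None = None,
                          ) -> tuple[list[VariantCall], dict, dict[str, str]]:
    """APOBEC-context sample with an exact planted YTCA/RTCA split.

    Places ``round(ytca_fraction * n)`` C>T/C>G mutations at TCA sites whose
    -2 base is a pyrimidine and the rest at purine -2 sites.  Returns the
    calls, a ledger with the exact planted counts, and the genome used.
    """
    rng = stage_rng(seed, "generate_tetra")
    if genome is None:
        genome, _ = make_genome(n_contigs=4, contig_len=50_000, seed=seed)
    comp = str.maketrans("ACGT", "TGCA")
    y_sites: list[tuple[str, int, bool]] = []  # (chrom, pos0, pyr_forward)
    r_sites: list[tuple[str, int, bool]] = []
    for chrom, seq in genome.items():
        for i in range(2, len(seq) - 2):
            if seq[i] == "C" and seq[i - 1] == "T" and seq[i + 1] == "A":
                minus2 = seq[i - 2]
                (y_sites if minus2 in "CT" else r_sites).append(
                    (chrom, i, True))
            elif seq[i] == "G" and seq[i + 1] == "A" and seq[i - 1] == "T":
                minus2 = seq[i + 2].translate(comp)
                (y_sites if minus2 in "CT" else r_sites).append(
                    (chrom, i, False))
    n_y = int(round(ytca_fraction * n_mutations))
    n_r = n_mutations - n_y
    if n_y > len(y_sites) or n_r > len(r_sites):
        raise RuntimeError("genome too small for the requested tetra counts")
    calls: list[VariantCall] = []
    for sites, count in ((y_sites, n_y), (r_sites, n_r)):
        chosen = rng.choice(len(sites), size=count, replace=False)
        for idx in chosen:
            chrom, pos0, fwd = sites[int(idx)]
            alt_pyr = "T" if rng.uniform() < 0.5 else "G"
            if fwd:
                ref, alt = "C", alt_pyr
            else:
                ref, alt = "G", alt_pyr.translate(comp)
            calls.append(VariantCall(sample_id=sample_id, caller_id="truth",
                                     chrom=chrom, pos=pos0 + 1, ref=ref,
                                     alt=alt))
    ledger = {"ytca": n_y, "rtca": n_r, "tca_total": n_mutations}
    return calls, ledger, genome


# ---------------------------------------------------------------------------
# Over-attribution benchmark


def benchmark_overattribution(signature_pool: SignatureMatrix,
                              absent_signature: str,
                              burden_grid=(50, 100, 200, 500, 1_000),
                              n_samples_per_burden: int = 500,
                              seed: int = 0, n_bootstrap: int = 100,
                              ci_alpha: float = 0.05) -> pd.DataFrame:
    """Measure attribution of a signature absent from the generating truth.

    For each burden, ``n_samples_per_burden`` spectra are generated from the
    pool *excluding* ``absent_signature`` (uniform-then-normalized weights)
    and refit against the *full* pool twice: plain NNLS, and NNLS with
    bootstrap-CI pruning.  Any activity landing on the absent signature is
    pure over-attribution.  Returns one row per (burden, fitter) with the
    mean attributed activity in mutation counts and as a fraction of burden.
    """
    ids = list(signature_pool.signature_ids)
    if absent_signature not in ids:
        raise ValueError(f"{absent_signature!r} not in pool")
    absent_idx = ids.index(absent_signature)
    present = [i for i in range(len(ids)) if i != absent_idx]
    gen_pool = signature_pool.subset([ids[i] for i in present])
    rows = []
    for burden in burden_grid:
        rng = stage_rng(seed, f"benchmark:burden={burden}")
        counts = {"nnls": [], "ci_pruned": []}
        for s in range(n_samples_per_burden):
            spectrum, _ = generate_profile(gen_pool, "random", burden, rng)
            act = nnls_fit(spectrum.astype(float), signature_pool)
            counts["nnls"].append(act[absent_idx])
            fit = attribute_with_ci(
                spectrum, signature_pool, n_bootstrap=n_bootstrap,
                ci_alpha=ci_alpha,
                seed=stage_seed(seed, f"benchmark:{burden}:{s}"),
                sample_id=f"b{burden}s{s}")
            counts["ci_pruned"].append(fit.activities[absent_idx])
        for fitter, vals in counts.items():
            vals = np.asarray(vals)
            rows.append({
                "burden": burden, "fitter": fitter,
                "signature": absent_signature,
                "mean_attributed_count": float(vals.mean()),
                "mean_attributed_fraction": float(vals.mean() / burden),
                "mean_true_activity": 0.0,
                "over_attribution_fraction": float(vals.mean() / burden),
            })
        log_stage("benchmark_overattribution", burden=burden,
                  nnls=round(rows[-2]["mean_attributed_fraction"], 4),
                  ci_pruned=round(rows[-1]["mean_attributed_fraction"], 4))
    return pd.DataFrame(rows)
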