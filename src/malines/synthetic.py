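"""Synthetic mutation-accumulation experiments and coalescent samples.

The MA generator emulates the study design the pipeline targets: one diploid
ancestor, offspring lines in three treatments (indoor, outdoor without UV,
outdoor with UV) propagated as single descendants for 20 generations, then
short-read sequenced at ~28x mean coverage. True mutations arise as
heterozygous single-nucleotide events, Poisson over callable site-generations;
ancestral heterozygous loci are inherited clonally with occasional loss of
heterozygosity; artifact sites (multi-sample sharing, dense clusters, low
quality annotations, repeat-region indels) are injected so every downstream
filter has work to do.

The coalescent generator is a standard Hudson infinite-sites simulator used
as a test harness for the diversity estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    HET,
    HOM_ALT,
    HOM_REF,
    CallableMask,
    SampleCall,
    SimTruth,
    SiteCall,
    sort_calls,
)

ANCESTOR_ID = "ancestor"
BASES = "ACGT"

# stable sub-stream keys so per-line streams are independent of each other
_K_REPEATS = 1
_K_REF = 2
_K_ANC = 3
_K_ART = 4
_K_DEPTH = 10_000
_K_LINE = 20_000
_K_ERR = 30_000
_K_SITE = 40_000


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(k) for k in key]])


@dataclass
class SimConfig:
    """Configuration of a synthetic MA experiment.

    Defaults mirror the targeted study design: 3 treatments x 5 lines,
    g = 20 single-descendant generations, 28x mean coverage, and per-treatment
    true rates equal to the treatment means estimated in the duckweed MA
    experiment (indoor 0, outdoor-noUV 7.92e-11, outdoor-UV 2.38e-10
    mutations/site/generation). The genome is scaled to 1 Mb so a run takes
    seconds; rates are per-site so all downstream estimators are unaffected
    by the scaling. ``depth_dispersion`` is the negative-binomial size
    parameter (variance = m + m^2/k); ``None`` gives constant depth.
    """

    genome_length: int = 1_000_000
    chrom: str = "chr1"
    treatments: tuple[str, ...] = ("indoor", "outdoor-noUV", "outdoor-UV")
    n_lines_per_treatment: int = 5
    true_mu_per_treatment: dict[str, float] = field(
        default_factory=lambda: {
            "indoor": 0.0,
            "outdoor-noUV": 7.92e-11,
            "outdoor-UV": 2.38e-10,
        }
    )
    generations: int = 20
    mean_depth: float = 28.0
    depth_dispersion: float | None = 20.0
    seq_error_rate: float = 1e-3
    n_ancestor_hets: int = 240  # matches the ancestral het density of ~2.4e-4/bp
    loh_rate: float = 6.6e-6  # per het site per line
    artifact_site_rate: float = 1e-6  # per bp
    indel_artifact_rate: float = 1.7e-7  # per bp, placed in repeats
    repeat_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for t in self.true_mu_per_treatment:
            if t not in self.treatments:
                raise ValueError(f"unknown treatment label {t!r}")
        for name in ("seq_error_rate", "loh_rate", "artifact_site_rate",
                     "indel_artifact_rate", "repeat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for t in self.treatments:
            if self.true_mu_per_treatment.get(t, 0.0) < 0:
                raise ValueError("mutation rates must be non-negative")

    @property
    def line_ids(self) -> list[str]:
        return [
            f"{t}-{i + 1}"
            for t in self.treatments
            for i in range(self.n_lines_per_treatment)
        ]

    def treatment_of(self, line_id: str) -> str:
        return line_id.rsplit("-", 1)[0]


def _sample_depths(config: SimConfig, sample_index: int) -> np.ndarray:
    rng = _rng(config.seed, _K_DEPTH + sample_index)
    m = config.mean_depth
    if config.depth_dispersion is None:
        return np.full(config.genome_length, int(round(m)), dtype=np.int32)
    k = config.depth_dispersion
    p = k / (k + m)
    return rng.negative_binomial(k, p, size=config.genome_length).astype(np.int32)


def simulate_repeat_mask(config: SimConfig) -> np.ndarray:
    """Repeat intervals (0-based half-open) covering ~repeat_fraction of the genome."""
    rng = _rng(config.seed, _K_REPEATS)
    L = config.genome_length
    target = int(config.repeat_fraction * L)
    intervals: list[tuple[int, int]] = []
    covered = 0
    while covered < target:
        width = min(500, L)
        start = int(rng.integers(0, max(1, L - width)))
        intervals.append((start, start + width))
        covered += width
    if not intervals:
        return np.empty((0, 2), dtype=np.int64)
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


GENOTYPING_ERROR = 1e-3  # per-read error the caller assumes (Q30 base quality)


def _ml_genotype(ad_ref: int, ad_alt: int, e: float = GENOTYPING_ERROR) -> str:
    """Maximum-likelihood diploid genotype from allele depths.

    Emulates a caller: hom-ref explains alt reads as errors (rate e), het
    expects balanced alleles, hom-alt mirrors hom-ref. This is what keeps a
    3-of-28 error pile-up from being called heterozygous.
    """
    if ad_ref + ad_alt == 0:
        return "missing"
    ll_rr = ad_alt * np.log(e) + ad_ref * np.log(1 - e)
    ll_het = (ad_ref + ad_alt) * np.log(0.5)
    ll_aa = ad_ref * np.log(e) + ad_alt * np.log(1 - e)
    best = max(ll_rr, ll_het, ll_aa)
    if best == ll_het:
        return HET
    return HOM_REF if ll_rr >= ll_aa else HOM_ALT


def _ref_alt(rng: np.random.Generator) -> tuple[str, str]:
    ref = BASES[rng.integers(4)]
    alt = BASES[rng.integers(4)]
    while alt == ref:
        alt = BASES[rng.integers(4)]
    return ref, alt


def _het_call(rng: np.random.Generator, dp: int) -> SampleCall:
    """A true heterozygote: balanced binomial allele depths, genotype as the
    caller would assign it (extreme imbalance is miscalled homozygous)."""
    if dp == 0:
        return SampleCall(gt="missing", ad_ref=0, ad_alt=0, dp=0)
    ad_alt = int(rng.binomial(dp, 0.5))
    return SampleCall(gt=_ml_genotype(dp - ad_alt, ad_alt),
                      ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp)


def _hom_ref_call(dp: int) -> SampleCall:
    return SampleCall(gt=HOM_REF, ad_ref=dp, ad_alt=0, dp=dp)


def _evidence_annotations(records: dict[str, SampleCall],
                          e: float = GENOTYPING_ERROR) -> dict:
    """QUAL/QD derived from the genotype-likelihood ratio, caller style.

    QUAL is the phred-scaled ratio of the called genotype's likelihood to
    the all-hom-ref explanation, summed over variant samples; QD divides by
    the variant samples' depth. Marginal error pile-ups land below the
    QUAL < 30 / QD < 5 hard-filter clauses, well-supported hets far above.
    """
    nats = 0.0
    dp_sum = 0
    for rec in records.values():
        if not rec.is_variant():
            continue
        ll_rr = rec.ad_alt * np.log(e) + rec.ad_ref * np.log(1 - e)
        if rec.gt == HET:
            ll_called = (rec.ad_ref + rec.ad_alt) * np.log(0.5)
        else:  # hom-alt
            ll_called = rec.ad_ref * np.log(e) + rec.ad_alt * np.log(1 - e)
        nats += ll_called - ll_rr
        dp_sum += rec.dp
    qual = 10.0 / np.log(10.0) * nats
    return {"qual": float(qual),
            "qd": float(qual / dp_sum) if dp_sum else 0.0, "mq0": 0}


def simulate_ma_experiment(
    config: SimConfig,
) -> tuple[list[SiteCall], dict[str, np.ndarray], SimTruth]:
    """Generate a variant table, per-sample depth profiles and the truth.

    Per line, the true mutation count is Poisson(mu * L_callable * g) with
    positions uniform over that line's callable sites; every true mutation is
    heterozygous in exactly one offspring and absent elsewhere. Identical
    config (including seed) reproduces the output exactly; random streams are
    split per sample/line so adding a line does not perturb the others.
    """
    L = config.genome_length
    samples = [ANCESTOR_ID] + config.line_ids
    depths = {s: _sample_depths(config, i) for i, s in enumerate(samples)}

    truth = SimTruth(
        true_mutations={s: [] for s in config.line_ids},
        loh_events={s: [] for s in config.line_ids},
    )
    # positions (0-based) already owning a variant record, to avoid collisions
    taken: set[int] = set()
    calls: list[SiteCall] = []

    def site(pos0: int, ref: str, alt: str, per_sample: dict[str, SampleCall],
             ann: dict | None = None) -> SiteCall:
        recs = {}
        for s in samples:
            recs[s] = per_sample.get(s) or _hom_ref_call(int(depths[s][pos0]))
        ann = ann or _evidence_annotations(recs)
        return SiteCall(
            chrom=config.chrom, pos=pos0 + 1, ref=ref, alt=alt, samples=recs,
            qual=ann["qual"], qd=ann["qd"], mq0=ann["mq0"],
            dp=int(sum(r.dp for r in recs.values())),
        )

    # --- ancestral heterozygous loci, inherited clonally with rare LOH ---
    anc_rng = _rng(config.seed, _K_ANC)
    n_hets = min(config.n_ancestor_hets, L)
    het_pos = np.sort(anc_rng.choice(L, size=n_hets, replace=False))
    truth.ancestor_hets = [int(p) + 1 for p in het_pos]
    for p in het_pos:
        taken.add(int(p))
        ref, alt = _ref_alt(anc_rng)
        per_sample: dict[str, SampleCall] = {}
        for j, s in enumerate(samples):
            dp = int(depths[s][p])
            srng = _rng(config.seed, _K_SITE, int(p), j + 1)
            if s != ANCESTOR_ID and srng.random() < config.loh_rate:
                gt = HOM_REF if srng.random() < 0.5 else HOM_ALT
                per_sample[s] = SampleCall(
                    gt=gt, ad_ref=dp if gt == HOM_REF else 0,
                    ad_alt=0 if gt == HOM_REF else dp, dp=dp,
                )
                truth.loh_events[s].append(int(p) + 1)
            else:
                per_sample[s] = _het_call(srng, dp)
        calls.append(site(int(p), ref, alt, per_sample))

    # --- true de novo mutations, Poisson over callable site-generations ---
    for i, line in enumerate(config.line_ids):
        lrng = _rng(config.seed, _K_LINE + i)
        mu = config.true_mu_per_treatment.get(config.treatment_of(line), 0.0)
        callable_sites = np.flatnonzero((depths[line] >= 9) & (depths[line] <= 75))
        lam = mu * callable_sites.size * config.generations
        k = int(lrng.poisson(lam)) if lam > 0 else 0
        placed = 0
        while placed < k and callable_sites.size:
            p = int(callable_sites[lrng.integers(callable_sites.size)])
            if p in taken:
                continue
            taken.add(p)
            ref, alt = _ref_alt(lrng)
            per_sample = {line: _het_call(lrng, int(depths[line][p]))}
            calls.append(site(p, ref, alt, per_sample))
            truth.true_mutations[line].append((p + 1, ref, alt))
            placed += 1
        truth.true_mutations[line].sort()

    # --- artifact sites: shared, clustered, or low-quality ---
    art_rng = _rng(config.seed, _K_ART)
    repeat_iv = simulate_repeat_mask(config)
    n_art = int(art_rng.poisson(config.artifact_site_rate * L))
    offspring = config.line_ids
    for _ in range(n_art):
        kind = art_rng.choice(["shared", "cluster", "lowqual"], p=[0.4, 0.4, 0.2])
        if kind == "cluster":
            start = int(art_rng.integers(0, max(1, L - 50)))
            members = sorted({start, start + int(art_rng.integers(1, 25)),
                              start + int(art_rng.integers(25, 50))})
            if len(members) < 3:
                continue
            for p in members:
                if p in taken:
                    continue
                taken.add(p)
                ref, alt = _ref_alt(art_rng)
                carrier = offspring[int(art_rng.integers(len(offspring)))]
                per_sample = {carrier: _het_call(art_rng, int(depths[carrier][p]))}
                calls.append(site(p, ref, alt, per_sample))
        else:
            p = int(art_rng.integers(L))
            if p in taken:
                continue
            taken.add(p)
            ref, alt = _ref_alt(art_rng)
            if kind == "shared":
                n_carriers = 3 + int(art_rng.poisson(1.0))
                carriers = art_rng.choice(offspring, size=min(n_carriers, len(offspring)),
                                          replace=False)
                per_sample = {c: _het_call(art_rng, int(depths[c][p])) for c in carriers}
                calls.append(site(p, ref, alt, per_sample))
            else:  # low-quality annotations: the hard filter's prey
                carrier = offspring[int(art_rng.integers(len(offspring)))]
                per_sample = {carrier: _het_call(art_rng, int(depths[carrier][p]))}
                ann = {"qual": float(art_rng.uniform(5.0, 29.0)),
                       "qd": float(art_rng.uniform(0.5, 4.9)), "mq0": 0}
                calls.append(site(p, ref, alt, per_sample, ann))

    # --- indel artifacts inside the repeat mask ---
    n_indel = int(art_rng.poisson(config.indel_artifact_rate * L))
    for _ in range(n_indel):
        if repeat_iv.size == 0:
            break
        iv = repeat_iv[int(art_rng.integers(len(repeat_iv)))]
        p = int(art_rng.integers(iv[0], iv[1]))
        if p in taken:
            continue
        taken.add(p)
        ref = BASES[art_rng.integers(4)]
        alt = ref + BASES[art_rng.integers(4)]
        carrier = offspring[int(art_rng.integers(len(offspring)))]
        per_sample = {carrier: _het_call(art_rng, int(depths[carrier][p]))}
        calls.append(site(p, ref, alt, per_sample))

    # --- sequencing errors: pile-ups large enough to be genotyped variant ---
    if config.seq_error_rate > 0:
        for j, s in enumerate(samples):
            erng = _rng(config.seed, _K_ERR + j)
            err = erng.binomial(depths[s], config.seq_error_rate)
            for p in np.flatnonzero(err >= 2):
                p = int(p)
                dp = int(depths[s][p])
                na = int(err[p])
                gt = _ml_genotype(dp - na, na)
                if gt == HOM_REF or p in taken:
                    continue  # the caller would not emit a variant here
                taken.add(p)
                ref, alt = _ref_alt(erng)
                per_sample = {s: SampleCall(gt=gt, ad_ref=dp - na, ad_alt=na, dp=dp)}
                calls.append(site(p, ref, alt, per_sample))

    return sort_calls(calls), depths, truth


# ---------------------------------------------------------------------------
# spike-in injection
# ---------------------------------------------------------------------------

def spike_in(
    calls: list[SiteCall],
    masks: dict[str, CallableMask],
    n: int,
    freq_mean: float = 0.5,
    freq_sd: float = 0.1,
    seed: int = 0,
    depth_profiles: dict[str, np.ndarray] | None = None,
    mean_depth: float = 28.0,
    min_spacing: int = 50,
) -> tuple[list[SiteCall], SimTruth]:
    """Inject ``n`` heterozygous-like variants into callable regions.

    Each spike lands uniformly in the callable space of a randomly chosen
    sample, with alternate-allele fraction drawn Normal(freq_mean, freq_sd)
    truncated to (0, 1). Depths come from ``depth_profiles`` when supplied,
    otherwise from a negative binomial redrawn into the callable band.
    Spikes keep ``min_spacing`` bp from existing variants and each other: at
    real genome scale an injected variant essentially never lands inside a
    variant cluster, and the spacing preserves that on the small synthetic
    genomes (otherwise the cluster filter's density artifact, not the
    pipeline's recall, would dominate the measurement). Returns a new table
    (input untouched) plus the spike truth.
    """
    if n == 0:
        return calls, SimTruth()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed, 11)
    sample_ids = sorted(masks)
    total_callable = sum(masks[s].total_callable for s in sample_ids)
    if total_callable < n:
        raise ValueError("callable space smaller than requested spike count")
    taken = {(c.chrom, c.pos) for c in calls}
    occupied = np.sort(np.array([c.pos for c in calls], dtype=np.int64))

    def too_close(pos1: int) -> bool:
        if min_spacing <= 0 or occupied.size == 0:
            return False
        i = int(np.searchsorted(occupied, pos1))
        for j in (i - 1, i):
            if 0 <= j < occupied.size and abs(int(occupied[j]) - pos1) < min_spacing:
                return True
        return False
    chrom = calls[0].chrom if calls else "chr1"
    all_samples = sorted(calls[0].samples) if calls else sample_ids

    def draw_depth(sample: str, pos0: int) -> int:
        if depth_profiles is not None:
            return int(depth_profiles[sample][pos0])
        while True:
            dp = int(rng.negative_binomial(3.0, 3.0 / (3.0 + mean_depth)))
            if 9 <= dp <= 75:
                return dp

    out = [c for c in calls]
    truth = SimTruth()
    placed = 0
    while placed < n:
        sample = sample_ids[int(rng.integers(len(sample_ids)))]
        mask = masks[sample]
        if mask.total_callable == 0:
            continue
        lengths = mask.intervals[:, 1] - mask.intervals[:, 0]
        offset = int(rng.integers(mask.total_callable))
        idx = int(np.searchsorted(np.cumsum(lengths), offset, side="right"))
        pos0 = int(mask.intervals[idx, 0] + offset - (np.cumsum(lengths)[idx] - lengths[idx]))
        if (chrom, pos0 + 1) in taken or too_close(pos0 + 1):
            continue
        taken.add((chrom, pos0 + 1))
        occupied = np.insert(occupied, int(np.searchsorted(occupied, pos0 + 1)),
                             pos0 + 1)
        f = float(rng.normal(freq_mean, freq_sd)) if freq_sd > 0 else freq_mean
        while not 0.0 < f < 1.0:  # truncate by redraw
            f = float(rng.normal(freq_mean, freq_sd))
        ref, alt = _ref_alt(rng)
        recs: dict[str, SampleCall] = {}
        for s in all_samples:
            dp = draw_depth(s, pos0)
            if s == sample:
                ad_alt = min(max(int(round(dp * f)), 1), dp - 1) if dp > 1 else dp
                recs[s] = SampleCall(gt=HET, ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp)
            else:
                recs[s] = _hom_ref_call(dp)
        ann = _evidence_annotations(recs)
        out.append(SiteCall(
            chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, samples=recs,
            qual=ann["qual"], qd=ann["qd"], mq0=0,
            dp=int(sum(r.dp for r in recs.values())),
        ))
        truth.spiked_variants.append((pos0 + 1, sample, f))
        placed += 1
    return sort_calls(out), truth


# ---------------------------------------------------------------------------
# infinite-sites coalescent (Hudson algorithm)
# ---------------------------------------------------------------------------

@dataclass
class CoalescentSample:
    """Haplotypes from one neutral infinite-sites coalescent replicate."""

    n_haplotypes: int
    theta: float
    haplotypes: np.ndarray  # (n_haplotypes, S) binary
    positions: np.ndarray  # relative coordinates in [0, 1)

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.size:
            counts = h.sum(axis=0)
            if np.any(counts == 0) or np.any(counts == self.n_haplotypes):
                raise ValueError("every segregating site must carry both alleles")


def simulate_coalescent(
    n_haplotypes: int, theta: float, seed: int = 0,
    rng: np.random.Generator | None = None,
) -> CoalescentSample:
    """Standard neutral coalescent with infinite-sites mutation.

    Waiting times while k lineages remain are Exp(k(k-1)/2) (units of 2N
    generations); mutations fall as Poisson(theta/2 * total branch length)
    and are placed on branches proportionally to branch length.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if rng is None:
        rng = _rng(seed, 21)
    # active lineages: (leaf index set, accumulated branch length)
    active: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n_haplotypes)
    ]
    branches: list[tuple[frozenset[int], float]] = []
    while len(active) > 1:
        k = len(active)
        t = rng.exponential(2.0 / (k * (k - 1)))
        active = [(ls, bl + t) for ls, bl in active]
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        (ls_j, bl_j) = active.pop(j)
        (ls_i, bl_i) = active.pop(i)
        branches.append((ls_i, bl_i))
        branches.append((ls_j, bl_j))
        active.append((ls_i | ls_j, 0.0))

    lengths = np.array([bl for _, bl in branches])
    total = float(lengths.sum())
    n_mut = int(rng.poisson(theta / 2.0 * total))
    haplotypes = np.zeros((n_haplotypes, n_mut), dtype=np.int8)
    if n_mut:
        which = rng.choice(len(branches), size=n_mut, p=lengths / total)
        for col, b in enumerate(which):
            for leaf in branches[int(b)][0]:
                haplotypes[leaf, col] = 1
    positions = rng.random(n_mut)
    order = np.argsort(positions, kind="stable")
    return CoalescentSample(n_haplotypes, theta, haplotypes[:, order], positions[order])
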