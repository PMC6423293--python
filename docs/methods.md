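# Methods

## The estimation problem

A mutation-accumulation (MA) experiment propagates replicate lineages from
one ancestor through repeated single-descendant bottlenecks, so selection is
nearly powerless and de novo mutations accumulate at the spontaneous rate.
Whole-genome sequencing of the ancestor and the final generation then turns
rate estimation into a counting problem: verified mutations k over callable
sites L and generations g give μ = (k/L)/g per site per generation. The
package implements this pipeline for the duckweed study design — 3
treatments × 5 lines, g = 20, ~28× coverage — together with the
population-genetic half of the analysis (diversity, LD decay, and
Nₑ = π_s/4μ).

## Filter cascade

Stages run in the order the candidates were vetted: read support → callable
band → hard filter → cluster removal → cross-sample sharing → heterozygote
support → classification. Each stage returns a subset of its input
(monotonicity is property-tested), and the pipeline reports survivor counts
per stage.

Boundary conventions, fixed once and tested at the exact boundary:

- **Callable band** [9, 75] is inclusive at both ends ("fewer than nine or
  greater than 75" reads are excluded).
- **Insert size** bounds (100, 600) are exclusive.
- **Hard filter** removes a site when (MQ0 ≥ 4 AND MQ0/DP > 0.1) OR
  QUAL < 30 OR QD < 5 — the disjunctive reading of the caller's combined
  expression; each clause can be disabled independently. Sites missing a
  needed annotation are returned separately, never silently kept.
- **Clusters**: a variant is flagged when any 50-bp span contains ≥3
  variants (span semantics: positions differing by ≤49 bp). A stricter
  literal ">3" reading is available via `cluster_min_count=4`.
- **Sharing**: a variant carried by more than two samples is removed; the
  ancestor counts as a carrier (a de novo candidate must be absent from the
  ancestor regardless, so the choice only affects artifact removal). The
  alternative reading is available via the `exclude` argument.
- **Cohort depth filter** for population samples keeps 510 < DP < 10,200,
  strict as printed.

Sanger-style validation is modeled only as the `likely_false` /
`filter_trail` demotion mechanism on candidates; no wet-lab step is
simulated.

## Synthetic MA experiments

The generator (`malines.synthetic`) emulates the features of the study data
that the filters react to:

- **Depth**: per-site, per-sample negative binomial with mean 28 and size
  parameter 20 (variance = m + m²/k, so sd ≈ 7.4 — mild overdispersion that
  exercises both callable-band boundaries at realistic frequency).
  `depth_dispersion=None` gives constant depth for controlled experiments.
- **True mutations**: heterozygous SNVs only (the only class entering the
  rate), Poisson(μ·L_callable·g) per line, uniform over the line's callable
  sites. Default per-treatment rates are the study's treatment means
  (0, 7.92×10⁻¹¹, 2.38×10⁻¹⁰); tests and calibration runs override them
  upward so events occur on megabase genomes.
- **Ancestral heterozygotes**: 240 per Mb (the study's ~2.4×10⁻⁴/bp
  density), inherited clonally with loss of heterozygosity at 6.6×10⁻⁶ per
  het per line (three LOH events among ~30,000 hets × 15 lines).
- **Genotype calls**: allele depths at het sites are Binomial(dp, 1/2); the
  emitted genotype is the maximum-likelihood diploid genotype under a Q30
  (10⁻³) read-error model, so extreme imbalance is miscalled homozygous
  exactly as a caller would.
- **Site annotations**: QUAL is the phred-scaled genotype-likelihood ratio
  of the called genotypes against the all-hom-ref explanation, summed over
  variant samples, and QD divides by their depth. Sequencing-error pile-ups
  (binomial per-base errors) therefore land under QUAL < 30 or QD < 5 and
  are eliminated by the hard filter, while balanced heterozygotes pass with
  wide margin.
- **Artifacts**: shared sites (het in ≥3 samples), dense 3-in-50-bp
  clusters, low-quality singletons, and indel artifacts placed inside a
  simulated repeat mask — one prey item per filter.
- **Scale**: the default genome is 1 Mb (the real assembly is ~158 Mb with
  ~126 Mb callable). All statistics are per-site, so scaling changes only
  event counts; simulation sizes used in tests and the acceptance script
  (200 replicates at 1 Mb, 5,000 coalescent replicates) are the package's
  chosen desk-scale operating points.
- **Determinism**: random streams are split per sample/line via stable
  integer sub-keys of the seed, so adding a line never perturbs the others,
  and an identical config reproduces the output byte for byte.

What the generator does *not* model — and hence what passing tests cannot
show about real data: mapping error and reference bias (MQ0 is exercised
only through injected annotations), indel realignment artifacts, base-quality
miscalibration, GC-coverage coupling, linked errors between samples, and any
recombination in the coalescent module. Quantities that depend on the real
sequencing data (π_s = 0.00093 itself, genome-wide SNP counts, F_st ranges,
LD half-distances, the four verified mutations, the 1.6% het-recall FN) are
covered as format contracts and estimator properties, not as numeric
reproductions.

### Sensitivity is 100% only up to the QD tail

With error-free data and depths inside the band, a true het still draws
minor allele depth ≤7 at 28× with probability ~1.2%, and QD then falls
below 5: the hard filter rejects it. This is the same stringency that gives
the real pipeline its measured ~5% spike-in false-negative rate, so the
package keeps it. Truth-recovery tests therefore assert zero false
positives and that every miss is attributable to the QD/het-support tail;
rate-recovery calibrations compare against Monte-Carlo error, which the
~1% downward bias sits well inside. Spike-ins at forced fraction 0.5 always
pass (QD ≥ 12 anywhere in the band), so guaranteed-recall checks hold
exactly.

### Spike-in placement

Spikes land uniformly in callable space of a randomly chosen sample with
allele fraction Normal(0.5, 0.1) truncated to (0,1), at the variant-table
level (allele-depth injection) — equivalent to read-level injection for
every filter this pipeline applies. Placement keeps 50 bp from existing
variants and other spikes: on a real-sized genome an injected variant
essentially never lands inside a variant cluster (density ~10⁻⁵/bp), but on
a 10³-fold smaller synthetic genome uniform placement would trip the
cluster filter often enough to dominate the measurement with a scale
artifact rather than pipeline behavior.

## Rate estimation and intervals

The treatment mean is the arithmetic mean of per-line rates — the only
reading that reproduces both published treatment means from the per-line
table. Intervals are exact Garwood bounds on the pooled Poisson count,
lower = ½χ²(α/2; 2k), upper = ½χ²(1−α/2; 2k+2), scaled by Σ Lᵢ·g. The
published treatment-interval endpoints are not reproduced by this (or any
standard) construction we tried; the spike-in FN interval (4.1–7.2% for
55/1000) is reproduced exactly, supporting the Garwood choice, and the
package documents its own intervals rather than guessing further.
Zero-count treatments report mean 0 with the exact upper bound
(3.689/ΣLg at 95%) and a `<bound (NA)` display form. The coding-genome
expectation uses the sample SD (n−1) — required to reproduce the published
0.0041 ± 0.0038. The het-recall FN interval is a t-interval (n−1 df) across
offspring miss fractions, reported as an upper bound because true LOH
counts as a miss.

## Population-genetic estimators

- π per site: c_ref·c_alt/C(n,2) with missing genotypes reducing n at that
  site; divided by callable length, not by segregating sites.
- Synonymous/nonsynonymous opportunity counting is Nei–Gojobori style with
  the standard code: each codon position contributes the fraction of its
  three substitutions that are synonymous; mutations to/from stops count as
  nonsynonymous; per-codon counts always sum to 3 (property-tested against
  exhaustive enumeration).
- Tajima's D uses the standard a₁…e₂ constants and is an error for S = 0
  rather than 0.
- F_st is Hudson's ratio of averages, 1 − mean(π_within)/mean(π_between);
  slightly negative values for exchangeable populations are expected from
  the unbiased within-term.
- LD r² is the squared Pearson correlation of genotype dosages
  (Rogers–Huff), appropriate for unphased diploids and exact for haploids;
  sites with MAF ≤ 0.05 are dropped first; pairing is capped at 100 kb by
  default.
- The Sved fit minimises pair-count-weighted residuals of
  1/(1+4βd) + 1/n with β ≥ 0, initialised from the empirical half-decay
  distance. A series with no spread carries no decay information and is
  reported at the β = 0 boundary. The useful-LD distance inverts the fitted
  curve at r² = 0.33 and is undefined when the target is at or below the
  1/n floor.

## Coalescent module

A standard Hudson n-coalescent: waiting times Exp(k(k−1)/2) in units of 2N
generations, mutations Poisson(θ/2 × total branch length) placed on
branches proportionally to length, infinite-sites haplotypes returned with
uniform relative positions. It exists as the test harness for the diversity
estimators (E[S] = θ·Σ1/i, E[π] = θ, neutral D ≈ 0) and is cross-checked
against msprime. No recombination is modeled, so it cannot generate LD
decay; the LD stage's self-check instead fits model-generated decay series
at known β.

## Nₑ inference

Nₑ = π_s/(4μ) with μ defaulting to the outdoor-UV treatment mean — the
natural-conditions rate, and the only choice that reproduces the published
headline Nₑ from π_s = 0.00093. The report surfaces (rather than models)
the assumptions: equal mutation rates in clonal and sexual phases, and
populations at genetic equilibrium (echoed by near-zero Tajima's D in the
coalescent check).

## Numerical and interface choices

Coordinates are 0-based half-open internally and 1-based in variant records
(VCF convention). VCF round-trips through pysam with GT/AD/DP plus PP
(proper-pair fraction) and MI (median insert) FORMAT fields; masks are BED;
candidates and truth are TSV; reports are JSON. The CLI
(`malines simulate|filter|rate|fn|report`) is a thin wrapper over the
library. All randomness flows from a single integer seed through
`numpy.random.Generator` sub-streams; reports with the same config hash to
identical bytes.

## Known limitations

Rate estimation assumes detection is calibrated by the FN machinery rather
than modeled jointly; the per-line Poisson model ignores within-line
mutation-rate heterogeneity; the spike-in operates on the variant table, so
alignment-level failure modes are out of reach; Hudson F_st and dosage r²
assume biallelic sites; and the published treatment-interval construction
remains unidentified, so interval comparisons against the published table
should use the package's documented Garwood intervals.
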