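"""Diversity, differentiation and LD-decay summaries.

Estimators operate on a genotype-dosage matrix (samples x sites) so both
diploid cohorts and coalescent haplotype panels (ploidy 1) flow through the
same code. Per-site diversity uses the unbiased pairwise estimator
c_ref * c_alt / C(n, 2); Tajima's D uses the standard constants; F_st is
Hudson's ratio-of-averages; LD is the squared Pearson correlation of
genotype dosages (Rogers-Huff), binned in non-overlapping 100-bp windows and
fitted with Sved's decay curve E(r^2) = 1/(1 + 4*beta*d) + 1/n, where the
1/n term absorbs finite-sample inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from Bio.Data.CodonTable import standard_dna_table

from .core import SiteCall

MISSING_DOSAGE = -1


@dataclass
class GenotypeMatrix:
    """Genotype dosages with positions and optional population labels.

    ``dosage`` is (n_samples, n_sites) with entries in {0..ploidy} or -1 for
    missing. ``callable_length`` is the number of sites assayed (monomorphic
    included); per-site statistics are scaled by it.
    """

    samples: list[str]
    positions: np.ndarray  # 1-based, strictly increasing
    dosage: np.ndarray
    callable_length: int
    ploidy: int = 2
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.positions)):
            raise ValueError("dosage shape mismatch")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        valid = (self.dosage == MISSING_DOSAGE) | (
            (self.dosage >= 0) & (self.dosage <= self.ploidy)
        )
        if not np.all(valid):
            raise ValueError("dosages out of range")

    @classmethod
    def from_calls(
        cls, calls: list[SiteCall], callable_length: int,
        populations: dict[str, str] | None = None,
    ) -> "GenotypeMatrix":
        """Diploid dosages from a variant table (het=1, hom-alt=2,
        missing=-1)."""
        code = {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": MISSING_DOSAGE}
        samples = sorted(calls[0].samples) if calls else []
        dosage = np.array(
            [[code[c.samples[s].gt] for c in calls] for s in samples], dtype=np.int8
        ).reshape(len(samples), len(calls))
        return cls(samples=samples,
                   positions=np.array([c.pos for c in calls], dtype=np.int64),
                   dosage=dosage, callable_length=callable_length,
                   populations=populations or {})

    @classmethod
    def from_haplotypes(
        cls, haplotypes: np.ndarray, positions: np.ndarray | None = None,
        callable_length: int | None = None,
    ) -> "GenotypeMatrix":
        """Wrap a binary haplotype matrix as a ploidy-1 panel."""
        h = np.asarray(haplotypes)
        n, s = h.shape
        if positions is None:
            positions = np.arange(1, s + 1)
        return cls(
            samples=[f"hap{i}" for i in range(n)],
            positions=np.asarray(positions), dosage=h,
            callable_length=callable_length if callable_length is not None else s,
            ploidy=1,
        )

    def subset(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(
            samples=list(samples), positions=self.positions.copy(),
            dosage=self.dosage[idx], callable_length=self.callable_length,
            ploidy=self.ploidy,
            populations={s: p for s, p in self.populations.items() if s in samples},
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per site: (alt allele count, total called alleles)."""
        called = self.dosage != MISSING_DOSAGE
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        tot = called.sum(axis=0) * self.ploidy
        return alt.astype(float), tot.astype(float)


def cohort_depth_filter(
    calls: list[SiteCall], min_dp: int = 510, max_dp: int = 10_200,
    exclude_mask: list[tuple[str, int, int]] | None = None,
) -> list[SiteCall]:
    """Keep sites with cohort depth strictly inside (min_dp, max_dp),
    optionally dropping sites inside an exclusion mask (e.g. organellar
    regions)."""
    exclude_mask = exclude_mask or []
    out = []
    for c in calls:
        if c.dp is None or not (min_dp < c.dp < max_dp):
            continue
        p0 = c.pos - 1
        if any(ch == c.chrom and s <= p0 < e for ch, s, e in exclude_mask):
            continue
        out.append(c)
    return out


def _site_diversity(alt: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity c0*c1/C(n,2)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = alt * (tot - alt) / (tot * (tot - 1) / 2.0)
    return np.where(tot > 1, pi, 0.0)


def nucleotide_diversity(m: GenotypeMatrix) -> float:
    """Mean pairwise diversity per callable site."""
    if m.callable_length <= 0:
        raise ValueError("callable_length must be positive")
    if len(m.samples) < 2 and m.ploidy == 1:
        raise ValueError("need at least two sequences")
    alt, tot = m.allele_counts()
    return float(_site_diversity(alt, tot).sum() / m.callable_length)


def pairwise_differences(m: GenotypeMatrix) -> float:
    """Sum of per-site unbiased diversities (mean pairwise differences)."""
    alt, tot = m.allele_counts()
    return float(_site_diversity(alt, tot).sum())


def segregating_sites(m: GenotypeMatrix) -> int:
    alt, tot = m.allele_counts()
    return int(np.sum((alt > 0) & (alt < tot)))


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from segregating sites and mean pairwise differences.

    Standard constants a1, a2, b1, b2, c1, c2, e1, e2; undefined for S = 0
    (variance vanishes) — raises rather than returning 0.
    """
    if n < 4:
        raise ValueError("need n >= 4 sequences")
    if S <= 0:
        raise ValueError("Tajima's D is undefined for S = 0")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


def hudson_fst(pop_a: GenotypeMatrix, pop_b: GenotypeMatrix) -> float:
    """Hudson's F_st as a ratio of averages: 1 - mean(pi_within)/mean(pi_between).

    pi_within averages the two within-population unbiased per-site
    diversities; pi_between is p_a(1-p_b) + p_b(1-p_a). Undefined (raises)
    when pi_between is zero everywhere.
    """
    for pop in (pop_a, pop_b):
        if len(pop.samples) < 2:
            raise ValueError("need >= 2 samples per population")
    alt_a, tot_a = pop_a.allele_counts()
    alt_b, tot_b = pop_b.allele_counts()
    usable = (tot_a > 1) & (tot_b > 1)
    pa = np.divide(alt_a, tot_a, out=np.zeros_like(alt_a), where=tot_a > 0)
    pb = np.divide(alt_b, tot_b, out=np.zeros_like(alt_b), where=tot_b > 0)
    hw = 0.5 * (_site_diversity(alt_a, tot_a) + _site_diversity(alt_b, tot_b))
    hb = pa * (1 - pb) + pb * (1 - pa)
    mean_hb = float(hb[usable].mean()) if usable.any() else 0.0
    if mean_hb == 0.0:
        raise ValueError("F_st undefined: no between-population diversity")
    return float(1.0 - hw[usable].mean() / mean_hb)


pairwise_fst = hudson_fst


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous site classification (codon-degeneracy based)
# ---------------------------------------------------------------------------

_CODON_TABLE = standard_dna_table
_STOPS = set(_CODON_TABLE.stop_codons)


def _translate(codon: str) -> str | None:
    return None if codon in _STOPS else _CODON_TABLE.forward_table[codon]


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) mutational-opportunity sites of a codon.

    Nei-Gojobori style: each position contributes the fraction of its three
    possible substitutions that preserve the encoded amino acid; changes to
    or from a stop codon count as nonsynonymous. The two counts always sum
    to 3 for a sense codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"malformed codon {codon!r}")
    if codon in _STOPS:
        raise ValueError("stop codon in reference frame")
    aa = _translate(codon)
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if _translate(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def classify_coding_sites(
    cds: str, variants: list[tuple[int, str]] | None = None
) -> tuple[float, float, list[str]]:
    """Synonymous/nonsynonymous site totals of a CDS plus per-SNP labels.

    ``cds`` must be in frame (length divisible by 3, no internal stops).
    ``variants`` are (0-based CDS position, alt base) pairs; each is labeled
    ``synonymous`` or ``nonsynonymous`` by whether the substituted codon
    encodes the same amino acid.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    syn_total = nonsyn_total = 0.0
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for codon in codons:
        s, ns = codon_site_counts(codon)
        syn_total += s
        nonsyn_total += ns
    labels = []
    for pos, alt in variants or []:
        if not 0 <= pos < len(cds):
            raise ValueError("variant outside CDS")
        ci, off = divmod(pos, 3)
        codon = codons[ci]
        if alt == codon[off]:
            raise ValueError("alt equals reference base")
        mutant = codon[:off] + alt + codon[off + 1:]
        labels.append(
            "synonymous" if _translate(mutant) == _translate(codon)
            else "nonsynonymous"
        )
    return syn_total, nonsyn_total, labels


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(
    m: GenotypeMatrix, maf_min: float = 0.05, max_distance: int = 100_000
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise dosage r^2 (Rogers-Huff) against inter-site distance.

    Sites with minor-allele frequency <= maf_min are dropped first
    ("greater than 0.05" is strict); pairs farther apart than
    ``max_distance`` are skipped. Missing dosages are excluded pairwise.
    """
    alt, tot = m.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.divide(alt, tot, out=np.zeros_like(alt), where=tot > 0)
    maf = np.minimum(p, 1 - p)
    keep = maf > maf_min
    dosage = m.dosage[:, keep].astype(float)
    pos = m.positions[keep]
    dosage[dosage == MISSING_DOSAGE] = np.nan
    dists, r2s = [], []
    n_sites = dosage.shape[1]
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            d = int(pos[j] - pos[i])
            if d > max_distance:
                break
            x, y = dosage[:, i], dosage[:, j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 2:
                continue
            xv, yv = x[ok], y[ok]
            sx, sy = xv.std(), yv.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
            dists.append(d)
            r2s.append(r * r)
    return np.asarray(dists, dtype=float), np.asarray(r2s, dtype=float)


def bin_ld(
    distances: np.ndarray, r2: np.ndarray, bin_width: int = 100,
    max_distance: int | None = None,
) -> list[tuple[float, float, int]]:
    """Mean r^2 in non-overlapping distance bins: (midpoint, mean, count);
    empty bins are omitted."""
    distances = np.asarray(distances, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if max_distance is not None:
        keep = distances <= max_distance
        distances, r2 = distances[keep], r2[keep]
    if distances.size == 0:
        return []
    idx = (distances // bin_width).astype(int)
    out = []
    for b in np.unique(idx):
        sel = idx == b
        out.append((b * bin_width + bin_width / 2.0, float(r2[sel].mean()),
                    int(sel.sum())))
    return out


@dataclass
class SvedFit:
    """Fitted Sved decay: E(r^2) = 1/(1 + 4*beta*d) + 1/n."""

    beta: float
    n: int
    rss: float
    bins: list[tuple[float, float, int]]

    def predict(self, d: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + 4.0 * self.beta * np.asarray(d, dtype=float)) + (
            1.0 / self.n if np.isfinite(self.n) else 0.0
        )


def fit_sved(bins: list[tuple[float, float, int]], n: int) -> SvedFit:
    """Weighted least squares of the Sved curve over binned r^2 means.

    Weights are pair counts; beta is constrained non-negative. With fewer
    than three bins the fit is ill-posed and raises.
    """
    if len(bins) < 3:
        raise ValueError("need at least three non-empty bins")
    d = np.array([b[0] for b in bins])
    y = np.array([b[1] for b in bins])
    w = np.sqrt(np.array([b[2] for b in bins], dtype=float))
    correction = 1.0 / n if np.isfinite(n) else 0.0
    if np.ptp(y) < 1e-12:  # degenerate: no decay information in the series
        resid0 = w * (1.0 + correction - y)
        return SvedFit(beta=0.0, n=n, rss=float(np.sum(resid0**2)),
                       bins=list(bins))

    def resid(params):
        beta = params[0]
        return w * (1.0 / (1.0 + 4.0 * beta * d) + correction - y)

    # initialise from the empirical half-decay distance
    target = (y.max() + y.min()) / 2.0
    below = d[y <= target]
    d_half = float(below[0]) if below.size else float(d[len(d) // 2])
    beta0 = 1.0 / (4.0 * d_half) if d_half > 0 else 1e-4
    sol = least_squares(resid, x0=[beta0], bounds=([0.0], [np.inf]))
    return SvedFit(beta=float(sol.x[0]), n=n, rss=float(np.sum(sol.fun**2)),
                   bins=list(bins))


def ld_distance_at(fit: SvedFit, r2_target: float = 0.33) -> float:
    """Distance where the fitted curve crosses r2_target:
    d = (1/(r2_target - 1/n) - 1) / (4*beta)."""
    correction = 1.0 / fit.n if np.isfinite(fit.n) else 0.0
    if r2_target <= correction:
        raise ValueError("target below the 1/n floor; unreachable under the model")
    if fit.beta <= 0:
        raise ValueError("no decay fitted (beta = 0): distance is infinite")
    return (1.0 / (r2_target - correction) - 1.0) / (4.0 * fit.beta)
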