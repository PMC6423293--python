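"""Spontaneous mutation-rate estimation from MA-line counts.

The per-line rate is mu_i = k_i / (L_i * g): verified point mutations over
callable sites times single-descendant generations, with no ploidy factor
(the denominator is callable positions). Treatment rates are the arithmetic
mean of per-line rates; confidence intervals treat the pooled mutation count
as Poisson and use exact Garwood (chi-square) bounds scaled by the summed
site-generations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .core import TRANSITIONS, MutationCandidate


@dataclass
class MALineMeta:
    """Per-line summary: verified point-mutation count and callable sites."""

    sample: str
    treatment: str
    generations: int
    callable_sites: float
    k: int

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.callable_sites <= 0:
            raise ValueError("callable_sites must be positive")
        if self.k < 0:
            raise ValueError("mutation count must be non-negative")

    @property
    def rate(self) -> float:
        return per_line_rate(self.k, self.callable_sites, self.generations)


def per_line_rate(k: int, callable_sites: float, generations: int) -> float:
    """mu_i = (k / L) / g, mutations per site per generation."""
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    return k / callable_sites / generations


def poisson_ci(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) Poisson bounds on a count.

    lower = chi2.ppf(alpha/2, 2k)/2 (0 when k = 0);
    upper = chi2.ppf(1 - alpha/2, 2k + 2)/2.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    lower = 0.0 if k == 0 else float(chi2.ppf(alpha / 2.0, 2 * k) / 2.0)
    upper = float(chi2.ppf(1.0 - alpha / 2.0, 2 * k + 2) / 2.0)
    return lower, upper


@dataclass
class TreatmentRate:
    """Mean rate and Poisson CI for one treatment group."""

    treatment: str
    per_line_rates: list[float]
    mean: float
    ci_low: float
    ci_high: float
    total_k: int
    total_site_generations: float
    upper_bound_only: bool = False
    fn_adjusted: bool = False

    def display(self) -> str:
        if self.upper_bound_only:
            return f"<{self.ci_high:.3g} (NA)"
        return f"{self.mean:.3g} ({self.ci_low:.3g} to {self.ci_high:.3g})"


def treatment_rate(lines: list[MALineMeta], alpha: float = 0.05) -> TreatmentRate:
    """Average per-line rates within a treatment; Garwood CI on the pooled
    count scaled by total site-generations. Zero-mutation treatments carry
    only the exact Poisson upper bound."""
    if not lines:
        raise ValueError("empty treatment")
    treatments = {m.treatment for m in lines}
    if len(treatments) != 1:
        raise ValueError(f"mixed treatments: {sorted(treatments)}")
    rates = [m.rate for m in lines]
    total_k = sum(m.k for m in lines)
    total_lg = float(sum(m.callable_sites * m.generations for m in lines))
    lo, hi = poisson_ci(total_k, alpha)
    return TreatmentRate(
        treatment=lines[0].treatment,
        per_line_rates=rates,
        mean=float(np.mean(rates)),
        ci_low=lo / total_lg,
        ci_high=hi / total_lg,
        total_k=total_k,
        total_site_generations=total_lg,
        upper_bound_only=total_k == 0,
    )


@dataclass
class CodingExpectation:
    """Expected mutations per generation over the protein-coding genome."""

    coding_size: float
    per_line: list[float]
    mean: float
    sd: float


def coding_expectation(
    rate: TreatmentRate, coding_size: float = 17.4e6
) -> CodingExpectation:
    """Per-line rate times coding-genome size; SD is the sample SD (n-1)."""
    per_line = [r * coding_size for r in rate.per_line_rates]
    sd = float(np.std(per_line, ddof=1)) if len(per_line) > 1 else 0.0
    return CodingExpectation(
        coding_size=coding_size, per_line=per_line,
        mean=float(np.mean(per_line)), sd=sd,
    )


def mutation_spectrum(
    candidates: list[MutationCandidate],
) -> tuple[Counter, dict[str, int]]:
    """Counts per complementary-pair class plus a transition/transversion
    tally. Accepts point candidates only."""
    spectrum: Counter = Counter()
    titv = {"transitions": 0, "transversions": 0}
    for c in candidates:
        if c.klass != "point" or c.spectrum is None:
            raise ValueError("spectrum is defined for point mutations only")
        spectrum[c.spectrum] += 1
        ref, alt = c.site.ref, c.site.alt
        if (ref, alt) in TRANSITIONS:
            titv["transitions"] += 1
        else:
            titv["transversions"] += 1
    return spectrum, titv


def lines_from_pipeline(
    result, treatment_of, generations: int = 20
) -> list[MALineMeta]:
    """Build line summaries from a pipeline result.

    ``result`` is a ``filtering.PipelineResult``; ``treatment_of`` maps a
    sample id to its treatment label. The ancestor (any sample without a
    treatment, i.e. treatment_of returns None) is skipped.
    """
    counts: Counter = Counter(c.sample for c in result.point_candidates if c.verified)
    lines = []
    for sample, mask in sorted(result.masks.items()):
        t = treatment_of(sample)
        if t is None:
            continue
        lines.append(MALineMeta(
            sample=sample, treatment=t, generations=generations,
            callable_sites=mask.total_callable, k=counts.get(sample, 0),
        ))
    return lines
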