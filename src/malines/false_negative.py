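"""False-negative estimation for the de novo mutation pipeline.

Two complementary procedures: (1) recall of the ancestor's heterozygous loci
in clonally derived offspring — every ancestral het should reappear, so the
miss fraction bounds the pipeline's false-negative rate from above (true
loss of heterozygosity inflates it); (2) recall of synthetic spike-in
variants injected into callable regions, which measures the filter cascade
directly and carries an exact Poisson confidence interval on the missed
count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import t as t_dist

from .core import HET, MutationCandidate, SimTruth, SiteCall
from .rates import TreatmentRate, poisson_ci


@dataclass
class FNEstimate:
    """A false-negative rate with its confidence interval.

    ``method`` is ``het_recall`` (upper bound; per-sample miss fractions and
    a t-interval across offspring) or ``spike_in`` (missed/spiked with
    Garwood Poisson bounds).
    """

    method: str
    rate: float
    ci_low: float
    ci_high: float
    n_trials: int
    n_missed: int
    per_sample_miss: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be a fraction")

    def display(self) -> str:
        return (f"average: {self.rate * 100:.1f}%, "
                f"95% CI {self.ci_low * 100:.1f}-{self.ci_high * 100:.1f}%")


def het_recall_fn(
    ancestor_hets: list[int],
    calls: list[SiteCall],
    offspring: list[str],
    min_depth: int = 9,
    max_depth: int = 75,
    min_reads: int = 3,
    alpha: float = 0.05,
) -> FNEstimate:
    """Fraction of ancestral het loci not recovered per offspring.

    A locus is recovered when the offspring is called het with depth inside
    [min_depth, max_depth] and at least ``min_reads`` reads on each allele —
    the same thresholds candidate calling uses. The estimate is the mean
    miss fraction across offspring with a t-interval (n-1 df), reported as
    an upper bound on the pipeline FN rate.
    """
    if not offspring:
        raise ValueError("no offspring samples")
    het_set = set(ancestor_hets)
    by_pos = {c.pos: c for c in calls if c.pos in het_set}
    miss: dict[str, float] = {}
    for s in sorted(offspring):
        n_missed = 0
        for pos in het_set:
            c = by_pos.get(pos)
            rec = c.samples.get(s) if c is not None else None
            ok = (
                rec is not None
                and rec.gt == HET
                and min_depth <= rec.dp <= max_depth
                and rec.ad_ref >= min_reads
                and rec.ad_alt >= min_reads
            )
            if not ok:
                n_missed += 1
        miss[s] = n_missed / len(het_set) if het_set else 0.0
    fractions = np.array([miss[s] for s in sorted(miss)])
    mean = float(fractions.mean())
    n = len(fractions)
    if n > 1:
        half = float(t_dist.ppf(1 - alpha / 2, n - 1) * fractions.std(ddof=1) / np.sqrt(n))
    else:
        half = 0.0
    return FNEstimate(
        method="het_recall", rate=mean,
        ci_low=max(0.0, mean - half), ci_high=min(1.0, mean + half),
        n_trials=len(het_set) * n, n_missed=int(round(sum(miss.values()) * len(het_set))),
        per_sample_miss=miss,
    )


def spikein_fn(truth: SimTruth, recovered: list[MutationCandidate],
               alpha: float = 0.05) -> FNEstimate:
    """FN rate from spike-in recall: missed/spiked with Garwood bounds on
    the missed count scaled by the number of spikes."""
    if not truth.spiked_variants:
        raise ValueError("no spike-in truth records")
    spiked = {(pos, sample) for pos, sample, _ in truth.spiked_variants}
    found = {(c.site.pos, c.sample) for c in recovered}
    n = len(spiked)
    missed = len(spiked - found)
    lo, hi = poisson_ci(missed, alpha)
    return FNEstimate(
        method="spike_in", rate=missed / n,
        ci_low=lo / n, ci_high=min(1.0, hi / n),
        n_trials=n, n_missed=missed,
    )


def fn_correct_rate(rate: TreatmentRate, fn: FNEstimate) -> TreatmentRate:
    """Scale a treatment rate up by 1/(1 - FN); flagged as adjusted."""
    if not 0.0 <= fn.rate < 1.0:
        raise ValueError("fn rate must be in [0, 1)")
    f = 1.0 / (1.0 - fn.rate)
    return replace(
        rate,
        per_line_rates=[r * f for r in rate.per_line_rates],
        mean=rate.mean * f, ci_low=rate.ci_low * f, ci_high=rate.ci_high * f,
        fn_adjusted=True,
    )
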