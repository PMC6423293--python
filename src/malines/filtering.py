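"""De novo candidate filtering for mutation-accumulation experiments.

The cascade mirrors the order the candidates were vetted in the targeted
study: restrict to well-supported read pairs, restrict to the callable depth
band (9-75 reads per sample, inclusive), apply the caller's hard-filter
expression, drop variant clusters, drop variants shared across samples, keep
heterozygotes with at least three reads on each allele, and finally classify
survivors as point mutations, loss-of-heterozygosity events or indels. Every
stage returns a subset of its input, so filter order is auditable and counts
can be reported per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CallableMask,
    MutationCandidate,
    SampleCall,
    SiteCall,
    sort_calls,
    spectrum_label,
)

logger = logging.getLogger(__name__)


@dataclass
class HardFilterThresholds:
    """Site-level hard-filter clauses; each is independently toggleable.

    A site is removed when (mq0 >= min_mq0 AND mq0/dp > max_mq0_fraction)
    OR qual < min_qual OR qd < min_qd. Non-biallelic records are also
    removed when ``biallelic_only`` is set.
    """

    min_qual: float | None = 30.0
    min_qd: float | None = 5.0
    min_mq0: int | None = 4
    max_mq0_fraction: float = 0.1
    biallelic_only: bool = True


def hard_filter_sites(
    calls: list[SiteCall], thresholds: HardFilterThresholds | None = None
) -> tuple[list[SiteCall], list[SiteCall]]:
    """Apply the site-annotation hard filter.

    Returns (kept, unevaluable); sites missing a needed annotation are not
    silently kept but reported in the second list.
    """
    th = thresholds or HardFilterThresholds()
    kept: list[SiteCall] = []
    unevaluable: list[SiteCall] = []
    for c in calls:
        needed = []
        if th.min_qual is not None:
            needed.append(c.qual)
        if th.min_qd is not None:
            needed.append(c.qd)
        if th.min_mq0 is not None:
            needed.extend([c.mq0, c.dp])
        if any(v is None for v in needed):
            unevaluable.append(c)
            continue
        if th.biallelic_only and not c.is_biallelic:
            continue
        if th.min_qual is not None and c.qual < th.min_qual:
            continue
        if th.min_qd is not None and c.qd < th.min_qd:
            continue
        if (
            th.min_mq0 is not None
            and c.mq0 >= th.min_mq0
            and c.dp > 0
            and c.mq0 / c.dp > th.max_mq0_fraction
        ):
            continue
        kept.append(c)
    return kept, unevaluable


def filter_read_support(
    calls: list[SiteCall],
    min_insert: float = 100.0,
    max_insert: float = 600.0,
    require_proper: bool = True,
    min_proper_fraction: float = 0.9,
) -> list[SiteCall]:
    """Zero out per-sample support not backed by proper pairs with insert
    sizes strictly inside (min_insert, max_insert).

    The boundaries are exclusive ("greater than 100 bp and less than
    600 bp"). Records lacking support summaries are treated as passing and
    logged. Returns a new table; failing records have depths zeroed so they
    drop out of downstream callable computations.
    """
    out: list[SiteCall] = []
    n_zeroed = 0
    for c in calls:
        c = c.copy()
        for s, rec in c.samples.items():
            if rec.median_insert is None or rec.proper_pair_fraction is None:
                logger.debug("no read-support summary for %s at %s:%d; passing",
                             s, c.chrom, c.pos)
                continue
            ok = min_insert < rec.median_insert < max_insert
            if require_proper:
                ok = ok and rec.proper_pair_fraction >= min_proper_fraction
            if not ok:
                c.samples[s] = SampleCall(gt=MISSING, ad_ref=0, ad_alt=0, dp=0)
                n_zeroed += 1
        out.append(c)
    if n_zeroed:
        logger.info("read-support filter zeroed %d sample records", n_zeroed)
    return out


def compute_callable(
    depth: np.ndarray, min_depth: int = 9, max_depth: int = 75, sample: str = ""
) -> CallableMask:
    """Callable mask for one sample; the band [min_depth, max_depth] is
    inclusive at both ends."""
    return CallableMask.from_depth(sample, depth, min_depth, max_depth)


def restrict_to_callable(
    calls: list[SiteCall], masks: dict[str, CallableMask]
) -> list[SiteCall]:
    """Mark per-sample records outside the sample's callable band missing;
    drop sites left without any variant carrier."""
    out: list[SiteCall] = []
    for c in calls:
        c = c.copy()
        for s, rec in c.samples.items():
            mask = masks.get(s)
            if mask is not None and not mask.contains(c.pos - 1):
                c.samples[s] = SampleCall(gt=MISSING, ad_ref=0, ad_alt=0, dp=rec.dp)
        if c.carriers():
            out.append(c)
    return out


def annotate_clusters(
    calls: list[SiteCall], window: int = 50, min_count: int = 3
) -> list[SiteCall]:
    """Flag every variant lying in any ``window``-bp span holding at least
    ``min_count`` variants (per chromosome).

    A span [p, p + window) covers positions differing by at most window - 1.
    Input is sorted internally if needed (logged). Returns a new table with
    ``in_cluster`` set; exclusion is the pipeline's job.
    """
    order = [(c.chrom, c.pos) for c in calls]
    if order != sorted(order):
        logger.info("cluster annotation: input unsorted; sorting internally")
        calls = sort_calls(calls)
    out = [c.copy() for c in calls]
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(out):
        by_chrom.setdefault(c.chrom, []).append(i)
    for idxs in by_chrom.values():
        pos = np.array([out[i].pos for i in idxs])
        j = 0
        for i in range(len(idxs)):
            # widest run starting at i inside one window
            j = max(j, i)
            while j + 1 < len(idxs) and pos[j + 1] - pos[i] <= window - 1:
                j += 1
            if j - i + 1 >= min_count:
                for t in range(i, j + 1):
                    out[idxs[t]].in_cluster = True
    return out


def drop_clusters(calls: list[SiteCall]) -> list[SiteCall]:
    return [c for c in calls if not c.in_cluster]


def cross_sample_filter(
    calls: list[SiteCall], max_samples: int = 2, exclude: tuple[str, ...] = ()
) -> list[SiteCall]:
    """Remove variants carried by more than ``max_samples`` individuals.

    The ancestor counts as a carrier by default; pass its id in ``exclude``
    for the alternative reading of the sharing rule.
    """
    out = []
    for c in calls:
        carriers = [s for s in c.carriers() if s not in exclude]
        if len(carriers) <= max_samples:
            out.append(c)
    return out


def het_support_filter(calls: list[SiteCall], min_reads: int = 3) -> list[SiteCall]:
    """Keep heterozygous records only when both alleles have >= min_reads
    supporting reads; failing het records become missing. Homozygous records
    are untouched. Sites left without a variant carrier are dropped."""
    out: list[SiteCall] = []
    for c in calls:
        c = c.copy()
        for s, rec in c.samples.items():
            if rec.gt == HET and (rec.ad_ref < min_reads or rec.ad_alt < min_reads):
                c.samples[s] = SampleCall(gt=MISSING, ad_ref=rec.ad_ref,
                                          ad_alt=rec.ad_alt, dp=rec.dp)
        if c.carriers():
            out.append(c)
    return out


def _in_mask(chrom: str, pos1: int, mask: list[tuple[str, int, int]]) -> bool:
    p0 = pos1 - 1
    return any(ch == chrom and s <= p0 < e for ch, s, e in mask)


def classify_candidates(
    calls: list[SiteCall],
    ancestor: str,
    repeat_mask: list[tuple[str, int, int]] | None = None,
) -> list[MutationCandidate]:
    """Triage surviving variants into point / LOH / indel candidates.

    point: ancestor hom-ref and exactly one offspring het (spectrum label in
    pyrimidine-first pair notation). LOH: ancestor het, offspring homozygous
    for either allele. Indels are flagged, and those inside the repeat mask
    marked likely-false. Only point mutations feed rate estimation.
    """
    repeat_mask = repeat_mask or []
    candidates: list[MutationCandidate] = []
    for c in calls:
        if ancestor not in c.samples:
            raise ValueError(f"ancestor {ancestor!r} absent from call table")
        anc = c.samples[ancestor]
        offspring = {s: r for s, r in c.samples.items() if s != ancestor}
        if c.is_indel:
            for s, rec in offspring.items():
                if rec.is_variant():
                    candidates.append(MutationCandidate(
                        site=c, sample=s, klass="indel",
                        likely_false=_in_mask(c.chrom, c.pos, repeat_mask),
                    ))
            continue
        hets = [s for s, r in offspring.items() if r.gt == HET]
        if anc.gt == HOM_REF and len(hets) == 1 and all(
            not r.is_variant() for s, r in offspring.items() if s != hets[0]
        ):
            candidates.append(MutationCandidate(
                site=c, sample=hets[0], klass="point",
                spectrum=spectrum_label(c.ref, c.alt),
            ))
        elif anc.gt == HET:
            for s, rec in offspring.items():
                if rec.gt in (HOM_REF, HOM_ALT):
                    candidates.append(MutationCandidate(site=c, sample=s, klass="LOH"))
    return candidates


def apply_validation(
    candidates: list[MutationCandidate],
    outcomes: dict[tuple[int, str], bool],
) -> list[MutationCandidate]:
    """Demote candidates refuted by an external validation truth table.

    ``outcomes`` maps (position, sample) to confirmed/refuted; refuted
    candidates get a failing ``validation`` trail entry and a likely-false
    flag, confirmed ones a passing entry, untested ones are untouched.
    """
    for c in candidates:
        verdict = outcomes.get((c.site.pos, c.sample))
        if verdict is None:
            continue
        c.filter_trail.append(("validation", bool(verdict)))
        if not verdict:
            c.likely_false = True
    return candidates


@dataclass
class PipelineConfig:
    """Thresholds and inputs for the full candidate cascade."""

    ancestor: str = "ancestor"
    min_depth: int = 9
    max_depth: int = 75
    min_insert: float = 100.0
    max_insert: float = 600.0
    min_proper_fraction: float = 0.9
    hard: HardFilterThresholds = field(default_factory=HardFilterThresholds)
    cluster_window: int = 50
    cluster_min_count: int = 3
    max_shared_samples: int = 2
    min_het_reads: int = 3
    repeat_mask: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class PipelineResult:
    candidates: list[MutationCandidate]
    masks: dict[str, CallableMask]
    report: dict[str, int]

    @property
    def point_candidates(self) -> list[MutationCandidate]:
        return [c for c in self.candidates if c.klass == "point"]


def run_ma_pipeline(
    calls: list[SiteCall],
    depth_profiles: dict[str, np.ndarray],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full cascade and report per-stage survivor counts."""
    cfg = config or PipelineConfig()
    report: dict[str, int] = {"input": len(calls)}

    calls = filter_read_support(
        calls, cfg.min_insert, cfg.max_insert,
        min_proper_fraction=cfg.min_proper_fraction,
    )
    report["read_support"] = len(calls)

    masks = {
        s: compute_callable(d, cfg.min_depth, cfg.max_depth, sample=s)
        for s, d in depth_profiles.items()
    }
    calls = restrict_to_callable(calls, masks)
    report["callable"] = len(calls)

    calls, unevaluable = hard_filter_sites(calls, cfg.hard)
    report["hard_filter"] = len(calls)
    report["unevaluable"] = len(unevaluable)

    calls = drop_clusters(annotate_clusters(calls, cfg.cluster_window,
                                            cfg.cluster_min_count))
    report["cluster"] = len(calls)

    calls = cross_sample_filter(calls, cfg.max_shared_samples)
    report["cross_sample"] = len(calls)

    calls = het_support_filter(calls, cfg.min_het_reads)
    report["het_support"] = len(calls)

    candidates = classify_candidates(calls, cfg.ancestor, cfg.repeat_mask)
    for cand in candidates:
        cand.filter_trail = [(name, True) for name in (
            "read_support", "callable", "hard_filter", "cluster",
            "cross_sample", "het_support",
        )]
    report["point"] = sum(1 for c in candidates if c.klass == "point")
    report["loh"] = sum(1 for c in candidates if c.klass == "LOH")
    report["indel"] = sum(1 for c in candidates if c.klass == "indel")
    return PipelineResult(candidates=candidates, masks=masks, report=report)
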