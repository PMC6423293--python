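"""Core data containers shared across the mutation-accumulation pipeline.

Coordinates are 0-based half-open internally (masks, depth profiles) and
1-based in variant records (``SiteCall.pos``), matching VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# genotype codes for per-sample calls
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


@dataclass
class SampleCall:
    """One sample's evidence at a variant site.

    ``proper_pair_fraction`` and ``median_insert`` summarise the supporting
    read pairs; they feed the read-support filter.
    """

    gt: str = HOM_REF
    ad_ref: int = 0
    ad_alt: int = 0
    dp: int = 0
    proper_pair_fraction: float = 1.0
    median_insert: float = 300.0

    def __post_init__(self) -> None:
        if self.gt not in GENOTYPES:
            raise ValueError(f"unknown genotype code {self.gt!r}")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError("ad_ref + ad_alt exceeds dp")

    def is_variant(self) -> bool:
        return self.gt in (HET, HOM_ALT)


@dataclass
class SiteCall:
    """A variant site with per-sample calls and site-level annotations.

    ``qual`` is the phred-scaled variant confidence, ``qd`` the quality
    normalised by depth, ``mq0`` the count of mapping-quality-zero reads and
    ``dp`` the cohort depth. Any of the annotations may be ``None`` when the
    upstream caller did not emit them; the hard filter reports such sites
    separately instead of silently keeping them.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    samples: dict[str, SampleCall]
    qual: float | None = None
    qd: float | None = None
    mq0: int | None = None
    dp: int | None = None
    in_cluster: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alt.split(","))

    @property
    def is_biallelic(self) -> bool:
        return "," not in self.alt

    def carriers(self) -> list[str]:
        """Samples carrying a non-reference genotype."""
        return [s for s, c in self.samples.items() if c.is_variant()]

    def copy(self) -> "SiteCall":
        return replace(self, samples={s: replace(c) for s, c in self.samples.items()})


def sort_calls(calls: list[SiteCall]) -> list[SiteCall]:
    return sorted(calls, key=lambda c: (c.chrom, c.pos))


@dataclass
class CallableMask:
    """Per-sample callable intervals (0-based half-open, sorted, disjoint)."""

    sample: str
    intervals: np.ndarray  # shape (k, 2)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size and (np.any(iv[:, 1] <= iv[:, 0]) or np.any(np.diff(iv[:, 0]) <= 0)):
            raise ValueError("intervals must be sorted and non-degenerate")
        if iv.size and np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("intervals must be non-overlapping")
        self.intervals = iv

    @property
    def total_callable(self) -> int:
        if self.intervals.size == 0:
            return 0
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        iv = self.intervals
        if iv.size == 0:
            return False
        i = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        return i >= 0 and pos0 < iv[i, 1]

    @classmethod
    def from_depth(
        cls, sample: str, depth: np.ndarray, min_depth: int = 9, max_depth: int = 75
    ) -> "CallableMask":
        """Callable band is inclusive: min_depth <= depth <= max_depth."""
        depth = np.asarray(depth)
        if np.any(depth < 0):
            raise ValueError("negative depth")
        ok = (depth >= min_depth) & (depth <= max_depth)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
        return cls(sample, edges.reshape(-1, 2))


@dataclass
class MutationCandidate:
    """A de novo candidate surviving the filter cascade.

    ``klass`` is one of ``point`` (ancestor hom-ref, one offspring het),
    ``LOH`` (ancestor het, offspring homozygous) or ``indel``. The
    ``spectrum`` label (pyrimidine-first complementary-pair notation, e.g.
    ``C:G->T:A``) is defined only for point mutations. ``filter_trail``
    records (filter name, passed) pairs in application order.
    """

    site: SiteCall
    sample: str
    klass: str
    spectrum: str | None = None
    likely_false: bool = False
    filter_trail: list[tuple[str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.klass not in ("point", "LOH", "indel"):
            raise ValueError(f"unknown candidate class {self.klass!r}")
        if self.spectrum is not None and self.klass != "point":
            raise ValueError("spectrum is defined only for point mutations")

    @property
    def verified(self) -> bool:
        return all(ok for _, ok in self.filter_trail) and not self.likely_false


def spectrum_label(ref: str, alt: str) -> str:
    """Complementary-pair mutation class, pyrimidine-first (C:G->T:A etc.)."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a SNV: {ref}>{alt}")
    if ref in "AG":  # normalise to the pyrimidine strand
        ref, alt = complement(ref), complement(alt)
    return f"{ref}:{complement(ref)}->{alt}:{complement(alt)}"


TRANSITIONS = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for downstream scoring."""

    true_mutations: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    ancestor_hets: list[int] = field(default_factory=list)
    loh_events: dict[str, list[int]] = field(default_factory=dict)
    spiked_variants: list[tuple[int, str, float]] = field(default_factory=list)
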