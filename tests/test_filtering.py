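"""Filter cascade semantics: boundary behavior, brute-force oracles, and
truth-set recovery on synthetic data."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from malines import (
    ANCESTOR_ID,
    HardFilterThresholds,
    PipelineConfig,
    SampleCall,
    SiteCall,
    annotate_clusters,
    classify_candidates,
    compute_callable,
    cross_sample_filter,
    filter_read_support,
    hard_filter_sites,
    het_support_filter,
    run_ma_pipeline,
    simulate_ma_experiment,
)

from conftest import clean_config


def site(pos=100, qual=200.0, qd=15.0, mq0=0, dp=100, alt="T", ref="C",
         samples=None, **kw):
    samples = samples or {"ancestor": SampleCall(gt="hom_ref", ad_ref=20, dp=20),
                          "off1": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20)}
    return SiteCall(chrom="chr1", pos=pos, ref=ref, alt=alt, samples=samples,
                    qual=qual, qd=qd, mq0=mq0, dp=dp, **kw)


# ---------------------------------------------------------------------------
# hard filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "qual,qd,mq0,dp,kept",
    [
        (25.0, 10.0, 0, 100, False),  # low QUAL alone removes
        (40.0, 10.0, 5, 20, False),   # MQ0>=4 and 5/20 > 0.1
        (40.0, 10.0, 0, 100, True),   # all clauses pass
        (40.0, 4.9, 0, 100, False),   # low QD alone removes
        (40.0, 10.0, 5, 100, True),   # MQ0>=4 but fraction 0.05 <= 0.1
        (30.0, 5.0, 0, 100, True),    # thresholds are strict (< not <=)
    ],
)
def test_hard_filter_clauses(qual, qd, mq0, dp, kept):
    kept_sites, unevaluable = hard_filter_sites([site(qual=qual, qd=qd,
                                                      mq0=mq0, dp=dp)])
    assert (len(kept_sites) == 1) is kept
    assert unevaluable == []


def test_hard_filter_reports_missing_annotations_separately():
    s = site()
    s.qd = None
    kept, unevaluable = hard_filter_sites([s])
    assert kept == [] and unevaluable == [s]
    # with the QD clause disabled the site is evaluable again
    kept, unevaluable = hard_filter_sites(
        [s], HardFilterThresholds(min_qd=None))
    assert len(kept) == 1 and unevaluable == []


def test_hard_filter_drops_multiallelic():
    kept, _ = hard_filter_sites([site(alt="T,G")])
    assert kept == []


# ---------------------------------------------------------------------------
# read support
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("insert,zeroed", [
    (700.0, True),   # above 600
    (300.0, False),
    (100.0, True),   # boundary is exclusive: "greater than 100" is strict
    (600.0, True),
    (101.0, False),
])
def test_read_support_insert_boundaries(insert, zeroed):
    s = site(samples={"off1": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20,
                                         median_insert=insert)})
    out = filter_read_support([s])[0]
    rec = out.samples["off1"]
    assert (rec.dp == 0) is zeroed
    # input untouched
    assert s.samples["off1"].dp == 20


def test_read_support_improper_pairs_zeroed():
    s = site(samples={"off1": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20,
                                         proper_pair_fraction=0.3)})
    assert filter_read_support([s])[0].samples["off1"].dp == 0


# ---------------------------------------------------------------------------
# callable mask
# ---------------------------------------------------------------------------

def test_callable_boundary_semantics():
    # "fewer than nine or greater than 75" excluded => [9, 75] inclusive
    mask = compute_callable(np.array([5, 9, 75, 76]))
    assert mask.total_callable == 2
    assert not mask.contains(0) and mask.contains(1) and mask.contains(2)


def test_callable_uniform_depth():
    assert compute_callable(np.full(1000, 28)).total_callable == 1000


def test_callable_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    depth = rng.negative_binomial(3, 3 / (3 + 28), size=100_000)
    mask = compute_callable(depth)
    brute = int(np.sum([(9 <= d <= 75) for d in depth]))
    assert mask.total_callable == brute
    pos = rng.integers(0, depth.size, size=300)
    for p in pos:
        assert mask.contains(int(p)) == (9 <= depth[p] <= 75)


def test_negative_depth_rejected():
    with pytest.raises(ValueError):
        compute_callable(np.array([-1, 10]))


# ---------------------------------------------------------------------------
# cluster annotation
# ---------------------------------------------------------------------------

def _cluster_oracle(positions, window=50, min_count=3):
    """All-windows scan: flagged iff some [p, p+window) holds >= min_count."""
    flagged = set()
    for start in positions:
        inside = [p for p in positions if start <= p < start + window]
        if len(inside) >= min_count:
            flagged.update(inside)
    return flagged


def test_cluster_examples():
    calls = [site(pos=p) for p in (100, 110, 120)]
    assert all(c.in_cluster for c in annotate_clusters(calls))
    calls = [site(pos=p) for p in (100, 500)]
    assert not any(c.in_cluster for c in annotate_clusters(calls))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=2_000), min_size=1,
                max_size=80, unique=True))
def test_cluster_flags_match_bruteforce(positions):
    calls = [site(pos=p) for p in sorted(positions)]
    flagged = {c.pos for c in annotate_clusters(calls) if c.in_cluster}
    assert flagged == _cluster_oracle(sorted(positions))


def test_cluster_sorts_unsorted_input():
    calls = [site(pos=p) for p in (120, 100, 110)]
    out = annotate_clusters(calls)
    assert [c.pos for c in out] == [100, 110, 120]
    assert all(c.in_cluster for c in out)


# ---------------------------------------------------------------------------
# cross-sample sharing and het support
# ---------------------------------------------------------------------------

def _shared_site(n_off_het, anc_het=False):
    samples = {"ancestor": SampleCall(gt="het" if anc_het else "hom_ref",
                                      ad_ref=10, ad_alt=10 if anc_het else 0,
                                      dp=20)}
    for i in range(5):
        gt = "het" if i < n_off_het else "hom_ref"
        samples[f"off{i}"] = SampleCall(gt=gt, ad_ref=10,
                                        ad_alt=10 if gt == "het" else 0, dp=20)
    return site(samples=samples)


@pytest.mark.parametrize("n_het,anc,kept", [
    (3, False, False),  # 3 offspring carriers removed
    (1, False, True),
    (2, True, False),   # ancestor counts: 3 carriers total
    (2, False, True),
])
def test_cross_sample_carrier_counting(n_het, anc, kept):
    out = cross_sample_filter([_shared_site(n_het, anc)])
    assert (len(out) == 1) is kept


def test_cross_sample_matches_carrier_oracle(realistic_run):
    _, calls, _, _, _ = realistic_run
    out = {(c.chrom, c.pos) for c in cross_sample_filter(calls)}
    for c in calls:
        expect = len(c.carriers()) <= 2
        assert ((c.chrom, c.pos) in out) is expect


@pytest.mark.parametrize("ad,kept", [((3, 3), True), ((2, 10), False),
                                     ((10, 2), False), ((3, 17), True)])
def test_het_support_requires_three_reads_both_alleles(ad, kept):
    s = site(samples={"off1": SampleCall(gt="het", ad_ref=ad[0], ad_alt=ad[1],
                                         dp=sum(ad))})
    out = het_support_filter([s])
    assert (len(out) == 1) is kept


def test_hom_alt_not_subject_to_het_support():
    s = site(samples={"off1": SampleCall(gt="hom_alt", ad_ref=0, ad_alt=12, dp=12)})
    assert len(het_support_filter([s])) == 1


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_point_loh_and_indel_classes():
    point = site(samples={"ancestor": SampleCall(gt="hom_ref", ad_ref=20, dp=20),
                          "off1": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20),
                          "off2": SampleCall(gt="hom_ref", ad_ref=20, dp=20)})
    loh = site(pos=200,
               samples={"ancestor": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20),
                        "off1": SampleCall(gt="hom_ref", ad_ref=20, dp=20),
                        "off2": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20)})
    indel = site(pos=300, ref="C", alt="CT",
                 samples={"ancestor": SampleCall(gt="hom_ref", ad_ref=20, dp=20),
                          "off1": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20)})
    cands = classify_candidates([point, loh, indel], "ancestor",
                                repeat_mask=[("chr1", 290, 310)])
    by_class = {c.klass: c for c in cands}
    assert by_class["point"].sample == "off1"
    assert by_class["point"].spectrum == "C:G->T:A"
    assert by_class["LOH"].sample == "off1"
    assert by_class["indel"].likely_false  # inside the repeat mask


def test_validation_truth_table_demotes_refuted_candidates():
    from malines import apply_validation
    s = site(samples={"ancestor": SampleCall(gt="hom_ref", ad_ref=20, dp=20),
                      "off1": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20)})
    cands = classify_candidates([s], "ancestor")
    cands = apply_validation(cands, {(100, "off1"): False})
    assert cands[0].likely_false and not cands[0].verified
    cands[0].likely_false = False
    cands2 = apply_validation(cands, {(100, "off1"): True})
    # latest verdict appended; an all-pass trail with no refutation verifies
    assert cands2[0].filter_trail[-1] == ("validation", True)


def test_missing_ancestor_raises():
    s = site(samples={"off1": SampleCall(gt="het", ad_ref=10, ad_alt=10, dp=20)})
    with pytest.raises(ValueError):
        classify_candidates([s], "ancestor")


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def test_pipeline_recovers_truth_on_clean_data():
    """Without noise sources, every detectable true mutation is found and
    nothing else is: the only admissible misses are hets whose sampled
    allele balance falls in the QD < 5 tail (the same stringency that gives
    the method a nonzero false-negative rate on real data)."""
    n_expected = n_detected = 0
    for seed in (21, 22, 23, 24):
        cfg = clean_config(seed=seed, mu=5e-7, genome_length=200_000)
        calls, depths, truth = simulate_ma_experiment(cfg)
        result = run_ma_pipeline(calls, depths)
        detected = {(c.site.pos, c.sample) for c in result.point_candidates}
        expected = {(p, line) for line, muts in truth.true_mutations.items()
                    for p, _, _ in muts}
        assert detected <= expected  # zero false positives
        by_pos = {c.pos: c for c in calls}
        for p, line in expected - detected:
            site = by_pos[p]
            rec = site.samples[line]
            assert site.qd < 5.0 or min(rec.ad_ref, rec.ad_alt) < 3
        n_expected += len(expected)
        n_detected += len(detected)
    assert n_expected > 0
    assert n_detected >= 0.9 * n_expected


def test_three_sample_artifacts_yield_no_candidates():
    calls = [_shared_site(3)]
    depths = {s: np.full(1000, 28) for s in calls[0].samples}
    result = run_ma_pipeline(calls, depths)
    assert result.candidates == []


def test_sample_order_invariance(realistic_run):
    _, calls, depths, _, result = realistic_run
    reordered = []
    for c in calls:
        c2 = c.copy()
        c2.samples = dict(sorted(c2.samples.items(), reverse=True))
        reordered.append(c2)
    r2 = run_ma_pipeline(reordered, depths)
    key = lambda res: sorted((c.site.pos, c.sample, c.klass)
                             for c in res.candidates)
    assert key(r2) == key(result)
    assert r2.report == result.report


def test_each_stage_is_monotone(realistic_run):
    _, calls, depths, _, result = realistic_run
    counts = [result.report[k] for k in
              ("input", "read_support", "callable", "hard_filter",
               "cluster", "cross_sample", "het_support")]
    assert counts == sorted(counts, reverse=True)
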