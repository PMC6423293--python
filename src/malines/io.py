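"""Reading and writing the pipeline's on-disk formats.

Variant tables round-trip through multi-sample VCF 4.2 (FORMAT GT:AD:DP plus
PP, the proper-pair fraction, and MI, the median insert size; INFO QD, MQ0
and DP). Masks are 4-column BED (0-based half-open). Candidates and truth go
to TSV. VCF parsing uses pysam; emission writes text directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CallableMask,
    MutationCandidate,
    SampleCall,
    SimTruth,
    SiteCall,
)

_GT_TO_VCF = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_VCF_TO_GT = {(0, 0): HOM_REF, (0, 1): HET, (1, 0): HET, (1, 1): HOM_ALT}


def write_vcf(calls: list[SiteCall], path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    samples = sorted(calls[0].samples) if calls else []
    chroms: dict[str, int] = {}
    for c in calls:
        chroms[c.chrom] = max(chroms.get(c.chrom, 0), c.pos)
    if contig_lengths:
        chroms.update(contig_lengths)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=malines",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Mapping quality zero count">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Cohort depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">',
        '##FORMAT=<ID=PP,Number=1,Type=Float,Description="Proper-pair fraction">',
        '##FORMAT=<ID=MI,Number=1,Type=Float,Description="Median insert size">',
    ]
    lines += [f"##contig=<ID={ch},length={ln}>" for ch, ln in sorted(chroms.items())]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 "FORMAT\t" + "\t".join(samples))
    for c in calls:
        info = []
        if c.qd is not None:
            info.append(f"QD={c.qd:.2f}")
        if c.mq0 is not None:
            info.append(f"MQ0={c.mq0}")
        if c.dp is not None:
            info.append(f"DP={c.dp}")
        fields = [
            c.chrom, str(c.pos), ".", c.ref, c.alt,
            f"{c.qual:.2f}" if c.qual is not None else ".",
            ".", ";".join(info) or ".", "GT:AD:DP:PP:MI",
        ]
        for s in samples:
            r = c.samples[s]
            fields.append(
                f"{_GT_TO_VCF[r.gt]}:{r.ad_ref},{r.ad_alt}:{r.dp}:"
                f"{r.proper_pair_fraction:.3f}:{r.median_insert:.1f}"
            )
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[SiteCall]:
    calls: list[SiteCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            samples: dict[str, SampleCall] = {}
            for s in rec.samples:
                fmt = rec.samples[s]
                gt = fmt.get("GT")
                gt = _VCF_TO_GT.get(tuple(gt), MISSING) if gt and None not in gt else MISSING
                ad = fmt.get("AD") or (0, 0)
                samples[s] = SampleCall(
                    gt=gt, ad_ref=int(ad[0] or 0), ad_alt=int(ad[1] or 0),
                    dp=int(fmt.get("DP") or 0),
                    proper_pair_fraction=float(fmt.get("PP") or 1.0),
                    median_insert=float(fmt.get("MI") or 300.0),
                )
            calls.append(SiteCall(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alt=",".join(rec.alts or ("N",)), samples=samples,
                qual=float(rec.qual) if rec.qual is not None else None,
                qd=float(rec.info["QD"]) if "QD" in rec.info else None,
                mq0=int(rec.info["MQ0"]) if "MQ0" in rec.info else None,
                dp=int(rec.info["DP"]) if "DP" in rec.info else None,
            ))
    return calls


def write_bed_mask(mask: CallableMask, path: str | Path, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        for s, e in mask.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{mask.sample}\n")


def read_bed_mask(path: str | Path, sample: str | None = None) -> CallableMask:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    name = sample or (str(df["name"].iloc[0]) if len(df) else "")
    return CallableMask(name, df[["start", "end"]].to_numpy(dtype=np.int64))


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


def write_candidates_tsv(candidates: list[MutationCandidate], path: str | Path) -> None:
    rows = [{
        "chrom": c.site.chrom, "pos": c.site.pos, "ref": c.site.ref,
        "alt": c.site.alt, "sample": c.sample, "class": c.klass,
        "spectrum": c.spectrum or ".",
        "likely_false": c.likely_false, "verified": c.verified,
    } for c in candidates]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample", "class",
                                "spectrum", "likely_false", "verified"]
                 ).to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: SimTruth, path: str | Path, chrom: str = "chr1") -> None:
    rows = []
    for line, muts in sorted(truth.true_mutations.items()):
        for pos, ref, alt in muts:
            rows.append({"line": line, "chrom": chrom, "pos": pos,
                         "ref": ref, "alt": alt, "class": "point"})
    for pos, sample, f in truth.spiked_variants:
        rows.append({"line": sample, "chrom": chrom, "pos": pos,
                     "ref": ".", "alt": ".", "class": f"spike:{f:.3f}"})
    pd.DataFrame(rows, columns=["line", "chrom", "pos", "ref", "alt", "class"]
                 ).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
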