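"""Published summary inputs for the giant-duckweed MA experiment.

Table-level inputs of the Spirodela polyrhiza mutation-accumulation study:
per-line verified point-mutation counts and callable genome sizes after 20
single-descendant generations under three treatments, plus the headline
diversity numbers the effective-population-size calculation uses. These are
printed summaries, usable without any sequencing data.
"""

from .rates import MALineMeta

GENERATIONS = 20
CODING_SIZE_BP = 17.4e6  # protein-coding portion of the S. polyrhiza genome
DUCKWEED_PI_S = 0.00093  # range-wide synonymous-site nucleotide diversity

_MB = 1e6

# (sample, treatment, mutations, callable sites in Mb)
_TABLE = [
    ("A", "indoor", 0, 126.4),
    ("E", "indoor", 0, 125.7),
    ("I", "indoor", 0, 126.0),
    ("J", "indoor", 0, 126.4),
    ("N", "indoor", 0, 125.9),
    ("B", "outdoor-noUV", 0, 126.1),
    ("G", "outdoor-noUV", 1, 126.3),
    ("K", "outdoor-noUV", 0, 124.2),
    ("O", "outdoor-noUV", 0, 125.9),
    ("P", "outdoor-noUV", 0, 126.4),
    ("C", "outdoor-UV", 1, 125.6),
    ("D", "outdoor-UV", 1, 126.3),
    ("L", "outdoor-UV", 1, 126.3),
    ("M", "outdoor-UV", 0, 126.3),
    ("Q", "outdoor-UV", 0, 126.0),
]


def duckweed_ma_lines() -> list[MALineMeta]:
    """The 15 MA-line summaries (counts, treatments, callable sites in bp)."""
    return [
        MALineMeta(sample=s, treatment=t, generations=GENERATIONS,
                   callable_sites=mb * _MB, k=k)
        for s, t, k, mb in _TABLE
    ]


def duckweed_treatment(label: str) -> list[MALineMeta]:
    lines = [m for m in duckweed_ma_lines() if m.treatment == label]
    if not lines:
        raise ValueError(f"unknown treatment {label!r}")
    return lines
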