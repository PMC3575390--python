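"""Published cSBT assay geometry.

The class I assay tiles nucleotides 50–1069 of the class I ORF with two
overlapping amplicons: HLA-1 (insert 50–725, 676 bp) and HLA-2 (insert
145–1069, 925 bp).  The class II DRB amplicon runs 61–727 (667 bp).  Fusion
primers add a fixed per-end overhead of adapter (25 nt) plus MID barcode
(10 nt), giving final product lengths of 746, 995 and 737 bp.  Primer
*intervals* for the class I amplicons are nominal 19-nt windows at the
insert ends; the DRB primer windows (61–79, 707–727) are as published.

The three amplicons are pooled at a 3:6:1 molar ratio (longer products
higher) to normalise read yield against the shorter-product amplification
bias of emulsion PCR.
"""

from __future__ import annotations

from .alleledb import Interval
from .ampdesign import Amplicon, PrimerSite

__all__ = [
    "ADAPTER_LEN",
    "MID_LEN",
    "ADAPTER_OVERHEAD_PER_END",
    "POOL_RATIO",
    "HLA1_FWD",
    "HLA1_REV",
    "HLA2_FWD",
    "HLA2_REV",
    "DRB_FWD",
    "DRB_REV",
    "CLASS1_COVERAGE",
    "DRB_COVERAGE",
    "coordinate_amplicon",
    "published_amplicon_geometry",
]

ADAPTER_LEN = 25
MID_LEN = 10
ADAPTER_OVERHEAD_PER_END = ADAPTER_LEN + MID_LEN  # 35 nt per end

POOL_RATIO = {"HLA-1": 3, "HLA-2": 6, "DRB": 1}

HLA1_FWD = Interval(50, 68)
HLA1_REV = Interval(707, 725)
HLA2_FWD = Interval(145, 163)
HLA2_REV = Interval(1051, 1069)
DRB_FWD = Interval(61, 79)
DRB_REV = Interval(707, 727)

# sequenced region per assay: union of amplicon inserts
CLASS1_COVERAGE = [Interval(50, 1069)]
DRB_COVERAGE = [Interval(61, 727)]


def coordinate_amplicon(
    name: str,
    fwd: Interval,
    rev: Interval,
    tag: str = "",
    adapter_overhead_per_end: int = ADAPTER_OVERHEAD_PER_END,
) -> Amplicon:
    """Geometry-only amplicon: placeholder primer consensus, no allele set.

    Used for coordinate/product-length arithmetic before any reference
    database is in hand.
    """
    return Amplicon(
        name,
        PrimerSite(fwd, "N" * fwd.length, {}),
        PrimerSite(rev, "N" * rev.length, {}),
        adapter_overhead_per_end,
        tag or name,
    )


def published_amplicon_geometry() -> dict[str, Amplicon]:
    """The three published amplicons as geometry-only objects."""
    return {
        "HLA-1": coordinate_amplicon("HLA-1", HLA1_FWD, HLA1_REV, tag="1"),
        "HLA-2": coordinate_amplicon("HLA-2", HLA2_FWD, HLA2_REV, tag="2"),
        "DRB": coordinate_amplicon("DRB", DRB_FWD, DRB_REV, tag="DRB"),
    }
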