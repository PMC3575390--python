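"""Primer-site discovery and in-silico typing resolution.

Universal ("pan-locus") amplification primers for highly polymorphic loci
are found by profiling a multiple alignment of all known alleles: per column
we record the *depth* (how many alleles have a non-gap base there) and the
*variability* (percentage of covering alleles whose base differs from the
modal base).  Runs of low-variability, well-covered columns are candidate
primer windows; two primer sites define an amplicon whose insert is the span
from the start of the forward site to the end of the reverse site.

Given a coverage region (the union of amplicon inserts actually sequenced),
the achievable typing resolution is predicted in silico by partitioning each
locus's alleles into groups indistinguishable over that region: name-distinct
alleles with identical sequence over ``coverage ∩ known`` form an ambiguity
group and can only be reported slash-joined.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alleledb import AlleleDatabase, AlleleName, AlleleRecord, Interval

__all__ = [
    "VariabilityProfile",
    "PrimerSite",
    "Amplicon",
    "AmbiguityGroup",
    "variability_profile",
    "find_conserved_windows",
    "define_amplicon",
    "in_silico_resolution",
    "indistinguishable_pairs",
    "groups_to_frame",
]

log = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


@dataclass
class VariabilityProfile:
    """Per-column depth and variability of an allele alignment.

    positions : 1-based consensus coordinates of the alignment columns
    depth     : number of alleles with a non-gap base per column
    variability : percentage (0-100) of covering alleles differing from the
        modal base; 0 wherever all covering alleles agree (or depth is 0)
    n_alleles : total alleles in the alignment
    """

    positions: np.ndarray
    depth: np.ndarray
    variability: np.ndarray
    n_alleles: int

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "depth": self.depth,
                "variability": self.variability,
            }
        )


def _modal_base(counts: Counter) -> tuple[str, int]:
    # ties broken lexicographically so profiles are deterministic
    top = max(counts.values())
    winner = min(b for b, c in counts.items() if c == top)
    return winner, top


def variability_profile(
    aligned: Sequence[str] | dict[str, str], start: int = 1
) -> VariabilityProfile:
    """Build a per-column depth/variability profile from aligned sequences.

    ``aligned`` is a list (or name→sequence mapping) of equal-length gapped
    sequences on a shared frame; ``start`` is the consensus coordinate of the
    first column.
    """
    seqs = list(aligned.values()) if isinstance(aligned, dict) else list(aligned)
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    depth = np.zeros(length, dtype=int)
    var = np.zeros(length, dtype=float)
    for i in range(length):
        col = [s[i].upper() for s in seqs if s[i] not in GAP_CHARS]
        depth[i] = len(col)
        if col:
            _, modal_count = _modal_base(Counter(col))
            var[i] = 100.0 * (len(col) - modal_count) / len(col)
    positions = np.arange(start, start + length)
    return VariabilityProfile(positions, depth, var, len(seqs))


def find_conserved_windows(
    profile: VariabilityProfile,
    window_len: int = 18,
    max_variability: float = 1.0,
    min_depth_fraction: float = 0.5,
) -> list[Interval]:
    """Maximal runs of conserved, well-covered columns of length >= window_len.

    A column qualifies when ``variability <= max_variability`` and
    ``depth >= min_depth_fraction * n_alleles``.  Returned intervals are in
    consensus coordinates, sorted by start.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    ok = (profile.variability <= max_variability) & (
        profile.depth >= min_depth_fraction * profile.n_alleles
    )
    out: list[Interval] = []
    run_start: int | None = None
    for i, good in enumerate(np.append(ok, False)):
        if good and run_start is None:
            run_start = i
        elif not good and run_start is not None:
            if i - run_start >= window_len:
                out.append(
                    Interval(int(profile.positions[run_start]), int(profile.positions[i - 1]))
                )
            run_start = None
    return out


@dataclass(frozen=True)
class PrimerSite:
    """A primer binding window: consensus sequence + per-allele mismatches."""

    interval: Interval
    consensus_seq: str
    per_allele_mismatches: dict[str, int]

    def __post_init__(self) -> None:
        if self.interval.length != len(self.consensus_seq):
            raise ValueError("primer interval length != consensus length")


@dataclass(frozen=True)
class Amplicon:
    """An amplicon: primer sites, insert span, and per-end adapter overhead.

    The insert runs from the forward primer's first base to the reverse
    primer's last base; the final (fusion) product adds fixed adapter+MID
    overhead at each end.  ``tag`` is the short read-group prefix ("1", "2",
    "DRB"), giving group labels like 1F/1R or DRB-F/DRB-R.
    """

    name: str
    fwd: PrimerSite
    rev: PrimerSite
    adapter_overhead_per_end: int = 35
    tag: str = ""

    def __post_init__(self) -> None:
        if self.fwd.interval.end >= self.rev.interval.start:
            raise ValueError(
                f"{self.name}: primer intervals overlap or are misordered"
            )

    @property
    def insert(self) -> Interval:
        return Interval(self.fwd.interval.start, self.rev.interval.end)

    @property
    def product_length(self) -> int:
        return self.insert.length + 2 * self.adapter_overhead_per_end

    def group_label(self, direction: str) -> str:
        tag = self.tag or self.name
        sep = "" if len(tag) == 1 else "-"
        return f"{tag}{sep}{direction}"


def _consensus_over(
    records: Iterable[AlleleRecord] | dict[str, str], interval: Interval
) -> tuple[str, dict[str, int]]:
    """Modal-base consensus over an interval plus per-allele mismatch counts.

    Accepts either AlleleRecords (consensus coordinates via known intervals)
    or a name→ungapped-full-frame-sequence mapping starting at position 1.
    """
    subseqs: dict[str, str] = {}
    if isinstance(records, dict):
        for name, seq in records.items():
            subseqs[name] = seq[interval.start - 1 : interval.end]
    else:
        for rec in records:
            s, ov = rec.subseq(interval)
            if ov is not None and ov == interval:
                subseqs[rec.name.text] = s
    if not subseqs:
        raise ValueError(f"no allele fully covers {interval}")
    cols = []
    for i in range(interval.length):
        counts = Counter(s[i] for s in subseqs.values())
        cols.append(_modal_base(counts)[0])
    consensus = "".join(cols)
    mism = {
        name: sum(a != b for a, b in zip(s, consensus)) for name, s in subseqs.items()
    }
    return consensus, mism


def define_amplicon(
    name: str,
    fwd_interval: Interval,
    rev_interval: Interval,
    alleles: Iterable[AlleleRecord] | dict[str, str],
    adapter_overhead_per_end: int = 35,
    tag: str = "",
) -> Amplicon:
    """Define an amplicon from primer intervals over an allele set.

    The consensus at each primer site is the modal base per column; each
    allele fully covering a site gets a mismatch count against that
    consensus (a DRB3-style single-mismatch allele scores 1).
    """
    fc, fm = _consensus_over(alleles, fwd_interval)
    rc, rm = _consensus_over(alleles, rev_interval)
    return Amplicon(
        name,
        PrimerSite(fwd_interval, fc, fm),
        PrimerSite(rev_interval, rc, rm),
        adapter_overhead_per_end,
        tag or name,
    )


@dataclass(frozen=True)
class AmbiguityGroup:
    """Name-distinct alleles indistinguishable over the assayed region."""

    locus: str
    members: tuple[str, ...]

    @property
    def slash_joined(self) -> str:
        return "/".join(self.members)


def _distinct_at(a: AlleleName, b: AlleleName, digits: int, suffix_distinct: bool) -> bool:
    n = digits // 2
    if a.truncated(n).fields != b.truncated(n).fields or a.locus != b.locus:
        return True
    if suffix_distinct and a.suffix != b.suffix:
        return True
    return False


def _indistinguishable(
    a: AlleleRecord, b: AlleleRecord, coverage: Sequence[Interval]
) -> bool | None:
    """True/False if comparable over coverage, None if nothing to compare."""
    compared = False
    for region in coverage:
        ov_a = a.known.intersect(region)
        ov_b = b.known.intersect(region)
        if ov_a is None or ov_b is None:
            continue
        ov = ov_a.intersect(ov_b)
        if ov is None:
            continue
        compared = True
        sa, _ = a.subseq(ov)
        sb, _ = b.subseq(ov)
        if sa != sb:
            return False
    return True if compared else None


def indistinguishable_pairs(
    db: AlleleDatabase, coverage: Sequence[Interval] | Interval
) -> list[tuple[str, str]]:
    """Same-locus allele pairs with identical sequence over the assayed region.

    Two alleles are compared only over ``coverage ∩ known_a ∩ known_b``; a
    pair sharing no assayed position is incomparable and excluded (with a
    warning) rather than guessed either way.

    Alleles that fully cover the coverage region are bucketed by their
    restricted sequence, so the common all-full-length case avoids the
    quadratic scan; partially known alleles fall back to pairwise
    comparison.  The result is identical to a naive all-pairs scan.
    """
    if isinstance(coverage, Interval):
        coverage = [coverage]
    if not coverage:
        raise ValueError("coverage must be non-empty")
    pairs: list[tuple[str, str]] = []
    for locus in db.loci:
        recs = db.by_locus[locus]
        full: dict[str, list[AlleleRecord]] = {}
        partial: list[AlleleRecord] = []
        for rec in recs:
            if all(rec.known.contains(region) for region in coverage):
                key = "|".join(rec.subseq(region)[0] for region in coverage)
                full.setdefault(key, []).append(rec)
            else:
                partial.append(rec)
        for bucket in full.values():
            names = sorted(r.name.text for r in bucket)
            pairs.extend(
                (names[i], names[j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
            )
        for rec in partial:
            for other in recs:
                if other is rec or (other in partial and other.name <= rec.name):
                    continue
                same = _indistinguishable(rec, other, coverage)
                if same is None:
                    warnings.warn(
                        f"{rec.name.text} and {other.name.text} share no "
                        "assayed position; incomparable, excluded from "
                        "ambiguity analysis",
                        stacklevel=2,
                    )
                elif same:
                    pairs.append(tuple(sorted((rec.name.text, other.name.text))))
    return sorted(set(pairs))


def in_silico_resolution(
    db: AlleleDatabase,
    coverage: Sequence[Interval] | Interval,
    digits: int = 4,
    suffix_distinct: bool = True,
) -> list[AmbiguityGroup]:
    """Predict typing resolution: ambiguity groups over a coverage region.

    Each locus's alleles are partitioned into classes with identical sequence
    over ``coverage ∩ known`` (two alleles are compared only where both are
    known); with partially known alleles the relation is not transitive, so
    classes are the connected components of the pairwise-indistinguishability
    graph — the assay cannot claim to separate alleles linked through an
    intermediary.  Classes holding >= 2 alleles that differ at the requested
    digit resolution are returned, deterministically ordered.
    ``suffix_distinct`` controls whether alleles differing only by an
    expression suffix (e.g. ``N``) count as distinct at that resolution.
    """
    pairs = indistinguishable_pairs(db, coverage)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    components: dict[str, list[str]] = {}
    for name in parent:
        components.setdefault(find(name), []).append(name)
    groups: list[AmbiguityGroup] = []
    for members in components.values():
        if len(members) < 2:
            continue
        names = [db[m].name for m in members]
        if any(
            _distinct_at(a, b, digits, suffix_distinct)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ):
            groups.append(
                AmbiguityGroup(names[0].locus, tuple(sorted(m for m in members)))
            )
    groups.sort(key=lambda g: (g.locus, g.members))
    return groups


def groups_to_frame(groups: Sequence[AmbiguityGroup]) -> pd.DataFrame:
    """Tabulate ambiguity groups for TSV export."""
    return pd.DataFrame(
        {
            "locus": [g.locus for g in groups],
            "members": [g.slash_joined for g in groups],
            "n_members": [len(g.members) for g in groups],
        }
    )
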