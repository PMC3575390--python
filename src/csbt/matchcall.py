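"""The genotyping core: exact-match mapping with match-condition typing.

Trimmed reads of each read group (1F/1R/2F/2R for the two class I
amplicons, DRB-F/DRB-R for class II) are mapped at 100% identity against
reference alleles at their expected offset.  Because reference alleles are
known over different extents of the ORF, each (allele, read group) pair has
a typed *match condition*:

* ``FULL`` ("1") — the read is an exact substring of the reference's known
  sequence along its entire length;
* ``EXTEND`` ("0") — the read matches perfectly over its overlap with the
  known interval but carries positions unknown to the reference on one
  side (e.g. exon-1 sequence against an exon-2/3-only allele);
* ``EXTEND_BOTH`` — class II variant of ``EXTEND`` where the read carries
  extra sequence at both the 5' and the 3' end relative to an
  exon-2-only reference;
* ``NONE`` (".") — no match observed, or none expected because the
  reference lacks the region.

Typing is iterative: perfectly matching key-group reads (2F for class I,
forward for class II) dictate the candidate reference subset for all other
groups.  Per-group matches are joined into a match matrix (inner joins on
the groups every allele must support, outer join on 2R to accommodate
short references), and an allele is called when its observed row equals
the row *expected* from interval geometry with sufficient read support.
Name-distinct called alleles identical over the region actually assayed
are merged into a slash-joined ambiguity set.

Reads matching no reference feed novel-allele detection: identical
unmatched reads are clustered, compared to the nearest reference by
Hamming distance at the expected offset, and reported with per-SNP
protein consequences.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .alleledb import AlleleDatabase, AlleleRecord, Interval
from .ampdesign import Amplicon, _indistinguishable
from .readprep import DemuxedRead
from .simlib import revcomp

__all__ = [
    "MatchCondition",
    "ReadGroup",
    "GroupMapping",
    "MatchMatrix",
    "GenotypeCall",
    "CallPolicy",
    "NovelPolicy",
    "SNP",
    "VariantEffect",
    "NovelCandidate",
    "expected_condition",
    "expected_matrix",
    "map_reads_exact",
    "restrict_references",
    "build_match_matrix",
    "build_match_matrix_classI",
    "build_match_matrix_classII",
    "call_genotype",
    "find_amplicon_discordant",
    "detect_novel",
    "annotate_variant",
]


class MatchCondition(Enum):
    FULL = "1"
    EXTEND = "0"
    EXTEND_BOTH = "0*"
    NONE = "."

    @property
    def symbol(self) -> str:
        return self.value

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{self.name}>"


# aggregation priority when reads of different lengths yield different
# conditions against the same allele
_PRIORITY = {
    MatchCondition.FULL: 3,
    MatchCondition.EXTEND_BOTH: 2,
    MatchCondition.EXTEND: 1,
    MatchCondition.NONE: 0,
}

_MATCHING = (MatchCondition.FULL, MatchCondition.EXTEND, MatchCondition.EXTEND_BOTH)


@dataclass(frozen=True)
class ReadGroup:
    """A read group: one direction of one amplicon, at its trim target.

    The genomic *window* is where a target-length read sits after MID and
    primer clipping: forward reads start right after the forward primer,
    reverse reads end right before the reverse primer (and are stored
    reverse-complemented in read orientation).
    """

    label: str
    amplicon: Amplicon
    direction: str
    target_len: int

    @property
    def window(self) -> Interval:
        return self.read_interval(self.target_len)

    def read_interval(self, read_len: int) -> Interval:
        if self.direction == "F":
            start = self.amplicon.fwd.interval.end + 1
            return Interval(start, start + read_len - 1)
        end = self.amplicon.rev.interval.start - 1
        return Interval(end - read_len + 1, end)

    @classmethod
    def for_amplicons(
        cls, amplicons: Mapping[str, Amplicon], targets: Mapping[str, int] | int = 320
    ) -> dict[str, "ReadGroup"]:
        out = {}
        for amp in amplicons.values():
            for d in "FR":
                label = amp.group_label(d)
                t = targets if isinstance(targets, int) else targets[label]
                out[label] = cls(label, amp, d, t)
        return out


def expected_condition(
    known: Interval, window: Interval, anchor_min: int = 30
) -> MatchCondition:
    """Expected match condition from interval geometry alone."""
    ov = known.intersect(window)
    if ov is None or ov.length < min(anchor_min, window.length):
        return MatchCondition.NONE
    if known.contains(window):
        return MatchCondition.FULL
    if window.start < known.start and window.end > known.end:
        return MatchCondition.EXTEND_BOTH
    return MatchCondition.EXTEND


def expected_matrix(
    db: AlleleDatabase,
    groups: Mapping[str, ReadGroup],
    anchor_min: int = 30,
) -> dict[str, dict[str, MatchCondition]]:
    """Per-allele expected conditions for each read group.

    Full-length alleles get all-FULL rows; an allele whose known interval
    misses a group's window (overlap below the anchor minimum) gets NONE
    there.
    """
    return {
        rec.name.text: {
            label: expected_condition(rec.known, g.window, anchor_min)
            for label, g in groups.items()
        }
        for rec in db
    }


@dataclass
class GroupMapping:
    """Mapping result of one read group against a reference subset."""

    group: ReadGroup
    per_allele: dict[str, tuple[MatchCondition, int]]
    per_seq_matches: dict[str, frozenset[tuple[str, MatchCondition]]]
    seq_counts: dict[str, int]

    @property
    def unmatched(self) -> dict[str, int]:
        """Unique read sequences matching no reference, with counts."""
        return {
            s: self.seq_counts[s]
            for s, m in self.per_seq_matches.items()
            if not m
        }

    @property
    def n_reads(self) -> int:
        return sum(self.seq_counts.values())


def _match_one(
    oriented: str, interval: Interval, rec: AlleleRecord, anchor_min: int
) -> MatchCondition | None:
    """Condition of one oriented read sequence against one reference."""
    ov = rec.known.intersect(interval)
    if ov is None:
        return None
    ref_part, _ = rec.subseq(ov)
    read_part = oriented[ov.start - interval.start : ov.end - interval.start + 1]
    if read_part != ref_part:
        return None
    if rec.known.contains(interval):
        return MatchCondition.FULL
    if ov.length < anchor_min:
        return None
    if interval.start < rec.known.start and interval.end > rec.known.end:
        return MatchCondition.EXTEND_BOTH
    return MatchCondition.EXTEND


def map_reads_exact(
    reads: Sequence[DemuxedRead],
    refs: AlleleDatabase,
    group: ReadGroup,
    anchor_min: int = 30,
) -> GroupMapping:
    """Map one group's trimmed reads at 100% identity against ``refs``.

    Reads are first clustered by sequence (identical reads map
    identically); reverse-group reads are reverse-complemented into
    reference orientation.  A read yields FULL iff it is an exact substring
    of the reference's known sequence at its expected offset, EXTEND /
    EXTEND_BOTH iff it matches with zero mismatches over an overlap of at
    least ``anchor_min`` nt while extending beyond the known interval, and
    no entry otherwise.
    """
    if len(refs) == 0:
        raise ValueError(
            f"empty reference subset for group {group.label}: upstream "
            "restriction failed"
        )
    seq_counts = Counter(r.seq for r in reads)
    per_seq: dict[str, frozenset[tuple[str, MatchCondition]]] = {}
    agg: dict[str, list[tuple[MatchCondition, int]]] = defaultdict(list)
    for seq, n in seq_counts.items():
        interval = group.read_interval(len(seq))
        oriented = seq if group.direction == "F" else revcomp(seq)
        hits = set()
        for rec in refs:
            cond = _match_one(oriented, interval, rec, anchor_min)
            if cond is not None:
                hits.add((rec.name.text, cond))
                agg[rec.name.text].append((cond, n))
        per_seq[seq] = frozenset(hits)
    per_allele = {
        name: (
            max((c for c, _ in entries), key=_PRIORITY.__getitem__),
            sum(n for _, n in entries),
        )
        for name, entries in agg.items()
    }
    return GroupMapping(group, per_allele, per_seq, dict(seq_counts))


def restrict_references(
    mapping: GroupMapping,
    conditions: Sequence[MatchCondition] = (MatchCondition.FULL,),
) -> list[str]:
    """Candidate allele subset dictated by the key group's matches.

    Class I uses perfect (FULL) 2F matches only; class II forward keys also
    admit EXTEND and EXTEND_BOTH because many references are exon-2-only.
    An empty result is the caller's cue to flag the sample not_detected.
    """
    allowed = set(conditions)
    return sorted(
        name for name, (cond, _n) in mapping.per_allele.items() if cond in allowed
    )


@dataclass
class MatchMatrix:
    """Observed match conditions and read counts per candidate allele."""

    sample: str
    group_labels: list[str]
    rows: dict[str, dict[str, tuple[MatchCondition, int]]]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for allele, row in sorted(self.rows.items()):
            for g in self.group_labels:
                cond, n = row[g]
                recs.append(
                    {
                        "sample": self.sample,
                        "allele": allele,
                        "group": g,
                        "condition": cond.symbol,
                        "reads": n,
                    }
                )
        return pd.DataFrame(recs)


def build_match_matrix(
    sample: str,
    mappings: Mapping[str, GroupMapping],
    expected: Mapping[str, Mapping[str, MatchCondition]],
    candidates: Iterable[str],
    inner_groups: Sequence[str],
    outer_groups: Sequence[str] = (),
) -> MatchMatrix:
    """Join per-group matches into a per-allele match matrix.

    A candidate's row is kept iff it has observed support in every inner
    group where support is *expected* (an expected-NONE inner group — e.g.
    a reference too short to reach that window — is exempt, mirroring the
    geometry-aware expected matrix).  Outer groups are attached where
    present and recorded as NONE with count 0 otherwise.
    """
    labels = list(inner_groups) + list(outer_groups)
    rows: dict[str, dict[str, tuple[MatchCondition, int]]] = {}
    for allele in candidates:
        row: dict[str, tuple[MatchCondition, int]] = {}
        keep = True
        for g in labels:
            obs = mappings[g].per_allele.get(allele, (MatchCondition.NONE, 0))
            row[g] = obs
            if (
                g in inner_groups
                and obs[0] is MatchCondition.NONE
                and expected[allele][g] is not MatchCondition.NONE
            ):
                keep = False
                break
        if keep:
            rows[allele] = row
    return MatchMatrix(sample, labels, rows)


def build_match_matrix_classI(
    sample: str,
    mappings: Mapping[str, GroupMapping],
    expected: Mapping[str, Mapping[str, MatchCondition]],
    candidates: Iterable[str],
) -> MatchMatrix:
    """Class I join: inner on 2F/1F/1R, outer on 2R (short references)."""
    return build_match_matrix(
        sample, mappings, expected, candidates, ["2F", "1F", "1R"], ["2R"]
    )


def build_match_matrix_classII(
    sample: str,
    mappings: Mapping[str, GroupMapping],
    expected: Mapping[str, Mapping[str, MatchCondition]],
    candidates: Iterable[str],
) -> MatchMatrix:
    """Class II join: forward reads are the key, reverse attached outer."""
    fwd = [g for g in mappings if g.endswith("F")]
    rev = [g for g in mappings if g.endswith("R")]
    return build_match_matrix(sample, mappings, expected, candidates, fwd, rev)


@dataclass
class CallPolicy:
    """Thresholds of the calling stage.

    ``min_reads_per_group`` applies to every expected-supporting group in
    stringent mode; low-stringency mode accepts allele-specific read groups
    of any number (>= 1) and downgrades confidence accordingly.
    """

    min_reads_per_group: int = 3
    mode: str = "stringent"  # or "low_stringency"
    anchor_min: int = 30
    homozygous_min_share: float = 0.8


@dataclass(frozen=True)
class GenotypeCall:
    """One called allele or ambiguity set at (sample, locus)."""

    sample: str
    locus: str
    alleles: tuple[str, ...]
    resolution: int
    confidence: str
    support: tuple[tuple[str, int], ...] = ()
    homozygous_consistent: bool | None = None
    warnings: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return "/".join(self.alleles) if self.alleles else "-"


def _shared_resolution(db: AlleleDatabase, names: Sequence[str]) -> int:
    names_ = [db[n].name for n in names]
    if len(names_) == 1:
        return names_[0].resolution
    depth = 0
    for k in range(1, 5):
        prefixes = {n.fields[:k] for n in names_ if len(n.fields) >= k}
        if len(prefixes) == 1 and all(len(n.fields) >= k for n in names_):
            depth = k
        else:
            break
    return 2 * depth


def call_genotype(
    matrix: MatchMatrix,
    expected: Mapping[str, Mapping[str, MatchCondition]],
    db: AlleleDatabase,
    groups: Mapping[str, ReadGroup],
    policy: CallPolicy = CallPolicy(),
    loci: Sequence[str] | None = None,
    mappings: Mapping[str, GroupMapping] | None = None,
) -> list[GenotypeCall]:
    """Deduce genotype calls from a match matrix.

    An allele is called when its observed row equals its expected row and
    every expected-supporting group carries sufficient reads.  Called
    alleles identical over the union of read-group windows actually
    supported for this sample are merged into an ambiguity set (dropout
    narrows, never widens, claimed resolution).  A locus with no called
    allele yields a not_detected placeholder; a locus with more than two
    protein-distinct calls is flagged with a warning.
    """
    min_reads = policy.min_reads_per_group if policy.mode == "stringent" else 1
    called: list[str] = []
    stringent_pass: set[str] = set()
    for allele, row in matrix.rows.items():
        exp = expected[allele]
        if any(row[g][0] is not exp[g] for g in matrix.group_labels):
            continue
        needed = [g for g in matrix.group_labels if exp[g] is not MatchCondition.NONE]
        if all(row[g][1] >= min_reads for g in needed):
            called.append(allele)
            if all(row[g][1] >= policy.min_reads_per_group for g in needed):
                stringent_pass.add(allele)

    # region actually assayed: windows of groups with any observed support
    supported_windows = [
        groups[g].window
        for g in matrix.group_labels
        if any(row[g][0] is not MatchCondition.NONE for row in matrix.rows.values())
    ]
    # merge called alleles indistinguishable over the assayed region
    parent = {a: a for a in called}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(called, 2):
        if db[a].locus != db[b].locus:
            continue
        if supported_windows and _indistinguishable(db[a], db[b], supported_windows):
            parent[find(a)] = find(b)
    sets: dict[str, list[str]] = defaultdict(list)
    for a in called:
        sets[find(a)].append(a)

    calls: list[GenotypeCall] = []
    by_locus: dict[str, list[GenotypeCall]] = defaultdict(list)
    for members in sets.values():
        members.sort()
        locus = db[members[0]].locus
        support = tuple(
            (g, max(matrix.rows[m][g][1] for m in members))
            for g in matrix.group_labels
        )
        if len(members) > 1:
            conf = "ambiguous_set"
        elif all(m in stringent_pass for m in members):
            conf = "unambiguous"
        else:
            conf = "low_stringency"
        call = GenotypeCall(
            matrix.sample,
            locus,
            tuple(members),
            _shared_resolution(db, members),
            conf,
            support,
        )
        by_locus[locus].append(call)

    for locus, locus_calls in by_locus.items():
        # an ambiguity set counts once: its members are one physical allele
        warn = (
            (f"{len(locus_calls)} protein-distinct calls at {locus}",)
            if len(locus_calls) > 2
            else ()
        )
        homozygous = None
        if len(locus_calls) == 1 and mappings is not None:
            homozygous = (
                _locus_read_share(mappings, db, locus, locus_calls[0].alleles)
                >= policy.homozygous_min_share
            )
        for c in locus_calls:
            calls.append(
                dataclasses.replace(
                    c, warnings=warn, homozygous_consistent=homozygous
                )
            )
    seen_loci = set(by_locus)
    for locus in loci or []:
        if locus not in seen_loci:
            calls.append(
                GenotypeCall(matrix.sample, locus, (), 0, "not_detected")
            )
    calls.sort(key=lambda c: (c.locus, c.alleles))
    return calls


def _locus_read_share(
    mappings: Mapping[str, GroupMapping],
    db: AlleleDatabase,
    locus: str,
    alleles: Sequence[str],
) -> float:
    """Fraction of this locus's matching reads that support ``alleles``."""
    target = set(alleles)
    num = den = 0
    for gm in mappings.values():
        for seq, hits in gm.per_seq_matches.items():
            names = {a for a, _c in hits if db[a].locus == locus}
            if not names:
                continue
            den += gm.seq_counts[seq]
            if names & target:
                num += gm.seq_counts[seq]
    return num / den if den else 0.0


def find_amplicon_discordant(
    sample: str,
    trimmed_by_group: Mapping[str, Sequence[DemuxedRead]],
    db: AlleleDatabase,
    groups: Mapping[str, ReadGroup],
    candidates: Iterable[str],
    called: Sequence[GenotypeCall],
    evidence_groups: Sequence[str] = ("1F", "1R"),
    anchor_min: int = 30,
) -> list[GenotypeCall]:
    """Alleles supported by amplicon-1 reads but absent from the 2F key.

    Detects the per-allele amplicon-dropout failure mode (e.g. a single-bp
    forward primer mismatch abolishing amplicon-2 amplification): the
    allele is invisible to the key-group restriction yet fully supported
    by the other amplicon's reads.  Such alleles are emitted as
    ``amplicon_discordant`` calls rather than silently missed.  Alleles
    indistinguishable from an already-called allele over the evidence
    windows are not flagged.
    """
    cand = set(candidates)
    called_names = {m for c in called for m in c.alleles}
    support: dict[str, dict[str, int]] = defaultdict(dict)
    for g in evidence_groups:
        if g not in trimmed_by_group:
            continue
        gm = map_reads_exact(list(trimmed_by_group[g]), db, groups[g], anchor_min)
        for allele, (cond, n) in gm.per_allele.items():
            # observed must equal the geometry-expected condition (FULL for
            # full-length references, EXTEND for partially known ones)
            if cond is expected_condition(
                db[allele].known, groups[g].window, anchor_min
            ):
                support[allele][g] = n
    # groups where the reference is long enough that evidence is expected
    needed = {
        allele: [
            g
            for g in evidence_groups
            if g in groups
            and expected_condition(db[allele].known, groups[g].window, anchor_min)
            is not MatchCondition.NONE
        ]
        for allele in support
    }
    windows = [groups[g].window for g in evidence_groups if g in groups]
    out = []
    for allele, sup in sorted(support.items()):
        if not needed[allele] or set(sup) != set(needed[allele]) or allele in cand:
            continue
        if any(
            db[c].locus == db[allele].locus
            and _indistinguishable(db[allele], db[c], windows)
            for c in called_names | cand
        ):
            continue
        out.append(
            GenotypeCall(
                sample,
                db[allele].locus,
                (allele,),
                db[allele].name.resolution,
                "amplicon_discordant",
                tuple(sorted(sup.items())),
            )
        )
    return out


@dataclass(frozen=True)
class SNP:
    """A single-nucleotide difference vs a reference, in ORF coordinates."""

    position: int
    ref_base: str
    alt_base: str
    effect: "VariantEffect | None" = None


@dataclass(frozen=True)
class VariantEffect:
    """Protein consequence of a substitution (ORF codon 1 = position 1)."""

    codon_index: int
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


def annotate_variant(
    ref: AlleleRecord | tuple[str, Interval], position: int, alt_base: str
) -> VariantEffect:
    """Protein consequence of substituting ``alt_base`` at ``position``.

    The reading frame is anchored at consensus position 1 (codon i spans
    positions 3i-2 .. 3i), so ``codon_index = ceil(position / 3)``.
    ``ref`` is an :class:`AlleleRecord` or a (sequence, known-interval)
    pair.  The position — and its whole codon — must lie inside the known
    interval.
    """
    if isinstance(ref, tuple):
        seq, known = ref
        rec = None
    else:
        seq, known = ref.seq, ref.known
        rec = ref
    if not known.contains_pos(position):
        raise ValueError(f"position {position} outside known interval {known}")
    codon_index = (position + 2) // 3
    codon_iv = Interval(3 * codon_index - 2, 3 * codon_index)
    if not known.contains(codon_iv):
        raise ValueError(
            f"codon {codon_index} ({codon_iv}) not fully inside known {known}"
        )
    off = codon_iv.start - known.start
    codon = seq[off : off + 3]
    within = position - codon_iv.start
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    return VariantEffect(
        codon_index, str(Seq(codon).translate()), str(Seq(alt_codon).translate())
    )


@dataclass
class NovelPolicy:
    """Thresholds of novel-allele detection."""

    min_cluster: int = 3
    max_snps: int = 3
    min_overlap: int = 30


@dataclass
class NovelCandidate:
    """A putative novel allele from clustered unmatched reads.

    ``nearest`` lists every reference at the minimum Hamming distance
    (ties are reported, not broken); ``snps`` maps each nearest reference
    to the differing positions.  ``consensus_seq`` is the primary nearest
    reference's known sequence with this candidate's SNPs applied.
    """

    sample: str
    nearest: tuple[str, ...]
    snps: dict[str, tuple[SNP, ...]]
    support: dict[str, int]
    consensus_seq: str

    @property
    def primary(self) -> str:
        return self.nearest[0]

    @property
    def n_reads(self) -> int:
        return sum(self.support.values())


def _cluster_vs_db(
    oriented: str, interval: Interval, db: AlleleDatabase, min_overlap: int
) -> tuple[int, list[tuple[str, list[SNP]]]]:
    """Nearest references by Hamming distance over the aligned overlap."""
    best = None
    hits: list[tuple[int, str, list[SNP]]] = []
    for rec in db:
        ov = rec.known.intersect(interval)
        if ov is None or ov.length < min_overlap:
            continue
        ref_part, _ = rec.subseq(ov)
        read_part = oriented[ov.start - interval.start : ov.end - interval.start + 1]
        snps = [
            SNP(ov.start + i, rb, ab)
            for i, (rb, ab) in enumerate(zip(ref_part, read_part))
            if rb != ab
        ]
        hits.append((len(snps), rec.name.text, snps))
    if not hits:
        return -1, []
    best = min(d for d, _, _ in hits)
    return best, [(name, snps) for d, name, snps in sorted(hits) if d == best]


def detect_novel(
    sample: str,
    mappings: Mapping[str, GroupMapping],
    db: AlleleDatabase,
    policy: NovelPolicy = NovelPolicy(),
) -> list[NovelCandidate]:
    """Detect putative novel alleles from unmatched read clusters.

    Identical unmatched reads of each group are clustered; clusters of at
    least ``min_cluster`` reads are compared to every reference by Hamming
    distance over the aligned overlap at the group's expected offset.
    Clusters within ``max_snps`` of a reference become candidates (all
    equidistant nearest references reported); consistent clusters across
    read groups — same nearest references, no conflicting SNPs — are
    merged into one candidate, with per-SNP protein consequences
    annotated where the codon is inside the reference's known interval.
    """
    raw: list[tuple[tuple[str, ...], dict[str, list[SNP]], str, int]] = []
    for label, gm in mappings.items():
        for seq, n in gm.unmatched.items():
            if n < policy.min_cluster:
                continue
            interval = gm.group.read_interval(len(seq))
            oriented = seq if gm.group.direction == "F" else revcomp(seq)
            dist, nearest = _cluster_vs_db(oriented, interval, db, policy.min_overlap)
            if dist < 1 or dist > policy.max_snps:
                continue
            raw.append(
                (
                    tuple(name for name, _ in nearest),
                    {name: snps for name, snps in nearest},
                    label,
                    n,
                )
            )
    # merge clusters with identical nearest sets and non-conflicting SNPs
    merged: list[NovelCandidate] = []
    for nearest, snps_by_ref, label, n in raw:
        target = None
        for cand in merged:
            if cand.nearest != nearest:
                continue
            conflict = False
            for ref in nearest:
                have = {s.position: s.alt_base for s in cand.snps[ref]}
                for s in snps_by_ref[ref]:
                    if have.get(s.position, s.alt_base) != s.alt_base:
                        conflict = True
                        break
                if conflict:
                    break
            if not conflict:
                target = cand
                break
        if target is None:
            annotated = {
                ref: tuple(
                    _annotate_snp(db[ref], s) for s in snps
                )
                for ref, snps in snps_by_ref.items()
            }
            primary = db[nearest[0]]
            merged.append(
                NovelCandidate(
                    sample,
                    nearest,
                    annotated,
                    {label: n},
                    _apply_snps(primary, annotated[nearest[0]]),
                )
            )
        else:
            for ref in nearest:
                have = {s.position for s in target.snps[ref]}
                extra = tuple(
                    _annotate_snp(db[ref], s)
                    for s in snps_by_ref[ref]
                    if s.position not in have
                )
                target.snps[ref] = tuple(
                    sorted(target.snps[ref] + extra, key=lambda s: s.position)
                )
            target.support[label] = target.support.get(label, 0) + n
            target.consensus_seq = _apply_snps(
                db[target.primary], target.snps[target.primary]
            )
    merged.sort(key=lambda c: (c.nearest, -c.n_reads))
    return merged


def _annotate_snp(rec: AlleleRecord, snp: SNP) -> SNP:
    try:
        effect = annotate_variant(rec, snp.position, snp.alt_base)
    except ValueError:
        effect = None
    return SNP(snp.position, snp.ref_base, snp.alt_base, effect)


def _apply_snps(rec: AlleleRecord, snps: Sequence[SNP]) -> str:
    chars = list(rec.seq)
    for s in snps:
        chars[s.position - rec.known.start] = s.alt_base
    return "".join(chars)
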