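"""Demultiplexing and stringent length filtering of amplicon reads.

A raw read is ``MID + gene-specific primer + insert`` (reverse reads carry
the reverse-complement of the insert, so their 5' end is the reverse
primer site).  Demultiplexing assigns a read to a (sample, amplicon,
direction) bin iff its 5' prefix matches exactly one MID within the
allowed mismatches and the following bases match one amplicon primer;
both MID and primer are clipped.  Reads failing either step land in an
unassigned bin with a reason code — demultiplexing is a strict partition
of the input.

Trimming then normalises read length per read group: reads shorter than
the group minimum are discarded, reads at least as long as the target are
truncated to the target from the 5' end.  This mirrors the stringent
length filter of the real pipeline (300–350 nt trimmed reads, depending
on the amplicon).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .ampdesign import Amplicon
from .simlib import MIDTag, revcomp

__all__ = [
    "DemuxedRead",
    "TrimPolicy",
    "read_fastq",
    "demultiplex",
    "trim_filter",
]


@dataclass(frozen=True)
class DemuxedRead:
    """A read assigned to (sample, amplicon, direction), MID+primer clipped."""

    id: str
    sample: str
    amplicon: str
    direction: str  # "F" or "R"
    group: str  # e.g. 1F, 1R, 2F, 2R, DRB-F, DRB-R
    seq: str


@dataclass(frozen=True)
class TrimPolicy:
    """Per-group (min, target, max) trimmed-read lengths in nt."""

    groups: Mapping[str, tuple[int, int, int]]

    def __post_init__(self) -> None:
        for g, (lo, target, hi) in self.groups.items():
            if not 0 < lo <= target <= hi:
                raise ValueError(f"group {g}: need 0 < min <= target <= max")

    @classmethod
    def uniform(
        cls,
        amplicons: Mapping[str, Amplicon],
        min_len: int = 300,
        target: int = 320,
        max_len: int = 350,
    ) -> "TrimPolicy":
        groups = {}
        for amp in amplicons.values():
            for d in "FR":
                groups[amp.group_label(d)] = (min_len, target, max_len)
        return cls(groups)

    def target_of(self, group: str) -> int:
        return self.groups[group][1]


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _normalize_manifest(
    manifest: pd.DataFrame | Mapping[str, MIDTag] | Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """→ list of (sample, mid_seq)."""
    if isinstance(manifest, pd.DataFrame):
        return list(zip(manifest["sample"], manifest["mid_seq"]))
    if isinstance(manifest, Mapping):
        return [(s, tag.seq) for s, tag in manifest.items()]
    return [(s, seq) for s, seq in manifest]


def demultiplex(
    reads: Iterable[tuple[str, str]],
    manifest: pd.DataFrame | Mapping[str, MIDTag] | Sequence[tuple[str, str]],
    amplicons: Mapping[str, Amplicon],
    mid_mismatches: int = 0,
    primer_mismatches: int = 2,
) -> tuple[list[DemuxedRead], list[tuple[str, str]]]:
    """Assign reads to (sample, amplicon, direction) bins by MID + primer.

    Returns (assigned, unassigned) where unassigned entries carry a reason
    code: ``mid_unknown``, ``mid_ambiguous``, ``primer_unknown`` or
    ``primer_ambiguous``.  Each input read lands in exactly one place.
    """
    pairs = _normalize_manifest(manifest)
    if not pairs:
        raise ValueError("empty MID manifest")
    mid_len = len(pairs[0][1])
    if any(len(seq) != mid_len for _, seq in pairs):
        raise ValueError("MID tags must have uniform length")
    # primer lookup: (amplicon, direction) -> expected 5' sequence post-MID
    primers = {}
    for name, amp in amplicons.items():
        primers[(name, "F")] = amp.fwd.consensus_seq
        primers[(name, "R")] = revcomp(amp.rev.consensus_seq)
    assigned: list[DemuxedRead] = []
    unassigned: list[tuple[str, str]] = []
    for rid, seq in reads:
        prefix = seq[:mid_len]
        hits = [
            (d, sample)
            for sample, mseq in pairs
            if (d := _hamming(prefix, mseq)) <= mid_mismatches
        ]
        if not hits:
            unassigned.append((rid, "mid_unknown"))
            continue
        best = min(d for d, _ in hits)
        top = [s for d, s in hits if d == best]
        if len(top) > 1:
            unassigned.append((rid, "mid_ambiguous"))
            continue
        sample = top[0]
        rest = seq[mid_len:]
        phits = [
            (d, key)
            for key, pseq in primers.items()
            if len(rest) >= len(pseq)
            and (d := _hamming(rest[: len(pseq)], pseq)) <= primer_mismatches
        ]
        if not phits:
            unassigned.append((rid, "primer_unknown"))
            continue
        pbest = min(d for d, _ in phits)
        ptop = [key for d, key in phits if d == pbest]
        if len(ptop) > 1:
            unassigned.append((rid, "primer_ambiguous"))
            continue
        amp_name, direction = ptop[0]
        plen = len(primers[(amp_name, direction)])
        assigned.append(
            DemuxedRead(
                rid,
                sample,
                amp_name,
                direction,
                amplicons[amp_name].group_label(direction),
                rest[plen:],
            )
        )
    return assigned, unassigned


def trim_filter(
    reads: Iterable[DemuxedRead], policy: TrimPolicy
) -> tuple[list[DemuxedRead], pd.DataFrame]:
    """Apply the stringent length filter/trim per read group.

    Reads shorter than the group minimum are discarded; reads at least the
    target length are truncated to the target from the 5' end (post-clip).
    Trimming is idempotent.  Returns (kept, per-group stats) with columns
    group, n_in, n_kept, retention.
    """
    kept: list[DemuxedRead] = []
    n_in: dict[str, int] = {}
    n_kept: dict[str, int] = {}
    for r in reads:
        if r.group not in policy.groups:
            raise KeyError(f"no trim policy for read group {r.group}")
        lo, target, _hi = policy.groups[r.group]
        n_in[r.group] = n_in.get(r.group, 0) + 1
        if len(r.seq) < lo:
            continue
        seq = r.seq[:target] if len(r.seq) >= target else r.seq
        kept.append(replace(r, seq=seq))
        n_kept[r.group] = n_kept.get(r.group, 0) + 1
    groups = sorted(n_in)
    stats = pd.DataFrame(
        {
            "group": groups,
            "n_in": [n_in[g] for g in groups],
            "n_kept": [n_kept.get(g, 0) for g in groups],
        }
    )
    stats["retention"] = stats["n_kept"] / stats["n_in"]
    return kept, stats
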