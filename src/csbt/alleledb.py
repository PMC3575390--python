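"""Reference allele databases with heterogeneous known-sequence extent.

HLA reference alleles are deposited with very different sequence coverage:
most classical class I alleles are known over (nearly) the full open reading
frame, while many others — and the majority of DRB alleles — are known only
from exon 2 or exons 2–3.  Every coordinate in this package is expressed in a
single consensus ORF frame, 1-based and inclusive at both ends, so that a
printed span such as 50–725 has length 676 by direct arithmetic.

An :class:`AlleleRecord` therefore carries, besides its name and sequence,
the *known interval*: the sub-interval of the consensus ORF its sequence
covers.  ``len(seq) == known.length`` always holds, and downstream stages
(expected match matrices, ambiguity resolution) reason about interval
geometry rather than hard-coding allele classes.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "AlleleName",
    "Interval",
    "AlleleRecord",
    "AlleleDatabase",
    "AlleleParseError",
    "DatabaseError",
    "parse_allele_name",
    "load_allele_fasta",
    "restrict_to_interval",
]


class AlleleParseError(ValueError):
    """Raised when an allele name cannot be parsed."""


class DatabaseError(ValueError):
    """Raised when database invariants are violated."""


_NAME_RE = re.compile(
    r"""^(?:HLA-)?
        (?P<locus>[A-Z][A-Z0-9]*)
        \*
        (?P<fields>\d+(?::\d+){0,3})
        (?P<suffix>[NLSCAQ]?)$""",
    re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class AlleleName:
    """A structured HLA-style allele name, e.g. ``C*08:56`` or ``B*18:01:01:01``.

    ``fields`` holds 1–4 numeric name fields (serological group, protein,
    synonymous coding change, non-coding change); resolution in digits is
    twice the number of fields, so a two-field name is a "four-digit"
    (high-resolution, protein-level) name.  ``suffix`` is an optional
    expression character such as ``N`` (null).
    """

    locus: str
    fields: tuple[int, ...]
    suffix: str = ""

    def __post_init__(self) -> None:
        if not self.locus:
            raise AlleleParseError("empty locus")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(f"need 1-4 name fields, got {self.fields!r}")

    @property
    def resolution(self) -> int:
        """Resolution in digits: 2 x number of name fields."""
        return 2 * len(self.fields)

    @property
    def text(self) -> str:
        """Canonical string form ``LOCUS*ff:ff[:ff[:ff]][suffix]``."""
        body = ":".join(f"{f:02d}" for f in self.fields)
        return f"{self.locus}*{body}{self.suffix}"

    def truncated(self, n_fields: int) -> "AlleleName":
        """Name truncated to the first ``n_fields`` fields (suffix kept)."""
        return AlleleName(self.locus, self.fields[:n_fields], self.suffix)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def parse_allele_name(text: str) -> AlleleName:
    """Parse an allele name string into its structured form.

    Accepts an optional ``HLA-`` prefix and an optional trailing expression
    suffix (``N``, ``L``, ``S``, ``C``, ``A``, ``Q``).

    >>> parse_allele_name("C*08:56").fields
    (8, 56)
    >>> parse_allele_name("B*18:01:01:01").resolution
    8
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele name")
    token = text.strip()
    if "*" not in token:
        raise AlleleParseError(f"no '*' separator in {token!r}")
    m = _NAME_RE.match(token)
    if m is None:
        raise AlleleParseError(f"malformed allele name {token!r}")
    fields = tuple(int(f) for f in m.group("fields").split(":"))
    return AlleleName(m.group("locus"), fields, m.group("suffix"))


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, inclusive coordinate span in the consensus ORF frame."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start},{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def intersect(self, other: "Interval") -> "Interval | None":
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return Interval(lo, hi) if lo <= hi else None

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class AlleleRecord:
    """A named reference allele and the ORF interval its sequence covers."""

    name: AlleleName
    seq: str
    known: Interval

    def __post_init__(self) -> None:
        if len(self.seq) != self.known.length:
            raise DatabaseError(
                f"{self.name.text}: sequence length {len(self.seq)} != "
                f"known interval length {self.known.length}"
            )
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise DatabaseError(
                f"{self.name.text}: sequence contains non-ACGT symbols {sorted(bad)}"
            )

    @property
    def locus(self) -> str:
        return self.name.locus

    def base_at(self, pos: int) -> str:
        """Base at consensus position ``pos`` (must lie in the known interval)."""
        if not self.known.contains_pos(pos):
            raise ValueError(f"position {pos} outside known interval {self.known}")
        return self.seq[pos - self.known.start]

    def subseq(self, region: Interval) -> tuple[str, Interval | None]:
        """Subsequence over ``region ∩ known`` plus the intersection itself.

        Returns ``("", None)`` when the intersection is empty.
        """
        ov = self.known.intersect(region)
        if ov is None:
            return "", None
        lo = ov.start - self.known.start
        return self.seq[lo : lo + ov.length], ov


@dataclass
class AlleleDatabase:
    """An indexed collection of reference alleles on one consensus frame."""

    records: list[AlleleRecord]
    consensus: Interval
    by_locus: dict[str, list[AlleleRecord]] = field(init=False)
    by_name: dict[str, AlleleRecord] = field(init=False)

    def __post_init__(self) -> None:
        self.by_locus = {}
        self.by_name = {}
        for rec in self.records:
            if rec.name.text in self.by_name:
                raise DatabaseError(f"duplicate allele name {rec.name.text}")
            if not self.consensus.contains(rec.known):
                raise DatabaseError(
                    f"{rec.name.text}: known interval {rec.known} outside "
                    f"consensus range {self.consensus}"
                )
            self.by_name[rec.name.text] = rec
            self.by_locus.setdefault(rec.locus, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> AlleleRecord:
        return self.by_name[name]

    @property
    def loci(self) -> list[str]:
        return sorted(self.by_locus)

    def subset(self, names: Iterable[str]) -> "AlleleDatabase":
        """A new database holding only the named records."""
        wanted = set(names)
        return AlleleDatabase(
            [r for r in self.records if r.name.text in wanted], self.consensus
        )

    def write_fasta(self, path: str | Path) -> None:
        """Write records as FASTA with ``known=START-END`` header metadata."""
        with open(path, "w") as fh:
            for rec in sorted(self.records, key=lambda r: r.name):
                fh.write(f">{rec.name.text} known={rec.known}\n")
                for i in range(0, len(rec.seq), 70):
                    fh.write(rec.seq[i : i + 70] + "\n")


_KNOWN_RE = re.compile(r"known=(\d+)-(\d+)")


def _read_sidecar(path: str | Path) -> dict[str, Interval]:
    out: dict[str, Interval] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "name":
                continue
            out[row[0]] = Interval(int(row[1]), int(row[2]))
    return out


def load_allele_fasta(
    path: str | Path,
    sidecar: str | Path | None = None,
    consensus: Interval | None = None,
) -> AlleleDatabase:
    """Load a reference allele database from FASTA.

    Each record header must be a parseable allele name; the known interval is
    taken from a ``known=START-END`` token in the header description, with a
    sidecar TSV (columns: name, start, end) as fallback.  ``consensus``
    defaults to the minimal interval covering every record.
    """
    side = _read_sidecar(sidecar) if sidecar is not None else {}
    records: list[AlleleRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = parse_allele_name(rec.id)
        m = _KNOWN_RE.search(rec.description)
        if m:
            known = Interval(int(m.group(1)), int(m.group(2)))
        elif name.text in side:
            known = side[name.text]
        else:
            raise DatabaseError(
                f"{name.text}: no known=START-END header metadata and no sidecar entry"
            )
        records.append(AlleleRecord(name, str(rec.seq).upper(), known))
    if not records:
        raise DatabaseError(f"no records in {path}")
    if consensus is None:
        consensus = Interval(
            min(r.known.start for r in records), max(r.known.end for r in records)
        )
    # loading is order-independent: index by sorted name
    records.sort(key=lambda r: r.name)
    return AlleleDatabase(records, consensus)


def restrict_to_interval(
    db: AlleleDatabase, region: Interval
) -> dict[str, tuple[str, Interval | None]]:
    """Restrict every allele to ``region``: name → (subsequence, overlap).

    The subsequence covers ``region ∩ known``; alleles whose known interval
    is disjoint from ``region`` map to ``("", None)``.
    """
    if not db.consensus.intersect(region):
        raise ValueError(f"region {region} outside consensus range {db.consensus}")
    return {rec.name.text: rec.subseq(region) for rec in db}
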