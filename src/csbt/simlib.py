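"""Synthetic amplicon-sequencing fixtures for the typing pipeline.

Emulates the structural properties of a multiplexed cDNA amplicon run on a
pyrosequencing-class instrument, so that every downstream stage (demux,
trim, map, call) is testable without external reference downloads:

* a multi-locus allele database with heterogeneous known-sequence extent —
  most alleles full-ORF, a configurable fraction known only over an
  exon-2/3-analog sub-interval;
* class I loci sharing conserved pan-locus primer sites, plus a DRB-style
  class II locus with its own amplicon;
* designed ambiguous allele pairs that differ only outside the sequenced
  coverage region (guaranteeing nonzero in-silico ambiguity);
* diploid genotypes per sample, 10-nt MID barcodes (pairwise Hamming
  distance >= 3), per-amplicon pooling ratios (default 3:6:1), optional
  per-base substitution errors and per-(sample, allele, amplicon) dropout.

Reads are emitted at full amplicon length (MID + insert, reverse reads
reverse-complemented) and trimmed downstream, mirroring the
trim-to-standard-length step of the real pipeline; quality strings are
constant because the pipeline's filters are length-based.  Truth labels
ride in FASTQ description fields (sample, locus, allele, amplicon,
direction) so tests can audit every stage; production inputs simply lack
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alleledb import AlleleDatabase, AlleleName, AlleleRecord, Interval
from .ampdesign import Amplicon, define_amplicon
from . import assay

__all__ = [
    "SimConfig",
    "MIDTag",
    "SimulatedDatabase",
    "SimulatedRun",
    "generate_mids",
    "simulate_database",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_run",
    "write_fastq",
]

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MIDTag:
    """A multiplex identifier barcode at the 5' end of a fusion primer."""

    id: str
    seq: str


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the real assay's structure: three loci (two class I
    analogues sharing pan-locus primer sites plus one DRB-style class II
    locus), amplicons pooled 3:6:1, reads trimmed to 300–350 nt, 10-nt
    MIDs.  ``reads_per_amplicon`` is the base count multiplied by each
    amplicon's pool ratio.
    """

    seed: int = 0
    loci: dict[str, str] = field(
        default_factory=lambda: {"A": "I", "B": "I", "DRB1": "II"}
    )
    alleles_per_locus: int = 20
    consensus_length: int = 1100
    snp_rate: float = 0.02
    locus_divergence: float = 0.05
    fraction_partial: float = 0.3
    partial_known_class1: tuple[int, int] = (104, 620)  # exon-2/3 analogue
    partial_known_class2: tuple[int, int] = (100, 330)  # exon-2-only analogue
    ambiguous_pairs_per_locus: int = 1
    n_samples: int = 10
    reads_per_amplicon: int = 300
    pool_ratio: dict[str, float] = field(
        default_factory=lambda: dict(assay.POOL_RATIO)
    )
    trim_window: tuple[int, int] = (300, 350)
    trim_target: int = 320
    error_rate: float = 0.0
    dropout: list[tuple[str, str, str]] = field(default_factory=list)
    primer_dropout_threshold: int | None = None
    protect_primer_sites: bool = True
    mid_length: int = 10

    def __post_init__(self) -> None:
        for p in (self.snp_rate, self.fraction_partial, self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if any(r <= 0 for r in self.pool_ratio.values()):
            raise ValueError("pool_ratio entries must be positive")
        if self.consensus_length < assay.HLA2_REV.end:
            raise ValueError(
                f"consensus_length {self.consensus_length} shorter than the "
                f"assay frame (needs >= {assay.HLA2_REV.end})"
            )
        # sequence-space feasibility: alleles are drawn by point mutation
        if self.alleles_per_locus > 2 ** min(self.consensus_length, 30):
            raise ValueError("more alleles requested than sequence space allows")


def generate_mids(
    n: int, rng: np.random.Generator, length: int = 10, min_dist: int = 3
) -> list[MIDTag]:
    """Generate ``n`` MID barcodes with pairwise Hamming distance >= min_dist."""
    bases = np.array(list("ACGT"))
    tags: list[str] = []
    attempts = 0
    while len(tags) < n:
        cand = "".join(rng.choice(bases, size=length))
        if all(_hamming(cand, t) >= min_dist for t in tags):
            tags.append(cand)
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("cannot generate enough distinct MIDs")
    return [MIDTag(f"MID{i + 1:02d}", t) for i, t in enumerate(tags)]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class SimulatedDatabase:
    """A simulated reference database plus the truth needed to audit it.

    ``db`` exposes only each allele's *known* sequence (partial alleles are
    truncated records), while ``full_seqs`` keeps the complete underlying
    ORF of every allele — the physical molecule reads are generated from.
    ``designed_ambiguous`` lists the allele pairs constructed to differ only
    outside the sequenced coverage region.
    """

    db: AlleleDatabase
    full_seqs: dict[str, str]
    designed_ambiguous: list[tuple[str, str]]
    locus_class: dict[str, str]

    def amplicons(self) -> dict[str, Amplicon]:
        """The three assay amplicons with consensus primers from this db."""
        class1 = {
            n: s for n, s in self.full_seqs.items()
            if self.locus_class[n.split("*")[0]] == "I"
        }
        class2 = {
            n: s for n, s in self.full_seqs.items()
            if self.locus_class[n.split("*")[0]] == "II"
        }
        out: dict[str, Amplicon] = {}
        if class1:
            out["HLA-1"] = define_amplicon(
                "HLA-1", assay.HLA1_FWD, assay.HLA1_REV, class1, tag="1"
            )
            out["HLA-2"] = define_amplicon(
                "HLA-2", assay.HLA2_FWD, assay.HLA2_REV, class1, tag="2"
            )
        if class2:
            out["DRB"] = define_amplicon(
                "DRB", assay.DRB_FWD, assay.DRB_REV, class2, tag="DRB"
            )
        return out


def _protected_positions(locus_class: str, cfg: SimConfig) -> set[int]:
    """0-based positions kept invariant so primers stay pan-locus conserved."""
    if not cfg.protect_primer_sites:
        return set()
    if locus_class == "I":
        ivs = [assay.HLA1_FWD, assay.HLA1_REV, assay.HLA2_FWD, assay.HLA2_REV]
    else:
        ivs = [assay.DRB_FWD, assay.DRB_REV]
    out: set[int] = set()
    for iv in ivs:
        out.update(range(iv.start - 1, iv.end))
    return out


def _mutate(
    seq: str, rate: float, rng: np.random.Generator, protected: set[int]
) -> str:
    chars = list(seq)
    n_mut = rng.binomial(len(chars), rate)
    if n_mut == 0:
        return seq
    free = [i for i in range(len(chars)) if i not in protected]
    sites = rng.choice(len(free), size=min(n_mut, len(free)), replace=False)
    for s in sites:
        i = free[int(s)]
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def simulate_database(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedDatabase:
    """Simulate a multi-locus reference allele database.

    Reproducible given ``cfg.seed``.  Per locus-class a base consensus is
    drawn; locus founders diverge from it outside primer sites; alleles are
    point mutations of the founder.  Alleles are named systematically
    (2-digit group = 1 + i // 10, protein field cycling, a third
    "synonymous" field on every fifth allele).  Each locus additionally
    carries ``ambiguous_pairs_per_locus`` designed pairs that differ only
    5' of the sequenced region, and ``fraction_partial`` of alleles are
    truncated to the class's partial known interval.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bases = np.array(list("ACGT"))
    class_consensus = {
        cls: "".join(rng.choice(bases, size=cfg.consensus_length))
        for cls in sorted(set(cfg.loci.values()))
    }
    records: list[AlleleRecord] = []
    full_seqs: dict[str, str] = {}
    designed: list[tuple[str, str]] = []
    for locus in sorted(cfg.loci):
        cls = cfg.loci[locus]
        protected = _protected_positions(cls, cfg)
        founder = _mutate(class_consensus[cls], cfg.locus_divergence, rng, protected)
        seqs: dict[str, str] = {}
        i = 0
        guard = 0
        while len(seqs) < cfg.alleles_per_locus:
            guard += 1
            if guard > 100 * cfg.alleles_per_locus:
                raise ValueError("cannot generate enough distinct alleles")
            seq = _mutate(founder, cfg.snp_rate, rng, protected)
            if seq in seqs.values():
                continue
            group = 1 + i // 10
            protein = 1 + i % 10
            fields = (group, protein, 1) if i % 5 == 4 else (group, protein)
            seqs[AlleleName(locus, fields).text] = seq
            i += 1
        names = list(seqs)
        # designed ambiguous pairs: differ only 5' of the sequenced region
        cov_start = (
            assay.CLASS1_COVERAGE[0].start if cls == "I" else assay.DRB_COVERAGE[0].start
        )
        for k in range(cfg.ambiguous_pairs_per_locus):
            src = names[k]
            twin_name = AlleleName(locus, (90 + k, 1)).text
            pos = int(rng.integers(0, cov_start - 1))  # 0-based, < coverage start
            src_seq = seqs[src]
            alt = [b for b in "ACGT" if b != src_seq[pos]][int(rng.integers(3))]
            seqs[twin_name] = src_seq[:pos] + alt + src_seq[pos + 1 :]
            designed.append(tuple(sorted((src, twin_name))))
        names = list(seqs)
        # partial-extent alleles; designed pairs stay full-length so their
        # distinguishing (off-coverage) position remains known
        designed_names = {n for pair in designed for n in pair}
        eligible = [n for n in names if n not in designed_names]
        n_partial = round(cfg.fraction_partial * cfg.alleles_per_locus)
        partial = set(
            rng.choice(eligible, size=min(n_partial, len(eligible)), replace=False)
        )
        pk = cfg.partial_known_class1 if cls == "I" else cfg.partial_known_class2
        for name in names:
            full = seqs[name]
            full_seqs[name] = full
            if name in partial:
                known = Interval(*pk)
                rec_seq = full[known.start - 1 : known.end]
            else:
                known = Interval(1, cfg.consensus_length)
                rec_seq = full
            records.append(
                AlleleRecord(
                    AlleleName(
                        locus,
                        tuple(
                            int(f)
                            for f in name.split("*")[1].rstrip("NLSCAQ").split(":")
                        ),
                    ),
                    rec_seq,
                    known,
                )
            )
    db = AlleleDatabase(records, Interval(1, cfg.consensus_length))
    return SimulatedDatabase(db, full_seqs, sorted(designed), dict(cfg.loci))


def simulate_genotypes(
    simdb: SimulatedDatabase, n_samples: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw diploid genotypes per sample and locus (truth table).

    Alleles are drawn uniformly with replacement, so occasional homozygotes
    occur.  Designed-ambiguous twins are excluded from truth genotypes: the
    assay cannot distinguish them from their source allele, and the truth
    table should be recoverable.
    """
    twins = {pair[1] for pair in simdb.designed_ambiguous}
    rows = []
    for s in range(1, n_samples + 1):
        sample = f"S{s:02d}"
        for locus in simdb.db.loci:
            pool = sorted(
                r.name.text for r in simdb.db.by_locus[locus] if r.name.text not in twins
            )
            a1, a2 = rng.choice(pool, size=2, replace=True)
            rows.append(
                {"sample": sample, "locus": locus, "allele1": str(a1), "allele2": str(a2)}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimRead:
    """One simulated read: MID + oriented insert sequence, plus truth tags."""

    id: str
    seq: str
    sample: str
    locus: str
    allele: str
    amplicon: str
    direction: str

    @property
    def description(self) -> str:
        return (
            f"sample={self.sample} locus={self.locus} allele={self.allele} "
            f"amplicon={self.amplicon} dir={self.direction}"
        )


@dataclass
class SimulatedRun:
    """Everything a pipeline run needs plus the audit truth."""

    reads: list[SimRead]
    manifest: pd.DataFrame  # sample, mid_id, mid_seq
    truth: pd.DataFrame  # sample, locus, allele1, allele2
    mids: list[MIDTag]
    amplicons: dict[str, Amplicon]


def simulate_reads(
    simdb: SimulatedDatabase,
    amplicons: dict[str, Amplicon],
    genotypes: pd.DataFrame,
    mids: Sequence[MIDTag],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[SimRead]:
    """Simulate MID-tagged amplicon reads from diploid genotypes.

    Per (sample, locus, amplicon) the read total is
    ``reads_per_amplicon x pool_ratio``, split over the two genotype
    alleles and the two directions by uniform multinomial draw.  Forward
    reads are MID + insert; reverse reads are MID + reverse-complemented
    insert.  Substitution errors hit every base (MID included) at
    ``error_rate``; dropout triples and primer-incompatible alleles yield
    zero reads for that amplicon.
    """
    samples = sorted(genotypes["sample"].unique())
    if len(mids) < len(samples):
        raise ValueError("not enough MIDs for samples")
    mid_of = {s: mids[i] for i, s in enumerate(samples)}
    db_names = set(simdb.full_seqs)
    dropout = set(cfg.dropout)
    reads: list[SimRead] = []
    counter = 0
    for row in genotypes.itertuples(index=False):
        if row.allele1 not in db_names or row.allele2 not in db_names:
            raise ValueError(f"genotype allele missing from database: {row}")
        cls = simdb.locus_class[row.locus]
        for amp_name, amp in amplicons.items():
            amp_cls = "II" if amp_name == "DRB" else "I"
            if amp_cls != cls:
                continue
            n_total = int(round(cfg.reads_per_amplicon * cfg.pool_ratio[amp_name]))
            cells = [
                (allele, d) for allele in (row.allele1, row.allele2) for d in "FR"
            ]
            counts = rng.multinomial(n_total, [1 / len(cells)] * len(cells))
            for (allele, d), n in zip(cells, counts):
                if (row.sample, allele, amp_name) in dropout:
                    continue
                if cfg.primer_dropout_threshold is not None:
                    mism = amp.fwd.per_allele_mismatches.get(
                        allele, 0
                    ) + amp.rev.per_allele_mismatches.get(allele, 0)
                    if mism >= cfg.primer_dropout_threshold:
                        continue
                insert = simdb.full_seqs[allele][
                    amp.insert.start - 1 : amp.insert.end
                ]
                body = insert if d == "F" else revcomp(insert)
                template = mid_of[row.sample].seq + body
                for _ in range(int(n)):
                    counter += 1
                    seq = template
                    if cfg.error_rate > 0:
                        seq = _mutate(seq, cfg.error_rate, rng, set())
                    reads.append(
                        SimRead(
                            f"read_{counter:07d}",
                            seq,
                            row.sample,
                            row.locus,
                            allele,
                            amp_name,
                            d,
                        )
                    )
    return reads


def simulate_run(cfg: SimConfig) -> tuple[SimulatedDatabase, SimulatedRun]:
    """One-call fixture: database, genotypes, MIDs and reads from a config."""
    rng = np.random.default_rng(cfg.seed)
    simdb = simulate_database(cfg, rng)
    amplicons = simdb.amplicons()
    truth = simulate_genotypes(simdb, cfg.n_samples, rng)
    mids = generate_mids(cfg.n_samples, rng, length=cfg.mid_length)
    reads = simulate_reads(simdb, amplicons, truth, mids, cfg, rng)
    samples = sorted(truth["sample"].unique())
    manifest = pd.DataFrame(
        {
            "sample": samples,
            "mid_id": [mids[i].id for i in range(len(samples))],
            "mid_seq": [mids[i].seq for i in range(len(samples))],
        }
    )
    return simdb, SimulatedRun(reads, manifest, truth, mids, amplicons)


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    """Write simulated reads as FASTQ with constant quality and truth tags."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id} {r.description}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
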