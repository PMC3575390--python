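"""Shared fixtures: toy allele databases and a seeded simulated run."""

from __future__ import annotations

import numpy as np
import pytest

from csbt.alleledb import AlleleDatabase, AlleleRecord, Interval, parse_allele_name
from csbt.pipeline import PipelineConfig, build_amplicons, type_reads
from csbt.readprep import TrimPolicy, demultiplex, trim_filter
from csbt.simlib import SimConfig, simulate_run


def make_record(name: str, seq: str, start: int = 1) -> AlleleRecord:
    return AlleleRecord(
        parse_allele_name(name), seq, Interval(start, start + len(seq) - 1)
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_db() -> AlleleDatabase:
    """5 alleles at 2 loci: 2 full-length, 1 exon-2/3-analog partial, plus
    a pair identical over positions 50+ (ambiguous under assay coverage)."""
    rng = np.random.default_rng(7)
    base = random_seq(rng, 1100)
    a1 = base
    a2 = base[:499] + ("A" if base[499] != "A" else "C") + base[500:]  # pos 500
    a3 = base[:20] + ("G" if base[20] != "G" else "T") + base[21:]  # pos 21 only
    b1 = random_seq(rng, 1100)
    records = [
        make_record("A*01:01", a1),
        make_record("A*01:02", a2),
        make_record("A*02:01", a3),  # differs from A*01:01 only at pos 21
        make_record("B*01:01", b1),
        make_record("B*02:01:01", b1[103:620], start=104),  # partial, exon-2/3
    ]
    return AlleleDatabase(records, Interval(1, 1100))


@pytest.fixture(scope="session")
def sim_small():
    """Seeded small simulated run (3 samples) plus its typing results."""
    cfg = SimConfig(seed=11, n_samples=3, reads_per_amplicon=60)
    simdb, run = simulate_run(cfg)
    return simdb, run


def type_run(simdb, run, pcfg: PipelineConfig | None = None, reads=None) -> dict:
    """Push simulated reads through demux → trim → type (in memory)."""
    pcfg = pcfg or PipelineConfig()
    amps = build_amplicons(simdb.db, pcfg)
    assigned, unassigned = demultiplex(
        [(r.id, r.seq) for r in (reads if reads is not None else run.reads)],
        run.manifest,
        amps,
    )
    trimmed, stats = trim_filter(
        assigned, TrimPolicy.uniform(amps, pcfg.trim_min, pcfg.trim_target, pcfg.trim_max)
    )
    calls, matrix, novel, acct = type_reads(trimmed, simdb.db, amps, pcfg)
    return {
        "simdb": simdb,
        "run": run,
        "amplicons": amps,
        "assigned": assigned,
        "unassigned": unassigned,
        "trimmed": trimmed,
        "calls": calls,
        "matrix": matrix,
        "novel": novel,
        "accounting": acct,
    }


@pytest.fixture(scope="session")
def typed_small(sim_small):
    """The small run pushed through demux → trim → type."""
    simdb, run = sim_small
    return type_run(simdb, run)
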