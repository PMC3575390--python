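"""End-to-end typing pipeline: demux → trim → map → matrix → call → novel.

Binds the stages into the two published analysis modes (stringent and
low-stringency) driven by a single serializable configuration, and
produces the report bundle: genotype table with confidence categories
(unambiguous / ambiguous_set / low_stringency / amplicon_discordant /
putative_novel / not_detected), match-matrix and novel-candidate tables,
per-stage read accounting, and run summary metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alleledb import AlleleDatabase, Interval, load_allele_fasta
from .ampdesign import Amplicon, define_amplicon
from .matchcall import (
    CallPolicy,
    GenotypeCall,
    GroupMapping,
    MatchCondition,
    NovelCandidate,
    NovelPolicy,
    ReadGroup,
    build_match_matrix_classI,
    build_match_matrix_classII,
    call_genotype,
    detect_novel,
    expected_matrix,
    find_amplicon_discordant,
    map_reads_exact,
    restrict_references,
)
from .readprep import DemuxedRead, TrimPolicy, demultiplex, read_fastq, trim_filter

__all__ = [
    "AmpliconDef",
    "PipelineConfig",
    "RunResult",
    "run_pipeline",
    "type_reads",
    "summarize_run",
    "calls_to_frame",
    "novel_to_frame",
]

log = logging.getLogger("csbt")


@dataclass
class AmpliconDef:
    """Serializable amplicon definition (coordinates + class + key role)."""

    name: str
    tag: str
    locus_class: str  # "I" or "II"
    fwd: tuple[int, int]
    rev: tuple[int, int]
    key: bool = False

    def build(
        self, db: AlleleDatabase, locus_class: Mapping[str, str] | None = None
    ) -> Amplicon:
        """Materialise with modal-base primer consensus from the database.

        Only alleles of this amplicon's locus class contribute to the
        primer consensus (pan-locus primers are conserved within a class,
        not across classes).
        """
        records = [
            r
            for r in db.records
            if locus_class is None or locus_class.get(r.locus) == self.locus_class
        ]
        return define_amplicon(
            self.name,
            Interval(*self.fwd),
            Interval(*self.rev),
            records,
            tag=self.tag,
        )


def default_amplicon_defs() -> list[AmpliconDef]:
    """The published three-amplicon assay (2F / forward keys)."""
    return [
        AmpliconDef("HLA-1", "1", "I", (50, 68), (707, 725)),
        AmpliconDef("HLA-2", "2", "I", (145, 163), (1051, 1069), key=True),
        AmpliconDef("DRB", "DRB", "II", (61, 79), (707, 727), key=True),
    ]


def _infer_locus_class(locus: str) -> str:
    return "II" if locus.startswith(("DR", "DQ", "DP")) else "I"


@dataclass
class PipelineConfig:
    """A fully serializable run configuration (YAML round-trip)."""

    db: str = ""
    reads: str = ""
    manifest: str = ""
    outdir: str = "csbt_out"
    amplicons: list[AmpliconDef] = field(default_factory=default_amplicon_defs)
    loci_class: dict[str, str] = field(default_factory=dict)
    trim_min: int = 300
    trim_target: int = 320
    trim_max: int = 350
    mid_mismatches: int = 0
    primer_mismatches: int = 2
    call: CallPolicy = field(default_factory=CallPolicy)
    novel: NovelPolicy = field(default_factory=NovelPolicy)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "amplicons" in kwargs:
            kwargs["amplicons"] = [
                AmpliconDef(
                    a["name"],
                    a.get("tag", a["name"]),
                    a.get("locus_class", a.get("class", "I")),
                    tuple(a["fwd"]),
                    tuple(a["rev"]),
                    bool(a.get("key", False)),
                )
                for a in kwargs["amplicons"]
            ]
        if "call" in kwargs:
            kwargs["call"] = CallPolicy(**kwargs["call"])
        if "novel" in kwargs:
            kwargs["novel"] = NovelPolicy(**kwargs["novel"])
        trim = kwargs.pop("trim", None)
        cfg = cls(**kwargs)
        if trim:
            cfg.trim_min = trim.get("min", cfg.trim_min)
            cfg.trim_target = trim.get("target", cfg.trim_target)
            cfg.trim_max = trim.get("max", cfg.trim_max)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "db": self.db,
            "reads": self.reads,
            "manifest": self.manifest,
            "outdir": self.outdir,
            "amplicons": [
                {
                    "name": a.name,
                    "tag": a.tag,
                    "locus_class": a.locus_class,
                    "fwd": list(a.fwd),
                    "rev": list(a.rev),
                    "key": a.key,
                }
                for a in self.amplicons
            ],
            "loci_class": dict(self.loci_class),
            "trim": {
                "min": self.trim_min,
                "target": self.trim_target,
                "max": self.trim_max,
            },
            "mid_mismatches": self.mid_mismatches,
            "primer_mismatches": self.primer_mismatches,
            "call": dataclasses.asdict(self.call),
            "novel": dataclasses.asdict(self.novel),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class RunResult:
    """The report bundle of one pipeline run."""

    calls: list[GenotypeCall]
    matrices: pd.DataFrame
    novel: list[NovelCandidate]
    demux_unassigned: list[tuple[str, str]]
    trim_stats: pd.DataFrame
    accounting: dict[str, int]
    summary: pd.DataFrame


def _locus_class_of(db: AlleleDatabase, cfg: PipelineConfig) -> dict[str, str]:
    return {
        locus: cfg.loci_class.get(locus, _infer_locus_class(locus))
        for locus in db.loci
    }


def build_amplicons(db: AlleleDatabase, cfg: PipelineConfig) -> dict[str, Amplicon]:
    """Materialise the configured amplicons with class-specific consensus."""
    locus_class = _locus_class_of(db, cfg)
    return {a.name: a.build(db, locus_class) for a in cfg.amplicons}


def type_reads(
    trimmed: Sequence[DemuxedRead],
    db: AlleleDatabase,
    amplicons: Mapping[str, Amplicon],
    cfg: PipelineConfig,
) -> tuple[list[GenotypeCall], pd.DataFrame, list[NovelCandidate], dict[str, int]]:
    """Map, join and call genotypes for every sample in a trimmed read set.

    Runs the class I branch (2F-keyed restriction, inner join on 2F/1F/1R,
    outer on 2R) on class I amplicons and the class II branch (forward key
    admitting extension matches, reverse outer) on class II amplicons.
    Returns (calls, match-matrix table, novel candidates, read accounting).
    """
    amp_class = {a.name: a.locus_class for a in cfg.amplicons}
    key_amp = {
        a.locus_class: a.name for a in cfg.amplicons if a.key
    }
    locus_class = _locus_class_of(db, cfg)
    groups = ReadGroup.for_amplicons(amplicons, cfg.trim_target)
    calls: list[GenotypeCall] = []
    matrices: list[pd.DataFrame] = []
    novel: list[NovelCandidate] = []
    n_matched = n_unmatched = 0
    samples = sorted({r.sample for r in trimmed})
    by_sample_group: dict[str, dict[str, list[DemuxedRead]]] = {}
    for r in trimmed:
        by_sample_group.setdefault(r.sample, {}).setdefault(r.group, []).append(r)

    for sample in samples:
        per_group = by_sample_group[sample]
        for cls in sorted({c for c in amp_class.values()}):
            cls_loci = sorted(l for l, c in locus_class.items() if c == cls)
            if not cls_loci:
                continue
            cls_db = db.subset(
                r.name.text for r in db if locus_class[r.locus] == cls
            )
            if len(cls_db) == 0:
                continue
            cls_groups = {
                g: rg
                for g, rg in groups.items()
                if amp_class[rg.amplicon.name] == cls
            }
            key_group = amplicons[key_amp[cls]].group_label("F")
            key_conditions = (
                (MatchCondition.FULL,)
                if cls == "I"
                else (
                    MatchCondition.FULL,
                    MatchCondition.EXTEND,
                    MatchCondition.EXTEND_BOTH,
                )
            )
            key_reads = per_group.get(key_group, [])
            if not key_reads:
                for locus in cls_loci:
                    calls.append(
                        GenotypeCall(sample, locus, (), 0, "not_detected")
                    )
                n_unmatched += sum(
                    len(per_group.get(g, [])) for g in cls_groups
                )
                continue
            key_mapping = map_reads_exact(
                key_reads, cls_db, cls_groups[key_group], cfg.call.anchor_min
            )
            candidates = restrict_references(key_mapping, key_conditions)
            if not candidates:
                for locus in cls_loci:
                    calls.append(
                        GenotypeCall(sample, locus, (), 0, "not_detected")
                    )
                n_unmatched += sum(
                    len(per_group.get(g, [])) for g in cls_groups
                )
                continue
            sub_db = cls_db.subset(candidates)
            mappings: dict[str, GroupMapping] = {key_group: key_mapping}
            for g, rg in cls_groups.items():
                if g == key_group:
                    continue
                mappings[g] = map_reads_exact(
                    per_group.get(g, []), sub_db, rg, cfg.call.anchor_min
                )
            expected = expected_matrix(cls_db, cls_groups, cfg.call.anchor_min)
            if cls == "I":
                matrix = build_match_matrix_classI(
                    sample, mappings, expected, candidates
                )
            else:
                matrix = build_match_matrix_classII(
                    sample, mappings, expected, candidates
                )
            sample_calls = call_genotype(
                matrix,
                expected,
                cls_db,
                cls_groups,
                cfg.call,
                loci=cls_loci,
                mappings=mappings,
            )
            if cls == "I":
                sample_calls.extend(
                    find_amplicon_discordant(
                        sample,
                        per_group,
                        cls_db,
                        cls_groups,
                        candidates,
                        sample_calls,
                        anchor_min=cfg.call.anchor_min,
                    )
                )
            calls.extend(sample_calls)
            matrices.append(matrix.to_frame())
            novel.extend(detect_novel(sample, mappings, cls_db, cfg.novel))
            for gm in mappings.values():
                n_unmatched += sum(gm.unmatched.values())
                n_matched += gm.n_reads - sum(gm.unmatched.values())
    matrix_df = (
        pd.concat(matrices, ignore_index=True)
        if matrices
        else pd.DataFrame(columns=["sample", "allele", "group", "condition", "reads"])
    )
    accounting = {"mapped": n_matched, "unmatched": n_unmatched}
    return calls, matrix_df, novel, accounting


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> RunResult:
    """Execute the full pipeline from files per the configuration.

    Stages run in order (demux → trim → map → matrix → call → novel);
    every input read ends in exactly one terminal accounting category
    (unassigned, length_rejected, mapped, unmatched).  With
    ``write=True``, TSV/JSON reports are written under ``cfg.outdir``.
    """
    db = load_allele_fasta(cfg.db)
    manifest = pd.read_csv(cfg.manifest, sep="\t")
    amplicons = build_amplicons(db, cfg)
    raw = list(read_fastq(cfg.reads))
    log.info("input reads: %d", len(raw))
    assigned, unassigned = demultiplex(
        raw, manifest, amplicons, cfg.mid_mismatches, cfg.primer_mismatches
    )
    log.info("demux: %d assigned, %d unassigned", len(assigned), len(unassigned))
    policy = TrimPolicy.uniform(amplicons, cfg.trim_min, cfg.trim_target, cfg.trim_max)
    trimmed, trim_stats = trim_filter(assigned, policy)
    log.info("trim: %d kept of %d", len(trimmed), len(assigned))
    calls, matrix_df, novel, mapping_acct = type_reads(trimmed, db, amplicons, cfg)
    accounting = {
        "input": len(raw),
        "unassigned": len(unassigned),
        "length_rejected": len(assigned) - len(trimmed),
        **mapping_acct,
    }
    summary = summarize_run(assigned)
    result = RunResult(
        calls, matrix_df, novel, unassigned, trim_stats, accounting, summary
    )
    if write:
        _write_bundle(result, cfg)
    return result


def calls_to_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "locus": [c.locus for c in calls],
            "call": [c.name for c in calls],
            "resolution": [c.resolution for c in calls],
            "confidence": [c.confidence for c in calls],
            "support": [
                ";".join(f"{g}={n}" for g, n in c.support) for c in calls
            ],
            "homozygous_consistent": [c.homozygous_consistent for c in calls],
            "warnings": [";".join(c.warnings) for c in calls],
        }
    )


def novel_to_frame(novel: Sequence[NovelCandidate]) -> pd.DataFrame:
    recs = []
    for c in novel:
        for ref in c.nearest:
            for s in c.snps[ref]:
                recs.append(
                    {
                        "sample": c.sample,
                        "nearest": ref,
                        "position": s.position,
                        "ref_base": s.ref_base,
                        "alt_base": s.alt_base,
                        "codon": s.effect.codon_index if s.effect else None,
                        "ref_aa": s.effect.ref_aa if s.effect else None,
                        "alt_aa": s.effect.alt_aa if s.effect else None,
                        "synonymous": s.effect.synonymous if s.effect else None,
                        "reads": c.n_reads,
                    }
                )
    return pd.DataFrame(
        recs,
        columns=[
            "sample", "nearest", "position", "ref_base", "alt_base",
            "codon", "ref_aa", "alt_aa", "synonymous", "reads",
        ],
    )


def _write_bundle(result: RunResult, cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls_to_frame(result.calls).to_csv(
        outdir / "genotypes.tsv", sep="\t", index=False
    )
    result.matrices.to_csv(outdir / "match_matrix.tsv", sep="\t", index=False)
    novel_to_frame(result.novel).to_csv(outdir / "novel.tsv", sep="\t", index=False)
    with open(outdir / "novel.fasta", "w") as fh:
        for i, c in enumerate(result.novel, 1):
            fh.write(f">novel_{i} sample={c.sample} nearest={c.primary}\n")
            fh.write(c.consensus_seq + "\n")
    result.trim_stats.to_csv(outdir / "trim_stats.tsv", sep="\t", index=False)
    result.summary.to_csv(outdir / "summary_metrics.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.accounting, fh, indent=2, sort_keys=True)


def summarize_run(
    assigned: Sequence[DemuxedRead] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample and per-amplicon read metrics (mean, sample sd).

    Accepts demultiplexed reads or a precomputed (sample, amplicon,
    n_reads) table.  Standard deviation uses the n-1 form; a single sample
    reports sd 0 with an ``n=1`` note, an empty run reports zeros.
    """
    if isinstance(assigned, pd.DataFrame):
        counts = assigned
    else:
        recs = [(r.sample, r.amplicon) for r in assigned]
        counts = (
            pd.DataFrame(recs, columns=["sample", "amplicon"])
            .groupby(["sample", "amplicon"])
            .size()
            .reset_index(name="n_reads")
            if recs
            else pd.DataFrame(columns=["sample", "amplicon", "n_reads"])
        )
    rows = []

    def _row(metric: str, values: pd.Series) -> dict:
        n = len(values)
        if n == 0:
            return {"metric": metric, "mean": 0.0, "sd": 0.0, "n": 0, "note": "empty"}
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        return {
            "metric": metric,
            "mean": float(values.mean()),
            "sd": sd,
            "n": n,
            "note": "n=1" if n == 1 else "",
        }

    per_sample = counts.groupby("sample")["n_reads"].sum() if len(counts) else pd.Series(dtype=float)
    rows.append(_row("reads_per_sample", per_sample))
    if len(counts):
        for amp, sub in counts.groupby("amplicon"):
            rows.append(
                _row(f"reads_per_sample[{amp}]", sub.set_index("sample")["n_reads"])
            )
    return pd.DataFrame(rows)
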