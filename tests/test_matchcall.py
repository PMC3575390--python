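"""Exact-match mapping, match-condition typing, matrix joins, calling,
novel-allele detection and variant annotation."""

import numpy as np
import pytest

from csbt.alleledb import AlleleDatabase, Interval
from csbt.ampdesign import Amplicon, PrimerSite
from csbt.matchcall import (
    CallPolicy,
    MatchCondition,
    NovelPolicy,
    ReadGroup,
    annotate_variant,
    build_match_matrix_classI,
    call_genotype,
    detect_novel,
    expected_condition,
    expected_matrix,
    map_reads_exact,
    restrict_references,
)
from csbt.readprep import DemuxedRead
from csbt.simlib import revcomp

from conftest import make_record, random_seq

F, E, EB, N = (
    MatchCondition.FULL,
    MatchCondition.EXTEND,
    MatchCondition.EXTEND_BOTH,
    MatchCondition.NONE,
)


def _amp(name, fwd, rev, tag):
    return Amplicon(
        name,
        PrimerSite(fwd, "N" * fwd.length, {}),
        PrimerSite(rev, "N" * rev.length, {}),
        tag=tag,
    )


@pytest.fixture(scope="module")
def frame():
    """A 1100-nt frame with one full-length allele, one exon-2/3-only
    partial sharing its sequence, and one distinct full-length allele."""
    rng = np.random.default_rng(42)
    base = random_seq(rng, 1100)
    other = random_seq(rng, 1100)
    db = AlleleDatabase(
        [
            make_record("A*01:01", base),
            make_record("A*02:01", base[103:620], start=104),
            make_record("A*03:01", other),
        ],
        Interval(1, 1100),
    )
    amps = {
        "HLA-1": _amp("HLA-1", Interval(50, 68), Interval(707, 725), "1"),
        "HLA-2": _amp("HLA-2", Interval(145, 163), Interval(1051, 1069), "2"),
    }
    groups = ReadGroup.for_amplicons(amps, 320)
    return db, base, groups


def _read(seq, group):
    return DemuxedRead("r", "S01", "x", group.direction, group.label, seq)


def window_seq(full, iv):
    return full[iv.start - 1 : iv.end]


class TestExpectedMatrix:
    def test_windows(self, frame):
        _, _, groups = frame
        assert groups["1F"].window == Interval(69, 388)
        assert groups["1R"].window == Interval(387, 706)
        assert groups["2F"].window == Interval(164, 483)
        assert groups["2R"].window == Interval(731, 1050)

    def test_full_length_row_all_full(self, frame):
        db, _, groups = frame
        exp = expected_matrix(db, groups)
        assert exp["A*01:01"] == {"1F": F, "1R": F, "2F": F, "2R": F}

    def test_partial_row_matches_condition_scheme(self, frame):
        """Exon-2/3-only reference: extension matches flanking exon reads,
        full 2F match, null 2R."""
        db, _, groups = frame
        exp = expected_matrix(db, groups)
        assert exp["A*02:01"] == {"1F": E, "1R": E, "2F": F, "2R": N}

    def test_extend_both_geometry(self):
        # window strictly containing the known interval on both sides
        assert expected_condition(Interval(100, 330), Interval(80, 399)) == EB

    def test_anchor_minimum(self):
        # 20-nt overlap below the 30-nt anchor -> NONE
        assert expected_condition(Interval(1, 100), Interval(81, 400)) == N


class TestMapReadsExact:
    def test_full_match(self, frame):
        db, base, groups = frame
        g = groups["2F"]
        m = map_reads_exact([_read(window_seq(base, g.window), g)], db, g)
        assert m.per_allele["A*01:01"] == (F, 1)
        assert m.per_allele["A*02:01"] == (F, 1)  # window inside known
        assert "A*03:01" not in m.per_allele

    def test_reverse_read_orientation(self, frame):
        db, base, groups = frame
        g = groups["1R"]
        m = map_reads_exact([_read(revcomp(window_seq(base, g.window)), g)], db, g)
        assert m.per_allele["A*01:01"] == (F, 1)

    def test_extend_against_partial_reference(self, frame):
        db, base, groups = frame
        g = groups["1F"]  # window 69-388 spans the partial's 5' edge at 104
        m = map_reads_exact([_read(window_seq(base, g.window), g)], db, g)
        assert m.per_allele["A*02:01"] == (E, 1)
        assert m.per_allele["A*01:01"] == (F, 1)

    def test_one_mismatch_no_entry(self, frame):
        db, base, groups = frame
        g = groups["2F"]
        seq = list(window_seq(base, g.window))
        seq[100] = "A" if seq[100] != "A" else "C"
        m = map_reads_exact([_read("".join(seq), g)], db, g)
        assert m.per_allele == {}
        assert sum(m.unmatched.values()) == 1

    def test_empty_reference_subset_rejected(self, frame):
        db, base, groups = frame
        empty = db.subset([])
        with pytest.raises(ValueError, match="empty reference"):
            map_reads_exact([], empty, groups["2F"])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_substring_scan(self, seed):
        """Oracle equivalence: FULL matches equal a string-search scan of
        every reference at the expected offset."""
        rng = np.random.default_rng(seed)
        base = random_seq(rng, 1100)
        records = [make_record("A*01:01", base)]
        for i in range(8):
            seq = list(base)
            for _ in range(1 + rng.integers(3)):
                seq[int(rng.integers(0, 1100))] = "ACGT"[int(rng.integers(4))]
            records.append(make_record(f"A*{i + 2:02d}:01", "".join(seq)))
        db = AlleleDatabase(records, Interval(1, 1100))
        amp = _amp("HLA-2", Interval(145, 163), Interval(1051, 1069), "2")
        g = ReadGroup.for_amplicons({"HLA-2": amp}, 320)["2F"]
        reads = []
        for rec in records[:4]:
            reads.append(_read(window_seq(rec.seq, g.window), g))
        m = map_reads_exact(reads, db, g)
        # oracle: str.find at the expected offset, over every (read, allele)
        offset = g.window.start - 1  # 0-based into a full-length sequence
        for r in reads:
            for rec in records:
                found = rec.seq.find(r.seq)
                hit = (rec.name.text, F) in m.per_seq_matches[r.seq]
                assert hit == (found != -1 and found == offset)


class TestRestrictionAndJoins:
    def test_restriction_keeps_all_window_sharers(self, frame):
        db, base, groups = frame
        g = groups["2F"]
        m = map_reads_exact([_read(window_seq(base, g.window), g)], db, g)
        # the partial shares the 2F window sequence with A*01:01
        assert restrict_references(m) == ["A*01:01", "A*02:01"]

    def test_restriction_soundness(self, frame):
        """Downstream mapping against the restricted subset equals mapping
        against the full database, for every candidate allele."""
        db, base, groups = frame
        g2f = groups["2F"]
        key = map_reads_exact([_read(window_seq(base, g2f.window), g2f)], db, g2f)
        candidates = restrict_references(key)
        sub = db.subset(candidates)
        for label in ("1F", "1R", "2R"):
            g = groups[label]
            reads = [_read(window_seq(base, g.window), g)]
            vs_sub = map_reads_exact(reads, sub, g).per_allele
            vs_full = map_reads_exact(reads, db, g).per_allele
            assert vs_sub == {a: c for a, c in vs_full.items() if a in candidates}

    def test_inner_join_drops_unsupported_row(self, frame):
        """An allele with 2F support but no 1F reads (where 1F support is
        expected) is dropped by the inner join."""
        db, base, groups = frame
        g2f = groups["2F"]
        mappings = {
            label: map_reads_exact(
                [_read(window_seq(base, groups[label].window), groups[label])]
                if label != "1F"
                else [],
                db,
                groups[label],
            )
            for label in ("2F", "1F", "1R", "2R")
        }
        # orientation fix for reverse groups
        for label in ("1R", "2R"):
            g = groups[label]
            mappings[label] = map_reads_exact(
                [_read(revcomp(window_seq(base, g.window)), g)], db, g
            )
        exp = expected_matrix(db, groups)
        matrix = build_match_matrix_classI(
            "S01", mappings, exp, restrict_references(mappings["2F"])
        )
        assert matrix.rows == {}

    def test_classI_rows(self, frame):
        db, base, groups = frame
        mappings = {}
        for label, g in groups.items():
            s = window_seq(base, g.window)
            mappings[label] = map_reads_exact(
                [_read(s if g.direction == "F" else revcomp(s), g)], db, g
            )
        exp = expected_matrix(db, groups)
        matrix = build_match_matrix_classI(
            "S01", mappings, exp, restrict_references(mappings["2F"])
        )
        assert {g: c for g, (c, _n) in matrix.rows["A*01:01"].items()} == {
            "2F": F, "1F": F, "1R": F, "2R": F,
        }
        assert {g: c for g, (c, _n) in matrix.rows["A*02:01"].items()} == {
            "2F": F, "1F": E, "1R": E, "2R": N,
        }


class TestCalling:
    def _mappings(self, db, base, groups):
        out = {}
        for label, g in groups.items():
            s = window_seq(base, g.window)
            reads = [
                _read(s if g.direction == "F" else revcomp(s), g) for _ in range(5)
            ]
            out[label] = map_reads_exact(reads, db, g)
        return out

    def test_full_and_partial_called_as_set(self, frame):
        """A full-length allele and a truncated reference with the same
        sequence are indistinguishable over the supported windows."""
        db, base, groups = frame
        mappings = self._mappings(db, base, groups)
        exp = expected_matrix(db, groups)
        matrix = build_match_matrix_classI(
            "S01", mappings, exp, restrict_references(mappings["2F"])
        )
        calls = call_genotype(matrix, exp, db, groups, CallPolicy(), loci=["A"])
        (call,) = calls
        assert call.alleles == ("A*01:01", "A*02:01")
        assert call.confidence == "ambiguous_set"

    def test_min_reads_threshold(self, frame):
        db, base, groups = frame
        mappings = self._mappings(db, base, groups)
        exp = expected_matrix(db, groups)
        matrix = build_match_matrix_classI(
            "S01", mappings, exp, restrict_references(mappings["2F"])
        )
        strict = call_genotype(
            matrix, exp, db, groups, CallPolicy(min_reads_per_group=6), loci=["A"]
        )
        assert [c.confidence for c in strict] == ["not_detected"]
        low = call_genotype(
            matrix,
            exp,
            db,
            groups,
            CallPolicy(min_reads_per_group=6, mode="low_stringency"),
            loci=["A"],
        )
        assert low[0].confidence == "ambiguous_set"

    def test_not_detected_when_no_key_support(self, frame):
        db, _, groups = frame
        empty = {
            label: map_reads_exact([], db, g) for label, g in groups.items()
        }
        exp = expected_matrix(db, groups)
        matrix = build_match_matrix_classI("S01", empty, exp, [])
        calls = call_genotype(matrix, exp, db, groups, loci=["A"])
        assert [c.confidence for c in calls] == ["not_detected"]


class TestAnnotateVariant:
    def test_codon_index_of_position_587(self):
        rng = np.random.default_rng(1)
        seq = list(random_seq(rng, 900))
        seq[585:588] = list("CCA")  # codon 196 = Pro
        rec = make_record("C*08:01", "".join(seq))
        eff = annotate_variant(rec, 587, "T")  # CCA -> CTA
        assert eff.codon_index == 196
        assert (eff.ref_aa, eff.alt_aa) == ("P", "L")
        assert not eff.synonymous

    def test_third_position_wobble_synonymous(self):
        rec = make_record("A*01:01", "ATGCTGGGTTAA")
        eff = annotate_variant(rec, 6, "A")  # CTG -> CTA, both Leu
        assert eff.synonymous

    def test_identity_substitution(self):
        rec = make_record("A*01:01", "ATGCTG")
        eff = annotate_variant(rec, 1, "A")
        assert eff.ref_aa == eff.alt_aa == "M"

    def test_position_outside_known_rejected(self):
        rec = make_record("A*01:01", "A" * 30, start=10)
        with pytest.raises(ValueError, match="outside"):
            annotate_variant(rec, 5, "C")

    def test_offframe_partial_reference(self):
        # known starts at 104; codon 196 (586-588) fully inside -> works
        rng = np.random.default_rng(2)
        seq = list(random_seq(rng, 517))
        rec = make_record("A*02:01", "".join(seq), start=104)
        eff = annotate_variant(rec, 587, "A")
        assert eff.codon_index == 196


class TestDetectNovel:
    def test_injected_snps_recovered_exactly(self, frame):
        db, base, groups = frame
        g = groups["2F"]
        novel_seq = list(window_seq(base, g.window))
        positions = [50, 120]  # 0-based within the window
        truth = []
        for p in positions:
            ref = novel_seq[p]
            alt = {"A": "C", "C": "T", "G": "A", "T": "G"}[ref]
            truth.append((g.window.start + p, ref, alt))
            novel_seq[p] = alt
        reads = [_read("".join(novel_seq), g) for _ in range(4)]
        m = map_reads_exact(reads, db, g)
        assert m.per_allele == {}
        cands = detect_novel("S01", {"2F": m}, db, NovelPolicy(min_cluster=3))
        (cand,) = cands
        # the partial reference shares the window sequence -> equidistant
        assert set(cand.nearest) == {"A*01:01", "A*02:01"}
        for ref in cand.nearest:
            assert [
                (s.position, s.ref_base, s.alt_base) for s in cand.snps[ref]
            ] == truth
        assert cand.support == {"2F": 4}

    def test_cluster_below_min_ignored(self, frame):
        db, base, groups = frame
        g = groups["2F"]
        seq = list(window_seq(base, g.window))
        seq[10] = "A" if seq[10] != "A" else "C"
        m = map_reads_exact([_read("".join(seq), g)] * 2, db, g)
        assert detect_novel("S01", {"2F": m}, db, NovelPolicy(min_cluster=3)) == []

    def test_equidistant_references_all_reported(self):
        rng = np.random.default_rng(9)
        base = random_seq(rng, 1100)
        # two references equidistant (1 SNP each, different positions)
        r1 = list(base)
        r1[200] = "A" if base[200] != "A" else "C"
        r2 = list(base)
        r2[260] = "A" if base[260] != "A" else "C"
        db = AlleleDatabase(
            [make_record("A*01:01", "".join(r1)), make_record("A*02:01", "".join(r2))],
            Interval(1, 1100),
        )
        amp = _amp("HLA-2", Interval(145, 163), Interval(1051, 1069), "2")
        g = ReadGroup.for_amplicons({"HLA-2": amp}, 320)["2F"]
        m = map_reads_exact([_read(window_seq(base, g.window), g)] * 3, db, g)
        (cand,) = detect_novel("S01", {"2F": m}, db, NovelPolicy())
        assert cand.nearest == ("A*01:01", "A*02:01")
        assert set(cand.snps) == {"A*01:01", "A*02:01"}

    def test_consensus_applies_snps(self, frame):
        db, base, groups = frame
        g = groups["2F"]
        seq = list(window_seq(base, g.window))
        seq[40] = "A" if seq[40] != "A" else "C"
        m = map_reads_exact([_read("".join(seq), g)] * 3, db, g)
        (cand,) = detect_novel("S01", {"2F": m}, db, NovelPolicy())
        snp = cand.snps[cand.primary][0]
        assert cand.consensus_seq[snp.position - db[cand.primary].known.start] == snp.alt_base
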