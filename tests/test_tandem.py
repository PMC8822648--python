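"""Tandem structure: read-pair classification, TSI, junctions, arrays, MAL."""

import numpy as np
import pytest

from satdyn.classify import build_consensus
from satdyn.sim import SimConfig, simulate_reads, simulate_satellitome
from satdyn.tandem import (
    ArrayInterval,
    ReadPairClass,
    annotate_junctions,
    best_family_hit,
    classify_read_pairs,
    mal,
    mal_table,
    merge_arrays,
    parse_rm_out,
    scan_read_arrays,
    tsi,
)
from tests.conftest import random_seq


@pytest.fixture(scope="module")
def family():
    rng = np.random.default_rng(7)
    cons = random_seq(rng, 150)
    array = cons * 12
    flank = random_seq(rng, 800)
    return {"cons": cons, "array": array, "flank": flank, "rng": rng}


class TestReadPairClassification:
    def test_pair_inside_array_is_homogeneous(self, family):
        pairs = [("p1", family["array"][100:201], family["array"][300:401])]
        counts, classed = classify_read_pairs(pairs, {"fam": family["cons"]})
        assert counts.loc[0, "homogeneous"] == 1
        assert classed[0].kind == "homogeneous"
        assert classed[0].external_annotation is None

    def test_array_flank_pair_is_heterogeneous(self, family):
        pairs = [("p1", family["array"][:101], family["flank"][:101])]
        counts, classed = classify_read_pairs(pairs, {"fam": family["cons"]})
        assert counts.loc[0, "heterogeneous"] == 1
        het = [c for c in classed if c.kind == "heterogeneous"]
        assert het[0].external_sequence == family["flank"][:101]

    def test_orphan_mates_skipped(self, family):
        pairs = [("p1", family["array"][:101], "")]
        counts, _ = classify_read_pairs(pairs, {"fam": family["cons"]})
        assert counts[["homogeneous", "heterogeneous"]].to_numpy().sum() == 0

    def test_reverse_complement_mate_detected(self, family):
        rc = family["array"][50:151].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert best_family_hit(rc, {"fam": family["cons"]}) == "fam"

    def test_all_array_genome_gives_full_tsi(self, family):
        """Every pair sampled from a genome that is one long array must come
        out homogeneous."""
        rng = np.random.default_rng(11)
        genome = family["cons"] * 30
        reads = simulate_reads(genome, 101, 180, 300, rng)
        counts, _ = classify_read_pairs(reads, {"fam": family["cons"]})
        assert counts.loc[0, "tsi"] == pytest.approx(100.0)


class TestTSI:
    def test_arithmetic(self):
        assert tsi(95, 5) == pytest.approx(95.0)
        assert tsi(0, 10) == 0.0

    def test_low_tsi_complement(self):
        # a poorly tandem family: most detected units sit next to foreign DNA
        value = tsi(111, 889)
        assert value == pytest.approx(11.1)
        assert 100 - value == pytest.approx(88.9)

    def test_zero_total_flagged(self):
        with pytest.raises(ValueError):
            tsi(0, 0)


class TestJunctionAnnotation:
    def test_known_te_annotated(self, family):
        rng = np.random.default_rng(3)
        helitron = random_seq(rng, 300)
        het = [ReadPairClass("p1", "fam", "heterogeneous", "unknown", helitron[:101])]
        table = annotate_junctions(het, {"Hel1": helitron}, classes={"Hel1": "TE/Helitron"})
        assert table.iloc[0]["annotation"] == "TE/Helitron"

    def test_random_external_is_unknown(self, family):
        rng = np.random.default_rng(4)
        het = [ReadPairClass("p1", "fam", "heterogeneous", "unknown", random_seq(rng, 101))]
        table = annotate_junctions(het, {"Hel1": random_seq(rng, 300)})
        assert table.iloc[0]["annotation"] == "unknown"

    def test_line_fraction_recovered(self, family):
        """Junction composition is recovered within binomial noise when a
        known fraction of flanks are LINE copies."""
        rng = np.random.default_rng(5)
        line = random_seq(rng, 400)
        other = random_seq(rng, 400)
        n, frac = 100, 0.57
        het = []
        for i in range(n):
            src = line if i < frac * n else other
            start = int(rng.integers(0, len(src) - 101))
            het.append(ReadPairClass(f"p{i}", "fam", "heterogeneous", "unknown",
                                     src[start:start + 101]))
        table = annotate_junctions(het, {"LINE1": line, "X1": other},
                                   classes={"LINE1": "LINE", "X1": "TE/other"})
        got = table.set_index("annotation")["count"]
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(got["LINE"] / n - frac) <= 3 * se


class TestMergeArrays:
    def test_small_gap_merges(self):
        hits = [("r", "f", 0, 500), ("r", "f", 502, 1004)]
        out = merge_arrays(hits, rul=100)
        assert len(out) == 1
        assert out[0].length == 1004

    def test_gap_above_limit_splits(self):
        hits = [("r", "f", 0, 500), ("r", "f", 504, 1004)]
        out = merge_arrays(hits, rul=100)
        assert len(out) == 2

    def test_below_min_monomers_discarded(self):
        out = merge_arrays([("r", "f", 0, 100)], rul=100)
        assert out == []

    def test_idempotent(self):
        hits = [("r", "f", 0, 500), ("r", "f", 502, 900), ("r", "f", 2000, 2500)]
        once = merge_arrays(hits, rul=100)
        again = merge_arrays([(iv.read_id, iv.family_id, iv.start, iv.end) for iv in once],
                             rul=100)
        assert [(iv.start, iv.end) for iv in again] == [(iv.start, iv.end) for iv in once]

    def test_array_count_monotone_in_gap(self, rng):
        pos = np.sort(rng.integers(0, 5000, size=30))
        hits = [("r", "f", int(p), int(p) + 120) for p in pos]
        counts = [len(merge_arrays(hits, rul=50, max_gap=g)) for g in (0, 3, 10, 50, 500)]
        assert counts == sorted(counts, reverse=True)

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            merge_arrays([("r", "f", -1, 100)], rul=50)


class TestMAL:
    def test_maximum_selected(self):
        ivs = [ArrayInterval("r1", "f", 0, 400, 100),
               ArrayInterval("r2", "f", 0, 1002, 100),
               ArrayInterval("r3", "f", 0, 800, 100)]
        assert mal(ivs) == {"f": 1002}

    def test_empty_flagged(self):
        assert mal([]) == {}

    def test_table_reports_both_units(self):
        ivs = [ArrayInterval("r1", "f", 0, 1002, 100)]
        table = mal_table(ivs)
        assert table.loc[0, "mal_bp"] == 1002
        assert table.loc[0, "mal_monomers"] == pytest.approx(10.02)

    def test_long_read_recovers_known_array(self, family):
        """A noisy long read over a 20-monomer array yields MAL equal to the
        true array length up to indel noise."""
        rng = np.random.default_rng(21)
        cons176 = random_seq(rng, 176)
        true_len = 176 * 20
        genome = random_seq(rng, 1500) + cons176 * 20 + random_seq(rng, 1500)
        # apply nanopore-style errors to the whole read
        from satdyn.sim import _apply_errors

        read = _apply_errors(genome, sub_rate=0.03, indel_rate=0.03, rng=rng)
        hits = scan_read_arrays(read, cons176, "f", "lr1")
        arrays = merge_arrays(hits, rul=176)
        got = mal(arrays)["f"]
        assert got == pytest.approx(true_len, rel=0.05)


class TestRMOutParsing:
    RM_TEXT = """\
   SW   perc perc perc  query      position in query    matching repeat
score   div. del. ins.  sequence   begin end (left)     repeat   class/family begin end (left) ID

  463   10.1  0.0  0.0  read1        101   700 (300)  +  SatA     Satellite      1   600 (0)    1
  321   12.0  0.5  0.0  read1        704  1200 (0)   C  SatA     Satellite      1   500 (0)    2
  100    5.0  0.0  0.0  read2          1   180 (20)  +  SatB     Satellite      1   180 (0)    3
"""

    def test_coordinates_converted(self):
        hits = parse_rm_out(self.RM_TEXT)
        assert hits[0] == ("read1", "SatA", 100, 700)
        assert hits[1] == ("read1", "SatA", 703, 1200)
        assert len(hits) == 3

    def test_merge_on_parsed_hits(self):
        hits = parse_rm_out(self.RM_TEXT)
        arrays = merge_arrays(hits, rul={"SatA": 200, "SatB": 90})
        by_read = {(iv.read_id, iv.family_id): iv for iv in arrays}
        assert by_read[("read1", "SatA")].length == 1100
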