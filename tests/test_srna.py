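"""Read trimming, classification, perfect mapping, context annotation and
normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirsil.srna import (CountTable, GenomeIndex, annotate_context,
                         annotate_table, classify_read, normalize, trim_adapter)
from pirsil.util import revcomp
from .oracles import naive_map

ADAPTER = "AGATCGGAAGAGC"
BASES = np.array(list("ACGT"))


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        insert = "TACGGATTACGGATTACGGAT"     # 21 nt
        assert trim_adapter(insert + ADAPTER, ADAPTER) == insert

    def test_partial_adapter_suffix_removed(self):
        insert = "TACGGATTACGGATTACGGAT"
        assert trim_adapter(insert + ADAPTER[:5], ADAPTER) == insert

    def test_no_adapter_unchanged(self):
        read = "TACGGATTACGGATTACGGAT"
        assert trim_adapter(read, ADAPTER) == read

    def test_short_insert_discarded(self):
        assert trim_adapter("ACGTACGTACGT" + ADAPTER, ADAPTER, min_length=18) is None

    def test_overlap_below_minimum_kept(self):
        read = "TACGGATTACGGATTACGGA" + ADAPTER[:2]
        assert trim_adapter(read, ADAPTER, min_overlap=3) == read


@pytest.mark.parametrize("seq,expected", [
    ("T" + "A" * 20, "p21U"),
    ("G" + "A" * 21, "s22G"),
    ("G" + "A" * 25, "s26G"),
    ("G" + "A" * 20, "other"),     # 21 nt but 5' G
    ("T" + "A" * 21, "other"),     # 22 nt but 5' T
    ("A" * 24, "other"),
])
def test_classify_read(seq, expected):
    assert classify_read(seq) == expected


def test_classify_idempotent_after_retrim():
    read = "TACGGATTACGGATTACGGAT" + ADAPTER
    once = trim_adapter(read, ADAPTER)
    twice = trim_adapter(once, ADAPTER)
    assert once == twice
    assert classify_read(once) == classify_read(twice)


@pytest.fixture(scope="module")
def genome():
    r = np.random.default_rng(5)
    return {"A": "".join(r.choice(BASES, 4000)),
            "B": "".join(r.choice(BASES, 2500))}


@pytest.fixture(scope="module")
def gindex(genome):
    return GenomeIndex(genome)


@pytest.fixture(scope="module")
def features():
    return pd.DataFrame([
        ("r1", "rRNA", "A", 100, 220, "+"),
        ("c1", "CDS", "A", 150, 450, "+"),
        ("c2", "CDS", "A", 600, 900, "-"),
        ("m1", "miRNA", "A", 1000, 1022, "+"),
    ], columns=["id", "type", "chrom", "start", "end", "strand"])


class TestPerfectMapping:
    def test_plus_strand_hit(self, genome, gindex):
        read = genome["A"][100:121]
        hits = [h for h in gindex.map_perfect(read)]
        assert ("A", 100, "+") in [(h.chrom, h.start, h.strand) for h in hits]

    def test_minus_strand_hit_leftmost_coordinate(self, genome, gindex):
        read = revcomp(genome["B"][500:522])
        hits = [(h.chrom, h.start, h.strand) for h in gindex.map_perfect(read)]
        assert ("B", 500, "-") in hits

    def test_substitution_kills_hit(self, genome, gindex):
        read = list(genome["A"][200:221])
        read[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[10]]
        assert gindex.map_perfect("".join(read)) == []

    def test_n_never_matches(self, gindex, genome):
        read = genome["A"][300:320] + "N"
        assert gindex.map_perfect(read) == []

    def test_agrees_with_naive_scan(self, genome, gindex):
        rng = np.random.default_rng(11)
        for _ in range(60):
            chrom = "A" if rng.random() < 0.5 else "B"
            pos = int(rng.integers(0, len(genome[chrom]) - 25))
            length = int(rng.integers(15, 26))
            read = genome[chrom][pos:pos + length]
            if rng.random() < 0.5:
                read = revcomp(read)
            if rng.random() < 0.3:      # sometimes mutate
                k = int(rng.integers(length))
                read = read[:k] + "ACGT"[int(rng.integers(4))] + read[k + 1:]
            got = sorted((h.chrom, h.start, h.strand)
                         for h in gindex.map_perfect(read))
            assert got == naive_map(read, genome)

    def test_short_read_fallback(self, genome, gindex):
        read = genome["A"][50:58]       # below the anchor size
        got = sorted((h.chrom, h.start, h.strand) for h in gindex.map_perfect(read))
        assert got == naive_map(read, genome)


class TestContext:
    def test_rrna_beats_cds(self, features):
        assert annotate_context("A", 160, 181, "+", features) == "rRNA"

    def test_antisense_cds(self, features):
        assert annotate_context("A", 300, 322, "-", features) == "CDS-antisense"
        assert annotate_context("A", 700, 722, "-", features) == "CDS-sense"

    def test_intergenic(self, features):
        assert annotate_context("A", 2000, 2021, "+", features) == "intergenic"

    def test_vectorized_matches_scalar(self, features):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 2500, size=120)
        hits = pd.DataFrame({
            "chrom": "A",
            "start": starts,
            "end": starts + 21,
            "strand": rng.choice(["+", "-"], size=120),
        })
        vec = annotate_table(hits, features)
        for i, row in hits.iterrows():
            assert vec[i] == annotate_context(row.chrom, row.start, row.end,
                                              row.strand, features)


class TestNormalize:
    def _table(self, counts, totals):
        return CountTable(counts=pd.DataFrame(counts),
                          total_mapped=totals, total_mirna=totals,
                          total_22g=totals)

    def test_ppm_arithmetic(self):
        t = self._table({"lib": [1]}, {"lib": 10_000_000})
        out = normalize(t, "ppm_total")
        assert out.counts.lib.iloc[0] == pytest.approx(0.1)

    def test_ppm_sums_to_million(self):
        t = self._table({"lib": [10, 30, 60]}, {"lib": 100})
        out = normalize(t, "ppm_total")
        assert out.counts.lib.sum() == pytest.approx(1e6, abs=1e-6)

    def test_scale_invariance(self):
        t1 = self._table({"lib": [5, 10]}, {"lib": 1000})
        t2 = self._table({"lib": [10, 20]}, {"lib": 2000})
        a = normalize(t1, "per_class_22G").counts
        b = normalize(t2, "per_class_22G").counts
        pd.testing.assert_frame_equal(a, b)

    def test_zero_denominator_names_library(self):
        t = self._table({"libX": [1]}, {"libX": 0})
        with pytest.raises(ValueError, match="libX"):
            normalize(t, "ppm_total")
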