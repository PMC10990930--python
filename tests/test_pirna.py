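"""piRNA locus calling: recovery of planted loci, threshold semantics,
distribution and quantification."""

import numpy as np
import pandas as pd
import pytest

from pirsil.pipeline import Library
from pirsil.pirna import call_pirna_loci, chromosome_distribution, quantify_pirnas


@pytest.fixture(scope="module")
def called(licensed_libs, repressed_libs, bundle):
    libs = licensed_libs + repressed_libs
    return call_pirna_loci(libs, bundle.sequences, min_mean_ppm=0.1)


def _fake_library(rows, total_mapped, name="lib", genome_id="g", mirna=1000):
    df = pd.DataFrame(rows, columns=["seq", "count", "length", "read_class",
                                     "nhits", "chrom", "start", "end",
                                     "strand", "context"])
    return Library(name=name, reads=df, genome_id=genome_id,
                   total_reads=total_mapped, total_mapped=total_mapped,
                   total_mirna=mirna, total_22g=1, total_26g=0)


def test_planted_loci_recovered(called, bundle):
    truth = set(zip(bundle.pirna_truth.chrom, bundle.pirna_truth.start,
                    bundle.pirna_truth.strand))
    got = set(zip(called.chrom, called.start, called.strand))
    # a binder planted as a PERFECT complement gives its piRNA reads a
    # second exact genomic match (antisense in the 3'UTR), so that locus is
    # excluded as a multimapper; every other planted locus must be called
    perfect_binders = {
        s["pirna_id"] for s in bundle.planted_sites
        if not s["mismatch_positions"] and not s["gu_positions"] and not s["bubble"]
    }
    excluded = {(r.chrom, r.start, r.strand)
                for r in bundle.pirna_truth.itertuples()
                if r.locus_id in perfect_binders}
    missing = truth - got
    assert missing <= excluded


def test_locus_invariants(called):
    assert (called.sequence.str[0] == "U").all()
    assert ((called.end - called.start) == 21).all()
    assert (called.mean_ppm >= 0.1).all()
    assert called.sort_values(["chrom", "start", "strand"]).equals(called)


def test_retained_set_shrinks_with_threshold(licensed_libs, bundle):
    sets = []
    for thr in (0.1, 50.0, 5000.0):
        loci = call_pirna_loci(licensed_libs, bundle.sequences, min_mean_ppm=thr)
        sets.append(set(loci.locus_id if False else
                        zip(loci.chrom, loci.start, loci.strand)))
    assert sets[2] <= sets[1] <= sets[0]
    assert len(sets[2]) < len(sets[0])


def test_threshold_is_inclusive():
    row = ("T" + "A" * 20, 1, 21, "p21U", 1, "I", 100, 121, "+", "intergenic")
    lib = _fake_library([row], total_mapped=10_000_000)
    loci = call_pirna_loci([lib], {"I": "x"}, min_mean_ppm=0.1)
    # one read in ten million mapped = exactly 0.1 ppm -> retained
    assert len(loci) == 1


def test_excluded_contexts_and_multimappers():
    rows = [
        ("T" + "A" * 20, 50, 21, "p21U", 1, "I", 100, 121, "+", "CDS-sense"),
        ("T" + "C" * 20, 50, 21, "p21U", 2, "I", 300, 321, "+", "intergenic"),
        ("T" + "G" * 20, 50, 21, "p21U", 1, "I", 500, 521, "+", "tRNA"),
        ("T" + "T" * 20, 50, 21, "p21U", 1, "I", 700, 721, "+", "intergenic"),
    ]
    lib = _fake_library(rows, total_mapped=1000)
    loci = call_pirna_loci([lib], {"I": "x"}, min_mean_ppm=0.1)
    assert list(loci.start) == [700]


def test_empty_library_set_rejected():
    with pytest.raises(ValueError):
        call_pirna_loci([], {}, 0.1)


def test_mixed_genomes_rejected(licensed_libs):
    other = Library(name="alien", reads=licensed_libs[0].reads,
                    genome_id="other-genome", total_mapped=1)
    with pytest.raises(ValueError, match="different genomes"):
        call_pirna_loci([licensed_libs[0], other], {}, 0.1)


def test_zero_21u_reads_zero_loci():
    row = ("G" + "A" * 21, 5, 22, "s22G", 1, "I", 100, 122, "+", "intergenic")
    lib = _fake_library([row], total_mapped=100)
    assert len(call_pirna_loci([lib], {"I": "x"}, 0.1)) == 0


class TestChromosomeDistribution:
    def test_sums_to_one(self, called):
        dist = chromosome_distribution(called)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_chromosome(self):
        loci = pd.DataFrame({"chrom": ["IV"] * 5, "start": range(5)})
        assert chromosome_distribution(loci)["IV"] == 1.0

    def test_cluster_dominates(self, licensed_libs, repressed_libs, bundle):
        # at this shallow fixture depth a 0.1 ppm cutoff cannot reject
        # single stray reads; a depth-appropriate threshold (well below the
        # weakest planted locus, well above one read) isolates true loci
        loci = call_pirna_loci(licensed_libs + repressed_libs,
                               bundle.sequences, min_mean_ppm=20.0)
        dist = chromosome_distribution(loci)
        planted = 1 - bundle.config.cluster.off_cluster_fraction
        assert dist["IV"] == pytest.approx(planted, abs=0.08)


class TestQuantify:
    def test_mirna_normalization_arithmetic(self):
        row = ("T" + "A" * 20, 10, 21, "p21U", 1, "I", 100, 121, "+", "intergenic")
        lib = _fake_library([row], total_mapped=10**6, mirna=10**5)
        loci = call_pirna_loci([lib], {"I": "x"}, 0.0)
        table = quantify_pirnas(loci, lib)
        from pirsil.srna import normalize

        out = normalize(table, "per_miRNA")
        assert out.counts.iloc[0, 0] == pytest.approx(100.0)

    def test_zero_mirna_rejected(self, called, licensed_libs):
        lib = licensed_libs[0]
        broken = Library(name=lib.name, reads=lib.reads, genome_id=lib.genome_id,
                         total_mapped=lib.total_mapped, total_mirna=0)
        with pytest.raises(ValueError, match="miRNA"):
            quantify_pirnas(called, broken)

    def test_abundance_ranks_recovered(self, called, licensed_libs, bundle):
        from scipy.stats import spearmanr

        lib = licensed_libs[0]
        table = quantify_pirnas(called, lib)
        counts = table.counts[lib.name]
        truth = bundle.pirna_truth.set_index(["chrom", "start", "strand"])
        key = pd.MultiIndex.from_frame(called[["chrom", "start", "strand"]])
        planted = truth.rel_abundance.reindex(key)
        mask = planted.notna().values
        rho = spearmanr(counts.values[mask], planted.values[mask]).statistic
        assert rho >= 0.9
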