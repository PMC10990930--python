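"""The synthetic-data generator: determinism, planted structure, read-class
purity, conservation, and the cross/ChIP/qPCR simulators."""

import numpy as np
import pandas as pd
import pytest

from pirsil.simulate import (ChipSpec, CrossSpec, PlantedSiteSpec, QpcrSpec,
                             SimulationConfig, build_genome, plant_target_sites,
                             simulate_chip, simulate_cross, simulate_qpcr,
                             simulate_srna_library)
from pirsil.simulate.config import PiRNAClusterSpec
from pirsil.silencing import chip_input_ratio
from pirsil.stats import ddct_fold_change
from pirsil.util import revcomp
from pirsil.workflows import small_config


class TestConfigValidation:
    def test_cluster_interval_must_fit(self):
        with pytest.raises(ValueError, match="cluster interval"):
            SimulationConfig(cluster=PiRNAClusterSpec(interval=(0, 10**9)))

    def test_penetrance_bounds(self):
        bad = CrossSpec(penetrance={"maternal": {"non/non": 1.5}})
        with pytest.raises(ValueError, match="[Pp]enetrance"):
            SimulationConfig(cross=bad)

    def test_fold_must_be_at_least_one(self):
        from pirsil.simulate.config import RepressedSpec

        with pytest.raises(ValueError, match="fold"):
            SimulationConfig(repressed=RepressedSpec(fold_22g=0.5))


class TestGenome:
    def test_determinism(self):
        b1 = build_genome(small_config(), seed=3)
        b2 = build_genome(small_config(), seed=3)
        assert b1.sequences == b2.sequences
        pd.testing.assert_frame_equal(b1.pirna_truth, b2.pirna_truth)

    def test_off_cluster_fraction_zero(self):
        cfg = small_config()
        cfg.cluster.off_cluster_fraction = 0.0
        b = build_genome(cfg, seed=1)
        assert (b.pirna_truth.chrom == cfg.cluster.chrom).all()

    def test_planted_cluster_fraction(self, bundle):
        frac = (bundle.pirna_truth.chrom == "IV").mean()
        planted = 1 - bundle.config.cluster.off_cluster_fraction
        n = len(bundle.pirna_truth)
        assert abs(frac - planted) <= 3.5 * np.sqrt(planted * (1 - planted) / n) + 2 / n

    def test_loci_are_21bp_with_5prime_t(self, bundle):
        for r in bundle.pirna_truth.itertuples():
            g = bundle.sequences[r.chrom][r.start:r.end]
            on_strand = g if r.strand == "+" else revcomp(g)
            assert len(on_strand) == 21
            assert on_strand[0] == "T"
            assert on_strand == r.sequence

    def test_features_inside_chromosomes(self, bundle):
        lens = bundle.config.chromosomes
        for r in bundle.features.itertuples():
            assert 0 <= r.start < r.end <= lens[r.chrom]

    def test_linked_pair_gap(self, bundle):
        t = bundle.pirna_truth
        a, b = t.iloc[0], t.iloc[1]
        assert a.chrom == b.chrom == bundle.config.cluster.chrom
        assert b.start - a.end == bundle.config.cluster.linked_pair_gap


class TestPlantSites:
    def test_perfect_site_is_exact_reverse_complement(self, bundle):
        site = bundle.planted_sites[0]
        pirna = bundle.pirna_truth.set_index("locus_id").loc[
            site["pirna_id"], "sequence"]
        utr = bundle.features[bundle.features.id == "toxin-1_utr3"].iloc[0]
        genomic = bundle.sequences[utr.chrom][
            site["genome_start"]:site["genome_start"] + site["site_length"]]
        assert genomic == revcomp(pirna)

    def test_designed_mismatches_hamming(self):
        cfg = small_config()
        b = build_genome(cfg, seed=9)
        b = plant_target_sites(b, [PlantedSiteSpec(
            pirna_id="tru21ur-0001", utr_offset=10, mismatches_outside_seed=2)],
            seed=9)
        site = b.planted_sites[0]
        pirna = b.pirna_truth.set_index("locus_id").loc[site["pirna_id"], "sequence"]
        perfect = revcomp(pirna)
        planted = site["site_sequence"]
        diffs = [i for i, (x, y) in enumerate(zip(perfect, planted)) if x != y]
        assert len(diffs) == 2
        # all deviations map to piRNA positions 9-21 (outside the seed)
        positions = [21 - i for i in diffs]
        assert all(9 <= p <= 21 for p in positions)

    def test_overlapping_sites_rejected(self):
        b = build_genome(small_config(), seed=9)
        with pytest.raises(ValueError, match="overlap"):
            plant_target_sites(b, [
                PlantedSiteSpec(pirna_id="tru21ur-0001", utr_offset=10),
                PlantedSiteSpec(pirna_id="tru21ur-0002", utr_offset=20),
            ])

    def test_gu_position_realized(self, bundle):
        site = next(s for s in bundle.planted_sites if s["gu_positions"])
        pirna = bundle.pirna_truth.set_index("locus_id").loc[
            site["pirna_id"], "sequence"]
        p = site["gu_positions"][0]
        site_base = site["site_sequence"][21 - p]
        assert (pirna[p - 1], site_base) in {("G", "T"), ("T", "G")}


class TestLibrarySimulation:
    def test_conservation(self, bundle):
        sim = simulate_srna_library(bundle, "licensed", depth=50_000, seed=4)
        assert sim.total == 50_000
        assert sum(sim.truth["class_counts"].values()) == 50_000

    def test_determinism(self, bundle):
        a = simulate_srna_library(bundle, "repressed", depth=20_000, seed=5)
        b = simulate_srna_library(bundle, "repressed", depth=20_000, seed=5)
        pd.testing.assert_frame_equal(a.read_counts, b.read_counts)

    def test_class_purity_of_planted_reads(self, bundle):
        sim = simulate_srna_library(bundle, "repressed", depth=50_000, seed=6)
        truth21 = sim.truth["locus_counts"]
        seqs = bundle.pirna_truth.set_index("locus_id").sequence
        for locus_id, n in truth21[truth21 > 0].items():
            s = seqs[locus_id]
            assert len(s) == 21 and s[0] == "T"
        for pos, n in sim.truth["target22_positions"].items():
            if n > 0:
                w = bundle.transcript_sequence[pos:pos + 22]
                assert revcomp(w)[0] == "G"

    def test_fold_one_and_no_26g_degenerate(self):
        cfg = small_config()
        cfg.repressed.fold_22g = 1.0
        cfg.repressed.w_26g = 0.0
        b = build_genome(cfg, seed=2)
        lic = simulate_srna_library(b, "licensed", depth=100_000, seed=3)
        rep = simulate_srna_library(b, "repressed", depth=100_000, seed=3)
        # identical expected composition and identical seed -> identical draws
        pd.testing.assert_frame_equal(lic.read_counts, rep.read_counts)

    def test_five_prime_bias_in_truth(self, bundle):
        sim = simulate_srna_library(bundle, "repressed", depth=100_000, seed=8)
        pos = sim.truth["target22_positions"]
        half = bundle.target_transcript.length // 2
        assert pos[pos.index < half].sum() > pos[pos.index >= half].sum()

    def test_depth_must_be_positive(self, bundle):
        with pytest.raises(ValueError):
            simulate_srna_library(bundle, "licensed", depth=0, seed=1)


class TestCross:
    def test_full_penetrance_non_carriers(self):
        spec = CrossSpec(n_f2=500)
        out = simulate_cross(spec, "maternal", seed=1)
        nn = out[out.genotype == "non/non"].iloc[0]
        assert nn.n_delayed == nn.n
        carriers = out[out.genotype != "non/non"]
        assert carriers.n_delayed.sum() == 0

    def test_zero_penetrance(self):
        spec = CrossSpec(n_f2=300, penetrance={
            "maternal": {g: 0.0 for g in
                         ("carrier/carrier", "carrier/non", "non/non")}})
        out = simulate_cross(spec, "maternal", seed=2)
        assert out.n_delayed.sum() == 0

    def test_mendelian_ratios(self):
        spec = CrossSpec(n_f2=10_000)
        out = simulate_cross(spec, "paternal", seed=3)
        fracs = out.set_index("genotype").n / 10_000
        for g, expect in (("carrier/carrier", 0.25), ("carrier/non", 0.5),
                          ("non/non", 0.25)):
            se = np.sqrt(expect * (1 - expect) / 10_000)
            assert abs(fracs[g] - expect) <= 3 * se


class TestChip:
    def test_enrichment_one_flat_ratio(self):
        spec = ChipSpec(enriched_intervals=((100, 200),), enrichment=1.0,
                        depth=500_000)
        chip, inp = simulate_chip(spec, length=1000, seed=4)
        ratio = chip_input_ratio(chip, inp)
        assert ratio.values.mean() == pytest.approx(1.0, abs=0.02)

    def test_library_scale_does_not_shift_ratio(self):
        spec = ChipSpec()
        lo, hi = spec.enriched_intervals[0]
        means = []
        for scale in (1.0, 10.0):
            chip, inp = simulate_chip(spec, length=spec.reference_length,
                                      seed=5, chip_scale=scale)
            ratio = chip_input_ratio(chip, inp)
            means.append(ratio.values[lo:hi].mean())
        # a 10x deeper ChIP library leaves the normalized ratio unchanged
        assert means[1] == pytest.approx(means[0], rel=0.05)
        assert means[0] > 4  # the planted 8x enrichment clearly shows


class TestQpcr:
    def test_exact_recovery_without_noise(self):
        for fold in (0.152, 0.202):
            spec = QpcrSpec(fold=fold, efficiency=1.0, noise_sd=0.0, replicates=3)
            ct = simulate_qpcr(spec, seed=1)
            res = ddct_fold_change(
                ct[(ct.condition == "case") & (ct.channel == "target")].ct,
                ct[(ct.condition == "case") & (ct.channel == "housekeeping")].ct,
                ct[(ct.condition == "control") & (ct.channel == "target")].ct,
                ct[(ct.condition == "control") & (ct.channel == "housekeeping")].ct,
            )
            assert res.fold == pytest.approx(fold, abs=1e-12)

    def test_fold_one_no_noise_equal_ct(self):
        spec = QpcrSpec(fold=1.0, efficiency=1.0, noise_sd=0.0, replicates=2)
        ct = simulate_qpcr(spec, seed=1)
        tgt = ct[ct.channel == "target"].groupby("condition").ct.mean()
        assert tgt["case"] == pytest.approx(tgt["control"])

    def test_noisy_recovery_within_error(self):
        spec = QpcrSpec(fold=0.152, efficiency=1.0, noise_sd=0.2, replicates=4)
        folds = []
        for s in range(12):
            ct = simulate_qpcr(spec, seed=s)
            res = ddct_fold_change(
                ct[(ct.condition == "case") & (ct.channel == "target")].ct,
                ct[(ct.condition == "case") & (ct.channel == "housekeeping")].ct,
                ct[(ct.condition == "control") & (ct.channel == "target")].ct,
                ct[(ct.condition == "control") & (ct.channel == "housekeeping")].ct,
            )
            folds.append(res.fold)
        assert np.median(folds) == pytest.approx(0.152, rel=0.25)
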