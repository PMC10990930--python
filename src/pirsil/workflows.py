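"""End-to-end study workflows.

Each function runs one complete analysis on synthetic data generated under
the study conditions — genome construction, library simulation, processing,
and the downstream estimate — or evaluates the cross statistics on the
published count tables. The numbered scripts under ``analysis/`` and the
acceptance machinery are thin wrappers over these functions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .pipeline import Library, process_library
from .pirna import call_pirna_loci, chromosome_distribution
from .silencing import antisense_coverage, chip_input_ratio, class_abundance, fold_change_test
from .simulate import (PlantedSiteSpec, SimulationConfig, build_genome,
                       plant_target_sites, simulate_chip, simulate_srna_library)
from .simulate.config import PiRNAClusterSpec
from .srna import GenomeIndex
from .stats import counts_from_percent, fisher_exact_two_sided, penetrance
from .targets import continuity_candidates, energy_candidates, linkage_pairs
from .util import dna_to_rna

# ---------------------------------------------------------------------------
# published cross outcomes, reconstructed from printed (percent delayed, n)
# pairs; these tables are inputs to the statistics layer

PUBLISHED_CROSSES = {
    # label: (percent delayed, n) among the scored class
    "TA_maternal": (100.0, 34),
    "TA_paternal": (9.4, 53),
    "no_paternal": (100.0, 34),
    "gen3_after_paternal": (3.0, 34),     # 97% wild type
    "gen9_after_paternal": (77.8, 27),    # 22.2% wild type
    "prg-1.1_paternal": (6.25, 16),
    "prg-1.2_paternal": (69.2, 78),
    "fs_allele_maternal": (100.0, 31),
    "fs_allele_paternal": (95.8, 24),
    "del_allele_maternal": (100.0, 18),
    "del_allele_paternal": (0.0, 25),
    "rna_injected": (47.6, 128),
    "control_injected": (9.6, 62),
}

CROSS_COMPARISONS = [
    # (name, group a, group b)
    ("maternal_vs_paternal", "TA_maternal", "TA_paternal"),
    ("no_paternal_vs_gen3", "no_paternal", "gen3_after_paternal"),
    ("no_paternal_vs_gen9", "no_paternal", "gen9_after_paternal"),
    ("wt_vs_prg-1.1", "TA_paternal", "prg-1.1_paternal"),
    ("wt_vs_prg-1.2", "TA_paternal", "prg-1.2_paternal"),
    ("fs_maternal_vs_paternal", "fs_allele_maternal", "fs_allele_paternal"),
    ("del_maternal_vs_paternal", "del_allele_maternal", "del_allele_paternal"),
    ("rna_vs_control_injection", "rna_injected", "control_injected"),
]


def cross_statistics() -> pd.DataFrame:
    """Penetrance and two-sided Fisher p for every published comparison."""
    groups = {k: counts_from_percent(p, n) for k, (p, n) in PUBLISHED_CROSSES.items()}
    rows = []
    for name, a, b in CROSS_COMPARISONS:
        ga, gb = groups[a], groups[b]
        res = fisher_exact_two_sided(ga.n_delayed, ga.n_wildtype,
                                     gb.n_delayed, gb.n_wildtype)
        rows.append({
            "comparison": name,
            "a": a, "b": b,
            "penetrance_a": penetrance(ga), "penetrance_b": penetrance(gb),
            "table": f"[[{ga.n_delayed},{ga.n_wildtype}],[{gb.n_delayed},{gb.n_wildtype}]]",
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequencing-scale workflows


def _process_replicates(bundle, index, state: str, depth: int, replicates: int,
                        seed0: int) -> list[Library]:
    libs = []
    for r in range(replicates):
        sim = simulate_srna_library(bundle, state, depth=depth,
                                    seed=(seed0 + r) % (2**31 - 1),
                                    name=f"{state}-{r + 1}")
        libs.append(process_library(sim.read_counts, index, bundle.features,
                                    name=sim.name, genome_id=bundle.genome_id,
                                    meta=sim.meta))
    return libs


def annotate_cluster_fraction(seed: int = 1, depth: int = 4_000_000,
                              replicates: int = 4):
    """Annotate piRNA loci on the default synthetic genome and measure the
    cluster-chromosome locus fraction (planted 0.969).

    The library depth is tied to the abundance threshold: with 0.1 ppm
    (inclusive) averaged over `replicates` libraries, a single stray read
    must fall below threshold, which requires depth > 1e6/(0.1 x replicates).
    """
    config = SimulationConfig()
    bundle = build_genome(config, seed=seed)
    index = GenomeIndex(bundle.sequences)
    libs = _process_replicates(bundle, index, "licensed", depth, replicates,
                               seed0=seed * 1000 + 1)
    loci = call_pirna_loci(libs, bundle.sequences, min_mean_ppm=0.1)
    dist = chromosome_distribution(loci)
    truth_keys = set(zip(bundle.pirna_truth.chrom, bundle.pirna_truth.start,
                         bundle.pirna_truth.strand))
    called_keys = set(zip(loci.chrom, loci.start, loci.strand))
    return {
        "loci": loci,
        "distribution": dist,
        "cluster_fraction": float(dist.get(config.cluster.chrom, 0.0)),
        "planted_fraction": 1 - config.cluster.off_cluster_fraction,
        "n_called": len(loci),
        "n_false": len(called_keys - truth_keys),
        "n_missed": len(truth_keys - called_keys),
        "bundle": bundle,
    }


def fold_22g_recovery(seed: int = 1, depth: int = 1_000_000, replicates: int = 4):
    """Simulate licensed vs repressed replicate libraries and estimate the
    antisense-22G fold change over the target (planted 33.7)."""
    config = SimulationConfig()
    bundle = build_genome(config, seed=seed)
    index = GenomeIndex(bundle.sequences)
    lic = _process_replicates(bundle, index, "licensed", depth, replicates,
                              seed0=seed * 1000 + 101)
    rep = _process_replicates(bundle, index, "repressed", depth, replicates,
                              seed0=seed * 1000 + 201)
    rec_l = [class_abundance(lb, bundle.target_transcript, "s22G") for lb in lic]
    rec_r = [class_abundance(lb, bundle.target_transcript, "s22G") for lb in rep]
    result = fold_change_test(rec_l, rec_r)
    cov_r = antisense_coverage(rep[0], bundle.target_transcript)
    cov_l = antisense_coverage(lic[0], bundle.target_transcript)
    rec26 = []
    for lb in rep:
        try:
            rec26.append(class_abundance(lb, bundle.target_transcript, "s26G"))
        except ValueError:
            pass
    return {
        "fold_result": result,
        "planted_fold": config.repressed.fold_22g,
        "coverage_repressed": cov_r,
        "coverage_licensed": cov_l,
        "abundances": {"licensed": rec_l, "repressed": rec_r, "repressed_26g": rec26},
        "bundle": bundle,
    }


def default_site_specs(bundle) -> list[PlantedSiteSpec]:
    """Two binding sites on the linked locus pair: one perfect, one with a
    single G:U wobble at the position nearest 12 that can form one."""
    from .simulate.genome import valid_gu_position

    seq2 = bundle.pirna_truth.set_index("locus_id").loc["tru21ur-0002", "sequence"]
    return [
        PlantedSiteSpec(pirna_id="tru21ur-0001", utr_offset=60),
        PlantedSiteSpec(pirna_id="tru21ur-0002", utr_offset=200,
                        gu_positions=(valid_gu_position(seq2),)),
    ]


def planted_binder_discovery(seed: int = 1, k_suboptimal: int = 5,
                             site_specs=None):
    """Plant two 3'UTR-binding piRNAs (a tightly linked cluster pair, 4.6 kb
    apart) among the full decoy piRNA complement, run both candidate
    procedures, and check that linkage analysis recovers the pair."""
    config = SimulationConfig()
    bundle = build_genome(config, seed=seed)
    if site_specs is None:
        site_specs = default_site_specs(bundle)
    bundle = plant_target_sites(bundle, list(site_specs), seed=seed)
    target_rna = dna_to_rna(bundle.transcript_sequence)
    pirnas = {r.locus_id: dna_to_rna(r.sequence)
              for r in bundle.pirna_truth.itertuples()}
    energy = energy_candidates(pirnas, target_rna, k=k_suboptimal)
    continuity = continuity_candidates(pirnas, target_rna)
    planted_ids = [s.pirna_id for s in site_specs]

    def rank_of(records, pid):
        for rec in records:
            if rec.pirna_id == pid:
                return rec.rank
        return None

    ranks = {
        pid: {"energy": rank_of(energy, pid), "continuity": rank_of(continuity, pid)}
        for pid in planted_ids
    }
    top_ids = {rec.pirna_id for rec in energy[:10]} | {rec.pirna_id for rec in continuity[:10]}
    cand_loci = bundle.pirna_truth[bundle.pirna_truth.locus_id.isin(top_ids)]
    pairs = linkage_pairs(cand_loci, max_distance=10_000)
    planted_pair = pairs[
        (pairs.locus_a.isin(planted_ids)) & (pairs.locus_b.isin(planted_ids))
    ]
    return {
        "energy": energy,
        "continuity": continuity,
        "ranks": ranks,
        "n_decoys": len(pirnas) - len(planted_ids),
        "linkage": pairs,
        "planted_pair_distance": (int(planted_pair.distance.iloc[0])
                                  if len(planted_pair) else None),
        "bundle": bundle,
    }


def chip_enrichment_recovery(seed: int = 1):
    """Simulate a ChIP/input pair with one planted enriched interval and
    measure the mean library-size-normalized ratio over it."""
    config = SimulationConfig()
    chip, inp = simulate_chip(config.chip, length=config.chip.reference_length,
                              seed=seed, chip_scale=1.5)
    ratio = chip_input_ratio(chip, inp, pseudocount=0.5)
    lo, hi = config.chip.enriched_intervals[0]
    inside = float(ratio.values[lo:hi].mean())
    outside = float(np.concatenate([ratio.values[:lo], ratio.values[hi:]]).mean())
    return {
        "ratio_track": ratio,
        "interval_mean": inside,
        "background_mean": outside,
        "planted_enrichment": config.chip.enrichment,
    }


# ---------------------------------------------------------------------------
# small end-to-end run used for the determinism contract


def small_config() -> SimulationConfig:
    """A scaled-down configuration for fast end-to-end runs."""
    return SimulationConfig(
        chromosomes={"I": 30_000, "II": 30_000, "III": 40_000,
                     "IV": 60_000, "V": 30_000, "X": 50_000},
        cluster=PiRNAClusterSpec(chrom="IV", interval=(5_000, 55_000),
                                 n_loci=60, off_cluster_fraction=0.05),
        n_background_genes=10,
        n_mirna=10,
    )


def run_small_pipeline(outdir: str | Path, seed: int = 1,
                       depth: int = 200_000) -> dict[str, Path]:
    """One deterministic end-to-end run at small scale, writing the three
    headline artifacts: locus BED, candidate TSV and coverage bedGraph."""
    outdir = pio.ensure_dir(outdir)
    config = small_config()
    bundle = build_genome(config, seed=seed)
    bundle = plant_target_sites(bundle, [
        PlantedSiteSpec(pirna_id="tru21ur-0001", utr_offset=30),
        PlantedSiteSpec(pirna_id="tru21ur-0002", utr_offset=150),
    ], seed=seed)
    index = GenomeIndex(bundle.sequences)
    libs = _process_replicates(bundle, index, "repressed", depth, 2,
                               seed0=seed * 100 + 1)
    loci = call_pirna_loci(libs, bundle.sequences, min_mean_ppm=0.1)

    bed = outdir / "pirna_loci.bed"
    pio.write_bed(loci.rename(columns={"locus_id": "name"}), bed)

    target_rna = dna_to_rna(bundle.transcript_sequence)
    pirnas = {r.locus_id: dna_to_rna(r.sequence)
              for r in bundle.pirna_truth.itertuples()}
    energy = energy_candidates(pirnas, target_rna, k=3)
    tsv = outdir / "energy_candidates.tsv"
    pd.DataFrame([{
        "rank": c.rank, "pirna_id": c.pirna_id, "dG": c.key,
        "target_start": c.best_hit.target_interval[0],
        "target_end": c.best_hit.target_interval[1],
        "gu_count": c.best_hit.gu_count,
        "mismatches_outside_seed": c.best_hit.mismatches_outside_seed,
        "pairing": c.best_hit.pairing_string,
    } for c in energy]).to_csv(tsv, sep="\t", index=False)

    cov = antisense_coverage(libs[0], bundle.target_transcript)
    bg = outdir / "antisense_22g_coverage.bedgraph"
    pio.write_bedgraph(bundle.target_transcript.transcript_id, cov.values, bg)
    return {"bed": bed, "tsv": tsv, "bedgraph": bg}
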