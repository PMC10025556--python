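"""Replicate-simulation benchmarks of the CIS caller and RE classifier.

These drive the calibration checks a screen analyst cares about: the
realized false-call proportion of the caller at its nominal error level,
how reliably strongly selected loci outrank background, and how well the
RE classifier recovers planted regulatory categories from clean evidence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import annotate_cis, classify_re, re_score
from .cis_discovery import CIS, calibrate_null, call_cis
from .insertion_io import deduplicate, normalize_coverage
from .simulate import (
    PlantedRE,
    default_driver_layout,
    make_gene_model,
    make_genome,
    simulate_screen,
    simulate_tracks,
)


@dataclass
class FalseCallResult:
    mean_false_call_proportion: float  # fraction of called CISs off-driver
    per_replicate: list[float]
    driver_top_rank_fraction: float  # replicates where drivers occupy the top ranks
    all_drivers_found_fraction: float
    n_replicates: int
    threshold: float


def false_call_benchmark(
    n_replicates: int = 50,
    seed: int = 0,
    genome_length: int = 10_000_000,
    n_samples: int = 30,
    transposons_per_cell: int = 200,
    n_drivers: int = 5,
    selection_strength: float = 12.0,
    driver_width: int = 5_000,
    scale: float = 5_000,
    alpha: float = 0.05,
    n_perm: int = 200,
) -> FalseCallResult:
    """Replicate screens with planted drivers on a uniform TTAA background.

    One genome and one null calibration (same background insertion count)
    are shared across replicates; each replicate simulates a fresh screen,
    runs the full dedup/normalize/call chain, and scores each called CIS as
    true (overlaps a planted driver locus) or false.  Returns the mean
    per-replicate false-call proportion plus ranking summaries.
    """
    genome = make_genome(1, [genome_length], seed=seed)
    drivers = default_driver_layout(
        genome, n_drivers=n_drivers, selection_strength=selection_strength,
        width=driver_width)
    driver_ivs = [(d.chrom, d.start, d.end) for d in drivers]
    n_nominal = n_samples * transposons_per_cell
    calib = calibrate_null(genome.ttaa_index, n_nominal, scale, n_perm, alpha,
                           seed=seed + 1)

    def overlaps_driver(c: CIS) -> bool:
        return any(ch == c.chrom and s < c.end and e > c.start
                   for ch, s, e in driver_ivs)

    props, top_ok, found_ok = [], 0, 0
    for rep in range(n_replicates):
        table, _ = simulate_screen(
            genome, n_samples=n_samples, transposons_per_cell=transposons_per_cell,
            drivers=drivers, seed=seed + 10 + rep)
        table = normalize_coverage(deduplicate(table))
        cis = call_cis(table, scale, alpha, calib)
        n_false = sum(not overlaps_driver(c) for c in cis)
        props.append(n_false / len(cis) if cis else 0.0)
        hit = set()
        for c in cis:
            for i, (ch, s, e) in enumerate(driver_ivs):
                if ch == c.chrom and s < c.end and e > c.start:
                    hit.add(i)
        found_ok += len(hit) == n_drivers
        # ranking property: no background CIS outranks any driver CIS
        flags = [overlaps_driver(c) for c in cis]  # cis already ranked
        last_true = max((i for i, f in enumerate(flags) if f), default=-1)
        top_ok += all(flags[: last_true + 1])
    return FalseCallResult(
        mean_false_call_proportion=float(np.mean(props)),
        per_replicate=props,
        driver_top_rank_fraction=top_ok / n_replicates,
        all_drivers_found_fraction=found_ok / n_replicates,
        n_replicates=n_replicates,
        threshold=calib.threshold,
    )


def re_recovery_benchmark(seed: int = 0, genome_length: int = 2_000_000,
                          n_genes: int = 20) -> float:
    """Fraction of planted RE categories recovered by the classifier from
    noise-free synthetic tracks.

    Plants intergenic enhancers in gene deserts, intronic enhancers with
    distal Hi-C targets inside silent protein-coding genes, ncRNA hits
    inside lncRNAs, and plain protein-coding hits in expressed genes.
    """
    genome = make_genome(1, [genome_length], seed=seed)
    genes = make_gene_model(genome, n_genes=n_genes, seed=seed + 1, expression=True)
    gdf = genes.genes.sort_values("start").reset_index(drop=True)
    planted: list[PlantedRE] = []
    # intergenic enhancers midway between consecutive genes
    for i in range(len(gdf) - 1):
        gap = gdf["start"][i + 1] - gdf["end"][i]
        if gap > 20_000 and len(planted) < 5:
            mid = int((gdf["end"][i] + gdf["start"][i + 1]) // 2)
            planted.append(PlantedRE("chr1", mid, mid + 3_000, "intergenic_enhancer"))
    pc_names = list(gdf[gdf["biotype"] == "protein_coding"]["name"])
    for row in gdf.itertuples():
        expr = genes.expression[row.name]
        start, end = int(row.start) + 2_000, int(row.start) + 4_000
        if row.biotype == "protein_coding" and expr == 0.0:
            target = next(n for n in pc_names if n != row.name)
            planted.append(PlantedRE("chr1", start, end,
                                     "intronic_enhancer_distal_target",
                                     target_gene=target, host_gene=row.name))
        elif row.biotype == "lncRNA":
            planted.append(PlantedRE("chr1", start, end, "ncRNA"))
        elif expr > 0.0 and len([p for p in planted if p.category == "pc_gene"]) < 3:
            planted.append(PlantedRE("chr1", start, end, "pc_gene"))
    tracks, links, seg = simulate_tracks(genome, planted, genes,
                                         noise_interval_rate=0.0, seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    ok = 0
    for re_ in planted:
        cis = CIS("chr1", re_.start, re_.end, re_.start, 1e-3, 1e-3, 10, 6, 5_000)
        ann = annotate_cis(cis, tracks, links, seg, genes)
        re_score(ann)
        n_fwd = 5 + int(rng.integers(-1, 2))
        ins = pd.DataFrame({
            "chrom": "chr1", "pos": re_.start,
            "strand": ["+"] * n_fwd + ["-"] * (10 - n_fwd),
            "sample": [f"S{i}" for i in range(10)], "reads": 10})
        cat, _ = classify_re(ann, ins, genes)
        ok += cat == re_.category
    return ok / len(planted)
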