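"""Cohort- and region-level screen statistics.

Exact contingency tests on tumor-spectrum tables, variants-per-Mb density
enrichment of (pre-pruned) GWAS variants in CIS-derived regions, gene-level
over-representation against the protein-coding gene universe, biallelic
high-coverage insertion-pair detection, developmental-stage overlap
assignment, and per-sample clonality summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ParameterError
from .intervals import merge_intervals, overlap_mask

#: GENCODE protein-coding gene count used as the enrichment universe
N_PROTEIN_CODING_GENES = 19_370

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table; rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ParameterError("contingency cells must be >= 0")
        if sum(cells) == 0:
            raise AnalysisError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class VariantSet:
    """LD-pruned variant positions with provenance of the external pruning
    (e.g. SNPclip with R^2 = 0.8, MAF = 0.01)."""

    variants: pd.DataFrame  # chrom, pos
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.variants = self.variants.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)

    @classmethod
    def from_tsv(cls, path: str, **provenance) -> "VariantSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}), provenance)


@dataclass
class EnrichmentResult:
    rate_in: float  # variants per Mb inside the regions
    rate_genome: float  # variants per Mb genome-wide
    statistic: float
    p_value: float
    region_width_total: int
    n_in: int
    n_total: int


def fisher_exact(t: ContingencyTable, alternative: str = "two_sided"):
    """Exact (hypergeometric) test on a 2x2 table; returns (odds_ratio, p)."""
    if alternative not in _ALTERNATIVES:
        raise ParameterError(f"unknown alternative {alternative!r}")
    odds, p = stats.fisher_exact(t.as_array(), alternative=_ALTERNATIVES[alternative])
    return float(odds), float(p)


def chisq_counts(observed, expected):
    """Pearson chi-square of observed counts against expected counts or
    proportions (proportions are scaled to the observed total)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ParameterError("observed/expected dimension mismatch")
    if np.isclose(expected.sum(), 1.0) and not np.isclose(observed.sum(), 1.0):
        expected = expected * observed.sum()
    if np.any(expected <= 0):
        raise ParameterError("expected counts must be > 0")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    dof = observed.size - 1
    p = float(stats.chi2.sf(statistic, dof))
    return statistic, p


def density_enrichment(variants: VariantSet, regions, genome_size: int) -> EnrichmentResult:
    """Variants-per-Mb inside merged regions vs the genome-wide rate, with a
    1-df chi-square on observed-inside vs its genome-proportional expectation.

    ``regions`` is an iterable of (chrom, start, end); overlapping regions
    are merged before width summation so shared bp are counted once.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    width = sum(e - s for ivs in merged.values() for s, e in ivs)
    if width <= 0:
        raise AnalysisError("total region width is zero")
    if genome_size <= 0:
        raise ParameterError("genome_size must be > 0")
    n_total = len(variants)
    n_in = 0
    for row in variants.variants.itertuples():
        ivs = merged.get(row.chrom, [])
        if any(s <= row.pos < e for s, e in ivs):
            n_in += 1
    expected_in = n_total * width / genome_size
    if width == genome_size:
        statistic, p = 0.0, 1.0
    else:
        statistic, p = chisq_counts(
            [n_in, n_total - n_in], [expected_in, n_total - expected_in])
    return EnrichmentResult(
        rate_in=n_in / width * 1e6,
        rate_genome=n_total / genome_size * 1e6,
        statistic=statistic, p_value=p,
        region_width_total=width, n_in=n_in, n_total=n_total,
    )


def gene_overrepresentation(hits_in_targets: int, n_targets: int, hits_genome: int,
                            n_genes: int = N_PROTEIN_CODING_GENES):
    """2x2 Pearson chi-square of hit vs non-hit genes among target vs
    non-target genes (universe defaults to the GENCODE protein-coding count)."""
    if n_targets > n_genes or hits_in_targets > hits_genome:
        raise ParameterError("targets must be a subset of the gene universe")
    if hits_in_targets > n_targets:
        raise ParameterError("hits_in_targets cannot exceed n_targets")
    table = np.array([
        [hits_in_targets, n_targets - hits_in_targets],
        [hits_genome - hits_in_targets, (n_genes - n_targets) - (hits_genome - hits_in_targets)],
    ])
    statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


def high_coverage_pairs(
    table, min_reads: int = 1000, max_dist: int = 50_000,
    subset: str = "all", genes=None,
) -> pd.DataFrame:
    """Within-sample unordered pairs of high-coverage insertions on the same
    chromosome within ``max_dist`` bp (candidate biallelic or local-hop pairs).

    ``subset='intergenic'`` restricts to insertions outside protein-coding/IG
    genes (requires ``genes``).
    """
    df = table.data
    qual = df[df["reads"] >= min_reads]
    if subset == "intergenic":
        if genes is None:
            raise ParameterError("subset='intergenic' requires a gene model")
        keep = [not genes.overlaps_genic(r.chrom, r.pos, r.pos + 1)
                for r in qual.itertuples()]
        qual = qual[np.asarray(keep, dtype=bool)]
    elif subset != "all":
        raise ParameterError(f"unknown subset {subset!r}")
    rows = []
    for (sample, chrom), sub in qual.groupby(["sample", "chrom"]):
        recs = sorted(sub.itertuples(), key=lambda r: r.pos)
        for r1, r2 in combinations(recs, 2):
            dist = abs(r2.pos - r1.pos)
            if dist <= max_dist:
                rows.append({
                    "sample": sample, "chrom": chrom,
                    "pos1": r1.pos, "pos2": r2.pos, "distance": dist,
                    "reads1": r1.reads, "reads2": r2.reads,
                })
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos1", "pos2",
                                       "distance", "reads1", "reads2"])


def stage_overlap_assignment(
    cis_list, stage_tracks: dict, grouping: dict[str, str] | None = None,
    mode: str = "fractional", priority: list[str] | None = None,
) -> dict[str, float]:
    """Assign each CIS to developmental-stage groups by peak overlap.

    ``mode='fractional'`` splits a multi-overlapping CIS equally across its
    groups; ``mode='priority'`` assigns it to the first overlapping group in
    ``priority`` order.  CISs overlapping no stage track fall into
    ``unassigned``.  Returned fractions sum to 1.
    """
    if mode not in ("fractional", "priority"):
        raise ParameterError(f"unknown mode {mode!r}")
    grouping = grouping or {name: name for name in stage_tracks}
    groups = sorted(set(grouping.values()))
    weights = {g: 0.0 for g in groups}
    weights["unassigned"] = 0.0
    for cis in cis_list:
        hit_groups = []
        for name, track in stage_tracks.items():
            sub = track.on_chrom(cis.chrom)
            if overlap_mask(sub["start"].to_numpy(), sub["end"].to_numpy(),
                            cis.start, cis.end).any():
                g = grouping[name]
                if g not in hit_groups:
                    hit_groups.append(g)
        if not hit_groups:
            weights["unassigned"] += 1.0
        elif mode == "fractional":
            for g in hit_groups:
                weights[g] += 1.0 / len(hit_groups)
        else:
            order = priority or groups
            chosen = next((g for g in order if g in hit_groups), hit_groups[0])
            weights[chosen] += 1.0
    total = sum(weights.values())
    if total == 0:
        raise AnalysisError("stage_overlap_assignment of an empty CIS list")
    return {g: w / total for g, w in weights.items()}


def clonality_metrics(table, gene_sets: dict[str, list[tuple[str, int, int]]]) -> pd.DataFrame:
    """Per-sample clonality summary: unique insertion count and, per named
    interval set, the sum of normalized coverages of contained insertions."""
    df = table.data
    if "norm_coverage" not in df.columns:
        raise AnalysisError("clonality_metrics requires a normalized table")
    rows = []
    for sample, sub in df.groupby("sample"):
        row = {"sample": sample, "n_insertions": len(sub)}
        for name, intervals in gene_sets.items():
            total = 0.0
            for chrom, start, end in intervals:
                inside = sub[(sub["chrom"] == chrom) & (sub["pos"] >= start)
                             & (sub["pos"] < end)]
                total += float(inside["norm_coverage"].sum())
            row[f"coverage_sum.{name}"] = total
        rows.append(row)
    return pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)
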