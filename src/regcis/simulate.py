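"""Synthetic genomes, screens, regulatory tracks and variant sets.

The simulator produces the same file dialects the pipeline consumes, with
full ground truth, so every stage — CIS calling, annotation, background
matching, enrichment — is testable offline.  It emulates the salient
features of an in vivo PiggyBac screen:

* TTAA-constrained integration (the transposon only lands on TTAA sites),
  optionally reweighted toward "open chromatin" intervals;
* local hopping: a fraction of insertions lands near the donor concatemer
  with Laplace-decaying displacement;
* clonal selection: insertions in planted driver loci amplify their clone,
  inflating both their read coverage and their cross-sample recurrence;
* heavy-tailed read coverage in [2, 10000] from a geometric
  branching approximation of clone sizes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import TTAAIndex, build_ttaa_index
from .errors import AnalysisError, ParameterError
from .insertion_io import COLUMNS, DonorLocus, InsertionTable

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_T, _A, _C = ord("T"), ord("A"), ord("C")


@dataclass
class SyntheticGenome:
    """Random genome with controllable TTAA site density."""

    names: list[str]
    lengths: dict[str, int]
    sequences: dict[str, str]
    ttaa_index: TTAAIndex

    def genome_size(self) -> int:
        return sum(self.lengths.values())

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass
class DriverSpec:
    """A planted selected locus."""

    chrom: str
    start: int
    end: int
    selection_strength: float = 10.0  # relative clonal growth multiplier
    mode: str = "activating_oriented"  # {activating_oriented, inactivating, regulatory}
    orientation_bias: float = 0.5  # fraction forward (activating mode)
    hit_probability: float = 0.9  # per-sample chance of acquiring an insertion

    def __post_init__(self):
        if self.selection_strength < 1:
            raise ParameterError("selection_strength must be >= 1")
        if not 0 <= self.orientation_bias <= 1:
            raise ParameterError("orientation_bias must be in [0, 1]")
        if self.mode not in ("activating_oriented", "inactivating", "regulatory"):
            raise ParameterError(f"unknown driver mode {self.mode!r}")


@dataclass
class PlantedRE:
    """A planted regulatory element with its ground-truth category."""

    chrom: str
    start: int
    end: int
    category: str
    target_gene: str | None = None
    host_gene: str | None = None


@dataclass
class SimTruth:
    """Ground truth of a simulated screen."""

    drivers: list[DriverSpec] = field(default_factory=list)
    planted_res: list[PlantedRE] = field(default_factory=list)
    provenance: pd.DataFrame | None = None  # one label per insertion row
    clone_sizes: pd.Series | None = None

    def to_json(self, path: str) -> None:
        payload = {
            "drivers": [vars(d) for d in self.drivers],
            "planted_res": [vars(r) for r in self.planted_res],
            "labels": (self.provenance["label"].tolist()
                       if self.provenance is not None else []),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _remove_ttaa(seq: np.ndarray) -> None:
    """Destroy every TTAA occurrence in place (last A -> C; C never appears
    in the motif, so no pass can create a new occurrence)."""
    while True:
        hits = np.flatnonzero(
            (seq[:-3] == _T) & (seq[1:-2] == _T) & (seq[2:-1] == _A) & (seq[3:] == _A))
        if hits.size == 0:
            return
        seq[hits + 3] = _C


def make_genome(
    n_chrom: int = 1,
    lengths=(10_000_000,),
    ttaa_density: float = 1 / 300,
    seed: int = 0,
) -> SyntheticGenome:
    """Random genome whose TTAA sites sit at ~``ttaa_density`` sites/bp.

    The backbone sequence is scrubbed of incidental TTAA occurrences and
    motifs are planted at randomly chosen, >= 4 bp-spaced positions, so the
    realized density tracks the request (the default, one site per 300 bp,
    is in the range of AT-rich mammalian sequence).  Bit-reproducible for a
    given seed.
    """
    if ttaa_density > 0.25:
        raise ParameterError("ttaa_density cannot exceed 1 site per 4 bp")
    lengths = list(lengths)
    if len(lengths) == 1 and n_chrom > 1:
        lengths = lengths * n_chrom
    if len(lengths) != n_chrom:
        raise ParameterError("need one length per chromosome")
    if any(l < 100_000 for l in lengths):
        raise ParameterError("chromosome lengths must be >= 100 kb")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    sequences = {}
    for name, length in zip(names, lengths):
        seq = BASES[rng.integers(0, 4, size=length)].copy()
        _remove_ttaa(seq)
        n_sites = int(round(ttaa_density * length))
        if n_sites > 0:
            cand = np.sort(rng.integers(0, length - 4, size=int(n_sites * 1.2) + 8))
            keep = [int(cand[0])]
            for p in cand[1:]:
                if p - keep[-1] >= 4:
                    keep.append(int(p))
                if len(keep) >= n_sites:
                    break
            for p in keep:
                seq[p:p + 4] = np.frombuffer(b"TTAA", dtype=np.uint8)
        sequences[name] = seq.tobytes().decode("ascii")
    index = build_ttaa_index(sequences)
    return SyntheticGenome(names, dict(zip(names, lengths)), sequences, index)


def default_driver_layout(
    genome: SyntheticGenome,
    n_drivers: int = 5,
    selection_strength: float = 12.0,
    width: int = 5_000,
    hit_probability: float = 0.9,
) -> list[DriverSpec]:
    """Evenly spaced driver loci across the genome's chromosomes."""
    drivers = []
    per_chrom = -(-n_drivers // len(genome.names))  # ceil division
    made = 0
    for chrom in genome.names:
        length = genome.lengths[chrom]
        k = min(per_chrom, n_drivers - made)
        for i in range(k):
            center = int(length * (i + 1) / (k + 1))
            drivers.append(DriverSpec(
                chrom, center - width // 2, center + width // 2,
                selection_strength=selection_strength,
                hit_probability=hit_probability))
        made += k
        if made >= n_drivers:
            break
    return drivers


def _snap_to_ttaa(pos: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Nearest TTAA site for each position."""
    idx = np.searchsorted(sites, pos)
    idx = np.clip(idx, 1, len(sites) - 1)
    left = sites[idx - 1]
    right = sites[idx]
    return np.where(pos - left <= right - pos, left, right)


def simulate_screen(
    genome: SyntheticGenome,
    n_samples: int = 30,
    transposons_per_cell: int = 200,
    donor: DonorLocus | None = None,
    local_hop_fraction: float = 0.0,
    local_hop_scale: int = 500_000,
    chromatin_bias=None,  # (FeatureTrack, weight) or None
    drivers: list[DriverSpec] | None = None,
    coverage_p: float = 0.02,
    seed: int = 0,
) -> tuple[InsertionTable, SimTruth]:
    """Simulate a multi-sample insertion screen with known truth.

    Per sample: ``transposons_per_cell`` background insertions drawn from
    TTAA sites (a ``local_hop_fraction`` of them Laplace-displaced from the
    donor and snapped to the nearest TTAA), plus at most one insertion per
    planted driver (with the driver's ``hit_probability``).  Every
    insertion starts a clone of geometric size (parameter ``coverage_p``);
    driver clones are multiplied by ``selection_strength``.  Read counts
    are twice the clone size, clipped to [2, 10000].
    """
    drivers = drivers or []
    if not 0 <= local_hop_fraction <= 1:
        raise ParameterError("local_hop_fraction must be in [0, 1]")
    if local_hop_fraction > 0 and donor is None:
        raise ParameterError("local hopping requires a donor locus")
    sites = genome.ttaa_index
    all_counts = sites.n_sites()
    if all_counts == 0:
        raise AnalysisError("genome has no TTAA sites")
    for d in drivers:
        if d.chrom not in genome.lengths or d.end > genome.lengths[d.chrom]:
            raise ParameterError(f"driver {d.chrom}:{d.start}-{d.end} outside genome")
    chroms = genome.names
    site_arrays = [sites.positions[c] for c in chroms]
    flat_chrom = np.concatenate([
        np.full(len(a), i, dtype=np.int32) for i, a in enumerate(site_arrays)])
    flat_pos = np.concatenate(site_arrays)
    weights = np.ones(len(flat_pos))
    if chromatin_bias is not None:
        track, w = chromatin_bias
        for i, c in enumerate(chroms):
            sub = track.on_chrom(c)
            pos_c = flat_pos[flat_chrom == i]
            inside = np.zeros(len(pos_c), dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                inside |= (pos_c >= s) & (pos_c < e)
            idx = np.flatnonzero(flat_chrom == i)
            weights[idx[inside]] = w
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    n_hop = int(round(local_hop_fraction * transposons_per_cell))
    n_uniform = transposons_per_cell - n_hop
    for s in range(n_samples):
        sample = f"S{s + 1:03d}"
        # background: TTAA-constrained, optionally chromatin-biased
        pick = rng.choice(len(flat_pos), size=n_uniform, p=weights)
        for i in pick:
            rows.append((chroms[flat_chrom[i]], int(flat_pos[i]),
                         "+" if rng.random() < 0.5 else "-", sample, 0))
            labels.append("background")
        # local hopping near the donor
        if n_hop:
            donor_sites = sites.positions[donor.chrom]
            disp = rng.laplace(0.0, local_hop_scale, size=n_hop)
            pos = np.clip(donor.pos + disp, 0, genome.lengths[donor.chrom] - 4)
            snapped = _snap_to_ttaa(pos, donor_sites)
            for p in snapped:
                rows.append((donor.chrom, int(p),
                             "+" if rng.random() < 0.5 else "-", sample, 0))
                labels.append("local_hop")
        # planted drivers: clonally selected insertions
        for di, d in enumerate(drivers):
            if rng.random() >= d.hit_probability:
                continue
            locus_sites = sites.positions[d.chrom]
            inside = locus_sites[(locus_sites >= d.start) & (locus_sites < d.end)]
            p = (int(inside[rng.integers(0, len(inside))]) if len(inside)
                 else int(rng.integers(d.start, d.end)))
            fwd = rng.random() < (d.orientation_bias
                                  if d.mode == "activating_oriented" else 0.5)
            rows.append((d.chrom, p, "+" if fwd else "-", sample, 0))
            labels.append(f"driver:{di}")

    df = pd.DataFrame(rows, columns=COLUMNS)
    clone = rng.geometric(coverage_p, size=len(df)).astype(float)
    strength = np.array([
        drivers[int(l.split(":")[1])].selection_strength if l.startswith("driver") else 1.0
        for l in labels])
    reads = np.clip(np.round(2 * clone * strength), 2, 10_000).astype(np.int64)
    df["reads"] = reads
    table = InsertionTable(df)
    table.log(
        f"simulate_screen: {len(df)} insertions, {n_samples} samples, "
        f"{len(drivers)} drivers, seed {seed}")
    truth = SimTruth(
        drivers=list(drivers),
        provenance=pd.DataFrame({"label": labels}),
        clone_sizes=pd.Series(clone * strength),
    )
    return table, truth


def make_gene_model(
    genome: SyntheticGenome,
    n_genes: int = 40,
    gene_length: int = 20_000,
    pc_fraction: float = 0.7,
    min_gap: int = 30_000,
    seed: int = 0,
    expression: bool = False,
):
    """Random non-overlapping gene model; ~``pc_fraction`` protein-coding,
    the rest lncRNA.  With ``expression=True``, attaches random expression
    values (a third of genes silent at 0)."""
    from .annotation import GeneModel

    rng = np.random.default_rng(seed)
    rows = []
    g = 0
    for chrom in genome.names:
        length = genome.lengths[chrom]
        pitch = max(gene_length + min_gap, length // max(1, n_genes))
        pos = min_gap
        while pos + gene_length < length and g < n_genes:
            jitter = int(rng.integers(0, min_gap // 2 + 1))
            start = pos + jitter
            end = start + gene_length
            biotype = "protein_coding" if rng.random() < pc_fraction else "lncRNA"
            rows.append({
                "name": f"Gene{g + 1}", "chrom": chrom, "start": start, "end": end,
                "strand": "+" if rng.random() < 0.5 else "-", "biotype": biotype,
            })
            g += 1
            pos += pitch
    genes = pd.DataFrame(rows)
    expr = None
    if expression:
        vals = rng.exponential(10.0, size=len(genes))
        silent = rng.random(len(genes)) < 1 / 3
        vals[silent] = 0.0
        expr = dict(zip(genes["name"], vals))
    return GeneModel(genes, expr)


def simulate_tracks(
    genome: SyntheticGenome,
    planted_res: list[PlantedRE],
    genes,
    noise_interval_rate: float = 0.0,  # noise intervals per Mb per track
    seed: int = 0,
):
    """Emit regulatory tracks/links/states consistent with planted RE labels.

    Planted enhancer-class REs receive an H3K27ac peak, an increasing-
    accessibility interval, an active-enhancer state segment and — when a
    ``target_gene`` is named — a Hi-C link to that gene's promoter.  Noise
    intervals are placed uniformly, away from nothing in particular.
    Returns (tracks, links, segmentation).
    """
    from .annotation import FeatureTrack, LinkSet, StateSegmentation

    rng = np.random.default_rng(seed)
    for re_ in planted_res:
        if re_.chrom not in genome.lengths or re_.end > genome.lengths[re_.chrom]:
            raise ParameterError(f"planted RE outside genome: {re_}")
    peak_rows, acc_rows, se_rows, state_rows, link_rows = [], [], [], [], []
    enhancer_classes = {"intergenic_enhancer", "intronic_enhancer_distal_target"}
    promoters = genes.promoters(2000) if genes is not None else None
    for re_ in planted_res:
        if re_.category in enhancer_classes:
            peak_rows.append({"chrom": re_.chrom, "start": re_.start, "end": re_.end,
                              "label": "planted"})
            acc_rows.append({"chrom": re_.chrom, "start": re_.start, "end": re_.end,
                             "label": "increasing"})
            state_rows.append({"chrom": re_.chrom, "start": re_.start, "end": re_.end,
                               "state": "active_enhancer"})
        if re_.target_gene is not None and promoters is not None:
            prom = promoters[promoters["name"] == re_.target_gene]
            if len(prom) == 0:
                raise ParameterError(f"target gene {re_.target_gene!r} not in gene model")
            p = prom.iloc[0]
            link_rows.append({
                "chromA": re_.chrom, "startA": re_.start, "endA": re_.end,
                "chromB": p["chrom"], "startB": int(p["start"]), "endB": int(p["end"]),
                "target_gene": None,
            })
    # uniform noise intervals (never labeled as planted truth)
    for target, kind_width in ((peak_rows, 500), (acc_rows, 1000), (se_rows, 8000)):
        for chrom in genome.names:
            lam = noise_interval_rate * genome.lengths[chrom] / 1e6
            for _ in range(rng.poisson(lam)):
                s = int(rng.integers(0, genome.lengths[chrom] - kind_width))
                row = {"chrom": chrom, "start": s, "end": s + kind_width}
                row["label"] = "noise" if target is not acc_rows else (
                    "increasing" if rng.random() < 0.5 else "decreasing")
                target.append(row)
    cols = ["chrom", "start", "end", "label"]
    tracks = [
        FeatureTrack("h3k27ac", pd.DataFrame(peak_rows, columns=cols), kind="peak"),
        FeatureTrack("accessibility", pd.DataFrame(acc_rows, columns=cols),
                     kind="accessibility_change"),
        FeatureTrack("super_enhancer", pd.DataFrame(se_rows, columns=cols),
                     kind="super_enhancer"),
    ]
    links = LinkSet(pd.DataFrame(
        link_rows, columns=["chromA", "startA", "endA", "chromB", "startB", "endB",
                            "target_gene"]))
    seg = StateSegmentation(pd.DataFrame(
        state_rows, columns=["chrom", "start", "end", "state"]))
    return tracks, links, seg


def simulate_variants(
    genome: SyntheticGenome,
    regions: list[tuple[str, int, int]],
    rate_in: float,
    rate_out: float,
    seed: int = 0,
):
    """Poisson variant placement at ``rate_in`` variants/Mb inside the
    regions and ``rate_out`` outside.  Returns (VariantSet, truth labels)."""
    from .intervals import merge_intervals
    from .screen_stats import VariantSet

    if rate_in < 0 or rate_out < 0:
        raise ParameterError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    by_chrom = {c: merge_intervals(v) for c, v in by_chrom.items()}
    rows, truth = [], []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        ivs = by_chrom.get(chrom, [])
        w_in = sum(e - s for s, e in ivs)
        n_in = rng.poisson(rate_in * w_in / 1e6)
        if w_in and n_in:
            # uniform over the union of region bp
            offsets = np.sort(rng.integers(0, w_in, size=n_in))
            cum = 0
            it = iter(sorted(ivs))
            s, e = next(it)
            for off in offsets:
                while off >= cum + (e - s):
                    cum += e - s
                    s, e = next(it)
                rows.append({"chrom": chrom, "pos": int(s + off - cum)})
                truth.append("in")
        n_out = rng.poisson(rate_out * (length - w_in) / 1e6)
        made = 0
        while made < n_out:
            p = int(rng.integers(0, length))
            if not any(s <= p < e for s, e in ivs):
                rows.append({"chrom": chrom, "pos": p})
                truth.append("out")
                made += 1
    vs = VariantSet(pd.DataFrame(rows, columns=["chrom", "pos"]),
                    {"source": "simulate_variants", "seed": seed})
    return vs, truth
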