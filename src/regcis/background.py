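"""Matched control regions and footprint/bootstrap profiles.

PiggyBac integrates exclusively at TTAA tetranucleotides, so a fair
background for a CIS is a region on the same chromosome with the same
width and a comparable number of TTAA sites that does not overlap any real
CIS.  A pool of such "control CISs" is sampled per CIS; footprint profiles
(feature-overlap density in bins around region centers) computed on
bootstrap draws from the pools yield the null envelope against which the
observed CIS profile is compared.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ParameterError
from .intervals import overlap_mask

TTAA_RE = re.compile(r"(?=TTAA)", re.IGNORECASE)


@dataclass
class TTAAIndex:
    """Per-chromosome sorted 0-based start positions of the TTAA motif."""

    positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


def build_ttaa_index(genome) -> TTAAIndex:
    """Scan a genome for TTAA sites (overlap-aware, case-insensitive).

    ``genome`` is a FASTA path or a mapping chrom -> sequence string.  The
    motif is its own reverse complement, so both strands collapse to the
    same site.  Non-ACGTN characters raise a warning and never match.
    """
    if isinstance(genome, (str, bytes)):
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(genome, "fasta")}
    else:
        seqs = {k: str(v) for k, v in genome.items()}
    positions, lengths = {}, {}
    for chrom, seq in seqs.items():
        if re.search(r"[^ACGTNacgtn]", seq):
            warnings.warn(f"{chrom}: non-ACGTN characters present; they never match TTAA")
        positions[chrom] = np.array(
            [m.start() for m in TTAA_RE.finditer(seq)], dtype=np.int64)
        lengths[chrom] = len(seq)
    return TTAAIndex(positions, lengths)


@dataclass
class ControlRegion:
    """A matched background region for one CIS."""

    chrom: str
    start: int
    end: int
    relative_peak: float  # peak offset as a fraction of width, copied from the CIS
    matched_cis_id: str

    @property
    def center(self) -> int:
        return int(self.start + self.relative_peak * (self.end - self.start))


@dataclass
class ControlPool:
    """Per-CIS candidate control regions plus the matching tolerances used."""

    pools: dict[str, list[ControlRegion]] = field(default_factory=dict)
    ttaa_tolerance: float = 0.10
    seed: int = 0


def sample_control_regions(
    cis,
    index: TTAAIndex,
    exclusions: list[tuple[str, int, int]],
    pool_size: int = 100,
    ttaa_tolerance: float = 0.10,
    seed: int = 0,
    max_draws: int = 10_000,
) -> list[ControlRegion]:
    """Rejection-sample matched control regions for one CIS.

    Candidates share the CIS chromosome and exact width, carry a TTAA count
    within ``+/- ttaa_tolerance`` (relative) of the CIS count, and overlap
    no excluded (real CIS) interval.  If the cap of ``max_draws`` random
    placements yields fewer than ``pool_size`` strict matches, the deficit
    is filled with the non-overlapping candidates nearest in TTAA count,
    with a warning.
    """
    if pool_size < 1:
        raise ParameterError("pool_size must be >= 1")
    width = cis.end - cis.start
    chrom_len = index.chrom_lengths.get(cis.chrom)
    if chrom_len is None or width >= chrom_len:
        raise AnalysisError(f"CIS wider than chromosome or unknown chromosome {cis.chrom}")
    target = index.count_in(cis.chrom, cis.start, cis.end)
    tol = max(1.0, ttaa_tolerance * target)
    excl = [(s, e) for c, s, e in exclusions if c == cis.chrom]
    excl_starts = np.array([s for s, _ in excl], dtype=np.int64)
    excl_ends = np.array([e for _, e in excl], dtype=np.int64)
    rel_peak = (cis.peak_pos - cis.start) / width if hasattr(cis, "peak_pos") else 0.5
    rng = np.random.default_rng(seed)
    accepted: list[ControlRegion] = []
    fallback: list[tuple[float, int]] = []  # (|count diff|, start)
    for start in rng.integers(0, chrom_len - width, size=max_draws):
        start = int(start)
        end = start + width
        if overlap_mask(excl_starts, excl_ends, start, end).any():
            continue
        count = index.count_in(cis.chrom, start, end)
        if abs(count - target) <= tol:
            accepted.append(ControlRegion(cis.chrom, start, end, rel_peak, cis.cis_id))
            if len(accepted) >= pool_size:
                break
        else:
            fallback.append((abs(count - target), start))
    if len(accepted) < pool_size:
        warnings.warn(
            f"{cis.cis_id}: only {len(accepted)} strict TTAA-matched controls found; "
            f"filling from nearest-count candidates")
        for _, start in sorted(fallback)[: pool_size - len(accepted)]:
            accepted.append(ControlRegion(cis.chrom, start, start + width, rel_peak, cis.cis_id))
    if not accepted:
        raise AnalysisError(f"{cis.cis_id}: no valid control region found")
    return accepted


def build_control_pool(cis_list, index: TTAAIndex, pool_size: int = 100,
                       ttaa_tolerance: float = 0.10, seed: int = 0) -> ControlPool:
    """Sample a control pool for every CIS, excluding all real CIS intervals."""
    exclusions = [(c.chrom, c.start, c.end) for c in cis_list]
    pool = ControlPool(ttaa_tolerance=ttaa_tolerance, seed=seed)
    rng = np.random.default_rng(seed)
    for cis in cis_list:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pool.pools[cis.cis_id] = sample_control_regions(
            cis, index, exclusions, pool_size, ttaa_tolerance, seed=sub_seed)
    return pool


@dataclass
class FootprintProfile:
    """Feature-overlap density around region centers, with optional
    bootstrap envelope."""

    offsets: np.ndarray  # bin centers, bp relative to region center
    observed: np.ndarray  # per-bin fraction of regions overlapping the track
    envelope: np.ndarray | None = None
    n_boot: int = 0
    quantile: float = 0.975


def _bin_edges(flank: int, bins: int) -> np.ndarray:
    return np.linspace(-flank, flank, bins + 1)


def footprint_profile(centers: list[tuple[str, int]], track, flank: int = 10_000,
                      bins: int = 101) -> FootprintProfile:
    """Per bin, the fraction of regions whose bin window overlaps >= 1 track
    interval.  ``centers`` is a list of (chrom, center_bp)."""
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    if flank <= 0:
        raise ParameterError("flank must be > 0")
    edges = _bin_edges(flank, bins)
    counts = np.zeros(bins)
    by_chrom = {}
    for chrom, center in centers:
        if chrom not in by_chrom:
            sub = track.on_chrom(chrom)
            by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        starts, ends = by_chrom[chrom]
        lo = center + edges[:-1]
        hi = center + edges[1:]
        for b in range(bins):
            if overlap_mask(starts, ends, lo[b], hi[b]).any():
                counts[b] += 1
    observed = counts / max(1, len(centers))
    offsets = (edges[:-1] + edges[1:]) / 2
    return FootprintProfile(offsets=offsets, observed=observed)


def bootstrap_envelope(
    cis_list, pool: ControlPool, track, flank: int = 10_000, bins: int = 101,
    n_boot: int = 100, q: float = 0.975, seed: int = 0,
) -> FootprintProfile:
    """Observed CIS footprint plus a bootstrap envelope from matched controls.

    Each bootstrap picks one control region per CIS at random and computes
    the control footprint; the envelope is the per-bin ``q`` quantile over
    bootstraps (default 100 bootstraps, 97.5% quantile).
    """
    if n_boot < 2:
        raise ParameterError("n_boot must be >= 2")
    for cis in cis_list:
        if not pool.pools.get(cis.cis_id):
            raise AnalysisError(f"{cis.cis_id}: empty control pool")
    observed = footprint_profile(
        [(c.chrom, c.peak_pos) for c in cis_list], track, flank, bins)
    rng = np.random.default_rng(seed)
    boot = np.zeros((n_boot, bins))
    for b in range(n_boot):
        picks = []
        for cis in cis_list:
            cands = pool.pools[cis.cis_id]
            ctrl = cands[int(rng.integers(0, len(cands)))]
            picks.append((ctrl.chrom, ctrl.center))
        boot[b] = footprint_profile(picks, track, flank, bins).observed
    envelope = np.quantile(boot, q, axis=0)
    return FootprintProfile(
        offsets=observed.offsets, observed=observed.observed,
        envelope=envelope, n_boot=n_boot, quantile=q)


def signal_profile_matrix(
    regions, signal_track, flank: int = 2000, bins: int = 100,
    mode: str = "center", body_bins: int | None = None,
):
    """Per-region binned signal matrix plus the mean (meta) profile.

    ``mode='center'``: bins tile [center - flank, center + flank) of each
    (chrom, center[, strand]) region.  ``mode='scaled_gene_body'``: each
    stranded (chrom, start, end, strand) gene contributes flank bins
    upstream of the TSS, ``body_bins`` bins over the length-scaled body,
    and flank bins downstream of the TES.  Rows are strand-flipped so
    5'->3' always reads left to right.  Signal per bin is the
    coverage-weighted mean of the track's score over the bin (score column
    optional; defaults to 1 inside intervals).
    """
    rows = []
    for region in regions:
        if mode == "center":
            chrom, center = region[0], region[1]
            strand = region[2] if len(region) > 2 else "+"
            edges = center + _bin_edges(flank, bins)
            row = _binned_signal(signal_track, chrom, edges)
        elif mode == "scaled_gene_body":
            chrom, start, end, strand = region[:4]
            if strand not in ("+", "-"):
                raise ParameterError("scaled_gene_body mode requires stranded intervals")
            nb = body_bins or bins
            n_flank = max(1, bins // 4)
            up = np.linspace(start - flank, start, n_flank + 1)
            body = np.linspace(start, end, nb + 1)
            down = np.linspace(end, end + flank, n_flank + 1)
            edges = np.concatenate([up[:-1], body[:-1], down])
            row = _binned_signal(signal_track, chrom, edges)
        else:
            raise ParameterError(f"unknown mode {mode!r}")
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    matrix = np.vstack(rows) if rows else np.zeros((0, bins))
    mean_profile = matrix.mean(axis=0) if len(rows) else np.zeros(matrix.shape[1])
    return matrix, mean_profile


def _binned_signal(track, chrom: str, edges: np.ndarray) -> np.ndarray:
    sub = track.on_chrom(chrom)
    starts = sub["start"].to_numpy(dtype=float)
    ends = sub["end"].to_numpy(dtype=float)
    scores = (sub["score"].to_numpy(dtype=float)
              if "score" in sub.columns else np.ones(len(sub)))
    out = np.zeros(len(edges) - 1)
    for b in range(len(out)):
        lo, hi = edges[b], edges[b + 1]
        if hi <= lo:
            continue
        ov = np.minimum(ends, hi) - np.maximum(starts, lo)
        ov = np.clip(ov, 0, None)
        out[b] = float((ov * scores).sum() / (hi - lo))
    return out
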