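"""Common-insertion-site (CIS) calling by Gaussian kernel convolution.

Insertion positions pooled over all samples of a screen are smoothed with a
Gaussian kernel of bandwidth ``scale`` (the scale parameter, in bp).
Genomic regions whose smoothed density exceeds a permutation-calibrated
threshold are called as CISs — regions hit by transposons more often than
expected by chance, i.e. evidence of clonal selection.

Error control: the null distribution is built by repeatedly drawing the
same number of insertions uniformly from the TTAA-eligible sites of the
genome and recording the genome-wide maximum peak height.  The calling
threshold is the (1 - alpha) quantile of those maxima, so on a fully null
screen the probability of calling any CIS is ~alpha (family-wise control
at an average error level of alpha, default 5%).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ParameterError
from .insertion_io import InsertionTable

SQRT2PI = math.sqrt(2.0 * math.pi)
#: kernel support truncated at +/- TRUNC * scale; error < 1e-4 of mass
TRUNC = 4.0
DEFAULT_SCALES = (5_000, 10_000, 20_000, 30_000, 50_000, 70_000, 90_000)
DEFAULT_BLACKLIST = ("Sfi1", "Arid1b", "Mmp16")


@dataclass
class DensityProfile:
    """Kernel-smoothed insertion density on a regular grid."""

    chrom: str
    grid_start: int
    grid_step: int
    values: np.ndarray
    scale: float

    @property
    def grid(self) -> np.ndarray:
        return self.grid_start + self.grid_step * np.arange(len(self.values))

    def integral(self) -> float:
        """Grid integral; approximately the number of contributing insertions."""
        return float(self.values.sum() * self.grid_step)


@dataclass
class CIS:
    """A scored common insertion site (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_height: float
    p_value: float
    n_insertions: int
    n_samples: int
    scale: float

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def cis_id(self) -> str:
        return f"CIS_{self.chrom}_{self.start}_{self.end}"


@dataclass
class NullCalibration:
    """Permutation-null calibration of the peak-height threshold."""

    scale: float
    n_perm: int
    alpha: float
    threshold: float
    seed: int
    grid_step: int
    null_max: np.ndarray = field(repr=False, default=None)


def _default_grid_step(scale: float) -> int:
    return max(1, int(round(scale / 10)))


def kernel_density(
    positions,
    scale: float,
    grid_step: int | None = None,
    chrom: str = "",
    grid_start: int | None = None,
    grid_end: int | None = None,
) -> DensityProfile:
    """Exact Gaussian-kernel density of insertion positions on one chromosome.

    ``values[g] = sum_i exp(-((g - pos_i)/scale)^2 / 2) / (scale * sqrt(2*pi))``
    with kernels truncated at +/- 4 * scale.  The grid is aligned to
    multiples of ``grid_step`` so results are independent of input order.
    """
    if scale <= 0:
        raise ParameterError("scale must be > 0")
    if grid_step is None:
        grid_step = _default_grid_step(scale)
    if grid_step > scale / 4:
        raise ParameterError("grid_step must be <= scale/4")
    positions = np.asarray(positions, dtype=np.float64)
    if positions.size == 0:
        return DensityProfile(chrom, 0, grid_step, np.zeros(0), scale)
    if np.any(np.diff(positions) < 0):
        positions = np.sort(positions)
    lo = positions[0] - TRUNC * scale if grid_start is None else grid_start
    hi = positions[-1] + TRUNC * scale if grid_end is None else grid_end
    g0 = int(math.floor(lo / grid_step)) * grid_step
    n_grid = int(math.floor((hi - g0) / grid_step)) + 1
    values = np.zeros(n_grid)

    # scatter each kernel onto its grid window (exact, vectorized)
    half = int(math.ceil(TRUNC * scale / grid_step)) + 1
    center_idx = np.round((positions - g0) / grid_step).astype(np.int64)
    rel = np.arange(-half, half + 1)
    idx = center_idx[:, None] + rel[None, :]
    gpos = g0 + idx.astype(np.float64) * grid_step
    u = (gpos - positions[:, None]) / scale
    contrib = np.exp(-0.5 * u * u) / (scale * SQRT2PI)
    keep = (np.abs(u) <= TRUNC) & (idx >= 0) & (idx < n_grid)
    np.add.at(values, idx[keep], contrib[keep])
    return DensityProfile(chrom, g0, grid_step, values, scale)


def _null_max_peak(ttaa_concat: np.ndarray, chrom_offsets: np.ndarray,
                   n_insertions: int, scale: float, grid_step: int,
                   rng: np.random.Generator) -> float:
    """Max peak height of one permutation: n insertions uniform over TTAA sites."""
    draw = ttaa_concat[rng.integers(0, len(ttaa_concat), size=n_insertions)]
    chrom_of = np.searchsorted(chrom_offsets, draw, side="right") - 1
    best = 0.0
    for c in np.unique(chrom_of):
        pos = np.sort(draw[chrom_of == c])
        prof = kernel_density(pos, scale, grid_step)
        if prof.values.size:
            best = max(best, float(prof.values.max()))
    return best


def calibrate_null(
    ttaa_index,
    n_insertions: int,
    scale: float,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    grid_step: int | None = None,
) -> NullCalibration:
    """Calibrate the peak-height threshold against a uniform-TTAA null.

    Each permutation draws ``n_insertions`` positions uniformly (with
    replacement) from the eligible TTAA sites and records the genome-wide
    maximum of the smoothed density; the threshold is the (1 - alpha)
    quantile of those maxima.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if grid_step is None:
        grid_step = _default_grid_step(scale)
    sites = ttaa_index.positions if hasattr(ttaa_index, "positions") else dict(ttaa_index)
    chroms = sorted(sites)
    arrays = [np.asarray(sites[c], dtype=np.int64) for c in chroms]
    if sum(a.size for a in arrays) == 0:
        raise AnalysisError("TTAA index is empty")
    # concatenate with large per-chromosome offsets so one flat draw suffices
    offsets = np.concatenate([[0], np.cumsum([a[-1] + 1 if a.size else 1 for a in arrays])])[:-1]
    concat = np.concatenate([a + off for a, off in zip(arrays, offsets)])
    rng = np.random.default_rng(seed)
    null_max = np.array([
        _null_max_peak(concat, offsets, n_insertions, scale, grid_step, rng)
        for _ in range(n_perm)
    ])
    threshold = float(np.quantile(null_max, 1.0 - alpha))
    return NullCalibration(scale, n_perm, alpha, threshold, seed, grid_step, null_max)


def call_cis(
    table: InsertionTable,
    scale: float,
    alpha: float,
    calibration: NullCalibration,
    min_insertions: int = 1,
) -> list[CIS]:
    """Call CISs as maximal grid runs with density >= calibrated threshold.

    Each CIS is annotated with its peak, the number of insertions and
    distinct samples inside the interval, and a permutation p-value (the
    fraction of null genome-wide maxima at or above the observed peak).
    The list is sorted by n_insertions, descending.
    """
    if calibration.scale != scale:
        raise ParameterError(
            f"calibration scale {calibration.scale} != requested scale {scale}")
    if calibration.alpha != alpha:
        raise ParameterError(
            f"calibration alpha {calibration.alpha} != requested alpha {alpha}")
    out: list[CIS] = []
    df = table.data
    for chrom in table.chromosomes():
        sub = df[df["chrom"] == chrom]
        pos = np.sort(sub["pos"].to_numpy())
        prof = kernel_density(pos, scale, calibration.grid_step, chrom=chrom)
        above = prof.values >= calibration.threshold
        if not above.any():
            continue
        # maximal runs of above-threshold grid points
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for i0, i1 in zip(edges[::2], edges[1::2]):  # [i0, i1) grid indices
            start = int(prof.grid_start + i0 * prof.grid_step)
            end = int(prof.grid_start + i1 * prof.grid_step)
            run = prof.values[i0:i1]
            peak_rel = int(np.argmax(run))
            peak_pos = int(prof.grid_start + (i0 + peak_rel) * prof.grid_step)
            inside = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
            n_ins = len(inside)
            if n_ins < min_insertions:
                continue
            peak_height = float(run[peak_rel])
            p_value = float(np.mean(calibration.null_max >= peak_height))
            out.append(CIS(
                chrom=chrom, start=start, end=max(end, peak_pos + 1),
                peak_pos=peak_pos, peak_height=peak_height, p_value=p_value,
                n_insertions=n_ins, n_samples=int(inside["sample"].nunique()),
                scale=scale,
            ))
    return rank_cis(out, key="n_insertions")


def recurrence_filter(
    cis_list: list[CIS], table: InsertionTable, min_sample_frac: float = 0.10
) -> list[CIS]:
    """Keep CISs found in at least ``min_sample_frac`` of screen samples
    (threshold = ceil(frac * n_samples), with a guard against float noise)."""
    n_samples = len(table.samples)
    need = math.ceil(min_sample_frac * n_samples - 1e-9)
    return [c for c in cis_list if c.n_samples >= need]


def apply_blacklist(cis_list: list[CIS], gene_model, blacklist_names=DEFAULT_BLACKLIST) -> list[CIS]:
    """Remove CISs overlapping known artefact genes (default: Sfi1 — a
    recurrent insertional-mutagenesis artefact — plus the donor-proximal
    Arid1b and Mmp16)."""
    import warnings

    spans = []
    for name in blacklist_names:
        iv = gene_model.gene_interval(name)
        if iv is None:
            warnings.warn(f"blacklist gene {name!r} not in gene model; ignored")
        else:
            spans.append(iv)
    kept = []
    for c in cis_list:
        hit = any(ch == c.chrom and s < c.end and e > c.start for ch, s, e in spans)
        if not hit:
            kept.append(c)
    return kept


def rank_cis(cis_list: list[CIS], key: str = "n_insertions") -> list[CIS]:
    """Stable descending sort by ``n_insertions`` or ``n_samples``; ties by
    peak height then coordinates."""
    if key not in ("n_insertions", "n_samples"):
        raise ParameterError(f"unknown ranking key {key!r}")
    return sorted(
        cis_list,
        key=lambda c: (-getattr(c, key), -c.peak_height, c.chrom, c.start),
    )


def scale_sweep(
    table: InsertionTable,
    ttaa_index,
    scales=DEFAULT_SCALES,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
    genes=None,
    min_insertions: int = 1,
):
    """Re-call CISs at each scale; summarize count, median width, and (when a
    gene model is given) the intergenic fraction.  Returns a DataFrame with
    one row per scale."""
    import pandas as pd

    from .annotation import intergenic_fraction

    scales = list(scales)
    if len(scales) < 2:
        raise ParameterError("scale_sweep requires >= 2 scales")
    n_total = len(table)
    rows = []
    for i, scale in enumerate(scales):
        calib = calibrate_null(ttaa_index, n_total, scale, n_perm, alpha, seed=seed + i)
        cis = call_cis(table, scale, alpha, calib, min_insertions=min_insertions)
        row = {
            "scale": scale,
            "n_cis": len(cis),
            "median_width": float(np.median([c.width for c in cis])) if cis else float("nan"),
        }
        if genes is not None and cis:
            row["intergenic_fraction"] = intergenic_fraction(cis, genes)[0]
        rows.append(row)
    return pd.DataFrame(rows)


def cis_to_frame(cis_list: list[CIS]):
    """CIS list as a BED6+ style DataFrame (score = n_insertions)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "chrom": c.chrom, "start": c.start, "end": c.end, "name": c.cis_id,
            "score": c.n_insertions, "strand": ".", "peak_pos": c.peak_pos,
            "peak_height": c.peak_height, "p_value": c.p_value,
            "n_samples": c.n_samples, "scale": c.scale,
        }
        for c in cis_list
    ], columns=["chrom", "start", "end", "name", "score", "strand", "peak_pos",
                "peak_height", "p_value", "n_samples", "scale"])


def frame_to_cis(df) -> list[CIS]:
    """Inverse of :func:`cis_to_frame`."""
    return [
        CIS(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            peak_pos=int(r.peak_pos), peak_height=float(r.peak_height),
            p_value=float(r.p_value), n_insertions=int(r.score),
            n_samples=int(r.n_samples), scale=float(r.scale))
        for r in df.itertuples()
    ]
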