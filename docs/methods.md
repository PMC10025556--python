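# Methods

## CIS calling by Gaussian kernel convolution

Insertion positions from all samples of a screen are pooled per chromosome
and smoothed with a Gaussian kernel of bandwidth `scale` (bp):

```
f(g) = Σ_i exp(−(g − x_i)² / 2·scale²) / (scale·√(2π))
```

evaluated on a regular grid (`grid_step = scale/10` by default, anchored to
multiples of the step so results do not depend on input order).  Kernels
are truncated at ±4·scale, which discards < 10⁻⁴ of each kernel's mass and
keeps the computation exact elsewhere — the implementation scatters each
kernel onto its grid window rather than binning positions first, so grid
values equal the direct Gaussian sum to floating-point accuracy.  The grid
integral of `f` approximates the number of contributing insertions; this is
checked as a test invariant (±1%).

**Error control.**  The null model is integration with no selection:
insertions fall uniformly on the genome's TTAA sites (PiggyBac's obligate
target motif, which makes site density the correct exposure measure — see
the matched controls below).  Each of `n_perm` permutations (default 200)
draws the observed number of insertions with replacement from the TTAA
index and records the genome-wide maximum of `f`.  The calling threshold is
the (1 − α) quantile of these maxima, so a fully null screen produces ≥ 1
CIS with probability ≈ α — a family-wise-style control whose realized
average false-call level is what the package's calibration benchmark
measures.  Drawing with replacement mirrors independent integration events:
two tumors can (and do) hit the same TTAA site.  Each CIS receives
`p = (# null maxima ≥ observed peak)/n_perm`.

CIS boundaries are the threshold crossings of the density (not insertion
extremes), which makes widths deterministic and scale-consistent.  Each CIS
records its peak position/height, the insertions and distinct samples
inside the interval, and is ranked by contributing insertions (ranking by
contributing samples is available; ties break by peak height, then
coordinates).  Downstream filters: recurrence (`n_samples ≥
ceil(frac·n_total)`, default 10% of samples, with a 1e-9 guard against
float noise in the product), and a gene blacklist defaulting to Sfi1 (a
known insertional-mutagenesis artefact) plus the donor-proximal Arid1b and
Mmp16.

Insertions are weighted equally for calling; read coverage informs the
clonality analyses, not the density.  The scale parameter is exposed
throughout: ~30 kb is the classic choice for protein-coding CIS discovery,
~5 kb resolves narrow regulatory elements; `scale_sweep` re-calls across a
scale list and reports CIS count, median width and intergenic fraction.

## Insertion tables

Internally 0-based, half-open; BED output likewise.  Deduplication
collapses identical `(chrom, pos, sample)` records and **sums** their read
counts (preserving total evidence; the alternative — keeping the max — was
rejected because 5′- and 3′-end libraries of the same junction each carry
real reads).  Exact-position identity is required for collapsing; no
position tolerance is applied.  Normalization divides each read count by
its sample's top hit, so per-sample `max(norm_coverage) == 1.0` exactly and
the operation is idempotent.  The donor exclusion removes insertions within
`radius` (default 3 Mb) of the donor midpoint on the donor chromosome.

## ARCIS-style annotation

Chromatin-state segmentations are first smoothed per state: segments with
gaps ≤ 3,000 bp merge into one region (bridging whatever states lie
between), and merged regions < 4,000 bp are dropped.  The operation is
idempotent and can also merge interrelated states as groups (e.g. active
with weak enhancer).

Per CIS, the annotation records: overlap count and closest distance per
peak track (0 when overlapping; an infinity sentinel on feature-less
chromosomes), super-enhancer overlap and its labeled gene, Hi-C link
targets (the link's annotated gene when present, else any gene whose
promoter — TSS ± 2 kb, configurable — overlaps the distal anchor),
accessibility change (increasing/decreasing), and the chromatin states
overlapped.  Chromosome-naming mismatches between inputs ('chr1' vs '1')
are a hard error rather than a silent zero-overlap.

**RE-score** is a weighted sum over four binary evidence classes
(super-enhancer overlap, increasing accessibility, active/weak enhancer
state, ≥ 1 Hi-C link); unit weights give an integer 0–4.  Binary
contributions were chosen over graded ones so that one feature-rich track
cannot dominate; a graded Hi-C variant sits behind a flag.

**RE categories** follow a rule cascade:
(a) no gene overlap → *intergenic_enhancer* given any enhancer evidence,
else *unresolved*; (b) protein-coding overlap + orientation-unbiased
insertions + Hi-C link to a non-host gene + host expression at/below the
cutoff → *intronic_enhancer_distal_target*; (c) non-coding overlap only →
*ncRNA*; (d) protein-coding + ncRNA overlap with insertions in both
orientations → *pc_plus_ncRNA*; (e) otherwise *pc_gene*.  "Unbiased
orientation" is an exact two-sided binomial test against 0.5 with p > 0.05
(no published threshold exists; 0.05 is the package's choice).  "Absent
host expression" means ≤ 0 in the supplied expression table; with no table
the criterion is treated as non-applicable (it passes), since it is an
auxiliary "often absent" indicator rather than a hard requirement.  The
tie-break order among (b)–(d) is this cascade's own choice and every
annotation carries a rationale string recording which rule fired.  Genic
means protein-coding or immunoglobulin biotype; all other biotypes count as
intergenic for the intergenic-fraction summary.

Target-gene priority: Hi-C-linked gene > super-enhancer-assigned gene >
nearest protein-coding TSS within 500 kb > none, ties by distance then
name.

## Matched controls and footprint envelopes

For each CIS, control regions are drawn on the same chromosome with
identical width, a TTAA count within ±10% (relative) of the CIS count, and
no overlap with any real CIS; the CIS's relative peak position is copied
onto each control.  Sampling is rejection-based (uniform placements, capped
at 10,000 draws), falling back to the nearest-TTAA-count non-overlapping
candidates with a warning when strict matches are scarce.  The ±10%
tolerance and the cap are package defaults; the matching features
(chromosome, width, TTAA count) are what make TTAA-target integration
backgrounds fair.

Footprint profiles report, per bin around region centers (±10 kb, 101 bins
by default, i.e. ~200 bp bins), the **fraction of regions** whose bin
window overlaps ≥ 1 track interval — bounded in [0, 1] and comparable
across bins, which is why region-fraction was chosen over interval counts.
The bootstrap envelope draws one control per CIS per iteration (default
100 iterations) and takes the per-bin 97.5% quantile.  Under the null the
observed profile stays below the envelope at ≈ 2q − 1 of bins on average;
a planted signal at CIS centers exceeds it at the center bin.

## Screen statistics

Fisher's exact test is the hypergeometric exact computation (two-sided sums
all tables with probability ≤ observed, with a small tie tolerance);
sidedness is always an explicit argument, since published tables rarely
state it — the package's tests pin one published table to its two-sided
value and another to its one-sided value, as the printed numbers imply.
Density enrichment merges regions before width summation (shared bp counted
once), computes variants/Mb inside vs genome-wide, and tests observed-inside
against its genome-proportional expectation with a 1-df Pearson χ².
Gene-level over-representation is a 2×2 Pearson χ² (no continuity
correction) against the 19,370-gene protein-coding universe.  Variant sets
arrive pre-pruned for linkage disequilibrium and pre-lifted between
genomes; their provenance fields record the external parameters (e.g.
R² = 0.8, MAF = 0.01).  High-coverage pair detection enumerates, within
each sample, unordered same-chromosome pairs of ≥ 1,000-read insertions
within 50 kb.

## Synthetic screens

The simulator generates what the pipeline needs and nothing more
sequence-realistic than that:

* **Genomes**: random sequence scrubbed of incidental TTAA, with motifs
  planted at the requested density (default 1/300 bp, in the range of
  AT-rich mammalian sequence).  The TTAA index is built by scanning the
  final sequence, so it is exact by construction.
* **Screens**: per sample, a fixed number of background insertions drawn
  uniformly from TTAA sites (optionally re-weighted ×3 inside an
  "open-chromatin" track — the magnitude of the real integration bias is
  not established, so it is a free parameter), a configurable local-hop
  fraction displaced from the donor by a Laplace kernel (the decay form is
  a modeling choice; only the phenomenon, strong proximity bias, is
  documented), and per-driver insertions with per-sample hit probability
  0.9 — strong clonal selection makes driver insertions recurrent in most
  tumors, and this default places planted clusters in the ≥ 20-insertion
  regime that the recovery guarantees are stated for.  Read counts are
  twice a geometric clone size (p = 0.02), multiplied by the driver's
  selection strength and clipped to [2, 10,000], reproducing the
  heavy-tailed normalized-coverage structure the clonality analyses need.
  Every insertion carries exactly one truth label (background, local_hop,
  driver:i).
* **Tracks/variants**: planted REs emit exactly the evidence their category
  implies (peak, increasing accessibility, active-enhancer state, Hi-C link
  to the named target's promoter) plus optional uniform noise intervals;
  variants are Poisson-placed at separate inside/outside rates.

What the simulator does **not** emulate: real sequence composition and
mappability, GC structure, integration-site biochemistry, subclonal
phylogenies, and inter-sample contamination.  Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated generative assumptions, not performance on any particular real
screen.

## Calibration benchmarks and problem sizes

`benchmark.false_call_benchmark` (also the engine of
`scripts/acceptance.py`) simulates 50 replicate screens on a 10 Mb genome —
30 samples, ~200 insertions/sample, 5 planted 5 kb drivers at selection
strength 12 — calls CISs at scale 5 kb and α = 5% with a 200-permutation
null shared across replicates (same genome, same insertion count, hence
the same null), and reports the mean proportion of called CISs not
overlapping a planted locus, plus how often drivers occupy the top ranks.
A 10 Mb genome at ~0.6 insertions/kb gives the null-fluctuation regime of a
dense screen while keeping each replicate under a second; the shared
calibration changes nothing statistically and dominates the saved time.
`benchmark.re_recovery_benchmark` plants REs of four unambiguous categories
with noise-free evidence on a 2 Mb genome and reports the classifier's
recall.

## Numerical choices and degenerate inputs

* Kernel truncation ±4·scale; grid step scale/10 (must be ≤ scale/4).
* Empty position lists yield empty profiles; empty tables yield empty CIS
  lists; an empty CIS list makes the intergenic fraction an error rather
  than a NaN.
* Quantiles use numpy's default linear interpolation.
* The recurrence ceiling subtracts 1e-9 before `ceil` so that 10% of 60
  samples is 6, not 7.
* All stochastic operations take explicit seeds; CLI reruns with the same
  config and seeds are byte-identical, and every primary output embeds a
  hash of its run configuration.
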