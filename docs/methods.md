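# Methods

This note documents the statistical models, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate,
and the numerical decisions taken where the underlying experimental
protocol leaves the computation open.

## 1. SILAC ChIP-MS interactor calling

### Model

The experiment is a triple-SILAC chromatin immunoprecipitation:
light = untreated asynchronous cells with bait (FANCD2) ChIP,
medium = APH-treated synchronized cells with IgG control ChIP,
heavy = APH-treated synchronized cells with bait ChIP. Per protein
group and per experiment, MaxQuant-style output reports ratios
H/M (bait over background under stress) and H/L (stressed bait ChIP
over unstressed cells). A pilot experiment may contribute only H/M;
the `ExperimentDesign` declares channel availability per experiment.

The cascade is:

1. **Identification filter** — ≥ 2 razor+unique peptides, not a
   contaminant, not a decoy. Contaminants/decoys are recognized by `+`
   flag columns *and* by `CON__`/`REV__` accession prefixes, because
   both conventions occur across MaxQuant versions.
2. **Tier 1 (potential interactor)** — H/M ≥ `fold_threshold` (default
   1.5) in strictly more than half of the experiments in which H/M was
   quantified. "More than half" is read literally: 1 of 2 fails, 2 of 3
   passes, 1 of 1 passes; a protein with no quantified ratio never
   passes (and never errors). The threshold comparison is inclusive
   (≥), matching "at least 1.5-fold".
3. **Tier 2 (APH-induced recruit)** — tier 1 *and* the same majority
   rule over H/L, restricted to experiments that carry an H/L channel.
   The aggregation rule for tier 2 is not dictated by the protocol;
   majority was chosen for symmetry with tier 1.

"Quantified" means a ratio is present in the table; identification
without quantification is not distinguishable in protein-group output
and is treated as missing.

Ranking uses the median of log2(H/M) over quantified experiments,
descending, ties broken by gene symbol; "most enriched" has no
canonical statistic and the median is robust to a single outlier
experiment. Normalized ratio columns are preferred over raw ones when
both exist, since MaxQuant's normalization corrects channel-loading
differences. Ratios are used exactly as exported — the design must
declare channel identity; nothing is inferred or re-inverted.

### Parameters

| parameter | default | notes |
| --- | --- | --- |
| `fold_threshold` | 1.5 | fold change, dimensionless; > 1 enforced |
| peptide floor | 2 | razor + unique peptides |

## 2. Term enrichment and network

Over-representation of a term with K members (within a universe of N
genes) among n selected genes with k hits is the upper-tail
hypergeometric probability P[X ≥ k]. The universe defaults to all genes
in the supplied annotation; a genome-scale reference is only meaningful
relative to a fixed annotation release, which the caller controls by
supplying the file. Multiple testing uses Benjamini–Hochberg across all
tested terms. Terms with no gene in the universe are skipped and
logged; a selection gene absent from the universe is an error rather
than a silent drop. This is a standard over-representation test, not a
re-implementation of any specific web service's variant statistic.

The network step takes a three-column scored edge table (STRING-like,
scores in [0, 1]) and keeps an edge iff both endpoints are called
interactors and score ≥ `min_score` (default 0.4, the conventional
"medium confidence" cut). Isolated called genes remain as nodes; node
attributes carry the ranking statistic and the APH-induced flag so a
renderer can reproduce the color/shape encoding of an interactome
figure. Export is GraphML; layout is out of scope.

## 3. QIBC

### Segmentation

Global Otsu threshold on DAPI (max projection for stacks), hole
filling, connected components, size filter `[min_area, max_area]`
(defaults 120–5000 px² at the generator's scale). Sub-`min_area`
objects are retained as micronucleus candidates: a candidate with area
≤ `max_mn_area` (80 px²) whose centroid lies within `search_radius`
(20 px) of a nucleus boundary is counted for the nearest nucleus.

### Cell-cycle gating

EdU-positive/negative split by a two-component Gaussian-mixture
threshold on log10 mean EdU (Otsu fallback when the fit degenerates; a
spread-less EdU channel gates everything EdU-negative). The 2N and 4N
DAPI modes are located by a two-component mixture on the EdU-negative
population; if the modes are closer than twice the larger component SD
the distribution is declared unimodal and a `GatingError` instructs
manual thresholds. EdU-negative cells are G1/G2 by the nearer mode;
EdU-positive cells split into early/mid/late S at DAPI terciles of the
2N–4N interval. With the optional Cyclin A gate (the selection used for
G1-specific structures such as 53BP1 nuclear bodies), EdU-negative
cells are G1 iff Cyclin A-negative.

### Foci detection

Difference of Gaussians at (`spot_sigma`, 1.6·`spot_sigma`) followed by
local maxima (minimum distance ≈ `spot_sigma`). A maximum is kept when
its band-passed response exceeds the nucleus' robust background by
`rel_threshold` robust SDs. The noise scale (1.4826·MAD) is estimated
from the band-passed response *outside* nuclei, because inside a
focus-rich nucleus the spots themselves dominate any pixel statistic;
the per-nucleus median provides the local offset and is clamped from
below at the background median since spot rings bias it downward.
Relative thresholding makes counts invariant to positive rescaling of
the image. Default `rel_threshold` = 6: detection of unit-amplitude
spots is lossless at the generator's noise levels while the expected
number of false maxima per nucleus is ≪ 1 (a 6-robust-SD exceedance).

### Colocalization

*Object level*: candidate A–B pairs within 2·`overlap_radius` are
matched greedily by increasing distance (ties by channel-A then
channel-B index), each focus used at most once; matched pairs at
distance ≤ `overlap_radius` are overlapping, the rest adjacent. The
default radius is 2·`spot_sigma` — about one PSF width — and the
adjacent band ends at twice that; the overlap/adjacent distinction is
morphological, not statistical.

*Pixel level (Costes-style)*: the observed Pearson r over mask pixels
is compared with r recomputed after shuffling channel B in
`block_px`×`block_px` tiles over the mask bounding box (default 5 px ≈
the PSF, the scale at which true spatial correlation lives), with
p = (1 + #{r_rand ≥ r_obs}) / (n_rand + 1). The p-value floor is
therefore 1/(n_rand+1); the default n_rand = 1000 resolves p = 0.001.
Under a true null (independent channels) the block permutation makes
the observed arrangement exchangeable with the shuffles, so p is
uniform — verified by simulation in the test suite. A constant channel
within the mask has undefined r and raises rather than returning a
sentinel.

## 4. Cytogenetic statistics

Per-group summaries report mean, SD (n−1) and SEM = SD/√n of per-spread
gap+break counts, gaps and breaks pooled into one count per spread.
Group comparisons use the unpaired t-test, Welch by default — the
variance-homogeneity assumption is rarely defensible for count data and
Welch costs little when variances are equal; a flag restores the
pooled-variance variant. Both groups constant and equal returns
(t = 0, p = 1) rather than NaN. Fragile-locus breakage uses Pearson
chi-square on the k×2 broken/intact table without continuity correction
(a flag enables Yates for 2×2); expected counts below 1 trigger a
warning recommending an exact test. MiDAS fractions pool EdU-positive
over total breaks per group with Wilson 95% intervals, which behave at
the 0 and 1 boundaries where Wald intervals collapse.

## 5. Synthetic-data generators

All generators take an integer seed and are bit-reproducible; every
generated record appears in the truth labels exactly once.

**Proteomics.** Log2 ratios are Normal — i.e. log-normal ratios, the
standard error model for SILAC — with sd `ratio_noise_sd` (default
0.3). Background centres at 0; interactors at
`log2_effect_bait_vs_igg` = 1.5 on H/M; APH-responsive interactors
additionally at 1.5 on H/L. Each per-experiment ratio is missing
completely at random with `missing_prob` = 0.2. The default population
(668 background + 226 interactors of which 45 APH-responsive, ≈ 26%
single-peptide rows, three H/M experiments of which two carry H/L — the
third being the pilot) mirrors the screen design the package targets.
The replicate-to-replicate dispersion of the real screen is unknown;
0.3 log2 units is a typical SILAC spread, not an estimate of it.
`cascade_fixture` is the deterministic companion: jitter is drawn away
from the threshold so its margins (894/229/226/45) are forced by
construction, independent of the seed.

**Imaging.** Nuclei are non-overlapping disks (radius 16 px) and foci
are isotropic Gaussians (σ = 1.5 px, amplitude 1) — minimal geometry
chosen so every measurement has an analytic ground truth, not realism.
DAPI integrated intensity interpolates linearly between the 2N and 4N
means (CV 6%) across S-phase positions (0, ¼, ½, ¾, 1); EdU per-pixel
intensity is 1.0 in S stages and 0.05 otherwise. Per-stage foci rates
default to the rising pattern that CFS-marking factors show (1, 2, 3,
5, 6 foci for G1 → G2), with the stressed condition at 1.5× in the
composite fixture; rates and the 0.3 colocalization fraction are
package choices of realistic magnitudes — the underlying distributions
are published only as box plots. Planted foci keep a 5 px minimum
separation, matching the optical resolution limit of the σ = 1.5
detector; the default population of 700 cells per condition matches
the per-condition cell counts of the targeted assay class. Stage mix
(0.40/0.12/0.12/0.11/0.25) is a typical asynchronous cycling line.

What the generator does *not* emulate: nucleus shape/texture variation,
clumping and touching nuclei, varying focus amplitude, chromatic
offsets, uneven illumination, 3D defocus, photobleaching. Passing
tests therefore demonstrate correctness of the measurement logic under
the model's assumptions, not robustness to real-microscope artifacts.

**Cytogenetics.** Per-spread break totals are Poisson with per-group
means; each break is EdU-positive with a per-group probability; locus
scoring is Bernoulli per locus. Defaults (40 spreads/group, 120 scored
loci, four siRNA × treatment groups with rates rising from 0.3 to 3
breaks/spread) match the scale of the targeted assays; the rate values
themselves are plausible magnitudes, not published numbers.

## 6. Pipeline

A strict-schema YAML config (unknown keys rejected) drives
simulate → interactome → enrichment/network → QIBC → statistics. A
single global seed fans out deterministically to per-module seeds; the
run report records per-stage counts and SHA-256 hashes of every output,
and rerunning an identical config reproduces identical hashes. The
Costes stage samples up to 25 G2 nuclei per condition (bounding-box
crops) to bound runtime at n_rand = 1000.

## 7. Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the imaging arm at
120–250 cells on 1000–1300 px frames, the Costes null at 200 runs of
99 randomizations on 40×40 frames, the classification oracle at 120
Monte-Carlo replicates of the full 894-row population, and the t-test
calibration at 2000 null replicates of n = 40 — sizes at which every
Monte-Carlo bound in the suite has comfortable margin while the whole
suite stays fast on one CPU.

## 8. Known limitations

- The enrichment statistic is the plain hypergeometric; conservative
  variants (e.g. EASE-style leave-one-out) will give larger p-values on
  small k.
- Gating assumes a bimodal DAPI distribution; heavily aneuploid or
  synchronized populations need manual thresholds (the error path).
- Object colocalization matching is greedy, not optimal assignment;
  for the sparse foci densities generated here the difference is
  negligible.
- The Costes block shuffle permutes tiles over the mask bounding box;
  for masks much smaller than their bounding box the effective
  randomization support includes out-of-mask context.
- Break/gap scoring itself (what counts as a break on a spread) is
  manual and upstream of this package; only the scored counts enter.
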