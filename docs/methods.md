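# Methods

This note documents the models and procedures implemented in `replidyn`,
the defaults that matter, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Fiber image quantification

### Localization

Fibers are detected on the ssDNA counterstain when present (otherwise on
the per-pixel maximum of the two label channels) with a multiscale
Hessian line filter (Sato vesselness, bright ridges), maximum over scales
(default sigmas 1.0, 1.6, 2.4 px), normalized to [0, 1]. The exact ridge
detector used in the original analysis pipeline this stage re-creates is
under-specified in the literature; Hessian line filtering is the standard,
testable choice for the same detection goal, and the scale set brackets a
~1.5-px PSF.

Fragmented fibers are reconnected by a spatially variant grayscale
closing: the local ridge direction (minor eigenvector of the structure
tensor, 8 orientation bins centered on k*pi/8 so axis-aligned fibers get
an axis-aligned element) selects a linear structuring element of 20 px
(at least the size of typical disconnections). The closing is extensive
(output >= input pointwise) and idempotent for a fixed orientation field;
parallel fibers further apart than the element length are never merged.

The map is thresholded at 0.5, components are thinned to one-pixel
skeletons, spurs shorter than 5 px are pruned, and each simple-path
skeleton is fitted with a cubic smoothing B-spline and resampled at a
1-px arclength step. The smoothing factor is fixed (s = 0.2 per point,
i.e. an allowed rms residual of ~0.45 px, matching skeleton quantization
noise) rather than chosen by cross-validation, for reproducibility.
Components whose pruned skeleton still branches (crossing fibers) are
flagged ambiguous and excluded from statistics by default. Skeletonization
of a blurred line shortens each fiber end by a few pixels; end-to-end
lengths are therefore accurate to ~2-3 px per end, which is irrelevant
for boundary-based measurements (speeds, IODs) because label boundaries
are interior features.

### Branch detection and pattern classification

Channel intensities are sampled along the centerline as means over a
5-px perpendicular cross-section. Because the two analog channels are not
comparable in absolute intensity, segmentation operates on the log of the
point-wise channel ratio after background subtraction (background = image
median, spread = 1.4826 x MAD). A point is "labeled" when the summed
background-subtracted signal exceeds 3 background s.d. and 20% of the
profile peak; the relative floor places the track edge near the
half-response point of the PSF, keeping track-length bias below ~0.3 um.

Labeled stretches are partitioned by a CART-style regression tree:
recursive binary splitting of the log-ratio sequence minimizing
within-segment SSE, with a split accepted only when its error reduction
is at least a fraction (default 0.01) of the profile's total SSE and both
children span at least 1 um. The boundaries chosen by the tree are then
re-placed exactly by dynamic programming over all partitions with that
number of segments, so the reported changepoints coincide with an
exhaustive SSE search (the tree decides *how many* segments; the DP
decides *where*). Leaves map to first/second label by the sign of the
mean log ratio; leaves with |mean| < 0.2 (dead zone) merge into the
neighbor with the closest mean. The segmentation is invariant to a common
positive rescaling of both channels.

Pattern classes follow a fixed grammar over the label sequence (unlabeled
gaps shorter than 2 um are elided; larger gaps split the fiber into
independent events): [first,second] (either order) = ongoing fork;
[first] = stalled after the first label; [second] = second-pulse origin;
[second,first,second] = first-pulse origin; [first,second,first] =
termination; four or more alternations = multi-origin, decomposed into
flanked-first-track origin events for counting. Anything else is
ambiguous by contract and routed to the review queue, which emits a
flagged-fiber table and applies an accept/reject id list
deterministically.

### Measurements

Fork speed uses 1 um = 2 kb: speed = track_um x 2 / pulse_min. Ongoing
forks are measured on the second-pulse track; first-pulse-only fibers are
excluded from speed but counted in pattern proportions (whether the
original measurements used first-, second- or averaged tracks is not
documented; the second-pulse convention is standard for ongoing forks).
Origins are midpoints of adjacent first/second label boundary pairs; IODs
are consecutive origin differences (reported in um and kb). "Pairwise
difference between origins" is interpreted as consecutive differences
along a fiber — all-pairs differences would not be an IOD. Pattern
proportions are compared by the two-sample proportion test with Yates
continuity correction; group comparisons use the two-sided Wilcoxon
rank-sum test (exact for small untied samples, tie-corrected normal
approximation otherwise) or Welch's t-test, with boxplot summaries in the
median/IQR/whisker convention. Identical constant samples return p = 1 by
contract.

## Cell-cycle compartment model

Cells progress G1 -> S -> G2/M with fixed durations (defaults 3, 6, 3 h)
and convert to the 2CLC state with a constant hazard per phase. The
expected converted fraction is the cohort integral of
1 - exp(-cumulative hazard), with the cumulative hazard computed exactly
piecewise (ages wrap through the cycle). Initial age distributions per
design: G1/S release = point mass at S entry; G1 sort = uniform over G1
ages; G2/M release = point mass at cycle end (i.e. G1 entry); asynchronous
= uniform over the cycle (a flat age density is an adequate stand-in for
the mildly non-uniform steady-state age structure at this precision).
Uniform densities are integrated by a 64-node midpoint rule; an optional
phase-duration dispersion is modeled as a common lognormal cycle-speed
factor via 7-node Gauss-Hermite quadrature (off by default). The horizon
is one cycle: both fates divide, so fractions are unchanged by division
and no division bookkeeping is attempted; 2CLC-to-ESC reversion is
ignored on this timescale (it operates over days, the experiments over
hours).

The feasible region evaluates the joint SSE of every grid triple
(default 41 log-spaced points per axis over [1e-4, 1] per hour) against
all observed curves and accepts {theta : SSE <= SSE_min + delta} with
delta = z^2 sigma_hat^2 N (z = 1.96 default, N observed points,
sigma_hat pooled replicate scatter, falling back to binomial error
without replicates). The accepted set is projected onto the ratio plane
(f_G1/f_S, f_G2M/f_S); the reported "intercepts" are the maximal feasible
ratios, i.e. where the upper-right frontier cuts the axes. Identifiability
is surfaced rather than hidden: with a single design and time point the
accepted set is a slab spanning the grid in the unseen directions.

A modeling constraint worth stating explicitly: with phase durations
(3, 6, 3) h, cohorts released at G1/S or sorted in G1 occupy G2/M only
for observation times beyond ~6 h. Time courses must therefore span a
full cycle (hourly over 0-12 h in the packaged experiment design) for the
G2/M hazard to be constrained at all; with sampling truncated at S-phase
completion the f_G2M direction is unidentified and the feasible region
extends to the grid edge in that axis.

## Repli-seq RT analysis

Counts (or fragment midpoints) are binned at 100 kb, each fraction is
normalized to reads per million, and log2(E/L) = log2((E_rpm + c) /
(L_rpm + c)) with pseudocount c = 0.5 is smoothed per chromosome with
fixed-span tricube local-linear regression (loess degree 1; span 500 kb
= 5 bins; the span is expressed in bp because no canonical span exists
for this assay). Missing bins are interpolated only inside covered
stretches; chromosomes with fewer than 5 covered bins are excluded with a
warning. The mid fraction is used only for gene-stage classification,
matching the traditional E/L definition of RT.

Differential RT between conditions applies the fold cutoff (2-fold
default; 1.5-fold for transitional S-phase comparisons) to the per-bin
difference of smoothed log2(E/L), inclusive at the boundary, and merges
maximal runs across at most one missing bin (minimum run length 1 bin,
configurable). Swapping conditions maps every earlier region to a later
region with the identical interval (exact antisymmetry). Domains are
called by circular binary segmentation: the arc maximizing the mean-shift
t statistic is split out when it survives a permutation test (defaults
alpha = 0.01, 200 permutations with early stopping, minimum 2 bins —
permutation count sized for desk-scale profiles), and same-state
neighbors merge. Genes take the stage with the highest overlap-weighted
normalized density over the gene body, ties breaking toward the earlier
stage; stage calls agree with the sign of smoothed log2(E/L) for >= 95%
of unambiguous genes in simulation. Repeat enrichment is
log2[(class bp in regions / region bp) / (class bp / genome bp)] with an
empirical p-value from shuffling region placements within chromosomes,
lengths preserved; classes absent genome-wide are reported missing, not
infinite.

## Synthetic data: what it emulates, and what it does not

**Fiber images.** Quadratic B-spline paths with bounded curvature
(stretched-fiber morphology), 0.142-um pixels, fork events painted
analytically (speed x time x 0.5 um/kb from the origin, bidirectional,
honoring firing and stall times), Gaussian PSF sigma 1.5 px, Poisson shot
noise on a ~400 photon/px-length signal over a 10-photon background, and
2% read noise — a typical confocal regime (SNR ~ 10). Ground truth
(segments, pattern class, origins, IODs) is computed before rendering, so
recovery tests compare against exact values. Per-fork speeds are
lognormal (sigma_log 0.25) around a configurable median since the
within-cell-type speed distribution is not characterized; fibers closer
than 1 um are rejected as collisions rather than rendered ambiguously.
Not emulated: optical aberrations and field inhomogeneity, stretching
variability of the 2 kb/um factor, antibody labeling chemistry, fiber
breakage correlated with labeling. Passing recovery tests therefore
demonstrates correctness of the measurement machinery, not robustness to
every real-world artifact — the review-queue stage exists precisely for
the residual cases.

**Time courses.** Binomial FACS sampling (default 10,000 cells/point, 4
replicates, hourly over one cycle) around the compartment-model
expectation, with phase-fraction columns. The packaged S-dominant ground
truth (f_S = 0.02/h, ratios 0.1) produces ~11% converted cells by cycle
end, matching the scale of reporter-positive fractions in synchronized
cultures. FACS gating error and reporter maturation delay are not
modeled.

**Repli-seq.** A 2 x 50 Mb genome at 100-kb bins. The latent RT score is
piecewise-constant alternating early/late domains (2-6 Mb, levels
0.3-1.0) mapped to fraction weights by softmax(beta s, 0, -beta s) with
beta = 1.2 (monotone map, mid fraction peaking at s = 0), and per-bin
Poisson counts at 3M reads per fraction. Two planted 2-Mb shift blocks
(one earlier, one later; 4% of the genome — the published comparison this
emulates reported RT changes on the order of a few percent of the
genome) with delta log2(E/L) = 1.5, applied exactly on the latent scale.
Block length was set to at least four smoothing spans because local
regression attenuates the outermost bin of a step; at 2 Mb the one-bin
edge effect keeps per-block recovery well-posed. The shift magnitude
(~2.8-fold) sits comfortably beyond the 2-fold call cutoff, as planted
effects should for a detection benchmark. The MT2-like repeat class is
placed at 5x density inside earlier blocks over a 0.5% genome-wide
background; with earlier regions at 2% of the genome the exact expected
enrichment is log2(5/(1 + 4 x 0.02)) = 2.21. RPM normalization is global
per fraction, so condition-level weight-mass differences shift log2(E/L)
by a small constant (~0.07 here), which the twofold cutoff absorbs.
Not emulated: mappability and GC bias, copy-number variation, BrdU
immunoprecipitation efficiency, diploid/allele-specific RT.

## Numerical and engineering choices

- All simulators are bit-reproducible from a single integer seed
  (numpy Generator / SeedSequence); permutation tests take explicit seeds.
- Coordinates are (row, col) with pixel centers at integers; genomic
  intervals are 0-based half-open throughout (BED convention), converted
  at readers when inputs are 1-based.
- Degenerate inputs are contracts, not crashes: empty ROI, odd boundary
  counts, zero-total proportion tables, mismatched bin grids, unknown
  review ids and beyond-horizon times raise ValueError; zero-fork ratios
  and absent repeat classes are reported missing rather than infinite.
- The feasible-region SSE is evaluated in batches of 4096 grid triples to
  bound memory (~7 MB of predictions at the default grid).
- Problem sizes in the test suite (150-fiber populations, 500-fiber
  classifier cohorts, 2 x 50 Mb genomes, 20-replicate fit studies) were
  chosen so each end-to-end study is a desk-scale experiment with stable
  statistics at the stated tolerances.

## Known limitations

- Fiber end positions are biased inward by skeleton end erosion (~2-3 px
  per end); only boundary-to-boundary measurements are unbiased.
- The CART complexity parameter trades merge/split errors near the 0.01
  default; profiles with true segments shorter than 1 um are not
  resolvable by design (min-segment constraint).
- CBS significance uses 200 permutations, bounding achievable p-value
  resolution at ~0.005; raise `n_perm` for genome-scale runs.
- The compartment model assumes deterministic phase durations unless a
  dispersion is supplied, and cannot represent hazards varying within a
  phase.
- The loess smoother uses a fixed bandwidth in bp; chromosomes with very
  uneven coverage would benefit from adaptive spans, which are not
  implemented.
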